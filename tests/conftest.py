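"""Shared fixtures: toy annotations and a default simulated run."""

from __future__ import annotations

import pandas as pd
import pytest

import drsdecay as dd
from drsdecay.core_io import TranscriptModel


@pytest.fixture()
def toy_transcripts() -> list[TranscriptModel]:
    return [
        TranscriptModel("txA", "g1", 1000, utr5_len=100, cds_len=600, utr3_len=300, gc_frac=0.5),
        TranscriptModel("txB", "g1", 800, utr5_len=80, cds_len=500, utr3_len=220, gc_frac=0.4),
        TranscriptModel("txC", "g2", 2000, utr5_len=150, cds_len=1400, utr3_len=450, gc_frac=0.6),
    ]


@pytest.fixture()
def toy_gtf(tmp_path):
    """A one-gene, one-transcript GTF with a 300+700 nt exon structure and a
    100/600/300 UTR-CDS-UTR partition."""
    lines = [
        'chr1\tsrc\tgene\t1\t1200\t.\t+\t.\tgene_id "g1";',
        'chr1\tsrc\ttranscript\t1\t1200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";',
        'chr1\tsrc\texon\t1\t300\t.\t+\t.\tgene_id "g1"; transcript_id "t1";',
        'chr1\tsrc\texon\t501\t1200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";',
        'chr1\tsrc\tfive_prime_utr\t1\t100\t.\t+\t.\tgene_id "g1"; transcript_id "t1";',
        'chr1\tsrc\tCDS\t101\t300\t.\t+\t.\tgene_id "g1"; transcript_id "t1";',
        'chr1\tsrc\tCDS\t501\t900\t.\t+\t.\tgene_id "g1"; transcript_id "t1";',
        'chr1\tsrc\tthree_prime_utr\t901\t1200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";',
    ]
    path = tmp_path / "toy.gtf"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture(scope="session")
def default_sim() -> dd.SimResult:
    """A default-condition simulated degradation series (moderate size)."""
    txome = dd.simulate_transcriptome(600, seed=21)
    return dd.simulate_experiment(dd.SimConfig(n_reads_per_sample=30_000, seed=21), txome)


@pytest.fixture(scope="session")
def default_gene_counts(default_sim) -> pd.DataFrame:
    from drsdecay.quantify import build_count_matrix, primary_gene_counts

    cols = {
        s.sample_id: primary_gene_counts(
            default_sim.alignments[s.sample_id], default_sim.transcriptome.transcripts
        )
        for s in default_sim.samples
    }
    return build_count_matrix(cols)
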