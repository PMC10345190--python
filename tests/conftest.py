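"""Shared fixtures: small synthetic worlds and toy transcripts."""

import numpy as np
import pytest

from boundary_m6a import edits, predictor, simulate
from boundary_m6a.gene_models import GenomicInterval, SequenceRecord, TranscriptModel


@pytest.fixture(scope="session")
def small_fixture():
    """A 60-gene default-config world shared across tests (seed 11)."""
    return simulate.generate_genome_fixture(
        simulate.GeneratorConfig(seed=11, n_genes=60)
    )


@pytest.fixture(scope="session")
def small_records(small_fixture):
    """All-intron-deletion DeltaRecords for the 60-gene world."""
    from boundary_m6a import delta

    fx = small_fixture
    pred = predictor.SyntheticPredictor(fx.weights, fx.predictor_config)
    records = []
    for g, tx in sorted(fx.transcripts.items()):
        if tx.n_exons == 1:
            continue
        pre = fx.pre_mrna(g)
        edited = edits.delete_introns(tx, pre, "all")
        records.extend(
            delta.compute_site_deltas(
                pred(pre.sequence, g), pred(edited.sequence.sequence, g),
                edited, tx, pre.sequence,
            )
        )
    return records


def make_transcript(exon_lens, intron_lens, strand="+", chrom="chrT", offset=0,
                    gene_id="toy"):
    """Plus/minus-strand TranscriptModel from exon/intron length lists."""
    assert len(intron_lens) == max(len(exon_lens) - 1, 0)
    blocks = []
    pos = offset
    for i, L in enumerate(exon_lens):
        blocks.append((pos, pos + L))
        pos += L
        if i < len(exon_lens) - 1:
            pos += intron_lens[i]
    if strand == "+":
        exons = [GenomicInterval(chrom, s, e, "+") for s, e in blocks]
    else:
        total_len = pos - offset
        exons = [
            GenomicInterval(chrom, offset + total_len - e, offset + total_len - s, "-")
            for s, e in [(s - offset, e - offset) for s, e in blocks]
        ]
    return TranscriptModel(gene_id, f"{gene_id}.t1", exons)


@pytest.fixture
def toy_3exon():
    """Plus-strand 3-exon transcript: exon lengths 50/60/70, introns 100/100."""
    tx = make_transcript([50, 60, 70], [100, 100])
    rng = np.random.default_rng(3)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, tx.pre_mrna_length))
    return tx, SequenceRecord(tx.transcript_id, seq)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
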