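"""Gene annotation parsing, transcript selection and sequence extraction.

Internal coordinates are 0-based half-open throughout; the GTF reader converts
from GTF's 1-based closed convention at the boundary.  For every gene exactly
one transcript is retained: the one with the largest mRNA (summed exon) length,
ties broken by lexicographically smallest transcript_id.  Minus-strand
transcripts are reported 5'->3', i.e. exon lists run in transcription order and
sequences are reverse-complemented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import gffutils
from pyfaidx import Fasta

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

EXON_ROLE_SINGLE = "single"
EXON_ROLE_FIRST = "first"
EXON_ROLE_INTERNAL = "internal"
EXON_ROLE_SECOND_TO_LAST = "second_to_last"
EXON_ROLE_LAST = "last"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval. ``start`` inclusive, ``end`` exclusive."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty/inverted interval [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class SequenceRecord:
    """Named uppercase DNA sequence, 5'->3'."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TranscriptModel:
    """Exon/intron structure of one transcript, exons in 5'->3' order.

    ``cds_start_offset`` is the transcript-coordinate (mRNA) offset of the
    first CDS base, or ``None`` for non-coding transcripts.
    """

    gene_id: str
    transcript_id: str
    exons: list[GenomicInterval]
    cds_start_offset: int | None = None
    cds_end_offset: int | None = None  # exclusive, mRNA coords

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        strand = self.exons[0].strand
        genomic_starts = [e.start for e in self.exons]
        if strand == "+":
            ordered = all(a.end <= b.start for a, b in zip(self.exons, self.exons[1:]))
        else:
            ordered = all(b.end <= a.start for a, b in zip(self.exons, self.exons[1:]))
        if not ordered:
            raise ValueError(
                f"{self.transcript_id}: exons overlap or are not in 5'->3' order "
                f"(strand {strand}, starts {genomic_starts})"
            )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def mrna_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def genomic_start(self) -> int:
        return min(e.start for e in self.exons)

    @property
    def genomic_end(self) -> int:
        return max(e.end for e in self.exons)

    @property
    def pre_mrna_length(self) -> int:
        return self.genomic_end - self.genomic_start

    def intron_lengths(self) -> list[int]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append(b.start - a.end)
            else:
                out.append(a.start - b.end)
        return out

    def exon_blocks_transcript(self) -> list[tuple[int, int]]:
        """Exon intervals in pre-mRNA (transcript) coordinates, 5'->3'."""
        blocks = []
        pos = 0
        introns = self.intron_lengths() + [0]
        for exon, gap in zip(self.exons, introns):
            blocks.append((pos, pos + len(exon)))
            pos += len(exon) + gap
        return blocks

    def intron_blocks_transcript(self) -> list[tuple[int, int]]:
        blocks = self.exon_blocks_transcript()
        return [(a[1], b[0]) for a, b in zip(blocks, blocks[1:])]

    def exon_roles(self) -> list[str]:
        return classify_exons(self)

    def exon_index_at(self, transcript_pos: int) -> int | None:
        """Exon index hosting a pre-mRNA position, None if intronic."""
        for i, (s, e) in enumerate(self.exon_blocks_transcript()):
            if s <= transcript_pos < e:
                return i
        return None


def classify_exons(transcript: TranscriptModel) -> list[str]:
    """Label each exon; a 2-exon transcript's first exon is both first and
    second-to-last (the second-to-last role is carried separately)."""
    n = transcript.n_exons
    if n == 1:
        return [EXON_ROLE_SINGLE]
    roles = []
    for i in range(n):
        if i == 0:
            roles.append(EXON_ROLE_FIRST)
        elif i == n - 1:
            roles.append(EXON_ROLE_LAST)
        else:
            roles.append(EXON_ROLE_INTERNAL)
    return roles


def second_to_last_index(transcript: TranscriptModel) -> int | None:
    """Index of the second-to-last exon; None for single-exon transcripts."""
    return transcript.n_exons - 2 if transcript.n_exons >= 2 else None


# ---------------------------------------------------------------------------
# sequence extraction
# ---------------------------------------------------------------------------

def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome[start:end) as uppercase string from a pyfaidx Fasta or a
    plain mapping of chrom -> sequence string."""
    if isinstance(genome, Mapping):
        seq = genome[chrom][start:end]
        if hasattr(seq, "seq"):
            seq = str(seq)
        return str(seq).upper()
    record = genome[chrom]
    if end > len(record):
        raise ValueError(f"interval [{start},{end}) beyond {chrom} length {len(record)}")
    return str(record[start:end]).upper()


def pre_mrna_sequence(transcript: TranscriptModel, genome) -> SequenceRecord:
    """Contiguous genomic span of the transcript, read 5'->3'."""
    raw = _fetch(genome, transcript.chrom, transcript.genomic_start, transcript.genomic_end)
    if transcript.strand == "-":
        raw = reverse_complement(raw)
    if raw and set(raw) <= {"N"}:
        warnings.warn(f"{transcript.transcript_id}: pre-mRNA is all N")
    return SequenceRecord(transcript.transcript_id, raw)


def mrna_sequence(transcript: TranscriptModel, genome) -> SequenceRecord:
    """Concatenated exon sequence, read 5'->3' (introns spliced out)."""
    parts = [
        _fetch(genome, transcript.chrom, e.start, e.end) for e in transcript.exons
    ]
    if transcript.strand == "-":
        parts = [reverse_complement(p) for p in parts]
    return SequenceRecord(transcript.transcript_id, "".join(parts))


# ---------------------------------------------------------------------------
# GTF reading / writing
# ---------------------------------------------------------------------------

def read_gene_annotation(
    gtf_source: str, genome_source=None
) -> dict[str, TranscriptModel]:
    """Read a GENCODE-dialect GTF and select one transcript per gene.

    The transcript with the largest summed exon length wins; ties break by
    lexicographically smallest transcript_id.  When ``genome_source`` (FASTA
    path, pyfaidx Fasta or mapping) is given, chromosome presence and bounds
    are validated.

    Returns a dict gene_id -> TranscriptModel.
    """
    db = gffutils.create_db(
        gtf_source,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genome = None
    if genome_source is not None:
        genome = genome_source if not isinstance(genome_source, str) else Fasta(genome_source)

    candidates: dict[str, list[TranscriptModel]] = {}
    for tx in db.features_of_type("transcript"):
        gene_id = tx.attributes["gene_id"][0]
        transcript_id = tx.attributes["transcript_id"][0]
        exon_feats = sorted(
            db.children(tx, featuretype="exon"), key=lambda f: f.start
        )
        if not exon_feats:
            continue
        strand = tx.strand
        exons = [
            GenomicInterval(f.seqid, f.start - 1, f.end, strand) for f in exon_feats
        ]
        if strand == "-":
            exons = exons[::-1]
        model = TranscriptModel(gene_id, transcript_id, exons)
        _attach_cds(db, tx, model)
        if genome is not None:
            _validate_bounds(model, genome)
        candidates.setdefault(gene_id, []).append(model)

    selected: dict[str, TranscriptModel] = {}
    for gene_id, models in candidates.items():
        best = min(models, key=lambda m: (-m.mrna_length, m.transcript_id))
        selected[gene_id] = best
    return selected


def _attach_cds(db, tx_feature, model: TranscriptModel) -> None:
    cds_feats = sorted(db.children(tx_feature, featuretype="CDS"), key=lambda f: f.start)
    if not cds_feats:
        return
    cds_gstart = min(f.start - 1 for f in cds_feats)
    cds_gend = max(f.end for f in cds_feats)
    offsets = []
    for gpos in (cds_gstart, cds_gend - 1):
        off = _genomic_to_mrna(model, gpos)
        if off is not None:
            offsets.append(off)
    if len(offsets) == 2:
        model.cds_start_offset = min(offsets)
        model.cds_end_offset = max(offsets) + 1


def _genomic_to_mrna(model: TranscriptModel, gpos: int) -> int | None:
    off = 0
    for exon in model.exons:
        if exon.start <= gpos < exon.end:
            if model.strand == "+":
                return off + (gpos - exon.start)
            return off + (exon.end - 1 - gpos)
        off += len(exon)
    return None


def _validate_bounds(model: TranscriptModel, genome) -> None:
    try:
        chrom_len = (
            len(genome[model.chrom])
            if not isinstance(genome, Mapping)
            else len(genome[model.chrom])
        )
    except KeyError:
        raise ValueError(
            f"transcript {model.transcript_id}: chromosome {model.chrom!r} missing from genome"
        ) from None
    for exon in model.exons:
        if exon.end > chrom_len or exon.start < 0:
            raise ValueError(
                f"transcript {model.transcript_id}: exon [{exon.start},{exon.end}) "
                f"outside {model.chrom} bounds (length {chrom_len})"
            )


def write_gtf(transcripts: Iterable[TranscriptModel], path: str) -> None:
    """Write selected transcripts back to a GENCODE-dialect GTF."""
    with open(path, "w") as fh:
        for tx in transcripts:
            attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
            rows = [
                (tx.genomic_start, tx.genomic_end, "gene"),
                (tx.genomic_start, tx.genomic_end, "transcript"),
            ]
            for start, end, feat in rows:
                fh.write(
                    f"{tx.chrom}\tboundary_m6a\t{feat}\t{start + 1}\t{end}\t.\t{tx.strand}\t.\t{attrs}\n"
                )
            exons = tx.exons if tx.strand == "+" else tx.exons[::-1]
            for exon in exons:
                fh.write(
                    f"{tx.chrom}\tboundary_m6a\texon\t{exon.start + 1}\t{exon.end}\t.\t{tx.strand}\t.\t{attrs}\n"
                )
            for cstart, cend in _cds_genomic_blocks(tx):
                fh.write(
                    f"{tx.chrom}\tboundary_m6a\tCDS\t{cstart + 1}\t{cend}\t.\t{tx.strand}\t0\t{attrs}\n"
                )


def _cds_genomic_blocks(tx: TranscriptModel) -> list[tuple[int, int]]:
    """Genomic (start, end) blocks of the CDS, ascending, empty if no CDS."""
    if tx.cds_start_offset is None or tx.cds_end_offset is None:
        return []
    blocks = []
    off = 0
    for exon in tx.exons:
        lo = max(tx.cds_start_offset, off)
        hi = min(tx.cds_end_offset, off + len(exon))
        if lo < hi:
            if tx.strand == "+":
                blocks.append((exon.start + (lo - off), exon.start + (hi - off)))
            else:
                blocks.append((exon.end - (hi - off), exon.end - (lo - off)))
        off += len(exon)
    return sorted(blocks)
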