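"""In-silico sequence surgeries on pre-mRNA with exact coordinate liftover.

All edits operate in transcript (pre-mRNA) coordinate space: position 0 is the
first transcribed base.  Three surgeries are provided:

- :func:`delete_introns` — remove selected introns (the all-introns case
  reproduces the mRNA exactly);
- :func:`truncate_introns` — shrink long introns to mini-introns that keep a
  fixed number of nucleotides at each end (splicing cis-elements live there);
- :func:`mutate_splice_sites` — knock out donor (GT->CA) and acceptor (AG->TC)
  dinucleotides of a mini-intron, mutating cryptic splice sites above
  probability 0.1 in one round and rejecting genes where a verification pass
  still finds new sites.

Every edit carries a :class:`CoordinateMap` so per-nucleotide scores computed
before and after an edit can be compared site-by-site.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Protocol, Sequence

from .gene_models import SequenceRecord, TranscriptModel


@dataclass(frozen=True)
class MapBlock:
    """One retained block: original [orig_start, orig_end) -> edited
    [edited_start, edited_start + length)."""

    orig_start: int
    orig_end: int
    edited_start: int

    @property
    def length(self) -> int:
        return self.orig_end - self.orig_start

    @property
    def edited_end(self) -> int:
        return self.edited_start + self.length


class CoordinateMap:
    """Bijection between retained original positions and edited positions.

    Deleted positions map to nothing (``None``).  Blocks are non-overlapping
    and order-preserving in both coordinate systems.
    """

    def __init__(self, blocks: Sequence[MapBlock], orig_length: int, edited_length: int):
        self.blocks = sorted(blocks, key=lambda b: b.orig_start)
        self.orig_length = orig_length
        self.edited_length = edited_length
        for a, b in zip(self.blocks, self.blocks[1:]):
            if a.orig_end > b.orig_start or a.edited_end > b.edited_start:
                raise ValueError("coordinate map blocks overlap or reorder")
        self._orig_starts = [b.orig_start for b in self.blocks]
        self._edited_starts = [b.edited_start for b in self.blocks]

    @classmethod
    def identity(cls, length: int) -> "CoordinateMap":
        return cls([MapBlock(0, length, 0)], length, length)

    @classmethod
    def from_retained(cls, retained: Sequence[tuple[int, int]], orig_length: int) -> "CoordinateMap":
        """Build from retained (start, end) original intervals, ascending."""
        blocks = []
        offset = 0
        for start, end in retained:
            blocks.append(MapBlock(start, end, offset))
            offset += end - start
        return cls(blocks, orig_length, offset)

    def map_position(self, original_pos: int) -> int | None:
        """Edited position for an original position; None if deleted."""
        if not 0 <= original_pos < self.orig_length:
            raise ValueError(f"position {original_pos} outside [0,{self.orig_length})")
        i = bisect.bisect_right(self._orig_starts, original_pos) - 1
        if i < 0:
            return None
        b = self.blocks[i]
        if original_pos < b.orig_end:
            return b.edited_start + (original_pos - b.orig_start)
        return None

    def invert_position(self, edited_pos: int) -> int:
        """Original position for an edited position (always defined)."""
        if not 0 <= edited_pos < self.edited_length:
            raise ValueError(f"position {edited_pos} outside [0,{self.edited_length})")
        i = bisect.bisect_right(self._edited_starts, edited_pos) - 1
        b = self.blocks[i]
        if edited_pos >= b.edited_end:
            raise ValueError(f"edited position {edited_pos} falls in a map gap")
        return b.orig_start + (edited_pos - b.edited_start)

    def compose(self, later: "CoordinateMap") -> "CoordinateMap":
        """Map through self then ``later`` (self's edited space = later's
        original space)."""
        blocks: list[MapBlock] = []
        for b in self.blocks:
            for pos in range(b.orig_start, b.orig_end):
                mid = b.edited_start + (pos - b.orig_start)
                out = later.map_position(mid)
                if out is None:
                    continue
                if blocks and blocks[-1].orig_end == pos and blocks[-1].edited_end == out:
                    blocks[-1] = MapBlock(blocks[-1].orig_start, pos + 1, blocks[-1].edited_start)
                else:
                    blocks.append(MapBlock(pos, pos + 1, out))
        return CoordinateMap(blocks, self.orig_length, later.edited_length)


def map_position(coordinate_map: CoordinateMap, original_pos: int) -> int | None:
    return coordinate_map.map_position(original_pos)


@dataclass
class EditDescriptor:
    kind: str                      # {identity, delete_introns, truncate_introns, splice_mut}
    introns: tuple[int, ...] = ()
    params: dict = field(default_factory=dict)


@dataclass
class EditedTranscript:
    """An edited pre-mRNA plus the liftover back to the original."""

    source_id: str
    edit: EditDescriptor
    sequence: SequenceRecord
    coordinate_map: CoordinateMap
    rejected: bool = False
    rejection_reason: str | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)


def _resolve_selection(transcript: TranscriptModel, selection) -> list[int]:
    n_introns = transcript.n_exons - 1
    if selection == "all":
        return list(range(n_introns))
    if selection == "last":
        if n_introns == 0:
            return []
        return [n_introns - 1]
    idx = sorted(set(int(i) for i in selection))
    for i in idx:
        if not 0 <= i < n_introns:
            raise ValueError(
                f"{transcript.transcript_id}: intron index {i} out of range (has {n_introns})"
            )
    return idx


def delete_introns(
    transcript: TranscriptModel, pre_mrna: SequenceRecord, selection="all"
) -> EditedTranscript:
    """Remove selected introns from the pre-mRNA.

    ``selection`` is ``"all"``, ``"last"`` or an iterable of 0-based intron
    indices.  Deleting all introns yields exactly the mRNA sequence.
    A single-exon gene with ``selection="last"`` is an identity edit with a
    warning.
    """
    if len(pre_mrna) != transcript.pre_mrna_length:
        raise ValueError(
            f"{transcript.transcript_id}: sequence length {len(pre_mrna)} != "
            f"pre-mRNA length {transcript.pre_mrna_length}"
        )
    idx = _resolve_selection(transcript, selection)
    if transcript.n_exons == 1 and selection == "last":
        warnings.warn(f"{transcript.transcript_id}: single-exon gene, identity edit")
    introns = transcript.intron_blocks_transcript()
    deleted = [introns[i] for i in idx]
    retained = _complement_blocks(deleted, len(pre_mrna))
    cmap = CoordinateMap.from_retained(retained, len(pre_mrna))
    seq = "".join(pre_mrna.sequence[s:e] for s, e in retained)
    return EditedTranscript(
        transcript.transcript_id,
        EditDescriptor("delete_introns" if idx else "identity", tuple(idx)),
        SequenceRecord(f"{transcript.transcript_id}|del", seq),
        cmap,
    )


def truncate_introns(
    transcript: TranscriptModel,
    pre_mrna: SequenceRecord,
    keep_per_end: int = 100,
    selection="all",
) -> EditedTranscript:
    """Truncate selected introns to 2*keep_per_end nt mini-introns.

    The center of each intron longer than ``2*keep_per_end`` is removed;
    shorter introns are untouched.  Terminal dinucleotides (and indeed the
    whole kept ends) are preserved verbatim.
    """
    if keep_per_end < 2:
        raise ValueError("keep_per_end must be >= 2 to preserve terminal dinucleotides")
    idx = _resolve_selection(transcript, selection)
    introns = transcript.intron_blocks_transcript()
    deleted = []
    for i in idx:
        s, e = introns[i]
        if e - s > 2 * keep_per_end:
            deleted.append((s + keep_per_end, e - keep_per_end))
    retained = _complement_blocks(deleted, len(pre_mrna))
    cmap = CoordinateMap.from_retained(retained, len(pre_mrna))
    seq = "".join(pre_mrna.sequence[s:e] for s, e in retained)
    return EditedTranscript(
        transcript.transcript_id,
        EditDescriptor("truncate_introns", tuple(idx), {"keep_per_end": keep_per_end}),
        SequenceRecord(f"{transcript.transcript_id}|mini", seq),
        cmap,
    )


def _complement_blocks(deleted: list[tuple[int, int]], length: int) -> list[tuple[int, int]]:
    retained = []
    pos = 0
    for s, e in sorted(deleted):
        if s > pos:
            retained.append((pos, s))
        pos = e
    if pos < length:
        retained.append((pos, length))
    return retained


# ---------------------------------------------------------------------------
# splice-site point mutation with cryptic-site guard
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrypticSite:
    position: int          # 0-based position of the first base of the dinucleotide
    kind: str              # {donor, acceptor}
    probability: float


class SplicePredictor(Protocol):
    """Contract for a cryptic-splice-site predictor: sequence -> sites."""

    def __call__(self, sequence: str) -> Iterable[CrypticSite]: ...


DONOR_REPLACEMENT = "CA"
ACCEPTOR_REPLACEMENT = "TC"
CRYPTIC_THRESHOLD = 0.1


def mutate_splice_sites(
    edited: EditedTranscript,
    transcript: TranscriptModel,
    intron_index: int,
    cryptic_predictor: SplicePredictor,
    scan_window: tuple[int, int] | None = None,
    rounds: int = 1,
) -> EditedTranscript:
    """Mutate the donor/acceptor of one (mini-)intron and guard against
    cryptic splice sites.

    The donor dinucleotide (canonically GT) becomes CA and the acceptor
    (canonically AG) becomes TC.  Cryptic sites with probability > 0.1
    reported by ``cryptic_predictor`` inside ``scan_window`` (edited
    coordinates; defaults to second-to-last exon start .. last exon end) are
    mutated the same way for ``rounds`` rounds; a final verification pass that
    still reports any site > 0.1 marks the gene rejected.

    Substitutions never change sequence length, so the coordinate map is
    inherited unchanged.
    """
    introns_orig = transcript.intron_blocks_transcript()
    if not 0 <= intron_index < len(introns_orig):
        raise ValueError(f"intron index {intron_index} out of range")
    s_orig, e_orig = introns_orig[intron_index]
    cmap = edited.coordinate_map
    s = cmap.map_position(s_orig)
    e_last = cmap.map_position(e_orig - 1)
    if s is None or e_last is None:
        raise ValueError("targeted intron was deleted by a previous edit")
    e = e_last + 1

    seq = list(edited.sequence.sequence)
    donor = "".join(seq[s:s + 2])
    acceptor = "".join(seq[e - 2:e])
    if donor != "GT" or acceptor != "AG":
        warnings.warn(
            f"{edited.source_id}: non-canonical intron ends {donor}..{acceptor}; "
            "mutating literal terminal dinucleotides"
        )
    seq[s:s + 2] = DONOR_REPLACEMENT
    seq[e - 2:e] = ACCEPTOR_REPLACEMENT

    if scan_window is None:
        scan_window = _default_scan_window(edited, transcript, intron_index)
    w_lo, w_hi = scan_window

    def _sites(sequence: str) -> list[CrypticSite]:
        found = []
        try:
            for site in cryptic_predictor(sequence[w_lo:w_hi]):
                if site.probability > CRYPTIC_THRESHOLD:
                    found.append(
                        CrypticSite(site.position + w_lo, site.kind, site.probability)
                    )
        except Exception as exc:  # propagate with gene id per contract
            raise RuntimeError(f"cryptic predictor failed for {edited.source_id}") from exc
        return found

    for _ in range(rounds):
        for site in _sites("".join(seq)):
            rep = DONOR_REPLACEMENT if site.kind == "donor" else ACCEPTOR_REPLACEMENT
            seq[site.position:site.position + 2] = rep

    remaining = _sites("".join(seq))
    rejected = len(remaining) > 0
    reason = (
        f"{len(remaining)} cryptic site(s) remain after {rounds} mutation round(s)"
        if rejected
        else None
    )
    params = {"intron_index": intron_index, "scan_window": scan_window, "rounds": rounds}
    return EditedTranscript(
        edited.source_id,
        EditDescriptor("splice_mut", (intron_index,), params),
        SequenceRecord(f"{edited.source_id}|splice_mut", "".join(seq)),
        cmap,
        rejected=rejected,
        rejection_reason=reason,
    )


def _default_scan_window(
    edited: EditedTranscript, transcript: TranscriptModel, intron_index: int
) -> tuple[int, int]:
    """Second-to-last-exon start through last-exon end, edited coordinates."""
    blocks = transcript.exon_blocks_transcript()
    up_exon = blocks[intron_index]
    down_exon = blocks[intron_index + 1]
    lo = edited.coordinate_map.map_position(up_exon[0])
    hi = edited.coordinate_map.map_position(down_exon[1] - 1)
    if lo is None:
        lo = 0
    if hi is None:
        hi = edited.length - 1
    return (lo, hi + 1)


def write_fasta(records: Iterable[SequenceRecord], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")
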