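"""DeltaProbability analysis: compare methylation profiles before and after an
in-silico edit at RAC sites, categorize changes and summarize them.

A RAC site whose probability rises by more than 0.1 upon intron removal is a
*latent* (boundary-repressed) site; drops below -0.1 are *decreased*; the
closed band [-0.1, 0.1] is *no change*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .edits import CoordinateMap, EditedTranscript
from .gene_models import TranscriptModel, classify_exons, second_to_last_index
from .motifs import rac_positions
from .predictor import MethylationProfile

DELTA_CUTOFF = 0.1

CAT_INCREASED = "increased"
CAT_DECREASED = "decreased"
CAT_NO_CHANGE = "no_change"


def categorize_site(delta: float, cutoff: float = DELTA_CUTOFF) -> str:
    """Category of a probability change; the boundary +-cutoff is no_change."""
    if math.isnan(delta):
        raise ValueError("delta is NaN")
    if delta > cutoff:
        return CAT_INCREASED
    if delta < -cutoff:
        return CAT_DECREASED
    return CAT_NO_CHANGE


@dataclass
class DeltaRecord:
    """Probability change of one exonic RAC site under one edit."""

    gene_id: str
    position: int            # original transcript (pre-mRNA) coordinates, the A
    exon_index: int
    exon_role: str
    is_second_to_last: bool
    dist_to_exon_start: int  # nt, 0 = first base of the host exon
    dist_to_exon_end: int    # nt, 0 = last base of the host exon
    p_before: float
    p_after: float

    @property
    def delta(self) -> float:
        return self.p_after - self.p_before

    @property
    def category(self) -> str:
        return categorize_site(self.delta)


def compute_site_deltas(
    profile_before: MethylationProfile,
    profile_after: MethylationProfile,
    edited: EditedTranscript | CoordinateMap,
    transcript: TranscriptModel,
    sequence: str,
    gene_id: str | None = None,
) -> list[DeltaRecord]:
    """One DeltaRecord per exonic RAC site of the original pre-mRNA that
    survives the edit.

    ``sequence`` is the original pre-mRNA; ``profile_before`` is scored on it
    and ``profile_after`` on the edited sequence.  Sites inside deleted blocks
    (e.g. intronic sites under intron deletion) emit no record.
    """
    cmap = edited.coordinate_map if isinstance(edited, EditedTranscript) else edited
    if len(profile_before) != len(sequence):
        raise ValueError("profile_before length != original sequence length")
    if len(profile_after) != cmap.edited_length:
        raise ValueError("profile_after length != edited sequence length")
    gene = gene_id if gene_id is not None else transcript.gene_id
    roles = classify_exons(transcript)
    stl = second_to_last_index(transcript)
    blocks = transcript.exon_blocks_transcript()
    records = []
    for pos in rac_positions(sequence):
        exon_idx = None
        for i, (s, e) in enumerate(blocks):
            if s <= pos < e:
                exon_idx = i
                break
        if exon_idx is None:
            continue
        mapped = cmap.map_position(int(pos))
        if mapped is None:
            continue
        s, e = blocks[exon_idx]
        records.append(
            DeltaRecord(
                gene_id=gene,
                position=int(pos),
                exon_index=exon_idx,
                exon_role=roles[exon_idx],
                is_second_to_last=(exon_idx == stl),
                dist_to_exon_start=int(pos) - s,
                dist_to_exon_end=e - 1 - int(pos),
                p_before=float(profile_before.probabilities[pos]),
                p_after=float(profile_after.probabilities[mapped]),
            )
        )
    return records


def records_to_frame(records: Iterable[DeltaRecord]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": r.gene_id,
            "position": r.position,
            "exon_index": r.exon_index,
            "exon_role": r.exon_role,
            "is_second_to_last": r.is_second_to_last,
            "dist_to_exon_start": r.dist_to_exon_start,
            "dist_to_exon_end": r.dist_to_exon_end,
            "p_before": r.p_before,
            "p_after": r.p_after,
            "delta": r.delta,
            "category": r.category,
        }
        for r in records
    ]
    columns = [
        "gene_id", "position", "exon_index", "exon_role", "is_second_to_last",
        "dist_to_exon_start", "dist_to_exon_end", "p_before", "p_after",
        "delta", "category",
    ]
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# metagene density
# ---------------------------------------------------------------------------

@dataclass
class MetageneProfile:
    """Mean probability per offset around an anchor, with coverage counts."""

    anchor: str
    offsets: np.ndarray
    mean_probability: np.ndarray   # NaN where n == 0
    n: np.ndarray


def _anchor_positions(transcript: TranscriptModel, anchor: str) -> list[int]:
    blocks = transcript.exon_blocks_transcript()
    if anchor == "last_exon_start":
        return [blocks[-1][0]] if transcript.n_exons >= 1 else []
    if anchor == "internal_exon_start":
        return [blocks[i][0] for i in range(1, transcript.n_exons - 1)]
    if anchor == "exon_end":
        return [e - 1 for _, e in blocks]
    raise ValueError(f"unknown anchor {anchor!r}")


def metagene_density(
    profiles: Sequence[MethylationProfile],
    transcripts: Sequence[TranscriptModel],
    anchor: str = "last_exon_start",
    flank_nt: int = 500,
    smooth_width: int = 1,
) -> MetageneProfile:
    """Mean per-offset probability across transcripts around an anchor.

    The "density" statistic is the arithmetic mean of per-nucleotide
    probability at each offset over the transcripts that cover it; optional
    sliding-mean smoothing (width 1 = none).
    """
    offsets = np.arange(-flank_nt, flank_nt + 1)
    total = np.zeros(len(offsets))
    n = np.zeros(len(offsets), dtype=int)
    found_anchor = False
    for profile, tx in zip(profiles, transcripts):
        for a in _anchor_positions(tx, anchor):
            found_anchor = True
            lo = max(a - flank_nt, 0)
            hi = min(a + flank_nt + 1, len(profile))
            idx = np.arange(lo, hi) - a + flank_nt
            total[idx] += profile.probabilities[lo:hi]
            n[idx] += 1
    if not found_anchor:
        raise ValueError(f"no transcript contains anchor {anchor!r}")
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, total / np.maximum(n, 1), np.nan)
    if smooth_width > 1:
        kernel = np.ones(smooth_width) / smooth_width
        valid = ~np.isnan(mean)
        padded = np.where(valid, mean, 0.0)
        smoothed = np.convolve(padded, kernel, mode="same")
        norm = np.convolve(valid.astype(float), kernel, mode="same")
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(norm > 0, smoothed / norm, np.nan)
    return MetageneProfile(anchor, offsets, mean, n)


def metagene_frame(profile: MetageneProfile) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "offset": profile.offsets,
            "mean_probability": profile.mean_probability,
            "n": profile.n,
        }
    )


# ---------------------------------------------------------------------------
# latent-site summary
# ---------------------------------------------------------------------------

def latent_site_summary(
    delta_records: Sequence[DeltaRecord],
    region_nt: int = 500,
    near_cutoff_nt: int = 100,
    length_bins: tuple[int, int] = (200, 400),
) -> dict:
    """Fractions of increased/decreased/no-change sites, localization of the
    increased (latent) sites near the exon start, and stratification by host
    exon length.

    Only records with ``dist_to_exon_start <= region_nt`` enter the summary
    (mirroring positional plots over the first ``region_nt`` nt of the exon).
    """
    recs = [r for r in delta_records if r.dist_to_exon_start <= region_nt]
    n = len(recs)
    if n == 0:
        return {
            "n_sites": 0,
            "fraction_increased": np.nan,
            "fraction_decreased": np.nan,
            "fraction_no_change": np.nan,
            "fraction_increased_near_start": np.nan,
            "by_exon_length": {},
        }
    cats = [r.category for r in recs]
    n_inc = cats.count(CAT_INCREASED)
    n_dec = cats.count(CAT_DECREASED)
    near = [
        r for r in recs
        if r.category == CAT_INCREASED and r.dist_to_exon_start <= near_cutoff_nt
    ]
    lo, hi = length_bins
    by_length = {}
    for label, pred in (
        (f"<={lo}", lambda L: L <= lo),
        (f"{lo}-{hi}", lambda L: lo < L < hi),
        (f">={hi}", lambda L: L >= hi),
    ):
        sub = [
            r for r in recs
            if pred(r.dist_to_exon_start + r.dist_to_exon_end + 1)
        ]
        by_length[label] = {
            "n_sites": len(sub),
            "fraction_increased": (
                sum(r.category == CAT_INCREASED for r in sub) / len(sub)
                if sub else np.nan
            ),
        }
    return {
        "n_sites": n,
        "fraction_increased": n_inc / n,
        "fraction_decreased": n_dec / n,
        "fraction_no_change": (n - n_inc - n_dec) / n,
        "fraction_increased_near_start": (len(near) / n_inc) if n_inc else np.nan,
        "by_exon_length": by_length,
    }


def called_site_fraction(
    profiles: Sequence[MethylationProfile], threshold: float = 0.05
) -> float:
    """Alternative density statistic: fraction of scored (nonzero) positions
    called above threshold, pooled over profiles."""
    called = scored = 0
    for p in profiles:
        nz = p.probabilities > 0
        scored += int(nz.sum())
        called += int((p.probabilities > threshold).sum())
    return called / scored if scored else float("nan")
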