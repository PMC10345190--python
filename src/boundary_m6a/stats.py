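"""Conservation, half-life, exon-number and codon-usage statistics.

Groups of RAC sites (latent vs no-change) are compared on per-base
conservation scores with a two-sided Wilcoxon rank-sum test, optionally
restricted to degenerate positions of synonymous codons; mRNA half-lives are
compared between matched transcript groups; codon and amino-acid usage over
the first 30 codons of exons is contrasted between exon clusters with Fisher
exact tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from scipy import stats as sps

from .gene_models import TranscriptModel

BASES = "ACGT"
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
CODON_TO_AA = dict(standard_dna_table.forward_table)


# ---------------------------------------------------------------------------
# degenerate synonymous positions
# ---------------------------------------------------------------------------

def _codon_degenerate_offsets(codon: str) -> list[int]:
    """Offsets (0,1,2) within a codon where >=1 single-base substitution is
    synonymous, derived from the standard genetic code."""
    if codon in STOP_CODONS or codon not in CODON_TO_AA:
        return []
    aa = CODON_TO_AA[codon]
    out = []
    for off in range(3):
        for b in BASES:
            if b == codon[off]:
                continue
            mut = codon[:off] + b + codon[off + 1:]
            if CODON_TO_AA.get(mut) == aa:
                out.append(off)
                break
    return out


_DEGENERATE_CACHE = {c: _codon_degenerate_offsets(c) for c in CODON_TO_AA}


def degenerate_synonymous_positions(
    transcript: TranscriptModel, mrna_sequence: str
) -> set[int]:
    """mRNA positions (0-based) inside the CDS where a synonymous single-base
    substitution exists.

    Computed from the standard genetic code, not hard-coded codon offsets.
    A trailing partial codon is trimmed with a warning.
    """
    if transcript.cds_start_offset is None or transcript.cds_end_offset is None:
        raise ValueError(f"{transcript.transcript_id}: CDS frame unknown")
    cds = mrna_sequence.upper()[transcript.cds_start_offset:transcript.cds_end_offset]
    if len(cds) % 3:
        warnings.warn(
            f"{transcript.transcript_id}: CDS length {len(cds)} not divisible by 3; "
            "trimming trailing partial codon"
        )
        cds = cds[: len(cds) - len(cds) % 3]
    positions = set()
    for i in range(0, len(cds), 3):
        codon = cds[i:i + 3]
        for off in _DEGENERATE_CACHE.get(codon, ()):
            positions.add(transcript.cds_start_offset + i + off)
    return positions


# ---------------------------------------------------------------------------
# conservation comparison
# ---------------------------------------------------------------------------

def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p: exact for small tie-free samples
    (both n <= 25), normal approximation with tie correction otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(x) <= 25 and len(y) <= 25 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def conservation_compare(
    latent_scores: Sequence[float],
    nochange_scores: Sequence[float],
    restrict_latent: Sequence[bool] | None = None,
    restrict_nochange: Sequence[bool] | None = None,
) -> dict:
    """Compare conservation of latent vs no-change sites.

    Optional boolean masks restrict each group (e.g. to degenerate synonymous
    positions); the restriction is applied symmetrically by the caller
    supplying both masks.  Returns medians, quartiles and the two-sided
    Wilcoxon rank-sum p.
    """
    lat = np.asarray(latent_scores, dtype=float)
    noc = np.asarray(nochange_scores, dtype=float)
    if restrict_latent is not None:
        lat = lat[np.asarray(restrict_latent, dtype=bool)]
    if restrict_nochange is not None:
        noc = noc[np.asarray(restrict_nochange, dtype=bool)]
    for name, g in (("latent", lat), ("no_change", noc)):
        if len(g) == 0:
            raise ValueError(f"group {name!r} is empty after restriction")
    return {
        "n_latent": len(lat),
        "n_nochange": len(noc),
        "median_latent": float(np.median(lat)),
        "median_nochange": float(np.median(noc)),
        "q25_latent": float(np.percentile(lat, 25)),
        "q75_latent": float(np.percentile(lat, 75)),
        "q25_nochange": float(np.percentile(noc, 25)),
        "q75_nochange": float(np.percentile(noc, 75)),
        "p_value": rank_sum_test(lat, noc),
    }


# ---------------------------------------------------------------------------
# m6A / RAC census and correlation
# ---------------------------------------------------------------------------

def m6a_rac_ratio(
    probabilities: np.ndarray, rac_sites: Sequence[int], threshold: float = 0.05
) -> tuple[int, int, float]:
    """(m6A count, RAC count, ratio): m6A sites are RAC sites whose
    probability is strictly above threshold; ratio is 0 when there are no
    RAC sites (flagged by the zero denominator)."""
    probs = np.asarray(probabilities, dtype=float)
    rac = np.asarray(rac_sites, dtype=int)
    n_rac = len(rac)
    n_m6a = int((probs[rac] > threshold).sum()) if n_rac else 0
    ratio = n_m6a / n_rac if n_rac else 0.0
    return n_m6a, n_rac, ratio


def correlate(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r with two-sided Student-t p-value.

    p is computed from t = r*sqrt((n-2)/(1-r^2)) with n-2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    xc, yc = x - x.mean(), y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    p = float(2 * sps.t.sf(abs(t), df=n - 2))
    return r, p


# ---------------------------------------------------------------------------
# half-life records and matched-group comparison
# ---------------------------------------------------------------------------

@dataclass
class HalfLifeRecord:
    gene_id: str
    t12_wt: float          # hours
    t12_ko: float          # hours
    exon_count: int
    m6a_count: int
    rac_count: int

    def __post_init__(self) -> None:
        if self.t12_wt <= 0 or self.t12_ko <= 0:
            raise ValueError(f"{self.gene_id}: half-lives must be > 0")

    @property
    def m6a_rac_ratio(self) -> float:
        return self.m6a_count / self.rac_count if self.rac_count else 0.0


def read_halflife_tsv(path: str) -> pd.DataFrame:
    """Read a transcript -> T1/2 table (columns gene_id, t12_wt, t12_ko,
    optional exon_count/m6a_count/rac_count)."""
    return pd.read_csv(path, sep="\t")


def match_groups(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    by: str = "rac_count",
    seed: int = 0,
    caliper: float = 0.10,
) -> pd.DataFrame:
    """Greedy 1:1 matching of rows of two tables without replacement.

    ``by="rac_count"`` matches on exact key equality; ``by="cdna_length"``
    takes the nearest value within a 10% caliper.  A rows are processed in a
    seeded random order.  Returns a frame with columns index_a / index_b /
    key_a / key_b; empty (with a warning) when nothing matches.
    """
    if by not in group_a.columns or by not in group_b.columns:
        raise ValueError(f"matching key {by!r} missing")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(group_a))
    b_keys = group_b[by].to_numpy(dtype=float)
    available = np.ones(len(group_b), dtype=bool)
    exact = by == "rac_count"
    pairs = []
    for ia in order:
        ka = float(group_a[by].iloc[ia])
        if exact:
            cand = np.nonzero(available & (b_keys == ka))[0]
            if len(cand) == 0:
                continue
            ib = int(cand[0])
        else:
            cand = np.nonzero(available)[0]
            if len(cand) == 0:
                break
            dist = np.abs(b_keys[cand] - ka)
            ib = int(cand[np.argmin(dist)])
            if abs(b_keys[ib] - ka) > caliper * max(abs(ka), 1e-12):
                continue
        available[ib] = False
        pairs.append((int(ia), ib, ka, float(b_keys[ib])))
    if not pairs:
        warnings.warn("no matched pairs found")
        return pd.DataFrame(columns=["index_a", "index_b", "key_a", "key_b"])
    return pd.DataFrame(pairs, columns=["index_a", "index_b", "key_a", "key_b"]).sort_values(
        "index_a", ignore_index=True
    )


def group_halflife_compare(
    group_a: pd.DataFrame, group_b: pd.DataFrame, pairs: pd.DataFrame
) -> dict:
    """Compare matched groups on m6A count, T1/2 (WT), T1/2 (KO) and
    DeltaT1/2 = KO - WT; each comparison reports medians and the two-sided
    Wilcoxon rank-sum p plus sorted values for cumulative-distribution plots.

    Comparisons whose columns are missing are skipped with a note.
    """
    a = group_a.iloc[pairs["index_a"].to_numpy(dtype=int)]
    b = group_b.iloc[pairs["index_b"].to_numpy(dtype=int)]
    out: dict = {"n_pairs": len(pairs), "metrics": {}, "skipped": []}
    metrics = {
        "m6a_count": ("m6a_count", None),
        "t12_wt": ("t12_wt", None),
        "t12_ko": ("t12_ko", None),
        "delta_t12": ("t12_ko", "t12_wt"),
    }
    for name, (col, minus) in metrics.items():
        if col not in a.columns or (minus is not None and minus not in a.columns):
            out["skipped"].append(name)
            continue
        va = a[col].to_numpy(dtype=float)
        vb = b[col].to_numpy(dtype=float)
        if minus is not None:
            va = va - a[minus].to_numpy(dtype=float)
            vb = vb - b[minus].to_numpy(dtype=float)
        out["metrics"][name] = {
            "median_a": float(np.median(va)),
            "median_b": float(np.median(vb)),
            "values_a": np.sort(va),
            "values_b": np.sort(vb),
            "p_value": rank_sum_test(va, vb),
        }
    return out


# ---------------------------------------------------------------------------
# codon / amino-acid usage
# ---------------------------------------------------------------------------

def _exon_codons(seq: str, frame_offset: int, n_codons: int) -> list[str]:
    """First ``n_codons`` complete in-frame sense codons of an exon sequence.

    ``frame_offset`` is the position within the exon of the first complete
    codon's first base.
    """
    s = seq.upper()[frame_offset:]
    codons = []
    for i in range(0, min(len(s) - len(s) % 3, n_codons * 3), 3):
        c = s[i:i + 3]
        if c in CODON_TO_AA:
            codons.append(c)
    return codons


def codon_amino_usage(
    exons_c1: Sequence[tuple[str, int]],
    exons_c2: Sequence[tuple[str, int]],
    n_codons: int = 30,
) -> pd.DataFrame:
    """Codon and amino-acid usage of C1 vs C2 exons.

    Each exon is a ``(sequence, frame_offset)`` pair; a negative frame offset
    marks unknown frame and skips the exon (counted).  Counts cover the first
    ``n_codons`` complete codons per exon, stop codons excluded.  Returns one
    row per codon and per amino acid with counts, odds ratio (C1 vs C2,
    Haldane-Anscombe corrected on zero cells) and two-sided Fisher p.
    """
    def _count(exons):
        codon_counts: dict[str, int] = {}
        skipped = 0
        for seq, frame in exons:
            if frame < 0:
                skipped += 1
                continue
            for c in _exon_codons(seq, frame, n_codons):
                codon_counts[c] = codon_counts.get(c, 0) + 1
        return codon_counts, skipped

    counts1, skip1 = _count(exons_c1)
    counts2, skip2 = _count(exons_c2)
    if skip1 or skip2:
        warnings.warn(f"skipped exons with unknown frame: C1={skip1}, C2={skip2}")
    total1, total2 = sum(counts1.values()), sum(counts2.values())
    rows = []

    def _fisher_row(kind, name, a, c):
        b, d = total1 - a, total2 - c
        _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if min(a, b, c, d) == 0:
            oddsr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            oddsr = (a * d) / (b * c)
        rows.append(
            {"kind": kind, "name": name, "count_c1": a, "count_c2": c,
             "odds_ratio": float(oddsr), "p_value": float(p)}
        )

    for codon in sorted(set(counts1) | set(counts2)):
        _fisher_row("codon", codon, counts1.get(codon, 0), counts2.get(codon, 0))
    aas = sorted(set(CODON_TO_AA[c] for c in set(counts1) | set(counts2)))
    for aa in aas:
        a = sum(v for c, v in counts1.items() if CODON_TO_AA[c] == aa)
        c = sum(v for c_, v in counts2.items() if CODON_TO_AA[c_] == aa)
        _fisher_row("amino_acid", aa, a, c)
    return pd.DataFrame(rows, columns=["kind", "name", "count_c1", "count_c2", "odds_ratio", "p_value"])
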