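"""Motif machinery: RAC site scanning, positional pentamer frequencies,
pentamer enrichment volcano statistics and motif dendrograms.

The methylation consensus used throughout is RAC (R = A/G, the methylated
base is the central A, followed by C).  N never matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform
from scipy.stats import fisher_exact

PURINES = frozenset("AG")
ALL_PENTAMERS = ["".join(p) for p in product("ACGT", repeat=5)]


@dataclass(frozen=True)
class MotifSite:
    """One RAC site: the methylated A and its R_A_C context."""

    sequence_id: str
    position: int          # 0-based index of the A
    context: str           # the RAC trinucleotide

    def __post_init__(self) -> None:
        if len(self.context) != 3 or self.context[1] != "A":
            raise ValueError(f"bad RAC context {self.context!r}")


def find_rac_sites(sequence: str, sequence_id: str = "") -> list[MotifSite]:
    """All RAC sites in a sequence (positions of the central A)."""
    seq = sequence.upper()
    out = []
    for i in range(1, len(seq) - 1):
        if seq[i] == "A" and seq[i - 1] in PURINES and seq[i + 1] == "C":
            out.append(MotifSite(sequence_id, i, seq[i - 1:i + 2]))
    return out


def rac_positions(sequence: str) -> np.ndarray:
    """Vectorized RAC scan; returns positions of the central A."""
    if len(sequence) < 3:
        return np.array([], dtype=int)
    arr = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
    a, c, g = ord("A"), ord("C"), ord("G")
    mid = arr[1:-1] == a
    left = (arr[:-2] == a) | (arr[:-2] == g)
    right = arr[2:] == c
    return np.nonzero(mid & left & right)[0] + 1


def is_nracn(pentamer: str) -> bool:
    """True when positions 2-4 of a pentamer form RAC."""
    return (
        len(pentamer) == 5
        and pentamer[1] in PURINES
        and pentamer[2] == "A"
        and pentamer[3] == "C"
    )


# ---------------------------------------------------------------------------
# positional pentamer frequency around sites
# ---------------------------------------------------------------------------

def positional_motif_frequency(
    sites: Sequence[MotifSite],
    sequences: dict[str, str],
    motif_set: Iterable[str],
    flank: int = 55,
) -> pd.DataFrame:
    """Per-offset frequency of a pentamer set around RAC sites.

    For each pentamer start offset ``o`` in [-flank, flank - 4] relative to
    the site's A, the frequency is the fraction of sites whose pentamer at
    that offset belongs to ``motif_set``, over the sites whose sequence covers
    positions ``o..o+4``.  Sites with short context simply drop out of the
    denominator at uncovered offsets.

    Returns a DataFrame with columns offset, n_motif, n_covered, frequency.
    """
    motifs = frozenset(m.upper() for m in motif_set)
    offsets = np.arange(-flank, flank - 3)
    n_motif = np.zeros(len(offsets), dtype=int)
    n_cov = np.zeros(len(offsets), dtype=int)
    for site in sites:
        seq = sequences[site.sequence_id].upper()
        for k, o in enumerate(offsets):
            start = site.position + o
            if start < 0 or start + 5 > len(seq):
                continue
            n_cov[k] += 1
            if seq[start:start + 5] in motifs:
                n_motif[k] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_cov > 0, n_motif / np.maximum(n_cov, 1), np.nan)
    return pd.DataFrame(
        {"offset": offsets, "n_motif": n_motif, "n_covered": n_cov, "frequency": freq}
    )


# ---------------------------------------------------------------------------
# pentamer enrichment (volcano) between two sequence groups
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    motif: str
    a: int                 # occurrences in group 1
    b: int                 # non-occurrence slots in group 1
    c: int                 # occurrences in group 2
    d: int                 # non-occurrence slots in group 2
    odds_ratio: float      # Haldane-Anscombe 0.5-corrected when any cell is 0
    p_value: float         # two-sided Fisher exact, uncorrected table
    is_nracn: bool = False
    is_enhancer: bool = False
    is_silencer: bool = False

    @property
    def log2_odds_ratio(self) -> float:
        return float(np.log2(self.odds_ratio))


def count_kmers(sequences: Iterable[str], k: int = 5) -> tuple[dict[str, int], int]:
    """Occurrence counts over all overlapping k-mer windows, plus the total
    number of windows (k-mers containing non-ACGT bases are skipped but still
    occupy a window slot)."""
    counts: dict[str, int] = {}
    total = 0
    valid = set("ACGT")
    for seq in sequences:
        s = seq.upper()
        for i in range(len(s) - k + 1):
            total += 1
            kmer = s[i:i + k]
            if set(kmer) <= valid:
                counts[kmer] = counts.get(kmer, 0) + 1
    return counts, total


def pentamer_enrichment(
    group1_sequences: Iterable[str],
    group2_sequences: Iterable[str],
    enhancers: Iterable[str] = (),
    silencers: Iterable[str] = (),
    k: int = 5,
) -> list[EnrichmentResult]:
    """Per-pentamer odds ratio and two-sided Fisher exact p, group 1 vs 2.

    Counting unit is the overlapping k-mer window.  The odds ratio uses a
    +0.5 Haldane-Anscombe correction only when a cell is zero; the p-value is
    always from the uncorrected exact test.
    """
    c1, t1 = count_kmers(group1_sequences, k)
    c2, t2 = count_kmers(group2_sequences, k)
    if t1 == 0 or t2 == 0:
        raise ValueError("both groups must contain at least one k-mer window")
    enh = frozenset(m.upper() for m in enhancers)
    sil = frozenset(m.upper() for m in silencers)
    results = []
    for motif in sorted(set(c1) | set(c2)):
        a = c1.get(motif, 0)
        c = c2.get(motif, 0)
        b, d = t1 - a, t2 - c
        table = np.array([[a, b], [c, d]])
        _, p = fisher_exact(table, alternative="two-sided")
        if min(a, b, c, d) == 0:
            oddsr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            oddsr = (a * d) / (b * c)
        results.append(
            EnrichmentResult(
                motif, a, b, c, d, float(oddsr), float(p),
                is_nracn=is_nracn(motif),
                is_enhancer=motif in enh,
                is_silencer=motif in sil,
            )
        )
    return results


def enrichment_table(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """Volcano-plot-ready table (pentamer, log2 OR, -log10 p, flags)."""
    rows = [
        {
            "motif": r.motif,
            "a": r.a, "b": r.b, "c": r.c, "d": r.d,
            "odds_ratio": r.odds_ratio,
            "log2_odds_ratio": r.log2_odds_ratio,
            "p_value": r.p_value,
            "neg_log10_p": float(-np.log10(max(r.p_value, 1e-300))),
            "is_nracn": r.is_nracn,
            "is_enhancer": r.is_enhancer,
            "is_silencer": r.is_silencer,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# motif dendrogram
# ---------------------------------------------------------------------------

def hamming_distance(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("motifs must have equal length")
    return sum(x != y for x, y in zip(a, b))


def motif_dendrogram(motifs: Sequence[str]) -> np.ndarray:
    """Average-linkage agglomerative clustering on pairwise Hamming distance.

    Returns a scipy linkage matrix (deterministic for a given input order);
    fewer than two motifs yield an empty linkage.
    """
    if len(motifs) < 2:
        return np.empty((0, 4))
    n = len(motifs)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dmat[i, j] = dmat[j, i] = hamming_distance(motifs[i], motifs[j])
    return average(squareform(dmat, checks=False))


def dendrogram_newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    """Serialize a linkage matrix as a newick string (text-friendly export)."""
    if linkage.shape[0] == 0:
        return f"({','.join(labels)});" if len(labels) > 1 else f"{labels[0] if labels else ''};"
    n = len(labels)
    nodes: dict[int, str] = {i: labels[i] for i in range(n)}
    heights: dict[int, float] = {i: 0.0 for i in range(n)}
    for k, (i, j, h, _) in enumerate(linkage):
        i, j = int(i), int(j)
        bi = max(h - heights[i], 0.0)
        bj = max(h - heights[j], 0.0)
        nodes[n + k] = f"({nodes[i]}:{bi:g},{nodes[j]}:{bj:g})"
        heights[n + k] = h
    return nodes[n + linkage.shape[0] - 1] + ";"
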