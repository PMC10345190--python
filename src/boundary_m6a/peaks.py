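"""m6A-IP vs input analysis: normalization, sliding-window Fisher tests,
Benjamini-Hochberg FDR, peak concatenation and expression gating.

Coverage comes in as per-base read counts (bedGraph); the genome is tiled
with non-overlapping 20-nt windows; each window's IP and input counts are
tested against the library remainders with a two-sided Fisher exact test;
windows with enrichment fold > 2 and FDR < 0.05 are concatenated into peaks
of at least 40 nt.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

WINDOW_NT = 20
MIN_FOLD = 2.0
MAX_FDR = 0.05
MIN_PEAK_NT = 40


@dataclass
class CoverageTrack:
    """Per-base read coverage on one reference with its library size."""

    coverage: np.ndarray
    library_size: float | None = None

    def __post_init__(self) -> None:
        self.coverage = np.asarray(self.coverage, dtype=float)
        if (self.coverage < 0).any():
            raise ValueError("coverage must be >= 0")
        if self.library_size is None:
            self.library_size = float(self.coverage.sum())
        if self.library_size <= 0:
            raise ValueError("library size must be > 0")

    def __len__(self) -> int:
        return len(self.coverage)


def read_bedgraph(path: str, length: int, chrom: str | None = None) -> CoverageTrack:
    """Read a bedGraph (chrom, start, end, value; 0-based half-open) into a
    dense per-base track of the given length."""
    cov = np.zeros(length)
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["chrom", "start", "end", "value"], header=None,
    )
    if chrom is not None:
        df = df[df["chrom"] == chrom]
    for start, end, value in zip(df["start"], df["end"], df["value"]):
        cov[int(start):int(end)] += float(value)
    return CoverageTrack(cov)


def write_bedgraph(track: CoverageTrack, path: str, chrom: str = "chr1") -> None:
    """Write a dense track as run-length-compressed bedGraph."""
    cov = track.coverage
    with open(path, "w") as fh:
        if len(cov) == 0:
            return
        change = np.nonzero(np.diff(cov))[0] + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(cov)]])
        for s, e in zip(starts, ends):
            if cov[s] != 0:
                fh.write(f"{chrom}\t{s}\t{e}\t{cov[s]:g}\n")


def enrichment_track(ip: CoverageTrack, input_: CoverageTrack) -> np.ndarray:
    """Per-base IP enrichment = (ip/ip_lib) / (input/input_lib); NaN where
    input coverage is zero (enrichment undefined there; the window-level
    Fisher test handles such positions with a pseudocount)."""
    if len(ip) != len(input_):
        raise ValueError("track lengths differ")
    ip_norm = ip.coverage / ip.library_size
    in_norm = input_.coverage / input_.library_size
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(in_norm > 0, ip_norm / np.where(in_norm > 0, in_norm, 1), np.nan)
    return e


@dataclass
class WindowTest:
    """One 20-nt IP-vs-input window test."""

    start: int
    end: int
    ip_count: int
    input_count: int
    enrichment: float
    p_value: float
    q_value: float = float("nan")


def scan_windows(
    ip: CoverageTrack,
    input_: CoverageTrack,
    window_nt: int = WINDOW_NT,
    step_nt: int | None = None,
) -> list[WindowTest]:
    """Tile the reference with windows and Fisher-test IP vs input counts.

    The 2x2 table is [[ip_in, ip_lib - ip_in], [input_in, input_lib -
    input_in]] (two-sided).  A window with zero reads in both tracks gets
    p = 1 and no enrichment; zero input with nonzero IP adds a pseudocount of
    1 read to both window sums for the enrichment fold only.
    """
    if len(ip) != len(input_):
        raise ValueError("track lengths differ")
    step = step_nt or window_nt
    ip_lib = int(round(ip.library_size))
    in_lib = int(round(input_.library_size))
    p_cache: dict[tuple[int, int], float] = {}
    tests = []
    for start in range(0, len(ip) - window_nt + 1, step):
        end = start + window_nt
        ip_in = int(round(ip.coverage[start:end].sum()))
        in_in = int(round(input_.coverage[start:end].sum()))
        if ip_in == 0 and in_in == 0:
            tests.append(WindowTest(start, end, 0, 0, float("nan"), 1.0))
            continue
        key = (ip_in, in_in)
        p = p_cache.get(key)
        if p is None:
            table = [[ip_in, max(ip_lib - ip_in, 0)], [in_in, max(in_lib - in_in, 0)]]
            p = float(fisher_exact(table, alternative="two-sided")[1])
            p_cache[key] = p
        if in_in == 0:
            fold = ((ip_in + 1) / ip.library_size) / ((in_in + 1) / input_.library_size)
        else:
            fold = (ip_in / ip.library_size) / (in_in / input_.library_size)
        tests.append(WindowTest(start, end, ip_in, in_in, float(fold), float(p)))
    return tests


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, capped at 1;
    output order matches input order.
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0,1]")
    m = len(p)
    if m == 0:
        return np.empty(0)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def attach_fdr(tests: Sequence[WindowTest]) -> None:
    q = bh_fdr([t.p_value for t in tests])
    for t, qv in zip(tests, q):
        t.q_value = float(qv)


@dataclass
class Peak:
    """Run of contiguous significant windows, at least 40 nt long."""

    start: int
    end: int
    windows: list[WindowTest] = field(default_factory=list)

    @property
    def summit(self) -> int:
        best = max(self.windows, key=lambda w: (w.enrichment, -w.start))
        return (best.start + best.end) // 2

    @property
    def min_q(self) -> float:
        return min(w.q_value for w in self.windows)


def call_peaks(
    window_tests: Sequence[WindowTest],
    min_fold: float = MIN_FOLD,
    max_fdr: float = MAX_FDR,
    min_len_nt: int = MIN_PEAK_NT,
) -> list[Peak]:
    """Concatenate adjacent significant windows (fold strictly > min_fold,
    FDR strictly < max_fdr) into peaks; runs shorter than min_len_nt are
    discarded.  Window tests must be coordinate-sorted."""
    if any(np.isnan(t.q_value) for t in window_tests):
        attach_fdr(list(window_tests))
    sig = [
        t for t in window_tests
        if not np.isnan(t.enrichment) and t.enrichment > min_fold and t.q_value < max_fdr
    ]
    peaks: list[Peak] = []
    current: Peak | None = None
    for t in sig:
        if current is not None and t.start == current.end:
            current.end = t.end
            current.windows.append(t)
        else:
            current = Peak(t.start, t.end, [t])
            peaks.append(current)
    return [p for p in peaks if p.end - p.start >= min_len_nt]


# ---------------------------------------------------------------------------
# expression gating
# ---------------------------------------------------------------------------

@dataclass
class ExpressionRecord:
    transcript_id: str
    fragment_count: float
    length_kb: float

    def fpkm(self, mapped_millions: float) -> float:
        if self.length_kb <= 0:
            raise ValueError(f"{self.transcript_id}: zero-length transcript")
        return self.fragment_count / (self.length_kb * mapped_millions)


def fpkm_filter(
    records: Iterable[ExpressionRecord], mapped_millions: float, min_fpkm: float = 1.0
) -> list[ExpressionRecord]:
    """Keep transcripts with FPKM >= min_fpkm (inclusive threshold)."""
    return [r for r in records if r.fpkm(mapped_millions) >= min_fpkm]


# ---------------------------------------------------------------------------
# exon methylation census
# ---------------------------------------------------------------------------

def exon_methylation_census(
    peaks: Sequence[Peak],
    exons: Sequence[tuple[int, int]],
    exon_sequences: Sequence[str] | None = None,
    max_len: int | None = 200,
) -> dict:
    """Census of exons with/without m6A peaks (and with/without RAC).

    ``exons`` are (start, end) intervals in the same coordinate system as the
    peaks.  An exon "has m6A" iff it overlaps at least one peak by >= 1 nt.
    When ``max_len`` is given, only exons of length <= max_len are counted
    (the short-internal-exon census).
    """
    from .motifs import rac_positions

    peak_iv = sorted((p.start, p.end) for p in peaks)
    counts = {"with_m6a": 0, "without_m6a": 0, "with_rac": 0, "without_rac": 0}
    for i, (s, e) in enumerate(exons):
        if max_len is not None and e - s > max_len:
            continue
        hit = any(ps < e and s < pe for ps, pe in peak_iv)
        counts["with_m6a" if hit else "without_m6a"] += 1
        if exon_sequences is not None:
            n_rac = len(rac_positions(exon_sequences[i]))
            counts["with_rac" if n_rac else "without_rac"] += 1
    return counts


def windows_frame(tests: Sequence[WindowTest]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "start": [t.start for t in tests],
            "end": [t.end for t in tests],
            "ip_count": [t.ip_count for t in tests],
            "input_count": [t.input_count for t in tests],
            "enrichment": [t.enrichment for t in tests],
            "p_value": [t.p_value for t in tests],
            "q_value": [t.q_value for t in tests],
        }
    )


def peaks_bed(peaks: Sequence[Peak], chrom: str = "chr1") -> pd.DataFrame:
    """BED6 frame; score = -log10(min window q), capped at 1000."""
    rows = []
    for i, p in enumerate(peaks):
        score = min(-np.log10(max(p.min_q, 1e-300)), 1000.0)
        rows.append((chrom, p.start, p.end, f"peak_{i + 1}", round(score, 3), "+"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
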