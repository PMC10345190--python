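"""k-means clustering of exons on binned DeltaProbability profiles.

The first (or last) 200 nt of each exon are binned into 40 intervals of 5 nt.
Within each interval the RAC site with the maximum (signed) probability
change is selected and its DeltaProbability kept as the interval's DeltaValue;
empty intervals are 0.  Exons are then k-means-clustered (k = 2) on the
40-dimensional DeltaValue rows; the cluster with the larger grand-mean
DeltaValue is labelled C1 (strong boundary inhibition), the other C2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .delta import CAT_INCREASED, DeltaRecord

REGION_NT = 200
BIN_NT = 5
N_BINS = REGION_NT // BIN_NT

C1 = "C1"
C2 = "C2"


@dataclass
class DeltaValueMatrix:
    """Exon-by-interval matrices of DeltaValues and companions."""

    exon_ids: list[str]                  # "<gene>:<exon_index>"
    delta: np.ndarray                    # (n_exons, 40) signed-max DeltaProbability
    p_before: np.ndarray                 # max p_before per interval
    p_after: np.ndarray                  # max p_after per interval
    rac_counts: np.ndarray               # RAC sites per interval
    region: str                          # {exon_start, exon_end}

    def __post_init__(self) -> None:
        for m in (self.delta, self.p_before, self.p_after, self.rac_counts):
            if m.shape != (len(self.exon_ids), N_BINS):
                raise ValueError(f"matrix shape {m.shape} != ({len(self.exon_ids)}, {N_BINS})")


def bin_delta_values(
    delta_records: Sequence[DeltaRecord],
    region: str = "exon_start",
    region_nt: int = REGION_NT,
    bin_nt: int = BIN_NT,
    signed_max: bool = True,
) -> DeltaValueMatrix:
    """Bin per-site DeltaProbabilities into fixed-width intervals per exon.

    ``region`` anchors distances at the exon start or end.  The per-interval
    DeltaValue is the DeltaProbability of the site with the maximum signed
    change (``signed_max=False`` selects by absolute change instead); empty
    intervals are imputed 0, keeping the fixed 40-column geometry.  Exons
    shorter than ``region_nt`` contribute only their covered intervals.
    """
    n_bins = region_nt // bin_nt
    groups: dict[str, list[DeltaRecord]] = {}
    for r in delta_records:
        groups.setdefault(f"{r.gene_id}:{r.exon_index}", []).append(r)
    exon_ids = sorted(groups)
    delta = np.zeros((len(exon_ids), n_bins))
    p_before = np.zeros((len(exon_ids), n_bins))
    p_after = np.zeros((len(exon_ids), n_bins))
    rac = np.zeros((len(exon_ids), n_bins))
    for row, exon_id in enumerate(exon_ids):
        best: dict[int, DeltaRecord] = {}
        for r in groups[exon_id]:
            dist = r.dist_to_exon_start if region == "exon_start" else r.dist_to_exon_end
            if dist >= region_nt:
                continue
            b = dist // bin_nt
            rac[row, b] += 1
            p_before[row, b] = max(p_before[row, b], r.p_before)
            p_after[row, b] = max(p_after[row, b], r.p_after)
            if b not in best:
                best[b] = r
            else:
                key = (lambda x: x.delta) if signed_max else (lambda x: abs(x.delta))
                if key(r) > key(best[b]):
                    best[b] = r
        for b, r in best.items():
            delta[row, b] = r.delta
    return DeltaValueMatrix(exon_ids, delta, p_before, p_after, rac, region)


@dataclass
class ClusterAssignment:
    labels: dict[str, str]               # exon id -> {C1, C2}
    seed: int
    inertia: float
    cluster_means: dict[str, np.ndarray]
    degenerate: bool = False

    def label_array(self, exon_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.labels[e] for e in exon_ids])


def kmeans_two_groups(
    matrix: DeltaValueMatrix, seed: int = 0, n_restarts: int = 10
) -> ClusterAssignment:
    """Two-cluster k-means on the DeltaValue rows.

    Best of ``n_restarts`` by inertia, deterministic for a fixed seed.  C1 is
    the cluster with the larger grand-mean DeltaValue.  Degenerate input (all
    rows identical) assigns everything to C2 with a flag.
    """
    X = matrix.delta
    if len(matrix.exon_ids) < 2 or (X == X[0]).all():
        labels = {e: C2 for e in matrix.exon_ids}
        means = {C2: X[0].copy() if len(X) else np.zeros(X.shape[1])}
        return ClusterAssignment(labels, seed, 0.0, means, degenerate=True)
    km = KMeans(n_clusters=2, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(X)
    grand_means = [X[raw == k].mean() for k in (0, 1)]
    c1_raw = int(np.argmax(grand_means))
    name = {c1_raw: C1, 1 - c1_raw: C2}
    labels = {e: name[k] for e, k in zip(matrix.exon_ids, raw)}
    means = {name[k]: km.cluster_centers_[k] for k in (0, 1)}
    return ClusterAssignment(labels, seed, float(km.inertia_), means)


def cluster_summary(
    matrix: DeltaValueMatrix,
    assignment: ClusterAssignment,
    delta_records: Sequence[DeltaRecord] | None = None,
) -> dict:
    """Heatmap-ready per-cluster interval means plus per-cluster latent-site
    fractions (fraction of sites with DeltaProbability > 0.1)."""
    lab = assignment.label_array(matrix.exon_ids)
    out: dict = {"interval_means": {}, "n_exons": {}, "latent_fraction": {}}
    for cl in (C1, C2):
        mask = lab == cl
        out["n_exons"][cl] = int(mask.sum())
        if mask.any():
            out["interval_means"][cl] = pd.DataFrame(
                {
                    "interval": np.arange(matrix.delta.shape[1]),
                    "delta_value": matrix.delta[mask].mean(axis=0),
                    "p_before": matrix.p_before[mask].mean(axis=0),
                    "p_after": matrix.p_after[mask].mean(axis=0),
                    "rac_count": matrix.rac_counts[mask].mean(axis=0),
                }
            )
    if delta_records is not None:
        exon_label = assignment.labels
        counts = {C1: [0, 0], C2: [0, 0]}  # [increased, total]
        for r in delta_records:
            cl = exon_label.get(f"{r.gene_id}:{r.exon_index}")
            if cl is None:
                continue
            counts[cl][1] += 1
            if r.category == CAT_INCREASED:
                counts[cl][0] += 1
        for cl in (C1, C2):
            inc, tot = counts[cl]
            out["latent_fraction"][cl] = inc / tot if tot else float("nan")
    return out


def matrix_frame(matrix: DeltaValueMatrix) -> pd.DataFrame:
    df = pd.DataFrame(matrix.delta, columns=[f"bin_{i}" for i in range(matrix.delta.shape[1])])
    df.insert(0, "exon_id", matrix.exon_ids)
    return df


def assignment_frame(assignment: ClusterAssignment) -> pd.DataFrame:
    return pd.DataFrame(
        sorted(assignment.labels.items()), columns=["exon_id", "cluster"]
    )
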