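"""Wet-assay math: SELECT qPCR m6A quantification and first-order mRNA decay.

SELECT quantifies m6A at single sites through qPCR Ct values: m6A impedes
the elongation/ligation step, so a methylated site amplifies later (higher
Ct).  Each site's Ct is normalized to two non-RAC control sites on the same
construct; the relative m6A level is 2^(Ct_site - mean Ct_controls) (the
direction is a documented, configurable convention).

Decay kinetics follow first-order loss: fitting ln(level) against time by
ordinary least squares gives the decay constant k = -slope and
T1/2 = ln(2)/k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class SelectMeasurement:
    """Ct replicates for one RAC site plus its two control (non-RAC) sites."""

    construct_id: str            # e.g. intron_containing | intron_deleted
    site_id: str
    ct_replicates: Sequence[float]
    control_cts: Sequence[float]  # pooled replicates of the two control sites

    def __post_init__(self) -> None:
        if len(self.ct_replicates) < 1:
            raise ValueError(f"{self.site_id}: need >= 1 Ct replicate")
        if len(self.control_cts) < 2:
            raise ValueError(
                f"{self.site_id}: need Ct values from two control sites"
            )


def select_relative_level(
    measurement: SelectMeasurement, higher_ct_means_more_m6a: bool = True
) -> float:
    """Relative m6A level of one site: 2^(mean site Ct - mean control Ct).

    With ``higher_ct_means_more_m6a=False`` the exponent is negated.  The
    linear delta-Ct itself is ``math.log2`` of the returned level.
    """
    cts = np.asarray(measurement.ct_replicates, dtype=float)
    controls = np.asarray(measurement.control_cts, dtype=float)
    if not (np.isfinite(cts).all() and np.isfinite(controls).all()):
        raise ValueError(f"{measurement.site_id}: non-finite Ct")
    delta_ct = float(cts.mean() - controls.mean())
    if not higher_ct_means_more_m6a:
        delta_ct = -delta_ct
    return 2.0 ** delta_ct


def relative_level_change(
    intron_deleted: Sequence[float], intron_containing: Sequence[float]
) -> np.ndarray:
    """Per-site change of relative m6A level, deleted minus containing
    (positive = more m6A once the intron is gone)."""
    a = np.asarray(intron_deleted, dtype=float)
    b = np.asarray(intron_containing, dtype=float)
    if a.shape != b.shape:
        raise ValueError("site vectors must align")
    return a - b


def one_sample_t(
    values: Sequence[float], mu: float = 0.0, alternative: str = "greater"
) -> tuple[float, float]:
    """One-sample Student t-test: t = (mean - mu)/(sd/sqrt(n)), p from the
    t distribution with n-1 df ('greater' = upper tail, 'two-sided', 'less')."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need n >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero sample standard deviation; t undefined")
    t = (x.mean() - mu) / (sd / math.sqrt(n))
    if alternative == "greater":
        p = float(sps.t.sf(t, df=n - 1))
    elif alternative == "less":
        p = float(sps.t.cdf(t, df=n - 1))
    elif alternative == "two-sided":
        p = float(2 * sps.t.sf(abs(t), df=n - 1))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(t), p


@dataclass
class DecayFit:
    """First-order decay fit of an mRNA time course."""

    times_h: np.ndarray
    levels_percent: np.ndarray
    k: float                    # decay constant, 1/h
    r_squared: float
    non_decaying: bool = False  # flagged when k <= 0

    @property
    def half_life_h(self) -> float:
        return math.log(2) / self.k


def fit_first_order_decay(
    times_h: Sequence[float], levels_percent: Sequence[float]
) -> DecayFit:
    """Fit level(t) = A * exp(-k t) by OLS on ln(level) vs time.

    Levels are percentages with t=0 normalized to 100% upstream; the
    intercept is left free.  k = -slope, T1/2 = ln(2)/k.  Non-positive
    levels are an error; k <= 0 is flagged non-decaying.
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(levels_percent, dtype=float)
    if len(t) < 3:
        raise ValueError("need >= 3 time points")
    if (y <= 0).any():
        raise ValueError("levels must be > 0 for log-linear fit")
    log_y = np.log(y)
    slope, _, r_value, _, _ = sps.linregress(t, log_y)
    k = -float(slope)
    return DecayFit(t, y, k, float(r_value**2), non_decaying=(k <= 0))
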