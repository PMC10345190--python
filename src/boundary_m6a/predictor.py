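"""Methylation-predictor contract and a transparent synthetic predictor.

Downstream analyses only assume a *contract*: a predictor maps a pre-mRNA
sequence to a per-nucleotide m6A probability profile that is nonzero only at
the A of RAC trinucleotides.  The synthetic predictor here fulfils it with an
explicit, testable mechanism: at every RAC site the log-odds of methylation
is a linear function of the number of enhancer and silencer pentamers inside
a two-sided window around the site,

    p(site) = logistic(beta0 + beta_e * E - beta_s * S),

where E and S count enhancer/silencer pentamers lying fully inside
[site - W_up, site + W_down].  Exon-intron boundary inhibition is not
hard-coded: it emerges when intron ends are silencer-rich, because deleting
the intron swaps those silencers out of the window.

External per-position score tables (e.g. from a trained deep model) are
adapted through :func:`load_external_scores`, which masks scores at non-RAC
positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
import pandas as pd
from scipy.special import expit

from .motifs import ALL_PENTAMERS, rac_positions

#: default per-site calling threshold: a RAC site with probability above this
#: is counted as an m6A site.
CALLING_THRESHOLD = 0.05


@dataclass
class MethylationProfile:
    """Per-nucleotide m6A probability over one sequence."""

    sequence_id: str
    probabilities: np.ndarray
    threshold: float = CALLING_THRESHOLD

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.ndim != 1:
            raise ValueError("profile must be one-dimensional")
        if ((self.probabilities < 0) | (self.probabilities > 1)).any():
            raise ValueError("probabilities must lie in [0,1]")

    def __len__(self) -> int:
        return len(self.probabilities)

    def called_sites(self) -> np.ndarray:
        """Positions with probability strictly above the calling threshold."""
        return np.nonzero(self.probabilities > self.threshold)[0]


class Predictor(Protocol):
    """Sequence -> MethylationProfile, deterministic for fixed inputs."""

    def __call__(self, sequence: str, sequence_id: str = "") -> MethylationProfile: ...


def predict_profile(sequence: str, predictor: Predictor, sequence_id: str = "") -> MethylationProfile:
    """Apply a predictor, attaching the sequence id to any failure."""
    try:
        profile = predictor(sequence, sequence_id)
    except Exception as exc:
        raise RuntimeError(f"predictor failed for sequence {sequence_id!r}") from exc
    if len(profile) != len(sequence):
        raise ValueError(
            f"{sequence_id!r}: profile length {len(profile)} != sequence length {len(sequence)}"
        )
    return profile


# ---------------------------------------------------------------------------
# pentamer weight table
# ---------------------------------------------------------------------------

@dataclass
class PentamerWeightTable:
    """Pentamer -> weight, with designated enhancer and silencer sets.

    Enhancers are the top-k weighted pentamers, silencers the bottom-k; the
    two sets are disjoint by construction.
    """

    weights: dict[str, float]
    enhancers: frozenset[str]
    silencers: frozenset[str]

    def __post_init__(self) -> None:
        if self.enhancers & self.silencers:
            raise ValueError("enhancer and silencer sets must be disjoint")
        if len(self.weights) > 4 ** 5:
            raise ValueError("more than 4^5 pentamer entries")

    @classmethod
    def generate(cls, seed: int, k: int = 50) -> "PentamerWeightTable":
        """Seeded random stand-in for a predictor-derived pentamer ranking.

        Draws a weight per pentamer from N(0,1) and designates the top-k as
        enhancers, bottom-k as silencers.
        """
        rng = np.random.default_rng(seed)
        w = rng.normal(size=len(ALL_PENTAMERS))
        order = np.argsort(w)
        weights = dict(zip(ALL_PENTAMERS, w))
        silencers = frozenset(ALL_PENTAMERS[i] for i in order[:k])
        enhancers = frozenset(ALL_PENTAMERS[i] for i in order[-k:])
        return cls(weights, enhancers, silencers)

    @classmethod
    def from_tsv(cls, path: str) -> "PentamerWeightTable":
        """Read a TSV with columns pentamer, weight, class ({enhancer,
        silencer, neutral})."""
        df = pd.read_csv(path, sep="\t")
        weights = dict(zip(df["pentamer"].str.upper(), df["weight"].astype(float)))
        enh = frozenset(df.loc[df["class"] == "enhancer", "pentamer"].str.upper())
        sil = frozenset(df.loc[df["class"] == "silencer", "pentamer"].str.upper())
        return cls(weights, enh, sil)

    def to_tsv(self, path: str) -> None:
        rows = []
        for pent, w in sorted(self.weights.items()):
            cls_ = (
                "enhancer" if pent in self.enhancers
                else "silencer" if pent in self.silencers
                else "neutral"
            )
            rows.append((pent, w, cls_))
        pd.DataFrame(rows, columns=["pentamer", "weight", "class"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class SyntheticPredictorConfig:
    """Parameters of the synthetic logistic predictor.

    ``window_up``/``window_down`` are the two-sided scoring-window extents in
    nt around the methylated A; a pentamer must lie fully inside
    [site - window_up, site + window_down] (and inside the sequence) to count.
    """

    intercept: float = -3.2
    enhancer_weight: float = 0.3
    silencer_weight: float = 0.6
    window_up: int = 100
    window_down: int = 100

    def __post_init__(self) -> None:
        if not np.isfinite([self.intercept, self.enhancer_weight, self.silencer_weight]).all():
            raise ValueError("weights must be finite")
        if self.enhancer_weight < 0 or self.silencer_weight < 0:
            raise ValueError("enhancer/silencer weights must be >= 0")
        if self.window_up + self.window_down < 5:
            raise ValueError("scoring window must span at least 5 nt")


_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i

_MOTIF_CODE_CACHE: dict[frozenset, np.ndarray] = {}


def _pentamer_codes(seq: str) -> np.ndarray:
    """Base-4 integer code of the pentamer starting at each position (-1 where
    any base is not ACGT); length len(seq) - 4."""
    arr = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n_starts = max(len(seq) - 4, 0)
    if n_starts == 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n_starts, dtype=np.int64)
    bad = np.zeros(n_starts, dtype=bool)
    for k in range(5):
        window = arr[k:k + n_starts]
        codes = codes * 4 + np.maximum(window, 0)
        bad |= window < 0
    codes[bad] = -1
    return codes


def _motif_codes(motifs: frozenset[str]) -> np.ndarray:
    if motifs not in _MOTIF_CODE_CACHE:
        vals = []
        for m in motifs:
            code = 0
            for b in m:
                code = code * 4 + int(_BASE_CODE[ord(b)])
            vals.append(code)
        _MOTIF_CODE_CACHE[motifs] = np.array(sorted(vals), dtype=np.int64)
    return _MOTIF_CODE_CACHE[motifs]


def synthetic_predict(
    sequence: str,
    weights: PentamerWeightTable,
    config: SyntheticPredictorConfig | None = None,
    sequence_id: str = "",
) -> MethylationProfile:
    """Score every RAC site of a sequence with the logistic pentamer model.

    Positions that are not the A of a RAC trinucleotide get probability 0.
    N never matches RAC and pentamers containing N count as neutral.
    """
    cfg = config or SyntheticPredictorConfig()
    seq = sequence.upper()
    n = len(seq)
    probs = np.zeros(n)
    sites = rac_positions(seq)
    if len(sites) == 0:
        return MethylationProfile(sequence_id, probs)

    # indicator of enhancer/silencer pentamer starting at each position
    n_starts = max(n - 4, 0)
    codes = _pentamer_codes(seq)
    enh = np.zeros(n_starts + 1)
    sil = np.zeros(n_starts + 1)
    valid = codes >= 0
    enh[1:][valid & np.isin(codes, _motif_codes(weights.enhancers))] = 1
    sil[1:][valid & np.isin(codes, _motif_codes(weights.silencers))] = 1
    enh_cum = np.cumsum(enh)
    sil_cum = np.cumsum(sil)

    # pentamer start range fully inside [site - W_up, site + W_down]:
    # start j in [site - W_up, site + W_down - 4], half-open upper bound +1
    lo = np.clip(sites - cfg.window_up, 0, n_starts)
    hi = np.clip(sites + cfg.window_down - 3, 0, n_starts)
    hi = np.maximum(hi, lo)
    e_counts = enh_cum[hi] - enh_cum[lo]
    s_counts = sil_cum[hi] - sil_cum[lo]
    logits = cfg.intercept + cfg.enhancer_weight * e_counts - cfg.silencer_weight * s_counts
    probs[sites] = expit(logits)
    return MethylationProfile(sequence_id, probs)


@dataclass
class SyntheticPredictor:
    """Callable predictor bundling a weight table and config (fulfils the
    :class:`Predictor` contract)."""

    weights: PentamerWeightTable
    config: SyntheticPredictorConfig = field(default_factory=SyntheticPredictorConfig)

    def __call__(self, sequence: str, sequence_id: str = "") -> MethylationProfile:
        return synthetic_predict(sequence, self.weights, self.config, sequence_id)


# ---------------------------------------------------------------------------
# external score tables
# ---------------------------------------------------------------------------

def load_external_scores(
    score_table: pd.DataFrame | str,
    sequence: str,
    sequence_id: str = "",
    one_based: bool = False,
) -> MethylationProfile:
    """Adapt an external (position, probability) score table to a profile.

    Rows at positions that are not the A of a RAC trinucleotide are masked to
    zero (with a warning reporting the count); positions beyond the sequence
    are an error.
    """
    if isinstance(score_table, str):
        score_table = pd.read_csv(score_table, sep="\t")
    seq = sequence.upper()
    probs = np.zeros(len(seq))
    if len(score_table) == 0:
        return MethylationProfile(sequence_id, probs)
    pos = score_table["position"].to_numpy(dtype=int)
    if one_based:
        pos = pos - 1
    if (pos < 0).any() or (pos >= len(seq)).any():
        bad = pos[(pos < 0) | (pos >= len(seq))]
        raise ValueError(f"{sequence_id!r}: score positions outside sequence: {bad[:5]}")
    vals = score_table["probability"].to_numpy(dtype=float)
    rac = np.zeros(len(seq), dtype=bool)
    rac[rac_positions(seq)] = True
    keep = rac[pos]
    n_masked = int((~keep).sum())
    if n_masked:
        warnings.warn(f"{sequence_id!r}: masked {n_masked} score row(s) at non-RAC positions")
    probs[pos[keep]] = np.clip(vals[keep], 0.0, 1.0)
    return MethylationProfile(sequence_id, probs)


def write_scores(profile: MethylationProfile, path: str) -> None:
    """Write nonzero profile entries as a (sequence_id, position, probability)
    TSV, 0-based, 6-decimal round trip."""
    pos = np.nonzero(profile.probabilities)[0]
    pd.DataFrame(
        {
            "sequence_id": profile.sequence_id,
            "position": pos,
            "probability": np.round(profile.probabilities[pos], 6),
        }
    ).to_csv(path, sep="\t", index=False)
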