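"""Type-1 signal-detection primitives for 2-AFC confidence-rating data.

A trial table holds one row per 2-AFC decision (with an optional 1..K
confidence rating); this module aggregates such tables into the
2 (stimulus) x 2 (response) x K (confidence) count tables that are the
sufficient statistic for every model downstream, and computes the
closed-form equal-variance type-1 estimates d', c and c' = c/d'.

Coordinate convention: "right" is treated as the signal (S2) stimulus and
a "right" response as "yes".  With hit rate H = P(respond right | right)
and false-alarm rate F = P(respond right | left),

    d' = z(H) - z(F),        c = -(z(H) + z(F)) / 2,

so a bias *towards "left" responses appears as c > 0*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

SIDES = ("left", "right")
#: probabilities are clipped to [EPS, 1 - EPS] before the quantile transform
EPS = 1e-6

__all__ = [
    "RatingCounts",
    "Type1Estimates",
    "counts_from_trials",
    "type1_fit",
]


@dataclass(frozen=True)
class RatingCounts:
    """2 x 2 x K confidence-rating count table.

    ``counts[s, r, y]`` is the number of responded trials with stimulus side
    ``s`` (0 = left, 1 = right), response side ``r`` and confidence ``y + 1``.
    ``n_dropped`` records non-responded trials removed during aggregation and
    ``n_zero_evidence`` the trials from the identical (zero-evidence)
    condition, which have no defined correct answer but are tabulated under
    their labelled stimulus side.
    """

    counts: np.ndarray
    K: int
    n_dropped: int = 0
    n_zero_evidence: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.shape != (2, 2, self.K):
            raise ValueError(f"counts must have shape (2, 2, {self.K}), got {c.shape}")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def response_marginals(self) -> np.ndarray:
        """Collapse confidence: 2x2 table of (stimulus, response) counts."""
        return self.counts.sum(axis=2)

    def scaled(self, k: int) -> "RatingCounts":
        return RatingCounts(self.counts * k, self.K, self.n_dropped, self.n_zero_evidence)


@dataclass(frozen=True)
class Type1Estimates:
    """Closed-form equal-variance type-1 SDT estimates."""

    d_prime: float
    c: float
    c_rel: float  # relative criterion c / d'; nan when d' == 0
    hit_rate: float
    fa_rate: float


def _validate_trials(trials: pd.DataFrame, K: int) -> pd.DataFrame:
    required = {"stimulus_side", "response_side", "confidence", "responded"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    resp = trials[trials["responded"].astype(bool)]
    if len(resp) == 0:
        raise ValueError("no responded trials")
    conf = resp["confidence"].to_numpy(dtype=float)
    if np.any(np.isnan(conf)):
        raise ValueError("confidence missing on responded trials")
    if np.any((conf < 1) | (conf > K) | (conf != np.round(conf))):
        raise ValueError(f"confidence ratings must be integers in 1..{K}")
    for col in ("stimulus_side", "response_side"):
        bad = set(resp[col].unique()) - set(SIDES)
        if bad:
            raise ValueError(f"invalid {col} values: {sorted(bad)}")
    return resp


def counts_from_trials(trials: pd.DataFrame, K: int = 6) -> RatingCounts:
    """Tabulate a trial table into a :class:`RatingCounts`.

    Non-responded trials are dropped (their number is reported on the result);
    zero-evidence trials are kept under their labelled stimulus side and
    counted in ``n_zero_evidence``.
    """
    resp = _validate_trials(trials, K)
    n_dropped = len(trials) - len(resp)
    counts = np.zeros((2, 2, K))
    s_idx = (resp["stimulus_side"] == "right").to_numpy().astype(int)
    r_idx = (resp["response_side"] == "right").to_numpy().astype(int)
    y_idx = resp["confidence"].to_numpy(dtype=int) - 1
    np.add.at(counts, (s_idx, r_idx, y_idx), 1.0)
    n_zero = 0
    if "evidence_level" in resp.columns:
        n_zero = int((resp["evidence_level"].to_numpy(dtype=float) == 0).sum())
    return RatingCounts(counts, K, n_dropped=n_dropped, n_zero_evidence=n_zero)


def z(p: np.ndarray | float) -> np.ndarray | float:
    """Standard-normal quantile with clipping to [EPS, 1-EPS]."""
    return norm.ppf(np.clip(p, EPS, 1.0 - EPS))


def type1_fit(counts: RatingCounts, padding: float | None = None) -> Type1Estimates:
    """Closed-form type-1 fit from the response marginals.

    ``padding`` is added to every rating cell before collapsing confidence
    (default 1/(2K), the convention used throughout the meta-d' fits); it
    guarantees finite rates for extreme observers.
    """
    if padding is None:
        padding = 1.0 / (2 * counts.K)
    if padding < 0:
        raise ValueError("padding must be >= 0")
    padded = counts.counts + padding
    marg = padded.sum(axis=2)  # (stimulus, response)
    row_tot = marg.sum(axis=1)
    if np.any(row_tot <= 0):
        raise ValueError("a stimulus row has zero total; cannot estimate rates")
    fa_rate = marg[0, 1] / row_tot[0]   # P(right | left stimulus)
    hit_rate = marg[1, 1] / row_tot[1]  # P(right | right stimulus)
    zh, zf = z(hit_rate), z(fa_rate)
    d_prime = float(zh - zf)
    c = float(-0.5 * (zh + zf))
    c_rel = c / d_prime if d_prime != 0 else float("nan")
    return Type1Estimates(d_prime=d_prime, c=c, c_rel=c_rel,
                          hit_rate=float(hit_rate), fa_rate=float(fa_rate))
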