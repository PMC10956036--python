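"""Transdiagnostic factor scores, questionnaire totals and Big-5 scores.

Factor scores apply a supplied 209-item x 3-factor weight matrix (the
published transdiagnostic solution, or a synthetic stand-in for testing):
each item column is z-scored across participants, multiplied by its weight,
summed within each factor, and the factor sums are z-scored again.  The three
resulting dimensions are anxious-depression (AD), compulsive behaviour and
intrusive thought (CIT) and social withdrawal (SW).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .instruments import (BIG5_RANGE, BIG5_SUBSCALES, FACTOR_NAMES,
                          PSYCHIATRIC_INSTRUMENTS, all_item_ids, item_ids)

__all__ = [
    "FactorWeights",
    "collapse_lsas",
    "score_factors",
    "questionnaire_totals",
]


@dataclass(frozen=True)
class FactorWeights:
    """209-item x 3-factor weight matrix keyed by item id."""

    weights: pd.DataFrame  # index: item_id; columns: AD, CIT, SW

    def __post_init__(self) -> None:
        w = self.weights
        if list(w.columns) != list(FACTOR_NAMES):
            raise ValueError(f"weight columns must be {FACTOR_NAMES}")
        if w.index.duplicated().any():
            raise ValueError("duplicate item ids in weight matrix")
        if w.isna().any().any():
            raise ValueError("missing weights")
        if len(w) != 209:
            raise ValueError(f"expected 209 items, got {len(w)}")

    @classmethod
    def from_csv(cls, path) -> "FactorWeights":
        df = pd.read_csv(path).set_index("item_id")
        return cls(df[list(FACTOR_NAMES)])

    def to_csv(self, path) -> None:
        self.weights.rename_axis("item_id").to_csv(path)


def collapse_lsas(fear: np.ndarray | pd.DataFrame,
                  avoidance: np.ndarray | pd.DataFrame) -> np.ndarray | pd.DataFrame:
    """Average the fear/anxiety and avoidance answer of each social-anxiety item."""
    if np.shape(fear) != np.shape(avoidance):
        raise ValueError("fear and avoidance matrices must have identical shapes")
    return (fear + avoidance) / 2


def _zscore_cols(x: np.ndarray, label: str = "column") -> np.ndarray:
    sd = x.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"zero-variance {label}(s) at index {bad.tolist()}")
    return (x - x.mean(axis=0)) / sd


def score_factors(items: pd.DataFrame, weights: FactorWeights) -> pd.DataFrame:
    """Weighted-sum factor scores: z-score items, weight, sum, z-score sums.

    ``items`` is a participants x items table whose columns are item ids
    matching the weight matrix.  Returns an n x 3 DataFrame (AD, CIT, SW),
    each column with cohort mean 0 and SD 1.
    """
    if len(items) < 3:
        raise ValueError("need at least 3 participants to z-score across the cohort")
    missing = set(weights.weights.index) - set(items.columns)
    if missing:
        raise ValueError(f"items table missing {len(missing)} weighted items, "
                         f"e.g. {sorted(missing)[:3]}")
    x = items[weights.weights.index].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("missing item responses")
    sd = x.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = [weights.weights.index[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance item column(s): {bad}")
    xz = (x - x.mean(axis=0)) / sd
    sums = xz @ weights.weights.to_numpy(dtype=float)
    scores = _zscore_cols(sums, "factor sum")
    return pd.DataFrame(scores, index=items.index, columns=list(FACTOR_NAMES))


def _reverse(resp: np.ndarray, lo: int, hi: int, reverse_idx: list[int]) -> np.ndarray:
    out = resp.astype(float).copy()
    for i in reverse_idx:
        out[:, i - 1] = lo + hi - out[:, i - 1]
    return out


def questionnaire_totals(items: pd.DataFrame, log_offset: float = 1.0,
                         big5_items: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-instrument totals, their log transform, and Big-5 subscale means.

    ``items`` holds raw (keyed-as-administered) responses, one column per
    item id; reverse-keyed items are re-coded per the instrument config
    before summation.  ``log_<name>`` columns are ``ln(total + log_offset)``
    (some instruments, e.g. the alcohol-use test, can legitimately total 0).
    """
    out = {}
    for name, cfg in PSYCHIATRIC_INSTRUMENTS.items():
        ids = item_ids(name)
        missing = [i for i in ids if i not in items.columns]
        if missing:
            raise ValueError(f"missing items for {name}: {missing}")
        resp = items[ids].to_numpy(dtype=float)
        if np.isnan(resp).any():
            raise ValueError(f"missing responses in {name}")
        resp = _reverse(resp, cfg["min"], cfg["max"], cfg["reverse"])
        total = resp.sum(axis=1)
        out[name] = total
        out[f"log_{name}"] = np.log(total + log_offset)
    if big5_items is not None:
        lo, hi = BIG5_RANGE
        start = 0
        for sub, n in BIG5_SUBSCALES.items():
            ids = [f"bfi_{i:02d}" for i in range(start + 1, start + n + 1)]
            missing = [i for i in ids if i not in big5_items.columns]
            if missing:
                raise ValueError(f"missing Big-5 items: {missing}")
            out[sub] = big5_items[ids].to_numpy(dtype=float).mean(axis=1)
            start += n
    return pd.DataFrame(out, index=items.index)
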