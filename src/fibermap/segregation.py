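"""Goodness-of-fit of phenotype counts against Mendelian ratios.

For a single partially dominant locus, brown and cream F2 plants are
both carriers, so the carrier:white split is expected to fit 3:1.
Pearson's chi-square without continuity correction is used — the
conventional test for segregation ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["SegregationResult", "chi_square_ratio"]


@dataclass(frozen=True)
class SegregationResult:
    observed: tuple[int, ...]
    expected: tuple[float, ...]
    chi2: float
    df: int
    p_value: float

    def to_row(self) -> dict:
        return {
            "observed": ":".join(str(o) for o in self.observed),
            "expected": ":".join(f"{e:g}" for e in self.expected),
            "chi2": self.chi2,
            "df": self.df,
            "p_value": self.p_value,
        }


def chi_square_ratio(
    observed: Sequence[int], ratio: Sequence[float]
) -> SegregationResult:
    """Pearson chi-square of observed class counts against a ratio.

    ``ratio`` is a vector of positive weights (e.g. ``(3, 1)``); expected
    counts are the observed total split in proportion. No Yates
    correction is applied. The statistic is invariant under rescaling of
    the weights.
    """
    obs = np.asarray(observed, dtype=float)
    w = np.asarray(ratio, dtype=float)
    if obs.shape != w.shape or obs.ndim != 1 or len(obs) < 2:
        raise ValueError("observed and ratio must be equal-length vectors of length >= 2")
    if np.any(obs < 0):
        raise ValueError("negative counts")
    if np.any(w <= 0):
        raise ValueError("ratio weights must be > 0")
    total = obs.sum()
    if total <= 0:
        raise ValueError("total observed count must be > 0")
    expected = total * w / w.sum()
    chi2, p = stats.chisquare(obs, f_exp=expected)
    return SegregationResult(
        observed=tuple(int(o) for o in obs),
        expected=tuple(float(e) for e in expected),
        chi2=float(chi2),
        df=len(obs) - 1,
        p_value=float(p),
    )
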