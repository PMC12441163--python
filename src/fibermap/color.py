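"""CIELab color arithmetic, replicate averaging, grouping, group comparison.

The phenotype currency of the mapping study is a CIELab triple
(L* lightness 0–100, a* green–red, b* blue–yellow) measured in three
technical replicates per fiber sample. Color differences use the CIE76
formula: the Euclidean distance ΔE = sqrt(ΔL² + Δa² + Δb²). As a rule of
thumb, ΔE < 1 is imperceptible, ≈ 2 is perceptible on close inspection,
≈ 10 clearly different, and > 50 completely different colors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "delta_e",
    "average_replicates",
    "classify_colors",
    "compare_groups",
    "GroupComparison",
]


def _as_lab(c) -> np.ndarray:
    arr = np.asarray(c, dtype=float)
    if arr.shape != (3,):
        raise ValueError("a color measurement is a (L*, a*, b*) triple")
    if not np.all(np.isfinite(arr)):
        raise ValueError("color channels must be finite")
    return arr


def delta_e(c1, c2) -> float:
    """CIE76 color difference between two CIELab triples.

    Symmetric, zero iff identical, Euclidean in (L*, a*, b*).
    """
    return float(np.linalg.norm(_as_lab(c1) - _as_lab(c2)))


def average_replicates(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Channel-wise mean over technical replicates, one row per sample.

    Expects a long table with columns ``id, L, a, b`` (a ``replicate``
    column may be present and is ignored). Every sample needs >= 1
    replicate with finite channels.
    """
    for col in ("id", "L", "a", "b"):
        if col not in phenotypes.columns:
            raise ValueError(f"phenotype table missing column {col!r}")
    if len(phenotypes) == 0:
        raise ValueError("empty phenotype table")
    if not np.all(np.isfinite(phenotypes[["L", "a", "b"]].to_numpy(dtype=float))):
        raise ValueError("non-finite color channel")
    return phenotypes.groupby("id", sort=False)[["L", "a", "b"]].mean().reset_index()


def classify_colors(
    samples: pd.DataFrame,
    brown_ref,
    white_ref,
    cream_band: float = 5.0,
) -> pd.Series:
    """Assign each sample to brown / cream / white by reference distance.

    A sample is *brown* when its ΔE to the brown reference undercuts its
    ΔE to the white reference by more than ``cream_band``, *white* in the
    mirrored case, and *cream* inside the band. With noiseless
    incomplete dominance the heterozygote midpoint color is exactly
    equidistant from the parents, so any positive band labels it cream.

    ``samples`` is a per-sample table (``id, L, a, b``), e.g. the output
    of :func:`average_replicates`. Returns a Series of labels indexed by
    sample id; assignment is deterministic and order-independent.
    """
    brown = _as_lab(brown_ref)
    white = _as_lab(white_ref)
    if cream_band < 0:
        raise ValueError("cream_band must be >= 0")
    if delta_e(brown, white) <= 2 * cream_band:
        raise ValueError("reference colors closer than twice the cream band")
    lab = samples[["L", "a", "b"]].to_numpy(dtype=float)
    d_brown = np.linalg.norm(lab - brown, axis=1)
    d_white = np.linalg.norm(lab - white, axis=1)
    labels = np.where(
        d_brown < d_white - cream_band,
        "brown",
        np.where(d_white < d_brown - cream_band, "white", "cream"),
    )
    return pd.Series(labels, index=samples["id"].to_numpy(), name="group")


@dataclass
class GroupComparison:
    """One-way ANOVA plus Tukey HSD pairwise comparisons for one trait."""

    trait: str
    group_means: dict[str, float]
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # group_a, group_b, mean_diff, p_adj

    def to_frame(self) -> pd.DataFrame:
        out = self.pairwise.copy()
        out.insert(0, "trait", self.trait)
        return out


def compare_groups(values, labels, trait: str = "trait") -> GroupComparison:
    """Compare a trait across >= 2 groups.

    One-way ANOVA for the overall test and Tukey's honest significant
    difference (studentized range; Tukey–Kramer for unbalanced groups)
    for all pairwise adjusted p-values — the standard multi-group
    comparison for both the color channels and the flame-retardancy
    (combustion calorimetry) traits.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must align")
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    per_group = [values[labels == g] for g in groups]
    if min(len(v) for v in per_group) < 2:
        raise ValueError("need >= 2 values per group")
    f_stat, p = stats.f_oneway(*per_group)
    hsd = stats.tukey_hsd(*per_group)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            rows.append(
                (
                    groups[i],
                    groups[j],
                    float(np.mean(per_group[i]) - np.mean(per_group[j])),
                    float(hsd.pvalue[i, j]),
                )
            )
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "mean_diff", "p_adj"])
    means = {str(g): float(np.mean(v)) for g, v in zip(groups, per_group)}
    return GroupComparison(
        trait=trait,
        group_means=means,
        f_statistic=float(f_stat),
        p_value=float(p),
        pairwise=pairwise,
    )
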