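"""Dominant-marker co-segregation counting and interval delimitation.

Mutant-specific PCR markers call P (positive) in any plant carrying the
mutant allele and N otherwise, so heterozygous and homozygous carriers
are indistinguishable and no recombination fraction is estimated — only
concordance with the phenotype groups. Brown and cream plants are both
carriers; a recombinant is a white plant scoring P or a carrier scoring
N. The mapped interval is bracketed by the nearest markers showing
recombinants on either side of the zero-recombinant (co-segregating)
set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["score_recombinants", "find_interval", "IntervalResult"]

_CARRIER_GROUPS = {"brown", "cream"}


def score_recombinants(
    calls: pd.DataFrame, groups: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Count phenotype-discordant plants per marker.

    ``calls`` is a long table ``individual, marker, call`` with calls in
    {P, N, missing}; ``groups`` maps individual id to brown/cream/white.
    Missing calls are excluded from the informative count. Returns a
    DataFrame ``marker, n_informative, recombinants``. A call for an
    individual with no phenotype group is an error.
    """
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    required = {"individual", "marker", "call"}
    if not required <= set(calls.columns):
        raise ValueError(f"calls table must have columns {sorted(required)}")
    bad = set(calls["call"].unique()) - {"P", "N", "missing"}
    if bad:
        raise ValueError(f"unknown marker calls: {sorted(bad)}")
    scored = calls[calls["call"] != "missing"].copy()
    unknown = set(scored["individual"].unique()) - set(groups.index)
    if unknown:
        raise ValueError(f"individuals with calls but no phenotype: {sorted(unknown)[:5]}")
    grp = scored["individual"].map(groups)
    if not set(grp.unique()) <= {"brown", "cream", "white"}:
        raise ValueError("phenotype groups must be brown/cream/white")
    carrier = grp.isin(_CARRIER_GROUPS)
    positive = scored["call"] == "P"
    scored["recombinant"] = carrier != positive
    out = (
        scored.groupby("marker", sort=False)
        .agg(n_informative=("recombinant", "size"), recombinants=("recombinant", "sum"))
        .reset_index()
    )
    out["recombinants"] = out["recombinants"].astype(int)
    return out


@dataclass
class IntervalResult:
    """The mapped interval around the co-segregating marker set.

    ``open_interval`` flags panels with no flanking recombinant marker on
    one or both sides (or no co-segregating marker at all), where the
    locus is localized only to one side of the panel.
    """

    chrom: str
    cosegregating: list[str]
    left_flank: str | None
    right_flank: str | None
    span_bp: int | None
    open_interval: bool
    per_marker: pd.DataFrame = field(repr=False)

    def to_row(self) -> dict:
        return {
            "chrom": self.chrom,
            "cosegregating": ",".join(self.cosegregating) or ".",
            "left_flank": self.left_flank or ".",
            "right_flank": self.right_flank or ".",
            "span_bp": self.span_bp if self.span_bp is not None else ".",
            "open_interval": self.open_interval,
        }


def find_interval(markers: pd.DataFrame, counts: pd.DataFrame) -> IntervalResult:
    """Delimit the locus interval from per-marker recombinant counts.

    ``markers`` holds ``name, chrom, pos`` (one chromosome only);
    ``counts`` is the output of :func:`score_recombinants`. The
    co-segregating set is every marker with zero recombinants; the
    flanks are the nearest markers with >= 1 recombinant outside the
    co-segregating span, and the interval span is the distance between
    the flank positions. With no zero-recombinant marker the result
    reports the minimum-recombinant marker(s) and is flagged open.
    """
    if markers["chrom"].nunique() != 1:
        raise ValueError("markers must lie on a single chromosome")
    chrom = str(markers["chrom"].iloc[0])
    table = markers.merge(counts, left_on="name", right_on="marker", how="inner")
    if len(table) == 0:
        raise ValueError("no scored markers")
    table = table.sort_values("pos", kind="mergesort").reset_index(drop=True)
    zero = table[table["recombinants"] == 0]
    if len(zero) == 0:
        # no co-segregation observed: report the best marker(s), open interval
        best = int(table["recombinants"].min())
        tied = table[table["recombinants"] == best]
        return IntervalResult(
            chrom=chrom,
            cosegregating=list(tied["name"]),
            left_flank=None,
            right_flank=None,
            span_bp=None,
            open_interval=True,
            per_marker=table,
        )
    lo_pos = zero["pos"].min()
    hi_pos = zero["pos"].max()
    left = table[(table["pos"] < lo_pos) & (table["recombinants"] > 0)]
    right = table[(table["pos"] > hi_pos) & (table["recombinants"] > 0)]
    left_flank = left.iloc[-1] if len(left) else None
    right_flank = right.iloc[0] if len(right) else None
    open_interval = left_flank is None or right_flank is None
    span = (
        int(right_flank["pos"] - left_flank["pos"])
        if not open_interval
        else None
    )
    if open_interval:
        span = int(table["pos"].iloc[-1] - table["pos"].iloc[0])
    return IntervalResult(
        chrom=chrom,
        cosegregating=list(zero["name"]),
        left_flank=None if left_flank is None else str(left_flank["name"]),
        right_flank=None if right_flank is None else str(right_flank["name"]),
        span_bp=span,
        open_interval=open_interval,
        per_marker=table,
    )


def calls_matrix(calls: pd.DataFrame, markers: pd.DataFrame) -> pd.DataFrame:
    """Individuals x markers P/N matrix, markers ordered by position."""
    order = markers.sort_values("pos", kind="mergesort")["name"].tolist()
    wide = calls.pivot(index="individual", columns="marker", values="call")
    return wide.reindex(columns=order)
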