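"""Genome-wide bulk comparison: subtract, bin, and find the peak.

The scan logic of bulked-segregant analysis at the called-variant level:
variants called identically in both phenotype bulks carry no mapping
information and are subtracted; the residual bulk-differential variants
are counted in fixed-width windows (default 5 Mb), and the causal region
shows up as the window run around the global peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sim import GenomeModel
from .variants import VariantSet

__all__ = ["subtract_shared_variants", "bin_counts", "detect_peak", "PeakRegion"]

_KEY = ["chrom", "pos", "ref", "alt"]


def _check_coordinates(a: VariantSet, b: VariantSet) -> None:
    if not a.contigs or not b.contigs:
        return
    for first, second, tag in ((a, b, "second"), (b, a, "first")):
        missing = set(first.df["chrom"].unique()) - set(second.contigs)
        if missing:
            raise ValueError(
                f"coordinate-system mismatch: contigs {sorted(missing)} absent "
                f"from the {tag} set's header"
            )
    shared = set(a.contigs) & set(b.contigs)
    bad = [c for c in shared if a.contigs[c] and b.contigs[c] and a.contigs[c] != b.contigs[c]]
    if bad:
        raise ValueError(f"coordinate-system mismatch: contig lengths differ for {sorted(bad)}")


def subtract_shared_variants(
    bulk_a: VariantSet,
    bulk_b: VariantSet,
    labels: tuple[str, str] = ("bulk_a", "bulk_b"),
) -> VariantSet:
    """Symmetric difference of two bulk variant sets.

    Identity is ``(chrom, pos, ref, alt)`` only — zygosity is ignored, so
    the same variant called in both bulks is removed regardless of
    pooled-genotype noise. Retained variants are tagged with their bulk
    of origin in an ``origin`` column. The result is unordered-symmetric:
    swapping the inputs permutes labels but not membership.
    """
    _check_coordinates(bulk_a, bulk_b)
    a = bulk_a.df.drop_duplicates(subset=_KEY).copy()
    b = bulk_b.df.drop_duplicates(subset=_KEY).copy()
    a_keys = pd.MultiIndex.from_frame(a[_KEY])
    b_keys = pd.MultiIndex.from_frame(b[_KEY])
    only_a = a.loc[~a_keys.isin(b_keys)].copy()
    only_b = b.loc[~b_keys.isin(a_keys)].copy()
    only_a["origin"] = labels[0]
    only_b["origin"] = labels[1]
    out = pd.concat([only_a, only_b], ignore_index=True)
    out = out.sort_values(["chrom", "pos", "ref", "alt"], kind="mergesort").reset_index(drop=True)
    contigs = {**bulk_b.contigs, **bulk_a.contigs}
    return VariantSet(out, contigs=contigs)


def bin_counts(
    variants: VariantSet, bin_width: int, genome: GenomeModel
) -> pd.DataFrame:
    """Count variants in fixed windows tiling every chromosome.

    Windows are 0-based half-open ``[0, w), [w, 2w), ...``; a variant at
    1-based position p falls in window ``floor((p - 1) / w)``. Every
    window is emitted, zeros included; the last window is clipped to the
    chromosome end. Returns a DataFrame ``chrom, start, end, count``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    frames = []
    df = variants.df
    for c in genome.chromosomes:
        sub = df[df["chrom"] == c.name]
        if len(sub) and int(sub["pos"].max()) > c.length_bp:
            raise ValueError(
                f"variant beyond declared length of {c.name} ({c.length_bp} bp)"
            )
        n_bins = int(np.ceil(c.length_bp / bin_width))
        idx = (sub["pos"].to_numpy() - 1) // bin_width
        counts = np.bincount(idx, minlength=n_bins) if len(sub) else np.zeros(n_bins, int)
        starts = np.arange(n_bins, dtype=np.int64) * bin_width
        ends = np.minimum(starts + bin_width, c.length_bp)
        frames.append(
            pd.DataFrame({"chrom": c.name, "start": starts, "end": ends, "count": counts})
        )
    stray = set(df["chrom"].unique()) - {c.name for c in genome.chromosomes}
    if stray:
        raise ValueError(f"variants on chromosomes absent from the genome model: {sorted(stray)}")
    return pd.concat(frames, ignore_index=True)


@dataclass
class PeakRegion:
    """The scan's peak window and its surrounding high-count run."""

    found: bool
    chrom: str | None = None
    start: int | None = None  # 0-based half-open, like the bins
    end: int | None = None
    peak_count: int = 0
    windows: pd.DataFrame | None = None

    def contains(self, chrom: str, pos: int) -> bool:
        """Whether a 1-based position falls inside the region."""
        if not self.found or chrom != self.chrom:
            return False
        return self.start < pos <= self.end  # 1-based pos vs half-open window


def detect_peak(bins: pd.DataFrame, extend_fraction: float = 0.5) -> PeakRegion:
    """Locate the global maximum window and extend it into a region.

    The peak is the window with the global maximum count (ties broken by
    lowest chromosome name, then lowest start); the region is the maximal
    run of adjacent windows on that chromosome whose counts stay at or
    above ``extend_fraction`` times the peak count. All-zero scans return
    a flagged no-peak result.
    """
    if len(bins) == 0:
        raise ValueError("no bins")
    if not 0.0 <= extend_fraction <= 1.0:
        raise ValueError("extend_fraction must be in [0, 1]")
    if int(bins["count"].max()) == 0:
        return PeakRegion(found=False)
    ordered = bins.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    peak_count = int(ordered["count"].max())
    peak_idx = int(
        ordered.index[ordered["count"] == peak_count][0]
    )  # first after the sort = lowest chrom, then lowest start
    chrom = ordered.at[peak_idx, "chrom"]
    on_chrom = ordered[ordered["chrom"] == chrom].reset_index(drop=True)
    local_idx = int(on_chrom.index[on_chrom["start"] == ordered.at[peak_idx, "start"]][0])
    threshold = extend_fraction * peak_count
    lo = local_idx
    while lo > 0 and on_chrom.at[lo - 1, "count"] >= threshold:
        lo -= 1
    hi = local_idx
    while hi < len(on_chrom) - 1 and on_chrom.at[hi + 1, "count"] >= threshold:
        hi += 1
    member = on_chrom.iloc[lo : hi + 1].reset_index(drop=True)
    return PeakRegion(
        found=True,
        chrom=str(chrom),
        start=int(member["start"].iloc[0]),
        end=int(member["end"].iloc[-1]),
        peak_count=peak_count,
        windows=member,
    )
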