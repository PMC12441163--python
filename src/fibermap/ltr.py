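"""LTR-retrotransposon structure annotation and presence/absence calls.

A Ty3/Gypsy-style element is bounded by two near-identical long terminal
repeats (LTRs) around an internal polyprotein region. Insertion leaves a
short target-site duplication (TSD, typically 4–6 bp) flanking the
element; intra-element recombination can leave a solo LTR behind. This
module finds the LTR pair inside an element sequence, decides whether a
locus region carries the element (PAV call), and scans an empty site for
excision signatures.

Alignment is a self-contained seed-and-extend scheme: exact k-mer seeds
(default k = 15) grouped by diagonal, then banded gapped extension with
X-drop termination (match +1, mismatch −2, gap −3, band 50) — simple and
adequate at the ~10-kb scale of a single locus, with no external aligner
dependency. Both strands are scanned; coordinates are always reported on
the forward strand of the query region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LTRAnnotation",
    "PAVCall",
    "annotate_ltr",
    "call_pav",
    "scan_remnants",
    "reverse_complement",
]

_NEG = -1.0e9
_COMP = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _normalize(seq: str, name: str = "sequence") -> str:
    seq = str(seq).upper()
    if not seq:
        raise ValueError(f"{name} is empty")
    if not set(seq) <= _VALID:
        raise ValueError(f"{name} contains characters outside A/C/G/T/N")
    return seq


# --------------------------------------------------------------------------
# seed-and-extend alignment core


def _extend(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = -2,
    gap: int = -3,
    band: int = 50,
    xdrop: int = 50,
) -> tuple[int, int, int, int, float]:
    """Banded X-drop extension aligning prefixes of ``a`` and ``b``.

    Returns ``(a_used, b_used, matches, columns, score)`` for the
    best-scoring extension endpoint. Linear gap penalties let the
    within-row insertion recursion be solved with a running max, so each
    DP row is a handful of vector operations.
    """
    an = np.frombuffer(a.encode(), dtype=np.uint8)
    bn = np.frombuffer(b.encode(), dtype=np.uint8)
    la, lb = len(an), len(bn)
    if la == 0 or lb == 0:
        return 0, 0, 0, 0, 0.0
    width = 2 * band + 1
    offs = np.arange(-band, band + 1)
    widx = np.arange(width)
    score = np.full(width, _NEG)
    matches = np.zeros(width, dtype=np.int64)
    cols = np.zeros(width, dtype=np.int64)
    init = (offs >= 0) & (offs <= lb)
    score[init] = gap * offs[init]
    cols[init] = offs[init]
    best_score, best = 0.0, (0, 0, 0, 0)
    for i in range(1, la + 1):
        j_row = i + offs  # b bases consumed at each band offset in this row
        in_b = (j_row >= 1) & (j_row <= lb)
        j_idx = np.clip(j_row - 1, 0, lb - 1)
        eq = bn[j_idx] == an[i - 1]
        sub = np.where(in_b, np.where(eq, match, mismatch), _NEG)
        diag_s = score + sub
        diag_m = matches + eq
        del_s = np.append(score[1:], _NEG) + gap  # consume a only
        del_m = np.append(matches[1:], 0)
        del_c = np.append(cols[1:], 0)
        take_diag = diag_s >= del_s
        tmp_s = np.where(take_diag, diag_s, del_s)
        tmp_m = np.where(take_diag, diag_m, del_m)
        tmp_c = np.where(take_diag, cols, del_c) + 1
        tmp_s[~((j_row >= 0) & (j_row <= lb))] = _NEG
        # within-row insertions (consume b): running max with linear gap
        t = tmp_s - gap * widx
        acc = np.maximum.accumulate(t)
        is_new = t >= np.concatenate(([_NEG - 1], acc[:-1]))
        src = np.maximum.accumulate(np.where(is_new, widx, -1))
        score = acc + gap * widx
        matches = tmp_m[src]
        cols = tmp_c[src] + (widx - src)
        invalid = ~((j_row >= 0) & (j_row <= lb))
        score[invalid] = _NEG
        row_best = float(score.max())
        if row_best > best_score:
            w = int(score.argmax())
            best_score = row_best
            best = (i, int(j_row[w]), int(matches[w]), int(cols[w]))
        if row_best < best_score - xdrop:
            break
    a_used, b_used, m, c = best
    return a_used, b_used, m, c, best_score


@dataclass
class _Alignment:
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    matches: int
    columns: int
    score: float

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


def _seeds(a: str, b: str, k: int, max_per_kmer: int = 10) -> list[tuple[int, int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(a) - k + 1):
        index.setdefault(a[i : i + k], []).append(i)
    out = []
    for j in range(len(b) - k + 1):
        hits = index.get(b[j : j + k])
        if hits and len(hits) <= max_per_kmer:
            out.extend((i, j) for i in hits)
    return out


def _diagonal_clusters(
    seeds: list[tuple[int, int]], band: int
) -> list[list[tuple[int, int]]]:
    """Group seeds whose diagonals lie within ``band`` of each other."""
    by_diag = sorted(seeds, key=lambda s: (s[1] - s[0], s[0]))
    clusters: list[list[tuple[int, int]]] = []
    last_diag = None
    for s in by_diag:
        d = s[1] - s[0]
        if last_diag is None or d - last_diag > band:
            clusters.append([])
        clusters[-1].append(s)
        last_diag = d
    clusters.sort(key=lambda c: (-len(c), c[0][1] - c[0][0]))
    return clusters


def _best_alignment(
    a: str,
    b: str,
    k: int = 15,
    band: int = 50,
    self_min_sep: int | None = None,
    n_clusters: int = 3,
    **extend_kw,
) -> _Alignment | None:
    """Best seeded local alignment of ``a`` against ``b`` (forward strand).

    With ``self_min_sep`` set, ``a`` and ``b`` are the same sequence and
    only seeds with ``j - i >= self_min_sep`` are considered (repeat
    discovery rather than the trivial self-diagonal).
    """
    seeds = _seeds(a, b, k)
    if self_min_sep is not None:
        seeds = [s for s in seeds if s[1] - s[0] >= self_min_sep]
    if not seeds:
        return None
    best: _Alignment | None = None
    for cluster in _diagonal_clusters(seeds, band)[:n_clusters]:
        i0, j0 = sorted(cluster)[len(cluster) // 2]
        fa, fb, fm, fc, fs = _extend(a[i0 + k :], b[j0 + k :], band=band, **extend_kw)
        ra, rb, rm, rc, rs = _extend(a[:i0][::-1], b[:j0][::-1], band=band, **extend_kw)
        aln = _Alignment(
            a_start=i0 - ra,
            a_end=i0 + k + fa,
            b_start=j0 - rb,
            b_end=j0 + k + fb,
            matches=rm + k + fm,
            columns=rc + k + fc,
            score=rs + k + fs,
        )
        if best is None or aln.score > best.score:
            best = aln
    return best


# --------------------------------------------------------------------------
# public operations


@dataclass
class LTRAnnotation:
    """Inferred structure of an LTR element within a query sequence.

    Coordinates are 0-based half-open on the query;
    ``ltr5 + internal + ltr3 == end - start`` by construction.
    """

    start: int
    end: int
    ltr5_length: int
    ltr3_length: int
    internal_length: int
    identity: float
    tsd: str | None = None

    @property
    def element_length(self) -> int:
        return self.end - self.start


def _flanking_tsd(seq: str, start: int, end: int, tsd_range: tuple[int, int]) -> str | None:
    lo, hi = tsd_range
    for k in range(hi, lo - 1, -1):
        if start >= k and end + k <= len(seq) and seq[start - k : start] == seq[end : end + k]:
            return seq[start - k : start]
    return None


def annotate_ltr(
    seq: str,
    min_ltr: int = 100,
    min_identity: float = 0.85,
    k: int = 15,
    band: int = 50,
    tsd_range: tuple[int, int] = (4, 6),
) -> LTRAnnotation | None:
    """Find the LTR pair of a retrotransposon in ``seq``.

    Seeds exact ``k``-mers between distant parts of the sequence, extends
    the densest diagonal cluster with banded gapped alignment, and reads
    the element structure off the aligned repeat pair: the two aligned
    spans are the 5' and 3' LTRs and the gap between them the internal
    region. Returns ``None`` when no repeat pair of at least ``min_ltr``
    bp at ``min_identity`` exists. If the element does not reach the
    sequence edges, flanking target-site duplications are looked up.
    """
    seq = _normalize(seq)
    if len(seq) < 2 * min_ltr:
        raise ValueError("sequence shorter than twice the minimum LTR length")
    aln = _best_alignment(seq, seq, k=k, band=band, self_min_sep=min_ltr)
    if aln is None:
        return None
    if aln.a_end > aln.b_start:  # overlapping copies are not an LTR pair
        return None
    ltr5 = aln.a_end - aln.a_start
    ltr3 = aln.b_end - aln.b_start
    if min(ltr5, ltr3) < min_ltr or aln.identity < min_identity:
        return None
    return LTRAnnotation(
        start=aln.a_start,
        end=aln.b_end,
        ltr5_length=ltr5,
        ltr3_length=ltr3,
        internal_length=aln.b_start - aln.a_end,
        identity=aln.identity,
        tsd=_flanking_tsd(seq, aln.a_start, aln.b_end, tsd_range),
    )


@dataclass
class PAVCall:
    """Presence/absence of an element at a locus region."""

    status: str  # "present" | "absent"
    identity: float
    coverage: float
    start: int | None  # forward-strand region coordinates of the match
    end: int | None
    strand: str | None
    remnant: str  # "none" | "solo_LTR" | "TSD" | "partial"


def _aligned_region_coords(aln: _Alignment, region_len: int, strand: str) -> tuple[int, int]:
    if strand == "+":
        return aln.b_start, aln.b_end
    return region_len - aln.b_end, region_len - aln.b_start


def call_pav(
    region: str,
    element: str,
    min_identity: float = 0.85,
    min_coverage: float = 0.8,
    partial_coverage: float = 0.15,
    k: int = 15,
    band: int = 50,
    insertion_point: int | None = None,
    tsd_range: tuple[int, int] = (4, 6),
) -> PAVCall:
    """Decide whether ``region`` carries ``element``.

    Present iff the best local alignment of the element (either strand)
    covers at least ``min_coverage`` of the element length at
    ``min_identity``. Absent calls are annotated with remnant evidence:
    a solo LTR, a target-site duplication at the (putative) insertion
    point, a partial element match, or none.
    """
    region = _normalize(region, "region")
    element = _normalize(element, "element")
    best, best_strand = None, None
    for strand, r in (("+", region), ("-", reverse_complement(region))):
        aln = _best_alignment(element, r, k=k, band=band)
        if aln is not None and (best is None or aln.score > best.score):
            best, best_strand = aln, strand
    identity = best.identity if best else 0.0
    coverage = (best.a_end - best.a_start) / len(element) if best else 0.0
    coords = (
        _aligned_region_coords(best, len(region), best_strand) if best else (None, None)
    )
    if best is not None and identity >= min_identity and coverage >= min_coverage:
        return PAVCall("present", identity, coverage, *coords, best_strand, "none")
    remnant = scan_remnants(
        region,
        element,
        tsd_range=tsd_range,
        insertion_point=insertion_point,
        min_identity=min_identity,
        k=k,
        band=band,
    )
    if remnant == "none" and coverage >= partial_coverage and identity >= min_identity:
        remnant = "partial"
    return PAVCall("absent", identity, coverage, *coords, best_strand, remnant)


def scan_remnants(
    empty_site: str,
    element: str,
    tsd_range: tuple[int, int] = (4, 6),
    insertion_point: int | None = None,
    min_identity: float = 0.85,
    min_ltr_coverage: float = 0.8,
    k: int = 15,
    band: int = 50,
) -> str:
    """Scan a locus for signatures of a past element insertion.

    Returns ``"solo_LTR"`` if either LTR of the element aligns locally to
    the site at ``min_identity`` over at least ``min_ltr_coverage`` of
    the LTR; else ``"TSD"`` if a duplicated motif whose length falls in
    ``tsd_range`` sits adjacent to the insertion point (default: the
    middle of the site); else ``"none"``. A clean removal — homologous
    recombination or structural rearrangement — leaves none of these.
    """
    site = _normalize(empty_site, "empty_site")
    element = _normalize(element, "element")
    lo, hi = tsd_range
    if not 0 < lo <= hi:
        raise ValueError("degenerate tsd_range")
    ann = annotate_ltr(element, k=k, band=band)
    ltrs = []
    if ann is not None:
        ltrs = [
            element[ann.start : ann.start + ann.ltr5_length],
            element[ann.end - ann.ltr3_length : ann.end],
        ]
    for ltr in ltrs:
        for target in (site, reverse_complement(site)):
            aln = _best_alignment(ltr, target, k=k, band=band)
            if aln is None:
                continue
            cov = (aln.a_end - aln.a_start) / len(ltr)
            if aln.identity >= min_identity and cov >= min_ltr_coverage:
                return "solo_LTR"
    ip = insertion_point if insertion_point is not None else len(site) // 2
    for kk in range(hi, lo - 1, -1):
        if kk <= ip <= len(site) - kk and site[ip - kk : ip] == site[ip : ip + kk]:
            return "TSD"
    return "none"
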