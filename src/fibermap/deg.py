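"""Gene-level differential expression between lines.

A transparent, fully specified stack: counts-per-million normalization,
pseudocounted fold changes, per-gene one-way ANOVA on log2 CPM (with two
lines this equals the pooled two-sample t-test), and Benjamini–Hochberg
FDR across genes. A gene is declared differentially expressed when its
q-value clears the FDR threshold **and** its fold change clears the fold
threshold (default FDR < 0.05, two-fold).

With two replicates per line a purely gene-wise test has only two error
degrees of freedom, so no effect — however large — can reach the BH
threshold across thousands of genes. By default the per-gene variance is
therefore moderated with an empirical-Bayes scaled-inverse-chi-square
prior fitted across all genes (moderated t/F in the limma tradition),
which borrows strength across genes and restores power at small n; pass
``moderation=False`` for the plain per-gene ANOVA.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = ["normalize", "fold_change", "test_deg", "summarize_pathway"]


def _sample_lines(design: pd.DataFrame) -> pd.Series:
    if not {"sample", "line"} <= set(design.columns):
        raise ValueError("design needs 'sample' and 'line' columns")
    return design.set_index("sample")["line"]


def normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million per sample (library size = column sum).

    Equal library sizes preserve count ratios exactly; any log transform
    downstream adds a pseudocount first (see :func:`test_deg`).
    """
    arr = counts.to_numpy(dtype=float)
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    libsize = arr.sum(axis=0)
    if np.any(libsize <= 0):
        raise ValueError("zero library size")
    return counts / libsize * 1.0e6


def fold_change(
    normalized: pd.DataFrame,
    design: pd.DataFrame,
    line_a: str,
    line_b: str,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene ratio of pseudocounted mean normalized expression, a over b."""
    lines = _sample_lines(design)
    for line in (line_a, line_b):
        if line not in set(lines):
            raise ValueError(f"line {line!r} absent from design")
    cols_a = [s for s in normalized.columns if lines.get(s) == line_a]
    cols_b = [s for s in normalized.columns if lines.get(s) == line_b]
    mean_a = normalized[cols_a].mean(axis=1) + pseudocount
    mean_b = normalized[cols_b].mean(axis=1) + pseudocount
    out = mean_a / mean_b
    out.name = "fold_change"
    return out


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone decreasing)."""
    if x > 1.0e7:
        return 1.0 / np.sqrt(x)
    if x < 1.0e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        step = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += step
        if abs(step) < 1.0e-8 * y:
            break
    return y


def _fit_variance_prior(
    s2: np.ndarray, df: int, abundance: np.ndarray
) -> tuple[float, np.ndarray]:
    """Moment-match a scaled-inverse-chi-square prior to gene variances.

    The prior scale follows the mean–variance trend: the expected log
    variance is smoothed (lowess) against mean log2 expression, so
    low-count genes — whose log-CPM variance is intrinsically larger —
    shrink toward an appropriately larger prior instead of a global one.
    The prior degrees of freedom ``d0`` come from the residual spread of
    log s² around the trend versus its theoretical chi-square spread;
    ``d0 = inf`` when gene variances are consistent with the trend alone.
    Genes with s² = 0 (tied replicate values) are excluded from the fit
    but still shrink toward the trend when moderating.

    Returns ``(d0, s0²)`` with s0² per gene, aligned to the input.
    """
    ok = s2 > 0
    tiny = float(np.finfo(float).tiny)
    if ok.sum() < 30:  # too few genes for a trend: global prior
        if ok.sum() < 2:
            return np.inf, np.full_like(s2, max(s2.mean(), tiny))
        e = np.log(s2[ok]) - special.digamma(df / 2.0) + np.log(df / 2.0)
        trend_at = np.full(len(s2), e.mean())
        evar = e.var(ddof=1) - float(special.polygamma(1, df / 2.0))
    else:
        from statsmodels.nonparametric.smoothers_lowess import lowess

        e = np.log(s2[ok]) - special.digamma(df / 2.0) + np.log(df / 2.0)
        a_ok = abundance[ok]
        fitted = lowess(e, a_ok, frac=0.4, it=2, return_sorted=True)
        trend_at = np.interp(abundance, fitted[:, 0], fitted[:, 1])
        evar = float(np.var(e - trend_at[ok], ddof=1)) - float(
            special.polygamma(1, df / 2.0)
        )
    if evar <= 0:
        return np.inf, np.exp(trend_at)
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_2 = np.exp(trend_at + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return d0, s0_2


def test_deg(
    normalized: pd.DataFrame,
    design: pd.DataFrame,
    alpha: float = 0.05,
    fold_threshold: float = 2.0,
    pseudocount: float = 1.0,
    moderation: bool = True,
) -> pd.DataFrame:
    """Per-gene one-way ANOVA across lines with BH FDR control.

    Works on log2(CPM + pseudocount). With ``moderation=True`` (default)
    the per-gene error variance is shrunk toward an empirical-Bayes prior
    fitted across all genes and the F test gains the prior degrees of
    freedom — necessary for any power at two replicates per line. With
    ``moderation=False`` this is the plain gene-wise one-way ANOVA
    (identical to :func:`scipy.stats.f_oneway`, and to the pooled t-test
    for two lines).

    Genes constant across all samples cannot be tested; they are
    reported with ``tested = False``, p = NaN, q = 1 and are never
    flagged significant. Returns a DataFrame indexed by gene:
    ``fold_change`` (first line over second, when exactly two lines),
    ``p_value``, ``q_value``, ``significant``, ``tested``.
    """
    lines = _sample_lines(design)
    labels = [lines.get(s) for s in normalized.columns]
    if any(l is None for l in labels):
        raise ValueError("every sample column needs a design row")
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need >= 2 lines")
    counts_per_line = pd.Series(labels).value_counts()
    if counts_per_line.min() < 2:
        raise ValueError("need >= 2 replicates per line")
    log_expr = np.log2(normalized.to_numpy(dtype=float) + pseudocount)
    n_samples = log_expr.shape[1]
    k = len(uniq)
    grand = log_expr.mean(axis=1)
    ss_between = np.zeros(len(normalized))
    ss_within = np.zeros(len(normalized))
    for u in uniq:
        block = log_expr[:, labels == u]
        mean_u = block.mean(axis=1)
        ss_between += block.shape[1] * (mean_u - grand) ** 2
        ss_within += ((block - mean_u[:, None]) ** 2).sum(axis=1)
    df_between = k - 1
    df_within = n_samples - k
    variable = (ss_between + ss_within) > 0
    s2 = ss_within / df_within
    ms_between = ss_between / df_between
    p = np.full(len(normalized), np.nan)
    if moderation:
        abundance = grand
        d0, s0_2 = _fit_variance_prior(s2[variable], df_within, abundance[variable])
        s0_full = np.empty_like(s2)
        s0_full[variable] = s0_2
        s0_full[~variable] = np.nan
        if np.isinf(d0):
            s2_tilde = s0_full
            df_total = 1.0e6  # effectively the chi-square limit
        else:
            s2_tilde = (d0 * s0_full + df_within * s2) / (d0 + df_within)
            df_total = d0 + df_within
        with np.errstate(divide="ignore", invalid="ignore"):
            f_stat = ms_between / s2_tilde
        p[variable] = stats.f.sf(f_stat[variable], df_between, df_total)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            f_stat = ms_between / s2
        p[variable] = stats.f.sf(f_stat[variable], df_between, df_within)
    tested = variable & np.isfinite(p)
    q = np.ones(len(normalized))
    if tested.any():
        q[tested] = multipletests(p[tested], method="fdr_bh")[1]
    if len(uniq) == 2:
        fc = fold_change(normalized, design, uniq[0], uniq[1], pseudocount=pseudocount)
    else:  # max pairwise ratio of line means, for the flag only
        means = pd.DataFrame(
            {u: normalized.loc[:, labels == u].mean(axis=1) + pseudocount for u in uniq}
        )
        fc = means.max(axis=1) / means.min(axis=1)
        fc.name = "fold_change"
    significant = (
        tested
        & (q < alpha)
        & (np.abs(np.log2(fc.to_numpy())) >= np.log2(fold_threshold))
    )
    return pd.DataFrame(
        {
            "fold_change": fc,
            "p_value": p,
            "q_value": q,
            "significant": significant,
            "tested": tested,
        },
        index=normalized.index,
    )


def summarize_pathway(
    results: pd.DataFrame, pathways: Mapping[str, str]
) -> pd.DataFrame:
    """Per-pathway counts of significant up/down genes and median fold.

    ``pathways`` maps gene id -> pathway name for the annotated subset of
    genes (e.g. shikimate / phenylpropanoid / flavonoid cohorts). Genes
    absent from the map are ignored. Returns a DataFrame with columns
    ``pathway, n_up, n_down, median_fold_change``.
    """
    rows = []
    mapped = pd.Series(dict(pathways), dtype=object)
    for pathway in sorted(set(mapped.values)):
        genes = [g for g in mapped.index[mapped == pathway] if g in results.index]
        if not genes:
            rows.append((pathway, 0, 0, np.nan))
            continue
        sub = results.loc[genes]
        sig = sub[sub["significant"]]
        rows.append(
            (
                pathway,
                int((sig["fold_change"] > 1).sum()),
                int((sig["fold_change"] < 1).sum()),
                float(sub["fold_change"].median()),
            )
        )
    return pd.DataFrame(rows, columns=["pathway", "n_up", "n_down", "median_fold_change"])
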