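"""Dosage-compensation statistics: per-copy expression summaries,
distribution comparisons, RNAi/mock fixed-fold estimation, expression-level
trends and variance tests.

Ratios are summarised by medians on the natural scale (matching the
headline RNAi/mock value of ~0.74), while the variance comparison between X
and autosomal ratios is performed on log ratios so up- and down-changes are
treated symmetrically.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

COPY_MIN, COPY_MAX = 1, 5


def _chrom_class(df: pd.DataFrame) -> pd.Series:
    if "is_x" in df.columns:
        isx = df["is_x"].astype(bool)
    else:
        isx = df["arm"].astype(str).str.upper().str.startswith("X")
    return np.where(isx, "X", "autosome")


def summarize_by_copy(expr: pd.DataFrame, copies: pd.DataFrame,
                      copy_min: int = COPY_MIN,
                      copy_max: int = COPY_MAX) -> pd.DataFrame:
    """Median expression (and per-copy expression) per chromosome class and
    copy number, over expressed, copy-annotated genes.

    Returns columns: class, copy, n_genes, median_rpkm, q25, q75,
    median_per_copy.
    """
    merged = expr.merge(copies[["gene_id", "copy", "excluded"]], on="gene_id")
    merged = merged[~merged["excluded"].astype(bool)]
    merged = merged[merged["copy"].notna()]
    merged = merged[(merged["copy"] >= copy_min) & (merged["copy"] <= copy_max)]
    if "expressed" in merged.columns:
        merged = merged[merged["expressed"]]
    merged = merged.assign(chrom_class=_chrom_class(merged))
    rows = []
    for (cls, copy), grp in merged.groupby(["chrom_class", "copy"], sort=True):
        if grp.empty:
            continue
        r = grp["mean_rpkm"].to_numpy(dtype=float)
        rows.append((cls, int(copy), len(r), float(np.median(r)),
                     float(np.quantile(r, 0.25)), float(np.quantile(r, 0.75)),
                     float(np.median(r / int(copy)))))
    out = pd.DataFrame(rows, columns=["class", "copy", "n_genes",
                                      "median_rpkm", "q25", "q75",
                                      "median_per_copy"])
    for cls in ("X", "autosome"):
        present = set(out.loc[out["class"] == cls, "copy"])
        missing = set(range(copy_min, copy_max + 1)) - present
        if missing:
            logger.info("summarize_by_copy: no %s genes at copies %s",
                        cls, sorted(missing))
    return out


def ks_compare(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test (asymptotic p-value).

    D is the maximum absolute difference between the two empirical CDFs.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if min(a.size, b.size) < 5:
        warnings.warn("sample size < 5: asymptotic KS p-value unreliable",
                      stacklevel=2)
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def variance_ratio_test(x_ratios, a_ratios,
                        log: bool = True) -> tuple[float, float]:
    """F test comparing ratio variances between two gene sets.

    F = var(first) / var(second), computed on log ratios by default; the
    p-value is two-sided from the F distribution.
    """
    x = np.asarray(x_ratios, dtype=float)
    a = np.asarray(a_ratios, dtype=float)
    if x.size < 2 or a.size < 2:
        raise ValueError("need at least 2 ratios per group")
    if log:
        x, a = np.log(x), np.log(a)
    vx, va = x.var(ddof=1), a.var(ddof=1)
    if vx == 0 or va == 0:
        raise ValueError("zero variance in one of the samples")
    f = vx / va
    dfx, dfa = x.size - 1, a.size - 1
    cdf = stats.f.cdf(f, dfx, dfa)
    p = 2.0 * min(cdf, 1.0 - cdf)
    return float(f), float(min(p, 1.0))


@dataclass
class ConditionComparison:
    """RNAi-vs-mock ratio analysis for one knockdown condition."""

    per_gene: pd.DataFrame = field(repr=False)
    median_ratio: dict
    per_copy: pd.DataFrame
    msl_fold: float
    f_stat: float
    f_pvalue: float
    ks_tests: pd.DataFrame | None = None


def rnai_effect(expr_rnai: pd.DataFrame, expr_mock: pd.DataFrame,
                copies: pd.DataFrame | None = None,
                ratio_stat: str = "median") -> ConditionComparison:
    """Per-gene RNAi/mock expression ratios and the MSL fixed-fold estimate.

    Only genes expressed in mock enter (non-expressed genes are useless for
    ratiometric analysis). The MSL fold is the reciprocal of the summary
    X-ratio; per-copy medians allow the fixed-fold (dose-independence) test,
    with pairwise KS comparisons of X ratio distributions across copies
    (raw p plus Benjamini–Hochberg columns; conclusions use raw p).
    """
    mock = expr_mock[["gene_id", "arm", "mean_rpkm"]].rename(
        columns={"mean_rpkm": "mock_rpkm"})
    if "is_x" in expr_mock.columns:
        mock["is_x"] = expr_mock["is_x"].to_numpy()
    if "expressed" in expr_mock.columns:
        mock = mock[expr_mock["expressed"].to_numpy()]
    rnai = expr_rnai[["gene_id", "mean_rpkm"]].rename(
        columns={"mean_rpkm": "rnai_rpkm"})
    per_gene = mock.merge(rnai, on="gene_id")
    if (per_gene["mock_rpkm"] <= 0).any():
        raise ValueError("mock RPKM must be positive for included genes")
    per_gene["ratio"] = per_gene["rnai_rpkm"] / per_gene["mock_rpkm"]
    per_gene["chrom_class"] = _chrom_class(per_gene)
    if copies is not None:
        per_gene = per_gene.merge(copies[["gene_id", "copy", "excluded"]],
                                  on="gene_id", how="left")

    stat = np.median if ratio_stat == "median" else np.mean
    median_ratio = {cls: float(stat(g["ratio"]))
                    for cls, g in per_gene.groupby("chrom_class")}

    per_copy_rows = []
    if "copy" in per_gene.columns:
        annotated = per_gene[~per_gene["excluded"].fillna(True).astype(bool)]
        annotated = annotated[(annotated["copy"] >= COPY_MIN)
                              & (annotated["copy"] <= COPY_MAX)]
        for (cls, copy), grp in annotated.groupby(["chrom_class", "copy"]):
            per_copy_rows.append((cls, int(copy), len(grp),
                                  float(stat(grp["ratio"]))))
    per_copy = pd.DataFrame(per_copy_rows,
                            columns=["class", "copy", "n_genes",
                                     "median_ratio"])

    x_ratios = per_gene.loc[per_gene["chrom_class"] == "X", "ratio"]
    a_ratios = per_gene.loc[per_gene["chrom_class"] == "autosome", "ratio"]
    msl_fold = 1.0 / median_ratio["X"] if "X" in median_ratio else np.nan
    try:
        f_stat, f_p = variance_ratio_test(x_ratios, a_ratios)
    except ValueError:  # degenerate (noise-free or tiny) ratio sets
        f_stat, f_p = np.nan, np.nan

    ks_rows = []
    if "copy" in per_gene.columns and len(per_copy):
        x_by_copy = {c: g["ratio"].to_numpy() for (cls, c), g in
                     annotated.groupby(["chrom_class", "copy"]) if cls == "X"}
        for c1, c2 in itertools.combinations(sorted(x_by_copy), 2):
            if min(x_by_copy[c1].size, x_by_copy[c2].size) >= 5:
                d, p = ks_compare(x_by_copy[c1], x_by_copy[c2])
                ks_rows.append((c1, c2, d, p))
    ks_tests = pd.DataFrame(ks_rows, columns=["copy_a", "copy_b", "D", "p"])
    if len(ks_tests):
        ks_tests["p_bh"] = multipletests(ks_tests["p"], method="fdr_bh")[1]

    return ConditionComparison(per_gene=per_gene, median_ratio=median_ratio,
                               per_copy=per_copy, msl_fold=float(msl_fold),
                               f_stat=f_stat, f_pvalue=f_p, ks_tests=ks_tests)


def moving_average_trend(ratios, order_by, window: int = 20) -> pd.DataFrame:
    """Sliding-mean ratio trend across expression levels.

    Genes are ordered by ``order_by`` (mock expression); the trend is the
    arithmetic mean of ratios over consecutive windows of ``window`` genes
    (step 1), paired with the median ``order_by`` value of each window.
    """
    r = np.asarray(ratios, dtype=float)
    e = np.asarray(order_by, dtype=float)
    if r.size != e.size:
        raise ValueError("ratios and ordering values must align")
    if r.size < window:
        raise ValueError(f"need at least {window} genes, got {r.size}")
    order = np.argsort(e, kind="stable")
    r, e = r[order], e[order]
    kernel = np.ones(window) / window
    means = np.convolve(r, kernel, mode="valid")
    med = pd.Series(e).rolling(window).median().to_numpy()[window - 1:]
    return pd.DataFrame({"median_expression": med, "mean_ratio": means})
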