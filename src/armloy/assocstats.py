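"""Downstream association statistics for LOY/aneuploidy cohorts.

Covers the standard post-calling analyses: differential expression
between carrier and non-carrier tumors (equal-variance t-test on log2
RPKM with Benjamini-Hochberg correction), per-gene regression of
expression on the affected-cell fraction, logistic regression of mosaic
LOY on age, Fisher's exact co-occurrence test for 2x2 tables, and the
any-aberration union summary per sex group.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_FDR = 0.01
DEFAULT_PSEUDOCOUNT = 1.0

_META_COLS = ("chromosome",)


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    p: float
    r: float


@dataclass
class LogisticFit:
    beta_age: float
    p: float
    odds_ratio: float
    separated: bool = False


def _expr_values(expr: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    samples = [c for c in expr.columns if c not in _META_COLS]
    chrom = expr["chromosome"] if "chromosome" in expr.columns else pd.Series("", index=expr.index)
    return expr[samples], chrom


def de_by_loy(
    expr: pd.DataFrame,
    loy_flags: pd.Series,
    scale: str = "rpkm",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    equal_var: bool = True,
    fdr: float = DEFAULT_FDR,
    min_mean_rpkm: float | None = None,
) -> pd.DataFrame:
    """Per-gene two-sample t-test of carrier vs non-carrier samples.

    ``expr`` has gene rows (optionally a ``chromosome`` column) and
    sample columns; ``loy_flags`` is a boolean Series indexed by the
    sample ids to test.  RPKM input is transformed as
    log2(RPKM + pseudocount); pass ``scale='log2'`` for data already on
    the log scale (e.g. array intensities).  The t-test is Student's
    (pooled variance) by default; ``equal_var=False`` switches to Welch.
    Genes with zero variance in both groups get p = 1.  BH correction
    runs over all tested genes; ``min_mean_rpkm`` optionally restricts
    the universe to genes with mean RPKM above the cutoff.

    Returns one row per tested gene: group means (log2), t, df, p,
    BH-adjusted ``fdr`` and ``significant`` (fdr < cutoff).
    """
    values, chrom = _expr_values(expr)
    flags = loy_flags.astype(bool)
    test_ids = [s for s in values.columns if s in flags.index]
    flags = flags.loc[test_ids]
    g1 = [s for s in test_ids if flags[s]]
    g0 = [s for s in test_ids if not flags[s]]
    if len(g1) < 2 or len(g0) < 2:
        raise ValueError(
            f"need at least two samples per group (got {len(g1)} carriers, {len(g0)} others)"
        )

    mat = values[test_ids].to_numpy(dtype=float)
    if scale == "rpkm":
        if np.any(mat < 0):
            raise ValueError("negative RPKM values")
        keep = np.ones(len(mat), dtype=bool)
        if min_mean_rpkm is not None:
            keep = mat.mean(axis=1) > min_mean_rpkm
        log2 = np.log2(mat + pseudocount)
    elif scale == "log2":
        keep = np.ones(len(mat), dtype=bool)
        log2 = mat
    else:
        raise ValueError(f"scale must be 'rpkm' or 'log2', got {scale!r}")

    idx1 = [test_ids.index(s) for s in g1]
    idx0 = [test_ids.index(s) for s in g0]
    a, b = log2[keep][:, idx1], log2[keep][:, idx0]
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    # zero variance in both groups: identical -> p = 1; distinct means with
    # no spread -> treat as overwhelming evidence only if means differ
    degenerate = np.isnan(p)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    if equal_var:
        df = np.full(len(a), a.shape[1] + b.shape[1] - 2, dtype=float)
    else:  # Welch-Satterthwaite
        va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
        na, nb = a.shape[1], b.shape[1]
        num = (va / na + vb / nb) ** 2
        den = (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            df = np.where(den > 0, num / den, na + nb - 2)

    rej, q, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    out = pd.DataFrame(
        {
            "gene_id": np.asarray(values.index)[keep],
            "chromosome": chrom.to_numpy()[keep],
            "mean_log2_loy": a.mean(axis=1),
            "mean_log2_other": b.mean(axis=1),
            "t": t,
            "df": df,
            "p": p,
            "fdr": q,
            "significant": q < fdr,
        }
    )
    return out


def expr_fraction_regression(expr_gene, fractions) -> RegressionFit:
    """OLS of one gene's expression on the affected-cell fraction.

    Two-sided p for the slope; raises on a degenerate design (all
    fractions equal)."""
    y = np.asarray(expr_gene, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if y.shape != f.shape or y.ndim != 1:
        raise ValueError("expression and fractions must be 1-D and aligned")
    if len(y) < 3:
        raise ValueError("need at least three samples")
    if np.any((f < 0) | (f > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    if np.ptp(f) == 0:
        raise ValueError("all fractions identical; regression design is degenerate")
    res = stats.linregress(f, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        p=float(res.pvalue),
        r=float(res.rvalue),
    )


def loy_age_logistic(loy_flags, ages) -> LogisticFit:
    """Maximum-likelihood logistic regression of an LOY flag on age.

    Returns the per-year log-odds coefficient, its two-sided Wald p and
    the per-year odds ratio.  Complete separation is reported via
    ``separated=True`` (estimates are then not meaningful) rather than
    raised."""
    y = np.asarray(loy_flags, dtype=float)
    x = np.asarray(ages, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("need both carrier and non-carrier samples")
    X = sm.add_constant(x)
    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception:  # PerfectSeparationError or non-convergence blowup
            return LogisticFit(beta_age=np.nan, p=np.nan, odds_ratio=np.nan, separated=True)
    beta = float(res.params[1])
    p = float(res.pvalues[1])
    if not res.mle_retvals.get("converged", True) or abs(beta) > 50 or not np.isfinite(p):
        separated = True
    return LogisticFit(
        beta_age=beta, p=p, odds_ratio=float(np.exp(beta)), separated=separated
    )


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table (probability-mass rule:
    sum over tables with the same margins whose hypergeometric
    probability does not exceed the observed one).

    A table with a zero row or column margin has only one achievable
    configuration; p = 1 by convention."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.all(np.equal(np.mod(t, 1), 0)):
        raise ValueError("table entries must be non-negative integers")
    t = t.astype(np.int64)
    if t.sum() == 0:
        raise ValueError("empty table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def aberration_union(samples: pd.DataFrame, flag_cols, sex_col: str = "sex") -> pd.DataFrame:
    """Per sex group: how many samples carry *any* of the given boolean
    aberration flags, with the percentage rounded to the nearest integer.
    """
    from .genome import SEXES

    unknown = set(samples[sex_col].unique()) - set(SEXES)
    if unknown:
        raise ValueError(f"unknown sex labels: {sorted(unknown)}")
    missing = [c for c in flag_cols if c not in samples.columns]
    if missing:
        raise ValueError(f"missing flag columns: {missing}")
    any_flag = samples[list(flag_cols)].astype(bool).any(axis=1)
    rows = []
    for sex, grp in samples.groupby(sex_col):
        n = len(grp)
        affected = int(any_flag.loc[grp.index].sum())
        rows.append(
            dict(
                sex=sex,
                n=n,
                n_affected=affected,
                percent=int(round(100.0 * affected / n)) if n else 0,
            )
        )
    return pd.DataFrame(rows)
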