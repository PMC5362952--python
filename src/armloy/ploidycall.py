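"""Arm-level aneuploidy calling against a two-Gaussian mixture null.

For each arm unit the per-sample arm medians form an empirical
distribution across the cohort: a tight mode at the expected dosage plus,
when an aberration recurs, a second displaced (usually broader) mode from
the affected samples.  A two-component univariate Gaussian mixture is
fitted by EM and the *main* component — the one with the larger weight —
is taken as the null.  Each sample's arm median is then scored with a
two-sided normal tail under that null, Bonferroni-adjusted, and flagged
when significant (adjusted p < alpha) *and* the implied fraction of
affected cells passes a minimum.

The affected-cell fraction follows from linear dosage mixing.  With a
fraction f of cells carrying the event, the expected normalized coverage
is baseline * (1 -/+ per-cell dosage change * f), so:

* single-copy unit (baseline 0.5, male X or Y): loss  f = (0.5 - cov)/0.5,
  gain f = (cov - 0.5)/0.5;
* two-copy unit (baseline 1.0), one copy changed:  loss f = (1 - cov)/0.5,
  gain f = (cov - 1)/0.5.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

from .genome import GenomeModel

DEFAULT_ALPHA = 0.01
DEFAULT_MIN_FRACTION = 0.10
SIGMA_FLOOR = 1e-4
REL_SIGMA_FLOOR = 0.05  # fraction of the overall sd; guards quantization atoms
WEIGHT_MARGIN = 0.15  # near-tied weights defer to baseline proximity
EM_TOL = 1e-8
EM_MAX_ITER = 500
MIN_FIT_N = 8

LOSS = "loss"
GAIN = "gain"


@dataclass
class MixtureNull:
    """Fitted (one- or two-component) Gaussian mixture with a designated
    null component."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    null_index: int
    n_samples: int
    converged: bool = True

    @property
    def n_components(self) -> int:
        return len(self.means)

    @property
    def null_mean(self) -> float:
        return float(self.means[self.null_index])

    @property
    def null_sd(self) -> float:
        return float(self.sds[self.null_index])


def _two_means(v: np.ndarray) -> np.ndarray:
    """Deterministic 2-means hard assignment (init at the quartiles)."""
    centers = np.percentile(v, [25.0, 75.0])
    if centers[0] == centers[1]:
        centers = np.array([v.min(), v.max()], dtype=float)
    assign = np.zeros(len(v), dtype=int)
    for _ in range(100):
        assign = np.abs(v[:, None] - centers[None, :]).argmin(axis=1)
        new = centers.copy()
        for j in (0, 1):
            if np.any(assign == j):
                new[j] = v[assign == j].mean()
        if np.allclose(new, centers):
            break
        centers = new
    return assign


def _single_null(v: np.ndarray, sigma_floor: float) -> MixtureNull:
    sd = max(float(np.std(v)), sigma_floor)
    return MixtureNull(
        means=np.array([float(np.mean(v))]),
        sds=np.array([sd]),
        weights=np.array([1.0]),
        null_index=0,
        n_samples=len(v),
    )


def fit_mixture_null(
    values,
    baseline: float | None = None,
    sigma_floor: float = SIGMA_FLOOR,
    rel_sigma_floor: float = REL_SIGMA_FLOOR,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> MixtureNull:
    """Fit a two-component Gaussian mixture by EM; the heavier component
    is the null.

    Initialization is a deterministic 2-means split; convergence when the
    total log-likelihood moves by less than ``tol`` (or ``max_iter``).
    Component standard deviations are floored at
    max(``sigma_floor``, ``rel_sigma_floor`` * sd of the input): read
    counts quantize arm medians, and without a resolution-scale floor a
    component collapses onto an exact-tie atom and sheds its near members.  When the two-component
    model does not improve BIC over a single Gaussian the single Gaussian
    is kept — on unimodal data an unconstrained two-component fit splits
    the sample and understates the null spread.  Fewer than 8 usable
    values, or values with no spread, fall back to a single-Gaussian null
    with a warning.

    The null is the component with the larger weight.  When the weights
    are nearly tied (within ``WEIGHT_MARGIN``) and a ``baseline`` is
    given, the component whose mean is nearer the expected baseline is
    the null instead: with an aberration in close to half the cohort the
    weight ordering is decided by noise, while the unaffected mode is
    always the one at the expected dosage.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no finite values to fit")
    if np.ptp(v) == 0:
        warnings.warn("all values identical; degenerate single-Gaussian null")
        return _single_null(v, sigma_floor)
    sigma_floor = max(sigma_floor, rel_sigma_floor * float(np.std(v)))
    if v.size < MIN_FIT_N:
        warnings.warn(
            f"only {v.size} values (< {MIN_FIT_N}); falling back to single-Gaussian null"
        )
        return _single_null(v, sigma_floor)

    assign = _two_means(v)
    if len(np.unique(assign)) < 2:  # 2-means failed to split
        return _single_null(v, sigma_floor)
    resp = np.zeros((len(v), 2))
    resp[np.arange(len(v)), assign] = 1.0

    prev_ll = -np.inf
    ll = -np.inf
    converged = False
    w = mu = sd = None
    for _ in range(max_iter):
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-10):
            break
        w = nk / len(v)
        mu = (resp * v[:, None]).sum(axis=0) / nk
        var = (resp * (v[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.maximum(np.sqrt(var), sigma_floor)
        log_comp = np.log(w)[None, :] + norm.logpdf(v[:, None], mu[None, :], sd[None, :])
        log_norm = logsumexp(log_comp, axis=1)
        resp = np.exp(log_comp - log_norm[:, None])
        ll = float(log_norm.sum())
        if abs(ll - prev_ll) < tol:
            converged = True
            break
        prev_ll = ll

    if w is None or mu is None or sd is None:
        return _single_null(v, sigma_floor)

    # model selection: keep the extra component only if it pays its way
    single = _single_null(v, sigma_floor)
    ll_single = float(norm.logpdf(v, single.null_mean, single.null_sd).sum())
    n = len(v)
    bic_two = -2.0 * ll + 5.0 * np.log(n)
    bic_single = -2.0 * ll_single + 2.0 * np.log(n)
    if bic_single <= bic_two:
        return single

    if abs(w[0] - w[1]) < WEIGHT_MARGIN and baseline is not None:
        null_index = int(np.argmin(np.abs(mu - baseline)))
    else:
        null_index = int(np.argmax(w))
    return MixtureNull(
        means=mu, sds=sd, weights=w, null_index=null_index,
        n_samples=len(v), converged=converged,
    )


def pvalue(value, null: MixtureNull):
    """Two-sided normal tail probability under the null component."""
    z = np.abs(np.asarray(value, dtype=float) - null.null_mean) / null.null_sd
    p = np.clip(2.0 * norm.sf(z), 0.0, 1.0)
    return float(p) if p.ndim == 0 else p


def estimate_fraction(coverage: float, baseline: float, direction: str) -> float:
    """Affected-cell fraction implied by the observed normalized coverage.

    One copy is assumed changed per affected cell, so the coverage deficit
    or excess per unit fraction is 0.5 on both one- and two-copy units.
    The estimate is clipped to [0, 1].
    """
    if coverage < 0:
        raise ValueError(f"negative coverage: {coverage}")
    if direction not in (LOSS, GAIN):
        raise ValueError(f"direction must be '{LOSS}' or '{GAIN}', got {direction!r}")
    if baseline not in (0.5, 1.0):
        raise ValueError(f"baseline must be 0.5 or 1.0, got {baseline}")
    delta = coverage - baseline
    f = -delta / 0.5 if direction == LOSS else delta / 0.5
    return float(np.clip(f, 0.0, 1.0))


def call_cohort(
    arm_coverage: pd.DataFrame,
    samples: pd.DataFrame,
    genome: GenomeModel,
    alpha: float = DEFAULT_ALPHA,
    f_min: float = DEFAULT_MIN_FRACTION,
    pool_tissues: bool = True,
    bonferroni_m: int | None = None,
    strict_fraction: bool = False,
    sigma_floor: float = SIGMA_FLOOR,
) -> pd.DataFrame:
    """Emit per sample x arm aneuploidy calls for a cohort.

    ``arm_coverage`` is the sample x arm median matrix from
    :func:`armloy.covnorm.arm_medians`; ``samples`` the sample sheet.

    Mixture nulls are fitted per arm unit on the arm medians across
    samples — by default pooling tumors and normals of the cohort, so that
    a near-ubiquitous tumor aberration (e.g. 3p loss) cannot hijack the
    main component; set ``pool_tissues=False`` to fit each tissue class
    separately.  Sex-chromosome units are always fitted per sex, since
    their baselines differ between karyotypes.

    The Bonferroni factor defaults to (number of arm units tested for the
    sample's sex) x (number of samples in the sample's tissue class);
    override with ``bonferroni_m``.  A sample is flagged when the adjusted
    p-value is below ``alpha`` and the estimated fraction reaches
    ``f_min`` (>= by default; strictly > with ``strict_fraction``).
    """
    sheet = samples.set_index("sample_id") if "sample_id" in samples.columns else samples
    sheet = sheet.loc[arm_coverage.index]
    n_by_tissue = sheet["tissue"].value_counts().to_dict()
    n_arms_by_sex = {
        sex: len([a for a in arm_coverage.columns if np.isfinite(genome.baseline(a, sex))])
        for sex in sheet["sex"].unique()
    }

    records: list[dict] = []
    for arm in arm_coverage.columns:
        chrom = genome.chrom_of_arm(arm)
        if chrom in ("chrX", "chrY"):
            groups = [
                sheet.index[sheet["sex"] == sex].tolist()
                for sex in sheet["sex"].unique()
            ]
        else:
            groups = [sheet.index.tolist()]
        for group in groups:
            ids = [
                s for s in group
                if np.isfinite(arm_coverage.loc[s, arm])
                and np.isfinite(genome.baseline(arm, sheet.loc[s, "sex"]))
            ]
            if not ids:
                continue
            baseline = genome.baseline(arm, sheet.loc[ids[0], "sex"])
            if pool_tissues:
                fit_groups = {None: ids}
            else:
                fit_groups = {
                    t: [s for s in ids if sheet.loc[s, "tissue"] == t]
                    for t in sheet.loc[ids, "tissue"].unique()
                }
            for _, fit_ids in fit_groups.items():
                if not fit_ids:
                    continue
                values = arm_coverage.loc[fit_ids, arm].to_numpy()
                if len(values) < MIN_FIT_N:
                    warnings.warn(
                        f"arm {arm}: only {len(values)} samples in fitting group; "
                        "single-Gaussian fallback"
                    )
                null = fit_mixture_null(values, baseline=baseline, sigma_floor=sigma_floor)
                for sid in fit_ids:
                    cov = float(arm_coverage.loc[sid, arm])
                    tissue = sheet.loc[sid, "tissue"]
                    sex = sheet.loc[sid, "sex"]
                    direction = LOSS if cov < null.null_mean else GAIN
                    f = estimate_fraction(cov, baseline, direction)
                    p = pvalue(cov, null)
                    m = bonferroni_m or (n_arms_by_sex[sex] * n_by_tissue[tissue])
                    p_adj = min(1.0, m * p)
                    passes_f = f > f_min if strict_fraction else f >= f_min
                    records.append(
                        dict(
                            sample_id=sid, arm=arm, tissue=tissue, sex=sex,
                            coverage=cov, baseline=baseline, direction=direction,
                            p=p, p_adj=p_adj, fraction=f,
                            flagged=bool(p_adj < alpha and passes_f),
                        )
                    )
    calls = pd.DataFrame.from_records(records)
    return calls.sort_values(["sample_id", "arm"], kind="mergesort").reset_index(drop=True)


def frequency_table(calls: pd.DataFrame, tissue: str = "tumor") -> pd.DataFrame:
    """Cohort frequency of flagged aberrations per arm x sex x direction
    among samples of one tissue class (the per-cohort summary view)."""
    sub = calls[calls["tissue"] == tissue]
    denom = sub.groupby(["arm", "sex"])["sample_id"].nunique()
    flagged = (
        sub[sub["flagged"]]
        .groupby(["arm", "sex", "direction"])["sample_id"]
        .nunique()
        .rename("n_flagged")
        .reset_index()
    )
    flagged["n_samples"] = [
        denom.loc[(a, s)] for a, s in zip(flagged["arm"], flagged["sex"])
    ]
    flagged["percent"] = 100.0 * flagged["n_flagged"] / flagged["n_samples"]
    return flagged


def tumor_blood_y_table(calls: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Per male patient: chrY arm coverage in tumor vs matched blood, with
    LOY flags for both tissues (the tumor-versus-blood scatter view)."""
    sheet = samples.set_index("sample_id") if "sample_id" in samples.columns else samples
    y = calls[calls["arm"] == "chrY"].copy()
    y["patient_id"] = [sheet.loc[s, "patient_id"] for s in y["sample_id"]]
    wide = y.pivot_table(
        index="patient_id", columns="tissue", values=["coverage", "flagged"],
        aggfunc="first",
    )
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    return wide.reset_index()
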