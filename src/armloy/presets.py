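"""Reference cohort designs and one-call pipeline runners.

These presets encode the cohort layouts used throughout the package's
documentation and validation: a 93-patient discovery-style cohort (52
male, 41 female, tumor + matched blood), its single-event variants, and
a 34-tumor expression cohort.  Each helper returns a plain config
mapping for :func:`armloy.synthcohort.plant_events`, so any parameter
can be overridden before planting.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import covnorm, ploidycall, synthcohort
from .genome import GenomeModel, MALE, default_genome

DISCOVERY_SEED = 42
BLOOD_SEED = 43
LOX_SEED = 44
CHR3P_SEED = 45
EXPRESSION_SEED = 11


def discovery_male_cohort() -> dict:
    """52 male tumor/blood pairs; somatic LOY in 19 tumors at cell
    fractions uniform in [0.2, 0.75]."""
    return dict(
        n_male=52,
        n_female=0,
        tissues=["tumor", "normal"],
        lam=30.0,
        events=[
            dict(arm="chrY", kind="loss", tissue="tumor", n=19,
                 fraction_range=(0.2, 0.75)),
        ],
    )


def blood_mosaic_cohort() -> dict:
    """52 male tumor/blood pairs; mosaic LOY in 5 blood samples at fixed
    fractions 0.15-0.55."""
    return dict(
        n_male=52,
        n_female=0,
        tissues=["tumor", "normal"],
        lam=30.0,
        events=[
            dict(arm="chrY", kind="loss", tissue="normal", n=5,
                 fractions=[0.15, 0.25, 0.35, 0.45, 0.55]),
        ],
    )


def female_lox_cohort() -> dict:
    """41 female tumor/blood pairs; whole-chromosome X loss in 7 tumors
    at fractions uniform in [0.2, 0.7]."""
    return dict(
        n_male=0,
        n_female=41,
        tissues=["tumor", "normal"],
        lam=30.0,
        events=[
            dict(arm="chrX", kind="loss", tissue="tumor", n=7, sex="female",
                 fraction_range=(0.2, 0.7)),
        ],
    )


def chr3p_cohort() -> dict:
    """93 tumor/blood pairs (52 male, 41 female); one-copy 3p loss in 85
    tumors at fractions uniform in [0.3, 0.9]."""
    return dict(
        n_male=52,
        n_female=41,
        tissues=["tumor", "normal"],
        lam=30.0,
        events=[
            dict(arm="3p", kind="loss", tissue="tumor", n=85,
                 fraction_range=(0.3, 0.9)),
        ],
    )


def expression_cohort() -> dict:
    """34 male tumors (no matched normals), somatic LOY in 13 at
    fractions uniform in [0.2, 0.75] — the differential-expression
    design."""
    return dict(
        n_male=34,
        n_female=0,
        tissues=["tumor"],
        lam=30.0,
        events=[
            dict(arm="chrY", kind="loss", tissue="tumor", n=13,
                 fraction_range=(0.2, 0.75)),
        ],
    )


def run_wgs_pipeline(
    cohort_config: dict,
    seed: int,
    genome: GenomeModel | None = None,
    k: int = covnorm.DEFAULT_K,
    alpha: float = ploidycall.DEFAULT_ALPHA,
    f_min: float = ploidycall.DEFAULT_MIN_FRACTION,
):
    """simulate -> normalize -> select stable bins -> arm medians -> call.

    Returns (truth, arm_coverage, calls)."""
    genome = genome or default_genome()
    truth = synthcohort.plant_events(cohort_config, seed)
    covset = synthcohort.simulate_bin_counts(truth, genome)
    normalized = covnorm.normalize_cohort(covset, genome)
    selection = covnorm.select_stable_bins(normalized, truth.samples, genome, k=k)
    arm_cov = covnorm.arm_medians(normalized, selection, truth.samples, genome)
    calls = ploidycall.call_cohort(
        arm_cov, truth.samples, genome, alpha=alpha, f_min=f_min
    )
    return truth, arm_cov, calls


def flagged_prevalence(
    calls: pd.DataFrame,
    samples: pd.DataFrame,
    unit: str,
    tissue: str = "tumor",
    direction: str = "loss",
) -> tuple[int, int, float]:
    """(n flagged, n eligible, percent) for one unit in one tissue class.

    ``unit`` may be an arm label or a whole chromosome (``chrX``): a
    sample counts as flagged if any of the unit's arms is flagged in the
    given direction.  Eligible samples are those of the tissue class that
    were tested for the unit at all (male-only for chrY)."""
    sub = calls[calls["tissue"] == tissue]
    if unit.startswith("chr") and unit not in set(sub["arm"]):
        stem = unit[3:]
        arms = [a for a in sub["arm"].unique() if a in (f"{stem}p", f"{stem}q", unit)]
    else:
        arms = [unit]
    if not arms:
        raise ValueError(f"unit {unit!r} has no tested arms in the calls")
    tested = sub[sub["arm"].isin(arms)]
    eligible = tested["sample_id"].nunique()
    hits = tested[tested["flagged"] & (tested["direction"] == direction)]
    n_flagged = hits["sample_id"].nunique()
    percent = 100.0 * n_flagged / eligible if eligible else float("nan")
    return n_flagged, eligible, percent
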