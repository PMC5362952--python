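"""Synthetic cohorts with arm-level events planted at known cell fractions.

The generator is the testbed for the whole pipeline: it emits binned read
counts, sample sheets, probe-amplification panels and expression matrices
from a single seeded truth object, so every downstream stage can be
checked against planted ground truth.

Generative model
----------------
* Bin counts:  count(s, b) ~ Poisson(lambda * bias_b * d(s, arm(b)))
  with a per-bin multiplicative bias shared by all samples (lognormal,
  sigma 0.1 by default — a static mappability-style artefact) and a
  dosage d = baseline * event factor.  An event at cell fraction f
  multiplies dosage by (1 - f) when the only copy is lost, (1 - f/2)
  when one of two copies is lost, (1 + f) / (1 + f/2) for the
  corresponding gains.
* Expression:  Y-linked genes in male tumors have mean RPKM
  base * (1 - f_LOY), other genes base, with multiplicative lognormal
  noise on the log2 scale; female samples get Y genes at a noise floor.
* Probe panel: each Y locus amplifies proportionally to Y dosage times a
  probe-specific efficiency shared across samples, with lognormal noise;
  a female control sits at the detection floor.

All randomness descends from the single cohort seed; identical
(config, seed) gives identical outputs.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .covnorm import BinCoverageSet
from .genome import FEMALE, MALE, GenomeModel

DEFAULT_LAMBDA = 30.0
DEFAULT_BIAS_SIGMA = 0.1
DEFAULT_EXPR_NOISE_SD = 0.3
DEFAULT_EXPR_FLOOR = 0.01
DEFAULT_PROBE_NOISE_SD = 0.1
DEFAULT_PROBE_FLOOR = 0.01

LOSS = "loss"
GAIN = "gain"


@dataclass(frozen=True)
class PlantedEvent:
    sample_id: str
    arm: str  # arm unit, or 'chrX'/'chrY' for a whole chromosome
    kind: str  # 'loss' | 'gain'
    fraction: float

    def __post_init__(self) -> None:
        if not (0.0 < self.fraction <= 1.0):
            raise ValueError(f"cell fraction must be in (0, 1], got {self.fraction}")
        if self.kind not in (LOSS, GAIN):
            raise ValueError(f"kind must be '{LOSS}' or '{GAIN}', got {self.kind!r}")


@dataclass
class CohortTruth:
    """Planted ground truth: sample sheet, event list, seed and noise
    parameters.  The seed fully determines every generated artefact."""

    samples: pd.DataFrame  # sample_id, patient_id, tissue, sex, age, kdm5c_mut, focal_del
    events: pd.DataFrame  # sample_id, arm, kind, fraction
    seed: int
    lam: float = DEFAULT_LAMBDA
    bias_sigma: float = DEFAULT_BIAS_SIGMA

    def events_for(self, sample_id: str) -> pd.DataFrame:
        return self.events[self.events["sample_id"] == sample_id]

    def loy_fraction(self, sample_id: str) -> float:
        """Planted chrY-loss fraction for a sample (0.0 if none)."""
        ev = self.events
        hit = ev[(ev["sample_id"] == sample_id) & (ev["arm"] == "chrY") & (ev["kind"] == LOSS)]
        return float(hit["fraction"].iloc[0]) if len(hit) else 0.0


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def _event_arm_sex(arm: str) -> str | None:
    """Karyotype constraint of an event unit: chrY units are male-only."""
    if arm == "chrY" or arm.startswith("Y"):
        return MALE
    return None


def plant_events(config: Mapping, seed: int) -> CohortTruth:
    """Build a seeded cohort truth from a config mapping.

    Config keys: ``n_male``, ``n_female``, ``tissues`` (default
    ``['tumor', 'normal']``), ``lam``, ``bias_sigma``, ``age`` (mapping
    with ``mean``, ``sd``, ``loy_blood_mean``) and ``events`` — a list of
    event requests, each with ``arm``, ``kind``, ``tissue``, an exact
    carrier count ``n`` (or explicit ``sample_ids``), and either
    ``fraction_range`` (uniform draw) or ``fractions`` (explicit list);
    an optional ``sex`` restricts eligibility.  Carrier counts are exact,
    never binomial draws.

    Only karyotype validity is enforced: chrY events require male
    samples.  Optional ``mutations`` plants per-sample boolean flags,
    e.g. ``{'kdm5c_mut': {'n': 3, 'tissue': 'tumor', 'within_arm': 'chrX'}}``
    picks carriers among samples already holding an event on that arm.
    """
    n_male = int(config.get("n_male", 0))
    n_female = int(config.get("n_female", 0))
    if n_male + n_female == 0:
        raise ValueError("cohort has no patients")
    tissues = list(config.get("tissues", ["tumor", "normal"]))
    lam = float(config.get("lam", DEFAULT_LAMBDA))
    if lam <= 0:
        raise ValueError(f"lam must be positive, got {lam}")
    bias_sigma = float(config.get("bias_sigma", DEFAULT_BIAS_SIGMA))

    patients = [(f"M{i + 1:03d}", MALE) for i in range(n_male)]
    patients += [(f"F{i + 1:03d}", FEMALE) for i in range(n_female)]
    rows = [
        dict(
            sample_id=f"{pid}_{tissue[0].upper()}",
            patient_id=pid,
            tissue=tissue,
            sex=sex,
        )
        for pid, sex in patients
        for tissue in tissues
    ]
    samples = pd.DataFrame(rows)

    rng = _rng(seed, 0)
    events: list[PlantedEvent] = []
    for req in config.get("events", []):
        arm = str(req["arm"])
        kind = str(req.get("kind", LOSS))
        tissue = str(req.get("tissue", "tumor"))
        req_sex = req.get("sex") or _event_arm_sex(arm)
        if "sample_ids" in req:
            chosen = list(req["sample_ids"])
            sub = samples.set_index("sample_id")
            for sid in chosen:
                sex = sub.loc[sid, "sex"]
                need = _event_arm_sex(arm)
                if need is not None and sex != need:
                    raise ValueError(
                        f"event on {arm} requires a {need} sample; {sid} is {sex}"
                    )
        else:
            pool = samples[samples["tissue"] == tissue]
            if req_sex is not None:
                pool = pool[pool["sex"] == req_sex]
            n = int(req["n"])
            if n > len(pool):
                raise ValueError(
                    f"requested {n} carriers of {kind} on {arm} but only "
                    f"{len(pool)} eligible samples"
                )
            chosen = sorted(rng.choice(pool["sample_id"].to_numpy(), size=n, replace=False))
        if "fractions" in req:
            fr = [float(x) for x in req["fractions"]]
            if len(fr) != len(chosen):
                raise ValueError("fractions list length does not match carrier count")
        else:
            lo, hi = req["fraction_range"]
            if not (0.0 < lo <= hi <= 1.0):
                raise ValueError(f"invalid fraction range [{lo}, {hi}]")
            fr = rng.uniform(lo, hi, size=len(chosen)).tolist()
        events.extend(
            PlantedEvent(sample_id=s, arm=arm, kind=kind, fraction=f)
            for s, f in zip(chosen, fr)
        )

    events_df = pd.DataFrame(
        [vars(e) for e in events],
        columns=["sample_id", "arm", "kind", "fraction"],
    )

    # Ages: non-carriers ~ N(59, 8); patients with blood (normal-tissue)
    # chrY loss ~ N(69, 8) — mosaic LOY skews old.
    age_cfg = dict(config.get("age", {}))
    mean = float(age_cfg.get("mean", 59.0))
    sd = float(age_cfg.get("sd", 8.0))
    loy_mean = float(age_cfg.get("loy_blood_mean", 69.0))
    blood_loy_samples = set(
        events_df.loc[
            (events_df["arm"] == "chrY") & (events_df["kind"] == LOSS), "sample_id"
        ]
    )
    sheet = samples.set_index("sample_id")
    blood_loy_patients = {
        sheet.loc[s, "patient_id"]
        for s in blood_loy_samples
        if sheet.loc[s, "tissue"] == "normal"
    }
    age_rng = _rng(seed, 1)
    ages = {}
    for pid, _sex in patients:
        mu = loy_mean if pid in blood_loy_patients else mean
        ages[pid] = float(np.clip(np.round(age_rng.normal(mu, sd), 1), 18.0, None))
    samples["age"] = [ages[p] for p in samples["patient_id"]]

    # Boolean covariate flags (mutations, focal deletions).
    mut_rng = _rng(seed, 2)
    for col in ("kdm5c_mut", "focal_del"):
        samples[col] = False
    for col, spec in dict(config.get("mutations", {})).items():
        tissue = spec.get("tissue", "tumor")
        pool = samples[samples["tissue"] == tissue]
        if spec.get("sex"):
            pool = pool[pool["sex"] == spec["sex"]]
        if spec.get("within_arm"):
            carriers = set(events_df.loc[events_df["arm"] == spec["within_arm"], "sample_id"])
            pool = pool[pool["sample_id"].isin(carriers)]
        n = int(spec["n"])
        if n > len(pool):
            raise ValueError(f"cannot place {n} {col} flags in {len(pool)} samples")
        chosen = mut_rng.choice(pool["sample_id"].to_numpy(), size=n, replace=False)
        if col not in samples.columns:
            samples[col] = False
        samples.loc[samples["sample_id"].isin(chosen), col] = True

    return CohortTruth(
        samples=samples, events=events_df, seed=int(seed), lam=lam, bias_sigma=bias_sigma
    )


def _dosage_factor(kind: str, single_copy: bool, f: float) -> float:
    if kind == LOSS:
        return 1.0 - f if single_copy else 1.0 - f / 2.0
    return 1.0 + f if single_copy else 1.0 + f / 2.0


def bin_bias(truth: CohortTruth, genome: GenomeModel) -> np.ndarray:
    """The cohort's static per-bin bias vector (lognormal, shared by all
    samples), reproducible from the truth seed."""
    rng = _rng(truth.seed, 10)
    return rng.lognormal(mean=0.0, sigma=truth.bias_sigma, size=genome.n_bins())


def expected_dosage(truth: CohortTruth, genome: GenomeModel) -> pd.DataFrame:
    """Closed-form expected normalized coverage per sample x bin (rows =
    bins, columns = samples) before Poisson noise and bias."""
    arms = genome.bins["arm"].to_numpy()
    chroms = genome.bins["chrom"].to_numpy()
    cols = {}
    for _, row in truth.samples.iterrows():
        sid, sex = row["sample_id"], row["sex"]
        base = np.ones(genome.n_bins())
        base[chroms == "chrX"] = 1.0 if sex == FEMALE else 0.5
        base[chroms == "chrY"] = 0.0 if sex == FEMALE else 0.5
        dosage = base.copy()
        for _, ev in truth.events_for(sid).iterrows():
            unit = ev["arm"]
            if unit in ("chrX", "chrY") and unit in set(chroms):
                mask = chroms == unit
            else:
                mask = arms == unit
            if not mask.any():
                raise ValueError(f"event unit {unit!r} not in genome")
            b = base[mask][0]
            if b == 0.0:
                raise ValueError(f"event on absent unit {unit} in {sid} ({sex})")
            single = b == 0.5
            dosage[mask] = base[mask] * _dosage_factor(ev["kind"], single, ev["fraction"])
        cols[sid] = dosage
    return pd.DataFrame(cols, index=genome.bins.index)


def simulate_bin_counts(truth: CohortTruth, genome: GenomeModel) -> BinCoverageSet:
    """Poisson bin counts for every sample: lambda * bias_b * dosage."""
    if truth.lam <= 0:
        raise ValueError(f"lam must be positive, got {truth.lam}")
    bias = bin_bias(truth, genome)
    dosage = expected_dosage(truth, genome)
    rng = _rng(truth.seed, 11)
    counts = {}
    for sid in dosage.columns:
        mean = truth.lam * bias * dosage[sid].to_numpy()
        counts[sid] = rng.poisson(mean).astype(np.int64)
    return BinCoverageSet(
        bins=genome.bins.copy(),
        counts=pd.DataFrame(counts, index=genome.bins.index),
    )


def default_gene_annotation(
    n_y_genes: int = 11,
    n_background: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene -> chromosome annotation with per-gene base RPKM.

    Y-linked genes get solid expression (uniform 8-64 RPKM) so dosage
    effects are visible; background autosomal genes draw base RPKM from a
    lognormal spanning silent to highly expressed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 20]))
    rows = [
        dict(
            gene_id=f"geneY{i + 1:02d}",
            chromosome="chrY",
            base_rpkm=float(rng.uniform(8.0, 64.0)),
        )
        for i in range(n_y_genes)
    ]
    autos = [f"chr{c}" for c in range(1, 23)]
    rows += [
        dict(
            gene_id=f"gene{i + 1:04d}",
            chromosome=str(rng.choice(autos)),
            base_rpkm=float(rng.lognormal(mean=np.log(8.0), sigma=1.0)),
        )
        for i in range(n_background)
    ]
    return pd.DataFrame(rows)


def simulate_expression(
    truth: CohortTruth,
    gene_annotation: pd.DataFrame,
    noise_sd_log2: float = DEFAULT_EXPR_NOISE_SD,
    noise_floor: float = DEFAULT_EXPR_FLOOR,
    tissue: str = "tumor",
    seed: int | None = None,
) -> pd.DataFrame:
    """RPKM matrix for the cohort's samples of one tissue class.

    Y-linked gene means scale by (1 - f) with f the sample's planted
    chrY-loss fraction; all genes carry multiplicative lognormal noise
    with the given sd on the log2 scale.  Female samples express Y genes
    at the noise floor.  Returns a DataFrame with ``gene_id`` index, a
    ``chromosome`` column, then one column per sample.
    """
    if noise_sd_log2 < 0:
        raise ValueError("noise sd must be non-negative")
    rng = _rng(truth.seed if seed is None else seed, 12)
    sub = truth.samples[truth.samples["tissue"] == tissue]
    base = gene_annotation["base_rpkm"].to_numpy(dtype=float)
    is_y = (gene_annotation["chromosome"] == "chrY").to_numpy()
    out = {}
    for _, row in sub.iterrows():
        sid, sex = row["sample_id"], row["sex"]
        mean = base.copy()
        if sex == FEMALE:
            mean[is_y] = noise_floor
        else:
            f = truth.loy_fraction(sid)
            mean[is_y] = np.maximum(base[is_y] * (1.0 - f), noise_floor)
        noise = np.exp2(rng.normal(0.0, noise_sd_log2, size=len(base)))
        out[sid] = mean * noise
    expr = pd.DataFrame(out, index=pd.Index(gene_annotation["gene_id"], name="gene_id"))
    expr.insert(0, "chromosome", gene_annotation["chromosome"].to_numpy())
    return expr


def simulate_probe_panel(
    truth: CohortTruth,
    n_probes: int = 20,
    noise_sd_log2: float = DEFAULT_PROBE_NOISE_SD,
    detection_floor: float = DEFAULT_PROBE_FLOOR,
    include_female_control: bool = False,
    seed: int | None = None,
) -> pd.DataFrame:
    """Amplification table for a panel of chrY loci.

    Rows: probes (``probe_id``, ``locus_label`` columns first); columns:
    all male samples of the cohort, plus the first female sample as a
    negative control when requested.  Each value is
    efficiency_p * Y-dosage_s * lognormal noise, in arbitrary density
    units; zero-dosage samples sit at the detection floor.
    """
    if n_probes < 1:
        raise ValueError(f"need at least one probe, got {n_probes}")
    rng = _rng(truth.seed if seed is None else seed, 13)
    efficiency = rng.lognormal(mean=np.log(1000.0), sigma=0.3, size=n_probes)

    panel_samples = truth.samples[truth.samples["sex"] == MALE]
    sample_ids = panel_samples["sample_id"].tolist()
    if include_female_control:
        females = truth.samples[truth.samples["sex"] == FEMALE]
        if females.empty:
            raise ValueError("no female sample available as control")
        sample_ids.append(females["sample_id"].iloc[0])

    sheet = truth.samples.set_index("sample_id")
    out = {}
    for sid in sample_ids:
        if sheet.loc[sid, "sex"] == FEMALE:
            dosage = 0.0
        else:
            dosage = 1.0 - truth.loy_fraction(sid)
        mean = np.maximum(efficiency * dosage, efficiency * detection_floor)
        out[sid] = mean * np.exp2(rng.normal(0.0, noise_sd_log2, size=n_probes))
    panel = pd.DataFrame(out)
    panel.insert(0, "locus_label", [f"Yloc{i + 1:02d}" for i in range(n_probes)])
    panel.insert(0, "probe_id", [f"probe{i + 1:02d}" for i in range(n_probes)])
    return panel
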