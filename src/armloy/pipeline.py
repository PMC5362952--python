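"""End-to-end driver: simulate -> normalize -> call -> associate.

A run is fully described by one YAML config (thresholds, genome, cohort
design, seed) and writes every intermediate table plus a manifest into
the output directory, so a run can be reproduced byte-for-byte from its
own provenance.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, assocstats, covnorm, io, pcrassay, ploidycall, synthcohort
from .genome import MALE


class PipelineError(RuntimeError):
    """Raised when a stage fails; carries the stage name and context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class RunConfig:
    """All knobs of one run; defaults are the pipeline's canonical
    thresholds (K = 1000 stable bins, alpha = 0.01, minimum fraction
    0.10, FDR cutoff 0.01)."""

    cohort: dict
    genome: dict | None = None
    seed: int = 0
    k: int = covnorm.DEFAULT_K
    alpha: float = ploidycall.DEFAULT_ALPHA
    f_min: float = ploidycall.DEFAULT_MIN_FRACTION
    fdr: float = assocstats.DEFAULT_FDR
    simulate_expression: bool = True
    simulate_probes: bool = True
    n_y_genes: int = 11
    n_background_genes: int = 1000
    expr_noise_sd: float = synthcohort.DEFAULT_EXPR_NOISE_SD

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = io.load_yaml(path)
        if "cohort" not in raw:
            raise ValueError(f"{path}: config needs a 'cohort' section")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc

    return wrap


def run_pipeline(config: RunConfig, out_dir, seed: int | None = None) -> Path:
    """Execute all stages and write the run directory; returns its path.

    Determinism: every random draw descends from ``config.seed`` (or the
    ``seed`` override), so identical configs give byte-identical tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else int(seed)
    log: list[str] = []

    genome = _stage("genome")(io.genome_from_config, config.genome)
    log.append(f"genome: {len(genome.bins)} bins, {len(genome.arms)} arm units")

    truth = _stage("simulate")(synthcohort.plant_events, config.cohort, seed)
    covset = _stage("simulate")(synthcohort.simulate_bin_counts, truth, genome)
    io.write_sample_sheet(out / "samples.tsv", truth.samples)
    io.write_truth(out / "truth.tsv", truth.events)
    io.write_counts_matrix(out / "bin_counts.tsv", covset)
    log.append(
        f"simulate: {len(truth.samples)} samples, {len(truth.events)} planted events"
    )

    normalized = _stage("normalize")(covnorm.normalize_cohort, covset, genome)
    selection = _stage("normalize")(
        covnorm.select_stable_bins, normalized, truth.samples, genome, config.k
    )
    arm_cov = _stage("normalize")(
        covnorm.arm_medians, normalized, selection, truth.samples, genome
    )
    io.write_selection(out / "stable_bins.bed", selection)
    io.write_arm_coverage(out / "arm_coverage.tsv", arm_cov)
    log.append(f"normalize: {len(selection.table)} stable bins over {len(arm_cov.columns)} arms")

    calls = _stage("call-wgs")(
        ploidycall.call_cohort, arm_cov, truth.samples, genome,
        config.alpha, config.f_min,
    )
    io.write_calls(out / "calls.tsv", calls)
    freq = ploidycall.frequency_table(calls)
    freq.to_csv(out / "frequency_summary.tsv", sep="\t", index=False)
    if (truth.samples["sex"] == MALE).any() and set(truth.samples["tissue"]) >= {"tumor", "normal"}:
        ploidycall.tumor_blood_y_table(calls, truth.samples).to_csv(
            out / "tumor_blood_chrY.tsv", sep="\t", index=False
        )
    log.append(f"call-wgs: {int(calls['flagged'].sum())} flagged calls")

    if config.simulate_probes and (truth.samples["sex"] == MALE).any():
        panel = _stage("call-pcr")(synthcohort.simulate_probe_panel, truth)
        io.write_probe_panel(out / "probe_panel.tsv", panel)
        sheet = truth.samples.set_index("sample_id")
        normal_ids = [
            s for s in panel.columns
            if s in sheet.index and sheet.loc[s, "tissue"] == "normal"
        ]
        if len(normal_ids) >= 2:
            norm_panel = _stage("call-pcr")(pcrassay.normalize_probes, panel, normal_ids)
            summaries = pcrassay.sample_summary(norm_panel)
            pcr_calls = _stage("call-pcr")(
                pcrassay.call_pcr_loy, summaries, normal_ids, config.alpha, config.f_min
            )
            io.write_calls(out / "pcr_calls.tsv", pcr_calls)
            log.append(f"call-pcr: {int(pcr_calls['flagged'].sum())} flagged samples")

    if config.simulate_expression and (truth.samples["tissue"] == "tumor").any():
        genes = synthcohort.default_gene_annotation(
            n_y_genes=config.n_y_genes,
            n_background=config.n_background_genes,
            seed=seed,
        )
        expr = _stage("assoc")(
            synthcohort.simulate_expression, truth, genes, config.expr_noise_sd
        )
        io.write_expression(out / "expression.tsv", expr)
        tumor_y = calls[
            (calls["arm"] == "chrY") & (calls["tissue"] == "tumor")
        ].set_index("sample_id")
        if len(tumor_y) >= 4 and tumor_y["flagged"].any() and not tumor_y["flagged"].all():
            de = _stage("assoc")(
                assocstats.de_by_loy, expr, tumor_y["flagged"], "rpkm",
            )
            de.to_csv(out / "de_by_loy.tsv", sep="\t", index=False)
            log.append(f"assoc: {int(de['significant'].sum())} DE genes at FDR<{config.fdr}")

    blood_y = calls[(calls["arm"] == "chrY") & (calls["tissue"] == "normal")]
    if len(blood_y) and blood_y["flagged"].any() and not blood_y["flagged"].all():
        sheet = truth.samples.set_index("sample_id")
        ages = [sheet.loc[s, "age"] for s in blood_y["sample_id"]]
        fit = _stage("assoc")(
            assocstats.loy_age_logistic, blood_y["flagged"].to_numpy(), ages
        )
        pd.DataFrame([vars(fit)]).to_csv(out / "loy_age_logistic.tsv", sep="\t", index=False)
        log.append(f"assoc: mosaic-LOY age logistic beta={fit.beta_age:.4f} p={fit.p:.3g}")

    manifest = dict(
        armloy_version=__version__,
        seed=seed,
        thresholds=dict(k=config.k, alpha=config.alpha, f_min=config.f_min, fdr=config.fdr),
        n_samples=len(truth.samples),
        n_bins=len(genome.bins),
        log=log,
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    return out
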