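"""Coverage normalization, stable-bin selection and arm medians.

The read-depth signal for arm-level dosage is built in three steps:

1. per-sample normalization — every bin count is divided by the sample's
   median autosomal bin count, so a diploid autosomal bin sits at 1.0 and
   a single-copy sex chromosome in males at 0.5, independent of depth;
2. stable-bin selection — within each arm, bins are ranked by the median
   (across normal samples) absolute divergence of their normalized
   coverage from the sex-aware baseline, and only the K most stable bins
   are kept.  This is a mappability proxy: systematically biased bins
   diverge in every normal and are discarded;
3. arm medians — for each sample, the median normalized coverage over the
   selected bins of each arm unit, the single number per sample x arm on
   which aneuploidy is tested downstream.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import FEMALE, GenomeModel

DEFAULT_K = 1000


@dataclass
class BinCoverageSet:
    """Raw bin counts for a cohort: ``bins`` (chrom, start, end, arm) plus
    a counts matrix with one column per sample, rows aligned to ``bins``."""

    bins: pd.DataFrame
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.bins) != len(self.counts):
            raise ValueError("bins and counts have different numbers of rows")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class StableBinSelection:
    """Selected bins per arm with their divergence scores.

    ``table`` columns: chrom, start, end, arm, divergence, bin_index
    (position in the genome bin grid); within each arm rows are ordered by
    non-decreasing divergence, ties broken by genomic position.
    """

    table: pd.DataFrame
    k: int

    def bins_for(self, arm: str) -> np.ndarray:
        return self.table.loc[self.table["arm"] == arm, "bin_index"].to_numpy()

    @property
    def arms(self) -> list[str]:
        return list(dict.fromkeys(self.table["arm"]))


def normalize_sample(raw_counts: np.ndarray, genome: GenomeModel, sex: str | None = None) -> np.ndarray:
    """Divide a sample's bin counts by its median autosomal bin count.

    ``sex`` is accepted for bookkeeping symmetry with the cohort API but
    plays no role: the autosomal median is sex-free by construction.
    """
    raw = np.asarray(raw_counts, dtype=float)
    if raw.shape != (genome.n_bins(),):
        raise ValueError(
            f"expected {genome.n_bins()} bin counts, got shape {raw.shape}"
        )
    if np.any(raw < 0):
        raise ValueError("negative bin counts")
    med = np.median(raw[genome.autosomal_mask()])
    if med <= 0:
        raise ValueError("autosomal median coverage is zero; sample unusable")
    return raw / med


def normalize_cohort(covset: BinCoverageSet, genome: GenomeModel) -> pd.DataFrame:
    """Normalized coverage matrix (bins x samples), one column per sample."""
    out = {}
    for sid in covset.sample_ids:
        out[sid] = normalize_sample(covset.counts[sid].to_numpy(), genome)
    return pd.DataFrame(out, index=covset.counts.index)


def select_stable_bins(
    normalized: pd.DataFrame,
    samples: pd.DataFrame,
    genome: GenomeModel,
    k: int = DEFAULT_K,
    max_zero_frac: float = 0.5,
) -> StableBinSelection:
    """Rank bins within each arm by median divergence from baseline in
    normal samples and keep the ``k`` most stable.

    ``samples`` is the sample sheet (sample_id, tissue, sex, ...); only
    rows with ``tissue == 'normal'`` enter the ranking, and for sex
    chromosomes only normals of the relevant karyotype (chrY in females
    has no baseline and is skipped for them).  Bins with zero coverage in
    at least ``max_zero_frac`` of the usable normals are excluded before
    ranking.  Ties on divergence are broken by genomic position, leftmost
    first.
    """
    sheet = samples.set_index("sample_id") if "sample_id" in samples.columns else samples
    normal_ids = [s for s in normalized.columns if sheet.loc[s, "tissue"] == "normal"]
    if not normal_ids:
        raise ValueError("stable-bin selection needs at least one normal sample")

    pieces: list[pd.DataFrame] = []
    for arm in genome.arms:
        usable = [
            s for s in normal_ids if np.isfinite(genome.baseline(arm, sheet.loc[s, "sex"]))
        ]
        if not usable:
            warnings.warn(f"arm {arm}: no normal sample with a defined baseline; dropped")
            continue
        idx = genome.arm_bin_index(arm)
        sub = normalized.iloc[idx][usable].to_numpy()
        baselines = np.array([genome.baseline(arm, sheet.loc[s, "sex"]) for s in usable])
        divergence = np.median(np.abs(sub - baselines[None, :]), axis=1)
        zero_frac = np.mean(sub == 0, axis=1)
        keep = zero_frac < max_zero_frac
        if not np.any(keep):
            warnings.warn(f"arm {arm}: all bins zero-inflated; dropped")
            continue
        arm_bins = genome.bins.iloc[idx].reset_index(drop=True)
        cand = arm_bins.loc[keep, ["chrom", "start", "end", "arm"]].copy()
        cand["divergence"] = divergence[keep]
        cand["bin_index"] = idx[keep]
        # stable mergesort: equal divergences keep genomic (leftmost) order
        cand = cand.sort_values("divergence", kind="mergesort").head(min(k, len(cand)))
        pieces.append(cand)

    if not pieces:
        raise ValueError("no arm retained any stable bins")
    return StableBinSelection(table=pd.concat(pieces, ignore_index=True), k=k)


def arm_medians(
    normalized: pd.DataFrame,
    selection: StableBinSelection,
    samples: pd.DataFrame,
    genome: GenomeModel,
) -> pd.DataFrame:
    """Per sample x arm median normalized coverage over the selected bins.

    Returns a DataFrame indexed by sample_id with one column per arm unit;
    entries are NaN where the unit has no baseline for the sample's sex
    (chrY in females) or no bins were selected.
    """
    sheet = samples.set_index("sample_id") if "sample_id" in samples.columns else samples
    arms = [a for a in genome.arms if a in selection.arms]
    out = pd.DataFrame(
        np.nan, index=pd.Index(normalized.columns, name="sample_id"), columns=arms
    )
    for arm in arms:
        rows = selection.bins_for(arm)
        if rows.size == 0:
            continue
        med = normalized.iloc[rows].median(axis=0)
        out[arm] = med
        for sid in normalized.columns:
            if not np.isfinite(genome.baseline(arm, sheet.loc[sid, "sex"])):
                out.loc[sid, arm] = np.nan
    return out
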