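"""PCR-probe LOY caller.

A multiplex PCR panel amplifies ~20 chromosome-Y loci per sample; the
amplification density of each probe is proportional to Y dosage.  The
caller mirrors the read-depth pipeline with the panel as the coverage
signal:

1. each probe is normalized by its median amplification across the
   designated normal samples, so an intact Y sits at 1.0;
2. each sample is summarized by the median of its normalized probe
   values — its overall chromosome-Y amplification;
3. a Gaussian-mixture null is fitted on the summaries of the *normal*
   samples only, each sample gets a two-sided tail p-value, and is
   flagged when p < alpha and the implied affected-cell fraction
   (1 - summary, since the expected normalized amplification of an
   intact Y is 1) exceeds the minimum.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ploidycall import MixtureNull, fit_mixture_null, pvalue

DEFAULT_ALPHA = 0.01
DEFAULT_MIN_FRACTION = 0.10
META_COLS = ("probe_id", "locus_label")


def _sample_columns(panel: pd.DataFrame) -> list[str]:
    return [c for c in panel.columns if c not in META_COLS]


def normalize_probes(panel: pd.DataFrame, normal_sample_ids) -> pd.DataFrame:
    """Divide every probe row by its median value across the normals.

    Probes whose median across normals is zero are dropped with a
    warning (they carry no reference signal).
    """
    normals = [s for s in normal_sample_ids if s in panel.columns]
    if len(normals) < 2:
        raise ValueError("probe normalization needs at least two normal samples")
    values = panel[_sample_columns(panel)].to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("negative probe amplification values")
    ref = panel[normals].median(axis=1).to_numpy(dtype=float)
    keep = ref > 0
    if not np.all(keep):
        dropped = panel.loc[~keep, "probe_id"].tolist() if "probe_id" in panel else list(np.flatnonzero(~keep))
        warnings.warn(f"dropping probes with zero normal median: {dropped}")
    out = panel.loc[keep].copy()
    samples = _sample_columns(out)
    out[samples] = out[samples].to_numpy(dtype=float) / ref[keep, None]
    return out


def sample_summary(normalized_panel: pd.DataFrame) -> pd.Series:
    """Per-sample median of the normalized probe values (the sample's
    overall chromosome-Y amplification)."""
    samples = _sample_columns(normalized_panel)
    if normalized_panel.empty:
        return pd.Series(np.nan, index=pd.Index(samples, name="sample_id"))
    s = normalized_panel[samples].median(axis=0)
    s.index.name = "sample_id"
    return s


def call_pcr_loy(
    summaries: pd.Series,
    normal_sample_ids,
    alpha: float = DEFAULT_ALPHA,
    f_min: float = DEFAULT_MIN_FRACTION,
    strict_fraction: bool = True,
) -> pd.DataFrame:
    """Flag samples whose overall Y amplification deviates from the
    normals-only null with an implied affected fraction above ``f_min``.

    The fraction threshold is strict (>) by default for the probe assay;
    p-values are not multiplicity-adjusted because one summary statistic
    is tested per sample.
    """
    normals = [s for s in normal_sample_ids if s in summaries.index]
    if not normals:
        raise ValueError("no normal samples among the summaries")
    null = fit_mixture_null(summaries.loc[normals].to_numpy(), baseline=1.0)
    records = []
    for sid, value in summaries.items():
        p = pvalue(value, null)
        fraction = float(np.clip(1.0 - value, 0.0, 1.0))
        passes_f = fraction > f_min if strict_fraction else fraction >= f_min
        records.append(
            dict(
                sample_id=sid,
                summary=float(value),
                p=p,
                fraction=fraction,
                flagged=bool(p < alpha and passes_f),
            )
        )
    return pd.DataFrame.from_records(records)


def relative_amplification(
    panel: pd.DataFrame, tumor_id: str, matched_normal_id: str
) -> pd.Series:
    """Tumor/normal amplification ratio per locus for one patient pair.

    Loci where the normal amplification is zero are skipped with a
    warning.
    """
    for sid in (tumor_id, matched_normal_id):
        if sid not in panel.columns:
            raise KeyError(f"sample {sid!r} not in panel")
    t = panel[tumor_id].to_numpy(dtype=float)
    n = panel[matched_normal_id].to_numpy(dtype=float)
    labels = panel["locus_label"] if "locus_label" in panel else panel.index
    ok = n > 0
    if not np.all(ok):
        warnings.warn(
            f"skipping loci with zero normal amplification: {list(np.asarray(labels)[~ok])}"
        )
    return pd.Series(t[ok] / n[ok], index=pd.Index(np.asarray(labels)[ok], name="locus"))


def group_relative_amplification(
    panel: pd.DataFrame,
    pairs: pd.DataFrame,
    loy_flags: pd.Series,
) -> pd.DataFrame:
    """Per-locus mean and range of tumor/normal ratios by LOY group.

    ``pairs`` needs columns ``tumor_id`` and ``normal_id`` (one row per
    patient); ``loy_flags`` is indexed by tumor_id.  This is the
    cohort-level per-locus comparison view: in a cohort with somatic LOY
    the affected group's mean ratio drops at every locus.
    """
    frames = []
    for _, row in pairs.iterrows():
        ratios = relative_amplification(panel, row["tumor_id"], row["normal_id"])
        frames.append(
            pd.DataFrame(
                {
                    "locus": ratios.index,
                    "ratio": ratios.to_numpy(),
                    "loy": bool(loy_flags.loc[row["tumor_id"]]),
                }
            )
        )
    long = pd.concat(frames, ignore_index=True)
    out = (
        long.groupby(["locus", "loy"])["ratio"]
        .agg(mean="mean", min="min", max="max", n="count")
        .reset_index()
    )
    return out
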