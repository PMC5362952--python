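"""Readers and writers for the pipeline's plain-text formats.

Everything is tab-separated UTF-8 with ``.`` decimals.  Bin counts use a
4-column BED-style layout (chrom, start, end, count; 0-based half-open),
or a combined matrix with three leading coordinate columns and one column
per sample.  Genome and cohort configuration is YAML.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .covnorm import BinCoverageSet
from .genome import GenomeModel, build_genome, default_genome


def load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def genome_from_config(config: dict | None) -> GenomeModel:
    """Genome from a config mapping: either explicit ``chromosomes`` (see
    :func:`armloy.genome.build_genome`) or the miniature human default,
    optionally with ``scale`` / ``bin_size`` overrides."""
    if not config or "chromosomes" not in config:
        kwargs = {}
        if config:
            if "scale" in config:
                kwargs["scale"] = int(config["scale"])
            if "bin_size" in config:
                kwargs["bin_size"] = int(config["bin_size"])
        return default_genome(**kwargs)
    return build_genome(config)


def read_bed_counts(path, genome: GenomeModel) -> np.ndarray:
    """Read one sample's 4-column BED-style counts, validated against the
    genome bin grid.

    Rows may be in any order (they are sorted on load); a ``#``-prefixed
    header line is allowed.  Malformed rows, negative counts, bins
    missing from or absent in the grid all raise with the offending line
    or bin named.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "count"],
        dtype={"chrom": str},
    )
    for col in ("start", "end", "count"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise ValueError(f"{path}: malformed {col!r} value on data line {line}")
        df[col] = df[col].astype(np.int64)
    neg = df["count"] < 0
    if neg.any():
        line = int(neg.idxmax()) + 1
        raise ValueError(f"{path}: negative count on data line {line}")

    grid = genome.bins[["chrom", "start", "end"]].copy()
    grid["_pos"] = np.arange(len(grid))
    merged = df.merge(grid, on=["chrom", "start", "end"], how="left")
    unknown = merged["_pos"].isna()
    if unknown.any():
        row = df.loc[unknown.idxmax()]
        raise ValueError(
            f"{path}: bin {row['chrom']}:{row['start']}-{row['end']} not in genome grid"
        )
    if merged["_pos"].duplicated().any():
        row = df.loc[merged["_pos"].duplicated().idxmax()]
        raise ValueError(
            f"{path}: duplicate bin {row['chrom']}:{row['start']}-{row['end']}"
        )
    if len(merged) != len(grid):
        present = set(merged["_pos"].astype(int))
        missing_pos = next(i for i in range(len(grid)) if i not in present)
        row = genome.bins.iloc[missing_pos]
        raise ValueError(
            f"{path}: missing bin {row['chrom']}:{row['start']}-{row['end']}"
        )
    out = np.zeros(len(grid), dtype=np.int64)
    out[merged["_pos"].astype(int)] = merged["count"].to_numpy()
    return out


def write_bed_counts(path, genome: GenomeModel, counts: np.ndarray) -> None:
    df = genome.bins[["chrom", "start", "end"]].copy()
    df["count"] = np.asarray(counts, dtype=np.int64)
    df.to_csv(path, sep="\t", header=False, index=False)


def write_counts_matrix(path, covset: BinCoverageSet) -> None:
    df = covset.bins[["chrom", "start", "end"]].reset_index(drop=True)
    df = pd.concat([df, covset.counts.reset_index(drop=True)], axis=1)
    df.to_csv(path, sep="\t", index=False)


def read_counts_matrix(path, genome: GenomeModel) -> BinCoverageSet:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    coord = ["chrom", "start", "end"]
    df = df.sort_values(coord, kind="mergesort").reset_index(drop=True)
    grid = genome.bins[coord].reset_index(drop=True)
    merged = grid.merge(df, on=coord, how="left", indicator=True)
    if (merged["_merge"] != "both").any() or len(df) != len(grid):
        raise ValueError(f"{path}: bin grid does not match the genome model")
    counts = merged.drop(columns=coord + ["_merge"]).astype(np.int64)
    return BinCoverageSet(bins=genome.bins.copy(), counts=counts)


def write_sample_sheet(path, samples: pd.DataFrame) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("kdm5c_mut", "focal_del"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def write_truth(path, events: pd.DataFrame) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_arm_coverage(path, arm_cov: pd.DataFrame) -> None:
    arm_cov.to_csv(path, sep="\t", index=True)


def read_arm_coverage(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_calls(path, calls: pd.DataFrame) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_calls(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["flagged"] = df["flagged"].astype(bool)
    return df


def write_expression(path, expr: pd.DataFrame) -> None:
    expr.to_csv(path, sep="\t", index=True)


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_probe_panel(path, panel: pd.DataFrame) -> None:
    panel.to_csv(path, sep="\t", index=False)


def read_probe_panel(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_selection(path, selection) -> None:
    selection.table[["chrom", "start", "end", "arm", "divergence"]].to_csv(
        path, sep="\t", header=False, index=False
    )
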