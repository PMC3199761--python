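"""Readers, writers, run configuration and the full-pipeline driver.

All tables are plain TSV with ``#``-prefixed metadata header lines
(version, parameters, seed), so every output is diff-able and a rerun
with the same configuration and seed is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .corr import ExpressionPair, compute_pcc, half_threshold_filter
from . import baselines as _baselines
from .dce import dce_run
from .dcp import dcp_permutation_test, gene_dc_table

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or contradictory run configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Malformed input data (CLI exit code 3)."""


def read_expression(path) -> pd.DataFrame:
    """Read a tab-delimited expression matrix (gene id column + header row).

    Rejects duplicate gene ids, non-numeric cells and missing values —
    each with an error naming the offender.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise DataError(f"{path}: cannot parse expression table: {exc}")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise DataError(f"{path}: duplicate gene ids: {dupes}")
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise DataError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
        df[col] = converted
    if df.isna().any().any():
        rows = df.index[df.isna().any(axis=1)].tolist()
        raise DataError(f"{path}: missing values in rows {rows}")
    if df.shape[1] < 4:
        raise DataError(f"{path}: at least 4 samples required, got {df.shape[1]}")
    return df


def read_labels(path) -> pd.Series:
    """Two-column (sample, condition) label file; exactly two levels."""
    labels = pd.read_csv(path, sep="\t", index_col=0).iloc[:, 0]
    if labels.nunique() != 2:
        raise DataError(
            f"{path}: expected exactly 2 condition levels, got {labels.nunique()}"
        )
    return labels


def split_by_labels(matrix: pd.DataFrame, labels: pd.Series) -> ExpressionPair:
    """Split one matrix into an :class:`ExpressionPair` by condition labels."""
    missing = [s for s in matrix.columns if s not in labels.index]
    if missing:
        raise DataError(f"samples without condition label: {missing}")
    levels = sorted(labels.unique())
    cols_x = [s for s in matrix.columns if labels[s] == levels[0]]
    cols_y = [s for s in matrix.columns if labels[s] == levels[1]]
    return ExpressionPair(matrix[cols_x], matrix[cols_y])


def load_pair(
    cond_x_path=None, cond_y_path=None, expression_path=None, labels_path=None
) -> ExpressionPair:
    """Load an expression pair from two files or one file plus labels."""
    two_files = cond_x_path is not None and cond_y_path is not None
    labeled = expression_path is not None and labels_path is not None
    if two_files == labeled:
        raise ConfigError(
            "provide either two condition matrices or one matrix plus labels"
        )
    if two_files:
        mx = read_expression(cond_x_path)
        my = read_expression(cond_y_path)
        if not mx.index.equals(my.index):
            raise DataError("the two condition matrices must share gene ids in order")
        return ExpressionPair(mx, my)
    return split_by_labels(read_expression(expression_path), read_labels(labels_path))


def write_table(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write a TSV with ``#``-prefixed metadata header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# dclink {__version__}\n")
        for key, value in (metadata or {}).items():
            fh.write(f"# {key} = {value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` (metadata lines skipped)."""
    return pd.read_csv(path, sep="\t", comment="#")


def write_truth(truth, out_dir) -> None:
    """Write drls.tsv, drgs.txt and extended_drls.tsv for a simulation."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    drls = pd.DataFrame(
        [(i, j, kind) for (i, j), kind in sorted(truth.drls.items())],
        columns=["gene_i", "gene_j", "type"],
    )
    write_table(drls, out_dir / "drls.tsv")
    (out_dir / "drgs.txt").write_text(
        "".join(f"{g}\n" for g in sorted(truth.drgs))
    )
    ext = pd.DataFrame(
        sorted(truth.extended_drls), columns=["gene_i", "gene_j"]
    )
    write_table(ext, out_dir / "extended_drls.tsv")


@dataclass
class RunConfig:
    """Configuration for the full pipeline run."""

    out_dir: str
    cond_x: str | None = None
    cond_y: str | None = None
    expression: str | None = None
    labels: str | None = None
    q_th: float | None = 0.25
    rho: float | None = None
    dce_rho: float = 0.8
    delta: float = 0.1
    n_bins: int = 20
    beta: float = 12
    n_perm: int = 1000
    seed: int = 0
    boundary_mode: str = "min-outlier"
    methods: tuple = ("dcp", "dce", "lrc", "asc", "wgcna")
    baseline_rho: float = 0.8

    def __post_init__(self) -> None:
        if (self.q_th is None) == (self.rho is None):
            raise ConfigError("exactly one of q_th / rho must be set")
        unknown = set(self.methods) - {"dcp", "dce", "lrc", "asc", "wgcna"}
        if unknown:
            raise ConfigError(f"unknown methods: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "methods" in raw and isinstance(raw["methods"], list):
            raw["methods"] = tuple(raw["methods"])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc))


def run_pipeline(config: RunConfig) -> dict:
    """Shared pre-processing, then every requested method, then writers.

    Returns the result bundle (in-memory frames); files are written
    under ``config.out_dir``.  All randomness flows from ``config.seed``.
    """
    pair = load_pair(
        cond_x_path=config.cond_x, cond_y_path=config.cond_y,
        expression_path=config.expression, labels_path=config.labels,
    )
    meta = {
        "seed": config.seed, "q_th": config.q_th, "rho": config.rho,
        "n_perm": config.n_perm, "delta": config.delta,
        "n_bins": config.n_bins, "beta": config.beta,
        "dce_rho": config.dce_rho, "boundary_mode": config.boundary_mode,
    }
    out = Path(config.out_dir)
    results: dict = {}

    links = compute_pcc(pair)
    fls = half_threshold_filter(links, q_th=config.q_th, rho=config.rho)
    kept_key = pd.MultiIndex.from_frame(fls.links[["gene_i", "gene_j"]])
    links = links.assign(
        kept=pd.MultiIndex.from_frame(links[["gene_i", "gene_j"]]).isin(kept_key)
    )
    logger.info("filtered link universe: N = %d of %d pairs",
                fls.n_links, len(links))
    write_table(links, out / "links.tsv", meta)
    results["links"] = links
    results["filtered"] = fls

    if "dcp" in config.methods:
        if config.n_perm > 0:
            dcg = dcp_permutation_test(
                pair, n_perm=config.n_perm, seed=config.seed,
                q_th=config.q_th, rho=config.rho,
            )
        else:
            dcg = gene_dc_table(pair, fls)
        write_table(dcg, out / "dcp_dcg.tsv", meta)
        results["dcp"] = dcg

    if "dce" in config.methods:
        dcl, dcg = dce_run(
            fls, rho=config.dce_rho, delta=config.delta,
            n_bins=config.n_bins, boundary_mode=config.boundary_mode,
        )
        write_table(dcl, out / "dce_dcl.tsv", meta)
        write_table(dcg, out / "dce_dcg.tsv", meta)
        logger.info("DCe: %d DCLs, %d genes scored",
                    int(dcl["is_dcl"].sum()), len(dcg))
        results["dce_dcl"] = dcl
        results["dce_dcg"] = dcg

    genes = pair.gene_ids
    if "lrc" in config.methods:
        tbl = _baselines.lrc(links, genes, rho=config.baseline_rho)
        write_table(tbl, out / "lrc.tsv", meta)
        results["lrc"] = tbl
    if "asc" in config.methods:
        tbl = _baselines.asc(links, genes, rho=config.baseline_rho)
        write_table(tbl, out / "asc.tsv", meta)
        results["asc"] = tbl
    if "wgcna" in config.methods:
        tbl = _baselines.wgcna(links, genes, beta=config.beta, mode="signed")
        write_table(tbl, out / "wgcna.tsv", meta)
        results["wgcna"] = tbl
    return results
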