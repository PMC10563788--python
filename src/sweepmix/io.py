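"""Readers and writers for the pipeline's plain-text formats.

Dialects: tab-delimited genetic maps (chrom, pos, cM), BED 3/5 for interval
tracks, BED-like gene tables with per-gene scalars, hapbin-style per-SNP
score tables with a configurable column mapping, and the package's own
feature/fit tables with a commented provenance header.  Readers raise
:class:`FileFormatError` with the file and 1-based line number on malformed
input.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import MDRFit
from .windows import GeneticMap

FEATURE_SCHEMA_VERSION = 1

#: default hapbin-style column mapping for SNP score tables
DEFAULT_SNP_COLUMNS = {"chrom": "chrom", "pos": "pos", "daf": "daf",
                       "ihs": "ihs_raw"}


class FileFormatError(ValueError):
    def __init__(self, path, line: int | None, reason: str):
        self.path = str(path)
        self.line = line
        where = f"{path}" if line is None else f"{path}:{line}"
        super().__init__(f"{where}: {reason}")


def _read_table(path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        return pd.read_csv(path, sep="\t", comment="#",
                           float_precision="round_trip", **kwargs)
    except Exception as exc:  # pandas raises several parse error types
        raise FileFormatError(path, None, f"cannot parse: {exc}") from exc


def read_genetic_map(path) -> GeneticMap:
    """Tab-delimited chrom / pos (bp) / cm table, header required."""
    df = _read_table(path)
    for col in ("chrom", "pos", "cm"):
        if col not in df.columns:
            raise FileFormatError(path, 1, f"missing column {col!r} "
                                           f"(found {list(df.columns)})")
    bad = ~np.isfinite(df["cm"].to_numpy(dtype=float))
    if bad.any():
        raise FileFormatError(path, int(np.flatnonzero(bad)[0]) + 2,
                              "non-numeric genetic position")
    try:
        return GeneticMap.from_frame(df)
    except ValueError as exc:
        raise FileFormatError(path, None, str(exc)) from exc


def read_bed(path, scored: bool = False) -> pd.DataFrame:
    """BED3 (chrom, start, end) or BED5 with the score in column 5."""
    names = ["chrom", "start", "end", "name", "score"]
    df = _read_table(path, header=None)
    if df.shape[1] < 3:
        raise FileFormatError(path, 1, "BED needs at least 3 columns")
    df = df.iloc[:, :min(df.shape[1], 5)]
    df.columns = names[:df.shape[1]]
    if scored and "score" not in df.columns:
        raise FileFormatError(path, 1, "scored BED needs 5 columns")
    for col in ("start", "end"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            raise FileFormatError(path, int(np.flatnonzero(bad)[0]) + 1,
                                  f"non-integer {col}")
        df[col] = vals.astype(np.int64)
    bad = df["end"] <= df["start"]
    if bad.any():
        raise FileFormatError(path, int(np.flatnonzero(bad)[0]) + 1,
                              "interval end must exceed start")
    return df


def read_gene_table(path) -> pd.DataFrame:
    """Gene annotation TSV: chrom, start, end, gene_id plus scalar columns."""
    df = _read_table(path)
    required = {"chrom", "start", "end", "gene_id"}
    missing = required - set(df.columns)
    if missing:
        raise FileFormatError(path, 1, f"missing columns {sorted(missing)}")
    bad = df["end"] <= df["start"]
    if bad.any():
        raise FileFormatError(path, int(np.flatnonzero(bad)[0]) + 2,
                              "gene end must exceed start")
    if "is_vip" in df.columns:
        df["is_vip"] = df["is_vip"].astype(bool)
    return df


def read_snp_scores(path, column_map: dict[str, str] | None = None,
                    ) -> pd.DataFrame:
    """hapbin-style per-SNP table -> canonical (chrom, pos, daf, ihs_raw).

    ``column_map`` renames the caller's columns onto the canonical roles,
    e.g. ``{"pos": "Location", "daf": "Freq", "ihs": "iHS"}``; whether the
    frequency column holds derived or minor allele frequency is the
    caller's responsibility to declare.
    """
    colmap = {**DEFAULT_SNP_COLUMNS, **(column_map or {})}
    df = _read_table(path)
    out = {}
    for role, src in colmap.items():
        if src not in df.columns:
            raise FileFormatError(path, 1,
                                  f"column {src!r} (role {role}) not found; "
                                  f"available: {list(df.columns)}")
        out["ihs_raw" if role == "ihs" else role] = df[src]
    res = pd.DataFrame(out)
    res["pos"] = pd.to_numeric(res["pos"], errors="raise").astype(np.int64)
    res["daf"] = res["daf"].astype(float)
    res["ihs_raw"] = res["ihs_raw"].astype(float)
    bad = (res["daf"] < 0) | (res["daf"] > 1) | res["daf"].isna()
    if bad.any():
        raise FileFormatError(path, int(np.flatnonzero(bad)[0]) + 2,
                              "allele frequency outside [0, 1]")
    return res


# ---------------------------------------------------------------------------
# Provenance + package tables
# ---------------------------------------------------------------------------

def config_hash(config: dict) -> str:
    return hashlib.sha1(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _provenance_lines(config: dict | None, seed: int | None,
                      timestamp: bool) -> list[str]:
    lines = [f"# sweepmix_version={__version__}"]
    if config is not None:
        lines.append(f"# config_hash={config_hash(config)}")
    if seed is not None:
        lines.append(f"# seed={seed}")
    if timestamp:
        lines.append(f"# written={datetime.now(timezone.utc).isoformat()}")
    return lines


def write_feature_table(features: pd.DataFrame, path,
                        config: dict | None = None, seed: int | None = None,
                        timestamp: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# schema_version={FEATURE_SCHEMA_VERSION}\n")
        for line in _provenance_lines(config, seed, timestamp):
            fh.write(line + "\n")
        features.to_csv(fh, sep="\t", index=False)


def read_feature_table(path) -> pd.DataFrame:
    return _read_table(path)


def write_fit_table(fit: MDRFit, lrt_table: pd.DataFrame, path,
                    component_magnitude: float,
                    config: dict | None = None, seed: int | None = None,
                    timestamp: bool = False) -> None:
    """Per-covariate slope / LR / p-value rows plus a model header block."""
    p = fit.params
    with open(path, "w") as fh:
        for line in _provenance_lines(config, seed, timestamp):
            fh.write(line + "\n")
        fh.write(f"# mu0={p.mu0!r}\n# sigma0={p.sigma0!r}\n")
        fh.write(f"# mu1={p.mu1!r}\n# sigma1={p.sigma1!r}\n")
        fh.write(f"# intercept={p.intercept!r}\n")
        fh.write(f"# loglik={fit.loglik!r}\n")
        fh.write(f"# n_windows={fit.n_windows}\n")
        fh.write(f"# component_magnitude={component_magnitude!r}\n")
        fh.write(f"# converged={fit.converged}\n")
        fh.write(f"# degenerate={fit.degenerate}\n")
        lrt_table.to_csv(fh, sep="\t", index=False)


def load_run_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FileFormatError(path, 1, "config must be a YAML mapping")
    return cfg
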