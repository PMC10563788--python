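"""From per-SNP raw iHS to the MDR response and standardized covariates.

Raw iHS depends strongly on allele frequency, so scores are standardized
within derived-allele-frequency bins computed genome-wide: 50 half-open bins
on [0, 1] (the top bin closed), each score mapped to
``(raw - bin mean) / bin SD``.  The per-window response is the mean of
\\|standardized iHS\\| over SNPs in the window; the model consumes its natural
log, z-scored over the analysis set.  Sample SD (ddof=1) is used throughout.

No randomness anywhere in this module: identical inputs give bit-identical
outputs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column names of a SNP score table
SNP_COLUMNS = ("chrom", "pos", "daf", "ihs_raw")

DEFAULT_N_BINS = 50
DEFAULT_MIN_MAF = 0.05
DEFAULT_MIN_BIN_COUNT = 2


def filter_maf(snps: pd.DataFrame, min_maf: float = DEFAULT_MIN_MAF) -> pd.DataFrame:
    """Keep SNPs with minor allele frequency strictly greater than ``min_maf``.

    Frequencies are derived-allele frequencies; MAF is ``min(f, 1-f)``.
    """
    f = snps["daf"].to_numpy(dtype=float)
    if np.any((f < 0) | (f > 1)) or not np.all(np.isfinite(f)):
        raise ValueError("derived allele frequencies must lie in [0, 1]")
    maf = np.minimum(f, 1.0 - f)
    kept = snps.loc[maf > min_maf].reset_index(drop=True)
    logger.info("MAF filter (> %.3g): kept %d of %d SNPs",
                min_maf, len(kept), len(snps))
    return kept


def assign_frequency_bin(freq, n_bins: int = DEFAULT_N_BINS):
    """Map frequency to bin index: half-open bins [k/n, (k+1)/n), top bin closed.

    Accepts a scalar or array; frequencies outside [0, 1] raise.
    """
    arr = np.asarray(freq, dtype=float)
    if np.any((arr < 0) | (arr > 1)) or not np.all(np.isfinite(arr)):
        raise ValueError("frequency outside [0, 1]")
    idx = np.minimum(np.floor(arr * n_bins).astype(int), n_bins - 1)
    return int(idx) if np.isscalar(freq) else idx


def standardize_ihs(snps: pd.DataFrame, n_bins: int = DEFAULT_N_BINS,
                    min_bin_count: int = DEFAULT_MIN_BIN_COUNT,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize raw iHS within genome-wide frequency bins.

    Bin mean and SD (ddof=1) are computed over the entire table — never per
    chromosome or per window.  SNPs in bins with fewer than ``min_bin_count``
    members or zero SD are dropped; the count is logged.  Returns the table
    with an ``ihs_std`` column plus per-bin statistics (``bin_index``,
    ``mean_raw``, ``sd_raw``, ``n_snps``).
    """
    if len(snps) == 0:
        raise ValueError("empty SNP table")
    raw = snps["ihs_raw"].to_numpy(dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw iHS contains non-finite values")
    bins = assign_frequency_bin(snps["daf"].to_numpy(dtype=float), n_bins)

    std = np.full(raw.shape, np.nan)
    stats_rows = []
    retained_bins = 0
    for b in range(n_bins):
        mask = bins == b
        n = int(mask.sum())
        if n == 0:
            continue
        mean = float(np.mean(raw[mask]))
        sd = float(np.std(raw[mask], ddof=1)) if n > 1 else 0.0
        stats_rows.append({"bin_index": b, "mean_raw": mean,
                           "sd_raw": sd, "n_snps": n})
        if n < min_bin_count or sd == 0.0:
            continue
        retained_bins += 1
        std[mask] = (raw[mask] - mean) / sd
    if retained_bins == 0:
        raise ValueError("all frequency bins degenerate "
                         "(too few SNPs or zero SD); cannot standardize")

    keep = np.isfinite(std)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropped %d SNPs in degenerate frequency bins",
                       n_dropped)
    out = snps.loc[keep].reset_index(drop=True).copy()
    out["ihs_std"] = std[keep]
    return out, pd.DataFrame(stats_rows)


def summarize_windows(snps: pd.DataFrame, windows: pd.DataFrame) -> pd.DataFrame:
    """Per-window mean \\|standardized iHS\\| and SNP count.

    ``windows`` needs columns gene_id, chrom, start, end; membership is
    half-open ``[start, end)``.  Windows containing zero scored SNPs are
    omitted from the result.
    """
    if "ihs_std" not in snps.columns:
        raise ValueError("SNP table lacks 'ihs_std'; run standardize_ihs first")
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in snps.groupby("chrom", sort=False):
        order = np.argsort(grp["pos"].to_numpy(), kind="stable")
        pos = grp["pos"].to_numpy()[order]
        val = np.abs(grp["ihs_std"].to_numpy(dtype=float)[order])
        by_chrom[chrom] = (pos, val)

    rows = []
    for win in windows.itertuples(index=False):
        got = by_chrom.get(win.chrom)
        if got is None:
            continue
        pos, val = got
        lo = np.searchsorted(pos, win.start, side="left")
        hi = np.searchsorted(pos, win.end, side="left")
        if hi <= lo:
            continue
        rows.append({"gene_id": win.gene_id, "chrom": win.chrom,
                     "start": win.start, "end": win.end,
                     "mean_abs_ihs": float(np.mean(val[lo:hi])),
                     "n_ihs": int(hi - lo)})
    return pd.DataFrame(rows,
                        columns=["gene_id", "chrom", "start", "end",
                                 "mean_abs_ihs", "n_ihs"])


def transform_response(mean_abs_ihs) -> np.ndarray:
    """z-score of the natural log of window mean \\|iHS\\| (the model's Y)."""
    v = np.asarray(mean_abs_ihs, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty window summary")
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise ValueError("window mean |iHS| must be positive and finite")
    logv = np.log(v)
    sd = float(np.std(logv, ddof=1)) if v.size > 1 else 0.0
    if sd == 0.0:
        raise ValueError("degenerate response: zero variance after log")
    return (logv - float(np.mean(logv))) / sd


def standardize_covariates(features: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each column to mean 0, SD 1 (ddof=1).

    Input must already be complete-case; zero-variance columns raise with
    the offending name.
    """
    mat = features.to_numpy(dtype=float)
    if not np.all(np.isfinite(mat)):
        raise ValueError("feature table contains missing values; "
                         "apply complete-case filtering first")
    out = {}
    for col in features.columns:
        v = features[col].to_numpy(dtype=float)
        sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        if sd == 0.0:
            raise ValueError(f"covariate {col!r} has zero variance")
        out[col] = (v - float(np.mean(v))) / sd
    return pd.DataFrame(out, index=features.index)
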