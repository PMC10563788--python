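"""Gene-centered windows and the genomic covariates measured inside them.

Windows of a fixed size (50, 100, 200, 500 or 1,000 kb) are centered at the
genomic center of each gene (midpoint of outermost transcription start/end).
Inside each window the module computes: recombination rate from a genetic
map (cM of the window edges by linear interpolation, searching for flanking
map points at most 50 kb from an edge; the whole window is dropped when an
edge has no genetic position), interval densities with assembly gaps
excluded from both numerator and denominator, GC content, gene counts,
distance to the nearest virus-interacting-protein (VIP) gene, per-gene
expression/PPI transforms, and optionally the fine-scale recombination rate
within 5 kb flanks of regulatory elements.

All coordinates are 0-based half-open ``[start, end)``.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

WINDOW_SIZES = (50_000, 100_000, 200_000, 500_000, 1_000_000)
EDGE_SEARCH_BP = 50_000       # max distance from a window edge to a map point
SNP_SEARCH_BP = 1_000_000     # max distance when interpolating SNP positions
REGULATORY_FLANK_BP = 5_000


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

class GeneticMap:
    """Monotone physical (bp) -> genetic (cM) lookup per chromosome."""

    def __init__(self, tables: dict[str, tuple[np.ndarray, np.ndarray]]):
        self._tables: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (pos, cm) in tables.items():
            pos = np.asarray(pos, dtype=np.int64)
            cm = np.asarray(cm, dtype=float)
            if pos.shape != cm.shape or pos.ndim != 1:
                raise ValueError(f"{chrom}: positions and cM must be equal-length 1-D arrays")
            if pos.size and np.any(np.diff(pos) <= 0):
                raise ValueError(f"{chrom}: physical positions must be strictly increasing")
            if cm.size and np.any(np.diff(cm) < 0):
                raise ValueError(f"{chrom}: genetic positions must be non-decreasing")
            self._tables[chrom] = (pos, cm)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneticMap":
        """Build from a table with columns chrom, pos, cm."""
        tables = {}
        for chrom, grp in df.groupby("chrom", sort=False):
            order = np.argsort(grp["pos"].to_numpy(), kind="stable")
            tables[chrom] = (grp["pos"].to_numpy()[order],
                             grp["cm"].to_numpy(dtype=float)[order])
        return cls(tables)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._tables)

    def points(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        return self._tables[chrom]

    def genetic_position(self, chrom: str, pos: int,
                         max_search: int = EDGE_SEARCH_BP) -> float:
        """cM at ``pos``, or NaN when it cannot be determined.

        An exact map point returns its stored cM regardless of
        ``max_search``; otherwise the two flanking points must each lie
        within ``max_search`` bp and the cM is linearly interpolated.  No
        extrapolation beyond the map's ends.
        """
        if max_search <= 0:
            raise ValueError("max_search must be positive")
        if chrom not in self._tables:
            return math.nan
        p, g = self._tables[chrom]
        if p.size == 0:
            return math.nan
        i = int(np.searchsorted(p, pos, side="left"))
        if i < p.size and p[i] == pos:
            return float(g[i])
        if i == 0 or i == p.size:
            return math.nan
        left, right = int(p[i - 1]), int(p[i])
        if pos - left > max_search or right - pos > max_search:
            return math.nan
        frac = (pos - left) / (right - left)
        return float(g[i - 1] + (g[i] - g[i - 1]) * frac)


def window_recombination_rate(gmap: GeneticMap, chrom: str, start: int,
                              end: int,
                              edge_search: int = EDGE_SEARCH_BP) -> float:
    """Window-wide rate in cM/Mb: genetic span of the edges over physical span.

    NaN when either edge has no genetic position under the ``edge_search``
    rule; callers treat NaN as missing (complete-case exclusion).
    """
    if end <= start:
        raise ValueError("window end must exceed start")
    g0 = gmap.genetic_position(chrom, start, edge_search)
    g1 = gmap.genetic_position(chrom, end, edge_search)
    if math.isnan(g0) or math.isnan(g1):
        return math.nan
    return (g1 - g0) / ((end - start) / 1e6)


def local_recombination_around_elements(gmap: GeneticMap,
                                        elements: pd.DataFrame,
                                        chrom: str, start: int, end: int,
                                        flank: int = REGULATORY_FLANK_BP,
                                        ) -> tuple[float, int]:
    """Fine-scale recombination within ``flank`` bp of regulatory elements.

    Element intervals are padded by ``flank`` on each side, merged, and
    clipped to the window; within each padded region the rates between
    consecutive map points are averaged weighted by physical span (which
    telescopes to total cM over total bp per region).  Returns
    ``(rate cM/Mb, n_points)`` where ``n_points`` counts the map data points
    used; ``(NaN, n)`` when fewer than two points fall in any region.
    """
    el = elements.loc[elements["chrom"] == chrom]
    starts = np.maximum(el["start"].to_numpy(dtype=np.int64) - flank, start)
    ends = np.minimum(el["end"].to_numpy(dtype=np.int64) + flank, end)
    keep = starts < ends
    ms, me = merge_intervals(starts[keep], ends[keep])
    if ms.size == 0 or chrom not in gmap.chromosomes:
        return math.nan, 0
    pos, cm = gmap.points(chrom)
    total_dg = 0.0
    total_dp = 0
    n_points = 0
    for s, e in zip(ms, me):
        lo = int(np.searchsorted(pos, s, side="left"))
        hi = int(np.searchsorted(pos, e, side="left"))
        n_points += hi - lo
        if hi - lo >= 2:
            total_dg += float(cm[hi - 1] - cm[lo])
            total_dp += int(pos[hi - 1] - pos[lo])
    if n_points == 0 or total_dp == 0:
        return math.nan, n_points
    return total_dg / (total_dp / 1e6), n_points


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

def gene_center_windows(genes: pd.DataFrame, size: int,
                        chrom_lengths: dict[str, int] | None = None,
                        ) -> pd.DataFrame:
    """Fixed-size windows centered at each gene's genomic center.

    Center is ``floor((start + end) / 2)``; the window is
    ``[center - size/2, center + size/2)``.  Windows may overlap freely.
    When ``chrom_lengths`` is given, windows running past a chromosome end
    are clipped and flagged ``truncated``; a gene on a chromosome absent
    from ``chrom_lengths`` raises.  Without lengths only the zero edge can
    be checked.
    """
    if size <= 0 or size % 2:
        raise ValueError("window size must be positive and even")
    half = size // 2
    rows = []
    for g in genes.itertuples(index=False):
        center = (int(g.start) + int(g.end)) // 2
        ws, we = center - half, center + half
        truncated = ws < 0
        ws = max(ws, 0)
        if chrom_lengths is not None:
            if g.chrom not in chrom_lengths:
                raise ValueError(
                    f"chromosome length unknown for {g.chrom!r}; cannot "
                    f"check window truncation")
            L = chrom_lengths[g.chrom]
            truncated = truncated or we > L
            we = min(we, L)
        rows.append({"gene_id": g.gene_id, "chrom": g.chrom,
                     "start": ws, "end": we, "truncated": truncated})
    return pd.DataFrame(rows,
                        columns=["gene_id", "chrom", "start", "end",
                                 "truncated"])


def select_non_overlapping(windows: pd.DataFrame) -> pd.DataFrame:
    """Greedy left-to-right selection of mutually non-overlapping windows."""
    kept_idx = []
    for chrom, grp in windows.groupby("chrom", sort=False):
        grp = grp.sort_values(["start", "end"], kind="stable")
        last_end = -1
        for idx, row in grp.iterrows():
            if row["start"] >= last_end:
                kept_idx.append(idx)
                last_end = row["end"]
    return windows.loc[sorted(kept_idx)]


# ---------------------------------------------------------------------------
# Interval arithmetic (sorted integer intervals, half-open)
# ---------------------------------------------------------------------------

def merge_intervals(starts, ends) -> tuple[np.ndarray, np.ndarray]:
    """Merge possibly overlapping/abutting half-open intervals."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    if np.any(ends <= starts):
        raise ValueError("interval end must exceed start")
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [int(starts[0])], [int(ends[0])]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], int(e))
        else:
            out_s.append(int(s))
            out_e.append(int(e))
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def _clip(starts: np.ndarray, ends: np.ndarray, lo: int, hi: int):
    s = np.maximum(starts, lo)
    e = np.minimum(ends, hi)
    keep = s < e
    return s[keep], e[keep]


def _subtract(a_s, a_e, b_s, b_e):
    """Set difference A \\ B of merged interval lists."""
    out_s, out_e = [], []
    j = 0
    for s, e in zip(a_s, a_e):
        cur = int(s)
        while j < len(b_s) and b_e[j] <= cur:
            j += 1
        jj = j
        while jj < len(b_s) and b_s[jj] < e:
            if b_s[jj] > cur:
                out_s.append(cur)
                out_e.append(int(b_s[jj]))
            cur = max(cur, int(b_e[jj]))
            jj += 1
        if cur < e:
            out_s.append(cur)
            out_e.append(int(e))
    return (np.asarray(out_s, dtype=np.int64),
            np.asarray(out_e, dtype=np.int64))


def interval_density(intervals: pd.DataFrame, chrom: str, start: int,
                     end: int, gaps: pd.DataFrame | None = None) -> float:
    """Fraction of non-gap window bases covered by the (merged) intervals.

    ``(intervals ∩ window) \\ gaps`` over ``window length − gap bases``;
    NaN when the window is entirely gap (zero denominator).
    """
    if end <= start:
        raise ValueError("window end must exceed start")
    sel = intervals.loc[intervals["chrom"] == chrom]
    iv_s, iv_e = merge_intervals(sel["start"].to_numpy(),
                                 sel["end"].to_numpy())
    iv_s, iv_e = _clip(iv_s, iv_e, start, end)
    if gaps is not None and len(gaps):
        gsel = gaps.loc[gaps["chrom"] == chrom]
        gp_s, gp_e = merge_intervals(gsel["start"].to_numpy(),
                                     gsel["end"].to_numpy())
        gp_s, gp_e = _clip(gp_s, gp_e, start, end)
    else:
        gp_s = gp_e = np.empty(0, dtype=np.int64)
    gap_bases = int((gp_e - gp_s).sum())
    denom = (end - start) - gap_bases
    if denom <= 0:
        return math.nan
    iv_s, iv_e = _subtract(iv_s, iv_e, gp_s, gp_e)
    return int((iv_e - iv_s).sum()) / denom


def score_threshold_for_fraction(intervals: pd.DataFrame, genome_length: int,
                                 target_fraction: float,
                                 ) -> tuple[float, float]:
    """Score cutoff keeping at most ``target_fraction`` of the genome.

    Walks unique scores from highest to lowest, accumulating the bases of
    each score class (ties kept together), and returns the smallest score
    ``t`` such that intervals scoring ``>= t`` cover at most
    ``target_fraction * genome_length`` bases, together with the achieved
    fraction.  Mirrors the conserved-element (4.17% of the genome) and
    regulatory (10%) calibrations.  Intervals are assumed non-overlapping,
    as in clustered annotation tracks.
    """
    if not 0 < target_fraction < 1:
        raise ValueError("target_fraction must be in (0, 1)")
    if len(intervals) == 0:
        raise ValueError("empty interval set")
    lengths = (intervals["end"] - intervals["start"]).to_numpy(dtype=np.int64)
    scores = intervals["score"].to_numpy(dtype=float)
    budget = target_fraction * genome_length

    per_score = pd.Series(lengths).groupby(pd.Series(scores)).sum()
    per_score = per_score.sort_index(ascending=False)
    cum = 0
    threshold = None
    for score, total in per_score.items():
        if cum + total > budget:
            break
        cum += int(total)
        threshold = float(score)
    if threshold is None:
        top = float(per_score.index[0])
        threshold = float(np.nextafter(top, np.inf))
        warnings.warn(
            f"even the top score class ({top}) exceeds the target fraction "
            f"{target_fraction}; threshold set above it (empty selection)",
            stacklevel=2)
    achieved = cum / genome_length
    logger.info("score threshold %.6g keeps %.4f%% of the genome "
                "(target %.4f%%)", threshold, 100 * achieved,
                100 * target_fraction)
    return threshold, achieved


def apply_score_threshold(intervals: pd.DataFrame,
                          threshold: float) -> pd.DataFrame:
    """Intervals with score >= threshold."""
    return intervals.loc[intervals["score"] >= threshold].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Sequence and per-gene covariates
# ---------------------------------------------------------------------------

def gc_content(sequence: str) -> float:
    """(G+C)/(A+C+G+T); ambiguous bases are excluded from the denominator.

    NaN for an all-N (or empty) stretch.
    """
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        return math.nan
    return gc / (gc + at)


def _fetch_sequence(source, chrom: str, start: int, end: int) -> str:
    """Window slice from a dict of strings or a pyfaidx.Fasta."""
    return str(source[chrom][start:end])


def distance_to_nearest_vip(gene, vips: pd.DataFrame,
                            mode: str = "edge") -> float:
    """bp to the closest same-chromosome VIP gene.

    ``edge`` mode (default) measures the edge-to-edge gap, 0 on any overlap
    (a VIP gene is at distance 0 from itself); ``center`` measures
    center-to-center.  NaN when the chromosome carries no VIP.
    """
    sel = vips.loc[vips["chrom"] == gene.chrom]
    if len(sel) == 0:
        return math.nan
    gs, ge = int(gene.start), int(gene.end)
    if mode == "edge":
        vs = sel["start"].to_numpy(dtype=np.int64)
        ve = sel["end"].to_numpy(dtype=np.int64)
        gap = np.maximum(vs - ge, 0) + np.maximum(gs - ve, 0)
        return float(gap.min())
    if mode == "center":
        gc_pos = (gs + ge) // 2
        centers = ((sel["start"] + sel["end"]) // 2).to_numpy(dtype=np.int64)
        return float(np.abs(centers - gc_pos).min())
    raise ValueError(f"unknown VIP distance mode {mode!r}")


def gene_number(genes: pd.DataFrame, chrom: str, start: int, end: int) -> int:
    """Genes with >= 1 bp intersection with the window (self included)."""
    sel = genes.loc[genes["chrom"] == chrom]
    return int(((sel["start"] < end) & (sel["end"] > start)).sum())


def log2_expression(tpm) -> np.ndarray | float:
    """log2(TPM + 1); the pseudocount keeps zero-expression genes defined."""
    arr = np.asarray(tpm, dtype=float)
    if np.any(arr < 0):
        raise ValueError("TPM must be nonnegative")
    out = np.log2(arr + 1.0)
    return float(out) if np.isscalar(tpm) else out


def log2_ppi(count) -> np.ndarray | float:
    """log2(PPI count + 1)."""
    arr = np.asarray(count, dtype=float)
    if np.any(arr < 0):
        raise ValueError("PPI counts must be nonnegative")
    out = np.log2(arr + 1.0)
    return float(out) if np.isscalar(count) else out


# ---------------------------------------------------------------------------
# Feature table assembly
# ---------------------------------------------------------------------------

@dataclass
class FeatureAssemblyResult:
    features: pd.DataFrame
    exclusions: dict[str, int]
    n_input_windows: int


def assemble_feature_table(genes: pd.DataFrame, window_size: int,
                           gmap: GeneticMap,
                           density_tracks: dict[str, pd.DataFrame],
                           gaps: pd.DataFrame | None,
                           sequences,
                           snp_scores: pd.DataFrame,
                           chrom_lengths: dict[str, int] | None = None,
                           edge_search: int = EDGE_SEARCH_BP,
                           expression_cols: list[str] | None = None,
                           non_overlapping: bool = False,
                           local_recomb_elements: pd.DataFrame | None = None,
                           local_recomb_flank: int = REGULATORY_FLANK_BP,
                           ) -> FeatureAssemblyResult:
    """One row of covariates per gene window, complete-case filtered.

    ``genes`` needs gene_id, chrom, start, end, is_vip, ppi, plus TPM
    columns (``expression_cols``, default: every column starting ``tpm_``).
    ``density_tracks`` maps a track name to already-thresholded intervals;
    each contributes a ``<name>_density`` column.  ``snp_scores`` must carry
    ``ihs_std``.  Rows with any missing covariate are dropped; counts per
    reason are returned (a row may tally several reasons).
    """
    from . import ihs as _ihs

    missing_chroms = sorted(set(genes["chrom"]) - set(gmap.chromosomes))
    if missing_chroms:
        raise ValueError(
            "chromosome names absent from the genetic map: "
            + ", ".join(map(str, missing_chroms)))

    if expression_cols is None:
        expression_cols = [c for c in genes.columns if c.startswith("tpm_")]

    windows = gene_center_windows(genes, window_size, chrom_lengths)
    if non_overlapping:
        windows = select_non_overlapping(windows)
    windows = windows.reset_index(drop=True)
    gene_rows = genes.set_index("gene_id")
    vips = genes.loc[genes["is_vip"].astype(bool)]
    summaries = _ihs.summarize_windows(snp_scores, windows)
    summaries = summaries.set_index("gene_id")

    rows = []
    exclusions: dict[str, int] = {}

    def _flag(reason: str):
        exclusions[reason] = exclusions.get(reason, 0) + 1

    for win in windows.itertuples(index=False):
        gene = gene_rows.loc[win.gene_id]
        row: dict[str, object] = {
            "gene_id": win.gene_id, "chrom": win.chrom,
            "win_start": int(win.start), "win_end": int(win.end),
            "truncated": bool(win.truncated),
            "gene_length": int(gene["end"] - gene["start"]),
            "gene_number": gene_number(genes, win.chrom, win.start, win.end),
        }
        ok = True

        rate = window_recombination_rate(gmap, win.chrom, win.start, win.end,
                                         edge_search)
        row["recomb_rate"] = rate
        if math.isnan(rate):
            _flag("no_recombination")
            ok = False

        for name, track in density_tracks.items():
            d = interval_density(track, win.chrom, win.start, win.end, gaps)
            row[f"{name}_density"] = d
            if math.isnan(d):
                _flag(f"no_density_{name}")
                ok = False

        gc = gc_content(_fetch_sequence(sequences, win.chrom,
                                        win.start, win.end))
        row["gc_content"] = gc
        if math.isnan(gc):
            _flag("no_gc")
            ok = False

        for col in expression_cols:
            row[f"expr_{col.removeprefix('tpm_')}"] = log2_expression(
                float(gene[col]))
        row["log2_ppi"] = log2_ppi(int(gene["ppi"]))

        class _G:
            chrom, start, end = win.chrom, gene["start"], gene["end"]
        vd = distance_to_nearest_vip(_G, vips)
        row["vip_distance"] = vd
        if math.isnan(vd):
            _flag("no_vip")
            ok = False

        if win.gene_id in summaries.index:
            summ = summaries.loc[win.gene_id]
            row["mean_abs_ihs"] = float(summ["mean_abs_ihs"])
            row["n_ihs"] = int(summ["n_ihs"])
        else:
            row["mean_abs_ihs"] = math.nan
            row["n_ihs"] = 0
            _flag("no_snps")
            ok = False

        if local_recomb_elements is not None:
            lr, npts = local_recombination_around_elements(
                gmap, local_recomb_elements, win.chrom, win.start, win.end,
                local_recomb_flank)
            row["local_recomb"] = lr
            row["local_recomb_n"] = npts
            if math.isnan(lr):
                _flag("no_local_recomb")
                ok = False

        if ok:
            rows.append(row)

    features = pd.DataFrame(rows)
    n_excluded = len(windows) - len(features)
    if n_excluded:
        logger.info("excluded %d of %d windows (reasons: %s)", n_excluded,
                    len(windows), exclusions)
    return FeatureAssemblyResult(features=features, exclusions=exclusions,
                                 n_input_windows=len(windows))
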