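"""Synthetic data: model-true MDR datasets and a toy genome with known truth.

Two generators back the test surface without any external downloads:

* :func:`simulate_mdr_dataset` samples the exact generative process the
  mixture density regression assumes — covariates, logistic mixing
  probability, Bernoulli component labels, Gaussian response — so parameter
  recovery and test calibration can be checked against known truth.

* :func:`simulate_toy_genome` builds a 2-chromosome, 5 Mb-each genome
  (piecewise-uniform genetic map, genes, scored annotation tracks, assembly
  gaps, sequence, binned SNP scores) together with a companion feature table
  computed *by construction* with independent brute-force code, against
  which the window/feature pipeline can be compared bit-exactly.  Gene
  centers and map points sit on a 5 kb grid so every window edge of the five
  standard sizes coincides with a map point.

All randomness flows from a single integer seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special

from .model import MDRParameters
from .windows import GeneticMap

TOY_CHROM_LENGTHS = {"chr1": 5_000_000, "chr2": 5_000_000}
TOY_MAP_SPACING = 5_000
TOY_WINDOW_SIZE = 100_000
TOY_TRACK_FRACTIONS = {"conserved": 0.0417, "dnase": 0.10, "chip": 0.10}


# ---------------------------------------------------------------------------
# Model-true MDR datasets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorConfig:
    """Sampling configuration for :func:`simulate_mdr_dataset`."""

    n_windows: int
    true_params: MDRParameters
    seed: int = 0
    correlation: np.ndarray | None = None  # optional covariate correlation
    covariate_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_windows <= 0:
            raise ValueError("n_windows must be positive")
        if self.correlation is not None:
            corr = np.asarray(self.correlation, dtype=float)
            k = self.true_params.n_covariates
            if corr.shape != (k, k):
                raise ValueError("correlation matrix must be k x k")
            if not np.allclose(corr, corr.T):
                raise ValueError("correlation matrix must be symmetric")
            if np.linalg.eigvalsh(corr).min() < -1e-10:
                raise ValueError("correlation matrix must be positive "
                                 "semi-definite")
            object.__setattr__(self, "correlation", corr)


def study_parameters(k: int = 17) -> MDRParameters:
    """Canonical ground-truth parameter set for simulation studies.

    Defaults emulate the fitted regime on real scans: baseline
    enriched-component probability around 0.3, clearly separated components
    on the z-scored response scale, and slopes spanning strong to null
    effects of both signs.
    """
    pattern = np.array([0.4, -0.4, 0.3, -0.3, 0.25, -0.25, 0.2, -0.2,
                        0.15, -0.15, 0.1, -0.1, 0.05, -0.05, 0.0, 0.0, 0.35])
    reps = int(np.ceil(k / pattern.size))
    slopes = np.tile(pattern, reps)[:k]
    return MDRParameters(intercept=float(special.logit(0.3)), slopes=slopes,
                         mu0=-0.39, sigma0=0.85, mu1=0.90, sigma1=0.95)


def simulate_mdr_dataset(config: GeneratorConfig,
                         ) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Sample (X, Y, labels) from the MDR generative model.

    Per window: x ~ N(0, I) (or the requested correlation), label ~
    Bernoulli(sigmoid(a + b.x)), Y ~ N(mu1, sigma1) for label 1 else
    N(mu0, sigma0).  Bit-reproducible for a fixed seed.
    """
    params = config.true_params
    k = params.n_covariates
    rng = np.random.default_rng(config.seed)
    X = rng.standard_normal((config.n_windows, k))
    if config.correlation is not None:
        # Gaussian copula with standard-normal marginals
        L = np.linalg.cholesky(
            config.correlation + 1e-12 * np.eye(k))
        X = X @ L.T
    eta = params.intercept + X @ params.slopes
    p = special.expit(eta)
    labels = (rng.random(config.n_windows) < p).astype(np.int8)
    y = np.where(labels == 1,
                 rng.normal(params.mu1, params.sigma1, config.n_windows),
                 rng.normal(params.mu0, params.sigma0, config.n_windows))
    names = (list(config.covariate_names) if config.covariate_names
             else [f"x{i + 1}" for i in range(k)])
    return pd.DataFrame(X, columns=names), y, labels


def simulate_null_covariate(X: pd.DataFrame, seed: int,
                            name: str = "null_noise") -> pd.DataFrame:
    """Append one standardized, independent standard-normal column."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(len(X))
    z = (z - z.mean()) / z.std(ddof=1)
    out = X.copy()
    out[name] = z
    return out


# ---------------------------------------------------------------------------
# Toy genome
# ---------------------------------------------------------------------------

@dataclass
class ToyGenome:
    """In-memory toy genome plus its construction-time ground truth."""

    seed: int
    window_size: int
    chrom_lengths: dict[str, int]
    map_frame: pd.DataFrame                 # chrom, pos, cm
    gmap: GeneticMap
    genes: pd.DataFrame                     # gene_id, chrom, start, end, ...
    scored_tracks: dict[str, pd.DataFrame]  # raw, with score column
    density_tracks: dict[str, pd.DataFrame]  # thresholded, ready for density
    track_thresholds: dict[str, float]
    gaps: pd.DataFrame
    sequences: dict[str, str]
    snps: pd.DataFrame                      # chrom, pos, daf, ihs_raw
    ground_truth: pd.DataFrame              # expected feature table


def _toy_map(rng, chrom_lengths, spacing):
    """Piecewise-uniform map: a constant cM/Mb rate per 1 Mb block."""
    frames = []
    tables = {}
    rate_choices = np.array([0.5, 1.0, 2.0, 3.0, 4.0])
    for chrom, length in chrom_lengths.items():
        pos = np.arange(0, length + spacing, spacing, dtype=np.int64)
        block_rates = rng.choice(rate_choices, size=length // 1_000_000)
        rates = block_rates[np.minimum(pos[:-1] // 1_000_000,
                                       block_rates.size - 1)]
        increments = rates * (spacing / 1e6)
        cm = np.concatenate([[0.0], np.cumsum(increments)])
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos, "cm": cm}))
        tables[chrom] = (pos, cm)
    return pd.concat(frames, ignore_index=True), tables


def _toy_genes(rng, chrom_lengths, spacing):
    rows = []
    gid = 0
    for chrom, length in chrom_lengths.items():
        lo, hi = 600_000 // spacing, (length - 600_000) // spacing
        centers = np.sort(rng.choice(np.arange(lo, hi) * spacing, size=25,
                                     replace=False))
        for c in centers:
            half = int(rng.integers(1_000, 25_000))
            gid += 1
            rows.append({"gene_id": f"g{gid:03d}", "chrom": chrom,
                         "start": int(c - half), "end": int(c + half)})
    genes = pd.DataFrame(rows)
    n = len(genes)
    genes["is_vip"] = False
    # at least a few VIP genes per chromosome so distances are always defined
    per_chrom = n // len(chrom_lengths)
    vip_idx = np.concatenate([
        off + rng.choice(per_chrom, size=4, replace=False)
        for off in range(0, n, per_chrom)])
    genes.loc[vip_idx, "is_vip"] = True
    genes["ppi"] = rng.integers(0, 200, size=n)
    for col in ("tpm_mean", "tpm_testis", "tpm_immune"):
        tpm = rng.gamma(shape=2.0, scale=10.0, size=n)
        tpm[rng.random(n) < 0.1] = 0.0  # silent genes
        genes[col] = tpm
    return genes


def _toy_intervals(rng, chrom_lengths, mean_gap, min_len, max_len,
                   scored: bool):
    rows = []
    for chrom, length in chrom_lengths.items():
        pos = int(rng.integers(0, mean_gap))
        while pos < length - max_len:
            ilen = int(rng.integers(min_len, max_len))
            row = {"chrom": chrom, "start": pos, "end": pos + ilen}
            if scored:
                row["score"] = int(rng.integers(1, 1001))
            rows.append(row)
            pos += ilen + int(rng.integers(mean_gap // 2, 2 * mean_gap))
    return pd.DataFrame(rows)


def _brute_threshold(track: pd.DataFrame, genome_length: int,
                     fraction: float) -> float:
    """Independent sort-and-accumulate score cutoff (construction-time)."""
    lengths = (track["end"] - track["start"]).to_numpy()
    scores = track["score"].to_numpy(dtype=float)
    budget = fraction * genome_length
    best = None
    covered = 0
    for s in np.unique(scores)[::-1]:
        total = int(lengths[scores == s].sum())
        if covered + total > budget:
            break
        covered += total
        best = float(s)
    if best is None:
        best = float(np.nextafter(scores.max(), np.inf))
    return best


def _toy_sequences(rng, chrom_lengths, gaps):
    seqs = {}
    bases = np.frombuffer(b"ACGT", dtype="S1")
    for chrom, length in chrom_lengths.items():
        arr = rng.choice(bases, size=length)
        for g in gaps.loc[gaps["chrom"] == chrom].itertuples(index=False):
            arr[g.start:g.end] = b"N"
        seqs[chrom] = arr.tobytes().decode("ascii")
    return seqs


def _toy_snps(rng, chrom_lengths):
    frames = []
    for chrom, length in chrom_lengths.items():
        pos = np.sort(rng.choice(length, size=6_000, replace=False))
        daf = rng.uniform(0.02, 0.98, size=pos.size)
        # raw iHS drifts with frequency so the bin standardization matters
        raw = rng.normal(loc=0.8 * (daf - 0.5),
                         scale=0.6 + 0.4 * daf)
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos,
                                    "daf": daf, "ihs_raw": raw}))
    return pd.concat(frames, ignore_index=True)


# --- independent brute-force feature computation (the construction oracle) --

def _mask_density(track, gaps, chrom, ws, we):
    cover = np.zeros(we - ws, dtype=bool)
    for iv in track.loc[track["chrom"] == chrom].itertuples(index=False):
        s, e = max(iv.start, ws), min(iv.end, we)
        if s < e:
            cover[s - ws:e - ws] = True
    gap_mask = np.zeros(we - ws, dtype=bool)
    for iv in gaps.loc[gaps["chrom"] == chrom].itertuples(index=False):
        s, e = max(iv.start, ws), min(iv.end, we)
        if s < e:
            gap_mask[s - ws:e - ws] = True
    denom = int((~gap_mask).sum())
    if denom == 0:
        return math.nan
    return int((cover & ~gap_mask).sum()) / denom


def _brute_standardize(snps: pd.DataFrame, min_maf=0.05, n_bins=50,
                       min_bin_count=2) -> pd.DataFrame:
    daf = snps["daf"].to_numpy()
    keep = np.minimum(daf, 1.0 - daf) > min_maf
    sub = snps.loc[keep].reset_index(drop=True)
    f = sub["daf"].to_numpy()
    raw = sub["ihs_raw"].to_numpy()
    b = np.minimum(np.floor(f * n_bins).astype(int), n_bins - 1)
    std = np.full(raw.shape, np.nan)
    for k in range(n_bins):
        m = b == k
        n = int(m.sum())
        if n < min_bin_count:
            continue
        sd = float(np.std(raw[m], ddof=1))
        if sd == 0.0:
            continue
        std[m] = (raw[m] - float(np.mean(raw[m]))) / sd
    out = sub.loc[np.isfinite(std)].reset_index(drop=True).copy()
    out["ihs_std"] = std[np.isfinite(std)]
    return out


def _ground_truth(genes, window_size, map_tables, density_tracks, gaps,
                  sequences, snps_std) -> pd.DataFrame:
    cm_at = {chrom: dict(zip(pos.tolist(), cm.tolist()))
             for chrom, (pos, cm) in map_tables.items()}
    vips = genes.loc[genes["is_vip"]]
    half = window_size // 2
    rows = []
    for g in genes.itertuples(index=False):
        center = (g.start + g.end) // 2
        ws, we = center - half, center + half
        row = {"gene_id": g.gene_id, "chrom": g.chrom,
               "win_start": ws, "win_end": we, "truncated": False,
               "gene_length": g.end - g.start}

        count = 0
        for o in genes.loc[genes["chrom"] == g.chrom].itertuples(index=False):
            if o.start < we and o.end > ws:
                count += 1
        row["gene_number"] = count

        g0, g1 = cm_at[g.chrom][ws], cm_at[g.chrom][we]
        row["recomb_rate"] = (g1 - g0) / ((we - ws) / 1e6)

        for name, track in density_tracks.items():
            row[f"{name}_density"] = _mask_density(track, gaps, g.chrom,
                                                   ws, we)

        seq = sequences[g.chrom][ws:we]
        gc = seq.count("G") + seq.count("C")
        at = seq.count("A") + seq.count("T")
        row["gc_content"] = gc / (gc + at) if gc + at else math.nan

        for col in ("tpm_mean", "tpm_testis", "tpm_immune"):
            row[f"expr_{col.removeprefix('tpm_')}"] = float(
                np.log2(getattr(g, col) + 1.0))
        row["log2_ppi"] = float(np.log2(g.ppi + 1.0))

        best = math.inf
        for v in vips.itertuples(index=False):
            if v.chrom != g.chrom:
                continue
            if v.start < g.end and v.end > g.start:
                d = 0
            elif v.start >= g.end:
                d = v.start - g.end
            else:
                d = g.start - v.end
            best = min(best, d)
        row["vip_distance"] = float(best) if math.isfinite(best) else math.nan

        sub = snps_std.loc[snps_std["chrom"] == g.chrom]
        m = (sub["pos"].to_numpy() >= ws) & (sub["pos"].to_numpy() < we)
        vals = np.abs(sub["ihs_std"].to_numpy()[m])
        if vals.size:
            row["mean_abs_ihs"] = float(np.mean(vals))
            row["n_ihs"] = int(vals.size)
        else:
            row["mean_abs_ihs"] = math.nan
            row["n_ihs"] = 0
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_toy_genome(seed: int = 0,
                        window_size: int = TOY_WINDOW_SIZE) -> ToyGenome:
    """Generate the toy genome and its by-construction expected features.

    The expected feature table is computed with independent brute-force code
    (per-base coverage masks, dictionary cM lookup, exhaustive loops), never
    with the pipeline under test; on this fixture the pipeline must
    reproduce it bit-exactly.
    """
    if window_size % (2 * TOY_MAP_SPACING):
        raise ValueError("toy window size must be a multiple of 10 kb so "
                         "window edges fall on map points")
    rng = np.random.default_rng(seed)
    map_frame, map_tables = _toy_map(rng, TOY_CHROM_LENGTHS, TOY_MAP_SPACING)
    genes = _toy_genes(rng, TOY_CHROM_LENGTHS, TOY_MAP_SPACING)
    coding = _toy_intervals(rng, TOY_CHROM_LENGTHS, 25_000, 200, 3_000,
                            scored=False)
    scored_tracks = {
        "conserved": _toy_intervals(rng, TOY_CHROM_LENGTHS, 20_000, 100,
                                    1_500, scored=True),
        "dnase": _toy_intervals(rng, TOY_CHROM_LENGTHS, 15_000, 150, 2_000,
                                scored=True),
        "chip": _toy_intervals(rng, TOY_CHROM_LENGTHS, 15_000, 150, 2_000,
                               scored=True),
    }
    genome_length = sum(TOY_CHROM_LENGTHS.values())
    thresholds = {}
    density_tracks = {"coding": coding}
    for name, frac in TOY_TRACK_FRACTIONS.items():
        t = _brute_threshold(scored_tracks[name], genome_length, frac)
        thresholds[name] = t
        kept = scored_tracks[name]
        density_tracks[name] = kept.loc[kept["score"] >= t].reset_index(
            drop=True)

    gaps_rows = []
    for chrom in TOY_CHROM_LENGTHS:
        for _ in range(3):
            s = int(rng.integers(700_000, 4_200_000))
            gaps_rows.append({"chrom": chrom, "start": s,
                              "end": s + int(rng.integers(10_000, 40_000))})
    gaps = pd.DataFrame(gaps_rows)

    sequences = _toy_sequences(rng, TOY_CHROM_LENGTHS, gaps)
    snps = _toy_snps(rng, TOY_CHROM_LENGTHS)
    snps_std = _brute_standardize(snps)
    truth = _ground_truth(genes, window_size, map_tables, density_tracks,
                          gaps, sequences, snps_std)

    return ToyGenome(seed=seed, window_size=window_size,
                     chrom_lengths=dict(TOY_CHROM_LENGTHS),
                     map_frame=map_frame, gmap=GeneticMap(map_tables),
                     genes=genes, scored_tracks=scored_tracks,
                     density_tracks=density_tracks,
                     track_thresholds=thresholds, gaps=gaps,
                     sequences=sequences, snps=snps, ground_truth=truth)


def write_toy_genome(toy: ToyGenome, out_dir) -> dict[str, Path]:
    """Write the toy genome in the dialects the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["map"] = out / "genetic_map.tsv"
    toy.map_frame.to_csv(paths["map"], sep="\t", index=False)

    paths["genes"] = out / "genes.tsv"
    toy.genes.to_csv(paths["genes"], sep="\t", index=False)

    paths["coding"] = out / "coding.bed"
    toy.density_tracks["coding"].to_csv(paths["coding"], sep="\t",
                                        index=False, header=False)
    for name, track in toy.scored_tracks.items():
        paths[name] = out / f"{name}.bed"
        bed = track.copy()
        bed.insert(3, "name", [f"{name}{i}" for i in range(len(bed))])
        bed.to_csv(paths[name], sep="\t", index=False, header=False)

    paths["gaps"] = out / "gaps.bed"
    toy.gaps.to_csv(paths["gaps"], sep="\t", index=False, header=False)

    paths["fasta"] = out / "genome.fa"
    with open(paths["fasta"], "w") as fh:
        for chrom, seq in toy.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")

    paths["snps"] = out / "ihs_scores.tsv"
    toy.snps.to_csv(paths["snps"], sep="\t", index=False)

    paths["ground_truth"] = out / "ground_truth_features.tsv"
    toy.ground_truth.to_csv(paths["ground_truth"], sep="\t", index=False)

    paths["manifest"] = out / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump({"seed": toy.seed, "window_size": toy.window_size,
                   "chrom_lengths": toy.chrom_lengths,
                   "track_thresholds": toy.track_thresholds,
                   "n_genes": len(toy.genes), "n_snps": len(toy.snps)},
                  fh, indent=2)
    return paths
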