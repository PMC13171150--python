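"""Diversity and differentiation statistics in genomic windows.

Estimators (all missingness-aware, computed from observed allele copies):

* per-site nucleotide diversity (pi) within a population:
  ``2 * n_alt * n_ref / (n * (n - 1))`` with ``n`` the non-missing allele
  copies at the site — the unbiased pairwise-difference estimator;
* per-site absolute divergence ``d_XY = p1(1-p2) + p2(1-p1)``;
* Hudson-style F_ST per window as a ratio of sums,
  ``(sum d_XY - sum pi_within_bar) / sum d_XY`` with ``pi_within_bar``
  the mean of the two within-population per-site pi values.

Window statistics follow the fixed-coordinate convention of windowed
popgen scripts: windows tile each chromosome from position 0 in ``step``
bp increments and a window is reported only if it holds at least
``min_sites`` genotyped sites (study settings: 20 kb / 20 kb / 100 sites,
or the 100 kb variant for the domestication scan).

LD decay is the mean genotypic r^2 of SNP pairs binned by physical
distance, capped at 50 kb as in PopLDdecay-style scans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import merge
from .vcfio import GenotypeMatrix, PopulationMap

# ---------------------------------------------------------------------------
# per-individual heterozygosity
# ---------------------------------------------------------------------------


def individual_heterozygosity(gm: GenotypeMatrix, sample: str) -> float:
    """Fraction of heterozygous calls among this sample's non-missing
    genotypes; NaN if the sample has no calls."""
    row = gm.dosage[gm.sample_index(sample)]
    called = row >= 0
    n = int(called.sum())
    if n == 0:
        return float("nan")
    return float((row == 1).sum() / n)


def population_heterozygosity(
    gm: GenotypeMatrix, popmap: PopulationMap
) -> pd.DataFrame:
    """Mean per-individual heterozygosity for every population."""
    rows = []
    for pop in popmap.populations():
        hets = [individual_heterozygosity(gm, s) for s in popmap.members(pop)]
        rows.append((pop, len(hets), float(np.nanmean(hets))))
    return pd.DataFrame(rows, columns=["population", "n_samples", "mean_heterozygosity"])


def percent_reduction(reduced: float, reference: float) -> int:
    """Percent loss of ``reduced`` relative to ``reference``, rounded to
    the nearest integer (e.g. captive vs wild heterozygosity)."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return int(round(100.0 * (reference - reduced) / reference))


# ---------------------------------------------------------------------------
# allele counts and window statistics
# ---------------------------------------------------------------------------


def _pop_counts(
    gm: GenotypeMatrix, popmap: PopulationMap
) -> Tuple[List[str], Dict[str, np.ndarray], Dict[str, np.ndarray]]:
    """Per-population alt-copy counts and total non-missing copies per site."""
    popmap.validate_against(gm)
    pops = popmap.populations()
    alt: Dict[str, np.ndarray] = {}
    n: Dict[str, np.ndarray] = {}
    for pop in pops:
        rows = [gm.sample_index(s) for s in popmap.members(pop)]
        d = gm.dosage[rows]
        called = d >= 0
        alt[pop] = np.where(called, d, 0).sum(axis=0).astype(float)
        n[pop] = 2.0 * called.sum(axis=0)
    return pops, alt, n


def _site_pi(alt: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Unbiased per-site heterozygosity 2*nA*na/(n(n-1)); NaN where n < 2."""
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * alt * (n - alt) / (n * (n - 1.0))
    pi[n < 2] = np.nan
    return pi


@dataclass
class WindowStat:
    chrom: str
    start: int  # 0-based half-open window bounds
    end: int
    n_sites: int
    pi: Dict[str, float]
    dxy: Dict[Tuple[str, str], float]
    fst: Dict[Tuple[str, str], float]


def window_stats(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    window_bp: int = 20_000,
    step_bp: int = 20_000,
    min_sites: int = 100,
    populations: Optional[Sequence[str]] = None,
) -> List[WindowStat]:
    """Windowed pi / d_XY / F_ST for all populations (or a subset).

    A site contributes to a population's pi when that population has >= 2
    observed allele copies there, and to a pair's d_XY/F_ST when both do.
    Pair statistics are NaN in windows where one population is entirely
    missing. Windows with fewer than ``min_sites`` genotyped sites are
    omitted.
    """
    pops_all, alt, n = _pop_counts(gm, popmap)
    pops = list(populations) if populations is not None else pops_all
    chrom_arr = gm.sites["chrom"].to_numpy()
    pos_arr = gm.sites["pos"].to_numpy()

    site_pi = {p: _site_pi(alt[p], n[p]) for p in pops}
    freq = {}
    for p in pops:
        with np.errstate(invalid="ignore", divide="ignore"):
            f = alt[p] / n[p]
        f[n[p] == 0] = np.nan
        freq[p] = f

    out: List[WindowStat] = []
    any_called = (gm.dosage >= 0).any(axis=0)
    for chrom in dict.fromkeys(chrom_arr):
        on = chrom_arr == chrom
        pos = pos_arr[on]
        idx = np.flatnonzero(on)
        max_pos = int(pos.max())
        start = 0
        while start < max_pos:
            end = start + window_bp
            in_win = (pos > start) & (pos <= end)  # 1-based pos in (start, end]
            w = idx[in_win]
            n_sites = int(any_called[w].sum())
            if n_sites >= min_sites:
                pi_w = {
                    p: float(np.nanmean(site_pi[p][w]))
                    if np.any(~np.isnan(site_pi[p][w]))
                    else float("nan")
                    for p in pops
                }
                dxy_w: Dict[Tuple[str, str], float] = {}
                fst_w: Dict[Tuple[str, str], float] = {}
                for p1, p2 in combinations(pops, 2):
                    ok = (n[p1][w] >= 2) & (n[p2][w] >= 2)
                    if not ok.any():
                        dxy_w[(p1, p2)] = float("nan")
                        fst_w[(p1, p2)] = float("nan")
                        continue
                    f1, f2 = freq[p1][w][ok], freq[p2][w][ok]
                    dxy_site = f1 * (1.0 - f2) + f2 * (1.0 - f1)
                    pi_bar = 0.5 * (site_pi[p1][w][ok] + site_pi[p2][w][ok])
                    sum_dxy = float(dxy_site.sum())
                    dxy_w[(p1, p2)] = sum_dxy / ok.sum()
                    fst_w[(p1, p2)] = (
                        (sum_dxy - float(pi_bar.sum())) / sum_dxy
                        if sum_dxy > 0
                        else float("nan")
                    )
                out.append(
                    WindowStat(str(chrom), start, end, n_sites, pi_w, dxy_w, fst_w)
                )
            start += step_bp
    return out


def window_stats_frame(stats: List[WindowStat]) -> pd.DataFrame:
    """Flatten window statistics to a table (TSV-ready)."""
    if not stats:
        return pd.DataFrame()
    rows = []
    for w in stats:
        row = {"chrom": w.chrom, "start": w.start, "end": w.end, "n_sites": w.n_sites}
        for p, v in w.pi.items():
            row[f"pi_{p}"] = v
        for (p1, p2), v in w.dxy.items():
            row[f"dxy_{p1}_{p2}"] = v
        for (p1, p2), v in w.fst.items():
            row[f"fst_{p1}_{p2}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def hudson_fst(
    gm: GenotypeMatrix,
    group1: Sequence[str],
    group2: Sequence[str],
) -> float:
    """Genome-wide Hudson F_ST as a ratio of per-site sums between two
    sample groups. ``group1``/``group2`` are sample ID lists; pass
    ``popmap.by_lineage(...)`` or ``popmap.members(...)`` to compare
    lineages or populations."""
    r1 = [gm.sample_index(s) for s in group1]
    r2 = [gm.sample_index(s) for s in group2]
    alt1, n1 = _group_counts(gm, r1)
    alt2, n2 = _group_counts(gm, r2)
    ok = (n1 >= 2) & (n2 >= 2)
    f1, f2 = alt1[ok] / n1[ok], alt2[ok] / n2[ok]
    dxy = f1 * (1.0 - f2) + f2 * (1.0 - f1)
    pi_bar = 0.5 * (_site_pi(alt1[ok], n1[ok]) + _site_pi(alt2[ok], n2[ok]))
    sum_dxy = float(dxy.sum())
    if sum_dxy == 0.0:
        return float("nan")
    return float((sum_dxy - np.nansum(pi_bar)) / sum_dxy)


def genome_wide_dxy(
    gm: GenotypeMatrix,
    group1: Sequence[str],
    group2: Sequence[str],
) -> float:
    """Mean per-site d_XY between two sample groups over sites where both
    have observed alleles."""
    r1 = [gm.sample_index(s) for s in group1]
    r2 = [gm.sample_index(s) for s in group2]
    alt1, n1 = _group_counts(gm, r1)
    alt2, n2 = _group_counts(gm, r2)
    ok = (n1 >= 1) & (n2 >= 1)
    f1, f2 = alt1[ok] / n1[ok], alt2[ok] / n2[ok]
    return float((f1 * (1.0 - f2) + f2 * (1.0 - f1)).mean())


def _group_counts(gm: GenotypeMatrix, rows: Sequence[int]) -> Tuple[np.ndarray, np.ndarray]:
    d = gm.dosage[np.asarray(rows)]
    called = d >= 0
    alt = np.where(called, d, 0).sum(axis=0).astype(float)
    n = 2.0 * called.sum(axis=0)
    return alt, n


def _pair_key(stats: List[WindowStat], pair: Tuple[str, str]) -> Tuple[str, str]:
    if pair in stats[0].fst:
        return pair
    rev = (pair[1], pair[0])
    if rev in stats[0].fst:
        return rev
    raise KeyError(f"pair {pair} not in window statistics")


# ---------------------------------------------------------------------------
# outlier windows
# ---------------------------------------------------------------------------


def fst_outlier_windows(
    stats: List[WindowStat],
    pair: Tuple[str, str],
    percentile: float = 99.0,
) -> List[Tuple[str, int, int]]:
    """Windows at or above the empirical F_ST percentile (linear
    interpolation), merged when adjacent; returned as BED-style intervals."""
    key = _pair_key(stats, pair)
    vals = np.array([w.fst[key] for w in stats], dtype=float)
    ok = ~np.isnan(vals)
    if ok.sum() < 2:
        raise ValueError("need >= 2 windows with defined F_ST")
    cut = np.percentile(vals[ok], percentile)
    if np.all(vals[ok] == vals[ok][0]):
        warnings.warn("all windows share one F_ST value; flagging all (degenerate ties)")
    flagged = [
        (w.chrom, w.start, w.end)
        for w, v, o in zip(stats, vals, ok)
        if o and v >= cut
    ]
    return merge(flagged)


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------


@dataclass
class LDPoint:
    bin_start: int
    bin_end: int
    mean_r2: float
    n_pairs: int


def ld_decay(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    population: str,
    max_dist: int = 50_000,
    bin_bp: int = 100,
) -> List[LDPoint]:
    """Mean genotypic r^2 by distance bin for intra-chromosomal SNP pairs
    separated by at most ``max_dist`` bp, within one population.

    SNPs monomorphic within the population are skipped (r^2 undefined).
    """
    members = popmap.members(population)
    if len(members) < 2:
        raise ValueError(f"population {population!r} needs >= 2 samples")
    rows = [gm.sample_index(s) for s in members]
    d = gm.dosage[rows].astype(float)
    d[d < 0] = np.nan
    chrom_arr = gm.sites["chrom"].to_numpy()
    pos_arr = gm.sites["pos"].to_numpy()

    n_bins = int(np.ceil(max_dist / bin_bp))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)

    for chrom in dict.fromkeys(chrom_arr):
        on = chrom_arr == chrom
        pos = pos_arr[on]
        dc = d[:, on]
        n_snp = len(pos)
        j_hi = np.searchsorted(pos, pos + max_dist, side="right")
        for i in range(n_snp):
            for j in range(i + 1, j_hi[i]):
                r2 = _nan_r2(dc[:, i], dc[:, j])
                if np.isnan(r2):
                    continue
                b = int((pos[j] - pos[i] - 1) // bin_bp)
                if b >= n_bins:
                    continue
                sums[b] += r2
                counts[b] += 1

    return [
        LDPoint(b * bin_bp, (b + 1) * bin_bp,
                float(sums[b] / counts[b]) if counts[b] else float("nan"),
                int(counts[b]))
        for b in range(n_bins)
        if counts[b] > 0
    ]


def _nan_r2(x: np.ndarray, y: np.ndarray) -> float:
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        return float("nan")
    xs, ys = x[ok], y[ok]
    vx, vy = xs.var(), ys.var()
    if vx == 0.0 or vy == 0.0:
        return float("nan")
    cov = ((xs - xs.mean()) * (ys - ys.mean())).mean()
    return float(cov * cov / (vx * vy))
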