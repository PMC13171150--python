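"""Runs of homozygosity: detection, consensus, hotspots, clustering test.

Detection uses the sliding-window scheme popularised by detectRUNS-style
tools: a fixed-size window of consecutive SNPs slides one SNP at a time;
a window is "homozygous" if it holds at most a small number of
heterozygous and missing calls; each SNP is scored by the proportion of
windows containing it that are homozygous, and stretches of SNPs whose
proportion clears a threshold become candidate runs, subject to minimum
SNP count, minimum physical length, minimum SNP density and a maximum
gap between consecutive SNPs. Study settings: window 20 SNPs, min 20
SNPs per run, min length 250 kb; the X-flagged chromosome ("S7") is
excluded from the scan.

Group-level consensus regions arise from interval algebra on the merged
per-status unions: intervals seen in both captive and wild individuals
are "shared"; the remainders are "captive-unique" / "wild-unique".

The clustering permutation test asks whether a region set occupies fewer
genome bins than random placement predicts (negative Z = spatially
clustered regions); significance is empirical over ``n`` randomizations
that re-place each region uniformly, preserving its length, on a
chromosome drawn with probability proportional to chromosome length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .intervals import Interval, coverage_intervals, intersect, merge, subtract, total_length
from .vcfio import GenotypeMatrix, PopulationMap

# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


@dataclass
class RoHParams:
    """Sliding-window run detection parameters (study values where the
    source states them; remaining fields follow the detection tool's
    documented defaults)."""

    window_snps: int = 20
    threshold: float = 0.05  # SNP-in-run proportion above which a SNP is a candidate
    max_het_per_window: int = 1
    max_miss_per_window: int = 1
    max_gap_bp: int = 1_000_000
    min_snps: int = 20
    min_length_bp: int = 250_000
    min_density_snp_per_kb: float = 1.0 / 100.0  # 1 SNP per 100 kb

    def __post_init__(self) -> None:
        for name in (
            "window_snps", "max_gap_bp", "min_snps", "min_length_bp",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")


@dataclass
class RoHSegment:
    """One homozygous run; 0-based half-open coordinates."""

    sample: str
    chrom: str
    start: int
    end: int
    n_snps: int

    @property
    def length(self) -> int:
        return self.end - self.start

    def interval(self) -> Interval:
        return (self.chrom, self.start, self.end)


def detect_roh(
    gm: GenotypeMatrix,
    sample: str,
    params: RoHParams = RoHParams(),
    exclude_chroms: Sequence[str] = (),
) -> List[RoHSegment]:
    """Sliding-window RoH detection for one individual.

    Chromosomes named in ``exclude_chroms`` (e.g. the X) are skipped;
    chromosomes with fewer SNPs than the window emit a warning and no runs.
    """
    row = gm.dosage[gm.sample_index(sample)]
    chrom_arr = gm.sites["chrom"].to_numpy()
    pos_arr = gm.sites["pos"].to_numpy()
    out: List[RoHSegment] = []
    excl = set(exclude_chroms)

    for chrom in dict.fromkeys(chrom_arr):
        if chrom in excl:
            continue
        on = chrom_arr == chrom
        pos = pos_arr[on]
        g = row[on]
        n = len(pos)
        K = params.window_snps
        if n < K:
            warnings.warn(f"{chrom}: {n} SNPs < window size {K}; no runs callable")
            continue

        het = (g == 1).astype(np.int32)
        miss = (g < 0).astype(np.int32)
        # window w covers SNPs [w, w+K); counts via cumulative sums
        c_het = np.concatenate(([0], np.cumsum(het)))
        c_miss = np.concatenate(([0], np.cumsum(miss)))
        n_win = n - K + 1
        w_het = c_het[K:] - c_het[:-K]
        w_miss = c_miss[K:] - c_miss[:-K]
        hom_win = (
            (w_het <= params.max_het_per_window)
            & (w_miss <= params.max_miss_per_window)
        ).astype(np.int32)

        # SNP i is covered by windows max(0, i-K+1) .. min(i, n_win-1)
        c_hom = np.concatenate(([0], np.cumsum(hom_win)))
        i = np.arange(n)
        lo = np.maximum(0, i - K + 1)
        hi = np.minimum(i, n_win - 1)
        n_cov = hi - lo + 1
        n_hom = c_hom[hi + 1] - c_hom[lo]
        candidate = n_hom / n_cov > params.threshold

        out.extend(
            _candidates_to_runs(sample, str(chrom), pos, candidate, params)
        )
    return out


def _candidates_to_runs(
    sample: str,
    chrom: str,
    pos: np.ndarray,
    candidate: np.ndarray,
    params: RoHParams,
) -> List[RoHSegment]:
    """Maximal stretches of consecutive candidate SNPs (split at gaps
    larger than ``max_gap_bp``) passing the run-level filters."""
    runs: List[RoHSegment] = []
    n = len(pos)
    i = 0
    while i < n:
        if not candidate[i]:
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and candidate[j + 1]
            and pos[j + 1] - pos[j] <= params.max_gap_bp
        ):
            j += 1
        n_snps = j - i + 1
        start = int(pos[i]) - 1  # to 0-based half-open
        end = int(pos[j])
        length = end - start
        density = n_snps / (length / 1000.0)
        if (
            n_snps >= params.min_snps
            and length >= params.min_length_bp
            and density >= params.min_density_snp_per_kb
        ):
            runs.append(RoHSegment(sample, chrom, start, end, n_snps))
        i = j + 1
    return runs


def detect_roh_all(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    params: RoHParams = RoHParams(),
    exclude_chroms: Sequence[str] = (),
) -> List[RoHSegment]:
    """Detect runs for every mapped sample present in the matrix."""
    out: List[RoHSegment] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in gm.samples:
            if s in popmap.population:
                out.extend(detect_roh(gm, s, params, exclude_chroms))
    return out


# ---------------------------------------------------------------------------
# consensus regions
# ---------------------------------------------------------------------------


@dataclass
class ConsensusRegion:
    chrom: str
    start: int
    end: int
    status: str  # "captive-unique" | "wild-unique" | "shared"
    n_samples: int = 0  # supporting individuals (any overlap)

    def interval(self) -> Interval:
        return (self.chrom, self.start, self.end)


def consensus_regions(
    segments: Iterable[RoHSegment],
    popmap: PopulationMap,
    strict_intersection: bool = False,
) -> Tuple[List[ConsensusRegion], Dict[str, dict]]:
    """Reduce per-individual runs to group-level regions.

    Default semantics: union-merge each captivity-status group's runs,
    intersect the two unions ("shared"), and subtract the shared part
    from each union ("captive-unique" / "wild-unique"). With
    ``strict_intersection`` a group's base set is instead the
    intersection across all of its individuals that have any run.

    Returns the regions and a per-status span report (count, total bp).
    """
    segs = list(segments)
    group_ivs: Dict[str, List[Interval]] = {}
    group_members: Dict[str, List[str]] = {"captive": [], "wild": []}
    for status in ("captive", "wild"):
        members = [s for s in popmap.by_status(status)]
        per_sample = {
            m: [g.interval() for g in segs if g.sample == m] for m in members
        }
        per_sample = {m: ivs for m, ivs in per_sample.items() if ivs}
        group_members[status] = list(per_sample)
        if not per_sample:
            group_ivs[status] = []
        elif strict_intersection:
            base = merge(next(iter(per_sample.values())))
            for ivs in list(per_sample.values())[1:]:
                base = intersect(base, ivs)
            group_ivs[status] = base
        else:
            group_ivs[status] = merge(
                [iv for ivs in per_sample.values() for iv in ivs]
            )

    if group_ivs["captive"] and group_ivs["wild"]:
        shared = intersect(group_ivs["captive"], group_ivs["wild"])
    else:
        shared = []
    cap_unique = subtract(group_ivs["captive"], shared) if group_ivs["captive"] else []
    wild_unique = subtract(group_ivs["wild"], shared) if group_ivs["wild"] else []

    def support(iv: Interval) -> int:
        c, s, e = iv
        return len(
            {g.sample for g in segs if g.chrom == c and g.start < e and g.end > s}
        )

    regions: List[ConsensusRegion] = []
    for status, ivs in (
        ("captive-unique", cap_unique),
        ("wild-unique", wild_unique),
        ("shared", shared),
    ):
        for iv in ivs:
            regions.append(ConsensusRegion(iv[0], iv[1], iv[2], status, support(iv)))

    report = {
        status: {
            "n_regions": sum(1 for r in regions if r.status == status),
            "total_bp": total_length(
                [r.interval() for r in regions if r.status == status]
            ),
        }
        for status in ("captive-unique", "wild-unique", "shared")
    }
    report["captive-union"] = {
        "n_regions": len(group_ivs["captive"]),
        "total_bp": total_length(group_ivs["captive"]),
    }
    report["wild-union"] = {
        "n_regions": len(group_ivs["wild"]),
        "total_bp": total_length(group_ivs["wild"]),
    }
    return regions, report


# ---------------------------------------------------------------------------
# hotspots
# ---------------------------------------------------------------------------


def roh_hotspots(
    segments: Iterable[RoHSegment],
    group_samples: Sequence[str],
    min_fraction: float = 0.45,
) -> List[ConsensusRegion]:
    """Maximal intervals covered by runs in more than ``min_fraction`` of
    the group's individuals (study: RoH clustering in >45% of captive
    samples)."""
    group = list(group_samples)
    if len(group) < 2:
        raise ValueError("hotspot calling needs a group of >= 2 samples")
    per_sample = [
        [g.interval() for g in segments if g.sample == m] for m in group
    ]
    per_sample = [ivs for ivs in per_sample if ivs]
    cov = coverage_intervals(per_sample)
    hot = [
        (chrom, s, e)
        for chrom, s, e, depth in cov
        if depth / len(group) > min_fraction
    ]
    out = []
    for chrom, s, e in merge(hot):
        depth = max(d for c2, s2, e2, d in cov if c2 == chrom and s2 < e and e2 > s)
        out.append(ConsensusRegion(chrom, s, e, "hotspot", depth))
    return out


# ---------------------------------------------------------------------------
# clustering permutation test
# ---------------------------------------------------------------------------


@dataclass
class PermutationResult:
    observed: float
    null_mean: float
    null_sd: float
    z: Optional[float]
    p: float
    n_randomizations: int
    seed: int

    def as_dict(self) -> dict:
        return {
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "Z": self.z,
            "p": self.p,
            "n_randomizations": self.n_randomizations,
            "seed": self.seed,
        }


def _bins_hit(
    chrom_idx: np.ndarray,
    starts: np.ndarray,
    lengths: np.ndarray,
    bin_bp: int,
    bin_offsets: np.ndarray,
) -> int:
    """Number of distinct genome bins overlapped by >= 1 region.

    ``chrom_idx``/``starts``/``lengths`` describe regions; ``bin_offsets``
    maps a chromosome index to its first global bin index.
    """
    b0 = bin_offsets[chrom_idx] + starts // bin_bp
    b1 = bin_offsets[chrom_idx] + (starts + lengths - 1) // bin_bp
    hit: set = set()
    for lo, hi in zip(b0, b1):
        hit.update(range(int(lo), int(hi) + 1))
    return len(hit)


def roh_clustering_permutation(
    regions: Iterable[Interval],
    chrom_lengths: Dict[str, int],
    n: int = 10_000,
    bin_bp: int = 1_000_000,
    seed: int = 0,
) -> PermutationResult:
    """Are the regions more spatially clustered than random placement?

    Statistic: genome bins (``bin_bp`` wide) overlapped by >= 1 region.
    Null: each region is independently re-placed, length preserved,
    uniformly on a chromosome chosen with probability proportional to its
    length (restricted to chromosomes long enough to hold it). Z is the
    standardized observed statistic; the empirical two-sided p counts
    null draws at least as far from the null mean as the observation.
    Clustered regions hit fewer bins than expected: negative Z.
    """
    regs = list(regions)
    if not regs:
        raise ValueError("no regions given")
    chroms = list(chrom_lengths)
    for c, s, e in regs:
        if c not in chrom_lengths or e > chrom_lengths[c]:
            raise ValueError(f"region {c}:{s}-{e} outside the given chromosome lengths")

    c_index = {c: i for i, c in enumerate(chroms)}
    lens = np.array([chrom_lengths[c] for c in chroms], dtype=np.int64)
    n_bins = (lens + bin_bp - 1) // bin_bp
    bin_offsets = np.concatenate(([0], np.cumsum(n_bins)))[:-1]

    obs_chrom = np.array([c_index[c] for c, _, _ in regs])
    obs_start = np.array([s for _, s, _ in regs], dtype=np.int64)
    reg_len = np.array([e - s for _, s, e in regs], dtype=np.int64)
    observed = _bins_hit(obs_chrom, obs_start, reg_len, bin_bp, bin_offsets)

    rng = np.random.default_rng(seed)
    R = len(regs)
    # per-region admissible chromosomes (long enough); sampled in one
    # vectorized pass per distinct admissible set
    admissible = [np.flatnonzero(lens >= L) for L in reg_len]
    for a in admissible:
        if len(a) == 0:
            raise ValueError("a region is longer than every chromosome")
    ch_mat = np.empty((n, R), dtype=np.int64)
    groups: Dict[tuple, List[int]] = {}
    for k, a in enumerate(admissible):
        groups.setdefault(tuple(a.tolist()), []).append(k)
    for a_key, ks in groups.items():
        a = np.asarray(a_key)
        cw = np.cumsum(lens[a] / lens[a].sum())
        draws = np.searchsorted(cw, rng.random((n, len(ks))), side="right")
        ch_mat[:, ks] = a[np.minimum(draws, len(a) - 1)]
    st_mat = (rng.random((n, R)) * (lens[ch_mat] - reg_len + 1)).astype(np.int64)
    b0 = bin_offsets[ch_mat] + st_mat // bin_bp
    b1 = bin_offsets[ch_mat] + (st_mat + reg_len - 1) // bin_bp
    total_bins = int(n_bins.sum())
    if n * total_bins <= 100_000_000:
        hitmat = np.zeros((n, total_bins), dtype=bool)
        span = b1 - b0
        for off in range(int(span.max()) + 1):
            mask = span >= off
            rows = np.nonzero(mask)[0]
            hitmat[rows, (b0 + off)[mask]] = True
        null = hitmat.sum(axis=1).astype(np.int64)
    else:
        null = np.array(
            [
                _bins_hit(ch_mat[t], st_mat[t], reg_len, bin_bp, bin_offsets)
                for t in range(n)
            ],
            dtype=np.int64,
        )

    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    z = (observed - null_mean) / null_sd if null_sd > 0 else None
    if null_sd > 0:
        extreme = np.abs(null - null_mean) >= abs(observed - null_mean)
        p = float((1 + extreme.sum()) / (n + 1))
    else:
        # degenerate null: one-sided tail on raw counts
        extreme = (null <= observed) if observed <= null_mean else (null >= observed)
        p = float((1 + extreme.sum()) / (n + 1))
    return PermutationResult(float(observed), null_mean, null_sd, z, p, n, seed)


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------


def compare_roh(
    segments: Iterable[RoHSegment], popmap: PopulationMap
) -> Dict[str, dict]:
    """Two-sided Wilcoxon rank-sum tests, captive vs wild, on per-individual
    run counts and mean run lengths. W is the Mann–Whitney U of the
    captive group; exact p for small tie-free groups, normal approximation
    with tie correction otherwise (scipy's 'auto' policy)."""
    segs = list(segments)
    per_sample: Dict[str, List[RoHSegment]] = {}
    for g in segs:
        per_sample.setdefault(g.sample, []).append(g)

    def group_values(status: str) -> Tuple[List[float], List[float]]:
        counts, mean_lens = [], []
        for s in popmap.by_status(status):
            runs = per_sample.get(s, [])
            if not runs:
                continue  # individuals with no runs are excluded, as in the study
            counts.append(float(len(runs)))
            mean_lens.append(float(np.mean([r.length for r in runs])))
        return counts, mean_lens

    cap_n, cap_len = group_values("captive")
    wild_n, wild_len = group_values("wild")
    if len(cap_n) < 2 or len(wild_n) < 2:
        raise ValueError("need >= 2 individuals with runs in each group")

    out = {}
    for name, a, b in (("count", cap_n, wild_n), ("mean_length", cap_len, wild_len)):
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        out[name] = {
            "W": float(res.statistic),
            "p": float(res.pvalue),
            "captive_median": float(np.median(a)),
            "wild_median": float(np.median(b)),
        }
    return out


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------


def segments_frame(segments: Iterable[RoHSegment]) -> pd.DataFrame:
    rows = [
        (g.sample, g.chrom, g.start, g.end, g.n_snps, g.length) for g in segments
    ]
    return pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "n_snps", "length_bp"]
    )


def regions_frame(regions: Iterable[ConsensusRegion]) -> pd.DataFrame:
    rows = [(r.chrom, r.start, r.end, r.status, r.n_samples) for r in regions]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "status", "n_samples"])
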