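"""Introgression statistics: D, f_dM scans, f-branch, mito-nuclear discordance.

All statistics work on population derived-allele frequencies in the
four-taxon arrangement (((P1, P2), P3), Outgroup). Polarization is
frequency-based: the outgroup's alt-allele frequency ``p4`` enters the
ABBA/BABA products directly, so no hard ancestral call is made and sites
where the outgroup is fixed for the alt allele contribute nothing.

* Patterson's D over all sites with block-jackknife standard errors
  (contiguous equal-SNP blocks), Z = |D|/SE, two-sided normal p, and
  Benjamini–Hochberg filtering across trios (retain adjusted p <= 0.05
  and Z >= 3, the study's rule).
* f_dM in sliding windows of 50 informative SNPs stepping by 25 — a
  bounded admixture-fraction estimator that is symmetric between
  P2–P3 and P1–P3 sharing (positive = P2–P3 excess).
* f-branch: assigns excess-sharing signals to branches of a rooted
  population tree, including internal branches, as the median over P2
  descendants of the minimum over P1 sister-clade leaves of the clamped
  admixture fraction f-hat.
* Mito-nuclear discordance: counts samples whose mitochondrial clade is
  not an allowed match for their nuclear lineage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .intervals import merge
from .vcfio import GenotypeMatrix, PopulationMap

# ---------------------------------------------------------------------------
# site patterns and frequencies
# ---------------------------------------------------------------------------


def site_patterns(
    p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Frequency-weighted ABBA and BABA pattern intensities.

    abba = (1-p1) * p2 * p3 * (1-p4); baba = p1 * (1-p2) * p3 * (1-p4).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    abba = (1.0 - p1) * p2 * p3 * (1.0 - p4)
    baba = p1 * (1.0 - p2) * p3 * (1.0 - p4)
    return abba, baba


def group_frequencies(
    gm: GenotypeMatrix, popmap: PopulationMap, groups: Sequence[Sequence[str] | str]
) -> List[np.ndarray]:
    """Alt-allele frequency per site for each group. A group may be a
    population name or an explicit list of sample IDs; sites with no
    observed alleles in a group get frequency NaN."""
    out = []
    for g in groups:
        samples = popmap.members(g) if isinstance(g, str) else list(g)
        rows = [gm.sample_index(s) for s in samples]
        out.append(gm.alt_freq(rows))
    return out


def _complete(freqs: Sequence[np.ndarray]) -> np.ndarray:
    ok = np.ones(len(freqs[0]), dtype=bool)
    for f in freqs:
        ok &= ~np.isnan(f)
    return ok


# ---------------------------------------------------------------------------
# Patterson's D
# ---------------------------------------------------------------------------


@dataclass
class TrioResult:
    p1: str
    p2: str
    p3: str
    outgroup: str
    abba: float
    baba: float
    d: Optional[float]
    se: Optional[float]
    z: Optional[float]
    p: Optional[float]
    p_adjusted: Optional[float] = None
    passed: Optional[bool] = None
    n_sites: int = 0


def d_statistic(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    trio: Sequence[str],
    outgroup: str,
    n_blocks: int = 20,
) -> TrioResult:
    """Patterson's D for one trio with block-jackknife SE.

    D = sum(abba - baba) / sum(abba + baba) over all sites where all four
    groups have observed alleles. SE comes from a delete-one jackknife
    over ``n_blocks`` contiguous blocks of equal informative-site counts;
    Z = |D| / SE with a two-sided normal p-value.
    """
    name1, name2, name3 = trio
    if outgroup in (name1, name2, name3):
        raise ValueError("outgroup must be distinct from the trio")
    f1, f2, f3, f4 = group_frequencies(gm, popmap, [name1, name2, name3, outgroup])
    ok = _complete([f1, f2, f3, f4])
    abba, baba = site_patterns(f1[ok], f2[ok], f3[ok], f4[ok])

    num = abba - baba
    den = abba + baba
    informative = den > 0
    total_den = float(den.sum())
    base = TrioResult(
        name1, name2, name3, outgroup,
        float(abba.sum()), float(baba.sum()),
        None, None, None, None, n_sites=int(informative.sum()),
    )
    if total_den == 0.0:
        return base

    d = float(num.sum() / total_den)
    # jackknife over contiguous blocks with equal numbers of informative sites
    inf_idx = np.flatnonzero(informative)
    blocks = min(n_blocks, len(inf_idx))
    if blocks < n_blocks:
        warnings.warn(
            f"only {len(inf_idx)} informative sites; using {blocks} jackknife blocks"
        )
    if blocks < 2:
        base.d = d
        return base
    bounds = np.linspace(0, len(inf_idx), blocks + 1).astype(int)
    d_jack = np.empty(blocks)
    for b in range(blocks):
        drop = inf_idx[bounds[b] : bounds[b + 1]]
        mask = np.ones(len(num), dtype=bool)
        mask[drop] = False
        den_b = float(den[mask].sum())
        d_jack[b] = num[mask].sum() / den_b if den_b > 0 else 0.0
    se = float(np.sqrt((blocks - 1) / blocks * ((d_jack - d_jack.mean()) ** 2).sum()))
    z = abs(d) / se if se > 0 else float("inf")
    p = float(2.0 * sps.norm.sf(z)) if np.isfinite(z) else 0.0
    base.d, base.se, base.z, base.p = d, se, z, p
    return base


def bh_filter_trios(
    results: Sequence[TrioResult], alpha: float = 0.05, z_min: float = 3.0
) -> List[TrioResult]:
    """Benjamini–Hochberg adjustment across trios; retain trios with
    adjusted p <= alpha and Z >= z_min. All inputs get ``p_adjusted`` and
    ``passed`` filled in; the returned list holds the survivors."""
    results = list(results)
    testable = [r for r in results if r.p is not None]
    if testable:
        pvals = np.array([r.p for r in testable])
        adj = _bh_adjust(pvals)
        for r, a in zip(testable, adj):
            r.p_adjusted = float(a)
    for r in results:
        r.passed = (
            r.p_adjusted is not None
            and r.z is not None
            and r.p_adjusted <= alpha
            and r.z >= z_min
        )
    return [r for r in results if r.passed]


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def trio_results_frame(results: Iterable[TrioResult]) -> pd.DataFrame:
    rows = [
        (r.p1, r.p2, r.p3, r.outgroup, r.n_sites, r.abba, r.baba, r.d, r.se,
         r.z, r.p, r.p_adjusted, r.passed)
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["P1", "P2", "P3", "outgroup", "n_sites", "ABBA", "BABA", "D",
                 "SE", "Z", "p", "p_adj", "passed"],
    )


# ---------------------------------------------------------------------------
# f_dM windows
# ---------------------------------------------------------------------------


@dataclass
class FdmWindow:
    chrom: str
    first_pos: int
    last_pos: int
    n_snps: int
    fdm: float


def _fdm_site_terms(
    f1: np.ndarray, f2: np.ndarray, f3: np.ndarray, f4: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-site numerator and f_dM denominator (dynamic donor choice)."""
    abba, baba = site_patterns(f1, f2, f3, f4)
    num = abba - baba
    # positive branch: donor candidate shared by P2/P3
    pd23 = np.maximum(f2, f3)
    a_pos, b_pos = site_patterns(f1, pd23, pd23, f4)
    den_pos = a_pos - b_pos
    # negative branch: donor candidate shared by P1/P3
    pd13 = np.maximum(f1, f3)
    a_neg, b_neg = site_patterns(pd13, f2, pd13, f4)
    den_neg = -(a_neg - b_neg)
    den = np.where(num >= 0, den_pos, den_neg)
    return num, den


def fdm_scan(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    trio: Sequence[str],
    outgroup: str,
    window_snps: int = 50,
    step_snps: int = 25,
) -> List[FdmWindow]:
    """Windowed f_dM over informative sites (abba + baba > 0), per
    chromosome, with windows of ``window_snps`` SNPs advanced by
    ``step_snps`` SNPs. Windows whose denominator sums to zero get NaN.
    """
    f1, f2, f3, f4 = group_frequencies(gm, popmap, list(trio) + [outgroup])
    ok = _complete([f1, f2, f3, f4])
    abba, baba = site_patterns(f1, f2, f3, f4)
    informative = ok & ((abba + baba) > 0)

    num_all, den_all = _fdm_site_terms(f1, f2, f3, f4)
    chrom_arr = gm.sites["chrom"].to_numpy()
    pos_arr = gm.sites["pos"].to_numpy()

    out: List[FdmWindow] = []
    for chrom in dict.fromkeys(chrom_arr):
        idx = np.flatnonzero((chrom_arr == chrom) & informative)
        if len(idx) < window_snps:
            continue
        for s in range(0, len(idx) - window_snps + 1, step_snps):
            w = idx[s : s + window_snps]
            den_sum = float(den_all[w].sum())
            fdm = float(num_all[w].sum() / den_sum) if den_sum != 0 else float("nan")
            out.append(
                FdmWindow(
                    str(chrom), int(pos_arr[w[0]]), int(pos_arr[w[-1]]),
                    window_snps, fdm,
                )
            )
    return out


def fdm_scan_frame(scan: Iterable[FdmWindow]) -> pd.DataFrame:
    rows = [(w.chrom, w.first_pos, w.last_pos, w.n_snps, w.fdm) for w in scan]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "fdm"])


def fdm_outlier_tracts(
    scan: Sequence[FdmWindow], top_fraction: float = 0.01
) -> List[Tuple[str, int, int]]:
    """Merge the top-``top_fraction`` f_dM windows into candidate
    introgression tracts (BED-style intervals spanning first to last SNP
    of the merged windows)."""
    vals = np.array([w.fdm for w in scan], dtype=float)
    ok = ~np.isnan(vals)
    if not ok.any():
        raise ValueError("all windows have undefined f_dM")
    if ok.sum() < 100:
        warnings.warn(
            f"only {int(ok.sum())} valid windows; the {top_fraction:.0%} quantile "
            "is poorly determined"
        )
    cut = np.quantile(vals[ok], 1.0 - top_fraction)
    if np.all(vals[ok] == vals[ok][0]):
        warnings.warn("uniform f_dM values; flagging all windows (degenerate ties)")
    flagged = [
        (w.chrom, w.first_pos - 1, w.last_pos)
        for w, v, o in zip(scan, vals, ok)
        if o and v >= cut
    ]
    return merge(flagged)


# ---------------------------------------------------------------------------
# f-branch
# ---------------------------------------------------------------------------


@dataclass
class FBranchMatrix:
    """Branch x donor matrix of f-branch values; NaN = topologically
    undefined cell. Branch labels are the sorted leaf sets of the clade
    below the branch (single leaf name for terminal branches)."""

    branches: List[str]
    donors: List[str]
    values: np.ndarray  # (n_branches, n_donors), NaN where undefined

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.branches, columns=self.donors)

    def max_cell(self) -> Tuple[str, str, float]:
        masked = np.where(np.isnan(self.values), -np.inf, self.values)
        i, j = np.unravel_index(int(np.argmax(masked)), self.values.shape)
        return self.branches[i], self.donors[j], float(self.values[i, j])


def _fhat(
    f1: np.ndarray, f2: np.ndarray, f3: np.ndarray, f4: np.ndarray
) -> float:
    """Admixture-fraction estimator f-hat with the dynamic-donor
    denominator (positive branch), clamped to [0, 1]."""
    abba, baba = site_patterns(f1, f2, f3, f4)
    pd23 = np.maximum(f2, f3)
    a_d, b_d = site_patterns(f1, pd23, pd23, f4)
    den = float((a_d - b_d).sum())
    if den == 0.0:
        return 0.0
    val = float((abba - baba).sum() / den)
    return min(max(val, 0.0), 1.0)


def f_branch(
    tree,
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    outgroup: str,
) -> FBranchMatrix:
    """f-branch statistic over a rooted population tree.

    ``tree`` is a dendropy Tree (or a newick string/path, converted) whose
    leaf taxa are population names in ``popmap``. For each branch b with
    sister clade a, and each donor population C not below a or b and not
    the outgroup: f_b(C) = median over P2 in leaves(b) of the minimum
    over P1 in leaves(a) of f-hat(P1, P2, C, outgroup).
    """
    import dendropy

    if isinstance(tree, str):
        tree = read_tree(tree)
    leaves = [t.taxon.label for t in tree.leaf_node_iter()]
    if outgroup not in leaves:
        raise ValueError(f"outgroup {outgroup!r} is not a leaf of the tree")
    root = tree.seed_node
    root_children = root.child_nodes()
    out_leafsets = [
        {t.taxon.label for t in c.leaf_iter()} for c in root_children
    ]
    if not any(ls == {outgroup} for ls in out_leafsets):
        raise ValueError(
            "tree must be rooted with the outgroup as one child of the root"
        )

    # frequency cache per population
    pops = [l for l in leaves if l != outgroup]
    freqs: Dict[str, np.ndarray] = {}
    for p in pops + [outgroup]:
        freqs[p] = group_frequencies(gm, popmap, [p])[0]

    def leafset(node) -> List[str]:
        return sorted(t.taxon.label for t in node.leaf_iter())

    branches: List[Tuple[str, List[str], List[str]]] = []  # label, leaves(b), leaves(a)
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        ls = leafset(node)
        if ls == [outgroup]:
            continue
        parent = node.parent_node
        sisters = [c for c in parent.child_nodes() if c is not node]
        if len(sisters) != 1:
            continue  # polytomy: sister clade ambiguous
        sis_ls = leafset(sisters[0])
        if outgroup in sis_ls or outgroup in ls:
            continue
        label = ls[0] if len(ls) == 1 else "(" + ",".join(ls) + ")"
        branches.append((label, ls, sis_ls))

    donors = pops
    values = np.full((len(branches), len(donors)), np.nan)
    for i, (label, b_leaves, a_leaves) in enumerate(branches):
        blocked = set(b_leaves) | set(a_leaves)
        for j, donor in enumerate(donors):
            if donor in blocked:
                continue  # topologically undefined
            per_p2 = []
            for p2 in b_leaves:
                vals = []
                for p1 in a_leaves:
                    ok = _complete(
                        [freqs[p1], freqs[p2], freqs[donor], freqs[outgroup]]
                    )
                    vals.append(
                        _fhat(
                            freqs[p1][ok], freqs[p2][ok],
                            freqs[donor][ok], freqs[outgroup][ok],
                        )
                    )
                per_p2.append(min(vals))
            values[i, j] = float(np.median(per_p2))
    return FBranchMatrix([b[0] for b in branches], donors, values)


def read_tree(path_or_newick: str):
    """Read a rooted newick tree from a file path or a literal string."""
    import dendropy

    if "(" in path_or_newick:
        return dendropy.Tree.get(
            data=path_or_newick, schema="newick", rooting="default-rooted",
            preserve_underscores=True
        )
    return dendropy.Tree.get(
        path=path_or_newick, schema="newick", rooting="default-rooted",
        preserve_underscores=True
    )


# ---------------------------------------------------------------------------
# mito-nuclear discordance
# ---------------------------------------------------------------------------


@dataclass
class DiscordanceReport:
    discordant: List[str]
    n_samples: int
    fraction: float
    nuclear: Dict[str, str]
    mito: Dict[str, str]

    @property
    def percent(self) -> int:
        return int(round(100.0 * self.fraction))

    def as_dict(self) -> dict:
        return {
            "discordant_samples": self.discordant,
            "n_samples": self.n_samples,
            "fraction": self.fraction,
            "percent": self.percent,
        }


def discordance_count(
    nuclear: Mapping[str, str],
    mito: Mapping[str, str],
    relation: Mapping[str, Iterable[str]],
) -> DiscordanceReport:
    """Count samples whose (nuclear lineage, mito clade) pair is not in
    the allowed correspondence relation (study: a -> {A, B1}, b -> {B2}).
    """
    samples = sorted(nuclear)
    missing = sorted(set(samples) ^ set(mito))
    if missing:
        raise ValueError(f"samples lacking a label in one map: {missing}")
    allowed = {k: set(v) for k, v in relation.items()}
    discordant = [
        s for s in samples if mito[s] not in allowed.get(nuclear[s], set())
    ]
    return DiscordanceReport(
        discordant=discordant,
        n_samples=len(samples),
        fraction=len(discordant) / len(samples) if samples else 0.0,
        nuclear=dict(nuclear),
        mito=dict(mito),
    )


def labels_from_tree(tree, reference_labels: Mapping[str, str]) -> Dict[str, str]:
    """Convenience: label every leaf of a tree by its nearest labelled
    reference leaf (patristic distance; topological distance when branch
    lengths are absent). Reference leaves keep their own labels."""
    import dendropy

    if isinstance(tree, str):
        tree = read_tree(tree)
    has_lengths = any(
        e.length is not None for e in tree.preorder_edge_iter() if e.head_node
    )
    if not has_lengths:
        for e in tree.preorder_edge_iter():
            e.length = 1.0
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    refs = {s: l for s, l in reference_labels.items() if s in taxa}
    if not refs:
        raise ValueError("no reference label matches a tree leaf")
    out: Dict[str, str] = {}
    for leaf in tree.leaf_node_iter():
        name = leaf.taxon.label
        if name in refs:
            out[name] = refs[name]
            continue
        best = min(refs, key=lambda r: pdm.distance(taxa[name], taxa[r]))
        out[name] = refs[best]
    return out
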