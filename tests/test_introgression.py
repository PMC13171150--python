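"""D statistic, BH trio filtering, f_dM scans, f-branch, discordance."""

import numpy as np
import pytest

import hermetia as hm
from hermetia import introgression
from hermetia.simdata import PopulationSpec, SimConfig, Tract

from conftest import make_matrix, make_popmap


# ---------------------------------------------------------------------------
# site patterns
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "freqs, expected",
    [
        ((0, 1, 1, 0), (1.0, 0.0)),
        ((1, 0, 1, 0), (0.0, 1.0)),
        ((0, 0.5, 0.5, 0), (0.25, 0.0)),
        ((0, 1, 1, 1), (0.0, 0.0)),  # outgroup fixed derived: no signal
    ],
)
def test_site_patterns(freqs, expected):
    abba, baba = hm.site_patterns(*[np.array([f]) for f in freqs])
    assert (abba[0], baba[0]) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# D statistic
# ---------------------------------------------------------------------------


def trio_matrix(freq_rows):
    """One haploid-pair sample per taxon; frequencies in {0, 0.5, 1}."""
    dosage = np.array(
        [[int(round(2 * f)) for f in col] for col in freq_rows], dtype=np.int8
    ).T
    gm = make_matrix(dosage, samples=["a", "b", "c", "o"])
    pm = make_popmap({"a": "P1", "b": "P2", "c": "P3", "o": "O"})
    return gm, pm


def test_d_all_abba_is_one():
    gm, pm = trio_matrix([(0, 1, 1, 0)] * 30)
    res = hm.d_statistic(gm, pm, ["P1", "P2", "P3"], "O", n_blocks=5)
    assert res.d == pytest.approx(1.0)


def test_d_hand_summed_three_sites():
    """Sites (0,1,1,0), (1,0,1,0), (0,0.5,0.5,0):
    D = (1.25 - 1) / 2.25 = 0.1111..."""
    gm, pm = trio_matrix([(0, 1, 1, 0), (1, 0, 1, 0), (0, 0.5, 0.5, 0)])
    with pytest.warns(UserWarning):  # fewer sites than default blocks
        res = hm.d_statistic(gm, pm, ["P1", "P2", "P3"], "O")
    assert res.d == pytest.approx(0.25 / 2.25)


def test_d_undefined_without_informative_sites():
    gm, pm = trio_matrix([(1, 1, 0, 0)] * 10)  # p3 = 0 everywhere
    res = hm.d_statistic(gm, pm, ["P1", "P2", "P3"], "O")
    assert res.d is None and res.n_sites == 0


def test_d_antisymmetric_in_p1_p2():
    rng = np.random.default_rng(13)
    freqs = rng.choice([0, 0.5, 1.0], size=(200, 4))
    gm, pm = trio_matrix([tuple(f) for f in freqs])
    d12 = hm.d_statistic(gm, pm, ["P1", "P2", "P3"], "O", n_blocks=10)
    d21 = hm.d_statistic(gm, pm, ["P2", "P1", "P3"], "O", n_blocks=10)
    assert d12.d == pytest.approx(-d21.d, abs=1e-12)


def test_d_matches_bruteforce_oracle():
    """Population-frequency D on simulated data equals an explicit
    site-by-site loop to 1e-12."""
    cfg = SimConfig(
        chromosomes={"S1": 600_000},
        x_chrom="S1",
        populations=[
            PopulationSpec("P1", "b", "wild", 4, 0.1),
            PopulationSpec("P2", "b", "wild", 4, 0.1),
            PopulationSpec("P3", "a", "wild", 4, 0.1),
            PopulationSpec("O", "o", "wild", 3, 0.3),
        ],
        snp_density=1 / 800,
        seed=14,
    )
    gm, pm, _ = hm.simulate_dataset(cfg)
    assert gm.n_sites <= 1000
    res = hm.d_statistic(gm, pm, ["P1", "P2", "P3"], "O")

    num = den = 0.0
    for j in range(gm.n_sites):
        fs = []
        for pop in ["P1", "P2", "P3", "O"]:
            rows = [gm.sample_index(s) for s in pm.members(pop)]
            g = gm.dosage[rows, j]
            g = g[g >= 0]
            fs.append(g.sum() / (2 * len(g)) if len(g) else np.nan)
        if any(np.isnan(f) for f in fs):
            continue
        p1, p2, p3, p4 = fs
        abba = (1 - p1) * p2 * p3 * (1 - p4)
        baba = p1 * (1 - p2) * p3 * (1 - p4)
        num += abba - baba
        den += abba + baba
    assert res.d == pytest.approx(num / den, abs=1e-12)


def test_d_null_calibration_fast():
    """No gene flow: |Z| < 3 in at least 19 of 20 replicate simulations
    (the full 100-replicate version runs in the acceptance suite)."""
    n_ok = 0
    for seed in range(20):
        cfg = SimConfig(
            chromosomes={"S1": 2_000_000},
            x_chrom="S1",
            populations=[
                PopulationSpec("P1", "b", "wild", 6, 0.05),
                PopulationSpec("P2", "b", "wild", 6, 0.05),
                PopulationSpec("P3", "a", "wild", 6, 0.05),
                PopulationSpec("O", "o", "wild", 4, 0.3),
            ],
            snp_density=1 / 500,
            seed=seed,
        )
        gm, pm, _ = hm.simulate_dataset(cfg)
        res = hm.d_statistic(gm, pm, ["P1", "P2", "P3"], "O")
        if res.z < 3:
            n_ok += 1
    assert n_ok >= 19


# ---------------------------------------------------------------------------
# BH filtering
# ---------------------------------------------------------------------------


def _trio(p, z):
    return introgression.TrioResult(
        "P1", "P2", "P3", "O", 1.0, 0.5, 0.2, 0.05, z, p
    )


def test_bh_single_trio_unchanged():
    [kept] = hm.bh_filter_trios([_trio(0.01, 5.0)])
    assert kept.p_adjusted == pytest.approx(0.01)
    assert kept.passed


def test_bh_adjustment_hand_computed():
    """p = (0.01, 0.02, 0.04) -> BH-adjusted (0.03, 0.03, 0.04)."""
    trios = [_trio(0.01, 5.0), _trio(0.02, 4.0), _trio(0.04, 3.5)]
    hm.bh_filter_trios(trios)
    assert [t.p_adjusted for t in trios] == pytest.approx([0.03, 0.03, 0.04])


def test_bh_z_rule_filters_low_z():
    trios = [_trio(0.001, 2.9), _trio(0.001, 3.2)]
    kept = hm.bh_filter_trios(trios)
    assert [t.z for t in kept] == [3.2]
    assert trios[0].passed is False


# ---------------------------------------------------------------------------
# f_dM
# ---------------------------------------------------------------------------


def test_fdm_complete_sharing_is_one():
    gm, pm = trio_matrix([(0, 1, 1, 0)] * 60)
    scan = hm.fdm_scan(gm, pm, ["P1", "P2", "P3"], "O", window_snps=50, step_snps=25)
    assert len(scan) == 1 and scan[0].fdm == pytest.approx(1.0)


def test_fdm_mirrored_sharing_is_minus_one():
    gm, pm = trio_matrix([(1, 0, 1, 0)] * 60)
    scan = hm.fdm_scan(gm, pm, ["P1", "P2", "P3"], "O", window_snps=50, step_snps=25)
    assert scan[0].fdm == pytest.approx(-1.0)


def test_fdm_window_arithmetic():
    """100 informative SNPs, window 50, step 25 -> 3 windows."""
    gm, pm = trio_matrix([(0, 1, 1, 0)] * 100)
    scan = hm.fdm_scan(gm, pm, ["P1", "P2", "P3"], "O")
    assert len(scan) == 3
    assert [w.first_pos for w in scan] == [1000, 26_000, 51_000]


def test_fdm_bounded_in_unit_interval():
    rng = np.random.default_rng(15)
    freqs = rng.choice([0, 0.5, 1.0], size=(400, 4))
    gm, pm = trio_matrix([tuple(f) for f in freqs])
    scan = hm.fdm_scan(gm, pm, ["P1", "P2", "P3"], "O")
    vals = [w.fdm for w in scan if not np.isnan(w.fdm)]
    assert vals and all(-1.0 - 1e-12 <= v <= 1.0 + 1e-12 for v in vals)


def test_fdm_antisymmetric_in_p1_p2():
    rng = np.random.default_rng(16)
    freqs = rng.choice([0, 0.5, 1.0], size=(150, 4))
    gm, pm = trio_matrix([tuple(f) for f in freqs])
    a = hm.fdm_scan(gm, pm, ["P1", "P2", "P3"], "O")
    b = hm.fdm_scan(gm, pm, ["P2", "P1", "P3"], "O")
    for wa, wb in zip(a, b):
        if np.isnan(wa.fdm):
            assert np.isnan(wb.fdm)
        else:
            assert wa.fdm == pytest.approx(-wb.fdm, abs=1e-12)


def test_fdm_outlier_tracts_merge_contiguous():
    # half-overlapping windows, as a 50/25 SNP scan produces
    windows = [
        introgression.FdmWindow("S1", i * 500 + 1, i * 500 + 1000, 50, v)
        for i, v in enumerate([0.0] * 198 + [0.9, 0.95])
    ]
    tracts = hm.fdm_outlier_tracts(windows, top_fraction=0.01)
    assert len(tracts) == 1
    assert tracts[0] == ("S1", 198 * 500, 199 * 500 + 1000)


def test_fdm_outlier_uniform_values_flags_all():
    windows = [
        introgression.FdmWindow("S1", i * 500 + 1, i * 500 + 1000, 50, 0.5)
        for i in range(150)
    ]
    with pytest.warns(UserWarning, match="uniform|degenerate"):
        tracts = hm.fdm_outlier_tracts(windows)
    assert len(tracts) == 1  # windows overlap/adjoin -> one merged tract


def test_fdm_outlier_all_nan_errors():
    windows = [introgression.FdmWindow("S1", 1, 500, 50, float("nan"))]
    with pytest.raises(ValueError):
        hm.fdm_outlier_tracts(windows)


# ---------------------------------------------------------------------------
# f-branch
# ---------------------------------------------------------------------------


def test_fbranch_reduces_to_fhat_on_four_leaf_tree():
    """With singleton clades the median/min collapse: the (P2, donor P3)
    cell equals f-hat(P1, P2, P3, O) computed directly."""
    rng = np.random.default_rng(17)
    freqs = rng.choice([0, 0.5, 1.0], size=(300, 4))
    gm, pm = trio_matrix([tuple(f) for f in freqs])
    fb = hm.f_branch("(((P1,P2),P3),O);", gm, pm, "O")
    cell = fb.frame().loc["P2", "P3"]

    f = freqs.T
    abba = (1 - f[0]) * f[1] * f[2] * (1 - f[3])
    baba = f[0] * (1 - f[1]) * f[2] * (1 - f[3])
    pd23 = np.maximum(f[1], f[2])
    a_d = (1 - f[0]) * pd23 * pd23 * (1 - f[3])
    b_d = f[0] * (1 - pd23) * pd23 * (1 - f[3])
    expected = min(max(float((abba - baba).sum() / (a_d - b_d).sum()), 0.0), 1.0)
    assert cell == pytest.approx(expected, abs=1e-12)


def test_fbranch_topology_disallowed_cells_undefined():
    rng = np.random.default_rng(18)
    freqs = rng.choice([0, 0.5, 1.0], size=(100, 4))
    gm, pm = trio_matrix([tuple(f) for f in freqs])
    fb = hm.f_branch("(((P1,P2),P3),O);", gm, pm, "O").frame()
    # P3's branch has sister clade (P1,P2): every donor is blocked
    assert fb.loc["P3"].isna().all()
    # the (P1,P2) internal branch has sister P3: blocked as well
    assert fb.loc["(P1,P2)"].isna().all()
    # P1 and P2 rows are defined exactly for donor P3
    assert not np.isnan(fb.loc["P1", "P3"])
    assert np.isnan(fb.loc["P1", "P2"])


def test_fbranch_requires_outgroup_leaf():
    gm, pm = trio_matrix([(0, 1, 1, 0)] * 10)
    with pytest.raises(ValueError):
        hm.f_branch("(((P1,P2),P3),O);", gm, pm, "X")


def _fbranch_sim(seed, gene_flow):
    tracts = []
    if gene_flow:
        tracts = [
            Tract(f"P2_{i:02d}", "S1", 500_000, 4_500_000, donor="P3")
            for i in range(1, 7)
        ]
    cfg = SimConfig(
        chromosomes={"S1": 10_000_000, "S2": 10_000_000},
        x_chrom="S2",
        populations=[
            PopulationSpec("P1", "b", "wild", 6, 0.05),
            PopulationSpec("P2", "b", "wild", 6, 0.05),
            PopulationSpec("P3", "a", "wild", 6, 0.05),
            PopulationSpec("O", "o", "wild", 4, 0.3),
        ],
        snp_density=1 / 400,
        introgression_tracts=tracts,
        seed=seed,
    )
    gm, pm, _ = hm.simulate_dataset(cfg)
    return hm.f_branch("(((P1,P2),P3),O);", gm, pm, "O")


def test_fbranch_null_near_zero():
    """No simulated gene flow: every defined cell < 0.02, 5/5 seeds."""
    for seed in range(5):
        fb = _fbranch_sim(seed, gene_flow=False)
        vals = fb.values[~np.isnan(fb.values)]
        assert len(vals) > 0
        assert np.all(vals < 0.02), f"seed {seed}: {vals}"


def test_fbranch_recovers_planted_gene_flow():
    fb = _fbranch_sim(19, gene_flow=True)
    branch, donor, value = fb.max_cell()
    assert (branch, donor) == ("P2", "P3")
    assert value > 0.05


# ---------------------------------------------------------------------------
# discordance
# ---------------------------------------------------------------------------


RELATION = {"a": ["A", "B1"], "b": ["B2"]}


def test_discordance_all_concordant():
    nuc = {"s1": "a", "s2": "b"}
    mito = {"s1": "A", "s2": "B2"}
    rep = hm.discordance_count(nuc, mito, RELATION)
    assert rep.discordant == [] and rep.fraction == 0.0


def test_discordance_crossing_lineages():
    rep = hm.discordance_count({"x": "a"}, {"x": "B2"}, RELATION)
    assert rep.discordant == ["x"]


def test_discordance_study_scale_fraction():
    """12 discordant of 54 samples -> 22% at integer rounding."""
    nuc = {f"s{i:02d}": ("a" if i < 30 else "b") for i in range(54)}
    mito = {}
    for i in range(54):
        s = f"s{i:02d}"
        if i < 12:  # nuclear-a individuals carrying a lineage-b mito clade
            mito[s] = "B2"
        elif i < 30:
            mito[s] = "A" if i % 2 else "B1"
        else:
            mito[s] = "B2"
    rep = hm.discordance_count(nuc, mito, RELATION)
    assert len(rep.discordant) == 12
    assert rep.percent == 22


def test_discordance_missing_label_errors():
    with pytest.raises(ValueError, match="s2"):
        hm.discordance_count({"s1": "a", "s2": "a"}, {"s1": "A"}, RELATION)


def test_labels_from_tree_nearest_reference():
    labels = hm.labels_from_tree(
        "((r1,q1),(r2,q2));", {"r1": "cladeA", "r2": "cladeB"}
    )
    assert labels == {"r1": "cladeA", "q1": "cladeA", "r2": "cladeB", "q2": "cladeB"}
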