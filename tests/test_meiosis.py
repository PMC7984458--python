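"""Closed-form gamete/zygote distributions and recombination algebra."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tetraqtl import meiosis as M
from conftest import table2_bivalent, table2_quadrivalent


# ---------------------------------------------------------------------------
# two-locus law against the printed class probabilities


@pytest.mark.parametrize(
    "alpha,r",
    [(0.0, 0.0), (0.1, 0.05), (0.25, 0.3), (0.2, 0.75), (0.05, 0.5)],
)
def test_two_locus_quadrivalent_matches_closed_form(het2, alpha, r):
    dist = M.two_locus_distribution(het2, "quadrivalent", alpha, r)
    got = M.two_locus_class_probability(dist)
    want = table2_quadrivalent(alpha, r)
    for cls in want:
        assert got[cls] == pytest.approx(want[cls], abs=1e-12)
    assert dist.total() == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("r", [0.0, 0.1, 0.5])
def test_two_locus_bivalent_matches_closed_form(het2, r):
    dist = M.two_locus_distribution(het2, "bivalent", 0.0, r)
    got = M.two_locus_class_probability(dist)
    want = table2_bivalent(r)
    for cls in want:
        assert got[cls] == pytest.approx(want[cls], abs=1e-12)


def test_mixed_is_lambda_mixture_of_pure_laws(het2):
    lam, alpha, r = 0.5, 0.2, 0.1
    mix = M.two_locus_distribution(het2, M.PairingModel("mixed", lam), alpha, r)
    quad = M.two_locus_distribution(het2, "quadrivalent", alpha, r)
    biv = M.two_locus_distribution(het2, "bivalent", 0.0, r)
    keys = set(mix.entries) | set(quad.entries) | set(biv.entries)
    for k in keys:
        expect = lam * quad.entries.get(k, 0.0) + (1 - lam) * biv.entries.get(k, 0.0)
        assert mix.entries.get(k, 0.0) == pytest.approx(expect, abs=1e-14)
    # the printed true-value form of the recombinant parental-type class
    got = M.two_locus_class_probability(mix)["AiBi/AjBk"]
    a_eff = lam * alpha
    assert got == pytest.approx(
        4 * (1 - a_eff) * r * (1 - r) / 3 + 2 * (1 - lam) * r * (1 - r) / 3, abs=1e-12
    )


def test_no_recombination_no_double_reduction_gives_parental_pairs(het2):
    dist = M.two_locus_distribution(het2, "quadrivalent", 0.0, 0.0)
    assert dist.support_size() == 6  # the C(4,2) parental haplotype pairs
    assert dist.dr_mass_at(0) == 0.0
    assert dist.dr_mass_at(1) == 0.0


def test_approximation_preserves_anchor_dr_mass_and_equals_truth_at_lambda1(het2):
    alpha, r = 0.2, 0.1
    for lam in (0.3, 0.5, 1.0):
        mix = M.two_locus_distribution(het2, M.PairingModel("mixed", lam), alpha, r)
        zeta = M.mixed_approximation(lam * alpha, r, het2)
        assert zeta.dr_mass_at(0) == pytest.approx(mix.dr_mass_at(0), abs=1e-12)
        if lam == 1.0:
            for k in set(mix.entries) | set(zeta.entries):
                assert mix.entries.get(k, 0) == pytest.approx(
                    zeta.entries.get(k, 0), abs=1e-14
                )


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    lam=st.floats(0, 1),
    alpha=st.floats(0, 0.25),
    r=st.floats(0, 0.5),
)
def test_normalization_over_parameter_space(lam, alpha, r):
    het2 = M.fully_heterozygous_parent(2)
    dist = M.two_locus_distribution(het2, M.PairingModel("mixed", lam), alpha, r)
    assert dist.total() == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# KL divergence


def test_kl_zero_for_identical_and_at_full_quadrivalent(het2):
    alpha, r = 0.2, 0.1
    g = M.two_locus_distribution(het2, "quadrivalent", alpha, r)
    assert M.kl_divergence_exact(g, g) == 0.0
    mix = M.two_locus_distribution(het2, M.PairingModel("mixed", 1.0), alpha, r)
    zeta = M.mixed_approximation(alpha, r, het2)
    assert M.kl_divergence_exact(mix, zeta) == pytest.approx(0.0, abs=1e-12)


def test_kl_nonnegative_and_brute_force_value(het2):
    # direct summation oracle over the collapsed classes at lambda=0
    alpha, r, lam = 0.2, 0.1, 0.0
    g = M.two_locus_distribution(het2, M.PairingModel("mixed", lam), alpha, r)
    zeta = M.mixed_approximation(lam * alpha, r, het2)
    expected = sum(
        p * math.log(p / zeta.entries[k]) for k, p in g.entries.items() if p > 0
    )
    got = M.kl_divergence_exact(g, zeta)
    assert got == pytest.approx(expected, abs=1e-12)
    assert got >= 0.0


def test_kl_quadratic_printed_values():
    assert M.kl_quadratic(0.585) == pytest.approx(0.103)
    assert round(M.kl_quadratic(0.05), 3) == 0.017
    assert abs(M.kl_quadratic(0.0)) < 1e-4


# ---------------------------------------------------------------------------
# recombination-frequency algebra


def test_r12_printed_examples():
    assert M.map_r12(0.0, 0.3) == pytest.approx(0.3)
    assert M.map_r12(0.75, 0.75) == pytest.approx(0.75)
    assert M.map_r12(0.1, 0.1) == pytest.approx(0.18667, abs=5e-6)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(r1=st.floats(0, 0.75), r2=st.floats(0, 0.75))
def test_r12_range_and_inversion(r1, r2):
    r12 = M.map_r12(r1, r2)
    assert 0.0 <= r12 <= 0.75 + 1e-12
    if r1 < 0.74:
        assert M.solve_r2(r12, r1) == pytest.approx(r2, abs=1e-9)


def test_map_function_consistent_with_r12_composition():
    d1, d2 = 7.0, 13.0
    r1 = M.recombination_fraction(d1)
    r2 = M.recombination_fraction(d2)
    assert M.map_r12(r1, r2) == pytest.approx(M.recombination_fraction(d1 + d2), abs=1e-12)
    b1 = M.recombination_fraction(d1, "bivalent")
    b2 = M.recombination_fraction(d2, "bivalent")
    assert M.map_r12(b1, b2, "bivalent") == pytest.approx(
        M.recombination_fraction(d1 + d2, "bivalent"), abs=1e-12
    )
    assert M.map_distance(r1) == pytest.approx(d1, abs=1e-9)


# ---------------------------------------------------------------------------
# enumeration oracles (independent combinatorial bookkeeping)


def _count_two_locus_pairs():
    haplotypes = list(itertools.product(range(4), range(4)))
    return len({frozenset([h1, h2]) if h1 != h2 else frozenset([h1])
                for h1 in haplotypes for h2 in haplotypes})


def _count_three_locus_bivalent_one_pairing():
    pair1, pair2 = (0, 1), (2, 3)
    h1s = list(itertools.product(pair1, repeat=3))
    h2s = list(itertools.product(pair2, repeat=3))
    return len({(h1, h2) for h1 in h1s for h2 in h2s})


def test_gamete_class_counts_match_combinatorial_oracle(het2, het3):
    assert _count_two_locus_pairs() == 136
    d2 = M.two_locus_distribution(het2, "quadrivalent", 0.1, 0.2)
    assert d2.support_size() == 136
    d3 = M.three_locus_distribution(het3, "quadrivalent", 0.1, 0.1, 0.2)
    assert d3.support_size() == 2080  # = C(64, 2) + 64 unordered haplotype pairs
    db = M.three_locus_distribution(het3, "bivalent", 0.0, 0.1, 0.2, partition=0)
    assert _count_three_locus_bivalent_one_pairing() == 64
    assert db.support_size() == 64


def test_zygote_distribution_counts_and_normalization(het3):
    d3 = M.three_locus_distribution(het3, "quadrivalent", 0.1, 0.1, 0.2)
    db = M.three_locus_distribution(het3, "bivalent", 0.0, 0.1, 0.2, partition=0)
    assert d3.support_size() ** 2 == 4326400
    assert db.support_size() ** 2 == 4096
    # collapsed zygote law on a small biallelic case sums to 1
    par = [("A", "B"), ("A", "b"), ("a", "B"), ("a", "b")]
    g1 = M.two_locus_distribution(par, "quadrivalent", 0.1, 0.2)
    g2 = M.two_locus_distribution(par, "quadrivalent", 0.0, 0.2)
    zy = M.zygote_distribution(g1, g2)
    assert sum(zy.values()) == pytest.approx(1.0, abs=1e-12)
    # degenerate co-parent: zygote classes mirror the other parent's gametes
    mono = [("A", "B")] * 4
    gm = M.two_locus_distribution(mono, "quadrivalent", 0.1, 0.2)
    zy2 = M.zygote_distribution(g1, gm)
    assert len(zy2) == len(g1.entries)


# ---------------------------------------------------------------------------
# three-point / two-point marginal consistency


@pytest.mark.parametrize("alpha,r1,r2", [(0.0, 0.0, 0.0), (0.15, 0.1, 0.2), (0.25, 0.4, 0.3)])
def test_three_point_marginal_recovers_two_point_quadrivalent(het3, alpha, r1, r2):
    d3 = M.three_locus_distribution(het3, "quadrivalent", alpha, r1, r2)
    marg = M.marginalize(d3, [0, 2])
    par2 = [(h[0], h[2]) for h in het3]
    d2 = M.two_locus_distribution(par2, "quadrivalent", alpha, M.map_r12(r1, r2))
    for k in set(marg.entries) | set(d2.entries):
        assert marg.entries.get(k, 0) == pytest.approx(d2.entries.get(k, 0), abs=1e-10)


def test_three_point_marginal_recovers_two_point_bivalent(het3):
    r1, r2 = 0.1, 0.2
    d3 = M.three_locus_distribution(het3, "bivalent", 0.0, r1, r2)
    marg = M.marginalize(d3, [0, 2])
    par2 = [(h[0], h[2]) for h in het3]
    d2 = M.two_locus_distribution(par2, "bivalent", 0.0, M.map_r12(r1, r2, "bivalent"))
    for k in set(marg.entries) | set(d2.entries):
        assert marg.entries.get(k, 0) == pytest.approx(d2.entries.get(k, 0), abs=1e-10)


def test_right_anchored_three_point_is_reflection_of_left_anchored(het3):
    d_right = M.three_locus_distribution(het3, "quadrivalent", 0.2, 0.1, 0.3, proximal="right")
    # reflecting the chromosome maps (r1, r2) -> (r2, r1) and anchors left
    refl = [tuple(reversed(h)) for h in het3]
    d_left = M.three_locus_distribution(refl, "quadrivalent", 0.2, 0.3, 0.1, proximal="left")
    for (h1, h2), p in d_right.entries.items():
        key = tuple(sorted([tuple(reversed(h1)), tuple(reversed(h2))]))
        assert d_left.entries.get(key, 0.0) == pytest.approx(p, abs=1e-12)


# ---------------------------------------------------------------------------
# conditional QTL distribution


def test_conditional_qtl_degenerate_when_fully_linked(informative_parents):
    hap1, hap2, _, _ = informative_parents
    q1, q2 = (1, 1, 1, 0), (1, 0, 0, 0)
    obs = ({"A1": 1, "A2": 1, "C1": 1, "C2": 1}, {"B1": 1, "B2": 1, "D1": 1, "D2": 1})
    v = M.conditional_qtl_given_flanking(hap1, hap2, q1, q2, obs, 0.0, 0.0, 0.0)
    assert v == pytest.approx(np.eye(5)[3])  # origins 0,1 of each parent: 2 + 1 copies


def test_conditional_qtl_uninformative_markers_give_segregation_prior():
    mono1 = [("X", "Y")] * 4
    mono2 = [("X", "Y")] * 4
    q1, q2 = (1, 1, 1, 0), (1, 0, 0, 0)
    obs = ({"X": 4}, {"Y": 4})
    v = M.conditional_qtl_given_flanking(mono1, mono2, q1, q2, obs, 0.0, 0.1, 0.1)
    # conditioning adds nothing: the chain's marginal at the QTL, i.e.
    # single-locus segregation of QQQq x Qqqq at the induced DR coefficient
    a_qtl = M.induced_alpha_profile(0.0, [0.1])[1]
    proc = M.origin_process("quadrivalent")
    nu = proc.initial(a_qtl)
    expected = np.zeros(5)
    for q in (np.array(q1), np.array(q2)):
        c = np.zeros(3)
        np.add.at(c, q[proc.origins[:, 0]] + q[proc.origins[:, 1]], nu)
        expected = (
            c if not expected.any() else np.convolve(expected[:3], c)
        )
    assert v == pytest.approx(expected, abs=1e-12)
    # and with the QTL fused to the anchor (alpha 0 there) the classical
    # no-DR segregation ratios appear
    v0 = M.conditional_qtl_given_flanking(mono1, mono2, q1, q2, obs, 0.0, 0.0, 0.1)
    assert v0 == pytest.approx([0.0, 0.25, 0.5, 0.25, 0.0], abs=1e-12)


def test_conditional_qtl_matches_exhaustive_three_locus_table(informative_parents):
    """Validate the contraction against the enumerated joint zygote table."""
    hap1, hap2, _, _ = informative_parents
    alpha, r1, r2 = 0.1, 0.1, 0.1
    q1, q2 = (1, 1, 1, 0), (1, 0, 0, 0)
    het3_1 = [(h[0], f"Q{i+1}", h[1]) for i, h in enumerate(hap1)]
    het3_2 = [(h[0], f"R{i+1}", h[1]) for i, h in enumerate(hap2)]
    d1 = M.three_locus_distribution(het3_1, "quadrivalent", alpha, r1, r2)
    d2 = M.three_locus_distribution(het3_2, "quadrivalent", alpha, r1, r2)
    obs = ({"A1": 1, "A3": 1, "C2": 1, "C4": 1}, {"B1": 1, "B2": 1, "D2": 1, "D3": 1})

    def qcount(hap_pair, placement, labels):
        idx = {f"{labels}{i+1}": placement[i] for i in range(4)}
        return idx[hap_pair[0][1]] + idx[hap_pair[1][1]]

    joint = np.zeros(5)
    for (g1a, g1b), p1 in d1.entries.items():
        if {g1a[0], g1b[0]} != {"A1", "A3"} or {g1a[2], g1b[2]} != {"B1", "B2"}:
            continue
        for (g2a, g2b), p2 in d2.entries.items():
            if {g2a[0], g2b[0]} != {"C2", "C4"} or {g2a[2], g2b[2]} != {"D2", "D3"}:
                continue
            k = qcount((g1a, g1b), q1, "Q") + qcount((g2a, g2b), q2, "R")
            joint[k] += p1 * p2
    expected = joint / joint.sum()
    got = M.conditional_qtl_given_flanking(hap1, hap2, q1, q2, obs, alpha, r1, r2)
    assert got == pytest.approx(expected, abs=1e-10)


def test_conditional_qtl_rejects_impossible_marker_zygote(informative_parents):
    hap1, hap2, _, _ = informative_parents
    obs = ({"A1": 2, "C1": 2}, {"B1": 1, "B2": 1, "D1": 1, "D2": 1})
    with pytest.raises(ValueError, match="zero probability"):
        M.conditional_qtl_given_flanking(
            hap1, hap2, (1, 1, 1, 0), (1, 0, 0, 0), obs, 0.0, 0.1, 0.1
        )


# ---------------------------------------------------------------------------
# single-locus estimation of alpha


def _simulate_single_locus(p1, p2, alpha, n, rng):
    from tetraqtl.simulate import _sample_gamete_origins

    loci = np.array([0.0])
    o1, _ = _sample_gamete_origins(n, loci, 1.0, alpha, rng)
    o2, _ = _sample_gamete_origins(n, loci, 1.0, alpha, rng)
    obs = []
    for i in range(n):
        counts = {}
        for al in (
            p1[o1[i, 0, 0]], p1[o1[i, 0, 1]], p2[o2[i, 0, 0]], p2[o2[i, 0, 1]]
        ):
            counts[al] = counts.get(al, 0) + 1
        obs.append(counts)
    dr = (o1[:, 0, 0] == o1[:, 0, 1]) | (o2[:, 0, 0] == o2[:, 0, 1])
    return obs, dr


def test_alpha_estimate_recovers_truth_and_zero():
    p1 = ("A", "A", "A", "a")
    p2 = ("A", "a", "a", "a")
    rng = np.random.default_rng(7)
    obs, _ = _simulate_single_locus(p1, p2, 0.0, 200, rng)
    est0 = M.estimate_alpha_single_locus(obs, p1, p2)
    assert est0 == pytest.approx(0.0, abs=0.02)
    ests = []
    for rep in range(20):
        obs, _ = _simulate_single_locus(p1, p2, 0.15, 200, rng)
        ests.append(M.estimate_alpha_single_locus(obs, p1, p2))
    mc_se = np.std(ests) / np.sqrt(len(ests))
    assert abs(np.mean(ests) - 0.15) < 3 * mc_se + 0.01


def test_alpha_estimate_biased_down_when_observable_carriers_removed():
    """Removing visibly incompatible offspring drags the estimate far below truth."""
    p1 = ("A", "A", "A", "a")
    p2 = ("A", "a", "a", "a")
    rng = np.random.default_rng(11)
    biv = M._zygote_class_probs(
        [(h,) for h in p1], [(h,) for h in p2], 0.0, "bivalent"
    )
    full_ests, excl_ests = [], []
    for rep in range(15):
        obs, _ = _simulate_single_locus(p1, p2, 0.2, 200, rng)
        full_ests.append(M.estimate_alpha_single_locus(obs, p1, p2))
        observable = [
            i for i, o in enumerate(obs) if M.observation_class(o) not in biv
        ]
        excl_ests.append(M.estimate_alpha_single_locus(obs, p1, p2, exclude=observable))
    assert np.mean(excl_ests) < np.mean(full_ests)
    assert np.mean(excl_ests) < 0.2 * 0.75  # clearly below the simulated value


def test_alpha_estimate_undefined_for_monomorphic_parents():
    p = ("A", "A", "A", "A")
    obs = [{"A": 4}] * 50
    assert M.estimate_alpha_single_locus(obs, p, p) is None


# ---------------------------------------------------------------------------
# input validation


def test_invalid_parameters_raise(het2):
    with pytest.raises(ValueError):
        M.two_locus_distribution(het2, "quadrivalent", 0.3, 0.1)  # alpha > 0.25
    with pytest.raises(ValueError):
        M.two_locus_distribution(het2, "quadrivalent", 0.1, 0.8)  # r > 0.75
    with pytest.raises(ValueError):
        M.two_locus_distribution(het2[:3], "quadrivalent", 0.1, 0.1)
    with pytest.raises(ValueError):
        M.PairingModel("mixed")  # lam required
    with pytest.raises(ValueError):
        M.three_locus_distribution(
            M.fully_heterozygous_parent(3), "quadrivalent", 0.1, 0.1, 0.1, proximal="middle"
        )
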