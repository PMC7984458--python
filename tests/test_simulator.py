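"""Simulator: generative-analytic agreement, scoring, incompatibility."""


import numpy as np
import pytest
from scipy.stats import chisquare

from tetraqtl import meiosis as M
from tetraqtl import simulate as S
from tetraqtl.simulate import _sample_gamete_origins


def _empirical_two_locus(het2, lam, alpha, d_cm, n, seed):
    rng = np.random.default_rng(seed)
    loci = np.array([0.0, d_cm])
    ori, _ = _sample_gamete_origins(n, loci, lam, alpha, rng)
    counts: dict = {}
    for i in range(n):
        h1 = (het2[ori[i, 0, 0]][0], het2[ori[i, 1, 0]][1])
        h2 = (het2[ori[i, 0, 1]][0], het2[ori[i, 1, 1]][1])
        key = tuple(sorted([h1, h2]))
        counts[key] = counts.get(key, 0) + 1
    return counts


@pytest.mark.parametrize(
    "lam,alpha,d_cm,seed",
    [(1.0, 0.15, 8.0, 0), (0.0, 0.0, 12.0, 1), (0.5, 0.2, 5.0, 2)],
)
def test_two_locus_class_frequencies_match_closed_form(het2, lam, alpha, d_cm, seed):
    n = 100_000
    counts = _empirical_two_locus(het2, lam, alpha, d_cm, n, seed)
    # expected law mixes the pairing-specific recombination fractions
    rq = M.recombination_fraction(d_cm, "quadrivalent")
    rb = M.recombination_fraction(d_cm, "bivalent")
    q = M.two_locus_distribution(het2, "quadrivalent", alpha, rq)
    b = M.two_locus_distribution(het2, "bivalent", 0.0, rb)
    expected = {}
    for k in set(q.entries) | set(b.entries):
        expected[k] = lam * q.entries.get(k, 0.0) + (1 - lam) * b.entries.get(k, 0.0)
    keys = [k for k, p in expected.items() if p * n >= 5]
    obs = np.array([counts.get(k, 0) for k in keys], dtype=float)
    exp = np.array([expected[k] * n for k in keys])
    rest_obs = n - obs.sum()
    rest_exp = n - exp.sum()
    if rest_exp > 5:
        obs = np.append(obs, rest_obs)
        exp = np.append(exp, rest_exp)
    else:
        exp = exp * obs.sum() / exp.sum()
    stat, p = chisquare(obs, exp)
    assert p > 0.01


def test_single_locus_dr_fraction_matches_alpha(het2):
    rng = np.random.default_rng(5)
    alpha, n = 0.12, 100_000
    ori, quad = _sample_gamete_origins(n, np.array([0.0]), 1.0, alpha, rng)
    dr = (ori[:, 0, 0] == ori[:, 0, 1]).mean()
    assert dr == pytest.approx(alpha, abs=3 * np.sqrt(alpha * (1 - alpha) / n))


def test_bivalent_meioses_never_show_double_reduction():
    rng = np.random.default_rng(6)
    ori, quad = _sample_gamete_origins(5000, np.array([0.0, 50.0, 100.0]), 0.0, 0.25, rng)
    assert not quad.any()
    assert np.all(ori[:, :, 0] != ori[:, :, 1])


def test_induced_dr_profile_along_chromosome_matches_chain():
    rng = np.random.default_rng(7)
    loci = np.array([0.0, 25.0, 50.0, 100.0])
    ori, _ = _sample_gamete_origins(200_000, loci, 1.0, 0.0, rng)
    emp = (ori[:, :, 0] == ori[:, :, 1]).mean(axis=0)
    r = [M.recombination_fraction(d) for d in np.diff(loci)]
    theory = M.induced_alpha_profile(0.0, r)
    assert emp == pytest.approx(theory, abs=0.005)


def test_seeded_determinism():
    cfg = S.table3_config(0.5, seed=33, n_offspring=50)
    p1 = S.simulate_population(cfg)
    p2 = S.simulate_population(cfg)
    assert np.array_equal(p1.dataset.y, p2.dataset.y)
    assert p1.dataset.observations == p2.dataset.observations
    assert np.array_equal(p1.origins, p2.origins)


def test_score_markers_model_ii_is_projection_of_model_i():
    cfg = S.table3_config(1.0, seed=8, n_offspring=40, n_markers=8)
    pop = S.simulate_population(cfg)
    marker_idx = [j for j in range(len(pop.loci_cm)) if j != pop.qtl_index]
    dosage = S.score_markers(pop.origins, cfg.parent1, cfg.parent2, marker_idx, True)
    presence = S.score_markers(pop.origins, cfg.parent1, cfg.parent2, marker_idx, False)
    for i in range(40):
        for j in range(8):
            assert frozenset(dosage[i][j]) == presence[i][j]
            assert sum(dosage[i][j].values()) == 4


def test_phenotypes_hit_target_heritability():
    cfg = S.table3_config(1.0, seed=12, heritability=0.25, n_offspring=4000)
    pop = S.simulate_population(cfg)
    assert pop.realized_h2 == pytest.approx(0.25, abs=1e-9)  # exact by construction
    resid = pop.dataset.y - pop.genotypic_value
    assert np.var(resid) == pytest.approx(pop.sigma**2, rel=0.1)


def test_zero_effects_give_zero_genetic_variance_error():
    cfg = S.table3_config(1.0, seed=1)
    cfg.theta = (0.0, 0.0, 0.0, 0.0)
    with pytest.raises(ValueError, match="zero genetic variance"):
        S.simulate_population(cfg)


# ---------------------------------------------------------------------------
# bivalent incompatibility


def test_detect_incompatible_none_under_pure_bivalent():
    pop = S.simulate_population(S.table3_config(0.0, seed=14, n_offspring=80))
    flags, detail = S.detect_incompatible(pop.dataset)
    assert not flags.any()
    assert all(d == [] for d in detail)


def test_detect_incompatible_flags_three_chromosome_gamete():
    """A three-locus gamete drawing on three parental chromosomes is flagged
    even though every single-locus genotype is individually possible."""
    from tetraqtl.io import Dataset

    cm = np.array([0.0, 5.0, 10.0])
    p1 = [tuple(f"A{h+1}" for h in range(4)),
          tuple(f"B{h+1}" for h in range(4)),
          tuple(f"C{h+1}" for h in range(4))]
    p2 = [("D", "D", "D", "D")] * 1 + [("E", "E", "E", "E")] + [("F", "F", "F", "F")]
    # maternal gamete A1B1C1 / A2B3C4 uses chromosomes 1, 2, 3, 4 of P1
    obs = [[{"A1": 1, "A2": 1, "D": 2}, {"B1": 1, "B3": 1, "E": 2}, {"C1": 1, "C4": 1, "F": 2}]]
    ds = Dataset(cm, ["m1", "m2", "m3"], p1, p2, ["x"], obs, np.array([0.0]))
    flags, detail = S.detect_incompatible(ds)
    assert flags[0]
    assert detail[0] == ["multilocus"]
    # policy variants
    _, _, removed = S.detect_incompatible(ds, policy="remove")
    assert removed.individuals == []


def test_detect_incompatible_flags_single_locus_dr_evidence():
    from tetraqtl.io import Dataset

    cm = np.array([0.0, 5.0])
    p1 = [tuple(f"A{h+1}" for h in range(4))] * 2
    p2 = [("D", "D", "D", "D")] * 2
    # gamete A1A1 from A1A2A3A4 requires double reduction
    obs = [[{"A1": 2, "D": 2}, {"A1": 1, "A2": 1, "D": 2}]]
    ds = Dataset(cm, ["m1", "m2"], p1, p2, ["x"], obs, np.array([0.0]))
    flags, detail = S.detect_incompatible(ds)
    assert flags[0] and detail[0] == ["m1"]


def test_removal_rate_no_false_positives_at_scale():
    from conftest import bivalent_compatible as _bivalent_compatible

    pop = S.simulate_population(S.table3_config(0.5, seed=15, n_offspring=200))
    flags, _ = S.detect_incompatible(pop.dataset)
    # flagged implies true double reduction or a gamete that no bivalent
    # pairing could produce (more than two contributing chromosomes)
    for i in np.flatnonzero(flags):
        ok = pop.dr_any[i] or any(
            not _bivalent_compatible(pop.origins[i, parent]) for parent in (0, 1)
        )
        assert ok


# ---------------------------------------------------------------------------
# double-reduction observability (single-locus analysis)


def _biallelic(dosage):
    return tuple("A" if h < dosage else "a" for h in range(4))


def test_expected_dr_fraction_closed_form():
    p = _biallelic(2)
    for a in (0.0, 0.1, 0.25):
        expected, observable = S.expected_dr_carriers(p, _biallelic(1), a)
        assert expected == pytest.approx(1 - (1 - a) ** 2)
        assert 0.0 <= observable <= expected + 1e-12


def test_three_of_twelve_biallelic_configs_have_no_observable_dr():
    """For 3 of the 12 segregating parental dosage configurations no
    bivalent-incompatible offspring phenotype exists at all."""
    configs = [
        (d1, d2)
        for d1 in range(5)
        for d2 in range(d1 + 1)
        if not (d1 in (0, 4) and d2 in (0, 4))
    ]
    assert len(configs) == 12
    silent = []
    for d1, d2 in configs:
        _, obs = S.expected_dr_carriers(_biallelic(d1), _biallelic(d2), 0.2)
        if obs < 1e-12:
            silent.append((d1, d2))
    assert len(silent) == 3
    assert set(silent) == {(2, 2), (2, 0), (4, 2)}
    # and observable < expected wherever anything is observable at all
    for d1, d2 in set(configs) - set(silent):
        exp, obs = S.expected_dr_carriers(_biallelic(d1), _biallelic(d2), 0.2)
        assert 0.0 < obs < exp
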