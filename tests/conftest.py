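import numpy as np
import pytest

from tetraqtl import meiosis as M
from tetraqtl import simulate as S


@pytest.fixture(scope="session")
def het2():
    """Fully heterozygous two-locus parent (four distinct alleles per locus)."""
    return M.fully_heterozygous_parent(2)


@pytest.fixture(scope="session")
def het3():
    return M.fully_heterozygous_parent(3)


@pytest.fixture(scope="session")
def informative_parents():
    """Fully informative multi-allelic parents as (per-homologue, per-marker) views."""
    hap1 = [(f"A{i+1}", f"B{i+1}") for i in range(4)]
    hap2 = [(f"C{i+1}", f"D{i+1}") for i in range(4)]
    per_marker1 = [tuple(h[j] for h in hap1) for j in range(2)]
    per_marker2 = [tuple(h[j] for h in hap2) for j in range(2)]
    return hap1, hap2, per_marker1, per_marker2


@pytest.fixture(scope="session")
def small_population():
    """A small quadrivalent Table-3-style population shared across tests."""
    cfg = S.table3_config(1.0, seed=42, n_offspring=150, n_markers=10)
    return S.simulate_population(cfg)


def bivalent_compatible(meiosis_origins):
    """True if some homologue pairing could have produced this gamete:
    each chromatid's origins stay within one bivalent of a disjoint pair."""
    c1 = set(meiosis_origins[:, 0])
    c2 = set(meiosis_origins[:, 1])
    partitions = (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2)))
    for p1, p2 in partitions:
        if (c1 <= set(p1) and c2 <= set(p2)) or (c1 <= set(p2) and c2 <= set(p1)):
            return True
    return False


def table2_quadrivalent(a, r):
    """Closed-form class probabilities of a quadrivalent meiosis."""
    return {
        "AiBi/AiBi": a * (1 - r) ** 2,
        "AiBj/AiBj": a * r * r / 3,
        "AiBi/AiBj": 2 * a * r * (1 - r),
        "AiBj/AiBk": 2 * a * r * r / 3,
        "AiBi/AjBi": 2 * (1 - a) * r * (1 - r) / 3,
        "AiBj/AkBj": 2 * (1 - a) * r * r / 9,
        "AiBi/AjBj": (1 - a) * (1 - r) ** 2,
        "AiBi/AjBk": 4 * (1 - a) * r * (1 - r) / 3,
        "AiBj/AjBi": (1 - a) * r * r / 9,
        "AiBj/AjBk": 4 * (1 - a) * r * r / 9,
        "AiBj/AkBl": 2 * (1 - a) * r * r / 9,
    }


def table2_bivalent(r):
    d = {k: 0.0 for k in table2_quadrivalent(0.0, 0.0)}
    d["AiBi/AjBj"] = (1 - r) ** 2
    d["AiBi/AjBk"] = 2 * r * (1 - r)
    d["AiBj/AkBl"] = r * r
    return d
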