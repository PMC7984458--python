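"""Orthogonal quantitative genetic model of a biallelic tetraploid QTL.

The genotypic value of the dosage-``k`` genotype (``k`` copies of the
trait-increasing allele Q, k = 0..4) is

    G_k = mu + w_k1 theta_1 + w_k2 theta_2 + w_k3 theta_3 + w_k4 theta_4

where theta_1..theta_4 are the monogenic, digenic, trigenic and quadrigenic
effects and the contrast scales ``w_kj`` are orthogonal polynomials of the
dosage under the genotype-probability weights of the mapping population:
``sum_k p_k w_kj = 0`` and ``sum_k p_k w_kj w_kj' = 0`` for j != j'.  The
contrasts here are monic orthogonal polynomials divided by j! (the
finite-difference scaling, on which theta_j is the j-th order interaction
per unit dosage step), a fixed scaling choice that leaves G_k, likelihoods,
LOD, BIC and the variance decomposition untouched and only fixes the units
of the theta estimates, keeping them comparable across interaction orders.

Depending on the parental QTL configuration some dosage classes never
segregate; the corresponding higher-order effects are not estimable and are
reported as masked (NaN), never as zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ContrastMatrix",
    "GeneticEffects",
    "ParentalQTLConfiguration",
    "build_contrasts",
    "genotype_means",
    "solve_effects",
    "enumerate_configurations",
    "count_full_model_parameters",
    "variance_decomposition",
]

_SUPPORT_TOL = 1e-9


@dataclass
class ContrastMatrix:
    """Orthogonal contrast scales for a given QTL genotype distribution."""

    w: np.ndarray  # (5, 4), NaN outside the estimable block
    genotype_probs: np.ndarray  # (5,)
    support: np.ndarray  # (5,) bool, classes with positive probability
    n_effects: int  # number of estimable theta (= #support classes - 1)


@dataclass
class GeneticEffects:
    """mu, theta_1..theta_4 and residual variance; masked where inestimable."""

    mu: float
    theta: np.ndarray  # (4,), NaN where not estimable
    sigma2: float
    estimable: np.ndarray  # (4,) bool

    def as_dict(self) -> dict:
        t = [None if not e else float(v) for v, e in zip(self.theta, self.estimable)]
        return {
            "mu": float(self.mu),
            "theta1": t[0],
            "theta2": t[1],
            "theta3": t[2],
            "theta4": t[3],
            "sigma2": float(self.sigma2),
        }


def build_contrasts(genotype_probs: np.ndarray) -> ContrastMatrix:
    """Weighted Gram–Schmidt contrasts of dosage powers {k, k², k³, k⁴}.

    Each contrast is the monic orthogonal polynomial of its order under the
    genotype-probability weights, divided by order! (finite-difference
    scaling).  ``genotype_probs`` is the 5-vector of QTL genotype
    probabilities (summing to 1).  Raises for a degenerate single-class
    distribution.
    """
    p = np.asarray(genotype_probs, dtype=float)
    if p.shape != (5,) or np.any(p < -1e-12):
        raise ValueError("genotype_probs must be a non-negative 5-vector")
    if abs(p.sum() - 1.0) > 1e-3:
        raise ValueError("genotype_probs must sum to 1")
    p = p / p.sum()
    support = p > _SUPPORT_TOL
    n_classes = int(support.sum())
    if n_classes < 2:
        raise ValueError("degenerate genotype distribution: no contrasts exist")
    n_effects = n_classes - 1
    k = np.arange(5, dtype=float)
    w = np.full((5, 4), np.nan)
    basis = [np.ones(5)]
    ps = p * support  # weights, zero off support
    fact = 1.0
    for j in range(1, n_effects + 1):
        v = k**j
        for b in basis:
            v = v - (ps * v * b).sum() / (ps * b * b).sum() * b
        fact *= j
        w[:, j - 1] = np.where(support, v / fact, np.nan)
        basis.append(np.where(support, v, 0.0))
    return ContrastMatrix(w=w, genotype_probs=p, support=support, n_effects=n_effects)


def genotype_means(effects: GeneticEffects, W: ContrastMatrix) -> np.ndarray:
    """G_k = mu + sum_j w_kj theta_j on the estimable support (NaN elsewhere)."""
    G = np.full(5, np.nan)
    for k in range(5):
        if not W.support[k]:
            continue
        g = effects.mu
        for j in range(W.n_effects):
            g += W.w[k, j] * effects.theta[j]
        G[k] = g
    return G


def solve_effects(G: np.ndarray, W: ContrastMatrix, sigma2: float = np.nan) -> GeneticEffects:
    """Invert the genotype-mean system for (mu, theta) on the support.

    With full support this is the 5x5 inversion of the contrast design; for
    crosses segregating fewer dosage classes the restricted square system is
    solved and the remaining effects are masked.
    """
    G = np.asarray(G, dtype=float)
    sup = np.flatnonzero(W.support)
    E = W.n_effects
    X = np.column_stack([np.ones(len(sup))] + [W.w[sup, j] for j in range(E)])
    sol = np.linalg.solve(X, G[sup])
    theta = np.full(4, np.nan)
    theta[:E] = sol[1:]
    estimable = np.zeros(4, dtype=bool)
    estimable[:E] = True
    return GeneticEffects(mu=float(sol[0]), theta=theta, sigma2=float(sigma2), estimable=estimable)


def variance_decomposition(
    effects: GeneticEffects, W: ContrastMatrix, genotype_probs: np.ndarray | None = None
) -> "tuple[float, float]":
    """(Vg %, rho-additive %) of a fitted QTL.

    Vg% is the proportion of phenotypic variance explained by the QTL
    (genetic variance of the genotype means over the genotype distribution,
    against genetic + residual); rho is the share of that genetic variance
    carried by the monogenic (additive) contrast, which is exact because the
    contrasts are orthogonal under the same weights.
    """
    p = W.genotype_probs if genotype_probs is None else np.asarray(genotype_probs, float)
    G = genotype_means(effects, W)
    ps = np.where(W.support, p, 0.0)
    ps = ps / ps.sum()
    g = np.where(W.support, G, 0.0)
    mean = (ps * g).sum()
    vg = (ps * (g - mean) ** 2).sum()
    if vg <= 0:
        raise ValueError("zero genetic variance")
    add = effects.theta[0] ** 2 * (ps * np.where(W.support, W.w[:, 0], 0.0) ** 2).sum()
    vg_percent = 100.0 * vg / (vg + effects.sigma2)
    rho = 100.0 * add / vg
    return float(vg_percent), float(rho)


# ---------------------------------------------------------------------------
# parental QTL configurations


# the nine admissible dosage combinations with P1 the higher-value parent
_DOSAGE_PAIRS = ((4, 3), (4, 2), (4, 1), (3, 2), (3, 1), (3, 0), (2, 1), (2, 0), (1, 0))
# dosage pairs whose likelihood profile duplicates another configuration's
# (at least one parent does not segregate in the offspring); resolved by the
# sign of the monogenic effect
_MIRRORED_PAIRS = {(4, 1), (3, 0)}


@dataclass(frozen=True)
class ParentalQTLConfiguration:
    """Phase-labelled placement of Q on the four homologues of each parent."""

    p1: tuple  # 0/1 per homologue of P1
    p2: tuple

    @property
    def dosage(self) -> "tuple[int, int]":
        return (sum(self.p1), sum(self.p2))

    @property
    def label(self) -> str:
        s1 = "".join("Q" if b else "q" for b in self.p1)
        s2 = "".join("Q" if b else "q" for b in self.p2)
        return f"{s1}x{s2}"

    @property
    def mirrored(self) -> bool:
        return self.dosage in _MIRRORED_PAIRS

    def mirror_partner(self) -> "ParentalQTLConfiguration | None":
        """The configuration with the identical likelihood profile, if any.

        Complementing the non-segregating parent's placement swaps Q and q
        on that parent, which relabels the offspring dosage classes without
        changing their partition of the population.
        """
        if not self.mirrored:
            return None
        if self.dosage == (4, 1):
            return ParentalQTLConfiguration(self.p1, tuple(1 - b for b in self.p2))
        return ParentalQTLConfiguration(tuple(1 - b for b in self.p1), self.p2)

    def offspring_support(self, double_reduction: bool) -> np.ndarray:
        """(5,) bool: dosage classes that can segregate in the offspring."""

        def gamete_counts(placement) -> set:
            d = sum(placement)
            counts = {c1 + c2 for c1, c2 in itertools.combinations(placement, 2)}
            if double_reduction:
                counts |= {2 * c for c in placement}
            return counts
        c1 = gamete_counts(self.p1)
        c2 = gamete_counts(self.p2)
        sup = np.zeros(5, dtype=bool)
        for a in c1:
            for b in c2:
                sup[a + b] = True
        return sup


def enumerate_configurations() -> "list[ParentalQTLConfiguration]":
    """All phase-labelled parental QTL configurations (92 in total).

    Iterates the nine admissible dosage combinations and, within each, every
    distinct placement of the Q alleles on the four phase-labelled
    homologues of each parent; deterministic order (dosage pair, then
    lexicographic placements).
    """
    out = []
    for d1, d2 in _DOSAGE_PAIRS:
        for c1 in itertools.combinations(range(4), d1):
            p1 = tuple(1 if h in c1 else 0 for h in range(4))
            for c2 in itertools.combinations(range(4), d2):
                p2 = tuple(1 if h in c2 else 0 for h in range(4))
                out.append(ParentalQTLConfiguration(p1, p2))
    return out


def count_full_model_parameters(
    alleles_p1: "int | list" = 4, alleles_p2: "int | list" = 4
) -> "tuple[int, int, int, int, int]":
    """Effect counts of the full multi-allelic quantitative genetic model.

    Counts, by exhaustive enumeration, the allelic subsets of size 1..4 that
    can co-occur in an offspring genotype (each gamete carries two alleles
    of its parent, both possibly the same copy through double reduction):
    (monogenic, digenic, trigenic, quadrigenic, total).  Two fully divergent
    parents give (8, 28, 48, 36), total 120.
    """
    a1 = [f"P1.{i}" for i in range(alleles_p1)] if isinstance(alleles_p1, int) else list(alleles_p1)
    a2 = [f"P2.{i}" for i in range(alleles_p2)] if isinstance(alleles_p2, int) else list(alleles_p2)
    gametes1 = {frozenset([x, y]) for x in a1 for y in a1}
    gametes2 = {frozenset([x, y]) for x in a2 for y in a2}
    subsets: "set[frozenset]" = set()
    for g1 in gametes1:
        for g2 in gametes2:
            alleles = g1 | g2
            for size in range(1, 5):
                for sub in itertools.combinations(sorted(alleles), size):
                    subsets.add(frozenset(sub))
    counts = [0, 0, 0, 0]
    for s in subsets:
        counts[len(s) - 1] += 1
    return (*counts, sum(counts))
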