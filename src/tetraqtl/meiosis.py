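"""Gamete and zygote genotype distributions of an autotetraploid meiosis.

An autotetraploid transmits a *diploid* gamete: two chromatids drawn from the
four homologous chromosomes.  Which pairs of chromatids can occur, and with
what probability, depends on how the homologues pair at meiosis:

* **bivalent** pairing — the four homologues form two pairs (three possible
  partitions); the gamete receives one (possibly recombinant) chromatid from
  each pair.  Sister chromatids can never end up together, so double
  reduction is impossible and at most two parental homologues contribute.
* **quadrivalent** pairing — all four homologues pair as one unit; both
  sister copies of a chromosome segment may enter the same gamete (*double
  reduction*, coefficient ``alpha`` per locus, at most 1/4).
* **mixed** pairing — each meiosis is quadrivalent with probability
  ``lambda`` and bivalent otherwise; the effective double-reduction
  coefficient is ``lambda * alpha``.

Everything in this module derives from a single chromatid-origin process.
A gamete is an ordered pair of origin labels (which homologue each chromatid
copies) at every locus.  At the centromere-proximal anchor locus the pair is
identical with probability ``alpha`` (uniform over the four homologues) and
otherwise uniform over the twelve ordered distinct pairs.  Moving along the
chromosome, each chromatid origin evolves independently as a symmetric
Markov chain: under quadrivalent pairing it keeps its origin with
probability ``1 - r`` and switches to each of the other three with
probability ``r/3``; under bivalent pairing it switches only within its own
bivalent, with probability ``r``.  This process reproduces the closed-form
two-locus class probabilities of tetrasomic linkage analysis exactly, and
composes across intervals according to ``r12 = r1 + r2 - 4 r1 r2 / 3``
(quadrivalent) or the classical ``r12 = r1 + r2 - 2 r1 r2`` (bivalent).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "PairingModel",
    "GameteDistribution",
    "fully_heterozygous_parent",
    "map_r12",
    "solve_r2",
    "recombination_fraction",
    "map_distance",
    "effective_alpha",
    "induced_alpha_profile",
    "two_locus_distribution",
    "three_locus_distribution",
    "single_locus_distribution",
    "mixed_approximation",
    "zygote_distribution",
    "kl_divergence_exact",
    "kl_quadratic",
    "classify_two_locus_gamete",
    "two_locus_class_probability",
    "conditional_qtl_given_flanking",
    "estimate_alpha_single_locus",
]

_PROB_TOL = 1e-12
ALPHA_MAX = 0.25
R_MAX = 0.75

# the three ways four homologues {0,1,2,3} can split into two bivalents
_PARTITIONS = (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2)))


@dataclass(frozen=True)
class PairingModel:
    """Chromosome pairing mode of a meiosis.

    ``mode`` is one of ``"bivalent"``, ``"quadrivalent"``, ``"mixed"``;
    ``lam`` is the proportion of quadrivalent pairing and is only free under
    ``"mixed"`` (bivalent pins it to 0, quadrivalent to 1).
    """

    mode: str
    lam: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("bivalent", "quadrivalent", "mixed"):
            raise ValueError(f"unknown pairing mode {self.mode!r}")
        lam = self.lam
        if self.mode == "bivalent":
            lam = 0.0
        elif self.mode == "quadrivalent":
            lam = 1.0
        elif lam is None:
            raise ValueError("mixed pairing requires lam")
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"lam must be in [0, 1], got {lam}")
        object.__setattr__(self, "lam", float(lam))

    @staticmethod
    def coerce(value: "PairingModel | str", lam: float | None = None) -> "PairingModel":
        if isinstance(value, PairingModel):
            return value
        return PairingModel(value, lam)


def _check_r(r: float, name: str = "r") -> None:
    if not 0.0 <= r <= R_MAX:
        raise ValueError(f"{name} must be in [0, {R_MAX}], got {r}")


def _check_alpha(alpha: float) -> None:
    if not 0.0 <= alpha <= ALPHA_MAX:
        raise ValueError(f"alpha must be in [0, {ALPHA_MAX}], got {alpha}")


# ---------------------------------------------------------------------------
# recombination-frequency algebra


def map_r12(r1: float, r2: float, mode: str = "quadrivalent") -> float:
    """Marker-marker recombination fraction implied by the two flanking ones.

    Quadrivalent: ``r12 = r1 + r2 - 4 r1 r2 / 3`` (upper bound 0.75).
    Bivalent: the classical ``r12 = r1 + r2 - 2 r1 r2``.
    """
    _check_r(r1, "r1")
    _check_r(r2, "r2")
    if mode == "quadrivalent":
        return r1 + r2 - 4.0 * r1 * r2 / 3.0
    if mode == "bivalent":
        if r1 > 0.5 or r2 > 0.5:
            raise ValueError("bivalent recombination fractions are bounded by 0.5")
        return r1 + r2 - 2.0 * r1 * r2
    raise ValueError(f"unknown mode {mode!r}")


def solve_r2(r12: float, r1: float, mode: str = "quadrivalent") -> float:
    """Invert :func:`map_r12` for the second flanking fraction."""
    _check_r(r12, "r12")
    _check_r(r1, "r1")
    if mode == "quadrivalent":
        denom = 1.0 - 4.0 * r1 / 3.0
        if abs(denom) < 1e-12:
            raise ValueError("r1 = 0.75 leaves r2 unidentifiable")
        r2 = (r12 - r1) / denom
    elif mode == "bivalent":
        denom = 1.0 - 2.0 * r1
        if abs(denom) < 1e-12:
            raise ValueError("r1 = 0.5 leaves r2 unidentifiable")
        r2 = (r12 - r1) / denom
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not -1e-12 <= r2 <= R_MAX + 1e-12:
        raise ValueError(f"no feasible r2 for r12={r12}, r1={r1} ({mode})")
    return min(max(r2, 0.0), R_MAX)


def recombination_fraction(d_cm: float, mode: str = "quadrivalent") -> float:
    """Map distance (cM) -> recombination fraction, no interference.

    For the bivalent two-state origin chain this is Haldane's map function,
    ``r = (1 - exp(-d/50)) / 2``.  For the quadrivalent four-state chain the
    analogous no-interference map is ``r = 3 (1 - exp(-d/75)) / 4``, the
    unique function that composes according to ``r12 = r1 + r2 - 4 r1 r2/3``.
    """
    if d_cm < 0:
        raise ValueError("map distance must be non-negative")
    if mode == "quadrivalent":
        return 0.75 * (1.0 - math.exp(-d_cm / 75.0))
    if mode == "bivalent":
        return 0.5 * (1.0 - math.exp(-d_cm / 50.0))
    raise ValueError(f"unknown mode {mode!r}")


def map_distance(r: float, mode: str = "quadrivalent") -> float:
    """Inverse of :func:`recombination_fraction`."""
    _check_r(r)
    if mode == "quadrivalent":
        return -75.0 * math.log(1.0 - r / 0.75)
    if mode == "bivalent":
        return -50.0 * math.log(1.0 - 2.0 * r)
    raise ValueError(f"unknown mode {mode!r}")


def effective_alpha(lam: float, alpha: float) -> float:
    """Effective double-reduction coefficient ``alpha' = lam * alpha``."""
    _check_alpha(alpha)
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must be in [0, 1]")
    return lam * alpha


def induced_alpha_profile(alpha0: float, r_intervals: Sequence[float]) -> np.ndarray:
    """Per-locus double-reduction coefficients induced along a chromosome.

    With ``alpha0`` at the centromere-proximal anchor locus, the chromatid
    origin chain makes the two gamete chromatids coincide at locus ``j+1``
    with probability

    ``a' = a [(1-r)^2 + r^2/3] + (1-a) [2 r (1-r)/3 + 2 r^2 / 9]``

    which increases toward the stationary ceiling 1/4 with distance.
    """
    _check_alpha(alpha0)
    out = np.empty(len(r_intervals) + 1)
    out[0] = a = alpha0
    for j, r in enumerate(r_intervals):
        _check_r(r)
        stay = (1 - r) ** 2 + r * r / 3.0
        gain = 2 * r * (1 - r) / 3.0 + 2 * r * r / 9.0
        a = a * stay + (1 - a) * gain
        out[j + 1] = a
    return out


# ---------------------------------------------------------------------------
# chromatid-origin processes


def _t_quad(r: float) -> np.ndarray:
    t = np.full((4, 4), r / 3.0)
    np.fill_diagonal(t, 1.0 - r)
    return t


class _OriginProcess:
    """State space of the ordered chromatid-origin pair of one gamete."""

    # subclasses define: origins (S, 2) int array, weight of each block
    origins: np.ndarray
    n_states: int
    is_quadrivalent: np.ndarray  # (S,) bool, True for quadrivalent block

    def initial(self, alpha: float) -> np.ndarray:
        raise NotImplementedError

    def transition(self, r: float) -> np.ndarray:
        raise NotImplementedError


class _Quadrivalent(_OriginProcess):
    def __init__(self) -> None:
        self.origins = np.array(list(itertools.product(range(4), range(4))))
        self.n_states = 16
        self.is_quadrivalent = np.ones(16, dtype=bool)

    def initial(self, alpha: float) -> np.ndarray:
        _check_alpha(alpha)
        same = self.origins[:, 0] == self.origins[:, 1]
        return np.where(same, alpha / 4.0, (1.0 - alpha) / 12.0)

    def transition(self, r: float) -> np.ndarray:
        _check_r(r)
        t = _t_quad(r)
        return np.kron(t, t)


class _Bivalent(_OriginProcess):
    """States are (partition, chromatid-from-first-pair, chromatid-from-second).

    The first pair of a partition is the one containing homologue 0, fixing
    an ordering convention for the (physically unordered) chromatid pair.
    ``partition`` restricts the meiosis to one of the three pairings; the
    default averages over them (random bivalent pairing).
    """

    def __init__(self, partition: int | None = None) -> None:
        self.partition = partition
        parts = _PARTITIONS if partition is None else (_PARTITIONS[partition],)
        states = []
        for p, (pair1, pair2) in enumerate(parts):
            for x1 in pair1:
                for x2 in pair2:
                    states.append((p, x1, x2))
        self.states = states
        self.origins = np.array([(x1, x2) for _, x1, x2 in states])
        self.n_states = len(states)
        self.is_quadrivalent = np.zeros(self.n_states, dtype=bool)

    def initial(self, alpha: float = 0.0) -> np.ndarray:
        return np.full(self.n_states, 1.0 / self.n_states)

    def transition(self, r: float) -> np.ndarray:
        _check_r(r)
        if r > 0.5:
            raise ValueError("bivalent recombination fraction is bounded by 0.5")
        T = np.zeros((12, 12))
        for a, (p, x1, x2) in enumerate(self.states):
            for b, (q, y1, y2) in enumerate(self.states):
                if p != q:
                    continue
                f1 = 1.0 - r if x1 == y1 else r
                f2 = 1.0 - r if x2 == y2 else r
                T[a, b] = f1 * f2
        return T


class _Mixed(_OriginProcess):
    def __init__(self, lam: float) -> None:
        self.lam = lam
        self.quad = _Quadrivalent()
        self.biv = _Bivalent()
        self.origins = np.vstack([self.quad.origins, self.biv.origins])
        self.n_states = 28
        self.is_quadrivalent = np.concatenate(
            [self.quad.is_quadrivalent, self.biv.is_quadrivalent]
        )

    def initial(self, alpha: float) -> np.ndarray:
        return np.concatenate(
            [self.lam * self.quad.initial(alpha), (1.0 - self.lam) * self.biv.initial()]
        )

    def transition(self, r: float) -> np.ndarray:
        T = np.zeros((28, 28))
        T[:16, :16] = self.quad.transition(r)
        T[16:, 16:] = self.biv.transition(min(r, 0.5))
        return T


def origin_process(
    pairing: PairingModel | str,
    lam: float | None = None,
    partition: int | None = None,
) -> _OriginProcess:
    pairing = PairingModel.coerce(pairing, lam)
    if pairing.mode == "quadrivalent":
        return _Quadrivalent()
    if pairing.mode == "bivalent":
        return _Bivalent(partition)
    return _Mixed(pairing.lam)


# ---------------------------------------------------------------------------
# gamete distributions


Haplotype = tuple  # allele labels, one per locus
GameteKey = tuple  # sorted pair of Haplotype


@dataclass
class GameteDistribution:
    """Probability distribution over diploid gamete genotypes.

    ``entries`` maps a collapsed genotype class — the sorted pair of the two
    haplotypes' allele tuples — to its probability.  Classes are maximal
    sets of origin-labelled gametes with identical allele content; the
    origin-labelled view is retained in ``origin_entries`` as
    ``(haplotype1, haplotype2, dr_loci, probability)`` rows.
    """

    loci: tuple
    entries: dict
    params: dict
    origin_entries: list = field(default_factory=list, repr=False)

    def total(self) -> float:
        return float(sum(self.entries.values()))

    def support_size(self, tol: float = _PROB_TOL) -> int:
        return sum(1 for p in self.entries.values() if p > tol)

    def dr_mass_at(self, locus_index: int) -> float:
        """Probability that double reduction occurred at the given locus."""
        return float(
            sum(p for _, _, dr, p in self.origin_entries if locus_index in dr)
        )

    def probability(self, hap1: Iterable, hap2: Iterable) -> float:
        key = tuple(sorted([tuple(hap1), tuple(hap2)]))
        return self.entries.get(key, 0.0)

    def to_table(self) -> "list[tuple[str, float]]":
        """Deterministic (class key, probability) rows for serialization."""
        rows = []
        for key in sorted(self.entries):
            rows.append(("|".join("/".join(h) for h in key), self.entries[key]))
        return rows


def fully_heterozygous_parent(n_loci: int = 2) -> list:
    """Phased genotype with four distinct alleles at every locus, in coupling.

    Locus ``l`` on homologue ``h`` carries allele ``"<letter><h+1>"`` with
    letters A, B, C ... along the chromosome.
    """
    letters = "ABCDEFGH"
    return [
        tuple(f"{letters[l]}{h + 1}" for l in range(n_loci)) for h in range(4)
    ]


def _validate_parent(parent: Sequence, n_loci: int) -> list:
    parent = [tuple(h) for h in parent]
    if len(parent) != 4:
        raise ValueError("a tetraploid parent must have exactly 4 phased haplotypes")
    if any(len(h) != n_loci for h in parent):
        raise ValueError(f"each haplotype must cover {n_loci} loci")
    return parent


def _chain_distribution(
    parent: Sequence,
    pairing: PairingModel | str,
    alpha: float,
    r_steps: Sequence[float],
    loci: tuple,
    reverse: bool = False,
    params: dict | None = None,
    partition: int | None = None,
) -> GameteDistribution:
    """Enumerate the origin-pair chain over ``len(r_steps)+1`` loci exactly.

    ``reverse=True`` anchors the chain (and ``alpha``) at the *last* locus,
    for chromosomes whose centromere-proximal end is on the right.
    """
    n_loci = len(r_steps) + 1
    parent = _validate_parent(parent, n_loci)
    proc = origin_process(pairing, partition=partition)
    init = proc.initial(alpha)
    steps = list(r_steps)[::-1] if reverse else list(r_steps)
    mats = [proc.transition(r) for r in steps]

    # joint over state paths (s_0, ..., s_{L-1})
    S = proc.n_states
    paths = [(i,) for i in range(S)]
    probs = init.copy()
    for T in mats:
        new_paths = []
        new_probs = np.empty(len(paths) * S)
        k = 0
        for path, p in zip(paths, probs):
            row = T[path[-1]]
            for s2 in range(S):
                new_paths.append(path + (s2,))
                new_probs[k] = p * row[s2]
                k += 1
        paths, probs = new_paths, new_probs

    entries: dict = {}
    origin_entries = []
    ori = proc.origins
    for path, p in zip(paths, probs):
        if p <= 0.0:
            continue
        locus_states = path[::-1] if reverse else path
        x1 = [ori[s, 0] for s in locus_states]
        x2 = [ori[s, 1] for s in locus_states]
        hap1 = tuple(parent[x1[l]][l] for l in range(n_loci))
        hap2 = tuple(parent[x2[l]][l] for l in range(n_loci))
        dr = frozenset(l for l in range(n_loci) if x1[l] == x2[l])
        key = tuple(sorted([hap1, hap2]))
        entries[key] = entries.get(key, 0.0) + p
        origin_entries.append((hap1, hap2, dr, p))

    dist = GameteDistribution(
        loci=loci,
        entries=entries,
        params=dict(params or {}),
        origin_entries=origin_entries,
    )
    if abs(dist.total() - 1.0) > 1e-9:
        raise AssertionError("gamete distribution does not sum to 1")
    return dist


def single_locus_distribution(
    parent: Sequence, pairing: PairingModel | str = "quadrivalent", alpha: float = 0.0
) -> GameteDistribution:
    """One-locus diploid gamete distribution of a single parent."""
    return _chain_distribution(
        parent, pairing, alpha, [], loci=("locus",), params={"alpha": alpha}
    )


def two_locus_distribution(
    parent: Sequence,
    pairing: PairingModel | str,
    alpha: float,
    r: float,
    approximate: bool = False,
) -> GameteDistribution:
    """Two-locus diploid gamete distribution of one parent.

    Under mixed pairing the *true* distribution (the lambda-weighted mixture
    of the quadrivalent and bivalent laws) is returned unless
    ``approximate=True``, in which case the quadrivalent law evaluated at the
    effective coefficient ``alpha' = lambda * alpha`` is used.
    """
    pairing = PairingModel.coerce(pairing)
    _check_alpha(alpha)
    _check_r(r)
    if approximate:
        return mixed_approximation(effective_alpha(pairing.lam, alpha), r, parent)
    return _chain_distribution(
        parent,
        pairing,
        alpha,
        [r],
        loci=("A", "B"),
        params={"alpha": alpha, "r": r, "pairing": pairing.mode, "lam": pairing.lam},
    )


def mixed_approximation(
    alpha_prime: float, r: float, parent: Sequence | None = None
) -> GameteDistribution:
    """Approximate mixed-pairing gamete distribution (the zeta law).

    The quadrivalent two-locus law evaluated at the effective coefficient of
    double reduction ``alpha'``.  It preserves the total probability of
    gametes with double reduction at the anchor locus exactly.
    """
    if parent is None:
        parent = fully_heterozygous_parent(2)
    return _chain_distribution(
        parent,
        "quadrivalent",
        alpha_prime,
        [r],
        loci=("A", "B"),
        params={"alpha": alpha_prime, "r": r, "pairing": "approximation"},
    )


def three_locus_distribution(
    parent: Sequence,
    pairing: PairingModel | str,
    alpha: float,
    r1: float,
    r2: float,
    proximal: str = "left",
    partition: int | None = None,
) -> GameteDistribution:
    """Marker–QTL–marker gamete distribution (locus order left, QTL, right).

    ``alpha`` applies at the centromere-proximal flanking marker; ``proximal``
    says whether that is the left or the right one.  ``r1`` (``r2``) is the
    recombination fraction between the QTL and its left (right) marker.

    ``partition`` (bivalent only) conditions on one of the three homologue
    pairings.  Within a single meiosis the pairing is fixed, so the canonical
    class count of the bivalent three-locus table (64 gamete genotypes for a
    fully informative parent, against 2080 under quadrivalent pairing) refers
    to one pairing configuration; the default ``None`` averages the three
    pairings, which is the across-meiosis law used everywhere else.
    """
    pairing = PairingModel.coerce(pairing)
    _check_alpha(alpha)
    _check_r(r1, "r1")
    _check_r(r2, "r2")
    if proximal not in ("left", "right"):
        raise ValueError("proximal must be 'left' or 'right'")
    return _chain_distribution(
        parent,
        pairing,
        alpha,
        [r1, r2],
        loci=("left", "qtl", "right"),
        reverse=(proximal == "right"),
        partition=partition,
        params={
            "alpha": alpha,
            "r1": r1,
            "r2": r2,
            "pairing": pairing.mode,
            "lam": pairing.lam,
            "proximal": proximal,
        },
    )


def marginalize(dist: GameteDistribution, keep: Sequence[int]) -> GameteDistribution:
    """Marginal gamete distribution over a subset of loci (by index)."""
    keep = list(keep)
    entries: dict = {}
    origin_entries = []
    for hap1, hap2, dr, p in dist.origin_entries:
        h1 = tuple(hap1[l] for l in keep)
        h2 = tuple(hap2[l] for l in keep)
        key = tuple(sorted([h1, h2]))
        entries[key] = entries.get(key, 0.0) + p
        origin_entries.append(
            (h1, h2, frozenset(keep.index(l) for l in dr if l in keep), p)
        )
    return GameteDistribution(
        loci=tuple(dist.loci[l] for l in keep),
        entries=entries,
        params=dict(dist.params),
        origin_entries=origin_entries,
    )


def zygote_distribution(
    d1: GameteDistribution, d2: GameteDistribution, collapse: bool = True
) -> dict:
    """Joint zygote genotype distribution under random union of gametes.

    Returns a dict mapping the zygote genotype — the sorted tuple of its four
    haplotypes when ``collapse`` is true, else the (gamete1, gamete2) class
    pair — to its probability.
    """
    if d1.loci != d2.loci:
        raise ValueError("gamete distributions cover different loci")
    out: dict = {}
    for k1, p1 in d1.entries.items():
        for k2, p2 in d2.entries.items():
            key = tuple(sorted(k1 + k2)) if collapse else (k1, k2)
            out[key] = out.get(key, 0.0) + p1 * p2
    return out


# ---------------------------------------------------------------------------
# Table-2 structural classes and KL divergence

_CLASS_NAMES = (
    "AiBi/AiBi",
    "AiBj/AiBj",
    "AiBi/AiBj",
    "AiBj/AiBk",
    "AiBi/AjBi",
    "AiBj/AkBj",
    "AiBi/AjBj",
    "AiBi/AjBk",
    "AiBj/AjBi",
    "AiBj/AjBk",
    "AiBj/AkBl",
)


def classify_two_locus_gamete(a1: int, b1: int, a2: int, b2: int) -> str:
    """Structural class of a two-locus gamete of a fully heterozygous parent.

    Arguments are the chromatid origins at locus A and B: the gamete is
    (A_{a1} B_{b1}) / (A_{a2} B_{b2}) with the parent in coupling phase
    A_i B_i / A_j B_j / A_k B_k / A_l B_l.
    """
    dr_a, dr_b = a1 == a2, b1 == b2
    if dr_a and dr_b:
        return "AiBi/AiBi" if a1 == b1 else "AiBj/AiBj"
    if dr_a:
        return "AiBi/AiBj" if a1 in (b1, b2) else "AiBj/AiBk"
    if dr_b:
        return "AiBi/AjBi" if b1 in (a1, a2) else "AiBj/AkBj"
    par1, par2 = a1 == b1, a2 == b2
    if par1 and par2:
        return "AiBi/AjBj"
    if par1 or par2:
        return "AiBi/AjBk"
    if b1 == a2 and b2 == a1:
        return "AiBj/AjBi"
    if b1 == a2 or b2 == a1:
        return "AiBj/AjBk"
    return "AiBj/AkBl"


def two_locus_class_probability(
    dist: GameteDistribution,
) -> "dict[str, float]":
    """Total probability of each of the 11 structural gamete classes.

    Only meaningful for a distribution built from a fully heterozygous
    parent, whose allele labels identify the chromatid origins.
    """
    out = {name: 0.0 for name in _CLASS_NAMES}
    for hap1, hap2, _, p in dist.origin_entries:
        a1 = int(hap1[0][1]) - 1
        b1 = int(hap1[1][1]) - 1
        a2 = int(hap2[0][1]) - 1
        b2 = int(hap2[1][1]) - 1
        out[classify_two_locus_gamete(a1, b1, a2, b2)] += p
    return out


def kl_divergence_exact(
    g_true: GameteDistribution, zeta: GameteDistribution
) -> float:
    """Kullback–Leibler divergence D(g' || zeta) over gamete classes, in nats.

    Requires ``zeta`` to be positive wherever ``g_true`` is; zero-probability
    classes of ``g_true`` contribute nothing.
    """
    if g_true.loci != zeta.loci:
        raise ValueError("distributions cover different loci")
    div = 0.0
    for key, g in g_true.entries.items():
        if g <= _PROB_TOL:
            continue
        z = zeta.entries.get(key, 0.0)
        if z <= 0.0:
            raise ValueError(f"support mismatch: class {key} has zero approximation")
        div += g * math.log(g / z)
    return max(div, 0.0)


def kl_quadratic(r: float) -> float:
    """Printed closed-form approximation of the divergence as a function of r."""
    _check_r(r)
    return -0.301 * (r - 0.585) ** 2 + 0.103


# ---------------------------------------------------------------------------
# conditional QTL genotype given flanking markers


def _allele_count_weights(obs: Mapping | None, alleles: "list[str]") -> np.ndarray | None:
    if obs is None:
        return None
    return np.array([obs.get(a, 0) for a in alleles], dtype=int)


def conditional_qtl_given_flanking(
    p1: Sequence,
    p2: Sequence,
    q_placement1: Sequence[int],
    q_placement2: Sequence[int],
    marker_obs: tuple,
    alpha: float,
    r1: float,
    r2: float,
    pairing: PairingModel | str = "quadrivalent",
    proximal: str = "left",
) -> np.ndarray:
    """Posterior over offspring QTL dosage (0..4) given flanking marker data.

    ``p1``/``p2`` are the parents' phased *marker* genotypes at the two
    flanking loci (4 haplotypes of 2 allele labels each); ``q_placement*``
    are 0/1 indicators over each parent's four homologues saying which carry
    the trait-increasing allele Q.  ``marker_obs`` is the offspring's
    observed zygote genotype at (left, right): each element a mapping from
    allele label to dosage count (summing to 4), or None for missing.

    Computed as the exact ratio of the three-locus zygote law to the
    two-locus marker marginal, by contraction over the chromatid-origin
    chains of the two parental meioses.
    """
    pairing = PairingModel.coerce(pairing)
    p1 = _validate_parent(p1, 2)
    p2 = _validate_parent(p2, 2)
    q1 = np.asarray(q_placement1, dtype=int)
    q2 = np.asarray(q_placement2, dtype=int)
    if q1.shape != (4,) or q2.shape != (4,):
        raise ValueError("QTL placements must be 0/1 vectors over 4 homologues")
    proc = origin_process(pairing)
    init = proc.initial(alpha)
    if proximal == "left":
        T1, T2 = proc.transition(r1), proc.transition(r2)
        chain = lambda: np.einsum("a,ab,bc->abc", init, T1, T2)  # noqa: E731
    elif proximal == "right":
        T1, T2 = proc.transition(r2), proc.transition(r1)
        chain = lambda: np.einsum("a,ab,bc->cba", init, T1, T2)  # noqa: E731
    else:
        raise ValueError("proximal must be 'left' or 'right'")
    # J[left state, qtl state, right state] per parent (same pairing process)
    J = chain()

    def locus_alleles(parent: list, locus: int) -> "list[str]":
        return [parent[h][locus] for h in range(4)]

    S = proc.n_states
    ori = proc.origins

    def match_matrix(locus: int, obs: Mapping | None) -> np.ndarray:
        """(S, S) indicator that maternal x paternal states reproduce obs."""
        if obs is None:
            return np.ones((S, S))
        al1 = locus_alleles(p1, locus)
        al2 = locus_alleles(p2, locus)
        labels = sorted(set(al1) | set(al2) | set(obs))
        want = np.array([obs.get(a, 0) for a in labels], dtype=int)
        if want.sum() != 4:
            raise ValueError("marker observation dosages must sum to 4")
        idx = {a: i for i, a in enumerate(labels)}
        cnt1 = np.zeros((S, len(labels)), dtype=int)
        cnt2 = np.zeros((S, len(labels)), dtype=int)
        for s in range(S):
            x1, x2 = ori[s]
            cnt1[s, idx[al1[x1]]] += 1
            cnt1[s, idx[al1[x2]]] += 1
            cnt2[s, idx[al2[x1]]] += 1
            cnt2[s, idx[al2[x2]]] += 1
        return (cnt1[:, None, :] + cnt2[None, :, :] == want).all(axis=2).astype(float)

    w_left = match_matrix(0, marker_obs[0])
    w_right = match_matrix(1, marker_obs[1])

    def dose_tensor(q: np.ndarray) -> np.ndarray:
        """(S_left, S_right, 3): gamete Q-count distribution given end states."""
        counts = q[ori[:, 0]] + q[ori[:, 1]]  # per QTL state
        K = np.zeros((S, S, 3))
        for c in range(3):
            K[:, :, c] = J[:, counts == c, :].sum(axis=1)
        return K

    K1 = dose_tensor(q1)
    K2 = dose_tensor(q2)
    # joint over (maternal count, paternal count) given the marker match
    joint = np.einsum("ace,bdf,ab,cd->ef", K1, K2, w_left, w_right)
    norm = joint.sum()
    if norm < 1e-14:
        raise ValueError("marker zygote has zero probability under the model")
    post = np.zeros(5)
    for cm in range(3):
        for cp in range(3):
            post[cm + cp] += joint[cm, cp]
    return post / norm


# ---------------------------------------------------------------------------
# single-locus estimation of the coefficient of double reduction


def _zygote_class_probs(
    p1: Sequence, p2: Sequence, alpha: float, pairing: PairingModel | str
) -> "dict[tuple, float]":
    """Distribution over observable single-locus dosage classes."""
    d1 = single_locus_distribution(p1, pairing, alpha)
    d2 = single_locus_distribution(p2, pairing, alpha)
    zy = zygote_distribution(d1, d2)
    out: dict = {}
    for key, p in zy.items():
        alleles = tuple(sorted(a for hap in key for a in hap))
        out[alleles] = out.get(alleles, 0.0) + p
    return out


def observation_class(obs: Mapping) -> tuple:
    """Canonical dosage-class key of a single-locus observation."""
    alleles = []
    for a in sorted(obs):
        alleles.extend([a] * int(obs[a]))
    if len(alleles) != 4:
        raise ValueError("single-locus dosages must sum to 4")
    return tuple(alleles)


def estimate_alpha_single_locus(
    observations: Sequence[Mapping],
    p1: Sequence,
    p2: Sequence,
    pairing: PairingModel | str = "quadrivalent",
    exclude: Sequence[int] | None = None,
) -> float | None:
    """Maximum-likelihood coefficient of double reduction from one locus.

    ``observations`` are per-offspring allele-dosage mappings at the locus;
    ``p1``/``p2`` the parents' phased single-locus genotypes (4 labels, each
    as a 1-tuple or bare string).  ``exclude`` drops the given individuals
    first (used to reproduce the downward bias caused by removing offspring
    whose genotypes visibly require double reduction).  Returns None when the
    likelihood carries no information about alpha.
    """
    p1 = [(h,) if isinstance(h, str) else tuple(h) for h in p1]
    p2 = [(h,) if isinstance(h, str) else tuple(h) for h in p2]
    keep = [
        obs for i, obs in enumerate(observations) if not exclude or i not in set(exclude)
    ]
    if not keep:
        raise ValueError("no observations left to estimate from")
    counts: dict = {}
    for obs in keep:
        key = observation_class(obs)
        counts[key] = counts.get(key, 0) + 1

    def negll(alpha: float) -> float:
        probs = _zygote_class_probs(p1, p2, alpha, pairing)
        ll = 0.0
        for key, n in counts.items():
            p = probs.get(key, 0.0)
            if p <= 0.0:
                return np.inf
            ll += n * math.log(p)
        return -ll

    grid = np.linspace(0.0, ALPHA_MAX, 26)
    vals = np.array([negll(a) for a in grid])
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        return None
    if finite.size > 1 and np.ptp(finite) < 1e-9:
        return None  # flat likelihood: alpha not identifiable
    res = minimize_scalar(negll, bounds=(0.0, ALPHA_MAX), method="bounded")
    best = float(res.x)
    # keep the boundary if the grid end beats the interior optimum
    cand = [best] + [float(g) for g in grid[[0, -1]]]
    return min(cand, key=negll)
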