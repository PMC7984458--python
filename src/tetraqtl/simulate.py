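"""Simulation of outbred autotetraploid mapping populations.

Generates first-generation segregating (S1) families from two phased
autotetraploid parents under bivalent, quadrivalent or mixed chromosome
pairing.  Each parental meiosis draws its pairing mode (quadrivalent with
probability lambda), then samples the chromatid-origin pair of the gamete
locus by locus with the same Markov walk that underlies the closed-form
gamete distributions, so the empirical one-, two- and three-locus class
frequencies converge to the analytic laws by construction.  The centromere
sits at the left end of the map: the coefficient of double reduction is
``alpha`` at the first locus and grows toward its 0.25 ceiling with
centromere distance through the chain, mirroring the rising fraction of
double-reduction carriers expected along a chromosome arm.

Trait values follow the orthogonal genetic model at the simulated parental
QTL configuration, with the residual variance set from the realized genetic
variance to hit a target heritability.  Marker data are emitted with
(model I) or without (model II) allele dosage information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genetics import build_contrasts
from .hmm import HMMParameters, MultipointModel
from .io import Dataset
from .meiosis import (
    PairingModel,
    _PARTITIONS,
    origin_process,
    recombination_fraction,
)

__all__ = [
    "SimulationConfig",
    "SimulatedPopulation",
    "simulate_population",
    "random_parents",
    "table3_config",
    "score_markers",
    "detect_incompatible",
    "expected_dr_carriers",
]

# homologue paired with h under bivalent partition p
_PARTNER = np.array(
    [[pair[1 - pair.index(h)] for pair in part if h in pair][0]
     for part in _PARTITIONS for h in range(4)]
).reshape(3, 4)


@dataclass
class SimulationConfig:
    """Study design of one simulated mapping population."""

    cm_positions: Sequence[float]
    parent1: Sequence[Sequence[str]]  # phased marker genotypes
    parent2: Sequence[Sequence[str]]
    qtl_cm: float
    q_placement1: Sequence[int]  # Q indicator on P1's four homologues
    q_placement2: Sequence[int]
    mu: float = 10.0
    theta: Sequence[float] = (10.0, -6.0, 3.0, -1.0)
    heritability: float = 0.10
    pairing: PairingModel | str = "quadrivalent"
    lam: float | None = None
    alpha: float = 0.0  # at the centromere-proximal (left) anchor locus
    n_offspring: int = 300
    dosage_scoring: bool = True  # model I; False = model II (presence/absence)
    seed: int | None = 0

    def __post_init__(self) -> None:
        self.pairing = PairingModel.coerce(self.pairing, self.lam)
        self.cm_positions = np.asarray(self.cm_positions, dtype=float)
        if not 0.0 < self.heritability < 1.0:
            raise ValueError("heritability must be in (0, 1)")
        if not self.cm_positions[0] <= self.qtl_cm <= self.cm_positions[-1]:
            raise ValueError("QTL must lie inside the map")
        if np.any(np.isclose(self.cm_positions, self.qtl_cm)):
            raise ValueError("place the QTL strictly between markers")


@dataclass
class SimulatedPopulation:
    """Observed data plus the latent truth record of a simulated family."""

    dataset: Dataset
    config: SimulationConfig
    qtl_dosage: np.ndarray  # (n,) true Q-allele count
    genotypic_value: np.ndarray  # (n,) true G
    origins: np.ndarray  # (n, 2 parents, L loci, 2 chromatids), QTL included
    modes: np.ndarray  # (n, 2) True where the meiosis was quadrivalent
    dr_any: np.ndarray  # (n,) True if any locus of either gamete shows DR
    loci_cm: np.ndarray  # marker positions with the QTL inserted
    qtl_index: int
    realized_h2: float
    sigma: float
    genotype_probs: np.ndarray  # theoretical 5-vector at the QTL


def _sample_gamete_origins(
    n: int, loci_cm: np.ndarray, lam: float, alpha: float, rng: np.random.Generator
):
    """Origin-pair paths for n independent meioses of one parent.

    Returns (origins (n, L, 2), quad_mode (n,)).
    """
    L = len(loci_cm)
    quad = rng.random(n) < lam
    x = np.empty((n, L, 2), dtype=np.int64)

    # anchor locus: double reduction w.p. alpha under quadrivalent pairing
    dr = rng.random(n) < alpha
    a = rng.integers(0, 4, n)
    b = (a + 1 + rng.integers(0, 3, n)) % 4
    part = rng.integers(0, 3, n)
    pairs = np.array(_PARTITIONS)  # (3, 2, 2)
    xb1 = pairs[part, 0, rng.integers(0, 2, n)]
    xb2 = pairs[part, 1, rng.integers(0, 2, n)]
    x[:, 0, 0] = np.where(quad, a, xb1)
    x[:, 0, 1] = np.where(quad, np.where(dr, a, b), xb2)

    for l in range(1, L):
        d = loci_cm[l] - loci_cm[l - 1]
        rq = recombination_fraction(d, "quadrivalent")
        rb = recombination_fraction(d, "bivalent")
        for c in range(2):
            prev = x[:, l - 1, c]
            switch_q = rng.random(n) < rq
            new_q = (prev + 1 + rng.integers(0, 3, n)) % 4
            switch_b = rng.random(n) < rb
            new_b = _PARTNER[part, prev]
            xq = np.where(switch_q, new_q, prev)
            xbv = np.where(switch_b, new_b, prev)
            x[:, l, c] = np.where(quad, xq, xbv)
    return x, quad


def _qtl_genotype_probs(cfg: SimulationConfig) -> np.ndarray:
    """Theoretical offspring QTL dosage distribution under the design."""
    proc = origin_process(cfg.pairing)
    d = cfg.qtl_cm - cfg.cm_positions[0]
    if cfg.pairing.mode == "mixed":
        T = np.zeros((proc.n_states, proc.n_states))
        T[:16, :16] = proc.quad.transition(recombination_fraction(d, "quadrivalent"))
        T[16:, 16:] = proc.biv.transition(recombination_fraction(d, "bivalent"))
    else:
        T = proc.transition(recombination_fraction(d, cfg.pairing.mode))
    nu = proc.initial(cfg.alpha) @ T
    ori = proc.origins
    p = np.zeros(5)
    q1 = np.asarray(cfg.q_placement1, dtype=int)
    q2 = np.asarray(cfg.q_placement2, dtype=int)
    c1 = np.zeros(3)
    c2 = np.zeros(3)
    np.add.at(c1, q1[ori[:, 0]] + q1[ori[:, 1]], nu)
    np.add.at(c2, q2[ori[:, 0]] + q2[ori[:, 1]], nu)
    for i in range(3):
        for j in range(3):
            p[i + j] += c1[i] * c2[j]
    return p


def genotype_values(cfg: SimulationConfig) -> "tuple[np.ndarray, np.ndarray]":
    """(G_k, p_k): genotype means under the orthogonal model and class probs.

    The contrast scales are built from the theoretical genotype distribution
    of the design; effects beyond the estimable order of the cross (e.g. the
    quadrigenic effect when fewer than five dosage classes segregate) do not
    enter the phenotypes.
    """
    p = _qtl_genotype_probs(cfg)
    W = build_contrasts(p)
    G = np.full(5, np.nan)
    theta = np.asarray(cfg.theta, dtype=float)
    for k in range(5):
        if W.support[k]:
            G[k] = cfg.mu + sum(
                W.w[k, j] * theta[j] for j in range(W.n_effects)
            )
    return G, p


def score_markers(
    origins: np.ndarray,
    parent1: Sequence[Sequence[str]],
    parent2: Sequence[Sequence[str]],
    marker_indices: Sequence[int],
    dosage_scoring: bool = True,
) -> list:
    """Observed marker phenotypes implied by the truth record.

    Model I (``dosage_scoring=True``) returns allele->count mappings; model
    II collapses each genotype to the set of alleles present.
    """
    n = origins.shape[0]
    out = []
    for i in range(n):
        row = []
        for jm, j in enumerate(marker_indices):
            alleles = [
                parent1[jm][origins[i, 0, j, 0]],
                parent1[jm][origins[i, 0, j, 1]],
                parent2[jm][origins[i, 1, j, 0]],
                parent2[jm][origins[i, 1, j, 1]],
            ]
            if dosage_scoring:
                obs: dict = {}
                for al in alleles:
                    obs[al] = obs.get(al, 0) + 1
                row.append(obs)
            else:
                row.append(frozenset(alleles))
        out.append(row)
    return out


def simulate_population(cfg: SimulationConfig) -> SimulatedPopulation:
    """Generate one S1 mapping population under the given design."""
    rng = np.random.default_rng(cfg.seed)
    cm = cfg.cm_positions
    loci_cm = np.sort(np.append(cm, cfg.qtl_cm))
    qtl_index = int(np.searchsorted(loci_cm, cfg.qtl_cm))
    marker_indices = [j for j in range(len(loci_cm)) if j != qtl_index]

    n = cfg.n_offspring
    lam = cfg.pairing.lam
    o1, m1 = _sample_gamete_origins(n, loci_cm, lam, cfg.alpha, rng)
    o2, m2 = _sample_gamete_origins(n, loci_cm, lam, cfg.alpha, rng)
    origins = np.stack([o1, o2], axis=1)  # (n, 2, L, 2)
    modes = np.stack([m1, m2], axis=1)

    q1 = np.asarray(cfg.q_placement1, dtype=int)
    q2 = np.asarray(cfg.q_placement2, dtype=int)
    k = (
        q1[o1[:, qtl_index, 0]]
        + q1[o1[:, qtl_index, 1]]
        + q2[o2[:, qtl_index, 0]]
        + q2[o2[:, qtl_index, 1]]
    )

    G, p_theory = genotype_values(cfg)
    g = G[k]
    if np.any(np.isnan(g)):
        raise RuntimeError("realized genotype outside the theoretical support")
    var_g = float(np.var(g))
    if var_g <= 0:
        raise ValueError("zero genetic variance in the simulated population")
    sigma = float(np.sqrt(var_g * (1.0 - cfg.heritability) / cfg.heritability))
    y = g + rng.normal(0.0, sigma, n)
    realized_h2 = var_g / (var_g + sigma**2)

    dr = (origins[:, :, :, 0] == origins[:, :, :, 1]) & modes[:, :, None]
    observations = score_markers(
        origins, cfg.parent1, cfg.parent2, marker_indices, cfg.dosage_scoring
    )
    individuals = [f"S{i + 1:04d}" for i in range(n)]
    dataset = Dataset(
        cm_positions=cm,
        markers=[f"M{j + 1:02d}" for j in range(len(cm))],
        parent1=[tuple(gt) for gt in cfg.parent1],
        parent2=[tuple(gt) for gt in cfg.parent2],
        individuals=individuals,
        observations=observations,
        y=y,
        dosage_scoring=cfg.dosage_scoring,
        meta={
            "pairing": cfg.pairing.mode,
            "lam": cfg.pairing.lam,
            "alpha": cfg.alpha,
            "qtl_cm": cfg.qtl_cm,
            "seed": cfg.seed,
        },
    )
    return SimulatedPopulation(
        dataset=dataset,
        config=cfg,
        qtl_dosage=k,
        genotypic_value=g,
        origins=origins,
        modes=modes,
        dr_any=dr.any(axis=(1, 2)),
        loci_cm=loci_cm,
        qtl_index=qtl_index,
        realized_h2=float(realized_h2),
        sigma=sigma,
        genotype_probs=p_theory,
    )


def random_parents(
    n_markers: int, rng: np.random.Generator, dosages=(1, 2, 3)
) -> "tuple[list, list]":
    """Random phased biallelic parental marker genotypes.

    Per marker and parent the dosage of the reference allele 'A' is drawn
    uniformly from ``dosages`` (simplex to triplex — the informative
    biallelic classes) and placed on random homologues.
    """
    p1, p2 = [], []
    for _ in range(n_markers):
        for plist in (p1, p2):
            d = int(rng.choice(dosages))
            carriers = rng.choice(4, size=d, replace=False)
            plist.append(tuple("A" if h in carriers else "a" for h in range(4)))
    return p1, p2


def table3_config(
    lam: float,
    seed: int | None = 0,
    n_offspring: int = 300,
    heritability: float = 0.10,
    n_markers: int = 20,
    length_cm: float = 100.0,
    dosage_scoring: bool = True,
    alpha: float = 0.0,
) -> SimulationConfig:
    """The mixed-pairing simulation design: 20 evenly spaced biallelic
    markers on a 100 cM chromosome, parental QTL genotype QQQq x Qqqq at
    mid-chromosome, trait heritability 10%.

    ``alpha`` is the double-reduction coefficient at the left (centromeric)
    map end; the default 0 places the centromere at the map origin, with
    double reduction arising along the chromosome through the chain.
    """
    rng = np.random.default_rng(None if seed is None else seed)
    cm = np.linspace(0.0, length_cm, n_markers)
    p1, p2 = random_parents(n_markers, rng)
    return SimulationConfig(
        cm_positions=cm,
        parent1=p1,
        parent2=p2,
        qtl_cm=length_cm / 2.0,
        q_placement1=(1, 1, 1, 0),
        q_placement2=(1, 0, 0, 0),
        mu=10.0,
        theta=(10.0, -6.0, 3.0, -1.0),
        heritability=heritability,
        pairing=PairingModel("mixed", lam),
        alpha=alpha,
        n_offspring=n_offspring,
        dosage_scoring=dosage_scoring,
        seed=None if seed is None else seed + 1,
    )


# ---------------------------------------------------------------------------
# bivalent-incompatibility screening


def detect_incompatible(dataset: Dataset, policy: str = "flag"):
    """Offspring whose observed genotypes are impossible under bivalent pairing.

    Runs the bivalent-model multipoint chain per individual: a zero
    likelihood means no bivalent meiosis pair can produce the observed
    marker phenotypes — either a locus shows direct double-reduction
    evidence (e.g. an A1A1 gamete from an A1A2A3A4 parent) or the phenotypes
    jointly require a gamete drawing on more than two parental chromosomes.
    Returns ``(flags, detail)``: a boolean array and, per individual, the
    list of loci with single-locus evidence ("multilocus" when the conflict
    is only joint).  ``policy="remove"`` additionally returns the dataset
    restricted to compatible individuals; ``policy="missing"`` blanks the
    single-locus-offending observations instead.
    """
    params = HMMParameters(
        dataset.cm_positions,
        dataset.parent1,
        dataset.parent2,
        pairing="bivalent",
        alpha=0.0,
    )
    model = MultipointModel(params)
    res = model.run(dataset.observations, dosage=dataset.dosage_scoring)
    flags = ~res.ok
    from .hmm import _observation_key

    detail = []
    for i in range(len(dataset.individuals)):
        loci = []
        if flags[i]:
            for j in range(len(dataset.markers)):
                obs = dataset.observations[i][j]
                if obs is None:
                    continue
                if _observation_key(obs, dataset.dosage_scoring) not in model.reachable_classes(
                    j, dataset.dosage_scoring
                ):
                    loci.append(dataset.markers[j])
            detail.append(loci or ["multilocus"])
        else:
            detail.append([])

    if policy == "flag":
        return flags, detail
    if policy == "remove":
        keep = ~flags
        sub = Dataset(
            cm_positions=dataset.cm_positions,
            markers=dataset.markers,
            parent1=dataset.parent1,
            parent2=dataset.parent2,
            individuals=[d for d, k in zip(dataset.individuals, keep) if k],
            observations=[o for o, k in zip(dataset.observations, keep) if k],
            y=dataset.y[keep],
            dosage_scoring=dataset.dosage_scoring,
            meta=dict(dataset.meta),
        )
        return flags, detail, sub
    if policy == "missing":
        obs = [list(row) for row in dataset.observations]
        for i, loci in enumerate(detail):
            for name in loci:
                if name == "multilocus":
                    continue
                obs[i][dataset.markers.index(name)] = None
        sub = Dataset(
            cm_positions=dataset.cm_positions,
            markers=dataset.markers,
            parent1=dataset.parent1,
            parent2=dataset.parent2,
            individuals=list(dataset.individuals),
            observations=obs,
            y=dataset.y.copy(),
            dosage_scoring=dataset.dosage_scoring,
            meta=dict(dataset.meta),
        )
        return flags, detail, sub
    raise ValueError("policy must be 'flag', 'remove' or 'missing'")


def expected_dr_carriers(
    p1_locus: Sequence[str],
    p2_locus: Sequence[str],
    alpha: float,
    dosage_scoring: bool = True,
) -> "tuple[float, float]":
    """(expected, observable) fraction of double-reduction carriers at a locus.

    Expected: probability that at least one of the two parental gametes of
    an offspring carries double reduction at the locus, 1 - (1 - alpha)^2.
    Observable: total probability of offspring phenotype classes that are
    impossible under bivalent pairing, i.e. the only directly detectable
    part.  For some parental genotype configurations no incompatible
    phenotype exists and the observable fraction is exactly zero.
    """
    from .meiosis import _zygote_class_probs

    p1 = [(h,) for h in p1_locus]
    p2 = [(h,) for h in p2_locus]
    quad = _zygote_class_probs(p1, p2, alpha, "quadrivalent")
    biv = _zygote_class_probs(p1, p2, 0.0, "bivalent")
    if not dosage_scoring:
        quad = _collapse_presence(quad)
        biv = _collapse_presence(biv)
    observable = sum(p for cls, p in quad.items() if cls not in biv)
    expected = 1.0 - (1.0 - alpha) ** 2
    return expected, float(observable)


def _collapse_presence(class_probs: dict) -> dict:
    out: dict = {}
    for cls, p in class_probs.items():
        key = frozenset(cls)
        out[key] = out.get(key, 0.0) + p
    return out
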