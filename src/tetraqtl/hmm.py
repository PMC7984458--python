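"""Multipoint genotype probabilities for an outbred autotetraploid family.

For each offspring the hidden chain runs over the joint chromatid-origin
states of its two parental gametes (one per parent).  Transitions factorize
as the product of the two parental meioses; emissions compare the allele
content implied by a joint state with the observed marker phenotype (allele
dosages, or presence/absence when dosage is unknown).  A scaled
forward–backward pass yields, per individual,

* the likelihood of its whole marker phenotype vector (zero for genotypes
  impossible under the assumed pairing model — the basis of the
  bivalent-incompatibility screen),
* posterior probabilities of the phased two-locus genotype configuration at
  every adjacent marker pair, and
* the posterior distribution of the QTL dosage genotype at any position
  inside an interval, given a parental QTL configuration.

The coefficient of double reduction is anchored at the centromere-proximal
end of the linkage group (``anchor``); coincidence rates at the remaining
loci are induced by the chain and follow the three-point law (see
:func:`tetraqtl.meiosis.induced_alpha_profile`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .meiosis import PairingModel, origin_process, recombination_fraction

__all__ = ["HMMParameters", "MultipointModel", "MultipointResult"]

_ZERO = 1e-300


@dataclass
class HMMParameters:
    """Inputs of the multipoint model (the linkage-analysis parameter set).

    ``cm_positions`` are marker positions on one linkage group, increasing;
    ``parent1``/``parent2`` give the phased parental genotype at each marker
    as the 4 allele labels carried by homologues 1..4; ``alpha`` applies at
    the anchor marker; ``epsilon`` is a per-locus symmetric genotyping error
    rate over the observable phenotype classes.
    """

    cm_positions: Sequence[float]
    parent1: Sequence[Sequence[str]]
    parent2: Sequence[Sequence[str]]
    pairing: PairingModel | str = "quadrivalent"
    alpha: float = 0.0
    anchor: str = "left"
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        self.cm_positions = np.asarray(self.cm_positions, dtype=float)
        if np.any(np.diff(self.cm_positions) <= 0):
            raise ValueError("marker positions must be strictly increasing")
        m = len(self.cm_positions)
        if len(self.parent1) != m or len(self.parent2) != m:
            raise ValueError("parental genotypes must cover every marker")
        for g in list(self.parent1) + list(self.parent2):
            if len(g) != 4:
                raise ValueError("each parental genotype needs 4 phased alleles")
        if self.anchor not in ("left", "right"):
            raise ValueError("anchor must be 'left' or 'right'")
        if not 0.0 <= self.epsilon < 0.5:
            raise ValueError("epsilon must be in [0, 0.5)")
        self.pairing = PairingModel.coerce(self.pairing)


def _observation_key(obs, dosage: bool):
    """Canonical comparable key of an observation (see Dataset formats)."""
    if obs is None:
        return None
    if dosage:
        if isinstance(obs, Mapping):
            items = tuple(sorted((a, int(c)) for a, c in obs.items() if c))
        else:
            raise TypeError("dosage observations must be allele->count mappings")
        if sum(c for _, c in items) != 4:
            raise ValueError(f"dosage observation does not sum to 4: {obs}")
        return items
    return frozenset(obs)


class MultipointModel:
    """Hidden Markov chain over joint parental gamete origins at the markers."""

    def __init__(self, params: HMMParameters):
        self.params = params
        self._reversed = params.anchor == "right"
        cm = params.cm_positions
        p1 = [tuple(g) for g in params.parent1]
        p2 = [tuple(g) for g in params.parent2]
        if self._reversed:
            cm = (cm[-1] - cm)[::-1].copy()
            p1, p2 = p1[::-1], p2[::-1]
        self.cm = cm
        self.p1, self.p2 = p1, p2
        self.m = len(cm)

        self.proc = origin_process(params.pairing)
        S = self.proc.n_states
        self.S = S
        self.n_states = S * S
        init = self.proc.initial(params.alpha)
        self.initial = np.kron(init, init)

        self.transitions = [
            self._joint_transition(cm[j + 1] - cm[j]) for j in range(self.m - 1)
        ]

        # per-locus phenotype class of every joint state, dosage and presence
        self._dosage_classes: list = []
        self._presence_classes: list = []
        ori = self.proc.origins
        for j in range(self.m):
            dcls, pcls = [], []
            for sm in range(S):
                a = [p1[j][ori[sm, 0]], p1[j][ori[sm, 1]]]
                for sp in range(S):
                    alleles = a + [p2[j][ori[sp, 0]], p2[j][ori[sp, 1]]]
                    counts: dict = {}
                    for al in alleles:
                        counts[al] = counts.get(al, 0) + 1
                    dcls.append(tuple(sorted(counts.items())))
                    pcls.append(frozenset(counts))
            self._dosage_classes.append(dcls)
            self._presence_classes.append(pcls)

    def _single_transition(self, d_cm: float) -> np.ndarray:
        proc = self.proc
        mode = self.params.pairing.mode
        if mode == "mixed":
            T = np.zeros((proc.n_states, proc.n_states))
            T[:16, :16] = proc.quad.transition(recombination_fraction(d_cm, "quadrivalent"))
            T[16:, 16:] = proc.biv.transition(recombination_fraction(d_cm, "bivalent"))
            return T
        return proc.transition(recombination_fraction(d_cm, mode))

    def _joint_transition(self, d_cm: float) -> np.ndarray:
        T = self._single_transition(d_cm)
        return np.kron(T, T)

    # -- emissions ---------------------------------------------------------

    def reachable_classes(self, j: int, dosage: bool = True) -> set:
        cls = self._dosage_classes if dosage else self._presence_classes
        jj = self.m - 1 - j if self._reversed else j
        return set(cls[jj])

    def emission_matrix(
        self, observations: Sequence[Sequence], dosage: bool = True
    ) -> np.ndarray:
        """(m, n, S*S) emission probabilities for all individuals."""
        n = len(observations)
        eps = self.params.epsilon
        E = np.ones((self.m, n, self.n_states))
        cls_lists = self._dosage_classes if dosage else self._presence_classes
        for j in range(self.m):
            jj = self.m - 1 - j if self._reversed else j
            classes = sorted(set(cls_lists[j]), key=repr)
            idx = {cl: i for i, cl in enumerate(classes)}
            cls = np.array([idx[cl] for cl in cls_lists[j]])
            K = len(classes)
            for i, obs_vec in enumerate(observations):
                key = _observation_key(obs_vec[jj], dosage)
                if key is None:
                    continue
                match = cls == idx.get(key, -1)
                if eps == 0.0:
                    E[j, i] = match.astype(float)
                else:
                    E[j, i] = np.where(match, 1.0 - eps, eps / max(K - 1, 1))
        return E

    # -- forward/backward --------------------------------------------------

    def run(self, observations: Sequence[Sequence], dosage: bool = True) -> "MultipointResult":
        E = self.emission_matrix(observations, dosage)
        n = len(observations)
        m, S2 = self.m, self.n_states
        F = np.empty((m, n, S2))
        B = np.empty((m, n, S2))
        c = np.empty((m, n))

        f = self.initial[None, :] * E[0]
        c[0] = f.sum(axis=1)
        ok0 = c[0] > 0
        f[ok0] /= c[0][ok0, None]
        f[~ok0] = 1.0 / S2
        F[0] = f
        for j in range(1, m):
            f = (F[j - 1] @ self.transitions[j - 1]) * E[j]
            c[j] = f.sum(axis=1)
            ok = c[j] > 0
            f[ok] /= c[j][ok, None]
            f[~ok] = 1.0 / S2
            F[j] = f

        B[m - 1] = 1.0
        for j in range(m - 2, -1, -1):
            b = (E[j + 1] * B[j + 1]) @ self.transitions[j].T
            scale = np.where(c[j + 1] > 0, c[j + 1], 1.0)
            B[j] = b / scale[:, None]

        ok = (c > 0).all(axis=0)
        loglik = np.where(ok, np.log(np.maximum(c, _ZERO)).sum(axis=0), -np.inf)
        return MultipointResult(self, F, B, c, E, loglik, ok)


@dataclass
class MultipointResult:
    """Forward–backward state of one family under one pairing model."""

    model: MultipointModel
    F: np.ndarray  # (m, n, S^2) scaled forward
    B: np.ndarray  # (m, n, S^2) scaled backward
    c: np.ndarray  # (m, n) scaling factors
    E: np.ndarray  # (m, n, S^2) emissions
    loglik: np.ndarray  # (n,) observation log-likelihood, -inf if impossible
    ok: np.ndarray  # (n,) bool, False for zero-likelihood individuals
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def n(self) -> int:
        return self.F.shape[1]

    def _internal_interval(self, j: int) -> int:
        m = self.model.m
        if not 0 <= j < m - 1:
            raise IndexError("interval index out of range")
        return m - 2 - j if self.model._reversed else j

    def state_posterior(self, j: int) -> np.ndarray:
        """(n, S^2) posterior over joint origin states at marker ``j``."""
        jj = self.model.m - 1 - j if self.model._reversed else j
        g = self.F[jj] * self.B[jj]
        tot = g.sum(axis=1, keepdims=True)
        return np.divide(g, tot, out=np.full_like(g, np.nan), where=tot > 0)

    def pairwise_posterior(self, j: int) -> np.ndarray:
        """(n, S^2, S^2) posterior over phased configurations at interval ``j``.

        Entry [i, u, v] is the posterior probability that individual i has
        joint origin state u at the left marker of the interval and v at the
        right one, given its full marker phenotype vector.  When the anchor
        is on the right the axes still refer to the user's (left, right)
        marker order.
        """
        jj = self._internal_interval(j)
        T = self.model.transitions[jj]
        xi = (
            self.F[jj][:, :, None]
            * T[None, :, :]
            * (self.E[jj + 1] * self.B[jj + 1])[:, None, :]
        )
        tot = xi.sum(axis=(1, 2), keepdims=True)
        xi = np.divide(xi, tot, out=np.full_like(xi, np.nan), where=tot > 0)
        if self.model._reversed:
            xi = np.swapaxes(xi, 1, 2)
        return xi

    # -- QTL posteriors ----------------------------------------------------

    def _gamete_qtl_kernel(self, j_int: int, d_left: float, d_right: float):
        """Per-parent kernels through a QTL placed inside internal interval j."""
        model = self.model
        A = model._single_transition(d_left)   # marker_j -> QTL
        Bt = model._single_transition(d_right)  # QTL -> marker_{j+1}
        return A, Bt

    def qtl_origin_posterior(self, j: int, d_left: float, d_right: float) -> np.ndarray:
        """(n, S, S) joint posterior of the two gametes' QTL origin states.

        ``d_left``/``d_right`` are map distances (cM) from the QTL to the
        left/right marker of interval ``j`` (user orientation).
        """
        jj = self._internal_interval(j)
        if self.model._reversed:
            d_left, d_right = d_right, d_left
        key = ("rho", jj, round(d_left, 9), round(d_right, 9))
        if key in self._cache:
            return self._cache[key]
        S = self.model.S
        A, Bt = self._gamete_qtl_kernel(jj, d_left, d_right)
        F = self.F[jj].reshape(self.n, S, S)
        G = (self.E[jj + 1] * self.B[jj + 1]).reshape(self.n, S, S)
        # maternal axis first: U pulls the forward mass through A for parent 1,
        # V pulls the backward mass through B; the elementwise product joins
        # the two half-chains at the QTL for both parents.
        U = np.einsum("sq,nsp->nqp", A, F)
        V = np.einsum("qs,nsp->nqp", Bt, G)
        R1 = np.einsum("nqp,pt->nqt", U, A)
        R2 = np.einsum("nqs,ts->nqt", V, Bt)
        rho = R1 * R2
        tot = rho.sum(axis=(1, 2), keepdims=True)
        rho = np.divide(rho, tot, out=np.zeros_like(rho), where=tot > 0)
        self._cache[key] = rho
        return rho

    def qtl_dosage_posterior(
        self,
        j: int,
        d_left: float,
        d_right: float,
        q_placement1: Sequence[int],
        q_placement2: Sequence[int],
    ) -> np.ndarray:
        """(n, 5) posterior over offspring QTL dosage given the marker data.

        This is the marker-conditional QTL genotype distribution of the
        likelihood factorization: the QTL dosage contributed by each gamete
        is the number of its two chromatid origins that fall on homologues
        carrying Q under the given parental placement.
        """
        rho = self.qtl_origin_posterior(j, d_left, d_right)
        q1 = tuple(int(b) for b in q_placement1)
        q2 = tuple(int(b) for b in q_placement2)
        key = ("dose", q1, q2)
        M = self._cache.get(key)
        if M is None:
            ori = self.model.proc.origins
            a1 = np.asarray(q1)
            a2 = np.asarray(q2)
            c1 = a1[ori[:, 0]] + a1[ori[:, 1]]
            c2 = a2[ori[:, 0]] + a2[ori[:, 1]]
            k = (c1[:, None] + c2[None, :]).ravel()
            M = np.zeros((k.size, 5))
            M[np.arange(k.size), k] = 1.0
            self._cache[key] = M
        return rho.reshape(self.n, -1) @ M


def pairwise_posteriors(
    params: HMMParameters, observations: Sequence[Sequence], dosage: bool = True
) -> "tuple[list[np.ndarray], np.ndarray]":
    """Posterior of every adjacent-pair phased configuration, per individual.

    Returns (list over intervals of (n, S^2, S^2) arrays, ok mask); rows of
    excluded (zero-likelihood) individuals are NaN.
    """
    res = MultipointModel(params).run(observations, dosage)
    return [res.pairwise_posterior(j) for j in range(params.cm_positions.size - 1)], res.ok
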