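"""Likelihood scan for a QTL on an autotetraploid linkage group.

At every tested position the phenotype likelihood is a 5-component normal
mixture whose weights are the marker-conditional QTL dosage probabilities of
each offspring (from the multipoint chain) under a candidate parental QTL
configuration.  Genotype means and the residual variance are estimated by
EM; the test statistic is

    LOD(r_j1) = log10 [ L(G_hat, sigma2_hat | O, Y) / L(G_tilde, sigma2_tilde | O, Y) ]

with the no-QTL likelihood taken at the trait mean and variance of all
individuals.  The parental QTL genotype and linkage phase are unknown, so
the scan is repeated over all 92 phase-labelled parental configurations and
the winner is the configuration with the lowest BIC = ln(n) k - 2 ln(L)
subject to the higher-value parent P1 having the larger estimated genotypic
value and the monogenic effect being positive (which resolves the eight
mirrored configurations whose likelihood profiles duplicate another's).
Genome-wide significance comes from permutation of the trait values over
the marker data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .genetics import (
    ContrastMatrix,
    GeneticEffects,
    ParentalQTLConfiguration,
    build_contrasts,
    enumerate_configurations,
    genotype_means,
    solve_effects,
    variance_decomposition,
)
from .hmm import HMMParameters, MultipointModel, MultipointResult
from .meiosis import PairingModel

__all__ = [
    "EMResult",
    "ScanResult",
    "QtlScan",
    "em_fit",
    "lod_at",
    "scan",
    "permutation_threshold",
]

_LN10 = np.log(10.0)
_LOGROOT2PI = 0.5 * np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# EM for the normal-mixture genotype model


def _null_loglik(y: np.ndarray) -> float:
    v = y.var()
    return float(-0.5 * len(y) - len(y) * (_LOGROOT2PI + 0.5 * np.log(v)))


def _log_density(y: np.ndarray, G: np.ndarray, s2: np.ndarray) -> np.ndarray:
    # y (n,) or (B, n); G (B, 5); s2 (B,)
    yy = y[None, :, None] if y.ndim == 1 else y[:, :, None]
    return (
        -0.5 * (yy - G[:, None, :]) ** 2 / s2[:, None, None]
        - _LOGROOT2PI
        - 0.5 * np.log(s2)[:, None, None]
    )


def _em_batch(
    y: np.ndarray,
    priors: np.ndarray,
    G0: np.ndarray,
    s20: np.ndarray,
    tol: float,
    max_iter: int,
):
    """Run B independent EMs sharing the same structure.

    y: (n,) or (B, n); priors: (B, n, 5); G0: (B, 5); s20: (B,).
    Returns (G, s2, loglik, omega, n_iter, converged).
    """
    B, n, _ = priors.shape
    G = G0.copy()
    s2 = s20.copy()
    ymat = np.ascontiguousarray(np.broadcast_to(y if y.ndim == 2 else y[None, :], (B, n)))
    ll_out = np.full(B, -np.inf)
    omega_out = np.empty_like(priors)
    active = np.arange(B)
    pa, ya = priors, ymat
    ll_prev = np.full(B, -np.inf)
    it = 0
    while it < max_iter and active.size:
        it += 1
        Ga, s2a = G[active], s2[active]
        z = ya[:, :, None] - Ga[:, None, :]
        logd = -0.5 * z * z / s2a[:, None, None] - _LOGROOT2PI - 0.5 * np.log(s2a)[:, None, None]
        dens = pa * np.exp(logd)
        li = np.maximum(dens.sum(axis=2), 1e-300)
        ll = np.log(li).sum(axis=1)
        om = dens / li[:, :, None]
        den = om.sum(axis=1)
        num = np.einsum("bnk,bn->bk", om, ya)
        Ga = np.where(den > 1e-12, num / np.maximum(den, 1e-12), Ga)
        z = ya[:, :, None] - Ga[:, None, :]
        s2a = np.maximum((om * z * z).sum(axis=(1, 2)) / n, 1e-12)
        G[active], s2[active] = Ga, s2a
        ll_out[active] = ll
        omega_out[active] = om
        done = np.abs(ll - ll_prev[active]) < tol
        ll_prev[active] = ll
        if done.any():
            keep = ~done
            active = active[keep]
            pa = pa[keep]
            ya = ya[keep]
    return G, s2, ll_out, omega_out, it, active.size == 0


def _kmeans1d(y: np.ndarray, K: int, rng: np.random.Generator, restarts: int = 10) -> np.ndarray:
    """Lloyd's algorithm on a 1-D sample; returns sorted cluster means."""
    best, best_inertia = None, np.inf
    for _ in range(restarts):
        centers = np.sort(rng.choice(y, size=K, replace=False).astype(float))
        for _ in range(100):
            d = np.abs(y[:, None] - centers[None, :])
            lab = d.argmin(axis=1)
            new = np.array(
                [y[lab == k].mean() if np.any(lab == k) else centers[k] for k in range(K)]
            )
            if np.allclose(new, centers):
                centers = new
                break
            centers = new
        inertia = ((y - centers[lab]) ** 2).sum()
        if inertia < best_inertia:
            best, best_inertia = np.sort(centers), inertia
    return best


@dataclass
class EMResult:
    G: np.ndarray  # (5,) genotype means, NaN off support
    sigma2: float
    loglik: float
    omega: np.ndarray  # (n, 5) posterior genotype memberships
    trace: np.ndarray  # per-iteration log-likelihood
    converged: bool
    support: np.ndarray  # (5,) bool


def em_fit(
    y: Sequence[float],
    qtl_posteriors: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int | None = 0,
    init: "tuple[np.ndarray, float] | None" = None,
) -> EMResult:
    """Maximum-likelihood genotype means and residual variance by EM.

    ``qtl_posteriors`` is the (n, 5) matrix of marker-conditional QTL dosage
    probabilities per individual.  E step: posterior genotype memberships
    from the current normal densities and the marker-conditional weights;
    M step: weighted means for G_k and the n-denominator variance update.
    Initialization uses the sample variance and K-means cluster centres of y
    (K = number of segregating dosage classes), and the fit is restarted
    from the no-QTL parameters if it ends below the null likelihood, so the
    reported maximum is never worse than the null.
    """
    y = np.asarray(y, dtype=float)
    priors = np.asarray(qtl_posteriors, dtype=float)
    if priors.ndim != 2 or priors.shape != (len(y), 5):
        raise ValueError("qtl_posteriors must be (n, 5)")
    if len(y) < 3:
        raise ValueError("not enough individuals")
    p_agg = priors.mean(axis=0)
    support = p_agg > 1e-9
    if support.sum() < 1:
        raise ValueError("empty posterior support")
    rng = np.random.default_rng(seed)
    ybar, yvar = y.mean(), y.var()

    if init is not None:
        G0 = np.asarray(init[0], dtype=float)[None, :].copy()
        s20 = np.array([float(init[1])])
    else:
        K = int(support.sum())
        G0 = np.full((1, 5), ybar)
        if K >= 2:
            centers = _kmeans1d(y, K, rng)
            G0[0, np.flatnonzero(support)] = centers
        s20 = np.array([yvar])

    trace = _em_trace(y, priors, G0[0], s20[0], tol, max_iter)
    G, s2, ll, omega, _, converged = _em_batch(y, priors[None], G0, s20, tol, max_iter)
    llnull = _null_loglik(y)
    if ll[0] < llnull - 1e-9:
        Gn = np.full((1, 5), ybar)
        G2, s22, ll2, om2, _, conv2 = _em_batch(
            y, priors[None], Gn, np.array([yvar]), tol, max_iter
        )
        if ll2[0] > ll[0]:
            G, s2, ll, omega, converged = G2, s22, ll2, om2, conv2
    Gout = np.where(support, G[0], np.nan)
    return EMResult(
        G=Gout,
        sigma2=float(s2[0]),
        loglik=float(ll[0]),
        omega=omega[0],
        trace=trace,
        converged=bool(converged),
        support=support,
    )


def _em_trace(y, priors, G0, s20, tol, max_iter) -> np.ndarray:
    """Per-iteration log-likelihood of a single EM run (for diagnostics)."""
    G = G0.copy()
    s2 = float(s20)
    out = []
    prev = -np.inf
    for _ in range(max_iter):
        dens = priors * np.exp(
            -0.5 * (y[:, None] - G[None, :]) ** 2 / s2
            - _LOGROOT2PI
            - 0.5 * np.log(s2)
        )
        li = np.maximum(dens.sum(axis=1), 1e-300)
        ll = float(np.log(li).sum())
        out.append(ll)
        om = dens / li[:, None]
        den = om.sum(axis=0)
        G = np.where(den > 1e-12, (om * y[:, None]).sum(axis=0) / np.maximum(den, 1e-12), G)
        s2 = max(float((om * (y[:, None] - G[None, :]) ** 2).sum() / len(y)), 1e-12)
        if abs(ll - prev) < tol:
            break
        prev = ll
    return np.asarray(out)


# ---------------------------------------------------------------------------
# the scan


@dataclass
class ScanResult:
    """Outcome of a likelihood scan over one linkage group."""

    positions_cm: np.ndarray
    intervals: np.ndarray
    r1: np.ndarray
    lod: np.ndarray  # profile of the selected configuration
    lod_by_config: np.ndarray  # (n_config, n_pos)
    bic_by_config: np.ndarray  # (n_config, n_pos)
    configurations: list
    best_config: ParentalQTLConfiguration
    best_config_index: int
    peak_index: int
    peak_cm: float
    peak_lod: float
    bic: float
    effects: GeneticEffects
    contrasts: ContrastMatrix
    genotype_probs: np.ndarray
    vg_percent: float
    rho_additive: float
    threshold: float | None
    n_used: int
    dropped: list
    seed: int | None
    settings: dict
    _ctx: dict = field(default_factory=dict, repr=False)


def _position_grid(cm: np.ndarray, grid_step: float):
    positions, intervals = [], []
    for j in range(len(cm) - 1):
        p = cm[j]
        while p < cm[j + 1] - 1e-9:
            positions.append(p)
            intervals.append(j)
            p += grid_step
    positions.append(cm[-1])
    intervals.append(len(cm) - 2)
    return np.asarray(positions), np.asarray(intervals)


def _config_priors(
    res: MultipointResult,
    j: int,
    d_left: float,
    d_right: float,
    configs: "list[ParentalQTLConfiguration]",
    keep: np.ndarray,
) -> np.ndarray:
    """(C, n_keep, 5) marker-conditional QTL dosage probabilities."""
    out = np.empty((len(configs), int(keep.sum()), 5))
    for ci, cfg in enumerate(configs):
        post = res.qtl_dosage_posterior(j, d_left, d_right, cfg.p1, cfg.p2)
        out[ci] = post[keep]
    return out


def scan(
    cm_positions: Sequence[float],
    parent1: Sequence[Sequence[str]],
    parent2: Sequence[Sequence[str]],
    observations: Sequence[Sequence],
    y: Sequence[float],
    pairing: PairingModel | str = "quadrivalent",
    lam: float | None = None,
    alpha: float = 0.0,
    anchor: str = "left",
    dosage_scoring: bool = True,
    epsilon: float = 0.0,
    grid_step: float = 1.0,
    configs: "list[ParentalQTLConfiguration] | None" = None,
    em_tol: float = 1e-8,
    em_max_iter: int = 500,
    seed: int | None = 0,
    incompatible_policy: str | None = None,
    n_perm: int = 0,
    quantile: float = 0.95,
    bic_k: str = "full",
) -> ScanResult:
    """Interval-mapping scan with configuration search (see module docstring).

    ``incompatible_policy`` governs individuals whose marker phenotypes have
    zero likelihood under the assumed pairing model: ``"remove"`` drops them
    (default for the bivalent model, the protocol used when bivalent-based
    methods meet quadrivalent data), ``"missing"`` blanks the offending loci
    first and drops only individuals that remain impossible, ``"keep"``
    raises if any occur.  If ``n_perm`` > 0 a permutation threshold at the
    given quantile is attached.
    """
    pairing = PairingModel.coerce(pairing, lam)
    if incompatible_policy is None:
        incompatible_policy = "remove" if pairing.mode == "bivalent" else "keep"
    if incompatible_policy not in ("remove", "missing", "keep"):
        raise ValueError("incompatible_policy must be remove, missing or keep")
    y = np.asarray(y, dtype=float)
    observations = [list(o) for o in observations]
    if len(observations) != len(y):
        raise ValueError("genotype and trait tables differ in length")
    params = HMMParameters(
        cm_positions, parent1, parent2, pairing, alpha=alpha, anchor=anchor, epsilon=epsilon
    )
    model = MultipointModel(params)
    res = model.run(observations, dosage=dosage_scoring)
    keep = res.ok.copy()
    if not keep.all():
        bad = np.flatnonzero(~keep)
        if incompatible_policy == "keep":
            raise ValueError(
                f"{bad.size} individuals have zero-likelihood marker phenotypes "
                "under this pairing model (use policy 'remove' or 'missing')"
            )
        if incompatible_policy == "missing":
            for i in bad:
                for j in range(model.m):
                    obs = observations[i][j]
                    if obs is None:
                        continue
                    from .hmm import _observation_key

                    if _observation_key(obs, dosage_scoring) not in model.reachable_classes(
                        j, dosage_scoring
                    ):
                        observations[i][j] = None
            res = model.run(observations, dosage=dosage_scoring)
            keep = res.ok.copy()
    dropped = np.flatnonzero(~keep).tolist()
    n_used = int(keep.sum())
    if n_used < 10:
        raise ValueError("fewer than 10 usable individuals")
    yk = y[keep]

    if configs is None:
        configs = enumerate_configurations()
    cm = np.asarray(cm_positions, dtype=float)
    positions, intervals = _position_grid(cm, grid_step)
    P, C = len(positions), len(configs)
    rng = np.random.default_rng(seed)

    llnull = _null_loglik(yk)
    ybar, yvar = yk.mean(), yk.var()
    kmeans_centers = {
        K: _kmeans1d(yk, K, rng) for K in range(2, 6)
    }

    # a mirrored configuration's mixture is its partner's with the dosage
    # classes reflected (k -> 6-k for the (4,1) pairs, k -> 2-k for (3,0)),
    # so its likelihood surface is copied rather than refitted; this also
    # makes the profile duplication exact
    label_to_idx = {c.label: i for i, c in enumerate(configs)}
    partner_of = {}
    for i, c in enumerate(configs):
        if c.mirrored:
            partner = c.mirror_partner()
            j = label_to_idx.get(partner.label)
            if j is not None:
                ref = 6 if c.dosage == (4, 1) else 2
                perm = np.array([ref - k if 0 <= ref - k <= 4 else k for k in range(5)])
                partner_of[i] = (j, perm)
    fit_idx = np.array([i for i in range(C) if i not in partner_of])

    lods = np.zeros((C, P))
    bics = np.zeros((C, P))
    Gs = np.zeros((C, P, 5))
    s2s = np.zeros((C, P))
    supports = np.zeros((C, P, 5), dtype=bool)
    prior_store = {}

    for pi, (pos, j) in enumerate(zip(positions, intervals)):
        d_left = pos - cm[j]
        d_right = cm[j + 1] - pos
        priors = _config_priors(res, j, d_left, d_right, configs, keep)
        prior_store[pi] = priors
        p_agg = priors.mean(axis=1)  # (C, 5)
        sup = p_agg > 1e-9
        G0 = np.full((C, 5), ybar)
        for ci in range(C):
            K = int(sup[ci].sum())
            if K >= 2:
                G0[ci, np.flatnonzero(sup[ci])] = kmeans_centers[K]
        s20 = np.full(C, yvar)
        G = G0.copy()
        s2 = s20.copy()
        ll = np.full(C, llnull)
        Gf, s2f, llf, _, _, _ = _em_batch(
            yk, priors[fit_idx], G0[fit_idx], s20[fit_idx], em_tol, em_max_iter
        )
        # never report a fitted likelihood below the no-QTL model
        low = llf < llnull - 1e-9
        if low.any():
            Gn = np.full((int(low.sum()), 5), ybar)
            G2, s22, ll2, _, _, _ = _em_batch(
                yk, priors[fit_idx][low], Gn, np.full(int(low.sum()), yvar), em_tol, em_max_iter
            )
            better = ll2 > llf[low]
            idx = np.flatnonzero(low)[better]
            Gf[idx], s2f[idx], llf[idx] = G2[better], s22[better], ll2[better]
        G[fit_idx], s2[fit_idx], ll[fit_idx] = Gf, s2f, llf
        for i, (j, perm) in partner_of.items():
            G[i] = G[j][perm]
            s2[i] = s2[j]
            ll[i] = ll[j]
            sup[i] = sup[j][perm]
        if bic_k == "full":
            # mean + the four genetic effects + residual variance
            kpar = np.full(C, 6)
        else:  # "estimable": count only effects the cross can determine
            kpar = 2 + (sup.sum(axis=1) - 1)
        lods[:, pi] = np.maximum(ll - llnull, 0.0) / _LN10
        bics[:, pi] = np.log(n_used) * kpar - 2.0 * ll
        Gs[:, pi] = G
        s2s[:, pi] = s2
        supports[:, pi] = sup

    # -- configuration selection -------------------------------------------
    order = []
    for ci, cfg in enumerate(configs):
        peak = int(lods[ci].argmax())
        order.append((float(bics[ci].min()), -float(lods[ci, peak]), cfg.label, ci))
    order.sort()

    chosen = None
    for _, _, _, ci in order:
        cfg = configs[ci]
        peak = int(lods[ci].argmax())
        prior = prior_store[peak][ci]
        eff, W, pbar = _effects_at(yk, prior, Gs[ci, peak], s2s[ci, peak], supports[ci, peak])
        if eff is None or not eff.estimable[0] or not eff.theta[0] > 0:
            continue
        d1, d2 = cfg.dosage
        Gm = genotype_means(eff, W)
        if W.support[d1] and W.support[d2] and not Gm[d1] > Gm[d2]:
            continue
        chosen = (ci, peak, eff, W, pbar)
        break
    if chosen is None:
        # no configuration satisfies the sign/ordering constraints (typical
        # of null data where theta1 hovers around 0); fall back to the
        # BIC-best configuration whose effects are solvable
        for _, _, _, ci in order:
            cfg = configs[ci]
            peak = int(lods[ci].argmax())
            prior = prior_store[peak][ci]
            eff, W, pbar = _effects_at(
                yk, prior, Gs[ci, peak], s2s[ci, peak], supports[ci, peak]
            )
            if eff is not None:
                warnings.warn(
                    "no configuration met the monogenic-sign and parental-order "
                    "constraints; reporting the BIC-best configuration"
                )
                chosen = (ci, peak, eff, W, pbar)
                break
    if chosen is None:
        raise RuntimeError("no parental QTL configuration could be fitted")
    ci, peak, eff, W, pbar = chosen
    cfg = configs[ci]
    vg, rho = variance_decomposition(eff, W)

    result = ScanResult(
        positions_cm=positions,
        intervals=intervals,
        r1=np.array(
            [
                _r_of(pos - cm[j], pairing.mode)
                for pos, j in zip(positions, intervals)
            ]
        ),
        lod=lods[ci],
        lod_by_config=lods,
        bic_by_config=bics,
        configurations=configs,
        best_config=cfg,
        best_config_index=ci,
        peak_index=peak,
        peak_cm=float(positions[peak]),
        peak_lod=float(lods[ci, peak]),
        bic=float(bics[ci].min()),
        effects=eff,
        contrasts=W,
        genotype_probs=pbar,
        vg_percent=vg,
        rho_additive=rho,
        threshold=None,
        n_used=n_used,
        dropped=dropped,
        seed=seed,
        settings={
            "pairing": pairing.mode,
            "lam": pairing.lam,
            "alpha": alpha,
            "anchor": anchor,
            "grid_step": grid_step,
            "epsilon": epsilon,
            "em_tol": em_tol,
            "em_max_iter": em_max_iter,
            "incompatible_policy": incompatible_policy,
            "dosage_scoring": dosage_scoring,
        },
        _ctx={
            "y": yk,
            "prior_store": prior_store,
            "llnull": llnull,
            "em_tol": em_tol,
            "em_max_iter": em_max_iter,
        },
    )
    if n_perm > 0:
        result.threshold = permutation_threshold(
            result, n_perm=n_perm, quantile=quantile, seed=seed
        )
    return result


def _r_of(d_cm: float, mode: str) -> float:
    from .meiosis import recombination_fraction

    return recombination_fraction(max(d_cm, 0.0), "quadrivalent" if mode == "mixed" else mode)


def _effects_at(y, prior, G, s2, support):
    """Solve (mu, theta) at a fitted position from the E-step aggregate."""
    dens = prior * np.exp(
        -0.5 * (y[:, None] - np.where(support, G, y.mean())[None, :]) ** 2 / s2
        - _LOGROOT2PI
        - 0.5 * np.log(s2)
    )
    li = np.maximum(dens.sum(axis=1), 1e-300)
    omega = dens / li[:, None]
    pbar = omega.mean(axis=0)
    pbar = pbar / pbar.sum()
    if (pbar > 1e-9).sum() < 2:
        return None, None, pbar
    try:
        W = build_contrasts(pbar)
        eff = solve_effects(np.where(support, G, np.nan), W, sigma2=s2)
    except (ValueError, np.linalg.LinAlgError):
        return None, None, pbar
    return eff, W, pbar


def lod_at(
    result: ScanResult, position_cm: float, config: ParentalQTLConfiguration | None = None
) -> float:
    """LOD of the (selected) configuration at the grid position nearest ``position_cm``."""
    pi = int(np.abs(result.positions_cm - position_cm).argmin())
    if config is None:
        return float(result.lod[pi])
    ci = result.configurations.index(config)
    return float(result.lod_by_config[ci, pi])


def permutation_threshold(
    result: ScanResult,
    n_perm: int = 100,
    quantile: float = 0.95,
    seed: int | None = 0,
) -> float:
    """Genome-wide LOD threshold from trait permutations.

    Trait values are shuffled against the marker data ``n_perm`` times; each
    permutation replays the EM scan of the selected configuration over the
    full position grid and records its maximum LOD; the requested quantile
    of these maxima is returned.  Marker-conditional genotype probabilities
    are unchanged by permutation and are reused.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ctx = result._ctx
    if not ctx:
        raise ValueError("ScanResult lacks scan context (was it deserialized?)")
    y = ctx["y"]
    n = len(y)
    rng = np.random.default_rng(None if seed is None else seed + 1)
    perm_idx = np.array([rng.permutation(n) for _ in range(n_perm)])
    yp = y[perm_idx]  # (n_perm, n)
    llnull = ctx["llnull"]
    ci = result.best_config_index
    maxlod = np.full(n_perm, 0.0)
    # deterministic quantile-based initial centres per permutation
    qs = {
        K: np.linspace(0, 1, K + 2)[1:-1] for K in range(2, 6)
    }
    for pi in range(len(result.positions_cm)):
        prior = ctx["prior_store"][pi][ci]  # (n, 5)
        priors = np.broadcast_to(prior, (n_perm, n, 5))
        sup = prior.mean(axis=0) > 1e-9
        K = int(sup.sum())
        G0 = np.full((n_perm, 5), y.mean())
        if K >= 2:
            G0[:, np.flatnonzero(sup)] = np.quantile(yp, qs[K], axis=1).T
        s20 = yp.var(axis=1)
        G, s2, ll, _, _, _ = _em_batch(yp, priors.copy(), G0, s20, ctx["em_tol"], ctx["em_max_iter"])
        maxlod = np.maximum(maxlod, np.maximum(ll - llnull, 0.0) / _LN10)
    return float(np.quantile(maxlod, quantile))


# ---------------------------------------------------------------------------
# estimator facade


class QtlScan(BaseEstimator):
    """Interval-mapping scan as a scikit-learn style estimator.

    Parameters mirror :func:`scan`; the linkage map and phased parental
    genotypes are constructor parameters, ``fit(X, y)`` takes the offspring
    marker observations (sequence of per-individual, per-marker observations
    — allele->dosage mappings, presence sets, or None) and the trait values.

    Attributes set by ``fit`` (trailing underscore): ``lod_``,
    ``positions_cm_``, ``best_config_``, ``effects_``, ``vg_percent_``,
    ``rho_additive_``, ``threshold_``, ``peak_cm_``, ``peak_lod_``,
    ``result_`` (the full :class:`ScanResult`).
    """

    def __init__(
        self,
        cm_positions=None,
        parent1=None,
        parent2=None,
        pairing="quadrivalent",
        lam=None,
        alpha=0.0,
        anchor="left",
        dosage_scoring=True,
        epsilon=0.0,
        grid_step=1.0,
        em_tol=1e-8,
        em_max_iter=500,
        n_perm=0,
        quantile=0.95,
        incompatible_policy=None,
        seed=0,
    ):
        self.cm_positions = cm_positions
        self.parent1 = parent1
        self.parent2 = parent2
        self.pairing = pairing
        self.lam = lam
        self.alpha = alpha
        self.anchor = anchor
        self.dosage_scoring = dosage_scoring
        self.epsilon = epsilon
        self.grid_step = grid_step
        self.em_tol = em_tol
        self.em_max_iter = em_max_iter
        self.n_perm = n_perm
        self.quantile = quantile
        self.incompatible_policy = incompatible_policy
        self.seed = seed

    def fit(self, X, y):
        if self.cm_positions is None or self.parent1 is None or self.parent2 is None:
            raise ValueError("cm_positions, parent1 and parent2 are required")
        result = scan(
            self.cm_positions,
            self.parent1,
            self.parent2,
            X,
            y,
            pairing=self.pairing,
            lam=self.lam,
            alpha=self.alpha,
            anchor=self.anchor,
            dosage_scoring=self.dosage_scoring,
            epsilon=self.epsilon,
            grid_step=self.grid_step,
            em_tol=self.em_tol,
            em_max_iter=self.em_max_iter,
            seed=self.seed,
            incompatible_policy=self.incompatible_policy,
            n_perm=self.n_perm,
            quantile=self.quantile,
        )
        self.result_ = result
        self.lod_ = result.lod
        self.positions_cm_ = result.positions_cm
        self.best_config_ = result.best_config
        self.effects_ = result.effects
        self.vg_percent_ = result.vg_percent
        self.rho_additive_ = result.rho_additive
        self.threshold_ = result.threshold
        self.peak_cm_ = result.peak_cm
        self.peak_lod_ = result.peak_lod
        return self

    def predict(self, X=None):
        """Posterior-mean genotypic value of each fitted individual at the peak."""
        if not hasattr(self, "result_"):
            raise ValueError("fit first")
        res = self.result_
        prior = res._ctx["prior_store"][res.peak_index][res.best_config_index]
        G = genotype_means(res.effects, res.contrasts)
        g = np.where(res.contrasts.support, G, 0.0)
        w = prior * res.contrasts.support
        w = w / np.maximum(w.sum(axis=1, keepdims=True), 1e-300)
        return w @ g
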