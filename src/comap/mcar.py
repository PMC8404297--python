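"""Multivariate Poisson disease-mapping models with coregionalized Leroux-CAR
spatial random effects, fitted by Metropolis-within-Gibbs MCMC.

Model
-----
Observed counts ``Y[i, j]`` for area ``i`` and disease ``j`` follow

    Y[i, j] ~ Poisson(E[i, j] * exp(beta[j] + phi[i, j]))

where ``E`` are expected counts under indirect (internal) standardization,
``beta[j]`` is a disease-specific intercept and ``phi[:, j]`` a
disease-specific spatial random effect.  The multivariate field ``phi`` is a
linear model of co-regionalization:

    phi = u @ A.T,        Sigma = A A'   (A lower triangular, Cholesky)

with latent processes ``u[:, l]`` independent across ``l``, each a Leroux CAR
field with precision ``Q(rho_l) = rho_l (D - W) + (1 - rho_l) I`` and unit
conditional scale; all marginal scale lives in ``Sigma``.

Three variants:

* ``M1`` — correlated diseases, disease-specific ``rho_j``;
* ``M2`` — correlated diseases, one shared ``rho`` (separable model);
* ``M3`` — independent diseases (``Sigma`` diagonal), disease-specific
  ``rho_j``; equivalent to univariate mapping of each disease.

Priors: uniform(0, sd_upper) on the standard deviations ``sqrt(Sigma_jj)``,
uniform(0, 1) on the pairwise correlations and on the spatial parameter(s)
``rho``, and a weakly informative Gaussian prior (mean 0, precision 0.1) on
the intercepts.  Positive definiteness of ``Sigma`` is enforced by rejection
(log-posterior of ``-inf``), not by reparameterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy.special import expit, gammaln, logit

from .geography import AdjacencyGraph

__all__ = [
    "MCARModelSpec",
    "PosteriorState",
    "MCMCControl",
    "ChainOutput",
    "leroux_precision",
    "leroux_logdet",
    "correlation_matrix",
    "log_posterior",
    "initial_states",
    "fit_mcmc",
]

_PAIRS3 = ((0, 1), (0, 2), (1, 2))


def _pairs(J: int):
    return tuple((a, b) for a in range(J) for b in range(a + 1, J))


# ---------------------------------------------------------------------------
# Specs and states
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MCARModelSpec:
    """Model variant and prior settings.

    ``likelihood="gaussian"`` replaces the Poisson observation model by
    ``y[i, j] ~ N(beta[j] + phi[i, j], gaussian_tau**2)`` (``E`` ignored);
    this exists as a validation harness because it makes the full
    conditional of ``u`` Gaussian with a closed form.
    """

    variant: str = "M2"
    n_diseases: int = 3
    prior_sd_upper: float = 10.0
    intercept_prior_precision: float = 0.1
    likelihood: str = "poisson"
    gaussian_tau: float = 1.0

    def __post_init__(self):
        if self.variant not in ("M1", "M2", "M3"):
            raise ValueError(f"unknown model variant {self.variant!r}")
        if self.prior_sd_upper <= 0:
            raise ValueError("prior_sd_upper must be > 0")
        if self.likelihood not in ("poisson", "gaussian"):
            raise ValueError(f"unknown likelihood {self.likelihood!r}")

    @property
    def shared_rho(self) -> bool:
        return self.variant == "M2"

    @property
    def correlated(self) -> bool:
        return self.variant in ("M1", "M2")


@dataclass
class PosteriorState:
    """One MCMC state.

    ``sigma_corr`` holds the pairwise correlations in the order
    (1,2), (1,3), (2,3); for M3 it is identically zero.  ``rho`` is a scalar
    for M2 and a length-``n_diseases`` vector for M1/M3.
    """

    beta: np.ndarray
    u: np.ndarray
    sigma_sd: np.ndarray
    sigma_corr: np.ndarray
    rho: np.ndarray

    def copy(self) -> "PosteriorState":
        return PosteriorState(
            self.beta.copy(), self.u.copy(), self.sigma_sd.copy(),
            self.sigma_corr.copy(), np.array(self.rho, copy=True),
        )

    def rho_per_latent(self, J: int) -> np.ndarray:
        r = np.atleast_1d(np.asarray(self.rho, dtype=float))
        return np.full(J, r[0]) if r.size == 1 else r

    def correlation_matrix(self) -> np.ndarray:
        return correlation_matrix(self.sigma_corr, len(self.beta))

    def sigma_matrix(self) -> np.ndarray:
        R = self.correlation_matrix()
        return R * np.outer(self.sigma_sd, self.sigma_sd)

    def cholesky(self) -> np.ndarray:
        """Lower-triangular A with Sigma = A A'; raises if Sigma not PD."""
        return self.sigma_sd[:, None] * np.linalg.cholesky(self.correlation_matrix())

    def phi(self) -> np.ndarray:
        return self.u @ self.cholesky().T

    def is_valid(self, spec: MCARModelSpec) -> bool:
        rho = self.rho_per_latent(len(self.beta))
        if np.any(rho < 0) or np.any(rho >= 1):
            return False
        if np.any(self.sigma_sd <= 0) or np.any(self.sigma_sd >= spec.prior_sd_upper):
            return False
        if spec.correlated:
            if np.any(self.sigma_corr <= 0) or np.any(self.sigma_corr >= 1):
                return False
        elif np.any(self.sigma_corr != 0):
            return False
        try:
            np.linalg.cholesky(self.correlation_matrix())
        except np.linalg.LinAlgError:
            return False
        return True


def correlation_matrix(sigma_corr: np.ndarray, J: int) -> np.ndarray:
    """Assemble the J x J correlation matrix from pairwise entries."""
    R = np.eye(J)
    for p, (a, b) in enumerate(_pairs(J)):
        R[a, b] = R[b, a] = sigma_corr[p]
    return R


# ---------------------------------------------------------------------------
# Leroux CAR precision
# ---------------------------------------------------------------------------

def leroux_precision(graph: AdjacencyGraph, rho: float) -> np.ndarray:
    """Precision matrix ``Q(rho) = rho (D - W) + (1 - rho) I``.

    Interpolates between independence (rho = 0) and the intrinsic CAR
    (rho -> 1); symmetric positive definite for rho in [0, 1).
    """
    if not 0 <= rho < 1:
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    W = graph.W.astype(float)
    D = np.diag(W.sum(axis=1))
    n = graph.n_areas
    return rho * (D - W) + (1 - rho) * np.eye(n)


def _structure_eigvals(graph: AdjacencyGraph) -> np.ndarray:
    """Eigenvalues of (D - W), precomputable once per graph."""
    W = graph.W.astype(float)
    L = np.diag(W.sum(axis=1)) - W
    return np.linalg.eigvalsh(L)


def leroux_logdet(graph_or_eigvals, rho: float) -> float:
    """log det Q(rho) via the eigenvalues of the graph Laplacian D - W."""
    lam = (
        _structure_eigvals(graph_or_eigvals)
        if isinstance(graph_or_eigvals, AdjacencyGraph)
        else np.asarray(graph_or_eigvals)
    )
    return float(np.sum(np.log(rho * lam + (1 - rho))))


# ---------------------------------------------------------------------------
# Log posterior
# ---------------------------------------------------------------------------

_LOG2PI = float(np.log(2 * np.pi))


def _loglik(spec: MCARModelSpec, state: PosteriorState, Y, E) -> float:
    phi = state.phi()
    eta = state.beta[None, :] + phi
    if spec.likelihood == "gaussian":
        tau = spec.gaussian_tau
        resid = Y - eta
        return float(np.sum(-0.5 * (resid / tau) ** 2 - np.log(tau) - 0.5 * _LOG2PI))
    valid = ~((E == 0) & (Y == 0))
    if np.any((E == 0) & (Y > 0)):
        raise ValueError("cells with E = 0 but Y > 0: model undefined")
    mu = E[valid] * np.exp(eta[valid])
    y = Y[valid]
    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))


def log_posterior(
    state: PosteriorState,
    spec: MCARModelSpec,
    Y: np.ndarray,
    E: np.ndarray,
    graph: AdjacencyGraph,
) -> float:
    """Unnormalised log posterior density; ``-inf`` outside prior support."""
    Y = np.asarray(Y, dtype=float)
    E = np.asarray(E, dtype=float)
    if not state.is_valid(spec):
        return -np.inf
    J = len(state.beta)
    n = graph.n_areas
    lp = _loglik(spec, state, Y, E)
    # latent Leroux fields, unit conditional scale
    lam = _structure_eigvals(graph)
    rho = state.rho_per_latent(J)
    W = graph.W.astype(float)
    deg = W.sum(axis=1)
    for l in range(J):
        ul = state.u[:, l]
        quad = rho[l] * (ul @ (deg * ul) - ul @ (W @ ul)) + (1 - rho[l]) * (ul @ ul)
        lp += 0.5 * leroux_logdet(lam, rho[l]) - 0.5 * quad - 0.5 * n * _LOG2PI
    # priors
    prec = spec.intercept_prior_precision
    lp += np.sum(0.5 * np.log(prec) - 0.5 * _LOG2PI - 0.5 * prec * state.beta ** 2)
    lp += -J * np.log(spec.prior_sd_upper)  # uniform(0, upper) densities
    # uniform(0,1) terms for corr and rho contribute 0 inside support
    return float(lp)


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------

@dataclass
class MCMCControl:
    """Sampler control parameters.

    ``iterations`` counts total iterations per chain including burn-in;
    retained draws per chain are ``(iterations - burn_in) // thin``.
    ``update`` switches individual parameter blocks off (validation use).
    """

    n_chains: int = 2
    iterations: int = 20_000
    burn_in: int = 10_000
    thin: int = 10
    seed: int = 0
    target_accept: float = 0.44
    adapt_batch: int = 50
    update: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be < iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    def do(self, block: str) -> bool:
        return bool(self.update.get(block, True))

    @property
    def retained_per_chain(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass
class ChainOutput:
    """Retained draws from one or more chains, stacked along the first axis.

    ``chain_id`` labels each draw's chain of origin.  ``phi`` is the
    disease-specific random effect ``u @ A.T`` recomputed per draw; ``mu``
    holds fitted Poisson means ``E * exp(beta + phi)``.
    """

    beta: np.ndarray          # (S, J)
    u: np.ndarray             # (S, n, J)
    sigma_sd: np.ndarray      # (S, J)
    sigma_corr: np.ndarray    # (S, P)
    rho: np.ndarray           # (S,) or (S, J)
    phi: np.ndarray           # (S, n, J)
    mu: np.ndarray            # (S, n, J)
    deviance: np.ndarray      # (S,)
    chain_id: np.ndarray      # (S,)
    meta: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def state(self, s: int) -> PosteriorState:
        rho = self.rho[s] if self.rho.ndim > 1 else np.array(self.rho[s])
        return PosteriorState(
            self.beta[s].copy(), self.u[s].copy(), self.sigma_sd[s].copy(),
            self.sigma_corr[s].copy(), np.array(rho, copy=True),
        )

    @staticmethod
    def concatenate(chunks: Sequence["ChainOutput"]) -> "ChainOutput":
        meta = {"chains": [c.meta for c in chunks]}
        return ChainOutput(
            *(np.concatenate([getattr(c, f) for c in chunks])
              for f in ("beta", "u", "sigma_sd", "sigma_corr", "rho",
                        "phi", "mu", "deviance", "chain_id")),
            meta=meta,
        )


try:  # compiled kernel for the site-wise field update (hot path)
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is a standard install here
    def _njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


@_njit(cache=True)
def _update_field_sites(
    idx, du, logu, u, v, phi, mu, Y, E, validf, beta,
    L_col, sd, W, deg, rho_l, gaussian, tau2,
):
    """Vectorised-in-spirit single-site RW Metropolis over one colour class.

    Sites in ``idx`` are pairwise non-adjacent, so their full conditionals
    given the rest are independent and per-site accept/reject is exact.
    Mutates u (one column as 1-d view), v, phi and mu in place; returns the
    number of accepted moves.
    """
    n = W.shape[0]
    J = phi.shape[1]
    acc = 0
    ds1 = 0.0  # change in u'(D - W)u
    ds0 = 0.0  # change in u'u
    for t in range(idx.shape[0]):
        i = idx[t]
        d = du[t]
        wu = 0.0
        for k in range(n):
            if W[i, k] != 0.0:
                wu += u[k]
        qii = rho_l * deg[i] + (1.0 - rho_l)
        ui = u[i]
        dsq = 2.0 * ui * d + d * d
        dlp = -0.5 * qii * dsq + rho_l * d * wu
        if gaussian:
            for j in range(J):
                dphi = d * L_col[j] * sd[j]
                r = Y[i, j] - beta[j] - phi[i, j]
                dlp += (r * dphi - 0.5 * dphi * dphi) / tau2
        else:
            for j in range(J):
                dphi = d * L_col[j] * sd[j]
                dlp += Y[i, j] * dphi - mu[i, j] * (np.exp(dphi) - 1.0)
        if logu[t] < dlp:
            acc += 1
            u[i] += d
            ds0 += dsq
            ds1 += deg[i] * dsq - 2.0 * d * wu
            for j in range(J):
                v[i, j] += d * L_col[j]
                phi[i, j] = v[i, j] * sd[j]
                if not gaussian and validf[i, j]:
                    mu[i, j] = E[i, j] * np.exp(beta[j] + phi[i, j])
    return acc, ds1, ds0


@_njit(cache=True)
def _chol_small(M):
    """Cholesky of a small symmetric matrix; returns (L, ok)."""
    J = M.shape[0]
    L = np.zeros((J, J))
    for a in range(J):
        s = M[a, a]
        for k in range(a):
            s -= L[a, k] * L[a, k]
        if s <= 1e-12:
            return L, False
        L[a, a] = np.sqrt(s)
        for b in range(a + 1, J):
            t = M[b, a]
            for k in range(a):
                t -= L[b, k] * L[a, k]
            L[b, a] = t / L[a, a]
    return L, True


@_njit(cache=True)
def _update_beta_sd(
    j, db, logu_b, eps, logu_s, beta, sd, sd_upper, v, phi, mu,
    Y, E, validf, prec, gaussian, tau2, do_beta, do_sd,
):
    """Random-walk updates of the intercept and marginal sd of disease j.

    The sd proposal is multiplicative (log-scale RW; the +eps term below is
    the log-scale Jacobian ratio).  Mutates beta, sd, phi, mu in place.
    Returns (beta_accepted, sd_accepted).
    """
    n = phi.shape[0]
    acc_b = 0
    acc_s = 0
    if do_beta:
        d_lik = 0.0
        if gaussian:
            for i in range(n):
                r = Y[i, j] - beta[j] - phi[i, j]
                d_lik += (r * db - 0.5 * db * db) / tau2
        else:
            em1 = np.expm1(db)
            for i in range(n):
                d_lik += Y[i, j] * db - mu[i, j] * em1
        d_prior = -0.5 * prec * (2.0 * beta[j] * db + db * db)
        if logu_b < d_lik + d_prior:
            acc_b = 1
            beta[j] += db
            if not gaussian:
                e = np.exp(db)
                for i in range(n):
                    mu[i, j] *= e
    if do_sd:
        sd_new = sd[j] * np.exp(eps)
        if sd_new < sd_upper:
            d_lik = 0.0
            if gaussian:
                for i in range(n):
                    pn = v[i, j] * sd_new
                    r_old = Y[i, j] - beta[j] - phi[i, j]
                    r_new = Y[i, j] - beta[j] - pn
                    d_lik += -0.5 * (r_new * r_new - r_old * r_old) / tau2
            else:
                for i in range(n):
                    pn = v[i, j] * sd_new
                    mn = E[i, j] * np.exp(beta[j] + pn) if validf[i, j] else 0.0
                    d_lik += Y[i, j] * (pn - phi[i, j]) - (mn - mu[i, j])
            if logu_s < d_lik + eps:
                acc_s = 1
                sd[j] = sd_new
                for i in range(n):
                    phi[i, j] = v[i, j] * sd_new
                    if not gaussian and validf[i, j]:
                        mu[i, j] = E[i, j] * np.exp(beta[j] + phi[i, j])
    return acc_b, acc_s


@_njit(cache=True)
def _update_corr_pair(
    p, pa, pb, eps, logu, corr, L_R, u, v, phi, mu,
    Y, E, validf, beta, sd, gaussian, tau2,
):
    """Logit-scale RW update of one pairwise correlation; rejection enforces
    positive definiteness.  Mutates corr, L_R, v, phi, mu in place."""
    n, J = phi.shape
    c_old = corr[p]
    z = np.log(c_old / (1.0 - c_old)) + eps
    c_prop = 1.0 / (1.0 + np.exp(-z))
    if not (0.0 < c_prop < 1.0):
        return 0
    R = np.eye(J)
    for q in range(corr.shape[0]):
        a, b = pa[q], pb[q]
        val = c_prop if q == p else corr[q]
        R[a, b] = val
        R[b, a] = val
    L_new, ok = _chol_small(R)
    if not ok:
        return 0
    d_lik = 0.0
    for i in range(n):
        for j in range(J):
            pn = 0.0
            for l in range(J):
                pn += u[i, l] * L_new[j, l]
            pn *= sd[j]
            if gaussian:
                r_old = Y[i, j] - beta[j] - phi[i, j]
                r_new = Y[i, j] - beta[j] - pn
                d_lik += -0.5 * (r_new * r_new - r_old * r_old) / tau2
            else:
                mn = E[i, j] * np.exp(beta[j] + pn) if validf[i, j] else 0.0
                d_lik += Y[i, j] * (pn - phi[i, j]) - (mn - mu[i, j])
    djac = (np.log(c_prop * (1.0 - c_prop)) - np.log(c_old * (1.0 - c_old)))
    if logu < d_lik + djac:
        corr[p] = c_prop
        for a in range(J):
            for b in range(J):
                L_R[a, b] = L_new[a, b]
        for i in range(n):
            for j in range(J):
                pn = 0.0
                for l in range(J):
                    pn += u[i, l] * L_new[j, l]
                v[i, j] = pn
                phi[i, j] = pn * sd[j]
                if not gaussian and validf[i, j]:
                    mu[i, j] = E[i, j] * np.exp(beta[j] + phi[i, j])
        return 1
    return 0


@_njit(cache=True)
def _rho_log_accept(r_old, r_new, lam, dq_scale, n_fields):
    """Log acceptance ratio pieces for a spatial-parameter move shared by
    ``n_fields`` latent columns: n_fields/2 * [logdet Q(r_new) - logdet
    Q(r_old)] - (r_new - r_old)/2 * dq_scale + logit Jacobian."""
    dl = 0.0
    for m in range(lam.shape[0]):
        dl += np.log(r_new * lam[m] + 1.0 - r_new) - np.log(r_old * lam[m] + 1.0 - r_old)
    dl *= 0.5 * n_fields
    dl += -0.5 * (r_new - r_old) * dq_scale
    dl += np.log(r_new * (1.0 - r_new)) - np.log(r_old * (1.0 - r_old))
    return dl


def _chain_rng(seed: int, chain: int, tag: int) -> np.random.Generator:
    # tag layout: 1000+label -> per-disease sampling stream, 999 -> shared,
    # 2000+label -> per-disease init jitter, 1999 -> shared init jitter.
    # Keyed by (seed, chain, tag) only, so a univariate refit of one disease
    # replays the identical stream.
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(chain), int(tag)]))


def initial_states(
    spec: MCARModelSpec,
    Y: np.ndarray,
    E: np.ndarray,
    n_chains: int,
    seed: int,
    disease_labels: Optional[Sequence[int]] = None,
) -> list:
    """Chain 1 starts at a null state (crude intercepts, flat field); further
    chains are perturbed by seeded overdispersed jitter."""
    Y = np.asarray(Y, dtype=float)
    E = np.asarray(E, dtype=float)
    n, J = Y.shape
    labels = list(disease_labels) if disease_labels is not None else list(range(J))
    P = len(_pairs(J))
    states = []
    for c in range(n_chains):
        if spec.likelihood == "gaussian":
            beta = Y.mean(axis=0)
        else:
            beta = np.log(Y.sum(axis=0) / E.sum(axis=0))
        u = np.zeros((n, J))
        sd = np.full(J, 0.5)
        corr = np.full(P, 0.1) if spec.correlated else np.zeros(P)
        rho = np.array(0.5) if spec.shared_rho else np.full(J, 0.5)
        if c > 0:
            for j, lab in enumerate(labels):
                rng = _chain_rng(seed, c, 2000 + lab)
                beta[j] += 0.5 * rng.standard_normal()
                sd[j] *= np.exp(0.3 * rng.standard_normal())
                sd[j] = min(sd[j], 0.99 * spec.prior_sd_upper)
                rj = expit(logit(0.5) + rng.standard_normal())
                if spec.shared_rho:
                    if j == 0:
                        rho = np.array(rj)
                else:
                    rho[j] = rj
                u[:, j] = 0.1 * rng.standard_normal(n)
            if spec.correlated and P:
                rng = _chain_rng(seed, c, 1999)
                corr = expit(logit(corr) + 0.5 * rng.standard_normal(P))
        st = PosteriorState(beta, u, sd, corr, rho)
        if not st.is_valid(spec):  # e.g. jittered corr not PD: re-draw shrunk
            corr = np.full(P, 0.1) if spec.correlated else np.zeros(P)
            st = PosteriorState(beta, u, sd, corr, rho)
        states.append(st)
    return states


def _colour_classes(graph: AdjacencyGraph) -> list:
    g = nx.from_numpy_array(graph.W)
    colours = nx.greedy_color(g, strategy="largest_first")
    k = max(colours.values()) + 1 if colours else 1
    return [
        np.array(sorted(i for i, c in colours.items() if c == col), dtype=int)
        for col in range(k)
    ]


class _StepSize:
    """Robbins-Monro step-size adaptation, frozen after burn-in."""

    def __init__(self, init: float, target: float, batch: int):
        self.log_step = float(np.log(init))
        self.target = target
        self.batch = batch
        self.n_acc = 0.0
        self.n_try = 0.0
        self.n_batches = 0

    @property
    def step(self) -> float:
        return float(np.exp(self.log_step))

    def record(self, accepted: float, attempted: float, adapting: bool):
        self.n_acc += accepted
        self.n_try += attempted
        if adapting and self.n_try >= self.batch:
            self.n_batches += 1
            rate = self.n_acc / self.n_try
            delta = min(0.1, 1.0 / np.sqrt(self.n_batches))
            self.log_step += delta * (rate - self.target)
            self.n_acc = self.n_try = 0.0


def fit_mcmc(
    spec: MCARModelSpec,
    Y: np.ndarray,
    E: np.ndarray,
    graph: AdjacencyGraph,
    control: MCMCControl,
    disease_labels: Optional[Sequence[int]] = None,
) -> ChainOutput:
    """Fit the model by Metropolis-within-Gibbs and return retained draws.

    Updates, in turn: each latent field ``u[:, l]`` by vectorised single-site
    random-walk Metropolis over graph-colouring classes; the intercepts by
    random-walk Metropolis; the standard deviations, correlations and spatial
    parameter(s) by random-walk Metropolis on log/logit scales with the
    appropriate Jacobians.  Step sizes adapt during burn-in only (target
    acceptance 0.44) and are frozen afterwards.  Deterministic given
    ``control.seed``.
    """
    Y = np.asarray(Y, dtype=float)
    E = np.asarray(E, dtype=float)
    n, J = Y.shape
    if E.shape != Y.shape:
        raise ValueError("Y and E must have the same shape")
    if spec.likelihood == "poisson":
        if np.any((E == 0) & (Y > 0)):
            raise ValueError("cells with E = 0 but Y > 0: model undefined")
        if np.any(E < 0) or np.any(Y < 0):
            raise ValueError("negative Y or E")
    labels = list(disease_labels) if disease_labels is not None else list(range(J))
    if len(labels) != J:
        raise ValueError("disease_labels length must match number of diseases")
    if (graph.degrees() == 0).any():
        raise ValueError(
            "graph has degree-0 areas; link islands before fitting "
            "(a disconnected field cannot borrow strength)"
        )

    chunks = [
        _run_chain(spec, Y, E, graph, control, chain=c, labels=labels)
        for c in range(control.n_chains)
    ]
    out = ChainOutput.concatenate(chunks)
    out.meta["seed"] = control.seed
    out.meta["burn_in"] = control.burn_in
    out.meta["thin"] = control.thin
    out.meta["iterations"] = control.iterations
    out.meta["variant"] = spec.variant
    return out


def _run_chain(spec, Y, E, graph, control, chain, labels):
    n, J = Y.shape
    pairs = _pairs(J)
    P = len(pairs)
    pair_a = np.array([a for a, _ in pairs], dtype=np.int64)
    pair_b = np.array([b for _, b in pairs], dtype=np.int64)
    gaussian = spec.likelihood == "gaussian"
    tau2 = spec.gaussian_tau ** 2

    W = graph.W.astype(float)
    deg = W.sum(axis=1)
    lam = _structure_eigvals(graph)
    colours = _colour_classes(graph)

    rngs = {lab: _chain_rng(control.seed, chain, 1000 + lab) for lab in labels}
    rng_shared = _chain_rng(control.seed, chain, 999)

    state = initial_states(
        spec, Y, E, chain + 1, control.seed, disease_labels=labels
    )[chain]
    beta = state.beta.copy()
    u = state.u.copy()
    sd = state.sigma_sd.copy()
    corr = state.sigma_corr.copy()
    rho = state.rho_per_latent(J).copy()
    shared = spec.shared_rho

    L_R = np.linalg.cholesky(correlation_matrix(corr, J))
    v = u @ L_R.T                       # phi = v * sd
    phi = v * sd[None, :]
    valid = ~((E == 0) & (Y == 0)) if not gaussian else np.ones_like(Y, bool)
    mu = np.where(valid, E * np.exp(beta[None, :] + phi), 0.0)

    steps = {
        ("u", j): _StepSize(1.0, control.target_accept, control.adapt_batch * n)
        for j in range(J)
    }
    for j in range(J):
        steps[("beta", j)] = _StepSize(0.05, 0.44, control.adapt_batch)
        steps[("sd", j)] = _StepSize(0.3, 0.44, control.adapt_batch)
    for p in range(P):
        steps[("corr", p)] = _StepSize(0.3, 0.44, control.adapt_batch)
    if shared:
        steps[("rho", "shared")] = _StepSize(0.5, 0.44, control.adapt_batch)
    else:
        for j in range(J):
            steps[("rho", j)] = _StepSize(0.5, 0.44, control.adapt_batch)

    S = control.retained_per_chain
    out_beta = np.empty((S, J))
    out_u = np.empty((S, n, J))
    out_sd = np.empty((S, J))
    out_corr = np.empty((S, P))
    out_rho = np.empty(S) if shared else np.empty((S, J))
    out_phi = np.empty((S, n, J))
    out_mu = np.empty((S, n, J))
    out_dev = np.empty(S)
    gamY = gammaln(Y + 1)

    # cached CAR quadratic parts s1 = u'(D-W)u, s0 = u'u per latent column,
    # kept current by the site-update kernel
    s1 = np.array([u[:, c] @ (deg * u[:, c]) - u[:, c] @ (W @ u[:, c])
                   for c in range(J)])
    s0 = np.array([u[:, c] @ u[:, c] for c in range(J)])

    s_idx = 0
    for it in range(control.iterations):
        adapting = it < control.burn_in
        for j in range(J):
            rng = rngs[labels[j]]
            # --- latent field u[:, j], colour class by colour class
            if control.do("u"):
                ss = steps[("u", j)]
                step = ss.step
                acc_total = 0
                for idx in colours:
                    du = step * rng.standard_normal(len(idx))
                    logu = np.log(rng.uniform(size=len(idx)))
                    acc, ds1, ds0 = _update_field_sites(
                        idx, du, logu, u[:, j], v, phi, mu, Y, E, valid,
                        beta, np.ascontiguousarray(L_R[:, j]), sd, W, deg,
                        float(rho[j]), gaussian, tau2,
                    )
                    acc_total += acc
                    s1[j] += ds1
                    s0[j] += ds0
                ss.record(acc_total, n, adapting)
            # --- intercept beta[j] and marginal sd[j]
            do_beta = control.do("beta")
            do_sd = control.do("sd")
            if do_beta or do_sd:
                ss_b = steps[("beta", j)]
                ss_s = steps[("sd", j)]
                db = logu_b = eps = logu_s = 0.0
                if do_beta:
                    db = ss_b.step * rng.standard_normal()
                    logu_b = np.log(rng.uniform())
                if do_sd:
                    eps = ss_s.step * rng.standard_normal()
                    logu_s = np.log(rng.uniform())
                acc_b, acc_s = _update_beta_sd(
                    j, db, logu_b, eps, logu_s, beta, sd, spec.prior_sd_upper,
                    v, phi, mu, Y, E, valid, spec.intercept_prior_precision,
                    gaussian, tau2, do_beta, do_sd,
                )
                if do_beta:
                    ss_b.record(acc_b, 1, adapting)
                if do_sd:
                    ss_s.record(acc_s, 1, adapting)
            # --- disease-specific rho[j] (M1/M3)
            if not shared and control.do("rho"):
                ss = steps[("rho", j)]
                eps = ss.step * rng.standard_normal()
                lu = np.log(rng.uniform())
                r_new = float(expit(logit(rho[j]) + eps))
                if 0 < r_new < 1 and lu < _rho_log_accept(
                    rho[j], r_new, lam, s1[j] - s0[j], 1.0
                ):
                    rho[j] = r_new
                    ss.record(1, 1, adapting)
                else:
                    ss.record(0, 1, adapting)
        # --- pairwise correlations (M1/M2), shared stream
        if spec.correlated and control.do("corr"):
            for p in range(P):
                ss = steps[("corr", p)]
                eps = ss.step * rng_shared.standard_normal()
                lu = np.log(rng_shared.uniform())
                acc = _update_corr_pair(
                    p, pair_a, pair_b, eps, lu, corr, L_R, u, v, phi, mu,
                    Y, E, valid, beta, sd, gaussian, tau2,
                )
                ss.record(acc, 1, adapting)
        # --- shared rho (M2), shared stream
        if shared and control.do("rho"):
            ss = steps[("rho", "shared")]
            eps = ss.step * rng_shared.standard_normal()
            lu = np.log(rng_shared.uniform())
            r_new = float(expit(logit(rho[0]) + eps))
            if 0 < r_new < 1 and lu < _rho_log_accept(
                rho[0], r_new, lam, float((s1 - s0).sum()), float(J)
            ):
                rho[:] = r_new
                ss.record(1, 1, adapting)
            else:
                ss.record(0, 1, adapting)
        # --- retain
        if it >= control.burn_in and (it - control.burn_in) % control.thin == control.thin - 1:
            out_beta[s_idx] = beta
            out_u[s_idx] = u
            out_sd[s_idx] = sd
            out_corr[s_idx] = corr
            if shared:
                out_rho[s_idx] = rho[0]
            else:
                out_rho[s_idx] = rho
            out_phi[s_idx] = phi
            if gaussian:
                eta = beta[None, :] + phi
                out_mu[s_idx] = eta
                out_dev[s_idx] = float(
                    np.sum((Y - eta) ** 2 / tau2 + np.log(tau2) + _LOG2PI)
                )
            else:
                out_mu[s_idx] = mu
                ll = np.sum(
                    np.where(valid, Y * np.log(np.where(mu > 0, mu, 1.0)) - mu - gamY, 0.0)
                )
                out_dev[s_idx] = -2.0 * ll
            s_idx += 1

    accept_rates = {
        f"{k[0]}[{k[1]}]": (s.n_acc / s.n_try if s.n_try else np.nan)
        for k, s in steps.items()
    }
    meta = {
        "chain": chain,
        "seed": control.seed,
        "acceptance_rates": accept_rates,
        "step_sizes": {f"{k[0]}[{k[1]}]": s.step for k, s in steps.items()},
        "burn_in": control.burn_in,
        "thin": control.thin,
        "iterations": control.iterations,
    }
    return ChainOutput(
        out_beta, out_u, out_sd, out_corr, out_rho, out_phi, out_mu, out_dev,
        np.full(S, chain, dtype=int), meta=meta,
    )
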