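"""Infinite Gaussian mixture (Dirichlet-process) population model.

The per-cell log-parameters x_i = (ln u_gluc, ln d_gluc) are modelled as draws
from a Gaussian mixture with an unbounded number of components:

    x_i | c_i = j        ~  N(mu_j, S_j^-1)
    mu_j | lam, r        ~  N(lam, r^-1)
    S_j | beta, w        ~  Wishart(df = beta, scale = (beta w)^-1)
    c   | alpha          ~  Chinese restaurant process (concentration alpha)

with hyperpriors (all conventions Wishart(scale, df), mean = df * scale):

    lam       ~ N(mu_0, Sigma_0)
    r         ~ Wishart(Sigma_0^-1 / 2, 2)        (mean Sigma_0^-1)
    beta - 1  ~ Gamma(1, 1)                        (so df beta > 1 = dim - 1)
    w         ~ Wishart(Sigma_0 / 2, 2)            (mean Sigma_0)
    alpha     ~ Gamma(1, 1)

(mu_0, Sigma_0) are fixed at the mean and covariance of the per-cell maximum-
likelihood estimates.  All conditional updates are conjugate except beta and
alpha, which are updated by Metropolis steps on log(beta-1) and log(alpha)
against their exact conditionals.  Unrepresented components are handled with
the auxiliary-component method (Neal's algorithm 8): each assignment update
offers ``n_aux`` fresh draws from the component prior, carrying the
concentration mass alpha split evenly among them.

An alternative reading of the "beta - 1 ~ Gamma(1,1)" hyperprior — placing the
Gamma(1,1) on 1/beta restricted to beta > 1 — is available via
``beta_prior="inverse_gamma"``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "Component",
    "IGMMState",
    "make_initial_state",
    "log_mixture_density",
    "draw_prior_component",
    "igmm_gibbs_update",
    "crp_occupied_counts",
]

logger = logging.getLogger(__name__)

_LOG_2PI = math.log(2.0 * math.pi)
_DIM = 2


class Component:
    """One mixture component in (ln u, ln d) space: mean and precision,
    with the precision's log-determinant cached for fast density evaluation."""

    __slots__ = ("m0", "m1", "pa", "pb", "pc", "ld")

    def __init__(self, mean, prec):
        self.m0 = float(mean[0])
        self.m1 = float(mean[1])
        a = float(prec[0][0] if not isinstance(prec, np.ndarray) else prec[0, 0])
        b = float(prec[0][1] if not isinstance(prec, np.ndarray) else prec[0, 1])
        c = float(prec[1][1] if not isinstance(prec, np.ndarray) else prec[1, 1])
        det = a * c - b * b
        if not (a > 0 and det > 0):
            raise ValueError("precision matrix must be positive definite")
        self.pa, self.pb, self.pc = a, b, c
        self.ld = math.log(det)

    @classmethod
    def from_prec_chol(cls, mean, b11: float, b21: float, b22: float) -> "Component":
        """Build from the lower Cholesky factor of the precision.

        Positive-definiteness and the log-determinant are exact in this form
        (det = (b11*b22)^2), which matters for heavy-tailed Wishart draws
        whose assembled matrix is numerically rank-deficient.
        """
        if not (b11 > 0 and b22 > 0):
            raise ValueError("degenerate precision factor")
        self = cls.__new__(cls)
        self.m0 = float(mean[0])
        self.m1 = float(mean[1])
        self.pa = b11 * b11
        self.pb = b11 * b21
        self.pc = b21 * b21 + b22 * b22
        self.ld = 2.0 * (math.log(b11) + math.log(b22))
        return self

    @property
    def mean(self) -> np.ndarray:
        return np.array([self.m0, self.m1])

    @property
    def prec(self) -> np.ndarray:
        return np.array([[self.pa, self.pb], [self.pb, self.pc]])

    def logpdf(self, x) -> float:
        dx0 = float(x[0]) - self.m0
        dx1 = float(x[1]) - self.m1
        q = self.pa * dx0 * dx0 + 2.0 * self.pb * dx0 * dx1 + self.pc * dx1 * dx1
        return -_LOG_2PI + 0.5 * self.ld - 0.5 * q


@dataclass
class IGMMState:
    """Mutable state of the population model during Gibbs sampling."""

    assignments: np.ndarray          # (n,) component index per cell
    components: list[Component]
    alpha: float
    lam: np.ndarray                  # (2,) prior mean of component means
    r: np.ndarray                    # (2,2) prior precision of component means
    beta: float                      # Wishart df for component precisions
    w: np.ndarray                    # (2,2) inverse-scale for component precisions
    hyper_mean: np.ndarray           # fixed mu_0 from MLE
    hyper_cov: np.ndarray            # fixed Sigma_0 from MLE

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def comp_means(self) -> list[np.ndarray]:
        return [c.mean for c in self.components]

    @property
    def comp_precisions(self) -> list[np.ndarray]:
        return [c.prec for c in self.components]

    def counts(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=len(self.components))

    def validate(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0")
        if not self.beta > _DIM - 1:
            raise ValueError("beta must exceed dim - 1")
        c = self.counts()
        if len(c) != len(self.components) or np.any(c == 0):
            raise ValueError("every occupied component must have >= 1 cell")


def make_initial_state(
    log_params: np.ndarray, hyper_mean: np.ndarray, hyper_cov: np.ndarray
) -> IGMMState:
    """One component per cell, centred on that cell's log-parameters.

    Starting fully split makes burn-in reliable: merging redundant
    components is an easy (downhill) move for incremental Gibbs sampling,
    whereas splitting an under-fitted component requires a rare sequence of
    individually unfavourable reassignments.
    """
    x = np.asarray(log_params, float).reshape(-1, 2)
    prec = np.linalg.inv(hyper_cov)
    return IGMMState(
        assignments=np.arange(x.shape[0], dtype=np.int64),
        components=[Component(xi, prec) for xi in x],
        alpha=1.0,
        lam=np.array(hyper_mean, float),
        r=prec.copy(),
        beta=float(_DIM),
        w=np.array(hyper_cov, float),
        hyper_mean=np.array(hyper_mean, float),
        hyper_cov=np.array(hyper_cov, float),
    )


# ---------------------------------------------------------------------------
# small 2x2 linear algebra and samplers (hot path: plain floats)

def _chol2(a, b, c):
    l11 = math.sqrt(a)
    l21 = b / l11
    t = c - l21 * l21
    if t <= 0:
        raise np.linalg.LinAlgError("2x2 matrix not positive definite")
    return l11, l21, math.sqrt(t)


def _wishart_chol_rvs(df: float, scale: np.ndarray, rng: np.random.Generator):
    """Bartlett sampler, p=2: returns the lower Cholesky factor (b11, b21,
    b22) of W = (L A)(L A)^T with chol(scale) = L."""
    l11, l21, l22 = _chol2(scale[0, 0], scale[0, 1], scale[1, 1])
    a11 = math.sqrt(rng.chisquare(df))
    a22 = math.sqrt(rng.chisquare(df - 1.0))
    a21 = rng.standard_normal()
    return l11 * a11, l21 * a11 + l22 * a21, l22 * a22


def _wishart_rvs(df: float, scale: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    b11, b21, b22 = _wishart_chol_rvs(df, scale, rng)
    return np.array([[b11 * b11, b11 * b21], [b11 * b21, b21 * b21 + b22 * b22]])


def _mvn_rvs_prec(mean, prec: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """N(mean, prec^-1) draw via the precision's Cholesky factor."""
    l11, l21, l22 = _chol2(prec[0, 0], prec[0, 1], prec[1, 1])
    z0, z1 = rng.standard_normal(2)
    # solve L^T x = z  =>  x ~ N(0, prec^-1)
    x1 = z1 / l22
    x0 = (z0 - l21 * x1) / l11
    return np.array([mean[0] + x0, mean[1] + x1])


def draw_prior_component(state: IGMMState, rng: np.random.Generator) -> Component:
    """Fresh component from its prior: S ~ Wishart(beta, (beta w)^-1),
    mu ~ N(lam, r^-1).  Jitters the inverse-scale if numerically singular."""
    scale = np.linalg.inv(state.beta * state.w)
    for attempt in range(4):
        try:
            b11, b21, b22 = _wishart_chol_rvs(state.beta, scale, rng)
            mu = _mvn_rvs_prec(state.lam, state.r, rng)
            return Component.from_prec_chol(mu, b11, b21, b22)
        except (np.linalg.LinAlgError, ValueError):
            # underflowing chi-square draws can occur when beta approaches
            # its lower bound; jitter relative to the scale and retry
            logger.warning(
                "prior component draw lost positive-definiteness; jittering"
            )
            scale = scale + (1e-9 * np.trace(scale)) * np.eye(2) * (10.0 ** attempt)
    raise np.linalg.LinAlgError("could not draw a positive-definite component")


# ---------------------------------------------------------------------------
# mixture density and assignment machinery

def _aux_components(
    state: IGMMState, singleton: Component | None, n_aux: int, rng
) -> list[Component]:
    """Auxiliary components for one assignment update; a detached singleton's
    own component fills the first slot (algorithm-8 bookkeeping)."""
    aux = [] if singleton is None else [singleton]
    while len(aux) < n_aux:
        aux.append(draw_prior_component(state, rng))
    return aux


def _detach(state: IGMMState, i: int, counts: np.ndarray):
    """Remove cell i from its component; returns (counts, singleton_comp)."""
    j = int(state.assignments[i])
    counts[j] -= 1
    singleton = None
    if counts[j] == 0:
        singleton = state.components.pop(j)
        counts = np.delete(counts, j)
        state.assignments[state.assignments > j] -= 1
    state.assignments[i] = -1
    return counts, singleton


def _attach(state: IGMMState, i: int, choice: int, counts: np.ndarray,
            aux: list[Component]):
    K = len(state.components)
    if choice < K:
        state.assignments[i] = choice
        counts[choice] += 1
        return counts
    state.components.append(aux[choice - K])
    state.assignments[i] = K
    return np.append(counts, 1)


def _assignment_logweights(
    state: IGMMState, counts: np.ndarray, aux: list[Component], x,
    n_aux: int, prior_only: bool = False,
) -> np.ndarray:
    logw = np.empty(len(counts) + len(aux))
    la = math.log(state.alpha / n_aux)
    for k, c in enumerate(state.components):
        dens = 0.0 if prior_only else c.logpdf(x)
        logw[k] = math.log(counts[k]) + dens
    for m, c in enumerate(aux):
        dens = 0.0 if prior_only else c.logpdf(x)
        logw[len(counts) + m] = la + dens
    return logw


def log_mixture_density(
    state: IGMMState, x, exclude: int | None = None,
    aux: list[Component] | None = None,
) -> float:
    """Log population-prior density of x under the current mixture.

    With ``exclude``/``aux`` given, this is the conditional-prior (CRP
    predictive) density for that cell: occupied components weighted by their
    membership counts excluding the cell, plus mass alpha spread over the
    auxiliary components.  Without them it is the plain count-weighted
    mixture over occupied components.
    """
    counts = state.counts().astype(float)
    if exclude is not None:
        counts[state.assignments[exclude]] -= 1
    terms = []
    for k, c in enumerate(state.components):
        if counts[k] > 0:
            terms.append(math.log(counts[k]) + c.logpdf(x))
    total = counts.sum()
    if aux:
        la = math.log(state.alpha / len(aux))
        terms.extend(la + c.logpdf(x) for c in aux)
        total += state.alpha
    return float(logsumexp(terms) - math.log(total))


def _resample_assignment(
    state: IGMMState, i: int, x, counts: np.ndarray, rng,
    n_aux: int, prior_only: bool = False,
) -> np.ndarray:
    counts, singleton = _detach(state, i, counts)
    aux = _aux_components(state, singleton, n_aux, rng)
    logw = _assignment_logweights(state, counts, aux, x, n_aux, prior_only)
    choice = int(np.argmax(logw + rng.gumbel(size=logw.size)))
    return _attach(state, i, choice, counts, aux)


# ---------------------------------------------------------------------------
# conjugate component and hyperparameter updates

def _update_components(state: IGMMState, X: np.ndarray, rng) -> None:
    counts = state.counts()
    for j, comp in enumerate(state.components):
        members = X[state.assignments == j]
        nj = counts[j]
        S = comp.prec
        # mean | precision, members, lam, r
        post_prec = state.r + nj * S
        rhs = state.r @ state.lam + nj * (S @ members.mean(axis=0))
        post_mean = np.linalg.solve(post_prec, rhs)
        mu = _mvn_rvs_prec(post_mean, post_prec, rng)
        # precision | mean, members, beta, w
        dx = members - mu
        scatter = dx.T @ dx
        scale = np.linalg.inv(state.beta * state.w + scatter)
        for attempt in range(3):
            try:
                b11, b21, b22 = _wishart_chol_rvs(state.beta + nj, scale, rng)
                state.components[j] = Component.from_prec_chol(mu, b11, b21, b22)
                break
            except (np.linalg.LinAlgError, ValueError):
                logger.warning("component precision update lost positive-"
                               "definiteness; jittering")
                scale = scale + (1e-9 * np.trace(scale)) * np.eye(2) * (10.0 ** attempt)
        else:
            raise np.linalg.LinAlgError("component update failed")


def _log_beta_conditional(beta: float, comps: list[Component], w: np.ndarray,
                          prior: str) -> float:
    if beta <= 1.0:
        return -np.inf
    if prior == "shifted_gamma":        # beta - 1 ~ Gamma(1, 1)
        lp = -(beta - 1.0)
    elif prior == "inverse_gamma":      # 1/beta ~ Gamma(1, 1), beta > 1
        lp = -2.0 * math.log(beta) - 1.0 / beta
    else:
        raise ValueError(f"unknown beta prior {prior!r}")
    ld_w = math.log(w[0, 0] * w[1, 1] - w[0, 1] ** 2)
    for c in comps:
        tr_wS = w[0, 0] * c.pa + 2.0 * w[0, 1] * c.pb + w[1, 1] * c.pc
        lp += 0.5 * ((beta - 3.0) * c.ld - beta * tr_wS
                     + beta * (2.0 * math.log(beta) + ld_w) - 2.0 * beta * math.log(2.0))
        lp -= 0.5 * math.log(math.pi) + gammaln(beta / 2.0) + gammaln((beta - 1.0) / 2.0)
    return lp


def _log_alpha_conditional(alpha: float, K: int, n: int) -> float:
    # Gamma(1,1) prior x CRP partition likelihood alpha^K Gamma(alpha)/Gamma(n+alpha)
    return -alpha + K * math.log(alpha) + gammaln(alpha) - gammaln(n + alpha)


def _update_hyperparameters(
    state: IGMMState, rng, beta_prior: str = "shifted_gamma",
) -> None:
    comps = state.components
    K = len(comps)
    n = state.assignments.size
    sigma0_inv = np.linalg.inv(state.hyper_cov)

    # lam | r, component means
    post_prec = sigma0_inv + K * state.r
    rhs = sigma0_inv @ state.hyper_mean + state.r @ np.sum(state.comp_means, axis=0)
    state.lam = _mvn_rvs_prec(np.linalg.solve(post_prec, rhs), post_prec, rng)

    # r | lam, component means
    dmu = np.asarray(state.comp_means) - state.lam
    state.r = _wishart_rvs(2.0 + K, np.linalg.inv(2.0 * state.hyper_cov + dmu.T @ dmu), rng)

    # w | beta, component precisions
    S_sum = np.sum(state.comp_precisions, axis=0)
    state.w = _wishart_rvs(
        2.0 + K * state.beta,
        np.linalg.inv(2.0 * sigma0_inv + state.beta * S_sum), rng,
    )

    # beta: Metropolis on log(beta - 1)
    theta = math.log(state.beta - 1.0)
    theta_new = theta + 0.5 * rng.standard_normal()
    beta_new = 1.0 + math.exp(theta_new)
    delta = (_log_beta_conditional(beta_new, comps, state.w, beta_prior)
             - _log_beta_conditional(state.beta, comps, state.w, beta_prior)
             + theta_new - theta)
    if math.log(rng.uniform()) < delta:
        state.beta = beta_new

    # alpha: Metropolis on log(alpha)
    la = math.log(state.alpha)
    la_new = la + 0.7 * rng.standard_normal()
    alpha_new = math.exp(la_new)
    delta = (_log_alpha_conditional(alpha_new, K, n)
             - _log_alpha_conditional(state.alpha, K, n) + la_new - la)
    if math.log(rng.uniform()) < delta:
        state.alpha = alpha_new


def igmm_gibbs_update(
    params_all: np.ndarray,
    state: IGMMState,
    rng: np.random.Generator,
    n_aux: int = 3,
    beta_prior: str = "shifted_gamma",
) -> IGMMState:
    """One full sweep of the population model given per-cell log-parameters:
    assignments (algorithm 8), component means/precisions, then the
    hyperparameters lam, r, w, beta and alpha."""
    X = np.asarray(params_all, float).reshape(-1, 2)
    if X.shape[0] != state.assignments.size:
        raise ValueError("params_all and assignments disagree on cell count")
    counts = state.counts()
    for i in range(X.shape[0]):
        counts = _resample_assignment(state, i, X[i], counts, rng, n_aux)
    _update_components(state, X, rng)
    _update_hyperparameters(state, rng, beta_prior=beta_prior)
    return state


def crp_occupied_counts(
    n: int, alpha: float, n_sweeps: int, rng: np.random.Generator, n_aux: int = 3
) -> np.ndarray:
    """Occupied-component count per sweep when the data coupling is disabled.

    With the component densities removed from the assignment conditionals the
    sweep is a Gibbs sampler on the bare Chinese restaurant process with fixed
    concentration alpha, so the stationary mean of the occupied count is the
    harmonic-number expectation sum_{i=1..n} alpha/(alpha+i-1).
    """
    state = make_initial_state(np.zeros((n, 2)), np.zeros(2), np.eye(2))
    state.alpha = float(alpha)
    X = np.zeros((n, 2))
    out = np.empty(n_sweeps, dtype=np.int64)
    counts = state.counts()
    for s in range(n_sweeps):
        for i in range(n):
            counts = _resample_assignment(state, i, X[i], counts, rng, n_aux,
                                          prior_only=True)
        out[s] = len(state.components)
    return out
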