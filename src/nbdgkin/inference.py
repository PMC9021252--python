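"""Hierarchical Bayesian inference of per-cell uptake/degradation rates.

The sampler alternates two blocks, Metropolis-within-Gibbs style:

  (a) for each cell i, a single Gaussian random-walk Metropolis-Hastings step
      on x_i = (ln u_gluc,i, ln d_gluc,i), targeting
      likelihood(y_i | x_i) x mixture-prior(x_i | population state),
      where the prior is the conditional (CRP-predictive) mixture density —
      occupied components weighted by membership counts excluding cell i plus
      concentration mass on auxiliary prior draws — followed by a Gibbs
      refresh of the cell's component assignment at the accepted value;

  (b) one sweep of the population model (assignments, component moments,
      hyperparameters; see ``igmm``).

Per-cell chains start at maximum-likelihood estimates and the fixed hyper-
moments (mu_0, Sigma_0) are the mean and covariance of those estimates.  The
proposal is a per-cell diagonal random-walk whose log-step is adapted toward
a target acceptance rate during burn-in and frozen afterwards, preserving
detailed balance for the retained draws.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import igmm
from .fitting import (
    NonIdentifiableError,
    gaussian_loglik,
    init_hyperpriors,
    loglik_trace,
    mle_fit,
)
from .igmm import IGMMState, igmm_gibbs_update, make_initial_state
from .model import (
    CellTrace,
    CompiledGrid,
    ExternalProfile,
    KineticParams,
    cell_volume,
    compile_grid,
)

__all__ = ["InferenceConfig", "PosteriorDraws", "mh_update_cell", "run_inference"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InferenceConfig:
    """Sampler settings.  The study itself fixes none of these; defaults are
    the package's own choices (5000 sweeps, 2000 burn-in, adaptive proposal
    tuned toward ~30% acceptance)."""

    n_iterations: int = 5000
    n_burnin: int = 2000
    mh_step: float = 0.08           # initial random-walk SD in log space
    adapt: bool = True
    target_accept: float = 0.3
    n_aux: int = 3
    cv_error: float = 0.05
    sigma_floor: float = 0.3
    seed: int = 0
    mle_max_iter: int = 15
    beta_prior: str = "shifted_gamma"

    def __post_init__(self) -> None:
        if not (0 <= self.n_burnin < self.n_iterations):
            raise ValueError("need 0 <= n_burnin < n_iterations")
        if not self.mh_step > 0:
            raise ValueError("mh_step must be > 0")
        if self.n_aux < 1:
            raise ValueError("n_aux must be >= 1")


@dataclass
class PosteriorDraws:
    """Post-burn-in draws: per-cell (ln u, ln d) samples plus population
    summaries per retained sweep."""

    cell_ids: list[str]
    samples: np.ndarray          # (n_kept, n_cells, 2)
    n_components: np.ndarray     # (n_kept,)
    alpha: np.ndarray            # (n_kept,)
    accept_rate: np.ndarray      # (n_cells,) post-burn-in MH acceptance
    mle_init: np.ndarray         # (n_cells, 2) (ln u, ln d) starting points
    seed: int
    failed_cells: list[str] = field(default_factory=list)

    def medians(self) -> np.ndarray:
        """Per-cell posterior medians of (ln u, ln d)."""
        return np.median(self.samples, axis=0)

    def quantiles(self, q) -> np.ndarray:
        return np.quantile(self.samples, q, axis=0)

    def credible_intervals(self, level: float = 0.9) -> np.ndarray:
        """(2, n_cells, 2) equal-tailed intervals at the given level."""
        half = (1.0 - level) / 2.0
        return self.quantiles([half, 1.0 - half])

    def summary_frame(self):
        """Columnar per-cell summary: medians and 5/95% quantiles."""
        import pandas as pd

        med = self.medians()
        lo, hi = self.quantiles([0.05, 0.95])
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "log_u_median": med[:, 0],
                "log_u_q05": lo[:, 0],
                "log_u_q95": hi[:, 0],
                "log_d_median": med[:, 1],
                "log_d_q05": lo[:, 1],
                "log_d_q95": hi[:, 1],
                "accept_rate": self.accept_rate,
            }
        )


def _mh_step_core(
    x: np.ndarray,
    loglik_x: float,
    loglik_fn,
    i: int,
    state: IGMMState,
    step: np.ndarray,
    n_aux: int,
    rng: np.random.Generator,
):
    """One MH update of cell i plus an assignment refresh.

    Returns (x_new, loglik_new, accepted, counts).  ``loglik_fn`` maps the
    log-parameter pair to the data log-likelihood; the cached value for the
    current point avoids recomputing the forward model.
    """
    counts = state.counts()
    counts, singleton = igmm._detach(state, i, counts)
    aux = igmm._aux_components(state, singleton, n_aux, rng)

    def prior_ld(xq):
        logw = igmm._assignment_logweights(state, counts, aux, xq, n_aux)
        return float(np.logaddexp.reduce(logw)) - math.log(counts.sum() + state.alpha)

    x_prop = x + step * rng.standard_normal(2)
    ll_prop = loglik_fn(x_prop)
    lp_old = loglik_x + prior_ld(x)
    lp_new = ll_prop + prior_ld(x_prop)
    accept = math.log(rng.uniform()) < lp_new - lp_old if lp_new > -np.inf else False
    if accept:
        x, loglik_x = x_prop, ll_prop
    # Gibbs refresh of the assignment at the (possibly unchanged) value
    logw = igmm._assignment_logweights(state, counts, aux, x, n_aux)
    choice = int(np.argmax(logw + rng.gumbel(size=logw.size)))
    counts = igmm._attach(state, i, choice, counts, aux)
    return x, loglik_x, accept, counts


def mh_update_cell(
    cell_state,
    trace: CellTrace | None,
    profile: ExternalProfile | None,
    igmm_state: IGMMState,
    config: InferenceConfig,
    rng: np.random.Generator,
    cell_index: int = 0,
):
    """Single Metropolis-Hastings update of one cell's (ln u, ln d).

    ``cell_state`` is the current log-parameter pair.  ``trace=None`` drops
    the likelihood (flat-likelihood mode, useful for checking that the chain
    then samples the population prior).  Exactly one accept/reject decision
    is made per call.  Returns (x_new, accepted).
    """
    x = np.asarray(cell_state, float)
    if trace is None:
        loglik_fn = lambda xq: 0.0
        ll_x = 0.0
    else:
        grid = compile_grid(profile, trace.times)
        V_c = cell_volume(trace.geometry)

        def loglik_fn(xq):
            mean = grid.propagate(math.exp(xq[0]) / V_c, math.exp(xq[1]))
            return gaussian_loglik(trace.values, mean, config.cv_error,
                                   config.sigma_floor)

        ll_x = loglik_fn(x)
    step = np.broadcast_to(np.asarray(config.mh_step, float), (2,)).copy()
    x_new, _, accepted, _ = _mh_step_core(
        x, ll_x, loglik_fn, cell_index, igmm_state, step, config.n_aux, rng
    )
    return x_new, accepted


def run_inference(
    traces: list[CellTrace],
    profile: ExternalProfile,
    config: InferenceConfig = InferenceConfig(),
) -> PosteriorDraws:
    """Full two-step Gibbs run over a set of traces.

    Cells whose MLE initialization fails are excluded with a logged warning
    (and listed in ``failed_cells``); at least two identifiable cells are
    required.  Fully reproducible for a fixed config (including seed).
    """
    if len(traces) < 2:
        raise ValueError("need at least 2 traces")
    rng = np.random.default_rng(config.seed)

    kept: list[CellTrace] = []
    failed: list[str] = []
    x0 = []
    for tr in traces:
        try:
            p = mle_fit(tr, profile, max_iter=config.mle_max_iter)
            x0.append(p.log)
            kept.append(tr)
        except (NonIdentifiableError, ValueError) as exc:
            logger.warning("cell %s excluded from inference: %s", tr.cell_id, exc)
            failed.append(tr.cell_id)
    if len(kept) < 2:
        raise NonIdentifiableError("fewer than 2 cells passed MLE initialization")
    X = np.asarray(x0)
    n = X.shape[0]

    mu0, sigma0 = init_hyperpriors(X)
    state = make_initial_state(X, mu0, sigma0)

    # per-cell compiled grids and cached likelihoods
    grid_cache: dict[bytes, CompiledGrid] = {}
    grids = []
    for tr in kept:
        key = tr.times.tobytes()
        if key not in grid_cache:
            grid_cache[key] = compile_grid(profile, tr.times)
        grids.append(grid_cache[key])
    vols = np.array([cell_volume(tr.geometry) for tr in kept])

    def make_loglik(idx):
        grid, V_c, y = grids[idx], vols[idx], kept[idx].values

        def fn(xq):
            mean = grid.propagate(math.exp(xq[0]) / V_c, math.exp(xq[1]))
            return gaussian_loglik(y, mean, config.cv_error, config.sigma_floor)

        return fn

    logliks = [make_loglik(i) for i in range(n)]
    ll = np.array([logliks[i](X[i]) for i in range(n)])

    steps = np.full((n, 2), config.mh_step)
    n_kept_iter = config.n_iterations - config.n_burnin
    samples = np.empty((n_kept_iter, n, 2))
    k_occ = np.empty(n_kept_iter, dtype=np.int64)
    alphas = np.empty(n_kept_iter)
    accepts = np.zeros(n)

    for it in range(config.n_iterations):
        in_burnin = it < config.n_burnin
        for i in range(n):
            X[i], ll[i], acc, _ = _mh_step_core(
                X[i], ll[i], logliks[i], i, state, steps[i], config.n_aux, rng
            )
            if in_burnin and config.adapt:
                gamma = 2.0 / math.sqrt(it + 2.0)
                steps[i] *= math.exp(gamma * ((1.0 if acc else 0.0)
                                              - config.target_accept))
            elif not in_burnin and acc:
                accepts[i] += 1
        igmm_gibbs_update(X, state, rng, n_aux=config.n_aux,
                          beta_prior=config.beta_prior)
        if not in_burnin:
            j = it - config.n_burnin
            samples[j] = X
            k_occ[j] = state.n_components
            alphas[j] = state.alpha

    return PosteriorDraws(
        cell_ids=[tr.cell_id for tr in kept],
        samples=samples,
        n_components=k_occ,
        alpha=alphas,
        accept_rate=accepts / max(n_kept_iter, 1),
        mle_init=np.asarray(x0),
        seed=config.seed,
        failed_cells=failed,
    )
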