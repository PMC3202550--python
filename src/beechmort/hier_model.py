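"""Hierarchical Bayesian individual-tree mortality model.

The model links each tree's annual mortality rate m_ij (tree i in plot j)
to covariates through a logit link,

    logit(m_ij) = beta0 + beta_D * D* + beta_X * X* + beta_DX * D* X* + alpha_j,

where D* is standardized diameter, X* a standardized crowding index (BA or
BAL), alpha_j ~ Normal(0, sigma_alpha^2) a plot random effect absorbing the
non-independence of trees within a plot, and standardization subtracts the
sample mean and divides by twice the sample SD so coefficients are
comparable across covariates (standardized covariates have SD 0.5).

Survival over an interval of t years assumes a constant annual rate:
S_ij(t) = (1 - m_ij)^t, which lets periods of unequal length (9, 10, 11
years) share one annual-rate scale.  With death indicators d_ij, the
log-likelihood is

    sum_j sum_i [(1 - d_ij) log S_ij + d_ij log(1 - S_ij)].

Priors are weakly informative: Normal(0, 100) on fixed effects and
Uniform(0, 10) on sigma_alpha (logit-scale effects beyond +-10 are
saturated).  Posterior sampling uses an adaptive random-walk
Metropolis-within-Gibbs scheme: a joint adaptive Metropolis block for the
fixed effects, vectorized per-plot Metropolis updates for the alpha_j, and
an exact Gibbs draw of sigma_alpha^2 from its truncated inverse-gamma
conditional.  Adaptation runs during burn-in only, so retained draws come
from a fixed-kernel chain.  Convergence is checked with the potential
scale reduction factor (R-hat) over three dispersed chains; model fit is
summarized by the DIC with the posterior-mean plug-in (including the
random effects) for Dhat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .census import (
    SIZE_CLASS_THRESHOLD_MM,
    STATUS_ABSENT,
    STATUS_DEAD,
    CensusPeriod,
    TreeRecord,
)
from .crowding import compute_crowding

__all__ = [
    "MortalityModelSpec",
    "StandardizedVariable",
    "StandardizedDesign",
    "ModelData",
    "MCMCSettings",
    "DICResult",
    "PosteriorResult",
    "standardize",
    "build_design",
    "linear_predictor",
    "survival_probability",
    "log_likelihood",
    "fit_mcmc",
    "compute_dic",
]

#: Likelihood clipping floor keeping log S and log(1 - S) finite.
LIK_EPS = 1e-12


# ---------------------------------------------------------------------------
# Model specification and design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MortalityModelSpec:
    """Which mortality model to fit: size class, period, crowding index.

    BA and BAL are never included together (their collinearity fails the
    VIF < 3 screen); the interaction requires both main effects.
    """

    size_class: str  # "small" | "large"
    period: CensusPeriod
    crowding_variable: str  # "BA" | "BAL"
    include_interaction: bool = False

    def __post_init__(self) -> None:
        if self.size_class not in ("small", "large"):
            raise ValueError("size_class must be 'small' or 'large'")
        if self.crowding_variable not in ("BA", "BAL"):
            raise ValueError("crowding_variable must be 'BA' or 'BAL'")

    @property
    def covariate_names(self) -> tuple[str, ...]:
        names = ("D", self.crowding_variable)
        if self.include_interaction:
            names = names + (f"D:{self.crowding_variable}",)
        return names


@dataclass(frozen=True)
class StandardizedVariable:
    """One covariate standardized to mean 0, SD 0.5."""

    name: str
    mean: float
    sd: float
    values: np.ndarray

    def transform(self, raw: float | np.ndarray) -> float | np.ndarray:
        return (raw - self.mean) / (2.0 * self.sd)

    def back_transform(self, standardized: float | np.ndarray) -> float | np.ndarray:
        return self.mean + 2.0 * self.sd * standardized


def standardize(values: Sequence[float] | np.ndarray, name: str = "x") -> StandardizedVariable:
    """Centre by the sample mean and divide by twice the sample SD (ddof=1)."""
    raw = np.asarray(values, dtype=float)
    if raw.size < 2 or np.ptp(raw) == 0:
        raise ValueError(f"covariate {name!r}: need >= 2 distinct values to standardize")
    mean = float(raw.mean())
    sd = float(raw.std(ddof=1))
    return StandardizedVariable(name=name, mean=mean, sd=sd, values=(raw - mean) / (2.0 * sd))


@dataclass(frozen=True)
class StandardizedDesign:
    """Standardized design matrix plus the transforms and raw samples.

    ``matrix`` has one column per covariate in ``names`` (no intercept);
    interaction columns are products of the standardized main effects and
    carry no transform of their own.  Raw main-effect samples are kept for
    quantile conditioning and grid construction in prediction.
    """

    names: tuple[str, ...]
    variables: dict[str, StandardizedVariable]
    matrix: np.ndarray
    raw: dict[str, np.ndarray]


@dataclass(frozen=True)
class ModelData:
    """Fitting sample for one model: outcomes, design, plot structure."""

    y: np.ndarray  # death indicators d_ij, 0/1
    t_years: float
    design: StandardizedDesign
    plot_index: np.ndarray  # 0..K-1 per tree
    plot_ids: tuple[str, ...]
    tree_ids: tuple[str, ...]
    spec: MortalityModelSpec

    @property
    def n_trees(self) -> int:
        return int(self.y.size)

    @property
    def n_plots(self) -> int:
        return len(self.plot_ids)

    @property
    def x_with_intercept(self) -> np.ndarray:
        return np.column_stack([np.ones(self.n_trees), self.design.matrix])


def build_design(
    records: Sequence[TreeRecord],
    spec: MortalityModelSpec,
    threshold_mm: float = SIZE_CLASS_THRESHOLD_MM,
) -> ModelData:
    """Assemble the fitting sample for a model spec.

    The sample holds focal-eligible trees (central four subplots) alive at
    the period's start census, in the requested size class at that census,
    and with a known fate (alive or dead, not absent) at the end census.
    Crowding indices use start-of-period diameters over the full 3 x 3
    window.  Covariates are standardized over this sample.
    """
    start = spec.period.start_census
    end = spec.period.end_census
    crowd = {c.tree_id: c for c in compute_crowding(records, start)}
    rows: list[tuple[TreeRecord, float, float, int]] = []
    for rec in records:
        c = crowd.get(rec.tree_id)
        if c is None:  # not focal-eligible or not alive at start
            continue
        d = rec.diameter_at(start)
        in_class = d < threshold_mm if spec.size_class == "small" else d >= threshold_mm
        if not in_class:
            continue
        status_end = rec.status_at(end)
        if status_end == STATUS_ABSENT:
            continue
        x = c.bal if spec.crowding_variable == "BAL" else c.ba
        rows.append((rec, d, x, int(status_end == STATUS_DEAD)))
    if not rows:
        raise ValueError("empty fitting sample for this spec")

    d_var = standardize([r[1] for r in rows], "D")
    x_var = standardize([r[2] for r in rows], spec.crowding_variable)
    columns = [d_var.values, x_var.values]
    if spec.include_interaction:
        columns.append(d_var.values * x_var.values)
    design = StandardizedDesign(
        names=spec.covariate_names,
        variables={"D": d_var, spec.crowding_variable: x_var},
        matrix=np.column_stack(columns),
        raw={
            "D": np.array([r[1] for r in rows]),
            spec.crowding_variable: np.array([r[2] for r in rows]),
        },
    )
    plot_ids = tuple(sorted({r[0].plot_id for r in rows}))
    plot_pos = {p: i for i, p in enumerate(plot_ids)}
    return ModelData(
        y=np.array([r[3] for r in rows], dtype=np.int8),
        t_years=float(spec.period.t_years),
        design=design,
        plot_index=np.array([plot_pos[r[0].plot_id] for r in rows]),
        plot_ids=plot_ids,
        tree_ids=tuple(r[0].tree_id for r in rows),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


def linear_predictor(
    beta: Sequence[float] | np.ndarray,
    x: np.ndarray,
    alpha_per_tree: float | np.ndarray = 0.0,
) -> np.ndarray:
    """k_ij = beta0 + sum_c beta_c x*_c + alpha_j (beta includes intercept)."""
    beta = np.asarray(beta, dtype=float)
    if beta.size != x.shape[1] + 1:
        raise ValueError(
            f"coefficient count {beta.size} does not match {x.shape[1]} covariates + intercept"
        )
    return beta[0] + x @ beta[1:] + alpha_per_tree


def survival_probability(m: float | np.ndarray, t: float) -> float | np.ndarray:
    """Period survival S = (1 - m)^t under a constant annual rate m."""
    if t < 0:
        raise ValueError("t must be >= 0")
    return (1.0 - np.asarray(m, dtype=float)) ** t


def _pointwise_loglik(k: np.ndarray, d: np.ndarray, t: float) -> np.ndarray:
    """Per-tree log-likelihood contributions, numerically guarded.

    With m = expit(k): log S = -t*log(1+e^k) and log(1-S) = log(1-e^{log S}),
    evaluated via softplus/expm1; the -t*softplus term is floored at
    LIK_EPS so log(1 - S) stays finite when m underflows to 0.
    """
    u = t * np.logaddexp(0.0, k)  # -log S
    u = np.maximum(u, LIK_EPS)
    log_dead = np.log(-np.expm1(-u))
    return np.where(d, log_dead, -u)


def log_likelihood(
    beta: Sequence[float] | np.ndarray,
    alpha: Sequence[float] | np.ndarray | float,
    data: ModelData,
) -> float:
    """Total interval-censored log-likelihood at given parameters.

    ``alpha`` is either a length-K vector of plot effects or a scalar
    applied to every tree (0 for a no-random-effect model).
    """
    alpha = np.asarray(alpha, dtype=float)
    alpha_per_tree = alpha[data.plot_index] if alpha.ndim == 1 else alpha
    k = linear_predictor(beta, data.design.matrix, alpha_per_tree)
    return float(_pointwise_loglik(k, data.y.astype(bool), data.t_years).sum())


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MCMCSettings:
    """Sampler configuration.

    Desk defaults (3 chains, 2 000 burn-in, 5 000 retained draws per chain)
    are sized for simulation studies; :meth:`paper_faithful` reproduces the
    original long-run schedule (the last 50 000 of 200 000 iterations per
    chain).
    """

    n_chains: int = 3
    burn_in: int = 2000
    draws: int = 5000
    thin: int = 1
    seed: int = 0
    random_effects: bool = True
    prior_sd: float = 100.0
    sigma_upper: float = 10.0

    @classmethod
    def paper_faithful(cls, seed: int = 0) -> "MCMCSettings":
        return cls(n_chains=3, burn_in=150_000, draws=50_000, thin=1, seed=seed)


@dataclass(frozen=True)
class DICResult:
    """Deviance Information Criterion decomposition.

    Dbar is the posterior-mean deviance, Dhat the deviance at the posterior
    means of all parameters (fixed effects and plot effects), pD = Dbar -
    Dhat the effective parameter count, and DIC = Dbar + pD.
    """

    dbar: float
    dhat: float
    p_d: float
    dic: float


@dataclass
class PosteriorResult:
    """Chains, summaries and diagnostics from one MCMC fit.

    ``beta_draws`` has shape (chains, draws, p+1) with the intercept first;
    ``alpha_draws`` is (chains, draws, K) (empty K axis when the model has
    no random effects); ``sigma_draws`` and ``deviance_draws`` are
    (chains, draws).
    """

    spec: MortalityModelSpec
    design: StandardizedDesign
    param_names: tuple[str, ...]
    beta_draws: np.ndarray
    alpha_draws: np.ndarray
    sigma_draws: np.ndarray
    deviance_draws: np.ndarray
    plot_ids: tuple[str, ...]
    rhat: dict[str, float]
    converged: bool
    dic: DICResult | None = None
    settings: MCMCSettings | None = None

    @property
    def pooled_beta(self) -> np.ndarray:
        return self.beta_draws.reshape(-1, self.beta_draws.shape[-1])

    @property
    def pooled_alpha(self) -> np.ndarray:
        return self.alpha_draws.reshape(-1, self.alpha_draws.shape[-1])

    @property
    def pooled_sigma(self) -> np.ndarray:
        return self.sigma_draws.reshape(-1)

    def posterior_mean_beta(self) -> np.ndarray:
        return self.pooled_beta.mean(axis=0)

    def posterior_mean_alpha(self) -> np.ndarray:
        if self.alpha_draws.shape[-1] == 0:
            return np.zeros(0)
        return self.pooled_alpha.mean(axis=0)

    def summary(self, include_plot_effects: bool = False) -> pd.DataFrame:
        """Posterior mean, SD, 95% credible bounds and R-hat per parameter."""
        rows = {}
        for i, name in enumerate(self.param_names):
            draws = self.pooled_beta[:, i]
            rows[name] = draws
        if self.sigma_draws.size:
            rows["sigma_alpha"] = self.pooled_sigma
        if include_plot_effects:
            for j, pid in enumerate(self.plot_ids):
                rows[f"alpha[{pid}]"] = self.pooled_alpha[:, j]
        table = pd.DataFrame(
            {
                "mean": {k: float(v.mean()) for k, v in rows.items()},
                "sd": {k: float(v.std(ddof=1)) for k, v in rows.items()},
                "q2.5": {k: float(np.quantile(v, 0.025)) for k, v in rows.items()},
                "q97.5": {k: float(np.quantile(v, 0.975)) for k, v in rows.items()},
            }
        )
        table["rhat"] = pd.Series(self.rhat).reindex(table.index)
        return table

    def credible_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        idx = self.param_names.index(name) if name in self.param_names else None
        draws = self.pooled_beta[:, idx] if idx is not None else self.pooled_sigma
        lo = (1.0 - level) / 2.0
        return float(np.quantile(draws, lo)), float(np.quantile(draws, 1.0 - lo))


def _init_state(
    data: ModelData, settings: MCMCSettings, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float]:
    """Dispersed but data-anchored starting values for one chain."""
    p1 = data.design.matrix.shape[1] + 1
    frac = float(data.y.mean())
    m0 = 1.0 - (1.0 - min(max(frac, 1e-4), 0.999)) ** (1.0 / data.t_years)
    beta = rng.normal(0.0, 1.0, size=p1)
    beta[0] += float(logit(min(max(m0, 1e-4), 0.5)))
    if settings.random_effects:
        alpha = rng.normal(0.0, 0.5, size=data.n_plots)
        sigma = float(rng.uniform(0.2, min(2.0, settings.sigma_upper)))
    else:
        alpha = np.zeros(0)
        sigma = 0.0
    return beta, alpha, sigma


def _sample_sigma_sq(
    ss: float, k_plots: int, upper: float, rng: np.random.Generator
) -> float:
    """Gibbs draw of sigma^2 | alpha under the Uniform(0, upper) prior on sigma.

    The conditional is InvGamma((K-1)/2, SS/2) truncated to sigma <= upper;
    sampled by drawing from the untruncated conditional and rejecting the
    (rare) draws beyond the bound.
    """
    shape = (k_plots - 1) / 2.0
    cap = upper * upper
    if ss <= 0.0 or shape <= 0.0:
        return float(rng.uniform(0.0, upper)) ** 2
    for _ in range(1000):
        g = rng.gamma(shape, 2.0 / ss)
        if g > 0 and 1.0 / g <= cap:
            return 1.0 / g
    return cap  # conditional mass essentially all above the bound


def _run_chain(
    data: ModelData, settings: MCMCSettings, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    x = data.x_with_intercept
    d = data.y.astype(bool)
    t = data.t_years
    plot_idx = data.plot_index
    n, p1 = x.shape
    k_plots = data.n_plots if settings.random_effects else 0
    prior_var = settings.prior_sd**2

    beta, alpha, sigma = _init_state(data, settings, rng)
    alpha_per_tree = alpha[plot_idx] if settings.random_effects else 0.0
    xb = x @ beta
    ll_i = _pointwise_loglik(xb + alpha_per_tree, d, t)
    if settings.random_effects:
        ll_plot = np.bincount(plot_idx, weights=ll_i, minlength=k_plots)
        ll_total = float(ll_plot.sum())
    else:
        ll_plot = np.zeros(0)
        ll_total = float(ll_i.sum())

    # proposal state
    log_step_beta = np.log(0.3 / np.sqrt(p1))
    chol = np.eye(p1)
    log_step_alpha = np.full(k_plots, np.log(0.5)) if settings.random_effects else None
    burn_betas = np.empty((settings.burn_in, p1))

    total = settings.burn_in + settings.draws * settings.thin
    out_beta = np.empty((settings.draws, p1))
    out_alpha = np.empty((settings.draws, k_plots))
    out_sigma = np.empty(settings.draws)
    out_dev = np.empty(settings.draws)

    for it in range(total):
        adapting = it < settings.burn_in
        gamma = (it + 1) ** -0.6
        # --- fixed-effect block (adaptive Metropolis), two sweeps for mixing ---
        for _ in range(2):
            step = np.exp(log_step_beta)
            beta_prop = beta + step * (chol @ rng.standard_normal(p1))
            xb_prop = x @ beta_prop
            ll_i_prop = _pointwise_loglik(
                xb_prop + (alpha[plot_idx] if settings.random_effects else 0.0), d, t
            )
            ll_prop = float(ll_i_prop.sum())
            log_r = (
                ll_prop
                - ll_total
                + (np.dot(beta, beta) - np.dot(beta_prop, beta_prop)) / (2.0 * prior_var)
            )
            accepted = np.log(rng.random()) < log_r
            if accepted:
                beta = beta_prop
                xb = xb_prop
                ll_total = ll_prop
                if settings.random_effects:
                    ll_plot = np.bincount(plot_idx, weights=ll_i_prop, minlength=k_plots)
            if adapting:
                log_step_beta += gamma * ((1.0 if accepted else 0.0) - 0.28)
        if adapting:
            burn_betas[it] = beta
            if it >= 400 and it % 200 == 0:
                cov = np.cov(burn_betas[it // 2 : it + 1].T) + 1e-8 * np.eye(p1)
                try:
                    chol = np.linalg.cholesky(cov / np.trace(cov) * p1)
                except np.linalg.LinAlgError:
                    pass

        if settings.random_effects:
            # --- plot effects (vectorized per-plot Metropolis) ---
            alpha_prop = alpha + np.exp(log_step_alpha) * rng.standard_normal(k_plots)
            ll_i_prop = _pointwise_loglik(xb + alpha_prop[plot_idx], d, t)
            ll_plot_prop = np.bincount(plot_idx, weights=ll_i_prop, minlength=k_plots)
            sig2 = max(sigma * sigma, 1e-12)
            log_r_plot = (
                ll_plot_prop - ll_plot + (alpha**2 - alpha_prop**2) / (2.0 * sig2)
            )
            acc = np.log(rng.random(k_plots)) < log_r_plot
            alpha = np.where(acc, alpha_prop, alpha)
            ll_plot = np.where(acc, ll_plot_prop, ll_plot)
            ll_total = float(ll_plot.sum())
            if adapting:
                log_step_alpha += gamma * (acc.astype(float) - 0.44)
            # --- sigma (Gibbs) ---
            sigma = float(
                np.sqrt(
                    _sample_sigma_sq(
                        float(np.dot(alpha, alpha)), k_plots, settings.sigma_upper, rng
                    )
                )
            )

        if not adapting and (it - settings.burn_in) % settings.thin == 0:
            j = (it - settings.burn_in) // settings.thin
            out_beta[j] = beta
            if settings.random_effects:
                out_alpha[j] = alpha
            out_sigma[j] = sigma
            out_dev[j] = -2.0 * ll_total

    return {"beta": out_beta, "alpha": out_alpha, "sigma": out_sigma, "deviance": out_dev}


def fit_mcmc(data: ModelData, settings: MCMCSettings | None = None) -> PosteriorResult:
    """Sample the posterior with multiple dispersed chains.

    Returns a :class:`PosteriorResult` with per-parameter R-hat and DIC.
    Non-convergence (any headline R-hat >= 1.05) sets ``converged`` to
    False and emits a warning; results are returned regardless.
    """
    if settings is None:
        settings = MCMCSettings()
    if data.n_trees == 0:
        raise ValueError("data is empty")
    if settings.random_effects and data.n_plots < 2:
        raise ValueError("random effects require at least 2 plots")

    seeds = np.random.SeedSequence(settings.seed).spawn(settings.n_chains)
    chains = [_run_chain(data, settings, np.random.default_rng(s)) for s in seeds]

    beta_draws = np.stack([c["beta"] for c in chains])
    alpha_draws = np.stack([c["alpha"] for c in chains])
    sigma_draws = np.stack([c["sigma"] for c in chains])
    deviance_draws = np.stack([c["deviance"] for c in chains])

    param_names = ("beta0",) + tuple(f"beta_{nm}" for nm in data.spec.covariate_names)
    posterior = {nm: beta_draws[:, :, i] for i, nm in enumerate(param_names)}
    if settings.random_effects:
        posterior["sigma_alpha"] = sigma_draws
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # arviz warns on short chains
        rhat_ds = az.rhat(az.from_dict(posterior=posterior))
    rhat = {nm: float(rhat_ds[nm].values) for nm in posterior}
    converged = all(np.isfinite(v) and v < 1.05 for v in rhat.values())
    if not converged:
        warnings.warn(
            "MCMC convergence check failed: max R-hat = "
            f"{max(rhat.values()):.3f} (threshold 1.05)",
            RuntimeWarning,
        )

    result = PosteriorResult(
        spec=data.spec,
        design=data.design,
        param_names=param_names,
        beta_draws=beta_draws,
        alpha_draws=alpha_draws,
        sigma_draws=sigma_draws,
        deviance_draws=deviance_draws,
        plot_ids=data.plot_ids,
        rhat=rhat,
        converged=converged,
        settings=settings,
    )
    result.dic = compute_dic(result, data)
    return result


def compute_dic(result: PosteriorResult, data: ModelData) -> DICResult:
    """DIC with the posterior-mean plug-in, including plot effects.

    Dbar averages the stored per-draw deviances; Dhat evaluates the
    deviance at the posterior means of the fixed and plot effects.  A
    negative pD (a known DIC pathology under strong non-normality) is
    reported with a warning rather than suppressed.
    """
    dbar = float(result.deviance_draws.mean())
    beta_mean = result.posterior_mean_beta()
    alpha_mean = result.posterior_mean_alpha()
    alpha_arg = alpha_mean if alpha_mean.size else 0.0
    dhat = -2.0 * log_likelihood(beta_mean, alpha_arg, data)
    p_d = dbar - dhat
    if p_d < -1e-8:
        warnings.warn(f"negative effective parameter count pD = {p_d:.2f}", RuntimeWarning)
    return DICResult(dbar=dbar, dhat=dhat, p_d=p_d, dic=dbar + p_d)
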