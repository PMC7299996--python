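"""Bayesian calibration of the concentration-formation parameters.

The observation model is multiplicative: measured concentrations scatter
lognormally around the closed-form prediction, so the likelihood is Gaussian
on log-concentration residuals,

    log C_obs_i ~ Normal(log C(Q_i, t_i; a, b, d), sigma^2).

``sigma`` (log-space s.d., roughly the relative measurement error) is either
estimated as a free parameter or fixed from the reported per-sample error.
Sampling uses the affine-invariant ensemble sampler (emcee) in log-parameter
space under log-uniform priors; summaries report the posterior median with a
2.5–97.5% credible interval per parameter, the split-chain R-hat diagnostic,
and a log-space R² of the point predictions.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from collections.abc import Sequence

import emcee
import numpy as np
from scipy import optimize

from .cq import CQParams, concentration_closed_form
from .timeseries import SampleRecord
from .trend import TrendParams

__all__ = [
    "DEFAULT_PRIOR_BOUNDS",
    "McmcConfig",
    "Chains",
    "ParamInterval",
    "PosteriorSummary",
    "log_likelihood",
    "run_mcmc",
    "posterior_summary",
    "r_squared",
    "posterior_predictive",
]

logger = logging.getLogger(__name__)

#: Log-uniform prior supports: the previously reported 95% credible ranges for
#: this model (a: 0.14-1.09 mm/day/m, b: 0.74-3.05 1/m, d: 1032-2989 m·day)
#: widened by one full decade on each side. The closed form is exactly
#: invariant under (a, b, d) -> (k*a, k*b, k*d) — only b/a and d/b are
#: identified by data — so the marginal posteriors along that scale direction
#: are set by the prior; the bounds must therefore be anchored on the
#: physically plausible scale rather than made arbitrarily wide.
DEFAULT_PRIOR_BOUNDS: dict[str, tuple[float, float]] = {
    "a": (0.014, 10.9),
    "b": (0.074, 30.5),
    "d": (103.2, 29890.0),
    "sigma": (1e-3, 2.0),
}

#: Default fixed log-space noise s.d. — the reported ~10.9% measurement error.
DEFAULT_SIGMA = 0.109


@dataclasses.dataclass(frozen=True)
class McmcConfig:
    """Sampler configuration.

    ``sigma_mode`` selects whether the observation noise is a free parameter
    ("estimated", the default) or fixed at ``sigma_fixed`` ("fixed").
    ``prior_only`` disables the likelihood (sampler sanity checks).
    """

    n_walkers: int = 16
    n_draws: int = 1500
    n_burn: int = 500
    seed: int = 0
    sigma_mode: str = "estimated"
    sigma_fixed: float = DEFAULT_SIGMA
    prior_bounds: dict[str, tuple[float, float]] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_PRIOR_BOUNDS)
    )
    prior_only: bool = False

    def __post_init__(self) -> None:
        if self.sigma_mode not in ("estimated", "fixed"):
            raise ValueError("sigma_mode must be 'estimated' or 'fixed'")
        if not self.n_draws > self.n_burn >= 0:
            raise ValueError("need n_draws > n_burn >= 0")
        n_free = 4 if self.sigma_mode == "estimated" else 3
        if self.n_walkers < 2 * n_free:
            raise ValueError(f"need at least {2 * n_free} walkers for {n_free} free parameters")
        for name, (lo, hi) in self.prior_bounds.items():
            if not (0 < lo < hi < np.inf):
                raise ValueError(f"prior bounds for {name} must be positive, finite, ordered")

    @property
    def param_names(self) -> tuple[str, ...]:
        return ("a", "b", "d", "sigma") if self.sigma_mode == "estimated" else ("a", "b", "d")


@dataclasses.dataclass(frozen=True)
class Chains:
    """Post-burn-in MCMC draws: shape (n_walkers, n_kept, n_params), natural scale."""

    samples: np.ndarray
    param_names: tuple[str, ...]
    acceptance_rate: float
    rhat: dict[str, float]
    config: McmcConfig

    @property
    def flat(self) -> np.ndarray:
        """All draws pooled: shape (n_walkers * n_kept, n_params)."""
        return self.samples.reshape(-1, self.samples.shape[-1])


@dataclasses.dataclass(frozen=True)
class ParamInterval:
    best_fit: float  # posterior median
    lo_2p5: float
    hi_97p5: float

    def covers(self, value: float) -> bool:
        return self.lo_2p5 <= value <= self.hi_97p5


@dataclasses.dataclass(frozen=True)
class PosteriorSummary:
    params: dict[str, ParamInterval]
    map_estimate: dict[str, float] | None = None
    r_squared: float | None = None
    acceptance_rate: float | None = None
    rhat: dict[str, float] | None = None

    def to_dict(self) -> dict:
        out: dict = {"schema_version": 1, "parameters": {}}
        for name, iv in self.params.items():
            out["parameters"][name] = {
                "best_fit": iv.best_fit,
                "lo_2p5": iv.lo_2p5,
                "hi_97p5": iv.hi_97p5,
            }
        if self.map_estimate is not None:
            out["map_estimate"] = self.map_estimate
        if self.r_squared is not None:
            out["r_squared"] = self.r_squared
        out["diagnostics"] = {"acceptance_rate": self.acceptance_rate, "rhat": self.rhat}
        return out


def _arrays(records: Sequence[SampleRecord]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    q = np.array([r.q for r in records], dtype=float)
    c = np.array([r.c for r in records], dtype=float)
    t = np.array([r.t_days for r in records], dtype=float)
    return q, c, t


def log_likelihood(
    cq: CQParams | tuple[float, float, float],
    sigma: float,
    records: Sequence[SampleRecord],
    trend: TrendParams,
) -> float:
    """Gaussian log-likelihood of log-concentrations around the model.

    Invalid parameter values (any nonpositive, or sigma <= 0) return ``-inf``
    — a rejected sampler state, not an exception.
    """
    if not isinstance(cq, CQParams):
        a, b, d = cq
        if a <= 0 or b <= 0 or d < 0 or not np.all(np.isfinite([a, b, d])):
            return -np.inf
        cq = CQParams(a, b, d)
    if sigma <= 0 or not np.isfinite(sigma):
        return -np.inf
    q, c, t = _arrays(records)
    resid = np.log(c) - np.log(concentration_closed_form(q, t, cq, trend))
    n = len(records)
    return float(-0.5 * np.sum((resid / sigma) ** 2) - n * np.log(sigma) - 0.5 * n * np.log(2 * np.pi))


def _log_prior(log_theta: np.ndarray, bounds: list[tuple[float, float]]) -> float:
    for v, (lo, hi) in zip(log_theta, bounds):
        if not (np.log(lo) <= v <= np.log(hi)):
            return -np.inf
    return 0.0  # log-uniform: flat in log space


def _init_point(records, trend, cfg) -> np.ndarray:
    """Deterministic starting point: posterior mode from a coarse simplex search."""
    names = cfg.param_names
    bounds = [cfg.prior_bounds[n] for n in names]
    start = {"a": 0.5, "b": 1.0, "d": 1000.0, "sigma": 0.2}
    x0 = np.log([start[n] for n in names])

    def neg_log_post(lt: np.ndarray) -> float:
        lp = _log_prior(lt, bounds)
        if not np.isfinite(lp):
            return np.inf
        theta = np.exp(lt)
        sigma = theta[3] if cfg.sigma_mode == "estimated" else cfg.sigma_fixed
        return -(lp + log_likelihood(tuple(theta[:3]), sigma, records, trend))

    res = optimize.minimize(neg_log_post, x0, method="Nelder-Mead", options={"maxfev": 4000})
    return res.x if np.isfinite(res.fun) else x0


def run_mcmc(records: Sequence[SampleRecord], trend: TrendParams, cfg: McmcConfig) -> Chains:
    """Sample the posterior of (a, b, d[, sigma]) with the ensemble sampler.

    Walkers start in a small log-space ball around the posterior mode (found by
    a deterministic simplex search); ``cfg.n_burn`` initial draws are
    discarded. Fully deterministic for a fixed seed. A split-chain R-hat above
    1.05 for any parameter triggers a warning, not an error.
    """
    if not cfg.prior_only and len(records) < 20:
        raise ValueError(f"need at least 20 records to calibrate, got {len(records)}")
    names = cfg.param_names
    ndim = len(names)
    bounds = [cfg.prior_bounds[n] for n in names]
    log_lo = np.log([b[0] for b in bounds])
    log_hi = np.log([b[1] for b in bounds])

    if cfg.prior_only:

        def log_prob(lt: np.ndarray) -> float:
            return _log_prior(lt, bounds)

    else:

        def log_prob(lt: np.ndarray) -> float:
            lp = _log_prior(lt, bounds)
            if not np.isfinite(lp):
                return -np.inf
            theta = np.exp(lt)
            sigma = theta[3] if cfg.sigma_mode == "estimated" else cfg.sigma_fixed
            return lp + log_likelihood(tuple(theta[:3]), sigma, records, trend)

    rng = np.random.default_rng(cfg.seed)
    if cfg.prior_only:
        p0 = rng.uniform(log_lo, log_hi, size=(cfg.n_walkers, ndim))
    else:
        center = _init_point(records, trend, cfg)
        p0 = center + 1e-3 * rng.standard_normal((cfg.n_walkers, ndim))
        p0 = np.clip(p0, log_lo + 1e-9, log_hi - 1e-9)
    if not np.any(np.isfinite([log_prob(p) for p in p0])):
        raise RuntimeError("non-finite posterior at every initial walker position")

    sampler = emcee.EnsembleSampler(cfg.n_walkers, ndim, log_prob)
    sampler.random_state = np.random.RandomState(cfg.seed).get_state()
    sampler.run_mcmc(p0, cfg.n_draws, progress=False)
    acc = float(np.mean(sampler.acceptance_fraction))
    if acc == 0.0:
        raise RuntimeError("sampler accepted no proposals; check data and priors")

    chain = np.exp(sampler.get_chain(discard=cfg.n_burn))  # (n_kept, n_walkers, ndim)
    samples = np.swapaxes(chain, 0, 1)  # (n_walkers, n_kept, ndim)
    rhat = _split_rhat(samples, names)
    flagged = {k: v for k, v in rhat.items() if v > 1.05}
    if flagged:
        warnings.warn(f"split-chain R-hat above 1.05: {flagged}; consider more draws", stacklevel=2)
    return Chains(samples=samples, param_names=names, acceptance_rate=acc, rhat=rhat, config=cfg)


def _split_rhat(samples: np.ndarray, names: tuple[str, ...]) -> dict[str, float]:
    import arviz  # heavy import, deferred

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = arviz.convert_to_dataset(
            {name: samples[:, :, i] for i, name in enumerate(names)}
        )
        r = arviz.rhat(ds, method="split")
    return {name: float(r[name].values) for name in names}


def posterior_summary(
    chains: Chains,
    records: Sequence[SampleRecord] | None = None,
    trend: TrendParams | None = None,
) -> PosteriorSummary:
    """Median and 2.5/97.5 percentiles per parameter (linear-interpolation convention).

    When records and trend are supplied, also reports the MAP draw re-scored by
    log-likelihood and the log-space R² at the posterior-median parameters.
    """
    flat = chains.flat
    if flat.size == 0:
        raise ValueError("empty chains")
    params: dict[str, ParamInterval] = {}
    for i, name in enumerate(chains.param_names):
        lo, med, hi = np.percentile(flat[:, i], [2.5, 50.0, 97.5], method="linear")
        params[name] = ParamInterval(best_fit=float(med), lo_2p5=float(lo), hi_97p5=float(hi))

    map_est, r2 = None, None
    if records is not None and trend is not None:
        sub = flat[:: max(1, len(flat) // 2000)]
        scores = [
            log_likelihood(
                tuple(row[:3]),
                row[3] if "sigma" in chains.param_names else chains.config.sigma_fixed,
                records,
                trend,
            )
            for row in sub
        ]
        best = sub[int(np.argmax(scores))]
        map_est = {n: float(v) for n, v in zip(chains.param_names, best)}
        med_cq = CQParams(params["a"].best_fit, params["b"].best_fit, params["d"].best_fit)
        r2 = r_squared(records, med_cq, trend)
    return PosteriorSummary(
        params=params,
        map_estimate=map_est,
        r_squared=r2,
        acceptance_rate=chains.acceptance_rate,
        rhat=chains.rhat,
    )


def r_squared(
    records: Sequence[SampleRecord],
    cq: CQParams,
    trend: TrendParams,
    space: str = "log",
) -> float:
    """Coefficient of determination of model point predictions vs observations.

    ``1 - SS_res/SS_tot``, computed on log concentrations by default (matching
    the multiplicative error model); ``space="linear"`` uses raw concentrations.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records for R²")
    q, c, t = _arrays(records)
    pred = concentration_closed_form(q, t, cq, trend)
    if space == "log":
        obs, fit = np.log(c), np.log(pred)
    elif space == "linear":
        obs, fit = c, pred
    else:
        raise ValueError("space must be 'log' or 'linear'")
    return _coefficient_of_determination(obs, fit)


def _coefficient_of_determination(obs: np.ndarray, fit: np.ndarray) -> float:
    """1 - SS_res/SS_tot; equals 1 for a perfect fit, 0 when predicting the mean."""
    ss_tot = float(np.sum((obs - np.mean(obs)) ** 2))
    if ss_tot == 0:
        raise ValueError("observations have zero variance; R² undefined")
    ss_res = float(np.sum((np.asarray(obs) - np.asarray(fit)) ** 2))
    return 1.0 - ss_res / ss_tot


def posterior_predictive(
    chains: Chains,
    q_grid,
    t_grid,
    trend: TrendParams,
    quantiles: Sequence[float] = (0.025, 0.5, 0.975),
    seed: int = 0,
    sigma: float | None = None,
) -> dict[float, np.ndarray]:
    """Quantile bands of model predictions with observation noise resampled per draw.

    For every posterior draw the model is evaluated on the (Q, t) grid and
    multiplied by lognormal observation noise (s.d. from the draw's sigma when
    estimated, else ``sigma`` or the config's fixed value). Returns a mapping
    quantile -> array over grid points. Wider requested quantiles always give
    wider (nested) bands.
    """
    qs = np.asarray(quantiles, dtype=float)
    if np.any((qs <= 0) | (qs >= 1)):
        raise ValueError("quantiles must lie strictly inside (0, 1)")
    q_grid = np.asarray(q_grid, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    flat = chains.flat
    rng = np.random.default_rng(seed)
    preds = np.empty((len(flat), q_grid.size))
    has_sigma = "sigma" in chains.param_names
    for j, row in enumerate(flat):
        cq = CQParams(row[0], row[1], row[2])
        s = row[3] if has_sigma else (sigma if sigma is not None else chains.config.sigma_fixed)
        mu = concentration_closed_form(q_grid, t_grid, cq, trend)
        noise = np.exp(rng.normal(0.0, s, size=q_grid.size)) if s > 0 else 1.0
        preds[j] = mu * noise
    bands = np.quantile(preds, qs, axis=0, method="linear")
    return {float(p): bands[i] for i, p in enumerate(qs)}
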