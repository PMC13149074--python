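"""Bayesian fitting of the pooled AFT survival models and DIC selection.

One likelihood is placed over all reconstructed patients with treatment
indicators on the AFT location and a single shared ancillary parameter
(fixed-effect, one-stage pooling).  Priors are effectively flat: normal(0,
sd 100) on every location coefficient and uniform on the log of the
ancillary parameter over [1e-4, 100].

Sampling uses a seeded affine-invariant ensemble sampler (emcee) run as
several independent chains, initialized with a small jitter around the
maximum-likelihood estimate; convergence is summarized by split-Rhat
(arviz).  The deviance information criterion uses the classical
Spiegelhalter plug-in form, with the ancillary parameter averaged on the
log scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy import optimize

from .families import FAMILIES, ParamVector, loglik_terms
from .reconstruct import PooledData

__all__ = [
    "McmcConfig",
    "FitResult",
    "SelectionResult",
    "sample_posterior",
    "compute_dic",
    "select_model",
    "PRIOR_SPEC",
]

PRIOR_SPEC = {
    "location": "normal(0, sd=100)",
    "ancillary": "uniform on log scale over [1e-4, 100]",
}

_LOG_ANC_LO = np.log(1e-4)
_LOG_ANC_HI = np.log(100.0)


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings: independent chains, iterations and warmup per chain."""

    chains: int = 3
    iterations: int = 4000
    warmup: int = 2000
    seed: int = 0
    walkers: int | None = None  # per-chain ensemble size; default 2*ndim + 2

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("at least 2 chains are required")
        if not self.warmup < self.iterations:
            raise ValueError("warmup must be smaller than iterations")

    @property
    def draws_per_chain(self) -> int:
        return self.iterations - self.warmup


@dataclass
class FitResult:
    """Posterior draws plus diagnostics for one family on one endpoint.

    ``draws`` has shape (chains, draws_per_chain, ndim) in the sampled
    parameterization: location coefficients on their natural scale and the
    ancillary parameter as its logarithm (column ``log_ancillary``).
    """

    family: str
    endpoint: str
    reference: str
    treatments: tuple[str, ...]
    param_names: tuple[str, ...]
    draws: np.ndarray
    dic: float
    p_d: float
    rhat: dict
    config: McmcConfig
    max_time: float
    mean_acceptance: float
    warnings: list = field(default_factory=list)
    prior: dict = field(default_factory=lambda: dict(PRIOR_SPEC))

    @property
    def flat_draws(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    @property
    def has_ancillary(self) -> bool:
        return self.family != "exponential"

    def location_draws(self, treatment: str) -> np.ndarray:
        """Per-draw AFT location for one treatment (reference included)."""
        flat = self.flat_draws
        loc = flat[:, 0].copy()
        if treatment != self.reference:
            if treatment not in self.treatments:
                raise KeyError(f"unknown treatment {treatment!r}")
            loc += flat[:, 1 + self.treatments.index(treatment)]
        return loc

    def ancillary_draws(self) -> np.ndarray | None:
        if not self.has_ancillary:
            return None
        return np.exp(self.flat_draws[:, -1])

    def posterior_mean_params(self) -> ParamVector:
        """Plug-in parameter vector at the posterior mean of the sampled
        (untransformed) parameters; the ancillary is averaged on log scale."""
        mean = self.flat_draws.mean(axis=0)
        beta = {t: float(mean[1 + i]) for i, t in enumerate(self.treatments)}
        anc = float(np.exp(mean[-1])) if self.has_ancillary else None
        return ParamVector(self.family, float(mean[0]), beta, anc)

    def draw_params(self, index: int) -> ParamVector:
        row = self.flat_draws[index]
        beta = {t: float(row[1 + i]) for i, t in enumerate(self.treatments)}
        anc = float(np.exp(row[-1])) if self.has_ancillary else None
        return ParamVector(self.family, float(row[0]), beta, anc)

    def summary(self) -> pd.DataFrame:
        flat = self.flat_draws
        q = np.quantile(flat, [0.025, 0.5, 0.975], axis=0)
        return pd.DataFrame(
            {
                "parameter": self.param_names,
                "mean": flat.mean(axis=0),
                "sd": flat.std(axis=0, ddof=1),
                "q2.5": q[0],
                "median": q[1],
                "q97.5": q[2],
                "rhat": [self.rhat.get(p, np.nan) for p in self.param_names],
            }
        )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "family": self.family,
            "endpoint": self.endpoint,
            "reference": self.reference,
            "treatments": list(self.treatments),
            "param_names": list(self.param_names),
            "dic": self.dic,
            "p_d": self.p_d,
            "rhat": self.rhat,
            "mean_acceptance": self.mean_acceptance,
            "warnings": list(self.warnings),
            "prior": self.prior,
            "config": {
                "chains": self.config.chains,
                "iterations": self.config.iterations,
                "warmup": self.config.warmup,
                "seed": self.config.seed,
            },
            "max_time": self.max_time,
            "posterior_summary": self.summary().to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def draws_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.flat_draws, columns=list(self.param_names))


class _LogPost:
    """Vectorized log-posterior over a (walkers, ndim) parameter matrix."""

    def __init__(self, pooled: PooledData, family: str):
        self.family = family
        self.time = pooled.data["time_months"].to_numpy(dtype=float)
        self.event = pooled.data["event"].to_numpy(dtype=int)
        self.X = pooled.indicators  # (n, k)
        self.k = self.X.shape[1]
        self.has_anc = family != "exponential"
        self.ndim = 1 + self.k + (1 if self.has_anc else 0)

    def loglik(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        loc = theta[:, [0]] + theta[:, 1 : 1 + self.k] @ self.X.T  # (W, n)
        anc = np.exp(theta[:, [-1]]) if self.has_anc else None
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            terms = loglik_terms(
                self.family, self.time, self.event, loc, anc
            )
        ll = terms.sum(axis=1)
        return np.where(np.isfinite(ll), ll, -np.inf)

    def __call__(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        lp = -0.5 * (theta[:, : 1 + self.k] / 100.0) ** 2
        lp = lp.sum(axis=1)
        if self.has_anc:
            log_anc = theta[:, -1]
            lp = np.where(
                (log_anc >= _LOG_ANC_LO) & (log_anc <= _LOG_ANC_HI), lp, -np.inf
            )
        out = np.full(theta.shape[0], -np.inf)
        ok = np.isfinite(lp)
        if np.any(ok):
            out[ok] = lp[ok] + self.loglik(theta[ok])
        return out


def _initial_point(lp: _LogPost) -> np.ndarray:
    """Crude MLE via Nelder-Mead from a moment-based starting point."""
    logt = np.log(np.maximum(lp.time, 1e-6))
    x0 = np.zeros(lp.ndim)
    x0[0] = float(np.median(logt))
    if lp.has_anc:
        spread = float(np.std(logt))
        x0[-1] = np.clip(np.log(max(spread, 0.2)), _LOG_ANC_LO + 1, _LOG_ANC_HI - 1)

    def neg(theta):
        return -float(lp(theta[None, :])[0])

    res = optimize.minimize(
        neg, x0, method="Nelder-Mead",
        options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-6},
    )
    return res.x if np.isfinite(res.fun) else x0


def sample_posterior(
    pooled: PooledData,
    family: str,
    config: McmcConfig | None = None,
    endpoint: str = "OS",
) -> FitResult:
    """Draw from the posterior of one family on the pooled dataset.

    Runs ``config.chains`` independent seeded ensembles; each chain's
    post-warmup draws are thinned across walkers so the total draw count is
    exactly ``chains * (iterations - warmup)``.  An Rhat above 1.01 attaches
    a convergence warning (not fatal).
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if len(pooled.data) == 0:
        raise ValueError("cannot fit an empty dataset")
    ev = pooled.data.groupby("treatment")["event"].sum()
    no_events = sorted(ev.index[ev == 0])
    if no_events:
        raise ValueError(f"treatments with no events: {no_events}")
    config = config or McmcConfig()

    lp = _LogPost(pooled, family)
    ndim = lp.ndim
    n_walkers = config.walkers or max(2 * ndim + 2, 6)
    center = _initial_point(lp)
    ss = np.random.SeedSequence(config.seed)
    chain_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(config.chains)]

    chains = np.empty((config.chains, config.draws_per_chain, ndim))
    acc = []
    for c, cseed in enumerate(chain_seeds):
        rng = np.random.default_rng(cseed)
        p0 = center + 0.01 * rng.standard_normal((n_walkers, ndim))
        if lp.has_anc:
            p0[:, -1] = np.clip(p0[:, -1], _LOG_ANC_LO + 0.5, _LOG_ANC_HI - 0.5)
        sampler = emcee.EnsembleSampler(n_walkers, ndim, lp, vectorize=True)
        sampler.random_state = np.random.RandomState(cseed)
        try:
            sampler.run_mcmc(
                p0, config.iterations, skip_initial_state_check=True, progress=False
            )
        except Exception as exc:  # pragma: no cover - engine failure surface
            raise RuntimeError(f"sampler failed for family {family!r}: {exc}") from exc
        chain = sampler.get_chain()[config.warmup :]  # (draws, walkers, ndim)
        # one draw per post-warmup step, rotating through walkers
        step_ix = np.arange(config.draws_per_chain)
        chains[c] = chain[step_ix, step_ix % n_walkers, :]
        acc.append(float(sampler.acceptance_fraction.mean()))

    param_names = tuple(
        ["beta0"]
        + [f"beta[{t}]" for t in pooled.treatments]
        + (["log_ancillary"] if lp.has_anc else [])
    )
    rhat = _rhat_table(chains, param_names)
    warnings = []
    worst = max(rhat.values())
    if worst > 1.01:
        warnings.append(f"convergence warning: max Rhat {worst:.4f} > 1.01")

    fit = FitResult(
        family=family,
        endpoint=endpoint,
        reference=pooled.reference,
        treatments=pooled.treatments,
        param_names=param_names,
        draws=chains,
        dic=np.nan,
        p_d=np.nan,
        rhat=rhat,
        config=config,
        max_time=float(pooled.data["time_months"].max()),
        mean_acceptance=float(np.mean(acc)),
        warnings=warnings,
    )
    dic, p_d = compute_dic(fit, pooled)
    fit.dic = dic
    fit.p_d = p_d
    if p_d < 0:
        fit.warnings.append(f"negative effective parameter count pD={p_d:.3f}")
    return fit


def _rhat_table(chains: np.ndarray, names: Sequence[str]) -> dict:
    ds = az.convert_to_dataset(chains, group="posterior")
    r = az.rhat(ds)["x"].to_numpy()
    return {name: float(r[i]) for i, name in enumerate(names)}


def compute_dic(
    fit: FitResult, pooled: PooledData, block: int = 512
) -> tuple[float, float]:
    """Deviance information criterion from posterior draws.

    D(theta) = -2 log L; DIC = mean D + pD with pD = mean D - D(theta_bar),
    theta_bar the posterior mean of the sampled parameters (ancillary
    averaged on log scale).  Requires at least 100 draws.
    """
    flat = fit.flat_draws
    if flat.shape[0] < 100:
        raise ValueError("compute_dic requires at least 100 draws")
    lp = _LogPost(pooled, fit.family)
    dev = np.empty(flat.shape[0])
    for start in range(0, flat.shape[0], block):
        dev[start : start + block] = -2.0 * lp.loglik(flat[start : start + block])
    mean_dev = float(dev.mean())
    dev_at_mean = float(-2.0 * lp.loglik(flat.mean(axis=0)[None, :])[0])
    if not np.isfinite(dev_at_mean):
        raise FloatingPointError("deviance at the posterior mean is not finite")
    p_d = mean_dev - dev_at_mean
    return mean_dev + p_d, p_d


@dataclass(frozen=True)
class SelectionResult:
    """Lowest-DIC family plus the full comparison table."""

    family: str
    table: pd.DataFrame
    tie: bool


def select_model(fits: Sequence[FitResult]) -> SelectionResult:
    """Pick the family with minimal DIC (ties: first in canonical order).

    All fits must be on the same endpoint; the full DIC table is retained.
    """
    if len(fits) < 2:
        raise ValueError("select_model needs at least two fits")
    endpoints = {f.endpoint for f in fits}
    if len(endpoints) != 1:
        raise ValueError(f"fits mix endpoints: {sorted(endpoints)}")
    ordered = sorted(fits, key=lambda f: FAMILIES.index(f.family))
    dics = np.array([f.dic for f in ordered])
    best_ix = int(np.argmin(dics))
    tie = bool(np.sum(dics == dics[best_ix]) > 1)
    table = pd.DataFrame(
        {
            "endpoint": [f.endpoint for f in ordered],
            "family": [f.family for f in ordered],
            "dic": [f.dic for f in ordered],
            "p_d": [f.p_d for f in ordered],
            "selected": [i == best_ix for i in range(len(ordered))],
        }
    )
    return SelectionResult(family=ordered[best_ix].family, table=table, tie=tie)
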