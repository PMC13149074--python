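"""Parametric survival families under an accelerated-failure-time linear predictor.

Five families are supported: exponential, Weibull, gamma, log-logistic and
log-normal.  Each is parameterized by a *location* on the log-time scale and,
except for the exponential, a shared positive *ancillary* parameter:

====================  =============================  =====================
family                location maps to               ancillary
====================  =============================  =====================
exponential           rate  lambda = exp(-loc)       --
weibull               scale lambda = exp(loc)        shape k
gamma                 rate  b = exp(-loc)            shape a
loglogistic           scale lambda = exp(loc)        shape k
lognormal             meanlog mu = loc               sdlog sigma
====================  =============================  =====================

Treatment indicators act additively on the location, so a positive treatment
effect always means longer survival.  The ancillary parameter is shared across
treatments; for the non-Weibull families this is exactly what makes hazard
ratios between treatments vary over time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import special

__all__ = [
    "FAMILIES",
    "TIME_FLOOR",
    "ParamVector",
    "survival",
    "hazard",
    "density",
    "quantile",
    "log_sf",
    "log_pdf",
    "loglik_censored",
    "loglik_terms",
]

#: canonical family order, used for tie-breaking in model selection
FAMILIES = ("exponential", "weibull", "gamma", "loglogistic", "lognormal")

#: times below this (months) are clamped so log-time evaluations stay finite
TIME_FLOOR = 1e-6

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


class InvalidFamilyError(ValueError):
    """Raised when a family name is not one of the five supported ones."""


def _check_family(family: str) -> str:
    if family not in FAMILIES:
        raise InvalidFamilyError(
            f"unknown family {family!r}; expected one of {FAMILIES}"
        )
    return family


@dataclass(frozen=True)
class ParamVector:
    """Parameters of one family under the AFT linear predictor.

    ``beta0`` is the location of the reference treatment; ``beta`` maps each
    non-reference treatment to its additive location effect (log-time scale).
    ``ancillary`` is the shared positive shape/sdlog parameter (``None`` for
    the exponential family).
    """

    family: str
    beta0: float
    beta: Mapping[str, float] = field(default_factory=dict)
    ancillary: float | None = None

    def __post_init__(self) -> None:
        _check_family(self.family)
        if self.family == "exponential":
            if self.ancillary is not None:
                raise ValueError("exponential family takes no ancillary parameter")
        else:
            if self.ancillary is None or not self.ancillary > 0:
                raise ValueError(
                    f"{self.family} requires a positive ancillary parameter"
                )

    def location(self, treatment: str | None = None) -> float:
        """AFT location for a treatment (reference when absent from ``beta``)."""
        if treatment is None:
            return self.beta0
        return self.beta0 + self.beta.get(treatment, 0.0)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "beta0": self.beta0,
            "beta": dict(self.beta),
            "ancillary": self.ancillary,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ParamVector":
        return cls(
            family=d["family"],
            beta0=float(d["beta0"]),
            beta={k: float(v) for k, v in dict(d.get("beta") or {}).items()},
            ancillary=None if d.get("ancillary") is None else float(d["ancillary"]),
        )


# ---------------------------------------------------------------------------
# Core kernels.  All accept broadcasting arrays for t / location / ancillary.
# ---------------------------------------------------------------------------

def log_sf(family: str, t, location, ancillary=None):
    """log S(t).  Vectorized over ``t``, ``location`` and ``ancillary``."""
    _check_family(family)
    t = np.maximum(np.asarray(t, dtype=float), TIME_FLOOR)
    loc = np.asarray(location, dtype=float)
    if family == "exponential":
        return -np.exp(-loc) * t
    anc = np.asarray(ancillary, dtype=float)
    logt = np.log(t)
    if family == "weibull":
        return -np.exp(anc * (logt - loc))
    if family == "gamma":
        with np.errstate(divide="ignore"):
            return np.log(special.gammaincc(anc, np.exp(-loc) * t))
    if family == "loglogistic":
        return -np.log1p(np.exp(anc * (logt - loc)))
    # lognormal
    return special.log_ndtr(-(logt - loc) / anc)


def log_pdf(family: str, t, location, ancillary=None):
    """log f(t).  Vectorized like :func:`log_sf`."""
    _check_family(family)
    t = np.maximum(np.asarray(t, dtype=float), TIME_FLOOR)
    loc = np.asarray(location, dtype=float)
    logt = np.log(t)
    if family == "exponential":
        return -loc - np.exp(-loc) * t
    anc = np.asarray(ancillary, dtype=float)
    z = anc * (logt - loc)
    if family == "weibull":
        return np.log(anc) - loc + (anc - 1.0) * (logt - loc) - np.exp(z)
    if family == "gamma":
        rate = np.exp(-loc)
        return (
            anc * np.log(rate)
            + (anc - 1.0) * logt
            - rate * t
            - special.gammaln(anc)
        )
    if family == "loglogistic":
        return np.log(anc) - loc + (anc - 1.0) * (logt - loc) - 2.0 * np.log1p(np.exp(z))
    # lognormal
    zstd = (logt - loc) / anc
    return -logt - np.log(anc) - _LOG_SQRT_2PI - 0.5 * zstd * zstd


def survival(family: str, params: ParamVector, treatment: str | None, t):
    """S(t) for one treatment arm.  ``t`` may be an array; negative t errors."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("survival requires t >= 0")
    out = np.exp(log_sf(family, np.maximum(t_arr, TIME_FLOOR),
                        params.location(treatment), params.ancillary))
    out = np.where(t_arr == 0, 1.0, out)
    return out if out.ndim else float(out)


def density(family: str, params: ParamVector, treatment: str | None, t):
    """f(t) for one treatment arm."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0):
        raise ValueError("density requires t > 0")
    out = np.exp(log_pdf(family, t_arr, params.location(treatment), params.ancillary))
    return out if out.ndim else float(out)


def hazard(family: str, params: ParamVector, treatment: str | None, t):
    """h(t) = f(t)/S(t) in events per month; requires t > 0."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0):
        raise ValueError("hazard requires t > 0")
    loc = params.location(treatment)
    out = np.exp(
        log_pdf(family, t_arr, loc, params.ancillary)
        - log_sf(family, t_arr, loc, params.ancillary)
    )
    return out if out.ndim else float(out)


def quantile(family: str, params: ParamVector, treatment: str | None, p):
    """Inverse CDF: the time t with 1 - S(t) = p, for p in (0, 1)."""
    _check_family(family)
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr <= 0) | (p_arr >= 1)):
        raise ValueError("quantile requires 0 < p < 1")
    loc = params.location(treatment)
    anc = params.ancillary
    if family == "exponential":
        out = -np.log1p(-p_arr) * np.exp(loc)
    elif family == "weibull":
        out = np.exp(loc) * (-np.log1p(-p_arr)) ** (1.0 / anc)
    elif family == "gamma":
        out = special.gammaincinv(anc, p_arr) * np.exp(loc)
    elif family == "loglogistic":
        out = np.exp(loc) * (p_arr / (1.0 - p_arr)) ** (1.0 / anc)
    else:  # lognormal
        out = np.exp(loc + anc * special.ndtri(p_arr))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Right-censored log-likelihood
# ---------------------------------------------------------------------------

def loglik_terms(family: str, time, event, location, ancillary=None):
    """Per-record censored log-likelihood terms.

    ``location`` broadcasts against ``time`` so batched parameter matrices
    (e.g. one row per MCMC walker) evaluate in one call.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    lp = log_pdf(family, time, location, ancillary)
    ls = log_sf(family, time, location, ancillary)
    return np.where(event == 1, lp, ls)


def loglik_censored(data, params: ParamVector) -> float:
    """Right-censored log-likelihood of a pooled dataset under ``params``.

    ``data`` needs columns ``time_months``, ``event`` and ``treatment``;
    each record's location is ``beta0`` plus its treatment effect.  Empty
    data gives 0.  A NaN term raises with the offending record index.
    """
    if len(data) == 0:
        return 0.0
    time = np.asarray(data["time_months"], dtype=float)
    if np.any(time <= 0):
        raise ValueError("loglik_censored requires all times > 0")
    event = np.asarray(data["event"], dtype=int)
    trt = np.asarray(data["treatment"], dtype=object)
    loc = np.fromiter(
        (params.location(t) for t in trt), dtype=float, count=len(trt)
    )
    terms = loglik_terms(params.family, time, event, loc, params.ancillary)
    if np.any(np.isnan(terms)):
        idx = int(np.flatnonzero(np.isnan(terms))[0])
        raise FloatingPointError(
            f"non-finite log-likelihood at record index {idx} "
            f"(time={time[idx]}, event={event[idx]}, treatment={trt[idx]})"
        )
    return float(terms.sum())
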