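import numpy as np
import pandas as pd
import pytest

from survpool.families import ParamVector
from survpool.fit import FitResult, McmcConfig


@pytest.fixture
def lognormal_params() -> ParamVector:
    return ParamVector("lognormal", beta0=2.6, beta={"combo": 0.4}, ancillary=0.9)


def make_fixed_fit(
    family: str = "lognormal",
    beta0: float = 2.5,
    delta: float = 0.3,
    log_anc: float | None = np.log(0.8),
    n_draws: int = 200,
    jitter: float = 0.0,
    seed: int = 0,
    treatment: str = "combo",
    max_time: float = 30.0,
) -> FitResult:
    """A FitResult built from known draws, bypassing MCMC.

    With ``jitter`` = 0 every draw is identical (a degenerate posterior);
    otherwise draws are normal around the given values.
    """
    rng = np.random.default_rng(seed)
    ndim = 3 if log_anc is not None else 2
    center = [beta0, delta] + ([log_anc] if log_anc is not None else [])
    flat = np.asarray(center) + jitter * rng.standard_normal((n_draws, ndim))
    chains = flat.reshape(2, n_draws // 2, ndim)
    names = ["beta0", f"beta[{treatment}]"] + (
        ["log_ancillary"] if log_anc is not None else []
    )
    return FitResult(
        family=family,
        endpoint="OS",
        reference="sorafenib",
        treatments=(treatment,),
        param_names=tuple(names),
        draws=chains,
        dic=0.0,
        p_d=0.0,
        rhat={n: 1.0 for n in names},
        config=McmcConfig(chains=2, iterations=n_draws, warmup=n_draws // 2),
        max_time=max_time,
        mean_acceptance=1.0,
    )


def ipd_frame(times, events, treatment="arm", trial_id="t1") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_months": np.asarray(times, dtype=float),
            "event": np.asarray(events, dtype=int),
            "treatment": treatment,
            "trial_id": trial_id,
        }
    )
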