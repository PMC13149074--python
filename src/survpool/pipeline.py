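"""End-to-end orchestration: read network inputs, reconstruct, fit, select,
derive effects, rank, plot, and run sensitivity analyses.

Input layout: one directory per endpoint (``<input>/<endpoint>/``) holding
``curves.csv`` (trial_id, arm_id, time_months, survival), ``risk.csv``
(trial_id, arm_id, time_months, n_risk) and ``arms.csv`` (trial_id, arm_id,
treatment, n_randomized, total_events; blank total allowed).  If no
endpoint subdirectory exists the files are read from the input directory
itself for every requested endpoint.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .effects import extrapolate_curves, rank_treatments, survival_at_times
from .families import FAMILIES
from .fit import FitResult, McmcConfig, SelectionResult, sample_posterior, select_model
from .km import DigitizedCurve, RiskTable
from .reconstruct import PooledData, ReconstructedIPD, pool_network, reconstruct_arm

__all__ = [
    "AnalysisConfig",
    "SchemaError",
    "DisconnectedNetworkError",
    "EndpointResult",
    "PipelineResult",
    "load_inputs",
    "run_pipeline",
    "sensitivity_suite",
]


class SchemaError(ValueError):
    """An input file violates the expected schema (exit code 2 in the CLI)."""


class DisconnectedNetworkError(ValueError):
    """A treatment has no path to the reference through any trial."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything one analysis run needs besides the input CSVs."""

    endpoints: tuple[str, ...] = ("OS", "PFS")
    reference: str = "sorafenib"
    families: tuple[str, ...] = FAMILIES
    time_points: tuple[float, ...] = (12.0, 24.0, 36.0, 60.0)
    horizon: float = 60.0
    hr_step: float = 0.1
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    seed: int = 0
    fidelity_threshold: float = 0.03
    relabel: Mapping[str, str] = field(default_factory=dict)
    # None means "every fitted family other than the selected one"
    sensitivity_families: tuple[str, ...] | None = None
    make_plots: bool = True

    def __post_init__(self) -> None:
        if not self.reference:
            raise ValueError("reference treatment must be non-empty")
        tp = tuple(float(t) for t in self.time_points)
        if any(t <= 0 for t in tp) or list(tp) != sorted(tp):
            raise ValueError("time points must be positive and sorted")
        for f in self.families:
            if f not in FAMILIES:
                raise ValueError(f"unknown family {f!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "AnalysisConfig":
        raw = dict(raw)
        mcmc = raw.pop("mcmc", None)
        kwargs = {}
        for key in (
            "endpoints",
            "families",
            "time_points",
            "sensitivity_families",
        ):
            if key in raw:
                kwargs[key] = tuple(raw.pop(key))
        for key in (
            "reference",
            "horizon",
            "hr_step",
            "seed",
            "fidelity_threshold",
            "relabel",
            "make_plots",
        ):
            if key in raw:
                kwargs[key] = raw.pop(key)
        if raw:
            raise SchemaError(f"unknown config keys: {sorted(raw)}")
        if mcmc is not None:
            kwargs["mcmc"] = McmcConfig(**mcmc)
        return cls(**kwargs)


_SCHEMAS = {
    "curves.csv": ["trial_id", "arm_id", "time_months", "survival"],
    "risk.csv": ["trial_id", "arm_id", "time_months", "n_risk"],
    "arms.csv": ["trial_id", "arm_id", "treatment", "n_randomized"],
}


def _read_csv(path: Path, name: str) -> pd.DataFrame:
    if not path.exists():
        raise SchemaError(f"missing input file: {path}")
    df = pd.read_csv(path)
    for col in _SCHEMAS[name]:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    numeric = {
        "curves.csv": ["time_months", "survival"],
        "risk.csv": ["time_months", "n_risk"],
        "arms.csv": ["n_randomized"],
    }[name]
    for col in numeric:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(df.index[bad][0])
            raise SchemaError(f"{path}: non-numeric value in column {col!r}, row {row}")
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0])
            raise SchemaError(f"{path}: missing value in column {col!r}, row {row}")
    return df


def load_inputs(
    input_dir: str | Path, endpoint: str
) -> tuple[list[tuple[DigitizedCurve, RiskTable, str]], pd.DataFrame]:
    """Read and schema-check one endpoint's curves, risk tables and arms.

    Returns per-arm (curve, risk table, treatment label) triples plus the
    arms metadata table.
    """
    input_dir = Path(input_dir)
    base = input_dir / endpoint if (input_dir / endpoint).is_dir() else input_dir
    curves_df = _read_csv(base / "curves.csv", "curves.csv")
    risk_df = _read_csv(base / "risk.csv", "risk.csv")
    arms_df = _read_csv(base / "arms.csv", "arms.csv")
    if "total_events" not in arms_df.columns:
        arms_df["total_events"] = np.nan
    out = []
    for _, arm in arms_df.iterrows():
        key = (arm["trial_id"], arm["arm_id"])
        cpts = curves_df[
            (curves_df["trial_id"] == key[0]) & (curves_df["arm_id"] == key[1])
        ].sort_values("time_months")
        rpts = risk_df[
            (risk_df["trial_id"] == key[0]) & (risk_df["arm_id"] == key[1])
        ].sort_values("time_months")
        if len(cpts) == 0:
            raise SchemaError(f"{base/'curves.csv'}: no points for arm {key}")
        if len(rpts) == 0:
            raise SchemaError(f"{base/'risk.csv'}: no entries for arm {key}")
        total = arm["total_events"]
        total = None if pd.isna(total) else int(total)
        curve = DigitizedCurve(
            trial_id=str(key[0]),
            arm_id=str(key[1]),
            times=cpts["time_months"].to_numpy(dtype=float),
            survival=np.minimum.accumulate(
                np.clip(cpts["survival"].to_numpy(dtype=float), 0, 1)
            ),
        )
        risk = RiskTable(
            trial_id=str(key[0]),
            arm_id=str(key[1]),
            times=rpts["time_months"].to_numpy(dtype=float),
            n_risk=rpts["n_risk"].to_numpy(dtype=int),
            total_events=total,
        )
        out.append((curve, risk, str(arm["treatment"])))
    return out, arms_df


def check_connectivity(arms_df: pd.DataFrame, reference: str) -> None:
    """Every treatment label must reach the reference through shared trials."""
    g = nx.Graph()
    for _, trial in arms_df.groupby("trial_id"):
        labels = list(trial["treatment"])
        g.add_nodes_from(labels)
        for a, b in zip(labels, labels[1:]):
            g.add_edge(a, b)
    if reference not in g:
        raise DisconnectedNetworkError(
            f"reference treatment {reference!r} appears in no trial"
        )
    reachable = nx.node_connected_component(g, reference)
    orphans = sorted(set(g.nodes) - reachable)
    if orphans:
        trials = sorted(
            arms_df[arms_df["treatment"].isin(orphans)]["trial_id"].unique()
        )
        raise DisconnectedNetworkError(
            f"treatments {orphans} have no path to {reference!r}; "
            f"offending trials: {trials}"
        )


@dataclass
class EndpointResult:
    """All artifacts of one endpoint's analysis."""

    endpoint: str
    pooled: PooledData
    reconstructions: list[ReconstructedIPD]
    fits: dict[str, FitResult]
    selection: SelectionResult
    surface: object
    predictions: pd.DataFrame
    rankings: pd.DataFrame


@dataclass
class PipelineResult:
    config: AnalysisConfig
    endpoints: dict[str, EndpointResult]
    out_dir: Path | None


def _reconstruct_endpoint(
    triples, config: AnalysisConfig
) -> tuple[PooledData, list[ReconstructedIPD]]:
    recons = []
    labelled = []
    for curve, risk, treatment in triples:
        treatment = config.relabel.get(treatment, treatment)
        recon = reconstruct_arm(
            curve, risk, fidelity_threshold=config.fidelity_threshold
        )
        recons.append(recon)
        labelled.append((recon, treatment))
    pooled = pool_network(labelled, reference=config.reference)
    return pooled, recons


def analyze_endpoint(
    triples,
    endpoint: str,
    config: AnalysisConfig,
) -> EndpointResult:
    """Reconstruct, fit every requested family, select by DIC, derive effects."""
    pooled, recons = _reconstruct_endpoint(triples, config)
    fits = {}
    for k, family in enumerate(config.families):
        fam_seed = int(
            np.random.SeedSequence(
                entropy=config.seed, spawn_key=(FAMILIES.index(family),)
            ).generate_state(1)[0]
            % 2**31
        )
        mc = replace(config.mcmc, seed=fam_seed)
        fits[family] = sample_posterior(pooled, family, mc, endpoint=endpoint)
    if len(fits) == 1:
        only = next(iter(fits.values()))
        selection = SelectionResult(
            family=only.family,
            table=pd.DataFrame(
                {
                    "endpoint": [only.endpoint],
                    "family": [only.family],
                    "dic": [only.dic],
                    "p_d": [only.p_d],
                    "selected": [True],
                }
            ),
            tie=False,
        )
    else:
        selection = select_model(list(fits.values()))
    best = fits[selection.family]
    surface = extrapolate_curves(best, horizon=config.horizon, step=config.hr_step)
    predictions = survival_at_times(best, times=config.time_points)
    rankings = _ranking_frame(predictions, config.time_points, endpoint)
    return EndpointResult(
        endpoint=endpoint,
        pooled=pooled,
        reconstructions=recons,
        fits=fits,
        selection=selection,
        surface=surface,
        predictions=predictions,
        rankings=rankings,
    )


def _ranking_frame(predictions, time_points, endpoint) -> pd.DataFrame:
    frames = []
    for tp in time_points:
        rk = rank_treatments(predictions, tp).table.copy()
        rk.insert(0, "time_months", tp)
        rk.insert(0, "endpoint", endpoint)
        frames.append(rk)
    return pd.concat(frames, ignore_index=True)


def run_pipeline(
    config: AnalysisConfig,
    input_dir: str | Path,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Full analysis: per endpoint, reconstruct -> fit all families -> select
    by DIC -> effect surfaces, predictions, rankings, plots, run log."""
    results: dict[str, EndpointResult] = {}
    out_path = Path(out_dir) if out_dir is not None else None
    for endpoint in config.endpoints:
        triples, arms_df = load_inputs(input_dir, endpoint)
        arms_df = arms_df.assign(
            treatment=arms_df["treatment"].map(lambda t: config.relabel.get(t, t))
        )
        check_connectivity(arms_df, config.reference)
        res = analyze_endpoint(triples, endpoint, config)
        results[endpoint] = res
        if out_path is not None:
            _write_endpoint(res, out_path / endpoint, config)
    bundle = PipelineResult(config=config, endpoints=results, out_dir=out_path)
    if out_path is not None:
        _write_run_log(bundle, out_path)
    return bundle


def _write_endpoint(res: EndpointResult, ep_dir: Path, config: AnalysisConfig) -> None:
    ep_dir.mkdir(parents=True, exist_ok=True)
    ipd = res.pooled.data[
        ["trial_id", "arm_id", "treatment", "time_months", "event"]
    ]
    ipd.to_csv(ep_dir / "ipd.csv", index=False)
    res.selection.table.to_csv(ep_dir / "dic_table.csv", index=False)
    fits_dir = ep_dir / "fits"
    fits_dir.mkdir(exist_ok=True)
    for family, fit in res.fits.items():
        fit.to_json(fits_dir / f"{family}.json")
        fit.draws_frame().to_csv(fits_dir / f"{family}_draws.csv", index=False)
    preds = res.predictions.copy()
    preds.insert(0, "endpoint", res.endpoint)
    preds["extrapolated"] = preds["time_months"] > res.fits[
        res.selection.family
    ].max_time
    preds.to_csv(ep_dir / "predictions.csv", index=False)
    res.rankings.to_csv(ep_dir / "rankings.csv", index=False)
    res.surface.survival.to_csv(ep_dir / "survival_surface.csv", index=False)
    res.surface.hazard_ratio.to_csv(ep_dir / "hr_surface.csv", index=False)
    fidelity = pd.DataFrame(
        [
            {"trial_id": r.trial_id, "arm_id": r.arm_id, **{
                k: v for k, v in r.provenance.items()
            }}
            for r in res.reconstructions
        ]
    )
    fidelity.to_csv(ep_dir / "fidelity.csv", index=False)
    if config.make_plots:
        from . import plots

        plots.plot_survival_surface(res.surface, ep_dir / "survival_curves.png")
        plots.plot_hr_surface(res.surface, ep_dir / "hr_curves.png")
        plots.plot_rankings(res.rankings, ep_dir / "rankings.png")


def _write_run_log(bundle: PipelineResult, out_path: Path) -> None:
    cfg = bundle.config
    log = {
        "survpool_version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "reference": cfg.reference,
        "families": list(cfg.families),
        "endpoints": list(cfg.endpoints),
        "mcmc": {
            "chains": cfg.mcmc.chains,
            "iterations": cfg.mcmc.iterations,
            "warmup": cfg.mcmc.warmup,
        },
        "prior": dict(
            next(iter(bundle.endpoints.values())).fits[
                next(iter(cfg.families))
            ].prior
        )
        if bundle.endpoints
        else {},
        "selected_family": {
            ep: res.selection.family for ep, res in bundle.endpoints.items()
        },
        "fidelity_summary": {
            ep: {
                "max_abs_deviation": max(
                    r.provenance["max_abs_deviation"] for r in res.reconstructions
                ),
                "arms_exceeding_threshold": sum(
                    r.provenance["exceeds_threshold"] for r in res.reconstructions
                ),
            }
            for ep, res in bundle.endpoints.items()
        },
    }
    (out_path / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))


def sensitivity_suite(
    config: AnalysisConfig,
    input_dir: str | Path,
    main: PipelineResult,
    out_dir: str | Path | None = None,
    relabel_input_dir: str | Path | None = None,
) -> pd.DataFrame:
    """The two sensitivity analyses.

    (a) For each alternative family (already fitted in the main run), derive
    rankings at every fixed time point and report the Spearman rank
    correlation with the selected family's ranking.  (b) If a relabel map is
    configured, rebuild the network with the relabelled control arm (reading
    from ``relabel_input_dir`` when the extended network lives in a separate
    directory) and report the same comparison against the main run.  Empty
    alternatives and no relabel map give an empty report.
    """
    rows = []
    alternatives = (
        config.sensitivity_families
        if config.sensitivity_families is not None
        else config.families
    )
    for endpoint, res in main.endpoints.items():
        base_rank = res.rankings
        for family in alternatives:
            if family == res.selection.family or family not in res.fits:
                continue
            alt_pred = survival_at_times(res.fits[family], times=config.time_points)
            for tp in config.time_points:
                alt = rank_treatments(alt_pred, tp).table
                base = base_rank[np.isclose(base_rank["time_months"], tp)]
                rho = _rank_correlation(base, alt)
                rows.append(
                    {
                        "endpoint": endpoint,
                        "analysis": "alternative_family",
                        "detail": family,
                        "time_months": tp,
                        "rank_correlation": rho,
                    }
                )
    if config.relabel:
        relabel_cfg = replace(config, relabel=dict(config.relabel))
        alt_run = run_pipeline(
            relabel_cfg,
            relabel_input_dir if relabel_input_dir is not None else input_dir,
            None if out_dir is None else Path(out_dir) / "relabelled",
        )
        for endpoint, res in alt_run.endpoints.items():
            if endpoint not in main.endpoints:
                continue
            base_rank = main.endpoints[endpoint].rankings
            for tp in config.time_points:
                base = base_rank[np.isclose(base_rank["time_months"], tp)]
                alt = res.rankings[np.isclose(res.rankings["time_months"], tp)]
                rho = _rank_correlation(base, alt)
                rows.append(
                    {
                        "endpoint": endpoint,
                        "analysis": "control_relabel",
                        "detail": ";".join(
                            f"{k}->{v}" for k, v in config.relabel.items()
                        ),
                        "time_months": tp,
                        "rank_correlation": rho,
                    }
                )
    report = pd.DataFrame(
        rows, columns=["endpoint", "analysis", "detail", "time_months", "rank_correlation"]
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "sensitivity_report.csv", index=False)
    return report


def _rank_correlation(base: pd.DataFrame, alt: pd.DataFrame) -> float:
    """Spearman correlation of two rankings over their shared treatments."""
    merged = base.merge(alt, on="treatment", suffixes=("_base", "_alt"))
    if len(merged) < 2:
        return np.nan
    rho = stats.spearmanr(merged["rank_base"], merged["rank_alt"]).statistic
    return float(rho)
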