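"""End-to-end orchestration: curves in, comparison result and artifacts out.

The full analysis chain is

    read -> monotone repair -> common-grid interpolation -> IDA prediction
    -> IPD reconstruction (observed and predicted cohorts)
    -> log-rank + Cox -> additivity classification

:func:`analyze_curves` runs that chain on in-memory objects and is the
workhorse behind :func:`run_analysis` (config + files), the simulation
helpers, and the CLI.  Every silent repair the pipeline makes -- monotone
fixes, product clamps, grid truncation, the borrowed risk table for the
predicted cohort, at-risk mismatches accepted during reconstruction -- is
surfaced in the returned metadata and in the results JSON.

The predicted cohort has no published risk table, so it borrows the
comparator doublet arm's risk-table times with counts rescaled by
S_pred(T)/S_A(T) and the comparator's sample size at t=0 (the
least-assumption choice; prominently flagged in the output).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import km_io
from .km_io import (
    KMCoordinates,
    KMCurve,
    RiskTable,
    common_t_max,
    enforce_monotone,
    interpolate_to_grid,
    read_km_csv,
    read_risk_table_csv,
    write_km_csv,
)
from .ida_model import IDAPrediction, predict_independent_action
from .ipd_reconstruct import IPDDataset, km_estimate, reconstruct_ipd, step_survival
from .survival_stats import ComparisonResult, cox_fit
from .synthetic_data import (
    ARM_COMBINATION,
    ARM_CONTROL,
    ARM_DOUBLET_A,
    ARM_DOUBLET_B,
    SimulationScenario,
    digitize_like,
    simulate_trials,
)

__all__ = [
    "AnalysisConfig",
    "AnalysisOutput",
    "ConfigError",
    "analyze_curves",
    "predicted_cohort_risk_table",
    "run_analysis",
    "run_simulated_analysis",
    "run_simulation_study",
    "plot_observed_vs_predicted",
]

OBSERVED = "observed"
PREDICTED = "predicted"


class ConfigError(ValueError):
    """Invalid analysis configuration; the message names the field."""


@dataclass
class AnalysisConfig:
    """File-based configuration of one observed-vs-predicted analysis.

    ``curve_*`` paths point at digitized-coordinate CSVs; risk tables are
    required for the combination arm (observed cohort) and the comparator
    doublet arm (borrowed by the predicted cohort).
    """

    curve_combination: Path
    curve_doublet_a: Path
    curve_doublet_b: Path
    curve_control: Path
    risk_table_combination: Path
    risk_table_doublet_a: Path
    endpoint: str = "OS"
    grid_step: float = 0.5
    epsilon: float = 0.01
    ties: str = "efron"
    total_events_observed: Optional[int] = None
    output_dir: Path = Path("ida_results")
    seed: int = 0  # used only by the simulation subcommand

    _PATH_FIELDS = (
        "curve_combination",
        "curve_doublet_a",
        "curve_doublet_b",
        "curve_control",
        "risk_table_combination",
        "risk_table_doublet_a",
    )

    def __post_init__(self):
        for name in self._PATH_FIELDS + ("output_dir",):
            setattr(self, name, Path(getattr(self, name)))
        self.validate()

    def validate(self) -> None:
        for name in self._PATH_FIELDS:
            p = getattr(self, name)
            if not p.exists():
                raise ConfigError(f"{name}: file not found: {p}")
        if self.grid_step <= 0:
            raise ConfigError("grid_step: must be > 0")
        if not 0 < self.epsilon < 0.5:
            raise ConfigError("epsilon: must lie in (0, 0.5)")
        if self.ties not in ("efron", "breslow"):
            raise ConfigError("ties: must be 'efron' or 'breslow'")

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "AnalysisConfig":
        """Load from YAML or JSON keyed by the field names."""
        path = Path(path)
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path}: expected a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"config {path}: unknown fields {sorted(unknown)}")
        base = path.parent
        for name in cls._PATH_FIELDS + ("output_dir",):
            if name in raw and not Path(raw[name]).is_absolute():
                raw[name] = base / raw[name]
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"config {path}: {exc}") from exc


@dataclass
class AnalysisOutput:
    """Everything one analysis produces, plus the repair metadata."""

    result: ComparisonResult
    prediction: IDAPrediction
    observed_curve: KMCurve
    predicted_curve: KMCurve
    ipd: IPDDataset
    metadata: Dict[str, object] = field(default_factory=dict)


def predicted_cohort_risk_table(
    predicted_curve: KMCurve,
    comparator_curve: KMCurve,
    comparator_risk_table: RiskTable,
) -> RiskTable:
    """Risk table for the predicted cohort, borrowed from the comparator arm.

    Times are the comparator's published risk times (within the predicted
    curve's extent); counts are the comparator's counts rescaled by
    S_pred(T)/S_A(T), rounded, and forced non-increasing.  The t=0 count is
    the comparator's sample size.
    """
    rt = comparator_risk_table.truncate(predicted_curve.t_max)
    s_pred = predicted_curve.survival_at(rt.times)
    s_comp = np.maximum(comparator_curve.survival_at(rt.times), 1e-12)
    scaled = np.rint(rt.counts * s_pred / s_comp).astype(int)
    scaled[0] = rt.n0
    scaled = np.minimum.accumulate(np.clip(scaled, 0, rt.n0))
    return RiskTable(rt.times, scaled)


def analyze_curves(
    coords_combination: KMCoordinates,
    coords_doublet_a: KMCoordinates,
    coords_doublet_b: KMCoordinates,
    coords_control: KMCoordinates,
    risk_table_combination: RiskTable,
    risk_table_doublet_a: RiskTable,
    grid_step: float = 0.5,
    epsilon: float = 0.01,
    ties: str = "efron",
    total_events_observed: Optional[int] = None,
) -> AnalysisOutput:
    """Run the full observed-vs-predicted chain on in-memory inputs."""
    raw = {
        OBSERVED: coords_combination,
        "doublet_A": coords_doublet_a,
        "doublet_B": coords_doublet_b,
        "control": coords_control,
    }
    mono = {k: enforce_monotone(c) for k, c in raw.items()}
    monotone_fixes = {
        k: int(np.sum(np.abs(mono[k].survival - raw[k].survival) > 1e-12))
        for k in raw
    }
    t_max = common_t_max(*mono.values())
    curves = {k: interpolate_to_grid(c, grid_step, t_max) for k, c in mono.items()}

    prediction = predict_independent_action(
        curves["doublet_A"], curves["doublet_B"], curves["control"], epsilon=epsilon
    )
    predicted_curve = prediction.as_curve(PREDICTED)
    # both cohorts are compared over the prediction's retained extent
    observed_curve = curves[OBSERVED].truncated(prediction.truncation_time)
    observed_curve = dataclasses.replace(observed_curve, arm_label=OBSERVED)

    rt_obs = risk_table_combination.truncate(prediction.truncation_time)
    rt_pred = predicted_cohort_risk_table(
        predicted_curve, curves["doublet_A"], risk_table_doublet_a
    )

    ipd_obs = reconstruct_ipd(
        observed_curve, rt_obs, total_events=total_events_observed, arm_label=OBSERVED
    )
    ipd_pred = reconstruct_ipd(predicted_curve, rt_pred, arm_label=PREDICTED)
    ipd = IPDDataset.concat(ipd_obs, ipd_pred)

    result = cox_fit(ipd, OBSERVED, PREDICTED, ties=ties)
    metadata = {
        "grid_step": grid_step,
        "epsilon": epsilon,
        "ties": ties,
        "common_t_max": t_max,
        "truncation_time": prediction.truncation_time,
        "clamp_count": prediction.clamp_count,
        "monotone_fixes": monotone_fixes,
        "predicted_risk_table": {
            "borrowed_from": curves["doublet_A"].arm_label or "doublet_A",
            "times": rt_pred.times.tolist(),
            "counts": rt_pred.counts.tolist(),
        },
        "reconstruction_diagnostics": ipd.diagnostics,
    }
    return AnalysisOutput(
        result=result,
        prediction=prediction,
        observed_curve=observed_curve,
        predicted_curve=predicted_curve,
        ipd=ipd,
        metadata=metadata,
    )


def run_analysis(config: AnalysisConfig, make_plot: bool = True) -> AnalysisOutput:
    """File-based analysis: read the four curves, run the chain, write artifacts.

    Writes to ``config.output_dir``: ``results.json`` (ComparisonResult plus
    metadata), ``ipd_observed.csv`` / ``ipd_predicted.csv``,
    ``predicted_curve.csv`` and ``km_observed_vs_predicted.png``.
    """
    config.validate()
    out = analyze_curves(
        read_km_csv(config.curve_combination, arm_label=OBSERVED),
        read_km_csv(config.curve_doublet_a, arm_label="doublet_A"),
        read_km_csv(config.curve_doublet_b, arm_label="doublet_B"),
        read_km_csv(config.curve_control, arm_label="control"),
        read_risk_table_csv(config.risk_table_combination),
        read_risk_table_csv(config.risk_table_doublet_a),
        grid_step=config.grid_step,
        epsilon=config.epsilon,
        ties=config.ties,
        total_events_observed=config.total_events_observed,
    )
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {
        "endpoint": config.endpoint,
        "result": out.result.to_dict(),
        "metadata": out.metadata,
    }
    (outdir / "results.json").write_text(json.dumps(payload, indent=2, default=str))
    IPDDataset(out.ipd.for_arm(OBSERVED)).to_csv(outdir / "ipd_observed.csv")
    IPDDataset(out.ipd.for_arm(PREDICTED)).to_csv(outdir / "ipd_predicted.csv")
    write_km_csv(out.predicted_curve, outdir / "predicted_curve.csv")
    if make_plot:
        plot_observed_vs_predicted(out, outdir / "km_observed_vs_predicted.png",
                                   endpoint=config.endpoint)
    return out


def plot_observed_vs_predicted(
    out: AnalysisOutput, path: Union[str, Path], endpoint: str = "OS"
) -> None:
    """KM plot of the two reconstructed cohorts with the HR/CI annotation."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for arm, color in ((OBSERVED, "black"), (PREDICTED, "tab:red")):
        km = km_estimate(out.ipd, arm)
        ax.step(km.times, km.survival, where="post", color=color, label=arm)
    r = out.result
    ax.set_xlabel("Time (months)")
    ax.set_ylabel(f"{endpoint} probability")
    ax.set_ylim(0, 1.02)
    ax.annotate(
        f"HR {r.hr:.3f} (95% CI {r.ci_low:.3f}-{r.ci_high:.3f})\n"
        f"Cox P = {r.p_cox:.3g}, log-rank P = {r.p_logrank:.3g}",
        xy=(0.02, 0.08), xycoords="axes fraction", fontsize=9,
    )
    ax.legend(loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Simulation-driven analyses

def run_simulated_analysis(
    scenario: SimulationScenario,
    jitter_sd: float = 0.0,
    ties: str = "efron",
    epsilon: float = 0.01,
    grid_step: float = 0.5,
) -> AnalysisOutput:
    """Simulate one two-trial dataset, digitize it, and run the full chain.

    The observed-vs-predicted hazard ratio estimates the scenario's synergy
    multiplier psi.
    """
    arms = simulate_trials(scenario)
    # independent digitization stream, distinct from the arm streams
    dig_rng = np.random.default_rng(np.random.SeedSequence((scenario.seed, 1)))
    coords: Dict[str, KMCoordinates] = {}
    tables: Dict[str, RiskTable] = {}
    for label, ipd in arms.items():
        coords[label], tables[label] = digitize_like(
            ipd,
            n_coordinates=scenario.n_coordinates,
            risk_table_step=scenario.risk_table_step,
            jitter_sd=jitter_sd,
            rng=dig_rng,
        )
    out = analyze_curves(
        coords[ARM_COMBINATION],
        coords[ARM_DOUBLET_A],
        coords[ARM_DOUBLET_B],
        coords[ARM_CONTROL],
        tables[ARM_COMBINATION],
        tables[ARM_DOUBLET_A],
        grid_step=grid_step,
        epsilon=epsilon,
        ties=ties,
    )
    out.metadata["scenario"] = dataclasses.asdict(scenario)
    return out


def run_simulation_study(
    psis: Sequence[float],
    replicates: int,
    seed: int,
    base_scenario: Optional[SimulationScenario] = None,
    jitter_sd: float = 0.0,
) -> pd.DataFrame:
    """Operating characteristics over a grid of synergy multipliers.

    Runs ``replicates`` independent full-pipeline analyses per psi and
    returns one row per psi: mean and SD of the estimated HR and the rate of
    each classification.  Deterministic given ``seed``; scenarios that fail
    (e.g. a degenerate replicate) are counted per cell, not fatal.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    base = base_scenario or SimulationScenario()
    rows = []
    for psi in psis:
        child_seeds = [int(s) for s in
                       np.random.SeedSequence((seed, int(round(psi * 1000)))).generate_state(replicates) % (2 ** 31)]
        hrs: List[float] = []
        classes: List[str] = []
        failures = 0
        for rep_seed in child_seeds:
            scenario = dataclasses.replace(base, psi=float(psi), seed=rep_seed)
            try:
                out = run_simulated_analysis(scenario, jitter_sd=jitter_sd)
            except Exception:
                failures += 1
                continue
            hrs.append(out.result.hr)
            classes.append(out.result.classification)
        n_ok = len(hrs)
        rows.append(
            {
                "psi": float(psi),
                "replicates": replicates,
                "completed": n_ok,
                "failures": failures,
                "mean_hr": float(np.mean(hrs)) if n_ok else np.nan,
                "sd_hr": float(np.std(hrs, ddof=1)) if n_ok > 1 else np.nan,
                "rate_greater_than_additive": classes.count("greater_than_additive") / n_ok if n_ok else np.nan,
                "rate_consistent_with_additive": classes.count("consistent_with_additive") / n_ok if n_ok else np.nan,
                "rate_less_than_additive": classes.count("less_than_additive") / n_ok if n_ok else np.nan,
            }
        )
    return pd.DataFrame(rows)


def write_simulated_dataset(
    scenario: SimulationScenario, outdir: Union[str, Path], jitter_sd: float = 0.0
) -> Dict[str, Path]:
    """Write one simulated, digitized dataset in the pipeline's CSV dialects.

    Produces per-arm curve and risk-table CSVs plus a ground-truth JSON, so
    simulated and real digitized data enter the pipeline identically.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    arms = simulate_trials(scenario)
    dig_rng = np.random.default_rng(np.random.SeedSequence((scenario.seed, 1)))
    paths: Dict[str, Path] = {}
    for label, ipd in arms.items():
        c, rt = digitize_like(
            ipd,
            n_coordinates=scenario.n_coordinates,
            risk_table_step=scenario.risk_table_step,
            jitter_sd=jitter_sd,
            rng=dig_rng,
        )
        curve_path = outdir / f"curve_{label}.csv"
        rt_path = outdir / f"risk_table_{label}.csv"
        write_km_csv(c, curve_path)
        pd.DataFrame({"time_months": rt.times, "n_at_risk": rt.counts}).to_csv(
            rt_path, index=False
        )
        paths[f"curve_{label}"] = curve_path
        paths[f"risk_table_{label}"] = rt_path
    truth = dataclasses.asdict(scenario)
    truth["lambda_combination"] = scenario.lambda_combination
    truth["additive_hazard"] = scenario.additive_hazard
    truth_path = outdir / "ground_truth.json"
    truth_path.write_text(json.dumps(truth, indent=2))
    paths["ground_truth"] = truth_path
    return paths
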