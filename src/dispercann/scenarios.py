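"""The six learning scenarios as reproducible, seeded sweep runs.

1. Sweep the Gaussian noise level on the data at perfect alignment
   (kappa_f = kappa_s = kappa_n = 0).
2. Add 3% noise and sweep fiber dispersion (kappa_s = kappa_n = 0).
3. Add 3% noise and sweep sheet/normal dispersion (kappa_f = 0).
4. Add 3% noise and sweep equal dispersion in all three directions.
5. Add 3% noise and treat kappa_f, kappa_s, kappa_n as trainable.
6. Train the dispersion-free network on data simulated from generator
   models with increasing equal dispersion (model misspecification).

Each scenario yields one discovered model and report per sweep value plus a
summary table in the published-table layout (one column per sweep value).
When no dataset is supplied, the input is simulated from a named catalog
model; scenario 6 always simulates its own (dispersed) training data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import pandas as pd

from .catalog import KAPPA_LEVELS, get_model
from .constitutive import save_model
from .discovery import DiscoveredModel, TrainingConfig, train, discover_kappa
from .dispersion import DispersionParams
from .protocols import (
    Dataset,
    NoiseSpec,
    add_noise,
    format_report,
    report_active_terms,
    simulate_dataset,
    write_dataset,
)

__all__ = ["ScenarioSpec", "run_scenario", "DEFAULT_KAPPA_SWEEP", "DEFAULT_NOISE_SWEEP"]

DEFAULT_NOISE_SWEEP = (0.0, 0.03, 0.05, 0.07, 0.1)
DEFAULT_KAPPA_SWEEP = KAPPA_LEVELS  # "0" ... "1/3"


@dataclass(frozen=True)
class ScenarioSpec:
    """Configuration of one learning scenario run."""

    scenario: int
    sweep: tuple = ()
    config: TrainingConfig = field(default_factory=TrainingConfig)
    noise_k: float = 0.03  # noise level for scenarios 2-5
    generator: tuple[str, str] = ("equal", "0")  # catalog model for simulated input

    def __post_init__(self) -> None:
        if self.scenario not in range(1, 7):
            raise ValueError("scenario id must be 1..6")
        if not self.sweep:
            default = DEFAULT_NOISE_SWEEP if self.scenario == 1 else (
                ("-",) if self.scenario == 5 else DEFAULT_KAPPA_SWEEP
            )
            object.__setattr__(self, "sweep", tuple(default))


def _kappas_for(scenario: int, level: str) -> DispersionParams:
    k = float(Fraction(level))
    if scenario == 2:
        return DispersionParams(k, 0.0, 0.0)
    if scenario == 3:
        return DispersionParams(0.0, k, k)
    return DispersionParams(k, k, k)


def run_scenario(
    spec: ScenarioSpec,
    dataset: Dataset | None = None,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, dict[str, DiscoveredModel]]:
    """Run one learning scenario; returns (summary table, models per sweep value).

    Partial results are kept on error: every completed sweep value is written
    to ``out_dir`` (model JSON, report CSV, simulated dataset CSV) before the
    next one starts.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    base = dataset
    if base is None:
        gen = get_model(*spec.generator)
        base = simulate_dataset(gen.weights, gen.kappas)
    models: dict[str, DiscoveredModel] = {}
    summary_rows = []
    for value in spec.sweep:
        tag = str(value).replace("/", "_").replace(":", "_")
        if spec.scenario == 1:
            k = float(value)
            data = add_noise(base, NoiseSpec(k=k, seed=spec.config.seed))
            model = train(data, spec.config, kappas=DispersionParams())
        elif spec.scenario in (2, 3, 4):
            data = add_noise(base, NoiseSpec(k=spec.noise_k, seed=spec.config.seed))
            model = train(data, spec.config, kappas=_kappas_for(spec.scenario, str(value)))
        elif spec.scenario == 5:
            data = add_noise(base, NoiseSpec(k=spec.noise_k, seed=spec.config.seed))
            model = discover_kappa(data, spec.config)
        else:  # scenario 6: misspecification on simulated dispersed data
            gen = get_model(spec.generator[0], str(value))
            data = simulate_dataset(gen.weights, gen.kappas)
            model = train(data, spec.config, kappas=DispersionParams())
        models[str(value)] = model
        report = report_active_terms(model.weights, model.kappas, r2_mean=model.r2_mean)
        for _, row in report.iterrows():
            summary_rows.append(
                {
                    "sweep_value": str(value),
                    "node": row["node"],
                    "term": row["term"],
                    "invariant": row["invariant"],
                    "magnitude_kPa": row["magnitude_kPa"],
                }
            )
        summary_rows.append(
            {"sweep_value": str(value), "node": 0, "term": "R^2", "invariant": "-",
             "magnitude_kPa": model.r2_mean}
        )
        if out is not None:
            save_model(
                out / f"model_{tag}.json",
                model.weights,
                model.kappas,
                metadata={
                    "scenario": spec.scenario,
                    "sweep_value": str(value),
                    "r2_mean": model.r2_mean,
                    "loss": model.loss,
                    "epochs_run": model.epochs_run,
                    "seed": spec.config.seed,
                },
            )
            report.to_csv(out / f"report_{tag}.csv", index=False)
            write_dataset(data, out / f"dataset_{tag}.csv")
            (out / f"report_{tag}.txt").write_text(format_report(report))
    long = pd.DataFrame(summary_rows)
    summary = long.pivot_table(
        index=["node", "term", "invariant"], columns="sweep_value",
        values="magnitude_kPa", sort=False,
    ).reset_index()
    if out is not None:
        summary.to_csv(out / "summary.csv", index=False)
    return summary, models
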