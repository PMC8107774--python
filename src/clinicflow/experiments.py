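"""Volume x staffing experiment grid over the clinic simulation.

Runs the simulation for patient volumes of 10, 20, 25, 30 and 40 patients
per provider under two staffing models — one provider with two technicians
and two providers with three shared technicians, each with four rooms per
provider — aggregates replication-level outcomes, and compares the two
models per volume with Welch t-tests on replication means (the unit of
analysis behind the reported mean ± SD values).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .analysis import SimParams, compare_means
from .des import ClinicConfig, run_replication

__all__ = [
    "StaffingModel",
    "DEFAULT_STAFFING_MODELS",
    "DEFAULT_VOLUMES",
    "ExperimentResult",
    "run_experiment",
    "report_tables",
]

DEFAULT_VOLUMES = (10, 20, 25, 30, 40)

#: replication-level metrics aggregated per grid cell
METRICS = ("mean_wait_before_room", "mean_total_time", "clinic_day_length",
           "time_at_capacity", "max_outside_queue", "max_outside_queue_pct")


@dataclass(frozen=True)
class StaffingModel:
    name: str
    n_providers: int
    n_techs: int


DEFAULT_STAFFING_MODELS = (
    StaffingModel("1-provider", n_providers=1, n_techs=2),
    StaffingModel("2-provider", n_providers=2, n_techs=3),
)


@dataclass
class ExperimentResult:
    """Replication-level outcomes for every (volume, staffing model) cell."""

    replications: pd.DataFrame  # one row per replication
    volumes: tuple[int, ...]
    models: tuple[StaffingModel, ...]
    n_replications: int
    master_seed: int
    params: SimParams = field(repr=False, default_factory=SimParams)

    def cell(self, volume: int, model: str) -> pd.DataFrame:
        frame = self.replications
        return frame[(frame["volume"] == volume) & (frame["model"] == model)]

    def cell_mean(self, volume: int, model: str, metric: str) -> float:
        return float(self.cell(volume, model)[metric].mean())

    def cell_sd(self, volume: int, model: str, metric: str) -> float:
        return float(self.cell(volume, model)[metric].std(ddof=1))

    def summary_frame(self) -> pd.DataFrame:
        """Cross-replication mean and SD of each metric per grid cell."""
        grouped = self.replications.groupby(["volume", "model"], sort=True)
        means = grouped[list(METRICS)].mean().add_suffix("_mean")
        sds = grouped[list(METRICS)].std(ddof=1).add_suffix("_sd")
        return pd.concat([means, sds], axis=1).reset_index()

    def between_model_tests(self) -> pd.DataFrame:
        """Welch t-test between the two staffing models at each volume."""
        if len(self.models) != 2:
            raise ValueError("between-model tests need exactly two staffing models")
        a, b = (m.name for m in self.models)
        rows = []
        for volume in self.volumes:
            for metric in METRICS:
                try:
                    t, p = compare_means(
                        self.cell(volume, a)[metric], self.cell(volume, b)[metric]
                    )
                except ValueError:  # degenerate zero-variance cells
                    t, p = float("nan"), float("nan")
                rows.append(dict(volume=volume, metric=metric, t=t, p=p))
        return pd.DataFrame(rows)


def _cell_config(model: StaffingModel, volume: int, **config_kwargs) -> ClinicConfig:
    return ClinicConfig(
        n_providers=model.n_providers,
        n_techs=model.n_techs,
        volume_per_provider=volume,
        **config_kwargs,
    )


def run_experiment(
    volumes=DEFAULT_VOLUMES,
    staffing_models=DEFAULT_STAFFING_MODELS,
    params: SimParams | None = None,
    n_reps: int = 100,
    master_seed: int = 42,
    **config_kwargs,
) -> ExperimentResult:
    """Run the full volume x staffing grid.

    Per-replication seeds are ``master_seed + cell_index * n_reps + rep``
    with cells enumerated in (volume-major, model-minor) order, so every
    cell draws an independent, reproducible stream.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    params = params or SimParams.covid_defaults()
    volumes = tuple(volumes)
    staffing_models = tuple(staffing_models)

    rows = []
    cell_index = 0
    for volume in volumes:
        for model in staffing_models:
            cfg = _cell_config(model, volume, **config_kwargs)
            for rep in range(n_reps):
                seed = master_seed + cell_index * n_reps + rep
                result = run_replication(cfg, params, seed=seed)
                rows.append(
                    dict(volume=volume, model=model.name, rep=rep, seed=seed,
                         **{m: getattr(result, m) for m in METRICS})
                )
            cell_index += 1
    return ExperimentResult(
        replications=pd.DataFrame(rows),
        volumes=volumes,
        models=staffing_models,
        n_replications=n_reps,
        master_seed=master_seed,
        params=params,
    )


def report_tables(result: ExperimentResult) -> dict[str, pd.DataFrame]:
    """Capacity table and per-volume wait/visit curves for reporting.

    ``table_capacity``: average time at capacity (minutes) and the maximum
    hold-queue length, formatted as "count (pct %)" of scheduled patients,
    per staffing model and volume, with between-model p-values.
    ``fig_wait`` / ``fig_total``: mean ± SD wait-before-room and total time
    in clinic (minutes) per volume and model.  ``day_length``: mean ± SD
    clinic-day length in hours.
    """
    summary = result.summary_frame()
    tests = result.between_model_tests().set_index(["volume", "metric"])
    model_names = [m.name for m in result.models]

    def metric_frame(metric: str) -> pd.DataFrame:
        rows = []
        for volume in result.volumes:
            row: dict = {"volume": volume}
            for name in model_names:
                row[f"{name}_mean"] = result.cell_mean(volume, name, metric)
                row[f"{name}_sd"] = result.cell_sd(volume, name, metric)
            if len(model_names) == 2:
                row["p"] = tests.loc[(volume, metric), "p"]
            rows.append(row)
        return pd.DataFrame(rows)

    capacity_rows = []
    for volume in result.volumes:
        row: dict = {"volume": volume}
        for name in model_names:
            cell = result.cell(volume, name)
            n_scheduled = volume * next(
                m.n_providers for m in result.models if m.name == name
            )
            max_q = cell["max_outside_queue"].mean()
            row[f"{name}_time_at_capacity"] = cell["time_at_capacity"].mean()
            row[f"{name}_max_waiting"] = (
                f"{max_q:.0f} ({100.0 * max_q / n_scheduled:.0f} %)"
            )
        if len(model_names) == 2:
            row["p_time_at_capacity"] = tests.loc[(volume, "time_at_capacity"), "p"]
            row["p_max_waiting"] = tests.loc[(volume, "max_outside_queue"), "p"]
        capacity_rows.append(row)

    return {
        "summary": summary,
        "table_capacity": pd.DataFrame(capacity_rows),
        "fig_wait": metric_frame("mean_wait_before_room"),
        "fig_total": metric_frame("mean_total_time"),
        "day_length": metric_frame("clinic_day_length"),
    }


def plot_experiment(result: ExperimentResult, path=None):
    """Simple line charts of wait-before-room and total visit length."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tables = report_tables(result)
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True)
    for ax, key, label in zip(
        axes, ("fig_wait", "fig_total"),
        ("Wait before rooming (min)", "Total time in clinic (min)"),
    ):
        frame = tables[key]
        for model in result.models:
            ax.errorbar(frame["volume"], frame[f"{model.name}_mean"],
                        yerr=frame[f"{model.name}_sd"], marker="o", label=model.name)
        ax.set_xlabel("patients per provider")
        ax.set_ylabel(label)
    axes[0].legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
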