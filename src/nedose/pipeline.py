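"""End-to-end pipeline: generate/ingest tables -> screen -> fit -> report bundle.

A run produces, under one output directory: the screened cohort CSV, the
exclusion ledger JSON, logistic fits (per dose variable) JSON, the
publication-style threshold tables CSV, per-formulation dose histograms CSV,
and a manifest recording the configuration, seed and package version so the
bundle is reproducible bit-for-bit (timestamps aside).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .formulations import FormulationRegistry, default_formulations
from .model import (
    DoseResponseFit,
    fit_dose_response,
    percent_or_reduction,
    stack_formulations,
    threshold_table,
)
from .screen import ScreenCriteria, ScreenResult, apply_screen
from .simulate import CohortConfig, SyntheticTables, generate_cohort, read_tables, write_tables

__all__ = ["PipelineConfig", "StageFailure", "run_pipeline", "summarize_distributions",
           "plot_dose_response"]

log = logging.getLogger(__name__)

DOSE_COLUMNS = {"diagnosis": "diagnosis_dose", "peak": "peak_dose_24h"}


class StageFailure(RuntimeError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.code = f"E_{stage.upper()}"


@dataclass
class PipelineConfig:
    """Exactly one of ``tables_dir`` (ingest) or ``cohort`` (simulate) is used."""

    tables_dir: str | None = None
    cohort: CohortConfig | None = None
    criteria: ScreenCriteria = dataclasses.field(default_factory=ScreenCriteria)
    outlier_ceiling: float = 5.0
    model_variant: str = "per_formulation"
    histogram_bin_width: float = 0.05

    def __post_init__(self) -> None:
        if (self.tables_dir is None) == (self.cohort is None):
            raise ValueError("supply exactly one of tables_dir or cohort config")


def summarize_distributions(
    cohort: pd.DataFrame,
    dose_column: str = "diagnosis_dose",
    bin_width: float = 0.05,
    registry: FormulationRegistry | None = None,
) -> pd.DataFrame:
    """Binned dose frequencies per reporting convention (histogram table).

    Machine-readable analogue of the published dose histograms: counts per
    ``bin_width``-wide dose bin for the base dose and each salt conversion.
    Total counts per formulation equal the cohort size.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    registry = registry or default_formulations()
    base = cohort[dose_column].to_numpy(float)
    rows = []
    for spec in registry.values():
        d = base * spec.factor
        idx = np.floor(d / bin_width).astype(int)
        for b, count in zip(*np.unique(idx, return_counts=True)):
            rows.append(
                {
                    "formulation": spec.name,
                    "bin_left": b * bin_width,
                    "bin_right": (b + 1) * bin_width,
                    "count": int(count),
                }
            )
    return pd.DataFrame(rows)


def _fit_payload(fit: DoseResponseFit) -> dict:
    base_or = fit.fits["base"].odds_ratio
    out = {"variant": fit.variant, "formulations": {}}
    for name, ff in fit.fits.items():
        lo, hi = ff.odds_ratio_ci()
        out["formulations"][name] = {
            "alpha": ff.alpha,
            "beta": ff.beta,
            "odds_ratio": ff.odds_ratio,
            "odds_ratio_ci95": [lo, hi],
            "percent_or_reduction_vs_base": percent_or_reduction(ff.odds_ratio, base_or),
            "cov": np.asarray(ff.cov).tolist(),
        }
    if fit.random_intercept_sd is not None:
        out["random_intercept_sd"] = fit.random_intercept_sd
    return out


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full analysis and write the report bundle; returns a summary.

    Stages: simulate/ingest -> screen (includes dose extraction) -> stack &
    fit (diagnosis and peak dose) -> threshold tables -> histograms ->
    manifest.  Any stage failure raises :class:`StageFailure` naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        if config.cohort is not None:
            tables: SyntheticTables = generate_cohort(config.cohort)
        else:
            tables = read_tables(config.tables_dir)
    except (OSError, ValueError) as exc:
        raise StageFailure("ingest", str(exc)) from exc

    try:
        result: ScreenResult = apply_screen(tables, config.criteria, config.outlier_ceiling)
    except Exception as exc:
        raise StageFailure("screen", str(exc)) from exc
    for crit, n_exc in result.ledger.items():
        log.info("screen: excluded %d patients at criterion %r", n_exc, crit)
    if result.cohort.empty:
        raise StageFailure("screen", "no patients passed the eligibility screen")

    result.cohort.to_csv(out / "cohort.csv", index=False, date_format="%Y-%m-%dT%H:%M:%S")
    (out / "exclusion_ledger.json").write_text(
        json.dumps({"retained": len(result.cohort), "excluded": result.ledger}, indent=2)
    )

    fits_payload, tables_payload = {}, []
    for label, col in DOSE_COLUMNS.items():
        try:
            design = stack_formulations(result.cohort, col)
            fit = fit_dose_response(design, config.model_variant)
        except Exception as exc:
            raise StageFailure("fit", f"{label} dose: {exc}") from exc
        fits_payload[label] = _fit_payload(fit)
        tt = threshold_table(fit)
        tt.insert(0, "dose_variable", label)
        tables_payload.append(tt)

    (out / "fits.json").write_text(json.dumps(fits_payload, indent=2))
    thresholds = pd.concat(tables_payload, ignore_index=True)
    thresholds.to_csv(out / "threshold_table.csv", index=False)

    hist = pd.concat(
        [
            summarize_distributions(result.cohort, col, config.histogram_bin_width).assign(
                dose_variable=label
            )
            for label, col in DOSE_COLUMNS.items()
        ],
        ignore_index=True,
    )
    hist.to_csv(out / "dose_histograms.csv", index=False)

    cfg_dict = dataclasses.asdict(config)
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
    manifest = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.cohort.seed if config.cohort is not None else None,
        "nedose_version": __version__,
        "n_input": result.n_input,
        "n_cohort": len(result.cohort),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    return {
        "n_input": result.n_input,
        "n_cohort": len(result.cohort),
        "ledger": result.ledger,
        "fits": fits_payload,
        "threshold_table": thresholds,
    }


def plot_dose_response(
    fit: DoseResponseFit,
    path: str | Path,
    dose_max: float = 1.2,
    thresholds=(0.1, 0.25, 1.0),
) -> None:
    """Sigmoid risk curves per reporting convention with threshold guide lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.special import expit

    doses = np.linspace(0, dose_max, 200)
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, ff in fit.fits.items():
        ax.plot(doses, expit(ff.alpha + ff.beta * doses), label=name)
    for thr, color in zip(thresholds, ("green", "orange", "red")):
        ax.axvline(thr, color=color, linestyle="--", linewidth=1)
    ax.set_xlabel("reported norepinephrine dose (ug/kg/min)")
    ax.set_ylabel("predicted 28-day mortality")
    ax.set_ylim(0, 1)
    ax.legend(title="reported as")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
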