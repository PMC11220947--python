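"""Synthetic MIMIC-like septic-shock cohort generator.

The real analysis runs on ICU electronic health records: a patients table, a
vasopressor infusion-event stream, lactate labs, culture/antibiotic events and
SOFA scores.  This module generates the same five tables with the statistical
structure the downstream pipeline assumes, so every stage is testable without
any data download:

* base-molecule peak norepinephrine doses are log-normal with median
  0.24 ug/kg/min and quartiles near 0.12 / 0.42 (the published septic-shock
  distribution); the diagnosis dose is the peak times a Beta-distributed
  fraction calibrated so its median is near 0.1 ug/kg/min;
* 28-day mortality is a Bernoulli draw on ``expit(alpha + beta * peak_dose)``,
  with (alpha, beta) calibrated by default to published mortality at the 0.1
  and 1.0 ug/kg/min cut-offs;
* infusion streams contain an up-titration, a sustained segment realising the
  latent peak, optional sub-5-minute spikes above it, optional registry-error
  outliers, and a second vasopressor in about 57% of patients;
* lactate / SOFA / infection tables are built so a configurable fraction of
  patients passes the Sepsis-3 screen, the rest failing one named criterion.

Latent truths (peak dose, death probability, injected artefacts) are retained
in the patients table so tests can check the extraction pipeline exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

__all__ = [
    "DIAGNOSIS_DOSE_ANCHORS",
    "PEAK_DOSE_ANCHORS",
    "CohortConfig",
    "SyntheticTables",
    "lognormal_from_median_iqr",
    "calibrate_logistic_from_anchors",
    "simulate_dose_mortality",
    "generate_cohort",
    "write_tables",
    "read_tables",
]

# Published 28-day mortality at the 0.1 and 1.0 ug/kg/min base-molecule
# cut-offs, used to calibrate the generative logistic: (dose, mortality).
DIAGNOSIS_DOSE_ANCHORS: tuple[tuple[float, float], ...] = ((0.1, 0.36), (1.0, 0.81))
PEAK_DOSE_ANCHORS: tuple[tuple[float, float], ...] = ((0.1, 0.27), (1.0, 0.83))

_FAIL_MODES = ("lactate", "sofa", "window", "demographics", "dose")


def lognormal_from_median_iqr(median: float, q1: float, q3: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal matching a median and the IQR ratio.

    mu is ln(median); sigma is chosen so the ratio of the fitted quartiles
    equals q3/q1 (the two quartiles themselves are matched exactly only when
    they are log-symmetric about the median).
    """
    if not (0 < q1 < median < q3):
        raise ValueError("need 0 < q1 < median < q3")
    z75 = norm.ppf(0.75)
    return float(np.log(median)), float(np.log(q3 / q1) / (2.0 * z75))


def calibrate_logistic_from_anchors(
    anchors: Sequence[tuple[float, float]],
) -> tuple[float, float]:
    """Solve ``logit(p_i) = alpha + beta * d_i`` through mortality anchors.

    With exactly two anchors the solution is exact; with more, least squares
    on the logit scale.  Returns (alpha, beta).
    """
    anchors = [(float(d), float(p)) for d, p in anchors]
    if len(anchors) < 2:
        raise ValueError("need at least two anchors")
    doses = np.array([d for d, _ in anchors])
    props = np.array([p for _, p in anchors])
    if len(np.unique(doses)) < len(doses):
        raise ValueError(f"anchor doses must be distinct, got {doses.tolist()}")
    if np.any((props <= 0) | (props >= 1)):
        raise ValueError(f"anchor proportions must lie strictly in (0,1), got {props.tolist()}")
    X = np.column_stack([np.ones_like(doses), doses])
    coef, *_ = np.linalg.lstsq(X, logit(props), rcond=None)
    return float(coef[0]), float(coef[1])


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; defaults are the study conditions being emulated."""

    n_patients: int = 4086
    seed: int = 0
    # mortality model on the latent base peak dose (log-odds scale); None
    # means "calibrate from PEAK_DOSE_ANCHORS at construction time"
    alpha: float | None = None
    beta: float | None = None
    # latent base peak-dose distribution: log-normal(median 0.24, IQR 0.12-0.42)
    peak_median: float = 0.24
    peak_q1: float = 0.12
    peak_q3: float = 0.42
    # diagnosis dose = peak * Beta(a, b) fraction; (2.5, 3.4) puts the median
    # fraction near 0.42, so median diagnosis dose ~ 0.1 when peak median 0.24
    diag_frac_beta: tuple[float, float] = (2.5, 3.4)
    spike_rate: float = 0.2  # expected transient (<5 min) spikes per patient
    outlier_rate: float = 0.02  # probability of a registry-error record
    second_pressor_prob: float = 0.57
    screen_pass_fraction: float = 1.0
    outlier_ceiling: float = 5.0  # latent peaks are clipped below this

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("spike_rate", "outlier_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("second_pressor_prob", "screen_pass_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if self.alpha is None or self.beta is None:
            a, b = calibrate_logistic_from_anchors(PEAK_DOSE_ANCHORS)
            object.__setattr__(self, "alpha", self.alpha if self.alpha is not None else a)
            object.__setattr__(self, "beta", self.beta if self.beta is not None else b)

    @property
    def peak_lognormal(self) -> tuple[float, float]:
        return lognormal_from_median_iqr(self.peak_median, self.peak_q1, self.peak_q3)


@dataclass
class SyntheticTables:
    """The five pipeline input tables plus the generation manifest."""

    patients: pd.DataFrame
    infusion_events: pd.DataFrame
    labs: pd.DataFrame
    infection_events: pd.DataFrame
    sofa: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    def as_dict(self) -> dict[str, pd.DataFrame]:
        return {
            "patients": self.patients,
            "infusion_events": self.infusion_events,
            "labs": self.labs,
            "infection_events": self.infection_events,
            "sofa": self.sofa,
        }


def simulate_dose_mortality(
    n: int,
    alpha: float,
    beta: float,
    dose_median: float,
    dose_q1: float,
    dose_q3: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw (dose, death) pairs from the generative logistic dose-response.

    Doses are log-normal (median / IQR parameterisation) and the death
    indicator is Bernoulli(expit(alpha + beta*dose)).  This is the direct
    simulation path used for parameter-recovery checks; :func:`generate_cohort`
    wraps the same model in full event tables.
    """
    mu, sigma = lognormal_from_median_iqr(dose_median, dose_q1, dose_q3)
    dose = rng.lognormal(mu, sigma, size=n)
    p = expit(alpha + beta * dose)
    death = rng.random(n) < p
    return pd.DataFrame({"dose": dose, "p_death": p, "death": death.astype(int)})


_EPOCH = pd.Timestamp("2023-01-01 00:00:00")
_SECOND_PRESSORS = (
    # (drug, native unit, rate draw range) ~ relative use in the cohort
    ("vasopressin", "U/min", (0.02, 0.04), 0.45),
    ("phenylephrine", "ug/kg/min", (0.5, 1.5), 0.32),
    ("epinephrine", "ug/kg/min", (0.05, 0.3), 0.23),
)


def _round_dose(x: np.ndarray | float) -> np.ndarray | float:
    return np.round(x, 4)


def generate_cohort(cfg: CohortConfig) -> SyntheticTables:
    """Generate the five event tables for ``cfg.n_patients`` patients.

    Deterministic given ``cfg.seed``; each table draws from an independently
    spawned substream of the master seed, so adding a table never perturbs the
    others.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_pat, rng_inf, rng_lab, rng_infx, rng_sofa = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    n = cfg.n_patients
    mu, sigma = cfg.peak_lognormal

    # -- latent patient-level draws ------------------------------------------
    age = np.clip(np.round(rng_pat.normal(67, 12, n)), 18, 99).astype(int)
    weight = np.clip(np.round(rng_pat.normal(81, 20, n), 1), 40.0, 160.0)
    admit_min = rng_pat.integers(0, 365 * 24 * 60, n)  # minutes after epoch
    susp_off = rng_pat.uniform(2 * 60, 24 * 60, n)  # infection suspicion after admit
    ne_off = rng_pat.uniform(30, 12 * 60, n)  # NE start after suspicion

    d_peak = _round_dose(
        np.clip(rng_pat.lognormal(mu, sigma, n), 0.02, 0.98 * cfg.outlier_ceiling)
    )
    frac = rng_pat.beta(*cfg.diag_frac_beta, n)
    d_diag = np.clip(_round_dose(d_peak * frac), 0.01, d_peak)
    p_death = expit(cfg.alpha + cfg.beta * d_peak)
    death = (rng_pat.random(n) < p_death).astype(int)

    n_spikes = rng_pat.poisson(cfg.spike_rate, n)
    has_outlier = rng_pat.random(n) < cfg.outlier_rate
    second = rng_pat.random(n) < cfg.second_pressor_prob
    sp_which = rng_pat.choice(
        len(_SECOND_PRESSORS), n, p=[s[3] for s in _SECOND_PRESSORS]
    )
    fails = rng_pat.random(n) >= cfg.screen_pass_fraction
    fail_mode = np.where(
        fails, np.array(_FAIL_MODES)[rng_pat.integers(0, len(_FAIL_MODES), n)], ""
    )

    # window-failing patients start NE long after the eligibility window
    ne_off = np.where(fail_mode == "window", 80 * 60.0, ne_off)

    admission = _EPOCH + pd.to_timedelta(admit_min, unit="m")
    t_susp = admission + pd.to_timedelta(np.round(susp_off), unit="m")
    t_ne = t_susp + pd.to_timedelta(np.round(ne_off), unit="m")

    patients = pd.DataFrame(
        {
            "patient_id": np.arange(1, n + 1),
            "age": age,
            "weight_kg": np.where(fail_mode == "demographics", np.nan, weight),
            "admission_time": admission,
            "death_28d": death,
            "true_peak_dose": d_peak,
            "true_diagnosis_dose": d_diag,
            "true_p_death": p_death,
            "true_n_spikes": n_spikes,
            "true_has_outlier": has_outlier.astype(int),
            "true_fail_mode": fail_mode,
        }
    )

    # -- infusion event streams ----------------------------------------------
    inf_rows: list[tuple] = []

    def add(pid: int, drug: str, t0: pd.Timestamp, start: float, end: float,
            rate: float, unit: str) -> None:
        inf_rows.append(
            (pid, drug, t0 + pd.to_timedelta(round(start), unit="m"),
             t0 + pd.to_timedelta(round(end), unit="m"), rate, unit)
        )

    for i in range(n):
        pid = i + 1
        t0 = t_ne[i]
        if fail_mode[i] == "dose":
            # every NE record is a registry-error outlier
            add(pid, "norepinephrine", t0, 0, 120, 60.0, "ug/kg/min")
            continue
        d_a = rng_inf.uniform(20, 60)
        d_b = rng_inf.uniform(15, 45)
        d_c = rng_inf.uniform(30, 180)
        d_d = rng_inf.uniform(60, 240)
        mid = float(_round_dose((d_diag[i] + d_peak[i]) / 2))
        t = 0.0
        add(pid, "norepinephrine", t0, t, t + d_a, float(d_diag[i]), "ug/kg/min")
        t += d_a
        add(pid, "norepinephrine", t0, t, t + d_b, mid, "ug/kg/min")
        t += d_b
        add(pid, "norepinephrine", t0, t, t + d_c, float(d_peak[i]), "ug/kg/min")
        t += d_c
        down = float(_round_dose(0.6 * d_peak[i]))
        for _ in range(n_spikes[i]):
            # sub-5-min spike bracketed by down-rate segments so that no two
            # spikes can merge into a >=5-min pseudo-stable run
            dur = rng_inf.uniform(1.0, 3.5)  # stays under 5 min after rounding
            add(pid, "norepinephrine", t0, t, t + dur,
                float(_round_dose(1.5 * d_peak[i])), "ug/kg/min")
            t += dur
            filler = rng_inf.uniform(6.0, 15.0)
            add(pid, "norepinephrine", t0, t, t + filler, down, "ug/kg/min")
            t += filler
        add(pid, "norepinephrine", t0, t, t + d_d, down, "ug/kg/min")
        t += d_d
        if has_outlier[i]:
            add(pid, "norepinephrine", t0, t, t + 1, 60.0, "ug/kg/min")
            t += 1
        if second[i]:
            drug, unit, (lo, hi), _ = _SECOND_PRESSORS[sp_which[i]]
            add(pid, drug, t0, d_a, d_a + rng_inf.uniform(120, 600),
                float(np.round(rng_inf.uniform(lo, hi), 3)), unit)

    infusion_events = pd.DataFrame(
        inf_rows,
        columns=["patient_id", "drug", "start_time", "end_time", "rate", "rate_unit"],
    )

    # -- labs: lactate around NE initiation ----------------------------------
    lac = np.round(np.maximum(rng_lab.lognormal(np.log(3.2), 0.45, n), 2.0), 1)
    lac = np.where(fail_mode == "lactate", np.round(rng_lab.uniform(0.5, 1.9, n), 1), lac)
    lac_off = np.round(rng_lab.uniform(-30, 30, n))
    lac2 = np.round(lac * rng_lab.uniform(0.7, 1.3, n), 1)
    labs = pd.DataFrame(
        {
            "patient_id": np.tile(np.arange(1, n + 1), 2),
            "charttime": np.concatenate(
                [t_ne + pd.to_timedelta(lac_off, unit="m"),
                 t_ne + pd.to_timedelta(6 * 60, unit="m")]
            ),
            "lactate_mmol_l": np.concatenate([lac, lac2]),
        }
    ).sort_values(["patient_id", "charttime"], kind="stable", ignore_index=True)

    # -- infection events: culture then antibiotics --------------------------
    abx_off = np.round(rng_infx.uniform(60, 12 * 60, n))
    infection_events = pd.DataFrame(
        {
            "patient_id": np.tile(np.arange(1, n + 1), 2),
            "event_type": ["culture"] * n + ["antibiotic"] * n,
            "charttime": np.concatenate([t_susp, t_susp + pd.to_timedelta(abx_off, unit="m")]),
        }
    ).sort_values(["patient_id", "charttime"], kind="stable", ignore_index=True)

    # -- SOFA scores ----------------------------------------------------------
    score = np.clip(np.round(rng_sofa.normal(7.5, 2.5, n)), 2, 20).astype(int)
    score = np.where(fail_mode == "sofa", 1, score)
    sofa = pd.DataFrame(
        {
            "patient_id": np.tile(np.arange(1, n + 1), 2),
            "charttime": np.concatenate(
                [t_susp + pd.to_timedelta(60, unit="m"),
                 t_susp + pd.to_timedelta(24 * 60, unit="m")]
            ),
            "sofa": np.concatenate([score, score]),
        }
    ).sort_values(["patient_id", "charttime"], kind="stable", ignore_index=True)

    manifest = {"config": dataclasses.asdict(cfg), "seed": cfg.seed}
    return SyntheticTables(patients, infusion_events, labs, infection_events, sofa, manifest)


def write_tables(tables: SyntheticTables, out_dir: str | Path) -> None:
    """Write the five tables as CSV (ISO-8601 timestamps) plus manifest.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.as_dict().items():
        df.to_csv(out / f"{name}.csv", index=False, date_format="%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(tables.manifest, indent=2, default=str))


_TIME_COLS = {
    "patients": ["admission_time"],
    "infusion_events": ["start_time", "end_time"],
    "labs": ["charttime"],
    "infection_events": ["charttime"],
    "sofa": ["charttime"],
}


def read_tables(in_dir: str | Path) -> SyntheticTables:
    """Read the five CSV tables written by :func:`write_tables`."""
    p = Path(in_dir)
    frames = {}
    for name, tcols in _TIME_COLS.items():
        path = p / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing input table: {path}")
        frames[name] = pd.read_csv(path, parse_dates=tcols)
    manifest_path = p / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    return SyntheticTables(manifest=manifest, **frames)
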