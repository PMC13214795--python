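"""Synthetic two-source EHR cohort generator with a ground-truth ledger.

The generator emits a hospital-information-system extract (demographics,
surgeries, discharge outcome), an ICU patient-data-management extract
(timestamped creatinine, hourly urine volumes, weight, dialysis sessions) and
a per-patient ledger of the generating truth.

Series are constructed by inversion: for a patient whose ledger says maximum
stage ``s``, the emitted observations satisfy the detection rules for exactly
stage ``s`` — oliguric blocks are isolated by one-hour documentation gaps and
their rate/duration ranges are chosen with guard margins so neither hourly
binning nor value rounding can move an episode across a staging threshold.
A configurable fraction of patients is emitted with whole parameter families
dropped so they fail the downstream computability minimum, and a fraction of
weights is recorded redundantly by a second, lower-quality source process.

All randomness flows from a single generator seeded once; a fixed spec yields
byte-identical CSV output.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    GroundTruthLedger,
    HisExtract,
    LEDGER_COLUMNS,
    OBSERVATION_COLUMNS,
    PARAMETER_UNITS,
    PdmsExtract,
    write_extracts,
)
from .errors import ConfigError

#: procedure mix matching the published per-procedure cohort margins
DEFAULT_PROCEDURE_MIX = {
    "OPCAB": 3990 / 8564,
    "ON-CABG": 234 / 8564,
    "Aortic surgery": 244 / 8564,
    "AV-Repair": 75 / 8564,
    "AV-Replacement": 733 / 8564,
    "MV-Repair": 472 / 8564,
    "MV-Replacement": 143 / 8564,
    "TV-Surgery": 39 / 8564,
    "Combined": 2423 / 8564,
    "Other": 211 / 8564,
}

#: maximum-stage marginal distribution (no-AKI fraction times published stage split)
DEFAULT_STAGE_PROBS = {0: 0.295, 1: 0.198, 2: 0.381, 3: 0.126}

#: oliguric block (rate_lo, rate_hi) mL/kg/h and (dur_lo, dur_hi) hours per stage.
#: Ranges carry guard margins: stage-1/2 rates stay in [0.30, 0.45] (never
#: reaching the 0.3 stage-3 bound), stage-2 durations stay < 24 h, and stage-3
#: rates stay positive (no accidental anuria) and below 0.3 after rounding.
DEFAULT_OLIGURIA_PARAMS = {
    1: ((0.30, 0.45), (6, 11)),
    2: ((0.30, 0.45), (12, 20)),
    3: ((0.05, 0.20), (24, 30)),
}

#: creatinine ratio-band multipliers per stage, with 0.05 guard margins against
#: two-decimal rounding of emitted values
DEFAULT_CREAT_MULTIPLIERS = {
    1: (1.55, 1.85),
    2: (2.05, 2.85),
    3: (3.05, 3.40),
}

DEFAULT_ROUTE_PROBS = {"urine": 0.87, "creatinine": 0.12, "dialysis": 0.01}

PDMS_SOURCE = "pdms_metavision"
HIS_SOURCE = "his_admission"

_ICU_STAY_H = 72          # discharge offset from surgery end
_HIGH_RATE = (0.8, 1.2)   # normal diuresis range, mL/kg/h
_FLAT_CR_TIMES = (4, 47)  # routine postoperative creatinine draws, hours


@dataclass
class MortalityModel:
    """In-hospital death log-odds: intercept for stage 0 plus per-stage increments."""

    intercept: float = -4.70
    stage_increments: tuple[float, float, float] = (0.54, 0.71, 3.59)

    def logit(self, stage: int) -> float:
        return self.intercept + (0.0 if stage == 0 else self.stage_increments[stage - 1])


@dataclass
class CohortSpec:
    """Full configuration of one synthetic cohort."""

    n_patients: int = 1000
    procedure_mix: dict = field(default_factory=lambda: dict(DEFAULT_PROCEDURE_MIX))
    aki_stage_probs: dict = field(default_factory=lambda: dict(DEFAULT_STAGE_PROBS))
    mortality_logit: MortalityModel = field(default_factory=MortalityModel)
    oliguria_params: dict = field(default_factory=lambda: dict(DEFAULT_OLIGURIA_PARAMS))
    creatinine_baseline: tuple[float, float] = (0.7, 1.3)
    creatinine_multipliers: dict = field(default_factory=lambda: dict(DEFAULT_CREAT_MULTIPLIERS))
    extra_creatinine_frac: float = 0.25
    extra_dialysis_frac: float = 0.30
    detection_route_probs: dict = field(default_factory=lambda: dict(DEFAULT_ROUTE_PROBS))
    missingness: float = 0.05
    redundancy: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError(f"n_patients must be >= 1, got {self.n_patients}")
        for name, probs in (
            ("procedure_mix", self.procedure_mix),
            ("aki_stage_probs", self.aki_stage_probs),
            ("detection_route_probs", self.detection_route_probs),
        ):
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{name} probabilities must sum to 1, got {total!r}")
            if any(p < 0 for p in probs.values()):
                raise ConfigError(f"{name} probabilities must be non-negative")
        for name, frac in (("missingness", self.missingness), ("redundancy", self.redundancy),
                           ("extra_creatinine_frac", self.extra_creatinine_frac),
                           ("extra_dialysis_frac", self.extra_dialysis_frac)):
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {frac}")
        if set(self.aki_stage_probs) != {0, 1, 2, 3}:
            raise ConfigError("aki_stage_probs must have keys {0, 1, 2, 3}")


def _stage_event_hour(stage: int, block_start: int) -> int:
    """Detection hour of the stage-``stage`` urine event for a block at ``block_start``."""
    return block_start + {1: 5, 2: 11, 3: 23}[stage]


def generate_ground_truth(spec: CohortSpec) -> pd.DataFrame:
    """Draw per-patient truth and latent generation parameters (no series).

    The returned frame carries both the public ledger columns and internal
    columns (weights, block timings, multipliers) consumed by
    :func:`generate_cohort`.  First stage and first detection time are derived
    analytically from the construction, independent of the detector.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    stage_keys = sorted(spec.aki_stage_probs)
    stages = rng.choice(stage_keys, size=n, p=[spec.aki_stage_probs[k] for k in stage_keys])
    proc_labels = sorted(spec.procedure_mix)
    procedures = rng.choice(proc_labels, size=n, p=[spec.procedure_mix[k] for k in proc_labels])

    route_names = ("urine", "creatinine", "dialysis")
    route_p = np.array([spec.detection_route_probs[r] for r in route_names])
    routes = rng.choice(route_names, size=n, p=route_p)
    # dialysis-first detection only makes sense at stage 3
    routes[(routes == "dialysis") & (stages != 3)] = "urine"
    routes[stages == 0] = "none"

    logits = np.array([spec.mortality_logit.logit(int(s)) for s in stages])
    death = rng.random(n) < 1.0 / (1.0 + np.exp(-logits))

    insufficient = rng.random(n) < spec.missingness
    redundant = rng.random(n) < spec.redundancy

    age = np.clip(np.round(rng.normal(68, 9, n)), 30, 92).astype(int)
    sex = np.where(rng.random(n) < 0.752, "male", "female")
    height_m = rng.uniform(1.55, 1.92, n)
    bmi = np.round(rng.uniform(21.0, 33.0, n), 1)
    weight = np.round(bmi * height_m**2, 1)
    comorbidity = rng.poisson(4.5, n)
    baseline_cr = np.round(rng.uniform(*spec.creatinine_baseline, n), 2)
    euroscore = np.round(np.exp(rng.normal(math.log(2.4), 0.8, n)), 1)
    urgency = rng.choice(["normal", "mid", "high"], size=n, p=[0.6, 0.3, 0.1])

    adm_offset = np.round(rng.uniform(0.5, 2.0, n), 2)
    op_hours = np.round(np.clip(rng.normal(3.3, 0.6, n), 1.5, 8.0), 2)

    block_start = rng.integers(6, 13, n)
    durations = np.zeros(n, dtype=int)
    mult = np.zeros(n)
    for s, ((_, _), (dlo, dhi)) in spec.oliguria_params.items():
        mask = stages == s
        durations[mask] = rng.integers(dlo, dhi + 1, int(mask.sum()))
    for s, (mlo, mhi) in spec.creatinine_multipliers.items():
        mask = stages == s
        mult[mask] = np.round(rng.uniform(mlo, mhi, int(mask.sum())), 3)

    extra_cr = (rng.random(n) < spec.extra_creatinine_frac) & (routes == "urine")
    extra_dial = (rng.random(n) < spec.extra_dialysis_frac) & (routes == "urine") & (stages == 3)

    t_cr = np.full(n, np.nan)
    cr_route = routes == "creatinine"
    t_cr[cr_route] = rng.integers(10, 21, int(cr_route.sum()))
    stage_hours = np.array(
        [_stage_event_hour(int(s), int(b)) if s > 0 else -1 for s, b in zip(stages, block_start)]
    )
    t_cr[extra_cr] = stage_hours[extra_cr] + rng.integers(2, 7, int(extra_cr.sum()))

    t_dial = np.full(n, np.nan)
    dia_route = routes == "dialysis"
    t_dial[dia_route] = rng.integers(12, 31, int(dia_route.sum()))
    t_dial[extra_dial] = (block_start + durations)[extra_dial] + rng.integers(
        2, 9, int(extra_dial.sum())
    )

    death_day = np.round(np.where(death, rng.uniform(3, 30, n), 0.0), 1)
    los = np.round(6.0 + rng.exponential(3.0, n), 1).clip(min=3.5)
    hospital_los = np.where(death, death_day, los)

    first_stage = np.zeros(n, dtype=int)
    first_time = np.full(n, np.nan)
    for i in range(n):
        s = int(stages[i])
        if s == 0:
            continue
        if routes[i] == "urine":
            first_stage[i] = 1
            first_time[i] = _stage_event_hour(1, int(block_start[i]))
        elif routes[i] == "creatinine":
            first_stage[i] = s
            first_time[i] = t_cr[i]
        else:  # dialysis
            first_stage[i] = 3
            first_time[i] = t_dial[i]

    return pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:06d}" for i in range(n)],
            "procedure": procedures,
            "computable": ~insufficient,
            "true_max_stage": stages.astype(int),
            "true_first_stage": first_stage,
            "true_first_time_h": first_time,
            "detection_route": routes,
            "death": death.astype(int),
            # internal generation parameters
            "gen_age": age,
            "gen_sex": sex,
            "gen_bmi": bmi,
            "gen_weight": weight,
            "gen_comorbidity": comorbidity,
            "gen_baseline_cr": baseline_cr,
            "gen_euroscore": euroscore,
            "gen_urgency": urgency,
            "gen_adm_offset": adm_offset,
            "gen_op_hours": op_hours,
            "gen_block_start": block_start,
            "gen_duration": durations,
            "gen_mult": mult,
            "gen_extra_cr": extra_cr,
            "gen_t_cr": t_cr,
            "gen_t_dial": t_dial,
            "gen_redundant": redundant,
            "gen_hospital_los": hospital_los,
        }
    )


def generate_cohort(spec: CohortSpec):
    """Generate the two source extracts and the ground-truth ledger.

    Returns ``(HisExtract, PdmsExtract, GroundTruthLedger)``.
    """
    truth = generate_ground_truth(spec)
    rng = np.random.default_rng(spec.seed + 1)  # per-bin draws, separate stream
    base = pd.Timestamp("2021-01-01 08:00:00")

    obs_rows: list[tuple] = []
    surg_rows: list[dict] = []

    def emit(pid, ts, parameter, value, source, rank):
        obs_rows.append(
            (pid, ts.isoformat(), parameter, value, PARAMETER_UNITS[parameter], source, rank)
        )

    for i, row in enumerate(truth.itertuples(index=False)):
        pid = row.patient_id
        surgery_start = base + pd.Timedelta(days=i)
        surgery_end = surgery_start + pd.Timedelta(hours=float(row.gen_op_hours))
        admission = surgery_end + pd.Timedelta(hours=float(row.gen_adm_offset))
        w = float(row.gen_weight)
        stage = int(row.true_max_stage)
        route = row.detection_route

        surg_rows.append(
            {
                "patient_id": pid,
                "procedure": row.procedure,
                "urgency": row.gen_urgency,
                "surgery_start": surgery_start.isoformat(),
                "surgery_end": surgery_end.isoformat(),
                "death": int(row.death),
                "hospital_los_days": float(row.gen_hospital_los),
            }
        )

        weight_hours = (float(row.gen_adm_offset), 24.0, 48.0)
        t0 = int(np.ceil(row.gen_adm_offset)) + 1

        if not row.computable:
            # drop the creatinine and dialysis families entirely and emit a
            # single urine volume: below the computability minimum by design
            for wh in weight_hours:
                emit(pid, surgery_end + pd.Timedelta(hours=wh), "weight", w, PDMS_SOURCE, 1)
            emit(
                pid,
                surgery_end + pd.Timedelta(hours=t0),
                "urine_output",
                round(float(rng.uniform(*_HIGH_RATE)) * w, 1),
                PDMS_SOURCE,
                1,
            )
            continue

        for wh in weight_hours:
            ts = surgery_end + pd.Timedelta(hours=wh)
            emit(pid, ts, "weight", w, PDMS_SOURCE, 1)
            if row.gen_redundant:
                # stale lower-quality duplicate; grossly off so a wrong
                # prioritization is caught by the inversion property
                emit(pid, ts, "weight", round(w * 2.2, 1), HIS_SOURCE, 2)

        b0, dur = int(row.gen_block_start), int(row.gen_duration)
        oliguric = route == "urine" and stage > 0
        gaps = {b0 - 1, b0 + dur} if oliguric else set()
        rate_lo, rate_hi = spec.oliguria_params.get(stage, ((0.0, 0.0), (0, 0)))[0]
        for t in range(t0, _ICU_STAY_H):
            if t in gaps:
                continue
            if oliguric and b0 <= t < b0 + dur:
                rate = float(rng.uniform(rate_lo, rate_hi))
            else:
                rate = float(rng.uniform(*_HIGH_RATE))
            emit(
                pid,
                surgery_end + pd.Timedelta(hours=t),
                "urine_output",
                round(rate * w, 1),
                PDMS_SOURCE,
                1,
            )

        b = float(row.gen_baseline_cr)
        cr_times = [t for t in _FLAT_CR_TIMES if np.isnan(row.gen_t_cr) or t != int(row.gen_t_cr)]
        for t in cr_times:
            emit(
                pid,
                surgery_end + pd.Timedelta(hours=t),
                "creatinine",
                round(b + float(rng.uniform(-0.05, 0.05)), 2),
                PDMS_SOURCE,
                1,
            )
        if not np.isnan(row.gen_t_cr):
            emit(
                pid,
                surgery_end + pd.Timedelta(hours=float(row.gen_t_cr)),
                "creatinine",
                round(b * float(row.gen_mult), 2),
                PDMS_SOURCE,
                1,
            )
        if not np.isnan(row.gen_t_dial):
            emit(
                pid,
                surgery_end + pd.Timedelta(hours=float(row.gen_t_dial)),
                "dialysis",
                1.0,
                PDMS_SOURCE,
                1,
            )

    observations = pd.DataFrame(obs_rows, columns=OBSERVATION_COLUMNS)
    patients = pd.DataFrame(
        {
            "patient_id": truth["patient_id"],
            "age": truth["gen_age"],
            "sex": truth["gen_sex"],
            "bmi": truth["gen_bmi"],
            "comorbidity_count": truth["gen_comorbidity"],
            "preop_creatinine": truth["gen_baseline_cr"],
            "euroscore2": truth["gen_euroscore"],
        }
    )
    surgeries = pd.DataFrame(surg_rows)
    ledger = GroundTruthLedger(truth[LEDGER_COLUMNS].copy())
    return HisExtract(patients, surgeries), PdmsExtract(observations), ledger


def generate_and_write(spec: CohortSpec, outdir) -> dict:
    """Generate a cohort and write the four CSV artifacts to ``outdir``."""
    his, pdms, ledger = generate_cohort(spec)
    return write_extracts(his, pdms, ledger, outdir)
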