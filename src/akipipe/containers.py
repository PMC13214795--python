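"""Shared data containers and CSV (de)serialization for the pipeline stages.

All on-disk artifacts are plain UTF-8 CSV with ISO-8601 timestamps so a
cohort round-trips bytewise under a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

OBSERVATION_COLUMNS = [
    "patient_id",
    "timestamp",
    "parameter",
    "value",
    "unit",
    "source_process",
    "quality_rank",
]

#: canonical unit per observed parameter
PARAMETER_UNITS = {
    "creatinine": "mg/dL",
    "urine_output": "mL",
    "weight": "kg",
    "dialysis": "session",
}

HIS_PATIENT_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "bmi",
    "comorbidity_count",
    "preop_creatinine",
    "euroscore2",
]

HIS_SURGERY_COLUMNS = [
    "patient_id",
    "procedure",
    "urgency",
    "surgery_start",
    "surgery_end",
    "death",
    "hospital_los_days",
]

LEDGER_COLUMNS = [
    "patient_id",
    "procedure",
    "computable",
    "true_max_stage",
    "true_first_stage",
    "true_first_time_h",
    "detection_route",
    "death",
]


@dataclass
class HisExtract:
    """Hospital-information-system extract: demographics plus surgery episodes."""

    patients: pd.DataFrame
    surgeries: pd.DataFrame


@dataclass
class PdmsExtract:
    """ICU patient-data-management extract: long-format timestamped observations."""

    observations: pd.DataFrame


@dataclass
class GroundTruthLedger:
    """Per-patient generating truth; the oracle for recovery tests."""

    table: pd.DataFrame


@dataclass
class FusedEpisode:
    """One surgery episode after linkage and redundancy resolution.

    Series hold times in hours since the end of surgery.  ``urine`` carries raw
    collection volumes (mL), ``creatinine`` mg/dL values and ``weight`` kg.
    """

    patient_id: str
    procedure: str
    surgery_start: pd.Timestamp
    surgery_end: pd.Timestamp
    icu_admission: pd.Timestamp
    icu_discharge: pd.Timestamp
    creatinine: pd.DataFrame
    urine: pd.DataFrame
    weight: pd.DataFrame
    dialysis_times_h: list[float]
    death: bool
    hospital_los_days: float
    icu_los_days: float
    covariates: dict = field(default_factory=dict)


@dataclass
class CohortFlow:
    """Counts along the cohort filter chain (raw -> linked -> mapped -> computable)."""

    raw: int
    linked: int
    icu_mapped: int
    computable: int

    @property
    def final(self) -> int:
        return self.computable

    def to_dict(self) -> dict:
        return {
            "raw": self.raw,
            "linked": self.linked,
            "icu_mapped": self.icu_mapped,
            "computable": self.computable,
            "final": self.final,
        }

    def validate(self) -> None:
        chain = [self.raw, self.linked, self.icu_mapped, self.computable]
        if any(b > a for a, b in zip(chain, chain[1:])):
            raise ValueError(f"cohort flow counts must be non-increasing: {chain}")


def write_extracts(
    his: HisExtract,
    pdms: PdmsExtract,
    ledger: GroundTruthLedger,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the three source extracts plus the ground-truth ledger as CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "his_patients": outdir / "his_patients.csv",
        "his_surgeries": outdir / "his_surgeries.csv",
        "pdms_observations": outdir / "pdms_observations.csv",
        "ground_truth": outdir / "ground_truth.csv",
    }
    his.patients.to_csv(paths["his_patients"], index=False)
    his.surgeries.to_csv(paths["his_surgeries"], index=False)
    pdms.observations.to_csv(paths["pdms_observations"], index=False)
    ledger.table.to_csv(paths["ground_truth"], index=False)
    return paths


def read_extracts(indir: str | Path) -> tuple[HisExtract, PdmsExtract, GroundTruthLedger | None]:
    """Read extracts written by :func:`write_extracts`; the ledger is optional."""
    indir = Path(indir)
    his = HisExtract(
        patients=pd.read_csv(indir / "his_patients.csv"),
        surgeries=pd.read_csv(indir / "his_surgeries.csv"),
    )
    pdms = PdmsExtract(observations=pd.read_csv(indir / "pdms_observations.csv"))
    ledger_path = indir / "ground_truth.csv"
    ledger = GroundTruthLedger(pd.read_csv(ledger_path)) if ledger_path.exists() else None
    return his, pdms, ledger
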