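"""Linkage of the two EHR extracts into per-surgery fused episodes.

Surgeries from the hospital information system are joined to ICU stays
reconstructed from the patient-data-management observations via the shared
patient identifier.  Redundantly recorded parameters are resolved by source
quality rank, and the computability exclusion filter emits a cohort-flow
accounting of every episode dropped along the way.

The contract is sort-then-process: inputs are canonically ordered before any
decision, so shuffling input rows never changes the fused result.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .containers import CohortFlow, FusedEpisode, HisExtract, PdmsExtract
from .errors import DataError, UnitError

#: earliest ICU admission accepted this many hours after the end of surgery
DEFAULT_ICU_WINDOW_H = 48.0
#: a silence longer than this splits one patient's observations into two stays
DEFAULT_STAY_GAP_H = 24.0


@dataclass
class FusionConfig:
    icu_window_h: float = DEFAULT_ICU_WINDOW_H
    stay_gap_h: float = DEFAULT_STAY_GAP_H


@dataclass
class LinkResult:
    """Outcome of :func:`link_and_map`: mapped episodes plus flow accounting."""

    episodes: list[FusedEpisode]
    unmapped: pd.DataFrame
    counts: dict = field(default_factory=dict)


def _parse_timestamps(series: pd.Series, context: str) -> pd.Series:
    parsed = pd.to_datetime(series, errors="coerce", format="ISO8601")
    bad = parsed.isna() & series.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise DataError(
            f"unparseable timestamp in {context} at row {row}: {series.iloc[row]!r}"
        )
    return parsed


def resolve_redundancy(observations: pd.DataFrame) -> pd.DataFrame:
    """Keep, per (patient, parameter, timestamp), the best-quality observation.

    Best = lowest ``quality_rank``; ties broken by lexicographic
    ``source_process`` name.  Raises :class:`UnitError` when one parameter
    carries contradictory units.  Resolution is deterministic and independent
    of input row order.
    """
    obs = observations.copy()
    units = obs.groupby("parameter")["unit"].nunique()
    conflicting = units[units > 1]
    if len(conflicting):
        raise UnitError(
            f"contradictory units for parameter(s): {', '.join(conflicting.index)}"
        )
    obs = obs.sort_values(
        ["patient_id", "parameter", "timestamp", "quality_rank", "source_process", "value"],
        kind="mergesort",
    )
    return obs.drop_duplicates(
        subset=["patient_id", "parameter", "timestamp"], keep="first"
    ).reset_index(drop=True)


def _detect_stays(times: np.ndarray, gap_h: float) -> list[tuple]:
    """Split sorted observation times into stays at silences longer than ``gap_h``."""
    stays = []
    start = prev = times[0]
    for t in times[1:]:
        if (t - prev) / np.timedelta64(1, "h") > gap_h:
            stays.append((start, prev))
            start = t
        prev = t
    stays.append((start, prev))
    return stays


def link_and_map(
    his: HisExtract,
    pdms: PdmsExtract,
    config: FusionConfig | None = None,
) -> LinkResult:
    """Join each surgery to the earliest ICU stay admitted within the window.

    A surgery maps to the earliest stay whose admission falls in
    ``(surgery_end, surgery_end + icu_window_h]``; surgeries without such a
    stay are returned as unmapped.  Observations outside the mapped stay are
    discarded.
    """
    config = config or FusionConfig()

    patients = his.patients.copy()
    if patients["patient_id"].duplicated().any():
        dupes = patients.loc[patients["patient_id"].duplicated(), "patient_id"].tolist()
        raise DataError(f"duplicate patient_id in HIS patients extract: {dupes[:5]}")
    patients = patients.set_index("patient_id")

    surgeries = his.surgeries.copy().reset_index(drop=True)
    surgeries["surgery_start"] = _parse_timestamps(surgeries["surgery_start"], "his_surgeries")
    surgeries["surgery_end"] = _parse_timestamps(surgeries["surgery_end"], "his_surgeries")
    surgeries = surgeries.sort_values(
        ["patient_id", "surgery_start"], kind="mergesort"
    ).reset_index(drop=True)

    obs = pdms.observations.copy().reset_index(drop=True)
    obs["timestamp"] = _parse_timestamps(obs["timestamp"], "pdms_observations")
    obs = resolve_redundancy(obs)
    obs_by_patient = {pid: grp for pid, grp in obs.groupby("patient_id")}

    episodes: list[FusedEpisode] = []
    unmapped_rows = []
    n_linked = 0
    for surg in surgeries.itertuples(index=False):
        pid = surg.patient_id
        grp = obs_by_patient.get(pid)
        if grp is None or not len(grp):
            unmapped_rows.append({**surg._asdict(), "reason": "no PDMS observations"})
            continue
        n_linked += 1
        times = np.sort(grp["timestamp"].to_numpy())
        stays = _detect_stays(times, config.stay_gap_h)
        window_end = surg.surgery_end + pd.Timedelta(hours=config.icu_window_h)
        eligible = [s for s in stays if surg.surgery_end < s[0] <= window_end]
        if not eligible:
            unmapped_rows.append(
                {**surg._asdict(), "reason": "no ICU admission within mapping window"}
            )
            continue
        admission, discharge = min(eligible, key=lambda s: s[0])
        admission, discharge = pd.Timestamp(admission), pd.Timestamp(discharge)

        stay_obs = grp[(grp["timestamp"] >= admission) & (grp["timestamp"] <= discharge)]
        t0 = surg.surgery_end

        def _series(parameter: str) -> pd.DataFrame:
            sel = stay_obs[stay_obs["parameter"] == parameter]
            return pd.DataFrame(
                {
                    "time_h": (sel["timestamp"] - t0) / pd.Timedelta(hours=1),
                    "value": sel["value"].astype(float),
                }
            ).reset_index(drop=True)

        dialysis = _series("dialysis")
        patient = patients.loc[pid]
        covariates = {
            "age": float(patient["age"]),
            "sex": str(patient["sex"]),
            "bmi": float(patient["bmi"]),
            "comorbidity_count": float(patient["comorbidity_count"]),
            "preop_creatinine": float(patient["preop_creatinine"]),
            "euroscore2": float(patient["euroscore2"]),
            "urgency": str(surg.urgency),
            "operative_hours": (surg.surgery_end - surg.surgery_start)
            / pd.Timedelta(hours=1),
        }
        episodes.append(
            FusedEpisode(
                patient_id=pid,
                procedure=str(surg.procedure),
                surgery_start=surg.surgery_start,
                surgery_end=surg.surgery_end,
                icu_admission=admission,
                icu_discharge=discharge,
                creatinine=_series("creatinine"),
                urine=_series("urine_output"),
                weight=_series("weight"),
                dialysis_times_h=dialysis["time_h"].tolist(),
                death=bool(surg.death),
                hospital_los_days=float(surg.hospital_los_days),
                icu_los_days=(discharge - admission) / pd.Timedelta(days=1),
                covariates=covariates,
            )
        )

    counts = {"raw": len(surgeries), "linked": n_linked, "icu_mapped": len(episodes)}
    return LinkResult(
        episodes=episodes, unmapped=pd.DataFrame(unmapped_rows), counts=counts
    )


#: computability minimum per criterion family
_MIN_URINE = 2
_MIN_CREATININE = 1
_MIN_DIALYSIS = 1


def apply_computability_filter(
    episodes: Iterable[FusedEpisode],
    upstream_counts: dict | None = None,
):
    """Partition episodes by the AKI-computability minimum.

    An episode is computable iff it has >= 2 urine observations OR >= 1
    creatinine value OR >= 1 dialysis record (disjunction of sufficiency
    conditions).  Returns ``(included, excluded, CohortFlow)`` where excluded
    entries are ``(episode, failed_criteria)`` pairs.
    """
    episodes = list(episodes)
    included: list[FusedEpisode] = []
    excluded: list[tuple[FusedEpisode, list[str]]] = []
    for ep in episodes:
        failed = []
        if len(ep.urine) < _MIN_URINE:
            failed.append(f"urine<{_MIN_URINE}")
        if len(ep.creatinine) < _MIN_CREATININE:
            failed.append(f"creatinine<{_MIN_CREATININE}")
        if len(ep.dialysis_times_h) < _MIN_DIALYSIS:
            failed.append(f"dialysis<{_MIN_DIALYSIS}")
        if len(failed) == 3:
            excluded.append((ep, failed))
        else:
            included.append(ep)

    upstream = upstream_counts or {}
    n_in = len(episodes)
    flow = CohortFlow(
        raw=int(upstream.get("raw", n_in)),
        linked=int(upstream.get("linked", n_in)),
        icu_mapped=int(upstream.get("icu_mapped", n_in)),
        computable=len(included),
    )
    flow.validate()
    assert len(included) + len(excluded) == n_in
    return included, excluded, flow


def fuse_extracts(
    his: HisExtract,
    pdms: PdmsExtract,
    config: FusionConfig | None = None,
):
    """Full fusion: link, map, resolve, filter.

    Returns ``(included, excluded, flow, unmapped)``.
    """
    link = link_and_map(his, pdms, config)
    included, excluded, flow = apply_computability_filter(link.episodes, link.counts)
    return included, excluded, flow, link.unmapped
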