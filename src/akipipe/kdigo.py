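"""Full KDIGO acute kidney injury detection and staging.

Three detection routes are evaluated on harmonized per-episode series:

* urine output — sustained low hourly rates (mL/kg/h) over rolling windows,
* serum creatinine — absolute 48-h rise and ratio-to-baseline bands,
* dialysis — any renal replacement session is stage 3.

Times are hours since the end of surgery.  Urine volumes are binned on an
hourly grid; bin ``t`` covers the interval ``(t-1, t]`` and an unobserved bin
is a gap, never an implicit zero.  Gaps break windows: no interpolation or
imputation is performed anywhere.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import DataError

#: guard for inclusive thresholds evaluated in floating point
EPS = 1e-9

URINE_LOW_RATE = 0.5       # mL/kg/h, strict "<"
URINE_VERY_LOW_RATE = 0.3  # mL/kg/h, strict "<"
STAGE1_HOURS = 6
STAGE2_HOURS = 12
STAGE3_HOURS = 24
ANURIA_HOURS = 12
CREAT_DELTA = 0.3          # mg/dL, inclusive ">="
CREAT_RATIO_STAGE1 = 1.5
CREAT_RATIO_STAGE2 = 2.0
CREAT_RATIO_STAGE3 = 3.0
CREAT_ABS_STAGE3 = 4.0     # mg/dL
DELTA_WINDOW_H = 48.0
RATIO_WINDOW_H = 168.0     # 7 days, anchored at surgery end

CRITERIA = ("urine", "creatinine", "dialysis")


@dataclass(frozen=True)
class StageEvent:
    """A criterion reaching a stage at a point in time (end of qualifying window)."""

    criterion: str
    stage: int
    time_h: float


@dataclass(frozen=True)
class BaselineCreatinine:
    """Reference creatinine with provenance; ``time_h`` anchors the 48-h delta rule."""

    value: float
    provenance: str  # 'preoperative' | 'first-postoperative'
    time_h: float = 0.0

    def __post_init__(self):
        if not self.value > 0:
            raise DataError(f"baseline creatinine must be > 0, got {self.value}")


@dataclass
class UrineRateSeries:
    """Weight-normalized hourly urine rates on an integer grid with explicit gaps."""

    hour: np.ndarray  # int bins, strictly increasing; bin t covers (t-1, t]
    rate: np.ndarray  # mL/kg/h, >= 0

    def __post_init__(self):
        self.hour = np.asarray(self.hour, dtype=int)
        self.rate = np.asarray(self.rate, dtype=float)
        if len(self.hour) != len(self.rate):
            raise DataError("hour and rate must have equal length")
        if len(self.hour) > 1 and not np.all(np.diff(self.hour) > 0):
            raise DataError("urine rate grid must be strictly increasing")
        if np.any(self.rate < 0):
            raise DataError("urine rates must be non-negative")


@dataclass
class AkiAssessment:
    """Per-episode result: first and maximum stage with criterion attribution."""

    patient_id: str | None
    first_stage: int          # 0 = no AKI
    first_time_h: float | None
    max_stage: int
    max_time_h: float | None
    trigger_criterion: str | None
    events: tuple[StageEvent, ...] = ()

    @property
    def has_aki(self) -> bool:
        return self.max_stage > 0


@dataclass
class KdigoConfig:
    """Detection options; defaults follow the reference pipeline behaviour."""

    uo_window_mode: str = "mean"  # 'mean' | 'all'
    tie_break: tuple[str, ...] = ("creatinine", "urine", "dialysis")
    delta_window_h: float = DELTA_WINDOW_H
    ratio_window_h: float = RATIO_WINDOW_H

    def __post_init__(self):
        if self.uo_window_mode not in ("mean", "all"):
            raise ValueError(f"uo_window_mode must be 'mean' or 'all', got {self.uo_window_mode!r}")
        if sorted(self.tie_break) != sorted(CRITERIA):
            raise ValueError(f"tie_break must be a permutation of {CRITERIA}")


# ---------------------------------------------------------------------------
# urine output
# ---------------------------------------------------------------------------

def compute_urine_rates(volumes, weights) -> UrineRateSeries:
    """Bin urine collection volumes hourly and normalize by body weight.

    Parameters
    ----------
    volumes : array-like of (time_h, mL)
        At least two observations.  An observation at time ``tau`` falls into
        bin ``ceil(tau)``; multiple volumes within one bin are summed.
    weights : array-like of (time_h, kg)
        At least one observation.  Each bin uses the latest weight at or
        before the bin end; bins before the first weight back-fill it.
    """
    volumes = np.atleast_2d(np.asarray(volumes, dtype=float))
    weights = np.atleast_2d(np.asarray(weights, dtype=float))
    if volumes.shape[0] < 2:
        raise DataError("at least two urine observations are required")
    if weights.shape[0] < 1:
        raise DataError("at least one weight observation is required")
    if np.any(weights[:, 1] <= 0):
        raise DataError("body weight must be positive")

    bins = np.ceil(volumes[:, 0]).astype(int)
    order = np.argsort(bins, kind="stable")
    bins, vols = bins[order], volumes[order, 1]
    uniq, inverse = np.unique(bins, return_inverse=True)
    summed = np.zeros(len(uniq))
    np.add.at(summed, inverse, vols)

    wt = weights[np.argsort(weights[:, 0], kind="stable")]
    # latest weight with time <= bin end, back-filled before the first weight
    idx = np.searchsorted(wt[:, 0], uniq.astype(float), side="right") - 1
    idx = np.clip(idx, 0, len(wt) - 1)
    rates = summed / wt[idx, 1]
    return UrineRateSeries(hour=uniq, rate=rates)


def _segments(series: UrineRateSeries):
    """Yield (hours, rates) for maximal contiguous gap-free runs."""
    h, r = series.hour, series.rate
    if len(h) == 0:
        return
    breaks = np.where(np.diff(h) != 1)[0] + 1
    for hs, rs in zip(np.split(h, breaks), np.split(r, breaks)):
        yield hs, rs


def stage_urine(series: UrineRateSeries, mode: str = "mean") -> list[StageEvent]:
    """Stage oliguria over all contiguous gap-free windows.

    ``mean`` mode stages on the window mean rate; ``all`` mode requires every
    hour of the window below threshold.  Stage 1: < 0.5 mL/kg/h over >= 6 h;
    stage 2: < 0.5 over >= 12 h; stage 3: < 0.3 over >= 24 h or anuria
    (rate 0) over >= 12 h.  One event is emitted per stage at the first bin
    where its condition holds; event time is the end of the qualifying window.
    """
    if mode not in ("mean", "all"):
        raise ValueError(f"mode must be 'mean' or 'all', got {mode!r}")
    firsts: dict[int, float] = {}
    for hours, rates in _segments(series):
        n = len(rates)
        if mode == "mean":
            csum = np.concatenate(([0.0], np.cumsum(rates)))
            zero_run = 0
            for j in range(n):
                zero_run = zero_run + 1 if rates[j] == 0 else 0
                if 3 in firsts and len(firsts) == 3:
                    break
                i = np.arange(j + 1)
                length = j + 1 - i
                mean = (csum[j + 1] - csum[i]) / length
                c1 = bool(np.any((length >= STAGE1_HOURS) & (mean < URINE_LOW_RATE)))
                c2 = bool(np.any((length >= STAGE2_HOURS) & (mean < URINE_LOW_RATE)))
                c3 = bool(
                    np.any((length >= STAGE3_HOURS) & (mean < URINE_VERY_LOW_RATE))
                ) or zero_run >= ANURIA_HOURS
                t = float(hours[j])
                for stage, hit in ((1, c1), (2, c2), (3, c3)):
                    if hit and stage not in firsts:
                        firsts[stage] = t
        else:  # 'all': run lengths below each threshold
            run_low = run_vlow = run_zero = 0
            for j in range(n):
                run_low = run_low + 1 if rates[j] < URINE_LOW_RATE else 0
                run_vlow = run_vlow + 1 if rates[j] < URINE_VERY_LOW_RATE else 0
                run_zero = run_zero + 1 if rates[j] == 0 else 0
                t = float(hours[j])
                c1 = run_low >= STAGE1_HOURS
                c2 = run_low >= STAGE2_HOURS
                c3 = run_vlow >= STAGE3_HOURS or run_zero >= ANURIA_HOURS
                for stage, hit in ((1, c1), (2, c2), (3, c3)):
                    if hit and stage not in firsts:
                        firsts[stage] = t
        if len(firsts) == 3:
            break
    return sorted(
        (StageEvent("urine", s, t) for s, t in firsts.items()),
        key=lambda e: (e.time_h, e.stage),
    )


# ---------------------------------------------------------------------------
# serum creatinine
# ---------------------------------------------------------------------------

def stage_creatinine(
    values,
    baseline: BaselineCreatinine,
    delta_window_h: float = DELTA_WINDOW_H,
    ratio_window_h: float = RATIO_WINDOW_H,
) -> list[StageEvent]:
    """Stage creatinine rises against a rolling 48-h minimum and baseline ratios.

    At each measurement time ``t``:

    * stage 1 if the value minus the minimum of measurements (and the
      baseline, when its anchor lies in the window) within ``[t-48h, t]``
      is >= 0.3 mg/dL;
    * within 7 days of surgery end, ratio bands versus baseline:
      >= 1.5x stage 1, >= 2.0x stage 2, >= 3.0x or an absolute value
      >= 4.0 mg/dL stage 3.

    One event per stage at first qualification.
    """
    vals = np.atleast_2d(np.asarray(values, dtype=float))
    if vals.shape[0] == 0:
        return []
    order = np.argsort(vals[:, 0], kind="stable")
    times, conc = vals[order, 0], vals[order, 1]

    firsts: dict[int, float] = {}
    for k in range(len(times)):
        t, v = float(times[k]), float(conc[k])
        window = (times >= t - delta_window_h) & (times <= t)
        refs = list(conc[window])
        if t - delta_window_h <= baseline.time_h <= t:
            refs.append(baseline.value)
        c1 = bool(refs) and (v - min(refs)) >= CREAT_DELTA - EPS
        c2 = c3 = False
        if 0.0 <= t <= ratio_window_h:
            ratio = v / baseline.value
            c1 = c1 or ratio >= CREAT_RATIO_STAGE1 - EPS
            c2 = ratio >= CREAT_RATIO_STAGE2 - EPS
            c3 = ratio >= CREAT_RATIO_STAGE3 - EPS or v >= CREAT_ABS_STAGE3 - EPS
        for stage, hit in ((1, c1), (2, c2), (3, c3)):
            if hit and stage not in firsts:
                firsts[stage] = t
        if len(firsts) == 3:
            break
    return sorted(
        (StageEvent("creatinine", s, t) for s, t in firsts.items()),
        key=lambda e: (e.time_h, e.stage),
    )


def stage_dialysis(times_h: Iterable[float]) -> list[StageEvent]:
    """First renal replacement session starts a stage-3 event; later ones are ignored."""
    times = sorted(float(t) for t in times_h)
    if not times:
        return []
    return [StageEvent("dialysis", 3, times[0])]


# ---------------------------------------------------------------------------
# combination
# ---------------------------------------------------------------------------

def combine_assessment(
    urine_events: Sequence[StageEvent],
    creatinine_events: Sequence[StageEvent],
    dialysis_events: Sequence[StageEvent],
    tie_break: tuple[str, ...] = ("creatinine", "urine", "dialysis"),
    patient_id: str | None = None,
) -> AkiAssessment:
    """Merge per-criterion events into one first/maximum-stage assessment.

    ``first_time`` is the earliest event time; ``first_stage`` the maximum
    stage among events at exactly that time, with ties between criteria at the
    same timestamp broken by ``tie_break`` priority.  ``max_time`` is the
    earliest time the overall maximum stage is reached.
    """
    events = sorted(
        [*urine_events, *creatinine_events, *dialysis_events],
        key=lambda e: (e.time_h, -e.stage),
    )
    if not events:
        return AkiAssessment(patient_id, 0, None, 0, None, None, ())

    priority = {c: i for i, c in enumerate(tie_break)}
    first_time = events[0].time_h
    at_first = [e for e in events if e.time_h == first_time]
    first_stage = max(e.stage for e in at_first)
    trigger = min(
        (e for e in at_first if e.stage == first_stage),
        key=lambda e: priority[e.criterion],
    ).criterion
    max_stage = max(e.stage for e in events)
    max_time = min(e.time_h for e in events if e.stage == max_stage)
    assessment = AkiAssessment(
        patient_id, first_stage, first_time, max_stage, max_time, trigger, tuple(events)
    )
    assert assessment.max_stage >= assessment.first_stage
    assert assessment.max_time_h >= assessment.first_time_h
    return assessment


def resolve_baseline(episode) -> BaselineCreatinine | None:
    """Preoperative creatinine when recorded, else the first postoperative value."""
    preop = episode.covariates.get("preop_creatinine")
    if preop is not None and not np.isnan(preop) and preop > 0:
        return BaselineCreatinine(float(preop), "preoperative", 0.0)
    if len(episode.creatinine):
        cr = episode.creatinine.sort_values("time_h")
        return BaselineCreatinine(
            float(cr["value"].iloc[0]), "first-postoperative", float(cr["time_h"].iloc[0])
        )
    return None


def assess_episode(episode, config: KdigoConfig | None = None) -> AkiAssessment:
    """Run all applicable criteria on one fused episode."""
    config = config or KdigoConfig()
    urine_events: list[StageEvent] = []
    if len(episode.urine) >= 2 and len(episode.weight) >= 1:
        series = compute_urine_rates(
            episode.urine[["time_h", "value"]].to_numpy(),
            episode.weight[["time_h", "value"]].to_numpy(),
        )
        urine_events = stage_urine(series, mode=config.uo_window_mode)
    creatinine_events: list[StageEvent] = []
    baseline = resolve_baseline(episode)
    if baseline is not None and len(episode.creatinine):
        creatinine_events = stage_creatinine(
            episode.creatinine[["time_h", "value"]].to_numpy(),
            baseline,
            delta_window_h=config.delta_window_h,
            ratio_window_h=config.ratio_window_h,
        )
    dialysis_events = stage_dialysis(episode.dialysis_times_h)
    return combine_assessment(
        urine_events,
        creatinine_events,
        dialysis_events,
        tie_break=config.tie_break,
        patient_id=episode.patient_id,
    )


def assess_cohort(episodes, config: KdigoConfig | None = None):
    """Assess every episode and summarize cohort-level detection statistics.

    Returns ``(assessments, summary)`` where the summary documents its
    denominators: stage distributions and criterion attribution are fractions
    over AKI patients; incidence over all assessed episodes.
    """
    config = config or KdigoConfig()
    assessments = [assess_episode(ep, config) for ep in episodes]
    n = len(assessments)
    aki = [a for a in assessments if a.has_aki]
    n_aki = len(aki)

    def _dist(stages):
        return {s: (sum(1 for x in stages if x == s) / n_aki if n_aki else float("nan"))
                for s in (1, 2, 3)}

    def _median_iqr(xs):
        if not xs:
            return {"median": float("nan"), "q1": float("nan"), "q3": float("nan")}
        q1, med, q3 = np.percentile(xs, [25, 50, 75])
        return {"median": float(med), "q1": float(q1), "q3": float(q3)}

    summary = {
        "n": n,
        "n_aki": n_aki,
        "incidence": n_aki / n if n else float("nan"),
        "first_stage_dist": _dist([a.first_stage for a in aki]),
        "max_stage_dist": _dist([a.max_stage for a in aki]),
        "first_time_h": _median_iqr([a.first_time_h for a in aki]),
        "max_time_h": _median_iqr([a.max_time_h for a in aki]),
        "criterion_attribution": {
            c: (sum(1 for a in aki if a.trigger_criterion == c) / n_aki if n_aki else float("nan"))
            for c in CRITERIA
        },
    }
    return assessments, summary
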