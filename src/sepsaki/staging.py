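"""AKI diagnosis and three-stage grading for sepsis patients.

Implements a KDIGO-style rules engine over timestamped serum-creatinine
(SCr, μmol/L) series and urine-output epochs (ml/kg/h):

* a *comprehensive* criterion flagging any AKI — an absolute SCr rise
  within 48 h, a ratio-to-baseline rise within one week, or sustained
  oliguria;
* a *staging* criterion assigning grade 1–3 from the worst SCr ratio,
  absolute SCr, or oliguria/anuria duration observed;
* absorbing overrides: renal replacement therapy, or paediatric patients
  (age < 18) with GFR below 31 ml/min/m², are always stage 3.

The baseline creatinine is the patient's historical value when known,
otherwise the first measurement collected on admission.  Every numeric
cut-off lives in :class:`StagingThresholds` and can be reconfigured; the
defaults are the published table values verbatim, including their quirks
(the comprehensive criterion uses 27.5 μmol/L / 1.8× where stage 1 uses
27.1 μmol/L / 1.6×, and the stage-2 SCr band collapses to exactly 2.3×).

Ratio comparisons carry a relative tolerance of 1e-9 so that "2.3 times
baseline" is reachable at exactly 2.3 (stage 2) while anything beyond the
tolerance above 2.3 is stage 3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

from .exceptions import ValidationError

HOURS_PER_WEEK = 168.0
HOURS_PER_DAY = 24.0

__all__ = [
    "ScrMeasurement", "UrineEpoch", "PatientTimeline", "StagingThresholds",
    "FiredCriterion", "StagingResult", "baseline_scr", "scr_stage",
    "urine_stage", "comprehensive_aki", "stage_aki",
]


@dataclass(frozen=True)
class ScrMeasurement:
    """One serum-creatinine draw: `time` in hours since admission,
    `value` in μmol/L (must be positive)."""
    time: float
    value: float

    def __post_init__(self):
        if self.time < 0:
            raise ValidationError(f"SCr time must be >= 0, got {self.time}")
        if not self.value > 0:
            raise ValidationError(
                f"SCr value must be positive, got {self.value}")


@dataclass(frozen=True)
class UrineEpoch:
    """Piecewise-constant urine-output epoch [start, end) in hours with
    `rate` in ml/kg/h."""
    start: float
    end: float
    rate: float

    def __post_init__(self):
        if not self.end > self.start:
            raise ValidationError(
                f"urine epoch must have end > start, got "
                f"[{self.start}, {self.end})")
        if self.rate < 0:
            raise ValidationError(
                f"urine rate must be >= 0, got {self.rate}")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class PatientTimeline:
    """Longitudinal record for one patient.

    Measurements and epochs are sorted on construction, so input order is
    irrelevant; duplicate SCr timestamps or overlapping urine epochs are
    rejected.
    """
    patient_id: str
    scr: Sequence[ScrMeasurement]
    urine: Sequence[UrineEpoch] = ()
    historical_baseline_scr: Optional[float] = None
    age: float = 50.0
    rrt: bool = False
    gfr: Optional[float] = None

    def __post_init__(self):
        if len(self.scr) == 0:
            raise ValidationError(
                f"patient {self.patient_id!r}: at least one SCr "
                "measurement is required")
        if self.age < 0:
            raise ValidationError(
                f"patient {self.patient_id!r}: age must be >= 0")
        if (self.historical_baseline_scr is not None
                and not self.historical_baseline_scr > 0):
            raise ValidationError(
                f"patient {self.patient_id!r}: historical baseline SCr "
                "must be positive")
        scr = tuple(sorted(self.scr, key=lambda m: m.time))
        for a, b in zip(scr, scr[1:]):
            if b.time <= a.time:
                raise ValidationError(
                    f"patient {self.patient_id!r}: SCr times must be "
                    f"strictly increasing (duplicate at t={b.time})")
        urine = tuple(sorted(self.urine, key=lambda e: e.start))
        for a, b in zip(urine, urine[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"patient {self.patient_id!r}: urine epochs overlap "
                    f"at t={b.start}")
        object.__setattr__(self, "scr", scr)
        object.__setattr__(self, "urine", urine)


@dataclass(frozen=True)
class StagingThresholds:
    """All numeric cut-offs of the diagnostic table (μmol/L, ratios,
    ml/kg/h, hours).  Defaults reproduce the published figures exactly."""

    # comprehensive criterion
    comp_delta48_umol: float = 27.5      # SCr rise within 48 h
    comp_ratio: float = 1.8              # x baseline within 1 week
    comp_uo_rate: float = 0.46           # ml/kg/h
    comp_uo_hours: float = 5.0           # sustained at least this long
    # stage 1
    s1_ratio: float = 1.6
    s1_rise_umol: float = 27.1           # 48-h rise, mirrors comp window
    s1_uo_rate: float = 0.46
    s1_uo_min_hours: float = 5.0
    s1_uo_max_hours: float = 10.0
    # stage 2
    s2_ratio: float = 2.3
    s2_uo_rate: float = 0.46
    s2_uo_hours: float = 10.0            # strictly more than
    # stage 3
    s3_ratio: float = 2.3                # strictly more than
    s3_abs_umol: float = 427.1
    s3_uo_rate: float = 0.26
    s3_uo_hours: float = 24.0            # strictly more than
    s3_anuria_hours: float = 12.0        # strictly more than
    # paediatric override
    pediatric_age: float = 18.0
    pediatric_gfr: float = 31.0
    # relative tolerance for ratio / threshold comparisons
    rtol: float = 1e-9

    def __post_init__(self):
        for name in ("comp_delta48_umol", "comp_ratio", "comp_uo_rate",
                     "comp_uo_hours", "s1_ratio", "s1_rise_umol",
                     "s1_uo_rate", "s1_uo_min_hours", "s1_uo_max_hours",
                     "s2_ratio", "s2_uo_rate", "s2_uo_hours", "s3_ratio",
                     "s3_abs_umol", "s3_uo_rate", "s3_uo_hours",
                     "s3_anuria_hours", "pediatric_age", "pediatric_gfr"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"threshold {name} must be positive")
        if not (self.s1_ratio <= self.s2_ratio <= self.s3_ratio):
            raise ValidationError("stage ratios must be non-decreasing")

    # tolerance-aware comparisons: `ge` admits equality to within rtol,
    # `gt` demands exceeding the threshold beyond rtol
    def ge(self, value: float, threshold: float) -> bool:
        return value >= threshold * (1.0 - self.rtol)

    def gt(self, value: float, threshold: float) -> bool:
        return value > threshold * (1.0 + self.rtol)


@dataclass(frozen=True)
class FiredCriterion:
    """A satisfied rule: its identifier, the triggering time window in
    hours, and the value that crossed the cut-off."""
    criterion: str
    window: tuple[float, float]
    value: float


@dataclass(frozen=True)
class StagingResult:
    patient_id: str
    stage: int
    comprehensive_positive: bool
    fired_criteria: tuple[FiredCriterion, ...] = ()

    def __post_init__(self):
        if self.stage not in (0, 1, 2, 3):
            raise ValidationError(f"stage must be in 0..3, got {self.stage}")


def baseline_scr(timeline: PatientTimeline) -> float:
    """Baseline creatinine: the historical value when available, else the
    first value collected on admission."""
    if timeline.historical_baseline_scr is not None:
        return timeline.historical_baseline_scr
    return timeline.scr[0].value


def _week_window(timeline: PatientTimeline) -> tuple[float, ...]:
    """Indices of SCr measurements within one week of the first draw."""
    t0 = timeline.scr[0].time
    return tuple(i for i, m in enumerate(timeline.scr)
                 if m.time - t0 <= HOURS_PER_WEEK)


def _rise_48h(timeline: PatientTimeline, j: int) -> float:
    """SCr rise at measurement j over the running 48-h minimum:
    scr_j - min{scr_i : i <= j, t_j - t_i <= 48 h}."""
    mj = timeline.scr[j]
    lo = min(m.value for m in timeline.scr[:j + 1]
             if mj.time - m.time <= 48.0)
    return mj.value - lo


def scr_stage(timeline: PatientTimeline,
              thresholds: StagingThresholds = StagingThresholds(),
              _fired: Optional[list] = None) -> int:
    """Highest creatinine-based stage satisfied within one week of
    baseline."""
    th = thresholds
    base = baseline_scr(timeline)
    stage = 0
    for j in _week_window(timeline):
        m = timeline.scr[j]
        ratio = m.value / base
        rise = _rise_48h(timeline, j)
        window = (timeline.scr[0].time, m.time)
        if th.gt(ratio, th.s3_ratio) or th.ge(m.value, th.s3_abs_umol):
            stage = max(stage, 3)
            if _fired is not None:
                which = ("scr_ratio_gt_stage3"
                         if th.gt(ratio, th.s3_ratio) else "scr_abs_stage3")
                _fired.append(FiredCriterion(which, window, m.value))
        elif th.ge(ratio, th.s2_ratio):
            stage = max(stage, 2)
            if _fired is not None:
                _fired.append(
                    FiredCriterion("scr_ratio_stage2", window, ratio))
        elif th.ge(ratio, th.s1_ratio) or th.ge(rise, th.s1_rise_umol):
            stage = max(stage, 1)
            if _fired is not None:
                which = ("scr_ratio_stage1" if th.ge(ratio, th.s1_ratio)
                         else "scr_rise48_stage1")
                _fired.append(FiredCriterion(
                    which, window,
                    ratio if which == "scr_ratio_stage1" else rise))
    return stage


def _max_run(urine: Sequence[UrineEpoch], predicate) -> tuple[float, tuple]:
    """Longest contiguous duration over epochs satisfying `predicate`.

    Epochs are half-open [start, end); a gap between consecutive epochs
    breaks contiguity.  Returns (duration, (start, end)) of the best run.
    """
    best, best_win = 0.0, (0.0, 0.0)
    run_start, run_end = None, None
    for e in urine:
        ok = predicate(e.rate)
        contiguous = run_end is not None and e.start == run_end
        if ok and contiguous:
            run_end = e.end
        elif ok:
            run_start, run_end = e.start, e.end
        else:
            run_start, run_end = None, None
        if ok and run_end - run_start > best:
            best, best_win = run_end - run_start, (run_start, run_end)
    return best, best_win


def urine_stage(timeline: PatientTimeline,
                thresholds: StagingThresholds = StagingThresholds(),
                _fired: Optional[list] = None) -> int:
    """Oliguria/anuria-based stage from maximal contiguous low-output
    durations."""
    th = thresholds
    dur46, win46 = _max_run(timeline.urine, lambda r: r < th.s1_uo_rate)
    dur26, win26 = _max_run(timeline.urine, lambda r: r < th.s3_uo_rate)
    dur0, win0 = _max_run(timeline.urine, lambda r: r == 0.0)
    if th.gt(dur26, th.s3_uo_hours) or th.gt(dur0, th.s3_anuria_hours):
        if _fired is not None:
            if th.gt(dur26, th.s3_uo_hours):
                _fired.append(
                    FiredCriterion("uo_stage3_oliguria", win26, dur26))
            if th.gt(dur0, th.s3_anuria_hours):
                _fired.append(FiredCriterion("uo_stage3_anuria", win0, dur0))
        return 3
    if th.gt(dur46, th.s2_uo_hours):
        if _fired is not None:
            _fired.append(FiredCriterion("uo_stage2", win46, dur46))
        return 2
    if th.ge(dur46, th.s1_uo_min_hours):
        if _fired is not None:
            _fired.append(FiredCriterion("uo_stage1", win46, dur46))
        return 1
    return 0


def comprehensive_aki(timeline: PatientTimeline,
                      thresholds: StagingThresholds = StagingThresholds(),
                      conjunction: Literal["and", "or"] = "or",
                      _fired: Optional[list] = None) -> bool:
    """Comprehensive (any-AKI) criterion.

    Creatinine part: a 48-h rise above `comp_delta48_umol` and/or a
    ratio-to-baseline at least `comp_ratio` within one week, combined by
    `conjunction` (default "or").  The result is OR'd with the urine
    criterion: output below `comp_uo_rate` sustained at least
    `comp_uo_hours`.
    """
    if conjunction not in ("and", "or"):
        raise ValidationError(
            f"conjunction must be 'and' or 'or', got {conjunction!r}")
    th = thresholds
    base = baseline_scr(timeline)
    delta_hit = ratio_hit = False
    delta_win = ratio_win = (0.0, 0.0)
    delta_val = ratio_val = 0.0
    for j in _week_window(timeline):
        m = timeline.scr[j]
        rise = _rise_48h(timeline, j)
        ratio = m.value / base
        if th.gt(rise, th.comp_delta48_umol) and rise > delta_val:
            delta_hit, delta_val = True, rise
            delta_win = (timeline.scr[0].time, m.time)
        if th.ge(ratio, th.comp_ratio) and ratio > ratio_val:
            ratio_hit, ratio_val = True, ratio
            ratio_win = (timeline.scr[0].time, m.time)
    scr_hit = (delta_hit and ratio_hit) if conjunction == "and" \
        else (delta_hit or ratio_hit)
    dur46, win46 = _max_run(timeline.urine,
                            lambda r: r < th.comp_uo_rate)
    uo_hit = th.ge(dur46, th.comp_uo_hours)
    if _fired is not None:
        if scr_hit and delta_hit:
            _fired.append(
                FiredCriterion("comp_delta48", delta_win, delta_val))
        if scr_hit and ratio_hit:
            _fired.append(
                FiredCriterion("comp_ratio_week", ratio_win, ratio_val))
        if uo_hit:
            _fired.append(FiredCriterion("comp_oliguria", win46, dur46))
    return scr_hit or uo_hit


def stage_aki(timeline: PatientTimeline,
              thresholds: StagingThresholds = StagingThresholds(),
              conjunction: Literal["and", "or"] = "or") -> StagingResult:
    """Full staging: max of the SCr and urine stages, with the RRT and
    paediatric-GFR overrides forcing stage 3.  Records every satisfied
    rule with its triggering window."""
    fired: list[FiredCriterion] = []
    s_scr = scr_stage(timeline, thresholds, _fired=fired)
    s_uo = urine_stage(timeline, thresholds, _fired=fired)
    comp = comprehensive_aki(timeline, thresholds, conjunction,
                             _fired=fired)
    stage = max(s_scr, s_uo)
    horizon = max([m.time for m in timeline.scr]
                  + [e.end for e in timeline.urine])
    if timeline.rrt:
        stage = 3
        fired.append(FiredCriterion("rrt_override", (0.0, horizon), 1.0))
    if (timeline.age < thresholds.pediatric_age
            and timeline.gfr is not None
            and timeline.gfr < thresholds.pediatric_gfr):
        stage = 3
        fired.append(FiredCriterion("pediatric_gfr_override",
                                    (0.0, horizon), timeline.gfr))
    return StagingResult(patient_id=timeline.patient_id, stage=stage,
                         comprehensive_positive=comp,
                         fired_criteria=tuple(fired))
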