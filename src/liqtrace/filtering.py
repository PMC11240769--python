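"""Baseline-relative fold-change trajectories and the triple candidate filter.

For each patient, every feature's expression over the clinical follow-up is
summarized as fold changes (FC) relative to a pre-surgery blood baseline.  A
candidate recurrence marker must then survive three sequential filters:

1. *Expressed before surgery* — at least ``min_norm_count`` normalized counts
   in every pre-surgery blood sample and, when a tumor-tissue sample exists,
   in the tumor sample too (the tumor requirement ties the blood signal to the
   tumor; it is dropped automatically for patients without usable tumor RNA).
2. *Downregulated after resection* — FC at or below ``fc_down`` (default 0.5,
   i.e. at least 2-fold down) in at least ``frac_down`` of the post-surgery
   samples (default half; recurrence samples do not count here).
3. *Rebound at recurrence* — FC at or above ``fc_recur`` (default 1, back to
   or above the pre-surgery level) in at least one recurrence sample under the
   default ``any`` rule; ``majority`` and ``all`` are stricter options.

The filters are applied as set intersections in order, so the cascade counts
(universe, filter 1, filters 1-2, filters 1-3) are non-increasing by
construction.  Candidates are the features surviving all three filters.

The half-of-samples rule in filter 2 is compared with ``>=``: with two
post-surgery samples, one sufficiently downregulated sample suffices.  Both
fold-change boundaries are inclusive (FC <= 0.5 counts as down, FC >= 1 as
rebound).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from liqtrace.core_data import Phase, SampleRecord, StudyTable, Tissue
from liqtrace.normalization import compute_size_factors, normalize

log = logging.getLogger(__name__)


class RecurrenceRule(str, enum.Enum):
    ANY = "any"
    MAJORITY = "majority"
    ALL = "all"


class TumorRequirement(str, enum.Enum):
    AUTO = "auto"          # require tumor expression when a tumor sample exists
    BLOOD_ONLY = "blood_only"


class PreRule(str, enum.Enum):
    EACH = "each"          # threshold met in every pre-surgery blood sample
    MEAN = "mean"          # threshold met by the mean across them


class NormalizationScope(str, enum.Enum):
    PER_PATIENT = "per_patient"
    COHORT = "cohort"


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the triple filter; the defaults are the published ones."""

    min_norm_count: float = 10.0
    fc_down: float = 0.5
    frac_down: float = 0.5
    fc_recur: float = 1.0
    recur_rule: RecurrenceRule = RecurrenceRule.ANY
    tumor_requirement: TumorRequirement = TumorRequirement.AUTO
    pre_rule: PreRule = PreRule.EACH

    def __post_init__(self) -> None:
        object.__setattr__(self, "recur_rule", RecurrenceRule(self.recur_rule))
        object.__setattr__(self, "tumor_requirement", TumorRequirement(self.tumor_requirement))
        object.__setattr__(self, "pre_rule", PreRule(self.pre_rule))
        if self.min_norm_count < 0:
            raise ValueError("min_norm_count must be >= 0")
        if not 0 < self.fc_down <= 1:
            raise ValueError("fc_down must be in (0, 1]")
        if not 0 < self.frac_down <= 1:
            raise ValueError("frac_down must be in (0, 1]")
        if self.fc_recur <= 0:
            raise ValueError("fc_recur must be > 0")


@dataclass(frozen=True)
class FoldChangeTrajectory:
    """One feature's baseline and per-sample fold changes for one patient.

    ``fc`` maps every non-baseline blood sample (post-surgery and recurrence)
    to normalized count / baseline.  When the baseline is zero the trajectory
    is undefined (``defined`` is False, ``fc`` empty) and can pass no filter.
    """

    feature_id: str
    patient_id: str
    baseline: float
    fc: Mapping[str, float] = field(default_factory=dict)

    @property
    def defined(self) -> bool:
        return self.baseline > 0


@dataclass
class CandidateSet:
    """Per-patient filter-cascade outcome."""

    patient_id: str
    universe_size: int
    pass_f1: frozenset[str]
    pass_f2: frozenset[str]
    pass_f3: frozenset[str]
    has_recurrence_sample: bool = True

    @property
    def candidates(self) -> frozenset[str]:
        return self.pass_f3

    @property
    def cascade_counts(self) -> tuple[int, int, int, int]:
        return (self.universe_size, len(self.pass_f1), len(self.pass_f2), len(self.pass_f3))


def _patient_records(
    samples: Sequence[SampleRecord], patient_id: str
) -> list[SampleRecord]:
    recs = [r for r in samples if r.patient_id == patient_id]
    if not recs:
        raise ValueError(f"no samples for patient {patient_id!r}")
    return recs


def _blood(recs: Iterable[SampleRecord], phase: Phase) -> list[SampleRecord]:
    return [r for r in recs if r.is_blood and r.phase is phase]


def compute_fold_changes(
    norm: pd.DataFrame, samples: Sequence[SampleRecord], patient_id: str
) -> list[FoldChangeTrajectory]:
    """Fold-change trajectories for one patient.

    The baseline is the arithmetic mean of normalized counts over the
    patient's pre-surgery blood samples; fold changes are computed for every
    post-surgery and recurrence blood sample.  Tumor columns are excluded.
    """
    recs = _patient_records(samples, patient_id)
    pre = _blood(recs, Phase.PRE_SURGERY)
    if not pre:
        raise ValueError(f"patient {patient_id!r} has no pre-surgery blood sample")
    follow = _blood(recs, Phase.POST_SURGERY) + _blood(recs, Phase.RECURRENCE)
    baseline = norm[[r.sample_id for r in pre]].mean(axis=1)
    out: list[FoldChangeTrajectory] = []
    follow_ids = [r.sample_id for r in follow]
    follow_vals = norm[follow_ids].to_numpy() if follow_ids else np.empty((len(norm), 0))
    base = baseline.to_numpy()
    for i, fid in enumerate(norm.index):
        b = float(base[i])
        if b > 0:
            fc = {sid: float(follow_vals[i, k] / b) for k, sid in enumerate(follow_ids)}
        else:
            fc = {}
        out.append(FoldChangeTrajectory(str(fid), patient_id, b, fc))
    return out


def filter1_expressed(
    norm: pd.DataFrame,
    samples: Sequence[SampleRecord],
    cfg: FilterConfig,
    patient_id: str,
) -> frozenset[str]:
    """Features expressed at/above threshold before surgery (blood, and tumor if present)."""
    recs = _patient_records(samples, patient_id)
    pre_blood = _blood(recs, Phase.PRE_SURGERY)
    if not pre_blood:
        raise ValueError(f"patient {patient_id!r} has no pre-surgery blood sample")
    cols = norm[[r.sample_id for r in pre_blood]]
    if cfg.pre_rule is PreRule.MEAN:
        ok = cols.mean(axis=1) >= cfg.min_norm_count
    else:
        ok = (cols >= cfg.min_norm_count).all(axis=1)
    tumor = [r for r in recs if r.tissue is Tissue.TUMOR]
    if tumor and cfg.tumor_requirement is TumorRequirement.AUTO:
        ok &= norm[tumor[0].sample_id] >= cfg.min_norm_count
    return frozenset(str(f) for f in norm.index[ok])


def _fraction_pass(values: list[float], predicate) -> float:
    if not values:
        return 0.0
    return sum(1 for v in values if predicate(v)) / len(values)


def filter2_downregulated(
    trajectories: Iterable[FoldChangeTrajectory],
    samples: Sequence[SampleRecord],
    cfg: FilterConfig,
) -> frozenset[str]:
    """Features at least 1/fc_down-fold down in >= frac_down of post-surgery samples."""
    post_ids = {
        r.sample_id for r in samples if r.is_blood and r.phase is Phase.POST_SURGERY
    }
    passed = set()
    for traj in trajectories:
        if not traj.defined:
            continue
        vals = [v for sid, v in traj.fc.items() if sid in post_ids]
        if not vals:
            continue
        frac = _fraction_pass(vals, lambda v: v <= cfg.fc_down)
        if frac >= cfg.frac_down:
            passed.add(traj.feature_id)
    return frozenset(passed)


def filter3_recurrence(
    trajectories: Iterable[FoldChangeTrajectory],
    samples: Sequence[SampleRecord],
    cfg: FilterConfig,
) -> frozenset[str]:
    """Features rebounding to >= fc_recur in recurrence samples (rule: any/majority/all)."""
    rec_ids = {
        r.sample_id for r in samples if r.is_blood and r.phase is Phase.RECURRENCE
    }
    passed = set()
    for traj in trajectories:
        if not traj.defined:
            continue
        vals = [v for sid, v in traj.fc.items() if sid in rec_ids]
        if not vals:
            continue
        n_up = sum(1 for v in vals if v >= cfg.fc_recur)
        if cfg.recur_rule is RecurrenceRule.ANY:
            ok = n_up >= 1
        elif cfg.recur_rule is RecurrenceRule.MAJORITY:
            ok = n_up > len(vals) / 2
        else:
            ok = n_up == len(vals)
        if ok:
            passed.add(traj.feature_id)
    return frozenset(passed)


def run_triple_filter(
    study: StudyTable,
    cfg: FilterConfig | None = None,
    *,
    scope: NormalizationScope | str = NormalizationScope.PER_PATIENT,
    positive_subset: bool = False,
) -> dict[str, CandidateSet]:
    """Normalize, compute trajectories, and apply filters 1-3 per patient.

    Normalization defaults to per-patient scope (each patient's blood and
    tumor columns are normalized jointly, keeping the expression threshold
    comparable across that patient's samples); ``scope="cohort"`` normalizes
    all columns at once instead.  Patients lacking a recurrence sample yield
    no candidates (filter 3 is skipped and logged).  One patient's failure is
    logged and does not abort the others.
    """
    cfg = cfg or FilterConfig()
    scope = NormalizationScope(scope)
    results: dict[str, CandidateSet] = {}

    cohort_norm: pd.DataFrame | None = None
    if scope is NormalizationScope.COHORT:
        sf = compute_size_factors(study.matrix, positive_subset=positive_subset)
        cohort_norm = normalize(study.matrix, sf)

    for pid in study.patient_ids:
        try:
            recs = study.samples_for(pid)
            ids = [r.sample_id for r in recs]
            if cohort_norm is not None:
                norm = cohort_norm[ids]
            else:
                sub = study.patient_matrix(pid)
                sf = compute_size_factors(sub, positive_subset=positive_subset)
                norm = normalize(sub, sf)
            f1 = filter1_expressed(norm, recs, cfg, pid)
            trajs = compute_fold_changes(norm, recs, pid)
            f2 = f1 & filter2_downregulated(trajs, recs, cfg)
            has_rec = any(r.is_blood and r.phase is Phase.RECURRENCE for r in recs)
            if has_rec:
                f3 = f2 & filter3_recurrence(trajs, recs, cfg)
            else:
                log.info("patient %s has no recurrence sample; filter 3 skipped, no candidates", pid)
                f3 = frozenset()
            results[pid] = CandidateSet(
                patient_id=pid,
                universe_size=len(study.matrix.feature_ids),
                pass_f1=f1,
                pass_f2=f2,
                pass_f3=f3,
                has_recurrence_sample=has_rec,
            )
        except Exception:
            log.exception("patient %s failed the filter cascade; marked incomplete", pid)
    return results


__all__ = [
    "CandidateSet",
    "FilterConfig",
    "FoldChangeTrajectory",
    "NormalizationScope",
    "PreRule",
    "RecurrenceRule",
    "TumorRequirement",
    "compute_fold_changes",
    "filter1_expressed",
    "filter2_downregulated",
    "filter3_recurrence",
    "run_triple_filter",
]
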