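"""Synthetic longitudinal whole-blood count studies with known ground truth.

The generator emulates the statistical structure the screening pipeline
assumes, without claiming to reproduce any real cohort:

* a latent *tumor-burden trajectory* per sample — high before surgery (1.0),
  zero after resection, rebounding at recurrence (default back to 1.0, the
  weakest rebound the recurrence filter should accept in expectation);
* *signal* features whose mean tracks that burden: ``mu_i * (1 + alpha * b)``,
  so with the default effect size ``alpha = 3`` a signal feature's expected
  post/pre fold change is 1/(1+alpha) = 0.25, i.e. within the 2-fold-down
  filter by construction;
* *surgery-response* features transiently elevated only in early post-surgery
  samples, modeling acute surgical effects;
* a *masking* knob: setting the early-post-surgery burden above zero keeps
  signal features partially elevated in early draws, emulating how acute
  surgical effects can hide tumor-associated downregulation shortly after
  surgery;
* overdispersed counts (negative binomial with configurable size parameter)
  around log-normally distributed feature means, times a log-normal per-sample
  depth factor that the median-of-ratios normalization must absorb.

Default patient timelines replicate the seven designs of the reference study
(one pre-surgery draw; one to four post-surgery draws; one or two
recurrence-phase draws, one of which precedes the diagnosis day; tumor tissue
available for patients 1-4 only), so downstream code is exercised on the edge
cases by default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from liqtrace.core_data import (
    CountMatrix,
    FeatureKind,
    Phase,
    SampleRecord,
    StudyTable,
    Tissue,
    validate_study,
    write_counts,
    write_metadata,
)
from liqtrace.filtering import CandidateSet

LABELS = ("signal", "surgery_response", "background")


@dataclass(frozen=True)
class TimelineSample:
    """One planned blood draw: phase, day relative to surgery, and (for
    recurrence-phase draws) day relative to the recurrence diagnosis."""

    phase: Phase
    day_rel_surgery: int
    day_rel_recurrence: int | None = None


@dataclass(frozen=True)
class PatientTimeline:
    patient_id: str
    samples: tuple[TimelineSample, ...]
    has_tumor: bool = False

    def __post_init__(self) -> None:
        if not any(s.phase is Phase.PRE_SURGERY for s in self.samples):
            raise ValueError(f"timeline for {self.patient_id!r} has no pre-surgery sample")


def default_timelines() -> list[PatientTimeline]:
    """The seven reference designs (days of blood sampling per patient).

    Recurrence-diagnosis days relative to surgery are not part of the
    published design; plausible values after each patient's last post-surgery
    draw are used.  Only the post-surgery days matter to the mean model.
    """
    P, T = Phase, TimelineSample

    def pre(day):
        return T(P.PRE_SURGERY, day)

    def post(day):
        return T(P.POST_SURGERY, day)

    def rec(day, drr):
        return T(P.RECURRENCE, day, drr)

    return [
        PatientTimeline("P1", (pre(-1), post(5), post(84), rec(260, 3)), has_tumor=True),
        PatientTimeline("P2", (pre(-1), post(6), post(28), rec(121, 1)), has_tumor=True),
        PatientTimeline(
            "P3", (pre(-1), post(6), post(19), post(29), post(97), rec(150, 0)), has_tumor=True
        ),
        PatientTimeline("P4", (pre(-1), post(7), rec(90, 0)), has_tumor=True),
        PatientTimeline("P5", (pre(-5), post(28), post(97), post(184), rec(187, -13))),
        PatientTimeline("P6", (pre(-1), post(9), post(27), rec(60, 0), rec(74, 14))),
        PatientTimeline("P7", (pre(-1), post(7), post(17), post(23), rec(54, 4), rec(67, 17))),
    ]


def early_only_timelines(
    timelines: Sequence[PatientTimeline] | None = None, early_cutoff_days: int = 14
) -> list[PatientTimeline]:
    """Variant timelines whose post-surgery draws all fall in the early window.

    Keeps each patient's number of post-surgery samples but moves them to days
    5, 6, 7, ... (all <= the early cutoff); pre-surgery and recurrence draws
    are unchanged.  Used to study masking by acute surgical effects.
    """
    timelines = list(timelines) if timelines is not None else default_timelines()
    out = []
    for tl in timelines:
        k = 0
        new_samples = []
        for s in tl.samples:
            if s.phase is Phase.POST_SURGERY:
                day = 5 + k
                k += 1
                if day > early_cutoff_days:
                    raise ValueError("too many post-surgery samples for the early window")
                new_samples.append(TimelineSample(Phase.POST_SURGERY, day))
            else:
                new_samples.append(s)
        out.append(PatientTimeline(tl.patient_id, tuple(new_samples), tl.has_tumor))
    return out


@dataclass
class SimConfig:
    """Generator settings.

    ``masking`` is the residual burden seen by signal features in early
    post-surgery samples (0 = clean resection signal, 0.6 = strong acute
    surgical masking).  ``dispersion`` is the negative-binomial size
    parameter (variance = mu + mu^2 / size).  ``depth_sd`` is the log-normal
    standard deviation of per-sample library scaling.
    """

    n_patients: int = 7
    n_features: int = 2000
    n_signal: int = 50
    n_surgery_response: int = 50
    timelines: list[PatientTimeline] | None = None
    burden_pre: float = 1.0
    masking: float = 0.0
    burden_late_post: float = 0.0
    burden_recurrence: float = 1.0
    early_cutoff_days: int = 14
    alpha: float = 3.0
    baseline_log_mean: float = float(np.log(50.0))
    baseline_log_sd: float = 1.0
    dispersion: float = 10.0
    depth_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.n_signal + self.n_surgery_response > self.n_features:
            raise ValueError("n_signal + n_surgery_response must be <= n_features")
        if self.alpha < 0 or self.dispersion <= 0 or self.depth_sd < 0:
            raise ValueError("alpha >= 0, dispersion > 0, depth_sd >= 0 required")

    def resolved_timelines(self) -> list[PatientTimeline]:
        if self.timelines is not None:
            if len(self.timelines) != self.n_patients:
                raise ValueError("len(timelines) must equal n_patients")
            return list(self.timelines)
        base = default_timelines()
        out = []
        for i in range(self.n_patients):
            tl = base[i % len(base)]
            pid = tl.patient_id if self.n_patients <= len(base) else f"{tl.patient_id}x{i // len(base)}"
            out.append(PatientTimeline(pid, tl.samples, tl.has_tumor))
        return out

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        timelines = raw.pop("timelines", None)
        if timelines is not None:
            parsed = []
            for tl in timelines:
                samples = tuple(
                    TimelineSample(
                        Phase(s["phase"]),
                        int(s["day_rel_surgery"]),
                        None
                        if s.get("day_rel_recurrence") in (None, "")
                        else int(s["day_rel_recurrence"]),
                    )
                    for s in tl["samples"]
                )
                parsed.append(
                    PatientTimeline(tl["patient_id"], samples, bool(tl.get("has_tumor", False)))
                )
            raw["timelines"] = parsed
            raw.setdefault("n_patients", len(parsed))
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        if self.timelines is not None:
            raw["timelines"] = [
                {
                    "patient_id": tl.patient_id,
                    "has_tumor": tl.has_tumor,
                    "samples": [
                        {
                            "phase": s.phase.value,
                            "day_rel_surgery": s.day_rel_surgery,
                            "day_rel_recurrence": s.day_rel_recurrence,
                        }
                        for s in tl.samples
                    ],
                }
                for tl in self.timelines
            ]
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


@dataclass
class SyntheticStudy:
    study: StudyTable
    truth: dict[str, str]
    config: SimConfig

    def truth_set(self, label: str) -> frozenset[str]:
        if label not in LABELS:
            raise ValueError(f"unknown label {label!r}")
        return frozenset(f for f, lab in self.truth.items() if lab == label)

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_counts(self.study.matrix, out_dir / "counts.tsv")
        write_metadata(self.study.samples, out_dir / "meta.tsv")
        truth = pd.DataFrame(
            {"feature_id": list(self.truth), "label": list(self.truth.values())}
        )
        truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
        self.config.to_yaml(out_dir / "sim_config.yaml")


def _burden(cfg: SimConfig, rec: SampleRecord) -> float:
    if rec.tissue is Tissue.TUMOR:
        return 1.0
    if rec.phase is Phase.PRE_SURGERY:
        return cfg.burden_pre
    if rec.phase is Phase.RECURRENCE:
        return cfg.burden_recurrence
    if rec.day_rel_surgery <= cfg.early_cutoff_days:
        return cfg.masking
    return cfg.burden_late_post


def _surgery_response(cfg: SimConfig, rec: SampleRecord) -> float:
    if (
        rec.tissue is Tissue.BLOOD
        and rec.phase is Phase.POST_SURGERY
        and rec.day_rel_surgery <= cfg.early_cutoff_days
    ):
        return 1.0
    return 0.0


def simulate_study(cfg: SimConfig) -> SyntheticStudy:
    """Draw one study.  Identical config (including seed) gives an identical study."""
    rng = np.random.default_rng(cfg.seed)
    timelines = cfg.resolved_timelines()

    records: list[SampleRecord] = []
    for tl in timelines:
        counters = {Phase.PRE_SURGERY: 0, Phase.POST_SURGERY: 0, Phase.RECURRENCE: 0}
        for s in tl.samples:
            counters[s.phase] += 1
            short = {"pre_surgery": "pre", "post_surgery": "post", "recurrence": "rec"}[
                s.phase.value
            ]
            records.append(
                SampleRecord(
                    sample_id=f"{tl.patient_id}_{short}{counters[s.phase]}",
                    patient_id=tl.patient_id,
                    tissue=Tissue.BLOOD,
                    phase=s.phase,
                    day_rel_surgery=s.day_rel_surgery,
                    day_rel_recurrence=s.day_rel_recurrence,
                )
            )
        if tl.has_tumor:
            records.append(
                SampleRecord(
                    sample_id=f"{tl.patient_id}_tumor",
                    patient_id=tl.patient_id,
                    tissue=Tissue.TUMOR,
                    phase=Phase.PRE_SURGERY,
                    day_rel_surgery=0,
                )
            )

    n = cfg.n_features
    width = max(5, len(str(n)))
    feature_ids = [f"f{i:0{width}d}" for i in range(n)]
    labels = np.array(
        ["signal"] * cfg.n_signal
        + ["surgery_response"] * cfg.n_surgery_response
        + ["background"] * (n - cfg.n_signal - cfg.n_surgery_response)
    )
    truth = dict(zip(feature_ids, labels))

    mu = rng.lognormal(mean=cfg.baseline_log_mean, sigma=cfg.baseline_log_sd, size=n)
    is_signal = labels == "signal"
    is_sr = labels == "surgery_response"

    depth = rng.lognormal(mean=0.0, sigma=cfg.depth_sd, size=len(records))

    counts = np.empty((n, len(records)), dtype=np.int64)
    size = cfg.dispersion
    for j, rec in enumerate(records):
        b = _burden(cfg, rec)
        r = _surgery_response(cfg, rec)
        mult = np.ones(n)
        mult[is_signal] = 1.0 + cfg.alpha * b
        mult[is_sr] = 1.0 + cfg.alpha * r
        mean = mu * mult * depth[j]
        counts[:, j] = rng.negative_binomial(size, size / (size + mean))

    matrix = CountMatrix(
        pd.DataFrame(counts, index=feature_ids, columns=[r.sample_id for r in records]),
        FeatureKind.GENERIC,
    )
    study = validate_study(matrix, records)
    return SyntheticStudy(study=study, truth=truth, config=cfg)


@dataclass
class RecoveryMetrics:
    """Confusion counts of a candidate set against the signal ground truth."""

    tp: int = 0
    fp: int = 0
    n_signal: int = 0
    n_candidates: int = 0
    n_negatives: int = 0

    @property
    def sensitivity(self) -> float:
        return self.tp / self.n_signal if self.n_signal else 0.0

    @property
    def fdp(self) -> float:
        return self.fp / max(self.n_candidates, 1)

    @property
    def specificity(self) -> float:
        return (self.n_negatives - self.fp) / self.n_negatives if self.n_negatives else 1.0

    def __add__(self, other: "RecoveryMetrics") -> "RecoveryMetrics":
        return RecoveryMetrics(
            tp=self.tp + other.tp,
            fp=self.fp + other.fp,
            n_signal=self.n_signal + other.n_signal,
            n_candidates=self.n_candidates + other.n_candidates,
            n_negatives=self.n_negatives + other.n_negatives,
        )


@dataclass
class RecoveryReport:
    per_patient: dict[str, RecoveryMetrics]
    pooled: RecoveryMetrics


def _candidate_features(cs: CandidateSet | frozenset[str] | set[str]) -> frozenset[str]:
    if isinstance(cs, CandidateSet):
        return cs.candidates
    return frozenset(cs)


def evaluate_recovery(
    candidate_sets: Mapping[str, CandidateSet | frozenset[str] | set[str]],
    truth: Mapping[str, str],
    *,
    require_recurrence: bool = False,
) -> RecoveryReport:
    """Per-patient and pooled sensitivity / false-discovery proportion.

    Sensitivity is |candidates ∩ signal| / |signal|; the false-discovery
    proportion is |candidates \\ signal| / max(|candidates|, 1).  The pooled
    metrics aggregate the confusion counts over patients (micro-average).
    With ``require_recurrence`` patients whose cascade had no recurrence
    sample are left out of the pooled metrics.
    """
    signal = frozenset(f for f, lab in truth.items() if lab == "signal")
    negatives = len(truth) - len(signal)
    per_patient: dict[str, RecoveryMetrics] = {}
    pooled = RecoveryMetrics()
    for pid, cs in candidate_sets.items():
        feats = _candidate_features(cs)
        unknown = feats - truth.keys()
        if unknown:
            raise ValueError(f"candidates without truth labels: {sorted(unknown)[:5]}")
        tp = len(feats & signal)
        m = RecoveryMetrics(
            tp=tp,
            fp=len(feats) - tp,
            n_signal=len(signal),
            n_candidates=len(feats),
            n_negatives=negatives,
        )
        per_patient[pid] = m
        if require_recurrence and isinstance(cs, CandidateSet) and not cs.has_recurrence_sample:
            continue
        pooled = pooled + m
    return RecoveryReport(per_patient=per_patient, pooled=pooled)


def pool_recovery(metrics: Iterable[RecoveryMetrics]) -> RecoveryMetrics:
    """Pool confusion counts across patients, seeds, or studies."""
    total = RecoveryMetrics()
    for m in metrics:
        total = total + m
    return total


def reference_config(seed: int = 0, **overrides) -> SimConfig:
    """The package's reference evaluation scenario.

    Seven patients on the default timelines, 2000 features of which 50 are
    signal and 50 surgery-response, effect size alpha = 3, dispersion 10,
    depth_sd 0.3, no masking.  Keyword overrides adjust individual knobs
    (e.g. ``masking=0.6`` or alternative timelines).
    """
    params = dict(
        n_patients=7,
        n_features=2000,
        n_signal=50,
        n_surgery_response=50,
        alpha=3.0,
        dispersion=10.0,
        depth_sd=0.3,
        masking=0.0,
        seed=seed,
    )
    params.update(overrides)
    if "timelines" in params and params["timelines"] is not None:
        params["n_patients"] = len(params["timelines"])
    return SimConfig(**params)


def recovery_experiment(seeds: Iterable[int], **cfg_overrides) -> RecoveryMetrics:
    """Run the full pipeline on fresh studies for each seed and pool recovery.

    Only patients whose cascade includes a recurrence-phase sample contribute
    to the pooled confusion counts (the recurrence filter is undefined for
    the others).
    """
    from liqtrace.filtering import run_triple_filter  # local to avoid cycle at import time

    pooled = RecoveryMetrics()
    for seed in seeds:
        sim = simulate_study(reference_config(seed=seed, **cfg_overrides))
        results = run_triple_filter(sim.study)
        report = evaluate_recovery(results, sim.truth, require_recurrence=True)
        pooled = pooled + report.pooled
    return pooled


__all__ = [
    "LABELS",
    "PatientTimeline",
    "RecoveryMetrics",
    "RecoveryReport",
    "SimConfig",
    "SyntheticStudy",
    "TimelineSample",
    "default_timelines",
    "early_only_timelines",
    "evaluate_recovery",
    "pool_recovery",
    "simulate_study",
]
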