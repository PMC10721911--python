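"""Synthetic depression-trial generator with a latent placebo-propensity mixture.

Generates item-level HAMD-17 / MADRS trajectories for multi-arm randomized
trials in which each subject belongs to one of three latent responder classes:

* ``D-P-`` — responds to neither drug nor placebo,
* ``D+P+`` — responds non-specifically to any treatment (the placebo-effect class),
* ``D+P-`` — responds to active drug only (carries the drug-specific signal).

Pre-randomization (screening -> baseline) item changes carry information about
the latent class, with separation controlled by ``propensity_signal``; this is
the signal a downstream classifier can learn to predict placebo response.
Post-baseline improvement is class- and arm-dependent: the ``D+P+`` class
improves in every arm, ``D+P-`` improves only under active drug (by the arm's
true drug-specific effect), and ``D-P-`` improves in no arm.  The ground truth
(latent class and generative placebo-response probability) is kept separate
from the analysis tables so parameter recovery can be tested.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "ScaleName",
    "ScaleDefinition",
    "HAMD17",
    "MADRS",
    "ResponderClass",
    "Arm",
    "TrialDesign",
    "SubjectTrajectory",
    "DesignError",
    "design_from_mapping",
    "generate_trial",
    "true_propensity",
    "trajectories_to_frame",
    "truth_to_frame",
    "frame_to_trajectories",
    "sep360029_like",
    "sep380201_like",
]


class DesignError(ValueError):
    """Raised when a trial design violates its invariants."""


class ScaleName(str, enum.Enum):
    HAMD17 = "HAMD17"
    MADRS = "MADRS"


# Standard instrument item maxima.  HAMD-17: nine items scored 0-4 and eight
# scored 0-2 (max total 52); MADRS: ten items scored 0-6 (max total 60).
_HAMD17_ITEM_MAX = (4, 4, 4, 2, 2, 2, 4, 4, 4, 4, 4, 2, 2, 2, 4, 2, 2)
_MADRS_ITEM_MAX = (6,) * 10


@dataclass(frozen=True)
class ScaleDefinition:
    """A depression rating scale: named items with integer score ranges."""

    name: ScaleName
    n_items: int
    item_max: tuple[int, ...]
    # typical screening severity (total score) for a moderate-to-severe
    # depression trial population on this scale
    typical_screening_total: float = 22.0

    def __post_init__(self) -> None:
        expected = {ScaleName.HAMD17: 17, ScaleName.MADRS: 10}[self.name]
        if self.n_items != expected or len(self.item_max) != self.n_items:
            raise DesignError(
                f"{self.name.value} requires {expected} items, got {self.n_items}"
            )

    @property
    def max_total(self) -> int:
        return int(sum(self.item_max))

    @property
    def item_columns(self) -> list[str]:
        return [f"item_{i + 1:02d}" for i in range(self.n_items)]


HAMD17 = ScaleDefinition(ScaleName.HAMD17, 17, _HAMD17_ITEM_MAX, typical_screening_total=22.0)
MADRS = ScaleDefinition(ScaleName.MADRS, 10, _MADRS_ITEM_MAX, typical_screening_total=30.0)


class ClassLabel(str, enum.Enum):
    DminusPminus = "D-P-"
    DplusPplus = "D+P+"
    DplusPminus = "D+P-"


@dataclass(frozen=True)
class ResponderClass:
    label: ClassLabel
    prevalence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise DesignError(f"prevalence {self.prevalence} outside [0, 1]")


@dataclass(frozen=True)
class Arm:
    """A treatment arm with its true drug-specific effect.

    ``effect`` is the end-of-study improvement, in total-score points, that a
    drug-responsive-only (``D+P-``) subject gains in this arm over and above
    any non-specific response.  The placebo arm must have effect 0.
    """

    label: str
    effect: float = 0.0


# Generative constants (fractions of baseline total unless noted).  The
# placebo-effect class improves by 85% of its baseline total at EOS under any
# treatment, comfortably past the 50% responder threshold (matching the
# extraordinarily high end-of-study placebo response these trials show); the
# residual noise splits into a subject-level slope component and an
# occasion-level component whose EOS standard deviation equals ``noise_sd``.
PLACEBO_IMPROVEMENT_FRACTION = 0.85
SLOPE_SD_FRACTION = 0.6
OCCASION_SD_FRACTION = 0.8
# per-item mean of the pre-randomization (baseline - screening) change, in
# points, at propensity_signal = 1; calibrated so a large-sample classifier
# reaches a validation AUC near 0.9, the level the published analyses report
_PRERAND_DELTA_MEAN = {
    ClassLabel.DplusPplus: -0.50,  # early non-specific improvement
    ClassLabel.DplusPminus: 0.15,
    ClassLabel.DminusPminus: 0.15,
}
_PRERAND_DELTA_SD = 0.8
_SCREENING_TOTAL_SD = 3.0
_ITEM_ALLOC_SD = 0.5


@dataclass(frozen=True)
class TrialDesign:
    arms: tuple[Arm, ...]
    n_per_arm: int
    visit_weeks: tuple[float, ...]  # includes screening (<0) and baseline (0)
    eos_week: float
    class_mix: tuple[ResponderClass, ...]
    dropout_rate: float = 0.0
    propensity_signal: float = 1.0
    noise_sd: float = 6.0
    placebo_label: str = "placebo"
    mnar_strength: float = 0.0  # >0 makes dropout depend on last observed change

    def __post_init__(self) -> None:
        if self.n_per_arm < 2:
            raise DesignError("n_per_arm must be >= 2")
        placebo = [a for a in self.arms if a.label == self.placebo_label]
        if len(placebo) != 1:
            raise DesignError("design must contain exactly one placebo arm")
        if placebo[0].effect != 0.0:
            raise DesignError("the placebo arm cannot carry a drug-specific effect")
        if self.eos_week not in self.visit_weeks:
            raise DesignError(f"eos_week {self.eos_week} not in visit schedule")
        if not any(w < 0 for w in self.visit_weeks) or 0.0 not in self.visit_weeks:
            raise DesignError("schedule must include a screening (<0) and baseline (0) visit")
        total = sum(c.prevalence for c in self.class_mix)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise DesignError(f"class prevalences sum to {total}, expected 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise DesignError("dropout_rate must be in [0, 1)")
        if self.propensity_signal < 0:
            raise DesignError("propensity_signal must be >= 0")
        if self.noise_sd < 0:
            raise DesignError("noise_sd must be >= 0")

    @property
    def screening_week(self) -> float:
        return min(w for w in self.visit_weeks if w < 0)

    @property
    def post_baseline_weeks(self) -> tuple[float, ...]:
        return tuple(w for w in self.visit_weeks if w > 0)


@dataclass
class SubjectTrajectory:
    subject_id: str
    arm: str
    latent_class: ClassLabel
    item_scores: dict[float, np.ndarray]  # visit week -> integer item vector
    missing: set[float] = field(default_factory=set)

    def total(self, week: float) -> int:
        return int(self.item_scores[week].sum())

    @property
    def observed_weeks(self) -> list[float]:
        return sorted(self.item_scores)


def _time_fraction(week: float, eos_week: float) -> float:
    """Linear improvement ramp from baseline to EOS, flat afterwards."""
    return min(week / eos_week, 1.0)


def _expected_improvement(
    latent: ClassLabel, arm: Arm, baseline_total: float, week: float, design: TrialDesign
) -> float:
    f = _time_fraction(week, design.eos_week)
    if latent is ClassLabel.DplusPplus:
        return f * PLACEBO_IMPROVEMENT_FRACTION * baseline_total
    if latent is ClassLabel.DplusPminus:
        return f * arm.effect
    return 0.0


def _allocate_items(
    target_total: float, reference: np.ndarray, scale: ScaleDefinition, rng: np.random.Generator
) -> np.ndarray:
    """Distribute a continuous total over items proportional to a reference
    item profile, with jitter, then clamp-round to instrument bounds."""
    ref_total = reference.sum()
    if ref_total <= 0:
        shares = np.asarray(scale.item_max, dtype=float) / scale.max_total
    else:
        shares = reference / ref_total
    raw = target_total * shares + rng.normal(0.0, _ITEM_ALLOC_SD, scale.n_items)
    return np.clip(np.rint(raw), 0, scale.item_max).astype(int)


def generate_trial(
    design: TrialDesign, scale: ScaleDefinition, seed: int
) -> list[SubjectTrajectory]:
    """Simulate one trial; deterministic given (design, scale, seed)."""
    rng = np.random.default_rng(seed)
    classes = [c.label for c in design.class_mix]
    prevalences = [c.prevalence for c in design.class_mix]
    scr_week = design.screening_week
    post_weeks = design.post_baseline_weeks

    subjects: list[SubjectTrajectory] = []
    sid = 0
    for arm in design.arms:
        for _ in range(design.n_per_arm):
            sid += 1
            latent = classes[rng.choice(len(classes), p=prevalences)]

            # screening items around the scale's typical severity
            scr_total = rng.normal(scale.typical_screening_total, _SCREENING_TOTAL_SD)
            scr_total = float(np.clip(scr_total, 5.0, scale.max_total))
            shares = np.asarray(scale.item_max, dtype=float) / scale.max_total
            scr_items = np.clip(
                np.rint(scr_total * shares + rng.normal(0.0, _ITEM_ALLOC_SD, scale.n_items)),
                0,
                scale.item_max,
            ).astype(int)

            # pre-randomization change: class-shifted item deltas
            delta_mu = design.propensity_signal * _PRERAND_DELTA_MEAN[latent]
            deltas = rng.normal(delta_mu, _PRERAND_DELTA_SD, scale.n_items)
            base_items = np.clip(np.rint(scr_items + deltas), 0, scale.item_max).astype(int)
            base_total = float(base_items.sum())

            # post-baseline totals: class/arm mean trajectory + correlated noise
            slope_noise = rng.normal(0.0, SLOPE_SD_FRACTION * design.noise_sd)
            item_scores: dict[float, np.ndarray] = {
                scr_week: scr_items,
                0.0: base_items,
            }
            for week in post_weeks:
                f = _time_fraction(week, design.eos_week)
                improvement = _expected_improvement(latent, arm, base_total, week, design)
                eps = rng.normal(0.0, OCCASION_SD_FRACTION * design.noise_sd)
                total_w = base_total - improvement + f * slope_noise + eps
                total_w = float(np.clip(total_w, 0.0, scale.max_total))
                item_scores[week] = _allocate_items(total_w, base_items, scale, rng)

            subj = SubjectTrajectory(
                subject_id=f"S{sid:04d}",
                arm=arm.label,
                latent_class=latent,
                item_scores=item_scores,
            )

            # monotone dropout, never removing screening/baseline
            if post_weeks and rng.random() < design.dropout_rate:
                if design.mnar_strength > 0:
                    # tilt the dropout visit toward early visits for subjects
                    # who are not improving (missing-not-at-random stress mode)
                    changes = np.array(
                        [subj.item_scores[w].sum() - base_total for w in post_weeks]
                    )
                    logits = design.mnar_strength * changes / max(design.noise_sd, 1e-9)
                    probs = np.exp(logits - logits.max())
                    probs /= probs.sum()
                    first_missing = post_weeks[rng.choice(len(post_weeks), p=probs)]
                else:
                    first_missing = post_weeks[rng.integers(len(post_weeks))]
                for week in post_weeks:
                    if week >= first_missing:
                        subj.missing.add(week)
                        del subj.item_scores[week]
            subjects.append(subj)
    return subjects


def true_propensity(subject: SubjectTrajectory, design: TrialDesign) -> float:
    """Generative probability of a >=50% end-of-study improvement under placebo.

    Oracle for recovery tests only; the analysis pipeline never sees it.  Uses
    the pre-rounding normal model: EOS improvement under placebo is
    ``N(mu_c, noise_sd^2)`` with ``mu_c = PLACEBO_IMPROVEMENT_FRACTION *
    baseline_total`` for the placebo-effect class and 0 otherwise.
    """
    baseline_total = float(subject.item_scores[0.0].sum())
    mu = (
        PLACEBO_IMPROVEMENT_FRACTION * baseline_total
        if subject.latent_class is ClassLabel.DplusPplus
        else 0.0
    )
    threshold = 0.5 * baseline_total
    if design.noise_sd == 0:
        return 1.0 if mu >= threshold else 0.0
    return float(norm.sf((threshold - mu) / design.noise_sd))


def trajectories_to_frame(
    subjects: Sequence[SubjectTrajectory], scale: ScaleDefinition
) -> pd.DataFrame:
    """Long-format analysis table: one row per subject x observed visit."""
    rows = []
    for s in subjects:
        for week in s.observed_weeks:
            items = s.item_scores[week]
            row = {"subject_id": s.subject_id, "arm": s.arm, "visit_week": week}
            row.update(dict(zip(scale.item_columns, (int(v) for v in items))))
            row["total_score"] = int(items.sum())
            rows.append(row)
    return pd.DataFrame(rows)


def truth_to_frame(
    subjects: Sequence[SubjectTrajectory], design: TrialDesign
) -> pd.DataFrame:
    """Subject-level ground truth, kept apart from the analysis tables."""
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "latent_class": [s.latent_class.value for s in subjects],
            "true_propensity": [true_propensity(s, design) for s in subjects],
        }
    )


def frame_to_trajectories(
    frame: pd.DataFrame, scale: ScaleDefinition
) -> list[SubjectTrajectory]:
    """Rebuild trajectories from a long-format table (latent class unknown)."""
    subjects = []
    cols = scale.item_columns
    for sid, g in frame.groupby("subject_id", sort=True):
        item_scores = {
            float(r["visit_week"]): np.asarray([int(r[c]) for c in cols])
            for _, r in g.iterrows()
        }
        subjects.append(
            SubjectTrajectory(
                subject_id=str(sid),
                arm=str(g["arm"].iloc[0]),
                latent_class=ClassLabel.DminusPminus,  # placeholder; truth not in table
                item_scores=item_scores,
            )
        )
    return subjects


def design_from_mapping(mapping: dict) -> tuple[TrialDesign, ScaleDefinition]:
    """Build a (design, scale) pair from a plain mapping (YAML/JSON config).

    Expected keys: ``scale`` ("HAMD17" or "MADRS"), ``arms`` (list of
    ``{label, effect}``), ``n_per_arm``, ``visit_weeks``, ``eos_week``,
    ``class_mix`` (mapping of class label -> prevalence, labels "D-P-",
    "D+P+", "D+P-"), and optionally ``dropout_rate``, ``propensity_signal``,
    ``noise_sd``, ``placebo_label``, ``mnar_strength``.
    """
    scale = {"HAMD17": HAMD17, "MADRS": MADRS}[str(mapping["scale"]).upper().replace("-", "")]
    arms = tuple(
        Arm(str(a["label"]), float(a.get("effect", 0.0))) for a in mapping["arms"]
    )
    mix = tuple(
        ResponderClass(ClassLabel(label), float(prev))
        for label, prev in dict(mapping["class_mix"]).items()
    )
    optional = {
        k: mapping[k]
        for k in ("dropout_rate", "propensity_signal", "noise_sd",
                  "placebo_label", "mnar_strength")
        if k in mapping
    }
    design = TrialDesign(
        arms=arms,
        n_per_arm=int(mapping["n_per_arm"]),
        visit_weeks=tuple(float(w) for w in mapping["visit_weeks"]),
        eos_week=float(mapping["eos_week"]),
        class_mix=mix,
        **optional,
    )
    return design, scale


# ---------------------------------------------------------------------------
# Design presets.  The class mix uses a dominant placebo-effect class (the
# published propensity histograms put the large majority of subjects above
# p = 0.8) with the remainder split toward the drug-unresponsive class, whose
# reported range is 30-50% of non-resistant depression populations.
# ---------------------------------------------------------------------------

_DEFAULT_MIX = (
    ResponderClass(ClassLabel.DminusPminus, 0.30),
    ResponderClass(ClassLabel.DplusPplus, 0.55),
    ResponderClass(ClassLabel.DplusPminus, 0.15),
)


def sep360029_like(
    n_per_arm: int = 118,
    effect_active: float = 22.0,
    dropout_rate: float = 0.2,
    propensity_signal: float = 1.0,
    noise_sd: float = 6.0,
) -> tuple[TrialDesign, ScaleDefinition]:
    """Four-arm, 8-week HAMD-17 design: two null actives and one effective
    comparator, emulating a negative monotherapy trial."""
    design = TrialDesign(
        arms=(
            Arm("placebo", 0.0),
            Arm("drug_low", 0.0),
            Arm("drug_high", 0.0),
            Arm("comparator", effect_active),
        ),
        n_per_arm=n_per_arm,
        visit_weeks=(-1.0, 0.0, 1.0, 2.0, 4.0, 6.0, 8.0),
        eos_week=8.0,
        class_mix=_DEFAULT_MIX,
        dropout_rate=dropout_rate,
        propensity_signal=propensity_signal,
        noise_sd=noise_sd,
    )
    return design, HAMD17


def sep380201_like(
    n_per_arm: int = 93,
    effect_active: float = 22.0,
    dropout_rate: float = 0.2,
    propensity_signal: float = 1.0,
    noise_sd: float = 7.0,
) -> tuple[TrialDesign, ScaleDefinition]:
    """Three-arm, 6-week MADRS design: two equally effective doses whose
    signal is masked by a heavy placebo-effect majority (a failed-trial
    pattern)."""
    design = TrialDesign(
        arms=(
            Arm("placebo", 0.0),
            Arm("dose_200", effect_active),
            Arm("dose_400", effect_active),
        ),
        n_per_arm=n_per_arm,
        visit_weeks=(-1.0, 0.0, 1.0, 2.0, 4.0, 6.0),
        eos_week=6.0,
        class_mix=_DEFAULT_MIX,
        dropout_rate=dropout_rate,
        propensity_signal=propensity_signal,
        noise_sd=noise_sd,
    )
    return design, MADRS
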