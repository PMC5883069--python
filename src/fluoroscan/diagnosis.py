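"""Rule-based stress diagnosis from indicator trajectories.

Encodes the field's working ranges — PhiPSII normal near 0.4 and
stressed near 0.3; Fv/Fm normal near 0.8 with the PSII reaction center
affected below 0.75; healthy 550/510 above 1.5 — plus the trajectory
patterns that distinguish the stresses: drought shows an early
PhiPSII-only decline with Fv/Fm and 550/510 following only when severe;
nitrogen deficiency pulls all three down gradually with old leaves
leading, driving up the Fv/Fm standard deviation; disease is fast and
spatially patchy (clumped lesions), and ties against nitrogen
deficiency resolve to disease so that action precedes spread.
"""

from __future__ import annotations

import numpy as np
from dataclasses import dataclass, field
from typing import Sequence

from scipy import ndimage

from .indicators import INDICATORS, IndicatorMap, IndicatorSummary

LABELS = (
    "healthy",
    "drought_early",
    "drought_severe",
    "nitrogen_deficiency",
    "disease",
    "indeterminate",
)

EVIDENCE_FLAGS = (
    "phipsii_declining",
    "fvfm_below_affected",
    "ratio_below_normal",
    "heterogeneity_rising",
    "rapid_decline",
    "patchy_lesions",
)


class InsufficientDataError(ValueError):
    """Raised when a trajectory is too short to classify."""


@dataclass
class NormalRanges:
    """Working ranges of the three indicators (configurable)."""

    phipsii_normal: float = 0.40
    phipsii_stressed: float = 0.30
    fvfm_normal: float = 0.80
    fvfm_affected: float = 0.75
    ratio_normal_min: float = 1.5

    def __post_init__(self) -> None:
        if self.phipsii_stressed >= self.phipsii_normal:
            raise ValueError("stressed PhiPSII bound must be below the normal level")
        if self.fvfm_affected >= self.fvfm_normal:
            raise ValueError("affected Fv/Fm bound must be below the normal level")
        if self.ratio_normal_min <= 0:
            raise ValueError("ratio_normal_min must be positive")


@dataclass
class RuleConfig:
    """Numeric cutoffs of the trajectory rules."""

    declining_slope: float = -0.01  # indicator units per day
    rapid_slope: float = -0.05  # PhiPSII units per day
    heterogeneity_std: float = 0.08  # Fv/Fm pixel std (healthy sits near 0.03)
    lesion_patchiness: float = 0.4
    impairment_threshold: float = 0.5  # Fv/Fm level defining "impaired" pixels


@dataclass
class Trajectory:
    """Per-day indicator summaries for one monitored plant/acquisition."""

    days: Sequence[int]
    summaries: dict[str, list[IndicatorSummary]]

    def __post_init__(self) -> None:
        self.days = list(self.days)
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValueError("days must be strictly increasing")
        missing = set(INDICATORS) - set(self.summaries)
        if missing:
            raise ValueError(f"trajectory missing indicators: {sorted(missing)}")
        for k in INDICATORS:
            if len(self.summaries[k]) != len(self.days):
                raise ValueError(f"indicator {k} does not cover every day")

    def __len__(self) -> int:
        return len(self.days)

    def means(self, indicator: str) -> np.ndarray:
        return np.array([s.mean for s in self.summaries[indicator]])

    def stds(self, indicator: str) -> np.ndarray:
        return np.array([s.std for s in self.summaries[indicator]])

    def prefix(self, n: int) -> "Trajectory":
        return Trajectory(
            days=self.days[:n],
            summaries={k: v[:n] for k, v in self.summaries.items()},
        )


@dataclass
class StressDiagnosis:
    """Classified stress label with its supporting evidence."""

    label: str
    evidence: dict[str, bool]
    confidence: float
    thresholds: dict = field(default_factory=dict)
    note: str | None = None  # e.g. recorded exclusion of confounders


def assess_snapshot(
    fvfm_mean: float,
    phipsii_mean: float,
    ratio_mean: float,
    ranges: NormalRanges | None = None,
) -> dict[str, bool]:
    """Flag a single day's means against the normal ranges.

    PhiPSII at or below the stressed bound flags stress; Fv/Fm strictly
    below the affected bound flags PSII impairment; 550/510 below its
    normal minimum flags abnormal leaf chroma.
    """
    r = ranges or NormalRanges()
    for v in (fvfm_mean, phipsii_mean, ratio_mean):
        if not np.isfinite(v):
            raise ValueError("snapshot means must be finite")
    return {
        "phipsii_stressed": bool(phipsii_mean <= r.phipsii_stressed),
        "fvfm_affected": bool(fvfm_mean < r.fvfm_affected),
        "ratio_abnormal": bool(ratio_mean < r.ratio_normal_min),
    }


def patchiness_score(fvfm_map: IndicatorMap, impairment_threshold: float = 0.5) -> float:
    """Spatial clumping of impaired plant pixels, in [0, 1].

    Let B be the defined plant pixels below the threshold.  The score is
    the mean, over pixels of B, of the fraction of their 4-neighbours
    within the plant that are also in B.  Under spatially independent
    impairment at density p the score concentrates near p; clumped
    lesions push it toward 1.  Zero when B is empty.
    """
    defined = fvfm_map.defined
    if not defined.any():
        raise ValueError("map has no defined pixels")
    below = defined & (fvfm_map.values < impairment_threshold)
    if not below.any():
        return 0.0
    kernel = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
    nb_below = ndimage.convolve(below.astype(float), kernel, mode="constant")
    nb_plant = ndimage.convolve(defined.astype(float), kernel, mode="constant")
    sel = below & (nb_plant > 0)
    if not sel.any():
        return 0.0
    return float((nb_below[sel] / nb_plant[sel]).mean())


def _slope(days: np.ndarray, values: np.ndarray) -> float:
    return float(np.polyfit(days, values, 1)[0])


def _classify_once(
    traj: Trajectory,
    per_day_patchiness: Sequence[float],
    ranges: NormalRanges,
    cfg: RuleConfig,
) -> StressDiagnosis:
    days = np.asarray(traj.days, dtype=float)
    fvfm = traj.means("fvfm")
    phi = traj.means("phipsii")
    ratio = traj.means("r550_510")
    fvfm_std = traj.stds("fvfm")

    phi_slope = _slope(days, phi)
    fvfm_slope = _slope(days, fvfm)
    ratio_slope = _slope(days, ratio)
    std_slope = _slope(days, fvfm_std)

    daily_flags = [
        assess_snapshot(fvfm[i], phi[i], ratio[i], ranges) for i in range(len(days))
    ]
    phi_flag_final = daily_flags[-1]["phipsii_stressed"]
    fvfm_flag_final = daily_flags[-1]["fvfm_affected"]
    ratio_flag_final = daily_flags[-1]["ratio_abnormal"]
    fvfm_flag_any = any(f["fvfm_affected"] for f in daily_flags)
    ratio_flag_any = any(f["ratio_abnormal"] for f in daily_flags)
    any_flag = any(any(f.values()) for f in daily_flags)

    evidence = {
        "phipsii_declining": bool(phi_slope < cfg.declining_slope),
        "fvfm_below_affected": bool(fvfm_flag_final),
        "ratio_below_normal": bool(ratio_flag_final),
        "heterogeneity_rising": bool(max(fvfm_std) > cfg.heterogeneity_std and std_slope > 0),
        "rapid_decline": bool(phi_slope < cfg.rapid_slope),
        "patchy_lesions": bool(max(per_day_patchiness, default=0.0) > cfg.lesion_patchiness),
    }
    all_declining = (
        evidence["phipsii_declining"]
        and fvfm_slope < cfg.declining_slope
        and ratio_slope < cfg.declining_slope
    )

    # Rule table; disease is checked first so that ties (disease and
    # nitrogen-deficiency patterns both firing) resolve to disease.
    if evidence["rapid_decline"] or evidence["patchy_lesions"]:
        label = "disease"
    elif all_declining and evidence["heterogeneity_rising"] and not evidence["patchy_lesions"]:
        label = "nitrogen_deficiency"
    elif (
        evidence["phipsii_declining"]
        and phi_flag_final
        and not evidence["heterogeneity_rising"]
    ):
        if fvfm_flag_final and ratio_flag_final:
            label = "drought_severe"
        elif not fvfm_flag_any and not ratio_flag_any:
            label = "drought_early"
        else:
            label = "indeterminate"
    elif not any_flag and not evidence["phipsii_declining"]:
        label = "healthy"
    else:
        label = "indeterminate"

    expected = _EXPECTED_EVIDENCE.get(label)
    if expected is None:
        confidence = 0.0
    else:
        confidence = sum(
            evidence[k] == expected[k] for k in EVIDENCE_FLAGS
        ) / len(EVIDENCE_FLAGS)
    return StressDiagnosis(
        label=label,
        evidence=evidence,
        confidence=confidence,
        thresholds={
            "ranges": vars(ranges).copy(),
            "rules": vars(cfg).copy(),
        },
    )


#: Evidence pattern each label is expected to show; the confidence is the
#: fraction of flags agreeing with the pattern.
_EXPECTED_EVIDENCE = {
    "healthy": dict.fromkeys(EVIDENCE_FLAGS, False),
    "drought_early": {
        "phipsii_declining": True,
        "fvfm_below_affected": False,
        "ratio_below_normal": False,
        "heterogeneity_rising": False,
        "rapid_decline": False,
        "patchy_lesions": False,
    },
    "drought_severe": {
        "phipsii_declining": True,
        "fvfm_below_affected": True,
        "ratio_below_normal": True,
        "heterogeneity_rising": False,
        "rapid_decline": False,
        "patchy_lesions": False,
    },
    "nitrogen_deficiency": {
        "phipsii_declining": True,
        "fvfm_below_affected": True,
        "ratio_below_normal": True,
        "heterogeneity_rising": True,
        "rapid_decline": False,
        "patchy_lesions": False,
    },
    "disease": {
        "phipsii_declining": True,
        "fvfm_below_affected": True,
        "ratio_below_normal": True,
        "heterogeneity_rising": True,
        "rapid_decline": True,
        "patchy_lesions": True,
    },
}


def classify_stress(
    traj: Trajectory,
    per_day_patchiness: Sequence[float] | None = None,
    ranges: NormalRanges | None = None,
    rule_cfg: RuleConfig | None = None,
    note: str | None = None,
) -> StressDiagnosis:
    """Classify the stress type of an indicator trajectory.

    Requires at least three days of data.  If the full series is
    indeterminate (for instance, recovery days trailing a severe-stress
    episode), the most recent determinate prefix label is reported — the
    "latest consistent label" rule.
    """
    if len(traj) < 3:
        raise InsufficientDataError("need at least 3 days of data to classify")
    if per_day_patchiness is None:
        per_day_patchiness = [0.0] * len(traj)
    if len(per_day_patchiness) != len(traj):
        raise ValueError("per_day_patchiness must align with trajectory days")
    ranges = ranges or NormalRanges()
    cfg = rule_cfg or RuleConfig()

    diag = _classify_once(traj, per_day_patchiness, ranges, cfg)
    if diag.label == "indeterminate":
        for n in range(len(traj) - 1, 2, -1):
            prev = _classify_once(traj.prefix(n), per_day_patchiness[:n], ranges, cfg)
            if prev.label != "indeterminate":
                diag = prev
                break
    diag.note = note
    return diag
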