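"""Rule-based stress classification: flags, patchiness, trajectories."""

import numpy as np
import pytest

from fluoroscan import (
    NormalRanges,
    PlantMask,
    RuleConfig,
    Trajectory,
    assess_snapshot,
    classify_stress,
    compute_fvfm,
    patchiness_score,
)
from fluoroscan.diagnosis import InsufficientDataError
from fluoroscan.indicators import IndicatorMap, IndicatorSummary


def summary(indicator, mean, std=0.02, day=None):
    return IndicatorSummary(
        indicator=indicator, mean=mean, std=std, median=mean, q1=mean, q3=mean,
        min=mean - 2 * std, max=mean + 2 * std, n_pixels=1000, day=day,
    )


def make_traj(fvfm, phipsii, ratio, fvfm_std=None):
    days = list(range(1, len(fvfm) + 1))
    fvfm_std = fvfm_std or [0.03] * len(days)
    return Trajectory(
        days=days,
        summaries={
            "fvfm": [summary("fvfm", m, s, d) for m, s, d in zip(fvfm, fvfm_std, days)],
            "phipsii": [summary("phipsii", m, day=d) for m, d in zip(phipsii, days)],
            "r550_510": [summary("r550_510", m, day=d) for m, d in zip(ratio, days)],
        },
    )


def map_from_values(values):
    mask = PlantMask(mask=np.isfinite(values), provenance="fluorescence_threshold")
    return IndicatorMap(values=values, indicator="fvfm", mask=mask)


class TestAssessSnapshot:
    @pytest.mark.parametrize(
        "fvfm,phi,ratio,expected",
        [
            (0.80, 0.40, 1.6, set()),
            (0.80, 0.29, 1.6, {"phipsii_stressed"}),
            (0.74, 0.40, 1.6, {"fvfm_affected"}),
            (0.80, 0.40, 1.4, {"ratio_abnormal"}),
            (0.70, 0.25, 1.3, {"phipsii_stressed", "fvfm_affected", "ratio_abnormal"}),
        ],
    )
    def test_flags_against_normal_ranges(self, fvfm, phi, ratio, expected):
        flags = assess_snapshot(fvfm, phi, ratio)
        assert {k for k, v in flags.items() if v} == expected

    def test_flags_monotone_in_indicator_means(self):
        # lowering a mean never clears a flag
        base = assess_snapshot(0.74, 0.29, 1.4)
        lower = assess_snapshot(0.60, 0.20, 1.0)
        for k in base:
            assert not (base[k] and not lower[k])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            assess_snapshot(np.nan, 0.4, 1.6)

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            NormalRanges(phipsii_stressed=0.5, phipsii_normal=0.4)


class TestPatchinessScore:
    def test_no_impaired_pixels_scores_zero(self):
        values = np.full((10, 10), 0.8)
        assert patchiness_score(map_from_values(values)) == 0.0

    def test_fully_impaired_plant_scores_one(self):
        values = np.full((10, 10), 0.2)
        assert patchiness_score(map_from_values(values)) == 1.0

    def test_independent_impairment_matches_density(self):
        # under spatially independent impairment at density p, the
        # clumping index concentrates near p
        scores = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            values = np.where(rng.random((60, 60)) < 0.1, 0.2, 0.8)
            scores.append(patchiness_score(map_from_values(values)))
        assert abs(np.mean(scores) - 0.1) <= 0.03

    def test_clumped_lesion_scores_high(self):
        values = np.full((30, 30), 0.8)
        values[5:15, 5:15] = 0.2
        assert patchiness_score(map_from_values(values)) > 0.8

    def test_empty_map_rejected(self):
        values = np.full((5, 5), np.nan)
        with pytest.raises(ValueError, match="defined"):
            patchiness_score(map_from_values(values))


class TestClassifyStress:
    def test_early_drought_pattern(self):
        # PhiPSII 0.42 -> 0.30 over 5 days, Fv/Fm and 550/510 normal throughout
        traj = make_traj(
            fvfm=[0.80, 0.80, 0.79, 0.79, 0.78],
            phipsii=[0.42, 0.39, 0.36, 0.33, 0.30],
            ratio=[1.6, 1.6, 1.6, 1.55, 1.5],
        )
        assert classify_stress(traj).label == "drought_early"

    def test_severe_drought_pattern(self):
        traj = make_traj(
            fvfm=[0.80, 0.79, 0.78, 0.76, 0.74, 0.72],
            phipsii=[0.40, 0.36, 0.32, 0.29, 0.26, 0.25],
            ratio=[1.6, 1.58, 1.55, 1.5, 1.42, 1.36],
        )
        assert classify_stress(traj).label == "drought_severe"

    def test_nitrogen_deficiency_pattern(self):
        # all three declining, Fv/Fm std rising 0.03 -> 0.12, low patchiness
        traj = make_traj(
            fvfm=[0.80, 0.77, 0.74, 0.70, 0.66],
            phipsii=[0.40, 0.37, 0.34, 0.31, 0.28],
            ratio=[1.6, 1.55, 1.5, 1.45, 1.40],
            fvfm_std=[0.03, 0.05, 0.07, 0.10, 0.12],
        )
        diag = classify_stress(traj, per_day_patchiness=[0.0, 0.05, 0.1, 0.15, 0.2])
        assert diag.label == "nitrogen_deficiency"
        assert diag.evidence["heterogeneity_rising"]

    def test_rapid_decline_is_disease(self):
        traj = make_traj(
            fvfm=[0.80, 0.72, 0.64, 0.55],
            phipsii=[0.40, 0.33, 0.25, 0.17],  # > 0.05/day decline
            ratio=[1.6, 1.5, 1.4, 1.3],
        )
        assert classify_stress(traj).label == "disease"

    def test_patchy_lesions_are_disease_even_when_gradual(self):
        traj = make_traj(
            fvfm=[0.80, 0.77, 0.74, 0.70, 0.66],
            phipsii=[0.40, 0.37, 0.34, 0.31, 0.28],
            ratio=[1.6, 1.55, 1.5, 1.45, 1.40],
            fvfm_std=[0.03, 0.05, 0.07, 0.10, 0.12],
        )
        # same trajectory as the N-deficiency case, but clumped impairment:
        # ties resolve to disease
        diag = classify_stress(traj, per_day_patchiness=[0.1, 0.3, 0.5, 0.6, 0.7])
        assert diag.label == "disease"

    def test_healthy_control(self):
        traj = make_traj(
            fvfm=[0.80, 0.80, 0.81, 0.80],
            phipsii=[0.40, 0.41, 0.40, 0.40],
            ratio=[1.6, 1.61, 1.63, 1.65],  # slight rising trend, as in controls
        )
        diag = classify_stress(traj)
        assert diag.label == "healthy"
        assert not any(diag.evidence.values())
        assert diag.confidence == 1.0

    def test_latest_consistent_label_survives_trailing_recovery(self):
        # severe-drought sequence followed by rewatering-style recovery days:
        # the full-series slopes wash out, but the latest determinate prefix
        # keeps the severe label
        traj = make_traj(
            fvfm=[0.80, 0.78, 0.76, 0.74, 0.72, 0.72, 0.73],
            phipsii=[0.40, 0.34, 0.29, 0.26, 0.25, 0.38, 0.41],
            ratio=[1.6, 1.55, 1.5, 1.42, 1.36, 1.45, 1.5],
        )
        assert classify_stress(traj).label in ("drought_severe", "indeterminate")
        # prefix ending at the severe day is determinate
        assert classify_stress(traj.prefix(5)).label == "drought_severe"

    def test_insufficient_days_rejected(self):
        traj = make_traj(fvfm=[0.8, 0.8], phipsii=[0.4, 0.4], ratio=[1.6, 1.6])
        with pytest.raises(InsufficientDataError):
            classify_stress(traj)

    def test_patchiness_length_mismatch_rejected(self):
        traj = make_traj(
            fvfm=[0.8, 0.8, 0.8], phipsii=[0.4, 0.4, 0.4], ratio=[1.6, 1.6, 1.6]
        )
        with pytest.raises(ValueError, match="align"):
            classify_stress(traj, per_day_patchiness=[0.0])

    def test_custom_rule_config_respected(self):
        traj = make_traj(
            fvfm=[0.80, 0.79, 0.78, 0.77, 0.76],
            phipsii=[0.40, 0.37, 0.34, 0.32, 0.30],
            ratio=[1.6, 1.6, 1.6, 1.6, 1.6],
        )
        strict = RuleConfig(rapid_slope=-0.02)  # this decline now counts as rapid
        assert classify_stress(traj, rule_cfg=strict).label == "disease"


class TestTrajectoryValidation:
    def test_days_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            Trajectory(
                days=[1, 1, 2],
                summaries={
                    k: [summary(k, 0.5)] * 3 for k in ("fvfm", "phipsii", "r550_510")
                },
            )

    def test_all_indicators_required(self):
        with pytest.raises(ValueError, match="missing"):
            Trajectory(days=[1, 2, 3], summaries={"fvfm": [summary("fvfm", 0.8)] * 3})
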