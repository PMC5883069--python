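"""Synthetic scene generator: geometry, stress dynamics, render algebra."""

import numpy as np
import pytest
from skimage.measure import label

from fluoroscan import (
    ImagingModel,
    SceneSpec,
    StressModel,
    apply_stress,
    build_scene,
    generate_dataset,
    render_stack,
)
from fluoroscan.scene import (
    DROUGHT_PHIPSII_FLOOR,
    HEALTHY_FVFM,
    HEALTHY_PHIPSII,
    InvalidSpecError,
)


def single_day_model(stress_type, severity):
    """A one-day stress model pinned at a given severity."""
    return StressModel(
        stress_type=stress_type, day_range=(1, 1), severity_trajectory=[severity]
    )


class TestBuildScene:
    def test_seeded_generation_is_reproducible(self, small_spec):
        a = build_scene(small_spec, seed=5)
        b = build_scene(small_spec, seed=5)
        for name in ("phi_max", "phi_op", "chroma"):
            np.testing.assert_array_equal(getattr(a, name), getattr(b, name))
        np.testing.assert_array_equal(a.footprint, b.footprint)
        np.testing.assert_array_equal(a.age, b.age)

    def test_footprint_has_one_component_per_plant(self):
        spec = SceneSpec(image_height=300, image_width=400, n_plants=4)
        field = build_scene(spec, seed=1)
        assert label(field.footprint, connectivity=1).max() == 4

    def test_healthy_working_point_exact_before_noise(self, healthy_field):
        # Texture is mean-centered, so the footprint means are the healthy
        # working point itself.
        assert healthy_field.footprint_mean("phi_max") == pytest.approx(
            HEALTHY_FVFM, abs=1e-12
        )
        assert healthy_field.footprint_mean("phi_op") == pytest.approx(
            HEALTHY_PHIPSII, abs=1e-12
        )
        assert healthy_field.footprint_mean("chroma") == pytest.approx(1.0, abs=1e-12)

    def test_fields_zero_off_footprint(self, healthy_field):
        off = ~healthy_field.footprint
        for name in ("phi_max", "phi_op", "chroma"):
            assert np.all(getattr(healthy_field, name)[off] == 0)

    def test_phi_ordering_on_footprint(self, healthy_field):
        fp = healthy_field.footprint
        assert np.all(healthy_field.phi_op[fp] <= healthy_field.phi_max[fp])
        assert np.all(healthy_field.phi_max[fp] < 1)

    @pytest.mark.parametrize(
        "kwargs", [{"n_plants": 0}, {"image_height": 0}, {"leaves_per_plant": 0}]
    )
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(InvalidSpecError):
            build_scene(SceneSpec(**kwargs), seed=0)

    def test_too_small_image_rejected(self):
        with pytest.raises(InvalidSpecError):
            build_scene(SceneSpec(image_height=8, image_width=8, n_plants=4), seed=0)


class TestApplyStress:
    def test_no_stress_is_identity(self, healthy_field):
        out = apply_stress(healthy_field, single_day_model("none", 0.0), day=1)
        np.testing.assert_array_equal(out.phi_op, healthy_field.phi_op)
        np.testing.assert_array_equal(out.phi_max, healthy_field.phi_max)

    def test_input_field_never_mutated(self, healthy_field):
        before = healthy_field.phi_op.copy()
        apply_stress(healthy_field, single_day_model("drought", 1.0), day=1)
        np.testing.assert_array_equal(healthy_field.phi_op, before)

    def test_drought_hits_phi_op_before_fvfm(self, healthy_field):
        out = apply_stress(healthy_field, single_day_model("drought", 0.5), day=1)
        assert out.footprint_mean("phi_op") < healthy_field.footprint_mean("phi_op")
        assert abs(
            out.footprint_mean("phi_max") - healthy_field.footprint_mean("phi_max")
        ) <= 0.02

    def test_full_drought_reaches_floor(self, healthy_field):
        out = apply_stress(healthy_field, single_day_model("drought", 1.0), day=1)
        assert out.footprint_mean("phi_op") == pytest.approx(
            DROUGHT_PHIPSII_FLOOR, abs=0.01
        )
        assert out.footprint_mean("phi_max") < 0.75  # severe drought pulls Fv/Fm down

    def test_nitrogen_deficiency_raises_fvfm_heterogeneity(self, healthy_field):
        fp = healthy_field.footprint
        base_std = healthy_field.phi_max[fp].std()
        out = apply_stress(
            healthy_field, single_day_model("nitrogen_deficiency", 0.6), day=1
        )
        assert out.phi_max[fp].std() > base_std

    def test_nitrogen_deficiency_old_leaves_lead(self, healthy_field):
        out = apply_stress(
            healthy_field, single_day_model("nitrogen_deficiency", 0.6), day=1
        )
        old = out.phi_max[out.age == 1].mean()
        new = out.phi_max[out.age == 2].mean()
        assert old < new

    def test_disease_carves_patchy_lesions(self, healthy_field):
        model = StressModel(stress_type="disease", day_range=(1, 9))
        out = apply_stress(healthy_field, model, day=9)
        fp = out.footprint
        lesioned = fp & (out.phi_op < 0.2)
        assert lesioned.any()
        # lesions are clumps, not scattered pixels
        assert label(lesioned, connectivity=1).max() < 0.01 * lesioned.sum()

    @pytest.mark.parametrize("stress", ["drought", "nitrogen_deficiency", "disease"])
    def test_mean_phi_op_non_increasing_in_severity(self, healthy_field, stress):
        means = []
        for s in (0.0, 0.25, 0.5, 0.75, 1.0):
            out = apply_stress(healthy_field, single_day_model(stress, s), day=1)
            means.append(out.footprint_mean("phi_op"))
        assert all(b <= a + 1e-12 for a, b in zip(means, means[1:]))

    def test_unknown_stress_type_rejected(self):
        with pytest.raises(ValueError, match="stress_type"):
            StressModel(stress_type="frost")

    def test_decreasing_severity_rejected(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            StressModel(
                stress_type="drought",
                day_range=(1, 3),
                severity_trajectory=[0.5, 0.3, 0.9],
            )

    def test_day_outside_range_rejected(self, healthy_field):
        with pytest.raises(ValueError, match="day_range"):
            apply_stress(healthy_field, single_day_model("drought", 1.0), day=4)


class TestRenderStack:
    def test_frame_ordering_invariants_noiseless(self, noiseless_stack):
        fo, fm = noiseless_stack["Fo"], noiseless_stack["Fm"]
        f, fmp = noiseless_stack["F"], noiseless_stack["Fm_prime"]
        assert np.all(fo <= fm + 1e-9)
        assert np.all(fmp <= fm + 1e-9)
        assert np.all(f <= fmp + 1e-9)

    def test_noiseless_background_is_exact(self, healthy_field, noiseless_stack):
        bg = ~healthy_field.footprint
        for k in ("Fo", "Fm", "F", "Fm_prime"):
            assert np.all(noiseless_stack[k][bg] == healthy_field.background_level)

    def test_noisy_render_is_quantized_and_clipped(self, noisy_stack, default_imaging):
        for k, frame in noisy_stack.frames.items():
            assert np.all(frame == np.round(frame)), k
            assert frame.max() <= default_imaging.max_count

    def test_render_determinism(self, healthy_field, default_imaging):
        a = render_stack(healthy_field, default_imaging, seed=9)
        b = render_stack(healthy_field, default_imaging, seed=9)
        for k in a.frames:
            np.testing.assert_array_equal(a[k], b[k])

    def test_out_of_range_phi_rejected(self, healthy_field, default_imaging):
        bad = healthy_field.copy()
        bad.phi_max[bad.footprint] = 1.5
        with pytest.raises(ValueError, match="phi_max"):
            render_stack(bad, default_imaging, seed=0)

    def test_saturation_warns(self, healthy_field):
        imaging = ImagingModel(fm_gain=6000.0)  # Fm overflows 12 bits
        with pytest.warns(UserWarning, match="saturate"):
            render_stack(healthy_field, imaging, seed=0)


class TestGenerateDataset:
    def test_drought_series_phi_op_non_increasing(self, small_spec):
        model = StressModel(stress_type="drought", day_range=(1, 9))
        pairs = generate_dataset(small_spec, model, ImagingModel(), seed=2)
        means = [fld.footprint_mean("phi_op") for _, fld in pairs]
        assert all(b <= a + 1e-12 for a, b in zip(means, means[1:]))

    def test_control_series_is_flat(self, small_spec):
        model = StressModel(stress_type="none", day_range=(1, 9))
        pairs = generate_dataset(small_spec, model, ImagingModel(), seed=2)
        means = [fld.footprint_mean("phi_max") for _, fld in pairs]
        assert max(means) - min(means) < 0.01

    def test_sidecars_byte_identical_for_same_seed(self, small_spec, tmp_path):
        model = StressModel(stress_type="drought", day_range=(1, 3))
        for sub in ("a", "b"):
            generate_dataset(
                small_spec, model, ImagingModel(), days=[1, 2, 3], seed=7,
                out_dir=tmp_path / sub,
            )
        for name in ["day_01.tif", "day_01.json", "day_01_truth.npz", "manifest.json"]:
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes(), name

    def test_empty_day_list_rejected(self, small_spec):
        model = StressModel(stress_type="none", day_range=(1, 9))
        with pytest.raises(ValueError, match="non-empty"):
            generate_dataset(small_spec, model, ImagingModel(), days=[], seed=0)
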