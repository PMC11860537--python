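import numpy as np
import pytest
from scipy.signal import find_peaks

from ridgekit import synthetic as syn
from conftest import angdiff


class TestSpecValidation:
    def test_subresolution_period_rejected(self):
        with pytest.raises(ValueError, match="ridge_period"):
            syn.SyntheticSpec(ridge_period=3.0).validate()

    def test_footprint_outside_bounds_rejected(self):
        spec = syn.SyntheticSpec(width=200, height=150, footprint=(75, 100, 100, 90))
        with pytest.raises(ValueError, match="footprint"):
            spec.validate()

    def test_model_string_parsing(self):
        assert syn.parse_orientation_model("constant:0.3") == ("constant", 0.3)
        assert syn.parse_orientation_model("linear:-0.5:0.5") == ("linear", -0.5, 0.5)
        assert syn.parse_orientation_model("core") == ("core",)
        with pytest.raises(ValueError):
            syn.parse_orientation_model("spiral")


class TestOrientationField:
    def test_constant_model_uniform(self):
        spec = syn.SyntheticSpec(width=120, height=90, orientation_model=("constant", 0.3))
        field = syn.make_orientation_field(spec)
        np.testing.assert_allclose(field, 0.3)

    def test_linear_model_midpoint_is_mid_angle(self):
        spec = syn.SyntheticSpec(
            width=1200, height=800, orientation_model=("linear", -np.pi / 4, np.pi / 4)
        )
        field = syn.make_orientation_field(spec)
        # grid center sits half a pixel from the geometric center, hence the
        # sub-milliradian tolerance
        mid = field[400, 600]
        assert abs(mid) < 2e-3

    def test_core_doubled_angle_circulation_is_2pi(self):
        spec = syn.SyntheticSpec(width=300, height=300, orientation_model=("core", 150.0, 150.0))
        field = syn.make_orientation_field(spec)
        # numeric line integral of d(2*theta) around a circle about the core
        angles = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        rr = (150 + 60 * np.sin(angles)).astype(int)
        cc = (150 + 60 * np.cos(angles)).astype(int)
        doubled = 2.0 * field[rr, cc]
        steps = np.angle(np.exp(1j * np.diff(np.append(doubled, doubled[0]))))
        assert np.sum(steps) == pytest.approx(2 * np.pi, abs=1e-2)

    def test_fields_stay_in_half_open_interval(self):
        for model in [("constant", 1.5), ("linear", -0.7, 0.7), ("core",)]:
            spec = syn.SyntheticSpec(width=100, height=80, orientation_model=model)
            f = syn.make_orientation_field(spec)
            assert (f > -np.pi / 2).all() and (f <= np.pi / 2).all()


class TestRender:
    def test_peak_spacing_matches_period(self):
        spec = syn.SyntheticSpec(
            width=400, height=200, ridge_period=8.0,
            orientation_model=("constant", 0.0), n_dislocations=0,
        )
        truth = syn.render_ridge_image(spec)
        row = truth.clean_image[100, 60:340]  # inside the footprint
        peaks, _ = find_peaks(row)
        spacing = np.diff(peaks)
        assert np.abs(spacing - 8.0).max() <= 0.5 + 1  # integer peak grid

    def test_zero_contrast_flat_footprint(self):
        spec = syn.SyntheticSpec(width=200, height=150, contrast=0.0)
        truth = syn.render_ridge_image(spec)
        fp = truth.footprint_mask
        assert np.ptp(truth.clean_image[fp]) == 0.0

    def test_same_seed_bit_identical(self):
        spec = syn.SyntheticSpec(width=200, height=150, seed=9)
        a = syn.render_ridge_image(spec)
        b = syn.render_ridge_image(spec)
        np.testing.assert_array_equal(a.clean_image, b.clean_image)
        assert [(m.row, m.col, m.kind) for m in a.minutiae] == [
            (m.row, m.col, m.kind) for m in b.minutiae
        ]
        np.testing.assert_array_equal(syn.degrade(a, spec), syn.degrade(b, spec))

    def test_orientation_truth_matches_phase_gradient(self):
        # finite-difference check of the recorded dense orientation
        spec = syn.SyntheticSpec(
            width=300, height=200, orientation_model=("linear", -0.5, 0.5),
            n_dislocations=0, contrast=1.0,
        )
        truth = syn.render_ridge_image(spec)
        phase, gr, gc = syn._base_phase_gradient(spec)
        num_r, num_c = np.gradient(phase)
        inner = np.s_[20:-20, 20:-20]
        ang = np.arctan2(num_r, num_c)[inner]
        diff = [angdiff(a, b) for a, b in zip(np.ravel(ang)[::501], np.ravel(truth.orientation[inner])[::501])]
        assert np.degrees(np.max(diff)) < 1.0

    def test_minutiae_positions_inside_footprint(self):
        spec = syn.SyntheticSpec(width=300, height=200, seed=4)
        truth = syn.render_ridge_image(spec)
        assert len(truth.minutiae) > 0
        for m in truth.minutiae:
            assert truth.footprint_mask[int(m.row), int(m.col)]


class TestDegrade:
    def test_zero_degradation_is_identity(self):
        spec = syn.SyntheticSpec(
            width=200, height=150, noise_sd=0.0, brightness_error_amplitude=0.0
        )
        truth = syn.render_ridge_image(spec)
        np.testing.assert_array_equal(syn.degrade(truth, spec), truth.clean_image)

    def test_noise_sd_matches_request(self):
        spec = syn.SyntheticSpec(
            width=1200, height=800, noise_sd=5.0, brightness_error_amplitude=0.0,
            orientation_model=("constant", 0.3),
        )
        truth = syn.render_ridge_image(spec)
        diff = syn.degrade(truth, spec) - truth.clean_image
        assert truth.footprint_mask.sum() > 5e5
        assert diff[truth.footprint_mask].std() == pytest.approx(5.0, abs=0.5)

    def test_brightness_field_moves_block_means(self):
        spec = syn.SyntheticSpec(
            width=600, height=400, noise_sd=0.0,
            brightness_error_amplitude=30.0, brightness_error_scale=300.0,
            orientation_model=("constant", 0.3), seed=2,
        )
        truth = syn.render_ridge_image(spec)
        degraded = syn.degrade(truth, spec)
        shift = degraded - truth.clean_image
        means = []
        for r in range(0, 400 - 40, 40):
            for c in range(0, 600 - 40, 40):
                if truth.footprint_mask[r : r + 40, c : c + 40].all():
                    means.append(shift[r : r + 40, c : c + 40].mean())
        assert max(means) - min(means) >= 20.0

    def test_truth_minutiae_invariant_under_degrade(self):
        spec = syn.SyntheticSpec(width=300, height=200, seed=6, noise_sd=20.0)
        truth = syn.render_ridge_image(spec)
        before = [(m.row, m.col, m.kind) for m in truth.minutiae]
        syn.degrade(truth, spec)
        assert [(m.row, m.col, m.kind) for m in truth.minutiae] == before


class TestConditionSet:
    def test_high_contrast_label_has_deeper_modulation(self):
        spec = syn.SyntheticSpec(width=300, height=200, seed=3)
        out = syn.emit_condition_set(spec, ["WC-B", "DC-R"])
        fp = out["WC-B"][1].footprint_mask
        interior = np.zeros_like(fp)
        interior[60:140, 80:220] = True
        mod = {k: np.subtract(*np.percentile(v[0][interior & fp], [90, 10])) for k, v in out.items()}
        assert mod["WC-B"] > mod["DC-R"]

    def test_duplicate_labels_rejected(self):
        spec = syn.SyntheticSpec(width=200, height=150)
        with pytest.raises(ValueError, match="duplicate"):
            syn.emit_condition_set(spec, ["WC", "WC"])

    def test_empty_label_list_empty_result(self, tmp_path):
        spec = syn.SyntheticSpec(width=200, height=150)
        assert syn.emit_condition_set(spec, [], tmp_path) == {}
        assert list(tmp_path.iterdir()) == []

    def test_shared_truth_and_determinism(self, tmp_path):
        spec = syn.SyntheticSpec(width=200, height=150, seed=8)
        a = syn.emit_condition_set(spec, ["WC", "UC", "DC"], tmp_path / "a")
        b = syn.emit_condition_set(spec, ["WC", "UC", "DC"], tmp_path / "b")
        for label in ("WC", "UC", "DC"):
            np.testing.assert_array_equal(a[label][0], b[label][0])
        t_wc, t_dc = a["WC"][1], a["DC"][1]
        assert [(m.row, m.col) for m in t_wc.minutiae] == [(m.row, m.col) for m in t_dc.minutiae]
        # truth CSV round-trip
        back = syn.read_truth_csv(tmp_path / "a" / "truth.csv")
        assert len(back) == len(t_wc.minutiae)
        assert {m.kind for m in back} <= {"ending", "bifurcation"}
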