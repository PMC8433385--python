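import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from acoustocalib.calibration import (
    CalibrationCurve,
    CalibrationKnot,
    build_curve,
    cell_modulus,
    interpolate_modulus,
)
from acoustocalib.deformability import DeformationSeries, fit_slope, summarize_group
from acoustocalib.errors import CalibrationRangeError, ValidationError

from conftest import PUBLISHED_AHS_MODULI, PUBLISHED_SLOPES, RAMP


def group_of_constant_slope(slope, n=3, label="g"):
    fits = [
        fit_slope(
            DeformationSeries(
                sample_id=f"{label}_{i}",
                group_label=label,
                pressures_mpa=RAMP,
                areas_um2=100 * (1 + slope * RAMP),
            )
        )
        for i in range(n)
    ]
    return summarize_group(fits, label)


class TestBuildCurve:
    def test_published_pairs_sorted_by_slope(self, published_curve):
        assert [k.label for k in published_curve.knots] == [
            "AHS_1.2", "AHS_0.9", "AHS_0.6", "AHS_0.3", "AHS_0.1",
        ]
        assert published_curve.slopes[0] == 0.016
        assert published_curve.moduli_kpa[0] == 9.235

    def test_two_knots_valid(self):
        curve = build_curve([("a", 0.1), ("b", 0.5)], [("a", 5.0, 0.1), ("b", 1.0, 0.1)])
        assert len(curve.knots) == 2

    def test_non_monotone_moduli_rejected_with_pair_named(self):
        with pytest.raises(ValidationError, match="'a'.*'b'|'b'.*'a'"):
            build_curve([("a", 0.1), ("b", 0.5)], [("a", 1.0, 0.1), ("b", 5.0, 0.1)])

    def test_label_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="mismatch"):
            build_curve([("a", 0.1), ("b", 0.5)], [("a", 5.0, 0.1), ("c", 1.0, 0.1)])

    def test_json_round_trip(self, published_curve, tmp_path):
        path = tmp_path / "curve.json"
        published_curve.to_json(path)
        loaded = CalibrationCurve.from_json(path)
        assert loaded == published_curve


class TestInterpolate:
    def test_published_skbr3_slope_maps_to_published_modulus(self, published_curve):
        assert interpolate_modulus(published_curve, 0.090) == pytest.approx(2.772, abs=0.01)

    def test_knot_identity_exact(self, published_curve):
        for knot in published_curve.knots:
            assert interpolate_modulus(published_curve, knot.slope) == knot.E_kpa

    def test_out_of_range_refused(self, published_curve):
        with pytest.raises(CalibrationRangeError):
            interpolate_modulus(published_curve, 0.8)
        with pytest.raises(CalibrationRangeError):
            interpolate_modulus(published_curve, 0.01)

    @given(
        s=st.floats(0.016, 0.728),
        t=st.floats(0.016, 0.728),
    )
    def test_monotone_decreasing(self, published_curve, s, t):
        lo, hi = sorted((s, t))
        assert interpolate_modulus(published_curve, lo) >= interpolate_modulus(
            published_curve, hi
        )

    def test_log_scheme_monotone_and_hits_knots(self):
        curve = build_curve(
            [(k, v) for k, v in PUBLISHED_SLOPES.items() if k.startswith("AHS")],
            [(k, E, sd) for k, (E, sd) in PUBLISHED_AHS_MODULI.items()],
            scheme="log",
        )
        for knot in curve.knots:
            assert interpolate_modulus(curve, knot.slope) == pytest.approx(
                knot.E_kpa, rel=1e-12
            )
        xs = np.linspace(0.016, 0.728, 50)
        ys = [interpolate_modulus(curve, x) for x in xs]
        assert np.all(np.diff(ys) <= 0)


class TestCellModulus:
    def test_degenerate_identical_slopes(self, published_curve):
        grp = group_of_constant_slope(0.090)
        m = cell_modulus(grp, published_curve)
        assert m.E_mean_kpa == pytest.approx(2.772, abs=0.01)
        assert m.E_sd_kpa == pytest.approx(0.0, abs=1e-12)

    def test_single_sample_sd_zero(self, published_curve):
        m = cell_modulus(group_of_constant_slope(0.2, n=1), published_curve)
        assert m.E_sd_kpa == 0.0
        assert len(m.per_sample_E_kpa) == 1

    def test_out_of_range_counted_and_warned(self, published_curve):
        fits = group_of_constant_slope(0.1, n=2).per_sample_fits
        wild = fit_slope(
            DeformationSeries(
                sample_id="wild", group_label="g",
                pressures_mpa=RAMP, areas_um2=100 * (1 + 0.9 * RAMP),
            )
        )
        grp = summarize_group(list(fits) + [wild], "g")
        with pytest.warns(UserWarning, match="outside the calibrated"):
            m = cell_modulus(grp, published_curve)
        assert m.out_of_range_count == 1
        assert len(m.per_sample_E_kpa) == 2

    def test_all_out_of_range_rejected(self, published_curve):
        grp = group_of_constant_slope(0.9, n=2)
        with pytest.raises(CalibrationRangeError, match="all"):
            cell_modulus(grp, published_curve)

    def test_recovery_of_known_mean(self, published_curve):
        # slopes drawn in the flat upper segment so the truth is analytic
        rng = np.random.default_rng(3)
        slopes = rng.uniform(0.2, 0.7, 400)
        fits = [
            fit_slope(
                DeformationSeries(
                    sample_id=f"s{i}", group_label="g",
                    pressures_mpa=RAMP, areas_um2=50 * (1 + s * RAMP),
                )
            )
            for i, s in enumerate(slopes)
        ]
        m = cell_modulus(summarize_group(fits, "g"), published_curve)
        truth = np.mean([interpolate_modulus(published_curve, s) for s in slopes])
        assert m.E_mean_kpa == pytest.approx(truth, rel=1e-6)
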