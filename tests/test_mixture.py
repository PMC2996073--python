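import numpy as np
import pytest
from hypothesis import given, strategies as st

import vierordt as v
from vierordt.mixture import MixtureMeasurement


def measurement(matrix, absorbances, pathlength=1.0):
    return MixtureMeasurement(
        wavelengths=matrix.wavelengths,
        absorbances=np.asarray(absorbances, float),
        pathlength=pathlength,
    )


class TestBuildMatrix:
    def test_lok_atl_preset(self, lok_atl_matrix):
        assert lok_atl_matrix.components == ("LOK", "ATL")
        assert lok_atl_matrix.wavelengths == (251.60, 224.20)
        np.testing.assert_array_equal(
            lok_atl_matrix.values, [[320.25, 8.1], [661.75, 380.50]]
        )

    def test_atl_hctz_preset(self, atl_hctz_matrix):
        np.testing.assert_array_equal(
            atl_hctz_matrix.values, [[866.75, 1288.0], [106.0, 720.0]]
        )

    def test_single_component_matrix_valid(self):
        m = v.build_matrix(["ATL"], [224.2], [[850.0]])
        assert m.is_square

    def test_duplicate_component_rejected(self):
        with pytest.raises(ValueError, match="duplicate component"):
            v.build_matrix(["A", "A"], [250.0, 260.0], [[1, 2], [3, 4]])

    def test_duplicate_wavelength_rejected(self):
        with pytest.raises(ValueError, match="duplicate wavelength"):
            v.build_matrix(["A", "B"], [250.0, 250.0], [[1, 2], [3, 4]])

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            v.build_matrix(["A", "B"], [250.0, 260.0], [[1, -2], [3, 4]])

    def test_unknown_preset(self):
        with pytest.raises(KeyError, match="unknown preset"):
            v.preset_matrix("nope")


class TestVierordtDenominator:
    def test_lok_atl_value(self, lok_atl_matrix):
        assert v.vierordt_denominator(lok_atl_matrix) == pytest.approx(
            -116494.95, abs=1e-9
        )

    def test_atl_hctz_value(self, atl_hctz_matrix):
        assert v.vierordt_denominator(atl_hctz_matrix) == pytest.approx(
            -487532.0, abs=1e-9
        )

    def test_identity_gives_minus_one(self):
        m = v.build_matrix(["A", "B"], [250.0, 260.0], np.eye(2))
        assert v.vierordt_denominator(m) == -1.0

    def test_equals_negated_determinant(self, lok_atl_matrix):
        assert v.vierordt_denominator(lok_atl_matrix) == pytest.approx(
            -np.linalg.det(lok_atl_matrix.values), rel=1e-12
        )

    def test_requires_2x2(self):
        m = v.build_matrix(["A"], [250.0], [[1.0]])
        with pytest.raises(ValueError, match="2x2"):
            v.vierordt_denominator(m)


class TestSolveTwoComponent:
    def test_forward_round_trip_lok_atl(self, lok_atl_matrix):
        conc = np.array([0.002, 0.002])  # g/100 ml, i.e. 20 µg/ml each
        absorbances = lok_atl_matrix.values @ conc
        np.testing.assert_allclose(absorbances, [0.6567, 2.0845], rtol=1e-12)
        res = v.solve_two_component(lok_atl_matrix, measurement(lok_atl_matrix, absorbances))
        np.testing.assert_allclose(res.concentrations_g_per_100ml, conc, rtol=1e-10)
        np.testing.assert_allclose(res.concentrations_ug_per_ml, [20.0, 20.0], rtol=1e-10)

    def test_identity_matrix_returns_absorbances(self):
        m = v.build_matrix(["A", "B"], [250.0, 260.0], np.eye(2))
        res = v.solve_two_component(m, measurement(m, [0.3, 0.7]))
        np.testing.assert_allclose(res.concentrations_g_per_100ml, [0.3, 0.7])

    def test_singular_matrix_raises(self):
        m = v.build_matrix(["A", "B"], [250.0, 260.0], [[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(v.SingularSystemError):
            v.solve_two_component(m, measurement(m, [0.3, 0.7]))

    def test_pathlength_normalisation(self, lok_atl_matrix):
        conc = np.array([0.0015, 0.0022])
        a_1cm = lok_atl_matrix.values @ conc
        res = v.solve_two_component(
            lok_atl_matrix, measurement(lok_atl_matrix, 0.5 * a_1cm, pathlength=0.5)
        )
        np.testing.assert_allclose(res.concentrations_g_per_100ml, conc, rtol=1e-12)

    def test_negative_concentration_flagged_not_clamped(self, lok_atl_matrix):
        # absorbance pattern impossible for a physical mixture
        res = v.solve_two_component(lok_atl_matrix, measurement(lok_atl_matrix, [0.5, 0.0]))
        assert "negative_concentration" in res.flags
        assert res.concentrations_g_per_100ml.min() < 0

    def test_determinant_reported(self, lok_atl_matrix):
        res = v.solve_two_component(lok_atl_matrix, measurement(lok_atl_matrix, [0.5, 1.0]))
        assert res.determinant == pytest.approx(116494.95)

    def test_wavelength_mismatch_raises(self, lok_atl_matrix):
        meas = MixtureMeasurement(wavelengths=(224.2, 251.6), absorbances=[0.5, 1.0])
        with pytest.raises(ValueError, match="wavelengths"):
            v.solve_two_component(lok_atl_matrix, meas)


class TestSolveGeneral:
    def test_agrees_with_closed_form_on_random_systems(self, rng):
        for _ in range(200):
            vals = rng.uniform(0.5, 1000.0, (2, 2))
            m = v.build_matrix(["A", "B"], [250.0, 260.0], vals)
            if np.linalg.cond(vals) > 1e6:
                continue
            a = rng.uniform(0.05, 2.5, 2)
            r1 = v.solve_two_component(m, measurement(m, a))
            r2 = v.solve_general(m, measurement(m, a))
            np.testing.assert_allclose(
                r1.concentrations_g_per_100ml,
                r2.concentrations_g_per_100ml,
                rtol=1e-9,
            )

    def test_three_component_forward_synthesis(self, band_models):
        wavelengths = (251.6, 224.2, 271.6)
        names = ("LOK", "ATL", "HCTZ")
        vals = np.array(
            [[band_models[n].absorptivity(w) for n in names] for w in wavelengths]
        )
        m = v.build_matrix(names, wavelengths, vals)
        conc = np.array([0.002, 0.0008, 0.0002])
        res = v.solve_general(m, measurement(m, vals @ conc))
        np.testing.assert_allclose(res.concentrations_g_per_100ml, conc, rtol=1e-9)

    def test_diagonal_matrix_is_componentwise_division(self):
        m = v.build_matrix(["A", "B"], [250.0, 260.0], np.diag([2.0, 4.0]))
        res = v.solve_general(m, measurement(m, [1.0, 1.0]))
        np.testing.assert_allclose(res.concentrations_g_per_100ml, [0.5, 0.25])

    def test_homogeneous_in_absorbance(self, atl_hctz_matrix, rng):
        a = rng.uniform(0.1, 1.0, 2)
        r1 = v.solve_general(atl_hctz_matrix, measurement(atl_hctz_matrix, a))
        r2 = v.solve_general(atl_hctz_matrix, measurement(atl_hctz_matrix, 3.0 * a))
        np.testing.assert_allclose(
            r2.concentrations_g_per_100ml, 3.0 * r1.concentrations_g_per_100ml,
            rtol=1e-12,
        )

    def test_non_square_raises(self):
        m = v.build_matrix(["A"], [250.0, 260.0], [[1.0], [2.0]])
        with pytest.raises(ValueError, match="square"):
            v.solve_general(m, MixtureMeasurement((250.0, 260.0), [0.1, 0.2]))


class TestRoundTripProperty:
    @given(
        st.lists(st.floats(1.0, 1500.0), min_size=4, max_size=4),
        st.lists(st.floats(1e-4, 5e-3), min_size=2, max_size=2),
    )
    def test_solve_inverts_forward_model(self, entries, conc):
        vals = np.array(entries).reshape(2, 2)
        if abs(np.linalg.det(vals)) < 1e-3 * vals.max() ** 2:
            return  # skip near-singular draws
        m = v.build_matrix(["A", "B"], [250.0, 260.0], vals)
        conc = np.asarray(conc)
        meas = MixtureMeasurement((250.0, 260.0), vals @ conc)
        res = v.solve_general(m, meas)
        np.testing.assert_allclose(res.concentrations_g_per_100ml, conc, rtol=1e-8)


class TestConditionDiagnostics:
    def test_identity_is_ok(self):
        m = v.build_matrix(["A", "B"], [250.0, 260.0], np.eye(2))
        cond, level = v.condition_diagnostics(m)
        assert cond == pytest.approx(1.0)
        assert level == "ok"

    def test_presets_are_ok(self, lok_atl_matrix, atl_hctz_matrix):
        for m in (lok_atl_matrix, atl_hctz_matrix):
            cond, level = v.condition_diagnostics(m)
            assert np.isfinite(cond) and level == "ok"

    def test_singular_reports_infinite_error(self):
        m = v.build_matrix(["A", "B"], [250.0, 260.0], [[1.0, 1.0], [1.0, 1.0]])
        cond, level = v.condition_diagnostics(m)
        assert cond == float("inf")
        assert level == "error"

    def test_warn_band(self):
        m = v.build_matrix(["A", "B"], [250.0, 260.0], [[1.0, 1.0], [1.0, 1.0002]])
        cond, level = v.condition_diagnostics(m)
        assert 1e3 <= cond < 1e8
        assert level == "warn"


class TestConvertUnits:
    def test_g_per_100ml_to_ug_per_ml(self):
        assert v.convert_units(0.002, "g/100 ml", "ug/ml") == pytest.approx(20.0)

    def test_inverse(self):
        assert v.convert_units(20.0, "µg/ml", "g/100 ml") == pytest.approx(0.002)

    def test_mg_per_ml(self):
        assert v.convert_units(1.0, "g/100 ml", "mg/ml") == pytest.approx(10.0)

    def test_unknown_unit_raises(self):
        with pytest.raises(ValueError, match="unknown concentration unit"):
            v.convert_units(1.0, "mol/l", "ug/ml")

    @given(st.floats(1e-6, 1e6), st.sampled_from(["g/100 ml", "ug/ml", "mg/ml"]),
           st.sampled_from(["g/100 ml", "ug/ml", "mg/ml"]))
    def test_round_trip_identity(self, value, u1, u2):
        back = v.convert_units(v.convert_units(value, u1, u2), u2, u1)
        assert back == pytest.approx(value, rel=1e-12)


class TestMatrixIO:
    def test_csv_round_trip(self, tmp_path, atl_hctz_matrix):
        path = tmp_path / "m.csv"
        v.write_matrix(atl_hctz_matrix, path)
        back = v.read_matrix(path)
        assert back.components == atl_hctz_matrix.components
        assert back.wavelengths == atl_hctz_matrix.wavelengths
        np.testing.assert_array_equal(back.values, atl_hctz_matrix.values)
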