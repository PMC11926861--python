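"""Shielding-tensor diagonalization, calibration, and convention algebra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from orimas import (
    ShieldingTensor,
    ShiftCalibration,
    diagonalize_shielding,
    haeberlen_parameters,
    read_tensor_table,
    shielding_tensor_to_params,
    shielding_to_shift,
    write_tensor_table,
)
from orimas.orientations import euler_zyz_to_matrix
from orimas.tensors import TensorTableError

from .conftest import make_params


class TestDiagonalize:
    def test_isotropic_matrix_is_degenerate(self):
        t = ShieldingTensor("s", "Gly", np.diag([100.0, 100.0, 100.0]))
        vals, euler, degenerate = diagonalize_shielding(t)
        assert np.allclose(vals, 100.0)
        assert degenerate

    def test_diagonal_matrix_recovers_entries(self):
        t = ShieldingTensor("s", "Pro", np.diag([120.0, 100.0, 80.0]))
        vals, euler, degenerate = diagonalize_shielding(t)
        assert np.allclose(sorted(vals, reverse=True), [120, 100, 80])
        assert not degenerate

    def test_rotated_matrix_same_principal_values(self):
        base = np.diag([120.0, 100.0, 80.0])
        R = euler_zyz_to_matrix(0.0, 0.0, np.radians(30.0))
        t = ShieldingTensor("s", "Hyp", R @ base @ R.T)
        vals, _, _ = diagonalize_shielding(t)
        assert np.allclose(sorted(vals, reverse=True), [120, 100, 80], atol=1e-9)

    def test_trace_preserved_iso_mean(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            m = rng.normal(size=(3, 3)) * 50
            t = ShieldingTensor("s", "other", m)
            vals, _, _ = diagonalize_shielding(t)
            assert abs(vals.mean() - np.trace(m) / 3.0) < 1e-9

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=50, deadline=None)
    def test_rotation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        evals = rng.normal(size=3) * 60
        from scipy.stats import special_ortho_group

        R = special_ortho_group.rvs(3, random_state=seed)
        t = ShieldingTensor("s", "other", R @ np.diag(evals) @ R.T)
        vals, _, _ = diagonalize_shielding(t)
        assert np.allclose(np.sort(vals), np.sort(evals), atol=1e-8)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ShieldingTensor("s", "Gly", np.full((3, 3), np.nan))

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            ShieldingTensor("s", "Xyz", np.eye(3))


class TestCalibration:
    def test_intercept_at_zero_shielding(self):
        assert shielding_to_shift(0.0) == pytest.approx(175.7662, abs=1e-12)

    def test_printed_line_at_100ppm(self):
        assert shielding_to_shift(100.0) == pytest.approx(78.1662, abs=1e-9)

    def test_round_trip_identity(self):
        cal = ShiftCalibration()
        delta = np.linspace(-50, 250, 13)
        assert np.allclose(cal(cal.inverse(delta)), delta, atol=1e-9)

    def test_monotone_decreasing(self):
        sigma = np.linspace(-100, 300, 100)
        delta = shielding_to_shift(sigma)
        assert np.all(np.diff(delta) < 0)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            ShiftCalibration(slope=0.0)


class TestHaeberlen:
    @pytest.mark.parametrize(
        "principal,expect",
        [
            # (delta_iso, zeta, eta, span, skew)
            ((10.0, -5.0, -5.0), (0.0, 10.0, 0.0, 15.0, -1.0)),
            ((30.0, 0.0, -10.0), (6.6667, 23.3333, 0.4286, 40.0, -0.5)),
        ],
    )
    def test_convention_examples(self, principal, expect):
        p = haeberlen_parameters(principal)
        assert p.delta_iso == pytest.approx(expect[0], abs=1e-4)
        assert p.zeta == pytest.approx(expect[1], abs=1e-4)
        assert p.eta == pytest.approx(expect[2], abs=1e-4)
        assert p.span_omega == pytest.approx(expect[3], abs=1e-4)
        assert p.skew_kappa == pytest.approx(expect[4], abs=1e-4)

    def test_isotropic_flagged_degenerate(self):
        p = haeberlen_parameters((5.0, 5.0, 5.0))
        assert p.zeta == 0.0 and p.eta == 0.0 and p.degenerate

    @given(
        st.floats(-120, 120).filter(lambda z: abs(z) > 1e-3),
        st.floats(0, 1),
        st.floats(-50, 250),
    )
    @settings(max_examples=200, deadline=None)
    def test_round_trip(self, zeta, eta, diso):
        """(diso, zeta, eta) -> principal values -> parameters is identity."""
        p0 = make_params(zeta, eta, diso)
        p1 = haeberlen_parameters(p0.principal_shifts())
        assert p1.delta_iso == pytest.approx(diso, abs=1e-9)
        assert p1.zeta == pytest.approx(zeta, abs=1e-9)
        assert p1.eta == pytest.approx(eta, abs=1e-8)

    def test_span_skew_consistent_with_principal_values(self):
        p = make_params(-75.0, 0.5, 172.0)
        d = np.sort(p.principal_shifts())[::-1]
        assert p.span_omega == pytest.approx(d[0] - d[2], abs=1e-9)
        assert p.skew_kappa == pytest.approx(
            3 * (d[1] - p.delta_iso) / p.span_omega, abs=1e-9
        )


class TestTensorTable:
    def _write(self, path, text):
        path.write_text(text)
        return path

    def test_three_row_principal_file(self, tmp_path):
        f = self._write(
            tmp_path / "t.tsv",
            "site_id\tresidue\ts11\ts22\ts33\n"
            "a\tGly\t240\t180\t96\n"
            "b\tPro\t245\t175\t95\n"
            "c\tHyp\t238\t182\t94\n",
        )
        records = read_tensor_table(f)
        assert len(records) == 3
        assert [r.residue for r in records] == ["Gly", "Pro", "Hyp"]

    def test_matrix_and_principal_routes_agree(self, tmp_path):
        rng = np.random.default_rng(1)
        m = rng.normal(size=(3, 3)) * 20 + np.diag([240.0, 180.0, 96.0])
        m = 0.5 * (m + m.T)
        evals = np.linalg.eigvalsh(m)
        f1 = self._write(
            tmp_path / "m.csv",
            "# scale=shielding\nsite_id,residue,"
            + ",".join(f"m{i}{j}" for i in (1, 2, 3) for j in (1, 2, 3))
            + "\n"
            + "a,Gly," + ",".join(f"{v:.12f}" for v in m.ravel()) + "\n",
        )
        f2 = self._write(
            tmp_path / "p.csv",
            "# scale=shielding\nsite_id,residue,s11,s22,s33\n"
            "a,Gly," + ",".join(f"{v:.12f}" for v in evals) + "\n",
        )
        p1 = read_tensor_table(f1)[0]
        p2 = read_tensor_table(f2)[0]
        assert p1.delta_iso == pytest.approx(p2.delta_iso, abs=1e-9)
        assert p1.zeta == pytest.approx(p2.zeta, abs=1e-9)
        assert p1.eta == pytest.approx(p2.eta, abs=1e-9)

    def test_empty_file_warns_and_returns_empty(self, tmp_path):
        f = self._write(tmp_path / "e.tsv", "")
        with pytest.warns(UserWarning):
            assert read_tensor_table(f) == []

    def test_missing_columns_named(self, tmp_path):
        f = self._write(tmp_path / "bad.tsv", "site_id\tresidue\tfoo\na\tGly\t1\n")
        with pytest.raises(TensorTableError):
            read_tensor_table(f)

    def test_non_numeric_cell_names_row(self, tmp_path):
        f = self._write(
            tmp_path / "bad2.tsv",
            "site_id\tresidue\ts11\ts22\ts33\na\tGly\tx\t2\t3\n",
        )
        with pytest.raises(TensorTableError, match="row 0"):
            read_tensor_table(f)

    def test_write_read_round_trip(self, tmp_path):
        p = make_params(-75.0, 0.5, 172.0, pas=(0.1, 0.8, 0.3))
        object.__setattr__(p, "residue", "Gly")
        f = tmp_path / "rt.tsv"
        write_tensor_table(f, [p])
        q = read_tensor_table(f)[0]
        assert q.zeta == pytest.approx(p.zeta, abs=1e-9)
        assert q.eta == pytest.approx(p.eta, abs=1e-9)
        assert np.allclose(q.pas_orientation, p.pas_orientation, atol=1e-9)


class TestCalibrationModes:
    def test_per_component_scales_anisotropy_by_slope(self):
        sigma = np.diag([60.0, 30.0, -20.0])
        t = ShieldingTensor("s", "Gly", sigma)
        p = shielding_tensor_to_params(t, calibrate_mode="per_component")
        # anisotropy on the shift scale is the sigma-scale anisotropy
        # scaled by |slope| and sign-flipped (slope < 0)
        sig_iso = np.diag(sigma).mean()
        sig_params = haeberlen_parameters(np.diag(sigma) - sig_iso)
        assert p.zeta == pytest.approx(-0.9760 * sig_params.zeta, abs=1e-9)
        assert p.eta == pytest.approx(sig_params.eta, abs=1e-9)

    def test_isotropic_only_negates_deviations(self):
        sigma = np.diag([60.0, 30.0, -20.0])
        t = ShieldingTensor("s", "Gly", sigma)
        p = shielding_tensor_to_params(t, calibrate_mode="isotropic_only")
        sig_iso = np.diag(sigma).mean()
        sig_params = haeberlen_parameters(np.diag(sigma) - sig_iso)
        assert p.zeta == pytest.approx(-sig_params.zeta, abs=1e-9)
        cal = ShiftCalibration()
        assert p.delta_iso == pytest.approx(float(cal(sig_iso)), abs=1e-9)
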