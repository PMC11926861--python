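"""Composite patterns, normalization, strain/alignment sweeps, and the
force->stress helper."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from orimas import (
    CompositeSpec,
    SidebandPattern,
    SpectrometerConfig,
    StrainPoint,
    alignment_sweep,
    composite_pattern,
    force_to_stress,
    normalize_pattern,
    strain_sweep,
)
from orimas.synthetic import SyntheticSpec, make_strain_tensor_table

from .conftest import make_params


def _pattern(intensities, config, delta_iso=170.0):
    inten = np.asarray(intensities, dtype=float)
    n = (len(inten) - 1) // 2
    return SidebandPattern(
        indices=np.arange(-n, n + 1), intensities=inten,
        delta_iso=delta_iso, config=config,
    )


class TestComposite:
    def test_identical_inputs_unchanged(self, config):
        pat = _pattern([0.1, 0.2, 0.4, 0.2, 0.1], config)
        comp = composite_pattern(
            {"Gly": pat, "Pro": pat, "Hyp": pat}, CompositeSpec()
        )
        assert np.allclose(comp.intensities, pat.intensities, atol=1e-12)

    def test_single_residue_weight(self, config):
        g = _pattern([0.1, 0.2, 0.4, 0.2, 0.1], config)
        p = _pattern([0.3, 0.1, 0.2, 0.1, 0.3], config)
        comp = composite_pattern(
            {"Gly": g, "Pro": p},
            CompositeSpec(residue_weights={"Gly": 1.0, "Pro": 0.0}),
        )
        assert np.allclose(comp.intensities, g.intensities, atol=1e-12)

    def test_matches_direct_weighted_mean(self, config):
        rng = np.random.default_rng(4)
        pats = {r: _pattern(rng.dirichlet(np.ones(5)), config)
                for r in ("Gly", "Pro", "Hyp")}
        w = {"Gly": 2.0, "Pro": 1.0, "Hyp": 3.0}
        comp = composite_pattern(pats, CompositeSpec(residue_weights=w))
        expected = sum(
            w[r] * pats[r].intensities for r in pats
        ) / sum(w.values())
        expected /= expected.sum()
        assert np.allclose(comp.intensities, expected, atol=1e-12)

    @given(st.floats(0.01, 5.0), st.floats(0.01, 5.0), st.floats(0.01, 5.0))
    @settings(max_examples=30, deadline=None)
    def test_linearity_in_weights(self, wg, wp, wh):
        config = SpectrometerConfig()
        rng = np.random.default_rng(9)
        pats = {r: _pattern(rng.dirichlet(np.ones(5)), config)
                for r in ("Gly", "Pro", "Hyp")}
        comp = composite_pattern(
            pats, CompositeSpec(residue_weights={"Gly": wg, "Pro": wp, "Hyp": wh})
        )
        direct = (wg * pats["Gly"].intensities + wp * pats["Pro"].intensities
                  + wh * pats["Hyp"].intensities)
        direct /= direct.sum()
        assert np.allclose(comp.intensities, direct, atol=1e-12)

    def test_mismatched_config_rejected(self, config):
        other = SpectrometerConfig(mas_rate_Hz=3000.0)
        g = _pattern([0.2, 0.6, 0.2], config)
        p = _pattern([0.2, 0.6, 0.2], other)
        with pytest.raises(ValueError, match="MAS"):
            composite_pattern(
                {"Gly": g, "Pro": p},
                CompositeSpec(residue_weights={"Gly": 1, "Pro": 1}),
            )


class TestNormalize:
    def test_isotropic_mode(self, config):
        pat = _pattern([0.1, 0.2, 0.4, 0.2, 0.1], config)
        assert normalize_pattern(pat, "isotropic").intensity(0) == 1.0

    def test_sideband_reference_mode(self, config):
        inten = np.zeros(9)
        inten[1] = 0.25  # index -3
        inten[4] = 0.5
        inten[7] = 0.25
        pat = _pattern(inten, config)
        assert normalize_pattern(pat, "sideband:-3").intensity(-3) == 1.0

    def test_none_mode_unchanged(self, config):
        pat = _pattern([0.1, 0.2, 0.4, 0.2, 0.1], config)
        assert normalize_pattern(pat, "none") is pat

    def test_zero_reference_rejected(self, config):
        pat = _pattern([0.5, 0.0, 0.5], config)
        with pytest.raises(ValueError, match="isotropic"):
            normalize_pattern(pat, "isotropic")


class TestStrainSweep:
    def _points_iso_only(self):
        """Strain table in which only delta_iso moves with strain."""
        spec = SyntheticSpec(
            strain_response={
                "Gly": (-0.30, 0.0, 0.0),
                "Pro": (-0.10, 0.0, 0.0),
                "Hyp": (0.05, 0.0, 0.0),
            }
        )
        return make_strain_tensor_table(spec)

    def test_reference_ratios_are_unity(self, config):
        sw = strain_sweep(self._points_iso_only(), CompositeSpec(), config,
                          grid_n=200, seed=1)
        assert np.allclose(sw.ratios[0], 1.0, atol=1e-12)

    def test_isotropic_shift_does_not_move_sidebands(self, config):
        """Sideband intensities depend on (zeta, eta, orientation) only."""
        sw = strain_sweep(self._points_iso_only(), CompositeSpec(), config,
                          grid_n=400, seed=1)
        assert np.abs(sw.ratios - 1.0).max() < 1e-6

    def test_ratios_match_per_strain_recomputation(self, config):
        from orimas.analysis import _composite_ensemble, _group_by_residue
        from orimas.orientations import DistributionSpec, sample_ellipsoid_projected

        points = make_strain_tensor_table(SyntheticSpec())
        sw = strain_sweep(points, CompositeSpec(), config, grid_n=300, seed=5)
        oset = sample_ellipsoid_projected(
            DistributionSpec(n_points=300, c_over_a=10.0, seed=5)
        )
        for i, sp in enumerate(sorted(points, key=lambda q: q.strain_pct)):
            pat = _composite_ensemble(
                _group_by_residue(sp.tensors), oset, CompositeSpec(), config
            )
            pat = normalize_pattern(pat, "isotropic")
            ref = _composite_ensemble(
                _group_by_residue(points[0].tensors), oset, CompositeSpec(), config
            )
            ref = normalize_pattern(ref, "isotropic")
            keep = np.abs(pat.indices) <= 6
            direct = pat.intensities[keep] / ref.intensities[keep]
            assert np.allclose(sw.ratios[i], direct, atol=1e-10)

    def test_same_seed_is_bit_identical(self, config):
        points = make_strain_tensor_table(SyntheticSpec())
        s1 = strain_sweep(points, CompositeSpec(), config, grid_n=200, seed=3)
        s2 = strain_sweep(points, CompositeSpec(), config, grid_n=200, seed=3)
        assert np.array_equal(s1.ratios, s2.ratios)

    def test_missing_reference_rejected(self, config):
        pts = [StrainPoint(force_pN=10.0, strain_pct=1.4,
                           tensors=[make_params(-75, 0.5, 170)])]
        with pytest.raises(ValueError, match="0%"):
            strain_sweep(pts, CompositeSpec(), config, grid_n=50, seed=0)


class TestAlignmentSweep:
    def test_reference_ratios_are_unity(self, config):
        points = make_strain_tensor_table(SyntheticSpec())
        sw = alignment_sweep(points[0].tensors, [1, 2, 5], CompositeSpec(),
                             config, grid_n=300, seed=2)
        assert np.allclose(sw.ratios[0], 1.0, atol=1e-12)

    def test_missing_unit_reference_rejected(self, config):
        points = make_strain_tensor_table(SyntheticSpec())
        with pytest.raises(ValueError, match="reference"):
            alignment_sweep(points[0].tensors, [2, 5], CompositeSpec(),
                            config, grid_n=50, seed=0)

    def test_extreme_alignment_approaches_axis_crystallite(self, config):
        """As c/a grows with the tensor PAS on the molecular axis, the
        ensemble approaches the beta = 0 single-crystallite pattern."""
        from orimas import crystallite_sidebands, ensemble_pattern
        from orimas.orientations import DistributionSpec, sample_ellipsoid_projected

        p = make_params(-75.0, 0.5, 170.0)  # PAS = molecular frame
        oset = sample_ellipsoid_projected(
            DistributionSpec(n_points=4000, c_over_a=5000.0, seed=4)
        )
        ens = ensemble_pattern(p, oset, config)
        limit = crystallite_sidebands(p, 0.0, 0.0, config)
        assert np.abs(ens.intensities - limit.intensities).max() < 0.02


class TestForceToStress:
    def test_reported_reference_stresses(self):
        assert force_to_stress(10.0, 1.5) == pytest.approx(5.7, rel=0.01)
        assert force_to_stress(750.0, 1.5) == pytest.approx(424.0, rel=0.01)

    def test_zero_force(self):
        assert force_to_stress(0.0) == 0.0

    @given(st.floats(0.1, 1000.0), st.floats(0.5, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_scaling_laws(self, f, d):
        s = force_to_stress(f, d)
        assert force_to_stress(2 * f, d) == pytest.approx(2 * s, rel=1e-12)
        assert force_to_stress(f, 2 * d) == pytest.approx(s / 4, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            force_to_stress(10.0, 0.0)
        with pytest.raises(ValueError):
            force_to_stress(-1.0)
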