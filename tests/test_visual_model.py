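"""Receptor-noise-limited model: templates, catches, noise and JND distances."""

import numpy as np
import pandas as pd
import pytest

from uvmorph import (
    CohortConfig,
    SpectrumSet,
    VisualSystem,
    WavelengthGrid,
    achromatic_distance,
    chromatic_distance,
    pairwise_jnd,
    pigment_template,
    quantum_catch,
    receptor_noise,
    template_spectrum,
)
from uvmorph.visual import _gls_ds2, log_catches

from conftest import GRID, make_set


def gls_oracle(df, w):
    """Independent scalar minimisation: ΔS² = min_x Σ (Δf_i − x)² / ω_i²."""
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(lambda x: float(np.sum((df - x) ** 2 / w**2)))
    return np.sqrt(res.fun)


class TestPigmentTemplate:
    @pytest.mark.parametrize("lmax", [365.0, 460.0, 495.0, 560.0])
    def test_peaks_at_lmax(self, lmax):
        s = pigment_template(lmax, GRID)
        assert s.max() == pytest.approx(1.0)
        assert abs(GRID.wavelengths()[np.argmax(s)] - lmax) <= 1.0

    def test_unimodal_over_grid(self):
        s = pigment_template(495.0, GRID)
        d = np.diff(s)
        sign_changes = np.sum(np.diff(np.sign(d[np.abs(d) > 1e-12])) != 0)
        assert sign_changes <= 1

    def test_half_maximum_bandwidth_matches_dense_evaluation(self):
        # FWHM read off the 1 nm grid agrees with the closed form evaluated
        # at 0.01 nm resolution to within 2 nm
        lmax = 495.0
        coarse = pigment_template(lmax, GRID)
        dense_grid = WavelengthGrid(300.0, 700.0, 0.01)
        dense = pigment_template(lmax, dense_grid)

        def fwhm(s, wl):
            above = wl[s >= 0.5]
            return above[-1] - above[0]

        assert abs(
            fwhm(coarse, GRID.wavelengths()) - fwhm(dense, dense_grid.wavelengths())
        ) < 2.0

    def test_lmax_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            pigment_template(250.0, GRID)


class TestQuantumCatch:
    def test_perfect_reflector_is_von_kries_fixed_point(self, vs):
        sset = make_set(np.ones((1, 401)))
        c = quantum_catch(sset, vs)
        for cone in vs.cone_names:
            assert c[f"q_{cone}"].iloc[0] == pytest.approx(1.0)
            assert c[f"f_{cone}"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_intensity_scaling_shifts_all_log_catches_equally(self, vs):
        rng = np.random.default_rng(2)
        base = rng.uniform(1, 50, 401)
        sset = make_set(np.vstack([base, 3.0 * base]), ids=["a", "b"])
        f = log_catches(quantum_catch(sset, vs), vs)
        np.testing.assert_allclose(f[1] - f[0], np.log(3.0), atol=1e-12)

    def test_zero_spectrum_flagged(self, vs):
        sset = make_set(np.zeros((1, 401)))
        c = quantum_catch(sset, vs)
        assert not c["valid"].iloc[0]
        assert np.isnan(c["f_LWS"].iloc[0])

    def test_illuminant_intensity_invariance(self):
        # von Kries normalisation cancels any overall illuminant scaling
        rng = np.random.default_rng(4)
        refl = rng.uniform(1, 40, (1, 401))
        sset = make_set(refl)
        q1 = quantum_catch(sset, VisualSystem())
        q2 = quantum_catch(sset, VisualSystem(illuminant=np.full(401, 7.5)))
        for cone in ("UVS", "SWS", "MWS", "LWS"):
            assert q1[f"q_{cone}"].iloc[0] == pytest.approx(q2[f"q_{cone}"].iloc[0])


class TestReceptorNoise:
    def test_stated_parameters_give_canonical_noise_vector(self, vs):
        np.testing.assert_allclose(receptor_noise(vs), [0.1, 0.1, 0.1, 0.05])

    def test_equal_abundances_give_uniform_weber(self):
        vs = VisualSystem(abundances=(2.0, 2.0, 2.0, 2.0), weber_ref=0.08)
        np.testing.assert_allclose(receptor_noise(vs), 0.08)

    def test_reference_cone_noise_equals_weber(self):
        for ab in [(1, 2, 3, 4), (5, 1, 1, 2)]:
            vs = VisualSystem(abundances=ab, weber_ref=0.06)
            assert receptor_noise(vs)[vs.reference_index] == pytest.approx(0.06)


class TestChromaticDistance:
    def test_identical_inputs_give_zero(self):
        f = np.array([0.1, -0.2, 0.3, 0.4])
        w = np.array([0.1, 0.1, 0.1, 0.05])
        assert chromatic_distance(f, f, w) == 0.0

    def test_pure_intensity_shift_is_achromatic(self):
        w = np.array([0.1, 0.1, 0.1, 0.05])
        for c in (-2.0, 0.5, 10.0):
            fB = np.array([0.3, 0.1, -0.4, 0.2])
            assert chromatic_distance(fB + c, fB, w) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_matches_gls_oracle_on_random_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            df = rng.normal(0, 1, 4)
            w = rng.uniform(0.01, 0.5, 4)
            closed = chromatic_distance(df, np.zeros(4), w)
            assert abs(closed - gls_oracle(df, w)) < 1e-9

    def test_noise_scaling_law(self):
        rng = np.random.default_rng(5)
        df = rng.normal(0, 1, 4)
        w = rng.uniform(0.02, 0.3, 4)
        d1 = chromatic_distance(df, np.zeros(4), w)
        d2 = chromatic_distance(df, np.zeros(4), w / 3.0)
        assert d2 == pytest.approx(3.0 * d1)

    def test_triangle_inequality_on_random_triples(self):
        rng = np.random.default_rng(6)
        w = np.array([0.1, 0.1, 0.1, 0.05])
        for _ in range(200):
            a, b, c = rng.normal(0, 1, (3, 4))
            dab = chromatic_distance(a, b, w)
            dbc = chromatic_distance(b, c, w)
            dac = chromatic_distance(a, c, w)
            assert dac <= dab + dbc + 1e-12

    def test_non_tetrachromatic_input_uses_generalized_path(self):
        # pentachromat: closed tetra form does not apply, GLS path must
        rng = np.random.default_rng(8)
        df = rng.normal(0, 1, 5)
        w = rng.uniform(0.05, 0.2, 5)
        assert chromatic_distance(df, np.zeros(5), w) == pytest.approx(gls_oracle(df, w))

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            chromatic_distance(np.zeros(4), np.zeros(4), np.zeros(3))


class TestAchromaticDistance:
    def test_one_weber_step_is_one_jnd(self, vs):
        fA = np.array([0.0, 0.0, 0.0, 0.05])
        fB = np.zeros(4)
        assert achromatic_distance(fA, fB, vs) == pytest.approx(1.0)

    def test_identical_spectra_zero(self, vs):
        f = np.array([0.1, 0.2, 0.3, 0.4])
        assert achromatic_distance(f, f, vs) == 0.0

    def test_monotone_in_reference_difference(self, vs):
        base = np.zeros(4)
        dists = [
            achromatic_distance(base + np.array([0, 0, 0, d]), base, vs)
            for d in (0.01, 0.05, 0.2)
        ]
        assert dists == sorted(dists)


class TestPairwiseJnd:
    def test_identical_spectra_give_zero_matrix(self, vs):
        refl = np.tile(np.random.default_rng(1).uniform(1, 40, 401), (3, 1))
        chrom, _ = pairwise_jnd(make_set(refl), vs)
        np.testing.assert_allclose(chrom.to_numpy(), 0.0, atol=1e-9)

    def test_symmetry_zero_diagonal_nonnegative(self, vs):
        refl = np.random.default_rng(2).uniform(1, 50, (6, 401))
        chrom, achro = pairwise_jnd(make_set(refl), vs, achromatic=True)
        for M in (chrom.to_numpy(), achro.to_numpy()):
            np.testing.assert_allclose(M, M.T, atol=1e-12)
            np.testing.assert_allclose(np.diag(M), 0.0, atol=1e-12)
            assert (M >= 0).all()

    def test_matrix_agrees_with_scalar_distance(self, vs):
        refl = np.random.default_rng(3).uniform(1, 50, (5, 401))
        sset = make_set(refl)
        chrom, _ = pairwise_jnd(sset, vs)
        f = log_catches(quantum_catch(sset, vs), vs)
        w = receptor_noise(vs)
        for i in range(5):
            for j in range(i):
                assert chrom.iloc[i, j] == pytest.approx(
                    chromatic_distance(f[i], f[j], w), abs=1e-9
                )

    def test_invalid_spectra_excluded_with_warning(self, vs):
        refl = np.vstack([np.zeros(401), np.random.default_rng(0).uniform(1, 40, (2, 401))])
        with pytest.warns(UserWarning, match="catch-invalid"):
            chrom, _ = pairwise_jnd(make_set(refl), vs)
        assert chrom.shape == (2, 2)

    def test_white_class_templates_easily_discriminable(self, vs):
        # noise-free UV+white vs UV-white templates sit well past the 3 JND
        # "easily discriminable" band
        cfg = CohortConfig()
        tp = template_spectrum("UVplus_white", cfg)
        tm = template_spectrum("UVminus_white", cfg)
        sset = make_set(np.vstack([tp.reflectance, tm.reflectance]), ids=["p", "m"])
        chrom, _ = pairwise_jnd(sset, vs)
        assert chrom.iloc[0, 1] > 3.0
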