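"""Outer-product connectome, FLN normalisation and power-law exponent fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import brainparc as bp
from brainparc.connectivity import DegenerateFitError, InsufficientDataError
from brainparc.fragmentation import InvalidInputError


class TestOuterProduct:
    def test_direct_substitution(self):
        C = bp.outer_product_connectome([1.0, 1.0], f=1.0, rho=1.0)
        assert C.values[0, 1] == 0.5
        assert C.values[1, 0] == 0.5
        assert C.values[0, 0] == 0.0  # diagonal excluded by default

    def test_total_count_identity_with_diagonal(self):
        # with the self-blocks kept, sum(C) = f * N^2 / 2 for N = rho * sum(v)
        v = np.array([2.0, 3.0, 5.0])
        f, rho = 0.3, 1.7
        C = bp.outer_product_connectome(v, f=f, rho=rho, include_diagonal=True)
        N = rho * v.sum()
        assert C.values.sum() == pytest.approx(f * N**2 / 2, rel=1e-12)

    def test_bilinearity_in_volumes(self, lognormal_volumes):
        a = bp.outer_product_connectome(lognormal_volumes)
        b = bp.outer_product_connectome(2.0 * lognormal_volumes)
        assert np.allclose(b.values, 4.0 * a.values)

    @pytest.mark.parametrize("kw", [dict(f=1.5), dict(f=-0.1), dict(rho=0.0)])
    def test_invalid_parameters(self, kw):
        with pytest.raises(InvalidInputError):
            bp.outer_product_connectome([1.0, 2.0], **kw)


class TestNormalizeFln:
    def test_simple_row(self):
        C = bp.ConnectivityMatrix(values=[[0.0, 2.0, 2.0], [1.0, 0.0, 3.0],
                                          [2.0, 2.0, 0.0]])
        fln = bp.normalize_fln(C)
        assert fln.values[0].tolist() == [0.0, 0.5, 0.5]
        assert fln.normalized

    def test_nonzero_rows_sum_to_one(self, lognormal_volumes):
        fln = bp.normalize_fln(bp.outer_product_connectome(lognormal_volumes))
        assert np.allclose(fln.values.sum(axis=1), 1.0, atol=1e-9)

    def test_fln_depends_on_source_only(self, lognormal_volumes):
        # with self-blocks kept, every FLN row is exactly v_j / sum(v)
        C = bp.outer_product_connectome(lognormal_volumes, include_diagonal=True)
        fln = bp.normalize_fln(C)
        spread = fln.values.max(axis=0) / fln.values.min(axis=0) - 1.0
        assert spread.max() < 1e-9

    def test_zero_row_left_zero_with_warning(self):
        C = bp.ConnectivityMatrix(values=[[0.0, 0.0], [1.0, 0.0]])
        with pytest.warns(UserWarning, match="all-zero"):
            fln = bp.normalize_fln(C)
        assert fln.values[0].tolist() == [0.0, 0.0]
        assert fln.values[1].tolist() == [1.0, 0.0]

    def test_double_normalization_rejected(self):
        fln = bp.normalize_fln(bp.ConnectivityMatrix(values=[[1.0, 1.0]]))
        with pytest.raises(InvalidInputError):
            bp.normalize_fln(fln)


class TestFitPowerLaw:
    def test_exact_log_linear_input(self, lognormal_volumes):
        fit = bp.fit_power_law(lognormal_volumes**2.33, lognormal_volumes)
        assert fit.exponent == pytest.approx(2.33, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.n_points == 90

    def test_pure_outer_product_fln_gives_unit_exponent(self, lognormal_volumes):
        fln = bp.normalize_fln(bp.outer_product_connectome(lognormal_volumes))
        fit = bp.fit_power_law(fln.values[0], lognormal_volumes)
        assert fit.exponent == pytest.approx(1.0, abs=1e-9)

    def test_zero_strengths_excluded(self, lognormal_volumes):
        s = lognormal_volumes**1.5
        s[::3] = 0.0
        fit = bp.fit_power_law(s, lognormal_volumes)
        assert fit.n_points == int((s > 0).sum())
        assert fit.exponent == pytest.approx(1.5, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            bp.fit_power_law([1.0, 2.0, 0.0, 0.0], [1.0, 2.0, 3.0, 4.0])

    def test_degenerate_volume_spread(self):
        with pytest.raises(DegenerateFitError):
            bp.fit_power_law([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_r_squared_consistency(self, lognormal_volumes):
        rng = np.random.default_rng(1)
        s = lognormal_volumes**2.0 * np.exp(rng.normal(0, 1.0, 90))
        fit = bp.fit_power_law(s, lognormal_volumes)
        assert fit.r_squared == pytest.approx(fit.r**2, abs=1e-12)

    @given(c=st.floats(1e-3, 1e3), d=st.floats(1e-3, 1e3))
    @settings(deadline=None, max_examples=50)
    def test_rescaling_invariance(self, c, d):
        v = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        s = v**1.7
        base = bp.fit_power_law(s, v)
        s_scaled = bp.fit_power_law(c * s, v)
        v_scaled = bp.fit_power_law(s, d * v)
        assert s_scaled.exponent == pytest.approx(base.exponent, abs=1e-7)
        assert s_scaled.intercept == pytest.approx(
            base.intercept + np.log(c), abs=1e-6)
        assert v_scaled.exponent == pytest.approx(base.exponent, abs=1e-7)


class TestFitIncomingOutgoing:
    def test_single_target_outer_product(self, lognormal_volumes):
        fln = bp.normalize_fln(bp.outer_product_connectome(lognormal_volumes))
        fits = bp.fit_incoming(fln, lognormal_volumes, target_ids=[0])
        assert fits[0].exponent == pytest.approx(1.0, abs=1e-9)

    def test_pooled_identical_rows_matches_single_row(self, lognormal_volumes):
        fln = bp.make_power_law_fln(lognormal_volumes, exponent=2.0, seed=0)
        # duplicate one row so pooling adds no new information
        vals = np.vstack([fln.values[0], fln.values[0], fln.values[0]])
        dup = bp.ConnectivityMatrix(values=vals, normalized=True)
        single = bp.fit_incoming(dup, lognormal_volumes, target_ids=[0])[0]
        pooled = bp.fit_incoming(dup, lognormal_volumes, pooled=True)
        assert pooled.exponent == pytest.approx(single.exponent, abs=1e-9)

    def test_unnormalized_matrix_rejected(self, lognormal_volumes):
        C = bp.outer_product_connectome(lognormal_volumes)
        with pytest.raises(InvalidInputError):
            bp.fit_incoming(C, lognormal_volumes)

    def test_pooled_exponent_between_planted_extremes(self):
        rng = np.random.default_rng(42)
        v = bp.make_lognormal_volumes(91, sigma=1.24, seed=10)
        planted = [2.67, 2.85, 1.79]
        rows = [
            v**eta * np.exp(rng.normal(0, 1.5, 91)) for eta in planted
        ]
        C = bp.ConnectivityMatrix(values=np.vstack(rows), normalized=True)
        pooled = bp.fit_incoming(C, v, pooled=True)
        per_row = bp.fit_incoming(C, v)
        lo = min(f.exponent for f in per_row.values())
        hi = max(f.exponent for f in per_row.values())
        assert lo <= pooled.exponent <= hi

    def test_incoming_exponent_recovery_at_realistic_noise(self):
        """Planted eta = 2.67 with scatter tuned so r^2 is near 0.6 (the
        regime of real tracer fits): mean recovery within 0.25."""
        estimates, r2s = [], []
        for seed in range(100):
            v = bp.make_lognormal_volumes(90, sigma=1.24, seed=200 + seed)
            fln = bp.make_power_law_fln(v, exponent=2.67, noise_sigma=2.6,
                                        seed=seed)
            fit = bp.fit_incoming(fln, v, target_ids=[0])[0]
            estimates.append(fit.exponent)
            r2s.append(fit.r_squared)
        assert abs(np.mean(estimates) - 2.67) < 0.25
        assert 0.45 < np.mean(r2s) < 0.8  # the intended noise regime

    def test_outgoing_exponent_recovery(self):
        """Planted kappa = 1.30 over 295 targets with moderate scatter."""
        estimates = []
        for seed in range(100):
            rng = np.random.default_rng(500 + seed)
            v = bp.make_lognormal_volumes(295, sigma=1.24, seed=900 + seed)
            col = v**1.30 * np.exp(rng.normal(0, 1.9, 295))
            C = bp.ConnectivityMatrix(values=col[:, None])
            fit = bp.fit_outgoing(C, v, source_ids=[0])[0]
            estimates.append(fit.exponent)
        assert abs(np.mean(estimates) - 1.30) < 0.15

    def test_exact_power_law_column(self):
        v = np.array([1.0, 2.0, 4.0, 8.0])
        C = bp.ConnectivityMatrix(values=(v**1.3)[:, None])
        fit = bp.fit_outgoing(C, v, source_ids=[0])[0]
        assert fit.exponent == pytest.approx(1.3, abs=1e-12)

    def test_outgoing_equal_volumes_degenerate(self):
        C = bp.ConnectivityMatrix(values=np.ones((4, 1)))
        with pytest.raises(DegenerateFitError):
            bp.fit_outgoing(C, np.full(4, 2.0), source_ids=[0])
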