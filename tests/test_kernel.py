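"""Kernel discretization: size limits, closed forms, quadrature, eviction."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.special import expit
from scipy.stats import norm

from lupine_ipm import (
    DiscretizedIPM,
    IPMConfig,
    build_kernel,
    check_eviction,
    compute_lambda,
    default_size_limits,
    resolve_size_limits,
)
from lupine_ipm.params import (
    GaussianRate,
    LinearRate,
    LogisticRate,
    RecruitSize,
    VitalRateParams,
)


def _make_params(**overrides):
    base = dict(
        survival=LogisticRate(1.13, 1.16),
        growth=GaussianRate(3.0, 0.2, 0.3),
        flowering=LogisticRate(0.3, -1.0),
        shoots=LinearRate(2.67, -0.49),
        recruit_size=RecruitSize(2.3, 0.25),
        e=0.122,
        e_sb=0.122,
        s_sb=0.977,
        seeds_per_shoot=60.0,
    )
    base.update(overrides)
    return VitalRateParams(**base)


class TestSizeLimits:
    def test_direct_arithmetic(self):
        assert resolve_size_limits([2.0, 3.0], IPMConfig()) == pytest.approx((1.8, 3.3))

    def test_degenerate_sizes_still_give_valid_interval(self):
        L, U = resolve_size_limits([2.5, 2.5], IPMConfig())
        assert (L, U) == pytest.approx((2.25, 2.75))
        assert L < U

    def test_empty_sizes_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            resolve_size_limits([], IPMConfig())

    def test_raw_scale_applies_factors_to_heights(self):
        cfg = IPMConfig(limits_scale="raw")
        L, U = resolve_size_limits([2.0, 3.0], cfg)
        assert L == pytest.approx(2.0 + math.log(0.9))
        assert U == pytest.approx(3.0 + math.log(1.1))

    def test_canonical_fallback_covers_recruit_mass(self, canonical):
        # The fallback limits must retain >= 99.99% of every f_d distribution.
        L, U = default_size_limits(canonical)
        for p in canonical.values():
            sd = math.sqrt(p.recruit_size.variance)
            mass = norm.cdf(U, p.recruit_size.mean, sd) - norm.cdf(L, p.recruit_size.mean, sd)
            assert mass >= 0.9999


class TestSeedBankEntries:
    def test_bank_retention_product_of_published_constants(self, canonical, resolved_config):
        for p in canonical.values():
            A = build_kernel(p, resolved_config).matrix
            assert A[0, 0] == pytest.approx(0.857806, abs=5e-7)
            assert A[0, 0] == p.s_sb * (1.0 - p.e)  # exact closed form

    def test_bank_column_is_scaled_recruit_density(self, canonical, resolved_config):
        p = canonical[("native_US", "intact")]
        ipm = build_kernel(p, resolved_config)
        expected = p.e_sb * norm.pdf(
            ipm.mesh, p.recruit_size.mean, math.sqrt(p.recruit_size.variance)
        ) * ipm.h
        np.testing.assert_array_equal(ipm.matrix[1:, 0], expected)

    def test_structural_zeros_without_seeds_or_bank_emergence(self, resolved_config):
        p = _make_params(seeds_per_shoot=0.0, e_sb=0.0)
        ipm = build_kernel(p, resolved_config)
        A = ipm.matrix
        assert np.all(A[0, 1:] == 0) and np.all(A[1:, 0] == 0)
        # Remaining continuous block is pure survival-growth.
        s = expit(p.survival.linear_predictor(ipm.mesh))
        g = norm.pdf(
            ipm.mesh[:, None], p.growth.mean(ipm.mesh)[None, :], math.sqrt(p.growth.variance)
        )
        np.testing.assert_allclose(A[1:, 1:], s[None, :] * g * ipm.h, rtol=0, atol=0)

    def test_column_survival_mass_matches_pooled_logistic(self, resolved_config):
        # With fecundity and the bank switched off, each column of the
        # continuous block sums to s(x_j) x (retained growth mass ~ 1).
        p = _make_params(seeds_per_shoot=0.0, e_sb=0.0)
        ipm = build_kernel(p, resolved_config)
        j = int(np.argmin(np.abs(ipm.mesh - 2.5)))
        col_mass = ipm.matrix[1:, j + 1].sum()
        assert col_mass == pytest.approx(expit(1.13 + 1.16 * ipm.mesh[j]), abs=1e-3)
        assert expit(1.13 + 1.16 * 2.5) == pytest.approx(0.9825, abs=2e-4)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    a_g=st.floats(1.0, 5.0),
    b_g=st.floats(-0.5, 0.9),
    var_g=st.floats(0.05, 1.0),
    a_p=st.floats(-10.0, 10.0),
    b_p=st.floats(-4.0, 4.0),
    seeds=st.floats(0.0, 120.0),
)
def test_kernel_entries_nonnegative_and_finite(a_g, b_g, var_g, a_p, b_p, seeds):
    p = _make_params(
        growth=GaussianRate(a_g, b_g, var_g),
        flowering=LogisticRate(a_p, b_p),
        seeds_per_shoot=seeds,
    )
    ipm = build_kernel(p, IPMConfig(L=0.0, U=7.0))
    assert np.all(ipm.matrix >= 0)
    assert np.all(np.isfinite(ipm.matrix))
    assert ipm.matrix.shape == (50, 50)


class TestQuadratureOracle:
    def _kernel_fn(self, p, xj):
        s = expit(p.survival.linear_predictor(xj))
        fec = (
            expit(p.flowering.linear_predictor(xj))
            * max(0.0, p.shoots.mean(xj))
            * p.seeds_per_shoot
        )

        def K(y):
            return s * norm.pdf(y, p.growth.mean(xj), math.sqrt(p.growth.variance)) + (
                fec * p.e * norm.pdf(y, p.recruit_size.mean, math.sqrt(p.recruit_size.variance))
            )

        return K

    def test_entries_match_cell_integrals_within_midpoint_bound(self, canonical, resolved_config):
        # Midpoint-rule theory: |h K(y_i) - int_cell K| <= h^3/24 max|K''|.
        rng = np.random.default_rng(12)
        for p in canonical.values():
            ipm = build_kernel(p, resolved_config)
            x, h = ipm.mesh, ipm.h
            for i, j in rng.integers(0, len(x), size=(10, 2)):
                K = self._kernel_fn(p, x[j])
                true, _ = quad(K, x[i] - h / 2, x[i] + h / 2, epsabs=1e-14)
                ys = np.linspace(x[i] - h / 2, x[i] + h / 2, 41)
                k2 = np.gradient(np.gradient([K(y) for y in ys], ys), ys)
                bound = h**3 / 24 * np.max(np.abs(k2)) + 1e-12
                assert abs(ipm.matrix[i + 1, j + 1] - true) <= bound

    def test_lambda_matches_exactly_integrated_kernel(self, canonical, resolved_config):
        # Replacing midpoint densities by exact Gaussian cell masses (CDF
        # differences) moves lambda by < 0.1% for every canonical cell.
        for p in canonical.values():
            ipm = build_kernel(p, resolved_config)
            x, h = ipm.mesh, ipm.h
            lo, hi = x - h / 2, x + h / 2
            sd_g = math.sqrt(p.growth.variance)
            sd_fd = math.sqrt(p.recruit_size.variance)
            G = norm.cdf(hi[:, None], p.growth.mean(x)[None, :], sd_g) - norm.cdf(
                lo[:, None], p.growth.mean(x)[None, :], sd_g
            )
            fd = norm.cdf(hi, p.recruit_size.mean, sd_fd) - norm.cdf(
                lo, p.recruit_size.mean, sd_fd
            )
            s = expit(p.survival.linear_predictor(x))
            fec = (
                expit(p.flowering.linear_predictor(x))
                * np.maximum(0.0, p.shoots.mean(x))
                * p.seeds_per_shoot
            )
            m = resolved_config.matrix_dim
            B = np.zeros((m, m))
            B[0, 0] = p.s_sb * (1 - p.e)
            B[0, 1:] = fec * (1 - p.e)
            B[1:, 0] = p.e_sb * fd
            B[1:, 1:] = s[None, :] * G + fec[None, :] * p.e * fd[:, None]
            assert compute_lambda(B) == pytest.approx(compute_lambda(ipm.matrix), rel=1e-3)


class TestEviction:
    def test_delta_like_growth_retains_all_mass(self, resolved_config):
        # Growth SD far below the domain span but still resolvable by the
        # mesh (the midpoint rule cannot see mass narrower than a cell).
        p = _make_params(growth=GaussianRate(3.0, 0.0, 0.01))
        ipm = build_kernel(p, resolved_config)
        rep = check_eviction(ipm, p, resolved_config)
        interior = rep[(rep["x"] > 1.0) & (rep["x"] < 5.0)]
        assert (interior["retained_growth_mass"] > 0.999).all()

    def test_growth_mean_at_upper_limit_loses_half_and_is_flagged(self, resolved_config):
        p = _make_params(growth=GaussianRate(resolved_config.U, 0.0, 0.2))
        ipm = build_kernel(p, resolved_config)
        rep = check_eviction(ipm, p, resolved_config)
        # Half of each Gaussian falls above U; the normal CDF is the oracle.
        assert rep["retained_growth_mass"].iloc[0] == pytest.approx(0.5, abs=0.02)
        assert rep["flagged"].all()

    def test_canonical_kernels_are_eviction_free(self, canonical, resolved_config):
        for p in canonical.values():
            ipm = build_kernel(p, resolved_config)
            rep = check_eviction(ipm, p, resolved_config)
            assert not rep["flagged"].any()


def test_lambda_converges_under_mesh_refinement(canonical, resolved_config):
    for p in canonical.values():
        lams = [
            compute_lambda(
                build_kernel(p, dataclasses.replace(resolved_config, matrix_dim=m)).matrix
            )
            for m in (50, 100, 200)
        ]
        assert abs(lams[1] - lams[0]) / lams[0] < 0.005
        assert abs(lams[2] - lams[1]) / lams[1] < 0.005


def test_matrix_csv_round_trip(tmp_path, canonical, resolved_config):
    ipm = build_kernel(canonical[("invasive_FI", "intact")], resolved_config)
    path = tmp_path / "kernel.csv"
    ipm.to_csv(path)
    back = DiscretizedIPM.from_csv(path)
    np.testing.assert_allclose(back.matrix, ipm.matrix, rtol=1e-12)
    assert back.L == ipm.L and back.U == ipm.U and back.matrix_dim == ipm.matrix_dim


@pytest.mark.parametrize(
    "kwargs,msg",
    [
        ({"matrix_dim": 2}, "matrix_dim"),
        ({"L": 3.0, "U": 2.0}, "L < U"),
        ({"limits_scale": "inches"}, "limits_scale"),
    ],
)
def test_invalid_config_rejected(kwargs, msg):
    with pytest.raises(ValueError, match=msg):
        IPMConfig(**kwargs).validate()
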