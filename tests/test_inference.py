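import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helixq.errors import (
    BoundarySolutionError,
    DegenerateManifoldError,
    DegenerateMeasurementError,
    InconsistentDataError,
    InvalidInputError,
    SignInconsistencyError,
)
from helixq.inference import (
    BRManifold,
    MeasuredCharge,
    CorrectionFactors,
    build_manifold,
    estimate_geometry,
    load_measurements,
    ratio_observables,
    solve_fM,
)

# the three B-form charges printed for the LiCl experiment
BDNA_LICL = {30: (-25.28, 0.07), 40: (-30.46, 0.06), 60: (-40.71, 0.07)}


def _measurements(values=BDNA_LICL, species="B-DNA", salt="LiCl"):
    return [
        MeasuredCharge(species=species, n_bp=n, q_m=q, sigma=s, salt=salt)
        for n, (q, s) in values.items()
    ]


class TestRatioObservables:
    def test_printed_bdna_values(self):
        # oracle: direct arithmetic on the dye-corrected charges
        # (-25.28 - 0.5, -30.46 - 0.5, -40.71 - 0.5)
        ratios = ratio_observables(_measurements(), f_A=0.5)
        assert ratios[0].n_i == 30 and ratios[0].n_j == 60
        assert ratios[0].value == pytest.approx(-25.78 / -41.21, rel=1e-12)
        assert ratios[1].value == pytest.approx(-30.96 / -41.21, rel=1e-12)

    def test_longest_fragment_is_common_denominator(self):
        ratios = ratio_observables(_measurements())
        assert {r.n_j for r in ratios} == {60}

    @settings(max_examples=25, deadline=None)
    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_scale_invariance_without_dye_offset(self, s):
        base = ratio_observables(_measurements(), f_A=0.0)
        scaled = ratio_observables(
            [dataclasses.replace(m, q_m=s * m.q_m) for m in _measurements()], f_A=0.0
        )
        for r0, r1 in zip(base, scaled):
            assert r1.value == pytest.approx(r0.value, rel=1e-12)

    def test_sigma_against_monte_carlo_oracle(self, rng):
        ms = _measurements()
        ratios = ratio_observables(ms, f_A=0.5)
        n_mc = 1_000_000
        draws = {
            m.n_bp: m.q_m + m.sigma * rng.standard_normal(n_mc) for m in ms
        }
        for ratio in ratios:
            mc = (draws[ratio.n_i] - 0.5) / (draws[ratio.n_j] - 0.5)
            assert ratio.sigma == pytest.approx(mc.std(), rel=0.02)

    def test_duplicate_length_rejected(self):
        ms = _measurements()
        ms[1] = dataclasses.replace(ms[1], n_bp=30)
        with pytest.raises(InvalidInputError):
            ratio_observables(ms)

    def test_mixed_species_rejected(self):
        ms = _measurements()
        ms[0] = dataclasses.replace(ms[0], species="A-RNA")
        with pytest.raises(InvalidInputError):
            ratio_observables(ms)

    def test_degenerate_measurement(self):
        ms = _measurements()
        ms[0] = dataclasses.replace(ms[0], q_m=-0.3)
        with pytest.raises(DegenerateMeasurementError):
            ratio_observables(ms, f_A=0.5)


def _synthetic_ratios(surfaces, b, r, rel_sigma=1e-5, f_m=1.0):
    """Forward-model ratios at known truth; f_m cancels identically."""
    q = {n: f_m * float(surfaces[n].q_eff_at(b, r)) for n in (30, 40, 60)}
    ms = [
        MeasuredCharge("syn", n, q[n], rel_sigma * abs(q[n]), "syn")
        for n in (30, 40, 60)
    ]
    return ratio_observables(ms, f_A=0.0), ms


class TestBuildManifold:
    def test_noiseless_truth_at_node(self, analytic_surfaces):
        b_star = analytic_surfaces[30].b_grid[12]
        r_star = analytic_surfaces[30].r_grid[20]
        ratios, _ = _synthetic_ratios(analytic_surfaces, b_star, r_star)
        man = build_manifold(ratios, analytic_surfaces)
        i, j = np.unravel_index(np.argmax(man.weights), man.weights.shape)
        assert man.b_grid[i] == b_star
        assert man.r_grid[j] == r_star

    def test_weights_normalized(self, analytic_surfaces):
        ratios, _ = _synthetic_ratios(analytic_surfaces, 3.3, 11.0, rel_sigma=0.003)
        man = build_manifold(ratios, analytic_surfaces)
        assert man.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(man.weights >= 0)

    def test_doubling_sigma_increases_entropy(self, analytic_surfaces):
        ratios, _ = _synthetic_ratios(analytic_surfaces, 3.3, 11.0, rel_sigma=0.003)
        wide = [dataclasses.replace(r, sigma=2 * r.sigma) for r in ratios]
        man_narrow = build_manifold(ratios, analytic_surfaces)
        man_wide = build_manifold(wide, analytic_surfaces)
        assert man_wide.entropy() > man_narrow.entropy()

    def test_fM_elimination_invariance(self, analytic_surfaces):
        # the module's defining property: datasets differing only in the
        # multiplicative factor give identical manifolds
        r_lo, _ = _synthetic_ratios(analytic_surfaces, 3.3, 11.0, 0.003, f_m=0.9)
        r_hi, _ = _synthetic_ratios(analytic_surfaces, 3.3, 11.0, 0.003, f_m=1.1)
        man_lo = build_manifold(r_lo, analytic_surfaces)
        man_hi = build_manifold(r_hi, analytic_surfaces)
        np.testing.assert_allclose(man_lo.weights, man_hi.weights, atol=1e-12)

    def test_inconsistent_data_error(self, analytic_surfaces):
        ratios, _ = _synthetic_ratios(analytic_surfaces, 3.3, 11.0, rel_sigma=1e-7)
        bad = [dataclasses.replace(ratios[0], value=5.0)] + ratios[1:]
        with pytest.raises(InconsistentDataError):
            build_manifold(bad, analytic_surfaces)

    def test_missing_surface(self, analytic_surfaces):
        ratios, _ = _synthetic_ratios(analytic_surfaces, 3.3, 11.0)
        partial = {30: analytic_surfaces[30], 60: analytic_surfaces[60]}
        with pytest.raises(InvalidInputError):
            build_manifold(ratios, partial)


def _gaussian_bump_manifold(b_grid, r_grid, b0, r0, sb, sr):
    bb, rr = np.meshgrid(b_grid, r_grid, indexing="ij")
    chi2 = ((bb - b0) / sb) ** 2 + ((rr - r0) / sr) ** 2
    w = np.exp(-0.5 * chi2)
    return BRManifold(b_grid=b_grid, r_grid=r_grid, weights=w / w.sum(), chi2=chi2)


class TestEstimateGeometry:
    def test_symmetric_bump_recovery(self):
        b_grid = np.linspace(2, 5, 31)
        r_grid = np.linspace(6, 30, 49)
        man = _gaussian_bump_manifold(b_grid, r_grid, b_grid[15], r_grid[24], 0.2, 1.5)
        est = estimate_geometry(man)
        assert est.b_m == pytest.approx(b_grid[15], abs=1e-9)
        assert est.r_m == pytest.approx(r_grid[24], abs=1e-9)
        assert est.sigma_b == pytest.approx(0.2, rel=0.05)
        assert est.sigma_r == pytest.approx(1.5, rel=0.05)

    def test_ratio_order_invariance(self, analytic_surfaces):
        ratios, _ = _synthetic_ratios(analytic_surfaces, 3.3, 11.0, rel_sigma=0.003)
        a = estimate_geometry(build_manifold(ratios, analytic_surfaces))
        b = estimate_geometry(build_manifold(ratios[::-1], analytic_surfaces))
        assert a == b

    def test_off_node_truth_recovered(self, analytic_surfaces):
        # noiseless forward model at off-node truth: recovery well within
        # one (coarse) grid spacing
        ratios, _ = _synthetic_ratios(analytic_surfaces, 3.25, 11.0, rel_sigma=1e-4)
        fine_b = np.linspace(2, 5, 61)
        fine_r = np.linspace(6, 30, 97)
        man = build_manifold(ratios, analytic_surfaces, b_grid=fine_b, r_grid=fine_r)
        est = estimate_geometry(man)
        assert est.b_m == pytest.approx(3.25, abs=0.1)
        assert est.r_m == pytest.approx(11.0, abs=0.5)

    def test_boundary_mode_error(self):
        b_grid = np.linspace(2, 5, 31)
        r_grid = np.linspace(6, 30, 49)
        man = _gaussian_bump_manifold(b_grid, r_grid, 2.0, 12.0, 0.2, 1.5)
        with pytest.raises(BoundarySolutionError):
            estimate_geometry(man)

    def test_single_ratio_ridge_detected(self, analytic_surfaces):
        ratios, _ = _synthetic_ratios(analytic_surfaces, 3.3, 11.0, rel_sigma=0.003)
        man = build_manifold(ratios[:1], analytic_surfaces)
        with pytest.raises(DegenerateManifoldError):
            estimate_geometry(man)


class TestSolveFM:
    def test_recovery_within_half_percent(self, analytic_surfaces, rng):
        truth_fm = 1.05
        ratios, ms = _synthetic_ratios(
            analytic_surfaces, 3.3, 11.0, rel_sigma=0.003, f_m=truth_fm
        )
        man = build_manifold(ratios, analytic_surfaces)
        est = estimate_geometry(man)
        f_m, _, _ = solve_fM(ms, analytic_surfaces, est, f_A=0.0)
        assert f_m == pytest.approx(truth_fm, rel=0.005)

    def test_unity_round_trip(self, analytic_surfaces):
        from helixq.inference import GeometryEstimate

        b_star = analytic_surfaces[30].b_grid[12]
        r_star = analytic_surfaces[30].r_grid[20]
        _, ms = _synthetic_ratios(analytic_surfaces, b_star, r_star, f_m=1.0)
        est = GeometryEstimate(b_m=b_star, r_m=r_star, sigma_b=0.1, sigma_r=1.0)
        f_m, _, _ = solve_fM(ms, analytic_surfaces, est, f_A=0.0)
        assert f_m == pytest.approx(1.0, abs=1e-6)

    def test_corrupted_fragment_flagged(self, analytic_surfaces):
        ratios, ms = _synthetic_ratios(analytic_surfaces, 3.3, 11.0, rel_sigma=0.003)
        man = build_manifold(ratios, analytic_surfaces)
        est = estimate_geometry(man)
        bad = [dataclasses.replace(ms[0], q_m=ms[0].q_m * 1.10)] + ms[1:]
        _, _, spread = solve_fM(bad, analytic_surfaces, est, f_A=0.0)
        assert spread > 3.0

    def test_sign_inconsistency(self, analytic_surfaces):
        ratios, ms = _synthetic_ratios(analytic_surfaces, 3.3, 11.0, rel_sigma=0.003)
        est = estimate_geometry(build_manifold(ratios, analytic_surfaces))
        flipped = [dataclasses.replace(m, q_m=-m.q_m) for m in ms]
        with pytest.raises(SignInconsistencyError):
            solve_fM(flipped, analytic_surfaces, est, f_A=0.0)


class TestCoverage:
    def test_credible_interval_coverage(self, analytic_surfaces):
        # 68% intervals from the local curvature should cover the truth
        # at roughly the nominal rate over repeated noisy experiments
        rng = np.random.default_rng(2024)
        b_true, r_true = 3.35, 11.5
        q_true = {n: float(analytic_surfaces[n].q_eff_at(b_true, r_true)) for n in (30, 40, 60)}
        hits_b = hits_r = 0
        n_rep = 200
        fine_b = np.linspace(2, 5, 121)
        fine_r = np.linspace(6, 30, 193)
        for _ in range(n_rep):
            ms = [
                MeasuredCharge(
                    "syn", n,
                    q_true[n] * (1.0 + 0.003 * rng.standard_normal()),
                    0.003 * abs(q_true[n]), "syn",
                )
                for n in (30, 40, 60)
            ]
            ratios, cov = ratio_observables(ms, f_A=0.0, with_covariance=True)
            man = build_manifold(
                ratios, analytic_surfaces, b_grid=fine_b, r_grid=fine_r,
                ratio_covariance=cov,
            )
            est = estimate_geometry(man)
            hits_b += abs(est.b_m - b_true) < est.sigma_b
            hits_r += abs(est.r_m - r_true) < est.sigma_r
        assert 0.60 <= hits_b / n_rep <= 0.76
        assert 0.60 <= hits_r / n_rep <= 0.76

    def test_ratio_covariance_against_monte_carlo(self, rng):
        # oracle for the shared-denominator covariance term
        ms = _measurements()
        _, cov = ratio_observables(ms, f_A=0.5, with_covariance=True)
        n_mc = 500_000
        draws = {m.n_bp: m.q_m + m.sigma * rng.standard_normal(n_mc) for m in ms}
        r1 = (draws[30] - 0.5) / (draws[60] - 0.5)
        r2 = (draws[40] - 0.5) / (draws[60] - 0.5)
        mc_cov = np.cov(r1, r2)
        assert cov[0, 1] == pytest.approx(mc_cov[0, 1], rel=0.05)
        assert cov[0, 0] == pytest.approx(mc_cov[0, 0], rel=0.05)

    def test_corrections_type(self):
        cf = CorrectionFactors(f_A=0.5, f_phi=1.1, f_ion=0.9)
        assert cf.f_M == pytest.approx(0.99)
        with pytest.raises(InvalidInputError):
            CorrectionFactors(f_A=0.5, f_phi=-1.0)


def test_load_measurements(tmp_path):
    path = tmp_path / "meas.csv"
    path.write_text(
        "species,salt,n_bp,q_m_e,sigma_e\n"
        "B-DNA,LiCl,30,-25.28,0.07\n"
        "B-DNA,LiCl,60,-40.71,0.07\n"
    )
    ms = load_measurements(path)
    assert len(ms) == 2
    assert ms[0].q_m == -25.28

    bad = tmp_path / "bad.csv"
    bad.write_text("species,n_bp\nB,30\n")
    with pytest.raises(InvalidInputError):
        load_measurements(bad)
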