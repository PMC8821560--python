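import numpy as np
import pytest

from selfbuckle import (
    allowable_weight_ratio,
    build_section,
    critical_height,
    greenhill_height,
    height_ratio,
    make_density_model,
    ratio_extremes,
    safety_factor_range,
    simplified_height,
    tree_application,
    tree_height_ratio,
)


class TestCriticalHeight:
    def test_uniform_hardwood_column(self, wood_section):
        """The reference hardwood cylinder buckles at 60.455 m."""
        res = critical_height(wood_section, make_density_model("C", 0.0))
        assert res.l_c == pytest.approx(60.455, abs=1e-3)
        assert res.xi_c == pytest.approx(wood_section.omega * res.l_c, rel=1e-12)

    def test_radius_two_thirds_power_scaling(self, wood_section):
        """Greenhill's law: l_c scales as r^(2/3)."""
        big = build_section(E=1.1e10, rho0=526.0, g=9.81, r=4 * 0.23)
        model = make_density_model("A", 2.0)
        l_small = critical_height(wood_section, model).l_c
        l_big = critical_height(big, model).l_c
        assert l_big == pytest.approx(l_small * 4 ** (2.0 / 3.0), rel=1e-9)

    def test_ratio_field_consistent_with_height_ratio(self, wood_section):
        res = critical_height(wood_section, make_density_model("B", 1.7))
        assert res.f_ratio == pytest.approx(height_ratio("B", 1.7), abs=1e-12)

    def test_ratio_is_section_independent(self):
        other = build_section(E=2.0e9, rho0=800.0, g=9.81, r=1.4)
        f_other = critical_height(other, make_density_model("D", 0.6)).f_ratio
        assert f_other == pytest.approx(height_ratio("D", 0.6), abs=1e-12)


class TestRatioCurves:
    @pytest.mark.parametrize(
        "mid, n, expected",
        [
            ("A", 1.0, 1.0),
            ("A", 3.0, 0.88),
            ("B", 0.0, 1.60),
            ("C", 1.0, 1.2713),  # closed form: first zero of J_{-1/4}
            ("D", 1.0, 1.38),
        ],
    )
    def test_ratio_values(self, mid, n, expected):
        assert height_ratio(mid, n) == pytest.approx(expected, abs=5e-3)

    def test_monotonic_in_n(self):
        """Top-heavier columns buckle lower: f decreases with n for A/B,
        increases for C/D (larger n shifts weight toward the ground)."""
        for mid, sign in [("A", -1), ("B", -1), ("C", +1), ("D", +1)]:
            lo, hi = (0, 3) if mid in "AB" else (-1, 1)
            f = [height_ratio(mid, n) for n in np.linspace(lo, hi, 31)]
            assert np.all(sign * np.diff(f) > 0), mid

    def test_branches_always_reduce_height(self):
        """f(n, W_R) strictly decreases with the branch weight ratio."""
        for mid in "EF":
            for n in (0.0, 0.5, 1.0):
                f = [tree_height_ratio(mid, n, wr) for wr in np.linspace(0.0, 1.0, 11)]
                assert f[0] == pytest.approx(1.0, abs=1e-4)
                assert np.all(np.diff(f) < 0), (mid, n)

    def test_branchless_tree_is_reference(self):
        assert tree_height_ratio("E", 0.42, 0.0) == pytest.approx(1.0, abs=1e-4)

    def test_tree_ratio_rejects_plain_models(self):
        with pytest.raises(ValueError):
            tree_height_ratio("C", 0.5, 0.3)


class TestExtremesAndSafety:
    def test_model_e_realistic_region(self):
        f_min, f_max = ratio_extremes("E", (0.0, 1.0), (0.1, 0.6))
        assert f_max == pytest.approx(0.985, abs=2e-3)
        assert f_min == pytest.approx(0.855, abs=2e-3)

    def test_single_point_grid(self):
        f_min, f_max = ratio_extremes("A", (2.0, 2.0), grid_steps=(1, 1))
        assert f_min == f_max == pytest.approx(height_ratio("A", 2.0))

    def test_safety_factor_rounding(self):
        assert safety_factor_range(0.855, 0.985) == (3.4, 3.9)
        assert safety_factor_range(1.0, 1.0) == (4.0, 4.0)
        assert safety_factor_range(0.855, 0.985, S0=1.0) == (0.9, 1.0)

    def test_safety_factor_invalid_ordering(self):
        with pytest.raises(ValueError):
            safety_factor_range(0.9, 0.8)

    def test_tree_application_bundles_extremes(self):
        app = tree_application("E", grid_steps=(5, 5))
        assert app.S_low <= app.S_high
        assert 0 < app.f_min <= app.f_max


class TestSimplifiedFormulas:
    def test_fraction_formula_anchor_points(self, wood_section):
        G = greenhill_height(wood_section)
        assert G == pytest.approx(60.455, abs=1e-2)
        assert simplified_height("C", 0.0, wood_section) == pytest.approx(G)
        assert simplified_height("B", 1.0, wood_section) == pytest.approx(G)
        assert simplified_height("A", 0.0, wood_section) == pytest.approx(1.1 * G)

    def test_model_b_excludes_zero(self, wood_section):
        with pytest.raises(ValueError):
            simplified_height("B", 0.0, wood_section)

    # Engineering-approximation quality over each applicable range: the
    # fraction-coefficient forms track the solver to a few percent, with
    # the largest deviation at a range end (B's power law at n = 3, the
    # exponential's missing curvature at n = -1 for C/D).
    @pytest.mark.parametrize(
        "mid, rel_bound", [("A", 0.03), ("B", 0.10), ("C", 0.06), ("D", 0.09)]
    )
    def test_tracks_full_solver_over_range(self, mid, rel_bound, wood_section):
        lo, hi = (0.0, 3.0) if mid in "AB" else (-1.0, 1.0)
        ns = np.linspace(lo, hi, 13)
        if mid == "B":
            ns = ns[ns > 0]  # power law undefined at n=0
        for n in ns:
            exact = critical_height(wood_section, make_density_model(mid, n)).l_c
            approx = simplified_height(mid, n, wood_section)
            assert abs(approx - exact) / exact < rel_bound, (mid, n)


class TestAllowableWeight:
    def test_cubic_interpretation(self):
        """l_c ~ gamma^(-1/3), so f in height means f^3 in carriable weight."""
        assert allowable_weight_ratio(1.25) == pytest.approx(1.95, abs=0.01)
        assert allowable_weight_ratio(1.38) == pytest.approx(2.63, abs=0.01)
        assert allowable_weight_ratio(1.0) == 1.0

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            allowable_weight_ratio(0.0)
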