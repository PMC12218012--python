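import numpy as np
import pandas as pd
import pytest

from ldne import (SolverConfig, composite_delta2_observed,
                  expected_delta2_between, expected_delta2_between_within,
                  expected_delta2_total, expected_delta2_within, metapop_ne,
                  solve_metapop, takahata_fst)
from ldne.ld import LDSummary


class TestExpectedWithin:
    def test_full_differentiation_vanishes(self):
        for c in (0.01, 0.1, 0.5):
            assert expected_delta2_within(c, 1000, 1.0) == 0.0

    def test_direct_substitution_c_half(self):
        # ((1-c)^2 + c^2) = 0.5 at c = 0.5; denominator 2*1000*0.75 + 0.55
        assert expected_delta2_within(0.5, 1000, 0.0) == \
            pytest.approx(0.5 / 1500.55, rel=1e-12)

    def test_c_zero_rejected(self):
        with pytest.raises(ValueError):
            expected_delta2_within(0.0, 1000, 0.0)

    def test_decreasing_in_n(self):
        vals = [expected_delta2_within(0.1, n, 0.0) for n in (100, 1000, 10000)]
        assert vals[0] > vals[1] > vals[2]


class TestExpectedBetween:
    def test_no_differentiation(self):
        assert expected_delta2_between(0.0, 3) == 0.0

    def test_arithmetic(self):
        assert expected_delta2_between(0.1, 2) == pytest.approx(0.01)

    def test_requires_two_demes(self):
        with pytest.raises(ValueError):
            expected_delta2_between(0.1, 1)


class TestExpectedBetweenWithin:
    def test_zero_migration(self):
        assert expected_delta2_between_within(0.5, 0.1, 2, 0.0) == 0.0

    def test_zero_fst(self):
        assert expected_delta2_between_within(0.5, 0.0, 2, 0.01) == 0.0

    def test_hand_evaluated_case(self):
        # s=2: (s/(s-1))^2 = 4, delta2_b = F^2
        f, m = 0.059, 0.001
        expect = 4 * f * f * m / (1 - (1 - 2 * m) ** 2 * 0.5)
        assert expected_delta2_between_within(0.5, f, 2, m) == \
            pytest.approx(expect, rel=1e-12)

    def test_migration_out_of_range(self):
        with pytest.raises(ValueError):
            expected_delta2_between_within(0.5, 0.1, 2, 0.7)


class TestTakahataFst:
    def test_isolation_limit(self):
        assert takahata_fst(1000, 0.0, 2) == 1.0

    def test_panmixia_limit(self):
        assert takahata_fst(10**7, 0.4, 5) < 1e-5

    def test_reference_value(self):
        assert takahata_fst(1000, 0.001, 2) == pytest.approx(1 / 17, rel=1e-9)

    def test_monotone_in_n_and_m(self):
        assert takahata_fst(100, 0.01, 3) > takahata_fst(1000, 0.01, 3)
        assert takahata_fst(100, 0.001, 3) > takahata_fst(100, 0.01, 3)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            takahata_fst(1000, 0.9, 2)
        with pytest.raises(ValueError):
            takahata_fst(1000, 0.01, 1)


class TestMetapopNe:
    def test_panmictic_equality(self):
        assert metapop_ne(1000, 0.0) == 1000

    def test_half_fst_doubles(self):
        assert metapop_ne(1000, 0.5) == pytest.approx(2000)

    def test_fst_one_rejected(self):
        with pytest.raises(ValueError):
            metapop_ne(1000, 1.0)


class TestExpectedTotal:
    def test_panmixia_reduction(self):
        for c in (0.05, 0.2, 0.5):
            assert expected_delta2_total(c, 800, 1, 0.0) == \
                pytest.approx(expected_delta2_within(c, 800, 0.0), rel=1e-12)

    def test_strong_structure_dominated_by_between(self):
        # N m << 1: between-deme term dominates at c = 0.5
        n, s, m = 1000, 2, 1e-6
        f = takahata_fst(n, m, s)
        total = expected_delta2_total(0.5, n, s, m)
        assert total == pytest.approx(expected_delta2_between(f, s), rel=0.01)


class TestSolver:
    @staticmethod
    def synthetic_obs(N, s, m, n=100):
        centers = np.linspace(0.055, 0.495, 40)
        w = np.ones_like(centers)
        du = composite_delta2_observed(0.5, N, s, m)
        dw = float(np.mean(composite_delta2_observed(centers, N, s, m)))
        F = takahata_fst(N, m, s) if s > 1 else 0.0
        return LDSummary(du, dw, pd.DataFrame(), F, n, 10000, 2, centers, w)

    @pytest.mark.parametrize("s", [2, 3, 4, 5, 6])
    @pytest.mark.parametrize("N", [100, 1000])
    @pytest.mark.parametrize("m", [0.001, 0.01, 0.1])
    def test_noiseless_round_trip(self, s, N, m):
        """Observables generated from the forward model are inverted back
        to the generating (N, s, m)."""
        obs = self.synthetic_obs(N, s, m)
        est = solve_metapop(obs, SolverConfig(s_max=8, seed=1))
        assert est.s == s
        assert est.N == pytest.approx(N, rel=0.05)
        assert est.m == pytest.approx(m, rel=0.05)
        assert est.N_T == pytest.approx(s * N, rel=0.05)
        assert est.N_e >= est.N_T * (1 - 1e-9)

    def test_panmictic_observables_reported_as_s1(self):
        obs = self.synthetic_obs(1500, 1, 0.0)
        est = solve_metapop(obs, SolverConfig(s_max=6, seed=1))
        assert est.s == 1
        assert est.F_ST == 0.0
        assert est.N_e == pytest.approx(est.N_T)
        assert est.N_T == pytest.approx(1500, rel=0.05)

    def test_negative_delta2_floored_with_warning(self):
        obs = self.synthetic_obs(1000, 2, 0.001)
        obs.delta2_unlinked = -1e-5
        with pytest.warns(UserWarning, match="noise floor"):
            est = solve_metapop(obs, SolverConfig(s_max=4, seed=1))
        assert np.isfinite(est.residual)

    def test_estimates_stay_in_range_at_high_nm(self):
        # N m >> 1: F_ST ~ 0, migration poorly identified, but outputs
        # must remain valid and the fit finite
        obs = self.synthetic_obs(1000, 4, 0.1)
        est = solve_metapop(obs, SolverConfig(s_max=8, seed=1))
        assert 0 <= est.F_ST < 1
        assert np.isfinite(est.residual)
        assert est.N_e >= est.N_T * (1 - 1e-9)

    def test_island_simulation_recovery(self, island_summary, island_sim):
        """Two-deme simulated metapopulation: structured N_T is near truth
        while the panmictic estimate collapses far below it."""
        _, truth = island_sim
        est = solve_metapop(island_summary, SolverConfig(seed=2))
        assert est.s >= 2
        assert est.N_T == pytest.approx(truth.N_T, rel=0.6)
        assert est.Ne_panmixia < 0.5 * truth.N_T
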