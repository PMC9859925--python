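import math

import numpy as np
import pytest
from scipy.optimize import brentq

import pfasrpf as p
from pfasrpf.errors import DirectionError, DomainError, PfasRpfError, UnreachableEffectError


def bisection_bmc(a, b, c, d, ces, lo=1e-12, hi=1e12):
    """Independent oracle: root of expo_response(x) = a*(1+ces) by brentq."""
    target = a * (1.0 + ces)
    return brentq(lambda x: p.expo_response(x, a, b, c, d) - target, lo, hi,
                  xtol=1e-15, rtol=1e-14)


class TestClosedForm:
    def test_reference_value(self):
        oracle = bisection_bmc(1.0, 10.0, 0.2, 1.0, -0.1)
        assert oracle == pytest.approx(0.6770531, abs=1e-6)
        assert p.bmc_closed_form(1.0, 10.0, 0.2, 1.0, -0.1) == pytest.approx(oracle, rel=1e-10)

    def test_against_bisection_on_random_draws(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            a = rng.uniform(0.5, 2.0)
            b = 10.0 ** rng.uniform(-1, 2)
            c = rng.uniform(0.05, 0.8)
            d = rng.uniform(0.3, 4.0)
            # valid decreasing effect sizes strictly inside the plateau
            ces = -rng.uniform(0.01, 1.0 - c - 1e-3) if c < 0.99 else -0.005
            bmc = p.bmc_closed_form(a, b, c, d, ces)
            assert bmc == pytest.approx(bisection_bmc(a, b, c, d, ces), rel=1e-8)
            # defining property
            assert p.expo_response(bmc, a, b, c, d) == pytest.approx(a * (1 + ces), rel=1e-10)

    def test_b_is_pure_scale(self):
        one = p.bmc_closed_form(1.0, 10.0, 0.2, 1.7, -0.1)
        two = p.bmc_closed_form(1.0, 20.0, 0.2, 1.7, -0.1)
        assert two == pytest.approx(2.0 * one, rel=1e-12)

    def test_effect_beyond_plateau_rejected(self):
        with pytest.raises(UnreachableEffectError):
            p.bmc_closed_form(1.0, 10.0, 0.2, 1.0, ces=0.2 - 1.0)

    def test_sign_mismatch_rejected(self):
        with pytest.raises(DirectionError):
            p.bmc_closed_form(1.0, 10.0, 0.2, 1.0, ces=+0.1)
        with pytest.raises(DirectionError):
            p.bmc_closed_form(1.0, 10.0, 3.0, 1.0, ces=-0.1)

    def test_zero_ces_rejected(self):
        with pytest.raises(DomainError):
            p.bmc_closed_form(1.0, 10.0, 0.2, 1.0, 0.0)


class TestRpfIdentities:
    def test_ced_ratio_equals_b_ratio_for_any_ces(self, parallel_fit):
        b = parallel_fit.params.b
        c, d = parallel_fit.params.c, parallel_fit.params.d
        for ces in (-0.05, -0.1, -0.2):
            for compound in b:
                ratio = (p.bmc_closed_form(1.0, b["PFOA"], c, d, ces)
                         / p.bmc_closed_form(1.0, b[compound], c, d, ces))
                assert ratio == pytest.approx(b["PFOA"] / b[compound], rel=1e-10)

    def test_rpf_point_estimates(self, sim_table, parallel_fit):
        rpfs = {r.compound: r for r in p.rpf_from_fit(sim_table, parallel_fit, "PFOA")}
        assert rpfs["PFOA"].rpf == 1.0
        assert rpfs["PFOA"].ci_low == 1.0 and rpfs["PFOA"].ci_high == 1.0
        b = parallel_fit.params.b
        for compound, est in rpfs.items():
            assert est.rpf == pytest.approx(b["PFOA"] / b[compound], rel=1e-10)
            assert est.ci_low <= est.rpf <= est.ci_high

    def test_non_parallel_fit_rejected(self, sim_table):
        shared = p.fit_model(sim_table, p.default_candidates()[1], seed=0)
        with pytest.raises(PfasRpfError):
            p.rpf_from_fit(sim_table, shared, "PFOA")

    def test_synthetic_truth_ratio_recovered(self):
        """True potencies 10 and 20 µM -> RPF near 0.5 at 10% noise."""
        design = p.SimDesign(
            compounds={"IDX": 10.0, "CMP": 20.0, "OTH": 15.0},
            concentrations={k: p.default_grid(100.0) for k in ("IDX", "CMP", "OTH")},
            cv=0.10, seed=5,
        )
        table = p.simulate_summary_table(design)
        fit = p.fit_model(table, p.default_candidates()[2], seed=5)
        rpfs = {r.compound: r.rpf for r in p.rpf_from_fit(table, fit, "IDX")}
        assert rpfs["CMP"] == pytest.approx(0.5, rel=0.15)


class TestProfileCi:
    def test_bounds_bracket_estimate_and_hit_the_drop(self, sim_table, parallel_fit):
        est = p.profile_ci_bmc(sim_table, parallel_fit, "PFOA")
        assert est.cedl <= est.ced <= est.cedu
        assert est.cedl < est.ced < est.cedu  # noise present, interval non-degenerate
        # the point estimate satisfies the closed form at the fitted parameters
        b, c, d = parallel_fit.params.b["PFOA"], parallel_fit.params.c, parallel_fit.params.d
        assert est.ced == pytest.approx(p.bmc_closed_form(1.0, b, c, d, -0.1), rel=1e-10)

    def test_profile_drop_at_bounds(self, sim_table, parallel_fit):
        """The profile log-likelihood at each returned bound sits at
        ll_max - chi2(1).ppf(0.9)/2, the defining crossing (and therefore the
        bounds are invariant to monotone reparameterization)."""
        from scipy.stats import chi2

        from pfasrpf.bmd import _ProfileProblem, _shape_factor
        from pfasrpf.fitting import _Packer

        est = p.profile_ci_bmc(sim_table, parallel_fit, "PFOS")
        packer = _Packer(parallel_fit.spec, sim_table)
        from pfasrpf.bmd import _theta_from_params
        theta_hat = _theta_from_params(packer, parallel_fit.params)
        i_b = packer.n_a + list(packer.b_levels).index("PFOS")
        free = [i for i in range(packer.size) if i != i_b]

        def inject(tr, ced):
            theta = np.empty(packer.size)
            theta[free] = tr
            c = math.exp(theta[packer.i_c])
            d = math.exp(theta[packer.i_d])
            theta[i_b] = math.log(ced) - math.log(_shape_factor(c, d, -0.1))
            return theta

        problem = _ProfileProblem(packer, inject, theta_hat[free])
        drop = chi2.ppf(0.90, 1) / 2
        for bound in (est.cedl, est.cedu):
            ll = problem.loglik_at(bound)
            assert ll == pytest.approx(parallel_fit.loglik - drop, abs=5e-3)

    def test_less_noise_narrows_interval(self):
        widths = {}
        for cv in (0.15, 0.015):
            design = p.SimDesign(seed=21, cv=cv)
            table = p.simulate_summary_table(design)
            fit = p.fit_model(table, p.default_candidates()[2], seed=21)
            est = p.profile_ci_bmc(table, fit, "PFOA")
            widths[cv] = est.cedu - est.cedl
        assert widths[0.015] < widths[0.15]
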