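"""Strategy assembly, background mortality, competing risks, calibration."""

import numpy as np
import pandas as pd
import pytest

from brafcea.cohort import run_cohort
from brafcea.economics import (
    STATE_BSC,
    STATE_DEATH,
    STATE_FIRST_LINE,
    STATE_NIVO_IPI,
    STATE_REGORAFENIB,
)
from brafcea.strategies import (
    CohortProfile,
    LifeTable,
    background_mortality,
    base_case,
    build_strategy,
    calibrate_bsc,
    combine_competing,
    evaluate_arm,
)
from brafcea.survival import HazardRatioAdjusted, WeibullLaw


@pytest.fixture()
def profile(params):
    return CohortProfile.from_params(params)


class TestBuildStrategy:
    def test_standard_first_line_is_printed_weibull(self, profile, params):
        spec = build_strategy(profile, params, "standard")
        law = spec.lines[STATE_FIRST_LINE].pfs_law
        assert isinstance(law, WeibullLaw)
        assert (law.lam, law.kappa) == (0.2415957, 1.280836)

    def test_doublet_first_line_is_hr_adjusted_weibull(self, profile, params):
        spec = build_strategy(profile, params, "doublet")
        law = spec.lines[STATE_FIRST_LINE].pfs_law
        assert isinstance(law, HazardRatioAdjusted)
        assert law.hr == 0.40
        assert (law.base.lam, law.base.kappa) == (0.2415957, 1.280836)

    def test_zero_msi_h_starves_checkpoint_branch(self, params):
        p = params.with_overrides({"pct_msi_h": 0.0})
        res = evaluate_arm(p, "standard")
        nivo_mass = res.trace.block(STATE_NIVO_IPI).sum()
        assert nivo_mass == 0.0

    def test_post_progression_structure_identical_between_arms(self, profile, params):
        """Only the first line differs; later-line rules are bitwise equal."""
        specs = {arm: build_strategy(profile, params, arm) for arm in ("doublet", "standard")}
        for state in (STATE_NIVO_IPI, STATE_REGORAFENIB, STATE_BSC):
            ra = next(r for r in specs["doublet"].rules if r.from_state == state)
            rb = next(r for r in specs["standard"].rules if r.from_state == state)
            np.testing.assert_array_equal(ra.p_move, rb.p_move)
            np.testing.assert_array_equal(ra.p_die, rb.p_die)
            assert [d for d, _ in ra.destinations] == [d for d, _ in rb.destinations]
            for (_, fa), (_, fb) in zip(ra.destinations, rb.destinations):
                np.testing.assert_array_equal(fa, fb)

    def test_bsc_only_scenario_drops_later_lines(self, profile, params):
        spec = build_strategy(profile, params, "doublet", bsc_only=True)
        assert set(spec.space.states) == {STATE_FIRST_LINE, STATE_BSC, STATE_DEATH}

    def test_unknown_arm_rejected(self, profile, params):
        with pytest.raises(ValueError):
            build_strategy(profile, params, "triplet")

    def test_missing_parameter_named_in_error(self, params):
        import copy
        from brafcea.config import ConfigError
        broken = copy.deepcopy(params.clinical)
        del broken["ae_discontinue"]["regorafenib"]
        p = type(params)(clinical=broken, costs=params.costs,
                         ae_costs=params.ae_costs, life_table=params.life_table)
        with pytest.raises(ConfigError, match="regorafenib"):
            build_strategy(CohortProfile.from_params(p), p, "standard")


class TestHrOneSymmetry:
    def test_hr_one_with_equal_toxicity_makes_arms_identical(self, params):
        """hr = 1 collapses the arms up to first-line drug costs."""
        p = params.with_overrides(
            {
                "doublet_hr": 1.0,
                "ae_discontinue_doublet": params.clin("ae_discontinue", "standard"),
                "ae_mortality_doublet": params.clin("ae_mortality", "standard"),
            }
        )
        res = base_case(p)
        np.testing.assert_allclose(
            res.doublet.trace.occupancy, res.standard.trace.occupancy, atol=1e-12
        )
        assert res.ce.inc_qaly == pytest.approx(0.0, abs=1e-12)
        ca = res.doublet.accrual.cost_by_component
        cb = res.standard.accrual.cost_by_component
        same = ("monitoring", "end_of_life", "regorafenib", "nivolumab", "ipilimumab")
        for key in same:
            assert ca[key] == pytest.approx(cb[key], abs=1e-9)
        assert "encorafenib" in ca and "chemo_backbone" in cb


class TestBackgroundMortality:
    def make_lt(self, q):
        return LifeTable(pd.DataFrame({"age": [60, 61], "male": [q, q], "female": [q, q]}))

    def test_boundary_values(self):
        assert background_mortality(self.make_lt(0.0), 61, 0.47) == 0.0
        assert background_mortality(self.make_lt(1.0), 61, 0.47) == 1.0

    def test_annual_to_monthly_conversion(self):
        m = background_mortality(self.make_lt(0.012), 61, 0.47)
        assert m == pytest.approx(0.0010055425391276573, rel=1e-12)

    def test_sex_mixture(self):
        lt = LifeTable(pd.DataFrame({"age": [61], "male": [0.02], "female": [0.01]}))
        assert lt.annual_q(61.5, 0.47) == pytest.approx(0.47 * 0.02 + 0.53 * 0.01)

    def test_beyond_table_uses_terminal_row(self):
        lt = self.make_lt(0.3)
        assert lt.annual_q(120, 0.5) == pytest.approx(0.3)

    def test_bundled_table_nondecreasing_above_30(self, params):
        lt = params.life_table
        older = lt[lt.age >= 30]
        assert (older[["male", "female"]].diff().dropna() >= 0).all().all()


class TestCombineCompeting:
    def test_degenerate_cases(self):
        assert combine_competing(0, 0, 0) == {"stay": 1.0, "progress": 0.0, "death": 0.0}
        out = combine_competing(0.2, 0, 0)
        assert out["progress"] == pytest.approx(0.2)
        assert out["stay"] == pytest.approx(0.8)

    def test_against_monte_carlo_mechanism(self):
        """Independent-risk composition matches direct simulation of the mechanism."""
        p_prog, p_ae, p_bg = 0.2, 0.01, 0.001
        n = 10_000_000
        rng = np.random.default_rng(2021)
        dies = (rng.uniform(size=n) < p_ae) | (rng.uniform(size=n) < p_bg)
        progresses = (~dies) & (rng.uniform(size=n) < p_prog)
        expected = combine_competing(p_prog, p_ae, p_bg)
        for key, emp in (
            ("death", dies.mean()),
            ("progress", progresses.mean()),
            ("stay", 1.0 - dies.mean() - progresses.mean()),
        ):
            se = np.sqrt(expected[key] * (1 - expected[key]) / n)
            assert abs(emp - expected[key]) <= 3 * se + 1e-7

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            combine_competing(1.2, 0, 0)


class TestClosedFormChain:
    def test_median_os_derives_from_pfs_chain(self, params):
        """With toxicity and background mortality off and the MSI-H branch
        closed, the alive curve is the discrete convolution of the two
        line-residence distributions plus one BSC cycle."""
        p = params.with_overrides(
            {
                "pct_msi_h": 0.0,
                "ae_discontinue_standard": 0.0,
                "ae_mortality_standard": 0.0,
                "ae_discontinue_regorafenib": 0.0,
                "ae_mortality_regorafenib": 0.0,
            }
        ).with_bsc_months(0.1)
        profile = CohortProfile.from_params(p)
        spec = build_strategy(profile, p, "standard")
        horizon = 120
        trace = run_cohort(spec.space, spec.rules, horizon=horizon,
                           initial=spec.initial, background=0.0, death_state=STATE_DEATH)
        alive = trace.alive_fraction()

        s1 = spec.lines[STATE_FIRST_LINE].pfs_law.survival(np.arange(horizon + 2))
        s2 = spec.lines[STATE_REGORAFENIB].pfs_law.survival(np.arange(horizon + 2))
        pmf1 = s1[:-1] - s1[1:]  # leaves first line during cycle k
        pmf2 = s2[:-1] - s2[1:]
        pmf_sum = np.convolve(pmf1, pmf2)[: horizon + 1]
        # death boundary = k1 + k2 + 3 (one boundary per line entry + BSC cycle)
        cdf = np.cumsum(pmf_sum)
        expected = np.ones(horizon + 1)
        for c in range(horizon + 1):
            expected[c] = 1.0 - (cdf[c - 3] if c >= 3 else 0.0)
        np.testing.assert_allclose(alive, expected, atol=1e-10)


class TestCalibration:
    def test_returned_value_minimizes_grid_objective(self, params):
        cal = calibrate_bsc(params, grid=(0.5, 3.0, 0.5))
        assert (cal.grid["objective"] >= cal.objective - 1e-12).all()
        assert cal.bsc_months == cal.grid.loc[cal.grid["objective"].idxmin(), "bsc_months"]

    def test_base_targets_reproduce_near_half_month(self, params):
        """The trial-median targets are met inside the low-residence tie set,
        which contains the half-month value the base configuration uses."""
        cal = calibrate_bsc(params, grid=(0.1, 2.0, 0.05))
        assert cal.bsc_months <= 0.5
        assert 0.5 in cal.ties
        assert cal.achieved["doublet"] == pytest.approx(9.3, abs=0.25)

    def test_absurd_targets_flagged_unreachable(self, params):
        cal = calibrate_bsc(
            params, targets={"doublet": 1000.0, "standard": 1000.0}, grid=(0.5, 2.0, 0.5)
        )
        assert cal.target_unreachable
        assert cal.bsc_months == 2.0  # best achievable is the largest residence

    def test_positive_targets_required(self, params):
        with pytest.raises(ValueError):
            calibrate_bsc(params, targets={"doublet": -1.0, "standard": 5.9})
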