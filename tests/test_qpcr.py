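"""Copy-number formula, normalization, exact rank-sum test, calls."""

import itertools

import numpy as np
import pandas as pd
import pytest

import mtscope as m
from mtscope import qpcr


class TestCopyNumber:
    def test_unit_efficiency_zero_cycles(self):
        assert m.copy_number(Ft=500.0, E=1.0, Ct=0.0, Amp=50.0) == 10.0

    def test_one_cycle_ratio_identity(self):
        """N0(Ct+1)/N0(Ct) = 1/(1+E) for any inputs."""
        for E, Ct, Amp in [(0.8, 5, 100), (1.0, 20, 250), (0.95, 33.3, 80)]:
            r = m.copy_number(1000, E, Ct + 1, Amp) / m.copy_number(1000, E, Ct, Amp)
            assert r == pytest.approx(1 / (1 + E), abs=1e-12)

    def test_regression_against_arbitrary_precision_oracle(self):
        # frozen from a 50-digit Decimal evaluation of 1000 * 1.95**-20 / 120
        assert m.copy_number(1000, 0.95, 20, 120) == pytest.approx(
            1.3186408534455085e-05, rel=1e-12
        )

    def test_percent_efficiency_autodetected(self):
        with pytest.warns(UserWarning, match="percentage"):
            v = m.copy_number(1000, 95.0, 20, 120)
        assert v == pytest.approx(m.copy_number(1000, 0.95, 20, 120))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            m.copy_number(1000, -0.5, 20, 120)
        with pytest.raises(ValueError):
            m.copy_number(1000, 0.95, 20, 0)


class TestBackgroundSubtraction:
    def test_plain_difference(self):
        assert m.subtract_dna_background(100.0, 30.0) == 70.0

    def test_floored_at_zero(self):
        assert m.subtract_dna_background(100.0, 150.0) == 0.0

    def test_missing_rt_minus_warns_and_passes_through(self):
        with pytest.warns(UserWarning, match="RT-minus"):
            assert m.subtract_dna_background(100.0, None) == 100.0


class TestNormalization:
    def _frame(self, control_values, target_value=100.0):
        rows = []
        for i, cv in enumerate(control_values, start=1):
            rows.append(
                dict(target="cox2", condition="leaf", bio_rep=i, tech_rep=1,
                     N0_corrected=cv)
            )
            rows.append(
                dict(target="orfX", condition="leaf", bio_rep=i, tech_rep=1,
                     N0_corrected=target_value)
            )
        return pd.DataFrame(rows)

    def test_worked_example(self):
        norm = m.normalize_to_control(self._frame([10.0, 20.0, 40.0]))
        got = norm[(norm.target == "orfX") & (norm.bio_rep == 2)]
        assert got["N0_normalized"].iloc[0] == pytest.approx(50.0)

    def test_controls_map_to_minimum(self):
        norm = m.normalize_to_control(self._frame([10.0, 20.0, 40.0]))
        ctrl = norm[norm.target == "cox2"]["N0_normalized"]
        assert np.allclose(ctrl, 10.0)

    def test_equal_controls_identity(self):
        norm = m.normalize_to_control(self._frame([7.0, 7.0, 7.0]))
        tgt = norm[norm.target == "orfX"]["N0_normalized"]
        assert np.allclose(tgt, 100.0)

    def test_zero_control_hard_error(self):
        with pytest.raises(ValueError, match="positive"):
            m.normalize_to_control(self._frame([0.0, 10.0, 20.0]))

    def test_missing_control_replicate_dropped(self):
        df = self._frame([10.0, 20.0])
        extra = pd.DataFrame(
            [dict(target="orfX", condition="leaf", bio_rep=9, tech_rep=1,
                  N0_corrected=5.0)]
        )
        with pytest.warns(UserWarning, match="no control well"):
            norm = m.normalize_to_control(pd.concat([df, extra]))
        assert 9 not in set(norm["bio_rep"])


def oracle_rank_sum_p(a, b):
    """Independent enumeration oracle: U by pair counting over all label
    permutations of the pooled multiset."""
    pooled = list(a) + list(b)
    n1 = len(a)
    mu = n1 * len(b) / 2.0
    u_obs = sum(
        (x > y) + 0.5 * (x == y) for x in a for y in b
    )
    dev = abs(u_obs - mu)
    total = extreme = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        g = [pooled[i] for i in combo]
        others = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = sum((x > y) + 0.5 * (x == y) for x in g for y in others)
        total += 1
        if abs(u - mu) >= dev - 1e-9:
            extreme += 1
    return extreme / total


class TestRankSum:
    def test_complete_separation_worked_example(self):
        res = m.rank_sum_test([1, 2, 3], [4, 5, 6])
        assert res.U == 0 and res.p_two_sided == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        res = m.rank_sum_test([5, 5, 7], [5, 5, 7])
        assert res.p_two_sided == pytest.approx(1.0)

    def test_symmetric_in_group_order(self):
        a, b = [1.2, 3.4, 2.2, 9.9], [0.5, 4.4, 4.4]
        assert m.rank_sum_test(a, b).p_two_sided == pytest.approx(
            m.rank_sum_test(b, a).p_two_sided
        )

    @pytest.mark.parametrize("n1,n2", [(n1, n2) for n1 in range(1, 7) for n2 in range(n1, 7)])
    def test_exact_p_matches_enumeration_oracle(self, n1, n2):
        """All group sizes up to 6 vs 6, with and without ties."""
        rng = np.random.default_rng(100 * n1 + n2)
        a = rng.integers(0, 6, size=n1).astype(float).tolist()  # ties likely
        b = rng.integers(0, 6, size=n2).astype(float).tolist()
        res = m.rank_sum_test(a, b)
        assert res.method == "exact"
        assert res.p_two_sided == pytest.approx(oracle_rank_sum_p(a, b))

    def test_agrees_with_scipy_exact_when_tie_free(self):
        from scipy import stats

        rng = np.random.default_rng(9)
        a = rng.normal(size=6).tolist()
        b = rng.normal(size=6).tolist()
        res = m.rank_sum_test(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert res.p_two_sided == pytest.approx(float(ref.pvalue))

    def test_large_samples_flagged_normal_approx(self):
        a = list(range(10))
        b = list(range(5, 15))
        res = m.rank_sum_test(a, b)
        assert res.method == "normal_approx"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            m.rank_sum_test([], [1.0])


class TestCalls:
    def test_clear_separation_above(self):
        tgt = [10.0, 12, 11, 13, 10.5, 12.5]
        bg = [1.0, 1.2, 0.9, 1.1, 1.05, 0.95]
        res = m.call_above_background(tgt, bg)
        assert res["is_above"] and res["p"] < 0.05

    def test_identical_to_background_not_above(self):
        bg = [1.0, 1.2, 0.9, 1.1, 1.05, 0.95]
        assert not m.call_above_background(bg, bg)["is_above"]

    def test_direction_enforced(self):
        low = [0.1, 0.12, 0.09, 0.11, 0.1, 0.08]
        bg = [1.0, 1.2, 0.9, 1.1, 1.05, 0.95]
        res = m.call_above_background(low, bg)
        assert not res["is_above"] and res["p"] < 0.05

    def test_polysome_association_delegates(self):
        tgt = [10.0, 12, 11, 13, 10.5, 12.5]
        bg = [1.0, 1.2, 0.9, 1.1, 1.05, 0.95]
        assert m.call_polysome_association(tgt, bg)["is_above"]


class TestParameterRecovery:
    def test_simulated_plate_recovers_ratios_within_15pct(self):
        """Ct noise sd 0.2, n = 6: normalized estimates recover true ratios."""
        truth = {"cox2": 1e-3, "orfA": 2e-4, "orfB": 4e-5, "orf161": 1e-6}
        wells, primers = m.simulate_qpcr_wells(truth, condition="leaf", seed=1)
        est = qpcr.estimate_copies(wells, primers)
        norm = m.normalize_to_control(est)
        means = norm.groupby("target")["N0_normalized"].mean()
        ratio = means["orfA"] / means["orfB"]
        assert abs(ratio / (truth["orfA"] / truth["orfB"]) - 1) <= 0.15

    def test_end_to_end_expression_calls(self):
        truth = {"cox2": 1e-3, "orfA": 2e-4, "orfB": 4e-5, "orf161": 1e-6}
        wells, primers = m.simulate_qpcr_wells(truth, condition="root", seed=2)
        norm = m.normalize_to_control(qpcr.estimate_copies(wells, primers))
        bg = norm[norm.target == "orf161"]["N0_normalized"].tolist()
        for t in ("orfA", "orfB"):
            vals = norm[norm.target == t]["N0_normalized"].tolist()
            assert m.call_above_background(vals, bg)["is_above"], t
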