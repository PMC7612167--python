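"""Exact comparator evaluation: Simon, Jung, Carsten, Chen."""

import numpy as np
import pytest
from scipy.stats import binom

from scblock import TwoStageDesign, comparator_search, simulate_comparator

from ._oracles import carsten_by_enumeration, chen_by_enumeration

# published two-stage / curtailed rows at (alpha, beta, p0, p1)
# = (0.15, 0.20, 0.30, 0.50); layout (r1, n1, r, n_arm, ESS00, ESS01)
SIMON_ROW = (2, 8, 10, 28, 17.0, 25.1)
JUNG_ROW = (0, 22, 5, 46, 64.9, 86.7)
CARSTEN_ROW = (5, 19, 12, 44, 51.3, 60.3)  # 10,000-replicate estimates
CHEN_ROW = (0, 16, 5, 45, 60.1, 76.9)  # 10,000-replicate estimates


class TestSimon:
    def test_published_row(self):
        r1, n1, r, n, ess00, _ = SIMON_ROW
        d = TwoStageDesign(kind="simon", r1=r1, n1=n1, r=r, n_arm=n)
        r1, n1, r, n, _, ess01 = SIMON_ROW
        a, e0 = d.evaluate(0.3, 0.3)
        pw, e1 = d.evaluate(0.5, 0.5)  # single-arm: response rate is pt
        assert round(e0, 1) == pytest.approx(ess00)
        assert round(e1, 1) == pytest.approx(ess01)
        assert a <= 0.15 and pw >= 0.80

    def test_pet_and_ess_identity(self):
        d = TwoStageDesign(kind="simon", r1=1, n1=10, r=5, n_arm=25)
        p = 0.2
        pet = binom.cdf(1, 10, p)
        _, en = d.evaluate(p, p)
        assert en == pytest.approx(10 + (1 - pet) * 15, abs=1e-12)

    def test_rejection_by_direct_sum(self):
        d = TwoStageDesign(kind="simon", r1=1, n1=6, r=4, n_arm=12)
        p = 0.35
        expected = sum(
            binom.pmf(x1, 6, p) * binom.sf(4 - x1, 6, p)
            for x1 in range(2, 7)
        )
        a, _ = d.evaluate(p, p)
        assert a == pytest.approx(expected, abs=1e-12)


class TestJung:
    def test_published_row(self):
        r1, n1, r, n, ess00, ess01 = JUNG_ROW
        d = TwoStageDesign(kind="jung", r1=r1, n1=n1, r=r, n_arm=n)
        a, e00 = d.evaluate(0.3, 0.3)
        pw, e01 = d.evaluate(0.3, 0.5)
        assert round(e00, 1) == pytest.approx(ess00)
        assert round(e01, 1) == pytest.approx(ess01)
        assert a <= 0.15 and pw >= 0.80

    def test_never_stopping_interim_equals_single_stage(self):
        """r1 = -n1 - 1 can never stop at the interim (D1 >= -n1 always):
        the design reduces to a single-stage comparison of X_T - X_C >= r
        at n per arm."""
        n, r = 12, 3
        d = TwoStageDesign(kind="jung", r1=-7, n1=6, r=r, n_arm=n)
        pc, pt = 0.3, 0.5
        a, en = d.evaluate(pc, pt)
        k = np.arange(n + 1)
        pmf = np.convolve(binom.pmf(k, n, pt), binom.pmf(k, n, 1 - pc))
        direct = pmf[np.arange(-n, n + 1) >= r].sum()
        assert a == pytest.approx(float(direct), abs=1e-12)
        assert en == pytest.approx(2.0 * n, abs=1e-12)

    def test_single_stage_when_n1_equals_n(self):
        d = TwoStageDesign(kind="jung", r1=0, n1=10, r=2, n_arm=10)
        a, en = d.evaluate(0.3, 0.5)
        assert en == pytest.approx(20.0)
        assert 0.0 < a < 1.0


class TestCarsten:
    def test_certain_pair_success(self):
        # pt=1, pc=0: every pair is a success; go at pair r exactly
        d = TwoStageDesign(kind="carsten", r1=2, n1=5, r=4, n_arm=10)
        rej, en = d.evaluate(0.0, 1.0)
        assert rej == pytest.approx(1.0, abs=1e-12)
        assert en == pytest.approx(2.0 * 4, abs=1e-12)

    def test_certain_pair_failure(self):
        # ps=0: successes never accrue; no-go as soon as r1 by n1 fails
        d = TwoStageDesign(kind="carsten", r1=2, n1=5, r=4, n_arm=10)
        rej, en = d.evaluate(0.3, 0.0)
        assert rej == 0.0
        # first j with 0 + (n1 - j) < r1, i.e. j > n1 - r1 = 3 -> j = 4
        assert en == pytest.approx(2.0 * 4, abs=1e-12)

    @pytest.mark.parametrize("params,rates", [
        ((1, 4, 3, 8), (0.3, 0.5)),
        ((2, 4, 3, 7), (0.3, 0.3)),
        ((0, 3, 2, 6), (0.1, 0.8)),
    ])
    def test_matches_sequence_enumeration(self, params, rates):
        r1, n1, r, n = params
        d = TwoStageDesign(kind="carsten", r1=r1, n1=n1, r=r, n_arm=n)
        rej_o, en_o = carsten_by_enumeration(d, *rates)
        rej, en = d.evaluate(*rates)
        assert rej == pytest.approx(rej_o, abs=1e-12)
        assert en == pytest.approx(en_o, abs=1e-10)

    def test_published_row_within_mc_tolerance(self):
        r1, n1, r, n, ess00, ess01 = CARSTEN_ROW
        d = TwoStageDesign(kind="carsten", r1=r1, n1=n1, r=r, n_arm=n)
        _, e00 = d.evaluate(0.3, 0.3)
        _, e01 = d.evaluate(0.3, 0.5)
        # published values are 10,000-replicate estimates; +-1.0 = ~3 SE
        assert abs(e00 - ess00) <= 1.0
        assert abs(e01 - ess01) <= 1.0


class TestChen:
    def test_unreachable_final_boundary(self):
        d = TwoStageDesign(kind="chen", r1=0, n1=2, r=5, n_arm=4)
        rej, en = d.evaluate(0.3, 0.5)
        assert rej == 0.0
        assert en == 1.0  # curtailed at the very first patient

    @pytest.mark.parametrize("params,rates", [
        ((0, 3, 2, 6), (0.3, 0.5)),
        ((-1, 2, 1, 5), (0.3, 0.3)),
        ((1, 3, 2, 5), (0.2, 0.7)),
    ])
    def test_matches_sequence_enumeration(self, params, rates):
        r1, n1, r, n = params
        d = TwoStageDesign(kind="chen", r1=r1, n1=n1, r=r, n_arm=n)
        rej_o, en_o = chen_by_enumeration(d, *rates)
        rej, en = d.evaluate(*rates)
        assert rej == pytest.approx(rej_o, abs=1e-12)
        assert en == pytest.approx(en_o, abs=1e-10)

    def test_published_row_within_mc_tolerance(self):
        r1, n1, r, n, ess00, ess01 = CHEN_ROW
        d = TwoStageDesign(kind="chen", r1=r1, n1=n1, r=r, n_arm=n)
        _, e00 = d.evaluate(0.3, 0.3)
        _, e01 = d.evaluate(0.3, 0.5)
        assert abs(e00 - ess00) <= 1.0
        assert abs(e01 - ess01) <= 1.0


class TestMonteCarloMode:
    @pytest.mark.parametrize("kind,params", [
        ("simon", (1, 10, 5, 25)),
        ("jung", (0, 8, 2, 16)),
        ("carsten", (2, 8, 5, 16)),
        ("chen", (0, 8, 3, 16)),
    ])
    def test_agrees_with_exact_within_3se(self, kind, params):
        r1, n1, r, n = params
        d = TwoStageDesign(kind=kind, r1=r1, n1=n1, r=r, n_arm=n)
        pc, pt = 0.3, 0.5
        exact = d.evaluate(pc, pt)
        est, se = simulate_comparator(d, pc, pt, n_reps=4000, seed=11)
        assert abs(est.reject_prob - exact.reject_prob) <= 3 * max(se.reject_prob, 1e-3)
        assert abs(est.expected_n - exact.expected_n) <= 3 * max(se.expected_n, 1e-3)

    def test_seed_determinism(self):
        d = TwoStageDesign(kind="carsten", r1=2, n1=8, r=5, n_arm=16)
        a = simulate_comparator(d, 0.3, 0.5, n_reps=500, seed=3)
        b = simulate_comparator(d, 0.3, 0.5, n_reps=500, seed=3)
        assert a == b


class TestValidationAndSearch:
    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            TwoStageDesign(kind="bogus", r1=0, n1=5, r=2, n_arm=10)
        with pytest.raises(ValueError):
            TwoStageDesign(kind="jung", r1=0, n1=11, r=2, n_arm=10)
        with pytest.raises(ValueError):
            TwoStageDesign(kind="jung", r1=3, n1=5, r=2, n_arm=10)

    def test_small_simon_search(self):
        # the published minimax Simon design needs n = 21
        out = comparator_search("simon", p0=0.3, p1=0.5, alpha=0.15,
                                beta=0.2, n_min=15, n_max=22)
        assert out  # feasible single-arm designs exist at this size
        from scblock import pareto_mask
        crit = np.array([[e00, e01, d.max_total]
                         for d, _, _, e00, e01 in out])
        assert pareto_mask(crit).all()
        for d, a, pw, _, _ in out:
            assert a <= 0.15 and pw >= 0.80
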