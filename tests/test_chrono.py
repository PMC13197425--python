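"""Joint chronological model: life events, date pooling, validation,
MCMC correctness against the single-date oracle, and agreement indices."""

import math

import numpy as np
import pytest
from scipy import stats

from tidechron import calcurve as cc
from tidechron import chrono
from tidechron import synthetic as syn
from tidechron.examples import juc73_histogram


class TestLifespanEvents:
    def test_second_molar_life_history(self):
        le = chrono.lifespan_events("JUC73", "second_molar", (40.0, 55.0))
        assert le.offset == (11.0, 1.0)
        assert le.age_at_death == (40.0, 55.0)
        assert le.birth_event == "birth:JUC73"
        assert le.death_event == "death:JUC73"

    def test_vomer_uses_informal_offset(self):
        le = chrono.lifespan_events("X", "vomer", (30.0, 40.0))
        assert le.offset == (15.0, 5.0)

    def test_zero_offset_makes_birth_coincide_with_tissue(self):
        le = chrono.lifespan_events("X", None, (20.0, 30.0), offset_override=(0.0, 0.0))
        assert le.offset == (0.0, 0.0)

    def test_unknown_tissue_without_override_raises(self):
        with pytest.raises(KeyError):
            chrono.lifespan_events("X", "femur", (20.0, 30.0))


class TestCombine:
    def test_equal_duplicates(self):
        d = [cc.RadiocarbonDetermination(f"L{i}", 1000, 20) for i in range(2)]
        pooled, rep = chrono.combine_determinations(d)
        assert pooled.age == pytest.approx(1000.0)
        assert pooled.sigma == pytest.approx(20.0 / math.sqrt(2))
        assert rep["passed"]

    def test_inverse_variance_oracle(self):
        d = [
            cc.RadiocarbonDetermination("a", 1000, 20),
            cc.RadiocarbonDetermination("b", 1040, 30),
        ]
        pooled, rep = chrono.combine_determinations(d)
        w = np.array([1 / 400, 1 / 900])
        assert pooled.age == pytest.approx((w @ [1000, 1040]) / w.sum())
        assert pooled.sigma == pytest.approx(w.sum() ** -0.5)
        chi2 = float(
            (w * (np.array([1000, 1040]) - pooled.age) ** 2).sum()
        )
        assert rep["statistic"] == pytest.approx(chi2)
        assert rep["pvalue"] == pytest.approx(stats.chi2.sf(chi2, 1))

    def test_inconsistent_pair_fails_chi2(self):
        d = [
            cc.RadiocarbonDetermination("a", 1000, 10),
            cc.RadiocarbonDetermination("b", 1200, 10),
        ]
        _, rep = chrono.combine_determinations(d)
        assert not rep["passed"]

    def test_single_input_rejected(self):
        with pytest.raises(ValueError):
            chrono.combine_determinations([cc.RadiocarbonDetermination("a", 1000, 10)])


class TestAssembly:
    def test_empty_determination_list_rejected(self, shcal20, marine20):
        with pytest.raises(chrono.ModelValidationError, match="no determinations"):
            chrono.assemble_model([], [], shcal20, marine20)

    def test_dangling_event_reference(self, shcal20, marine20):
        det = cc.RadiocarbonDetermination("x", 800, 20)
        with pytest.raises(chrono.ModelValidationError, match="undeclared event"):
            chrono.assemble_model(
                [], [chrono.ModelDate(det, "s:nowhere")], shcal20, marine20
            )

    def test_contradictory_sequence_rejected(self, shcal20, marine20):
        det = cc.RadiocarbonDetermination("x", 800, 20)
        seq = chrono.StratSequence("bad", [["s:a"], ["s:b"], ["s:a"]])
        with pytest.raises(chrono.ModelValidationError, match="cycle"):
            chrono.assemble_model(
                [], [chrono.ModelDate(det, "s:a")], shcal20, marine20,
                sequences=[seq], extra_events=["s:a", "s:b"],
            )


@pytest.fixture(scope="module")
def single_date_run(shcal20, marine20):
    """Unconstrained single terrestrial date, long chains."""
    det = cc.RadiocarbonDetermination("X", 895, 20, material="charcoal")
    model = chrono.assemble_model(
        [], [chrono.ModelDate(det, "s:X")], shcal20, marine20, extra_events=["s:X"]
    )
    chains = chrono.run_mcmc(model, chains=4, iterations=100_000, seed=3)
    return det, model, chains


class TestMcmc:
    def test_single_date_marginal_matches_calibration(self, shcal20, single_date_run):
        # total variation between the MCMC marginal and the direct
        # calibration, at 200k retained draws
        det, _, chains = single_date_run
        draws = chains.event_draws("s:X")
        assert draws.size == 200_000
        ref = cc.calibrate_single(det, shcal20)
        edges = np.concatenate([ref.grid - 0.5, [ref.grid[-1] + 0.5]])
        h, _ = np.histogram(draws, bins=edges)
        h = h / draws.size
        tv = 0.5 * (np.abs(h - ref.weights).sum() + (1.0 - h.sum()))
        assert tv < 0.02

    def test_seeded_rerun_is_bit_identical(self, shcal20, marine20):
        det = cc.RadiocarbonDetermination("X", 700, 25)
        model = chrono.assemble_model(
            [], [chrono.ModelDate(det, "s:X")], shcal20, marine20, extra_events=["s:X"]
        )
        a = chrono.run_mcmc(model, chains=3, iterations=2000, seed=42,
                            check_convergence=False)
        b = chrono.run_mcmc(model, chains=3, iterations=2000, seed=42,
                            check_convergence=False)
        for name in a.draws:
            np.testing.assert_array_equal(a.draws[name], b.draws[name])

    def test_point_mass_priors_give_constant_chains(self, shcal20, marine20):
        # fixed reservoir offset, zero-sd tissue offset, zero-width age
        # interval and a one-bin diet histogram: those parameters never move
        hist_counts = np.zeros(100, int)
        hist_counts[20] = 1000  # marine fraction fixed at 20.5%
        from tidechron.diet import DietHistogram

        le = chrono.lifespan_events("A", None, (45.0, 45.0), offset_override=(11.0, 0.0))
        det = cc.RadiocarbonDetermination("X", 800, 20, material="human bone")
        model = chrono.assemble_model(
            [le],
            [chrono.ModelDate(det, "tissue:A", histogram=DietHistogram(hist_counts))],
            shcal20, marine20,
            delta_r=cc.ReservoirOffset("fixed", mean=-300.0, sd=0.0),
        )
        chains = chrono.run_mcmc(model, chains=3, iterations=2000, seed=1,
                                 check_convergence=False)
        assert np.ptp(chains.draws["o:A"]) == 0
        assert np.ptp(chains.draws["a:A"]) == 0
        assert np.ptp(chains.draws["dR"]) == 0
        assert np.ptp(chains.draws["m:0"]) == 0
        # the tissue date itself still mixes
        assert np.ptp(chains.draws["t:A"]) > 0

    def test_hard_constraints_hold_in_every_draw(self, shcal20, marine20):
        truth = syn.family_scenario(seed=2, delta_r=-300.0)
        dates = syn.simulate_chronology(truth, shcal20, marine20, seed=3)
        hists = {
            i.id: syn.true_histogram(i.marine, sd=0.05, seed=4) for i in truth.sampled
        }
        model = syn.build_model(truth, dates, hists, shcal20, marine20)
        chains = chrono.run_mcmc(model, chains=3, iterations=3000, seed=5,
                                 check_convergence=False)
        below = chains.event_draws("s:below")
        above = chains.event_draws("s:above")
        for ind in truth.sampled:
            birth = chains.event_draws(f"birth:{ind.id}")
            death = chains.event_draws(f"death:{ind.id}")
            assert np.all(death <= birth)  # cal BP: death is younger
            assert np.all(death < below)
            assert np.all(death > above)
            m = chains.flat(f"m:{dates[dates.individual == ind.id].index[0]}")
            assert np.all((m >= 0) & (m <= 1))


class TestAgreement:
    def test_unconstrained_single_date_agrees_fully(self, single_date_run):
        _, model, chains = single_date_run
        out = chrono.agreement_indices(chains, model)
        assert out["A_i"]["X"] == pytest.approx(100.0, abs=5.0)
        assert out["A_model"] == pytest.approx(100.0, abs=5.0)
        assert out["flagged"] == []

    def test_gaussian_overlap_matches_closed_form(self):
        # for N(0,s) vs N(d,s) on a fine grid the index is
        # 100*exp(-d^2/(4 s^2))
        s = 30.0
        grid = np.arange(-400.0, 401.0)
        p0 = stats.norm.pdf(grid, 0, s)
        p0 /= p0.sum()
        prev = np.inf
        for d in (0.0, 20.0, 40.0, 80.0, 160.0):
            p1 = stats.norm.pdf(grid, d, s)
            p1 /= p1.sum()
            a = chrono.agreement_index(p1, p0)
            assert a == pytest.approx(100.0 * math.exp(-(d**2) / (4 * s**2)), rel=1e-3)
            assert a < prev or d == 0.0
            prev = a

    def test_flag_fires_below_sixty(self, single_date_run):
        det, model, chains = single_date_run
        shifted = chrono.PosteriorChains(
            {k: v - 150.0 if k == "e:s:X" else v for k, v in chains.draws.items()},
            chains.rhat, chains.acceptance, chains.seed, model,
        )
        out = chrono.agreement_indices(shifted, model)
        assert out["A_i"]["X"] < 60.0
        assert out["flagged"] == ["X"]

    def test_worked_example_histogram_loads(self):
        # the published 100-bin marine-diet histogram used in docs
        h = juc73_histogram()
        assert h.counts.sum() == 3000
        assert h.counts[0] == 140 and h.counts[-1] == 1
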