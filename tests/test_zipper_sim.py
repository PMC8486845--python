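"""Zipper-model physics: NN energetics, FJC elasticity, force balance,
KMC detailed balance, unzipping and restoration."""

import math
import time

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import chisquare

from zipperjunction.constants import KCAL_PER_MOL_TO_PN_NM, kt_pn_nm
from zipperjunction.restoration import DWELL_90MER, dwell_length
from zipperjunction.synthetic_data import SeriesGenParams, gen_sequence, preset_trace
from zipperjunction.trace_analysis import judge_plateau, set_displacement_origin
from zipperjunction.zipper_sim import (
    ConductanceMap,
    Duplex,
    Protocol,
    ZipperParams,
    duplex_free_energy,
    fjc_extension,
    force_balance,
    fork_energies,
    gen_simulated_series,
    junction_conductance,
    kmc_run,
    nn_step_free_energies,
    sample_fork_occupancy,
    trace_from_trajectory,
    unzip_force_plateau,
)

KT300 = kt_pn_nm(300.0)


def _revcomp(seq: str) -> str:
    return seq[::-1].translate(str.maketrans("ACGT", "TGCA"))


class TestNearestNeighbour:
    def test_gc_duplex_stabler_than_at(self):
        at = nn_step_free_energies("AT" * 10).sum()
        gc = nn_step_free_energies("GC" * 10).sum()
        assert gc > at > 0

    @pytest.mark.parametrize("seed", range(4))
    def test_reverse_complement_invariance(self, seed):
        seq = gen_sequence(30, 0.5, seed=seed)
        a = nn_step_free_energies(seq).sum()
        b = nn_step_free_energies(_revcomp(seq)).sum()
        assert a == pytest.approx(b, rel=1e-12)

    def test_five_bp_hand_sum(self):
        """ACGTA at 300 K: steps AC, CG, GT, TA from the embedded table,
        summed by hand: 1.68 + 2.44 + 1.68 + 0.81 = 6.61 kcal/mol."""
        total = nn_step_free_energies("ACGTA", 300.0).sum()
        assert total == pytest.approx(6.61, abs=1e-9)

    def test_pair_costs_sum_to_step_total_and_symmetry(self):
        seq = gen_sequence(25, 0.6, seed=9)
        d = Duplex.from_sequence(seq)
        assert d.pair_opening_costs().sum() == pytest.approx(
            d.step_free_energies.sum())
        dr = Duplex.from_sequence(_revcomp(seq))
        assert np.allclose(d.pair_opening_costs(),
                           dr.pair_opening_costs()[::-1])

    def test_initiation_included_in_duplex_free_energy(self):
        dg = duplex_free_energy("ACGTA", 300.0)
        assert dg < 0  # stable duplex overall
        assert abs(dg) < nn_step_free_energies("ACGTA").sum()

    def test_unknown_characters_rejected(self):
        with pytest.raises(ValueError):
            nn_step_free_energies("ACGUX")


class TestFJC:
    def test_zero_force_zero_extension(self):
        assert float(fjc_extension(0.0, ZipperParams())) == 0.0

    def test_saturates_at_contour(self):
        p = ZipperParams()
        x = float(fjc_extension(1e6, p))
        assert x == pytest.approx(p.contour_per_nt, rel=1e-4)

    def test_langevin_point_at_kt_per_kuhn(self):
        """f = kT/b gives extension c (coth 1 - 1) = 0.3130 c."""
        p = ZipperParams()
        f = KT300 / p.kuhn_length
        expect = p.contour_per_nt * (1 / math.tanh(1.0) - 1.0)
        assert float(fjc_extension(f, p)) == pytest.approx(expect, rel=1e-12)

    def test_strictly_increasing(self):
        p = ZipperParams()
        f = np.linspace(0, 200, 400)
        x = fjc_extension(f, p)
        assert np.all(np.diff(x) > 0)


class TestForceBalance:
    def test_zero_inside_slack(self):
        p = ZipperParams()
        assert force_balance(10, 0.0, p) == 0.0
        assert force_balance(0, p.slack_nm, p) == 0.0

    def test_hookean_spring_limit(self):
        """With no released strand and no linker compliance the two springs
        in series give f = (k/2) (z - slack)."""
        p = ZipperParams(linker_nt=0)
        dz = 1e-4  # nm past the slack
        f = force_balance(0, p.slack_nm + dz, p)
        assert f == pytest.approx(p.k_spring_pn_nm / 2 * dz, rel=1e-9)

    def test_residual_oracle_random_cases(self):
        """The returned force satisfies the extension equation to 1e-9 nm
        over 10^4 random configurations."""
        p = ZipperParams()
        rng = np.random.default_rng(0)
        t0 = time.time()
        worst = 0.0
        for _ in range(10_000):
            n = int(rng.integers(0, 91))
            z = float(rng.uniform(p.slack_nm + 1e-3, 80.0))
            f = force_balance(n, z, p)
            ext = (p.slack_nm + 2 * f / p.k_spring_pn_nm
                   + (2 * n + p.linker_nt) * float(fjc_extension(f, p)))
            worst = max(worst, abs(ext - z))
        assert worst < 1e-9
        assert time.time() - t0 < 10.0

    def test_monotonicity_in_z_and_n(self):
        p = ZipperParams()
        zs = np.linspace(0, 40, 30)
        grid = np.array([[force_balance(n, z, p) for z in zs]
                         for n in (0, 2, 5, 10, 30, 90)])
        assert np.all(np.diff(grid, axis=1) >= -1e-9)  # nondecreasing in z
        assert np.all(np.diff(grid, axis=0) <= 1e-9)  # nonincreasing in n


class TestKMC:
    def test_zero_pull_keeps_duplex_closed(self, duplex90):
        traj = kmc_run(duplex90, ZipperParams(),
                       Protocol(pull_distance=0.0, hold_time=0.3,
                                return_tip=False), seed=0)
        assert traj.n_open.max() <= 3
        assert np.mean(traj.n_open == 0) > 0.5

    def test_detailed_balance_against_exact_enumeration(self):
        """At frozen tip the chain samples the Boltzmann law of the
        enumerated fork energies (5-bp duplex, all 6 states)."""
        dup = Duplex.from_sequence("ACGTA")
        p = ZipperParams()
        z = 3.5
        energies = fork_energies(dup, p, z)
        w = np.exp(-(energies - energies.min()) / KT300)
        p_exact = w / w.sum()
        counts = sample_fork_occupancy(dup, p, z, 1_000_000, seed=3,
                                       burn_in=10_000)
        p_emp = counts / counts.sum()
        assert np.abs(p_emp - p_exact).max() < 0.01
        # chi^2 at an effective sample size that discounts the chain's
        # autocorrelation (~100 attempts) so the test is calibrated
        eff = 10_000
        obs = np.round(p_emp * eff)
        keep = p_exact * eff >= 5
        f_exp = p_exact[keep] / p_exact[keep].sum() * obs[keep].sum()
        _, pval = chisquare(obs[keep], f_exp)
        assert pval > 1e-3

    def test_trajectory_bit_reproducible(self, duplex90):
        a = kmc_run(duplex90, ZipperParams(), Protocol(), seed=7)
        b = kmc_run(duplex90, ZipperParams(), Protocol(), seed=7)
        assert np.array_equal(a.n_open, b.n_open)
        assert np.array_equal(a.force, b.force)

    def test_90bp_partial_unzip_and_full_restore(self, traj90):
        """30 nm pull opens part of the duplex, never all of it, and the
        return leg reanneals every pair."""
        assert traj90.termination == "completed"
        assert traj90.n_open.max() > 0
        assert traj90.n_open.max() < 90
        assert traj90.n_open[-1] == 0
        assert traj90.n_duplex[-1] == 90

    def test_unzip_force_in_experimental_window(self, traj90):
        f = unzip_force_plateau(traj90)
        assert 10.0 <= f <= 50.0
        assert traj90.force.max() < 100.0  # << 1-2 nN Au-S rupture scale

    def test_uniform_duplex_force_matches_self_consistent_fixed_point(self):
        """For a uniform-energy duplex the unzipping force solves
        2 g_ss(f) = dG_bp; the KMC plateau matches within 15%."""
        dup = Duplex.from_sequence("A" * 90)
        p = ZipperParams()
        cost = dup.pair_opening_costs()[5] * KCAL_PER_MOL_TO_PN_NM

        def gibbs_gain(f):
            u = f * p.kuhn_length / KT300
            return (2 * p.contour_per_nt / p.kuhn_length * KT300
                    * math.log(math.sinh(u) / u)) - cost

        f_theory = brentq(gibbs_gain, 0.1, 200.0)
        traj = kmc_run(dup, p, Protocol(return_tip=False, hold_time=0.0,
                                        settle_time=0.0), seed=5)
        assert unzip_force_plateau(traj) == pytest.approx(f_theory, rel=0.15)

    def test_10bp_separates_under_30nm_pull(self):
        dup10 = Duplex.from_sequence(gen_sequence(10, 0.5, seed=2))
        for seed in range(5):
            traj = kmc_run(dup10, ZipperParams(), Protocol(), seed=seed)
            assert traj.termination == "strand_separation"
            assert traj.n_open[-1] == 10

    def test_release_protocol_also_reanneals(self, duplex90):
        traj = kmc_run(duplex90, ZipperParams(),
                       Protocol(return_tip=False, release_after_pull=True,
                                settle_time=0.5), seed=11)
        assert traj.n_open.max() > 0
        assert traj.n_open[-1] == 0

    def test_no_unzipping_phase_signalled(self, duplex90):
        traj = kmc_run(duplex90, ZipperParams(),
                       Protocol(pull_distance=0.0, hold_time=0.05,
                                return_tip=False), seed=0)
        if traj.n_open.max() == 0:
            with pytest.raises(ValueError):
                unzip_force_plateau(traj)

    def test_pair_state_record(self, duplex90):
        traj = kmc_run(duplex90, ZipperParams(),
                       Protocol(pull_distance=5.0, hold_time=0.0,
                                return_tip=False, settle_time=0.0),
                       seed=0, record_pair_state=True)
        k = len(traj.time) - 1
        bits = traj.pair_state[k]
        assert bits.count("1") == traj.n_open[k]
        assert np.array_equal(traj.pair_state_at(k),
                              np.array([c == "1" for c in bits]))

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            Protocol(return_tip=True, release_after_pull=True)
        with pytest.raises(ValueError):
            Protocol(pull_distance=-1.0)


class TestConductanceCoupling:
    def test_separated_strands_give_bare_tunnelling(self):
        g_sep = junction_conductance(0.2, 10, 10, intact=False)
        expect = 50.0 * math.exp(-22.0 * 0.2)
        assert g_sep == pytest.approx(expect)

    def test_intact_frame_gives_plateau_preset(self):
        assert junction_conductance(5.0, 30, 90) == pytest.approx(1.9)

    def test_simulated_trace_passes_plateau_filter(self, traj90):
        tr = set_displacement_origin(trace_from_trajectory(traj90))
        assert judge_plateau(tr).present
        assert dwell_length(tr, DWELL_90MER) > DWELL_90MER.threshold_nm
        cfgmap = ConductanceMap()
        assert tr.conductance.max() == pytest.approx(cfgmap.plateau_mg0 * 1e-3)

    def test_simulator_driven_series(self):
        """A short duplex that separates each cycle yields a series driven
        by rehybridization."""
        sp = SeriesGenParams(n_traces=4, mode="simulator-driven",
                             p_form=1.0, seed=0)
        dup = Duplex.from_sequence(gen_sequence(5, 0.5, seed=1))
        series = gen_simulated_series(
            sp, preset_trace("90mer"), duplex=dup,
            params=ZipperParams(),
            protocol=Protocol(pull_distance=12.0, hold_time=0.0,
                              settle_time=0.0, return_tip=False))
        assert len(series) == 4
        assert all("formed_truth" in tr.meta for tr in series)
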