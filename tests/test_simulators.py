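"""SSA simulators: rate plumbing, stationary moments, determinism."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from grnabc import units
from grnabc.core import make_parameters
from grnabc.simulators import (
    DEFAULT_REACTION_RADIUS,
    CompartmentRates,
    SimulationConfig,
    SimulationOverflowError,
    compartment_rates,
    effective_association_rate,
    simulate,
    simulate_cbm,
    simulate_wmm,
    without_feedback,
)


class TestEffectiveAssociationRate:
    def test_reaction_limited_at_high_diffusion(self):
        # D -> infinity: k_eff -> ka
        k = effective_association_rate(1e9, 1e9, DEFAULT_REACTION_RADIUS)
        assert k == pytest.approx(1e9, rel=1e-3)

    def test_harmonic_at_matched_rates(self):
        # sigma chosen so kD == ka at this D: k_eff = ka/2
        k = effective_association_rate(1e9, 0.6, DEFAULT_REACTION_RADIUS)
        assert k == pytest.approx(5e8, rel=1e-9)

    def test_unit_conversion_oracle(self):
        # 1e9 / (M min) corresponds to 1e9 * 1e15/NA um^3/min = 1.661 um^3/min
        assert units.per_molar_to_um3(1e9) == pytest.approx(1e9 * 1e15 / 6.022e23)
        # and the default radius is the Smoluchowski radius matching it at D=0.6
        kD = 4 * np.pi * DEFAULT_REACTION_RADIUS * 0.6
        assert units.um3_to_per_molar(kD) == pytest.approx(1e9, rel=1e-9)

    def test_bounded_by_both_rates_and_monotone_in_D(self):
        ks = [effective_association_rate(1e9, D, 0.22) for D in (0.01, 0.1, 1, 10)]
        assert all(np.diff(ks) > 0)
        for D, k in zip((0.01, 0.1, 1, 10), ks):
            kD = units.um3_to_per_molar(4 * np.pi * 0.22 * D)
            assert k <= min(1e9, kD) + 1e-6


class TestCompartmentRates:
    def test_base_point_closed_forms(self):
        rates = compartment_rates(0.6, 2.5, 6.0)
        assert rates.k_exit == pytest.approx(15 * 0.6 / 2.5**2)  # = 1.44
        assert rates.k_entry == pytest.approx(0.0602, abs=0.0005)

    def test_rates_linear_in_D(self):
        a = compartment_rates(0.3, 2.5, 6.0)
        b = compartment_rates(0.6, 2.5, 6.0)
        assert b.k_exit == pytest.approx(2 * a.k_exit)
        assert b.k_entry == pytest.approx(2 * a.k_entry)

    def test_geometry_validated(self):
        with pytest.raises(ValueError):
            compartment_rates(0.6, 6.0, 2.5)


class TestWMM:
    def test_open_loop_stationary_means(self):
        # without feedback the cascade is linear: E[mRNA]=mu/gamma=75,
        # E[P]=kappa*mu/gamma^2=1875; check within 3 SE over 32 trajectories
        p = without_feedback(make_parameters(1.0, 0.6))
        means = []
        for i in range(32):
            cfg = SimulationConfig(t_burn=500, n_samples=40, dt_sample=10, seed=900 + i)
            means.append(simulate_wmm(p, cfg).counts.mean(axis=0))
        means = np.array(means)
        for col, target in ((0, 75.0), (1, 1875.0)):
            m = means[:, col].mean()
            se = means[:, col].std(ddof=1) / np.sqrt(len(means))
            assert abs(m - target) < 3 * se + 1e-9, f"col {col}: {m} vs {target}"

    def test_open_loop_mrna_is_poisson(self):
        # stationary law of a linear birth-death process is Poisson(mu/gamma)
        p = without_feedback(make_parameters(1.0, 0.6))
        counts = []
        for i in range(24):
            cfg = SimulationConfig(t_burn=500, n_samples=10, dt_sample=50, seed=50 + i)
            counts.extend(simulate_wmm(p, cfg).counts[:, 0])
        counts = np.array(counts)
        lam = 75.0
        edges = [0, 62, 68, 72, 75, 78, 82, 88, np.inf]
        obs, _ = np.histogram(counts, bins=edges)
        probs = np.diff([stats.poisson.cdf(e - 1 if np.isfinite(e) else np.inf, lam) for e in edges])
        exp = probs * len(counts)
        chi2 = ((obs - exp) ** 2 / exp).sum()
        pval = stats.chi2.sf(chi2, df=len(obs) - 1)
        assert pval > 0.01, f"Poisson GOF rejected: p={pval}"

    def test_deterministic_replay(self):
        p = make_parameters(1.3, 0.9)
        cfg = SimulationConfig(t_burn=100, n_samples=20, dt_sample=5, seed=77)
        a = simulate_wmm(p, cfg)
        b = simulate_wmm(p, cfg)
        assert np.array_equal(a.counts, b.counts)

    def test_overflow_signals_not_truncates(self):
        p = make_parameters(16.0, 16.0)
        cfg = SimulationConfig(t_burn=200, n_samples=10, dt_sample=5, seed=1, count_cap=50)
        with pytest.raises(SimulationOverflowError):
            simulate_wmm(p, cfg)


class TestCBM:
    def test_deterministic_replay(self):
        p = make_parameters(0.8, 2.0)
        cfg = SimulationConfig(t_burn=100, n_samples=20, dt_sample=5, seed=5)
        assert np.array_equal(simulate_cbm(p, cfg).counts, simulate_cbm(p, cfg).counts)

    def test_hop_only_occupancy_matches_two_state_chain(self):
        # chemistry off, fixed molecules: nuclear occupancy k_entry/(k_entry+k_exit)
        from grnabc._ssa import ssa_mass_action

        rates = compartment_rates(0.6, 2.5, 6.0)
        stoich = np.array([[-1, 1], [1, -1]], dtype=np.int64)
        orders = np.array([[1, 0], [0, 1]], dtype=np.int64)
        cvec = np.array([rates.k_exit, rates.k_entry])
        x0 = np.array([100, 0], dtype=np.int64)
        times = 50.0 + 2.0 * np.arange(400)
        counts, status = ssa_mass_action(stoich, orders, cvec, x0, times, 3, 10**7)
        assert status == 0
        occ = counts[:, 0].mean() / 100.0
        expected = rates.k_entry / (rates.k_entry + rates.k_exit)
        assert occ == pytest.approx(expected, abs=0.015)

    @staticmethod
    def _open_loop_analytic(D, mu=3.0, kappa=1.0, gamma=0.04):
        """Stationary means of the open-loop (linear) compartment model.

        Transcription feeds the nuclear mRNA pool, translation only the
        cytoplasmic one, so the species means solve a linear system in the
        hop and degradation rates.
        """
        k = compartment_rates(D, 2.5, 6.0)
        A = np.array(
            [[-(k.k_exit + gamma), k.k_entry], [k.k_exit, -(k.k_entry + gamma)]]
        )
        m = np.linalg.solve(A, [-mu, 0.0])  # (m_nuc, m_cyt)
        p = np.linalg.solve(A, [0.0, -kappa * m[1]])  # protein born in cytoplasm
        return m.sum(), p.sum()

    def test_open_loop_matches_analytic_means_any_D(self):
        # no bimolecular step: the network is linear and its compartment
        # means are exactly solvable; total mRNA is mu/gamma at any D
        for D in (0.05, 4.0):
            m_target, p_target = self._open_loop_analytic(D)
            assert m_target == pytest.approx(75.0)
            p = without_feedback(make_parameters(1.0, D))
            means = []
            for i in range(24):
                cfg = SimulationConfig(t_burn=500, n_samples=30, dt_sample=10, seed=2000 + i)
                means.append(simulate_cbm(p, cfg).counts.mean(axis=0))
            means = np.array(means)
            for col, target in ((0, m_target), (1, p_target)):
                m = means[:, col].mean()
                se = means[:, col].std(ddof=1) / np.sqrt(len(means))
                assert abs(m - target) < 3.5 * se + 1e-9, f"D={D} col {col}: {m} vs {target}"


class TestDispatch:
    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            simulate("pde", make_parameters(1, 1), SimulationConfig(seed=0))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(dt_bd=1.0, dt_sample=5.0)  # dt_bd too coarse
        with pytest.raises(ValueError):
            SimulationConfig(n_samples=0)
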