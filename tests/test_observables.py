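"""Densities, quasi-potential, fate fractions, limit cycles, switching."""

import numpy as np
import pytest

from stemfate import (
    DensityGrid,
    FeedbackParams,
    SimulationConfig,
    SystemState,
    Trajectory,
    equilibria,
    fate_fractions,
    limit_cycle_summary,
    pdf_over_time,
    quasi_potential,
    simulate,
    simulate_ensemble,
    switching_report,
)
from stemfate.observables import default_basins


@pytest.fixture(scope="module")
def model1_ensemble(model1):
    """Scaled-down symmetry-breaking ensemble from the pluripotent high-noise start."""
    cfg = SimulationConfig(t_final=100.0, dt=1e-3, sigma=1e-4, n_traj=60, master_seed=11,
                           initial_state=SystemState(0.0, 1.5))
    return simulate_ensemble(model1, FeedbackParams(G=0.6, M=0.2), cfg)


@pytest.fixture(scope="module")
def model2_cycle_traj(model2):
    cfg = SimulationConfig(t_final=2500.0, dt=1e-3, sigma=0.0,
                           initial_state=SystemState(0.001, 1.5))
    return simulate(model2, FeedbackParams(G=0.05, M=0.68), cfg)


class TestDensity:
    def test_normalization_at_every_time_node(self, model1_ensemble):
        grid = pdf_over_time(model1_ensemble, t_nodes=np.array([0.0, 10.0, 50.0, 100.0]))
        dm = np.diff(grid.m_edges)
        for row in grid.density:
            assert np.sum(row * dm) == pytest.approx(1.0, abs=1e-9)

    def test_early_unimodal_late_bimodal(self, model1_ensemble):
        """Mass sits at m=0 early and near +-M late (spontaneous differentiation)."""
        grid = pdf_over_time(model1_ensemble, t_nodes=np.array([5.0, 100.0]))
        c = grid.m_centers
        early, late = grid.density
        assert abs(c[np.argmax(early)]) < 0.05
        dm = np.diff(grid.m_edges)
        assert np.sum(late[np.abs(np.abs(c) - 0.2) < 0.1] * dm[np.abs(np.abs(c) - 0.2) < 0.1]) > 0.95
        assert np.sum(late[np.abs(c) < 0.05] * dm[np.abs(c) < 0.05]) < 0.05

    def test_symmetric_model_density_symmetric(self, model1_ensemble):
        grid = pdf_over_time(model1_ensemble, t_nodes=np.array([100.0]))
        p = grid.density[0]
        dm = np.diff(grid.m_edges)
        # left/right mass within binomial sampling error of half
        right = np.sum((p * dm)[grid.m_centers > 0])
        assert abs(right - 0.5) <= 3 * np.sqrt(0.25 / len(model1_ensemble))

    def test_empty_ensemble_and_bad_nodes_rejected(self, model1_ensemble):
        with pytest.raises(ValueError):
            pdf_over_time(model1_ensemble, t_nodes=np.array([1e6]))


class TestQuasiPotential:
    def test_uniform_density_gives_flat_phi(self):
        edges = np.linspace(-1.0, 1.0, 11)
        k, dm = 10, 0.2
        grid = DensityGrid(m_edges=edges, t_nodes=np.array([0.0]),
                           density=np.full((1, k), 1.0 / (k * dm)))
        q = quasi_potential(grid)
        assert np.allclose(q.phi, np.log(k * dm))

    def test_argmin_phi_equals_argmax_density(self, model1_ensemble):
        grid = pdf_over_time(model1_ensemble, t_nodes=np.array([10.0, 100.0]))
        q = quasi_potential(grid)
        for p_row, phi_row in zip(grid.density, q.phi):
            assert np.nanargmin(phi_row) == np.argmax(p_row)

    def test_empty_bins_are_masked_not_imputed(self, model1_ensemble):
        grid = pdf_over_time(model1_ensemble, t_nodes=np.array([100.0]))
        q = quasi_potential(grid)
        assert np.isnan(q.phi[0][grid.density[0] == 0.0]).all()
        assert np.isfinite(q.phi[0][grid.density[0] > 0.0]).all()

    def test_late_time_landscape_has_two_wells(self, model1_ensemble):
        """The reconstructed landscape shows minima at the differentiated states."""
        grid = pdf_over_time(model1_ensemble, t_nodes=np.array([100.0]))
        q = quasi_potential(grid)
        c = q.m_centers
        phi = q.phi[0]
        left = np.nanmin(phi[(c < 0)])
        right = np.nanmin(phi[(c > 0)])
        c_left = c[c < 0][np.nanargmin(phi[c < 0])]
        c_right = c[c > 0][np.nanargmin(phi[c > 0])]
        assert abs(c_left + 0.2) < 0.1 and abs(c_right - 0.2) < 0.1
        assert np.isfinite(left) and np.isfinite(right)


class TestFateFractions:
    def test_fractions_sum_to_one_and_split_evenly(self, model1, model1_ensemble):
        eqs = equilibria(model1, FeedbackParams(G=0.6, M=0.2))
        fr = fate_fractions(model1_ensemble, eqs, radius=0.1, t_eval=100.0)
        assert sum(fr.values()) == pytest.approx(1.0, abs=1e-12)
        n = len(model1_ensemble)
        assert abs(fr["E_plus"] - 0.5) <= 3 * np.sqrt(0.25 / n)
        assert fr["undecided"] < 0.05

    def test_deterministic_identical_starts_one_label(self, model1):
        cfg = SimulationConfig(t_final=60.0, sigma=0.0, n_traj=3,
                               initial_state=SystemState(0.05, 1.2))
        ens = simulate_ensemble(model1, FeedbackParams(G=0.6, M=0.2), cfg)
        eqs = equilibria(model1, FeedbackParams(G=0.6, M=0.2))
        fr = fate_fractions(ens, eqs, radius=0.1, t_eval=60.0)
        assert fr["E_plus"] == 1.0 and fr["E_minus"] == 0.0

    def test_model3_noise_absorbs_into_E_minus(self, model3):
        """Finite-size noise drains the asymmetric model's m0/m+ cycle into the
        absorbing stable point E-: its share only grows, and E+ is never a
        terminal fate."""
        fb = FeedbackParams(G=0.2, M=0.35)
        cfg = SimulationConfig(t_final=2000.0, dt=1e-3, sigma=2e-4, n_traj=20, master_seed=5,
                               initial_state=SystemState(0.0, 1.5))
        ens = simulate_ensemble(model3, fb, cfg)
        eqs = equilibria(model3, fb)
        shares = [fate_fractions(ens, eqs, radius=0.1, t_eval=t)["E_minus"]
                  for t in (500.0, 1000.0, 1500.0, 2000.0)]
        assert all(b >= a for a, b in zip(shares, shares[1:]))  # absorbing
        assert shares[-1] > 0.5
        assert fate_fractions(ens, eqs, radius=0.1, t_eval=2000.0)["E_plus"] <= 0.05


class TestLimitCycle:
    def test_model2_cycle_detected_counterclockwise(self, model2_cycle_traj):
        lc = limit_cycle_summary(model2_cycle_traj)
        assert lc.is_cycle and lc.orientation == "counterclockwise"
        assert lc.period > 0 and lc.m_amplitude > 0.1
        assert lc.mean_point[0] > 0  # orbiting the E+ branch

    def test_model2_spiral_converges(self, model2):
        cfg = SimulationConfig(t_final=2500.0, dt=1e-3, sigma=0.0,
                               initial_state=SystemState(0.001, 1.5))
        tr = simulate(model2, FeedbackParams(G=0.05, M=0.71), cfg)
        lc = limit_cycle_summary(tr)
        assert not lc.is_cycle and lc.status == "ok"
        assert abs(tr.m[-1] - 0.71) < 0.05

    def test_orientation_flips_with_mirror_start(self, model2):
        cfg = SimulationConfig(t_final=2500.0, dt=1e-3, sigma=0.0,
                               initial_state=SystemState(-0.001, 1.5))
        tr = simulate(model2, FeedbackParams(G=0.05, M=0.68), cfg)
        lc = limit_cycle_summary(tr)
        assert lc.is_cycle and lc.orientation == "clockwise"
        assert lc.mean_point[0] < 0

    def test_detection_robust_to_dt_and_transient(self, model2, model2_cycle_traj):
        """Period/amplitude move < 2% under halving dt or doubling the discard."""
        ref = limit_cycle_summary(model2_cycle_traj, transient_fraction=0.4)
        longer = limit_cycle_summary(model2_cycle_traj, transient_fraction=0.8)
        cfg = SimulationConfig(t_final=2500.0, dt=5e-4, sigma=0.0, record_stride=200,
                               initial_state=SystemState(0.001, 1.5))
        fine = limit_cycle_summary(simulate(model2, FeedbackParams(G=0.05, M=0.68), cfg),
                                   transient_fraction=0.4)
        for other in (longer, fine):
            assert other.is_cycle
            assert other.period == pytest.approx(ref.period, rel=0.02)
            assert other.m_amplitude == pytest.approx(ref.m_amplitude, rel=0.02)

    def test_oscillation_shorter_than_five_periods_undetermined(self):
        t = np.arange(0.0, 25.0, 0.1)
        m = 0.3 * np.sin(2 * np.pi * t / 10.0)  # only ~2.5 periods
        tr = Trajectory(times=t, m=m, xi=np.ones_like(t), seed=0)
        assert limit_cycle_summary(tr, transient_fraction=0.0).status == "undetermined"


class TestSwitching:
    def _traj(self, m_values, dt=0.1):
        m = np.asarray(m_values, dtype=float)
        return Trajectory(times=np.arange(len(m)) * dt, m=m, xi=np.zeros_like(m), seed=0)

    def test_counts_and_dwells_on_synthetic_path(self):
        tr = self._traj([0.0, 0.0, 1.0, 1.0, 1.0, 0.0, -1.0, -1.0])
        rep = switching_report(tr, {"m0": (-0.2, 0.2), "p": (0.8, 1.2), "n": (-1.2, -0.8)})
        assert rep.transition_count == 3
        assert rep.dwell_times["m0"] == [pytest.approx(0.2), pytest.approx(0.1)]
        assert rep.dwell_times["p"] == [pytest.approx(0.3)]
        assert rep.dwell_times["n"] == [pytest.approx(0.2)]

    def test_hysteretic_labels_suppress_boundary_chatter(self):
        """Oscillation inside the unlabeled gap keeps the previous label."""
        tr = self._traj([1.0, 0.5, 0.7, 0.4, 0.6, 1.0, 0.0])
        rep = switching_report(tr, {"m0": (-0.2, 0.2), "p": (0.9, 1.2)})
        assert rep.transition_count == 1
        assert list(rep.labels) == ["p"] * 6 + ["m0"]

    def test_overlapping_basins_rejected(self):
        tr = self._traj([0.0, 1.0])
        with pytest.raises(ValueError):
            switching_report(tr, {"a": (-0.5, 0.5), "b": (0.4, 1.0)})

    def test_default_basins_are_disjoint(self):
        basins = default_basins([-0.2, 0.0, 0.2])
        vals = sorted(basins.values())
        for (lo1, hi1), (lo2, hi2) in zip(vals, vals[1:]):
            assert hi1 < lo2

    def test_model2_hybrid_state_cycles_through_pluripotent_basin(self, model2):
        """Large-amplitude cycle + noise: repeated m0 <-> m+/- transitions, and
        both differentiated basins reached across an ensemble."""
        basins = {"m0": (-0.25, 0.25), "m_plus": (0.75, 1.4), "m_minus": (-1.4, -0.75)}
        visited = set()
        for seed in (0, 1):
            cfg = SimulationConfig(t_final=2000.0, dt=1e-3, sigma=2e-4, master_seed=seed,
                                   initial_state=SystemState(0.0, 1.5))
            tr = simulate(model2, FeedbackParams(G=0.05, M=0.5), cfg)
            rep = switching_report(tr, basins)
            assert rep.transition_count > 20
            visited |= {l for l in rep.labels if l is not None}
        assert "m0" in visited and ("m_plus" in visited and "m_minus" in visited)

    def test_model3_dwells_longer_near_pluripotent_state(self, model3):
        """On the big asymmetric cycle the slow mode at m0 outlasts the one at m+."""
        cfg = SimulationConfig(t_final=400.0, dt=1e-3, sigma=0.0,
                               initial_state=SystemState(0.001, 1.5))
        tr = simulate(model3, FeedbackParams(G=0.2, M=0.35), cfg)
        rep = switching_report(tr, {"m0": (-0.2, 0.2), "m_plus": (0.8, 1.6)})
        assert rep.mean_dwell("m0") > 2 * rep.mean_dwell("m_plus")
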