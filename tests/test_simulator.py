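import numpy as np
import pytest

from riboflux.simulate import (
    SimConfig,
    SimulationError,
    measure_true_codon_times,
    measure_true_synthesis_time,
    simulate_runoff,
    simulate_steady_state,
    step_kinetics,
)
from riboflux import _kernels
from ._oracles import stationary_occupancy
from .conftest import make_model


class TestStepKinetics:
    def test_absorbing_state_reported(self):
        m = make_model(alpha=0.0)
        state, dt = step_kinetics([], m, np.random.default_rng(0))
        assert len(state) == 0 and np.isinf(dt)

    def test_single_ribosome_mean_waiting_time(self):
        m = make_model(omega=5.0)
        rng = np.random.default_rng(1)
        m.alpha = 0.0  # only the hop is enabled
        waits = [step_kinetics([50], m, rng)[1] for _ in range(4000)]
        assert np.mean(waits) == pytest.approx(1 / 5.0, rel=0.05)

    def test_excluded_volume_blocks_trailing_hop(self):
        # A-sites at 5 and 15 with ell=10: 5 -> 6 is disabled (15 = 5+ell)
        m = make_model(n_codons=20, alpha=0.5, ell=10)
        rng = np.random.default_rng(2)
        for _ in range(200):
            new, _ = step_kinetics([5, 15], m, rng)
            assert 5 in new  # trailing ribosome never moved
            assert list(new) in ([5, 15], [5, 16])  # initiation also blocked


class TestSteadyState:
    def test_alpha_zero_gives_empty_profile(self):
        m = make_model(alpha=0.0)
        snap, prof = simulate_steady_state(m, SimConfig(seed=1, target_reads=100))
        assert prof.total_reads == 0

    def test_fixed_seed_bit_identical(self):
        m = make_model(alpha=0.2)
        cfg = SimConfig(seed=7, target_reads=2000)
        s1, p1 = simulate_steady_state(m, cfg)
        s2, p2 = simulate_steady_state(m, cfg)
        assert np.array_equal(p1.counts, p2.counts)
        assert np.array_equal(s1.positions, s2.positions)
        assert np.array_equal(s1.offsets, s2.offsets)

    def test_snapshots_respect_excluded_volume(self):
        m = make_model(alpha=0.5, omega=3.0)
        snap, _ = simulate_steady_state(m, SimConfig(seed=3, target_reads=5000))
        snap.validate()  # asserts pairwise A-site gaps >= ell

    def test_occupancy_matches_master_equation(self):
        """Small-instance equivalence with the exact stationary solution."""
        nc, ell = 20, 3
        omega = np.full(nc - 1, 10.0)
        m = make_model(n_codons=nc, omega=omega, alpha=0.5, beta=35.0, ell=ell)
        rho_exact = stationary_occupancy(nc, ell, m.alpha, omega, m.beta)
        snap, _ = simulate_steady_state(m, SimConfig(seed=11, target_reads=300_000))
        n = snap.n_snapshots
        rho_sim = snap.counts() / n
        # batch-means standard error (snapshots are weakly correlated)
        n_batches = 20
        edges = np.linspace(0, n, n_batches + 1).astype(int)
        batches = np.array(
            [
                np.bincount(
                    snap.positions[snap.offsets[a] : snap.offsets[b]] - 1,
                    minlength=nc,
                )
                / (b - a)
                for a, b in zip(edges[:-1], edges[1:])
            ]
        )
        se = batches.std(axis=0, ddof=1) / np.sqrt(n_batches)
        assert np.all(np.abs(rho_sim - rho_exact) <= 3 * se + 1e-4)

    def test_flux_equal_across_positions(self):
        m = make_model(n_codons=60, alpha=0.3, omega=8.0)
        snap, _ = simulate_steady_state(m, SimConfig(seed=5, target_reads=100_000))
        d = snap.flux_diagnostics
        flux = d["hop_counts"] / d["sampling_time"]
        assert flux.std() / flux.mean() < 0.05

    def test_initiation_flux_matches_first_order_relation(self):
        """Measured initiations/time ~ alpha * (1 - sum rho(2..ell+1))."""
        m = make_model(alpha=0.05, omega=5.0)
        snap, _ = simulate_steady_state(m, SimConfig(seed=9, target_reads=100_000))
        d = snap.flux_diagnostics
        rho = snap.counts() / snap.n_snapshots
        predicted = m.alpha * (1 - rho[1 : m.ell + 1].sum())
        measured = d["n_initiations"] / d["sampling_time"]
        assert measured == pytest.approx(predicted, rel=0.10)


class TestRunoff:
    def test_dt_zero_reproduces_steady_profile(self):
        m = make_model(alpha=0.2)
        cfg = SimConfig(seed=13, target_reads=3000)
        series = simulate_runoff([m], cfg)
        prof0 = series.profiles[0.0][m.gene_id]
        assert prof0.total_reads >= 3000

    def test_large_dt_clears_5prime_density(self):
        m = make_model(n_codons=101, alpha=0.3, omega=5.0)
        cfg = SimConfig(seed=17, target_reads=3000, runoff_dts=(0.0, 200.0))
        series = simulate_runoff([m], cfg)
        late = series.profiles[200.0][m.gene_id]
        assert late.counts[:90].sum() == 0

    def test_single_ribosome_advances_at_omega(self):
        """Mean A-site displacement after dt is omega*dt (Poisson hops)."""
        nc, ell, w, dt = 400, 10, 5.0, 20.0
        omega = np.full(nc - 1, w)
        n_rep = 400
        offsets = np.arange(n_rep + 1, dtype=np.int64)
        starts = np.full(n_rep, 50, dtype=np.int32)
        counts, status = _kernels.runoff_kernel(
            omega, 35.0, ell, offsets, starts, np.array([dt]), 10**9, 123
        )
        assert status == _kernels.STATUS_OK
        positions = np.repeat(np.arange(1, nc + 1), counts[0])
        expected = 50 + w * dt
        se = np.sqrt(w * dt / n_rep)
        assert abs(positions.mean() - expected) < 4 * se


class TestTimeMeasurements:
    def test_single_ribosome_synthesis_time_closed_form(self):
        """alpha -> 0: <T> = sum 1/omega + 1/beta = 20.03 s for this model."""
        m = make_model(n_codons=101, omega=5.0, alpha=0.001, beta=35.0)
        t, se = measure_true_synthesis_time(m, n_ribosomes=3000, seed=1)
        assert t == pytest.approx(100 / 5.0 + 1 / 35.0, abs=4 * se)

    def test_crowding_only_delays(self):
        m_lo = make_model(alpha=0.005, omega=5.0)
        m_hi = make_model(alpha=0.45, omega=5.0)
        t_lo, _ = measure_true_synthesis_time(m_lo, 2000, seed=2)
        t_hi, _ = measure_true_synthesis_time(m_hi, 2000, seed=3)
        assert t_hi >= t_lo

    def test_dwell_times_exceed_intrinsic(self):
        m = make_model(n_codons=60, alpha=0.4, omega=6.0)
        dwell = measure_true_codon_times(m, min_passages=4000, seed=4)
        # in expectation dwell(j) >= 1/omega(j); allow Monte-Carlo slack
        assert np.all(dwell[:-1] >= 1 / m.omega * 0.97)

    def test_dwell_sum_matches_synthesis_time(self):
        m = make_model(n_codons=80, alpha=0.2, omega=7.0)
        dwell = measure_true_codon_times(m, min_passages=4000, seed=5)
        t, se = measure_true_synthesis_time(m, 4000, seed=6)
        assert dwell.sum() == pytest.approx(t, rel=0.02)

    def test_alpha_zero_rejected(self):
        m = make_model(alpha=0.0)
        with pytest.raises(SimulationError):
            measure_true_synthesis_time(m, 10, seed=1)
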