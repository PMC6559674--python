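import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from riboflux.initiation import (
    InitiationError,
    calibrate_xi,
    estimate_initiation,
    filter_initiation_genes,
    occupancy_from_experiment,
    occupancy_from_snapshots,
    synthesis_time_scaling,
)
from riboflux.model import FootprintProfile, OccupancyProfile, SnapshotSet
from riboflux.simulate import SimConfig, simulate_steady_state
from .conftest import make_model


class TestSynthesisTimeScaling:
    @pytest.mark.parametrize(
        "nc,tau_a,expected", [(500, 0.2, 100.0), (1, 0.37, 0.37), (400, 0.2, 80.0)]
    )
    def test_scaling_relation(self, nc, tau_a, expected):
        assert synthesis_time_scaling(nc, tau_a) == pytest.approx(expected)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(InitiationError):
            synthesis_time_scaling(100, 0.0)


class TestCalibration:
    def test_exact_proportionality(self):
        te = pd.Series(np.arange(1.0, 13.0), index=[f"g{i}" for i in range(12)])
        fit = calibrate_xi(te, 2.0 * te)
        assert fit.xi == pytest.approx(2.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_outlier_shifts_by_closed_form(self):
        # through-origin slope is sum(xy)/sum(x^2); verified on a toy table
        x = np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 9, 10, 4.0])
        y = np.append(2.0 * x[:-1], 20.0)  # one outlier
        te = pd.Series(x, index=[f"g{i}" for i in range(11)])
        load = pd.Series(y, index=te.index)
        assert calibrate_xi(te, load).xi == pytest.approx(np.sum(x * y) / np.sum(x * x))

    def test_disjoint_gene_sets_error(self):
        te = pd.Series([1.0] * 12, index=[f"a{i}" for i in range(12)])
        load = pd.Series([1.0] * 12, index=[f"b{i}" for i in range(12)])
        with pytest.raises(InitiationError):
            calibrate_xi(te, load)


class TestOccupancy:
    def test_uniform_counts_split_load_evenly(self):
        counts = np.full(101, 7)
        occ = occupancy_from_experiment(
            FootprintProfile("g", counts), ribosome_load=1.0
        )
        assert np.allclose(occ.rho[1:], 0.01)
        assert occ.rho[0] == 0.0  # start codon excluded from apportionment
        assert occ.mean_rho == pytest.approx(1.0 / 100)

    def test_zero_load_gives_zero_occupancy(self):
        occ = occupancy_from_experiment(
            FootprintProfile("g", np.full(50, 3)), ribosome_load=0.0
        )
        assert occ.rho.sum() == 0.0

    def test_overfull_profile_flagged(self):
        counts = np.zeros(40, dtype=int)
        counts[5] = 100
        occ = occupancy_from_experiment(FootprintProfile("g", counts), ribosome_load=2.0)
        assert occ.flagged

    def test_snapshot_frequency(self):
        confs = [[7]] * 3 + [[]] * 7
        snaps = SnapshotSet.from_configurations("g", confs, n_codons=20, ell=10)
        occ = occupancy_from_snapshots(snaps)
        assert occ.rho[6] == pytest.approx(0.3)

    def test_experimental_route_consistent_with_snapshots(self):
        """Apportioning the snapshot-derived per-mRNA load along the read
        profile reproduces the direct snapshot occupancy."""
        m = make_model(alpha=0.25, omega=6.0)
        snap, prof = simulate_steady_state(m, SimConfig(seed=21, target_reads=40_000))
        direct = occupancy_from_snapshots(snap)
        load = prof.counts[1:].sum() / snap.n_snapshots
        via_counts = occupancy_from_experiment(prof, ribosome_load=load)
        assert np.allclose(via_counts.rho[1:], direct.rho[1:], atol=1e-12)


class TestEstimateInitiation:
    def test_plugin_example(self):
        """Nc=101, rho=0.01 everywhere, ell=10, T=20 s -> 1/18 per s."""
        rho = np.full(101, 0.01)
        rho[0] = 0.0
        occ = OccupancyProfile("g", rho)
        est = estimate_initiation(occ, t_mean=20.0, ell=10)
        assert est.alpha_hat == pytest.approx((0.01 * 100) / (20 * 0.90), rel=1e-12)

    def test_zero_occupancy_gives_zero_alpha(self):
        occ = OccupancyProfile("g", np.zeros(50))
        assert estimate_initiation(occ, 10.0, 10).alpha_hat == 0.0

    def test_blocked_regime_raises(self):
        rho = np.zeros(50)
        rho[1:11] = 0.1  # start region fully occupied on average
        with pytest.raises(InitiationError, match="initiation-blocked"):
            estimate_initiation(OccupancyProfile("g", rho), 10.0, 10)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        mean=st.floats(0.001, 0.02),
        scale=st.floats(1.1, 3.0),
        t1=st.floats(5.0, 50.0),
        t2=st.floats(51.0, 500.0),
    )
    def test_monotone_in_density_and_time(self, mean, scale, t1, t2):
        """alpha-hat increases with occupancy and decreases with <T>."""
        rho = np.full(60, mean)
        rho[0] = 0.0
        occ_lo = OccupancyProfile("g", rho)
        occ_hi = OccupancyProfile("g", np.clip(rho * scale, 0, 1))
        assert (
            estimate_initiation(occ_hi, t1, 10).alpha_hat
            > estimate_initiation(occ_lo, t1, 10).alpha_hat
        )
        assert (
            estimate_initiation(occ_lo, t2, 10).alpha_hat
            < estimate_initiation(occ_lo, t1, 10).alpha_hat
        )


class TestFiltering:
    def _profile(self, n_zero, flags=None):
        counts = np.ones(100, dtype=int)
        counts[:n_zero] = 0
        return FootprintProfile("g", counts, **(flags or {}))

    def test_boundary_inclusive_at_95_percent(self):
        assert filter_initiation_genes([self._profile(5)])  # exactly 95% kept
        assert not filter_initiation_genes([self._profile(6)])

    def test_flagged_genes_dropped(self):
        assert not filter_initiation_genes(
            [self._profile(0, {"multimap_excluded": True})]
        )
        assert not filter_initiation_genes([self._profile(0, {"has_intron": True})])
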