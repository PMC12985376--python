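"""Lattice extrusion: movement rules, exclusion, CTCF, diffusion, metrics."""

import numpy as np
import pytest

import burstex as bx
from burstex.lattice import (
    CTCFConfig,
    DiffusionConfig,
    ExtrusionTrajectory,
    LatticeConfig,
    condensation_metrics,
    kymograph,
    simulate,
)
from burstex.measurements import MeasurementSet, ProteinMeasurement
from burstex.network import ConfigurationError
from burstex.topology import CohesinState as S, enumerate_cycles

from conftest import assert_exclusion

TINY = 1e-7


@pytest.fixture(scope="module")
def rich_pools():
    """Measurement set with abundant regulators, so mean-field pools stay
    large even when the whole cohesin population is bound."""
    return MeasurementSet(
        {
            "RAD21": ProteinMeasurement("RAD21", 100_000, 0.65, 822.0),
            "NIPBL": ProteinMeasurement("NIPBL", 500_000, 0.40, 72.0),
            "PDS5": ProteinMeasurement("PDS5", 500_000, 0.45, 70.0),
            "WAPL": ProteinMeasurement("WAPL", 500_000, 0.35, 45.0),
        }
    )


def pinned_rates(topology, load_key, load_rate=0.01):
    """Rates that load quickly and then freeze the entry state."""
    rates = {t.key: TINY for t in topology.transitions}
    rates[load_key] = load_rate
    return bx.RateSet(rates)


@pytest.fixture(scope="module")
def active_topo():
    """NIPBL-first cycle: loaded extruders stay in the active RN state."""
    return next(c for c in enumerate_cycles() if c.name == "RN-R-RP-RW")


@pytest.fixture(scope="module")
def passive_topo():
    """Bare-first cycle: loaded extruders stay in the passive R state."""
    return next(c for c in enumerate_cycles() if c.name == "R-RN-RP-RW")


class TestMovementRules:
    def test_pinned_active_extruder_grows_two_sites_per_step(
        self, rich_pools, active_topo
    ):
        rates = pinned_rates(active_topo, "free->RN")
        cfg = LatticeConfig(
            n_sites=400, n_chains=1, duration_steps=150, record_every=1,
            n_extruders=1, seed=3,
        )
        traj = simulate(cfg, active_topo, rates, rich_pools)
        legs = traj.legs[:, 0, :]
        loaded = np.flatnonzero(legs[:, 0] >= 0)
        assert len(loaded) > 20, "extruder never loaded"
        t0 = loaded[0]
        for t in range(t0, len(legs) - 1):
            l0, r0 = legs[t]
            l1, r1 = legs[t + 1]
            interior = l0 > 0 and r0 < cfg.n_sites - 1
            if interior:
                assert (r1 - l1) - (r0 - l0) == 2
            else:  # legs at chain ends stop there
                assert l1 == max(l0 - 1, 0) and r1 <= cfg.n_sites - 1

    def test_converging_extruders_stall_without_bypass(self, rich_pools, active_topo):
        rates = pinned_rates(active_topo, "free->RN")
        cfg = LatticeConfig(
            n_sites=80, n_chains=1, duration_steps=300, record_every=1,
            n_extruders=2, seed=9,
        )
        traj = simulate(cfg, active_topo, rates, rich_pools)
        assert_exclusion(traj)
        # relative order of all four legs never changes while both loaded
        both = (traj.legs[:, :, 0] >= 0).all(axis=1)
        orders = []
        for t in np.flatnonzero(both):
            flat = [(traj.legs[t, i, j], (i, j)) for i in range(2) for j in range(2)]
            orders.append(tuple(tag for _, tag in sorted(flat)))
        assert len(set(orders)) == 1

    def test_wt_run_respects_exclusion(self, hela, selected):
        topo, rates = selected
        cfg = LatticeConfig(
            n_sites=600, n_chains=2, duration_steps=1500, burnin_steps=1000,
            record_every=3, seed=21,
        )
        traj = simulate(cfg, topo, rates, hela)
        assert traj.n_extruders > 10
        assert_exclusion(traj)


class TestChemistry:
    def test_movement_does_not_feed_back_on_chemistry(self, hela, selected):
        """With the same seed, disabling movement leaves the chemical state
        series bit-identical (movement uses a separate random stream)."""
        topo, rates = selected
        kwargs = dict(
            n_sites=2000, n_chains=2, duration_steps=800, record_every=1, seed=5
        )
        with_move = simulate(LatticeConfig(**kwargs), topo, rates, hela)
        without = simulate(
            LatticeConfig(movement_enabled=False, **kwargs), topo, rates, hela
        )
        assert with_move.deferred_loads == 0
        np.testing.assert_array_equal(with_move.states, without.states)

    def test_active_fraction_matches_network_oracle(self, hela, selected, wt_steady):
        """Time-averaged fraction of loaded extruders in RN matches the
        steady-state ratio within 3 SE (batch means over time)."""
        topo, rates = selected
        cfg = LatticeConfig(
            n_sites=1000, n_chains=2, duration_steps=4500, burnin_steps=2500,
            record_every=3, seed=13,
        )
        traj = simulate(cfg, topo, rates, hela)
        i_rn = traj.states_order.index(S.NIPBL_BOUND)
        loaded = traj.legs[:, :, 0] >= 0
        active = (traj.states == i_rn) & loaded
        ratio_t = active.sum(axis=1) / np.maximum(loaded.sum(axis=1), 1)
        n_batches = 15
        batches = np.array_split(ratio_t, n_batches)
        means = np.array([b.mean() for b in batches])
        se = means.std(ddof=1) / np.sqrt(n_batches)
        assert abs(ratio_t.mean() - wt_steady.active_to_loaded_ratio) < 3 * se + 1e-3


class TestKymograph:
    def test_always_active_trace_has_unit_slopes(self, rich_pools, active_topo):
        rates = pinned_rates(active_topo, "free->RN")
        cfg = LatticeConfig(
            n_sites=500, n_chains=1, duration_steps=120, record_every=1,
            n_extruders=1, seed=17,
        )
        traj = simulate(cfg, active_topo, rates, rich_pools)
        kym = kymograph(traj, 0)
        loaded = np.flatnonzero(kym.left >= 0)
        t0 = loaded[0]
        dl = np.diff(kym.left[t0:])
        dr = np.diff(kym.right[t0:])
        interior = (kym.left[t0:-1] > 0) & (kym.right[t0:-1] < cfg.n_sites - 1)
        assert np.array_equal(dl[interior], -np.ones(interior.sum()))
        assert np.array_equal(dr[interior], np.ones(interior.sum()))

    def test_never_active_trace_is_flat(self, rich_pools, passive_topo):
        rates = pinned_rates(passive_topo, "free->R")
        cfg = LatticeConfig(
            n_sites=500, n_chains=1, duration_steps=120, record_every=1,
            n_extruders=1, seed=19,
        )
        traj = simulate(cfg, passive_topo, rates, rich_pools)
        kym = kymograph(traj, 0)
        loaded = np.flatnonzero(kym.left >= 0)
        assert len(loaded) > 5
        assert len(np.unique(kym.left[loaded])) == 1
        assert len(np.unique(kym.right[loaded])) == 1

    def test_unknown_extruder_rejected(self, rich_pools, active_topo):
        rates = pinned_rates(active_topo, "free->RN")
        cfg = LatticeConfig(n_sites=100, n_chains=1, duration_steps=10, n_extruders=1)
        traj = simulate(cfg, active_topo, rates, rich_pools)
        with pytest.raises(IndexError):
            kymograph(traj, 5)

    def test_wt_translocation_rate_matches_closed_form(self, hela, selected, wt_steady):
        """Pooled per-lifetime translocation over unobstructed loading
        windows reproduces v = 2L/tau * [RN]/[R]_loaded."""
        topo, rates = selected
        cfg = LatticeConfig(
            n_sites=20_000, n_chains=1, duration_steps=7000, record_every=1,
            n_extruders=10, seed=23,
        )
        traj = simulate(cfg, topo, rates, hela)
        i_rn = traj.states_order.index(S.NIPBL_BOUND)
        L, dt = cfg.site_size_bp, cfg.timestep_s
        growth, duration = [], []
        for i in range(traj.n_extruders):
            left = traj.legs[:, i, 0]
            right = traj.legs[:, i, 1]
            loaded = left >= 0
            # complete windows strictly inside the record
            edges = np.flatnonzero(np.diff(loaded.astype(int)))
            starts = [e + 1 for e in edges if not loaded[e]]
            ends = [e for e in edges if loaded[e]]
            for s0 in starts:
                e0 = next((e for e in ends if e >= s0), None)
                if e0 is None:
                    continue
                seg = slice(s0, e0 + 1)
                if left[seg].min() <= 0 or right[seg].max() >= cfg.n_sites - 1:
                    continue
                # discard windows with a blocked active step (collision)
                act = traj.states[s0 + 1 : e0 + 1, i] == i_rn
                dsize = np.diff(right[seg] - left[seg])
                if (act & (dsize != 2)).any():
                    continue
                growth.append((right[e0] - left[e0] - 1) * L)
                duration.append((e0 - s0) * dt)
        growth, duration = np.array(growth, float), np.array(duration, float)
        assert len(growth) >= 20
        rate = growth.sum() / duration.sum()
        v = bx.mean_extrusion_rate(wt_steady, L, dt)
        se = np.sqrt(np.sum((growth - rate * duration) ** 2)) / duration.sum()
        assert abs(rate - v) < 3 * se


class TestCondensationMetrics:
    def _fake_traj(self, legs_frame, n_sites, n_chains=1):
        legs = np.asarray(legs_frame, dtype=np.int32)[None, :, :]
        states = np.zeros((1, legs.shape[1]), dtype=np.uint8)
        cfg = LatticeConfig(n_sites=n_sites, n_chains=n_chains, duration_steps=1)
        return ExtrusionTrajectory(
            times_s=np.zeros(1), legs=legs, states=states,
            states_order=(S.FREE,), config=cfg, seed=0,
        )

    def test_single_extruder_conventions(self):
        traj = self._fake_traj([(10, 20)], 100)
        m = condensation_metrics(traj)
        assert m["loop_coverage"] == pytest.approx(11 / 100)
        assert m["collided_fraction"] == 0.0
        assert m["percolation_score"] == 0.0

    def test_no_loaded_extruder_gives_zeros(self):
        traj = self._fake_traj([(-1, -1)], 100)
        assert condensation_metrics(traj) == {
            "loop_coverage": 0.0, "collided_fraction": 0.0, "percolation_score": 0.0,
        }

    def test_fully_tiled_lattice_percolates(self):
        legs = [(2 * i, 2 * i + 1) for i in range(50)]
        traj = self._fake_traj(legs, 100)
        m = condensation_metrics(traj)
        assert m["loop_coverage"] == 1.0
        assert m["collided_fraction"] == 1.0
        assert m["percolation_score"] == 1.0

    def test_random_placement_matches_brute_force(self):
        """collided_fraction equals a direct O(N^2) adjacency count."""
        rng = np.random.default_rng(31)
        n_sites = 600
        for _ in range(5):
            sites = rng.choice(n_sites, size=60, replace=False)
            sites.sort()
            legs = [(int(sites[2 * i]), int(sites[2 * i + 1])) for i in range(30)]
            traj = self._fake_traj(legs, n_sites)
            m = condensation_metrics(traj)
            collided = set()
            for i, (li, ri) in enumerate(legs):
                for j, (lj, rj) in enumerate(legs):
                    if i == j:
                        continue
                    for a in (li, ri):
                        for b in (lj, rj):
                            if abs(a - b) == 1:
                                collided.add(i)
            assert m["collided_fraction"] == pytest.approx(len(collided) / 30)

    def test_chain_boundary_is_not_adjacency(self):
        """Legs on the last site of one chain and the first of the next
        are not collided."""
        traj = self._fake_traj([(48, 49), (50, 51)], 50, n_chains=2)
        m = condensation_metrics(traj)
        assert m["collided_fraction"] == 0.0


class TestCTCF:
    def test_occupancy_reproduces_bound_fraction(self, hela, selected):
        topo, rates = selected
        positions = tuple(range(50, 1000, 50))
        cfg = LatticeConfig(
            n_sites=1000, n_chains=1, duration_steps=4000, record_every=2, seed=37,
            ctcf=CTCFConfig(positions=positions, bound_fraction=0.6, residence_time_s=30.0),
        )
        traj = simulate(cfg, topo, rates, hela)
        occ_t = traj.ctcf_occupancy.mean(axis=1)
        batches = np.array_split(occ_t, 15)
        means = np.array([b.mean() for b in batches])
        se = means.std(ddof=1) / np.sqrt(len(batches))
        assert abs(occ_t.mean() - 0.6) < 3 * se + 1e-3

    def test_occupied_sites_block_active_legs(self, rich_pools, active_topo):
        """No active leg ever steps onto an occupied CTCF site (bypass 0)."""
        rates = pinned_rates(active_topo, "free->RN")
        positions = (100, 200, 300)
        cfg = LatticeConfig(
            n_sites=400, n_chains=1, duration_steps=400, record_every=1,
            n_extruders=4, seed=41,
            ctcf=CTCFConfig(positions=positions, bound_fraction=0.7,
                            residence_time_s=200.0, bypass_probability=0.0),
        )
        traj = simulate(cfg, active_topo, rates, rich_pools)
        pos_idx = {g: j for j, g in enumerate(positions)}
        for t in range(1, len(traj.times_s)):
            for i in range(traj.n_extruders):
                for leg in (0, 1):
                    g = traj.legs[t, i, leg]
                    prev = traj.legs[t - 1, i, leg]
                    if g in pos_idx and prev >= 0 and abs(g - prev) == 1:
                        assert not traj.ctcf_occupancy[t, pos_idx[g]], (
                            f"leg moved onto occupied CTCF site {g} at frame {t}"
                        )

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            CTCFConfig(positions=(10,), bound_fraction=1.5)
        with pytest.raises(ConfigurationError):
            CTCFConfig(positions=(10, 20), orientations=(1,))


class TestDiffusion:
    def test_tandem_mode_preserves_loop_size(self, rich_pools, passive_topo):
        rates = pinned_rates(passive_topo, "free->R")
        cfg = LatticeConfig(
            n_sites=2000, n_chains=1, duration_steps=600, record_every=1,
            n_extruders=5, seed=43,
            diffusion=DiffusionConfig(D_kb2_s=0.4, mode="tandem"),
        )
        traj = simulate(cfg, passive_topo, rates, rich_pools)
        assert_exclusion(traj)
        moved = 0
        for i in range(traj.n_extruders):
            left = traj.legs[:, i, 0]
            loaded = left >= 0
            if loaded.sum() < 10:
                continue
            sizes = traj.legs[loaded, i, 1] - left[loaded]
            assert len(np.unique(sizes)) == 1  # loop size frozen
            moved += len(np.unique(left[loaded])) > 1
        assert moved >= 1  # but the extruders do slide

    def test_independent_mode_leg_msd(self, rich_pools, passive_topo):
        """Sparse passive extruders: outer-leg displacement variance grows
        like an unbiased +-1 walk with per-direction hop probability p."""
        rates = pinned_rates(passive_topo, "free->R", load_rate=0.05)
        diff = DiffusionConfig(D_kb2_s=0.4, mode="independent")
        cfg = LatticeConfig(
            n_sites=3000, n_chains=1, duration_steps=700, record_every=1,
            n_extruders=30, seed=47, diffusion=diff,
        )
        traj = simulate(cfg, passive_topo, rates, rich_pools)
        assert_exclusion(traj)
        p = diff.hop_probability(cfg.site_size_bp, cfg.timestep_s)
        horizon = 300
        disps = []
        for i in range(traj.n_extruders):
            left = traj.legs[:, i, 0]
            loaded = np.flatnonzero(left >= 0)
            if len(loaded) < horizon + 1:
                continue
            t0 = loaded[0]
            disps.append(left[t0 + horizon] - left[t0])
        disps = np.array(disps, float)
        assert len(disps) >= 15
        expected_var = 2 * p * horizon
        # loose band: loop-shrink rejections suppress inward hops slightly
        assert 0.4 * expected_var < disps.var(ddof=1) < 1.8 * expected_var

    def test_out_of_range_coefficient_rejected(self):
        with pytest.raises(ConfigurationError):
            DiffusionConfig(D_kb2_s=0.8)


class TestTrajectoryIO:
    def test_h5_round_trip(self, hela, selected, tmp_path):
        topo, rates = selected
        cfg = LatticeConfig(
            n_sites=200, n_chains=2, duration_steps=100, record_every=5, seed=51,
            ctcf=CTCFConfig(positions=(20, 120)),
            diffusion=DiffusionConfig(D_kb2_s=0.2, mode="tandem"),
        )
        traj = simulate(cfg, topo, rates, hela)
        path = tmp_path / "traj.h5"
        traj.save_h5(path)
        back = ExtrusionTrajectory.load_h5(path)
        np.testing.assert_array_equal(back.legs, traj.legs)
        np.testing.assert_array_equal(back.states, traj.states)
        np.testing.assert_array_equal(back.ctcf_occupancy, traj.ctcf_occupancy)
        assert back.config == traj.config
        assert back.states_order == traj.states_order
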