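"""Mass-action dynamics, steady state, residence times, KMC sampling."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import burstex as bx
from burstex.network import (
    ConfigurationError,
    discrete_map_curve,
    random_rates,
    transition_matrix,
)
from burstex.topology import REGULATORS, CohesinState as S, enumerate_cycles

RN, R, RP, RW, FREE = S.NIPBL_BOUND, S.BARE, S.PDS5_BOUND, S.WAPL_BOUND, S.FREE


def zero_rates(topology):
    return bx.RateSet({t.key: 0.0 for t in topology.transitions})


# ---------------------------------------------------------------------------
# dynamics


class TestBuildDynamics:
    def test_zero_rates_zero_derivative(self, hela, selected):
        topo, _ = selected
        rhs = bx.build_dynamics(topo, zero_rates(topo), hela)
        rng = np.random.default_rng(0)
        for _ in range(5):
            y = rng.random(len(topo.states) + 3)
            assert np.all(rhs(0.0, y) == 0.0)

    def test_derivative_vanishes_at_inferred_steady_state(self, hela, selected, wt_steady):
        topo, rates = selected
        rhs = bx.build_dynamics(topo, rates, hela)
        y = np.empty(len(topo.states) + 3)
        for s, i in rhs.state_index.items():
            y[i] = wt_steady.concentration(s)
        for r, i in rhs.pool_index.items():
            y[i] = wt_steady.pool_concentration(r)
        assert np.abs(rhs(0.0, y)).max() < 1e-10

    def test_single_unimolecular_load_decays_exponentially(self, hela):
        """Only a bare-state load reaction: R_free(t) = exp(-k t) exactly."""
        topo = next(c for c in enumerate_cycles() if c.name == "R-RN-RP-RW")
        k = 0.004
        rates = bx.RateSet({**{t.key: 0.0 for t in topo.transitions}, "free->R": k})
        rhs = bx.build_dynamics(topo, rates, hela)
        sol = solve_ivp(
            rhs, (0.0, 600.0), rhs.initial_unloaded, rtol=1e-10, atol=1e-12,
            t_eval=[100.0, 300.0, 600.0],
        )
        free = sol.y[rhs.state_index[FREE]]
        np.testing.assert_allclose(free, np.exp(-k * sol.t), rtol=1e-7)

    def test_bimolecular_load_initial_rate(self, hela, selected):
        """Loading with NIPBL co-binding starts at rate k * N_free."""
        topo, _ = selected
        k = 0.004
        rates = bx.RateSet({**{t.key: 0.0 for t in topo.transitions}, "free->RN": k})
        rhs = bx.build_dynamics(topo, rates, hela)
        d0 = rhs(0.0, rhs.initial_unloaded)
        # fully unloaded start: the whole NIPBL pool is free
        assert d0[rhs.state_index[FREE]] == pytest.approx(
            -k * hela.total("NIPBL"), rel=1e-12
        )

    def test_missing_rate_is_configuration_error(self, hela, selected):
        topo, rates = selected
        partial = bx.RateSet({k: v for k, v in rates.rates.items() if k != "RW->free"})
        with pytest.raises(ConfigurationError, match="RW->free"):
            bx.build_dynamics(topo, partial, hela)

    @pytest.mark.parametrize("topo_idx", [0, 7, 23])
    def test_conservation_laws_exact(self, hela, topo_idx):
        """rhs is orthogonal to every conservation vector for any state."""
        topo = enumerate_cycles()[topo_idx]
        rates = random_rates(topo, topo_idx)
        rhs = bx.build_dynamics(topo, rates, hela)
        nstat = len(topo.states)
        rng = np.random.default_rng(topo_idx)
        cohesin = np.zeros(nstat + 3)
        cohesin[:nstat] = 1.0
        for _ in range(5):
            y = rng.random(nstat + 3)
            d = rhs(0.0, y)
            assert cohesin @ d == pytest.approx(0.0, abs=1e-15)
            for reg, pi in rhs.pool_index.items():
                vec = np.zeros(nstat + 3)
                vec[pi] = 1.0
                for s, si in rhs.state_index.items():
                    if reg in REGULATORS[s]:
                        vec[si] = 1.0
                assert vec @ d == pytest.approx(0.0, abs=1e-15)


# ---------------------------------------------------------------------------
# steady state


class TestSteadyState:
    def test_wt_occupancies_match_bound_fraction_arithmetic(self, wt_steady, hela):
        """Regulator-bound occupancies are forced by the bound fractions."""
        assert wt_steady.occupancy[RN] == pytest.approx(
            0.40 * 111_000 / 264_000, abs=1e-10
        )
        expected_bare = 0.65 - (
            0.40 * 111_000 + 0.45 * 164_000 + 0.35 * 65_000
        ) / 264_000
        assert wt_steady.occupancy[R] == pytest.approx(expected_bare, abs=1e-10)
        assert sum(wt_steady.occupancy.values()) == pytest.approx(1.0, abs=1e-12)

    def test_free_pool_conservation(self, wt_steady, hela):
        for reg in ("NIPBL", "PDS5", "WAPL"):
            bound = sum(
                wt_steady.concentration(s)
                for s in wt_steady.occupancy
                if reg in REGULATORS[s]
            )
            total = bound + wt_steady.pool_concentration(reg)
            assert total == pytest.approx(hela.total(reg), abs=1e-12)

    def test_uniqueness_from_different_initial_conditions(self, hela, selected):
        """Fully unloaded vs fully bare-loaded vs random all converge alike."""
        topo, rates = selected
        ref = bx.steady_state(topo, rates, hela, "ode_integration")
        for initial in (
            {R: 1.0},
            {RN: 0.3, R: 0.3, FREE: 0.4},
            {RP: 0.2, FREE: 0.8},
        ):
            ss = bx.steady_state(topo, rates, hela, "ode_integration", initial=initial)
            for s in ref.occupancy:
                assert ss.occupancy[s] == pytest.approx(ref.occupancy[s], abs=1e-8)

    def test_root_and_ode_methods_agree(self, hela, selected):
        topo, rates = selected
        a = bx.steady_state(topo, rates, hela, "root_solve")
        b = bx.steady_state(topo, rates, hela, "ode_integration")
        for s in a.occupancy:
            assert a.occupancy[s] == pytest.approx(b.occupancy[s], abs=1e-9)

    def test_net_flux_balance_at_every_state(self, selected, wt_steady):
        topo, _ = selected
        for s in topo.states:
            net = sum(
                v for t, v in zip(topo.transitions, wt_steady.fluxes.values())
                if t.target is s
            ) - sum(
                v for t, v in zip(topo.transitions, wt_steady.fluxes.values())
                if t.source is s
            )
            assert net == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# residence times


def mc_first_passage(topology, rates, steady, n_samples, rng):
    """Brute-force Monte Carlo first-passage oracle (independent of the
    linear-solve implementation): exponential races over the loaded chain
    with pools frozen at the steady state."""
    loaded = list(topology.loaded_states)
    idx = {s: i for i, s in enumerate(loaded)}
    absorbing = len(loaded)
    # per-state exits
    exits = [[] for _ in loaded]
    for t in topology.transitions:
        if t.source is FREE:
            continue
        v = rates[t.key]
        for reg in t.consumed:
            v *= steady.pool_concentration(reg)
        tgt = absorbing if t.target is FREE else idx[t.target]
        exits[idx[t.source]].append((tgt, v))
    entry = idx[topology.loading_transitions[0].target]

    state = np.full(n_samples, entry)
    time = np.zeros(n_samples)
    alive = state != absorbing
    while alive.any():
        for i, ex in enumerate(exits):
            mask = alive & (state == i)
            n = int(mask.sum())
            if n == 0:
                continue
            total = sum(v for _, v in ex)
            time[mask] += rng.exponential(1.0 / total, n)
            u = rng.random(n) * total
            nxt = np.full(n, ex[-1][0])
            acc = 0.0
            assigned = np.zeros(n, bool)
            for tgt, v in ex:
                sel = (~assigned) & (u < acc + v)
                nxt[sel] = tgt
                assigned |= sel
                acc += v
            state[mask] = nxt
        alive = state != absorbing
    return time


class TestResidenceTime:
    def test_single_exit_dwell_is_reciprocal_rate(self, hela, selected, wt_steady):
        """NIPBL leaves RN through one unimolecular exit: dwell = 1/k."""
        topo, rates = selected
        modified = bx.RateSet({**rates.rates, "RN->R": 0.1})
        ss = bx.steady_state(topo, modified, hela)
        assert bx.residence_time(topo, modified, ss, "NIPBL") == pytest.approx(10.0)

    def test_wt_round_trip_reproduces_input_residence_times(
        self, hela, selected, wt_steady
    ):
        topo, rates = selected
        for protein, tau in (("RAD21", 822.0), ("NIPBL", 72.0), ("PDS5", 70.0), ("WAPL", 45.0)):
            assert bx.residence_time(topo, rates, wt_steady, protein) == pytest.approx(
                tau, rel=1e-10
            )

    def test_first_passage_matches_monte_carlo(self, hela, selected, wt_steady):
        topo, rates = selected
        rng = np.random.default_rng(42)
        samples = mc_first_passage(topo, rates, wt_steady, 200_000, rng)
        se = samples.std(ddof=1) / math.sqrt(len(samples))
        predicted = bx.residence_time(topo, rates, wt_steady, "RAD21")
        assert abs(samples.mean() - predicted) < 3 * se

    @pytest.mark.parametrize("topo_idx", range(24))
    def test_first_passage_oracle_on_all_cycles(self, hela, topo_idx):
        """Linear-solve MFPT equals stochastic simulation on every cycle."""
        topo = enumerate_cycles()[topo_idx]
        rates = random_rates(topo, 100 + topo_idx)
        ss = bx.steady_state(topo, rates, hela)
        predicted = bx.residence_time(topo, rates, ss, "RAD21")
        rng = np.random.default_rng(200 + topo_idx)
        samples = mc_first_passage(topo, rates, ss, 20_000, rng)
        se = samples.std(ddof=1) / math.sqrt(len(samples))
        assert abs(samples.mean() - predicted) < 4 * se

    def test_zero_unload_path_reports_infinity(self, hela, selected):
        topo, rates = selected
        no_unload = bx.RateSet({**rates.rates, "RW->free": 0.0})
        ss = bx.steady_state(topo, rates, hela)  # pools from a feasible state
        assert bx.residence_time(topo, no_unload, ss, "RAD21") == math.inf


# ---------------------------------------------------------------------------
# motor observables


class TestMeanExtrusionRate:
    def _steady_with_ratio(self, wt_steady, ratio):
        occ = dict(wt_steady.occupancy)
        loaded = 1.0 - occ[FREE]
        occ[RN] = ratio * loaded
        occ[R] = loaded - occ[RN] - occ[RP] - occ[RW]
        return bx.SteadyState(
            occupancy=occ,
            free_pools=wt_steady.free_pools,
            fluxes=wt_steady.fluxes,
            entry_frequency=wt_steady.entry_frequency,
            abundance=wt_steady.abundance,
        )

    def test_plugin_arithmetic(self, wt_steady):
        ss = self._steady_with_ratio(wt_steady, 0.5)
        assert bx.mean_extrusion_rate(ss, 2500.0, 1.25) == pytest.approx(2000.0)

    def test_zero_active_gives_zero_rate(self, wt_steady):
        ss = self._steady_with_ratio(wt_steady, 0.0)
        assert bx.mean_extrusion_rate(ss) == 0.0

    def test_wt_ratio_close_to_quarter(self, wt_steady):
        # 0.168 / 0.65 ~ 0.259 of loaded extruders active
        assert wt_steady.active_to_loaded_ratio == pytest.approx(
            (0.40 * 111 / 264) / 0.65, rel=1e-9
        )

    def test_no_loaded_cohesin_is_an_error(self, wt_steady):
        occ = {s: 0.0 for s in wt_steady.occupancy}
        occ[FREE] = 1.0
        ss = bx.SteadyState(occ, wt_steady.free_pools, {}, {}, wt_steady.abundance)
        with pytest.raises(ZeroDivisionError):
            bx.mean_extrusion_rate(ss)


# ---------------------------------------------------------------------------
# KMC


class TestKMC:
    def test_zero_rates_freeze_all_complexes(self, hela, selected):
        topo, _ = selected
        traj = bx.kmc_trajectory(
            topo, zero_rates(topo), hela, n_complexes=200, duration_s=50.0, seed=1
        )
        assert (traj.counts == traj.counts[0]).all()
        assert all(v == 0 for v in traj.entry_counts.values())

    def test_population_curves_match_mean_field_map(self, hela, selected):
        """Ensemble occupancies track the discrete-time map within 3 SE."""
        topo, rates = selected
        n = 4000
        traj = bx.kmc_trajectory(
            topo, rates, hela, n_complexes=n, duration_s=2500.0, seed=7,
            record_every=200,
        )
        times, occ_map = discrete_map_curve(
            topo, rates, hela, 2500.0, record_every=200
        )
        occ_kmc = traj.counts / n
        for j in range(len(topo.states)):
            p = occ_map[:, j]
            se = np.sqrt(np.maximum(p * (1 - p), 1e-12) / n)
            assert (np.abs(occ_kmc[:, j] - p) <= 3 * se + 1e-9).all()

    def test_entry_frequency_matches_flux_oracle(self, hela, selected, wt_steady):
        """Entries into RN per loaded complex-time match the steady-state flux."""
        topo, rates = selected
        n, dur = 3000, 9000.0
        traj = bx.kmc_trajectory(
            topo, rates, hela, n_complexes=n, duration_s=dur, seed=11
        )
        i_free = traj.states_order.index(FREE)
        loaded_steps = traj.counts[1:].sum(axis=1).sum() - traj.counts[1:, i_free].sum()
        loaded_time = loaded_steps * traj.timestep_s
        measured = traj.entry_counts[RN] / loaded_time
        expected = wt_steady.entry_frequency[RN]
        assert measured == pytest.approx(expected, rel=0.10)

    def test_timestep_guard(self, hela, selected):
        topo, rates = selected
        with pytest.raises(ConfigurationError, match="timestep"):
            bx.kmc_trajectory(
                topo, rates, hela, n_complexes=10, duration_s=100.0, timestep_s=50.0
            )


class TestRateSet:
    def test_json_round_trip(self, selected, tmp_path):
        _, rates = selected
        path = tmp_path / "rates.json"
        rates.to_json(path)
        back = bx.RateSet.from_json(path)
        assert back.rates == rates.rates

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            bx.RateSet({"free->RN": math.nan})
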