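"""Mass-action dynamics of the cohesin reaction network and derived motor observables.

Concentration convention
------------------------
All species are expressed as fractions of the *total RAD21 copy number of
the measurement set used for rate inference*.  Unimolecular rate constants
are in s^-1; bimolecular constants in (fraction * s)^-1.  Depletions and
over-expressions rescale the totals in these fixed units, so the rate
constants themselves never change — this is what makes abundance
perturbations pure re-equilibrations of the same network.

The state vector of :func:`build_dynamics` is ``[occupancies of the
topology's states..., free NIPBL, free PDS5, free WAPL]``, and mass action
guarantees two exact conservation laws: total cohesin, and bound + free of
each regulator.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .measurements import REGULATOR_PROTEINS, MeasurementSet
from .topology import REGULATORS, CohesinState, NetworkTopology, Transition

__all__ = [
    "RateSet",
    "SteadyState",
    "ConfigurationError",
    "ConvergenceError",
    "build_dynamics",
    "steady_state",
    "residence_time",
    "mean_extrusion_rate",
    "kmc_trajectory",
    "KMCTrajectory",
    "abundances",
    "random_rates",
]

S = CohesinState

#: Default lattice/motor scale constants: 2.5 kb per site, 1.25 s per step.
DEFAULT_SITE_SIZE_BP = 2500.0
DEFAULT_TIMESTEP_S = 1.25

#: Discrete-time kinetic Monte Carlo guard: the total per-step exit
#: probability from any state must stay below this value.
KMC_GUARD = 0.1


class ConfigurationError(ValueError):
    """A topology/rate/measurement combination is inconsistent."""


class ConvergenceError(RuntimeError):
    """A numerical solve failed to reach the requested tolerance."""


@dataclass(frozen=True)
class RateSet:
    """The eight transition-rate constants of one topology.

    Keys are ``"source->target"`` state strings (see
    :attr:`burstex.topology.Transition.key`).  Values follow the
    pseudo-first-order convention documented in this module: unimolecular
    rates in s^-1, bimolecular rates in per-(fraction-of-total-RAD21 * s).
    """

    rates: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rates", dict(self.rates))
        for k, v in self.rates.items():
            if not math.isfinite(v):
                raise ValueError(f"rate {k} is not finite")

    def __getitem__(self, key: str | Transition) -> float:
        if isinstance(key, Transition):
            key = key.key
        return self.rates[key]

    def for_topology(self, topology: NetworkTopology) -> np.ndarray:
        """Rates ordered as ``topology.transitions``; raises if any is missing."""
        try:
            return np.array([self.rates[t.key] for t in topology.transitions])
        except KeyError as e:  # pragma: no cover - message formatting
            raise ConfigurationError(
                f"rate missing for transition {e.args[0]} of topology {topology.name}"
            ) from e

    @property
    def feasible(self) -> bool:
        return all(v >= 0.0 for v in self.rates.values())

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dict(sorted(self.rates.items())), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RateSet":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls(json.loads(text))


@dataclass(frozen=True)
class SteadyState:
    """The unique equilibrium of a network at given rates and abundances.

    ``occupancy`` is normalized to the *current* total cohesin content
    (entries sum to 1 over the network's cohesin states); ``free_pools``
    gives each regulator's free amount as a fraction of its own total;
    ``fluxes`` are steady-state reaction fluxes per current total RAD21 per
    second; ``entry_frequency`` maps each loaded state to its mean number
    of entries per loading window divided by the cohesin residence time
    (units s^-1).  ``abundance`` records the totals, in fractions of the
    inference-time RAD21 content, at which the equilibrium was computed.
    """

    occupancy: Mapping[CohesinState, float]
    free_pools: Mapping[str, float]
    fluxes: Mapping[str, float]
    entry_frequency: Mapping[CohesinState, float]
    abundance: Mapping[str, float]
    derivative_norm: float = 0.0

    @property
    def cohesin_total(self) -> float:
        """Current total cohesin in inference concentration units."""
        return self.abundance["RAD21"]

    @property
    def loaded_fraction(self) -> float:
        return 1.0 - self.occupancy[S.FREE]

    @property
    def active_fraction(self) -> float:
        """Fraction of all cohesin in NIPBL-bound (actively extruding) states."""
        return sum(
            v for s, v in self.occupancy.items() if "NIPBL" in REGULATORS[s]
        )

    @property
    def active_to_loaded_ratio(self) -> float:
        loaded = self.loaded_fraction
        if loaded <= 0.0:
            raise ZeroDivisionError("no loaded cohesin at this steady state")
        return self.active_fraction / loaded

    def concentration(self, state: CohesinState) -> float:
        """State concentration in inference units (fractions of WT RAD21)."""
        return self.occupancy[state] * self.cohesin_total

    def pool_concentration(self, regulator: str) -> float:
        """Free-pool concentration in inference units."""
        return self.free_pools[regulator] * self.abundance[regulator]

    def bound_fraction(self, protein: str) -> float:
        if protein == "RAD21":
            return self.loaded_fraction
        return 1.0 - self.free_pools[protein]

    def to_json(self, path: str | Path | None = None) -> str:
        flat = {
            **{f"occupancy.{s.value}": v for s, v in self.occupancy.items()},
            **{f"free_pool.{r}": v for r, v in self.free_pools.items()},
            **{f"flux.{k}": v for k, v in self.fluxes.items()},
            **{f"abundance.{p}": v for p, v in self.abundance.items()},
        }
        text = json.dumps(flat, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


# ---------------------------------------------------------------------------
# dynamics construction


def abundances(
    measurements: MeasurementSet,
    depletion: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Total abundances in inference units, optionally depleted.

    ``depletion`` maps protein name to a depletion fraction in ``[0, 1)``
    (negative values over-express).
    """
    depletion = depletion or {}
    out = {"RAD21": 1.0}
    for reg in REGULATOR_PROTEINS:
        out[reg] = measurements.total(reg)
    for name, level in depletion.items():
        if name not in out:
            raise ConfigurationError(f"unknown protein {name!r}")
        out[name] *= 1.0 - level
        if out[name] <= 0.0:
            raise ConfigurationError(f"depletion leaves no {name} copies")
    return out


def _propensities(
    topology: NetworkTopology,
    k: np.ndarray,
    conc: Mapping[CohesinState, float],
    pools: Mapping[str, float],
) -> np.ndarray:
    """Reaction fluxes (inference units per second) for each transition."""
    a = np.empty(len(topology.transitions))
    for j, t in enumerate(topology.transitions):
        v = k[j] * conc[t.source]
        for reg in t.consumed:
            v *= pools[reg]
        a[j] = v
    return a


def build_dynamics(
    topology: NetworkTopology,
    rates: RateSet,
    measurements: MeasurementSet,
    depletion: Mapping[str, float] | None = None,
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Mass-action right-hand side over (cohesin states, free regulator pools).

    The returned callable ``rhs(t, y)`` acts on the concatenated vector of
    state concentrations (in topology state order) and the three free
    pools, all in inference units.  Attributes ``state_index``,
    ``pool_index``, ``initial_unloaded`` and ``abundance`` describe the
    layout.
    """
    k = rates.for_topology(topology)
    states = topology.states
    sidx = {s: i for i, s in enumerate(states)}
    nstat = len(states)
    pidx = {r: nstat + i for i, r in enumerate(REGULATOR_PROTEINS)}
    totals = abundances(measurements, depletion)

    # stoichiometry per transition
    stoich = np.zeros((len(topology.transitions), nstat + 3))
    for j, t in enumerate(topology.transitions):
        stoich[j, sidx[t.source]] -= 1.0
        stoich[j, sidx[t.target]] += 1.0
        for reg in t.consumed:
            stoich[j, pidx[reg]] -= 1.0
        for reg in t.released:
            stoich[j, pidx[reg]] += 1.0

    trans = topology.transitions
    src = np.array([sidx[t.source] for t in trans])
    pool_factors = [tuple(pidx[r] for r in t.consumed) for t in trans]

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        a = k * y[src]
        for j, pf in enumerate(pool_factors):
            for pi in pf:
                a[j] *= y[pi]
        return a @ stoich

    y0 = np.zeros(nstat + 3)
    y0[sidx[S.FREE]] = totals["RAD21"]
    for r in REGULATOR_PROTEINS:
        y0[pidx[r]] = totals[r]

    rhs.state_index = sidx  # type: ignore[attr-defined]
    rhs.pool_index = pidx  # type: ignore[attr-defined]
    rhs.initial_unloaded = y0  # type: ignore[attr-defined]
    rhs.abundance = totals  # type: ignore[attr-defined]
    return rhs


# ---------------------------------------------------------------------------
# steady state


def _package_steady_state(
    topology: NetworkTopology,
    k: np.ndarray,
    y_loaded: np.ndarray,
    totals: Mapping[str, float],
    derivative_norm: float,
) -> SteadyState:
    loaded = topology.loaded_states
    rtot = totals["RAD21"]
    conc = {s: float(v) for s, v in zip(loaded, y_loaded)}
    conc[S.FREE] = rtot - sum(conc.values())
    pools_conc = {
        r: totals[r] - sum(conc[s] for s in loaded if r in REGULATORS[s])
        for r in REGULATOR_PROTEINS
    }
    a = _propensities(topology, k, conc, pools_conc)
    fluxes = {t.key: float(v) / rtot for t, v in zip(topology.transitions, a)}
    # entries per loading window / cohesin residence time == influx per
    # loaded cohesin (Little's law), reported per second
    loaded_conc = rtot - conc[S.FREE]
    entry = {}
    for s in loaded:
        influx = sum(v for t, v in zip(topology.transitions, a) if t.target is s)
        entry[s] = float(influx / loaded_conc) if loaded_conc > 0 else 0.0
    occupancy = {s: conc[s] / rtot for s in topology.states}
    free_pools = {
        r: (pools_conc[r] / totals[r]) if totals[r] > 0 else 1.0
        for r in REGULATOR_PROTEINS
    }
    return SteadyState(
        occupancy=occupancy,
        free_pools=free_pools,
        fluxes=fluxes,
        entry_frequency=entry,
        abundance=dict(totals),
        derivative_norm=derivative_norm,
    )


def steady_state(
    topology: NetworkTopology,
    rates: RateSet,
    measurements: MeasurementSet,
    method: str = "root_solve",
    *,
    depletion: Mapping[str, float] | None = None,
    tol: float = 1e-10,
    ode_tol: float = 1e-8,
    max_time_s: float = 1e7,
    initial: Mapping[CohesinState, float] | None = None,
) -> SteadyState:
    """Solve for the unique equilibrium of the network.

    ``root_solve`` solves the algebraic flux balance on the loaded-state
    concentrations (free cohesin and free pools eliminated through the
    conservation laws) to derivative max-norm below ``tol``;
    ``ode_integration`` integrates the mass-action ODE from a fully
    unloaded population until the derivative max-norm falls below
    ``ode_tol``.  ``initial`` optionally seeds either method with a custom
    starting occupancy (fractions of current cohesin total).
    """
    if not rates.feasible:
        raise ConfigurationError("rates must be non-negative for steady-state solves")
    k = rates.for_topology(topology)
    totals = abundances(measurements, depletion)
    loaded = topology.loaded_states
    idx = {s: i for i, s in enumerate(loaded)}
    rtot = totals["RAD21"]

    def residual(y: np.ndarray) -> np.ndarray:
        conc = {s: y[idx[s]] for s in loaded}
        conc[S.FREE] = rtot - y.sum()
        pools = {
            r: totals[r] - sum(conc[s] for s in loaded if r in REGULATORS[s])
            for r in REGULATOR_PROTEINS
        }
        a = _propensities(topology, k, conc, pools)
        res = np.zeros(len(loaded))
        for t, v in zip(topology.transitions, a):
            if t.target in idx:
                res[idx[t.target]] += v
            if t.source in idx:
                res[idx[t.source]] -= v
        return res

    if method == "root_solve":
        starts: list[np.ndarray] = []
        if initial is not None:
            starts.append(np.array([initial.get(s, 0.0) * rtot for s in loaded]))
        starts += [np.full(len(loaded), f * rtot) for f in (0.1, 0.01, 0.2, 0.02, 0.15)]
        best = None
        for y0 in starts:
            sol = root(residual, y0, method="hybr", tol=1e-14)
            y = sol.x
            norm = float(np.abs(residual(y)).max())
            ok = (
                norm < tol
                and (y > -1e-9).all()
                and y.sum() <= rtot + 1e-9
            )
            if ok:
                return _package_steady_state(topology, k, np.clip(y, 0.0, None), totals, norm)
            if best is None or norm < best[1]:
                best = (y, norm)
        # fall back to integration, then polish
        ss = steady_state(
            topology, rates, measurements, "ode_integration",
            depletion=depletion, ode_tol=max(tol * 100, 1e-9), max_time_s=max_time_s,
        )
        y0 = np.array([ss.concentration(s) for s in loaded])
        sol = root(residual, y0, method="hybr", tol=1e-14)
        norm = float(np.abs(residual(sol.x)).max())
        if norm < tol and (sol.x > -1e-9).all():
            return _package_steady_state(topology, k, np.clip(sol.x, 0.0, None), totals, norm)
        raise ConvergenceError(
            f"root solve stalled for topology {topology.name}: residual norm {norm:.3e} "
            f"(tolerance {tol:.1e}); best occupancies {best[0] if best else None}"
        )

    if method == "ode_integration":
        rhs = build_dynamics(topology, rates, measurements, depletion)
        y = rhs.initial_unloaded.copy()  # type: ignore[attr-defined]
        if initial is not None:
            sidx = rhs.state_index  # type: ignore[attr-defined]
            y[: len(topology.states)] = 0.0
            for s, frac in initial.items():
                y[sidx[s]] = frac * rtot
            for r in REGULATOR_PROTEINS:
                y[rhs.pool_index[r]] = totals[r] - sum(  # type: ignore[attr-defined]
                    frac * rtot for s, frac in initial.items() if r in REGULATORS[s]
                )
        t, horizon = 0.0, 1e4
        while t < max_time_s:
            sol = solve_ivp(
                rhs, (0.0, horizon), y, method="LSODA", rtol=1e-12, atol=1e-14
            )
            y = sol.y[:, -1]
            t += horizon
            horizon *= 4.0
            norm = float(np.abs(rhs(0.0, y)).max())
            if norm < ode_tol:
                sidx = rhs.state_index  # type: ignore[attr-defined]
                y_loaded = np.array([y[sidx[s]] for s in loaded])
                return _package_steady_state(topology, k, y_loaded, totals, norm)
        raise ConvergenceError(
            f"ODE integration did not equilibrate within {max_time_s:.3g} s "
            f"(residual norm {norm:.3e})"
        )

    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# residence times and motor observables


def _loaded_generator(
    topology: NetworkTopology, k: np.ndarray, steady: SteadyState
) -> tuple[np.ndarray, dict[CohesinState, int]]:
    """CTMC generator over loaded states, pools frozen at steady state.

    FREE is absorbing (dropped); pseudo-first-order propensities use the
    steady-state free-pool concentrations.
    """
    loaded = topology.loaded_states
    idx = {s: i for i, s in enumerate(loaded)}
    Q = np.zeros((len(loaded), len(loaded)))
    for j, t in enumerate(topology.transitions):
        if t.source is S.FREE:
            continue
        v = k[j]
        for reg in t.consumed:
            v *= steady.pool_concentration(reg)
        Q[idx[t.source], idx[t.source]] -= v
        if t.target is not S.FREE:
            Q[idx[t.source], idx[t.target]] += v
    return Q, idx


def residence_time(
    topology: NetworkTopology,
    rates: RateSet,
    steady: SteadyState,
    protein: str,
) -> float:
    """Mean chromatin-bound duration of ``protein`` at the given equilibrium.

    For RAD21 this is the mean first-passage time from the loading entry
    state(s) to the unloaded state over the loaded-state continuous-time
    Markov chain (entry states weighted by loading flux).  For a regulator
    it is the mean dwell of its bound state(s): bound population divided by
    gross binding flux, which for a single bound state reduces to the
    reciprocal of the total exit propensity.  An unreachable unload path
    yields ``inf``.
    """
    k = rates.for_topology(topology)
    if protein == "RAD21":
        Q, idx = _loaded_generator(topology, k, steady)
        w = np.zeros(len(idx))
        tot = 0.0
        for j, t in enumerate(topology.transitions):
            if t.source is not S.FREE:
                continue
            v = k[j] * steady.concentration(S.FREE)
            for reg in t.consumed:
                v *= steady.pool_concentration(reg)
            w[idx[t.target]] += v
            tot += v
        if tot <= 0.0:
            return math.inf
        try:
            tau = np.linalg.solve(Q, -np.ones(len(idx)))
        except np.linalg.LinAlgError:
            return math.inf
        val = float(tau @ (w / tot))
        return val if val > 0 else math.inf

    if protein not in REGULATOR_PROTEINS:
        raise ValueError(f"unknown protein {protein!r}")
    bound = sum(
        steady.concentration(s)
        for s in topology.loaded_states
        if protein in REGULATORS[s]
    )
    binding_flux = 0.0
    for j, t in enumerate(topology.transitions):
        if protein not in t.consumed:
            continue
        v = k[j] * steady.concentration(t.source)
        for reg in t.consumed:
            v *= steady.pool_concentration(reg)
        binding_flux += v
    if binding_flux <= 0.0:
        return math.inf
    return float(bound / binding_flux)


def mean_extrusion_rate(
    steady: SteadyState,
    site_size_bp: float = DEFAULT_SITE_SIZE_BP,
    timestep_s: float = DEFAULT_TIMESTEP_S,
) -> float:
    """Mean extrusion speed ``v = 2 L / tau * [RN]/[R]_loaded`` in bp/s.

    The factor 2 counts both legs; the active-to-loaded ratio is the
    fraction of time a loaded extruder spends NIPBL bound.
    """
    if steady.loaded_fraction <= 0.0:
        raise ZeroDivisionError("mean extrusion rate undefined: no loaded cohesin")
    return 2.0 * site_size_bp / timestep_s * steady.active_to_loaded_ratio


# ---------------------------------------------------------------------------
# discrete-time kinetic Monte Carlo


@dataclass
class KMCTrajectory:
    """Ensemble output of the discrete-time KMC sampler.

    ``counts[t, i]`` is the number of complexes in state ``states_order[i]``
    at recorded time ``times_s[t]``; ``state_series`` optionally holds the
    per-complex state indices at each recorded step; ``entry_counts``
    accumulates the number of transitions into each state over the run.
    """

    times_s: np.ndarray
    counts: np.ndarray
    states_order: tuple[CohesinState, ...]
    entry_counts: dict[CohesinState, int]
    seed: int
    timestep_s: float
    state_series: Optional[np.ndarray] = None

    def occupancy_curve(self, state: CohesinState) -> np.ndarray:
        i = self.states_order.index(state)
        return self.counts[:, i] / self.counts.sum(axis=1)


def transition_matrix(
    topology: NetworkTopology,
    rates: RateSet,
    pools_conc: Mapping[str, float],
    timestep_s: float,
) -> np.ndarray:
    """Per-step state transition probability matrix at fixed free pools."""
    k = rates.for_topology(topology)
    states = topology.states
    idx = {s: i for i, s in enumerate(states)}
    P = np.zeros((len(states), len(states)))
    for j, t in enumerate(topology.transitions):
        v = k[j]
        for reg in t.consumed:
            v *= pools_conc[reg]
        P[idx[t.source], idx[t.target]] += v * timestep_s
    exit_p = P.sum(axis=1)
    if exit_p.max() >= KMC_GUARD:
        raise ConfigurationError(
            f"per-step exit probability {exit_p.max():.3f} exceeds the KMC guard "
            f"{KMC_GUARD}; choose a timestep smaller than "
            f"{timestep_s * KMC_GUARD / exit_p.max():.3g} s"
        )
    np.fill_diagonal(P, 1.0 - exit_p + np.diag(P))
    return P


def kmc_trajectory(
    topology: NetworkTopology,
    rates: RateSet,
    measurements: MeasurementSet,
    n_complexes: int,
    duration_s: float,
    timestep_s: float = DEFAULT_TIMESTEP_S,
    seed: int = 0,
    *,
    depletion: Mapping[str, float] | None = None,
    record_every: int = 1,
    record_states: bool = False,
) -> KMCTrajectory:
    """Discrete-time KMC sampling of the network with mean-field free pools.

    All complexes start unloaded.  Each step, every complex draws its next
    state from per-step probabilities ``rate * dt`` (pseudo-first-order,
    with free pools computed self-consistently from the current ensemble
    bound counts).  Population curves converge to the ODE solution as
    ``n_complexes`` grows.
    """
    rng = np.random.default_rng(seed)
    totals = abundances(measurements, depletion)
    k = rates.for_topology(topology)
    states = topology.states
    nS = len(states)
    idx = {s: i for i, s in enumerate(states)}
    # per-regulator bound indicator per state
    bound_of = {
        r: np.array([1.0 if r in REGULATORS[s] else 0.0 for s in states])
        for r in REGULATOR_PROTEINS
    }
    per_copy = totals["RAD21"] / n_complexes  # concentration per complex

    n_steps = int(round(duration_s / timestep_s))
    state = np.full(n_complexes, idx[S.FREE], dtype=np.int8)
    n_rec = n_steps // record_every + 1
    times = np.empty(n_rec)
    counts = np.zeros((n_rec, nS), dtype=np.int64)
    series = (
        np.empty((n_rec, n_complexes), dtype=np.int8) if record_states else None
    )
    entry = {s: 0 for s in states}

    def record(r: int, t_s: float) -> None:
        times[r] = t_s
        counts[r] = np.bincount(state, minlength=nS)
        if series is not None:
            series[r] = state

    record(0, 0.0)
    rec = 1
    for step in range(1, n_steps + 1):
        cnt = np.bincount(state, minlength=nS)
        pools = {
            r: totals[r] - float(bound_of[r] @ cnt) * per_copy
            for r in REGULATOR_PROTEINS
        }
        P = transition_matrix(topology, rates, pools, timestep_s)
        cum = P.cumsum(axis=1)
        u = rng.random(n_complexes)
        new = np.empty_like(state)
        for i in range(nS):
            mask = state == i
            if not mask.any():
                continue
            new[mask] = np.searchsorted(cum[i], u[mask], side="right")
        changed = new != state
        if changed.any():
            for i in np.bincount(new[changed], minlength=nS).nonzero()[0]:
                entry[states[i]] += int((new[changed] == i).sum())
        state = new
        if step % record_every == 0:
            record(rec, step * timestep_s)
            rec += 1

    return KMCTrajectory(
        times_s=times[:rec],
        counts=counts[:rec],
        states_order=states,
        entry_counts=entry,
        seed=seed,
        timestep_s=timestep_s,
        state_series=series[:rec] if series is not None else None,
    )


def discrete_map_curve(
    topology: NetworkTopology,
    rates: RateSet,
    measurements: MeasurementSet,
    duration_s: float,
    timestep_s: float = DEFAULT_TIMESTEP_S,
    *,
    depletion: Mapping[str, float] | None = None,
    record_every: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic mean-field iteration of the discrete-time KMC map.

    The expectation of the KMC ensemble follows this map exactly (up to
    O(1/n) free-pool coupling), and the map converges to the mass-action
    ODE as the timestep shrinks.  Returns (times, occupancy fractions) with
    columns ordered as ``topology.states``.
    """
    totals = abundances(measurements, depletion)
    states = topology.states
    nS = len(states)
    idx = {s: i for i, s in enumerate(states)}
    bound_of = {
        r: np.array([1.0 if r in REGULATORS[s] else 0.0 for s in states])
        for r in REGULATOR_PROTEINS
    }
    x = np.zeros(nS)
    x[idx[S.FREE]] = totals["RAD21"]
    n_steps = int(round(duration_s / timestep_s))
    times, rows = [0.0], [x.copy()]
    for step in range(1, n_steps + 1):
        pools = {r: totals[r] - float(bound_of[r] @ x) for r in REGULATOR_PROTEINS}
        P = transition_matrix(topology, rates, pools, timestep_s)
        x = x @ P
        if step % record_every == 0:
            times.append(step * timestep_s)
            rows.append(x.copy())
    occ = np.array(rows) / totals["RAD21"]
    return np.array(times), occ


def random_rates(
    topology: NetworkTopology,
    rng: np.random.Generator | int | None = None,
    *,
    low: float = 1e-3,
    high: float = 1e-1,
) -> RateSet:
    """Log-uniform random positive rate constants for a topology."""
    rng = np.random.default_rng(rng)
    k = 10 ** rng.uniform(np.log10(low), np.log10(high), len(topology.transitions))
    return RateSet({t.key: float(v) for t, v in zip(topology.transitions, k)})
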