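"""Discrete-time multi-state loop extrusion on a 1D lattice.

Each extruder is one cohesin complex carrying the chemical state of the
reaction network.  Per step, every extruder first updates its chemical
state by discrete-time kinetic Monte Carlo (per-step probabilities
``rate * dt`` with mean-field free pools frozen at the deterministic
steady state of the — possibly depleted — network), then every leg of
every NIPBL-bound (active) extruder attempts one outward hop, blocked
per-leg by occupied sites and chain ends.  Loading places two legs on a
uniformly chosen vacant adjacent site pair; unloading vacates both sites.
Optional features: dynamic CTCF barriers that block active legs while
occupied, and passive 1D diffusion of loaded-but-inactive extruders with
tandem or independent leg sliding.

Coordinates are 0-based site indices; a loop is the closed interval
``[left, right]``; chains are independent (no extruder crosses a chain
boundary).  Update order within the movement phase is a fresh random
permutation each step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from numba import njit

from .measurements import MeasurementSet
from .network import (
    DEFAULT_SITE_SIZE_BP,
    DEFAULT_TIMESTEP_S,
    ConfigurationError,
    RateSet,
    SteadyState,
    steady_state,
    transition_matrix,
)
from .topology import REGULATORS, CohesinState, NetworkTopology

__all__ = [
    "LatticeConfig",
    "CTCFConfig",
    "DiffusionConfig",
    "ExtrusionTrajectory",
    "simulate",
    "kymograph",
    "condensation_metrics",
    "default_extruder_count",
]

S = CohesinState


@dataclass(frozen=True)
class CTCFConfig:
    """Dynamic CTCF barriers at fixed sites.

    Occupancy of each site follows a two-state telegraph process whose
    binding/unbinding probabilities reproduce ``bound_fraction`` at
    equilibrium with mean occupied dwell ``residence_time_s``.  While a
    site is occupied it blocks the passage of *active* extruder legs
    (passive legs never pass); an active leg bypasses with probability
    ``bypass_probability``.  ``orientations`` per site: +1 blocks legs
    moving rightward (arriving from the left), -1 blocks legs moving
    leftward, 2 blocks both directions.
    """

    positions: tuple[int, ...]
    orientations: tuple[int, ...] | None = None
    bound_fraction: float = 0.5
    residence_time_s: float = 60.0
    bypass_probability: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.bound_fraction < 1.0:
            raise ConfigurationError("CTCF bound_fraction must lie in (0,1)")
        if self.residence_time_s <= 0:
            raise ConfigurationError("CTCF residence_time_s must be positive")
        if self.orientations is not None and len(self.orientations) != len(self.positions):
            raise ConfigurationError("orientations must match positions")

    def rates(self, timestep_s: float) -> tuple[float, float]:
        """(binding, unbinding) per-step probabilities."""
        p_off = timestep_s / self.residence_time_s
        p_on = p_off * self.bound_fraction / (1.0 - self.bound_fraction)
        if max(p_on, p_off) >= 1.0:
            raise ConfigurationError("CTCF per-step probability >= 1; reduce timestep")
        return p_on, p_off


@dataclass(frozen=True)
class DiffusionConfig:
    """Passive 1D diffusion of loaded, inactive extruders.

    ``mode`` is ``"tandem"`` (both legs slide together, loop size fixed) or
    ``"independent"`` (each leg hops on its own).  The per-step, per-direction
    hop probability is ``D * dt / l**2`` with ``D`` in kb^2/s and ``l`` the
    site size in kb.
    """

    D_kb2_s: float = 0.4
    mode: str = "independent"

    def __post_init__(self) -> None:
        if self.mode not in ("tandem", "independent"):
            raise ConfigurationError("diffusion mode must be 'tandem' or 'independent'")
        if not 0.0 <= self.D_kb2_s <= 0.5:
            raise ConfigurationError("D must lie in [0, 0.5] kb^2/s")

    def hop_probability(self, site_size_bp: float, timestep_s: float) -> float:
        l_kb = site_size_bp / 1000.0
        p = self.D_kb2_s * timestep_s / l_kb**2
        if p >= 1.0:
            raise ConfigurationError("per-step hop probability >= 1; reduce timestep")
        return p


@dataclass(frozen=True)
class LatticeConfig:
    """Geometry, clock and population of one lattice simulation."""

    n_sites: int = 4000
    n_chains: int = 2
    site_size_bp: float = DEFAULT_SITE_SIZE_BP
    timestep_s: float = DEFAULT_TIMESTEP_S
    duration_steps: int = 2000
    burnin_steps: int = 0
    record_every: int = 1
    seed: int = 0
    n_extruders: Optional[int] = None  # default: copy-number scaling
    ctcf: Optional[CTCFConfig] = None
    diffusion: Optional[DiffusionConfig] = None
    movement_enabled: bool = True

    def __post_init__(self) -> None:
        if self.n_sites < 2 or self.n_chains < 1:
            raise ConfigurationError("lattice needs at least 2 sites and 1 chain")
        if self.duration_steps < 1 or self.record_every < 1:
            raise ConfigurationError("duration_steps and record_every must be >= 1")

    @property
    def total_sites(self) -> int:
        return self.n_sites * self.n_chains

    @property
    def total_bp(self) -> float:
        return self.total_sites * self.site_size_bp

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2)


def default_extruder_count(config: LatticeConfig, measurements: MeasurementSet) -> int:
    """Extruders (loaded + unloaded) from nuclear copy number scaling.

    Total RAD21 copies per bp of genome, times the simulated lattice span.
    """
    density = measurements["RAD21"].copy_number / measurements.genome_size_bp
    return max(1, int(round(density * config.total_bp)))


@dataclass
class ExtrusionTrajectory:
    """Recorded lattice run: per-step extruder legs and chemical states.

    ``legs[t, i]`` are the (left, right) 0-based global site indices of
    extruder ``i`` (−1 when unloaded); ``states[t, i]`` indexes
    ``states_order``.  ``times_s`` are seconds from the start of the
    recorded window.
    """

    times_s: np.ndarray
    legs: np.ndarray  # (T, N, 2) int32
    states: np.ndarray  # (T, N) uint8
    states_order: tuple[CohesinState, ...]
    config: LatticeConfig
    seed: int
    deferred_loads: int = 0
    ctcf_occupancy: Optional[np.ndarray] = None  # (T, n_ctcf) bool

    @property
    def n_extruders(self) -> int:
        return self.legs.shape[1]

    def loaded_mask(self, t: int) -> np.ndarray:
        return self.legs[t, :, 0] >= 0

    def active_state_indices(self) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.states_order) if "NIPBL" in REGULATORS[s]]
        )

    def save_h5(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("legs", data=self.legs.astype(np.int32), compression="gzip")
            f.create_dataset("states", data=self.states.astype(np.uint8), compression="gzip")
            f.create_dataset("times_s", data=self.times_s)
            f.attrs["config"] = self.config.to_json()
            f.attrs["seed"] = self.seed
            f.attrs["states_order"] = json.dumps([s.value for s in self.states_order])
            f.attrs["deferred_loads"] = self.deferred_loads
            if self.ctcf_occupancy is not None:
                f.create_dataset("ctcf_occupancy", data=self.ctcf_occupancy)

    @classmethod
    def load_h5(cls, path: str | Path) -> "ExtrusionTrajectory":
        import h5py

        with h5py.File(path, "r") as f:
            cfg_dict = json.loads(f.attrs["config"])
            for key, sub in (("ctcf", CTCFConfig), ("diffusion", DiffusionConfig)):
                if cfg_dict.get(key) is not None:
                    sub_d = cfg_dict[key]
                    for tup in ("positions", "orientations"):
                        if tup in sub_d and sub_d[tup] is not None:
                            sub_d[tup] = tuple(sub_d[tup])
                    cfg_dict[key] = sub(**sub_d)
            config = LatticeConfig(**cfg_dict)
            order = tuple(CohesinState(v) for v in json.loads(f.attrs["states_order"]))
            return cls(
                times_s=f["times_s"][:],
                legs=f["legs"][:],
                states=f["states"][:],
                states_order=order,
                config=config,
                seed=int(f.attrs["seed"]),
                deferred_loads=int(f.attrs["deferred_loads"]),
                ctcf_occupancy=f["ctcf_occupancy"][:] if "ctcf_occupancy" in f else None,
            )


# ---------------------------------------------------------------------------
# numba kernel


@njit(cache=False, inline="always")
def _ctcf_blocks(g, direction, ctcf_ori, ctcf_occ):
    """Does an occupied CTCF site at g block a leg moving in `direction`?"""
    if not ctcf_occ[g]:
        return False
    o = ctcf_ori[g]
    if o == 0:
        return False
    if o == 2:
        return True
    return (o == 1 and direction > 0) or (o == -1 and direction < 0)


@njit(cache=False)
def _run_kernel(
    chem_u,  # (n_steps, N) float64 chemistry draws (separate stream)
    move_seed,
    n_burnin,
    record_every,
    cum,  # (S, S) cumulative per-step transition probabilities
    active,  # (S,) bool
    free_idx,
    n_sites,
    n_chains,
    states,  # (N,) int8, modified in place
    legs,  # (N, 2) int32, modified in place
    movement_enabled,
    p_diff,
    diff_mode,  # 0 off, 1 tandem, 2 independent
    ctcf_ori,  # (total_sites,) int8: 0 none, +1/-1/2 blocking codes
    ctcf_occ,  # (total_sites,) bool, modified in place
    p_ctcf_on,
    p_ctcf_off,
    p_bypass,
    rec_states,  # (n_rec, N) uint8
    rec_legs,  # (n_rec, N, 2) int32
    rec_ctcf,  # (n_rec, n_ctcf) bool
    ctcf_positions,  # (n_ctcf,) int64
):
    np.random.seed(move_seed)
    n_steps, N = chem_u.shape
    total_sites = n_sites * n_chains
    occ = np.zeros(total_sites, dtype=np.int32)  # 0 empty, else extruder id + 1
    for i in range(N):
        if legs[i, 0] >= 0:
            occ[legs[i, 0]] = i + 1
            occ[legs[i, 1]] = i + 1
    deferred = 0
    rec = 0
    ctcf_on = ctcf_positions.shape[0] > 0
    order = np.empty(N, dtype=np.int64)

    for step in range(n_steps):
        # --- CTCF occupancy telegraph ---
        if ctcf_on:
            for j in range(ctcf_positions.shape[0]):
                g = ctcf_positions[j]
                if ctcf_occ[g]:
                    if np.random.random() < p_ctcf_off:
                        ctcf_occ[g] = False
                elif np.random.random() < p_ctcf_on:
                    ctcf_occ[g] = True

        # --- chemical update (order-independent under mean-field pools) ---
        for i in range(N):
            s = states[i]
            u = chem_u[step, i]
            row = cum[s]
            ns = 0
            while ns < row.shape[0] - 1 and row[ns] <= u:
                ns += 1
            if ns == s:
                continue
            if s == free_idx and ns != free_idx:
                # loading: place both legs on a vacant adjacent pair
                if movement_enabled:
                    placed = False
                    for _ in range(64):
                        g = np.random.randint(0, total_sites)
                        if g % n_sites == n_sites - 1:
                            continue
                        if occ[g] == 0 and occ[g + 1] == 0:
                            legs[i, 0] = g
                            legs[i, 1] = g + 1
                            occ[g] = i + 1
                            occ[g + 1] = i + 1
                            placed = True
                            break
                    if not placed:
                        # exact scan over all vacant adjacent pairs
                        count = 0
                        for g in range(total_sites - 1):
                            if g % n_sites != n_sites - 1 and occ[g] == 0 and occ[g + 1] == 0:
                                count += 1
                        if count == 0:
                            deferred += 1
                            continue  # loading deferred; stays unloaded
                        pick = np.random.randint(0, count)
                        count = 0
                        for g in range(total_sites - 1):
                            if g % n_sites != n_sites - 1 and occ[g] == 0 and occ[g + 1] == 0:
                                if count == pick:
                                    legs[i, 0] = g
                                    legs[i, 1] = g + 1
                                    occ[g] = i + 1
                                    occ[g + 1] = i + 1
                                    break
                                count += 1
                states[i] = ns
            elif ns == free_idx:
                # unloading vacates both sites
                if movement_enabled and legs[i, 0] >= 0:
                    occ[legs[i, 0]] = 0
                    occ[legs[i, 1]] = 0
                    legs[i, 0] = -1
                    legs[i, 1] = -1
                states[i] = ns
            else:
                states[i] = ns

        # --- movement phase: fresh random permutation each step ---
        if movement_enabled:
            for i in range(N):
                order[i] = i
            for i in range(N - 1, 0, -1):
                j = np.random.randint(0, i + 1)
                tmp = order[i]
                order[i] = order[j]
                order[j] = tmp
            for oi in range(N):
                i = order[oi]
                if legs[i, 0] < 0:
                    continue
                if active[states[i]]:
                    # each leg attempts one outward hop, blocked per leg;
                    # an occupied CTCF site is bypassed with prob p_bypass
                    l = legs[i, 0]
                    if l % n_sites > 0 and occ[l - 1] == 0:
                        blocked = ctcf_on and _ctcf_blocks(l - 1, -1, ctcf_ori, ctcf_occ)
                        if blocked and np.random.random() < p_bypass:
                            blocked = False
                        if not blocked:
                            occ[l] = 0
                            occ[l - 1] = i + 1
                            legs[i, 0] = l - 1
                    r = legs[i, 1]
                    if r % n_sites < n_sites - 1 and occ[r + 1] == 0:
                        blocked = ctcf_on and _ctcf_blocks(r + 1, 1, ctcf_ori, ctcf_occ)
                        if blocked and np.random.random() < p_bypass:
                            blocked = False
                        if not blocked:
                            occ[r] = 0
                            occ[r + 1] = i + 1
                            legs[i, 1] = r + 1
                elif diff_mode > 0:
                    # passive diffusion; inactive legs never bypass CTCF
                    l = legs[i, 0]
                    r = legs[i, 1]
                    if diff_mode == 1:
                        # tandem: both legs slide one site together
                        u = np.random.random()
                        if u < p_diff:  # leftward
                            ok = (
                                l % n_sites > 0
                                and occ[l - 1] == 0
                                and (r - 1 == l or occ[r - 1] == 0)
                                and not (ctcf_on and _ctcf_blocks(l - 1, -1, ctcf_ori, ctcf_occ))
                            )
                            if ok:
                                occ[l] = 0
                                occ[r] = 0
                                occ[l - 1] = i + 1
                                occ[r - 1] = i + 1
                                legs[i, 0] = l - 1
                                legs[i, 1] = r - 1
                        elif u < 2.0 * p_diff:  # rightward
                            ok = (
                                r % n_sites < n_sites - 1
                                and occ[r + 1] == 0
                                and (l + 1 == r or occ[l + 1] == 0)
                                and not (ctcf_on and _ctcf_blocks(r + 1, 1, ctcf_ori, ctcf_occ))
                            )
                            if ok:
                                occ[l] = 0
                                occ[r] = 0
                                occ[l + 1] = i + 1
                                occ[r + 1] = i + 1
                                legs[i, 0] = l + 1
                                legs[i, 1] = r + 1
                    else:
                        # independent legs; loop-inverting hops rejected
                        u = np.random.random()
                        if u < p_diff:  # left leg leftward
                            if (
                                l % n_sites > 0
                                and occ[l - 1] == 0
                                and not (ctcf_on and _ctcf_blocks(l - 1, -1, ctcf_ori, ctcf_occ))
                            ):
                                occ[l] = 0
                                occ[l - 1] = i + 1
                                legs[i, 0] = l - 1
                        elif u < 2.0 * p_diff:  # left leg rightward (shrink)
                            if (
                                l + 1 < r
                                and occ[l + 1] == 0
                                and not (ctcf_on and _ctcf_blocks(l + 1, 1, ctcf_ori, ctcf_occ))
                            ):
                                occ[l] = 0
                                occ[l + 1] = i + 1
                                legs[i, 0] = l + 1
                        l = legs[i, 0]
                        u2 = np.random.random()
                        if u2 < p_diff:  # right leg rightward
                            if (
                                r % n_sites < n_sites - 1
                                and occ[r + 1] == 0
                                and not (ctcf_on and _ctcf_blocks(r + 1, 1, ctcf_ori, ctcf_occ))
                            ):
                                occ[r] = 0
                                occ[r + 1] = i + 1
                                legs[i, 1] = r + 1
                        elif u2 < 2.0 * p_diff:  # right leg leftward (shrink)
                            if (
                                r - 1 > l
                                and occ[r - 1] == 0
                                and not (ctcf_on and _ctcf_blocks(r - 1, -1, ctcf_ori, ctcf_occ))
                            ):
                                occ[r] = 0
                                occ[r - 1] = i + 1
                                legs[i, 1] = r - 1

        # --- record ---
        if step >= n_burnin and (step - n_burnin) % record_every == 0:
            for i in range(N):
                rec_states[rec, i] = states[i]
                rec_legs[rec, i, 0] = legs[i, 0]
                rec_legs[rec, i, 1] = legs[i, 1]
            if ctcf_on:
                for j in range(ctcf_positions.shape[0]):
                    rec_ctcf[rec, j] = ctcf_occ[ctcf_positions[j]]
            rec += 1
    return deferred, rec


def simulate(
    config: LatticeConfig,
    topology: NetworkTopology,
    rates: RateSet,
    measurements: MeasurementSet,
    depletion: Mapping[str, float] | None = None,
) -> ExtrusionTrajectory:
    """Run the lattice simulator and return the recorded trajectory.

    Chemical transition probabilities are ``rate * dt`` with free pools
    frozen at the deterministic steady state of the (depleted) network —
    rates are identical to the values inferred from measurements.  The
    extruder count scales with the (depleted) RAD21 copy number.
    """
    ss = steady_state(topology, rates, measurements, "root_solve", depletion=depletion)
    pools = {r: ss.pool_concentration(r) for r in ss.free_pools}
    P = transition_matrix(topology, rates, pools, config.timestep_s)
    cum = P.cumsum(axis=1)
    cum[:, -1] = 1.0  # guard against round-off in the final bin

    states_order = topology.states
    free_idx = states_order.index(S.FREE)
    active = np.array([("NIPBL" in REGULATORS[s]) for s in states_order])

    n = config.n_extruders
    if n is None:
        n = default_extruder_count(config, measurements)
        if depletion and "RAD21" in depletion:
            n = max(1, int(round(n * (1.0 - depletion["RAD21"]))))

    rng = np.random.default_rng(config.seed)
    n_steps = config.burnin_steps + config.duration_steps
    chem_u = rng.random((n_steps, n))
    move_seed = int(rng.integers(0, 2**31 - 1))

    states = np.full(n, free_idx, dtype=np.int8)
    legs = np.full((n, 2), -1, dtype=np.int32)

    total = config.total_sites
    ctcf_ori = np.zeros(total, dtype=np.int8)
    ctcf_occ = np.zeros(total, dtype=np.bool_)
    ctcf_positions = np.zeros(0, dtype=np.int64)
    p_on = p_off = p_bypass = 0.0
    if config.ctcf is not None:
        c = config.ctcf
        ctcf_positions = np.asarray(c.positions, dtype=np.int64)
        if (ctcf_positions < 0).any() or (ctcf_positions >= total).any():
            raise ConfigurationError("CTCF positions outside the lattice")
        ori = c.orientations if c.orientations is not None else (2,) * len(c.positions)
        for g, o in zip(ctcf_positions, ori):
            ctcf_ori[g] = o
        p_on, p_off = c.rates(config.timestep_s)
        p_bypass = c.bypass_probability
        # start at equilibrium occupancy
        ctcf_occ[ctcf_positions] = rng.random(len(ctcf_positions)) < c.bound_fraction

    p_diff = 0.0
    diff_mode = 0
    if config.diffusion is not None:
        p_diff = config.diffusion.hop_probability(config.site_size_bp, config.timestep_s)
        diff_mode = 1 if config.diffusion.mode == "tandem" else 2

    n_rec = (config.duration_steps - 1) // config.record_every + 1
    rec_states = np.zeros((n_rec, n), dtype=np.uint8)
    rec_legs = np.zeros((n_rec, n, 2), dtype=np.int32)
    rec_ctcf = np.zeros((n_rec, len(ctcf_positions)), dtype=np.bool_)

    deferred, rec = _run_kernel(
        chem_u,
        move_seed,
        config.burnin_steps,
        config.record_every,
        cum,
        active,
        free_idx,
        config.n_sites,
        config.n_chains,
        states,
        legs,
        config.movement_enabled,
        p_diff,
        diff_mode,
        ctcf_ori,
        ctcf_occ,
        p_on,
        p_off,
        p_bypass,
        rec_states,
        rec_legs,
        rec_ctcf,
        ctcf_positions,
    )
    times = (
        np.arange(rec) * config.record_every * config.timestep_s
    )
    return ExtrusionTrajectory(
        times_s=times,
        legs=rec_legs[:rec],
        states=rec_states[:rec],
        states_order=states_order,
        config=config,
        seed=config.seed,
        deferred_loads=int(deferred),
        ctcf_occupancy=rec_ctcf[:rec] if len(ctcf_positions) else None,
    )


# ---------------------------------------------------------------------------
# analyses


@dataclass(frozen=True)
class Kymograph:
    """Leg positions versus time for one extruder, with state coloring."""

    times_s: np.ndarray
    left: np.ndarray  # site index, -1 unloaded
    right: np.ndarray
    state: np.ndarray  # index into states_order
    states_order: tuple[CohesinState, ...]

    def loop_size_sites(self) -> np.ndarray:
        size = self.right - self.left
        return np.where(self.left >= 0, size, 0)


def kymograph(trajectory: ExtrusionTrajectory, extruder_id: int) -> Kymograph:
    """Extract one extruder's leg trace; growth occurs only while active."""
    if not 0 <= extruder_id < trajectory.n_extruders:
        raise IndexError(f"extruder {extruder_id} not in trajectory")
    return Kymograph(
        times_s=trajectory.times_s,
        left=trajectory.legs[:, extruder_id, 0].copy(),
        right=trajectory.legs[:, extruder_id, 1].copy(),
        state=trajectory.states[:, extruder_id].copy(),
        states_order=trajectory.states_order,
    )


def _collision_pairs(legs: np.ndarray, loaded: np.ndarray, n_sites: int) -> list[tuple[int, int]]:
    """Pairs of loaded extruders with legs on adjacent sites of one chain."""
    site_owner: dict[int, int] = {}
    for i in np.flatnonzero(loaded):
        site_owner[int(legs[i, 0])] = i
        site_owner[int(legs[i, 1])] = i
    pairs = set()
    for g, i in site_owner.items():
        if g % n_sites == n_sites - 1:
            continue
        j = site_owner.get(g + 1)
        if j is not None and j != i:
            pairs.add((min(i, j), max(i, j)))
    return sorted(pairs)


def condensation_metrics(
    trajectory: ExtrusionTrajectory, frame: int = -1
) -> dict[str, float]:
    """1D condensation metrics of one recorded frame.

    ``loop_coverage``: fraction of lattice sites inside at least one loop
    interval; ``collided_fraction``: fraction of loaded extruders with a
    leg adjacent to another extruder's leg; ``percolation_score``:
    fraction of loaded extruders in the largest connected cluster of
    collided extruders (0 when no collisions exist, by convention).  All
    metrics are 0 when no extruder is loaded.
    """
    legs = trajectory.legs[frame]
    loaded = legs[:, 0] >= 0
    n_loaded = int(loaded.sum())
    if n_loaded == 0:
        return {"loop_coverage": 0.0, "collided_fraction": 0.0, "percolation_score": 0.0}
    n_sites = trajectory.config.n_sites
    total = trajectory.config.total_sites

    covered = np.zeros(total, dtype=bool)
    for i in np.flatnonzero(loaded):
        covered[legs[i, 0] : legs[i, 1] + 1] = True
    coverage = float(covered.mean())

    pairs = _collision_pairs(legs, loaded, n_sites)
    collided = {i for p in pairs for i in p}
    collided_fraction = len(collided) / n_loaded

    if not pairs:
        percolation = 0.0
    else:
        parent = {i: i for i in collided}

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in pairs:
            parent[find(a)] = find(b)
        sizes: dict[int, int] = {}
        for i in collided:
            r = find(i)
            sizes[r] = sizes.get(r, 0) + 1
        percolation = max(sizes.values()) / n_loaded
    return {
        "loop_coverage": coverage,
        "collided_fraction": collided_fraction,
        "percolation_score": percolation,
    }
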