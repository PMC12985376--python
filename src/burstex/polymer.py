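"""Coarse-grained polymer model coupled to lattice extrusion trajectories.

Each lattice site is one chromatin bead (default 2.5 kb, spatial extent
sigma ~ 50 nm).  Extruder leg pairs become harmonic bonds that are updated
every lattice step, with ``steps_per_update`` integration steps of the
polymer in between.  The integrator is the package's own overdamped
Langevin (Brownian) dynamics: harmonic chain and extruder bonds, a
polynomial soft repulsion that stays finite at overlap (so topology can
change, as appropriate for interphase chromatin at these scales), and
melt-like density imposed through a cubic periodic box at 20% bead volume
fraction.  Energies are in kT, lengths in sigma, and the mobility is 1, so
time is in units of sigma^2/D_0.

Contact analysis mirrors Hi-C: pairs of beads within a capture radius
R_c = 2.3 sigma (~115 nm) are contacts, and P(s) is the log-binned mean
contact frequency versus genomic separation over all intra-chain pairs and
frames.  Goodness of fit between two curves is
``R^2 = 1 - sum[(P_ref - P)^2] / sum[(P_ref - mean(P_ref))^2]`` over a
genomic range (default 50 kb to 10 Mb), with the compared curve anchored
to the reference at s = 50 kb.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

from .lattice import ExtrusionTrajectory
from .network import ConfigurationError

__all__ = [
    "PolymerConfig",
    "ConformationEnsemble",
    "ContactCurve",
    "equilibrate_melt",
    "run_coupled",
    "contacts",
    "p_of_s",
    "goodness_of_fit",
    "log_log_slope",
    "loop_enrichment",
    "shoulder_position",
]

#: Documented physical-time mapping of one integration time unit, obtained
#: by matching monomer (Rouse-regime) mobility to live-imaging estimates of
#: chromatin dynamics; shipped as a constant, not re-derived here.
TAU_3D_SECONDS = 5e-3


@dataclass(frozen=True)
class PolymerConfig:
    """Geometry, potentials and clock of the polymer stage."""

    bead_size_nm: float = 50.0
    bp_per_bead: float = 2500.0
    volume_fraction: float = 0.20
    timestep: float = 0.005  # integration step, units of sigma^2/D_0
    steps_per_update: int = 250  # integration steps per lattice step
    bond_k: float = 20.0  # harmonic chain-bond stiffness, kT/sigma^2
    bond_r0: float = 1.0  # rest length, sigma
    extruder_bond_k: float = 20.0  # defaults to the chain-bond value
    extruder_bond_r0: float = 1.0
    repulsion_eps: float = 5.0  # soft-core height at overlap, kT
    repulsion_cutoff: float = 1.0  # sigma
    contact_radius: float = 2.3  # sigma (~115 nm)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.volume_fraction < 0.64:
            raise ConfigurationError("volume_fraction must lie in (0, 0.64)")
        if self.timestep <= 0 or self.steps_per_update < 1:
            raise ConfigurationError("timestep and steps_per_update must be positive")

    def box_size(self, n_beads: int) -> float:
        """Cubic box edge (sigma) at the configured volume fraction."""
        return (n_beads * math.pi / 6.0 / self.volume_fraction) ** (1.0 / 3.0)


@dataclass
class ConformationEnsemble:
    """Recorded polymer frames with the extruder bonds active at each frame.

    ``frames[f]`` are bead coordinates in sigma, wrapped into the periodic
    box; ``extruder_bonds[f]`` is an (n_loaded, 2) array of bead index
    pairs; ``n_unloaded[f]`` counts unloaded extruders (used as the
    diffuse cohesin population by the microscopy stage).
    """

    frames: np.ndarray  # (F, N, 3) float32
    extruder_bonds: list[np.ndarray]
    n_unloaded: np.ndarray  # (F,) int
    box_size: float  # sigma
    n_chains: int
    n_sites: int
    bp_per_bead: float
    bead_size_nm: float
    seed: int

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_beads(self) -> int:
        return self.frames.shape[1]


# ---------------------------------------------------------------------------
# Brownian dynamics kernel


@njit(cache=False)
def _bd_run(pos, bonds, bond_k, bond_r0, eps, rc, L, dt, n_steps, seed):
    """Overdamped Langevin steps in a periodic box; modifies pos in place.

    Pair forces come from U = eps*(1-(r/rc)^2)^2 for r < rc (finite at
    overlap); bonds are harmonic with minimum-image displacements.
    """
    np.random.seed(seed)
    N = pos.shape[0]
    ncell = max(1, int(L / rc))
    cell_w = L / ncell
    head = np.empty(ncell * ncell * ncell, dtype=np.int64)
    nxt = np.empty(N, dtype=np.int64)
    force = np.empty((N, 3))
    inv_rc2 = 1.0 / (rc * rc)
    noise_amp = math.sqrt(2.0 * dt)

    for step in range(n_steps):
        # cell list
        head[:] = -1
        for i in range(N):
            cx = int(pos[i, 0] / cell_w) % ncell
            cy = int(pos[i, 1] / cell_w) % ncell
            cz = int(pos[i, 2] / cell_w) % ncell
            c = (cx * ncell + cy) * ncell + cz
            nxt[i] = head[c]
            head[c] = i

        force[:] = 0.0
        # soft repulsion over neighboring cells
        for cx in range(ncell):
            for cy in range(ncell):
                for cz in range(ncell):
                    c = (cx * ncell + cy) * ncell + cz
                    i = head[c]
                    while i >= 0:
                        for ox in range(-1, 2):
                            for oy in range(-1, 2):
                                for oz in range(-1, 2):
                                    nx = (cx + ox) % ncell
                                    ny = (cy + oy) % ncell
                                    nz = (cz + oz) % ncell
                                    c2 = (nx * ncell + ny) * ncell + nz
                                    j = head[c2]
                                    while j >= 0:
                                        if j > i:
                                            dx = pos[i, 0] - pos[j, 0]
                                            dy = pos[i, 1] - pos[j, 1]
                                            dz = pos[i, 2] - pos[j, 2]
                                            dx -= L * round(dx / L)
                                            dy -= L * round(dy / L)
                                            dz -= L * round(dz / L)
                                            r2 = dx * dx + dy * dy + dz * dz
                                            if r2 < rc * rc:
                                                # F = 4*eps/rc^2 * (1 - r^2/rc^2) * r_vec
                                                fpref = 4.0 * eps * inv_rc2 * (1.0 - r2 * inv_rc2)
                                                force[i, 0] += fpref * dx
                                                force[i, 1] += fpref * dy
                                                force[i, 2] += fpref * dz
                                                force[j, 0] -= fpref * dx
                                                force[j, 1] -= fpref * dy
                                                force[j, 2] -= fpref * dz
                                        j = nxt[j]
                        i = nxt[i]

        # harmonic bonds (chain + extruder)
        for b in range(bonds.shape[0]):
            i = bonds[b, 0]
            j = bonds[b, 1]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= L * round(dx / L)
            dy -= L * round(dy / L)
            dz -= L * round(dz / L)
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            if r > 1e-9:
                fpref = -bond_k * (r - bond_r0) / r
                force[i, 0] += fpref * dx
                force[i, 1] += fpref * dy
                force[i, 2] += fpref * dz
                force[j, 0] -= fpref * dx
                force[j, 1] -= fpref * dy
                force[j, 2] -= fpref * dz

        # Euler-Maruyama update + wrap
        for i in range(N):
            for d in range(3):
                x = pos[i, d] + dt * force[i, d] + noise_amp * np.random.normal()
                x = x % L
                pos[i, d] = x
    return 0


def _initial_conformation(
    n_chains: int, n_sites: int, L: float, rng: np.random.Generator
) -> np.ndarray:
    """Random-walk chains (step 1 sigma) wrapped into the periodic box."""
    pos = np.empty((n_chains * n_sites, 3))
    for c in range(n_chains):
        start = rng.random(3) * L
        steps = rng.normal(size=(n_sites, 3))
        steps /= np.linalg.norm(steps, axis=1)[:, None]
        steps[0] = 0.0
        pos[c * n_sites : (c + 1) * n_sites] = (start + np.cumsum(steps, axis=0)) % L
    return pos


def _chain_bonds(n_chains: int, n_sites: int) -> np.ndarray:
    bonds = []
    for c in range(n_chains):
        base = c * n_sites
        for i in range(n_sites - 1):
            bonds.append((base + i, base + i + 1))
    return np.array(bonds, dtype=np.int64)


def equilibrate_melt(
    n_chains: int,
    n_sites: int,
    config: PolymerConfig | None = None,
    seed: int = 0,
    n_steps: int = 20_000,
) -> np.ndarray:
    """Relax a loop-free melt; returns positions usable as a shared
    initial conformation for matched-condition coupled runs."""
    config = config or PolymerConfig()
    n_beads = n_chains * n_sites
    L = config.box_size(n_beads)
    rng = np.random.default_rng(seed)
    pos = _initial_conformation(n_chains, n_sites, L, rng)
    _bd_run(
        pos,
        _chain_bonds(n_chains, n_sites),
        config.bond_k,
        config.bond_r0,
        config.repulsion_eps,
        config.repulsion_cutoff,
        L,
        config.timestep,
        n_steps,
        int(rng.integers(0, 2**31 - 1)),
    )
    return pos


def run_coupled(
    trajectory: ExtrusionTrajectory,
    config: PolymerConfig | None = None,
    seed: int = 0,
    *,
    equilibration_updates: int = 20,
    record_every_updates: int = 1,
    max_frames: Optional[int] = None,
    initial_positions: Optional[np.ndarray] = None,
) -> ConformationEnsemble:
    """Advance the polymer through a recorded lattice trajectory.

    For each recorded lattice step, extruder leg pairs become harmonic
    bonds and ``config.steps_per_update`` integration steps are run.  The
    first ``equilibration_updates`` lattice steps relax the chain (frames
    not recorded); afterwards one frame is recorded every
    ``record_every_updates`` lattice steps, up to ``max_frames``.
    ``initial_positions`` (e.g. from :func:`equilibrate_melt`) seeds the
    conformation, letting matched conditions share one relaxed melt.

    Raises :class:`ConfigurationError` on resolution mismatch and
    ``RuntimeError`` (with a diagnostic) if the integration diverges.
    """
    config = config or PolymerConfig()
    if config.bp_per_bead != trajectory.config.site_size_bp:
        raise ConfigurationError(
            "bp_per_bead must equal the lattice site size "
            f"({config.bp_per_bead} vs {trajectory.config.site_size_bp})"
        )
    n_chains = trajectory.config.n_chains
    n_sites = trajectory.config.n_sites
    n_beads = n_chains * n_sites
    L = config.box_size(n_beads)
    rng = np.random.default_rng(seed)
    if initial_positions is not None:
        if initial_positions.shape != (n_beads, 3):
            raise ConfigurationError("initial_positions shape mismatch")
        pos = np.array(initial_positions, dtype=np.float64)
    else:
        pos = _initial_conformation(n_chains, n_sites, L, rng)
    chain_bonds = _chain_bonds(n_chains, n_sites)

    n_lattice = trajectory.legs.shape[0]
    frames: list[np.ndarray] = []
    frame_bonds: list[np.ndarray] = []
    frame_unloaded: list[int] = []

    for t in range(n_lattice):
        legs = trajectory.legs[t]
        loaded = legs[:, 0] >= 0
        ebonds = legs[loaded].astype(np.int64)
        bonds = np.vstack([chain_bonds, ebonds]) if len(ebonds) else chain_bonds
        _bd_run(
            pos,
            bonds,
            config.bond_k,
            config.bond_r0,
            config.repulsion_eps,
            config.repulsion_cutoff,
            L,
            config.timestep,
            config.steps_per_update,
            int(rng.integers(0, 2**31 - 1)),
        )
        if not np.isfinite(pos).all():
            raise RuntimeError(
                f"polymer integration diverged at lattice update {t}; "
                f"last finite frame had {len(frames)} recorded frames"
            )
        if t >= equilibration_updates and (t - equilibration_updates) % record_every_updates == 0:
            frames.append(pos.astype(np.float32).copy())
            frame_bonds.append(ebonds.copy())
            frame_unloaded.append(int((~loaded).sum()))
            if max_frames is not None and len(frames) >= max_frames:
                break

    if not frames:
        raise ConfigurationError("no frames recorded; lattice trajectory too short")
    return ConformationEnsemble(
        frames=np.stack(frames),
        extruder_bonds=frame_bonds,
        n_unloaded=np.array(frame_unloaded),
        box_size=L,
        n_chains=n_chains,
        n_sites=n_sites,
        bp_per_bead=trajectory.config.site_size_bp,
        bead_size_nm=config.bead_size_nm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# contacts and P(s)


def contacts(
    frame: np.ndarray, cutoff: float, box_size: Optional[float] = None
) -> np.ndarray:
    """Symmetric, self-exclusive bead pairs within the capture radius.

    ``frame`` is (N, 3) in sigma; with ``box_size`` the search uses
    periodic minimum-image distances.  Returns an (M, 2) int array with
    ``i < j``.
    """
    if cutoff <= 0:
        raise ConfigurationError("contact cutoff must be positive")
    if box_size is not None:
        pts = np.mod(frame, box_size)
        tree = cKDTree(pts, boxsize=box_size)
    else:
        tree = cKDTree(frame)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    return pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]


@dataclass
class ContactCurve:
    """Log-binned contact frequency versus genomic separation.

    ``s_bp`` are geometric bin centers; ``p`` the mean contact frequency
    of bead pairs in the bin (contacts per pair per frame); ``n_pairs``
    the number of (pair, frame) observations per bin.
    """

    s_bp: np.ndarray
    p: np.ndarray
    n_pairs: np.ndarray
    anchor_s_bp: float = 50_000.0

    def normalized_to(self, ref: "ContactCurve") -> "ContactCurve":
        """Rescale so this curve matches ``ref`` at the anchor separation."""
        i = int(np.argmin(np.abs(self.s_bp - self.anchor_s_bp)))
        j = int(np.argmin(np.abs(ref.s_bp - self.anchor_s_bp)))
        if self.p[i] <= 0 or ref.p[j] <= 0:
            raise ConfigurationError("cannot anchor curves with zero frequency at s0")
        return ContactCurve(
            self.s_bp, self.p * (ref.p[j] / self.p[i]), self.n_pairs, self.anchor_s_bp
        )


def p_of_s(
    ensemble: ConformationEnsemble,
    cutoff: Optional[float] = None,
    n_bins: int = 40,
    s_min_sites: int = 2,
) -> ContactCurve:
    """P(s): log-binned mean intra-chain contact frequency over all frames.

    Adjacent beads (|i - j| <= 1) are excluded.  The frequency in a bin is
    total contacts divided by the number of eligible (pair, frame)
    combinations in the bin.
    """
    if ensemble.n_frames == 0:
        raise ConfigurationError("empty ensemble")
    cutoff = cutoff if cutoff is not None else 2.3
    n_sites = ensemble.n_sites
    edges = np.unique(
        np.round(
            np.geomspace(s_min_sites, n_sites - 1, n_bins + 1)
        ).astype(np.int64)
    )
    counts = np.zeros(len(edges) - 1)
    for f in range(ensemble.n_frames):
        pairs = contacts(ensemble.frames[f], cutoff, ensemble.box_size)
        if len(pairs) == 0:
            continue
        same_chain = pairs[:, 0] // n_sites == pairs[:, 1] // n_sites
        pairs = pairs[same_chain]
        s = pairs[:, 1] % n_sites - pairs[:, 0] % n_sites
        s = s[s >= s_min_sites]
        counts += np.histogram(s, bins=edges)[0]
    # eligible pair count per separation, per chain
    seps = np.arange(n_sites)
    pairs_per_s = np.where(seps >= s_min_sites, n_sites - seps, 0)
    denom = np.array(
        [
            pairs_per_s[edges[i] : edges[i + 1]].sum()
            for i in range(len(edges) - 1)
        ],
        dtype=float,
    ) * ensemble.n_chains * ensemble.n_frames
    valid = denom > 0
    centers = np.sqrt(edges[:-1] * edges[1:]) * ensemble.bp_per_bead
    return ContactCurve(
        s_bp=centers[valid],
        p=np.where(valid, counts / np.maximum(denom, 1), 0.0)[valid],
        n_pairs=denom[valid],
    )


def goodness_of_fit(
    sim: ContactCurve,
    ref: ContactCurve,
    s_range: tuple[float, float] = (50_000.0, 10_000_000.0),
    normalize: bool = True,
) -> float:
    """R^2 of a simulated P(s) against a reference over a genomic range.

    Defined as ``1 - sum[(P_ref - P)^2] / sum[(P_ref - mean(P_ref))^2]``
    over bins shared by both curves in ``s_range``; may be negative for
    poor fits.  With ``normalize`` the simulated curve is first anchored to
    the reference at its anchor separation (50 kb by default).
    """
    if len(sim.s_bp) != len(ref.s_bp) or not np.allclose(sim.s_bp, ref.s_bp):
        raise ConfigurationError("curves must share their binning")
    if normalize:
        sim = sim.normalized_to(ref)
    mask = (ref.s_bp >= s_range[0]) & (ref.s_bp <= s_range[1])
    if not mask.any():
        raise ConfigurationError("no shared bins in the requested range")
    pexp = ref.p[mask]
    psim = sim.p[mask]
    ss_res = float(np.sum((pexp - psim) ** 2))
    ss_tot = float(np.sum((pexp - pexp.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


def log_log_slope(curve: ContactCurve, smooth: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """(s, d log P / d log s) with a small moving-average smoothing."""
    valid = curve.p > 0
    s = curve.s_bp[valid]
    p = curve.p[valid]
    slope = np.gradient(np.log(p), np.log(s))
    if smooth > 1 and len(slope) >= smooth:
        kern = np.ones(smooth) / smooth
        slope = np.convolve(slope, kern, mode="same")
    return s, slope


def loop_enrichment(
    curve: ContactCurve,
    control: ContactCurve,
    s_range: tuple[float, float] = (50_000.0, 1_500_000.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Log contact enrichment of a curve over a loop-free control.

    Returns ``(s, log(P/P_control))`` on the curve's separations within
    ``s_range``.  The range should stay below the finite-box mixing scale,
    where both curves flatten onto the background contact level and the
    ratio loses meaning.
    """
    v = curve.p > 0
    s, p = curve.s_bp[v], curve.p[v]
    vc = control.p > 0
    pc = np.interp(s, control.s_bp[vc], control.p[vc])
    m = (s >= s_range[0]) & (s <= s_range[1]) & (pc > 0)
    if not m.any():
        raise ConfigurationError("no shared separations in the requested range")
    return s[m], np.log(p[m] / pc[m])


def shoulder_position(
    curve: ContactCurve,
    control: ContactCurve,
    s_range: tuple[float, float] = (50_000.0, 1_500_000.0),
) -> tuple[float, float]:
    """Locate the extrusion 'shoulder' of a P(s) curve.

    Returns ``(position, prominence)``: the enrichment-weighted geometric
    mean separation of the positive log enrichment over a loop-free
    control (the scale the extrusion shoulder sits at), and the maximum
    log enrichment (its strength).  A prominence near zero means the
    shoulder has disappeared; larger positions mean contacts extend to
    larger genomic separations.
    """
    s, logr = loop_enrichment(curve, control, s_range)
    w = np.clip(logr, 0.0, None)
    prominence = float(logr.max())
    if w.sum() <= 0:
        return float("nan"), prominence
    position = float(np.exp((w * np.log(s)).sum() / w.sum()))
    return position, prominence
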