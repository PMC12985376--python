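"""Simulate multi-state loop extrusion on a 1D lattice.

Extruders carry the chemical state of the reaction network; only
NIPBL-bound extruders translocate (one site outward per leg per 1.25 s
step), everyone blocks everyone, and loading/unloading follow the network
fluxes.  The run below is a scaled-down version of the production
geometry (two independent 10-Mb chains at 2.5-kb resolution).
"""

import numpy as np

import burstex as bx
from burstex.lattice import LatticeConfig, condensation_metrics, kymograph, simulate

ms = bx.hela_wildtype()
survivor, _ = bx.select_network(ms)
topo, rates = survivor.topology, survivor.rates

cfg = LatticeConfig(
    n_sites=2000,        # 5 Mb per chain
    n_chains=2,
    duration_steps=2000,  # ~42 min of physical time
    burnin_steps=3000,
    record_every=4,
    seed=7,
)
traj = simulate(cfg, topo, rates, ms)
print(f"extruders: {traj.n_extruders} (copy-number scaling), frames: {len(traj.times_s)}")

loaded = traj.legs[:, :, 0] >= 0
i_rn = traj.states_order.index(bx.CohesinState.NIPBL_BOUND)
print(f"loaded fraction (time avg):  {loaded.mean():.3f}")
print(f"active / loaded (time avg):  {((traj.states == i_rn) & loaded).sum() / loaded.sum():.3f}")

m = condensation_metrics(traj)
print("condensation metrics (final frame):")
for k, v in m.items():
    print(f"  {k}: {v:.3f}")
# At wild-type density loops grow until they collide, so the collided
# fraction is high even though no vermicelli axis forms (percolation
# stays well below 1).

kym = kymograph(traj, extruder_id=0)
window = np.flatnonzero(kym.left >= 0)
if len(window):
    sizes = kym.loop_size_sites() * cfg.site_size_bp / 1e3
    print(f"\nextruder 0: loaded in {len(window)} frames, "
          f"final loop {sizes[window[-1]]:.0f} kb")
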