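# Methods

`burstex` models interphase cohesin as a multi-state molecular motor whose
activity is set by which regulatory protein is bound. This note documents
the model, its assumptions, the numerical choices, and what the shipped
simulations do and do not show.

## The reaction network

The core cohesin complex (tracked through its kleisin subunit RAD21) is in
one of five states: unloaded (`free`), bare loaded (`R`), or loaded with
exactly one of NIPBL (`RN`), PDS5 (`RP`) or WAPL (`RW`) bound. Three
assumptions make this tractable:

1. RAD21 loading/unloading stands in for the whole core complex;
2. regulators bind chromatin only through the loaded core complex;
3. regulators bind mutually exclusively (a single binding interface).

Mass-action kinetics over these states gives a coupled ODE system for the
five cohesin states and the three free regulator pools. A *topology* fixes
which transitions exist; the main family are cycles — one irreversible
loading transition into an entry state, three reversible exchange steps
along an ordering of the four loaded states, and one irreversible unload
from the exit state — eight rate constants in every case. A direct
exchange between two regulator-bound states is modelled as a concerted
swap (one release plus one binding in a single reaction), which preserves
mutual exclusivity without extra states. Since extrusion requires the
ATPase activity licensed by NIPBL, only `RN` extruders translocate:
loop growth is *bursty*, alternating active windows with pauses.

### Concentration convention

All species are expressed as fractions of the total RAD21 copy number of
the wild-type measurement set. Unimolecular rates are s⁻¹; bimolecular
rates are per (fraction · s). Depletions then rescale totals only — rate
constants, which encode the chemistry, never change. This is what turns
abundance perturbations into parameter-free predictions.

## Rate inference (exact inversion)

The model's sole empirical input is a table of nuclear copy number,
chromatin-bound fraction and FRAP residence time for RAD21, NIPBL, PDS5
and WAPL (the packaged wild-type HeLa values), plus a 19.539-Gb diploid
genome size for density conversions. Bound fractions alone pin the
equilibrium occupancies: each regulator's bound population occupies its
bound state, the RAD21 bound fraction fixes the loaded total, and the bare
state takes the remainder (negative remainder ⇒ the table is infeasible
for every topology — the "regulator-bound cannot exceed loaded" constraint).

With occupancies fixed, eight *linear* constraints determine the eight
rates exactly:

- four steady-state flux balances, one per loaded state;
- four residence-time constraints of Little's-law form,
  `gross binding flux × residence time = bound population`, one per
  protein. For a regulator with a single bound state this reduces to the
  familiar `dwell = 1/(total exit propensity)`; for RAD21 it is exactly
  equivalent to requiring the mean first-passage time from the loading
  entry state to the unloaded state to equal the measured residence time.
  The same form covers the PDS5+WAPL co-binding variant, where PDS5
  occupies two states.

The system is solved numerically (`numpy.linalg.solve`; residual required
< 1e-10) with an exact-rational `sympy` pathway for verification.
Residence times are interpreted as mean bound durations, the convention of
exponential-turnover FRAP fitting; no photobleaching or rebinding
corrections are applied.

## Topology selection (two-stage pruning)

All 24 cycle orderings are inverted and pruned:

- **Stage 1 (physical kinetics):** all eight rates ≥ 0 and all implied
  occupancies ≥ 0. Rates in `[-1e-12, 0]` are clamped to zero (guard
  against round-off in the exact solve); degenerate zero rates are not
  themselves grounds for rejection. Eight cycles survive.
- **Stage 2 (depletion signs):** with rates fixed, each regulator is
  depleted by 90% (an RNAi-like level) and the equilibrium recomputed; the
  RAD21 loaded fraction must fall under ΔNIPBL and rise under ΔPDS5 and
  ΔWAPL. One cycle survives: `RN-R-RP-RW` — NIPBL loads (and defines the
  active state), PDS5 competes for the bare complex and recruits WAPL,
  WAPL licenses unloading. The same selection holds in the full-knockout
  limit of the sign tests.

Alternative families are enumerated for comparison: all 64 fully
reversible tree networks (linear/branched/star), the NIPBL- and
PDS5-excursion cycles, and a PDS5+WAPL co-binding cycle. Every reversible
tree fails the ΔWAPL-increase requirement — with detailed balance, losing
a binding partner can only lower the loaded population — which is the
structural argument for distinct loading and unloading pathways. For the
co-binding variant the constraint bookkeeping is not uniquely dictated by
the five measured quantities; we let the co-bound state inherit the WAPL
residence time and aggregate the PDS5 constraints over both PDS5-containing
states. A one-at-a-time ±10% robustness scan over every table entry leaves
the selection unchanged.

## Steady state, residence times, motor observables

The equilibrium is unique; we solve it two ways and require agreement: a
root solve on the loaded-state balances (free cohesin and pools eliminated
by conservation; derivative max-norm < 1e-10) and ODE integration from a
fully unloaded population (LSODA, norm < 1e-8, horizon doubling up to
1e7 s). RAD21 residence times are mean first-passage times over the
loaded-state CTMC with pseudo-first-order propensities frozen at the
steady-state pools (linear solve; entry states weighted by loading flux);
an absent unload path reports `inf`. The mean extrusion rate is
`v = 2L/τ₁D × [RN]/[R]_loaded` with L = 2.5 kb and τ₁D = 1.25 s — the
lattice clock calibrated so the wild-type mean matches the ~1 kb/s
single-molecule estimate. At wild type the model gives an active-to-loaded
ratio of ≈ 25.9% (reported in the source literature as ≃26% in one place
and 27% in another) and ≈ 16.8% of all cohesin actively extruding.

The entry frequency into a state is its total steady-state influx per
loaded cohesin (equivalently, mean entries per loading window divided by
the cohesin residence time). For `RN` this evaluates to ≈ 0.216/min at
wild type. Note the value is forced by Little's law
(`influx = [RN]/τ_NIPBL`) whichever viable topology is chosen; the ~0.3/min
sometimes quoted for this quantity corresponds to a hazard-style
normalization by the loaded-but-inactive population (≈ 0.291/min).

## Stochastic sampling (discrete-time KMC)

The ensemble sampler is discrete-time: per step, a complex in state *s*
jumps to *s′* with probability `k·Δt` (times the mean-field free-pool
concentration for binding steps), with a guard that the total per-step
exit probability stays below 0.1 and an error instructing a smaller step
otherwise. Free pools are recomputed each step from the ensemble's own
bound counts, so population curves converge to the ODE as the ensemble
grows. The expectation of this sampler follows the deterministic
discrete-time map exactly (up to O(1/n) pool coupling); the map itself is
an Euler discretization of the ODE, differing from it transiently by
O(k·Δt). Equivalence tests therefore compare the sampler to the map at
3 binomial standard errors and separately bound the map-ODE gap (< 0.01
absolute occupancy at Δt = 1.25 s).

## Lattice extrusion

Chromatin is a set of independent chains of 2.5-kb sites; production runs
in the source work use 50 × 10-Mb chains, the shipped defaults are 2 ×
10-Mb (tests use smaller still; sizes are stated where used). The extruder
count follows nuclear copy-number scaling: total RAD21 per genome bp times
the simulated span (≈ 13.5 extruders/Mb, of which 65% are loaded at WT
steady state ⇒ ≈ 8.8 loaded/Mb). Each step: (1) every extruder updates its
chemical state by the KMC rule above, with pools frozen at the
deterministic steady state of the (possibly depleted) network — the
lattice inherits the inferred rates unchanged; (2) loading places both
legs on a uniformly chosen vacant adjacent pair (deferred and logged if
none exists), unloading vacates both sites; (3) every leg of every `RN`
extruder attempts one outward hop, rejected at occupied sites and chain
ends (per-leg blocking: one leg may advance while the other is stalled; a
failed hop is not retried within the step). Movement order is a fresh
random permutation each step; chemistry uses a dedicated random stream so
that disabling movement leaves the chemical series bit-identical.

Optional components: dynamic CTCF sites whose occupancy follows a
telegraph process reproducing a configured bound fraction and residence
time, blocking *active* legs only (bypass probability configurable,
orientation-sensitive blocking optional); and passive diffusion of loaded,
inactive extruders with per-direction hop probability `D·Δt/l²`
(D ≤ 0.5 kb²/s), either with both legs in tandem (loop size frozen) or
independently (loop-inverting hops rejected).

Condensation metrics on a frame: loop coverage (sites under ≥ 1 loop
interval), collided fraction (loaded extruders with a leg adjacent to
another's leg), and percolation score (largest connected cluster of
collided extruders over loaded extruders; 0 when there are no collisions).

## Polymer stage

Each lattice site is one bead (σ ≈ 50 nm, 2.5 kb). The integrator is the
package's own overdamped-Langevin (Brownian) dynamics in a cubic periodic
box at 20% bead volume fraction: harmonic chain bonds (k = 20 kT/σ²,
r₀ = 1σ), extruder bonds with the same constants created from the leg
pairs of each lattice frame, and a polynomial soft repulsion
`U = ε(1 − (r/r_c)²)²` (ε = 5 kT, r_c = 1σ) that stays finite at overlap so
chains can cross — appropriate at this coarse-graining. Units: kT = 1,
mobility 1, lengths in σ; the documented physical mapping of one time unit
is ~5 ms, a constant matched to live-imaging chromatin mobility rather
than re-derived here. The production-scale coupling ratio is 250
integration steps (dt = 0.005) per 1.25-s lattice step; shipped desk-scale
runs use 25 steps at dt = 0.02 (stable for these soft potentials) together
with a shared pre-relaxed melt as the initial conformation and several
hundred coupled equilibration updates — stated wherever used. This
preserves the ordinal contrasts tested while keeping runs to minutes.

Contacts are bead pairs within R_c = 2.3σ ≈ 115 nm (periodic KD-tree
search); P(s) is the log-binned mean intra-chain contact frequency over
all pairs and frames, excluding |i−j| ≤ 1 (nearest neighbors are in
permanent contact by construction). Goodness of fit between curves sharing
a binning is `R² = 1 − Σ(P_ref − P)²/Σ(P_ref − mean(P_ref))²` over
50 kb–10 Mb, after anchoring the compared curve to the reference at 50 kb.

Locating the extrusion "shoulder" needs care in a small periodic box: at
separations approaching the box scale (here ~2–3 Mb) every P(s) flattens
onto the background contact level ("mixing plateau"), which corrupts raw
log-log-slope maxima. We therefore measure the shoulder against a
loop-free control ensemble that shares the same initial melt and the same
number of coupled updates: the shoulder *position* is the
enrichment-weighted geometric-mean separation of the positive
`log(P/P_ctrl)` over 50 kb–1.5 Mb, and its *prominence* is the maximum log
enrichment. A prominence near zero means no shoulder; a larger position
means extrusion-driven contacts extend further. The raw smoothed log-log
slope remains available (`log_log_slope`).

In-silico microscopy rasterizes all beads (DNA channel) and both legs of
every loaded extruder plus uniformly scattered diffuse molecules matching
the unloaded cohesin count (cohesin channel) into 100-nm voxels covering
the periodic box, then blurs both with a 250-nm Gaussian (wrap mode). The
vermicelli score is the Pearson correlation of the two blurred volumes.

## What the shipped simulations show — and don't

The synthetic-data generator and packaged table emulate measurement tables
(positive copies, fractions in (0,1), residence times in seconds) and
perturbed variants; they do not emulate measurement *error*, paralog
heterogeneity (PDS5A/B are amalgamated), or cell-to-cell variability.
Desk-scale polymer runs (2 chains, ≤ 10 Mb, hundreds of frames, reduced
coupling ratio) support ordinal conclusions about the contact shoulder
under depletions, but not the production-scale quantitative Hi-C agreement
(R² > 0.99 against experimental curves), which requires ~200,000-monomer
ensembles and external Hi-C data and is out of scope here. The vermicelli
score has a sharper limitation at this scale: with two chains in a ~1.4-µm
box the soft-repulsion melt keeps the *total* DNA density homogeneous
(blurred-raster coefficient of variation ~0.03 in every condition), so
condensation morphology cannot register, and the Pearson score is
dominated by how the cohesin channel samples chromatin — clustered legs
(WAPL depletion) then *lower* the score. The score cleanly separates
conditions dominated by the diffuse pool (RAD21 depletion scores low) but
does not reproduce the WAPL-depletion increase seen at production scale
with ~50 condensing chromatids; resolving that ordering requires the
full-size system. CTCF barriers use genome-average occupancy kinetics, not
site-specific bound times. Extruder bypassing, trans-capture, asymmetric
extrusion, additional regulators (SA1/2, SCC4, Sororin, SMC3 acetylation)
and sister-chromatid cohesion are outside the model.

## Numerical footnotes

- Tolerances: inversion residual < 1e-10; root-solve derivative norm
  < 1e-10; ODE norm < 1e-8; method cross-agreement ≤ 1e-9.
- Rate clamp: values in [−1e-12, 0] are exact zeros; below is unphysical.
- Stage-2 depletion level: 0.9 (sign-consistent with the knockout limit).
- Degenerate inputs: infeasible tables yield infeasibility records, not
  exceptions; singular constraint systems likewise; an unreachable unload
  path reports an infinite residence time.
- Every stochastic entry point takes an explicit seed; derived kernel
  seeds are drawn below 2³¹ from a `numpy` Generator seeded by it.
- Predicted depletion responses at 90%: residence folds ≈ 9.3 (ΔWAPL) and
  ≈ 2.7 (ΔPDS5); loaded-fraction changes ≈ +44% and +16%; the NIPBL level
  best matching a 45% loaded-fraction reduction is 60%. These are computed
  by the test suite and acceptance script, not asserted constants.
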