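"""Analytical inversion of measurements to transition rates, and topology pruning.

For any candidate topology, the equilibrium occupancies of the cohesin
states are fixed directly by the measured bound fractions (a regulator's
bound population occupies its bound state; loaded total equals the RAD21
bound fraction; the bare state takes the remainder).  Writing the four
steady-state flux balances of the loaded states together with four
residence-time constraints — gross binding flux times residence time
equals bound population, for RAD21 and for each regulator — yields a
system of 8 *linear* equations in the 8 unknown rate constants, solved
exactly.

The two-stage pruning procedure then selects viable networks:

* stage 1 — physical kinetics: all 8 rates non-negative and all implied
  occupancies non-negative;
* stage 2 — qualitative depletion signs: with rates held fixed, the
  re-equilibrated RAD21 loaded fraction must decrease under NIPBL
  depletion and increase under PDS5 and under WAPL depletion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .measurements import (
    DEFAULT_GENOME_SIZE_BP,
    REGULATOR_PROTEINS,
    MeasurementSet,
    ProteinMeasurement,
)
from .network import (
    ConvergenceError,
    RateSet,
    SteadyState,
    abundances,
    residence_time,
    steady_state,
)
from .topology import (
    LOADED_STATES,
    REGULATORS,
    CohesinState,
    NetworkTopology,
    enumerate_cycles,
    enumerate_variants,
)

__all__ = [
    "InferenceResult",
    "implied_occupancies",
    "infer_rates",
    "infer_rates_symbolic",
    "prune",
    "robustness_scan",
    "implied_measurements",
    "pruning_report",
    "select_network",
]

S = CohesinState

#: Rates in [-RATE_CLAMP, 0] are treated as exact zeros (floating-point
#: guard on the exact linear solve); anything below is unphysical.
RATE_CLAMP = 1e-12

#: Depletion level used by the stage-2 sign tests (RNAi-like).
STAGE2_DEPLETION = 0.9


@dataclass
class InferenceResult:
    """Rates (or an infeasibility record) for one topology and measurement set."""

    topology: NetworkTopology
    rates: Optional[RateSet]
    implied: Optional[SteadyState]
    stage1_pass: bool
    stage2_pass: bool = False
    residual: float = math.nan
    failure_reason: str = ""

    @property
    def feasible(self) -> bool:
        return self.rates is not None and self.stage1_pass


def implied_occupancies(
    topology: NetworkTopology, measurements: MeasurementSet
) -> tuple[dict[CohesinState, float], dict[str, float]]:
    """Equilibrium occupancies and free pools fixed by the bound fractions.

    All values in inference concentration units (fractions of total RAD21).
    For the PDS5+WAPL co-binding state the occupancy equals the bound WAPL
    population, and the singly PDS5-bound state takes the remaining bound
    PDS5 (the co-bound state accounts for one bound copy of each).
    """
    f_r = measurements["RAD21"].bound_fraction
    bound = {r: measurements.bound_amount(r) for r in REGULATOR_PROTEINS}
    occ: dict[CohesinState, float] = {}
    remaining = dict(bound)
    for s in sorted(topology.loaded_states, key=lambda s: -len(REGULATORS[s])):
        regs = REGULATORS[s]
        if not regs:
            continue
        amount = min(remaining[r] for r in regs) if len(regs) > 1 else remaining[next(iter(regs))]
        occ[s] = amount
        for r in regs:
            remaining[r] -= amount
    occ[S.BARE] = f_r - sum(occ.values())
    occ[S.FREE] = 1.0 - f_r
    pools = {r: measurements.free_amount(r) for r in REGULATOR_PROTEINS}
    return occ, pools


def _linear_system(
    topology: NetworkTopology,
    measurements: MeasurementSet,
    occ: Mapping[CohesinState, float],
    pools: Mapping[str, float],
) -> tuple[np.ndarray, np.ndarray]:
    trans = topology.transitions
    loaded = topology.loaded_states
    # per-unit-rate equilibrium propensity of each transition
    coef = np.empty(len(trans))
    for j, t in enumerate(trans):
        v = occ[t.source]
        for r in t.consumed:
            v *= pools[r]
        coef[j] = v
    A = np.zeros((8, len(trans)))
    b = np.zeros(8)
    row = 0
    for s in loaded:  # flux balances
        for j, t in enumerate(trans):
            if t.target is s:
                A[row, j] += coef[j]
            if t.source is s:
                A[row, j] -= coef[j]
        row += 1
    for reg in REGULATOR_PROTEINS:  # regulator residence (Little's law)
        tau = measurements[reg].residence_time_s
        for j, t in enumerate(trans):
            if reg in t.consumed:
                A[row, j] += coef[j] * tau
        b[row] = sum(occ[s] for s in loaded if reg in REGULATORS[s])
        row += 1
    # cohesin residence: gross loading flux * tau = loaded population
    tau_r = measurements["RAD21"].residence_time_s
    for j, t in enumerate(trans):
        if t.source is S.FREE:
            A[row, j] += coef[j] * tau_r
    b[row] = measurements["RAD21"].bound_fraction
    return A, b


def infer_rates(
    topology: NetworkTopology, measurements: MeasurementSet
) -> InferenceResult:
    """Exactly invert a measurement table to the topology's 8 rate constants.

    Returns an :class:`InferenceResult` whose ``stage1_pass`` flag records
    whether all rates and implied occupancies are physical; a singular
    constraint system or negative implied occupancy yields an
    infeasibility record rather than an exception.  The round-trip
    guarantee holds for feasible results: re-solving the steady state and
    residence times at the inferred rates reproduces the input bound
    fractions and residence times.
    """
    occ, pools = implied_occupancies(topology, measurements)
    if occ[S.BARE] < -RATE_CLAMP or any(v < -RATE_CLAMP for v in occ.values()):
        return InferenceResult(
            topology, None, None, False,
            failure_reason="negative implied occupancy (regulator-bound exceeds loaded)",
        )
    A, b = _linear_system(topology, measurements, occ, pools)
    try:
        k = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return InferenceResult(
            topology, None, None, False, failure_reason="singular constraint system"
        )
    residual = float(np.abs(A @ k - b).max())
    stage1 = bool((k >= -RATE_CLAMP).all()) and residual < 1e-8
    k = np.where((k < 0) & (k >= -RATE_CLAMP), 0.0, k)
    rates = RateSet({t.key: float(v) for t, v in zip(topology.transitions, k)})
    implied = None
    if stage1:
        implied = steady_state(
            topology, rates, measurements, "root_solve",
            initial={s: v for s, v in occ.items()},
        )
    return InferenceResult(
        topology,
        rates,
        implied,
        stage1,
        residual=residual,
        failure_reason="" if stage1 else "negative transition rate",
    )


def infer_rates_symbolic(
    topology: NetworkTopology, measurements: MeasurementSet
) -> dict[str, float]:
    """Exact-rational solve of the same linear system via sympy.

    A documentation/verification pathway: the numeric and symbolic
    solutions must agree to 1e-10.  Returns rates keyed like
    :class:`~burstex.network.RateSet`.
    """
    import sympy as sp

    occ, pools = implied_occupancies(topology, measurements)
    A, b = _linear_system(topology, measurements, occ, pools)
    Am = sp.Matrix([[sp.Rational(float(x)) for x in row] for row in A])
    bm = sp.Matrix([sp.Rational(float(x)) for x in b])
    sol = Am.LUsolve(bm)
    return {
        t.key: float(sol[j]) for j, t in enumerate(topology.transitions)
    }


def _loaded_fraction_after(
    result: InferenceResult,
    measurements: MeasurementSet,
    depletion: Mapping[str, float],
) -> float:
    ss = steady_state(
        result.topology, result.rates, measurements, "root_solve", depletion=depletion
    )
    return ss.loaded_fraction


def prune(
    candidates: Iterable[InferenceResult],
    measurements: MeasurementSet,
    depletion_level: float = STAGE2_DEPLETION,
) -> list[InferenceResult]:
    """Two-stage pruning; returns the candidates passing both stages.

    Stage-2 flags are written onto the input results.  The sign tests
    re-equilibrate each stage-1 survivor with one regulator depleted by
    ``depletion_level`` (rates fixed) and require the loaded cohesin
    fraction to move in the experimentally observed direction: down for
    NIPBL, up for PDS5 and for WAPL.
    """
    wt_loaded = measurements["RAD21"].bound_fraction
    survivors = []
    for res in candidates:
        if not res.stage1_pass:
            continue
        ok = True
        for reg, sign in (("NIPBL", -1.0), ("PDS5", +1.0), ("WAPL", +1.0)):
            try:
                lf = _loaded_fraction_after(res, measurements, {reg: depletion_level})
            except ConvergenceError:
                ok = False
                res.failure_reason = f"steady state did not converge under {reg} depletion"
                break
            if sign * (lf - wt_loaded) <= 0.0:
                ok = False
                res.failure_reason = (
                    f"loaded fraction moves the wrong way under {reg} depletion"
                )
                break
        res.stage2_pass = ok
        if ok:
            survivors.append(res)
    return survivors


def select_network(
    measurements: MeasurementSet,
    include_variants: bool = False,
) -> tuple[InferenceResult, list[InferenceResult]]:
    """Run enumerate -> infer -> prune and return (survivor, all results).

    Raises :class:`LookupError` unless pruning selects exactly one network.
    """
    topologies = list(enumerate_cycles())
    if include_variants:
        topologies += enumerate_variants()
    results = [infer_rates(t, measurements) for t in topologies]
    survivors = prune(results, measurements)
    if len(survivors) != 1:
        raise LookupError(
            f"pruning selected {len(survivors)} networks, expected exactly 1"
        )
    return survivors[0], results


def pruning_report(results: Sequence[InferenceResult]) -> pd.DataFrame:
    """One row per topology: id, family, 8 rates, stage flags, failure reason."""
    rows = []
    for res in results:
        row: dict[str, object] = {
            "topology": res.topology.name,
            "family": res.topology.family,
        }
        for j, t in enumerate(res.topology.transitions):
            row[f"k{j + 1}"] = res.rates[t.key] if res.rates is not None else math.nan
        row["stage1_pass"] = res.stage1_pass
        row["stage2_pass"] = res.stage2_pass
        row["failure_reason"] = res.failure_reason
        rows.append(row)
    return pd.DataFrame(rows)


def implied_measurements(
    topology: NetworkTopology,
    rates: RateSet,
    copy_numbers: Mapping[str, float],
    genome_size_bp: float = DEFAULT_GENOME_SIZE_BP,
) -> MeasurementSet:
    """Measurement table a given network would produce at equilibrium.

    The self-inversion oracle for parameter-recovery tests: simulate a
    known rate set, read off the bound fractions and residence times it
    implies, and feed them back through :func:`infer_rates`.
    """
    rad = copy_numbers["RAD21"]
    base = MeasurementSet(
        {
            name: ProteinMeasurement(name, copies, 0.5, 1.0)
            for name, copies in copy_numbers.items()
        },
        genome_size_bp,
    )
    ss = steady_state(topology, rates, base, "root_solve")
    proteins = {}
    for name in copy_numbers:
        bf = ss.bound_fraction(name)
        tau = residence_time(topology, rates, ss, name)
        proteins[name] = ProteinMeasurement(name, copy_numbers[name], bf, tau)
    return MeasurementSet(proteins, genome_size_bp)


def robustness_scan(
    measurements: MeasurementSet,
    factors: Sequence[float] = (0.9, 1.0, 1.1),
    quantities: Sequence[str] = ("copy_number", "bound_fraction", "residence_time_s"),
) -> pd.DataFrame:
    """One-at-a-time multiplicative perturbation of every measurement entry.

    Each grid point rescales a single (protein, quantity) entry, re-runs
    infer + prune over the 24 cycles, and records the surviving topology
    count and identity.
    """
    from dataclasses import replace

    rows = []
    for protein in measurements.proteins:
        for qty in quantities:
            for f in factors:
                m = measurements[protein]
                value = getattr(m, qty) * f
                if qty == "bound_fraction" and not 0.0 < value < 1.0:
                    rows.append(
                        {
                            "protein": protein, "quantity": qty, "factor": f,
                            "n_survivors": 0, "selected": "",
                            "note": "bound fraction outside (0,1)",
                        }
                    )
                    continue
                proteins = dict(measurements.proteins)
                proteins[protein] = replace(m, **{qty: value})
                try:
                    ms = MeasurementSet(proteins, measurements.genome_size_bp)
                    results = [infer_rates(t, ms) for t in enumerate_cycles()]
                    survivors = prune(results, ms)
                except (ValueError, ConvergenceError) as e:
                    rows.append(
                        {
                            "protein": protein, "quantity": qty, "factor": f,
                            "n_survivors": 0, "selected": "", "note": str(e),
                        }
                    )
                    continue
                rows.append(
                    {
                        "protein": protein,
                        "quantity": qty,
                        "factor": f,
                        "n_survivors": len(survivors),
                        "selected": survivors[0].topology.name if len(survivors) == 1 else "",
                        "note": "",
                    }
                )
    return pd.DataFrame(rows)
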