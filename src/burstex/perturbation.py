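"""In-silico protein depletions with transition rates held fixed.

Mass-action rate constants subsume the chemistry of each transition and do
not depend on protein abundance, so the network predicts the consequences
of depleting (or over-expressing) any subunit by rescaling the totals,
re-solving the equilibrium with the wild-type rates untouched, and reading
off extrusion observables from the new steady state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .measurements import REGULATOR_PROTEINS, MeasurementSet
from .network import (
    ConfigurationError,
    RateSet,
    SteadyState,
    mean_extrusion_rate,
    residence_time,
    steady_state,
)
from .topology import NetworkTopology

__all__ = [
    "DepletionSpec",
    "PredictedObservables",
    "predict",
    "depletion_scan",
    "co_depletion",
    "fit_depletion_level",
]

PROTEINS = ("RAD21",) + REGULATOR_PROTEINS


@dataclass(frozen=True)
class DepletionSpec:
    """Per-protein depletion fractions: 0 = wild type, 0.9 = 90% depleted.

    Negative values over-express.  Resulting copy numbers must stay
    positive, so levels are restricted to ``< 1``.
    """

    levels: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", dict(self.levels))
        for name, level in self.levels.items():
            if name not in PROTEINS:
                raise ConfigurationError(f"unknown protein {name!r}")
            if level >= 1.0:
                raise ConfigurationError(
                    f"{name}: depletion {level} leaves no copies (must be < 1)"
                )

    @property
    def is_wildtype(self) -> bool:
        return all(v == 0.0 for v in self.levels.values())


@dataclass(frozen=True)
class PredictedObservables:
    """Extrusion observables at one perturbed equilibrium, with WT folds."""

    residence_time_s: float
    loaded_fraction: float
    extrusion_rate_bp_s: float
    regulator_bound_fraction: Mapping[str, float]
    regulator_residence_time_s: Mapping[str, float]
    residence_fold: float
    loaded_fraction_fold: float
    extrusion_rate_fold: float
    steady: SteadyState

    @property
    def processivity_bp(self) -> float:
        """Loop-size proxy: mean extrusion rate times residence time."""
        return self.extrusion_rate_bp_s * self.residence_time_s


def _observe(
    topology: NetworkTopology,
    rates: RateSet,
    measurements: MeasurementSet,
    depletion: Mapping[str, float],
) -> tuple[float, float, float, SteadyState]:
    ss = steady_state(topology, rates, measurements, "root_solve", depletion=depletion)
    tau = residence_time(topology, rates, ss, "RAD21")
    v = mean_extrusion_rate(ss) if ss.loaded_fraction > 0 else 0.0
    return tau, ss.loaded_fraction, v, ss


def predict(
    topology: NetworkTopology,
    wt_rates: RateSet,
    measurements: MeasurementSet,
    spec: DepletionSpec | Mapping[str, float] | None = None,
) -> PredictedObservables:
    """Observables at the re-equilibrated network under a depletion spec.

    Copy numbers are rescaled per the depletion spec, the steady state is recomputed
    with the wild-type rate constants unchanged, and all observables are
    derived from the new equilibrium.  The loaded fraction refers to the
    remaining cohesin (bound fraction, not absolute copies).
    """
    if spec is None:
        spec = DepletionSpec({})
    elif not isinstance(spec, DepletionSpec):
        spec = DepletionSpec(spec)
    tau0, lf0, v0, _ = _observe(topology, wt_rates, measurements, {})
    tau, lf, v, ss = _observe(topology, wt_rates, measurements, spec.levels)
    reg_bf = {r: ss.bound_fraction(r) for r in REGULATOR_PROTEINS}
    reg_tau = {r: residence_time(topology, wt_rates, ss, r) for r in REGULATOR_PROTEINS}
    return PredictedObservables(
        residence_time_s=tau,
        loaded_fraction=lf,
        extrusion_rate_bp_s=v,
        regulator_bound_fraction=reg_bf,
        regulator_residence_time_s=reg_tau,
        residence_fold=tau / tau0,
        loaded_fraction_fold=lf / lf0,
        extrusion_rate_fold=v / v0 if v0 > 0 else math.inf,
        steady=ss,
    )


def co_depletion(
    topology: NetworkTopology,
    wt_rates: RateSet,
    measurements: MeasurementSet,
    spec: DepletionSpec | Mapping[str, float],
) -> PredictedObservables:
    """Combinatorial depletion of two or more proteins (delegates to predict)."""
    if not isinstance(spec, DepletionSpec):
        spec = DepletionSpec(spec)
    if len(spec.levels) < 2:
        raise ConfigurationError("co_depletion requires at least two proteins")
    return predict(topology, wt_rates, measurements, spec)


def depletion_scan(
    topology: NetworkTopology,
    wt_rates: RateSet,
    measurements: MeasurementSet,
    protein: str,
    levels: Sequence[float],
) -> pd.DataFrame:
    """Observables along a grid of depletion levels for one protein.

    Returns a tidy table with per-level observables and fold changes, plus
    a ``direction`` column per observable in the frame attributes
    (monotonic-structure metadata: +1 increasing, -1 decreasing, 0 mixed).
    """
    if any(not -1e-12 <= lev <= 0.95 + 1e-9 for lev in levels):
        raise ConfigurationError("scan levels must lie within [0, 0.95]")
    rows = []
    for lev in levels:
        obs = predict(topology, wt_rates, measurements, {protein: float(lev)})
        rows.append(
            {
                "protein": protein,
                "level": float(lev),
                "residence_time_s": obs.residence_time_s,
                "loaded_fraction": obs.loaded_fraction,
                "extrusion_rate_bp_s": obs.extrusion_rate_bp_s,
                "residence_fold": obs.residence_fold,
                "loaded_fraction_fold": obs.loaded_fraction_fold,
                "extrusion_rate_fold": obs.extrusion_rate_fold,
                "processivity_bp": obs.processivity_bp,
            }
        )
    df = pd.DataFrame(rows).sort_values("level").reset_index(drop=True)

    def direction(col: str) -> int:
        d = np.diff(df[col].to_numpy())
        if (d >= 0).all():
            return 1
        if (d <= 0).all():
            return -1
        return 0

    df.attrs["directions"] = {
        col: direction(col)
        for col in ("residence_time_s", "loaded_fraction", "extrusion_rate_bp_s")
    }
    return df


def fit_depletion_level(
    topology: NetworkTopology,
    wt_rates: RateSet,
    measurements: MeasurementSet,
    protein: str,
    observable: str,
    experimental_value: float,
    levels: Sequence[float],
) -> tuple[float, bool]:
    """Depletion level best matching an experimental relative change.

    ``observable`` is one of ``residence_time_s``, ``loaded_fraction`` or
    ``extrusion_rate_bp_s``; ``experimental_value`` is the target relative
    change versus wild type (e.g. ``-0.45`` for a 45% reduction).  Returns
    ``(best_level, in_range)`` where ``in_range`` is False when the target
    lies outside the attainable range and the argmin clamps to a boundary
    of the grid.
    """
    if len(levels) == 0:
        raise ConfigurationError("empty depletion level grid")
    fold_col = {
        "residence_time_s": "residence_fold",
        "loaded_fraction": "loaded_fraction_fold",
        "extrusion_rate_bp_s": "extrusion_rate_fold",
    }[observable]
    df = depletion_scan(topology, wt_rates, measurements, protein, levels)
    rel = df[fold_col].to_numpy() - 1.0
    err = np.abs(rel - experimental_value)
    i = int(np.argmin(err))
    lo, hi = float(rel.min()), float(rel.max())
    in_range = lo - 1e-12 <= experimental_value <= hi + 1e-12
    return float(df["level"].iloc[i]), in_range
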