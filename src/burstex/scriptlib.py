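"""Headline-quantity recomputation shared by the CLI and acceptance script.

Everything here is recomputed from the packaged wild-type measurement
table at call time: topology enumeration and pruning, the wild-type
steady state, and the fixed-rate depletion predictions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .inference import infer_rates, prune, pruning_report
from .measurements import hela_wildtype
from .network import mean_extrusion_rate, residence_time, steady_state
from .perturbation import depletion_scan, fit_depletion_level, predict
from .topology import CohesinState, enumerate_cycles

__all__ = ["NetworkSummary", "compute_network_summary", "reproduce_report"]


@dataclass
class NetworkSummary:
    """Deterministic headline quantities of the network stage."""

    n_cycles: int
    n_stage1: int
    n_stage2: int
    survivor: str
    active_fraction_pct: float
    active_to_loaded_pct: float
    rn_entry_per_min: float
    loaded_density_per_mb: float
    rad21_residence_s: float
    extrusion_rate_bp_s: float
    wapl90_residence_fold: float
    pds5_90_residence_fold: float
    wapl90_loaded_increase_pct: float
    pds5_90_loaded_increase_pct: float
    nipbl_best_fit_depletion_pct: float
    results: list


def compute_network_summary() -> NetworkSummary:
    """Enumerate, invert, prune and predict from the packaged HeLa table."""
    ms = hela_wildtype()
    results = [infer_rates(t, ms) for t in enumerate_cycles()]
    survivors = prune(results, ms)
    n_stage1 = sum(r.stage1_pass for r in results)
    if len(survivors) != 1:
        raise RuntimeError(f"expected a unique survivor, found {len(survivors)}")
    surv = survivors[0]
    topo, rates = surv.topology, surv.rates

    ss = steady_state(topo, rates, ms)
    rn = CohesinState.NIPBL_BOUND
    obs_wapl = predict(topo, rates, ms, {"WAPL": 0.9})
    obs_pds5 = predict(topo, rates, ms, {"PDS5": 0.9})
    best_level, _ = fit_depletion_level(
        topo, rates, ms, "NIPBL", "loaded_fraction", -0.45,
        levels=np.arange(0.1, 0.91, 0.1),
    )
    return NetworkSummary(
        n_cycles=len(results),
        n_stage1=n_stage1,
        n_stage2=len(survivors),
        survivor=topo.name,
        active_fraction_pct=100.0 * ss.active_fraction,
        active_to_loaded_pct=100.0 * ss.active_to_loaded_ratio,
        rn_entry_per_min=60.0 * ss.entry_frequency[rn],
        loaded_density_per_mb=ms.loaded_density_per_mb(),
        rad21_residence_s=residence_time(topo, rates, ss, "RAD21"),
        extrusion_rate_bp_s=mean_extrusion_rate(ss),
        wapl90_residence_fold=obs_wapl.residence_fold,
        pds5_90_residence_fold=obs_pds5.residence_fold,
        wapl90_loaded_increase_pct=100.0 * (obs_wapl.loaded_fraction_fold - 1.0),
        pds5_90_loaded_increase_pct=100.0 * (obs_pds5.loaded_fraction_fold - 1.0),
        nipbl_best_fit_depletion_pct=100.0 * best_level,
        results=results,
    )


def reproduce_report(out_dir: Path, seed: int = 1) -> Path:
    """Write a markdown report + TSVs of the recomputed quantities."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    s = compute_network_summary()
    ms = hela_wildtype()
    surv = [r for r in s.results if r.stage2_pass][0]
    pruning_report(s.results).to_csv(out_dir / "pruning_report.tsv", sep="\t", index=False)
    surv.rates.to_json(out_dir / "rates.json")
    for protein in ("NIPBL", "PDS5", "WAPL", "RAD21"):
        df = depletion_scan(
            surv.topology, surv.rates, ms, protein, np.arange(0.0, 0.951, 0.025)
        )
        df.to_csv(out_dir / f"scan_{protein}.tsv", sep="\t", index=False)

    rows = [
        ("reaction cycles enumerated", s.n_cycles),
        ("stage-1 survivors (physical rates)", s.n_stage1),
        ("stage-2 survivors (depletion signs)", s.n_stage2),
        ("selected network", s.survivor),
        ("actively extruding fraction of all cohesin [%]", f"{s.active_fraction_pct:.2f}"),
        ("active-to-loaded ratio [%]", f"{s.active_to_loaded_pct:.2f}"),
        ("entries into RN per loaded cohesin [1/min]", f"{s.rn_entry_per_min:.3f}"),
        ("loaded cohesin density [1/Mb]", f"{s.loaded_density_per_mb:.2f}"),
        ("RAD21 residence time (round trip) [s]", f"{s.rad21_residence_s:.1f}"),
        ("mean extrusion rate [bp/s]", f"{s.extrusion_rate_bp_s:.0f}"),
        ("residence fold, 90% WAPL depletion", f"{s.wapl90_residence_fold:.2f}"),
        ("residence fold, 90% PDS5 depletion", f"{s.pds5_90_residence_fold:.2f}"),
        ("loaded-fraction increase, 90% WAPL depletion [%]", f"{s.wapl90_loaded_increase_pct:.1f}"),
        ("loaded-fraction increase, 90% PDS5 depletion [%]", f"{s.pds5_90_loaded_increase_pct:.1f}"),
        ("NIPBL depletion best matching 45% loaded reduction [%]", f"{s.nipbl_best_fit_depletion_pct:.0f}"),
    ]
    lines = ["# Recomputed headline quantities", ""]
    lines += [f"| {k} | {v} |" for k, v in [("quantity", "value"), ("---", "---")] + rows]
    path = out_dir / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path
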