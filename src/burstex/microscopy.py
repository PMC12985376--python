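"""In-silico fluorescence microscopy and the vermicelli score.

Chromatin (all beads) and cohesin (both legs of every loaded extruder,
plus uniformly scattered diffuse molecules matching the unloaded
population) are rasterized into a 3D voxel grid and blurred with a
Gaussian kernel approximating the microscope point-spread function.  The
vermicelli score is the Pearson correlation of the two blurred signals:
1 for perfectly overlapping cohesin and DNA foci (ideal vermicelli
condensation), ~0 for fully decorrelated diffuse signals.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter

from .network import ConfigurationError
from .polymer import ConformationEnsemble

__all__ = ["in_silico_microscopy", "vermicelli_score", "ensemble_vermicelli_score"]

DEFAULT_VOXEL_NM = 100.0
DEFAULT_BLUR_NM = 250.0


def in_silico_microscopy(
    frame: np.ndarray,
    extruder_legs: np.ndarray,
    n_unloaded: int,
    box_size: float,
    bead_size_nm: float = 50.0,
    voxel_nm: float = DEFAULT_VOXEL_NM,
    blur_nm: float = DEFAULT_BLUR_NM,
    grid_shape: Optional[int] = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize one conformation into (cohesin, DNA) fluorescence volumes.

    ``frame`` is (N, 3) bead coordinates in sigma; ``extruder_legs`` an
    (M, 2) array of loaded leg bead indices; ``n_unloaded`` diffuse
    cohesins are placed uniformly at random in the field of view.  The
    grid covers the periodic box (voxels of ``voxel_nm`` per side; pass
    ``grid_shape`` to override) and the Gaussian blur wraps around the
    box.  Coordinates are wrapped into the box before binning, so frames
    always fit the field of view.
    """
    rng = np.random.default_rng(rng)
    box_nm = box_size * bead_size_nm
    if grid_shape is None:
        grid_shape = max(8, int(round(box_nm / voxel_nm)))
    edges = np.linspace(0.0, box_nm, grid_shape + 1)

    def raster(points_nm: np.ndarray) -> np.ndarray:
        pts = np.mod(points_nm, box_nm)
        h, _ = np.histogramdd(pts, bins=(edges, edges, edges))
        return h

    dna = raster(frame * bead_size_nm)

    coh_points = []
    if len(extruder_legs):
        coh_points.append(frame[extruder_legs.reshape(-1)] * bead_size_nm)
    if n_unloaded > 0:
        coh_points.append(rng.random((int(n_unloaded), 3)) * box_nm)
    if not coh_points:
        raise ConfigurationError("no cohesin signal: no loaded legs and no diffuse pool")
    coh = raster(np.vstack(coh_points))

    sigma_vox = blur_nm / (box_nm / grid_shape)
    dna = gaussian_filter(dna, sigma=sigma_vox, mode="wrap")
    coh = gaussian_filter(coh, sigma=sigma_vox, mode="wrap")
    return coh, dna


def vermicelli_score(cohesin_raster: np.ndarray, dna_raster: np.ndarray) -> float:
    """Pearson correlation of the blurred cohesin and DNA signals.

    1 means proportional signals (complete overlap of foci); values near 0
    indicate full decorrelation.  Raises on an all-constant raster, where
    the correlation is undefined.
    """
    a = cohesin_raster.ravel()
    b = dna_raster.ravel()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ConfigurationError("vermicelli score undefined for a constant raster")
    return float(np.corrcoef(a, b)[0, 1])


def ensemble_vermicelli_score(
    ensemble: ConformationEnsemble,
    voxel_nm: float = DEFAULT_VOXEL_NM,
    blur_nm: float = DEFAULT_BLUR_NM,
    seed: int = 0,
    max_frames: Optional[int] = None,
) -> tuple[float, float]:
    """Mean and standard error of the vermicelli score across frames."""
    rng = np.random.default_rng(seed)
    scores = []
    n = ensemble.n_frames if max_frames is None else min(max_frames, ensemble.n_frames)
    for f in range(n):
        coh, dna = in_silico_microscopy(
            ensemble.frames[f],
            ensemble.extruder_bonds[f],
            int(ensemble.n_unloaded[f]),
            ensemble.box_size,
            ensemble.bead_size_nm,
            voxel_nm,
            blur_nm,
            rng=rng,
        )
        scores.append(vermicelli_score(coh, dna))
    arr = np.asarray(scores)
    se = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return float(arr.mean()), se
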