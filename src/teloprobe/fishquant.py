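"""smFISH stack quantification: segmentation, CLEAN spot calling, localization.

Single telomerase RNA molecules appear as diffraction-limited Gaussian
spots in the Cy3 channel; the nucleolus is marked by a Cy5 probe against
ITS1 and the nucleus by DAPI.  Compartments are segmented by global
intensity thresholding with small-object removal; spots are extracted by
a CLEAN loop — fit a 3D Gaussian at the brightest residual voxel,
subtract it, repeat until the residual maximum inside the cell falls
below the minimum acceptable single-fluorophore intensity.  Each spot is
assigned nucleolar (NO), nucleoplasmic (NP) or cytoplasmic (CYT)
localization by the compartment containing its centroid, with NO taking
precedence over NP over CYT.  Per-cell spot counts and compartment
fractions are compared between strains with the two-sample
Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats
from skimage.filters import threshold_otsu

from .synthetic import gaussian_spot

__all__ = [
    "CompartmentMasks",
    "Spot",
    "CellStats",
    "segment_compartments",
    "clean_detect",
    "classify_spot",
    "classify_spots",
    "summarize_cells",
    "compare_strains",
    "spots_to_frame",
]

MIN_VOXEL_OBJECT = 10  # connected components smaller than this are removed
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity in 3D


@dataclass
class CompartmentMasks:
    """Labeled 3D masks (same cell label across the three masks)."""

    cells: np.ndarray
    nuclei: np.ndarray
    nucleoli: np.ndarray


@dataclass
class Spot:
    """One detected spot with fitted Gaussian parameters."""

    cell_id: int
    z: float
    y: float
    x: float
    amplitude: float
    sigma_xy: float
    sigma_z: float
    integrated_intensity: float
    compartment: str = ""

    @property
    def centroid(self) -> tuple[float, float, float]:
        return (self.z, self.y, self.x)


def _threshold_mask(channel: np.ndarray, threshold, min_voxel_object: int, cells: np.ndarray):
    if threshold == "otsu":
        if channel.max() <= channel.min():
            warnings.warn("flat channel; mask is empty", stacklevel=3)
            return np.zeros(channel.shape, dtype=np.int32)
        thr = threshold_otsu(channel)
    else:
        thr = float(threshold)
    binary = channel > thr
    labeled, _ = ndimage.label(binary, structure=_STRUCT26)
    sizes = np.bincount(labeled.ravel())
    small = np.flatnonzero(sizes < min_voxel_object)
    binary[np.isin(labeled, small)] = False
    if not binary.any():
        warnings.warn("mask empty after small-object removal", stacklevel=3)
    # inherit per-cell labels; voxels outside any cell are dropped
    return np.where(binary, cells, 0).astype(np.int32)


def segment_compartments(
    channels: dict,
    cells: np.ndarray,
    threshold_method="otsu",
    min_voxel_object: int = MIN_VOXEL_OBJECT,
) -> CompartmentMasks:
    """Segment nucleus (DAPI) and nucleolus (Cy5) by intensity thresholding.

    ``threshold_method`` is "otsu" or a fixed numeric value (or a dict
    with per-channel entries "cy5"/"dapi").  Connected components
    (26-connectivity) smaller than ``min_voxel_object`` voxels are
    removed before labeling.
    """
    for name in ("cy5", "dapi"):
        if name not in channels:
            raise ValueError(f"channel {name!r} required for segmentation")
    cells = np.asarray(cells)
    if cells.shape != channels["dapi"].shape:
        raise ValueError("cell mask shape differs from channel shape")

    def thr_for(name):
        if isinstance(threshold_method, dict):
            return threshold_method.get(name, "otsu")
        return threshold_method

    nuclei = _threshold_mask(channels["dapi"], thr_for("dapi"), min_voxel_object, cells)
    nucleoli = _threshold_mask(channels["cy5"], thr_for("cy5"), min_voxel_object, cells)
    # a nucleolus must lie within the nucleus
    nucleoli = np.where(nuclei > 0, nucleoli, 0)
    return CompartmentMasks(cells=cells.astype(np.int32), nuclei=nuclei, nucleoli=nucleoli)


def _gaussian_model(params, zz, yy, xx):
    amp, z0, y0, x0, s_xy, s_z, bg = params
    return bg + amp * np.exp(
        -((zz - z0) ** 2) / (2 * s_z**2)
        - ((yy - y0) ** 2) / (2 * s_xy**2)
        - ((xx - x0) ** 2) / (2 * s_xy**2)
    )


def _fit_spot(residual, peak, psf_sigma, window_factor=4.0):
    """Least-squares 3D Gaussian fit in a window around ``peak``.

    Returns (amplitude, z0, y0, x0, sigma_xy, sigma_z, background) or
    None when the fit fails/diverges.
    """
    shape = residual.shape
    rz = int(np.ceil(window_factor * 2.0 * psf_sigma))
    rxy = int(np.ceil(window_factor * psf_sigma))
    zs = slice(max(0, peak[0] - rz), min(shape[0], peak[0] + rz + 1))
    ys = slice(max(0, peak[1] - rxy), min(shape[1], peak[1] + rxy + 1))
    xs = slice(max(0, peak[2] - rxy), min(shape[2], peak[2] + rxy + 1))
    window = residual[zs, ys, xs]
    zz, yy, xx = np.meshgrid(
        np.arange(zs.start, zs.stop),
        np.arange(ys.start, ys.stop),
        np.arange(xs.start, xs.stop),
        indexing="ij",
    )
    peak_val = residual[tuple(peak)]
    p0 = np.array(
        [peak_val - window.min(), peak[0], peak[1], peak[2], psf_sigma, 2 * psf_sigma,
         max(window.min(), 0.0)]
    )
    lo = [0.0, zs.start - 1, ys.start - 1, xs.start - 1, 0.3 * psf_sigma, 0.3 * psf_sigma, 0.0]
    hi = [
        4 * max(peak_val, 1e-9), zs.stop, ys.stop, xs.stop,
        4 * psf_sigma, 8 * psf_sigma, max(peak_val, 1e-9),
    ]
    p0 = np.clip(p0, lo, hi)
    try:
        res = optimize.least_squares(
            lambda p: (_gaussian_model(p, zz, yy, xx) - window).ravel(),
            p0, bounds=(lo, hi), max_nfev=200,
        )
    except Exception:
        return None
    if not np.all(np.isfinite(res.x)):
        return None
    return res.x


def clean_detect(
    cy3: np.ndarray,
    masks: CompartmentMasks,
    min_fluorophore_intensity: float,
    psf_sigma: float = 1.3,
    max_iterations: int = 10_000,
    trace: list | None = None,
) -> list[Spot]:
    """CLEAN spot extraction: sequential Gaussian subtraction per cell.

    In each iteration the brightest residual voxel inside the cell seeds
    a local 3D Gaussian fit; the fitted profile (without its background
    offset) is subtracted from the residual and recorded as a spot.  The
    loop stops when the residual maximum inside the cell falls below
    ``min_fluorophore_intensity``, the minimum acceptable intensity of a
    single fluorophore.  A non-convergent fit falls back to a
    fixed-sigma, peak-amplitude profile.  ``trace``, if given, collects
    the per-cell sequence of residual maxima, one list per cell.
    """
    if min_fluorophore_intensity <= 0:
        raise ValueError("min_fluorophore_intensity must be > 0")

    spots: list[Spot] = []
    residual = cy3.astype(float).copy()
    for cid in np.unique(masks.cells):
        if cid == 0:
            continue
        in_cell = masks.cells == cid
        cell_trace: list[float] = []
        if trace is not None:
            trace.append(cell_trace)
        for iteration in range(max_iterations + 1):
            if iteration == max_iterations:
                raise RuntimeError(
                    f"cell {cid}: CLEAN did not terminate in {max_iterations} iterations"
                )
            masked = np.where(in_cell, residual, -np.inf)
            peak = np.unravel_index(np.argmax(masked), residual.shape)
            peak_val = residual[peak]
            cell_trace.append(float(peak_val))
            if peak_val < min_fluorophore_intensity:
                break
            fit = _fit_spot(residual, np.array(peak), psf_sigma)
            if fit is None or fit[0] <= 0:
                # amplitude-only fallback at fixed PSF width
                fit = np.array(
                    [peak_val, peak[0], peak[1], peak[2], psf_sigma, 2 * psf_sigma, 0.0]
                )
            amp, z0, y0, x0, s_xy, s_z, _bg = fit
            profile = gaussian_spot(residual.shape, (z0, y0, x0), amp, s_xy, s_z)
            # never let subtraction raise the peak: enforce a decrement there
            if profile[peak] < 0.5 * peak_val:
                profile = gaussian_spot(
                    residual.shape, peak, peak_val, psf_sigma, 2 * psf_sigma
                )
                amp, (z0, y0, x0), s_xy, s_z = peak_val, peak, psf_sigma, 2 * psf_sigma
            residual -= profile
            # integrated intensity is the flux actually removed from the
            # image; away from stack boundaries this equals the analytic
            # Gaussian volume amp * (2*pi)^1.5 * sigma_xy^2 * sigma_z
            spots.append(
                Spot(
                    cell_id=int(cid),
                    z=float(z0), y=float(y0), x=float(x0),
                    amplitude=float(amp),
                    sigma_xy=float(s_xy), sigma_z=float(s_z),
                    integrated_intensity=float(profile.sum()),
                )
            )
        # refinement sweep: restore each spot into the residual and refit it
        # with its neighbours already removed, which unbiases fits whose
        # first-pass window contained another spot's core
        cell_spots = [s for s in spots if s.cell_id == cid]
        if len(cell_spots) > 1:
            for spot in cell_spots:
                old = gaussian_spot(
                    residual.shape, spot.centroid, spot.amplitude, spot.sigma_xy, spot.sigma_z
                )
                residual += old
                peak = tuple(
                    int(np.clip(round(c), 0, s - 1))
                    for c, s in zip(spot.centroid, residual.shape)
                )
                fit = _fit_spot(residual, np.array(peak), psf_sigma)
                if fit is None or fit[0] <= 0:
                    residual -= old
                    continue
                amp, z0, y0, x0, s_xy, s_z, _bg = fit
                refined = gaussian_spot(residual.shape, (z0, y0, x0), amp, s_xy, s_z)
                residual -= refined
                spot.z, spot.y, spot.x = float(z0), float(y0), float(x0)
                spot.amplitude = float(amp)
                spot.sigma_xy, spot.sigma_z = float(s_xy), float(s_z)
                spot.integrated_intensity = float(refined.sum())
    return _merge_components(spots, merge_radius=2.0 * psf_sigma)


def _merge_components(spots: list[Spot], merge_radius: float) -> list[Spot]:
    """Fold sub-resolution CLEAN components into their dominant spot.

    Components closer than ``merge_radius`` (in PSF units: z compressed
    by the 2x axial elongation) are one diffraction-limited source; the
    fainter component's flux is added to the brighter one.
    """
    kept: list[Spot] = []
    for spot in sorted(spots, key=lambda s: -s.amplitude):
        scaled = np.array([spot.z / 2.0, spot.y, spot.x])
        for other in kept:
            if other.cell_id != spot.cell_id:
                continue
            if np.linalg.norm(scaled - np.array([other.z / 2.0, other.y, other.x])) < merge_radius:
                other.integrated_intensity += spot.integrated_intensity
                break
        else:
            kept.append(spot)
    return kept


def classify_spot(spot: Spot, masks: CompartmentMasks) -> str | None:
    """NO > NP > CYT by centroid voxel; ``None`` if outside every cell."""
    voxel = tuple(
        int(np.clip(round(c), 0, s - 1))
        for c, s in zip(spot.centroid, masks.cells.shape)
    )
    if masks.cells[voxel] == 0:
        return None
    if masks.nucleoli[voxel] > 0:
        return "NO"
    if masks.nuclei[voxel] > 0:
        return "NP"
    return "CYT"


def classify_spots(spots: list[Spot], masks: CompartmentMasks) -> tuple[list[Spot], int]:
    """Classify in place; spots outside every cell are dropped (counted)."""
    kept: list[Spot] = []
    discarded = 0
    for spot in spots:
        comp = classify_spot(spot, masks)
        if comp is None:
            discarded += 1
        else:
            spot.compartment = comp
            kept.append(spot)
    return kept, discarded


@dataclass
class CellStats:
    """Spot counts and compartment fractions for one cell."""

    cell_id: int
    total: int
    counts: dict  # compartment -> count
    fractions: dict | None  # None when the cell has no spots


def summarize_cells(spots: list[Spot], masks: CompartmentMasks) -> list[CellStats]:
    """Per-cell totals, compartment counts and fractions.

    Cells without spots appear with ``fractions=None``; they contribute
    to spots-per-cell statistics but not to fraction averages.
    """
    cell_ids = [int(c) for c in np.unique(masks.cells) if c != 0]
    by_cell: dict[int, dict] = {cid: {"NO": 0, "NP": 0, "CYT": 0} for cid in cell_ids}
    for spot in spots:
        if spot.cell_id in by_cell and spot.compartment:
            by_cell[spot.cell_id][spot.compartment] += 1
    stats_list = []
    for cid in cell_ids:
        counts = by_cell[cid]
        total = sum(counts.values())
        fractions = (
            {k: v / total for k, v in counts.items()} if total > 0 else None
        )
        stats_list.append(CellStats(cell_id=cid, total=total, counts=counts, fractions=fractions))
    return stats_list


def _per_cell_arrays(stats_list: list[CellStats]):
    totals = np.array([s.total for s in stats_list], dtype=float)
    fracs = {
        comp: np.array([s.fractions[comp] for s in stats_list if s.fractions is not None])
        for comp in ("NO", "NP", "CYT")
    }
    return totals, fracs


def compare_strains(stats_a: list[CellStats], stats_b: list[CellStats]) -> dict:
    """Kolmogorov-Smirnov two-sample comparisons between strains.

    Tests per-cell total spot counts and per-cell compartment fractions;
    reports the D statistic, the p-value, mean and standard error of the
    mean per strain for each quantity.
    """
    if len(stats_a) < 2 or len(stats_b) < 2:
        raise ValueError("need at least 2 cells per strain")
    totals_a, fracs_a = _per_cell_arrays(stats_a)
    totals_b, fracs_b = _per_cell_arrays(stats_b)

    def ks_entry(x, y):
        res = stats.ks_2samp(x, y)
        return {
            "D": float(res.statistic),
            "p": float(res.pvalue),
            "mean_a": float(np.mean(x)) if len(x) else float("nan"),
            "sem_a": float(stats.sem(x)) if len(x) > 1 else float("nan"),
            "mean_b": float(np.mean(y)) if len(y) else float("nan"),
            "sem_b": float(stats.sem(y)) if len(y) > 1 else float("nan"),
            "n_a": int(len(x)),
            "n_b": int(len(y)),
        }

    report = {"spots_per_cell": ks_entry(totals_a, totals_b)}
    for comp in ("NO", "NP", "CYT"):
        report[f"fraction_{comp}"] = ks_entry(fracs_a[comp], fracs_b[comp])
    return report


def spots_to_frame(spots: list[Spot]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell": [s.cell_id for s in spots],
            "z": [round(s.z, 3) for s in spots],
            "y": [round(s.y, 3) for s in spots],
            "x": [round(s.x, 3) for s in spots],
            "amplitude": [round(s.amplitude, 3) for s in spots],
            "sigma_xy": [round(s.sigma_xy, 3) for s in spots],
            "sigma_z": [round(s.sigma_z, 3) for s in spots],
            "integrated_intensity": [round(s.integrated_intensity, 3) for s in spots],
            "compartment": [s.compartment for s in spots],
        }
    )
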