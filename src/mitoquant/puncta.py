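"""2D puncta assays: spot detection, mitophagy-reporter classification, cargo
co-localization, linescan FWHM, spot density on a mask, and ROI means.

Workflow mirrors the fixed-cell assays: compress the confocal z-stack to a
maximum-intensity projection, subtract background, segment puncta by intensity
threshold with a strict size filter (> 0.01 μm² by default), then apply the
assay-specific readout.  The acid-quenched mitophagy reporter is classified
per punctum from 1-μm line profiles: mCherry (peak − background)/background
must reach 2:1 while the GFP profile stays flat (a lack of GFP fluorescence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

__all__ = [
    "Punctum",
    "LinescanResult",
    "max_project",
    "subtract_background",
    "detect_puncta",
    "classify_mcherry_only",
    "linescan_fwhm",
    "classify_cargo",
    "puncta_density_on_mask",
    "region_mean_intensity",
    "parkin_positive_area",
]


@dataclass
class Punctum:
    """One detected diffraction-limited spot."""

    centroid: tuple[float, float]  # (y, x) μm
    area: float  # μm²
    peak: float  # counts, max pixel of the detection channel
    background: float  # counts, annulus median on the detection channel
    label: int = 0
    flags: dict = field(default_factory=dict)
    ratios: dict = field(default_factory=dict)  # channel -> (peak-bg)/bg


@dataclass
class LinescanResult:
    positions: np.ndarray  # μm along the line
    profile: np.ndarray  # counts
    peak_position: float  # μm
    fwhm: float  # μm (nan when undefined)
    defined: bool


def max_project(volume: np.ndarray) -> np.ndarray:
    """Per-pixel maximum over z of a single-channel stack."""
    volume = np.asarray(volume)
    if volume.ndim == 2:
        return volume
    if volume.ndim != 3:
        raise ValueError(f"expected (z,y,x) or (y,x), got ndim={volume.ndim}")
    return volume.max(axis=0)


def subtract_background(plane: np.ndarray, radius_um: float, pixel_size: float) -> np.ndarray:
    """Remove smooth background by greyscale opening with a disk (rolling-ball).

    ``radius_um`` must exceed the punctum radius so spots are not absorbed
    into the background estimate.  Output is clipped at zero.
    """
    r_px = radius_um / pixel_size
    if r_px < 1:
        raise ValueError(f"background radius {radius_um} μm is below one pixel ({pixel_size} μm)")
    footprint = morphology.disk(int(round(r_px)))
    background = morphology.opening(plane, footprint)
    return np.clip(plane - background, 0, None)


def detect_puncta(
    plane: np.ndarray,
    pixel_size: float,
    threshold: float | str = "auto",
    min_area: float = 0.01,
) -> list[Punctum]:
    """Segment suprathreshold connected components larger than ``min_area`` μm².

    Expects a background-subtracted plane.  Per punctum: intensity-weighted
    centroid (μm), area (μm², strict ``> min_area``), peak pixel value, and a
    local background as the median of an annulus starting one pixel outside
    the component's equivalent radius, three pixels wide.
    """
    plane = np.asarray(plane, dtype=float)
    if isinstance(threshold, str):
        if plane.max() == plane.min():
            return []
        if threshold == "auto":
            from skimage.filters import threshold_otsu

            threshold = threshold_otsu(plane)
        elif threshold == "halfmax":
            # half of the bright-signal level: separates diffraction-limited
            # spots from dimmer extended structures and their blur halos
            bg = np.median(plane)
            threshold = bg + 0.5 * (np.percentile(plane, 99.8) - bg)
        else:
            raise ValueError(f"unknown threshold mode {threshold!r}")
    mask = plane > float(threshold)
    labels = measure.label(mask, connectivity=2)
    px_area = pixel_size**2
    out: list[Punctum] = []
    for prop in measure.regionprops(labels, intensity_image=plane):
        area = prop.area * px_area
        if area <= min_area:
            continue
        comp = labels == prop.label
        r_eq = np.sqrt(prop.area / np.pi)
        inner = morphology.dilation(comp, morphology.disk(int(np.ceil(r_eq)) + 1))
        outer = morphology.dilation(comp, morphology.disk(int(np.ceil(r_eq)) + 4))
        annulus = outer & ~inner
        background = float(np.median(plane[annulus])) if annulus.any() else 0.0
        cy, cx = prop.centroid_weighted
        out.append(
            Punctum(
                centroid=((cy + 0.5) * pixel_size, (cx + 0.5) * pixel_size),
                area=float(area),
                peak=float(prop.intensity_max),
                background=background,
                label=int(prop.label),
            )
        )
    return out


def _line_profile(plane: np.ndarray, p0_px: np.ndarray, p1_px: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sample a line at pixel pitch with linear interpolation; returns (t_px, values)."""
    length = float(np.hypot(*(p1_px - p0_px)))
    n = max(int(np.ceil(length)), 1) + 1
    t = np.linspace(0.0, 1.0, n)
    coords = p0_px[:, None] + (p1_px - p0_px)[:, None] * t
    vals = ndimage.map_coordinates(np.asarray(plane, dtype=float), coords, order=1, mode="nearest")
    return t * length, vals


def _profile_ratio(plane: np.ndarray, centroid_um, direction, pixel_size: float, length_um: float = 1.0):
    """(peak − line-end background)/background along a centered line profile."""
    c_px = np.array([centroid_um[0] / pixel_size - 0.5, centroid_um[1] / pixel_size - 0.5])
    d = direction / np.linalg.norm(direction)
    half = (length_um / 2.0) / pixel_size
    p0 = c_px - d * half
    p1 = c_px + d * half
    ny, nx = plane.shape
    p0 = np.clip(p0, 0, [ny - 1, nx - 1])
    p1 = np.clip(p1, 0, [ny - 1, nx - 1])
    _, vals = _line_profile(plane, p0, p1)
    n_end = max(2, len(vals) // 8)
    background = float(np.mean(np.concatenate([vals[:n_end], vals[-n_end:]])))
    peak = float(vals.max())
    return peak, background


def classify_mcherry_only(
    punctum: Punctum,
    gfp_plane: np.ndarray,
    mcherry_plane: np.ndarray,
    pixel_size: float,
    rho_min: float = 2.0,
    gfp_absent_ratio: float = 0.5,
) -> Punctum:
    """Flag acidified reporter puncta: mCherry 2:1 over background, GFP absent.

    Ratios ρ = (peak − background)/background come from a 1-μm line profile
    through the punctum centroid, oriented toward the brightest neighboring
    pixel of the mCherry channel; background is the mean of the line ends.
    A non-positive background excludes the punctum with a reason code.
    """
    cy, cx = punctum.centroid
    iy = int(round(cy / pixel_size - 0.5))
    ix = int(round(cx / pixel_size - 0.5))
    ny, nx = np.asarray(mcherry_plane).shape
    iy, ix = np.clip(iy, 1, ny - 2), np.clip(ix, 1, nx - 2)
    nb = np.asarray(mcherry_plane)[iy - 1:iy + 2, ix - 1:ix + 2].copy()
    nb[1, 1] = -np.inf
    dy, dx = np.unravel_index(np.argmax(nb), nb.shape)
    direction = np.array([dy - 1.0, dx - 1.0])
    if not direction.any():
        direction = np.array([0.0, 1.0])
    rhos = {}
    for name, plane in (("mcherry", mcherry_plane), ("gfp", gfp_plane)):
        peak, background = _profile_ratio(plane, (cy, cx), direction, pixel_size)
        if background <= 0:
            punctum.flags["excluded"] = f"nonpositive background on {name}"
            punctum.flags["mcherry_only"] = False
            return punctum
        rhos[name] = (peak - background) / background
    punctum.ratios.update(rhos)
    punctum.flags["gfp_positive"] = rhos["gfp"] >= gfp_absent_ratio
    punctum.flags["mcherry_only"] = (
        rhos["mcherry"] >= rho_min and rhos["gfp"] < gfp_absent_ratio
    )
    return punctum


def linescan_fwhm(
    plane: np.ndarray,
    p0_um: tuple[float, float],
    p1_um: tuple[float, float],
    pixel_size: float,
) -> LinescanResult:
    """Full width at half maximum of an intensity linescan.

    The profile is sampled at pixel pitch with linear interpolation; the
    minimum is subtracted; the FWHM is the distance between the two half-max
    crossings bracketing the global peak (linearly interpolated).  A profile
    without a crossing on either side is flagged undefined.
    """
    p0 = np.asarray(p0_um, dtype=float)
    p1 = np.asarray(p1_um, dtype=float)
    if np.allclose(p0, p1):
        raise ValueError("p0 and p1 must differ")
    pos_px, vals = _line_profile(
        plane, p0 / pixel_size - 0.5, p1 / pixel_size - 0.5
    )
    pos = pos_px * pixel_size
    prof = vals - vals.min()
    i_peak = int(np.argmax(prof))
    half = prof[i_peak] / 2.0
    if prof[i_peak] <= 0:
        return LinescanResult(pos, vals, float(pos[i_peak]), float("nan"), False)

    def _cross(idx_range, reverse):
        seq = idx_range[::-1] if reverse else idx_range
        for i in seq:
            a, b = (i, i + 1) if not reverse else (i, i + 1)
            if (prof[a] - half) * (prof[b] - half) <= 0 and prof[a] != prof[b]:
                t = (half - prof[a]) / (prof[b] - prof[a])
                return pos[a] + t * (pos[b] - pos[a])
        return None

    left = _cross(range(0, i_peak), reverse=True)
    right = _cross(range(i_peak, len(prof) - 1), reverse=False)
    if left is None or right is None:
        return LinescanResult(pos, vals, float(pos[i_peak]), float("nan"), False)
    return LinescanResult(pos, vals, float(pos[i_peak]), float(right - left), True)


def classify_cargo(
    spots_a: np.ndarray, spots_b: np.ndarray, match_radius: float
) -> dict[str, int]:
    """Greedy nearest-pair matching of two spot lists (μm coordinates).

    Pairs within ``match_radius`` are matched closest-first (ties by lower
    index); matched pairs count as ``dual``, the rest as single-positive.
    """
    spots_a = np.atleast_2d(np.asarray(spots_a, dtype=float)) if len(spots_a) else np.empty((0, 2))
    spots_b = np.atleast_2d(np.asarray(spots_b, dtype=float)) if len(spots_b) else np.empty((0, 2))
    pairs = []
    for i, pa in enumerate(spots_a):
        for j, pb in enumerate(spots_b):
            d = float(np.linalg.norm(pa - pb))
            if d <= match_radius:
                pairs.append((d, i, j))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    dual = 0
    for d, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        dual += 1
    return {
        "A_only": len(spots_a) - dual,
        "B_only": len(spots_b) - dual,
        "dual": dual,
    }


def puncta_density_on_mask(
    spots_um: np.ndarray, mask: np.ndarray, pixel_size: float
) -> float:
    """Spots whose centroid falls on the mask, per μm² of mask area."""
    mask = np.asarray(mask, dtype=bool)
    area = float(mask.sum()) * pixel_size**2
    if area == 0:
        raise ValueError("mask area is zero; density undefined")
    spots_um = np.atleast_2d(np.asarray(spots_um, dtype=float)) if len(spots_um) else np.empty((0, 2))
    count = 0
    ny, nx = mask.shape
    for cy, cx in spots_um:
        iy = int(cy / pixel_size)
        ix = int(cx / pixel_size)
        if 0 <= iy < ny and 0 <= ix < nx and mask[iy, ix]:
            count += 1
    return count / area


def region_mean_intensity(plane: np.ndarray, cell_mask: np.ndarray) -> float:
    """Arithmetic mean intensity within a cell mask (TMRE / MitoSOX readout)."""
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise ValueError("empty cell mask")
    return float(np.asarray(plane, dtype=float)[cell_mask].mean())


def parkin_positive_area(
    plane: np.ndarray, threshold: float, cell_mask: np.ndarray, pixel_size: float
) -> float:
    """Area (μm²) of suprathreshold pixels within the cell mask."""
    plane = np.asarray(plane, dtype=float)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    return float(np.sum((plane >= threshold) & cell_mask)) * pixel_size**2
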