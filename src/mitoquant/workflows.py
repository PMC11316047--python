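"""Condition-comparison workflows: synthetic cohorts through the full pipelines.

Each function generates per-cell synthetic scenes for a control-like and a
KO-like condition, runs the corresponding detection pipeline on every cell,
and reduces the cohort to the effect-size estimate the fixed-cell assays
report (a fold change between conditions).  Seeds are split deterministically
from one base seed: cells 1..n get ``base + i`` (control) and
``base + n + i`` (KO).
"""

from __future__ import annotations

import numpy as np

from .puncta import (
    classify_mcherry_only,
    detect_puncta,
    linescan_fwhm,
    max_project,
    parkin_positive_area,
    subtract_background,
)
from .synth import generate_scene, preset, render_spot

__all__ = [
    "lc3_puncta_counts",
    "lc3_fold_change",
    "parkin_areas",
    "parkin_fold_change",
    "cox8_mcherry_only_counts",
    "cox8_fold_change",
    "fwhm_worked_example",
]


def _condition_seeds(base_seed: int, n_cells: int) -> tuple[list[int], list[int]]:
    return (
        [base_seed + i for i in range(1, n_cells + 1)],
        [base_seed + n_cells + i for i in range(1, n_cells + 1)],
    )


def lc3_puncta_counts(condition: str, seeds) -> np.ndarray:
    """Per-cell LC3 puncta counts: MIP → background subtraction → threshold
    → strict >0.01 μm² size filter → count."""
    counts = []
    for s in seeds:
        vol, _ = generate_scene(preset("lc3", condition, seed=s))
        px = vol.voxel_size[2]
        mip = max_project(vol.channel("lc3"))
        sub = subtract_background(mip, 0.5, px)
        counts.append(len(detect_puncta(sub, px, threshold="auto", min_area=0.01)))
    return np.array(counts)


def lc3_fold_change(base_seed: int = 0, n_cells: int = 30) -> dict:
    ctrl_seeds, ko_seeds = _condition_seeds(base_seed, n_cells)
    ctrl = lc3_puncta_counts("control", ctrl_seeds)
    ko = lc3_puncta_counts("ko", ko_seeds)
    return {
        "control_median": float(np.median(ctrl)),
        "ko_median": float(np.median(ko)),
        "fold": float(np.median(ko) / np.median(ctrl)),
        "n": n_cells,
    }


#: fixed analysis threshold for the Parkin channel, identical across
#: conditions (half of the accumulation plateau over the camera baseline)
PARKIN_THRESHOLD = 250.0


def parkin_areas(condition: str, seeds) -> np.ndarray:
    """Per-cell thresholded Parkin-positive area (μm²) within the cell mask."""
    areas = []
    for s in seeds:
        vol, truth = generate_scene(preset("parkin", condition, seed=s))
        px = vol.voxel_size[2]
        mip = max_project(vol.channel("parkin"))
        areas.append(parkin_positive_area(mip, PARKIN_THRESHOLD, truth.cell_mask, px))
    return np.array(areas)


def parkin_fold_change(base_seed: int = 0, n_cells: int = 30) -> dict:
    ctrl_seeds, ko_seeds = _condition_seeds(base_seed, n_cells)
    ctrl = parkin_areas("control", ctrl_seeds)
    ko = parkin_areas("ko", ko_seeds)
    return {
        "control_median": float(np.median(ctrl)),
        "ko_median": float(np.median(ko)),
        "fold": float(np.median(ko) / np.median(ctrl)),
        "n": n_cells,
    }


def cox8_mcherry_only_counts(condition: str, seeds) -> np.ndarray:
    """Per-cell acidified-reporter puncta: detect on mCherry, classify each
    punctum by line-profile ratios (mCherry ≥ 2:1 over background, GFP absent)."""
    counts = []
    for s in seeds:
        vol, _ = generate_scene(preset("cox8_48h", condition, seed=s))
        px = vol.voxel_size[2]
        mch = max_project(vol.channel("mcherry"))
        gfp = max_project(vol.channel("gfp"))
        sub = subtract_background(mch, 0.5, px)
        spots = detect_puncta(sub, px, threshold="auto", min_area=0.01)
        n = 0
        for spot in spots:
            classify_mcherry_only(spot, gfp, mch, px, rho_min=2.0, gfp_absent_ratio=0.5)
            n += bool(spot.flags.get("mcherry_only"))
        counts.append(n)
    return np.array(counts)


def cox8_fold_change(base_seed: int = 0, n_cells: int = 30) -> dict:
    ctrl_seeds, ko_seeds = _condition_seeds(base_seed, n_cells)
    ctrl = cox8_mcherry_only_counts("control", ctrl_seeds)
    ko = cox8_mcherry_only_counts("ko", ko_seeds)
    return {
        "control_mean": float(ctrl.mean()),
        "ko_mean": float(ko.mean()),
        "fold": float(ko.mean() / ctrl.mean()),
        "n": n_cells,
    }


def fwhm_worked_example(sigma_um: float = 0.0637, pixel_size: float = 0.02) -> float:
    """FWHM (μm) of a rendered noiseless Gaussian spot via the linescan
    operator (horizontal line through the center)."""
    center = 1.0
    vol = render_spot((center, center), sigma_um, 500.0, (100, 100), pixel_size)
    res = linescan_fwhm(vol.data[0], (center, 0.1), (center, 1.9), pixel_size)
    return float(res.fwhm)
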