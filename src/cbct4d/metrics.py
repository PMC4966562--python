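"""Image-quality measurement suite.

Implements the QA metrics evaluated across the gantry-speed sweep:

* raw square-wave modulation vs spatial frequency from bar-pattern line
  profiles, with a Gaussian model MTF(f) = exp(-f^2 / (2 sigma^2)) fitted to
  the raw points; the maximal spatial resolution f_max is where the fitted
  MTF crosses 10%, f_max = sigma * sqrt(2 ln 10);
* contrast-to-noise ratio CNR = |mean_s - mean_bg| / sd_bg of the 1.5 cm
  low-contrast insert, averaged over slices;
* uniformity index UI = max - min of five ROI mean HU values (center plus
  four peripheral ROIs 5 cm away), averaged over slices;
* HU sensitivity: per-insert mean HU difference from a static baseline scan;
* excursion of the air sensitometry insert across phase volumes (max - min
  z-centroid of sub-threshold voxels) with percent difference and RMSE
  against the 3.0 cm ground truth;
* square-root-of-mAs normalization used to compare protocols at equal noise
  budget.

Raw modulation is computed on HU + 1000 (non-negative attenuation-like
values, so the denominator cannot vanish near air) and normalized by the
nominal bar/background modulation so an unblurred profile scores 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from scipy.optimize import curve_fit

from .errors import InsertDetectionError, MtfFitError
from .reconstruction import VoxelVolume

EXCURSION_TRUTH_CM = 3.0
AIR_THRESHOLD_HU = -500.0
F_MAX_SIGMA_RATIO = math.sqrt(2.0 * math.log(10.0))  # ~2.146


# ---------------------------------------------------------------------------
# Regions of interest
# ---------------------------------------------------------------------------

@dataclass
class RoiSpec:
    """In-plane ROI replicated over a range of axial slices.

    ``kind`` is ``disk`` (dimensions: radius), ``annulus`` (inner, outer
    radius) or ``box`` (half-width x, half-width y); dimensions in cm,
    ``center`` is the in-plane (x, y) position, ``slice_range`` a half-open
    (lo, hi) range of z indices (None = all slices).
    """

    kind: str
    center: tuple
    dimensions: tuple
    slice_range: tuple | None = None

    def __post_init__(self):
        if self.kind not in ("disk", "annulus", "box"):
            raise ValueError(f"unknown ROI kind '{self.kind}'")
        self.dimensions = tuple(float(d) for d in self.dimensions)
        if any(d <= 0 for d in self.dimensions):
            raise ValueError("ROI dimensions must be positive")
        self.center = (float(self.center[0]), float(self.center[1]))

    def _radius_bound(self) -> float:
        if self.kind == "disk":
            return self.dimensions[0]
        if self.kind == "annulus":
            return self.dimensions[1]
        return math.hypot(*self.dimensions[:2])

    def mask_inplane(self, volume: VoxelVolume) -> np.ndarray:
        xs, ys, _ = volume.axis_centers()
        cx, cy = self.center
        r = self._radius_bound()
        if (cx - r < xs[0] - 1e-9 or cx + r > xs[-1] + 1e-9
                or cy - r < ys[0] - 1e-9 or cy + r > ys[-1] + 1e-9):
            raise ValueError("ROI extends outside the volume in-plane bounds")
        dx = xs[:, None] - cx
        dy = ys[None, :] - cy
        if self.kind == "disk":
            return dx * dx + dy * dy <= self.dimensions[0] ** 2
        if self.kind == "annulus":
            r2 = dx * dx + dy * dy
            return (r2 >= self.dimensions[0] ** 2) \
                & (r2 <= self.dimensions[1] ** 2)
        return (np.abs(dx) <= self.dimensions[0]) \
            & (np.abs(dy) <= self.dimensions[1])

    def slice_indices(self, volume: VoxelVolume) -> np.ndarray:
        nz = volume.values.shape[2]
        if self.slice_range is None:
            return np.arange(nz)
        lo, hi = self.slice_range
        if lo < 0 or hi > nz or lo >= hi:
            raise ValueError("slice_range outside volume")
        return np.arange(lo, hi)

    def slice_means(self, volume: VoxelVolume) -> np.ndarray:
        mask = self.mask_inplane(volume)
        if not mask.any():
            raise ValueError("ROI covers no voxels at this grid resolution")
        return np.array([volume.values[:, :, iz][mask].mean()
                         for iz in self.slice_indices(volume)])


def _check_same_grid(a: VoxelVolume, b: VoxelVolume) -> None:
    if (a.values.shape != b.values.shape or a.spacing != b.spacing
            or a.origin != b.origin):
        raise ValueError("volumes are not on the same grid")


# ---------------------------------------------------------------------------
# Spatial resolution (square-wave modulation -> Gaussian MTF -> f_max)
# ---------------------------------------------------------------------------

@dataclass
class MtfCurve:
    frequencies: np.ndarray   # lp/cm
    raw_values: np.ndarray    # in [0, 1]
    sigma: float              # lp/cm
    r_squared: float
    f_max: float              # lp/cm, 10% crossing
    excluded: list = field(default_factory=list)  # unresolvable frequencies


def mtf_raw(volume: VoxelVolume, bar_groups, n_lines: int = 5,
            samples_per_cycle: int = 40):
    """Raw modulation per bar group from averaged line profiles.

    For each group, line intensity profiles are taken through the bars
    perpendicular to their long axis (``n_lines`` parallel lines averaged,
    over the central half of the bar length and height), shifted by +1000 HU,
    and reduced to (mean of per-cycle maxima - mean of per-cycle minima) /
    (sum of the two), normalized by the group's nominal modulation. Groups
    whose bar width is not resolved by at least two in-plane samples are
    excluded and reported separately.

    Returns ``(frequencies, raw_values, excluded_frequencies)``.
    """
    spacing_xy = max(volume.spacing[0], volume.spacing[1])
    freqs, raws, excluded = [], [], []
    for bg in bar_groups:
        if bg.bar_width < 2.0 * spacing_xy:
            excluded.append(bg.frequency)
            continue
        th = math.radians(bg.orientation)
        axis = np.array([math.cos(th), math.sin(th)])
        perp = np.array([-math.sin(th), math.cos(th)])
        ext = bg.n_cycles * bg.cycle_length
        t = np.linspace(-ext / 2, ext / 2, bg.n_cycles * samples_per_cycle,
                        endpoint=False)
        offsets = np.linspace(-bg.bar_length / 4, bg.bar_length / 4, n_lines)
        z_offsets = np.linspace(-bg.bar_height / 4, bg.bar_height / 4, 3)
        profiles = []
        for off in offsets:
            for zoff in z_offsets:
                pts = (np.array(bg.center)[None, :]
                       + t[:, None] * np.r_[axis, 0.0][None, :]
                       + off * np.r_[perp, 0.0][None, :])
                pts[:, 2] += zoff
                idx = (pts - np.array(volume.origin)) / np.array(volume.spacing)
                profiles.append(map_coordinates(volume.values, idx.T, order=1,
                                                mode="nearest"))
        prof = np.mean(profiles, axis=0) + 1000.0
        cyc = prof.reshape(bg.n_cycles, samples_per_cycle)
        if bg.n_cycles >= 4:
            # interior cycles only: the outermost gap borders open
            # background instead of a neighbouring bar and dips deeper
            cyc = cyc[1:-1]
        hu_max = cyc.max(axis=1).mean()
        hu_min = cyc.min(axis=1).mean()
        raw = (hu_max - hu_min) / (hu_max + hu_min)
        m0 = (bg.bar_hu - bg.background_hu) \
            / (bg.bar_hu + bg.background_hu + 2000.0)
        freqs.append(bg.frequency)
        raws.append(raw / m0)
    return np.asarray(freqs), np.asarray(raws), excluded


def fit_mtf_gaussian(frequencies, raw_values):
    """Least-squares fit of exp(-f^2/(2 sigma^2)); returns (sigma, R^2)."""
    f = np.asarray(frequencies, dtype=float)
    y = np.asarray(raw_values, dtype=float)
    if len(f) < 3:
        raise MtfFitError(f"need at least 3 MTF points, got {len(f)}")

    def model(x, sigma):
        return np.exp(-x ** 2 / (2.0 * sigma ** 2))

    try:
        popt, _ = curve_fit(model, f, y, p0=[max(f.max() / 2.0, 1e-3)],
                            maxfev=10_000)
    except RuntimeError as exc:
        raise MtfFitError(
            f"Gaussian MTF fit did not converge on {len(f)} points "
            f"(f range {f.min():.2f}-{f.max():.2f} lp/cm): {exc}") from exc
    sigma = float(abs(popt[0]))
    resid = y - model(f, sigma)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return sigma, r2


def f_max_10pct(sigma: float) -> float:
    """Frequency (lp/cm) where the Gaussian MTF crosses 10%."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return sigma * F_MAX_SIGMA_RATIO


def mtf_curve(volume: VoxelVolume, bar_groups, **kwargs) -> MtfCurve:
    """Full resolution analysis: raw modulation, Gaussian fit, f_max."""
    freqs, raws, excluded = mtf_raw(volume, bar_groups, **kwargs)
    sigma, r2 = fit_mtf_gaussian(freqs, raws)
    return MtfCurve(frequencies=freqs, raw_values=raws, sigma=sigma,
                    r_squared=r2, f_max=f_max_10pct(sigma),
                    excluded=excluded)


# ---------------------------------------------------------------------------
# CNR, uniformity, HU sensitivity
# ---------------------------------------------------------------------------

def cnr(volume: VoxelVolume, roi_signal: RoiSpec, roi_background: RoiSpec):
    """Slice-wise contrast-to-noise ratio; returns (mean, standard error).

    Per slice, CNR = |mean_signal - mean_background| / sd_background; the
    slice values (typically 10 slices) are averaged and their standard error
    reported.
    """
    sig_mask = roi_signal.mask_inplane(volume)
    bg_mask = roi_background.mask_inplane(volume)
    if (sig_mask & bg_mask).any():
        raise ValueError("signal and background ROIs overlap")
    vals = []
    for iz in roi_signal.slice_indices(volume):
        sl = volume.values[:, :, iz]
        sd = sl[bg_mask].std(ddof=1)
        if sd == 0:
            raise ValueError("background has zero variance; CNR undefined")
        vals.append(abs(sl[sig_mask].mean() - sl[bg_mask].mean()) / sd)
    vals = np.asarray(vals)
    se = vals.std(ddof=1) / math.sqrt(len(vals)) if len(vals) > 1 else 0.0
    return float(vals.mean()), float(se)


def uniformity_index(volume: VoxelVolume, center_roi: RoiSpec,
                     peripheral_rois):
    """Slice-wise uniformity index; returns (mean, standard error).

    Per slice, UI = max - min over the mean HU of the center ROI and the
    (typically four) peripheral ROIs.
    """
    rois = [center_roi] + list(peripheral_rois)
    masks = [r.mask_inplane(volume) for r in rois]
    vals = []
    for iz in center_roi.slice_indices(volume):
        sl = volume.values[:, :, iz]
        means = [sl[m].mean() for m in masks]
        vals.append(max(means) - min(means))
    vals = np.asarray(vals)
    se = vals.std(ddof=1) / math.sqrt(len(vals)) if len(vals) > 1 else 0.0
    return float(vals.mean()), float(se)


def hu_sensitivity(volume: VoxelVolume, baseline_volume: VoxelVolume,
                   inserts: dict) -> pd.DataFrame:
    """Per-insert mean HU (over slices) and difference from the baseline scan.

    ``inserts`` maps labels to :class:`RoiSpec`. Returns a DataFrame with
    mean_hu, sd_hu, baseline_mean_hu and difference_hu per insert.
    """
    _check_same_grid(volume, baseline_volume)
    rows = []
    for label, roi in inserts.items():
        means = roi.slice_means(volume)
        base = roi.slice_means(baseline_volume)
        mask = roi.mask_inplane(volume)
        sl = roi.slice_indices(volume)
        vox = volume.values[:, :, sl[0]:sl[-1] + 1][mask]
        rows.append({
            "insert": label,
            "mean_hu": means.mean(),
            "sd_hu": float(vox.std(ddof=1)),
            "baseline_mean_hu": base.mean(),
            "difference_hu": means.mean() - base.mean(),
        })
    return pd.DataFrame(rows).set_index("insert")


# ---------------------------------------------------------------------------
# Excursion
# ---------------------------------------------------------------------------

@dataclass
class ExcursionResult:
    per_phase_positions: np.ndarray  # cm, z-centroid per phase
    excursion: float                 # cm, max - min
    percent_difference: float        # % vs truth
    truth: float = EXCURSION_TRUTH_CM


def measure_excursion(phase_volumes, air_insert_roi: RoiSpec,
                      threshold_hu: float = AIR_THRESHOLD_HU,
                      truth: float = EXCURSION_TRUTH_CM) -> ExcursionResult:
    """Track the air insert across phase volumes and report its travel.

    Per phase, the insert position is the z-centroid of voxels below
    ``threshold_hu`` inside the tracking ROI (which must cover the full
    expected travel); the excursion is the difference between the extreme
    positions.
    """
    if len(phase_volumes) < 2:
        raise ValueError("need at least two phase volumes")
    for v in phase_volumes[1:]:
        _check_same_grid(phase_volumes[0], v)
    positions = []
    for k, vol in enumerate(phase_volumes):
        mask2d = air_insert_roi.mask_inplane(vol)
        sl = air_insert_roi.slice_indices(vol)
        _, _, zs = vol.axis_centers()
        sub = vol.values[:, :, sl][mask2d]       # (n_mask, n_sl)
        below = sub < threshold_hu
        if not below.any():
            raise InsertDetectionError(
                f"no voxels below {threshold_hu} HU in phase {k}")
        w = below.sum(axis=0).astype(float)      # per-slice voxel counts
        positions.append(float(np.sum(w * zs[sl]) / np.sum(w)))
    positions = np.asarray(positions)
    exc = float(positions.max() - positions.min())
    return ExcursionResult(
        per_phase_positions=positions, excursion=exc,
        percent_difference=100.0 * (exc - truth) / truth, truth=truth)


def rmse_excursion(excursions, truth: float = EXCURSION_TRUTH_CM) -> float:
    """Root-mean-square error of measured excursions against the truth (cm)."""
    e = np.asarray(excursions, dtype=float)
    if e.size == 0:
        raise ValueError("need at least one excursion value")
    return float(np.sqrt(np.mean((e - truth) ** 2)))


def normalize_sqrt_mas(value: float, total_mas: float) -> float:
    """Normalize a metric by the square root of the scan's total mAs."""
    if total_mas <= 0:
        raise ValueError("total mAs must be positive")
    return value / math.sqrt(total_mas)


# ---------------------------------------------------------------------------
# Report container
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Per-protocol metric table plus run metadata."""

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path) -> None:
        import json
        payload = {"metadata": self.metadata,
                   "rows": self.table.to_dict(orient="records")}
        with open(path, "w") as f:
            json.dump(payload, f, indent=2, default=float)
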