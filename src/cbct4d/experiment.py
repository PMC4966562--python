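"""Study orchestration: the six-protocol gantry-speed sweep.

For each gantry speed the moving phantom is scanned by the virtual
cone-beam system, the projections are retrospectively phase-sorted from the
surrogate trace, CBCT-ave (all projections) and per-phase volumes are
reconstructed, and the full metric suite (spatial resolution, CNR,
uniformity, HU sensitivity vs a static baseline, excursion, dose
bookkeeping) is evaluated and collected into one report table.

Problem sizes are configurable: the ``scale`` factor reduces the detector
frame rate (and with it the simulated projection count, preserving the
N = F*theta/omega relationship), while reconstruction grids are explicit
configuration values with desk-scale defaults. Full-scale N, acquisition
time and mAs are always reported from the nominal 15 fps protocol
definition regardless of scale.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
import tomllib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import _toml, dose
from .acquisition import (AcquisitionProtocol, DetectorGeometry, apply_noise,
                          acquisition_time, forward_project, num_projections,
                          total_mas)
from .errors import ConfigurationError
from .metrics import (EXCURSION_TRUTH_CM, MetricsReport, RoiSpec, cnr,
                      hu_sensitivity, measure_excursion, mtf_curve,
                      normalize_sqrt_mas, rmse_excursion, uniformity_index)
from .motion import MotionWaveform, generate_surrogate_trace
from .phantom import build_default_phantom
from .reconstruction import (GridSpec, VoxelVolume, calibrate_hu, reconstruct,
                             reconstruct_4d)
from .sorting import assign_bins, partition_projections, phase_function

log = logging.getLogger("cbct4d")


@dataclass
class ExperimentConfig:
    """Everything that defines one run of the study."""

    gantry_speeds: list = field(
        default_factory=lambda: [1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    frame_rate: float = 15.0          # fps, full-scale protocol value
    arc: float = 360.0                # deg
    mas_per_projection: float = 1.057
    kvp: float = 125.0
    waveform_a0: float = 0.75         # cm (3.0 cm excursion)
    waveform_period: float = 5.0      # s
    n_phase_sets: list = field(default_factory=lambda: [4, 10])
    scale: float = 1.0                # frame-rate reduction factor in (0, 1]
    # detector
    n_u: int = 192
    n_v: int = 128
    du: float = 0.2
    dv: float = 0.25
    sad: float = 100.0
    sdd: float = 150.0
    v_center: float = 0.0
    sampling_step: float = 0.1        # cm along rays
    # noise; None disables photon noise
    photons_per_mas: float | None = 2.0e5
    surrogate_rate: float = 30.0      # Hz
    surrogate_noise_sd: float = 0.0   # cm
    baseline_gantry_speed: float = 3.0
    # reconstruction grids
    excursion_grid_n: int = 96
    excursion_voxel_xy: float = 0.25  # cm
    excursion_voxel_z: float = 0.1    # cm
    metrics_inplane_n: int = 160
    metrics_voxel_xy: float = 0.15
    # 0.05 cm pixels resolve bar groups up to 5 lp/cm for the MTF fit
    mtf_inplane_n: int = 360
    mtf_voxel_xy: float = 0.05
    n_metric_slices: int = 10
    window: str = "ramp"
    seed: int = 0

    def __post_init__(self):
        if not self.gantry_speeds:
            raise ConfigurationError("need at least one gantry speed")
        if not 0 < self.scale <= 1:
            raise ConfigurationError("scale must lie in (0, 1]")

    # -- derived objects ----------------------------------------------------
    def detector(self) -> DetectorGeometry:
        return DetectorGeometry(sad=self.sad, sdd=self.sdd, n_u=self.n_u,
                                n_v=self.n_v, du=self.du, dv=self.dv,
                                v_center=self.v_center)

    def waveform(self) -> MotionWaveform:
        return MotionWaveform(A0=self.waveform_a0,
                              period=self.waveform_period)

    def protocol(self, omega: float, scaled: bool = True) -> AcquisitionProtocol:
        rate = self.frame_rate * (self.scale if scaled else 1.0)
        return AcquisitionProtocol(
            gantry_speed=omega, frame_rate=rate, arc=self.arc,
            mas_per_projection=self.mas_per_projection, kvp=self.kvp,
            detector=self.detector())

    def excursion_grid(self) -> GridSpec:
        n = self.excursion_grid_n
        # sensitometry volume of interest: air insert plus its travel
        z_lo = -9.0  # 1 cm below the air insert; top edge covers the travel
        nz = n
        z_center = z_lo + (nz - 1) / 2 * self.excursion_voxel_z
        return GridSpec.centered(
            (n, n, nz),
            (self.excursion_voxel_xy, self.excursion_voxel_xy,
             self.excursion_voxel_z),
            (0.0, 0.0, z_center))

    def module_grid(self, z_center: float, fine: bool = False) -> GridSpec:
        n = self.mtf_inplane_n if fine else self.metrics_inplane_n
        dxy = self.mtf_voxel_xy if fine else self.metrics_voxel_xy
        nz = 4 if fine else self.n_metric_slices
        dz = 0.5 if fine else 0.2
        return GridSpec.centered((n, n, nz), (dxy, dxy, dz),
                                 (0.0, 0.0, z_center))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    # -- TOML ---------------------------------------------------------------
    def to_toml(self) -> str:
        d = asdict(self)
        if d["photons_per_mas"] is None:
            d["photons_per_mas"] = 0.0  # TOML has no null; 0 disables noise
        return _toml.dumps(d)

    @classmethod
    def from_toml(cls, text: str) -> "ExperimentConfig":
        return cls(**tomllib.loads(text))


# ---------------------------------------------------------------------------
# Simulation stages
# ---------------------------------------------------------------------------

def simulate_protocol(config: ExperimentConfig, omega: float, phantom=None,
                      moving: bool = True, seed: int | None = None):
    """Scan one protocol; returns (projection set, surrogate trace).

    ``moving=False`` scans the static phantom (used for the baseline);
    photon noise is applied when the config requests it.
    """
    phantom = phantom or build_default_phantom()
    proto = config.protocol(omega)
    wave = config.waveform() if moving else None
    t0 = time.perf_counter()
    projs = forward_project(phantom, wave, proto,
                            sampling_step=config.sampling_step)
    log.info("forward projection omega=%.1f deg/s: %d projections in %.1f s",
             omega, projs.n_projections, time.perf_counter() - t0)
    if config.photons_per_mas:
        projs = apply_noise(projs, config.photons_per_mas, seed=seed)
    duration = projs.timestamps[-1] + 1.0
    trace = generate_surrogate_trace(
        config.waveform(), duration, config.surrogate_rate,
        noise_sd=config.surrogate_noise_sd,
        seed=None if seed is None else seed + 1)
    return projs, trace


def sort_and_reconstruct_phases(config: ExperimentConfig, projs, trace,
                                n_bins: int, grid: GridSpec):
    """Surrogate-driven phase sorting followed by per-bin reconstruction."""
    phi = phase_function(trace)
    assignment = assign_bins(projs.timestamps, phi, n_bins, centered=True)
    bins = partition_projections(projs, assignment)
    vols = reconstruct_4d(bins, grid, window=config.window)
    return assignment, vols


def excursion_study_config(seed: int = 0) -> ExperimentConfig:
    """Desk-scale conditions for the noiseless 10-phase excursion study.

    Frame rate reduced to 2.5 fps (1/6 of the nominal 15 fps, preserving the
    N = F*theta/omega ratios and leaving at least 15 projections per
    10-phase bin at the fastest gantry speed), detector rows narrowed to the
    band covering the sensitometry volume of interest, photon noise off.
    """
    return ExperimentConfig(scale=1.0 / 6.0, photons_per_mas=None,
                            n_v=80, v_center=-7.0, seed=seed)


def measure_protocol_excursion(config: ExperimentConfig, omega: float,
                               n_bins: int = 10, phantom=None,
                               seed: int | None = None):
    """Full surrogate-driven excursion measurement for one protocol.

    Simulates the scan, sorts projections into ``n_bins`` centered phase
    bins using only the surrogate trace, reconstructs every phase volume on
    the sensitometry volume of interest and tracks the air insert. Returns
    the :class:`~cbct4d.metrics.ExcursionResult`.
    """
    phantom = phantom or build_default_phantom()
    grid = config.excursion_grid()
    roi = excursion_roi(config, grid)
    projs, trace = simulate_protocol(config, omega, phantom, seed=seed)
    _, vols = sort_and_reconstruct_phases(config, projs, trace, n_bins, grid)
    return measure_excursion(vols, roi)


# ---------------------------------------------------------------------------
# Regions of interest tied to the default phantom layout
# ---------------------------------------------------------------------------

def default_rois(config: ExperimentConfig) -> dict:
    """ROI specifications matching :func:`build_default_phantom`."""
    nz = config.n_metric_slices
    rois = {
        "cnr_signal": RoiSpec("disk", (4.0, 0.0), (0.6,), (0, nz)),
        "cnr_background": RoiSpec("annulus", (4.0, 0.0), (0.95, 1.45),
                                  (0, nz)),
        "ui_center": RoiSpec("disk", (0.0, 0.0), (0.5,), (0, nz)),
        "ui_peripheral": [
            RoiSpec("disk", (5.0, 0.0), (0.5,), (0, nz)),
            RoiSpec("disk", (-5.0, 0.0), (0.5,), (0, nz)),
            RoiSpec("disk", (0.0, 5.0), (0.5,), (0, nz)),
            RoiSpec("disk", (0.0, -5.0), (0.5,), (0, nz)),
        ],
    }
    phantom = build_default_phantom()
    sens = {}
    for ins in phantom.modules[3].inserts:
        sens[ins.label] = RoiSpec("disk", ins.center[:2], (ins.radius * 0.6,),
                                  (0, nz))
    rois["sensitometry"] = sens
    return rois


def excursion_roi(config: ExperimentConfig, grid: GridSpec) -> RoiSpec:
    """Tracking box around the air insert covering its full travel."""
    phantom = build_default_phantom()
    air = phantom.find_insert("air")
    _, _, zs = GridSpec(grid.shape, grid.spacing, grid.origin).axis_centers()
    z_lo = air.center[2] - air.length / 2 - 0.3
    z_hi = air.center[2] + air.length / 2 \
        + 4.0 * config.waveform_a0 + 0.3
    idx = np.nonzero((zs >= z_lo) & (zs <= z_hi))[0]
    return RoiSpec("box", air.center[:2], (air.radius + 0.1, air.radius + 0.1),
                   (int(idx[0]), int(idx[-1]) + 1))


# ---------------------------------------------------------------------------
# Study drivers
# ---------------------------------------------------------------------------

def run_baseline(config: ExperimentConfig, phantom=None,
                 grid: GridSpec | None = None) -> VoxelVolume:
    """Static-phantom CBCT-ave scan, the HU-sensitivity ground truth."""
    phantom = phantom or build_default_phantom()
    grid = grid or config.module_grid(-6.0)
    seed = np.random.SeedSequence(config.seed).generate_state(1)[0] % (2**31)
    projs, _ = simulate_protocol(config, config.baseline_gantry_speed,
                                 phantom, moving=False, seed=int(seed))
    vol = calibrate_hu(reconstruct(projs, grid, window=config.window))
    vol.provenance["baseline"] = True
    return vol


def run_sweep(config: ExperimentConfig, phantom=None,
              with_mtf: bool = True) -> MetricsReport:
    """The full gantry-speed study; per-protocol failures are isolated.

    Returns a :class:`MetricsReport` with one row per gantry speed and
    excursion RMSE values (one per phase-set) in the metadata.
    """
    phantom = phantom or build_default_phantom()
    rois = default_rois(config)
    exc_grid = config.excursion_grid()
    exc_roi = excursion_roi(config, exc_grid)
    cnr_grid = config.module_grid(2.0)
    ui_grid = config.module_grid(-2.0)
    hu_grid = config.module_grid(-6.0)
    mtf_grid = config.module_grid(6.0, fine=True)
    bar_groups = phantom.modules[0].bar_groups

    baseline = run_baseline(config, phantom, hu_grid)
    seeds = np.random.SeedSequence(config.seed).generate_state(
        len(config.gantry_speeds) + 1) % (2**31)

    rows, failures = [], {}
    excursions = {n: {} for n in config.n_phase_sets}
    for i, omega in enumerate(config.gantry_speeds):
        try:
            row = _run_protocol(config, phantom, omega, int(seeds[i + 1]),
                                rois, baseline, bar_groups, exc_grid, exc_roi,
                                cnr_grid, ui_grid, hu_grid, mtf_grid,
                                excursions, with_mtf)
            rows.append(row)
        except Exception as exc:  # isolate per-protocol failures
            log.exception("protocol omega=%.1f failed", omega)
            failures[omega] = repr(exc)
    table = pd.DataFrame(rows)
    metadata = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "scale": config.scale,
        "failures": failures,
        "excursion_truth_cm": EXCURSION_TRUTH_CM,
    }
    for n in config.n_phase_sets:
        vals = [excursions[n][w] for w in config.gantry_speeds
                if w in excursions[n]]
        if vals:
            metadata[f"excursion_rmse_cm_{n}ph"] = rmse_excursion(vals)
    return MetricsReport(table=table, metadata=metadata)


def _run_protocol(config, phantom, omega, seed, rois, baseline, bar_groups,
                  exc_grid, exc_roi, cnr_grid, ui_grid, hu_grid, mtf_grid,
                  excursions, with_mtf) -> dict:
    t_start = time.perf_counter()
    projs, trace = simulate_protocol(config, omega, phantom, seed=seed)
    proto_full = config.protocol(omega, scaled=False)
    mas = total_mas(proto_full)

    row = {
        "gantry_speed_deg_s": omega,
        "n_projections_full": num_projections(
            config.frame_rate, config.arc, omega),
        "n_projections_simulated": projs.n_projections,
        "acq_time_min": acquisition_time(config.arc, omega),
        "total_mas_full": mas,
    }
    for pos in sorted(dose.DOSE_RATES_CGY_PER_MAS):
        row[f"dose_cgy_pos{pos}"] = dose.scan_dose(pos, mas)

    # CBCT-ave on each metric grid
    ave_cnr = calibrate_hu(reconstruct(projs, cnr_grid, window=config.window))
    ave_ui = calibrate_hu(reconstruct(projs, ui_grid, window=config.window))
    ave_hu = calibrate_hu(reconstruct(projs, hu_grid, window=config.window))
    c, c_se = cnr(ave_cnr, rois["cnr_signal"], rois["cnr_background"])
    u, u_se = uniformity_index(ave_ui, rois["ui_center"],
                               rois["ui_peripheral"])
    sens = hu_sensitivity(ave_hu, baseline, rois["sensitometry"])
    row.update({
        "cnr": c, "cnr_se": c_se,
        "cnr_per_sqrt_mas": normalize_sqrt_mas(c, mas),
        "ui_hu": u, "ui_se": u_se,
        "ui_per_sqrt_mas": normalize_sqrt_mas(u, mas),
        "hu_diff_air": float(sens.loc["air", "difference_hu"]),
        "hu_diff_max_abs": float(sens["difference_hu"].abs().max()),
    })

    if with_mtf:
        ave_mtf = calibrate_hu(reconstruct(projs, mtf_grid,
                                           window=config.window))
        curve = mtf_curve(ave_mtf, bar_groups)
        row.update({
            "f_max_lpcm": curve.f_max, "mtf_sigma": curve.sigma,
            "mtf_r2": curve.r_squared,
            "f_max_per_sqrt_mas": normalize_sqrt_mas(curve.f_max, mas),
        })

    for n_bins in config.n_phase_sets:
        _, vols = sort_and_reconstruct_phases(config, projs, trace, n_bins,
                                              exc_grid)
        res = measure_excursion(vols, exc_roi)
        excursions[n_bins][omega] = res.excursion
        row[f"excursion_cm_{n_bins}ph"] = res.excursion
        row[f"excursion_pct_diff_{n_bins}ph"] = res.percent_difference
    log.info("protocol omega=%.1f complete in %.1f s", omega,
             time.perf_counter() - t_start)
    return row


# ---------------------------------------------------------------------------
# Optional figures
# ---------------------------------------------------------------------------

def plot_report(report: MetricsReport, outdir) -> list:
    """CNR / UI / f_max versus gantry speed as PNG files; returns paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t = report.table
    paths = []
    panels = [("cnr", "cnr_se", "CNR"), ("ui_hu", "ui_se", "UI (HU)")]
    if "f_max_lpcm" in t.columns:
        panels.append(("f_max_lpcm", None, "f_max (lp/cm)"))
    for col, err, label in panels:
        fig, ax = plt.subplots(figsize=(4, 3))
        if err:
            ax.errorbar(t["gantry_speed_deg_s"], t[col], yerr=t[err],
                        fmt="o-")
        else:
            ax.plot(t["gantry_speed_deg_s"], t[col], "o-")
        ax.set_xlabel("gantry speed (deg/s)")
        ax.set_ylabel(label)
        fig.tight_layout()
        p = outdir / f"{col}_vs_speed.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths
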