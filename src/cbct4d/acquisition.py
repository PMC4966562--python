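"""Virtual gantry: acquisition protocols, projection schedules, forward model.

The scanner model is a circular cone-beam system: kV source and flat-panel
detector rotating about the z (superior-inferior) axis at a constant gantry
speed ``omega`` (deg/s) while the detector reads out at frame rate ``F``
(Hz). Over an arc ``theta`` the scan therefore collects

    N = F * theta / omega

projections, the bookkeeping at the heart of the gantry-speed trade-off:
halving the speed doubles both the projection count and, at fixed tube
output per frame, the total mAs (and so the imaging dose).

Projections hold line integrals of linear attenuation (unitless). Photon
noise is applied in the count domain with a Poisson model whose mean scales
with mAs per projection, so contrast-to-noise behaviour tracks the total
mAs of each protocol.

A 2D parallel-beam mode is provided alongside the cone-beam geometry for
fast analytic cross-checks (chord-length oracles, textbook FBP comparison).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
from numba import njit

from .errors import ConfigurationError, NoiseAlreadyAppliedError
from .motion import MotionWaveform, displacement_at_time
from .phantom import MU_WATER, DigitalPhantom, _mu_point

DEFAULT_KVP = 125.0
DEFAULT_FRAME_RATE = 15.0        # fps
DEFAULT_ARC = 360.0              # deg
#: mAs per projection pulse: mean ratio of total mAs to projection count
#: across the six protocols of the reference technique chart.
DEFAULT_MAS_PER_PROJECTION = 1.057
DEFAULT_PHOTONS_PER_MAS = 2.0e5  # detected photons per mAs per detector bin


@dataclass
class DetectorGeometry:
    """Flat-panel geometry for the circular cone-beam trajectory.

    ``sad`` is the source-axis distance and ``sdd`` the source-detector
    distance (cm). The panel has ``n_u`` columns (in-plane) of pitch ``du``
    and ``n_v`` rows (axial) of pitch ``dv``; ``v_center`` offsets the panel
    along z to center it on a volume of interest.
    """

    sad: float = 100.0
    sdd: float = 150.0
    n_u: int = 192
    n_v: int = 128
    du: float = 0.2
    dv: float = 0.25
    v_center: float = 0.0

    def __post_init__(self):
        if self.sad <= 0 or self.sdd <= 0:
            raise ConfigurationError("distances must be positive")
        if self.sdd <= self.sad:
            raise ConfigurationError("sdd must exceed sad")
        if self.n_u < 2 or self.n_v < 1 or self.du <= 0 or self.dv <= 0:
            raise ConfigurationError("degenerate detector geometry")

    def u_coords(self) -> np.ndarray:
        return (np.arange(self.n_u) - (self.n_u - 1) / 2) * self.du

    def v_coords(self) -> np.ndarray:
        return (np.arange(self.n_v) - (self.n_v - 1) / 2) * self.dv \
            + self.v_center


@dataclass
class AcquisitionProtocol:
    """One gantry-speed protocol of the sweep."""

    gantry_speed: float                   # deg/s, in (0, 6]
    frame_rate: float = DEFAULT_FRAME_RATE
    arc: float = DEFAULT_ARC
    mas_per_projection: float = DEFAULT_MAS_PER_PROJECTION
    kvp: float = DEFAULT_KVP
    fov: float = 46.5                     # cm
    detector: DetectorGeometry = field(default_factory=DetectorGeometry)

    def __post_init__(self):
        if not 0 < self.gantry_speed <= 6.0:
            raise ConfigurationError(
                f"gantry speed {self.gantry_speed} deg/s outside (0, 6]")
        if self.frame_rate <= 0:
            raise ConfigurationError("frame rate must be positive")
        if self.arc < 360.0:
            raise ConfigurationError("arc must cover at least 360 degrees")
        if self.mas_per_projection <= 0:
            raise ConfigurationError("mAs per projection must be positive")


@dataclass
class ProjectionSet:
    """Stack of timestamped, angle-tagged line-integral projections."""

    data: np.ndarray          # (n_proj, n_v, n_u), or (n_proj, 1, n_s) parallel
    timestamps: np.ndarray    # s
    angles: np.ndarray        # deg
    protocol: AcquisitionProtocol | None = None
    geometry: DetectorGeometry | None = None
    mode: str = "cone"        # "cone" | "parallel"
    noise_applied: bool = False
    seed: int | None = None

    def __post_init__(self):
        n = self.data.shape[0]
        if len(self.timestamps) != n or len(self.angles) != n:
            raise ValueError("data, timestamps and angles lengths differ")

    @property
    def n_projections(self) -> int:
        return self.data.shape[0]

    def subset(self, indices) -> "ProjectionSet":
        idx = np.asarray(indices)
        if idx.size == 0:
            idx = idx.astype(int)
        return replace(self, data=self.data[idx],
                       timestamps=self.timestamps[idx],
                       angles=self.angles[idx])

    # -- persistence --------------------------------------------------------
    def save_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data, compression="gzip")
            f.create_dataset("timestamps", data=self.timestamps)
            f.create_dataset("angles", data=self.angles)
            f.attrs["mode"] = self.mode
            f.attrs["noise_applied"] = self.noise_applied
            if self.seed is not None:
                f.attrs["seed"] = self.seed
            if self.protocol is not None:
                for k in ("gantry_speed", "frame_rate", "arc",
                          "mas_per_projection", "kvp", "fov"):
                    f.attrs[f"protocol_{k}"] = getattr(self.protocol, k)
            if self.geometry is not None:
                for k in ("sad", "sdd", "n_u", "n_v", "du", "dv", "v_center"):
                    f.attrs[f"detector_{k}"] = getattr(self.geometry, k)

    @classmethod
    def load_hdf5(cls, path) -> "ProjectionSet":
        with h5py.File(path, "r") as f:
            geom = None
            if "detector_sad" in f.attrs:
                geom = DetectorGeometry(
                    sad=float(f.attrs["detector_sad"]),
                    sdd=float(f.attrs["detector_sdd"]),
                    n_u=int(f.attrs["detector_n_u"]),
                    n_v=int(f.attrs["detector_n_v"]),
                    du=float(f.attrs["detector_du"]),
                    dv=float(f.attrs["detector_dv"]),
                    v_center=float(f.attrs["detector_v_center"]))
            proto = None
            if "protocol_gantry_speed" in f.attrs:
                proto = AcquisitionProtocol(
                    gantry_speed=float(f.attrs["protocol_gantry_speed"]),
                    frame_rate=float(f.attrs["protocol_frame_rate"]),
                    arc=float(f.attrs["protocol_arc"]),
                    mas_per_projection=float(
                        f.attrs["protocol_mas_per_projection"]),
                    kvp=float(f.attrs["protocol_kvp"]),
                    fov=float(f.attrs["protocol_fov"]),
                    detector=geom or DetectorGeometry())
            return cls(data=f["data"][...],
                       timestamps=f["timestamps"][...],
                       angles=f["angles"][...],
                       protocol=proto, geometry=geom,
                       mode=str(f.attrs["mode"]),
                       noise_applied=bool(f.attrs["noise_applied"]),
                       seed=int(f.attrs["seed"]) if "seed" in f.attrs
                       else None)


# ---------------------------------------------------------------------------
# Protocol bookkeeping
# ---------------------------------------------------------------------------

def num_projections(frame_rate: float, arc: float, gantry_speed: float) -> int:
    """Projection count N = round(F * theta / omega)."""
    if gantry_speed <= 0:
        raise ValueError("gantry speed must be positive")
    if frame_rate <= 0 or arc <= 0:
        raise ValueError("frame rate and arc must be positive")
    return int(round(frame_rate * arc / gantry_speed))


def acquisition_time(arc: float, gantry_speed: float) -> float:
    """Scan duration theta / omega, in minutes."""
    if gantry_speed <= 0:
        raise ValueError("gantry speed must be positive")
    return arc / gantry_speed / 60.0


def total_mas(protocol: AcquisitionProtocol) -> float:
    """Cumulative tube output of the scan: N * mAs-per-projection."""
    n = num_projections(protocol.frame_rate, protocol.arc,
                        protocol.gantry_speed)
    return n * protocol.mas_per_projection


def build_schedule(protocol: AcquisitionProtocol):
    """Uniform frame times t_i = i/F and gantry angles omega * t_i (deg)."""
    n = num_projections(protocol.frame_rate, protocol.arc,
                        protocol.gantry_speed)
    ts = np.arange(n) / protocol.frame_rate
    return ts, protocol.gantry_speed * ts


# ---------------------------------------------------------------------------
# Forward projection kernels
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _cone_project_one(out, cosb, sinb, sad, sdd, us, vs, shift, step,
                      h_r, h_zlo, h_zhi, h_mu,
                      mod_z, mod_mu, p_kind, p_c, p_d, p_cos, p_sin, p_mu):
    sx = sad * cosb
    sy = sad * sinb
    zlo = h_zlo + shift
    zhi = h_zhi + shift
    for iv in range(vs.shape[0]):
        v = vs[iv]
        for iu in range(us.shape[0]):
            u = us[iu]
            dx = (sad - sdd) * cosb - u * sinb - sx
            dy = (sad - sdd) * sinb + u * cosb - sy
            dz = v
            norm = math.sqrt(dx * dx + dy * dy + dz * dz)
            rx, ry, rz = dx / norm, dy / norm, dz / norm
            # entry/exit of the housing cylinder |xy| <= R
            a = rx * rx + ry * ry
            b = 2.0 * (sx * rx + sy * ry)
            c = sx * sx + sy * sy - h_r * h_r
            disc = b * b - 4.0 * a * c
            if disc <= 0.0:
                out[iv, iu] = 0.0
                continue
            sq = math.sqrt(disc)
            t0 = (-b - sq) / (2.0 * a)
            t1 = (-b + sq) / (2.0 * a)
            # clamp to the (shifted) axial extent of the housing
            if rz > 1e-12:
                t0 = max(t0, zlo / rz)
                t1 = min(t1, zhi / rz)
            elif rz < -1e-12:
                t0 = max(t0, zhi / rz)
                t1 = min(t1, zlo / rz)
            else:
                if not (zlo <= 0.0 <= zhi):
                    out[iv, iu] = 0.0
                    continue
            if t1 <= t0:
                out[iv, iu] = 0.0
                continue
            n = int(math.ceil((t1 - t0) / step))
            h = (t1 - t0) / n
            acc = 0.0
            for k in range(n):
                t = t0 + (k + 0.5) * h
                acc += _mu_point(
                    sx + t * rx, sy + t * ry, t * rz - shift,
                    h_r, h_zlo, h_zhi, h_mu,
                    mod_z, mod_mu, p_kind, p_c, p_d, p_cos, p_sin, p_mu)
            out[iv, iu] = acc * h


@njit(cache=True, fastmath=True)
def _parallel_project_one(out, cosb, sinb, ss, z, shift, step,
                          h_r, h_zlo, h_zhi, h_mu,
                          mod_z, mod_mu, p_kind, p_c, p_d,
                          p_cos, p_sin, p_mu):
    # parallel rays travelling along (cosb, sinb) offset by s along the
    # perpendicular (-sinb, cosb); one z slice
    for i in range(ss.shape[0]):
        s = ss[i]
        c2 = s * s - h_r * h_r
        if c2 >= 0.0:
            out[i] = 0.0
            continue
        half = math.sqrt(-c2)
        n = int(math.ceil(2.0 * half / step))
        h = 2.0 * half / n
        ox = -s * sinb
        oy = s * cosb
        acc = 0.0
        zq = z - shift
        for k in range(n):
            t = -half + (k + 0.5) * h
            acc += _mu_point(
                ox + t * cosb, oy + t * sinb, zq,
                h_r, h_zlo, h_zhi, h_mu,
                mod_z, mod_mu, p_kind, p_c, p_d, p_cos, p_sin, p_mu)
        out[i] = acc * h


def forward_project(phantom: DigitalPhantom,
                    waveform: MotionWaveform | None,
                    protocol: AcquisitionProtocol,
                    sampling_step: float = 0.05,
                    schedule=None,
                    mu_water: float = MU_WATER) -> ProjectionSet:
    """Scan the (moving) phantom: line integrals for every scheduled frame.

    For each frame time t_i the phantom is displaced along z by the waveform
    displacement at t_i and integrated along source-to-detector-bin rays
    with a fixed ``sampling_step`` (cm). ``waveform=None`` scans the static
    phantom. Deterministic; noise is applied separately.
    """
    if sampling_step <= 0:
        raise ValueError("sampling_step must be positive")
    geom = protocol.detector
    ts, angles = build_schedule(protocol) if schedule is None else schedule
    ts = np.asarray(ts, dtype=float)
    angles = np.asarray(angles, dtype=float)
    shifts = (displacement_at_time(waveform, ts) if waveform is not None
              else np.zeros_like(ts))
    tabs = phantom.tables(mu_water)
    us = geom.u_coords()
    vs = geom.v_coords()
    data = np.empty((len(ts), geom.n_v, geom.n_u), dtype=float)
    for i in range(len(ts)):
        beta = math.radians(angles[i])
        _cone_project_one(data[i], math.cos(beta), math.sin(beta),
                          geom.sad, geom.sdd, us, vs, float(shifts[i]),
                          float(sampling_step), *tabs)
    return ProjectionSet(data=data, timestamps=ts, angles=angles,
                         protocol=protocol, geometry=geom, mode="cone")


def parallel_sinogram(phantom: DigitalPhantom, angles_deg, s_coords,
                      z_slice: float = 0.0, sampling_step: float = 0.02,
                      si_shifts=None,
                      mu_water: float = MU_WATER) -> np.ndarray:
    """2D parallel-beam sinogram of one axial slice, shape (n_angles, n_s).

    ``si_shifts`` optionally displaces the phantom per view (cm along z).
    """
    angles_deg = np.asarray(angles_deg, dtype=float)
    ss = np.asarray(s_coords, dtype=float)
    shifts = (np.zeros_like(angles_deg) if si_shifts is None
              else np.asarray(si_shifts, dtype=float))
    tabs = phantom.tables(mu_water)
    sino = np.empty((len(angles_deg), len(ss)), dtype=float)
    for i, ang in enumerate(angles_deg):
        b = math.radians(ang)
        _parallel_project_one(sino[i], math.cos(b), math.sin(b), ss,
                              float(z_slice), float(shifts[i]),
                              float(sampling_step), *tabs)
    return sino


# ---------------------------------------------------------------------------
# Photon noise
# ---------------------------------------------------------------------------

def apply_noise(projections: ProjectionSet,
                photons_per_mas: float = DEFAULT_PHOTONS_PER_MAS,
                seed: int | None = None) -> ProjectionSet:
    """Poisson count noise in the transmission domain.

    Each detector bin receives a mean fluence I0 = photons_per_mAs * mAs per
    projection; transmitted counts are Poisson(I0 * exp(-p)) (clamped at one
    count) and the noisy line integral is -ln(counts / I0). Lower gantry
    speed means more projections and thus more total mAs, but the noise per
    projection is unchanged -- exactly the trade the protocol sweep probes.
    """
    if photons_per_mas <= 0:
        raise ValueError("photons_per_mas must be positive")
    if projections.noise_applied:
        raise NoiseAlreadyAppliedError("noise already applied to this set")
    mas = (projections.protocol.mas_per_projection
           if projections.protocol is not None else 1.0)
    i0 = photons_per_mas * mas
    rng = np.random.default_rng(seed)
    counts = rng.poisson(i0 * np.exp(-projections.data)).astype(float)
    np.maximum(counts, 1.0, out=counts)
    noisy = -np.log(counts / i0)
    return replace(projections, data=noisy, noise_applied=True, seed=seed)
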