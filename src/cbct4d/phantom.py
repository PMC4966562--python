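"""Digital image-quality phantom.

A Catphan-style cylindrical QA phantom is modelled analytically as a
water-equivalent housing subdivided into axial modules (bar-pattern
resolution section, low-contrast section, homogeneous section, sensitometry
section), each holding cylindrical inserts or bar groups. Attenuation is
evaluated on demand at arbitrary 3D points, so the forward projector can
sample at any resolution, and superior-inferior (SI) motion enters as a
rigid shift of the sampling coordinate.

Conventions: world coordinates in cm, isocenter at the origin, +z superior,
axial slices are xy planes. Attenuation is linear attenuation mu in 1/cm;
Hounsfield units follow HU = 1000*(mu - mu_water)/mu_water.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import _toml
from .errors import ConfigurationError

#: Linear attenuation of water (1/cm) at the effective energy of a 125 kVp
#: beam; used as the HU calibration point throughout.
MU_WATER = 0.2

HU_MIN, HU_MAX = -1000.0, 3000.0


# ---------------------------------------------------------------------------
# HU <-> mu conversion
# ---------------------------------------------------------------------------

def hu_to_mu(hu, mu_water: float = MU_WATER):
    """Convert Hounsfield units to linear attenuation (1/cm)."""
    if mu_water <= 0:
        raise ConfigurationError(f"mu_water must be positive, got {mu_water}")
    return mu_water * (1.0 + np.asarray(hu, dtype=float) / 1000.0)


def mu_to_hu(mu, mu_water: float = MU_WATER):
    """Convert linear attenuation (1/cm) to Hounsfield units."""
    if mu_water <= 0:
        raise ConfigurationError(f"mu_water must be positive, got {mu_water}")
    return 1000.0 * (np.asarray(mu, dtype=float) - mu_water) / mu_water


# ---------------------------------------------------------------------------
# Specification dataclasses
# ---------------------------------------------------------------------------

@dataclass
class InsertSpec:
    """A homogeneous cylindrical insert (axis parallel to z).

    Parameters
    ----------
    label : str
        Identifier, e.g. ``"air"`` or ``"low_contrast"``.
    center : tuple of float
        Insert axis center (x, y, z) in cm.
    radius : float
        Cylinder radius in cm.
    length : float
        Full cylinder length along z in cm.
    nominal_hu : float
        Nominal Hounsfield value of the insert material.
    """

    label: str
    center: tuple
    radius: float
    length: float
    nominal_hu: float

    def __post_init__(self):
        if self.radius <= 0 or self.length <= 0:
            raise ConfigurationError(
                f"insert '{self.label}': dimensions must be positive"
            )
        if not (HU_MIN <= self.nominal_hu <= HU_MAX):
            raise ConfigurationError(
                f"insert '{self.label}': nominal_hu {self.nominal_hu} outside "
                f"[{HU_MIN}, {HU_MAX}]"
            )
        self.center = tuple(float(c) for c in self.center)


@dataclass
class BarGroupSpec:
    """A square-wave bar group of known spatial frequency.

    The group is a run of ``n_cycles`` [bar, gap] cycles along the in-plane
    modulation axis; the bars carry ``bar_hu`` against the surrounding module
    background. The frequency in line pairs per cm is the quantity the
    resolution analysis reads off directly.
    """

    frequency: float          # lp/cm
    n_cycles: int
    center: tuple             # group center (x, y, z), cm
    bar_hu: float = 500.0
    background_hu: float = 0.0
    orientation: float = 0.0  # in-plane angle of the modulation axis, degrees
    bar_length: float = 1.0   # extent along the bar (perp. to modulation), cm
    bar_height: float = 2.0   # extent along z, cm

    def __post_init__(self):
        if self.frequency <= 0:
            raise ConfigurationError("bar group frequency must be positive")
        if self.n_cycles < 2:
            raise ConfigurationError("bar group needs at least 2 cycles")
        for hu in (self.bar_hu, self.background_hu):
            if not (HU_MIN <= hu <= HU_MAX):
                raise ConfigurationError(f"bar group HU {hu} out of range")
        self.center = tuple(float(c) for c in self.center)

    @property
    def cycle_length(self) -> float:
        return 1.0 / self.frequency

    @property
    def bar_width(self) -> float:
        return 0.5 / self.frequency

    def bar_centers(self) -> np.ndarray:
        """Offsets of bar centers along the modulation axis (cm)."""
        ext = self.n_cycles * self.cycle_length
        return np.array(
            [-ext / 2 + k * self.cycle_length + self.bar_width / 2
             for k in range(self.n_cycles)]
        )


@dataclass
class PhantomModule:
    """One axial section of the phantom."""

    name: str
    z_range: tuple            # (z_lo, z_hi), cm
    background_hu: float = 0.0
    inserts: list = field(default_factory=list)
    bar_groups: list = field(default_factory=list)

    def __post_init__(self):
        lo, hi = self.z_range
        if not hi > lo:
            raise ConfigurationError(f"module '{self.name}': empty z range")
        self.z_range = (float(lo), float(hi))


@dataclass
class DigitalPhantom:
    """Analytic phantom: water housing cylinder + axial modules of inserts."""

    housing_radius: float
    modules: list
    housing_hu: float = 0.0

    def __post_init__(self):
        if self.housing_radius <= 0:
            raise ConfigurationError("housing radius must be positive")
        spans = sorted(m.z_range for m in self.modules)
        for (a, b), (c, d) in zip(spans, spans[1:]):
            if c < b - 1e-12:
                raise ConfigurationError("module z ranges overlap")
        for m in self.modules:
            for ins in m.inserts:
                r_out = math.hypot(ins.center[0], ins.center[1]) + ins.radius
                if r_out > self.housing_radius + 1e-9:
                    raise ConfigurationError(
                        f"insert '{ins.label}' extends outside housing"
                    )
        self._tables_cache = None

    # -- extent -------------------------------------------------------------
    @property
    def z_extent(self) -> tuple:
        if not self.modules:
            return (-math.inf, math.inf)
        los, his = zip(*(m.z_range for m in self.modules))
        return (min(los), max(his))

    def find_insert(self, label: str) -> InsertSpec:
        for m in self.modules:
            for ins in m.inserts:
                if ins.label == label:
                    return ins
        raise KeyError(f"no insert labelled '{label}'")

    # -- numba-friendly flat encoding ----------------------------------------
    def tables(self, mu_water: float = MU_WATER):
        """Flatten the phantom into arrays consumed by the numba kernels."""
        if self._tables_cache is not None and self._tables_cache[0] == mu_water:
            return self._tables_cache[1]
        kinds, centers, dims, coss, sins, mus = [], [], [], [], [], []
        mod_z, mod_mu = [], []
        for m in self.modules:
            mod_z.append(m.z_range)
            mod_mu.append(float(hu_to_mu(m.background_hu, mu_water)))
            for ins in m.inserts:
                kinds.append(0)
                centers.append(ins.center)
                dims.append((ins.radius, 0.0, ins.length / 2))
                coss.append(1.0)
                sins.append(0.0)
                mus.append(float(hu_to_mu(ins.nominal_hu, mu_water)))
            for bg in m.bar_groups:
                th = math.radians(bg.orientation)
                c, s = math.cos(th), math.sin(th)
                for off in bg.bar_centers():
                    kinds.append(1)
                    centers.append(
                        (bg.center[0] + off * c, bg.center[1] + off * s,
                         bg.center[2])
                    )
                    dims.append(
                        (bg.bar_width / 2, bg.bar_length / 2, bg.bar_height / 2)
                    )
                    coss.append(c)
                    sins.append(s)
                    mus.append(float(hu_to_mu(bg.bar_hu, mu_water)))
        z_lo, z_hi = self.z_extent
        tabs = (
            float(self.housing_radius), float(z_lo), float(z_hi),
            float(hu_to_mu(self.housing_hu, mu_water)),
            np.asarray(mod_z, dtype=float).reshape(-1, 2),
            np.asarray(mod_mu, dtype=float),
            np.asarray(kinds, dtype=np.int64),
            np.asarray(centers, dtype=float).reshape(-1, 3),
            np.asarray(dims, dtype=float).reshape(-1, 3),
            np.asarray(coss, dtype=float),
            np.asarray(sins, dtype=float),
            np.asarray(mus, dtype=float),
        )
        self._tables_cache = (mu_water, tabs)
        return tabs


# ---------------------------------------------------------------------------
# Point evaluation (numba kernels)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _mu_point(x, y, z, h_r, h_zlo, h_zhi, h_mu,
              mod_z, mod_mu, p_kind, p_c, p_d, p_cos, p_sin, p_mu):
    if x * x + y * y > h_r * h_r or z < h_zlo or z > h_zhi:
        return 0.0  # air outside the housing
    for i in range(p_kind.shape[0]):
        dz = z - p_c[i, 2]
        if abs(dz) > p_d[i, 2]:
            continue
        dx = x - p_c[i, 0]
        dy = y - p_c[i, 1]
        if p_kind[i] == 0:  # z-axis cylinder
            if dx * dx + dy * dy <= p_d[i, 0] * p_d[i, 0]:
                return p_mu[i]
        else:  # in-plane rotated box (bar)
            u = p_cos[i] * dx + p_sin[i] * dy
            v = -p_sin[i] * dx + p_cos[i] * dy
            if abs(u) <= p_d[i, 0] and abs(v) <= p_d[i, 1]:
                return p_mu[i]
    for m in range(mod_z.shape[0]):
        if mod_z[m, 0] <= z <= mod_z[m, 1]:
            return mod_mu[m]
    return h_mu


@njit(cache=True)
def _sample_kernel(pts, shift, h_r, h_zlo, h_zhi, h_mu,
                   mod_z, mod_mu, p_kind, p_c, p_d, p_cos, p_sin, p_mu, out):
    for i in range(pts.shape[0]):
        out[i] = _mu_point(
            pts[i, 0], pts[i, 1], pts[i, 2] - shift,
            h_r, h_zlo, h_zhi, h_mu,
            mod_z, mod_mu, p_kind, p_c, p_d, p_cos, p_sin, p_mu,
        )


def sample_mu(phantom: DigitalPhantom, points, si_shift: float = 0.0,
              mu_water: float = MU_WATER) -> np.ndarray:
    """Linear attenuation of the rigidly displaced phantom at 3D points.

    The phantom displaced by ``si_shift`` along +z is sampled at ``points``
    (shape ``(n, 3)``, cm); equivalently the static phantom is sampled at
    ``points - (0, 0, si_shift)``. Points outside the housing return the
    attenuation of air (0).
    """
    pts = np.asarray(points, dtype=float)
    squeeze = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if pts.shape[-1] != 3:
        raise ValueError("points must have shape (n, 3)")
    if not np.all(np.isfinite(pts)) or not math.isfinite(si_shift):
        raise ValueError("points and si_shift must be finite")
    out = np.empty(pts.shape[0], dtype=float)
    _sample_kernel(pts, float(si_shift), *phantom.tables(mu_water), out)
    return out[0] if squeeze else out


# ---------------------------------------------------------------------------
# Default phantom
# ---------------------------------------------------------------------------

#: Packaged defaults. Insert HU values follow common solid-insert QA
#: materials; bar frequencies bracket the 3.8-5.9 lp/cm range over which the
#: 10% MTF crossing is interpolated.
DEFAULT_CONFIG = {
    "housing_radius_cm": 10.0,
    "housing_hu": 0.0,
    "bar_frequencies_lpcm": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0],
    "bar_hu": 500.0,
    "bar_ring_radius_cm": 5.5,
    "low_contrast_hu": 10.0,        # 1.0% contrast over water
    "low_contrast_diameter_cm": 1.5,
    "sensitometry_hu": {
        "air": -1000.0,
        "pmp": -200.0,
        "ldpe": -100.0,
        "polystyrene": -35.0,
        "acrylic": 120.0,
        "delrin": 340.0,
        "teflon": 990.0,
    },
    "sensitometry_ring_radius_cm": 5.0,
    "sensitometry_diameter_cm": 1.25,
}


def build_default_phantom(config: dict | None = None) -> DigitalPhantom:
    """Assemble the default four-module phantom.

    Modules from superior to inferior: bar-pattern resolution section
    (z 4..8 cm), low-contrast section with a 1.5 cm diameter 1.0% insert
    (z 0..4), homogeneous section (z -4..0), and a sensitometry section
    whose density inserts (air insert included) span z -8..-4 inside a
    longer water column (down to z -13), so the air insert stays surrounded
    by material over the full superior-inferior motion range.

    ``config`` overrides entries of :data:`DEFAULT_CONFIG`.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        unknown = set(config) - set(DEFAULT_CONFIG)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(config)
    sens = cfg["sensitometry_hu"]
    if not isinstance(sens, dict) or not all(
        isinstance(v, (int, float)) and HU_MIN <= v <= HU_MAX
        for v in sens.values()
    ):
        raise ConfigurationError("invalid sensitometry HU table")

    freqs = list(cfg["bar_frequencies_lpcm"])
    bar_groups = []
    for k, f in enumerate(freqs):
        ang = 360.0 * k / max(len(freqs), 1)
        r = cfg["bar_ring_radius_cm"]
        bar_groups.append(BarGroupSpec(
            frequency=float(f), n_cycles=4,
            center=(r * math.cos(math.radians(ang)),
                    r * math.sin(math.radians(ang)), 6.0),
            bar_hu=float(cfg["bar_hu"]), background_hu=float(cfg["housing_hu"]),
            orientation=ang,
        ))

    inserts_sens = []
    labels = list(sens)
    for k, label in enumerate(labels):
        ang = math.radians(90.0 + 360.0 * k / max(len(labels), 1))
        r = cfg["sensitometry_ring_radius_cm"]
        inserts_sens.append(InsertSpec(
            label=label,
            center=(r * math.cos(ang), r * math.sin(ang), -6.0),
            radius=cfg["sensitometry_diameter_cm"] / 2,
            length=4.0,
            nominal_hu=float(sens[label]),
        ))

    modules = [
        PhantomModule("bar_patterns", (4.0, 8.0),
                      background_hu=cfg["housing_hu"], bar_groups=bar_groups),
        PhantomModule("low_contrast", (0.0, 4.0),
                      background_hu=cfg["housing_hu"],
                      inserts=[InsertSpec(
                          "low_contrast", (4.0, 0.0, 2.0),
                          radius=cfg["low_contrast_diameter_cm"] / 2,
                          length=4.0, nominal_hu=float(cfg["low_contrast_hu"]),
                      )]),
        PhantomModule("uniformity", (-4.0, 0.0),
                      background_hu=cfg["housing_hu"]),
        # extends well past the insert stack so that, over the full motion
        # range, no open air below the phantom enters the imaged region
        PhantomModule("sensitometry", (-13.0, -4.0),
                      background_hu=cfg["housing_hu"], inserts=inserts_sens),
    ]
    return DigitalPhantom(
        housing_radius=cfg["housing_radius_cm"], modules=modules,
        housing_hu=cfg["housing_hu"],
    )


# ---------------------------------------------------------------------------
# Voxelization (ground truth volumes)
# ---------------------------------------------------------------------------

def voxelize(phantom: DigitalPhantom, grid, si_shift: float = 0.0,
             mu_water: float = MU_WATER):
    """Sample the phantom on a voxel grid, returning a HU volume.

    Intended for ground-truth references; the simulation pipeline itself
    samples the analytic phantom directly.
    """
    from .reconstruction import VoxelVolume  # deferred: avoids import cycle

    xs, ys, zs = grid.axis_centers()
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    mu = sample_mu(phantom, pts, si_shift=si_shift, mu_water=mu_water)
    hu = mu_to_hu(mu, mu_water).reshape(grid.shape)
    return VoxelVolume(values=hu, spacing=grid.spacing, origin=grid.origin,
                       provenance={"source": "voxelized ground truth",
                                   "si_shift_cm": si_shift})


# ---------------------------------------------------------------------------
# TOML (de)serialization
# ---------------------------------------------------------------------------

def phantom_to_toml(phantom: DigitalPhantom) -> str:
    doc = {
        "housing_radius_cm": phantom.housing_radius,
        "housing_hu": phantom.housing_hu,
        "module": [
            {
                "name": m.name,
                "z_range_cm": list(m.z_range),
                "background_hu": m.background_hu,
                "insert": [
                    {"label": i.label, "center_cm": list(i.center),
                     "radius_cm": i.radius, "length_cm": i.length,
                     "nominal_hu": i.nominal_hu}
                    for i in m.inserts
                ],
                "bar_group": [
                    {"frequency_lpcm": b.frequency, "n_cycles": b.n_cycles,
                     "center_cm": list(b.center), "bar_hu": b.bar_hu,
                     "background_hu": b.background_hu,
                     "orientation_deg": b.orientation,
                     "bar_length_cm": b.bar_length,
                     "bar_height_cm": b.bar_height}
                    for b in m.bar_groups
                ],
            }
            for m in phantom.modules
        ],
    }
    return _toml.dumps(doc)


def phantom_from_toml(text: str) -> DigitalPhantom:
    doc = tomllib.loads(text)
    modules = []
    for m in doc.get("module", []):
        modules.append(PhantomModule(
            name=m["name"], z_range=tuple(m["z_range_cm"]),
            background_hu=m.get("background_hu", 0.0),
            inserts=[InsertSpec(i["label"], tuple(i["center_cm"]),
                                i["radius_cm"], i["length_cm"],
                                i["nominal_hu"])
                     for i in m.get("insert", [])],
            bar_groups=[BarGroupSpec(
                frequency=b["frequency_lpcm"], n_cycles=b["n_cycles"],
                center=tuple(b["center_cm"]), bar_hu=b["bar_hu"],
                background_hu=b["background_hu"],
                orientation=b["orientation_deg"],
                bar_length=b["bar_length_cm"], bar_height=b["bar_height_cm"])
                for b in m.get("bar_group", [])],
        ))
    return DigitalPhantom(
        housing_radius=doc["housing_radius_cm"], modules=modules,
        housing_hu=doc.get("housing_hu", 0.0),
    )
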