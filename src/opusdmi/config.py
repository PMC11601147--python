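"""Probe, acquisition and image-grid configuration.

Conventions (frozen; every matrix row/column index is meaningless without
them):

* Coordinate frame: ``x`` lateral (along the aperture), ``y`` elevational,
  ``z`` axial depth into the medium.  The aperture plane is ``z = 0`` and the
  single receiver sits at the origin.
* Pixel flattening: ``j = ix * n_z + iz`` (axial index fastest).
* Sample flattening (see :mod:`opusdmi.forward`): ``row = k * n_t + it``
  (time fastest within a channel).
* Units are SI internally (metres, seconds, Hz).  Config files may use
  suffixed keys (``aperture_width_mm``, ``sampling_rate_mhz``, ``dx_um`` ...)
  which are converted on load.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

logger = logging.getLogger("opusdmi")

DEFAULT_SEED = 20241121


class ConfigError(ValueError):
    """Raised when a configuration violates one or more invariants.

    The message lists *every* violated invariant, not just the first.
    """


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeGeometry:
    """Positions of the circular ultrasound sources and the point receiver.

    The probe modelled here is a linear aperture of circular piston sources
    (fibre-optic ultrasound generators, 200 µm diameter by default) with a
    single omnidirectional point receiver placed centrally within the
    aperture, all in the ``z = 0`` plane.
    """

    source_centers: np.ndarray          # (n_src, 3) metres
    source_radius: float = 100e-6       # metres
    receiver_position: np.ndarray = field(
        default_factory=lambda: np.zeros(3))
    aperture_width: float = 15e-3       # metres

    def __post_init__(self):
        object.__setattr__(self, "source_centers",
                           np.atleast_2d(np.asarray(self.source_centers, float)))
        object.__setattr__(self, "receiver_position",
                           np.asarray(self.receiver_position, float))
        errs = []
        if self.source_centers.ndim != 2 or self.source_centers.shape[1] != 3:
            errs.append("source_centers must be an (n, 3) array")
        else:
            if self.source_centers.shape[0] < 1:
                errs.append("at least one source is required")
            if np.any(np.abs(self.source_centers[:, 2]) > 1e-12):
                errs.append("all source centres must lie in the z=0 aperture plane")
            xs = self.source_centers[:, 0]
            rx = self.receiver_position[0]
            if xs.size and not (xs.min() - 1e-12 <= rx <= xs.max() + 1e-12):
                errs.append("receiver must lie within the lateral span of the sources")
        if abs(self.receiver_position[2]) > 1e-12:
            errs.append("receiver must lie in the z=0 aperture plane")
        if not self.source_radius > 0:
            errs.append("source_radius must be positive")
        if errs:
            raise ConfigError("; ".join(errs))

    @property
    def n_sources(self) -> int:
        return self.source_centers.shape[0]

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.source_centers).tobytes())
        h.update(np.ascontiguousarray(self.receiver_position).tobytes())
        h.update(np.float64(self.source_radius).tobytes())
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class AcquisitionSettings:
    """Time sampling of the RF record.

    ``time_origin`` is the instant of the first stored sample relative to the
    excitation (0 = record starts at the excitation instant); a positive
    origin crops the dead time before the first possible echo.
    """

    sampling_rate: float = 62.5e6       # Hz
    n_time_samples: int = 1004
    sound_speed: float = 1500.0         # m/s
    time_origin: float = 0.0            # seconds

    def __post_init__(self):
        errs = []
        if not self.sampling_rate > 0:
            errs.append("sampling_rate must be positive")
        if self.n_time_samples < 2:
            errs.append("n_time_samples must be at least 2")
        if not self.sound_speed > 0:
            errs.append("sound_speed must be positive")
        if errs:
            raise ConfigError("; ".join(errs))

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def time_axis(self) -> np.ndarray:
        return self.time_origin + np.arange(self.n_time_samples) * self.dt

    @property
    def record_end(self) -> float:
        return self.time_origin + self.n_time_samples / self.sampling_rate

    def content_hash(self) -> str:
        h = hashlib.sha256(repr((self.sampling_rate, self.n_time_samples,
                                 self.sound_speed, self.time_origin)).encode())
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class ImageGrid:
    """Lateral × axial pixel lattice.

    Pixel *centres* define the coordinates and include both extent endpoints,
    so a 10 mm lateral span at 50 µm pitch has 201 columns (this is the
    convention under which a 10×7 mm image at 50×25 µm holds 56 481 pixels).
    Flattened pixel index ``j = ix * n_z + iz`` (axial fastest).
    """

    x_extent: tuple[float, float] = (-5e-3, 5e-3)
    z_extent: tuple[float, float] = (0.0, 7e-3)
    dx: float = 50e-6
    dz: float = 25e-6

    def __post_init__(self):
        errs = []
        if not (self.dx > 0 and self.dz > 0):
            errs.append("pixel pitches dx, dz must be positive")
        if self.x_extent[1] < self.x_extent[0]:
            errs.append("x_extent must be increasing")
        if self.z_extent[1] < self.z_extent[0]:
            errs.append("z_extent must be increasing")
        if errs:
            raise ConfigError("; ".join(errs))
        object.__setattr__(self, "x_extent", (float(self.x_extent[0]),
                                              float(self.x_extent[1])))
        object.__setattr__(self, "z_extent", (float(self.z_extent[0]),
                                              float(self.z_extent[1])))

    @property
    def n_x(self) -> int:
        return int(round((self.x_extent[1] - self.x_extent[0]) / self.dx)) + 1

    @property
    def n_z(self) -> int:
        return int(round((self.z_extent[1] - self.z_extent[0]) / self.dz)) + 1

    @property
    def n_pixels(self) -> int:
        return self.n_x * self.n_z

    @property
    def x_coords(self) -> np.ndarray:
        return self.x_extent[0] + np.arange(self.n_x) * self.dx

    @property
    def z_coords(self) -> np.ndarray:
        return self.z_extent[0] + np.arange(self.n_z) * self.dz

    def flatten_index(self, ix, iz):
        ix = np.asarray(ix)
        iz = np.asarray(iz)
        if np.any((ix < 0) | (ix >= self.n_x) | (iz < 0) | (iz >= self.n_z)):
            raise IndexError("pixel index out of range")
        return ix * self.n_z + iz

    def unflatten_index(self, j):
        j = np.asarray(j)
        if np.any((j < 0) | (j >= self.n_pixels)):
            raise IndexError("flat pixel index out of range")
        return j // self.n_z, j % self.n_z

    def pixel_positions(self) -> np.ndarray:
        """All pixel centres as an (n_pixels, 3) array in flattening order."""
        xx, zz = np.meshgrid(self.x_coords, self.z_coords, indexing="ij")
        out = np.zeros((self.n_pixels, 3))
        out[:, 0] = xx.ravel()
        out[:, 2] = zz.ravel()
        return out

    def image_from_vector(self, vec: np.ndarray) -> np.ndarray:
        """Reshape a flattened reflectivity vector to an [n_z, n_x] image."""
        return np.asarray(vec).reshape(self.n_x, self.n_z).T

    def vector_from_image(self, img: np.ndarray) -> np.ndarray:
        return np.asarray(img).T.ravel()

    def content_hash(self) -> str:
        h = hashlib.sha256(repr((self.x_extent, self.z_extent,
                                 self.dx, self.dz)).encode())
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class InversionDefaults:
    """Runtime defaults for the regularised pseudo-inverse."""

    sv_threshold: float = 1e-4
    regularizer: str = "tikhonov"
    alpha: float = 0.01

    def __post_init__(self):
        errs = []
        if not (0 <= self.sv_threshold < 1):
            errs.append("sv_threshold must satisfy 0 <= threshold < 1")
        if self.regularizer not in ("tsvd", "tikhonov"):
            errs.append("regularizer must be 'tsvd' or 'tikhonov'")
        if self.alpha < 0:
            errs.append("alpha must be non-negative")
        if errs:
            raise ConfigError("; ".join(errs))


# --------------------------------------------------------------------------
# probe builder
# --------------------------------------------------------------------------

def make_default_probe(n_sources: int = 64,
                       aperture_width: float = 15e-3,
                       jitter_fraction: float = 0.0,
                       seed: int = DEFAULT_SEED,
                       source_radius: float = 100e-6) -> ProbeGeometry:
    """Uniformly spaced sources across the aperture, optionally jittered.

    The physical probe's irregular source layout is not published; a uniform
    array with seeded lateral jitter (uniform in
    ``±jitter_fraction × pitch``) stands in for it.  The receiver sits at the
    aperture centre (the origin).
    """
    if n_sources < 1:
        raise ConfigError("n_sources must be at least 1")
    if not (0 <= jitter_fraction < 0.5):
        raise ConfigError("jitter_fraction must satisfy 0 <= f < 0.5")
    if n_sources == 1:
        xs = np.zeros(1)
        pitch = aperture_width
    else:
        xs = np.linspace(-aperture_width / 2, aperture_width / 2, n_sources)
        pitch = aperture_width / (n_sources - 1)
    if jitter_fraction > 0:
        rng = np.random.default_rng(seed)
        xs = xs + rng.uniform(-jitter_fraction, jitter_fraction,
                              n_sources) * pitch
    xs_sorted = np.sort(xs)
    if n_sources > 1 and np.min(np.diff(xs_sorted)) < 2 * source_radius:
        raise ConfigError(
            "source discs overlap: minimum centre spacing "
            f"{np.min(np.diff(xs_sorted)) * 1e6:.1f} um < diameter "
            f"{2 * source_radius * 1e6:.1f} um")
    centers = np.zeros((n_sources, 3))
    centers[:, 0] = xs
    return ProbeGeometry(source_centers=centers, source_radius=source_radius,
                         aperture_width=aperture_width)


# --------------------------------------------------------------------------
# record-length validation
# --------------------------------------------------------------------------

def record_shortfall_samples(geometry: ProbeGeometry,
                             acquisition: AcquisitionSettings,
                             grid: ImageGrid) -> int:
    """Samples by which the record falls short of the longest two-way path.

    The longest path is taken over all (source, corner pixel, receiver)
    triples.  Non-positive result means the record is long enough.
    """
    xc = np.array(grid.x_extent)
    zc = np.array(grid.z_extent)
    corners = np.array([[x, 0.0, z] for x in xc for z in zc])
    d_src = np.linalg.norm(corners[None, :, :]
                           - geometry.source_centers[:, None, :], axis=-1)
    d_rec = np.linalg.norm(corners - geometry.receiver_position, axis=-1)
    t_max = float(np.max(d_src + d_rec[None, :])) / acquisition.sound_speed
    return int(np.ceil((t_max - acquisition.record_end)
                       * acquisition.sampling_rate))


def validate_record_length(geometry, acquisition, grid):
    short = record_shortfall_samples(geometry, acquisition, grid)
    if short > 0:
        raise ConfigError(
            f"record too short: two-way travel time to the deepest image "
            f"pixel exceeds the record end by {short} samples")


# --------------------------------------------------------------------------
# structured-text config (YAML)
# --------------------------------------------------------------------------

_UNIT_FACTORS = {
    "m": 1.0, "mm": 1e-3, "um": 1e-6,
    "s": 1.0, "ms": 1e-3, "us": 1e-6, "ns": 1e-9,
    "hz": 1.0, "khz": 1e3, "mhz": 1e6,
}


def _strip_units(section: dict) -> dict:
    """Resolve suffixed keys (``dx_um: 50`` -> ``dx: 50e-6``)."""
    out = {}
    for key, value in section.items():
        base, _, suffix = key.rpartition("_")
        if base and suffix in _UNIT_FACTORS:
            factor = _UNIT_FACTORS[suffix]
            if isinstance(value, (list, tuple)):
                value = [v * factor for v in value]
            else:
                value = value * factor
            key = base
        out[key] = value
    return out


def load_config(path):
    """Read a YAML config with sections probe/acquisition/grid/inversion.

    Returns ``(ProbeGeometry, AcquisitionSettings, ImageGrid,
    InversionDefaults)``.  Unspecified fields take the package defaults;
    validation failures list every violated invariant.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    known = {"probe", "acquisition", "grid", "inversion"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")

    probe_cfg = _strip_units(raw.get("probe", {}) or {})
    acq_cfg = _strip_units(raw.get("acquisition", {}) or {})
    grid_cfg = _strip_units(raw.get("grid", {}) or {})
    inv_cfg = _strip_units(raw.get("inversion", {}) or {})

    if "source_centers" in probe_cfg:
        geometry = ProbeGeometry(
            source_centers=np.asarray(probe_cfg["source_centers"], float),
            source_radius=probe_cfg.get("source_radius", 100e-6),
            receiver_position=np.asarray(
                probe_cfg.get("receiver_position", [0, 0, 0]), float),
            aperture_width=probe_cfg.get("aperture_width", 15e-3),
        )
    else:
        geometry = make_default_probe(
            n_sources=probe_cfg.get("n_sources", 64),
            aperture_width=probe_cfg.get("aperture_width", 15e-3),
            jitter_fraction=probe_cfg.get("jitter_fraction", 0.0),
            seed=probe_cfg.get("seed", DEFAULT_SEED),
            source_radius=probe_cfg.get("source_radius", 100e-6),
        )
    acquisition = AcquisitionSettings(
        sampling_rate=acq_cfg.get("sampling_rate", 62.5e6),
        n_time_samples=acq_cfg.get("n_time_samples", 1004),
        sound_speed=acq_cfg.get("sound_speed", 1500.0),
        time_origin=acq_cfg.get("time_origin", 0.0),
    )
    grid = ImageGrid(
        x_extent=tuple(grid_cfg.get("x_extent", (-5e-3, 5e-3))),
        z_extent=tuple(grid_cfg.get("z_extent", (0.0, 7e-3))),
        dx=grid_cfg.get("dx", 50e-6),
        dz=grid_cfg.get("dz", 25e-6),
    )
    inversion = InversionDefaults(
        sv_threshold=inv_cfg.get("sv_threshold", 1e-4),
        regularizer=inv_cfg.get("regularizer", "tikhonov"),
        alpha=inv_cfg.get("alpha", 0.01),
    )
    validate_record_length(geometry, acquisition, grid)
    return geometry, acquisition, grid, inversion


def save_config(path, geometry: ProbeGeometry,
                acquisition: AcquisitionSettings, grid: ImageGrid,
                inversion: InversionDefaults | None = None):
    """Write a config that :func:`load_config` reproduces field-exactly."""
    doc = {
        "probe": {
            "source_centers": [[float(v) for v in row]
                               for row in geometry.source_centers],
            "source_radius": float(geometry.source_radius),
            "receiver_position": [float(v)
                                  for v in geometry.receiver_position],
            "aperture_width": float(geometry.aperture_width),
        },
        "acquisition": {
            "sampling_rate": float(acquisition.sampling_rate),
            "n_time_samples": int(acquisition.n_time_samples),
            "sound_speed": float(acquisition.sound_speed),
            "time_origin": float(acquisition.time_origin),
        },
        "grid": {
            "x_extent": [float(grid.x_extent[0]), float(grid.x_extent[1])],
            "z_extent": [float(grid.z_extent[0]), float(grid.z_extent[1])],
            "dx": float(grid.dx),
            "dz": float(grid.dz),
        },
    }
    if inversion is not None:
        doc["inversion"] = dataclasses.asdict(inversion)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def full_size_matrix_bytes(geometry: ProbeGeometry | None = None,
                           acquisition: AcquisitionSettings | None = None,
                           grid: ImageGrid | None = None,
                           bytes_per_entry: int = 4) -> int:
    """Single-precision storage requirement of the system matrix, in bytes.

    Pure arithmetic: ``n_sources * n_time_samples * n_pixels * 4``.  With the
    package defaults (64 sources, 1004 samples, 201×281 pixels) this is the
    ~13.5 GiB bookkeeping figure for the full-size configuration.
    """
    geometry = geometry or make_default_probe()
    acquisition = acquisition or AcquisitionSettings()
    grid = grid or ImageGrid()
    return (geometry.n_sources * acquisition.n_time_samples
            * grid.n_pixels * bytes_per_entry)
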