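"""HDF5 persistence, run manifests and image export.

HDF5 is the single container for B-scans (``/rf``), system matrices
(``/P``) and SVD factor sets (``/U``, ``/S``, ``/V``); configuration
objects travel alongside the arrays as a YAML document in the ``/meta``
attributes so any artefact can be reloaded into fully validated objects.
Reconstruction operators are never persisted — they depend on the runtime
regulariser/alpha and are cheap to rebuild from the factors.  PNG/TIFF are
display formats only.
"""

from __future__ import annotations

import dataclasses
import getpass
import hashlib
import json
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from . import __version__
from .config import (AcquisitionSettings, ImageGrid, InversionDefaults,
                     ProbeGeometry)
from .forward import SourceSignature, SystemMatrix
from .inversion import SVDFactors
from .synthetic import BScan


# --------------------------------------------------------------------------
# config object <-> YAML strings
# --------------------------------------------------------------------------

def _objects_to_yaml(geometry=None, acquisition=None, grid=None,
                     signature=None) -> str:
    doc = {}
    if geometry is not None:
        doc["probe"] = {
            "source_centers": np.asarray(geometry.source_centers).tolist(),
            "source_radius": float(geometry.source_radius),
            "receiver_position":
                np.asarray(geometry.receiver_position).tolist(),
            "aperture_width": float(geometry.aperture_width),
        }
    if acquisition is not None:
        doc["acquisition"] = {
            "sampling_rate": float(acquisition.sampling_rate),
            "n_time_samples": int(acquisition.n_time_samples),
            "sound_speed": float(acquisition.sound_speed),
            "time_origin": float(acquisition.time_origin),
        }
    if grid is not None:
        doc["grid"] = {"x_extent": list(grid.x_extent),
                       "z_extent": list(grid.z_extent),
                       "dx": float(grid.dx), "dz": float(grid.dz)}
    if signature is not None:
        doc["signature"] = {
            "kind": signature.kind,
            "centre_frequency": float(signature.centre_frequency),
            "n_cycles": int(signature.n_cycles),
            "window": signature.window,
        }
        if signature.samples is not None:
            doc["signature"]["samples"] = signature.samples.tolist()
            doc["signature"]["sample_rate"] = float(signature.sample_rate)
    return yaml.safe_dump(doc, sort_keys=True)


def _objects_from_yaml(text: str):
    doc = yaml.safe_load(text) or {}
    geometry = acquisition = grid = signature = None
    if "probe" in doc:
        geometry = ProbeGeometry(
            source_centers=np.asarray(doc["probe"]["source_centers"]),
            source_radius=doc["probe"]["source_radius"],
            receiver_position=np.asarray(doc["probe"]["receiver_position"]),
            aperture_width=doc["probe"]["aperture_width"])
    if "acquisition" in doc:
        acquisition = AcquisitionSettings(**doc["acquisition"])
    if "grid" in doc:
        g = doc["grid"]
        grid = ImageGrid(x_extent=tuple(g["x_extent"]),
                         z_extent=tuple(g["z_extent"]),
                         dx=g["dx"], dz=g["dz"])
    if "signature" in doc:
        s = dict(doc["signature"])
        if "samples" in s:
            s["samples"] = np.asarray(s.pop("samples"))
        signature = SourceSignature(**s)
    return geometry, acquisition, grid, signature


# --------------------------------------------------------------------------
# B-scans
# --------------------------------------------------------------------------

def save_bscan(path, bscan: BScan):
    with h5py.File(path, "w") as fh:
        fh.create_dataset("rf", data=np.asarray(bscan.samples, np.float32))
        meta = fh.create_group("meta")
        meta.attrs["config"] = _objects_to_yaml(
            geometry=bscan.geometry, acquisition=bscan.acquisition)
        meta.attrs["provenance"] = json.dumps(bscan.provenance, sort_keys=True)
        meta.attrs["row_convention"] = \
            "row = source * n_t + time (time fastest)"


def load_bscan(path) -> BScan:
    with h5py.File(path, "r") as fh:
        samples = fh["rf"][()]
        geometry, acquisition, _, _ = _objects_from_yaml(
            fh["meta"].attrs["config"])
        provenance = json.loads(fh["meta"].attrs["provenance"])
    return BScan(samples=np.asarray(samples, np.float64),
                 acquisition=acquisition, geometry=geometry,
                 provenance=provenance)


# --------------------------------------------------------------------------
# system matrices and factors
# --------------------------------------------------------------------------

def save_system_matrix(path, sm: SystemMatrix, column_chunk: int = 256):
    with h5py.File(path, "w") as fh:
        chunk = (sm.entries.shape[0], min(column_chunk,
                                          sm.entries.shape[1]))
        fh.create_dataset("P", data=sm.entries, chunks=chunk)
        meta = fh.create_group("meta")
        meta.attrs["config"] = _objects_to_yaml(
            geometry=sm.geometry, acquisition=sm.acquisition, grid=sm.grid,
            signature=sm.signature)
        meta.attrs["provenance_hash"] = sm.provenance_hash()
        meta.attrs["row_convention"] = sm.row_convention
        meta.attrs["col_convention"] = sm.col_convention


def load_system_matrix(path) -> SystemMatrix:
    with h5py.File(path, "r") as fh:
        entries = fh["P"][()]
        geometry, acquisition, grid, signature = _objects_from_yaml(
            fh["meta"].attrs["config"])
        stored_hash = fh["meta"].attrs["provenance_hash"]
    sm = SystemMatrix(entries=entries, geometry=geometry,
                      acquisition=acquisition, grid=grid,
                      signature=signature)
    if sm.provenance_hash() != stored_hash:
        raise IOError("system matrix provenance hash mismatch on load")
    return sm


def save_factors(path, factors: SVDFactors):
    with h5py.File(path, "w") as fh:
        fh.create_dataset("U", data=factors.U)
        fh.create_dataset("S", data=factors.S)
        fh.create_dataset("V", data=factors.V)
        meta = fh.create_group("meta")
        meta.attrs["sv_threshold"] = factors.sv_threshold
        meta.attrs["provenance"] = factors.provenance
        meta.attrs["backend"] = factors.backend
        if factors.matrix is not None:
            sm = factors.matrix
            meta.attrs["config"] = _objects_to_yaml(
                geometry=sm.geometry, acquisition=sm.acquisition,
                grid=sm.grid, signature=sm.signature)


def load_factors(path, matrix: SystemMatrix | None = None) -> SVDFactors:
    """Load factors; if the source matrix is unavailable, a shape-consistent
    metadata-only :class:`SystemMatrix` stub is rebuilt when possible so the
    operators keep their provenance checks."""
    with h5py.File(path, "r") as fh:
        U, S, V = fh["U"][()], fh["S"][()], fh["V"][()]
        meta = fh["meta"]
        threshold = float(meta.attrs["sv_threshold"])
        provenance = str(meta.attrs["provenance"])
        backend = str(meta.attrs["backend"])
        config = meta.attrs.get("config")
    if matrix is None and config is not None:
        geometry, acquisition, grid, signature = _objects_from_yaml(config)
        if geometry is not None:
            stub = np.broadcast_to(
                np.zeros(1, np.float32),
                (geometry.n_sources * acquisition.n_time_samples,
                 grid.n_pixels))
            matrix = SystemMatrix(entries=stub, geometry=geometry,
                                  acquisition=acquisition, grid=grid,
                                  signature=signature)
    return SVDFactors(U=U, S=S, V=V, sv_threshold=threshold,
                      provenance=provenance, backend=backend, matrix=matrix)


# --------------------------------------------------------------------------
# run manifests
# --------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Reproducibility record written alongside every CLI output."""

    command: str
    arguments: dict
    inputs: dict = field(default_factory=dict)      # path -> sha256
    outputs: list = field(default_factory=list)
    seeds: dict = field(default_factory=dict)
    wall_time_s: float = 0.0
    package_version: str = __version__
    host: str = ""

    def write(self, path):
        doc = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()[:16]


def make_manifest(command: str, arguments: dict, inputs=(), seeds=None,
                  t_start: float | None = None) -> RunManifest:
    try:
        host = f"{getpass.getuser()}@{platform.node()}"
    except Exception:
        host = platform.node()
    return RunManifest(
        command=command,
        arguments={k: (str(v) if isinstance(v, Path) else v)
                   for k, v in arguments.items()},
        inputs={str(p): file_digest(p) for p in inputs},
        seeds=dict(seeds or {}),
        wall_time_s=(time.time() - t_start) if t_start else 0.0,
        host=host)


# --------------------------------------------------------------------------
# image export
# --------------------------------------------------------------------------

def export_image(image: np.ndarray, grid: ImageGrid, dynamic_range: float,
                 path_base, annotated: bool = False) -> list:
    """Write a dB-scaled 8-bit PNG and a float32 TIFF of an image.

    The PNG grey levels span exactly [-dynamic_range, 0] dB; the TIFF stores
    the raw float image with the physical pixel pitches recorded in its
    description tag.  With ``annotated=True`` an additional PNG with mm axes
    is produced (requires matplotlib).
    """
    import imageio.v3 as iio
    import tifffile

    from .metrics import to_db

    base = Path(path_base)
    base.parent.mkdir(parents=True, exist_ok=True)
    written = []

    db = to_db(image, dynamic_range)
    levels = np.round((db + dynamic_range) / dynamic_range * 255)
    png_path = base.with_suffix(".png")
    iio.imwrite(png_path, levels.astype(np.uint8))
    written.append(png_path)

    tif_path = base.with_suffix(".tiff")
    tifffile.imwrite(
        tif_path, np.asarray(image, np.float32),
        description=json.dumps({"dx_m": grid.dx, "dz_m": grid.dz,
                                "x_extent_m": list(grid.x_extent),
                                "z_extent_m": list(grid.z_extent)}),
        resolution=(1e-4 / grid.dx, 1e-4 / grid.dz),
        resolutionunit="CENTIMETER")
    written.append(tif_path)

    if annotated:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        extent = [grid.x_extent[0] * 1e3, grid.x_extent[1] * 1e3,
                  grid.z_extent[1] * 1e3, grid.z_extent[0] * 1e3]
        im = ax.imshow(db, cmap="gray", extent=extent, aspect="equal",
                       vmin=-dynamic_range, vmax=0)
        ax.set_xlabel("lateral x (mm)")
        ax.set_ylabel("depth z (mm)")
        fig.colorbar(im, ax=ax, label="dB")
        fig_path = base.with_name(base.stem + "_annotated.png")
        fig.savefig(fig_path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(fig_path)
    return written
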