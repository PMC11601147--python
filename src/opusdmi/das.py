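"""Delay-and-sum baseline for the single-receiver geometry.

For every pixel the round-trip delay of each source is computed,

    tau_jk = (|r_src,k - r_img,j| + |r_img,j - r_rec|) / c ,

the RF record of channel ``k`` is sampled at ``tau_jk`` (nearest or linear
interpolation; delays outside the record contribute zero) and the samples
are summed without apodisation.  With a single receiver no receive
beamforming is possible, so every channel smears its echo along an ellipse
of constant delay; the sparse transmit aperture additionally produces the
wing-shaped grating-lobe artefacts that model-based inversion is meant to
suppress — the baseline deliberately leaves both untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import AcquisitionSettings, ImageGrid, ProbeGeometry
from .metrics import axial_envelope


@dataclass(frozen=True)
class DasSettings:
    interpolation: str = "linear"       # nearest | linear
    envelope: str = "axial_analytic"    # none | axial_analytic
    normalisation: str = "peak"         # none | peak

    def __post_init__(self):
        if self.interpolation not in ("nearest", "linear"):
            raise ValueError(f"unknown interpolation {self.interpolation!r}")
        if self.envelope not in ("none", "axial_analytic"):
            raise ValueError(f"unknown envelope mode {self.envelope!r}")
        if self.normalisation not in ("none", "peak"):
            raise ValueError(f"unknown normalisation {self.normalisation!r}")


def das_reconstruct(bscan, geometry: ProbeGeometry, grid: ImageGrid,
                    acquisition: AcquisitionSettings,
                    settings: DasSettings = DasSettings()) -> np.ndarray:
    """Unapodised delay-and-sum image [n_z, n_x]."""
    if bscan.samples.shape[1] != geometry.n_sources:
        raise ValueError("B-scan channel count disagrees with geometry")
    if bscan.acquisition.content_hash() != acquisition.content_hash():
        raise ValueError("B-scan acquisition settings disagree")
    pixels = grid.pixel_positions()
    r_rec = np.linalg.norm(pixels - geometry.receiver_position[None, :],
                           axis=1)
    samples = np.asarray(bscan.samples, np.float64)
    n_t = acquisition.n_time_samples
    img = np.zeros(grid.n_pixels)
    for k in range(geometry.n_sources):
        r_src = np.linalg.norm(pixels - geometry.source_centers[k][None, :],
                               axis=1)
        tau = (r_src + r_rec) / acquisition.sound_speed
        s = (tau - acquisition.time_origin) * acquisition.sampling_rate
        if settings.interpolation == "nearest":
            idx = np.rint(s).astype(np.int64)
            valid = (idx >= 0) & (idx < n_t)
            img[valid] += samples[idx[valid], k]
        else:
            i0 = np.floor(s).astype(np.int64)
            frac = s - i0
            valid = (i0 >= 0) & (i0 < n_t - 1)
            iv = i0[valid]
            img[valid] += samples[iv, k] * (1 - frac[valid]) \
                + samples[iv + 1, k] * frac[valid]
    image = grid.image_from_vector(img)
    if settings.envelope == "axial_analytic":
        image = axial_envelope(image)
    if settings.normalisation == "peak":
        peak = np.max(np.abs(image))
        if peak > 0:
            image = image / peak
    return image
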