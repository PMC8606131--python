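"""HSV composite rendering and orthogonal slice extraction.

A dynamics tomogram is displayed as an HSV composite: the dynamics value
drives the hue (red → green at the defaults, so necrotic tissue appears
red and viable tissue green), the OCT intensity drives the value channel
(dim voxels fade to black regardless of their dynamics), and saturation
is 1 everywhere.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from matplotlib.colors import hsv_to_rgb
from pydantic import BaseModel, Field, model_validator

from .stack import DynamicsVolume


class DisplayRange(BaseModel):
    """Linear mapping ranges for the HSV composite.

    Dynamics values are clipped to [dynamics_lo, dynamics_hi] and mapped
    onto [hue_lo_deg, hue_hi_deg]; intensity is clipped to
    [intensity_lo, intensity_hi] and mapped onto value [0, 1].
    """

    dynamics_lo: float = 0.0
    dynamics_hi: float
    intensity_lo: float
    intensity_hi: float
    hue_lo_deg: float = 0.0    # red
    hue_hi_deg: float = 120.0  # green

    @model_validator(mode="after")
    def _ordered(self) -> "DisplayRange":
        for lo, hi, name in ((self.dynamics_lo, self.dynamics_hi, "dynamics"),
                             (self.intensity_lo, self.intensity_hi, "intensity"),
                             (self.hue_lo_deg, self.hue_hi_deg, "hue")):
            if not lo < hi:
                raise ValueError(f"{name} range degenerate: lo={lo} !< hi={hi}")
        return self


#: default dynamics display spans (intensity span 40 dB ending at 35 dB)
def default_display_range(metric: str,
                          intensity_lo: float = -5.0,
                          intensity_hi: float = 35.0) -> DisplayRange:
    spans = {"liv": 10.0, "ocdsl": 6e-4}
    if metric not in spans:
        raise ValueError(f"unknown metric {metric!r}")
    return DisplayRange(dynamics_lo=0.0, dynamics_hi=spans[metric],
                        intensity_lo=intensity_lo, intensity_hi=intensity_hi)


def hsv_composite(dynamics: np.ndarray,
                  intensity_db: np.ndarray,
                  drange: DisplayRange) -> np.ndarray:
    """RGB image (float, [0, 1]) of a dynamics slice over an intensity slice."""
    dyn = np.asarray(dynamics, dtype=np.float64)
    inten = np.asarray(intensity_db, dtype=np.float64)
    if dyn.shape != inten.shape:
        raise ValueError(f"dynamics shape {dyn.shape} != intensity shape {inten.shape}")
    dfrac = (np.clip(dyn, drange.dynamics_lo, drange.dynamics_hi) - drange.dynamics_lo) \
        / (drange.dynamics_hi - drange.dynamics_lo)
    value = (np.clip(inten, drange.intensity_lo, drange.intensity_hi) - drange.intensity_lo) \
        / (drange.intensity_hi - drange.intensity_lo)
    hue = (drange.hue_lo_deg + dfrac * (drange.hue_hi_deg - drange.hue_lo_deg)) / 360.0
    hsv = np.stack([hue, np.ones_like(hue), value], axis=-1)
    return hsv_to_rgb(hsv)


class PlaneSlice(NamedTuple):
    """A 2D orthogonal slice with its axis names and physical extents (µm)."""

    data: np.ndarray
    axes: tuple[str, str]
    extent_um: tuple[float, float]


_PLANES = ("fast", "slow", "enface")


def extract_slice(volume: np.ndarray | DynamicsVolume,
                  plane: str,
                  index: int,
                  *,
                  x_pitch_um: float | None = None,
                  y_pitch_um: float | None = None,
                  z_pitch_um: float | None = None) -> PlaneSlice:
    """Orthogonal slice of a (location, depth, fast) volume.

    ``fast``: the B-scan plane (depth × fast axis) at one slow-axis
    location; ``slow``: depth × location at one fast-axis column;
    ``enface``: location × fast at one depth.
    """
    if isinstance(volume, DynamicsVolume):
        if x_pitch_um is None:
            x_pitch_um, y_pitch_um, z_pitch_um = (
                volume.x_pitch_um, volume.y_pitch_um, volume.z_pitch_um)
        vol = volume.values
    else:
        vol = np.asarray(volume)
    if vol.ndim != 3:
        raise ValueError(f"volume must be 3D, got shape {vol.shape}")
    xp = 1.0 if x_pitch_um is None else x_pitch_um
    yp = 1.0 if y_pitch_um is None else y_pitch_um
    zp = 1.0 if z_pitch_um is None else z_pitch_um
    ny, nz, nx = vol.shape
    if plane == "fast":
        axis_len, sl = ny, lambda i: vol[i]
        axes, ext = ("depth", "fast"), (nz * zp, nx * xp)
    elif plane == "slow":
        axis_len, sl = nx, lambda i: vol[:, :, i].T
        axes, ext = ("depth", "slow"), (nz * zp, ny * yp)
    elif plane == "enface":
        axis_len, sl = nz, lambda i: vol[:, i, :]
        axes, ext = ("slow", "fast"), (ny * yp, nx * xp)
    else:
        raise ValueError(f"plane must be one of {_PLANES}, got {plane!r}")
    if not 0 <= index < axis_len:
        raise IndexError(f"slice index {index} out of range [0, {axis_len}) for plane {plane!r}")
    return PlaneSlice(data=sl(index), axes=axes, extent_um=ext)
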