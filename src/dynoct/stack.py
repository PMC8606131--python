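"""In-memory containers for 4D dynamics-OCT data.

Axis convention, fixed project-wide (see also the JSON sidecars written by
:mod:`dynoct.io`):

    ``(location, repeat, depth, fast)``  ==  ``(y, t, z, x)``

``location`` indexes the slow galvo axis (B-scan position), ``repeat`` the
time axis (repeated B-scans at the same position, spaced ``dt_ms``
apart), ``depth`` the axial direction and ``fast`` the fast galvo axis.
All indices are 0-based.

Units: intensity in dB, time in ms, space in µm, LIV in dB², OCDS in ms⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: default pixel pitches of the modelled instrument, µm
DEFAULT_X_PITCH_UM = 1.95
DEFAULT_Z_PITCH_UM = 7.24
DEFAULT_Y_PITCH_UM = 1000.0 / 128.0  # 1 mm slow-axis scan over 128 locations


@dataclass
class TimeSeriesStack:
    """A 4D stack of repeated, co-located B-scans on the dB scale.

    ``data[y, i]`` is the *i*-th repeat of the B-scan at slow-axis location
    *y*; repeats are ``dt_ms`` apart in wall-clock time.
    """

    data: np.ndarray  # (location, repeat, depth, fast), dB
    dt_ms: float
    x_pitch_um: float = DEFAULT_X_PITCH_UM
    y_pitch_um: float = DEFAULT_Y_PITCH_UM
    z_pitch_um: float = DEFAULT_Z_PITCH_UM

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(
                f"stack data must be 4D (location, repeat, depth, fast); got shape {self.data.shape}"
            )
        if self.dt_ms <= 0:
            raise ValueError(f"dt_ms must be > 0, got {self.dt_ms}")
        for name, v in (("x_pitch_um", self.x_pitch_um),
                        ("y_pitch_um", self.y_pitch_um),
                        ("z_pitch_um", self.z_pitch_um)):
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")

    @property
    def n_locations(self) -> int:
        return self.data.shape[0]

    @property
    def n_repeats(self) -> int:
        """The N of the LIV estimator: repeated frames per location."""
        return self.data.shape[1]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        """(location, depth, fast) shape of derived 3D volumes."""
        return (self.data.shape[0], self.data.shape[2], self.data.shape[3])

    @property
    def voxel_volume_um3(self) -> float:
        return self.x_pitch_um * self.y_pitch_um * self.z_pitch_um

    def tau_grid_ms(self, i_max: int) -> np.ndarray:
        """Delay grid τ_i = i·Δt for i = 0..i_max."""
        return np.arange(i_max + 1, dtype=np.float64) * self.dt_ms

    def validate_finite(self) -> None:
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack contains non-finite values")


@dataclass
class DynamicsVolume:
    """A 3D dynamics map co-registered with the mean-intensity volume.

    ``metric`` is ``"liv"`` (units dB²) or ``"ocdsl"`` (units ms⁻¹).
    """

    values: np.ndarray  # (location, depth, fast)
    metric: str
    mean_intensity_db: np.ndarray
    x_pitch_um: float = DEFAULT_X_PITCH_UM
    y_pitch_um: float = DEFAULT_Y_PITCH_UM
    z_pitch_um: float = DEFAULT_Z_PITCH_UM

    _UNITS = {"liv": "dB^2", "ocdsl": "ms^-1"}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mean_intensity_db = np.asarray(self.mean_intensity_db, dtype=np.float64)
        if self.metric not in self._UNITS:
            raise ValueError(f"metric must be one of {sorted(self._UNITS)}, got {self.metric!r}")
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got shape {self.values.shape}")
        if self.mean_intensity_db.shape != self.values.shape:
            raise ValueError("mean_intensity_db shape must match values shape")

    @property
    def units(self) -> str:
        return self._UNITS[self.metric]

    @property
    def voxel_volume_um3(self) -> float:
        return self.x_pitch_um * self.y_pitch_um * self.z_pitch_um


@dataclass
class ACFProfile:
    """Per-voxel temporal autocorrelation ρ_A(τ_i) on the delay grid τ_i = i·Δt.

    ``rho`` has shape ``(location, lag, depth, fast)`` with ``lag`` running
    0..i_max.  ``degenerate`` flags (per voxel and lag) where the pooled
    variance vanished and ρ was defined by convention (1 at lag 0, 0 at
    later lags) instead of computed.
    """

    rho: np.ndarray  # (location, lag, depth, fast)
    tau_ms: np.ndarray  # (lag,)
    dt_ms: float
    degenerate: Optional[np.ndarray] = None
    mean_intensity_db: Optional[np.ndarray] = None
    x_pitch_um: float = DEFAULT_X_PITCH_UM
    y_pitch_um: float = DEFAULT_Y_PITCH_UM
    z_pitch_um: float = DEFAULT_Z_PITCH_UM

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=np.float64)
        self.tau_ms = np.asarray(self.tau_ms, dtype=np.float64)
        if self.rho.ndim != 4:
            raise ValueError(f"rho must be 4D (location, lag, depth, fast), got {self.rho.shape}")
        if self.tau_ms.shape != (self.rho.shape[1],):
            raise ValueError("tau_ms length must equal the lag axis of rho")

    @property
    def n_lags(self) -> int:
        return self.rho.shape[1]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return (self.rho.shape[0], self.rho.shape[2], self.rho.shape[3])
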