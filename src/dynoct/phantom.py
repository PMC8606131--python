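"""Synthetic spheroid phantoms with known ground-truth dynamics.

The phantom emulates the statistical signature that a tumor spheroid
leaves in a repeated-B-scan dB-intensity record: a sphere embedded in a
low-backscatter medium, with a high-fluctuation viable shell and a
low-fluctuation necrotic core.  Each voxel's dB time series is

    I_dB(t_i) = mean_db + s(t_i) + ε_i

with ``s`` a stationary zero-mean Gaussian AR(1) process of variance
``sigma2_db2`` and autocorrelation exp(−τ/τ_c) on the Δt grid
(AR coefficient φ = exp(−Δt/τ_c) — the unique discrete Gaussian process
with exactly exponential ACF), and ε i.i.d. N(0, noise_db2) white
measurement noise.  Voxels are mutually independent.  Every expectation
of the LIV / ACF / OCDS estimators is therefore closed-form:

    E[LIV]  = (σ_d² + σ_n²)·(N−1)/N
    E[ρ(τ)] ≈ r·exp(−τ/τ_c),   r = σ_d² / (σ_d² + σ_n²)

This is a statistical stand-in for sub-cellular motion, not a physical
speckle model (dB fluctuations of real speckle are not Gaussian); it is
what makes the estimation pipeline testable end-to-end with exact
oracles.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .stack import (
    DEFAULT_X_PITCH_UM,
    DEFAULT_Y_PITCH_UM,
    DEFAULT_Z_PITCH_UM,
    TimeSeriesStack,
)

LABEL_MEDIUM, LABEL_SHELL, LABEL_CORE = 0, 1, 2
LABEL_NAMES = {LABEL_MEDIUM: "medium", LABEL_SHELL: "shell", LABEL_CORE: "core"}


class CompartmentDynamics(BaseModel):
    """Dynamics parameters of one phantom compartment.

    ``sigma2_db2`` is the target fluctuation variance (the LIV scale),
    ``tau_c_ms`` the exponential decorrelation time, ``noise_db2`` the
    white measurement-noise variance.
    """

    mean_db: float
    sigma2_db2: float = Field(ge=0)
    tau_c_ms: float = Field(gt=0)
    noise_db2: float = Field(ge=0)


#: default study conditions: shell well above the 3 dB² / 2e-4 ms⁻¹
#: viability cutoffs, core well below, medium dim and static.
DEFAULT_SHELL = CompartmentDynamics(mean_db=30.0, sigma2_db2=8.0, tau_c_ms=400.0, noise_db2=0.2)
DEFAULT_CORE = CompartmentDynamics(mean_db=25.0, sigma2_db2=0.5, tau_c_ms=6000.0, noise_db2=0.3)
DEFAULT_MEDIUM = CompartmentDynamics(mean_db=5.0, sigma2_db2=0.05, tau_c_ms=200.0, noise_db2=0.3)


class PhantomSpec(BaseModel):
    """Geometry + dynamics of a two-compartment spheroid phantom.

    The grid is (location, depth, fast) with anisotropic pitches; the
    spheroid is a sphere of ``spheroid_radius_um`` (necrotic core inside
    ``core_radius_um``) centered at ``center_um`` (grid center when
    omitted), and must fit inside the grid.
    """

    shape: tuple[int, int, int] = (72, 104, 288)  # (location, depth, fast)
    x_pitch_um: float = Field(default=DEFAULT_X_PITCH_UM, gt=0)
    y_pitch_um: float = Field(default=DEFAULT_Y_PITCH_UM, gt=0)
    z_pitch_um: float = Field(default=DEFAULT_Z_PITCH_UM, gt=0)
    spheroid_radius_um: float = Field(default=250.0, gt=0)
    core_radius_um: float = Field(default=150.0, ge=0)
    center_um: Optional[tuple[float, float, float]] = None  # (y, z, x), µm
    shell: CompartmentDynamics = DEFAULT_SHELL
    core: CompartmentDynamics = DEFAULT_CORE
    medium: CompartmentDynamics = DEFAULT_MEDIUM
    n_repeats: int = Field(default=32, ge=2)
    dt_ms: float = Field(default=204.8, gt=0)
    rng_seed: int = 0

    @model_validator(mode="after")
    def _geometry_valid(self) -> "PhantomSpec":
        if self.core_radius_um > self.spheroid_radius_um:
            raise ValueError("core_radius_um must be <= spheroid_radius_um")
        center = self.resolved_center_um()
        extents = self.extent_um()
        for ax, (c, e) in enumerate(zip(center, extents)):
            if c - self.spheroid_radius_um < -1e-9 or c + self.spheroid_radius_um > e + 1e-9:
                raise ValueError(
                    f"spheroid (center {center}, radius {self.spheroid_radius_um} µm) "
                    f"exceeds grid extent {extents} µm on axis {ax}"
                )
        return self

    def pitches_um(self) -> tuple[float, float, float]:
        """(y, z, x) pitches, µm — grid axis order."""
        return (self.y_pitch_um, self.z_pitch_um, self.x_pitch_um)

    def extent_um(self) -> tuple[float, float, float]:
        return tuple((n - 1) * p for n, p in zip(self.shape, self.pitches_um()))

    def resolved_center_um(self) -> tuple[float, float, float]:
        if self.center_um is not None:
            return self.center_um
        return tuple(e / 2.0 for e in self.extent_um())


def label_volume(spec: PhantomSpec) -> tuple[np.ndarray, dict[str, int]]:
    """Ground-truth label map (0 medium, 1 shell, 2 core) and per-label counts.

    A voxel at indices (iy, iz, ix) sits at physical position
    (iy·y_pitch, iz·z_pitch, ix·x_pitch) µm; labels are assigned by
    Euclidean distance to the sphere center.
    """
    center = spec.resolved_center_um()
    coords = [
        (np.arange(n) * p - c)
        for n, p, c in zip(spec.shape, spec.pitches_um(), center)
    ]
    d2 = (coords[0][:, None, None] ** 2
          + coords[1][None, :, None] ** 2
          + coords[2][None, None, :] ** 2)
    labels = np.zeros(spec.shape, dtype=np.uint8)
    labels[d2 <= spec.spheroid_radius_um ** 2] = LABEL_SHELL
    labels[d2 <= spec.core_radius_um ** 2] = LABEL_CORE
    counts = {name: int((labels == lab).sum()) for lab, name in LABEL_NAMES.items()}
    return labels, counts


def _ar1_series(comp: CompartmentDynamics, n_voxels: int, n_repeats: int,
                dt_ms: float, rng: np.random.Generator) -> np.ndarray:
    """(n_repeats, n_voxels) dB series for one compartment."""
    phi = np.exp(-dt_ms / comp.tau_c_ms)
    sigma = np.sqrt(comp.sigma2_db2)
    innov = sigma * np.sqrt(max(1.0 - phi * phi, 0.0))
    noise = np.sqrt(comp.noise_db2)
    out = np.empty((n_repeats, n_voxels), dtype=np.float64)
    s = rng.normal(0.0, sigma, size=n_voxels)
    for t in range(n_repeats):
        out[t] = comp.mean_db + s + rng.normal(0.0, noise, size=n_voxels)
        s = phi * s + rng.normal(0.0, innov, size=n_voxels)
    return out


def simulate_stack(spec: PhantomSpec, seed: int | None = None
                   ) -> tuple[TimeSeriesStack, np.ndarray]:
    """Simulate the repeated-B-scan stack of a phantom.

    Returns the (location, repeat, depth, fast) stack and the ground-truth
    label map.  Identical ``seed`` (or ``spec.rng_seed`` when None) gives
    byte-identical output.
    """
    rng = np.random.default_rng(spec.rng_seed if seed is None else seed)
    labels, _ = label_volume(spec)
    ny, nz, nx = spec.shape
    data = np.empty((ny, spec.n_repeats, nz, nx), dtype=np.float64)
    view = data.swapaxes(0, 1)  # (repeat, location, depth, fast)
    for lab, comp in ((LABEL_MEDIUM, spec.medium),
                      (LABEL_SHELL, spec.shell),
                      (LABEL_CORE, spec.core)):
        mask = labels == lab
        n_vox = int(mask.sum())
        if n_vox == 0:
            continue
        series = _ar1_series(comp, n_vox, spec.n_repeats, spec.dt_ms, rng)
        for t in range(spec.n_repeats):
            view[t][mask] = series[t]
    stack = TimeSeriesStack(
        data=data,
        dt_ms=spec.dt_ms,
        x_pitch_um=spec.x_pitch_um,
        y_pitch_um=spec.y_pitch_um,
        z_pitch_um=spec.z_pitch_um,
    )
    return stack, labels


def simulate_uniform(comp: CompartmentDynamics,
                     shape: tuple[int, int, int],
                     *,
                     n_repeats: int = 32,
                     dt_ms: float = 204.8,
                     seed: int = 0,
                     x_pitch_um: float = DEFAULT_X_PITCH_UM,
                     y_pitch_um: float = DEFAULT_Y_PITCH_UM,
                     z_pitch_um: float = DEFAULT_Z_PITCH_UM) -> TimeSeriesStack:
    """Single-compartment stack (every voxel drawn from ``comp``).

    Convenience for estimator calibration: i.i.d. Gaussian voxels are the
    ``sigma2_db2 = 0`` + ``noise_db2 > 0`` corner of the model.
    """
    rng = np.random.default_rng(seed)
    ny, nz, nx = shape
    series = _ar1_series(comp, ny * nz * nx, n_repeats, dt_ms, rng)
    data = series.reshape(n_repeats, ny, nz, nx).swapaxes(0, 1).copy()
    return TimeSeriesStack(data=data, dt_ms=dt_ms, x_pitch_um=x_pitch_um,
                           y_pitch_um=y_pitch_um, z_pitch_um=z_pitch_um)


#: shell (sigma2_db2, tau_c_ms) stages of the default viability-decline
#: series: fluctuation magnitude shrinks and decorrelation slows as the
#: shell loses viability, so mean LIV, mean OCDS and both viable ratios
#: fall stage over stage.
DEFAULT_DECLINE_STAGES: tuple[tuple[float, float], ...] = (
    (8.0, 400.0), (4.0, 1400.0), (2.0, 3000.0), (1.0, 7000.0),
)


def viability_decline_series(base: PhantomSpec | None = None,
                             stages: Sequence[tuple[float, float]] = DEFAULT_DECLINE_STAGES,
                             ) -> list[PhantomSpec]:
    """Phantom time course emulating progressive loss of shell viability.

    Each stage reuses ``base`` with the shell's (sigma2_db2, tau_c_ms)
    replaced; seeds differ per stage so stages are independent draws.
    """
    base = base or PhantomSpec()
    specs = []
    for j, (sigma2, tau_c) in enumerate(stages):
        shell = base.shell.model_copy(update={"sigma2_db2": sigma2, "tau_c_ms": tau_c})
        specs.append(base.model_copy(update={"shell": shell,
                                             "rng_seed": base.rng_seed + j}))
    return specs
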