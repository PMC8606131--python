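"""Dynamics contrasts from repeated B-scans: LIV, pooled ACF, and OCDS.

Two complementary statistics summarize the temporal speckle fluctuation of
the dB-scale OCT signal at each voxel:

* **LIV** (logarithmic intensity variance, dB²): the population (1/N)
  variance of the N-point dB time series.  Sensitive to the *magnitude*
  of the fluctuation.

* **OCDSl** (late OCT correlation decay speed, ms⁻¹): the negated
  ordinary-least-squares slope of the temporal autocorrelation ρ_A(τ)
  over a late delay window (default [204.8, 1228.8] ms, i.e. lags 1..6
  at Δt = 204.8 ms).  Sensitive to *slow* dynamics; faster decorrelation
  gives a larger OCDSl.

With only N = 32 repeats the single-voxel autocorrelation is noisy, so
ρ_A is estimated from a small spatial kernel (default 2 axial × 4 lateral
pixels) centered on each voxel: for lag i, the covariance and the two
per-lag variances are accumulated over *all* kernel pixels and all N − i
overlapping time pairs, with the per-lag means taken over that same
pooled sample.  Pooling never crosses the slow (location) axis, whose
neighbours are not time-synchronized.

The pooled estimator for lag i at voxel v with kernel window W(v) is

    a = { I(p, t)      : p ∈ W(v), 0 ≤ t < N−i }
    b = { I(p, t+τ_i)  : p ∈ W(v), 0 ≤ t < N−i }
    ρ_A(τ_i; v) = Σ (a−ā)(b−b̄) / sqrt( Σ (a−ā)² · Σ (b−b̄)² )

which is exactly 1 at lag 0 wherever the pooled variance is nonzero.
Two implementations are provided: a ``direct`` time-domain path and an
``fft`` path that computes the O(N²) lagged cross-products via FFT; they
agree to better than 1e−9 relative and differ only in rounding.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, Field
from scipy import fft as sp_fft

from .stack import ACFProfile, DynamicsVolume, TimeSeriesStack

#: default OCDSl fit window, ms (lags 1..6 at the default Δt of 204.8 ms)
DEFAULT_FIT_LO_MS = 204.8
DEFAULT_FIT_HI_MS = 1228.8
#: default maximum ACF delay, ms
DEFAULT_TAU_MAX_MS = DEFAULT_FIT_HI_MS


class Kernel(BaseModel):
    """Spatial pooling kernel: ``k`` pixels axially (depth), ``l`` laterally (fast axis)."""

    k: int = Field(default=2, ge=1)
    l: int = Field(default=4, ge=1)


def compute_liv(stack: TimeSeriesStack) -> DynamicsVolume:
    """Logarithmic intensity variance: per-voxel 1/N variance of the dB series.

    LIV(v) = (1/N) Σ_i [ I_dB(v, t_i) − ⟨I_dB(v)⟩_t ]²  — the *population*
    variance, so its expectation under i.i.d. noise of variance σ² is
    σ²·(N−1)/N.
    """
    if stack.n_repeats < 2:
        raise ValueError(f"LIV needs at least 2 repeats, got {stack.n_repeats}")
    stack.validate_finite()
    mean = stack.data.mean(axis=1)
    liv = stack.data.var(axis=1)  # two-pass, ddof=0 (population normalization)
    return DynamicsVolume(
        values=liv,
        metric="liv",
        mean_intensity_db=mean,
        x_pitch_um=stack.x_pitch_um,
        y_pitch_um=stack.y_pitch_um,
        z_pitch_um=stack.z_pitch_um,
    )


def _sliding_sum(a: np.ndarray, size: int, axis: int) -> np.ndarray:
    """Box sum over a window of ``size`` centered on each index, truncated at borders.

    The window at index c spans [c − (size−1)//2, c + size//2]; for even
    sizes the extra pixel sits on the high side.
    """
    n = a.shape[axis]
    if size > n:
        raise ValueError(f"kernel extent {size} larger than image extent {n}")
    c = np.cumsum(a, axis=axis)
    pad_shape = list(a.shape)
    pad_shape[axis] = 1
    c = np.concatenate([np.zeros(pad_shape, dtype=a.dtype), c], axis=axis)
    idx = np.arange(n)
    lo = np.clip(idx - (size - 1) // 2, 0, n)
    hi = np.clip(idx + size // 2 + 1, 0, n)
    return np.take(c, hi, axis=axis) - np.take(c, lo, axis=axis)


def _pool2d(a: np.ndarray, kernel: Kernel) -> np.ndarray:
    """Kernel box sum over the trailing (depth, fast) axes."""
    return _sliding_sum(_sliding_sum(a, kernel.k, axis=-2), kernel.l, axis=-1)


def _lag_moments(d: np.ndarray, i_max: int, method: str) -> tuple[np.ndarray, ...]:
    """Per-pixel lagged raw moments of a (T, Z, X) record.

    Returns arrays of shape (i_max+1, Z, X): cross products
    S_ab[i] = Σ_t d(t)·d(t+τ_i) over the N−i overlapping pairs, the
    leading/lagged sums S_a, S_b, and sums of squares Q_a, Q_b.
    """
    N = d.shape[0]
    lags = i_max + 1
    if method == "fft":
        nfft = sp_fft.next_fast_len(2 * N)
        F = sp_fft.rfft(d, n=nfft, axis=0)
        s_ab = sp_fft.irfft(F * np.conj(F), n=nfft, axis=0)[:lags]
    elif method == "direct":
        s_ab = np.empty((lags,) + d.shape[1:], dtype=np.float64)
        for i in range(lags):
            s_ab[i] = np.einsum("t...,t...->...", d[: N - i], d[i:])
    else:
        raise ValueError(f"method must be 'direct' or 'fft', got {method!r}")
    s_a = np.empty_like(s_ab)
    s_b = np.empty_like(s_ab)
    q_a = np.empty_like(s_ab)
    q_b = np.empty_like(s_ab)
    d2 = d * d
    for i in range(lags):
        s_a[i] = d[: N - i].sum(axis=0)
        s_b[i] = d[i:].sum(axis=0)
        q_a[i] = d2[: N - i].sum(axis=0)
        q_b[i] = d2[i:].sum(axis=0)
    return s_ab, s_a, s_b, q_a, q_b


def compute_acf(stack: TimeSeriesStack,
                kernel: Kernel | None = None,
                *,
                tau_max_ms: float = DEFAULT_TAU_MAX_MS,
                i_max: int | None = None,
                method: str = "fft") -> ACFProfile:
    """Kernel-pooled per-voxel temporal autocorrelation ρ_A(τ_i).

    Parameters
    ----------
    kernel:
        Spatial pooling window (default 2 × 4, axial × lateral).  The
        window is centered on the output voxel and truncated at image
        borders, so the output retains full spatial extent.
    tau_max_ms, i_max:
        Maximum delay; ``i_max`` defaults to ``floor(tau_max_ms / Δt)``,
        capped at N − 1.
    method:
        ``"fft"`` (lagged cross-products via FFT) or ``"direct"``
        (time-domain sums).  Identical up to rounding.

    Voxels whose pooled variance vanishes at a lag (e.g. constant
    background) get ρ = 0 at that lag (1 at lag 0, by convention) and
    are flagged in ``degenerate``; OCDS is then 0 rather than NaN.
    """
    kernel = kernel or Kernel()
    N = stack.n_repeats
    if N < 2:
        raise ValueError(f"ACF needs at least 2 repeats, got {N}")
    if kernel.k * kernel.l * N < 2:
        raise ValueError("kernel too small: k*l*n_repeats must be >= 2")
    stack.validate_finite()
    if i_max is None:
        i_max = int(np.floor(tau_max_ms / stack.dt_ms + 1e-9))
    i_max = min(i_max, N - 1)
    if i_max < 0:
        raise ValueError("i_max must be >= 0")
    lags = i_max + 1
    ny, _, nz, nx = stack.data.shape
    if kernel.k > nz or kernel.l > nx:
        raise ValueError(
            f"kernel {kernel.k}x{kernel.l} larger than image {nz}x{nx}"
        )

    cnt = _pool2d(np.ones((nz, nx)), kernel)  # in-bounds kernel pixels per voxel
    n_pairs = (N - np.arange(lags, dtype=np.float64))[:, None, None]
    M = cnt[None] * n_pairs  # pooled sample size per voxel and lag

    rho = np.empty((ny, lags, nz, nx), dtype=np.float64)
    degenerate = np.zeros((ny, lags, nz, nx), dtype=bool)
    for y in range(ny):
        d = stack.data[y]
        # Center by a scalar so the moment sums do not cancel catastrophically
        # on large dB offsets; a global shift leaves rho exactly invariant.
        d = d - d.mean()
        s_ab, s_a, s_b, q_a, q_b = _lag_moments(d, i_max, method)
        p_ab = _pool2d(s_ab, kernel)
        p_a = _pool2d(s_a, kernel)
        p_b = _pool2d(s_b, kernel)
        p_qa = _pool2d(q_a, kernel)
        p_qb = _pool2d(q_b, kernel)
        cov = p_ab - p_a * p_b / M
        var_a = p_qa - p_a * p_a / M
        var_b = p_qb - p_b * p_b / M
        scale = np.maximum(p_qa, p_qb)  # nonnegative magnitude reference
        bad = (var_a <= 1e-12 * scale) | (var_b <= 1e-12 * scale) | (scale == 0.0)
        denom = np.sqrt(np.maximum(var_a, 0.0) * np.maximum(var_b, 0.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = cov / denom
        r[bad] = 0.0
        r[0] = 1.0  # self-correlation is 1 exactly (by convention also where degenerate)
        rho[y] = r
        degenerate[y] = bad

    return ACFProfile(
        rho=rho,
        tau_ms=stack.tau_grid_ms(i_max),
        dt_ms=stack.dt_ms,
        degenerate=degenerate,
        mean_intensity_db=stack.data.mean(axis=1),
        x_pitch_um=stack.x_pitch_um,
        y_pitch_um=stack.y_pitch_um,
        z_pitch_um=stack.z_pitch_um,
    )


def compute_ocds(acf: ACFProfile,
                 fit_lo_ms: float = DEFAULT_FIT_LO_MS,
                 fit_hi_ms: float = DEFAULT_FIT_HI_MS) -> DynamicsVolume:
    """OCDS: negated OLS slope (with intercept) of ρ_A over a delay window.

    The sign convention makes a decaying correlation positive; rising
    correlation yields negative values and is not clipped.  Degenerate
    voxels (ρ ≡ 0 across the window) yield OCDS = 0.
    """
    tol = 1e-9 * max(abs(fit_lo_ms), abs(fit_hi_ms), 1.0)
    sel = (acf.tau_ms >= fit_lo_ms - tol) & (acf.tau_ms <= fit_hi_ms + tol)
    if int(sel.sum()) < 2:
        raise ValueError(
            f"fit window [{fit_lo_ms}, {fit_hi_ms}] ms contains "
            f"{int(sel.sum())} delay point(s); need >= 2"
        )
    tau = acf.tau_ms[sel]
    rho = acf.rho[:, sel]  # (location, m, depth, fast)
    tc = tau - tau.mean()
    rc = rho - rho.mean(axis=1, keepdims=True)
    slope = np.tensordot(tc, rc, axes=([0], [1])) / np.dot(tc, tc)
    mean_db = acf.mean_intensity_db
    if mean_db is None:
        mean_db = np.zeros_like(slope)
    return DynamicsVolume(
        values=-slope,
        metric="ocdsl",
        mean_intensity_db=mean_db,
        x_pitch_um=acf.x_pitch_um,
        y_pitch_um=acf.y_pitch_um,
        z_pitch_um=acf.z_pitch_um,
    )


def fit_exponential_decay(acf: ACFProfile, min_rho: float = 0.05
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel exponential fit ρ(τ) ≈ r·exp(−τ/τ_c) over lags ≥ 1.

    Weighted log-linear least squares (weights ρ², the delta-method inverse
    variance of log ρ) restricted to lags where ρ > ``min_rho``.  Returns
    ``(tau_c_ms, amplitude)``; voxels with fewer than two usable lags or a
    non-decaying fit get NaN.  The amplitude absorbs the noise floor
    r = σ_d²/(σ_d² + σ_n²), so τ_c is insensitive to white measurement
    noise.  Used for parameter-recovery validation of the pipeline.
    """
    tau = acf.tau_ms[1:]
    rho = acf.rho[:, 1:]
    valid = rho > min_rho
    w = np.where(valid, rho * rho, 0.0)
    logr = np.where(valid, np.log(np.where(valid, rho, 1.0)), 0.0)
    t = tau[None, :, None, None]
    sw = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mt = (w * t).sum(axis=1) / sw
        ml = (w * logr).sum(axis=1) / sw
        cov = (w * (t - mt[:, None]) * (logr - ml[:, None])).sum(axis=1)
        var = (w * (t - mt[:, None]) ** 2).sum(axis=1)
        slope = cov / var
        intercept = ml - slope * mt
    enough = valid.sum(axis=1) >= 2
    ok = enough & np.isfinite(slope) & (slope < 0)
    tau_c = np.full(slope.shape, np.nan)
    amp = np.full(slope.shape, np.nan)
    tau_c[ok] = -1.0 / slope[ok]
    amp[ok] = np.exp(intercept[ok])
    return tau_c, amp
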