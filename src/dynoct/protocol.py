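"""Interleaved volumetric scan protocol: scheduling, timing, demultiplexing.

The protocol splits the en-face plane into ``n_groups`` groups of
``locations_per_group`` adjacent B-scan locations.  Each group is raster
scanned ``n_repeats`` times before the slow galvo moves on to the next
group.  A location is therefore revisited every
``locations_per_group × bscan_period`` — the inter-frame separation Δt
that sets the time resolution of the dynamics contrasts — while the whole
volume still completes in under a minute at the defaults
(8 × 16 × 32 frames, 12.8 ms per B-scan slot → Δt = 204.8 ms,
6.5536 s per group, 52.4288 s per volume).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .stack import (
    DEFAULT_X_PITCH_UM,
    DEFAULT_Y_PITCH_UM,
    DEFAULT_Z_PITCH_UM,
    TimeSeriesStack,
)


class ScanProtocol(BaseModel):
    """Constants of the interleaved dynamics scan.

    ``bscan_period_ms`` is the wall-clock slot per B-scan including galvo
    flyback; it must at least fit the active sweep
    (``a_lines_per_bscan / a_line_rate``).
    """

    n_groups: int = Field(default=8, ge=1)
    locations_per_group: int = Field(default=16, ge=1)
    n_repeats: int = Field(default=32, ge=1)
    a_lines_per_bscan: int = Field(default=512, ge=1)
    a_line_rate: float = Field(default=50_000.0, gt=0, description="A-lines per second")
    bscan_period_ms: float = Field(default=12.8, gt=0)

    @model_validator(mode="after")
    def _sweep_fits_slot(self) -> "ScanProtocol":
        active_ms = 1000.0 * self.a_lines_per_bscan / self.a_line_rate
        if self.bscan_period_ms < active_ms - 1e-9:
            raise ValueError(
                f"bscan_period_ms ({self.bscan_period_ms}) shorter than the active sweep "
                f"({active_ms} ms = a_lines_per_bscan / a_line_rate)"
            )
        return self

    @property
    def n_locations(self) -> int:
        return self.n_groups * self.locations_per_group

    @property
    def total_frames(self) -> int:
        return self.n_groups * self.locations_per_group * self.n_repeats

    @property
    def inter_frame_separation_ms(self) -> float:
        """Δt between successive repeats of one location (204.8 ms at defaults)."""
        return self.locations_per_group * self.bscan_period_ms


@dataclass(frozen=True)
class FrameAddress:
    """Where one acquisition-ordered frame lands in the (location, repeat) lattice."""

    stream_index: int
    group: int
    repeat: int
    location_in_group: int
    global_location: int
    acquisition_time_ms: float


def timing_summary(protocol: ScanProtocol) -> dict[str, float]:
    """Named timing quantities of a protocol.

    Returns inter-frame separation (ms), group time (s), volume time (s),
    the Nyquist frequency of the repeat sampling (Hz), total frame count
    and location count.
    """
    dt_ms = protocol.inter_frame_separation_ms
    group_time_s = protocol.n_repeats * dt_ms / 1000.0
    return {
        "inter_frame_separation_ms": dt_ms,
        "group_time_s": group_time_s,
        "volume_time_s": protocol.n_groups * group_time_s,
        "nyquist_hz": 1000.0 / (2.0 * dt_ms),
        "total_frames": protocol.total_frames,
        "n_locations": protocol.n_locations,
    }


def address_of(stream_index: int, protocol: ScanProtocol) -> FrameAddress:
    """Map an acquisition-order frame index to its lattice address.

    The stream is ordered group-major, then repeat, then location within
    the group: ``stream_index = group·(R·L) + repeat·L + location_in_group``.
    """
    total = protocol.total_frames
    if not 0 <= stream_index < total:
        raise IndexError(f"stream_index {stream_index} out of range [0, {total})")
    L = protocol.locations_per_group
    R = protocol.n_repeats
    group, rem = divmod(stream_index, R * L)
    repeat, loc = divmod(rem, L)
    return FrameAddress(
        stream_index=stream_index,
        group=group,
        repeat=repeat,
        location_in_group=loc,
        global_location=group * L + loc,
        acquisition_time_ms=stream_index * protocol.bscan_period_ms,
    )


def stream_index_of(group: int, repeat: int, location_in_group: int,
                    protocol: ScanProtocol) -> int:
    """Inverse of :func:`address_of`."""
    if not 0 <= group < protocol.n_groups:
        raise IndexError(f"group {group} out of range")
    if not 0 <= repeat < protocol.n_repeats:
        raise IndexError(f"repeat {repeat} out of range")
    if not 0 <= location_in_group < protocol.locations_per_group:
        raise IndexError(f"location_in_group {location_in_group} out of range")
    L = protocol.locations_per_group
    return group * (protocol.n_repeats * L) + repeat * L + location_in_group


def schedule(protocol: ScanProtocol) -> Iterator[FrameAddress]:
    """All frame addresses in acquisition order."""
    for s in range(protocol.total_frames):
        yield address_of(s, protocol)


def demultiplex(stream: Sequence[np.ndarray] | np.ndarray,
                protocol: ScanProtocol,
                *,
                x_pitch_um: float = DEFAULT_X_PITCH_UM,
                y_pitch_um: float = DEFAULT_Y_PITCH_UM,
                z_pitch_um: float = DEFAULT_Z_PITCH_UM) -> TimeSeriesStack:
    """Reorder an acquisition-ordered frame stream into a (location, repeat) stack.

    ``stream`` holds ``total_frames`` 2D frames of identical shape.  The
    returned stack's repeat axis is in acquisition-time order for each
    location; :func:`remultiplex` is its exact inverse.
    """
    arr = np.asarray(stream, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError(f"stream must be a sequence of 2D frames; got array of shape {arr.shape}")
    if arr.shape[0] != protocol.total_frames:
        raise ValueError(
            f"stream length {arr.shape[0]} != protocol total_frames {protocol.total_frames}"
        )
    G, L, R = protocol.n_groups, protocol.locations_per_group, protocol.n_repeats
    nz, nx = arr.shape[1:]
    # (G, R, L, z, x) -> (G, L, R, z, x) -> (G*L, R, z, x)
    data = arr.reshape(G, R, L, nz, nx).transpose(0, 2, 1, 3, 4).reshape(G * L, R, nz, nx)
    return TimeSeriesStack(
        data=data.copy(),
        dt_ms=protocol.inter_frame_separation_ms,
        x_pitch_um=x_pitch_um,
        y_pitch_um=y_pitch_um,
        z_pitch_um=z_pitch_um,
    )


def remultiplex(stack: TimeSeriesStack, protocol: ScanProtocol) -> np.ndarray:
    """Inverse of :func:`demultiplex`: back to acquisition order."""
    G, L, R = protocol.n_groups, protocol.locations_per_group, protocol.n_repeats
    if stack.n_locations != G * L or stack.n_repeats != R:
        raise ValueError(
            f"stack shape {stack.data.shape[:2]} inconsistent with protocol "
            f"({G * L} locations x {R} repeats)"
        )
    nz, nx = stack.data.shape[2:]
    return (stack.data.reshape(G, L, R, nz, nx)
            .transpose(0, 2, 1, 3, 4)
            .reshape(G * L * R, nz, nx)
            .copy())


def schedule_rows(protocol: ScanProtocol) -> list[tuple[int, float, int, int, int, int]]:
    """Schedule as plain rows (stream_index, time_ms, group, repeat, location_in_group, global_location)."""
    return [
        (a.stream_index, a.acquisition_time_ms, a.group, a.repeat,
         a.location_in_group, a.global_location)
        for a in schedule(protocol)
    ]
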