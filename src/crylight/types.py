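"""Core data containers shared across the pipeline.

Conventions used throughout:

* Activity is recorded in half-open 1-minute bins ``[t, t + 60 s)``.
* ZT0 (Zeitgeber time zero) is lights-on; ZT is carried in decimal hours.
* Membrane voltage is in millivolts; time in seconds; firing rates in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "LightSchedule",
    "ActivitySeries",
    "SweepProtocol",
    "VoltageRecording",
    "ChoiceSeries",
    "replace",
]

#: one civil day in 1-minute bins
BINS_PER_DAY = 1440


def _parse_clock(hhmm: str) -> int:
    """Parse ``"HH:MM"`` into minutes after midnight."""
    try:
        hh, mm = hhmm.split(":")
        minutes = int(hh) * 60 + int(mm)
    except (ValueError, AttributeError) as exc:
        raise ValueError(f"clock time must be 'HH:MM', got {hhmm!r}") from exc
    if not 0 <= minutes < 1440:
        raise ValueError(f"clock time out of range: {hhmm!r}")
    return minutes


@dataclass(frozen=True)
class LightSchedule:
    """The light regime an activity recording ran under.

    Parameters
    ----------
    zt0_clock_time:
        Wall-clock time of lights-on, ``"HH:MM"``.
    photoperiod_h:
        Hours of light per 24 h day (12:12 LD by default).
    lux:
        White-light entrainment intensity (1 or 400 lux in the assays
        this pipeline targets, but any positive value is accepted).
    dd_start_bin:
        Index of the first constant-darkness (DD) bin, or ``None`` if the
        whole recording is entrained LD.
    """

    zt0_clock_time: str = "08:00"
    photoperiod_h: float = 12.0
    lux: float = 400.0
    dd_start_bin: Optional[int] = None

    def __post_init__(self) -> None:
        _parse_clock(self.zt0_clock_time)
        if not 0.0 < self.photoperiod_h < 24.0:
            raise ValueError(
                f"photoperiod_h must be in (0, 24), got {self.photoperiod_h}"
            )
        if self.dd_start_bin is not None and self.dd_start_bin < 0:
            raise ValueError("dd_start_bin must be nonnegative")

    @property
    def zt0_minute_of_day(self) -> int:
        return _parse_clock(self.zt0_clock_time)


@dataclass
class ActivitySeries:
    """Per-minute beam-crossing counts for one fly.

    ``counts[i]`` is the number of infrared-beam crossings in the half-open
    minute ``[t0 + i min, t0 + (i+1) min)``.
    """

    fly_id: str
    genotype: str
    t0_clock_time: str  # wall-clock "HH:MM" of the first bin's left edge
    counts: np.ndarray
    schedule: LightSchedule
    bin_seconds: int = 60

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if counts.size and (
            not np.issubdtype(counts.dtype, np.integer) or (counts < 0).any()
        ):
            raise ValueError("counts must be nonnegative integers")
        self.counts = counts.astype(np.int64)
        _parse_clock(self.t0_clock_time)
        if self.bin_seconds != 60:
            raise ValueError("activity bins must be 60 s")
        if (
            self.schedule.dd_start_bin is not None
            and self.schedule.dd_start_bin > self.counts.size
        ):
            raise ValueError("dd_start_bin beyond end of series")

    def __len__(self) -> int:
        return int(self.counts.size)

    @property
    def n_days(self) -> int:
        return self.counts.size // BINS_PER_DAY

    def zt0_offset_bins(self) -> int:
        """Bins from the start of the series to the first lights-on."""
        t0 = _parse_clock(self.t0_clock_time)
        return (self.schedule.zt0_minute_of_day - t0) % BINS_PER_DAY

    def dd_counts(self) -> np.ndarray:
        """The constant-darkness portion (empty if no DD segment)."""
        if self.schedule.dd_start_bin is None:
            return self.counts[:0]
        return self.counts[self.schedule.dd_start_bin:]


@dataclass(frozen=True)
class SweepProtocol:
    """Timing of one light-evoked potential sweep.

    The default is the five-sweep protocol used throughout: 50 s darkness
    for baseline, 5 s of monochromatic light at 200 uW/cm2, then 95 s of
    inter-pulse darkness.
    """

    pre_dark_s: float = 50.0
    stim_s: float = 5.0
    post_s: float = 95.0
    n_sweeps: int = 5
    wavelength_nm: int = 450
    intensity_uw_cm2: float = 200.0

    VALID_WAVELENGTHS = (365, 405, 450, 635)

    def __post_init__(self) -> None:
        for name in ("pre_dark_s", "stim_s", "post_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")
        if self.wavelength_nm not in self.VALID_WAVELENGTHS:
            raise ValueError(
                f"wavelength_nm must be one of {self.VALID_WAVELENGTHS}, "
                f"got {self.wavelength_nm}"
            )
        if self.intensity_uw_cm2 <= 0:
            raise ValueError("intensity_uw_cm2 must be positive")

    @property
    def sweep_s(self) -> float:
        return self.pre_dark_s + self.stim_s + self.post_s

    @property
    def total_s(self) -> float:
        return self.n_sweeps * self.sweep_s

    def n_samples(self, sampling_hz: float) -> int:
        return int(round(self.total_s * sampling_hz))

    def sweep_samples(self, sampling_hz: float) -> int:
        return int(round(self.sweep_s * sampling_hz))


@dataclass
class VoltageRecording:
    """Whole-cell current-clamp voltage trace for one neuron.

    The trace concatenates ``protocol.n_sweeps`` identical sweeps; sweep
    boundaries are implicit from the protocol timing.
    """

    cell_id: str
    genotype: str
    zt_of_recording: float
    sampling_hz: float
    voltage_mv: np.ndarray
    protocol: SweepProtocol = field(default_factory=SweepProtocol)

    def __post_init__(self) -> None:
        if self.sampling_hz < 2000:
            raise ValueError(
                f"sampling_hz must be >= 2000, got {self.sampling_hz}"
            )
        v = np.asarray(self.voltage_mv, dtype=np.float64)
        if v.ndim != 1:
            raise ValueError("voltage_mv must be one-dimensional")
        expected = self.protocol.n_samples(self.sampling_hz)
        if abs(v.size - expected) > 1:
            raise ValueError(
                f"trace length {v.size} does not match protocol "
                f"({expected} samples at {self.sampling_hz} Hz)"
            )
        self.voltage_mv = v

    def sweeps(self) -> np.ndarray:
        """Trace reshaped to (n_sweeps, samples_per_sweep), trimming any
        trailing off-by-one sample."""
        per = self.protocol.sweep_samples(self.sampling_hz)
        n = self.protocol.n_sweeps
        return self.voltage_mv[: per * n].reshape(n, per)


@dataclass
class ChoiceSeries:
    """Per-minute activity counts of one fly in a two-environment
    (lit vs. dark) choice tube."""

    fly_id: str
    genotype: str
    lit_counts: np.ndarray
    dark_counts: np.ndarray
    wavelength_nm: int = 450
    intensity_uw_cm2: float = 10.0
    bin_seconds: int = 60

    def __post_init__(self) -> None:
        lit = np.asarray(self.lit_counts)
        dark = np.asarray(self.dark_counts)
        if lit.shape != dark.shape or lit.ndim != 1:
            raise ValueError("lit/dark series must be 1-D and equal length")
        for arr, name in ((lit, "lit_counts"), (dark, "dark_counts")):
            if arr.size and (
                not np.issubdtype(arr.dtype, np.integer) or (arr < 0).any()
            ):
                raise ValueError(f"{name} must be nonnegative integers")
        self.lit_counts = lit.astype(np.int64)
        self.dark_counts = dark.astype(np.int64)

    def __len__(self) -> int:
        return int(self.lit_counts.size)

    @property
    def total_counts(self) -> np.ndarray:
        return self.lit_counts + self.dark_counts

    @property
    def inactive(self) -> bool:
        """True when the fly never crossed either beam."""
        return bool((self.total_counts == 0).all())
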