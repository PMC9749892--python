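"""Synthetic assay generators with known ground truth.

Each generator emulates one of the four assays the pipeline analyses —
locomotor activity monitoring, light-evoked current-clamp recording,
two-environment light choice, and ROI fluorescence — with the statistical
structure the downstream analyses assume, and returns the latent
parameters/events alongside the data so every analysis stage can be tested
by parameter recovery.  All randomness flows from one explicit ``seed``
per call; there is no global generator state.

The waveform and noise models are deliberately simple fixtures (raised-
cosine activity lobes, exponential depolarisation kinetics, a fixed spike
template, lognormal ROI noise): they exercise the analysis code, they do
not model pacemaker or channel biophysics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .types import (
    BINS_PER_DAY,
    ActivitySeries,
    ChoiceSeries,
    LightSchedule,
    SweepProtocol,
    VoltageRecording,
)

__all__ = [
    "LocomotorParams",
    "EphysParams",
    "ChoiceParams",
    "IccParams",
    "GenotypePreset",
    "SimulatedLocomotor",
    "SimulatedVoltage",
    "simulate_locomotor",
    "simulate_voltage",
    "simulate_choice",
    "simulate_roi",
    "standard_presets",
]

VALID_ZT = (5, 11, 17, 23)

PLitFn = Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class LocomotorParams:
    """Latent parameters of the activity generator.

    ``rate(t) = base_rate * (1 + amplitude * s(phi(t)))`` counts/min,
    clipped at zero, where ``s`` is a bimodal profile with raised-cosine
    lobes at lights-on/off plus exponential anticipation ramps rising over
    ``anticipation_ramp_h`` before each transition.  In DD the phase
    advances with free-running period ``tau_h``.
    """

    tau_h: float = 24.0
    base_rate: float = 1.5
    amplitude: float = 3.0
    anticipation_ramp_h: float = 3.0
    rhythmic_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 16.0 < self.tau_h < 32.0:
            raise ValueError(f"tau_h must be in (16, 32), got {self.tau_h}")
        if self.base_rate < 0 or self.amplitude < 0:
            raise ValueError("base_rate and amplitude must be nonnegative")
        if not 0.0 <= self.rhythmic_fraction <= 1.0:
            raise ValueError("rhythmic_fraction must be in [0, 1]")


@dataclass(frozen=True)
class EphysParams:
    """Latent parameters of the voltage-trace generator.

    ``voltage = rmp + D(t) + spikes + noise`` with light-evoked
    depolarisation ``D(t) = depol_amplitude*(1 - exp(-t/tau_on))`` during
    the stimulus and exponential decay with ``tau_off`` afterwards; spikes
    are an inhomogeneous Poisson process with rate
    ``basal_rate_hz + gain_hz_per_mv * D(t)`` rendered as a fixed 2-ms
    template with a +60 mV peak.  Burst presets emit spike triplets with
    50-ms intra-burst intervals at Poisson burst onsets.
    """

    rmp_mv: float = -37.0
    basal_rate_hz: float = 5.0
    depol_amplitude_mv: float = 8.0
    tau_on_s: float = 1.5
    tau_off_s: float = 12.0
    gain_hz_per_mv: float = 0.8
    noise_sd_mv: float = 1.2
    burst: bool = False

    def __post_init__(self) -> None:
        if self.basal_rate_hz < 0 or self.depol_amplitude_mv < 0:
            raise ValueError("rates and amplitudes must be nonnegative")
        if self.tau_on_s <= 0 or self.tau_off_s <= 0:
            raise ValueError("kinetic time constants must be positive")
        if self.noise_sd_mv < 0:
            raise ValueError("noise_sd_mv must be nonnegative")


@dataclass(frozen=True)
class ChoiceParams:
    """Latent parameters of the two-environment choice generator.

    Per minute ``t``: ``total ~ Poisson(total_rate)`` and
    ``lit ~ Binomial(total, p_lit(t))``; ``dark = total - lit``.
    ``p_lit`` may be a constant or a function of the minute index.
    """

    p_lit: Union[float, PLitFn] = 0.5
    total_rate: float = 8.0

    def __post_init__(self) -> None:
        if self.total_rate < 0:
            raise ValueError("total_rate must be nonnegative")
        if isinstance(self.p_lit, float) and not 0.0 <= self.p_lit <= 1.0:
            raise ValueError("constant p_lit must be in [0, 1]")

    def p_lit_at(self, minutes: np.ndarray) -> np.ndarray:
        if callable(self.p_lit):
            p = np.asarray(self.p_lit(minutes), dtype=float)
            p = np.broadcast_to(p, minutes.shape).copy()
        else:
            p = np.full(minutes.shape, float(self.p_lit))
        if ((p < 0) | (p > 1)).any():
            raise ValueError("p_lit returned values outside [0, 1]")
        return p


@dataclass(frozen=True)
class IccParams:
    """Latent parameters of the ROI-fluorescence generator: per-ZT mean
    intensity with lognormal multiplicative noise of coefficient of
    variation ``noise_cv``, and a per-brain background level around
    ``background_mean``."""

    mean_by_zt: Dict[int, float] = field(
        default_factory=lambda: {5: 60.0, 11: 65.0, 17: 110.0, 23: 150.0}
    )
    background_mean: float = 50.0
    noise_cv: float = 0.25

    def __post_init__(self) -> None:
        for zt, m in self.mean_by_zt.items():
            if zt not in VALID_ZT:
                raise ValueError(f"ZT keys must be in {VALID_ZT}, got {zt}")
            if m <= 0:
                raise ValueError("mean intensities must be positive")
        if self.background_mean <= 0:
            raise ValueError("background_mean must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")


@dataclass(frozen=True)
class GenotypePreset:
    """Bundle of latent parameters for one simulated genotype."""

    name: str
    locomotor: LocomotorParams = field(default_factory=LocomotorParams)
    ephys: EphysParams = field(default_factory=EphysParams)
    choice: ChoiceParams = field(default_factory=ChoiceParams)
    icc: IccParams = field(default_factory=IccParams)

    def to_json_dict(self) -> dict:
        """Ground-truth sidecar payload (callable p_lit noted, not encoded)."""
        d = dataclasses.asdict(self)
        if callable(d["choice"]["p_lit"]):
            d["choice"]["p_lit"] = "<callable>"
        return d


# ---------------------------------------------------------------------------
# locomotor


def _activity_profile(phase_h: np.ndarray, ramp_h: float,
                      photoperiod_h: float = 12.0) -> np.ndarray:
    """Dimensionless daily activity shape s(phase) >= 0.

    Two raised-cosine lobes centred on lights-on (phase 0) and lights-off
    (phase = photoperiod) plus exponential anticipation ramps rising over
    ``ramp_h`` before each transition.  The 4-h lobe half-width reflects
    the hours-long morning and evening activity bouts of real flies;
    narrow pulses would produce unrealistically sharp periodogram peaks.
    """
    half_width = 4.0
    s = np.zeros_like(phase_h, dtype=float)
    for center in (0.0, photoperiod_h):
        d = (phase_h - center + 12.0) % 24.0 - 12.0
        in_lobe = np.abs(d) < half_width
        s[in_lobe] += 0.5 * (1.0 + np.cos(np.pi * d[in_lobe] / half_width))
        if ramp_h > 0:
            # hours until the transition, measured backwards
            until = (center - phase_h) % 24.0
            in_ramp = (until > 0) & (until < ramp_h)
            s[in_ramp] += np.exp(-3.0 * until[in_ramp] / ramp_h)
    return s


def _phase_hours(n_bins: int, dd_start_bin: int, tau_h: float) -> np.ndarray:
    """Circadian phase (hours, mod 24) per 1-min bin: entrained 24-h phase
    in LD, free-running drift with period ``tau_h`` in DD."""
    t_h = np.arange(n_bins) / 60.0
    phase = t_h % 24.0
    if dd_start_bin < n_bins:
        t_dd = t_h[dd_start_bin:] - t_h[dd_start_bin]
        phase0 = phase[dd_start_bin] if dd_start_bin > 0 else 0.0
        phase[dd_start_bin:] = (phase0 + t_dd * 24.0 / tau_h) % 24.0
    return phase


@dataclass
class SimulatedLocomotor:
    """Locomotor cohort plus its generating ground truth."""

    series: List[ActivitySeries]
    rhythmic_mask: np.ndarray  # bool per fly: amplitude was nonzero
    preset: GenotypePreset
    seed: int


def simulate_locomotor(
    preset: GenotypePreset,
    n_flies: int,
    days_ld: int = 7,
    days_dd: int = 7,
    lux: float = 400.0,
    seed: int = 0,
) -> SimulatedLocomotor:
    """Simulate a DAM cohort: ``days_ld`` days of 12:12 LD entrainment
    followed by ``days_dd`` days of constant darkness, one count per
    1-minute bin, inhomogeneous-Poisson beam crossings.

    A ``1 - rhythmic_fraction`` subset of flies is generated with
    amplitude 0 (arrhythmic); which flies is drawn from the seed.
    """
    if n_flies < 1:
        raise ValueError("n_flies must be >= 1")
    if days_ld < 1 or days_dd < 0:
        raise ValueError("days_ld must be >= 1 and days_dd >= 0")
    p = preset.locomotor
    rng = np.random.default_rng(seed)
    n_bins = (days_ld + days_dd) * BINS_PER_DAY
    dd_start = days_ld * BINS_PER_DAY

    phase = _phase_hours(n_bins, dd_start, p.tau_h)
    s = _activity_profile(phase, p.anticipation_ramp_h)

    n_arrhythmic = int(round(n_flies * (1.0 - p.rhythmic_fraction)))
    order = rng.permutation(n_flies)
    rhythmic_mask = np.ones(n_flies, dtype=bool)
    rhythmic_mask[order[:n_arrhythmic]] = False

    schedule = LightSchedule(
        zt0_clock_time="08:00", photoperiod_h=12.0, lux=lux,
        dd_start_bin=dd_start if days_dd > 0 else None,
    )
    series = []
    for i in range(n_flies):
        amp = p.amplitude if rhythmic_mask[i] else 0.0
        rate = np.clip(p.base_rate * (1.0 + amp * s), 0.0, None)
        counts = rng.poisson(rate)
        series.append(
            ActivitySeries(
                fly_id=f"{preset.name}_fly{i:03d}",
                genotype=preset.name,
                t0_clock_time="08:00",
                counts=counts,
                schedule=schedule,
            )
        )
    return SimulatedLocomotor(series, rhythmic_mask, preset, seed)


# ---------------------------------------------------------------------------
# electrophysiology

SPIKE_TEMPLATE_MS = 2.0
SPIKE_PEAK_MV = 60.0


def _spike_template(sampling_hz: float) -> tuple[np.ndarray, int]:
    """Fixed biphasic 2-ms action-potential shape and its peak offset."""
    n = int(round(SPIKE_TEMPLATE_MS * 1e-3 * sampling_hz))
    if n < 3:
        raise ValueError(
            f"sampling rate {sampling_hz} Hz too low to render the "
            f"{SPIKE_TEMPLATE_MS}-ms spike template"
        )
    u = np.arange(n + 1) / n
    tpl = SPIKE_PEAK_MV * np.exp(-((u - 0.35) / 0.16) ** 2)
    tpl -= 12.0 * np.exp(-((u - 0.8) / 0.15) ** 2)
    peak = int(np.argmax(tpl))
    # make the printed peak exact regardless of sample placement
    tpl *= SPIKE_PEAK_MV / tpl[peak]
    return tpl, peak


def _depolarisation(t_in_sweep: np.ndarray, p: EphysParams,
                    proto: SweepProtocol) -> np.ndarray:
    """Light-evoked depolarisation D(t) over one sweep, in mV."""
    t_on = proto.pre_dark_s
    t_off = proto.pre_dark_s + proto.stim_s
    d = np.zeros_like(t_in_sweep)
    during = (t_in_sweep >= t_on) & (t_in_sweep < t_off)
    d[during] = p.depol_amplitude_mv * (
        1.0 - np.exp(-(t_in_sweep[during] - t_on) / p.tau_on_s)
    )
    d_end = p.depol_amplitude_mv * (1.0 - np.exp(-proto.stim_s / p.tau_on_s))
    after = t_in_sweep >= t_off
    d[after] = d_end * np.exp(-(t_in_sweep[after] - t_off) / p.tau_off_s)
    return d


def _poisson_times(rng: np.random.Generator, rate_fn, t_max: float,
                   rate_max: float) -> np.ndarray:
    """Inhomogeneous Poisson event times on [0, t_max) by thinning."""
    if rate_max <= 0:
        return np.empty(0)
    n = rng.poisson(rate_max * t_max)
    cand = np.sort(rng.uniform(0.0, t_max, n))
    keep = rng.uniform(0.0, rate_max, n) < rate_fn(cand)
    return cand[keep]


@dataclass
class SimulatedVoltage:
    """Voltage recording plus generating ground truth."""

    recording: VoltageRecording
    true_spike_times_s: List[np.ndarray]  # per sweep, template-peak times
    true_depol_mv: np.ndarray  # D(t) over one sweep
    preset: GenotypePreset
    seed: int


def simulate_voltage(
    preset: GenotypePreset,
    protocol: SweepProtocol | None = None,
    sampling_hz: float = 5000.0,
    zt_of_recording: float = 8.0,
    seed: int = 0,
) -> SimulatedVoltage:
    """Simulate one multi-sweep current-clamp recording under the
    dark/light/dark protocol, returning ground-truth spike times (at the
    spike-template peak) and the depolarisation waveform for oracle tests.
    """
    proto = protocol or SweepProtocol()
    p = preset.ephys
    rng = np.random.default_rng(seed)
    per = proto.sweep_samples(sampling_hz)
    t_sweep = np.arange(per) / sampling_hz
    d = _depolarisation(t_sweep, p, proto)
    tpl, peak_off = _spike_template(sampling_hz)
    peak_dt = peak_off / sampling_hz

    def rate_at(times: np.ndarray) -> np.ndarray:
        idx = np.clip((times * sampling_hz).astype(int), 0, per - 1)
        return p.basal_rate_hz + p.gain_hz_per_mv * d[idx]

    rate_max = p.basal_rate_hz + p.gain_hz_per_mv * d.max()
    trace = np.empty(proto.n_sweeps * per)
    true_times: List[np.ndarray] = []
    for k in range(proto.n_sweeps):
        v = np.full(per, p.rmp_mv) + d
        if p.noise_sd_mv > 0:
            v += rng.normal(0.0, p.noise_sd_mv, per)
        if p.burst:
            onsets = _poisson_times(
                rng, lambda t: rate_at(t) / 3.0, proto.sweep_s, rate_max / 3.0
            )
            times = np.sort(
                np.concatenate([onsets, onsets + 0.05, onsets + 0.10])
            )
        else:
            times = _poisson_times(rng, rate_at, proto.sweep_s, rate_max)
        # enforce the template's own 2-ms dead time
        kept = []
        last = -np.inf
        for t in times:
            if t - last >= SPIKE_TEMPLATE_MS * 1e-3:
                kept.append(t)
                last = t
        rendered = []
        for t in kept:
            i0 = int(round(t * sampling_hz))
            i1 = min(i0 + tpl.size, per)
            if i1 - i0 < tpl.size // 2:
                continue
            v[i0:i1] += tpl[: i1 - i0]
            rendered.append(t + peak_dt)
        true_times.append(np.asarray(rendered))
        trace[k * per:(k + 1) * per] = v

    rec = VoltageRecording(
        cell_id=f"{preset.name}_cell{seed}",
        genotype=preset.name,
        zt_of_recording=zt_of_recording,
        sampling_hz=sampling_hz,
        voltage_mv=trace,
        protocol=proto,
    )
    return SimulatedVoltage(rec, true_times, d, preset, seed)


# ---------------------------------------------------------------------------
# light choice


def simulate_choice(
    preset: GenotypePreset,
    n_flies: int,
    minutes: int = 30,
    wavelength_nm: int = 450,
    intensity_uw_cm2: float = 10.0,
    seed: int = 0,
) -> List[ChoiceSeries]:
    """Simulate a lit-vs-dark choice cohort of ``n_flies`` over ``minutes``
    1-minute bins (Poisson totals, binomial lit split)."""
    if minutes < 1:
        raise ValueError("minutes must be >= 1")
    if n_flies < 1:
        raise ValueError("n_flies must be >= 1")
    p = preset.choice
    rng = np.random.default_rng(seed)
    t = np.arange(minutes)
    p_lit = p.p_lit_at(t)
    out = []
    for i in range(n_flies):
        total = rng.poisson(p.total_rate, minutes)
        lit = rng.binomial(total, p_lit)
        out.append(
            ChoiceSeries(
                fly_id=f"{preset.name}_fly{i:03d}",
                genotype=preset.name,
                lit_counts=lit,
                dark_counts=total - lit,
                wavelength_nm=wavelength_nm,
                intensity_uw_cm2=intensity_uw_cm2,
            )
        )
    return out


# ---------------------------------------------------------------------------
# ROI fluorescence


def _lognormal_around(rng: np.random.Generator, mean: float, cv: float,
                      size) -> np.ndarray:
    """Lognormal samples with the requested arithmetic mean and CV."""
    if cv == 0:
        return np.full(size, mean, dtype=float)
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def simulate_roi(
    preset: GenotypePreset,
    n_brains: int,
    neurons_per_brain: int,
    zt: int,
    seed: int = 0,
    channel: str = "TIM",
) -> pd.DataFrame:
    """Simulate an ROI fluorescence table at one ZT point: one row per
    neuron with its brain's background intensity attached."""
    p = preset.icc
    if zt not in p.mean_by_zt:
        raise ValueError(
            f"ZT{zt} not in preset means {sorted(p.mean_by_zt)}"
        )
    if n_brains < 1 or neurons_per_brain < 1:
        raise ValueError("n_brains and neurons_per_brain must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    # per-brain background varies with half the neuron-level CV
    bg = _lognormal_around(rng, p.background_mean, p.noise_cv / 2.0, n_brains)
    for b in range(n_brains):
        inten = _lognormal_around(
            rng, p.mean_by_zt[zt], p.noise_cv, neurons_per_brain
        )
        for j in range(neurons_per_brain):
            rows.append(
                {
                    "brain_id": f"{preset.name}_zt{zt}_brain{b:02d}",
                    "neuron_id": f"n{j:02d}",
                    "channel": channel,
                    "mean_intensity": inten[j],
                    "background_intensity": bg[b],
                    "zt": zt,
                    "genotype": preset.name,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# presets


def standard_presets() -> Dict[str, GenotypePreset]:
    """The four demo genotypes: a wild-type-like positive control, two
    heterologous CRY1 expressors, and a cry-null negative control.

    Free-running periods follow the cohort averages the assays are built
    to resolve (24.7 h control, 24.6 and 25.4 h for the two CRY1 lines,
    23.6 h with low rhythmic fraction for the null); other values are
    fixture choices documented in the methods note.
    """
    return {
        "DmCRY": GenotypePreset(
            name="DmCRY",
            locomotor=LocomotorParams(tau_h=24.7, base_rate=1.5,
                                      amplitude=3.0, rhythmic_fraction=0.95),
            ephys=EphysParams(rmp_mv=-37.0, basal_rate_hz=5.0,
                              depol_amplitude_mv=8.0),
            choice=ChoiceParams(p_lit=0.55, total_rate=8.0),
            icc=IccParams(mean_by_zt={5: 60.0, 11: 65.0, 17: 110.0,
                                      23: 150.0}),
        ),
        "AeCRY1": GenotypePreset(
            name="AeCRY1",
            locomotor=LocomotorParams(tau_h=24.6, base_rate=1.5,
                                      amplitude=3.0, rhythmic_fraction=0.9),
            ephys=EphysParams(rmp_mv=-33.0, basal_rate_hz=7.0,
                              depol_amplitude_mv=4.0, tau_off_s=6.0),
            choice=ChoiceParams(p_lit=0.65, total_rate=8.0),
            icc=IccParams(mean_by_zt={5: 70.0, 11: 75.0, 17: 130.0,
                                      23: 160.0}),
        ),
        "AgCRY1": GenotypePreset(
            name="AgCRY1",
            locomotor=LocomotorParams(tau_h=25.4, base_rate=1.5,
                                      amplitude=3.0, rhythmic_fraction=0.9),
            ephys=EphysParams(rmp_mv=-33.0, basal_rate_hz=7.0,
                              depol_amplitude_mv=10.0, tau_off_s=20.0,
                              burst=True),
            choice=ChoiceParams(p_lit=0.35, total_rate=8.0),
            icc=IccParams(mean_by_zt={5: 140.0, 11: 145.0, 17: 140.0,
                                      23: 150.0}),
        ),
        "cry-null": GenotypePreset(
            name="cry-null",
            locomotor=LocomotorParams(tau_h=23.6, base_rate=1.5,
                                      amplitude=1.5, rhythmic_fraction=0.6),
            ephys=EphysParams(rmp_mv=-33.0, basal_rate_hz=7.0,
                              depol_amplitude_mv=0.5),
            choice=ChoiceParams(p_lit=0.7, total_rate=8.0),
            icc=IccParams(mean_by_zt={5: 60.0, 11: 62.0, 17: 100.0,
                                      23: 140.0}),
        ),
    }
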