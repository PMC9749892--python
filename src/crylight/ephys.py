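"""Light-evoked current-clamp analysis.

Spike detection on multi-sweep recordings, pooled firing-frequency ratios
(stimulus rate over 10-s-binned baseline rate), the averaged/baseline-
adjusted/low-pass-filtered evoked potential, basal metrics (resting
membrane potential, basal firing rate) and tonic/burst classification.

Statistics are pooled across a recording's sweeps; the cell is the
statistical unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Literal, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as ssig
from scipy.ndimage import gaussian_filter1d

from .types import SweepProtocol, VoltageRecording

__all__ = [
    "SpikeTrain",
    "FiringSummary",
    "EvokedPotential",
    "CellBasal",
    "detect_spikes",
    "firing_frequency_ratio",
    "evoked_potential",
    "basal_metrics",
    "classify_firing_mode",
]


@dataclass
class SpikeTrain:
    """Spike times (s, relative to sweep start) for one sweep."""

    sweep_index: int
    spike_times_s: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times_s, dtype=float)
        if t.size > 1 and not (np.diff(t) > 0).all():
            raise ValueError("spike times must be strictly increasing")
        self.spike_times_s = t


@dataclass
class FiringSummary:
    """Pooled firing-rate summary of one cell.

    ``ff_ratio`` is the stimulus-window firing rate (spike count converted
    to Hz) divided by the mean of the five 10-s baseline bin rates; the
    four ``post_ratios`` are the 10-s post-stimulus bin rates (up to 40 s)
    over the same baseline.  ``defined`` is False when the baseline holds
    no spikes, in which case the cell is flagged for exclusion.
    """

    baseline_bin_rates_hz: np.ndarray
    baseline_rate_hz: float
    stim_rate_hz: float
    ff_ratio: Optional[float]
    post_ratios: Optional[np.ndarray]
    defined: bool


@dataclass
class EvokedPotential:
    """Sweep-averaged, baseline-adjusted, low-pass-filtered light response."""

    time_s: np.ndarray  # relative to sweep start
    delta_mv: np.ndarray
    n_sweeps: int
    filter_settings: dict
    stim_onset_s: float
    stim_offset_s: float

    def last_60s(self) -> Tuple[np.ndarray, np.ndarray]:
        """The display window: final 60 s of the sweep."""
        mask = self.time_s >= self.time_s[-1] - 60.0
        return self.time_s[mask], self.delta_mv[mask]


@dataclass
class CellBasal:
    cell_id: str
    rmp_mv: float
    basal_rate_hz: float
    firing_mode: Literal["tonic", "burst", "unclassified"]
    zt_of_recording: float


# ---------------------------------------------------------------------------
# spike detection

_MIN_PROMINENCE_MV = 10.0


def _highpass_residual(v: np.ndarray, sampling_hz: float) -> np.ndarray:
    """Fast fluctuations left after removing a 20-ms Gaussian-smoothed
    version of the trace; isolates spikes from slow depolarisation."""
    sigma = 0.020 * sampling_hz
    return v - gaussian_filter1d(v, sigma)


def detect_spikes(
    rec: VoltageRecording,
    threshold_k_mad: float = 6.0,
    refractory_ms: float = 2.0,
) -> List[SpikeTrain]:
    """Threshold-crossing spike detection, one train per sweep.

    The threshold on the high-pass residual is ``median + k*MAD`` with a
    floor at an absolute prominence of 10 mV (so noiseless flat traces
    yield no detections); at most one event is kept per refractory window
    and the spike time is the peak sample.
    """
    if rec.voltage_mv.size == 0:
        raise ValueError("empty trace")
    fs = rec.sampling_hz
    sweeps = rec.sweeps()
    refr = int(round(refractory_ms * 1e-3 * fs))
    out: List[SpikeTrain] = []
    for k, v in enumerate(sweeps):
        resid = _highpass_residual(v, fs)
        med = np.median(resid)
        mad = np.median(np.abs(resid - med))
        thr = med + max(threshold_k_mad * mad, _MIN_PROMINENCE_MV)
        peaks, _ = ssig.find_peaks(resid, height=thr, distance=max(refr, 1))
        out.append(SpikeTrain(k, peaks / fs))
    return out


# ---------------------------------------------------------------------------
# firing-frequency ratio

def _pooled_count(trains: Sequence[SpikeTrain], lo: float, hi: float) -> int:
    """Spikes in window [lo, hi) pooled across sweeps."""
    return int(
        sum(((t.spike_times_s >= lo) & (t.spike_times_s < hi)).sum()
            for t in trains)
    )


def firing_frequency_ratio(
    spikes: Sequence[SpikeTrain],
    protocol: SweepProtocol = SweepProtocol(),
) -> FiringSummary:
    """Firing-frequency ratios for one cell from its per-sweep trains.

    The 50-s pre-stimulus window is split into five 10-s bins; spike
    counts are pooled across sweeps and converted to Hz.  The FF ratio is
    the stimulus-window rate over the mean baseline bin rate, and the four
    post-stimulus ratios cover 10-s bins up to 40 s after light-off.
    """
    n = max(len(spikes), 1)
    bin_s = 10.0
    n_base = int(protocol.pre_dark_s // bin_s)
    base_edges = np.arange(n_base + 1) * bin_s
    base_rates = np.array([
        _pooled_count(spikes, base_edges[i], base_edges[i + 1]) / (bin_s * n)
        for i in range(n_base)
    ])
    baseline = float(base_rates.mean())
    t_on = protocol.pre_dark_s
    t_off = t_on + protocol.stim_s
    stim_rate = _pooled_count(spikes, t_on, t_off) / (protocol.stim_s * n)
    if baseline == 0:
        return FiringSummary(base_rates, baseline, stim_rate,
                             ff_ratio=None, post_ratios=None, defined=False)
    n_post = 4
    post = np.array([
        _pooled_count(spikes, t_off + i * bin_s, t_off + (i + 1) * bin_s)
        / (bin_s * n) / baseline
        for i in range(n_post)
    ])
    return FiringSummary(base_rates, baseline, stim_rate,
                         ff_ratio=stim_rate / baseline, post_ratios=post,
                         defined=True)


# ---------------------------------------------------------------------------
# evoked potential

def evoked_potential(
    rec: VoltageRecording,
    baseline_window_s: float = 10.0,
    gaussian_sigma_ms: float = 50.0,
    butter_order: int = 3,
    butter_cutoff_hz: float = 2.0,
) -> EvokedPotential:
    """Averaged light-evoked potential of one cell.

    Sweeps are aligned on stimulus onset and averaged pointwise; the mean
    of the final ``baseline_window_s`` before the stimulus is subtracted;
    the average is then Gaussian-smoothed and zero-phase low-pass
    Butterworth filtered.  The pre-pulse baseline mean is re-zeroed after
    filtering so the reported trace is exactly baseline-referenced.
    """
    proto = rec.protocol
    fs = rec.sampling_hz
    if butter_cutoff_hz >= fs / 2:
        raise ValueError("Butterworth cutoff must be below Nyquist")
    sweeps = rec.sweeps()
    if sweeps.shape[0] < 1:
        raise ValueError("need at least one complete sweep")
    avg = sweeps.mean(axis=0)
    t = np.arange(avg.size) / fs
    t_on = proto.pre_dark_s
    base_mask = (t >= t_on - baseline_window_s) & (t < t_on)
    avg = avg - avg[base_mask].mean()
    smooth = gaussian_filter1d(avg, gaussian_sigma_ms * 1e-3 * fs)
    sos = ssig.butter(butter_order, butter_cutoff_hz, btype="low",
                      fs=fs, output="sos")
    filt = ssig.sosfiltfilt(sos, smooth)
    filt = filt - filt[base_mask].mean()
    return EvokedPotential(
        time_s=t, delta_mv=filt, n_sweeps=sweeps.shape[0],
        filter_settings={
            "baseline_window_s": baseline_window_s,
            "gaussian_sigma_ms": gaussian_sigma_ms,
            "butter_order": butter_order,
            "butter_cutoff_hz": butter_cutoff_hz,
            "zero_phase": True,
        },
        stim_onset_s=t_on, stim_offset_s=t_on + proto.stim_s,
    )


# ---------------------------------------------------------------------------
# basal metrics and firing mode

def basal_metrics(
    rec: VoltageRecording,
    spikes: Optional[Sequence[SpikeTrain]] = None,
    blank_ms: float = 5.0,
) -> CellBasal:
    """Resting membrane potential and basal firing rate of one cell.

    RMP is the mode of the 1-mV-binned voltage histogram over pre-stimulus
    samples with ``blank_ms`` blanked around each spike; the basal rate is
    the pooled pre-stimulus spike count over the total pre-stimulus time.
    """
    if spikes is None:
        spikes = detect_spikes(rec)
    proto = rec.protocol
    fs = rec.sampling_hz
    sweeps = rec.sweeps()
    pre = int(round(proto.pre_dark_s * fs))
    blank = int(round(blank_ms * 1e-3 * fs))
    samples = []
    n_base_spikes = 0
    for train, v in zip(spikes, sweeps):
        keep = np.ones(pre, dtype=bool)
        for ts in train.spike_times_s:
            i = int(round(ts * fs))
            if i < pre + blank:
                keep[max(i - blank, 0): min(i + blank + 1, pre)] = False
        base = train.spike_times_s[train.spike_times_s < proto.pre_dark_s]
        n_base_spikes += base.size
        samples.append(v[:pre][keep])
    pool = np.concatenate(samples)
    if pool.size == 0:
        raise ValueError("all pre-stimulus samples blanked; cannot "
                         "estimate RMP")
    edges = np.arange(np.floor(pool.min()), np.ceil(pool.max()) + 1.0, 1.0)
    if edges.size < 2:
        rmp = float(np.round(pool.mean()))
    else:
        hist, _ = np.histogram(pool, bins=edges)
        j = int(np.argmax(hist))
        rmp = float((edges[j] + edges[j + 1]) / 2.0)
    if rmp >= 0:
        import warnings

        warnings.warn(f"implausible nonnegative RMP ({rmp:.1f} mV) for "
                      f"{rec.cell_id}")
    rate = n_base_spikes / (proto.pre_dark_s * len(sweeps))
    mode = classify_firing_mode(spikes, protocol=proto)
    return CellBasal(rec.cell_id, rmp, rate, mode, rec.zt_of_recording)


def classify_firing_mode(
    spikes: Sequence[SpikeTrain],
    protocol: SweepProtocol = SweepProtocol(),
    intra_burst_isi_s: float = 0.100,
    min_run: int = 3,
    gap_s: float = 0.300,
    min_spikes: int = 10,
) -> Literal["tonic", "burst", "unclassified"]:
    """Tonic/burst classification from pooled baseline spikes.

    Burst when at least half the baseline spikes lie in runs of
    ``min_run`` or more spikes with inter-spike intervals of at most
    ``intra_burst_isi_s``, the runs separated by gaps of at least
    ``gap_s``.  Fewer than ``min_spikes`` baseline spikes is unclassified.
    """
    base = [t.spike_times_s[t.spike_times_s < protocol.pre_dark_s]
            for t in spikes]
    n_total = sum(b.size for b in base)
    if n_total < min_spikes:
        return "unclassified"
    in_burst = 0
    for b in base:
        if b.size == 0:
            continue
        isi = np.diff(b)
        # split at gaps >= gap_s; count runs of >= min_run tight ISIs
        run_start = 0
        for i in range(b.size):
            end_of_run = i == b.size - 1 or isi[i] > intra_burst_isi_s
            if end_of_run:
                run_len = i - run_start + 1
                tight = (isi[run_start:i] <= intra_burst_isi_s).all() \
                    if run_len > 1 else False
                before_ok = run_start == 0 or isi[run_start - 1] >= gap_s
                after_ok = i == b.size - 1 or isi[i] >= gap_s
                if run_len >= min_run and tight and before_ok and after_ok:
                    in_burst += run_len
                run_start = i + 1
    return "burst" if in_burst >= 0.5 * n_total else "tonic"
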