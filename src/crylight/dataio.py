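"""Readers and writers for every on-disk format the pipeline touches.

All readers validate strictly and fail with line/column context; there is
no silent coercion.  Write/read round-trips are identities on the data
model.

Formats
-------
* DAM monitor text: tab-delimited, one row per minute, >= 42 columns
  (record index, date, time, monitor status, 6 metadata columns, 32
  channel counts).  Status code 1 marks valid data; rows with other
  status codes are skipped with a warning.
* Voltage trace TSV: ``# key<TAB>value`` metadata lines, a header row, a
  units row, then (time_s, voltage_mv) samples.
* ROI fluorescence TSV: header + units row, one row per neuron.
* Choice-assay TSV: header + units row, one row per fly x minute.
* YAML run configuration and JSON ground-truth sidecars.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import warnings
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .types import (
    ActivitySeries,
    ChoiceSeries,
    LightSchedule,
    SweepProtocol,
    VoltageRecording,
)

__all__ = [
    "read_dam",
    "write_dam",
    "read_voltage_table",
    "write_voltage_table",
    "read_roi_table",
    "write_roi_table",
    "read_choice_table",
    "write_choice_table",
    "read_config",
    "write_ground_truth",
]

DAM_STATUS_VALID = 1
DAM_N_CHANNELS = 32
DAM_MIN_COLUMNS = 4 + 6 + DAM_N_CHANNELS  # index, date, time, status, meta6
_DAM_EPOCH = _dt.date(2024, 1, 1)

ROI_COLUMNS = ["brain_id", "neuron_id", "channel", "mean_intensity",
               "background_intensity", "zt", "genotype"]
ROI_UNITS = ["id", "id", "label", "au", "au", "h", "label"]
VALID_ZT = (5, 11, 17, 23)
VALID_CHANNELS = ("TIM", "GFP")
CHOICE_INTENSITIES = (10.0, 400.0)


# ---------------------------------------------------------------------------
# DAM monitor text


def _fmt_dam_date(day_index: int) -> str:
    d = _DAM_EPOCH + _dt.timedelta(days=day_index)
    return d.strftime("%d %b %y")


def write_dam(path: Union[str, Path],
              cohort: Sequence[ActivitySeries]) -> None:
    """Write up to 32 activity series as one DAM monitor file.

    All series must share length and start time; unused channels are
    written as zeros.
    """
    if not 1 <= len(cohort) <= DAM_N_CHANNELS:
        raise ValueError(f"a monitor holds 1-{DAM_N_CHANNELS} channels, "
                         f"got {len(cohort)}")
    n = len(cohort[0])
    t0 = cohort[0].t0_clock_time
    for s in cohort:
        if len(s) != n or s.t0_clock_time != t0:
            raise ValueError("all series in a monitor file must share "
                             "length and start time")
    counts = np.zeros((n, DAM_N_CHANNELS), dtype=np.int64)
    for ch, s in enumerate(cohort):
        counts[:, ch] = s.counts
    h0, m0 = (int(v) for v in t0.split(":"))
    start_min = h0 * 60 + m0
    with open(path, "w") as fh:
        for i in range(n):
            total = start_min + i
            day, minute = divmod(total, 1440)
            hh, mm = divmod(minute, 60)
            fields = [
                str(i + 1), _fmt_dam_date(day), f"{hh:02d}:{mm:02d}:00",
                str(DAM_STATUS_VALID),
            ] + ["0"] * 6 + [str(c) for c in counts[i]]
            fh.write("\t".join(fields) + "\n")


def _parse_dam_time(date_s: str, time_s: str, lineno: int) -> int:
    try:
        d = _dt.datetime.strptime(date_s.strip(), "%d %b %y").date()
        parts = time_s.strip().split(":")
        hh, mm = int(parts[0]), int(parts[1])
    except (ValueError, IndexError) as exc:
        raise ValueError(
            f"line {lineno}: unparseable timestamp {date_s!r} {time_s!r}"
        ) from exc
    return (d - _DAM_EPOCH).days * 1440 + hh * 60 + mm


def read_dam(
    path: Union[str, Path],
    channel_map: Optional[Dict[int, Tuple[str, str]]] = None,
    schedule: Optional[LightSchedule] = None,
    zero_fill_gaps: bool = False,
) -> List[ActivitySeries]:
    """Read a DAM monitor file into one series per mapped channel.

    Parameters
    ----------
    channel_map:
        ``{channel (1-32): (fly_id, genotype)}``; default maps all 32
        channels with generated ids.
    schedule:
        Light schedule to attach (default 12:12 LD, lights-on 08:00).
    zero_fill_gaps:
        Missing minutes are a hard error by default; this flag fills them
        with zero counts instead (deviates from strict QC, logged).
    """
    schedule = schedule or LightSchedule()
    if channel_map is None:
        channel_map = {ch: (f"ch{ch:02d}", "unknown")
                       for ch in range(1, DAM_N_CHANNELS + 1)}
    for ch in channel_map:
        if not 1 <= ch <= DAM_N_CHANNELS:
            raise ValueError(f"channel {ch} out of range 1-{DAM_N_CHANNELS}")

    times: List[int] = []
    rows: List[np.ndarray] = []
    first_clock: Optional[str] = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < DAM_MIN_COLUMNS:
                raise ValueError(
                    f"line {lineno}: expected >= {DAM_MIN_COLUMNS} "
                    f"tab-separated columns, got {len(fields)}"
                )
            t = _parse_dam_time(fields[1], fields[2], lineno)
            try:
                status = int(fields[3])
            except ValueError as exc:
                raise ValueError(
                    f"line {lineno}: bad status code {fields[3]!r}"
                ) from exc
            if status != DAM_STATUS_VALID:
                warnings.warn(
                    f"line {lineno}: skipping row with monitor status "
                    f"{status}"
                )
                continue
            try:
                counts = np.array(
                    [int(v) for v in fields[10:10 + DAM_N_CHANNELS]],
                    dtype=np.int64,
                )
            except ValueError as exc:
                raise ValueError(
                    f"line {lineno}: non-integer count field"
                ) from exc
            if (counts < 0).any():
                col = 10 + int(np.argmax(counts < 0)) + 1
                raise ValueError(
                    f"line {lineno}, column {col}: negative count"
                )
            if times and t <= times[-1]:
                raise ValueError(
                    f"line {lineno}: non-monotone timestamp"
                )
            if times and t > times[-1] + 1:
                if not zero_fill_gaps:
                    raise ValueError(
                        f"line {lineno}: {t - times[-1] - 1} missing "
                        f"minute(s); pass zero_fill_gaps=True to fill"
                    )
                warnings.warn(
                    f"line {lineno}: zero-filling {t - times[-1] - 1} "
                    f"missing minute(s)"
                )
                for miss in range(times[-1] + 1, t):
                    times.append(miss)
                    rows.append(np.zeros(DAM_N_CHANNELS, dtype=np.int64))
            if first_clock is None:
                hh, mm = divmod(t % 1440, 60)
                first_clock = f"{hh:02d}:{mm:02d}"
            times.append(t)
            rows.append(counts)
    if not rows:
        raise ValueError(f"{path}: no valid data rows")
    matrix = np.vstack(rows)
    out = []
    for ch in sorted(channel_map):
        fly_id, genotype = channel_map[ch]
        out.append(
            ActivitySeries(
                fly_id=fly_id, genotype=genotype,
                t0_clock_time=first_clock, counts=matrix[:, ch - 1],
                schedule=schedule,
            )
        )
    return out


# ---------------------------------------------------------------------------
# voltage traces


def write_voltage_table(path: Union[str, Path],
                        rec: VoltageRecording) -> None:
    """Write one recording as TSV with metadata comment lines, a header
    row, a units row, then the samples."""
    proto = rec.protocol
    meta = {
        "cell_id": rec.cell_id,
        "genotype": rec.genotype,
        "zt_of_recording": rec.zt_of_recording,
        "sampling_hz": rec.sampling_hz,
        "pre_dark_s": proto.pre_dark_s,
        "stim_s": proto.stim_s,
        "post_s": proto.post_s,
        "n_sweeps": proto.n_sweeps,
        "wavelength_nm": proto.wavelength_nm,
        "intensity_uw_cm2": proto.intensity_uw_cm2,
    }
    t = np.arange(rec.voltage_mv.size) / rec.sampling_hz
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}\t{v}\n")
        fh.write("time_s\tvoltage_mv\n")
        fh.write("s\tmV\n")
        np.savetxt(fh, np.column_stack([t, rec.voltage_mv]),
                   fmt="%.6f", delimiter="\t")


def read_voltage_table(path: Union[str, Path]) -> VoltageRecording:
    """Read a voltage-trace TSV written by :func:`write_voltage_table`.

    The trace length must match the protocol timing within one sample.
    """
    meta: Dict[str, str] = {}
    header_seen = units_seen = False
    n_skip = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                n_skip = lineno
                continue
            if line.startswith("#"):
                try:
                    k, v = line[1:].strip().split("\t")
                except ValueError as exc:
                    raise ValueError(
                        f"line {lineno}: malformed metadata line"
                    ) from exc
                meta[k] = v
                n_skip = lineno
                continue
            if not header_seen:
                if line.split("\t") != ["time_s", "voltage_mv"]:
                    raise ValueError(
                        f"line {lineno}: expected header "
                        f"'time_s\\tvoltage_mv'"
                    )
                header_seen = True
                n_skip = lineno
                continue
            if line.split("\t") != ["s", "mV"]:
                raise ValueError(f"line {lineno}: units row absent "
                                 f"(expected 's\\tmV')")
            units_seen = True
            n_skip = lineno
            break
    if not (header_seen and units_seen):
        raise ValueError(f"{path}: header or units row absent")
    data = pd.read_csv(path, sep="\t", skiprows=n_skip, header=None)
    if data.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 data columns, got "
                         f"{data.shape[1]}")
    volts = data.iloc[:, 1].to_numpy(dtype=float)
    required = {"cell_id", "genotype", "zt_of_recording", "sampling_hz",
                "pre_dark_s", "stim_s", "post_s", "n_sweeps"}
    missing = required - set(meta)
    if missing:
        raise ValueError(f"{path}: missing metadata keys {sorted(missing)}")
    proto = SweepProtocol(
        pre_dark_s=float(meta["pre_dark_s"]),
        stim_s=float(meta["stim_s"]),
        post_s=float(meta["post_s"]),
        n_sweeps=int(meta["n_sweeps"]),
        wavelength_nm=int(meta.get("wavelength_nm", 450)),
        intensity_uw_cm2=float(meta.get("intensity_uw_cm2", 200.0)),
    )
    return VoltageRecording(
        cell_id=meta["cell_id"], genotype=meta["genotype"],
        zt_of_recording=float(meta["zt_of_recording"]),
        sampling_hz=float(meta["sampling_hz"]),
        voltage_mv=np.asarray(volts), protocol=proto,
    )


# ---------------------------------------------------------------------------
# ROI tables


def validate_roi_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(ROI_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"ROI table missing columns: {sorted(missing)}")
    bad_bg = table.index[table["background_intensity"] <= 0]
    if len(bad_bg):
        raise ValueError(
            f"ROI rows {list(bad_bg[:5])}: background_intensity must be "
            f"positive"
        )
    if (table["mean_intensity"] < 0).any():
        raise ValueError("mean_intensity must be nonnegative")
    bad_zt = set(table["zt"].unique()) - set(VALID_ZT)
    if bad_zt:
        raise ValueError(f"out-of-range zt values {sorted(bad_zt)}; "
                         f"measured points are {VALID_ZT}")
    bad_ch = set(table["channel"].unique()) - set(VALID_CHANNELS)
    if bad_ch:
        raise ValueError(f"unknown channels {sorted(bad_ch)}; expected "
                         f"{VALID_CHANNELS}")
    return table


def write_roi_table(path: Union[str, Path], table: pd.DataFrame) -> None:
    validate_roi_table(table)
    with open(path, "w") as fh:
        fh.write("\t".join(ROI_COLUMNS) + "\n")
        fh.write("\t".join(ROI_UNITS) + "\n")
        table[ROI_COLUMNS].to_csv(fh, sep="\t", header=False, index=False)


def read_roi_table(path: Union[str, Path]) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        units = fh.readline().rstrip("\n").split("\t")
        if header != ROI_COLUMNS:
            raise ValueError(f"line 1: expected columns {ROI_COLUMNS}, "
                             f"got {header}")
        if units != ROI_UNITS:
            raise ValueError("line 2: units row absent or malformed")
        table = pd.read_csv(fh, sep="\t", header=None, names=ROI_COLUMNS)
    table["zt"] = table["zt"].astype(int)
    return validate_roi_table(table)


# ---------------------------------------------------------------------------
# choice tables

CHOICE_COLUMNS = ["fly_id", "genotype", "wavelength_nm", "intensity_uw_cm2",
                  "minute", "lit", "dark"]
CHOICE_UNITS = ["id", "label", "nm", "uW/cm2", "min", "counts", "counts"]


def write_choice_table(path: Union[str, Path],
                       cohort: Sequence[ChoiceSeries]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CHOICE_COLUMNS) + "\n")
        fh.write("\t".join(CHOICE_UNITS) + "\n")
        for s in cohort:
            for m in range(len(s)):
                fh.write(
                    f"{s.fly_id}\t{s.genotype}\t{s.wavelength_nm}\t"
                    f"{s.intensity_uw_cm2:g}\t{m}\t{s.lit_counts[m]}\t"
                    f"{s.dark_counts[m]}\n"
                )


def read_choice_table(path: Union[str, Path]) -> List[ChoiceSeries]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        units = fh.readline().rstrip("\n").split("\t")
        if header != CHOICE_COLUMNS:
            raise ValueError(f"line 1: expected columns {CHOICE_COLUMNS}")
        if units != CHOICE_UNITS:
            raise ValueError("line 2: units row absent or malformed")
        df = pd.read_csv(fh, sep="\t", header=None, names=CHOICE_COLUMNS)
    out = []
    for (fly, geno, wl, inten), grp in df.groupby(
        ["fly_id", "genotype", "wavelength_nm", "intensity_uw_cm2"],
        sort=False,
    ):
        grp = grp.sort_values("minute")
        if not (grp["minute"].to_numpy()
                == np.arange(len(grp))).all():
            raise ValueError(f"fly {fly}: minutes not contiguous from 0")
        out.append(
            ChoiceSeries(
                fly_id=str(fly), genotype=str(geno),
                lit_counts=grp["lit"].to_numpy(),
                dark_counts=grp["dark"].to_numpy(),
                wavelength_nm=int(wl), intensity_uw_cm2=float(inten),
            )
        )
    return out


# ---------------------------------------------------------------------------
# configuration and ground truth


def read_config(path: Union[str, Path]) -> dict:
    """Load a YAML run configuration; structural validation happens in
    :mod:`crylight.cli` where the schema is defined."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def write_ground_truth(path: Union[str, Path], payload: dict) -> None:
    """JSON sidecar of generator ground-truth parameters."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return str(o)

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=default, sort_keys=True)
        fh.write("\n")
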