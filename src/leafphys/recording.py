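"""Whole-cell recording container and its plain-text on-disk dialect.

A recording is one protoplast's set of voltage-clamp sweeps.  Each sweep is
a long square pre-pulse followed by a brief conductance-testing voltage
ramp.  On disk a recording is a pair of files:

* ``<id>.meta.yaml`` — protoplast id, diameter (um), cell type, bath
  solution name, liquid-junction potential (mV), sampling rate and the
  full pulse/ramp protocol;
* ``<id>.tsv`` — tab-delimited samples with columns ``time_ms``,
  ``command_mV_nominal``, ``current_pA``, ``sweep_index``.

Command voltages in the trace are *nominal* (amplifier values); the
liquid-junction correction is applied downstream during analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["ProtocolSpec", "CurrentRecording", "read_recording", "write_recording"]

#: default pulse levels: +120 mV down to -160 mV in -20 mV steps (nominal)
DEFAULT_PULSE_LEVELS = tuple(range(120, -161, -20))


@dataclass
class ProtocolSpec:
    """Voltage-clamp sweep protocol (all voltages nominal, mV).

    Each sweep holds at ``holding_mv``, steps to one pulse level for
    ``pulse_duration_ms``, then runs a linear ramp from ``ramp_start_mv``
    to ``ramp_end_mv`` over ``ramp_duration_ms``.
    """

    holding_mv: float = 0.0
    pulse_levels: tuple = DEFAULT_PULSE_LEVELS
    pulse_duration_ms: float = 1000.0
    ramp_start_mv: float = 70.0
    ramp_end_mv: float = -70.0
    ramp_duration_ms: float = 30.0
    sampling_rate_hz: float = 2000.0
    ljp_mv: float = -23.0

    def __post_init__(self):
        self.pulse_levels = tuple(float(v) for v in self.pulse_levels)
        diffs = np.diff(self.pulse_levels)
        if len(self.pulse_levels) == 0 or (len(diffs) and not np.all(diffs < 0)):
            raise ValueError("pulse_levels must be non-empty and strictly decreasing")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.pulse_duration_ms <= 0 or self.ramp_duration_ms <= 0:
            raise ValueError("pulse and ramp durations must be positive")

    @property
    def n_pulse_samples(self) -> int:
        return int(round(self.pulse_duration_ms * self.sampling_rate_hz / 1000.0))

    @property
    def n_ramp_samples(self) -> int:
        return int(round(self.ramp_duration_ms * self.sampling_rate_hz / 1000.0))

    def ramp_voltages(self) -> np.ndarray:
        """Nominal command voltage at each ramp sample (endpoints included)."""
        n = self.n_ramp_samples
        return np.linspace(self.ramp_start_mv, self.ramp_end_mv, n)

    def to_dict(self) -> dict:
        return {
            "holding_mv": self.holding_mv,
            "pulse_levels": list(self.pulse_levels),
            "pulse_duration_ms": self.pulse_duration_ms,
            "ramp_start_mv": self.ramp_start_mv,
            "ramp_end_mv": self.ramp_end_mv,
            "ramp_duration_ms": self.ramp_duration_ms,
            "sampling_rate_hz": self.sampling_rate_hz,
            "ljp_mv": self.ljp_mv,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolSpec":
        return cls(**d)


@dataclass
class CurrentRecording:
    """Per-sweep current traces for one protoplast plus metadata.

    ``data`` columns: time_ms (within-sweep), command_mv_nominal,
    current_pa, sweep_index.  ``flags`` carries quality warnings (e.g. the
    frozen-gate assumption being violated by a slow ramp); ``truth`` holds
    the generating parameters for synthetic recordings, None for real data.
    """

    protoplast_id: str
    diameter_um: float
    cell_type: str
    bath: str
    protocol: ProtocolSpec
    data: pd.DataFrame
    flags: list = field(default_factory=list)
    truth: dict | None = None

    @property
    def ljp_mv(self) -> float:
        return self.protocol.ljp_mv

    def sweep(self, index: int) -> pd.DataFrame:
        return self.data[self.data["sweep_index"] == index]

    def ramp_samples(self, index: int) -> pd.DataFrame:
        """Samples belonging to the conductance-testing ramp of one sweep."""
        sw = self.sweep(index)
        n_pulse = self.protocol.n_pulse_samples
        return sw.iloc[n_pulse : n_pulse + self.protocol.n_ramp_samples]


def write_recording(rec: CurrentRecording, directory) -> Path:
    """Write the two-file recording dialect; returns the metadata path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "protoplast_id": rec.protoplast_id,
        "diameter_um": rec.diameter_um,
        "cell_type": rec.cell_type,
        "bath": rec.bath,
        "flags": list(rec.flags),
        "protocol": rec.protocol.to_dict(),
    }
    if rec.truth is not None:
        meta["truth"] = {k: float(v) for k, v in rec.truth.items()}
    meta_path = directory / f"{rec.protoplast_id}.meta.yaml"
    meta_path.write_text(yaml.safe_dump(meta, sort_keys=False))
    out = rec.data.rename(
        columns={"command_mv_nominal": "command_mV_nominal", "current_pa": "current_pA"}
    )
    out.to_csv(directory / f"{rec.protoplast_id}.tsv", sep="\t", index=False,
               float_format="%.6g")
    return meta_path


def read_recording(meta_path) -> CurrentRecording:
    """Read a recording written by :func:`write_recording`."""
    meta_path = Path(meta_path)
    meta = yaml.safe_load(meta_path.read_text())
    tsv = meta_path.with_name(meta_path.name.replace(".meta.yaml", ".tsv"))
    data = pd.read_csv(tsv, sep="\t")
    data = data.rename(
        columns={"command_mV_nominal": "command_mv_nominal", "current_pA": "current_pa"}
    )
    return CurrentRecording(
        protoplast_id=meta["protoplast_id"],
        diameter_um=meta["diameter_um"],
        cell_type=meta["cell_type"],
        bath=meta["bath"],
        protocol=ProtocolSpec.from_dict(meta["protocol"]),
        data=data,
        flags=list(meta.get("flags", [])),
        truth=meta.get("truth"),
    )
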