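"""Data model and file I/O for single-channel current recordings.

Containers
----------
:class:`RecordingMeta`
    Validated recording metadata (holding potential, cis/trans KCl, temperature,
    sample rate, duration).
:class:`Trace`
    A uniformly sampled current recording in pA.
:class:`IdealizedTrace`
    Piecewise-constant representation of a trace: contiguous segments of
    (start_s, duration_s, level_pA).
:class:`EventTable`
    Gating transitions extracted from an idealized trace, one row per level
    change passing the amplitude floor.

File formats are deliberately plain: traces are two-column delimited text
(``time_s``, ``current_pA``) with a JSON metadata sidecar ``<name>.meta.json``;
event tables and segment tables are TSV.  Floats are serialized with
round-trip (17 significant digit) precision so read(write(x)) is bit-exact.

Sign convention
---------------
Reported potentials are the potential of the *trans* (IMS-facing) side
relative to *cis*.  Under the standard 250:20 mM cis:trans KCl gradient a
cation-selective channel therefore has a **positive** reversal potential.
Every writer records this convention in the sidecar/header.

Units are fixed throughout the package: current pA, conductance pS,
voltage mV, time s, concentration mM, temperature K.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import pydantic

from .errors import (
    MetadataError,
    MissingColumnError,
    NonUniformSamplingError,
    SchemaError,
)

SIGN_CONVENTION = (
    "voltage_mV is trans (IMS side) relative to cis; "
    "cation-selective + cis-high KCl gradient => positive reversal potential"
)

#: Relative tolerance on sample spacing before a trace is declared non-uniform.
UNIFORMITY_TOL = 1e-6

EVENT_COLUMNS = ["time_s", "amplitude_pA", "conductance_pS", "direction"]
SEGMENT_COLUMNS = ["start_s", "duration_s", "level_pA"]


class RecordingMeta(pydantic.BaseModel):
    """Metadata of one bilayer recording.

    Parameters
    ----------
    voltage_mV : float
        Holding potential (trans relative to cis, see module docstring).
    cis_K_mM, trans_K_mM : float
        KCl concentration in each chamber.  Buffers are pure KCl, so the
        Cl- concentration on each side equals the K+ concentration.
    temperature_K : float
        Absolute temperature; bilayer work is at room temperature, the
        accepted range is 273-320 K.
    sample_rate_Hz : float
        Digitization rate.
    duration_s : float
        Recording length.
    label : str
        Free text (variant, substrate concentration, ...).
    u_rev_mV : float, optional
        Reversal potential under the recording's buffers, if known.  Used by
        event extraction to convert current steps into conductances; ``None``
        means 0 mV (symmetric buffers).
    """

    model_config = pydantic.ConfigDict(frozen=True)

    voltage_mV: float
    cis_K_mM: float = pydantic.Field(gt=0)
    trans_K_mM: float = pydantic.Field(gt=0)
    temperature_K: float = pydantic.Field(default=298.15, ge=273.0, le=320.0)
    sample_rate_Hz: float = pydantic.Field(gt=0)
    duration_s: float = pydantic.Field(gt=0)
    label: str = ""
    u_rev_mV: Optional[float] = None

    @classmethod
    def from_dict(cls, d: dict) -> "RecordingMeta":
        """Build from a plain dict, raising :class:`MetadataError` on any
        invariant violation (wraps pydantic's ValidationError)."""
        try:
            return cls(**d)
        except pydantic.ValidationError as exc:
            raise MetadataError(str(exc)) from exc


@dataclasses.dataclass(frozen=True)
class Trace:
    """A uniformly sampled current recording."""

    meta: RecordingMeta
    samples: np.ndarray  # pA, float64, length == round(duration_s * rate)

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        expected = int(round(self.meta.duration_s * self.meta.sample_rate_Hz))
        if samples.ndim != 1 or len(samples) != expected:
            raise MetadataError(
                f"trace has {len(samples)} samples, metadata implies {expected}"
            )
        if not np.all(np.isfinite(samples)):
            raise MetadataError("trace contains non-finite samples")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.meta.sample_rate_Hz

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Trace)
            and self.meta == other.meta
            and np.array_equal(self.samples, other.samples)
        )


@dataclasses.dataclass(frozen=True)
class IdealizedTrace:
    """Piecewise-constant fit of a trace.

    ``segments`` is a DataFrame with columns start_s, duration_s, level_pA.
    Segments are contiguous, non-overlapping, and adjacent levels differ.
    """

    segments: pd.DataFrame
    meta: RecordingMeta

    def __post_init__(self):
        seg = self.segments.reset_index(drop=True)
        object.__setattr__(self, "segments", seg)
        missing = [c for c in SEGMENT_COLUMNS if c not in seg.columns]
        if missing:
            raise SchemaError(f"idealized trace missing columns {missing}")
        if len(seg) == 0:
            raise SchemaError("idealized trace needs at least one segment")
        starts = seg["start_s"].to_numpy()
        durs = seg["duration_s"].to_numpy()
        if np.any(durs <= 0):
            raise SchemaError("segment durations must be positive")
        if not np.allclose(starts[1:], starts[:-1] + durs[:-1], rtol=0, atol=1e-9):
            raise SchemaError("segments must be contiguous")

    @property
    def levels(self) -> np.ndarray:
        return self.segments["level_pA"].to_numpy()

    @property
    def durations(self) -> np.ndarray:
        return self.segments["duration_s"].to_numpy()

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def reconstruct(self, n_samples: Optional[int] = None) -> np.ndarray:
        """Sample-by-sample piecewise-constant reconstruction on the
        recording's uniform grid."""
        fs = self.meta.sample_rate_Hz
        if n_samples is None:
            n_samples = int(round(self.meta.duration_s * fs))
        out = np.empty(n_samples)
        starts = np.round(self.segments["start_s"].to_numpy() * fs).astype(int)
        bounds = np.append(starts, n_samples)
        for i, level in enumerate(self.levels):
            out[bounds[i]: bounds[i + 1]] = level
        return out


@dataclasses.dataclass(frozen=True)
class EventTable:
    """Gating transitions of one recording.

    ``events`` columns: time_s, amplitude_pA (signed level difference,
    new - old), conductance_pS (always positive), direction
    ('opening' or 'closing').
    """

    events: pd.DataFrame
    meta: RecordingMeta

    def __post_init__(self):
        ev = self.events.reset_index(drop=True)
        object.__setattr__(self, "events", ev)
        missing = [c for c in EVENT_COLUMNS if c not in ev.columns]
        if missing:
            raise SchemaError(f"event table missing columns {missing}")
        if len(ev) and not np.all(ev["conductance_pS"].to_numpy() > 0):
            raise SchemaError("conductance_pS must be positive")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def conductances_pS(self) -> np.ndarray:
        return self.events["conductance_pS"].to_numpy()


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"


def _sidecar_path(path: Path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".meta.json")


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "," if ("," in header and "\t" not in header) else "\t"


def _meta_to_json_dict(meta: RecordingMeta) -> dict:
    d = meta.model_dump()
    d["sign_convention"] = SIGN_CONVENTION
    return d


def _meta_from_json_dict(d: dict) -> RecordingMeta:
    d = dict(d)
    d.pop("sign_convention", None)
    return RecordingMeta.from_dict(d)


def read_trace(path, sidecar_path=None) -> Trace:
    """Read a delimited trace file plus its JSON metadata sidecar.

    Raises
    ------
    MissingColumnError
        if ``time_s`` or ``current_pA`` is absent.
    NonUniformSamplingError
        if timestamps deviate from the uniform grid by more than 1 ppm of the
        sample interval.
    MetadataError
        if the sidecar violates a metadata invariant.
    """
    path = Path(path)
    sidecar = Path(sidecar_path) if sidecar_path is not None else _sidecar_path(path)
    with open(sidecar) as fh:
        meta = _meta_from_json_dict(json.load(fh))

    df = pd.read_csv(path, sep=_detect_sep(path), float_precision="round_trip")
    for col in ("time_s", "current_pA"):
        if col not in df.columns:
            raise MissingColumnError(f"{path}: missing column {col!r}")
    t = df["time_s"].to_numpy(float)
    dt = 1.0 / meta.sample_rate_Hz
    expected_t = t[0] + np.arange(len(t)) * dt
    if len(t) > 1 and np.max(np.abs(t - expected_t)) > UNIFORMITY_TOL * dt:
        raise NonUniformSamplingError(
            f"{path}: timestamps deviate from uniform {meta.sample_rate_Hz} Hz grid"
        )
    return Trace(meta=meta, samples=df["current_pA"].to_numpy(float))


def write_trace(trace: Trace, path) -> Path:
    """Write a trace as TSV plus ``<name>.meta.json`` sidecar; returns path."""
    path = Path(path)
    t = trace.times
    arr = np.column_stack([t, trace.samples])
    np.savetxt(
        path, arr, fmt=_FLOAT_FMT, delimiter="\t",
        header="time_s\tcurrent_pA", comments="",
    )
    with open(_sidecar_path(path), "w") as fh:
        json.dump(_meta_to_json_dict(trace.meta), fh, indent=1)
    return path


def write_events(table: EventTable, path) -> Path:
    """Write an event table as TSV plus metadata sidecar; returns path."""
    path = Path(path)
    table.events.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    with open(_sidecar_path(path), "w") as fh:
        json.dump(_meta_to_json_dict(table.meta), fh, indent=1)
    return path


def read_events(path, sidecar_path=None) -> EventTable:
    """Read an event table written by :func:`write_events`.

    Raises :class:`SchemaError` if a required column is missing.
    """
    path = Path(path)
    sidecar = Path(sidecar_path) if sidecar_path is not None else _sidecar_path(path)
    with open(sidecar) as fh:
        meta = _meta_from_json_dict(json.load(fh))
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        df = pd.DataFrame({c: pd.Series(dtype=float) for c in EVENT_COLUMNS})
        df["direction"] = df["direction"].astype(str)
    return EventTable(events=df[EVENT_COLUMNS], meta=meta)


def write_segments(ideal: IdealizedTrace, path) -> Path:
    """Write idealized-trace segments as TSV plus metadata sidecar."""
    path = Path(path)
    ideal.segments.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    with open(_sidecar_path(path), "w") as fh:
        json.dump(_meta_to_json_dict(ideal.meta), fh, indent=1)
    return path


def read_segments(path, sidecar_path=None) -> IdealizedTrace:
    """Read a segment table written by :func:`write_segments`."""
    path = Path(path)
    sidecar = Path(sidecar_path) if sidecar_path is not None else _sidecar_path(path)
    with open(sidecar) as fh:
        meta = _meta_from_json_dict(json.load(fh))
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return IdealizedTrace(segments=df[SEGMENT_COLUMNS], meta=meta)
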