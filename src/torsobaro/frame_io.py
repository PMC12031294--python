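"""Reading, validating and writing pressure-mat recordings.

The sensor is a 160 x 100 capacitive pressure mat (50.8 cm x 81.2 cm,
5.08 mm pitch) sampled at 10 Hz for 10 s.  Values are relative pressure
integers in [0, 12000].  This module owns the grid-geometry constants and
two on-disk formats:

* an HDF5 container per recording (dataset ``frames[n, 160, 100]`` plus
  attributes), the primary format;
* a plain-text CSV dialect (all frames stacked row-wise) with a JSON
  sidecar for metadata, for fully text-based interchange.

Axis convention (0-based, used throughout the package): rows ``j`` run
0..159 cranial to caudal, columns ``i`` run 0..99 across the body.  The
mat's symmetry axis is column ``i_sym = 49`` (column 50 in the vendor's
1-based numbering).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .errors import FormatError, ValidationError

__all__ = [
    "GridGeometry",
    "PressureFrame",
    "PressureRecording",
    "grid_geometry",
    "read_recording",
    "write_recording",
    "mirror_columns",
]

_AXIS_NOTE = "rows j=0..159 cranial->caudal; cols i=0..99; symmetry axis i_sym=49 (0-based)"


@dataclass(frozen=True)
class GridGeometry:
    """Immutable sensor-grid constants."""

    n_rows: int = 160
    n_cols: int = 100
    width_cm: float = 50.8
    height_cm: float = 81.2
    i_sym: int = 49
    value_min: int = 0
    value_max: int = 12000

    @property
    def pitch_mm(self) -> float:
        """Sensor pitch derived from the transverse extent (10 * cm / cols)."""
        return 10.0 * self.width_cm / self.n_cols

    @property
    def pitch_mm_longitudinal(self) -> float:
        return 10.0 * self.height_cm / self.n_rows

    def check(self) -> None:
        if abs(self.pitch_mm - self.pitch_mm_longitudinal) > 0.01:
            raise ValidationError(
                "anisotropic grid: pitch %.4f mm (cols) vs %.4f mm (rows)"
                % (self.pitch_mm, self.pitch_mm_longitudinal)
            )


_GEOMETRY = GridGeometry()


def grid_geometry() -> GridGeometry:
    """Return the constant mat geometry."""
    return _GEOMETRY


@dataclass
class PressureFrame:
    """A single 160 x 100 grid of relative pressure integers."""

    values: np.ndarray
    geometry: GridGeometry = field(default_factory=grid_geometry)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.validate()

    def validate(self) -> None:
        g = self.geometry
        if self.values.shape != (g.n_rows, g.n_cols):
            raise ValidationError(
                f"frame shape {self.values.shape} != ({g.n_rows}, {g.n_cols})"
            )
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.values, 1), 0)):
                raise ValidationError("frame values must be integers")
            self.values = self.values.astype(np.int32)
        bad = (self.values < g.value_min) | (self.values > g.value_max)
        if bad.any():
            j, i = np.argwhere(bad)[0]
            raise ValidationError(
                f"value {int(self.values[j, i])} at cell (j={int(j)}, i={int(i)}) "
                f"outside [{g.value_min}, {g.value_max}]"
            )

    def mean_pressure(self) -> float:
        return float(self.values.mean())


@dataclass
class PressureRecording:
    """An ordered 10 Hz time series of pressure frames plus subject metadata."""

    frames: list
    rate_hz: float = 10.0
    duration_s: float = 10.0
    subject_meta: dict | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.frames) == 0:
            raise ValidationError("recording has no frames")
        g = self.frames[0].geometry
        for k, f in enumerate(self.frames):
            if f.geometry != g:
                raise ValidationError(f"frame {k} has a different grid geometry")
        expected = int(round(self.rate_hz * self.duration_s))
        if len(self.frames) != expected:
            warnings.warn(
                f"recording has {len(self.frames)} frames, expected {expected}; "
                "accepted as incomplete",
                stacklevel=3,
            )

    @property
    def geometry(self) -> GridGeometry:
        return self.frames[0].geometry

    def values_array(self) -> np.ndarray:
        return np.stack([f.values for f in self.frames])


def mirror_columns(arr: np.ndarray, i_sym: int = 49) -> np.ndarray:
    """Reflect an array about the mat's symmetry column (``i -> 2*i_sym - i``).

    On the even 100-column grid one border column has no mirror partner and
    is zero-filled; imprints are acquired with a lateral margin so no torso
    pressure is lost.
    """
    out = np.zeros_like(arr)
    n = 2 * i_sym + 1
    out[..., :n] = np.flip(arr[..., :n], axis=-1)
    return out


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("grid-csv", "hdf5"):
            raise FormatError(f"unknown format {fmt!r}")
        return fmt
    if path.suffix.lower() in (".h5", ".hdf5"):
        return "hdf5"
    if path.suffix.lower() == ".csv":
        return "grid-csv"
    raise FormatError(f"cannot infer format from suffix {path.suffix!r}")


def write_recording(rec: PressureRecording, path, fmt: str | None = None) -> Path:
    """Write a recording; the result round-trips bit-exactly via read_recording."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    rec.validate()
    data = rec.values_array().astype(np.int32)
    meta = {
        "rate_hz": rec.rate_hz,
        "duration_s": rec.duration_s,
        "subject_meta": rec.subject_meta or {},
        "axis_convention": _AXIS_NOTE,
        "n_frames": len(rec.frames),
        "n_rows": rec.geometry.n_rows,
        "n_cols": rec.geometry.n_cols,
    }
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("frames", data=data)
            for k, v in meta.items():
                f.attrs[k] = json.dumps(v) if isinstance(v, dict) else v
    else:
        np.savetxt(path, data.reshape(-1, data.shape[-1]), fmt="%d", delimiter=",")
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def read_recording(path, fmt: str | None = None) -> PressureRecording:
    """Read and validate a recording written by :func:`write_recording`."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "hdf5":
        try:
            with h5py.File(path, "r") as f:
                if "frames" not in f:
                    raise FormatError(f"{path}: missing 'frames' dataset")
                data = f["frames"][...]
                meta = {k: f.attrs[k] for k in f.attrs}
        except OSError as exc:
            raise FormatError(f"{path}: not a readable HDF5 container ({exc})") from exc
        subject = meta.get("subject_meta", "{}")
        subject = json.loads(subject) if isinstance(subject, str) else dict(subject)
    else:
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FormatError(f"{path}: missing JSON sidecar {sidecar.name}")
        meta = json.loads(sidecar.read_text())
        for key in ("n_frames", "n_rows", "n_cols"):
            if key not in meta:
                raise FormatError(f"{sidecar}: missing header key {key!r}")
        try:
            flat = np.loadtxt(path, dtype=np.int64, delimiter=",", ndmin=2)
        except ValueError as exc:
            raise FormatError(f"{path}: malformed CSV ({exc})") from exc
        try:
            data = flat.reshape(int(meta["n_frames"]), int(meta["n_rows"]), int(meta["n_cols"]))
        except ValueError as exc:
            raise FormatError(f"{path}: data shape does not match sidecar ({exc})") from exc
        subject = meta.get("subject_meta", {}) or {}
    if data.ndim != 3:
        raise FormatError(f"{path}: frames dataset must be 3-dimensional")
    frames = []
    g = grid_geometry()
    for k in range(data.shape[0]):
        try:
            frames.append(PressureFrame(values=data[k].astype(np.int32), geometry=g))
        except ValidationError as exc:
            raise ValidationError(f"frame {k}: {exc}") from exc
    return PressureRecording(
        frames=frames,
        rate_hz=float(meta.get("rate_hz", 10.0)),
        duration_s=float(meta.get("duration_s", 10.0)),
        subject_meta=subject or None,
    )
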