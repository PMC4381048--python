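"""Readers and writers for 2D spectra and peak lists.

Two spectrum dialects are supported:

``matrix``
    This package's own self-describing format: a two-line ASCII header
    (magic line + one JSON object with dims, axis calibration and label)
    followed by raw little-endian float64 intensities in row-major order.
    Round-trips are bit-exact, which is what the test suite leans on.

``nmrpipe2d``
    The standard NMRPipe stream: a 512-float32 header followed by float32
    data. Only single-plane real 2D spectra are handled; pseudo-3D inputs
    must be split upstream. The usual header slots are honoured: FDSIZE /
    FDSPECNUM for point counts, FDF2SW / FDF1SW for spectral widths (Hz),
    FDF2OBS / FDF1OBS for observe frequencies (MHz) and FDF2ORIG /
    FDF1ORIG for the Hz coordinate of the last point of each axis, so that
    ppm(i) = (ORIG + SW * (n - 1 - i) / n) / OBS.

Peak lists are plain CSV/TSV tables with header ``id,h_ppm,n_ppm,intensity``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Union

import numpy as np
import pandas as pd

from .errors import DimensionalityError, SpectrumFormatError, ValidationError
from .spectra import (
    AxisCalibration,
    PeakEntry,
    PeakList,
    Spectrum2D,
    stack_ensemble,
)

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_peaklist",
    "write_peaklist",
    "stack_ensemble",
]

_MATRIX_MAGIC = b"#SIA-MATRIX 1\n"

# NMRPipe header slots (indices into the 512-float32 block).
_FD = {
    "FDMAGIC": 0,
    "FDFLTFORMAT": 1,
    "FDFLTORDER": 2,
    "FDDIMCOUNT": 9,
    "FDF3SIZE": 15,
    "FDF4SIZE": 32,
    "FDF1QUADFLAG": 55,
    "FDF2QUADFLAG": 56,
    "FDSIZE": 99,
    "FDF2SW": 100,
    "FDF2ORIG": 101,
    "FDQUADFLAG": 106,
    "FDF2OBS": 119,
    "FDF1OBS": 218,
    "FDSPECNUM": 219,
    "FDF2FTFLAG": 220,
    "FDTRANSPOSED": 221,
    "FDF1FTFLAG": 222,
    "FDF1SW": 229,
    "FDF1ORIG": 249,
    "FD2DPHASE": 256,
}
_FDCOMMENT_START = 312  # 160-byte free-text slot used here for the label
_FDCOMMENT_LEN = 160

# float32 bit pattern NMRPipe uses to mark native byte order
_FLTFORMAT = np.frombuffer(np.uint32(0xEEA12989).tobytes(), dtype=np.float32)[0]


def _axis_dict(axis: AxisCalibration) -> dict:
    return {
        "n_points": axis.n_points,
        "spectral_width": axis.spectral_width,
        "ppm_first": axis.ppm_first,
        "obs_mhz": axis.obs_mhz,
    }


def _axis_from_dict(d: Mapping, name: str) -> AxisCalibration:
    try:
        return AxisCalibration(
            n_points=int(d["n_points"]),
            spectral_width=float(d["spectral_width"]),
            ppm_first=float(d["ppm_first"]),
            obs_mhz=float(d.get("obs_mhz", 700.13)),
        )
    except KeyError as exc:
        raise SpectrumFormatError(f"matrix header missing field {exc} in {name}") from None


def _write_matrix(spectrum: Spectrum2D, path: Path) -> None:
    header = {
        "shape": list(spectrum.shape),
        "axis_h": _axis_dict(spectrum.axis_h),
        "axis_n": _axis_dict(spectrum.axis_n),
        "label": spectrum.label,
    }
    payload = np.ascontiguousarray(spectrum.intensities, dtype="<f8").tobytes()
    with open(path, "wb") as fh:
        fh.write(_MATRIX_MAGIC)
        fh.write(json.dumps(header).encode("utf-8") + b"\n")
        fh.write(payload)


def _read_matrix(path: Path) -> Spectrum2D:
    with open(path, "rb") as fh:
        magic = fh.readline()
        if magic != _MATRIX_MAGIC:
            raise SpectrumFormatError(
                f"{path}: bad magic line {magic[:20]!r}, expected {_MATRIX_MAGIC!r}"
            )
        try:
            header = json.loads(fh.readline().decode("utf-8"))
        except (UnicodeDecodeError, json.JSONDecodeError) as exc:
            raise SpectrumFormatError(f"{path}: unreadable JSON header ({exc})") from None
        if "shape" not in header:
            raise SpectrumFormatError(f"{path}: header missing field 'shape'")
        shape = tuple(int(x) for x in header["shape"])
        if len(shape) != 2:
            raise DimensionalityError(f"{path}: shape {shape} is not 2D")
        data = np.frombuffer(fh.read(), dtype="<f8")
    expected = shape[0] * shape[1]
    if data.size != expected:
        raise DimensionalityError(
            f"{path}: payload holds {data.size} points, header promises {expected} "
            "(not a single 2D plane?)"
        )
    return Spectrum2D(
        intensities=data.reshape(shape).copy(),
        axis_h=_axis_from_dict(header.get("axis_h", {}), f"{path} axis_h"),
        axis_n=_axis_from_dict(header.get("axis_n", {}), f"{path} axis_n"),
        label=str(header.get("label", "")),
    )


def _write_nmrpipe(spectrum: Spectrum2D, path: Path) -> None:
    n_h, n_n = spectrum.shape
    hdr = np.zeros(512, dtype=np.float32)
    hdr[_FD["FDFLTFORMAT"]] = _FLTFORMAT
    hdr[_FD["FDFLTORDER"]] = np.float32(2.345)
    hdr[_FD["FDDIMCOUNT"]] = 2.0
    hdr[_FD["FDF3SIZE"]] = 1.0
    hdr[_FD["FDF4SIZE"]] = 1.0
    hdr[_FD["FDSIZE"]] = float(n_h)  # direct (1H) points per trace
    hdr[_FD["FDSPECNUM"]] = float(n_n)  # number of traces (15N increments)
    hdr[_FD["FDQUADFLAG"]] = 1.0  # real data
    hdr[_FD["FDF2QUADFLAG"]] = 1.0
    hdr[_FD["FDF1QUADFLAG"]] = 1.0
    hdr[_FD["FDF2FTFLAG"]] = 1.0  # frequency domain
    hdr[_FD["FDF1FTFLAG"]] = 1.0
    hdr[_FD["FD2DPHASE"]] = 2.0  # States
    for axis, sw_key, obs_key, orig_key, n in (
        (spectrum.axis_h, "FDF2SW", "FDF2OBS", "FDF2ORIG", n_h),
        (spectrum.axis_n, "FDF1SW", "FDF1OBS", "FDF1ORIG", n_n),
    ):
        sw_hz = axis.spectral_width * axis.obs_mhz
        hdr[_FD[sw_key]] = sw_hz
        hdr[_FD[obs_key]] = axis.obs_mhz
        # ORIG = Hz of the last (most upfield) point on the axis
        hdr[_FD[orig_key]] = axis.obs_mhz * axis.ppm_first - sw_hz * (n - 1) / n
    comment = spectrum.label.encode("utf-8")[:_FDCOMMENT_LEN]
    hdr_bytes = bytearray(hdr.tobytes())
    hdr_bytes[4 * _FDCOMMENT_START : 4 * _FDCOMMENT_START + len(comment)] = comment
    # traces of the direct dimension, indirect increments as records
    data = np.ascontiguousarray(spectrum.intensities.T, dtype="<f4")
    with open(path, "wb") as fh:
        fh.write(bytes(hdr_bytes))
        fh.write(data.tobytes())


def _read_nmrpipe(path: Path) -> Spectrum2D:
    raw = Path(path).read_bytes()
    if len(raw) < 512 * 4:
        raise SpectrumFormatError(f"{path}: shorter than a 512-float NMRPipe header")
    hdr = np.frombuffer(raw[: 512 * 4], dtype="<f4")
    dimcount = int(round(float(hdr[_FD["FDDIMCOUNT"]])))
    if dimcount != 2:
        raise DimensionalityError(f"{path}: FDDIMCOUNT={dimcount}, expected 2")
    if int(round(float(hdr[_FD["FDQUADFLAG"]]))) != 1:
        raise SpectrumFormatError(f"{path}: FDQUADFLAG != 1 (complex data unsupported)")
    n_h = int(round(float(hdr[_FD["FDSIZE"]])))
    n_n = int(round(float(hdr[_FD["FDSPECNUM"]])))
    if n_h < 2 or n_n < 2:
        raise SpectrumFormatError(f"{path}: FDSIZE/FDSPECNUM give grid {n_h} x {n_n}")
    planes3 = int(round(float(hdr[_FD["FDF3SIZE"]]))) or 1
    planes4 = int(round(float(hdr[_FD["FDF4SIZE"]]))) or 1
    if planes3 * planes4 > 1:
        raise DimensionalityError(
            f"{path}: {planes3 * planes4} planes present (pseudo-3D); split upstream"
        )
    data = np.frombuffer(raw[512 * 4 :], dtype="<f4")
    if data.size != n_h * n_n:
        raise DimensionalityError(
            f"{path}: data block has {data.size} points, header promises "
            f"{n_h} x {n_n} = {n_h * n_n} (pseudo-3D passed as 2D?)"
        )
    axes = {}
    for name, sw_key, obs_key, orig_key, n in (
        ("axis_h", "FDF2SW", "FDF2OBS", "FDF2ORIG", n_h),
        ("axis_n", "FDF1SW", "FDF1OBS", "FDF1ORIG", n_n),
    ):
        sw_hz = float(hdr[_FD[sw_key]])
        obs = float(hdr[_FD[obs_key]])
        if sw_hz <= 0 or obs <= 0:
            raise SpectrumFormatError(f"{path}: non-positive {sw_key}/{obs_key}")
        orig = float(hdr[_FD[orig_key]])
        ppm_first = (orig + sw_hz * (n - 1) / n) / obs
        axes[name] = AxisCalibration(
            n_points=n, spectral_width=sw_hz / obs, ppm_first=ppm_first, obs_mhz=obs
        )
    comment = raw[4 * _FDCOMMENT_START : 4 * _FDCOMMENT_START + _FDCOMMENT_LEN]
    label = comment.split(b"\x00", 1)[0].decode("utf-8", errors="replace")
    intensities = data.reshape(n_n, n_h).T.astype(float)
    return Spectrum2D(intensities=intensities, label=label, **axes)


def read_spectrum(path: Union[str, Path], format: str = "matrix") -> Spectrum2D:
    """Read a 2D spectrum from ``path`` in the named dialect.

    Parameters
    ----------
    path
        File to read.
    format
        ``"matrix"`` (the package's float64 dialect) or ``"nmrpipe2d"``.
    """
    path = Path(path)
    if not path.exists():
        raise SpectrumFormatError(f"no such file: {path}")
    if format == "matrix":
        return _read_matrix(path)
    if format == "nmrpipe2d":
        return _read_nmrpipe(path)
    raise ValueError(f"unknown spectrum format {format!r}")


def write_spectrum(spectrum: Spectrum2D, path: Union[str, Path], format: str = "matrix") -> None:
    """Write a validated :class:`Spectrum2D` to ``path``.

    The matrix dialect round-trips bit-exactly; nmrpipe2d stores float32
    and round-trips within float32 rounding.
    """
    if not isinstance(spectrum, Spectrum2D):
        raise ValidationError("write_spectrum expects a Spectrum2D")
    if not np.all(np.isfinite(spectrum.intensities)):  # re-check: arrays are mutable
        raise ValidationError("refusing to write non-finite intensities")
    path = Path(path)
    if format == "matrix":
        _write_matrix(spectrum, path)
    elif format == "nmrpipe2d":
        _write_nmrpipe(spectrum, path)
    else:
        raise ValueError(f"unknown spectrum format {format!r}")


_PEAK_COLUMNS = ["id", "h_ppm", "n_ppm", "intensity"]


def read_peaklist(path: Union[str, Path]) -> PeakList:
    """Read a peak list from a CSV or TSV table with header
    ``id,h_ppm,n_ppm,intensity``. The delimiter is sniffed from the header."""
    path = Path(path)
    if not path.exists():
        raise SpectrumFormatError(f"no such file: {path}")
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in _PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise SpectrumFormatError(f"{path}: missing column(s) {missing}")
    dup = df["id"].astype(str)[df["id"].astype(str).duplicated()]
    if len(dup):
        raise ValidationError(f"{path}: duplicate assignment id {dup.iloc[0]!r}")
    entries = [
        PeakEntry(
            assignment_id=str(row.id),
            delta_h=float(row.h_ppm),
            delta_n=float(row.n_ppm),
            intensity=float(row.intensity),
        )
        for row in df.itertuples()
    ]
    return PeakList(entries=entries)


def write_peaklist(peaks: PeakList, path: Union[str, Path], sep: str = ",") -> None:
    """Write a peak list as a delimited table (CSV by default)."""
    df = pd.DataFrame(
        {
            "id": [e.assignment_id for e in peaks],
            "h_ppm": [e.delta_h for e in peaks],
            "n_ppm": [e.delta_n for e in peaks],
            "intensity": [e.intensity for e in peaks],
        }
    )
    df.to_csv(path, sep=sep, index=False, float_format="%.6f")
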