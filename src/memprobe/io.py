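"""Plain-text readers and writers for the five data kinds.

All tabular formats are whitespace-delimited text with ``# key=value``
comment headers, so every artifact is diffable and instrument-agnostic.
Floats are written with 17 significant digits, which makes every
read/write round-trip lossless for IEEE doubles.  A compact binary trace
option (raw counts + JSON sidecar) exists for very long traces but is
never required.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .simulate import IntensityTrace
from .correlate import CorrelationCurve
from .fcsmodels import FcsFit, FcsModelSpec
from .spr import Sensorgram
from .cd import CDSpectrum

__all__ = [
    "read_trace", "write_trace", "write_trace_binary", "read_trace_binary",
    "read_curve", "write_curve",
    "read_sensorgram", "write_sensorgram",
    "read_spectrum", "write_spectrum",
    "write_fit_report", "read_fit_report",
    "checksum",
]

_F = "%.17g"


def checksum(path: Union[str, Path]) -> str:
    """sha256 of a file's bytes (first 16 hex digits)."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def _write_table(path: Path, header: dict, columns: list[np.ndarray],
                 fmt: Optional[list[str]] = None) -> None:
    with open(path, "w") as fh:
        for k, v in header.items():
            fh.write(f"# {k}={v}\n")
        rows = len(columns[0])
        fmt = fmt or [_F] * len(columns)
        for i in range(rows):
            fh.write(" ".join(f % c[i] for f, c in zip(fmt, columns)) + "\n")


def _read_table(path: Path, n_cols: int):
    header: dict[str, str] = {}
    data: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    header[k.strip()] = v.strip()
                continue
            parts = line.split()
            data.append([float(p) for p in parts[:n_cols]])
    return header, np.asarray(data)


def write_trace(path: Union[str, Path], trace: IntensityTrace) -> None:
    """Trace as two columns (time_s, counts) with metadata in the header."""
    path = Path(path)
    header = {"bin_width": _F % trace.bin_width}
    for k, v in trace.metadata.items():
        if k != "bin_width" and np.isscalar(v):
            header[k] = v
    _write_table(path, header, [trace.times, trace.counts], [_F, "%d"])


def read_trace(path: Union[str, Path]) -> IntensityTrace:
    header, data = _read_table(Path(path), 2)
    if "bin_width" not in header:
        raise ValueError("trace file lacks a '# bin_width=' header")
    meta = {k: _maybe_num(v) for k, v in header.items() if k != "bin_width"}
    return IntensityTrace(data[:, 1].astype(np.int64), float(header["bin_width"]), meta)


def _maybe_num(s: str):
    try:
        f = float(s)
        return int(f) if f.is_integer() and "." not in s and "e" not in s.lower() else f
    except ValueError:
        return s


def write_trace_binary(path: Union[str, Path], trace: IntensityTrace) -> None:
    """Compact option: flat uint32 counts plus a JSON sidecar (.json)."""
    path = Path(path)
    trace.counts.astype(np.uint32).tofile(path)
    sidecar = {"bin_width": trace.bin_width, "dtype": "uint32",
               "n_bins": int(len(trace.counts)),
               "metadata": {k: v for k, v in trace.metadata.items()
                            if isinstance(v, (int, float, str))}}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_trace_binary(path: Union[str, Path]) -> IntensityTrace:
    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    counts = np.fromfile(path, dtype=np.uint32).astype(np.int64)
    if len(counts) != sidecar["n_bins"]:
        raise ValueError("binary trace length disagrees with its sidecar")
    return IntensityTrace(counts, sidecar["bin_width"], sidecar.get("metadata", {}))


def write_curve(path: Union[str, Path], curve: CorrelationCurve,
                source: Optional[str] = None) -> None:
    """Curve as three columns (lag_s, G, stderr); stderr is nan if absent."""
    header = {}
    if source is not None:
        header["source"] = source
    se = curve.stderr if curve.stderr is not None else np.full_like(curve.G, np.nan)
    _write_table(Path(path), header, [curve.lags, curve.G, se])


def read_curve(path: Union[str, Path]) -> CorrelationCurve:
    _, data = _read_table(Path(path), 3)
    se = data[:, 2]
    return CorrelationCurve(data[:, 0], data[:, 1],
                            None if np.all(np.isnan(se)) else se)


def write_sensorgram(path: Union[str, Path], sg: Sensorgram) -> None:
    header = {
        "injection_start": _F % sg.injection_start,
        "injection_end": _F % sg.injection_end,
        "dissociation_end": _F % sg.dissociation_end,
        "immobilization": _F % sg.immobilization,
    }
    _write_table(Path(path), header, [sg.time, sg.response])


def read_sensorgram(path: Union[str, Path]) -> Sensorgram:
    header, data = _read_table(Path(path), 2)
    for key in ("injection_start", "injection_end", "dissociation_end", "immobilization"):
        if key not in header:
            raise ValueError(f"sensorgram file lacks '# {key}=' header")
    return Sensorgram(data[:, 0], data[:, 1],
                      float(header["injection_start"]),
                      float(header["injection_end"]),
                      float(header["dissociation_end"]),
                      float(header["immobilization"]))


def write_spectrum(path: Union[str, Path], spec: CDSpectrum) -> None:
    header = {
        "pathlength_cm": _F % spec.pathlength,
        "concentration_M": _F % spec.concentration,
        "n_residues": "%d" % spec.n_residues,
    }
    _write_table(Path(path), header, [spec.wavelength, spec.theta])


def read_spectrum(path: Union[str, Path]) -> CDSpectrum:
    header, data = _read_table(Path(path), 2)
    return CDSpectrum(data[:, 0], data[:, 1],
                      float(header["pathlength_cm"]),
                      float(header["concentration_M"]),
                      int(header["n_residues"]))


_FIT_FIELDS = ["N", "F1", "tau_d1", "tau_d2", "F_trip", "tau_trip", "offset", "redchi"]


def write_fit_report(path: Union[str, Path], fits: list[tuple[str, FcsFit]]) -> None:
    """One row per fitted curve: id, model, parameters, redchi, flags."""
    with open(path, "w") as fh:
        fh.write("# columns=id model K " + " ".join(_FIT_FIELDS) + " success flags\n")
        for trace_id, f in fits:
            model = f.model.name if f.model is not None else "?"
            K = f.model.K if f.model is not None else float("nan")
            vals = " ".join(_F % getattr(f, k) for k in _FIT_FIELDS)
            flags = ",".join(f.flags) if f.flags else "-"
            fh.write(f"{trace_id} {model} {_F % K} {vals} {int(f.success)} {flags}\n")


def read_fit_report(path: Union[str, Path]) -> list[tuple[str, FcsFit]]:
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        trace_id, model_name, K = parts[0], parts[1], float(parts[2])
        vals = dict(zip(_FIT_FIELDS, map(float, parts[3:3 + len(_FIT_FIELDS)])))
        success = bool(int(parts[3 + len(_FIT_FIELDS)]))
        flags = parts[4 + len(_FIT_FIELDS)]
        spec = None
        if model_name != "?":
            dim = model_name[:2].upper()
            ncomp = int(model_name[2])
            spec = FcsModelSpec(dim, ncomp, model_name.endswith("1t"),
                                K=K if np.isfinite(K) else 5.0)
        redchi = vals.pop("redchi")
        fit = FcsFit(**vals, redchi=redchi, success=success,
                     flags=() if flags == "-" else tuple(flags.split(",")),
                     model=spec)
        out.append((trace_id, fit))
    return out
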