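"""Plain-text I/O for curves, spectra, decays and run configuration.

All on-disk formats are locale-independent delimited text with ``# key=value``
metadata headers.  Times are stored in SI seconds on disk and converted to
the package's internal microsecond convention on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .fcs import FcsCurve
from .spectral import EmissionSpectrumSet
from .tcspc import DecayHistogram
from .trast import TrastCurve

__all__ = [
    "RunConfig",
    "read_curve",
    "write_curve",
    "read_spectra",
    "write_spectra",
    "read_decay",
    "write_decay",
]

_US_PER_S = 1e6


def _write_table(path, meta: dict, columns: dict) -> None:
    arrs = {k: np.asarray(v, dtype=float) for k, v in columns.items()}
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        fh.write("# columns: " + " ".join(arrs) + "\n")
        np.savetxt(fh, np.column_stack(list(arrs.values())), fmt="%.12g")


def _read_table(path):
    meta = {}
    columns = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if body.startswith("columns:"):
                columns = body.split(":", 1)[1].split()
            elif "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    data = np.loadtxt(path, ndmin=2)
    if columns is None:
        columns = [f"col{i}" for i in range(data.shape[1])]
    if data.shape[1] != len(columns):
        raise ValueError(f"{path}: expected {len(columns)} columns, "
                         f"found {data.shape[1]}")
    return meta, dict(zip(columns, data.T))


def write_curve(path, curve) -> None:
    """Write an FCS or TRAST curve as delimited text (times in seconds)."""
    if isinstance(curve, FcsCurve):
        meta = {"kind": "fcs", "intensity_kw_cm2": curve.intensity,
                "filter_id": curve.filter_id}
        cols = {"tau_s": curve.lags / _US_PER_S, "g": curve.g}
        if curve.sd is not None:
            cols["sd"] = curve.sd
    elif isinstance(curve, TrastCurve):
        meta = {"kind": "trast", "intensity_kw_cm2": curve.intensity,
                "filter_id": curve.filter_id, "w0_s": curve.w0 / _US_PER_S}
        cols = {"w_s": curve.widths / _US_PER_S, "f_norm": curve.f_norm}
        if curve.sd is not None:
            cols["sd"] = curve.sd
    else:
        raise TypeError(f"cannot write {type(curve).__name__}")
    _write_table(path, meta, cols)


def read_curve(path, kind: str | None = None):
    """Read an FCS or TRAST curve written by :func:`write_curve`.

    ``kind`` ("fcs"/"trast") overrides the file's own header; a mismatch
    is an error.
    """
    meta, cols = _read_table(path)
    file_kind = meta.get("kind", kind)
    if kind is not None and file_kind != kind:
        raise ValueError(f"{path}: file is kind={file_kind!r}, "
                         f"expected {kind!r}")
    intensity = float(meta.get("intensity_kw_cm2", 0.0))
    filter_id = meta.get("filter_id", "full")
    sd = cols.get("sd")
    if file_kind == "fcs":
        return FcsCurve(lags=cols["tau_s"] * _US_PER_S, g=cols["g"],
                        intensity=intensity, filter_id=filter_id, sd=sd)
    if file_kind == "trast":
        return TrastCurve(widths=cols["w_s"] * _US_PER_S,
                          f_norm=cols["f_norm"], intensity=intensity,
                          filter_id=filter_id,
                          w0=float(meta.get("w0_s", 1e-7)) * _US_PER_S,
                          sd=sd)
    raise ValueError(f"{path}: unknown curve kind {file_kind!r}")


def write_spectra(path, sset: EmissionSpectrumSet) -> None:
    """Wide table: wavelength_nm column plus one column per pulse width (s)."""
    df = pd.DataFrame(sset.spectra.T,
                      columns=[f"{w / _US_PER_S:.9g}" for w in sset.widths])
    df.insert(0, "wavelength_nm", sset.wavelengths)
    with open(path, "w") as fh:
        fh.write(f"# intensity_kw_cm2={sset.intensity}\n")
        fh.write(f"# duty={sset.duty}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_spectra(path) -> EmissionSpectrumSet:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            k, v = line[1:].strip().split("=", 1)
            meta[k.strip()] = v.strip()
            pos = fh.tell()
        df = pd.read_csv(fh, sep="\t")
    widths = np.array([float(c) for c in df.columns[1:]]) * _US_PER_S
    return EmissionSpectrumSet(
        wavelengths=df.iloc[:, 0].to_numpy(),
        spectra=df.iloc[:, 1:].to_numpy().T, widths=widths,
        intensity=float(meta.get("intensity_kw_cm2", 0.0)),
        duty=float(meta.get("duty", 0.002)))


def write_decay(path, h: DecayHistogram) -> None:
    _write_table(path, {"kind": "decay"},
                 {"time_ns": h.bin_times, "counts": h.counts,
                  "irf_counts": h.irf})


def read_decay(path) -> DecayHistogram:
    _, cols = _read_table(path)
    return DecayHistogram(bin_times=cols["time_ns"], counts=cols["counts"],
                          irf=cols["irf_counts"])


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {
    "command", "inputs", "out_dir", "seed", "model", "filter_map",
    "fixed", "init_guess", "weights", "thermal_free", "n_starts",
    "n_components", "bands", "noise_scale", "plot", "strict",
    "quadrature_grid", "saturation",
}


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Unknown keys are rejected at construction; every run writes a resolved
    copy (``config.json``) next to its outputs so that re-running it is a
    pure function of that file plus the inputs.
    """

    command: str
    inputs: list = field(default_factory=list)
    out_dir: str = "."
    seed: int = 0
    model: str = "three_state"
    filter_map: dict = field(default_factory=dict)
    fixed: dict = field(default_factory=dict)
    init_guess: dict = field(default_factory=dict)
    weights: bool = True
    thermal_free: bool | None = None
    n_starts: int = 3
    n_components: int = 1
    bands: list = field(default_factory=list)
    noise_scale: float | None = None
    plot: bool = False
    strict: bool = False
    quadrature_grid: int = 32
    saturation: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def write_fit_report(path, result, extra: dict | None = None) -> None:
    """Serialize a FitResult (parameters, 1-sigma errors, diagnostics)."""
    def clean(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        if isinstance(v, dict):
            return {k: clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [clean(x) for x in v]
        if hasattr(v, "to_dict"):
            return v.to_dict()
        if hasattr(v, "__dict__") and not isinstance(v, (int, float, str,
                                                         bool)):
            try:
                return {k: clean(x) for k, x in asdict(v).items()}
            except TypeError:
                return repr(v)
        return v

    payload = {
        "params": clean(result.params),
        "locals": clean(result.locals),
        "uncertainties": clean(result.uncertainties),
        "cost": result.cost,
        "redchi": result.redchi,
        "success": result.success,
        "message": result.message,
        "n_outer_iterations": result.n_outer_iterations,
        "trace": clean(result.trace),
        "residuals": clean(result.residuals),
    }
    if extra:
        payload.update(clean(extra))
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
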