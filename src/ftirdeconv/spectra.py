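"""Spectrum container and I/O for absorbance spectra.

The package-wide convention is an ASCENDING wavenumber axis (cm⁻¹);
instrument exports commonly run 4000 → 400 cm⁻¹ and are flipped on read.
Two text formats are supported:

* CSV — two columns ``wavenumber_cm-1,absorbance`` with ``#``-prefixed
  header/metadata lines (``# key: value``).
* JCAMP-DX — AFFN-encoded ``##XYDATA=(X++(Y..Y))`` or ``##XYPOINTS=(XY..XY)``
  blocks only; compressed SQZ/DIF encodings are rejected.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Spectrum",
    "SpectrumParseError",
    "read_spectrum",
    "write_spectrum",
    "resample",
    "average_replicates",
]

logger = logging.getLogger(__name__)


class SpectrumParseError(ValueError):
    """A spectrum file could not be parsed; the message names the line."""


@dataclass
class Spectrum:
    """A sampled absorbance trace on a strictly ascending wavenumber grid.

    Parameters
    ----------
    wavenumbers : array-like
        Wavenumber axis in cm⁻¹.  Any input ordering is accepted;
        the axis is canonicalized to strictly ascending order and rows
        with duplicate wavenumbers are collapsed by their mean.
    absorbance : array-like
        Absorbance in AU, same length as ``wavenumbers``, finite everywhere.
    label : str
        Free-text sample label.
    metadata : dict[str, str]
        Key→string map (resolution, replicate id, treatment, ...).
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        nu = np.asarray(self.wavenumbers, dtype=float).ravel()
        ab = np.asarray(self.absorbance, dtype=float).ravel()
        if nu.size != ab.size:
            raise ValueError(
                f"wavenumbers ({nu.size}) and absorbance ({ab.size}) differ in length"
            )
        if nu.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not np.all(np.isfinite(nu)):
            raise ValueError("non-finite wavenumber values")
        if not np.all(np.isfinite(ab)):
            raise ValueError("non-finite absorbance values")
        order = np.argsort(nu, kind="stable")
        nu, ab = nu[order], ab[order]
        if np.any(np.diff(nu) == 0.0):
            # collapse duplicate wavenumber rows by mean (instrument quirks)
            uniq, inverse, counts = np.unique(nu, return_inverse=True, return_counts=True)
            summed = np.zeros_like(uniq)
            np.add.at(summed, inverse, ab)
            logger.warning(
                "collapsed %d duplicate wavenumber rows by mean", int(nu.size - uniq.size)
            )
            nu, ab = uniq, summed / counts
            if nu.size < 2:
                raise ValueError("a spectrum needs at least 2 distinct wavenumbers")
        self.wavenumbers = nu
        self.absorbance = ab
        self.metadata = dict(self.metadata)

    def __len__(self) -> int:
        return self.wavenumbers.size

    @property
    def range(self) -> tuple[float, float]:
        """(min, max) wavenumber covered."""
        return float(self.wavenumbers[0]), float(self.wavenumbers[-1])

    def crop(self, low: float, high: float) -> "Spectrum":
        """Restrict to wavenumbers within [low, high]."""
        mask = (self.wavenumbers >= low) & (self.wavenumbers <= high)
        if mask.sum() < 2:
            raise ValueError(f"fewer than 2 points in [{low}, {high}]")
        return Spectrum(
            self.wavenumbers[mask], self.absorbance[mask], self.label, dict(self.metadata)
        )

    def with_absorbance(self, absorbance: np.ndarray, **extra_meta: str) -> "Spectrum":
        md = dict(self.metadata)
        md.update({k: str(v) for k, v in extra_meta.items()})
        return Spectrum(self.wavenumbers.copy(), absorbance, self.label, md)

    def value_at(self, nu: float) -> float:
        """Absorbance at the grid point nearest ``nu``."""
        lo, hi = self.range
        if not (lo <= nu <= hi):
            raise ValueError(f"wavenumber {nu} outside spectrum range [{lo}, {hi}]")
        idx = int(np.argmin(np.abs(self.wavenumbers - nu)))
        return float(self.absorbance[idx])

    def allclose(self, other: "Spectrum", atol: float = 1e-6) -> bool:
        return (
            self.wavenumbers.size == other.wavenumbers.size
            and np.allclose(self.wavenumbers, other.wavenumbers, atol=atol)
            and np.allclose(self.absorbance, other.absorbance, atol=atol)
        )


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

_CSV_HEADER = "wavenumber_cm-1,absorbance"


def _read_csv(path: Path) -> Spectrum:
    nus: list[float] = []
    abs_: list[float] = []
    metadata: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    metadata[key.strip()] = val.strip()
                continue
            if line.replace(" ", "").lower() == _CSV_HEADER:
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise SpectrumParseError(
                    f"{path}: line {lineno}: expected 2 comma-separated values, got {len(parts)}"
                )
            try:
                nus.append(float(parts[0]))
                abs_.append(float(parts[1]))
            except ValueError as exc:
                raise SpectrumParseError(
                    f"{path}: line {lineno}: non-numeric entry {line!r}"
                ) from exc
    if not nus:
        raise SpectrumParseError(f"{path}: no data rows found")
    label = metadata.pop("label", Path(path).stem)
    return Spectrum(np.array(nus), np.array(abs_), label=label, metadata=metadata)


def _write_csv(spectrum: Spectrum, path: Path) -> None:
    with open(path, "w") as fh:
        if spectrum.label:
            fh.write(f"# label: {spectrum.label}\n")
        for key, val in spectrum.metadata.items():
            fh.write(f"# {key}: {val}\n")
        fh.write(_CSV_HEADER + "\n")
        for nu, ab in zip(spectrum.wavenumbers, spectrum.absorbance):
            fh.write(f"{nu:.8g},{ab:.8g}\n")


# ---------------------------------------------------------------------------
# JCAMP-DX (AFFN only)
# ---------------------------------------------------------------------------

_AFFN_OK = re.compile(r"^[\s0-9.+\-eE,;]*$")


def _read_jcamp(path: Path) -> Spectrum:
    metadata: dict[str, str] = {}
    numeric: dict[str, float] = {}
    xfactor = yfactor = 1.0
    data_mode: str | None = None
    xs: list[float] = []
    ys: list[float] = []
    xydata_lines: list[tuple[float, list[float]]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("##"):
                key, _, val = line[2:].partition("=")
                key = key.strip().upper()
                val = val.strip()
                if key == "END":
                    data_mode = None
                elif key == "XYDATA":
                    if "X++" not in val.replace(" ", ""):
                        raise SpectrumParseError(
                            f"{path}: line {lineno}: unsupported XYDATA form {val!r}"
                        )
                    data_mode = "xydata"
                elif key == "XYPOINTS":
                    data_mode = "xypoints"
                elif key == "XFACTOR":
                    xfactor = float(val)
                elif key == "YFACTOR":
                    yfactor = float(val)
                elif key in ("FIRSTX", "LASTX", "NPOINTS", "DELTAX"):
                    numeric[key] = float(val)
                else:
                    data_mode = None
                    if val:
                        metadata[key.lstrip("$").lower()] = val
                continue
            if data_mode is None:
                continue
            if not _AFFN_OK.match(line):
                raise SpectrumParseError(
                    f"{path}: line {lineno}: non-AFFN (compressed SQZ/DIF?) data not supported"
                )
            try:
                if data_mode == "xydata":
                    vals = [float(tok) for tok in line.replace(",", " ").split()]
                    if len(vals) < 2:
                        raise SpectrumParseError(
                            f"{path}: line {lineno}: XYDATA line needs an X and >=1 Y"
                        )
                    xydata_lines.append((vals[0], vals[1:]))
                else:  # xypoints: "x, y; x, y" or whitespace separated pairs
                    vals = [float(tok) for tok in re.split(r"[,;\s]+", line) if tok]
                    if len(vals) % 2:
                        raise SpectrumParseError(
                            f"{path}: line {lineno}: odd number of values in XYPOINTS"
                        )
                    xs.extend(vals[0::2])
                    ys.extend(vals[1::2])
            except ValueError as exc:
                raise SpectrumParseError(
                    f"{path}: line {lineno}: non-numeric entry"
                ) from exc
    if xydata_lines:
        # X++(Y..Y): per-line abscissa start, implicit step DELTAX or
        # (LASTX-FIRSTX)/(NPOINTS-1), else inferred from line starts
        n_y = sum(len(yvals) for _, yvals in xydata_lines)
        if "DELTAX" in numeric:
            dx = numeric["DELTAX"]
        elif "FIRSTX" in numeric and "LASTX" in numeric and n_y > 1:
            dx = (numeric["LASTX"] - numeric["FIRSTX"]) / (n_y - 1)
        elif len(xydata_lines) > 1:
            (x0, y0), (x1, _) = xydata_lines[0], xydata_lines[1]
            dx = (x1 - x0) / len(y0)
        else:
            raise SpectrumParseError(
                f"{path}: cannot infer XYDATA abscissa step (need DELTAX or FIRSTX/LASTX/NPOINTS)"
            )
        for x0, yvals in xydata_lines:
            xs.extend(x0 + i * dx for i in range(len(yvals)))
            ys.extend(yvals)
    if not xs:
        raise SpectrumParseError(f"{path}: no XYDATA/XYPOINTS block found")
    nu = np.array(xs) * xfactor
    ab = np.array(ys) * yfactor
    label = metadata.pop("title", Path(path).stem)
    return Spectrum(nu, ab, label=label, metadata=metadata)


def _write_jcamp(spectrum: Spectrum, path: Path) -> None:
    nu, ab = spectrum.wavenumbers, spectrum.absorbance
    with open(path, "w") as fh:
        fh.write(f"##TITLE={spectrum.label or Path(path).stem}\n")
        fh.write("##JCAMP-DX=4.24\n")
        fh.write("##DATA TYPE=INFRARED SPECTRUM\n")
        fh.write("##XUNITS=1/CM\n")
        fh.write("##YUNITS=ABSORBANCE\n")
        for key, val in spectrum.metadata.items():
            fh.write(f"##${key.upper()}={val}\n")
        fh.write("##XFACTOR=1\n##YFACTOR=1\n")
        fh.write(f"##FIRSTX={nu[0]:.8g}\n##LASTX={nu[-1]:.8g}\n")
        fh.write(f"##NPOINTS={nu.size}\n")
        fh.write("##XYPOINTS=(XY..XY)\n")
        for x, y in zip(nu, ab):
            fh.write(f"{x:.8g}, {y:.8g}\n")
        fh.write("##END=\n")


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def read_spectrum(path, format: str | None = None) -> Spectrum:
    """Read a spectrum from ``path``.

    ``format`` is ``"csv"`` or ``"jcamp"``; when omitted it is inferred from
    the file suffix (``.jdx``/``.dx`` → jcamp, anything else → csv).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "jcamp" if path.suffix.lower() in {".jdx", ".dx", ".jcm"} else "csv"
    if format == "csv":
        return _read_csv(path)
    if format == "jcamp":
        return _read_jcamp(path)
    raise ValueError(f"unknown format {format!r}")


def write_spectrum(spectrum: Spectrum, path, format: str | None = None) -> None:
    """Write ``spectrum`` to ``path`` (CSV or JCAMP-DX), 8 significant digits."""
    if not isinstance(spectrum, Spectrum):
        raise TypeError("write_spectrum expects a Spectrum")
    path = Path(path)
    if format is None:
        format = "jcamp" if path.suffix.lower() in {".jdx", ".dx", ".jcm"} else "csv"
    if format == "csv":
        _write_csv(spectrum, path)
    elif format == "jcamp":
        _write_jcamp(spectrum, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def resample(spectrum: Spectrum, grid: Sequence[float]) -> Spectrum:
    """Linearly interpolate ``spectrum`` onto ``grid`` (no extrapolation)."""
    grid = np.asarray(grid, dtype=float)
    lo, hi = spectrum.range
    if grid.min() < lo or grid.max() > hi:
        raise ValueError(
            f"target grid [{grid.min()}, {grid.max()}] outside spectrum range [{lo}, {hi}]"
        )
    ab = np.interp(grid, spectrum.wavenumbers, spectrum.absorbance)
    return Spectrum(grid, ab, spectrum.label, dict(spectrum.metadata))


def average_replicates(spectra: Iterable[Spectrum]) -> Spectrum:
    """Pointwise mean of replicate spectra sharing one wavenumber grid."""
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra to average")
    ref = spectra[0]
    for s in spectra[1:]:
        if s.wavenumbers.size != ref.wavenumbers.size or not np.allclose(
            s.wavenumbers, ref.wavenumbers
        ):
            raise ValueError("replicate spectra are not on a common wavenumber grid")
    mean = np.mean([s.absorbance for s in spectra], axis=0)
    md = dict(ref.metadata)
    md["n_replicates"] = str(len(spectra))
    return Spectrum(ref.wavenumbers.copy(), mean, ref.label, md)


def uniform_grid(low: float, high: float, step: float = 1.0) -> np.ndarray:
    """Ascending wavenumber grid from ``low`` to ``high`` inclusive."""
    n = int(round((high - low) / step))
    return low + step * np.arange(n + 1)
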