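"""Spectrum containers and plain-text I/O.

A spectrum file is a two-column delimited text body (wavenumber in
cm⁻¹, intensity in arbitrary units) preceded by optional ``#key: value``
header lines carrying acquisition metadata.  A manifest is a delimited
table with columns ``path, excitation_nm, region_label, replicate_id``
grouping spectrum files into an excitation series.  Hyperspectral
stacks are stored as a single matrix file whose first row is the shared
wavenumber axis and whose remaining rows are per-pixel intensities
(row-major pixel order), plus grid metadata in ``#`` headers.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .errors import ParseError, RangeError, ValidationError

__all__ = [
    "Spectrum",
    "ExcitationSeries",
    "HyperMap",
    "read_spectrum",
    "write_spectrum",
    "read_series",
    "read_hypermap",
    "write_hypermap",
    "resample",
    "common_grid",
]

_META_KEYS = ("excitation_nm", "region_label", "replicate_id", "source")


@dataclass
class Spectrum:
    """One Raman trace: ascending wavenumber axis, intensities, metadata.

    Descending input axes are silently reversed to ascending (the
    intensities are co-reversed); duplicate wavenumbers are rejected as
    ambiguous.  ``flags`` accumulates non-fatal processing warnings
    (e.g. baseline non-convergence).
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    excitation_nm: float | None = None
    region_label: str = ""
    replicate_id: str = ""
    source: str = "synthetic"
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if w.ndim != 1 or y.ndim != 1 or w.size != y.size:
            raise ValidationError("wavenumbers and intensities must be 1-D and equal length")
        if w.size < 2:
            raise ValidationError(f"spectrum needs at least 2 points, got {w.size}")
        if not np.all(np.isfinite(w)) or not np.all(np.isfinite(y)):
            raise ValidationError("non-finite values in spectrum")
        d = np.diff(w)
        if np.all(d < 0):  # descending axis: normalize
            w, y = w[::-1], y[::-1]
            d = -d[::-1]
        if np.any(d == 0):
            dup = w[:-1][d == 0][0]
            raise ValidationError(f"duplicate wavenumber {dup:g} cm^-1")
        if np.any(d < 0):
            raise ValidationError("wavenumber axis is not monotonic")
        if self.excitation_nm is not None and not self.excitation_nm > 0:
            raise ValidationError("excitation_nm must be positive")
        self.wavenumbers = w
        self.intensities = y

    def __len__(self) -> int:
        return self.wavenumbers.size

    def with_intensities(self, intensities: np.ndarray, extra_flags: Iterable[str] = ()) -> "Spectrum":
        """Copy carrying new intensities on the same axis (metadata kept)."""
        out = replace(self, intensities=np.asarray(intensities, dtype=float),
                      wavenumbers=self.wavenumbers.copy())
        out.flags = list(self.flags) + list(extra_flags)
        return out

    def metadata(self) -> dict:
        return {
            "excitation_nm": self.excitation_nm,
            "region_label": self.region_label,
            "replicate_id": self.replicate_id,
            "source": self.source,
        }


@dataclass
class ExcitationSeries:
    """Replicate-averaged spectra for one feather region, keyed by
    excitation wavelength (nm), kept in ascending wavelength order."""

    region_label: str
    entries: dict[float, Spectrum]
    notes: str = ""

    def __post_init__(self) -> None:
        items = sorted(self.entries.items())
        if len(items) != len({nm for nm, _ in items}):
            raise ValidationError("duplicate excitation wavelengths in series")
        for nm, spec in items:
            if not nm > 0:
                raise ValidationError("excitation wavelengths must be positive")
            if spec.excitation_nm is not None and abs(spec.excitation_nm - nm) > 1e-9:
                raise ValidationError(
                    f"series key {nm} nm disagrees with spectrum metadata {spec.excitation_nm} nm")
        self.entries = dict(items)

    @property
    def excitations(self) -> list[float]:
        return list(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class HyperMap:
    """Pixel grid of spectra sharing one wavenumber axis.

    ``data`` has shape (n_rows, n_cols, n_points).
    """

    n_rows: int
    n_cols: int
    pixel_size_um: float
    wavenumbers: np.ndarray
    data: np.ndarray
    excitation_nm: float | None = None

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (self.n_rows, self.n_cols, self.wavenumbers.size):
            raise ValidationError(
                f"data shape {self.data.shape} does not match "
                f"({self.n_rows}, {self.n_cols}, {self.wavenumbers.size})")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValidationError("shared wavenumber axis must be strictly increasing")

    def spectrum(self, row: int, col: int) -> Spectrum:
        return Spectrum(self.wavenumbers.copy(), self.data[row, col].copy(),
                        excitation_nm=self.excitation_nm,
                        replicate_id=f"px({row},{col})", source="hypermap")


# ---------------------------------------------------------------- file I/O

def _sniff_delimiter(line: str, dialect: str) -> str:
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    return None  # whitespace


def _parse_header(lines: list[str]) -> tuple[dict, int]:
    meta: dict = {}
    n = 0
    for line in lines:
        s = line.strip()
        if not s.startswith("#"):
            if s:
                break
            n += 1
            continue
        n += 1
        body = s.lstrip("#").strip()
        if ":" in body:
            key, _, val = body.partition(":")
            meta[key.strip()] = val.strip()
    return meta, n


def read_spectrum(path: str | os.PathLike, dialect: str = "auto") -> Spectrum:
    """Read a two-column delimited spectrum file.

    ``#key: value`` header lines populate metadata.  A descending axis
    is normalized to ascending; duplicate wavenumbers raise
    :class:`ValidationError`; a non-numeric row raises
    :class:`ParseError` naming the offending line.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    meta, nskip = _parse_header(lines)
    body = [(i + 1, ln.strip()) for i, ln in enumerate(lines)
            if ln.strip() and not ln.strip().startswith("#")]
    if not body:
        raise ParseError(f"{path}: no data rows")
    delim = _sniff_delimiter(body[0][1], dialect)
    w, y = [], []
    for lineno, ln in body:
        parts = ln.split(delim) if delim else ln.split()
        parts = [p for p in parts if p != ""]
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        try:
            w.append(float(parts[0]))
            y.append(float(parts[1]))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric value ({exc})") from None
    exc_nm = meta.get("excitation_nm")
    return Spectrum(
        np.array(w), np.array(y),
        excitation_nm=float(exc_nm) if exc_nm not in (None, "") else None,
        region_label=meta.get("region_label", ""),
        replicate_id=meta.get("replicate_id", ""),
        source=str(path),
    )


def write_spectrum(spec: Spectrum, path: str | os.PathLike, delimiter: str = ",") -> None:
    """Write a spectrum as delimited text with a ``#`` metadata header.

    Values are printed with shortest round-trip precision so
    :func:`read_spectrum` inverts this exactly.
    """
    with open(path, "w", encoding="utf-8") as fh:
        meta = spec.metadata()
        meta["source"] = None  # source is where it was read from, not payload
        for key in _META_KEYS:
            val = meta.get(key)
            if val not in (None, ""):
                fh.write(f"#{key}: {val}\n")
        for wv, iv in zip(spec.wavenumbers, spec.intensities):
            fh.write(f"{float(wv)!r}{delimiter}{float(iv)!r}\n")


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read a series/survey manifest (delimited table).

    Required column: ``path``; optional: ``excitation_nm``,
    ``region_label``, ``replicate_id``, ``hue``, ``specimen_id``.
    Relative paths resolve against the manifest's directory.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#",
                         skip_blank_lines=True)
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse manifest ({exc})") from None
    if "path" not in df.columns:
        raise ParseError(f"{path}: manifest lacks a 'path' column")
    base = os.path.dirname(os.fspath(path))
    df["path"] = [p if os.path.isabs(p) else os.path.join(base, p) for p in df["path"]]
    return df


def read_series(
    manifest: str | os.PathLike,
    preprocess: Callable[[Spectrum], Spectrum] | None = None,
    average: Callable[[list[Spectrum]], Spectrum] | None = None,
) -> ExcitationSeries:
    """Assemble an excitation series from a manifest of replicate spectra.

    Replicates are grouped per excitation wavelength, optionally passed
    through ``preprocess`` (per spectrum), resampled to their common
    grid, then combined with ``average`` (default: pointwise mean via
    :func:`ramanfd.preprocess.average_replicates`).  Entries are keyed
    ascending by excitation wavelength.
    """
    from .preprocess import average_replicates  # deferred: avoid cycle

    df = read_manifest(manifest)
    if "excitation_nm" not in df.columns:
        raise ParseError(f"{manifest}: series manifest lacks 'excitation_nm'")
    if "replicate_id" not in df.columns:
        df = df.assign(replicate_id=[str(i) for i in range(len(df))])
    dup = df.duplicated(subset=["excitation_nm", "replicate_id"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            f"duplicate manifest entry: excitation {row['excitation_nm']} nm, "
            f"replicate {row['replicate_id']!r}")
    if average is None:
        average = average_replicates

    entries: dict[float, Spectrum] = {}
    region = ""
    for nm, grp in df.groupby("excitation_nm"):
        reps = []
        for _, row in grp.iterrows():
            if not os.path.exists(row["path"]):
                raise ParseError(f"manifest references missing file: {row['path']}")
            spec = read_spectrum(row["path"])
            if spec.excitation_nm is None:
                spec.excitation_nm = float(nm)
            if "region_label" in row and isinstance(row.get("region_label"), str):
                spec.region_label = row["region_label"] or spec.region_label
            if "replicate_id" in row:
                spec.replicate_id = str(row["replicate_id"])
            if preprocess is not None:
                spec = preprocess(spec)
            reps.append(spec)
        grid = common_grid(reps)
        reps = [resample(s, grid) for s in reps]
        mean = average(reps)
        entries[float(nm)] = mean
        region = mean.region_label or region
    return ExcitationSeries(region_label=region, entries=entries)


def common_grid(specs: Iterable[Spectrum]) -> np.ndarray:
    """Largest shared grid: the first spectrum's axis clipped to the
    intersection of all axis ranges (linear resampling target)."""
    specs = list(specs)
    lo = max(s.wavenumbers[0] for s in specs)
    hi = min(s.wavenumbers[-1] for s in specs)
    if lo >= hi:
        raise RangeError("spectra share no overlapping wavenumber range")
    ax = specs[0].wavenumbers
    return ax[(ax >= lo) & (ax <= hi)]


def resample(spec: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linear interpolation onto ``grid`` (no extrapolation)."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValidationError("resample grid must be 1-D and strictly increasing")
    if grid[0] < spec.wavenumbers[0] - 1e-12 or grid[-1] > spec.wavenumbers[-1] + 1e-12:
        raise RangeError(
            f"grid [{grid[0]:g}, {grid[-1]:g}] extends beyond spectrum axis "
            f"[{spec.wavenumbers[0]:g}, {spec.wavenumbers[-1]:g}]")
    y = np.interp(grid, spec.wavenumbers, spec.intensities)
    out = replace(spec, wavenumbers=grid, intensities=y)
    out.flags = list(spec.flags)
    return out


def read_hypermap(path: str | os.PathLike) -> HyperMap:
    """Read a hyperspectral stack from a single matrix file.

    First non-header row = shared wavenumber axis; each further row is
    one pixel (row-major).  Header keys: n_rows, n_cols, pixel_size_um,
    excitation_nm.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    meta, _ = _parse_header(lines)
    for key in ("n_rows", "n_cols"):
        if key not in meta:
            raise ParseError(f"{path}: hypermap file lacks '#{key}:' header")
    n_rows, n_cols = int(meta["n_rows"]), int(meta["n_cols"])
    body = "".join(ln for ln in lines if not ln.strip().startswith("#"))
    mat = np.loadtxt(io.StringIO(body), delimiter=",")
    axis, pix = mat[0], mat[1:]
    if pix.shape[0] != n_rows * n_cols:
        raise ValidationError(
            f"{path}: {pix.shape[0]} pixel rows, expected {n_rows * n_cols}")
    exc = meta.get("excitation_nm")
    return HyperMap(n_rows, n_cols, float(meta.get("pixel_size_um", 1.0)),
                    axis, pix.reshape(n_rows, n_cols, axis.size),
                    excitation_nm=float(exc) if exc else None)


def write_hypermap(hmap: HyperMap, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#n_rows: {hmap.n_rows}\n#n_cols: {hmap.n_cols}\n")
        fh.write(f"#pixel_size_um: {hmap.pixel_size_um!r}\n")
        if hmap.excitation_nm is not None:
            fh.write(f"#excitation_nm: {hmap.excitation_nm!r}\n")
        np.savetxt(fh, hmap.wavenumbers[None, :], delimiter=",", fmt="%.17g")
        np.savetxt(fh, hmap.data.reshape(-1, hmap.wavenumbers.size),
                   delimiter=",", fmt="%.17g")
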