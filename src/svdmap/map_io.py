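"""Plain-text I/O for spectral maps, scalar maps, labels and spectra.

All formats are tab-separated UTF-8 with a mandatory header and a decimal
point.  Two map dialects exist:

wide
    ``x  y  <wavenumber> <wavenumber> ...`` — one row per map point.
long
    ``x  y  wavenumber  intensity`` — one row per (point, channel) pair.

Values are written with 9 significant digits, enough for a lossless-in-
practice round trip of float32-grade spectral data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .spectral_model import HyperMap, SpectralAxis

__all__ = [
    "ScalarMap",
    "MapFormatError",
    "read_map",
    "write_map",
    "select_region",
    "write_scalar_map",
    "read_scalar_map",
    "write_labels",
    "write_spectra",
]

_FMT = "%.9g"


class MapFormatError(ValueError):
    """Raised when a map file violates the expected dialect."""


@dataclass(eq=False)
class ScalarMap:
    """One real value per map point, e.g. a re-spatialized amplitude vector."""

    coords: np.ndarray  # (n_points, 2) x, y
    values: np.ndarray  # (n_points,)
    name: str = "value"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must have shape (n_points, 2)")
        if self.values.shape != (self.coords.shape[0],):
            raise ValueError("values must have one entry per point")

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScalarMap):
            return NotImplemented
        return (
            np.array_equal(self.coords, other.coords)
            and np.array_equal(self.values, other.values)
            and self.name == other.name
        )


# ---------------------------------------------------------------------------
# HyperMap I/O


def _sniff_dialect(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
    tokens = header.split("\t")
    if [t.strip().lower() for t in tokens] == ["x", "y", "wavenumber", "intensity"]:
        return "long"
    if len(tokens) >= 3 and [t.strip().lower() for t in tokens[:2]] == ["x", "y"]:
        try:
            [float(t) for t in tokens[2:]]
        except ValueError as exc:
            raise MapFormatError(
                f"{path}: header is neither wide (numeric wavenumbers) nor long"
            ) from exc
        return "wide"
    raise MapFormatError(f"{path}: unrecognized header {header!r}")


def read_map(path, dialect: str = "auto") -> HyperMap:
    """Read a spectral map from a wide or long TSV file.

    Points are canonicalized to row-major (y, x) order.  Duplicate points
    (or, in long form, duplicate (x, y, wavenumber) triples) are rejected.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = _sniff_dialect(path)
    elif dialect not in ("wide", "long"):
        raise ValueError(f"dialect must be wide, long or auto, got {dialect!r}")
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=float)
    except (ValueError, pd.errors.ParserError) as exc:
        raise MapFormatError(f"{path}: {exc}") from exc
    if df.isna().any(axis=None):
        bad = (df.index[df.isna().any(axis=1)] + 2).tolist()[:5]
        raise MapFormatError(f"{path}: missing/short fields at line(s) {bad}")

    if dialect == "long":
        expected = ["x", "y", "wavenumber", "intensity"]
        if [c.lower() for c in df.columns] != expected:
            raise MapFormatError(f"{path}: long dialect requires columns {expected}")
        df.columns = expected
        dup = df.duplicated(subset=["x", "y", "wavenumber"])
        if dup.any():
            lines = (df.index[dup] + 2).tolist()[:5]
            raise MapFormatError(
                f"{path}: duplicate (x, y, wavenumber) triples at line(s) {lines}"
            )
        wide = df.pivot(index=["y", "x"], columns="wavenumber", values="intensity")
        if wide.isna().any().any():
            raise MapFormatError(
                f"{path}: points do not share a common wavenumber axis"
            )
        axis = SpectralAxis(wide.columns.to_numpy(dtype=float))
        yx = np.asarray(wide.index.to_list(), dtype=float)
        coords = yx[:, ::-1]  # index is (y, x); canonical sort is built in
        return HyperMap(axis=axis, coords=coords, spectra=wide.to_numpy(dtype=float))

    if len(df.columns) < 4:
        raise MapFormatError(f"{path}: wide dialect needs x, y and >= 2 wavenumbers")
    try:
        wn = np.array([float(c) for c in df.columns[2:]])
    except ValueError as exc:
        raise MapFormatError(f"{path}: non-numeric wavenumber in header") from exc
    coords = df.iloc[:, :2].to_numpy(dtype=float)
    if len(np.unique(coords, axis=0)) != len(coords):
        raise MapFormatError(f"{path}: duplicate (x, y) points")
    hmap = HyperMap(
        axis=SpectralAxis(wn), coords=coords, spectra=df.iloc[:, 2:].to_numpy(dtype=float)
    )
    return hmap.canonicalized()


def write_map(hmap: HyperMap, path, dialect: str = "wide") -> None:
    """Write a spectral map as TSV; the output re-reads into an equal map."""
    path = Path(path)
    w = hmap.axis.wavenumbers
    try:
        with open(path, "w", encoding="utf-8") as fh:
            if dialect == "wide":
                header = "x\ty\t" + "\t".join(_FMT % v for v in w)
                fh.write(header + "\n")
                for (x, y), spec in zip(hmap.coords, hmap.spectra):
                    fh.write(
                        (_FMT % x) + "\t" + (_FMT % y) + "\t"
                        + "\t".join(_FMT % v for v in spec) + "\n"
                    )
            elif dialect == "long":
                fh.write("x\ty\twavenumber\tintensity\n")
                for (x, y), spec in zip(hmap.coords, hmap.spectra):
                    for wv, inten in zip(w, spec):
                        fh.write(
                            "\t".join(_FMT % v for v in (x, y, wv, inten)) + "\n"
                        )
            else:
                raise ValueError(f"dialect must be wide or long, got {dialect!r}")
    except OSError as exc:
        raise OSError(f"cannot write map to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# spectral-window selection and baseline subtraction


def select_region(
    hmap: HyperMap, wmin: float, wmax: float, baseline: str = "none"
) -> HyperMap:
    """Restrict the map to the wavenumber window [wmin, wmax].

    With ``baseline='linear'`` a straight line is subtracted from each
    spectrum; it passes through the mean of the first three and the mean of
    the last three in-window channels (3-channel end means damp noise better
    than single anchor channels).
    """
    if not (wmin < wmax):
        raise ValueError("wmin must be below wmax")
    if baseline not in ("none", "linear"):
        raise ValueError(f"baseline must be none or linear, got {baseline!r}")
    sel = hmap.axis.window(wmin, wmax)
    m = int(sel.sum())
    if m < 3:
        raise ValueError(f"window [{wmin}, {wmax}] contains {m} channels; need >= 3")
    w = hmap.axis.wavenumbers[sel]
    spectra = hmap.spectra[:, sel].copy()
    if baseline == "linear":
        x1, x2 = w[:3].mean(), w[-3:].mean()
        y1, y2 = spectra[:, :3].mean(axis=1), spectra[:, -3:].mean(axis=1)
        if x2 == x1:  # degenerate 3-channel window: flat baseline
            spectra -= y1[:, None]
        else:
            slope = (y2 - y1) / (x2 - x1)
            spectra -= y1[:, None] + slope[:, None] * (w - x1)[None, :]
    return HyperMap(
        axis=SpectralAxis(w), coords=hmap.coords.copy(), spectra=spectra,
        mask=hmap.mask.copy(),
    )


# ---------------------------------------------------------------------------
# auxiliary tables


def write_scalar_map(smap: ScalarMap, path) -> None:
    """Write ``x  y  <name>`` TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"x\ty\t{smap.name}\n")
        for (x, y), v in zip(smap.coords, smap.values):
            fh.write("\t".join(_FMT % u for u in (x, y, v)) + "\n")


def read_scalar_map(path) -> ScalarMap:
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] != 3:
        raise MapFormatError(f"{path}: scalar map needs exactly 3 columns")
    return ScalarMap(
        coords=df.iloc[:, :2].to_numpy(dtype=float),
        values=df.iloc[:, 2].to_numpy(dtype=float),
        name=str(df.columns[2]),
    )


def write_labels(coords: np.ndarray, labels: np.ndarray, path) -> None:
    """Write ``x  y  cluster`` TSV (excluded points carry label 0)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("x\ty\tcluster\n")
        for (x, y), lab in zip(coords, labels):
            fh.write((_FMT % x) + "\t" + (_FMT % y) + f"\t{int(lab)}\n")


def write_spectra(axis: SpectralAxis, spectra: np.ndarray, path, names=None) -> None:
    """Write ``wavenumber  <name1> <name2> ...`` TSV, one column per spectrum."""
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    if names is None:
        names = [f"spectrum{i + 1}" for i in range(spectra.shape[0])]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("wavenumber\t" + "\t".join(names) + "\n")
        for j, wv in enumerate(axis.wavenumbers):
            fh.write(
                (_FMT % wv) + "\t" + "\t".join(_FMT % s[j] for s in spectra) + "\n"
            )
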