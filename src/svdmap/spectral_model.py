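"""Synthetic Lorentzian spectral phantoms.

This module generates the model hyperspectral maps used to exercise and
validate the SVD-clustering pipeline.  Each map is an N x N pixel grid in
which every pixel carries a spectrum that is a weighted sum of two Lorentzian
bands ("spectrum-1" and "spectrum-2").  Three spatial arrangements are
provided:

``distinct``
    Each band lives on its own concentric circle, with a rectangular
    (all-or-nothing) radial profile: the two components are perfectly
    separated in space.
``overlapping``
    Same two circles, but the radial profiles are Lorentzian, so every pixel
    contains a mixture of both components.
``on_top``
    Both bands share a single circle with Lorentzian radial profiles;
    the minor band is additionally confined to an arc by a Lorentzian
    angular profile (half-width at half-maximum convention).

The default intensity ratio between the major and minor band is 100:1, which
makes the minor component invisible in any conventional (total-intensity)
image and is the regime in which factor-space imaging earns its keep.
White Gaussian noise can be injected at a level expressed as a percentage of
the map's maximum intensity.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SpectralAxis",
    "PeakSpec",
    "ModelSpec",
    "HyperMap",
    "MODEL_KINDS",
    "default_axis",
    "lorentzian",
    "radial_profile",
    "angular_profile",
    "concentration_fields",
    "build_model_map",
    "minor_component_mask",
    "add_white_noise",
]

MODEL_KINDS = ("distinct", "overlapping", "on_top")


def default_axis() -> "SpectralAxis":
    """Default wavenumber grid: 1400-2100 cm^-1 in 2 cm^-1 steps.

    Covers both default bands beyond twice their FWHM.
    """
    return SpectralAxis(np.arange(1400.0, 2100.0 + 1.0, 2.0))


@dataclass(frozen=True, eq=False)
class SpectralAxis:
    """A shared wavenumber grid (cm^-1), strictly increasing."""

    wavenumbers: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        if w.ndim != 1 or w.size < 2:
            raise ValueError("spectral axis needs at least 2 channels")
        if not np.all(np.isfinite(w)):
            raise ValueError("spectral axis contains non-finite values")
        if not np.all(np.diff(w) > 0):
            raise ValueError("spectral axis must be strictly increasing")
        object.__setattr__(self, "wavenumbers", w)

    def __len__(self) -> int:
        return self.wavenumbers.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralAxis):
            return NotImplemented
        return np.array_equal(self.wavenumbers, other.wavenumbers)

    def nearest_index(self, wavenumber: float) -> int:
        """Index of the channel closest to ``wavenumber``."""
        return int(np.argmin(np.abs(self.wavenumbers - wavenumber)))

    def window(self, wmin: float, wmax: float) -> np.ndarray:
        """Boolean channel mask for the closed interval [wmin, wmax]."""
        return (self.wavenumbers >= wmin) & (self.wavenumbers <= wmax)


@dataclass(frozen=True)
class PeakSpec:
    """One Lorentzian band: center and FWHM in cm^-1, dimensionless height."""

    center: float
    fwhm: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.center):
            raise ValueError("peak center must be finite")
        if not (self.fwhm > 0):
            raise ValueError("peak fwhm must be positive")
        if not (self.amplitude >= 0):
            raise ValueError("peak amplitude must be non-negative")


# Default bands: major at 1620 cm^-1 (FWHM 60), minor at 1850 cm^-1 (FWHM 40),
# heights 100:1 so the stated intensity ratio holds at the profile maxima.
DEFAULT_PEAK1 = PeakSpec(center=1620.0, fwhm=60.0, amplitude=100.0)
DEFAULT_PEAK2 = PeakSpec(center=1850.0, fwhm=40.0, amplitude=1.0)


@dataclass(frozen=True, eq=False)
class ModelSpec:
    """Full parameterization of one synthetic model map.

    Geometry is in pixel units on an N x N grid centered at the origin.
    ``radial_halfwidth_rect`` is the half-width of the all-or-nothing ring
    profile (distinct model); ``radial_fwhm_lorentz`` the FWHM of the
    Lorentzian ring profile (overlapping / on-top models).  The arc of the
    on-top model uses a Lorentzian angular profile with
    ``arc_halfwidth_deg`` as its half-width at half-maximum.
    """

    kind: str
    peak1: PeakSpec = DEFAULT_PEAK1
    peak2: PeakSpec = DEFAULT_PEAK2
    grid_size: int = 101
    circle1_radius: float = 30.0
    circle2_radius: float = 15.0
    radial_halfwidth_rect: float = 3.0
    radial_fwhm_lorentz: float = 6.0
    arc_center_deg: float = 0.0
    arc_halfwidth_deg: float = 20.0
    axis: SpectralAxis = field(default_factory=default_axis)

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"kind must be one of {MODEL_KINDS}, got {self.kind!r}")
        if self.grid_size < 8:
            raise ValueError("grid_size must be at least 8")
        if not (self.circle1_radius > 0 and self.circle2_radius > 0):
            raise ValueError("circle radii must be positive")
        if not (self.circle2_radius < self.circle1_radius):
            raise ValueError("circle2_radius must be smaller than circle1_radius")
        if not (self.radial_halfwidth_rect > 0 and self.radial_fwhm_lorentz > 0):
            raise ValueError("radial profile widths must be positive")
        if not (0 < self.arc_halfwidth_deg < 180):
            raise ValueError("arc_halfwidth_deg must lie in (0, 180)")

    # -- flat key=value serialization ------------------------------------

    def to_config(self) -> str:
        """Serialize to a flat key=value text block (one key per line)."""
        lines = [f"kind={self.kind}"]
        for i, pk in ((1, self.peak1), (2, self.peak2)):
            lines += [
                f"peak{i}_center={float(pk.center)!r}",
                f"peak{i}_fwhm={float(pk.fwhm)!r}",
                f"peak{i}_amplitude={float(pk.amplitude)!r}",
            ]
        lines.append(f"grid_size={int(self.grid_size)}")
        for key in (
            "circle1_radius",
            "circle2_radius",
            "radial_halfwidth_rect",
            "radial_fwhm_lorentz",
            "arc_center_deg",
            "arc_halfwidth_deg",
        ):
            lines.append(f"{key}={float(getattr(self, key))!r}")
        w = self.axis.wavenumbers
        step = np.diff(w)
        if np.allclose(step, step[0]):
            lines.append(f"axis={float(w[0])!r}:{float(w[-1])!r}:{float(step[0])!r}")
        else:
            lines.append("axis=" + ",".join(repr(float(v)) for v in w))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config(cls, text: str) -> "ModelSpec":
        """Parse the flat key=value form produced by :meth:`to_config`."""
        kv: dict[str, str] = {}
        for ln, raw in enumerate(io.StringIO(text), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"config line {ln}: expected key=value, got {line!r}")
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
        axis_str = kv.pop("axis", None)
        if axis_str is None:
            axis = default_axis()
        elif ":" in axis_str:
            lo, hi, step = (float(v) for v in axis_str.split(":"))
            axis = SpectralAxis(np.arange(lo, hi + step / 2, step))
        else:
            axis = SpectralAxis(np.array([float(v) for v in axis_str.split(",")]))
        peaks = {}
        for i in (1, 2):
            peaks[f"peak{i}"] = PeakSpec(
                center=float(kv.pop(f"peak{i}_center")),
                fwhm=float(kv.pop(f"peak{i}_fwhm")),
                amplitude=float(kv.pop(f"peak{i}_amplitude")),
            )
        kind = kv.pop("kind")
        numeric = {k: (int(v) if k == "grid_size" else float(v)) for k, v in kv.items()}
        return cls(kind=kind, axis=axis, **peaks, **numeric)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ModelSpec):
            return NotImplemented
        return self.to_config() == other.to_config()


@dataclass(eq=False)
class HyperMap:
    """A spatial grid of spectra: one (x, y) point per row of ``spectra``.

    Points are kept in canonical row-major order (sorted by y, then x) so
    that amplitude vectors derived from the map are comparable across runs.
    ``mask`` flags points excluded from analysis (e.g. outliers); it is all
    False for a freshly generated map.
    """

    axis: SpectralAxis
    coords: np.ndarray  # (n_points, 2) float, columns x, y
    spectra: np.ndarray  # (n_points, n_channels) float
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.spectra = np.asarray(self.spectra, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must have shape (n_points, 2)")
        if self.spectra.ndim != 2:
            raise ValueError("spectra must be a 2-D matrix")
        if self.spectra.shape[0] != self.coords.shape[0]:
            raise ValueError("coords and spectra disagree on the number of points")
        if self.spectra.shape[1] != len(self.axis):
            raise ValueError("spectra and axis disagree on the number of channels")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates contain non-finite values")
        if not np.all(np.isfinite(self.spectra)):
            raise ValueError("spectra contain non-finite values")
        if len(np.unique(self.coords, axis=0)) != self.coords.shape[0]:
            raise ValueError("duplicate (x, y) coordinates")
        if self.mask is None:
            self.mask = np.zeros(self.n_points, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (self.n_points,):
                raise ValueError("mask must have one flag per point")

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    @property
    def n_channels(self) -> int:
        return self.spectra.shape[1]

    def canonicalized(self) -> "HyperMap":
        """Return a copy with points sorted row-major by (y, x)."""
        order = np.lexsort((self.coords[:, 0], self.coords[:, 1]))
        return HyperMap(
            axis=self.axis,
            coords=self.coords[order],
            spectra=self.spectra[order],
            mask=self.mask[order],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HyperMap):
            return NotImplemented
        return (
            self.axis == other.axis
            and np.array_equal(self.coords, other.coords)
            and np.array_equal(self.spectra, other.spectra)
            and np.array_equal(self.mask, other.mask)
        )


# ---------------------------------------------------------------------------
# profiles


def lorentzian(axis: SpectralAxis, peak: PeakSpec) -> np.ndarray:
    """Lorentzian band evaluated on the axis.

    The form is ``A / (1 + (2 (k - k0) / gamma)^2)`` with ``gamma`` the full
    width at half maximum: the value is A at the center and A/2 at
    ``center +/- fwhm/2``.
    """
    k = axis.wavenumbers
    u = 2.0 * (k - peak.center) / peak.fwhm
    return peak.amplitude / (1.0 + u * u)


def radial_profile(distance: np.ndarray | float, profile: str, width: float):
    """Ring cross-section as a function of signed distance from the circle.

    ``rect``: 1 inside ``|distance| <= width`` (width is a half-width), else 0.
    ``lorentz``: Lorentzian with ``width`` as its FWHM.
    """
    if not (width > 0):
        raise ValueError("width must be positive")
    d = np.asarray(distance, dtype=float)
    if profile == "rect":
        out = (np.abs(d) <= width).astype(float)
    elif profile == "lorentz":
        u = 2.0 * d / width
        out = 1.0 / (1.0 + u * u)
    else:
        raise ValueError(f"unknown radial profile {profile!r}")
    return out if out.ndim else float(out)


def angular_profile(angle_deg, center_deg: float, halfwidth_deg: float):
    """Lorentzian arc profile in the wrapped angular difference.

    ``halfwidth_deg`` follows the half-width-at-half-maximum convention:
    the profile is 1 at the arc center and 0.5 at ``center +/- halfwidth``.
    Input angles are wrapped into (-180, 180] before evaluation.
    """
    if not (halfwidth_deg > 0):
        raise ValueError("halfwidth_deg must be positive")
    delta = (np.asarray(angle_deg, dtype=float) - center_deg + 180.0) % 360.0 - 180.0
    out = 1.0 / (1.0 + (delta / halfwidth_deg) ** 2)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# map construction


def _grid_coords(grid_size: int) -> np.ndarray:
    """(x, y) pixel coordinates of an N x N grid centered at the origin,
    in canonical row-major (y, x) order."""
    half = (grid_size - 1) / 2.0
    axis1d = np.arange(grid_size, dtype=float) - half
    X, Y = np.meshgrid(axis1d, axis1d)  # Y varies along rows -> row-major (y, x)
    return np.column_stack([X.ravel(), Y.ravel()])


def concentration_fields(spec: ModelSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-point weights (c1, c2) of the two component spectra, in [0, 1]."""
    coords = _grid_coords(spec.grid_size)
    r = np.hypot(coords[:, 0], coords[:, 1])
    if spec.kind == "distinct":
        c1 = radial_profile(r - spec.circle1_radius, "rect", spec.radial_halfwidth_rect)
        c2 = radial_profile(r - spec.circle2_radius, "rect", spec.radial_halfwidth_rect)
    elif spec.kind == "overlapping":
        c1 = radial_profile(r - spec.circle1_radius, "lorentz", spec.radial_fwhm_lorentz)
        c2 = radial_profile(r - spec.circle2_radius, "lorentz", spec.radial_fwhm_lorentz)
    else:  # on_top: both components ride circle-1, minor confined to an arc
        ring = radial_profile(r - spec.circle1_radius, "lorentz", spec.radial_fwhm_lorentz)
        theta = np.degrees(np.arctan2(coords[:, 1], coords[:, 0]))
        c1 = ring
        c2 = ring * angular_profile(theta, spec.arc_center_deg, spec.arc_halfwidth_deg)
    return c1, c2


def build_model_map(spec: ModelSpec) -> HyperMap:
    """Deterministically build the noiseless model map for ``spec``.

    Every point's spectrum is ``c1(x, y) * L1 + c2(x, y) * L2`` where L1, L2
    are the two Lorentzian bands (amplitudes included) and c1, c2 the
    geometry-dependent concentration fields.
    """
    w = spec.axis.wavenumbers
    for name, pk in (("peak1", spec.peak1), ("peak2", spec.peak2)):
        if pk.center - 2 * pk.fwhm < w[0] or pk.center + 2 * pk.fwhm > w[-1]:
            warnings.warn(
                f"spectral axis truncates {name} (center {pk.center}, fwhm {pk.fwhm})",
                stacklevel=2,
            )
    c1, c2 = concentration_fields(spec)
    spectra = np.outer(c1, lorentzian(spec.axis, spec.peak1)) + np.outer(
        c2, lorentzian(spec.axis, spec.peak2)
    )
    return HyperMap(axis=spec.axis, coords=_grid_coords(spec.grid_size), spectra=spectra)


def minor_component_mask(spec: ModelSpec) -> np.ndarray:
    """Boolean ground-truth support of the minor component, per map point.

    Rectangular profiles use their exact support; Lorentzian profiles are cut
    at half maximum (so the mask is the HWHM support of the minor field).
    """
    coords = _grid_coords(spec.grid_size)
    r = np.hypot(coords[:, 0], coords[:, 1])
    if spec.kind == "distinct":
        return radial_profile(r - spec.circle2_radius, "rect", spec.radial_halfwidth_rect) > 0
    if spec.kind == "overlapping":
        return (
            radial_profile(r - spec.circle2_radius, "lorentz", spec.radial_fwhm_lorentz) >= 0.5
        )
    ring = radial_profile(r - spec.circle1_radius, "lorentz", spec.radial_fwhm_lorentz)
    theta = np.degrees(np.arctan2(coords[:, 1], coords[:, 0]))
    ang = angular_profile(theta, spec.arc_center_deg, spec.arc_halfwidth_deg)
    return (ring >= 0.5) & (ang >= 0.5)


def add_white_noise(hmap: HyperMap, percent: float, seed: int) -> HyperMap:
    """Add i.i.d. Gaussian noise to every channel of every point.

    The noise standard deviation is ``percent/100`` of the global maximum
    intensity of the input map (the maximum of the major band for the model
    maps).  ``percent=0`` returns the input unchanged.
    """
    if percent < 0:
        raise ValueError("noise percent must be non-negative")
    if percent == 0:
        return hmap
    sigma = (percent / 100.0) * float(np.max(hmap.spectra))
    rng = np.random.default_rng(seed)
    noisy = hmap.spectra + rng.normal(0.0, sigma, size=hmap.spectra.shape)
    return replace(hmap, spectra=noisy, mask=hmap.mask.copy())
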