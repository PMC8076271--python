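"""Amide I spectral preprocessing and second-derivative band picking.

The preprocessing chain mirrors standard protein-FTIR practice: baseline
correction (rubberband, i.e. lower convex hull, or a linear chord),
normalization to the Amide I maximum, and a Savitzky-Golay second
derivative (DII) over 1580-1720 cm^-1.  Overlapping component bands that
merge in the absorbance trace appear as separate local minima in DII, so
band picking reduces to prominence-filtered minima detection, with known
aromatic side-chain positions (Phe 1600, Tyr 1616, Trp 1620 cm^-1)
excluded when the peptide sequence contains the residue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, savgol_filter
from scipy.spatial import ConvexHull, QhullError

from .bands import BandAnnotation

__all__ = [
    "Spectrum",
    "DerivativeSpectrum",
    "AROMATIC_BAND_POSITIONS",
    "ANALYSIS_WINDOW",
    "read_spectrum",
    "write_spectrum",
    "average_spectra",
    "baseline_correct",
    "normalize_amide_one",
    "second_derivative",
    "pick_bands",
]

#: DII analysis window, cm^-1.
ANALYSIS_WINDOW = (1580.0, 1720.0)

#: Amide I normalization / dominant-band search window, cm^-1.
AMIDE_I_WINDOW = (1600.0, 1700.0)

#: Side-chain ring vibrations excluded from band assignment when the
#: corresponding residue is present in the sequence.
AROMATIC_BAND_POSITIONS = {"F": 1600.0, "Y": 1616.0, "W": 1620.0}

#: Exclusion half-width around an aromatic position, cm^-1.
AROMATIC_TOLERANCE = 3.0


@dataclass(frozen=True)
class Spectrum:
    """A single IR trace: wavenumber grid (cm^-1, ascending) + absorbance."""

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    mode: str = "synthetic"  # "atr_ftir" | "ir_microscopy" | "synthetic"

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if w.ndim != 1 or a.shape != w.shape:
            raise ValueError("wavenumbers and absorbance must be 1-D arrays of equal length")
        if w.size < 3:
            raise ValueError("spectrum needs at least 3 points")
        if not np.all(np.diff(w) > 0):
            raise ValueError("wavenumber grid must be strictly ascending")
        if not (np.all(np.isfinite(w)) and np.all(np.isfinite(a))):
            raise ValueError("spectrum contains non-finite values")
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "absorbance", a)

    def replace_absorbance(self, absorbance: np.ndarray) -> "Spectrum":
        return Spectrum(self.wavenumbers, absorbance, self.mode)


@dataclass(frozen=True)
class DerivativeSpectrum:
    """Second derivative of a spectrum, restricted to the analysis window."""

    wavenumbers: np.ndarray
    dii: np.ndarray
    source_mode: str = "synthetic"

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        d = np.asarray(self.dii, dtype=float)
        if w.shape != d.shape or w.ndim != 1:
            raise ValueError("wavenumbers and dii must be 1-D arrays of equal length")
        lo, hi = ANALYSIS_WINDOW
        if w.size and (w[0] < lo - 1e-9 or w[-1] > hi + 1e-9):
            raise ValueError(f"derivative spectrum must lie within [{lo}, {hi}] cm^-1")
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "dii", d)


def read_spectrum(source, mode: str = "synthetic") -> Spectrum:
    """Read a two-column (wavenumber, absorbance) text file.

    Accepts whitespace- or comma-delimited columns, ``#`` comments, and
    either grid direction (descending instruments are flipped to ascending).
    """
    with open(source) as fh:
        text = fh.read()
    delimiter = "," if ("," in text.splitlines()[0] if text.splitlines() else False) else None
    for line in text.splitlines():
        line = line.split("#")[0].strip()
        if line:
            delimiter = "," if "," in line else None
            break
    data = np.genfromtxt(text.splitlines(), delimiter=delimiter, comments="#")
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{source}: expected two columns (wavenumber, absorbance)")
    w, a = data[:, 0], data[:, 1]
    if w[0] > w[-1]:
        w, a = w[::-1], a[::-1]
    return Spectrum(w, a, mode)


def write_spectrum(spectrum: Spectrum, destination) -> None:
    """Write a spectrum as two-column whitespace-delimited text."""
    np.savetxt(
        destination,
        np.column_stack([spectrum.wavenumbers, spectrum.absorbance]),
        fmt="%.4f %.6e",
        header="wavenumber_cm-1 absorbance",
    )


def average_spectra(spectra: list[Spectrum]) -> Spectrum:
    """Arithmetic mean of traces sharing one grid (e.g. a spectral map)."""
    if not spectra:
        raise ValueError("no spectra to average")
    grid = spectra[0].wavenumbers
    for s in spectra[1:]:
        if not np.array_equal(s.wavenumbers, grid):
            raise ValueError("spectra must share a common wavenumber grid")
    mean = np.mean([s.absorbance for s in spectra], axis=0)
    return Spectrum(grid, mean, spectra[0].mode)


def _rubberband_baseline(w: np.ndarray, a: np.ndarray) -> np.ndarray:
    points = np.column_stack([w, a])
    try:
        hull = ConvexHull(points)
    except QhullError:  # collinear trace: chord is exact
        return np.interp(w, [w[0], w[-1]], [a[0], a[-1]])
    v = hull.vertices  # counterclockwise
    v = np.roll(v, -int(np.argmin(points[v, 0])))
    right = int(np.argmax(points[v, 0]))
    lower = v[: right + 1]
    return np.interp(w, points[lower, 0], points[lower, 1])


def baseline_correct(spectrum: Spectrum, method: str = "rubberband") -> Spectrum:
    """Subtract the baseline estimate from the absorbance trace.

    ``rubberband`` subtracts the lower convex hull of the (wavenumber,
    absorbance) point set; ``linear`` subtracts the chord between the first
    and last points of the trace.
    """
    w, a = spectrum.wavenumbers, spectrum.absorbance
    if method == "rubberband":
        baseline = _rubberband_baseline(w, a)
    elif method == "linear":
        baseline = np.interp(w, [w[0], w[-1]], [a[0], a[-1]])
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    return spectrum.replace_absorbance(a - baseline)


def normalize_amide_one(spectrum: Spectrum) -> Spectrum:
    """Scale the trace so the Amide I maximum (1600-1700 cm^-1) equals 1.

    Raises
    ------
    ValueError
        If the maximum over the window is not positive (empty or negative
        trace), or the grid does not cover the window.
    """
    lo, hi = AMIDE_I_WINDOW
    mask = (spectrum.wavenumbers >= lo) & (spectrum.wavenumbers <= hi)
    if not mask.any():
        raise ValueError("grid does not cover the Amide I window")
    peak = float(spectrum.absorbance[mask].max())
    if peak <= 0:
        raise ValueError("non-positive Amide I maximum; cannot normalize")
    return spectrum.replace_absorbance(spectrum.absorbance / peak)


def second_derivative(
    spectrum: Spectrum,
    window_pts: int = 31,
    polyorder: int = 2,
    method: str = "single_pass",
) -> DerivativeSpectrum:
    """Savitzky-Golay second derivative on the 1580-1720 cm^-1 window.

    ``single_pass`` (default) evaluates the second derivative of the local
    polynomial fit directly; ``two_step`` first takes a finite-difference
    second derivative and then smooths it with a zeroth-order SG pass of
    the same window.  Both use ``polyorder`` 2 and a 31-point window by
    default (the nearest odd width to a nominal 30).

    Raises
    ------
    ValueError
        If ``window_pts`` is even, not greater than ``polyorder``, or
        exceeds the number of points in the window.
    """
    if window_pts % 2 == 0 or window_pts <= polyorder:
        raise ValueError("window_pts must be odd and greater than polyorder")
    lo, hi = ANALYSIS_WINDOW
    mask = (spectrum.wavenumbers >= lo) & (spectrum.wavenumbers <= hi)
    w = spectrum.wavenumbers[mask]
    a = spectrum.absorbance[mask]
    if w.size < window_pts:
        raise ValueError(
            f"window_pts={window_pts} exceeds the {w.size} points available in "
            f"[{lo}, {hi}] cm^-1"
        )
    steps = np.diff(w)
    if np.ptp(steps) > 1e-6 * steps.mean():
        raise ValueError("second_derivative requires a uniform wavenumber grid")
    delta = float(steps.mean())
    if method == "single_pass":
        dii = savgol_filter(a, window_pts, polyorder, deriv=2, delta=delta)
    elif method == "two_step":
        raw = np.gradient(np.gradient(a, w), w)
        dii = savgol_filter(raw, window_pts, polyorder)
    else:
        raise ValueError(f"unknown derivative method {method!r}")
    return DerivativeSpectrum(w, dii, spectrum.mode)


def pick_bands(
    dii: DerivativeSpectrum,
    sequence: str = "",
    prominence: float = 0.05,
) -> list[BandAnnotation]:
    """Pick component bands as prominence-filtered local minima of DII.

    ``prominence`` is relative: a minimum survives if its prominence in
    ``-DII`` exceeds ``prominence`` times the deepest excursion.  Minima
    within +-3 cm^-1 of the Phe/Tyr/Trp side-chain positions are discarded
    when the sequence contains the residue.  The surviving minimum with the
    deepest DII value inside 1600-1700 cm^-1 is marked dominant; intensity
    grades are assigned from relative depth (s >= 0.6 x max depth,
    m >= 0.25, else w).  Shape flags (broad/shoulder) are an expert-reading
    convention and are not emitted.

    Raises
    ------
    ValueError
        If no minima survive (featureless spectrum).
    """
    w, d = dii.wavenumbers, dii.dii
    depth = -d
    scale = float(depth.max())
    if scale <= 0:
        raise ValueError("featureless spectrum: DII has no negative excursion")
    idx, _ = find_peaks(depth, prominence=prominence * scale)
    keep = []
    for i in idx:
        excluded = any(
            res in sequence and abs(w[i] - pos) <= AROMATIC_TOLERANCE
            for res, pos in AROMATIC_BAND_POSITIONS.items()
        )
        if not excluded:
            keep.append(i)
    if not keep:
        raise ValueError("no component bands survive prominence and aromatic filtering")
    keep = np.asarray(keep)
    lo, hi = AMIDE_I_WINDOW
    in_amide = keep[(w[keep] >= lo) & (w[keep] <= hi)]
    dom_pool = in_amide if in_amide.size else keep
    dom_idx = int(dom_pool[np.argmax(depth[dom_pool])])
    max_depth = float(depth[keep].max())
    bands = []
    for i in sorted(keep, key=lambda i: -w[i]):  # high-to-low, as band lists are printed
        rel = depth[i] / max_depth
        grade = "s" if rel >= 0.6 else "m" if rel >= 0.25 else "w"
        bands.append(
            BandAnnotation(
                position=int(round(w[i])),
                intensity_grade=grade,
                is_dominant=(i == dom_idx),
            )
        )
    return bands
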