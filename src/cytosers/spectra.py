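"""SERS spectral pipeline for cytochrome c redox analysis.

Implements the band library for mitochondrial / purified cytochrome c SERS
spectra (oxidized vs dithionite-reduced), a synthetic-spectrum generator
(Lorentzian bands + spline baseline + Gaussian noise), knot-based spline
baseline subtraction, max-in-window peak metrics, the I748/I1638,
I1170/I1638, I1371/I1638 band ratios, percent-of-control treatment
statistics, and a two-end-member redox-state classifier.

Band *positions* are the published assignments; band widths and relative
amplitudes are package fixture constants chosen so the noiseless oxidized
spectrum has the qualitative intensity ordering of recorded mitochondrial
SERS traces (strong 748 / 1371 / 1585 / 1638).  They are deliberately
editable module constants, not measured values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import CubicSpline
from scipy.optimize import nnls

from .exceptions import InvalidInputError, SpectrumError, UndefinedRatioError

__all__ = [
    "RamanBand",
    "BandLibrary",
    "SpectrumTrace",
    "BaselineKnots",
    "RatioReport",
    "RedoxCall",
    "band_library",
    "synthesize_spectrum",
    "mixture_spectrum",
    "subtract_baseline",
    "default_knots",
    "peak_maximum",
    "peak_ratios",
    "percent_of_control",
    "classify_redox",
    "treatment_series",
    "read_spectrum",
    "write_spectrum",
    "read_jcamp",
]

#: default Lorentzian full width at half maximum, cm^-1 (fixture constant)
DEFAULT_FWHM = 12.0
#: default half-window for max-in-window peak metrics, cm^-1
DEFAULT_HALF_WINDOW = 15.0
#: default wavenumber axis: (min, max, step) cm^-1
DEFAULT_AXIS = (600.0, 1800.0, 1.0)


@dataclass(frozen=True)
class RamanBand:
    """One parametric Raman band (Lorentzian)."""

    center: float  # cm^-1
    fwhm: float = DEFAULT_FWHM
    relative_amplitude: float = 1.0
    assignment: str = ""
    redox_sensitive: bool = False

    def __post_init__(self):
        if self.center <= 0 or self.fwhm <= 0 or self.relative_amplitude < 0:
            raise InvalidInputError("band requires center > 0, fwhm > 0, amplitude >= 0")


def _bands(rows) -> tuple:
    return tuple(
        RamanBand(center=c, relative_amplitude=a, assignment=s, redox_sensitive=r)
        for (c, a, s, r) in rows
    )


# (center cm^-1, relative amplitude, assignment, redox sensitive)
# Centers follow the published assignment table; amplitudes are fixtures.
_MITO_OXIDIZED = _bands([
    (748.0, 0.80, "nu15 B1g, heme breathing", True),
    (1127.0, 0.35, "nu5 B1g, Cb-CH3", False),
    (1170.0, 0.45, "nu30 B2g, asym pyrrole half-ring", True),
    (1313.0, 0.50, "all heme-c bonds", True),
    (1371.0, 0.90, "nu4 A1g, sym pyrrole half-ring", True),
    (1403.0, 0.25, "B2g, CaCb/CbC1", True),
    (1565.0, 0.45, "B1g, CaCm/CaCb/CaN", True),
    (1585.0, 0.70, "A2g, CaCm/CaCmH/CaCb", False),
    (1638.0, 0.80, "nu10 B1g, CaCm/CaCmH/CaCb", False),
])
_MITO_REDUCED = _bands([
    (690.0, 0.25, "reduced-state marker", True),
    (748.0, 1.30, "nu15 B1g, heme breathing", True),
    (1127.0, 0.35, "nu5 B1g, Cb-CH3", False),
    (1170.0, 0.45, "nu30 B2g, asym pyrrole half-ring", True),
    (1311.0, 0.55, "all heme-c bonds", True),
    (1356.0, 1.00, "nu4 A1g, sym pyrrole half-ring", True),
    (1396.0, 0.30, "B2g, CaCb/CbC1", True),
    (1545.0, 0.80, "A2g, CaCm/CaCmH/CaCb", False),
    (1605.0, 0.70, "nu10 B1g, CaCm/CaCmH/CaCb", False),
])
_CYT_OXIDIZED = _bands([
    (758.0, 0.85, "nu15 B1g, heme breathing", True),
    (1130.0, 0.35, "nu5 B1g, Cb-CH3", False),
    (1172.0, 0.45, "nu30 B2g, asym pyrrole half-ring", True),
    (1317.0, 0.45, "all heme-c bonds", True),
    (1373.0, 0.90, "nu4 A1g, sym pyrrole half-ring", True),
    (1403.0, 0.25, "B2g, CaCb/CbC1", True),
    (1569.0, 0.50, "B1g, CaCm/CaCb/CaN", True),
    (1638.0, 0.80, "nu10 B1g, CaCm/CaCmH/CaCb", False),
])
_CYT_REDUCED = _bands([
    (690.0, 0.25, "reduced-state marker", True),
    (758.0, 1.30, "nu15 B1g, heme breathing", True),
    (1130.0, 0.35, "nu5 B1g, Cb-CH3", False),
    (1172.0, 0.45, "nu30 B2g, asym pyrrole half-ring", True),
    (1316.0, 0.50, "all heme-c bonds", True),
    (1363.0, 1.00, "nu4 A1g, sym pyrrole half-ring", True),
    (1400.0, 0.30, "B2g, CaCb/CbC1", True),
    (1549.0, 0.80, "A2g, CaCm/CaCmH/CaCb", False),
    (1608.0, 0.70, "nu10 B1g, CaCm/CaCmH/CaCb", False),
])

#: window centers used for the three ratios, per redox state
RATIO_CENTERS = {
    "oxidized": {"r748": 748.0, "r1170": 1170.0, "r1371": 1371.0, "denominator": 1638.0},
    "reduced": {"r748": 748.0, "r1170": 1170.0, "r1371": 1356.0, "denominator": 1605.0},
}


@dataclass(frozen=True)
class BandLibrary:
    """Four named band sets: mitochondria and isolated cytochrome c, ox/red."""

    mitochondria_oxidized: tuple = _MITO_OXIDIZED
    mitochondria_reduced: tuple = _MITO_REDUCED
    cytochrome_oxidized: tuple = _CYT_OXIDIZED
    cytochrome_reduced: tuple = _CYT_REDUCED

    def get(self, which: str, state: str) -> tuple:
        key = {"mitochondria": "mitochondria", "isolated": "cytochrome"}.get(which)
        if key is None or state not in ("oxidized", "reduced"):
            raise InvalidInputError(
                "which must be 'mitochondria'/'isolated', state 'oxidized'/'reduced'"
            )
        return getattr(self, f"{key}_{state}")

    def to_dict(self) -> dict:
        out = {}
        for name in (
            "mitochondria_oxidized", "mitochondria_reduced",
            "cytochrome_oxidized", "cytochrome_reduced",
        ):
            out[name] = [
                {
                    "center": b.center,
                    "fwhm": b.fwhm,
                    "relative_amplitude": b.relative_amplitude,
                    "assignment": b.assignment,
                    "redox_sensitive": b.redox_sensitive,
                }
                for b in getattr(self, name)
            ]
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "BandLibrary":
        kwargs = {}
        for name, rows in data.items():
            kwargs[name] = tuple(RamanBand(**row) for row in rows)
        return cls(**kwargs)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "BandLibrary":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def band_library() -> BandLibrary:
    """The default band library (published positions, fixture amplitudes)."""
    return BandLibrary()


@dataclass(frozen=True)
class SpectrumTrace:
    """Wavenumber-indexed spectrum on a uniform, strictly increasing axis."""

    wavenumber: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        wn = np.asarray(self.wavenumber, dtype=float)
        it = np.asarray(self.intensity, dtype=float)
        if wn.ndim != 1 or wn.shape != it.shape:
            raise SpectrumError("axis and intensity must be 1-D arrays of equal length")
        steps = np.diff(wn)
        if len(steps) == 0 or np.any(steps <= 0):
            raise SpectrumError("wavenumber axis must be strictly increasing")
        if np.ptp(steps) > 1e-6 * steps[0]:
            raise SpectrumError("wavenumber axis must have a uniform step")
        object.__setattr__(self, "wavenumber", wn)
        object.__setattr__(self, "intensity", it)

    @property
    def step(self) -> float:
        return float(self.wavenumber[1] - self.wavenumber[0])


@dataclass(frozen=True)
class BaselineKnots:
    """Knot x-positions plus the neighborhood half-width for knot ordinates.

    ``half_width`` counts axis points on each side of the nearest sample;
    the default 2 gives the 5-point neighborhood average.  ``half_width=0``
    interpolates raw samples, making the operator exact on cubic baselines.
    """

    positions: tuple
    half_width: int = 2

    def __post_init__(self):
        if len(self.positions) < 4:
            raise SpectrumError("cubic spline baseline needs >= 4 knots")
        if self.half_width < 0:
            raise SpectrumError("half_width must be >= 0")
        object.__setattr__(self, "positions", tuple(float(x) for x in self.positions))


#: default knot positions, chosen inside band-free windows of the
#: cytochrome spectrum: <640, 800-1100, 1200-1290, 1420-1520, >1660 cm^-1
DEFAULT_KNOT_POSITIONS = (
    610.0, 635.0, 820.0, 910.0, 1000.0, 1090.0,
    1215.0, 1280.0, 1430.0, 1510.0, 1680.0, 1780.0,
)


def default_knots(axis_min: float = DEFAULT_AXIS[0],
                  axis_max: float = DEFAULT_AXIS[1]) -> BaselineKnots:
    """The 12 default knots restricted to the given axis range."""
    pos = tuple(x for x in DEFAULT_KNOT_POSITIONS if axis_min <= x <= axis_max)
    return BaselineKnots(positions=pos)


def _lorentzian_sum(bands, x: np.ndarray) -> np.ndarray:
    y = np.zeros_like(x)
    for b in bands:
        hw2 = (b.fwhm / 2.0) ** 2
        y += b.relative_amplitude * hw2 / ((x - b.center) ** 2 + hw2)
    return y


def _make_axis(axis) -> np.ndarray:
    lo, hi, step = (float(v) for v in axis)
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def _baseline_curve(x: np.ndarray, baseline_knot_values) -> np.ndarray:
    if baseline_knot_values is None:
        return np.zeros_like(x)
    kx, ky = baseline_knot_values
    kx = np.asarray(kx, dtype=float)
    ky = np.asarray(ky, dtype=float)
    if len(kx) < 4:
        raise SpectrumError("baseline needs >= 4 knot values for a cubic spline")
    return CubicSpline(kx, ky)(x)


def synthesize_spectrum(bands, axis=DEFAULT_AXIS, baseline_knot_values=None,
                        noise_sd: float = 0.0, seed: int = 0,
                        metadata: dict = None) -> SpectrumTrace:
    """Sum of Lorentzian bands + spline baseline + i.i.d. Gaussian noise.

    ``baseline_knot_values`` is a (knot_x, knot_y) pair defining a cubic
    spline background, or None for a flat zero baseline.  Identical seed ->
    identical trace.
    """
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be >= 0")
    x = _make_axis(axis)
    for b in bands:
        if not x[0] <= b.center <= x[-1]:
            raise SpectrumError(f"band center {b.center} cm^-1 outside axis")
    y = _lorentzian_sum(bands, x)
    y = y + _baseline_curve(x, baseline_knot_values)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=x.shape)
    md = {"generator": "synthesize_spectrum", "noise_sd": noise_sd, "seed": seed}
    if metadata:
        md.update(metadata)
    return SpectrumTrace(wavenumber=x, intensity=y, metadata=md)


def mixture_spectrum(f_red: float, library: BandLibrary = None,
                     which: str = "mitochondria", axis=DEFAULT_AXIS,
                     baseline_knot_values=None, noise_sd: float = 0.0,
                     seed: int = 0) -> SpectrumTrace:
    """Two-state redox mixture f_red * S_red + (1 - f_red) * S_ox (+ baseline, noise).

    Emulates a cytochrome pool in a partially reduced steady state.
    """
    if not 0.0 <= f_red <= 1.0:
        raise InvalidInputError("f_red must lie in [0, 1]")
    lib = library or band_library()
    x = _make_axis(axis)
    y = (1.0 - f_red) * _lorentzian_sum(lib.get(which, "oxidized"), x)
    y = y + f_red * _lorentzian_sum(lib.get(which, "reduced"), x)
    y = y + _baseline_curve(x, baseline_knot_values)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=x.shape)
    md = {
        "generator": "mixture_spectrum", "f_red": f_red, "which": which,
        "noise_sd": noise_sd, "seed": seed,
    }
    return SpectrumTrace(wavenumber=x, intensity=y, metadata=md)


def subtract_baseline(trace: SpectrumTrace, knots: BaselineKnots = None) -> SpectrumTrace:
    """Subtract a cubic spline through neighborhood-averaged knot ordinates.

    Knot ordinates are means of the (2 * half_width + 1) samples nearest each
    knot x-position (5 samples by default); the same knot x-positions can be
    reused across a whole spectrum set.
    """
    if knots is None:
        knots = default_knots(trace.wavenumber[0], trace.wavenumber[-1])
    x, y = trace.wavenumber, trace.intensity
    kx = np.asarray(knots.positions)
    if np.any(kx < x[0]) or np.any(kx > x[-1]):
        raise SpectrumError("baseline knots must lie inside the wavenumber axis")
    ky = np.empty_like(kx)
    for j, xk in enumerate(kx):
        i = int(np.argmin(np.abs(x - xk)))
        lo = max(0, i - knots.half_width)
        hi = min(len(x), i + knots.half_width + 1)
        ky[j] = float(np.mean(y[lo:hi]))
    baseline = CubicSpline(kx, ky)(x)
    md = dict(trace.metadata)
    md["baseline_knots"] = tuple(kx)
    md["baseline_half_width"] = knots.half_width
    return SpectrumTrace(wavenumber=x, intensity=y - baseline, metadata=md)


def peak_maximum(trace: SpectrumTrace, center: float,
                 half_window: float = DEFAULT_HALF_WINDOW):
    """(argmax position, max intensity) within [center - hw, center + hw].

    Ties break toward the lower wavenumber.
    """
    x, y = trace.wavenumber, trace.intensity
    sel = (x >= center - half_window) & (x <= center + half_window)
    if not sel.any():
        raise SpectrumError(f"empty peak window around {center} cm^-1")
    xs, ys = x[sel], y[sel]
    i = int(np.argmax(ys))  # first occurrence = lowest wavenumber on ties
    return float(xs[i]), float(ys[i])


@dataclass(frozen=True)
class RatioReport:
    """The three band-intensity ratios, normalized to the nu10 marker peak."""

    r748: float
    r1170: float
    r1371: float
    centers: dict = field(default_factory=dict)


def peak_ratios(trace: SpectrumTrace, state: str = "oxidized",
                half_window: float = DEFAULT_HALF_WINDOW) -> RatioReport:
    """I748/I1638-type ratios from max-in-window peak intensities.

    ``state`` selects the window centers: oxidized uses (748, 1170, 1371)
    over 1638; reduced uses the shifted markers (748, 1170, 1356) over 1605.
    Baseline subtraction is assumed to have been applied already.
    """
    if state not in RATIO_CENTERS:
        raise InvalidInputError("state must be 'oxidized' or 'reduced'")
    cen = RATIO_CENTERS[state]
    _, den = peak_maximum(trace, cen["denominator"], half_window)
    if den <= 0:
        raise UndefinedRatioError(
            f"denominator peak at {cen['denominator']} cm^-1 has non-positive intensity"
        )
    vals = {}
    for key in ("r748", "r1170", "r1371"):
        _, num = peak_maximum(trace, cen[key], half_window)
        vals[key] = num / den
    return RatioReport(centers=dict(cen), **vals)


@dataclass(frozen=True)
class PercentOfControl:
    r748: float
    r1170: float
    r1371: float


def percent_of_control(treated: RatioReport, control: RatioReport) -> PercentOfControl:
    """100 x treated/control for each ratio; control ratios taken as 100%."""
    out = {}
    for key in ("r748", "r1170", "r1371"):
        c = getattr(control, key)
        if c <= 0:
            raise UndefinedRatioError(f"control ratio {key} is non-positive")
        out[key] = 100.0 * getattr(treated, key) / c
    return PercentOfControl(**out)


@dataclass(frozen=True)
class RedoxCall:
    """Redox-state decision with the marker evidence behind it."""

    state: str  # 'oxidized' | 'reduced' | 'mixed'
    reduced_fraction_estimate: float
    evidence: dict
    low_confidence: bool = False


def classify_redox(trace: SpectrumTrace, library: BandLibrary = None,
                   which: str = "mitochondria") -> RedoxCall:
    """Classify a baseline-subtracted trace as oxidized / reduced / mixed.

    The reduced fraction is a non-negative least-squares projection onto the
    two library end-member band spectra, normalized to sum to one.  Marker
    evidence (nu4 position 1371 vs 1356, nu10 position 1638 vs 1605, and the
    748 relative intensity) is reported alongside.
    """
    if trace.wavenumber[0] > 650.0 or trace.wavenumber[-1] < 1700.0:
        raise SpectrumError("classification requires coverage of 650-1700 cm^-1")
    lib = library or band_library()
    x = trace.wavenumber
    S_ox = _lorentzian_sum(lib.get(which, "oxidized"), x)
    S_red = _lorentzian_sum(lib.get(which, "reduced"), x)
    A = np.column_stack([S_ox, S_red])
    coef, resid = nnls(A, trace.intensity)
    total = coef.sum()
    noise = _noise_mad(trace.intensity - A @ coef)

    nu4_pos, nu4_amp = peak_maximum(trace, 1363.5, 22.5)  # covers 1356 and 1371
    nu10_pos, nu10_amp = peak_maximum(trace, 1621.5, 31.5)  # covers 1605 and 1638
    _, i748 = peak_maximum(trace, 748.0)
    evidence = {
        "nu4_position": nu4_pos,
        "nu10_position": nu10_pos,
        "r748_vs_nu10": i748 / nu10_amp if nu10_amp > 0 else np.inf,
    }

    markers_detectable = min(nu4_amp, nu10_amp, i748) > 3.0 * noise
    if total <= 0 or not markers_detectable:
        return RedoxCall(
            state="mixed", reduced_fraction_estimate=0.5 if total <= 0 else coef[1] / total,
            evidence=evidence, low_confidence=True,
        )
    frac = float(coef[1] / total)
    if frac < 1.0 / 3.0:
        state = "oxidized"
    elif frac > 2.0 / 3.0:
        state = "reduced"
    else:
        state = "mixed"
    return RedoxCall(
        state=state, reduced_fraction_estimate=frac, evidence=evidence,
        low_confidence=False,
    )


def _noise_mad(residual: np.ndarray) -> float:
    """Robust noise scale: median absolute deviation scaled to Gaussian sigma."""
    med = np.median(residual)
    return float(1.4826 * np.median(np.abs(residual - med)))


#: default curved background used by the treatment emulation, (knot_x, knot_y)
DEFAULT_TREATMENT_BASELINE = (
    (600.0, 900.0, 1200.0, 1500.0, 1800.0),
    (2.0, 3.5, 4.0, 3.0, 1.5),
)


def treatment_series(f_red_control: float = 0.6, delta_f: float = -0.3,
                     n_replicates: int = 10, noise_sd: float = 0.05,
                     seed: int = 0, library: BandLibrary = None,
                     which: str = "mitochondria", axis=DEFAULT_AXIS,
                     baseline_knot_values=DEFAULT_TREATMENT_BASELINE,
                     knots: BaselineKnots = None) -> pd.DataFrame:
    """Emulate a treatment experiment and run the full ratio pipeline.

    Generates paired control / treated replicate spectra via
    :func:`mixture_spectrum` (treated reduced fraction = control + delta_f,
    clipped to [0, 1]), subtracts the baseline, computes the three ratios and
    percent-of-control values.  A protonophore-uncoupler emulation uses
    delta_f < 0 (cytochrome pool oxidizes); an ATP-synthase-inhibitor
    emulation uses delta_f > 0.

    Returns one row per replicate with ratio and percent-of-control columns.
    """
    f_treated = f_red_control + delta_f
    if not 0.0 <= f_treated <= 1.0:
        warnings.warn("treated reduced fraction clipped to [0, 1]", stacklevel=2)
        f_treated = float(np.clip(f_treated, 0.0, 1.0))
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        s_ctrl = int(rng.integers(0, 2**31 - 1))
        s_trt = int(rng.integers(0, 2**31 - 1))
        ctrl = mixture_spectrum(f_red_control, library, which, axis,
                                baseline_knot_values, noise_sd, s_ctrl)
        trt = mixture_spectrum(f_treated, library, which, axis,
                               baseline_knot_values, noise_sd, s_trt)
        r_ctrl = peak_ratios(subtract_baseline(ctrl, knots))
        r_trt = peak_ratios(subtract_baseline(trt, knots))
        pct = percent_of_control(r_trt, r_ctrl)
        rows.append({
            "replicate": rep,
            "f_red_control": f_red_control,
            "f_red_treated": f_treated,
            "r748_control": r_ctrl.r748, "r1170_control": r_ctrl.r1170,
            "r1371_control": r_ctrl.r1371,
            "r748_treated": r_trt.r748, "r1170_treated": r_trt.r1170,
            "r1371_treated": r_trt.r1371,
            "pct_r748": pct.r748, "pct_r1170": pct.r1170, "pct_r1371": pct.r1371,
        })
    return pd.DataFrame(rows)


# -- spectrum file I/O --------------------------------------------------------

def write_spectrum(trace: SpectrumTrace, path, comment: str = "") -> None:
    """Write a two-column ASCII spectrum (wavenumber, intensity); '#' comments."""
    lines = []
    if comment:
        for ln in comment.splitlines():
            lines.append(f"# {ln}")
    for key, val in trace.metadata.items():
        lines.append(f"# {key}: {val}")
    for wn, it in zip(trace.wavenumber, trace.intensity):
        lines.append(f"{wn:.6f}\t{it:.8e}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_spectrum(path) -> SpectrumTrace:
    """Read a two-column delimited ASCII spectrum; lines starting '#' ignored."""
    wn, it = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise SpectrumError(f"cannot parse spectrum line: {line!r}")
            wn.append(float(parts[0]))
            it.append(float(parts[1]))
    if not wn:
        raise SpectrumError(f"no data in {path}")
    return SpectrumTrace(
        wavenumber=np.array(wn), intensity=np.array(it),
        metadata={"origin": str(path)},
    )


def read_jcamp(path) -> SpectrumTrace:
    """Minimal JCAMP-DX reader: (X++(Y..Y)) and XYPOINTS (XY..XY) forms."""
    headers = {}
    data_x, data_y = [], []
    mode = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("##"):
                key, _, val = line[2:].partition("=")
                key = key.strip().upper()
                val = val.strip()
                headers[key] = val
                if key == "XYDATA":
                    mode = "xydata"
                elif key == "XYPOINTS":
                    mode = "xypoints"
                elif key == "END":
                    mode = None
                continue
            if mode is None:
                continue
            nums = [float(t) for t in line.replace(",", " ").split()]
            if not nums:
                continue
            if mode == "xydata":
                x0 = nums[0]
                data_x.append(x0)
                data_y.append(nums[1:])
            else:
                for xv, yv in zip(nums[::2], nums[1::2]):
                    data_x.append(xv)
                    data_y.append(yv)
    xf = float(headers.get("XFACTOR", 1.0))
    yf = float(headers.get("YFACTOR", 1.0))
    if mode == "xydata" or (data_y and isinstance(data_y[0], list)):
        dx = float(headers.get("DELTAX", 0.0))
        if dx == 0.0 and "LASTX" in headers and "FIRSTX" in headers and "NPOINTS" in headers:
            npts = int(float(headers["NPOINTS"]))
            dx = (float(headers["LASTX"]) - float(headers["FIRSTX"])) / max(npts - 1, 1)
        xs, ys = [], []
        # the leading abscissa on each data line is stored as x/XFACTOR;
        # DELTAX is in actual units
        for x0, yrow in zip(data_x, data_y):
            for j, yv in enumerate(yrow):
                xs.append(x0 * xf + j * dx)
                ys.append(yv * yf)
        x = np.array(xs)
        y = np.array(ys)
    else:
        x = np.array(data_x) * xf
        y = np.array(data_y, dtype=float) * yf
    order = np.argsort(x)
    return SpectrumTrace(
        wavenumber=x[order], intensity=y[order],
        metadata={"origin": str(path), "format": "jcamp-dx"},
    )
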