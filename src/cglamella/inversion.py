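"""Boltzmann inversion of Gaussian bond/angle distributions.

A harmonic bonded term at temperature T produces a Gaussian distribution
of the coordinate x (bond length r or angle θ):

    y ∝ exp[ -k (x - x0)² / (2 k_B T) ]

so the distribution width σ and the force constant are related by
k = k_B T / σ².  This module fits single Gaussians to binned samples
(moment estimates refined by least squares with a bin-integrated model,
so histogram binning does not broaden the fit), inverts widths to force
constants, and round-trips parameters through synthetic sampling.

Units: bonds in Å with k in kcal/(mol·Å²); angles in degrees with k in
kcal/(mol·rad²) — widths are converted to radians before inversion.
Angle distributions are fitted as plain Gaussians, without a sin θ
Jacobian (switchable would be meaningless here: the harvested samples are
treated as the distribution itself).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import special
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .mapping import TermSamples

__all__ = [
    "KB_KCAL_MOL_K",
    "DistributionHistogram",
    "GaussianFit",
    "HarmonicParams",
    "fit_gaussian",
    "invert",
    "sample_width",
    "sample_term",
    "derive_bonded_table",
    "params_to_table",
    "write_param_table",
    "read_param_table",
]

#: Boltzmann constant in kcal/(mol·K).
KB_KCAL_MOL_K = 0.0019872041

DEFAULT_BIN_WIDTH = {"bond": 0.01, "angle": 1.0}  # Å, degrees
MIN_SAMPLES = 100


@dataclass
class DistributionHistogram:
    """A normalized bond-length (Å) or angle (degree) distribution."""

    kind: str  # "bond" | "angle"
    centers: np.ndarray
    density: np.ndarray  # integrates to 1 over the binned range
    n_samples: int
    temperature: float  # K
    bin_width: float

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if len(self.centers) < 2:
            raise ValueError("histogram needs at least 2 bins")
        if np.any(self.density < 0):
            raise ValueError("negative density")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    @classmethod
    def from_samples(
        cls,
        samples: np.ndarray,
        kind: str,
        temperature: float,
        bin_width: float | None = None,
    ) -> "DistributionHistogram":
        samples = np.asarray(samples, dtype=float)
        if samples.size == 0:
            raise ValueError("empty sample array")
        if np.ptp(samples) == 0:
            raise ValueError("zero-variance samples")
        h = DEFAULT_BIN_WIDTH[kind] if bin_width is None else bin_width
        lo = np.floor(samples.min() / h) * h - 3 * h
        hi = np.ceil(samples.max() / h) * h + 3 * h
        edges = np.arange(lo, hi + h / 2, h)
        counts, edges = np.histogram(samples, bins=edges)
        density = counts / (samples.size * h)
        centers = 0.5 * (edges[:-1] + edges[1:])
        return cls(kind, centers, density, samples.size, temperature, h)


@dataclass
class GaussianFit:
    x0: float
    sigma: float
    multimodal: bool


@dataclass
class HarmonicParams:
    """One harmonic bonded term: x0 (Å or degrees), k (kcal/(mol·Å²) or
    kcal/(mol·rad²)), temperature, and a flag for terms whose underlying
    distribution was multimodal (single-Gaussian compromise fit)."""

    term: str
    kind: str  # "bond" | "angle"
    x0: float
    k: float
    temperature: float
    multimodal: bool = False
    n_samples: int = 0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"{self.term}: k must be > 0")
        if self.temperature <= 0:
            raise ValueError(f"{self.term}: T must be > 0")
        if self.kind == "bond" and self.x0 <= 0:
            raise ValueError(f"{self.term}: bond x0 must be > 0")
        if self.kind == "angle" and not (0.0 < self.x0 <= 180.0):
            raise ValueError(f"{self.term}: angle x0 must be in (0, 180]")


def _bin_gaussian(centers: np.ndarray, h: float, amp: float, x0: float, sigma: float):
    """Gaussian averaged over bins of width h (exact, via erf)."""
    a = (centers - h / 2 - x0) / (np.sqrt(2) * sigma)
    b = (centers + h / 2 - x0) / (np.sqrt(2) * sigma)
    return amp * (special.erf(b) - special.erf(a)) / (2 * h)


def fit_gaussian(hist: DistributionHistogram) -> GaussianFit:
    """Fit the best single Gaussian to a binned distribution.

    Moment estimates seed a least-squares refinement against the density
    with a bin-integrated Gaussian model.  The multimodal flag is set when
    a second peak with prominence above 20% of the main peak survives
    Gaussian smoothing (2-bin kernel) — peak detection only; the fit is
    always on the unsmoothed density.
    """
    if hist.n_samples < MIN_SAMPLES:
        raise ValueError(f"need >= {MIN_SAMPLES} samples, have {hist.n_samples}")
    w = hist.density * hist.bin_width
    if w.sum() <= 0:
        raise ValueError("empty histogram")
    p = w / w.sum()
    mean = float(np.sum(p * hist.centers))
    var = float(np.sum(p * (hist.centers - mean) ** 2))
    if var <= 0:
        raise ValueError("zero-variance distribution")
    sigma0 = np.sqrt(max(var - hist.bin_width**2 / 12.0, var * 1e-3))

    smoothed = gaussian_filter1d(hist.density, sigma=2.0)
    peaks, props = find_peaks(smoothed, prominence=0.2 * smoothed.max())
    multimodal = len(peaks) >= 2

    try:
        popt, _ = curve_fit(
            lambda x, amp, x0, s: _bin_gaussian(x, hist.bin_width, amp, x0, s),
            hist.centers,
            hist.density,
            p0=[1.0, mean, sigma0],
            maxfev=10000,
        )
        amp, x0, sigma = popt
        sigma = abs(float(sigma))
        x0 = float(x0)
        # reject degenerate refinements (can happen on strongly bimodal data)
        if not np.isfinite(x0) or not np.isfinite(sigma) or sigma <= 0:
            raise RuntimeError
    except RuntimeError:
        x0, sigma = mean, sigma0
    return GaussianFit(x0=x0, sigma=sigma, multimodal=multimodal)


def invert(sigma: float, temperature: float) -> float:
    """Force constant from a Gaussian width: k = k_B T / σ².

    ``sigma`` in Å gives k in kcal/(mol·Å²); in radians, kcal/(mol·rad²).
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    return KB_KCAL_MOL_K * temperature / sigma**2


def sample_width(k: float, temperature: float) -> float:
    """Inverse relation: σ = sqrt(k_B T / k)."""
    if k <= 0:
        raise ValueError("k must be > 0")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    return float(np.sqrt(KB_KCAL_MOL_K * temperature / k))


def sample_term(
    params: HarmonicParams, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw n samples from the Gaussian implied by a harmonic term.

    Bonds sample in Å directly; angle force constants are per rad², so
    the width is converted to degrees before sampling.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = sample_width(params.k, params.temperature)
    if params.kind == "angle":
        s = np.degrees(s)
    return rng.normal(params.x0, s, size=n)


def derive_bonded_table(
    samples: Mapping[str, TermSamples],
    temperature: float,
    bin_widths: Mapping[str, float] | None = None,
) -> list[HarmonicParams]:
    """Fit every term and invert widths to harmonic force constants.

    Terms with fewer than 100 samples are excluded with a warning.
    Multimodal terms keep the single-Gaussian compromise fit, flagged.
    """
    if not samples:
        raise ValueError("no terms to fit")
    bw = dict(DEFAULT_BIN_WIDTH)
    if bin_widths:
        bw.update(bin_widths)
    out = []
    for term, ts in samples.items():
        if ts.values.size < MIN_SAMPLES:
            warnings.warn(
                f"term {term}: only {ts.values.size} samples (< {MIN_SAMPLES}); excluded"
            )
            continue
        hist = DistributionHistogram.from_samples(
            ts.values, ts.kind, temperature, bin_width=bw[ts.kind]
        )
        fit = fit_gaussian(hist)
        sigma = np.radians(fit.sigma) if ts.kind == "angle" else fit.sigma
        out.append(
            HarmonicParams(
                term=term,
                kind=ts.kind,
                x0=fit.x0,
                k=invert(sigma, temperature),
                temperature=temperature,
                multimodal=fit.multimodal,
                n_samples=int(ts.values.size),
            )
        )
    return out


# ---------------------------------------------------------------------------
# structured-text parameter tables
# ---------------------------------------------------------------------------

_UNITS = {"bond": ("Å", "kcal/(mol Å^2)"), "angle": ("deg", "kcal/(mol rad^2)")}


def params_to_table(params: list[HarmonicParams]) -> pd.DataFrame:
    rows = []
    for p in params:
        xu, ku = _UNITS[p.kind]
        rows.append(
            {
                "term": p.term,
                "kind": p.kind,
                "x0": p.x0,
                "k": p.k,
                "x0_units": xu,
                "k_units": ku,
                "T_K": p.temperature,
                "multimodal": p.multimodal,
                "n_samples": p.n_samples,
            }
        )
    return pd.DataFrame(rows)


def write_param_table(params: list[HarmonicParams], path) -> None:
    params_to_table(params).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_param_table(path) -> list[HarmonicParams]:
    df = pd.read_csv(path, sep="\t")
    return [
        HarmonicParams(
            term=r.term,
            kind=r.kind,
            x0=float(r.x0),
            k=float(r.k),
            temperature=float(r.T_K),
            multimodal=bool(r.multimodal),
            n_samples=int(r.n_samples),
        )
        for r in df.itertuples()
    ]
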