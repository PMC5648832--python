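"""Raman spectrum container, preprocessing chain and synthetic spectra.

The preprocessing chain mirrors a conventional dispersive-Raman pipeline:

    wavenumber calibration -> system-response correction -> Savitzky-Golay
    smoothing -> iterative modified-polynomial fluorescence subtraction ->
    area-under-curve (AUC) normalisation

Each operation stamps a provenance tag on the spectrum and refuses input
on which a *later* stage has already been applied, so out-of-order
processing fails loudly instead of silently corrupting band ratios.

Intensities are in arbitrary units throughout; wavenumbers (Raman shift)
are in 1/cm, stored strictly ascending.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import savgol_filter

#: Canonical pipeline order used for provenance checking.
STAGE_ORDER = (
    "raw",
    "calibrated",
    "response_corrected",
    "smoothed",
    "baseline_subtracted",
    "normalized",
)

DEFAULT_AXIS_START = 900.0
DEFAULT_AXIS_STOP = 1800.0
DEFAULT_AXIS_STEP = 1.0


def default_axis(
    start: float = DEFAULT_AXIS_START,
    stop: float = DEFAULT_AXIS_STOP,
    step: float = DEFAULT_AXIS_STEP,
) -> np.ndarray:
    """Default fingerprint-region wavenumber axis, 900-1800 1/cm at 1 1/cm."""
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


@dataclass(frozen=True)
class Spectrum:
    """A single Raman spectrum: wavenumber axis plus intensity vector.

    ``meta`` carries provenance: ``meta["stages"]`` is the tuple of
    pipeline stages already applied, in order.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        wn = np.asarray(self.wavenumbers, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        if wn.ndim != 1 or it.ndim != 1 or wn.shape != it.shape:
            raise ValueError("wavenumbers and intensities must be 1-D and equal length")
        if wn.size < 2:
            raise ValueError("a spectrum needs at least 2 samples")
        if np.any(~np.isfinite(wn)) or np.any(~np.isfinite(it)):
            raise ValueError("spectrum contains NaN or inf")
        if np.any(np.diff(wn) <= 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "intensities", it)
        if "stages" not in self.meta:
            self.meta["stages"] = ("raw",)

    @property
    def stages(self) -> tuple:
        return tuple(self.meta.get("stages", ("raw",)))

    def with_intensities(self, intensities: np.ndarray, stage: str | None = None,
                         **extra) -> "Spectrum":
        meta = dict(self.meta)
        meta.update(extra)
        if stage is not None:
            meta["stages"] = self.stages + (stage,)
        return Spectrum(self.wavenumbers, np.asarray(intensities, float), meta)

    def auc(self) -> float:
        return float(np.trapezoid(self.intensities, self.wavenumbers))


def _check_order(spectrum: Spectrum, incoming: str) -> None:
    """Refuse input on which a stage later than ``incoming`` was applied."""
    rank = STAGE_ORDER.index(incoming)
    for s in spectrum.stages:
        if s in STAGE_ORDER and STAGE_ORDER.index(s) > rank:
            raise ValueError(
                f"pipeline order violation: cannot apply {incoming!r} after "
                f"{s!r} (expected order {' -> '.join(STAGE_ORDER[1:])})"
            )
        if s == incoming:
            raise ValueError(f"stage {incoming!r} already applied")


def common_axis(spectra: Iterable[Spectrum]) -> np.ndarray:
    spectra = list(spectra)
    axis = spectra[0].wavenumbers
    for s in spectra[1:]:
        if s.wavenumbers.shape != axis.shape or not np.allclose(
            s.wavenumbers, axis, rtol=0, atol=1e-9
        ):
            raise ValueError("spectra do not share a common wavenumber axis")
    return axis


# ---------------------------------------------------------------------------
# Wavenumber calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WavenumberCalibration:
    """Polynomial pixel -> wavenumber map (highest-order coefficient first)."""

    coefficients: np.ndarray
    residuals: np.ndarray

    def __call__(self, pixels) -> np.ndarray:
        return np.polyval(self.coefficients, np.asarray(pixels, float))

    @property
    def residual_rms(self) -> float:
        return float(np.sqrt(np.mean(self.residuals**2))) if self.residuals.size else 0.0


def calibrate_wavenumber(
    peak_pixel_positions: Sequence[float],
    known_wavenumbers: Sequence[float],
    order: int = 2,
) -> WavenumberCalibration:
    """Fit a pixel->wavenumber polynomial from reference-lamp peak pairs.

    Standards such as a neon-argon lamp, naphthalene and acetaminophen give
    peaks of known Raman shift at measured pixel positions; a low-order
    polynomial maps the detector axis to 1/cm.
    """
    px = np.asarray(peak_pixel_positions, float)
    wn = np.asarray(known_wavenumbers, float)
    if px.shape != wn.shape or px.ndim != 1:
        raise ValueError("peak pixel and wavenumber lists must be equal-length 1-D")
    if px.size < order + 1:
        raise ValueError(
            f"underdetermined calibration: {px.size} pairs for order {order} "
            f"(need >= {order + 1})"
        )
    coef = np.polyfit(px, wn, order)
    return WavenumberCalibration(coef, wn - np.polyval(coef, px))


# ---------------------------------------------------------------------------
# System-response correction
# ---------------------------------------------------------------------------

def correct_response(spectrum: Spectrum, measured_lamp: Spectrum,
                     true_lamp: Spectrum) -> Spectrum:
    """Correct for the spectrograph/CCD wavelength response.

    Given the measured spectrum of a calibrated broadband lamp and its
    certified emission curve, the pointwise ratio true/measured is the
    inverse response; multiplying the data by it removes the instrument
    throughput shape.
    """
    _check_order(spectrum, "response_corrected")
    axis = common_axis([spectrum, measured_lamp, true_lamp])
    m = measured_lamp.intensities
    if np.any(m <= 0):
        raise ValueError("measured lamp spectrum must be strictly positive")
    del axis
    return spectrum.with_intensities(
        spectrum.intensities * true_lamp.intensities / m, stage="response_corrected"
    )


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------

def smooth(spectrum: Spectrum, window: int = 7, polyorder: int = 3) -> Spectrum:
    """Savitzky-Golay noise smoothing (axis unchanged)."""
    if window % 2 != 1 or window <= polyorder or polyorder < 0:
        raise ValueError("window must be odd and greater than polyorder")
    _check_order(spectrum, "smoothed")
    out = savgol_filter(spectrum.intensities, window, polyorder)
    return spectrum.with_intensities(out, stage="smoothed",
                                     smooth_window=window, smooth_polyorder=polyorder)


def smooth_array(intensities: np.ndarray, window: int = 7, polyorder: int = 3) -> np.ndarray:
    """Vectorised Savitzky-Golay over the last axis of a 2-D intensity block."""
    if window % 2 != 1 or window <= polyorder:
        raise ValueError("window must be odd and greater than polyorder")
    return savgol_filter(np.asarray(intensities, float), window, polyorder, axis=-1)


# ---------------------------------------------------------------------------
# Fluorescence baseline (iterative modified polynomial)
# ---------------------------------------------------------------------------

def modpoly_baseline_array(
    intensities: np.ndarray,
    wavenumbers: np.ndarray,
    order: int = 5,
    max_iter: int = 100,
    tol: float = 1e-4,
    grid_stride: int = 3,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Vectorised modified-polynomial baseline for (n_spectra, n_wn) blocks.

    Iteratively least-squares fits a polynomial of ``order`` and clips the
    working signal to ``min(signal, fit)`` so peaks are progressively
    excluded; the limit is the smooth fluorescence floor. A spectrum
    counts as converged once its fitted baseline moves by less than
    ``tol`` (in units of its own maximum) between iterations, and is then
    frozen out of the working batch. The polynomial is estimated on every
    ``grid_stride``-th wavenumber (the baseline is smooth by
    construction) and evaluated on the full axis. Returns
    ``(baseline, corrected, converged)``.
    """
    y = np.atleast_2d(np.asarray(intensities, float))
    x = np.asarray(wavenumbers, float)
    if order < 1:
        raise ValueError("baseline order must be >= 1")
    # scaled Vandermonde + pseudo-inverse, shared across spectra
    t = (x - x.mean()) / (x.max() - x.min())
    V_full = np.vander(t, order + 1, increasing=True)
    V = np.vander(t[::grid_stride], order + 1, increasing=True)
    P = np.linalg.pinv(V).astype(np.float32)
    V = V.astype(np.float32)
    scale = np.maximum(np.abs(y).max(axis=1), 1e-300)
    # transposed (n_grid, n_active) float32 working set
    W = np.asfortranarray((y[:, ::grid_stride].T / scale), dtype=np.float32)
    coef = P @ W
    fit = V @ coef
    n_spec = W.shape[1]
    coef_out = np.empty((order + 1, n_spec), np.float32, order="F")
    idx = np.arange(n_spec)
    converged = False
    for _ in range(max_iter):
        np.minimum(W, fit, out=W)
        coef = P @ W
        new_fit = V @ coef
        delta = np.abs(new_fit - fit).max(axis=0)
        fit = new_fit
        done = delta < tol
        if done.all():
            coef_out[:, idx] = coef
            converged = True
            break
        if done.mean() > 0.3:
            coef_out[:, idx[done]] = coef[:, done]
            keep = ~done
            idx = idx[keep]
            W = np.asfortranarray(W[:, keep])
            fit = np.asfortranarray(fit[:, keep])
    if not converged:
        coef_out[:, idx] = coef
    baseline = (V_full @ coef_out.astype(float)).T * scale[:, None]
    return baseline, y - baseline, converged


def subtract_baseline_modpoly(
    spectrum: Spectrum, order: int = 5, max_iter: int = 100, tol: float = 1e-4
) -> Spectrum:
    """Subtract the fluorescence background by iterative polynomial fitting.

    Non-convergence within ``max_iter`` is flagged in the output metadata
    (``baseline_converged``) rather than raised, matching how the device
    pipeline degrades gracefully on pathological spectra.
    """
    _check_order(spectrum, "baseline_subtracted")
    baseline, corrected, converged = modpoly_baseline_array(
        spectrum.intensities, spectrum.wavenumbers, order, max_iter, tol
    )
    return spectrum.with_intensities(
        corrected[0], stage="baseline_subtracted",
        baseline_order=order, baseline_converged=bool(converged),
        baseline_max_iter=max_iter,
    )


# ---------------------------------------------------------------------------
# Normalisation and band features
# ---------------------------------------------------------------------------

def normalize_auc(spectrum: Spectrum) -> Spectrum:
    """Divide by the trapezoidal area under the curve so the AUC becomes 1.

    AUC normalisation makes spectra comparable across acquisitions and
    specimens (laser power, focus and collection efficiency all scale the
    spectrum multiplicatively). Idempotent: a spectrum already tagged as
    normalized is returned unchanged.
    """
    if "normalized" in spectrum.stages:
        return spectrum
    _check_order(spectrum, "normalized")
    area = float(np.trapezoid(np.abs(spectrum.intensities), spectrum.wavenumbers))
    if area <= 0:
        raise ValueError("cannot normalize a zero-area spectrum")
    return spectrum.with_intensities(spectrum.intensities / area, stage="normalized")


def trapezoid_weights(wavenumbers: np.ndarray) -> np.ndarray:
    """Quadrature weights w with trapz(y, x) == y @ w."""
    x = np.asarray(wavenumbers, float)
    w = np.empty_like(x)
    w[0] = (x[1] - x[0]) / 2.0
    w[-1] = (x[-1] - x[-2]) / 2.0
    w[1:-1] = (x[2:] - x[:-2]) / 2.0
    return w


def normalize_auc_array(intensities: np.ndarray, wavenumbers: np.ndarray) -> np.ndarray:
    y = np.atleast_2d(np.asarray(intensities, float))
    area = np.abs(y) @ trapezoid_weights(wavenumbers)
    if np.any(area <= 0):
        raise ValueError("cannot normalize a zero-area spectrum")
    return y / area[:, None]


def band_intensity(spectrum: Spectrum, center: float, halfwidth: float = 4.0) -> float:
    """Mean intensity in [center-halfwidth, center+halfwidth]."""
    wn = spectrum.wavenumbers
    if center - halfwidth < wn[0] or center + halfwidth > wn[-1]:
        raise ValueError(f"band {center}+-{halfwidth} 1/cm outside the axis range")
    sel = (wn >= center - halfwidth) & (wn <= center + halfwidth)
    return float(spectrum.intensities[sel].mean())


def band_ratio(
    spectrum: Spectrum,
    numerator_center: float,
    denominator_center: float,
    halfwidth: float = 4.0,
) -> float:
    """Ratio of band-mean intensities, e.g. 1265/1304 or 1445/1265 1/cm.

    Band means over +-halfwidth are used rather than single bins so the
    feature is robust to 1 1/cm axis shifts.
    """
    num = band_intensity(spectrum, numerator_center, halfwidth)
    den = band_intensity(spectrum, denominator_center, halfwidth)
    if den == 0:
        raise ValueError("zero denominator band")
    return num / den


def snr(spectrum: Spectrum, signal_band=(1400.0, 1500.0),
        noise_band=(1750.0, 1800.0)) -> float:
    """Signal-to-noise: mean in a signal band over std in a signal-free band."""
    wn = spectrum.wavenumbers
    sig = spectrum.intensities[(wn >= signal_band[0]) & (wn <= signal_band[1])]
    noi = spectrum.intensities[(wn >= noise_band[0]) & (wn <= noise_band[1])]
    sd = float(np.std(noi))
    if sd == 0:
        return float("inf")
    return float(np.mean(sig)) / sd


# ---------------------------------------------------------------------------
# Synthetic spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakModel:
    """One vibrational band: center (1/cm), FWHM (1/cm), amplitude, shape."""

    center: float
    width: float
    amplitude: float
    shape: str = "gaussian"

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("peak width must be > 0")
        if self.amplitude < 0:
            raise ValueError("peak amplitude must be >= 0")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown peak shape {self.shape!r}")

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        x = np.asarray(wavenumbers, float) - self.center
        if self.shape == "gaussian":
            sigma = self.width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
            return self.amplitude * np.exp(-0.5 * (x / sigma) ** 2)
        hwhm = self.width / 2.0
        return self.amplitude / (1.0 + (x / hwhm) ** 2)


@dataclass(frozen=True)
class ComponentLibraryEntry:
    """A named pure component as a sum of parametric bands."""

    name: str
    peaks: tuple

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        out = np.zeros_like(np.asarray(wavenumbers, float))
        for p in self.peaks:
            out += p.profile(wavenumbers)
        return out


def synthesize_spectrum(
    components,
    fractions=None,
    baseline_coefficients: Sequence[float] = (),
    noise_sigma: float = 0.0,
    seed: int = 0,
    wavenumbers: np.ndarray | None = None,
) -> Spectrum:
    """Build a synthetic spectrum from fraction-weighted component profiles.

    ``components`` is a single :class:`ComponentLibraryEntry` or a list of
    them with matching ``fractions`` (non-negative, summing to 1 within
    1e-6). The polynomial baseline (coefficients in increasing order, on
    the axis scaled to [0, 1]) emulates fluorescence; gaussian noise is
    seeded for reproducibility.
    """
    if wavenumbers is None:
        wavenumbers = default_axis()
    wn = np.asarray(wavenumbers, float)
    if isinstance(components, ComponentLibraryEntry):
        components = [components]
        fractions = [1.0]
    frac = np.asarray(fractions, float)
    if frac.shape != (len(components),):
        raise ValueError("one fraction per component required")
    if np.any(frac < 0) or abs(frac.sum() - 1.0) > 1e-6:
        raise ValueError("fractions must be >= 0 and sum to 1 within 1e-6")
    y = np.zeros_like(wn)
    for f, comp in zip(frac, components):
        y += f * comp.profile(wn)
    if len(baseline_coefficients):
        t = (wn - wn[0]) / (wn[-1] - wn[0])
        y += np.polynomial.polynomial.polyval(t, np.asarray(baseline_coefficients, float))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sigma, size=wn.size)
    meta = {
        "stages": ("raw",),
        "synthetic": True,
        "components": tuple(c.name for c in components),
        "fractions": tuple(float(f) for f in frac),
        "noise_sigma": float(noise_sigma),
        "seed": int(seed),
    }
    return Spectrum(wn, y, meta)


__all__ = [
    "Spectrum", "PeakModel", "ComponentLibraryEntry", "WavenumberCalibration",
    "default_axis", "common_axis", "calibrate_wavenumber", "correct_response",
    "smooth", "smooth_array", "subtract_baseline_modpoly", "modpoly_baseline_array",
    "normalize_auc", "normalize_auc_array", "band_intensity", "band_ratio", "snr",
    "synthesize_spectrum", "STAGE_ORDER",
]
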