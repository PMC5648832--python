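"""Classical least squares (CLS) spectral unmixing and margin rules.

A measured spectrum is modelled as a linear combination of known pure
component spectra; the least-squares coefficients, normalised to their
sum, are the relative spectral contributions. Two threshold rules turn
fractions into margin labels:

* tissue mode: fatty iff fat fraction >= 0.5 (the >=50% rule, inclusive),
  else fibroadenomatoid;
* phantom mode: paraffin-positive iff paraffin fraction >= 0.05 (the 5%
  relative-contribution detection threshold of the spatially offset
  probe), else clean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .spectral_processing import Spectrum, common_axis


@dataclass(frozen=True)
class CLSFit:
    """Result of unmixing one spectrum against a component library."""

    components: tuple          # component names, library order
    coefficients: np.ndarray   # raw least-squares coefficients
    fractions: np.ndarray      # coefficient shares, sum to 1
    residual_norm: float
    r_squared: float

    def fraction(self, name: str) -> float:
        return float(self.fractions[self.components.index(name)])


@dataclass(frozen=True)
class MarginLabel:
    """A per-point margin call with the fractions it was derived from."""

    label: str
    fractions: dict

    POSITIVE_TISSUE = "fibroadenomatoid"
    POSITIVE_PHANTOM = "paraffin_positive"


def _library_matrix(library) -> tuple[np.ndarray, tuple]:
    names = tuple(s.meta.get("component", f"component_{i}")
                  for i, s in enumerate(library))
    L = np.stack([s.intensities for s in library], axis=1)  # (n_wn, k)
    if np.linalg.matrix_rank(L) < L.shape[1]:
        raise ValueError("library spectra are rank deficient (linearly dependent)")
    return L, names


def fit_cls(library, spectrum: Spectrum, nonnegative: bool = True) -> CLSFit:
    """Unmix one spectrum against a list of pure component spectra.

    With ``nonnegative=True`` (default, used for classification) the
    coefficients are constrained to be >= 0 so their shares read as a
    composition; unconstrained mode equals the normal-equations solution
    and leaves the residual orthogonal to the library span.
    """
    common_axis(list(library) + [spectrum])
    L, names = _library_matrix(library)
    y = spectrum.intensities
    if nonnegative:
        coef, _ = nnls(L, y)
    else:
        coef, *_ = np.linalg.lstsq(L, y, rcond=None)
    resid = y - L @ coef
    total = float(np.sum((y - y.mean()) ** 2))
    rsq = 1.0 - float(np.sum(resid**2)) / total if total > 0 else float("nan")
    s = coef.sum()
    frac = coef / s if s != 0 else np.full_like(coef, np.nan)
    return CLSFit(names, coef, frac, float(np.linalg.norm(resid)), rsq)


def fit_cls_batch(library, intensities: np.ndarray,
                  nonnegative: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Unmix many spectra at once.

    ``intensities`` is (n_spectra, n_wn) on the library axis. Returns
    ``(coefficients, residual_ss)`` with coefficients (n_spectra, k). The
    unconstrained batch is one pseudo-inverse product; rows with negative
    entries are re-solved with NNLS when ``nonnegative``.
    """
    L, _ = _library_matrix(library)
    Y = np.atleast_2d(np.asarray(intensities, float))
    coef = (np.linalg.pinv(L) @ Y.T).T
    if nonnegative:
        bad = np.where(np.any(coef < -1e-15, axis=1))[0]
        if bad.size:
            coef[bad] = _nnls_by_support(L, Y[bad])
    resid = Y - coef @ L.T
    return coef, np.sum(resid**2, axis=1)


def _nnls_by_support(L: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Exact non-negative least squares for a small library, vectorised.

    Enumerates all supports; the NNLS optimum is the minimum-residual
    restricted least-squares solution whose coefficients are feasible.
    Efficient for the 2-6 component libraries used here; larger
    libraries fall back to the iterative solver.
    """
    k = L.shape[1]
    if k > 6:
        return np.stack([nnls(L, y)[0] for y in Y])
    n = Y.shape[0]
    best_rss = np.full(n, np.inf)
    best = np.zeros((n, k))
    for mask in range(1, 2**k):
        sup = [j for j in range(k) if mask >> j & 1]
        Ls = L[:, sup]
        cs = (np.linalg.pinv(Ls) @ Y.T).T          # (n, |sup|)
        feas = np.all(cs >= 0, axis=1)
        if not feas.any():
            continue
        rss = np.sum((Y[feas] - cs[feas] @ Ls.T) ** 2, axis=1)
        rows = np.flatnonzero(feas)
        better = rss < best_rss[rows]
        rows = rows[better]
        best_rss[rows] = rss[better]
        full = np.zeros((rows.size, k))
        full[:, sup] = cs[rows]
        best[rows] = full
    return best


def variance_explained(fits, spectra) -> float:
    """Percent of the dataset's centered variance captured by the CLS model.

    100 * (1 - pooled residual SS / pooled mean-centered total SS), the
    'cumulative variance' figure of merit for a component library: ~100%
    means the library accounts for essentially everything but noise.
    """
    fits = list(fits)
    spectra = list(spectra)
    if not fits or len(fits) != len(spectra):
        raise ValueError("need equal, non-empty lists of fits and spectra")
    rss = sum(f.residual_norm**2 for f in fits)
    tss = sum(float(np.sum((s.intensities - s.intensities.mean()) ** 2))
              for s in spectra)
    if tss == 0:
        raise ValueError("zero total variance")
    return 100.0 * (1.0 - rss / tss)


def variance_explained_arrays(residual_ss: np.ndarray, intensities: np.ndarray) -> float:
    Y = np.atleast_2d(np.asarray(intensities, float))
    tss = float(np.sum((Y - Y.mean(axis=1, keepdims=True)) ** 2))
    if tss == 0:
        raise ValueError("zero total variance")
    return 100.0 * (1.0 - float(np.sum(residual_ss)) / tss)


FAT_FRACTION_THRESHOLD = 0.5
PARAFFIN_FRACTION_THRESHOLD = 0.05


def classify_fraction(fit: CLSFit, mode: str = "tissue") -> MarginLabel:
    """Apply the composition threshold rule for the given mode."""
    fractions = {n: float(f) for n, f in zip(fit.components, fit.fractions)}
    if mode == "tissue":
        fat = fractions.get("fatty", 0.0)
        label = "fatty" if fat >= FAT_FRACTION_THRESHOLD else "fibroadenomatoid"
    elif mode == "phantom":
        par = fractions.get("paraffin", 0.0)
        label = "paraffin_positive" if par >= PARAFFIN_FRACTION_THRESHOLD else "clean"
    else:
        raise ValueError(f"unknown classification mode {mode!r}")
    return MarginLabel(label, fractions)


__all__ = [
    "CLSFit", "MarginLabel", "fit_cls", "fit_cls_batch",
    "variance_explained", "variance_explained_arrays", "classify_fraction",
    "FAT_FRACTION_THRESHOLD", "PARAFFIN_FRACTION_THRESHOLD",
]
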