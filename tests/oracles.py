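"""Independent oracles used to cross-check the implementation.

Each oracle is written directly from the defining formula (or as a brute
force enumeration) and stays independent of the code path it checks.
"""

import itertools
import math

import numpy as np


def farrell_reflectance(r, mua, musp, n_rel):
    """Steady-state diffusion-approximation reflectance R(r) for a
    semi-infinite medium: the standard dipole (source + image above the
    extrapolated boundary) solution."""
    r = np.asarray(r, float)
    D = 1.0 / (3.0 * (mua + musp))
    z0 = 1.0 / (mua + musp)
    mueff = math.sqrt(3.0 * mua * (mua + musp))
    # internal-reflection parameter (Groenhuis polynomial approximation)
    rd = -1.440 / n_rel**2 + 0.710 / n_rel + 0.668 + 0.0636 * n_rel
    A = (1.0 + rd) / (1.0 - rd)
    zb = 2.0 * A * D
    r1 = np.sqrt(z0**2 + r**2)
    r2 = np.sqrt((z0 + 2 * zb) ** 2 + r**2)
    return (z0 * (mueff + 1 / r1) * np.exp(-mueff * r1) / r1**2
            + (z0 + 2 * zb) * (mueff + 1 / r2) * np.exp(-mueff * r2) / r2**2)


def brute_force_allocation(pce, max_per_ring):
    """Enumerate every integer count vector; same objective and
    tie-breaks as the spec: minimal product spread, then minimal total,
    then lexicographic order."""
    best_key, best_counts = None, None
    for counts in itertools.product(range(1, max_per_ring + 1),
                                    repeat=len(pce)):
        products = [c * p for c, p in zip(counts, pce)]
        key = (max(products) - min(products), sum(counts), counts)
        if best_key is None or key < best_key:
            best_key, best_counts = key, counts
    return best_counts


def welch_formula(a, b):
    """Welch t statistic, Welch-Satterthwaite dof and two-tailed p,
    straight from the textbook formulas."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    dof = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * tdist.sf(abs(t), dof)
    return t, p


def savgol_center_coefficients(window, polyorder):
    """Savitzky-Golay convolution coefficients for the window center,
    from the least-squares projection onto local monomials."""
    half = window // 2
    x = np.arange(-half, half + 1, dtype=float)
    A = np.vander(x, polyorder + 1, increasing=True)
    # value of the LS polynomial at x=0 is e0^T (A^T A)^-1 A^T y
    return np.linalg.solve(A.T @ A, A.T)[0]


def normal_equations_cls(L, y):
    """Unconstrained CLS coefficients via the normal equations."""
    return np.linalg.solve(L.T @ L, L.T @ y)


def confusion_from_labels(truth, pred):
    """Agreement-table metrics computed from raw label arrays."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    tp = int(np.sum((truth == 1) & (pred == 1)))
    fn = int(np.sum((truth == 1) & (pred == 0)))
    tn = int(np.sum((truth == 0) & (pred == 0)))
    fp = int(np.sum((truth == 0) & (pred == 1)))
    n = truth.size
    po = (tp + tn) / n
    pe = ((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn)) / n**2
    kappa = (po - pe) / (1 - pe) if pe != 1 else float("nan")
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "accuracy": po,
        "kappa": kappa,
    }


def gaussian_band_mean(amplitude, center, fwhm, band_lo, band_hi, n=20001):
    """Mean of a gaussian peak over a band, by dense quadrature."""
    x = np.linspace(band_lo, band_hi, n)
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    y = amplitude * np.exp(-0.5 * ((x - center) / sigma) ** 2)
    return float(np.trapezoid(y, x) / (band_hi - band_lo))
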