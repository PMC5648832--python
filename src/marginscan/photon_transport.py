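"""Monte Carlo probe design: photon collection efficiency vs S-D offset.

The spatially offset Raman probe is designed from elastic photon
transport in a breast-like turbid medium: a pencil beam enters at the
origin, and photons remitted through the surface are collected in
annular bins centered at candidate source-detector (S-D) offsets. The
relative photon collection efficiency (PCE) per unit detector area,
normalised to 100% at a 0.75 mm reference offset, falls roughly
logarithmically with offset; equalising the product of fibre count and
relative PCE across rings yields the 2/3/4 fibre allocation of the
36-fibre probe. The same simulations give the depth origin of the
detected signal, which anchors the 5%-contribution-at-2-mm sampling
depth rule used for margin calls.

Tissue optical properties are not uniquely known; the shipped
``breast_785nm`` preset (absorption 0.01/mm, reduced scattering 1.0/mm,
anisotropy 0.9, index 1.4) is a documented stand-in with typical
soft-tissue values at 785 nm, and every value is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from . import _mc

# roulette and truncation defaults (variance control; configurable)
W_MIN = 1e-4
P_SURVIVE = 0.1
DEPTH_CUTOFF = 20.0   # mm; ~3.5x the diffusion penetration depth of the preset
MAX_STEPS = 1_000_000


@dataclass(frozen=True)
class Layer:
    thickness: float
    absorption_coefficient: float
    scattering_coefficient: float
    anisotropy: float
    refractive_index: float


@dataclass(frozen=True)
class OpticalProperties:
    """Optical properties of a homogeneous or layered semi-infinite medium.

    Coefficients are per mm; ``scattering_coefficient`` is the full (not
    reduced) scattering coefficient. ``layers``, if given, is an ordered
    tuple of :class:`Layer` from the surface down; the medium below the
    last finite layer continues with the top-level properties.
    """

    absorption_coefficient: float
    scattering_coefficient: float
    anisotropy: float
    refractive_index: float
    layers: tuple = ()

    def __post_init__(self):
        def check(name, value, lo, hi=None):
            if not np.isfinite(value) or value < lo or (hi is not None and value > hi):
                raise ValueError(f"non-physical {name}: {value!r}")
        check("absorption_coefficient", self.absorption_coefficient, 0.0)
        check("scattering_coefficient", self.scattering_coefficient, 0.0)
        check("anisotropy", self.anisotropy, -1.0, 1.0)
        if self.refractive_index <= 1.0 or not np.isfinite(self.refractive_index):
            raise ValueError(f"non-physical refractive_index: {self.refractive_index!r}")
        for i, layer in enumerate(self.layers):
            if layer.thickness <= 0:
                raise ValueError(f"non-physical layer thickness in layer {i}: "
                                 f"{layer.thickness!r}")
            check(f"layer {i} absorption_coefficient", layer.absorption_coefficient, 0.0)
            check(f"layer {i} scattering_coefficient", layer.scattering_coefficient, 0.0)
            check(f"layer {i} anisotropy", layer.anisotropy, -1.0, 1.0)
            if layer.refractive_index <= 1.0:
                raise ValueError(f"non-physical layer {i} refractive_index")

    @property
    def reduced_scattering(self) -> float:
        return self.scattering_coefficient * (1.0 - self.anisotropy)

    def _arrays(self, depth_cutoff: float):
        """Flatten to the kernel's layer arrays, truncated at depth_cutoff."""
        rows = [(l.thickness, l.absorption_coefficient, l.scattering_coefficient,
                 l.anisotropy, l.refractive_index) for l in self.layers]
        rows.append((np.inf, self.absorption_coefficient, self.scattering_coefficient,
                     self.anisotropy, self.refractive_index))
        z = [0.0]
        mua, mus, g, n = [], [], [], []
        for t, a, s, gg, nn in rows:
            bottom = min(z[-1] + t, depth_cutoff)
            if bottom <= z[-1]:
                continue
            z.append(bottom)
            mua.append(a)
            mus.append(s)
            g.append(gg)
            n.append(nn)
            if bottom >= depth_cutoff:
                break
        z[-1] = depth_cutoff
        if any(a + s <= 0 for a, s in zip(mua, mus)):
            raise ValueError("each layer needs absorption + scattering > 0")
        return (np.array(z), np.array(mua), np.array(mus),
                np.array(g), np.array(n))


def breast_785nm() -> OpticalProperties:
    """Breast-tissue stand-in at 785 nm (see module docstring)."""
    return OpticalProperties(
        absorption_coefficient=0.01,
        scattering_coefficient=10.0,   # reduced scattering 1.0/mm at g=0.9
        anisotropy=0.9,
        refractive_index=1.4,
    )


@dataclass(frozen=True)
class DetectionGeometry:
    """Annular detectors on the surface: S-D offsets and fibre diameter."""

    offsets: tuple = (0.75, 1.57, 2.68, 3.5)
    fibre_diameter: float = 0.1
    reference_offset: float = 0.75

    def __post_init__(self):
        offs = np.asarray(self.offsets, float)
        if offs.size == 0 or np.any(offs <= 0) or np.any(np.diff(offs) <= 0):
            raise ValueError("offsets must be strictly increasing and positive")
        if self.fibre_diameter <= 0:
            raise ValueError("fibre_diameter must be > 0")
        if self.reference_offset <= 0:
            raise ValueError("reference_offset must be > 0")


@dataclass(frozen=True)
class PCECurve:
    """Relative photon collection efficiency vs S-D offset."""

    offsets: np.ndarray
    raw_counts: np.ndarray      # detected weight per unit detector area per photon
    relative_pce: np.ndarray    # percent of the reference-offset value
    fit_params: tuple           # (a, b) of pce = a + b*ln(offset)

    def __post_init__(self):
        if np.any(np.asarray(self.relative_pce) <= 0):
            raise ValueError("relative PCE must be strictly positive; "
                             "increase n_photons")


@dataclass(frozen=True)
class FiberAllocation:
    """Integer fibre counts per ring equalising count x PCE products."""

    counts: tuple
    products: tuple

    @property
    def spread(self) -> float:
        return max(self.products) - min(self.products)


def _run_kernel(props: OpticalProperties, offsets, half_width, n_photons, seed,
                depth_cutoff=DEPTH_CUTOFF):
    z, mua, mus, g, n = props._arrays(depth_cutoff)
    return _mc.mc_kernel(
        int(n_photons), int(seed), z, mua, mus, g, n, 1.0,
        np.asarray(offsets, float), float(half_width),
        W_MIN, P_SURVIVE, MAX_STEPS,
    )


def run_mc_detailed(props: OpticalProperties, geometry: DetectionGeometry,
                    n_photons: int, seed: int) -> dict:
    """Run the transport kernel and return detected weights plus the
    energy ledger (reflected/absorbed/transmitted/roulette buckets)."""
    if n_photons < 10_000:
        raise ValueError("n_photons must be >= 10^4")
    offsets = np.asarray(geometry.offsets, float)
    if geometry.reference_offset not in offsets:
        offsets = np.sort(np.append(offsets, geometry.reference_offset))
    det_w, ledger, det_idx, det_weight, det_depth = _run_kernel(
        props, offsets, geometry.fibre_diameter / 2.0, n_photons, seed
    )
    return {
        "offsets": offsets,
        "detected_weight": det_w,
        "ledger": {
            "reflected": float(ledger[_mc.REFLECTED]),
            "absorbed": float(ledger[_mc.ABSORBED]),
            "transmitted": float(ledger[_mc.TRANSMITTED]),
            "roulette_killed": float(ledger[_mc.ROULETTE_KILLED]),
            "step_killed": float(ledger[_mc.STEP_KILLED]),
            "roulette_boost": float(ledger[_mc.ROULETTE_BOOST]),
            "launched": float(n_photons),
        },
        "det_idx": det_idx,
        "det_weight": det_weight,
        "det_depth": det_depth,
    }


def run_mc(props: OpticalProperties, geometry: DetectionGeometry,
           n_photons: int = 100_000, seed: int = 0) -> PCECurve:
    """Compute the PCE curve for the given detection geometry.

    Detected photon weight is binned by radial exit distance into annuli
    of width equal to the fibre diameter (azimuthal symmetry of the
    normal-incidence pencil beam), normalised per unit annulus area and
    per launched photon, then expressed relative to the reference offset
    (100%). Identical seeds give identical curves.
    """
    res = run_mc_detailed(props, geometry, n_photons, seed)
    offsets_all = res["offsets"]
    d = geometry.fibre_diameter
    areas = np.pi * ((offsets_all + d / 2) ** 2 - (offsets_all - d / 2) ** 2)
    raw = res["detected_weight"] / areas / n_photons
    iref = int(np.argmin(np.abs(offsets_all - geometry.reference_offset)))
    if raw[iref] <= 0:
        raise ValueError("no photons detected at the reference offset; "
                         "increase n_photons")
    rel = 100.0 * raw / raw[iref]
    keep = np.isin(offsets_all, np.asarray(geometry.offsets, float))
    offsets = offsets_all[keep]
    raw, rel = raw[keep], rel[keep]
    fit = fit_log_curve(offsets, rel) if offsets.size >= 2 else (float("nan"),) * 2
    return PCECurve(offsets, raw, rel, tuple(fit[:2]) if offsets.size >= 2 else fit)


def fit_log_curve(offsets, relative_pce):
    """Least-squares fit of pce = a + b*ln(offset); returns (a, b, residuals)."""
    x = np.asarray(offsets, float)
    y = np.asarray(relative_pce, float)
    if x.size < 2 or np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct offsets")
    if np.any(x <= 0):
        raise ValueError("offsets must be positive")
    A = np.column_stack([np.ones_like(x), np.log(x)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return float(coef[0]), float(coef[1]), resid


def allocate_fibers(relative_pce, max_per_ring: int = 8) -> FiberAllocation:
    """Exhaustively search integer fibre counts equalising count x PCE.

    Minimises the spread (max - min) of the per-ring products, tie-broken
    by smallest total fibre count, then lexicographically. With the probe
    PCE values 68.6/45.7/34.3% this returns 2/3/4 fibres per quadrant.
    """
    pce = np.asarray(relative_pce, float)
    if pce.size == 0:
        raise ValueError("empty PCE list")
    if np.any(pce <= 0):
        raise ValueError("relative PCE values must be > 0")
    if max_per_ring < 1:
        raise ValueError("max_per_ring must be >= 1")
    best = None
    for combo in np.ndindex(*(max_per_ring,) * pce.size):
        counts = tuple(c + 1 for c in combo)
        products = tuple(c * p for c, p in zip(counts, pce))
        key = (max(products) - min(products), sum(counts), counts)
        if best is None or key < best[0]:
            best = (key, counts, products)
    return FiberAllocation(best[1], best[2])


@lru_cache(maxsize=32)
def depth_profile(props: OpticalProperties, offset: float,
                  n_photons: int = 100_000, seed: int = 0,
                  fibre_diameter: float = 0.1):
    """Maximum penetration depths and weights of photons detected at one
    annulus. Returns (depths_mm, weights), both 1-D, unordered."""
    det_w, ledger, det_idx, det_weight, det_depth = _run_kernel(
        props, np.array([float(offset)]), fibre_diameter / 2.0, n_photons, seed
    )
    return det_depth.copy(), det_weight.copy()


def depth_contribution(props: OpticalProperties, offset: float,
                       layer_top: float, layer_bottom: float,
                       n_photons: int = 100_000, seed: int = 0,
                       fibre_diameter: float = 0.1) -> float:
    """Fraction of detected weight whose maximum penetration depth lies in
    [layer_top, layer_bottom).

    Fractions over a partition of [0, inf) computed with the same seed
    and inputs sum to exactly 1 (the same detected photon set is
    partitioned).
    """
    if not 0 <= layer_top < layer_bottom:
        raise ValueError("need 0 <= layer_top < layer_bottom (non-degenerate band)")
    depths, weights = depth_profile(props, offset, n_photons, seed, fibre_diameter)
    total = weights.sum()
    if total <= 0:
        raise ValueError("no detected photons at this offset; increase n_photons")
    sel = (depths >= layer_top) & (depths < layer_bottom)
    return float(weights[sel].sum() / total)


def mean_depth_decay_length(props: OpticalProperties, offset: float,
                            n_photons: int = 100_000, seed: int = 0) -> float:
    """Exponential decay length (mm) summarising the max-depth distribution
    of detected photons at one offset (weighted mean depth of an
    exponential equals its decay length). Used to calibrate the fast
    depth-weighting model of the synthetic scan generator."""
    depths, weights = depth_profile(props, offset, n_photons, seed)
    return float(np.average(depths, weights=weights))


__all__ = [
    "OpticalProperties", "Layer", "DetectionGeometry", "PCECurve",
    "FiberAllocation", "breast_785nm", "run_mc", "run_mc_detailed",
    "fit_log_curve", "allocate_fibers", "depth_profile", "depth_contribution",
    "mean_depth_decay_length",
]
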