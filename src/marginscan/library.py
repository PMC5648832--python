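"""Synthetic pure-component spectral library.

The entries are parametric stand-ins for measured pure spectra of the two
breast-tissue classes and the three phantom materials. Band positions are
anchored to the standard fingerprint assignments used in breast Raman
work; widths and relative amplitudes are invented but fixed, and chosen so
the tissue pair reproduces the qualitative contrasts that drive margin
classification:

* fibroadenomatoid (fibro-glandular, protein-rich) vs fatty (lipid-rich):
  a detectable phenylalanine band at 1006 1/cm, a higher 1265/1304 ratio
  (amide III vs CH2 twist), a lower CH2-deformation intensity at 1445
  1/cm, and a broader, left-shouldered amide I band at ~1657 1/cm.
* paraffin: sharp alkane bands (1062, 1133, 1296, 1441 1/cm).
* polymer film / soft paper: PET-like and cellulose-like band sets.

Every entry is rescaled at build time so its pure spectrum has unit AUC
on the default 900-1800 1/cm axis; mixture fractions are then identically
"relative spectral contributions" in the classical-least-squares sense.
"""

from __future__ import annotations

import numpy as np

from .spectral_processing import (
    ComponentLibraryEntry,
    PeakModel,
    Spectrum,
    default_axis,
)

_RAW_PEAKS = {
    # lipid-rich adipose tissue
    "fatty": [
        (1078, 14, 0.30),   # C-C skeletal
        (1265, 16, 0.35),   # =C-H in-plane
        (1304, 14, 0.90),   # CH2 twist
        (1445, 18, 1.00),   # CH2 deformation
        (1657, 16, 0.55),   # C=C stretch
        (1746, 16, 0.30),   # ester C=O
    ],
    # fibro-glandular / fibroepithelial tissue
    "fibroadenomatoid": [
        (1006, 9, 0.35),    # phenylalanine ring breathing
        (1080, 18, 0.25),
        (1265, 18, 0.80),   # amide III
        (1304, 14, 0.50),
        (1340, 16, 0.30),   # CH deformation (protein/nucleic)
        (1445, 18, 0.55),
        (1630, 28, 0.35),   # amide I left shoulder -> broadened band
        (1660, 24, 0.75),   # amide I
    ],
    "paraffin": [
        (1062, 8, 0.55),
        (1133, 8, 0.50),
        (1296, 9, 1.00),
        (1418, 8, 0.35),
        (1441, 10, 0.85),
        (1463, 10, 0.40),
    ],
    "polymer_film": [
        (1096, 12, 0.35),
        (1120, 10, 0.30),
        (1286, 12, 0.45),
        (1614, 8, 1.00),
        (1726, 12, 0.60),
    ],
    "soft_paper": [
        (1095, 14, 0.80),
        (1120, 12, 0.60),
        (1340, 18, 0.45),
        (1378, 14, 0.50),
        (1480, 16, 0.35),
    ],
}

TISSUE_COMPONENTS = ("fatty", "fibroadenomatoid")
PHANTOM_COMPONENTS = ("polymer_film", "soft_paper", "paraffin")


def _build_entry(name: str) -> ComponentLibraryEntry:
    axis = default_axis()
    peaks = [PeakModel(c, w, a) for c, w, a in _RAW_PEAKS[name]]
    raw = ComponentLibraryEntry(name, tuple(peaks))
    area = float(np.trapezoid(raw.profile(axis), axis))
    scaled = tuple(PeakModel(p.center, p.width, p.amplitude / area) for p in peaks)
    return ComponentLibraryEntry(name, scaled)


_CACHE: dict[str, ComponentLibraryEntry] = {}


def component(name: str) -> ComponentLibraryEntry:
    """Return the named library entry (unit AUC on the default axis)."""
    if name not in _RAW_PEAKS:
        raise KeyError(f"unknown component {name!r}; have {sorted(_RAW_PEAKS)}")
    if name not in _CACHE:
        _CACHE[name] = _build_entry(name)
    return _CACHE[name]


def default_library(names=None) -> list[ComponentLibraryEntry]:
    names = list(names) if names is not None else sorted(_RAW_PEAKS)
    return [component(n) for n in names]


def pure_spectrum(name: str, wavenumbers: np.ndarray | None = None) -> Spectrum:
    """Noiseless pure spectrum of one component on the given axis."""
    wn = default_axis() if wavenumbers is None else np.asarray(wavenumbers, float)
    entry = component(name)
    return Spectrum(wn, entry.profile(wn), {"stages": ("raw",), "component": name,
                                            "synthetic": True})


__all__ = [
    "component", "default_library", "pure_spectrum",
    "TISSUE_COMPONENTS", "PHANTOM_COMPONENTS",
]
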