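"""Probe geometry: 36-fibre, 4-quadrant, 3-ring SORS contact probe.

The probe delivers excitation through a central fibre and collects with
detector fibres arranged in three rings (source-detector offsets 1.57,
2.68 and 3.5 mm) split into four quadrants. Fibre counts per ring (2/3/4
per quadrant) equalise the product of fibre count and relative photon
collection efficiency, so all rings reach a comparable signal-to-noise
ratio. Each measurement point therefore yields 12 ring-quadrant spectra,
which the device reduces to one depth-averaged spectrum per point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .spectral_processing import Spectrum, common_axis


@dataclass(frozen=True)
class ProbeGeometry:
    """Contact probe: outer diameter, detector rings and quadrant count."""

    diameter: float = 7.0
    rings: tuple = ((1.57, 2), (2.68, 3), (3.5, 4))
    quadrants: int = 4

    def __post_init__(self):
        if self.diameter <= 0:
            raise ValueError("probe diameter must be > 0")
        offs = [r[0] for r in self.rings]
        if any(np.diff(offs) <= 0):
            raise ValueError("ring offsets must be strictly increasing")
        if any(c < 1 for _, c in self.rings):
            raise ValueError("each ring needs >= 1 fibre per quadrant")

    @property
    def n_rings(self) -> int:
        return len(self.rings)

    @property
    def offsets(self) -> tuple:
        return tuple(r[0] for r in self.rings)

    @property
    def total_fibres(self) -> int:
        return self.quadrants * sum(c for _, c in self.rings)

    @property
    def spectra_per_point(self) -> int:
        return self.quadrants * self.n_rings


DEFAULT_PROBE = ProbeGeometry()


def contact_area(diameter: float) -> float:
    """Contact area (mm^2) of a circular probe tip of the given diameter."""
    if diameter < 0:
        raise ValueError("diameter must be >= 0")
    return math.pi * (diameter / 2.0) ** 2


def estimate_point_count(surface_area: float, probe_diameter: float) -> int:
    """Measurement points needed to tile a surface with probe footprints.

    The budget is surface area divided by the probe contact area, with the
    contact area taken at its displayed precision (0.1 mm^2) and the
    quotient rounded to the nearest integer — e.g. a 5600 mm^2 specimen
    with a 7 mm probe (38.5 mm^2) needs ~145 points, and a 5 cm sphere
    ~204.
    """
    if surface_area <= 0 or probe_diameter <= 0:
        raise ValueError("surface area and probe diameter must be > 0")
    footprint = round(contact_area(probe_diameter), 1)
    return int(round(surface_area / footprint))


@dataclass(frozen=True)
class RingSpectraBundle:
    """The quadrants x rings spectra acquired at one measurement point.

    ``spectra`` maps (quadrant, ring) -> :class:`Spectrum`, with 0-based
    indices; a complete default-probe bundle holds 12 spectra on one axis.
    """

    spectra: dict
    point_id: int = 0
    probe: ProbeGeometry = field(default=DEFAULT_PROBE)

    def __post_init__(self):
        expected = {
            (q, r)
            for q in range(self.probe.quadrants)
            for r in range(self.probe.n_rings)
        }
        got = set(self.spectra)
        if got != expected:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            raise ValueError(
                f"incomplete ring-spectra bundle: missing {missing}, extra {extra}"
            )
        common_axis(self.spectra.values())


def depth_average(bundle: RingSpectraBundle) -> Spectrum:
    """Unweighted mean of the bundle's ring-quadrant spectra.

    Averaging the 12 spectra pools signal from all source-detector offsets
    (hence all sampled depths) into one depth-averaged spectrum per point,
    exactly as the device reduces each acquisition.
    """
    specs = [bundle.spectra[k] for k in sorted(bundle.spectra)]
    axis = common_axis(specs)
    mean = np.mean([s.intensities for s in specs], axis=0)
    meta = {"stages": specs[0].stages, "point_id": bundle.point_id,
            "depth_averaged": True, "n_averaged": len(specs)}
    return Spectrum(axis, mean, meta)


__all__ = [
    "ProbeGeometry", "RingSpectraBundle", "DEFAULT_PROBE",
    "contact_area", "estimate_point_count", "depth_average",
]
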