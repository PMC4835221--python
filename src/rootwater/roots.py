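"""Root-length bookkeeping from soil cores.

Fine-root length measured per depth increment of a core gives a per-volume
density (cm of root per cm³ of soil), a per-ground-area total (cm cm⁻²,
summing a core's increments over its cross-section and averaging replicate
cores), and a cumulative depth distribution (the fraction of total root
length above a given depth, pro-rated linearly inside an increment).
Open-ended bottom increments must be recorded with the depth of refusal as
their bottom boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .isotope import SlopePosition

__all__ = [
    "RootCoreSample",
    "cumulative_fraction",
    "density_per_area",
    "density_per_volume",
]


@dataclass(frozen=True)
class RootCoreSample:
    """Root length recovered from one depth increment of one core."""

    site_id: str
    depth_top_cm: float
    depth_bottom_cm: float
    root_length_cm: float
    core_radius_cm: float
    slope_position: SlopePosition | None = None
    core_id: str | None = None

    def __post_init__(self) -> None:
        if not self.depth_bottom_cm > self.depth_top_cm >= 0:
            raise ValueError(
                f"need depth_bottom > depth_top >= 0, got "
                f"({self.depth_top_cm}, {self.depth_bottom_cm})"
            )
        if self.root_length_cm < 0:
            raise ValueError("root_length_cm must be non-negative")
        if self.core_radius_cm <= 0:
            raise ValueError("core_radius_cm must be positive")

    @property
    def thickness_cm(self) -> float:
        return self.depth_bottom_cm - self.depth_top_cm

    @property
    def area_cm2(self) -> float:
        return math.pi * self.core_radius_cm**2


def density_per_volume(s: RootCoreSample) -> float:
    """Root length density per soil volume: length / (π r² × increment
    thickness), in cm cm⁻³."""
    return s.root_length_cm / (s.area_cm2 * s.thickness_cm)


def density_per_area(cores: Sequence[RootCoreSample]) -> float:
    """Root length per ground surface area (cm cm⁻²): each core's summed
    length over its cross-section, averaged over replicate cores.

    Cores are grouped by ``core_id``; samples without one are treated as a
    single core.  Increments of one core must share a radius.
    """
    samples = list(cores)
    if not samples:
        raise ValueError("no core samples supplied")
    groups: dict[str | None, list[RootCoreSample]] = {}
    for s in samples:
        groups.setdefault(s.core_id, []).append(s)
    totals = []
    for cid, incs in groups.items():
        radii = {s.core_radius_cm for s in incs}
        if len(radii) > 1:
            raise ValueError(
                f"core {cid!r} mixes radii {sorted(radii)}; group increments "
                "by core before aggregating"
            )
        area = incs[0].area_cm2
        totals.append(sum(s.root_length_cm for s in incs) / area)
    return float(np.mean(totals))


def cumulative_fraction(cores: Iterable[RootCoreSample], depth_cm: float) -> float:
    """Fraction of total root length shallower than ``depth_cm``, assuming
    uniform density inside each increment (partial increments pro-rated)."""
    samples = list(cores)
    total = sum(s.root_length_cm for s in samples)
    if total <= 0:
        raise ValueError("undefined fraction: zero total root length")
    above = 0.0
    for s in samples:
        overlap = min(s.depth_bottom_cm, depth_cm) - s.depth_top_cm
        if overlap > 0:
            above += s.root_length_cm * min(overlap / s.thickness_cm, 1.0)
    return above / total
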