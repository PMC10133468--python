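"""Greenwood place-frequency mapping for cochlear-implant electrode arrays.

The cochlea maps acoustic frequency onto position along the basilar membrane.
Greenwood's closed form,

    F(x) = A * (10**(a * x) - K),

gives the characteristic frequency at relative distance ``x`` from the apex
(``x = 0`` apex, ``x = 1`` base).  With the published human constants
(A = 165.4 Hz, a = 2.1, K = 0.88) the map spans roughly 20 Hz at the apex to
20.7 kHz at the base.

Electrode contacts are localised as arc-length distances along the lateral
wall measured from the round window (the basal end), so a contact at
insertion depth ``d`` in a cochlea of duct length ``CDL`` sits at
``x = (CDL - d) / CDL`` and its tonotopic (place) frequency is ``F(x)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GreenwoodParams",
    "LateralWallTrace",
    "ElectrodeGeometry",
    "greenwood_frequency",
    "greenwood_position",
    "insertion_depth",
    "place_frequencies",
]


@dataclass(frozen=True)
class GreenwoodParams:
    """Constants of the Greenwood map ``F(x) = A * (10**(a*x) - K)``.

    Defaults are the published human fit with ``x`` expressed as the
    proportion of cochlear length from the apex.
    """

    A: float = 165.4  # Hz
    a: float = 2.1  # per unit relative distance
    K: float = 0.88  # dimensionless; K < 1 keeps the apex frequency positive

    def __post_init__(self) -> None:
        if not self.A > 0:
            raise ValueError(f"A must be positive, got {self.A}")
        if not self.a > 0:
            raise ValueError(f"a must be positive, got {self.a}")
        if not 0 <= self.K < 1:
            raise ValueError(f"K must lie in [0, 1), got {self.K}")


@dataclass(frozen=True)
class LateralWallTrace:
    """Ordered 3-D polyline along the lateral wall, round window -> helicotrema.

    ``points`` is an (n, 3) array in mm.  Arc length must be strictly
    increasing, i.e. no repeated consecutive vertices.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValueError("trace needs >= 2 points of shape (n, 3)")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError("trace arc length must be strictly increasing")
        object.__setattr__(self, "points", pts)

    @property
    def arc_lengths(self) -> np.ndarray:
        """Cumulative arc length at each vertex, starting at 0 mm."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])


@dataclass(frozen=True)
class ElectrodeGeometry:
    """Per-contact insertion depths (mm from round window) for one ear.

    Contact 1 is the most apical (deepest) contact, contact ``contact_count``
    the most basal; ``insertion_depths[0]`` belongs to contact 1 and depths
    strictly decrease toward the base.
    """

    insertion_depths: np.ndarray  # ordered contact 1 (apical) .. n (basal)
    cochlear_duct_length: float  # mm
    contact_count: int = 16
    subject_id: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        depths = np.asarray(self.insertion_depths, dtype=float)
        if depths.shape != (self.contact_count,):
            raise ValueError(
                f"expected {self.contact_count} depths, got shape {depths.shape}"
            )
        cdl = float(self.cochlear_duct_length)
        if cdl <= 0:
            raise ValueError("cochlear duct length must be positive")
        for i, d in enumerate(depths, start=1):
            if d < 0 or d > cdl:
                raise ValueError(
                    f"contact {i}: depth {d:.3f} mm outside [0, CDL={cdl:.3f}] mm"
                )
        if np.any(np.diff(depths) >= 0):
            raise ValueError("depths must strictly increase toward the apical contact")
        object.__setattr__(self, "insertion_depths", depths)
        object.__setattr__(self, "cochlear_duct_length", cdl)


def greenwood_frequency(x, params: GreenwoodParams = GreenwoodParams()):
    """Characteristic frequency (Hz) at relative distance ``x`` from the apex.

    ``x`` may be a scalar or array; every element must lie in [0, 1].
    """
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("relative distance x must lie in [0, 1]")
    f = params.A * (10.0 ** (params.a * x) - params.K)
    return float(f) if f.ndim == 0 else f


def greenwood_position(frequency, params: GreenwoodParams = GreenwoodParams()):
    """Analytic inverse of :func:`greenwood_frequency`: frequency -> x."""
    f = np.asarray(frequency, dtype=float)
    arg = f / params.A + params.K
    if np.any(arg <= 0):
        raise ValueError("frequency outside the Greenwood range")
    x = np.log10(arg) / params.a
    return float(x) if x.ndim == 0 else x


def insertion_depth(trace: LateralWallTrace, marker) -> float:
    """Arc length (mm) from the round window to the trace point nearest a marker.

    The nearest point is taken on the polyline segments, not only at the
    vertices: for each segment the marker is projected onto the segment
    (clamped to its ends) and the closest projection wins.  Ties between
    segments resolve to the smaller arc length.
    """
    marker = np.asarray(marker, dtype=float).reshape(3)
    pts = trace.points
    p0, p1 = pts[:-1], pts[1:]
    seg = p1 - p0
    seg_len2 = np.einsum("ij,ij->i", seg, seg)
    t = np.clip(np.einsum("ij,ij->i", marker - p0, seg) / seg_len2, 0.0, 1.0)
    proj = p0 + t[:, None] * seg
    dist2 = np.einsum("ij,ij->i", proj - marker, proj - marker)
    best = int(np.argmin(dist2))
    return float(trace.arc_lengths[best] + t[best] * np.sqrt(seg_len2[best]))


def place_frequencies(
    geom: ElectrodeGeometry, params: GreenwoodParams = GreenwoodParams(),
    length_correction: float = 1.0,
) -> np.ndarray:
    """Tonotopic frequency (Hz) for every contact, ordered like the geometry.

    Depths are measured from the round window, so the relative apex distance
    of a contact at depth ``d`` is ``x = (CDL - d) / CDL``; deeper (more
    apical) contacts therefore get lower frequencies.  ``length_correction``
    optionally rescales the lateral-wall distance before mapping (default 1.0:
    the lateral-wall arc length is used as-is).
    """
    cdl = geom.cochlear_duct_length * length_correction
    d = geom.insertion_depths * length_correction
    x = (cdl - d) / cdl
    return greenwood_frequency(x, params)
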