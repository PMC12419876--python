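"""Planar cross-section geometry of the pedicle–attachment bending unit.

A dandelion seed connects to the receptacle through a thin porous pedicle
that emerges from a raised, horseshoe-shaped attachment site.  When the
seed is pulled sideways, the pedicle and the part of the attachment site
that is put into compression bend as one composite unit.  This module
represents that unit as a collection of weighted planar regions and
provides the primitive area / second-moment formulas that the beam
mechanics is built on.

The two materials (stiff pedicle, softer base) are handled with the
classical transformed-section method: base regions enter every integral
with modulus weight 1/beta, where beta = Ep/Eb > 1 is the pedicle-to-base
stiffness ratio.

Conventions
-----------
* lengths in micrometres, areas in µm², second moments in µm⁴;
* the bending axis x points toward the capitulum apex, i.e. the positive
  pull direction; negative x points toward the scape;
* bending is about the lateral axis (perpendicular to the scape–apex
  line), so all second moments are ∫x² dA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

__all__ = [
    "InvalidGeometryError",
    "MorphParams",
    "SectionRegion",
    "CompositeSection",
    "region_area",
    "region_self_moment",
    "engaged_section",
]

Direction = Literal["straight", "positive", "negative"]

#: Shape tags for the primitive regions making up a composite section.
POROUS_DISC = "porous-disc"
RECTANGLE = "rectangle"
SEMI_ELLIPSE = "semi-ellipse"


class InvalidGeometryError(ValueError):
    """Raised for non-positive dimensions or malformed sections."""


@dataclass(frozen=True)
class MorphParams:
    """Morphological parameters of the seed–receptacle attachment.

    Defaults are the measured population means for *Taraxacum officinale*.

    Attributes
    ----------
    L : float
        Seed length (pappus centre to achene tip), µm.  The achene+beak act
        as the rigid lever through which the pull force is applied.
    w : float
        Attachment-site (base) width, µm.
    r : float
        Attachment-site radius on the scape side, µm: the distance from the
        pedicle to the edge of the raised zone.
    c : float
        Pedicle radius, µm.
    k : float
        Pedicle solid fraction in (0, 1]: the load-bearing fraction of the
        pedicle cross-section (the vascular bundle is porous).
    ell : float
        Pedicle length ℓ, µm.  Not reported morphologically; default 200 µm
        keeps L/ℓ = 62 within the slender-lever regime.
    beta : float
        Stiffness ratio Ep/Eb ≥ 1 between pedicle and base material.
    sigma_break : float or None
        Pedicle breaking stress, mN/µm².  Optional; it cancels in every
        force *ratio* and is never needed by this package's computations.
    """

    L: float = 12_400.0
    w: float = 64.0
    r: float = 39.0
    c: float = 18.6
    k: float = 0.33
    ell: float = 200.0
    beta: float = 25.9
    sigma_break: float | None = None

    def __post_init__(self) -> None:
        for name in ("L", "w", "r", "c", "ell"):
            if not getattr(self, name) > 0:
                raise InvalidGeometryError(f"{name} must be strictly positive")
        if not 0 < self.k <= 1:
            raise InvalidGeometryError("k must lie in (0, 1]")
        if not self.beta >= 1:
            raise InvalidGeometryError("beta = Ep/Eb must be >= 1")

    @property
    def pedicle_area(self) -> float:
        """Load-bearing pedicle cross-section A = kπc², µm²."""
        return self.k * math.pi * self.c**2

    def to_config(self) -> dict[str, float]:
        """Flat config mapping (units encoded in the key names)."""
        out = {
            "L_um": self.L,
            "w_um": self.w,
            "r_um": self.r,
            "c_um": self.c,
            "k": self.k,
            "ell_um": self.ell,
            "beta": self.beta,
        }
        if self.sigma_break is not None:
            out["sigma_break"] = self.sigma_break
        return out

    @classmethod
    def from_config(cls, mapping: Mapping[str, float]) -> "MorphParams":
        kwargs = {}
        for key, attr in (
            ("L_um", "L"), ("w_um", "w"), ("r_um", "r"), ("c_um", "c"),
            ("k", "k"), ("ell_um", "ell"), ("beta", "beta"),
            ("sigma_break", "sigma_break"),
        ):
            if key in mapping:
                kwargs[attr] = float(mapping[key])
        return cls(**kwargs)

    def replace(self, **changes: float) -> "MorphParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class SectionRegion:
    """One primitive region of the composite bending section.

    ``dims`` is shape-specific:

    * ``porous-disc``  — ``{"c": radius, "k": solid fraction}``; always the
      pedicle, centred at x = 0 with weight 1.
    * ``rectangle``    — ``{"d": extent along the bending axis x,
      "b": lateral width}``.
    * ``semi-ellipse`` — ``{"a": semi-axis along x, "b": lateral semi-axis,
      "bulge": ±1}``; the flat edge is perpendicular to x and the curved
      side extends a further ``a`` in the ``bulge`` direction.  The centroid
      sits 4a/(3π) from the flat edge toward the bulge.

    ``centroid_x`` is the signed centroid offset along x (µm, positive
    toward the capitulum apex) and ``weight`` the modulus weight (1 for
    pedicle material, 1/beta for base material).
    """

    shape: str
    dims: Mapping[str, float]
    centroid_x: float = 0.0
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.shape not in (POROUS_DISC, RECTANGLE, SEMI_ELLIPSE):
            raise InvalidGeometryError(f"unknown region shape {self.shape!r}")
        if not 0 < self.weight <= 1:
            raise InvalidGeometryError("weight must lie in (0, 1]")
        for key, val in self.dims.items():
            if key == "bulge":
                continue
            if not val > 0:
                raise InvalidGeometryError(f"dimension {key}={val} must be positive")
        object.__setattr__(self, "dims", dict(self.dims))


@dataclass(frozen=True)
class CompositeSection:
    """Weighted planar regions engaged in bending for one pull direction."""

    regions: tuple[SectionRegion, ...]
    direction: Direction

    def __post_init__(self) -> None:
        if not self.regions:
            raise InvalidGeometryError("section must contain at least one region")
        discs = [g for g in self.regions if g.shape == POROUS_DISC]
        if len(discs) != 1 or discs[0].centroid_x != 0.0:
            raise InvalidGeometryError(
                "section must contain exactly one pedicle disc centred at x=0"
            )


def region_area(region: SectionRegion) -> float:
    """Geometric area of a primitive region, µm².

    The modulus weight is *not* applied here; weighting integrals is the
    caller's contract (see :func:`abscission.beam_mechanics.section_moment`).
    """
    d = region.dims
    if region.shape == POROUS_DISC:
        return d["k"] * math.pi * d["c"] ** 2
    if region.shape == RECTANGLE:
        return d["d"] * d["b"]
    if region.shape == SEMI_ELLIPSE:
        return math.pi * d["a"] * d["b"] / 2.0
    raise InvalidGeometryError(f"unknown region shape {region.shape!r}")


def region_self_moment(region: SectionRegion) -> float:
    """Second moment of area ∫x²dA about the region's own centroid, µm⁴.

    Bending is about the lateral axis, so the integration variable is the
    offset along the bending axis x.
    """
    d = region.dims
    if region.shape == POROUS_DISC:
        return d["k"] * math.pi * d["c"] ** 4 / 4.0
    if region.shape == RECTANGLE:
        return d["b"] * d["d"] ** 3 / 12.0
    if region.shape == SEMI_ELLIPSE:
        # πa³b/8 about the flat edge, shifted to the centroid at 4a/(3π).
        return d["a"] ** 3 * d["b"] * (math.pi / 8.0 - 8.0 / (9.0 * math.pi))
    raise InvalidGeometryError(f"unknown region shape {region.shape!r}")


def engaged_section(params: MorphParams, direction: Direction) -> CompositeSection:
    """Composite section that bends as one unit for a given pull direction.

    Only base material on the *compression* side of the bend joins the
    bending unit — the resting achene–base contact cannot transmit tension.

    * ``straight``  — the pedicle disc alone (axisymmetric pull).
    * ``positive``  — pull toward the apex puts the apex-side halves of the
      two base rectangles in compression: pedicle + two c×w half-rectangles
      centred at x = +c/2, weight 1/beta.
    * ``negative``  — pull toward the scape engages the scape-side
      half-rectangles (x = −c/2) plus the semi-elliptical back of the
      horseshoe (semi-axes r along −x and c+w laterally, flat edge at
      x = −c), all with weight 1/beta.
    """
    if direction not in ("straight", "positive", "negative"):
        raise InvalidGeometryError(f"unknown direction {direction!r}")

    pedicle = SectionRegion(POROUS_DISC, {"c": params.c, "k": params.k})
    if direction == "straight":
        return CompositeSection((pedicle,), direction)

    base_weight = 1.0 / params.beta
    sign = 1.0 if direction == "positive" else -1.0
    half_rect = SectionRegion(
        RECTANGLE,
        {"d": params.c, "b": params.w},
        centroid_x=sign * params.c / 2.0,
        weight=base_weight,
    )
    regions = [pedicle, half_rect, half_rect]
    if direction == "negative":
        a = params.r
        regions.append(
            SectionRegion(
                SEMI_ELLIPSE,
                {"a": a, "b": params.c + params.w, "bulge": -1.0},
                centroid_x=-params.c - 4.0 * a / (3.0 * math.pi),
                weight=base_weight,
            )
        )
    return CompositeSection(tuple(regions), direction)
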