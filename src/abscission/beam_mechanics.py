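"""Composite-beam mechanics of directional seed abscission.

A pull force Fa applied at angle θ1 to the original seed axis loads the
pedicle with both a tension component Ft = Fa·cos(|θ1|−|θ2|) and a bending
moment M = Fa·p, where θ2 is the axis angle at the moment of abscission and
p the moment arm.  The seed detaches when the combined stress on the
pedicle's tension edge reaches the (direction-independent) breaking stress:

    σt + σb = σ_break,    σt = Ft/A,    σb = M·y_max/I.

Dividing by the straight-pull case (σ_break = Fas/A) cancels the breaking
stress and gives the directional force ratio

    Fa/Fas = 1 / ( cos(|θ1|−|θ2|) + A·y_max·p / I ),

which in the bending-dominated regime reduces to

    Fa/Fas ≈ I / ( kπc² · y_max · L · sin(|θ1|−|θ2|) ).

Because the horseshoe-shaped attachment site only backs the pedicle on the
scape side, the engaged section — hence the neutral axis, y_max and I —
differs between positive (toward-apex) and negative (toward-scape) pulls.
That geometric asymmetry is the entire source of the directional bias.

Angles are degrees at every public interface and radians internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .section_geometry import (
    CompositeSection,
    Direction,
    InvalidGeometryError,
    MorphParams,
    engaged_section,
    region_area,
    region_self_moment,
)

__all__ = [
    "PullScenario",
    "ForceRatioResult",
    "DEFAULT_THETA2",
    "neutral_axis_offset",
    "section_moment",
    "y_max_of",
    "moment_arm",
    "stress_components",
    "force_ratio_full",
    "force_ratio_approx",
    "validity_check",
]

#: Video-derived abscission angles θ2 (degrees) per pull direction.
DEFAULT_THETA2: dict[str, float] = {"straight": 0.0, "positive": 15.0, "negative": 35.0}


@dataclass(frozen=True)
class PullScenario:
    """A pull direction with its applied-force and abscission angles.

    ``theta1`` is the angle of the applied force to the original seed axis
    and ``theta2`` the axis angle at which the seed actually abscises
    (|θ2| ≤ |θ1|); both in degrees.
    """

    direction: Direction
    theta1: float = 90.0
    theta2: float | None = None

    def __post_init__(self) -> None:
        if self.theta2 is None:
            object.__setattr__(self, "theta2", DEFAULT_THETA2[self.direction])
        if abs(self.theta2) > abs(self.theta1):
            raise ValueError("|theta2| must not exceed |theta1|")

    @property
    def delta_theta_rad(self) -> float:
        """Bend angle |θ1|−|θ2| in radians."""
        return math.radians(abs(self.theta1) - abs(self.theta2))

    @classmethod
    def straight(cls) -> "PullScenario":
        return cls("straight", theta1=0.0, theta2=0.0)


@dataclass(frozen=True)
class ForceRatioResult:
    """Directional force ratio Fa/Fas with its mechanical ingredients.

    ``flags`` are the named model-validity conditions; ``warnings`` lists
    the names of any that failed.
    """

    ratio: float
    y_max: float
    I: float
    p: float
    flags: dict[str, bool] = field(default_factory=dict)

    @property
    def valid(self) -> bool:
        return all(self.flags.values())

    @property
    def warnings(self) -> tuple[str, ...]:
        return tuple(name for name, ok in self.flags.items() if not ok)


def neutral_axis_offset(section: CompositeSection) -> float:
    """Signed neutral-axis offset δ (µm): the modulus-weighted centroid.

    δ = Σ wᵢAᵢxᵢ / Σ wᵢAᵢ over the engaged regions; the sign follows the
    +x (toward-apex) convention.
    """
    wa = [g.weight * region_area(g) for g in section.regions]
    total = sum(wa)
    if total <= 0:
        raise InvalidGeometryError("section has zero weighted area")
    return sum(w * g.centroid_x for w, g in zip(wa, section.regions)) / total


def section_moment(section: CompositeSection, about_x: float) -> float:
    """Modulus-weighted second moment of area I (µm⁴) about ``about_x``.

    Parallel-axis theorem on the transformed section:
    I = Σ wᵢ·(I_selfᵢ + Aᵢ·(xᵢ − about_x)²).
    """
    return sum(
        g.weight
        * (region_self_moment(g) + region_area(g) * (g.centroid_x - about_x) ** 2)
        for g in section.regions
    )


def y_max_of(section: CompositeSection, params: MorphParams) -> float:
    """Distance (µm) from the neutral axis to the pedicle's tension edge.

    A sideways pull puts the pedicle edge *opposite* the pull direction in
    tension (cantilever convention), so y_max = c + |δ| for positive and
    negative pulls, and simply c for a straight pull.  Whether the result
    lies inside the pedicle (c ≤ y_max ≤ 2c) is reported by
    :func:`validity_check`, not raised here.
    """
    if section.direction == "straight":
        return params.c
    return params.c + abs(neutral_axis_offset(section))


def moment_arm(params: MorphParams, scen: PullScenario) -> float:
    """Moment arm p (µm) of the applied force about the pedicle base.

    p = (L+ℓ)·sin(|θ1|−|θ2|): the seed lever of length L+ℓ, bent by
    |θ1|−|θ2| relative to the pull line.  Reduces to the slender-lever
    approximation p ≈ L·sin(|θ1|−|θ2|) when L ≫ ℓ.
    """
    if abs(scen.theta1) < abs(scen.theta2):
        raise ValueError("|theta1| must be at least |theta2|")
    return (params.L + params.ell) * math.sin(scen.delta_theta_rad)


def stress_components(
    F: float,
    params: MorphParams,
    section: CompositeSection,
    scen: PullScenario,
) -> tuple[float, float]:
    """Tension and bending stresses (σt, σb) in mN/µm² for applied force F.

    σt = F·cos(|θ1|−|θ2|)/A with A = kπc², and σb = F·p·y_max/I with I and
    y_max taken from the engaged composite section.
    """
    if not F > 0:
        raise ValueError("F must be positive")
    A = params.pedicle_area
    sigma_t = F * math.cos(scen.delta_theta_rad) / A
    delta = neutral_axis_offset(section)
    I = section_moment(section, delta)
    y_max = y_max_of(section, params)
    p = moment_arm(params, scen)
    sigma_b = F * p * y_max / I
    return sigma_t, sigma_b


def validity_check(
    params: MorphParams, scen: PullScenario, y_max: float
) -> dict[str, bool]:
    """Named boolean conditions under which the model (and the
    bending-dominated approximation) is considered valid.

    * ``slender_lever``   — L/ℓ ≥ 20;
    * ``angle_ratio``     — θ1/θ2 ≥ 3/2;
    * ``bend_angle``      — |θ1|−|θ2| ≥ π/4 (45°);
    * ``y_max_in_pedicle``— c ≤ y_max ≤ 2c (neutral axis inside the pedicle).
    """
    t1, t2 = abs(scen.theta1), abs(scen.theta2)
    return {
        "slender_lever": params.L / params.ell >= 20.0,
        "angle_ratio": (t2 == 0.0) or (t1 / t2 >= 1.5),
        "bend_angle": math.radians(t1 - t2) >= math.pi / 4.0,
        "y_max_in_pedicle": params.c <= y_max <= 2.0 * params.c,
    }


def force_ratio_full(
    params: MorphParams,
    scen: PullScenario,
    *,
    eq32_halfangle: bool = False,
) -> ForceRatioResult:
    """Exact directional force ratio Fa/Fas = 1/(cos Δθ + A·y_max·p/I).

    Derived from σt + σb = σ_break with σ_break = Fas/A, so the breaking
    stress cancels.  ``eq32_halfangle`` switches the tension term to
    cos(Δθ/2) — an alternative reading of the relation that is kept
    available but is not the default (the full-angle form is the one
    consistent with the tension projection and the bending-dominated
    limit).
    """
    section = engaged_section(params, scen.direction)
    delta = neutral_axis_offset(section)
    I = section_moment(section, delta)
    y_max = y_max_of(section, params)
    p = moment_arm(params, scen)
    A = params.pedicle_area
    dtheta = scen.delta_theta_rad
    cos_term = math.cos(dtheta / 2.0) if eq32_halfangle else math.cos(dtheta)
    ratio = 1.0 / (cos_term + A * y_max * p / I)
    flags = validity_check(params, scen, y_max)
    return ForceRatioResult(ratio=ratio, y_max=y_max, I=I, p=p, flags=flags)


def force_ratio_approx(params: MorphParams, scen: PullScenario) -> ForceRatioResult:
    """Bending-dominated force ratio Fa/Fas = I/(kπc²·y_max·L·sin Δθ).

    Valid when the lever is slender and the bend angle large (see
    :func:`validity_check`); the flags on the result record whether that
    regime actually holds for the given inputs.
    """
    section = engaged_section(params, scen.direction)
    delta = neutral_axis_offset(section)
    I = section_moment(section, delta)
    y_max = y_max_of(section, params)
    sin_term = math.sin(scen.delta_theta_rad)
    if sin_term == 0.0:
        raise ZeroDivisionError(
            "force_ratio_approx undefined at theta1 == theta2 (no bending)"
        )
    A = params.pedicle_area
    ratio = I / (A * y_max * params.L * sin_term)
    p = moment_arm(params, scen)
    flags = validity_check(params, scen, y_max)
    return ForceRatioResult(ratio=ratio, y_max=y_max, I=I, p=p, flags=flags)
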