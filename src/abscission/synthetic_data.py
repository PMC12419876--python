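"""Synthetic force measurements and morphology draws.

The raw load-cell data are not bundled with this package, so every
analysis stage can instead run on synthetic data with the same
statistical structure: per angle bin, abscission forces are right-skewed
and strictly positive, which a log-normal reproduces with a closed-form
calibration — choose (µ, σ) so that the distribution's median and
interquartile range equal the published summary exactly:

    µ = ln(median),    σ = ln(Q3/Q1) / (2·z₀.₇₅),   z₀.₇₅ = Φ⁻¹(0.75).

Morphological parameters are drawn from independent normals at the
published means and standard deviations, truncated to their physical
ranges (lengths positive, solid fraction in (0, 1]).

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .robust_stats import ForceSample, samples_to_frame
from .section_geometry import MorphParams

__all__ = [
    "BinSpec",
    "GeneratorConfig",
    "TABLE_BINS",
    "MORPH_MEANS",
    "MORPH_SDS",
    "MORPH_BOOT_ERRORS",
    "calibrate_lognormal",
    "sample_forces",
    "sample_morphology",
    "write_forces_csv",
    "read_forces_csv",
    "load_generator_config",
]

_Z75 = float(stats.norm.ppf(0.75))  # 0.674489750196...

#: Published per-parameter means (µm; k dimensionless).
MORPH_MEANS: dict[str, float] = {"L": 12_400.0, "w": 64.0, "r": 39.0, "c": 18.6, "k": 0.33}
#: Published per-parameter population standard deviations.
MORPH_SDS: dict[str, float] = {"L": 1_000.0, "w": 16.0, "r": 10.0, "c": 5.0, "k": 0.10}
#: Bootstrapped standard errors of the means (c symmetrised from −0.9/+1.0).
MORPH_BOOT_ERRORS: dict[str, float] = {"L": 100.0, "w": 2.0, "r": 2.0, "c": 0.95, "k": 0.05}


@dataclass(frozen=True)
class BinSpec:
    """Target summary for one experiment × angle bin (forces in mN)."""

    experiment: str
    angle_bin: str
    median: float
    q1: float
    q3: float
    n: int

    def __post_init__(self) -> None:
        if not 0 < self.q1 <= self.median <= self.q3:
            raise ValueError("require 0 < q1 <= median <= q3")
        if self.n < 1:
            raise ValueError("n must be at least 1")


#: The nine published experiment × angle bins (median, Q1, Q3 in mN).
#: Per-bin n is an even split of the experiment totals (128 / 75 / 90).
TABLE_BINS: tuple[BinSpec, ...] = (
    BinSpec("sideways", "0", 45.0, 23.0, 68.0, 40),
    BinSpec("sideways", "-90", 1.3, 0.7, 3.2, 40),
    BinSpec("sideways", "+90", 0.26, 0.20, 0.37, 40),
    BinSpec("azimuth", "0", 54.0, 28.0, 83.0, 25),
    BinSpec("azimuth", "~45", 2.3, 1.0, 5.1, 25),
    BinSpec("azimuth", "~90", 0.71, 0.47, 1.08, 25),
    BinSpec("elevation", "0", 47.0, 28.0, 75.0, 30),
    BinSpec("elevation", "acute", 2.0, 0.8, 7.1, 30),
    BinSpec("elevation", "obtuse", 0.30, 0.25, 0.44, 30),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic force/morphology generator."""

    bins: tuple[BinSpec, ...] = TABLE_BINS
    seed: int = 0
    morph_means: Mapping[str, float] = field(default_factory=lambda: dict(MORPH_MEANS))
    morph_sds: Mapping[str, float] = field(default_factory=lambda: dict(MORPH_SDS))
    ell: float = 200.0
    beta: float = 25.9

    def __post_init__(self) -> None:
        if any(sd < 0 for sd in self.morph_sds.values()):
            raise ValueError("morphology spreads must be non-negative")

    def with_bins(self, bins: Iterable[BinSpec]) -> "GeneratorConfig":
        return replace(self, bins=tuple(bins))


def calibrate_lognormal(median: float, q1: float, q3: float) -> tuple[float, float]:
    """Log-normal (µ, σ) matching a published median and quartile spread.

    The log-normal quantile at level p is exp(µ + σ·z_p), so the median
    fixes µ = ln(median) and the interquartile ratio fixes
    σ = ln(Q3/Q1)/(2·z₀.₇₅).  The calibrated distribution reproduces the
    median and the quartile ratio Q3/Q1 exactly; with only two parameters
    the individual quartiles are matched exactly as well whenever the
    median is the geometric mean of Q1 and Q3 (log-symmetric summaries),
    and approximately otherwise.  A degenerate Q3 = Q1 gives σ = 0 (a
    spike at the median).
    """
    if not 0 < q1 <= q3:
        raise ValueError("require 0 < q1 <= q3")
    if q1 > median or median > q3:
        raise ValueError("median must lie within [q1, q3]")
    mu = math.log(median)
    sigma = math.log(q3 / q1) / (2.0 * _Z75)
    return mu, sigma


def sample_forces(config: GeneratorConfig) -> list[ForceSample]:
    """Draw direction-binned abscission forces for every configured bin.

    Each bin contributes ``n`` independent log-normal draws at its
    calibrated (µ, σ).  Bins get independent streams spawned from the
    config seed, so a bin's draws do not depend on the other bins present.
    """
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(len(config.bins))
    out: list[ForceSample] = []
    for spec, stream in zip(config.bins, streams):
        mu, sigma = calibrate_lognormal(spec.median, spec.q1, spec.q3)
        rng = np.random.default_rng(stream)
        forces = np.exp(rng.normal(mu, sigma, size=spec.n))
        out.extend(
            ForceSample(spec.experiment, spec.angle_bin, float(f)) for f in forces
        )
    return out


def sample_morphology(
    n: int,
    config: GeneratorConfig | None = None,
    *,
    sds: Mapping[str, float] | None = None,
    seed: int | None = None,
) -> list[MorphParams]:
    """Draw ``n`` morphology parameter sets from truncated normals.

    Each of L, w, r, c is drawn from N(mean, sd) truncated to (0, ∞); the
    solid fraction k is truncated to (0, 1].  ``sds`` overrides the
    per-parameter spreads (e.g. bootstrapped standard errors of the means
    for error propagation instead of the population SDs).  The pedicle
    length ℓ and stiffness ratio β are held at their configured constants.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    config = config or GeneratorConfig()
    means = dict(config.morph_means)
    spreads = dict(sds if sds is not None else config.morph_sds)
    rng = np.random.default_rng(config.seed if seed is None else seed)

    draws: dict[str, np.ndarray] = {}
    for name in ("L", "w", "r", "c", "k"):
        mean, sd = means[name], spreads[name]
        if sd == 0:
            draws[name] = np.full(n, mean)
            continue
        upper = 1.0 if name == "k" else math.inf
        # Rejection sampling from the truncated normal; acceptance is high
        # for all published mean/SD combinations (worst case k: ~75%).
        vals = np.empty(n)
        filled = 0
        while filled < n:
            cand = rng.normal(mean, sd, size=2 * (n - filled) + 16)
            cand = cand[(cand > 0) & (cand <= upper)]
            take = min(cand.size, n - filled)
            vals[filled : filled + take] = cand[:take]
            filled += take
        draws[name] = vals
    return [
        MorphParams(
            L=float(draws["L"][i]),
            w=float(draws["w"][i]),
            r=float(draws["r"][i]),
            c=float(draws["c"][i]),
            k=float(draws["k"][i]),
            ell=config.ell,
            beta=config.beta,
        )
        for i in range(n)
    ]


def write_forces_csv(samples: Iterable[ForceSample], path: str | Path) -> None:
    """Write force samples as UTF-8 CSV (header experiment,angle_bin,force_mN)."""
    samples_to_frame(samples).to_csv(path, index=False, float_format="%.17g")


def read_forces_csv(path: str | Path) -> list[ForceSample]:
    """Read a force CSV back into samples, validating every row.

    A malformed or non-positive force raises ``ValueError`` naming the
    offending line number (1-based, counting the header as line 1).
    """
    frame = pd.read_csv(
        path, dtype={"experiment": str, "angle_bin": str},
        float_precision="round_trip",
    )
    expected = ["experiment", "angle_bin", "force_mN"]
    if list(frame.columns) != expected:
        raise ValueError(f"expected header {','.join(expected)} in {path}")
    out = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        force = row.force_mN
        if pd.isna(force) or not float(force) > 0:
            raise ValueError(f"{path}: line {i}: force must be a positive number")
        out.append(ForceSample(str(row.experiment), str(row.angle_bin), float(force)))
    return out


def load_generator_config(path: str | Path) -> GeneratorConfig:
    """Load a GeneratorConfig from YAML or JSON.

    Recognised keys: ``seed``, ``ell``, ``beta``, ``morph`` (mapping with
    ``means``/``sds`` sub-mappings over L, w, r, c, k) and ``bins`` (list
    of mappings with experiment, angle_bin, median, q1, q3, n).  Omitted
    keys keep the published defaults.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    for key in ("ell", "beta"):
        if key in raw:
            kwargs[key] = float(raw[key])
    morph = raw.get("morph", {})
    if "means" in morph:
        kwargs["morph_means"] = {**MORPH_MEANS, **{k: float(v) for k, v in morph["means"].items()}}
    if "sds" in morph:
        kwargs["morph_sds"] = {**MORPH_SDS, **{k: float(v) for k, v in morph["sds"].items()}}
    if "bins" in raw:
        kwargs["bins"] = tuple(
            BinSpec(
                experiment=str(b["experiment"]),
                angle_bin=str(b["angle_bin"]),
                median=float(b["median"]),
                q1=float(b["q1"]),
                q3=float(b["q3"]),
                n=int(b["n"]),
            )
            for b in raw["bins"]
        )
    return GeneratorConfig(**kwargs)
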