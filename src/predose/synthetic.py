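"""Synthetic biodistribution generator with known ground-truth kinetics.

Every pipeline stage — aggregation, transposition, curve fitting,
integration, dose computation — can be exercised against data whose true
TIACs are known in closed form.  Region kinetics are sums of decaying
exponentials (exactly the model class the fitting stage assumes); regions
are taken to be disjoint and to collectively cover the body, so the
total-body curve is the sum of the region curves.

The forward model inverts the analysis chain: the true decay-uncorrected
fraction a(rS, t) is decay-corrected, converted to SUV with the phantom
mass ratio, then to %IA/g with each animal's own sampled body mass, and
finally multiplied by unit-mean log-normal measurement noise (counting
measurements are positive with roughly constant coefficient of variation).
Dose-calibrator whole-body readings are derived from the same ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .biodist import pct_ia_per_g_from_suv
from .errors import ValidationError
from .refdata import Phantom

__all__ = ["KineticSpec", "SimulationResult", "simulate_biodist", "spec_from_yaml"]

Components = tuple[tuple[float, float], ...]  # ((amplitude, lambda_b [1/h]), ...)


@dataclass(frozen=True)
class KineticSpec:
    """Ground-truth kinetics and study design for one synthetic experiment.

    Parameters
    ----------
    regions : dict
        Region name -> components ``((c, lambda_b), ...)``: zero-time
        amplitudes (fractions of administered activity) and biological
        clearance rates in 1/h.  Regions are disjoint and cover the body;
        zero-time amplitudes summed over regions may not exceed 1.
    half_life_h : float
        Physical half-life of the radionuclide.
    times_h : sequence
        Measurement schedule (typically from the planning module).
    urinary_fractions : tuple
        Per-total-body-component urinary excretion fractions (bladder model).
    body_mass_mean_g, body_mass_sd_g : float
        Animal body-mass distribution; defaults model a ~25 g mouse cohort.
    noise_cv : float
        Coefficient of variation of the multiplicative log-normal
        measurement noise; 0.05 mimics well-executed ex vivo counting.
    replicates : int
        Animals sacrificed per time point (3 is the customary minimum).
    seed : int
        Seed for the generator; recorded in the output for provenance.
    """

    regions: dict[str, Components]
    half_life_h: float
    times_h: tuple[float, ...]
    urinary_fractions: tuple[float, ...] = ()
    body_mass_mean_g: float = 25.0
    body_mass_sd_g: float = 1.5
    noise_cv: float = 0.05
    replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if not self.regions:
            raise ValidationError("at least one region is required")
        zero_time = 0.0
        for region, components in self.regions.items():
            if not components:
                raise ValidationError(f"region {region!r} has no kinetic components")
            for c, lam_b in components:
                if c < 0:
                    raise ValidationError(f"region {region!r}: amplitudes must be >= 0")
                if lam_b < 0:
                    raise ValidationError(f"region {region!r}: biological rates must be >= 0")
                zero_time += c
        if zero_time > 1 + 1e-9:
            raise ValidationError(
                f"zero-time amplitudes sum to {zero_time} > 1: more than the "
                "administered activity would be in the body at t = 0"
            )
        if not self.half_life_h > 0:
            raise ValidationError("physical half-life must be positive")
        t = np.asarray(self.times_h, dtype=float)
        if t.size < 1 or np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValidationError("times must be positive and strictly increasing")
        if any(f < 0 or f > 1 for f in self.urinary_fractions):
            raise ValidationError("urinary fractions must lie in [0, 1]")
        if sum(self.urinary_fractions) > 1 + 1e-12:
            raise ValidationError("urinary fractions must sum to at most 1")
        if not self.body_mass_mean_g > 0 or self.body_mass_sd_g < 0:
            raise ValidationError("body-mass distribution must have positive mean, SD >= 0")
        if self.noise_cv < 0:
            raise ValidationError("noise CV must be >= 0")
        if self.replicates < 1:
            raise ValidationError("at least one replicate per time point is required")

    @property
    def lambda_p(self) -> float:
        return math.log(2.0) / self.half_life_h

    def decay_corrected_fraction(self, region: str, t) -> np.ndarray:
        """True decay-corrected fraction of administered activity in ``region``."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for c, lam_b in self.regions[region]:
            out = out + c * np.exp(-lam_b * t)
        return out

    def total_body_components(self) -> Components:
        """All components pooled; the total-body curve under full coverage."""
        return tuple(comp for components in self.regions.values() for comp in components)

    def true_tiac(self, region: str) -> float:
        """Closed-form ground-truth TIAC of ``region`` in hours."""
        return sum(c / (lam_b + self.lambda_p) for c, lam_b in self.regions[region])

    def true_tiac_total_body(self) -> float:
        return sum(self.true_tiac(region) for region in self.regions)


@dataclass(frozen=True)
class SimulationResult:
    """Generated tables plus the paired ground truth."""

    biodist: pd.DataFrame  # region, time_h, replicate, value, unit, body_mass_g
    wholebody_ratios: pd.DataFrame  # time_h, reading
    truth: pd.DataFrame  # region, tiac_h  (includes Totalbody)
    spec: KineticSpec
    meta: dict = field(default_factory=dict)


def simulate_biodist(spec: KineticSpec, phantom: Phantom) -> SimulationResult:
    """Generate one synthetic ex vivo biodistribution experiment.

    Each (time point, replicate) pair is one animal with its own sampled
    body mass; all of that animal's regions share the mass.  Region rows are
    emitted in %IA/g.  Whole-body dose-calibrator readings carry the same
    noise model and are decay-uncorrected by construction.  Identical specs
    and seeds produce bit-identical tables.
    """
    for region in spec.regions:
        if region not in phantom.regions:
            raise ValidationError(
                f"kinetic spec region {region!r} is not defined in phantom {phantom.name!r}"
            )
    rng = np.random.default_rng(spec.seed)
    times = np.asarray(spec.times_h, dtype=float)
    sigma = math.sqrt(math.log1p(spec.noise_cv**2))

    def noise(size) -> np.ndarray:
        if sigma == 0.0:
            return np.ones(size)
        # unit-mean log-normal: multiplicative, positive, CV = noise_cv
        return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=size))

    masses = rng.normal(spec.body_mass_mean_g, spec.body_mass_sd_g, size=(times.size, spec.replicates))
    masses = np.clip(masses, 0.1 * spec.body_mass_mean_g, None)

    m_tb = phantom.total_body_mass_g
    rows = []
    for region in spec.regions:
        suv_true = spec.decay_corrected_fraction(region, times) * m_tb / phantom.mass(region)
        eps = noise((times.size, spec.replicates))
        for i, t in enumerate(times):
            for j in range(spec.replicates):
                pct = pct_ia_per_g_from_suv(suv_true[i], masses[i, j]) * eps[i, j]
                rows.append(
                    {
                        "region": region,
                        "time_h": t,
                        "replicate": f"animal_{i}_{j}",
                        "value": pct,
                        "unit": "pct_ia_per_g",
                        "body_mass_g": masses[i, j],
                    }
                )
    biodist = pd.DataFrame(rows)

    # dose-calibrator whole-body readings: decay-uncorrected, T0 included
    tb_components = spec.total_body_components()
    ratio_times = np.concatenate([[0.0], times])
    a_tb = np.zeros_like(ratio_times)
    for c, lam_b in tb_components:
        a_tb = a_tb + c * np.exp(-(lam_b + spec.lambda_p) * ratio_times)
    readings = a_tb * noise(ratio_times.size)
    readings[0] = a_tb[0]  # the T0 reading defines 100% by construction
    ratios = pd.DataFrame({"time_h": ratio_times, "reading": readings})

    truth = pd.DataFrame(
        [{"region": region, "tiac_h": spec.true_tiac(region)} for region in spec.regions]
        + [{"region": "Totalbody", "tiac_h": spec.true_tiac_total_body()}]
    )
    return SimulationResult(
        biodist=biodist,
        wholebody_ratios=ratios,
        truth=truth,
        spec=spec,
        meta={"seed": spec.seed, "phantom": phantom.name, "noise_cv": spec.noise_cv},
    )


def spec_from_yaml(path) -> KineticSpec:
    """Load a :class:`KineticSpec` from a YAML file.

    Layout mirrors the dataclass; region components are lists of
    ``[amplitude, lambda_b]`` pairs::

        regions:
          Liver: [[0.3, 0.05]]
          Carcass: [[0.6, 0.1], [0.1, 0.01]]
        half_life_h: 6.0
        times_h: [1, 3, 6, 12, 24]
    """
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    regions = {
        str(name): tuple((float(c), float(lb)) for c, lb in components)
        for name, components in raw["regions"].items()
    }
    return KineticSpec(
        regions=regions,
        half_life_h=float(raw["half_life_h"]),
        times_h=tuple(float(t) for t in raw["times_h"]),
        urinary_fractions=tuple(float(f) for f in raw.get("urinary_fractions", ())),
        body_mass_mean_g=float(raw.get("body_mass_mean_g", 25.0)),
        body_mass_sd_g=float(raw.get("body_mass_sd_g", 1.5)),
        noise_cv=float(raw.get("noise_cv", 0.05)),
        replicates=int(raw.get("replicates", 3)),
        seed=int(raw.get("seed", 0)),
    )
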