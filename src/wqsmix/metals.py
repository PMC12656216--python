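"""Canonical urinary-metal panel and its distributional calibration.

The package models a prenatal exposure panel of 14 urinary trace metals,
split into eight essential metals (Mg, Cr, Mn, Mo, Co, Cu, Zn, Se) and six
toxic metals (As, Cd, Sb, Hg, Pb, Ni).  Each metal carries a calibration
target for the synthetic-cohort generator: the geometric mean (GM) and
interquartile range (IQR) of its creatinine-adjusted concentration
(µg/g creatinine) observed in the reference pregnancy cohort, and the
assay limit of detection (LOD, µg/L).

Exposures are modelled log-normally.  With median fixed at the GM, the
log-scale standard deviation is the unique sigma solving

    exp(mu + sigma*z75) - exp(mu + sigma*z25) = IQR,   mu = ln(GM),

where z25/z75 are the standard-normal quartiles; ``_solve_log_sigma``
finds it by bracketed one-dimensional root finding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.optimize import brentq
from scipy.stats import norm

__all__ = [
    "MetalSpec",
    "ESSENTIAL_METALS",
    "TOXIC_METALS",
    "CANONICAL_METALS",
    "default_metal_specs",
    "lookup",
]

ESSENTIAL_METALS: tuple[str, ...] = ("Mg", "Cr", "Mn", "Mo", "Co", "Cu", "Zn", "Se")
TOXIC_METALS: tuple[str, ...] = ("As", "Cd", "Sb", "Hg", "Pb", "Ni")
CANONICAL_METALS: tuple[str, ...] = ESSENTIAL_METALS + TOXIC_METALS

# metal -> (group, GM µg/g creatinine, IQR µg/g creatinine, LOD µg/L)
_CALIBRATION: dict[str, tuple[str, float, float, float]] = {
    "Mg": ("essential", 7.43e4, 4.27e4, 2.0),
    "Cr": ("essential", 0.26, 0.21, 0.05),
    "Mn": ("essential", 0.11, 0.23, 0.04),
    "Mo": ("essential", 39.87, 26.78, 0.02),
    "Co": ("essential", 0.35, 0.39, 0.004),
    "Cu": ("essential", 6.71, 4.88, 0.1),
    "Zn": ("essential", 271.80, 233.81, 1.0),
    "Se": ("essential", 26.67, 8.80, 1.0),
    "As": ("toxic", 30.44, 67.62, 0.1),
    "Cd": ("toxic", 0.22, 0.19, 0.02),
    "Sb": ("toxic", 0.05, 0.04, 0.03),
    "Hg": ("toxic", 0.50, 0.63, 0.03),
    "Pb": ("toxic", 0.37, 0.45, 0.07),
    "Ni": ("toxic", 1.70, 1.33, 0.2),
}


@dataclass(frozen=True)
class MetalSpec:
    """Per-metal calibration for simulation and column validation.

    Attributes
    ----------
    name : str
        Element symbol, e.g. ``"Cd"``.
    group : str
        Either ``"essential"`` or ``"toxic"``.
    gm_target : float
        Target geometric mean, µg/g creatinine.
    iqr_target : float
        Target interquartile range, µg/g creatinine.
    lod : float
        Assay limit of detection, µg/L (note: LOD is on the unadjusted
        concentration scale, not per gram creatinine).
    log_sigma : float
        Log-scale SD of the log-normal marginal, derived from the IQR.
    """

    name: str
    group: str
    gm_target: float
    iqr_target: float
    lod: float
    log_sigma: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.group not in ("essential", "toxic"):
            raise ValueError(f"unknown metal group {self.group!r}")
        if self.gm_target <= 0 or self.iqr_target <= 0:
            raise ValueError(f"{self.name}: GM and IQR targets must be positive")
        if self.lod < 0:
            raise ValueError(f"{self.name}: LOD must be non-negative")
        if self.log_sigma == 0.0:
            object.__setattr__(
                self, "log_sigma", _solve_log_sigma(self.gm_target, self.iqr_target)
            )
        if self.log_sigma <= 0:
            raise ValueError(f"{self.name}: log_sigma must be positive")


def _solve_log_sigma(gm: float, iqr: float) -> float:
    """Solve for the log-normal sigma whose quartile spread equals ``iqr``.

    The IQR of LogNormal(ln gm, sigma^2) is gm*(exp(sigma*z75) -
    exp(-sigma*z75)), strictly increasing in sigma, so a sign change
    brackets the root.
    """
    z75 = norm.ppf(0.75)

    def gap(sigma: float) -> float:
        return gm * (math.exp(sigma * z75) - math.exp(-sigma * z75)) - iqr

    lo, hi = 1e-8, 1.0
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 1e3:  # pragma: no cover - unreachable for positive targets
            raise RuntimeError("failed to bracket log_sigma")
    return float(brentq(gap, lo, hi, xtol=1e-12, rtol=1e-14))


def default_metal_specs() -> list[MetalSpec]:
    """The canonical 14-metal panel with its reference-cohort calibration."""
    return [
        MetalSpec(name=m, group=g, gm_target=gm, iqr_target=iqr, lod=lod)
        for m, (g, gm, iqr, lod) in _CALIBRATION.items()
    ]


def lookup(name: str, specs: list[MetalSpec] | None = None) -> MetalSpec:
    """Return the spec for one metal symbol (case-sensitive)."""
    for spec in specs if specs is not None else default_metal_specs():
        if spec.name == name:
            return spec
    raise KeyError(f"unknown metal {name!r}")
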