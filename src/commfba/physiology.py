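"""Physiological parameter estimation from chemostat and microscopy data.

Covers the procedures used to parameterize community simulations from
literature data:

* Pirt partitioning of chemostat substrate uptake into growth and
  maintenance: ``q_S = mu / Y_true + m_S`` fitted by ordinary least squares,
  giving the true biomass yield ``Y_true`` (gDW/mmol) and the maintenance
  uptake ``m_S`` (uptake extrapolated to zero growth, mmol/gDW/h).
* The ATP maintenance coefficient: ``ATPmaint = m_S * Y_ATP_max`` where the
  maximum ATP yield on the substrate is computed from the stoichiometric
  model at zero growth.
* Cell-geometry dry weights: ``m = 435 * V**0.85`` (m in fg, V in um^3) with
  sphere and capped-rod volumes, used to convert cell-count ratios into
  biomass-fraction compositions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from . import core
from .community import CommunityComposition

logger = logging.getLogger(__name__)

DRY_WEIGHT_COEF = 435.0
DRY_WEIGHT_EXP = 0.85


@dataclass
class ChemostatSeries:
    """Paired (growth rate mu [1/h], specific uptake q_S [mmol/gDW/h])."""

    mu: Tuple[float, ...]
    q_s: Tuple[float, ...]

    def __post_init__(self):
        self.mu = tuple(float(x) for x in self.mu)
        self.q_s = tuple(float(x) for x in self.q_s)
        if len(self.mu) != len(self.q_s):
            raise ValueError("mu and q_s must have equal length")
        if len(set(self.mu)) < 2:
            raise ValueError("need at least 2 distinct growth rates")
        if any(x < 0 for x in self.mu + self.q_s):
            raise ValueError("rates must be nonnegative")


@dataclass
class MaintenanceEstimate:
    true_yield: float          # gDW/mmol
    maintenance_uptake: float  # mmol/gDW/h, uptake at zero growth
    atp_maintenance: Optional[float] = None  # mmol ATP/gDW/h


def pirt_fit(series: ChemostatSeries) -> MaintenanceEstimate:
    """Least-squares fit of ``q_S = mu / Y_true + m_S``.

    The slope is the inverse true yield; the intercept is the maintenance
    substrate uptake.  A negative intercept is clipped to zero with a warning
    (maintenance uptake cannot be negative).
    """
    fit = stats.linregress(series.mu, series.q_s)
    if fit.slope <= 0:
        raise ValueError(
            f"non-positive slope {fit.slope:.3g}: uptake must increase with growth"
        )
    m_s = fit.intercept
    if m_s < 0:
        logger.warning("negative maintenance intercept %.3g clipped to 0", m_s)
        m_s = 0.0
    return MaintenanceEstimate(true_yield=1.0 / fit.slope, maintenance_uptake=m_s)


def atp_maintenance(
    m_s: float,
    model: core.StoichiometricModel,
    substrate_rxn: str,
    atp_rxn: str,
    biomass_rxn: Optional[str] = None,
) -> float:
    """ATPmaint = substrate uptake at zero growth x maximum ATP yield.

    The maximum ATP yield (mol ATP per mol substrate) is the maximum of the
    ATP-hydrolysis flux per substrate uptake, with growth fixed to zero when
    a biomass reaction is given.
    """
    y_atp = max_atp_yield(model, substrate_rxn, atp_rxn, biomass_rxn)
    return m_s * y_atp


def max_atp_yield(
    model: core.StoichiometricModel,
    substrate_rxn: str,
    atp_rxn: str,
    biomass_rxn: Optional[str] = None,
) -> float:
    """Maximum ATP-hydrolysis flux per unit substrate uptake at zero growth."""
    work = model.copy()
    if biomass_rxn is not None:
        rxn = work.reactions[biomass_rxn]
        rxn.lb = 0.0
        rxn.ub = 0.0
    work.reactions[atp_rxn].ub = math.inf
    return core.fractional_extremum(work, {atp_rxn: 1.0}, {substrate_rxn: 1.0}, "max")


def atp_maintenance_from_yield(m_s: float, y_atp_max: float) -> float:
    """ATPmaint from an already known maximum ATP yield (mol/mol)."""
    return m_s * y_atp_max


def species_atp_maintenance(per_substrate: Iterable[float]) -> float:
    """Species-level ATPmaint: unweighted mean over substrate estimates."""
    values = list(per_substrate)
    if not values:
        raise ValueError("need at least one per-substrate estimate")
    return float(np.mean(values))


def cell_volume(shape: str, diameter: float, length: Optional[float] = None) -> float:
    """Cell volume in um^3 for a sphere or a rod.

    A rod is a cylinder with hemispherical caps; ``length`` is the total
    length including caps, so the cylindrical section has length
    ``length - diameter``.  A rod with ``length == diameter`` degenerates to
    a sphere.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    sphere = math.pi * diameter**3 / 6.0
    if shape == "sphere":
        return sphere
    if shape == "rod":
        if length is None:
            raise ValueError("rod shape needs a length")
        if length < diameter:
            raise ValueError("rod length must be >= diameter")
        return math.pi * (diameter / 2.0) ** 2 * (length - diameter) + sphere
    raise ValueError(f"unknown shape {shape!r}")


def dry_weight(volume: float) -> float:
    """Cell dry weight in fg from volume in um^3: ``435 * V**0.85``."""
    if volume <= 0:
        raise ValueError("volume must be positive")
    return DRY_WEIGHT_COEF * volume**DRY_WEIGHT_EXP


def counts_to_fractions(
    counts: Sequence[float], dry_weights: Sequence[float]
) -> CommunityComposition:
    """Convert cell counts and per-cell dry weights into biomass fractions."""
    if len(counts) != len(dry_weights):
        raise ValueError("counts and dry_weights must have equal length")
    mass = np.asarray(counts, dtype=float) * np.asarray(dry_weights, dtype=float)
    if mass.sum() <= 0:
        raise ValueError("total biomass must be positive")
    return CommunityComposition(tuple(mass / mass.sum()))
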