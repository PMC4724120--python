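"""Core stoichiometric data model and the linear-programming contract.

A :class:`StoichiometricModel` is the in-memory form of a constraint-based
metabolic model: metabolites (rows of the stoichiometric matrix ``N``),
reactions (columns, each with flux bounds ``lb <= r <= ub``), and a linear
objective ``c``.  Flux balance analysis (FBA) maximizes or minimizes
``c^T r`` subject to the steady-state balance ``N r = 0`` on internal
metabolites and the flux bounds.  Boundary metabolites are excluded from the
balance and may accumulate.

All LPs are solved with the HiGHS solvers in :func:`scipy.optimize.linprog`.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import linprog

logger = logging.getLogger(__name__)

#: Numerical tolerance used for feasibility checks on returned solutions.
FEASIBILITY_TOL = 1e-9
#: Relative tolerance for comparing LP optima.
OPTIMALITY_TOL = 1e-6

Objective = Union[str, Mapping[str, float]]


class InfeasibleError(RuntimeError):
    """The LP (after fixing/blocking fluxes) has an empty feasible region."""


class UnboundedError(RuntimeError):
    """The LP objective is unbounded on the feasible region."""


class ModelConsistencyError(ValueError):
    """The model violates a structural invariant (ids, bounds, references)."""


@dataclass
class Metabolite:
    """A chemical species.  Boundary metabolites are exempt from balancing."""

    id: str
    name: str = ""
    compartment: str = "c"
    is_boundary: bool = False


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds.

    ``stoichiometry`` maps metabolite ids to signed coefficients
    (negative = consumed).  Rates are in mmol/gDW/h except biomass-producing
    reactions (gDW/gDW/h) and a community growth reaction (1/h).
    """

    id: str
    stoichiometry: Dict[str, float]
    lb: float = 0.0
    ub: float = math.inf
    reversible: bool = False
    name: str = ""

    def validate(self) -> None:
        if self.lb > self.ub:
            raise ModelConsistencyError(
                f"reaction {self.id!r}: lb {self.lb} > ub {self.ub}"
            )
        if not self.reversible and self.lb < 0:
            raise ModelConsistencyError(
                f"reaction {self.id!r}: irreversible but lb {self.lb} < 0"
            )

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lb=self.lb,
            ub=self.ub,
            reversible=self.reversible,
            name=self.name,
        )


class StoichiometricModel:
    """Ordered collections of metabolites and reactions plus an objective.

    The implied stoichiometric matrix has one row per *internal* (non
    boundary) metabolite and one column per reaction, in insertion order.
    """

    def __init__(self, model_id: str = "model"):
        self.id = model_id
        self.metabolites: Dict[str, Metabolite] = {}
        self.reactions: Dict[str, Reaction] = {}
        self.objective: Dict[str, float] = {}

    # -- construction -----------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if met.id in self.metabolites:
            raise ModelConsistencyError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met
        return met

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if rxn.id in self.reactions:
            raise ModelConsistencyError(f"duplicate reaction id {rxn.id!r}")
        rxn.validate()
        for mid in rxn.stoichiometry:
            if mid not in self.metabolites:
                raise ModelConsistencyError(
                    f"reaction {rxn.id!r} references unknown metabolite {mid!r}"
                )
        self.reactions[rxn.id] = rxn
        return rxn

    # -- views ------------------------------------------------------------
    @property
    def internal_metabolite_ids(self) -> list:
        return [m.id for m in self.metabolites.values() if not m.is_boundary]

    @property
    def reaction_ids(self) -> list:
        return list(self.reactions)

    def stoichiometric_matrix(self) -> Tuple[np.ndarray, list, list]:
        """Dense ``N`` over internal metabolites: (N, row ids, column ids)."""
        rows = self.internal_metabolite_ids
        cols = self.reaction_ids
        row_index = {m: i for i, m in enumerate(rows)}
        N = np.zeros((len(rows), len(cols)))
        for j, rid in enumerate(cols):
            for mid, coef in self.reactions[rid].stoichiometry.items():
                i = row_index.get(mid)
                if i is not None:
                    N[i, j] = coef
        return N, rows, cols

    def copy(self) -> "StoichiometricModel":
        m = StoichiometricModel(self.id)
        for met in self.metabolites.values():
            m.metabolites[met.id] = Metabolite(
                met.id, met.name, met.compartment, met.is_boundary
            )
        for rxn in self.reactions.values():
            m.reactions[rxn.id] = rxn.copy()
        m.objective = dict(self.objective)
        return m

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<StoichiometricModel {self.id}: {len(self.reactions)} reactions, "
            f"{len(self.metabolites)} metabolites>"
        )


@dataclass
class FluxDistribution:
    """A solved flux vector with its objective value and solver status."""

    fluxes: Dict[str, float]
    objective_value: float
    status: str  # "optimal" | "infeasible" | "unbounded"

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]

    def to_csv(self, path) -> None:
        """Write the distribution as two-column CSV (reaction_id, flux)."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["reaction_id", "flux"])
            for rid, v in self.fluxes.items():
                writer.writerow([rid, f"{v:.6g}"])


def _objective_vector(model: StoichiometricModel, objective: Objective) -> np.ndarray:
    cols = model.reaction_ids
    c = np.zeros(len(cols))
    if isinstance(objective, str):
        coeffs: Mapping[str, float] = {objective: 1.0}
    else:
        coeffs = objective
    index = {rid: j for j, rid in enumerate(cols)}
    for rid, w in coeffs.items():
        if rid not in index:
            raise ModelConsistencyError(f"objective references unknown reaction {rid!r}")
        c[index[rid]] = w
    return c


_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def fba(
    model: StoichiometricModel,
    objective: Optional[Objective] = None,
    sense: str = "max",
) -> FluxDistribution:
    """Flux balance analysis: optimize ``c^T r`` s.t. ``N r = 0``, bounds.

    Parameters
    ----------
    objective:
        Reaction id or mapping reaction id -> coefficient.  Defaults to the
        model's stored objective.
    sense:
        ``"max"`` or ``"min"``.

    Infeasibility and unboundedness are reported in the returned
    :class:`FluxDistribution.status`, never as a silent zero.
    """
    if objective is None:
        objective = model.objective
    if not objective:
        raise ModelConsistencyError("no objective given and model has none")
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")

    N, _, cols = model.stoichiometric_matrix()
    c = _objective_vector(model, objective)
    sign = -1.0 if sense == "max" else 1.0
    bounds = [(model.reactions[rid].lb, model.reactions[rid].ub) for rid in cols]
    b_eq = np.zeros(N.shape[0]) if N.shape[0] else None
    res = linprog(
        sign * c,
        A_eq=N if N.shape[0] else None,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
    )
    status = _STATUS.get(res.status, "infeasible")
    if status != "optimal":
        return FluxDistribution({}, math.nan, status)
    fluxes = {rid: float(res.x[j]) for j, rid in enumerate(cols)}
    return FluxDistribution(fluxes, float(c @ res.x), "optimal")


def flux_extremum(
    model: StoichiometricModel,
    target: Objective,
    fixed: Iterable[Tuple[str, float]] = (),
    sense: str = "max",
) -> float:
    """Extremal value of a flux (or linear flux combination) after fixing others.

    ``fixed`` is an iterable of ``(reaction_id, value)`` pairs imposed as
    equality bounds.  Raises :class:`InfeasibleError` if fixing empties the
    feasible region and :class:`UnboundedError` on an unbounded objective.
    """
    work = model.copy()
    for rid, value in fixed:
        rxn = work.reactions[rid]
        rxn.lb = value
        rxn.ub = value
    sol = fba(work, target, sense)
    if sol.status == "infeasible":
        raise InfeasibleError(f"no feasible flux after fixing {dict(fixed)!r}")
    if sol.status == "unbounded":
        raise UnboundedError(f"extremum of {target!r} is unbounded")
    return sol.objective_value


def fractional_extremum(
    model: StoichiometricModel,
    numerator: Mapping[str, float],
    denominator: Mapping[str, float],
    sense: str = "max",
) -> float:
    """Optimize a ratio of flux combinations via the Charnes-Cooper transform.

    Solves ``opt (num . r) / (den . r)`` over the flux polyhedron with the
    substitution ``y = t r``, ``den . y = 1``, ``t >= 0``; each finite bound
    ``lb <= r <= ub`` becomes ``lb t <= y <= ub t``.  Exact (one LP, no
    iteration).  The denominator must be able to take positive values.
    """
    N, _, cols = model.stoichiometric_matrix()
    n = len(cols)
    num = _objective_vector(model, dict(numerator))
    den = _objective_vector(model, dict(denominator))

    # variables: y_0..y_{n-1}, t
    n_int = N.shape[0]
    A_eq = np.zeros((n_int + 1, n + 1))
    if n_int:
        A_eq[:n_int, :n] = N
    A_eq[n_int, :n] = den
    b_eq = np.zeros(n_int + 1)
    b_eq[n_int] = 1.0

    rows_ub = []
    rhs_ub = []
    for j, rid in enumerate(cols):
        rxn = model.reactions[rid]
        if math.isfinite(rxn.lb):
            row = np.zeros(n + 1)
            row[j] = -1.0
            row[n] = rxn.lb
            rows_ub.append(row)  # lb*t - y <= 0
            rhs_ub.append(0.0)
        if math.isfinite(rxn.ub):
            row = np.zeros(n + 1)
            row[j] = 1.0
            row[n] = -rxn.ub
            rows_ub.append(row)  # y - ub*t <= 0
            rhs_ub.append(0.0)
    A_ub = np.vstack(rows_ub) if rows_ub else None
    b_ub = np.array(rhs_ub) if rows_ub else None

    sign = -1.0 if sense == "max" else 1.0
    c = np.concatenate([sign * num, [0.0]])
    bounds = [(None, None)] * n + [(0.0, None)]
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs"
    )
    status = _STATUS.get(res.status, "infeasible")
    if status == "infeasible":
        raise InfeasibleError("fractional program infeasible (denominator cannot be 1)")
    if status == "unbounded":
        raise UnboundedError("fractional objective unbounded")
    return float(num @ res.x[:n])


def max_yield(
    model: StoichiometricModel,
    biomass_rxn: str,
    substrate_rxn: str,
    blocked: Iterable[str] = (),
    fixed_growth: Optional[float] = None,
    maintenance_rxn: Optional[str] = None,
) -> float:
    """Maximum biomass yield (gDW per mmol substrate) on one substrate.

    With ``fixed_growth`` absent the *true* yield is returned: the
    maintenance flux lower bound is relaxed to zero and the ratio
    biomass rate / substrate uptake is maximized exactly (fractional LP).
    With ``fixed_growth`` given, maintenance stays active and the yield is
    the growth rate divided by the minimal substrate uptake supporting it
    (the growth-rate-dependent apparent yield).

    ``blocked`` lists other substrate uptake reactions forced to zero so the
    chosen substrate is the sole one among the configured substrates.
    """
    work = model.copy()
    for rid in blocked:
        rxn = work.reactions[rid]
        rxn.lb = 0.0
        rxn.ub = 0.0
    uptake = work.reactions[substrate_rxn]
    if uptake.ub <= 0:
        raise InfeasibleError(f"substrate reaction {substrate_rxn!r} allows no uptake")

    if fixed_growth is None:
        if maintenance_rxn is not None:
            work.reactions[maintenance_rxn].lb = 0.0
        try:
            return fractional_extremum(
                work, {biomass_rxn: 1.0}, {substrate_rxn: 1.0}, sense="max"
            )
        except InfeasibleError as exc:
            raise InfeasibleError(
                f"substrate {substrate_rxn!r} does not support growth"
            ) from exc

    growth = work.reactions[biomass_rxn]
    growth.lb = fixed_growth
    growth.ub = fixed_growth
    try:
        min_uptake = flux_extremum(work, substrate_rxn, sense="min")
    except InfeasibleError as exc:
        raise InfeasibleError(
            f"substrate {substrate_rxn!r} does not support growth rate {fixed_growth}"
        ) from exc
    if min_uptake <= FEASIBILITY_TOL:
        # zero growth with zero maintenance: fall back to the true yield
        return max_yield(
            model, biomass_rxn, substrate_rxn, blocked, None, maintenance_rxn
        )
    return fixed_growth / min_uptake
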