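"""Composition-simplex and growth-rate scans.

Sweeps the lattice of community compositions (default step 0.01) and, per
point, evaluates feasibility, the maximum community growth rate, the
optimality degree, and extremal product rates/yields (e.g. minimum methane
production rate and minimum methane yield referred to the primary
substrate).  Results are returned as a tidy :class:`pandas.DataFrame`, one
row per evaluated (composition, growth rate) pair; infeasible cells are
flagged explicitly and carry NaN metrics rather than being dropped.

The minimum product *yield* is a linear-fractional program (product export
over reference-substrate uptake) solved exactly by the Charnes-Cooper
transformation; a bisection fallback is provided for cross-checking.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import core
from .community import CommunityComposition, CommunityModel
from .hierarchy import OPTDEG_TOL, optdeg, max_community_growth

#: Significant digits used when exporting scan metrics.
EXPORT_DIGITS = 6


def simplex_grid(n_species: int, step: float = 0.01) -> List[CommunityComposition]:
    """All compositions on the ``step`` lattice with fractions summing to 1.

    ``step`` must divide 1 (e.g. 0.01 gives 101 compositions for two species
    and 5151 for three).
    """
    k = round(1.0 / step)
    if abs(k * step - 1.0) > 1e-9:
        raise ValueError(f"step {step} does not divide 1")
    grid = []
    for combo in itertools.combinations_with_replacement(range(n_species), k):
        counts = [0] * n_species
        for i in combo:
            counts[i] += 1
        grid.append(CommunityComposition([c / k for c in counts]))
    grid.sort(key=lambda F: tuple(F))
    return grid


def min_product_rate(
    cm: CommunityModel, F, mu_c: float, product: str
) -> float:
    """Minimum environment-export rate of a pool metabolite at fixed
    ``(F, mu_C)`` (mmol/gDW_C/h).  Raises
    :class:`~commfba.core.InfeasibleError` if the point is infeasible."""
    rid = cm.env_export.get(product)
    if rid is None:
        raise ValueError(f"product {product!r} has no environment export (policy)")
    model = cm.instantiate(F)
    return core.flux_extremum(
        model, rid, fixed=[(cm.community_rxn, mu_c)], sense="min"
    )


def _yield_model(cm: CommunityModel, F, mu_c: float):
    model = cm.instantiate(F)
    growth = model.reactions[cm.community_rxn]
    growth.lb = mu_c
    growth.ub = mu_c
    return model


def min_product_yield(
    cm: CommunityModel,
    F,
    mu_c: float,
    product: str,
    reference_substrate: str,
) -> float:
    """Minimum product yield (mol product per mol reference substrate) over
    the feasible set at fixed ``(F, mu_C)``, via Charnes-Cooper.

    The reference substrate must be a medium metabolite with positive uptake
    at the point; a zero-uptake denominator raises
    :class:`~commfba.core.InfeasibleError` (the yield is undefined there).
    """
    export = cm.env_export.get(product)
    uptake = cm.env_uptake.get(reference_substrate)
    if export is None:
        raise ValueError(f"product {product!r} has no environment export")
    if uptake is None:
        raise ValueError(f"{reference_substrate!r} is not a medium metabolite")
    model = _yield_model(cm, F, mu_c)
    return core.fractional_extremum(model, {export: 1.0}, {uptake: 1.0}, "min")


def min_ratio_bisection(
    model,
    numerator: Dict[str, float],
    denominator: Dict[str, float],
    lo: float = 0.0,
    hi: float = 100.0,
    tol: float = 1e-6,
) -> float:
    """Bisection alternative to Charnes-Cooper: a ratio ``gamma`` is
    attainable iff the polyhedron admits a flux vector with
    ``num . r - gamma * den . r <= 0`` (and positive denominator).  Each
    bracket step is a plain feasibility LP, making this an independent
    cross-check of :func:`min_product_yield`."""
    from scipy.optimize import linprog

    N, _, cols = model.stoichiometric_matrix()
    index = {rid: j for j, rid in enumerate(cols)}
    num = np.zeros(len(cols))
    den = np.zeros(len(cols))
    for rid, w in numerator.items():
        num[index[rid]] = w
    for rid, w in denominator.items():
        den[index[rid]] = w
    bounds = [(model.reactions[rid].lb, model.reactions[rid].ub) for rid in cols]

    def feasible(gamma: float) -> bool:
        res = linprog(
            np.zeros(len(cols)),
            A_ub=np.vstack([num - gamma * den, -den]),
            b_ub=np.array([0.0, -tol]),
            A_eq=N if N.shape[0] else None,
            b_eq=np.zeros(N.shape[0]) if N.shape[0] else None,
            bounds=bounds,
            method="highs",
        )
        return res.status == 0

    if not feasible(hi):
        raise core.InfeasibleError("no feasible ratio below upper bracket")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if feasible(mid):
            hi = mid
        else:
            lo = mid
    return hi


def scan(
    cm: CommunityModel,
    grid: Sequence[CommunityComposition],
    mu_c_values: Union[str, Sequence[float]] = "max",
    product: Optional[str] = None,
    reference_substrate: Optional[str] = None,
) -> pd.DataFrame:
    """Evaluate every grid composition (and growth rate, if a list is given).

    With ``mu_c_values="max"`` each composition is evaluated at its maximum
    community growth rate; with a list of rates, each (F, mu_C) pair is
    evaluated at that fixed rate (infeasible pairs flagged).  When
    ``product`` is given, the minimum product export rate is computed per
    feasible cell, and additionally the minimum product yield when
    ``reference_substrate`` is given.
    """
    cache: Dict = {}
    rows = []
    for F in grid:
        mu_max = max_community_growth(cm, F)
        mu_list = [mu_max] if mu_c_values == "max" else list(mu_c_values)
        for mu in mu_list:
            row = {f"F_{sid}": f for sid, f in zip(cm.species_ids, F)}
            row["mu_C"] = mu
            row["mu_C_max"] = mu_max
            feasible = mu_max > core.FEASIBILITY_TOL and mu <= mu_max + 1e-9
            result = None
            if feasible and mu > core.FEASIBILITY_TOL:
                result = optdeg(cm, F, mu, cache=cache)
                feasible = result.feasible
            row["feasible"] = feasible
            row["optdeg"] = result.optdeg if result is not None and feasible else math.nan
            row["z_opt"] = result.z_opt if result is not None and feasible else math.nan
            if product is not None:
                rate = yld = math.nan
                if feasible:
                    try:
                        rate = min_product_rate(cm, F, mu, product)
                    except core.InfeasibleError:
                        pass
                    if reference_substrate is not None:
                        try:
                            yld = min_product_yield(
                                cm, F, mu, product, reference_substrate
                            )
                        except (core.InfeasibleError, core.UnboundedError):
                            pass
                row["min_product_rate"] = rate
                if reference_substrate is not None:
                    row["min_product_yield"] = yld
            rows.append(row)
    return pd.DataFrame(rows)


def locate_optima(grid_df: pd.DataFrame, tol: float = OPTDEG_TOL) -> pd.DataFrame:
    """Rows whose OptDeg reaches 1 within ``tol`` (the predicted operation
    points).  All ties are reported: with functionally redundant species the
    optimum is a line or region of compositions, not a single point."""
    mask = grid_df["feasible"] & (grid_df["optdeg"] >= 1.0 - tol)
    return grid_df[mask].reset_index(drop=True)


def predicted_operation_points(
    grid_df: pd.DataFrame, tol: float = OPTDEG_TOL, tie_tol: float = 1e-6
) -> pd.DataFrame:
    """The predicted operation point(s): compositions with OptDeg = 1 when
    any lattice point attains it, otherwise the maximum-OptDeg lattice
    point(s) (ties within ``tie_tol`` all reported)."""
    at_one = locate_optima(grid_df, tol)
    if len(at_one):
        return at_one
    feas = grid_df[grid_df["feasible"]]
    if not len(feas):
        return feas.reset_index(drop=True)
    best = feas["optdeg"].max()
    return feas[feas["optdeg"] >= best - tie_tol].reset_index(drop=True)


def write_grid(grid_df: pd.DataFrame, csv_path=None, json_path=None) -> None:
    """Export a scan as tidy CSV and/or JSON with fixed precision."""
    fmt = f"%.{EXPORT_DIGITS}g"
    if csv_path is not None:
        grid_df.to_csv(csv_path, index=False, float_format=fmt)
    if json_path is not None:
        rounded = grid_df.copy()
        for col in rounded.columns:
            if rounded[col].dtype.kind == "f":
                rounded[col] = rounded[col].map(
                    lambda v: float(fmt % v) if math.isfinite(v) else None
                )
        rounded.to_json(json_path, orient="records", indent=1)
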