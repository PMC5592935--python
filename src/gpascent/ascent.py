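"""Steepest ascent (and descent) along a fitted first-order response model.

Given a first-order fit on coded variables, the basis factor is the one with
the largest absolute slope; the researcher chooses its natural-unit step
(e.g. 0.25 for a proportion-type factor).  Every other factor's coded step
is tied to the basis by the ratio of fitted coefficients,

    step_i = (b_i / b_basis) * step_basis    (coded units),

so the path moves along the fitted gradient.  Coded steps convert back to
natural increments through each factor's half-range, and path coordinates
are base + k * Delta, rounded (counts to integers, proportions to two
decimals) and clamped to each factor's operability region.

Two rounding conventions are provided.  The default keeps full precision
everywhere and only rounds for presentation.  The compatibility mode
reproduces hand-computed tables: coded steps may be rounded to a fixed
number of decimals before forming increments, and each non-integer
increment is then rounded to two significant figures before accumulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .doe import (
    CodedDesign,
    Factor,
    FirstOrderFit,
    decode_value,
    fit_first_order,
    full_factorial,
    half_fraction,
)
from .errors import ConfigurationError, ConvergenceSignal

__all__ = [
    "AscentPath",
    "AscentResult",
    "choose_basis",
    "coded_step_sizes",
    "natural_increments",
    "path_coordinates",
    "evaluate_path",
    "build_path",
    "run_ascent",
    "round_sig",
]


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def choose_basis(fit: FirstOrderFit, override: str | None = None) -> str:
    """The factor with the largest absolute fitted slope (unless overridden)."""
    if override is not None:
        if override not in fit.slopes:
            raise ConfigurationError(f"unknown factor {override!r}")
        return override
    if all(b == 0.0 for b in fit.slopes.values()):
        raise ConvergenceSignal("all slopes are zero: no direction of improvement")
    return max(fit.slopes, key=lambda k: abs(fit.slopes[k]))


def coded_step_sizes(
    fit: FirstOrderFit,
    basis: str,
    basis_step_natural: float,
    factors: dict[str, Factor],
    direction: str = "ascent",
    ndigits: int | None = None,
) -> dict[str, float]:
    """Per-factor coded steps tied to the basis by coefficient ratios.

    The basis coded step is |basis_step_natural| / half_range carrying the
    sign of the basis coefficient (reversed for descent); every other step
    is (b_i / b_basis) times it.  ``ndigits`` optionally rounds each coded
    step (compatibility with hand-computed tables).
    """
    b_basis = fit.slopes[basis]
    if b_basis == 0.0:
        raise ConfigurationError("basis coefficient is zero")
    hr = factors[basis].half_range
    if hr <= 0:
        raise ConfigurationError("basis factor has zero half-range")
    orient = 1.0 if direction == "ascent" else -1.0
    base_step = orient * math.copysign(abs(basis_step_natural) / hr, b_basis)
    steps = {}
    for name, b in fit.slopes.items():
        s = (b / b_basis) * base_step
        steps[name] = round(s, ndigits) if ndigits is not None else s
    return steps


def natural_increments(
    coded_steps: dict[str, float],
    factors: dict[str, Factor],
    compat: bool = False,
) -> dict[str, float]:
    """Delta_i = half_range_i * coded_step_i, per factor.

    In compatibility mode each increment that is not integer-valued is
    rounded to two significant figures before accumulation (integer-valued
    increments are kept exact).
    """
    deltas = {}
    for name, s in coded_steps.items():
        d = factors[name].half_range * s
        if compat and d != round(d):
            d = round_sig(d, 2)
        deltas[name] = d
    return deltas


def path_coordinates(
    factors: dict[str, Factor],
    deltas: dict[str, float],
    k_max: int,
    base: dict[str, float] | None = None,
) -> list[dict[str, float]]:
    """Coordinates base + k*Delta for k = 1..k_max, rounded and clamped.

    Integer factors round to the nearest integer, proportion-type factors to
    two decimals; every coordinate is clamped to its operability region.
    """
    if k_max < 1:
        raise ConfigurationError("k_max must be >= 1")
    base = base or {name: f.base for name, f in factors.items()}
    coords = []
    for k in range(1, k_max + 1):
        point = {}
        for name, f in factors.items():
            z = base[name] + k * deltas.get(name, 0.0)
            point[name] = f.clamp(f.round_natural(z))
        coords.append(point)
    return coords


@dataclass
class AscentPath:
    """A steepest-ascent path: base point, increments and coordinates."""

    factors: dict[str, Factor]
    base: dict[str, float]
    basis: str
    basis_step_natural: float
    coded_steps: dict[str, float]
    deltas: dict[str, float]
    coordinates: list[dict[str, float]]
    responses: list[float] | None = None

    def path_table(self) -> pd.DataFrame:
        """Base / increment / base+kDelta rows, one column per factor."""
        rows = {"Base": self.base, "Delta": self.deltas}
        for k, c in enumerate(self.coordinates, start=1):
            rows[f"Base+{k}D"] = c
        df = pd.DataFrame(rows).T[list(self.factors)]
        if self.responses is not None:
            resp = [np.nan, np.nan] + list(self.responses)
            df["response"] = resp
        return df


def build_path(
    fit: FirstOrderFit,
    factors: dict[str, Factor],
    basis_step_natural: float,
    k_max: int = 9,
    basis: str | None = None,
    direction: str = "ascent",
    compat: bool = False,
    coded_step_decimals: int | None = None,
    base: dict[str, float] | None = None,
) -> AscentPath:
    """Assemble a full path from a first-order fit."""
    chosen = choose_basis(fit, basis)
    steps = coded_step_sizes(
        fit, chosen, basis_step_natural, factors, direction, ndigits=coded_step_decimals
    )
    deltas = natural_increments(steps, factors, compat=compat)
    base = base or {name: f.base for name, f in factors.items()}
    coords = path_coordinates(factors, deltas, k_max, base)
    return AscentPath(
        factors=factors,
        base=dict(base),
        basis=chosen,
        basis_step_natural=basis_step_natural,
        coded_steps=steps,
        deltas=deltas,
        coordinates=coords,
    )


def evaluate_path(path: AscentPath, response_fn, stop_on_error: bool = False) -> AscentPath:
    """Attach a response to every coordinate; per-coordinate failures become NaN."""
    responses: list[float] = []
    for point in path.coordinates:
        try:
            responses.append(float(response_fn(point)))
        except Exception:
            if stop_on_error:
                break
            responses.append(float("nan"))
    path.responses = responses
    return path


@dataclass
class AscentResult:
    """Final point of an iterated ascent plus the full audit trail."""

    best_point: dict[str, float]
    best_response: float
    n_evaluations: int
    converged: bool
    iterations: list[dict] = field(default_factory=list)


def run_ascent(
    factors: dict[str, Factor],
    response_fn,
    basis_step: float = 0.25,
    max_iterations: int = 5,
    k_max: int = 9,
    direction: str = "ascent",
    margin: float = 0.0,
    compat: bool = False,
    coded_step_decimals: int | None = None,
    fraction_sign: int = -1,
) -> AscentResult:
    """Iterate design -> first-order fit -> path -> region relocation.

    Each round evaluates a half-fraction of the current two-level region
    (defining relation I = sign * <all letters>), fits the first-order model
    in coded units, follows the steepest-ascent path, and recenters the
    region on the best path point.  Stops when the best path response fails
    to beat the previous round's best by ``margin``, when all slopes vanish,
    or when the region is pinned against the operability boundary.
    """
    sign = 1.0 if direction == "ascent" else -1.0
    current = dict(factors)
    letters = {name: chr(ord("A") + i) for i, name in enumerate(current)}
    best_point = {name: f.base for name, f in current.items()}
    best_resp = sign * float(response_fn(best_point))
    n_eval = 1
    trail: list[dict] = []
    converged = False
    pinned: set[str] = set()
    for it in range(max_iterations):
        active = {n: f for n, f in current.items() if n not in pinned}
        if not active:
            converged = True
            break
        p = len(active)
        if 2 ** (p - 1) >= p + 1:
            design = half_fraction(p, sign=fraction_sign, names=[letters[n] for n in active])
        else:  # a half fraction of <3 factors cannot support a first-order fit
            design = full_factorial(p, names=[letters[n] for n in active])
        design.factors = list(active.values())
        nat_runs = []
        for row in design.runs:
            pt = dict(best_point)
            for (name, f), x in zip(active.items(), row):
                pt[name] = f.round_natural(decode_value(f, x))
            nat_runs.append(pt)
        responses = np.array([float(response_fn(pt)) for pt in nat_runs])
        n_eval += len(nat_runs)
        coded = CodedDesign([letters[n] for n in active], design.runs, design.defining_relation)
        fit = fit_first_order(coded, responses)
        fit = FirstOrderFit(
            fit.intercept,
            {name: fit.slopes[letters[name]] for name in active},
            fit.residual_variance,
        )
        try:
            path = build_path(
                fit,
                active,
                basis_step,
                k_max=k_max,
                direction=direction,
                compat=compat,
                coded_step_decimals=coded_step_decimals,
            )
        except ConvergenceSignal:
            converged = True
            break
        # carry pinned factors along the path unchanged
        for coord in path.coordinates:
            for name in current:
                coord.setdefault(name, best_point[name])
        evaluate_path(path, response_fn)
        n_eval += len(path.coordinates)
        resp = np.array(path.responses, dtype=float)
        trail.append({"design": nat_runs, "fit": fit, "path": path})
        if np.all(np.isnan(resp)):
            break
        k_best = int(np.nanargmax(sign * resp))
        path_best = sign * resp[k_best]
        if path_best <= best_resp + margin:
            converged = True
            break
        best_resp = path_best
        best_point = dict(path.coordinates[k_best])
        # recenter each factor's two-level region on the best point; a factor
        # whose region collapses against the operability boundary is pinned
        relocated = {}
        for name, f in current.items():
            hr = f.half_range
            lo = f.clamp(best_point[name] - hr)
            hi = f.clamp(best_point[name] + hr)
            if f.integer_valued:
                lo, hi = round(lo), round(hi)
            if hi - lo <= 1e-12:
                pinned.add(name)
                relocated[name] = f
                continue
            relocated[name] = Factor(
                name, lo, hi, f.integer_valued, f.operability_min, f.operability_max
            )
        current = relocated
        if len(pinned) == len(current):
            converged = True
            break
    return AscentResult(
        best_point=best_point,
        best_response=sign * best_resp if direction == "descent" else best_resp,
        n_evaluations=n_eval,
        converged=converged,
        iterations=trail,
    )
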