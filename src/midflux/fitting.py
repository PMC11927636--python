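"""KL-divergence flux fitting with multi-start constrained optimization.

Measured replicate MIDs are averaged per metabolite, then the flux vector v
is fitted by minimizing the total Kullback-Leibler divergence between the
observed and predicted MIDs,

    L_total(v) = sum_i D_KL( M_i || M~_i(v) )
               = sum_i sum_j M_ij log( M_ij / M~_ij(v) ),

subject to the flux-balance equalities A v = b and bounds lb <= v <= ub.
The divergence is observed-weighted and nonnegative, zero only when the
predicted MIDs match the data (up to the epsilon floor that keeps the log
finite at boundary fluxes).

The optimization is a multi-start scheme: local gradient-based solves from
random feasible starting points, keeping the ``n_keep`` solutions with the
smallest final loss.  Equalities are eliminated exactly by parametrizing
the affine feasible space through its null-space basis, so every iterate
satisfies A v = b to machine precision and only the bounds remain as
inequality constraints for the local solver (SLSQP, finite-difference
gradients).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.linalg import null_space
from scipy.optimize import minimize

from .isotopomer import MID, CompiledModel, MIDSet, TracerSpec, predict_mids
from .network import NetworkModel, feasible_point

__all__ = [
    "FluxVector",
    "MeasurementSet",
    "SolutionSet",
    "average_replicates",
    "kl_loss",
    "total_loss",
    "sample_feasible_flux",
    "fit_fluxes",
    "summarize_solutions",
    "compare_conditions",
]

EPS = 1e-9  #: floor applied to MID entries before the log
FEAS_TOL = 1e-6  #: equality residual allowed in retained solutions
BOUND_SLACK = 1e-7  #: bound violation tolerated before a start is discarded


@dataclass
class FluxVector:
    """A flux assignment in model column order with its equality residual."""

    values: np.ndarray
    reaction_ids: Tuple[str, ...]
    residual: float = 0.0

    def __getitem__(self, rxn_id: str) -> float:
        return float(self.values[self.reaction_ids.index(rxn_id)])

    def as_dict(self) -> Dict[str, float]:
        return dict(zip(self.reaction_ids, map(float, self.values)))


@dataclass
class MeasurementSet:
    """Replicate MIDs of one experimental condition.

    ``replicates`` maps metabolite id -> list of replicate MIDs; ``averaged``
    holds the per-metabolite replicate mean actually used in fitting.
    """

    condition: str
    replicates: Dict[str, List[MID]]
    averaged: Dict[str, MID] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.averaged:
            self.averaged = {
                met: average_replicates(reps) for met, reps in self.replicates.items()
            }

    def missing(self, model: NetworkModel) -> Tuple[str, ...]:
        """Model metabolites marked measured but absent from this set."""
        return tuple(m for m in model.measured_ids if m not in self.averaged)


@dataclass
class SolutionSet:
    """Retained multi-start solutions, sorted by ascending total loss."""

    solutions: List[Tuple[FluxVector, float]]
    condition: str
    n_starts: int
    n_keep: int
    seed: int
    diagnostics: pd.DataFrame
    reaction_ids: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.reaction_ids and self.solutions:
            self.reaction_ids = self.solutions[0][0].reaction_ids

    @property
    def best(self) -> Tuple[FluxVector, float]:
        return self.solutions[0]

    @property
    def losses(self) -> np.ndarray:
        return np.array([l for _, l in self.solutions])

    def flux_matrix(self) -> np.ndarray:
        """Solutions stacked as rows (n_solutions x n_reactions)."""
        return np.vstack([fv.values for fv, _ in self.solutions])


def average_replicates(mids: Sequence[MID]) -> MID:
    """Arithmetic mean of replicate MIDs per isotopologue, renormalized."""
    if len(mids) == 0:
        raise ValueError("no replicates to average")
    lengths = {m.fractions.size for m in mids}
    if len(lengths) != 1:
        raise ValueError("replicate MIDs have mismatched lengths")
    mean = np.mean([m.fractions for m in mids], axis=0)
    return MID(mids[0].metabolite_id, mean)


def _floor_and_norm(f: np.ndarray) -> np.ndarray:
    f = np.clip(np.asarray(f, dtype=float), EPS, None)
    return f / f.sum()


def kl_loss(predicted: MID, observed: MID) -> float:
    """D_KL(observed || predicted) in nats, epsilon-regularized.

    Both distributions are floored at 1e-9 and renormalized before the log,
    so the loss is finite even when a boundary flux predicts an exactly-zero
    isotopologue that was observed.
    """
    p = _floor_and_norm(predicted.fractions)
    q = _floor_and_norm(observed.fractions)
    if p.size != q.size:
        raise ValueError("predicted and observed MIDs have different lengths")
    return float(np.sum(q * np.log(q / p)))


def total_loss(
    model: NetworkModel,
    flux,
    measurements: MeasurementSet,
    tracer: TracerSpec,
    *,
    compiled: Optional[CompiledModel] = None,
    check_feasibility: bool = True,
    per_replicate: bool = False,
) -> float:
    """Sum of per-metabolite KL losses over all measured metabolites.

    By default each metabolite contributes one term against its
    replicate-averaged MID.  With ``per_replicate=True`` every replicate
    contributes its own term instead (non-default alternative to averaging
    before fitting).
    """
    predicted = predict_mids(
        model, flux, tracer, compiled=compiled, check_feasibility=check_feasibility
    )
    loss = 0.0
    for met_id in sorted(measurements.averaged):
        if per_replicate:
            for obs in measurements.replicates[met_id]:
                loss += kl_loss(predicted[met_id], obs)
        else:
            loss += kl_loss(predicted[met_id], measurements.averaged[met_id])
    return loss


# ---------------------------------------------------------------------------
# feasible-space parametrization and sampling
# ---------------------------------------------------------------------------

def _interior_point(model: NetworkModel) -> np.ndarray:
    """Feasible point maximizing the smallest slack to any bound.

    Solved as an LP over (v, t): maximize t subject to A v = b and
    lb + t <= v <= ub - t.  Gives the sampler and the local solver an
    anchor well inside the box instead of an LP vertex.
    """
    from scipy.optimize import linprog

    n = len(model.reactions)
    lb, ub = model.lb, model.ub
    # variables [v, t]; constraints: -v + t <= -lb ;  v + t <= ub
    A_ub = np.block([[-np.eye(n), np.ones((n, 1))], [np.eye(n), np.ones((n, 1))]])
    b_ub = np.concatenate([-lb, ub])
    A_eq = np.hstack([model.A, np.zeros((model.A.shape[0], 1))])
    c = np.zeros(n + 1)
    c[-1] = -1.0  # maximize t
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=model.b,
        bounds=[(None, None)] * n + [(0.0, None)], method="highs",
    )
    if not res.success:
        return feasible_point(model)
    return np.asarray(res.x[:n], dtype=float)


class _FeasibleSpace:
    """Affine parametrization v = v0 + N z of {A v = b}, with cached pieces."""

    def __init__(self, model: NetworkModel):
        self.model = model
        self.v0 = _interior_point(model)
        N = null_space(model.A)
        self.N = N  # (n_reactions x dim); dim may be 0
        self.dim = N.shape[1]
        self.lb = model.lb
        self.ub = model.ub

    def to_z(self, v: np.ndarray) -> np.ndarray:
        return self.N.T @ (v - self.v0)

    def to_v(self, z: np.ndarray) -> np.ndarray:
        return self.v0 + self.N @ z


def sample_feasible_flux(model: NetworkModel, rng: np.random.Generator, *, _space: Optional[_FeasibleSpace] = None) -> FluxVector:
    """A random flux vector satisfying bounds and A v = b within 1e-6.

    Draws uniformly inside the bounding box, then alternates least-squares
    projection onto the equality manifold with clipping to the box (at most
    50 rounds).  When the alternating projection has not closed the residual,
    falls back to casting a ray from an interior feasible point toward the
    draw's projection, stopping just inside the box — always feasible and
    still seed-deterministic.
    """
    space = _space or _FeasibleSpace(model)
    draw = rng.uniform(model.lb, model.ub)
    v = draw
    for _ in range(50):
        v = space.to_v(space.to_z(v))  # orthogonal projection onto {A v = b}
        clipped = np.clip(v, model.lb, model.ub)
        if model.residual(clipped) <= FEAS_TOL:
            return FluxVector(clipped, model.reaction_ids, model.residual(clipped))
        v = clipped
    # ray cast within the feasible affine space: v0 + alpha * d stays on
    # {A v = b} for all alpha; pick the largest step keeping v inside the box
    d = space.to_v(space.to_z(draw)) - space.v0
    with np.errstate(divide="ignore", invalid="ignore"):
        hi = np.where(d > 0, (model.ub - space.v0) / d, np.inf)
        lo = np.where(d < 0, (model.lb - space.v0) / d, np.inf)
    alpha = min(1.0, 0.95 * float(np.min(np.minimum(hi, lo), initial=np.inf)))
    v = np.clip(space.v0 + max(alpha, 0.0) * d, model.lb, model.ub)
    return FluxVector(v, model.reaction_ids, model.residual(v))


def fit_fluxes(
    model: NetworkModel,
    measurements: MeasurementSet,
    tracer: TracerSpec,
    n_starts: int = 10000,
    n_keep: int = 50,
    seed: int = 0,
    *,
    maxiter: int = 500,
    ftol: float = 1e-9,
    per_replicate: bool = False,
) -> SolutionSet:
    """Multi-start KL fit of the flux vector to one condition's MID data.

    Runs ``n_starts`` local constrained minimizations from random feasible
    starting points and returns the ``n_keep`` converged solutions with
    smallest total loss.  Defaults mirror the study-scale procedure
    (10,000 starts, keep 50); tests and desk runs use smaller values.
    Fully reproducible from ``seed``.
    """
    if n_keep > n_starts:
        raise ValueError("n_keep cannot exceed n_starts")
    missing = measurements.missing(model)
    space = _FeasibleSpace(model)
    compiled = CompiledModel(model)
    tracer = tracer.for_model(model)
    rng = np.random.default_rng(seed)

    def objective(z: np.ndarray) -> float:
        v = np.clip(space.to_v(z), model.lb, model.ub)
        return total_loss(
            model, v, measurements, tracer, compiled=compiled,
            check_feasibility=False, per_replicate=per_replicate,
        )

    constraints = []
    if space.dim:
        constraints = [
            {"type": "ineq", "fun": lambda z: space.to_v(z) - model.lb, "jac": lambda z: space.N},
            {"type": "ineq", "fun": lambda z: model.ub - space.to_v(z), "jac": lambda z: -space.N},
        ]

    retained: List[Tuple[float, int, np.ndarray]] = []
    diag_rows = []
    for start in range(n_starts):
        init = sample_feasible_flux(model, rng, _space=space)
        z0 = space.to_z(init.values)
        if space.dim == 0:
            v, loss, ok, nit = init.values, objective(z0), True, 0
        else:
            res = minimize(
                objective,
                z0,
                method="SLSQP",
                constraints=constraints,
                options={"maxiter": maxiter, "ftol": ftol},
            )
            v = space.to_v(res.x)
            loss = float(res.fun)
            nit = int(res.nit)
            ok = bool(res.success)
        bound_violation = float(
            max(np.max(model.lb - v, initial=0.0), np.max(v - model.ub, initial=0.0))
        )
        v = np.clip(v, model.lb, model.ub)
        residual = model.residual(v)
        feasible = bound_violation <= BOUND_SLACK and residual <= FEAS_TOL
        diag_rows.append(
            {
                "start": start,
                "loss": loss,
                "iterations": nit,
                "converged": ok,
                "feasible": feasible,
                "residual": residual,
                "bound_violation": bound_violation,
            }
        )
        if ok and feasible and np.isfinite(loss):
            retained.append((loss, start, v))

    if not retained:
        raise RuntimeError("no start converged to a feasible solution")

    retained.sort(key=lambda t: (t[0], t[1]))  # loss, then start index (determinism)
    kept = retained[: min(n_keep, len(retained))]
    solutions = [
        (FluxVector(v, model.reaction_ids, model.residual(v)), loss)
        for loss, _, v in kept
    ]
    return SolutionSet(
        solutions=solutions,
        condition=measurements.condition,
        n_starts=n_starts,
        n_keep=n_keep,
        seed=seed,
        diagnostics=pd.DataFrame(diag_rows),
        reaction_ids=model.reaction_ids,
    )


def summarize_solutions(solution_set: SolutionSet) -> pd.DataFrame:
    """Per-reaction median, interquartile range, min and max over solutions."""
    if not solution_set.solutions:
        raise ValueError("empty solution set")
    m = solution_set.flux_matrix()
    return pd.DataFrame(
        {
            "reaction": solution_set.reaction_ids,
            "median": np.median(m, axis=0),
            "iqr_low": np.percentile(m, 25, axis=0),
            "iqr_high": np.percentile(m, 75, axis=0),
            "min": m.min(axis=0),
            "max": m.max(axis=0),
            "n_solutions": m.shape[0],
        }
    )


def compare_conditions(set_a: SolutionSet, set_b: SolutionSet) -> pd.DataFrame:
    """Per-reaction contrast between two fitted conditions (sign: b - a).

    ``median_diff`` is median(b) - median(a).  ``p_b_greater`` is the
    Mann-Whitney common-language effect size: the probability that a flux
    drawn from set b exceeds one drawn from set a (0.5 = fully overlapping
    solution sets).
    """
    if set_a.reaction_ids != set_b.reaction_ids:
        raise ValueError("solution sets come from different models")
    ma, mb = set_a.flux_matrix(), set_b.flux_matrix()
    med_a = np.median(ma, axis=0)
    med_b = np.median(mb, axis=0)
    greater = (mb[:, None, :] > ma[None, :, :]).mean(axis=(0, 1))
    ties = (mb[:, None, :] == ma[None, :, :]).mean(axis=(0, 1))
    return pd.DataFrame(
        {
            "reaction": set_a.reaction_ids,
            "median_a": med_a,
            "median_b": med_b,
            "median_diff": med_b - med_a,
            "p_b_greater": greater + 0.5 * ties,
        }
    )
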