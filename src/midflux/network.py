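"""Carbon-mapped metabolic network models and the flux-balance system.

A model is a set of metabolites (balanced intracellular pools, labeled or
unlabeled substrates, and sinks) plus unidirectional reactions, each carrying
an atom map that states which substrate carbon every product carbon comes
from.  From the reaction list the model assembles the steady-state equality
system ``A @ v = b`` (one row per balanced metabolite: production minus
consumption equals zero) plus any user-supplied equality rows (e.g. a fixed,
experimentally measured uptake rate), and elementwise flux bounds.

Reversible steps are represented as two irreversible reactions; all fluxes
are nonnegative.  Symmetric intermediates can be modeled by duplicating a
reaction with the two atom-map variants, each carrying half the flux.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "Metabolite",
    "CarbonSource",
    "Reaction",
    "NetworkModel",
    "build_model",
    "validate_atom_balance",
    "feasible_point",
]

KINDS = ("balanced", "substrate", "sink")


@dataclass(frozen=True)
class Metabolite:
    """A metabolite pool.

    kind: "balanced" (intracellular, steady state enforced), "substrate"
    (network input with a fixed labeling state) or "sink" (excreted or
    accumulated; no balance row).  ``measured`` marks metabolites whose MID
    enters the fitting loss.
    """

    id: str
    n_carbons: int
    kind: str = "balanced"
    measured: bool = False

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"metabolite {self.id!r}: unknown kind {self.kind!r}")
        if self.n_carbons < 0:
            raise ValueError(f"metabolite {self.id!r}: negative carbon count")


# A carbon source for one product carbon position: (substrate occurrence
# index within the reaction's substrate list, carbon index within that
# substrate), or None for a carbon drawn from an unlabeled (12C) source.
CarbonSource = Optional[Tuple[int, int]]


@dataclass(frozen=True)
class Reaction:
    """One irreversible reaction with its atom map and flux bounds.

    ``substrates`` / ``products`` are sequences of ``(metabolite_id, coeff)``.
    Metabolites participating more than once in a carbon-mapped role appear
    as separate occurrences with coefficient 1 (e.g. one hexose cleaving into
    two trioses lists the triose product twice, each with its own map).

    ``atom_map`` has one entry per product occurrence: a tuple over that
    product's carbon positions of :data:`CarbonSource` entries.
    """

    id: str
    substrates: Tuple[Tuple[str, float], ...]
    products: Tuple[Tuple[str, float], ...]
    atom_map: Tuple[Tuple[CarbonSource, ...], ...]
    lb: float = 0.0
    ub: float = 1000.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.lb <= self.ub):
            raise ValueError(f"reaction {self.id!r}: bounds must satisfy 0 <= lb <= ub")
        for _, c in list(self.substrates) + list(self.products):
            if c <= 0:
                raise ValueError(f"reaction {self.id!r}: nonpositive stoichiometry")
        if len(self.atom_map) != len(self.products):
            raise ValueError(
                f"reaction {self.id!r}: atom map must have one entry per product occurrence"
            )


@dataclass
class NetworkModel:
    """Validated network with the assembled equality system and bounds.

    Rows of ``A`` are the balanced metabolites in sorted-id order followed by
    one row per extra user equality; columns are reactions in sorted-id
    order.  ``b`` is zero on steady-state rows.
    """

    metabolites: Tuple[Metabolite, ...]
    reactions: Tuple[Reaction, ...]
    A: np.ndarray
    b: np.ndarray
    extra_constraints: Tuple[Tuple[Mapping[str, float], float], ...] = ()
    _met_index: Mapping[str, int] = field(default_factory=dict, repr=False)
    _rxn_index: Mapping[str, int] = field(default_factory=dict, repr=False)

    # -- lookups ---------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    def reaction_index(self, rxn_id: str) -> int:
        return self._rxn_index[rxn_id]

    @property
    def reaction_ids(self) -> Tuple[str, ...]:
        return tuple(r.id for r in self.reactions)

    @property
    def balanced_ids(self) -> Tuple[str, ...]:
        return tuple(m.id for m in self.metabolites if m.kind == "balanced")

    @property
    def measured_ids(self) -> Tuple[str, ...]:
        return tuple(m.id for m in self.metabolites if m.measured)

    @property
    def lb(self) -> np.ndarray:
        return np.array([r.lb for r in self.reactions])

    @property
    def ub(self) -> np.ndarray:
        return np.array([r.ub for r in self.reactions])

    def flux_array(self, values: Mapping[str, float]) -> np.ndarray:
        """Order a {reaction id: flux} mapping into the model's column order."""
        missing = set(self.reaction_ids) - set(values)
        if missing:
            raise KeyError(f"missing flux values for reactions: {sorted(missing)}")
        return np.array([values[r] for r in self.reaction_ids], dtype=float)

    def residual(self, v: np.ndarray) -> float:
        """Equality-constraint residual ``||A v - b||_inf``."""
        if self.A.shape[0] == 0:
            return 0.0
        return float(np.max(np.abs(self.A @ np.asarray(v, dtype=float) - self.b)))


def _validate_reaction(rxn: Reaction, mets: Mapping[str, Metabolite]) -> None:
    for mid, _ in list(rxn.substrates) + list(rxn.products):
        if mid not in mets:
            raise ValueError(f"reaction {rxn.id!r}: unknown metabolite {mid!r}")
    used: set = set()
    for occ, (pid, _) in enumerate(rxn.products):
        pmap = rxn.atom_map[occ]
        met = mets[pid]
        if len(pmap) != met.n_carbons:
            raise ValueError(
                f"reaction {rxn.id!r}: atom map for {pid!r} has {len(pmap)} entries, "
                f"metabolite has {met.n_carbons} carbons"
            )
        for src in pmap:
            if src is None:
                continue
            s_occ, s_pos = src
            if not (0 <= s_occ < len(rxn.substrates)):
                raise ValueError(f"reaction {rxn.id!r}: atom map references substrate occurrence {s_occ}")
            smet = mets[rxn.substrates[s_occ][0]]
            if not (0 <= s_pos < smet.n_carbons):
                raise ValueError(
                    f"reaction {rxn.id!r}: carbon index {s_pos + 1} exceeds "
                    f"{smet.id!r} carbon count {smet.n_carbons}"
                )
            if (s_occ, s_pos) in used:
                raise ValueError(
                    f"reaction {rxn.id!r}: substrate carbon {smet.id}:{s_pos + 1} mapped twice"
                )
            used.add((s_occ, s_pos))


def build_model(
    metabolites: Iterable[Metabolite],
    reactions: Iterable[Reaction],
    extra_constraints: Sequence[Tuple[Mapping[str, float], float]] = (),
) -> NetworkModel:
    """Validate inputs and assemble the flux-balance system.

    ``extra_constraints`` are user equalities, each a pair of
    ``({reaction_id: coefficient}, value)`` appended as rows below the
    steady-state rows.  Row/column order is deterministic: sorted by id.
    """
    mets = tuple(sorted(metabolites, key=lambda m: m.id))
    rxns = tuple(sorted(reactions, key=lambda r: r.id))
    met_map = {m.id: m for m in mets}
    if len(met_map) != len(mets):
        raise ValueError("duplicate metabolite ids")
    if len({r.id for r in rxns}) != len(rxns):
        raise ValueError("duplicate reaction ids")

    for rxn in rxns:
        _validate_reaction(rxn, met_map)

    balanced = [m for m in mets if m.kind == "balanced"]
    rxn_index = {r.id: j for j, r in enumerate(rxns)}
    met_row = {m.id: i for i, m in enumerate(balanced)}

    n_extra = len(extra_constraints)
    A = np.zeros((len(balanced) + n_extra, len(rxns)))
    b = np.zeros(len(balanced) + n_extra)
    producers: dict = {m.id: 0 for m in balanced}
    consumers: dict = {m.id: 0 for m in balanced}
    for j, rxn in enumerate(rxns):
        for mid, c in rxn.substrates:
            if mid in met_row:
                A[met_row[mid], j] -= c
                consumers[mid] += 1
        for mid, c in rxn.products:
            if mid in met_row:
                A[met_row[mid], j] += c
                producers[mid] += 1

    for mid in met_row:
        if producers[mid] and not consumers[mid]:
            raise ValueError(
                f"balanced metabolite {mid!r} has producers but no consumers: "
                "steady state cannot close (mark it as a sink or add a drain)"
            )

    for k, (coeffs, value) in enumerate(extra_constraints):
        for rid, c in coeffs.items():
            if rid not in rxn_index:
                raise ValueError(f"extra constraint references unknown reaction {rid!r}")
            A[len(balanced) + k, rxn_index[rid]] = c
        b[len(balanced) + k] = value

    return NetworkModel(
        metabolites=mets,
        reactions=rxns,
        A=A,
        b=b,
        extra_constraints=tuple((dict(c), v) for c, v in extra_constraints),
        _met_index={m.id: i for i, m in enumerate(mets)},
        _rxn_index=rxn_index,
    )


def validate_atom_balance(model: NetworkModel) -> "pd.DataFrame":
    """Report reactions whose mapped-carbon bookkeeping is suspicious.

    For each reaction, counts total substrate carbons, how many of them are
    mapped into products, and how many product carbons draw from unlabeled
    sources.  A reaction is flagged when substrate carbons vanish without any
    declared single-carbon release product (e.g. CO2) accounting for them.
    Report-only: never raises.
    """
    import pandas as pd

    rows = []
    for rxn in model.reactions:
        total_sub = sum(model.metabolite(mid).n_carbons for mid, _ in rxn.substrates)
        mapped = sum(1 for pmap in rxn.atom_map for src in pmap if src is not None)
        unlabeled = sum(1 for pmap in rxn.atom_map for src in pmap if src is None)
        rows.append(
            {
                "reaction": rxn.id,
                "substrate_carbons": total_sub,
                "mapped_to_products": mapped,
                "unlabeled_source_carbons": unlabeled,
                "unmapped_substrate_carbons": total_sub - mapped,
                "flagged": mapped < total_sub,
            }
        )
    return pd.DataFrame(rows)


def feasible_point(model: NetworkModel) -> np.ndarray:
    """A flux vector satisfying A v = b and the bounds (phase-1 LP).

    Raises ValueError when the constraint system is infeasible; fitting and
    simulation both require a feasible model.
    """
    n = len(model.reactions)
    res = linprog(
        c=np.zeros(n),
        A_eq=model.A,
        b_eq=model.b,
        bounds=list(zip(model.lb, model.ub)),
        method="highs",
    )
    if not res.success:
        raise ValueError(f"model is infeasible: {res.message}")
    return np.asarray(res.x, dtype=float)
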