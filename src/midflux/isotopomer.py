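"""Mass isotopomer distributions and the steady-state forward model.

The forward model predicts, for every metabolite, the MID
``M~_i = sum_j v_ji M_ji / sum_j v_ji`` — the average of the MIDs produced
through each generating reaction, weighted by that reaction's flux.  The
MID a single reaction produces (``M_ji``) is determined by the reaction's
atom map: each product carbon inherits the labeling state of one specific
substrate carbon.

Whole-molecule MIDs do not carry enough information to propagate label
through cleavage and condensation reactions, so internally every metabolite
is tracked as a full positional-isotopomer distribution — a vector over the
2**n labeling patterns of its n carbons (pattern bit k set = carbon k+1 is
13C).  Substrate pools of one reaction are treated as statistically
independent, the standard steady-state MFA assumption.  MIDs are the
popcount marginals of these vectors.

Acyclic precursor graphs are solved in topological order; strongly
connected components (metabolic cycles, e.g. the TCA cycle) by damped
fixed-point iteration from the all-unlabeled state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import networkx as nx
import numpy as np

from .network import NetworkModel, Reaction

__all__ = [
    "MID",
    "TracerSpec",
    "MIDSet",
    "convolve",
    "reaction_mid",
    "predict_mids",
    "fractional_abundance",
]

#: metabolites above this carbon count would need 2**n positional states
MAX_CARBONS = 16


@dataclass(frozen=True)
class MID:
    """Mass isotopomer distribution of one metabolite.

    ``fractions[k]`` is the fraction of molecules carrying k heavy carbons
    (M+k), k = 0..n.  Renormalized to sum to 1 on construction; entries must
    be nonnegative.
    """

    metabolite_id: str
    fractions: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if f.ndim != 1 or f.size == 0:
            raise ValueError("MID fractions must be a nonempty 1-D vector")
        if np.any(f < -1e-12):
            raise ValueError(f"MID of {self.metabolite_id!r} has negative entries")
        f = np.clip(f, 0.0, None)
        total = f.sum()
        if total <= 0:
            raise ValueError(f"MID of {self.metabolite_id!r} sums to zero")
        object.__setattr__(self, "fractions", f / total)

    @property
    def n_carbons(self) -> int:
        return self.fractions.size - 1

    def __getitem__(self, k: int) -> float:
        return float(self.fractions[k])


def convolve(mid_a: np.ndarray, mid_b: np.ndarray) -> np.ndarray:
    """Mass distribution of a fragment formed by joining two fragments.

    Discrete convolution: a combined molecule has k heavy carbons in all the
    ways its two parts can split k between them.
    """
    return np.convolve(np.asarray(mid_a, dtype=float), np.asarray(mid_b, dtype=float))


@dataclass
class TracerSpec:
    """Fixed labeling state of every substrate-kind metabolite.

    ``mids`` maps substrate id -> its MID (e.g. uniformly labeled glucose =
    100% M+6, unlabeled inputs = 100% M+0).  ``purity`` optionally dilutes a
    tracer with its unlabeled form: the effective MID is
    ``purity * MID + (1 - purity) * delta(M+0)``.  Default purity 1.0.
    """

    mids: Dict[str, MID]
    purity: Dict[str, float] = field(default_factory=dict)

    @staticmethod
    def uniform(met_id: str, n_carbons: int, purity: float = 1.0) -> "TracerSpec":
        """Single fully labeled tracer (all n carbons 13C)."""
        frac = np.zeros(n_carbons + 1)
        frac[-1] = 1.0
        return TracerSpec(mids={met_id: MID(met_id, frac)}, purity={met_id: purity})

    def add_unlabeled(self, met_id: str, n_carbons: int) -> "TracerSpec":
        frac = np.zeros(n_carbons + 1)
        frac[0] = 1.0
        self.mids[met_id] = MID(met_id, frac)
        return self

    def effective_mid(self, met_id: str) -> MID:
        mid = self.mids[met_id]
        p = float(self.purity.get(met_id, 1.0))
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"purity for {met_id!r} outside [0, 1]")
        if p == 1.0:
            return mid
        f = p * mid.fractions.copy()
        f[0] += 1.0 - p
        return MID(met_id, f)

    def for_model(self, model: NetworkModel) -> "TracerSpec":
        """Fill in 100% M+0 for any substrate the spec does not mention."""
        out = TracerSpec(dict(self.mids), dict(self.purity))
        for met in model.metabolites:
            if met.kind == "substrate" and met.id not in out.mids:
                out.add_unlabeled(met.id, met.n_carbons)
        return out


@dataclass
class MIDSet:
    """Predicted MIDs for every non-substrate metabolite plus convergence info."""

    mids: Dict[str, MID]
    iterations: int = 0
    residual: float = 0.0
    pruned: Tuple[str, ...] = ()

    def __getitem__(self, met_id: str) -> MID:
        return self.mids[met_id]

    def __contains__(self, met_id: str) -> bool:
        return met_id in self.mids

    def __iter__(self):
        return iter(self.mids)


def fractional_abundance(mid_set: MIDSet, metabolite: str, k: int) -> float:
    """The M+k entry of one metabolite's (predicted or measured) MID."""
    if metabolite not in mid_set:
        raise KeyError(f"metabolite {metabolite!r} not in MID set")
    mid = mid_set[metabolite]
    if not (0 <= k <= mid.n_carbons):
        raise ValueError(f"M+{k} out of range for {metabolite!r} ({mid.n_carbons} carbons)")
    return mid[k]


# ---------------------------------------------------------------------------
# positional-state machinery
# ---------------------------------------------------------------------------

def positional_from_mid(mid: MID) -> np.ndarray:
    """Positional distribution assuming exchangeable carbon positions.

    Molecules with k labels are spread uniformly over the C(n, k) patterns
    with popcount k.  Exact for the common tracers (fully labeled or fully
    unlabeled substrates have a single pattern per mass).
    """
    n = mid.n_carbons
    pop = _popcounts(n)
    counts = np.bincount(pop, minlength=n + 1).astype(float)
    return mid.fractions[pop] / counts[pop]


def mid_from_positional(met_id: str, p: np.ndarray, n: int) -> MID:
    return MID(met_id, np.bincount(_popcounts(n), weights=p, minlength=n + 1))


_POPCACHE: Dict[int, np.ndarray] = {}


def _popcounts(n: int) -> np.ndarray:
    if n not in _POPCACHE:
        states = np.arange(1 << n, dtype=np.int64)
        pop = np.zeros(1 << n, dtype=np.int64)
        for bit in range(n):
            pop += (states >> bit) & 1
        _POPCACHE[n] = pop
    return _POPCACHE[n]


class _OccurrenceRule:
    """Compiled recipe for one (reaction, product occurrence).

    Computes the product's positional distribution from the positional
    distributions of the reaction's substrates:  for each substrate
    occurrence contributing carbons, marginalize its distribution onto the
    contributed fragment, then combine fragments (independent pools) by an
    outer product mapped onto product bit positions.  Unmapped product
    carbons stay unlabeled (bit 0).
    """

    def __init__(self, model: NetworkModel, rxn: Reaction, occ: int):
        pid, coeff = rxn.products[occ]
        self.reaction_id = rxn.id
        self.product_id = pid
        self.weight_coeff = coeff
        n_prod = model.metabolite(pid).n_carbons
        self.n_prod = n_prod
        pmap = rxn.atom_map[occ]

        # group mapped product positions by substrate occurrence
        by_sub: Dict[int, List[Tuple[int, int]]] = {}
        for p_pos, src in enumerate(pmap):
            if src is None:
                continue
            s_occ, s_pos = src
            by_sub.setdefault(s_occ, []).append((p_pos, s_pos))

        self.steps = []  # (substrate_id, frag_index_array, lift_mask_array)
        for s_occ in sorted(by_sub):
            sid = rxn.substrates[s_occ][0]
            n_sub = model.metabolite(sid).n_carbons
            pairs = by_sub[s_occ]
            k = len(pairs)
            sub_states = np.arange(1 << n_sub, dtype=np.int64)
            frag_idx = np.zeros(1 << n_sub, dtype=np.int64)
            lift = np.zeros(1 << k, dtype=np.int64)
            frag_states = np.arange(1 << k, dtype=np.int64)
            for j, (p_pos, s_pos) in enumerate(pairs):
                frag_idx |= ((sub_states >> s_pos) & 1) << j
                lift |= ((frag_states >> j) & 1) << p_pos
            self.steps.append((sid, frag_idx, lift, k))

    def product_state(self, states: Mapping[str, np.ndarray]) -> np.ndarray:
        # fold substrate fragments one at a time
        cur = np.array([1.0])
        cur_idx = np.array([0], dtype=np.int64)
        for sid, frag_idx, lift, k in self.steps:
            frag = np.bincount(frag_idx, weights=states[sid], minlength=1 << k)
            cur = np.multiply.outer(cur, frag).ravel()
            cur_idx = (cur_idx[:, None] | lift[None, :]).ravel()
        out = np.bincount(cur_idx, weights=cur, minlength=1 << self.n_prod)
        return out


class CompiledModel:
    """Per-model compiled structures for fast repeated MID prediction."""

    def __init__(self, model: NetworkModel):
        self.model = model
        for met in model.metabolites:
            if met.n_carbons > MAX_CARBONS:
                raise ValueError(
                    f"metabolite {met.id!r} has {met.n_carbons} carbons; positional "
                    f"tracking supports at most {MAX_CARBONS}"
                )
        # producing rules per metabolite
        self.rules: Dict[str, List[_OccurrenceRule]] = {
            m.id: [] for m in model.metabolites if m.kind != "substrate"
        }
        for rxn in model.reactions:
            for occ, (pid, _) in enumerate(rxn.products):
                if pid in self.rules:
                    self.rules[pid].append(_OccurrenceRule(model, rxn, occ))

        # metabolite dependency graph: substrate -> product edges
        g = nx.DiGraph()
        g.add_nodes_from(self.rules)
        for pid, rules in self.rules.items():
            for rule in rules:
                for sid, *_ in rule.steps:
                    if sid in self.rules:
                        g.add_edge(sid, pid)
        # condensation of SCCs in topological order; deterministic ordering
        sccs = list(nx.strongly_connected_components(g))
        cond = nx.condensation(g, scc=sccs)
        order = list(nx.lexicographical_topological_sort(cond))
        self.blocks: List[List[str]] = [sorted(cond.nodes[i]["members"]) for i in order]
        self.cyclic_blocks = [len(b) > 1 or g.has_edge(b[0], b[0]) for b in self.blocks]


def _mix_rules(
    compiled: CompiledModel,
    met_id: str,
    flux: Mapping[str, float],
    states: Mapping[str, np.ndarray],
    prune_tol: float,
) -> Optional[np.ndarray]:
    """Flux-weighted average of per-reaction product states; None if starved."""
    rules = compiled.rules[met_id]
    total = 0.0
    acc = None
    for rule in rules:
        w = rule.weight_coeff * flux[rule.reaction_id]
        if w <= prune_tol:
            continue
        contrib = rule.product_state(states)
        acc = w * contrib if acc is None else acc + w * contrib
        total += w
    if acc is None or total <= prune_tol:
        return None
    return acc / total


def predict_mids(
    model: NetworkModel,
    flux,
    tracer: TracerSpec,
    *,
    compiled: Optional[CompiledModel] = None,
    damping: float = 0.5,
    tol: float = 1e-9,
    max_iter: int = 10000,
    feas_tol: float = 1e-6,
    check_feasibility: bool = True,
) -> MIDSet:
    """Predict steady-state MIDs of all balanced and sink metabolites.

    ``flux`` may be an array in model column order or a {reaction_id: value}
    mapping.  Metabolites with zero total inflow under ``flux`` are pruned to
    100% M+0 and flagged in the result rather than raising, so optimizer
    iterates at the boundary of the feasible box remain evaluable.
    """
    v = flux if isinstance(flux, np.ndarray) else model.flux_array(flux)
    v = np.asarray(v, dtype=float)
    if check_feasibility and model.residual(v) > feas_tol:
        raise ValueError(
            f"flux vector violates equality constraints (residual {model.residual(v):.3g})"
        )
    flux_map = dict(zip(model.reaction_ids, v))
    compiled = compiled or CompiledModel(model)
    tracer = tracer.for_model(model)

    states: Dict[str, np.ndarray] = {}
    for met in model.metabolites:
        if met.kind == "substrate":
            states[met.id] = positional_from_mid(tracer.effective_mid(met.id))

    vmax = max(float(np.max(np.abs(v))), 1.0)
    prune_tol = 1e-12 * vmax
    pruned: List[str] = []
    total_iters = 0
    worst_residual = 0.0

    for block, cyclic in zip(compiled.blocks, compiled.cyclic_blocks):
        if not cyclic:
            met_id = block[0]
            mixed = _mix_rules(compiled, met_id, flux_map, states, prune_tol)
            if mixed is None:
                n = model.metabolite(met_id).n_carbons
                mixed = np.zeros(1 << n)
                mixed[0] = 1.0
                pruned.append(met_id)
            states[met_id] = mixed
            continue

        # cycle: damped fixed point from all-unlabeled
        for met_id in block:
            n = model.metabolite(met_id).n_carbons
            s = np.zeros(1 << n)
            s[0] = 1.0
            states[met_id] = s
        starved = set()
        converged = False
        for it in range(max_iter):
            delta = 0.0
            for met_id in block:
                mixed = _mix_rules(compiled, met_id, flux_map, states, prune_tol)
                if mixed is None:
                    starved.add(met_id)
                    continue
                new = (1.0 - damping) * states[met_id] + damping * mixed
                delta = max(delta, float(np.max(np.abs(new - states[met_id]))))
                states[met_id] = new
            total_iters = it + 1
            if delta <= tol * damping:
                worst_residual = max(worst_residual, delta)
                converged = True
                break
        if not converged:
            raise RuntimeError(
                f"fixed-point iteration did not converge for cycle {block} "
                f"within {max_iter} iterations"
            )
        pruned.extend(sorted(starved))

    mids = {
        met.id: mid_from_positional(met.id, states[met.id], met.n_carbons)
        for met in model.metabolites
        if met.kind != "substrate"
    }
    return MIDSet(mids=mids, iterations=total_iters, residual=worst_residual, pruned=tuple(pruned))


def reaction_mid(
    model: NetworkModel,
    reaction_id: str,
    product_id: str,
    substrate_states: Mapping[str, np.ndarray],
) -> MID:
    """MID of ``product_id`` as produced through one specific reaction.

    ``substrate_states`` maps each substrate id of the reaction to its
    positional distribution (see :func:`positional_from_mid` to build one
    from a plain MID).  This is the single-reaction term M_ji of the
    flux-weighted average computed by :func:`predict_mids`.
    """
    rxn = model.reaction(reaction_id)
    occs = [occ for occ, (pid, _) in enumerate(rxn.products) if pid == product_id]
    if not occs:
        raise ValueError(f"reaction {reaction_id!r} does not produce {product_id!r}")
    n = model.metabolite(product_id).n_carbons
    acc = np.zeros(1 << n)
    w = 0.0
    for occ in occs:
        rule = _OccurrenceRule(model, rxn, occ)
        for sid, *_ in rule.steps:
            if sid not in substrate_states:
                raise KeyError(f"no label state supplied for substrate {sid!r}")
        acc += rule.weight_coeff * rule.product_state(substrate_states)
        w += rule.weight_coeff
    return mid_from_positional(product_id, acc / w, n)
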