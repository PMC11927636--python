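"""Independent oracles for the forward label-propagation model.

Two deliberately different computational routes from the package's
vectorized simulator:

* :func:`enumerate_mids` — pure-Python, dictionary-based exhaustive
  enumeration of positional isotopomers on acyclic networks, recursing
  through precursors and multiplying out every combination of substrate
  labeling patterns.

* :func:`linear_cycle_solve` — for networks whose reactions each draw
  product carbons from at most one non-fixed metabolite, the steady-state
  positional balance is a linear system; assemble it explicitly over all
  positional states and solve it in one shot with numpy.

Plus :func:`random_acyclic_model`, a generator of small random carbon-mapped
DAG networks with a feasible flux vector, used for randomized equivalence
testing.
"""

from __future__ import annotations

import itertools
from math import comb
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.optimize import linprog

from midflux.isotopomer import MID, TracerSpec
from midflux.network import Metabolite, NetworkModel, Reaction, build_model

Pattern = Tuple[int, ...]  # one 0/1 entry per carbon position
Dist = Dict[Pattern, float]


def _substrate_dist(mid: MID) -> Dist:
    """Spread each mass fraction uniformly over its positional patterns."""
    n = mid.n_carbons
    dist: Dist = {}
    for pattern in itertools.product((0, 1), repeat=n):
        k = sum(pattern)
        dist[pattern] = mid.fractions[k] / comb(n, k)
    return dist


def enumerate_mids(model: NetworkModel, flux: Dict[str, float], tracer: TracerSpec) -> Dict[str, np.ndarray]:
    """Exhaustive positional-isotopomer MIDs on an acyclic network."""
    tracer = tracer.for_model(model)
    dists: Dict[str, Dist] = {}
    for met in model.metabolites:
        if met.kind == "substrate":
            dists[met.id] = _substrate_dist(tracer.effective_mid(met.id))

    producers: Dict[str, List[Tuple[Reaction, int]]] = {}
    for rxn in model.reactions:
        for occ, (pid, _) in enumerate(rxn.products):
            producers.setdefault(pid, []).append((rxn, occ))

    in_progress: set = set()

    def resolve(met_id: str) -> Dist:
        if met_id in dists:
            return dists[met_id]
        if met_id in in_progress:
            raise ValueError(f"cycle through {met_id!r}; enumeration needs an acyclic network")
        in_progress.add(met_id)
        n = model.metabolite(met_id).n_carbons
        acc: Dist = {p: 0.0 for p in itertools.product((0, 1), repeat=n)}
        total_w = 0.0
        for rxn, occ in producers.get(met_id, []):
            w = flux[rxn.id] * rxn.products[occ][1]
            if w <= 0:
                continue
            total_w += w
            pmap = rxn.atom_map[occ]
            sub_ids = sorted({src[0] for src in pmap if src is not None})
            sub_dists = [resolve(rxn.substrates[s][0]) for s in sub_ids]
            for combo in itertools.product(*(d.items() for d in sub_dists)):
                prob = w
                states = {}
                for s_occ, (pattern, p) in zip(sub_ids, combo):
                    prob *= p
                    states[s_occ] = pattern
                if prob == 0.0:
                    continue
                out = tuple(
                    0 if src is None else states[src[0]][src[1]] for src in pmap
                )
                acc[out] += prob
        in_progress.discard(met_id)
        if total_w <= 0:
            acc = {p: 0.0 for p in acc}
            acc[(0,) * n] = 1.0
        else:
            acc = {p: v / total_w for p, v in acc.items()}
        dists[met_id] = acc
        return acc

    out: Dict[str, np.ndarray] = {}
    for met in model.metabolites:
        if met.kind == "substrate":
            continue
        dist = resolve(met.id)
        mid = np.zeros(met.n_carbons + 1)
        for pattern, p in dist.items():
            mid[sum(pattern)] += p
        out[met.id] = mid
    return out


def linear_cycle_solve(model: NetworkModel, flux: Dict[str, float], tracer: TracerSpec) -> Dict[str, np.ndarray]:
    """Direct linear solve of the positional steady state.

    Valid when every product occurrence draws carbons from at most one
    non-substrate metabolite (substrate-kind pools have fixed, known
    states), which makes each balance equation linear in the unknown
    positional vectors.  Covers single-substrate cycles like a labeled
    3-member loop with inflow and outflow.
    """
    tracer = tracer.for_model(model)
    fixed: Dict[str, np.ndarray] = {}
    for met in model.metabolites:
        if met.kind == "substrate":
            dist = _substrate_dist(tracer.effective_mid(met.id))
            n = met.n_carbons
            vec = np.zeros(1 << n)
            for pattern, p in dist.items():
                idx = sum(bit << i for i, bit in enumerate(pattern))
                vec[idx] = p
            fixed[met.id] = vec

    unknown = [m for m in model.metabolites if m.kind != "substrate"]
    sizes = [1 << m.n_carbons for m in unknown]
    offsets = dict(zip((m.id for m in unknown), np.concatenate([[0], np.cumsum(sizes)[:-1]])))
    dim = int(np.sum(sizes))
    M = np.zeros((dim, dim))
    rhs = np.zeros(dim)

    def transfer(rxn: Reaction, occ: int, n_sub: int, n_prod: int) -> np.ndarray:
        """Indicator matrix mapping substrate patterns to product patterns."""
        pmap = rxn.atom_map[occ]
        T = np.zeros((1 << n_prod, 1 << n_sub))
        for s in range(1 << n_sub):
            p = 0
            for pos, src in enumerate(pmap):
                if src is not None and (s >> src[1]) & 1:
                    p |= 1 << pos
            T[p, s] += 1.0
        return T

    for met in unknown:
        off = offsets[met.id]
        n = met.n_carbons
        sz = 1 << n
        total_w = 0.0
        for rxn in model.reactions:
            for occ, (pid, coeff) in enumerate(rxn.products):
                if pid != met.id:
                    continue
                w = flux[rxn.id] * coeff
                if w <= 0:
                    continue
                total_w += w
                pmap = rxn.atom_map[occ]
                sub_ids = sorted({src[0] for src in pmap if src is not None})
                if not sub_ids:
                    rhs[off] -= w  # all-unlabeled product
                    continue
                if len(sub_ids) > 1:
                    non_fixed = [
                        s for s in sub_ids if rxn.substrates[s][0] not in fixed
                    ]
                    if len(non_fixed) > 1:
                        raise ValueError("reaction is nonlinear in the unknown states")
                (s_occ,) = sub_ids if len(sub_ids) == 1 else (sub_ids[0],)
                # fold any fixed co-substrates into an effective transfer
                sid = rxn.substrates[s_occ][0]
                n_sub = model.metabolite(sid).n_carbons
                T = transfer(rxn, occ, n_sub, n)
                if len(sub_ids) > 1:
                    raise ValueError("mixed fixed/unknown co-substrates not supported")
                if sid in fixed:
                    rhs[off : off + sz] -= w * (T @ fixed[sid])
                else:
                    s_off = offsets[sid]
                    M[off : off + sz, s_off : s_off + T.shape[1]] += w * T
        if total_w <= 0:
            M[off : off + sz, off : off + sz] = np.eye(sz)
            rhs[off] = 1.0  # starved pool pinned at unlabeled
            continue
        M[off : off + sz, off : off + sz] -= total_w * np.eye(sz)
        rhs[off : off + sz] *= 1.0  # already negative contributions

    x = np.linalg.solve(M, rhs)
    out: Dict[str, np.ndarray] = {}
    for met in unknown:
        off = offsets[met.id]
        n = met.n_carbons
        vec = x[off : off + (1 << n)]
        mid = np.zeros(n + 1)
        for s in range(1 << n):
            mid[bin(s).count("1")] += vec[s]
        out[met.id] = mid
    return out


def random_acyclic_model(rng: np.random.Generator, max_reactions: int = 6, max_carbons: int = 4):
    """A random carbon-mapped DAG network plus a feasible positive flux.

    Returns ``(model, flux_dict, tracer)`` or None when the sampled
    stoichiometry admits no feasible flux (caller retries).
    """
    n_substrates = int(rng.integers(1, 3))
    mets: List[Metabolite] = []
    for i in range(n_substrates):
        mets.append(Metabolite(f"S{i}", int(rng.integers(1, max_carbons + 1)), "substrate"))
    created: List[Metabolite] = []
    reactions: List[Reaction] = []
    n_rxn = int(rng.integers(2, max_reactions + 1))
    for j in range(n_rxn):
        pool = mets + created
        k_sub = int(rng.integers(1, min(2, len(pool)) + 1))
        subs_idx = rng.choice(len(pool), size=k_sub, replace=False)
        subs = [pool[i] for i in subs_idx]
        carbons = [(occ, pos) for occ, s in enumerate(subs) for pos in range(s.n_carbons)]
        perm = rng.permutation(len(carbons))
        carbons = [carbons[i] for i in perm]
        k_prod = int(rng.integers(1, 3))
        prods: List[Metabolite] = []
        atom_map = []
        for p in range(k_prod):
            n_c = int(rng.integers(1, max_carbons + 1))
            met = Metabolite(f"M{j}_{p}", n_c, "sink")
            prods.append(met)
            pmap: List[Optional[Tuple[int, int]]] = []
            for _ in range(n_c):
                if carbons and rng.random() < 0.85:
                    pmap.append(carbons.pop())
                else:
                    pmap.append(None)
            atom_map.append(tuple(pmap))
        created.extend(prods)
        reactions.append(
            Reaction(
                id=f"r{j}",
                substrates=tuple((s.id, 1.0) for s in subs),
                products=tuple((p.id, 1.0) for p in prods),
                atom_map=tuple(atom_map),
                lb=0.1,
                ub=10.0,
            )
        )

    consumed = {mid for r in reactions for mid, _ in r.substrates}
    final_mets = list(mets) + [
        Metabolite(m.id, m.n_carbons, "balanced" if m.id in consumed else "sink")
        for m in created
    ]
    try:
        model = build_model(final_mets, reactions)
    except ValueError:
        return None
    res = linprog(
        c=rng.normal(size=len(model.reactions)),
        A_eq=model.A,
        b_eq=model.b,
        bounds=list(zip(model.lb, model.ub)),
        method="highs",
    )
    if not res.success:
        return None
    flux = dict(zip(model.reaction_ids, map(float, res.x)))

    tracer = TracerSpec(mids={})
    for i in range(n_substrates):
        n_c = model.metabolite(f"S{i}").n_carbons
        fracs = rng.dirichlet(np.ones(n_c + 1))
        tracer.mids[f"S{i}"] = MID(f"S{i}", fracs)
    return model, flux, tracer
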