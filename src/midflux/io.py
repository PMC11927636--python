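"""Plain-text formats: reaction models, constraints, role maps, MID tables.

Everything is line-oriented UTF-8 text or comma-separated CSV with a header
row and ``.`` decimals, so results can be re-derived without any binary
state.

Reaction-model grammar (one reaction per line)::

    ID: c1 SUB1(abc) + c2 SUB2(de) -> c3 PROD1(adbce) [+ ...] ; lb=0 ; ub=10

Lowercase letters are carbon labels; a letter shared between the two sides
assigns that substrate carbon to that product position.  A product letter
absent from every substrate is an error.  Omitted coefficients default to 1;
omitted bounds to lb=0, ub=1000.  Metabolite declarations::

    @MET id carbons=N kind=balanced|substrate|sink measured=0|1

Constraint files hold ``FIX reaction value`` and
``EQ c1*rxn1 + c2*rxn2 = value`` lines; role-map files hold
``ROLE role_name = reaction_id`` lines.  ``#`` starts a comment anywhere.

MID table CSV: columns ``condition, replicate, metabolite, m0, m1, ...``
(rows padded with empty cells past a metabolite's M+n); values are
fractions, not intensities.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fitting import MID, MeasurementSet, SolutionSet, summarize_solutions
from .network import Metabolite, NetworkModel, Reaction, build_model

__all__ = [
    "read_model",
    "write_model",
    "read_constraints",
    "read_role_map",
    "read_mids",
    "write_mids",
    "write_flux_report",
]

_MET_RE = re.compile(
    r"@MET\s+(?P<id>\S+)\s+carbons=(?P<n>\d+)\s+kind=(?P<kind>\w+)(?:\s+measured=(?P<meas>[01]))?\s*$"
)
_TERM_RE = re.compile(r"^\s*(?:(\d+(?:\.\d+)?)\s+)?([A-Za-z0-9_]+)(?:\((\w*)\))?\s*$")


class ParseError(ValueError):
    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


def _strip(line: str) -> str:
    return line.split("#", 1)[0].strip()


def _parse_side(text: str, path, lineno: int) -> List[Tuple[float, str, str]]:
    terms = []
    for raw in text.split("+"):
        m = _TERM_RE.match(raw)
        if not m:
            raise ParseError(path, lineno, f"cannot parse term {raw.strip()!r}")
        coeff = float(m.group(1)) if m.group(1) else 1.0
        terms.append((coeff, m.group(2), m.group(3) or ""))
    return terms


def read_model(path) -> NetworkModel:
    """Parse a reaction-model file into a validated :class:`NetworkModel`.

    Parse errors name the offending line.  Constraints live in a separate
    file (:func:`read_constraints`) and are applied via
    :func:`midflux.network.build_model`'s ``extra_constraints``.
    """
    text = Path(path).read_text()
    return parse_model_text(text, source=str(path))


def parse_model_text(text: str, source: str = "<string>") -> NetworkModel:
    metabolites: List[Metabolite] = []
    reactions: List[Reaction] = []
    met_by_id: Dict[str, Metabolite] = {}

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = _strip(raw)
        if not line:
            continue
        if line.startswith("@MET"):
            m = _MET_RE.match(line)
            if not m:
                raise ParseError(source, lineno, f"malformed metabolite declaration: {line!r}")
            met = Metabolite(
                id=m.group("id"),
                n_carbons=int(m.group("n")),
                kind=m.group("kind"),
                measured=m.group("meas") == "1",
            )
            if met.kind not in ("balanced", "substrate", "sink"):
                raise ParseError(source, lineno, f"unknown metabolite kind {met.kind!r}")
            if met.id in met_by_id:
                raise ParseError(source, lineno, f"duplicate metabolite {met.id!r}")
            met_by_id[met.id] = met
            metabolites.append(met)
            continue

        if ":" not in line or "->" not in line:
            raise ParseError(source, lineno, f"cannot parse line: {line!r}")
        rid, rest = line.split(":", 1)
        rid = rid.strip()
        parts = [p.strip() for p in rest.split(";")]
        lb, ub = 0.0, 1000.0
        for opt in parts[1:]:
            if opt.startswith("lb="):
                lb = float(opt[3:])
            elif opt.startswith("ub="):
                ub = float(opt[3:])
            elif opt:
                raise ParseError(source, lineno, f"unknown option {opt!r}")
        lhs, rhs = parts[0].split("->", 1)
        subs = _parse_side(lhs, source, lineno)
        prods = _parse_side(rhs, source, lineno)

        # letter -> (substrate occurrence, carbon position)
        letter_src: Dict[str, Tuple[int, int]] = {}
        for occ, (coeff, mid, letters) in enumerate(subs):
            if mid not in met_by_id:
                raise ParseError(source, lineno, f"undeclared metabolite {mid!r}")
            if letters and len(letters) != met_by_id[mid].n_carbons:
                raise ParseError(
                    source,
                    lineno,
                    f"{mid!r} declared with {met_by_id[mid].n_carbons} carbons "
                    f"but atom string {letters!r} has {len(letters)}",
                )
            for pos, letter in enumerate(letters):
                if letter in letter_src:
                    raise ParseError(source, lineno, f"carbon label {letter!r} used twice on the left side")
                letter_src[letter] = (occ, pos)

        atom_map = []
        used: set = set()
        for coeff, mid, letters in prods:
            if mid not in met_by_id:
                raise ParseError(source, lineno, f"undeclared metabolite {mid!r}")
            if letters and len(letters) != met_by_id[mid].n_carbons:
                raise ParseError(
                    source,
                    lineno,
                    f"{mid!r} declared with {met_by_id[mid].n_carbons} carbons "
                    f"but atom string {letters!r} has {len(letters)}",
                )
            pmap = []
            for letter in letters:
                if letter not in letter_src:
                    raise ParseError(
                        source,
                        lineno,
                        f"product carbon label {letter!r} does not appear in any substrate",
                    )
                if letter in used:
                    raise ParseError(source, lineno, f"carbon label {letter!r} used twice on the right side")
                used.add(letter)
                pmap.append(letter_src[letter])
            if not letters:
                pmap = [None] * met_by_id[mid].n_carbons
            atom_map.append(tuple(pmap))

        reactions.append(
            Reaction(
                id=rid,
                substrates=tuple((mid, c) for c, mid, _ in subs),
                products=tuple((mid, c) for c, mid, _ in prods),
                atom_map=tuple(atom_map),
                lb=lb,
                ub=ub,
            )
        )

    return build_model(metabolites, reactions)


def write_model(model: NetworkModel, path) -> None:
    """Serialize a model back to the reaction-file grammar (round-trips)."""
    lines = []
    for met in model.metabolites:
        lines.append(
            f"@MET {met.id} carbons={met.n_carbons} kind={met.kind} "
            f"measured={1 if met.measured else 0}"
        )
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for rxn in model.reactions:
        letters: Dict[Tuple[int, int], str] = {}
        k = 0
        for occ, (mid, _) in enumerate(rxn.substrates):
            for pos in range(model.metabolite(mid).n_carbons):
                letters[(occ, pos)] = alphabet[k]
                k += 1
        subs = " + ".join(
            (f"{c:g} " if c != 1 else "")
            + mid
            + "("
            + "".join(letters[(occ, p)] for p in range(model.metabolite(mid).n_carbons))
            + ")"
            for occ, (mid, c) in enumerate(rxn.substrates)
        )
        prod_terms = []
        for occ, (mid, c) in enumerate(rxn.products):
            pmap = rxn.atom_map[occ]
            s = "".join(letters[src] if src is not None else "?" for src in pmap)
            if any(src is None for src in pmap):
                s = ""  # unlabeled-source products serialize without atoms
            prod_terms.append((f"{c:g} " if c != 1 else "") + mid + (f"({s})" if s else ""))
        lines.append(f"{rxn.id}: {subs} -> {' + '.join(prod_terms)} ; lb={rxn.lb:g} ; ub={rxn.ub:g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_constraints(path) -> List[Tuple[Dict[str, float], float]]:
    """Parse FIX/EQ constraint lines into ``extra_constraints`` pairs."""
    return parse_constraints_text(Path(path).read_text(), source=str(path))


def parse_constraints_text(text: str, source: str = "<string>") -> List[Tuple[Dict[str, float], float]]:
    path = source
    out: List[Tuple[Dict[str, float], float]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = _strip(raw)
        if not line:
            continue
        if line.startswith("FIX"):
            try:
                _, rid, value = line.split()
            except ValueError:
                raise ParseError(path, lineno, f"malformed FIX line: {line!r}") from None
            out.append(({rid: 1.0}, float(value)))
        elif line.startswith("EQ"):
            body = line[2:]
            if "=" not in body:
                raise ParseError(path, lineno, "EQ line lacks '='")
            lhs, value = body.rsplit("=", 1)
            coeffs: Dict[str, float] = {}
            for term in lhs.split("+"):
                term = term.strip()
                if "*" in term:
                    c, rid = term.split("*", 1)
                    coeffs[rid.strip()] = coeffs.get(rid.strip(), 0.0) + float(c)
                else:
                    coeffs[term] = coeffs.get(term, 0.0) + 1.0
            out.append((coeffs, float(value)))
        else:
            raise ParseError(path, lineno, f"unknown constraint line: {line!r}")
    return out


def read_role_map(path) -> Dict[str, str]:
    """Parse ``ROLE name = reaction`` lines into a role map."""
    return parse_roles_text(Path(path).read_text(), source=str(path))


def parse_roles_text(text: str, source: str = "<string>") -> Dict[str, str]:
    path = source
    roles: Dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = _strip(raw)
        if not line:
            continue
        m = re.match(r"ROLE\s+(\w+)\s*=\s*(\S+)\s*$", line)
        if not m:
            raise ParseError(path, lineno, f"malformed ROLE line: {line!r}")
        roles[m.group(1)] = m.group(2)
    return roles


# ---------------------------------------------------------------------------
# MID tables
# ---------------------------------------------------------------------------

SUM_TOL = 0.01  #: rows whose fractions deviate from 1 beyond this are rejected


def read_mids(path, model: Optional[NetworkModel] = None) -> Dict[str, MeasurementSet]:
    """Read a MID table CSV into one :class:`MeasurementSet` per condition.

    Rows whose fractions sum outside ``1 +/- 0.01`` are rejected with their
    row number; duplicate (condition, replicate, metabolite) rows are an
    error.  When ``model`` is given, each metabolite's vector length is
    taken from its carbon count; otherwise the non-empty prefix is used.
    """
    df = pd.read_csv(path)
    required = {"condition", "replicate", "metabolite"}
    if not required.issubset(df.columns):
        raise ValueError(f"MID table must have columns {sorted(required)} + m0, m1, ...")
    mcols = [c for c in df.columns if re.fullmatch(r"m\d+", c)]
    mcols.sort(key=lambda c: int(c[1:]))

    seen = set()
    per_condition: Dict[str, Dict[str, List[Tuple[object, MID]]]] = {}
    for idx, row in df.iterrows():
        key = (row["condition"], row["replicate"], row["metabolite"])
        if key in seen:
            raise ValueError(f"row {idx + 2}: duplicate (condition, replicate, metabolite) {key}")
        seen.add(key)
        vals = row[mcols].to_numpy(dtype=float)
        if model is not None:
            n = model.metabolite(str(row["metabolite"])).n_carbons
            vals = vals[: n + 1]
        else:
            nonnan = np.where(~np.isnan(vals))[0]
            if nonnan.size == 0:
                raise ValueError(f"row {idx + 2}: no fraction values")
            vals = vals[: nonnan[-1] + 1]
        if np.any(np.isnan(vals)):
            raise ValueError(f"row {idx + 2}: missing fraction inside the vector")
        if abs(vals.sum() - 1.0) > SUM_TOL:
            raise ValueError(
                f"row {idx + 2}: fractions sum to {vals.sum():.4f}, outside 1 +/- {SUM_TOL}"
            )
        mid = MID(str(row["metabolite"]), vals)
        cond = per_condition.setdefault(str(row["condition"]), {})
        cond.setdefault(str(row["metabolite"]), []).append((row["replicate"], mid))

    out = {}
    for cond, mets in per_condition.items():
        replicates = {
            met: [mid for _, mid in sorted(pairs, key=lambda p: str(p[0]))]
            for met, pairs in mets.items()
        }
        out[cond] = MeasurementSet(condition=cond, replicates=replicates)
    return out


def write_mids(tables: Mapping[str, MeasurementSet], path) -> None:
    """Write MeasurementSets back to the MID table CSV dialect."""
    max_len = max(
        mid.fractions.size
        for ms in tables.values()
        for reps in ms.replicates.values()
        for mid in reps
    )
    rows = []
    for cond in sorted(tables):
        ms = tables[cond]
        for met in sorted(ms.replicates):
            for rep, mid in enumerate(ms.replicates[met], start=1):
                row: Dict[str, object] = {
                    "condition": cond,
                    "replicate": rep,
                    "metabolite": met,
                }
                for k in range(max_len):
                    row[f"m{k}"] = (
                        repr(float(mid.fractions[k])) if k < mid.fractions.size else ""
                    )
                rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_flux_report(
    solution_set: SolutionSet,
    out_dir,
    prefix: str = "fluxes",
    extra_metadata: Optional[Mapping[str, object]] = None,
) -> Tuple[Path, Path]:
    """Write the per-reaction summary CSV and a JSON metadata sidecar.

    Returns (csv_path, json_path).  The CSV holds
    ``reaction, median, iqr_low, iqr_high, min, max, n_solutions``; the
    sidecar records seed, start counts, tolerances and the best loss so any
    number in the CSV can be re-derived.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = summarize_solutions(solution_set)
    csv_path = out_dir / f"{prefix}_{solution_set.condition}.csv"
    summary.to_csv(csv_path, index=False, float_format="%.10g")
    meta = {
        "condition": solution_set.condition,
        "seed": solution_set.seed,
        "n_starts": solution_set.n_starts,
        "n_keep": solution_set.n_keep,
        "n_retained": len(solution_set.solutions),
        "best_loss": float(solution_set.best[1]),
        "feasibility_tolerance": 1e-6,
        "epsilon_floor": 1e-9,
    }
    if extra_metadata:
        meta.update(extra_metadata)
    json_path = out_dir / f"{prefix}_{solution_set.condition}.json"
    json_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return csv_path, json_path
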