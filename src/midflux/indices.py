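"""Derived flux indices: cancer (lactate-ratio), TCA and noncanonical TCA.

The cancer index is a Warburg-style lactate ratio: lactate excretion flux
over glucose uptake flux.  The TCA index relates pyruvate entry into the
TCA cycle to glucose uptake, and the noncanonical TCA index relates the
citrate-efflux (cytosolic citrate) route to pyruvate entry into the cycle.
All three are ratios of fluxes, hence invariant to global flux rescaling.

The exact reactions standing in each role are supplied by the caller
through a role map, so alternative index definitions are a role-map edit,
not a code change; the formulas actually applied are recorded verbatim in
the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

from .fitting import FluxVector, SolutionSet
from .network import NetworkModel

__all__ = ["ROLES", "FluxIndices", "compute_indices", "indices_over_set"]

ROLES = (
    "glucose_uptake",
    "lactate_excretion",
    "pyruvate_to_tca",
    "citrate_efflux_route",
)

_DEFINITIONS = {
    "cancer_index": "lactate_excretion / glucose_uptake",
    "tca_index": "pyruvate_to_tca / glucose_uptake",
    "noncanonical_tca_index": "citrate_efflux_route / pyruvate_to_tca",
}


@dataclass
class FluxIndices:
    """Index values for one flux vector; None marks an undefined ratio."""

    cancer_index: Optional[float]
    tca_index: Optional[float]
    noncanonical_tca_index: Optional[float]
    undefined: tuple = ()
    definitions_used: Dict[str, str] = field(default_factory=lambda: dict(_DEFINITIONS))

    def as_dict(self) -> Dict[str, Optional[float]]:
        return {
            "cancer_index": self.cancer_index,
            "tca_index": self.tca_index,
            "noncanonical_tca_index": self.noncanonical_tca_index,
        }


def _ratio(num: float, den: float):
    if den == 0.0:
        return None
    return num / den


def compute_indices(
    model: NetworkModel, flux, role_map: Mapping[str, str]
) -> FluxIndices:
    """Compute the three flux indices for one flux vector.

    ``role_map`` assigns a model reaction id to each role in :data:`ROLES`.
    A zero denominator yields an explicitly flagged undefined index (None),
    never a silent zero.
    """
    missing = [r for r in ROLES if r not in role_map]
    if missing:
        raise KeyError(f"role map missing roles: {missing}")
    values = flux.as_dict() if isinstance(flux, FluxVector) else dict(flux)
    role_flux = {}
    for role in ROLES:
        rid = role_map[role]
        if rid not in model.reaction_ids:
            raise KeyError(f"role {role!r} assigned to unknown reaction {rid!r}")
        role_flux[role] = float(values[rid])

    cancer = _ratio(role_flux["lactate_excretion"], role_flux["glucose_uptake"])
    tca = _ratio(role_flux["pyruvate_to_tca"], role_flux["glucose_uptake"])
    noncanon = _ratio(role_flux["citrate_efflux_route"], role_flux["pyruvate_to_tca"])
    undefined = tuple(
        name
        for name, val in zip(
            ("cancer_index", "tca_index", "noncanonical_tca_index"),
            (cancer, tca, noncanon),
        )
        if val is None
    )
    return FluxIndices(cancer, tca, noncanon, undefined=undefined)


def indices_over_set(
    model: NetworkModel, solution_set: SolutionSet, role_map: Mapping[str, str]
) -> pd.DataFrame:
    """Median and IQR of each index over a solution set's retained solutions.

    Solutions for which an index is undefined (zero denominator) are
    excluded from that index's summary and counted in ``n_undefined``.
    """
    if not solution_set.solutions:
        raise ValueError("empty solution set")
    per_solution = [
        compute_indices(model, fv, role_map) for fv, _ in solution_set.solutions
    ]
    rows = []
    for name in ("cancer_index", "tca_index", "noncanonical_tca_index"):
        vals = np.array(
            [getattr(ix, name) for ix in per_solution if getattr(ix, name) is not None]
        )
        rows.append(
            {
                "index": name,
                "median": np.median(vals) if vals.size else np.nan,
                "iqr_low": np.percentile(vals, 25) if vals.size else np.nan,
                "iqr_high": np.percentile(vals, 75) if vals.size else np.nan,
                "n_defined": vals.size,
                "n_undefined": len(per_solution) - vals.size,
                "definition": _DEFINITIONS[name],
            }
        )
    return pd.DataFrame(rows)
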