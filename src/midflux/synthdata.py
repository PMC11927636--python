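"""Synthetic tracer experiments with known ground-truth fluxes.

Emulates a steady-state U-13C6-glucose labeling experiment on the shipped
fixture network under two conditions: a "vehicle" regime and a "shift"
regime in which flux is redirected into the de novo serine branch, the
lactate share of the pyruvate node rises and the oxidative PPP falls —
the directional template of a medium-chain-fatty-acid-induced shift toward
serine/one-carbon metabolism.  Ground-truth flux values are published
constants; random seeds control only the measurement noise.

Measurement noise is i.i.d. Gaussian per MID entry (default sd 0.01),
clipped at zero and renormalized — a simple, standard error model for MID
fractions.  Replicates default to 3 (biological triplicate).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Optional, Tuple

import numpy as np

from .fitting import MID, FluxVector, MeasurementSet
from .io import parse_constraints_text, parse_model_text, parse_roles_text
from .isotopomer import MIDSet, TracerSpec, predict_mids
from .network import NetworkModel, build_model

__all__ = [
    "FluxRegime",
    "SyntheticDataset",
    "fixture_model",
    "fixture_role_map",
    "fixture_tracer",
    "make_regimes",
    "simulate_dataset",
    "IDENTIFIABLE_REACTIONS",
    "UNIDENTIFIABLE_REACTIONS",
]

#: the citrate oxidation/efflux split carries no labeling information
#: (both routes drain the same citrate pool), so it is structurally
#: unidentifiable from MIDs; every other fixture flux is identifiable once
#: the four exchange rates are fixed.
UNIDENTIFIABLE_REACTIONS = ("v_cit_ox", "v_cit_exp")


def _data_text(name: str) -> str:
    return resources.files("midflux.data").joinpath(name).read_text()


def fixture_model(with_constraints: bool = True) -> NetworkModel:
    """The shipped 19-reaction glycolysis/PPP/serine-one-carbon/TCA-entry model.

    With ``with_constraints`` (default) the four measured exchange rates
    (glucose uptake, serine uptake, alanine uptake, beta-oxidation acetyl
    inflow) are fixed as extra equality rows.
    """
    model = parse_model_text(_data_text("fixture_model.txt"), source="fixture_model.txt")
    if not with_constraints:
        return model
    extra = parse_constraints_text(
        _data_text("fixture_constraints.txt"), source="fixture_constraints.txt"
    )
    return build_model(model.metabolites, model.reactions, extra)


def fixture_role_map() -> Dict[str, str]:
    return parse_roles_text(_data_text("fixture_roles.txt"), source="fixture_roles.txt")


def fixture_tracer(purity: float = 1.0) -> TracerSpec:
    """Uniformly 13C6-labeled glucose; all other inflows unlabeled."""
    return TracerSpec.uniform("GLC", 6, purity=purity)


IDENTIFIABLE_REACTIONS: Tuple[str, ...] = ()  # filled below, after ground truth


@dataclass
class FluxRegime:
    """A named ground-truth flux assignment for the fixture model."""

    name: str
    fluxes: Dict[str, float]
    description: str

    def flux_vector(self, model: NetworkModel) -> FluxVector:
        v = model.flux_array(self.fluxes)
        return FluxVector(v, model.reaction_ids, model.residual(v))


# Ground-truth regimes (rate units match the fixed exchange rates).
# vehicle: modest serine branch, higher PPP; shift: serine branch up,
# lactate share of the pyruvate node up, PPP down.
_VEHICLE = {
    "v_upt": 10.0, "v_ald": 8.5, "v_ppp": 1.5, "v_tkt": 1.5,
    "v_gapdh": 18.5, "v_pk": 17.5, "v_phgdh": 1.0, "v_serup": 2.0,
    "v_shmt": 3.0, "v_glyout": 3.0, "v_ms": 3.0, "v_mat": 3.0,
    "v_alaup": 2.0, "v_ldh": 13.5, "v_pdh": 6.0, "v_fao": 1.0,
    "v_cs": 7.0, "v_cit_ox": 6.0, "v_cit_exp": 1.0,
}
_SHIFT = {
    "v_upt": 10.0, "v_ald": 9.2, "v_ppp": 0.8, "v_tkt": 0.8,
    "v_gapdh": 19.2, "v_pk": 16.7, "v_phgdh": 2.5, "v_serup": 2.0,
    "v_shmt": 4.5, "v_glyout": 4.5, "v_ms": 4.5, "v_mat": 4.5,
    "v_alaup": 2.0, "v_ldh": 14.0, "v_pdh": 4.7, "v_fao": 1.0,
    "v_cs": 5.7, "v_cit_ox": 4.2, "v_cit_exp": 1.5,
}

IDENTIFIABLE_REACTIONS = tuple(
    r for r in sorted(_VEHICLE) if r not in UNIDENTIFIABLE_REACTIONS
)


def make_regimes(model: Optional[NetworkModel] = None, seed: int = 0) -> Tuple[FluxRegime, FluxRegime]:
    """The (vehicle, shift) ground-truth regimes, validated against the model.

    The constants are fixed; ``seed`` is accepted for interface symmetry but
    does not alter them (noise seeds live in :func:`simulate_dataset`).
    """
    model = model or fixture_model()
    vehicle = FluxRegime(
        "vehicle",
        dict(_VEHICLE),
        "baseline: serine branch 1.0, PPP 1.5, lactate share 0.692",
    )
    shift = FluxRegime(
        "shift",
        dict(_SHIFT),
        "serine branch 2.5 (up), PPP 0.8 (down), lactate share 0.749 (up)",
    )
    for regime in (vehicle, shift):
        fv = regime.flux_vector(model)
        if fv.residual > 1e-6:
            raise ValueError(f"regime {regime.name!r} infeasible (residual {fv.residual:.3g})")
        if np.any(fv.values < model.lb - 1e-9) or np.any(fv.values > model.ub + 1e-9):
            raise ValueError(f"regime {regime.name!r} violates flux bounds")
    return vehicle, shift


@dataclass
class SyntheticDataset:
    """Replicate MID tables plus the generating ground truth."""

    regime: FluxRegime
    tracer: TracerSpec
    n_replicates: int
    noise_sd: float
    seed: int
    measurements: MeasurementSet
    noiseless: MIDSet

    @property
    def condition(self) -> str:
        return self.regime.name


def simulate_dataset(
    model: NetworkModel,
    regime: FluxRegime,
    tracer: Optional[TracerSpec] = None,
    n_replicates: int = 3,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> SyntheticDataset:
    """Forward-simulate noisy replicate MIDs for the measured metabolites.

    Each replicate entry is the noiseless fraction plus N(0, noise_sd)
    noise, clipped at zero and renormalized.  ``noise_sd = 0`` reproduces
    the noiseless MIDs exactly.  Deterministic given ``seed``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    tracer = tracer or fixture_tracer()
    fv = regime.flux_vector(model)
    noiseless = predict_mids(model, fv.values, tracer)
    rng = np.random.default_rng(seed)

    replicates: Dict[str, List[MID]] = {}
    for met_id in sorted(model.measured_ids):
        base = noiseless[met_id].fractions
        reps = []
        for _ in range(n_replicates):
            if noise_sd == 0.0:
                reps.append(MID(met_id, base.copy()))
            else:
                noisy = np.clip(base + rng.normal(0.0, noise_sd, size=base.size), 0.0, None)
                if noisy.sum() <= 0:
                    noisy = base.copy()
                reps.append(MID(met_id, noisy))
        replicates[met_id] = reps

    measurements = MeasurementSet(condition=regime.name, replicates=replicates)
    return SyntheticDataset(
        regime=regime,
        tracer=tracer,
        n_replicates=n_replicates,
        noise_sd=noise_sd,
        seed=seed,
        measurements=measurements,
        noiseless=noiseless,
    )
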