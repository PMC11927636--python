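"""Forward model: convolution, single-reaction MIDs, network prediction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import midflux as mf
from midflux.isotopomer import positional_from_mid

import _oracle


# ---------------------------------------------------------------------------
# convolve
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "a, b, expected",
    [
        ([1, 0], [0, 1], [0, 1, 0]),            # M+0 joined with M+1 gives M+1
        ([0.5, 0.5], [0.5, 0.5], [0.25, 0.5, 0.25]),  # binomial
        ([0.2, 0.3, 0.5], [1.0], [0.2, 0.3, 0.5]),    # M+0 fragment is identity
    ],
)
def test_convolve_examples(a, b, expected):
    np.testing.assert_allclose(mf.convolve(a, b), expected, atol=1e-12)


@given(
    st.lists(st.floats(0.01, 1.0), min_size=1, max_size=5),
    st.lists(st.floats(0.01, 1.0), min_size=1, max_size=5),
)
@settings(deadline=None, max_examples=50, derandomize=True)
def test_convolve_preserves_mass(a, b):
    out = mf.convolve(a, b)
    assert out.size == len(a) + len(b) - 1
    assert np.isclose(out.sum(), np.sum(a) * np.sum(b))


# ---------------------------------------------------------------------------
# reaction_mid
# ---------------------------------------------------------------------------

def _two_sub_condensation():
    mets = [
        mf.Metabolite("X", 2, "substrate"),
        mf.Metabolite("Y", 2, "substrate"),
        mf.Metabolite("Z", 4, "sink"),
    ]
    rxn = mf.Reaction(
        "r_cond",
        (("X", 1.0), ("Y", 1.0)),
        (("Z", 1.0),),
        (((0, 0), (0, 1), (1, 0), (1, 1)),),
    )
    return mf.build_model(mets, [rxn])


def test_cleavage_splits_full_labeling(model):
    """Fully labeled hexose cleaves into two fully labeled trioses."""
    g6p = np.zeros(64)
    g6p[63] = 1.0  # all six carbons labeled
    mid = mf.reaction_mid(model, "v_ald", "GAP", {"G6P": g6p})
    np.testing.assert_allclose(mid.fractions, [0, 0, 0, 1], atol=1e-12)


def test_serine_cleavage_routes_c3_to_one_carbon_unit(model):
    """Serine 100% M+3 yields a fully labeled one-carbon unit (CH2-THF)."""
    ser = np.zeros(8)
    ser[7] = 1.0
    mlthf = mf.reaction_mid(model, "v_shmt", "MLTHF", {"SER": ser})
    np.testing.assert_allclose(mlthf.fractions, [0, 1], atol=1e-12)
    gly = mf.reaction_mid(model, "v_shmt", "GLY", {"SER": ser})
    np.testing.assert_allclose(gly.fractions, [0, 0, 1], atol=1e-12)


def test_condensation_matches_positional_enumeration():
    """2C+2C condensation with nonuniform substrates vs brute-force enumeration."""
    model = _two_sub_condensation()
    rng = np.random.default_rng(5)
    # positionally nonuniform substrate states
    px = rng.dirichlet(np.ones(4))
    py = rng.dirichlet(np.ones(4))
    mid = mf.reaction_mid(model, "r_cond", "Z", {"X": px, "Y": py})
    expected = np.zeros(5)
    for sx in range(4):
        for sy in range(4):
            z = (sx & 1) + ((sx >> 1) & 1) + (sy & 1) + ((sy >> 1) & 1)
            expected[z] += px[sx] * py[sy]
    np.testing.assert_allclose(mid.fractions, expected, atol=1e-12)


# ---------------------------------------------------------------------------
# predict_mids
# ---------------------------------------------------------------------------

def _linear_chain_model():
    mets = [
        mf.Metabolite("S", 1, "substrate"),
        mf.Metabolite("A", 1, "balanced"),
        mf.Metabolite("B", 1, "sink"),
    ]
    rxns = [
        mf.Reaction("r1", (("S", 1.0),), (("A", 1.0),), (((0, 0),),), lb=0, ub=10),
        mf.Reaction("r2", (("A", 1.0),), (("B", 1.0),), (((0, 0),),), lb=0, ub=10),
    ]
    return mf.build_model(mets, rxns)


def test_single_precursor_chain_passes_label_through():
    model = _linear_chain_model()
    tracer = mf.TracerSpec.uniform("S", 1)
    mids = mf.predict_mids(model, {"r1": 2.0, "r2": 2.0}, tracer)
    np.testing.assert_allclose(mids["A"].fractions, [0, 1], atol=1e-12)
    np.testing.assert_allclose(mids["B"].fractions, [0, 1], atol=1e-12)


def test_two_precursors_weighted_average():
    """Pools mixing 1:3 from an unlabeled and a labeled precursor give [0.25, 0.75]."""
    mets = [
        mf.Metabolite("U", 1, "substrate"),
        mf.Metabolite("L", 1, "substrate"),
        mf.Metabolite("P", 1, "sink"),
    ]
    rxns = [
        mf.Reaction("r_u", (("U", 1.0),), (("P", 1.0),), (((0, 0),),), lb=0, ub=10),
        mf.Reaction("r_l", (("L", 1.0),), (("P", 1.0),), (((0, 0),),), lb=0, ub=10),
    ]
    model = mf.build_model(mets, rxns)
    tracer = mf.TracerSpec.uniform("L", 1)
    mids = mf.predict_mids(model, {"r_u": 1.0, "r_l": 3.0}, tracer)
    np.testing.assert_allclose(mids["P"].fractions, [0.25, 0.75], atol=1e-12)


def _cycle_model():
    """Labeled inflow, 3-reaction cycle, outflow: A -> B -> C -> A."""
    mets = [
        mf.Metabolite("S", 2, "substrate"),
        mf.Metabolite("A", 2, "balanced"),
        mf.Metabolite("B", 2, "balanced"),
        mf.Metabolite("C", 2, "balanced"),
        mf.Metabolite("X", 2, "sink"),
    ]
    rxns = [
        mf.Reaction("v_in", (("S", 1.0),), (("A", 1.0),), (((0, 0), (0, 1)),), lb=0, ub=10),
        mf.Reaction("v1", (("A", 1.0),), (("B", 1.0),), (((0, 1), (0, 0)),), lb=0, ub=10),
        mf.Reaction("v2", (("B", 1.0),), (("C", 1.0),), (((0, 0), (0, 1)),), lb=0, ub=10),
        mf.Reaction("v3", (("C", 1.0),), (("A", 1.0),), (((0, 0), (0, 1)),), lb=0, ub=10),
        mf.Reaction("v_out", (("A", 1.0),), (("X", 1.0),), (((0, 0), (0, 1)),), lb=0, ub=10),
    ]
    return mf.build_model(mets, rxns)


def test_cycle_fixed_point_matches_linear_solve():
    model = _cycle_model()
    tracer = mf.TracerSpec(mids={"S": mf.MID("S", [0.2, 0.3, 0.5])})
    flux = {"v_in": 1.0, "v1": 2.0, "v2": 2.0, "v3": 2.0, "v_out": 1.0}
    mids = mf.predict_mids(model, flux, tracer)
    expected = _oracle.linear_cycle_solve(model, flux, tracer)
    for met in ("A", "B", "C", "X"):
        np.testing.assert_allclose(mids[met].fractions, expected[met], atol=1e-6)
    assert mids.iterations > 0  # solved by fixed-point iteration


def test_random_acyclic_networks_match_enumeration():
    """Vectorized simulator vs dictionary-based exhaustive enumeration."""
    rng = np.random.default_rng(123)
    checked = 0
    while checked < 10:
        sample = _oracle.random_acyclic_model(rng)
        if sample is None:
            continue
        model, flux, tracer = sample
        mids = mf.predict_mids(model, flux, tracer)
        expected = _oracle.enumerate_mids(model, flux, tracer)
        for met, exp in expected.items():
            np.testing.assert_allclose(
                mids[met].fractions, exp, atol=1e-8, err_msg=f"{met} (network {checked})"
            )
        checked += 1


def test_predicted_mids_are_normalized(model, regimes, tracer):
    vehicle, _ = regimes
    mids = mf.predict_mids(model, vehicle.fluxes, tracer)
    for met in mids:
        f = mids[met].fractions
        assert np.all(f >= 0)
        assert abs(f.sum() - 1.0) < 1e-8


def test_scale_invariance(model, regimes, tracer):
    """Multiplying all fluxes by a constant leaves predicted MIDs unchanged."""
    vehicle, _ = regimes
    base = mf.predict_mids(model, vehicle.fluxes, tracer, check_feasibility=False)
    scaled_flux = {k: 3.7 * v for k, v in vehicle.fluxes.items()}
    scaled = mf.predict_mids(model, scaled_flux, tracer, check_feasibility=False)
    for met in base:
        np.testing.assert_allclose(base[met].fractions, scaled[met].fractions, atol=1e-12)


def test_unlabeled_inflow_dilution_is_monotone(model, regimes, tracer):
    """Raising unlabeled serine uptake never increases any labeled serine fraction."""
    vehicle, _ = regimes
    fluxes = dict(vehicle.fluxes)
    prev = None
    for serup in (1.0, 2.0, 4.0, 8.0):
        f = dict(fluxes)
        f["v_serup"] = serup
        f["v_shmt"] = f["v_phgdh"] + serup  # keep serine balanced
        f["v_glyout"] = f["v_ms"] = f["v_mat"] = f["v_shmt"]
        mids = mf.predict_mids(model, f, tracer, check_feasibility=False)
        labeled = mids["SER"].fractions[1:]
        if prev is not None:
            assert np.all(labeled <= prev + 1e-12)
        prev = labeled


def test_starved_pool_is_pruned_not_fatal(model, regimes, tracer):
    """Zero serine-branch flux starves the one-carbon pools; they are flagged M+0."""
    vehicle, _ = regimes
    f = dict(vehicle.fluxes)
    f["v_phgdh"] = f["v_serup"] = f["v_shmt"] = 0.0
    f["v_glyout"] = f["v_ms"] = f["v_mat"] = 0.0
    f["v_pk"] = 18.5  # reroute PG3
    f["v_ldh"] = 14.5
    mids = mf.predict_mids(model, f, tracer, check_feasibility=False)
    assert "MLTHF" in mids.pruned and "SAM" in mids.pruned
    np.testing.assert_allclose(mids["SAM"].fractions, [1, 0], atol=1e-12)


def test_fractional_abundance_lookup_and_errors(model, regimes, tracer):
    vehicle, _ = regimes
    mids = mf.predict_mids(model, vehicle.fluxes, tracer)
    assert mf.fractional_abundance(mids, "SAM", 1) == mids["SAM"][1]
    with pytest.raises(KeyError):
        mf.fractional_abundance(mids, "NOPE", 0)
    with pytest.raises(ValueError):
        mf.fractional_abundance(mids, "SAM", 5)


def test_serine_branch_raises_sam_m1(model, regimes, tracer):
    """Routing more 3-phosphoglycerate into the serine branch raises SAM M+1."""
    vehicle, _ = regimes
    high = dict(vehicle.fluxes)
    low = dict(vehicle.fluxes)
    low.update({"v_phgdh": 0.0, "v_pk": 18.5, "v_ldh": 14.5,
                "v_shmt": 2.0, "v_glyout": 2.0, "v_ms": 2.0, "v_mat": 2.0})
    m_high = mf.predict_mids(model, high, tracer, check_feasibility=False)
    m_low = mf.predict_mids(model, low, tracer, check_feasibility=False)
    assert mf.fractional_abundance(m_high, "SAM", 1) > mf.fractional_abundance(m_low, "SAM", 1)


def test_tracer_purity_mixes_in_unlabeled():
    tracer = mf.TracerSpec.uniform("S", 2, purity=0.9)
    eff = tracer.effective_mid("S")
    np.testing.assert_allclose(eff.fractions, [0.1, 0.0, 0.9], atol=1e-12)


def test_mid_validation():
    with pytest.raises(ValueError):
        mf.MID("m", [-0.2, 1.2])
    mid = mf.MID("m", [0.5, 1.5])  # renormalized
    np.testing.assert_allclose(mid.fractions, [0.25, 0.75])


def test_positional_from_mid_spreads_mass_uniformly():
    p = positional_from_mid(mf.MID("m", [0.4, 0.4, 0.2]))
    # two singly labeled patterns share the M+1 mass
    np.testing.assert_allclose(p, [0.4, 0.2, 0.2, 0.2], atol=1e-12)
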