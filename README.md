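# midflux

Steady-state ¹³C-glucose tracing analysis: forward simulation of mass
isotopomer distributions (MIDs) on carbon-mapped metabolic networks, and
flux inference by Kullback–Leibler fitting under flux-balance constraints
with multi-start optimization.

## The problem

In a stable-isotope tracing experiment, cells are fed a labeled substrate
(here uniformly labeled [U-¹³C₆]glucose) and the isotopologue composition of
downstream metabolites — the MID, the vector of fractions of molecules
carrying 0, 1, …, *n* heavy carbons — is measured by LC-MS once labeling has
reached steady state. Because every reaction passes specific carbons from
substrate to product, the MIDs encode the relative fluxes through competing
pathways: glycolysis vs the pentose phosphate shunt, de novo serine
synthesis vs serine uptake, lactate excretion vs pyruvate oxidation.
`midflux` turns a carbon-mapped reaction network plus MID measurements into
fitted fluxes and derived pathway indices.

## The model

For a flux vector **v** over the network's reactions, the predicted MID of
metabolite *i* is the flux-weighted average of the MIDs produced through
each generating reaction *j*:

    M̃ᵢ = Σⱼ vⱼᵢ · Mⱼᵢ / Σⱼ vⱼᵢ

where `Mⱼᵢ` follows from reaction *j*'s atom map (internally the package
tracks full positional-isotopomer distributions so that cleavage and
condensation reactions are handled exactly; see `docs/methods.md`). Acyclic
precursor graphs are solved in topological order, metabolic cycles by damped
fixed-point iteration.

Fluxes are fitted by minimizing the total divergence between observed
(replicate-averaged) and predicted MIDs,

    L_total(v) = Σᵢ D_KL(Mᵢ ‖ M̃ᵢ(v))    s.t.  A·v = b,  lb ≤ v ≤ ub

where `A·v = b` encodes steady state for every balanced metabolite plus any
fixed measured exchange rates. The optimization is multi-start: local
constrained solves from random feasible points (default 10,000 starts,
keeping the 50 best by loss; tests use desk-scale analogues). Derived
indices summarize the fitted fluxes: the **cancer index** (lactate excretion
/ glucose uptake, a Warburg-style lactate ratio), the **TCA index**
(pyruvate entry into the TCA cycle / glucose uptake) and the **noncanonical
TCA index** (citrate efflux / pyruvate entry into the cycle).

The package ships a curated 19-reaction fixture network (glycolysis,
oxidative PPP, de novo serine → glycine → CH₂-THF → methionine-cycle methyl
→ SAM, pyruvate → lactate/PDH, citrate branch, unlabeled medium inflows)
plus two ground-truth flux regimes, `vehicle` and `shift`, emulating the
redirection of glucose carbon into the serine/one-carbon pathway seen when
epithelial cells are exposed to a medium-chain fatty acid.

## Worked example

```python
import midflux as mf

model = mf.fixture_model()          # 19 reactions, 11 balanced metabolites
tracer = mf.fixture_tracer()        # U-13C6 glucose
vehicle, shift = mf.make_regimes(model)

for regime in (vehicle, shift):
    mids = mf.predict_mids(model, regime.fluxes, tracer)
    print(f"{regime.name:8s} SAM M+1 = {mf.fractional_abundance(mids, 'SAM', 1):.3f}")

ds = mf.simulate_dataset(model, vehicle, tracer, n_replicates=3, noise_sd=0.01, seed=7)
fit = mf.fit_fluxes(model, ds.measurements, tracer, n_starts=50, n_keep=10, seed=7)
best, loss = fit.best
print(f"best total KL loss = {loss:.4f}")
print(f"serine-branch flux v_phgdh: true {vehicle.fluxes['v_phgdh']:.2f}, "
      f"fitted {best['v_phgdh']:.2f}")
```

prints

```
vehicle  SAM M+1 = 0.333
shift    SAM M+1 = 0.556
best total KL loss = 0.6988
serine-branch flux v_phgdh: true 1.00, fitted 0.99
```

Under the `shift` regime more 3-phosphoglycerate is routed through the
serine branch, so a larger share of SAM methyl groups carries one heavy
carbon (M+1 rises from 0.33 to 0.56). Refitting noisy triplicate data
recovers the serine-branch flux to 1% here; the residual loss (~0.7 nats)
reflects the measurement noise. Note that the citrate oxidation/efflux
split is deliberately *not* identifiable from MIDs — the noncanonical TCA
index therefore varies freely across retained solutions, which is visible
in its wide interquartile range from `indices_over_set`.

The same pipeline is scriptable from the shell:

```sh
mfa simulate --model fixture_model.txt --constraints fixture_constraints.txt \
    --reps 3 --noise 0.01 --seed 7 -o out/sim
mfa fit --model fixture_model.txt --constraints fixture_constraints.txt \
    --mids out/sim/mids.csv --n-starts 200 --n-keep 20 --seed 7 -o out/fit
mfa report --fit-a out/fit/solutions_vehicle.csv --fit-b out/fit/solutions_shift.csv \
    --model fixture_model.txt --constraints fixture_constraints.txt \
    --role-map fixture_roles.txt -o out/report
```

(The fixture files live under `src/midflux/data/`.)

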