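# serotonin-terminal

A calibrated, tested simulator of serotonin (5-HT) biochemistry in a single
serotonergic nerve terminal: synthesis from tryptophan, vesicular storage,
firing-dependent release, reuptake by the serotonin transporter (SERT),
catabolism to 5-HIAA, and feedback control by the terminal 5-HT1B
autoreceptors.

It is aimed at computational neuroscientists and neuropharmacologists who
want a small, fully deterministic kinetic platform for questions like: how
much does a SERT or TPH polymorphism actually move extracellular 5-HT once
autoreceptor feedback is accounted for? What does an acute SSRI dose do to
extracellular 5-HT in projection regions where the drug also suppresses
raphe firing?

## The model

Nine coupled stiff ODEs track concentrations (μM; time in hours) of
dihydro- and tetrahydrobiopterin (`bh2`, `bh4`), cellular tryptophan `trp`
and a large exchange pool `trp_pool`, 5-HTP, cytosolic/vesicular/
extracellular serotonin (`c5ht`, `v5ht`, `e5ht`), and 5-HIAA:

```
bh2'      =  V_TPH − V_DRR
bh4'      =  V_DRR − V_TPH
trp'      =  V_trpin(btrp) − V_TPH − (k₁·trp − k₋₁·pool)
5htp'     =  V_TPH − V_AADC
c5ht'     =  V_AADC − V_MAT + fluox(t)·V_SERT − V_catab(c5ht)
v5ht'     =  V_MAT − release(e5ht)·fire(t)·v5ht
e5ht'     =  release(e5ht)·fire(t)·v5ht − fluox(t)·V_SERT
             − V_catab(e5ht) − k_rem·e5ht
5hiaa'    =  V_catab(c5ht) + V_catab(e5ht) − k_hiaa·5hiaa
pool'     =  (k₁·trp − k₋₁·pool) − k_catab·pool
```

Transport and enzyme steps are Michaelis–Menten; tryptophan hydroxylase
(TPH) additionally carries weak substrate inhibition,

```
V_TPH = Vmax·trp·bh4 / [(K_trp + trp + trp²/K_i)(K_bh4 + bh4)] · synth(e5ht)
```

and the 5-HT1B autoreceptors enter as two dimensionless factors of
extracellular 5-HT: `synth(e5ht) = 1.5 − e5ht²/(e*² + e5ht²)` and a
piecewise-linear `release(e5ht)` (1.5 → 1.0 → 0.4), both equal to exactly 1
at the normal operating point e\* = 0.768 nM, so switching the feedback off
leaves the resting state unchanged. Three exogenous drivers — firing rate
`fire(t)`, unblocked-SERT fraction `fluox(t)`, and serum tryptophan
`btrp(t)` — encode stimulation pulses, SSRI doses, and meals.

Three constants are pinned by calibration rather than measurement (the
biopterin pool, the vesicular leak `k_out`, and the tryptophan-pool
turnover); `serotonin_terminal.calibration` derives them from steady-state
flux balance and ships them as the frozen defaults. See
[docs/methods.md](docs/methods.md) for the derivation, the numerical
choices, and known limitations.

## Worked example

```python
from serotonin_terminal import baseline_model, find_steady_state

params, state, autoreceptors = baseline_model()
rep = find_steady_state(params, autoreceptors, fluox=0.5, x0=state)

print(f"e5ht = {rep.state.e5ht_nM:.3f} nM")
print(f"v5ht = {rep.state.v5ht:.2f} uM")
print(f"V_SERT = {rep.velocities['v_sert']:.2f} uM/hr")
print(f"V_TPH  = {rep.velocities['v_tph']:.2f} uM/hr")
```

prints

```
e5ht = 1.180 nM
v5ht = 19.89 uM
V_SERT = 16.20 uM/hr
V_TPH  = 4.58 uM/hr
```

With half the SERTs blocked (`fluox = 0.5`, a moderate SSRI dose held at
steady state), extracellular 5-HT rises from 0.768 to 1.18 nM while the
vesicular store barely drops (21.45 → 19.9 μM) and synthesis is trimmed
from 5.57 to 4.58 μM/hr by the autoreceptors — tissue 5-HT stays close to
normal even though reuptake has fallen by a quarter.

The same protocols are available from the shell:

```
serotonin-terminal steady --fluox 0            # SERT knockout steady state
serotonin-terminal experiment table4           # full f = 1 … 0 sweep
serotonin-terminal experiment pulse --blocked-fraction 0.5
serotonin-terminal experiment ssri --region frontal_cortex --knockout-1b
```

Each experiment writes CSV tables/trajectories, a JSON summary, and a TOML
echo of its effective configuration; identical configs produce byte-identical
outputs.

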