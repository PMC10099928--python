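# airmn — cytokinesis-block micronucleus analysis for airway tissue models

`airmn` analyzes cytokinesis-block micronucleus (CBMN) test data from
organotypic human airway epithelium cultures — slowly dividing,
air–liquid-interface tissue inserts in which binucleated cells (BNCs) are
accumulated with cytochalasin B under EGF stimulation, and chromosome
damage shows up as micronuclei (MN) in once-divided BNCs. It is written
for genetic toxicologists who score such slides (or simulate them) and
need reproducible cytotoxicity indices, MN frequencies, and a defensible
genotoxic / not-genotoxic call per chemical.

## What it computes

Per dose group, from the nucleation-class tally (mono-, bi-,
multinucleated cells out of N classified):

- **%BNC** = 100 · n_bi / N, absolute and relative to the solvent control;
- **CBPI** = (n_mono + 2·n_bi + 3·n_multi) / N ∈ [1, 3], reported
  relative to control;
- **RI** = 100 · [(n_bi + 2·n_multi)/N]_treated / [(n_bi + 2·n_multi)/N]_control;
- **%MN** = 100 · (micronucleated BNCs) / (BNCs scored), pooled over
  replicate inserts.

The genotoxicity verdict is a conjunction rule at α = 0.05: a chemical is
called genotoxic iff the Cochran–Armitage trend test over
control + dose groups,

    Z = Σᵢ sᵢ(xᵢ − nᵢp̄) / √( p̄(1−p̄) [Σᵢ nᵢsᵢ² − (Σᵢ nᵢsᵢ)²/N] ),

is significant **and** Fisher's exact test finds at least one dose with a
significant excess of micronucleated BNCs over the concurrent control.
Fisher tails are computed by exact integer hypergeometric enumeration;
the trend test defaults to concentration scores (control = 0) with a
one-sided (increasing) alternative, and an exact permutation mode is
available for sparse counts. Secondary endpoints — TEER area
normalization (Ω × insert cm²) and adenylate-kinase release
(ΔRLU = L_P − L_A) — and Welch's t-test for comparing them are included.

A beta-binomial simulator (`airmn.simulator`) generates synthetic
experiments with the assay's structure (triplicate inserts, ~500 cells
classified and up to 667 BNCs scored per insert, log-logistic
binucleation suppression, logit-linear MN dose–response, between-insert
overdispersion) for power / type-I-error characterization.

## Worked example

The package bundles the published validation dataset: pooled triplicate
MN counts for mitomycin C (MMC), methyl methanesulfonate (MMS) and
colchicine (COL) applied apically to airway tissue inserts.

```python
from airmn import reference_experiments, genotoxic_call, pool_mn, pct_mn

exp = reference_experiments()["MMC"]
for g in exp.groups:
    mn = pool_mn(g)
    print(f"{g.concentration:>6} ug/mL  {mn.n_bnc_mn:>3}/{mn.n_bnc_scored:<4}  %MN={pct_mn(mn):.2f}")
call = genotoxic_call(exp)
print("verdict:", "genotoxic" if call.verdict else "not genotoxic",
      f"(trend p={call.trend_p:.2e}, significant doses: {sorted(call.significant_doses)})")
```

prints

```
   0.0 ug/mL    5/1811  %MN=0.28
  1.25 ug/mL   44/2098  %MN=2.10
   2.5 ug/mL   88/2125  %MN=4.14
   5.0 ug/mL  176/1827  %MN=9.63
  10.0 ug/mL  171/1033  %MN=16.55
  20.0 ug/mL   23/217   %MN=10.60
verdict: genotoxic (trend p=3.30e-73, significant doses: [1.25, 2.5, 5.0, 10.0, 20.0])
```

%MN rises from the 0.28% solvent-control background to a 16.55% peak at
10 µg/mL, then drops at 20 µg/mL where cytotoxicity leaves only 217
scorable BNCs; every dose shows a significant excess over control and the
dose trend is overwhelming, so MMC is called genotoxic.

The same pipeline runs from the shell on any scoring table
(one row per insert, CSV or TSV):

```sh
airmn score table.csv        # index report (%MN, %BNC, CBPI, RI, stars)
airmn call  table.csv        # verdict per chemical
airmn simulate --seed 7 --out sim.csv   # synthetic experiment
airmn simulate --oc --reps 1000         # rejection-rate table
```

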