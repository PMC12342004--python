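# losartan-pkpd

Genotype-aware pharmacokinetic/pharmacodynamic modeling of the
antihypertensive drug **losartan** and its active metabolite **E-3174**
(carboxylosartan).

Losartan is an angiotensin II type-1 (AT1) receptor antagonist whose effect
is dominated by E-3174, formed in the liver mainly by the polymorphic
enzyme **CYP2C9**. The common alleles *1 (wild type), *2 and *3 confer
decreasing catalytic activity, so a patient's diplotype (e.g. `*1/*3`)
shifts metabolite exposure and, with it, the blood-pressure response. This
package is for modelers and pharmacogenetics researchers who want to
simulate, calibrate and interrogate that chain quantitatively:

1. **PK model** (`losartan_pkpd.model`) — a four-compartment model (stomach,
   small intestine, central, peripheral) with a sinusoidal pyloric-flux term
   for gastric emptying and a delay differential equation for metabolite
   formation:

   ```
   dA_s/dt   = -r(t)·A_s                      r(t) = a·(1 + sin(b·t))/2
   dA_i/dt   =  r(t)·A_s − k_a·A_i
   dA_c/dt   =  k_a·A_i − k_m·A_c − (CL_p/V_p1)·A_c − (Q/V_p1)·A_c + (Q/V_p2)·A_per
   dA_per/dt =  (Q/V_p1)·A_c − (Q/V_p2)·A_per
   dA_m/dt   =  k_m·A_c(t−T) − (CL_m/V_m)·A_m
   dAUC_p/dt =  A_c/V_p1          dAUC_m/dt = A_m/V_m
   ```

   `k_m` (1/h) is the CYP2C9-activity parameter: 1.056 / 0.823 / 0.025 for
   the `*1/*1` / `*2/*2` / `*3/*3` homozygotes, arithmetic mean of the two
   homozygote values for heterozygotes.
2. **PK metrics** (`losartan_pkpd.metrics`) — Cmax, tmax, terminal
   half-life (semilog regression), AUC(0–24 h) and the piecewise
   AUC_losartan/AUC_E-3174 ratio.
3. **Exposure–effect link** (`losartan_pkpd.genotype`) — a sigmoid E-max
   model `k_block = Emax·AUC^α / (ED50^α + AUC^α)` fitted exactly through
   three dose anchors (25/50/100 mg), mapping any genotype's metabolite
   exposure to its AT1-blocking coefficient `k_block ∈ [0, 1]`.
4. **Calibration & identifiability** (`losartan_pkpd.calibrate`) — a
   stochastic ranking evolutionary strategy (SRES) minimizing the pooled
   sum of squared concentration residuals, plus fix-and-refit profiling
   that classifies each parameter as identifiable / partially identifiable
   / unidentifiable.
5. **Synthetic data & virtual cohorts** (`losartan_pkpd.synthetic`) —
   sparse noisy concentration profiles on the clinical sampling schedule,
   Hardy–Weinberg genotype sampling from published allele frequencies, and
   a *labelled reduced-order surrogate* that maps `k_block` to
   blood-pressure response for cohort demonstrations.

## Worked example

```python
from losartan_pkpd import (reference_parameters, reference_regimen, simulate,
                           summarize, fit_emax, kblock_for_genotype)

res = simulate(reference_parameters("*1/*3"), reference_regimen())  # 50 mg oral
s = summarize(res)
print(f"Cmax losartan : {s.cmax['losartan']:7.1f} nM at t = {s.tmax['losartan']:.2f} h")
print(f"AUC  E-3174   : {s.auc['e3174']:7.1f} nmol*h/L")
print(f"k_block       : {kblock_for_genotype('*1/*3', fit_emax()):7.3f}")
```

prints

```
Cmax losartan :   709.2 nM at t = 0.61 h
AUC  E-3174   :  2976.5 nmol*h/L
k_block       :   0.620
```

A heterozygous `*1/*3` carrier converts losartan at roughly half the
wild-type rate, so losartan peaks high (709 nM) while metabolite exposure
falls to ~2977 nmol·h/L — which the E-max link translates into an
AT1-blocking coefficient of 0.62, well below the wild-type 0.886: such a
patient is predicted to get a weaker blood-pressure response from the same
50 mg dose.

The same pipeline is available from a shell:

```sh
losartan-pkpd simulate --genotype '*1/*3' --out sim.csv
losartan-pkpd metrics --input sim.csv --out pk.json
losartan-pkpd emax --out emax.json
losartan-pkpd cohort --n 100 --genotype '*1/*1' --outdir cohort/
```

Every CLI run writes a `manifest.json` recording the config hash, seed and
outputs.

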