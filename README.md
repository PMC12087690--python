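# ddginet

Physiologically-based pharmacokinetic (PBPK) simulation of **drug–drug–gene
interactions (DDGIs)** around CYP2D6, for pharmacometricians and clinical
pharmacologists who want to explore how genetic CYP2D6 activity
(activity score, AS) and co-administered inhibitors/inducers jointly shift
a victim drug's exposure — and what dose would restore it.

CYP2D6 is highly polymorphic (poor to ultrarapid metabolizers) and a
frequent target of inhibiting co-medication, so a patient's *apparent*
phenotype is the product of genotype **and** drug context
(phenoconversion). `ddginet` provides the computational core of a DDGI
network analysis:

* a **multi-compound PBPK engine** — a minimal five-compartment whole-body
  model per compound (gut lumen, gut wall, liver, central, peripheral;
  perfusion-limited, oral first-pass in gut wall and liver, P-gp efflux),
  integrated as one coupled ODE system per scenario;
* **mechanistic enzyme interactions** — competitive (`Km·(1 + Σ Iu/Ki)`)
  and noncompetitive (`Vmax/(1 + Σ Iu/Ki)`) inhibition, mechanism-based
  inactivation (enzyme loss at `kinact·Iu/(KI + Iu)` against turnover
  `kdeg`), induction (`kdeg·(1 + Emax·Iu/(EC50 + Iu))` synthesis) and
  synthesis down-regulation (`·(1 − Imax·Iu/(IC50 + Iu))`), all driven by
  unbound tissue concentration `Cu = fu·C_tissue/Kp`;
* **genotype scaling and virtual populations** — CYP2D6 abundance scales
  linearly as AS/2 (AS 2 = normal-metabolizer reference, AS 0 = null
  pathway), with log-normal enzyme-expression variability and allometric
  physiology;
* **interaction-evaluation statistics** — effect PK ratios
  (PK_effect/PK_reference), geometric mean fold errors
  `GMFE = 10^(Σ|log10(pred/obs)|/n)`, and observed-ratio-dependent
  prediction-success limits with a 20% variability margin;
* **exposure-matching dose adaptation** — grid search (1% steps below
  100%, 10% above) for the dose whose steady-state AUC matches the
  AS 2 monotherapy reference, with the 80–125% bioequivalence band;
* a **synthetic-study generator** — archetype compounds (FDA-style
  sensitive/moderate substrates, strong/weak/mechanism-based inhibitors,
  inducers, mixed perpetrators), a fixture network covering all five
  mechanisms, and virtual clinical studies with log-normal observation
  noise plus truth records for parameter recovery.

## Worked example

```python
import warnings; warnings.simplefilter("ignore")
from ddginet import (build_fixture_network, fraction_metabolized,
                     adapt_dose, reference_exposure)

net = build_fixture_network(seed=0)
print(f"fm_CYP2D6(VIC_SENS) = {fraction_metabolized(net, 'VIC_SENS'):.3f}")

scenarios = {s.label: s for s in net.scenarios}
ref = reference_exposure(net, "VIC_SENS",
                         scenarios["ref_sens"].victim_regimen)
print(f"reference AUC_ss   = {ref:.2f} umol*h/L")
for label in ("dgi_pm", "ddi_comp", "ddgi_mbi"):
    rec = adapt_dose(net, scenarios[label], reference_auc=ref)
    print(label, rec.fold_change_unadapted, rec.adapted_percent,
          rec.achieved_ratio)
```

prints

```
fm_CYP2D6(VIC_SENS) = 0.883
reference AUC_ss   = 2.78 umol*h/L
dgi_pm    AS=0    fold=14.04 adapted=  7% ratio=0.983 bioequivalent=True
ddi_comp  AS=2    fold= 6.86 adapted= 15% ratio=1.027 bioequivalent=True
ddgi_mbi  AS=0.5  fold=12.40 adapted=  8% ratio=0.983 bioequivalent=True
```

Reading: the sensitive victim archetype (`VIC_SENS`) is 88% cleared by
CYP2D6. In a poor metabolizer (`dgi_pm`, AS 0) its steady-state exposure
is 14-fold the normal-metabolizer reference, and matching the reference
exposure requires reducing the dose to 7% of the original; strong
competitive inhibition in a normal metabolizer (`ddi_comp`) behaves like
partial phenoconversion (6.9-fold, 15% dose); the combined DDGI
(`ddgi_mbi`: mechanism-based inactivator in an AS 0.5 carrier) lands in
between at 8%. All adapted exposures fall inside the 80–125%
bioequivalence band.

## Command line

```bash
ddginet generate-fixtures --seed 0 --out fixtures/
ddginet simulate --network fixtures/network.json --scenario ref_sens --out sim/
ddginet evaluate --predicted sim/pk.csv --study fixtures/study --out eval/
ddginet adapt    --network fixtures/network.json --grid grid.json --out doses/
```

Every command writes delimited tables plus a `manifest.json` with seeds
and output hashes; exit code 2 flags configuration errors, 3 engine
errors. The network/scenario JSON schema is documented field-by-field in
`docs/schema.md`; the model itself in `docs/methods.md`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes from scratch (t1) the upper prediction-success limit at an
observed ratio of 1 with the 20% variability margin, and (t3) the
worst-case achieved exposure percentage of the exposure-matching dose
search over the full fixture grid — eight activity scores × eight
perpetrator combinations for the sensitive victim archetype — each entry
reported as `{"value": ..., "n": ...}`.
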