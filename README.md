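# sirnapbpk

A whole-body physiologically based pharmacokinetic–pharmacodynamic
(WB-PBPK-PD) simulator for GalNAc-conjugated siRNAs in mouse.

The model combines:

- **Two-pore extravasation** — plasma↔interstitial exchange in 15 tissue
  compartments through small (4.4 nm) and large (22.85 nm) endothelial
  pores, with hindered diffusion and convective sieving, plus an additional
  liver-specific permeability pathway (0.02 cm/min) capturing the fast
  hepatic extravasation of GalNAc-siRNAs.
- **ASGPR-mediated liver disposition** — target-mediated drug disposition:
  receptor binding, internalization, endosomal cleavage, receptor recycling
  and degradation, compound-specific endosomal degradation/escape
  (`k_endosome`), 1% cytoplasmic escape, and Ago2/RISC loading.
- **Indirect-response pharmacodynamics** — loaded RISC stimulates mRNA
  degradation (Smax/SC50), and protein production tracks mRNA raised to an
  empirical power (gamma).
- **Systemic disposition** — first-order SC absorption with compound-specific
  bioavailability, unspecific endosomal trafficking in non-liver tissues
  (kidney with its own rates), ribonuclease degradation, and passive
  glomerular filtration of unbound drug.
- **Evaluation toolkit** — trapezoid AUC, terminal half-life, AFE/AAFE
  geometric fold-error metrics with the 2-fold adequacy rule, normalized
  local sensitivity coefficients with WHO magnitude classes, and bounded
  least-squares parameter fitting.
- **Synthetic data** — a bundled library of nine compound parameter sets
  with per-parameter provenance tags, plus log-normal-noise observation
  generation and parameter-recovery experiments.

Internal units: amounts in nmol, concentrations in nmol/L, time in hours.
The bundled mouse physiology (0.025 kg reference animal, linear body-weight
scaling) ships as a documented TSV (`src/sirnapbpk/data/mouse_physiology.tsv`)
and can be overridden.

## CLI

```bash
# simulate 1 mg/kg SC of the ALN-AT3 library compound over 1000 h
sirnapbpk simulate --compound ALN-AT3 --dose 1 --route sc --t-end 1000 --out sim.csv

# local sensitivity of plasma AUC(0-1000 h)
sirnapbpk sensitivity --compound ALN-AT3 --dose 25 --parameter fu --out sens.json

# synthetic observations and a fit
sirnapbpk generate --compound ALN-AT3 --measurement liver --cv 0.15 --out obs.csv
sirnapbpk fit --compound ALN-AT3 --observations obs.csv \
    --free k_endosome=0.02:0.001:0.1 --out fit.json
```

`simulate` also accepts a YAML config (`--config run.yaml`) with keys
`compound`, `doses`, `body_weight`, `t_end`, `n_points`, `rtol`, `atol`,
`seed`, `physiology`, `outputs`. Trajectories are tidy CSV
(`time_h, observable, value, unit`) with a JSON metadata sidecar; fit and
sensitivity reports are JSON.

## Python API

```python
import numpy as np
import sirnapbpk as sp

entry = sp.get_compound("ALN-AT3")
res = sp.simulate_entry(entry, [sp.DoseEvent(0.0, "SC", 1.0)],
                        np.linspace(0, 1000, 500))
res.observables["liver"]   # nmol/L liver tissue
res.observables["mRNA"]    # % of baseline
```

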