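# fcrnpk

Mechanistic pharmacokinetic analysis of a recombinant ADAMTS13 fragment
(MDTCS) and its FcRn-binding Fc fusion (MDTCS-Fc) in the mouse.

Fusing an IgG Fc domain to a protein therapeutic extends its circulation
time by exploiting neonatal Fc-receptor (FcRn) recycling: protein taken
into sorting endosomes by pinocytosis is normally routed to the lysosome,
but Fc-bearing protein bound to FcRn at endosomal pH is rescued and
recycled back to plasma.  This package implements the full quantitative
workflow for dissecting that effect from plasma concentration--time data:

* **Compartmental ODE models** of drug disposition across plasma,
  endosome, interstitial fluid and lymph -- four states for the native
  protein, six for the Fc fusion (free and FcRn-bound endosomal drug plus
  the free-receptor pool).  Protein-dependent unknowns are the
  plasma-to-ISF rate `k_pi`, the pinocytosis rate `k_up`, the recycled
  fraction `FR`, and (Fc only) the FcRn association rate `k_on`;
  `k_off = K_D * k_on` is derived, never fitted.
* **Cluster Gauss--Newton multi-start estimation** of those parameters
  against the log10 least-squares objective
  `SSR = sum_i (log10 y_obs,i - log10 y_pred,i)^2`, with an elbow rule on
  the sorted final SSRs and an iterative one-sided Grubbs test defining
  the "accepted" parameter sets, summarized as rank-1 / min / max / median.
* **Non-compartmental analysis** (naive pooled; AUC, terminal half-life,
  CL, MRT, Vss), **BLI 1:1 binding-kinetics fitting**, **ELISA 4PL
  calibration** with LLOQ-based censoring, **approximate profile
  likelihood** identifiability from the optimizer's iterate history, and
  **local sensitivity** of windowed exposure to rate-constant fold changes.
* A **synthetic-study generator** reproducing the animal study design
  (destructive sampling at 0.083--168 h, 3--4 mice per time, two dose
  levels per protein, lognormal replicate error, BLQ-to-missing
  censoring), so the entire pipeline runs end-to-end with no external
  data.

## Worked example

```python
import numpy as np
import fcrnpk as f

fixed = f.FixedPhysiology()          # mouse physiology + endosomal sorting
fc = f.rank1_params(f.MDTCS_FC)      # lowest-SSR estimates for the fusion

# simulate a 0.0394 nmol/kg i.v. bolus in a 25 g mouse
trace = f.simulate(f.MDTCS_FC, fc, fixed, 0.0394 * 0.025,
                   np.geomspace(0.05, 96.0, 80))
print(round(trace.C_plasma[0], 3))          # 1.063  (nM, at 0.05 h)
print(round(f.auc_numeric(trace, (0, 96)), 3))   # 3.653 (nM*h over 0-96 h)

# what if the fusion associated with FcRn ten times faster?
from fcrnpk.post_analysis import local_sensitivity
res = local_sensitivity(f.MDTCS_FC, fc, fixed, "k_on", fold_changes=(10.0,))
print(round(res[0].percent_change, 1))      # 337.5  (% increase in AUC 0-96h)
```

The first two numbers are the initial plasma concentration
(`1000 * dose / V1`) and the windowed exposure of the reference
simulation.  The last is the headline mechanistic result: because
recycling of the FcRn-bound complex is orders of magnitude faster than
dissociation, speeding up association (k_on x10, k_off fixed) more than
quadruples systemic exposure, whereas slowing dissociation tenfold changes
exposure by less than 1%.

A full report bundle (NCA table, accepted-set summaries, overlay and
sensitivity figures, APL profiles, provenance manifest) can be produced
from one seed with:

```bash
fcrnpk report --seed 0 --out fcrnpk_out --iterates 200 --iterations 30
```

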