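# edemastir

Edema-weighted cardiac MR (STIR) simulation and semi-quantitative
infarct analysis.

In the first week after myocardial infarction the injured myocardium is
edematous: both its T1 and T2 relaxation times rise. On a short-TI
inversion-recovery (STIR) black-blood turbo-spin-echo image the inversion
pulse makes those two elevations act in the *same* direction, so the area
at risk (AAR) appears bright, while late gadolinium enhancement (LGE)
marks only the necrotic core. Comparing the two yields the myocardial
salvage index, and the presence/absence of edema separates acute from
chronic infarcts. `edemastir` packages this analysis chain for imaging
scientists who want a testable, fully synthetic reference implementation:

* **`mr_signal`** — closed-form steady-state magnitude signals for STIR,
  plain TSE and IR-GRE (LGE):
  `Mz(TI) = 1 − 2·e^(−TI/T1) + e^(−TR/T1)`,
  `S = pd·|Mz(TI)|·e^(−TE/T2)`, the myocardium-nulling rule
  `TI = T1·ln(2/(1+e^(−TR/T1)))`, and the ECG gating rule
  (TR = 2 RR for heart rate ≤ 80/min, else 4 RR).
* **`phantom`** — a seeded digital short-axis phantom: three slices of
  annular LV myocardium, a wedge-shaped AAR (T1/T2 1300/80 ms vs remote
  1000/50 ms at 1.5 T), a nested infarct with optional hypointense core,
  idealized black-blood cavities, and Rician magnitude noise.
* **`segmentation`** — the semi-quantitative delineation: remote-segment
  selection, mean + 2 SD threshold for STIR, full-width-at-half-maximum
  threshold for LGE, minimum-component filtering, and inclusion of dark
  (hypoenhanced) cores enclosed by the hyperintense zone.
* **`aha_segments`** — AHA 16-segment maps (6/6/4 sectors referenced to the
  anterior RV insertion), radial transmural-extent measurement, and the
  four-level grade (none / subendocardial / transmural / transmural with
  dark core).
* **`metrics`** — lesion extent in %LV, myocardial salvage index
  MSI = (AAR − infarct)/AAR, per-segment sensitivity/specificity,
  acute-vs-chronic classification, grade tabulation, and the
  pooled-variance two-sample t test.
* **`pipeline` / `cli`** — the end-to-end chain
  simulate → segment → grade → report, with NIfTI/JSON/YAML/CSV I/O.

## Worked example

```python
from dataclasses import replace
from edemastir import PhantomSpec, RunConfig, run_pipeline
from edemastir.phantom import DarkCoreSpec

cfg = RunConfig(phantom=replace(PhantomSpec(), dark_core=DarkCoreSpec()), seed=42)
report = run_pipeline(cfg, "scratch/demo")
print("edema  %.2f %%LV" % report["extents_pct_lv"]["edema"])
print("infarct %.2f %%LV" % report["extents_pct_lv"]["infarct"])
print("MSI     %.3f (truth %.3f)" % (report["msi"], report["msi_truth"]))
print("STIR confusion", report["confusion"]["stir"])
```

prints

```
edema  27.53 %LV
infarct 12.20 %LV
MSI     0.557 (truth 0.552)
STIR confusion {'tp': 8, 'fp': 0, 'fn': 0, 'tn': 8}
```

i.e. the 120°-wide, 85%-deep default AAR wedge occupies ~28 % of the LV
myocardium, the nested infarct ~12 %, so roughly 56 % of the at-risk
myocardium was salvaged; all 8 truly involved AHA segments are detected
with no false positives. The same run is available from the shell:

```sh
edemastir run --out scratch/demo --seed 42
edemastir plot-signal --heart-rate 60 --out scratch/panel.png
```

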