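# Methods

## Signal model

All three sequences are modelled with the single-compartment longitudinal
Bloch equation in steady state, magnitude display, and normalized
equilibrium magnetization (M0 ≡ relative proton density `pd`).

For the inversion-prepared kinds (STIR and IR-GRE/LGE) the longitudinal
magnetization at the excitation pulse is

    Mz(TI) = 1 − 2·exp(−TI/T1) + exp(−TR/T1)

which is the steady state of the cycle *invert → recover TI → saturating
readout → recover TR − TI*; the third term vanishes as TR → ∞. The
displayed pixel value is `pd·|Mz(TI)|·exp(−TE/T2)` — the sign of Mz is
discarded, as on a magnitude/modulus display. Plain TSE uses the
saturation-recovery term `1 − exp(−TR/T1)` instead. The closed forms are
cross-checked against direct piecewise numerical integration
(`edemastir.bloch`, an independent DOP853 integration of
dMz/dt = (M0 − Mz)/T1 with instantaneous pulse events) to ≤ 1e−9 over a
clinical (T1, TI, TR) grid.

Assumptions and simplifications:

* The double-inversion black-blood preparation is a net identity for
  in-slice stationary tissue and is not modelled; blood suppression is
  idealized (cavity proton density 0). An optional one-pixel slow-flow
  bright rim at the endocardial border can be enabled to emulate the
  classic artifact.
* Echo-train effects, half-scan reconstruction, coil-sensitivity bias and
  flowing-blood physics are out of scope; the phantom is bias-free.
* IR-GRE neglects low-flip-angle saturation and uses T2 in place of T2*;
  at the protocol's TE of 2 ms the transverse factor is ≈ 1 and LGE
  contrast is carried entirely by post-contrast T1 differences.

### Edema weighting

With TI chosen so that myocardial Mz is still negative at the excitation
pulse, `|Mz|` *grows* with T1, so the T1 and T2 elevations of edema both
raise the STIR signal, while in plain TSE they oppose. Two care points,
both visible in the closed forms:

* The additive behaviour requires a long TR. At finite TR the term
  `exp(−TR/T1)` introduces a peak T1 (≈ 1050 ms at TR 2000 ms, TI 180 ms)
  beyond which signal declines again — the reason the gating rule demands
  TR ≥ 2 RR intervals (and 4 RR at fast heart rates). The monotonicity
  property is therefore asserted in the long-TR limit.
* The boost is a statement about *conspicuity against remote myocardium*.
  The package exposes both the signed signal difference (`contrast`) and
  the remote-referenced Weber contrast (`relative_contrast`,
  (S_edema − S_remote)/S_remote). The inversion lowers the overall signal
  level, so the raw difference can be smaller under STIR than under TSE
  even though the image contrast a reader perceives — and the relative
  measure captures — is reliably larger. The edema-weighting assertions
  use the relative measure.

Bundled reference tissues (1.5 T): A 100/20, B 150/30, fat 250/80,
remote myocardium 1000/50, edematous myocardium 1300/80 ms. The protocol
timing is TI 180 ms (fat nulls at 250·ln 2 ≈ 173 ms), TE 100 ms, TR from
the gating rule.

## Phantom

Three short-axis slices (basal/mid/apical; endo/epi radii 24/33, 21/30,
15/24 mm) of annular myocardium on a 128×128 grid at 1.5×1.5 mm pixels and
8 mm slice thickness, covering the 16 short-axis segments of the AHA
17-segment model (the apical cap has no short-axis representation). The
area at risk is a wedge growing from the endocardium to a configurable
fraction of the wall; the infarct is a nested wedge; the optional
hypointense core is confined to a one-pixel erosion of the infarct so it
always keeps an enclosing enhancing rim at this resolution. Default
geometry (120° AAR at 0.85 depth, 90° infarct at 0.55 depth) gives ≈ 28
%LV edema and ≈ 12 %LV infarct — a salvage index near 0.55, matching a
typical partly reperfused first-week cohort.

Tissue assignments: remote 1000/50 ms, edema 1300/80 ms; the hemorrhagic
core keeps the edema T1 but a shortened T2 (30 ms), making it hypointense
on STIR. Post-contrast T1 defaults: remote 600 ms (nulled by the LGE TI),
infarct 400 ms (bright), core 700 ms — chosen near the magnitude-display
zero crossing so the obstructed core reads hypoenhanced, consistent with
delayed gadolinium arrival. These are phantom inputs, not modelled
pharmacokinetics, and are user-overridable in the spec.

In the chronic stage edema has resolved: the STIR ground-truth lesion is
empty, cores are absent, and the area at risk collapses onto the scar.

Noise is Rician, `sqrt((x+n1)² + n2²)` with i.i.d. Gaussian components,
seeded. The default sigma (0.0036) gives SNR ≈ 20 in remote myocardium on
STIR at TR 2000 ms, a representative clinical value; evaluation cohorts
use exactly 0 or the sigma matching SNR 20.

What the phantom does **not** emulate: papillary muscles and
trabeculation, motion/breathing, through-plane partial volume, coil
shading, realistic blood-pool signal. Passing tests therefore demonstrate
correctness of the analysis chain under the stated geometry and noise
model, not clinical performance on patient images.

## Segmentation

* STIR threshold: remote mean + 2·SD (sample SD, n−1). The "2 SD"
  convention is interpreted as mean-plus-two-SD of the remote segment;
  the multiplier is configurable. Statistics are per slice by default;
  a pooled-across-slices option exists because the original convention
  leaves this open.
* LGE threshold: half the robust maximum (99th percentile) of myocardial
  intensity, computed over the pooled myocardium of all slices — a single
  maximum per study prevents scar-free slices from degenerating to a
  noise-level threshold. The percentile replaces the single brightest
  pixel, which is noise-dominated at clinical SNR.
* Delineation takes pixels strictly above the threshold (so a flat STIR
  image yields an empty mask) and removes connected components smaller
  than 5 pixels (speckle suppression that still preserves subendocardial
  lesions at 1.5 mm spacing).
* Remote selection: first pass takes the lowest-mean segment; thereafter,
  among segments free of suprathreshold pixels, the one at maximal
  angular distance from the lesion's circular-mean angle, ties to the
  lowest id. Threshold and remote choice are iterated to a fixed point
  (≤ 10 rounds; non-convergence keeps the last result and flags a
  warning). The iteration is this package's resolution of the
  remote/threshold circularity; a one-shot software selection would be
  equally compatible with the convention.
* Dark-core inclusion: a subthreshold connected component is added when,
  in the annulus frame about the LV center, it touches the hyperintense
  mask, every pixel of it has hyperintense pixels within 4° of arc
  (≈ one pixel at the annulus radius), and no background neighbour lies
  radially beyond its outermost pixel. This fills hypoenhanced cores —
  including ones reaching the endocardial edge — while excluding remote
  myocardium and the non-enhancing epicardial rim over partial-thickness
  lesions. The angular tolerance absorbs the discreteness of pixel
  angles; 1° bins misclassify at this resolution.

## Grading and metrics

Transmural extent is the maximum over 1°-spaced rays of (lesion samples)/
(wall samples) along the ray, with rays attributed to a segment only when
the majority of their wall lies in it (guards against one-pixel walls at
sector corners). A segment is positive at ≥ 5% suprathreshold area,
transmural at extent ≥ 0.75, and upgrades to "transmural with dark core"
when a detected core pixel lies in it. Both cutoffs are modelling choices
standing in for visual calls, are configuration, and are echoed into every
report. On a six-pixel wall the extent is quantized in steps of ≈ 1/6, so
wedge depths within one step of the cutoff can grade either way; the
evaluation cohorts avoid that band.

%LV, MSI, confusion counts, acuity classification (LGE+/STIR+ acute,
LGE+/STIR− chronic, LGE−/STIR− normal, LGE−/STIR+ reported as its own
edema-without-infarct category), grade tabulation and the pooled-variance
Student t test are direct implementations; numeric functions return
unrounded values and only the reporting layer rounds to table precision.

## Evaluation cohorts and problem sizes

Randomized cohorts draw AAR wedges of 90–150° width and 0.6–1.0 depth,
infarcts at 60–100% of the AAR width and 40–100% of its depth (keeping
scar above ~3% of the myocardium so the robust maximum lands inside it),
random centers, and cores in half the phantoms. The standard evaluation
uses 20 phantoms per condition (noise-free and SNR 20) plus 10 chronic
phantoms; at these sizes the full evaluation completes in well under a
minute on one CPU while exercising every segment configuration. Determinism
is verified by byte-comparing two pipeline reports produced from the same
seed.

## Known limitations

* Accuracy claims transfer only as far as the phantom's realism; surface
  coil bias and motion, the dominant practical failure modes of STIR, are
  deliberately absent.
* The transmural-extent measurement assumes a roughly convex annulus and
  a center inside the cavity.
* The LGE model has no gadolinium kinetics: post-contrast T1 values are
  inputs.
* Magnitude display makes very long-T1 structures bright again at the
  chosen TI; the core's post-contrast T1 default was picked inside the
  hypointense window, and other values can leave that window.
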