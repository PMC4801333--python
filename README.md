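# canaloflow

Regionally discrete quantification of aqueous-humor outflow from
fluorescein canalograms — time-lapse images of dye filling the
conventional outflow pathway (trabecular meshwork → Schlemm's canal /
angular aqueous plexus → collector channels → episcleral veins) around
the corneal limbus of perfused eyes.

Bulk outflow can be measured by tonography or fluorophotometry, but
those methods are blind to *where* the fluid leaves the eye. This
package is for researchers running ex vivo perfusion experiments
(whole-globe or anterior-segment cultures) who image fluorescein filling
with a fluorescence stereo microscope and want segmental outflow maps
instead of a single bulk number.

## Method

Given a stack of frames `I(x, y, t)` (one frame per 30 s over 20 min in
the reference protocol):

1. **Macropixels.** The image is reduced to a 32 × 32 grid (1024
   macropixels); each macropixel is the mean intensity of its pixel
   block, normalized so the brightest observation in the stack is 100 %.
2. **Individual fits.** Each macropixel's time course is fit with a
   penalized cubic regression spline (a GAM smooth: `k = min(10, n−1)`
   basis functions, roughness penalty weighted by λ chosen through
   generalized cross-validation). From the fitted curve `f̂(t)`:
   `I_max = max f̂`, `I_half = I_max / 2`, `t_half` = earliest time with
   `f̂(t) ≥ I_half`, and the filling rate `r = I_half / t_half`.
3. **36-region model.** Macropixels outside the corneal disk that form a
   complete ring are grouped by clock hour (12 sectors of 30°, hour 12
   superior) and into 3 equal-width perilimbal rings. A single global
   model — a cyclic-in-hour × time tensor-product smooth per ring — is
   fit to all 36 region means, and per-region `t_half` and rate are read
   off the fitted surface.
4. **Quadrant flows.** Each filling macropixel contributes an increment
   `[f̂(t_half) − f̂(t_first)] / n_frame_intervals` in percent
   fluorescence per frame. The share of the summed increments falling in
   each anatomical quadrant (IN, SN, ST, IT; nasal mirrored by
   laterality) is converted to µl/min against a reference total of
   3 µl/min, so quadrant flows always sum to that total: the method
   measures the distribution of outflow, not its absolute magnitude.
   Quadrant first-appearance filling times and paired t-tests between
   matched groups complete the report.

A seed-deterministic synthetic-canalogram generator (logistic filling of
a perilimbal annulus around a dark cornea, with closed-form half-max
crossings) provides exact ground truth for every stage.

## Worked example

```python
from canaloflow import preset, generate, analyze_stack

spec = preset("whole_eye", seed=1)        # 580x610 px, 41 frames @ 30 s
stack, truth = generate(spec)
result = analyze_stack(stack, spec.geometry())
print(result.report.per_quadrant[["quadrant", "flow_fraction",
                                  "flow_ul_min", "filling_time_min"]])
```

prints

```
  quadrant  flow_fraction  flow_ul_min  filling_time_min
0       IN       0.334816     1.004447               2.0
1       SN       0.308455     0.925366               3.0
2       ST       0.184248     0.552745               6.5
3       IT       0.172481     0.517442               7.5
```

The preset programs nasal quadrants (IN, SN) to fill roughly twice as
fast as temporal ones (ST, IT); the report recovers that contrast: the
nasal quadrants carry about 64 % of the imputed flow
(1.00 + 0.93 µl/min of the 3 µl/min total) and light up 3.5–5.5 minutes
earlier. The four flows sum to the 3 µl/min reference by construction.
The same pipeline is available from the shell:

```
canaloflow simulate --preset whole_eye --seed 1 --out eye.tif --config geom.yaml
canaloflow analyze eye.tif --config geom.yaml --out results/
canaloflow plot rings eye.tif --config geom.yaml --out rings.png
```

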