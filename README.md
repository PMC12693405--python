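# podosem

Quantitative podocyte morphometry from scanning electron micrographs.

Podocytes wrap glomerular capillaries with interdigitated foot processes
(FPs); the slit diaphragm (SD) spanning the groove between adjacent FPs is
the final filtration barrier of the kidney. Early diabetic injury flattens
FPs and narrows slits before albuminuria appears, and surface SEM resolves
this topography directly — but without standardized metrics. `podosem`
implements three complementary SEM measurements and the statistics needed
to evaluate them as diagnostic markers:

1. **Threshold SD fraction** — Gaussian blur (σ = 2 px), Yen's
   maximum-correlation automatic threshold of the ROI histogram, SD% =
   100·|dark pixels ∩ ROI| / |ROI|.
2. **Ridge-detection SD fraction** — Steger-style curvilinear detection of
   the dark slit grooves: Gaussian derivatives at scale σ, Hessian
   eigen-analysis with subpixel line-point localization (|t| ≤ 0.5 along
   the principal eigenvector), hysteresis linking, per-point line widths
   from gradient-magnitude extrema along the normal, and SD% from the
   rasterized width envelope.
3. **Foot-process width (FPW)** — bilinear intensity profiles along
   annotated polylines perpendicular to the FPs; FPW = mean spacing (µm)
   of adjacent profile peaks.

A diagnostics layer supplies per-mouse aggregation, pooled-variance
t-tests, Hedges' g (J = 1 − 3/(4N − 9)) with CI, t-based group CIs,
empirical ROC/AUC with the Youden-optimal cutoff (J = max(TPR − FPR)),
Wilson score intervals for sensitivity/specificity, Pearson correlation,
OLS fits, and Bland–Altman agreement (bias ± 1.96·SD of differences).

Because the original micrographs are not distributable, `podosem.simulate`
renders SEM-like interdigitated FP/slit patterns with pixel-exact ground
truth (groove mask, true SD%, true FPW) and whole two-group cohorts with
hierarchical mouse/image variation, so the entire pipeline is testable end
to end.

## Worked example

```python
import podosem as ps
from podosem.simulate import PatternSpec, make_pattern
from podosem.io import PolygonRoi
from podosem.preprocess import BlurParams
from podosem.ridge import matched_ridge_params

spec = PatternSpec(slit_width=0.165, fp_period=0.55, scale=0.01,
                   curvature=0.1, orientation=20.0, noise_sd=0.05, seed=42)
image, truth = make_pattern(spec)
roi = PolygonRoi([(8, 8), (247, 8), (247, 247), (8, 247)], label="glom")

params = matched_ridge_params(slit_width_px=0.165 / 0.01)
m = ps.sd_fraction_by_ridge(image, roi, blur=BlurParams(radius=2.0),
                            params=params)
```

prints, together with the other two methods and a group effect size:

```
true SD fraction : 29.73%
ridge SD fraction: 32.56%  (18600 of 57121 px)
Yen SD fraction  : 43.54%  (threshold 209.5)
FPW              : 0.587 um (true 0.55 um)
Hedges g         : 1.04  (95% CI 0.32-1.77)
```

The ridge method lands within ~3 pp of the rendered truth; the Yen
threshold overshoots because its cut hugs the bright foot-process mode and
sweeps in the groove shoulders (the same behavior that makes it a weak
diagnostic), and the profile FPW is inflated by the pattern's warp — see
`docs/methods.md` for the quantitative error model of all three methods.

A CLI mirrors the library: `podosem simulate|measure|stats|compare|sweep`
(see `podosem --help`); measurement defaults are the published ImageJ
parameter profile (blur radii 2.00/4.00; ridge σ 5.70, line width 15,
hysteresis 0.00/0.17, minimum length 5.00, maximum length 0 = unbounded).

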