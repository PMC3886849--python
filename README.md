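# gliaquant

Unbiased quantification of perinatal white-matter injury (WMI) from
GFAP/Iba1 immunofluorescence, with a calibrated synthetic fetal-sheep
hypoxia-ischemia (H-I) cohort for end-to-end validation.

## The problem

Most perinatal WMI today is diffuse, non-necrotic gliosis. The traditional
readout — an ordinal 0–4 pathologist score of the percent of white matter
showing necrosis on H&E — assigns 0 to the majority of injured animals and
cannot rank them. A continuous alternative is the **stained area
fraction**: the fraction of white-matter ROI pixels labeled by GFAP
(astrogliosis) or Iba1 (microgliosis), estimated from the pixel-intensity
histogram with no operator threshold:

1. build a histogram with one bin per intensity level over the ROI;
2. find the background peak from the three highest-frequency (adjacent)
   bins — count-weighted centroid, ties toward lower intensity;
3. integrate the histogram on the background (dark) side of the peak and
   **double** it, exploiting the symmetry of the background mode; add the
   peak bin once;
4. the labeled area is the ROI total minus this background estimate;
   fraction = labeled / total, clamped to [0, 1].

Because no real images or animal-level data are deposited for this study,
`gliaquant` ships seeded simulators for every input — section images with
exact ground-truth masks, and a 17-animal H-I cohort (plus twin controls)
whose epoch physiology (BP, heart rate, blood gases, glucose, lactate)
matches the published means/SDs and whose latent injury severity reproduces
the published week-adjusted r² structure between physiology and marker
fractions, and the zero-inflated ordinal pathology pattern (12 of 17
animals scoring 0 while spanning most of the GFAP range). See
`docs/methods.md` for the model and calibration details.

## Worked example

```python
from gliaquant import ImageSpec, generate_section_image
from gliaquant.areafrac import (compute_histogram, locate_background_peak,
                                labeled_area_fraction_detailed)

spec = ImageSpec(width=256, height=256, true_fraction=0.40, seed=7)
img = generate_section_image(spec)          # synthetic GFAP section
hist = compute_histogram(img)
peak, _ = locate_background_peak(hist)
frac, bg = labeled_area_fraction_detailed(img)
print(f"true fraction      : {img.truth_fraction:.4f}")
print(f"background peak    : {peak:.2f}")
print(f"background pixels  : {bg.background_count} of {hist.total}")
print(f"estimated fraction : {frac:.4f}")
```

prints

```
true fraction      : 0.4000
background peak    : 30.00
background pixels  : 39122 of 65536
estimated fraction : 0.4030
```

The peak sits at the background mode (intensity 30); doubling the dark
side of the histogram attributes 39,122 of 65,536 pixels to background,
and the remaining pixels give a stained fraction of 0.403 against a ground
truth of 0.400.

The full study runs from the command line:

```bash
gliaquant all --config examples/run.yaml --out runs/demo --seed 1
```

which simulates a cohort, renders and quantifies 204 section images,
scores pathology, runs the week-adjusted association analyses, and writes
CSV/JSON outputs plus a recovered-vs-target report. `gliaquant simulate`,
`quantify` and `analyze` expose the individual stages; `--skip-images`
bypasses the imaging stage to use generator fractions directly.

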