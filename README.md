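# ctiq

Task-based CT image-quality analysis for QA phantom scans, paired with a
synthetic Catphan-style phantom simulator so that every metric can be
validated by parameter recovery and analytic oracles — no scanner data
required.

## Metrics

| Stage | Module | Outputs |
|---|---|---|
| Uniformity & contrast | `ctiq.uniformity` | uniformity index (UI), integral non-uniformity (IN), cupping/capping classification, histogram median/IQR/skewness/excess kurtosis, insert CT numbers, Michelson contrast, CNR, SNR |
| Noise power spectrum | `ctiq.nps` | detrended 2D NPS (HU² mm²), radial NPS, `f_peak`, `f_average`, noise magnitude |
| Spatial resolution | `ctiq.resolution` | slice thickness from 23°-tilted wire ramps, ESF/LSF/TTF of circular inserts, `f50`, `f10` |
| Detectability & linearity | `ctiq.detectability` | NPW detectability index `d'` for a circular task, labelled `d'` comparisons, HU-vs-μ linear regression with R² |
| Simulator | `ctiq.phantom` | sensitometry / uniformity / low-contrast modules and tilted-ramp stacks with Gaussian blur, correlated noise of known spectrum, radial cupping/capping fields, and a full ground-truth sidecar |

Conventions (documented in the API docstrings): population standard
deviations throughout; NPS normalised as `dx·dy/(Nx·Ny)·⟨|FFT2(residual)|²⟩`
so Parseval holds exactly; TTF(0) = 1 by construction; `d'² =
(∬W²T²)² / ∬W²T²·NPS` on the common frequency grid.

## CLI

```sh
# render a synthetic uniformity module (13 slices, white noise σ=10 HU)
ctiq simulate --module uniformity --out scans/unif --noise-sigma 10 --seed 1

# analyse it
ctiq uniformity --series scans/unif
ctiq nps --series scans/unif --curve-out nps1d.csv

# slice thickness from tilted ramps
ctiq simulate --module ramps --out scans/ramps --n-pixels 640 --pixel-spacing 0.25
ctiq thickness --series scans/ramps --nominal 0.8

# TTF of an insert, then detectability for a 5 mm circular task
ctiq simulate --module sensitometry --out scans/sens --blur-sigma 0.4 --noise-sigma 0
ctiq ttf --series scans/sens --material teflon
ctiq dprime --nps-series scans/unif --ttf-series scans/sens --material teflon

# HU linearity from a CSV of hu,mu pairs
ctiq linearity --pairs pairs.csv
```

Geometry defaults to a built-in Catphan-style layout (inserts on a 58.4 mm
ring, four 23° ramps, centre + four 55 mm periphery uniformity ROIs) and can
be overridden with `--geometry config.yaml` (see
`ctiq.geometry.load_geometry` for the schema). All commands exit nonzero on
precondition failures.

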