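# nsdremote

Evaluation harness for the **"n-SD from remote"** infarct-quantification
method used with late gadolinium enhancement (LGE) cardiac MR. The method
labels as infarct every myocardial pixel brighter than
`threshold = mu + n * sigma`, where `mu` and `sigma` are the mean and SD of
intensity inside a manually placed remote-myocardium region of interest
(ROI). Its accuracy and precision depend on where the ROI is placed, how
big it is, which `n` is chosen, and the underlying image signal
variability.

This package quantifies those error sources on **synthetic short-axis
phantoms with exact ground truth**: an annular myocardium with a nulled
remote region, a hyper-enhanced infarct sector of configurable extent and
transmurality, an optional dark microvascular-obstruction (MVO) core, a
smooth coil-sensitivity bias field, and magnitude-image noise (Gaussian,
Rician, or non-central chi).

## Modules

| module | what it does |
|---|---|
| `nsdremote.phantom` | phantom spec/validation, noise samplers, slice and multi-site cohort generation (fully seeded) |
| `nsdremote.myogeometry` | myocardium rasterization from contours, circumferential-angle / transmural-depth coordinates, rim-excluded sector ROIs, remote-arc enumeration, slice inclusion filter, candidate ROI positions/sizes |
| `nsdremote.nsd_core` | remote-ROI statistics, the `mu + n*sigma` threshold, strict-`>` classification, small-island (spurious pixel) removal, infarct size as % of myocardial area |
| `nsdremote.variability_study` | ROI-position / ROI-size / n-sweep studies, paired naive-vs-no-spurious comparison, per-slice optimal-n search, signal-variability report, accuracy (mean error) and precision (per-slice coefficient of variation) aggregation |
| `nsdremote.interface` | JSON/YAML cohort configs (pydantic-validated), NIfTI + JSON slice bundles, run manifests, CLI |

## CLI

```sh
# generate a cohort of phantom slices from a config file
nsdremote phantom generate --config cohort.json --out cohort_dir

# run one or all studies on it
nsdremote study run --cohort cohort_dir --study all --out results_dir

# print the summary and optionally plot measured vs reference size
nsdremote study report --results results_dir --plot fig.png
```

A minimal cohort config:

```json
{
  "master_seed": 7,
  "sites": [
    {"label": "siteA", "count": 10,
     "template": {"remote_sd": 0.013,
                  "infarct_extent_range": [60, 150],
                  "infarct_center_angle_range": [0, 360]}},
    {"label": "siteB", "count": 10, "template": {"remote_sd": 0.026}}
  ]
}
```

Angles are degrees, lengths millimetres, intensities normalized to [0, 1].
Each slice is written as an uncompressed NIfTI image, a labeled NIfTI mask
(0 background, 1 myocardium, 2 infarct, 3 MVO) and a JSON sidecar with the
contours and the generating spec; `manifest.json` records the config hash,
master seed and file list.

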