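# bonemap

Cortical bone mapping from quantitative CT (QCT), built for longitudinal
treatment studies of the vertebral cortex.  The cortex of an osteoporotic
vertebra is often thinner than the scanner's point-spread function, so
threshold- or FWHM-based measurements fail exactly where fractures start.
`bonemap` instead fits a blurred model of the cortex to the CT values sampled
along the surface normal at every vertex of a periosteal mesh, recovering
sub-voxel structure, and then carries per-vertex maps through canonical-shape
registration into group statistical parametric mapping (SPM).

## The model

Along each inward surface normal the density is piecewise,

```
rho(x) = y_bg                   x < x0         soft tissue
         y_c                    x0 <= x < x1   cortical plateau
         y_c -> y_t linearly    x1 <= x < x2   endocortical transition
         y_t                    x >= x2        cancellous interior
```

and the scan shows `rho * G_sigma` (Gaussian PSF).  Fitting the blurred
model (closed form, analytic Jacobians) per vertex yields

* **Ct.Th** = (x1+x2)/2 − x0 — cortical thickness, periosteal edge to the
  midpoint of the endocortical transition (mm),
* **Ec.Th** = x2 − x1 — endocortical thickness (mm),
* **Ct.BMD** = y_c and **Cn.BMD** = y_t (mg/cm³),
* **CMSD** = 0.1 · Ct.Th · Ct.BMD — cortical mass surface density (mg/cm²).

Because thickness and density trade off below the PSF width, the cortical
density is constrained per scan from the thickest "anchor" vertices, with
baseline and follow-up scans of one subject coupled longitudinally; see
`docs/methods.md` for the identifiability analysis behind this design.

The package includes a full synthetic-study generator (blurred shell
phantoms, two-time-point cohorts with treatment-effect distributions taken
from the published trial tables), surface smoothing with geodesic Gaussian
kernels, ICP + thin-plate-spline mesh registration, and permutation
max-statistic SPM with family-wise error control.

## Worked example

Simulate a three-arm cohort at profile level (56 subjects, two time points,
120 vertices each) and recover the group-mean percentage changes:

```python
import numpy as np
from bonemap import CohortSpec, FitConfig, gen_cohort
from bonemap.pipeline import analyze_profile_cohort

cohort = gen_cohort(CohortSpec(n_vertices=120, seed=1000))
result = analyze_profile_cohort(cohort, FitConfig(sigma=1.0, noise_sd=25.0))
for metric in ("ct_th", "cn_bmd", "cmsd"):
    print(metric, {g: round(v, 1) for g, v in result.group_means[metric].items()})
```

prints

```
ct_th {'placebo': 2.2, 'teriparatide': 4.1, 'romosozumab': 14.3}
cn_bmd {'placebo': -5.6, 'teriparatide': 18.8, 'romosozumab': 21.9}
cmsd {'placebo': 1.2, 'teriparatide': 4.7, 'romosozumab': 15.4}
```

The group-mean effects this particular cohort actually received (recorded by
the generator) were Ct.Th +0.7 / +4.5 / +12.0, Cn.BMD −5.6 / +18.7 / +21.8
and CMSD +0.6 / +5.0 / +15.4 — the pipeline reads the injected treatment
effects back out of the blurred, noisy profiles to within a couple of
percentage points per arm.  `result.summaries[...]` carries the group
SDs and the vs-baseline / between-group t-tests, and
`bonemap.stats.vertexwise_spm` turns per-vertex change maps into
significance-masked surface maps.

There is also a CLI covering the volume/mesh pipeline end to end:

```
bonemap run-all --out demo --seed 1 --subjects-per-group 3
bonemap simulate-cohort / fit / register / stats / render ...
```

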