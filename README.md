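# aortaflow

Quantitative hemodynamics for aortic 4D flow velocity fields and Doppler
traces: voxelwise viscous energy loss rate (VELR) and vorticity maps with
ascending-aorta ROI summaries, particle pathline tracing, continuity-equation
valve metrics, and a normality-gated three-group statistical comparison.
Everything is verifiable against analytic flow phantoms with closed-form
dissipation and vorticity, so no patient data are required.

## Modules

| Module | Contents |
| --- | --- |
| `aortaflow.flow_field_io` | NIfTI + JSON-sidecar I/O for velocity fields, masks, and derived maps; venc-based velocity anti-aliasing |
| `aortaflow.hemodynamics` | peak-systole detection, mask-aware velocity-gradient tensor, VELR (2μ S:S) and vorticity (curl) maps, ROI summaries, RK4 pathlines |
| `aortaflow.echo_metrics` | ejection-window detection, VTI, simplified-Bernoulli TPV/TPG, continuity-equation EOA, EOA index, discharge coefficient |
| `aortaflow.synthetic_data` | analytic phantoms (uniform, shear, solid rotation, Poiseuille, Lamb–Oseen), half-sine Doppler traces, cohort simulator |
| `aortaflow.cohort_stats` | Monte-Carlo Lilliefors normality test, ANOVA/Kruskal–Wallis omnibus, Bonferroni-adjusted pairwise t / rank-sum tests, summary tables |

## CLI

```bash
# generate a Poiseuille phantom dataset (NIfTI components + JSON sidecar)
aortaflow synth phantom --out data/ --seed 1

# validate and summarise a dataset
aortaflow load-check data/poiseuille

# peak-systolic VELR / vorticity summary over an ROI
aortaflow quantify --field data/poiseuille --aorta data/poiseuille_mask.nii \
    --roi data/poiseuille_mask.nii --maps-out data/maps

# particle pathlines as CSV
aortaflow pathlines --field data/poiseuille --aorta data/poiseuille_mask.nii \
    --out pathlines.csv

# Doppler-based valve metrics
aortaflow synth doppler --out av.csv --tpv 1.9
aortaflow synth doppler --out lvot.csv --tpv 1.0
aortaflow echo --av av.csv --lvot lvot.csv --lvot-diameter 2.2 --bsa 2.1 --goa 3.73

# cohort simulation and group comparison
aortaflow synth cohort --out cohort.csv --seed 1
aortaflow stats --cohort cohort.csv --out summary.md
```

## Units

Velocities m/s, spacings mm, frame intervals ms, venc cm/s; VELR density
W/m³, ROI total VELR mW, vorticity s⁻¹, VTI cm, pressure gradients mmHg,
areas cm². Voxel centres sit at `origin + (index + 0.5) * spacing`.
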