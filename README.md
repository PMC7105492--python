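# gliaquant

Quantitative analysis pipelines for studies of astrocyte remodeling in brain
slices, with synthetic ground-truth generators for every input.  Built for
experiments of the kind that compare hippocampal astrocytes between dietary
or treatment groups: patch-clamp dye fills, two-photon morphometry,
immunofluorescent connexin staining, astrocytic current recordings, and
field-potential plasticity measurements.

Astrocytes enwrap synapses with perisynaptic leaflets that are thinner than
the diffraction limit, so their presence is measured indirectly: along
radial fluorescence profiles of a dye-filled cell, the **volume fraction**
of unresolved processes at point *i* is

    VF(i) = (F(i) − F₀) / (F_max − F₀)

where F_max is the peak soma fluorescence (100% occupancy) and F₀ the
background in a dye-free circle; VF is averaged over the 8–30 µm segment
after excising branch crossings.  Gap-junction coupling is quantified by the
**coupling length constant** C_λ of the dye spread, F(d) = exp(−d/C_λ),
fitted on a semilog scale against 3-D distance.  Connexin puncta are
segmented by a high-pass percentile rule and summarized by diameter
(max pairwise distance), Delaunay edge lengths, and ring-density profiles
around the soma.  Synaptically evoked astrocyte currents are decomposed into
the fast transporter current I_GluT and the slow potassium current I_K
(5-minus-4 train subtraction, 200-ms measurement window, mono-exponential
decay fits), and field recordings yield input–output curves and LTP
magnitude (% of the pre-induction baseline).  A statistics layer reproduces
the group-comparison framework (two-sample t, repeated-measures two-way
ANOVA with partial η², Western-blot normalization) and an experiment driver
runs the whole chain on synthetic control-vs-CR cohorts.

## Worked example

```python
import gliaquant as gq

# a dye-filled astrocyte with 3.2% leaflet occupancy and realistic noise
img = gq.gen_astrocyte_image(gq.ImagingParams(leaflet_vf=0.032,
                                              noise_sd=10.0, seed=1))
vf = gq.leaflet_vf(img)
print(f"leaflet VF: {100 * vf.mean_vf:.2f}% (truth 3.20%)")

# a dye-coupled network with a 19.9 µm length constant, 5% noise
net = gq.gen_coupled_network(gq.CouplingParams(n_cells=13,
                                               length_constant_um=19.9,
                                               noise_sd=0.05, seed=1))
fit = gq.fit_length_constant(net)
print(f"coupling length constant: {fit.length_constant_um:.1f} um "
      f"(truth 19.9, R^2 = {fit.r_squared:.3f})")

# a small end-to-end control-vs-CR experiment
from gliaquant.stats_report import ExperimentConfig, run_experiment
report = run_experiment(ExperimentConfig(
    n_per_group=5, metrics=("vf", "coupling_lambda", "ltp"), seed=1))
print(report)
```

prints

```
leaflet VF: 3.53% (truth 3.20%)
coupling length constant: 19.9 um (truth 19.9, R^2 = 0.999)
Synthetic experiment report (seed=1, config=431697ea6858)
                vf: control 3.3 ± 0.074 (n=5) | CR 4.34 ± 0.084 (n=5) | t=-9.26, p=1.5e-05 (two-sided)
   coupling_lambda: control 19.9 ± 0.046 (n=5) | CR 26.2 ± 0.13 (n=5) | t=-46.27, p=5.26e-11 (two-sided)
               ltp: control 147 ± 0.96 (n=5) | CR 168 ± 0.7 (n=5) | t=-17.68, p=1.07e-07 (two-sided)
```

The single-image VF estimate (3.53%) scatters around the truth with the
imaging noise; group means over seven cells recover it to well within one
SEM.  The experiment report shows both group means at their preset ground
truths with the declared test per metric.

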