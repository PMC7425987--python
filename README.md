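# clonalrhythm

Analysis toolkit for **clonal heterogeneity of circadian period** in cultured
reporter-cell lines. Single-cell cloning of an oscillating cell culture
yields clonal lines whose free-running periods spread over several hours;
repeated rounds of cloning and selection of short- and long-period clones
("assay generations") split that spread into a heritable and a stochastic
component. `clonalrhythm` provides the full analysis chain for such an
experiment, together with a synthetic-data generator so that every stage is
testable without instrument data:

- **simulate** — clonal pedigrees with truncated-Gaussian heritable-period
  transmission, damped-cosine bioluminescence plate recordings with
  photon-count noise, and probe-count (nCounter-style) expression panels
  whose gene means depend on clone period linearly or as an inverted U.
- **rhythm** — sliding-window ratio detrending and multi-start nonlinear
  least-squares fitting of the damped oscillator
  `y(t) = A·exp(−γt)·cos(2πft + φ)`, reporting period τ = 1/f, relative
  amplitude A, damping γ, phase φ, and MESOR.
- **stability** — peak-to-peak intercycle period SD (3–4 cycles) and phase
  of entrainment under temperature T-cycles.
- **heritability** — one-way variance partitioning
  (`MS_b = V_NH + n·V_H`, `MS_w = V_NH`, `H² = V_H/(V_H+V_NH)`), with the
  Sokal–Rohlf `n₀` correction for unbalanced designs, parent–progeny
  regression, and Spearman trait correlations.
- **selection** — the multi-generation truncation-selection protocol, with
  selection differential S, response R, and a breeder's-equation check
  R ≈ H²·S.
- **expression** — three-step control-probe normalization (positive
  spike-ins, negative-control background with a floor of one count,
  housekeeping geometric mean), Bartlett's sphericity test, correlation PCA
  with cos²/contribution tables, broken-stick PC retention, top-25% gene
  selection, complete-linkage hierarchical clustering, and a five-index
  optimal-k scan (silhouette, WSS elbow, gap statistic, Calinski–Harabasz,
  BIC).

## Worked example

```python
import numpy as np
from clonalrhythm import (SimConfig, generate_pedigree, generate_plate,
                          pedigree_to_frame, summarize_plate,
                          heritability_by_generation)

cfg = SimConfig(seed=7)                      # founding period 24.6 h,
rng = np.random.default_rng(7)               # sigma_H = 0.8, sigma_NH = 0.66
records = generate_pedigree(cfg, n_founders=25, progeny_per_parent=10,
                            n_generations=1, rng=rng)
plate = generate_plate([r for r in records if r.generation == 0], cfg, rng=rng)

params = summarize_plate(plate)              # damped-cosine fit per well
print(params[["well_id", "period_h", "relative_amplitude"]].head(3))

h2 = heritability_by_generation(pedigree_to_frame(records))
print(h2[["generation", "V_H", "V_NH", "H2"]].to_string(index=False))
```

Output:

```
  well_id   period_h  relative_amplitude
0  G0-000  24.282877            0.351305
1  G0-001  24.265737            0.377077
2  G0-002  24.795255            0.391862
```
```
 generation      V_H    V_NH       H2
          1 0.850874 0.42752 0.665581
```

Each well's fitted period tracks its clone's simulated period; the variance
partition of 250 progeny over 25 parents estimates `H² ≈ 0.67` against a
generating value of `0.8²/(0.8²+0.66²) ≈ 0.595` — within the sampling spread
of a 25-parent design (the acceptance script averages 200 such replicates
and lands on 0.58).

The same pipeline is available from the shell:

```sh
clonalrhythm all --seed 7 --outdir out/
```

which writes the pedigree, plate, rhythm-parameter, stability, heritability
and expression tables plus a run summary, all stamped with a config hash and
seed.

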