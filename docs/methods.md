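# Methods

## The trait model

A clone's free-running circadian period is modelled as

    tau = g + e,    e ~ N(0, sigma_NH^2)

where `g` is a heritable value transmitted from parent to progeny and `e` is
the nonheritable (stochastic/environmental) deviation drawn fresh at every
assay. Heritable transmission adds a small truncated-Gaussian drift:

    g_child = TruncNorm(g_parent, sigma_m^2; [tau_lo, tau_hi])

Founders draw `g` from `TruncNorm(mu_0, sigma_H^2; [tau_lo, tau_hi])`.
Defaults: founding mean `mu_0 = 24.6 h`, `sigma_H = 0.8 h`,
`sigma_NH = 0.66 h` (so the generating broad-sense heritability is
`H^2 = sigma_H^2/(sigma_H^2 + sigma_NH^2) ~= 0.595`), bounds
`[22, 28] h` — the span of periods such clone panels exhibit. The drift SD
`sigma_m = 0.2 h` is a free parameter: nothing in the experimental
literature pins the per-subcloning rate of heritable change, and it is
deliberately much smaller than `sigma_NH`. Truncation at the bounds is the
model's whole account of divergence saturation under selection; it encodes
a homeostatic limit on period without claiming a mechanism.

## Bioluminescence traces

A well's recording is

    y(t) = M(tau) * exp(-delta t) * [1 + A0 exp(-gamma t) cos(2 pi t / tau + phi)] * eta(t)

with `M(tau) = mesor0 + slope*(tau - mu_0)` (brighter long-period clones,
slope 120 counts/h on a 1000-count baseline), baseline decay
`delta = 0.005 /h`, oscillation amplitude `A0 = 0.5`, damping
`gamma = 0.025 /h`, and multiplicative lognormal noise `eta` with unit mean
and CV 0.05. Sampling every 0.5 h for 168 h (7 days on a plate
luminometer). `gamma = 0.025 /h` makes the relative amplitude in a day-6
window about 5% of the day-1 window (`exp(-0.025*120) ~= 0.05`), the regime
in which a week-old culture is effectively arrhythmic; `A0 = 0.5` puts the
day-1 window amplitude near 0.37 on the detrended scale.

## Detrending and the damped-cosine fit

Detrending divides by a centred 24-h moving average and subtracts 1
(`raw/trend - 1`), producing a dimensionless trace and discarding 12 h at
each end. Division rather than subtraction keeps the relative amplitude
scale-free.

The detrended trace is fitted by nonlinear least squares to
`A exp(-gamma t) cos(2 pi f t + phi)` with `t` rebased to zero at the
window start (so `A` is the relative amplitude at the start of the usable
record). The RSS surface is multimodal in `f`, so the optimiser is
multi-started from periods {20, 22, 24, 26, 28} h plus the periodogram peak
in the 16–40 h band; the lowest-RMSE converged start wins. Period is
bounded to [16, 40] h; fits within 0.01% of a bound are flagged, not
discarded. `A < 0` is folded into a pi phase shift and `phi` is wrapped to
[-pi, pi). MESOR is the mean of the raw trace over the full recording (the
averaging window is a convention; the full-record mean is the most robust
choice). Windowed amplitudes (e.g. day 1 vs day 6) come from the same fit
restricted to a 24-h window with `gamma` pinned to 0.

**Precision.** With noise CV 0.05 and moderate damping (`gamma = 0.01 /h`)
the median absolute period error over 200 simulated traces is ~0.03 h. The
attainable precision is set by how long the oscillation stays above the
noise floor: at the heavy-damping default (`gamma = 0.025 /h`) the signal
falls below the noise by ~day 4 and the information content of the trace
itself bounds any estimator near 0.1 h. Recovery benchmarks therefore run
at `gamma = 0.01 /h`; the distinction is a property of the data, not of the
fitting code (the noiseless bias of the full detrend-and-fit path is below
0.03 h everywhere in 22–28 h).

## Intercycle stability and entrainment phase

Peaks are local maxima of the detrended trace that strictly dominate a
+/- 8 h neighbourhood (full neighbourhoods only — edge-truncated windows
otherwise promote boundary samples to spurious peaks); surviving peaks
closer than 16 h resolve to the higher one, ties to the earlier. The
intercycle period SD is the sample SD (n-1) of the first min(4, available)
peak-to-peak intervals, requiring at least 3; capping at four cycles keeps
short- and long-period clones comparable. Note that argmax peak-picking
localises a noisy, nearly flat cosine maximum to only ~1–2 h at noise CV
0.03–0.05, so simulated intercycle SDs are dominated by peak-localisation
noise and sit well above the fitted-period precision; the statistic orders
clones by stability rather than measuring period error.

Under a temperature cycle of period T, the phase of entrainment is
(peak time − preceding warm onset) mod T per cycle, discarding the first
cycle as a transient; the report carries the mean and SD over the remaining
cycles.

## Variance partitioning and heritability

For `a` parental clones with `n_i` progeny each, one-way ANOVA gives

    MS_w = V_NH,    MS_b = V_NH + n * V_H
    V_H = (MS_b - MS_w)/n,   H^2 = V_H / (V_H + V_NH)

with `n` replaced by the Sokal–Rohlf effective size
`n0 = (N - sum(n_i^2)/N)/(a-1)` when group sizes differ. A negative
method-of-moments `V_H` is truncated to 0 (keeping `H^2` in [0, 1], at the
cost of a small upward bias near `H^2 = 0`), and `H^2` is defined as 0 when
both components vanish. Across 200 replicate 25-parent x 10-progeny
pedigrees at the default variance components the mean estimate is within
0.05 of the generating 0.595. Parent–progeny association is summarised by
OLS of progeny means on parent values; trait associations by Spearman rank
correlation with average ranks, p-values by the large-sample approximation
and reported descriptively only.

## Selection protocol simulation

Each assay generation measures every clone's period (either directly as
`g + e`, or through the full trace-simulation + fitting path; optionally
averaging k repeat assays), selects the lower/upper `tail_fraction`
(default 0.1) of the distribution as parents of the short/long lineage, and
subclones them round-robin to refill a 96-clone generation. Recorded per
generation: mean and SD, the selection differential
`S = mean(selected) - mean(all)`, and the response
`R = mean(next) - mean(current)`. Away from the period bounds the simulator
reproduces the breeder's equation (`R/(H^2 S) ~= 1.0` averaged over
replicates); lineages pressed against the bounds respond less than
`H^2 S` and their means plateau — the saturation mechanism.

## Expression panel and its analysis

The synthetic panel mimics a digital probe-count assay of 19 clock and
clock-associated genes over a clone panel, plus 6 positive spike-ins, 8
negative controls and 4 housekeeping probes. Endogenous mean log2 counts
follow the gene's archetype: linear in period (`+/- 0.35 log2/h`; e.g.
ARNTL2 and BHLHE40 rising, DBP/NR1D2/PER2 falling), an inverted U peaking
at 25 h (`-0.25 log2/h^2`; NR1D1, CLOCK, CSNK1D, CIPC, NFIL3), or flat.
Per-gene lognormal dispersion is 0.15 log2 units; housekeeping probes use
0.05 (reference genes are chosen for stability, and with equal dispersion
the residual noise of a 4-probe geometric mean would itself become a
spurious shared factor rivalling the biological ones). A per-sample
lognormal technical scale (SD 0.3) multiplies everything except the
negative controls.

Normalization follows the three-step control scheme: (1) scale each sample
by the grand mean of positive-control means over its own positive-control
mean, (2) subtract the sample's mean negative-control count, flooring at
one count so log2 stays defined, (3) scale by the grand geometric mean of
housekeeping geometric means over the sample's own. Grand-mean referencing
makes the procedure idempotent up to count rounding. Probes that failed
upstream QC can be dropped by name with the reason logged.

Bartlett's sphericity (`chi2 = -(n-1-(2p+5)/6) ln det R`,
`df = p(p-1)/2`) checks PCA adequacy; a singular correlation matrix is
flagged rather than fatal. Correlation PCA eigendecomposes the gene-gene
correlation matrix; loadings are variable–PC correlations, `cos^2` their
squares, contributions `100 * v_gk^2` (summing to 100 per PC), and each
eigenvector is oriented so its largest-magnitude element is positive (a
fixed convention, since eigenvector sign is arbitrary). The broken-stick
null `b_k = (1/p) sum_{i=k..p} 1/i` retains the leading run of PCs whose
variance share exceeds it, keeping at least PC1 (with a warning if even PC1
falls below). Top-gene selection ranks by contribution to a chosen PC and
returns the top `ceil(fraction * p)` — 5 of 19 genes at the default 25% —
with ties broken by `cos^2`, then name.

Sample clustering uses Euclidean distance and complete linkage on per-gene
z-scores (standardisation is the default so abundant genes do not dominate;
raw log2 clustering is a flag away), serialisable as a parenthesised
(newick) tree. The optimal-k scan runs seeded multi-restart k-means for
k = 1–10 and scores each k by average silhouette width, WSS (elbow = the k
after which the decrease in WSS drops the most), the gap statistic (B = 50
uniform reference draws over the data bounding box, 1-SE rule),
Calinski–Harabasz, and the BIC of a spherical Gaussian mixture initialised
at the k-means solution; the consensus is the modal per-index optimum with
ties broken by silhouette.

## What the synthetic data does and does not show

The generators reproduce the statistical structure the analysis assumes —
variance components and their pedigree transmission, damped oscillations
with period-dependent baseline, archetype-driven expression with shared
technical scale. They do not emulate transcription–translation-loop
dynamics, cell-division coupling, entrainment dynamics under forcing, or
the cross-correlation that a real interconnected clock network imposes on
*all* genes at once (real panels are more collinear than the synthetic
ones, which is why the synthetic PC1+PC2 share of variance, ~55%, sits
below what heavily intercorrelated real panels show). Passing tests
demonstrate that the estimators recover what the generators put in, at the
stated sizes — not that real recordings meet the generators' assumptions.

## Problem sizes and determinism

Test and acceptance runs use 25 parents x 10 progeny pedigrees (200
replicates for recovery statistics), 200 traces for fit precision, 96
clones x 4 generations for selection (1000 clones for the single-round
breeder's check), and 19-gene x 25-clone panels — sizes at which the
Monte-Carlo error of each summary is comfortably below its acceptance
band. Every stochastic routine takes an explicit seed or Generator;
`scripts/acceptance.py` expands one `--seed` into per-stage child seeds via
`SeedSequence.spawn`, so outputs are bit-reproducible.

## Known limitations

- `sigma_m` is a modelling choice, not an estimate; heritability decay
  across generations therefore tracks the truncation geometry, not a
  measured epigenetic drift rate.
- The method-of-moments `V_H` with truncation is biased upward near zero
  heritability; REML/mixed models are out of scope.
- Peak-based stability is argmax-limited (see above); no smoothing is
  applied before peak-picking.
- The damped cosine assumes a single dominant oscillatory mode; traces
  with strong second harmonics or period drift within the record will fit
  with inflated RMSE rather than being modelled.
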