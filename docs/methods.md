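# Methods

`siapca` determines the nucleobase preference of an RNA-binding protein
domain from ensembles of 2D ¹H{¹⁵N} correlation NMR spectra. For each
position of a short single-stranded RNA, the domain is mixed with four
quasi-degenerate RNA pools that fix A, C, G or U at that position and
randomize the rest (`NNNAN`, `NNNCN`, …). The pool the domain binds most
tightly produces, on average, the largest spectral change relative to the
free protein, so ranking the four complexes by spectral change ranks the
bases. The package implements two readouts of that change — a whole-spectrum
PCA score and the classical per-peak chemical-shift-perturbation (CSP)
score — plus a simulator that generates complete experiments with known
ground truth.

## Binding and spectral model

Each pool is treated as a single effective species with one dissociation
constant Kd (µM): the pool's quasi-degenerate mixture binds with some
distribution of affinities, but the observable — the population-averaged
peak position — is the same as that of a single species with the average
bound fraction. For total protein P and total RNA R, the bound fraction is
the exact root of the 1:1 quadratic

    f = [(P + R + Kd) − sqrt((P + R + Kd)² − 4 P R)] / (2 P).

Binding is assumed to be in fast exchange on the chemical-shift timescale:
each responsive amide peak appears at the population-weighted average of
its free and saturated positions, i.e. displaced by `f · Δδ_max` in both
dimensions. Δδ_max (the saturated-complex shift) is a property of the bound
state and is shared by the four pools of a position; pools therefore differ
only through `f`, which is exactly the premise that lets shift magnitude
report relative affinity. Peaks are rendered as separable 2D Lorentzians
(product of 1D Lorentzians, unit height at the centre, HWHM per dimension).

## PCA of one ensemble

The five spectra of a position — free, A, C, G, U, in that fixed order —
are flattened into a 5 × (n₁·n₂) matrix, one spectrum per row. The
decomposition is sequential NIPALS with one modification: **the first basis
vector is anchored to the free-protein spectrum**. Component 1 is the unit
vector along the reference row; its projections carry the shared overall
intensity, including the dilution of the bound samples. NIPALS then
extracts the remaining components from the residual.

The anchoring is not cosmetic. The per-pool score used for ranking is

    score(base) = |t_free| − |t_bound(base)|

on the second component, where t are the per-spectrum projections (the
quantity practitioners of this assay call the spectra's "loadings").
Without anchoring, PC1 of an uncentered (or mean-/reference-centered)
ensemble absorbs the ensemble mean, and the PC2 coordinates of any
one-parameter family of spectra — which the four complexes approximately
are, parameterized by f — must straddle their own mean (they are
orthogonal to PC1). The |free| − |bound| construction is then non-monotone
in f and the ranking is scrambled; this is a geometric fact, confirmed
numerically for every centering mode. Anchoring the first component to the
free spectrum puts the reference at exactly zero on all later components,
making the PC2 projection of each complex proportional to its shift
pattern amplitude, hence monotone in f. Under the default conditions this
yields the expected variance structure (component 1 ≈ 89%, component 2
≈ 9%, components 3–5 ≈ 1% each, five components from five spectra) and
ranking that recovers the programmed affinity order.

Numerical details:

* The NIPALS inner loop iterates in the row space on the precomputed Gram
  matrix, `t ← G t / sqrt(tᵀ G t)` — algebraically identical to the
  textbook alternation `p ← Xᵀt/tᵀt, p ← p/‖p‖, t ← Xp` but O(rows²) per
  step, so near-degenerate singular pairs can run to convergence
  (default tol 1e-11 on the relative change of t, cap 50 000 iterations;
  hitting the cap records a warning on the result rather than raising).
* Eigen-spectra are re-orthogonalized against earlier components;
  components beyond the matrix rank get zero projections and a
  Gram–Schmidt filler direction so the returned set stays orthonormal.
* Signs are fixed so the reference projection is ≥ 0 (first clearly
  nonzero projection when the reference sits at zero), making runs
  reproducible across platforms.
* Variance fractions are sums of squared projections over the total sum
  of squares of the input matrix, so they read as "% of total variance".
* Mean- and reference-centering (subtracting the free row) remain
  available as options, as does plain unanchored NIPALS; an all-zero
  matrix raises a degenerate-input error.

Rankings sort the four bases by |score| (descending): component signs are
a convention, so the magnitude of separation is the robust ordering. Ties
are broken alphabetically and flagged. The signed scores are reported
alongside.

## Reliability flag

For small domains where few resonances shift on binding, the variance
spreads evenly over the components and component 2 loses its shift-tracking
role. An ensemble is flagged unreliable when `var(PC2) < 3 × var(PC3)`.
The threshold is a heuristic calibrated to the anchored basis: because the
four bound planes share a residual direction (dilution + the reference
plane's own noise), even a signal-free ensemble shows PC2 at roughly twice
PC3, while healthy ensembles sit at 7× and above; 3 separates the two
regimes cleanly in simulation (failure regime ≤ 2.8 across seeds, healthy
≥ 3.0). The threshold is exposed as a parameter. Flagged positions should
be scored manually.

## Manual CSP score

From tracked peak lists (free + four complexes), the weighted shift of
peak i against pool b is

    Δδ(i, b) = sqrt(ΔδH² + (α · ΔδN)²),   α = 0.2,

the community-standard amide combination that rescales the ¹⁵N ppm range
onto ¹H (α is exposed). Per peak, the four Δδ values are normalized by the
peak's maximum; per pool, the normalized values are averaged over the
selected peaks, giving scores in [0, 1] with the tightest pool at 1. Peaks
with zero shift against every pool are excluded from the averages and
reported. Peak selection is an explicit input; a helper picks the n
largest shifters, mirroring manual practice. `subset_sensitivity` reports
the maximum score difference across alternative peak selections: with
exact fast-exchange lists it is identically zero (normalization removes
all per-peak structure), and it becomes the familiar few-×-0.01 selection
bias once realistic read-out error on the measured positions is present.

`compare_methods` cross-validates the two readouts: Kendall τ between the
base rankings per position, and per principal component the Pearson
correlation between each pool's projection distance and its mean weighted
shift, pooled over positions × pools. Under the default conditions the
correlation peaks at component 2, with component 1 high but inferior (it
is intensity-dominated and decorrelated from binding by sample-to-sample
intensity error).

## Simulator defaults and what they emulate

| parameter | default | meaning |
|---|---|---|
| grid | 290 × 256 | frequency-domain points (¹H × ¹⁵N) |
| ¹H axis | 11.0 ppm first point, 5 ppm width, 700.13 MHz | amide region |
| ¹⁵N axis | 135.0 ppm first point, 30 ppm width, 70.95 MHz | amide region |
| n_peaks / responsive | 100 / 30% | amide count of an RRM-sized domain |
| Δδ_max draws | N(0, 0.05) ppm ¹H, N(0, 0.25) ppm ¹⁵N | saturated CSPs |
| linewidths (HWHM) | 0.02 ppm ¹H, 0.15 ppm ¹⁵N | processed lineshape |
| Kd ladder | 2, 10, 50, 250 µM | programmed preference order per position |
| protein / RNA ratio | 25 µM / 1:1 | experimental conditions |
| dilution_factor | 0.9 | volume added with the RNA pool |
| noise_sd | 0.005 of max free intensity | thermal noise |
| scale_jitter_sd | 0.02 | per-sample intensity (pipetting) error |

Per-plane noise is seeded deterministically from
`(seed, position, plane_index)`; identical configs give bit-identical
spectra. The per-sample intensity jitter exists because each complex is an
independently prepared tube: without it, the dilution would be exactly
uniform and the intensity component's projections would become a spuriously
perfect function of the bound fraction, which real intensity channels are
not.

What the simulator deliberately does **not** model: exchange broadening
(slow/intermediate regimes and f-dependent linewidths), peak overlap
rearrangements beyond what Lorentzian tails produce, baseline and water
artefacts, ¹H/¹⁵N cross-correlated effects, titration series (the assay is
single-point). Passing tests therefore demonstrate the analysis recovers
the programmed preferences under idealized fast-exchange, shift-dominated
conditions, not that it is robust to every pathology of real spectra —
the reliability flag exists precisely because real small-domain data can
break the shift/PC2 relationship.

## File formats

The `matrix` dialect is this package's own: a magic line, a one-line JSON
header (shape, per-axis calibration, label), then raw little-endian
float64 intensities row-major — bit-exact round trips by construction.
NMRPipe 2D streams (512-float32 header + float32 data) are read and
written for single real planes, honouring the standard slots for point
counts, spectral widths, observe frequencies and axis origins
(`ppm(i) = (ORIG + SW·(n−1−i)/n)/OBS`); pseudo-3D inputs must be split
upstream, and round trips are exact to float32 rounding. Peak lists are
CSV/TSV with header `id,h_ppm,n_ppm,intensity`. ppm decreases with
increasing index on both axes and all grid indexing is 0-based.

## Problem sizes in the test suite

Unit and property tests run on a scaled-down 64 × 48 grid with ~20 peaks
and two positions, which preserves every qualitative feature (anchored
variance structure, ranking recovery, reliability separation) at a
fraction of the cost. The acceptance-level checks run the full default
conditions: single positions on the 290 × 256 grid, a 50-seed sweep of the
five-position experiment for ranking recovery, and 20 random 5 × 1000
matrices against an SVD oracle.
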