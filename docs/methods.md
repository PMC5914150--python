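# Methods

## Connectivity model

Input is one ROI time-series matrix (T timepoints × d regions) per subject
and condition, assumed already preprocessed (motion/confound regression,
filtering, task-block concatenation are upstream of this package). Pearson
correlation between every pair of regional time courses is Fisher
z-transformed, z = atanh(r), giving a symmetric d×d matrix with a zero
diagonal. Correlations are clamped to ±(1 − 10⁻⁷) before atanh so duplicated
or perfectly correlated regions produce a large finite value rather than an
error.

Graphs are **binary**: an edge joins regions i and j when z_ij > τ, with
τ = 0 by default — only positive connections enter the graph metrics, and
negative connections are dropped, not absolute-valued. We binarize rather
than retain weights because the metric definitions used here are count-based
(degree as the number of links); weighted variants would be a natural
extension but are deliberately out of scope.

## Graph metrics

Per node: degree k_i = Σ_j a_ij; clustering coefficient
c_i = 2t_i / (k_i(k_i − 1)) with t_i the number of triangles at i (defined
as 0 when k_i < 2, keeping feature vectors finite); betweenness centrality
b_i = Σ_{s<t} σ_st(i)/σ_st over unordered pairs, computed with Brandes'
algorithm, unnormalized by default (a flag divides by (d−1)(d−2)/2).
Unreachable pairs contribute zero; endpoints are excluded from their own
paths.

Community structure of the group-averaged positive graph is summarised by
Newman modularity Q = Σ_c (e_c/m − (d_c/2m)²). The search is
leading-eigenvector spectral bisection with iterative subdivision, each
split refined by Kernighan–Lin-style single-node moves and kept only if it
increases Q; a community whose generalized modularity matrix has no positive
eigenvalue is indivisible. Spectral bisection is a heuristic: the returned Q
is guaranteed consistent with the returned assignment (to 10⁻¹²) and, on
small graphs, is validated against exhaustive partition enumeration as a
lower bound of the optimum — not as the optimum itself. Modularity is
descriptive output only; it is never a classification feature.

## Classification protocol

Each graph metric yields a feature table of 2n samples (n subjects × two
conditions) × d regions. Classification is an RBF-kernel soft-margin C-SVM
(libsvm solver), validated by leave-one-subject-out cross-validation: both
samples of the held-out subject leave together, and per-feature z-scoring is
fit on the training folds only, so no statistic of the held-out subject
reaches training. Class balance is exact by design (one sample per subject
per condition), so plain pooled accuracy is the score.

Hyperparameters come from a grid search maximizing the LOSOCV accuracy
itself, over C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵} and γ ∈ {2⁻¹⁵, 2⁻¹³, …, 2³} (the
standard libsvm practice); ties break toward the smallest C, then the
smallest γ. Because the selection criterion is the same accuracy that is
reported, the estimate is optimistically biased; this mirrors the wrapper
formulation the package implements and is flagged here rather than hidden.
Inside the GA, fitness uses a coarse 3×3 sub-grid (C ∈ {1, 2⁴, 2⁸},
γ ∈ {2⁻⁷, 2⁻⁴, 2⁻¹}) for speed, and the final reported result of a
selection is re-scored on the full grid. The LOSOCV inner loop builds the
RBF kernel once per fold and γ on fold-standardized features and reuses it
across C values, calling scikit-learn's low-level libsvm binding directly;
the test suite verifies exact agreement of this path with the public `SVC`
estimator, which also serves as the fallback.

## Genetic algorithm

Chromosomes are length-d bit masks. Defaults: population 100, 100
generations, two-point crossover with probability 0.7 per pair, tournament
selection of size 4, mutation probability 0.5 per individual. A mutated
individual flips each gene independently with probability 1/d; we read the
"mutation rate" as the per-individual probability, the convention of the
common GA frameworks — a per-gene rate of 0.5 would randomize chromosomes
each generation and destroy convergence. The population is initialized with
i.i.d. Bernoulli(0.5) bits. Selection is generational without elitism; the
returned optimum is the best individual ever evaluated ("hall of fame"),
so the best-ever fitness trajectory is non-decreasing by construction.
Tournament ties break toward the earliest-drawn contestant, which is
deterministic under a seeded generator and reduces to a uniform resample
when all fitnesses are equal. Crossover pairs consecutive individuals of
the shuffled selected population. The empty mask has fitness 0 by
definition. Fitness values are cached by mask bits, since LOSOCV × grid is
the cost bottleneck and masks recur as the population converges. One GA run
is performed per graph metric; the three metrics are never pooled into one
selection problem.

The manual baseline selects regions whose metric increases from the
low-load to the high-load condition by a one-sided paired t-test at
p < 0.05, uncorrected, then grid-searches the SVM on that mask. If nothing
is significant the result is an empty mask with accuracy 0 and a warning.

## Synthetic cohorts

The generator emulates a within-subject two-condition study (defaults:
d = 40 regions, n = 28 subjects, T = 150 timepoints, 10 planted regions) —
d is reduced from a whole-brain parcellation's 116 to keep end-to-end GA
experiments at desk scale while preserving the cohort size; full d = 116 is
supported.

**Network mode** builds a base correlation matrix from a k = 5-factor
loading model with community structure (so the modularity stage sees
realistic modular graphs). A common additive offset on the off-diagonal,
found by bisection, calibrates the fraction of positive correlations to
`base_density` (default 0.6, approximate by design). Per subject, loadings
are jittered at scale `subject_sd`; in the high-load condition only,
`edge_effect` Δ (default 0.3, correlation units) is added to every
correlation incident to a planted region. Matrices are repaired to the
nearest valid correlation matrix by eigenvalue clipping and renormalization,
and T multivariate-normal timepoints are drawn per scan. If most bumped
correlations saturate at 1 the configuration is rejected with a hint to
reduce Δ. Note that an edge (s, j) with s planted also raises the degree of
its non-planted endpoint j: in network mode the planted set is the *source*
of the effect, not a sharp boundary of affected features.

**Feature mode** emits metric tables directly:
x = μ_region + b_subject + δ·1[region planted, high-load] + ε with
ε ~ N(0, 1) and b ~ N(0, subject_sd²), so δ (`feature_effect`, default 1.5)
is the planted shift in within-subject SD units. `subject_sd` defaults to
0.1; subject intercepts are shared across regions and conditions, providing
the exchangeable within-subject correlation a paired test assumes.

The generator does not model hemodynamics, autocorrelated noise, scanner
drift or motion: passing tests demonstrate correctness of the algorithms
and the expected qualitative behaviour (planted effects are detected,
effect-size monotonicity, chance-level nulls), not performance on real BOLD
data.

## Numerical choices and degenerate inputs

- Constant (zero-variance) time courses are rejected at load, naming the
  region; T < 3 and atlas/dimension mismatches are input errors.
- The diagonal is forced to zero everywhere; self-connections do not exist.
- A negative positive-edge threshold τ is a configuration error.
- Grid-search ties and tournament ties have the deterministic tie-breaks
  described above; GA runs are bit-reproducible given `rng_seed`.
- Constant features inside a training fold get unit scale after centring
  (they carry no information either way).
- Accuracy is always recomputable from the serialized per-fold predictions,
  and the pipeline's `verify` subcommand re-derives every reported accuracy
  from the stored mask + feature table + hyperparameters.

## Known limitations

- The non-nested grid search inflates the reported accuracy; a nested
  protocol would be slower and less faithful to the wrapper formulation.
- An accuracy-only fitness cannot distinguish masks once accuracy
  saturates: on strongly separable cohorts the GA's mask contains
  uninformative regions alongside planted ones (a neutral plateau), so
  region recovery should be read jointly with the fitness level.
- Binary graphs at τ = 0 discard edge-weight information; weighted metric
  variants are a possible extension.
- Modularity of averaged connectivity matrices inherits the usual caveats
  of group-averaging subject networks.
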