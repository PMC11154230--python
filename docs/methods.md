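# Methods

## The model class

`fluxmodes` analyzes deterministic mass-action reaction networks.  The rate
of change of species *xᵢ* is a polynomial in the state,

    dxᵢ/dt = Σⱼ kⱼ Sᵢⱼ x^αⱼ,

where each unidirectional reaction *j* contributes a monomial
Mⱼ = kⱼ x^αⱼ with exponents αⱼ equal to the stoichiometry of the consuming
side, and Sᵢⱼ is the net stoichiometric coefficient.  A reversible reaction
contributes two unidirectional monomials, collapsed into a single net term
ΔMⱼ = Mⱼ,for − Mⱼ,rev signed with respect to the focal species.
Trajectories are integrated with LSODA (SciPy `solve_ivp`) on a fixed output
grid shared across an ensemble, so per-time-point labels line up
positionally.  Default solver tolerances are rtol = atol = 1e-6; looser
tolerances (e.g. 1e-2/1e-1, adequate for large copy-per-cell models) are
exposed as configuration but not used as defaults because dominance
decisions compare rate magnitudes in log space and are sensitive to solver
noise on small models.  States are clipped at zero before monomial
evaluation, since the integrator can produce slightly negative amounts and
the analysis uses magnitudes and log10 transforms.

## Tropical dominance discretization

At a fixed state, the focal species' net rate terms are filtered to the
strictly positive ones, R⁺ (the producers; zero-valued terms are excluded
before any log transform).  Two positive magnitudes are *on par* at level
ρ > 0 when their log10 separation is below ρ:

    sep(m₁, m₂) = |log10 m₁ − log10 m₂|,   par ⟺ sep < ρ.

The dominant set is the argmax production term plus everything on par with
it.  Ties at exactly sep = ρ count as dominated (strict inequality), and
the base is 10 because ρ is an order-of-magnitude threshold; defaults are
ρ = 1.0 and depth = 5, both configurable.

The dominant subnetwork at one time point is built by hierarchical
back-tracing: starting from the user-chosen target species, find its
dominant producing reactions, add one species→species edge per source
reactant of the producing direction, and expand the whole frontier per
iteration for `depth` iterations.  A species already expanded within the
trace still receives edges but is not re-expanded, so feedback cycles (e.g.
the MOMP self-amplification loop) terminate.  Reactions in which the focal
species is a pure catalyst contribute no net term and are never traced
through.  The analysis can equally be run in consumption direction, in
which case dominant *consuming* reactions are followed forward to the
species they produce (edges focal→sink).

Each distinct edge set receives a stable integer label from an
insertion-ordered registry (label 0 is reserved for the empty subnetwork).
One registry is shared across an ensemble — and across wild-type and
perturbed conditions within a run — so labels are comparable everywhere
they appear.  The per-time-point label sequence of one simulation is its
*dynamic fingerprint*.

## Execution modes

Fingerprints are compared at full time resolution with the
longest-common-subsequence distance

    d(x, y) = |x| + |y| − 2·LCS(x, y),

a metric on label sequences that penalizes differences in the order in
which dominant subnetworks appear.  No run-length compression is applied:
full resolution keeps the metric sensitive to how long each subnetwork
stays dominant.  The pairwise matrix computation deduplicates identical
fingerprints, which makes ensemble-scale matrices cheap when only a handful
of distinct fingerprints occur.

Clustering runs on the precomputed distance matrix.  The default is
agglomerative clustering with average linkage; spectral clustering (on a
Gaussian affinity exp(−(d/d̄)²)) and HDBSCAN are alternatives, with HDBSCAN
noise points reported as their own reserved mode so probabilities still sum
to one.  When the number of modes is not fixed by the user it is chosen by
maximal mean silhouette over a k range, ties breaking toward the smallest
k; an all-zero distance matrix yields a single mode with a warning.

A mode's probability is the summed normalized weight of its member
parameter vectors.  Weights resolve from explicit weights, else from a
log-posterior column via max-subtracted exponentiation (overflow-safe
softmax), else uniformly.  A mode's representative subnetwork is the label
with the highest total occurrence count across its members' fingerprints,
ties breaking toward the smaller label.

## Synthetic ensembles

The generator stands in for Bayesian-calibration output, which this package
consumes but deliberately does not produce (no MCMC sampler is
reimplemented).  It provides three levels:

- **Prior sampling**: i.i.d. log-normal draws centered at biologically
  plausible rates (binding 1e-6, unbinding 1e-3, catalysis 1) with a
  configurable log10 standard deviation (default 1.0, i.e. one order of
  magnitude).
- **Likelihood weighting**: homoscedastic Gaussian likelihood of synthetic
  (or real) observation curves, attached as importance-style weights over
  prior samples; failed simulations get zero weight.
- **Planted regimes**: multiplicative rate overrides on the two-branch toy
  network force known dominant branches; the default regime set is
  branch-1 × 100, branch-2 × 100, and balanced (both branches on par — the
  2-branch fixture admits exactly these three distinct label patterns).
  Members jitter the regime centers by 0.05 log10 units, small against the
  2-decade separation, so regimes stay cleanly separable; construction
  fails loudly if the regime centers do not produce distinct fingerprints.

What this emulates — and what it does not: planted ensembles have exact
ground-truth labels and near-degenerate within-regime variation, unlike
real posterior chains whose modes blur into each other and whose weights
decay smoothly.  Passing the recovery tests therefore demonstrates that the
discretize→distance→cluster chain is correct and seed-stable, not that any
particular biological ensemble has three modes.

## Downstream analyses

**Time of death.** ToD = (T10 + T90)/2, where T10/T90 are the first upward
crossings of 10%/90% of the completion marker's maximum (cleaved PARP in
the apoptosis model), linearly interpolated between grid points; the result
is invariant to positive rescaling of the trajectory.  A flat-zero marker
yields a missing value rather than an error, so ensemble summaries degrade
gracefully.

**Knockdowns.** A knockdown scales one species' initial abundance by
(1 − fraction) and the whole ensemble is re-simulated; per-mode reports
give mean ± sd ToD under both conditions and Δt = mean(KD) − mean(WT).
Reaction-rate peak responses are summarized as signed percent changes of
the peak value (ΔF) and the first-occurrence time-to-peak (ΔT), computed
per member and then medianed with interquartile ranges (median of the
per-vector percentages, not a ratio of medians).

**Bayesian update.** After measuring a rate constant s, mode probabilities
update as P(modeᵢ | s) ∝ pᵢ Xᵢ(s), where Xᵢ is a Gaussian kernel density
(Scott's-rule bandwidth) over the mode members' log10 values of that
parameter.  The update conserves probability, is invariant to common
rescaling of the densities, and raises an error when every density is zero
at s (measurement incompatible with all modes).

**Classification.** A gradient-boosted tree classifier (XGBoost,
learning rate 0.1, 100 estimators, softmax multiclass objective, L1/L2
regularization 1, 16 histogram bins) predicts mode membership from log10
parameter values with a 75%/25% stratified train/test split; total-gain
importances rank which parameters carry mode information.

## Numerical choices and degenerate inputs

- Zero monomials never enter log transforms (strict positivity of R⁺).
- The empty production set yields the sentinel label 0, not an error.
- LCS length uses a row-vectorized dynamic program (the running maximum of
  max(prev[j], prev[j−1] + eq) reproduces the classic three-way
  recurrence), keeping 100-point fingerprints fast in pure numpy.
- All randomness (prior sampling, jitter, clustering seeds, classifier
  split) flows from explicit integer seeds; reruns are byte-identical,
  which the pipeline manifest verifies with content hashes.

## Problem sizes

The bundled analyses run at desk scale by design: planted ensembles of 150
vectors on the 4-species toy network with 100-point time grids, and
single-vector or small-ensemble runs of the 22-species apoptosis model on
a 100-point grid over 20,000 s.  The same code path accepts externally
calibrated ensembles of arbitrary size through `read_ensemble` /
`run_pipeline`; the distance stage deduplicates fingerprints, which is the
main lever at posterior-chain scale.

## Known limitations

- Mass-action kinetics only; saturating rate laws (Hill/Michaelis–Menten)
  would need a generalization of the reversible-pair ΔM bookkeeping.
- Dominance is defined on absolute flux; flux relative to protein
  abundance is a plausible alternative the architecture does not yet
  expose.
- The abridged apoptosis model is a reconstruction from its motif
  description constrained to 22 species / 28 parameters
  (see `docs/aearm_model.md`); rate constants default to prior centers,
  not calibrated values, so its printed ToD numbers characterize the
  nominal parameterization only.
- SBML import is not provided; models enter through the plain-text DSL or
  the Python API.
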