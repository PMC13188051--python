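# Methods

## Scope and model classes

The package applies two classes of QSA(P)R models to target chemicals:
multiple linear regression (MLR) for continuous endpoints and Gaussian
linear discriminant analysis (LDA) for class endpoints. It does not develop
models (no variable selection, no cross-validated model search); it fits or
verifies a stated model from its stated training set and then quantifies,
for each target chemical, the prediction, its uncertainty, and whether the
chemical lies inside the model's applicability domain (AD).

## MLR: fit, uncertainty, applicability domain

The design matrix is intercept-augmented: X̃ = [1 | X], so p descriptors give
p′ = p + 1 estimated coefficients and n − p − 1 residual degrees of freedom.
Fits require n ≥ p + 2, leaving at least one degree of freedom for the
residual standard error s = √(Σrᵢ²/(n − p − 1)). Rank deficiency is detected
by a condition-number threshold (10¹⁰) on X̃ and is a hard error naming the
collinear descriptors: a pseudo-inverse would silently produce leverages and
intervals with no meaning.

**Leverage.** h = x̃ (X̃ᵀX̃)⁻¹ x̃ᵀ, the standard hat form with the intercept
column included. This is the convention under which the training leverages
sum to p′ and the centroid has h = 1/n, and it is the convention the 3·p′/n
structural-AD cutoff presumes. A chemical with h ≥ 3·p′/n is out of the
structural AD; the boundary value itself is out. When a model is so small
that 3·p′/n > 1 the cutoff is unreachable and fitting emits a warning.

**Prediction interval.** halfwidth = t(1 − α/2, n − p − 1) · s · √(1 + h),
α = 0.05 by default and configurable per call. The "+1" under the root is
the single-observation noise term, so intervals are wider than confidence
intervals for the mean response; on correctly specified Gaussian data each
tail is escaped with probability exactly α/2 for any n > p + 1, which is the
calibration property the acceptance script measures.

**Endpoint AD.** Three criteria, each reported with its numeric evidence:

1. standardized residual r′ = (y − ŷ)/(s·√(1 − h)), out when |r′| > 2.5
   (strictly; |r′| = 2.5 is in). Applicable only when an observed y exists
   and h < 1; for target chemicals without experimental values it is marked
   `not_applicable` and the verdict rests on the other two criteria.
2. experimental range: out when ŷ leaves [min y, max y] of the training set.
3. interval range: out when the prediction halfwidth leaves the
   [min, max] range of training halfwidths. The comparison is on
   halfwidths, not full intervals — the halfwidth is the uncertainty the
   rule constrains, and comparing positions would duplicate criterion 2.
   Note this flags queries on *both* sides: a query closer to the centroid
   than every training chemical has a narrower interval than the model has
   ever produced, and that extrapolation of the uncertainty estimate is
   worth flagging too.

By default the criteria combine disjunctively (any applicable failure puts
the chemical out) with every reason recorded. A conjunction of criteria 1
and 2 — out only if the residual is extreme *and* the prediction leaves the
experimental range — is available as `strict_and`; it is not the default
because it would let extreme extrapolations pass whenever no experimental
value is available to compute r′.

A leave-one-out Q² (via PRESS = Σ(rᵢ/(1 − hᵢᵢ))²) is provided as a
convenience statistic on fitted models.

## LDA: posteriors, entropy, applicability domain

LDA uses the pooled within-class covariance (divisor n − K), empirical
priors, and requires at least two classes with at least two members each and
n − K ≥ p. Posteriors are the softmax of the linear discriminant scores
δ_k(x) = xᵀΣ⁻¹μ_k − ½μ_kᵀΣ⁻¹μ_k + ln π_k; they are invariant under affine
rescaling of any descriptor, so no scaling is applied before fitting.
Prediction uncertainty is the Shannon entropy of the posteriors in bits
(base 2: bounded by log₂K, = 1 for a maximally uncertain binary prediction;
the base is configurable). Tied posteriors predict the first class in
declared order (order of first appearance in the training set) and are
flagged.

**Structural AD (similarity percentile rule).** Each chemical receives a
similarity score and the cutoff is a percentile of the training scores.
Scoring: each descriptor is divided by its training standard deviation —
*without centering* — and the score is the cosine similarity between the
scaled query and the scaled training centroid. Centering was deliberately
rejected: it maps the training centroid to the origin, where cosine
similarity is undefined, and makes all training scores noise around zero.
Scaling alone removes unit effects while keeping the centroid a meaningful
reference direction. A query that lands exactly at the origin of the scaled
space has no direction and scores 0 (conservatively dissimilar). An
alternative mode scores each query by its maximum cosine similarity to any
single training chemical (`similarity_mode="max_train"`).

Cutoff direction: with a 95th-percentile rule read literally, ~95% of the
training set would fall outside its own AD. The default therefore places the
cutoff at the 5th percentile of training scores (≈95% of training chemicals
in-AD), and `literal_percentile=True` reproduces the verbatim reading for
comparability. Percentiles use numpy's linear-interpolation convention in
both modes; a score strictly below the cutoff is out.

**Endpoint AD.** Out when the winning posterior lies strictly inside
(0.25, 0.75); the bounds themselves are in. For binary models this verdict
is identical whether the band is applied to the event class or its
complement.

## Consensus

Inverse-variance weighting is defined only for predictions carrying a σ, so
consensus is restricted to MLR members; LDA entropy is not a standard
deviation and classification predictions are excluded with an explicit
reason. Weights w = 1/σ² use the prediction-interval halfwidth as σ. Members
with σ = 0 (exact-fit models) are excluded as degenerate rather than given
infinite weight. Policies: `all`, `in_ad_only` (out-of-AD members excluded
with reasons), and `user_selected` (mirroring interactive click-to-combine);
`user_selected` is the default in the library call, while the batch profiler
defaults to no consensus unless asked.

## Chemistry layer

RDKit is the backend; its aromaticity and canonicalization conventions
apply, and the canonical SMILES is recorded in outputs for auditability.
The built-in descriptor set is deliberately limited to eight exactly
specified descriptors (molecular_weight, heavy_atom_count, ring_count,
hbond_donor_count, hbond_acceptor_count, rotatable_bond_count, wiener_index,
tpsa); H-bond counts follow the backend's Lipinski-style definitions and the
Wiener index is half the sum of the heavy-atom topological distance matrix.
Models built on any other descriptor supply values through a CSV table
(id column first, one descriptor per column); supplied values always win
over computed ones and carry `provenance="supplied"`. Missing cells fail at
read time; a table merely lacking a column a model needs fails at
prediction time, naming the descriptor, so one table can serve many models.

Fingerprints are three documented kinds behind one interface: hashed linear
heavy-atom paths of 1–7 bonds over 1024 bits (path keys are canonical
min(forward, reverse) atom/bond token strings hashed with CRC32, so the
fingerprint depends only on the heavy-atom graph), and a frozen ~50-pattern
SMARTS functional-group key set in binary and count variants. These are not
reimplementations of published fingerprint systems (PubChem, E-State,
Klekota–Roth); `register_fingerprint_kind` is the adapter point for plugging
in a backend's named fingerprints. Two empty fingerprints compare as
similarity 1 with a warning (trivially similar, but uninformative); empty
versus non-empty is 0.

## Model exchange and registry

The XML dialect stores metadata, descriptor specs, the full training set and
optionally the published coefficients. Training data is mandatory because
every AD statistic needs the training matrix; stated coefficients are
*verified* against a refit (tolerance 10⁻⁶ per coefficient) and a conflict
is a validation error — a model whose coefficients contradict its training
set should not silently predict with either. Reals are serialized with 17
significant digits, which round-trips IEEE doubles exactly; write→parse
equality is tested on randomized models. Registry loading is fault-isolated:
a corrupt file yields a diagnostic, never aborts the batch.

## Profiler

Profiling is the full cross product targets × models in deterministic order;
a pair that cannot be predicted (unparsable SMILES, missing descriptor)
yields a row with a machine-readable skip reason, never a silently dropped
row. The run is a pure function of its inputs, so repeated CSV exports are
byte-identical. Metabolite detection is an external-process boundary: the
hook contract is a callable SMILES → [(metabolite SMILES, reaction label)];
a deterministic stub is used in tests and a subprocess adapter is provided
for an external tool; hook failures leave the parent profiled alone with a
warning. Exports: CSV (canonical) and XLSX (four sheets: predictions,
consensus, neighbors, ad_details) with units, citations and AD evidence
echoed into every row for QPRF traceability.

## Synthetic study conditions

The fixture module defines the study conditions under which the statistical
guarantees are verified:

- MLR fixtures: descriptors i.i.d. standard Gaussian, y = x̃·β + N(0, σ)
  with default n=30, p=3, β = (1, 2, 3, 4), σ = 1 — a moderately sized,
  well-conditioned training set typical of the regression QSARs this package
  targets. Extrapolated queries are placed 10 training-SDs from the centroid.
- LDA fixtures: two unit-covariance Gaussian classes at ±separation/2 along
  a random direction, default separation 5 SD (well-separated but not
  degenerate).
- The calibration study runs 10,000 replicates (Monte-Carlo SE of the tail
  fraction ≈ 0.0016, so the ±0.005 acceptance band is ≈3 SE); bias checks
  use 1,000 replicates. These sizes keep the full suite under a minute of
  simulation while leaving Monte-Carlo error well inside the tolerances.

What the synthetic studies do **not** show: real descriptor distributions
are neither Gaussian nor independent, real residuals are rarely homoskedastic,
and real training sets carry measurement error in y. Interval calibration
and unbiasedness hold exactly only under correct specification; on real
data the AD machinery is precisely the guard against relying on them where
specification fails. The toy chemical set exercises the chemistry layer on
hand-checkable molecules; it emulates no real endpoint.

## Numerical conventions

- Leverage, cutoffs: boundary h = cutoff is OUT; |r′| = 2.5 is IN;
  posterior = 0.25 or 0.75 is IN; similarity = cutoff is IN.
- t quantiles from scipy with df = n − p − 1.
- s = 0 (exact fit): halfwidths are 0, standardized residuals defined as 0,
  such models excluded from consensus.
- Condition-number threshold 10¹⁰ for both X̃ᵀX̃ and the pooled covariance.
- Sorting ties in neighbor ranking break by training order; profiler output
  order is target order × registry registration order.
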