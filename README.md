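# qsarprofiler

Batch application of user-defined QSA(P)R models — quantitative
structure–activity/property relationships — to target chemicals, with full
uncertainty quantification, applicability-domain (AD) analysis, consensus
averaging and structural-similarity neighbor detection.

It is written for the workflow of regulatory and environmental chemists who
profile chemicals against many endpoints at once (ecotoxicity, environmental
fate, ADME, ...) and must document every prediction's reliability in QPRF-style
reports: every verdict this package emits comes with its numeric evidence.

## The statistics at the core

**Regression (MLR).** A model is an ordinary least-squares fit
ŷ = x̃·β on an intercept-augmented design X̃ (n training chemicals,
p descriptors). Around the fit:

- residual standard error s = √(Σ(yᵢ − ŷᵢ)² / (n − p − 1));
- prediction interval halfwidth σ = t₍₁₋α/₂, n−p−1₎ · s · √(1 + h), with
  leverage h = x̃ (X̃ᵀX̃)⁻¹ x̃ᵀ;
- **structural AD**: a chemical is out when h ≥ 3·p′/n (p′ = p + 1);
- **endpoint AD**: out when the standardized residual
  r′ = r / (s·√(1−h)) exceeds 2.5 in magnitude (when an experimental value is
  available), when the prediction leaves the training experimental range, or
  when its interval halfwidth leaves the training halfwidth range.

**Consensus.** N predictions of the same endpoint combine with
inverse-variance weights w = 1/σ²: value Σwᵢŷᵢ/Σwᵢ, uncertainty √(1/Σwᵢ).

**Classification (LDA).** Gaussian linear discriminant analysis with pooled
within-class covariance; uncertainty is the Shannon entropy −Σ p·log₂p of the
posteriors (bits). Structural AD uses a cosine-similarity percentile rule
over the training set; endpoint AD flags posteriors inside the indecision
band (0.25, 0.75).

**Neighbors.** Tanimoto / Dice / cosine similarity over binary or count
fingerprints (hashed linear paths, SMARTS functional-group keys); distance
is 1 − similarity.

Models travel as plain-text XML carrying descriptors, training data and
optional published coefficients (verified against a refit, never trusted);
drop files in a directory, list it in a one-line config, and they load.

## Worked example

Profile two targets (descriptor values supplied as a CSV) against the three
shipped synthetic example models:

```sh
qsarprofiler profile \
    --descriptor-table descriptors.csv \
    --registry examples/registry.cfg \
    --out out --consensus all
# profiled 2 targets x 3 models (6 predictions); wrote out/predictions.csv,
# out/consensus.csv, out/neighbors.csv, out/ad_details.csv
```

A prediction row from `out/predictions.csv`:

```
targetA, example_mlr_a, mlr, prediction=0.6715, uncertainty=1.6194 (interval_halfwidth),
structural_in_ad=True, endpoint_in_ad=False,
reasons="halfwidth 1.61943 outside training halfwidth range [1.63652, 1.97549]"
```

targetA's predicted endpoint is 0.67 ± 1.62 (95% prediction interval). Its
leverage is below the 3·p′/n cutoff (structurally in-domain), but the
interval is *narrower* than any training chemical's — the query sits closer
to the descriptor centroid than the whole training set, which the
interval-range rule flags so the report can say the uncertainty estimate is
extrapolated. The consensus of the two regression models in the subgroup:

```sh
qsarprofiler consensus --descriptor-table descriptors.csv \
    --registry examples/registry.cfg --subgroup "Synthetic endpoint A"
# targetA: value=0.716116 uncertainty=1.27172 members=example_mlr_a,example_mlr_b
```

The combined uncertainty (1.27) is below both members' (1.62, 1.84), as
inverse-variance weighting guarantees. `validate-model`, `fit`, `neighbors`
and `make-fixture` subcommands round out the CLI; the same operations are
available as library functions (`fit_mlr`, `prediction_interval`,
`structural_ad_check`, `combine`, `find_neighbors`, ...) and as
scikit-learn-compatible estimators (`MlrRegressor`, `LdaClassifier`).

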