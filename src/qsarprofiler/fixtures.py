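"""Synthetic models, chemicals and query sets with known ground truth.

Every statistical claim in this package is testable without external data
because fixtures are generated from stated distributions:

* MLR fixtures draw descriptors from a standard multivariate Gaussian and
  responses from ``y = x̃·β + N(0, noise_sd)``, so coverage, bias and
  leverage behavior have known expectations;
* LDA fixtures draw two Gaussian classes at ±separation/2 along a random
  unit direction with unit within-class covariance, so the Bayes boundary
  and error rate are known;
* the toy chemical set is ~20 frozen small-molecule SMILES whose descriptor
  values are simple enough to verify by hand.

Same seed, same fixture — generation is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .base import DescriptorSpec, ModelMetadata, TrainingRecord
from .lda import LdaModel, fit_lda
from .mlr import MlrModel, MlrRegressor, fit_mlr

__all__ = [
    "FixtureConfig",
    "MlrQuery",
    "LdaQuery",
    "make_mlr_fixture",
    "make_lda_fixture",
    "toy_chemical_set",
    "random_mlr_model",
    "random_lda_model",
    "write_example_models",
    "interval_noncoverage",
]


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for one synthetic model."""

    n: int = 30
    p: int = 3
    beta_true: Optional[tuple] = None  # intercept first; default 1, 2, ..., p+1
    noise_sd: float = 1.0
    class_separation: float = 5.0
    seed: int = 0
    n_queries: int = 10

    def resolved_beta(self) -> np.ndarray:
        if self.beta_true is not None:
            beta = np.asarray(self.beta_true, dtype=float)
            if beta.shape != (self.p + 1,):
                raise ValueError(f"beta_true must have length p+1={self.p + 1}")
            return beta
        return np.arange(1.0, self.p + 2.0)


@dataclass(frozen=True)
class MlrQuery:
    values: tuple
    y_true: float
    label: str  # "in_ad" | "extrapolated"


@dataclass(frozen=True)
class LdaQuery:
    values: tuple
    true_class: str


def _specs(p: int) -> list:
    return [DescriptorSpec(name=f"d{j + 1}", source="supplied") for j in range(p)]


def make_mlr_fixture(config: FixtureConfig):
    """Return (MlrModel, queries).  Queries mix in-distribution points with
    points displaced 10 training-SDs from the centroid along each axis
    (labeled "extrapolated"; their leverage exceeds the 3·(p+1)/n cutoff for
    any reasonable n)."""
    rng = np.random.default_rng(config.seed)
    beta = config.resolved_beta()
    X = rng.standard_normal((config.n, config.p))
    y = beta[0] + X @ beta[1:] + rng.normal(0.0, config.noise_sd, size=config.n)
    training = [
        TrainingRecord(id=f"t{i + 1}", descriptor_values=tuple(X[i]), y=float(y[i]))
        for i in range(config.n)
    ]
    metadata = ModelMetadata(
        model_id=f"mlr_fixture_seed{config.seed}",
        endpoint_name="synthetic endpoint", units="a.u.",
        group="Synthetic", subgroup="MLR fixtures",
        citation="synthetic fixture, Gaussian design",
    )
    model = fit_mlr(_specs(config.p), training, metadata=metadata)

    queries = []
    centroid = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    for _ in range(config.n_queries):
        xq = rng.standard_normal(config.p)
        yq = float(beta[0] + xq @ beta[1:] + rng.normal(0.0, config.noise_sd))
        queries.append(MlrQuery(values=tuple(xq), y_true=yq, label="in_ad"))
    for j in range(config.p):
        xq = centroid.copy()
        xq[j] += 10.0 * sd[j]
        yq = float(beta[0] + xq @ beta[1:])
        queries.append(MlrQuery(values=tuple(xq), y_true=yq, label="extrapolated"))
    return model, queries


def make_lda_fixture(config: FixtureConfig):
    """Return (LdaModel, queries): two unit-covariance Gaussian classes at
    ±class_separation/2 along a random unit direction."""
    rng = np.random.default_rng(config.seed)
    direction = rng.standard_normal(config.p)
    direction /= np.linalg.norm(direction)
    half = config.class_separation / 2.0
    n1 = config.n // 2
    n0 = config.n - n1
    X0 = rng.standard_normal((n0, config.p)) - half * direction
    X1 = rng.standard_normal((n1, config.p)) + half * direction
    training = []
    for i, x in enumerate(X0):
        training.append(TrainingRecord(id=f"a{i + 1}", descriptor_values=tuple(x),
                                       y="inactive"))
    for i, x in enumerate(X1):
        training.append(TrainingRecord(id=f"b{i + 1}", descriptor_values=tuple(x),
                                       y="active"))
    metadata = ModelMetadata(
        model_id=f"lda_fixture_seed{config.seed}",
        endpoint_name="synthetic class", units="",
        group="Synthetic", subgroup="LDA fixtures",
        citation="synthetic fixture, two Gaussian classes",
    )
    model = fit_lda(_specs(config.p), training, metadata=metadata)
    queries = []
    for _ in range(config.n_queries):
        cls = rng.integers(0, 2)
        x = rng.standard_normal(config.p) + (half if cls else -half) * direction
        queries.append(LdaQuery(values=tuple(x),
                                true_class="active" if cls else "inactive"))
    return model, queries


# frozen SMILES set; expected descriptor values are asserted in the tests
TOY_CHEMICALS = (
    ("methane", "C"),
    ("ethane", "CC"),
    ("propane", "CCC"),
    ("butane", "CCCC"),
    ("isobutane", "CC(C)C"),
    ("pentane", "CCCCC"),
    ("cyclohexane", "C1CCCCC1"),
    ("benzene", "c1ccccc1"),
    ("toluene", "Cc1ccccc1"),
    ("phenol", "Oc1ccccc1"),
    ("methanol", "CO"),
    ("ethanol", "CCO"),
    ("acetic_acid", "CC(=O)O"),
    ("acetone", "CC(C)=O"),
    ("acetamide", "CC(N)=O"),
    ("aniline", "Nc1ccccc1"),
    ("pyridine", "c1ccncc1"),
    ("chlorobenzene", "Clc1ccccc1"),
    ("diethyl_ether", "CCOCC"),
    ("naphthalene", "c1ccc2ccccc2c1"),
)


def toy_chemical_set() -> list:
    """~20 frozen small-molecule structures for chemistry tests and examples."""
    from .chemistry import parse_smiles

    return [parse_smiles(smi, id=name) for name, smi in TOY_CHEMICALS]


def random_mlr_model(rng: np.random.Generator) -> MlrModel:
    """A random valid MLR model (for round-trip and oracle property tests)."""
    p = int(rng.integers(1, 5))
    n = int(rng.integers(p + 3, p + 25))
    cfg = FixtureConfig(
        n=n, p=p,
        beta_true=tuple(rng.normal(0, 3, size=p + 1)),
        noise_sd=float(rng.uniform(0.1, 2.0)),
        seed=int(rng.integers(0, 2**31 - 1)),
        n_queries=0,
    )
    model, _ = make_mlr_fixture(cfg)
    return model


def random_lda_model(rng: np.random.Generator) -> LdaModel:
    p = int(rng.integers(1, 5))
    n = int(rng.integers(max(2 * p + 4, 8), 40))
    cfg = FixtureConfig(
        n=n, p=p,
        class_separation=float(rng.uniform(1.0, 8.0)),
        seed=int(rng.integers(0, 2**31 - 1)),
        n_queries=0,
    )
    model, _ = make_lda_fixture(cfg)
    return model


def write_example_models(outdir, seed: int = 12345) -> list:
    """Write two MLR and one LDA example model plus a registry config.

    Returns the written paths.  Used by the ``make-fixture`` CLI command and
    to generate the examples shipped in the repository.
    """
    from .model_io import write_model_file

    outdir = Path(outdir)
    models_dir = outdir / "models"
    models_dir.mkdir(parents=True, exist_ok=True)
    written = []

    m1, _ = make_mlr_fixture(FixtureConfig(n=12, p=2, seed=seed, noise_sd=0.5,
                                           n_queries=0))
    m1.metadata = ModelMetadata(
        model_id="example_mlr_a", endpoint_name="synthetic pLC50",
        units="-log10(mol/L)", group="Examples", subgroup="Synthetic endpoint A",
        citation="synthetic example model A",
    )
    m2, _ = make_mlr_fixture(FixtureConfig(n=15, p=2, seed=seed + 1, noise_sd=0.8,
                                           n_queries=0))
    m2.metadata = ModelMetadata(
        model_id="example_mlr_b", endpoint_name="synthetic pLC50",
        units="-log10(mol/L)", group="Examples", subgroup="Synthetic endpoint A",
        citation="synthetic example model B",
    )
    m3, _ = make_lda_fixture(FixtureConfig(n=16, p=2, seed=seed + 2,
                                           class_separation=5.0, n_queries=0))
    m3.metadata = ModelMetadata(
        model_id="example_lda", endpoint_name="synthetic toxicity class",
        units="", group="Examples", subgroup="Synthetic classification",
        citation="synthetic example classifier",
    )
    for m, fname in ((m1, "example_mlr_a.xml"), (m2, "example_mlr_b.xml"),
                     (m3, "example_lda.xml")):
        path = models_dir / fname
        write_model_file(m, path)
        written.append(path)

    cfg_path = outdir / "registry.cfg"
    cfg_path.write_text(
        "# qsarprofiler registry configuration\n"
        "model_dir = models\n",
        encoding="utf-8",
    )
    written.append(cfg_path)
    return written


def interval_noncoverage(
    n_replicates: int,
    seed: int,
    n: int = 30,
    p: int = 3,
    noise_sd: float = 1.0,
    alpha: float = 0.05,
) -> dict:
    """Empirical per-tail non-coverage of the MLR prediction interval.

    For each replicate: draw a fresh Gaussian design and response, fit the
    regression, predict one held-out in-distribution query with its
    default-alpha interval, and record on which side (if any) the true
    simulated y escapes the interval.  Under a correctly specified Gaussian
    linear model each tail escapes with probability alpha/2 exactly, for any
    n > p + 1.

    Returns {"upper": fraction above the upper bound, "lower": ..., "n": ...}.
    """
    rng = np.random.default_rng(seed)
    beta = np.arange(1.0, p + 2.0)
    above = below = 0
    est = MlrRegressor(alpha=alpha)
    for _ in range(n_replicates):
        X = rng.standard_normal((n, p))
        y = beta[0] + X @ beta[1:] + rng.normal(0.0, noise_sd, size=n)
        est.fit(X, y)
        xq = rng.standard_normal((1, p))
        y_true = float(beta[0] + xq[0] @ beta[1:] + rng.normal(0.0, noise_sd))
        yhat, hw = est.predict_interval(xq)
        if y_true > yhat[0] + hw[0]:
            above += 1
        elif y_true < yhat[0] - hw[0]:
            below += 1
    return {
        "upper": above / n_replicates,
        "lower": below / n_replicates,
        "n": n_replicates,
    }
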