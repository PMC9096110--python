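"""Logistic-fusion composite features.

A composite feature is the linear predictor (logit) of a logistic
regression over a handful of named base descriptors:

    composite(x) = b0 + b1*x_1 + ... + bn*x_n

Two frozen composites, ``comF`` and ``comF2``, ship as package constants
with their published intercepts and coefficients; they were originally
fitted on a large AHTP training corpus and are used as extra input columns
for the ensemble. New composites can be fitted on any labeled feature
matrix with :func:`fit_composite`.

The ``hydrophobicity`` term of comF is not a schema component name; it is
bound to the Eisenberg-scale residue mean (an interpretation — the defining
scale was not recorded with the equation).
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from sklearn.linear_model import LogisticRegression

from .features import FeatureMatrix, FeatureSchema, FeatureVector
from .peptide_io import POSITIVE_LABEL
from .tables import EISENBERG

#: alias names resolvable in addition to schema component names
ALIASES = {"hydrophobicity": "eisenberg residue mean"}


@dataclass(frozen=True)
class CompositeFeatureSpec:
    """Intercept and named coefficients of one composite feature."""

    name: str
    intercept: float
    coefficients: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for fname, c in self.coefficients.items():
            if not np.isfinite(c):
                raise ValueError(f"{self.name}: non-finite coefficient for {fname}")

    def feature_names(self) -> tuple[str, ...]:
        return tuple(self.coefficients)

    def to_json(self) -> str:
        return json.dumps({"name": self.name, "intercept": self.intercept,
                           "coefficients": self.coefficients}, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "CompositeFeatureSpec":
        return cls(name=d["name"], intercept=float(d["intercept"]),
                   coefficients={k: float(v) for k, v in d["coefficients"].items()})


def frozen_composites() -> dict[str, CompositeFeatureSpec]:
    """The packaged frozen composite specs, keyed by name (comF, comF2)."""
    with resources.files("ahtpscreen.data").joinpath("frozen_composites.json").open() as fh:
        raw = json.load(fh)
    return {k: CompositeFeatureSpec.from_dict(v) for k, v in raw.items()}


def _resolve(name: str, v: FeatureVector, peptide_seq: str | None = None) -> float:
    if name == "hydrophobicity":
        # Eisenberg residue mean; derivable from the AAC block of the vector
        aac = {a: v[f"AAC{i + 1}"] for i, a in enumerate(sorted(EISENBERG))}
        return sum(EISENBERG[a] * aac[a] for a in aac)
    return v[name]


def evaluate_composite(spec: CompositeFeatureSpec, v: FeatureVector) -> float:
    """b0 + sum_j bj * feature_j on one feature vector."""
    total = spec.intercept
    for fname, coef in spec.coefficients.items():
        total += coef * _resolve(fname, v)
    return total


def evaluate_composite_on_values(spec: CompositeFeatureSpec,
                                 values: dict[str, float]) -> float:
    """Evaluate a composite on an explicit name->value mapping.

    Every referenced feature (aliases included) must be present; useful for
    checking the frozen equations at chosen component values.
    """
    missing = [n for n in spec.coefficients if n not in values]
    if missing:
        raise KeyError(f"{spec.name}: missing features {missing}")
    return spec.intercept + sum(c * values[n] for n, c in spec.coefficients.items())


@dataclass
class CompositeFit:
    spec: CompositeFeatureSpec
    converged: bool
    n_iter: int
    separable_warning: bool


def fit_composite(matrix: FeatureMatrix, feature_names: list[str], name: str,
                  regularization: float = 1e-4, max_iter: int = 1000,
                  seed: int = 0) -> CompositeFit:
    """Fit a logistic composite on selected columns of a labeled matrix.

    ``regularization`` is a ridge strength (L2); 0 requests a pure
    maximum-likelihood fit. Perfectly separable data is reported through
    ``separable_warning`` (huge coefficients) and non-convergence through
    ``converged`` rather than silently truncated.
    """
    y = matrix.y
    if y is None:
        raise ValueError("matrix has no labels")
    yb = (np.asarray(y) == POSITIVE_LABEL).astype(int)
    if len(np.unique(yb)) < 2:
        raise ValueError("both classes must be present")
    X = matrix.frame[feature_names].to_numpy(dtype=float)

    C = np.inf if regularization == 0 else 1.0 / (regularization * len(yb))
    model = LogisticRegression(C=C if np.isfinite(C) else 1e12,
                               max_iter=max_iter, random_state=seed)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model.fit(X, yb)
    converged = not any("onverge" in str(w.message) for w in caught)
    coefs = dict(zip(feature_names, model.coef_[0]))
    # perfect training separation with large weights: the MLE diverges and
    # the returned coefficients are an artifact of the stopping rule
    train_acc = float((model.predict(X) == yb).mean())
    separable = bool(np.max(np.abs(model.coef_)) > 10 and train_acc == 1.0)
    if not converged or separable:
        warnings.warn(f"composite {name!r}: "
                      + ("did not converge; " if not converged else "")
                      + ("coefficients diverging (separable data?); consider "
                         "a larger ridge strength" if separable else ""),
                      stacklevel=2)
    spec = CompositeFeatureSpec(name=name, intercept=float(model.intercept_[0]),
                                coefficients={k: float(v) for k, v in coefs.items()})
    return CompositeFit(spec=spec, converged=converged,
                        n_iter=int(np.max(model.n_iter_)),
                        separable_warning=separable)


def augment_matrix(matrix: FeatureMatrix,
                   specs: list[CompositeFeatureSpec]) -> FeatureMatrix:
    """Append one column per composite, computed from the base columns.

    The returned matrix's schema gains a ``composites`` block; prediction
    and training then see the composites as ordinary features.
    """
    if not specs:
        return matrix
    names = [s.name for s in specs]
    existing = set(matrix.schema.names)
    clash = [n for n in names if n in existing]
    if clash or len(set(names)) != len(names):
        raise ValueError(f"composite name collision: {clash or names}")
    frame = matrix.frame.copy()
    for s in specs:
        cols = np.full(len(frame), s.intercept, dtype=float)
        for fname, coef in s.coefficients.items():
            if fname == "hydrophobicity":
                aac_cols = [f"AAC{i + 1}" for i in range(20)]
                h = np.array([EISENBERG[a] for a in sorted(EISENBERG)])
                cols += coef * frame[aac_cols].to_numpy() @ h
            else:
                cols += coef * frame[fname].to_numpy(dtype=float)
        frame[s.name] = cols
    blocks = matrix.schema.blocks + (("composites", tuple(names)),)
    schema = FeatureSchema(blocks=blocks, version=matrix.schema.version)
    order = [c for c in ["label"] if c in frame.columns]
    frame = frame[list(schema.names) + order]
    return FeatureMatrix(schema=schema, frame=frame)


def augment_schema(schema: FeatureSchema,
                   specs: list[CompositeFeatureSpec]) -> FeatureSchema:
    """Extended schema with one component per composite."""
    if not specs:
        return schema
    names = [s.name for s in specs]
    if set(names) & set(schema.names):
        raise ValueError("composite name collision")
    return FeatureSchema(blocks=schema.blocks + (("composites", tuple(names)),),
                         version=schema.version)
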