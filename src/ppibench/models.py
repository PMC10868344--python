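"""Baseline model families behind one uniform fit/score interface.

The benchmark's point is the evaluation design, not model research, so the
families are standard references: logistic regression, Gaussian naive
Bayes, random forest, gradient boosting (XGBoost), and ``kmer_logistic`` —
a logistic regression restricted to sequence-derived pair columns, shipped
as the desk-scale stand-in for sequence deep-learning models so the
topology and overlap analyses remain runnable end to end.

Scores are probabilities of interaction in [0, 1]; fits are deterministic
given the ModelSpec seed; training wall-time is recorded because resource
cost is part of the reported sheet.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .core import ConfigurationError, SchemaMismatchError
from .features import SEQ_COLUMNS

FAMILIES = ("logistic", "naive_bayes", "random_forest", "gradient_boosting", "kmer_logistic")
ID_COLUMNS = ("idA", "idB")


@dataclass
class ModelSpec:
    family: str = "logistic"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(
                f"family must be one of {FAMILIES}, got {self.family!r}"
            )


@dataclass
class FitResult:
    spec: ModelSpec
    model: object
    feature_names: list[str]
    wall_time_s: float
    coefficients: Optional[pd.DataFrame] = None

    @property
    def schema_fingerprint(self) -> str:
        payload = "\n".join([self.spec.family] + self.feature_names)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _build_estimator(spec: ModelSpec):
    hp = dict(spec.hyperparameters)
    if spec.family in ("logistic", "kmer_logistic"):
        hp.setdefault("max_iter", 2000)
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", LogisticRegression(random_state=spec.seed, **hp)),
            ]
        )
    if spec.family == "naive_bayes":
        return GaussianNB(**hp)
    if spec.family == "random_forest":
        hp.setdefault("n_estimators", 200)
        return RandomForestClassifier(random_state=spec.seed, n_jobs=1, **hp)
    if spec.family == "gradient_boosting":
        from xgboost import XGBClassifier

        hp.setdefault("n_estimators", 200)
        hp.setdefault("max_depth", 4)
        return XGBClassifier(
            random_state=spec.seed, n_jobs=1, eval_metric="logloss", **hp
        )
    raise ConfigurationError(f"unknown family {spec.family!r}")


def _matrix(feature_table: pd.DataFrame, columns: Sequence[str]) -> np.ndarray:
    missing = [c for c in columns if c not in feature_table.columns]
    if missing:
        present_only = [c for c in feature_table.columns if c not in ID_COLUMNS and c not in columns]
        raise SchemaMismatchError(
            f"feature table is missing columns {missing}"
            + (f"; unexpected columns present: {present_only}" if present_only else "")
        )
    return feature_table.loc[:, list(columns)].to_numpy(dtype=float)


def _feature_names(feature_table: pd.DataFrame, family: str) -> list[str]:
    names = [c for c in feature_table.columns if c not in ID_COLUMNS]
    if family == "kmer_logistic":
        names = [c for c in names if c in SEQ_COLUMNS or c == "miss_seq"]
        if not names:
            raise SchemaMismatchError(
                "kmer_logistic requires sequence feature columns "
                f"({SEQ_COLUMNS[:2]}...); none found"
            )
    return names


def fit(spec: ModelSpec, feature_table: pd.DataFrame, labels: Sequence[int]) -> FitResult:
    """Train a model; deterministic given ``spec.seed``.

    ``labels`` are binary (0/1 or positive/negative strings).  Raises on
    single-class labels and on tables with fewer than 10 rows.
    """
    spec.validate()
    y = _binary_labels(labels)
    if len(feature_table) != len(y):
        raise ValueError("feature table and labels differ in length")
    if len(y) < 10:
        raise ValueError(f"need at least 10 training rows, got {len(y)}")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(
            f"training labels contain a single class ({classes.tolist()}); "
            "both positives and negatives are required"
        )
    names = _feature_names(feature_table, spec.family)
    X = _matrix(feature_table, names)
    estimator = _build_estimator(spec)
    start = time.perf_counter()
    estimator.fit(X, y)
    wall = time.perf_counter() - start

    coefficients = None
    if spec.family in ("logistic", "kmer_logistic"):
        clf = estimator.named_steps["clf"]
        coefficients = pd.DataFrame(
            {"feature": names, "coefficient": clf.coef_.ravel()}
        )
    return FitResult(spec, estimator, names, wall, coefficients)


def predict_scores(fit_result: FitResult, feature_table: pd.DataFrame) -> np.ndarray:
    """Interaction probability per row, order-preserving with the input.

    Columns are matched by name against the training schema, so column
    permutations score identically; missing columns raise a
    :class:`SchemaMismatchError` naming them.
    """
    X = _matrix(feature_table, fit_result.feature_names)
    return fit_result.model.predict_proba(X)[:, 1]


def agreement_rate(
    scores_a: Sequence[float], scores_b: Sequence[float], threshold: float = 0.5
) -> float:
    """Fraction of rows where the two models' thresholded decisions agree."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"score vectors differ in length: {a.shape} vs {b.shape}")
    return float(np.mean((a >= threshold) == (b >= threshold)))


def _binary_labels(labels: Sequence) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UO":
        mapping = {"positive": 1, "negative": 0, "1": 1, "0": 0}
        try:
            arr = np.array([mapping[str(v)] for v in arr])
        except KeyError as exc:
            raise ValueError(f"unrecognized label {exc.args[0]!r}") from exc
    arr = arr.astype(int)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    return arr


def save_model(fit_result: FitResult, path) -> None:
    """Persist a fit as a single-file artifact with its schema fingerprint."""
    joblib.dump(
        {
            "spec": fit_result.spec,
            "model": fit_result.model,
            "feature_names": fit_result.feature_names,
            "wall_time_s": fit_result.wall_time_s,
            "coefficients": fit_result.coefficients,
            "fingerprint": fit_result.schema_fingerprint,
        },
        path,
    )


def load_model(path) -> FitResult:
    payload = joblib.load(path)
    result = FitResult(
        payload["spec"],
        payload["model"],
        payload["feature_names"],
        payload["wall_time_s"],
        payload["coefficients"],
    )
    if result.schema_fingerprint != payload["fingerprint"]:
        raise SchemaMismatchError("model artifact fingerprint mismatch")
    return result
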