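"""Linear valence models over form/semantic features.

The same engine serves three uses: (i) fitting valence norms on large
surface-feature design matrices (up to 754 form columns plus embedding
dimensions), (ii) predicting a valence index for arbitrary strings,
including pseudowords, and (iii) univariate "observed ~ predictor"
regressions used to compare predictor sources on best-worst scores.

Fits are ordinary least squares.  Wide form blocks are routinely rank
deficient (most of the 676 bigram columns never occur); the minimum-norm
solution is used and aliased columns are logged rather than silently
dropped.  Model quality is summarised by R^2, Pearson r between fitted and
observed values, and AIC under the convention

    AIC = n * ln(RSS / n) + 2 * k,   k = slopes + intercept + 1

(the +1 counts the error variance).  Absolute AICs depend on this constant
convention and are only comparable within it; orderings are the meaningful
quantity.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .form_features import FeatureSetSpec, build_design_matrix

if TYPE_CHECKING:  # pragma: no cover
    from .embeddings import EmbeddingTable

logger = logging.getLogger(__name__)


@dataclass
class LinearValenceModel:
    spec: FeatureSetSpec | None
    intercept: float
    coefficients: np.ndarray
    column_labels: list[str]
    training_n: int
    rss: float

    def predict_design(self, design: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(design, dtype=np.float64) @ self.coefficients

    def predict(self, strings: Sequence[str], embeddings: "EmbeddingTable | None" = None) -> np.ndarray:
        """Predicted valence for letter strings; not clamped to the 1-9 scale
        (extrapolation beyond the scale maximum is legitimate and occurs)."""
        if self.spec is None:
            raise ValueError("model has no feature spec; use predict_design")
        design, labels = build_design_matrix(strings, self.spec, embeddings)
        if labels != self.column_labels:
            raise ValueError("design columns do not match the trained model")
        return self.predict_design(design)

    def to_json(self, path) -> None:
        doc = {
            "format_version": 1,
            "spec": None
            if self.spec is None
            else {
                "include_letters": self.spec.include_letters,
                "include_bigrams": self.spec.include_bigrams,
                "include_boundaries": self.spec.include_boundaries,
                "include_dimensions": self.spec.include_dimensions,
                "name": self.spec.name,
            },
            "intercept": self.intercept,
            "column_labels": self.column_labels,
            "coefficients": self.coefficients.tolist(),
            "training_n": self.training_n,
            "rss": self.rss,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "LinearValenceModel":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        spec = None
        if doc["spec"] is not None:
            spec = FeatureSetSpec(**doc["spec"])
        return cls(
            spec=spec,
            intercept=float(doc["intercept"]),
            coefficients=np.asarray(doc["coefficients"], dtype=np.float64),
            column_labels=list(doc["column_labels"]),
            training_n=int(doc["training_n"]),
            rss=float(doc["rss"]),
        )


@dataclass(frozen=True)
class ModelFitStats:
    name: str
    r: float
    r_squared: float
    aic: float
    n: int
    k: int


def fit(
    design: np.ndarray,
    valence: np.ndarray,
    spec: FeatureSetSpec | None = None,
    column_labels: list[str] | None = None,
) -> LinearValenceModel:
    """OLS fit of valence on a design matrix (intercept added internally).

    Rank-deficient problems get the minimum-norm solution; aliased columns
    (those orthogonal to the attained row space, e.g. never-occurring
    bigrams) are logged by label.
    """
    design = np.asarray(design, dtype=np.float64)
    y = np.asarray(valence, dtype=np.float64)
    n, p = design.shape
    if len(y) != n:
        raise ValueError("design rows and valence length differ")
    if n <= p:
        raise ValueError(
            f"need more observations ({n}) than predictors ({p}); "
            "use a larger lexicon or a smaller feature set"
        )
    X = np.hstack([np.ones((n, 1)), design])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p + 1:
        n_aliased = p + 1 - rank
        if column_labels is not None:
            # columns whose removal does not change the fit: detect by zero
            # projection of the column onto the row space complement is costly;
            # report count plus all-zero columns, the dominant case here.
            zero_cols = [column_labels[j] for j in range(p) if not np.any(design[:, j])]
            logger.info("fit: rank deficient (%d aliased); all-zero columns: %s",
                        n_aliased, ", ".join(zero_cols[:20]) + ("..." if len(zero_cols) > 20 else ""))
        else:
            logger.info("fit: rank deficient (%d aliased columns), minimum-norm solution used", n_aliased)
    fitted = X @ beta
    rss = float(np.sum((y - fitted) ** 2))
    return LinearValenceModel(
        spec=spec,
        intercept=float(beta[0]),
        coefficients=beta[1:],
        column_labels=column_labels or [f"x{j}" for j in range(p)],
        training_n=n,
        rss=rss,
    )


def fit_stats(
    model: LinearValenceModel,
    design: np.ndarray,
    valence: np.ndarray,
    name: str = "",
) -> ModelFitStats:
    """R^2, Pearson r(fitted, observed) and AIC on the given data."""
    y = np.asarray(valence, dtype=np.float64)
    fitted = model.predict_design(design)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss <= np.finfo(float).eps * len(y) * max(1.0, float(y.mean()) ** 2):
        raise ValueError("observed valence has zero variance")
    rss = float(np.sum((y - fitted) ** 2))
    r_squared = 1.0 - rss / tss
    if np.std(fitted) == 0.0:
        r = 0.0
    else:
        r = float(np.corrcoef(fitted, y)[0, 1])
    n = len(y)
    k = len(model.coefficients) + 2  # slopes + intercept + error variance
    aic = aic_from_rss(rss, n, k)
    return ModelFitStats(name=name or (model.spec.name if model.spec else ""), r=r,
                         r_squared=r_squared, aic=aic, n=n, k=k)


def aic_from_rss(rss: float, n: int, k: int) -> float:
    if rss <= 0.0:
        return float("-inf")
    return n * float(np.log(rss / n)) + 2 * k


def compare_models(
    predictors: Mapping[str, "FeatureSetSpec | np.ndarray"],
    observed: np.ndarray,
    words: Sequence[str] | None = None,
    embeddings: "EmbeddingTable | None" = None,
) -> pd.DataFrame:
    """Fit one model per named predictor and rank them.

    A FeatureSetSpec value fits the multi-column OLS model on ``words``.
    A vector value is treated as a single external predictor (e.g. a
    predicted-valence index or a neighbor-valence index) and enters a
    univariate regression of observed on predictor.  Returns a table with
    r, R^2, AIC and ranks by both R^2 (descending) and AIC (ascending).
    """
    y = np.asarray(observed, dtype=np.float64)
    rows = []
    for name, pred in predictors.items():
        if isinstance(pred, FeatureSetSpec):
            if words is None:
                raise ValueError("feature-spec predictors require the word list")
            design, labels = build_design_matrix(words, pred, embeddings)
            model = fit(design, y, spec=pred, column_labels=labels)
            st = fit_stats(model, design, y, name=name)
        else:
            x = np.asarray(pred, dtype=np.float64)
            if len(x) != len(y):
                raise ValueError(f"predictor {name!r} misaligned with observed items")
            design = x.reshape(-1, 1)
            model = fit(design, y, column_labels=[name])
            st = fit_stats(model, design, y, name=name)
        rows.append({"model": name, "r": st.r, "r_squared": st.r_squared,
                     "aic": st.aic, "n": st.n, "k": st.k})
    table = pd.DataFrame(rows)
    table["rank_r2"] = table["r_squared"].rank(ascending=False, method="min").astype(int)
    table["rank_aic"] = table["aic"].rank(ascending=True, method="min").astype(int)
    return table.sort_values("rank_r2", kind="stable").reset_index(drop=True)


def nested_f_test(
    design_base: np.ndarray,
    design_full: np.ndarray,
    observed: np.ndarray,
) -> tuple[float, float]:
    """F-test for nested OLS models (full must extend base).

    Returns (F, p).  Used to decide whether extra predictor columns (e.g. a
    neighbor-valence index added to the letters model) earn their keep.
    """
    y = np.asarray(observed, dtype=np.float64)
    base = fit(design_base, y)
    full = fit(design_full, y)
    n = len(y)
    p_base = design_base.shape[1]
    p_full = design_full.shape[1]
    if p_full <= p_base:
        raise ValueError("full model must add predictors to the base model")
    df1 = p_full - p_base
    df2 = n - p_full - 1
    if df2 <= 0:
        raise ValueError("not enough observations for the F test")
    f = ((base.rss - full.rss) / df1) / (full.rss / df2)
    p_value = float(stats.f.sf(f, df1, df2))
    return float(f), p_value
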