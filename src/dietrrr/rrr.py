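"""Reduced rank regression (redundancy analysis) pattern extraction.

The model: with standardized foods X (n x p) and standardized responses
Y (n x q), compute the OLS fit Yhat = X (X'X)^-1 X'Y and eigendecompose the
sample covariance of Yhat. The eigenvectors v_k (orthonormal, q x k) are the
response loadings; pattern weights are a_k = B v_k rescaled so each training
score t_k = X a_k has sample SD 1 (participants receive z-scores); the
eigenvalues lambda_k = var(Yhat v_k) order the patterns. Factor k maximizes
the summed squared correlation of a unit-variance linear combination of
foods with the response set, orthogonally to the earlier factors;
equivalently a_k is the k-th generalized eigenvector of
(S_xy S_yx, S_xx).

"Explained variation" of factor k in response j is 100 x corr(t_k, y_j)^2;
the table carries an all-responses row (mean over responses, the criterion
RRR maximizes) and an all-foods row (mean squared correlation of the score
with each food column).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import StandardizedMatrix, apply_standardization, standardize

_COND_LIMIT = 1e10


class RRRError(ValueError):
    """Raised for ill-posed reduced rank regression fits."""


@dataclass
class RRRModel:
    """A fitted reduced-rank-regression pattern model for one wave."""

    weights: pd.DataFrame  # foods x k, scaled so training scores are z-scores
    response_loadings: pd.DataFrame  # responses x k, orthonormal columns
    eigenvalues: np.ndarray  # variance of fitted-response projections, nonincreasing
    scores: pd.DataFrame  # training z-scores, participants x k
    food_loadings: pd.DataFrame  # corr(food, score): the "loadings" scaling
    x_means: pd.Series
    x_sds: pd.Series
    wave: str | None = None

    @property
    def k(self) -> int:
        return self.weights.shape[1]

    @property
    def food_names(self) -> list[str]:
        return list(self.weights.index)

    @property
    def factor_names(self) -> list[str]:
        return list(self.weights.columns)

    def to_json(self, path: str | Path) -> Path:
        """Serialize weights, loadings, eigenvalues and scaling parameters.

        Training scores are not stored; confirmatory scoring needs only the
        weights and standardization parameters.
        """
        payload = {
            "wave": self.wave,
            "foods": self.food_names,
            "responses": list(self.response_loadings.index),
            "factors": self.factor_names,
            "weights": self.weights.to_numpy().tolist(),
            "response_loadings": self.response_loadings.to_numpy().tolist(),
            "food_loadings": self.food_loadings.to_numpy().tolist(),
            "eigenvalues": np.asarray(self.eigenvalues).tolist(),
            "x_means": self.x_means.to_numpy().tolist(),
            "x_sds": self.x_sds.to_numpy().tolist(),
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "RRRModel":
        d = json.loads(Path(path).read_text())
        foods = d["foods"]
        factors = d["factors"]
        return cls(
            weights=pd.DataFrame(d["weights"], index=foods, columns=factors),
            response_loadings=pd.DataFrame(
                d["response_loadings"], index=d["responses"], columns=factors
            ),
            eigenvalues=np.asarray(d["eigenvalues"], dtype=float),
            scores=pd.DataFrame(columns=factors),
            food_loadings=pd.DataFrame(
                d["food_loadings"], index=foods, columns=factors
            ),
            x_means=pd.Series(d["x_means"], index=foods),
            x_sds=pd.Series(d["x_sds"], index=foods),
            wave=d["wave"],
        )


def _eig_sorted(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of a symmetric matrix, eigenvalues nonincreasing.

    numpy returns ascending order; exact eigenvalue ties would make the
    ordering (and the factors) non-unique — documented instability.
    """
    vals, vecs = np.linalg.eigh(S)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def fit_rrr(X: StandardizedMatrix, Y: StandardizedMatrix, k: int) -> RRRModel:
    """Extract ``k`` dietary patterns from standardized foods and responses.

    Raises :class:`RRRError` when X'X is near-singular (condition number
    diagnostic included) or when ``k`` exceeds the rank of the fitted
    responses.
    """
    Xv = X.values.to_numpy(dtype=float)
    Yv = Y.values.to_numpy(dtype=float)
    n, p = Xv.shape
    q = Yv.shape[1]
    if k < 1:
        raise RRRError("k must be >= 1")
    if k > min(p, q):
        raise RRRError(f"k={k} exceeds min(#foods={p}, #responses={q})")
    if n <= p:
        raise RRRError(f"need more participants (n={n}) than foods (p={p})")

    G = Xv.T @ Xv
    cond = np.linalg.cond(G)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise RRRError(
            f"X'X is rank-deficient or ill-conditioned (condition number {cond:.3g}); "
            "remove collinear food groups"
        )
    B = np.linalg.solve(G, Xv.T @ Yv)  # p x q OLS coefficients
    Yhat = Xv @ B
    S = Yhat.T @ Yhat / (n - 1)
    eigvals, eigvecs = _eig_sorted(S)
    rank_tol = max(eigvals[0], 0.0) * 1e-10
    if eigvals[k - 1] <= rank_tol:
        raise RRRError(
            f"k={k} exceeds the rank of the fitted responses "
            f"(eigenvalue {k} = {eigvals[k - 1]:.3g})"
        )

    V = eigvecs[:, :k]
    raw_weights = B @ V  # p x k
    t = Xv @ raw_weights
    sd_t = t.std(axis=0, ddof=1)
    weights = raw_weights / sd_t
    t = t / sd_t
    # sign convention: the largest-|weight| food is positive in each factor
    V = V.copy()
    for j in range(k):
        lead = int(np.argmax(np.abs(weights[:, j])))
        if weights[lead, j] < 0:
            weights[:, j] *= -1
            t[:, j] *= -1
            V[:, j] *= -1

    factors = [f"factor_{i + 1}" for i in range(k)]
    foods = X.columns
    food_loadings = Xv.T @ t / (n - 1)  # corr(food, score): both unit variance
    return RRRModel(
        weights=pd.DataFrame(weights, index=foods, columns=factors),
        response_loadings=pd.DataFrame(V, index=Y.columns, columns=factors),
        eigenvalues=eigvals[:k],
        scores=pd.DataFrame(t, index=X.values.index, columns=factors),
        food_loadings=pd.DataFrame(food_loadings, index=foods, columns=factors),
        x_means=X.means,
        x_sds=X.sds,
        wave=X.wave,
    )


def project_scores(
    model: RRRModel, intake: pd.DataFrame, standardization: str = "self"
) -> pd.DataFrame:
    """Score raw intakes (g/day) with a fitted model's weights.

    ``standardization="self"`` z-scores the new data by its own means/SDs;
    ``"training"`` reuses the model's stored training parameters. On the
    model's own training table, ``"self"`` reproduces the stored training
    z-scores exactly.
    """
    missing = [f for f in model.food_names if f not in intake.columns]
    if missing:
        raise ValueError(f"intake data lacks model food columns: {missing}")
    sub = intake[model.food_names]
    if standardization == "self":
        Z = standardize(sub).values
    elif standardization == "training":
        Z = (sub - model.x_means) / model.x_sds
    else:
        raise ValueError("standardization must be 'self' or 'training'")
    return pd.DataFrame(
        Z.to_numpy() @ model.weights.to_numpy(),
        index=intake.index,
        columns=model.factor_names,
    )


def explained_variation(
    model: RRRModel, X: StandardizedMatrix, Y: StandardizedMatrix
) -> pd.DataFrame:
    """Percent explained variation per factor and response, with summary rows.

    Cell (j, k) is 100 x corr(t_k, y_j)^2. The ``all_responses`` row is the
    mean over responses; ``all_foods`` is the mean squared correlation of the
    score with each food column. The ``total`` column sums across factors;
    per response it equals 100 x the OLS R^2 of that response on the foods
    when all q factors are extracted.
    """
    t = model.scores.to_numpy()
    n = t.shape[0]
    Yv = Y.values.to_numpy(dtype=float)
    Xv = X.values.to_numpy(dtype=float)
    corr_y = Yv.T @ t / (n - 1)  # responses x k, all columns unit variance
    corr_x = Xv.T @ t / (n - 1)
    cells = 100.0 * corr_y**2
    all_resp = cells.mean(axis=0)
    all_foods = 100.0 * (corr_x**2).mean(axis=0)
    table = pd.DataFrame(cells, index=Y.columns, columns=model.factor_names)
    table.loc["all_responses"] = all_resp
    table.loc["all_foods"] = all_foods
    table["total"] = table.sum(axis=1)
    return table


def label_patterns(model: RRRModel, highlight_threshold: float = 0.10) -> list[dict]:
    """High-weight flags and a label per factor.

    A food is flagged when its weight is strictly above the threshold in
    absolute value. The label names the food with the maximal absolute
    weight, prefixed "(low in) " when that weight is negative.
    """
    out = []
    for factor in model.factor_names:
        w = model.weights[factor]
        flags = [
            (food, float(w[food]))
            for food in w.index
            if abs(w[food]) > highlight_threshold
        ]
        lead = w.abs().idxmax()
        label = f"(low in) {lead}" if w[lead] < 0 else str(lead)
        out.append(
            {
                "factor": factor,
                "label": label,
                "high_weight": sorted(flags, key=lambda fw: -abs(fw[1])),
            }
        )
    return out
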