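"""Fisher linear and quadratic classification of cell populations.

Each cell is a point in the three-feature space (i_average, i_skewness,
K_naaGc).  The Fisher linear discriminant projects onto the direction
``w = S_w^-1 (mu_1 - mu_2)`` (``S_w`` the pooled within-class scatter) and
thresholds at the midpoint of the projected class means (equal priors);
the quadratic classifier uses Gaussian class-conditional densities with
per-class covariances.  Performance is reported as a confusion matrix with
per-class percent correct, the binomial standard error sqrt(p(1-p)/N), and
a one-sided exact binomial p-value against chance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .volume_io import round_half_away

__all__ = [
    "ClassifierModel",
    "ConfusionReport",
    "fit_fisher_linear",
    "fit_quadratic",
    "evaluate",
    "scatter_with_boundary",
    "DEFAULT_FEATURES",
]

logger = logging.getLogger(__name__)

DEFAULT_FEATURES = ("K_naaGc", "i_average")
_RIDGE = 1e-6


def _class_split(table: pd.DataFrame, features, label_col: str):
    labels = sorted(table[label_col].unique().tolist())
    if len(labels) != 2:
        raise ValueError(f"need exactly two classes, got {labels}")
    X = [table.loc[table[label_col] == lab, list(features)].to_numpy(float) for lab in labels]
    for lab, x in zip(labels, X):
        if x.shape[0] < 2:
            raise ValueError(f"class {lab!r} has fewer than 2 samples")
        if not np.isfinite(x).all():
            raise ValueError(f"class {lab!r} contains missing or non-finite feature values")
    return labels, X


def _regularize(S: np.ndarray, context: str) -> np.ndarray:
    """Ridge-stabilize a scatter/covariance matrix when near-singular."""
    d = S.shape[0]
    ridge = _RIDGE * np.trace(S) / d
    if ridge <= 0:
        ridge = _RIDGE
    if np.linalg.cond(S) > 1e10:
        logger.warning("%s matrix near-singular; adding ridge %g", context, ridge)
        return S + ridge * np.eye(d)
    return S


@dataclass
class ClassifierModel:
    """A fitted two-class discriminant.

    ``kind`` is "fisher_linear" (weights + offset) or "quadratic"
    (per-class means and covariances, equal priors).  ``labels`` are sorted;
    scores > 0 predict ``labels[0]``.
    """

    kind: str
    features: tuple[str, ...]
    labels: tuple[str, str]
    weights: np.ndarray | None = None
    offset: float = 0.0
    means: list[np.ndarray] = field(default_factory=list)
    covs: list[np.ndarray] = field(default_factory=list)

    def scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.kind == "fisher_linear":
            return X @ self.weights + self.offset
        g = []
        for mu, cov in zip(self.means, self.covs):
            diff = X - mu
            sol = np.linalg.solve(cov, diff.T).T
            g.append(-0.5 * np.einsum("ij,ij->i", diff, sol) - 0.5 * np.linalg.slogdet(cov)[1])
        return g[0] - g[1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        s = self.scores(X)
        return np.where(s > 0, self.labels[0], self.labels[1])

    def predict_table(self, table: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.features if f not in table.columns]
        if missing:
            raise ValueError(f"feature table lacks columns {missing}")
        return self.predict(table[list(self.features)].to_numpy(float))


def fit_fisher_linear(
    table: pd.DataFrame, features=DEFAULT_FEATURES, label_col: str = "label"
) -> ClassifierModel:
    """Fisher linear discriminant with midpoint offset (equal priors).

    Features are standardized internally before the scatter solve, so the
    fitted assignments do not depend on per-feature units.
    """
    labels, (X0, X1) = _class_split(table, features, label_col)
    scale = np.vstack([X0, X1]).std(axis=0)
    scale[scale == 0] = 1.0
    X0s, X1s = X0 / scale, X1 / scale
    mu0, mu1 = X0s.mean(axis=0), X1s.mean(axis=0)
    Sw = np.zeros((len(features), len(features)))
    for x, mu in ((X0s, mu0), (X1s, mu1)):
        d = x - mu
        Sw += d.T @ d
    Sw = _regularize(Sw, "within-class scatter")
    w = np.linalg.solve(Sw, mu0 - mu1) / scale  # back to raw feature units
    offset = -float(w @ (X0.mean(axis=0) + X1.mean(axis=0)) / 2.0)
    return ClassifierModel(
        kind="fisher_linear",
        features=tuple(features),
        labels=tuple(labels),
        weights=w,
        offset=offset,
    )


def fit_quadratic(
    table: pd.DataFrame, features=DEFAULT_FEATURES, label_col: str = "label"
) -> ClassifierModel:
    """Gaussian class-conditional discriminant with per-class covariance."""
    labels, Xs = _class_split(table, features, label_col)
    d = len(features)
    scale = np.vstack(Xs).std(axis=0)
    scale[scale == 0] = 1.0
    means, covs = [], []
    for lab, x in zip(labels, Xs):
        if x.shape[0] <= d:
            logger.warning("class %r has n <= d; covariance will rely on ridge", lab)
        mu = x.mean(axis=0)
        diff = (x - mu) / scale
        cov = diff.T @ diff / x.shape[0]
        # regularize in standardized space, then restore raw feature units
        cov = _regularize(cov, f"class {lab!r} covariance") * np.outer(scale, scale)
        means.append(mu)
        covs.append(cov)
    return ClassifierModel(
        kind="quadratic", features=tuple(features), labels=tuple(labels), means=means, covs=covs
    )


@dataclass
class ConfusionReport:
    """Confusion counts and per-class binomial summaries.

    ``counts[i, j]`` is the number of class-``labels[j]`` cells predicted as
    ``labels[i]`` (columns sum to the class sizes).  Percentages carry the
    binomial standard error sqrt(p(1-p)/N); ``percent_correct_int`` and
    ``se_int`` are the integer-rounded presentation.  ``p_values`` are
    one-sided exact binomial tails against chance (0.5).
    """

    labels: tuple[str, str]
    counts: np.ndarray
    percent_correct: dict
    standard_error: dict
    percent_correct_int: dict
    se_int: dict
    p_values: dict
    mode: str = "resubstitution"

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "counts": self.counts.tolist(),
            "percent_correct": self.percent_correct,
            "standard_error": self.standard_error,
            "percent_correct_int": self.percent_correct_int,
            "se_int": self.se_int,
            "p_values": self.p_values,
            "mode": self.mode,
        }


def binomial_summary(correct: int, n: int) -> tuple[float, float, int, int, float]:
    """Percent correct, SE in percent, their integer roundings, and the
    one-sided exact binomial p-value against chance."""
    if not 0 <= correct <= n or n == 0:
        raise ValueError("need 0 <= correct <= n with n > 0")
    p = correct / n
    pct = 100.0 * p
    se = 100.0 * np.sqrt(p * (1 - p) / n)
    pval = float(stats.binomtest(correct, n, 0.5, alternative="greater").pvalue)
    return pct, se, round_half_away(pct), round_half_away(se), pval


def evaluate(model: ClassifierModel, table: pd.DataFrame, label_col: str = "label",
             mode: str = "resubstitution") -> ConfusionReport:
    """Confusion matrix of a fitted model on a labelled feature table.

    ``mode="resubstitution"`` (default) evaluates on the given table as-is;
    ``mode="loo"`` refits the model once per held-out cell (leave-one-out),
    a stricter protocol than the resubstitution convention.
    """
    labels = model.labels
    if mode == "resubstitution":
        pred = model.predict_table(table)
    elif mode == "loo":
        logger.warning("leave-one-out evaluation departs from the resubstitution convention")
        fit = fit_fisher_linear if model.kind == "fisher_linear" else fit_quadratic
        pred = np.empty(len(table), dtype=object)
        for i in range(len(table)):
            m = fit(table.drop(table.index[i]), model.features, label_col)
            pred[i] = m.predict_table(table.iloc[[i]])[0]
    else:
        raise ValueError(f"unknown evaluation mode {mode!r}")

    true = table[label_col].to_numpy()
    counts = np.zeros((2, 2), dtype=int)
    for i, pl in enumerate(labels):  # predicted
        for j, tl in enumerate(labels):  # true
            counts[i, j] = int(np.sum((pred == pl) & (true == tl)))

    pct, se, pct_i, se_i, pv = {}, {}, {}, {}, {}
    for j, lab in enumerate(labels):
        n = int(counts[:, j].sum())
        correct = int(counts[j, j])
        pct[lab], se[lab], pct_i[lab], se_i[lab], pv[lab] = binomial_summary(correct, n)
    return ConfusionReport(labels, counts, pct, se, pct_i, se_i, pv, mode)


def scatter_with_boundary(
    table: pd.DataFrame,
    model: ClassifierModel,
    out_path,
    label_col: str = "label",
):
    """Scatter plot of a two-feature table with the linear decision line."""
    if model.kind != "fisher_linear" or len(model.features) != 2:
        raise ValueError("boundary plotting needs a 2-feature linear model")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fx, fy = model.features
    fig, ax = plt.subplots(figsize=(5, 4))
    markers = {model.labels[0]: "*", model.labels[1]: "s"}
    for lab in model.labels:
        sub = table[table[label_col] == lab]
        ax.scatter(sub[fx], sub[fy], label=lab, marker=markers[lab], alpha=0.8)
    (w1, w2), b = model.weights, model.offset
    xs = np.linspace(table[fx].min(), table[fx].max(), 100)
    if abs(w2) > 1e-300:
        ax.plot(xs, -(w1 * xs + b) / w2, "k--", label="decision line")
    else:
        ax.axvline(-b / w1, color="k", ls="--", label="decision line")
    ax.set_xlabel(fx)
    ax.set_ylabel(fy)
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
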