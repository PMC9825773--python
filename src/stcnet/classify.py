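"""Per-ADR logistic-regression classifiers on drug embeddings (binary relevance).

Predicting the set of ADRs of a drug is a multi-label problem; it is
decomposed into one independent L2-regularized logistic regression per ADR
(binary relevance), trained on the drug embedding vectors.  Model quality is
assessed by k-fold cross-validation with per-ADR AUROC and average precision,
macro-averaged over ADRs that have enough positive drugs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import KFold

from .embedding import EmbeddingMatrix, Node2VecEmbedding
from .network import DrugADRLabels, HeteroNetwork

logger = logging.getLogger(__name__)

#: Paper-convention inverse regularization strength (scikit-learn ``C``);
#: smaller means a stronger L2 penalty.
DEFAULT_INVERSE_REG_STRENGTH = 0.1


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve.

    Equals the probability that a uniformly drawn positive outscores a
    uniformly drawn negative, with ties counted half (the Mann–Whitney
    convention).  Raises :class:`ValueError` when only one class is present,
    where the quantity is undefined.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("AUROC undefined: labels contain a single class")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def average_precision(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Average precision: the step-sum AP = Σ (Rn − Rn−1)·Pn over descending
    score thresholds (not the interpolated variant).

    Raises :class:`ValueError` when there is no positive label.
    """
    y = np.asarray(labels)
    if y.sum() == 0:
        raise ValueError("average precision undefined: no positive labels")
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


@dataclass
class ADRClassifierBundle:
    """Trained per-ADR logistic models: weight vectors plus intercepts.

    ``skipped`` lists ADRs that could not be trained (single-class label
    column) — they are reported, never silently dropped.
    """

    adr_ids: list[str]
    weights: np.ndarray          # (n_adrs, d)
    intercepts: np.ndarray       # (n_adrs,)
    inverse_reg_strength: float
    skipped: list[str] = field(default_factory=list)

    def __post_init__(self):
        self._index = {a: i for i, a in enumerate(self.adr_ids)}
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite classifier weights")

    def adr_index(self, adr: str) -> int:
        if adr not in self._index:
            raise KeyError(f"no classifier trained for ADR {adr!r}")
        return self._index[adr]

    def decision(self, X: np.ndarray) -> np.ndarray:
        """Affine scores for all ADRs: (n_samples, n_adrs)."""
        return X @ self.weights.T + self.intercepts

    def predict_proba_matrix(self, X: np.ndarray) -> np.ndarray:
        from scipy.special import expit
        return expit(self.decision(X))

    def save(self, path: str | Path) -> None:
        payload = {
            "adr_ids": self.adr_ids,
            "weights": self.weights.tolist(),
            "intercepts": self.intercepts.tolist(),
            "inverse_reg_strength": self.inverse_reg_strength,
            "skipped": self.skipped,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str | Path) -> "ADRClassifierBundle":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(adr_ids=d["adr_ids"], weights=np.array(d["weights"]),
                   intercepts=np.array(d["intercepts"]),
                   inverse_reg_strength=d["inverse_reg_strength"],
                   skipped=d.get("skipped", []))


def _standardizer(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column mean and (guarded) standard deviation of a feature matrix."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


class BinaryRelevanceClassifier(BaseEstimator):
    """One independent logistic regression per label column.

    Embedding coordinates are column-standardized before fitting (the SGD
    training of the embedding leaves dimensions on unequal scales, which an
    L2-penalized linear model is sensitive to); the scaler is folded back
    into ``coef_``/``intercept_`` so the fitted model applies directly to
    raw embedding vectors.

    Parameters
    ----------
    C : float
        Inverse regularization strength passed to each
        :class:`~sklearn.linear_model.LogisticRegression` (L2 penalty).
    max_iter : int
        Solver iteration cap.
    standardize : bool
        Z-score the feature columns on the training data before fitting.

    Attributes
    ----------
    adr_ids_ : list of str
        Labels actually trained (single-class columns are skipped).
    coef_ : ndarray of shape (n_trained, d)
    intercept_ : ndarray of shape (n_trained,)
    skipped_ : list of str
        Label columns with zero positives or zero negatives.
    """

    def __init__(self, C: float = DEFAULT_INVERSE_REG_STRENGTH,
                 max_iter: int = 1000, standardize: bool = True):
        self.C = C
        self.max_iter = max_iter
        self.standardize = standardize

    def fit(self, X: np.ndarray, Y: np.ndarray,
            adr_ids: Sequence[str] | None = None) -> "BinaryRelevanceClassifier":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y)
        if Y.ndim != 2 or X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must share the sample axis; Y must be "
                             "a drug × label matrix")
        if adr_ids is None:
            adr_ids = [f"label{i}" for i in range(Y.shape[1])]
        if self.standardize:
            mu, sd = _standardizer(X)
        else:
            mu = np.zeros(X.shape[1])
            sd = np.ones(X.shape[1])
        Xs = (X - mu) / sd
        trained, coefs, icpts, skipped = [], [], [], []
        for j, adr in enumerate(adr_ids):
            col = Y[:, j].astype(int)
            if col.sum() == 0 or col.sum() == len(col):
                skipped.append(adr)
                continue
            clf = LogisticRegression(C=self.C,
                                     max_iter=self.max_iter)
            clf.fit(Xs, col)
            trained.append(adr)
            # fold the scaler into the affine model: w·(x−μ)/σ + b
            w = clf.coef_[0] / sd
            coefs.append(w)
            icpts.append(clf.intercept_[0] - float(w @ mu))
        if skipped:
            logger.info("BinaryRelevanceClassifier: skipped %d single-class "
                        "label(s): %s", len(skipped), ", ".join(skipped))
        self.adr_ids_ = trained
        self.coef_ = np.array(coefs) if coefs else np.empty((0, X.shape[1]))
        self.intercept_ = np.array(icpts)
        self.skipped_ = skipped
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """(n_samples, n_trained_labels) matrix of positive-class
        probabilities."""
        from scipy.special import expit
        return expit(np.asarray(X, float) @ self.coef_.T + self.intercept_)

    def to_bundle(self) -> ADRClassifierBundle:
        return ADRClassifierBundle(
            adr_ids=list(self.adr_ids_), weights=self.coef_.copy(),
            intercepts=self.intercept_.copy(),
            inverse_reg_strength=self.C, skipped=list(self.skipped_))


def train_adr_classifiers(
        drug_embeddings: EmbeddingMatrix, labels: DrugADRLabels,
        inverse_reg_strength: float = DEFAULT_INVERSE_REG_STRENGTH,
) -> ADRClassifierBundle:
    """Fit one logistic model per ADR on all labeled drugs.

    Every drug of ``labels`` must have an embedding row.  ADR columns with
    zero positives or zero negatives are skipped and listed in the returned
    bundle.
    """
    X = drug_embeddings.subset(labels.drugs)
    est = BinaryRelevanceClassifier(C=inverse_reg_strength)
    est.fit(X, labels.matrix, adr_ids=labels.adrs)
    return est.to_bundle()


def predict_proba(bundle: ADRClassifierBundle, adr: str,
                  vector: np.ndarray) -> float:
    """Logistic of the affine score of ``adr``'s classifier at ``vector``."""
    i = bundle.adr_index(adr)
    v = np.asarray(vector, dtype=float)
    if v.shape != (bundle.weights.shape[1],):
        raise ValueError(f"vector has shape {v.shape}, expected "
                         f"({bundle.weights.shape[1]},)")
    from scipy.special import expit
    return float(expit(bundle.weights[i] @ v + bundle.intercepts[i]))


@dataclass
class CVReport:
    """Per-ADR cross-validated AUROC/AP plus macro averages."""

    per_adr: pd.DataFrame          # adr_pt, n_drugs, auroc, ap
    macro_auroc: float
    macro_ap: float
    k: int
    min_drugs: int
    excluded: list[str] = field(default_factory=list)

    def save(self, tsv_path: str | Path, json_path: str | Path | None = None):
        self.per_adr.to_csv(tsv_path, sep="\t", index=False)
        if json_path is not None:
            with open(json_path, "w", encoding="utf-8") as fh:
                json.dump({"macro_auroc": self.macro_auroc,
                           "macro_ap": self.macro_ap,
                           "k": self.k, "min_drugs": self.min_drugs,
                           "n_adrs": int(len(self.per_adr)),
                           "excluded": self.excluded}, fh, indent=2)


def cross_validate(drug_embeddings: EmbeddingMatrix, labels: DrugADRLabels,
                   k: int = 10, min_drugs: int = 10, seed: int = 0,
                   inverse_reg_strength: float = DEFAULT_INVERSE_REG_STRENGTH,
                   ) -> CVReport:
    """k-fold cross-validation of the per-ADR classifiers.

    Drugs are partitioned into ``k`` folds once, shared by every ADR (labels
    live on drugs, so the split is drug-level and unstratified).  Out-of-fold
    probabilities are pooled per ADR before computing AUROC and AP.  ADRs
    with fewer than ``min_drugs`` positive drugs are excluded from the
    report; folds whose training labels collapse to one class fall back to
    predicting the training prevalence.  Features are column-standardized
    with training-fold statistics, matching
    :class:`BinaryRelevanceClassifier`.
    """
    if k < 2:
        raise ValueError("cross-validation needs k >= 2 folds")
    X = drug_embeddings.subset(labels.drugs)
    n = X.shape[0]
    if n < k:
        raise ValueError(f"{n} drugs cannot be split into {k} folds")

    pos_counts = labels.matrix.sum(axis=0)
    # need min_drugs positives and at least one negative, else AUROC/AP are
    # undefined for the ADR
    eligible = [j for j in range(labels.n_adrs)
                if min_drugs <= pos_counts[j] < n]
    excluded = [labels.adrs[j] for j in range(labels.n_adrs)
                if j not in set(eligible)]

    oof = np.full((n, len(eligible)), np.nan)
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    for train_idx, test_idx in splitter.split(X):
        mu, sd = _standardizer(X[train_idx])
        X_tr = (X[train_idx] - mu) / sd
        X_te = (X[test_idx] - mu) / sd
        for col, j in enumerate(eligible):
            y_tr = labels.matrix[train_idx, j].astype(int)
            if y_tr.sum() == 0 or y_tr.sum() == len(y_tr):
                oof[test_idx, col] = y_tr.mean()
                continue
            clf = LogisticRegression(C=inverse_reg_strength,
                                     max_iter=1000)
            clf.fit(X_tr, y_tr)
            oof[test_idx, col] = clf.predict_proba(X_te)[:, 1]

    rows = []
    for col, j in enumerate(eligible):
        y = labels.matrix[:, j].astype(int)
        rows.append({
            "adr_pt": labels.adrs[j],
            "n_drugs": int(pos_counts[j]),
            "auroc": auroc(oof[:, col], y),
            "ap": average_precision(oof[:, col], y),
        })
    per_adr = pd.DataFrame(rows, columns=["adr_pt", "n_drugs", "auroc", "ap"])
    if per_adr.empty:
        raise ValueError(f"no ADR has >= {min_drugs} positive drugs")
    return CVReport(per_adr=per_adr,
                    macro_auroc=float(per_adr["auroc"].mean()),
                    macro_ap=float(per_adr["ap"].mean()),
                    k=k, min_drugs=min_drugs, excluded=excluded)


def optimize_walk_params(net: HeteroNetwork, labels: DrugADRLabels,
                         p_grid: Sequence[float], q_grid: Sequence[float],
                         embedder: Node2VecEmbedding | None = None,
                         k: int = 10, min_drugs: int = 10, seed: int = 0,
                         inverse_reg_strength: float = DEFAULT_INVERSE_REG_STRENGTH,
                         ) -> tuple[tuple[float, float], pd.DataFrame]:
    """Grid-search the walk bias (p, q) by cross-validated macro AUROC.

    Runs the full embed → train → CV loop at every grid point.  Ties are
    broken toward (1, 1), then lexicographically.  Returns the winning pair
    and the full score table.
    """
    if not p_grid or not q_grid:
        raise ValueError("p_grid and q_grid must be non-empty")
    base = embedder if embedder is not None else Node2VecEmbedding(seed=seed)
    rows = []
    cache: dict[tuple[float, float], float] = {}
    for p, q in product(p_grid, q_grid):
        key = (float(p), float(q))
        if key not in cache:
            emb = Node2VecEmbedding(**{**base.get_params(),
                                       "p": key[0], "q": key[1]})
            emb.fit(net)
            report = cross_validate(emb.embedding_, labels, k=k,
                                    min_drugs=min_drugs, seed=seed,
                                    inverse_reg_strength=inverse_reg_strength)
            cache[key] = report.macro_auroc
        rows.append({"p": key[0], "q": key[1], "macro_auroc": cache[key]})
    table = pd.DataFrame(rows)
    best_score = table["macro_auroc"].max()
    tied = table[table["macro_auroc"] == best_score]
    candidates = sorted((r["p"], r["q"]) for _, r in tied.iterrows())
    if (1.0, 1.0) in candidates:
        best = (1.0, 1.0)
    else:
        best = candidates[0]
    return best, table
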