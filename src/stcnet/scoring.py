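"""Protein scoring and ranking via the single-target-compound read-out.

The trained per-ADR classifiers are applied to STC embeddings: the predicted
probability that a protein's STC "causes" an ADR is read as the relation
score between that protein and the ADR.  Per-ADR rankings over all proteins
(average ranks on ties, percentile = 100 · rank / N) prioritize candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .classify import ADRClassifierBundle
from .embedding import EmbeddingMatrix
from .network import HeteroNetwork


@dataclass
class ScoreMatrix:
    """ADR × protein predicted-probability matrix, the method's output."""

    adr_ids: list[str]
    protein_ids: list[str]
    scores: np.ndarray  # (n_adrs, n_proteins), values in [0, 1]

    def __post_init__(self):
        if self.scores.shape != (len(self.adr_ids), len(self.protein_ids)):
            raise ValueError("score matrix shape disagrees with id lists")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("score matrix contains non-finite entries")
        self._adr_index = {a: i for i, a in enumerate(self.adr_ids)}
        self._protein_index = {p: i for i, p in enumerate(self.protein_ids)}

    def adr_row(self, adr: str) -> np.ndarray:
        if adr not in self._adr_index:
            raise KeyError(f"unknown ADR {adr!r}")
        return self.scores[self._adr_index[adr]]

    def entry(self, adr: str, protein: str) -> float:
        if protein not in self._protein_index:
            raise KeyError(f"unknown protein {protein!r}")
        return float(self.adr_row(adr)[self._protein_index[protein]])

    def to_long_frame(self) -> pd.DataFrame:
        """Long format with ranks: adr_pt, protein, score, rank, percentile —
        sorted by ADR then rank."""
        frames = []
        for adr in self.adr_ids:
            frames.append(rank_proteins(self, adr).table.assign(adr_pt=adr))
        out = pd.concat(frames, ignore_index=True)
        return out[["adr_pt", "protein", "score", "rank", "percentile"]]

    def save(self, path: str | Path) -> None:
        self.to_long_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path: str | Path) -> "ScoreMatrix":
        long = pd.read_csv(path, sep="\t")
        wide = long.pivot(index="adr_pt", columns="protein", values="score")
        return cls(adr_ids=list(wide.index), protein_ids=list(wide.columns),
                   scores=wide.to_numpy())


@dataclass
class RankedList:
    """Descending-score protein ranking for one ADR.

    ``table`` columns: protein, score, rank (ties averaged), percentile
    (= 100 · rank / N).  Rows are ordered by rank, ties by protein id.
    """

    adr_id: str
    table: pd.DataFrame

    def percentile_of(self, protein: str) -> float:
        row = self.table.loc[self.table["protein"] == protein]
        if row.empty:
            raise KeyError(f"protein {protein!r} not in ranking")
        return float(row["percentile"].iloc[0])


def score_proteins(bundle: ADRClassifierBundle, embeddings: EmbeddingMatrix,
                   net: HeteroNetwork) -> ScoreMatrix:
    """Score every protein of the network for every trained ADR.

    Entry (a, p) is the predicted probability of ADR *a*'s classifier on the
    embedding of ``stc_of(p)``.  A protein whose STC has no embedding row
    raises :class:`KeyError` naming the protein.
    """
    proteins = sorted(net.stc_of)
    stc_rows = []
    for p in proteins:
        stc = net.stc_of[p]
        if stc not in embeddings:
            raise KeyError(f"no embedding for the STC of protein {p!r}")
        stc_rows.append(embeddings.vector(stc))
    X = np.vstack(stc_rows)
    probs = bundle.predict_proba_matrix(X)  # (n_proteins, n_adrs)
    return ScoreMatrix(adr_ids=list(bundle.adr_ids), protein_ids=proteins,
                       scores=probs.T.copy())


def rank_proteins(scores: ScoreMatrix, adr: str) -> RankedList:
    """Rank all proteins for one ADR by descending score.

    Ties receive average ranks; percentile = 100 · rank / N so the top
    protein of an N-protein ranking sits at 100/N.
    """
    row = scores.adr_row(adr)
    ranks = rankdata(-row, method="average")
    n = len(row)
    table = pd.DataFrame({
        "protein": scores.protein_ids,
        "score": row,
        "rank": ranks,
        "percentile": 100.0 * ranks / n,
    }).sort_values(["rank", "protein"], kind="mergesort").reset_index(drop=True)
    return RankedList(adr_id=adr, table=table)


def top_k(scores: ScoreMatrix, adr: str, k: int = 50) -> list[str]:
    """The k best-scoring proteins for ``adr``.

    Boundary ties are broken by lexicographic protein id so the selection is
    deterministic.  ``k`` must not exceed the protein count.
    """
    n = len(scores.protein_ids)
    if k > n:
        raise ValueError(f"k={k} exceeds the protein count {n}")
    ranked = rank_proteins(scores, adr)
    return list(ranked.table["protein"].iloc[:k])
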