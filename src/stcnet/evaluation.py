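"""Evaluation statistics for predicted ADR–protein relations.

Central idea: treat "drug targets protein P" as a diagnostic test for the
event "drug has ADR A".  Over the drug universe this yields a 2×2 confusion
matrix per (ADR, protein) pair, from which come

* PPV = TP / (TP + FP) — fraction of P-targeting drugs showing A;
* prevalence = (TP + FN) / N — fraction of all drugs showing A;
* VAPPV = PPV − prevalence — 0 when targeting is independent of the ADR;
* LR (positive likelihood ratio) = sensitivity / (1 − specificity)
  = TP·(FP+TN) / (FP·(TP+FN)) — 1 under independence.

The module also provides benchmark rank recovery, balanced negative-sampling
AUROC/AP over resampled test sets, drug-pair similarity correlation (Jaccard
over ADR sets vs cosine over embeddings), confidence-threshold selection,
and grouped score-vector similarity for arbitrary ADR groupings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import auroc, average_precision
from .network import DrugADRLabels
from .scoring import ScoreMatrix, rank_proteins, top_k

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN/TN drug counts for one (ADR, protein) pair."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class PairMetrics:
    """PPV, prevalence, VAPPV and LR for one (ADR, protein) pair.

    ``ppv`` and ``vappv`` are None when no drug targets the protein (the
    quantities are undefined and must never be imputed as 0).
    ``lr_corrected`` flags the Haldane–Anscombe continuity correction
    (+0.5 on all four cells), applied only when FP = 0 or TP + FN = 0.
    """

    ppv: float | None
    prevalence: float
    vappv: float | None
    lr: float
    lr_corrected: bool = False


def confusion_counts(adr: str, protein: str,
                     drug_targets: Mapping[str, set[str]],
                     labels: DrugADRLabels) -> ConfusionCounts:
    """Count drugs by (targets protein?) × (has ADR?) over ``labels.drugs``.

    ``drug_targets`` maps drug → target-protein set; drugs of the label
    universe missing from the map count as non-targeting.
    """
    has_adr = labels.adr_column(adr)  # raises KeyError on unknown ADR
    tp = fp = fn = tn = 0
    for i, d in enumerate(labels.drugs):
        targets = protein in drug_targets.get(d, ())
        if targets and has_adr[i]:
            tp += 1
        elif targets:
            fp += 1
        elif has_adr[i]:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, fn, tn)


def pair_metrics(c: ConfusionCounts) -> PairMetrics:
    """PPV / prevalence / VAPPV / LR from a confusion matrix.

    LR uses the +0.5 continuity correction on all four cells exactly when a
    denominator cell pattern (FP = 0 or TP + FN = 0) would make it infinite
    or undefined; PPV (and hence VAPPV) is undefined when TP + FP = 0 and is
    returned as None rather than zero.
    """
    n = c.n
    if n <= 0:
        raise ValueError("confusion matrix is empty")
    prevalence = (c.tp + c.fn) / n
    if c.tp + c.fp == 0:
        ppv = vappv = None
    else:
        ppv = c.tp / (c.tp + c.fp)
        vappv = ppv - prevalence
    if c.fp == 0 or c.tp + c.fn == 0:
        tp, fp, fn, tn = (c.tp + 0.5, c.fp + 0.5, c.fn + 0.5, c.tn + 0.5)
        lr = (tp * (fp + tn)) / (fp * (tp + fn))
        corrected = True
    else:
        lr = (c.tp * (c.fp + c.tn)) / (c.fp * (c.tp + c.fn))
        corrected = False
    return PairMetrics(ppv=ppv, prevalence=prevalence, vappv=vappv,
                       lr=float(lr), lr_corrected=corrected)


def pairwise_confusion(labels: DrugADRLabels,
                       drug_targets: Mapping[str, set[str]],
                       protein_ids: Sequence[str] | None = None):
    """Vectorized confusion counts for every (ADR, protein) combination.

    Returns ``(protein_ids, tp, fp, fn, tn)`` where the count arrays have
    shape (n_adrs, n_proteins).  Row/column order follows ``labels.adrs`` and
    ``protein_ids`` (default: sorted union of all target sets).
    """
    if protein_ids is None:
        protein_ids = sorted({p for s in drug_targets.values() for p in s})
    pi = {p: j for j, p in enumerate(protein_ids)}
    T = np.zeros((labels.n_drugs, len(protein_ids)), dtype=np.int64)
    for i, d in enumerate(labels.drugs):
        for p in drug_targets.get(d, ()):
            if p in pi:
                T[i, pi[p]] = 1
    A = labels.matrix.astype(np.int64)
    tp = A.T @ T
    m = T.sum(axis=0)[None, :]
    k = A.sum(axis=0)[:, None]
    fp = m - tp
    fn = k - tp
    tn = labels.n_drugs - tp - fp - fn
    return list(protein_ids), tp, fp, fn, tn


def support_filtered_pair_means(labels: DrugADRLabels,
                                drug_targets: Mapping[str, set[str]],
                                min_support: int = 5) -> dict[str, float]:
    """Mean VAPPV and LR over all (ADR, protein) pairs passing the support
    filter: protein targeted by ≥ ``min_support`` drugs and ADR carried by
    ≥ ``min_support`` drugs.

    The workhorse behind the null-world baselines (VAPPV → 0, LR → 1 under
    independence).  Computation is vectorized but definitionally identical to
    :func:`confusion_counts` + :func:`pair_metrics` per pair; undefined PPVs
    cannot occur here because the protein margin is positive.
    """
    protein_ids, tp, fp, fn, tn = pairwise_confusion(labels, drug_targets)
    n = labels.n_drugs
    m = (tp + fp)[0] if tp.size else np.zeros(0)  # per-protein margin
    k = (tp + fn)[:, 0] if tp.size else np.zeros(0)  # per-ADR margin
    keep = (m[None, :] >= min_support) & (k[:, None] >= min_support)
    if not keep.any():
        raise ValueError("no (ADR, protein) pair passes the support filter")
    tp_f = tp[keep].astype(float)
    fp_f = fp[keep].astype(float)
    fn_f = fn[keep].astype(float)
    tn_f = tn[keep].astype(float)
    ppv = tp_f / (tp_f + fp_f)
    vappv = ppv - (tp_f + fn_f) / n
    need_corr = (fp_f == 0) | (tp_f + fn_f == 0)
    tp_c = np.where(need_corr, tp_f + 0.5, tp_f)
    fp_c = np.where(need_corr, fp_f + 0.5, fp_f)
    fn_c = np.where(need_corr, fn_f + 0.5, fn_f)
    tn_c = np.where(need_corr, tn_f + 0.5, tn_f)
    lr = (tp_c * (fp_c + tn_c)) / (fp_c * (tp_c + fn_c))
    return {"mean_vappv": float(vappv.mean()), "mean_lr": float(lr.mean()),
            "n_pairs": int(keep.sum()),
            "n_corrected": int(need_corr.sum())}


def evaluate_top_k(scores: ScoreMatrix,
                   drug_targets: Mapping[str, set[str]],
                   labels: DrugADRLabels,
                   k: int = 50, min_support: int = 5) -> dict:
    """VAPPV / LR of each ADR's top-k predicted proteins, support-filtered.

    For each ADR the top-k proteins by relation score are taken; pairs whose
    protein is targeted by fewer than ``min_support`` drugs, or whose ADR is
    carried by fewer than ``min_support`` drugs, are dropped, as are pairs
    with undefined PPV.  Returns per-ADR mean VAPPV/LR (ADRs with no
    surviving pair are listed under ``"missing"``, never reported as zero)
    plus overall means pooled over all surviving pairs.
    """
    per_adr_rows = []
    missing = []
    pooled_vappv: list[float] = []
    pooled_lr: list[float] = []
    n_undefined = 0
    adr_support = {a: int(s) for a, s in
                   labels.positives_per_adr().items()}
    protein_support: dict[str, int] = {}
    for d in labels.drugs:
        for p in drug_targets.get(d, ()):
            protein_support[p] = protein_support.get(p, 0) + 1
    for adr in scores.adr_ids:
        if adr not in labels._adr_index:
            missing.append(adr)
            continue
        if adr_support.get(adr, 0) < min_support:
            missing.append(adr)
            continue
        vappvs, lrs = [], []
        for p in top_k(scores, adr, k=k):
            if protein_support.get(p, 0) < min_support:
                continue
            m = pair_metrics(confusion_counts(adr, p, drug_targets, labels))
            if m.vappv is None:
                n_undefined += 1
                continue
            vappvs.append(m.vappv)
            lrs.append(m.lr)
        if not vappvs:
            missing.append(adr)
            continue
        per_adr_rows.append({"adr_pt": adr, "n_pairs": len(vappvs),
                             "mean_vappv": float(np.mean(vappvs)),
                             "mean_lr": float(np.mean(lrs))})
        pooled_vappv.extend(vappvs)
        pooled_lr.extend(lrs)
    per_adr = pd.DataFrame(per_adr_rows,
                           columns=["adr_pt", "n_pairs", "mean_vappv",
                                    "mean_lr"])
    return {
        "per_adr": per_adr,
        "missing": missing,
        "n_undefined_ppv": n_undefined,
        "overall_mean_vappv": (float(np.mean(pooled_vappv))
                               if pooled_vappv else None),
        "overall_mean_lr": (float(np.mean(pooled_lr))
                            if pooled_lr else None),
        "n_pairs": len(pooled_vappv),
    }


def benchmark_recovery(scores: ScoreMatrix,
                       bench: Sequence[tuple[str, str]]) -> dict:
    """Percentile ranks of known (ADR, protein) pairs in the score matrix.

    Each mappable pair gets the percentile of its protein in its ADR's
    ranking; summary fractions report how many land in the top 5% and top
    20%.  Pairs whose ADR or protein is absent from the matrix are counted
    as unmapped, not silently dropped.
    """
    rows = []
    unmapped = 0
    rank_cache: dict[str, object] = {}
    adr_set = set(scores.adr_ids)
    prot_set = set(scores.protein_ids)
    for adr, protein in bench:
        if adr not in adr_set or protein not in prot_set:
            unmapped += 1
            continue
        if adr not in rank_cache:
            rank_cache[adr] = rank_proteins(scores, adr)
        pct = rank_cache[adr].percentile_of(protein)
        rows.append({"adr_pt": adr, "protein": protein, "percentile": pct,
                     "bin": int(min(pct // 5, 19))})
    if not rows:
        raise ValueError("no benchmark pair is mappable to the score matrix")
    table = pd.DataFrame(rows)
    hist = (table["bin"].value_counts().reindex(range(20), fill_value=0)
            .sort_index())
    return {
        "pairs": table,
        "histogram": hist,
        "frac_top5": float((table["percentile"] <= 5.0).mean()),
        "frac_top20": float((table["percentile"] <= 20.0).mean()),
        "n_mapped": len(table),
        "n_unmapped": unmapped,
    }


def balanced_benchmark_eval(scores: ScoreMatrix,
                            bench: Sequence[tuple[str, str]],
                            n_resamples: int = 1000,
                            seed: int = 0) -> dict:
    """Balanced-test AUROC/AP distributions under repeated negative sampling.

    Positives are the mappable benchmark pairs.  The negative pool is every
    other (ADR, protein) combination over the benchmark's own ADRs and
    proteins (restricted to those present in the score matrix); each of the
    ``n_resamples`` iterations samples as many negatives as there are
    positives and scores the balanced set.
    """
    adr_set = set(scores.adr_ids)
    prot_set = set(scores.protein_ids)
    pos = sorted({(a, p) for a, p in bench if a in adr_set and p in prot_set})
    if not pos:
        raise ValueError("no benchmark pair is mappable to the score matrix")
    bench_adrs = sorted({a for a, _ in pos})
    bench_prots = sorted({p for _, p in pos})
    pos_set = set(pos)
    pool = [(a, p) for a in bench_adrs for p in bench_prots
            if (a, p) not in pos_set]
    if len(pool) < len(pos):
        raise ValueError(
            f"negative pool ({len(pool)}) smaller than the positive set "
            f"({len(pos)})")
    pos_scores = np.array([scores.entry(a, p) for a, p in pos])
    pool_scores = np.array([scores.entry(a, p) for a, p in pool])
    rng = np.random.default_rng(seed)
    aurocs = np.empty(n_resamples)
    aps = np.empty(n_resamples)
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(pos))])
    for r in range(n_resamples):
        neg_idx = rng.choice(len(pool), size=len(pos), replace=False)
        s = np.concatenate([pos_scores, pool_scores[neg_idx]])
        aurocs[r] = auroc(s, y)
        aps[r] = average_precision(s, y)
    return {"auroc": aurocs, "ap": aps,
            "mean_auroc": float(aurocs.mean()), "mean_ap": float(aps.mean()),
            "n_positives": len(pos), "n_negative_pool": len(pool)}


def jaccard(a: set, b: set) -> float:
    """|a ∩ b| / |a ∪ b|; undefined (ValueError) when both sets are empty."""
    union = len(a | b)
    if union == 0:
        raise ValueError("Jaccard undefined for two empty sets")
    return len(a & b) / union


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity; undefined (ValueError) for a zero vector."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine undefined for a zero vector")
    return float(u @ v / (nu * nv))


def drug_similarity_correlation(drug_embeddings: np.ndarray,
                                drug_ids: Sequence[str],
                                labels: DrugADRLabels,
                                n_bins: int = 10) -> dict:
    """ADR-set Jaccard vs embedding cosine over all drug pairs.

    ``drug_embeddings`` rows must align with ``drug_ids``; only drugs present
    in ``labels`` are used.  Returns the pair table, boxplot-ready per-bin
    summaries of cosine similarity binned by Jaccard similarity, and the
    Spearman rank correlation.
    """
    keep = [i for i, d in enumerate(drug_ids) if d in labels._drug_index]
    if len(keep) < 2:
        raise ValueError("need at least two drugs with labels")
    X = np.asarray(drug_embeddings, float)[keep]
    rows = [labels.drug_index(drug_ids[i]) for i in keep]
    A = labels.matrix[rows].astype(np.int64)

    inter = A @ A.T
    sizes = A.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore"):
        jac = np.where(union > 0, inter / np.maximum(union, 1), np.nan)

    norms = np.linalg.norm(X, axis=1, keepdims=True)
    Xn = X / np.where(norms > 0, norms, 1.0)
    cos = Xn @ Xn.T

    iu, ju = np.triu_indices(len(keep), k=1)
    pair_jac = jac[iu, ju]
    pair_cos = cos[iu, ju]
    ok = np.isfinite(pair_jac)
    pair_jac, pair_cos = pair_jac[ok], pair_cos[ok]

    rho, pval = stats.spearmanr(pair_jac, pair_cos)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(pair_jac, edges[1:-1]), 0, n_bins - 1)
    summaries = []
    for b in range(n_bins):
        sel = pair_cos[which == b]
        if len(sel) == 0:
            continue
        summaries.append({
            "bin_lo": edges[b], "bin_hi": edges[b + 1], "n": int(len(sel)),
            "median": float(np.median(sel)),
            "q1": float(np.percentile(sel, 25)),
            "q3": float(np.percentile(sel, 75)),
        })
    return {"pairs": pd.DataFrame({"jaccard": pair_jac, "cosine": pair_cos}),
            "bins": pd.DataFrame(summaries),
            "spearman": float(rho), "spearman_p": float(pval)}


def select_confidence_threshold(drug_target_records,
                                labels: DrugADRLabels,
                                thresholds: Sequence[int]) -> tuple[int, pd.DataFrame]:
    """Pick the confidence cutoff maximizing the Pearson correlation between
    ADR similarity and target similarity of drug pairs.

    For each threshold the drug–target records are filtered, per-drug target
    sets formed, and Jaccard(ADR sets) correlated with Jaccard(target sets)
    over all pairs of drugs that retain at least one target.  Thresholds
    leaving fewer than two such drugs (or degenerate similarity vectors) are
    reported as undefined (NaN).  Ties go to the smallest threshold.
    """
    if len(thresholds) < 2:
        if len(thresholds) == 1:
            t = int(thresholds[0])
            return t, pd.DataFrame([{"threshold": t, "pearson": np.nan,
                                     "n_drugs": np.nan}])
        raise ValueError("need at least one threshold")
    rows = []
    for thr in thresholds:
        sets: dict[str, set[str]] = {}
        for rec in drug_target_records:
            if rec.score >= thr and rec.source_id in labels._drug_index:
                sets.setdefault(rec.source_id, set()).add(rec.target_id)
        drugs = sorted(sets)
        if len(drugs) < 2:
            rows.append({"threshold": int(thr), "pearson": np.nan,
                         "n_drugs": len(drugs)})
            continue
        adr_sets = {d: set(labels.adr_set(d)) for d in drugs}
        xs, ys = [], []
        for i in range(len(drugs)):
            for j in range(i + 1, len(drugs)):
                di, dj = drugs[i], drugs[j]
                xs.append(jaccard(adr_sets[di], adr_sets[dj]))
                ys.append(jaccard(sets[di], sets[dj]))
        xs = np.array(xs)
        ys = np.array(ys)
        if xs.std() == 0 or ys.std() == 0:
            rows.append({"threshold": int(thr), "pearson": np.nan,
                         "n_drugs": len(drugs)})
            continue
        r, _ = stats.pearsonr(xs, ys)
        rows.append({"threshold": int(thr), "pearson": float(r),
                     "n_drugs": len(drugs)})
    table = pd.DataFrame(rows)
    defined = table.dropna(subset=["pearson"])
    if defined.empty:
        raise ValueError("no threshold yields a defined correlation")
    best_val = defined["pearson"].max()
    best = int(defined.loc[defined["pearson"] == best_val, "threshold"].min())
    return best, table


def grouped_score_similarity(scores: ScoreMatrix,
                             grouping: Mapping[str, set[str]]) -> pd.DataFrame:
    """Within-group cosine similarity of ADR score vectors vs baseline.

    ``grouping`` maps each ADR to the set of category labels it carries
    (e.g. disease-class terms).  For every label, the mean cosine similarity
    over ADR pairs sharing that label is compared to the baseline — the mean
    over ADR pairs sharing *no* label — with a Welch two-sample t-test;
    Benjamini–Hochberg-adjusted p-values are reported alongside the raw ones
    because many labels are tested at once.
    """
    adrs = [a for a in scores.adr_ids]
    n = len(adrs)
    norms = np.linalg.norm(scores.scores, axis=1, keepdims=True)
    Xn = scores.scores / np.where(norms > 0, norms, 1.0)
    cos = Xn @ Xn.T

    label_sets = {a: frozenset(grouping.get(a, ())) for a in adrs}
    all_labels = sorted({lab for s in label_sets.values() for lab in s})

    baseline_vals = []
    shared_vals: dict[str, list[float]] = {lab: [] for lab in all_labels}
    for i in range(n):
        for j in range(i + 1, n):
            shared = label_sets[adrs[i]] & label_sets[adrs[j]]
            c = cos[i, j]
            if shared:
                for lab in shared:
                    shared_vals[lab].append(c)
            else:
                baseline_vals.append(c)
    if not baseline_vals:
        raise ValueError("baseline pool empty: every ADR pair shares a label")
    baseline = np.array(baseline_vals)

    rows = []
    for lab in all_labels:
        vals = np.array(shared_vals[lab])
        if len(vals) < 2:
            continue
        t, p = stats.ttest_ind(vals, baseline, equal_var=False)
        rows.append({"label": lab, "n_pairs": len(vals),
                     "mean_cosine": float(vals.mean()),
                     "baseline_mean": float(baseline.mean()),
                     "t": float(t), "p": float(p)})
    if not rows:
        raise ValueError("no label has at least two ADR pairs")
    table = pd.DataFrame(rows)
    from statsmodels.stats.multitest import multipletests
    table["p_bh"] = multipletests(table["p"], method="fdr_bh")[1]
    return table
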