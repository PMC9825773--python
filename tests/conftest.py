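"""Shared fixtures: toy graphs and a small planted synthetic world.

The "quick" world is deliberately small (60 proteins in 4 modules, 40 drugs,
8 ADRs) so the full embed → classify → score path can run once per session
and be reused by many tests.
"""

import numpy as np
import pytest

import stcnet as sn


def make_undirected_network(edges):
    """Protein-only network with symmetric edges (no drugs/STCs)."""
    out = {}
    for a, b in edges:
        out.setdefault(a, set()).add(b)
        out.setdefault(b, set()).add(a)
    return sn.HeteroNetwork(
        roles={n: "protein" for n in out},
        out={n: tuple(sorted(v)) for n, v in out.items()},
        stc_of={},
    )


def records_of(df):
    """World table → InteractionRecord list."""
    return [sn.InteractionRecord(a, b, int(s))
            for a, b, s in df.itertuples(index=False)]


def labels_of(world):
    return sn.DrugADRLabels(list(zip(world.drug_adr_table["drug"],
                                     world.drug_adr_table["adr_pt"])))


def auroc_oracle(scores, labels):
    """Brute-force pairwise enumeration with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def ap_oracle(scores, labels):
    """Explicit precision–recall step sum over descending distinct
    thresholds."""
    n_pos = sum(labels)
    ap = 0.0
    prev_recall = 0.0
    for t in sorted(set(scores), reverse=True):
        flagged = [l for s, l in zip(scores, labels) if s >= t]
        tp = sum(flagged)
        precision = tp / len(flagged)
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def pair_metrics_oracle(tp, fp, fn, tn):
    """Spreadsheet-style recomputation of PPV/prevalence/VAPPV/LR in exact
    rational arithmetic, including the +0.5 correction rule."""
    from fractions import Fraction as F
    n = tp + fp + fn + tn
    prevalence = F(tp + fn, n)
    if tp + fp == 0:
        ppv = vappv = None
    else:
        ppv = F(tp, tp + fp)
        vappv = ppv - prevalence
    if fp == 0 or tp + fn == 0:
        tpc, fpc, fnc, tnc = (F(2 * tp + 1, 2), F(2 * fp + 1, 2),
                              F(2 * fn + 1, 2), F(2 * tn + 1, 2))
        lr = (tpc * (fpc + tnc)) / (fpc * (tpc + fnc))
    else:
        lr = F(tp * (fp + tn), fp * (tp + fn))
    return ppv, prevalence, vappv, lr


@pytest.fixture(scope="session")
def toy_bias_net():
    """Square with a chord: {t–v, v–x1, v–x2, t–x1}, the hand-worked
    second-order bias example."""
    return make_undirected_network(
        [("t", "v"), ("v", "x1"), ("v", "x2"), ("t", "x1")])


@pytest.fixture(scope="session")
def quick_world():
    cfg = sn.SyntheticWorldConfig(
        n_proteins=60, n_modules=4, n_drugs=40, n_adrs=8,
        p_in=0.4, p_out=0.02, n_targets_per_drug=6, focus_prob=0.7,
        theta_hi=0.8, theta_lo=0.05, seed=7)
    return sn.generate_world(cfg)


@pytest.fixture(scope="session")
def quick_labels(quick_world):
    return labels_of(quick_world)


@pytest.fixture(scope="session")
def quick_net(quick_world, quick_labels):
    return sn.build_network(records_of(quick_world.ppi_table),
                            records_of(quick_world.drug_target_table),
                            quick_labels)


@pytest.fixture(scope="session")
def quick_fit(quick_net, quick_labels):
    """Fitted embedding, classifier bundle and score matrix on the quick
    world."""
    est = sn.Node2VecEmbedding(dimensions=32, num_walks=5, walk_length=20,
                               seed=1)
    est.fit(quick_net)
    bundle = sn.train_adr_classifiers(est.embedding_, quick_labels)
    scores = sn.score_proteins(bundle, est.embedding_, quick_net)
    return {"embedder": est, "embeddings": est.embedding_,
            "bundle": bundle, "scores": scores}
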