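"""Interaction-table I/O and integrated drug–protein–STC network construction.

The integrated network is a directed, unweighted heterogeneous graph with three
node roles:

``drug``
    A compound with at least one recorded adverse drug reaction (ADR) and at
    least one target protein in the PPI network.  Drug → protein edges only;
    drugs have in-degree 0.
``protein``
    A node of the protein–protein interaction (PPI) network.  Each undirected
    PPI pair contributes two directed edges (one per direction).
``stc``
    A fictitious *single-target compound*, one per protein, with exactly one
    outgoing edge to its protein and no incoming edges.  Classifier output on
    an STC's embedding is interpreted as its protein's ADR-relation score.

Interaction tables follow the STRING / STITCH / SIDER tab-separated dialects:
confidence scores are integers on 0–1000 and records below a confidence
threshold (default 700, the databases' "high confidence" convention, applied
inclusively) are discarded on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Reserved identifier prefix for single-target-compound nodes.  Input tables
#: must not use it, which keeps the STC namespace disjoint from real nodes.
STC_PREFIX = "STC::"

#: Default confidence-score cutoff (inclusive), the STRING/STITCH
#: "high confidence" convention.
DEFAULT_THRESHOLD = 700


@dataclass(frozen=True)
class InteractionRecord:
    """One scored pairwise interaction (PPI or chemical–protein).

    Attributes
    ----------
    source_id, target_id : str
        Interactor identifiers.  For chemical–protein records the source is
        the chemical.
    score : int
        Combined confidence score in [0, 1000].
    """

    source_id: str
    target_id: str
    score: int

    def unordered_key(self) -> tuple[str, str]:
        a, b = self.source_id, self.target_id
        return (a, b) if a <= b else (b, a)


class DrugADRLabels:
    """Binary drug × ADR relation matrix (SIDER-style training labels).

    Every drug row has at least one positive entry and every ADR column has at
    least one positive entry; rows/columns that would be empty are dropped at
    construction (a drug with no ADR cannot be a training example, and an ADR
    with no drug cannot be a label).

    Parameters
    ----------
    pairs : iterable of (drug, adr)
        Positive drug–ADR relations; duplicates are collapsed.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        uniq = sorted(set(pairs))
        if not uniq:
            raise ValueError("DrugADRLabels requires at least one (drug, adr) pair")
        self.drugs: list[str] = sorted({d for d, _ in uniq})
        self.adrs: list[str] = sorted({a for _, a in uniq})
        di = {d: i for i, d in enumerate(self.drugs)}
        ai = {a: i for i, a in enumerate(self.adrs)}
        mat = np.zeros((len(self.drugs), len(self.adrs)), dtype=bool)
        for d, a in uniq:
            mat[di[d], ai[a]] = True
        self.matrix: np.ndarray = mat
        self._drug_index = di
        self._adr_index = ai

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"DrugADRLabels({len(self.drugs)} drugs × {len(self.adrs)} ADRs, "
                f"{int(self.matrix.sum())} positives)")

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    @property
    def n_adrs(self) -> int:
        return len(self.adrs)

    def drug_index(self, drug: str) -> int:
        return self._drug_index[drug]

    def adr_index(self, adr: str) -> int:
        return self._adr_index[adr]

    def adr_column(self, adr: str) -> np.ndarray:
        """Binary label vector over ``self.drugs`` for one ADR."""
        return self.matrix[:, self._adr_index[adr]]

    def adr_set(self, drug: str) -> frozenset[str]:
        row = self.matrix[self._drug_index[drug]]
        return frozenset(np.array(self.adrs)[row])

    def positives_per_adr(self) -> pd.Series:
        return pd.Series(self.matrix.sum(axis=0), index=self.adrs, name="n_drugs")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.drugs, columns=self.adrs)


@dataclass
class HeteroNetwork:
    """Typed directed graph of drug, protein and STC nodes.

    Attributes
    ----------
    roles : dict
        node id → role, one of ``{"drug", "protein", "stc"}``.
    out : dict
        node id → sorted tuple of out-neighbor ids.  Nodes without out-edges
        (proteins can only point at proteins) map to an empty tuple.
    stc_of : dict
        protein id → its STC node id (a bijection).
    """

    roles: dict[str, str]
    out: dict[str, tuple[str, ...]]
    stc_of: dict[str, str]
    _indexed: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def n_edges(self) -> int:
        return sum(len(v) for v in self.out.values())

    def nodes_with_role(self, role: str) -> list[str]:
        return sorted(n for n, r in self.roles.items() if r == role)

    def out_neighbors(self, node: str) -> tuple[str, ...]:
        return self.out.get(node, ())

    def has_edge(self, u: str, v: str) -> bool:
        return v in self.out.get(u, ())

    def indexed(self):
        """CSR view ``(node_ids, index_of, indptr, indices)`` for walk kernels.

        Node order is sorted identifier order; neighbor lists are sorted by
        index so membership can be tested by binary search.
        """
        if self._indexed is None:
            node_ids = sorted(self.roles)
            index_of = {n: i for i, n in enumerate(node_ids)}
            indptr = np.zeros(len(node_ids) + 1, dtype=np.int64)
            for i, n in enumerate(node_ids):
                indptr[i + 1] = indptr[i] + len(self.out.get(n, ()))
            indices = np.empty(indptr[-1], dtype=np.int64)
            for i, n in enumerate(node_ids):
                nbr = sorted(index_of[v] for v in self.out.get(n, ()))
                indices[indptr[i]:indptr[i + 1]] = nbr
            self._indexed = (node_ids, index_of, indptr, indices)
        return self._indexed


def _iter_data_rows(path: str | Path, n_fields: int):
    """Yield ``(lineno, fields)`` for data rows of a headered TSV.

    Lines starting with ``#`` and blank lines are ignored; the first remaining
    line is the header.  Malformed rows raise :class:`ValueError` naming the
    1-based line number (the reason the reader walks lines itself rather than
    delegating to a bulk CSV parser).
    """
    path = Path(path)
    header_seen = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("#"):
                continue
            if not header_seen:
                header_seen = True
                continue
            fields = line.split("\t")
            if len(fields) != n_fields:
                raise ValueError(
                    f"{path}: line {lineno}: expected {n_fields} tab-separated "
                    f"fields, got {len(fields)}")
            yield lineno, fields


def read_interactions(path: str | Path,
                      threshold: int = DEFAULT_THRESHOLD) -> list[InteractionRecord]:
    """Read a scored interaction TSV, filter by confidence, and deduplicate.

    Parameters
    ----------
    path : path
        Three-column TSV (``id_a  id_b  combined_score``), header row
        required, ``#`` lines ignored — the STRING protein-links / STITCH
        dialect.
    threshold : int
        Inclusive confidence cutoff; records with ``score >= threshold`` are
        kept.

    Returns
    -------
    list of InteractionRecord
        Self-loops dropped; duplicate unordered pairs collapsed keeping the
        maximum score (symmetric listings are the only expected duplicate
        source).  Ordering follows first appearance in the file.

    Raises
    ------
    ValueError
        On malformed rows, non-integer scores, or scores outside [0, 1000]
        (the error names the offending line).
    """
    best: dict[tuple[str, str], InteractionRecord] = {}
    for lineno, (a, b, s) in _iter_data_rows(path, 3):
        try:
            score = int(s)
        except ValueError:
            raise ValueError(
                f"{path}: line {lineno}: non-integer score {s!r}") from None
        if not 0 <= score <= 1000:
            raise ValueError(
                f"{path}: line {lineno}: score {score} outside [0, 1000]")
        if a == b:
            continue
        if score < threshold:
            continue
        rec = InteractionRecord(a, b, score)
        key = rec.unordered_key()
        prev = best.get(key)
        if prev is None or score > prev.score:
            best[key] = rec
    return list(best.values())


def read_drug_adr(path: str | Path) -> DrugADRLabels:
    """Read a two-column ``drug  adr_pt`` TSV into :class:`DrugADRLabels`."""
    pairs = [(d, a) for _, (d, a) in _iter_data_rows(path, 2)]
    return DrugADRLabels(pairs)


def read_benchmark(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column ``adr_pt  protein`` benchmark TSV as unique pairs."""
    return sorted({(a, p) for _, (a, p) in _iter_data_rows(path, 2)})


def build_network(ppi: Sequence[InteractionRecord],
                  drug_target: Sequence[InteractionRecord],
                  labels: DrugADRLabels,
                  stc_prefix: str = STC_PREFIX) -> HeteroNetwork:
    """Assemble the integrated directed network of drugs, proteins and STCs.

    The protein set is exactly the node set of the filtered PPI graph.
    Drug–target records are kept only when the drug has at least one ADR in
    ``labels`` and the protein is present in the PPI graph; each surviving
    pair becomes one drug → protein edge.  Each PPI pair becomes two directed
    edges.  One STC node per protein is added with a single STC → protein
    edge, so the directed edge count equals ``D + 2·P + S`` with D kept
    drug–target pairs, P kept PPI pairs and S proteins.

    Raises
    ------
    ValueError
        If no PPI records are given or no drug survives filtering.
    """
    if not ppi:
        raise ValueError("PPI record list is empty; cannot build a network")

    proteins: set[str] = set()
    ppi_pairs: set[tuple[str, str]] = set()
    for rec in ppi:
        proteins.add(rec.source_id)
        proteins.add(rec.target_id)
        ppi_pairs.add(rec.unordered_key())

    label_drugs = set(labels.drugs)
    kept_pairs: set[tuple[str, str]] = set()
    n_drop_drug = n_drop_protein = 0
    for rec in drug_target:
        if rec.source_id not in label_drugs:
            n_drop_drug += 1
            continue
        if rec.target_id not in proteins:
            n_drop_protein += 1
            continue
        kept_pairs.add((rec.source_id, rec.target_id))
    if n_drop_drug or n_drop_protein:
        logger.info(
            "build_network: dropped %d drug–target records (drug without ADR) "
            "and %d (protein absent from PPI)", n_drop_drug, n_drop_protein)

    drugs = sorted({d for d, _ in kept_pairs})
    if not drugs:
        raise ValueError("no trainable drugs: every drug–target record was "
                         "filtered out (no overlap between target and ADR tables)")

    for node in proteins | set(drugs):
        if node.startswith(stc_prefix):
            raise ValueError(f"input identifier {node!r} collides with the "
                             f"reserved STC prefix {stc_prefix!r}")

    roles: dict[str, str] = {}
    out: dict[str, set[str]] = {}
    for p in proteins:
        roles[p] = "protein"
        out[p] = set()
    for d in drugs:
        roles[d] = "drug"
        out[d] = set()
    for a, b in ppi_pairs:
        out[a].add(b)
        out[b].add(a)
    for d, p in kept_pairs:
        out[d].add(p)
    stc_of: dict[str, str] = {}
    for p in sorted(proteins):
        stc = stc_prefix + p
        stc_of[p] = stc
        roles[stc] = "stc"
        out[stc] = {p}

    return HeteroNetwork(
        roles=roles,
        out={n: tuple(sorted(v)) for n, v in out.items()},
        stc_of=stc_of,
    )


def network_stats(net: HeteroNetwork) -> dict[str, int]:
    """Summary counts of a network plus the edge-count identity check.

    Returns ``{"drugs", "proteins", "stcs", "edges"}``; raises
    :class:`AssertionError` if the ``D + 2·P + S`` identity is violated,
    which would indicate a construction bug.
    """
    n_drugs = sum(1 for r in net.roles.values() if r == "drug")
    n_prot = sum(1 for r in net.roles.values() if r == "protein")
    n_stc = sum(1 for r in net.roles.values() if r == "stc")
    n_edges = net.n_edges
    d_edges = sum(len(net.out[n]) for n, r in net.roles.items() if r == "drug")
    ppi_directed = sum(
        len(net.out[n]) for n, r in net.roles.items() if r == "protein")
    assert n_edges == d_edges + ppi_directed + n_stc, \
        "edge-count identity D + 2P + S violated"
    return {"drugs": n_drugs, "proteins": n_prot, "stcs": n_stc,
            "edges": n_edges}


def drug_target_sets(records: Sequence[InteractionRecord],
                     drugs: Iterable[str] | None = None) -> dict[str, set[str]]:
    """Per-drug target-protein sets from chemical–protein records.

    ``drugs`` optionally restricts (and completes, with empty sets) the drug
    universe — used when the confusion-matrix evaluation needs a set for
    every labeled drug including non-targeting ones.
    """
    sets: dict[str, set[str]] = {}
    if drugs is not None:
        sets = {d: set() for d in drugs}
    for rec in records:
        if drugs is not None and rec.source_id not in sets:
            continue
        sets.setdefault(rec.source_id, set()).add(rec.target_id)
    return sets
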