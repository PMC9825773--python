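"""Synthetic drug–protein–ADR worlds with planted causal modules.

The generator emits the same three input tables the pipeline reads (STRING-,
STITCH- and SIDER-style TSVs) plus a ground-truth benchmark of (ADR, protein)
pairs, so the full pipeline is testable without any database download.

World model
-----------
* Proteins are partitioned into ``n_modules`` equal blocks (remainder in the
  last block) and wired by a stochastic block model: within-module edge
  probability ``p_in``, between-module ``p_out``.
* Each ADR is assigned one *causal module*, round-robin over modules.
* Each drug draws ``n_targets_per_drug`` target proteins without replacement —
  from one random module with probability ``focus_prob`` (module-focused
  drugs), otherwise uniformly from all proteins.  If the focal module is
  smaller than the target count the remainder is drawn uniformly outside it.
* Drug *d* acquires ADR *a* with probability ``theta_hi`` when *d* targets at
  least one protein of *a*'s causal module ("exposed"), else ``theta_lo``.
  Setting ``theta_hi == theta_lo`` yields a *null world* in which targets and
  ADRs are independent — the configuration under which the value-added PPV
  baseline is 0 and the positive-likelihood-ratio baseline is 1.

Confidence scores are drawn uniformly on ``[score_threshold, 1000]`` so the
default read-time filter is exercised but lossless; ``low_score_fraction``
optionally adds that fraction of sub-threshold decoy records (non-edges for
PPI, non-target pairs for drug–target) to test the filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .network import DEFAULT_THRESHOLD


@dataclass(frozen=True)
class SyntheticWorldConfig:
    """Parameters of a synthetic world.  Defaults are the planted-module
    study conditions used throughout the package's own evaluation."""

    n_proteins: int = 300
    n_modules: int = 10
    n_drugs: int = 120
    n_adrs: int = 20
    p_in: float = 0.3
    p_out: float = 0.01
    n_targets_per_drug: int = 15
    focus_prob: float = 0.7
    theta_hi: float = 0.8
    theta_lo: float = 0.05
    seed: int = 0
    score_threshold: int = DEFAULT_THRESHOLD
    low_score_fraction: float = 0.0

    def validate(self) -> None:
        if not (self.n_proteins >= self.n_modules >= 1):
            raise ValueError("need n_proteins >= n_modules >= 1")
        for name in ("p_in", "p_out", "focus_prob", "theta_hi", "theta_lo",
                     "low_score_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.theta_hi < self.theta_lo:
            raise ValueError("theta_hi must be >= theta_lo")
        if self.n_drugs < 1 or self.n_adrs < 1:
            raise ValueError("need at least one drug and one ADR")
        if not 1 <= self.n_targets_per_drug <= self.n_proteins:
            raise ValueError("n_targets_per_drug must be in [1, n_proteins]")
        if not 0 <= self.score_threshold <= 1000:
            raise ValueError("score_threshold outside [0, 1000]")
        # expected PPI degree must be positive or proteins would be isolated
        if self.p_in == 0.0 and self.p_out == 0.0:
            raise ValueError("p_in and p_out cannot both be 0: expected PPI "
                             "degree would be 0")
        if self.p_in <= self.p_out and self.theta_hi > self.theta_lo:
            raise ValueError("planted worlds require p_in > p_out")


@dataclass
class SyntheticWorld:
    """Generated tables plus the planted ground truth.

    ``truth`` holds every (ADR, causal-module protein) pair; ``module_of``
    maps proteins to module indices and ``adr_module`` maps each ADR to its
    causal module.
    """

    config: SyntheticWorldConfig
    ppi_table: pd.DataFrame            # protein_a, protein_b, combined_score
    drug_target_table: pd.DataFrame    # chemical, protein, combined_score
    drug_adr_table: pd.DataFrame       # drug, adr_pt
    truth: set[tuple[str, str]] = field(default_factory=set)
    module_of: dict[str, int] = field(default_factory=dict)
    adr_module: dict[str, int] = field(default_factory=dict)

    def drug_targets(self) -> dict[str, set[str]]:
        sets: dict[str, set[str]] = {}
        for d, p in zip(self.drug_target_table["chemical"],
                        self.drug_target_table["protein"]):
            sets.setdefault(d, set()).add(p)
        return sets

    def exposed(self, drug: str, adr: str) -> bool:
        """Whether ``drug`` targets at least one protein of ``adr``'s causal
        module (ignoring decoy sub-threshold records)."""
        mod = self.adr_module[adr]
        thr = self.config.score_threshold
        tab = self.drug_target_table
        rows = tab[(tab["chemical"] == drug) & (tab["combined_score"] >= thr)]
        return any(self.module_of[p] == mod for p in rows["protein"])


def _module_assignment(n_proteins: int, n_modules: int) -> np.ndarray:
    """Equal-size blocks; the remainder goes to the last block."""
    size = n_proteins // n_modules
    mods = np.repeat(np.arange(n_modules), size)
    if len(mods) < n_proteins:
        mods = np.concatenate(
            [mods, np.full(n_proteins - len(mods), n_modules - 1)])
    return mods


def generate_world(config: SyntheticWorldConfig) -> SyntheticWorld:
    """Draw a fully reproducible synthetic world from ``config.seed``.

    See the module docstring for the generative model.  All emitted
    confidence scores are at or above ``config.score_threshold`` (decoy
    records excepted), so reading the tables back with the default filter is
    lossless.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m = config.n_proteins, config.n_modules

    proteins = [f"P{i:04d}" for i in range(n)]
    drugs = [f"D{i:04d}" for i in range(config.n_drugs)]
    adrs = [f"ADR{i:03d}" for i in range(config.n_adrs)]
    mods = _module_assignment(n, m)
    module_of = {proteins[i]: int(mods[i]) for i in range(n)}

    # --- PPI edges: stochastic block model over the upper triangle
    same = mods[:, None] == mods[None, :]
    prob = np.where(same, config.p_in, config.p_out)
    draw = rng.random((n, n))
    iu, ju = np.triu_indices(n, k=1)
    edge_mask = draw[iu, ju] < prob[iu, ju]
    ei, ej = iu[edge_mask], ju[edge_mask]

    # reconnect isolated proteins (possible at small p) to a same-module
    # partner so every protein appears in the PPI table
    deg = np.bincount(np.concatenate([ei, ej]), minlength=n)
    extra_i, extra_j = [], []
    for v in np.flatnonzero(deg == 0):
        pool = np.flatnonzero((mods == mods[v]) if (mods == mods[v]).sum() > 1
                              else np.ones(n, bool))
        pool = pool[pool != v]
        u = int(rng.choice(pool))
        extra_i.append(min(u, v))
        extra_j.append(max(u, v))
        deg[v] += 1
        deg[u] += 1
    if extra_i:
        ei = np.concatenate([ei, np.array(extra_i)])
        ej = np.concatenate([ej, np.array(extra_j)])

    ppi_scores = rng.integers(config.score_threshold, 1001, size=len(ei))
    ppi = pd.DataFrame({
        "protein_a": [proteins[i] for i in ei],
        "protein_b": [proteins[j] for j in ej],
        "combined_score": ppi_scores,
    })

    # --- drug targets
    by_module = [np.flatnonzero(mods == k) for k in range(m)]
    target_rows: list[tuple[str, str]] = []
    drug_target_sets: list[set[int]] = []
    k_t = config.n_targets_per_drug
    for d in range(config.n_drugs):
        if rng.random() < config.focus_prob:
            mod = int(rng.integers(m))
            block = by_module[mod]
            take = min(k_t, len(block))
            chosen = rng.choice(block, size=take, replace=False)
            if take < k_t:  # focal module smaller than the target count
                rest = np.setdiff1d(np.arange(n), block, assume_unique=True)
                chosen = np.concatenate(
                    [chosen, rng.choice(rest, size=k_t - take, replace=False)])
        else:
            chosen = rng.choice(n, size=k_t, replace=False)
        chosen = np.sort(chosen)
        drug_target_sets.append(set(int(c) for c in chosen))
        target_rows.extend((drugs[d], proteins[int(c)]) for c in chosen)
    dt_scores = rng.integers(config.score_threshold, 1001,
                             size=len(target_rows))
    drug_target = pd.DataFrame({
        "chemical": [r[0] for r in target_rows],
        "protein": [r[1] for r in target_rows],
        "combined_score": dt_scores,
    })

    # --- ADR assignment driven by causal-module exposure
    adr_mods = {adrs[a]: a % m for a in range(config.n_adrs)}
    module_sets = [set(int(i) for i in by_module[k]) for k in range(m)]
    adr_rows: list[tuple[str, str]] = []
    for d in range(config.n_drugs):
        tset = drug_target_sets[d]
        for a in range(config.n_adrs):
            exposed = bool(tset & module_sets[adr_mods[adrs[a]]])
            theta = config.theta_hi if exposed else config.theta_lo
            if rng.random() < theta:
                adr_rows.append((drugs[d], adrs[a]))
    drug_adr = pd.DataFrame({
        "drug": [r[0] for r in adr_rows],
        "adr_pt": [r[1] for r in adr_rows],
    })

    truth = {(a, proteins[int(p)])
             for a, mod in adr_mods.items() for p in by_module[mod]}

    # --- optional sub-threshold decoys, to exercise the read-time filter
    if config.low_score_fraction > 0 and config.score_threshold > 0:
        ppi = pd.concat(
            [ppi, _decoy_ppi(rng, proteins, ei, ej, config)],
            ignore_index=True)
        drug_target = pd.concat(
            [drug_target,
             _decoy_targets(rng, drugs, proteins, drug_target_sets, config)],
            ignore_index=True)

    return SyntheticWorld(config=config, ppi_table=ppi,
                          drug_target_table=drug_target,
                          drug_adr_table=drug_adr, truth=truth,
                          module_of=module_of, adr_module=adr_mods)


def _decoy_ppi(rng, proteins, ei, ej, config) -> pd.DataFrame:
    n = len(proteins)
    existing = set(zip(ei.tolist(), ej.tolist()))
    want = int(round(config.low_score_fraction * len(ei)))
    rows = []
    while len(rows) < want:
        i, j = int(rng.integers(n)), int(rng.integers(n))
        if i == j:
            continue
        key = (min(i, j), max(i, j))
        if key in existing:
            continue
        existing.add(key)
        rows.append((proteins[key[0]], proteins[key[1]],
                     int(rng.integers(0, config.score_threshold))))
    return pd.DataFrame(rows,
                        columns=["protein_a", "protein_b", "combined_score"])


def _decoy_targets(rng, drugs, proteins, target_sets, config) -> pd.DataFrame:
    n = len(proteins)
    want = int(round(config.low_score_fraction
                     * sum(len(s) for s in target_sets)))
    rows = []
    taken = [set(s) for s in target_sets]
    while len(rows) < want:
        d = int(rng.integers(len(drugs)))
        p = int(rng.integers(n))
        if p in taken[d]:
            continue
        taken[d].add(p)
        rows.append((drugs[d], proteins[p],
                     int(rng.integers(0, config.score_threshold))))
    return pd.DataFrame(rows, columns=["chemical", "protein", "combined_score"])


def write_world(world: SyntheticWorld, directory: str | Path) -> dict[str, Path]:
    """Write the world as the four pipeline-input TSVs plus its config.

    Emits ``ppi.tsv``, ``drug_target.tsv``, ``drug_adr.tsv``,
    ``benchmark.tsv`` and ``world_config.json``.  Row order is sorted, so the
    same world always produces byte-identical files.  Returns the path map.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {name: directory / f"{name}.tsv"
             for name in ("ppi", "drug_target", "drug_adr", "benchmark")}

    ppi = world.ppi_table.sort_values(
        ["protein_a", "protein_b"]).reset_index(drop=True)
    ppi.to_csv(paths["ppi"], sep="\t", index=False)
    dt = world.drug_target_table.sort_values(
        ["chemical", "protein"]).reset_index(drop=True)
    dt.to_csv(paths["drug_target"], sep="\t", index=False)
    da = world.drug_adr_table.sort_values(
        ["drug", "adr_pt"]).reset_index(drop=True)
    da.to_csv(paths["drug_adr"], sep="\t", index=False)
    bench = pd.DataFrame(sorted(world.truth), columns=["adr_pt", "protein"])
    bench.to_csv(paths["benchmark"], sep="\t", index=False)

    import json
    cfg_path = directory / "world_config.json"
    with open(cfg_path, "w", encoding="utf-8") as fh:
        json.dump(asdict(world.config), fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["config"] = cfg_path
    return paths
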