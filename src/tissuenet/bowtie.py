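"""Bow-tie decomposition of common / tissue-specific motif instances.

Genes occurring in both CM and TS motif instances of a tissue network are
its core; genes only in TS instances form the input layer and genes only in
CM instances the output layer.  Molecular composition and the average
degrees within and between layers are tested against permutation nulls that
shuffle layer labels over the motif-instance genes while keeping layer sizes
and the arc set fixed, and the layer size ratios classify each tissue's
bow-tie pattern as input-dominated, symmetric or output-dominated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .network import MIRNA, NONTF, RegulatoryNetwork, TF

logger = logging.getLogger(__name__)

INPUT = "input"  # non-core TS genes
CORE = "core"
OUTPUT = "output"  # non-core CM genes
LAYERS = (INPUT, CORE, OUTPUT)

INPUT_DOMINATED = "input-dominated"
SYMMETRIC = "symmetric"
OUTPUT_DOMINATED = "output-dominated"
UNCLASSIFIED = "unclassified"

_ROLE_IDX = {TF: 0, MIRNA: 1, NONTF: 2}


def partition_genes(
    cm_instances: Iterable[tuple[str, str, str]],
    ts_instances: Iterable[tuple[str, str, str]],
) -> tuple[set[str], set[str], set[str]]:
    """Split motif-instance genes into (core, noncore_cm, noncore_ts).

    Core genes occur in at least one CM and at least one TS instance;
    noncore_cm (output layer) genes only in CM instances; noncore_ts (input
    layer) genes only in TS instances.  Empty TS input (the liver case)
    yields an empty core and input layer.
    """
    cm_genes = {g for inst in cm_instances for g in inst}
    ts_genes = {g for inst in ts_instances for g in inst}
    core = cm_genes & ts_genes
    return core, cm_genes - core, ts_genes - core


def composition(
    sets: Mapping[str, Iterable[str]], roles: Mapping[str, str]
) -> pd.DataFrame:
    """Role fractions per gene set (rows: set name; columns TF/miRNA/nonTF).

    Fractions of a non-empty set sum to 1.  An empty set is flagged
    ``defined=False`` with zero fractions.
    """
    rows = []
    for name, genes in sets.items():
        genes = list(genes)
        counts = {r: 0 for r in _ROLE_IDX}
        for g in genes:
            counts[roles[g]] += 1
        n = len(genes)
        rows.append(
            {
                "set": name,
                TF: counts[TF] / n if n else 0.0,
                MIRNA: counts[MIRNA] / n if n else 0.0,
                NONTF: counts[NONTF] / n if n else 0.0,
                "n_genes": n,
                "defined": n > 0,
            }
        )
    return pd.DataFrame(rows).set_index("set")


def average_degree(
    set_i: Iterable[str],
    set_j: Iterable[str] | None,
    arcs: Iterable[tuple[str, str]],
    norm: str = "source",
) -> float:
    """Average regulation degree within a set or from set i to set j.

    Within-set (``set_j is None`` or identical): number of arcs with both
    endpoints in set i divided by N_i.  Between sets: number of arcs from
    set i to set j, normalized by N_i (``norm='source'``, the default
    per-source-gene average), by N_i*N_j (``'pair'``) or by (N_i+N_j)/2
    (``'mean'``).
    """
    si = set(set_i)
    if not si:
        raise ValueError("empty source set has no average degree")
    if set_j is None:
        count = sum(1 for a, b in arcs if a in si and b in si)
        return count / len(si)
    sj = set(set_j)
    if si == sj:
        count = sum(1 for a, b in arcs if a in si and b in si)
        return count / len(si)
    count = sum(1 for a, b in arcs if a in si and b in sj)
    if norm == "source":
        denom = len(si)
    elif norm == "pair":
        denom = len(si) * len(sj)
    elif norm == "mean":
        denom = (len(si) + len(sj)) / 2
    else:
        raise ValueError(f"unknown normalization {norm!r}")
    if denom == 0:
        raise ValueError("empty set in between-set average degree")
    return count / denom


@dataclass
class PatternCall:
    pattern: str
    degenerate: bool = False

    def __str__(self) -> str:
        return ("degenerate " if self.degenerate else "") + self.pattern


def size_ratios(
    core: set[str], noncore_cm: set[str], noncore_ts: set[str]
) -> tuple[float, float, float]:
    """(sr_input, sr_core, sr_output): layer sizes over the bow-tie union."""
    total = len(core) + len(noncore_cm) + len(noncore_ts)
    if total == 0:
        raise ValueError("empty bow-tie: no motif-instance genes")
    return len(noncore_ts) / total, len(core) / total, len(noncore_cm) / total


def classify_pattern(
    sr: tuple[float, float, float], kappa: float = 2.0, tau_sym: float = 0.1
) -> PatternCall:
    """Bow-tie pattern from (sr_input, sr_core, sr_output).

    Non-degenerate rules (all layers populated), applied in order:
    symmetric when |sr_input - sr_output| <= tau_sym and both exceed
    sr_core; input-dominated when sr_input >= kappa*sr_core > ... with
    sr_core > sr_output; output-dominated when sr_output >= kappa*sr_core
    and sr_input < sr_core; otherwise unclassified.  Any empty layer flags
    the call degenerate and the label follows the dominant layer (e.g. the
    liver-like (0, 0, 1) triple is a degenerate output-dominated bow-tie).
    """
    sr_input, sr_core, sr_output = sr
    if min(sr) < 0 or abs(sum(sr) - 1.0) > 1e-9:
        raise ValueError(f"size ratios must be non-negative and sum to 1, got {sr}")
    if min(sr) == 0.0:
        if sr_output >= kappa * max(sr_input, sr_core):
            return PatternCall(OUTPUT_DOMINATED, degenerate=True)
        if sr_input >= kappa * max(sr_core, sr_output):
            return PatternCall(INPUT_DOMINATED, degenerate=True)
        if abs(sr_input - sr_output) <= tau_sym and min(sr_input, sr_output) > sr_core:
            return PatternCall(SYMMETRIC, degenerate=True)
        return PatternCall(UNCLASSIFIED, degenerate=True)
    if abs(sr_input - sr_output) <= tau_sym and min(sr_input, sr_output) > sr_core:
        return PatternCall(SYMMETRIC)
    if sr_input >= kappa * sr_core and sr_core > sr_output:
        return PatternCall(INPUT_DOMINATED)
    if sr_output >= kappa * sr_core and sr_input < sr_core:
        return PatternCall(OUTPUT_DOMINATED)
    return PatternCall(UNCLASSIFIED)


@dataclass
class BowTieDecomposition:
    """Layered decomposition of one tissue's CM/TS motif-instance genes."""

    tissue: str
    core: set[str]
    noncore_cm: set[str]
    noncore_ts: set[str]
    composition: pd.DataFrame = None
    avg_degree: pd.DataFrame = None  # 3x3, rows = source layer
    size_ratios: tuple[float, float, float] = None
    pattern: PatternCall = None

    @property
    def layers(self) -> dict[str, set[str]]:
        return {INPUT: self.noncore_ts, CORE: self.core, OUTPUT: self.noncore_cm}

    @property
    def union(self) -> set[str]:
        return self.core | self.noncore_cm | self.noncore_ts


def decompose(
    tissue: str,
    cm_instances: Iterable[tuple[str, str, str]],
    ts_instances: Iterable[tuple[str, str, str]],
    network: RegulatoryNetwork,
    norm: str = "source",
    kappa: float = 2.0,
    tau_sym: float = 0.1,
) -> BowTieDecomposition:
    """Full bow-tie decomposition of one tissue's motif instances.

    The degree statistics count TRN arcs between motif-instance genes
    whether or not the specific arc lies inside a motif instance (the
    adjacency matrix is the source of the degree statistics, not instance
    membership).
    """
    core, noncore_cm, noncore_ts = partition_genes(cm_instances, ts_instances)
    d = BowTieDecomposition(
        tissue=tissue, core=core, noncore_cm=noncore_cm, noncore_ts=noncore_ts
    )
    d.composition = composition(d.layers, network.roles)
    union = d.union
    arcs = [(a, b) for a, b in network.arcs if a in union and b in union]
    mat = pd.DataFrame(np.nan, index=list(LAYERS), columns=list(LAYERS))
    for li in LAYERS:
        if not d.layers[li]:
            continue
        for lj in LAYERS:
            if li != lj and not d.layers[lj]:
                continue
            mat.loc[li, lj] = average_degree(
                d.layers[li], d.layers[lj] if li != lj else None, arcs, norm=norm
            )
    d.avg_degree = mat
    d.size_ratios = size_ratios(core, noncore_cm, noncore_ts)
    d.pattern = classify_pattern(d.size_ratios, kappa=kappa, tau_sym=tau_sym)
    return d


@dataclass
class PermutationResult:
    """Empirical significance of composition and degree statistics.

    ``comp_*`` frames are layers x roles; ``deg_*`` frames are source layer
    x target layer.  p_high is the one-sided enrichment p-value
    (1 + #{random >= real})/(1 + n_random); p_low the depletion analogue
    with <=.  Statistics involving an empty layer are NaN.
    """

    n_random: int
    comp_real: pd.DataFrame
    comp_p_high: pd.DataFrame
    comp_p_low: pd.DataFrame
    deg_real: pd.DataFrame
    deg_p_high: pd.DataFrame
    deg_p_low: pd.DataFrame


def permutation_test(
    decomposition: BowTieDecomposition,
    network: RegulatoryNetwork,
    n_random: int = 5000,
    seed: int | None = None,
    norm: str = "source",
) -> PermutationResult:
    """Label-shuffling null for composition and average-degree statistics.

    Each replicate redistributes the motif-instance genes over the three
    layers, keeping every layer's size and the arc set fixed, and recomputes
    all statistics.
    """
    union = sorted(decomposition.union)
    if len(union) < 3:
        raise ValueError("permutation test needs at least 3 motif-instance genes")
    rng = np.random.default_rng(seed)
    uidx = {g: i for i, g in enumerate(union)}
    n = len(union)
    labels0 = np.empty(n, dtype=np.int64)
    for k, layer in enumerate(LAYERS):
        for g in decomposition.layers[layer]:
            labels0[uidx[g]] = k
    sizes = np.bincount(labels0, minlength=3).astype(float)
    role_arr = np.array([_ROLE_IDX[network.roles[g]] for g in union], dtype=np.int64)
    arcs = [
        (uidx[a], uidx[b]) for a, b in network.arcs if a in uidx and b in uidx
    ]
    ai = np.array([a for a, _ in arcs], dtype=np.int64)
    bi = np.array([b for _, b in arcs], dtype=np.int64)

    if norm == "source":
        denom = np.repeat(sizes[:, None], 3, axis=1)
    elif norm == "pair":
        denom = np.outer(sizes, sizes)
        np.fill_diagonal(denom, sizes)  # within-set stays arcs / N_i
    elif norm == "mean":
        denom = (sizes[:, None] + sizes[None, :]) / 2
        np.fill_diagonal(denom, sizes)
    else:
        raise ValueError(f"unknown normalization {norm!r}")

    def stats(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        comp = np.zeros((3, 3))
        np.add.at(comp, (labels, role_arr), 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            comp = comp / sizes[:, None]
            deg = np.zeros((3, 3))
            if len(ai):
                np.add.at(deg, (labels[ai], labels[bi]), 1.0)
            deg = deg / denom
        comp[sizes == 0, :] = np.nan
        deg[sizes == 0, :] = np.nan
        deg[:, sizes == 0] = np.nan
        np.fill_diagonal(deg, np.where(sizes > 0, np.diagonal(deg), np.nan))
        return comp, deg

    comp_real, deg_real = stats(labels0)
    ge_comp = np.zeros((3, 3))
    le_comp = np.zeros((3, 3))
    ge_deg = np.zeros((3, 3))
    le_deg = np.zeros((3, 3))
    for _ in range(n_random):
        labels = labels0[rng.permutation(n)]
        comp_r, deg_r = stats(labels)
        ge_comp += comp_r >= comp_real
        le_comp += comp_r <= comp_real
        ge_deg += deg_r >= deg_real
        le_deg += deg_r <= deg_real

    def finish(count: np.ndarray, real: np.ndarray) -> pd.DataFrame:
        p = (1 + count) / (1 + n_random)
        p[np.isnan(real)] = np.nan
        return p

    roles_cols = [TF, MIRNA, NONTF]
    mk = lambda a, cols: pd.DataFrame(a, index=list(LAYERS), columns=cols)
    return PermutationResult(
        n_random=n_random,
        comp_real=mk(comp_real, roles_cols),
        comp_p_high=mk(finish(ge_comp, comp_real), roles_cols),
        comp_p_low=mk(finish(le_comp, comp_real), roles_cols),
        deg_real=mk(deg_real, list(LAYERS)),
        deg_p_high=mk(finish(ge_deg, deg_real), list(LAYERS)),
        deg_p_low=mk(finish(le_deg, deg_real), list(LAYERS)),
    )
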