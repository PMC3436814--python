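"""Hub identification, specificity index and sigma_RF analysis.

A vertex is an in-hub (out-hub) of a tissue network when its in-degree
(out-degree) is significantly higher than that of the same vertex in an
ensemble of equivalent Erdos-Renyi-style random networks that keep the
number of vertices and arcs but redistribute the arcs uniformly over
distinct ordered vertex pairs.  Tissue specificity of hub status is scaled
by the specificity index SI = (N - n)/(N - 1), and the deviation of the
relative frequency of hubs at each SI value from degree-redistribution
nulls gives the signed sigma_RF curve.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .network import (
    IN,
    OUT,
    REGULATOR_ROLES,
    RegulatoryNetwork,
    ROLES,
    TF,
)

logger = logging.getLogger(__name__)

STRONG = "strong"
WEAK = "weak"
NON_HUB = "non-hub"


@dataclass
class HubCall:
    """Hub test outcome for one gene in one tissue and direction."""

    gene_id: str
    tissue: str
    direction: str
    observed_degree: int
    p_value: float
    is_hub: bool


@dataclass
class HubProfile:
    """Cross-tissue hub behaviour of one gene in one direction."""

    gene_id: str
    role: str
    direction: str
    n_tissues: int  # N: tissues analyzed
    n_expressed: int  # tissues where the gene is expressed
    n_hub: int  # tissues where the gene is called a hub
    si: float  # specificity index; NaN when n_hub == 0
    strength: str = NON_HUB
    active_ratios: dict[str, float] = field(default_factory=dict)


def er_randomize(
    n_vertices: int,
    n_arcs: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> RegulatoryNetwork:
    """Random simple digraph: ``n_arcs`` arcs uniform over distinct ordered pairs.

    The null ensemble deliberately ignores vertex roles (arcs may start
    anywhere); all vertices are labeled TF so the container's role invariant
    holds while the topology is the literal unconstrained ER digraph.
    """
    max_arcs = n_vertices * (n_vertices - 1)
    if n_arcs > max_arcs:
        raise ValueError(f"n_arcs={n_arcs} exceeds {max_arcs} ordered distinct pairs")
    if rng is None:
        rng = np.random.default_rng(seed)
    src, dst = _sample_er_pairs(n_vertices, n_arcs, rng)
    width = len(str(max(n_vertices - 1, 0)))
    names = [f"v{i:0{width}d}" for i in range(n_vertices)]
    arcs = {(names[a], names[b]) for a, b in zip(src, dst)}
    return RegulatoryNetwork(
        roles=dict.fromkeys(names, TF), arcs=arcs, label="er_random"
    )


def _sample_er_pairs(
    n: int, m: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample m distinct ordered pairs (i, j), i != j, uniformly without replacement."""
    total = n * (n - 1)
    codes = rng.choice(total, size=m, replace=False)
    src = codes // (n - 1)
    rem = codes % (n - 1)
    dst = np.where(rem < src, rem, rem + 1)
    return src, dst


def call_hubs(
    trn: RegulatoryNetwork,
    direction: str,
    n_random: int = 2000,
    alpha: float = 0.01,
    seed: int | None = None,
    role_preserving: bool = False,
) -> list[HubCall]:
    """Empirical per-vertex hub test against the ER null ensemble.

    For each vertex v, p = (1 + #{replicates with null degree of v >=
    observed}) / (1 + n_random); ``is_hub`` iff p < alpha.  Vertices with
    observed degree 0 always get p = 1.  With ``role_preserving`` the null
    restricts arc sources to TF/miRNA vertices (sensitivity analysis; the
    default is the literal unconstrained null).
    """
    if direction not in (IN, OUT):
        raise ValueError(f"direction must be 'in' or 'out', got {direction!r}")
    if n_random < 100:
        warnings.warn(
            f"n_random={n_random} < 100 gives unstable hub p-values", stacklevel=2
        )
    genes = sorted(trn.roles)
    n = len(genes)
    m = trn.n_arcs
    degs = trn.degrees(direction)
    obs = np.array([degs[g] for g in genes], dtype=np.int64)
    if m == 0 or n < 2:
        return [
            HubCall(g, trn.label, direction, int(o), 1.0, False)
            for g, o in zip(genes, obs)
        ]
    rng = np.random.default_rng(seed)
    ge_counts = np.zeros(n, dtype=np.int64)
    if role_preserving:
        reg_idx = np.array(
            [i for i, g in enumerate(genes) if trn.roles[g] in REGULATOR_ROLES],
            dtype=np.int64,
        )
        r = len(reg_idx)
        if m > r * (n - 1):
            raise ValueError("too many arcs for a role-preserving null")
        for _ in range(n_random):
            codes = rng.choice(r * (n - 1), size=m, replace=False)
            src = reg_idx[codes // (n - 1)]
            rem = codes % (n - 1)
            # rem indexes targets excluding the source itself
            s_pos = codes // (n - 1)
            dst = np.where(rem < reg_idx[s_pos], rem, rem + 1)
            deg_r = np.bincount(src if direction == OUT else dst, minlength=n)
            ge_counts += deg_r >= obs
    else:
        for _ in range(n_random):
            src, dst = _sample_er_pairs(n, m, rng)
            deg_r = np.bincount(src if direction == OUT else dst, minlength=n)
            ge_counts += deg_r >= obs
    p = (1 + ge_counts) / (1 + n_random)
    return [
        HubCall(g, trn.label, direction, int(o), float(pv), bool(pv < alpha))
        for g, o, pv in zip(genes, obs, p)
    ]


def specificity_index(N: int, n: int) -> float:
    """SI = (N - n)/(N - 1): 1 = hub in exactly one tissue, 0 = hub in all N."""
    if N < 2:
        raise ValueError("specificity index needs at least 2 tissues")
    if n < 1:
        raise ValueError("specificity index is undefined for a gene that is no hub")
    if n > N:
        raise ValueError(f"n={n} exceeds N={N}")
    return (N - n) / (N - 1)


def active_ratio(
    gene_id: str,
    direction: str,
    trn: RegulatoryNetwork,
    reference: RegulatoryNetwork,
) -> float:
    """Fraction of a gene's reference connections realized in one TRN."""
    ref_deg = reference.degrees(direction).get(gene_id)
    if ref_deg is None:
        raise KeyError(f"gene {gene_id!r} absent from reference")
    if ref_deg == 0:
        raise ValueError(f"gene {gene_id!r} has reference {direction}-degree 0")
    if gene_id not in trn.roles:
        return 0.0
    return trn.degrees(direction)[gene_id] / ref_deg


def classify_strength(profiles: Iterable[HubProfile]) -> list[HubProfile]:
    """Strong: hub everywhere it is expressed; weak: hub in a strict subset."""
    out = []
    for p in profiles:
        if p.n_hub == 0:
            p.strength = NON_HUB
        elif p.n_hub == p.n_expressed:
            p.strength = STRONG
        else:
            p.strength = WEAK
        out.append(p)
    return out


def build_hub_profiles(
    reference: RegulatoryNetwork,
    trns: Sequence[RegulatoryNetwork],
    calls_by_tissue: Mapping[str, Sequence[HubCall]],
    direction: str,
    si_func: Callable[[int, int], float] = specificity_index,
) -> list[HubProfile]:
    """Aggregate per-tissue hub calls into cross-tissue profiles.

    ``si_func`` defaults to the linear SI and may be substituted.  Active
    ratios are computed per tissue for genes with nonzero reference degree.
    """
    N = len(trns)
    ref_deg = reference.degrees(direction)
    hub_in: dict[str, set[str]] = {}
    for t, calls in calls_by_tissue.items():
        for c in calls:
            if c.is_hub:
                hub_in.setdefault(c.gene_id, set()).add(t)
    profiles = []
    for g in sorted(reference.roles):
        expressed_in = [t.label for t in trns if g in t.roles]
        n_hub = len(hub_in.get(g, ()))
        ratios = {}
        if ref_deg[g] > 0:
            for t in trns:
                if g in t.roles:
                    ratios[t.label] = active_ratio(g, direction, t, reference)
        profiles.append(
            HubProfile(
                gene_id=g,
                role=reference.roles[g],
                direction=direction,
                n_tissues=N,
                n_expressed=len(expressed_in),
                n_hub=n_hub,
                si=si_func(N, n_hub) if n_hub >= 1 else float("nan"),
                active_ratios=ratios,
            )
        )
    return classify_strength(profiles)


@dataclass
class SigmaRFPoint:
    si: float
    rf_real: float
    rf_rand_mean: float
    rf_rand_sd: float
    sigma_rf: float
    sd_zero: bool = False


@dataclass
class SigmaRFCurve:
    direction: str
    role: str
    n_tissues: int
    mode: str
    points: list[SigmaRFPoint] = field(default_factory=list)


def sigma_rf(
    trns: Sequence[RegulatoryNetwork],
    calls_by_tissue: Mapping[str, Sequence[HubCall]],
    direction: str,
    role: str,
    n_random: int = 2000,
    seed: int | None = None,
    mode: str = "zscore",
) -> SigmaRFCurve:
    """Deviation of the hub SI spectrum from degree-redistribution nulls.

    RF_real(s) is the fraction of real hubs of the given role/direction whose
    SI equals s, over the N discrete SI values (N-n)/(N-1).  Each random
    replicate permutes, within every tissue, the observed degree values among
    the expressed genes of the role; because the empirical hub p-value is a
    monotone function of degree, re-identifying hubs reduces to re-applying
    each tissue's real hub degree threshold to the permuted degrees.  The
    curve reports (RF_real - mean_rand)/sd_rand per SI value (``mode
    'zscore'``) or the raw difference (``mode 'diff'``); zero ensemble
    variance is flagged and reported as sigma 0.
    """
    if role not in ROLES:
        raise ValueError(f"unknown role {role!r}")
    if mode not in ("zscore", "diff"):
        raise ValueError(f"mode must be 'zscore' or 'diff', got {mode!r}")
    N = len(trns)
    if N < 2:
        raise ValueError("sigma_rf needs at least 2 tissue networks")
    rng = np.random.default_rng(seed)

    # Gene universe: genes of this role expressed in >= 1 tissue.
    gene_ids = sorted({g for t in trns for g in t.roles if t.roles[g] == role})
    gidx = {g: i for i, g in enumerate(gene_ids)}
    n_genes = len(gene_ids)

    per_tissue: list[tuple[np.ndarray, np.ndarray, float]] = []
    n_hub_real = np.zeros(n_genes, dtype=np.int64)
    for t in trns:
        calls = calls_by_tissue[t.label]
        hub_degs = [c.observed_degree for c in calls if c.is_hub]
        thr = min(hub_degs) if hub_degs else math.inf
        degs = t.degrees(direction)
        members = np.array(
            [gidx[g] for g in sorted(degs) if t.roles[g] == role], dtype=np.int64
        )
        dvec = np.array(
            [degs[g] for g in sorted(degs) if t.roles[g] == role], dtype=np.int64
        )
        per_tissue.append((members, dvec, thr))
        for c in calls:
            if c.is_hub and c.gene_id in gidx:
                n_hub_real[gidx[c.gene_id]] += 1

    curve = SigmaRFCurve(direction=direction, role=role, n_tissues=N, mode=mode)
    if n_hub_real.sum() == 0:
        warnings.warn(
            f"no {role} {direction}-hubs: empty sigma_rf curve", stacklevel=2
        )
        return curve

    def rf_from_nhub(n_hub: np.ndarray) -> np.ndarray:
        hist = np.bincount(n_hub, minlength=N + 1)[1 : N + 1].astype(float)
        total = hist.sum()
        return hist / total if total > 0 else hist

    rf_real = rf_from_nhub(n_hub_real)
    rf_rand = np.zeros((n_random, N))
    for r in range(n_random):
        n_hub = np.zeros(n_genes, dtype=np.int64)
        for members, dvec, thr in per_tissue:
            if len(members) == 0 or math.isinf(thr):
                continue
            perm = rng.permutation(len(dvec))
            hubs = members[dvec[perm] >= thr]
            n_hub[hubs] += 1
        rf_rand[r] = rf_from_nhub(n_hub)

    means = rf_rand.mean(axis=0)
    sds = rf_rand.std(axis=0, ddof=1) if n_random > 1 else np.zeros(N)
    for k in range(N):  # k = n_hub - 1  ->  SI = (N - (k+1))/(N - 1)
        n_val = k + 1
        si = specificity_index(N, n_val)
        sd_zero = sds[k] == 0.0
        if mode == "diff":
            sigma = float(rf_real[k] - means[k])
        else:
            sigma = 0.0 if sd_zero else float((rf_real[k] - means[k]) / sds[k])
        curve.points.append(
            SigmaRFPoint(
                si=si,
                rf_real=float(rf_real[k]),
                rf_rand_mean=float(means[k]),
                rf_rand_sd=float(sds[k]),
                sigma_rf=sigma,
                sd_zero=bool(sd_zero),
            )
        )
    return curve
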