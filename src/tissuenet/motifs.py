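"""Colored three-vertex motif analysis.

Connected three-vertex subgraphs are classified up to isomorphism of the
vertex-colored digraph: a signature is the lexicographic minimum, over the
six vertex orderings, of the pair (role triple, 6-bit adjacency pattern).
Over-representation is assessed against an ensemble of degree-preserving
switch-randomized networks, and motifs are labeled common (CM) when
significant in every tissue network or tissue-specific (TS) when significant
in at least one but not all.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np

from .network import RegulatoryNetwork, ROLES

logger = logging.getLogger(__name__)

#: Ordered vertex pairs defining the 6 adjacency bits of a triad, for local
#: vertex positions 0,1,2.  Bit k is set when the arc PAIRS[k] is present.
PAIRS = ((0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1))
_POS = {p: k for k, p in enumerate(PAIRS)}
_PERMS = tuple(itertools.permutations(range(3)))

FFL = "FFL"
FBL = "FBL"
CMPLX = "CMPLX"
NONLOOP = "non-loop"

CM = "CM"
TS = "TS"
NONE = "none"


@dataclass(frozen=True, order=True)
class TriadSignature:
    """Canonical colored-triad class: role triple + 6-bit adjacency pattern."""

    roles: tuple[str, str, str]
    bits: int

    @property
    def pattern(self) -> str:
        """6-character 0/1 string in :data:`PAIRS` order."""
        return "".join(str((self.bits >> k) & 1) for k in range(6))

    def __str__(self) -> str:
        return "-".join(self.roles) + "|" + self.pattern

    @classmethod
    def from_string(cls, s: str) -> "TriadSignature":
        roles_s, pattern = s.split("|")
        roles = tuple(roles_s.split("-"))
        if len(roles) != 3 or any(r not in ROLES for r in roles):
            raise ValueError(f"bad signature roles in {s!r}")
        if len(pattern) != 6 or set(pattern) - {"0", "1"}:
            raise ValueError(f"bad signature pattern in {s!r}")
        bits = sum(1 << k for k, c in enumerate(pattern) if c == "1")
        return canonical_signature(roles, bits)

    def arc_positions(self) -> list[tuple[int, int]]:
        return [PAIRS[k] for k in range(6) if (self.bits >> k) & 1]

    def is_connected(self) -> bool:
        und = {frozenset(p) for p in self.arc_positions()}
        if len(und) < 2:
            return False
        # 3 vertices are weakly connected iff >=2 distinct undirected pairs
        return True

    def is_role_valid(self) -> bool:
        return all(self.roles[i] != "nonTF" for i, _ in self.arc_positions())


@lru_cache(maxsize=None)
def _canon(roles: tuple[str, str, str], bits: int) -> tuple[tuple[str, str, str], int]:
    best = None
    for perm in _PERMS:
        r = (roles[perm[0]], roles[perm[1]], roles[perm[2]])
        b = 0
        for k, (i, j) in enumerate(PAIRS):
            if (bits >> _POS[(perm[i], perm[j])]) & 1:
                b |= 1 << k
        key = (r, b)
        if best is None or key < best:
            best = key
    return best


def canonical_signature(roles: Sequence[str], bits: int) -> TriadSignature:
    """Canonical signature of a colored triad given in an arbitrary vertex order."""
    r, b = _canon(tuple(roles), bits)
    return TriadSignature(r, b)


def classify_structure(signature: TriadSignature) -> str:
    """Structural class of a connected triad: FFL, FBL, CMPLX or non-loop.

    FFL: acyclic with a two-step path plus its shortcut arc.  FBL: the pure
    directed 3-cycle (no bidirectional pair).  CMPLX: contains at least one
    bidirectional (dyad) pair together with both a feed-forward and a
    feedback pattern.  Everything else is non-loop.
    """
    e = lambda i, j: (signature.bits >> _POS[(i, j)]) & 1
    has_dyad = any(e(i, j) and e(j, i) for i, j in ((0, 1), (0, 2), (1, 2)))
    has_3cycle = bool(
        (e(0, 1) and e(1, 2) and e(2, 0)) or (e(0, 2) and e(2, 1) and e(1, 0))
    )
    has_ffl = any(
        e(x, y) and e(y, z) and e(x, z) for x, y, z in itertools.permutations(range(3))
    )
    if has_3cycle and not has_dyad:
        return FBL
    if has_ffl and not has_dyad and not has_3cycle:
        return FFL
    if has_dyad and has_ffl:  # the dyad itself supplies the feedback pattern
        return CMPLX
    return NONLOOP


@dataclass
class MotifStat:
    """Per-tissue occurrence and significance of one triad signature."""

    tissue: str
    signature: TriadSignature
    occurrence: int
    rand_mean: float = float("nan")
    rand_sd: float = float("nan")
    z_score: float = float("nan")
    p_value: float = float("nan")
    significant: bool = False
    z_undefined: bool = False
    instances: list[tuple[str, str, str]] = field(default_factory=list)


def _census(
    trn: RegulatoryNetwork, with_instances: bool
) -> dict[TriadSignature, MotifStat]:
    genes = sorted(trn.roles)
    idx = {g: i for i, g in enumerate(genes)}
    role = [trn.roles[g] for g in genes]
    arcs = {(idx[a], idx[b]) for a, b in trn.arcs}
    n = len(genes)
    adj: list[set[int]] = [set() for _ in range(n)]
    for a, b in arcs:
        adj[a].add(b)
        adj[b].add(a)

    out: dict[TriadSignature, MotifStat] = {}

    def record(v: int, w: int, x: int) -> None:
        bits = 0
        for k, (i, j) in enumerate(PAIRS):
            t = (v, w, x)
            if (t[i], t[j]) in arcs:
                bits |= 1 << k
        sig = canonical_signature((role[v], role[w], role[x]), bits)
        st = out.get(sig)
        if st is None:
            st = MotifStat(tissue=trn.label, signature=sig, occurrence=0)
            out[sig] = st
        st.occurrence += 1
        if with_instances:
            st.instances.append(tuple(sorted((genes[v], genes[w], genes[x]))))

    # ESU for size 3: each connected triple is visited exactly once with v
    # its minimum vertex.
    for v in range(n):
        nv = sorted(u for u in adj[v] if u > v)
        for i, w in enumerate(nv):
            for x in nv[i + 1 :]:
                record(v, w, x)
            for u in adj[w]:
                if u > v and u not in adj[v] and u != v:
                    record(v, w, u)
    return out


def enumerate_triads(
    trn: RegulatoryNetwork, with_instances: bool = True
) -> dict[TriadSignature, MotifStat]:
    """Census of all weakly connected three-vertex induced subgraphs.

    Returns one :class:`MotifStat` per observed signature with ``occurrence``
    (and ``instances`` unless disabled) filled in; significance fields stay
    unset until :func:`motif_significance` runs.
    """
    if trn.n_vertices < 3:
        return {}
    return _census(trn, with_instances)


def brute_force_census(trn: RegulatoryNetwork) -> dict[TriadSignature, int]:
    """Independent oracle: scan all vertex triples (use only on small networks)."""
    genes = sorted(trn.roles)
    arcs = trn.arcs
    counts: dict[TriadSignature, int] = {}
    for a, b, c in itertools.combinations(genes, 3):
        t = (a, b, c)
        bits = 0
        for k, (i, j) in enumerate(PAIRS):
            if (t[i], t[j]) in arcs:
                bits |= 1 << k
        pairs_present = {
            frozenset((i, j)) for i, j in PAIRS if (t[i], t[j]) in arcs
        }
        if len(pairs_present) < 2:
            continue  # not weakly connected
        sig = canonical_signature((trn.roles[a], trn.roles[b], trn.roles[c]), bits)
        counts[sig] = counts.get(sig, 0) + 1
    return counts


def switch_randomize(
    trn: RegulatoryNetwork,
    n_swap_factor: float = 10.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> RegulatoryNetwork:
    """Degree-preserving randomization by repeated double-arc switches.

    Each attempted switch picks two arcs (a→b, c→d) and proposes (a→d, c→b),
    rejected when it would create a self-loop or duplicate arc.  Every vertex
    keeps its exact in-/out-degree and role.  The number of attempts is
    ``n_swap_factor * |arcs|``.
    """
    if trn.n_arcs < 2:
        raise ValueError("switch randomization needs at least 2 arcs")
    if rng is None:
        rng = np.random.default_rng(seed)
    arcs = sorted(trn.arcs)  # stable order: reproducible across processes
    aset = set(arcs)
    m = len(arcs)
    attempts = int(round(n_swap_factor * m))
    ii = rng.integers(0, m, size=attempts)
    jj = rng.integers(0, m, size=attempts)
    for i, j in zip(ii, jj):
        if i == j:
            continue
        a, b = arcs[i]
        c, d = arcs[j]
        if a == d or c == b:
            continue  # self-loop
        if (a, d) in aset or (c, b) in aset:
            continue  # duplicate
        aset.discard((a, b))
        aset.discard((c, d))
        aset.add((a, d))
        aset.add((c, b))
        arcs[i] = (a, d)
        arcs[j] = (c, b)
    return RegulatoryNetwork(roles=dict(trn.roles), arcs=aset, label=trn.label)


def motif_significance(
    trn: RegulatoryNetwork,
    n_random: int = 1000,
    seed: int | None = None,
    n_swap_factor: float = 10.0,
    min_occurrence: int = 6,
    p_max: float = 0.05,
    z_min: float = 2.2,
) -> list[MotifStat]:
    """Assess over-representation of every observed signature.

    For each signature: z = (occurrence − mean_rand)/sd_rand and a one-sided
    empirical p-value with pseudocount, p = (1 + #{replicates ≥ observed}) /
    (1 + n_random).  A motif is significant when occurrence ≥ min_occurrence
    (i.e. strictly more than 5), p < p_max and z > z_min.  Zero ensemble
    variance flags z as undefined and forces non-significance.
    """
    if n_random < 100:
        warnings.warn(
            f"n_random={n_random} < 100 gives unstable motif p-values", stacklevel=2
        )
    rng = np.random.default_rng(seed)
    real = enumerate_triads(trn, with_instances=True)
    sigs = sorted(real)
    counts = np.zeros((n_random, len(sigs)), dtype=np.int64)
    pos = {s: k for k, s in enumerate(sigs)}
    for r in range(n_random):
        net_r = switch_randomize(trn, n_swap_factor=n_swap_factor, rng=rng)
        census_r = enumerate_triads(net_r, with_instances=False)
        for s, st in census_r.items():
            k = pos.get(s)
            if k is not None:
                counts[r, k] = st.occurrence
    stats: list[MotifStat] = []
    for s in sigs:
        st = real[s]
        col = counts[:, pos[s]]
        st.rand_mean = float(col.mean())
        st.rand_sd = float(col.std(ddof=1)) if n_random > 1 else 0.0
        st.p_value = float((1 + int((col >= st.occurrence).sum())) / (1 + n_random))
        if st.rand_sd == 0.0:
            st.z_score = 0.0
            st.z_undefined = True
            st.significant = False
        else:
            st.z_score = (st.occurrence - st.rand_mean) / st.rand_sd
            st.significant = bool(
                st.occurrence >= min_occurrence
                and st.p_value < p_max
                and st.z_score > z_min
            )
        stats.append(st)
    return stats


@dataclass
class CatalogEntry:
    signature: TriadSignature
    significant_in: set[str]
    label: str  # CM / TS / none
    structure: str  # FFL / FBL / CMPLX / non-loop


@dataclass
class MotifCatalog:
    """Cross-tissue classification of triad signatures as CM / TS / none."""

    tissues: list[str]
    entries: dict[TriadSignature, CatalogEntry]

    def signatures(self, label: str) -> list[TriadSignature]:
        return sorted(s for s, e in self.entries.items() if e.label == label)


def classify_cm_ts(
    stats_by_tissue: Mapping[str, Sequence[MotifStat]], tissues: Sequence[str]
) -> MotifCatalog:
    """Label each signature CM (significant in all tissues), TS (in some) or none."""
    tissues = list(tissues)
    sig_tissues: dict[TriadSignature, set[str]] = {}
    observed: set[TriadSignature] = set()
    for t in tissues:
        for st in stats_by_tissue.get(t, ()):
            observed.add(st.signature)
            if st.significant:
                sig_tissues.setdefault(st.signature, set()).add(t)
    entries = {}
    for s in observed:
        hits = sig_tissues.get(s, set())
        if hits and hits >= set(tissues):
            label = CM
        elif hits:
            label = TS
        else:
            label = NONE
        entries[s] = CatalogEntry(
            signature=s, significant_in=hits, label=label, structure=classify_structure(s)
        )
    return MotifCatalog(tissues=tissues, entries=entries)
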