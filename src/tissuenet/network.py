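"""Role-typed directed regulatory networks and tissue-network construction.

A regulatory network is a simple directed graph over genes, each carrying one
of three roles: transcription factor (``TF``), microRNA (``miRNA``) or
non-TF target gene (``nonTF``).  Only TFs and miRNAs regulate, i.e. may be
the source of an arc; non-TF genes are targets only.  A tissue regulatory
network (TRN) is the subgraph of a genome-wide reference network induced by
the set of genes expressed in that tissue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

TF = "TF"
MIRNA = "miRNA"
NONTF = "nonTF"
ROLES = (TF, MIRNA, NONTF)
REGULATOR_ROLES = frozenset({TF, MIRNA})

IN = "in"
OUT = "out"
DIRECTIONS = (IN, OUT)


class NetworkError(ValueError):
    """Invalid network structure (role violation, unknown vertex, ...)."""


@dataclass
class RegulatoryNetwork:
    """Simple directed graph over role-typed gene vertices.

    Parameters
    ----------
    roles
        Mapping ``gene_id -> role``; the key set is the vertex set.
    arcs
        Set of ordered ``(source, target)`` pairs.  Duplicates are
        impossible by construction; self-loops are rejected.
    label
        Free-text name, e.g. ``"reference"`` or a tissue name.
    plants
        Optional metadata attached by the synthetic generator describing
        planted structures (hubs, motif instances, bow-tie layers).
    """

    roles: dict[str, str]
    arcs: set[tuple[str, str]]
    label: str = ""
    plants: object | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        for g, r in self.roles.items():
            if r not in ROLES:
                raise NetworkError(f"unknown role {r!r} for gene {g!r}")
        for a, b in self.arcs:
            if a == b:
                raise NetworkError(f"self-loop on {a!r} is not allowed")
            if a not in self.roles or b not in self.roles:
                raise NetworkError(f"arc ({a!r}, {b!r}) references undeclared vertex")
            if self.roles[a] not in REGULATOR_ROLES:
                raise NetworkError(
                    f"arc source {a!r} has role {self.roles[a]!r}; only TF/miRNA regulate"
                )

    # -- basic accessors ---------------------------------------------------

    @property
    def vertices(self) -> set[str]:
        return set(self.roles)

    @property
    def n_vertices(self) -> int:
        return len(self.roles)

    @property
    def n_arcs(self) -> int:
        return len(self.arcs)

    def genes_with_role(self, role: str) -> set[str]:
        return {g for g, r in self.roles.items() if r == role}

    def out_degrees(self) -> dict[str, int]:
        d = dict.fromkeys(self.roles, 0)
        for a, _ in self.arcs:
            d[a] += 1
        return d

    def in_degrees(self) -> dict[str, int]:
        d = dict.fromkeys(self.roles, 0)
        for _, b in self.arcs:
            d[b] += 1
        return d

    def degrees(self, direction: str) -> dict[str, int]:
        if direction == IN:
            return self.in_degrees()
        if direction == OUT:
            return self.out_degrees()
        raise ValueError(f"direction must be 'in' or 'out', got {direction!r}")

    def to_networkx(self):
        """Directed networkx graph with a ``role`` vertex attribute."""
        import networkx as nx

        g = nx.DiGraph(label=self.label)
        for gene, role in self.roles.items():
            g.add_node(gene, role=role)
        g.add_edges_from(self.arcs)
        return g


def build_trn(
    reference: RegulatoryNetwork, expressed: Iterable[str], label: str = ""
) -> RegulatoryNetwork:
    """Induced-subgraph TRN: expressed genes plus arcs with both endpoints expressed.

    Raises :class:`NetworkError` listing offenders if any expressed gene is
    absent from the reference.
    """
    expressed = set(expressed)
    missing = expressed - reference.vertices
    if missing:
        raise NetworkError(
            f"expressed genes absent from reference: {sorted(missing)[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    roles = {g: reference.roles[g] for g in expressed}
    arcs = {(a, b) for a, b in reference.arcs if a in expressed and b in expressed}
    return RegulatoryNetwork(roles=roles, arcs=arcs, label=label, plants=reference.plants)


@dataclass
class ExpressionProfile:
    """Binary expression: for each tissue, the set of expressed gene ids."""

    tissues: list[str]
    expressed: dict[str, set[str]]

    def __post_init__(self) -> None:
        if set(self.tissues) != set(self.expressed):
            raise ValueError("tissue list and expression mapping disagree")

    def validate_against(self, reference: RegulatoryNetwork) -> None:
        for t in self.tissues:
            missing = self.expressed[t] - reference.vertices
            if missing:
                raise NetworkError(
                    f"tissue {t!r}: expressed genes not in reference: {sorted(missing)[:10]}"
                )


def degree_table(network: RegulatoryNetwork) -> pd.DataFrame:
    """Per-gene in/out degrees (columns: gene_id, tissue, role, in_degree, out_degree)."""
    ind = network.in_degrees()
    outd = network.out_degrees()
    genes = sorted(network.roles)
    return pd.DataFrame(
        {
            "gene_id": genes,
            "tissue": network.label,
            "role": [network.roles[g] for g in genes],
            "in_degree": [ind[g] for g in genes],
            "out_degree": [outd[g] for g in genes],
        }
    )


def inverse_cumulative_distribution(degrees: Sequence[int]) -> list[tuple[int, float]]:
    """Points ``(k, fraction of vertices with degree >= k)`` for observed k.

    The fraction at the minimum observed degree is 1 and the curve is
    non-increasing in k.
    """
    if len(degrees) == 0:
        raise ValueError("empty degree list")
    n = len(degrees)
    ks = sorted(set(degrees))
    return [(k, sum(1 for d in degrees if d >= k) / n) for k in ks]


# -- TSV / GraphML input and output ---------------------------------------


def write_network(network: RegulatoryNetwork, nodes_path, arcs_path) -> None:
    genes = sorted(network.roles)
    pd.DataFrame(
        {"gene_id": genes, "role": [network.roles[g] for g in genes]}
    ).to_csv(nodes_path, sep="\t", index=False)
    arcs = sorted(network.arcs)
    pd.DataFrame(arcs, columns=["source", "target"]).to_csv(
        arcs_path, sep="\t", index=False
    )


def read_network(nodes_path, arcs_path, label: str = "") -> RegulatoryNetwork:
    """Read node/arc TSV tables.

    Duplicate arcs (a natural consequence of taking unions of predictions)
    are collapsed with a warning; self-loops are dropped with a warning.
    """
    nodes = pd.read_csv(nodes_path, sep="\t", dtype=str)
    arcs_df = pd.read_csv(arcs_path, sep="\t", dtype=str)
    roles = dict(zip(nodes["gene_id"], nodes["role"]))
    raw = list(zip(arcs_df["source"], arcs_df["target"]))
    arcs: set[tuple[str, str]] = set()
    n_dup = n_loop = 0
    for a, b in raw:
        if a == b:
            n_loop += 1
            continue
        if (a, b) in arcs:
            n_dup += 1
            continue
        arcs.add((a, b))
    if n_dup:
        logger.warning("%s: collapsed %d duplicate arcs", arcs_path, n_dup)
    if n_loop:
        logger.warning("%s: dropped %d self-loops", arcs_path, n_loop)
    return RegulatoryNetwork(roles=roles, arcs=arcs, label=label)


def write_graphml(network: RegulatoryNetwork, path) -> None:
    import networkx as nx

    nx.write_graphml(network.to_networkx(), path)


def write_expression(profile: ExpressionProfile, genes: Iterable[str], path) -> None:
    """Long-format TSV (gene_id, tissue, expressed in {0,1}) over all genes."""
    genes = sorted(genes)
    rows = [
        (g, t, int(g in profile.expressed[t])) for t in profile.tissues for g in genes
    ]
    pd.DataFrame(rows, columns=["gene_id", "tissue", "expressed"]).to_csv(
        path, sep="\t", index=False
    )


def read_expression(path) -> ExpressionProfile:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "tissue": str, "expressed": int})
    tissues = list(dict.fromkeys(df["tissue"]))
    expressed = {
        t: set(df.loc[(df["tissue"] == t) & (df["expressed"] == 1), "gene_id"])
        for t in tissues
    }
    return ExpressionProfile(tissues=tissues, expressed=expressed)
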