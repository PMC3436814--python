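"""Synthetic reference networks and tissue expression profiles.

The generator emulates the statistical structure of a genome-wide predicted
regulatory map and its tissue expression filters: heavy-tailed regulator
out-degrees (discretized Pareto), a hard role constraint (non-TF genes never
regulate), binary tissue expression composed of a shared housekeeping
fraction plus per-tissue specific fractions, and optional planted
structures (hubs, enriched colored-triad motifs, bow-tie layers) whose
identities are recorded on the generated network for recovery tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .motifs import TriadSignature
from .network import (
    ExpressionProfile,
    MIRNA,
    NONTF,
    REGULATOR_ROLES,
    RegulatoryNetwork,
    ROLES,
    TF,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneratorParams:
    """Study conditions for the synthetic reference network and expression.

    Defaults describe a small genome with 100 TFs, 50 miRNAs and 350 non-TF
    genes over 8 tissues, mean regulator out-degree 5 with Pareto tail
    exponent 2, half the genes housekeeping and a further fifth
    tissue-specific per tissue.
    """

    seed: int
    n_tf: int = 100
    n_mirna: int = 50
    n_nontf: int = 350
    n_tissues: int = 8
    mean_out_degree_tf: float = 5.0
    mean_out_degree_mirna: float = 5.0
    degree_tail_exponent: float = 2.0
    housekeeping_fraction: float = 0.5
    tissue_specific_fraction: float = 0.2

    def __post_init__(self) -> None:
        if min(self.n_tf, self.n_mirna, self.n_nontf, self.n_tissues) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_tf + self.n_mirna + self.n_nontf < 3:
            raise ValueError("need at least 3 genes")
        if self.degree_tail_exponent <= 1:
            raise ValueError("degree_tail_exponent must exceed 1 for a finite mean")
        if not (0 <= self.housekeeping_fraction <= 1):
            raise ValueError("housekeeping_fraction must be in [0, 1]")
        if not (0 <= self.tissue_specific_fraction <= 1):
            raise ValueError("tissue_specific_fraction must be in [0, 1]")
        if self.housekeeping_fraction + self.tissue_specific_fraction > 1:
            raise ValueError("housekeeping + tissue-specific fractions exceed 1")

    @property
    def n_genes(self) -> int:
        return self.n_tf + self.n_mirna + self.n_nontf

    def tissue_names(self) -> list[str]:
        return [f"tissue_{i + 1}" for i in range(self.n_tissues)]


@dataclass(frozen=True)
class PlantedHub:
    role: str
    direction: str  # 'in' or 'out'
    target_degree: int
    tissues: tuple[str, ...]


@dataclass(frozen=True)
class PlantedMotif:
    signature: TriadSignature
    n_extra_instances: int
    tissues: tuple[str, ...]


@dataclass(frozen=True)
class PlantedBowtie:
    n_input: int
    n_core: int
    n_output: int


@dataclass(frozen=True)
class PlantSpec:
    planted_hubs: tuple[PlantedHub, ...] = ()
    planted_motifs: tuple[PlantedMotif, ...] = ()
    planted_bowtie: PlantedBowtie | None = None

    @classmethod
    def empty(cls) -> "PlantSpec":
        return cls()


@dataclass
class PlantRecord:
    """What was planted where; attached to the generated network.

    ``force_on[tissue]``/``force_off[tissue]`` drive the expression
    generator so that planted structures are expressed exactly in the
    tissues they were planted in.
    """

    hubs: list[dict] = field(default_factory=list)
    motifs: list[dict] = field(default_factory=list)
    bowtie: dict | None = None
    force_on: dict[str, set[str]] = field(default_factory=dict)
    force_off: dict[str, set[str]] = field(default_factory=dict)


class PlantError(ValueError):
    """A planted structure cannot be realized (names the offending entry)."""


def _gene_ids(params: GeneratorParams) -> tuple[list[str], dict[str, str]]:
    ids = (
        [f"TF{i + 1:04d}" for i in range(params.n_tf)]
        + [f"MIR{i + 1:04d}" for i in range(params.n_mirna)]
        + [f"GEN{i + 1:04d}" for i in range(params.n_nontf)]
    )
    roles = {}
    for g in ids:
        roles[g] = TF if g.startswith("TF") else MIRNA if g.startswith("MIR") else NONTF
    return ids, roles


def _sample_out_degrees(
    n: int, mean: float, tail: float, cap: int, rng: np.random.Generator
) -> np.ndarray:
    """Discretized Pareto-I out-degrees with the configured mean and tail shape."""
    if n == 0 or mean <= 0:
        return np.zeros(n, dtype=np.int64)
    x_min = mean * (tail - 1) / tail
    x = x_min * (1.0 + rng.pareto(tail, size=n))
    return np.clip(np.rint(x).astype(np.int64), 0, cap)


def generate_reference(
    params: GeneratorParams, plant: PlantSpec | None = None
) -> RegulatoryNetwork:
    """Sample the reference network, then insert planted structures.

    Background arcs: each TF/miRNA regulator draws a heavy-tailed out-degree
    and targets chosen uniformly among all other genes (regulators may
    target TF, miRNA and non-TF vertices alike; no self-loops, no duplicate
    arcs).  Planted hubs, motif instances and bow-tie layers are inserted
    last and recorded on ``network.plants``.  Fully reproducible from
    ``params.seed``.
    """
    plant = plant or PlantSpec.empty()
    rng = np.random.default_rng((params.seed, 0))
    ids, roles = _gene_ids(params)
    n = len(ids)
    arcs: set[tuple[str, str]] = set()

    regulators = ids[: params.n_tf + params.n_mirna]
    degs_tf = _sample_out_degrees(
        params.n_tf, params.mean_out_degree_tf, params.degree_tail_exponent, n - 1, rng
    )
    degs_mir = _sample_out_degrees(
        params.n_mirna,
        params.mean_out_degree_mirna,
        params.degree_tail_exponent,
        n - 1,
        rng,
    )
    pos = {g: i for i, g in enumerate(ids)}
    for reg, k in zip(regulators, np.concatenate([degs_tf, degs_mir])):
        if k == 0:
            continue
        # draw k distinct targets uniformly among the other n-1 genes
        picks = rng.choice(n - 1, size=int(k), replace=False)
        reg_pos = pos[reg]
        for p in picks:
            t = int(p) if p < reg_pos else int(p) + 1
            arcs.add((reg, ids[t]))

    record = PlantRecord()
    tissue_names = set(params.tissue_names())

    for k, ph in enumerate(plant.planted_hubs):
        _plant_hub(k, ph, ids, roles, arcs, record, rng, tissue_names)
    for k, pm in enumerate(plant.planted_motifs):
        _plant_motif(k, pm, ids, roles, arcs, record, rng, tissue_names)
    if plant.planted_bowtie is not None:
        _plant_bowtie(plant.planted_bowtie, params, ids, roles, arcs, record, rng)

    return RegulatoryNetwork(roles=roles, arcs=arcs, label="reference", plants=record)


def _plant_hub(k, ph, ids, roles, arcs, record, rng, tissue_names) -> None:
    if ph.role not in ROLES:
        raise PlantError(f"planted hub #{k}: unknown role {ph.role!r}")
    if ph.direction not in ("in", "out"):
        raise PlantError(f"planted hub #{k}: direction must be 'in' or 'out'")
    if ph.direction == "out" and ph.role not in REGULATOR_ROLES:
        raise PlantError(f"planted hub #{k}: non-TF genes cannot be out-hubs")
    unknown = set(ph.tissues) - tissue_names
    if unknown:
        raise PlantError(f"planted hub #{k}: unknown tissues {sorted(unknown)}")
    role_genes = [g for g in ids if roles[g] == ph.role]
    taken = {h["gene_id"] for h in record.hubs}
    candidates = [g for g in role_genes if g not in taken]
    if not candidates:
        raise PlantError(f"planted hub #{k}: no unused {ph.role} gene available")
    gene = candidates[int(rng.integers(len(candidates)))]
    if ph.direction == "in":
        eligible = [g for g in ids if roles[g] in REGULATOR_ROLES and g != gene]
    else:
        eligible = [g for g in ids if g != gene]
    if ph.target_degree > len(eligible):
        raise PlantError(
            f"planted hub #{k} ({gene}): target_degree {ph.target_degree} exceeds "
            f"{len(eligible)} eligible partners"
        )
    existing = (
        {a for a, b in arcs if b == gene}
        if ph.direction == "in"
        else {b for a, b in arcs if a == gene}
    )
    partners = set(existing)
    pool = [g for g in eligible if g not in partners]
    need = ph.target_degree - len(partners)
    if need > 0:
        extra = rng.choice(len(pool), size=need, replace=False)
        for i in extra:
            partners.add(pool[int(i)])
    for p in partners:
        arcs.add((p, gene) if ph.direction == "in" else (gene, p))
    record.hubs.append(
        {
            "gene_id": gene,
            "role": ph.role,
            "direction": ph.direction,
            "target_degree": ph.target_degree,
            "tissues": tuple(ph.tissues),
            "partners": sorted(partners),
        }
    )
    for t in ph.tissues:
        record.force_on.setdefault(t, set()).update({gene, *partners})


def _plant_motif(k, pm, ids, roles, arcs, record, rng, tissue_names) -> None:
    sig = pm.signature
    if not sig.is_connected():
        raise PlantError(f"planted motif #{k} ({sig}): signature not connected")
    if not sig.is_role_valid():
        raise PlantError(
            f"planted motif #{k} ({sig}): a non-TF vertex would regulate"
        )
    unknown = set(pm.tissues) - tissue_names
    if unknown:
        raise PlantError(f"planted motif #{k}: unknown tissues {sorted(unknown)}")
    by_role = {r: [g for g in ids if roles[g] == r] for r in ROLES}
    used: set[str] = set()
    instances: list[tuple[str, str, str]] = []
    attempts = 0
    while len(instances) < pm.n_extra_instances:
        attempts += 1
        if attempts > 200 * pm.n_extra_instances + 200:
            raise PlantError(
                f"planted motif #{k} ({sig}): could not place "
                f"{pm.n_extra_instances} clean instances"
            )
        triple = []
        ok = True
        for r in sig.roles:
            pool = [g for g in by_role[r] if g not in used and g not in triple]
            if not pool:
                ok = False
                break
            triple.append(pool[int(rng.integers(len(pool)))])
        if not ok:
            raise PlantError(
                f"planted motif #{k} ({sig}): not enough unused genes of roles "
                f"{sig.roles}"
            )
        if len(set(triple)) < 3:
            continue
        # require a clean triple: no pre-existing arcs among the three genes
        clean = all(
            (triple[i], triple[j]) not in arcs
            for i in range(3)
            for j in range(3)
            if i != j
        )
        if not clean:
            continue
        for i, j in sig.arc_positions():
            arcs.add((triple[i], triple[j]))
        used.update(triple)
        instances.append(tuple(triple))
    record.motifs.append(
        {"signature": sig, "tissues": tuple(pm.tissues), "instances": instances}
    )
    genes = {g for inst in instances for g in inst}
    for t in tissue_names:
        if t in pm.tissues:
            record.force_on.setdefault(t, set()).update(genes)
        else:
            record.force_off.setdefault(t, set()).update(genes)


def _plant_bowtie(pb, params, ids, roles, arcs, record, rng) -> None:
    if pb.n_core < 2:
        raise PlantError("planted bow-tie: n_core must be >= 2 to build FFLs")
    by_role = {r: [g for g in ids if roles[g] == r] for r in ROLES}
    if pb.n_input > len(by_role[MIRNA]):
        raise PlantError(
            f"planted bow-tie: n_input {pb.n_input} exceeds {len(by_role[MIRNA])} miRNAs"
        )
    if pb.n_core > len(by_role[TF]):
        raise PlantError(
            f"planted bow-tie: n_core {pb.n_core} exceeds {len(by_role[TF])} TFs"
        )
    if pb.n_output > len(by_role[NONTF]):
        raise PlantError(
            f"planted bow-tie: n_output {pb.n_output} exceeds "
            f"{len(by_role[NONTF])} non-TF genes"
        )
    pick = lambda pool, m: [
        pool[int(i)] for i in rng.choice(len(pool), size=m, replace=False)
    ]
    inputs = pick(by_role[MIRNA], pb.n_input)
    cores = pick(by_role[TF], pb.n_core)
    outputs = pick(by_role[NONTF], pb.n_output)

    # Cycle core pairs through at least n_core instances on each side so that
    # every core TF takes part in >=1 CM and >=1 TS instance (the defining
    # property of core genes).
    cm_instances = []
    if pb.n_output > 0:
        for k in range(max(pb.n_output, pb.n_core)):
            o = outputs[k % pb.n_output]
            t1 = cores[k % pb.n_core]
            t2 = cores[(k + 1) % pb.n_core]
            arcs.update({(t1, t2), (t1, o), (t2, o)})
            cm_instances.append((t1, t2, o))
    ts_instances = []
    if pb.n_input > 0:
        for k in range(max(pb.n_input, pb.n_core)):
            mir = inputs[k % pb.n_input]
            t1 = cores[k % pb.n_core]
            t2 = cores[(k + 1) % pb.n_core]
            arcs.update({(mir, t1), (t1, t2), (mir, t2)})
            ts_instances.append((mir, t1, t2))

    record.bowtie = {
        "input": sorted(inputs),
        "core": sorted(cores),
        "output": sorted(outputs),
        "cm_instances": cm_instances,
        "ts_instances": ts_instances,
    }
    all_genes = set(inputs) | set(cores) | set(outputs)
    for t in params.tissue_names():
        record.force_on.setdefault(t, set()).update(all_genes)


def generate_expression(
    params: GeneratorParams, network: RegulatoryNetwork
) -> ExpressionProfile:
    """Binary expression: shared housekeeping set plus per-tissue specific sets.

    A fixed housekeeping fraction of genes is expressed in every tissue; each
    tissue additionally expresses its own random tissue-specific fraction.
    Genes attached to planted structures are forced on in the tissues they
    were planted in (and, for planted motifs, forced off elsewhere so that
    planted enrichment stays tissue-restricted).  Every gene ends up
    expressed in at least one tissue.
    """
    rng = np.random.default_rng((params.seed, 1))
    genes = sorted(network.roles)
    n = len(genes)
    tissues = params.tissue_names()
    record: PlantRecord | None = getattr(network, "plants", None)
    force_on = {t: set() for t in tissues}
    force_off = {t: set() for t in tissues}
    if record is not None:
        for t in tissues:
            force_on[t] = set(record.force_on.get(t, set()))
            force_off[t] = set(record.force_off.get(t, set()))
    constrained = set().union(*force_off.values()) if force_off else set()

    hk_pool = [g for g in genes if g not in constrained]
    n_hk = min(int(round(params.housekeeping_fraction * n)), len(hk_pool))
    hk = {hk_pool[int(i)] for i in rng.choice(len(hk_pool), size=n_hk, replace=False)}

    n_ts = int(round(params.tissue_specific_fraction * n))
    expressed: dict[str, set[str]] = {}
    for t in tissues:
        pool = [g for g in genes if g not in hk and g not in force_off[t]]
        m = min(n_ts, len(pool))
        spec = {pool[int(i)] for i in rng.choice(len(pool), size=m, replace=False)}
        expressed[t] = (hk | spec | force_on[t]) - force_off[t]

    covered = set().union(*expressed.values()) if tissues else set()
    for g in genes:
        if g not in covered:
            options = [t for t in tissues if g not in force_off[t]]
            if options:
                expressed[options[int(rng.integers(len(options)))]].add(g)
    return ExpressionProfile(tissues=tissues, expressed=expressed)
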