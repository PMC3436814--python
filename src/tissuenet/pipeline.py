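"""End-to-end orchestration: simulate -> TRNs -> hubs -> motifs -> bow-tie.

Each stage is a standalone function that reads its inputs from and writes
its outputs to the run directory as TSV, so stages can be rerun
individually; :func:`run_pipeline` chains them.  Per-stage seeds are
deterministic functions of the global seed and the stage name, so a rerun
with the same configuration reproduces every output byte for byte.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import bowtie as bt
from . import hubs as hb
from . import motifs as mf
from . import network as nw
from . import synthetic as syn

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable derived seed (< 2^31) for one named stage."""
    h = hashlib.blake2s(f"{global_seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(h, "big") % (2**31)


@dataclass
class PipelineConfig:
    """All knobs of the pipeline and their standard defaults.

    Ensemble sizes default to 2000 ER networks for hub calling, 1000
    switch-randomized networks for motif significance and 5000 label
    permutations for the bow-tie statistics.
    """

    seed: int
    outdir: str = "results/run"
    # either a simulation block...
    simulate: syn.GeneratorParams | None = None
    plant: syn.PlantSpec | None = None
    # ...or paths to existing inputs
    reference_nodes: str | None = None
    reference_arcs: str | None = None
    expression: str | None = None
    # hub analysis
    hub_n_random: int = 2000
    alpha: float = 0.01
    role_preserving_null: bool = False
    sigma_n_random: int = 2000
    sigma_mode: str = "zscore"
    # motif analysis
    motif_n_random: int = 1000
    n_swap_factor: float = 10.0
    motif_min_occurrence: int = 6
    motif_p_max: float = 0.05
    motif_z_min: float = 2.2
    # bow-tie analysis
    perm_n_random: int = 5000
    degree_norm: str = "source"
    kappa: float = 2.0
    tau_sym: float = 0.1
    write_graphml: bool = False

    def __post_init__(self) -> None:
        for name in ("hub_n_random", "sigma_n_random", "motif_n_random", "perm_n_random"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 < self.alpha < 1) or not (0 < self.motif_p_max < 1):
            raise ValueError("alpha and motif_p_max must lie in (0, 1)")
        if self.motif_z_min < 0 or self.motif_min_occurrence < 1:
            raise ValueError("motif thresholds out of range")
        if self.simulate is None and not (
            self.reference_nodes and self.reference_arcs and self.expression
        ):
            raise ValueError(
                "config needs either a simulation block or reference/expression paths"
            )

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulate", None)
        if sim is not None:
            sim = syn.GeneratorParams(**sim)
        plant = d.pop("plant", None)
        if plant is not None:
            plant = _plant_from_dict(plant)
        return cls(simulate=sim, plant=plant, **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _plant_from_dict(d: Mapping) -> syn.PlantSpec:
    hubs = tuple(
        syn.PlantedHub(
            role=h["role"],
            direction=h["direction"],
            target_degree=int(h["target_degree"]),
            tissues=tuple(h["tissues"]),
        )
        for h in d.get("planted_hubs", ())
    )
    motifs = tuple(
        syn.PlantedMotif(
            signature=mf.TriadSignature.from_string(m["signature"]),
            n_extra_instances=int(m["n_extra_instances"]),
            tissues=tuple(m["tissues"]),
        )
        for m in d.get("planted_motifs", ())
    )
    pb = d.get("planted_bowtie")
    bowtie = (
        syn.PlantedBowtie(
            n_input=int(pb["n_input"]),
            n_core=int(pb["n_core"]),
            n_output=int(pb["n_output"]),
        )
        if pb
        else None
    )
    return syn.PlantSpec(planted_hubs=hubs, planted_motifs=motifs, planted_bowtie=bowtie)


# -- stages ----------------------------------------------------------------


def run_simulate(cfg: PipelineConfig) -> tuple[nw.RegulatoryNetwork, nw.ExpressionProfile]:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.simulate is not None:
        logger.info("simulate: generating reference network (seed=%d)", cfg.simulate.seed)
        reference = syn.generate_reference(cfg.simulate, cfg.plant)
        profile = syn.generate_expression(cfg.simulate, reference)
    else:
        logger.info("simulate: loading reference from %s", cfg.reference_nodes)
        reference = nw.read_network(cfg.reference_nodes, cfg.reference_arcs, "reference")
        profile = nw.read_expression(cfg.expression)
        profile.validate_against(reference)
    nw.write_network(reference, out / "reference_nodes.tsv", out / "reference_arcs.tsv")
    nw.write_expression(profile, reference.vertices, out / "expression.tsv")
    if cfg.write_graphml:
        nw.write_graphml(reference, out / "reference.graphml")
    return reference, profile


def load_reference(cfg: PipelineConfig) -> tuple[nw.RegulatoryNetwork, nw.ExpressionProfile]:
    out = Path(cfg.outdir)
    reference = nw.read_network(
        out / "reference_nodes.tsv", out / "reference_arcs.tsv", "reference"
    )
    profile = nw.read_expression(out / "expression.tsv")
    return reference, profile


def run_build_trns(
    cfg: PipelineConfig,
    reference: nw.RegulatoryNetwork | None = None,
    profile: nw.ExpressionProfile | None = None,
) -> list[nw.RegulatoryNetwork]:
    if reference is None:
        reference, profile = load_reference(cfg)
    out = Path(cfg.outdir)
    trns = []
    rows = []
    for t in profile.tissues:
        trn = nw.build_trn(reference, profile.expressed[t], label=t)
        trns.append(trn)
        nw.write_network(trn, out / f"trn_{t}_nodes.tsv", out / f"trn_{t}_arcs.tsv")
        nw.degree_table(trn).to_csv(out / f"trn_{t}_degrees.tsv", sep="\t", index=False)
        rows.append({"tissue": t, "n_vertices": trn.n_vertices, "n_arcs": trn.n_arcs})
        logger.info("trn %s: %d vertices, %d arcs", t, trn.n_vertices, trn.n_arcs)
    pd.DataFrame(rows).to_csv(out / "trn_sizes.tsv", sep="\t", index=False)
    return trns


def load_trns(cfg: PipelineConfig, tissues) -> list[nw.RegulatoryNetwork]:
    out = Path(cfg.outdir)
    return [
        nw.read_network(out / f"trn_{t}_nodes.tsv", out / f"trn_{t}_arcs.tsv", t)
        for t in tissues
    ]


def run_hubs(
    cfg: PipelineConfig,
    reference: nw.RegulatoryNetwork,
    trns: list[nw.RegulatoryNetwork],
) -> dict[str, dict[str, list[hb.HubCall]]]:
    """Hub calling per tissue and direction, profiles, and sigma_RF curves."""
    out = Path(cfg.outdir)
    calls: dict[str, dict[str, list[hb.HubCall]]] = {d: {} for d in nw.DIRECTIONS}
    call_rows = []
    for direction in nw.DIRECTIONS:
        for trn in trns:
            seed = stage_seed(cfg.seed, f"hubs:{direction}:{trn.label}")
            cs = hb.call_hubs(
                trn,
                direction,
                n_random=cfg.hub_n_random,
                alpha=cfg.alpha,
                seed=seed,
                role_preserving=cfg.role_preserving_null,
            )
            calls[direction][trn.label] = cs
            call_rows += [
                {
                    "gene_id": c.gene_id,
                    "tissue": c.tissue,
                    "direction": c.direction,
                    "observed_degree": c.observed_degree,
                    "p_value": c.p_value,
                    "is_hub": int(c.is_hub),
                }
                for c in cs
            ]
            logger.info(
                "hubs %s/%s: %d hubs (seed=%d)",
                trn.label,
                direction,
                sum(c.is_hub for c in cs),
                seed,
            )
    pd.DataFrame(call_rows).to_csv(out / "hub_calls.tsv", sep="\t", index=False)

    prof_rows = []
    for direction in nw.DIRECTIONS:
        profiles = hb.build_hub_profiles(reference, trns, calls[direction], direction)
        for p in profiles:
            prof_rows.append(
                {
                    "gene_id": p.gene_id,
                    "role": p.role,
                    "direction": p.direction,
                    "n_tissues": p.n_tissues,
                    "n_expressed": p.n_expressed,
                    "n_hub": p.n_hub,
                    "si": p.si,
                    "strength": p.strength,
                    "mean_active_ratio": (
                        sum(p.active_ratios.values()) / len(p.active_ratios)
                        if p.active_ratios
                        else float("nan")
                    ),
                }
            )
    pd.DataFrame(prof_rows).to_csv(out / "hub_profiles.tsv", sep="\t", index=False)

    sig_rows = []
    for direction in nw.DIRECTIONS:
        for role in nw.ROLES:
            any_hub = any(
                c.is_hub and reference.roles.get(c.gene_id) == role
                for t in calls[direction]
                for c in calls[direction][t]
            )
            if not any_hub:
                continue
            curve = hb.sigma_rf(
                trns,
                calls[direction],
                direction,
                role,
                n_random=cfg.sigma_n_random,
                seed=stage_seed(cfg.seed, f"sigma:{direction}:{role}"),
                mode=cfg.sigma_mode,
            )
            for pt in curve.points:
                sig_rows.append(
                    {
                        "direction": direction,
                        "role": role,
                        "si": pt.si,
                        "rf_real": pt.rf_real,
                        "rf_rand_mean": pt.rf_rand_mean,
                        "rf_rand_sd": pt.rf_rand_sd,
                        "sigma_rf": pt.sigma_rf,
                        "sd_zero": int(pt.sd_zero),
                    }
                )
    pd.DataFrame(
        sig_rows,
        columns=[
            "direction",
            "role",
            "si",
            "rf_real",
            "rf_rand_mean",
            "rf_rand_sd",
            "sigma_rf",
            "sd_zero",
        ],
    ).to_csv(out / "sigma_rf.tsv", sep="\t", index=False)
    return calls


def run_motifs(
    cfg: PipelineConfig, trns: list[nw.RegulatoryNetwork]
) -> tuple[dict[str, list[mf.MotifStat]], mf.MotifCatalog]:
    out = Path(cfg.outdir)
    stats_by_tissue: dict[str, list[mf.MotifStat]] = {}
    rows = []
    inst_rows = []
    for trn in trns:
        seed = stage_seed(cfg.seed, f"motifs:{trn.label}")
        stats = mf.motif_significance(
            trn,
            n_random=cfg.motif_n_random,
            seed=seed,
            n_swap_factor=cfg.n_swap_factor,
            min_occurrence=cfg.motif_min_occurrence,
            p_max=cfg.motif_p_max,
            z_min=cfg.motif_z_min,
        )
        stats_by_tissue[trn.label] = stats
        logger.info(
            "motifs %s: %d signatures, %d significant (seed=%d)",
            trn.label,
            len(stats),
            sum(s.significant for s in stats),
            seed,
        )
        for s in stats:
            rows.append(
                {
                    "tissue": s.tissue,
                    "signature": str(s.signature),
                    "structure": mf.classify_structure(s.signature),
                    "occurrence": s.occurrence,
                    "rand_mean": s.rand_mean,
                    "rand_sd": s.rand_sd,
                    "z_score": s.z_score,
                    "p_value": s.p_value,
                    "significant": int(s.significant),
                    "z_undefined": int(s.z_undefined),
                }
            )
            for inst in s.instances:
                inst_rows.append(
                    {
                        "tissue": s.tissue,
                        "signature": str(s.signature),
                        "gene_1": inst[0],
                        "gene_2": inst[1],
                        "gene_3": inst[2],
                    }
                )
    pd.DataFrame(rows).to_csv(out / "motif_stats.tsv", sep="\t", index=False)
    pd.DataFrame(inst_rows).to_csv(out / "motif_instances.tsv", sep="\t", index=False)
    catalog = mf.classify_cm_ts(stats_by_tissue, [t.label for t in trns])
    pd.DataFrame(
        [
            {
                "signature": str(s),
                "structure": e.structure,
                "label": e.label,
                "n_tissues_significant": len(e.significant_in),
                "tissues": ",".join(sorted(e.significant_in)),
            }
            for s, e in sorted(catalog.entries.items())
        ]
    ).to_csv(out / "motif_catalog.tsv", sep="\t", index=False)
    return stats_by_tissue, catalog


def collect_instances(
    stats_by_tissue: Mapping[str, list[mf.MotifStat]],
    catalog: mf.MotifCatalog,
    tissue: str,
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]]]:
    """Per-tissue CM and TS instance lists for the bow-tie stage.

    CM instances are all instances of CM-labeled signatures in this tissue;
    TS instances are instances of TS-labeled signatures that are themselves
    significant in this tissue (a tissue without significant TS motifs, the
    liver case, therefore has an empty TS part).
    """
    cm_sigs = set(catalog.signatures(mf.CM))
    ts_sigs = set(catalog.signatures(mf.TS))
    cm_inst, ts_inst = [], []
    for s in stats_by_tissue.get(tissue, ()):
        if s.signature in cm_sigs:
            cm_inst += s.instances
        elif s.signature in ts_sigs and s.significant:
            ts_inst += s.instances
    return cm_inst, ts_inst


def run_bowtie(
    cfg: PipelineConfig,
    trns: list[nw.RegulatoryNetwork],
    stats_by_tissue: Mapping[str, list[mf.MotifStat]],
    catalog: mf.MotifCatalog,
) -> dict[str, bt.BowTieDecomposition]:
    out = Path(cfg.outdir)
    decomps = {}
    layer_rows, stat_rows, pattern_rows = [], [], []
    for trn in trns:
        t = trn.label
        cm_inst, ts_inst = collect_instances(stats_by_tissue, catalog, t)
        if not cm_inst and not ts_inst:
            logger.info("bowtie %s: no CM/TS motif instances, skipping", t)
            pattern_rows.append(
                {
                    "tissue": t,
                    "sr_input": float("nan"),
                    "sr_core": float("nan"),
                    "sr_output": float("nan"),
                    "pattern": "empty",
                    "degenerate": 1,
                }
            )
            continue
        d = bt.decompose(
            t, cm_inst, ts_inst, trn, norm=cfg.degree_norm, kappa=cfg.kappa,
            tau_sym=cfg.tau_sym,
        )
        decomps[t] = d
        for layer, genes in d.layers.items():
            for g in sorted(genes):
                layer_rows.append(
                    {"tissue": t, "gene_id": g, "layer": layer, "role": trn.roles[g]}
                )
        if len(d.union) >= 3:
            perm = bt.permutation_test(
                d,
                trn,
                n_random=cfg.perm_n_random,
                seed=stage_seed(cfg.seed, f"bowtie:{t}"),
                norm=cfg.degree_norm,
            )
            for layer in bt.LAYERS:
                for role in (nw.TF, nw.MIRNA, nw.NONTF):
                    stat_rows.append(
                        {
                            "tissue": t,
                            "statistic": f"fraction_{role}",
                            "set": layer,
                            "real": perm.comp_real.loc[layer, role],
                            "p_high": perm.comp_p_high.loc[layer, role],
                            "p_low": perm.comp_p_low.loc[layer, role],
                        }
                    )
                for lj in bt.LAYERS:
                    name = f"avg_degree_{layer}" if layer == lj else f"avg_degree_{layer}_to_{lj}"
                    stat_rows.append(
                        {
                            "tissue": t,
                            "statistic": name,
                            "set": layer,
                            "real": perm.deg_real.loc[layer, lj],
                            "p_high": perm.deg_p_high.loc[layer, lj],
                            "p_low": perm.deg_p_low.loc[layer, lj],
                        }
                    )
        sr = d.size_ratios
        pattern_rows.append(
            {
                "tissue": t,
                "sr_input": sr[0],
                "sr_core": sr[1],
                "sr_output": sr[2],
                "pattern": d.pattern.pattern,
                "degenerate": int(d.pattern.degenerate),
            }
        )
        logger.info("bowtie %s: SR=%s pattern=%s", t, sr, d.pattern)
    pd.DataFrame(layer_rows).to_csv(out / "bowtie_layers.tsv", sep="\t", index=False)
    pd.DataFrame(stat_rows).to_csv(out / "bowtie_stats.tsv", sep="\t", index=False)
    pd.DataFrame(pattern_rows).to_csv(out / "bowtie_patterns.tsv", sep="\t", index=False)
    return decomps


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write a consolidated plain-text summary."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    reference, profile = run_simulate(cfg)
    trns = run_build_trns(cfg, reference, profile)
    calls = run_hubs(cfg, reference, trns)
    stats_by_tissue, catalog = run_motifs(cfg, trns)
    decomps = run_bowtie(cfg, trns, stats_by_tissue, catalog)

    lines = [
        "tissuenet pipeline summary",
        f"seed: {cfg.seed}",
        f"reference: {reference.n_vertices} vertices, {reference.n_arcs} arcs",
        "",
        "TRN sizes:",
    ]
    for t in trns:
        lines.append(f"  {t.label}: {t.n_vertices} vertices, {t.n_arcs} arcs")
    lines.append("")
    lines.append("hub counts by role and direction (distinct genes, any tissue):")
    for direction in nw.DIRECTIONS:
        for role in nw.ROLES:
            hubs_set = {
                c.gene_id
                for t in calls[direction]
                for c in calls[direction][t]
                if c.is_hub and reference.roles.get(c.gene_id) == role
            }
            lines.append(f"  {role} {direction}-hubs: {len(hubs_set)}")
    lines.append("")
    cm = catalog.signatures(mf.CM)
    ts = catalog.signatures(mf.TS)
    lines.append(f"motifs: {len(cm)} CM, {len(ts)} TS")
    for s in cm:
        lines.append(f"  CM {s} ({catalog.entries[s].structure})")
    for s in ts:
        e = catalog.entries[s]
        lines.append(
            f"  TS {s} ({e.structure}) significant in {len(e.significant_in)} tissues"
        )
    lines.append("")
    lines.append("bow-tie patterns:")
    for t in trns:
        if t.label in decomps:
            d = decomps[t.label]
            sr = tuple(round(x, 3) for x in d.size_ratios)
            lines.append(f"  {t.label}: SR(input,core,output)={sr} -> {d.pattern}")
        else:
            lines.append(f"  {t.label}: no CM/TS instances")
    summary = "\n".join(lines) + "\n"
    (out / "summary.txt").write_text(summary)
    logger.info("pipeline complete; summary written to %s", out / "summary.txt")
    return {
        "reference": reference,
        "profile": profile,
        "trns": trns,
        "hub_calls": calls,
        "motif_stats": stats_by_tissue,
        "catalog": catalog,
        "decompositions": decomps,
        "summary": summary,
    }
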