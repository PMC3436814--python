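"""Generate the synthetic reference network and tissue expression profiles.

Writes reference_nodes.tsv / reference_arcs.tsv / expression.tsv under
results/analysis and reports basic descriptive statistics of what was
generated, including the planted structures the later stages should find.
"""

import logging

import numpy as np

from config import make_config
from tissuenet import inverse_cumulative_distribution
from tissuenet.pipeline import run_simulate

logging.basicConfig(level=logging.INFO)


def main() -> None:
    cfg = make_config()
    reference, profile = run_simulate(cfg)
    print(f"reference network: {reference.n_vertices} genes, {reference.n_arcs} arcs")
    for role in ("TF", "miRNA", "nonTF"):
        genes = reference.genes_with_role(role)
        outd = reference.out_degrees()
        degs = sorted(outd[g] for g in genes)
        print(
            f"  {role}: {len(genes)} genes, out-degree median {np.median(degs):.0f}, "
            f"max {max(degs)}"
        )
    outd = reference.out_degrees()
    reg_degs = [d for g, d in outd.items() if reference.roles[g] != "nonTF" and d > 0]
    curve = inverse_cumulative_distribution(reg_degs)
    print(
        "  regulator out-degree inverse cumulative curve spans "
        f"k={curve[0][0]}..{curve[-1][0]} (heavy tail: top degree "
        f"{curve[-1][0]} vs median {int(np.median(reg_degs))})"
    )
    sizes = [len(profile.expressed[t]) for t in profile.tissues]
    print(f"expression: {len(profile.tissues)} tissues, {min(sizes)}-{max(sizes)} genes each")
    rec = reference.plants
    print(
        f"planted: {len(rec.hubs)} hubs, {len(rec.motifs)} motif enrichments, "
        f"bow-tie layers "
        f"{len(rec.bowtie['input'])}/{len(rec.bowtie['core'])}/{len(rec.bowtie['output'])}"
    )


if __name__ == "__main__":
    main()
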