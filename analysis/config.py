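"""Shared configuration for the numbered analysis scripts.

One synthetic study at the package's default conditions: a 500-gene
reference (100 TF, 50 miRNA, 350 non-TF, mean regulator out-degree 5,
Pareto tail exponent 2) filtered into 8 tissue networks (housekeeping
fraction 0.5, tissue-specific fraction 0.2), with planted structure so
every analysis stage has known signal to find: a TF in-hub and a miRNA
out-hub shared by all tissues, one tissue-restricted feed-forward motif
(3 of 8 tissues), one ubiquitous feed-forward motif (all 8), and a
bow-tie with layer sizes 40/6/20.

Ensemble sizes: 2000 ER networks per hub test and 5000 label permutations
per bow-tie test (the full standard sizes); 300 switch-randomized
networks per motif test and 1000 degree redistributions for sigma_RF, both
scaled down from 1000/2000 to keep a full desktop run in minutes.
"""

from tissuenet import (
    GeneratorParams,
    PipelineConfig,
    PlantedBowtie,
    PlantedHub,
    PlantedMotif,
    PlantSpec,
    canonical_signature,
)

SEED = 20260921
OUTDIR = "results/analysis"

FFL_TTN = canonical_signature(("TF", "TF", "nonTF"), 0b001011)
FFL_MTN = canonical_signature(("miRNA", "TF", "nonTF"), 0b001011)

ALL_TISSUES = tuple(f"tissue_{i + 1}" for i in range(8))


def make_config() -> PipelineConfig:
    return PipelineConfig(
        seed=SEED,
        outdir=OUTDIR,
        simulate=GeneratorParams(seed=SEED),
        plant=PlantSpec(
            planted_hubs=(
                PlantedHub("TF", "in", 25, ALL_TISSUES),
                PlantedHub("miRNA", "out", 30, ALL_TISSUES),
            ),
            planted_motifs=(
                PlantedMotif(FFL_TTN, 30, ALL_TISSUES),
                PlantedMotif(FFL_MTN, 30, ALL_TISSUES[:3]),
            ),
            planted_bowtie=PlantedBowtie(n_input=40, n_core=6, n_output=20),
        ),
        hub_n_random=2000,
        sigma_n_random=1000,
        motif_n_random=300,
        perm_n_random=5000,
    )
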