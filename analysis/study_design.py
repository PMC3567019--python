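"""Shared study design for the analysis scripts.

A desk-scale rendition of a two-origin SNP-chip survey: five native
populations (lower divergence, one admixed with a commercial breed, one
loaded with long autozygous tracts), three commercial populations (higher
divergence from the ancestral pool, longer LD), and a handful of planted
selection outliers distinguishing the "highland" population from the rest.
"""

from pathlib import Path

from snppop import (
    AdmixtureSpec,
    PlantedRoh,
    PopulationSpec,
    SimulationConfig,
)

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"
PANEL_PREFIX = SCRATCH / "panel"

#: native vs commercial super-groups, used for the common-subset MAF rule,
#: the headline F_ST contrast, and pooled-LD comparisons
GROUPS = {
    "native": ["HIGHLAND", "NATIVE1", "NATIVE2", "INBRED", "ADMIXED"],
    "commercial": ["COMM1", "COMM2", "COMM3"],
}

#: contrast design for the selection scan: highland vs everything else
HIGHLAND_CONTRAST = {
    "HIGHLAND": "highland",
    **{p: "lowland" for p in
       ["NATIVE1", "NATIVE2", "INBRED", "ADMIXED", "COMM1", "COMM2", "COMM3"]},
}

OUTLIER_LOCI = {400: 0.85, 1400: 0.9, 2400: 0.8}


def study_config(seed: int = 20260930) -> SimulationConfig:
    return SimulationConfig(
        seed=seed,
        n_snps=3000,
        snp_spacing_bp=20_000,
        n_chromosomes=3,
        populations=[
            PopulationSpec("HIGHLAND", 16, 0.12),
            PopulationSpec("NATIVE1", 20, 0.10),
            PopulationSpec("NATIVE2", 12, 0.12),
            PopulationSpec("INBRED", 10, 0.18),
            PopulationSpec("ADMIXED", 12, 0.12),
            PopulationSpec("COMM1", 16, 0.25),
            PopulationSpec("COMM2", 16, 0.25),
            PopulationSpec("COMM3", 8, 0.28),
        ],
        admixture=AdmixtureSpec("ADMIXED", "NATIVE1", "COMM1", fraction=0.5),
        ld_beta_per_kb={
            "HIGHLAND": 0.03, "NATIVE1": 0.03, "NATIVE2": 0.025,
            "INBRED": 0.008, "ADMIXED": 0.03,
            "COMM1": 0.012, "COMM2": 0.012, "COMM3": 0.01,
        },
        planted_roh=[
            PlantedRoh("INBRED", i, "1", 2_000_000 + 2_500_000 * i, 1_500_000)
            for i in range(6)
        ],
        outlier_loci=OUTLIER_LOCI,
        missing_rate=0.02,
    )
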