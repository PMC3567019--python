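"""Simulate the study panel and write it in PLINK text format.

Output: scratch/analysis/panel.{ped,map,pop} plus a JSON echo of the
simulation config (large raw genotype files stay under scratch/).
"""

from study_design import PANEL_PREFIX, SCRATCH, study_config

from snppop.simulate import write_simulation


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    cfg = study_config()
    panel = write_simulation(cfg, PANEL_PREFIX)
    print(
        f"simulated {panel.n_samples} diploids x {panel.n_snps} SNPs "
        f"in {panel.markers.chromosome.nunique()} chromosomes"
    )
    print("populations:", ", ".join(panel.population_names()))
    print(f"planted outliers at SNP indices {sorted(cfg.outlier_loci)}")
    print(f"wrote {PANEL_PREFIX}.ped/.map/.pop")


if __name__ == "__main__":
    main()
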