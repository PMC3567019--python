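"""Population structure: LD pruning and PCA.

Output: results/pca_scores.tsv (per-sample scores on the top components).
"""

import pandas as pd

from study_design import PANEL_PREFIX, RESULTS

from snppop import filter_snps, ld_prune, pca, read_plink_text


def main() -> None:
    panel = read_plink_text(
        f"{PANEL_PREFIX}.ped", f"{PANEL_PREFIX}.map", f"{PANEL_PREFIX}.pop"
    )
    filtered, _ = filter_snps(panel)
    pruned, kept = ld_prune(filtered, r2_threshold=0.2)
    print(f"LD pruning at r² >= 0.2: {len(kept)}/{filtered.n_snps} SNPs retained")

    res = pca(pruned, k=4)
    scores = pd.DataFrame(
        res.scores, index=res.samples, columns=[f"PC{i+1}" for i in range(4)]
    )
    scores.insert(0, "population", filtered.population_labels)
    RESULTS.mkdir(exist_ok=True)
    scores.to_csv(RESULTS / "pca_scores.tsv", sep="\t", float_format="%.4f")

    by_pop = scores.groupby("population").PC1.mean().sort_values()
    print("variance explained:", [f"{e:.1%}" for e in res.explained])
    print("mean PC1 per population (native vs commercial axis):")
    print(by_pop.round(2).to_string())
    lo = min(by_pop["NATIVE1"], by_pop["COMM1"])
    hi = max(by_pop["NATIVE1"], by_pop["COMM1"])
    print("ADMIXED sits between its sources:", lo < by_pop["ADMIXED"] < hi)


if __name__ == "__main__":
    main()
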