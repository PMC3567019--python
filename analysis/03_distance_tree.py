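"""Allele-sharing distances and the neighbor-joining tree of individuals.

Output: results/nj_tree.nwk (full distance matrix goes to scratch/).
"""

from study_design import PANEL_PREFIX, RESULTS, SCRATCH

from snppop import distance_matrix, filter_snps, read_plink_text
from snppop.distance import neighbor_joining


def main() -> None:
    panel = read_plink_text(
        f"{PANEL_PREFIX}.ped", f"{PANEL_PREFIX}.map", f"{PANEL_PREFIX}.pop"
    )
    filtered, _ = filter_snps(panel)
    dmat = distance_matrix(filtered)
    dmat.to_csv(SCRATCH / "distance_matrix.tsv", sep="\t", float_format="%.5f")

    tree = neighbor_joining(dmat)
    newick = tree.newick()
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "nj_tree.nwk").write_text(newick + "\n")

    # report whether the native/commercial split appears as a bipartition
    def tips(node):
        if node.is_leaf:
            return {node.label}
        out = set()
        for child, _ in node.children:
            out |= tips(child)
        return out

    splits = []

    def collect(node):
        for child, _ in node.children:
            splits.append(tips(child))
            collect(child)

    collect(tree)
    all_samples = set(filtered.samples)
    labels = filtered.population_labels
    mono = []
    for pop in filtered.population_names():
        members = {s for s, l in zip(filtered.samples, labels) if l == pop}
        if any(s == members or s == all_samples - members for s in splits):
            mono.append(pop)
    print(f"NJ tree over {len(all_samples)} individuals -> results/nj_tree.nwk")
    print(
        f"populations monophyletic in the unrooted tree: {len(mono)}/"
        f"{len(filtered.population_names())} ({', '.join(mono)})"
    )
    print("(the admixed population is expected to break up or attach to its sources)")


if __name__ == "__main__":
    main()
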