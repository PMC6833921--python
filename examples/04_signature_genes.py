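"""Extract per-class highly expressed genes and their intersections.

Each column of the basis matrix W is one class's expression signature.
The top-weighted genes per class, and the overlap of those lists between
classes, measure how much transcriptional identity classes share.
"""

from scgnmf import (
    SolverConfig,
    factorize,
    planted_matrix,
    shared_genes,
    top_genes,
)

x, truth = planted_matrix(n=500, m=8, r=4, signal_genes_per_class=30,
                          noise_sigma=0.02, seed=5)
model = factorize(x, r=4, cfg=SolverConfig(seed=3))

lists = top_genes(model.W, list(x.gene_ids), k=30)
for c, genes in enumerate(lists, start=1):
    print(f"class {c}: top genes {genes[:5]} ...")

print()
for pair in ([1, 2], [1, 3], [2, 4]):
    count, _ = shared_genes(lists, pair)
    print(f"classes {pair}: {count} shared genes in their top-30 lists")
count_all, _ = shared_genes(lists, [1, 2, 3, 4])
print(f"all four classes: {count_all} shared genes")
print("\nPlanted classes have disjoint signal blocks, so intersections are")
print("near zero; on real cohorts they quantify shared transcriptional identity.")
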