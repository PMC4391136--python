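"""Select single-copy marker genes and co-occurring gene clusters.

From a genome-by-KO copy matrix (here: the simulator's 21-genome pool) this
selects KOs in the strict universal single-copy band (prevalence >= 91.5%,
conditional mean copy < 1.1) and the relaxed semi-universal band
[85%, 91.5%), then finds clusters of genes with near-identical
presence/absence patterns (pairwise Jaccard > 0.95, cliques of >= 5).
"""

import scgnorm as sg

pool, ko_length, markers, pathway = sg.build_genome_pool(seed=17)
content = sg.pool_content_matrix(pool, ko_length)

strict = sg.select_markers(content, 0.915, None, 1.1)
print(f"strict universal single-copy KOs: {len(strict)}")
try:
    semi = sg.select_markers(content, 0.85, 0.915, 1.1, role="semi_usicg")
    n_semi = len(semi)
except ValueError:
    n_semi = 0  # with only 21 genomes the relaxed band can be empty
print(f"semi-universal ({0.85:.0%} <= prevalence < {0.915:.1%}): {n_semi}")

res = sg.jaccard_cooccurrence(content, threshold=0.95, min_cluster_size=5)
print(f"co-occurring pairs (Jaccard > 0.95): {len(res.pairs)}")
print(f"clusters of >= 5 genes: {len(res.clusters)}")
if res.clusters:
    print("largest cluster size:", max(len(c) for c in res.clusters))

# In this synthetic pool, the planted markers and the invariant pathway
# dominate both bands: markers and pathway KOs are in every genome, and the
# pathway KOs form one large perfectly co-occurring cluster.
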