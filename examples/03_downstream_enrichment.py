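"""Downstream annotation of discovered biclusters.

Links one implant to a copy-number gain and a subtype label, rediscovers the
biclusters, and runs the enrichment battery: categorical (subtype) Fisher
tests, per-gene copy-number tests combined by Fisher's method, proximal-locus
classification, and Hamming clustering of the membership matrix.
"""

import pandas as pd

import tuba
from tuba.simulate import linked_cna_matrix, linked_labels

matrix, _ = tuba.default_benchmark(seed=42, n_genes=400)
# re-implant block 0 with CNA and subtype links for the demonstration
spec = tuba.ImplantSpec(gene_indices=tuple(range(20)),
                        sample_indices=tuple(range(10)),
                        effect=6.0, cna_linked=True, subtype_label="basal")
truth = tuba.TruthTable(seed=42)
matrix, truth = tuba.implant(matrix, spec, truth)

collection = tuba.run_tuba(matrix, tuba.RunConfig(percentile=0.05, cutoff=1e-8))
print(f"{len(collection)} biclusters")

labels = linked_labels(matrix, truth)
subtype = tuba.categorical_enrichment(collection, labels, "subtype")
print("\nsubtype enrichment (FDR < 0.05 marks subtype-specific biclusters):")
print(subtype[subtype["target"] == "basal"].to_string(index=False))

cna = linked_cna_matrix(matrix, truth, rng_seed=42)
gains = tuba.cna_enrichment_collection(collection, cna, direction="gain")
print("\ncopy-number gain enrichment (Fisher's method across member genes):")
print(gains.to_string(index=False))

# invent loci placing the first 20 genes within 2 Mb on chromosome 8
loci = pd.DataFrame({
    "gene_id": matrix.index[:40],
    "chromosome": ["8"] * 20 + ["1", "2", "3", "4"] * 5,
    "start": [1_000_000 + 100_000 * i for i in range(20)] + [5_000_000] * 20,
    "end": [1_050_000 + 100_000 * i for i in range(20)] + [5_100_000] * 20,
})
for b in collection:
    print(tuba.classify_proximal(b, loci))
# the CNA-linked bicluster is classified proximal: its genes sit in one
# 2 Mb window, the signature of a transcriptionally active amplicon.

samples = list(matrix.columns)
hc = tuba.membership_and_hamming_clustering(collection, samples)
print("\nbicluster merge tree (Hamming distance, average linkage):")
print(hc.newick)
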