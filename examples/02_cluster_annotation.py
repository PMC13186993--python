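"""Taxonomic annotation of orthogroup clusters.

Assigns each cluster its last-common-ancestor (LCA) rank — the deepest of
the eight ranks at which all member genomes share one non-absent taxon —
plus genus-ORFan status, paralog bins of a focal genome, and virion-shape
class.
"""

from gvortho import synthetic as syn
from gvortho import taxonomy as tx

universe, taxonomy, seq_edges, struct_edges, truth = syn.simulate_orthogroups(
    n_genomes=15, n_groups=25, seed=4)
clustering = syn.truth_clustering(truth)
focal = sorted(set(truth.genome_of.values()))[0]

annotations = tx.annotate_clusters(clustering, truth.genome_of, taxonomy,
                                   focal_genome=focal)
hist = tx.lca_histogram(annotations)
print("conservation profile (clusters per LCA rank, deepest first):")
for rank, count in hist.items():
    if count:
        print(f"  {rank:>13}: {count}")
# Deep ranks (species/genus) mean narrowly conserved clusters; shallow
# ranks mean the cluster spans distant lineages.

orfans = [a for a in annotations.values() if a.is_genus_orfan]
print(f"genus ORFans of {focal}'s genus: {len(orfans)} clusters")
paralog_rich = [a for a in annotations.values() if a.paralog_count >= 2]
print(f"clusters with >= 2 {focal} paralogs: {len(paralog_rich)}")
mixed = sum(1 for a in annotations.values() if a.shape_class == "mixed")
print(f"clusters spanning icosahedral and non-icosahedral virions: {mixed}")
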