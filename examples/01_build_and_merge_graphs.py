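"""Build a curated graph and a literature graph, then merge them.

A tiny curated edge table (gene-disease, compound-gene relations) is fused
with co-occurrence edges extracted from two annotated abstracts, using a
synonym lexicon to recognize that "msg1" is the gene "cited1".
"""

import io

from kgpathrank import (
    LexiconEntry,
    MergeConfig,
    SynonymLexicon,
    cooccurrence_graph,
    mapping_for_graphs,
    merge_graphs,
    read_edge_table,
    read_pubtator,
)

CURATED = """\
head,head_type,relation,tail,tail_type,weight
cited1,gene,GENE_DISEASE,rheumatoid arthritis,disease,1
chloroquine,compound,COMPOUND_GENE,cited1,gene,1
"""

CORPUS = """\
101|t|msg1 expression in arthritis
101|a|We measured msg1 alongside chloroquine treatment.
101\t0\t4\tmsg1\tGene\tX1
101\t28\t39\tchloroquine\tChemical\tD002738
101\t19\t28\tarthritis\tDisease\tD001168

102|t|chloroquine and arthritis
102|a|A second study of chloroquine in arthritis.
102\t0\t11\tchloroquine\tChemical\tD002738
102\t16\t25\tarthritis\tDisease\tD001168
"""

curated = read_edge_table(io.StringIO(CURATED), sources=frozenset({"AG"}))
literature = cooccurrence_graph(read_pubtator(io.StringIO(CORPUS)))
print(f"curated:    {curated.entity_count} entities, {curated.edge_count} edges")
print(f"literature: {literature.entity_count} entities, "
      f"{literature.edge_count} edges")

lexicon = SynonymLexicon([
    LexiconEntry("cited1", "gene", frozenset({"msg1"})),
])
cfg = MergeConfig(similarity_threshold=0.95)
mapping = mapping_for_graphs(curated, literature, lexicon, cfg)
merged, report = merge_graphs(curated, literature, mapping, cfg,
                              with_report=True)

print(f"merged:     {merged.entity_count} entities, {merged.edge_count} edges")
print(f"absorbed {report.entities_absorbed} duplicate entity "
      f"(msg1 -> cited1), combined {report.cooccur_pairs_combined} "
      f"co-occurrence pairs")
cited1 = merged.find_by_name("cited1", "gene")[0]
print(f"cited1 synonyms after merge: {sorted(cited1.synonyms)}")
# The gene now carries both its curated edges and the literature evidence:
print(f"cited1 degree in merged graph: {merged.degree(cited1.entity_id)}")
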