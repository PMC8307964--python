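"""Work with the bundled published top-ranked path records.

Two drug-repurposing case studies ship with the package as plain-text path
records: IL-6 receptor -> hydroxychloroquine and STAT1 -> chloroquine.
This example counts their per-depth blocks and the distinct relationships
they cover under both counting conventions.
"""

from kgpathrank import count_distinct_relationships, load_case_study

for case in ("il6_receptor_hydroxychloroquine", "stat1_chloroquine"):
    records = load_case_study(case)
    print(f"\n{case}: {len(records)} records")
    for depth in (2, 3, 4):
        block = [p for d, p, _ in records if d == depth]
        if not block:
            continue
        clean = [p for p in block if p.depth == depth]
        typed = count_distinct_relationships(clean, typed=True)
        untyped = count_distinct_relationships(clean, typed=False)
        note = ""
        if len(clean) != len(block):
            note = f" ({len(block) - len(clean)} row(s) with mismatched depth)"
        print(f"  depth {depth}: {len(clean)} records{note}, "
              f"{typed} typed relationships, {untyped} distinct node pairs")

# Typed counting distinguishes gene_gene from co_occur between the same
# node pair; untyped counting collapses them, which is why the STAT1 depth-3
# block covers 15 node pairs but many more typed triples.
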