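"""Count exclusive Venn regions of candidate sets across patients.

Inter-individual variance makes candidate overlap across patients small and
therefore informative; the same gene can also surface on different exons in
different patients, which an optional feature-to-gene collapse makes visible.
"""

from liqtrace import collapse_to_genes, overlap_counts

candidates = {
    "P1": {"TMSB4X_ex2", "EEF1G_ex1", "OAZ1_ex5"},
    "P2": {"TMSB4X_ex2", "EEF1G_ex3", "SNORD141B"},
    "P5": {"SORL1_ex10", "OAZ1_ex5"},
}

table = overlap_counts(candidates)
print("Exon-level exclusive regions (non-empty):")
for subset, n in sorted(table.regions.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))):
    if n:
        print(f"  {'+'.join(sorted(subset))}: {n}")

gene_map = {f: f.split("_")[0] for f in set().union(*candidates.values())}
collapsed = overlap_counts(collapse_to_genes(candidates, gene_map))
print("\nAfter collapsing exons to genes (EEF1G now overlaps P1 and P2):")
for subset, n in sorted(collapsed.regions.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))):
    if n:
        print(f"  {'+'.join(sorted(subset))}: {n}")
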