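"""Restriction digest of a toy chromosome and fragment assignment.

Cuts a short sequence at every GATC (MboI chemistry), then assigns a SNP
(a point, 1-based) and a gene region (0-based half-open) to the resulting
fragments.
"""

import pandas as pd

from spatialeqtl import assign_genes_to_fragments, assign_snps_to_fragments, digest_genome

seq = "AAGATCTTGATCAAACCGGTTGATCCA"
fragments = digest_genome({"chr1": seq})
print("fragments:")
print(fragments.to_string(index=False))

snp = pd.DataFrame({"rsid": ["rs1"], "chrom": ["chr1"], "pos": [10]})
print("\nSNP rs1 (pos 10, 1-based) lands on fragment:",
      int(assign_snps_to_fragments(snp, fragments)["fragment"][0]))

gene = pd.DataFrame({"gene_id": ["geneA"], "chrom": ["chr1"], "start": [4], "end": [20]})
hits = assign_genes_to_fragments(gene, fragments)
print("geneA [4, 20) overlaps fragments:", list(hits["fragment"]))
# The SNP maps to exactly one fragment; the gene claims every fragment it
# touches by >= 1 bp -- no padding is applied around fragments.
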