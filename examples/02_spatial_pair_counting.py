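"""Fragment-interaction vs supporting-interaction bookkeeping.

Reconstructs the canonical counting example: a SNP fragment contacts gene
fragment A once (cell line CL1, replicate R1) and gene fragment B three
times (CL1-R1, CL1-R2, CL2-R1).  The SNP-gene pair therefore has 2
distinct fragment interactions carried by 4 supporting interactions.
"""

import pandas as pd

from spatialeqtl import find_spatial_pairs
from spatialeqtl.interactions import INTERACTION_COLUMNS

snp = pd.DataFrame({"rsid": ["rs1"], "chrom": ["chr1"], "fragment": [3]})
gene = pd.DataFrame({"gene_id": ["geneA"] * 2, "chrom": ["chr1"] * 2, "fragment": [7, 8]})


def contact(frag2, cell_line, replicate):
    row = [["read", 0, "chr1", 1, 3, 16, "chr1", 1, frag2]]
    return pd.DataFrame(row, columns=INTERACTION_COLUMNS).assign(
        cell_line=cell_line, replicate=replicate
    )


tables = [
    pd.concat([contact(7, "CL1", "R1"), contact(8, "CL1", "R1")], ignore_index=True),
    contact(8, "CL1", "R2"),
    contact(8, "CL2", "R1"),
]
pairs, observations = find_spatial_pairs(snp, gene, tables)
print(pairs.to_string(index=False))
# fragment_interactions counts distinct (SNP fragment, gene fragment)
# contacts; supporting_interactions counts every replicate-level
# observation across cell lines.
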