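"""Integrate per-gene regulatory features and inspect the evasion rule.

Three genes with 3' UTR annotations and miRNA-family target predictions:
one gene can shed all sites of a family by switching to its short UTR
(alternative polyadenylation), one cannot, one has a single UTR.
"""

import pandas as pd

from rbpkit.features import build_feature_table, mirna_evasion

gene_model = pd.DataFrame(
    [("gX", "gX.p1"), ("gX", "gX.p2"), ("gY", "gY.p1"), ("gZ", "gZ.p1")],
    columns=["gene_id", "protein_id"],
)

utrs = pd.DataFrame(
    [
        ("gX", "gX.u1", 300, "chrI", 1000, 1300, "+"),
        ("gX", "gX.u2", 120, "chrI", 1000, 1120, "+"),
        ("gY", "gY.u1", 250, "chrI", 5000, 5250, "+"),
        ("gY", "gY.u2", 150, "chrI", 5000, 5150, "+"),
        ("gZ", "gZ.u1", 200, "chrII", 100, 300, "+"),
    ],
    columns=["gene_id", "utr_id", "length", "chrom", "start", "end", "strand"],
)

predictions = pd.DataFrame(
    [("gX.u1", "miR-fam-a", 2), ("gY.u1", "miR-fam-b", 1), ("gY.u2", "miR-fam-b", 1)],
    columns=["utr_id", "mirna_family", "n_sites"],
)

table = build_feature_table(gene_model, utrs=utrs, predictions=predictions)
print(table.to_string(index=False))

print("\nevadable families per gene:", mirna_evasion(predictions, utrs))

# gX has two distinct 3' UTR isoforms (uses_apa True) and miR-fam-a sites
# only in the long one, so it can evade that family; gY's family has sites
# in both isoforms (nothing to lose); single-UTR gZ can never evade.
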