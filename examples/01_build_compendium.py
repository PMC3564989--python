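"""Build an RBP compendium from a tiny hand-written domain scan.

Six genes: two with sequence-specific domains (KH; RRM+CCCH), one
argonaute-like gene (PAZ+PIWI), one non-RBP (WD40 only), one removed and
one added by manual curation.
"""

import tempfile
from pathlib import Path

import pandas as pd

from rbpkit.compendium import CurationList, build_compendium

SCAN = """\
geneA.p1\t-\t400\tHMMPfam\tPF00013\tKH_domain\t10\t80\t1e-12
geneB.p1\t-\t350\tHMMPfam\tPF00076\tRRM_domain\t5\t75\t1e-10
geneB.p2\t-\t500\tHMMSmart\tSM0999\tCCCH\t200\t230\t1e-6
geneC.p1\t-\t900\tHMMPfam\tPF02170\tPAZ_domain\t50\t160\t1e-20
geneC.p1\t-\t900\tHMMPfam\tPF02171\tPiwi_domain\t400\t700\t1e-30
geneD.p1\t-\t300\tHMMPfam\tPF00400\tWD40\t20\t60\t1e-8
geneE.p1\t-\t280\tHMMPfam\tPF00013\tKH_domain\t30\t100\t1e-9
"""

gene_model = pd.DataFrame(
    [(f"gene{c}", f"gene{c}.p{i}") for c in "ABCDEF" for i in (1, 2)],
    columns=["gene_id", "protein_id"],
)

curation = CurationList(
    removals={("geneE", "domain-length")},
    additions={("geneF", "literature-supported RGG-box protein", None)},
)

with tempfile.TemporaryDirectory() as tmp:
    scan_path = Path(tmp) / "scan.tsv"
    scan_path.write_text(SCAN)
    records, log = build_compendium(scan_path, gene_model, curation=curation)

print("stage counts:", log)
for gene_id, rec in sorted(records.items()):
    rbds = ",".join(sorted(n for n, _ in rec.rbds)) or "-"
    print(f"{gene_id}: group {rec.assigned_group}  RBDs [{rbds}]  ({rec.provenance})")

# Expected: geneA and geneB are group 1 (sequence-specific domains), geneC
# group 2 (specificity supplied by the loaded miRNA, not the domain),
# geneD is no RBP, geneE is curated away and geneF curated in as group 1.
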