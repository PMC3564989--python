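# File formats

All tables are UTF-8, tab-separated, with a header row unless noted.
Genomic coordinates are 0-based half-open and stranded (BED convention);
amino-acid positions are 1-based inclusive.

## Domain scan (`scan.tsv`, no header)

Classic InterProScan raw dialect: protein id, checksum, length,
application, accession, name, start, end, e-value, status, date,
InterPro id, InterPro description. Trailing columns may be missing; the
first eight are required. Application spellings are normalised
(`HMMPfam`→Pfam, `HMMSmart`→SMART, `superfamily`/`SSF`→Superfamily,
`ProfileScan`/`ScanRegExp`/`ProSitePatterns`/`ProSiteProfiles`→ProSite);
anything else becomes `other` and is dropped by the application filter.

## Gene model (`gene_model.tsv`)

`gene_id  protein_id  transcript_id` — one row per protein isoform. A
protein may map to exactly one gene. Gene ids are opaque, case-sensitive
keys; the isoform→gene mapping is never inferred from id suffixes.

## 3′ UTRs (`utrs.tsv`, optional `utrs.bed`)

`gene_id  utr_id  length [chrom start end strand]`. If interval columns
are present, `end − start` must equal `length`. The BED companion is
BED6 with `utr_id` in the name column.

## miRNA target predictions (`targets.tsv`)

`utr_id  mirna_family  n_sites` with `n_sites ≥ 1`; one row per
(UTR, family); duplicates collapse to the maximal site count.

## Regulator bindings (`bindings.tsv`)

`regulator_id  regulator_class  target_gene_id` with class in
{TF, RBP, CLIP}, events pre-assigned to genes.

## CLIP sites (`clip_sites.bed`)

BED6 intervals; strand is honoured during UTR intersection.

## Phosphosites (`phospho.tsv`)

`protein_id  residue_index [residue]`, 1-based residues.

## Detection list (`detected_genes.txt`)

One gene id per line, no header.

## Catalog (`catalog.tsv`)

`rbd_name  group  application  pattern  sequence_specific` — one row per
match pattern; `application = *` marks a name pattern valid under any
application.

## Curation (`curation.tsv`)

`action  gene_id  reason  group_override` with action in {add, remove};
`group_override` empty means the configured default (group 1).

## Gene sets (`sets.tsv`)

`set_name  gene_id` — one row per membership.

## Outputs

`compendium.tsv` (gene_id, group, rbds as `name:group;…`, provenance,
applications, protein_ids, note), `features.tsv` (one row per gene, NA
marks unannotated), `enrichment.tsv` (one row per comparison),
`summary.json` (keyed `set|feature`), `run.log` (timestamps live only
here).
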