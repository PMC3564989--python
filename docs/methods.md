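# Methods

## The compendium model

A gene encodes an RBP when at least one of its protein isoforms carries at
least one domain from a 17-entry RBD catalog, as called by a domain scanner
and reported by one of four applications (Pfam, SMART, Superfamily,
ProSite). Hits from other applications are dropped before matching — those
four are the ones that detect RBDs reliably in this setting — so an RBD
accession reported only by, say, Gene3D never classifies a gene. Matching
is two-route: exact accession under a stated application, or
case-insensitive domain-name match under any application. An accession or
name claimed by two catalog entries is a configuration error raised at
catalog load, not at match time.

Isoform hits are collapsed to genes by set union (nonredundant: duplicated
rows never change the result). Group assignment is a fixed priority over
the groups present in a gene's RBD set: **1 > 3 > 2 > 4**. Group 1 first is
the sequence-specific-first principle; placing group 3 ahead of group 2
reflects that groups 1 and 3 are the putatively *sequence*-specific classes
while group 2's specificity is extrinsic to the domain. The priority is a
parameter of `assign_group` for users who prefer a different convention.
In practice the choice is consequential only for the handful of genes
carrying domains of two or more groups.

Manual curation is applied last: removals (over/under-length domain calls,
pseudogenes, missing homology) then additions (literature-supported RBPs,
e.g. RGG-box proteins, which have no usable domain signature and are
*only* supported via curation). Additions without an explicit group
override default to group 1, since literature-supported additions are
typically specific binders; the default is configurable and the shipped
curation list overrides the secondary-search additions (general factors:
deaminases, initiation factors, tRNA binders) to group 4.

The default catalog pins group 2 membership (helicase, PAZ, PIWI, NTF2)
and places the canonical exemplars (KH, RRM, CCCH, dsRBD in group 1; C2H2,
SAM in group 3). The remaining entries are reasonable defaults and are
deliberately editable: the catalog round-trips through a plain TSV and the
pipeline takes any catalog satisfying the ambiguity check. Projects with a
vetted accession list should substitute their own.

## Feature integration

All counting is idempotent under row duplication. Conventions that the
underlying data do not fix themselves, and how this package fixes them:

* **UTR distinctness.** Two 3′ UTR records of one gene are the same
  isoform iff their 3′-end coordinates coincide (interval `end` on the +
  strand, `start` on the −) when intervals are present, else iff their
  lengths coincide. Rationale: 3′-seq-style annotation defines a UTR
  isoform by its cleavage/poly(A) site. APA = ≥ 2 distinct isoforms.
* **miRNA evasion.** A family is evadable for a gene iff the gene has ≥ 2
  distinct UTR isoforms and the family has ≥ 1 predicted site in at least
  one isoform and 0 in at least one other — switching isoforms then loses
  *all* of that family's sites.
* **Representative UTR length.** The feature table stores one length per
  gene (`longest` by default; `shortest` available). Distribution
  comparisons of UTR length use the per-UTR multiset by default (each
  distinct UTR one observation), because the natural unit of a UTR-length
  distribution is the UTR; pass `utr_lengths` to the suite to enable it.
* **Coordinates.** Genomic intervals are 0-based half-open and stranded
  (BED); site→UTR assignment requires same chromosome, same strand, ≥ 1 nt
  overlap. Amino-acid positions are 1-based inclusive.
* **Phosphorylation.** Residues are counted as distinct
  (protein, residue) pairs, combined per gene across isoforms. No attempt
  is made to align homologous residues between isoforms; a site conserved
  in two isoforms counts twice. This is a documented limitation, not a
  bug — alignment would require the proteome sequences and a choice of
  aligner.
* **Missingness.** Absence means "unannotated" (NA) for UTR-derived
  features and for MS detection when no reference list is supplied; it
  means "none observed" (0) for bindings and phosphorylation. Frequency
  tests restrict their universe to non-missing genes.

## Statistics

Frequency features (multi-isoform, bound-by-≥1-RBP/TF, uses-APA,
miRNA-targeted, evades-≥1-family, phosphorylated) are tested with the
exact hypergeometric tail; count/length features (numbers of TFs, RBPs,
isoforms, miRNA families, phospho-residues, UTR length) with the
two-sample KS statistic. The routing is a fixed table, not inferred from
dtypes. Direction is the sign of k/n − K/N; both one-sided tails are
reported with the upper (enrichment) tail as the headline p-value, and
stars follow the tail matching the observed direction (so a significant
*depletion* is starred too). Raw p-values with the two-level star
convention (\* < 0.05, \*\* < 0.005) are the default; Benjamini–Hochberg
adjustment is an opt-in column, since the suite runs only a few dozen
pre-registered comparisons.

Set-vs-set mode (e.g. gene-specific RBPs against TFs) replaces the
universe with the union of the two sets for frequency tests and compares
the two value samples directly for KS. Identical sets therefore give
degenerate tests (p = 1, D = 0) rather than errors.

Numerical choices: hypergeometric tails come from exact pmf summation
(scipy's `hypergeom`), validated in the test suite against full subset
enumeration for every N ≤ 12 at 1e-12. KS uses the asymptotic two-sample
p-value, with an optional exact small-sample mode below combined n = 25;
D itself is exact and tie-safe (validated against a direct ECDF oracle).
Quartile edges use linear interpolation between order statistics
(numpy's default, "type 7"); the convention is configurable in effect by
pre-binning, and is irrelevant at study scale. Degenerate inputs raise:
empty samples, fewer than four distinct background values for quartiles,
groups with no detected members in the detection-normalised test (the
latter returns an explicit `undefined` flag rather than a p-value).

## The synthetic study

The generator emulates the study's input tables at their published
magnitudes, with one root seed and per-table derived substreams (adding a
table never perturbs another table's draws; same config + seed is
byte-identical).

Defaults and where they come from:

| parameter | default | basis |
|---|---|---|
| universe | 5,000 genes | scaled-down proteome; keeps group sizes at their printed values |
| group sizes | 250 / 169 / 226 / 279, TF set 234 | printed compendium group sizes; TF set scaled to genome proportion |
| UTR medians | 215 / 173 / 173 / 100 nt; background 129 nt | 215 (group 1), 100 (group 4) and 129 (transcriptome) are printed; 173 for groups 2–3 is solved so the pooled RBP median of the log-normal mixture is the printed 156 nt |
| UTR dispersion | σ = 0.9 (log scale) | right-skewed, positive lengths typical of metazoan 3′ UTR length distributions |
| multi-isoform | 30.4% (g1), 21.5% (g2–4), 14.4% background | 30.4% and 14.4% printed; 21.5% solves the pooled RBP fraction to the printed 23.9% |
| RBP binding | per-regulator 0.312 (g1–3), 0.481 (g4), 0.097 background; 3 regulators | solves ≥1-binder frequencies to the printed 73% (RBPs), 86% (group 4), 35% (transcriptome, which includes the RBP groups at this scale) |
| TF binding | 22 assayed regulators; per-regulator 0.10–0.18 | 22 ChIP-assayed TFs; binding probabilities chosen to give RBP promoters more bound TFs, magnitude unprinted |
| miRNA model | 120 families; per-(UTR, family) site probability 1 − exp(−r·L·m), r = 6.2e-6/nt, m = 1.5 for groups 1–3 | length-dependence lets tests separate length from targeting effects; r chosen so group-1 APA-mediated evasion lands above 15% and at more than twice the transcriptome rate, as published |
| APA | P(≥2 isoforms) 0.45 (g1) … 0.30 background; extra isoforms 1 + Poisson(0.25) | ~30% background APA usage typical of 3′-seq annotations; group-1 excess planted |
| phosphorylation | P(phospho) 0.25 (g1) … 0.08 (g4), 0.12 background; sites 1 + Poisson(mean−1) | background rate ≈ detected phosphoproteome fraction; ~2.9 sites/protein matches the published site/protein ratio |
| MS detection | 0.60 (g4) … 0.35 background | abundant general machinery is detected more readily — this planted bias is what the detection-normalised test corrects |

Distinct 3′ ends are enforced within a gene (ties nudged by +1 nt), so
generated isoforms are always distinct under the features module's rule.
Scan rows plant only the gene's own group's domains (exercising both the
accession and the name match route), plus non-catalog noise domains and
occasional RBD accessions under a rejected application as filter decoys.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: domain-call errors and boundary noise (the scan
is clean, so recovery of planted groups is exact by construction),
correlated regulators, shared miRNA sites between overlapping UTR isoforms
(site presence is drawn independently per isoform), expression- or
germline-driven ascertainment beyond the single planted MS detection bias,
and realistic miRNA site density (the chosen site rate yields ~0.1–0.5
conserved families per gene, below typical TargetScan density, as the
price of matching the published evasion percentages). Conclusions about
real proteomes require real scans and annotations through the same
interfaces.

## Problem sizes used by the checks

The test suite runs the null-calibration property on 200 independent null
studies of 2,000 genes (false-positive rate of upper-tail hypergeometric
p-values at 0.05 within [0.02, 0.08]; observed ≈ 0.026, mildly
conservative because the statistic is discrete) and the effect-recovery
property on 100 seeded studies at the default 5,000-gene scale (KS
rejection at p < 0.005 in ≥ 95 runs; per-run sample medians average
within 10% of 215/129 nt — single-run medians at ~375 group-1 UTRs carry
~6% sampling error, so the aggregate is the meaningful check).
`scripts/acceptance.py` runs one default-scale study end to end.
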