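# rbpkit

Predict, classify and analyse RNA-binding proteins (RBPs) from protein
domain-scan output, and test how RBP genes are themselves regulated.

RBPs sit at the centre of post-transcriptional gene regulation, yet unlike
transcription factors they have historically lacked genome-wide compendia
in multicellular model organisms. `rbpkit` implements the computational
half of building such a compendium for a proteome like *C. elegans*'s:
starting from InterProScan-style domain annotation, it keeps hits from the
four applications that detect RNA-binding domains reliably (Pfam, SMART,
Superfamily, ProSite), matches them against a curated 17-domain RBD
catalog, collapses protein isoforms to genes nonredundantly, classifies
each RBP gene into one of four groups, and applies a manual curation list:

* **Group 1** — sequence/structure-specific RBDs (KH, RRM, PUF, CCCH zinc
  finger, dsRBD, ...): *gene-specific* RBPs, conceptually analogous to TFs;
* **Group 2** — gene-specific binding whose specificity is extrinsic to
  the domain (helicase, PAZ, PIWI, NTF2 — e.g. argonautes guided by their
  loaded miRNA);
* **Group 3** — putatively specific domains that may bind DNA or protein
  instead (C2H2 zinc finger, SAM, ...);
* **Group 4** — general RNA-binding machinery (splicing, translation).

Tie-break: any group-1 domain wins, then 3 > 2 > 4.

Around the compendium, a feature-integration layer reduces public-style
datasets to one row per gene — protein isoform counts, TF (ChIP-seq) and
RBP (RIP-Chip) binders, 3′ UTR lengths, distinct 3′ UTR isoforms and
alternative polyadenylation (APA), miRNA-family target counts, miRNA
*evasion* (families whose sites are entirely lost in an alternative UTR
isoform), CLIP-site-to-UTR interval intersection, and phosphorylated
residues. A statistics layer then compares any gene set against a
background: frequency features via the exact hypergeometric tail
P(X ≥ k) for X ~ Hypergeom(N, K, n), count/length features via the
two-sample Kolmogorov–Smirnov statistic
D = sup<sub>x</sub> |F̂<sub>set</sub>(x) − F̂<sub>bg</sub>(x)|,
annotated with the conventional stars (\* p < 0.05, \*\* p < 0.005). Two
bias controls are built in: a quartile-binned comparison that holds UTR
length fixed while testing miRNA targeting, and a detection-normalised
phosphorylation test restricted to proteins observable in an independent
mass-spectrometry survey.

Because no raw datasets ship with the package, a synthetic-study
generator produces every input table (plus ground truth) with the
published effect magnitudes planted — group sizes 250/169/226/279 in a
5,000-gene universe, UTR medians 215/100/129 nt, multi-isoform fractions
30.4%/14.4%, RBP-binding frequencies ~73%/86%/35% — so the entire
pipeline runs and is tested end to end offline.

## Worked example

```sh
rbpkit simulate --out bundle --seed 1
rbpkit run-all --bundle bundle --out report --seed 1
```

or, from Python (`examples/04_synthetic_study.py`):

```text
gene-set sizes: {'RBP': 924, 'group1': 250, 'group2': 169, 'group3': 226, 'group4': 279}
group1|utr_len           ks              stat=0.213 p=4.85e-14 enriched [**]
group4|utr_len           ks              stat=0.209 p=4.69e-14 depleted [**]
RBP|multi_isoform        hypergeometric  stat=0.252 p=2.25e-17 enriched [**]
RBP|rbp_bound            hypergeometric  stat=0.755 p=2.74e-162 enriched [**]
group1|mirna_evasion     hypergeometric  stat=0.235 p=2.05e-10 enriched [**]
```

The compendium stage recovered the four planted groups exactly from the
domain scan (250 + 169 + 226 + 279 = 924 RBP genes). Gene-specific
(group-1) RBPs show the planted 3′ UTR lengthening (KS D = 0.21 against
the transcriptome, per-UTR values), general (group-4) RBPs the planted
shortening; RBP genes are enriched for multiple isoforms (25.2% vs
15.6%), for binding by the assayed RBPs (75.5% vs 36.3%), and group-1
genes for the ability to evade at least one miRNA family through APA
(23.5% vs 9.7%).

The other example scripts walk the individual capabilities: building a
compendium from a hand-written scan (`01`), the feature table and the
evasion rule on a three-gene toy (`02`), and the statistical toolkit with
its two bias controls (`03`).

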