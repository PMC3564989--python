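"""Generate the default synthetic study and run the whole pipeline on it.

The default configuration plants the published effect magnitudes: 3' UTR
medians of 215/100/129 nt (group 1 / group 4 / background), multi-isoform
fractions of 30.4% vs 14.4%, and RBP-binding frequencies of ~73% vs 35%.
The pipeline then has to recover them from the generated files alone.
"""

import tempfile
from pathlib import Path

from rbpkit.pipeline import run_all
from rbpkit.synth import default_study_config, generate_study

config = default_study_config(seed=1)
with tempfile.TemporaryDirectory() as tmp:
    bundle = Path(tmp) / "bundle"
    out = Path(tmp) / "report"
    generate_study(config, bundle)
    summary = run_all(bundle, out, seed=1)

    print("gene-set sizes:", summary["gene_set_sizes"])
    for key in (
        "group1|utr_len",
        "group4|utr_len",
        "RBP|multi_isoform",
        "RBP|rbp_bound",
        "group1|mirna_evasion",
    ):
        r = summary["results"][key]
        print(
            f"{key:24s} {r['test']:15s} stat={r['statistic']:.3f} "
            f"p={r['p_value']:.2e} {r['direction']} [{r['significance']}]"
        )

# group1|utr_len shows a strong KS shift (planted 215 vs 129 nt medians);
# RBP|multi_isoform and RBP|rbp_bound are hypergeometrically enriched; the
# group-1 evasion frequency roughly doubles the transcriptome's.
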