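import pandas as pd
import pytest

# ---------------------------------------------------------------------------
# Six-gene toy study traced by hand through every pipeline rule:
#   geneA  one isoform, KH (Pfam)                     -> group 1
#   geneB  two isoforms, RRM and RRM+CCCH             -> group 1 (union)
#   geneC  PAZ + PIWI                                 -> group 2
#   geneD  WD40 only, plus a KH accession under the
#          rejected Gene3D application                -> not an RBP
#   geneE  KH, but removed by curation                -> absent
#   geneF  no scan hits, added by curation            -> group 1, curated
# ---------------------------------------------------------------------------

TOY_GENE_MODEL = pd.DataFrame(
    [
        ("geneA", "geneA.p1", "geneA.t1"),
        ("geneB", "geneB.p1", "geneB.t1"),
        ("geneB", "geneB.p2", "geneB.t2"),
        ("geneC", "geneC.p1", "geneC.t1"),
        ("geneD", "geneD.p1", "geneD.t1"),
        ("geneE", "geneE.p1", "geneE.t1"),
        ("geneF", "geneF.p1", "geneF.t1"),
    ],
    columns=["gene_id", "protein_id", "transcript_id"],
)

TOY_SCAN_LINES = [
    "geneA.p1\t-\t400\tHMMPfam\tPF00013\tKH_domain\t10\t80\t1e-12",
    "geneB.p1\t-\t350\tHMMPfam\tPF00076\tRRM_domain\t5\t75\t1e-10",
    "geneB.p2\t-\t500\tHMMPfam\tPF00076\tRRM_domain\t5\t75\t1e-10",
    "geneB.p2\t-\t500\tHMMSmart\tSM0999\tCCCH\t200\t230\t1e-6",
    "geneC.p1\t-\t900\tHMMPfam\tPF02170\tPAZ_domain\t50\t160\t1e-20",
    "geneC.p1\t-\t900\tHMMPfam\tPF02171\tPiwi_domain\t400\t700\t1e-30",
    "geneD.p1\t-\t300\tHMMPfam\tPF00400\tWD40\t20\t60\t1e-8",
    "geneD.p1\t-\t300\tGene3D\tPF00013\tKH_domain\t10\t80\t1e-8",
    "geneE.p1\t-\t280\tHMMPfam\tPF00013\tKH_domain\t30\t100\t1e-9",
]

#: hand-derived expectation for the toy study after curation
TOY_EXPECTED_GROUPS = {"geneA": 1, "geneB": 1, "geneC": 2, "geneF": 1}


@pytest.fixture
def toy_gene_model():
    return TOY_GENE_MODEL.copy()


@pytest.fixture
def toy_scan_path(tmp_path):
    path = tmp_path / "scan.tsv"
    path.write_text("\n".join(TOY_SCAN_LINES) + "\n")
    return path


@pytest.fixture
def toy_curation():
    from rbpkit.compendium import CurationList

    return CurationList(
        removals={("geneE", "domain-length")},
        additions={("geneF", "literature", None)},
    )


# ---------------------------------------------------------------------------
# Three-gene miRNA-evasion fixture, hand-traced:
#   gX  two UTRs; fam-a has a site only in the first  -> evades {fam-a}
#   gY  two UTRs; fam-b has sites in both             -> nothing evadable
#   gZ  one UTR;  fam-c present                       -> single UTR, no APA
# evading fraction = 1/3
# ---------------------------------------------------------------------------

EVASION_UTRS = pd.DataFrame(
    [
        ("gX", "gX.u1", 300, "chrI", 1000, 1300, "+"),
        ("gX", "gX.u2", 120, "chrI", 1000, 1120, "+"),
        ("gY", "gY.u1", 250, "chrI", 5000, 5250, "+"),
        ("gY", "gY.u2", 150, "chrI", 5000, 5150, "+"),
        ("gZ", "gZ.u1", 200, "chrII", 100, 300, "+"),
    ],
    columns=["gene_id", "utr_id", "length", "chrom", "start", "end", "strand"],
)

EVASION_PREDICTIONS = pd.DataFrame(
    [
        ("gX.u1", "fam-a", 2),
        ("gY.u1", "fam-b", 1),
        ("gY.u2", "fam-b", 1),
        ("gZ.u1", "fam-c", 1),
    ],
    columns=["utr_id", "mirna_family", "n_sites"],
)

EVASION_EXPECTED = {"gX": {"fam-a"}}


@pytest.fixture
def evasion_fixture():
    return EVASION_UTRS.copy(), EVASION_PREDICTIONS.copy(), dict(EVASION_EXPECTED)


@pytest.fixture
def small_config():
    """A fast, fully featured synthetic study for integration tests."""
    from rbpkit.synth import default_study_config

    config = default_study_config(seed=11)
    config.n_genes = 400
    config.group_counts = {"group1": 30, "group2": 15, "group3": 20, "group4": 25, "TF": 20}
    return config
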