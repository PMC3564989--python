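"""Enrichment and distribution tests for gene sets against a background.

Two test families, mirroring how regulatory-feature comparisons are
routed in practice:

* frequency features (a per-gene yes/no, e.g. "uses alternative
  polyadenylation") → exact hypergeometric tail probabilities against the
  universe;
* count/length features (e.g. 3' UTR length, miRNA families per gene) →
  two-sample Kolmogorov–Smirnov on the empirical distributions.

Two bias controls are provided: a quartile-binned comparison that holds a
confounder (UTR length) fixed while testing a secondary feature, and a
detection-normalised frequency test that restricts both gene set and
universe to proteins detectable in an independent mass-spectrometry
survey before testing phosphorylation frequency.

Significance is annotated with the conventional two-level stars:
``*`` p < 0.05, ``**`` p < 0.005.  Raw p-values are reported by default;
Benjamini–Hochberg adjustment is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "EnrichmentResult",
    "DistributionComparison",
    "hypergeometric_test",
    "ks_two_sample",
    "quartile_binned_comparison",
    "detection_normalized_frequency",
    "run_enrichment_suite",
    "significance_stars",
    "FREQUENCY_FEATURES",
    "COUNT_FEATURES",
]

ALPHA_STAR = 0.05
ALPHA_DOUBLE_STAR = 0.005


def significance_stars(p: float) -> str:
    if p < ALPHA_DOUBLE_STAR:
        return "**"
    if p < ALPHA_STAR:
        return "*"
    return "ns"


@dataclass(frozen=True)
class EnrichmentResult:
    """One hypergeometric comparison of a gene set against a universe."""

    set_name: str
    feature: str
    k: int  # successes in the set
    n: int  # set size
    K: int  # successes in the universe
    N: int  # universe size
    p_value: float  # headline: upper (enrichment) tail
    p_lower: float  # depletion tail, P(X <= k)
    direction: str  # enriched | depleted
    significance: str  # ns | * | **
    undefined: bool = False


@dataclass(frozen=True)
class DistributionComparison:
    """One two-sample KS comparison of a feature's distributions."""

    set_name: str
    feature: str
    n_set: int
    n_background: int
    D: float
    p_value: float
    median_set: float
    median_background: float
    significance: str


def _check_counts(k: int, n: int, K: int, N: int) -> None:
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"invalid hypergeometric counts k={k} n={n} K={K} N={N}")
    if k < max(0, n + K - N):
        raise ValueError(
            f"impossible count k={k} < n+K-N = {n + K - N} (n={n} K={K} N={N})"
        )


def hypergeometric_test(k: int, n: int, K: int, N: int, tail: str = "upper") -> float:
    """Exact hypergeometric tail probability.

    Drawing ``n`` genes without replacement from a universe of ``N`` of
    which ``K`` carry the property, with ``k`` carriers observed in the
    draw: upper tail is P(X ≥ k), lower tail P(X ≤ k).  Computed by exact
    summation of the hypergeometric pmf — no normal approximation.
    """
    _check_counts(k, n, K, N)
    dist = sps.hypergeom(N, K, n)
    if tail == "upper":
        return float(min(1.0, dist.sf(k - 1)))
    if tail == "lower":
        return float(min(1.0, dist.cdf(k)))
    raise ValueError(f"tail must be 'upper' or 'lower', got {tail!r}")


def ks_two_sample(
    sample: Sequence[float],
    background: Sequence[float],
    set_name: str = "sample",
    feature: str = "",
    exact_small: bool = False,
) -> DistributionComparison:
    """Two-sample Kolmogorov–Smirnov comparison.

    D is the supremum of |ECDF_sample − ECDF_background| over all observed
    values (ties handled by evaluating both ECDFs at every observed
    point); the p-value uses the standard asymptotic two-sample formula,
    optionally switching to the exact distribution when the combined
    sample size is below 25.
    """
    x = np.asarray(sample, dtype=float)
    y = np.asarray(background, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    method = "exact" if (exact_small and x.size + y.size < 25) else "asymp"
    res = sps.ks_2samp(x, y, method=method)
    p = float(min(1.0, res.pvalue))
    return DistributionComparison(
        set_name=set_name,
        feature=feature,
        n_set=int(x.size),
        n_background=int(y.size),
        D=float(res.statistic),
        p_value=p,
        median_set=float(np.median(x)),
        median_background=float(np.median(y)),
        significance=significance_stars(p),
    )


def _enrichment(
    set_name: str, feature: str, k: int, n: int, K: int, N: int
) -> EnrichmentResult:
    # direction from the sign of (k/n - K/N); both one-sided tails reported,
    # upper (enrichment) tail is the headline p-value
    p_upper = hypergeometric_test(k, n, K, N, tail="upper")
    p_lower = hypergeometric_test(k, n, K, N, tail="lower")
    direction = "enriched" if (n and N and k / n >= K / N) else "depleted"
    stars_p = p_upper if direction == "enriched" else p_lower
    return EnrichmentResult(
        set_name=set_name,
        feature=feature,
        k=k,
        n=n,
        K=K,
        N=N,
        p_value=p_upper,
        p_lower=p_lower,
        direction=direction,
        significance=significance_stars(stars_p),
    )


def quartile_binned_comparison(
    bin_values: Mapping[str, float],
    secondary_values: Mapping[str, float],
    subset: Iterable[str],
    background: Iterable[str],
    set_name: str = "subset",
    feature: str = "secondary",
) -> list[dict]:
    """Compare a secondary feature within quartile bins of a confounder.

    Quartile boundaries are computed on the background's ``bin_values``
    (linear interpolation between order statistics); every gene is
    assigned to a bin, and within each bin the subset's
    ``secondary_values`` are KS-compared against the background's.  Bins
    where the subset is empty are reported as skipped.  This is the
    length-matched control: an apparent enrichment that vanishes in every
    bin was a confounder effect.
    """
    subset = [g for g in subset if g in bin_values and g in secondary_values]
    background = [g for g in background if g in bin_values and g in secondary_values]
    bg_vals = np.array([bin_values[g] for g in background], dtype=float)
    if np.unique(bg_vals).size < 4:
        raise ValueError("need at least 4 distinct background values for quartiles")
    edges = np.quantile(bg_vals, [0.25, 0.5, 0.75], method="linear")

    def bin_of(v: float) -> int:
        return int(np.searchsorted(edges, v, side="left"))

    results = []
    for b in range(4):
        sub_vals = [secondary_values[g] for g in subset if bin_of(bin_values[g]) == b]
        back_vals = [secondary_values[g] for g in background if bin_of(bin_values[g]) == b]
        entry = {
            "set_name": set_name,
            "feature": feature,
            "bin": b + 1,
            "bin_edges": (
                float("-inf") if b == 0 else float(edges[b - 1]),
                float("inf") if b == 3 else float(edges[b]),
            ),
            "skipped": False,
        }
        if not sub_vals or not back_vals:
            entry["skipped"] = True
        else:
            cmp = ks_two_sample(sub_vals, back_vals, set_name, feature)
            entry.update(
                D=cmp.D,
                p_value=cmp.p_value,
                n_set=cmp.n_set,
                n_background=cmp.n_background,
                median_set=cmp.median_set,
                median_background=cmp.median_background,
                significance=cmp.significance,
            )
        results.append(entry)
    return results


def detection_normalized_frequency(
    phospho_flags: Mapping[str, bool],
    detection_reference: Iterable[str],
    group: Iterable[str],
    universe: Iterable[str],
    set_name: str = "group",
) -> dict:
    """Phosphorylation frequency corrected for detectability.

    Restricts both the gene set and the universe to proteins detected in
    an independent (non-phospho-enriched) mass-spectrometry survey, then
    tests phosphorylation frequency hypergeometrically within the
    restricted sets.  Reports raw and restricted frequencies side by
    side; a group with no detected members yields an undefined result
    (no p-value) rather than a spurious one.
    """
    universe = set(universe)
    group = set(group) & universe
    detected = set(detection_reference) & universe

    def freq(genes: set[str]) -> float:
        return (
            sum(1 for g in genes if phospho_flags.get(g, False)) / len(genes)
            if genes
            else float("nan")
        )

    group_det = group & detected
    out = {
        "set_name": set_name,
        "raw_frequency_set": freq(group),
        "raw_frequency_universe": freq(universe),
        "restricted_frequency_set": freq(group_det),
        "restricted_frequency_universe": freq(detected),
        "undefined": not group_det,
    }
    if group_det:
        k = sum(1 for g in group_det if phospho_flags.get(g, False))
        K = sum(1 for g in detected if phospho_flags.get(g, False))
        res = _enrichment(set_name, "phosphorylated|detected", k, len(group_det), K, len(detected))
        out.update(
            k=res.k, n=res.n, K=res.K, N=res.N,
            p_value=res.p_value, direction=res.direction,
            significance=res.significance,
        )
    return out


# Feature routing mirrors the frequency-vs-cumulative-distribution split of
# the comparisons: (column, predicate) pairs for frequencies, plain columns
# for KS.  Fixed here, not inferred from dtypes.
FREQUENCY_FEATURES: dict[str, tuple[str, object]] = {
    "multi_isoform": ("n_isoforms", lambda s: s >= 2),
    "rbp_bound": ("n_rbps", lambda s: s >= 1),
    "tf_bound": ("n_tfs", lambda s: s >= 1),
    "uses_apa": ("uses_apa", lambda s: s),
    "mirna_targeted": ("n_mirna_families", lambda s: s >= 1),
    "mirna_evasion": ("n_evadable_families", lambda s: s >= 1),
    "phosphorylated": ("n_phospho_residues", lambda s: s >= 1),
}

COUNT_FEATURES: tuple[str, ...] = (
    "n_tfs",
    "n_rbps",
    "n_isoforms",
    "utr_len",
    "n_mirna_families",
    "n_phospho_residues",
)


def run_enrichment_suite(
    features: pd.DataFrame,
    set_definitions: Mapping[str, Iterable[str]],
    background: Optional[str] = None,
    frequency_features: Optional[Sequence[str]] = None,
    count_features: Optional[Sequence[str]] = None,
    utr_lengths: Optional[pd.DataFrame] = None,
    bh: bool = False,
) -> pd.DataFrame:
    """Run every routed (gene set, feature) comparison and tabulate.

    ``background`` may name one of the sets, switching to set-vs-set mode
    (the test universe becomes the union of the two sets); by default the
    background is the whole feature-table universe.  ``utr_lengths`` — a
    long (gene_id, length) table of distinct UTRs — makes the ``utr_len``
    KS comparison use per-UTR values (each UTR one observation) instead of
    the per-gene representative column.  ``bh=False`` reports raw
    p-values, matching the two-level star convention; ``bh=True`` adds a
    Benjamini–Hochberg adjusted column.
    """
    freq_names = list(frequency_features or FREQUENCY_FEATURES)
    count_names = list(count_features or COUNT_FEATURES)
    for name in freq_names:
        if name not in FREQUENCY_FEATURES:
            raise ValueError(f"unknown frequency feature {name!r}")
    for name in count_names:
        if name not in features.columns:
            raise ValueError(f"unknown count feature {name!r}")

    table = features.set_index("gene_id")
    universe_all = set(table.index)
    sets = {name: set(genes) & universe_all for name, genes in set_definitions.items()}
    if background is not None and background not in sets:
        raise ValueError(f"background set {background!r} not among set definitions")

    rows: list[dict] = []
    for set_name, genes in sets.items():
        if background is not None and set_name == background:
            continue
        bg_universe = genes | sets[background] if background is not None else universe_all

        for feat in freq_names:
            col, pred = FREQUENCY_FEATURES[feat]
            flags = pred(table[col])
            valid = table[col].notna()
            uni = [g for g in bg_universe if valid.get(g, False)]
            member = [g for g in genes if valid.get(g, False)]
            if not uni or not member:
                continue
            truthy = {g for g in uni if bool(flags.get(g, False))}
            res = _enrichment(
                set_name, feat, len(set(member) & truthy), len(member), len(truthy), len(uni)
            )
            rows.append(
                {
                    "set_name": set_name,
                    "feature": feat,
                    "test": "hypergeometric",
                    "k": res.k,
                    "n": res.n,
                    "K": res.K,
                    "N": res.N,
                    "statistic": res.k / res.n if res.n else float("nan"),
                    "p_value": res.p_value,
                    "p_lower": res.p_lower,
                    "direction": res.direction,
                    "significance": res.significance,
                }
            )

        for feat in count_names:
            if feat == "utr_len" and utr_lengths is not None:
                per_utr = utr_lengths.set_index("gene_id")["length"]
                sub_vals = per_utr.loc[per_utr.index.isin(genes)].to_numpy(dtype=float)
                bg_vals = per_utr.loc[per_utr.index.isin(bg_universe)].to_numpy(dtype=float)
            else:
                col = table[feat].dropna()
                sub_vals = col.loc[col.index.isin(genes)].to_numpy(dtype=float)
                bg_vals = col.loc[col.index.isin(bg_universe)].to_numpy(dtype=float)
            if sub_vals.size == 0 or bg_vals.size == 0:
                continue
            cmp = ks_two_sample(sub_vals, bg_vals, set_name, feat)
            rows.append(
                {
                    "set_name": set_name,
                    "feature": feat,
                    "test": "ks",
                    "k": pd.NA,
                    "n": cmp.n_set,
                    "K": pd.NA,
                    "N": cmp.n_background,
                    "statistic": cmp.D,
                    "p_value": cmp.p_value,
                    "p_lower": pd.NA,
                    "direction": (
                        "enriched" if cmp.median_set >= cmp.median_background else "depleted"
                    ),
                    "significance": cmp.significance,
                }
            )

    report = pd.DataFrame(rows)
    if bh and not report.empty:
        from statsmodels.stats.multitest import multipletests  # optional extra

        report["p_adjusted"] = multipletests(report["p_value"], method="fdr_bh")[1]
    return report
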