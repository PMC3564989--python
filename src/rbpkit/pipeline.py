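"""End-to-end orchestration: build → integrate → test → report.

:func:`run_all` consumes a study bundle directory (real data laid out in
the bundle dialects, or the output of :func:`rbpkit.synth.generate_study`)
and writes the compendium, the integrated feature table, the enrichment
report and a JSON summary.  All outputs are deterministic for fixed
inputs; timestamps appear only in the log.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import io as rio
from .catalog import default_catalog, load_catalog
from .compendium import (
    CurationList,
    build_compendium,
    compendium_to_frame,
    load_curation,
    rbp_gene_set,
    write_compendium,
)
from .features import build_feature_table, utr_lengths_long
from .stats import run_enrichment_suite
from .synth import BUNDLE_FILES

__all__ = ["run_all", "load_gene_sets", "RunError"]

logger = logging.getLogger("rbpkit")


class RunError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


def _bundle_path(bundle: Path, key: str, required: bool) -> Optional[Path]:
    path = bundle / BUNDLE_FILES[key]
    if not path.exists():
        if required:
            raise RunError(f"stage inputs: missing required file {path}")
        return None
    return path


def load_gene_sets(path: rio.PathLike) -> dict[str, set[str]]:
    """Gene-set definition TSV: columns set_name, gene_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {name: set(sub["gene_id"]) for name, sub in df.groupby("set_name")}


def run_all(
    bundle: rio.PathLike,
    outdir: rio.PathLike,
    catalog_path: Optional[rio.PathLike] = None,
    curation_path: Optional[rio.PathLike] = None,
    sets_path: Optional[rio.PathLike] = None,
    utr_policy: str = "longest",
    per_utr_lengths: bool = True,
    bh: bool = False,
    seed: int = 0,
) -> dict:
    """Run the full analysis on a bundle directory; returns the summary.

    Writes ``compendium.tsv``, ``features.tsv``, ``enrichment.tsv``,
    ``summary.json`` and ``run.log`` under ``outdir``.
    """
    bundle = Path(bundle)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("run_all start: bundle=%s seed=%d", bundle, seed)

        gene_model = rio.read_gene_model(_bundle_path(bundle, "gene_model", True))
        scan_path = _bundle_path(bundle, "scan", True)
        catalog = load_catalog(catalog_path) if catalog_path else default_catalog()
        curation = load_curation(curation_path) if curation_path else CurationList()

        try:
            records, stage_log = build_compendium(
                scan_path, gene_model, catalog=catalog, curation=curation
            )
        except Exception as exc:
            raise RunError(f"stage build: {scan_path}: {exc}") from exc
        write_compendium(records, outdir / "compendium.tsv")
        logger.info("compendium: %s", stage_log)

        def _read(key: str, reader):
            path = _bundle_path(bundle, key, False)
            if path is None:
                return None
            try:
                return reader(path)
            except Exception as exc:
                raise RunError(f"stage features: {path}: {exc}") from exc

        # UTR analyses are part of the default suite, so the UTR table is
        # required; binding/phospho/detection inputs degrade gracefully
        _bundle_path(bundle, "utrs", True)
        utrs = _read("utrs", rio.read_utrs)
        targets = _read("targets", rio.read_target_predictions)
        bindings = _read("bindings", rio.read_bindings)
        phospho = _read("phospho", rio.read_phosphosites)
        detected = _read("detected", rio.read_detection_list)

        gene_sets: dict[str, set[str]] = {
            f"group{g}": rbp_gene_set(records, g) for g in (1, 2, 3, 4)
        }
        gene_sets["RBP"] = rbp_gene_set(records)
        if sets_path:
            gene_sets.update(load_gene_sets(sets_path))

        features = build_feature_table(
            gene_model,
            utrs=utrs,
            predictions=targets,
            bindings=bindings,
            phospho=phospho,
            detected_genes=detected,
            gene_sets=gene_sets,
            utr_policy=utr_policy,
        )
        features.to_csv(outdir / "features.tsv", sep="\t", index=False)

        utr_long = utr_lengths_long(utrs) if (utrs is not None and per_utr_lengths) else None
        try:
            report = run_enrichment_suite(
                features, gene_sets, utr_lengths=utr_long, bh=bh
            )
        except Exception as exc:
            raise RunError(f"stage test: enrichment suite: {exc}") from exc
        report.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

        summary = {
            "seed": seed,
            "stage_counts": stage_log,
            "n_genes_universe": int(features.shape[0]),
            "gene_set_sizes": {k: len(v) for k, v in sorted(gene_sets.items())},
            "results": {
                f"{r.set_name}|{r.feature}": {
                    "test": r.test,
                    "statistic": None if pd.isna(r.statistic) else float(r.statistic),
                    "p_value": float(r.p_value),
                    "direction": r.direction,
                    "significance": r.significance,
                }
                for r in report.itertuples()
            },
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        logger.info("run_all done: %d comparisons", len(report))
        return summary
    finally:
        logger.removeHandler(handler)
        handler.close()
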