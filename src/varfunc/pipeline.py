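"""End-to-end orchestration: alignment processing, subfamily clustering,
per-cluster profile scoring, and soft classification for a batch of variants,
with a run manifest for reproducibility."""

from __future__ import annotations

import csv
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .classify import DEFAULT_CUTOFF, RESULT_COLUMNS, SoftClassification, classify, result_row
from .clustering import ceo_cluster, kmeans_cluster
from .hmm import score_variant_across_clusters
from .msa import (
    MultipleAlignment,
    VariantSpec,
    filter_columns,
    map_variant_to_column,
    read_alignment,
    remove_redundant,
    select_region,
)

log = logging.getLogger("varfunc")


@dataclass
class RunConfig:
    """Everything a classification run depends on; recorded in the manifest."""

    msa_path: str
    query_id: str
    variants: list[str]
    msa_format: str = "fasta"
    cutoff: float = DEFAULT_CUTOFF
    clustering: str = "ceo"            # "ceo" | "kmeans"
    k: int = 4                         # kmeans only
    restarts: int = 3
    kmeans_restarts: int = 100
    shuffles: int = 20
    score_mode: str = "ratio"          # "ratio" | "difference"
    identity_threshold: float = 0.95
    max_gap_fraction: float = 0.99
    min_width: int = 10
    extension_gap_fraction: float = 0.10
    significance_floor: float = 0.0
    pseudocount: float = 1.0
    match_gap_threshold: float = 0.5
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        if not 0 < self.identity_threshold <= 1:
            raise ValueError("identity threshold must be in (0, 1]")
        if not 0 <= self.max_gap_fraction <= 1:
            raise ValueError("column gap threshold must be in [0, 1]")
        if not 0 <= self.extension_gap_fraction <= 1:
            raise ValueError("extension gap threshold must be in [0, 1]")
        if self.min_width < 1:
            raise ValueError("min width must be >= 1")
        if self.clustering not in ("ceo", "kmeans"):
            raise ValueError("clustering must be 'ceo' or 'kmeans'")
        if self.score_mode not in ("ratio", "difference"):
            raise ValueError("score mode must be 'ratio' or 'difference'")


def run_pipeline(
    config: RunConfig, msa: MultipleAlignment | None = None
) -> tuple[list[dict], dict]:
    """Run the full classification chain for every variant in the config.

    Returns the per-variant result rows (the output TSV content) and the run
    manifest.  A variant that fails at some stage yields a row whose
    ``error`` column names the stage; it is never silently dropped.  The run
    is deterministic: identical config and seed give identical rows.
    """
    config.validate()
    t0 = time.time()
    if msa is None:
        msa = read_alignment(config.msa_path, config.query_id, config.msa_format)
    log.info("alignment: %d rows x %d columns", msa.n_rows, msa.width)

    deduped = remove_redundant(msa, config.identity_threshold)
    filtered, _ = filter_columns(deduped, config.max_gap_fraction)
    log.info(
        "redundancy removal kept %d/%d rows; column filter kept %d/%d columns",
        deduped.n_rows, msa.n_rows, filtered.width, deduped.width,
    )

    rows_out: list[dict] = []
    stage_info: list[dict] = []
    for vtext in config.variants:
        stage = "variant_parsing"
        try:
            variant = VariantSpec.parse(vtext)
            stage = "msa_processing"
            col = map_variant_to_column(filtered, variant)
            window = select_region(
                filtered, col, config.min_width, config.extension_gap_fraction
            )
            stage = "clustering"
            if config.clustering == "ceo":
                partition = ceo_cluster(
                    window, config.restarts, config.shuffles, config.seed
                )
            else:
                partition = kmeans_cluster(
                    window, config.k, config.kmeans_restarts, config.seed
                )
            stage = "profile_hmm"
            scores = score_variant_across_clusters(
                window, partition, variant,
                significance_floor=config.significance_floor,
                mode=config.score_mode,
                pseudocount=config.pseudocount,
                match_gap_threshold=config.match_gap_threshold,
            )
            stage = "classification"
            result = classify(scores, config.cutoff, variant=str(variant))
            row = result_row(result)
            row["error"] = ""
            rows_out.append(row)
            stage_info.append({
                "variant": vtext,
                "window": [window.first_column + 1, window.last_column + 1],
                "window_rows": window.n_rows,
                "cluster_sizes": partition.sizes(),
                "score_mode_used": scores.mode_used,
            })
        except Exception as e:                       # noqa: BLE001
            log.warning("variant %s failed at %s: %s", vtext, stage, e)
            row = {c: "" for c in RESULT_COLUMNS}
            row.update(variant=vtext, predicted="error", no_call="")
            row["error"] = f"{stage}: {e}"
            rows_out.append(row)
            stage_info.append({"variant": vtext, "error_stage": stage})

    manifest = {
        "package": "varfunc",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "n_rows_input": msa.n_rows,
        "n_rows_after_redundancy": deduped.n_rows,
        "rows_removed_redundant": msa.n_rows - deduped.n_rows,
        "n_columns_input": deduped.width,
        "n_columns_after_filter": filtered.width,
        "columns_removed": deduped.width - filtered.width,
        "variants": stage_info,
        "runtime_s": round(time.time() - t0, 3),
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_results(rows_out, out / "results.tsv")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return rows_out, manifest


def write_results(rows: list[dict], path) -> None:
    cols = RESULT_COLUMNS + ["error"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols, delimiter="\t", lineterminator="\n")
        writer.writeheader()
        for row in rows:
            writer.writerow(row)


def setup_logging(verbose: bool = True) -> None:
    """Stage logs go to stderr so result streams stay clean."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(asctime)s] %(levelname)s %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.INFO if verbose else logging.WARNING)


def classification_results(rows: list[dict]) -> list[SoftClassification]:
    """Rehydrate minimal SoftClassification objects from result rows (used by
    the evaluate subcommand when chaining from a results TSV)."""
    out = []
    for r in rows:
        if r.get("error"):
            continue
        conf = None
        if r["conf_LoF"] != "":
            conf = {t: float(r[f"conf_{t}"]) for t in ("LoF", "SoF", "GoF", "CoF")}
        out.append(SoftClassification(
            variant=r["variant"],
            target_score=float(r["S0"]) if r["S0"] != "" else None,
            min_other_score=float(r["Sx"]) if r["Sx"] != "" else None,
            argmin_cluster=int(r["argmin_cluster"]) if r["argmin_cluster"] != "" else None,
            cutoff=float("nan"),
            loss_prob=float(r["L"]) if r["L"] != "" else None,
            acquire_prob=float(r["A"]) if r["A"] != "" else None,
            confidences=conf,
            predicted=r["predicted"],
        ))
    return out
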