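"""End-to-end orchestration: load -> OAV -> multivariate -> screen -> ROC -> report.

``run_full_analysis`` drives every stage on a compound table plus a
content matrix and writes machine-readable outputs (``summary.json``
and per-stage CSVs) into an output directory. Stage skipping is
explicit: replicate-level statistics (t-tests, OPLS-DA, ROC) require at
least two replicates per cultivar and are skipped with a logged warning
on cultivar-mean inputs — never silently emitted as NaNs.

``render_report`` formats a summary for humans: contents and OAVs to 3
significant figures, shares as percentages with one decimal. Every
number in the report is taken from the summary; no report-only
arithmetic.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import differential_screen as ds
from . import multivariate as mv
from . import odor_activity as oa
from .volatile_table import (
    class_counts,
    cultivar_means,
    load_compound_table,
    load_content_matrix,
)

__all__ = ["RunConfig", "run_full_analysis", "render_report", "sigfig"]

logger = logging.getLogger("aromascreen")


@dataclass
class RunConfig:
    """Inputs, thresholds and seeds of one full pipeline run."""

    compounds_path: str | Path
    contents_path: str | Path
    out_dir: str | Path
    target_cultivar: str = "CV4"
    screen: ds.ScreenConfig = field(default_factory=ds.ScreenConfig)
    n_ortho: int = 1
    n_permutations: int = 0  # 0 disables the OPLS-DA permutation test
    kmeans_k: int = 9
    seed: int = 0
    sensory_scores: dict[str, float] | None = None  # optional annotations


def sigfig(x: float, digits: int = 3) -> float:
    """Round to ``digits`` significant figures (reporting convention)."""
    if x == 0 or not np.isfinite(x):
        return x
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + digits - 1)


def _pct1(fraction: float) -> float:
    return round(100.0 * fraction, 1)


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage and write ``summary.json`` plus per-stage CSVs.

    Returns the summary dict. Deterministic given identical inputs and
    seeds: rerunning writes byte-identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    table = load_compound_table(config.compounds_path)
    matrix = load_content_matrix(config.contents_path)
    if config.target_cultivar not in matrix.cultivars:
        raise ValueError(
            f"target cultivar {config.target_cultivar!r} not in content matrix "
            f"(stage: load)"
        )
    means = cultivar_means(matrix)
    n_replicates = {cv: matrix.replicates(cv).shape[1] for cv in matrix.cultivars}
    replicate_stats = min(n_replicates.values()) >= 2

    # ---- odor activity -------------------------------------------------
    oav = oa.oav_matrix(means, table)
    keys = oa.key_odorants(oav, table)
    shared = oa.shared_key_odorants(oav, table)
    nonanal = next((r.compound_id for r in table if r.name == "nonanal"), None)

    oav_long = oav.values.reset_index(names="compound_id").melt(
        id_vars="compound_id", var_name="cultivar", value_name="oav"
    )
    oav_long["defined_flag"] = oav_long["compound_id"].map(oav.defined)
    oav_long["oav"] = oav_long["oav"].fillna("-")
    oav_long.to_csv(out / "oav.csv", index=False)

    summary: dict = {
        "n_compounds": len(table),
        "n_thresholded": int(oav.defined.sum()),
        "class_counts": {},
        "cultivars": matrix.cultivars,
        "n_replicates": n_replicates,
        "target_cultivar": config.target_cultivar,
        "key_odorants": sorted(keys),
        "n_key_odorants": len(keys),
        "shared_key_odorants": sorted(shared),
        "n_shared_key_odorants": len(shared),
        "total_oav": {
            cv: float(oav.values.loc[oav.defined_compounds, cv].sum())
            for cv in oav.cultivars
        },
    }
    summary["class_counts"] = class_counts(table)
    if nonanal is not None and nonanal in oav.defined_compounds:
        summary["nonanal_share"] = {
            cv: oa.oav_share(oav, {nonanal}, cv) for cv in oav.cultivars
        }

    # ---- compound-level multivariate (works on cultivar means) ---------
    # cluster compounds on their standardized cross-cultivar profiles
    profiles = mv.zscore(means.values.to_numpy().T).values.T  # compounds x cultivars
    km = mv.kmeans(profiles, k=min(config.kmeans_k, len(table)), seed=config.seed)
    pd.DataFrame(
        {"compound_id": matrix.compounds, "cluster": km.labels + 1}
    ).to_csv(out / "clusters.csv", index=False)
    hca = mv.hca_ward(profiles)
    summary["kmeans"] = {
        "k": int(km.centers.shape[0]),
        "n_nonempty": int(len(np.unique(km.labels))),
        "wcss": km.wcss,
    }
    summary["hca_merges"] = int(hca.merges.shape[0])

    # ---- replicate-level statistics ------------------------------------
    comparisons = [cv for cv in matrix.cultivars if cv != config.target_cultivar]
    if replicate_stats:
        tables = []
        up_down: dict[str, dict[str, int]] = {}
        for ref in comparisons:
            diff = ds.discriminating_screen(
                matrix, ref, config.target_cultivar, config.screen, config.n_ortho
            )
            diff.table.to_csv(out / f"diff_{ref}_vs_{config.target_cultivar}.csv")
            tables.append(diff)
            up_down[f"{ref}_vs_{config.target_cultivar}"] = {
                "up": int((diff.table["status"] == ds.STATUS_UP).sum()),
                "down": int((diff.table["status"] == ds.STATUS_DOWN).sum()),
            }
        venn = ds.venn_intersections(tables)
        triple = sorted(
            cid for cid, comps in venn.items() if len(comps) == len(tables)
        )
        pd.DataFrame(
            [
                {"compound_id": cid, "comparisons": ";".join(sorted(comps))}
                for cid, comps in sorted(venn.items())
            ]
        ).to_csv(out / "venn.csv", index=False)
        disc_keys = ds.discriminating_key_odorants(tables, keys)
        summary["screen"] = up_down
        summary["venn_triple_intersection"] = triple
        summary["discriminating_key_odorants"] = sorted(disc_keys)
        share_key = "discriminating_key_share"
        if disc_keys:
            summary[share_key] = {
                cv: oa.oav_share(oav, disc_keys & set(oav.defined_compounds), cv)
                for cv in oav.cultivars
            }

        # ROC: target vs pooled rest, per discriminating key odorant
        labels = np.array(
            [cv == config.target_cultivar for cv, _ in matrix.values.columns]
        )
        aucs = {}
        for cid in sorted(disc_keys):
            scores = matrix.values.loc[cid].to_numpy(float)
            curve = ds.roc_auc(scores, labels)
            aucs[cid] = curve.auc
            pd.DataFrame(
                {"fpr": curve.fpr, "tpr": curve.tpr, "threshold": curve.thresholds}
            ).to_csv(out / f"roc_{cid}.csv", index=False)
        summary["roc_auc"] = aucs

        if config.n_permutations > 0:
            perms = {}
            for ref in comparisons:
                x_ref = matrix.replicates(ref)
                x_tgt = matrix.replicates(config.target_cultivar)
                X = np.vstack([x_ref.values.T, x_tgt.values.T])
                y = [ref] * x_ref.shape[1] + [config.target_cultivar] * x_tgt.shape[1]
                perms[f"{ref}_vs_{config.target_cultivar}"] = mv.permutation_test(
                    mv.zscore(X), y, config.n_ortho, config.n_permutations, config.seed
                )
            summary["opls_permutation_p"] = perms
    else:
        logger.warning(
            "single-replicate input: t-tests, OPLS-DA, screen and ROC skipped"
        )
        summary["screen"] = None
        summary["skipped_stages"] = ["screen", "opls_da", "roc"]

    if config.sensory_scores:
        summary["sensory_scores"] = config.sensory_scores

    summary["elapsed_s"] = round(time.perf_counter() - t0, 3)
    payload = {k: v for k, v in summary.items() if k != "elapsed_s"}
    (out / "summary.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    logger.info("pipeline finished in %.2fs", summary["elapsed_s"])
    return summary


def render_report(summary: dict) -> str:
    """Human-readable report mirroring the package's reporting conventions."""
    lines = []
    lines.append("Volatile odor-activity screening report")
    lines.append("=" * 40)
    lines.append(f"Compounds: {summary['n_compounds']}  "
                 f"(with odor threshold: {summary['n_thresholded']})")
    counts = summary.get("class_counts", {})
    if counts:
        lines.append("By class: " + ", ".join(f"{k} {v}" for k, v in counts.items()))
    lines.append("")
    lines.append(f"Key odor-active compounds (GC-O and OAV > 1): "
                 f"{summary['n_key_odorants']}")
    lines.append("  " + ", ".join(summary["key_odorants"]) if summary["key_odorants"] else "  none")
    lines.append(f"Shared across all cultivars (OAV > 1 everywhere): "
                 f"{summary['n_shared_key_odorants']}")
    lines.append("  " + ", ".join(summary["shared_key_odorants"])
                 if summary["shared_key_odorants"] else "  none")
    lines.append("")
    lines.append("Total OAV per cultivar:")
    for cv, total in summary["total_oav"].items():
        lines.append(f"  {cv}: {sigfig(total):g}")
    if "nonanal_share" in summary:
        shares = summary["nonanal_share"]
        lo, hi = min(shares.values()), max(shares.values())
        lines.append(
            f"Nonanal share of total OAV: {_pct1(lo)}%–{_pct1(hi)}% across cultivars"
        )
        for cv, sh in shares.items():
            lines.append(f"  {cv}: {_pct1(sh)}%")
    if summary.get("discriminating_key_share"):
        lines.append("Discriminating key odorant share of total OAV:")
        for cv, sh in summary["discriminating_key_share"].items():
            lines.append(f"  {cv}: {_pct1(sh)}%")
    lines.append("")
    if summary.get("screen"):
        lines.append(f"Discriminating-volatile screen vs {summary['target_cultivar']}:")
        for comp, ud in summary["screen"].items():
            lines.append(f"  {comp}: {ud['up']} up, {ud['down']} down")
        triple = summary.get("venn_triple_intersection", [])
        lines.append("Present in all comparisons: "
                     + (", ".join(triple) if triple else "none"))
        dk = summary.get("discriminating_key_odorants", [])
        lines.append("Discriminating key odor-active compounds: "
                     + (", ".join(dk) if dk else "none"))
        aucs = summary.get("roc_auc", {})
        if aucs:
            lines.append("ROC AUC (target vs rest):")
            for cid, auc in aucs.items():
                lines.append(f"  {cid}: {sigfig(auc):g}")
        else:
            lines.append("ROC AUC: none")
    else:
        lines.append("Replicate-level screen: skipped (single-replicate input)")
    return "\n".join(lines) + "\n"
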