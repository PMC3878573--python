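"""End-to-end orchestration: run every stage on a manifest of input files.

The manifest names the peak files per experiment, the peak-sequence FASTA,
the expression TSVs, the triad time course, and the TSS table. Outputs are
per-stage TSV tables plus a machine-readable JSON summary; runs are
deterministic given the config seed.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import interplay, linkage, motifs, triad
from .io import (
    AnalysisConfig,
    GATA1_E,
    CORE_EXPERIMENTS,
    read_expression,
    read_fasta,
    read_peaks,
    read_tss,
)

logger = logging.getLogger("gatatriad")

REQUIRED_MANIFEST_KEYS = ("peaks", "fasta", "expression", "triad_expression", "tss")


def _check_manifest(manifest: dict) -> None:
    missing = [k for k in REQUIRED_MANIFEST_KEYS if k not in manifest]
    if missing:
        raise KeyError(f"manifest missing entries: {missing}")
    missing_exps = [e for e in CORE_EXPERIMENTS if e not in manifest["peaks"]]
    if missing_exps:
        raise KeyError(f"manifest missing peak files for experiments: {missing_exps}")


def _sequence_lookup(sequences: dict):
    """Map FASTA ids 'chrom:start-end' to per-chromosome interval lists."""
    by_chrom = {}
    for sid in sequences:
        chrom, span = sid.rsplit(":", 1)
        start, end = (int(x) for x in span.split("-"))
        by_chrom.setdefault(chrom, []).append((start, end, sid))
    for ivs in by_chrom.values():
        ivs.sort()
    return by_chrom

def _find_sequence(by_chrom, chrom, summit):
    for start, end, sid in by_chrom.get(chrom, ()):
        if start <= summit < end:
            return sid
    return None


def run_pipeline(config: AnalysisConfig, manifest: dict, outdir) -> dict:
    """Run interplay, motif, linkage, and triad stages; write outputs.

    Returns the summary dict (also written as summary.json).
    """
    _check_manifest(manifest)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline start: seed=%d, outdir=%s", config.rng_seed, outdir)

    peaksets = {
        exp: read_peaks(path, exp) for exp, path in sorted(manifest["peaks"].items())
    }
    sequences = read_fasta(manifest["fasta"])
    expression = {
        lineage: read_expression(path, lineage)
        for lineage, path in sorted(manifest["expression"].items())
    }
    triad_expr = read_expression(manifest["triad_expression"], "erythroid")
    tss = read_tss(manifest["tss"])

    summary = {"config": {"rng_seed": config.rng_seed}}

    # --- interplay ---------------------------------------------------------
    core = [peaksets[e] for e in CORE_EXPERIMENTS]
    anchors = interplay.anchors_from_peaksets(core, window=config.summit_window_bp)
    profiles = interplay.assign_profiles(
        anchors,
        *core,
        bound_window=config.summit_window_bp,
        notbound_window=config.notbound_window_bp,
    )
    profiles.to_csv(outdir / "profiles.tsv", sep="\t", index=False)
    overlap = interplay.pairwise_overlap(
        {e: peaksets[e] for e in CORE_EXPERIMENTS}, window=config.summit_window_bp
    )
    overlap.to_csv(outdir / "overlap.tsv", sep="\t", index=False)
    letter_freqs = profiles["letter"].value_counts(normalize=True).sort_index()
    summary["profile_frequencies"] = {k: float(v) for k, v in letter_freqs.items()}

    # --- motifs: GATA1-recruiting vs non-recruiting GATA2MP peaks ----------
    by_chrom = _sequence_lookup(sequences)
    profiles = profiles.assign(
        sequence_id=[
            _find_sequence(by_chrom, c, s) for c, s in zip(profiles["chrom"], profiles["summit"])
        ]
    )
    with_seq = profiles.dropna(subset=["sequence_id"])
    fg_ids = with_seq.loc[with_seq["letter"].isin(["c", "f"]), "sequence_id"].tolist()
    bg_ids = with_seq.loc[with_seq["letter"].isin(["a", "d"]), "sequence_id"].tolist()
    lexicon = motifs.default_lexicon()
    counts = motifs.count_matrix(sequences, lexicon)
    counts.to_csv(outdir / "motif_counts.tsv", sep="\t")
    if fg_ids and bg_ids:
        presence, _multi = motifs.motif_indicators(counts)
        enr = motifs.enrichment_table(
            fg_ids, bg_ids, presence,
            alpha=config.fdr_alpha, seed=config.stage_seed("motifs"),
        )
        enr.to_csv(outdir / "motif_enrichment.tsv", sep="\t", index=False)
        summary["motif_enrichment"] = {
            row["pattern"]: row["call"] for _, row in enr.iterrows()
        }

    # --- expression linkage -------------------------------------------------
    assignment = interplay.assign_nearest_tss(peaksets[GATA1_E], tss)
    bound_genes = sorted(set(assignment["gene_id"].dropna()))
    link_summary = {}
    for lineage, matrix in expression.items():
        k = min(config.kmeans_k, max(2, len(matrix.values) // 10))
        clusters = linkage.cluster_timecourse(
            matrix, k=k, seed=config.stage_seed(f"kmeans_{lineage}")
        )
        clusters.labels.to_csv(outdir / f"clusters_{lineage}.tsv", sep="\t")
        bound_here = [g for g in bound_genes if g in clusters.labels.index]
        enrich = linkage.cluster_enrichment(bound_here, clusters, alpha=config.fdr_alpha)
        enrich.to_csv(outdir / f"cluster_enrichment_{lineage}.tsv", sep="\t", index=False)
        # contingency: experiments x clusters of bound-gene counts
        contingency = {}
        for exp in CORE_EXPERIMENTS:
            asg = interplay.assign_nearest_tss(peaksets[exp], tss)
            genes = [g for g in set(asg["gene_id"].dropna()) if g in clusters.labels.index]
            contingency[exp] = clusters.labels.loc[genes].value_counts().reindex(
                range(k), fill_value=0
            )
        table = pd.DataFrame(contingency).T
        table = table.loc[:, table.sum(axis=0) > 0]
        ca = linkage.correspondence(table + 1)  # +1 smoothing guards zero rows
        ca.row_coords.to_csv(outdir / f"ca_rows_{lineage}.tsv", sep="\t")
        ca.col_coords.to_csv(outdir / f"ca_cols_{lineage}.tsv", sep="\t")
        link_summary[lineage] = {
            "k": k,
            "n_bound_genes": len(bound_here),
            "enriched_clusters": enrich.loc[enrich["call"] == "enriched", "cluster"].tolist(),
            "depleted_clusters": enrich.loc[enrich["call"] == "depleted", "cluster"].tolist(),
            "ca_total_inertia": ca.total_inertia,
        }
    summary["expression_link"] = link_summary

    # --- triad model --------------------------------------------------------
    fits = triad.fit_all_architectures(
        triad_expr,
        n_starts=config.n_architect_param_sets,
        n_keep=config.n_best_solutions,
        seed=config.stage_seed("triad"),
        refine="stochastic",
    )
    consensus, arch_summary = triad.rank_and_consensus(fits, low_energy_quantile=0.05)
    consensus.to_csv(outdir / "triad_consensus.tsv", sep="\t", index=False)
    arch_summary.to_csv(outdir / "triad_architectures.tsv", sep="\t", index=False)
    summary["triad_consensus"] = {
        row["edge"]: int(row["consensus_sign"]) for _, row in consensus.iterrows()
    }
    best_arch = int(arch_summary.loc[arch_summary["best_energy"].idxmin(), "arch_id"])
    summary["triad_best_architecture"] = best_arch

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    logger.info("pipeline done")
    return summary
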