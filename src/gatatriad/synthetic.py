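"""Ground-truth synthetic data for every pipeline stage.

Each generator emulates the statistical structure the corresponding analysis
stage assumes and returns explicit truth labels so recovery can be verified:
peak sets with planted binding profiles (a-g) and controlled summit
co-occurrence, peak sequences with planted IUPAC motif instances at
class-specific Poisson rates over an i.i.d. background, clustered expression
time courses with planted cluster-binding associations, and noisy three-gene
circuit trajectories generated from a known signed architecture.

Tag counts are negative-binomial (mean 50, dispersion 5) to give occupancy a
realistic spread. Summit jitter is truncated Gaussian, clipped at half the
summit-matching window so co-planted summits always pair. Background
sequence is i.i.d. with a specified GC fraction (no higher-order Markov
structure; see the methods note for what this does and does not emulate).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    GenomeSpec,
    PeakRecord,
    PeakSet,
    ExpressionMatrix,
    CORE_EXPERIMENTS,
)
from .interplay import PROFILE_BY_TRIPLE
from .motifs import IUPAC, MotifPattern, revcomp
from . import triad as triad_mod
from .triad import (
    CircuitArchitecture,
    DynamicsParameters,
    InteractionTimeProfile,
    DEFAULT_TIME_GRID,
)

logger = logging.getLogger("gatatriad")

#: default profile frequencies; qualitatively decreasing a > b > c > d > e > f > g
DEFAULT_PROFILE_FREQS = {
    "a": 0.34, "b": 0.25, "c": 0.16, "d": 0.10, "e": 0.07, "f": 0.05, "g": 0.03,
}

PEAK_HALFWIDTH = 150
TAG_MEAN = 50.0
TAG_DISPERSION = 5.0


def make_genome(n_chroms: int = 4, chrom_length: int = 30_000_000) -> GenomeSpec:
    return GenomeSpec(
        chrom_names=tuple(f"chr{i + 1}" for i in range(n_chroms)),
        chrom_lengths=tuple(chrom_length for _ in range(n_chroms)),
    )


def _nb_tags(rng: np.random.Generator, size: int, mean: float = TAG_MEAN, dispersion: float = TAG_DISPERSION):
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def plant_binding_profiles(
    profile_freqs: dict | None = None,
    n_regions: int = 1000,
    genome: GenomeSpec | None = None,
    summit_jitter_sd: float = 10.0,
    seed: int = 0,
    bound_window: int = 70,
    notbound_window: int = 1000,
    include_stages: bool = False,
    tag_mean: float = TAG_MEAN,
):
    """Plant regions with prescribed binding profiles across the GATA triple.

    For each region a profile letter is drawn from ``profile_freqs``; peaks
    are emitted exactly in the experiments the letter prescribes, with
    summits jittered (truncated at bound_window/2) around a shared anchor.
    Anchors of different regions are at least 2 x notbound_window apart.
    Returns ({experiment_id: PeakSet}, truth DataFrame).

    With ``include_stages`` the intermediate-stage sets GATA1_E1/E3 and
    GATA2_E1/E3 are also produced: most regions acquire GATA1 only after day
    3, except GATA2-retaining co-bound regions which may acquire it earlier,
    and GATA2 loss happens during day 1.
    """
    freqs = dict(DEFAULT_PROFILE_FREQS if profile_freqs is None else profile_freqs)
    total = sum(freqs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"profile frequencies sum to {total}, expected 1")
    for letter in freqs:
        if letter not in PROFILE_BY_TRIPLE.values():
            raise ValueError(f"unknown profile letter {letter!r}")
    genome = genome or make_genome()
    rng = np.random.default_rng(seed)

    spacing = 2 * notbound_window + 6 * bound_window + 2 * PEAK_HALFWIDTH
    margin = notbound_window + 2 * PEAK_HALFWIDTH
    # sequential anchor placement chromosome by chromosome
    anchors = []
    chrom_iter = iter(zip(genome.chrom_names, genome.chrom_lengths))
    chrom, length = next(chrom_iter)
    pos = margin
    for i in range(n_regions):
        while pos > length - margin:
            try:
                chrom, length = next(chrom_iter)
            except StopIteration:
                raise ValueError("genome too small for requested number of regions") from None
            pos = margin
        anchors.append((chrom, pos))
        pos += spacing

    letters = list(freqs)
    probs = np.array([freqs[l] for l in letters])
    drawn = rng.choice(letters, size=n_regions, p=probs) if n_regions else np.array([], dtype=object)

    jitter_cap = bound_window // 2
    records = {exp: [] for exp in CORE_EXPERIMENTS}
    staged_records = {}
    if include_stages:
        staged_records = {f"{tf}_{st}": [] for tf in ("GATA1", "GATA2") for st in ("E1", "E3")}
    truth_rows = []
    for i, ((chrom, anchor), letter) in enumerate(zip(anchors, drawn)):
        bound_triple = {
            exp: b
            for exp, b in zip(
                CORE_EXPERIMENTS,
                next(k for k, v in PROFILE_BY_TRIPLE.items() if v == letter),
            )
        }
        summits = {}
        for exp in CORE_EXPERIMENTS:
            if not bound_triple[exp]:
                continue
            jit = int(np.clip(rng.normal(0.0, summit_jitter_sd), -jitter_cap, jitter_cap))
            summit = anchor + jit
            summits[exp] = summit
            records[exp].append(
                PeakRecord(
                    chrom=chrom,
                    start=summit - PEAK_HALFWIDTH,
                    end=summit + PEAK_HALFWIDTH,
                    summit=summit,
                    tag_count=int(_nb_tags(rng, 1, mean=tag_mean)[0]),
                    experiment_id=exp,
                    name=f"r{i:06d}",
                )
            )
        if include_stages:
            _plant_stage_peaks(rng, staged_records, chrom, anchor, i, letter,
                               summit_jitter_sd, jitter_cap, tag_mean)
        truth_rows.append((f"r{i:06d}", chrom, anchor, letter))

    peaksets = {exp: PeakSet(exp, recs) for exp, recs in records.items()}
    for exp, recs in staged_records.items():
        peaksets[exp] = PeakSet(exp, recs)
    truth = pd.DataFrame(truth_rows, columns=["region_id", "chrom", "anchor", "letter"])
    return peaksets, truth


def _plant_stage_peaks(rng, staged_records, chrom, anchor, i, letter,
                       jitter_sd, jitter_cap, tag_mean):
    """Intermediate-stage binding consistent with the end-state letter."""
    gata1_e5 = letter in ("b", "c", "f", "g")
    gata2_mp = letter in ("a", "c", "d", "f")
    gata2_e5 = letter in ("c", "d", "e", "g")
    # GATA1 acquisition: mostly after day 3; GATA2-retaining co-bound regions earlier
    if gata1_e5:
        if letter == "c":
            first = rng.choice(["E1", "E3", "E5"], p=[0.3, 0.3, 0.4])
        else:
            first = rng.choice(["E1", "E3", "E5"], p=[0.05, 0.15, 0.8])
        stages = {"E1": first == "E1", "E3": first in ("E1", "E3")}
    else:
        stages = {"E1": False, "E3": False}
    for st, bound in stages.items():
        if bound:
            jit = int(np.clip(rng.normal(0.0, jitter_sd), -jitter_cap, jitter_cap))
            s = anchor + jit
            staged_records[f"GATA1_{st}"].append(
                PeakRecord(chrom, s - PEAK_HALFWIDTH, s + PEAK_HALFWIDTH, s,
                           int(_nb_tags(rng, 1, mean=tag_mean)[0]), f"GATA1_{st}", f"r{i:06d}")
            )
    # GATA2: loss (a, f) during day 1; retention (c, d) throughout; de novo
    # (e, g) emerging from day 1
    for st in ("E1", "E3"):
        if gata2_mp and gata2_e5:
            bound = True
        elif gata2_mp and not gata2_e5:
            bound = False  # lost during day 1
        elif gata2_e5 and not gata2_mp:
            bound = True  # de novo peaks emerge at day 1
        else:
            bound = False
        if bound:
            jit = int(np.clip(rng.normal(0.0, jitter_sd), -jitter_cap, jitter_cap))
            s = anchor + jit
            staged_records[f"GATA2_{st}"].append(
                PeakRecord(chrom, s - PEAK_HALFWIDTH, s + PEAK_HALFWIDTH, s,
                           int(_nb_tags(rng, 1, mean=tag_mean)[0]), f"GATA2_{st}", f"r{i:06d}")
            )


def _sample_instance(rng: np.random.Generator, pattern_string: str) -> str:
    return "".join(rng.choice(list(IUPAC[ch])) for ch in pattern_string)


def generate_sequences_with_motifs(
    regions: pd.DataFrame,
    background_gc: float = 0.42,
    motif_rates: dict | None = None,
    seed: int = 0,
    max_place_tries: int = 200,
):
    """Sequences with planted, non-overlapping motif instances.

    ``regions`` needs columns region_id, length, class. ``motif_rates`` maps
    (class, MotifPattern) -> expected planted copies per region (Poisson).
    Returns ({region_id: sequence}, plants DataFrame with exact positions,
    strands, and realized instances).
    """
    motif_rates = motif_rates or {}
    for (cls, pat), rate in motif_rates.items():
        if rate < 0:
            raise ValueError(f"negative motif rate for ({cls}, {pat.name})")
    rng = np.random.default_rng(seed)
    gc = float(background_gc)
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))

    sequences = {}
    plant_rows = []
    for _, row in regions.iterrows():
        rid, length, cls = row["region_id"], int(row["length"]), row["class"]
        seq = rng.choice(bases, size=length, p=base_p)
        occupied = []
        for (rate_cls, pattern), rate in motif_rates.items():
            if rate_cls != cls or rate == 0:
                continue
            variants = pattern.variants()
            if min(len(v) for v in variants) > length:
                raise ValueError(
                    f"motif {pattern.name} longer than region {rid} ({length} bp)"
                )
            n_copies = rng.poisson(rate)
            for _ in range(n_copies):
                variant = variants[rng.integers(len(variants))]
                L = len(variant)
                if L > length:
                    continue
                placed = False
                for _try in range(max_place_tries):
                    start = int(rng.integers(0, length - L + 1))
                    if any(start < e and start + L > s for s, e in occupied):
                        continue
                    strand = "+" if rng.random() < 0.5 else "-"
                    inst = _sample_instance(rng, variant)
                    ins = inst if strand == "+" else revcomp(inst)
                    seq[start : start + L] = list(ins)
                    occupied.append((start, start + L))
                    plant_rows.append((rid, pattern.name, start, strand, inst))
                    placed = True
                    break
                if not placed:
                    logger.warning(
                        "could not place %s in region %s without overlap", pattern.name, rid
                    )
        sequences[rid] = "".join(seq)
    plants = pd.DataFrame(
        plant_rows, columns=["region_id", "pattern", "position", "strand", "instance"]
    )
    return sequences, plants


def default_centroids(k: int, timepoints: np.ndarray, seed: int = 0) -> np.ndarray:
    """Smooth, z-scored random centroid shapes (k x timepoints)."""
    rng = np.random.default_rng(seed)
    t = (timepoints - timepoints[0]) / (timepoints[-1] - timepoints[0])
    shapes = []
    for j in range(k):
        a, b, c = rng.normal(size=3)
        phase = rng.uniform(0, 2 * np.pi)
        curve = a * t + b * np.sin(np.pi * t + phase) + c * t**2
        curve = (curve - curve.mean()) / (curve.std() + 1e-12)
        shapes.append(curve)
    return np.asarray(shapes)


def generate_clustered_expression(
    n_genes: int = 1000,
    k: int = 5,
    centroid_shapes: np.ndarray | None = None,
    noise_sd: float = 0.3,
    association: dict | None = None,
    classes=("bound", "unbound"),
    timepoints: np.ndarray = DEFAULT_TIME_GRID,
    seed: int = 0,
    lineage: str = "erythroid",
):
    """Clustered time courses with planted binding-class associations.

    Each gene is its cluster centroid plus i.i.d. Gaussian noise. A binding
    class is drawn per gene with probability proportional to
    ``association[(cluster, class)]`` (default 1). Returns
    (ExpressionMatrix, truth DataFrame with true cluster and binding class).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    association = association or {}
    for key, mult in association.items():
        if mult <= 0:
            raise ValueError(f"odds multiplier for {key} must be > 0")
    rng = np.random.default_rng(seed)
    timepoints = np.asarray(timepoints, dtype=float)
    centroids = (
        centroid_shapes
        if centroid_shapes is not None
        else default_centroids(k, timepoints, seed=seed)
    )
    if centroids.shape != (k, len(timepoints)):
        raise ValueError("centroid_shapes must be k x len(timepoints)")

    cluster_ids = rng.integers(0, k, size=n_genes)
    values = centroids[cluster_ids] + rng.normal(0.0, noise_sd, size=(n_genes, len(timepoints)))
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]

    class_labels = []
    classes = list(classes)
    for c in cluster_ids:
        w = np.array([association.get((int(c), cls), 1.0) for cls in classes], dtype=float)
        class_labels.append(classes[rng.choice(len(classes), p=w / w.sum())])

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=timepoints), lineage=lineage
    )
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "cluster": cluster_ids, "binding_class": class_labels}
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Triad circuit ground truth


def triad_truth(gata2_pu1_sign: int = -1):
    """The ground-truth circuit used by the sign-recovery experiment.

    GATA2 self-activates (decreasing strength) and activates GATA1; the
    GATA1->GATA2 and PU.1->GATA2 strengths are zero, making GATA2
    autonomous, which keeps the planted knockdown phenotypes clean (Gata2
    knockdown derepresses Pu.1; Pu.1 knockdown leaves Gata2 intact).

    The Pu.1 trace is designed to be diagnostic for the GATA2->PU.1 sign:
    it falls early and recovers late (fall-then-rise). Such a shape demands
    an exogenous drive on Pu.1 that strengthens over time; every other input
    to Pu.1 (constant self-activation, growing GATA1 antagonism) pushes the
    trajectory monotonically, so only the correctly signed GATA2 edge can
    explain it. In the default (repression) world the GATA2 edge weakens as
    GATA2 binding decays, so the strengthening drive is *derepression*; in
    the activation control world the generator posits GATA2 binding at the
    Pu.1 locus that grows during differentiation (an increasing trend, with
    GATA2 expression settling at a plateau), so the strengthening drive is
    the *activation* itself and the recovered consensus flips sign.
    Returns (architecture, timeprofiles, parameters, x0); the timeprofiles
    differ between the two worlds and must be passed to the fits.
    """
    if gata2_pu1_sign not in (-1, +1):
        raise ValueError("gata2_pu1_sign must be -1 or +1")
    # unknown edges (a2..a6) = (G2->G2, G2->G1, G1->G2, G2->P, P->G2)
    bits = (1, 1, 0, 1 if gata2_pu1_sign > 0 else 0, 0)
    arch_id = int("".join(str(b) for b in bits), 2)
    arch = CircuitArchitecture.from_id(arch_id)
    profiles = triad_mod.default_timeprofiles()
    shared = {
        "G1->G1": 4.0,
        "P-|G1": 0.3,
        "G2->G2": 7.0,
        "G2->G1": 0.8,
        "G1->G2": 0.0,
        "P->G2": 0.0,
    }
    if gata2_pu1_sign < 0:
        params = DynamicsParameters(
            alpha=np.array([0.06, 0.05, 0.07]),
            gamma=np.array([0.06, 0.07, 0.08]),
            strengths={**shared, "P->P": 14.0, "G1-|P": 0.3, "G2->P": 8.0},
            x_input=0.15,
            h=2.0,
        )
        x0 = np.array([0.05, 0.85, 0.55])
    else:
        profiles["G2->P"] = InteractionTimeProfile("increasing", float(np.log(16.0)))
        params = DynamicsParameters(
            alpha=np.array([0.06, 0.028, 0.25]),
            gamma=np.array([0.06, 0.025, 0.25]),
            strengths={**shared, "P->P": 0.2, "G1-|P": 0.15, "G2->P": 0.35},
            x_input=0.15,
            h=2.0,
        )
        x0 = np.array([0.05, 0.85, 0.75])
    return arch, profiles, params, x0


def simulate_noisy_timecourse(
    architecture: CircuitArchitecture,
    params: DynamicsParameters,
    time_grid: np.ndarray = DEFAULT_TIME_GRID,
    noise_sd: float = 0.05,
    seed: int = 0,
    timeprofiles: dict | None = None,
    x0: np.ndarray | None = None,
):
    """Noisy three-gene trajectories from a known architecture.

    Integrates the circuit, adds i.i.d. Gaussian noise (clipped at zero),
    and returns (ExpressionMatrix, truth dict).
    """
    timeprofiles = timeprofiles or triad_mod.default_timeprofiles()
    traj = triad_mod.simulate(architecture, timeprofiles, params, time_grid, x0=x0)
    rng = np.random.default_rng(seed)
    noisy = np.clip(traj.values + rng.normal(0.0, noise_sd, size=traj.values.shape), 0.0, None)
    matrix = ExpressionMatrix(
        values=pd.DataFrame(noisy, index=list(triad_mod.GENES), columns=np.asarray(time_grid, float)),
        lineage="erythroid",
    )
    truth = {
        "arch_id": architecture.arch_id,
        "signs": dict(architecture.signs),
        "params": params,
        "clean": traj,
    }
    return matrix, truth


# ---------------------------------------------------------------------------
# Full bundle


@dataclass
class SyntheticBundle:
    genome: GenomeSpec
    peaksets: dict
    sequences: dict
    expression: dict  # lineage -> ExpressionMatrix
    triad_expression: ExpressionMatrix
    tss: pd.DataFrame
    truth: dict  # stage name -> truth table / object


def make_bundle(
    seed: int = 0,
    n_regions: int = 300,
    n_genes: int = 400,
    k_clusters: int = 5,
    noise_sd: float = 0.3,
    region_length: int = 300,
    summit_jitter_sd: float = 10.0,
) -> SyntheticBundle:
    """A coherent synthetic data set feeding every pipeline stage.

    Peak regions carry planted profiles; their sequences carry class-specific
    motif rates (GATA1-recruiting classes get canonical GATA motifs, GATA2-
    only classes get WGAT repeats); genes sit near region anchors so peak-to
    gene assignment is well-defined; expression clusters associate with
    GATA1-binding; and a three-gene trajectory from the ground-truth circuit
    feeds the architecture fit.
    """
    from .motifs import default_lexicon

    rng_seq = seed * 10 + 1
    genome = make_genome()
    peaksets, peak_truth = plant_binding_profiles(
        n_regions=n_regions, genome=genome, summit_jitter_sd=summit_jitter_sd, seed=seed
    )

    lex = {p.name: p for p in default_lexicon()}
    region_rows = []
    for _, row in peak_truth.iterrows():
        cls = "recruiting" if row["letter"] in ("c", "f", "g", "b") else "nonrecruiting"
        region_rows.append((row["region_id"], region_length, cls, row["chrom"], row["anchor"]))
    regions = pd.DataFrame(
        region_rows, columns=["region_id", "length", "class", "chrom", "anchor"]
    )
    motif_rates = {
        ("recruiting", lex["WGATAAG"]): 2.0,
        ("recruiting", lex["WGATAR"]): 1.0,
        ("nonrecruiting", lex["WGAT_repeat_3_4"]): 1.5,
        ("nonrecruiting", lex["WGATAR"]): 0.3,
    }
    seqs_by_region, plants = generate_sequences_with_motifs(
        regions, motif_rates=motif_rates, seed=rng_seq
    )
    # FASTA ids follow the chrom:start-end convention for the anchor window
    sequences = {}
    seq_id_by_region = {}
    for _, row in regions.iterrows():
        start = int(row["anchor"]) - region_length // 2
        sid = f"{row['chrom']}:{start}-{start + region_length}"
        sequences[sid] = seqs_by_region[row["region_id"]]
        seq_id_by_region[row["region_id"]] = sid
    regions["sequence_id"] = regions["region_id"].map(seq_id_by_region)

    # genes: one TSS near each of the first n_genes anchors (cycling)
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    anchor_cycle = peak_truth.iloc[np.arange(n_genes) % len(peak_truth)]
    tss = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": anchor_cycle["chrom"].to_numpy(),
            "tss_position": anchor_cycle["anchor"].to_numpy() + 250,
            "strand": np.where(np.arange(n_genes) % 2 == 0, "+", "-"),
        }
    )

    # expression: GATA1-bound genes (regions with GATA1_E peaks) enriched in
    # cluster 0, depleted from cluster 1
    letters = anchor_cycle["letter"].to_numpy()
    bound_class = np.where(np.isin(letters, ("b", "c", "f", "g")), "boundG1", "unbound")
    association = {(0, "boundG1"): 6.0, (1, "boundG1"): 0.15}
    expr, expr_truth = generate_clustered_expression(
        n_genes=n_genes, k=k_clusters, noise_sd=noise_sd,
        association=association, classes=("boundG1", "unbound"), seed=seed + 17,
    )
    expr_truth["planted_binding_class"] = bound_class

    arch, profiles, params, x0 = triad_truth()
    triad_expr, triad_truth_rec = simulate_noisy_timecourse(
        arch, params, noise_sd=0.05, seed=seed + 29, timeprofiles=profiles, x0=x0
    )

    return SyntheticBundle(
        genome=genome,
        peaksets=peaksets,
        sequences=sequences,
        expression={"erythroid": expr},
        triad_expression=triad_expr,
        tss=tss,
        truth={
            "profiles": peak_truth,
            "regions": regions,
            "plants": plants,
            "expression": expr_truth,
            "triad": triad_truth_rec,
        },
    )


def write_bundle(bundle: SyntheticBundle, outdir) -> dict:
    """Write a bundle in the pipeline's input formats; returns the manifest."""
    from pathlib import Path
    from .io import write_peaks, write_fasta, write_expression, write_tss

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"peaks": {}, "expression": {}}
    for exp, ps in bundle.peaksets.items():
        path = outdir / f"peaks_{exp}.bed"
        write_peaks(ps, path)
        manifest["peaks"][exp] = str(path)
    fasta = outdir / "regions.fa"
    write_fasta(bundle.sequences, fasta)
    manifest["fasta"] = str(fasta)
    for lineage, mat in bundle.expression.items():
        path = outdir / f"expression_{lineage}.tsv"
        write_expression(mat, path)
        manifest["expression"][lineage] = str(path)
    triad_path = outdir / "expression_triad.tsv"
    write_expression(bundle.triad_expression, triad_path)
    manifest["triad_expression"] = str(triad_path)
    tss_path = outdir / "tss.tsv"
    write_tss(bundle.tss, tss_path)
    manifest["tss"] = str(tss_path)
    for name, table in bundle.truth.items():
        if isinstance(table, pd.DataFrame):
            table.to_csv(outdir / f"truth_{name}.tsv", sep="\t", index=False)
    return manifest
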