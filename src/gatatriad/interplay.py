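"""Cross-experiment peak interplay.

Summit-based matching of peaks between ChIP-seq experiments, stringent
bound / not-bound calls, the seven GATA binding profiles a-g over the triple
(GATA2 in MP, GATA2 in E, GATA1 in E), binding-timing classification across
differentiation stages, occupancy quantitation, and peak-to-gene assignment.

Two summits denote the same bound region when they fall within
``bound_window`` (70 bp by default, inclusive). A region is stringently not
bound in an experiment when no peak of that experiment comes within
``notbound_window`` (1 kb) of the region's anchor, measured anchor-to-nearest
peak edge: a peak overlapping the window in any base blocks the not-bound
call. Everything in between is ambiguous and excluded from profiles.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PeakSet, CORE_EXPERIMENTS, STAGE_ORDER

logger = logging.getLogger("gatatriad")

BOUND = "bound"
NOT_BOUND = "not_bound"
AMBIGUOUS = "ambiguous"

#: profile letter for each (GATA2@MP, GATA2@E, GATA1@E) bound-triple
PROFILE_BY_TRIPLE = {
    (True, False, False): "a",
    (False, False, True): "b",
    (True, True, True): "c",
    (True, True, False): "d",
    (False, True, False): "e",
    (True, False, True): "f",
    (False, True, True): "g",
}
PROFILE_LETTERS = tuple("abcdefg")
UNCLASSIFIED = "unclassified"


@dataclass
class Pairing:
    """Result of summit matching: index pairs into (a, b) plus leftovers."""

    pairs: list  # [(i_a, i_b), ...] indices into the record tuples
    unmatched_a: list
    unmatched_b: list


def match_summits(a: PeakSet, b: PeakSet, window: int = 70) -> Pairing:
    """Greedy nearest-summit matching per chromosome.

    Candidate pairs with |summit_a - summit_b| <= window are taken in order
    of increasing distance; distance ties break toward the earlier-sorted
    peak. Each peak participates in at most one pair.
    """
    pairs = []
    used_a, used_b = set(), set()
    by_chrom_b = b.summits_by_chrom()
    for chrom, (sa, ia) in a.summits_by_chrom().items():
        if chrom not in by_chrom_b:
            continue
        sb, ib = by_chrom_b[chrom]
        cands = []
        lo = np.searchsorted(sb, sa - window, side="left")
        hi = np.searchsorted(sb, sa + window, side="right")
        for k in range(len(sa)):
            for j in range(lo[k], hi[k]):
                cands.append((abs(int(sa[k]) - int(sb[j])), int(ia[k]), int(ib[j])))
        cands.sort()
        for _dist, i, j in cands:
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            pairs.append((i, j))
    pairs.sort()
    unmatched_a = [i for i in range(len(a)) if i not in used_a]
    unmatched_b = [j for j in range(len(b)) if j not in used_b]
    return Pairing(pairs=pairs, unmatched_a=unmatched_a, unmatched_b=unmatched_b)


def classify_status(
    anchor,
    other: PeakSet,
    bound_window: int = 70,
    notbound_window: int = 1000,
    permissive: PeakSet | None = None,
) -> str:
    """Stringent bound / not-bound / ambiguous call for one anchor.

    ``permissive`` is the non-filtered peak list used for the not-bound test
    when available; otherwise the stringent set itself is used.
    """
    chrom, summit = anchor
    statuses = classify_statuses(
        {chrom: np.array([summit], dtype=np.int64)},
        other,
        bound_window=bound_window,
        notbound_window=notbound_window,
        permissive=permissive,
    )
    return statuses[chrom][0]


def classify_statuses(
    anchors_by_chrom: dict,
    other: PeakSet,
    bound_window: int = 70,
    notbound_window: int = 1000,
    permissive: PeakSet | None = None,
) -> dict:
    """Vectorized status calls: {chrom: array of status strings}."""
    notbound_set = permissive if permissive is not None else other
    summits = other.summits_by_chrom()
    intervals = notbound_set.intervals_by_chrom()
    out = {}
    for chrom, pos in anchors_by_chrom.items():
        pos = np.asarray(pos, dtype=np.int64)
        n = len(pos)
        status = np.full(n, AMBIGUOUS, dtype=object)
        if chrom in summits:
            s, _ = summits[chrom]
            idx = np.searchsorted(s, pos)
            dist = np.full(n, np.iinfo(np.int64).max)
            right_ok = idx < len(s)
            dist[right_ok] = np.abs(s[idx[right_ok]] - pos[right_ok])
            left_ok = idx > 0
            dist[left_ok] = np.minimum(dist[left_ok], np.abs(s[idx[left_ok] - 1] - pos[left_ok]))
            bound = dist <= bound_window
        else:
            bound = np.zeros(n, dtype=bool)
        if chrom in intervals:
            starts, _ends, maxends = intervals[chrom]
            hi = pos + notbound_window
            lo = pos - notbound_window
            # a peak blocks not_bound if start <= hi and end-1 >= lo
            k = np.searchsorted(starts, hi, side="right")
            blocked = np.zeros(n, dtype=bool)
            has_left = k > 0
            blocked[has_left] = maxends[k[has_left] - 1] - 1 >= lo[has_left]
        else:
            blocked = np.zeros(n, dtype=bool)
        status[bound] = BOUND
        status[~bound & ~blocked] = NOT_BOUND
        out[chrom] = status
    return out


def anchors_from_peaksets(peaksets, window: int = 70) -> list:
    """Deduplicated union of summits across peak sets.

    Summits are pooled per chromosome, sorted, and grouped greedily: a summit
    joins the current group while it lies within ``window`` of the group's
    first summit (which becomes the anchor). Deterministic and documented;
    equivalent to iterated summit matching for well-separated regions.
    """
    pooled = {}
    for ps in peaksets:
        for r in ps:
            pooled.setdefault(r.chrom, []).append(r.summit)
    anchors = []
    for chrom in sorted(pooled):
        positions = sorted(pooled[chrom])
        group_start = None
        for p in positions:
            if group_start is None or p - group_start > window:
                group_start = p
                anchors.append((chrom, p))
    return anchors


def assign_profiles(
    anchors,
    gata2_mp: PeakSet,
    gata2_e: PeakSet,
    gata1_e: PeakSet,
    bound_window: int = 70,
    notbound_window: int = 1000,
    permissive: dict | None = None,
) -> pd.DataFrame:
    """Profile letters a-g per anchor region.

    Returns a DataFrame with columns chrom, summit, one status column per
    core experiment, and ``letter`` (a-g or 'unclassified' when any status is
    ambiguous or no experiment is bound).
    """
    permissive = permissive or {}
    by_chrom = {}
    order = []
    for chrom, summit in anchors:
        by_chrom.setdefault(chrom, []).append(summit)
        order.append((chrom, summit))
    by_chrom = {c: np.array(v, dtype=np.int64) for c, v in by_chrom.items()}

    status_cols = {}
    for exp, ps in zip(CORE_EXPERIMENTS, (gata2_mp, gata2_e, gata1_e)):
        st = classify_statuses(
            by_chrom,
            ps,
            bound_window=bound_window,
            notbound_window=notbound_window,
            permissive=permissive.get(exp),
        )
        # map back to anchor order
        counters = {c: 0 for c in by_chrom}
        col = []
        for chrom, _ in order:
            col.append(st[chrom][counters[chrom]])
            counters[chrom] += 1
        status_cols[exp] = col

    letters = []
    for i in range(len(order)):
        triple = tuple(status_cols[exp][i] for exp in CORE_EXPERIMENTS)
        if AMBIGUOUS in triple:
            letters.append(UNCLASSIFIED)
        else:
            key = tuple(s == BOUND for s in triple)
            letters.append(PROFILE_BY_TRIPLE.get(key, UNCLASSIFIED))
    df = pd.DataFrame(
        {
            "chrom": [c for c, _ in order],
            "summit": [s for _, s in order],
            **{f"status_{exp}": status_cols[exp] for exp in CORE_EXPERIMENTS},
            "letter": letters,
        }
    )
    return df


def pairwise_overlap(peaksets: dict, window: int = 70) -> pd.DataFrame:
    """Ordered-pair overlap fractions: matched(A, B) / |A| for every pair.

    Empty sets yield NaN fractions (undefined, not zero). Returns a tidy
    DataFrame with columns a, b, n_a, matched, fraction.
    """
    if len(peaksets) < 2:
        raise ValueError("need at least two peak sets")
    names = list(peaksets)
    rows = []
    for na in names:
        for nb in names:
            a, b = peaksets[na], peaksets[nb]
            if len(a) == 0:
                rows.append((na, nb, 0, 0, np.nan))
                continue
            if na == nb:
                rows.append((na, nb, len(a), len(a), 1.0))
                continue
            matched = len(match_summits(a, b, window=window).pairs)
            rows.append((na, nb, len(a), matched, matched / len(a)))
    return pd.DataFrame(rows, columns=["a", "b", "n_a", "matched", "fraction"])


def quantify_occupancy(region, tags) -> int:
    """Number of tag positions within [start, end) of the region.

    ``region`` is (start, end) or (chrom, start, end); ``tags`` is a sorted
    array of tag positions (for the region's chromosome).
    """
    if len(region) == 3:
        _, start, end = region
    else:
        start, end = region
    tags = np.asarray(tags)
    return int(np.searchsorted(tags, end, side="left") - np.searchsorted(tags, start, side="left"))


def timing_classify(
    anchors,
    staged_peaksets: dict,
    stage_order=STAGE_ORDER,
    bound_window: int = 70,
) -> pd.DataFrame:
    """First and last differentiation stage at which each anchor is bound.

    ``staged_peaksets`` maps TF name -> {stage -> PeakSet}. Regions never
    bound by a TF get no row for that TF (absent from the acquisition table).
    """
    by_chrom = {}
    order = []
    for chrom, summit in anchors:
        by_chrom.setdefault(chrom, []).append(summit)
        order.append((chrom, summit))
    by_chrom = {c: np.array(v, dtype=np.int64) for c, v in by_chrom.items()}

    rows = []
    for tf, stages in staged_peaksets.items():
        bound_by_stage = {}
        for stage, ps in stages.items():
            st = classify_statuses(by_chrom, ps, bound_window=bound_window)
            counters = {c: 0 for c in by_chrom}
            flags = []
            for chrom, _ in order:
                flags.append(st[chrom][counters[chrom]] == BOUND)
                counters[chrom] += 1
            bound_by_stage[stage] = flags
        for i, (chrom, summit) in enumerate(order):
            stages_bound = [s for s in stage_order if bound_by_stage.get(s, [False] * len(order))[i]]
            if not stages_bound:
                continue
            rows.append((chrom, summit, tf, stages_bound[0], stages_bound[-1]))
    return pd.DataFrame(rows, columns=["chrom", "summit", "tf", "first_stage", "last_stage"])


def timing_summary(timing: pd.DataFrame, letters: pd.DataFrame, stage_order=STAGE_ORDER) -> pd.DataFrame:
    """Acquisition counts: per (profile letter, TF), how many regions first
    bind at each stage. ``letters`` is the assign_profiles output."""
    merged = timing.merge(letters[["chrom", "summit", "letter"]], on=["chrom", "summit"], how="left")
    table = (
        merged.groupby(["letter", "tf", "first_stage"]).size().rename("n").reset_index()
    )
    table["first_stage"] = pd.Categorical(table["first_stage"], categories=stage_order, ordered=True)
    return table.sort_values(["letter", "tf", "first_stage"]).reset_index(drop=True)


def assign_nearest_tss(peaks: PeakSet, tss_table: pd.DataFrame) -> pd.DataFrame:
    """Assign each peak to the gene whose TSS is nearest its summit.

    Distance ties break toward the lexicographically smaller gene_id. Peaks
    on chromosomes absent from the TSS table are left unassigned (NaN) and
    logged. Returns a DataFrame: chrom, summit, peak name, gene_id, distance.
    """
    if len(tss_table) == 0:
        raise ValueError("TSS table is empty")
    tss_sorted = tss_table.sort_values(["chrom", "tss_position", "gene_id"])
    by_chrom = {
        chrom: (
            grp["tss_position"].to_numpy(dtype=np.int64),
            grp["gene_id"].to_numpy(dtype=object),
        )
        for chrom, grp in tss_sorted.groupby("chrom")
    }
    rows = []
    for r in peaks:
        if r.chrom not in by_chrom:
            logger.warning("peak %s on chromosome %s has no TSS annotation", r.name, r.chrom)
            rows.append((r.chrom, r.summit, r.name, None, np.nan))
            continue
        pos, genes = by_chrom[r.chrom]
        idx = int(np.searchsorted(pos, r.summit))
        best_d = None
        for j in (idx - 1, idx):
            if 0 <= j < len(pos):
                d = abs(int(pos[j]) - r.summit)
                if best_d is None or d < best_d:
                    best_d = d
        # collect all equidistant candidates around the insertion point
        cands = []
        j = idx - 1
        while j >= 0 and abs(int(pos[j]) - r.summit) == best_d:
            cands.append(genes[j])
            j -= 1
        j = idx
        while j < len(pos) and abs(int(pos[j]) - r.summit) == best_d:
            cands.append(genes[j])
            j += 1
        rows.append((r.chrom, r.summit, r.name, min(cands), best_d))
    return pd.DataFrame(rows, columns=["chrom", "summit", "name", "gene_id", "distance"])


def binding_complexity_score(gene: str, peak_genes: pd.DataFrame, status: pd.DataFrame) -> int:
    """Surrogate dynamic binding complexity score for one gene.

    Counts distinct (region, experiment) bound events over the regions
    assigned to the gene: the number of 'bound' cells in the gene's slice of
    the region x experiment status matrix. ``peak_genes`` is the
    assign_nearest_tss output (or any frame with region index + gene_id);
    ``status`` is indexed by region with one boolean/status column per
    experiment.
    """
    regions = peak_genes.index[peak_genes["gene_id"] == gene]
    if len(regions) == 0:
        return 0
    sub = status.loc[status.index.intersection(regions)]
    if sub.size == 0:
        return 0
    vals = sub.to_numpy()
    if vals.dtype == bool:
        return int(vals.sum())
    return int((vals == BOUND).sum())
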