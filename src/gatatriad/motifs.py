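"""IUPAC motif matching and permutation enrichment over peak sequences.

The motif lexicon carries the consensus motifs relevant to GATA/ETS biology:
the canonical WGATAR/WGATAAG/AGATAAG GATA motifs and the WGATAASA variant,
direct-repeat and palindromic WGAT configurations with 3-4 / 3-5 bp spacers,
ETS (GGAAGTG, AAAGAGGAAGTG, GGAAG), AP-1/NF-E2/MAF (TGASTCA), RUNX1 (CCACA),
MYC (CACGTGAC), an SCL-like E box (CWGCWGC), a degenerate GATA (WGNTAAG),
and the composite half-E box-GATA motif CTG-N8-WGATAA.

Matching semantics: a pattern character matches a sequence character when the
sequence character's base set is contained in the pattern character's IUPAC
set; consequently an N in the sequence matches only an N in the pattern,
while a pattern N matches anything. Overlapping matches are all reported.
Enrichment uses the region-level presence statistic (fraction of regions
with at least one match) against a resampling null, with Benjamini-Hochberg
FDR across the lexicon.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

KINDS = ("simple_iupac", "gapped_composite", "spaced_repeat", "spaced_palindrome")


def revcomp(s: str) -> str:
    """Reverse complement of an IUPAC string."""
    return s.translate(_COMPLEMENT)[::-1]


def _validate_iupac(core: str, name: str) -> str:
    core = core.upper()
    for ch in core:
        if ch not in IUPAC:
            raise ValueError(f"pattern {name!r}: invalid IUPAC character {ch!r}")
    if not core:
        raise ValueError(f"pattern {name!r}: empty core")
    return core


@dataclass(frozen=True)
class MotifPattern:
    name: str
    kind: str
    cores: tuple
    spacer_range: tuple | None = None

    def variants(self) -> list:
        """Concrete IUPAC strings, one per spacer length (spacers as N runs)."""
        if self.kind == "simple_iupac":
            return [self.cores[0]]
        lo, hi = self.spacer_range
        return [self.cores[0] + "N" * s + self.cores[1] for s in range(lo, hi + 1)]

    @property
    def min_length(self) -> int:
        return min(len(v) for v in self.variants())


def compile_pattern(
    name: str,
    kind: str = "simple_iupac",
    cores: Sequence[str] | str = (),
    spacer_range: tuple | None = None,
) -> MotifPattern:
    """Build a normalized MotifPattern.

    For ``spaced_palindrome`` only the first core is given; the second core
    is its reverse complement. Lowercase letters (as in wGATAAsA) are
    normalized to uppercase and matched by their plain IUPAC meaning.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown pattern kind {kind!r}")
    if isinstance(cores, str):
        cores = (cores,)
    cores = tuple(_validate_iupac(c, name) for c in cores)
    if kind == "simple_iupac":
        if len(cores) != 1:
            raise ValueError(f"pattern {name!r}: simple patterns take one core")
        return MotifPattern(name=name, kind=kind, cores=cores)
    if spacer_range is None or spacer_range[0] > spacer_range[1] or spacer_range[0] < 0:
        raise ValueError(f"pattern {name!r}: invalid spacer range {spacer_range}")
    spacer_range = (int(spacer_range[0]), int(spacer_range[1]))
    if kind == "spaced_repeat":
        if len(cores) != 1:
            raise ValueError(f"pattern {name!r}: spaced_repeat takes one core")
        cores = (cores[0], cores[0])
    elif kind == "spaced_palindrome":
        if len(cores) != 1:
            raise ValueError(f"pattern {name!r}: spaced_palindrome takes one core")
        cores = (cores[0], revcomp(cores[0]))
    elif kind == "gapped_composite":
        if len(cores) != 2:
            raise ValueError(f"pattern {name!r}: gapped_composite takes two cores")
    return MotifPattern(name=name, kind=kind, cores=cores, spacer_range=spacer_range)


def default_lexicon() -> list:
    """The standard motif lexicon used throughout the pipeline."""
    return [
        compile_pattern("WGATAR", cores="WGATAR"),
        compile_pattern("WGATAAG", cores="WGATAAG"),
        compile_pattern("AGATAAG", cores="AGATAAG"),
        compile_pattern("WGATAASA", cores="WGATAASA"),
        compile_pattern("WGAT_repeat_3_4", kind="spaced_repeat", cores="WGAT", spacer_range=(3, 4)),
        compile_pattern(
            "WGAT_palindrome_3_5", kind="spaced_palindrome", cores="WGAT", spacer_range=(3, 5)
        ),
        compile_pattern("GGAAGTG", cores="GGAAGTG"),
        compile_pattern("AAAGAGGAAGTG", cores="AAAGAGGAAGTG"),
        compile_pattern("GGAAG", cores="GGAAG"),
        compile_pattern("TGASTCA", cores="TGASTCA"),
        compile_pattern("CCACA", cores="CCACA"),
        compile_pattern("CACGTGAC", cores="CACGTGAC"),
        compile_pattern("CWGCWGC", cores="CWGCWGC"),
        compile_pattern("WGNTAAG", cores="WGNTAAG"),
        compile_pattern(
            "CTG_N8_WGATAA", kind="gapped_composite", cores=("CTG", "WGATAA"), spacer_range=(8, 8)
        ),
    ]


def _char_class(ch: str) -> str:
    # sequence N matches only pattern N; pattern N matches any base or N
    letters = IUPAC[ch] + ("N" if ch == "N" else "")
    return f"[{letters}]" if len(letters) > 1 else letters


def _variant_regex(variant: str):
    return re.compile("(?=(" + "".join(_char_class(c) for c in variant) + "))")


_SEQ_OK = re.compile(r"^[ACGTN]*$")


def scan_sequence(seq: str, pattern: MotifPattern, both_strands: bool = True) -> list:
    """All (offset, strand) matches of the pattern in the sequence.

    Offsets are 0-based positions on the forward strand where the match
    begins; '-' strand matches are matches of the pattern's reverse
    complement at that forward offset. Every spacer length is tested for
    gapped/spaced kinds; duplicate (offset, strand) hits (from different
    spacer lengths) are collapsed.
    """
    seq = seq.upper()
    if not _SEQ_OK.match(seq):
        bad = next(ch for ch in seq if ch not in "ACGTN")
        raise ValueError(f"sequence contains invalid character {bad!r}")
    hits = set()
    for variant in pattern.variants():
        for m in _variant_regex(variant).finditer(seq):
            hits.add((m.start(), "+"))
        if both_strands:
            for m in _variant_regex(revcomp(variant)).finditer(seq):
                hits.add((m.start(), "-"))
    return sorted(hits)


def count_matrix(
    sequences: Mapping[str, str],
    lexicon: Iterable[MotifPattern] | None = None,
    regions: Sequence[str] | None = None,
    both_strands: bool = True,
) -> pd.DataFrame:
    """Region x pattern counts of distinct (offset, strand) matches.

    ``regions`` restricts/orders rows; every requested region must have a
    sequence. Presence and >1-instance indicators derive from this matrix
    via :func:`motif_indicators`.
    """
    lexicon = list(lexicon) if lexicon is not None else default_lexicon()
    if regions is None:
        regions = list(sequences)
    missing = [r for r in regions if r not in sequences]
    if missing:
        raise ValueError(f"no sequence for region {missing[0]!r}")
    data = {
        p.name: [len(scan_sequence(sequences[r], p, both_strands)) for r in regions]
        for p in lexicon
    }
    return pd.DataFrame(data, index=pd.Index(regions, name="region"))


def motif_indicators(counts: pd.DataFrame):
    """(has_motif, multiple_instances) boolean frames from a count matrix."""
    return counts >= 1, counts >= 2


@dataclass
class EnrichmentResult:
    pattern: str
    observed_fraction: float
    null_mean: float
    null_sd: float
    z: float
    p: float
    q: float = np.nan
    call: str = "ns"
    note: str = ""


def enrichment(
    foreground: Sequence[str],
    background: Sequence[str],
    presence: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> EnrichmentResult:
    """Permutation z-score for one pattern's region-level presence.

    The statistic is the fraction of foreground regions containing at least
    one match. The null resamples foreground-sized sets (without
    replacement) from foreground union background. The empirical two-sided
    p-value uses +1 smoothing.
    """
    if n_perm < 1000:
        raise ValueError("n_perm must be >= 1000")
    rng = rng if rng is not None else np.random.default_rng(seed)
    fg = list(foreground)
    pool = fg + list(background)
    x = presence.loc[pool].to_numpy(dtype=float)
    n_fg = len(fg)
    obs = float(x[:n_fg].mean())
    # vectorized resampling: first n_fg entries of n_perm random permutations
    order = np.argsort(rng.random((n_perm, len(pool))), axis=1)[:, :n_fg]
    null = x[order].mean(axis=1)
    mu, sd = float(null.mean()), float(null.std(ddof=1))
    if sd == 0:
        return EnrichmentResult(
            pattern=str(presence.name), observed_fraction=obs, null_mean=mu, null_sd=0.0,
            z=np.nan, p=1.0, call="ns", note="degenerate null (sd = 0)",
        )
    z = (obs - mu) / sd
    p = (1.0 + float(np.sum(np.abs(null - mu) >= abs(obs - mu)))) / (n_perm + 1.0)
    return EnrichmentResult(
        pattern=str(presence.name), observed_fraction=obs, null_mean=mu, null_sd=sd, z=z, p=p
    )


def enrichment_table(
    foreground: Sequence[str],
    background: Sequence[str],
    presence_matrix: pd.DataFrame,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Enrichment/depletion calls across a lexicon with BH FDR control.

    ``presence_matrix`` is boolean, regions x patterns (from
    :func:`motif_indicators`). Calls: enriched iff z > 0 and q < alpha,
    depleted iff z < 0 and q < alpha, else ns.
    """
    rng = np.random.default_rng(seed)
    results = [
        enrichment(foreground, background, presence_matrix[col], n_perm=n_perm, rng=rng)
        for col in presence_matrix.columns
    ]
    df = pd.DataFrame(
        {
            "pattern": [r.pattern for r in results],
            "observed_fraction": [r.observed_fraction for r in results],
            "null_mean": [r.null_mean for r in results],
            "null_sd": [r.null_sd for r in results],
            "z": [r.z for r in results],
            "p": [r.p for r in results],
            "note": [r.note for r in results],
        }
    )
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    call = np.where(
        (df["q"] < alpha) & (df["z"] > 0), "enriched",
        np.where((df["q"] < alpha) & (df["z"] < 0), "depleted", "ns"),
    )
    call = np.where(df["note"] != "", "ns", call)
    df["call"] = call
    return df


def lexicon_to_tsv(lexicon: Iterable[MotifPattern], path) -> None:
    rows = []
    for p in lexicon:
        lo, hi = p.spacer_range if p.spacer_range else ("", "")
        rows.append((p.name, p.kind, ",".join(p.cores), lo, hi))
    pd.DataFrame(rows, columns=["name", "kind", "cores", "spacer_min", "spacer_max"]).to_csv(
        path, sep="\t", index=False
    )


def lexicon_from_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        cores = tuple(str(row["cores"]).split(","))
        spacer = None
        if not pd.isna(row["spacer_min"]) and str(row["spacer_min"]) != "":
            spacer = (int(row["spacer_min"]), int(row["spacer_max"]))
        if row["kind"] in ("spaced_repeat", "spaced_palindrome"):
            cores = cores[:1]
        out.append(compile_pattern(row["name"], row["kind"], cores, spacer))
    return out
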