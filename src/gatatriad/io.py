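"""File formats, domain containers, and configuration.

Coordinates are 0-based half-open (BED convention) throughout. Peak summits
are stored as absolute chromosome positions internally and serialized as
offsets relative to the peak start. ChIP peaks are unstranded; the BED strand
column is read but ignored.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("gatatriad")

#: canonical experiment labels for the GATA interplay triple
GATA2_MP = "GATA2_MP"
GATA2_E = "GATA2_E"
GATA1_E = "GATA1_E"
CORE_EXPERIMENTS = (GATA2_MP, GATA2_E, GATA1_E)

STAGE_ORDER = ("MP", "E1", "E3", "E5")


@dataclass(frozen=True)
class GenomeSpec:
    """A minimal genome description: chromosome names and lengths (bp)."""

    chrom_names: tuple
    chrom_lengths: tuple

    def __post_init__(self):
        if len(self.chrom_names) != len(set(self.chrom_names)):
            raise ValueError("chromosome names must be unique")
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("names and lengths must have equal length")
        for name, length in zip(self.chrom_names, self.chrom_lengths):
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def lengths(self) -> dict:
        return dict(zip(self.chrom_names, self.chrom_lengths))


@dataclass(frozen=True)
class PeakRecord:
    """One ChIP-seq peak with its summit and tag count.

    ``start``/``end`` are 0-based half-open; ``summit`` is an absolute
    position with ``start <= summit < end``.
    """

    chrom: str
    start: int
    end: int
    summit: int
    tag_count: int
    experiment_id: str = ""
    name: str = "."

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"peak {self.name}: start {self.start} must be < end {self.end}")
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"peak {self.name}: summit {self.summit} outside [{self.start}, {self.end})"
            )
        if self.tag_count < 0:
            raise ValueError(f"peak {self.name}: negative tag count {self.tag_count}")


class PeakSet:
    """An experiment's peaks, sorted by (chrom, start).

    Duplicate (chrom, summit) pairs within one set are rejected: a summit
    identifies a bound region within an experiment.
    """

    def __init__(self, experiment_id: str, records: Iterable[PeakRecord]):
        recs = sorted(records, key=lambda r: (r.chrom, r.start, r.summit))
        seen = set()
        for r in recs:
            key = (r.chrom, r.summit)
            if key in seen:
                raise ValueError(f"duplicate (chrom, summit) {key} in {experiment_id}")
            seen.add(key)
        self.experiment_id = experiment_id
        self.records = tuple(recs)
        self._summit_cache = None
        self._interval_cache = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PeakRecord]:
        return iter(self.records)

    def __getitem__(self, i) -> PeakRecord:
        return self.records[i]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PeakSet)
            and self.experiment_id == other.experiment_id
            and self.records == other.records
        )

    def summits_by_chrom(self) -> dict:
        """Sorted summit positions and record indices per chromosome."""
        if self._summit_cache is None:
            out = {}
            for idx, r in enumerate(self.records):
                out.setdefault(r.chrom, []).append((r.summit, idx))
            self._summit_cache = {
                c: (
                    np.array([s for s, _ in sorted(v)], dtype=np.int64),
                    np.array([i for _, i in sorted(v)], dtype=np.int64),
                )
                for c, v in out.items()
            }
        return self._summit_cache

    def intervals_by_chrom(self) -> dict:
        """Per chromosome: (starts, ends) sorted by start, plus running max end."""
        if self._interval_cache is None:
            out = {}
            for r in self.records:
                out.setdefault(r.chrom, []).append((r.start, r.end))
            cache = {}
            for c, ivs in out.items():
                ivs.sort()
                starts = np.array([s for s, _ in ivs], dtype=np.int64)
                ends = np.array([e for _, e in ivs], dtype=np.int64)
                cache[c] = (starts, ends, np.maximum.accumulate(ends))
            self._interval_cache = cache
        return self._interval_cache


def read_peaks(path, experiment_id: str) -> PeakSet:
    """Read a BED6+2 peak file: chrom, start, end, name, score, strand,
    summit_offset (relative to start), tag_count."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 8:
                raise ValueError(
                    f"{path}:{lineno}: expected 8 tab-separated fields, got {len(fields)}"
                )
            chrom, start_s, end_s, name, _score, _strand, off_s, tags_s = fields
            try:
                start, end = int(start_s), int(end_s)
                summit_offset = int(off_s)
                tag_count = int(tags_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer field ({exc})") from None
            if not (0 <= summit_offset < end - start):
                raise ValueError(
                    f"{path}:{lineno}: summit offset {summit_offset} outside "
                    f"[0, {end - start}) for peak {name}"
                )
            try:
                records.append(
                    PeakRecord(
                        chrom=chrom,
                        start=start,
                        end=end,
                        summit=start + summit_offset,
                        tag_count=tag_count,
                        experiment_id=experiment_id,
                        name=name,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return PeakSet(experiment_id, records)


def write_peaks(peakset: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for r in peakset.records:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t0\t.\t"
                f"{r.summit - r.start}\t{r.tag_count}\n"
            )


@dataclass
class ExpressionMatrix:
    """Normalized expression, genes x timepoints (hours), one lineage."""

    values: pd.DataFrame  # index: gene ids; columns: float hours
    lineage: str = "erythroid"

    def __post_init__(self):
        tp = np.asarray([float(c) for c in self.values.columns], dtype=float)
        if len(tp) >= 2 and not np.all(np.diff(tp) > 0):
            raise ValueError("timepoints must be strictly increasing")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if self.values.isna().any().any():
            gene = self.values.index[self.values.isna().any(axis=1)][0]
            raise ValueError(f"missing value for gene {gene!r}")
        self.values = self.values.astype(float)
        self.values.columns = tp

    @property
    def timepoints(self) -> np.ndarray:
        return np.asarray(self.values.columns, dtype=float)

    @property
    def gene_ids(self):
        return self.values.index

    def __eq__(self, other):
        return (
            isinstance(other, ExpressionMatrix)
            and self.lineage == other.lineage
            and self.values.equals(other.values)
        )


def read_expression(path, lineage: str = "erythroid") -> ExpressionMatrix:
    """Read a TSV with a header row of timepoints (hours) and gene ids in the
    first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad][0]
            raise ValueError(f"{path}: non-numeric cell for gene {gene!r}, column {col!r}")
    try:
        [float(c) for c in df.columns]
    except ValueError:
        raise ValueError(f"{path}: header must contain numeric timepoints in hours") from None
    return ExpressionMatrix(values=df.apply(pd.to_numeric), lineage=lineage)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    out = matrix.values.copy()
    out.columns = [format(c, "g") for c in out.columns]
    out.to_csv(path, sep="\t", index_label="gene_id")


TSS_COLUMNS = ("gene_id", "chrom", "tss_position", "strand")


def read_tss(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TSS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: TSS table missing columns {missing}")
    return df


def write_tss(df: pd.DataFrame, path) -> None:
    df.loc[:, list(TSS_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_fasta(path) -> dict:
    """Read FASTA into an {id: sequence} dict (uppercase)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(recs, str(path), "fasta")


@dataclass
class AnalysisConfig:
    """Pipeline-wide tunables. Windows in bp; one root seed feeds every stage."""

    summit_window_bp: int = 70
    notbound_window_bp: int = 1000
    fdr_alpha: float = 0.05
    kmeans_k: int = 30
    n_architect_param_sets: int = 200
    n_best_solutions: int = 60
    rng_seed: int = 0

    def __post_init__(self):
        if self.summit_window_bp <= 0 or self.notbound_window_bp <= 0:
            raise ValueError("windows must be positive")
        if not (0 < self.fdr_alpha < 1):
            raise ValueError("fdr_alpha must be in (0, 1)")

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage child seed derived from the root seed."""
        ss = np.random.SeedSequence(
            entropy=int(self.rng_seed), spawn_key=(hash_stage(stage),)
        )
        return int(ss.generate_state(1)[0] % (2**31))


def hash_stage(stage: str) -> int:
    # stable across processes (unlike built-in hash on str)
    h = 0
    for ch in stage:
        h = (h * 131 + ord(ch)) % (2**31)
    return h
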