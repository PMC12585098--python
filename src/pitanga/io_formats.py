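"""Readers and writers for the external formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere; GFF3 serialization is
1-based inclusive. FASTA goes through Bio.SeqIO, GFF3 parsing through
gffutils; the tabular formats (counts, sample sheet, edge lists, term maps)
are plain TSV handled with pandas.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("pitanga")

VALID_BASES = set("ACGTN")

POPULATIONS = ("RE", "RF")
CONDITIONS = ("control", "drought")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int | None:
        """Gap in bp between two intervals on the same sequence; 0 if they
        overlap or touch, None if on different sequences."""
        if self.seq_id != other.seq_id:
            return None
        return max(0, max(self.start, other.start) - min(self.end, other.end))


#: MISA-convention minimum repeat numbers by motif length 1..6.
DEFAULT_MIN_REPEATS = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}


@dataclass
class PipelineConfig:
    """Every numeric threshold the pipeline uses, with study defaults.

    Defaults are the study's stated parameters: association-score filter
    > 800, transcriptogram window radius 30 (61-gene interior windows),
    DEG thresholds |FC| >= 1.5 at p < 0.05, transcriptogram selection at
    R30 p < 0.01 and R0 p < 0.05, 100 bp same-sequence locus merging,
    2 kbp SSR-gene linking, chi-square confidence 0.01 with a 0.5% class
    representation floor, and MISA-style minimum repeat numbers.
    """

    window_radius: int = 30
    score_threshold: int = 800
    fc_threshold: float = 1.5
    p_deg: float = 0.05
    p_r30: float = 0.01
    p_r0: float = 0.05
    merge_window_bp: int = 100
    link_window_bp: int = 2000
    chi2_alpha: float = 0.01
    min_class_representation: float = 0.005
    ssr_min_repeats: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_REPEATS)
    )
    compound_max_interruption_bp: int = 100
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "window_radius", "score_threshold", "fc_threshold",
            "merge_window_bp", "link_window_bp",
            "compound_max_interruption_bp",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("p_deg", "p_r30", "p_r0", "chi2_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        self.ssr_min_repeats = {int(k): int(v) for k, v in self.ssr_min_repeats.items()}
        if sorted(self.ssr_min_repeats) != [1, 2, 3, 4, 5, 6]:
            raise ValueError("ssr_min_repeats must cover motif lengths 1..6")
        if any(v < 1 for v in self.ssr_min_repeats.values()):
            raise ValueError("minimum repeat numbers must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.snapshot(), fh, sort_keys=True)

    def snapshot(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# FASTA

_NON_ACGTN = re.compile(r"[^ACGTN]")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into an ordered list of (id, uppercase sequence).

    Lowercase is lifted to uppercase; characters outside {A,C,G,T,N} are
    mapped to N with a logged warning. Duplicate ids or an empty file are
    errors.
    """
    entries: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id: {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for FASTA id {rec.id!r}")
        n_bad = len(_NON_ACGTN.findall(seq))
        if n_bad:
            logger.warning(
                "%s: %d non-ACGTN characters mapped to N in %r", path, n_bad, rec.id
            )
            seq = _NON_ACGTN.sub("N", seq)
        entries.append((rec.id, seq))
    if not entries:
        raise FormatError(f"no FASTA records in {path}")
    return entries


def write_fasta(entries: Iterable[tuple[str, str]], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in entries
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# STRING-style edge list


def read_edges(path: str | Path) -> list[tuple[str, str, int]]:
    """Read a 3-column scored edge list (node node combined-score 0-1000).

    Self-loops are dropped with a warning; duplicate undirected pairs keep
    the maximum score. Output is sorted by node pair.
    """
    best: dict[tuple[str, str], int] = {}
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            a, b, raw = parts
            try:
                score = int(raw)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer score {raw!r}"
                ) from None
            if not 0 <= score <= 1000:
                raise FormatError(f"{path}:{lineno}: score {score} outside 0-1000")
            if a == b:
                n_self += 1
                continue
            key = (a, b) if a < b else (b, a)
            best[key] = max(best.get(key, -1), score)
    if n_self:
        logger.warning("%s: dropped %d self-loop edge(s)", path, n_self)
    return [(a, b, s) for (a, b), s in sorted(best.items())]


def write_edges(edges: Iterable[tuple[str, str, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b, s in edges:
            fh.write(f"{a}\t{b}\t{s}\n")


# ---------------------------------------------------------------------------
# Count matrix and sample sheet


def read_counts(
    path: str | Path, sample_sheet_path: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a gene x sample count TSV and its sample sheet.

    Returns (counts, sheet): counts is an integer DataFrame indexed by gene
    id; sheet is indexed by sample with columns population, condition,
    replicate. The sheet must cover exactly the matrix's samples.
    """
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if counts.index.has_duplicates:
        dup = counts.index[counts.index.duplicated()][0]
        raise FormatError(f"duplicate gene id {dup!r} in {path}")
    try:
        numeric = counts.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric count in {path}: {exc}") from None
    if (numeric < 0).any().any() or (numeric % 1 != 0).any().any():
        raise FormatError(f"counts in {path} must be non-negative integers")
    counts = numeric.astype(int)

    sheet = pd.read_csv(sample_sheet_path, sep="\t", index_col=0)
    required = {"population", "condition", "replicate"}
    missing_cols = required - set(sheet.columns)
    if missing_cols:
        raise FormatError(f"sample sheet missing columns: {sorted(missing_cols)}")
    unknown_pop = set(sheet["population"]) - set(POPULATIONS)
    if unknown_pop:
        raise FormatError(f"unknown population label(s): {sorted(unknown_pop)}")
    unknown_cond = set(sheet["condition"]) - set(CONDITIONS)
    if unknown_cond:
        raise FormatError(f"unknown condition label(s): {sorted(unknown_cond)}")
    absent = [s for s in counts.columns if s not in sheet.index]
    if absent:
        raise FormatError(f"sample(s) missing from sheet: {absent}")
    extra = [s for s in sheet.index if s not in counts.columns]
    if extra:
        raise FormatError(f"sheet sample(s) absent from matrix: {extra}")
    return counts, sheet.loc[list(counts.columns)]


def write_counts(counts: pd.DataFrame, sheet: pd.DataFrame,
                 counts_path: str | Path, sheet_path: str | Path) -> None:
    counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    sheet.to_csv(sheet_path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# GFF3


def write_gff3_ssr(loci, path: str | Path,
                   seq_lengths: dict[str, int] | None = None) -> None:
    """Write SSR loci as GFF3 ``microsatellite`` features.

    Attributes carry locus id, motif, canonical class, repeat count and the
    transcribed flag. Coordinates convert to 1-based inclusive.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for locus in loci:
            iv = locus.interval
            if seq_lengths is not None:
                length = seq_lengths.get(iv.seq_id)
                if length is None:
                    raise FormatError(f"unknown sequence {iv.seq_id!r}")
                if iv.end > length:
                    raise FormatError(
                        f"locus {locus.locus_id} extends past end of {iv.seq_id}"
                    )
            attrs = (
                f"ID={locus.locus_id};motif={locus.motif};"
                f"class={locus.motif_class};repeats={locus.n_repeats};"
                f"transcribed={'true' if locus.transcribed else 'false'}"
            )
            fh.write(
                f"{iv.seq_id}\tpitanga\tmicrosatellite\t{iv.start + 1}\t{iv.end}"
                f"\t.\t{iv.strand}\t.\t{attrs}\n"
            )


def write_gff3_genes(genes, path: str | Path) -> None:
    """Write gene models (id -> GenomicInterval) as GFF3 gene features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id, iv in genes.items():
            fh.write(
                f"{iv.seq_id}\tpitanga\tgene\t{iv.start + 1}\t{iv.end}"
                f"\t.\t{iv.strand}\t.\tID={gene_id}\n"
            )


def read_gff3(path: str | Path, feature_type: str | None = None):
    """Read GFF3 features as (feature_id, GenomicInterval, attributes).

    Parsing goes through gffutils; coordinates convert back to 0-based
    half-open, inverting the writers above.
    """
    import gffutils.iterators

    out = []
    for feat in gffutils.iterators.DataIterator(str(path)):
        if feature_type is not None and feat.featuretype != feature_type:
            continue
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end,
                             feat.strand if feat.strand in "+-" else ".")
        attrs = {k: v[0] for k, v in feat.attributes.items()}
        out.append((attrs.get("ID", f"{feat.seqid}:{feat.start}"), iv, attrs))
    return out


# ---------------------------------------------------------------------------
# Gene -> term map


def read_term_map(path: str | Path) -> dict[str, set[str]]:
    """Read a 2-column gene->term TSV into {gene: {terms}}."""
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            mapping.setdefault(parts[0], set()).add(parts[1])
    return mapping


# ---------------------------------------------------------------------------
# Report arithmetic


def percent_report(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to 2 decimals, as printed in reports."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def filter_accounting(initial: int, exclusions: list[int]) -> int:
    """Remaining count after successive exclusions from an initial total."""
    if any(e < 0 for e in exclusions):
        raise ValueError("exclusions must be non-negative")
    remaining = initial - sum(exclusions)
    if remaining < 0:
        raise ValueError(
            f"exclusions ({sum(exclusions)}) exceed initial total ({initial})"
        )
    return remaining
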