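"""Readers, writers and domain types for miRNA annotation and user tables.

Handles four input families:

* mature-sequence FASTA (miRBase header dialect: the first header token is
  the mature name, e.g. ``hsa-miR-320a-3p``);
* precursor-coordinate GFF3 (miRBase genome dialect: feature types
  ``miRNA_primary_transcript`` and ``miRNA``, attributes ``ID``/``Name``/
  ``Derives_from``);
* target-prediction tables (long two-column TSV or wide comma-separated);
* numeric score tables (TSV/CSV with a header row, one row per mature).

Coordinates are converted to a single internal convention — 0-based
half-open — immediately at the parse boundary and converted back only when
writing GFF3.  All readers transparently accept gzip-compressed input.
"""

from __future__ import annotations

import gzip
import io
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")
SEED_START = 1  # 0-based slice start for 1-based position 2
SEED_END = 7  # exclusive; covers 1-based positions 2-7


class AnnotationError(ValueError):
    """Raised on malformed or inconsistent annotation input."""


class ScoreTableError(ValueError):
    """Raised on malformed score-table input."""


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def normalize_mirna_id(mirna_id: str) -> str:
    """Case-folded lookup key for a mature miRNA name.

    User tables frequently differ from miRBase in the casing of the
    ``miR``/``mir``/``let`` tokens (``HSA-MIR-21-5P`` vs ``hsa-miR-21-5p``),
    so comparisons are done on the lowercase form.  Original casing is kept
    for output everywhere else.
    """
    return mirna_id.strip().lower()


def extract_seed(sequence: str) -> str:
    """Return the seed: the six nucleotides at positions 2-7 (1-based).

    Raises
    ------
    AnnotationError
        If the sequence is shorter than 7 nucleotides.
    """
    if len(sequence) < 7:
        raise AnnotationError(
            f"sequence of length {len(sequence)} is too short for seed extraction (need >= 7 nt)"
        )
    return sequence[SEED_START:SEED_END]


@dataclass
class MatureMiRNA:
    """A mature miRNA: the node unit of every network built here."""

    id: str
    species_code: str
    sequence: str
    seed: str
    precursor_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sequence) < 7:
            raise AnnotationError(f"{self.id}: sequence shorter than 7 nt")
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise AnnotationError(f"{self.id}: non-RNA characters {sorted(bad)}")
        if self.seed != extract_seed(self.sequence):
            raise AnnotationError(f"{self.id}: seed does not match sequence positions 2-7")

    @property
    def norm_id(self) -> str:
        return normalize_mirna_id(self.id)


@dataclass
class PrecursorLocus:
    """A precursor (hairpin) genomic interval.

    ``start``/``end`` are 0-based half-open; conversion from the GFF3
    1-based inclusive convention happens at parse time only.
    """

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    mature_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise AnnotationError(f"{self.id}: start > end ({self.start} > {self.end})")
        if self.strand not in {"+", "-"}:
            raise AnnotationError(f"{self.id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def _species_code(name: str) -> str:
    head = name.split("-", 1)[0]
    return head.lower()


def parse_mature_fasta(path: str | Path) -> list[MatureMiRNA]:
    """Parse a miRBase-style mature FASTA into :class:`MatureMiRNA` records.

    The first whitespace-separated token of each header is the mature name.
    ``T`` is auto-converted to ``U`` with a warning.  Duplicate ids and
    sequences shorter than 7 nt are hard errors.
    """
    with _open_text(path) as handle:
        text = handle.read()
    # Pre-scan headers so errors can name the offending line.
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(">") and not line[1:].strip():
            raise AnnotationError(f"{path}: malformed FASTA header at line {lineno} (no name token)")
    records: list[MatureMiRNA] = []
    seen: set[str] = set()
    converted: list[str] = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        name = rec.id
        seq = str(rec.seq).upper()
        if "T" in seq:
            seq = seq.replace("T", "U")
            converted.append(name)
        if len(seq) < 7:
            raise AnnotationError(f"{path}: sequence for {name} shorter than 7 nt")
        bad = set(seq) - RNA_ALPHABET
        if bad:
            raise AnnotationError(f"{path}: {name} contains non-RNA characters {sorted(bad)}")
        key = normalize_mirna_id(name)
        if key in seen:
            raise AnnotationError(f"{path}: duplicate mature id {name!r}")
        seen.add(key)
        records.append(
            MatureMiRNA(
                id=name,
                species_code=_species_code(name),
                sequence=seq,
                seed=extract_seed(seq),
            )
        )
    if converted:
        warnings.warn(
            f"{len(converted)} sequence(s) contained 'T'; converted to 'U' "
            f"(first: {converted[0]})",
            stacklevel=2,
        )
    if not records:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return records


def write_mature_fasta(matures: Sequence[MatureMiRNA], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as out:
        for m in matures:
            out.write(f">{m.id}\n{m.sequence}\n")


PRECURSOR_FEATURE = "miRNA_primary_transcript"
MATURE_FEATURE = "miRNA"


def parse_locus_gff3(path: str | Path) -> list[PrecursorLocus]:
    """Parse a miRBase genome-coordinate GFF3 into precursor loci.

    Each precursor carries the mature names whose ``miRNA`` features
    ``Derives_from`` it.  GFF3 1-based inclusive coordinates are converted
    to 0-based half-open here and nowhere else.
    """
    with _open_text(path) as handle:
        text = handle.read()
    if not any(line.strip() and not line.startswith("#") for line in text.splitlines()):
        warnings.warn(f"{path}: empty GFF3, no loci parsed", stacklevel=2)
        return []
    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    loci: list[PrecursorLocus] = []
    by_key: dict[str, PrecursorLocus] = {}
    for feat in db.features_of_type(PRECURSOR_FEATURE, order_by=("seqid", "start")):
        if feat.start > feat.end:
            raise AnnotationError(f"{path}: precursor {feat.id} has start > end")
        name = feat.attributes.get("Name", [feat.id])[0]
        locus = PrecursorLocus(
            id=name,
            chrom=feat.seqid,
            start=feat.start - 1,  # GFF3 1-based inclusive -> 0-based half-open
            end=feat.end,
            strand=feat.strand,
        )
        loci.append(locus)
        by_key[feat.id] = locus
        by_key.setdefault(name, locus)
    for feat in db.features_of_type(MATURE_FEATURE, order_by=("seqid", "start")):
        parents = feat.attributes.get("Derives_from", [])
        mature_name = feat.attributes.get("Name", [feat.id])[0]
        if not parents:
            raise AnnotationError(f"{path}: miRNA feature {mature_name} lacks Derives_from")
        for parent in parents:
            if parent not in by_key:
                raise AnnotationError(
                    f"{path}: miRNA feature {mature_name} Derives_from unknown precursor {parent!r}"
                )
            locus = by_key[parent]
            if mature_name not in locus.mature_ids:
                locus.mature_ids.append(mature_name)
    return loci


def write_locus_gff3(loci: Sequence[PrecursorLocus], path: str | Path) -> None:
    """Write loci back to miRBase-dialect GFF3 (1-based inclusive)."""
    with open(path, "wt", encoding="utf-8") as out:
        out.write("##gff-version 3\n")
        counter = 0
        for locus in loci:
            start1 = locus.start + 1
            out.write(
                f"{locus.chrom}\t.\t{PRECURSOR_FEATURE}\t{start1}\t{locus.end}\t.\t"
                f"{locus.strand}\t.\tID={locus.id};Name={locus.id}\n"
            )
            for mature_id in locus.mature_ids:
                counter += 1
                out.write(
                    f"{locus.chrom}\t.\t{MATURE_FEATURE}\t{start1}\t{locus.end}\t.\t"
                    f"{locus.strand}\t.\tID=MAT{counter:06d};Name={mature_id};"
                    f"Derives_from={locus.id}\n"
                )


def link_annotation(matures: Sequence[MatureMiRNA], loci: Sequence[PrecursorLocus]) -> None:
    """Cross-link matures and loci in place.

    Fills ``precursor_ids`` on each mature from the loci whose
    ``mature_ids`` reference it; raises if a locus references a mature
    name absent from the FASTA.
    """
    by_norm = {m.norm_id: m for m in matures}
    for locus in loci:
        for mature_id in locus.mature_ids:
            mature = by_norm.get(normalize_mirna_id(mature_id))
            if mature is None:
                raise AnnotationError(
                    f"locus {locus.id} references unknown mature {mature_id!r}"
                )
            if locus.id not in mature.precursor_ids:
                mature.precursor_ids.append(locus.id)


def load_annotation(
    fasta_path: str | Path, gff3_path: str | Path | None = None
) -> tuple[list[MatureMiRNA], list[PrecursorLocus]]:
    """Load and cross-link a mature FASTA and (optionally) a locus GFF3."""
    matures = parse_mature_fasta(fasta_path)
    loci = parse_locus_gff3(gff3_path) if gff3_path is not None else []
    if loci:
        link_annotation(matures, loci)
    return matures, loci


@dataclass
class TargetPredictionTable:
    """Predicted (or validated) mRNA targets per mature miRNA."""

    source_label: str
    targets: dict[str, set[str]]

    @property
    def empty_ids(self) -> list[str]:
        return sorted(k for k, v in self.targets.items() if not v)

    def universe(self) -> set[str]:
        out: set[str] = set()
        for genes in self.targets.values():
            out |= genes
        return out


def parse_target_table(path: str | Path, source_label: str | None = None) -> TargetPredictionTable:
    """Parse a target-prediction table.

    Two dialects are auto-detected: long format (one ``mature<TAB>gene``
    row per pair) and wide format (``mature<TAB>geneA,geneB,...``).  Target
    sets are deduplicated; empty sets are kept but flagged with a warning.
    """
    with _open_text(path) as handle:
        lines = [ln.rstrip("\n") for ln in handle if ln.strip()]
    if not lines:
        return TargetPredictionTable(source_label or str(path), {})
    body = lines[1:] if _looks_like_header(lines[0]) else lines
    targets: dict[str, set[str]] = {}
    wide = any("," in ln.split("\t", 1)[-1] for ln in body if "\t" in ln)
    for lineno, line in enumerate(body, start=2 if body is not lines else 1):
        parts = line.split("\t")
        if len(parts) < 1 or not parts[0].strip():
            raise AnnotationError(f"{path}: unparseable target row at line {lineno}: {line!r}")
        mature_id = parts[0].strip()
        bucket = targets.setdefault(mature_id, set())
        if len(parts) < 2 or not parts[1].strip():
            continue  # empty target list, retained
        if wide:
            bucket.update(g.strip() for g in parts[1].split(",") if g.strip())
        else:
            if len(parts) != 2:
                raise AnnotationError(
                    f"{path}: expected 2 columns in long format at line {lineno}: {line!r}"
                )
            bucket.add(parts[1].strip())
    table = TargetPredictionTable(source_label or str(path), targets)
    if table.empty_ids:
        warnings.warn(
            f"{path}: {len(table.empty_ids)} miRNA(s) with empty target sets "
            f"(first: {table.empty_ids[0]})",
            stacklevel=2,
        )
    logger.info(
        "parsed target table %s: %d miRNAs, %d genes",
        path,
        len(targets),
        len(table.universe()),
    )
    return table


def _looks_like_header(line: str) -> bool:
    first = line.split("\t")[0].strip().lower()
    return first in {"mirna", "mirna_id", "mature", "mature_id", "id", "name", "mir"}


def write_target_table(table: TargetPredictionTable, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as out:
        out.write("mirna_id\ttargets\n")
        for mature_id in sorted(table.targets):
            genes = ",".join(sorted(table.targets[mature_id]))
            out.write(f"{mature_id}\t{genes}\n")


@dataclass
class ScoreTable:
    """Per-miRNA numeric measurements.

    ``data`` is indexed by the verbatim mature id; missing values are NaN
    (always distinct from 0).  ``expression_mask`` optionally marks which
    miRNAs count as measured/expressed.  ``report`` carries parse and
    id-matching bookkeeping so no row is ever silently dropped.
    """

    data: pd.DataFrame
    expression_mask: pd.Series | None = None
    report: dict = field(default_factory=dict)

    @property
    def column_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def ids(self) -> list[str]:
        return list(self.data.index)

    def norm_key_map(self) -> dict[str, str]:
        return {normalize_mirna_id(i): i for i in self.data.index}

    def value(self, mirna_id: str, column: str) -> float:
        """Value for an id (matched case-insensitively); NaN if absent."""
        if column not in self.data.columns:
            raise ScoreTableError(f"unknown column {column!r}; available: {self.column_names}")
        original = self.norm_key_map().get(normalize_mirna_id(mirna_id))
        if original is None:
            return math.nan
        return float(self.data.at[original, column])

    def is_expressed(self, mirna_id: str) -> bool:
        if self.expression_mask is None:
            return True
        original = self.norm_key_map().get(normalize_mirna_id(mirna_id))
        if original is None:
            return False
        return bool(self.expression_mask.get(original, False))

    def set_expression_mask(self, column: str, threshold: float) -> None:
        """Derive the expressed mask from ``column > threshold``."""
        if column not in self.data.columns:
            raise ScoreTableError(f"unknown expression column {column!r}")
        self.expression_mask = self.data[column] > threshold


def parse_score_table(
    path: str | Path,
    id_column: str | None = None,
    sep: str | None = None,
    decimal: str = ".",
    annotation_ids: Iterable[str] | None = None,
) -> ScoreTable:
    """Parse a delimited score table into a :class:`ScoreTable`.

    The separator is sniffed from the extension unless given (``.csv`` →
    comma, otherwise tab).  Non-numeric cells become missing (NaN).
    Duplicate ids are an error.  When ``annotation_ids`` is supplied, the
    table ids are matched case-insensitively against it and the match
    counts recorded in ``report``; zero matches is an error (likely a
    species mismatch).
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.name.replace(".gz", "").endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, decimal=decimal, dtype=str)
    if df.empty and df.columns.empty:
        raise ScoreTableError(f"{path}: empty score table")
    if id_column is None:
        id_column = df.columns[0]
    if id_column not in df.columns:
        raise ScoreTableError(f"{path}: id column {id_column!r} not found; columns: {list(df.columns)}")
    ids = df[id_column].astype(str).str.strip()
    dupes = ids[ids.duplicated()].unique().tolist()
    if dupes:
        raise ScoreTableError(f"{path}: duplicated mature id row(s): {dupes}")
    value_cols = [c for c in df.columns if c != id_column]
    numeric = pd.DataFrame(index=pd.Index(ids, name=id_column))
    n_missing = 0
    for col in value_cols:
        coerced = pd.to_numeric(df[col].str.strip() if df[col].dtype == object else df[col], errors="coerce")
        n_missing += int(coerced.isna().sum() - df[col].isna().sum())
        numeric[col] = coerced.to_numpy()
    report: dict = {
        "rows_in": int(len(df)),
        "n_columns": len(value_cols),
        "n_coerced_to_missing": n_missing,
    }
    if annotation_ids is not None:
        known = {normalize_mirna_id(i) for i in annotation_ids}
        matched = [i for i in ids if normalize_mirna_id(i) in known]
        unmatched = [i for i in ids if normalize_mirna_id(i) not in known]
        report["rows_matched"] = len(matched)
        report["rows_unmatched"] = len(unmatched)
        report["unmatched_ids"] = unmatched[:50]
        if not matched:
            raise ScoreTableError(
                f"{path}: none of the {len(ids)} table ids match the annotation; "
                "check the species (id prefixes) and the id column"
            )
        if unmatched:
            logger.warning(
                "%s: %d/%d ids not in annotation (first: %s)",
                path,
                len(unmatched),
                len(ids),
                unmatched[0],
            )
    return ScoreTable(data=numeric, report=report)


def collapse_log2_mean(
    raw: ScoreTable,
    groups: Mapping[str, str],
    pseudocount: float = 1.0,
) -> ScoreTable:
    """Collapse replicate columns to one log2-scale column per condition.

    Each replicate column is transformed with ``log2(value + pseudocount)``
    and the per-condition mean taken across replicates.  Raw values must be
    non-negative.
    """
    missing_cols = [c for c in groups if c not in raw.data.columns]
    if missing_cols:
        raise ScoreTableError(f"grouping references unknown column(s): {missing_cols}")
    conditions: dict[str, list[str]] = {}
    for col, cond in groups.items():
        conditions.setdefault(cond, []).append(col)
    out = pd.DataFrame(index=raw.data.index)
    for cond, cols in conditions.items():
        block = raw.data[cols]
        if (block < 0).any().any():
            bad = block[(block < 0).any(axis=1)].index[0]
            raise ScoreTableError(f"negative raw value for {bad!r}; expected counts/intensities >= 0")
        out[cond] = np.log2(block + pseudocount).mean(axis=1)
    return ScoreTable(data=out, expression_mask=raw.expression_mask, report=dict(raw.report))
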