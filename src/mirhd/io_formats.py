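"""Readers and writers for the on-disk formats the pipeline touches.

Conventions
-----------
* Genomic coordinates are 1-based inclusive everywhere inside the package
  (the GFF3/SAM convention). BED, which is 0-based half-open, is converted
  at this boundary and nowhere else.
* FASTQ qualities are Phred+33; no other encoding is supported.
* Count matrices are TSV: first column the miRNA id, header row the sample
  ids, integer cells.
* Alignments are assumed ungapped and mismatch-free; SAM records with any
  non-match CIGAR operation are rejected with a warning.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """An input file violates its declared format."""


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_STRANDS = ("+", "-")

#: Numeric columns of the sample metadata table (all may contain missing values).
SAMPLE_NUMERIC_COLUMNS = (
    "grade", "age_death", "pmi", "rin", "cag",
    "onset_age", "duration", "hv_striatal", "hv_cortical",
)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, slots=True)
class ReadRecord:
    """One sequencing read: id, uppercase DNA and per-base Phred scores."""

    read_id: str
    sequence: str
    qualities: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, slots=True)
class AlignmentRecord:
    """An ungapped, mismatch-free alignment of one read to the genome.

    ``start``/``end`` are 1-based inclusive.  ``multiplicity`` carries the
    number of identical collapsed reads this record represents.
    """

    read_id: str
    chrom: str
    strand: str
    start: int
    end: int
    sequence: str | None = None
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise FormatError(f"unknown strand {self.strand!r} for read {self.read_id!r}")
        if self.start > self.end:
            raise FormatError(f"start > end for read {self.read_id!r}")

    @property
    def five_prime(self) -> int:
        """Genomic position of the read's 5' end (start on '+', end on '-')."""
        return self.start if self.strand == "+" else self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True, slots=True)
class MatureAnnotation:
    """Genomic record of one mature miRNA locus (1-based inclusive).

    The same ``mature_id`` may occur at multiple loci (multi-locus matures).
    """

    mature_id: str
    precursor_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.mature_id:
            raise FormatError("empty mature_id")
        if self.strand not in VALID_STRANDS:
            raise FormatError(f"unknown strand {self.strand!r} for {self.mature_id!r}")
        if self.start > self.end:
            raise FormatError(f"start > end for {self.mature_id!r}")

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream records from a 4-line-per-record Phred+33 FASTQ file.

    Sequences are uppercased.  Malformed records raise :class:`FormatError`
    naming the offending line number.
    """
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise FormatError(f"{path}:{lineno}: expected '@' header, got {header[:30]!r}")
            seq = fh.readline().rstrip("\n").upper()
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not plus.startswith("+"):
                raise FormatError(f"{path}:{lineno + 2}: expected '+' separator")
            if len(seq) != len(qual):
                raise FormatError(
                    f"{path}:{lineno + 3}: sequence and quality lengths differ "
                    f"({len(seq)} vs {len(qual)})"
                )
            quals = tuple(ord(c) - 33 for c in qual)
            if any(q < 0 or q > 93 for q in quals):
                raise FormatError(f"{path}:{lineno + 3}: Phred score outside [0, 93]")
            lineno += 3
            yield ReadRecord(header[1:], seq, quals)


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> int:
    """Write Phred+33 FASTQ; returns the number of records written."""
    n = 0
    with open(path, "w") as fh:
        for r in records:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# FASTA (genome, collapsed reads)
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{name: sequence}`` dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


_COLLAPSED_ID = re.compile(r"_x(\d+)$")


def multiplicity_from_read_id(read_id: str) -> int:
    """Parse a FASTX-collapser-style ``..._x<count>`` suffix; 1 if absent."""
    m = _COLLAPSED_ID.search(read_id)
    return int(m.group(1)) if m else 1


def write_collapsed_fasta(collapsed, path: str | Path) -> None:
    """Write collapsed reads as FASTA with ``c<i>_x<multiplicity>`` ids."""
    with open(path, "w") as fh:
        for i, rec in enumerate(collapsed, start=1):
            fh.write(f">c{i}_x{rec.multiplicity}\n{rec.sequence}\n")


def read_collapsed_fasta(path: str | Path) -> list[tuple[str, str, int]]:
    """Read a collapsed FASTA; returns ``(read_id, sequence, multiplicity)``."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.id, str(rec.seq).upper(), multiplicity_from_read_id(rec.id)))
    return out


# ---------------------------------------------------------------------------
# miRBase-style GFF3
# ---------------------------------------------------------------------------

def _parse_gff_attributes(field: str) -> dict[str, str]:
    attrs = {}
    for part in field.rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise FormatError(f"malformed GFF3 attribute {part!r}")
        key, value = part.split("=", 1)
        attrs[key.strip()] = value.strip()
    return attrs


def read_annotation_gff3(path: str | Path) -> list[MatureAnnotation]:
    """Parse mature miRNA records from a miRBase-dialect GFF3.

    Only feature type ``miRNA`` is returned; ``miRNA_primary_transcript``
    (precursor) lines are consulted solely through ``Derives_from``.
    Coordinates are kept 1-based inclusive exactly as printed.
    """
    matures: list[MatureAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated fields")
            chrom, _source, ftype, start, end, _score, strand, _frame, attr_field = fields
            if ftype != "miRNA":
                continue
            attrs = _parse_gff_attributes(attr_field)
            if "Name" not in attrs:
                raise FormatError(f"{path}:{lineno}: miRNA feature missing Name attribute")
            if strand not in VALID_STRANDS:
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            matures.append(
                MatureAnnotation(
                    mature_id=attrs["Name"],
                    precursor_id=attrs.get("Derives_from", ""),
                    chrom=chrom,
                    strand=strand,
                    start=int(start),
                    end=int(end),
                )
            )
    return matures


def write_annotation_gff3(
    matures: Iterable[MatureAnnotation],
    path: str | Path,
    precursors: Iterable[tuple[str, str, str, int, int]] = (),
) -> None:
    """Write miRBase-dialect GFF3.

    ``precursors`` is an optional iterable of
    ``(precursor_id, chrom, strand, start, end)`` for primary-transcript lines.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for pid, chrom, strand, start, end in precursors:
            fh.write(
                f"{chrom}\t.\tmiRNA_primary_transcript\t{start}\t{end}\t.\t{strand}\t.\t"
                f"ID={pid};Name={pid}\n"
            )
        for i, m in enumerate(matures, start=1):
            fh.write(
                f"{m.chrom}\t.\tmiRNA\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t"
                f"ID=MIMAT{i:07d};Name={m.mature_id};Derives_from={m.precursor_id}\n"
            )


# ---------------------------------------------------------------------------
# Alignments: SAM and BED6
# ---------------------------------------------------------------------------

def read_alignments(path: str | Path, dialect: str) -> Iterator[AlignmentRecord]:
    """Stream alignments from SAM or BED6, normalized to 1-based inclusive.

    Unmapped SAM records are skipped; gapped or clipped CIGARs are rejected
    with a warning because the pipeline assumes ungapped, mismatch-free
    alignments.  Reverse-strand reads have their as-sequenced orientation
    restored (SAM stores the reverse complement).
    """
    if dialect == "sam":
        yield from _read_sam(path)
    elif dialect == "bed":
        yield from _read_bed(path)
    else:
        raise ValueError(f"unknown alignment dialect {dialect!r}")


def _read_sam(path: str | Path) -> Iterator[AlignmentRecord]:
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            cigar = aln.cigartuples or []
            if any(op != 0 for op, _ in cigar):
                warnings.warn(
                    f"rejecting gapped/clipped alignment for read {aln.query_name!r} "
                    f"(CIGAR {aln.cigarstring})"
                )
                continue
            strand = "-" if aln.is_reverse else "+"
            seq = aln.query_sequence
            if seq is not None and strand == "-":
                seq = reverse_complement(seq)
            yield AlignmentRecord(
                read_id=aln.query_name,
                chrom=aln.reference_name,
                strand=strand,
                start=aln.reference_start + 1,
                end=aln.reference_end,
                sequence=seq,
                multiplicity=multiplicity_from_read_id(aln.query_name),
            )


def _read_bed(path: str | Path) -> Iterator[AlignmentRecord]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: BED6 requires 6 fields")
            chrom, start0, end0, name, _score, strand = fields[:6]
            if strand not in VALID_STRANDS:
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            yield AlignmentRecord(
                read_id=name,
                chrom=chrom,
                strand=strand,
                start=int(start0) + 1,  # half-open -> 1-based inclusive
                end=int(end0),
                multiplicity=multiplicity_from_read_id(name),
            )


def write_alignments_sam(
    records: Iterable[AlignmentRecord],
    path: str | Path,
    reference_lengths: dict[str, int],
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in reference_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.flag = 16 if r.strand == "-" else 0
            a.reference_id = out.header.get_tid(r.chrom)
            a.reference_start = r.start - 1
            a.mapping_quality = 255
            a.cigarstring = f"{r.length}M"
            if r.sequence is not None:
                a.query_sequence = (
                    reverse_complement(r.sequence) if r.strand == "-" else r.sequence
                )
                a.query_qualities = pysam.qualitystring_to_array("I" * r.length)
            out.write(a)


def write_alignments_bed(records: Iterable[AlignmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.read_id}\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------
# Tables: count matrix and sample metadata
# ---------------------------------------------------------------------------

def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Read a miRNA x sample TSV of non-negative integer counts."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "miRNA"
    if df.index.has_duplicates:
        raise FormatError("duplicate miRNA ids in count matrix")
    if df.columns.has_duplicates:
        raise FormatError("duplicate sample ids in count matrix")
    try:
        df = df.astype("int64")
    except ValueError as exc:
        raise FormatError(f"non-integer cell in count matrix: {exc}") from exc
    if (df.values < 0).any():
        raise FormatError("negative count in count matrix")
    return df


def write_count_matrix(counts: pd.DataFrame, path: str | Path) -> None:
    counts = counts.copy()
    counts.index.name = "miRNA"
    counts.to_csv(path, sep="\t")


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "miRNA"
    return df.astype(float)


def write_expression_matrix(expr: pd.DataFrame, path: str | Path) -> None:
    expr = expr.copy()
    expr.index.name = "miRNA"
    expr.to_csv(path, sep="\t", float_format="%.10g")


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Read the clinical/technical metadata table, indexed by sample id.

    Missing values (empty cells or ``NA``) become NaN in numeric columns.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.index.name = "sample_id"
    df = df.replace({"": pd.NA, "NA": pd.NA})
    for col in SAMPLE_NUMERIC_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col])
    validate_sample_table(df)
    return df


def write_sample_table(samples: pd.DataFrame, path: str | Path) -> None:
    out = samples.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g")


def validate_sample_table(samples: pd.DataFrame) -> None:
    """Enforce the cohort invariants.

    Controls carry no grade/CAG/onset/H-V data; symptomatic HD brains have
    grade 2-4 and a CAG length; grade-0 (asymptomatic gene-positive) brains
    have neither onset nor H-V scores.
    """
    if samples.index.has_duplicates:
        raise FormatError("duplicate sample ids in metadata")
    bad = set(samples["condition"]) - {"HD", "control"}
    if bad:
        raise FormatError(f"unknown condition values: {sorted(bad)}")
    ctrl = samples["condition"] == "control"
    for col in ("grade", "cag", "onset_age", "hv_striatal", "hv_cortical"):
        if col in samples.columns and samples.loc[ctrl, col].notna().any():
            raise FormatError(f"control sample carries a value in {col!r}")
    hd = samples[~ctrl]
    if "grade" in samples.columns:
        if hd["grade"].isna().any():
            raise FormatError("HD sample with missing grade")
        if not hd["grade"].isin([0, 2, 3, 4]).all():
            raise FormatError("HD grade outside {0, 2, 3, 4}")
        symptomatic = hd[hd["grade"] > 0]
        if "cag" in samples.columns and symptomatic["cag"].isna().any():
            raise FormatError("symptomatic HD sample with missing CAG")
        grade0 = hd[hd["grade"] == 0]
        for col in ("onset_age", "duration", "hv_striatal", "hv_cortical"):
            if col in samples.columns and grade0[col].notna().any():
                raise FormatError(f"grade-0 sample carries a value in {col!r}")
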