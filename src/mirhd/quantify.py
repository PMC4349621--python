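"""5'-anchored assignment of aligned reads to mature miRNAs.

The counting rule, applied to ungapped mismatch-free alignments of
collapsed reads:

1. reads longer than ``max_len`` (default 27 nt) are removed;
2. an alignment "hits" a mature miRNA when it lies on the same chromosome
   and strand, overlaps the mature interval by at least one base, and its
   5' start is within ``window`` nt (default +/-4, inclusive) of the
   annotated mature 5' start — this window tolerates 5' isomiRs;
3. the hit sets of all of a read's alignments are unioned: exactly one
   distinct mature id means the read is counted once for that mature
   (multi-locus mappings of a single mature collapse to one count); two or
   more distinct matures means the read is discarded; none means it is
   unassigned.

Counts are multiplicities of collapsed reads, so a collapsed read seen
``k`` times contributes ``k`` to its assigned mature.
"""

from __future__ import annotations

import warnings
from collections import OrderedDict, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import AlignmentRecord, MatureAnnotation

ASSIGNED = "assigned"
DISCARDED_LONG = "discarded_long"
DISCARDED_MULTI_MATURE = "discarded_multi_mature"
UNASSIGNED = "unassigned"

OUTCOME_CLASSES = (ASSIGNED, DISCARDED_LONG, DISCARDED_MULTI_MATURE, UNASSIGNED)


@dataclass(frozen=True, slots=True)
class AssignmentOutcome:
    read_id: str
    outcome: str
    mature_id: str | None = None
    multiplicity: int = 1


class AnnotationIndex:
    """Mature annotations grouped by (chromosome, strand) for hit lookup."""

    def __init__(self, matures: Iterable[MatureAnnotation]):
        self.matures = list(matures)
        self._by_key: dict[tuple[str, str], list[MatureAnnotation]] = defaultdict(list)
        for m in self.matures:
            self._by_key[(m.chrom, m.strand)].append(m)
        # deterministic row order: first appearance of each mature id
        self.mature_ids: list[str] = list(
            OrderedDict((m.mature_id, None) for m in self.matures)
        )

    def candidates(self, chrom: str, strand: str) -> list[MatureAnnotation]:
        return self._by_key.get((chrom, strand), [])


def mature_hits(
    alignment: AlignmentRecord,
    annotation: AnnotationIndex | Sequence[MatureAnnotation],
    window: int = 4,
) -> set[str]:
    """Mature ids hit by one alignment under the overlap + 5' window rule."""
    if not isinstance(annotation, AnnotationIndex):
        annotation = AnnotationIndex(annotation)
    hits = set()
    for m in annotation.candidates(alignment.chrom, alignment.strand):
        if alignment.start <= m.end and m.start <= alignment.end:
            if abs(alignment.five_prime - m.five_prime) <= window:
                hits.add(m.mature_id)
    return hits


def assign_read(
    alignments: Sequence[AlignmentRecord],
    annotation: AnnotationIndex | Sequence[MatureAnnotation],
    window: int = 4,
    max_len: int = 27,
    max_loci: int | None = None,
) -> AssignmentOutcome:
    """Resolve all alignments of one collapsed read into a single outcome.

    ``max_loci`` mirrors an aligner-side multimap cap: reads with more
    alignment loci than this are unassigned (default: unlimited).
    """
    if not alignments:
        return AssignmentOutcome("", UNASSIGNED)
    read_id = alignments[0].read_id
    mult = alignments[0].multiplicity
    length = (
        len(alignments[0].sequence) if alignments[0].sequence else alignments[0].length
    )
    if length > max_len:
        return AssignmentOutcome(read_id, DISCARDED_LONG, multiplicity=mult)
    if max_loci is not None and len(alignments) > max_loci:
        return AssignmentOutcome(read_id, UNASSIGNED, multiplicity=mult)
    if not isinstance(annotation, AnnotationIndex):
        annotation = AnnotationIndex(annotation)
    hits: set[str] = set()
    for aln in alignments:
        hits |= mature_hits(aln, annotation, window=window)
    if len(hits) == 1:
        return AssignmentOutcome(read_id, ASSIGNED, mature_id=hits.pop(), multiplicity=mult)
    if len(hits) >= 2:
        return AssignmentOutcome(read_id, DISCARDED_MULTI_MATURE, multiplicity=mult)
    return AssignmentOutcome(read_id, UNASSIGNED, multiplicity=mult)


def quantify_sample(
    alignments: Iterable[AlignmentRecord],
    annotation: AnnotationIndex | Sequence[MatureAnnotation],
    window: int = 4,
    max_len: int = 27,
    max_loci: int | None = None,
    multiplicities: Mapping[str, int] | None = None,
) -> tuple[pd.Series, list[AssignmentOutcome]]:
    """Count one sample's alignments against the annotation.

    Alignments are grouped by read id; duplicate (read id, locus) records
    are deduplicated with a warning.  Returns the per-mature count vector
    (annotation order) and the per-read outcome list; every read appears in
    exactly one outcome class.
    """
    if not isinstance(annotation, AnnotationIndex):
        annotation = AnnotationIndex(annotation)
    grouped: dict[str, dict[tuple, AlignmentRecord]] = defaultdict(dict)
    for aln in alignments:
        key = (aln.chrom, aln.strand, aln.start, aln.end)
        if key in grouped[aln.read_id]:
            warnings.warn(f"duplicate alignment record for read {aln.read_id!r} at {key}")
            continue
        grouped[aln.read_id][key] = aln
    counts = pd.Series(0, index=pd.Index(annotation.mature_ids, name="miRNA"), dtype=int)
    outcomes = []
    for read_id, records in grouped.items():
        outcome = assign_read(
            list(records.values()), annotation, window=window,
            max_len=max_len, max_loci=max_loci,
        )
        if multiplicities is not None:
            outcome = AssignmentOutcome(
                outcome.read_id, outcome.outcome, outcome.mature_id,
                multiplicities.get(read_id, 1),
            )
        outcomes.append(outcome)
        if outcome.outcome == ASSIGNED:
            counts[outcome.mature_id] += outcome.multiplicity
    return counts, outcomes


def outcome_summary(outcomes: Iterable[AssignmentOutcome]) -> pd.DataFrame:
    """Per-class read and multiplicity tallies, one row per outcome class."""
    reads = {c: 0 for c in OUTCOME_CLASSES}
    mass = {c: 0 for c in OUTCOME_CLASSES}
    for o in outcomes:
        reads[o.outcome] += 1
        mass[o.outcome] += o.multiplicity
    return pd.DataFrame(
        {"reads": pd.Series(reads), "multiplicity": pd.Series(mass)},
        index=pd.Index(OUTCOME_CLASSES, name="outcome"),
    )


def build_count_matrix(
    per_sample_counts: Mapping[str, pd.Series],
    annotation: AnnotationIndex | Sequence[MatureAnnotation] | None = None,
) -> pd.DataFrame:
    """Assemble per-sample count vectors into a miRNA x sample matrix.

    Row order follows the annotation (or the union of indices in first-seen
    order); column order follows the mapping order.  Missing entries are 0.
    """
    sample_ids = list(per_sample_counts)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample_id in per-sample counts")
    if annotation is not None:
        if not isinstance(annotation, AnnotationIndex):
            annotation = AnnotationIndex(annotation)
        index = pd.Index(annotation.mature_ids, name="miRNA")
    else:
        seen: OrderedDict[str, None] = OrderedDict()
        for counts in per_sample_counts.values():
            for mid in counts.index:
                seen.setdefault(mid, None)
        index = pd.Index(list(seen), name="miRNA")
    matrix = pd.DataFrame(0, index=index, columns=sample_ids, dtype=int)
    for sample_id, counts in per_sample_counts.items():
        matrix.loc[counts.index, sample_id] = counts.astype(int)
    return matrix
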