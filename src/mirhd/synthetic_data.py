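"""Seeded generators for every input the pipeline consumes.

Three layers, all driven by one :class:`SimulationConfig` and one seeded
NumPy generator:

* **annotation + genome** — a small synthetic genome into which mature
  miRNA sequences are planted, including multi-locus matures (one mature
  id at two genomic loci with identical sequence), overlapping locus pairs
  (two distinct matures whose intervals overlap, so one read can hit
  both), and both strands;
* **reads + alignments** — per-sample FASTQ reads built from the planted
  matures with 5' isomiR offsets, adapter read-through at a fixed 51 nt
  read length, planted quality failures, and decoy reads sampled from
  unannotated genome; alignments are produced by exhaustive string search
  of each insert against the genome (both strands), so every read is
  emitted at every locus sharing its sequence;
* **clinical cohort** — an HD-like cohort with negative-binomial counts
  carrying planted condition log2 fold changes and batch effects, plus
  clinical covariates in which onset, striatal and cortical scores depend
  on CAG repeat length and on a latent per-brain severity scale that is
  coupled to the planted differentially expressed miRNAs.  Vonsattel
  grade is derived by binning the striatal score, mirroring the tight
  empirical coupling between grade and striatal involvement.

A :class:`TruthTable` records everything the generator knows, so each
downstream stage can be checked against planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    AlignmentRecord,
    MatureAnnotation,
    ReadRecord,
    multiplicity_from_read_id,
    reverse_complement,
)
from .preprocess import DEFAULT_ADAPTER

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with cohort defaults shaped like
    the brain study being emulated (26 symptomatic HD, 2 asymptomatic
    grade-0 gene carriers, 36 controls; CAG ~ 44.6 +/- 2.9; onset
    ~ 44.5 y; striatal score 2.70 +/- 0.65; cortical 1.25 +/- 0.50)."""

    seed: int = 0
    # annotation / genome
    n_mirnas: int = 100
    n_multilocus: int = 4
    n_overlap_pairs: int = 2
    mature_len_range: tuple[int, int] = (20, 23)
    # cohort
    n_hd: int = 26
    n_grade0: int = 2
    n_control: int = 36
    n_reference: int = 346      # clinical-only cohort for CAG residual models
    n_batches: int = 2
    batch_shift: float = 0.35   # additive log2-scale location effect
    batch_scale: float = 1.4    # multiplicative dispersion effect
    # planted expression structure
    n_de: int = 15
    logfc_range: tuple[float, float] = (1.0, 3.0)   # |log2FC| of planted DE
    frac_de_up: float = 0.6
    grade0_effect: float = 0.3      # fraction of the DE effect in grade-0 brains
    expr_severity_coupling: float = 0.35
    dispersion: tuple[float, float] = (0.05, 2.0)   # (alpha0, alpha1)
    lib_size_range: tuple[float, float] = (0.7, 1.4)
    base_log2_mean_range: tuple[float, float] = (2.0, 8.0)
    # read-level
    isomir_sd: float = 1.2
    frac_offset_gt4: float = 0.02
    max_abs_offset: int = 6
    frac_decoy: float = 0.05
    frac_quality_fail: float = 0.03
    adapter: str = DEFAULT_ADAPTER
    adapter_error_rate: float = 0.0
    read_length: int = 51
    # clinical models
    cag_range: tuple[int, int] = (40, 52)
    cag_mean: float = 44.6
    cag_sd: float = 2.9
    onset_model: tuple[float, float, float] = (6.47, -0.06, 0.18)  # a, b, sigma of ln(onset)
    onset_severity_coupling: float = 0.5
    striatal_cag_slope: float = 0.20
    striatal_severity_slope: float = 0.45
    cortical_striatal_slope: float = 0.35
    cortical_noise: float = 0.30
    grade_thresholds: tuple[float, float] = (2.0, 3.2)  # striatal cutpoints for 2/3/4

    def __post_init__(self) -> None:
        for name in ("n_mirnas", "n_multilocus", "n_overlap_pairs", "n_hd",
                     "n_grade0", "n_control", "n_batches", "n_de"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.frac_offset_gt4 <= 1.0):
            raise ValueError("frac_offset_gt4 must be in [0, 1]")
        if self.logfc_range[0] <= 0:
            raise ValueError("logfc_range must exclude 0 (magnitudes of planted DE)")
        if self.n_de > self.n_mirnas:
            raise ValueError("n_de cannot exceed n_mirnas")
        if 2 * self.n_overlap_pairs + self.n_multilocus > self.n_mirnas:
            raise ValueError("not enough miRNAs for requested overlap/multi-locus structure")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        kwargs = {}
        for key, value in d.items():
            if isinstance(value, list):
                value = tuple(value)
            kwargs[key] = value
        return cls(**kwargs)


@dataclass
class TruthTable:
    """Planted truth: per-miRNA effects, per-sample covariates, per-read fate."""

    per_mirna: pd.DataFrame
    per_sample: pd.DataFrame
    per_read: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# Annotation + genome
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def simulate_annotation(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], list[MatureAnnotation]]:
    """Build a synthetic genome and its mature miRNA annotation.

    Returns ``(genome, matures)``.  The first ``2 * n_overlap_pairs``
    matures form overlapping locus pairs; the next ``n_multilocus``
    matures are planted at two loci each (identical sequence, second
    locus possibly on the other strand).  Placement is verified by
    exhaustive string search: every mature's sequence must occur at
    exactly its number of loci, otherwise an error is raised.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_mirnas
    lengths = rng.integers(config.mature_len_range[0],
                           config.mature_len_range[1] + 1, size=n)
    arms = ["5p" if i % 2 == 0 else "3p" for i in range(n)]
    mature_ids = [f"hsa-miR-{1000 + i}-{arms[i]}" for i in range(n)]
    precursor_ids = [f"hsa-mir-{1000 + i}" for i in range(n)]

    multilocus = set(range(2 * config.n_overlap_pairs,
                           2 * config.n_overlap_pairs + config.n_multilocus))

    # placement units: (kind, payload)
    units: list[tuple[str, tuple]] = []
    for i in range(config.n_overlap_pairs):
        units.append(("pair", (2 * i, 2 * i + 1)))
    for i in range(2 * config.n_overlap_pairs, n):
        units.append(("single", (i,)))
    for i in sorted(multilocus):
        units.append(("copy", (i,)))

    # lay units out on two chromosomes with random gaps
    placements: list[tuple[int, str, str, int, int, str]] = []  # (mature_idx, precursor, chrom, start, end, kind)
    cursors = {"chr1": 0, "chr2": 0}
    chroms = list(cursors)
    for u, (kind, payload) in enumerate(units):
        chrom = chroms[u % 2]
        pos = cursors[chrom] + int(rng.integers(30, 61))
        strand = "+" if rng.random() < 0.5 else "-"
        if kind == "pair":
            a, b = payload
            d = int(rng.integers(2, 5))
            start_a = pos + 1
            placements.append((a, precursor_ids[a], chrom, start_a,
                               start_a + int(lengths[a]) - 1, strand))
            start_b = start_a + d
            placements.append((b, precursor_ids[b], chrom, start_b,
                               start_b + int(lengths[b]) - 1, strand))
            pos = max(start_a + int(lengths[a]), start_b + int(lengths[b])) - 1
        elif kind == "single":
            (i,) = payload
            start = pos + 1
            placements.append((i, precursor_ids[i], chrom, start,
                               start + int(lengths[i]) - 1, strand))
            pos = start + int(lengths[i]) - 1
        else:  # second locus of a multi-locus mature
            (i,) = payload
            start = pos + 1
            placements.append((i, precursor_ids[i] + "-2", chrom, start,
                               start + int(lengths[i]) - 1, strand))
            pos = start + int(lengths[i]) - 1
        cursors[chrom] = pos

    # leave a generous unannotated tail on each chromosome (decoy reads are
    # sampled away from any mature locus)
    genome_arrays = {
        c: rng.choice(_BASES, size=cursors[c] + 500) for c in chroms
    }

    # plant primary sequences, then copy multi-locus segments
    primary_locus: dict[int, tuple[str, int, int, str]] = {}
    for idx, _pid, chrom, start, end, strand in placements:
        if idx in primary_locus:
            continue
        primary_locus[idx] = (chrom, start, end, strand)
    # overlap-pair members share genome bases, so plant pair "a" first and
    # derive "b" from the final genome; order of placements already does this
    planted = set()
    for idx, _pid, chrom, start, end, strand in placements:
        if idx in planted or (chrom, start, end, strand) != primary_locus[idx]:
            continue
        is_pair_b = idx % 2 == 1 and idx < 2 * config.n_overlap_pairs
        if not is_pair_b:
            seq = _random_seq(rng, end - start + 1)
            segment = seq if strand == "+" else reverse_complement(seq)
            genome_arrays[chrom][start - 1 : end] = list(segment)
        planted.add(idx)
    genome = {c: "".join(a) for c, a in genome_arrays.items()}
    # copy second loci of multi-locus matures from the (now final) primaries
    for idx, _pid, chrom, start, end, strand in placements:
        if (chrom, start, end, strand) == primary_locus[idx]:
            continue
        p_chrom, p_start, p_end, p_strand = primary_locus[idx]
        segment = genome[p_chrom][p_start - 1 : p_end]
        if strand != p_strand:
            segment = reverse_complement(segment)
        arr = genome_arrays[chrom]
        arr[start - 1 : end] = list(segment)
    genome = {c: "".join(a) for c, a in genome_arrays.items()}

    matures = [
        MatureAnnotation(mature_ids[idx], pid, chrom, strand, start, end)
        for idx, pid, chrom, start, end, strand in placements
    ]

    # verify feasibility: each mature's transcript occurs at exactly its loci
    expected: dict[str, int] = {}
    for m in matures:
        expected[m.mature_id] = expected.get(m.mature_id, 0) + 1
    for idx in range(n):
        chrom, start, end, strand = primary_locus[idx]
        seq = genome[chrom][start - 1 : end]
        if strand == "-":
            seq = reverse_complement(seq)
        found = sum(
            len(_find_all(genome[c], seq)) + len(_find_all(genome[c], reverse_complement(seq)))
            for c in genome
        )
        if found != expected[mature_ids[idx]]:
            raise RuntimeError(
                f"infeasible placement: {mature_ids[idx]} occurs {found}x, "
                f"expected {expected[mature_ids[idx]]}"
            )
    return genome, matures


def _find_all(haystack: str, needle: str) -> list[int]:
    """All 0-based occurrence positions of ``needle`` in ``haystack``."""
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def mature_sequence(genome: dict[str, str], m: MatureAnnotation) -> str:
    """Transcript (5'->3') sequence of a mature locus."""
    seq = genome[m.chrom][m.start - 1 : m.end]
    return seq if m.strand == "+" else reverse_complement(seq)


# ---------------------------------------------------------------------------
# Clinical cohort + counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Negative-binomial draws with mean mu and variance mu + alpha*mu^2."""
    size = 1.0 / np.clip(alpha, 1e-12, None)
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def nb_variance(mu: np.ndarray, trend: tuple[float, float]) -> np.ndarray:
    a0, a1 = trend
    mu = np.asarray(mu, float)
    return mu + (a0 + a1 / mu) * mu**2


def simulate_cohort(
    config: SimulationConfig,
    mature_ids: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthTable]:
    """Simulate the sample table and the count matrix with planted truth.

    Returns ``(samples, counts, truth)``.  ``truth.per_sample`` includes a
    ``severity`` column (the latent per-brain scale coupled to the planted
    miRNAs) and the per-sample library size used; ``truth.per_mirna``
    records base means, planted log2 fold changes and the DE flags.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if mature_ids is None:
        arms = ["5p" if i % 2 == 0 else "3p" for i in range(config.n_mirnas)]
        mature_ids = [f"hsa-miR-{1000 + i}-{arms[i]}" for i in range(config.n_mirnas)]
    mature_ids = list(mature_ids)
    g = len(mature_ids)

    sample_rows = []
    a_on, b_on, sig_on = config.onset_model
    w = config.onset_severity_coupling

    def hd_clinical(sid: str, grade0: bool) -> dict:
        cag = int(np.clip(round(rng.normal(config.cag_mean, config.cag_sd)),
                          config.cag_range[0], config.cag_range[1]))
        z = float(rng.normal())
        if grade0:
            return {
                "sample_id": sid, "condition": "HD", "grade": 0, "cag": 42,
                "age_death": float(np.clip(rng.normal(67.5, 10.0), 35, 95)),
                "pmi": float(np.clip(rng.normal(28.0, 7.9), 2, 50)),
                "rin": float(np.clip(rng.normal(7.7, 0.6), 5, 10)),
                "onset_age": np.nan, "duration": np.nan,
                "hv_striatal": np.nan, "hv_cortical": np.nan,
                "severity": z,
            }
        striatal = float(np.clip(
            2.70 + config.striatal_cag_slope * (cag - config.cag_mean)
            + config.striatal_severity_slope * z, 0.2, 4.0))
        cortical = float(np.clip(
            1.25 + config.cortical_striatal_slope * (striatal - 2.70)
            + config.cortical_noise * rng.normal(), 0.1, 4.0))
        t1, t2 = config.grade_thresholds
        grade = 2 if striatal <= t1 else (3 if striatal <= t2 else 4)
        eps = sig_on * (-w * z + np.sqrt(1.0 - w**2) * rng.normal())
        onset = float(np.exp(a_on + b_on * cag + eps))
        duration = float(np.clip(rng.normal(15.0, 6.1), 3.0, 35.0))
        return {
            "sample_id": sid, "condition": "HD", "grade": grade, "cag": cag,
            "age_death": onset + duration,
            "pmi": float(np.clip(rng.normal(15.7, 7.7), 2, 50)),
            "rin": float(np.clip(rng.normal(7.3, 0.9), 5, 10)),
            "onset_age": onset, "duration": duration,
            "hv_striatal": striatal, "hv_cortical": cortical,
            "severity": z,
        }

    for i in range(config.n_hd):
        sample_rows.append(hd_clinical(f"HD{i + 1:03d}", grade0=False))
    for i in range(config.n_grade0):
        sample_rows.append(hd_clinical(f"G0{i + 1:02d}", grade0=True))
    for i in range(config.n_control):
        sample_rows.append({
            "sample_id": f"C{i + 1:03d}", "condition": "control", "grade": np.nan,
            "cag": np.nan,
            "age_death": float(np.clip(rng.normal(68.6, 14.3), 35, 100)),
            "pmi": float(np.clip(rng.normal(14.4, 8.8), 2, 50)),
            "rin": float(np.clip(rng.normal(7.7, 0.7), 5, 10)),
            "onset_age": np.nan, "duration": np.nan,
            "hv_striatal": np.nan, "hv_cortical": np.nan,
            "severity": float(rng.normal()),
        })
    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    n = len(samples)

    # batch assignment: shuffled round-robin so batches mix conditions
    order = rng.permutation(n)
    batch_labels = np.empty(n, dtype=object)
    for rank, j in enumerate(order):
        batch_labels[j] = f"b{rank % max(config.n_batches, 1) + 1}"
    samples["batch"] = batch_labels

    # planted expression structure
    base = rng.uniform(*config.base_log2_mean_range, size=g)
    de_idx = rng.choice(g, size=config.n_de, replace=False)
    lfc = np.zeros(g)
    signs = np.where(rng.random(config.n_de) < config.frac_de_up, 1.0, -1.0)
    lfc[de_idx] = signs * rng.uniform(*config.logfc_range, size=config.n_de)
    is_de = np.zeros(g, dtype=bool)
    is_de[de_idx] = True
    lib = np.exp(rng.uniform(np.log(config.lib_size_range[0]),
                             np.log(config.lib_size_range[1]), size=n))

    is_hd = (samples["condition"] == "HD").to_numpy()
    grade0 = is_hd & (samples["grade"].to_numpy() == 0)
    symptomatic = is_hd & ~grade0
    z = samples["severity"].to_numpy()
    not_b1 = (samples["batch"] != "b1").to_numpy()

    cond_frac = np.where(symptomatic, 1.0, np.where(grade0, config.grade0_effect, 0.0))
    log2mu = (
        base[:, None]
        + lfc[:, None] * cond_frac[None, :]
        + config.expr_severity_coupling * np.sign(lfc)[:, None]
        * np.where(symptomatic, z, 0.0)[None, :] * is_de[:, None]
        + config.batch_shift * not_b1[None, :]
        + np.log2(lib)[None, :]
    )
    mu = 2.0**log2mu
    a0, a1 = config.dispersion
    alpha = (a0 + a1 / mu) * np.where(not_b1, config.batch_scale, 1.0)[None, :]
    counts = pd.DataFrame(
        _nb_draw(rng, mu, alpha),
        index=pd.Index(mature_ids, name="miRNA"),
        columns=samples.index,
    )

    per_mirna = pd.DataFrame(
        {"base_log2_mean": base, "log2fc": lfc, "is_de": is_de},
        index=pd.Index(mature_ids, name="miRNA"),
    )
    per_sample = samples.copy()
    per_sample["lib_size"] = lib
    samples_out = samples.drop(columns=["severity"])
    truth = TruthTable(per_mirna=per_mirna, per_sample=per_sample)
    return samples_out, counts, truth


def simulate_reference_cohort(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Clinical-only reference cohort for fitting CAG residual models.

    Larger and wider than the sequenced cohort (CAG can exceed the 55-repeat
    analysis cutoff, exercising the exclusion rule); no expression data.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_reference
    a_on, b_on, sig_on = config.onset_model
    rows = []
    for i in range(n):
        cag = int(np.clip(round(rng.normal(config.cag_mean + 1.0, 4.5)), 38, 70))
        z = float(rng.normal())
        striatal = float(np.clip(
            2.70 + config.striatal_cag_slope * (cag - config.cag_mean)
            + config.striatal_severity_slope * z, 0.2, 4.0))
        cortical = float(np.clip(
            1.25 + config.cortical_striatal_slope * (striatal - 2.70)
            + config.cortical_noise * rng.normal(), 0.1, 4.0))
        w = config.onset_severity_coupling
        eps = sig_on * (-w * z + np.sqrt(1.0 - w**2) * rng.normal())
        onset = float(np.exp(a_on + b_on * cag + eps))
        duration = float(np.clip(rng.normal(15.0, 6.1), 3.0, 35.0))
        rows.append({
            "sample_id": f"REF{i + 1:04d}", "condition": "HD",
            "grade": 2, "cag": cag, "onset_age": onset, "duration": duration,
            "age_death": onset + duration,
            "hv_striatal": striatal, "hv_cortical": cortical,
            "pmi": np.nan, "rin": np.nan,
        })
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# Reads and alignments
# ---------------------------------------------------------------------------

class ReadSimulator:
    """Per-sample read generation against a fixed genome + annotation.

    Precomputes, for every (mature, 5' offset) combination, the insert
    sequence, the number of genomic loci carrying it, and the set of
    matures such a read hits under the +/-``window`` rule — the planted
    truth that the quantifier is later checked against.
    """

    def __init__(
        self,
        config: SimulationConfig,
        genome: dict[str, str],
        annotation: Sequence[MatureAnnotation],
        window: int = 4,
    ):
        self.config = config
        self.genome = genome
        self.annotation = list(annotation)
        self.window = window
        self._loci: dict[str, list[MatureAnnotation]] = {}
        for m in self.annotation:
            self._loci.setdefault(m.mature_id, []).append(m)
        self.mature_ids = list(self._loci)
        self._variants: dict[tuple[str, int], tuple[str, int, frozenset]] = {}
        for mid, loci in self._loci.items():
            seq = mature_sequence(genome, loci[0])
            for o in range(-config.max_abs_offset, config.max_abs_offset + 1):
                insert, read_loci = self._insert_for_offset(loci, seq, o)
                if insert is None:
                    continue
                hits = frozenset(
                    h for locus in read_loci for h in self._interval_hits(locus)
                )
                self._variants[(mid, o)] = (insert, len(read_loci), hits)
        self._free_regions = self._unannotated_regions(margin=window + 40)

    def _insert_for_offset(
        self, loci: list[MatureAnnotation], seq: str, o: int
    ) -> tuple[str | None, list[tuple[str, str, int, int]]]:
        """Insert sequence for 5' offset ``o`` plus its genomic intervals.

        ``o > 0`` starts inside the mature (the insert is a suffix present
        at every locus of the mature); ``o < 0`` extends 5' into flanking
        genome, which is locus-specific, so only the first locus carries it.
        """
        if o >= 0:
            if o >= len(seq):
                return None, []
            insert = seq[o:]
            intervals = []
            for m in loci:
                if m.strand == "+":
                    intervals.append((m.chrom, m.strand, m.start + o, m.end))
                else:
                    intervals.append((m.chrom, m.strand, m.start, m.end - o))
            return insert, intervals
        m = loci[0]
        ext = -o
        if m.strand == "+":
            start, end = m.start - ext, m.end
            if start < 1:
                return None, []
            flank = self.genome[m.chrom][start - 1 : m.start - 1]
            insert = flank + seq
        else:
            start, end = m.start, m.end + ext
            if end > len(self.genome[m.chrom]):
                return None, []
            flank = reverse_complement(self.genome[m.chrom][m.end : end])
            insert = flank + seq
        intervals = [(m.chrom, m.strand, start, end)]
        # the extended insert may coincidentally sit at another locus of a
        # multi-locus mature only if the flank matches there; check directly
        for other in loci[1:]:
            if other.strand == "+":
                s2, e2 = other.start - ext, other.end
                if s2 >= 1 and self.genome[other.chrom][s2 - 1 : e2] == insert:
                    intervals.append((other.chrom, "+", s2, e2))
            else:
                s2, e2 = other.start, other.end + ext
                seg = self.genome[other.chrom][s2 - 1 : e2]
                if e2 <= len(self.genome[other.chrom]) and reverse_complement(seg) == insert:
                    intervals.append((other.chrom, "-", s2, e2))
        return insert, intervals

    def _interval_hits(self, interval: tuple[str, str, int, int]) -> set[str]:
        """Matures hit by a read at this interval (overlap + 5' window)."""
        chrom, strand, start, end = interval
        five = start if strand == "+" else end
        hits = set()
        for m in self.annotation:
            if m.chrom != chrom or m.strand != strand:
                continue
            if start <= m.end and m.start <= end and abs(five - m.five_prime) <= self.window:
                hits.add(m.mature_id)
        return hits

    def _unannotated_regions(self, margin: int) -> list[tuple[str, int, int]]:
        regions = []
        for chrom, seq in self.genome.items():
            occupied = sorted(
                (m.start - margin, m.end + margin)
                for m in self.annotation if m.chrom == chrom
            )
            pos = 1
            for s, e in occupied:
                if s - pos >= 30:
                    regions.append((chrom, pos, s - 1))
                pos = max(pos, e + 1)
            if len(seq) - pos >= 30:
                regions.append((chrom, pos, len(seq)))
        if not regions:
            raise RuntimeError("no unannotated genome available for decoy reads")
        return regions

    def _draw_offset(self, rng: np.random.Generator) -> int:
        cfg = self.config
        if rng.random() < cfg.frac_offset_gt4:
            mag = int(rng.integers(self.window + 1, cfg.max_abs_offset + 1))
            return mag if rng.random() < 0.5 else -mag
        if cfg.isomir_sd == 0:
            return 0
        o = int(np.clip(round(rng.normal(0.0, cfg.isomir_sd)), -self.window, self.window))
        return o

    def sample_reads(
        self,
        sample_id: str,
        mirna_counts: pd.Series,
        rng: np.random.Generator,
    ) -> tuple[list[ReadRecord], pd.DataFrame]:
        """Generate one sample's FASTQ reads plus their per-read truth rows."""
        cfg = self.config
        rows = []
        reads: list[ReadRecord] = []
        serial = 0

        def emit(insert: str, source: str, offset: int, n_loci: int,
                 hits: frozenset) -> None:
            nonlocal serial
            serial += 1
            read_id = f"{sample_id}:r{serial:06d}"
            fails_quality = rng.random() < cfg.frac_quality_fail
            adapter = list(cfg.adapter)
            n_adapter_errors = 0
            if cfg.adapter_error_rate > 0:
                for k in range(len(adapter)):
                    if rng.random() < cfg.adapter_error_rate:
                        choices = [b for b in "ACGT" if b != adapter[k]]
                        adapter[k] = choices[int(rng.integers(3))]
                        n_adapter_errors += 1
            seq = insert + "".join(adapter)
            if len(seq) < cfg.read_length:
                seq += _random_seq(rng, cfg.read_length - len(seq))
            seq = seq[: cfg.read_length]
            L = len(seq)
            if fails_quality:
                quals = rng.integers(30, 41, size=L)
                n_bad = int(np.ceil((1 - 0.8) * L)) + 2
                bad_pos = rng.choice(L, size=min(n_bad, L), replace=False)
                quals[bad_pos] = rng.integers(2, 20, size=len(bad_pos))
            else:
                quals = rng.integers(30, 41, size=L)
            reads.append(ReadRecord(read_id, seq, tuple(int(q) for q in quals)))
            insert_len = len(insert)
            single = len(hits) == 1
            counted = (
                not fails_quality
                and n_adapter_errors == 0
                and 15 <= insert_len <= 27
                and single
            )
            rows.append({
                "read_id": read_id, "sample_id": sample_id, "source": source,
                "offset": offset, "n_loci": n_loci, "insert": insert,
                "insert_len": insert_len, "passes_quality": not fails_quality,
                "adapter_errors": n_adapter_errors,
                "n_matures_hit": len(hits),
                "assigned_mature": next(iter(hits)) if single else "",
                "counted": counted,
            })

        for mid in self.mature_ids:
            c = int(mirna_counts.get(mid, 0))
            for _ in range(c):
                o = self._draw_offset(rng)
                variant = self._variants.get((mid, o))
                if variant is None:
                    continue
                insert, n_loci, hits = variant
                emit(insert, mid, o, n_loci, hits)

        n_decoys = int(round(cfg.frac_decoy * serial))
        for _ in range(n_decoys):
            chrom, lo, hi = self._free_regions[int(rng.integers(len(self._free_regions)))]
            length = int(rng.integers(*cfg.mature_len_range))
            if hi - lo + 1 <= length:
                continue
            start = int(rng.integers(lo, hi - length + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            seg = self.genome[chrom][start - 1 : start - 1 + length]
            insert = seg if strand == "+" else reverse_complement(seg)
            emit(insert, "decoy", 0, 1, frozenset())

        perm = rng.permutation(len(reads))
        reads = [reads[i] for i in perm]
        rows = [rows[i] for i in perm]
        truth = pd.DataFrame(rows) if rows else pd.DataFrame(
            columns=["read_id", "sample_id", "source", "offset", "n_loci", "insert",
                     "insert_len", "passes_quality", "adapter_errors",
                     "n_matures_hit", "assigned_mature", "counted"])
        return reads, truth


def simulate_reads(
    config: SimulationConfig,
    genome: dict[str, str],
    annotation: Sequence[MatureAnnotation],
    counts: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, list[ReadRecord]], pd.DataFrame]:
    """Generate reads for every sample of a count matrix at once.

    Convenience wrapper around :class:`ReadSimulator` for moderate scales;
    the pipeline streams sample by sample instead.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    sim = ReadSimulator(config, genome, annotation)
    reads_by_sample = {}
    truth_frames = []
    for sample_id in counts.columns:
        reads, truth = sim.sample_reads(sample_id, counts[sample_id], rng)
        reads_by_sample[sample_id] = reads
        truth_frames.append(truth)
    per_read = pd.concat(truth_frames, ignore_index=True)
    return reads_by_sample, per_read


def exhaustive_align(
    items: Iterator[tuple[str, str]] | Sequence[tuple[str, str]],
    genome: dict[str, str],
) -> list[AlignmentRecord]:
    """Align (read_id, sequence) pairs by exhaustive string search.

    Every occurrence on either strand yields one ungapped, mismatch-free
    record, so a read whose sequence occurs at several loci is emitted at
    all of them; a read absent from the genome yields none.
    """
    items = list(items)
    cache: dict[str, list[tuple[str, str, int, int]]] = {}
    for _rid, seq in items:
        if seq in cache:
            continue
        loci = []
        rc = reverse_complement(seq)
        for chrom, ref in genome.items():
            for p in _find_all(ref, seq):
                loci.append((chrom, "+", p + 1, p + len(seq)))
            for p in _find_all(ref, rc):
                loci.append((chrom, "-", p + 1, p + len(seq)))
        cache[seq] = loci
    records = []
    for rid, seq in items:
        for chrom, strand, start, end in cache[seq]:
            records.append(AlignmentRecord(
                read_id=rid, chrom=chrom, strand=strand,
                start=start, end=end, sequence=seq,
                multiplicity=multiplicity_from_read_id(rid),
            ))
    return records


def simulate_alignments(
    per_read_truth: pd.DataFrame,
    genome: dict[str, str],
) -> list[AlignmentRecord]:
    """Alignment records for generated reads, via exhaustive string search."""
    items = list(zip(per_read_truth["read_id"], per_read_truth["insert"]))
    return exhaustive_align(items, genome)


def expected_counts(
    per_read_truth: pd.DataFrame,
    mature_ids: Sequence[str],
    sample_ids: Sequence[str],
) -> pd.DataFrame:
    """Truth tally: counts the quantifier should report.

    A read counts for the unique mature it hits when it passes the quality
    and adapter stages, its insert is 15-27 nt, and it hits exactly one
    mature id (the ``counted`` flag set at generation time).
    """
    tally = (
        per_read_truth[per_read_truth["counted"]]
        .groupby(["assigned_mature", "sample_id"])
        .size()
    )
    out = pd.DataFrame(0, index=pd.Index(mature_ids, name="miRNA"),
                       columns=list(sample_ids), dtype=int)
    for (mid, sid), c in tally.items():
        if mid in out.index and sid in out.columns:
            out.loc[mid, sid] = c
    return out
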