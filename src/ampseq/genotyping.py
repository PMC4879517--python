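"""From dual-indexed amplicon reads to genotypes and QC.

A batch is four 96-well plates indexed by 16 row (S5xx) by 24 column (N7xx)
8-bp dual indexes — 384 unique combinations; the default layout carries 380
sample wells and 4 blanks, each plate contributing two duplicated-sample
pairs and one blank as quality controls. Reads are 51-bp single-end with the
forward primer at the 5' end, so each read reports the base at a known SNP
offset; genotypes are called from per-allele read counts with an
allele-fraction rule, and per-amplicon depth/missing statistics mirror the
working thresholds (>50x mean depth, <10% missing) used to judge amplicon
efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .io import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix
from .primers import AmpliconPanel

N_ROWS = 16  # S5xx index set
N_COLS = 24  # N7xx index set
INDEX_LEN = 8
DEFAULT_MIN_DEPTH = 5


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


@lru_cache(maxsize=None)
def default_index_sets() -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Deterministic synthetic 8-bp index sets: 16 row and 24 column indexes
    with pairwise Hamming distance >= 3, so a single sequencing error never
    makes an index ambiguous."""
    rng = np.random.default_rng(20160217)
    bases = np.array(list("ACGT"))
    picked: list[str] = []
    while len(picked) < N_ROWS + N_COLS:
        cand = "".join(rng.choice(bases, size=INDEX_LEN))
        if all(_hamming(cand, p) >= 3 for p in picked):
            picked.append(cand)
    return tuple(picked[:N_ROWS]), tuple(picked[N_ROWS:])


@dataclass
class PlateLayout:
    """Assignment of samples to the 384 (row, column) dual-index wells.

    ``assignments`` maps (row, col) 0-based indices to a sample id, or None
    for a blank well. Each of the four 96-well plates occupies six columns.
    """

    assignments: dict[tuple[int, int], str | None]
    row_indexes: tuple[str, ...] = field(default_factory=lambda: default_index_sets()[0])
    col_indexes: tuple[str, ...] = field(default_factory=lambda: default_index_sets()[1])

    def __post_init__(self) -> None:
        if len(self.assignments) > N_ROWS * N_COLS:
            raise ValueError("more than 384 well assignments")
        for r, c in self.assignments:
            if not (0 <= r < N_ROWS and 0 <= c < N_COLS):
                raise ValueError(f"well ({r},{c}) outside the 16x24 grid")

    @property
    def sample_wells(self) -> dict[tuple[int, int], str]:
        return {w: s for w, s in self.assignments.items() if s is not None}

    @property
    def blank_wells(self) -> list[tuple[int, int]]:
        return [w for w, s in self.assignments.items() if s is None]

    def index_pair(self, well: tuple[int, int]) -> tuple[str, str]:
        r, c = well
        return self.row_indexes[r], self.col_indexes[c]

    def duplicated_samples(self) -> set[str]:
        seen: set[str] = set()
        dups: set[str] = set()
        for s in self.assignments.values():
            if s is None:
                continue
            (dups if s in seen else seen).add(s)
        return dups


def build_layout(
    samples: list[str],
    n_blanks: int = 4,
    dup_pairs_per_plate: int = 2,
    seed: int = 0,
) -> PlateLayout:
    """Deterministically place samples on a four-plate batch.

    Each 96-well plate receives one blank (when blanks remain),
    ``dup_pairs_per_plate`` duplicated individuals and unique samples in the
    remaining wells; with the defaults the batch holds 380 sample wells and
    4 blanks.
    """
    rng = np.random.default_rng(seed)
    wells_per_plate = [
        [(r, plate * 6 + c) for c in range(6) for r in range(N_ROWS)] for plate in range(4)
    ]
    n_sample_wells = N_ROWS * N_COLS - n_blanks
    capacity = n_sample_wells - 4 * dup_pairs_per_plate  # unique individuals
    if len(samples) > capacity:
        raise ValueError(f"{len(samples)} samples exceed capacity {capacity}")

    assignments: dict[tuple[int, int], str | None] = {}
    pool = list(samples)
    blanks_left = n_blanks
    for plate, wells in enumerate(wells_per_plate):
        wells = list(wells)
        n_blank = 1 if blanks_left > 0 and plate < n_blanks else 0
        if plate == 3:
            n_blank = blanks_left  # any remainder lands on the last plate
        n_unique = min(len(pool), len(wells) - n_blank - dup_pairs_per_plate)
        chunk, pool = pool[:n_unique], pool[n_unique:]
        dup_ids = list(rng.choice(chunk, size=min(dup_pairs_per_plate, len(chunk)), replace=False)) if chunk else []
        plate_samples = chunk + dup_ids
        order = rng.permutation(len(wells))
        blanks_left -= n_blank
        si = 0
        for k, wi in enumerate(order):
            well = wells[wi]
            if k < n_blank:
                assignments[well] = None
            elif si < len(plate_samples):
                assignments[well] = plate_samples[si]
                si += 1
    return PlateLayout(assignments=assignments)


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndexedRead:
    """A 51-bp single-end read with its 8-bp dual index pair."""

    name: str
    seq: str
    qual: str
    row_index: str
    col_index: str


def parse_indexed_fastq(path: str) -> list[IndexedRead]:
    """Read a FASTQ whose headers end in ``:<row_index>+<col_index>``."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    out = []
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            idx = title.rsplit(":", 1)[-1]
            i1, _, i2 = idx.partition("+")
            out.append(IndexedRead(title.split(" ")[0], seq, qual, i1, i2))
    return out


def _match_index(obs: str, candidates: tuple[str, ...], max_mismatch: int) -> int | None:
    """Index of the unique candidate within ``max_mismatch`` of ``obs``,
    else None (no match or ambiguous)."""
    hits = [i for i, c in enumerate(candidates) if _hamming(obs, c) <= max_mismatch]
    return hits[0] if len(hits) == 1 else None


@dataclass
class DemultiplexResult:
    by_sample: dict[str, list[IndexedRead]]
    blank: list[IndexedRead]
    unassigned: list[IndexedRead]

    @property
    def n_assigned(self) -> int:
        return sum(len(v) for v in self.by_sample.values()) + len(self.blank)


def demultiplex(
    reads: list[IndexedRead], layout: PlateLayout, max_mismatch: int = 1
) -> DemultiplexResult:
    """Assign reads to layout wells by their dual index pair.

    A read is assigned when each of its two indexes matches exactly one
    layout index within ``max_mismatch`` (default 1) and the well is
    assigned; reads landing on blank wells are kept separately as
    contamination QC. assigned + blank + unassigned partitions the input.
    """
    result = DemultiplexResult({s: [] for s in set(layout.sample_wells.values())}, [], [])
    for read in reads:
        if len(read.row_index) != INDEX_LEN or len(read.col_index) != INDEX_LEN:
            raise ValueError(
                f"index length must be {INDEX_LEN}: {read.row_index}/{read.col_index}"
            )
        r = _match_index(read.row_index, layout.row_indexes, max_mismatch)
        c = _match_index(read.col_index, layout.col_indexes, max_mismatch)
        if r is None or c is None or (r, c) not in layout.assignments:
            result.unassigned.append(read)
            continue
        sample = layout.assignments[(r, c)]
        if sample is None:
            result.blank.append(read)
        else:
            result.by_sample[sample].append(read)
    return result


# ---------------------------------------------------------------------------
# Allele counting and genotype calling
# ---------------------------------------------------------------------------

@dataclass
class AmpliconCounts:
    """Per (sample, amplicon) read counts for the two expected alleles and
    anything else; ``unassigned`` tallies reads matching no panel primer."""

    samples: list[str]
    markers: list[str]  # site names, panel order
    reads_a1: np.ndarray
    reads_a2: np.ndarray
    reads_other: np.ndarray
    unassigned: np.ndarray  # per sample

    def depth(self) -> np.ndarray:
        """Total reads per (sample, amplicon)."""
        return self.reads_a1 + self.reads_a2 + self.reads_other


def count_alleles(
    reads_by_sample: dict[str, list[IndexedRead]],
    panel: AmpliconPanel,
    max_primer_mismatch: int = 1,
) -> AmpliconCounts:
    """Assign each sample's reads to amplicons by forward-primer prefix
    match (at most ``max_primer_mismatch`` substitutions) and tally the base
    observed at the SNP offset against the template's two alleles."""
    samples = sorted(reads_by_sample)
    markers = [p.site.name for p in panel.pairs]
    shape = (len(samples), len(panel.pairs))
    a1 = np.zeros(shape, dtype=np.int64)
    a2 = np.zeros(shape, dtype=np.int64)
    other = np.zeros(shape, dtype=np.int64)
    unassigned = np.zeros(len(samples), dtype=np.int64)

    primers = [(j, p.fwd_seq, len(p.fwd_seq)) for j, p in enumerate(panel.pairs)]

    for i, sample in enumerate(samples):
        for read in reads_by_sample[sample]:
            seq = read if isinstance(read, str) else read.seq
            j = None
            for pj, pseq, plen in primers:
                if seq[:plen] == pseq:
                    j = pj
                    break
            if j is None:
                best = None
                for pj, pseq, plen in primers:
                    if len(seq) >= plen and _hamming(seq[:plen], pseq) <= max_primer_mismatch:
                        if best is not None:
                            best = None
                            break
                        best = pj
                j = best
            if j is None:
                unassigned[i] += 1
                continue
            pair = panel.pairs[j]
            offset = len(pair.fwd_seq)
            base = seq[offset] if len(seq) > offset else "N"
            if base == pair.template.a1:
                a1[i, j] += 1
            elif base == pair.template.a2:
                a2[i, j] += 1
            else:
                other[i, j] += 1
    return AmpliconCounts(samples, markers, a1, a2, other, unassigned)


def call_genotypes(
    counts: AmpliconCounts,
    panel: AmpliconPanel,
    min_depth: int = DEFAULT_MIN_DEPTH,
    hom_max_fraction: float = 0.1,
    het_min_fraction: float = 0.2,
) -> tuple[GenotypeMatrix, list[str]]:
    """Call diploid genotypes from per-allele read counts.

    With d = reads_a1 + reads_a2 and minor fraction f = min/d: d < min_depth
    gives missing; f <= ``hom_max_fraction`` the majority homozygote;
    f >= ``het_min_fraction`` a heterozygote; the ambiguous band in between
    is missing. Sites with no alternate allele called in any sample are
    flagged failed ("no polymorphism") and listed for exclusion from VCF
    output.
    """
    n_s, n_m = len(counts.samples), len(counts.markers)
    calls = np.full((n_s, n_m), MISSING, dtype=np.int8)
    for j, pair in enumerate(panel.pairs):
        t = pair.template
        # dosage codes refer to the site's ref/alt, not a1/a2 ordering
        a1_is_alt = t.a1 == t.site.alt_allele
        for i in range(n_s):
            c1, c2 = int(counts.reads_a1[i, j]), int(counts.reads_a2[i, j])
            d = c1 + c2
            if d < min_depth:
                continue
            f = min(c1, c2) / d
            if f <= hom_max_fraction:
                major_is_a1 = c1 >= c2
                major_is_alt = (major_is_a1 and a1_is_alt) or (not major_is_a1 and not a1_is_alt)
                calls[i, j] = HOM_ALT if major_is_alt else HOM_REF
            elif f >= het_min_fraction:
                calls[i, j] = HET
    depths = counts.reads_a1 + counts.reads_a2
    sites = [p.site for p in panel.pairs]
    gm = GenotypeMatrix(list(counts.samples), sites, calls, depths.astype(np.int32))
    failed = []
    for j, site in enumerate(sites):
        col = calls[:, j]
        observed = set(int(c) for c in col if c != MISSING)
        if observed <= {HOM_REF} or observed <= {HOM_ALT}:
            failed.append(site.name)
    return gm, failed


@dataclass
class DepthStats:
    """Per-amplicon and per-sample depth/missing summaries with the >50x
    depth and <10% missing pass/fail flags."""

    per_amplicon: pd.DataFrame  # marker, mean_depth, cv, missing_individuals, missing_rate, flags
    per_sample: pd.DataFrame  # sample, mean_depth, missing_rate

    DEPTH_THRESHOLD = 50.0
    MISSING_THRESHOLD = 0.10


def depth_missing_stats(counts: AmpliconCounts, calls: GenotypeMatrix) -> DepthStats:
    """Per-amplicon mean depth over all assigned samples, CV (sample SD /
    mean), count of missing individuals and missing rate; per-sample mean
    depth and missing rate."""
    depth = counts.depth().astype(float)
    missing = calls.calls == MISSING
    rows = []
    for j, marker in enumerate(counts.markers):
        d = depth[:, j]
        mean = float(d.mean()) if d.size else 0.0
        sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
        cv = sd / mean if mean > 0 else 0.0
        n_missing = int(missing[:, j].sum())
        rate = n_missing / len(counts.samples) if counts.samples else 0.0
        rows.append(
            {
                "marker": marker,
                "mean_depth": mean,
                "cv": cv,
                "missing_individuals": n_missing,
                "missing_rate": rate,
                "pass_depth": mean > DepthStats.DEPTH_THRESHOLD,
                "pass_missing": rate < DepthStats.MISSING_THRESHOLD,
            }
        )
    per_amplicon = pd.DataFrame(rows)
    per_sample = pd.DataFrame(
        {
            "sample": counts.samples,
            "mean_depth": depth.mean(axis=1) if depth.size else 0.0,
            "missing_rate": missing.mean(axis=1) if missing.size else 0.0,
        }
    )
    return DepthStats(per_amplicon, per_sample)


def window_read_counts(
    read_intervals: list[tuple[str, int, int]],
    amplicons: list[tuple[str, int, int]],
    window: int = 500,
    step: int | None = None,
) -> tuple[pd.DataFrame, float]:
    """Read counts in ``window``-bp windows (default non-overlapping tiling)
    plus the on-target fraction: reads in windows overlapping a panel
    amplicon / total reads.

    Windows are 1-based [start, start+window-1]; a read is counted in every
    window its interval overlaps (exactly one when step == window and the
    read is within one window).
    """
    step = step or window
    counts: dict[tuple[str, int], int] = {}
    target_windows: set[tuple[str, int]] = set()
    for chrom, a_start, a_end in amplicons:
        first = ((a_start - 1) // step) * step + 1
        for w in range(first, a_end + 1, step):
            if w <= a_end and w + window - 1 >= a_start:
                target_windows.add((chrom, w))
    on_target = 0
    for chrom, start, end in read_intervals:
        first = ((start - 1) // step) * step + 1
        hit_target = False
        for w in range(first, end + 1, step):
            if w <= end and w + window - 1 >= start:
                counts[(chrom, w)] = counts.get((chrom, w), 0) + 1
                if (chrom, w) in target_windows:
                    hit_target = True
        if hit_target:
            on_target += 1
    frame = pd.DataFrame(
        [
            {"chrom": c, "window_start": w, "window_end": w + window - 1, "reads": n}
            for (c, w), n in sorted(counts.items())
        ]
    )
    frac = on_target / len(read_intervals) if read_intervals else 0.0
    return frame, frac
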