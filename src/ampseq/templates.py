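"""Per-allele consensus template extraction from GBS read stacks.

Primer templates are built from the actual sequences observed in the GBS
reads rather than the reference genome, so that primers match the alleles
they are meant to amplify. Each candidate SNP yields an
:class:`AlleleTemplate` carrying the 18 numeric parameters used downstream
by the primer-efficiency classifier, plus a rejection code:

==== =======================================================
code meaning
==== =======================================================
0    OK — exactly two alleles with clean, matching flanks
1    allele-count violation (!= 2 alleles among the reads)
2    insufficient flanking coverage (< min_flank on a side)
3    inter-allele flank mismatch (< min_match % identity)
4    depth outlier (putative repetitive region)
==== =======================================================

Only code 0 is eligible for primer design.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .io import AlignedRead, SnpSite, VALID_BASES
from .haploblock import LdRecord

#: canonical order of the 18 numeric template/primer parameters
FEATURE_NAMES = [
    "num_tags", "pvalue", "phase", "reject_code",
    "a1", "a1_count", "a1_lseq_pct", "a1_rseq_pct",
    "a2", "a2_count", "a2_lseq_pct", "a2_rseq_pct",
    "ltemp", "rtemp",
    "a1_lseq_len", "a1_rseq_len", "a2_lseq_len", "a2_rseq_len",
]

# numeric encoding of allele bases for the feature vector
BASE_CODE = {"A": 1, "C": 2, "G": 3, "T": 4, "": 0}

DEFAULT_MAX_FLANK = 30
DEFAULT_MIN_FLANK = 10
DEFAULT_MATCH_WINDOW = 20
DEFAULT_MIN_MATCH = 90.0


class RejectCode(IntEnum):
    OK = 0
    ALLELE_COUNT = 1
    SHORT_FLANK = 2
    FLANK_MISMATCH = 3
    DEPTH_OUTLIER = 4


@dataclass
class AlleleTemplate:
    """Per-SNP record of the two allele consensus templates and the 18
    numeric parameters consumed by the efficiency classifier.

    Flank sequences are stored in genomic orientation: ``*_lseq`` ends at the
    base adjacent to the SNP, ``*_rseq`` starts at the base adjacent to it.
    ``ltemp``/``rtemp`` are filled by the primer-design stage.
    """

    site: SnpSite
    num_tags: int = 0
    pvalue: float = float("nan")
    phase: int = 0
    reject_code: int = int(RejectCode.ALLELE_COUNT)
    a1: str = ""
    a2: str = ""
    a1_count: int = 0
    a2_count: int = 0
    a1_lseq: str = ""
    a1_rseq: str = ""
    a2_lseq: str = ""
    a2_rseq: str = ""
    a1_lseq_pct: float = 0.0
    a1_rseq_pct: float = 0.0
    a2_lseq_pct: float = 0.0
    a2_rseq_pct: float = 0.0
    ltemp: float = float("nan")
    rtemp: float = float("nan")

    @property
    def a1_lseq_len(self) -> int:
        return len(self.a1_lseq)

    @property
    def a1_rseq_len(self) -> int:
        return len(self.a1_rseq)

    @property
    def a2_lseq_len(self) -> int:
        return len(self.a2_lseq)

    @property
    def a2_rseq_len(self) -> int:
        return len(self.a2_rseq)

    def feature_vector(self) -> np.ndarray:
        """The 18 numeric parameters in canonical order (allele bases coded
        A=1, C=2, G=3, T=4)."""
        values = {
            "num_tags": self.num_tags,
            "pvalue": self.pvalue,
            "phase": self.phase,
            "reject_code": self.reject_code,
            "a1": BASE_CODE[self.a1],
            "a1_count": self.a1_count,
            "a1_lseq_pct": self.a1_lseq_pct,
            "a1_rseq_pct": self.a1_rseq_pct,
            "a2": BASE_CODE[self.a2],
            "a2_count": self.a2_count,
            "a2_lseq_pct": self.a2_lseq_pct,
            "a2_rseq_pct": self.a2_rseq_pct,
            "ltemp": self.ltemp,
            "rtemp": self.rtemp,
            "a1_lseq_len": self.a1_lseq_len,
            "a1_rseq_len": self.a1_rseq_len,
            "a2_lseq_len": self.a2_lseq_len,
            "a2_rseq_len": self.a2_rseq_len,
        }
        return np.array([float(values[n]) for n in FEATURE_NAMES])

    def design_template(self) -> str | None:
        """Allele-1 template (left flank + a1 + right flank), only for
        design-eligible (code 0) templates."""
        if self.reject_code != RejectCode.OK:
            return None
        return self.a1_lseq + self.a1 + self.a1_rseq


def collect_site_reads(
    reads: list[AlignedRead], site: SnpSite
) -> tuple[dict[str, list[AlignedRead]], int]:
    """Group the reads covering ``site`` by the base they show there.

    Reads with a deletion or N at the site are discarded. Returns the groups
    (keyed A/C/G/T, insertion order by first observation, groups sorted by
    descending size then base) and ``num_tags`` — the number of distinct read
    sequences across all groups.
    """
    groups: dict[str, list[AlignedRead]] = {}
    tags: set[str] = set()
    for read in reads:
        base = read.base_at(site.pos)
        if base is None or base.upper() not in VALID_BASES:
            continue
        groups.setdefault(base.upper(), []).append(read)
        tags.add(read.seq)
    ordered = dict(sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0])))
    return ordered, len(tags)


def build_allele_consensus(
    group: list[AlignedRead], site: SnpSite, max_flank: int = DEFAULT_MAX_FLANK
) -> tuple[str, str, float, float]:
    """Majority-rule consensus of the flanks left and right of the SNP for
    one allele group.

    Per column the consensus base is the majority of covering reads (ties
    broken lexicographically); the consensus is truncated at the first column
    covered by zero reads. The agreement percent is the mean over consensus
    columns of (majority count / covering reads) * 100.

    Returns (left consensus, right consensus, left agreement %, right
    agreement %); flanks are in genomic orientation.
    """
    if not group:
        raise ValueError("empty allele group")

    def one_side(step: int) -> tuple[str, float]:
        bases: list[str] = []
        agreements: list[float] = []
        for off in range(1, max_flank + 1):
            pos = site.pos + step * off
            column = [b for b in (r.base_at(pos) for r in group)
                      if b is not None and b.upper() in VALID_BASES]
            if not column:
                break
            counts: dict[str, int] = {}
            for b in column:
                counts[b.upper()] = counts.get(b.upper(), 0) + 1
            # tie-break: highest count, then lexicographically smallest base
            best_count = max(counts.values())
            top = min(b for b, c in counts.items() if c == best_count)
            bases.append(top)
            agreements.append(counts[top] / len(column) * 100.0)
        if not bases:
            return "", 0.0
        return "".join(bases), float(np.mean(agreements))

    left_rev, left_pct = one_side(-1)
    right, right_pct = one_side(+1)
    return left_rev[::-1], right, left_pct, right_pct


def flank_match_pct(c1: str, c2: str, window: int = DEFAULT_MATCH_WINDOW, side: str = "left") -> float:
    """Percent identity between two allele consensi over the first
    min(window, overlap) bases adjacent to the SNP.

    ``side='left'`` compares from the SNP-adjacent (right) end of the left
    flanks; ``side='right'`` from the start of the right flanks. Either side
    empty gives 0%.
    """
    if not c1 or not c2:
        return 0.0
    k = min(window, len(c1), len(c2))
    if side == "left":
        s1, s2 = c1[-k:], c2[-k:]
    else:
        s1, s2 = c1[:k], c2[:k]
    matches = sum(1 for x, y in zip(s1, s2) if x == y)
    return matches / k * 100.0


@dataclass(frozen=True)
class TemplateThresholds:
    min_flank: int = DEFAULT_MIN_FLANK
    match_window: int = DEFAULT_MATCH_WINDOW
    min_match: float = DEFAULT_MIN_MATCH
    max_flank: int = DEFAULT_MAX_FLANK
    depth_outlier: float | None = None  # site depth above this -> reject code 4


def make_template(
    site: SnpSite,
    reads: list[AlignedRead],
    ld: LdRecord | None = None,
    thresholds: TemplateThresholds = TemplateThresholds(),
    phase: int = 0,
) -> AlleleTemplate:
    """Build the full 18-parameter :class:`AlleleTemplate` for one site.

    Rejection codes are assigned in priority order 1 (allele count) -> 2
    (short flank) -> 3 (flank mismatch) -> 4 (depth outlier) -> 0. Rejected
    templates are still returned fully populated for the classifier.
    Allele 1 is the allele with the higher read count (ties: reference
    allele first), making the parameter vector deterministic.
    """
    groups, num_tags = collect_site_reads(reads, site)
    tpl = AlleleTemplate(
        site=site,
        num_tags=num_tags,
        pvalue=ld.p_value if ld is not None else float("nan"),
        phase=phase,
    )

    ordered = sorted(
        groups.items(),
        key=lambda kv: (-len(kv[1]), kv[0] != site.ref_allele, kv[0]),
    )
    if ordered:
        tpl.a1 = ordered[0][0]
        tpl.a1_count = len(ordered[0][1])
        tpl.a1_lseq, tpl.a1_rseq, tpl.a1_lseq_pct, tpl.a1_rseq_pct = build_allele_consensus(
            ordered[0][1], site, thresholds.max_flank
        )
    if len(ordered) > 1:
        tpl.a2 = ordered[1][0]
        tpl.a2_count = len(ordered[1][1])
        tpl.a2_lseq, tpl.a2_rseq, tpl.a2_lseq_pct, tpl.a2_rseq_pct = build_allele_consensus(
            ordered[1][1], site, thresholds.max_flank
        )

    if len(groups) != 2:
        tpl.reject_code = int(RejectCode.ALLELE_COUNT)
        return tpl
    if min(tpl.a1_lseq_len, tpl.a1_rseq_len, tpl.a2_lseq_len, tpl.a2_rseq_len) < thresholds.min_flank:
        tpl.reject_code = int(RejectCode.SHORT_FLANK)
        return tpl
    left_id = flank_match_pct(tpl.a1_lseq, tpl.a2_lseq, thresholds.match_window, side="left")
    right_id = flank_match_pct(tpl.a1_rseq, tpl.a2_rseq, thresholds.match_window, side="right")
    if left_id < thresholds.min_match or right_id < thresholds.min_match:
        tpl.reject_code = int(RejectCode.FLANK_MISMATCH)
        return tpl
    site_depth = tpl.a1_count + tpl.a2_count
    if thresholds.depth_outlier is not None and site_depth > thresholds.depth_outlier:
        tpl.reject_code = int(RejectCode.DEPTH_OUTLIER)
        return tpl
    tpl.reject_code = int(RejectCode.OK)
    return tpl


def depth_outlier_threshold(site_depths: list[int] | np.ndarray) -> float:
    """Depth above which a site is treated as a putative repeat: the larger
    of mean + 4*SD and the 99th percentile of candidate-site depths."""
    d = np.asarray(site_depths, dtype=float)
    if d.size == 0:
        return float("inf")
    return float(max(d.mean() + 4 * d.std(), np.percentile(d, 99)))
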