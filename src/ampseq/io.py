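"""Core data types and readers/writers for the standard formats the pipeline touches.

Coordinates are 1-based inclusive everywhere user-facing (VCF convention);
marker names follow the ``S<chrom>_<pos>`` style used on grape linkage maps,
e.g. ``S2_5186869`` for chromosome 2, position 5,186,869.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pysam

logger = logging.getLogger("ampseq")

VALID_BASES = frozenset("ACGT")

# genotype call codes (doubling as alt-allele dosage; MISSING excluded pairwise)
MISSING = -1
HOM_REF = 0
HET = 1
HOM_ALT = 2


@dataclass(frozen=True, order=True)
class SnpSite:
    """A biallelic SNP on the reference genome (1-based position)."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref_allele not in VALID_BASES or self.alt_allele not in VALID_BASES:
            raise ValueError(
                f"alleles must be single bases in ACGT: {self.ref_allele}/{self.alt_allele}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt allele must differ")

    @property
    def name(self) -> str:
        """Marker name in ``S<chrom>_<pos>`` style (chr prefix stripped)."""
        chrom = re.sub(r"^chr", "", self.chrom, flags=re.IGNORECASE)
        return f"S{chrom}_{self.pos}"


@dataclass
class GenotypeMatrix:
    """Samples x sites diploid genotype calls with per-cell read depths.

    ``calls`` holds codes ``HOM_REF``/``HET``/``HOM_ALT``/``MISSING``; the
    non-missing codes equal the alt-allele dosage 0/1/2 used by the LD and
    association statistics.
    """

    samples: list[str]
    sites: list[SnpSite]
    calls: np.ndarray  # int8, shape (n_samples, n_sites)
    depths: np.ndarray  # int32, same shape

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.depths = np.asarray(self.depths, dtype=np.int32)
        shape = (len(self.samples), len(self.sites))
        if self.calls.shape != shape or self.depths.shape != shape:
            raise ValueError(
                f"calls/depths shape must be {shape}, got {self.calls.shape}/{self.depths.shape}"
            )
        if (self.depths < 0).any():
            raise ValueError("depths must be non-negative")
        # depth 0 implies a missing call
        self.calls[self.depths == 0] = MISSING

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_index(self, chrom: str, pos: int) -> int:
        for i, s in enumerate(self.sites):
            if s.chrom == chrom and s.pos == pos:
                return i
        raise KeyError(f"site {chrom}:{pos} not in matrix")

    def dosage(self) -> np.ndarray:
        """Alt-allele dosage as float, with NaN for missing calls."""
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        return d

    def site_missing_fraction(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)


@dataclass(frozen=True)
class TestMarkerFile:
    """Physical positions of the three markers that define a design run:
    haploblock start, haploblock end, and the anchor SNP."""

    chrom: str
    start_pos: int
    end_pos: int
    anchor_pos: int

    def __post_init__(self) -> None:
        if not (self.start_pos <= self.anchor_pos <= self.end_pos):
            raise ValueError("require start <= anchor <= end")


def read_test_marker(path: str) -> TestMarkerFile:
    """Read the three-line TSV ``chrom<TAB>pos<TAB>role`` (roles start/end/anchor)."""
    roles: dict[str, tuple[str, int]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3 or parts[2] not in {"start", "end", "anchor"}:
                raise ValueError(f"{path}:{ln}: expected 'chrom<TAB>pos<TAB>start|end|anchor'")
            roles[parts[2]] = (parts[0], int(parts[1]))
    missing = {"start", "end", "anchor"} - roles.keys()
    if missing:
        raise ValueError(f"{path}: missing roles {sorted(missing)}")
    chroms = {c for c, _ in roles.values()}
    if len(chroms) != 1:
        raise ValueError(f"{path}: all three markers must be on one chromosome, got {sorted(chroms)}")
    return TestMarkerFile(
        chrom=roles["start"][0],
        start_pos=roles["start"][1],
        end_pos=roles["end"][1],
        anchor_pos=roles["anchor"][1],
    )


def write_test_marker(tm: TestMarkerFile, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"{tm.chrom}\t{tm.start_pos}\tstart\n")
        fh.write(f"{tm.chrom}\t{tm.end_pos}\tend\n")
        fh.write(f"{tm.chrom}\t{tm.anchor_pos}\tanchor\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF 4.x into a :class:`GenotypeMatrix`.

    Biallelic SNP records only; multi-allelic and indel records are skipped
    with a logged warning. Depth is taken from FORMAT/DP, else summed
    FORMAT/AD, else 1 for called genotypes.
    """
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        sites: list[SnpSite] = []
        call_rows: list[list[int]] = []
        depth_rows: list[list[int]] = []
        n_skipped = 0
        for rec in vf:
            alts = rec.alts or ()
            if (
                len(alts) != 1
                or rec.ref is None
                or len(rec.ref) != 1
                or len(alts[0]) != 1
                or rec.ref.upper() not in VALID_BASES
                or alts[0].upper() not in VALID_BASES
            ):
                n_skipped += 1
                logger.warning("skipping non-biallelic-SNP record %s:%s", rec.chrom, rec.pos)
                continue
            sites.append(SnpSite(rec.chrom, rec.pos, rec.ref.upper(), alts[0].upper()))
            calls, depths = [], []
            for s in samples:
                sample = rec.samples[s]
                gt = sample.get("GT")
                if gt is None or any(a is None for a in gt):
                    code = MISSING
                else:
                    code = int(sum(gt))
                dp = sample.get("DP")
                if dp is None:
                    ad = sample.get("AD")
                    dp = int(sum(x for x in ad if x is not None)) if ad else (
                        1 if code != MISSING else 0
                    )
                calls.append(code)
                depths.append(int(dp))
            call_rows.append(calls)
            depth_rows.append(depths)
        if n_skipped:
            logger.info("read_vcf(%s): skipped %d records", path, n_skipped)
    calls_arr = (
        np.array(call_rows, dtype=np.int8).T if call_rows else np.zeros((len(samples), 0), np.int8)
    )
    depth_arr = (
        np.array(depth_rows, dtype=np.int32).T
        if depth_rows
        else np.zeros((len(samples), 0), np.int32)
    )
    return GenotypeMatrix(samples, sites, calls_arr, depth_arr)


_GT_FOR_CODE = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1), MISSING: (None, None)}


def write_vcf(gm: GenotypeMatrix, path: str, contig_lengths: dict[str, int] | None = None) -> None:
    """Write a :class:`GenotypeMatrix` as VCF 4.2 with GT and DP fields."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    chroms: dict[str, int] = {}
    for site in gm.sites:
        chroms[site.chrom] = max(chroms.get(site.chrom, 0), site.pos)
    for chrom, max_pos in chroms.items():
        length = (contig_lengths or {}).get(chrom, max_pos + 1000)
        header.add_line(f"##contig=<ID={chrom},length={length}>")
    for s in gm.samples:
        header.add_sample(s)
    with pysam.VariantFile(path, "w", header=header) as vf:
        for j, site in enumerate(gm.sites):
            rec = vf.new_record(
                contig=site.chrom,
                start=site.pos - 1,
                stop=site.pos,
                alleles=(site.ref_allele, site.alt_allele),
            )
            for i, s in enumerate(gm.samples):
                rec.samples[s]["GT"] = _GT_FOR_CODE[int(gm.calls[i, j])]
                rec.samples[s]["DP"] = int(gm.depths[i, j])
            vf.write(rec)


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

@dataclass
class AlignedRead:
    """An aligned read with its CIGAR-resolved per-base reference mapping.

    ``ref_map`` maps 1-based reference positions to query offsets; positions
    spanned by deletions and bases that are soft-clipped or inserted are
    absent from the map.
    """

    name: str
    seq: str
    ref_start: int  # 1-based leftmost aligned reference position
    ref_map: dict[int, int] = field(repr=False)

    def base_at(self, pos: int) -> str | None:
        q = self.ref_map.get(pos)
        return self.seq[q] if q is not None else None


def read_alignments(path: str, chrom: str, start: int, end: int) -> list[AlignedRead]:
    """Fetch mapped reads overlapping ``chrom:start-end`` (1-based inclusive).

    Requires a coordinate-sorted, indexed BAM; a missing index is a hard
    error. Unmapped reads are ignored.
    """
    out: list[AlignedRead] = []
    with pysam.AlignmentFile(path) as af:
        if not af.has_index():
            raise FileNotFoundError(f"alignment file {path} has no index (.bai)")
        for read in af.fetch(chrom, start - 1, end):
            if read.is_unmapped or read.query_sequence is None:
                continue
            ref_map = {
                rpos + 1: qpos
                for qpos, rpos in read.get_aligned_pairs(matches_only=True)
            }
            out.append(
                AlignedRead(
                    name=read.query_name or "",
                    seq=read.query_sequence,
                    ref_start=read.reference_start + 1,
                    ref_map=ref_map,
                )
            )
    return out
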