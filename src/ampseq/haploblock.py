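"""Marker phase/effect estimation, haploblock definition and anchor-LD retrieval.

A haploblock is the contiguous chromosomal segment around a QTL whose markers
share a similar absolute phenotypic effect; candidate SNPs for amplicon design
are retrieved from it by linkage disequilibrium (LD) with an anchor marker —
the mapped SNP with the strongest trait association inside the QTL support
interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import HET, MISSING, GenotypeMatrix, SnpSite, TestMarkerFile

DEFAULT_MAX_MISSING = 0.05
DEFAULT_P_CUTOFF = 1e-25


@dataclass(frozen=True)
class PhasedMarker:
    """A mapped marker with, per informative (heterozygous) parent, the allele
    carried on haplotype 1 vs haplotype 2."""

    site: SnpSite
    linkage_group: str
    cM: float
    parent_phase: dict  # parent id -> (hap1 allele, hap2 allele)

    def __post_init__(self) -> None:
        if self.cM < 0:
            raise ValueError("cM must be >= 0")


@dataclass
class MarkerEffect:
    """Signed phenotype-mean difference between the two parental-haplotype
    classes of progeny; ``effect`` is None when a class has < 2 members."""

    site: SnpSite
    effect: float | None
    n1: int
    n2: int

    @property
    def abs_effect(self) -> float | None:
        return None if self.effect is None else abs(self.effect)


@dataclass(frozen=True)
class Haploblock:
    chrom: str
    start_pos: int
    end_pos: int
    anchor: SnpSite
    qtl_r2: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.start_pos <= self.anchor.pos <= self.end_pos):
            raise ValueError("require start <= anchor <= end")

    def to_test_marker(self) -> TestMarkerFile:
        return TestMarkerFile(self.chrom, self.start_pos, self.end_pos, self.anchor.pos)


@dataclass(frozen=True)
class LdRecord:
    site: SnpSite
    r2: float  # NaN when undefined (monomorphic input)
    p_value: float
    n: int


def estimate_marker_effects(
    phased: list[PhasedMarker],
    genotypes: GenotypeMatrix,
    phenotype: dict[str, float],
    parent: str,
) -> list[MarkerEffect]:
    """Estimate per-marker phenotypic effects in a pseudo-testcross family.

    For each marker heterozygous in ``parent``, progeny are split into the two
    parental-haplotype classes — in a testcross configuration (other parent
    homozygous reference) a heterozygous progeny received the informative
    parent's alt allele and a homozygous-reference progeny its ref allele —
    and the effect is mean(phenotype | haplotype-1 class) minus
    mean(phenotype | haplotype-2 class). Markers where either class has fewer
    than two phenotyped progeny get effect ``None``.
    """
    pheno = {s: phenotype[s] for s in genotypes.samples if s in phenotype
             and phenotype[s] is not None and not math.isnan(phenotype[s])}
    if not pheno:
        raise ValueError("phenotype missing for all progeny")
    out: list[MarkerEffect] = []
    for pm in phased:
        if parent not in pm.parent_phase:
            continue
        hap1_allele, hap2_allele = pm.parent_phase[parent]
        j = genotypes.site_index(pm.site.chrom, pm.site.pos)
        site = genotypes.sites[j]
        class_values: dict[str, list[float]] = {site.ref_allele: [], site.alt_allele: []}
        for i, s in enumerate(genotypes.samples):
            if s not in pheno:
                continue
            call = int(genotypes.calls[i, j])
            if call == MISSING:
                continue
            # allele inherited from the informative parent
            inherited = site.alt_allele if call >= HET else site.ref_allele
            class_values[inherited].append(pheno[s])
        v1 = class_values.get(hap1_allele, [])
        v2 = class_values.get(hap2_allele, [])
        if len(v1) < 2 or len(v2) < 2:
            out.append(MarkerEffect(site, None, len(v1), len(v2)))
        else:
            out.append(
                MarkerEffect(site, float(np.mean(v1) - np.mean(v2)), len(v1), len(v2))
            )
    return out


def define_haploblock(
    effects: list[MarkerEffect],
    anchor: SnpSite,
    tau: float = 0.8,
    qtl_r2: float = float("nan"),
) -> Haploblock:
    """Define the haploblock as the maximal contiguous run of markers around
    the anchor whose |effect| >= tau * |effect(anchor)|.

    ``effects`` must be position-sorted on one chromosome; markers with an
    undefined effect break the run.
    """
    effects = sorted(effects, key=lambda e: e.site.pos)
    try:
        ai = next(i for i, e in enumerate(effects) if e.site == anchor)
    except StopIteration:
        raise ValueError(f"anchor {anchor.name} not among effects") from None
    if effects[ai].effect is None:
        raise ValueError(f"anchor {anchor.name} has undefined effect")
    threshold = tau * abs(effects[ai].effect)

    def ok(e: MarkerEffect) -> bool:
        return e.abs_effect is not None and e.abs_effect >= threshold

    lo = ai
    while lo > 0 and ok(effects[lo - 1]):
        lo -= 1
    hi = ai
    while hi < len(effects) - 1 and ok(effects[hi + 1]):
        hi += 1
    return Haploblock(
        chrom=anchor.chrom,
        start_pos=effects[lo].site.pos,
        end_pos=effects[hi].site.pos,
        anchor=anchor,
        qtl_r2=qtl_r2,
    )


def ld_r2_p(
    a: np.ndarray, b: np.ndarray, exact: bool = False, rng: np.random.Generator | None = None
) -> tuple[float, float, int]:
    """Squared genotype correlation between two 0/1/2 dosage vectors.

    Missing values (NaN or negative) are excluded pairwise. The P-value is
    the upper tail of chi-square = n * r^2 with 1 df — the standard
    genotype-r2 LD test. ``exact=True`` replaces it with a permutation P
    (recommended for n < 30). Monomorphic input over the complete pairs gives
    (nan, nan, n): no association detectable.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    mask = ~(np.isnan(a) | np.isnan(b) | (a < 0) | (b < 0))
    x, y = a[mask], b[mask]
    n = int(mask.sum())
    if n < 2:
        raise ValueError("need at least 2 pairwise-complete samples")
    if np.std(x) == 0 or np.std(y) == 0:
        return (float("nan"), float("nan"), n)
    r = float(np.corrcoef(x, y)[0, 1])
    r2 = r * r
    if exact:
        rng = rng or np.random.default_rng(0)
        n_perm = 10_000
        count = 0
        for _ in range(n_perm):
            yp = rng.permutation(y)
            rp = np.corrcoef(x, yp)[0, 1]
            if rp * rp >= r2 - 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
    else:
        p = float(stats.chi2.sf(n * r2, df=1))
    return (r2, p, n)


def retrieve_ld_snps(
    vcf: GenotypeMatrix,
    block: Haploblock,
    anchor: SnpSite | None = None,
    max_missing: float = DEFAULT_MAX_MISSING,
    p_cutoff: float = DEFAULT_P_CUTOFF,
) -> list[LdRecord]:
    """Retrieve candidate SNPs inside the haploblock that are in LD with the
    anchor marker.

    Sites are kept when their position lies in [start, end], their missing
    fraction is <= ``max_missing`` (default 5%) and the anchor-LD P-value is
    <= ``p_cutoff`` (default 1e-25). Output is position-sorted.
    """
    anchor = anchor or block.anchor
    try:
        aj = vcf.site_index(anchor.chrom, anchor.pos)
    except KeyError:
        raise ValueError(f"anchor {anchor.name} absent from genotype matrix") from None
    dose = vcf.dosage()
    a_dose = dose[:, aj]
    missing_frac = vcf.site_missing_fraction()
    out: list[LdRecord] = []
    for j, site in enumerate(vcf.sites):
        if site.chrom != block.chrom or not (block.start_pos <= site.pos <= block.end_pos):
            continue
        if missing_frac[j] > max_missing:
            continue
        r2, p, n = ld_r2_p(a_dose, dose[:, j])
        if math.isnan(r2) or not (p <= p_cutoff):
            continue
        out.append(LdRecord(site, r2, p, n))
    out.sort(key=lambda r: r.site.pos)
    return out
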