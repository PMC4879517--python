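"""Synthetic biparental families, GBS read stacks and amplicon runs.

The generator emulates the study designs every other module consumes:

* a biparental F1 pseudo-testcross family — the informative (donor) parent
  heterozygous at every marker with haplotype 1 carrying the alt alleles,
  the other parent homozygous reference, so markers segregate 1:1 het:hom
  with an expected minor allele frequency of 0.25;
* a three-allele flower-sex locus with dominance M > H > f (phenotype coded
  M=2, H=1, f=0 after resolving dominance);
* quantitative trait loci with a configurable target R^2 (fraction of
  phenotypic variance explained), implemented by scaling Gaussian noise
  around the causal-allele effect;
* GBS-like 64-bp read stacks over each SNP for template extraction;
* dual-indexed 51-bp amplicon reads with negative-binomial depth (the large
  depth CVs seen in real runs), configurable dropout and error rate.

Everything is deterministic under a seed; identical config + seed gives
byte-identical FASTQ output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam

from .io import AlignedRead, GenotypeMatrix, HET, HOM_REF, SnpSite
from .genotyping import IndexedRead, PlateLayout
from .primers import AmpliconPanel

BASES = np.array(list("ACGT"))

SEX_CODE = {"M": 2, "H": 1, "f": 0}  # dominance M > H > f


@dataclass
class LocusSpec:
    """A trait locus: a three-allele sex locus (genotypes like 'HH' x 'Mf')
    or a biallelic quantitative locus with a target R^2."""

    pos: int
    kind: str = "quantitative"  # or "sex_MHf"
    qtl_r2: float = 0.5
    effect: float = 1.0
    parent_genotypes: tuple[str, str] = ("Hf", "Mf")  # sex loci only

    def __post_init__(self) -> None:
        if self.kind not in {"quantitative", "sex_MHf"}:
            raise ValueError(f"unknown locus kind {self.kind}")
        if not (0.0 <= self.qtl_r2 <= 1.0):
            raise ValueError("qtl_r2 must be in [0, 1]")
        if self.kind == "sex_MHf":
            for g in self.parent_genotypes:
                if len(g) != 2 or any(a not in SEX_CODE for a in g):
                    raise ValueError(f"bad sex genotype {g!r}")


@dataclass
class FamilyConfig:
    """Parameters of one simulated F1 family."""

    n_progeny: int = 200
    chrom: str = "chr2"
    chrom_length: int = 2_000_000
    marker_positions: list[int] = field(default_factory=list)
    recomb_rate: float = 3.0  # cM per Mb
    loci: list[LocusSpec] = field(default_factory=list)
    depth_mean: float = 100.0
    depth_dispersion: float = 8.0
    missing_prob: float = 0.0
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.recomb_rate < 0 or self.error_rate < 0 or self.missing_prob < 0:
            raise ValueError("rates must be >= 0")
        for pos in self.marker_positions:
            if not (1 <= pos <= self.chrom_length):
                raise ValueError(f"marker position {pos} outside chromosome")
        for locus in self.loci:
            if not (1 <= locus.pos <= self.chrom_length):
                raise ValueError(f"locus position {locus.pos} outside chromosome")


@dataclass
class SimTruth:
    """Ground truth of a simulated family."""

    config: FamilyConfig
    sites: list[SnpSite]
    genotypes: GenotypeMatrix  # progeny calls at the markers
    phenotypes: dict[str, float]
    inherited_hap1: np.ndarray  # (n_progeny, n_markers) 1 where donor hap1 inherited
    causal_inherited_hap1: dict[int, np.ndarray]  # locus pos -> per-progeny indicator
    favorable_allele: dict[int, str]  # marker pos -> allele linked to donor hap1
    sex_phenotype: dict[str, str] = field(default_factory=dict)  # sample -> M/H/f


def _gamete_hap_indicator(
    rng: np.random.Generator, positions: np.ndarray, length: int, rate_cm_per_mb: float
) -> np.ndarray:
    """Which haplotype (1 or 2) a gamete carries at each position, after
    Poisson crossovers at the given genetic rate."""
    expected = length / 1e6 * rate_cm_per_mb / 100.0
    n_xo = rng.poisson(expected)
    breaks = np.sort(rng.integers(1, length + 1, size=n_xo))
    start = rng.integers(0, 2)  # which hap at the left end
    hap = np.full(len(positions), start)
    for b in breaks:
        hap[positions >= b] = 1 - hap[positions >= b]
    return (hap == 0).astype(int)  # 1 = haplotype 1


def simulate_family(config: FamilyConfig) -> SimTruth:
    """Simulate progeny genotypes and phenotypes for one family.

    Marker model: donor parent heterozygous everywhere with alt on haplotype
    1, other parent homozygous reference; a progeny is heterozygous at a
    marker exactly when it inherited donor haplotype 1 there. Quantitative
    phenotypes add Gaussian noise scaled so the realized R^2 at the causal
    position approximates the target; the sex locus resolves dominance
    M > H > f and codes the phenotype M=2, H=1, f=0.
    """
    rng = np.random.default_rng(config.seed)
    positions = np.array(sorted(config.marker_positions), dtype=int)
    all_pos = np.unique(np.concatenate([positions, [l.pos for l in config.loci]])) \
        if config.loci else positions
    samples = [f"P{i + 1:04d}" for i in range(config.n_progeny)]

    # alleles: ref/alt per marker chosen deterministically from the seed
    refs = rng.choice(BASES, size=len(positions))
    alts = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in refs])
    sites = [
        SnpSite(config.chrom, int(p), str(r), str(a))
        for p, r, a in zip(positions, refs, alts)
    ]

    inherit = np.zeros((config.n_progeny, len(all_pos)), dtype=int)
    for i in range(config.n_progeny):
        inherit[i] = _gamete_hap_indicator(rng, all_pos, config.chrom_length, config.recomb_rate)
    pos_index = {int(p): k for k, p in enumerate(all_pos)}
    marker_cols = [pos_index[int(p)] for p in positions]
    marker_inherit = inherit[:, marker_cols]

    calls = np.where(marker_inherit == 1, HET, HOM_REF).astype(np.int8)
    genotypes = GenotypeMatrix(samples, sites, calls, np.ones_like(calls, dtype=np.int32))

    phenotypes: dict[str, float] = {}
    sex_pheno: dict[str, str] = {}
    causal_ind: dict[int, np.ndarray] = {}
    total = np.zeros(config.n_progeny)
    for locus in config.loci:
        ind = inherit[:, pos_index[locus.pos]]
        causal_ind[locus.pos] = ind
        if locus.kind == "sex_MHf":
            g1, g2 = locus.parent_genotypes
            # other parent's gamete segregates independently of this chromosome
            a_from_donor = np.array([g1[0] if x == 1 else g1[1] for x in ind])
            a_from_other = np.array([g2[rng.integers(0, 2)] for _ in range(config.n_progeny)])
            codes = np.array(
                [max(SEX_CODE[a], SEX_CODE[b]) for a, b in zip(a_from_donor, a_from_other)]
            )
            inv = {v: k for k, v in SEX_CODE.items()}
            for s, c in zip(samples, codes):
                sex_pheno[s] = inv[int(c)]
            total = total + codes
        else:
            g = ind * locus.effect
            var_g = locus.effect ** 2 * 0.25  # Bernoulli(1/2) allele sampling
            if locus.qtl_r2 >= 1.0:
                noise = np.zeros(config.n_progeny)
            elif locus.qtl_r2 <= 0.0:
                g = np.zeros(config.n_progeny)
                noise = rng.normal(0.0, 1.0, config.n_progeny)
            else:
                sigma = np.sqrt(var_g * (1 - locus.qtl_r2) / locus.qtl_r2)
                noise = rng.normal(0.0, sigma, config.n_progeny)
            total = total + g + noise
    for s, v in zip(samples, total):
        phenotypes[s] = float(v)

    favorable = {int(p): str(a) for p, a in zip(positions, alts)}  # alt rides donor hap1
    return SimTruth(
        config=config,
        sites=sites,
        genotypes=genotypes,
        phenotypes=phenotypes,
        inherited_hap1=marker_inherit,
        causal_inherited_hap1=causal_ind,
        favorable_allele=favorable,
        sex_phenotype=sex_pheno,
    )


# ---------------------------------------------------------------------------
# GBS read stacks
# ---------------------------------------------------------------------------

@dataclass
class GbsStack:
    """Simulated GBS reads over one SNP plus the planted per-allele flanks."""

    site: SnpSite
    reads: list[AlignedRead]
    left_flank: dict[str, str]  # allele -> planted left flank (genomic order)
    right_flank: dict[str, str]


def simulate_gbs_stack(
    site: SnpSite,
    reads_per_allele: dict[str, int],
    error_rate: float = 0.0,
    read_len: int = 64,
    flank: int = 40,
    seed: int = 0,
    flank_divergence: dict[str, list[int]] | None = None,
) -> GbsStack:
    """Simulate an aligned GBS read stack over ``site``.

    All alleles share the same planted flanks unless ``flank_divergence``
    plants allele-specific substitutions at the given offsets (1-based
    distance from the SNP; negative = left flank). Reads are ``read_len`` bp,
    fully aligned, placed so each covers the SNP, with iid substitution
    errors at ``error_rate``.
    """
    rng = np.random.default_rng(seed)
    left = "".join(rng.choice(BASES, size=flank))
    right = "".join(rng.choice(BASES, size=flank))
    lefts: dict[str, str] = {}
    rights: dict[str, str] = {}
    for allele in reads_per_allele:
        l, r = list(left), list(right)
        for off in (flank_divergence or {}).get(allele, []):
            if off < 0:
                idx = flank + off  # off=-1 -> base adjacent to SNP
                l[idx] = next(b for b in "ACGT" if b != l[idx])
            else:
                r[off - 1] = next(b for b in "ACGT" if b != r[off - 1])
        lefts[allele] = "".join(l)
        rights[allele] = "".join(r)

    reads: list[AlignedRead] = []
    n = 0
    for allele, count in sorted(reads_per_allele.items()):
        hap = lefts[allele] + allele + rights[allele]
        hap_start = site.pos - flank  # reference position of hap[0]
        snp_idx = flank
        for _ in range(count):
            max_off = min(snp_idx, len(hap) - read_len)
            min_off = max(0, snp_idx - read_len + 1)
            off = int(rng.integers(min_off, max_off + 1))
            seq = list(hap[off:off + read_len])
            for k in range(len(seq)):
                if error_rate > 0 and rng.random() < error_rate:
                    seq[k] = str(rng.choice([b for b in "ACGT" if b != seq[k]]))
            start = hap_start + off
            n += 1
            reads.append(
                AlignedRead(
                    name=f"gbs{n}",
                    seq="".join(seq),
                    ref_start=start,
                    ref_map={start + k: k for k in range(read_len)},
                )
            )
    return GbsStack(site, reads, lefts, rights)


def write_bam(reads: list[AlignedRead], chrom: str, chrom_length: int, path: str) -> None:
    """Write fully-matched aligned reads as a coordinate-sorted, indexed BAM."""
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": chrom, "LN": chrom_length}]}
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for read in sorted(reads, key=lambda r: r.ref_start):
            a = pysam.AlignedSegment()
            a.query_name = read.name
            a.query_sequence = read.seq
            a.reference_id = 0
            a.reference_start = read.ref_start - 1
            a.mapping_quality = 60
            a.cigarstring = f"{len(read.seq)}M"
            a.query_qualities = pysam.qualitystring_to_array("I" * len(read.seq))
            bam.write(a)
    pysam.index(path)


# ---------------------------------------------------------------------------
# Amplicon sequencing runs
# ---------------------------------------------------------------------------

def simulate_ampseq_run(
    truth: SimTruth,
    panel: AmpliconPanel,
    layout: PlateLayout,
    sample_to_progeny: dict[str, str] | None = None,
    depth_mean: float | None = None,
    depth_dispersion: float | None = None,
    error_rate: float | None = None,
    dropout: dict[str, float] | None = None,
    read_len: int = 51,
    blank_depth: float = 0.2,
    seed: int = 0,
) -> list[IndexedRead]:
    """Simulate a dual-indexed single-end amplicon run over a plate layout.

    Per (well, amplicon) the read depth is negative-binomial with the given
    mean and dispersion; each read carries the sampled allele of the well's
    individual at the SNP offset, the panel forward primer as its 5' prefix,
    and iid substitution errors. ``dropout`` maps marker names to a
    probability that a (well, amplicon) yields zero reads. Blank wells draw
    Poisson(``blank_depth``) stray reads. Deterministic under the seed.
    """
    cfg = truth.config
    depth_mean = cfg.depth_mean if depth_mean is None else depth_mean
    disp = cfg.depth_dispersion if depth_dispersion is None else depth_dispersion
    err = cfg.error_rate if error_rate is None else error_rate
    rng = np.random.default_rng(seed)
    sample_map = sample_to_progeny or {s: s for s in truth.genotypes.samples}
    progeny_row = {s: i for i, s in enumerate(truth.genotypes.samples)}
    site_col = {s.pos: j for j, s in enumerate(truth.genotypes.sites)}

    reads: list[IndexedRead] = []
    n = 0
    p_nb = disp / (disp + depth_mean)
    for well in sorted(layout.assignments):
        sample = layout.assignments[well]
        i1, i2 = layout.index_pair(well)
        for pair in panel.pairs:
            t = pair.template
            if sample is None:
                depth = int(rng.poisson(blank_depth))
                call = HOM_REF
            else:
                depth = int(rng.negative_binomial(disp, p_nb))
                if dropout and rng.random() < dropout.get(pair.site.name, 0.0):
                    depth = 0
                if cfg.missing_prob > 0 and rng.random() < cfg.missing_prob:
                    depth = 0
                row = progeny_row[sample_map[sample]]
                call = int(truth.genotypes.calls[row, site_col[pair.site.pos]])
            interior = t.a1_rseq[len(pair.rev_seq):]
            for _ in range(depth):
                if call == HET:
                    allele = t.site.alt_allele if rng.random() < 0.5 else t.site.ref_allele
                elif call == HOM_REF:
                    allele = t.site.ref_allele
                else:
                    allele = t.site.alt_allele
                amplicon = pair.fwd_seq + allele + t.a1_rseq[:len(pair.rev_seq)]
                seq = (amplicon + interior + "A" * read_len)[:read_len]
                chars = list(seq)
                for k in range(len(chars)):
                    if err > 0 and rng.random() < err:
                        chars[k] = str(rng.choice([b for b in "ACGT" if b != chars[k]]))
                n += 1
                reads.append(
                    IndexedRead(
                        name=f"amp{n}",
                        seq="".join(chars),
                        qual="I" * read_len,
                        row_index=i1,
                        col_index=i2,
                    )
                )
    return reads


def write_fastq(reads: list[IndexedRead], path: str) -> None:
    """Write indexed reads as FASTQ with the dual index pair in the header
    (``<name> 1:N:0:<row_index>+<col_index>``)."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name} 1:N:0:{r.row_index}+{r.col_index}\n{r.seq}\n+\n{r.qual}\n")
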