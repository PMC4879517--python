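"""Marker-trait co-segregation statistics and marker-assisted-selection calls.

Per family (and pooled over families sharing a segregation pattern) each
marker is tested for co-segregation with the trait by a one-way ANOVA across
genotype classes; marker R^2 = SS_between / SS_total is the fraction of
phenotypic variance the marker explains. Minor allele frequency is checked
for segregation distortion against the 0.25 expected in a pseudo-testcross
(het x hom) family by an exact binomial test. Parental genotypes phase each
marker (which allele travels with the favorable trait allele), pairwise
marker r^2 dendrograms summarize transferability, and the decision table
votes per seedling across the phased panel.

Undefined statistics (monomorphic marker, constant phenotype) print as the
literal token ``NaN``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, to_tree
from scipy.spatial.distance import squareform

from .io import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix, SnpSite
from .haploblock import ld_r2_p

EXPECTED_TESTCROSS_MAF = 0.25


@dataclass
class AssociationResult:
    marker: SnpSite
    family: str  # family label or "pooled"
    p_value: float  # NaN when no association detectable
    marker_r2: float
    maf: float
    n: int

    def p_token(self) -> str:
        return "NaN" if math.isnan(self.p_value) else f"{self.p_value:.2E}"


def _anova(dosages: np.ndarray, phenotypes: np.ndarray) -> tuple[float, float]:
    """One-way ANOVA of phenotype across genotype classes.

    Returns (p_value, r2) with r2 = SS_between / SS_total; fewer than two
    classes or zero total sum of squares gives (NaN, 0) — no association
    detectable.
    """
    classes = [phenotypes[dosages == g] for g in np.unique(dosages)]
    classes = [c for c in classes if len(c) > 0]
    if len(classes) < 2:
        return (float("nan"), 0.0)
    grand = np.concatenate(classes)
    ss_total = float(((grand - grand.mean()) ** 2).sum())
    if ss_total == 0:
        return (float("nan"), 0.0)
    ss_between = float(sum(len(c) * (c.mean() - grand.mean()) ** 2 for c in classes))
    r2 = ss_between / ss_total
    df_b = len(classes) - 1
    df_w = len(grand) - len(classes)
    if df_w <= 0 or ss_total - ss_between <= 0:
        # perfect separation: R2 = 1, P underflows to 0
        return (0.0, min(r2, 1.0))
    f = (ss_between / df_b) / ((ss_total - ss_between) / df_w)
    return (float(stats.f.sf(f, df_b, df_w)), r2)


def marker_maf(calls: np.ndarray) -> float:
    """Minor allele frequency among non-missing diploid calls."""
    valid = calls[calls != MISSING]
    if valid.size == 0:
        return float("nan")
    alt = (valid == HET).sum() + 2 * (valid == HOM_ALT).sum()
    freq = alt / (2 * valid.size)
    return float(min(freq, 1 - freq))


def anova_association(
    genotypes: GenotypeMatrix,
    phenotype: dict[str, float],
    families: dict[str, str],
    pool_groups: dict[str, list[str]] | None = None,
) -> list[AssociationResult]:
    """Per-family and pooled marker-trait association.

    ``families`` maps sample id to family label; ``pool_groups`` maps a pool
    label to the families it concatenates (families sharing a segregation
    pattern; no family covariate). Samples missing a phenotype are excluded.
    """
    usable = [
        i for i, s in enumerate(genotypes.samples)
        if s in phenotype and phenotype[s] is not None and not math.isnan(phenotype[s])
    ]
    if not usable:
        raise ValueError("no sample has both genotype and phenotype")

    groups: dict[str, list[int]] = {}
    for i in usable:
        fam = families.get(genotypes.samples[i])
        if fam is not None:
            groups.setdefault(fam, []).append(i)
    for pool, members in (pool_groups or {}).items():
        idx = [i for fam in members for i in groups.get(fam, [])]
        if idx:
            groups[pool] = idx

    results: list[AssociationResult] = []
    for fam, idx in groups.items():
        pheno = np.array([phenotype[genotypes.samples[i]] for i in idx], dtype=float)
        for j, site in enumerate(genotypes.sites):
            calls = genotypes.calls[idx, j]
            mask = calls != MISSING
            if mask.sum() < 2:
                results.append(AssociationResult(site, fam, float("nan"), 0.0,
                                                 marker_maf(calls), int(mask.sum())))
                continue
            p, r2 = _anova(calls[mask].astype(float), pheno[mask])
            results.append(AssociationResult(site, fam, p, r2, marker_maf(calls), int(mask.sum())))
    return results


def association_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Long-format association table; P-values print the literal NaN token
    when no association was detectable."""
    return pd.DataFrame(
        [
            {
                "marker": r.marker.name,
                "chrom": r.marker.chrom,
                "pos": r.marker.pos,
                "family": r.family,
                "p_value": r.p_token(),
                "marker_r2": round(r.marker_r2, 4),
                "maf": round(r.maf, 4) if not math.isnan(r.maf) else "NaN",
                "n": r.n,
            }
            for r in results
        ]
    )


def maf_and_distortion(
    calls: np.ndarray, expected: float = EXPECTED_TESTCROSS_MAF, alpha: float = 0.05
) -> tuple[float, bool, float]:
    """MAF plus a segregation-distortion flag from an exact binomial test of
    the minor-allele count against the expected frequency (0.25 for a
    pseudo-testcross marker).

    Returns (maf, distorted, p_value).
    """
    valid = calls[calls != MISSING]
    if valid.size == 0:
        return (float("nan"), False, float("nan"))
    alt = int((valid == HET).sum() + 2 * (valid == HOM_ALT).sum())
    n_alleles = 2 * int(valid.size)
    minor = min(alt, n_alleles - alt)
    maf = minor / n_alleles
    p = float(stats.binomtest(minor, n_alleles, expected).pvalue)
    return (float(maf), p < alpha, p)


@dataclass
class PhaseAssignment:
    marker: SnpSite
    favorable_allele: str | None  # None when out of phase / unphasable
    source_parent: str | None
    status: str  # "phased" | "out_of_phase" | "unphasable"


def phase_markers(
    parent_calls: dict[str, np.ndarray],
    sites: list[SnpSite],
    donor: str,
    progeny: GenotypeMatrix,
    phenotype: dict[str, float],
    favorable_high: bool = True,
) -> list[PhaseAssignment]:
    """Phase each marker: which allele co-segregates with the favorable
    trait state.

    The candidate favorable allele is the allele the trait-donor parent
    carries at higher dosage than the other parent; progeny confirm it when
    carriers of that allele have the more favorable phenotype mean. Markers
    where the progeny signal contradicts the parental candidate are flagged
    ``out_of_phase``; markers with no resolvable candidate (both parents
    identical) and no progeny signal are ``unphasable``.
    """
    parents = list(parent_calls)
    if donor not in parents or len(parents) < 2:
        raise ValueError("need calls for both parents incl. the trait donor")
    other = next(p for p in parents if p != donor)
    out: list[PhaseAssignment] = []
    for j, site in enumerate(sites):
        d_call = int(parent_calls[donor][j])
        o_call = int(parent_calls[other][j])
        candidate: str | None = None
        if d_call != MISSING and o_call != MISSING and d_call != o_call:
            candidate = site.alt_allele if d_call > o_call else site.ref_allele

        # progeny check: phenotype mean of carriers vs non-carriers of alt
        jj = progeny.site_index(site.chrom, site.pos)
        calls = progeny.calls[:, jj]
        ph = np.array(
            [phenotype.get(s, np.nan) for s in progeny.samples], dtype=float
        )
        mask = (calls != MISSING) & ~np.isnan(ph)
        carriers = ph[mask & (calls > HOM_REF)]
        noncarr = ph[mask & (calls == HOM_REF)]
        progeny_fav: str | None = None
        if len(carriers) >= 2 and len(noncarr) >= 2 and carriers.mean() != noncarr.mean():
            alt_is_fav = (carriers.mean() > noncarr.mean()) == favorable_high
            progeny_fav = site.alt_allele if alt_is_fav else site.ref_allele

        if candidate is None and progeny_fav is None:
            out.append(PhaseAssignment(site, None, None, "unphasable"))
        elif candidate is None:
            out.append(PhaseAssignment(site, progeny_fav, donor, "phased"))
        elif progeny_fav is None or progeny_fav == candidate:
            out.append(PhaseAssignment(site, candidate, donor, "phased"))
        else:
            out.append(PhaseAssignment(site, None, donor, "out_of_phase"))
    return out


@dataclass
class MarkerCorrelationMatrix:
    markers: list[str]
    r2: np.ndarray  # symmetric, diagonal 1 for polymorphic markers
    linkage: np.ndarray  # scipy linkage matrix, average linkage on 1 - r2

    def newick(self) -> str:
        tree = to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.markers[node.id]
            left, right = walk(node.left), walk(node.right)
            return (
                f"({left}:{node.dist - node.left.dist:.6g},"
                f"{right}:{node.dist - node.right.dist:.6g})"
            )

        return walk(tree) + ";"


def marker_dendrogram(genotypes: GenotypeMatrix) -> MarkerCorrelationMatrix:
    """Pairwise dosage r^2 among markers (pairwise-complete) and the
    average-linkage dendrogram on distance 1 - r^2; undefined pairs get
    distance 1."""
    dose = genotypes.dosage()
    poly = [j for j in range(genotypes.n_sites)
            if np.nanstd(dose[:, j]) > 0]
    if len(poly) < 2:
        raise ValueError("need at least 2 polymorphic markers")
    names = [genotypes.sites[j].name for j in poly]
    k = len(poly)
    r2 = np.eye(k)
    for a in range(k):
        for b in range(a + 1, k):
            try:
                val, _, _ = ld_r2_p(dose[:, poly[a]], dose[:, poly[b]])
            except ValueError:
                val = float("nan")
            r2[a, b] = r2[b, a] = val
    dist = 1.0 - np.where(np.isnan(r2), 0.0, r2)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, 1.0)
    linkage = average(squareform(dist, checks=False))
    return MarkerCorrelationMatrix(names, r2, linkage)


def marker_density(positions: list[int]) -> int:
    """Average marker density in kb per marker: span / count / 1000, rounded
    to the nearest integer kb. A single marker has no span (density 0)."""
    if not positions:
        raise ValueError("no marker positions given")
    if len(positions) == 1:
        return 0
    span = max(positions) - min(positions)
    # round half up, so a 0.5-kb density reports as 1 kb
    return int(math.floor(span / len(positions) / 1000 + 0.5))


@dataclass
class MasDecision:
    sample: str
    trait: str
    vote: float | None  # favorable-dosage vote in [0, 1]; None = uncallable
    keep: bool | None
    n_markers: int


def mas_report(
    associations: list[AssociationResult],
    phases: list[PhaseAssignment],
    genotypes: GenotypeMatrix,
    trait: str = "trait",
    vote_threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-seedling decision table for one trait.

    Each phased marker contributes its seedling favorable-allele dosage
    (0, 1/2 or 1) weighted by the marker's R^2 (pooled result preferred);
    the vote is the weighted mean and the keep call compares it to
    ``vote_threshold``. Seedlings with no non-missing phased marker, or
    traits with no phased marker, are uncallable.
    """
    r2_by_marker: dict[str, float] = {}
    for r in associations:
        key = r.marker.name
        if r.family == "pooled" or key not in r2_by_marker:
            if not math.isnan(r.marker_r2):
                r2_by_marker[key] = r.marker_r2
    phased = [p for p in phases if p.status == "phased" and p.favorable_allele is not None]

    rows = []
    for i, sample in enumerate(genotypes.samples):
        if not phased:
            rows.append(MasDecision(sample, trait, None, None, 0))
            continue
        wsum = 0.0
        vsum = 0.0
        used = 0
        for p in phased:
            j = genotypes.site_index(p.marker.chrom, p.marker.pos)
            call = int(genotypes.calls[i, j])
            if call == MISSING:
                continue
            alt_dosage = call / 2.0
            fav = alt_dosage if p.favorable_allele == p.marker.alt_allele else 1 - alt_dosage
            w = r2_by_marker.get(p.marker.name, 0.0) or 1e-6
            wsum += w
            vsum += w * fav
            used += 1
        if used == 0:
            rows.append(MasDecision(sample, trait, None, None, 0))
        else:
            vote = vsum / wsum
            rows.append(MasDecision(sample, trait, vote, vote >= vote_threshold, used))
    return pd.DataFrame(
        [
            {
                "sample": d.sample,
                "trait": d.trait,
                "vote": d.vote if d.vote is not None else "NaN",
                "keep": d.keep if d.keep is not None else "uncallable",
                "n_markers": d.n_markers,
            }
            for d in rows
        ]
    )


def pyramiding_view(reports: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Join per-trait decision tables into one spreadsheet: a seedling is
    selected when it is kept for every trait (multi-trait pyramiding in a
    single run)."""
    merged: pd.DataFrame | None = None
    for trait, rep in reports.items():
        cols = rep[["sample", "vote", "keep"]].rename(
            columns={"vote": f"{trait}_vote", "keep": f"{trait}_keep"}
        )
        merged = cols if merged is None else merged.merge(cols, on="sample")
    assert merged is not None
    keep_cols = [c for c in merged.columns if c.endswith("_keep")]
    merged["select"] = merged[keep_cols].apply(
        lambda row: all(v is True for v in row), axis=1
    )
    return merged
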