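"""Co-segregation ANOVA, MAF/distortion, phasing, dendrograms, MAS calls."""

import math

import numpy as np
import pytest

from ampseq import (
    GenotypeMatrix,
    SnpSite,
    anova_association,
    association_frame,
    maf_and_distortion,
    marker_dendrogram,
    marker_density,
    mas_report,
    phase_markers,
    pyramiding_view,
)
from ampseq.io import HET, HOM_ALT, HOM_REF, MISSING
from ampseq.mas import _anova
from ampseq.published import load_panel_summary


def matrix(calls, positions=None, chrom="chr1"):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    positions = positions or [100 * (j + 1) for j in range(m)]
    sites = [SnpSite(chrom, p, "A", "G") for p in positions]
    depths = np.where(calls == MISSING, 0, 30).astype(np.int32)
    return GenotypeMatrix([f"S{i}" for i in range(n)], sites, calls, depths)


def anova_permutation_oracle(dosages, phenos, n_perm=20000, seed=0):
    """Monte-Carlo P for the between-class variance ratio."""
    rng = np.random.default_rng(seed)
    _, r2_obs = _anova(dosages, phenos)
    count = 0
    for _ in range(n_perm):
        _, r2 = _anova(dosages, rng.permutation(phenos))
        if r2 >= r2_obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


class TestAnova:
    def test_two_class_hand_example(self):
        # classes {1,2} vs {3,4}: F = 8, P ~ 0.1056, R2 = 0.8
        p, r2 = _anova(np.array([0, 0, 1, 1.0]), np.array([1, 2, 3, 4.0]))
        assert r2 == pytest.approx(0.8)
        assert p == pytest.approx(0.10557, abs=1e-4)

    def test_matches_permutation_oracle_on_small_input(self):
        rng = np.random.default_rng(1)
        dosages = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2, 0, 1, 2], dtype=float)
        phenos = dosages + rng.normal(0, 1.0, 12)
        p, _ = _anova(dosages, phenos)
        p_perm = anova_permutation_oracle(dosages, phenos)
        assert abs(p - p_perm) < 0.03  # Monte-Carlo error

    def test_perfect_determination_gives_r2_one(self):
        p, r2 = _anova(np.array([0, 0, 1, 1.0]), np.array([5, 5, 9, 9.0]))
        assert r2 == pytest.approx(1.0)
        assert p == 0.0

    def test_single_class_and_constant_phenotype_are_nan(self):
        assert math.isnan(_anova(np.array([1, 1, 1.0]), np.array([1, 2, 3.0]))[0])
        assert math.isnan(_anova(np.array([0, 1, 2.0]), np.array([4, 4, 4.0]))[0])

    def test_r2_one_iff_constant_within_classes(self):
        p, r2 = _anova(np.array([0, 0, 1, 1.0]), np.array([5, 5.1, 9, 9.0]))
        assert r2 < 1.0


class TestAssociation:
    def test_per_family_and_pooled(self):
        calls = [[HET], [HET], [HOM_REF], [HOM_REF]] * 4
        gm = matrix(calls)
        pheno = {s: float(gm.calls[i, 0] == HET) + (0.1 if i % 2 else 0.0)
                 for i, s in enumerate(gm.samples)}
        fams = {s: ("A" if i < 8 else "B") for i, s in enumerate(gm.samples)}
        res = anova_association(gm, pheno, fams, {"pooled": ["A", "B"]})
        assert {r.family for r in res} == {"A", "B", "pooled"}
        pooled = next(r for r in res if r.family == "pooled")
        assert pooled.n == 16

    def test_pooling_does_not_change_per_family_results(self):
        rng = np.random.default_rng(2)
        calls = rng.integers(0, 3, size=(30, 3))
        gm = matrix(calls)
        pheno = {s: float(rng.normal()) for s in gm.samples}
        fams = {s: ("A" if i < 15 else "B") for i, s in enumerate(gm.samples)}
        solo = anova_association(gm, pheno, fams)
        both = anova_association(gm, pheno, fams, {"pooled": ["A", "B"]})
        solo_map = {(r.marker.name, r.family): (r.p_value, r.marker_r2) for r in solo}
        for r in both:
            if r.family in {"A", "B"}:
                want = solo_map[(r.marker.name, r.family)]
                assert (r.p_value == want[0]) or (
                    math.isnan(r.p_value) and math.isnan(want[0])
                )

    def test_monomorphic_marker_prints_nan_token(self):
        gm = matrix([[HOM_REF]] * 6)
        pheno = {s: float(i) for i, s in enumerate(gm.samples)}
        res = anova_association(gm, pheno, {s: "F" for s in gm.samples})
        frame = association_frame(res)
        assert frame.iloc[0]["p_value"] == "NaN"
        assert res[0].marker_r2 == 0.0


def binom_pvalue_oracle(k, n, p):
    """Two-sided exact binomial P by full enumeration (minimum-likelihood)."""
    from math import comb

    pk = lambda i: comb(n, i) * p ** i * (1 - p) ** (n - i)
    obs = pk(k)
    return sum(pk(i) for i in range(n + 1) if pk(i) <= obs * (1 + 1e-9))


class TestMafDistortion:
    def test_pseudo_testcross_expectation(self):
        calls = np.array([HET] * 50 + [HOM_REF] * 50, dtype=np.int8)
        maf, distorted, p = maf_and_distortion(calls)
        assert maf == pytest.approx(0.25)
        assert not distorted

    def test_fixed_marker_has_zero_maf(self):
        maf, distorted, _ = maf_and_distortion(np.array([HOM_REF] * 20, dtype=np.int8))
        assert maf == 0.0

    def test_distorted_marker_flagged_with_exact_binomial(self):
        calls = np.array([HET] * 90 + [HOM_REF] * 10, dtype=np.int8)
        maf, distorted, p = maf_and_distortion(calls)
        assert maf == pytest.approx(0.45)
        assert distorted
        assert p == pytest.approx(binom_pvalue_oracle(90, 200, 0.25), rel=1e-6)


class TestPhasing:
    def _progeny(self, n=40, seed=3):
        rng = np.random.default_rng(seed)
        calls = rng.integers(0, 2, size=(n, 1)).astype(np.int8)  # het/hom_ref
        gm = matrix(calls, positions=[500])
        # alt carriers (het) are resistant (higher score)
        pheno = {s: 2.0 if gm.calls[i, 0] == HET else 0.0 for i, s in enumerate(gm.samples)}
        return gm, pheno

    def test_donor_het_allele_with_resistant_progeny(self):
        gm, pheno = self._progeny()
        parents = {"donor": np.array([HET]), "other": np.array([HOM_REF])}
        (pa,) = phase_markers(parents, gm.sites, "donor", gm, pheno)
        assert pa.status == "phased"
        assert pa.favorable_allele == gm.sites[0].alt_allele

    def test_contradictory_progeny_signal_flags_out_of_phase(self):
        gm, pheno = self._progeny()
        flipped = {s: 2.0 - v for s, v in pheno.items()}
        parents = {"donor": np.array([HET]), "other": np.array([HOM_REF])}
        (pa,) = phase_markers(parents, gm.sites, "donor", gm, flipped)
        assert pa.status == "out_of_phase"

    def test_uninformative_configuration_is_unphasable(self):
        gm = matrix([[HET]] * 4)
        pheno = {s: 1.0 for s in gm.samples}  # no progeny signal
        parents = {"donor": np.array([HET]), "other": np.array([HET])}
        (pa,) = phase_markers(parents, gm.sites, "donor", gm, pheno)
        assert pa.status == "unphasable"


class TestDendrogram:
    def test_duplicated_markers_merge_at_height_zero(self):
        rng = np.random.default_rng(4)
        col = rng.integers(0, 3, 40)
        gm = matrix(np.column_stack([col, col, rng.integers(0, 3, 40)]))
        mcm = marker_dendrogram(gm)
        assert mcm.r2[0, 1] == pytest.approx(1.0)
        assert mcm.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_independent_markers_have_low_r2(self):
        rng = np.random.default_rng(5)
        gm = matrix(rng.integers(0, 3, size=(500, 2)))
        mcm = marker_dendrogram(gm)
        assert mcm.r2[0, 1] < 0.05

    def test_planted_structure_merges_correlated_pair_first(self):
        rng = np.random.default_rng(6)
        a = rng.integers(0, 3, 200)
        b = a.copy()  # r2 = 1 with a
        c = rng.integers(0, 3, 200)
        gm = matrix(np.column_stack([a, b, c]))
        mcm = marker_dendrogram(gm)
        first = set(mcm.linkage[0, :2].astype(int))
        assert first == {0, 1}
        assert mcm.newick().count(",") == 2

    def test_heights_within_unit_interval(self):
        rng = np.random.default_rng(7)
        gm = matrix(rng.integers(0, 3, size=(100, 6)))
        mcm = marker_dendrogram(gm)
        assert np.all(mcm.linkage[:, 2] >= 0) and np.all(mcm.linkage[:, 2] <= 1 + 1e-12)

    def test_too_few_polymorphic_markers_is_error(self):
        gm = matrix([[HOM_REF, HET], [HOM_REF, HOM_REF], [HOM_REF, HET]])
        with pytest.raises(ValueError):
            marker_dendrogram(gm)


class TestMarkerDensity:
    @pytest.mark.parametrize(
        "trait,expected",
        [("flower_sex", 55), ("pm_resistance", 218), ("anthocyanin", 133)],
    )
    def test_published_panels(self, trait, expected):
        df = load_panel_summary(trait)
        assert marker_density(df["pos"].tolist()) == expected

    def test_half_kb_rounds_up(self):
        assert marker_density([1000, 2000]) == 1  # span 1000 / 2 markers

    def test_single_marker_density_zero(self):
        assert marker_density([123]) == 0

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            marker_density([])


class TestMasReport:
    def _setup(self):
        from ampseq.mas import AssociationResult, PhaseAssignment

        gm = matrix([[HOM_ALT, HOM_ALT], [MISSING, MISSING], [HOM_REF, HOM_REF]])
        assoc = [AssociationResult(s, "pooled", 1e-10, 0.9, 0.25, 3) for s in gm.sites]
        phases = [PhaseAssignment(s, s.alt_allele, "donor", "phased") for s in gm.sites]
        return gm, assoc, phases

    def test_all_favorable_keeps_with_full_vote(self):
        gm, assoc, phases = self._setup()
        rep = mas_report(assoc, phases, gm)
        row = rep[rep["sample"] == "S0"].iloc[0]
        assert row.vote == pytest.approx(1.0) and row.keep is True

    def test_all_missing_is_uncallable(self):
        gm, assoc, phases = self._setup()
        rep = mas_report(assoc, phases, gm)
        row = rep[rep["sample"] == "S1"].iloc[0]
        assert row.keep == "uncallable"

    def test_no_phased_marker_is_uncallable(self):
        gm, assoc, _ = self._setup()
        rep = mas_report(assoc, [], gm)
        assert set(rep["keep"]) == {"uncallable"}

    def test_pyramiding_selects_joint_keepers(self):
        gm, assoc, phases = self._setup()
        rep = mas_report(assoc, phases, gm)
        merged = pyramiding_view({"sex": rep, "pm": rep})
        assert bool(merged[merged["sample"] == "S0"].iloc[0]["select"]) is True
        assert bool(merged[merged["sample"] == "S2"].iloc[0]["select"]) is False
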