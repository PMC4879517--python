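"""Phase/effect estimation, haploblock bounds and anchor-LD retrieval."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ampseq import (
    FamilyConfig,
    GenotypeMatrix,
    Haploblock,
    LocusSpec,
    MarkerEffect,
    PhasedMarker,
    SnpSite,
    define_haploblock,
    estimate_marker_effects,
    ld_r2_p,
    retrieve_ld_snps,
    simulate_family,
)
from ampseq.io import HET, HOM_REF


def site(pos, ref="A", alt="G", chrom="chr2"):
    return SnpSite(chrom, pos, ref, alt)


def matrix_from_dosages(dosages, positions=None):
    """samples x sites int dosage array (-1 = missing) -> GenotypeMatrix."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    positions = positions or [100 * (j + 1) for j in range(m)]
    sites = [site(p) for p in positions]
    depths = np.where(dosages < 0, 0, 30).astype(np.int32)
    return GenotypeMatrix([f"S{i}" for i in range(n)], sites, dosages, depths)


class TestMarkerEffects:
    def _setup(self, phenos_by_call):
        """Progeny het/hom_ref with given phenotypes; marker phased alt|ref."""
        calls = [[HET]] * len(phenos_by_call[HET]) + [[HOM_REF]] * len(phenos_by_call[HOM_REF])
        gm = matrix_from_dosages(calls, positions=[500])
        pheno = {}
        i = 0
        for v in phenos_by_call[HET]:
            pheno[f"S{i}"] = v
            i += 1
        for v in phenos_by_call[HOM_REF]:
            pheno[f"S{i}"] = v
            i += 1
        pm = PhasedMarker(gm.sites[0], "LG2", 10.0, {"P1": ("G", "A")})  # hap1 = alt
        return pm, gm, pheno

    def test_mean_difference_between_classes(self):
        pm, gm, pheno = self._setup({HET: [2.0, 2.0], HOM_REF: [0.0, 0.0]})
        (eff,) = estimate_marker_effects([pm], gm, pheno, parent="P1")
        assert eff.effect == pytest.approx(2.0)
        assert (eff.n1, eff.n2) == (2, 2)

    def test_identical_phenotypes_give_zero_effect(self):
        pm, gm, pheno = self._setup({HET: [1.0, 1.0, 1.0], HOM_REF: [1.0, 1.0]})
        (eff,) = estimate_marker_effects([pm], gm, pheno, parent="P1")
        assert eff.effect == pytest.approx(0.0)

    def test_small_class_gives_undefined_effect(self):
        pm, gm, pheno = self._setup({HET: [1.0], HOM_REF: [0.0, 0.0]})
        (eff,) = estimate_marker_effects([pm], gm, pheno, parent="P1")
        assert eff.effect is None

    def test_no_phenotyped_progeny_is_error(self):
        pm, gm, _ = self._setup({HET: [1.0], HOM_REF: [0.0]})
        with pytest.raises(ValueError):
            estimate_marker_effects([pm], gm, {}, parent="P1")

    def test_linked_marker_recovers_planted_effect(self):
        cfg = FamilyConfig(
            n_progeny=40,
            marker_positions=[1_000_000],
            loci=[LocusSpec(pos=1_000_000, qtl_r2=0.9, effect=1.0)],
            seed=5,
        )
        truth = simulate_family(cfg)
        gm = truth.genotypes
        pm = PhasedMarker(gm.sites[0], "LG", 0.0, {"P1": (gm.sites[0].alt_allele, gm.sites[0].ref_allele)})
        (eff,) = estimate_marker_effects([pm], gm, truth.phenotypes, parent="P1")
        # fully linked marker: effect ~ planted +1 within 2 SE
        se = np.std(list(truth.phenotypes.values())) / np.sqrt(10)
        assert abs(eff.effect - 1.0) < 2 * se


class TestDefineHaploblock:
    def _effects(self, abs_effects, signs=None):
        out = []
        for j, e in enumerate(abs_effects):
            s = (signs or [1] * len(abs_effects))[j]
            out.append(MarkerEffect(site(100 * (j + 1)), s * e if e is not None else None, 10, 10))
        return out

    def test_uniform_effects_span_everything(self):
        effects = self._effects([0.5] * 5)
        block = define_haploblock(effects, effects[2].site, tau=0.8)
        assert (block.start_pos, block.end_pos) == (100, 500)

    def test_similarity_threshold_bounds_block(self):
        effects = self._effects([0.1, 0.9, 1.0, 0.85, 0.2])
        block = define_haploblock(effects, effects[2].site, tau=0.8)
        assert (block.start_pos, block.end_pos) == (200, 400)

    def test_undefined_anchor_effect_is_error(self):
        effects = self._effects([0.5, None, 0.5])
        with pytest.raises(ValueError):
            define_haploblock(effects, effects[1].site)

    def test_emits_test_marker_coordinates(self):
        effects = self._effects([0.9, 1.0, 0.95], signs=[1, -1, 1])
        block = define_haploblock(effects, effects[1].site, tau=0.8)
        tm = block.to_test_marker()
        assert (tm.start_pos, tm.anchor_pos, tm.end_pos) == (100, 200, 300)


def pearson_r2_oracle(a, b):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    r = np.sum((a - a.mean()) * (b - b.mean())) / np.sqrt(
        np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2)
    )
    return r * r


class TestLdR2P:
    def test_identical_vectors_give_r2_one(self):
        a = np.tile([0, 1, 2, 1], 10)
        r2, p, n = ld_r2_p(a, a)
        assert r2 == pytest.approx(1.0)
        assert n == 40

    def test_matches_direct_pearson_and_chi2(self):
        from scipy.stats import chi2

        a = np.array([0, 0, 1, 1, 2, 2], float)
        b = np.array([0, 1, 0, 1, 2, 2], float)
        r2, p, n = ld_r2_p(a, b)
        assert r2 == pytest.approx(pearson_r2_oracle(a, b), abs=1e-12)
        assert p == pytest.approx(float(chi2.sf(6 * r2, 1)), abs=1e-12)

    def test_monomorphic_partner_is_nan(self):
        r2, p, n = ld_r2_p([0, 1, 2, 1], [1, 1, 1, 1])
        assert math.isnan(r2) and math.isnan(p)

    def test_missing_excluded_pairwise(self):
        a = [0, 1, 2, np.nan, 2]
        b = [0, 1, 2, 2, np.nan]
        r2, p, n = ld_r2_p(a, b)
        assert n == 3 and r2 == pytest.approx(1.0)

    def test_permutation_p_close_to_chi2_for_moderate_n(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 3, 25).astype(float)
        b = rng.integers(0, 3, 25).astype(float)  # independent: null is true
        _, p_asym, _ = ld_r2_p(a, b)
        _, p_perm, _ = ld_r2_p(a, b, exact=True, rng=np.random.default_rng(3))
        assert abs(p_perm - p_asym) < 0.15

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 2), min_size=6, max_size=40), st.data())
    def test_symmetry_and_allele_relabeling_invariance(self, a, data):
        b = data.draw(st.lists(st.integers(0, 2), min_size=len(a), max_size=len(a)))
        a, b = np.array(a, float), np.array(b, float)
        if np.std(a) == 0 or np.std(b) == 0:
            return
        r2_ab, _, _ = ld_r2_p(a, b)
        r2_ba, _, _ = ld_r2_p(b, a)
        r2_flip, _, _ = ld_r2_p(2 - a, b)
        assert r2_ab == pytest.approx(r2_ba, abs=1e-12)
        assert r2_ab == pytest.approx(r2_flip, abs=1e-12)


class TestRetrieveLdSnps:
    def _planted(self, n=200, n_linked=30, n_unlinked=30, seed=9):
        rng = np.random.default_rng(seed)
        anchor = rng.integers(0, 2, n)  # het/hom testcross dosages
        cols = [anchor]
        positions = [1000]
        for k in range(n_linked):
            cols.append(anchor)  # perfect LD
            positions.append(2000 + k * 100)
        for k in range(n_unlinked):
            cols.append(rng.integers(0, 2, n))
            positions.append(10_000 + k * 100)
        gm = matrix_from_dosages(np.array(cols).T, positions=positions)
        block = Haploblock("chr2", 1, 20_000, gm.sites[0])
        return gm, block

    def test_exact_recovery_of_planted_linked_sites(self):
        gm, block = self._planted()
        records = retrieve_ld_snps(gm, block)
        kept = {r.site.pos for r in records} - {block.anchor.pos}
        assert kept == {2000 + k * 100 for k in range(30)}

    def test_output_confined_to_block_and_sorted(self):
        gm, block = self._planted()
        records = retrieve_ld_snps(gm, block)
        positions = [r.site.pos for r in records]
        assert positions == sorted(positions)
        assert all(block.start_pos <= p <= block.end_pos for p in positions)

    def test_lowering_p_cutoff_never_adds_sites(self):
        gm, block = self._planted()
        loose = {r.site.pos for r in retrieve_ld_snps(gm, block, p_cutoff=1e-10)}
        tight = {r.site.pos for r in retrieve_ld_snps(gm, block, p_cutoff=1e-40)}
        assert tight <= loose

    def test_missing_data_filter(self):
        gm, block = self._planted()
        gm.calls[: int(0.2 * gm.n_samples), 5] = -1  # 20% missing at one linked site
        gm.depths[: int(0.2 * gm.n_samples), 5] = 0
        records = retrieve_ld_snps(gm, block, max_missing=0.05)
        assert gm.sites[5].pos not in {r.site.pos for r in records}

    def test_absent_anchor_is_error(self):
        gm, block = self._planted()
        bad = Haploblock("chr2", 1, 20_000, site(99, "A", "G"))
        with pytest.raises(ValueError):
            retrieve_ld_snps(gm, bad)


def test_effect_sign_tracks_planted_phase_for_tightly_linked_markers():
    """Markers in strong LD with the causal site show the planted effect sign."""
    positions = list(np.linspace(900_000, 1_100_000, 10).astype(int))
    cfg = FamilyConfig(
        n_progeny=300,
        marker_positions=positions,
        loci=[LocusSpec(pos=1_000_000, qtl_r2=0.8, effect=1.0)],
        seed=21,
    )
    truth = simulate_family(cfg)
    gm = truth.genotypes
    causal = truth.causal_inherited_hap1[1_000_000].astype(float)
    phased = [
        PhasedMarker(s, "LG", 0.0, {"P1": (s.alt_allele, s.ref_allele)}) for s in gm.sites
    ]
    effects = estimate_marker_effects(phased, gm, truth.phenotypes, parent="P1")
    checked = agree = 0
    for j, eff in enumerate(effects):
        r2, _, _ = ld_r2_p(gm.dosage()[:, j], causal)
        if r2 > 0.8 and eff.effect is not None:
            checked += 1
            agree += eff.effect > 0  # hap1/alt carries the +1 allele
    assert checked >= 3
    assert agree / checked >= 0.95
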