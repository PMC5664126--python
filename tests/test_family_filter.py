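"""Filter cascade: per-stage rules, cross-family intersection, segregation."""

import random

import pytest
from hypothesis import given, strategies as st

from famscreen import (
    Affection,
    Consequence,
    FilterCascadeResult,
    FilterConfig,
    FilterError,
    Individual,
    MissingAfPolicy,
    MissingGenotypePolicy,
    Pedigree,
    SimulationConfig,
    Zygosity,
    apply_consequence_filter,
    apply_frequency_filter,
    cross_family_candidates,
    run_family_cascade,
    segregation_report,
    shared_among_affected,
    simulate_family,
    simulate_panel,
)
from conftest import make_variant

CFG = FilterConfig()


class TestConsequenceFilter:
    @pytest.mark.parametrize(
        "consequence, kept",
        [
            (Consequence.MISSENSE, True),
            (Consequence.NONSENSE, True),
            (Consequence.FRAMESHIFT, True),
            (Consequence.SPLICE_SITE, True),
            (Consequence.SYNONYMOUS, False),
            (Consequence.INTRONIC, False),
            (Consequence.UTR, False),
            (Consequence.OTHER, False),
        ],
    )
    def test_protein_changing_classes(self, consequence, kept):
        v = make_variant(consequence=consequence)
        assert (apply_consequence_filter([v], CFG) == [v]) is kept

    def test_idempotent_and_order_preserving(self):
        vs = [
            make_variant(pos=i, consequence=c)
            for i, c in enumerate(
                [Consequence.MISSENSE, Consequence.SYNONYMOUS, Consequence.NONSENSE], 1
            )
        ]
        once = apply_consequence_filter(vs, CFG)
        assert [v.pos for v in once] == [1, 3]
        assert apply_consequence_filter(once, CFG) == once


class TestFrequencyFilter:
    def test_rare_retained_common_removed(self):
        rare = make_variant(pos=1, panel_af=0.0003)
        common = make_variant(pos=2, panel_af=0.05)
        boundary = make_variant(pos=3, panel_af=0.01)  # strict inequality
        assert apply_frequency_filter([rare, common, boundary], CFG) == [rare]

    def test_missing_af_policy(self):
        novel = make_variant(panel_af=None)
        assert apply_frequency_filter([novel], CFG) == [novel]
        drop = FilterConfig(missing_af_policy=MissingAfPolicy.DROP)
        assert apply_frequency_filter([novel], drop) == []

    def test_bad_threshold_rejected(self):
        with pytest.raises(FilterError):
            FilterConfig(maf_threshold=1.5)


def _family(affections):
    members = [
        Individual(f"m{i}", "FAM", affection=aff) for i, aff in enumerate(affections)
    ]
    return Pedigree("FAM", members)


def _calls(zygosities, key):
    return {(f"m{i}", key): z for i, z in enumerate(zygosities)}


class TestSharedAmongAffected:
    def test_all_affected_het_retained(self):
        v = make_variant()
        fam = _family([Affection.AFFECTED] * 3)
        calls = _calls([Zygosity.HET] * 3, v.key)
        assert shared_among_affected(fam, calls, [v], CFG) == [v]

    def test_one_affected_hom_ref_removes(self):
        v = make_variant()
        fam = _family([Affection.AFFECTED] * 3)
        calls = _calls([Zygosity.HET, Zygosity.HET, Zygosity.HOM_REF], v.key)
        assert shared_among_affected(fam, calls, [v], CFG) == []

    def test_homozygous_carrier_counts_as_carrying(self):
        v = make_variant()
        fam = _family([Affection.AFFECTED])
        calls = _calls([Zygosity.HOM_ALT], v.key)
        assert shared_among_affected(fam, calls, [v], CFG) == [v]

    def test_unknown_and_unaffected_impose_no_constraint(self):
        v = make_variant()
        fam = _family([Affection.AFFECTED, Affection.UNAFFECTED, Affection.UNKNOWN])
        calls = _calls([Zygosity.HET, Zygosity.HOM_REF, Zygosity.HOM_REF], v.key)
        assert shared_among_affected(fam, calls, [v], CFG) == [v]

    def test_missing_genotype_policy(self):
        v = make_variant()
        fam = _family([Affection.AFFECTED, Affection.AFFECTED])
        calls = _calls([Zygosity.HET, Zygosity.MISSING], v.key)
        assert shared_among_affected(fam, calls, [v], CFG) == []
        lenient = FilterConfig(missing_genotype_policy=MissingGenotypePolicy.IGNORE)
        assert shared_among_affected(fam, calls, [v], lenient) == [v]

    def test_no_affected_members_raises(self):
        fam = _family([Affection.UNAFFECTED])
        with pytest.raises(FilterError, match="FAM"):
            shared_among_affected(fam, {}, [make_variant()], CFG)


def _brute_force_cascade(family, variants, calls, cfg):
    """Independent oracle: the cascade as literal set-rule composition."""
    exonic = {
        v.key
        for v in variants
        if v.consequence in (set(cfg.exonic_splicing_classes) | {Consequence.SPLICE_SITE})
    }
    protein = {v.key for v in variants if v.consequence in cfg.protein_changing_classes}
    rare = set()
    for v in variants:
        if v.panel_af is None:
            if cfg.missing_af_policy is MissingAfPolicy.KEEP:
                rare.add(v.key)
        elif v.panel_af < cfg.maf_threshold:
            rare.add(v.key)
    affected = [m for m in family.members if m.affection is Affection.AFFECTED]
    shared = set()
    for v in variants:
        ok = True
        for m in affected:
            z = calls.get((m.id, v.key), Zygosity.MISSING)
            if z is Zygosity.MISSING:
                if cfg.missing_genotype_policy is MissingGenotypePolicy.FAIL_SHARING:
                    ok = False
                    break
            elif z not in (Zygosity.HET, Zygosity.HOM_ALT):
                ok = False
                break
        if ok:
            shared.add(v.key)
    final = {v.key for v in variants} & exonic & protein & rare & shared
    counts = (
        len(variants),
        len(exonic),
        len(protein & exonic),
        len(rare & protein & exonic),
        len(final),
    )
    return counts, final


class TestCascade:
    def test_empty_variant_list_gives_zero_counts(self, make_trio):
        res = run_family_cascade(make_trio(), [], {}, CFG)
        assert res.stage_counts == (0, 0, 0, 0, 0)
        assert res.final_variants == frozenset()

    def test_planted_causal_variant_survives(self):
        cfg = SimulationConfig(seed=3, n_background_variants=200, penetrance=1.0,
                               phenocopy_rate=0.0)
        panel = simulate_panel(cfg)
        ped, calls = simulate_family(cfg, panel, family_id="FAMX")
        res = run_family_cascade(ped, panel.variants, calls, CFG)
        assert panel.causal_key in res.final_variants

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_cascade_equals_brute_force_oracle(self, seed):
        cfg = SimulationConfig(seed=seed, n_background_variants=300, penetrance=1.0,
                               phenocopy_rate=0.05)
        panel = simulate_panel(cfg)
        ped, call_list = simulate_family(cfg, panel, family_id="FAMO")
        calls = {(c.sample_id, c.variant_key): c.zygosity for c in call_list}
        res = run_family_cascade(ped, panel.variants, calls, CFG)
        counts, final = _brute_force_cascade(ped, panel.variants, calls, CFG)
        assert res.stage_counts == counts
        assert res.final_variants == final

    def test_monotone_counts_and_subset_final(self):
        cfg = SimulationConfig(seed=11, n_background_variants=150, penetrance=0.8)
        panel = simulate_panel(cfg)
        ped, calls = simulate_family(cfg, panel, family_id="FAMM")
        res = run_family_cascade(ped, panel.variants, calls, CFG)
        assert all(a >= b for a, b in zip(res.stage_counts, res.stage_counts[1:]))
        assert res.final_variants <= {v.key for v in panel.variants}

    def test_order_independence(self):
        cfg = SimulationConfig(seed=5, n_background_variants=100, penetrance=1.0,
                               phenocopy_rate=0.0)
        panel = simulate_panel(cfg)
        ped, calls = simulate_family(cfg, panel, family_id="FAMP")
        res1 = run_family_cascade(ped, panel.variants, calls, CFG)
        shuffled = list(panel.variants)
        random.Random(42).shuffle(shuffled)
        res2 = run_family_cascade(ped, shuffled, calls, CFG)
        assert res1.stage_counts == res2.stage_counts
        assert res1.final_variants == res2.final_variants

    def test_inconsistent_result_rejected(self):
        with pytest.raises(FilterError):
            FilterCascadeResult("F", stage_counts=(1, 2, 0, 0, 0))
        with pytest.raises(FilterError):
            FilterCascadeResult("F", stage_counts=(2, 1, 1, 1, 1), final_variants=frozenset())


class TestCrossFamilyCandidates:
    @staticmethod
    def _result(fid, keys):
        n = len(keys)
        return FilterCascadeResult(fid, stage_counts=(n,) * 5, final_variants=frozenset(keys))

    def test_gene_shared_by_two_families_is_candidate(self):
        k1 = ("18", 100, "A", "G")
        k2 = ("18", 200, "C", "T")
        k3 = ("3", 50, "G", "A")
        lookup = {k1: "RAB12", k2: "RAB12", k3: "MUC4"}
        cand = cross_family_candidates(
            [self._result("A", [k1]), self._result("C", [k2, k3])], lookup, CFG
        )
        assert cand.shared_genes == ("RAB12",)
        assert cand.gene_families["RAB12"] == frozenset({"A", "C"})

    def test_same_variant_in_both_families(self):
        key = ("18", 8609447, "A", "G")
        cand = cross_family_candidates(
            [self._result("B", [key]), self._result("D", [key])], {key: "MUC4"}, CFG
        )
        assert cand.shared_genes == ("MUC4",)

    def test_disjoint_gene_sets_give_empty_shared(self):
        k1, k2 = ("1", 1, "A", "G"), ("2", 2, "C", "T")
        cand = cross_family_candidates(
            [self._result("A", [k1]), self._result("B", [k2])],
            {k1: "G1", k2: "G2"},
            CFG,
        )
        assert cand.shared_genes == ()
        assert set(cand.gene_families) == {"G1", "G2"}

    def test_variant_missing_from_lookup_raises(self):
        key = ("1", 1, "A", "G")
        with pytest.raises(FilterError, match="missing from the gene lookup"):
            cross_family_candidates([self._result("A", [key])], {}, CFG)

    def test_multi_gene_variant_counts_once_per_gene(self):
        key = ("1", 1, "A", "G")
        cand = cross_family_candidates(
            [self._result("A", [key]), self._result("B", [key])], {key: "G1;G2"}, CFG
        )
        assert cand.shared_genes == ("G1", "G2")


class TestSegregationReport:
    KEY = ("18", 8609447, "A", "G")

    def test_affected_noncarrier_father_is_phenocopy_candidate(self, make_trio):
        fam = make_trio(father_aff=Affection.AFFECTED, mother_aff=Affection.UNKNOWN,
                        child_aff=Affection.AFFECTED)
        calls = {
            ("dad", self.KEY): Zygosity.HOM_REF,
            ("mum", self.KEY): Zygosity.HOM_ALT,
            ("kid", self.KEY): Zygosity.HET,
        }
        rep = segregation_report(self.KEY, fam, calls)
        assert rep.phenocopy_candidates == {"dad"}
        assert rep.reduced_penetrance_carriers == {"mum"}
        assert rep.homozygous_carriers == {"mum"}
        assert rep.status["dad"].value == "-/-"
        assert rep.status["mum"].value == "+/+"
        assert rep.status["kid"].value == "+/-"

    def test_unaffected_het_mother_flagged_reduced_penetrance(self, make_trio):
        fam = make_trio(mother_aff=Affection.UNAFFECTED)
        calls = {("mum", self.KEY): Zygosity.HET}
        rep = segregation_report(self.KEY, fam, calls)
        assert "mum" in rep.reduced_penetrance_carriers

    def test_all_hom_ref_unaffected_gives_empty_flags(self, make_trio):
        fam = make_trio(father_aff=Affection.UNAFFECTED, mother_aff=Affection.UNAFFECTED,
                        child_aff=Affection.UNAFFECTED)
        calls = {(m, self.KEY): Zygosity.HOM_REF for m in ("dad", "mum", "kid")}
        rep = segregation_report(self.KEY, fam, calls)
        assert not rep.phenocopy_candidates
        assert not rep.reduced_penetrance_carriers
        assert not rep.homozygous_carriers

    def test_missing_calls_are_not_determined_and_unflagged(self, make_trio):
        rep = segregation_report(self.KEY, make_trio(), {})
        assert all(s.value == "n.d." for s in rep.status.values())
        assert not (rep.phenocopy_candidates | rep.reduced_penetrance_carriers
                    | rep.homozygous_carriers)


@given(
    afs=st.lists(
        st.one_of(st.none(), st.floats(min_value=0, max_value=1)), min_size=0, max_size=30
    ),
    threshold=st.floats(min_value=0, max_value=1),
)
def test_frequency_filter_is_monotone_in_threshold(afs, threshold):
    """Everything passing a tighter threshold also passes a looser one."""
    variants = [make_variant(pos=i + 1, panel_af=af) for i, af in enumerate(afs)]
    tight = apply_frequency_filter(variants, FilterConfig(maf_threshold=threshold))
    loose = apply_frequency_filter(variants, FilterConfig(maf_threshold=1.0))
    assert set(v.key for v in tight) <= set(v.key for v in loose)
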