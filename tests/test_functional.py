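import numpy as np
import pandas as pd
import pytest

from protshift.functional import (
    ModuleDefinition, completeness, coverage_report, enrichment_proportion_test,
    functional_groups, ko_abundance, module_abundance, module_dynamics,
    parse_modules, write_modules,
)
from protshift.mgs import MGSAbundance


def module(mid="M1", steps=(("K1", "K2"), ("K3",)), category="other", aa=None):
    return ModuleDefinition(mid, mid, category,
                            tuple(frozenset(s) for s in steps), amino_acid=aa)


class TestModuleFormat:
    def test_roundtrip(self, tmp_path):
        mods = [
            module("M1", (("K00001", "K00002"), ("K00003",))),
            module("M2", (("K00004",),), category="aa_synthesis", aa="lysine"),
        ]
        path = tmp_path / "modules.txt"
        write_modules(mods, path)
        back = parse_modules(path.read_text())
        assert back == mods

    def test_malformed_header_rejected(self):
        with pytest.raises(ValueError, match="header"):
            parse_modules("MODULE\tM1\tname-only\n")

    def test_step_outside_block_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            parse_modules("K00001,K00002\n")

    def test_module_without_steps_rejected(self):
        with pytest.raises(ValueError, match="step"):
            parse_modules("MODULE\tM1\tname\tother\n//\n")

    def test_amino_acid_required_for_aa_categories(self):
        with pytest.raises(ValueError, match="amino_acid"):
            module(category="aa_synthesis")


class TestKoAbundance:
    def test_sums_gene_abundances_per_ko(self):
        genes = pd.DataFrame({"s1": [0.01, 0.02, 0.5]}, index=["g1", "g2", "g3"])
        mapping = pd.DataFrame({"gene": ["g1", "g2"], "ko": ["K00001", "K00001"]})
        out = ko_abundance(genes, mapping)
        assert out.loc["K00001", "s1"] == pytest.approx(0.03)
        assert list(out.index) == ["K00001"]  # unmapped KOs absent

    def test_multi_ko_gene_counts_fully_toward_each(self):
        genes = pd.DataFrame({"s1": [0.2]}, index=["g1"])
        mapping = pd.DataFrame({"gene": ["g1", "g1"], "ko": ["K1", "K2"]})
        out = ko_abundance(genes, mapping)
        assert out.loc["K1", "s1"] == out.loc["K2", "s1"] == pytest.approx(0.2)

    def test_unannotated_genes_never_increase_abundance(self):
        genes = pd.DataFrame({"s1": [0.1, 0.9]}, index=["g1", "g2"])
        mapping = pd.DataFrame({"gene": ["g1"], "ko": ["K1"]})
        out = ko_abundance(genes, mapping)
        assert out.to_numpy().sum() <= genes.to_numpy().sum()


class TestModuleAbundance:
    def kos(self, values):
        return pd.DataFrame({"s1": values}, index=[f"K{i+1}" for i in range(len(values))])

    def test_median_with_zeros_when_coverage_passes(self):
        m = module(steps=(("K1",), ("K2",), ("K3",)))
        ab, cov = module_abundance(self.kos([0.0, 4e-4, 6e-4]), [m], 0.66)
        assert cov.loc["M1", "s1"] == pytest.approx(2 / 3)
        assert ab.loc["M1", "s1"] == pytest.approx(4e-4)

    def test_below_cutoff_scores_zero_despite_signal(self):
        m = module(steps=(("K1",), ("K2",), ("K3",)))
        ab, cov = module_abundance(self.kos([0.0, 0.0, 6e-4]), [m], 0.66)
        assert cov.loc["M1", "s1"] == pytest.approx(1 / 3)
        assert ab.loc["M1", "s1"] == 0.0

    def test_all_steps_zero_scores_zero(self):
        m = module(steps=(("K1",), ("K2",)))
        ab, _ = module_abundance(self.kos([0.0, 0.0]), [m], 0.5)
        assert ab.loc["M1", "s1"] == 0.0

    def test_alternative_kos_sum_within_a_step(self):
        m = module(steps=(("K1", "K2"),))
        ab, _ = module_abundance(self.kos([1e-4, 2e-4]), [m], 0.5)
        assert ab.loc["M1", "s1"] == pytest.approx(3e-4)

    def test_unknown_ko_module_scores_zero_with_warning(self, caplog):
        m = module(steps=(("K99",),))
        with caplog.at_level("WARNING"):
            ab, cov = module_abundance(self.kos([1e-4]), [m], 0.5)
        assert ab.loc["M1", "s1"] == 0.0 and cov.loc["M1", "s1"] == 0.0
        assert "no known KO" in caplog.text

    def test_monotone_in_ko_abundance(self):
        rng = np.random.default_rng(0)
        mods = [module("Ma", (("K1", "K2"), ("K3",))), module("Mb", (("K2",), ("K4",)))]
        base = pd.DataFrame(rng.random((4, 3)) * 1e-3,
                            index=["K1", "K2", "K3", "K4"],
                            columns=["s1", "s2", "s3"])
        ab0, _ = module_abundance(base, mods, 0.5)
        for ko in base.index:
            bumped = base.copy()
            bumped.loc[ko] += 5e-4
            ab1, _ = module_abundance(bumped, mods, 0.5)
            assert (ab1.to_numpy() >= ab0.to_numpy() - 1e-15).all()


class TestDynamicsAndEnrichment:
    def test_zero_mean_fold_change_is_unchanged_class(self):
        table = pd.DataFrame({"a_t0": [0.1], "a_t12": [0.1]}, index=["M1"])
        pairs = pd.DataFrame({"t0": ["a_t0"], "t12": ["a_t12"]}, index=["a"])
        arms = pd.Series({"a": "IP"})
        dyn = module_dynamics(table, pairs, arms)
        assert dyn.loc[0, "class"] == "unchanged"

    def test_binomial_p_for_unanimous_increase(self):
        mods = [module(f"M{i}", category="aa_synthesis", aa="lysine") for i in range(10)]
        dyn = pd.DataFrame({"module": [m.module_id for m in mods],
                            "arm": ["IP"] * 10,
                            "mean_lfc": [0.5] * 10,
                            "class": ["increase"] * 10})
        out = enrichment_proportion_test(dyn, mods, "aa_synthesis")
        assert out.loc[0, "binomial_p"] == pytest.approx(2 * 0.5**10, abs=1e-12)

    def test_balanced_split_gives_p_one(self):
        mods = [module(f"M{i}", category="aa_synthesis", aa="lysine") for i in range(10)]
        dyn = pd.DataFrame({"module": [m.module_id for m in mods],
                            "arm": ["IP"] * 10,
                            "mean_lfc": [0.5] * 5 + [-0.5] * 5,
                            "class": ["increase"] * 5 + ["decrease"] * 5})
        out = enrichment_proportion_test(dyn, mods, "aa_synthesis")
        assert out.loc[0, "binomial_p"] == pytest.approx(1.0)

    def test_chi_square_matches_hand_formula(self):
        # 2x2 [[18,2],[2,13]] increased/decreased x arm
        mods = [module(f"M{i}", category="aa_synthesis", aa="lysine") for i in range(35)]
        rows = []
        for i, m in enumerate(mods[:20]):
            rows.append({"module": m.module_id, "arm": "IP",
                         "mean_lfc": 1.0 if i < 18 else -1.0,
                         "class": "increase" if i < 18 else "decrease"})
        for i, m in enumerate(mods[20:]):
            rows.append({"module": m.module_id, "arm": "CP",
                         "mean_lfc": 1.0 if i < 2 else -1.0,
                         "class": "increase" if i < 2 else "decrease"})
        out = enrichment_proportion_test(pd.DataFrame(rows), mods, "aa_synthesis")
        obs = np.array([[2, 13], [18, 2]])  # arms sorted CP first
        exp = obs.sum(1)[:, None] * obs.sum(0)[None] / obs.sum()
        chi2 = ((obs - exp) ** 2 / exp).sum()
        from scipy.stats import chi2 as chi2_dist

        p_hand = chi2_dist.sf(chi2, 1)
        assert out["between_arm_chi2_p"].iloc[0] == pytest.approx(p_hand, abs=1e-9)

    def test_empty_category_is_an_error(self):
        mods = [module("M1", category="aa_synthesis", aa="lysine")]
        dyn = pd.DataFrame({"module": ["M1"], "arm": ["IP"],
                            "mean_lfc": [0.0], "class": ["unchanged"]})
        with pytest.raises(ValueError):
            enrichment_proportion_test(dyn, mods, "aa_synthesis")


class TestCompletenessAndGroups:
    def test_fraction_of_covered_steps(self):
        from protshift.mgs import MGSCatalog

        genes = [f"g{i}" for i in range(501)]
        cat = MGSCatalog(members={"m1": genes}, markers={"m1": genes[:2]},
                         genus={"m1": "Bacteroides"})
        mod = module("M4", (("K1",), ("K2",), ("K3",), ("K4",)))
        mapping = pd.DataFrame({"gene": genes[:3], "ko": ["K1", "K2", "K3"]})
        comp = completeness(cat, mapping, [mod])
        assert comp.loc["m1", "M4"] == pytest.approx(0.75)
        # MGS with no annotations scores 0 everywhere
        comp0 = completeness(cat, mapping.iloc[:0], [mod])
        assert comp0.loc["m1", "M4"] == 0.0

    def test_simulated_producers_are_fully_complete(self, small_profile):
        from protshift.functional import completeness as comp_fn

        cat = small_profile["catalog"]
        comp = comp_fn(cat, small_profile["gene_to_ko"], small_profile["modules"])
        by_aa = {m.amino_acid: m.module_id for m in small_profile["modules"]
                 if m.category == "aa_synthesis"}
        for aa, members in small_profile["cohort"].truth.producers.items():
            for m in members:
                assert comp.loc[m, by_aa[aa]] == 1.0

    def test_threshold_one_recovers_ground_truth_membership(self, small_profile):
        comp = completeness(small_profile["catalog"], small_profile["gene_to_ko"],
                            small_profile["modules"])
        membership, table = functional_groups(
            comp, small_profile["mgs"], small_profile["modules"], threshold=1.0)
        truth = small_profile["cohort"].truth
        for aa, members in truth.producers.items():
            assert membership.get((aa, "producer"), []) == sorted(members)
        for aa, members in truth.degraders.items():
            assert membership.get((aa, "degrader"), []) == sorted(members)

    def test_lowering_threshold_never_shrinks_groups(self, small_profile):
        comp = completeness(small_profile["catalog"], small_profile["gene_to_ko"],
                            small_profile["modules"])
        hi, _ = functional_groups(comp, small_profile["mgs"],
                                  small_profile["modules"], threshold=1.0)
        lo, _ = functional_groups(comp, small_profile["mgs"],
                                  small_profile["modules"], threshold=0.5)
        for key, members in hi.items():
            assert set(members) <= set(lo.get(key, []))

    def test_group_abundance_is_member_sum(self, small_profile):
        comp = completeness(small_profile["catalog"], small_profile["gene_to_ko"],
                            small_profile["modules"])
        membership, table = functional_groups(
            comp, small_profile["mgs"], small_profile["modules"], threshold=1.0)
        (aa, role), members = next(iter(membership.items()))
        expect = small_profile["mgs"].abundance.loc[members].sum(axis=0)
        assert np.allclose(table.loc[f"{aa}_{role}"], expect)


class TestCoverageReport:
    def test_synthesis_annotation_richer_than_degradation(self, small_profile):
        comp = completeness(small_profile["catalog"], small_profile["gene_to_ko"],
                            small_profile["modules"])
        rep = coverage_report(comp, small_profile["modules"])
        syn = rep.loc[rep["category"] == "aa_synthesis", "mean_completeness"].mean()
        deg = rep.loc[rep["category"] == "aa_degradation", "mean_completeness"].mean()
        assert syn > deg
        assert len(rep) == len(small_profile["modules"])

    def test_all_complete_summaries_are_one(self):
        mods = [module("M1", (("K1",),))]
        comp = pd.DataFrame({"M1": [1.0, 1.0]}, index=["m1", "m2"])
        rep = coverage_report(comp, mods)
        assert rep.loc["M1", "mean_completeness"] == 1.0
        assert rep.loc["M1", "frac_mgs_ge_threshold"] == 1.0
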