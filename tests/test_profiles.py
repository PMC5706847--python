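import itertools
import math

import numpy as np
import pytest
from scipy import stats

from pina.profiles import (
    CorrelationResult,
    DiseaseProfile,
    PIPPConfig,
    PairType,
    PathwayPair,
    build_disease_profiles,
    classify_pair,
    compound_disease_pairs,
    correlation_keep,
    enrich_pathways,
    pathway_activity,
    pipp_score,
)
from pina.types import (
    AssociationMatrix,
    CompoundRecord,
    DiseaseRecord,
    ExpressionMatrix,
    GeneSetCollection,
    PPINetwork,
)


def genes(prefix, n):
    return [f"{prefix}{i}" for i in range(n)]


class TestEnrichment:
    def test_exact_overlap_is_most_significant(self):
        bg = genes("g", 100)
        gs = GeneSetCollection({"P1": frozenset(bg[:10]), "P2": frozenset(bg[50:60])})
        hits = enrich_pathways(bg[:10], gs, background=bg, fdr=0.05)
        assert set(hits) == {"P1"}

    def test_disjoint_query_yields_nothing(self):
        bg = genes("g", 50)
        gs = GeneSetCollection({"P1": frozenset(bg[:5])})
        assert enrich_pathways(bg[40:45], gs, background=bg, fdr=0.05) == {}

    def test_pvalue_matches_exhaustive_enumeration(self):
        # background of 20 genes, one 5-gene set, 6-gene query overlapping by 3:
        # enumerate every C(20,6) draw and count overlaps >= 3
        bg = genes("g", 20)
        members = set(bg[:5])
        query = bg[2:5] + bg[10:13]  # overlap exactly 3
        assert len(set(query) & members) == 3
        n_hits = sum(
            1
            for draw in itertools.combinations(bg, 6)
            if len(set(draw) & members) >= 3
        )
        expected = n_hits / math.comb(20, 6)
        gs = GeneSetCollection({"P1": frozenset(members)})
        got = enrich_pathways(query, gs, background=bg, fdr=1.0)["P1"]
        assert got == pytest.approx(expected, abs=1e-10)

    def test_genes_outside_background_dropped(self, caplog):
        bg = genes("g", 20)
        gs = GeneSetCollection({"P1": frozenset(bg[:5])})
        with caplog.at_level("WARNING", logger="pina"):
            out = enrich_pathways(["alien1", "alien2"], gs, background=bg, fdr=0.05)
        assert out == {} and "background" in caplog.text


class TestPathwayActivity:
    def _expr(self):
        return ExpressionMatrix(
            ["g1", "g2", "g3"],
            ["t1", "t2"],
            np.array([[2.0, 8.0], [4.0, 0.0], [1.0, 1.0]]),
        )

    def test_single_gene_is_its_row(self):
        assert np.allclose(pathway_activity(self._expr(), {"g3"}), [1.0, 1.0])

    def test_mean_of_members(self):
        assert np.allclose(pathway_activity(self._expr(), {"g1", "g2"}), [3.0, 4.0])

    def test_unmeasured_pathway_errors(self):
        with pytest.raises(ValueError, match="no genes measured"):
            pathway_activity(self._expr(), {"absent"})


class TestClassifyPair:
    gs = GeneSetCollection(
        {"P1": frozenset({"a", "b"}), "P2": frozenset({"b", "c"}), "P3": frozenset({"x", "y"})}
    )

    def test_same_pathway_is_common(self):
        assert classify_pair("P1", "P1", self.gs, PPINetwork(set())) is PairType.COMMON

    def test_shared_gene_is_crosstalk(self):
        assert classify_pair("P1", "P2", self.gs, PPINetwork(set())) is PairType.CROSSTALK

    def test_bridging_edge_is_interacting(self):
        ppi = PPINetwork({("a", "x")})
        assert classify_pair("P1", "P3", self.gs, ppi) is PairType.INTERACTING

    def test_unrelated_is_none(self):
        assert classify_pair("P1", "P3", self.gs, PPINetwork(set())) is None

    def test_unknown_pathway_errors(self):
        with pytest.raises(KeyError):
            classify_pair("P1", "P9", self.gs, PPINetwork(set()))


class TestCorrelationKeep:
    def test_perfect_linear_kept(self):
        a = np.arange(36, dtype=float)
        res = correlation_keep(a, 2 * a + 1, alpha=0.01)
        assert res.keep and res.r == pytest.approx(1.0)

    def test_constant_vector_degenerate(self):
        res = correlation_keep(np.ones(36), np.arange(36.0), alpha=0.01)
        assert not res.keep and res.degenerate

    def test_p_matches_closed_form_t_test(self, rng):
        a = rng.normal(size=36)
        b = 0.4 * a + rng.normal(size=36)
        res = correlation_keep(a, b, alpha=0.01)
        r, n = res.r, 36
        t = abs(r) * math.sqrt((n - 2) / (1 - r * r))
        expected = 2 * stats.t.sf(t, df=n - 2)
        assert res.p_value == pytest.approx(expected, rel=1e-9)

    def test_positive_only_flag_rejects_anticorrelation(self):
        a = np.arange(36, dtype=float)
        assert correlation_keep(a, -a, alpha=0.01, positive_only=True).keep is False
        assert correlation_keep(a, -a, alpha=0.01).keep is True


def _pair(pa, pb, ptype):
    return PathwayPair.make(pa, pb, ptype)


class TestPippScore:
    def test_no_matching_pairs_scores_zero(self):
        prof = DiseaseProfile("d", {_pair("P1", "P1", PairType.COMMON): 1.0}, 3)
        assert pipp_score([_pair("P2", "P2", PairType.COMMON)], prof) == 0.0

    def test_single_common_pair_full_support(self):
        pair = _pair("P1", "P1", PairType.COMMON)
        prof = DiseaseProfile("d", {pair: 1.0}, 3)
        assert pipp_score([pair], prof) == pytest.approx(0.5)

    def test_one_pair_per_type_full_support_scores_one(self):
        pairs = [
            _pair("P1", "P1", PairType.COMMON),
            _pair("P2", "P3", PairType.CROSSTALK),
            _pair("P4", "P5", PairType.INTERACTING),
        ]
        prof = DiseaseProfile("d", {p: 1.0 for p in pairs}, 2)
        assert pipp_score(pairs, prof) == pytest.approx(1.0)

    def test_missing_profile_scores_zero(self):
        assert pipp_score([_pair("P1", "P1", PairType.COMMON)], None) == 0.0

    def test_monotone_in_profile_scores_and_added_pairs(self):
        p1 = _pair("P1", "P1", PairType.COMMON)
        p2 = _pair("P2", "P2", PairType.COMMON)
        lo = DiseaseProfile("d", {p1: 0.3, p2: 0.4}, 10)
        hi = DiseaseProfile("d", {p1: 0.6, p2: 0.4}, 10)
        assert pipp_score([p1], lo) < pipp_score([p1], hi)
        assert pipp_score([p1], lo) < pipp_score([p1, p2], lo)
        for prof in (lo, hi):
            assert 0.0 <= pipp_score([p1, p2], prof) <= 1.0

    def test_complement_variant(self):
        # 1 - sum_m alpha_m prod(1-P): one common pair at P=1 kills only the
        # alpha_1 survival term -> 1 - (0.3 + 0.2) = 0.5 here too, but with
        # P=0.5 the two readings differ
        pair = _pair("P1", "P1", PairType.COMMON)
        prof = DiseaseProfile("d", {pair: 0.5}, 2)
        cfg = PIPPConfig(eq2_variant="complement")
        assert pipp_score([pair], prof, cfg) == pytest.approx(1 - (0.5 * 0.5 + 0.3 + 0.2))
        assert pipp_score([pair], prof) == pytest.approx(0.25)


class TestBuildProfiles:
    def test_fraction_of_treaters(self):
        pair = _pair("P1", "P1", PairType.COMMON)
        assoc = AssociationMatrix.from_pairs(
            [(f"c{i}", "d") for i in range(4)], diseases=["d"]
        )
        pair_sets = {("c0", "d"): frozenset({pair}), ("c1", "d"): frozenset({pair})}
        prof = build_disease_profiles(assoc, pair_sets)["d"]
        assert prof.pair_scores[pair] == pytest.approx(0.5)
        assert prof.n_treating == 4

    def test_universal_pair_scores_one(self):
        pair = _pair("P1", "P1", PairType.COMMON)
        assoc = AssociationMatrix.from_pairs([("c0", "d"), ("c1", "d")])
        pair_sets = {(c, "d"): frozenset({pair}) for c in ("c0", "c1")}
        assert build_disease_profiles(assoc, pair_sets)["d"].pair_scores[pair] == 1.0

    def test_untreated_disease_has_no_profile(self):
        assoc = AssociationMatrix.from_pairs([("c0", "d1")], diseases=["d1", "d2"])
        assert "d2" not in build_disease_profiles(assoc, {})

    def test_scores_are_exact_rationals_and_match_recount(self, crosstalk_bundle, rng):
        from pina.profiles import PairComputer, all_pair_sets

        bundle, _ = crosstalk_bundle
        pair_sets = all_pair_sets(bundle)
        profiles = build_disease_profiles(bundle.associations, pair_sets)
        assoc = bundle.associations
        for d, prof in profiles.items():
            treaters = [c for c in assoc.compounds if assoc.get(c, d)]
            assert prof.n_treating == len(treaters)
            for pair, s in prof.pair_scores.items():
                k = sum(1 for c in treaters if pair in pair_sets[(c, d)])
                assert s == k / prof.n_treating  # exact rational


class TestCompoundDiseasePairs:
    def _setup(self, share_gene: bool, correlated: bool):
        ga, gb = genes("a", 6), genes("b", 6)
        if share_gene:
            gb = gb[:-1] + [ga[0]]
        gs = GeneSetCollection({"P1": frozenset(ga), "P2": frozenset(gb)})
        rng = np.random.default_rng(1)
        base = rng.normal(size=36)
        rows = []
        for g in sorted(set(ga + gb)):
            if correlated or g in ga:
                rows.append(base + rng.normal(scale=0.05, size=36))
            else:
                rows.append(rng.normal(size=36))
        expr = ExpressionMatrix(sorted(set(ga + gb)), [f"t{i}" for i in range(36)], np.array(rows))
        compound = CompoundRecord("c", frozenset(ga))
        disease = DiseaseRecord("d", frozenset(gb))
        return compound, disease, gs, expr

    def test_shared_enrichment_gives_common_pair(self):
        ga, gz = genes("a", 6), genes("z", 20)
        gs = GeneSetCollection({"P1": frozenset(ga), "PZ": frozenset(gz)})
        expr = ExpressionMatrix(
            ga + gz, ["t1", "t2", "t3"], np.ones((26, 3))
        )
        pairs = compound_disease_pairs(
            CompoundRecord("c", frozenset(ga)),
            DiseaseRecord("d", frozenset(ga)),
            gs,
            PPINetwork(set()),
            expr,
        )
        assert pairs == {PathwayPair.make("P1", "P1", PairType.COMMON)}

    def test_unrelated_pathways_give_nothing(self):
        compound, disease, gs, expr = self._setup(share_gene=False, correlated=True)
        assert compound_disease_pairs(compound, disease, gs, PPINetwork(set()), expr) == frozenset()

    def test_uncorrelated_crosstalk_filtered(self):
        compound, disease, gs, expr = self._setup(share_gene=True, correlated=False)
        pairs = compound_disease_pairs(compound, disease, gs, PPINetwork(set()), expr)
        assert pairs == frozenset()

    def test_correlated_crosstalk_kept_with_stats(self):
        compound, disease, gs, expr = self._setup(share_gene=True, correlated=True)
        pairs = compound_disease_pairs(compound, disease, gs, PPINetwork(set()), expr)
        assert len(pairs) == 1
        (pair,) = pairs
        assert pair.ptype is PairType.CROSSTALK
        assert pair.p_value < 0.01 and pair.r > 0.9
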