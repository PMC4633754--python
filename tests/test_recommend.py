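import numpy as np
import pytest

from mediarec import (
    EnvironmentTable,
    GrowthDatabase,
    MediarecError,
    MediumRecommender,
    MediumVariant,
    OrganismProfile,
    PopularityNullRecommender,
    TaxonomyTree,
    apply_filters,
    build_profiles,
    classify_oxygen,
    classify_salt,
    classify_salt_org,
    evaluate_by_score_bin,
    filter_predictions,
    permutation_enrichment,
)
from mediarec.core import CompiledComponent
from mediarec.recommend import nacl_equivalent_g_per_l


@pytest.fixture(scope="module")
def wide_tree():
    """100-leaf caterpillar-free tree giving controllable subtree distances.

    Balanced over 100 leaves named L00..L99; with total 100 the cutoff 0.04
    admits LCA subtree sizes up to 4.
    """
    leaves = [f"L{i:02d}" for i in range(100)]

    def nwk(group):
        if len(group) == 1:
            return group[0]
        mid = (len(group) + 1) // 2
        return f"({nwk(group[:mid])},{nwk(group[mid:])})"

    return TaxonomyTree.from_newick(nwk(leaves) + ";")


class TestCollabScore:
    def test_no_neighbor_on_medium_scores_zero(self, wide_tree):
        db = GrowthDatabase(organisms=["L00", "L01"], media=["m"])
        rec = MediumRecommender().fit(db, tree=wide_tree)
        assert rec.score_pair("L00", "m") == 0.0

    def test_neighbor_at_cutoff_weight_one(self, wide_tree):
        # L00 vs L02: LCA subtends 4 leaves -> d = 0.04 exactly
        db = GrowthDatabase(organisms=["L02"], media=["m"])
        db.add_pairing("L02", "m")
        rec = MediumRecommender().fit(db, tree=wide_tree)
        assert wide_tree.subtree_distance("L00", "L02") == pytest.approx(0.04)
        assert rec.score_pair("L00", "m") == pytest.approx(1.0)

    def test_two_neighbors_weighted_sum(self, wide_tree):
        # L01 at d=0.02 contributes 0.04/0.02 = 2; L02 at d=0.04 contributes 1
        db = GrowthDatabase(organisms=["L01", "L02"], media=["m"])
        db.add_pairing("L01", "m").add_pairing("L02", "m")
        rec = MediumRecommender().fit(db, tree=wide_tree)
        assert rec.score_pair("L00", "m") == pytest.approx(3.0)

    def test_additive_over_disjoint_neighbor_sets(self, wide_tree):
        db_both = GrowthDatabase(organisms=["L01", "L02"], media=["m"])
        db_both.add_pairing("L01", "m").add_pairing("L02", "m")
        score_both = MediumRecommender().fit(db_both, tree=wide_tree).score_pair("L00", "m")
        parts = 0.0
        for org in ("L01", "L02"):
            db = GrowthDatabase(organisms=[org], media=["m"])
            db.add_pairing(org, "m")
            parts += MediumRecommender().fit(db, tree=wide_tree).score_pair("L00", "m")
        assert score_both == pytest.approx(parts)

    def test_weight_bounded_by_cutoff_over_floor(self, wide_tree):
        db = GrowthDatabase(organisms=["L01"], media=["m"])
        db.add_pairing("L01", "m")
        rec = MediumRecommender().fit(db, tree=wide_tree)
        for org, d in rec.neighbors("L00"):
            w = rec.cutoff_ / max(d, rec.floor_)
            assert 1.0 <= w <= rec.cutoff_ / rec.floor_

    def test_leave_one_out_honesty(self, wide_tree):
        """Deleting the test organism's own rows leaves its scores unchanged."""
        db = GrowthDatabase(organisms=["L00", "L01", "L02"], media=["m", "m2"])
        db.add_pairing("L00", "m").add_pairing("L00", "m2")  # own rows
        db.add_pairing("L01", "m").add_pairing("L02", "m")
        stripped = GrowthDatabase(organisms=["L01", "L02"], media=["m", "m2"])
        stripped.add_pairing("L01", "m").add_pairing("L02", "m")
        with_own = MediumRecommender().fit(db, tree=wide_tree)
        without = MediumRecommender().fit(stripped, tree=wide_tree)
        assert with_own.score_pair("L00", "m") == without.score_pair("L00", "m")
        assert with_own.score_pair("L00", "m2") == without.score_pair("L00", "m2") == 0.0

    def test_organism_absent_from_tree_rejected(self, wide_tree):
        db = GrowthDatabase(organisms=["L01"], media=["m"])
        rec = MediumRecommender().fit(db, tree=wide_tree)
        with pytest.raises(MediarecError, match="not in the taxonomy"):
            rec.score_pair("alien", "m")

    def test_ecological_mode_uniform_weights(self):
        envs = EnvironmentTable(
            {"a": {"e1", "e2"}, "b": {"e1", "e2"}, "c": {"e1", "e2", "e3"}}
        )
        db = GrowthDatabase(organisms=["b", "c"], media=["m"])
        db.add_pairing("b", "m").add_pairing("c", "m")
        rec = MediumRecommender(mode="ecological").fit(db, environments=envs)
        # b at distance 0, c at 1/3 > 0.15; only b votes, weight 1
        assert rec.score_pair("a", "m") == pytest.approx(1.0)


class TestPredictMedia:
    def test_clade_medium_ranked_first(self, wide_tree):
        db = GrowthDatabase(
            organisms=["L01", "L02", "L03"], media=["clade_m", "other"]
        )
        for org in ("L01", "L02", "L03"):
            db.add_pairing(org, "clade_m")
        db.add_pairing("L03", "other")
        rec = MediumRecommender().fit(db, tree=wide_tree)
        preds = rec.predict_media("L00")
        assert preds[0].medium == "clade_m"
        assert preds[0].score > preds[-1].score or len(preds) == 1

    def test_isolated_organism_gets_nothing(self, wide_tree):
        db = GrowthDatabase(organisms=["L99"], media=["m"])
        db.add_pairing("L99", "m")
        rec = MediumRecommender().fit(db, tree=wide_tree)
        assert rec.predict_media("L00") == []

    def test_ties_broken_by_medium_id(self, wide_tree):
        db = GrowthDatabase(organisms=["L01"], media=["mB", "mA"])
        db.add_pairing("L01", "mA").add_pairing("L01", "mB")
        rec = MediumRecommender().fit(db, tree=wide_tree)
        preds = rec.predict_media("L00")
        assert [p.medium for p in preds] == ["mA", "mB"]

    def test_held_out_true_media_rank_high_under_signal(self, s1_dataset):
        """On planted-preference data the held-out organism's own media are
        recovered near the top of the ranking."""
        rec = MediumRecommender().fit(s1_dataset.db, tree=s1_dataset.tree)
        ranks = []
        for org in rec.organisms_[:32]:
            preds = rec.predict_media(org)
            if not preds:
                continue
            for i, p in enumerate(preds):
                if p.is_known:
                    ranks.append(i / len(preds))
        assert ranks, "no known media recovered at all"
        assert np.median(ranks) < 0.5


class TestNullPredictor:
    def test_single_pair_always(self):
        db = GrowthDatabase(organisms=["a"], media=["m"])
        db.add_pairing("a", "m")
        null = PopularityNullRecommender().fit(db)
        assert set(null.sample(10, random_state=0)) == {("a", "m")}

    def test_popularity_proportional_sampling(self):
        db = GrowthDatabase(organisms=["heavy", "light"], media=["m1", "m2"])
        db.add_pairing("heavy", "m1").add_pairing("heavy", "m2")
        db.add_pairing("light", "m1")
        null = PopularityNullRecommender().fit(db)
        pairs = null.sample(100_000, random_state=1)
        freq = sum(o == "heavy" for o, _ in pairs) / len(pairs)
        assert freq == pytest.approx(2 / 3, abs=0.01)

    def test_invalid_n_rejected(self):
        db = GrowthDatabase(organisms=["a"], media=["m"])
        db.add_pairing("a", "m")
        with pytest.raises(MediarecError):
            PopularityNullRecommender().fit(db).sample(0)

    def test_reproducible(self):
        db = GrowthDatabase(organisms=["a", "b"], media=["m1", "m2"])
        db.add_pairing("a", "m1").add_pairing("b", "m2")
        null = PopularityNullRecommender().fit(db)
        assert null.sample(50, random_state=7) == null.sample(50, random_state=7)


class TestScoreBins:
    def test_known_only_predictor_full_tp(self, s1_dataset):
        rec = MediumRecommender().fit(s1_dataset.db, tree=s1_dataset.tree)
        preds = [p for p in rec.predict() if p.is_known]
        table = evaluate_by_score_bin(preds, s1_dataset.db, n_bins=6)
        occ = table.counts > 0
        assert np.allclose(table.tp_fractions[occ], 1.0)

    def test_constant_scores_rejected(self, s1_dataset):
        rec = MediumRecommender().fit(s1_dataset.db, tree=s1_dataset.tree)
        preds = rec.predict()
        same_score = [preds[0]] * 5  # a single occupied bin
        with pytest.raises(MediarecError):
            evaluate_by_score_bin(same_score, s1_dataset.db, n_bins=6)

    def test_partial_spearman_self_control_vanishes(self):
        from mediarec._stats import partial_spearman

        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = 2 * x + rng.normal(scale=0.1, size=30)
        rho, _ = partial_spearman(y, x, x)
        assert abs(rho) < 1e-6

    def test_partial_spearman_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        from mediarec._stats import partial_spearman

        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        z = rng.normal(size=40)
        y = x + 0.5 * z + rng.normal(size=40)
        rho, _ = partial_spearman(x, y, z)
        expected = pg.partial_corr(
            data=pd.DataFrame({"x": x, "y": y, "z": z}),
            x="x", y="y", covar="z", method="spearman",
        )["r"].iloc[0]
        assert rho == pytest.approx(expected, abs=1e-6)


class TestPermutation:
    def test_null_predictions_not_enriched(self, s0_dataset):
        rec = MediumRecommender().fit(s0_dataset.db, tree=s0_dataset.tree)
        preds = rec.predict()
        res = permutation_enrichment(
            preds, s0_dataset.db, organisms=rec.organisms_,
            n_permutations=99, random_state=0,
        )
        assert res["p_value"] > 0.05

    def test_planted_signal_enriched(self, s1_dataset):
        rec = MediumRecommender().fit(s1_dataset.db, tree=s1_dataset.tree)
        preds = rec.predict()
        res = permutation_enrichment(
            preds, s1_dataset.db, organisms=rec.organisms_,
            n_permutations=99, random_state=0,
        )
        assert res["enrichment_ratio"] > 1.0
        assert res["p_value"] == pytest.approx(1 / 100)


def _medium_with_salt(mid, g_per_l, name=""):
    mol = g_per_l / 58.44
    return MediumVariant(
        medium_id=mid,
        name=name or mid,
        components=[
            CompiledComponent("Na+", "defined", mol),
            CompiledComponent("Cl-", "defined", mol),
        ],
    )


class TestClassifiers:
    def test_oxygen_rules(self):
        db = GrowthDatabase(organisms=["aer", "ana", "fac", "unk"],
                            media=["a1", "a2", "n1"])
        db.add_pairing("aer", "a1").add_pairing("aer", "a2")
        db.add_pairing("ana", "n1")
        db.add_pairing("fac", "a1").add_pairing("fac", "n1")
        db.add_pairing("unk", "a1")
        oxy = {"a1": "aerobic", "a2": "aerobic", "n1": "anaerobic"}
        assert classify_oxygen("aer", db, oxy) == "aerobic"
        assert classify_oxygen("ana", db, oxy) == "anaerobic"
        assert classify_oxygen("fac", db, oxy) == "facultative"
        assert classify_oxygen("unk", db, {}) == "unknown"

    def test_salt_threshold_rule(self):
        assert classify_salt(_medium_with_salt("m", 20.0)) == "salty"
        assert classify_salt(_medium_with_salt("m", 5.0)) == "not_salty"
        assert classify_salt(_medium_with_salt("m", 15.0)) == "salty"  # boundary

    def test_sea_name_overrides_composition(self):
        m = _medium_with_salt("m", 1.0, name="Artificial sea water")
        assert classify_salt(m) == "salty"

    def test_nacl_equivalent_uses_limiting_ion(self):
        m = MediumVariant(
            medium_id="m",
            components=[
                CompiledComponent("Na+", "defined", 1.0),
                CompiledComponent("Cl-", "defined", 0.1),
            ],
        )
        assert nacl_equivalent_g_per_l(m) == pytest.approx(0.1 * 58.44)

    def test_salt_org_classes(self):
        db = GrowthDatabase(organisms=["hi", "lo", "mix"], media=["s1", "s2", "f1"])
        db.add_pairing("hi", "s1").add_pairing("hi", "s2")
        db.add_pairing("lo", "f1")
        db.add_pairing("mix", "s1").add_pairing("mix", "f1")
        salt = {"s1": "salty", "s2": "salty", "f1": "not_salty"}
        assert classify_salt_org("hi", db, salt) == "high"
        assert classify_salt_org("lo", db, salt) == "low"
        assert classify_salt_org("mix", db, salt) == "unknown"


class TestFilters:
    def _pred(self, org, medium):
        from mediarec.recommend import CollabPrediction

        return CollabPrediction(org, medium, 1.0, 1, False)

    def test_oxygen_mismatch_excluded_both_directions(self):
        profiles = {"ana": OrganismProfile(oxygen_class="anaerobic"),
                    "aer": OrganismProfile(oxygen_class="aerobic")}
        oxy = {"air": "aerobic", "jar": "anaerobic"}
        preds = [self._pred("ana", "air"), self._pred("aer", "jar")]
        assert filter_predictions(preds, profiles, oxy) == []

    def test_facultative_passes_everything(self):
        profiles = {"fac": OrganismProfile(oxygen_class="facultative")}
        oxy = {"air": "aerobic", "jar": "anaerobic"}
        preds = [self._pred("fac", "air"), self._pred("fac", "jar")]
        assert len(filter_predictions(preds, profiles, oxy)) == 2

    def test_salt_mismatch_excluded(self):
        profiles = {"lo": OrganismProfile(salt_class="low"),
                    "hi": OrganismProfile(salt_class="high")}
        salt = {"brine": "salty", "fresh": "not_salty"}
        preds = [self._pred("lo", "brine"), self._pred("hi", "fresh")]
        assert filter_predictions(preds, profiles, media_salt=salt) == []

    def test_flags_retained_on_all_predictions(self):
        profiles = {"lo": OrganismProfile(salt_class="low")}
        salt = {"brine": "salty"}
        out = apply_filters([self._pred("lo", "brine")], profiles, media_salt=salt)
        assert out[0].passed_filters is False
        assert dict(out[0].filter_flags) == {"oxygen": True, "salt": False}

    def test_filters_never_drop_known_pairings(self, s1_dataset):
        """Profiles derive from an organism's own media, so a documented
        pairing can never contradict them."""
        from mediarec.recommend import media_salt_statuses

        ds = s1_dataset
        rec = MediumRecommender().fit(ds.db, tree=ds.tree)
        preds = rec.predict()
        salt = media_salt_statuses(ds.media)
        profiles = build_profiles(ds.db, ds.media_oxygen, salt)
        kept = filter_predictions(preds, profiles, ds.media_oxygen, salt)
        assert {(p.organism, p.medium) for p in preds if p.is_known} == {
            (p.organism, p.medium) for p in kept if p.is_known
        }
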