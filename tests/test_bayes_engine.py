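import math

import numpy as np
import pytest

import esipred as ep
from esipred.bayes_engine import LRBin, LRTable, enumerate_scan_pairs
from esipred.config import ModelConfig


# ---------------------------------------------------------------------------
# LR estimation
# ---------------------------------------------------------------------------


class TestEstimateLRTable:
    def test_direct_ratio_no_smoothing(self):
        pos = [0.5] * 10 + [5.0] * 90
        neg = [0.5] * 2 + [5.0] * 198
        table = ep.estimate_lr_table(pos, neg, [0.0, 1.0, math.inf], smoothing=0.0)
        assert table.bins[0].lr == pytest.approx((10 / 100) / (2 / 200))
        assert table.bins[0].lr == pytest.approx(10.0)

    def test_pseudocount_example(self):
        # tp=9, T=99, fp=0, F=199, s=1 -> (10/100)/(1/200) = 20
        pos = [0.5] * 9 + [5.0] * 90
        neg = [5.0] * 199
        table = ep.estimate_lr_table(pos, neg, [0.0, 1.0, math.inf], smoothing=1.0)
        assert table.bins[0].lr == pytest.approx(20.0)

    def test_empty_bin_gets_lr_one(self):
        table = ep.estimate_lr_table([5.0], [5.0], [0.0, 1.0, math.inf], 1.0)
        assert table.bins[0].lr == 1.0

    def test_same_distribution_lr_near_one(self):
        rng = np.random.default_rng(0)
        pos = rng.exponential(2.0, size=10_000)
        neg = rng.exponential(2.0, size=10_000)
        table = ep.estimate_lr_table(
            pos, neg, [0.0, 1.0, 2.0, 4.0, 8.0, math.inf], smoothing=1.0
        )
        for b in table.bins:
            if b.tp_f + b.fp_f > 50:
                assert 0.8 <= b.lr <= 1.25

    def test_bad_edges_rejected(self):
        with pytest.raises(ValueError):
            ep.estimate_lr_table([1.0], [1.0], [0.0, 2.0, 1.0], 1.0)
        with pytest.raises(ValueError):
            ep.estimate_lr_table([1.0], [1.0], [0.0], 1.0)

    def test_lookup_total_over_axis(self):
        table = ep.estimate_lr_table([0.5], [3.0], [0.0, 1.0, math.inf], 1.0)
        assert table.lookup(0.0) == table.bins[0].lr
        assert table.lookup(1e9) == table.bins[1].lr
        with pytest.raises(ValueError):
            table.lookup(-1.0)

    def test_lr_cap(self):
        pos = [0.5] * 100
        neg = [5.0] * 100
        table = ep.estimate_lr_table(
            pos, neg, [0.0, 1.0, math.inf], 0.0, lr_cap=(1e-3, 1e3)
        )
        assert table.bins[0].lr == 1e3
        assert table.bins[1].lr == 1e-3


# ---------------------------------------------------------------------------
# combination, prior, score
# ---------------------------------------------------------------------------


class TestCombine:
    def test_product(self):
        assert ep.combine({"a": 2.0, "b": 5.0}) == pytest.approx(10.0)

    def test_empty_is_one(self):
        assert ep.combine({}) == 1.0

    def test_order_invariant(self):
        lrs = {"a": 1.7, "b": 0.3, "c": 42.0}
        fwd = ep.combine(dict(sorted(lrs.items())))
        rev = ep.combine(dict(sorted(lrs.items(), reverse=True)))
        assert fwd == pytest.approx(rev, rel=1e-12)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            ep.combine({"a": 0.0})
        with pytest.raises(ValueError):
            ep.combine({"a": -1.0})


class TestPrior:
    def test_published_counts(self):
        gold = ep.GoldStandard(
            frozenset(ep.ESIPair(f"E{i}", f"S{i}") for i in range(913)),
            frozenset(ep.ESIPair(f"E{i}", f"N{i}") for i in range(2734)),
        )
        prior, o_post = ep.prior_and_posterior(gold, 1.0)
        assert prior.p_positive == pytest.approx(913 / 3647)
        assert prior.o_prior == pytest.approx(913 / 2734)
        assert o_post == pytest.approx(prior.o_prior)

    def test_even_prior(self):
        prior = ep.PriorModel.from_counts(5, 5)
        assert prior.o_prior == pytest.approx(1.0)

    def test_zero_counts_error(self):
        with pytest.raises(ValueError):
            ep.PriorModel.from_counts(0, 5)


class TestConfidenceScore:
    def test_published_worked_example(self):
        assert ep.confidence_score(195.79) == pytest.approx(0.908, abs=5e-4)

    def test_neutral(self):
        assert ep.confidence_score(1.0) == pytest.approx(0.5)

    def test_closed_form_ten(self):
        assert ep.confidence_score(10.0) == pytest.approx(1 / (1 + math.exp(-1)), abs=5e-5)
        assert ep.confidence_score(10.0) == pytest.approx(0.7311, abs=5e-5)

    def test_logistic_symmetry(self):
        for lr in (0.001, 0.5, 1.0, 3.7, 195.79, 1e5):
            assert ep.confidence_score(lr) + ep.confidence_score(1 / lr) == pytest.approx(1.0)

    def test_strictly_increasing(self):
        grid = [0.01, 0.1, 1.0, 2.0, 10.0, 100.0]
        scores = [ep.confidence_score(x) for x in grid]
        assert scores == sorted(scores)
        assert all(0 < s < 1 for s in scores)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            ep.confidence_score(0.0)


# ---------------------------------------------------------------------------
# evidence_lr / predict
# ---------------------------------------------------------------------------


def _constant_table(etype: str, lr: float) -> LRTable:
    return LRTable(etype, (LRBin(0.0, math.inf, 1, 1, lr),), 1.0)


def _toy_model(lr_tables, enriched=None, motifs=None) -> ep.TrainedModel:
    return ep.TrainedModel(
        config=ModelConfig(),
        prior=ep.PriorModel.from_counts(1, 1),
        enriched=enriched or {},
        motifs=motifs or {},
        lr_tables=lr_tables,
        fingerprint="toy",
    )


class TestEvidenceLR:
    def test_max_rule_within_type(self):
        # two matching domain features with different LR bins -> max retained
        table = LRTable(
            "domain",
            (LRBin(0.0, 4.0, 1, 1, 3.0), LRBin(4.0, math.inf, 1, 1, 7.0)),
            1.0,
        )
        go_table = LRTable("go", (LRBin(0.0, math.inf, 1, 1, 2.0),), 1.0)
        enriched = {
            "domain": {
                ("A", "B"): ep.EnrichmentFeature("A", "B", 2.0, 2),
                ("A", "C"): ep.EnrichmentFeature("A", "C", 9.0, 2),
            },
            "go": {("G1", "G2"): ep.EnrichmentFeature("G1", "G2", 1.5, 2)},
        }
        model = _toy_model({"domain": table, "go": go_table}, enriched=enriched)
        inputs = ep.EvidenceInputs(
            domain_ann=ep.AnnotationMap(
                "domain",
                {"E": frozenset({"A"}), "S": frozenset({"B", "C"})},
            ),
            go_ann=ep.AnnotationMap(
                "go", {"E": frozenset({"G1"}), "S": frozenset({"G2"})}
            ),
        )
        lrs = ep.evidence_lr(ep.ESIPair("E", "S"), model, inputs)
        assert lrs == {"domain": 7.0, "go": 2.0}

    def test_no_evidence_empty_map(self):
        model = _toy_model({"domain": _constant_table("domain", 5.0)})
        lrs = ep.evidence_lr(ep.ESIPair("E", "S"), model, ep.EvidenceInputs())
        assert lrs == {}

    def test_brute_force_feature_lookup(self, small_world, small_model):
        # hand-enumerate every firing feature for one pair and compare
        pair = sorted(small_world.gold.positives)[0]
        inputs = small_world.inputs()
        got = ep.evidence_lr(pair, small_model, inputs)
        expected = {}
        for etype in ("domain", "go"):
            ann = inputs.domain_ann if etype == "domain" else inputs.go_ann
            lrs = []
            for le in ann.labels(pair.e3):
                for ls in ann.labels(pair.substrate):
                    feat = small_model.enriched.get(etype, {}).get((le, ls))
                    if feat is not None:
                        lrs.append(small_model.lr_tables[etype].lookup(feat.ratio))
            if lrs:
                expected[etype] = max(lrs)
        if pair.e3 in inputs.ppi and pair.substrate in inputs.ppi:
            lc = ep.count_loops(pair, inputs.ppi)
            expected["network_n3"] = small_model.lr_tables["network_n3"].lookup(lc.n3)
            expected["network_n4"] = small_model.lr_tables["network_n4"].lookup(lc.n4)
        seq = inputs.sequences.get(pair.substrate)
        if seq is not None:
            scores = [
                m.motif_score
                for m in small_model.motifs.get(pair.e3, [])
                if ep.match_motif(seq, m)
            ]
            if scores:
                expected["motif"] = small_model.lr_tables["motif"].lookup(max(scores))
        if ep.homology_support(pair, inputs.mouse_esis, inputs.omap).supported:
            expected["homology"] = small_model.lr_tables["homology"].lookup(1.0)
        assert got == expected

    def test_all_tables_one_gives_score_half(self, small_world, small_model):
        flat = {
            etype: _constant_table(etype, 1.0) for etype in small_model.lr_tables
        }
        model = ep.TrainedModel(
            config=small_model.config,
            prior=small_model.prior,
            enriched=small_model.enriched,
            motifs=small_model.motifs,
            lr_tables=flat,
            fingerprint=small_model.fingerprint,
        )
        for pair in sorted(small_world.gold.positives)[:10]:
            pred = ep.predict(pair, model, small_world.inputs())
            assert pred.score == pytest.approx(0.5)

    def test_prediction_invariants(self, small_world, small_model):
        inputs = small_world.inputs()
        for pair in sorted(small_world.gold.positives)[:20]:
            pred = ep.predict(pair, small_model, inputs)
            assert pred.lr_comp == pytest.approx(
                math.prod(pred.per_type_lr.values()) if pred.per_type_lr else 1.0
            )
            assert pred.o_post == pytest.approx(
                small_model.prior.o_prior * pred.lr_comp
            )
            assert 0 < pred.score < 1

    def test_training_separation_direction(self, small_world, small_model):
        inputs = small_world.inputs()
        pos = sorted(
            ep.predict(p, small_model, inputs, with_provenance=False).lr_comp
            for p in small_world.gold.positives
        )
        neg = sorted(
            ep.predict(p, small_model, inputs, with_provenance=False).lr_comp
            for p in small_world.gold.negatives
        )
        assert pos[len(pos) // 2] > neg[len(neg) // 2]


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


class TestCalibrateEnrichmentLR:
    def test_planted_signal_top_bins_informative(self, small_world):
        gold = small_world.gold
        table, lr_table = ep.calibrate_enrichment_lr(
            gold.positives, gold.negatives, small_world.domain_ann, seed=0
        )
        planted = {
            tuple(v) for v in small_world.truth["planted_domain_pairs"].values()
        }
        assert planted & set(table)
        occupied = [b for b in lr_table.bins if b.tp_f > 0]
        assert max(b.lr for b in occupied) > 1.0

    def test_label_shuffled_null_lr_near_one(self, small_world):
        rng = np.random.default_rng(1)
        gold = small_world.gold
        ann = small_world.domain_ann
        proteins = sorted(ann.proteins())
        perm = rng.permutation(len(proteins))
        shuffled = ep.AnnotationMap(
            "domain",
            {proteins[i]: ann.labels(proteins[perm[i]]) for i in range(len(proteins))},
        )
        _, lr_table = ep.calibrate_enrichment_lr(
            gold.positives, gold.negatives, shuffled, seed=1
        )
        for b in lr_table.bins:
            if b.tp_f + b.fp_f >= 30:
                assert 0.55 <= b.lr <= 1.8

    def test_determinism(self, small_world):
        gold = small_world.gold
        args = (gold.positives, gold.negatives, small_world.domain_ann)
        t1, l1 = ep.calibrate_enrichment_lr(*args, seed=7)
        t2, l2 = ep.calibrate_enrichment_lr(*args, seed=7)
        assert t1 == t2
        assert l1 == l2


# ---------------------------------------------------------------------------
# model archive
# ---------------------------------------------------------------------------


class TestModelArchive:
    def test_roundtrip_rescores_identically(self, tmp_path, small_world, small_model):
        ep.save_model(small_model, tmp_path / "model")
        reloaded = ep.load_model(tmp_path / "model")
        assert reloaded.fingerprint == small_model.fingerprint
        inputs = small_world.inputs()
        pairs = (sorted(small_world.gold.positives) + sorted(small_world.gold.negatives))[:100]
        for pair in pairs:
            a = ep.predict(pair, small_model, inputs, with_provenance=False)
            b = ep.predict(pair, reloaded, inputs, with_provenance=False)
            assert a.lr_comp == b.lr_comp  # bit-identical

    def test_archive_is_byte_stable(self, tmp_path, small_model):
        ep.save_model(small_model, tmp_path / "m1")
        ep.save_model(small_model, tmp_path / "m2")
        for name in ("model.json", "lr_tables.tsv", "enriched_domain.tsv",
                     "enriched_go.tsv", "motifs.tsv"):
            assert (tmp_path / "m1" / name).read_bytes() == (
                tmp_path / "m2" / name
            ).read_bytes()

    def test_schema_version_checked(self, tmp_path, small_model):
        import json

        ep.save_model(small_model, tmp_path / "m")
        manifest = json.loads((tmp_path / "m" / "model.json").read_text())
        manifest["schema_version"] = 99
        (tmp_path / "m" / "model.json").write_text(json.dumps(manifest))
        with pytest.raises(ValueError):
            ep.load_model(tmp_path / "m")

    def test_train_determinism(self, small_world):
        m1 = ep.train_model(small_world.gold, small_world.inputs(), seed=3)
        m2 = ep.train_model(small_world.gold, small_world.inputs(), seed=3)
        assert m1.lr_tables == m2.lr_tables
        assert m1.enriched == m2.enriched
        assert {k: [str(m) for m in v] for k, v in m1.motifs.items()} == {
            k: [str(m) for m in v] for k, v in m2.motifs.items()
        }


# ---------------------------------------------------------------------------
# scan
# ---------------------------------------------------------------------------


class TestScan:
    def test_enumeration_count_small(self):
        e3s = [f"E{i}" for i in range(3)]
        prots = [f"P{i}" for i in range(4)] + ["E0"]
        n = sum(1 for _ in enumerate_scan_pairs(e3s, prots, include_self=True))
        assert n == 15
        n_excl = sum(1 for _ in enumerate_scan_pairs(e3s, prots))
        assert n_excl == 14

    def test_toy_scan_equals_exhaustive_predict(self, small_world, small_model):
        inputs = small_world.inputs()
        e3s = small_world.e3_ids[:3]
        prots = small_world.protein_ids[:4]
        result = ep.proteome_scan(e3s, prots, small_model, inputs, min_score=0.0)
        assert result.n_enumerated + result.n_self_excluded == len(e3s) * len(prots)
        expected = {}
        for e3 in e3s:
            for prot in prots:
                if e3 == prot:
                    continue
                pred = ep.predict(
                    ep.ESIPair(e3, prot), small_model, inputs, with_provenance=False
                )
                expected[(e3, prot)] = pred.score
        got = {(p.pair.e3, p.pair.substrate): p.score for p in result.predictions}
        assert got == expected
        scores = [p.score for p in result.predictions]
        assert scores == sorted(scores, reverse=True)

    def test_min_score_one_emits_nothing(self, small_world, small_model):
        result = ep.proteome_scan(
            small_world.e3_ids[:2],
            small_world.protein_ids[:5],
            small_model,
            small_world.inputs(),
            min_score=1.0,
        )
        assert result.predictions == []

    def test_empty_lists_error(self, small_model, small_world):
        with pytest.raises(ValueError):
            ep.proteome_scan([], ["P1"], small_model, small_world.inputs())
        with pytest.raises(ValueError):
            ep.proteome_scan(["E1"], [], small_model, small_world.inputs())
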