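import numpy as np
import pandas as pd
import pytest

from assocmod.dataio import Dataset, SamplePanel
from assocmod.module_builder import (AnalysisContext, BuilderConfig,
                                     CandidateAssociation, assemble_modules,
                                     benchmark_config, build_modules,
                                     exclude_explained_tfs, find_mediators,
                                     pairwise_screen, replaceability_filter)
from assocmod.synthetic_data import conditional_probs
from conftest import make_context

CFG = benchmark_config()


def _truth_by_type(truth):
    return {m["driver_type"]: m for m in truth.modules}


class TestPairwiseScreen:
    def test_planted_cis_effect_power(self, bench_ctx):
        ctx, truth = bench_ctx
        cands = pairwise_screen(ctx, "cis_cnv", config=CFG)
        planted = set(_truth_by_type(truth)["cis_cnv"]["passengers"])
        hit = {c.passenger_id for c in cands} & planted
        assert len(hit) >= 0.8 * len(planted)

    def test_cis_only_tests_local_pairs(self, bench_ctx):
        ctx, _ = bench_ctx
        for c in pairwise_screen(ctx, "cis_cnv", config=CFG):
            assert ctx.gene_to_segment.get(c.passenger_id) == c.driver_id
            assert c.sign == 1

    def test_methylation_sign_convention(self, bench_ctx):
        ctx, _ = bench_ctx
        assert all(c.sign == -1
                   for c in pairwise_screen(ctx, "methylation", config=CFG))

    def test_empty_driver_type(self, bench_ctx):
        ctx, _ = bench_ctx
        ids, Q = ctx.passengers["mrna"]
        stripped = Dataset(panel=ctx.dataset.panel,
                           tracks={"mrna": ctx.dataset.tracks["mrna"]},
                           annotations=ctx.dataset.annotations)
        stripped.quantize()
        ctx2 = AnalysisContext(stripped, [], {})
        assert pairwise_screen(ctx2, "mutation", config=CFG) == []


class TestFindMediators:
    def test_recovers_planted_mediator(self, bench_ctx):
        ctx, truth = bench_ctx
        tm = _truth_by_type(truth)["trans_cnv"]
        tf = tm["regulators"][0]
        seg = ctx.gene_to_segment[tf]
        found = 0
        for p in tm["passengers"]:
            meds = find_mediators(ctx, seg, p, config=CFG)
            if any(m[0] == tf for m in meds):
                found += 1
        assert found >= 0.8 * len(tm["passengers"])

    def test_local_passenger_is_an_error(self, bench_ctx):
        ctx, truth = bench_ctx
        tf = _truth_by_type(truth)["trans_cnv"]["regulators"][0]
        seg = ctx.gene_to_segment[tf]
        with pytest.raises(ValueError, match="cis"):
            find_mediators(ctx, seg, tf, config=CFG)

    def test_unrelated_passenger_gets_no_mediator(self, bench_ctx):
        ctx, truth = bench_ctx
        tf = _truth_by_type(truth)["trans_cnv"]["regulators"][0]
        seg = ctx.gene_to_segment[tf]
        assert find_mediators(ctx, seg, "decoy_mrna_1", config=CFG) == []


class TestExcludeExplainedTfs:
    def test_trivial_cases(self):
        aber = [CandidateAssociation("TF1", "mrna", "cis_cnv", "seg_1", 1,
                                     1.0, 20.0, 1e-5, 1)]
        assert exclude_explained_tfs(["TF1", "TF2"], aber) == ["TF2"]
        assert exclude_explained_tfs(["TF1"], []) == ["TF1"]

    def test_planted_cnv_driven_tf_excluded(self, bench_ctx):
        """The trans-module mediator is CNV-driven; the exogenous TF is not."""
        ctx, truth = bench_ctx
        by_type = _truth_by_type(truth)
        med = by_type["trans_cnv"]["regulators"][0]
        exo = by_type["tf"]["driver"]
        aber = []
        for dt in ("cis_cnv", "mutation", "methylation"):
            aber += pairwise_screen(ctx, dt, config=CFG)
        kept = exclude_explained_tfs(ctx.tf_ids, aber)
        assert med not in kept
        assert exo in kept


def _redundancy_context(seed):
    """Passenger driven by TF A; B is A's profile plus small noise."""
    rng = np.random.default_rng(seed)
    n = 60
    z = rng.normal(size=n)
    ranks = np.argsort(np.argsort(z))
    x = np.where(ranks < n // 3, -1.0, np.where(ranks >= n - n // 3, 1.0, 0.0))
    y = np.array([rng.choice((-1.0, 0.0, 1.0), p=conditional_probs(v, 1.5, 1))
                  for v in x])
    # B is a corrupted copy of A: still screens in, but strictly dominated
    rows = {
        "TFA": z + rng.normal(0, 0.05, n),
        "TFB": z + rng.normal(0, 0.6, n),
        "X": y + rng.normal(0, 0.4, n),
    }
    panel = SamplePanel(tuple(f"s{i}" for i in range(n)), tuple("T") * n)
    ds = Dataset(panel=panel,
                 tracks={"mrna": pd.DataFrame.from_dict(
                     rows, orient="index", columns=list(panel.sample_ids))},
                 tf_ids=frozenset({"TFA", "TFB"}))
    ds.quantize()
    return AnalysisContext(ds, [], {})


def _tf_candidate(ctx, tf, passenger="X"):
    from assocmod import assoc_model as am
    x = ctx.driver_profile("tf", tf)
    q = ctx.passenger_q("mrna", passenger)
    lam, llr, p, _ = am.screen_single_driver(x, q, 1)
    return CandidateAssociation(passenger, "mrna", "tf", tf, 1,
                                float(lam[0]), float(llr[0]), float(p[0]), 3)


class TestReplaceabilityFilter:
    def test_single_candidate_retained(self):
        ctx = _redundancy_context(3)
        c = _tf_candidate(ctx, "TFA")
        assert replaceability_filter([c], ctx) == [c]

    def test_noisy_copy_removed_original_kept(self):
        removed_b = 0
        for seed in range(5):
            ctx = _redundancy_context(seed)
            cands = [_tf_candidate(ctx, "TFA"), _tf_candidate(ctx, "TFB")]
            kept = {c.driver_id for c in replaceability_filter(cands, ctx)}
            if kept == {"TFA"}:
                removed_b += 1
        assert removed_b >= 4

    def test_independent_drivers_both_kept(self):
        rng = np.random.default_rng(9)
        n = 60
        za, zb = rng.normal(size=n), rng.normal(size=n)
        xa, xb = np.sign(za) * (np.abs(za) > 0.43), np.sign(zb) * (np.abs(zb) > 0.43)
        y = np.array([rng.choice(
            (-1.0, 0.0, 1.0),
            p=np.exp(1.2 * (a + b) * np.array([-1, 0, 1])) /
            np.exp(1.2 * (a + b) * np.array([-1, 0, 1])).sum())
            for a, b in zip(xa, xb)])
        rows = {"TFA": za, "TFB": zb, "X": y + rng.normal(0, 0.4, n)}
        panel = SamplePanel(tuple(f"s{i}" for i in range(n)), tuple("T") * n)
        ds = Dataset(panel=panel, tracks={"mrna": pd.DataFrame.from_dict(
            rows, orient="index", columns=list(panel.sample_ids))},
            tf_ids=frozenset({"TFA", "TFB"}))
        ds.quantize()
        ctx = AnalysisContext(ds, [], {})
        cands = [_tf_candidate(ctx, "TFA"), _tf_candidate(ctx, "TFB")]
        kept = {c.driver_id for c in replaceability_filter(cands, ctx)}
        assert kept == {"TFA", "TFB"}

    def test_idempotent(self, bench_ctx):
        ctx, _ = bench_ctx
        cands = []
        for dt in ("mutation", "methylation", "mirna", "tf"):
            cands += pairwise_screen(ctx, dt, config=CFG)
        once = replaceability_filter(cands, ctx, config=CFG)
        twice = replaceability_filter(once, ctx, config=CFG)
        assert {(c.passenger_id, c.driver_type, c.driver_id, c.sign) for c in once} \
            == {(c.passenger_id, c.driver_type, c.driver_id, c.sign) for c in twice}


class TestAssembleModules:
    def _cand(self, passenger, driver="D", dtype="mutation", sign=1):
        return CandidateAssociation(passenger, "mrna", dtype, driver, sign,
                                    1.0, 20.0, 1e-6, 2)

    def test_size_rule(self, bench_ctx):
        ctx, _ = bench_ctx
        nine = [self._cand(f"p{i}") for i in range(9)]
        assert assemble_modules(nine, ctx) == []
        ten = [self._cand(f"p{i}") for i in range(10)]
        mods = assemble_modules(ten, ctx)
        assert len(mods) == 1 and mods[0].size == 10 and mods[0].sign == 1

    def test_end_to_end_recovery_on_benchmark(self, bench_ctx):
        ctx, truth = bench_ctx
        mods, _ = build_modules(ctx, CFG)
        matched = set()
        for t in truth.modules:
            tp = set(t["passengers"])
            best_j, best = 0.0, None
            for m in mods:
                if m.driver_type != t["driver_type"] or m.sign != t["sign"]:
                    continue
                j = len(set(m.passengers) & tp) / len(set(m.passengers) | tp)
                if j > best_j:
                    best_j, best = j, m
            assert best_j >= 0.7, t["driver_type"]
            matched.add(best.module_id)
            if t["driver_type"] == "trans_cnv":
                assert set(t["regulators"]) <= set(best.regulators)
        assert len([m for m in mods if m.module_id not in matched]) <= 1

    def test_module_invariants(self, bench_ctx):
        ctx, _ = bench_ctx
        mods, retained = build_modules(ctx, CFG)
        sign_ok = {"cis_cnv": {1}, "methylation": {-1}, "mirna": {-1},
                   "mutation": {1, -1}, "tf": {1, -1}, "trans_cnv": {1, -1}}
        for m in mods:
            assert m.size >= 10
            assert m.sign in sign_ok[m.driver_type]
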