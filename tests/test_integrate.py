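"""Set-logic integrations against brute-force rule oracles, plus monotonicity."""

import numpy as np
import pandas as pd
import pytest

from chemosig import annotate, differential, integrate
from chemosig.differential import DMRecord, DEResult, ExpressionRecord
from chemosig.io import MethylationProfile, TargetPredictionSet
from chemosig.simulate import simulate_dataset
from tests.conftest import small_config


def _de(directions: dict[str, str]) -> DEResult:
    recs = []
    for fid, d in directions.items():
        lfc = {"up": 2.0, "down": -2.0, "unchanged": 0.0}[d]
        fdr = 1e-6 if d != "unchanged" else 0.5
        recs.append(ExpressionRecord(fid, 10, 40, 1.0, 4.0, lfc, fdr, fdr, d))
    return DEResult(recs)


def _dmr(gene, kind, direction, significant=True, delta=None):
    delta = delta if delta is not None else (0.35 if direction == "hyper" else -0.35)
    return DMRecord(f"{gene}:{kind}", gene, kind, 10, delta, 1e-4, direction, significant)


class TestConsensus:
    def test_spec_fixture_matches_set_algebra(self):
        sets = [
            TargetPredictionSet("A", {("m1", "g1"), ("m1", "g2")}),
            TargetPredictionSet("B", {("m1", "g1")}),
            TargetPredictionSet("C", {("m1", "g2"), ("m2", "g3")}),
        ]
        cm = integrate.consensus_targets(sets, min_sources=2)
        # brute-force oracle: pairwise unions of intersections
        all_pairs = set().union(*(s.pairs for s in sets))
        oracle = {
            p for p in all_pairs if sum(p in s.pairs for s in sets) >= 2
        }
        assert set(cm.pairs) == oracle == {("m1", "g1"), ("m1", "g2")}

    def test_multiplicity_counts_sources_not_rows(self):
        sets = [
            TargetPredictionSet("A", {("m1", "g1")}),
            TargetPredictionSet("B", {("m1", "g1")}),
            TargetPredictionSet("C", {("m1", "g1")}),
        ]
        cm = integrate.consensus_targets(sets)
        assert cm.pairs[("m1", "g1")] == 3

    def test_min_sources_exceeding_sources_rejected(self):
        sets = [TargetPredictionSet("A", set()), TargetPredictionSet("B", set())]
        with pytest.raises(ValueError):
            integrate.consensus_targets(sets, min_sources=3)


class TestMethExpr:
    def test_sign_rule_enumeration(self):
        """5-gene fixture: retention equals brute-force application of the rule."""
        gene_dirs = {"g1": "up", "g2": "up", "g3": "down", "g4": "down", "g5": "up"}
        dmr_dirs = {"g1": "hypo", "g2": "hyper", "g3": "hyper", "g4": "hypo", "g5": "hypo"}
        dmrs = [_dmr(g, "promoter", d) for g, d in dmr_dirs.items()]
        de = _de(gene_dirs)
        got = integrate.match_meth_expr(dmrs, de)["promoter"]
        oracle_anti = {
            g
            for g in gene_dirs
            if (dmr_dirs[g] == "hyper" and gene_dirs[g] == "down")
            or (dmr_dirs[g] == "hypo" and gene_dirs[g] == "up")
        }
        assert got == oracle_anti == {"g1", "g3", "g5"}
        got_pos = integrate.match_meth_expr(dmrs, de, sign="pos")["promoter"]
        assert got_pos == set(gene_dirs) - oracle_anti

    def test_insignificant_dmr_ignored(self):
        dmrs = [_dmr("g1", "promoter", "hypo", significant=False)]
        assert integrate.match_meth_expr(dmrs, _de({"g1": "up"}))["promoter"] == set()


class TestMirnaExpr:
    def test_pair_requires_map_membership_and_opposition(self):
        cm = integrate.ConsensusTargetMap({("m1", "g1"): 2}, 2)
        de_m = _de({"m1": "up", "m2": "up"})
        de_g = _de({"g1": "down", "g2": "down"})
        assert integrate.match_mirna_expr(de_m, de_g, cm) == [("m1", "g1")]
        # same direction → excluded
        assert integrate.match_mirna_expr(de_m, _de({"g1": "up"}), cm) == []
        # empty DE miRNA list → empty result
        assert integrate.match_mirna_expr(_de({}), de_g, cm) == []


class TestMirnaMeth:
    def test_overall_meth_diff_weighted_by_coverage(self):
        depths = [10, 20, 10]
        beta_a = [0.5, 0.8, 0.3]
        beta_b = [0.3, 0.4, 0.3]  # diffs −0.2, −0.4, 0.0
        positions = [5001, 5051, 5101]  # 1-based → 0-based 5000, 5050, 5100

        def prof(name, betas):
            df = pd.DataFrame(
                {
                    "chrom": "chr1",
                    "pos": positions,
                    "strand": "+",
                    "context": "CpG",
                    "meth_reads": [round(b * d) for b, d in zip(betas, depths)],
                    "total_reads": depths,
                }
            )
            return MethylationProfile(name, df)

        a, b = prof("A", beta_a), prof("B", beta_b)
        windows = annotate.mirna_tss_windows(
            [__import__("chemosig").io.GeneModel("m1", "chr1", "+", 5050, [])], flank=2000
        )
        annotate.assign_cpgs(windows, a)
        calls = integrate.match_mirna_meth(
            _de({"m1": "up"}), a, b, windows,
            mirna_tss={"m1": 5050},
            effect_min=0.05, p_max=1.01, min_cpgs=3, min_depth=1,
        )
        (call,) = calls
        # hand computation: (10·−0.2 + 20·−0.4 + 10·0) / 40 = −0.25
        assert call.overall_meth_diff == pytest.approx(-0.25, abs=1e-9)
        assert call.overall_meth_diff_unweighted == pytest.approx(-0.2, abs=1e-9)
        assert sorted(call.tss_offsets) == [-50, 0, 50]

    def test_mirna_without_significant_window_dmr_excluded(self, small_ds):
        windows = annotate.mirna_tss_windows(small_ds.mirnas)
        annotate.assign_cpgs(windows, small_ds.profiles["WT"])
        shared = differential.filter_sites(list(small_ds.profiles.values()))
        de_m = differential.test_de(small_ds.mirna, "WT", "R1")
        calls = integrate.match_mirna_meth(
            de_m, small_ds.profiles["WT"], small_ds.profiles["R1"], windows,
            shared_sites=shared,
        )
        called = {c.mirna_id for c in calls}
        truth = set(small_ds.truth.meth_mirnas["R1"])
        assert truth <= called  # planted meth-miRNAs recovered
        for c in calls:
            assert c.window_dmrs  # every call carries ≥1 significant window DMR

    def test_direction_stratified_summary_signs(self, small_ds):
        """Up-regulated miRNAs show decreased TSS methylation and vice versa."""
        windows = annotate.mirna_tss_windows(small_ds.mirnas)
        annotate.assign_cpgs(windows, small_ds.profiles["WT"])
        shared = differential.filter_sites(list(small_ds.profiles.values()))
        de_m = differential.test_de(small_ds.mirna, "WT", "R1")
        calls = integrate.match_mirna_meth(
            de_m, small_ds.profiles["WT"], small_ds.profiles["R1"], windows,
            shared_sites=shared,
        )
        summary = integrate.summarize_mirna_meth(calls)
        means = dict(zip(summary["mirna_direction"], summary["mean_meth_diff"]))
        if not np.isnan(means["up"]):
            assert means["up"] < 0
        if not np.isnan(means["down"]):
            assert means["down"] > 0


class TestTripleIntegration:
    def _fixture(self):
        gene_dirs = {
            "g1": "down", "g2": "up", "g3": "down", "g4": "up", "g5": "down", "g6": "up",
        }
        dmrs = [
            _dmr("g1", "promoter", "hyper"),   # anti ✓
            _dmr("g2", "promoter", "hypo"),    # anti ✓
            _dmr("g3", "promoter", "hypo"),    # same sign ✗
            _dmr("g4", "cds", "hypo"),         # gene body → excluded ✗
            _dmr("g5", "promoter", "hyper"),   # anti ✓ but no miRNA
        ]
        mirna_dirs = {"m1": "up", "m2": "down", "m3": "up"}
        cm = integrate.ConsensusTargetMap(
            {("m1", "g1"): 2, ("m2", "g2"): 3, ("m1", "g3"): 2, ("m3", "g4"): 2},
            2,
        )
        return _de(gene_dirs), dmrs, _de(mirna_dirs), cm

    def test_planted_fixture_matches_brute_force_rule(self):
        de_g, dmrs, de_m, cm = self._fixture()
        calls = integrate.triple_integrate(de_g, dmrs, de_m, cm)
        got = {c.gene_id for c in calls}

        # brute-force oracle: exhaustive application of the three conditions
        gene_dir = de_g.directions()
        mirna_dir = de_m.directions()
        opp = {"up": "down", "down": "up", "hyper": "down", "hypo": "up"}
        oracle = set()
        for g, gd in gene_dir.items():
            has_prom = any(
                r.gene_or_mirna_id == g and r.kind == "promoter" and r.significant
                and opp[r.direction] == gd
                for r in dmrs
            )
            has_mirna = any(
                g2 == g and m in mirna_dir and opp[mirna_dir[m]] == gd
                for (m, g2) in cm.pairs
            )
            if has_prom and has_mirna:
                oracle.add(g)
        assert got == oracle == {"g1", "g2"}

    def test_call_evidence_invariants(self):
        de_g, dmrs, de_m, cm = self._fixture()
        for c in integrate.triple_integrate(de_g, dmrs, de_m, cm):
            assert c.regulating_mirnas
            assert (c.promoter_dmr.median_beta_diff > 0) == (c.gene_direction == "down")
            for _, mdir in c.regulating_mirnas:
                assert mdir != c.gene_direction

    def test_subset_of_pairwise_integrations(self, small_ds):
        """triple ⊆ promoter-anticorrelated ∩ genes in miRNA-expression pairs."""
        ds = small_ds
        shared = differential.filter_sites(list(ds.profiles.values()))
        proms = annotate.derive_promoters(ds.genes)
        feats = annotate.gene_feature_regions(ds.genes)
        annotate.assign_cpgs(proms + feats, ds.profiles["WT"])
        dmrs = differential.call_dmrs(
            ds.profiles["WT"], ds.profiles["R1"], proms + feats, shared_sites=shared
        )
        de_g = differential.test_de(ds.mrna, "WT", "R1")
        de_m = differential.test_de(ds.mirna, "WT", "R1")
        cm = integrate.consensus_targets(ds.target_sets)
        triple = {c.gene_id for c in integrate.triple_integrate(de_g, dmrs, de_m, cm)}
        prom_anti = integrate.match_meth_expr(dmrs, de_g)["promoter"]
        pair_genes = {g for _, g in integrate.match_mirna_expr(de_m, de_g, cm)}
        assert triple <= prom_anti & pair_genes


class TestIntersect:
    def _calls(self, genes):
        de = _de({g: "up" for g in genes})
        dmr = _dmr(genes[0], "promoter", "hypo") if genes else None
        return [
            integrate.RegulatoryCall(g, "up", _dmr(g, "promoter", "hypo"), [("m", "down")])
            for g in genes
        ]

    def test_venn_counts(self):
        common, venn = integrate.intersect_comparisons(
            self._calls(["g1", "g2", "g3"]), self._calls(["g2", "g3", "g4"])
        )
        assert common == {"g2", "g3"}
        assert venn == {"a_only": 1, "b_only": 1, "both": 2}

    def test_disjoint_and_identical(self):
        a = self._calls(["g1"])
        assert integrate.intersect_comparisons(a, self._calls(["g2"]))[0] == set()
        assert integrate.intersect_comparisons(a, a)[0] == {"g1"}


class TestThresholdMonotonicity:
    def test_relaxing_thresholds_never_shrinks_outputs(self):
        """Looser effect/p/FDR/lfc/min_sources cuts can only grow every set."""
        ds = simulate_dataset(small_config(), seed=19)
        shared = differential.filter_sites(list(ds.profiles.values()))
        proms = annotate.derive_promoters(ds.genes)
        feats = annotate.gene_feature_regions(ds.genes)
        annotate.assign_cpgs(proms + feats, ds.profiles["WT"])

        def run(effect_min, p_max, fdr_max, lfc_min, min_sources):
            dmrs = differential.call_dmrs(
                ds.profiles["WT"], ds.profiles["R1"], proms + feats,
                shared_sites=shared, effect_min=effect_min, p_max=p_max,
            )
            de_g = differential.test_de(ds.mrna, "WT", "R1", fdr_max=fdr_max, lfc_min=lfc_min)
            de_m = differential.test_de(ds.mirna, "WT", "R1", fdr_max=fdr_max, lfc_min=lfc_min)
            cm = integrate.consensus_targets(ds.target_sets, min_sources=min_sources)
            triple = {c.gene_id for c in integrate.triple_integrate(de_g, dmrs, de_m, cm)}
            prom = integrate.match_meth_expr(dmrs, de_g)["promoter"]
            pairs = set(integrate.match_mirna_expr(de_m, de_g, cm))
            return triple, prom, pairs

        strict = run(0.20, 0.01, 0.001, 1.0, 2)
        loose = run(0.10, 0.05, 0.01, 0.5, 1)
        for s, l in zip(strict, loose):
            assert s <= l
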