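"""End-to-end orchestration: simulate → filter/DMR → DE → integrate → signature
→ classify → survival, with a validated config and a JSON run summary.

Every intermediate table is written as TSV under ``outdir``; the run summary
records thresholds, seed, and the row counts of each written table.  A stage
failure leaves partial outputs plus a ``.partial`` marker naming the stage.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate, differential, integrate, io, signature, simulate, survival

__all__ = ["RunConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All knobs of a pipeline run; unknown keys and out-of-range values reject."""

    outdir: str = "chemosig_run"
    seed: int = 0
    simulate: bool = True
    # input paths (used when simulate = False)
    cpg_wt: str | None = None
    cpg_r1: str | None = None
    cpg_r2: str | None = None
    gene_models: str | None = None
    mirna_models: str | None = None
    mrna_counts: str | None = None
    mirna_counts: str | None = None
    targets: list[str] = field(default_factory=list)
    clinical: str | None = None
    # thresholds
    min_depth: int = 4
    effect_min: float = 0.20
    p_max: float = 0.01
    min_cpgs: int = 5
    fdr_max: float = 0.001
    lfc_min: float = 1.0
    pseudocount: float = 1.0
    min_sources: int = 2
    promoter_upstream: int = 2000
    promoter_downstream: int = 500
    tss_flank: int = 2000
    selection_p_max: float = 0.10
    n_metagenes: int | None = None
    prior_precision: float = 1.0
    context: str = "CpG"
    label_map: dict = field(default_factory=dict)
    # simulation overrides (SimulationConfig field names)
    sim: dict = field(default_factory=dict)
    # cohort generation (simulate mode)
    cohort_effect_sd: float = 2.0
    cohort_hazard_ratio: float = 3.0
    cohort_censor_rate: float = 0.3
    cohort_n_sensitive: int = 13
    cohort_n_resistant: int = 14

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def validate(self) -> None:
        checks = [
            (self.min_depth >= 1, "min_depth must be >= 1"),
            (0.0 <= self.effect_min <= 1.0, "effect_min must be in [0, 1]"),
            (0.0 < self.p_max <= 1.0, "p_max must be in (0, 1]"),
            (self.min_cpgs >= 1, "min_cpgs must be >= 1"),
            (0.0 < self.fdr_max <= 1.0, "fdr_max must be in (0, 1]"),
            (self.lfc_min >= 0.0, "lfc_min must be >= 0"),
            (self.pseudocount > 0.0, "pseudocount must be > 0"),
            (self.min_sources >= 1, "min_sources must be >= 1"),
            (self.promoter_upstream >= 0, "promoter_upstream must be >= 0"),
            (self.promoter_downstream >= 0, "promoter_downstream must be >= 0"),
            (self.tss_flank > 0, "tss_flank must be > 0"),
            (0.0 < self.selection_p_max <= 1.0, "selection_p_max must be in (0, 1]"),
            (self.n_metagenes is None or self.n_metagenes >= 1, "n_metagenes must be >= 1"),
            (self.prior_precision > 0.0, "prior_precision must be > 0"),
            (0.0 <= self.cohort_censor_rate < 1.0, "cohort_censor_rate must be in [0, 1)"),
            (self.cohort_hazard_ratio > 0.0, "cohort_hazard_ratio must be > 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)
        sim_known = {f.name for f in fields(simulate.SimulationConfig)}
        unknown = set(self.sim) - sim_known
        if unknown:
            raise ValueError(f"unknown sim config keys: {sorted(unknown)}")

    def sim_config(self) -> simulate.SimulationConfig:
        base = simulate.SimulationConfig(
            promoter_upstream=self.promoter_upstream,
            promoter_downstream=self.promoter_downstream,
            tss_flank=self.tss_flank,
        )
        for k, v in self.sim.items():
            setattr(base, k, v)
        return base


def _write(df: pd.DataFrame, path: Path, summary_counts: dict, key: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    summary_counts[key] = int(len(df))


def run_pipeline(config: RunConfig, log=None, upto: str | None = None) -> dict:
    """Execute the workflow (optionally only up to a named stage).

    ``upto`` ∈ {simulate, dmr, de, integrate, signature, classify, None};
    None (or "survival") runs everything.  Returns (and writes) the run
    summary.
    """
    log = log or (lambda msg: print(msg, file=sys.stderr))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "seed": config.seed,
        "thresholds": {
            k: getattr(config, k)
            for k in (
                "min_depth", "effect_min", "p_max", "min_cpgs", "fdr_max", "lfc_min",
                "pseudocount", "min_sources", "promoter_upstream", "promoter_downstream",
                "tss_flank", "selection_p_max", "prior_precision",
            )
        },
        "counts": {},
        "stages": [],
    }
    counts = summary["counts"]
    current_stage = "setup"

    def stage(name: str):
        nonlocal current_stage
        current_stage = name
        t0 = time.time()
        log(f"[chemosig] stage {name}")
        summary["stages"].append({"name": name, "started": t0})
        return t0

    def finalize() -> dict:
        summary["ok"] = True
        with open(outdir / "run_summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True, default=float)
        return summary

    try:
        # ------------------------------------------------------------ inputs
        if config.simulate:
            stage("simulate")
            sim_cfg = config.sim_config()
            ds = simulate.simulate_dataset(sim_cfg, seed=config.seed)
            genes, mirnas = ds.genes, ds.mirnas
            profiles = ds.profiles
            mrna, mirna_cm = ds.mrna, ds.mirna
            target_sets = ds.target_sets
            truth = ds.truth
            io.write_gene_models(genes, outdir / "gene_models.tsv")
            io.write_gene_models(mirnas, outdir / "mirna_models.tsv")
            for name, prof in profiles.items():
                io.write_cpg_report(prof, outdir / f"cpg_{name}.tsv")
            io.write_counts(mrna, outdir / "mrna_counts.tsv")
            io.write_counts(mirna_cm, outdir / "mirna_counts.tsv")
            for ts in target_sets:
                io.write_targets(ts, outdir / f"targets_{ts.source_name}.tsv")
            truth.to_json(outdir / "truth.json")
            counts["simulated_genes"] = len(genes)
            counts["simulated_mirnas"] = len(mirnas)
        else:
            stage("load")
            truth = None
            required = ["cpg_wt", "cpg_r1", "cpg_r2", "gene_models", "mirna_models",
                        "mrna_counts", "mirna_counts"]
            missing = [k for k in required if getattr(config, k) is None]
            if missing or len(config.targets) < 2:
                raise ValueError(f"simulate=False requires input paths; missing {missing}")
            profiles = {
                "WT": io.read_cpg_report(config.cpg_wt, sample="WT"),
                "R1": io.read_cpg_report(config.cpg_r1, sample="R1"),
                "R2": io.read_cpg_report(config.cpg_r2, sample="R2"),
            }
            genes = io.read_gene_models(config.gene_models)
            mirnas = io.read_gene_models(config.mirna_models)
            mrna = io.read_counts(config.mrna_counts)
            mirna_cm = io.read_counts(config.mirna_counts)
            target_sets = io.read_targets(config.targets)

        if upto == "simulate":
            return finalize()

        # ------------------------------------------------------- filter + DMR
        stage("filter")
        shared = differential.filter_sites(
            list(profiles.values()), min_depth=config.min_depth, context=config.context
        )
        counts["shared_sites"] = int(len(shared))

        stage("dmr")
        promoters = annotate.derive_promoters(
            genes, config.promoter_upstream, config.promoter_downstream
        )
        features = annotate.gene_feature_regions(genes)
        windows = annotate.mirna_tss_windows(mirnas, config.tss_flank)
        all_regions = promoters + features + windows
        wt = profiles["WT"]
        # one assignment pass serves every downstream region query
        annotate.assign_cpgs(all_regions, wt)
        dmr_results = {}
        for line in ("R1", "R2"):
            res = differential.call_dmrs(
                wt,
                profiles[line],
                promoters + features,
                shared_sites=shared,
                effect_min=config.effect_min,
                p_max=config.p_max,
                min_cpgs=config.min_cpgs,
            )
            dmr_results[line] = res
            _write(res.to_frame(), outdir / f"dmr_{line}_vs_WT.tsv", counts, f"dmr_{line}")
            counts[f"dmr_{line}_significant"] = len(res.significant)
            counts[f"dmr_{line}_skipped"] = len(res.skipped_regions)
        loc = differential.dmr_location_summary(
            [r for line in ("R1", "R2") for r in dmr_results[line].significant]
        )
        _write(loc, outdir / "dmr_location_summary.tsv", counts, "dmr_location_rows")
        if upto == "dmr":
            return finalize()

        # ------------------------------------------------------------------ DE
        stage("de")
        de_genes, de_mirnas = {}, {}
        for line in ("R1", "R2"):
            de_genes[line] = differential.test_de(
                mrna, "WT", line,
                fdr_max=config.fdr_max, lfc_min=config.lfc_min, pseudocount=config.pseudocount,
            )
            de_mirnas[line] = differential.test_de(
                mirna_cm, "WT", line,
                fdr_max=config.fdr_max, lfc_min=config.lfc_min, pseudocount=config.pseudocount,
            )
            _write(de_genes[line].to_frame(), outdir / f"de_mrna_{line}.tsv", counts, f"de_mrna_{line}")
            _write(de_mirnas[line].to_frame(), outdir / f"de_mirna_{line}.tsv", counts, f"de_mirna_{line}")
            counts[f"de_mrna_{line}_significant"] = len(de_genes[line].significant)
            counts[f"de_mirna_{line}_significant"] = len(de_mirnas[line].significant)
        if upto == "de":
            return finalize()

        # ----------------------------------------------------------- integrate
        stage("integrate")
        target_map = integrate.consensus_targets(target_sets, min_sources=config.min_sources)
        counts["consensus_pairs"] = len(target_map)
        mirna_tss = {m.gene_id: m.tss for m in mirnas}
        reg_calls = {}
        for line in ("R1", "R2"):
            matched = integrate.match_meth_expr(dmr_results[line], de_genes[line])
            body_pos = integrate.match_meth_expr(
                dmr_results[line], de_genes[line], kinds=("cds", "intron", "utr3"), sign="pos"
            )
            rows = [(k, g) for k, gs in matched.items() for g in sorted(gs)]
            rows += [("genebody_pos", g) for gs in body_pos.values() for g in sorted(gs)]
            _write(
                pd.DataFrame(rows, columns=["kind", "gene_id"]),
                outdir / f"meth_expr_{line}.tsv", counts, f"meth_expr_{line}",
            )
            pairs = integrate.match_mirna_expr(de_mirnas[line], de_genes[line], target_map)
            _write(
                pd.DataFrame(pairs, columns=["mirna_id", "gene_id"]),
                outdir / f"mirna_gene_pairs_{line}.tsv", counts, f"mirna_gene_pairs_{line}",
            )
            meth_calls = integrate.match_mirna_meth(
                de_mirnas[line], wt, profiles[line], windows,
                mirna_tss=mirna_tss, shared_sites=shared,
                effect_min=config.effect_min, p_max=config.p_max, min_cpgs=config.min_cpgs,
            )
            _write(
                pd.DataFrame(
                    [
                        (c.mirna_id, c.mirna_direction, c.overall_meth_diff,
                         c.overall_meth_diff_unweighted, len(c.window_dmrs))
                        for c in meth_calls
                    ],
                    columns=["mirna_id", "direction", "overall_meth_diff",
                             "overall_meth_diff_unweighted", "n_window_dmrs"],
                ),
                outdir / f"mirna_meth_{line}.tsv", counts, f"mirna_meth_{line}",
            )
            _write(
                integrate.summarize_mirna_meth(meth_calls),
                outdir / f"mirna_meth_summary_{line}.tsv", counts, f"mirna_meth_summary_{line}",
            )
            calls = integrate.triple_integrate(
                de_genes[line], dmr_results[line], de_mirnas[line], target_map
            )
            reg_calls[line] = calls
            _write(
                pd.DataFrame(
                    [
                        (c.gene_id, c.gene_direction, c.promoter_dmr.median_beta_diff,
                         c.promoter_dmr.p_value,
                         ";".join(f"{m}:{d}" for m, d in c.regulating_mirnas))
                        for c in calls
                    ],
                    columns=["gene_id", "direction", "promoter_median_beta_diff",
                             "promoter_p", "regulating_mirnas"],
                ),
                outdir / f"regulatory_calls_{line}.tsv", counts, f"regulatory_calls_{line}",
            )
        common, venn = integrate.intersect_comparisons(reg_calls["R1"], reg_calls["R2"])
        with open(outdir / "venn.json", "w") as fh:
            json.dump({"common_genes": sorted(common), **venn}, fh, indent=1, sort_keys=True)
        counts["double_regulated_common"] = len(common)
        if upto == "integrate":
            return finalize()

        # ----------------------------------------------------------- signature
        stage("signature")
        candidates = sorted(common) or sorted(
            {c.gene_id for line in ("R1", "R2") for c in reg_calls[line]}
        )
        if config.simulate:
            directions = {
                g: truth.de_genes[g]["direction"] for g in candidates if g in truth.de_genes
            }
            cohort = simulate.simulate_cohort(
                directions or {g: "up" for g in candidates},
                n_sensitive=config.cohort_n_sensitive,
                n_resistant=config.cohort_n_resistant,
                effect_sd=config.cohort_effect_sd,
                hazard_ratio=config.cohort_hazard_ratio,
                censor_rate=config.cohort_censor_rate,
                seed=config.seed,
            )
            io.write_clinical(cohort, outdir / "clinical.tsv")
        else:
            if config.clinical is None:
                raise ValueError("simulate=False requires a clinical table path")
            cohort = io.read_clinical(config.clinical, label_map=config.label_map or None)
        sig = signature.select_signature(
            candidates, cohort, p_max=config.selection_p_max
        )
        if not sig.genes:
            raise ValueError("signature selection retained no genes")
        _write(sig.to_frame(), outdir / "signature.tsv", counts, "signature_genes")
        if upto == "signature":
            return finalize()

        # ------------------------------------------------------------ classify
        stage("classify")
        params = signature.fit_bbr(
            cohort, genes=sig.genes,
            n_metagenes=config.n_metagenes, prior_precision=config.prior_precision,
        )
        bbr_results = signature.predict_bbr(params, cohort.table[sig.genes])
        hc_results, hc_acc, _ = signature.hclust_classify(cohort, sig.genes, sig.directions)
        nc_results = signature.centroid_classify(cohort, cohort.table[sig.genes], sig.genes)
        labels = cohort.labels
        pred_rows = []
        for res_list in (bbr_results, hc_results, nc_results):
            for r in res_list:
                pred_rows.append(
                    (r.patient_id, r.method, r.predicted,
                     "" if r.probability_resistant is None else r.probability_resistant,
                     labels.get(r.patient_id, "unknown"))
                )
        _write(
            pd.DataFrame(pred_rows, columns=["patient_id", "method", "predicted",
                                             "probability_resistant", "true_label"]),
            outdir / "predictions.tsv", counts, "predictions",
        )
        acc = {
            "bbr": float(np.mean([r.predicted == labels[r.patient_id] for r in bbr_results])),
            "hclust": hc_acc,
            "centroid": float(np.mean([r.predicted == labels[r.patient_id] for r in nc_results])),
        }
        summary["accuracy"] = acc
        with open(outdir / "classifier_params.json", "w") as fh:
            json.dump(
                {
                    "genes": params.genes,
                    "n_metagenes": params.n_metagenes,
                    "prior_precision": params.prior_precision,
                    "coef": [float(c) for c in params.coef],
                    "n_iter": params.n_iter,
                },
                fh, indent=1, sort_keys=True,
            )
        if upto == "classify":
            return finalize()

        # ------------------------------------------------------------ survival
        stage("survival")
        pred_by_patient = {r.patient_id: r.predicted for r in bbr_results}
        t = cohort.table
        groups = {}
        for cls in ("sensitive", "resistant"):
            pids = [p for p in cohort.patient_ids if pred_by_patient[p] == cls]
            groups[cls] = (
                t.loc[pids, "time"].to_numpy(dtype=float),
                t.loc[pids, "event"].to_numpy(dtype=int),
            )
        km_rows = []
        for cls, (tt, ee) in groups.items():
            if len(tt) == 0:
                continue
            curve = survival.km_estimate(tt, ee)
            frame = curve.to_frame()
            frame.insert(0, "group", cls)
            km_rows.append(frame)
        _write(
            pd.concat(km_rows, ignore_index=True) if km_rows
            else pd.DataFrame(columns=["group", "time", "at_risk", "events", "survival"]),
            outdir / "km_curves.tsv", counts, "km_rows",
        )
        if all(len(g[0]) > 0 for g in groups.values()):
            chi2, p = survival.logrank(groups["sensitive"], groups["resistant"])
            summary["logrank"] = {"chi_square": chi2, "p": p}
            pred = np.array([pred_by_patient[p_] for p_ in cohort.patient_ids])
            ev = t["event"].to_numpy(dtype=int)
            table2x2 = np.array(
                [
                    [int(((pred == "resistant") & (ev == 1)).sum()),
                     int(((pred == "resistant") & (ev == 0)).sum())],
                    [int(((pred == "sensitive") & (ev == 1)).sum()),
                     int(((pred == "sensitive") & (ev == 0)).sum())],
                ]
            )
            meta = survival.meta_or([table2x2], names=["cohort"])
            _write(meta.to_frame(), outdir / "forest.tsv", counts, "forest_rows")
            summary["pooled_or"] = meta.pooled_or
        else:
            summary["logrank"] = None
            log("[chemosig] survival: a predicted group is empty; log-rank skipped")

        return finalize()
    except Exception as exc:  # noqa: BLE001 — stage attribution for the CLI
        (outdir / ".partial").write_text(f"failed at stage: {current_stage}\n{exc}\n")
        raise StageError(current_stage, exc) from exc
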