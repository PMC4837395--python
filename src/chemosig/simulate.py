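"""Seeded synthetic-data generator with planted, queryable ground truth.

The generator emulates the study design every stage of the pipeline expects:
three "cell lines" on a toy linear chromosome — one chemosensitive baseline
(WT) and two chemoresistant lines (R1, R2) whose planted effects are shared
with probability ``share_prob`` (resistant lines derived from the same
parent respond similarly) — with

* CpG-level methylomes: per-region baseline β, per-site jitter shared across
  lines, per-line binomial read sampling at ~Poisson(20) depth; planted
  regions (promoters, gene-body features, miRNA TSS windows) shift β by
  ±``dmr_effect``;
* mRNA/miRNA count matrices: log-normal baseline abundance times a
  gene-level Gamma(1/dispersion) factor shared by all libraries (so each
  count is marginally negative-binomial with the configured dispersion while
  cross-library null differences carry only Poisson sampling noise — the
  regime the no-replicate exact test assumes), planted |log₂FC| on DE
  features;
* three target-prediction sources: true pairs appear in ≥2 sources, decoys
  in exactly one;
* a labelled patient cohort with class-separated signature-gene expression
  and exponential survival whose hazard depends on class.

Planted effects are wired so that double-regulated genes exist by
construction: each gets an anticorrelated promoter DMR and ≥1 anticorrelated
regulator miRNA present in ≥2 sources.  ``SimulationTruth`` records every
planted object; the per-line truth sets (including the double-regulated gene
lists) are *derived* from the planted components by the same sign rules the
pipeline applies, so chance combinations of background effects are counted
as truth rather than as false positives.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .annotate import (
    FeatureRegion,
    derive_promoters,
    gene_feature_regions,
    mirna_tss_windows,
)
from .io import CohortTable, CountMatrix, GeneModel, MethylationProfile, TargetPredictionSet

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "SimulatedDataset",
    "simulate_annotation",
    "plan_truth",
    "refresh_derived_truth",
    "simulate_methylomes",
    "simulate_expression",
    "simulate_target_map",
    "simulate_cohort",
    "simulate_dataset",
]

LINES = ("R1", "R2")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset (defaults = default run)."""

    n_genes: int = 300
    n_mirnas: int = 60
    chrom: str = "chrS"
    # methylation
    frac_dmr_regions: float = 0.10  # fraction of regions carrying a planted Δβ
    dmr_effect: float = 0.35
    cpgs_min: int = 20
    cpgs_max: int = 60
    depth_mean: float = 20.0
    site_jitter_sd: float = 0.05
    frac_non_cpg: float = 0.02
    share_prob: float = 0.8  # planted effect present in both resistant lines
    # annotation windows
    promoter_upstream: int = 2000
    promoter_downstream: int = 500
    tss_flank: int = 2000
    # expression
    lfc: float = 2.0
    dispersion: float = 0.05
    mrna_library: int = 10_000_000
    mirna_library: int = 20_000_000
    abundance_sigma: float = 1.2
    # planted structure
    n_double: int = 20
    n_regulator_mirnas: int = 12  # DE miRNAs available to wire to double genes
    n_bg_de_genes: int = 30
    n_bg_de_mirnas: int = 8
    n_meth_mirnas: int = 10  # DE miRNAs with a planted TSS-window DMR
    # targets
    n_neutral_true_pairs: int = 100
    decoy_rate: float = 0.5  # decoys per source, as a fraction of true pairs


@dataclass
class SimulationTruth:
    """Every planted object, plus per-line truth sets derived from them."""

    dmr_regions: dict  # region_id → {owner, kind, delta, lines}
    de_genes: dict  # gene → {direction, lfc, lines}
    de_mirnas: dict  # mirna → {direction, lfc, lines}
    true_pairs: list  # [(mirna, gene), ...] present in ≥2 sources
    double_genes: dict  # line → sorted gene list
    meth_mirnas: dict  # line → sorted miRNA list (DE + anticorrelated window DMR)
    clip_events: int = 0

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["true_pairs"] = [list(p) for p in self.true_pairs]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            payload = json.load(fh)
        payload["true_pairs"] = [tuple(p) for p in payload["true_pairs"]]
        return cls(**payload)


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(
    n_genes: int,
    n_mirnas: int,
    seed: int,
    chrom: str = "chrS",
    chrom_length: int | None = None,
) -> tuple[list[GeneModel], list[GeneModel]]:
    """Non-overlapping gene models plus intergenic miRNA TSSs on a toy chromosome.

    Each gene span is partitioned into utr5/cds/intron/cds/intron/utr3 tiles
    (mirrored on the − strand); gaps are large enough for promoter windows
    and miRNA ±2 kb windows not to collide with neighbouring gene bodies.
    """
    if n_genes < 1 or n_mirnas < 0:
        raise ValueError("need n_genes >= 1 and n_mirnas >= 0")
    rng = np.random.default_rng(seed)
    slots = ["gene"] * n_genes + ["mirna"] * n_mirnas
    rng.shuffle(slots)
    genes: list[GeneModel] = []
    mirnas: list[GeneModel] = []
    cursor = 10_000
    gi = mi = 0
    # fixed fractional tiling of a gene span, 5′→3′
    tiling = [("utr5", 0.10), ("cds", 0.20), ("intron", 0.15), ("cds", 0.20),
              ("intron", 0.15), ("utr3", 0.20)]
    for slot in slots:
        if slot == "gene":
            gi += 1
            span = int(rng.integers(3000, 6001))
            strand = "+" if rng.random() < 0.5 else "-"
            bounds = np.rint(np.cumsum([0] + [f for _, f in tiling]) * span).astype(int)
            kinds = [k for k, _ in tiling]
            if strand == "-":
                kinds = kinds[::-1]
            feats = [
                (kinds[j], cursor + int(bounds[j]), cursor + int(bounds[j + 1]))
                for j in range(len(kinds))
                if bounds[j + 1] > bounds[j]
            ]
            tss = cursor if strand == "+" else cursor + span - 1
            genes.append(GeneModel(f"G{gi:04d}", chrom, strand, tss, feats))
            cursor += span + int(rng.integers(6000, 9001))
        else:
            mi += 1
            strand = "+" if rng.random() < 0.5 else "-"
            tss = cursor + 2500
            mirnas.append(GeneModel(f"miR-{mi:03d}", chrom, strand, tss, []))
            cursor += 5001 + int(rng.integers(6000, 9001))
    if chrom_length is not None and cursor > chrom_length:
        raise ValueError(
            f"chromosome of length {chrom_length} too short for "
            f"{n_genes} genes + {n_mirnas} miRNAs (need {cursor})"
        )
    return genes, mirnas


def _simulation_regions(
    genes: list[GeneModel], mirnas: list[GeneModel], config: SimulationConfig
) -> list[FeatureRegion]:
    return (
        derive_promoters(genes, config.promoter_upstream, config.promoter_downstream)
        + gene_feature_regions(genes)
        + mirna_tss_windows(mirnas, config.tss_flank)
    )


# ---------------------------------------------------------------------------
# truth planning


def _draw_lines(rng: np.random.Generator, share_prob: float) -> list[str]:
    if rng.random() < share_prob:
        return list(LINES)
    return [LINES[int(rng.integers(0, 2))]]


def plan_truth(
    genes: list[GeneModel],
    mirnas: list[GeneModel],
    config: SimulationConfig,
    seed: int,
) -> SimulationTruth:
    """Wire the planted structure and derive the per-line truth sets."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    gene_ids = [g.gene_id for g in genes]
    mirna_ids = [m.gene_id for m in mirnas]
    regions = _simulation_regions(genes, mirnas, config)
    region_by_id = {r.region_id: r for r in regions}
    if config.n_double + config.n_bg_de_genes > len(gene_ids):
        raise ValueError("not enough genes for the requested planted structure")
    n_reg = config.n_regulator_mirnas
    if n_reg + config.n_bg_de_mirnas > len(mirna_ids):
        raise ValueError("not enough miRNAs for the requested planted structure")

    picked = [str(x) for x in rng.choice(gene_ids, size=config.n_double + config.n_bg_de_genes, replace=False)]
    double_intent = picked[: config.n_double]
    bg_de = picked[config.n_double:]

    picked_m = [str(x) for x in rng.choice(mirna_ids, size=n_reg + config.n_bg_de_mirnas, replace=False)]
    regulators = picked_m[:n_reg]
    bg_de_m = picked_m[n_reg:]

    de_genes: dict[str, dict] = {}
    de_mirnas: dict[str, dict] = {}
    dmr_regions: dict[str, dict] = {}
    true_pairs: set[tuple[str, str]] = set()

    # regulator miRNAs get fixed directions, half up / half down
    reg_dirs = {}
    for i, m in enumerate(regulators):
        d = "up" if i % 2 == 0 else "down"
        reg_dirs[m] = d
        sign = 1.0 if d == "up" else -1.0
        de_mirnas[m] = {"direction": d, "lfc": sign * config.lfc,
                        "lines": _draw_lines(rng, config.share_prob)}
    for m in bg_de_m:
        d = "up" if rng.random() < 0.5 else "down"
        sign = 1.0 if d == "up" else -1.0
        de_mirnas[m] = {"direction": d, "lfc": sign * config.lfc,
                        "lines": _draw_lines(rng, config.share_prob)}

    # double-regulated intent: DE gene + anticorrelated promoter DMR + wiring
    for g in double_intent:
        gdir = "up" if rng.random() < 0.5 else "down"
        gsign = 1.0 if gdir == "up" else -1.0
        lines = _draw_lines(rng, config.share_prob)
        de_genes[g] = {"direction": gdir, "lfc": gsign * config.lfc, "lines": lines}
        rid = f"{g}:promoter"
        dmr_regions[rid] = {
            "owner": g,
            "kind": "promoter",
            "delta": -gsign * config.dmr_effect,  # hypo for up-regulated genes
            "lines": _draw_lines(rng, config.share_prob),
        }
        want = "down" if gdir == "up" else "up"
        pool = [m for m in regulators if reg_dirs[m] == want]
        k = int(rng.integers(1, min(2, len(pool)) + 1))
        for m in rng.choice(pool, size=k, replace=False):
            true_pairs.add((str(m), g))

    for g in bg_de:
        gdir = "up" if rng.random() < 0.5 else "down"
        gsign = 1.0 if gdir == "up" else -1.0
        de_genes[g] = {"direction": gdir, "lfc": gsign * config.lfc,
                       "lines": _draw_lines(rng, config.share_prob)}

    # methylation-silenced (or -activated) miRNAs: window DMR opposite to DE
    de_m_ids = list(de_mirnas)
    n_meth = min(config.n_meth_mirnas, len(de_m_ids))
    for m in rng.choice(de_m_ids, size=n_meth, replace=False):
        msign = 1.0 if de_mirnas[m]["direction"] == "up" else -1.0
        dmr_regions[f"{m}:tss_window"] = {
            "owner": str(m),
            "kind": "mirna_tss_window",
            "delta": -msign * config.dmr_effect,
            "lines": _draw_lines(rng, config.share_prob),
        }

    # background DMRs on gene-body features, filled to the target fraction;
    # promoter-window overlaps are excluded so a promoter's methylation is
    # only ever shifted by its own planting
    n_target = int(round(config.frac_dmr_regions * len(regions)))
    eligible = []
    promoter_end = {}
    for g in genes:
        pr = region_by_id[f"{g.gene_id}:promoter"]
        promoter_end[g.gene_id] = (pr.start, pr.end)
    for r in regions:
        if r.region_id in dmr_regions or r.kind in ("promoter", "utr5", "mirna_tss_window"):
            continue
        ps, pe = promoter_end.get(r.owner_id, (0, 0))
        if r.start < pe and r.end > ps:  # overlaps the owner's promoter window
            continue
        eligible.append(r.region_id)
    n_bg = max(0, n_target - len(dmr_regions))
    for rid in rng.choice(eligible, size=min(n_bg, len(eligible)), replace=False):
        r = region_by_id[str(rid)]
        delta = config.dmr_effect * (1.0 if rng.random() < 0.5 else -1.0)
        dmr_regions[str(rid)] = {
            "owner": r.owner_id,
            "kind": r.kind,
            "delta": delta,
            "lines": _draw_lines(rng, config.share_prob),
        }

    truth = SimulationTruth(
        dmr_regions=dmr_regions,
        de_genes=de_genes,
        de_mirnas=de_mirnas,
        true_pairs=sorted(true_pairs),
        double_genes={},
        meth_mirnas={},
    )
    refresh_derived_truth(truth)
    return truth


def refresh_derived_truth(truth: SimulationTruth) -> SimulationTruth:
    """Recompute the per-line double-gene and meth-miRNA truth sets.

    Applies the pipeline's own sign rules to the planted components, so any
    chance combination of background plants counts as truth.  Must be re-run
    whenever ``true_pairs`` changes (e.g. after neutral pairs are added).
    """
    for line in LINES:
        gset = {g: v["direction"] for g, v in truth.de_genes.items() if line in v["lines"]}
        mset = {m: v["direction"] for m, v in truth.de_mirnas.items() if line in v["lines"]}
        doubles = []
        for g, gdir in gset.items():
            prom = truth.dmr_regions.get(f"{g}:promoter")
            if prom is None or line not in prom["lines"]:
                continue
            anti = (prom["delta"] > 0 and gdir == "down") or (prom["delta"] < 0 and gdir == "up")
            if not anti:
                continue
            want = "down" if gdir == "up" else "up"
            if any(m in mset and mset[m] == want for (m, g2) in truth.true_pairs if g2 == g):
                doubles.append(g)
        truth.double_genes[line] = sorted(doubles)
        mm = []
        for m, mdir in mset.items():
            w = truth.dmr_regions.get(f"{m}:tss_window")
            if w is None or line not in w["lines"]:
                continue
            anti = (w["delta"] > 0 and mdir == "down") or (w["delta"] < 0 and mdir == "up")
            if anti:
                mm.append(m)
        truth.meth_mirnas[line] = sorted(mm)
    return truth


# ---------------------------------------------------------------------------
# methylomes


def simulate_methylomes(
    genes: list[GeneModel],
    mirnas: list[GeneModel],
    truth: SimulationTruth,
    config: SimulationConfig,
    seed: int,
) -> dict[str, MethylationProfile]:
    """WT/R1/R2 CpG profiles; planted regions shift β by their Δ in their lines.

    Site positions, strands, contexts and per-site baseline β (region mean +
    jitter) are shared across the three profiles; read depths and methylated
    counts are drawn independently per profile.  β pushed outside [0,1] is
    clipped and counted in ``truth.clip_events``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    regions = _simulation_regions(genes, mirnas, config)
    region_by_id = {r.region_id: r for r in regions}

    planted: dict[str, list[tuple[int, int, float]]] = {line: [] for line in LINES}
    for rid, info in truth.dmr_regions.items():
        r = region_by_id[rid]
        for line in info["lines"]:
            planted[line].append((r.start, r.end, info["delta"]))
    for line in LINES:
        planted[line].sort()

    used: set[int] = set()
    positions: list[int] = []
    base_beta: list[float] = []
    for r in regions:
        n = int(rng.integers(config.cpgs_min, config.cpgs_max + 1))
        n = min(n, len(r))
        info = truth.dmr_regions.get(r.region_id)
        if info is None:
            mu = float(rng.beta(2.0, 2.0))
        elif info["delta"] > 0:
            mu = float(rng.uniform(0.15, 0.60))
        else:
            mu = float(rng.uniform(0.40, 0.85))
        pos = rng.choice(np.arange(r.start, r.end), size=n, replace=False)
        for p in pos:
            p = int(p)
            if p in used:
                continue
            used.add(p)
            positions.append(p)
            base_beta.append(mu)
    order = np.argsort(positions)
    positions_arr = np.array(positions)[order]
    base_arr = np.array(base_beta)[order]
    base_arr = np.clip(
        base_arr + rng.normal(0.0, config.site_jitter_sd, size=base_arr.size), 0.02, 0.98
    )
    strands = np.where(rng.random(base_arr.size) < 0.5, "+", "-")
    contexts = np.where(rng.random(base_arr.size) < config.frac_non_cpg, "CHH", "CpG")

    def _delta_for(line: str) -> np.ndarray:
        d = np.zeros(positions_arr.size)
        for s, e, delta in planted.get(line, []):
            mask = (positions_arr >= s) & (positions_arr < e)
            d[mask] += delta
        return d

    profiles = {}
    clip_events = 0
    for sample in ("WT",) + LINES:
        beta = base_arr + (_delta_for(sample) if sample != "WT" else 0.0)
        clipped = np.clip(beta, 0.0, 1.0)
        clip_events += int((clipped != beta).sum())
        depth = np.maximum(1, rng.poisson(config.depth_mean, size=beta.size))
        meth = rng.binomial(depth, clipped)
        df = pd.DataFrame(
            {
                "chrom": config.chrom,
                "pos": positions_arr + 1,  # 1-based report coordinates
                "strand": strands,
                "context": contexts,
                "meth_reads": meth,
                "total_reads": depth,
            }
        )
        profiles[sample] = MethylationProfile(sample, df)
    truth.clip_events = clip_events
    return profiles


# ---------------------------------------------------------------------------
# expression


def _nb_counts(
    rng: np.random.Generator,
    feature_ids: list[str],
    de_info: dict[str, dict],
    library: int,
    config: SimulationConfig,
) -> CountMatrix:
    n = len(feature_ids)
    baseline = rng.lognormal(0.0, config.abundance_sigma, size=n)
    if config.dispersion > 0:
        shape = 1.0 / config.dispersion
        baseline = baseline * rng.gamma(shape, 1.0 / shape, size=n)
    cols = {}
    for sample in ("WT",) + LINES:
        w = baseline.copy()
        for i, f in enumerate(feature_ids):
            info = de_info.get(f)
            if info and sample in info["lines"]:
                w[i] *= 2.0 ** info["lfc"]
        mu = w / w.sum() * library
        cols[sample] = rng.poisson(mu)
    return CountMatrix(pd.DataFrame(cols, index=pd.Index(feature_ids, name="feature_id")))


def simulate_expression(
    genes: list[GeneModel],
    mirnas: list[GeneModel],
    truth: SimulationTruth,
    config: SimulationConfig,
    seed: int,
) -> tuple[CountMatrix, CountMatrix]:
    """mRNA and miRNA count matrices (columns WT, R1, R2)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    mrna = _nb_counts(rng, [g.gene_id for g in genes], truth.de_genes, config.mrna_library, config)
    mir = _nb_counts(
        rng, [m.gene_id for m in mirnas], truth.de_mirnas, config.mirna_library, config
    )
    return mrna, mir


# ---------------------------------------------------------------------------
# target predictions


def simulate_target_map(
    genes: list[GeneModel],
    mirnas: list[GeneModel],
    truth: SimulationTruth,
    config: SimulationConfig,
    seed: int,
    source_names: tuple[str, str, str] = ("mirtarget2", "mirecords", "miranda"),
    n_neutral: int | None = None,
) -> list[TargetPredictionSet]:
    """Three prediction sources; true pairs hit ≥2 of them, decoys exactly 1.

    Neutral true pairs (random wiring with no planted expression change) are
    added to ``truth.true_pairs`` so the consensus map looks realistic.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    gene_ids = [g.gene_id for g in genes]
    mirna_ids = [m.gene_id for m in mirnas]
    existing = set(truth.true_pairs)
    n_neutral = config.n_neutral_true_pairs if n_neutral is None else n_neutral
    attempts = 0
    while len(existing) < len(truth.true_pairs) + n_neutral and attempts < 50 * n_neutral + 100:
        attempts += 1
        pair = (
            str(mirna_ids[int(rng.integers(len(mirna_ids)))]),
            str(gene_ids[int(rng.integers(len(gene_ids)))]),
        )
        existing.add(pair)
    truth.true_pairs = sorted(existing)
    sources: dict[str, set[tuple[str, str]]] = {s: set() for s in source_names}
    for pair in truth.true_pairs:
        if rng.random() < 0.3:
            chosen = list(source_names)
        else:
            chosen = list(rng.choice(source_names, size=2, replace=False))
        for s in chosen:
            sources[s].add(pair)
    n_decoys = int(round(config.decoy_rate * len(truth.true_pairs)))
    taken = set(truth.true_pairs)
    for s in source_names:
        added = 0
        attempts = 0
        while added < n_decoys and attempts < 50 * n_decoys + 100:
            attempts += 1
            pair = (
                str(mirna_ids[int(rng.integers(len(mirna_ids)))]),
                str(gene_ids[int(rng.integers(len(gene_ids)))]),
            )
            if pair in taken:
                continue
            taken.add(pair)
            sources[s].add(pair)
            added += 1
    refresh_derived_truth(truth)
    return [TargetPredictionSet(s, sources[s]) for s in source_names]


# ---------------------------------------------------------------------------
# patient cohort


def _uniform_censor_bound(rate: float, censor_rate: float) -> float:
    """Upper bound u of C ~ U(0, u) giving P(C < T) = censor_rate for T ~ Exp(rate)."""

    def f(u):
        return (1.0 - np.exp(-rate * u)) / (rate * u) - censor_rate

    return brentq(f, 1e-9, 1e9)


def simulate_cohort(
    signature_genes,
    n_sensitive: int = 13,
    n_resistant: int = 14,
    effect_sd: float = 2.0,
    hazard_ratio: float = 3.0,
    censor_rate: float = 0.3,
    baseline_hazard: float = 1.0 / 24.0,
    seed: int = 0,
) -> CohortTable:
    """Labelled patient cohort over the signature genes.

    ``signature_genes`` maps gene → direction ("up"/"down" in resistant) or is
    a list of (gene, direction).  Expression ~ Normal(class mean, 1) with
    symmetric class means ∓/± (effect_sd/2)·direction, so the between-class
    separation is ``effect_sd`` and both classes carry a correlated pattern.
    Survival ~ Exponential; the resistant hazard is ``hazard_ratio`` × the
    sensitive (baseline) hazard; censoring is independent uniform with the
    bound solved so the expected sensitive-class censored fraction equals
    ``censor_rate``.
    """
    if n_sensitive < 2 or n_resistant < 2:
        raise ValueError("need at least two patients per class")
    if isinstance(signature_genes, dict):
        items = list(signature_genes.items())
    else:
        items = [(g, d) for g, d in signature_genes]
    if not items:
        raise ValueError("empty signature gene list")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 505]))
    genes = [g for g, _ in items]
    signs = np.array([1.0 if d == "up" else -1.0 for _, d in items])
    half = effect_sd / 2.0
    rows = []
    ids = []
    labels = []
    for i in range(n_sensitive):
        ids.append(f"S{i + 1:02d}")
        labels.append("sensitive")
        rows.append(rng.normal(-half * signs, 1.0))
    for i in range(n_resistant):
        ids.append(f"R{i + 1:02d}")
        labels.append("resistant")
        rows.append(rng.normal(half * signs, 1.0))
    hazards = np.where(np.array(labels) == "resistant", hazard_ratio * baseline_hazard, baseline_hazard)
    event_t = rng.exponential(1.0 / hazards)
    if censor_rate > 0:
        u = _uniform_censor_bound(baseline_hazard, censor_rate)
        censor_t = rng.uniform(0.0, u, size=len(ids))
    else:
        censor_t = np.full(len(ids), np.inf)
    time = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)
    table = pd.DataFrame(rows, index=pd.Index(ids, name="patient_id"), columns=genes)
    table.insert(0, "label", labels)
    table.insert(1, "time", np.round(time, 6))
    table.insert(2, "event", event)
    return CohortTable(table)


# ---------------------------------------------------------------------------
# one-call bundle


@dataclass
class SimulatedDataset:
    genes: list[GeneModel]
    mirnas: list[GeneModel]
    profiles: dict[str, MethylationProfile]
    mrna: CountMatrix
    mirna: CountMatrix
    target_sets: list[TargetPredictionSet]
    truth: SimulationTruth
    config: SimulationConfig = field(default_factory=SimulationConfig)


def simulate_dataset(config: SimulationConfig | None = None, seed: int = 0) -> SimulatedDataset:
    """Generate every pipeline input from one seed (pure function of both)."""
    config = config or SimulationConfig()
    genes, mirnas = simulate_annotation(config.n_genes, config.n_mirnas, seed, config.chrom)
    truth = plan_truth(genes, mirnas, config, seed)
    target_sets = simulate_target_map(genes, mirnas, truth, config, seed)
    profiles = simulate_methylomes(genes, mirnas, truth, config, seed)
    mrna, mirna = simulate_expression(genes, mirnas, truth, config, seed)
    return SimulatedDataset(genes, mirnas, profiles, mrna, mirna, target_sets, truth, config)
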