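"""Pairwise and triple integration of methylation, mRNA and miRNA contrasts.

"Negative correlation" is implemented as strict direction opposition of
significant calls (hyper↔down, hypo↔up; miRNA up↔gene down), because each
comparison has a single library per condition — there is no axis along which
to compute a continuous correlation coefficient.  A double-regulated gene is
a significantly differentially expressed gene carrying an anticorrelated
promoter DMR AND at least one anticorrelated, consensus-predicted targeting
miRNA (gene-body methylation is excluded from this step).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import FeatureRegion
from .differential import DEResult, DMRecord, DMRResult, call_dmrs
from .io import MethylationProfile, TargetPredictionSet

__all__ = [
    "ConsensusTargetMap",
    "RegulatoryCall",
    "MiRNAMethylationCall",
    "consensus_targets",
    "match_meth_expr",
    "match_mirna_expr",
    "match_mirna_meth",
    "summarize_mirna_meth",
    "triple_integrate",
    "intersect_comparisons",
]

_OPPOSITE_METH = {"hyper": "down", "hypo": "up"}  # DMR direction → anticorrelated DE direction
_OPPOSITE_EXPR = {"up": "down", "down": "up"}


@dataclass
class ConsensusTargetMap:
    """(miRNA → genes) pairs supported by ≥ min_sources prediction sources."""

    pairs: dict[tuple[str, str], int]  # (mirna, gene) → number of supporting sources
    min_sources: int

    def targets_of(self, mirna_id: str) -> set[str]:
        return {g for (m, g) in self.pairs if m == mirna_id}

    def mirnas_targeting(self, gene_id: str) -> set[str]:
        return {m for (m, g) in self.pairs if g == gene_id}

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


def consensus_targets(
    prediction_sets: list[TargetPredictionSet], min_sources: int = 2
) -> ConsensusTargetMap:
    """Retain (miRNA, gene) pairs predicted by ≥ ``min_sources`` distinct sources."""
    names = {s.source_name for s in prediction_sets}
    if len(names) != len(prediction_sets):
        raise ValueError("prediction sets must have distinct source names")
    if min_sources > len(prediction_sets):
        raise ValueError(
            f"min_sources={min_sources} exceeds the {len(prediction_sets)} available sources"
        )
    multiplicity: dict[tuple[str, str], int] = {}
    for s in prediction_sets:
        for pair in s.pairs:  # pairs is a set → each source counts once
            multiplicity[pair] = multiplicity.get(pair, 0) + 1
    kept = {p: c for p, c in multiplicity.items() if c >= min_sources}
    return ConsensusTargetMap(kept, min_sources)


def match_meth_expr(
    dmrs: DMRResult | list[DMRecord],
    de_genes: DEResult,
    kinds: tuple[str, ...] = ("promoter", "utr5"),
    sign: str = "anti",
) -> dict[str, set[str]]:
    """Genes whose significant DMR (per kind) and DE call have opposite signs.

    ``sign="anti"`` keeps hyper↔down / hypo↔up pairs (methylation silencing);
    ``sign="pos"`` keeps same-sign pairs (used for the gene-body summary,
    where methylation and expression tend to move together).
    Returns {kind: set of gene_ids}.
    """
    if sign not in ("anti", "pos"):
        raise ValueError("sign must be 'anti' or 'pos'")
    gene_dir = de_genes.directions()
    out: dict[str, set[str]] = {k: set() for k in kinds}
    for r in dmrs:
        if not r.significant or r.kind not in kinds:
            continue
        gdir = gene_dir.get(r.gene_or_mirna_id)
        if gdir is None:
            continue
        anti = _OPPOSITE_METH[r.direction] == gdir
        if (sign == "anti") == anti:
            out[r.kind].add(r.gene_or_mirna_id)
    return out


def match_mirna_expr(
    de_mirnas: DEResult, de_genes: DEResult, target_map: ConsensusTargetMap
) -> list[tuple[str, str]]:
    """(miRNA, gene) pairs: both significant, consensus-predicted, opposite directions."""
    mdir = de_mirnas.directions()
    gdir = de_genes.directions()
    pairs = []
    for (m, g), _count in sorted(target_map.pairs.items()):
        dm, dg = mdir.get(m), gdir.get(g)
        if dm is not None and dg is not None and _OPPOSITE_EXPR[dm] == dg:
            pairs.append((m, g))
    return pairs


@dataclass
class MiRNAMethylationCall:
    """A dysregulated miRNA with differential methylation near its TSS."""

    mirna_id: str
    mirna_direction: str
    window_dmrs: list[DMRecord]
    overall_meth_diff: float  # coverage-weighted mean β difference over window CpGs
    overall_meth_diff_unweighted: float
    tss_offsets: list[int] = field(default_factory=list)  # window-CpG offsets vs TSS


def match_mirna_meth(
    de_mirnas: DEResult,
    profile_a: MethylationProfile,
    profile_b: MethylationProfile,
    tss_windows: list[FeatureRegion],
    mirna_tss: dict[str, int] | None = None,
    shared_sites: pd.DataFrame | None = None,
    effect_min: float = 0.20,
    p_max: float = 0.01,
    min_cpgs: int = 5,
    min_depth: int = 4,
) -> list[MiRNAMethylationCall]:
    """miRNAs that are significantly DE and carry ≥1 significant TSS-window DMR.

    ``overall_meth_diff`` is the coverage-weighted mean β difference over the
    window's shared CpGs (weights = summed read depth in the two samples); an
    unweighted mean is reported alongside.  ``mirna_tss`` (id → 0-based TSS)
    enables per-CpG offsets relative to the TSS.
    """
    from .differential import filter_sites  # local to avoid cycle noise

    if shared_sites is None:
        shared_sites = filter_sites([profile_a, profile_b], min_depth=min_depth)
    dmr_result = call_dmrs(
        profile_a,
        profile_b,
        tss_windows,
        shared_sites=shared_sites,
        effect_min=effect_min,
        p_max=p_max,
        min_cpgs=min_cpgs,
    )
    by_mirna: dict[str, list[DMRecord]] = {}
    for r in dmr_result:
        by_mirna.setdefault(r.gene_or_mirna_id, []).append(r)
    ba, bb = f"beta_{profile_a.sample}", f"beta_{profile_b.sample}"
    ta, tb = f"total_{profile_a.sample}", f"total_{profile_b.sample}"
    site = {
        (c, p, s): (vb - va, wa + wb)
        for c, p, s, va, vb, wa, wb in zip(
            shared_sites["chrom"],
            shared_sites["pos"],
            shared_sites["strand"],
            shared_sites[ba],
            shared_sites[bb],
            shared_sites[ta],
            shared_sites[tb],
        )
    }
    windows_by_mirna = {w.owner_id: w for w in tss_windows}
    calls = []
    for rec in de_mirnas.significant:
        mid = rec.feature_id
        window = windows_by_mirna.get(mid)
        if window is None:
            continue
        sig_dmrs = [r for r in by_mirna.get(mid, []) if r.significant]
        if not sig_dmrs:
            continue
        diffs, weights, offsets = [], [], []
        tss = mirna_tss.get(mid) if mirna_tss else None
        for key in window.cpg_site_keys:
            if key not in site:
                continue
            d, w = site[key]
            diffs.append(d)
            weights.append(w)
            if tss is not None:
                offsets.append((key[1] - 1) - tss)
        if not diffs:
            continue
        diffs_arr = np.asarray(diffs)
        weights_arr = np.asarray(weights, dtype=float)
        calls.append(
            MiRNAMethylationCall(
                mirna_id=mid,
                mirna_direction=rec.direction,
                window_dmrs=sig_dmrs,
                overall_meth_diff=float(np.average(diffs_arr, weights=weights_arr)),
                overall_meth_diff_unweighted=float(diffs_arr.mean()),
                tss_offsets=offsets,
            )
        )
    return calls


def summarize_mirna_meth(calls: list[MiRNAMethylationCall]) -> pd.DataFrame:
    """Direction-stratified overall TSS-window methylation change.

    Up-regulated miRNAs are expected to show an overall methylation decrease
    around their TSSs and down-regulated ones an increase; both the mean and
    median across miRNAs are reported per direction.
    """
    rows = []
    for direction in ("up", "down"):
        vals = [c.overall_meth_diff for c in calls if c.mirna_direction == direction]
        if vals:
            rows.append((direction, len(vals), float(np.mean(vals)), float(np.median(vals))))
        else:
            rows.append((direction, 0, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["mirna_direction", "n", "mean_meth_diff", "median_meth_diff"])


@dataclass
class RegulatoryCall:
    """A double-regulated gene with its full evidence."""

    gene_id: str
    gene_direction: str
    promoter_dmr: DMRecord
    regulating_mirnas: list[tuple[str, str]]  # (mirna_id, mirna_direction)

    def __post_init__(self) -> None:
        if not self.regulating_mirnas:
            raise ValueError(f"{self.gene_id}: regulating miRNA set must be non-empty")


def triple_integrate(
    de_genes: DEResult,
    dmrs: DMRResult | list[DMRecord],
    de_mirnas: DEResult,
    target_map: ConsensusTargetMap,
) -> list[RegulatoryCall]:
    """Double-regulated genes: DE + anticorrelated promoter DMR + ≥1 anticorrelated miRNA.

    Only promoter DMRs participate (gene-body methylation is excluded from
    this step).  The promoter DMR with the largest |median Δβ| is attached
    when a gene has several.
    """
    gene_dir = de_genes.directions()
    mirna_dir = de_mirnas.directions()
    promoter_dmrs: dict[str, list[DMRecord]] = {}
    for r in dmrs:
        if r.significant and r.kind == "promoter":
            promoter_dmrs.setdefault(r.gene_or_mirna_id, []).append(r)
    calls = []
    for gene, gdir in sorted(gene_dir.items()):
        anti_dmrs = [r for r in promoter_dmrs.get(gene, []) if _OPPOSITE_METH[r.direction] == gdir]
        if not anti_dmrs:
            continue
        mirnas = sorted(
            (m, mirna_dir[m])
            for m in target_map.mirnas_targeting(gene)
            if m in mirna_dir and _OPPOSITE_EXPR[mirna_dir[m]] == gdir
        )
        if not mirnas:
            continue
        best = max(anti_dmrs, key=lambda r: abs(r.median_beta_diff))
        calls.append(RegulatoryCall(gene, gdir, best, mirnas))
    return calls


def intersect_comparisons(
    calls_a: list[RegulatoryCall], calls_b: list[RegulatoryCall]
) -> tuple[set[str], dict[str, int]]:
    """Common double-regulated genes between two comparisons, plus Venn counts."""
    a = {c.gene_id for c in calls_a}
    b = {c.gene_id for c in calls_b}
    common = a & b
    return common, {"a_only": len(a - b), "b_only": len(b - a), "both": len(common)}
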