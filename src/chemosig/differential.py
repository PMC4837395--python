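"""Differential methylation (DMRs) and differential expression between two samples.

DMRs: per feature-anchored region, paired per-CpG β differences between the
two samples; effect size is the median difference and the p-value comes from
a two-sided Wilcoxon signed-rank test (exact tail enumeration for n ≤ 25,
normal approximation with continuity and tie corrections beyond).  A region
is significant when |median Δβ| > 0.20 and p < 0.01 (defaults).

DE: with a single library per condition, each feature's counts are compared
with an exact two-sided binomial test of x₂ successes in x₁+x₂ trials
against p₀ = N₂/(N₁+N₂) (N = library sizes) — the classic no-replicate
RNA-seq contrast — followed by Benjamini–Hochberg adjustment across
features.  A feature is called up/down when FDR ≤ 0.001 and |log₂FC| ≥ 1
(defaults), with a pseudocount applied to the fold change only, never to
the test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotate import FeatureRegion
from .io import CountMatrix, MethylationProfile

__all__ = [
    "DMRecord",
    "ExpressionRecord",
    "DMRResult",
    "DEResult",
    "filter_sites",
    "wilcoxon_signed_rank",
    "call_dmrs",
    "test_de",
    "dmr_location_summary",
]


# ---------------------------------------------------------------------------
# shared-site filtering


def filter_sites(
    profiles: list[MethylationProfile], min_depth: int = 4, context: str | None = "CpG"
) -> pd.DataFrame:
    """Sites covered ≥ ``min_depth`` in EVERY profile (and matching context).

    Returns a frame keyed by (chrom, pos, strand) with per-sample columns
    ``beta_<sample>`` and ``total_<sample>``, ordered by (chrom, pos, strand).
    An empty intersection is returned as an empty frame, not an error.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    merged: pd.DataFrame | None = None
    for p in profiles:
        df = p.sites
        if context is not None:
            df = df[df["context"] == context]
        df = df[df["total_reads"] >= min_depth]
        df = df[["chrom", "pos", "strand", "beta", "total_reads"]].rename(
            columns={"beta": f"beta_{p.sample}", "total_reads": f"total_{p.sample}"}
        )
        merged = df if merged is None else merged.merge(df, on=["chrom", "pos", "strand"], how="inner")
    assert merged is not None
    return merged.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank (paired β differences within a region)


def _exact_signed_rank_p(diffs: np.ndarray) -> float:
    """Two-sided exact p: P(W⁺ ≤ min(w⁺,w⁻)) + P(W⁺ ≥ max(w⁺,w⁻)).

    Exact over all 2ⁿ equiprobable sign assignments (zeros dropped first);
    midranks for ties are doubled to keep integer rank weights, and the
    distribution of W⁺ is built by dynamic-programming convolution, which is
    equivalent to full enumeration.
    """
    d = diffs[diffs != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w = np.rint(2 * ranks).astype(np.int64)  # integer weights (ties → odd sums)
    total = int(w.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for wi in w:
        shifted = np.zeros_like(counts)
        shifted[wi:] = counts[:-wi] if wi else counts
        counts = counts + shifted
    counts /= 2.0**n
    w_pos = int(w[d > 0].sum())
    w_neg = total - w_pos
    lo, hi = min(w_pos, w_neg), max(w_pos, w_neg)
    return float(min(1.0, counts[: lo + 1].sum() + counts[hi:].sum()))


def _approx_signed_rank_p(diffs: np.ndarray) -> float:
    """Normal approximation with continuity and tie corrections."""
    d = diffs[diffs != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_pos = ranks[d > 0].sum()
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return 1.0
    z = (abs(w_pos - mean) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    return float(min(1.0, 2 * stats.norm.sf(z)))


def wilcoxon_signed_rank(diffs, exact_max_n: int = 25) -> tuple[float, float]:
    """(median difference, two-sided p) for paired differences.

    Exact enumeration tail probability for n ≤ ``exact_max_n`` non-zero
    differences, normal approximation with continuity correction otherwise.
    All-zero input gives p = 1.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size == 0:
        return 0.0, 1.0
    nz = int((d != 0).sum())
    p = _exact_signed_rank_p(d) if nz <= exact_max_n else _approx_signed_rank_p(d)
    return float(np.median(d)), p


# ---------------------------------------------------------------------------
# DMR calling


@dataclass
class DMRecord:
    """One tested region's methylation contrast (sample2 − sample1)."""

    region_id: str
    gene_or_mirna_id: str
    kind: str
    n_shared_cpgs: int
    median_beta_diff: float
    p_value: float
    direction: str  # hyper / hypo in sample2 relative to sample1
    significant: bool


@dataclass
class DMRResult:
    """All tested regions plus the ids skipped for too few shared CpGs."""

    records: list[DMRecord]
    skipped_regions: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)

    @property
    def significant(self) -> list[DMRecord]:
        return [r for r in self.records if r.significant]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (
                    r.region_id,
                    r.gene_or_mirna_id,
                    r.kind,
                    r.n_shared_cpgs,
                    r.median_beta_diff,
                    r.p_value,
                    r.direction,
                    r.significant,
                )
                for r in self.records
            ],
            columns=[
                "region_id",
                "gene_or_mirna_id",
                "kind",
                "n_shared_cpgs",
                "median_beta_diff",
                "p_value",
                "direction",
                "significant",
            ],
        )


def call_dmrs(
    profile_a: MethylationProfile,
    profile_b: MethylationProfile,
    regions: list[FeatureRegion],
    shared_sites: pd.DataFrame | None = None,
    effect_min: float = 0.20,
    p_max: float = 0.01,
    min_cpgs: int = 5,
    min_depth: int = 4,
    context: str | None = "CpG",
) -> DMRResult:
    """Call DMRs (B vs A) over regions with assigned CpGs.

    ``shared_sites`` may be precomputed (e.g. the 3-way shared set) — it must
    carry ``beta_<sample>`` columns for both profiles; otherwise the pairwise
    shared set at ``min_depth`` is computed here.  Regions with fewer than
    ``min_cpgs`` shared sites are skipped and recorded.
    """
    if shared_sites is None:
        shared_sites = filter_sites([profile_a, profile_b], min_depth=min_depth, context=context)
    ba, bb = f"beta_{profile_a.sample}", f"beta_{profile_b.sample}"
    lookup = {
        (c, p, s): (va, vb)
        for c, p, s, va, vb in zip(
            shared_sites["chrom"],
            shared_sites["pos"],
            shared_sites["strand"],
            shared_sites[ba],
            shared_sites[bb],
        )
    }
    records: list[DMRecord] = []
    skipped: list[str] = []
    for region in regions:
        diffs = [
            lookup[k][1] - lookup[k][0] for k in region.cpg_site_keys if k in lookup
        ]
        if len(diffs) < min_cpgs:
            skipped.append(region.region_id)
            continue
        median, p = wilcoxon_signed_rank(np.array(diffs))
        significant = abs(median) > effect_min and p < p_max
        records.append(
            DMRecord(
                region_id=region.region_id,
                gene_or_mirna_id=region.owner_id,
                kind=region.kind,
                n_shared_cpgs=len(diffs),
                median_beta_diff=median,
                p_value=p,
                direction="hyper" if median > 0 else "hypo",
                significant=significant,
            )
        )
    return DMRResult(records, skipped)


# ---------------------------------------------------------------------------
# differential expression


@dataclass
class ExpressionRecord:
    """One feature's two-condition expression contrast (condition2 vs 1)."""

    feature_id: str
    count1: int
    count2: int
    cpm1: float
    cpm2: float
    log2fc: float
    p_value: float
    fdr: float
    direction: str  # up / down / unchanged


@dataclass
class DEResult:
    records: list[ExpressionRecord]

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)

    @property
    def significant(self) -> list[ExpressionRecord]:
        return [r for r in self.records if r.direction != "unchanged"]

    def directions(self) -> dict[str, str]:
        """feature_id → up/down for significant features."""
        return {r.feature_id: r.direction for r in self.records if r.direction != "unchanged"}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.feature_id, r.count1, r.count2, r.cpm1, r.cpm2, r.log2fc, r.p_value, r.fdr, r.direction)
                for r in self.records
            ],
            columns=["feature_id", "count1", "count2", "cpm1", "cpm2", "log2fc", "p_value", "fdr", "direction"],
        )


def test_de(
    counts: CountMatrix,
    condition1: str,
    condition2: str,
    fdr_max: float = 0.001,
    lfc_min: float = 1.0,
    pseudocount: float = 1.0,
) -> DEResult:
    """Exact binomial DE test of ``condition2`` vs ``condition1``.

    Features with zero counts in both conditions are reported with p = 1,
    log2fc = 0 and are excluded from the BH multiplicity (they are untested).
    """
    x1 = counts.counts[condition1].to_numpy()
    x2 = counts.counts[condition2].to_numpy()
    n1 = int(x1.sum())
    n2 = int(x2.sum())
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    p0 = n2 / (n1 + n2)
    features = counts.feature_ids
    pvals = np.ones(len(features))
    tested = (x1 + x2) > 0
    for i in np.flatnonzero(tested):
        pvals[i] = stats.binomtest(int(x2[i]), int(x1[i] + x2[i]), p0).pvalue
    fdr = np.ones(len(features))
    if tested.any():
        fdr[tested] = multipletests(pvals[tested], method="fdr_bh")[1]
    log2fc = np.where(
        tested,
        np.log2((x2 + pseudocount) / n2) - np.log2((x1 + pseudocount) / n1),
        0.0,
    )
    records = []
    for i, fid in enumerate(features):
        sig = tested[i] and fdr[i] <= fdr_max and abs(log2fc[i]) >= lfc_min
        direction = "unchanged"
        if sig:
            direction = "up" if log2fc[i] > 0 else "down"
        records.append(
            ExpressionRecord(
                feature_id=fid,
                count1=int(x1[i]),
                count2=int(x2[i]),
                cpm1=float(x1[i] / n1 * 1e6),
                cpm2=float(x2[i] / n2 * 1e6),
                log2fc=float(log2fc[i]),
                p_value=float(pvals[i]),
                fdr=float(fdr[i]),
                direction=direction,
            )
        )
    return DEResult(records)


# ---------------------------------------------------------------------------
# descriptive summaries


def dmr_location_summary(dmrs: list[DMRecord] | DMRResult) -> pd.DataFrame:
    """Counts and fractions of DMRs per feature kind (descriptive)."""
    recs = list(dmrs)
    if not recs:
        return pd.DataFrame(columns=["kind", "count", "fraction"])
    kinds = pd.Series([r.kind for r in recs])
    counts = kinds.value_counts()
    return pd.DataFrame(
        {"kind": counts.index, "count": counts.values, "fraction": counts.values / len(recs)}
    ).reset_index(drop=True)
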