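"""Feature-region derivation and CpG→region assignment.

Promoters are derived (the annotation never stores them): −2000/+500 bp
around the strand-aware TSS by default.  miRNA TSS windows are symmetric
±flank windows (default 2000 bp, the window used when relating miRNA
expression to methylation around its transcription start site).  A CpG may
fall in several regions at once (e.g. the promoter of one gene and the
intron of another); assignment is deliberately non-exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .io import GeneModel, MethylationProfile

__all__ = [
    "FeatureRegion",
    "derive_promoters",
    "mirna_tss_windows",
    "gene_feature_regions",
    "derive_intergenic",
    "assign_cpgs",
]

REGION_KINDS = (
    "promoter",
    "utr5",
    "cds",
    "intron",
    "utr3",
    "intergenic",
    "mirna_tss_window",
)


@dataclass
class FeatureRegion:
    """A genomic interval tied to a gene/miRNA and a feature kind.

    Interval is 0-based half-open.  ``cpg_site_keys`` is filled by
    :func:`assign_cpgs` with (chrom, pos, strand) keys (pos 1-based, matching
    the profile frames).
    """

    region_id: str
    owner_id: str  # gene or miRNA id; "" for intergenic catch-alls
    kind: str
    chrom: str
    start: int
    end: int
    cpg_site_keys: list[tuple[str, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in REGION_KINDS:
            raise ValueError(f"unknown region kind {self.kind!r}")
        if self.end <= self.start:
            raise ValueError(f"{self.region_id}: empty interval [{self.start},{self.end})")

    def __len__(self) -> int:
        return self.end - self.start


def derive_promoters(
    models: list[GeneModel], upstream: int = 2000, downstream: int = 500
) -> list[FeatureRegion]:
    """Strand-aware promoter windows around each TSS, clipped at 0.

    ``+``: [tss − upstream, tss + downstream); ``−`` mirrors to
    [tss − downstream, tss + upstream + 1) so the window always contains the
    TSS base itself.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream/downstream must be non-negative")
    regions = []
    for m in models:
        if m.strand == "+":
            start, end = m.tss - upstream, m.tss + downstream
        else:
            start, end = m.tss - downstream, m.tss + upstream + 1
        start = max(0, start)
        if end > start:
            regions.append(
                FeatureRegion(f"{m.gene_id}:promoter", m.gene_id, "promoter", m.chrom, start, end)
            )
    return regions


def mirna_tss_windows(mirna_models: list[GeneModel], flank: int = 2000) -> list[FeatureRegion]:
    """Symmetric ±flank windows [tss − flank, tss + flank + 1) per miRNA."""
    if flank <= 0:
        raise ValueError("flank must be positive")
    regions = []
    for m in mirna_models:
        start = max(0, m.tss - flank)
        end = m.tss + flank + 1
        regions.append(
            FeatureRegion(
                f"{m.gene_id}:tss_window", m.gene_id, "mirna_tss_window", m.chrom, start, end
            )
        )
    return regions


def gene_feature_regions(models: list[GeneModel]) -> list[FeatureRegion]:
    """One region per stored gene feature (utr5/cds/intron/utr3)."""
    regions = []
    for m in models:
        counters: dict[str, int] = {}
        for kind, s, e in m.features:
            if e <= s:
                continue
            n = counters.get(kind, 0)
            counters[kind] = n + 1
            rid = f"{m.gene_id}:{kind}" + (f".{n}" if n else "")
            regions.append(FeatureRegion(rid, m.gene_id, kind, m.chrom, s, e))
    return regions


def derive_intergenic(
    models: list[GeneModel], pad: int = 2000, chrom_end: int | None = None
) -> list[FeatureRegion]:
    """Complement of gene spans padded by ``pad`` bp; descriptive use only."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for m in models:
        span = m.span
        if span is None:
            span = (m.tss, m.tss + 1)
        s = max(0, span[0] - pad)
        e = span[1] + pad
        by_chrom.setdefault(m.chrom, []).append((s, e))
    regions = []
    for chrom, spans in by_chrom.items():
        spans.sort()
        merged: list[list[int]] = []
        for s, e in spans:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        cursor = 0
        i = 0
        for s, e in merged:
            if s > cursor:
                regions.append(
                    FeatureRegion(f"{chrom}:intergenic.{i}", "", "intergenic", chrom, cursor, s)
                )
                i += 1
            cursor = max(cursor, e)
        end = chrom_end if chrom_end is not None else cursor + pad
        if end > cursor:
            regions.append(
                FeatureRegion(f"{chrom}:intergenic.{i}", "", "intergenic", chrom, cursor, end)
            )
    return regions


def assign_cpgs(
    regions: list[FeatureRegion], profile: MethylationProfile
) -> list[FeatureRegion]:
    """Fill each region's ``cpg_site_keys`` with the profile sites inside it.

    Membership is by cytosine position (0-based ``pos − 1``) falling in the
    half-open interval, independent of strand.  Sites on chromosomes absent
    from the annotation are simply left unassigned.  Returns the same region
    objects (mutated) for chaining.
    """
    trees: dict[str, IntervalTree] = {}
    for idx, r in enumerate(regions):
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, idx)
        r.cpg_site_keys = []
    df = profile.sites
    for chrom, grp in df.groupby("chrom", sort=True):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for pos, strand in zip(grp["pos"], grp["strand"]):
            for iv in tree.at(int(pos) - 1):
                regions[iv.data].cpg_site_keys.append((chrom, int(pos), strand))
    for r in regions:
        r.cpg_site_keys.sort()
    return regions


def regions_to_bed(regions: list[FeatureRegion]) -> pd.DataFrame:
    """BED-like frame (chrom, start, end, name) for export of derived regions."""
    return pd.DataFrame(
        [(r.chrom, r.start, r.end, r.region_id, r.kind) for r in regions],
        columns=["chrom", "start", "end", "name", "kind"],
    )
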