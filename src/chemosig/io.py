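"""Typed containers and TSV readers/writers for every external table the pipeline touches.

Conventions
-----------
Internal coordinates are 0-based half-open throughout the package.  The one
externally 1-based dialect is the CpG report (Bismark-style), whose ``pos``
column is the 1-based coordinate of the cytosine; it is kept 1-based in the
:class:`MethylationProfile` frame (column ``pos``) and converted on the fly
when sites are assigned to intervals.  Annotation TSVs and BED12 are 0-based
half-open, and a gene's TSS is stored 0-based (BED start for ``+`` strand,
``end − 1`` for ``−``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "MethylationProfile",
    "GeneModel",
    "CountMatrix",
    "TargetPredictionSet",
    "CohortTable",
    "DEFAULT_LABEL_MAP",
    "read_cpg_report",
    "write_cpg_report",
    "read_gene_models",
    "write_gene_models",
    "read_counts",
    "write_counts",
    "read_targets",
    "write_targets",
    "read_clinical",
    "write_clinical",
]

CPG_CONTEXTS = ("CpG", "CHG", "CHH")
FEATURE_KINDS = ("promoter", "utr5", "cds", "intron", "utr3", "intergenic")
LABELS = ("sensitive", "resistant", "unknown")

#: Clinical response tokens → class labels.  CR and pCR denote responders
#: (chemosensitive); progressive/stable disease and extensive residual cancer
#: burden denote non-responders (chemoresistant).  Override via the
#: ``label_map`` argument of :func:`read_clinical`.
DEFAULT_LABEL_MAP = {
    "CR": "sensitive",
    "pCR": "sensitive",
    "PD": "resistant",
    "SD": "resistant",
    "RCB-II": "resistant",
    "RCB-III": "resistant",
    "sensitive": "sensitive",
    "resistant": "resistant",
    "unknown": "unknown",
}


class ParseError(ValueError):
    """Malformed input table; the message names the offending line/cell."""


# ---------------------------------------------------------------------------
# methylation


@dataclass
class MethylationProfile:
    """Per-sample CpG-level methylation calls.

    ``sites`` columns: chrom, pos (1-based cytosine position), strand,
    context, meth_reads, total_reads, beta.  ``beta`` is
    ``meth_reads / total_reads`` and NaN where ``total_reads == 0``
    (coverage-less sites are retained but carry no β).
    """

    sample: str
    sites: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.sites
        required = ["chrom", "pos", "strand", "context", "meth_reads", "total_reads"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"profile frame missing columns {missing}")
        if (df["meth_reads"] > df["total_reads"]).any():
            raise ValueError("meth_reads exceeds total_reads")
        if (df[["meth_reads", "total_reads"]] < 0).any().any():
            raise ValueError("negative read counts")
        if df.duplicated(["chrom", "pos", "strand"]).any():
            raise ValueError("duplicate (chrom, pos, strand) site keys")
        if "beta" not in df.columns:
            with np.errstate(invalid="ignore", divide="ignore"):
                df = df.assign(
                    beta=np.where(
                        df["total_reads"] > 0,
                        df["meth_reads"] / df["total_reads"].replace(0, np.nan),
                        np.nan,
                    )
                )
        self.sites = df.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.sites)


def read_cpg_report(path, sample: str | None = None) -> MethylationProfile:
    """Read a Bismark-style CpG report (chrom, pos, strand, meth, unmeth, context).

    Positions are 1-based.  Rows with zero total coverage are kept (β = NaN).
    Raises :class:`ParseError` naming the first malformed line.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if lineno == 1 and line.split("\t")[0] in ("chrom", "chr"):
                continue  # optional header
            parts = line.split("\t")
            if len(parts) != 6:
                raise ParseError(f"{path.name}:{lineno}: expected 6 columns, got {len(parts)}")
            chrom, pos_s, strand, meth_s, unmeth_s, context = parts
            try:
                pos = int(pos_s)
                meth = int(meth_s)
                unmeth = int(unmeth_s)
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: non-integer field ({exc})") from None
            if meth < 0 or unmeth < 0:
                raise ParseError(f"{path.name}:{lineno}: negative read count")
            if strand not in ("+", "-"):
                raise ParseError(f"{path.name}:{lineno}: bad strand {strand!r}")
            if context not in CPG_CONTEXTS:
                raise ParseError(f"{path.name}:{lineno}: unknown context {context!r}")
            rows.append((chrom, pos, strand, context, meth, meth + unmeth))
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "meth_reads", "total_reads"]
    )
    if df.empty:
        df = df.astype(
            {"pos": "int64", "meth_reads": "int64", "total_reads": "int64"}
        )
    return MethylationProfile(sample or path.stem, df)


def write_cpg_report(profile: MethylationProfile, path) -> None:
    df = profile.sites
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos"],
            "strand": df["strand"],
            "count_methylated": df["meth_reads"],
            "count_unmethylated": df["total_reads"] - df["meth_reads"],
            "context": df["context"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene / miRNA models


@dataclass
class GeneModel:
    """A gene (or miRNA) locus: strand-aware TSS plus typed feature intervals.

    ``tss`` is 0-based; ``features`` are (kind, start, end) 0-based half-open.
    miRNA models typically carry an empty feature list — only the TSS matters
    for their ±flank methylation windows.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    features: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        for kind, start, end in self.features:
            if kind not in FEATURE_KINDS:
                raise ValueError(f"{self.gene_id}: unknown feature kind {kind!r}")
            if end < start:
                raise ValueError(f"{self.gene_id}: negative-length interval [{start},{end})")

    @property
    def span(self) -> tuple[int, int] | None:
        if not self.features:
            return None
        return (min(s for _, s, _ in self.features), max(e for _, _, e in self.features))


def read_gene_models(path) -> list[GeneModel]:
    """Read gene models from BED12 (``.bed``) or the simplified feature TSV.

    TSV columns: gene_id, chrom, strand, tss, feature_kind, start, end
    (0-based half-open; one row per feature, rows grouped by gene_id in any
    order).  Duplicate gene_ids across separated blocks raise.
    """
    path = Path(path)
    if path.suffix == ".bed":
        return _read_bed12(path)
    df = pd.read_csv(path, sep="\t")
    required = ["gene_id", "chrom", "strand", "tss", "feature_kind", "start", "end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path.name}: missing columns {missing}")
    models = []
    seen = {}
    for gid, grp in df.groupby("gene_id", sort=False):
        chroms = grp["chrom"].unique()
        strands = grp["strand"].unique()
        tsss = grp["tss"].unique()
        if len(chroms) > 1 or len(strands) > 1 or len(tsss) > 1:
            raise ParseError(f"{path.name}: inconsistent rows for gene {gid}")
        feats = [
            (k, int(s), int(e))
            for k, s, e in zip(grp["feature_kind"], grp["start"], grp["end"])
            if k != "tss_only"
        ]
        if gid in seen:
            raise ParseError(f"{path.name}: duplicate gene_id {gid}")
        seen[gid] = True
        models.append(GeneModel(str(gid), str(chroms[0]), str(strands[0]), int(tsss[0]), feats))
    return models


def write_gene_models(models: list[GeneModel], path) -> None:
    rows = []
    for m in models:
        if m.features:
            for kind, s, e in m.features:
                rows.append((m.gene_id, m.chrom, m.strand, m.tss, kind, s, e))
        else:
            rows.append((m.gene_id, m.chrom, m.strand, m.tss, "tss_only", m.tss, m.tss + 1))
    pd.DataFrame(
        rows, columns=["gene_id", "chrom", "strand", "tss", "feature_kind", "start", "end"]
    ).to_csv(path, sep="\t", index=False)


def _read_bed12(path: Path) -> list[GeneModel]:
    """Minimal BED12: blocks → exons, thick interval → CDS, gaps → introns."""
    models = []
    seen = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            p = line.split("\t")
            if len(p) < 12:
                raise ParseError(f"{path.name}:{lineno}: expected 12 BED columns")
            chrom, start, end, name, _score, strand = p[0], int(p[1]), int(p[2]), p[3], p[4], p[5]
            thick_s, thick_e = int(p[6]), int(p[7])
            n_blocks = int(p[9])
            sizes = [int(x) for x in p[10].rstrip(",").split(",")]
            offsets = [int(x) for x in p[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ParseError(f"{path.name}:{lineno}: block count mismatch")
            if name in seen:
                raise ParseError(f"{path.name}:{lineno}: duplicate gene_id {name}")
            seen.add(name)
            tss = start if strand == "+" else end - 1
            feats: list[tuple[str, int, int]] = []
            prev_end = None
            for off, size in zip(offsets, sizes):
                bs, be = start + off, start + off + size
                if prev_end is not None and bs > prev_end:
                    feats.append(("intron", prev_end, bs))
                prev_end = be
                # split exon block against the thick (CDS) interval
                if thick_e <= thick_s:  # non-coding
                    kind = "utr5" if strand == "+" else "utr3"
                    feats.append((kind, bs, be))
                    continue
                if bs < thick_s:
                    left = ("utr5" if strand == "+" else "utr3", bs, min(be, thick_s))
                    feats.append(left)
                cs, ce = max(bs, thick_s), min(be, thick_e)
                if ce > cs:
                    feats.append(("cds", cs, ce))
                if be > thick_e:
                    right = ("utr3" if strand == "+" else "utr5", max(bs, thick_e), be)
                    feats.append(right)
            feats = [f for f in feats if f[2] > f[1]]
            models.append(GeneModel(name, chrom, strand, tss, feats))
    return models


# ---------------------------------------------------------------------------
# counts


@dataclass
class CountMatrix:
    """Features × samples non-negative integer counts."""

    counts: pd.DataFrame  # index = feature_ids, columns = sample_ids

    def __post_init__(self) -> None:
        if (self.counts < 0).any().any():
            raise ValueError("negative counts")
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate feature ids")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


def read_counts(path) -> CountMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals % 1 != 0)
        if bad.any():
            feat = bad.idxmax()
            raise ParseError(
                f"{path.name}: non-integer count at ({feat}, {col}): {df.loc[feat, col]!r}"
            )
        df[col] = vals
    return CountMatrix(df.astype("int64"))


def write_counts(cm: CountMatrix, path) -> None:
    out = cm.counts.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# miRNA target predictions


@dataclass
class TargetPredictionSet:
    """One prediction source's (miRNA, gene) pairs."""

    source_name: str
    pairs: set[tuple[str, str]]


def read_targets(paths, source_names: list[str] | None = None) -> list[TargetPredictionSet]:
    """Read one TSV per source (columns mirna_id, gene_id).

    The source name defaults to the file stem.  A (mirna, gene) pair repeated
    within one source file raises; the same pair across sources is the whole
    point (consensus counting) and both are retained.
    """
    sets = []
    for i, p in enumerate(paths):
        p = Path(p)
        name = source_names[i] if source_names else p.stem
        df = pd.read_csv(p, sep="\t")
        if not {"mirna_id", "gene_id"} <= set(df.columns):
            raise ParseError(f"{p.name}: expected columns mirna_id, gene_id")
        dup = df.duplicated(["mirna_id", "gene_id"])
        if dup.any():
            m, g = df.loc[dup.idxmax(), ["mirna_id", "gene_id"]]
            raise ParseError(f"{p.name}: duplicated pair ({m}, {g}) within source")
        sets.append(
            TargetPredictionSet(name, set(zip(df["mirna_id"].astype(str), df["gene_id"].astype(str))))
        )
    return sets


def write_targets(ts: TargetPredictionSet, path) -> None:
    pd.DataFrame(sorted(ts.pairs), columns=["mirna_id", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# clinical cohort


@dataclass
class CohortTable:
    """Patients × signature-gene expression with response labels and survival.

    ``table`` is indexed by patient_id with columns label, time, event, then
    one column per gene (continuous expression).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        for col in ("label", "time", "event"):
            if col not in t.columns:
                raise ValueError(f"cohort table missing column {col!r}")
        bad = set(t["label"]) - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}")
        has_event = t["event"].notna()
        if (t.loc[has_event, "time"].isna()).any():
            raise ValueError("event present without survival time")
        if (t["time"].dropna() < 0).any():
            raise ValueError("negative survival time")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def genes(self) -> list[str]:
        return [c for c in self.table.columns if c not in ("label", "time", "event")]

    @property
    def expression(self) -> pd.DataFrame:
        return self.table[self.genes]

    @property
    def labels(self) -> pd.Series:
        return self.table["label"]


def read_clinical(path, label_map: dict | None = None) -> CohortTable:
    """Read the clinical TSV (patient_id, label, time, event, gene columns).

    Raw response tokens (CR, PD, SD, pCR, RCB-II, RCB-III, …) are mapped to
    sensitive/resistant via ``label_map`` (default :data:`DEFAULT_LABEL_MAP`);
    unmapped tokens raise.
    """
    path = Path(path)
    lm = DEFAULT_LABEL_MAP if label_map is None else label_map
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "label" not in df.columns:
        raise ParseError(f"{path.name}: missing label column")
    mapped = []
    for pid, tok in df["label"].items():
        if tok not in lm:
            raise ParseError(f"{path.name}: unknown response label {tok!r} for patient {pid}")
        mapped.append(lm[tok])
    df = df.assign(label=mapped)
    return CohortTable(df)


def write_clinical(cohort: CohortTable, path) -> None:
    out = cohort.table.copy()
    out.index.name = "patient_id"
    out.to_csv(path, sep="\t", float_format="%.12g")
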