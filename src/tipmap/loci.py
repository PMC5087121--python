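"""Panel-level insertion loci: merging, DB matching, classification, summaries.

Retained peaks from all (cell line, family) tracks are merged into loci by
margin-expanded transitive overlap within a family.  Each locus is matched
against known-insertion databases with a 1-2 kb margin and classified as
reference, known polymorphic, novel polymorphic (no DB match, >= 2 lines)
or singleton (no DB match, exactly 1 line).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DB_COLUMNS = ["chrom", "start", "end", "family", "source", "db_id"]
DB_SOURCES = ("reference", "known_polymorphic")


def collapse_family(family: str) -> str:
    """Alu subfamily channels collapse to "Alu" for panel summaries."""
    return "Alu" if family.startswith("Alu") else family


@dataclass
class KnownInsertionDB:
    """Positions of reference and known-polymorphic insertions by family."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DB_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"DB missing columns {missing}")
        bad = set(self.records["source"]) - set(DB_SOURCES)
        if bad:
            raise ValueError(f"unknown DB sources {bad}")

    def __len__(self) -> int:
        return len(self.records)

    def subset(
        self, family: str | None = None, source: str | None = None
    ) -> "KnownInsertionDB":
        df = self.records
        if family is not None:
            df = df[df["family"] == family]
        if source is not None:
            df = df[df["source"] == source]
        return KnownInsertionDB(df.reset_index(drop=True))


@dataclass
class InsertionLocus:
    locus_id: str
    chrom: str
    start: int
    end: int
    family: str
    presence: np.ndarray  # bool per cell line, panel order
    category: str = ""
    matched_db_ids: list[str] = field(default_factory=list)
    #: reference locus also listed as polymorphic ("counted in both groups")
    ref_and_poly: bool = False
    member_peaks: list = field(default_factory=list)

    @property
    def n_present(self) -> int:
        return int(np.asarray(self.presence).sum())

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class PresenceMatrix:
    """Loci x cell lines boolean matrix."""

    matrix: pd.DataFrame  # index locus_id, columns cell lines, dtype bool

    def __post_init__(self) -> None:
        sums = self.matrix.sum(axis=1)
        if len(sums) and (sums < 1).any():
            raise ValueError("every locus must be present in >= 1 line")

    def frequencies(self) -> pd.Series:
        return self.matrix.mean(axis=1)


def match_known(peak, db: KnownInsertionDB, margin_bp: int = 1000) -> list[str]:
    """DB record ids of the peak's family within margin of the peak interval.

    ``peak`` needs chrom/start/end/family attributes.  The margin follows
    the published 1-2 kb annotation margins and must lie in that range.
    """
    if not 1000 <= margin_bp <= 2000:
        raise ValueError("margin_bp must be within [1000, 2000]")
    df = db.records
    sel = (
        (df["family"] == peak.family)
        & (df["chrom"] == peak.chrom)
        & (df["start"] < peak.end + margin_bp)
        & (df["end"] > peak.start - margin_bp)
    )
    return df.loc[sel, "db_id"].tolist()


def build_loci(
    peaks: list,
    cell_lines: list[str],
    merge_margin_bp: int = 1000,
) -> tuple[list[InsertionLocus], PresenceMatrix]:
    """Merge retained panel peaks into per-family loci.

    Same-family peaks whose margin-expanded intervals overlap are merged
    transitively (a sorted sweep gives the transitive closure for
    intervals).  Locus coordinates are the union of member peak intervals;
    presence marks every line contributing a member peak.
    """
    line_idx = {c: i for i, c in enumerate(cell_lines)}
    groups: dict[tuple[str, str], list] = {}
    for p in peaks:
        groups.setdefault((p.family, p.chrom), []).append(p)

    loci: list[InsertionLocus] = []
    counters: dict[str, int] = {}
    for (family, chrom), members in sorted(groups.items()):
        members.sort(key=lambda p: (p.start, p.end))
        cluster: list = []
        cluster_end = -1
        def flush() -> None:
            if not cluster:
                return
            k = counters.get(family, 0)
            counters[family] = k + 1
            presence = np.zeros(len(cell_lines), dtype=bool)
            for m in cluster:
                presence[line_idx[m.cell_line]] = True
            loci.append(
                InsertionLocus(
                    locus_id=f"locus_{family}_{k:05d}",
                    chrom=chrom,
                    start=min(m.start for m in cluster),
                    end=max(m.end for m in cluster),
                    family=family,
                    presence=presence,
                    member_peaks=list(cluster),
                )
            )
        for p in members:
            if cluster and p.start - merge_margin_bp < cluster_end + merge_margin_bp:
                cluster.append(p)
                cluster_end = max(cluster_end, p.end)
            else:
                flush()
                cluster = [p]
                cluster_end = p.end
        flush()

    loci.sort(key=lambda l: (l.family, l.chrom, l.start))
    mat = pd.DataFrame(
        {l.locus_id: l.presence for l in loci}, index=cell_lines
    ).T.astype(bool)
    mat.columns = list(cell_lines)
    return loci, PresenceMatrix(mat)


def classify_locus(
    locus: InsertionLocus, db: KnownInsertionDB, margin_bp: int = 1000
) -> str:
    """Assign the locus category and record its DB matches.

    Precedence: reference DB match, then known-polymorphic DB match, then
    carrier count (>= 2 lines novel polymorphic, else singleton).  A locus
    matching both reference and polymorphic records keeps category
    ``reference`` and sets ``ref_and_poly``.
    """
    ref_ids = match_known(locus, db.subset(source="reference"), margin_bp)
    poly_ids = match_known(locus, db.subset(source="known_polymorphic"), margin_bp)
    locus.matched_db_ids = ref_ids + poly_ids
    locus.ref_and_poly = bool(ref_ids) and bool(poly_ids)
    if ref_ids:
        locus.category = "reference"
    elif poly_ids:
        locus.category = "known_polymorphic"
    elif locus.n_present >= 2:
        locus.category = "novel_polymorphic"
    else:
        locus.category = "singleton"
    return locus.category


@dataclass
class PanelSummary:
    #: rows (cell_line, family, category, count) — stacked-bar table
    per_line_counts: pd.DataFrame
    #: rows (family, n_lines, n_loci) — locus frequency distribution
    frequency_table: pd.DataFrame
    #: family -> singletons / non-reference loci
    singleton_fraction: dict[str, float]


def summarize_panel(
    loci: list[InsertionLocus],
    cell_lines: list[str],
    collapse_alu: bool = True,
) -> PanelSummary:
    """Panel summaries with Alu subfamilies collapsed by default."""
    fam_of = collapse_family if collapse_alu else (lambda f: f)
    rows = []
    for li, line in enumerate(cell_lines):
        counts: dict[tuple[str, str], int] = {}
        for locus in loci:
            if locus.presence[li]:
                key = (fam_of(locus.family), locus.category)
                counts[key] = counts.get(key, 0) + 1
        for (fam, cat), n in sorted(counts.items()):
            rows.append(dict(cell_line=line, family=fam, category=cat, count=n))
    per_line = pd.DataFrame(rows, columns=["cell_line", "family", "category", "count"])

    freq_rows = []
    families = sorted({fam_of(l.family) for l in loci})
    for fam in families:
        fam_loci = [l for l in loci if fam_of(l.family) == fam]
        counts = np.bincount(
            [l.n_present for l in fam_loci], minlength=len(cell_lines) + 1
        )
        for n_lines in range(1, len(cell_lines) + 1):
            freq_rows.append(
                dict(family=fam, n_lines=n_lines, n_loci=int(counts[n_lines]))
            )
    freq = pd.DataFrame(freq_rows, columns=["family", "n_lines", "n_loci"])

    singleton_fraction: dict[str, float] = {}
    for fam in families:
        fam_loci = [l for l in loci if fam_of(l.family) == fam]
        nonref = [l for l in fam_loci if l.category != "reference"]
        n_single = sum(1 for l in nonref if l.category == "singleton")
        singleton_fraction[fam] = n_single / len(nonref) if nonref else 0.0
    return PanelSummary(per_line, freq, singleton_fraction)


def exon_overlap_report(
    loci: list[InsertionLocus],
    genes: list,
    flank_bp: int = 10_000,
) -> pd.DataFrame:
    """Gene context per locus.

    Labels by midpoint containment: exonic_3utr, exonic_cds, intronic,
    flank (within gene +/- flank but outside the transcript), or untiled.
    ``partial_overlap`` flags a locus interval that overlaps an exon without
    being contained in it (insertions near exon boundaries).  Gene objects
    need gene_id/chrom/start/end/exons/utr3 attributes.
    """
    rows = []
    for locus in loci:
        mid = locus.midpoint
        label, gene_id, partial = "untiled", "", False
        for g in genes:
            if g.chrom != locus.chrom:
                continue
            if not (g.start - flank_bp <= mid < g.end + flank_bp):
                continue
            gene_id = g.gene_id
            us, ue = g.utr3
            if us <= mid < ue:
                label = "exonic_3utr"
            elif any(s <= mid < e for s, e in g.exons):
                label = "exonic_cds"
            elif g.start <= mid < g.end:
                label = "intronic"
            else:
                label = "flank"
            for s, e in g.exons:
                overlaps = locus.start < e and s < locus.end
                contained = s <= locus.start and locus.end <= e
                if overlaps and not contained:
                    partial = True
            break
        if label == "untiled":
            logger.info("locus %s falls outside all tiled regions", locus.locus_id)
        rows.append(
            dict(
                locus_id=locus.locus_id,
                label=label,
                gene_id=gene_id,
                partial_overlap=partial,
            )
        )
    return pd.DataFrame(rows, columns=["locus_id", "label", "gene_id", "partial_overlap"])


def deletion_flag(
    loci: list[InsertionLocus],
    cell_lines: list[str],
    max_absent: int = 1,
) -> pd.DataFrame:
    """Reference loci absent from at most ``max_absent`` lines: candidate
    genomic deletions in the absent lines."""
    rows = []
    for locus in loci:
        if locus.category != "reference":
            continue
        absent = [c for c, p in zip(cell_lines, locus.presence) if not p]
        if 1 <= len(absent) <= max_absent:
            rows.append(
                dict(
                    locus_id=locus.locus_id,
                    chrom=locus.chrom,
                    start=locus.start,
                    end=locus.end,
                    n_absent=len(absent),
                    absent_lines=",".join(absent),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["locus_id", "chrom", "start", "end", "n_absent", "absent_lines"],
    )
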