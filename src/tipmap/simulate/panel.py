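"""Genome layout, planted truth and restriction maps.

Coordinates are 0-based, half-open throughout.  Determinism contract: every
random draw comes from a generator seeded as ``default_rng([seed, stage])``
(plus per-track indices where applicable), so identical configs produce
byte-identical outputs regardless of call order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tipmap.config import CATEGORIES, SimConfig
from tipmap.loci import KnownInsertionDB

logger = logging.getLogger(__name__)

# rng stage tags (second word of the seed sequence)
_STAGE_LAYOUT = 1
_STAGE_TRUTH = 2
_STAGE_RESTRICT = 3


class CapacityError(ValueError):
    """Requested insertion counts cannot be placed in the tiled regions."""


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]
    utr3: tuple[int, int]


@dataclass
class GenomeLayout:
    """Tiled gene loci with flanks, plus the probe grid covering them."""

    chrom_lengths: dict[str, int]
    genes: list[GeneModel]
    #: merged, sorted (chrom, start, end) union of gene +/- flank intervals
    tiled_regions: list[tuple[str, int, int]]
    #: columns chrom, start, end, masked — sorted by (chrom, start)
    probes: pd.DataFrame
    flank_bp: int = 0

    def total_tiled_bp(self) -> int:
        return sum(e - s for _, s, e in self.tiled_regions)


@dataclass
class Insertion:
    locus_id: str
    chrom: str
    position: int
    strand: str
    family: str
    category: str
    presence: np.ndarray  # bool per cell line

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass
class PlantedTruth:
    cell_lines: list[str]
    insertions: list[Insertion]
    #: filled by simulate_intensities: (locus_id, cell_line) -> (chrom, s, e)
    footprints: dict[tuple[str, str], tuple[str, int, int]] = field(
        default_factory=dict
    )

    def by_id(self) -> dict[str, Insertion]:
        return {ins.locus_id: ins for ins in self.insertions}

    def counts_by_category(self) -> dict[tuple[str, str], int]:
        out: dict[tuple[str, str], int] = {}
        for ins in self.insertions:
            key = (ins.family, ins.category)
            out[key] = out.get(key, 0) + 1
        return out


@dataclass
class RestrictionMap:
    """Per-enzyme cut-site positions plus their union, per contig."""

    sites: dict[str, dict[str, np.ndarray]]  # enzyme -> chrom -> sorted pos

    def enzymes(self) -> list[str]:
        return sorted(self.sites)

    def union(self, chrom: str) -> np.ndarray:
        arrs = [s.get(chrom, np.empty(0, int)) for s in self.sites.values()]
        if not arrs:
            return np.empty(0, dtype=int)
        return np.unique(np.concatenate(arrs))


def _sample_gene_lengths(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    m, s = cfg.gene_length_mean_bp, cfg.gene_length_sd_bp
    if s <= 0:
        lengths = np.full(cfg.n_genes, m)
    else:
        sigma2 = np.log1p((s / m) ** 2)
        mu = np.log(m) - sigma2 / 2.0
        lengths = rng.lognormal(mu, np.sqrt(sigma2), size=cfg.n_genes)
    return np.maximum(lengths.astype(int), cfg.min_gene_length_bp)


def _make_exons(
    start: int, end: int, strand: str, rng: np.random.Generator
) -> tuple[list[tuple[int, int]], tuple[int, int]]:
    """Split a gene body into alternating exons/introns; carve a 3'UTR out of
    the terminal exon (in transcription direction)."""
    n_ex = int(rng.integers(2, 9))
    n_break = 2 * n_ex - 2
    interior = np.unique(rng.integers(start + 1, end - 1, size=n_break * 3))
    if interior.size < n_break:
        exons = [(start, end)]
    else:
        picks = np.sort(rng.choice(interior, size=n_break, replace=False))
        bounds = [start, *picks.tolist(), end]
        exons = [
            (bounds[i], bounds[i + 1]) for i in range(0, len(bounds) - 1, 2)
        ]
    if strand == "+":
        es, ee = exons[-1]
        utr_len = max(1, int(0.3 * (ee - es)))
        utr3 = (ee - utr_len, ee)
    else:
        es, ee = exons[0]
        utr_len = max(1, int(0.3 * (ee - es)))
        utr3 = (es, es + utr_len)
    return exons, utr3


def _merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(iv):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def build_layout(cfg: SimConfig) -> GenomeLayout:
    """Place genes on contigs, tile transcript +/- flank regions with probes."""
    rng = np.random.default_rng([cfg.seed, _STAGE_LAYOUT])
    lengths = _sample_gene_lengths(cfg, rng)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    genes: list[GeneModel] = []
    cursors = {c: cfg.intergenic_gap_bp for c in chroms}
    for gi in range(cfg.n_genes):
        chrom = chroms[gi % cfg.n_chroms]
        start = cursors[chrom]
        end = start + int(lengths[gi])
        strand = "+" if rng.random() < 0.5 else "-"
        exons, utr3 = _make_exons(start, end, strand, rng)
        genes.append(
            GeneModel(f"G{gi:04d}", chrom, start, end, strand, exons, utr3)
        )
        cursors[chrom] = end + cfg.intergenic_gap_bp
    chrom_lengths = {c: cursors[c] + cfg.flank_bp for c in chroms}

    tiled: list[tuple[str, int, int]] = []
    for chrom in chroms:
        iv = [
            (max(0, g.start - cfg.flank_bp), min(chrom_lengths[chrom], g.end + cfg.flank_bp))
            for g in genes
            if g.chrom == chrom
        ]
        tiled.extend((chrom, s, e) for s, e in _merge_intervals(iv))

    rows = []
    for chrom, s, e in tiled:
        starts = np.arange(s, e - cfg.probe_length_bp + 1, cfg.probe_spacing_bp)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + cfg.probe_length_bp,
                }
            )
        )
    probes = pd.concat(rows, ignore_index=True)
    probes = probes.sort_values(["chrom", "start"], kind="mergesort").reset_index(
        drop=True
    )
    mask_rng = np.random.default_rng([cfg.seed, _STAGE_LAYOUT, 99])
    probes["masked"] = mask_rng.random(len(probes)) < cfg.masked_probe_fraction
    return GenomeLayout(chrom_lengths, genes, tiled, probes, flank_bp=cfg.flank_bp)


def _sample_positions(
    n: int,
    tiled: list[tuple[str, int, int]],
    taken: dict[str, list[int]],
    min_spacing: int,
    rng: np.random.Generator,
) -> list[tuple[str, int]]:
    """Uniform positions over tiled regions, rejecting any within
    ``min_spacing`` of an already-taken same-family position."""
    if n == 0:
        return []
    lens = np.array([e - s for _, s, e in tiled], dtype=np.int64)
    total = int(lens.sum())
    if n * min_spacing > total:
        raise CapacityError(
            f"cannot place {n} insertions with {min_spacing} bp spacing "
            f"in {total} bp of tiled sequence"
        )
    cum = np.cumsum(lens)
    out: list[tuple[str, int]] = []
    tries = 0
    max_tries = 500 * n + 1000
    while len(out) < n:
        tries += 1
        if tries > max_tries:
            raise CapacityError(
                f"placement rejection budget exhausted after {tries} tries "
                f"({len(out)}/{n} placed)"
            )
        off = int(rng.integers(0, total))
        ridx = int(np.searchsorted(cum, off, side="right"))
        chrom, s, _ = tiled[ridx]
        pos = s + off - (int(cum[ridx - 1]) if ridx else 0)
        near = taken.setdefault(chrom, [])
        if near and min(abs(pos - p) for p in near) < min_spacing:
            continue
        near.append(pos)
        out.append((chrom, pos))
    return out


def _presence_vector(
    n_lines: int,
    freq: float,
    min_carriers: int,
    rng: np.random.Generator,
) -> np.ndarray:
    vec = rng.random(n_lines) < freq
    if vec.sum() < min_carriers:
        extra = rng.choice(n_lines, size=min_carriers, replace=False)
        vec[extra] = True
    return vec


def simulate_panel(
    cfg: SimConfig,
) -> tuple[GenomeLayout, PlantedTruth, KnownInsertionDB]:
    """Generate the tiled layout, planted insertions and the known-insertion DB.

    Reference insertions are present in every line and recorded in the DB
    with source ``reference``; known-polymorphic insertions are recorded
    with source ``known_polymorphic`` (a ``known_poly_db_fraction`` < 1
    drops some from the DB and relabels them by their carrier count, so the
    truth stays consistent with DB membership).  Novel-polymorphic and
    singleton insertions never enter the DB.
    """
    layout = build_layout(cfg)
    rng = np.random.default_rng([cfg.seed, _STAGE_TRUTH])
    n_lines = cfg.n_cell_lines
    cell_lines = [f"CL{i + 1:02d}" for i in range(n_lines)]
    lo, hi = cfg.allele_freq_range

    insertions: list[Insertion] = []
    db_rows: list[dict] = []
    for fam in cfg.families:
        counts = {
            cat: cfg.counts_per_family(name)[fam]
            for cat, name in (
                ("reference", "n_reference"),
                ("known_polymorphic", "n_known_poly"),
                ("novel_polymorphic", "n_novel_poly"),
                ("singleton", "n_singleton"),
            )
        }
        n_fam = sum(counts.values()) + cfg.n_db_extra_reference
        taken: dict[str, list[int]] = {}
        positions = _sample_positions(
            n_fam, layout.tiled_regions, taken, cfg.min_insertion_spacing_bp, rng
        )
        pi = 0
        idx = 0
        for cat in CATEGORIES:
            for _ in range(counts[cat]):
                chrom, pos = positions[pi]
                pi += 1
                strand = "+" if rng.random() < 0.5 else "-"
                locus_id = f"{fam}_{idx:04d}"
                idx += 1
                if cat == "reference":
                    presence = np.ones(n_lines, dtype=bool)
                    db_rows.append(
                        dict(chrom=chrom, start=pos, end=pos + 1, family=fam,
                             source="reference", db_id=f"db_{locus_id}")
                    )
                    if rng.random() < cfg.reference_also_polymorphic_fraction:
                        db_rows.append(
                            dict(chrom=chrom, start=pos, end=pos + 1, family=fam,
                                 source="known_polymorphic",
                                 db_id=f"db_{locus_id}_poly")
                        )
                elif cat == "known_polymorphic":
                    presence = _presence_vector(
                        n_lines, rng.uniform(lo, hi), 1, rng
                    )
                    if rng.random() < cfg.known_poly_db_fraction:
                        db_rows.append(
                            dict(chrom=chrom, start=pos, end=pos + 1, family=fam,
                                 source="known_polymorphic",
                                 db_id=f"db_{locus_id}")
                        )
                    else:
                        # dropped from DB: relabel by carrier count
                        cat = (
                            "novel_polymorphic" if presence.sum() >= 2 else "singleton"
                        )
                elif cat == "novel_polymorphic":
                    presence = _presence_vector(
                        n_lines, rng.uniform(lo, hi), 2, rng
                    )
                else:  # singleton
                    presence = np.zeros(n_lines, dtype=bool)
                    presence[int(rng.integers(0, n_lines))] = True
                insertions.append(
                    Insertion(locus_id, chrom, pos, strand, fam, cat, presence)
                )
        for j in range(cfg.n_db_extra_reference):
            chrom, pos = positions[pi]
            pi += 1
            db_rows.append(
                dict(chrom=chrom, start=pos, end=pos + 1, family=fam,
                     source="reference", db_id=f"db_{fam}_extra{j:04d}")
            )

    truth = PlantedTruth(cell_lines=cell_lines, insertions=insertions)
    db = KnownInsertionDB(pd.DataFrame(
        db_rows, columns=["chrom", "start", "end", "family", "source", "db_id"]
    ))
    return layout, truth, db


def simulate_restriction_map(cfg: SimConfig, layout: GenomeLayout) -> RestrictionMap:
    """Cut sites per enzyme as a Poisson process with the configured mean
    spacing: exponential inter-site gaps accumulated along each contig."""
    sites: dict[str, dict[str, np.ndarray]] = {}
    for ei in range(cfg.n_enzymes):
        enzyme = f"E{ei + 1}"
        rng = np.random.default_rng([cfg.seed, _STAGE_RESTRICT, ei])
        per_chrom: dict[str, np.ndarray] = {}
        for chrom in sorted(layout.chrom_lengths):
            length = layout.chrom_lengths[chrom]
            if length <= 0:
                per_chrom[chrom] = np.empty(0, dtype=int)
                continue
            n_exp = max(16, int(2 * length / cfg.enzyme_site_mean_spacing_bp))
            gaps = rng.exponential(cfg.enzyme_site_mean_spacing_bp, size=n_exp)
            pos = np.cumsum(gaps)
            while pos.size and pos[-1] < length:
                gaps = rng.exponential(cfg.enzyme_site_mean_spacing_bp, size=n_exp)
                pos = np.concatenate([pos, pos[-1] + np.cumsum(gaps)])
            per_chrom[chrom] = pos[pos < length].astype(int)
        sites[enzyme] = per_chrom
    return RestrictionMap(sites)
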