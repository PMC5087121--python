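"""Amplicon-footprint intensity model.

The wet assay amplifies, in four parallel digests, the fragment running from
an insertion to that digest's nearest downstream cut site (downstream in the
direction the element points: plus strand -> rightward).  The hybridized
material is the pool of those reactions, so the probe-level footprint of an
insertion is the interval from the insertion to the *farthest* per-enzyme
nearest site, capped at ``max_footprint_bp`` (long fragments amplify
poorly).  With four enzymes at 2.5 kb mean spacing this gives a median
footprint of ~4-5 kb.  Probes inside a footprint draw intensities from
``Normal(signal_mean, signal_sd)``; everything else is
``Normal(0, baseline_sd)`` (log2-ratio units).
"""

from __future__ import annotations

import logging

import numpy as np

from tipmap.config import SimConfig
from tipmap.peaks import ProbeTrack
from tipmap.simulate.panel import (
    GenomeLayout,
    Insertion,
    PlantedTruth,
    RestrictionMap,
)

logger = logging.getLogger(__name__)

_STAGE_INTENSITY = 4


def amplicon_footprint(
    ins: Insertion,
    rmap: RestrictionMap,
    chrom_length: int,
    max_footprint_bp: int,
    min_len_bp: int,
) -> tuple[int, int]:
    """Footprint interval (0-based half-open) of one insertion.

    Pooled union over enzymes: each digest contributes the fragment from the
    insertion to its own nearest cut site on the strand-dictated side, so
    the union runs to the farthest of those per-enzyme nearest sites.
    Capped at ``max_footprint_bp``, clipped to the contig, and at least
    ``min_len_bp`` long.
    """
    pos = ins.position
    rightward = ins.strand == "+"
    per_enzyme: list[int] = []
    for enzyme in rmap.enzymes():
        sites = rmap.sites[enzyme].get(ins.chrom, np.empty(0, int))
        if rightward:
            i = int(np.searchsorted(sites, pos, side="right"))
            per_enzyme.append(int(sites[i]) if i < sites.size else chrom_length)
        else:
            i = int(np.searchsorted(sites, pos, side="left")) - 1
            per_enzyme.append(int(sites[i]) if i >= 0 else 0)
    if rightward:
        far = max(per_enzyme) if per_enzyme else chrom_length
        if far > chrom_length or pos + max_footprint_bp > chrom_length:
            logger.debug("footprint for %s clipped at contig end", ins.locus_id)
        start, end = pos, min(pos + max_footprint_bp, far, chrom_length)
        if end - start < min_len_bp:
            end = min(chrom_length, start + min_len_bp)
    else:
        far = min(per_enzyme) if per_enzyme else 0
        start, end = max(pos - max_footprint_bp, far, 0), pos
        if end - start < min_len_bp:
            start = max(0, end - min_len_bp)
    return start, end


def compute_footprints(
    cfg: SimConfig,
    truth: PlantedTruth,
    rmap: RestrictionMap,
    layout: GenomeLayout,
) -> dict[str, tuple[str, int, int]]:
    """Per-locus footprint; also records per-(locus, carrier line) entries in
    ``truth.footprints``."""
    out: dict[str, tuple[str, int, int]] = {}
    for ins in truth.insertions:
        start, end = amplicon_footprint(
            ins,
            rmap,
            layout.chrom_lengths[ins.chrom],
            cfg.max_footprint_bp,
            cfg.probe_spacing_bp,
        )
        out[ins.locus_id] = (ins.chrom, start, end)
        for li, line in enumerate(truth.cell_lines):
            if ins.presence[li]:
                truth.footprints[(ins.locus_id, line)] = (ins.chrom, start, end)
    return out


def simulate_intensities(
    cfg: SimConfig,
    truth: PlantedTruth,
    rmap: RestrictionMap,
    layout: GenomeLayout,
) -> dict[tuple[str, str], ProbeTrack]:
    """One ProbeTrack per (cell line, family channel).

    Returns a dict keyed by ``(cell_line, family)``.  Footprints are
    identical across carrier lines (the restriction map is a property of the
    genome); intensities are drawn independently per track.
    """
    footprints = compute_footprints(cfg, truth, rmap, layout)
    probes = layout.probes
    by_chrom: dict[str, tuple[int, np.ndarray, np.ndarray]] = {}
    for chrom, sub in probes.groupby("chrom", sort=True):
        by_chrom[chrom] = (
            int(sub.index[0]),
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
        )

    by_family: dict[str, list[Insertion]] = {f: [] for f in cfg.families}
    for ins in truth.insertions:
        by_family[ins.family].append(ins)

    tracks: dict[tuple[str, str], ProbeTrack] = {}
    for li, line in enumerate(truth.cell_lines):
        for fi, fam in enumerate(cfg.families):
            rng = np.random.default_rng([cfg.seed, _STAGE_INTENSITY, li, fi])
            vals = rng.normal(0.0, cfg.baseline_sd, size=len(probes))
            for ins in by_family[fam]:
                if not ins.presence[li]:
                    continue
                chrom, fs, fe = footprints[ins.locus_id]
                off, starts, ends = by_chrom[chrom]
                i0 = int(np.searchsorted(ends, fs, side="right"))
                i1 = int(np.searchsorted(starts, fe, side="left"))
                if i1 > i0:
                    vals[off + i0 : off + i1] = rng.normal(
                        cfg.signal_mean, cfg.signal_sd, size=i1 - i0
                    )
            df = probes.copy()
            df["intensity"] = vals
            df = df[["chrom", "start", "end", "intensity", "masked"]]
            tracks[(line, fam)] = ProbeTrack(df, cell_line=line, family=fam)
    return tracks


def footprint_probe_counts(
    truth: PlantedTruth, layout: GenomeLayout, unmasked_only: bool = True
) -> dict[str, int]:
    """Number of (unmasked) probes overlapping each locus's footprint."""
    probes = layout.probes
    by_chrom = {
        chrom: (
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
            sub["masked"].to_numpy(),
        )
        for chrom, sub in probes.groupby("chrom", sort=True)
    }
    seen: dict[str, tuple[str, int, int]] = {}
    for (locus_id, _line), fp in truth.footprints.items():
        seen.setdefault(locus_id, fp)
    out: dict[str, int] = {}
    for locus_id, (chrom, fs, fe) in seen.items():
        starts, ends, masked = by_chrom[chrom]
        i0 = int(np.searchsorted(ends, fs, side="right"))
        i1 = int(np.searchsorted(starts, fe, side="left"))
        if unmasked_only:
            out[locus_id] = int((~masked[i0:i1]).sum())
        else:
            out[locus_id] = i1 - i0
    return out
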