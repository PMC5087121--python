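"""End-to-end pipeline helpers shared by acceptance tests and the
acceptance report script."""

from __future__ import annotations

import numpy as np

from tipmap.calibrate import calibrate_track
from tipmap.peaks import PeakParams, call_peaks
from tipmap.simulate import footprint_probe_counts, simulate_all


def run_panel_pipeline(cfg, peak_params: PeakParams | None = None, margin: int = 1000):
    """Simulate a panel, call peaks per (line, family) track, and calibrate
    each track's cutoff (knee with fixed-cutoff fallback).

    Returns (SimResult, retained_peaks dict keyed by (line, family)).
    """
    params = peak_params or PeakParams()
    res = simulate_all(cfg, with_phenotypes=False)
    retained = {}
    for (line, fam), track in sorted(res.tracks.items()):
        calls = call_peaks(track, params)
        kept, _, _ = calibrate_track(
            calls, res.db, margin_bp=margin, family=fam, cell_line=line
        )
        retained[(line, fam)] = kept
    return res, retained


def recall_precision(res, retained, margin: int = 1000, min_probes: int = 5):
    """Recall/precision of retained peaks against planted truth.

    Recall is over (insertion, carrier line) pairs whose footprint covers at
    least ``min_probes`` unmasked probes; a pair is recovered when a
    retained peak of the right family/line lies within ``margin`` of the
    insertion position.  Precision is the fraction of retained peaks lying
    within ``margin`` of any planted insertion present in that line.
    """
    probe_counts = footprint_probe_counts(res.truth, res.layout)
    truth_by = {}
    for ins in res.truth.insertions:
        truth_by.setdefault(ins.family, []).append(ins)

    n_eligible = 0
    n_recovered = 0
    n_peaks = 0
    n_matched_peaks = 0
    for li, line in enumerate(res.truth.cell_lines):
        for fam in res.config.families:
            kept = retained.get((line, fam), [])
            n_peaks += len(kept)
            fam_truth = [i for i in truth_by.get(fam, []) if i.presence[li]]
            for ins in fam_truth:
                if probe_counts.get(ins.locus_id, 0) < min_probes:
                    continue
                n_eligible += 1
                hit = any(
                    p.chrom == ins.chrom
                    and p.start - margin <= ins.position < p.end + margin
                    for p in kept
                )
                n_recovered += hit
            for p in kept:
                chrom, fs_fe = p.chrom, None
                matched = any(
                    i.chrom == p.chrom
                    and p.start - margin <= i.position < p.end + margin
                    for i in fam_truth
                )
                n_matched_peaks += matched
    recall = n_recovered / n_eligible if n_eligible else float("nan")
    precision = n_matched_peaks / n_peaks if n_peaks else float("nan")
    return dict(
        recall=recall,
        precision=precision,
        n_eligible=n_eligible,
        n_recovered=n_recovered,
        n_peaks=n_peaks,
        n_matched_peaks=n_matched_peaks,
    )


def default_recovery_config(seed: int = 2016):
    """The end-to-end recovery panel: 20 lines, 200 genes, ~300 planted
    insertions (100 per family), signal_mean 8, baseline_sd 0.3."""
    from tipmap.config import SimConfig

    return SimConfig(
        seed=seed,
        n_cell_lines=20,
        n_genes=200,
        n_reference=34,
        n_known_poly=16,
        n_novel_poly=20,
        n_singleton=30,
        signal_mean=8.0,
        baseline_sd=0.3,
    )
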