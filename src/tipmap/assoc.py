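"""Insertion-phenotype association across the cell panel.

Each locus's presence/absence vector is correlated with every phenotype
feature by point-biserial correlation (Pearson r of the 0/1 indicator with
the values; two-sided p from t = r * sqrt((n-2)/(1-r^2)) on n-2 df).
Singleton loci are tested only against features anchored in cis (within
30 kb); p-values are Bonferroni-corrected with family size equal to the
number of tests actually performed in the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from tipmap.loci import InsertionLocus, PresenceMatrix

logger = logging.getLogger(__name__)

CIS_WINDOW_BP = 30_000


class NotEstimable(ValueError):
    """Association statistic cannot be computed for this pair."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass
class AssociationResult:
    locus_id: str
    feature_id: str
    r: float
    p_raw: float
    p_bonf: float
    n_lines_used: int
    cis: bool
    distance_bp: int | None = None  # None when the feature is unanchored


def point_biserial(
    presence: np.ndarray, values: np.ndarray
) -> tuple[float, float]:
    """Point-biserial correlation and two-sided p-value.

    Raises :class:`NotEstimable` when fewer than 3 paired observations
    remain after dropping missing values, when either carrier group is
    empty, or when the values are constant.
    """
    presence = np.asarray(presence, dtype=float)
    values = np.asarray(values, dtype=float)
    keep = ~np.isnan(values)
    presence, values = presence[keep], values[keep]
    n = len(values)
    if n < 3:
        raise NotEstimable("fewer than 3 paired observations")
    n1 = int(presence.sum())
    if n1 == 0 or n1 == n:
        raise NotEstimable("single-group presence vector")
    if np.allclose(values, values[0]):
        raise NotEstimable("constant phenotype values")
    r, p = stats.pearsonr(presence, values)
    return float(r), float(p)


def bonferroni(p_raw: float, m: int) -> float:
    """min(1, p_raw * m)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, p_raw * m)


def classify_cis_trans(
    locus: InsertionLocus,
    anchor: tuple[str, int] | None,
    window_bp: int = CIS_WINDOW_BP,
) -> tuple[bool, int | None]:
    """Cis iff the anchor is on the locus chromosome within ``window_bp`` of
    the locus interval.  Unanchored features are always trans.  Returns
    (cis flag, distance or None)."""
    if anchor is None:
        return False, None
    chrom, pos = anchor
    if chrom != locus.chrom:
        return False, None
    if locus.start <= pos < locus.end:
        return True, 0
    dist = min(abs(pos - locus.start), abs(pos - (locus.end - 1)))
    return dist <= window_bp, dist


def run_compare(
    matrix: PresenceMatrix,
    phenotypes,
    loci: list[InsertionLocus],
    window_bp: int = CIS_WINDOW_BP,
    min_minor_count: int = 2,
) -> pd.DataFrame:
    """Associate every locus with phenotype features, COMPARE-style.

    Non-singleton loci are tested against all features, provided the minor
    presence group has at least ``min_minor_count`` lines; singleton loci
    are tested only against features anchored in cis.  The Bonferroni
    family size m is the number of tests performed in this run.
    ``phenotypes`` needs ``values`` (features x lines DataFrame) and
    ``anchor_of(feature_id)``.
    """
    pm_lines = list(matrix.matrix.columns)
    ph_lines = list(phenotypes.values.columns)
    if set(pm_lines) != set(ph_lines):
        only_pm = sorted(set(pm_lines) - set(ph_lines))
        only_ph = sorted(set(ph_lines) - set(pm_lines))
        raise ValueError(
            "cell-line label mismatch between presence matrix and phenotypes: "
            f"only in matrix {only_pm}, only in phenotypes {only_ph}"
        )
    values = phenotypes.values[pm_lines]
    by_id = {l.locus_id: l for l in loci}

    anchors = {
        fid: phenotypes.anchor_of(fid) for fid in values.index
    }
    tested: list[AssociationResult] = []
    skipped: list[tuple[str, str, str]] = []
    for locus_id in matrix.matrix.index:
        locus = by_id.get(locus_id)
        if locus is None:
            raise ValueError(f"presence matrix row {locus_id} has no locus record")
        presence = matrix.matrix.loc[locus_id].to_numpy(dtype=bool)
        singleton = locus.category == "singleton"
        minor = min(int(presence.sum()), len(presence) - int(presence.sum()))
        for fid in values.index:
            cis, dist = classify_cis_trans(locus, anchors[fid], window_bp)
            if singleton:
                if not cis:
                    continue  # singletons: cis effects only
            elif minor < min_minor_count:
                skipped.append((locus_id, fid, "minor group too small"))
                continue
            try:
                r, p_raw = point_biserial(presence, values.loc[fid].to_numpy())
            except NotEstimable as exc:
                skipped.append((locus_id, fid, exc.reason))
                continue
            n_used = int(np.sum(~np.isnan(values.loc[fid].to_numpy())))
            tested.append(
                AssociationResult(
                    locus_id=locus_id,
                    feature_id=fid,
                    r=r,
                    p_raw=p_raw,
                    p_bonf=np.nan,
                    n_lines_used=n_used,
                    cis=cis,
                    distance_bp=dist,
                )
            )
    m = len(tested)
    for res in tested:
        res.p_bonf = bonferroni(res.p_raw, m)
    if skipped:
        logger.info("%d locus-feature pairs not estimable/skipped", len(skipped))
    df = pd.DataFrame(
        [r.__dict__ for r in tested],
        columns=[
            "locus_id", "feature_id", "r", "p_raw", "p_bonf",
            "n_lines_used", "cis", "distance_bp",
        ],
    )
    df.attrs["m_tests"] = m
    df.attrs["skipped"] = skipped
    return df


def manhattan_export(
    results: pd.DataFrame, loci: list[InsertionLocus]
) -> pd.DataFrame:
    """Plot-ready table: (chrom, pos, neg_log10_p_bonf, feature_id, cis)
    ordered by genome position, one row per association at the locus start
    coordinate."""
    cols = ["chrom", "pos", "neg_log10_p_bonf", "locus_id", "feature_id", "cis"]
    if results.empty:
        return pd.DataFrame(columns=cols)
    by_id = {l.locus_id: l for l in loci}
    rows = []
    for rec in results.itertuples():
        locus = by_id[rec.locus_id]
        with np.errstate(divide="ignore"):
            nlp = float(-np.log10(rec.p_bonf)) if rec.p_bonf > 0 else float("inf")
        rows.append(
            dict(
                chrom=locus.chrom,
                pos=locus.start,
                neg_log10_p_bonf=nlp,
                locus_id=rec.locus_id,
                feature_id=rec.feature_id,
                cis=bool(rec.cis),
            )
        )
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(["chrom", "pos", "feature_id"], kind="mergesort").reset_index(
        drop=True
    )
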