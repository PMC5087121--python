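"""Rank-cutoff calibration from reference-insertion recovery curves.

Peaks are ranked by detection threshold; plotting the cumulative number of
distinct reference insertions recovered against peak rank gives a curve
that rises while ranks still capture real insertions and flattens once they
do not.  The cutoff is placed at the curve's knee — the point of maximum
perpendicular deviation *above* the chord joining its endpoints — with a
fixed family threshold (percentile > 70 for L1, > 60 for Alu) as fallback
for degenerate curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from tipmap.loci import KnownInsertionDB, match_known
from tipmap.peaks import PeakCall

logger = logging.getLogger(__name__)

#: fixed fallback cutoffs: retain peaks with rank_threshold strictly above.
FIXED_CUTOFFS = {"L1": 70.0, "Alu": 60.0, "AluYa": 60.0, "AluYb": 60.0}


class DegenerateCurveError(ValueError):
    """Recovery curve has no knee (linear or constant)."""


@dataclass
class RecoveryCurve:
    """Cumulative distinct reference insertions recovered by rank.

    ``cumulative[i]`` counts reference DB records matched by peaks of rank
    1..i+1; the curve is non-decreasing and bounded by the reference DB
    size for the family.
    """

    ranks: np.ndarray  # 1..N
    cumulative: np.ndarray
    family: str = ""
    cell_line: str = ""

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=int)
        self.cumulative = np.asarray(self.cumulative, dtype=int)
        if len(self.ranks) != len(self.cumulative):
            raise ValueError("ranks and cumulative must have equal length")
        if len(self.cumulative) and (np.diff(self.cumulative) < 0).any():
            raise ValueError("cumulative hits must be non-decreasing")

    def __len__(self) -> int:
        return len(self.ranks)


@dataclass
class CutoffDecision:
    rank_cutoff: int
    threshold_cutoff: float
    method: str  # "knee" or "fixed"
    family: str = ""
    cell_line: str = ""
    reference_recovered: int = 0


def recovery_curve(
    peaks: list[PeakCall],
    ref_db: KnownInsertionDB,
    margin_bp: int = 1000,
    family: str | None = None,
    cell_line: str = "",
) -> RecoveryCurve:
    """Build the recovery curve for a ranked peak list.

    A peak matches a reference record of its own family whose position lies
    within ``margin_bp`` of the peak interval; each DB record counts once
    however many peaks hit it.
    """
    fam = family or (peaks[0].family if peaks else "")
    ref = ref_db.subset(source="reference")
    seen: set[str] = set()
    cum = np.zeros(len(peaks), dtype=int)
    for i, peak in enumerate(peaks):
        for rec in match_known(peak, ref, margin_bp):
            seen.add(rec)
        cum[i] = len(seen)
    return RecoveryCurve(
        ranks=np.arange(1, len(peaks) + 1),
        cumulative=cum,
        family=fam,
        cell_line=cell_line,
    )


def find_inflection(curve: RecoveryCurve, method: str = "chord") -> int:
    """Knee rank of a recovery curve.

    ``chord`` (default): the rank maximizing the signed perpendicular
    deviation of the curve above the chord joining its first and last
    points; ties take the smallest rank.  ``second_diff``: the rank of the
    most negative discrete second difference.  Raises
    :class:`DegenerateCurveError` for curves with no point above the chord
    (linear or constant), in which case callers fall back to the fixed
    family cutoff.
    """
    if len(curve) < 3:
        raise DegenerateCurveError("curve needs >= 3 points")
    x = curve.ranks.astype(float)
    y = curve.cumulative.astype(float)
    if method == "chord":
        dx, dy = x[-1] - x[0], y[-1] - y[0]
        norm = float(np.hypot(dx, dy))
        if norm == 0.0:
            raise DegenerateCurveError("zero-length chord")
        # positive where the curve lies above the chord
        dev = (dx * (y - y[0]) - dy * (x - x[0])) / norm
        best = int(np.argmax(dev))
        if dev[best] <= 1e-12:
            raise DegenerateCurveError("curve is linear or below its chord")
        return int(x[best])
    if method == "second_diff":
        d2 = np.diff(y, 2)
        if not len(d2) or np.allclose(d2, 0.0):
            raise DegenerateCurveError("no curvature")
        return int(x[int(np.argmin(d2)) + 1])
    raise ValueError(f"unknown knee method {method!r}")


def apply_cutoff(peaks: list[PeakCall], decision: CutoffDecision) -> list[PeakCall]:
    """Retain peaks allowed by a cutoff decision.

    ``knee``: keep ranks 1..rank_cutoff (a prefix of the ranked list).
    ``fixed``: keep peaks whose rank_threshold is strictly above the
    family's fixed percentile cutoff.
    """
    if decision.method == "knee":
        return list(peaks[: decision.rank_cutoff])
    if decision.method == "fixed":
        return [
            p
            for p in peaks
            if p.rank_threshold > FIXED_CUTOFFS[decision.family or p.family]
        ]
    raise ValueError(f"unknown cutoff method {decision.method!r}")


def calibrate_track(
    peaks: list[PeakCall],
    ref_db: KnownInsertionDB,
    margin_bp: int = 1000,
    family: str | None = None,
    cell_line: str = "",
    knee_method: str = "chord",
) -> tuple[list[PeakCall], CutoffDecision, RecoveryCurve]:
    """Per-(array, family) calibration: knee if the curve has one, else the
    fixed family cutoff.

    A knee is only accepted when the curve actually flattens past it: the
    mean slope after the knee must fall below half the slope before it, and
    the flat tail must span at least 5 ranks and 10 % of the curve.  A
    curve still rising at its end has no meaningful inflection and falls
    back to the fixed cutoff.
    """
    fam = family or (peaks[0].family if peaks else "")
    curve = recovery_curve(peaks, ref_db, margin_bp, family=fam, cell_line=cell_line)
    try:
        rank = find_inflection(curve, method=knee_method)
        y = curve.cumulative
        slope_before = y[rank - 1] / rank
        n_after = len(curve) - rank
        slope_after = (y[-1] - y[rank - 1]) / n_after if n_after else 0.0
        if slope_after > 0.5 * slope_before:
            raise DegenerateCurveError("curve still rising after candidate knee")
        if n_after < max(5, 0.1 * len(curve)):
            raise DegenerateCurveError("flat tail too short to support a knee")
        # the cutoff is imposed on the threshold value, so extend the knee
        # rank through peaks tied at the knee peak's rank_threshold
        knee_threshold = peaks[rank - 1].rank_threshold
        while rank < len(peaks) and peaks[rank].rank_threshold >= knee_threshold:
            rank += 1
        decision = CutoffDecision(
            rank_cutoff=rank,
            threshold_cutoff=knee_threshold,
            method="knee",
            family=fam,
            cell_line=cell_line,
            reference_recovered=int(curve.cumulative[rank - 1]),
        )
    except DegenerateCurveError:
        logger.info(
            "degenerate recovery curve for %s/%s; using fixed cutoff",
            cell_line, fam,
        )
        decision = CutoffDecision(
            rank_cutoff=len(peaks),
            threshold_cutoff=FIXED_CUTOFFS.get(fam, 0.0),
            method="fixed",
            family=fam,
            cell_line=cell_line,
            reference_recovered=int(curve.cumulative[-1]) if len(curve) else 0,
        )
    return apply_cutoff(peaks, decision), decision, curve


def synthetic_recovery_curve(
    n_true: int,
    n_noise: int,
    true_hit_rate: float,
    noise_hit_rate: float,
    rng: np.random.Generator,
    family: str = "",
    cell_line: str = "",
) -> RecoveryCurve:
    """Stochastic recovery curve: the top ``n_true`` ranks hit reference
    insertions at ``true_hit_rate``, the remaining ``n_noise`` at
    ``noise_hit_rate``.  Used to exercise knee detection against a known
    transition rank."""
    hits = np.concatenate(
        [
            rng.random(n_true) < true_hit_rate,
            rng.random(n_noise) < noise_hit_rate,
        ]
    )
    return RecoveryCurve(
        ranks=np.arange(1, n_true + n_noise + 1),
        cumulative=np.cumsum(hits),
        family=family,
        cell_line=cell_line,
    )
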