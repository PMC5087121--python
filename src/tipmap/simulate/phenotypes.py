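"""Synthetic phenotype profiles over the cell panel.

Null features are standard-normal per line.  A planted effect adds
``effect_sd`` times the carrier indicator of a locus to one feature.  Cis
effects get a genomic anchor placed within the cis window of their locus;
unanchored features are treated as trans by the association stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tipmap.config import SimConfig
from tipmap.simulate.panel import GenomeLayout, PlantedTruth

logger = logging.getLogger(__name__)

_STAGE_PHENO = 5


@dataclass
class PlantedEffect:
    locus_id: str
    feature_id: str
    effect_sd: float
    cis: bool = True


@dataclass
class PhenotypeMatrix:
    """Feature x cell-line continuous values with optional genomic anchors."""

    values: pd.DataFrame  # index: feature_id, columns: cell lines
    anchors: pd.DataFrame  # feature_id, chrom, position (chrom="" if none)
    effects: list[PlantedEffect] = field(default_factory=list)

    def anchor_of(self, feature_id: str) -> tuple[str, int] | None:
        row = self.anchors.loc[self.anchors["feature_id"] == feature_id]
        if row.empty or not row.iloc[0]["chrom"]:
            return None
        return str(row.iloc[0]["chrom"]), int(row.iloc[0]["position"])


def _random_anchor(
    layout: GenomeLayout, rng: np.random.Generator
) -> tuple[str, int]:
    chroms = sorted(layout.chrom_lengths)
    lens = np.array([layout.chrom_lengths[c] for c in chroms], dtype=float)
    ci = int(rng.choice(len(chroms), p=lens / lens.sum()))
    return chroms[ci], int(rng.integers(0, layout.chrom_lengths[chroms[ci]]))


def simulate_phenotypes(
    cfg: SimConfig,
    truth: PlantedTruth,
    layout: GenomeLayout,
    effects: list[PlantedEffect] | None = None,
) -> PhenotypeMatrix:
    """Null features plus any requested planted effects.

    ``anchored_fraction`` of null features get an anchor placed uniformly
    over the genome; effect features with ``cis=True`` are anchored within
    ``cis_anchor_window_bp`` of their locus.  Effects on singleton loci are
    allowed (they are only testable in cis) and logged.
    """
    rng = np.random.default_rng([cfg.seed, _STAGE_PHENO])
    effects = list(effects or [])
    lines = truth.cell_lines
    n = len(lines)
    by_id = truth.by_id()

    rows: dict[str, np.ndarray] = {}
    anchor_rows: list[dict] = []
    for i in range(cfg.n_null_features):
        fid = f"F{i:04d}"
        rows[fid] = rng.normal(0.0, 1.0, size=n)
        if rng.random() < cfg.anchored_fraction:
            chrom, pos = _random_anchor(layout, rng)
            anchor_rows.append(dict(feature_id=fid, chrom=chrom, position=pos))
        else:
            anchor_rows.append(dict(feature_id=fid, chrom="", position=-1))

    for eff in effects:
        ins = by_id.get(eff.locus_id)
        if ins is None:
            raise ValueError(f"planted effect references unknown locus {eff.locus_id}")
        if ins.category == "singleton":
            logger.info(
                "planted effect on singleton locus %s (cis-only testable)",
                eff.locus_id,
            )
        vals = rng.normal(0.0, 1.0, size=n) + eff.effect_sd * ins.presence.astype(float)
        rows[eff.feature_id] = vals
        if eff.cis:
            w = cfg.cis_anchor_window_bp
            offset = int(rng.integers(-w, w + 1))
            pos = int(np.clip(ins.position + offset, 0,
                              layout.chrom_lengths[ins.chrom] - 1))
            anchor_rows.append(
                dict(feature_id=eff.feature_id, chrom=ins.chrom, position=pos)
            )
        else:
            anchor_rows.append(dict(feature_id=eff.feature_id, chrom="", position=-1))

    values = pd.DataFrame.from_dict(rows, orient="index", columns=lines)
    values.index.name = "feature_id"
    anchors = pd.DataFrame(anchor_rows, columns=["feature_id", "chrom", "position"])
    return PhenotypeMatrix(values=values, anchors=anchors, effects=effects)
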