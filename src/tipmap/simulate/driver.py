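"""One-call simulation driver bundling all stages."""

from __future__ import annotations

from dataclasses import dataclass, field

from tipmap.config import SimConfig
from tipmap.loci import KnownInsertionDB
from tipmap.peaks import ProbeTrack
from tipmap.simulate.panel import (
    GenomeLayout,
    PlantedTruth,
    RestrictionMap,
    simulate_panel,
    simulate_restriction_map,
)
from tipmap.simulate.phenotypes import (
    PhenotypeMatrix,
    PlantedEffect,
    simulate_phenotypes,
)
from tipmap.simulate.signal import simulate_intensities


@dataclass
class SimResult:
    config: SimConfig
    layout: GenomeLayout
    truth: PlantedTruth
    db: KnownInsertionDB
    rmap: RestrictionMap
    tracks: dict[tuple[str, str], ProbeTrack]
    phenotypes: PhenotypeMatrix | None = None
    effects: list[PlantedEffect] = field(default_factory=list)


def simulate_all(
    cfg: SimConfig,
    effects: list[PlantedEffect] | None = None,
    with_phenotypes: bool = True,
) -> SimResult:
    """Run layout -> truth/DB -> restriction map -> tracks -> phenotypes."""
    layout, truth, db = simulate_panel(cfg)
    rmap = simulate_restriction_map(cfg, layout)
    tracks = simulate_intensities(cfg, truth, rmap, layout)
    pheno = None
    if with_phenotypes:
        pheno = simulate_phenotypes(cfg, truth, layout, effects=effects)
    return SimResult(
        config=cfg,
        layout=layout,
        truth=truth,
        db=db,
        rmap=rmap,
        tracks=tracks,
        phenotypes=pheno,
        effects=list(effects or []),
    )
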