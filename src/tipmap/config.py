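"""Simulation configuration.

All knobs of the synthetic panel generator live in :class:`SimConfig`.
Where possible defaults mirror the assay geometry (gene loci tiled with
10 kb flanks, ~250 bp probe spacing, four parallel restriction digests with
~2.5 kb mean site spacing); noise-model parameters have no published values
and are simply exposed with documented defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml

#: TE family channels simulated and called.  AluYa/AluYb collapse to "Alu"
#: in panel summaries.
FAMILIES = ("L1", "AluYa", "AluYb")

#: Categories a planted or called insertion locus can take.
CATEGORIES = ("reference", "known_polymorphic", "novel_polymorphic", "singleton")


@dataclass
class SimConfig:
    """Parameters for the synthetic TIP panel.

    Insertion counts (``n_reference`` etc.) are *per family*: either a single
    int applied to every family or a ``{family: count}`` mapping.

    ``min_insertion_spacing_bp`` keeps same-family insertions far enough
    apart that their amplicon footprints (capped at ``max_footprint_bp``)
    can never merge after margin expansion, so planted categories stay
    recoverable; the default leaves ``> 2 kb`` of clearance beyond two
    opposing maximal footprints.
    """

    seed: int = 0

    # panel
    n_cell_lines: int = 20

    # genome layout
    n_genes: int = 200
    n_chroms: int = 4
    gene_length_mean_bp: float = 20_000.0
    gene_length_sd_bp: float = 10_000.0
    min_gene_length_bp: int = 2_000
    #: default keeps untiled inter-region gaps (gap - 2*flank) wider than
    #: max_footprint_bp so an amplicon cannot bleed onto the next gene's tile
    intergenic_gap_bp: int = 36_000
    flank_bp: int = 10_000

    # array
    probe_spacing_bp: int = 250
    probe_length_bp: int = 50
    masked_probe_fraction: float = 0.05

    # restriction digests (parallel reactions)
    n_enzymes: int = 4
    enzyme_site_mean_spacing_bp: float = 2_500.0
    max_footprint_bp: int = 15_000

    # planted insertions, per family
    n_reference: int | Mapping[str, int] = 30
    n_known_poly: int | Mapping[str, int] = 15
    n_novel_poly: int | Mapping[str, int] = 15
    n_singleton: int | Mapping[str, int] = 15
    allele_freq_range: tuple[float, float] = (0.1, 0.9)
    min_insertion_spacing_bp: int = 33_000
    known_poly_db_fraction: float = 1.0
    reference_also_polymorphic_fraction: float = 0.0
    n_db_extra_reference: int = 0

    # intensity model (log2-ratio units)
    signal_mean: float = 8.0
    signal_sd: float = 1.0
    baseline_sd: float = 0.3

    # phenotypes
    n_null_features: int = 50
    anchored_fraction: float = 0.5
    cis_anchor_window_bp: int = 30_000

    families: tuple[str, ...] = field(default=FAMILIES)

    def __post_init__(self) -> None:
        if self.n_cell_lines < 1:
            raise ValueError("n_cell_lines must be >= 1")
        if self.probe_spacing_bp <= 0:
            raise ValueError("probe_spacing_bp must be > 0")
        if not (0 < self.probe_length_bp <= self.probe_spacing_bp):
            raise ValueError("probe_length_bp must be in (0, probe_spacing_bp]")
        if self.enzyme_site_mean_spacing_bp <= 0:
            raise ValueError("enzyme_site_mean_spacing_bp must be > 0")
        lo, hi = self.allele_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("allele_freq_range must lie within (0, 1)")
        if not 0.0 <= self.masked_probe_fraction <= 1.0:
            raise ValueError("masked_probe_fraction must be in [0, 1]")
        if not 0.0 <= self.known_poly_db_fraction <= 1.0:
            raise ValueError("known_poly_db_fraction must be in [0, 1]")
        for name in ("n_reference", "n_known_poly", "n_novel_poly", "n_singleton"):
            for fam, n in self.counts_per_family(name).items():
                if n < 0:
                    raise ValueError(f"{name}[{fam}] must be >= 0")

    def counts_per_family(self, name: str) -> dict[str, int]:
        """Expand an int-or-mapping count field to ``{family: count}``."""
        raw = getattr(self, name)
        if isinstance(raw, Mapping):
            out = {fam: int(raw.get(fam, 0)) for fam in self.families}
        else:
            out = {fam: int(raw) for fam in self.families}
        return out

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "allele_freq_range" in data:
            data["allele_freq_range"] = tuple(data["allele_freq_range"])
        if "families" in data:
            data["families"] = tuple(data["families"])
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
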