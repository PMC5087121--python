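"""Gene-set over-representation of insertion-bearing genes.

A gene is "hit" when at least one selected locus overlaps its universe
interval (transcript +/- flank); hits are counted once per gene.  Each
gene set is intersected with the array universe before testing, and
enrichment is the exact upper-tail hypergeometric probability
P(X >= k) for k hit genes in the set, K set genes in the universe, n hit
genes overall and N universe genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from tipmap.loci import InsertionLocus

logger = logging.getLogger(__name__)


@dataclass
class GeneUniverse:
    """Genes tiled on the array: gene_id -> (chrom, start, end) with flanks."""

    intervals: pd.DataFrame  # gene_id, chrom, start, end

    def __post_init__(self) -> None:
        need = ["gene_id", "chrom", "start", "end"]
        missing = [c for c in need if c not in self.intervals.columns]
        if missing:
            raise ValueError(f"universe missing columns {missing}")
        if self.intervals["gene_id"].duplicated().any():
            raise ValueError("duplicate gene_ids in universe")
        if not (self.intervals["start"] < self.intervals["end"]).all():
            raise ValueError("invalid universe intervals")

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def gene_ids(self) -> set[str]:
        return set(self.intervals["gene_id"])


def universe_from_genes(genes: list, flank_bp: int = 10_000) -> GeneUniverse:
    """Array universe: transcript +/- flank per tiled gene."""
    df = pd.DataFrame(
        [
            dict(
                gene_id=g.gene_id,
                chrom=g.chrom,
                start=max(0, g.start - flank_bp),
                end=g.end + flank_bp,
            )
            for g in genes
        ]
    )
    return GeneUniverse(df)


@dataclass
class EnrichmentResult:
    set_name: str
    selector: str
    k: int  # hit genes in set
    K: int  # set size within universe
    n: int  # hit genes overall
    N: int  # universe size
    p: float
    neg_log10_p: float


def gene_hit_set(
    loci: list[InsertionLocus],
    universe: GeneUniverse,
    categories: set[str] | None = None,
    families: set[str] | None = None,
) -> set[str]:
    """Universe genes overlapped by at least one selected locus.

    ``categories``/``families`` restrict the loci considered (None = all);
    family selection matches either the channel name or its collapsed form
    ("Alu" selects AluYa and AluYb).
    """
    selected = []
    for locus in loci:
        if categories is not None and locus.category not in categories:
            continue
        if families is not None:
            from tipmap.loci import collapse_family

            if locus.family not in families and collapse_family(locus.family) not in families:
                continue
        selected.append(locus)
    if not selected:
        logger.info("locus selector matched nothing; empty hit set")
        return set()
    hits: set[str] = set()
    df = universe.intervals
    for locus in selected:
        sel = (
            (df["chrom"] == locus.chrom)
            & (df["start"] < locus.end)
            & (df["end"] > locus.start)
        )
        hits.update(df.loc[sel, "gene_id"])
    return hits


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail P(X >= k), X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich_gene_sets(
    hit_sets: dict[str, set[str]],
    gene_sets: dict[str, set[str]],
    universe: GeneUniverse,
) -> pd.DataFrame:
    """One EnrichmentResult row per (selector, gene set).

    Gene sets and hit sets are intersected with the universe before
    counting.  A gene set disjoint from the universe yields K=0, p=1 with a
    warning.
    """
    uni = universe.gene_ids
    N = len(uni)
    rows = []
    for selector, hits in hit_sets.items():
        hit_in_uni = hits & uni
        n = len(hit_in_uni)
        for set_name, genes in gene_sets.items():
            set_in_uni = genes & uni
            K = len(set_in_uni)
            if K == 0:
                logger.warning("gene set %s is disjoint from the universe", set_name)
                p = 1.0
                k = 0
            else:
                k = len(hit_in_uni & set_in_uni)
                p = hypergeom_pvalue(k, K, n, N)
            rows.append(
                EnrichmentResult(
                    set_name=set_name,
                    selector=selector,
                    k=k,
                    K=K,
                    n=n,
                    N=N,
                    p=p,
                    neg_log10_p=float(-np.log10(p)) if p > 0 else float("inf"),
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])
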