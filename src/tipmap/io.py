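"""Readers and writers for the plain-text formats used between stages.

Everything is TSV with BED-style 0-based half-open coordinates.  Track
files carry ``#key=value`` header lines for the cell line and family
channel.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from tipmap.loci import InsertionLocus, KnownInsertionDB, PresenceMatrix
from tipmap.peaks import PeakCall, ProbeTrack

PEAK_COLUMNS = [
    "chrom", "start", "end", "peak_id", "rank_threshold", "strand",
    "n_probes", "max_intensity", "cell_line", "family",
]


# -- probe tracks -----------------------------------------------------------

def write_track(track: ProbeTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#cell_line={track.cell_line}\n#family={track.family}\n")
        df = track.probes.copy()
        df["masked"] = df["masked"].astype(int)
        df.to_csv(fh, sep="\t", index=False)


def read_track(path: str | Path) -> ProbeTrack:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key] = val
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    df["masked"] = df["masked"].astype(bool)
    return ProbeTrack(
        df, cell_line=meta.get("cell_line", ""), family=meta.get("family", "")
    )


# -- peak calls -------------------------------------------------------------

def write_peaks(calls: list[PeakCall], path: str | Path) -> None:
    rows = [
        dict(
            chrom=c.chrom, start=c.start, end=c.end, peak_id=c.peak_id,
            rank_threshold=c.rank_threshold, strand=".",
            n_probes=c.n_probes, max_intensity=c.max_intensity,
            cell_line=c.cell_line, family=c.family,
        )
        for c in calls
    ]
    pd.DataFrame(rows, columns=PEAK_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_peaks(path: str | Path) -> list[PeakCall]:
    df = pd.read_csv(
        path, sep="\t", keep_default_na=False, float_precision="round_trip"
    )
    return [
        PeakCall(
            chrom=str(r.chrom), start=int(r.start), end=int(r.end),
            rank_threshold=float(r.rank_threshold), n_probes=int(r.n_probes),
            max_intensity=float(r.max_intensity), cell_line=str(r.cell_line),
            family=str(r.family), peak_id=str(r.peak_id),
        )
        for r in df.itertuples()
    ]


# -- known-insertion DB -----------------------------------------------------

def write_db(db: KnownInsertionDB, path: str | Path) -> None:
    cols = ["chrom", "start", "end", "db_id", "family", "source"]
    db.records[cols].to_csv(path, sep="\t", index=False)


def read_db(path: str | Path) -> KnownInsertionDB:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return KnownInsertionDB(
        df[["chrom", "start", "end", "family", "source", "db_id"]]
    )


# -- gene models ------------------------------------------------------------

def write_genes(genes: list, path: str | Path) -> None:
    """Flatten gene models to rows (chrom, start, end, gene_id, feature,
    strand) with feature in {transcript, exon, utr3}."""
    rows = []
    for g in genes:
        rows.append(dict(chrom=g.chrom, start=g.start, end=g.end,
                         gene_id=g.gene_id, feature="transcript", strand=g.strand))
        for s, e in g.exons:
            rows.append(dict(chrom=g.chrom, start=s, end=e,
                             gene_id=g.gene_id, feature="exon", strand=g.strand))
        us, ue = g.utr3
        rows.append(dict(chrom=g.chrom, start=us, end=ue,
                         gene_id=g.gene_id, feature="utr3", strand=g.strand))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_genes(path: str | Path) -> list:
    from tipmap.simulate.panel import GeneModel

    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    genes = []
    for gid, sub in df.groupby("gene_id", sort=True):
        tr = sub[sub["feature"] == "transcript"].iloc[0]
        exons = [
            (int(r.start), int(r.end))
            for r in sub[sub["feature"] == "exon"].itertuples()
        ]
        utr = sub[sub["feature"] == "utr3"].iloc[0]
        genes.append(
            GeneModel(
                gene_id=str(gid), chrom=str(tr.chrom), start=int(tr.start),
                end=int(tr.end), strand=str(tr.strand),
                exons=sorted(exons), utr3=(int(utr.start), int(utr.end)),
            )
        )
    return genes


# -- planted truth ----------------------------------------------------------

def write_truth(truth, path_bed: str | Path, path_json: str | Path) -> None:
    rows = [
        dict(chrom=i.chrom, start=i.position, end=i.position + 1,
             locus_id=i.locus_id, family=i.family, strand=i.strand,
             category=i.category)
        for i in truth.insertions
    ]
    pd.DataFrame(rows).to_csv(path_bed, sep="\t", index=False)
    sidecar = {
        "cell_lines": truth.cell_lines,
        "presence": {
            i.locus_id: [int(v) for v in i.presence] for i in truth.insertions
        },
        "footprints": {
            f"{lid}|{line}": list(fp)
            for (lid, line), fp in sorted(truth.footprints.items())
        },
    }
    with open(path_json, "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)


# -- phenotypes -------------------------------------------------------------

def write_phenotypes(pheno, path: str | Path) -> None:
    anchors = pheno.anchors.set_index("feature_id")
    df = pheno.values.copy()
    df.insert(0, "anchor_chrom", anchors.loc[df.index, "chrom"].values)
    df.insert(1, "anchor_pos", anchors.loc[df.index, "position"].values)
    df.to_csv(path, sep="\t", index=True)


def read_phenotypes(path: str | Path):
    from tipmap.simulate.phenotypes import PhenotypeMatrix

    df = pd.read_csv(path, sep="\t", index_col="feature_id", keep_default_na=False)
    anchors = pd.DataFrame(
        {
            "feature_id": df.index,
            "chrom": df["anchor_chrom"].astype(str).replace("nan", ""),
            "position": pd.to_numeric(df["anchor_pos"], errors="coerce")
            .fillna(-1)
            .astype(int),
        }
    ).reset_index(drop=True)
    values = df.drop(columns=["anchor_chrom", "anchor_pos"]).astype(float)
    return PhenotypeMatrix(values=values, anchors=anchors)


# -- loci and presence matrix ----------------------------------------------

def write_loci(loci: list[InsertionLocus], path: str | Path) -> None:
    rows = [
        dict(
            chrom=l.chrom, start=l.start, end=l.end, locus_id=l.locus_id,
            family=l.family, category=l.category, n_present=l.n_present,
            ref_and_poly=int(l.ref_and_poly),
            matched_db_ids=",".join(l.matched_db_ids),
            presence="".join(str(int(v)) for v in l.presence),
        )
        for l in loci
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_loci(path: str | Path) -> list[InsertionLocus]:
    df = pd.read_csv(
        path, sep="\t", keep_default_na=False,
        dtype={"presence": str, "matched_db_ids": str},
    )
    out = []
    for r in df.itertuples():
        out.append(
            InsertionLocus(
                locus_id=str(r.locus_id), chrom=str(r.chrom), start=int(r.start),
                end=int(r.end), family=str(r.family),
                presence=np.array([c == "1" for c in str(r.presence)]),
                category=str(r.category),
                matched_db_ids=[x for x in str(r.matched_db_ids).split(",") if x],
                ref_and_poly=bool(int(r.ref_and_poly)),
            )
        )
    return out


def write_presence_matrix(pm: PresenceMatrix, path: str | Path) -> None:
    pm.matrix.astype(int).to_csv(path, sep="\t", index_label="locus_id")


def read_presence_matrix(path: str | Path) -> PresenceMatrix:
    df = pd.read_csv(path, sep="\t", index_col="locus_id")
    df.index.name = None
    return PresenceMatrix(df.astype(bool))


# -- gene sets --------------------------------------------------------------

def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """A directory of ``*.txt`` one-gene-per-line files (set name = stem) or
    a single two-column (set, gene) TSV."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    if path.is_dir():
        for f in sorted(path.glob("*.txt")):
            genes = {
                ln.strip() for ln in f.read_text().splitlines() if ln.strip()
            }
            sets[f.stem] = genes
    else:
        df = pd.read_csv(path, sep="\t", header=None, names=["set", "gene"])
        for name, sub in df.groupby("set"):
            sets[str(name)] = set(sub["gene"].astype(str))
    return sets
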