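"""Readers and writers for the pipeline's plain-text formats.

* Per-sample intensity TSV, Beadstudio-like: ``SNP_Name  Chr  Position
  LogR`` with 1-based positions in the file (0-based in memory).
* Pedigree TSV: ``family  child  father  mother``.
* Truth and call tables: BED-like TSV, 0-based half-open.  Truth is BED5
  (chrom, start, end, sample, origin); calls carry extra columns
  (n_snps, mean_logr, provenance, first_snp, last_snp).
* Gene models: GFF3 (exon features, via gffutils) or BED12.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .calling import DeletionCall
from .genome import Gene, SnpMap
from .synthetic_cohort import Cohort, IntensityTrack, Trio, TruthDeletion

__all__ = [
    "write_cohort",
    "read_intensity_tsv",
    "read_pedigree",
    "read_truth_bed",
    "read_cohort_tracks",
    "write_calls_bed",
    "read_calls_bed",
    "read_gene_models",
]

INTENSITY_COLUMNS = ["SNP_Name", "Chr", "Position", "LogR"]


def _snp_names(snp_map: SnpMap) -> list[str]:
    names = []
    for chrom in snp_map.chroms:
        names.extend(
            f"rs_{chrom}_{i}" for i in range(len(snp_map.positions[chrom]))
        )
    return names


def _chrom_column(snp_map: SnpMap) -> np.ndarray:
    return np.concatenate(
        [np.repeat(chrom, len(snp_map.positions[chrom])) for chrom in snp_map.chroms]
    )


def write_cohort(cohort: Cohort, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write tracks, pedigree and truth; returns the paths written.

    Per-sample TSVs go under ``tracks/``; LogR values are written at full
    float precision so a write/read cycle is lossless.
    """
    out = Path(out_dir)
    (out / "tracks").mkdir(parents=True, exist_ok=True)
    smap = cohort.model.snp_map
    names = _snp_names(smap)
    chroms = _chrom_column(smap)
    positions = np.concatenate([smap.positions[c] for c in smap.chroms])
    seen: set[str] = set()
    paths: dict[str, Path] = {}
    for sample, track in cohort.tracks.items():
        if sample in seen:
            raise ValueError(f"duplicate sample id {sample}")
        seen.add(sample)
        frame = pd.DataFrame(
            {
                "SNP_Name": names,
                "Chr": chroms,
                "Position": positions + 1,  # 1-based on disk
                "LogR": track.values,
            }
        )
        path = out / "tracks" / f"{sample}.tsv"
        # %.17g always round-trips an IEEE double exactly
        frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
        paths[sample] = path
    ped = pd.DataFrame(
        [(t.family, t.child, t.father, t.mother) for t in cohort.trios],
        columns=["family", "child", "father", "mother"],
    )
    ped.to_csv(out / "pedigree.tsv", sep="\t", index=False)
    paths["pedigree"] = out / "pedigree.tsv"
    truth = pd.DataFrame(
        [(t.chrom, t.start, t.end, t.sample, t.origin) for t in cohort.truth],
        columns=["chrom", "start", "end", "sample", "origin"],
    )
    truth.to_csv(out / "truth.bed", sep="\t", index=False, header=False)
    paths["truth"] = out / "truth.bed"
    return paths


def read_intensity_tsv(path: str | os.PathLike) -> tuple[SnpMap, IntensityTrack]:
    """Read one Beadstudio-like per-sample TSV into (SnpMap, IntensityTrack)."""
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in INTENSITY_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    chrom_order = list(dict.fromkeys(frame["Chr"].astype(str)))
    positions = {
        chrom: frame.loc[frame["Chr"].astype(str) == chrom, "Position"].to_numpy()
        - 1  # back to 0-based
        for chrom in chrom_order
    }
    snp_map = SnpMap(chrom_order, positions)
    sample = Path(path).stem
    return snp_map, IntensityTrack(sample=sample, values=frame["LogR"].to_numpy())


def read_pedigree(path: str | os.PathLike) -> list[Trio]:
    frame = pd.read_csv(path, sep="\t")
    return [
        Trio(family=r.family, child=r.child, father=r.father, mother=r.mother)
        for r in frame.itertuples()
    ]


def read_truth_bed(path: str | os.PathLike) -> list[TruthDeletion]:
    frame = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "sample", "origin"],
    )
    return [
        TruthDeletion(
            sample=r.sample, chrom=r.chrom, start=int(r.start), end=int(r.end),
            origin=r.origin,
        )
        for r in frame.itertuples()
    ]


def read_cohort_tracks(
    tracks_dir: str | os.PathLike,
) -> tuple[SnpMap, dict[str, IntensityTrack]]:
    """Read every per-sample TSV in a directory; maps must agree."""
    tracks: dict[str, IntensityTrack] = {}
    snp_map: SnpMap | None = None
    for path in sorted(Path(tracks_dir).glob("*.tsv")):
        this_map, track = read_intensity_tsv(path)
        if snp_map is None:
            snp_map = this_map
        elif snp_map != this_map:
            raise ValueError(f"{path}: SNP map differs from the rest of the cohort")
        tracks[track.sample] = track
    if snp_map is None:
        raise ValueError(f"no intensity TSVs under {tracks_dir}")
    return snp_map, tracks


CALL_COLUMNS = [
    "chrom", "start", "end", "sample", "n_snps", "mean_logr", "provenance",
    "first_snp", "last_snp",
]


def write_calls_bed(calls: list[DeletionCall], path: str | os.PathLike) -> None:
    frame = pd.DataFrame(
        [
            (c.chrom, c.start, c.end, c.sample, c.n_snps, c.mean_logr,
             c.provenance, c.first_snp, c.last_snp)
            for c in calls
        ],
        columns=CALL_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)


def read_calls_bed(path: str | os.PathLike) -> list[DeletionCall]:
    frame = pd.read_csv(path, sep="\t")
    return [
        DeletionCall(
            sample=r.sample, chrom=r.chrom, first_snp=int(r.first_snp),
            last_snp=int(r.last_snp), start=int(r.start), end=int(r.end),
            n_snps=int(r.n_snps), mean_logr=float(r.mean_logr),
            provenance=r.provenance,
        )
        for r in frame.itertuples()
    ]


def _genes_from_bed12(path: str | os.PathLike) -> list[Gene]:
    frame = pd.read_csv(path, sep="\t", header=None)
    if frame.shape[1] < 12:
        raise ValueError(f"{path}: BED12 requires 12 columns")
    genes = []
    for row in frame.itertuples(index=False):
        chrom, chrom_start, name = str(row[0]), int(row[1]), str(row[3])
        sizes = [int(x) for x in str(row[10]).rstrip(",").split(",")]
        starts = [int(x) for x in str(row[11]).rstrip(",").split(",")]
        if len(sizes) != len(starts):
            raise ValueError(f"{path}: blockSizes/blockStarts mismatch for {name}")
        exons = tuple(
            (chrom_start + s, chrom_start + s + size)
            for s, size in zip(starts, sizes)
        )
        genes.append(Gene(name=name, chrom=chrom, exons=exons))
    return genes


def _genes_from_gff3(path: str | os.PathLike) -> list[Gene]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    by_gene: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent") or exon.attributes.get("gene_id")
        name = parents[0] if parents else exon.id
        # GFF3 is 1-based inclusive; convert to 0-based half-open
        by_gene.setdefault((name, exon.seqid), []).append((exon.start - 1, exon.end))
    genes = []
    for (name, chrom), exons in by_gene.items():
        genes.append(Gene(name=name, chrom=chrom, exons=tuple(sorted(exons))))
    return genes


def read_gene_models(path: str | os.PathLike) -> list[Gene]:
    """Read gene/exon models from GFF3 (.gff/.gff3) or BED12 (anything else)."""
    suffix = Path(path).suffix.lower()
    if suffix in (".gff", ".gff3"):
        return _genes_from_gff3(path)
    return _genes_from_bed12(path)
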