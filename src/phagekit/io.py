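"""File-format helpers: FASTA, GFF3 feature tracks, TSV tables, PHYLIP matrices.

FASTA goes through Biopython. GFF3 here is the minimal 9-column flavour used
for CDS tracks and structural calls; only the columns the pipeline consumes
are interpreted.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .kinetics import TiterSeries
from .records import CdsFeature, GenomeRecord

GFF3_HEADER = "##gff-version 3"


def write_titers_tsv(series_list: Sequence[TiterSeries], path) -> None:
    """Long-format TSV: time_min, replicate, treatment, pfu_per_ml."""
    rows = []
    for s in series_list:
        for r in range(s.n_replicates):
            for ti, t in enumerate(s.times):
                rows.append((t, r + 1, s.treatment, s.pfu[r, ti]))
    pd.DataFrame(rows, columns=["time_min", "replicate", "treatment", "pfu_per_ml"]).to_csv(
        path, sep="\t", index=False
    )


def read_titers_tsv(path, cell_density: float | None = None) -> dict[str, TiterSeries]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for treatment, grp in df.groupby("treatment"):
        piv = grp.pivot(index="replicate", columns="time_min", values="pfu_per_ml")
        piv = piv.sort_index().sort_index(axis=1)
        out[str(treatment)] = TiterSeries(
            times=piv.columns.to_numpy(dtype=float),
            pfu=piv.to_numpy(dtype=float),
            treatment=str(treatment),
            cell_density=cell_density,
        )
    return out


def write_fasta(records: Iterable[GenomeRecord], path: str | os.PathLike) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path: str | os.PathLike, circular: bool = False) -> list[GenomeRecord]:
    return [
        GenomeRecord(id=rec.id, sequence=str(rec.seq).upper(), circular=circular)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_protein_fasta(seqs: dict[str, str], path: str | os.PathLike) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_protein_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(
    features: Sequence[CdsFeature],
    seqid: str,
    path: str | os.PathLike,
    source: str = "phagekit",
    ftype: str = "CDS",
) -> None:
    with open(path, "w") as fh:
        fh.write(GFF3_HEADER + "\n")
        for i, f in enumerate(features, 1):
            attrs = f"ID={ftype.lower()}{i};support={f.support}"
            fh.write(
                f"{seqid}\t{f.source or source}\t{ftype}\t{f.start}\t{f.end}\t.\t"
                f"{f.strand}\t0\t{attrs}\n"
            )


def read_gff3(path: str | os.PathLike) -> list[CdsFeature]:
    feats = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 8:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            feats.append(
                CdsFeature(
                    start=int(cols[3]),
                    end=int(cols[4]),
                    strand=cols[6],
                    source=cols[1],
                )
            )
    return feats


def write_coverage_tsv(depth: np.ndarray, path: str | os.PathLike) -> None:
    """Two-column TSV: 1-based position, read depth."""
    df = pd.DataFrame({"pos": np.arange(1, len(depth) + 1), "depth": depth})
    df.to_csv(path, sep="\t", index=False)


def read_coverage_tsv(path: str | os.PathLike) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    return df["depth"].to_numpy()


def write_matrix_tsv(labels: Sequence[str], values: np.ndarray, path) -> None:
    pd.DataFrame(values, index=list(labels), columns=list(labels)).to_csv(
        path, sep="\t", float_format="%.6f"
    )


def read_matrix_tsv(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return [str(c) for c in df.columns], df.to_numpy(dtype=float)


def write_phylip_distances(labels: Sequence[str], values: np.ndarray, path) -> None:
    """Relaxed PHYLIP square distance matrix (labels up to any length)."""
    n = len(labels)
    with open(path, "w") as fh:
        fh.write(f"{n}\n")
        for i, lab in enumerate(labels):
            row = " ".join(f"{values[i, j]:.6f}" for j in range(n))
            fh.write(f"{lab}  {row}\n")
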