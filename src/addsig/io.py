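"""Readers and writers for the formats the pipeline exchanges.

FASTA in (Biopython), plain-text artifacts out: FCGR matrices as a dense grid
or sparse triples, distance matrices as labelled square CSV, Molecular
Distance Maps as CSV or JSON with per-point provenance, fragment sets as
FASTA plus a TSV manifest.  Every writer has a matching reader so artifacts
round-trip.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .distances import DistanceMatrix, MetricId
from .embedding import EmbeddedMap
from .fcgr import DnaSequence, FcgrMatrix
from .prep import FragmentSet, GenomeRecord, clean_sequence

__all__ = [
    "read_fasta",
    "read_genome",
    "write_fasta",
    "write_fcgr_dense",
    "read_fcgr_dense",
    "write_fcgr_sparse",
    "read_fcgr_sparse",
    "write_distance_matrix",
    "read_distance_matrix",
    "write_map_csv",
    "write_map_json",
    "write_fragment_set",
    "read_fragment_set",
]


def read_fasta(path: str | Path, clean: bool = True) -> list[DnaSequence]:
    """Read FASTA records; by default non-ACGT letters are dropped (cleaned)."""
    seqs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if clean:
            seqs.append(clean_sequence(str(rec.seq), id=rec.id))
        else:
            seqs.append(DnaSequence(str(rec.seq), id=rec.id))
    return seqs


def read_genome(
    path: str | Path, organism: str | None = None, assembly_level: str = "chromosome"
) -> GenomeRecord:
    """Read a multi-record FASTA as one genome (records become units)."""
    units = read_fasta(path, clean=True)
    if organism is None:
        organism = Path(path).stem
    return GenomeRecord(organism=organism, units=units, assembly_level=assembly_level)


def _fragment_header(s: DnaSequence, organism: str = "") -> str:
    p = s.provenance or {}
    unit = p.get("unit", s.id)
    idx = p.get("fragment_index", 1)
    start = p.get("start", 1)
    return f"{organism or 'NA'}|{unit}|frag{idx}|start{start}"


def write_fasta(seqs: Iterable[DnaSequence], path: str | Path, organism: str = "") -> None:
    """Write sequences as FASTA; fragment provenance is encoded in the header."""
    records = []
    for s in seqs:
        name = _fragment_header(s, organism) if s.provenance else (s.id or "seq")
        records.append(SeqRecord(Seq(s.residues), id=name, description=""))
    SeqIO.write(records, str(path), "fasta")


# --- FCGR matrices ----------------------------------------------------------


def write_fcgr_dense(F: FcgrMatrix, path: str | Path) -> None:
    """Dense text grid with a one-line header ``k=<k> total=<total>``."""
    with open(path, "w") as fh:
        fh.write(f"k={F.k} total={F.total}\n")
        fmt = "%d" if np.issubdtype(F.counts.dtype, np.integer) else "%.17g"
        np.savetxt(fh, F.counts, fmt=fmt)


def read_fcgr_dense(path: str | Path) -> FcgrMatrix:
    with open(path) as fh:
        header = fh.readline().split()
        k = int(header[0].split("=")[1])
        counts = np.loadtxt(fh, ndmin=2)
    if np.all(counts == np.rint(counts)):
        counts = counts.astype(np.int64)
    return FcgrMatrix(k, counts)


def write_fcgr_sparse(F: FcgrMatrix, path: str | Path) -> None:
    """Sparse triples ``row<TAB>col<TAB>count`` after the same one-line header."""
    rows, cols = np.nonzero(F.counts)
    with open(path, "w") as fh:
        fh.write(f"k={F.k} total={F.total}\n")
        for r, c in zip(rows, cols):
            fh.write(f"{r}\t{c}\t{F.counts[r, c]}\n")


def read_fcgr_sparse(path: str | Path) -> FcgrMatrix:
    with open(path) as fh:
        header = fh.readline().split()
        k = int(header[0].split("=")[1])
        side = 1 << k
        counts = np.zeros((side, side), dtype=np.float64)
        is_int = True
        for line in fh:
            r, c, v = line.split("\t")
            counts[int(r), int(c)] = float(v)
            is_int &= float(v).is_integer()
    if is_int:
        counts = counts.astype(np.int64)
    return FcgrMatrix(k, counts)


# --- distance matrices ------------------------------------------------------


def write_distance_matrix(D: DistanceMatrix, path: str | Path) -> None:
    """Square CSV with a label header row/column; the metric is the index name."""
    df = pd.DataFrame(D.values, index=D.labels, columns=D.labels)
    df.index.name = D.metric.value
    df.to_csv(path, float_format="%.17g")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    metric = MetricId(df.index.name)
    return DistanceMatrix(list(df.columns), df.to_numpy(dtype=np.float64), metric)


# --- embedded maps ----------------------------------------------------------


def write_map_csv(emap: EmbeddedMap, path: str | Path) -> None:
    axes = [f"axis{i}" for i in range(emap.q)] if emap.q != 3 else ["x", "y", "z"]
    df = pd.DataFrame(emap.coords, columns=axes)
    df.insert(0, "label", emap.labels)
    df.to_csv(path, index=False, float_format="%.17g")


def write_map_json(emap: EmbeddedMap, path: str | Path) -> None:
    prov = emap.provenance or [None] * len(emap)
    payload = {
        "scaled": emap.scaled,
        "eigenvalues": [float(v) for v in emap.eigenvalues],
        "points": [
            {
                "label": lab,
                "coords": [float(c) for c in xyz],
                "provenance": p,
            }
            for lab, xyz, p in zip(emap.labels, emap.coords, prov)
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


# --- fragment sets ----------------------------------------------------------


def write_fragment_set(
    fs: FragmentSet, fasta_path: str | Path, manifest_path: str | Path, organism: str = ""
) -> None:
    """Fragments as FASTA plus a TSV manifest of provenance."""
    write_fasta(fs.fragments, fasta_path, organism=organism)
    rows = []
    for f in fs.fragments:
        p = f.provenance or {}
        rows.append(
            {
                "organism": organism or "NA",
                "unit": p.get("unit", f.id),
                "fragment_index": p.get("fragment_index", 1),
                "start": p.get("start", 1),
                "length": len(f),
            }
        )
    pd.DataFrame(rows).to_csv(manifest_path, sep="\t", index=False)


def read_fragment_set(fasta_path: str | Path) -> FragmentSet:
    """Re-read a fragment FASTA written by :func:`write_fragment_set`."""
    frags = []
    length = None
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        parts = rec.id.split("|")
        prov = None
        if len(parts) == 4 and parts[2].startswith("frag") and parts[3].startswith("start"):
            prov = {
                "unit": parts[1],
                "fragment_index": int(parts[2][4:]),
                "start": int(parts[3][5:]),
            }
        frags.append(DnaSequence(str(rec.seq), id=rec.id, provenance=prov))
        length = len(rec.seq)
    return FragmentSet(frags, fragment_length=length if length is not None else 0)
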