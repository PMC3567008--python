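"""Readers and writers for the formats the pipeline touches.

Supported formats: aligned multi-FASTA (one file per locus), a TSV species
map (columns ``individual``, ``species``, ``clade`` and optional
``is_outgroup``), Newick trees (bootstrap supports as integer internal-node
labels) and distance matrices as square TSV or PHYLIP (square or
lower-triangular).
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple, Union

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

from .containers import Alignment, ReferenceLibrary, SpeciesMap
from .distances import DistanceMatrix

PathLike = Union[str, os.PathLike]


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------
def read_alignment(path: PathLike, locus_name: Optional[str] = None) -> Alignment:
    """Read an aligned multi-FASTA file.

    All records must have the same length; unequal lengths raise a
    "not aligned" error naming the offending record, and duplicate ids are
    rejected.  ``locus_name`` defaults to the file stem.
    """
    path = Path(path)
    if locus_name is None:
        locus_name = path.stem
    rows: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in rows:
            raise ValueError(f"duplicate id '{rec.id}' in {path}")
        rows[rec.id] = str(rec.seq)
    if not rows:
        raise ValueError(f"no FASTA records in {path}")
    lengths = {len(s) for s in rows.values()}
    if len(lengths) > 1:
        expected = len(next(iter(rows.values())))
        for ind, s in rows.items():
            if len(s) != expected:
                raise ValueError(
                    f"{path} is not aligned: record '{ind}' has length "
                    f"{len(s)}, expected {expected}"
                )
    return Alignment(locus_name, rows)


def write_alignment(aln: Alignment, path: PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for ind in aln.ids:
            fh.write(f">{ind}\n")
            seq = aln.sequence(ind)
            for k in range(0, len(seq), width):
                fh.write(seq[k : k + width] + "\n")


# ---------------------------------------------------------------------------
# species map
# ---------------------------------------------------------------------------
def read_species_map(path: PathLike) -> SpeciesMap:
    """Read a TSV with columns individual, species, clade[, is_outgroup]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"individual", "species", "clade"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"species map {path} missing columns: {sorted(missing)}")
    entries: Dict[str, Tuple[str, str]] = {}
    outgroup = set()
    for _, row in df.iterrows():
        ind = row["individual"]
        if ind in entries:
            raise ValueError(f"duplicate individual '{ind}' in {path}")
        entries[ind] = (row["species"], row["clade"])
        if "is_outgroup" in df.columns and str(row["is_outgroup"]) in {"1", "true", "True"}:
            outgroup.add(ind)
    return SpeciesMap(entries, outgroup=outgroup)


def write_species_map(sp_map: SpeciesMap, path: PathLike) -> None:
    rows = []
    for ind, (sp, clade) in sp_map.entries().items():
        rows.append(
            {
                "individual": ind,
                "species": sp,
                "clade": clade,
                "is_outgroup": 1 if ind in sp_map.outgroup else 0,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------
def read_tree(path: PathLike, rooted: Optional[bool] = None) -> dendropy.Tree:
    """Read a Newick tree; internal-node labels are bootstrap percents."""
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"malformed Newick in {path}: {exc}") from exc
    if rooted is not None:
        tree.is_rooted = rooted
    return tree


def write_tree(tree: dendropy.Tree, path: PathLike) -> None:
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".6f",
    )
    with open(path, "w") as fh:
        fh.write(s)


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------
def write_distance_matrix(
    dm: DistanceMatrix, path: PathLike, fmt: str = "phylip"
) -> None:
    """Write a distance matrix.

    ``fmt`` is one of ``phylip`` (square), ``phylip-lower`` (lower
    triangle) or ``tsv`` (square with header row/column).  Values are
    written with 6 decimals; NA as ``NA``.
    """
    if len(dm) == 0:
        raise ValueError("empty distance matrix")

    def cell(v: float) -> str:
        return "NA" if np.isnan(v) else f"{v:.6f}"

    with open(path, "w") as fh:
        if fmt == "tsv":
            fh.write("\t".join([""] + dm.ids) + "\n")
            for i, ind in enumerate(dm.ids):
                fh.write("\t".join([ind] + [cell(v) for v in dm.values[i]]) + "\n")
        elif fmt == "phylip":
            fh.write(f"{len(dm)}\n")
            for i, ind in enumerate(dm.ids):
                fh.write(ind + "\t" + "\t".join(cell(v) for v in dm.values[i]) + "\n")
        elif fmt == "phylip-lower":
            fh.write(f"{len(dm)}\n")
            for i, ind in enumerate(dm.ids):
                cells = [cell(v) for v in dm.values[i, :i]]
                fh.write("\t".join([ind] + cells).rstrip("\t") + "\n")
        else:
            raise ValueError(f"unknown distance matrix format '{fmt}'")


def read_distance_matrix(
    path: PathLike, model: str = "k2p", deletion: str = "pairwise"
) -> DistanceMatrix:
    """Read a distance matrix, sniffing TSV vs PHYLIP square vs lower."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"empty distance matrix file {path}")

    def parse(v: str) -> float:
        return float("nan") if v == "NA" else float(v)

    first = lines[0].split("\t")
    if first[0] == "" and len(first) > 1:  # TSV with header
        ids = first[1:]
        n = len(ids)
        vals = np.zeros((n, n))
        for i, ln in enumerate(lines[1:]):
            parts = ln.split("\t")
            vals[i] = [parse(v) for v in parts[1:]]
        return DistanceMatrix(ids, vals, model=model, deletion=deletion)
    # PHYLIP
    n = int(lines[0].split()[0])
    body = [ln.split("\t") for ln in lines[1:]]
    if len(body) != n:
        raise ValueError(f"{path}: expected {n} rows, found {len(body)}")
    ids = [row[0] for row in body]
    lower = any(len(row) - 1 != n for row in body)
    vals = np.zeros((n, n))
    if lower:
        for i, row in enumerate(body):
            got = [parse(v) for v in row[1:]]
            if len(got) != i:
                raise ValueError(f"{path}: row '{ids[i]}' has {len(got)} entries, expected {i}")
            vals[i, :i] = got
            vals[:i, i] = got
    else:
        for i, row in enumerate(body):
            vals[i] = [parse(v) for v in row[1:]]
    return DistanceMatrix(ids, vals, model=model, deletion=deletion)


# ---------------------------------------------------------------------------
# libraries
# ---------------------------------------------------------------------------
def load_library(
    alignment_paths: Sequence[PathLike],
    species_map_path: PathLike,
    partition_labels: Dict[str, str],
) -> ReferenceLibrary:
    """Assemble and validate a reference library from files."""
    alignments = [read_alignment(p) for p in alignment_paths]
    sp_map = read_species_map(species_map_path)
    return ReferenceLibrary(alignments, sp_map, partition_labels)


def write_library(library: ReferenceLibrary, directory: PathLike) -> None:
    """Write a library as one FASTA per locus plus the species map and
    a ``partitions.tsv`` mapping locus -> genome."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for aln in library.alignments:
        write_alignment(aln, directory / f"{aln.locus_name}.fasta")
    write_species_map(library.species_map, directory / "species_map.tsv")
    pd.DataFrame(
        [(k, v) for k, v in library.partition_labels.items()],
        columns=["locus", "genome"],
    ).to_csv(directory / "partitions.tsv", sep="\t", index=False)


def read_library(directory: PathLike) -> ReferenceLibrary:
    directory = Path(directory)
    parts = pd.read_csv(directory / "partitions.tsv", sep="\t", dtype=str)
    labels = dict(zip(parts["locus"], parts["genome"]))
    alignments = [
        read_alignment(directory / f"{locus}.fasta", locus) for locus in labels
    ]
    sp_map = read_species_map(directory / "species_map.tsv")
    return ReferenceLibrary(alignments, sp_map, labels)
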