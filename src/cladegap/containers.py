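"""Core in-memory containers for multi-locus barcode libraries.

The pipeline operates on three joint structures:

* :class:`Alignment` — one pre-aligned locus, rows indexed by individual id.
* :class:`SpeciesMap` — the individual -> species -> clade bookkeeping that
  stands in for a reference library's voucher table, including outgroup
  designation.
* :class:`ReferenceLibrary` — the set of per-locus alignments plus the map
  and a genome-partition label (cpDNA vs nuclear) per locus, which is what
  the incongruence screen needs.

Sequences are stored upper-case over the alphabet ``{A, C, G, T, -, N, ?}``.
``-`` is an alignment gap (a real indel state, used by indel coding) while
``N``/``?`` mean "missing"; every other IUPAC symbol is conservatively mapped
to ``?`` on input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

logger = logging.getLogger(__name__)

#: integer codes used throughout: A,C,G,T then gap, then missing
CODE_GAP = 4
CODE_MISSING = 5

_CHAR_TO_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "-": CODE_GAP, "N": CODE_MISSING, "?": CODE_MISSING}
_CODE_TO_CHAR = np.array(list("ACGT-?"))

# lookup table over all byte values; unknown characters -> missing
_BYTE_LUT = np.full(256, CODE_MISSING, dtype=np.int8)
for _c, _v in _CHAR_TO_CODE.items():
    _BYTE_LUT[ord(_c)] = _v
_KNOWN_BYTES = np.zeros(256, dtype=bool)
for _c in "ACGT-N?":
    _KNOWN_BYTES[ord(_c)] = True


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an upper-case aligned sequence as int8 codes."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _BYTE_LUT[raw]


def decode_sequence(codes: np.ndarray) -> str:
    return "".join(_CODE_TO_CHAR[codes])


class Alignment:
    """A single pre-aligned locus.

    Parameters
    ----------
    locus_name:
        Identifier of the locus (e.g. a gene or spacer name).
    rows:
        Ordered mapping of individual id -> aligned sequence.  All rows must
        share one length.  Characters outside ``{A,C,G,T,-,N,?}`` are mapped
        to ``?`` with a logged warning count.
    """

    def __init__(self, locus_name: str, rows: Mapping[str, str]):
        if not rows:
            raise ValueError(f"alignment '{locus_name}' has no sequences")
        self.locus_name = str(locus_name)
        self.ids: List[str] = list(rows)
        if len(set(self.ids)) != len(self.ids):
            raise ValueError(f"duplicate individual ids in alignment '{locus_name}'")
        length = None
        cleaned: Dict[str, str] = {}
        n_mapped = 0
        for ind, seq in rows.items():
            s = str(seq).upper()
            if length is None:
                length = len(s)
            elif len(s) != length:
                raise ValueError(
                    f"alignment '{locus_name}' is not aligned: record '{ind}' has "
                    f"length {len(s)}, expected {length}"
                )
            raw = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
            bad = ~_KNOWN_BYTES[raw]
            if bad.any():
                n_mapped += int(bad.sum())
                arr = raw.copy()
                arr[bad] = ord("?")
                s = arr.tobytes().decode("ascii")
            cleaned[ind] = s
        if length == 0:
            raise ValueError(f"alignment '{locus_name}' has zero columns")
        if n_mapped:
            logger.warning(
                "alignment '%s': %d characters outside {A,C,G,T,-,N,?} mapped to '?'",
                locus_name,
                n_mapped,
            )
        self.aligned_length: int = int(length)
        self._rows = cleaned
        self._encoded: Optional[np.ndarray] = None

    # -- basic access ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, individual: str) -> bool:
        return individual in self._rows

    def sequence(self, individual: str) -> str:
        return self._rows[individual]

    def items(self):
        return self._rows.items()

    @property
    def rows(self) -> Mapping[str, str]:
        return dict(self._rows)

    def encoded(self) -> np.ndarray:
        """int8 matrix (n_individuals x aligned_length) of sequence codes."""
        if self._encoded is None:
            mat = np.empty((len(self.ids), self.aligned_length), dtype=np.int8)
            for i, ind in enumerate(self.ids):
                mat[i] = encode_sequence(self._rows[ind])
            self._encoded = mat
        return self._encoded

    # -- derived views ---------------------------------------------------
    def subset(self, individuals: Iterable[str]) -> "Alignment":
        keep = [i for i in individuals if i in self._rows]
        missing = [i for i in individuals if i not in self._rows]
        if missing:
            raise KeyError(f"individuals not in alignment '{self.locus_name}': {missing}")
        return Alignment(self.locus_name, {i: self._rows[i] for i in keep})

    def with_row(self, individual: str, seq: str) -> "Alignment":
        if individual in self._rows:
            raise ValueError(f"individual '{individual}' already present")
        rows = dict(self._rows)
        rows[individual] = seq
        return Alignment(self.locus_name, rows)

    def take_columns(self, columns: np.ndarray) -> "Alignment":
        enc = self.encoded()[:, columns]
        return Alignment(
            self.locus_name,
            {ind: decode_sequence(enc[i]) for i, ind in enumerate(self.ids)},
        )

    def ungapped_lengths(self) -> Dict[str, int]:
        """Number of called bases (A/C/G/T) per individual."""
        enc = self.encoded()
        counts = (enc < CODE_GAP).sum(axis=1)
        return {ind: int(counts[i]) for i, ind in enumerate(self.ids)}

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Alignment({self.locus_name!r}, n={len(self)}, columns={self.aligned_length})"


class SpeciesMap:
    """Individual -> (species, clade) labels with optional outgroup set.

    Invariants enforced: individual ids unique, each species belongs to a
    single clade, and outgroup individuals belong to species whose clade is
    not shared with any ingroup species.
    """

    def __init__(
        self,
        entries: Mapping[str, Tuple[str, str]],
        outgroup: Iterable[str] = (),
    ):
        self._species: Dict[str, str] = {}
        self._clade_of_species: Dict[str, str] = {}
        for ind, (sp, clade) in entries.items():
            if ind in self._species:
                raise ValueError(f"duplicate individual '{ind}' in species map")
            prior = self._clade_of_species.get(sp)
            if prior is not None and prior != clade:
                raise ValueError(
                    f"species '{sp}' mapped to two clades: '{prior}' and '{clade}'"
                )
            self._species[ind] = sp
            self._clade_of_species[sp] = clade
        self.outgroup: Set[str] = set(outgroup)
        unknown = self.outgroup - set(self._species)
        if unknown:
            raise ValueError(f"outgroup individuals not in map: {sorted(unknown)}")
        og_clades = {self._clade_of_species[self._species[i]] for i in self.outgroup}
        in_clades = {
            self._clade_of_species[self._species[i]]
            for i in self._species
            if i not in self.outgroup
        }
        shared = og_clades & in_clades
        if shared:
            raise ValueError(
                f"outgroup species share clade(s) {sorted(shared)} with the ingroup"
            )

    # -- lookups -----------------------------------------------------------
    @property
    def individuals(self) -> List[str]:
        return list(self._species)

    def species_of(self, individual: str) -> str:
        return self._species[individual]

    def clade_of(self, individual: str) -> str:
        return self._clade_of_species[self._species[individual]]

    def clade_of_species(self, species: str) -> str:
        return self._clade_of_species[species]

    @property
    def species(self) -> List[str]:
        return list(self._clade_of_species)

    def individuals_of_species(self, species: str) -> List[str]:
        return [i for i, s in self._species.items() if s == species]

    def species_in_clade(self, clade: str) -> List[str]:
        return [s for s, c in self._clade_of_species.items() if c == clade]

    @property
    def ingroup_individuals(self) -> List[str]:
        return [i for i in self._species if i not in self.outgroup]

    @property
    def ingroup_species(self) -> List[str]:
        og_species = {self._species[i] for i in self.outgroup}
        return [s for s in self._clade_of_species if s not in og_species]

    @property
    def ingroup_clades(self) -> List[str]:
        seen: List[str] = []
        for s in self.ingroup_species:
            c = self._clade_of_species[s]
            if c not in seen:
                seen.append(c)
        return seen

    def entries(self) -> Dict[str, Tuple[str, str]]:
        return {i: (s, self._clade_of_species[s]) for i, s in self._species.items()}

    def without(self, individuals: Iterable[str]) -> "SpeciesMap":
        drop = set(individuals)
        ent = {i: v for i, v in self.entries().items() if i not in drop}
        return SpeciesMap(ent, outgroup=self.outgroup - drop)

    def with_entry(
        self, individual: str, species: str, clade: str, is_outgroup: bool = False
    ) -> "SpeciesMap":
        ent = self.entries()
        ent[individual] = (species, clade)
        og = set(self.outgroup) | ({individual} if is_outgroup else set())
        return SpeciesMap(ent, outgroup=og)

    def validate_alignment(self, alignment: Alignment) -> None:
        unmapped = [i for i in alignment.ids if i not in self._species]
        if unmapped:
            raise ValueError(
                f"alignment '{alignment.locus_name}' has unmapped individuals: {unmapped}"
            )

    def __len__(self) -> int:
        return len(self._species)


GENOMES = ("cpDNA", "nuclear")


@dataclass
class ReferenceLibrary:
    """A multi-locus reference library with genome-partition labels.

    ``partition_labels`` maps each locus name to ``"cpDNA"`` or ``"nuclear"``;
    the incongruence screen compares trees built from the two partitions.
    Individuals may be absent from some loci (their rows are filled with
    ``?`` on concatenation).
    """

    alignments: List[Alignment]
    species_map: SpeciesMap
    partition_labels: Dict[str, str]

    def __post_init__(self) -> None:
        if not self.alignments:
            raise ValueError("library requires at least one alignment")
        names = [a.locus_name for a in self.alignments]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate locus names: {names}")
        missing = [n for n in names if n not in self.partition_labels]
        if missing:
            raise ValueError(f"loci without a genome partition label: {missing}")
        bad = {n: g for n, g in self.partition_labels.items() if g not in GENOMES}
        if bad:
            raise ValueError(f"unknown genome labels (expected {GENOMES}): {bad}")
        for aln in self.alignments:
            self.species_map.validate_alignment(aln)

    # -- access ------------------------------------------------------------
    @property
    def loci(self) -> List[str]:
        return [a.locus_name for a in self.alignments]

    def locus(self, name: str) -> Alignment:
        for a in self.alignments:
            if a.locus_name == name:
                return a
        raise KeyError(f"no locus named '{name}'")

    @property
    def individuals(self) -> List[str]:
        seen: List[str] = []
        for a in self.alignments:
            for i in a.ids:
                if i not in seen:
                    seen.append(i)
        return seen

    def genome_loci(self, genome: str) -> List[Alignment]:
        return [a for a in self.alignments if self.partition_labels[a.locus_name] == genome]

    def combined(self) -> Alignment:
        from .stats import concatenate

        return concatenate(self.alignments)

    def genome_alignment(self, genome: str) -> Alignment:
        from .stats import concatenate

        loci = self.genome_loci(genome)
        if not loci:
            raise ValueError(f"library has no {genome} loci")
        return concatenate(loci)

    def without(self, individuals: Iterable[str]) -> "ReferenceLibrary":
        drop = set(individuals)
        alns = []
        for a in self.alignments:
            keep = [i for i in a.ids if i not in drop]
            alns.append(Alignment(a.locus_name, {i: a.sequence(i) for i in keep}))
        return ReferenceLibrary(alns, self.species_map.without(drop), dict(self.partition_labels))

    def validate(self) -> None:
        """Re-run all joint invariants (id mapping, partitions)."""
        self.__post_init__()
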