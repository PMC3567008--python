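"""Per-locus summary statistics, locus concatenation and simple indel coding.

The summary mirrors the classic barcode character table: ungapped length
range, aligned length, counts and percentages of variable and
parsimony-informative columns, and mean pairwise sequence divergence (Pi,
taken from a supplied distance matrix, K2P by default).

Indel coding follows the *simple indel coding* scheme: every distinct
maximal gap run observed in at least one sequence becomes one binary
presence/absence character; a sequence whose own gap strictly contains the
character's range (different endpoints) is scored as missing (``?``)
because the shorter indel's presence cannot be assessed inside the longer
deletion.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import CODE_GAP, Alignment
from .distances import DistanceMatrix


def _round_half_up_percent(count: int, total: int) -> float:
    """100*count/total rounded half-up to 2 decimals, computed exactly."""
    frac = Fraction(100 * count, total) * 100 + Fraction(1, 2)
    return (frac.numerator // frac.denominator) / 100.0


def _state_counts(aln: Alignment) -> np.ndarray:
    """(4, L) counts of A/C/G/T per column; gaps and missing are ignored."""
    enc = aln.encoded()
    return np.stack([(enc == b).sum(axis=0) for b in range(4)])


def variable_sites(aln: Alignment) -> int:
    """Columns with >=2 distinct nucleotide states among {A,C,G,T}."""
    counts = _state_counts(aln)
    return int(((counts > 0).sum(axis=0) >= 2).sum())


def parsimony_informative_sites(aln: Alignment) -> int:
    """Columns with >=2 nucleotide states each present in >=2 sequences."""
    counts = _state_counts(aln)
    return int(((counts >= 2).sum(axis=0) >= 2).sum())


@dataclass
class AlignmentStats:
    locus: str
    n_sequences: int
    length_range: Tuple[int, int]
    aligned_length: int
    n_variable: int
    pct_variable: float
    n_parsimony_informative: int
    pct_parsimony_informative: float
    pi: float  # NaN when undefined (single sequence)

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "locus": self.locus,
                "n_sequences": self.n_sequences,
                "length_range_min": self.length_range[0],
                "length_range_max": self.length_range[1],
                "aligned_length": self.aligned_length,
                "n_variable": self.n_variable,
                "pct_variable": self.pct_variable,
                "n_parsimony_informative": self.n_parsimony_informative,
                "pct_parsimony_informative": self.pct_parsimony_informative,
                "pi": self.pi,
            }
        )


def stats(aln: Alignment, dm: Optional[DistanceMatrix] = None) -> AlignmentStats:
    """Summary statistics for one alignment.

    ``pi`` is the mean of all off-diagonal pairwise distances in ``dm``
    (NaN-skipping); pass the K2P matrix computed from the same alignment
    for the conventional corrected divergence, or a p-distance matrix for
    uncorrected divergence.
    """
    n_var = variable_sites(aln)
    n_pi = parsimony_informative_sites(aln)
    lengths = list(aln.ungapped_lengths().values())
    if dm is not None and len(aln) >= 2:
        off = dm.offdiagonal()
        pi = float(np.nanmean(off)) if not np.all(np.isnan(off)) else float("nan")
    else:
        pi = float("nan")
    return AlignmentStats(
        locus=aln.locus_name,
        n_sequences=len(aln),
        length_range=(min(lengths), max(lengths)),
        aligned_length=aln.aligned_length,
        n_variable=n_var,
        pct_variable=_round_half_up_percent(n_var, aln.aligned_length),
        n_parsimony_informative=n_pi,
        pct_parsimony_informative=_round_half_up_percent(n_pi, aln.aligned_length),
        pi=pi,
    )


def concatenate(alignments: Sequence[Alignment], name: Optional[str] = None) -> Alignment:
    """Concatenate loci in the given order.

    The result has one row per individual in the union of the inputs, in
    first-seen order; loci where an individual is absent are filled with
    ``?`` over that locus's aligned length.
    """
    if not alignments:
        raise ValueError("nothing to concatenate")
    if len(alignments) == 1:
        return alignments[0]
    individuals: List[str] = []
    for a in alignments:
        for ind in a.ids:
            if ind not in individuals:
                individuals.append(ind)
    rows: Dict[str, str] = {}
    for ind in individuals:
        parts = []
        for a in alignments:
            parts.append(a.sequence(ind) if ind in a else "?" * a.aligned_length)
        rows[ind] = "".join(parts)
    if name is None:
        name = "+".join(a.locus_name for a in alignments)
    return Alignment(name, rows)


@dataclass
class IndelCharacter:
    """One coded gap range: columns [start, end], 1-based inclusive."""

    locus: str
    start_column: int
    end_column: int

    @property
    def label(self) -> str:
        return f"{self.locus}:{self.start_column}-{self.end_column}"


@dataclass
class IndelCharacterMatrix:
    characters: List[IndelCharacter]
    states: pd.DataFrame  # individuals x characters, values '0'/'1'/'?'

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def appended_columns(self) -> Dict[str, str]:
        """Per-individual string of coded states, for appending to data."""
        return {ind: "".join(self.states.loc[ind]) for ind in self.states.index}


def _gap_runs(seq_codes: np.ndarray, ignore_terminal: bool) -> List[Tuple[int, int]]:
    """Maximal '-' runs as 0-based [start, end) intervals."""
    isgap = seq_codes == CODE_GAP
    if not isgap.any():
        return []
    padded = np.concatenate([[False], isgap, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    runs = list(zip(starts.tolist(), ends.tolist()))
    if ignore_terminal:
        L = len(seq_codes)
        runs = [(s, e) for s, e in runs if s > 0 and e < L]
    return runs


def simple_indel_coding(
    aln: Alignment, ignore_terminal_gaps: bool = False
) -> IndelCharacterMatrix:
    """Code gaps as binary characters under simple indel coding.

    Every distinct maximal gap run becomes one character.  A sequence is
    scored ``1`` if it carries exactly that run, ``?`` if one of its runs
    strictly contains the range (with different endpoints), and ``0``
    otherwise.  Terminal gap runs are coded like internal ones unless
    ``ignore_terminal_gaps`` is set.
    """
    enc = aln.encoded()
    per_seq: Dict[str, set] = {}
    all_runs: set = set()
    for i, ind in enumerate(aln.ids):
        runs = set(_gap_runs(enc[i], ignore_terminal_gaps))
        per_seq[ind] = runs
        all_runs |= runs
    chars = sorted(all_runs)
    characters = [
        IndelCharacter(aln.locus_name, s + 1, e) for s, e in chars
    ]  # 1-based inclusive columns
    data = {}
    for ind in aln.ids:
        runs = per_seq[ind]
        states = []
        for s, e in chars:
            if (s, e) in runs:
                states.append("1")
            elif any(rs <= s and e <= re and (rs, re) != (s, e) for rs, re in runs):
                states.append("?")
            else:
                states.append("0")
        data[ind] = states
    frame = pd.DataFrame.from_dict(
        data, orient="index", columns=[c.label for c in characters]
    ).loc[list(aln.ids)]
    return IndelCharacterMatrix(characters=characters, states=frame)
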