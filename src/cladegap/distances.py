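"""Pairwise evolutionary distances with an explicit missing-data policy.

Two models are provided:

* ``p`` — the uncorrected proportion of differing shared sites.
* ``k2p`` — the Kimura two-parameter correction, which distinguishes
  transitions (A<->G, C<->T; observed proportion ``P`` over shared sites)
  from transversions (proportion ``Q``)::

      d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

  Pairs where either logarithm argument is non-positive are *saturated*:
  the correction diverges and the distance is reported as NA rather than a
  capped value.

Missing-data policies:

* ``pairwise`` deletion (default) drops, per pair, only the columns where
  either sequence has a gap or missing state.
* ``complete`` deletion first removes every column containing any gap or
  missing state in any sequence, then compares the remainder.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import CODE_GAP, Alignment, encode_sequence

MODELS = ("k2p", "p")
DELETION_POLICIES = ("pairwise", "complete")


@dataclass
class PairResult:
    """Distance between one pair of sequences plus its ingredients."""

    distance: float  # NaN when undefined
    p_transitions: float
    q_transversions: float
    n_shared: int
    flag: Optional[str] = None  # None | "saturated" | "no overlap"


def _counts(ea: np.ndarray, eb: np.ndarray) -> Tuple[int, int, int]:
    valid = (ea < CODE_GAP) & (eb < CODE_GAP)
    shared = int(valid.sum())
    if shared == 0:
        return 0, 0, 0
    diff = valid & (ea != eb)
    # transitions swap within a purine (A,G -> codes 0,2) or pyrimidine
    # (C,T -> codes 1,3) pair, i.e. both codes have the same parity
    ts = diff & ((ea & 1) == (eb & 1))
    n_ts = int(ts.sum())
    n_tv = int(diff.sum()) - n_ts
    return shared, n_ts, n_tv


def _as_codes(seq) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        return seq
    return encode_sequence(str(seq).upper())


def k2p_pair(seq_a, seq_b) -> PairResult:
    """K2P distance between two equal-length aligned sequences.

    Gap and missing sites are excluded pairwise.  Returns NaN with flag
    ``"saturated"`` when the correction is undefined and ``"no overlap"``
    when the sequences share no comparable site.
    """
    ea, eb = _as_codes(seq_a), _as_codes(seq_b)
    if len(ea) != len(eb):
        raise ValueError(f"unequal sequence lengths: {len(ea)} vs {len(eb)}")
    shared, n_ts, n_tv = _counts(ea, eb)
    if shared == 0:
        return PairResult(float("nan"), float("nan"), float("nan"), 0, "no overlap")
    p = n_ts / shared
    q = n_tv / shared
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return PairResult(float("nan"), p, q, shared, "saturated")
    d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
    return PairResult(max(float(d), 0.0), p, q, shared, None)


def k2p(seq_a, seq_b) -> float:
    """K2P distance as a bare float (NaN when saturated / no overlap)."""
    return k2p_pair(seq_a, seq_b).distance


def p_distance_pair(seq_a, seq_b) -> PairResult:
    ea, eb = _as_codes(seq_a), _as_codes(seq_b)
    if len(ea) != len(eb):
        raise ValueError(f"unequal sequence lengths: {len(ea)} vs {len(eb)}")
    shared, n_ts, n_tv = _counts(ea, eb)
    if shared == 0:
        return PairResult(float("nan"), float("nan"), float("nan"), 0, "no overlap")
    p = n_ts / shared
    q = n_tv / shared
    return PairResult((n_ts + n_tv) / shared, p, q, shared, None)


def p_distance(seq_a, seq_b) -> float:
    return p_distance_pair(seq_a, seq_b).distance


class DistanceMatrix:
    """Symmetric pairwise distance matrix with model/deletion metadata."""

    def __init__(
        self,
        ids: Sequence[str],
        values: np.ndarray,
        model: str = "k2p",
        deletion: str = "pairwise",
    ):
        ids = list(ids)
        values = np.asarray(values, dtype=float)
        if len(ids) == 0:
            raise ValueError("empty distance matrix")
        if values.shape != (len(ids), len(ids)):
            raise ValueError(f"matrix shape {values.shape} does not match {len(ids)} ids")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ids in distance matrix")
        if len(ids) > 1:
            diff = np.abs(values - values.T)
            if not np.all(np.isnan(diff)) and np.nanmax(diff) > 1e-9:
                raise ValueError("distance matrix is not symmetric")
        self.ids = ids
        self.values = values
        self.model = model
        self.deletion = deletion
        self._index = {ind: i for i, ind in enumerate(ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    @property
    def has_missing(self) -> bool:
        off = ~np.eye(len(self.ids), dtype=bool)
        return bool(np.isnan(self.values[off]).any())

    def missing_pairs(self) -> List[Tuple[str, str]]:
        out = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                if np.isnan(self.values[i, j]):
                    out.append((self.ids[i], self.ids[j]))
        return out

    def submatrix(self, ids: Iterable[str]) -> "DistanceMatrix":
        ids = list(ids)
        idx = [self._index[i] for i in ids]
        return DistanceMatrix(ids, self.values[np.ix_(idx, idx)], self.model, self.deletion)

    def mean_to(self, a: str, others: Iterable[str]) -> float:
        """Mean distance from one individual to a set of others (NaN-aware)."""
        idx = [self._index[o] for o in others if o != a]
        if not idx:
            return float("nan")
        row = self.values[self._index[a], idx]
        return float(np.nanmean(row)) if not np.all(np.isnan(row)) else float("nan")

    def offdiagonal(self) -> np.ndarray:
        n = len(self.ids)
        iu = np.triu_indices(n, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def _onehot_matmuls(enc: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shared-site, transition and transversion counts for all pairs."""
    V = (enc < CODE_GAP).astype(np.float64)
    S = V @ V.T
    X = [(enc == b).astype(np.float64) for b in range(4)]
    M = sum(Xb @ Xb.T for Xb in X)
    TS = X[0] @ X[2].T + X[2] @ X[0].T + X[1] @ X[3].T + X[3] @ X[1].T
    TV = S - M - TS
    return S, TS, TV


def _distances_from_counts(
    S: np.ndarray, TS: np.ndarray, TV: np.ndarray, model: str
) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        P = TS / S
        Q = TV / S
        if model == "p":
            D = (TS + TV) / S
        else:
            w1 = 1.0 - 2.0 * P - Q
            w2 = 1.0 - 2.0 * Q
            D = -0.5 * np.log(w1) - 0.25 * np.log(w2)
            D = np.where((w1 > 0) & (w2 > 0), D, np.nan)
    D = np.where(S > 0, D, np.nan)
    D = np.where(np.isnan(D), D, np.maximum(D, 0.0))
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def distance_matrix(
    aln: Alignment, model: str = "k2p", deletion: str = "pairwise"
) -> DistanceMatrix:
    """All-pairs distance matrix for one alignment.

    ``complete`` deletion removes every column containing any gap/missing
    character before computing, and raises if no column survives.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model '{model}' (expected one of {MODELS})")
    if deletion not in DELETION_POLICIES:
        raise ValueError(f"unknown deletion policy '{deletion}'")
    if len(aln) < 2:
        raise ValueError("distance matrix requires at least two sequences")
    enc = aln.encoded()
    if deletion == "complete":
        keep = ~(enc >= CODE_GAP).any(axis=0)
        if not keep.any():
            raise ValueError("complete deletion removed all columns")
        enc = enc[:, keep]
    S, TS, TV = _onehot_matmuls(enc)
    D = _distances_from_counts(S, TS, TV, model)
    return DistanceMatrix(aln.ids, D, model=model, deletion=deletion)


class PairColumnCounts:
    """Per-pair, per-column indicator matrices for fast column bootstraps.

    For a column resample expressed as multiplicity weights ``w`` (one
    integer per original column, summing to the alignment length), the
    resampled pair counts are plain matrix-vector products, so a whole
    batch of bootstrap replicates reduces to three GEMMs.
    """

    def __init__(self, enc: np.ndarray, ids: Sequence[str]):
        n, L = enc.shape
        self.ids = list(ids)
        self.n = n
        self.L = L
        iu, ju = np.triu_indices(n, k=1)
        self._iu, self._ju = iu, ju
        valid = enc < CODE_GAP
        shared = valid[iu] & valid[ju]
        diff = shared & (enc[iu] != enc[ju])
        ts = diff & ((enc[iu] & 1) == (enc[ju] & 1))
        self._shared = shared.astype(np.float32)
        self._ts = ts.astype(np.float32)
        self._tv = (diff & ~ts).astype(np.float32)

    def distance_batch(self, weights: np.ndarray, model: str = "k2p") -> np.ndarray:
        """Distance matrices for a batch of column-weight vectors.

        Parameters
        ----------
        weights : array (L, B)
            Column multiplicities for B replicates.
        Returns
        -------
        array (B, n, n) with NaN where a pair is saturated or unshared.
        """
        W = np.asarray(weights, dtype=np.float32)
        if W.ndim == 1:
            W = W[:, None]
        S = self._ts @ W, self._tv @ W, self._shared @ W
        TS, TV, SH = S
        B = W.shape[1]
        out = np.empty((B, self.n, self.n), dtype=np.float64)
        for b in range(B):
            sq = np.zeros((self.n, self.n))
            s = np.zeros((self.n, self.n))
            tv = np.zeros((self.n, self.n))
            s[self._iu, self._ju] = SH[:, b]
            sq[self._iu, self._ju] = TS[:, b]
            tv[self._iu, self._ju] = TV[:, b]
            s += s.T
            sq += sq.T
            tv += tv.T
            out[b] = _distances_from_counts(s, sq, tv, model)
        return out
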