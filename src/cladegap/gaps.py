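"""Barcode-gap analysis and PCA of the distance matrix.

Two flavours of gap test are provided:

* :func:`gap_report` — the classical all-species comparison of the
  intraspecific and interspecific distance distributions, summarised by the
  fraction of interspecific distances that fall at or below the largest
  intraspecific distance (the *overlap fraction*).
* :func:`target_gap` — the target-specific variant for incompletely
  sampled genera: the focal species' maximum intraspecific distance is
  compared only against its distances to its closest relatives.  A gap
  exists when the smallest target-to-relative distance exceeds the largest
  within-target distance.  Distances among the relatives themselves are
  deliberately ignored; only target-to-relative comparisons matter.

:func:`pca_scatter` ordinates individuals by treating the rows of the
symmetric distance matrix as observations and the columns as variables
(centred, covariance eigendecomposition) — i.e. a PCA of the distance
matrix as a data table, not a principal-coordinates analysis.  A PCoA
alternative (:func:`pcoa_scatter`) is provided and is a different method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .containers import SpeciesMap
from .distances import DistanceMatrix


@dataclass
class GapReport:
    intra: List[Tuple[str, float]]  # (species, distance)
    inter: List[Tuple[str, str, float]]  # (species_a, species_b, distance)
    overlap_fraction: float  # NaN when no intraspecific pairs exist

    @property
    def max_intra(self) -> float:
        vals = [d for _, d in self.intra if not np.isnan(d)]
        return max(vals) if vals else float("nan")

    @property
    def min_inter(self) -> float:
        vals = [d for *_, d in self.inter if not np.isnan(d)]
        return min(vals) if vals else float("nan")


def gap_report(
    dm: DistanceMatrix, sp_map: SpeciesMap, include_outgroup: bool = False
) -> GapReport:
    """Classify every unordered pair as intra- or inter-specific.

    ``overlap_fraction`` is the proportion of interspecific distances less
    than or equal to the maximum intraspecific distance (NaN when every
    species is a singleton).
    """
    ids = [
        i
        for i in dm.ids
        if include_outgroup or i not in sp_map.outgroup
    ]
    intra: List[Tuple[str, float]] = []
    inter: List[Tuple[str, str, float]] = []
    for a_i, a in enumerate(ids):
        sp_a = sp_map.species_of(a)
        for b in ids[a_i + 1 :]:
            sp_b = sp_map.species_of(b)
            d = dm.get(a, b)
            if sp_a == sp_b:
                intra.append((sp_a, d))
            else:
                inter.append((sp_a, sp_b, d))
    intra_vals = np.array([d for _, d in intra if not np.isnan(d)])
    inter_vals = np.array([d for *_, d in inter if not np.isnan(d)])
    if intra_vals.size == 0 or inter_vals.size == 0:
        overlap = float("nan")
    else:
        overlap = float((inter_vals <= intra_vals.max()).mean())
    return GapReport(intra=intra, inter=inter, overlap_fraction=overlap)


@dataclass
class TargetGapReport:
    target: str
    relatives: List[str]
    max_intra: float  # NaN for singleton targets
    min_inter: float
    gap_exists: Optional[bool]  # None when max_intra undefined
    histogram: pd.DataFrame  # bin_left, count_intra, count_inter
    advisory: Optional[str] = None


def closest_relatives(
    dm: DistanceMatrix, sp_map: SpeciesMap, target: str, k: int = 2
) -> List[str]:
    """The k species with smallest mean interspecific distance to the target.

    The mean (rather than minimum) is used so a single aberrant individual
    does not decide the relative set.  Outgroup species are excluded.
    """
    target_inds = sp_map.individuals_of_species(target)
    if not target_inds:
        raise ValueError(f"unknown species '{target}'")
    og_species = {sp_map.species_of(i) for i in sp_map.outgroup}
    means = []
    for sp in sp_map.species:
        if sp == target or sp in og_species:
            continue
        inds = [i for i in sp_map.individuals_of_species(sp) if i in set(dm.ids)]
        if not inds:
            continue
        vals = [dm.get(a, b) for a in target_inds for b in inds]
        vals = [v for v in vals if not np.isnan(v)]
        if vals:
            means.append((float(np.mean(vals)), sp))
    means.sort(key=lambda t: (t[0], t[1]))
    return [sp for _, sp in means[:k]]


def target_gap(
    dm: DistanceMatrix,
    sp_map: SpeciesMap,
    target: str,
    relatives: Union[str, Iterable[str]] = "auto",
    k: int = 2,
    bin_width: float = 0.002,
) -> TargetGapReport:
    """Target-specific barcode-gap test.

    ``relatives="auto"`` resolves the closest relatives as the ``k``
    species with smallest mean interspecific distance to the target.
    ``gap_exists`` is True iff the minimum target-to-relative distance
    exceeds the maximum within-target distance; it is None (with an
    advisory) when the target is a singleton.
    """
    target_inds = [i for i in dm.ids if sp_map.species_of(i) == target]
    if not target_inds:
        raise ValueError(f"no individuals of species '{target}' in the matrix")
    if isinstance(relatives, str) and relatives == "auto":
        rel_species = closest_relatives(dm, sp_map, target, k=k)
    else:
        rel_species = list(relatives)
    if not rel_species:
        raise ValueError("no relative species resolved")
    rel_inds = [
        i for i in dm.ids if sp_map.species_of(i) in set(rel_species)
    ]
    if not rel_inds:
        raise ValueError(f"no individuals of relatives {rel_species} in the matrix")

    intra_vals = []
    for a_i, a in enumerate(target_inds):
        for b in target_inds[a_i + 1 :]:
            d = dm.get(a, b)
            if not np.isnan(d):
                intra_vals.append(d)
    inter_vals = []
    for a in target_inds:
        for b in rel_inds:
            d = dm.get(a, b)
            if not np.isnan(d):
                inter_vals.append(d)

    advisory = None
    if intra_vals:
        max_intra = float(max(intra_vals))
    else:
        max_intra = float("nan")
        advisory = (
            f"species '{target}' has a single usable individual; the "
            "within-species spread is undefined — add conspecific individuals"
        )
    min_inter = float(min(inter_vals)) if inter_vals else float("nan")
    if np.isnan(max_intra) or np.isnan(min_inter):
        gap_exists: Optional[bool] = None
    else:
        gap_exists = bool(min_inter > max_intra)

    top = max(inter_vals + intra_vals) if (inter_vals or intra_vals) else bin_width
    edges = np.arange(0.0, top + 2 * bin_width, bin_width)
    c_intra, _ = np.histogram(intra_vals, bins=edges)
    c_inter, _ = np.histogram(inter_vals, bins=edges)
    hist = pd.DataFrame(
        {"bin_left": edges[:-1], "count_intra": c_intra, "count_inter": c_inter}
    )
    return TargetGapReport(
        target=target,
        relatives=rel_species,
        max_intra=max_intra,
        min_inter=min_inter,
        gap_exists=gap_exists,
        histogram=hist,
        advisory=advisory,
    )


@dataclass
class PcaResult:
    coordinates: pd.DataFrame  # individuals x PC scores
    eigenvalues: np.ndarray  # non-increasing
    variance_explained: np.ndarray


def pca_scatter(dm: DistanceMatrix, n_components: Optional[int] = None) -> PcaResult:
    """PCA of the distance matrix treated as a data table.

    Rows are observations, columns variables; columns are centred (no
    standardisation) and the covariance matrix is eigendecomposed.  Scores
    are the projections of the centred rows onto the eigenvectors.
    """
    if len(dm) < 3:
        raise ValueError("PCA needs at least three individuals")
    if dm.has_missing:
        raise ValueError("PCA requires a complete distance matrix (no NA)")
    from sklearn.decomposition import PCA

    n = len(dm)
    if n_components is None:
        n_components = min(n, n)  # all available
    pca = PCA(n_components=None, svd_solver="full")
    scores = pca.fit_transform(dm.values)
    ncomp = scores.shape[1]
    cols = [f"PC{i+1}" for i in range(ncomp)]
    coords = pd.DataFrame(scores, index=dm.ids, columns=cols)
    return PcaResult(
        coordinates=coords,
        eigenvalues=pca.explained_variance_.copy(),
        variance_explained=pca.explained_variance_ratio_.copy(),
    )


def pcoa_scatter(dm: DistanceMatrix) -> PcaResult:
    """Principal-coordinates analysis of the distances (metric MDS).

    This embeds the distances themselves rather than ordinating the matrix
    rows; it is provided as an alternative and gives different coordinates
    from :func:`pca_scatter`.
    """
    if dm.has_missing:
        raise ValueError("PCoA requires a complete distance matrix (no NA)")
    from skbio.stats.ordination import pcoa as _pcoa
    from skbio import DistanceMatrix as SkbioDM

    res = _pcoa(SkbioDM(dm.values, ids=dm.ids))
    coords = res.samples.copy()
    coords.index = list(dm.ids)
    return PcaResult(
        coordinates=coords,
        eigenvalues=res.eigvals.to_numpy(),
        variance_explained=res.proportion_explained.to_numpy(),
    )
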