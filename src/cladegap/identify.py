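"""Organellar-vs-nuclear incongruence screening and two-step identification.

Two procedures operate on a :class:`~cladegap.containers.ReferenceLibrary`
whose loci are partitioned into a chloroplast (maternally inherited) and a
nuclear (biparentally inherited) genome:

* :func:`classify_incongruence` reads each individual's placement off two
  rooted, bootstrapped trees (one per genome) and issues a verdict:
  ``concordant``, ``putative_hybrid`` (maternal parent from the cpDNA
  placement, paternal from the nuclear one), ``suspected_misidentification``
  (both genomes agree with each other but contradict the nominal label) or
  ``unresolved``.  A hybrid verdict requires the two genomes to disagree at
  the *clade* level — species-level conflict alone stays unresolved, since
  it could reflect incomplete lineage sorting.

* :func:`identify` implements the two-step strategy for incompletely
  sampled genera: step 1 ("clade barcoding") assigns a query to a major
  clade by mean multi-locus distance, cross-checked by NJ placement;
  step 2 restricts the library to that clade, builds a bootstrapped NJ
  tree, and accepts a species-level identification only when the query is
  nested in a well-supported monophyletic group with the nearest species
  AND the target-specific barcode gap holds with the query included.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Tuple

import dendropy
import numpy as np
import pandas as pd

from .containers import Alignment, ReferenceLibrary, SpeciesMap
from .distances import distance_matrix
from .gaps import target_gap
from .stats import concatenate
from .trees import (
    bootstrap,
    is_monophyletic,
    nj,
    node_support,
    root_with_outgroup,
    tree_tip_labels,
    _leafset,
)

DEFAULT_SUPPORT_THRESHOLD = 75
DEFAULT_BOOT_REPS = 500

VERDICTS = (
    "concordant",
    "putative_hybrid",
    "suspected_misidentification",
    "unresolved",
)


@dataclass
class TreeAssignment:
    """Placement of one individual in one rooted, bootstrapped tree."""

    species: Optional[str]  # unique species of the co-members, if any
    clade: Optional[str]  # unique clade of the co-members, if any
    support: Optional[int]

    @property
    def resolved(self) -> bool:
        return self.clade is not None


@dataclass
class IncongruenceRecord:
    individual: str
    nominal_species: str
    nominal_clade: str
    cp: TreeAssignment
    nuc: TreeAssignment
    verdict: str
    maternal: Optional[str] = None  # cpDNA-side parent (hybrid verdicts)
    paternal: Optional[str] = None  # nuclear-side parent


@dataclass
class IncongruenceReport:
    records: List[IncongruenceRecord]
    support_threshold: int

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, individual: str) -> IncongruenceRecord:
        for r in self.records:
            if r.individual == individual:
                return r
        raise KeyError(individual)

    def verdicts(self) -> Dict[str, str]:
        return {r.individual: r.verdict for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "individual": r.individual,
                    "species": r.nominal_species,
                    "clade": r.nominal_clade,
                    "cp_species": r.cp.species,
                    "cp_clade": r.cp.clade,
                    "cp_support": r.cp.support,
                    "nuc_species": r.nuc.species,
                    "nuc_clade": r.nuc.clade,
                    "nuc_support": r.nuc.support,
                    "verdict": r.verdict,
                    "maternal": r.maternal,
                    "paternal": r.paternal,
                }
            )
        return pd.DataFrame(rows)


def _assign_in_tree(
    tree: dendropy.Tree,
    individual: str,
    sp_map: SpeciesMap,
    threshold: int,
) -> TreeAssignment:
    """Smallest well-supported clade containing the individual plus >= 1
    other (non-outgroup) reference individual; returns the unique species
    and clade of the co-members (None where not unique)."""
    leaf = None
    for lf in tree.leaf_node_iter():
        if lf.taxon.label == individual:
            leaf = lf
            break
    if leaf is None:
        raise ValueError(f"individual '{individual}' not in tree")
    node = leaf.parent_node
    while node is not None:
        others = _leafset(node) - {individual} - sp_map.outgroup
        sup = node_support(node)
        if others and node.parent_node is not None and sup is not None and sup >= threshold:
            # strict majority of the co-members decides; a planted hybrid or
            # mislabel among them must not veto the assignment of its
            # (innocent) neighbours
            def majority(labels: List[str]) -> Optional[str]:
                counts = Counter(labels)
                top, n_top = counts.most_common(1)[0]
                return top if 2 * n_top > len(labels) else None

            return TreeAssignment(
                species=majority([sp_map.species_of(o) for o in others]),
                clade=majority([sp_map.clade_of(o) for o in others]),
                support=sup,
            )
        node = node.parent_node
    return TreeAssignment(species=None, clade=None, support=None)


def classify_incongruence(
    cp_tree: dendropy.Tree,
    nuc_tree: dendropy.Tree,
    sp_map: SpeciesMap,
    support_threshold: int = DEFAULT_SUPPORT_THRESHOLD,
) -> IncongruenceReport:
    """Compare placements across the two genome trees per individual.

    Both trees must be rooted, share a tip set, and carry bootstrap
    supports as internal-node labels.  Outgroup individuals are used for
    rooting only and are not classified.
    """
    for name, tree in (("cpDNA", cp_tree), ("nuclear", nuc_tree)):
        if not tree.is_rooted:
            raise ValueError(f"{name} tree is not rooted; root with the outgroup first")
    cp_tips = tree_tip_labels(cp_tree)
    nuc_tips = tree_tip_labels(nuc_tree)
    if cp_tips != nuc_tips:
        raise ValueError(
            "tip sets differ between the cpDNA and nuclear trees: "
            f"{sorted(cp_tips ^ nuc_tips)}"
        )

    records: List[IncongruenceRecord] = []
    for ind in sorted(cp_tips):
        if ind in sp_map.outgroup:
            continue
        nominal_sp = sp_map.species_of(ind)
        nominal_clade = sp_map.clade_of(ind)
        cp = _assign_in_tree(cp_tree, ind, sp_map, support_threshold)
        nuc = _assign_in_tree(nuc_tree, ind, sp_map, support_threshold)
        maternal = paternal = None
        n_conspecifics = len(sp_map.individuals_of_species(nominal_sp)) - 1

        if not cp.resolved or not nuc.resolved:
            verdict = "unresolved"
        elif cp.clade != nuc.clade:
            verdict = "putative_hybrid"
            maternal = cp.species or cp.clade
            paternal = nuc.species or nuc.clade
        else:  # genomes agree with each other at clade level
            # for singleton species only the clade level is assessable:
            # clustering with a congener of the right clade is expected
            def consistent(a: TreeAssignment) -> bool:
                return a.clade == nominal_clade and (
                    a.species in (nominal_sp, None) or n_conspecifics == 0
                )

            consistent_cp = consistent(cp)
            consistent_nuc = consistent(nuc)
            if consistent_cp and consistent_nuc:
                verdict = "concordant"
            elif cp.clade != nominal_clade:
                # both genomes place it in a foreign clade
                verdict = "suspected_misidentification"
            elif (
                cp.species is not None
                and cp.species == nuc.species
                and cp.species != nominal_sp
                and n_conspecifics >= 1
            ):
                # same clade but both genomes nest it in another species,
                # away from its nominal conspecifics
                verdict = "suspected_misidentification"
            else:
                verdict = "unresolved"
        records.append(
            IncongruenceRecord(
                individual=ind,
                nominal_species=nominal_sp,
                nominal_clade=nominal_clade,
                cp=cp,
                nuc=nuc,
                verdict=verdict,
                maternal=maternal,
                paternal=paternal,
            )
        )
    return IncongruenceReport(records=records, support_threshold=support_threshold)


def partition_trees(
    library: ReferenceLibrary,
    boot_reps: int = DEFAULT_BOOT_REPS,
    seed: int = 1,
    model: str = "k2p",
    deletion: str = "pairwise",
) -> Tuple[dendropy.Tree, dendropy.Tree]:
    """Bootstrapped, outgroup-rooted NJ trees for the two genome partitions."""
    if not library.species_map.outgroup:
        raise ValueError("library has no outgroup individuals to root with")
    out = []
    for k, genome in enumerate(("cpDNA", "nuclear")):
        aln = library.genome_alignment(genome)
        tree = bootstrap(aln, n_reps=boot_reps, seed=seed + k, model=model, deletion=deletion)
        og = set(library.species_map.outgroup) & set(aln.ids)
        out.append(root_with_outgroup(tree, og))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# two-step identification
# ---------------------------------------------------------------------------
@dataclass
class CladeAssignment:
    clade: str
    margin: float  # runner-up mean distance minus best mean distance
    mean_distances: Dict[str, float]
    placement_conflict: bool


@dataclass
class IdentificationResult:
    query_id: str
    step1_clade: str
    margin: float
    step2_species: Optional[str]
    monophyly: Optional[bool]
    monophyly_support: Optional[int]
    cohesive: Optional[bool]  # gap wider than the within-species spread
    gap_exists: Optional[bool]
    decision: str  # identified | clade_only | unresolved
    advisory: Optional[str] = None


def _extend_library_with_query(
    library: ReferenceLibrary, query: Mapping[str, str], query_id: str
) -> List[Alignment]:
    """Per-locus alignments with the query row appended (``?`` where a
    locus is missing from the query)."""
    known = set(library.loci)
    unknown = set(query) - known
    if unknown:
        raise ValueError(f"query loci not in library: {sorted(unknown)}")
    out = []
    for aln in library.alignments:
        seq = query.get(aln.locus_name)
        if seq is None:
            seq = "?" * aln.aligned_length
        if len(seq) != aln.aligned_length:
            raise ValueError(
                f"query sequence for locus '{aln.locus_name}' has length "
                f"{len(seq)}, expected {aln.aligned_length} (pre-aligned input required)"
            )
        out.append(aln.with_row(query_id, seq))
    return out


def assign_clade(
    query: Mapping[str, str],
    library: ReferenceLibrary,
    query_id: str = "query",
    model: str = "k2p",
    deletion: str = "pairwise",
) -> CladeAssignment:
    """Step 1: assign a query to a major clade by mean combined distance.

    The clade with the smallest mean distance from the query to its
    individuals wins; the margin is the runner-up mean minus the best
    mean.  An NJ placement cross-check flags a conflict when the query
    does not attach among the winning clade's individuals (or the margin
    is zero).
    """
    sp_map = library.species_map
    clades = sp_map.ingroup_clades
    if len(clades) < 2:
        raise ValueError("clade assignment requires a library with >= 2 clades")
    extended = _extend_library_with_query(library, query, query_id)
    combined = concatenate(extended)
    dm = distance_matrix(combined, model=model, deletion=deletion)
    if np.isnan(dm.values[dm.ids.index(query_id)]).all():
        raise ValueError("query shares no comparable sites with the library")

    means: Dict[str, float] = {}
    for clade in clades:
        inds = [
            i
            for sp in sp_map.species_in_clade(clade)
            for i in sp_map.individuals_of_species(sp)
            if i in set(dm.ids)
        ]
        means[clade] = dm.mean_to(query_id, inds)
    ranked = sorted(means.items(), key=lambda kv: (np.isnan(kv[1]), kv[1], kv[0]))
    best_clade, best = ranked[0]
    runner = ranked[1][1] if len(ranked) > 1 else float("nan")
    margin = float(runner - best) if not np.isnan(runner) else float("nan")

    # NJ placement cross-check
    conflict = margin == 0.0
    tree = nj(dm)
    if sp_map.outgroup:
        og = set(sp_map.outgroup) & set(combined.ids)
        if og:
            tree = root_with_outgroup(tree, og)
    leaf = [lf for lf in tree.leaf_node_iter() if lf.taxon.label == query_id][0]
    node = leaf.parent_node
    while node is not None:
        others = _leafset(node) - {query_id} - sp_map.outgroup
        if others:
            other_clades = {sp_map.clade_of(o) for o in others}
            if other_clades != {best_clade}:
                conflict = True
            break
        node = node.parent_node
    return CladeAssignment(
        clade=best_clade,
        margin=max(margin, 0.0) if not np.isnan(margin) else margin,
        mean_distances=means,
        placement_conflict=bool(conflict),
    )


def identify(
    query: Mapping[str, str],
    library: ReferenceLibrary,
    query_id: str = "query",
    support_threshold: int = DEFAULT_SUPPORT_THRESHOLD,
    boot_reps: int = DEFAULT_BOOT_REPS,
    seed: int = 1,
    model: str = "k2p",
    deletion: str = "pairwise",
) -> IdentificationResult:
    """Two-step identification of a pre-aligned query against the library.

    ``identified`` requires, inside the assigned clade: (i) monophyly of
    the nearest species together with the query at or above the support
    threshold; (ii) a target-specific barcode gap with the query counted
    among that species' individuals; and (iii) cohesion — the gap must be
    wider than the within-species spread it sits on
    (``min_inter > 2 * max_intra``), so a query that merely attaches as a
    long-branch sister at near-interspecific distance is not absorbed into
    the species.  When the step-2 criteria fail the decision is
    ``clade_only``; a step-1 placement conflict yields ``unresolved``.
    """
    sp_map = library.species_map
    step1 = assign_clade(query, library, query_id=query_id, model=model, deletion=deletion)
    if step1.placement_conflict:
        return IdentificationResult(
            query_id=query_id,
            step1_clade=step1.clade,
            margin=step1.margin,
            step2_species=None,
            monophyly=None,
            monophyly_support=None,
            cohesive=None,
            gap_exists=None,
            decision="unresolved",
            advisory="step-1 placement conflict: distance and tree placement disagree",
        )

    clade_species = sp_map.species_in_clade(step1.clade)
    if len(clade_species) < 2:
        return IdentificationResult(
            query_id=query_id,
            step1_clade=step1.clade,
            margin=step1.margin,
            step2_species=None,
            monophyly=None,
            monophyly_support=None,
            cohesive=None,
            gap_exists=None,
            decision="clade_only",
            advisory=(
                f"clade '{step1.clade}' holds a single reference species; "
                "densify sampling in this clade before species-level identification"
            ),
        )

    clade_inds = [
        i for sp in clade_species for i in sp_map.individuals_of_species(sp)
    ]
    keep = set(clade_inds) | set(sp_map.outgroup)
    sub_library = library.without([i for i in library.individuals if i not in keep])
    extended = _extend_library_with_query(sub_library, query, query_id)
    combined = concatenate(extended)
    dm = distance_matrix(combined, model=model, deletion=deletion)

    # nearest species inside the clade by mean distance to the query
    means = []
    for sp in clade_species:
        inds = [i for i in sp_map.individuals_of_species(sp) if i in set(dm.ids)]
        m = dm.mean_to(query_id, inds)
        if not np.isnan(m):
            means.append((m, sp))
    means.sort(key=lambda t: (t[0], t[1]))
    nearest = means[0][1]

    tree = bootstrap(combined, n_reps=boot_reps, seed=seed, model=model, deletion=deletion)
    og = set(sp_map.outgroup) & set(combined.ids)
    rooted = root_with_outgroup(tree, og) if og else tree
    group = set(sp_map.individuals_of_species(nearest)) & set(combined.ids)
    group.add(query_id)
    try:
        mono, mono_support = is_monophyletic(rooted, group)
    except ValueError:
        mono, mono_support = None, None

    # gap test with the query provisionally counted as the nearest species
    ext_map = sp_map.without(
        [i for i in sp_map.individuals if i not in set(combined.ids)]
    ).with_entry(query_id, nearest, step1.clade)
    n_other = len([s for s in clade_species if s != nearest])
    gap = target_gap(dm, ext_map, nearest, relatives="auto", k=min(2, n_other))

    # cohesion: the gap must be wider than the within-species spread,
    # i.e. min_inter - max_intra > max_intra (scale-invariant, no units)
    cohesive: Optional[bool] = None
    if gap.gap_exists is True:
        cohesive = bool(gap.min_inter > 2.0 * gap.max_intra)
    ok = bool(mono) and mono_support is not None and mono_support >= support_threshold
    decision = (
        "identified" if ok and gap.gap_exists is True and cohesive else "clade_only"
    )
    advisory = None
    if decision == "clade_only":
        reasons = []
        if not ok:
            reasons.append("monophyly with the nearest species is not well supported")
        if gap.gap_exists is not True:
            reasons.append("no target-specific barcode gap")
        elif not cohesive:
            reasons.append(
                "the barcode gap is narrower than the within-species spread "
                "(the query sits at near-interspecific distance)"
            )
        advisory = (
            "; ".join(reasons)
            + " — add species/individuals of this clade until the query nests "
            "exclusively within one species (consider the PCA scatter export)"
        )
    return IdentificationResult(
        query_id=query_id,
        step1_clade=step1.clade,
        margin=step1.margin,
        step2_species=nearest if decision == "identified" else None,
        monophyly=mono,
        monophyly_support=mono_support,
        cohesive=cohesive,
        gap_exists=gap.gap_exists,
        decision=decision,
        advisory=advisory,
    )
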