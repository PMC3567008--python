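"""Seeded simulator of clade/species/individual-structured barcode libraries.

The generator emulates the sampling structure of a species-rich plant genus
surveyed with two chloroplast loci and one nuclear locus:

* an ultrametric species history: clades radiate from a single point at
  depth ``depth_clade`` (expected substitutions/site), species within a
  clade at ``depth_species``, and conspecific individuals coalesce in a
  star at ``depth_intra``; a single outgroup individual diverges deeper;
* a two-parameter (transition/transversion, ratio ``kappa``) substitution
  process, matching the K2P estimator used downstream so that distance
  estimates are consistent with the simulation depths;
* indels simulated as inherited deletion events only (geometric length),
  which keeps all sequences in shared alignment coordinates;
* planted *hybrids* (chloroplast loci follow the maternal species' lineage,
  the nuclear locus the paternal one; the nominal label is the maternal
  species) and planted *mislabels* (an extra individual of one species
  carrying the nominal label of a species from another clade).

All randomness is driven by ``SimConfig.seed``; identical configs produce
byte-identical libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Set, Tuple

import numpy as np
import pandas as pd

from .containers import Alignment, ReferenceLibrary, SpeciesMap


@dataclass
class SimConfig:
    """Simulation parameters.

    Depths are in expected substitutions per site and must be ordered
    ``depth_intra < depth_species < depth_clade``.  Defaults mirror a
    moderately diverged genus: individuals of one species differ by about
    ``2*depth_intra = 1%``, congeneric species within a clade by about
    ``2*depth_species = 6%``, and clades by about ``2*depth_clade = 16%``.
    """

    n_clades: int = 9
    species_per_clade: int = 4
    individuals_per_species: Tuple[int, int] = (1, 3)
    locus_lengths: Tuple[int, ...] = (1745, 681, 1527)
    locus_names: Tuple[str, ...] = ("cp1", "cp2", "nuc1")
    partition_labels: Tuple[str, ...] = ("cpDNA", "cpDNA", "nuclear")
    depth_clade: float = 0.08
    depth_species: float = 0.03
    depth_intra: float = 0.005
    depth_outgroup: float = 0.16
    kappa: float = 2.0
    indel_rate: float = 0.02
    mean_indel_length: float = 3.0
    n_hybrids: int = 1
    n_mislabels: int = 1
    include_outgroup: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.depth_intra < self.depth_species < self.depth_clade):
            raise ValueError(
                "depths must satisfy 0 <= depth_intra < depth_species < depth_clade"
            )
        if self.depth_outgroup <= self.depth_clade:
            raise ValueError("depth_outgroup must exceed depth_clade")
        if len(self.locus_lengths) != len(self.locus_names) or len(
            self.locus_names
        ) != len(self.partition_labels):
            raise ValueError("locus_lengths, locus_names and partition_labels must align")
        if min(self.individuals_per_species) < 1:
            raise ValueError("at least one individual per species")
        if self.indel_rate < 0 or self.kappa <= 0:
            raise ValueError("rates must be non-negative and kappa positive")
        if self.n_hybrids and self.n_clades < 2:
            raise ValueError("hybrids require at least two clades")
        if self.n_mislabels and self.n_clades < 2:
            raise ValueError("mislabels require at least two clades")


@dataclass
class Role:
    kind: str  # normal | hybrid | mislabeled
    maternal: Optional[str] = None  # hybrid: cpDNA-side parent species
    paternal: Optional[str] = None  # hybrid: nuclear-side parent species
    true_species: Optional[str] = None  # mislabeled: the generating species


@dataclass
class SimTruth:
    """Ground truth of a simulated library."""

    roles: Dict[str, Role]
    true_species: Dict[str, str]  # generating species per individual
    true_clade: Dict[str, str]
    species_trees: Dict[str, str]  # genome -> newick of the generating history
    config: SimConfig
    ancestors: Dict[str, Dict[str, Tuple[np.ndarray, np.ndarray]]] = field(
        default_factory=dict, repr=False
    )  # locus -> species -> (ancestor codes, gap mask); used to plant hybrids

    def individuals_with_role(self, kind: str) -> List[str]:
        return [i for i, r in self.roles.items() if r.kind == kind]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ind, role in self.roles.items():
            rows.append(
                {
                    "individual": ind,
                    "true_species": self.true_species[ind],
                    "true_clade": self.true_clade[ind],
                    "role": role.kind,
                    "maternal": role.maternal,
                    "paternal": role.paternal,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# substitution / indel machinery
# ---------------------------------------------------------------------------
_TS_PARTNER = np.array([2, 3, 0, 1])  # A<->G, C<->T
_TV_PARTNERS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])  # two transversions each


def _k80_probs(d: float, kappa: float) -> Tuple[float, float, float]:
    """(p_same, p_transition, p_each_transversion) after depth ``d``."""
    if d <= 0:
        return 1.0, 0.0, 0.0
    beta_t = d / (kappa + 2.0)
    alpha_t = kappa * beta_t
    e1 = np.exp(-4.0 * beta_t)
    e2 = np.exp(-2.0 * (alpha_t + beta_t))
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1  # each of the two transversion targets
    p_same = 1.0 - p_ts - 2.0 * p_tv
    return p_same, p_ts, p_tv


def _evolve_branch(
    rng: np.random.Generator,
    seq: np.ndarray,
    gaps: np.ndarray,
    depth: float,
    cfg: SimConfig,
) -> Tuple[np.ndarray, np.ndarray]:
    """Evolve one branch: substitutions, then inherited deletions."""
    L = seq.size
    p_same, p_ts, p_tv = _k80_probs(depth, cfg.kappa)
    u = rng.random(L)
    child = seq.copy()
    ts = (u >= p_same) & (u < p_same + p_ts)
    tv1 = (u >= p_same + p_ts) & (u < p_same + p_ts + p_tv)
    tv2 = u >= p_same + p_ts + p_tv
    child[ts] = _TS_PARTNER[seq[ts]]
    child[tv1] = _TV_PARTNERS[seq[tv1], 0]
    child[tv2] = _TV_PARTNERS[seq[tv2], 1]
    new_gaps = gaps.copy()
    n_events = rng.poisson(cfg.indel_rate * depth * L)
    for _ in range(n_events):
        start = int(rng.integers(0, L))
        length = int(rng.geometric(1.0 / cfg.mean_indel_length))
        new_gaps[start : start + length] = True
    return child, new_gaps


_CHARS = np.array(list("ACGT"))


def _to_string(seq: np.ndarray, gaps: np.ndarray) -> str:
    out = _CHARS[seq].copy()
    out[gaps] = "-"
    return "".join(out)


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------
OUTGROUP_SPECIES = "outgroup_sp"
OUTGROUP_CLADE = "outgroup"


def _species_structure(cfg: SimConfig, rng: np.random.Generator):
    """Draw species names, clade membership and individual counts."""
    clades = [f"clade{c+1}" for c in range(cfg.n_clades)]
    species: Dict[str, str] = {}
    individuals: Dict[str, List[str]] = {}
    lo, hi = cfg.individuals_per_species
    for c, clade in enumerate(clades):
        for s in range(cfg.species_per_clade):
            sp = f"sp_c{c+1}_{s+1}"
            species[sp] = clade
            n_ind = int(rng.integers(lo, hi + 1))
            individuals[sp] = [f"{sp}_i{k+1}" for k in range(n_ind)]
    return clades, species, individuals


def simulate_library(cfg: SimConfig) -> Tuple[ReferenceLibrary, SimTruth]:
    """Simulate a two-genome reference library plus its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    clades, species_clade, individuals = _species_structure(cfg, rng)
    species_list = list(species_clade)

    # --- choose planted hybrids -----------------------------------------
    hybrid_specs: List[Tuple[str, str, str]] = []  # (id, maternal, paternal)
    for h in range(cfg.n_hybrids):
        while True:
            maternal, paternal = rng.choice(species_list, size=2, replace=False)
            if species_clade[maternal] != species_clade[paternal]:
                break
        hybrid_specs.append((f"hybrid_{h+1}", str(maternal), str(paternal)))

    # --- choose planted mislabels ----------------------------------------
    mislabel_specs: List[Tuple[str, str, str]] = []  # (id, true_species, nominal)
    for m in range(cfg.n_mislabels):
        while True:
            true_sp, nominal_sp = rng.choice(species_list, size=2, replace=False)
            if species_clade[true_sp] != species_clade[nominal_sp]:
                break
        mislabel_specs.append((f"{true_sp}_x{m+1}", str(true_sp), str(nominal_sp)))

    # --- per-genome tip memberships ---------------------------------------
    # lineage_members[genome][species] -> tip ids evolving on that lineage
    lineage_members: Dict[str, Dict[str, List[str]]] = {
        "cpDNA": {sp: list(inds) for sp, inds in individuals.items()},
        "nuclear": {sp: list(inds) for sp, inds in individuals.items()},
    }
    for hid, maternal, paternal in hybrid_specs:
        lineage_members["cpDNA"][maternal].append(hid)
        lineage_members["nuclear"][paternal].append(hid)
    for mid, true_sp, _nominal in mislabel_specs:
        lineage_members["cpDNA"][true_sp].append(mid)
        lineage_members["nuclear"][true_sp].append(mid)

    # --- evolve each locus -------------------------------------------------
    alignments: List[Alignment] = []
    ancestors: Dict[str, Dict[str, Tuple[np.ndarray, np.ndarray]]] = {}
    for locus, L, genome in zip(cfg.locus_names, cfg.locus_lengths, cfg.partition_labels):
        rows: Dict[str, str] = {}
        anc: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        root_seq = rng.integers(0, 4, size=L).astype(np.int64)
        root_gaps = np.zeros(L, dtype=bool)
        if cfg.include_outgroup:
            og_seq, og_gaps = _evolve_branch(rng, root_seq, root_gaps, cfg.depth_outgroup, cfg)
            rows["outgroup_1"] = _to_string(og_seq, og_gaps)
        in_seq, in_gaps = _evolve_branch(
            rng, root_seq, root_gaps, cfg.depth_outgroup - cfg.depth_clade, cfg
        )
        for clade in clades:
            c_seq, c_gaps = _evolve_branch(
                rng, in_seq, in_gaps, cfg.depth_clade - cfg.depth_species, cfg
            )
            for sp in [s for s in species_list if species_clade[s] == clade]:
                s_seq, s_gaps = _evolve_branch(
                    rng, c_seq, c_gaps, cfg.depth_species - cfg.depth_intra, cfg
                )
                anc[sp] = (s_seq, s_gaps)
                for tip in lineage_members[genome][sp]:
                    t_seq, t_gaps = _evolve_branch(rng, s_seq, s_gaps, cfg.depth_intra, cfg)
                    rows[tip] = _to_string(t_seq, t_gaps)
        ancestors[locus] = anc
        # fixed row order: outgroup, then normal/mislabel/hybrid tips sorted
        ordered = {}
        for tip in sorted(rows):
            ordered[tip] = rows[tip]
        alignments.append(Alignment(locus, ordered))

    # --- bookkeeping ---------------------------------------------------------
    entries: Dict[str, Tuple[str, str]] = {}
    roles: Dict[str, Role] = {}
    true_species: Dict[str, str] = {}
    true_clade: Dict[str, str] = {}
    outgroup: Set[str] = set()
    if cfg.include_outgroup:
        entries["outgroup_1"] = (OUTGROUP_SPECIES, OUTGROUP_CLADE)
        outgroup.add("outgroup_1")
    for sp, inds in individuals.items():
        for ind in inds:
            entries[ind] = (sp, species_clade[sp])
            roles[ind] = Role(kind="normal")
            true_species[ind] = sp
            true_clade[ind] = species_clade[sp]
    for hid, maternal, paternal in hybrid_specs:
        entries[hid] = (maternal, species_clade[maternal])  # nominal: maternal parent
        roles[hid] = Role(kind="hybrid", maternal=maternal, paternal=paternal)
        true_species[hid] = maternal
        true_clade[hid] = species_clade[maternal]
    for mid, true_sp, nominal in mislabel_specs:
        entries[mid] = (nominal, species_clade[nominal])
        roles[mid] = Role(kind="mislabeled", true_species=true_sp)
        true_species[mid] = true_sp
        true_clade[mid] = species_clade[true_sp]

    sp_map = SpeciesMap(entries, outgroup=outgroup)
    library = ReferenceLibrary(
        alignments, sp_map, dict(zip(cfg.locus_names, cfg.partition_labels))
    )
    truth = SimTruth(
        roles=roles,
        true_species=true_species,
        true_clade=true_clade,
        species_trees={g: _structure_newick(cfg, lineage_members[g]) for g in ("cpDNA", "nuclear")},
        config=cfg,
        ancestors=ancestors,
    )
    return library, truth


def _structure_newick(cfg: SimConfig, members: Dict[str, List[str]]) -> str:
    """Newick of the generating (ultrametric, star-radiation) history."""
    clade_parts = {}
    for sp, tips in members.items():
        tip_str = ",".join(f"{t}:{cfg.depth_intra}" for t in tips)
        sp_str = f"({tip_str}):{cfg.depth_species - cfg.depth_intra}"
        clade_parts.setdefault(sp.split("_")[1], []).append(sp_str)
    clades = ",".join(
        f"({','.join(parts)}):{cfg.depth_clade - cfg.depth_species}"
        for _, parts in sorted(clade_parts.items())
    )
    ingroup = f"({clades}):{cfg.depth_outgroup - cfg.depth_clade}"
    if cfg.include_outgroup:
        return f"({ingroup},outgroup_1:{cfg.depth_outgroup});"
    return f"({ingroup});"


def plant_hybrid(
    library: ReferenceLibrary,
    truth: SimTruth,
    maternal: str,
    paternal: str,
    seed: int,
    allow_same_clade: bool = False,
) -> Tuple[ReferenceLibrary, SimTruth]:
    """Append one hybrid individual to an existing simulated library.

    Its chloroplast loci descend from the maternal species' stored lineage
    ancestor and the nuclear locus from the paternal one; the nominal
    label is the maternal species.
    """
    sp_map = library.species_map
    for sp in (maternal, paternal):
        if sp not in sp_map.species:
            raise ValueError(f"unknown species '{sp}'")
    if maternal == paternal:
        raise ValueError("self-cross: maternal and paternal species are identical")
    if not allow_same_clade and sp_map.clade_of_species(maternal) == sp_map.clade_of_species(
        paternal
    ):
        raise ValueError(
            "maternal and paternal species are in the same clade "
            "(pass allow_same_clade=True to permit)"
        )
    cfg = truth.config
    rng = np.random.default_rng(seed)
    existing = {i for i in library.individuals if i.startswith("hybrid_")}
    hid = f"hybrid_{len(existing) + 1}"
    alignments = []
    for aln, genome in zip(library.alignments, (library.partition_labels[l] for l in library.loci)):
        parent_sp = maternal if genome == "cpDNA" else paternal
        anc_seq, anc_gaps = truth.ancestors[aln.locus_name][parent_sp]
        t_seq, t_gaps = _evolve_branch(rng, anc_seq, anc_gaps, cfg.depth_intra, cfg)
        alignments.append(aln.with_row(hid, _to_string(t_seq, t_gaps)))
    new_map = sp_map.with_entry(hid, maternal, sp_map.clade_of_species(maternal))
    new_lib = ReferenceLibrary(alignments, new_map, dict(library.partition_labels))
    new_truth = SimTruth(
        roles={**truth.roles, hid: Role(kind="hybrid", maternal=maternal, paternal=paternal)},
        true_species={**truth.true_species, hid: maternal},
        true_clade={**truth.true_clade, hid: sp_map.clade_of_species(maternal)},
        species_trees=dict(truth.species_trees),
        config=cfg,
        ancestors=truth.ancestors,
    )
    return new_lib, new_truth


# ---------------------------------------------------------------------------
# truth evaluation
# ---------------------------------------------------------------------------
def truth_eval(report, truth: SimTruth):
    """Confusion table of verdicts/decisions against the planted truth.

    Accepts either an incongruence report (verdict per individual) or an
    iterable of identification results.  Returns ``(confusion, metrics)``
    where ``confusion`` is a pandas DataFrame (truth role x outcome) and
    ``metrics`` a dict of sensitivities/false-positive rates.
    """
    from .identify import IdentificationResult, IncongruenceReport

    if isinstance(report, IncongruenceReport):
        verdicts = report.verdicts()
        unknown = set(verdicts) - set(truth.roles)
        if unknown:
            raise ValueError(f"verdicts for individuals not in truth: {sorted(unknown)}")
        rows = []
        for ind, verdict in verdicts.items():
            rows.append({"role": truth.roles[ind].kind, "outcome": verdict})
        df = pd.DataFrame(rows)
        confusion = pd.crosstab(df["role"], df["outcome"])
        metrics: Dict[str, float] = {}
        n_hyb = (df["role"] == "hybrid").sum()
        n_mis = (df["role"] == "mislabeled").sum()
        n_norm = (df["role"] == "normal").sum()
        if n_hyb:
            metrics["hybrid_sensitivity"] = float(
                ((df["role"] == "hybrid") & (df["outcome"] == "putative_hybrid")).sum() / n_hyb
            )
        if n_mis:
            metrics["mislabel_sensitivity"] = float(
                (
                    (df["role"] == "mislabeled")
                    & (df["outcome"] == "suspected_misidentification")
                ).sum()
                / n_mis
            )
        if n_norm:
            metrics["false_positive_rate"] = float(
                ((df["role"] == "normal") & (df["outcome"].isin(
                    ["putative_hybrid", "suspected_misidentification"]
                ))).sum()
                / n_norm
            )
        return confusion, metrics

    # identification results
    results = list(report)
    if not all(isinstance(r, IdentificationResult) for r in results):
        raise TypeError("expected an IncongruenceReport or IdentificationResult iterable")
    rows = []
    for r in results:
        if r.query_id not in truth.true_species:
            raise ValueError(f"query '{r.query_id}' not in truth")
        true_sp = truth.true_species[r.query_id]
        if r.decision == "identified":
            outcome = "correct" if r.step2_species == true_sp else "wrong_species"
        else:
            outcome = r.decision
        rows.append({"role": "query", "outcome": outcome, "true_species": true_sp})
    df = pd.DataFrame(rows)
    confusion = pd.crosstab(df["role"], df["outcome"])
    n = len(df)
    metrics = {
        "identified_correct_rate": float((df["outcome"] == "correct").sum() / n),
        "wrong_species_count": int((df["outcome"] == "wrong_species").sum()),
    }
    return confusion, metrics
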