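# Methods

`cladegap` implements distance- and tree-based species identification for a
large, incompletely sampled genus surveyed with multi-locus DNA barcodes
from two genomes (chloroplast and nuclear). This note documents the models,
the procedures, the tunable parameters, and the design choices made where
the design was genuinely open.

## The problem setting

A reference library holds pre-aligned sequences for a handful of loci (e.g.
two chloroplast regions and one single-copy nuclear gene), one row per
voucher individual, with a table mapping each individual to a species and
each species to one of the genus's major evolutionary clades. Sampling is
deliberately incomplete: only representative species of each clade, with
dense sampling limited to a few target species and their closest relatives.
The questions the pipeline answers are (1) can a focal species be told
apart from its closest relatives (a *target-specific barcode gap*), (2) can
an unknown query be assigned first to a clade and then to a species (the
*two-step identification*), and (3) do any individuals show conflicting
placements between the maternally inherited chloroplast loci and the
biparentally inherited nuclear locus, indicating hybrids or
misidentified vouchers.

## Distances

Pairwise distances use the Kimura two-parameter model. Over the sites
shared by a pair (both states in `{A,C,G,T}`), with transition proportion
`P` and transversion proportion `Q`:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Pairs where either logarithm argument is non-positive are *saturated* and
propagate as NA rather than a capped value; tree building refuses matrices
containing NA and tells the user to change the deletion policy or prune.
The default missing-data policy is *pairwise* deletion (per-pair shared
sites); *complete* deletion (drop every column containing any gap/missing
state) is available, and the two coincide on gapless data. Pairwise is the
default because a multi-genus matrix with patchy indels loses most of its
columns under complete deletion. An uncorrected p-distance is available
everywhere the K2P model is.

## Alignment statistics and indel coding

Per-locus summaries report the ungapped length range, aligned length,
variable and parsimony-informative column counts with percentages (rounded
half-up to two decimals, the convention of published character tables), and
mean pairwise divergence Pi (the mean off-diagonal entry of the distance
matrix; K2P by default, p-distance optionally). Column variability ignores
gaps and missing states, so indel signal lives exclusively in the coded gap
characters.

Gaps are recoded by *simple indel coding*: every distinct maximal gap run
becomes one binary presence/absence character; a sequence whose own gap
strictly contains a character's range is scored `?` (its state cannot be
observed inside the longer deletion). Terminal gap runs are coded like
internal ones by default because the simulator produces genuine terminal
deletions; an `ignore_terminal_gaps` switch exists for data where terminal
gaps are ragged-end artifacts.

## Trees

Neighbor-joining (Saitou–Nei agglomeration with the Studier–Keppler
Q-criterion) with two reproducibility rules: Q-ties are broken by the
lexicographically smallest tip label contained in each candidate cluster
(deterministic and invariant to input row order), and negative branch-length
estimates are clamped to zero with the deficit moved to the sibling branch,
preserving path lengths. Internal edges of exactly zero length are
collapsed into polytomies, so uninformative data yield stars instead of
arbitrary caterpillars. NJ is exact on additive matrices; the test suite
verifies topology and path-length recovery to 1e-9 on hundreds of random
trees and cross-checks split sets against scikit-bio's independent NJ.

Bootstrap supports resample aligned columns with replacement. A resample is
represented as a vector of column multiplicities, so a batch of replicate
distance matrices reduces to three matrix products over precomputed
per-pair, per-column transition/transversion/shared indicators — this is
what makes hundred-replicate bootstraps on ~80-tip libraries cheap.
Supports are integer percents of successful replicates containing each
internal split of the reference tree; replicates with saturated pairs are
skipped and counted, with a warning above 10%. Supports are written as
Newick internal-node labels and carried across rerooting by split identity.

Fitch small-parsimony scoring of a fixed topology handles polytomies
exactly (Hartigan's generalisation); gaps and missing states are fully
ambiguous and contribute no cost. Binary indel characters can be appended
so their changes add to the score. Tree *search* is out of scope: partition
trees in the incongruence screen are bootstrapped NJ trees.

## Barcode-gap tests

The all-species report classifies every pair as intra- or interspecific and
summarises overlap as the fraction of interspecific distances at or below
the maximum intraspecific distance. The target-specific variant compares
the focal species' maximum intraspecific distance only against its
distances to its closest relatives (`gap_exists ⇔ min_inter > max_intra`);
distances among the relatives themselves are ignored. In auto mode the
relatives are the k species (default 2) with the smallest *mean*
interspecific distance to the target — mean rather than minimum so one
aberrant individual cannot decide the set. Histograms use a default bin
width of 0.002 distance units (configurable).

PCA of the distance matrix treats the rows of the symmetric matrix as
observations and the columns as variables (centred, covariance
eigendecomposition, scores = projections) — an ordination of distance
*profiles*, not principal coordinates of the distances. A PCoA alternative
is provided and documented as a different method.

## Incongruence screening

Both genome partitions get a bootstrapped, outgroup-rooted NJ tree. Each
ingroup individual is assigned, per tree, to the smallest well-supported
clade (support ≥ 75% by default) containing at least one other non-outgroup
individual; the assignment's species and clade are the strict *majority*
labels of those co-members. Majority rather than unanimity matters: a
single hybrid or mislabelled voucher inside an otherwise clean species
cluster would otherwise veto the assignment of every innocent neighbour.

Verdicts: **concordant** when both genomes place the individual in its
nominal clade (and species where resolvable); **putative hybrid** when the
two genomes place it in *different clades*, both with support — the
chloroplast side names the maternal parent, the nuclear side the paternal;
**suspected misidentification** when the genomes agree with each other but
contradict the nominal label (a foreign clade, or another species while the
nominal species' other individuals sit elsewhere); **unresolved**
otherwise. Species-level conflict between the genomes within one clade
stays unresolved deliberately — at that scale incomplete lineage sorting is
a plausible alternative to hybridisation, so the hybrid verdict demands
clade-level conflict. One known and accepted failure mode: when a
mislabelled voucher's true species has exactly one other sampled
individual, the two form a cluster with mixed labels and both are flagged —
the screen can only say that at least one of the pair is misidentified.

## Two-step identification

Step 1 (*clade barcoding*): the query is assigned to the clade with the
smallest mean combined-locus distance to its members; the margin to the
runner-up clade is reported, and an NJ placement cross-check flags a
conflict when the tree disagrees (or the margin is zero).

Step 2: the library is restricted to the assigned clade plus the outgroup,
a bootstrapped NJ tree is built, and the nearest species S (smallest mean
distance to the query) is tested. The decision is **identified** only when
all three hold:

1. S ∪ {query} is monophyletic with bootstrap support ≥ threshold
   (default 75%);
2. the target-specific barcode gap holds with the query counted among S's
   individuals;
3. *cohesion*: the gap is wider than the within-species spread it sits on,
   `min_inter > 2 · max_intra`.

The third condition is the package's own guard against a failure mode of
the raw gap comparison: when the query's true species is absent from the
library, the query attaches as a long-branch sister of a congener, and with
all between-species distances at a similar scale the raw
`min_inter > max_intra` comparison can pass by a sliver (a "gap" far
narrower than the intra spread it sits on). Requiring the gap width to
exceed `max_intra` is scale-invariant and parameter-free (it is the minimal
form of a cohesion multiple), keeps every true conspecific query in the
simulation study identified, and rejected every absent-species query over
100 seeded trials. A topological alternative (requiring that S's own
individuals not form a supported clade excluding the query) was tried and
rejected: among star-coalescing conspecifics, chance mutation-count
differences give the remaining-members-only clade high support in roughly
one case in eight, falsely vetoing true conspecifics.

Failing step 2 yields **clade_only** with an advisory to densify sampling
in the clade (more species/individuals) — identification under incomplete
sampling is explicitly a process of adding material until the query nests
exclusively within one species. A step-1 conflict yields **unresolved**
with the PCA export recommended for inspection.

## The simulator

`simulate_library` generates the study conditions every stochastic test
runs under. Structure: nine clades radiating from one point at depth
`D_clade = 0.08` expected substitutions/site, four species per clade
radiating at `D_sp = 0.03`, individuals star-coalescing at
`D_intra = 0.005`, and one outgroup individual at depth 0.16. Expected
pairwise divergences are therefore ~0.01 within species, ~0.06 within
clades and ~0.16 between clades. The number of individuals per species is
drawn uniformly from 1–3: real surveys of this kind sample most species
once or twice and only targets densely (70 individuals across 48 species is
typical), and 9 × 4 species at 1–3 individuals reproduces that library size
(~72 + outgroup).

Substitutions follow the two-parameter transition/transversion process with
ratio κ = 2, deliberately matching the K2P estimator so that distance
estimates are consistent with the simulation depths and parameter-recovery
tests are meaningful. Indels are *deletions only* (Poisson events at rate
0.02 per site per unit depth, geometric lengths with mean 3, inherited down
the tree), which keeps all sequences in shared coordinates — the pipeline
consumes pre-aligned data, so insertion events would only exercise an
aligner that is out of scope.

Planted anomalies: a *hybrid* is an extra individual whose chloroplast loci
evolve on one species' lineage (the maternal parent, which also supplies
the nominal label) and whose nuclear locus evolves on a species from a
different clade (the paternal parent). A *mislabel* is an extra individual
of one species carrying the nominal label of a species from another clade.
Defaults plant one of each per library. Within-species genealogies are
independent star coalescences per genome; full coalescent machinery is
deliberately avoided — the procedures under test use only the depth
hierarchy, not genealogy shape.

What the simulator does *not* emulate: rate heterogeneity across sites and
lineages, insertions and alignment error, recombination, incomplete lineage
sorting (within-clade gene-tree discordance), intra-individual variants, or
the heterogeneous per-species divergences of real genera. Passing the
simulation suite therefore shows the procedures are correct and well
calibrated under their own assumptions, not that real data meet those
assumptions.

## Problem sizes used by tests and the acceptance script

The stochastic test suite runs seeds 1–100 at the default depths with
50-replicate bootstraps for the partition trees and 100-replicate
bootstraps for step-2 identification; unit tests use smaller libraries with
300–600 bp loci. `scripts/acceptance.py` recomputes the headline quantities
with 25 libraries for the gap and screening properties, 20 identification
queries and 200 random additive matrices for NJ exactness. These sizes are
the package's chosen trade-off between Monte-Carlo error and runtime;
sensitivities and rates move by at most a few percentage points when the
replicate counts are doubled.

## Reanalysing the published Solanum-type datasets

The pipeline's inputs are plain aligned FASTA plus a TSV species map, so a
real survey is reproduced by downloading the study's GenBank accessions,
aligning each locus (e.g. with MAFFT; alignment itself is out of scope
here), writing the individual→species→clade table, and running `cladegap
stats`, `dist`, `boot`, `gap`, `incongruence` and `identify` exactly as in
the worked example. This workflow is optional and requires network access
to GenBank; no third-party sequence data ships with the package, and the
test suite covers the corresponding claims with the simulator instead.

## Known limitations

* Hybrid verdicts are *putative*: the screen cannot distinguish
  hybridisation from introgression or extreme lineage sorting; the verdict
  wording and the clade-level requirement reflect that.
* Clade assignment trusts the species map's clade labels; a library whose
  clades are not actually monophyletic will produce placement conflicts.
* The cohesion rule makes identification conservative when a species'
  within-species spread approaches half its distance to the closest
  relative; such cases return `clade_only` with the densify-sampling
  advisory rather than a risky species call.
* Saturated (NA) distances are not imputed; users must switch deletion
  policy or prune divergent taxa.
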