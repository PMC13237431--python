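# Methods

`hcarkit` implements the inference chain used to resolve the duplicative
history and functional assignment of a recently duplicated receptor family
— concretely, the primate HCAR2/HCAR3 hydroxycarboxylic acid receptors,
where apes carry independently duplicated copies and non-ape primates
retain the ancestral single-copy gene. This note records the models and
procedures, the parameters that matter, what the synthetic generator does
and does not emulate, and the numerical choices made where the design was
genuinely open.

## Coordinate frame

All residue positions are 1-based numbers on a single declared reference
sequence (human HCAR2 for the worked examples). Alignment columns where
the reference carries a gap are insertions relative to the reference and
have no position number: diagnostic analyses skip them, indel analyses
consume them. `X` means "unknown residue" and never matches any state.
This frame is a choice, not a fact of the alignment — the published
positions (27, 83, ..., 178) are interpreted as human-HCAR2 numbering,
which the package makes explicit and configurable via `reference_id`.

## Diagnostic (fingerprint) positions

A position is diagnostic between paralog groups A and B when, in strict
mode (default), every group-A sequence carries one residue, every group-B
sequence carries one *different* residue, and no gap or `X` occurs in
either group at that column. Relaxed mode collects per-group state sets
and requires only disjointness (gaps/`X` stripped). Strictness is the
operational reading of "consistently and unambiguously distinguishing";
nothing weaker guarantees that a single query residue identifies a group.

Classification of a query scores each profile position as `MATCH_A`,
`MATCH_B`, `NEITHER`, or — for gap/`X` — `AMBIGUOUS`; unknowable is
deliberately distinct from mismatching. The default verdict rule is a
majority vote gated on pocket purity: a query is `A_LIKE` only if A wins
the overall count *and* no pocket-proximal position matches B
(symmetrically for `B_LIKE`); ties and pocket conflicts give `MIXED`.
The gate encodes the structural argument that mismatches far from the
ligand-binding pocket are unlikely to change ligand interactions, so only
pocket-proximal conflicts should block a functional assignment. The rule
is a plain function and can be replaced by the caller.

Discovery warns below four sequences per group: with very small groups,
within-group invariance is weakly constrained and sample-level false
positives appear (see the simulator discussion below).

## Indels and identity

Indel features are maximal runs of reference-gap columns that a record
fills (insertions) or of record-gaps at reference columns (deletions).
Records sharing *exactly* the same block coordinates are merged into one
feature with a carrier set; near-identical blocks stay separate — calls
remain auditable at the cost of occasional duplicate-looking rows.
`min_length` defaults to 3 to suppress single-column alignment noise; the
features of interest here (a 24-residue insertion, an 11-residue
deletion) are robust to this.

Percent identity is reported under an explicit denominator convention,
because published identity values rarely state one:

* `UNGAPPED_COLUMNS` (default) — columns where both sequences have residues;
* `SHORTER_SEQ` — same numerator over the shorter ungapped length;
* `ALL_COLUMNS` — columns where at least one sequence has a residue.

Mutual-gap columns are excluded even under `ALL_COLUMNS`: they say nothing
about either sequence, and their exclusion keeps self-identity at exactly
100 under every convention (an invariant the test suite enforces).
Rounding happens only at display.

## Reconciliation

`lca_reconcile` is the standard parsimony LCA mapping: each gene leaf maps
to its species; each internal gene node maps to the species-tree LCA of
its children's images; a node is a duplication iff its image equals the
image of at least one child. Losses are counted per gene-tree edge
(u, v): with `d` species-tree edges between the images of u and v, the
edge implies `d − 1` losses below a speciation and `d` below a
duplication; each loss is placed on the concrete species branch whose
lineage went missing. Both counts are cross-checked in the tests against
an independent oracle that maps nodes by ancestor-leafset containment and
enumerates loss paths explicitly.

Gene trees must be rooted and binary. Polytomies are rejected unless
`allow_polytomies=True`, in which case they are resolved (arbitrarily but
deterministically) before reconciliation; an outgroup rooting helper
exists but rooting is never applied silently. Support values are carried
through parsing and ignored by reconciliation.

`compare_scenarios` turns a verbal argument — "one ancestral duplication"
versus "several independent ones" — into a duplication/loss cost
comparison with configurable weights (default 1:1) and explicit tie
reporting. On the transcribed primate topologies the observed-style tree
costs 4 duplications + 2 losses and the single-ancestral-duplication
alternative 1 duplication + 5 losses: a tie at equal weights, which is
itself informative — the parsimony comparison only separates the
hypotheses through the weights, whereas the sequence-level evidence (the
gene tree itself) is what rejects the single-duplication topology. The
alternative's loss count depends on treating the non-ape single-copy
genes as members of the HCAR2 clade, which is what the single-duplication
proposal implied; on an ape-only tree that scenario would need just one
loss and the comparison would be vacuous.

`species_clustering_test` checks the gene-conversion expectation: under
within-genome homogenization, a species' paralogs should form a
species-specific clade. Species with one copy report "not applicable"
rather than false. Note the test is per species, not per event: a
within-species duplication (the Hoolock pair here) legitimately clusters
and is not evidence of conversion.

## Structural comparison

Superposition is the Kabsch algorithm: SVD of the cross-covariance of
centered point sets, with the smallest singular vector flipped when the
naive solution is a reflection, so the rotation is always proper. Atoms
are paired by residue-number intersection; inside an explicitly requested
range, *missing residues are an error*, not silently dropped — fixed
ranges such as 8–302 and 17–300 exist precisely to keep n identical
across models, and silent dropping would break the pairing of the
downstream test. The paired t-test is the classical closed form on the
per-model RMSD differences (two-tailed p from Student's t with n − 1 df);
zero-variance differences are reported with an explicit flag rather than
NaN. PDB Cα extraction reads fixed-column ATOM records, takes altloc
`A`-or-blank only, and treats a duplicate Cα without altloc as a format
error.

The published RMSD numbers (0.801 ± 0.173 Å vs 1.336 ± 0.082 Å,
P = 0.0003) derive from deep-learning structure models that this package
does not regenerate; the structural module's guarantees are therefore
oracle-based (quaternion-method agreement to 1e-9 Å; reference t-test
agreement to 1e-10) plus a Monte-Carlo power calibration on simulated
coordinates (below).

## The synthetic generator

`simulate_family` evolves a protein family along a species tree with
duplication events *placed* on named branches. The stated world:

* Background sites substitute along a branch of length `t` with
  probability `1 − exp(−rate·t)` to a uniformly chosen different residue.
  This is deliberately minimal — no empirical exchangeability matrix, no
  rate heterogeneity, no site-specific constraints. It is sufficient to
  exercise discovery/reconciliation logic; it is not a biological model,
  and green tests on it establish correctness of the machinery, not
  realism of inference on real proteins.
* A designated set of D diagnostic sites is frozen except at
  state-switching duplications, where the derived daughter flips to a
  second global state set. Using one global derived state set means
  independently duplicated copies share the derived profile — exactly the
  situation the classifier must handle in this family, where independent
  duplicates converge on the same functional dichotomy. A duplication
  nested *inside* an already-derived lineage sets `switches_states=False`
  so both daughters stay in their parent's group (flipping again would
  invent a third history no lineage here has).
* Indels and the preset's loss are placed deterministically
  (`IndelSpec`, `forced_losses`), not evolved: the analyses treat them as
  discrete lineage-specific features, and a stochastic indel process
  would only blur the ground truth. A stochastic per-branch
  `loss_probability` exists for post-duplication lineages.
* One `numpy` Generator seeded once drives every draw; identical seeds
  give byte-identical FASTA/Newick/JSON output (tested).

`simulate_hcar_like` is the preset emulating the family's qualitative
history on a 15-species primate-like tree: independent duplications in
the hominine ancestor, the orangutan ancestor and the gibbon ancestor, a
nested duplication in the Hoolock lineage, loss of the ancestral-like
gibbon copy in Hoolock, D = 12 diagnostic sites on a 300-residue protein,
and a 24-residue insertion in the hominine derived-copy subclade. Branch
lengths are a few percent substitutions per site (great-ape scale);
`background_rate_scale` defaults to 1.0 so lengths are used as-is.

For profile building on simulated data, *all* duplicated-lineage copies
carry their true group label and single-copy species are queries
(`profile_labels`). With groups spanning three independent duplications, a
background site can only masquerade as diagnostic through parallel
identical fixation on all derived stems — effectively impossible — so
recall and false-positive rate are clean measures of the discovery
machinery. Had the groups been a single young clade pair (as in the real
profile's four hominine species), stem substitutions would create genuine
sample-level diagnostics at a rate of order 1% of sites, which is a
property of small samples, not a bug; the discovery warning threshold
reflects this.

`simulate_coord_pairs` builds a self-avoiding random Cα chain (3.8 Å
steps, 3 Å exclusion) of 300 residues — receptor-sized, matching the
~295-residue superposition ranges used for real models — and, per model
index, one copy perturbed with per-coordinate Gaussian noise σ_A = 0.8 Å
and one with σ_B = 1.3 Å, each under its own random rigid motion. After
superposition the expected RMSD is ≈ σ√3 (slightly shrunk because the
fitted transform absorbs six degrees of freedom). The 0.8 vs 1.3
contrast mirrors the magnitude of the published two-group comparison;
with n = 6 paired models the t-test detects it in ≥ 95% of 200 seeds
(calibrated in the acceptance suite).

## Worked-example panel

`hcarkit.examples` constructs a synthetic stand-in for the real sequence
panel: every residue state and per-lineage match count that the source
analysis states is honoured (12 diagnostic positions with V/A at 27 and
G/T at 173 and leucine as the derived state at 167; 18 human
HCAR2-vs-HCAR3 differences; the 24-residue insertion absent in gorilla;
the 11-residue colobine deletion; the orangutan 10-of-12 pattern; the
gibbon 11/1 and 8/3/1 patterns; the tarsier 9/2 with serine at 173; the
New World monkey neither-states at 27 and 173), while the background
sequence and all unstated residues are invented. Tests on this panel
verify that the machinery reproduces the published counts *given* those
states; they cannot and do not validate the states themselves. Where the
source gives only counts (e.g. "three positions match"), the panel
assigns them to arbitrary positions consistent with every stated count.

## Numerical and degenerate-input choices

* Kabsch requires ≥ 3 paired atoms and non-collinear geometry (rank ≥ 2
  after centering, tolerance 1e-8); otherwise `GeometryError`.
* RMSD equality with the quaternion oracle is asserted at 1e-9 Å;
  rotation orthonormality at 1e-10.
* The t-test with zero-variance differences returns t = ±inf, p = 0 (or
  t = 0, p = 1 for identical vectors) with `zero_variance=True`.
* Identity percentages are stored as exact ratios; rounding only at
  display (2 decimals in TSV).
* Scenario cost ties report all minimal-cost scenarios; `preferred` is
  the first in input order, never a silent tie-break.
* Empty diagnostic profiles are legal discovery output but illegal
  classification input.
* The pipeline report contains no timestamps; provenance is the package
  version plus a SHA-256 hash of the config (output directory excluded),
  so identical runs are byte-identical.

## Known limitations

* The substitution model is uniform-replacement; do not use the simulator
  to benchmark statistical power on real proteins.
* Reconciliation is unweighted-parsimony LCA; it has no model of
  incomplete lineage sorting, and a duplication/loss history that mimics
  ILS will be mis-attributed.
* The gene-conversion check is topological only; partial-tract conversion
  that does not change the topology is invisible to it.
* Carrier merging of indels is exact-coordinate; alignment jitter splits
  a single biological event into multiple reported features.
* The identity conventions cover the common denominators but cannot
  recover which convention an external publication used; reproducing a
  published identity value requires trying the conventions explicitly.
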