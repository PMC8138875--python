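# Methods

## Model and procedure

### Dollo parsimony and LECA calling

The pipeline treats each orthologous group (OG) as a binary phylogenetic
profile over the leaves of a rooted species tree. Under Dollo
parsimony a gene is gained exactly once; every absence is explained by
losses, minimized in number. For LECA OGs the gain is fixed at the root
rather than at the most recent common ancestor of the present species:
the supergroup criterion already guarantees presence deep on both sides
of the root, and losses are counted from LECA to the extant species.
With gain at the root the minimum-loss reconstruction is unique and
local: an internal node is present iff any descendant leaf is present,
and an independent loss is an edge from a present parent into an
entirely absent subtree. The rule extends verbatim to multifurcations
(each child edge into an absent subtree is one loss), so unresolved
trees need no binarization. The implementation is verified against an
exhaustive search over all loss-edge subsets for every tree shape with
up to six leaves and every non-empty presence pattern.

An OG is a LECA OG when its members span at least `min_supergroups`
supergroups (default 3; 2 and 4 supported as the less/more stringent
variants) covering both the Amorphae and the Diaphoretickes side of the
eukaryotic root. The count of LECA OGs is non-increasing in
`min_supergroups` by construction; the suite asserts this on simulated
orthologies. Loss distributions of two methods are compared with the
tie-corrected Kruskal–Wallis H test (chi-square p-value, via scipy).

### Profile distances

Thirteen measures are supported. Set-based distances go through
scipy.spatial.distance; `kulsinski` — (ntf + nft − ntt + n)/(ntf + nft + n) —
and `sokalmichener` — 2(ntf + nft)/(n + ntf + nft) — are computed
directly from the 2×2 contingency counts (ntt/ntf/nft/nff), using the
classic dissimilarity formulas, since measure dialects vary between
libraries; the formulas above are the authoritative definition for this
package. Rank correlations (Kendall tau-b, Spearman) use midranks and
are converted to distances by (1 − C)/2, so anticorrelated profiles are
at distance 1 and identical non-constant profiles at 0. Unbounded
distances (cityblock, euclidean, yule) are divided by the maximum raw
value observed in the analyzed pair set — normalization is
dataset-relative, so the pooled positive+negative set of each
experiment is normalized together and the maximum is recorded in the
output. Pairs for which a measure is undefined (a constant profile
under a rank correlation; yule's vanishing denominator) are dropped
with a logged count rather than given an arbitrary value, to avoid
injecting fabricated distances into ROC analysis. The cosine distance
is the default for downstream analyses, being the best-performing
measure for co-occurrence prediction.

### Interaction sets and ROC

Positives are interaction records with ≥ `min_pubs` (default 5)
supporting publications. Pseudo-negatives pair proteins that each
participate in at least one well-supported interaction but have no
record with each other at any support level; the candidate space is
subsampled uniformly (seeded) above `max_pairs` (default 100 000). The
alternative reading of "well-studied" — at least `min_pubs` distinct
interaction partners rather than one interaction with `min_pubs`
publications — is available through the `well_studied="partners"`
switch of the pseudo-negative builder; the publication-count reading is
the default. Protein pairs map to OG pairs through a
reference-species gene index; pairs falling in the same OG are excluded
(their distance is 0 by construction) and counted. Reference genes hit
by several OGs (possible with profile-search annotation) resolve
deterministically to the largest OG, ties lexicographic.

AUC is computed as the Mann–Whitney probability with the ½-weight tie
convention; the test suite confirms it equals the trapezoidal area
under the threshold-swept ROC curve to 1e-10. The 95% CI is a
percentile bootstrap (default n = 1000) resampling positives and
negatives independently; the reported interval is widened, if
necessary, to contain the point estimate.

### Cluster-overlap scores

ARS is the standard adjusted Rand index from the contingency table.
When the maximum index equals the expected index (both partitions
trivial) the score is defined as 1 for identical partitions and 0
otherwise, with a degenerate flag. FGKCS is implemented as the grand
mean, over reference clusters, of the best F-score (harmonic mean of
member precision and recall) over predicted clusters; the definition is
isolated behind the `score_type` interface so a stricter
clique-matching variant can be swapped in. Comparisons use the
intersection universe — genes placed in a LECA, non-singleton OG by
*both* inputs — because pair-counting scores over-penalize singletons
and coverage is already measured separately by the assignment
percentage; drop counts are reported, and a union universe can be
obtained by restricting partitions manually.

Shuffle calibration reassigns a chosen percentage of genes to uniformly
random existing clusters (possibly their own, keeping the cluster count
fixed) and reports mean ± sd of both scores over replicates; at 0% both
scores are exactly 1, and at 100% the ARS is at chance level.

Splitting diagnostics follow the overlap-count matrix between reference
(manual) and inferred OGs: per row (reference OG), sequences outside
the largest-overlap inferred OG are oversplit; per column, sequences
outside the largest-overlap reference OG are undersplit; percentages
pool numerators and denominators over rows (columns), and the
assignment percentage divides all overlap counts by the total reference
sequence count. The packaged curated-set registry records the
complex-level bookkeeping of the reference collection (26
intraflagellar-transport, 91 kinetochore and 8 TBP-associated-factor
OGs, 125 in total) with synthetic placeholder identifiers, since the
member lists themselves are not distributed with the package.

## Synthetic data: what it emulates and what it does not

The generator mirrors the evaluated inference problem: a balanced
rooted tree whose first split separates the two sides, monophyletic
supergroups, families all present at the root, and irreversible loss
along edges — the exact generative counterpart of Dollo parsimony, so
parsimony is consistent by construction and the estimated loss count is
a lower bound on the simulated event count (equality fails only when
independent losses cover all children of a present node and merge into
one inferred loss). Functional modules couple losses: on each edge a
module-level event (probability `p_loss · rho`) removes all surviving
members at once, while member-level events (probability
`p_loss · (1 − rho)`) strike singly. The designated reference species
is shielded from loss for module families along its root path — applied
during simulation, not post hoc, so recorded event counts stay
consistent with emitted patterns — guaranteeing that interaction pairs
can always be mapped to OGs.

Mock methods perturb the truth with four operators applied in order
(merge, split, drop, misassign), chosen to produce the characteristic
error regimes: merging causes undersplitting, splitting causes
oversplitting, dropping lowers assignment, misassignment degrades ARS
smoothly. Interaction tables contain all within-module pairs at 6
supporting publications and weakly supported (1–4) cross-module decoys.

Deliberately not emulated: sequence evolution, paralogy and duplication
histories (the main suspected source of real-method disagreement, left
as an extension point), gene gain after the root, regain/homoplasy,
realistic branch lengths, and prediction-induced false absences.
Passing tests therefore demonstrate correctness of the evaluation
machinery under the stated loss model, not robustness of any orthology
method to duplication-driven errors.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_supergroups` | 3 | supergroup threshold for the LECA call (2/4 = sensitivity variants) |
| `min_pubs` | 5 | publication support for a positive interaction |
| `max_pairs` | 100 000 | pseudo-negative subsample cap (the full candidate space is quadratic) |
| `measure` | cosine | profile distance for downstream analyses |
| `n_bootstrap` | 1000 | AUC bootstrap replicates |
| `p_loss` | 0.1 | per-edge, per-family loss probability |
| `rho` | 0.5 | fraction of loss pressure acting at module level (co-loss coupling) |
| `n_pub_positive` | 6 | support attached to simulated true interactions (above the positive filter) |

All randomness flows from one master seed through named substreams
(taxonomy, content, perturb, interactions), so stages regenerate
independently and the full pipeline is bit-reproducible under a fixed
seed (asserted by the suite at the file level, manifest timestamps
excluded).

## Numerical choices and degenerate inputs

* Loss counting requires at least one present leaf; all-absent profiles
  are rejected (they cannot be LECA OGs).
* Standard deviations of single-element summaries are reported as 0
  with a `sd_degenerate` flag.
* Constant-profile pairs under rank correlations and undefined yule
  pairs are dropped and counted, never imputed.
* ARI's degenerate denominator returns 1/0 by identity, flagged.
* Identical constant loss samples short-circuit the Kruskal–Wallis test
  to (H = 0, p = 1) where the rank formula is 0/0.
* Multi-OG reference genes resolve to the largest group, ties
  lexicographic by OG id; heatmap layout breaks ties by id — every
  ordering in the package is deterministic.

## Problem sizes

The shipped test-suite and acceptance-script scenarios use 12–24
species, 60–500 families and 5–10 bootstrap/replicate repetitions —
sizes at which every stochastic property (≥ 95% exact loss recovery at
`p_loss = 0.05`, ARS decay under perturbation, AUC gain from co-loss
coupling) is already stable across seeds while the full pipeline runs
in seconds. Larger studies only change runtime: all algorithms are
linear in families × edges except pseudo-negative enumeration
(quadratic in well-studied proteins, hence `max_pairs`).

## Known limitations

* FGKCS follows the best-match F interpretation described above; other
  clique-matching formulations exist and may score differently.
* The Dollo estimate is a lower bound in principle; at high loss rates
  nested/sibling losses are merged, and the package reports the
  parsimony value, not a corrected estimate.
* The union-universe variant of partition comparison must be composed
  by the caller; only the intersection policy is wired into the
  pipeline functions.
* The pseudo-negative construction cannot rule out unreported true
  interactions; it is a benchmark convention, not biological truth.
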