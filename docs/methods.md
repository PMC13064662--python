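# Methods

This note documents the models, rules and numerical choices behind each
stage of the pipeline, the parameters that matter, and what the
synthetic studies do and do not demonstrate.

## Curation model

**Record model.** An assay record is one measurement with provenance:
structure, assay kind (in vitro inhibition, in vitro efflux, in vivo
inhibition), measure (IC50 or Ki in µM, efflux ratio, digoxin AUC
ratio), optional probe substrate and cell line, and an `annotated` flag.
A record counts as annotated when the flag says so, or — if the column
is absent — when the metadata its assay kind requires is present (probe
substrate and cell line for inhibition, cell line for efflux).  The
exact metadata criteria are deliberately a configuration predicate, not
hard-coded, because they vary between source databases.

**Structure cleaning.** RDKit parses each structure; carbon-free
fragments made of ordinary organic elements and single-atom
alkali/alkaline-earth (and zinc) ions are stripped as pharmaceutical
counterions; any fragment carrying another metal rejects the whole
record as a metal complex; structures with no organic fragment are
rejected as inorganic.  The largest organic fragment is neutralized
(RDKit Uncharger) and canonicalized.  The canonical string is the
compound identity everywhere downstream.

**Label rules.** Ki values are first harmonized to the IC50 scale by
IC50 = 2·Ki (the competitive-inhibition boundary condition with
substrate concentration at Km).  In vitro inhibition bands:
IC50 ≤ 15 µM → strong, ≥ 50 µM → non-inhibitor, the open interval in
between → moderate (ambiguous).  The bands are closed at both published
boundaries.  Efflux: ER > 2 → substrate, else non-substrate.  In vivo:
digoxin AUC ratio ≥ 1.25 → inhibitor, < 1.125 → non-inhibitor, the gap
excluded.  Units are normalized to µM before thresholding when a units
column is present (nM ÷ 1000, mM × 1000).

**Trees and aggregation.** Inhibition records form three-level trees
(compound → probe substrate → cell line); efflux records form two-level
trees (compound → cell line).  Within each leaf, duplicate labels
collapse and conflicting leaves are dropped.  Aggregation runs bottom-up
with a voting rule applied at each internal node: if only strong and
moderate labels are present, the node is an inhibitor exactly when
strong labels strictly outnumber moderate ones (ties excluded — the
strict reading of "surpassed"); if only non-inhibitor labels are
present, the node is a non-inhibitor; any mixture is excluded.  At
internal levels an inhibitor verdict propagates as "strong"; excluded
children drop out of their parent's multiset (their records flow to the
noisy tier), and a node whose children are all excluded is excluded.
Efflux data receives no cross-level voting — only leaf-level dedupe —
because its experimental conditions are homogeneous; compounds whose
surviving cell-line labels disagree are excluded.  For the INH call,
in vivo evidence takes precedence over in vitro aggregation when both
exist (higher confidence wins); unanimous non-gap in vivo labels decide,
conflicts exclude.

**Noisy tier.** Every record that did not produce a refined label —
unannotated records, dropped leaves, ambiguous bands, in vivo gap
values, voting exclusions — contributes interaction evidence to the
noisy tier: strong/moderate/substrate/inhibitor(/gap) evidence marks the
compound an allocrite, exclusively-negative evidence a non-allocrite.
Moderate-only and gap-only compounds are allocrite evidence: a measured
mid-band potency is evidence of interaction, just not of tier-worthy
strength.  Compounds holding any refined label are finally removed from
the noisy tier, which makes the tiers disjoint by construction (and the
invariant is asserted on every output).

## Feature maps

The layout is learned from a reference descriptor matrix: descriptor
dissimilarity 1 − |Spearman ρ|, a 2D embedding (UMAP with a fixed seed
by default; classical Torgerson MDS as a fully deterministic,
eigendecomposition-based alternative with a sign convention for
reproducibility), then a one-to-one assignment of descriptors to lattice
cells solved as a linear assignment problem minimizing total squared
displacement between the rescaled embedding coordinates and cell
centers.  Bijectivity therefore holds by construction rather than by a
greedy tie-break.  Classical MDS is preferred for small descriptor sets
(< a few hundred), where UMAP's neighborhood graph is less meaningful;
the pipeline-level studies in this package use it for that reason.

Rendering standardizes each descriptor by median/IQR learned from the
reference matrix, clips at ±3 scaled units, and writes values to the
assigned cells (unoccupied cells are 0).  A `scaling="none"` mode makes
rendering an exact, invertible placement, used by the round-trip tests.
Failed or missing descriptor values are imputed by the reference median.

The default RDKit-backed registry (~400 descriptors: the standard 2D
descriptor list plus 2D autocorrelation) is binned into the 13
conventional category names by prefix rules.  The registry is pluggable
and intentionally makes no claim about any particular total count; the
published large-scale descriptor layouts can be loaded from the JSON
sidecar format instead of refit.

## Model and training

**Architecture.** The shared encoder is either a small CNN over feature
maps (valid 3×3 convolutions, optional max pooling, flatten, dense
projection to a latent vector) or an MLP over flat descriptor vectors.
Two parameter-disjoint MLP heads map the latent vector to a sigmoid
probability.  Defaults (two conv blocks of 8 and 16 channels, no
pooling, latent 32, head hidden 8, tanh activations) are small enough
for CPU training.  Max pooling is off by default: descriptor grids
carry cell-identity information (each cell is one named descriptor), and
pooling discards exactly that, which measurably hurt held-out
discrimination in the planted-signal studies.  tanh is the default
nonlinearity because it cannot die the way ReLU units can on this loss
surface and is smooth, which the exact second-order meta-gradients
appreciate; ReLU remains available.  There is no dropout or batch
normalization, so inference is deterministic by construction.

**Gradients.** All gradients come from a small reverse-mode autodiff
engine written for this package.  Its backward rules emit graph
operations, so differentiating a gradient (double backward) is exact —
that is what makes the full second-order meta-gradient available rather
than approximated.  Gradient correctness is pinned by finite-difference
tests at 1e−4 relative tolerance on every layer type.

**Stage I.** Each batch of size N (default 64) is half refined, half
noisy; per epoch the larger tier is cycled without replacement and the
smaller tier resampled.  The L task takes one inner gradient step of
size `meta_alpha` (default 0.05) on the refined half through (θ, φ_L),
then returns the gradient of the noisy-half loss at the adapted
parameters — applied to the originals in first-order (FOMAML) mode, or
differentiated through the inner step exactly in full mode.  First
order is the default: it is a factor ~2–3 cheaper and the standard
practical choice; full mode exists for exactness-sensitive work and for
verifying the first-order approximation.  The H task is the plain
refined-half gradient through φ_H.  The two θ-gradients are combined by
the closed-form two-task min-norm solution γ* = clip(((g_L−g_H)·g_L) /
‖g_H−g_L‖², 0, 1), re-expressed asymmetrically as g_H + β g_L with
β = (1−γ*)/γ* capped to [1e−3, 1e3] for degenerate γ*.  By default the
min-norm problem is solved on the flattened θ-gradients; a
representation-gradient mode (the cheaper upper-bound trick, balancing
gradients taken with respect to each task's encoder output at the
current parameters) is available for speed on larger encoders.  Head
gradients update their own heads unbalanced.  The outer optimizer is
Adam (lr 0.003 default; SGD available); all loops are seeded.

**Stage II.** Fine-tuning initializes from the pretrained {θ, φ_L} —
the L head is the one carried forward — and trains supervised on
refined data only, holding out a 20% validation split for early
stopping (patience 5, up to 30 epochs).  Stage I runs a fixed epoch
count (default 5) since it has no natural validation target; the count
is configurable.

**Benchmark presets.** The comparison/ablation suite maps each named
variant to a config: Vanilla PTM (supervised pretraining on the noisy
tier, then fine-tuning), Multi-task PTM (both tasks supervised — the
inner meta step vanishes), Meta PTM / MolMM w/o H (Stage I without the
supervised branch; these two names denote the same computation here,
kept separate because they answer different comparison questions),
CNN/MLP w/o pretraining, MLP with the full two-stage procedure, Mixed
(one supervised model on refined+noisy pooled labels), and inverse
(tier roles swapped in Stage I, Stage II unchanged).  The benchmark
harness trains every requested preset on identical stratified folds of
the refined set (noisy data is auxiliary training material in every
fold) and reports mean (sd) of AUC-ROC and accuracy over the k test
folds.

## Interpretation

Attributions are permutation-sampling Shapley values: features are
switched from a background reference to the molecule's values in random
orders, each feature credited with its average marginal effect on the
model output, averaged over permutations (default 4) and a fixed-seed
background subset (default up to 50 maps).  Marginal contributions
telescope, so per-molecule attributions sum to f(x) − mean_b f(b)
exactly — local accuracy holds at float precision, not just in
expectation — and for a linear model the estimator is exact with a
single permutation, which the tests exploit as a closed-form oracle.

The variant map adds, for each pixel pair within cutoff `c`, the
attribution difference scaled by 1/(α d²).  The pairwise terms are
antisymmetric, so the grid total is conserved (asserted to 1e−9).  On an
integer lattice d ≥ 1 for distinct pixels, so no small-distance
regularizer is needed.  Defaults α = 1, c = 2 lattice units; both are
exposed because they are genuinely free parameters of the analysis, and
this α is unrelated to the meta-learning step size despite the shared
letter in common notation.

Cluster seeds are local maxima of the variant map under weak
inequality, with ties resolved by plateau collapse: pixels of equal
value connected within the cutoff form a single candidate represented by
its row-major-first pixel.  (Plain row-major suppression without the
collapse lets a flat background seed spurious clusters; the plateau rule
gives one cluster per isolated peak, and exactly one seed — at the
origin — on a constant grid.)  Members are all pixels within the cutoff
of a seed, assigned to the nearest seed, sorted by variant value
descending, with an average-linkage dendrogram on lattice coordinates
per cluster.  Annotation attaches min–max-scaled relative coefficients
within each cluster (singleton or constant clusters map to 1 by
convention), and — when per-molecule features and attributions are
supplied — the Spearman ρ between feature and attribution, its sign
(p/n) and its mark (labeled above 0.8, asterisk above 0.9, strict
inequalities).  Aggregation across molecules supports both the signed
mean (direction) and the mean absolute value (intensity); both are kept
because they answer different questions about a cluster.

## Synthetic studies

The record generator plants a per-compound truth (inhibitor?,
substrate?) and draws records whose values fall in the correct band for
the truth, flipping the band with probability `conflict_rate` and
stripping metadata with probability `frac_missing_metadata`.  The
descriptor generator draws correlated Gaussian blocks (default block
size 8, within-block correlation 0.7) so layouts have real correlation
structure to embed, plants a class-conditional mean shift of
`effect_size` standard deviations on the first `signal_dims` columns,
and flips labels independently at `noisy_flip_rate` for the noisy copy.
Everything is reproducible from the spec seed.

The headline study uses 200 refined molecules, 2000 noisy molecules at
flip rate 0.3, effect size 1.0 over 10 signal dimensions, 16×16 grids,
and 400 held-out clean molecules, averaged over 5 seeds — sizes chosen
so the full three-model comparison runs in minutes on one CPU.  Under
these conditions the two-stage model reaches a mean held-out AUC near
80%, roughly ten points above both supervised training on the noisy
labels alone and the pooled "Mixed" baseline.

**What these fixtures do not show.** The planted signal is a Gaussian
mean shift with symmetric label noise — far simpler than real
structure–activity landscapes, where noise correlates with assay type
and chemistry, classes are imbalanced, and descriptors are heavy-tailed
and discrete.  Passing these studies demonstrates that the machinery is
correct and that the two-stage procedure extracts value from corrupted
auxiliary labels in a controlled setting; it does not certify
performance on real ABCB1 data, and no claim about published benchmark
figures on externally curated datasets is made or tested here.

## Known limitations

* The curation workflow exposes metadata criteria as predicates but
  ships only the presence-based default; source-specific criteria must
  be supplied by the user.
* The descriptor registry is a few hundred descriptors, not the
  thousands of a large pretrained layout; layouts of any size can be
  loaded from JSON.
* Training is single-process CPU numpy; it is sized for small grids and
  thousands of molecules, not for large-scale screening.
* Permutation Shapley costs O(pixels × permutations × background) model
  evaluations per molecule; for large grids reduce the background or
  permutation count.
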