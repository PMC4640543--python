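# Methods

`mvh` implements a Bayesian account of how a modality-independent,
part-based representation of a 3-D object can be inferred from visual
input, haptic input, or both, together with the similarity metrics used
to compare objects once representations are in hand.  This note records
the model, the numerical choices, and the design decisions taken where
the problem left the design open.

## The generative model

**Shape grammar.** An object is a derivation of the probabilistic
context-free grammar

    S -> P | P S | P S S | P S S S        (spatial skeleton)
    P -> P0 | P1 | ... | P8               (part identity)

The derivation's parse tree `T` is augmented into a *spatial tree* by
attaching a voxel coordinate to every non-root S node.  Space is carved
multi-resolution style: the root S node owns the whole workspace (edge
`w`, default 1.0) and sits at the origin; a child S node at tree depth
`d` is displaced from its parent by `v * w / 3^d` where `v` is one of
the 26 offsets `{-1,0,1}^3` minus `(0,0,0)` (the center offset is
excluded because it would stack a child part on its parent's position).
Each part is placed at the position of the S node above its P node.
Parts have fixed scale and orientation; grammars with scaling/rotation
or other branching factors are out of scope.

**Prior.** `P(T,S|G) = P(T|G) P(S|T)`.  The tree prior marginalizes the
production probabilities under a uniform Dirichlet, giving a closed-form
product of multinomial beta functions of the production counts,
evaluated in log-gamma arithmetic.  The spatial prior is uniform,
`|V|^-|N_S|` over the non-root S nodes.  Both factors shrink as trees
grow, so the prior is an Occam's razor: about 7.9 nats per added part
(`log 4 + log 9 + log 26`).  Two properties of the marginalized prior
matter operationally:

* it rewards *repeated* productions (a tree using one part twice beats a
  tree using two different parts by `log 2`), which is exactly the
  margin an impostor interpretation gains by duplicating a part already
  present — the synthetic stimuli are designed so every such impostor
  pays more than `log 2` in likelihood (see below);
* the grammar's branching process under uniform rule probabilities is
  supercritical (mean S offspring 1.5), so naive ancestral sampling
  diverges with probability `1 - (sqrt(2) - 1) ≈ 0.59`.  All sampling
  paths therefore retry until the (sub)derivation has at most
  `max_parts` parts (default 30).  The retry normalizer depends only on
  the start symbol, so it cancels exactly in every Metropolis-Hastings
  ratio; the chain additionally auto-rejects any proposal that would
  push the whole tree over the cap, which bounds the state space without
  bias.

**Likelihood.** Sensory data are modeled as the forward-model prediction
plus isotropic Gaussian noise: `log P(D|T,S) = -||D - F(T,S)||^2 / (2
sigma^2)` on a feature vector whose per-modality blocks are scaled by
`1/sqrt(dim)` so that a 120,000-pixel image and a 384-value grasp vector
carry comparable weight under a single variance.

`sigma^2` is the model's sole free parameter, one value per stimulus
condition.  It trades off prior and likelihood: too large and the Occam
prior deletes the least visible part (the bound is `sigma^2 <
min-part-cost / 15.8`, where the smallest measured single-part feature
cost is ~2.7e-3 visual / ~8.2e-3 haptic on the modality-scaled square
distance); too small and the sampler cannot traverse imperfect
intermediate representations.  The defaults — visual `1.2e-4`, haptic
`3e-4`, multisensory `4e-4` — sit a factor ~1.5-2 inside the deletion
bound for every stimulus and were chosen by computing those bounds
directly, not by fitting.

## Forward models

**Vision.** Three orthographic views, `r x r` (default 200, reduced
sizes for tests), flattened visual-first into a `3 r^2` vector.  Cameras
sit on +x, -y and +z; the -y camera views the underside so that the
lowest part slot is depth-visible to at least one camera.  The default
shading is an 8-bit *depth* image: a pixel holds the quantized depth of
the nearest surface (brighter = closer), background 0 — a flat-lit
grayscale rendering.  A binary silhouette mode exists but is not the
default: with pure occupancy masks, unions of misplaced parts can
reproduce the target mask exactly, and the repeated-production bonus
then ranks such impostors above the truth; depth shading makes every
covering surface answer for *where* it is, which restores
identifiability.  Rasterization is axis-aligned box painting with a
max-blend over depth; everything is integer-exact and bit-reproducible.

**Haptics.** A deterministic grasp surrogate replaces a physics-based
hand simulator while preserving its interface: 24 grasp orientations
(8 rotations of 45 degrees about each axis) times 16 pseudo joint
angles = 384 features.  Each grasp casts a 4x4 bundle of parallel rays
from a palm plane toward the object; a ray's feature is
`(pi/2) * min(contact distance, d_max) / d_max`, i.e. a finger that
travels farther before touching closes more, and a finger that never
touches closes fully.  The ray lattice has spacing 0.28 (< w/3, so any
feature spanning a part cube is always sampled) and each orientation's
lattice is shifted by a deterministic golden-ratio offset.  Without the
shifts the same 16 lattice lines probe every grasp and laterally
displaced shapes can produce *identical* contact sets (measured: a
nested part moved one voxel sideways left the feature vector unchanged);
the offsets emulate fingers meeting different surface points from every
approach direction and make single-voxel displacements register
(minimum measured effect 0.39 on the raw squared distance).

## Stimuli

Sixteen five-part objects: a common elongated body `P0` (length 0.9 w,
half-width 0.12 w) plus one of two interchangeable parts at each of four
fixed locations — three at level-1 voxels `(0,-1,0)`, `(1,0,0)`,
`(-1,1,0)` and a fourth nested one level deeper at `(0,1,0)` under the
third.  A 4-bit *list-of-parts code* names the choice at each location.

The original multi-part laboratory objects ("Fribbles") are not publicly
available, so the part templates are simplified box primitives designed
to honor the relations the model's behavior depends on, all
test-enforced:

* each of P1..P6 occupies a grossly different *sector* of the part cube
  (upper/lower z half-slabs, high/low x half-slabs, two opposite thick
  corner columns), so substituting one part for another empties whole
  ray corridors and image regions — the minimum duplicate-creating
  substitution costs ~1.9e-3 (haptic scale), nearly 3x the `log 2`
  prior bonus at the haptic variance;
* P7 and P8 are a small plate near the top of the nested slot's cube,
  identical except that P8 is one fifth thinner — the smallest part, a
  near-subset of P7 (cell overlap >= 0.8), their difference protruding
  into free space above the object so both forward models retain a
  strictly nonzero trace of it;
* all other template pairs differ in at least 30% of occupied cells, and
  all 120 non-identical stimulus pairs are discriminable in both
  modalities.

Early iterations used parts whose differences hid in occluded or
sub-lattice regions; inference then legitimately preferred impostor
interpretations (the posterior was right — the stimuli were
unidentifiable).  The sector design was adopted for identifiability and
then frozen; it is a property of this synthetic stimulus family, not a
claim about real objects, which is the main caveat when reading the
recovery results.

**Synthetic ratings.** The ratings generator emulates the empirical
regularity that similarity judgments track shared parts: rating =
`clamp(round(7 - 1.5 * Hamming(codes) + N(0, sd)), 1, 7)` per subject,
block and unordered pair (136 per block), defaulting to 7 subjects per
condition and 4 blocks as in the study design.  It reproduces the
code-driven structure of ratings but none of the perceptual noise
correlations, subject idiosyncrasies, or condition differences of real
raters — so tests against it validate the analysis pipeline, not human
behavior.

## Inference

Metropolis-Hastings over spatial trees, alternating two kernels:

* **subtree regeneration** (even iterations): pick one of the `N_nt`
  non-terminal nodes uniformly, regrow its subtree from the grammar with
  uniform rule probabilities, drawing uniform coordinates for new S
  nodes.  Acceptance: likelihood ratio x marginalized-tree-prior ratio x
  `|N_nt|/|N_nt'|` x the uniform-rho probability ratio of the replaced
  and new subtrees (spatial priors cancel against the uniform coordinate
  proposals).
* **add/remove part** (odd iterations): with probability 1/2 insert a
  fresh `S -> P -> part` chain (uniform part, uniform attachable S node
  with < 4 children, uniform voxel, uniform insertion slot among the
  parent's `s+1` S positions), else delete a uniformly chosen removable
  S node (non-root, sole child a P node).  Acceptance carries
  `|Gt| |A| (s+1) / |R'|` for the add and the reciprocal for the
  remove.  The insertion-slot choice (and its `(s+1)` factor) is what
  makes the pair exactly reversible on ordered trees, including states
  with interchangeable sibling subtrees; an append-only variant without
  the factor fails the detailed-balance audit precisely by the sibling
  multiplicity.  A move whose candidate set is empty, or that would
  exceed the part cap, is an automatic rejection.

Both kernels are audited exhaustively on a restricted grammar (2 parts,
2 voxels): analytic flow `pi(x) q(x->x') A` equals its reverse for every
reachable pair, and a 60,000-iteration chain matches the enumerated
exact posterior within total variation 0.05.

Chains run 10,000 iterations with 6,000 burn-in, initialized from a
prior draw; the MAP estimate is the highest-posterior state visited
after burn-in (earliest on ties), reported in canonical form, taking the
best across 3 seeded chains.  Canonical form sorts the S children of
every node by their serialized subtree string — the grammar leaves
sibling order meaningless, and a fixed order is what makes tree equality
and the ordered tree edit distance well-defined.

Reported recovery runs use resolution 64 and the default variances; at
those settings the full 16-object visual sweep runs in a few minutes on
one CPU.  Recovery is stochastic: a single chain finds the exact
generating representation most of the time (visual ~0.9 per chain), and
best-of-3 makes per-object failure rare; the haptic-only condition has
the most rugged landscape and is the occasional residual failure mode.

## Similarity metrics and evaluation

* **MVH-M** — tree edit distance (Zhang-Shasha, ordered trees, unit
  costs; S-node labels include the voxel coordinate, P leaves their part
  id) between canonical forms.  On the 16 stimuli this equals the
  Hamming distance between list-of-parts codes (1 rename per differing
  location).
* **MVH-V / MVH-H** — Euclidean distance between rendered pixel vectors
  or grasp feature vectors.
* Distances become similarities by negation and min-max scaling over the
  136 unordered pairs (any affine map gives the same Pearson
  correlations); correlations are computed over the 136-pair
  vectorizations, with Fisher z available for averaging.

Rating tables are reduced to per-subject matrices (averaging blocks and
presentation order), condition matrices (averaging subjects),
within/between-condition correlation summaries (n(n-1) ordered
within-condition pairings, n*m between), and a subject-resampling
bootstrap (within-condition cells correlate two independent resamples,
since a matrix's correlation with itself is trivially 1).

## Known limitations

* The stimulus geometry is synthetic and engineered for
  identifiability; passing recovery tests demonstrates correctness of
  the inference machinery on this family, not performance on real
  objects or laboratory stimuli.
* The grasp surrogate is kinematic ray-probing, not contact dynamics; it
  preserves the 16 x 24 deterministic interface of a grasp simulator,
  nothing more.
* Exact MAP recovery depends on the likelihood variance staying inside
  the per-condition bounds documented above; the bounds are recomputed
  by the test suite but are properties of this stimulus set.
* MCMC recovery within 10,000 iterations is probabilistic; seeds make
  any single run reproducible but headline counts vary by 1-2 objects
  across seed families, mostly in the haptic-only condition.
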