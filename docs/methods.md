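# Methods

This note documents the models, algorithms and numerical choices behind
`profclust`, and what the synthetic benchmark does and does not show.

## Self-detection and thresholds

A candidate cluster (a monophyletic clade of the training tree) is accepted
only under **strict self-detection**: with a profile built from the clade's
own alignment, the minimum member score must strictly exceed the maximum
non-member score over the entire training set. Ties fail by design — an
equal score cannot separate members from non-members, and score ties are
common with short or near-duplicate sequences. The inclusion threshold is
the *minimum member* score (not, say, a midpoint between member minimum and
non-member maximum) so that the boundary member itself is re-admitted by
the `score ≥ T` inclusion rule; inclusion is inclusive (`≥`) while
separation is strict (`>`), deliberately asymmetric.

A member whose score falls below the detection floor fails self-detection
outright; the "not detected" state is a sentinel equal to −∞, never zero —
an undetected sequence must sort below every finite score, not between
small positive ones.

Candidate clades are walked in descending size order; ties break by
post-order position, making the walk a pure function of topology.
Multifurcating nodes are allowed (one candidate per internal node). The
minimum clade size is 2, because a profile needs an alignment of at least
two sequences; singleton training sequences are orphans by definition.
Accepting a cluster removes every clade sharing at least one leaf —
"overlapping" includes "nested" — which is what makes the final partition
disjoint. Acceptance is delegated to a policy callback (the supervision
point): `accept_all_policy` is the library default; `split_root_policy`
declines any cluster spanning the whole training set, since the
universe-wide clade always passes self-detection vacuously (it has no
non-members) while the point of the method is subfamily resolution. The
pipeline and benchmark runs use `split_root_policy`.

## Internal scoring backend

The internal scorer is a position-specific log-odds model:

* **Match columns** are alignment columns with < 50% gaps.
* **Column probabilities** are `(count + α·bg) / (N + α)` with pseudocount
  `α = 1` and uniform background `bg = 1/20`, over the non-ambiguous
  residues observed in the column; unknown residues (X) score 0.
* **Information shrinkage.** Raw small-sample counts produce profiles so
  over-specific that a member's own counts lift its self-score by tens of
  bits over statistically identical sequences outside the alignment. The
  min-member threshold then sits above essentially every true positive and
  iterative recruitment stalls. The builder therefore blends column
  probabilities toward the background (binary search on the mixing weight)
  until the mean per-column relative entropy reaches `info_target`
  (default **1.0 bit/column**; profile-HMM builders use the same idea with
  a default near 0.59 for proteins). `info_target=None` gives the raw α=1
  model.
* **Scoring** is a glocal, optionally multihit, affine-gap dynamic program:
  one *pass* consumes all match columns in order via match / delete /
  interior-insert moves (gap open −4 bits, extend −1 bit); residues outside
  passes are free; in the default full-sequence mode disjoint passes add,
  so tandem repeats accumulate elevated scores exactly as full-sequence
  bit scores do on repeat proteins; `best_domain` mode scores the single
  best pass and neutralises repeat inflation. Raw scores below 0 bits are
  reported as not-detected. The kernel is numba-compiled and bit-exact
  deterministic; a brute-force path-enumeration oracle reproduces it
  exactly on small instances (tests).

The internal scorer is a contract implementation with defensible defaults,
not a re-implementation of profile-HMM statistics: no E-values, no
composition-bias correction, no Dirichlet mixture priors. For real data the
pyhmmer backend provides the full profile-HMM machinery behind the same
interface (build from MSA, score a universe, full-sequence or best-domain
bit score, absent hits = not-detected).

## Classification dynamics

Automated rounds recruit pool sequences scoring at or above a live group's
threshold, then rebuild that group (realign members from scratch, rebuild
the profile, rescore the combined training+target universe, reset the
threshold to the new member minimum). Because recruits are typically not
self-inflated, the member minimum drifts downward across rounds, which is
what gives the method its sensitivity. Convergence is reached when a round
recruits nothing; `max_rounds` (default 100) guards against oscillation and
returns a flagged partial result on exhaustion.

Conflicts freeze groups permanently: a target claimed by ≥ 2 groups is
removed from all groups and the pool; a training sequence detected by a
foreign group stays only with its origin group; every involved group
(including the origin) is excluded from all subsequent iterations but keeps
its members in the final output. The self-detection universe during
classification is all training plus all target sequences outside the
group; unclassified homologs below threshold do not violate it because
separation is tested at the member minimum.

Posterior inclusion considers, per live group, the detected-but-below-
threshold candidates in descending score order (the "seemingly negative"
sequences closest to the boundary first). Each candidate is provisionally
added, the profile rebuilt, and kept only if strict self-detection holds
*with the candidate inside the profile*; a rejection restores the previous
group exactly (verified structurally). An acceptance re-opens the automated
recruitment rounds, nesting the automated cycle inside the supervised one.
Each candidate is tried at most once per group, which bounds the phase.

### Score-drop stopping rule

Batch mode replaces the human looking at the score plot with a rule on the
descending score series: stop a group's posterior phase when the gap below
the current boundary is (a) more than `drop_factor` (default 10×) the
median successive gap above it **and** (b) more than `rel_drop` (default
0.25) of the boundary score itself. Condition (a) alone misfires on very
homogeneous groups: when member-to-member gaps are hundredths of a bit,
any bit-level noise gap is "10× the median", yet the true subfamily
boundary is a cliff of hundreds of bits. Condition (b) makes the rule
scale-free in the score as well as in the gaps; the sharp drop that
motivated the rule (a boundary score roughly halving) satisfies both.
Both knobs are exposed, and a custom policy callable can replace the rule
entirely (e.g. an interactive front-end).

## Synthetic benchmark

The generator emulates the data regime the classifier is designed for:
`n_families` subfamilies evolved from a common consensus by independent
per-site substitution over the 20 amino acids (a Jukes–Cantor-style model:
along a branch of `d` expected substitutions/site each site changes with
probability `(19/20)(1 − e^{−20d/19})` to a uniformly drawn other residue).
The consensus→family-ancestor branch is `between/2` and ancestor→sequence
branches are `within/2`, so expected pairwise divergence is ≈ `within`
inside a family and ≈ `between + within` across families. The emitted
training tree is the true generating topology (families are multifurcating
clades). Defaults — 8 families, 12 training + 30 target sequences each,
length 150, `within = 0.2`, `between = 1.2` substitutions/site — define
the study conditions used by the test suite and the acceptance script;
20 seeds keep the pooled figures stable at a few minutes of CPU.

Two planted pathologies reproduce known failure modes:

* **Rogue** (`inject_rogue`): a training sequence re-attached inside a
  foreign family's clade while keeping its own family's residues — a
  misplaced leaf in the training tree. The contaminated clade still
  *passes* self-detection (a sequence inside the profile outscores its
  true-family siblings via its own counts — the external profile-HMM
  backend behaves identically), but its threshold is dragged down to the
  rogue's own score, and classification then degrades: foreign targets are
  claimed, conflicts arrest groups, recall collapses while precision
  stays at 100%. Removing the rogue restores exact planted recovery. This
  is the corrupted-then-corrected narrative the tests assert.
* **Repeat** (`inject_repeat`): a target replaced by a tandem concatenation
  of partial segments of itself. Full-sequence scoring inflates its score;
  best-domain scoring neutralises the inflation; conflict arrest keeps it
  from ending up in two groups.

What the benchmark does **not** emulate: indels are off by default (the
pass-through aligner then suffices; `indel_rate > 0` exercises mafft),
substitution is uniform rather than an empirical matrix (no BLOSUM-like
exchangeability, no rate heterogeneity), and there is no compositional
bias, domain architecture or convergent evolution. Passing tests therefore
show the *algorithmic* machinery is correct under separable conditions —
they do not certify performance on real proteomes, where training-set
bias, divergent subfamilies and biased composition dominate (the score
floor and conflict arrest are the designed safety nets there).

## Determinism and degenerate inputs

With the internal backend, identical configuration and seed give
byte-identical artifacts: the DP kernel is exact floating-point, every
iteration order is sorted or topology-derived, and no artifact embeds a
timestamp. Degenerate inputs are hard errors, not warnings: duplicate or
empty leaf labels, tree/FASTA id mismatches, all-zero branch lengths for
midpoint rooting, alignments with zero match columns, and fewer than two
sequences per alignment. Midpoint rooting of a two-leaf tree is handled
explicitly (root placed on the single path).

## Known limitations

* Micro-average recall, precision and the recall interval are the only
  built-in metrics; no statistical tests on recall differences.
* The internal scorer's bit scores are not calibrated against profile-HMM
  E-values; comparing absolute scores across backends is meaningless.
* Posterior inclusion tries each candidate once per group; a candidate
  rejected early is not revisited even though later acceptances may have
  changed the profile in its favour (bounded runtime was preferred).
* Trees must be rooted or midpoint-rootable; no tree inference or
  trimming is provided — the phylogeny is the user's responsibility, and
  a single misplaced leaf measurably corrupts downstream classification
  (see the rogue experiment).
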