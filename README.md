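# profclust

Phylogeny-guided profile classification of protein superfamilies with
reliable, subfamily-specific inclusion thresholds.

## The problem

Annotating protein sequences at the *subfamily* level (orthologs, not just
homologs) is hard because similarity scoring lacks a cut-off that is both
sensitive and specific. Profile scores (HMMER-style bit scores) built from a
conserved subfamily alignment are far more specific than superfamily-wide
profiles — but they still need a principled threshold.

`profclust` derives that threshold from a supervised training set. Given a
high-quality phylogeny of training sequences, it:

1. **Training (clustering).** Enumerates every monophyletic clade, largest
   first, and tests each for *100% precision-and-recall self-detection*:
   build an alignment and profile from the clade's sequences, score the
   whole training set, and require that the lowest-scoring clade member
   strictly outscores the highest-scoring non-member. Passing clades become
   clusters (subject to an accept/reject policy — the supervision point);
   accepting a cluster removes all nested/overlapping clades. The lowest
   member score is the cluster's **inclusion threshold**
   `T = min_{m ∈ cluster} score(m)`, with strict separation
   `T > max_{x ∉ cluster} score(x)`.
2. **Automated classification.** Each cluster grows into a *group* by
   recruiting target sequences with `score ≥ T`, realigning, rebuilding the
   profile, rescoring everything and resetting `T` to the new member
   minimum — iterated to convergence. A sequence claimed by two groups is a
   *conflict*: conflicting targets are discarded, conflicting training
   sequences stay only with their origin group, and all involved groups are
   frozen ("arrested") — this is what protects precision.
3. **Posterior inclusion.** Detected-but-below-threshold candidates are
   tried one at a time in descending score order: each is provisionally
   added and kept only if strict self-detection still holds with the
   rebuilt profile. A score-drop policy (the automated stand-in for a
   supervisor reading the score plot) stops a group at a sharp score cliff.
4. **Evaluation.** Per-group TP/FP/FN against a reference labeling, with
   the pooled micro-average recall `Σᵢ TPᵢ / Σᵢ (TPᵢ + FNᵢ)`.

Two scoring backends sit behind one contract: a self-contained
position-specific log-odds scorer (glocal, multihit, affine-gap dynamic
programming, numba-compiled, fully deterministic) and a profile-HMM backend
built on pyhmmer. Alignments use mafft (`--anysymbol --auto`) when rows are
not already aligned.

The intended user is a biologist with a curated superfamily phylogeny who
wants to classify large target sets (e.g. proteomes) into subfamilies with
near-perfect precision, accepting that remote homologs in the twilight zone
may stay unclassified.

## Worked example

```bash
# simulate a superfamily: 3 subfamilies, 5 training + 6 targets each
profclust simulate --out bench --families 3 --train 5 --targets 6 \
    --length 100 --seed 17

# training: cluster with supervision that declines the superfamily-wide clade
profclust train --tree bench/tree.nwk --seqs bench/training.fasta \
    --out part --policy split-root
# -> 3 clusters, 0 orphans -> part

# classification (automated rounds + posterior inclusion)
profclust classify --partition part --targets bench/targets.fasta --out cls
# -> 18 targets classified, 0 unclassified, 0 conflicts -> cls

# evaluation against the planted labels
profclust evaluate --pred cls/classification.tsv --labels bench/labels.tsv
```

The evaluation prints, for this example:

```
group_id	label	TP	FP	FN	recall
G1	fam01	6	0	0	1.0000
G2	fam02	6	0	0	1.0000
G3	fam03	6	0	0	1.0000
micro_average_recall	1.0000
overall_precision	1.0000
unclassified	0
```

i.e. all 18 target sequences were recruited into the group of their true
subfamily (TP), none into a wrong group (FP = 0, precision 1.0), and none
were left out (FN = 0, micro-average recall 1.0). `part/thresholds.tsv`
holds each cluster's inclusion threshold in bits;
`cls/groups/G*_scores.tsv` holds the per-group score tables behind the
score-drop plots.

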