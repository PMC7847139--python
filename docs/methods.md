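# Methods

## The gap-aware JC model

The classical Jukes–Cantor model assumes every residue substitutes to each
of the other 19 amino acids (3 nucleotides) at the same rate α, giving the
distance `K = −a ln(1 − P/a)` with `a = 19/20` (amino acids) or `3/4`
(nucleotides) from the mismatch fraction *P*. The gap-aware extension adds
indel events with the same equal-rates logic: every residue deletes at rate
ε, and a gap state re-fills with each amino acid at rate ε/20 (total
insertion rate ε). The total change rate per site is then the mixture
`k = w(19α + ε) + (1 − w)ε`, where *w* is the probability that a compared
site carries residues rather than gaps. Solving the resulting divergence
relation for two sequences separated by time 2t gives

    K = −(19/20) · w · ln((S − P/19) / w)

with *S* and *P* the identical/different residue-column fractions. When the
pair is gap-free, *w* = 1 and *S* = 1 − *P*, and the expression collapses to
the classical formula; the test suite asserts this identity to 1e-12.

### Counting conventions

The model constrains *w* only in the gap-free limit, so the package fixes
the estimator as follows (each choice is isolated in
`phylogap.pairwise` and can be changed in one place):

* **w** is the fraction of residue characters among the 2L characters of
  the pair: `w = S + P + (g₁ + g₂)/2`. It weights both sequences equally
  and reduces to 1 without gaps.
* **Both-gap columns are excluded** from all counts. A shared gap is not an
  event on the path between the two sequences, and counting such columns
  would shrink the estimate for pairs that share deletions. (Empirically
  this choice is near-neutral: re-running the full simulation grid with
  both-gap columns included in the denominators moved the grand-average
  accuracy of the gap-aware measure by 0.5 points.)
* **Ambiguity codes** (X, B, Z, …; N, R, Y, … for DNA) make a column
  uninformative for the pair and it is excluded everywhere. Input keeps
  them; only the statistics ignore them.
* **p-distance under +Gap** counts residue-vs-gap columns as differences
  (`d = P + g₁ + g₂`) — the simplest model-free reading of "gaps count".
* **Logarithms** are natural throughout; the gap-free reduction to the
  classical formula forces this reading.

Saturated pairs (log argument ≤ 0) yield a NaN sentinel plus a logged
warning instead of an exception, so one bad pair does not abort a matrix;
tree builders refuse matrices containing the sentinel.

## Tree reconstruction

`nj` is standard Saitou–Nei neighbor joining with the Studier–Keppler
Q-criterion, exact on additive matrices (property-tested against path-length
matrices of random trees, and cross-checked against dendropy's
implementation). `upgma` is size-weighted average linkage with heights at
half the cluster distance, producing ultrametric rooted trees. Both break
criterion ties by the smallest (row, column) index of the working matrix so
runs are exactly reproducible, and clamp negative NJ branch lengths to zero
to keep serialized trees valid for viewers. Robinson–Foulds distance is the
symmetric difference of the non-trivial unrooted bipartition sets (bitmask
implementation, verified against brute-force enumeration and dendropy);
"same topology" means RF = 0. Midpoint rooting delegates to dendropy on a
copy of the tree.

## The evolution simulator

`simulate_replicate` evolves a uniformly random amino-acid sequence
root-to-leaves along a perfect binary tree with unit branches. Per branch
and per residue site, one categorical draw selects substitution
(probability `p_sub`, target uniform over the other 19 residues), deletion
(`p_indel`, the site becomes a permanent gap for the lineage), or no event;
an independent draw then inserts one uniform residue after the site with
probability `p_indel`. Defaults mirror the benchmark conditions:
`p_sub = 0.01`, `p_indel ∈ {0.001, 0.002, 0.005}` per site per branch,
100 replicates (the desk-scale grid below uses 20).

Design choices where the mechanics were open:

* **Insertion attachment**: insertion draws attach to parent residue sites
  only — not to gap columns and not to the sequence ends. This keeps one
  insertion opportunity per surviving site and matches the "per site per
  branch" probability reading; end-insertions would add a length-independent
  edge effect.
* **True alignment**: inserted residues open fresh alignment columns
  (gaps everywhere else); leaves are never realigned. Column order is
  maintained with hierarchical sort keys — ancestral column *i* is `(i,)`,
  a column inserted after key *K* on preorder branch *b* is `K + (−b,)` —
  which keeps a single global column order consistent with every lineage
  without padding all live sequences on each insertion. A naive
  pad-every-row driver consuming the identical random stream is used as an
  equivalence oracle in the tests.
* **Reproducibility**: one `numpy` generator per replicate seeded with
  `(seed, replicate_index)`; the stream is consumed as ancestral sequence,
  then branches in preorder with the fixed per-branch draw order above.
  Grid conditions get seeds `(master·100003 + index) mod 2³¹`.

What the simulator does *not* emulate: multi-residue indels, rate
heterogeneity across sites, non-uniform amino-acid frequencies or empirical
exchange matrices (WAG/LG), and alignment error — real pipelines infer the
alignment, and alignment mistakes would degrade all measures, the gap-aware
one most. Passing benchmarks therefore demonstrate the estimators'
behaviour under their own model assumptions with a known true alignment,
not performance on real, realigned data.

## The topology-recovery benchmark

`run_grid` scores, per condition, the percentage of replicates in which NJ
on each of three matrices — JC after complete deletion, JC with pairwise
deletion, and the gap-aware JC on all columns — recovers the model tree's
unrooted topology (RF = 0). The default grid is 5 taxa counts × 4 lengths ×
3 indel rates = 60 conditions at 20 replicates (~3 minutes on one CPU),
with the full 100-replicate study available via `n_replicates=100` or
`phylogap bench --reps 100`. Replicates whose matrix is saturated or has an
empty column set are scored incorrect for that measure rather than dropped.
Summary standard errors combine per-condition binomial variances with
Agresti–Coull shrinkage so conditions at 0 % or 100 % still contribute
spread.

At these settings the two classical-JC pipelines and the qualitative
structure of the comparison (gap-aware > pairwise > complete deletion at
moderate indel rates; monotone degradation of complete deletion as the
indel rate grows) are stable across seeds; the gap-aware measure's absolute
accuracy is the quantity most sensitive to the simulator details listed
above, since it is the only estimator that uses the indel events
themselves.

## Limitations

* The gap-aware distance is defined for amino acids; nucleotide analyses
  fall back to JC/K2P with gap-excluding treatments.
* Terminal gaps are counted like internal ones; for partial sequences they
  may reflect missing data rather than indels, so complete protein or gene
  sequences are the intended input.
* Distances assume stationarity and equal rates; no gamma heterogeneity or
  model selection is provided.
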