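# phylogap

Gap-aware genetic distances and distance-based phylogenetics.

Most evolutionary distance measures discard alignment columns that contain
gaps, throwing away the evolutionary signal carried by insertions and
deletions. `phylogap` implements a gap-aware extension of the Jukes–Cantor
(JC) amino-acid distance that treats indel events as changes on the same
footing as substitutions, alongside the classical measures it generalises,
and everything needed to evaluate it: distance-matrix construction under
three gap treatments, neighbor-joining (NJ) and UPGMA tree building,
Robinson–Foulds topology comparison, and an indel-aware sequence-evolution
simulator that emits the true alignment of its leaf sequences.

## The measures

For one pair of aligned sequences let *S* and *P* be the fractions of
columns showing identical and differing residues, *g₁*, *g₂* the fractions
with a gap in one sequence only, and *w = S + P + (g₁+g₂)/2* the
residue-occurrence probability of the pair (*w* = 1 when gap-free).
Columns where both sequences have a gap are excluded.

* classical JC: `K = −a · ln(1 − P/a)` with `a = 3/4` (nucleotides) or
  `19/20` (amino acids), after removing gapped columns either across the
  whole alignment (*complete deletion*) or per pair (*pairwise deletion*);
* gap-aware JC (*+Gap*, amino acids):

  `K = −(19/20) · w · ln((S − P/19) / w)`

  which reduces exactly to classical JC when the pair is gap-free;
* p-distance (mismatch fraction; under +Gap, residue-vs-gap columns count
  as differences) and the Kimura two-parameter (K2P) distance for
  nucleotides (gap-excluding treatments).

## Worked example

```python
import phylogap as pg

a = pg.AlignedSeqRecord("a", "ACDE-")
b = pg.AlignedSeqRecord("b", "ACD-F")
st = pg.pair_stats(a, b, pg.GapTreatment.PLUS_GAP)
print(st.s_same, st.p_diff, st.g1, st.g2, st.w_occ)
# 0.6 0.0 0.2 0.2 0.8
print(pg.jc_gap_distance(st))
# 0.21863837506335362
```

The two sequences are identical except for one single-residue indel in
each: pairwise deletion sees a distance of exactly 0, while the gap-aware
estimate charges the two events, giving −0.95·0.8·ln(0.6/0.8) ≈ 0.2186
changes per site. `examples/` contains this and two more narrated scripts
(the FASTA → matrix → NJ-tree pipeline, and a simulation condition scored
for topology recovery); each prints the numbers shown in its comments.

The same pipeline is available from the shell:

```bash
phylogap run -i aligned.fasta --type aa --measure jc --gaps gap --tree nj -o out/
# writes out/alignment.txt (FASTA), out/matrix.txt (PHYLIP), out/tree.txt (Newick)
phylogap bench --reps 20 --seed 1 --out results.tsv   # the simulation study
```

## Scope notes

Input must already be aligned (align with MAFFT/ClustalW first; the package
deliberately does not shell out to aligners). A gap-aware K2P variant for
nucleotides is not included. An empirical workflow — e.g. a p53 protein
study across vertebrates — is a matter of downloading Swiss-Prot sequences,
aligning with MAFFT, and running `phylogap run` with `--gaps gap`,
`--gaps pairwise` and `--gaps complete` to compare the resulting
topologies; see `docs/methods.md` for details and caveats about terminal
gaps.
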