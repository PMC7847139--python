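"""Indel-aware amino-acid sequence evolution along perfect binary trees.

The simulator mirrors the validation setup for gap-aware distance measures:
an ancestral sequence drawn uniformly over the 20 amino acids evolves
root-to-leaves along a perfect binary tree with unit-length branches.  Per
branch and per residue site a single categorical draw selects a substitution
(probability ``p_sub``, target uniform over the 19 other residues), a
deletion (probability ``p_indel``, the site becomes ``'-'`` permanently in
that lineage), or no event; an independent draw then inserts one uniformly
chosen residue *after* the site with probability ``p_indel``.  Insertions
open a fresh alignment column carrying gaps in every other lineage, so the
leaf alignment emitted is the *true* alignment — no realignment step.

Column bookkeeping uses hierarchical sort keys rather than padding every
live sequence on each insertion: ancestral column ``i`` has key ``(i,)`` and
a column inserted after the column with key ``K`` on preorder branch ``b``
gets key ``K + (-b,)``.  Because every branch has a larger preorder index
than all of its ancestors, lexicographic key order is consistent with the
residue order of every lineage, and sorting the union of leaf keys yields
the global alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import dendropy
import numpy as np

from .io import AA_LETTERS, Alignment, AlignedSeqRecord, Alphabet
from .pairwise import GAP_CODE, encode_sequence

__all__ = [
    "SimConfig",
    "SimReplicate",
    "BranchOutcome",
    "perfect_binary_tree",
    "evolve_branch",
    "simulate_replicate",
]

_DECODE = np.frombuffer(("-" + AA_LETTERS).encode("ascii"), dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulation condition.

    Defaults are the benchmark's reference condition: substitution
    probability 0.01 per site per branch with indel probability 0.001 (the
    same rate is applied separately to insertion and deletion), 100
    replicates.
    """

    n_taxa: int
    ancestral_length: int
    p_sub: float = 0.01
    p_indel: float = 0.001
    n_replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2 or self.n_taxa & (self.n_taxa - 1):
            raise ValueError("n_taxa must be a power of 2 (perfect binary tree)")
        if self.ancestral_length < 1:
            raise ValueError("ancestral_length must be positive")
        for name in ("p_sub", "p_indel"):
            p = getattr(self, name)
            if not 0.0 <= p < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.p_sub + self.p_indel > 1.0:
            raise ValueError("p_sub + p_indel must not exceed 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")


@dataclass(frozen=True)
class SimReplicate:
    """Model tree, true leaf alignment and realized event counts."""

    model_tree: dendropy.Tree
    leaf_alignment: Alignment
    n_substitutions: int
    n_insertions: int
    n_deletions: int


class BranchOutcome(NamedTuple):
    """Result of evolving one sequence along one branch."""

    sequence: str  #: child sequence, inserted columns included
    insertions: tuple[int, ...]  #: child-coordinate indices of new columns
    n_substitutions: int
    n_deletions: int


def perfect_binary_tree(n_taxa: int) -> dendropy.Tree:
    """Complete binary tree with unit branch lengths, leaves ``t1..tn``."""
    if n_taxa < 2 or n_taxa & (n_taxa - 1):
        raise ValueError("n_taxa must be a power of 2")
    tns = dendropy.TaxonNamespace()
    counter = iter(range(1, n_taxa + 1))

    def build(size: int) -> dendropy.Node:
        node = dendropy.Node()
        if size == 1:
            node.taxon = tns.require_taxon(label=f"t{next(counter)}")
            return node
        for _ in range(2):
            child = build(size // 2)
            node.add_child(child)
            child.edge.length = 1.0
        return node

    tree = dendropy.Tree(taxon_namespace=tns, seed_node=build(n_taxa))
    tree.is_rooted = True
    return tree


def _evolve_codes(
    codes: np.ndarray, p_sub: float, p_indel: float, rng: np.random.Generator
):
    """One branch of evolution on encoded codes (0 = gap, 1..20 = residues).

    Returns ``(child, ins_after, ins_codes, n_sub, n_del)`` where ``child``
    is in parent coordinates (insertions *not* yet applied), ``ins_after``
    the parent-coordinate residue positions each followed by one insertion,
    and ``ins_codes`` the inserted residues.  Draw order per branch: one
    uniform per residue site (substitution/deletion), substitution targets,
    one uniform per residue site (insertion), inserted residues.
    """
    res_idx = np.nonzero(codes != GAP_CODE)[0]
    child = codes.copy()
    u = rng.random(res_idx.size)
    sub_sites = res_idx[u < p_sub]
    del_sites = res_idx[(u >= p_sub) & (u < p_sub + p_indel)]
    offsets = rng.integers(1, 20, size=sub_sites.size)
    child[sub_sites] = (child[sub_sites] - 1 + offsets) % 20 + 1
    child[del_sites] = GAP_CODE
    v = rng.random(res_idx.size)
    ins_after = res_idx[v < p_indel]
    ins_codes = rng.integers(1, 21, size=ins_after.size).astype(np.uint8)
    return child, ins_after, ins_codes, sub_sites.size, del_sites.size


def evolve_branch(
    seq: str, p_sub: float, p_indel: float, rng: np.random.Generator
) -> BranchOutcome:
    """Evolve one gapped sequence along one branch (string interface).

    The returned sequence is in child coordinates with inserted residues in
    place; ``insertions`` gives their column indices so a driver can pad the
    other rows of a growing alignment with gaps.
    """
    codes = encode_sequence(seq.upper(), Alphabet.AMINO_ACID)
    child, ins_after, ins_codes, n_sub, n_del = _evolve_codes(
        codes, p_sub, p_indel, rng
    )
    grown = np.insert(child, ins_after + 1, ins_codes)
    ins_positions = tuple(int(p) for p in ins_after + 1 + np.arange(ins_after.size))
    return BranchOutcome(
        sequence=_DECODE[grown].tobytes().decode("ascii"),
        insertions=ins_positions,
        n_substitutions=int(n_sub),
        n_deletions=int(n_del),
    )


def _child_keys(parent_keys: list, ins_after: np.ndarray, branch: int) -> list:
    out: list = []
    prev = 0
    for p in ins_after:
        out.extend(parent_keys[prev : p + 1])
        out.append(parent_keys[p] + (-branch,))
        prev = p + 1
    out.extend(parent_keys[prev:])
    return out


def simulate_replicate(cfg: SimConfig, rep_index: int = 0) -> SimReplicate:
    """Simulate one replicate: model tree plus the true leaf alignment.

    Deterministic given ``(cfg.seed, rep_index)``; the random stream is
    consumed as (ancestral sequence, then branches in preorder).
    """
    tree = perfect_binary_tree(cfg.n_taxa)
    rng = np.random.default_rng([cfg.seed, rep_index])
    root_codes = rng.integers(1, 21, size=cfg.ancestral_length, dtype=np.uint8)
    root_keys = [(i,) for i in range(cfg.ancestral_length)]

    store: dict[int, tuple[list, np.ndarray]] = {
        id(tree.seed_node): (root_keys, root_codes)
    }
    totals = {"sub": 0, "ins": 0, "del": 0}
    branch = 0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        branch += 1
        parent_keys, parent_codes = store[id(node.parent_node)]
        child, ins_after, ins_codes, n_sub, n_del = _evolve_codes(
            parent_codes, cfg.p_sub, cfg.p_indel, rng
        )
        if ins_after.size:
            child = np.insert(child, ins_after + 1, ins_codes)
            keys = _child_keys(parent_keys, ins_after, branch)
        else:
            keys = parent_keys
        store[id(node)] = (keys, child)
        totals["sub"] += n_sub
        totals["del"] += n_del
        totals["ins"] += int(ins_after.size)

    leaves = [(n.taxon.label, store[id(n)]) for n in tree.leaf_node_iter()]
    all_keys: set = set()
    for _, (keys, _codes) in leaves:
        all_keys.update(keys)
    order = {k: i for i, k in enumerate(sorted(all_keys))}
    n_cols = len(order)
    records = []
    for label, (keys, codes) in leaves:
        row = np.zeros(n_cols, dtype=np.uint8)
        row[[order[k] for k in keys]] = codes
        records.append(
            AlignedSeqRecord(
                label, _DECODE[row].tobytes().decode("ascii"), Alphabet.AMINO_ACID
            )
        )
    return SimReplicate(
        model_tree=tree,
        leaf_alignment=Alignment(tuple(records)),
        n_substitutions=totals["sub"],
        n_insertions=totals["ins"],
        n_deletions=totals["del"],
    )
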