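"""Cluster trees, marker (cpn60) species trees, and congruence metrics.

Trees are built by neighbor joining over JC69 (or p / K2P) distances from a
simple deterministic progressive alignment; branch support comes from
column-resampling bootstrap. Congruence between a gene-cluster tree and the
species tree is quantified with the Robinson-Foulds distance, per-genus
monophyly checks in both trees, and a greedy "displaced leaf" set — the
leaves whose removal restores genus-level agreement, which is where
horizontally transferred clusters surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import dendropy
import numpy as np
import skbio
from skbio.tree import nj as _skbio_nj

from .survey import align_pair

JC69_SATURATION_CAP = 5.0  # substitutions/site reported for p >= 0.75


class PhyloError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Multiple alignment (deterministic star-progressive scheme)


def _kmer_profile(seq: str, k: int = 6) -> set:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _kmer_distance(a: set, b: set) -> float:
    if not a or not b:
        return 1.0
    return 1.0 - len(a & b) / len(a | b)


def build_msa(sequences: dict[str, str]) -> dict[str, str]:
    """Progressive star alignment around a k-mer-central seed sequence.

    Every input residue appears in the output; all rows share one length.
    Deterministic: the center is the sequence with the smallest total k-mer
    distance to the rest (ties by label), others join in label order.
    """
    if len(sequences) < 2:
        raise PhyloError("need at least two sequences to align")
    names = sorted(sequences)
    profiles = {n: _kmer_profile(sequences[n]) for n in names}
    totals = {n: sum(_kmer_distance(profiles[n], profiles[m])
                     for m in names if m != n) for n in names}
    center = min(names, key=lambda n: (totals[n], n))

    master = list(sequences[center])          # center row with gaps
    rows: dict[str, list[str]] = {center: master}
    for name in names:
        if name == center:
            continue
        _, _, blocks = align_pair(sequences[name], sequences[center],
                                  mode="global")
        rows[name] = _thread_onto_master(sequences[name], blocks, rows, center)
    length = len(rows[center])
    return {n: "".join(rows[n]) + "-" * (length - len(rows[n]))
            for n in sorted(rows)}


def _thread_onto_master(query: str, blocks, rows, center) -> list[str]:
    """Merge one query-vs-center alignment into the growing master rows."""
    master = rows[center]
    # map: ungapped center position -> column index in master
    col_of = []
    for col, ch in enumerate(master):
        if ch != "-":
            col_of.append(col)

    new_row = ["-"] * len(master)
    inserts: list[tuple[int, list[str]]] = []   # (column, residues)
    prev_qe = prev_ce = 0
    first = True
    for qs, qe, cs, ce in blocks:
        if not first or True:
            q_gap = query[prev_qe:qs]
            if q_gap:
                # unaligned query residues: insert new columns
                col = col_of[cs] if cs < len(col_of) else len(master)
                inserts.append((col, list(q_gap)))
        for qi, ci in zip(range(qs, qe), range(cs, ce)):
            new_row[col_of[ci]] = query[qi]
        prev_qe, prev_ce = qe, ce
        first = False
    tail = query[prev_qe:]
    if tail:
        inserts.append((len(master), list(tail)))

    if inserts:
        # splice new all-gap columns into every existing row
        for col, residues in sorted(inserts, key=lambda t: -t[0]):
            pad = ["-"] * len(residues)
            for r in rows.values():
                r[col:col] = pad
            new_row[col:col] = residues
    return new_row


# ---------------------------------------------------------------------------
# Distances


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray
    saturated: list[tuple[str, str]] = field(default_factory=list)

    def value(self, a: str, b: str) -> float:
        return float(self.matrix[self.labels.index(a), self.labels.index(b)])


def pairwise_distance(msa: dict[str, str], model: str = "jc69"
                      ) -> DistanceMatrix:
    """p, JC69 or K2P distances with pairwise deletion of gap/N columns."""
    if model not in ("p", "jc69", "k2p"):
        raise PhyloError(f"unknown model {model!r}")
    labels = sorted(msa)
    arrs = {n: np.frombuffer(msa[n].upper().encode(), dtype="S1")
            for n in labels}
    lengths = {len(a) for a in arrs.values()}
    if len(lengths) != 1:
        raise PhyloError("aligned sequences must share one length")
    valid = {n: np.isin(arrs[n], np.array([b"A", b"C", b"G", b"T"]))
             for n in labels}
    n = len(labels)
    mat = np.zeros((n, n))
    saturated = []
    purine = np.array([b"A", b"G"])
    for i, j in combinations(range(n), 2):
        a, b = arrs[labels[i]], arrs[labels[j]]
        ok = valid[labels[i]] & valid[labels[j]]
        m = int(ok.sum())
        if m == 0:
            raise PhyloError(f"no comparable columns: {labels[i]}/{labels[j]}")
        diff = (a != b) & ok
        p = diff.sum() / m
        if model == "p":
            d = p
        elif model == "jc69":
            if p >= 0.75:
                d = JC69_SATURATION_CAP
                saturated.append((labels[i], labels[j]))
            else:
                d = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
        else:  # k2p
            a_pur = np.isin(a, purine)
            b_pur = np.isin(b, purine)
            ts = (diff & (a_pur == b_pur)).sum() / m   # transition
            tv = (diff & (a_pur != b_pur)).sum() / m   # transversion
            x, y = 1.0 - 2.0 * ts - tv, 1.0 - 2.0 * tv
            if x <= 0 or y <= 0:
                d = JC69_SATURATION_CAP
                saturated.append((labels[i], labels[j]))
            else:
                d = -0.5 * np.log(x) - 0.25 * np.log(y)
        mat[i, j] = mat[j, i] = d
    return DistanceMatrix(labels=labels, matrix=mat, saturated=saturated)


# ---------------------------------------------------------------------------
# Neighbor joining and bootstrap


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Standard neighbor joining; exactly inverts additive matrices."""
    if len(dm.labels) < 3:
        raise PhyloError("need at least three taxa")
    sk_dm = skbio.DistanceMatrix(dm.matrix, ids=dm.labels)
    newick = str(_skbio_nj(sk_dm))
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial splits as the smaller-or-lexicographic leaf side."""
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return splits


@dataclass
class SupportTree:
    tree: dendropy.Tree
    supports: dict[frozenset[str], float]   # split -> percent of replicates
    n_reps: int

    def annotated_newick(self) -> str:
        for node in self.tree.preorder_internal_node_iter():
            if node.parent_node is None:
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            leaves = frozenset(lf.taxon.label
                               for lf in self.tree.leaf_node_iter())
            key = min(side, leaves - side, key=lambda s: (len(s), sorted(s)))
            if key in self.supports:
                node.label = f"{self.supports[key]:.0f}"
        return self.tree.as_string(schema="newick",
                                   unquoted_underscores=True,
                                   suppress_rooting=True).strip() + "\n"


def bootstrap_support(msa: dict[str, str], n_reps: int = 1000, seed: int = 0,
                      model: str = "jc69") -> SupportTree:
    """Column-resampling bootstrap; replicate r consumes RNG draw block r."""
    if n_reps < 1:
        raise PhyloError("n_reps must be >= 1")
    base_dm = pairwise_distance(msa, model)
    base = nj_tree(base_dm)
    if not base_dm.matrix.any():
        # identical sequences: nothing to resolve, report no supports
        return SupportTree(tree=base, supports={}, n_reps=n_reps)
    targets = bipartitions(base)
    counts = {s: 0 for s in targets}
    labels = sorted(msa)
    length = len(next(iter(msa.values())))
    cols = np.array([list(msa[n]) for n in labels])
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        idx = rng.integers(0, length, size=length)
        rep = {n: "".join(cols[i, idx]) for i, n in enumerate(labels)}
        try:
            rep_splits = bipartitions(nj_tree(pairwise_distance(rep, model)))
        except PhyloError:
            continue
        for s in targets & rep_splits:
            counts[s] += 1
    supports = {s: 100.0 * c / n_reps for s, c in counts.items()}
    return SupportTree(tree=base, supports=supports, n_reps=n_reps)


# ---------------------------------------------------------------------------
# Robinson-Foulds and congruence


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree,
                prune_to_common: bool = False) -> int:
    """Symmetric-difference count of non-trivial bipartitions."""
    l1 = {lf.taxon.label for lf in t1.leaf_node_iter()}
    l2 = {lf.taxon.label for lf in t2.leaf_node_iter()}
    if l1 != l2:
        if not prune_to_common:
            raise PhyloError("trees have different leaf sets")
        common = l1 & l2
        if len(common) < 4:
            raise PhyloError("fewer than four shared leaves")
        t1, t2 = _pruned(t1, common), _pruned(t2, common)
    s1, s2 = bipartitions(t1), bipartitions(t2)
    return len(s1 ^ s2)


def _pruned(tree: dendropy.Tree, keep: set[str]) -> dendropy.Tree:
    t = tree.clone(depth=1)
    t.retain_taxa_with_labels(sorted(keep))
    return t


def max_rf(n_leaves: int) -> int:
    return max(2 * (n_leaves - 3), 1)


def is_monophyletic(tree: dendropy.Tree, labels: set[str]) -> bool:
    """Unrooted-sense monophyly: the label set is one side of some edge."""
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    group = labels & leaves
    if len(group) <= 1 or group == leaves:
        return True
    for node in tree.preorder_node_iter():
        side = {lf.taxon.label for lf in node.leaf_iter()}
        if side == group or (leaves - side) == group:
            return True
    return False


@dataclass
class CongruenceReport:
    rf: int
    normalized_rf: float
    genus_monophyly_cluster: dict[str, bool]
    genus_monophyly_species: dict[str, bool]
    displaced_leaves: list[str]

    def to_dict(self) -> dict:
        return {
            "rf": self.rf,
            "normalized_rf": self.normalized_rf,
            "genus_monophyly_cluster_tree": self.genus_monophyly_cluster,
            "genus_monophyly_species_tree": self.genus_monophyly_species,
            "displaced_leaves": self.displaced_leaves,
        }


def congruence_report(cluster_tree: dendropy.Tree,
                      species_tree: dendropy.Tree,
                      genus_map: dict[str, str]) -> CongruenceReport:
    """RF distance plus genus-level agreement between the two trees.

    Displaced leaves are found greedily: while some genus fails monophyly in
    either tree, remove the leaf whose removal fixes the most violations
    (ties by label) — an approximation of the minimal displaced set.
    """
    l1 = {lf.taxon.label for lf in cluster_tree.leaf_node_iter()}
    l2 = {lf.taxon.label for lf in species_tree.leaf_node_iter()}
    common = l1 & l2
    ct = _pruned(cluster_tree, common) if l1 != common else cluster_tree
    st = _pruned(species_tree, common) if l2 != common else species_tree
    rf = rf_distance(ct, st)
    nrf = rf / max_rf(len(common))

    def verdicts(tree, leaves):
        by_genus: dict[str, set[str]] = {}
        for leaf in leaves:
            by_genus.setdefault(genus_map.get(leaf, "unknown"), set()).add(leaf)
        return {g: is_monophyletic(tree, s) for g, s in sorted(by_genus.items())}

    mono_c = verdicts(ct, common)
    mono_s = verdicts(st, common)

    displaced: list[str] = []
    remaining = set(common)

    def disagreement(ctree, stree, leaves):
        """(monophyly violations, RF) — (0, 0) means full agreement."""
        v = verdicts(ctree, leaves)
        w = verdicts(stree, leaves)
        viol = sum(1 for g in v if not (v[g] and w[g]))
        try:
            d = rf_distance(ctree, stree)
        except PhyloError:
            d = 0
        return (viol, d)

    cur_ct, cur_st = ct, st
    cur = disagreement(cur_ct, cur_st, remaining)
    while cur > (0, 0) and len(remaining) > 4:
        best_leaf, best_score = None, None
        for leaf in sorted(remaining):
            trial = remaining - {leaf}
            score = disagreement(_pruned(cur_ct, trial),
                                 _pruned(cur_st, trial), trial)
            if best_score is None or score < best_score:
                best_leaf, best_score = leaf, score
        if best_leaf is None or best_score >= cur:
            break   # no single removal improves agreement
        displaced.append(best_leaf)
        remaining -= {best_leaf}
        cur_ct, cur_st = _pruned(cur_ct, remaining), _pruned(cur_st, remaining)
        cur = best_score
    return CongruenceReport(rf=rf, normalized_rf=nrf,
                            genus_monophyly_cluster=mono_c,
                            genus_monophyly_species=mono_s,
                            displaced_leaves=displaced)
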