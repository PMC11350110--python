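"""Independent brute-force oracles used to check the library's fast paths.

Everything here is deliberately naive (full dynamic programming, sliding
windows, exhaustive enumeration) and shares no code with the implementation
it checks.
"""

from __future__ import annotations

_COMP = str.maketrans("ACGTN", "TGCAN")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Full-DP pairwise alignment (match +1 / mismatch -1 / gap -2)


def dp_align(a: str, b: str, mode: str = "global",
             match: int = 1, mismatch: int = -1, gap: int = -2):
    """Return (score, identity_percent) under the simple scoring scheme.

    Identity is matches / aligned columns, end gaps excluded (global) or
    within the best local path (local). Traceback prefers diagonal, then
    up, then left (ties broken consistently; identity of co-optimal paths
    can differ only when the implementation also faces a tie, so tests
    should compare scores exactly and identities loosely where ties are
    possible).
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    score = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        score[i][0] = gap * i if mode == "global" else 0.0
    for j in range(1, m + 1):
        score[0][j] = gap * j if mode == "global" else 0.0
    best, best_ij = 0.0, (0, 0)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            d = score[i - 1][j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            u = score[i - 1][j] + gap
            l = score[i][j - 1] + gap
            s = max(d, u, l)
            if mode == "local":
                s = max(s, 0.0)
            score[i][j] = s
            if s >= best:
                best, best_ij = s, (i, j)
    if mode == "global":
        end_i, end_j = n, m
        final = score[n][m]
    else:
        end_i, end_j = best_ij
        final = best
    # traceback for identity
    i, j = end_i, end_j
    cols = []
    while i > 0 and j > 0:
        if mode == "local" and score[i][j] == 0:
            break
        d = score[i - 1][j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
        if score[i][j] == d:
            cols.append(("m", a[i - 1] == b[j - 1]))
            i, j = i - 1, j - 1
        elif score[i][j] == score[i - 1][j] + gap:
            cols.append(("g", False))
            i -= 1
        else:
            cols.append(("g", False))
            j -= 1
    if mode == "global":
        # drop leading/trailing pure-gap runs (end gaps)
        cols.reverse()
        while cols and cols[0][0] == "g":
            cols.pop(0)
        while cols and cols[-1][0] == "g":
            cols.pop()
    n_cols = len(cols)
    n_match = sum(1 for k, eq in cols if k == "m" and eq)
    identity = 100.0 * n_match / n_cols if n_cols else 0.0
    return final, identity


# ---------------------------------------------------------------------------
# Six-frame ORF scan


def six_frame_orfs(seq: str, min_length: int = 150) -> set[tuple]:
    """(start, end, strand) of every maximal start..stop ORF >= min_length.

    One ORF per stop-bounded region per frame: first ATG/GTG/TTG after the
    previous stop, ending at (and including) the stop codon.
    """
    seq = seq.upper()
    out = set()
    for strand in ("+", "-"):
        s = seq if strand == "+" else rc(seq)
        n = len(s)
        for frame in range(3):
            prev_stop_end = frame
            i = frame
            while i + 3 <= n:
                if s[i:i + 3] in ("TAA", "TAG", "TGA"):
                    region = range(prev_stop_end, i, 3)
                    for j in region:
                        if s[j:j + 3] in ("ATG", "GTG", "TTG"):
                            if (i + 3 - j) >= min_length:
                                if strand == "+":
                                    out.add((j, i + 3, "+"))
                                else:
                                    out.add((n - (i + 3), n - j, "-"))
                            break
                    prev_stop_end = i + 3
                i += 3
    return out


# ---------------------------------------------------------------------------
# Naive restriction-site scan


def naive_find_sites(seq: str, site: str) -> list[int]:
    """O(n*m) sliding-window IUPAC match on both strands, deduplicated."""
    seq = seq.upper()
    site = site.upper()
    rsite = "".join({"A": "T", "C": "G", "G": "C", "T": "A",
                     "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M",
                     "M": "K", "B": "V", "D": "H", "H": "D", "V": "B",
                     "N": "N"}[c] for c in reversed(site))
    hits = set()
    for pat in {site, rsite}:
        m = len(pat)
        for i in range(len(seq) - m + 1):
            if all(seq[i + k] in IUPAC[pat[k]] for k in range(m)):
                hits.add(i)
    return sorted(hits)


# ---------------------------------------------------------------------------
# Tree bipartitions by exhaustive recursion (for RF oracle)


def newick_splits(newick: str) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, canonical smaller side."""
    import dendropy
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    leaves = frozenset(t.label for t in tree.taxon_namespace)
    splits = set()

    def clade(node):
        if node.is_leaf():
            return frozenset([node.taxon.label])
        got = frozenset().union(*(clade(c) for c in node.child_nodes()))
        if node.parent_node is not None and 1 < len(got) < len(leaves) - 1:
            splits.add(min(got, leaves - got,
                           key=lambda s: (len(s), sorted(s))))
        return got

    clade(tree.seed_node)
    return splits


def brute_rf(nwk1: str, nwk2: str) -> int:
    return len(newick_splits(nwk1) ^ newick_splits(nwk2))


def all_quartet_topologies(taxa: list[str]) -> list[str]:
    a, b, c, d = taxa
    return [f"(({a},{b}),({c},{d}));",
            f"(({a},{c}),({b},{d}));",
            f"(({a},{d}),({b},{c}));"]


# ---------------------------------------------------------------------------
# Window scoring oracle for restriction-map localization


def brute_best_window(site_positions: dict[str, list[int]],
                      expected: list[tuple[str, int]], span: int,
                      genome_length: int, slack: int, step: int = 100):
    """Best-scoring window by direct per-window greedy matching."""
    best = (None, float("-inf"))
    for ws in range(0, max(1, genome_length - span + 1), step):
        matched = 0
        used: dict[str, set[int]] = {}
        last = ws - 1
        for name, rel in expected:
            target = ws + rel
            cands = [p for p in site_positions.get(name, [])
                     if abs(p - target) <= slack and p > last
                     and p not in used.get(name, set())]
            if cands:
                p = min(cands, key=lambda p: abs(p - target))
                used.setdefault(name, set()).add(p)
                matched += 1
                last = p
        in_window = sum(1 for name, ps in site_positions.items()
                        for p in ps if ws <= p < ws + span)
        missed = len(expected) - matched
        extra = in_window - matched
        s = matched - missed - extra
        if s > best[1]:
            best = (ws, s)
    return best
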