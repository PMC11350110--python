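"""In-silico restriction digestion and map-based cluster localization.

A published restriction-site pattern over a ~25 kb region can serve as a
locational fingerprint: sliding windows of the genome are scored by how
well their observed sites reproduce the expected ordered pattern, which is
how an undescribed cluster can be pinned down inside an assembly without
any gene-level annotation. Scoring is +1 per matched site, -1 per missed
expected site and -1 per extra observed site, with positional slack equal
to ``tolerance x span``.
"""

from __future__ import annotations

import json
import re
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path

from .io import GenomeRecord

_IUPAC_RE = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


class RestrictionError(ValueError):
    pass


@dataclass(frozen=True)
class RestrictionEnzyme:
    name: str
    site: str           # IUPAC recognition pattern
    cut_offset: int = 0  # bp from site start to the cut on the top strand

    def __post_init__(self) -> None:
        if len(self.site) < 4:
            raise RestrictionError(f"{self.name}: site shorter than 4 bp")
        if not set(self.site.upper()) <= set(_IUPAC_RE):
            raise RestrictionError(f"{self.name}: invalid IUPAC in site")
        if not 0 <= self.cut_offset <= len(self.site):
            raise RestrictionError(f"{self.name}: cut offset outside site")

    @property
    def is_palindromic(self) -> bool:
        return self.site.upper() == _iupac_revcomp(self.site.upper())


def _iupac_revcomp(pat: str) -> str:
    comp = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
    return pat.translate(comp)[::-1]


def find_sites(seq: str, enzyme: RestrictionEnzyme) -> list[int]:
    """0-based start positions of the duplex site, sorted, counted once.

    Palindromic sites occur identically on both strands and are reported
    once; non-palindromic sites are searched on both strands and reported
    at the position of the site on the forward strand.
    """
    if not seq:
        raise RestrictionError("empty sequence")
    s = seq.upper()
    pat = "".join(_IUPAC_RE[c] for c in enzyme.site.upper())
    hits = {m.start() for m in re.finditer(f"(?=({pat}))", s)}
    if not enzyme.is_palindromic:
        rpat = "".join(_IUPAC_RE[c] for c in _iupac_revcomp(enzyme.site.upper()))
        hits |= {m.start() for m in re.finditer(f"(?=({rpat}))", s)}
    return sorted(hits)


def digest(seq: str, enzymes: list[RestrictionEnzyme]) -> list[int]:
    """Ordered fragment lengths of a linear digest; lengths sum to len(seq)."""
    if not enzymes:
        raise RestrictionError("need at least one enzyme")
    cuts: set[int] = set()
    for enz in enzymes:
        for pos in find_sites(seq, enz):
            cut = pos + enz.cut_offset
            if 0 < cut < len(seq):
                cuts.add(cut)
    bounds = [0, *sorted(cuts), len(seq)]
    return [b - a for a, b in zip(bounds, bounds[1:])]


# ---------------------------------------------------------------------------
# Map-based localization


@dataclass
class RestrictionMap:
    """Ordered (enzyme name, position) signature over a region of total span."""
    sites: list[tuple[str, int]]        # positions relative to region start
    span: int
    enzymes: dict[str, RestrictionEnzyme] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pos = [p for _, p in self.sites]
        if pos != sorted(pos) or len(set(pos)) != len(pos):
            raise RestrictionError("map positions must be strictly increasing")
        if any(p < 0 or p > self.span for p in pos):
            raise RestrictionError("map position outside span")

    @property
    def reversed(self) -> "RestrictionMap":
        sites = [(name, self.span - p) for name, p in reversed(self.sites)]
        return RestrictionMap(sites=sites, span=self.span, enzymes=self.enzymes)


def map_from_region(seq: str, enzymes: list[RestrictionEnzyme]
                    ) -> RestrictionMap:
    """Build the site signature of a region (the self-digest fingerprint)."""
    sites = sorted(
        ((enz.name, p) for enz in enzymes for p in find_sites(seq, enz)),
        key=lambda t: t[1])
    return RestrictionMap(sites=sites, span=len(seq),
                          enzymes={e.name: e for e in enzymes})


@dataclass
class MapMatch:
    contig: str
    start: int
    end: int
    orientation: str     # "+" map as given, "-" map read in reverse
    matched: int
    missed: int
    extra: int
    score: int

    @property
    def match_fraction(self) -> float:
        total = self.matched + self.missed
        return self.matched / total if total else 0.0


def _score_window(expected: list[tuple[str, int]],
                  observed: dict[str, list[int]],
                  win_start: int, span: int, slack: int) -> tuple[int, int, int]:
    """Order-preserving greedy matching of expected to observed sites."""
    used: dict[str, set[int]] = {e: set() for e in observed}
    matched = missed = 0
    last_abs = win_start - 1
    for name, rel in expected:
        target = win_start + rel
        obs = observed.get(name, [])
        lo = bisect_left(obs, max(target - slack, last_abs + 1))
        hi = bisect_right(obs, target + slack)
        best = None
        for i in range(lo, hi):
            if i in used.get(name, set()):
                continue
            if best is None or abs(obs[i] - target) < abs(obs[best] - target):
                best = i
        if best is None:
            missed += 1
        else:
            matched += 1
            used.setdefault(name, set()).add(best)
            last_abs = obs[best]
    extra = 0
    for name, obs in observed.items():
        lo = bisect_left(obs, win_start)
        hi = bisect_right(obs, win_start + span)
        extra += (hi - lo) - len([i for i in used.get(name, set())
                                  if lo <= i < hi])
    return matched, missed, extra


def locate_by_map(genome: GenomeRecord, rmap: RestrictionMap,
                  tolerance: float = 0.05, step: int | None = None,
                  enzymes: list[RestrictionEnzyme] | None = None
                  ) -> list[MapMatch]:
    """Rank genome windows by how well they reproduce the site pattern.

    Windows of length ``span`` slide along every contig; each is scored in
    both orientations (a region found on the reverse strand reproduces the
    map read in reverse). Deterministic ordering: score desc, then contig,
    then position.
    """
    if not 0 < tolerance < 0.5:
        raise RestrictionError("tolerance must be in (0, 0.5)")
    if len(rmap.sites) < 2:
        raise RestrictionError("map with < 2 sites is under-determined")
    enz_map = {e.name: e for e in enzymes} if enzymes else rmap.enzymes
    missing = {n for n, _ in rmap.sites} - set(enz_map)
    if missing:
        raise RestrictionError(f"no enzyme definition for {sorted(missing)}")
    span = rmap.span
    slack = int(tolerance * span)
    step = step or max(100, slack // 2)
    results: list[MapMatch] = []
    for contig_id, seq in genome.contigs:
        if len(seq) < span // 2:
            continue
        observed = {name: find_sites(seq, enz_map[name])
                    for name in {n for n, _ in rmap.sites}}
        for orientation, sites in (("+", rmap.sites), ("-", rmap.reversed.sites)):
            for ws in range(0, max(1, len(seq) - span + 1), step):
                matched, missed_, extra = _score_window(
                    sites, observed, ws, span, slack)
                results.append(MapMatch(
                    contig=contig_id, start=ws, end=min(ws + span, len(seq)),
                    orientation=orientation, matched=matched, missed=missed_,
                    extra=extra, score=matched - missed_ - extra))
    results.sort(key=lambda m: (-m.score, m.contig, m.start, m.orientation))
    return _suppress_overlaps(results)


def _suppress_overlaps(matches: list[MapMatch]) -> list[MapMatch]:
    """Keep the best-scoring window per overlapping stack."""
    kept: list[MapMatch] = []
    for m in matches:
        if any(k.contig == m.contig and k.start < m.end and m.start < k.end
               for k in kept):
            continue
        kept.append(m)
    return kept


# ---------------------------------------------------------------------------
# JSON dialect


def parse_restriction_map(path: str | Path) -> RestrictionMap:
    with open(path) as fh:
        doc = json.load(fh)
    enzymes = {e["name"]: RestrictionEnzyme(e["name"], e["site"],
                                            int(e.get("cut_offset", 0)))
               for e in doc.get("enzymes", [])}
    sites = [(s["enzyme"], int(s["position"])) for s in doc["sites"]]
    return RestrictionMap(sites=sites, span=int(doc["span"]), enzymes=enzymes)


def write_restriction_map(rmap: RestrictionMap, path: str | Path) -> None:
    doc = {
        "span": rmap.span,
        "enzymes": [{"name": e.name, "site": e.site, "cut_offset": e.cut_offset}
                    for e in rmap.enzymes.values()],
        "sites": [{"enzyme": n, "position": p} for n, p in rmap.sites],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")
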