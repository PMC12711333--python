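"""Pedigree simulation and meiotic transmission of haplotype mosaics.

A pedigree is a set of individuals connected by parent relations; haplotypes
are dropped through it by simulated meiosis under the Haldane model
(crossover count per chromosome ~ Poisson(length/100), positions uniform,
no interference).  Each founder carries two uniquely labelled haplotypes, so
identity by descent (IBD) between any two descendants is exactly traceable:
a genomic interval is IBD when both individuals carry a copy of the same
founder haplotype there.

The "half-identical" convention is used throughout: a position counts as
shared when at least one of the four haplotype pairings between two diploid
individuals matches.  This mirrors what imputation-based segment callers
detect in ancient-DNA data; regions identical on both pairings (IBD2) are
counted once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import deque

import numpy as np

from .genmap import GeneticMap

# A mosaic maps chromosome -> ordered disjoint intervals (start, end, founder
# haplotype label) tiling [0, length) exactly.
Interval = tuple[float, float, str]
Mosaic = dict[str, list[Interval]]

_TOL = 1e-9


@dataclass(frozen=True)
class IBDSegment:
    """One shared genome segment between a pair of individuals."""

    iid1: str
    iid2: str
    ch: str
    start_cm: float
    end_cm: float

    @property
    def length_cm(self) -> float:
        return self.end_cm - self.start_cm


@dataclass
class Pedigree:
    """Acyclic parent structure with generation and family bookkeeping.

    ``parents[i]`` is ``None`` for founders and a ``(father, mother)`` pair
    otherwise; every non-founder has exactly two parents.
    """

    parents: dict[str, tuple[str, str] | None]
    generation: dict[str, int]
    family: dict[str, str] = field(default_factory=dict)

    @property
    def members(self) -> list[str]:
        return sorted(self.parents)

    @property
    def founders(self) -> list[str]:
        return sorted(i for i, p in self.parents.items() if p is None)

    def validate(self) -> None:
        for ind, par in self.parents.items():
            if par is not None:
                fa, mo = par
                for p in (fa, mo):
                    if p not in self.parents:
                        raise ValueError(f"parent {p!r} of {ind!r} not in pedigree")
                    if self.generation[p] >= self.generation[ind]:
                        raise ValueError(f"parent {p!r} not older than {ind!r}")

    def ancestor_depths(self, ind: str) -> dict[str, int]:
        """Minimum number of meioses from ``ind`` up to each ancestor (incl. self at 0)."""
        depths = {ind: 0}
        queue = deque([ind])
        while queue:
            cur = queue.popleft()
            par = self.parents[cur]
            if par is None:
                continue
            for p in par:
                d = depths[cur] + 1
                if p not in depths or d < depths[p]:
                    depths[p] = d
                    queue.append(p)
        return depths

    def meiotic_distance(self, a: str, b: str) -> int | None:
        """Number of meioses on the shortest genealogical path linking a and b.

        Parent-child = 1, full sibs = 2, first cousins = 4.  ``None`` when no
        common ancestor exists (genealogically unrelated).
        """
        if a == b:
            return 0
        da, db = self.ancestor_depths(a), self.ancestor_depths(b)
        common = set(da) & set(db)
        if not common:
            return None
        return min(da[x] + db[x] for x in common)

    def related_pairs(self, max_meioses: int | None = None):
        """Yield (a, b, meioses) over all related unordered pairs."""
        mem = self.members
        for i, a in enumerate(mem):
            for b in mem[i + 1:]:
                m = self.meiotic_distance(a, b)
                if m is not None and (max_meioses is None or m <= max_meioses):
                    yield a, b, m


def simulate_pedigree(
    n_families: int = 1,
    generations: int = 2,
    children_per_couple: int = 2,
    cross_family_rate: float = 0.0,
    n_cross_marriages: int | None = None,
    seed: int = 0,
) -> Pedigree:
    """Simulate a multi-family pedigree.

    Each family starts from one founder couple (generation 0).  Every couple
    has ``children_per_couple`` children; children of non-terminal generations
    marry either a fresh unrelated founder spouse, a child from another
    family (with probability ``cross_family_rate``, or exactly
    ``n_cross_marriages`` such marriages when given).  Cross-family couples
    and their offspring are assigned to the first partner's family.

    Deterministic given ``seed``.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if generations >= 2 and children_per_couple < 1:
        raise ValueError(
            "children_per_couple must be >= 1 when generations >= 2 "
            "(children need two available parents)"
        )
    if not 0.0 <= cross_family_rate <= 1.0:
        raise ValueError("cross_family_rate must be in [0, 1]")

    rng = np.random.default_rng(seed)
    parents: dict[str, tuple[str, str] | None] = {}
    generation: dict[str, int] = {}
    family: dict[str, str] = {}

    def add(ind: str, fam: str, gen: int, par: tuple[str, str] | None) -> None:
        parents[ind] = par
        generation[ind] = gen
        family[ind] = fam

    fams = [f"F{i}" for i in range(n_families)]
    couples: dict[str, list[tuple[str, str]]] = {}
    for fam in fams:
        a, b = f"{fam}_G0_P0", f"{fam}_G0_P1"
        add(a, fam, 0, None)
        add(b, fam, 0, None)
        couples[fam] = [(a, b)]

    for g in range(1, generations):
        kids: dict[str, list[str]] = {fam: [] for fam in fams}
        for fam in fams:
            idx = 0
            for fa, mo in couples[fam]:
                for _ in range(children_per_couple):
                    kid = f"{fam}_G{g}C{idx}"
                    idx += 1
                    add(kid, fam, g, (fa, mo))
                    kids[fam].append(kid)
        if g == generations - 1:
            break  # terminal generation does not marry

        # cross-family marriages: pair children from different families
        cross_couples: list[tuple[str, str]] = []
        if n_families > 1:
            avail = {fam: list(rng.permutation(kids[fam])) for fam in fams}
            if n_cross_marriages is not None:
                # only the last marrying generation hosts the requested marriages
                want = n_cross_marriages if g == generations - 2 else 0
                for _ in range(want):
                    nonempty = sorted(f for f in fams if avail[f])
                    if len(nonempty) < 2:
                        break
                    fa_a, fa_b = rng.choice(nonempty, size=2, replace=False)
                    cross_couples.append((avail[fa_a].pop(0), avail[fa_b].pop(0)))
            elif cross_family_rate > 0:
                crossers = [
                    k for fam in fams for k in avail[fam]
                    if rng.random() < cross_family_rate
                ]
                by_fam = {fam: [k for k in crossers if family[k] == fam] for fam in fams}
                while True:
                    ranked = sorted(
                        (f for f in fams if by_fam[f]),
                        key=lambda f: -len(by_fam[f]),
                    )
                    if len(ranked) < 2:
                        break
                    cross_couples.append(
                        (by_fam[ranked[0]].pop(0), by_fam[ranked[1]].pop(0))
                    )
        married = {x for c in cross_couples for x in c}

        new_couples: dict[str, list[tuple[str, str]]] = {fam: [] for fam in fams}
        for a, b in cross_couples:
            new_couples[family[a]].append((a, b))
        for fam in fams:
            sidx = 0
            for k in kids[fam]:
                if k in married:
                    continue
                sp = f"{fam}_G{g}S{sidx}"
                sidx += 1
                add(sp, fam, g, None)
                new_couples[fam].append((k, sp))
        couples = new_couples

    ped = Pedigree(parents=parents, generation=generation, family=family)
    ped.validate()
    return ped


# ---------------------------------------------------------------------------
# meiosis and haplotype dropping


def founder_mosaics(ind: str, gmap: GeneticMap) -> tuple[Mosaic, Mosaic]:
    """Two whole-chromosome mosaics with unique labels ``ind|0`` and ``ind|1``."""
    h0 = {ch: [(0.0, L, f"{ind}|0")] for ch, L in gmap.chromosomes}
    h1 = {ch: [(0.0, L, f"{ind}|1")] for ch, L in gmap.chromosomes}
    return h0, h1


def _slice(intervals: list[Interval], a: float, b: float) -> list[Interval]:
    out = []
    for s, e, lab in intervals:
        if e <= a or s >= b:
            continue
        out.append((max(s, a), min(e, b), lab))
    return out


def _merge_adjacent(intervals: list[Interval]) -> list[Interval]:
    out: list[Interval] = []
    for s, e, lab in intervals:
        if out and out[-1][2] == lab and abs(out[-1][1] - s) < _TOL:
            out[-1] = (out[-1][0], e, lab)
        else:
            out.append((s, e, lab))
    return out


def meiosis(
    haplotypes: tuple[Mosaic, Mosaic], gmap: GeneticMap, rng: np.random.Generator
) -> Mosaic:
    """One gamete from a parent's two haplotype mosaics (Haldane model)."""
    hap0, hap1 = haplotypes
    gamete: Mosaic = {}
    for ch, L in gmap.chromosomes:
        n_x = rng.poisson(L / 100.0)
        xs = np.sort(rng.uniform(0.0, L, n_x)) if n_x else np.empty(0)
        cur = int(rng.integers(2))
        segs: list[Interval] = []
        prev = 0.0
        for x in list(xs) + [L]:
            src = hap0[ch] if cur == 0 else hap1[ch]
            segs.extend(_slice(src, prev, float(x)))
            cur ^= 1
            prev = float(x)
        gamete[ch] = _merge_adjacent(segs)
    return gamete


def drop_haplotypes(
    ped: Pedigree, gmap: GeneticMap, seed: int = 0
) -> dict[str, tuple[Mosaic, Mosaic]]:
    """Assign founder haplotypes and transmit them through the pedigree.

    Individuals are processed in (generation, id) order so the result is
    deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    haps: dict[str, tuple[Mosaic, Mosaic]] = {}
    for ind in sorted(ped.parents, key=lambda i: (ped.generation[i], i)):
        par = ped.parents[ind]
        if par is None:
            haps[ind] = founder_mosaics(ind, gmap)
        else:
            fa, mo = par
            haps[ind] = (meiosis(haps[fa], gmap, rng), meiosis(haps[mo], gmap, rng))
    return haps


# ---------------------------------------------------------------------------
# true IBD extraction


def _label_matches(a: list[Interval], b: list[Interval]) -> list[tuple[float, float]]:
    """Overlaps of two sorted interval lists where founder labels agree."""
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e - s > _TOL and a[i][2] == b[j][2]:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _union(ivs: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1] + _TOL:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def true_ibd_segments(
    ind1: tuple[Mosaic, Mosaic],
    ind2: tuple[Mosaic, Mosaic],
    iid1: str = "ind1",
    iid2: str = "ind2",
    min_cm: float = 0.0,
) -> list[IBDSegment]:
    """Half-identical IBD segments between two diploid individuals.

    For each of the four haplotype pairings, intervals carrying the same
    founder-haplotype label are intersected; the union over pairings is
    merged into maximal runs.  Segments shorter than ``min_cm`` are dropped.
    """
    chroms1 = set(ind1[0])
    if chroms1 != set(ind2[0]):
        raise ValueError("individuals are not on the same genetic map")
    if iid2 < iid1:
        iid1, iid2 = iid2, iid1
        ind1, ind2 = ind2, ind1
    segments: list[IBDSegment] = []
    for ch in ind1[0]:
        matched: list[tuple[float, float]] = []
        for h1 in ind1:
            for h2 in ind2:
                matched.extend(_label_matches(h1[ch], h2[ch]))
        for s, e in _union(matched):
            if e - s >= min_cm:
                segments.append(IBDSegment(iid1, iid2, ch, s, e))
    return segments


def pairwise_ibd(
    haplotypes: dict[str, tuple[Mosaic, Mosaic]], min_cm: float = 0.0
) -> list[IBDSegment]:
    """True IBD segments for every unordered pair of individuals."""
    ids = sorted(haplotypes)
    out: list[IBDSegment] = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            out.extend(true_ibd_segments(haplotypes[a], haplotypes[b], a, b, min_cm))
    return out


def ibd_total(segments: list[IBDSegment]) -> float:
    return float(sum(s.length_cm for s in segments))
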