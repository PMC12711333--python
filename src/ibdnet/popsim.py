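"""Allele-frequency simulation under drift with one two-way admixture event,
and pseudo-haploid genotype sampling.

Populations sit on a rooted tree; every branch applies Balding-Nichols
drift: given parent frequency p and drift parameter F, the child frequency
is Beta(p(1-F)/F, (1-p)(1-F)/F), which has mean p and variance F*p*(1-p).
One population may instead be an admixture of two others with proportion
alpha: its frequency is exactly alpha*p_S1 + (1-alpha)*p_S2 at every SNP,
providing an exact ground truth for the two-way estimator.

Genotypes are sampled pseudo-haploid (a single allele per site, coded 0/2 on
the diploid scale, 9 = missing), the standard representation for
low-coverage ancient DNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genmap import GeneticMap, make_genetic_map

MISSING = 9


@dataclass
class AlleleFreqTable:
    """Per-SNP allele frequencies for a set of populations.

    ``snps`` has columns ``snp_id, chrom, cm, block``; ``freqs`` has one
    column per population, row-aligned with ``snps``.  NaN marks a frequency
    that is unusable (e.g. no non-missing calls in that population).
    """

    snps: pd.DataFrame
    freqs: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.snps) != len(self.freqs):
            raise ValueError("snps and freqs must have the same number of rows")
        vals = self.freqs.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=0.0) < -1e-12 or np.nanmax(vals, initial=0.0) > 1 + 1e-12:
                raise ValueError("allele frequencies must lie in [0, 1]")

    @property
    def populations(self) -> list[str]:
        return list(self.freqs.columns)

    @property
    def n_snps(self) -> int:
        return len(self.snps)


@dataclass
class PopulationTree:
    """Rooted drift tree plus at most one two-way admixture event.

    ``branches`` is a list of ``(parent, child, F)``; parents must either be
    the root name or appear as a child earlier in the list.  ``admixture``
    is ``(target, source1, source2, alpha)``; the target's frequencies are
    the exact mixture of the two sources.
    """

    branches: list[tuple[str, str, float]]
    admixture: tuple[str, str, str, float] | None = None
    root: str = "root"

    def __post_init__(self) -> None:
        known = {self.root}
        for parent, child, F in self.branches:
            if parent not in known:
                raise ValueError(f"branch parent {parent!r} defined after child or unknown")
            if child in known:
                raise ValueError(f"duplicate node {child!r}")
            if F < 0:
                raise ValueError(f"negative drift F={F} on branch to {child!r}")
            known.add(child)
        if self.admixture is not None:
            target, s1, s2, alpha = self.admixture
            if not 0.0 <= alpha <= 1.0:
                raise ValueError(f"admixture proportion alpha={alpha} outside [0, 1]")
            for s in (s1, s2):
                if s not in known:
                    raise ValueError(f"admixture source {s!r} not in tree")
            if target in known:
                raise ValueError(f"admixture target {target!r} collides with a tree node")

    @property
    def leaves(self) -> list[str]:
        parents = {p for p, _, _ in self.branches}
        nodes = [c for _, c, _ in self.branches]
        out = [n for n in nodes if n not in parents]
        if self.admixture is not None:
            out.append(self.admixture[0])
        return out


def two_way_tree(
    alpha: float,
    drift: float = 0.02,
    n_outgroups: int = 6,
    base: str = "Base",
    base_drift: float = 0.1,
) -> PopulationTree:
    """Standard layout for two-way admixture experiments.

    Two internal lineages L and R split from the root; Source1 and half of
    the outgroups descend from L, Source2 and the rest from R, so outgroups
    are differentially related to the sources (the identifying condition of
    the estimator).  ``base`` is a deep outgroup off the root.  The target
    is the exact alpha:(1-alpha) mixture of Source1 and Source2.
    """
    half = n_outgroups // 2
    branches = [("root", base, base_drift), ("root", "L", drift), ("root", "R", drift),
                ("L", "Source1", drift), ("R", "Source2", drift)]
    for i in range(n_outgroups):
        parent = "L" if i < half else "R"
        branches.append((parent, f"OG{i}", drift))
    return PopulationTree(branches, admixture=("Target", "Source1", "Source2", alpha))


def _balding_nichols(
    p: np.ndarray, F: float, rng: np.random.Generator
) -> np.ndarray:
    if F == 0:
        return p.copy()
    a = p * (1.0 - F) / F
    b = (1.0 - p) * (1.0 - F) / F
    return rng.beta(a, b)


def simulate_allele_freqs(
    pop_tree: PopulationTree,
    n_snps: int,
    seed: int = 0,
    gmap: GeneticMap | None = None,
    snps_per_block: int = 100,
    keep: str = "leaves",
) -> AlleleFreqTable:
    """Simulate an allele-frequency table on the tree.

    Ancestral frequencies are Uniform(0.05, 0.95); each branch applies
    Balding-Nichols drift; the admixed population is the exact linear
    mixture of its sources.  SNP positions are uniform on the genetic map
    (sorted within chromosomes); jackknife blocks are assigned by a fixed
    SNP count per block, never spanning chromosomes.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    gmap = gmap or make_genetic_map()
    rng = np.random.default_rng(seed)

    # SNP placement: chromosomes drawn proportional to genetic length
    names = [c for c, _ in gmap.chromosomes]
    lengths = np.array([L for _, L in gmap.chromosomes])
    counts = rng.multinomial(n_snps, lengths / lengths.sum())
    chrom_col, cm_col, block_col = [], [], []
    block_offset = 0
    for name, L, k in zip(names, lengths, counts):
        if k == 0:
            continue
        pos = np.sort(rng.uniform(0.0, L, k))
        chrom_col.extend([name] * k)
        cm_col.extend(pos.tolist())
        block_col.extend((block_offset + np.arange(k) // snps_per_block).tolist())
        block_offset = block_col[-1] + 1
    snps = pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(n_snps)],
            "chrom": chrom_col,
            "cm": cm_col,
            "block": np.asarray(block_col, dtype=int),
        }
    )

    freqs = {pop_tree.root: rng.uniform(0.05, 0.95, n_snps)}
    for parent, child, F in pop_tree.branches:
        freqs[child] = _balding_nichols(freqs[parent], F, rng)
    if pop_tree.admixture is not None:
        target, s1, s2, alpha = pop_tree.admixture
        freqs[target] = alpha * freqs[s1] + (1.0 - alpha) * freqs[s2]

    cols = pop_tree.leaves if keep == "leaves" else [
        c for _, c, _ in pop_tree.branches
    ] + ([pop_tree.admixture[0]] if pop_tree.admixture else [])
    return AlleleFreqTable(snps=snps, freqs=pd.DataFrame({c: freqs[c] for c in cols}))


@dataclass
class GenotypeMatrix:
    """SNPs x individuals genotype calls on the diploid scale.

    Pseudo-haploid mode emits only {0, 2, 9}; diploid mode {0, 1, 2, 9};
    9 is missing.  ``calls`` is laid out (n_snps, n_individuals), matching
    the EIGENSTRAT geno file orientation.
    """

    calls: np.ndarray
    individuals: list[str]
    populations: list[str]
    snps: pd.DataFrame
    ploidy: str = "pseudohaploid"

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.snps), len(self.individuals)):
            raise ValueError("calls shape does not match snps x individuals")
        if len(self.populations) != len(self.individuals):
            raise ValueError("one population label required per individual")
        allowed = {0, 2, MISSING} if self.ploidy == "pseudohaploid" else {0, 1, 2, MISSING}
        bad = set(np.unique(self.calls)) - allowed
        if bad:
            raise ValueError(f"invalid genotype codes for {self.ploidy} mode: {sorted(bad)}")

    def missing_rate(self) -> np.ndarray:
        """Per-individual missingness fraction."""
        return (self.calls == MISSING).mean(axis=0)


def sample_pseudohaploid(
    freqs: AlleleFreqTable,
    n_per_pop: int | dict[str, int],
    missing_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Draw pseudo-haploid genotypes from population allele frequencies.

    One allele per individual per SNP: Bernoulli(p) coded {0, 2}; entries
    are then masked missing independently at ``missing_rate``.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_snps = freqs.n_snps
    individuals, pops, cols = [], [], []
    for pop in freqs.populations:
        n = n_per_pop[pop] if isinstance(n_per_pop, dict) else n_per_pop
        p = freqs.freqs[pop].to_numpy()
        for i in range(n):
            calls = 2 * (rng.random(n_snps) < p).astype(np.int8)
            if missing_rate > 0:
                calls[rng.random(n_snps) < missing_rate] = MISSING
            calls[np.isnan(p)] = MISSING
            individuals.append(f"{pop}_{i}")
            pops.append(pop)
            cols.append(calls)
    return GenotypeMatrix(
        calls=np.column_stack(cols).astype(np.int8),
        individuals=individuals,
        populations=pops,
        snps=freqs.snps.copy(),
    )
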