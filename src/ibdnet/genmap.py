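"""Genetic map: chromosome lengths in centimorgans (cM).

All downstream coordinates (crossover positions, IBD segment bounds, SNP
positions, jackknife blocks) live in this cM coordinate system.  The default
map is a fixed table of sex-averaged genetic lengths for the 22 human
autosomes; it is a documented stand-in for panel-specific maps, adequate
because every quantity of interest (segment-length distributions, block
counts) depends only on chromosome lengths, not on local recombination-rate
variation.
"""

from __future__ import annotations

from dataclasses import dataclass

# Sex-averaged autosome lengths in cM; total 3545.4 cM.
DEFAULT_AUTOSOME_CM: tuple[tuple[str, float], ...] = (
    ("1", 286.3), ("2", 268.6), ("3", 223.4), ("4", 214.6), ("5", 204.1),
    ("6", 192.0), ("7", 187.2), ("8", 168.0), ("9", 166.4), ("10", 181.1),
    ("11", 158.2), ("12", 174.7), ("13", 125.9), ("14", 120.2), ("15", 141.9),
    ("16", 134.0), ("17", 128.5), ("18", 117.2), ("19", 107.9), ("20", 108.3),
    ("21", 62.8), ("22", 74.1),
)


@dataclass(frozen=True)
class GeneticMap:
    """Ordered set of chromosomes with genetic lengths in cM.

    The X chromosome is deliberately absent from the default: the IBD
    analyses here are autosomal.
    """

    chromosomes: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genetic map must contain at least one chromosome")
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in genetic map")
        for name, length in self.chromosomes:
            if not length > 0:
                raise ValueError(
                    f"chromosome {name!r} has non-positive length {length} cM"
                )

    @property
    def total_cm(self) -> float:
        """Total map length L in cM."""
        return float(sum(length for _, length in self.chromosomes))

    @property
    def lengths(self) -> dict[str, float]:
        return dict(self.chromosomes)

    def __len__(self) -> int:
        return len(self.chromosomes)


def make_genetic_map(lengths: list[float] | None = None) -> GeneticMap:
    """Build a genetic map.

    With no argument, returns the built-in 22-autosome default.  With a list
    of cM lengths, chromosomes are named "1", "2", ... in order.
    """
    if lengths is None:
        return GeneticMap(DEFAULT_AUTOSOME_CM)
    return GeneticMap(tuple((str(i + 1), float(x)) for i, x in enumerate(lengths)))
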