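"""Doubled-haploid genome and genotype simulation.

A doubled-haploid (DH) line is fully homozygous, so each marker locus takes
one of two states, coded -1 / +1 (Cockerham scaling for a diallelic
homozygous population).  Genotypes are simulated chromosome by chromosome as
a two-state Markov chain along equally spaced markers: the first marker of a
chromosome is +-1 with probability 1/2, and adjacent markers recombine with
the Haldane map-function frequency r(d) = (1 - exp(-2 d)) / 2 at inter-marker
distance d (Morgans).  Chromosomes assort independently.  Because doubling a
single recombinant gamete is deterministic, one gamete per line is simulated
directly; the distribution of the +-1 codes is identical to simulating F1
meiosis and then doubling.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ConstraintViolation

__all__ = [
    "GenomeSpec",
    "DHPopulation",
    "haldane",
    "simulate_dh_genotypes",
    "place_qtl",
    "export_genotypes",
    "export_plink",
]


def haldane(d: float | np.ndarray) -> float | np.ndarray:
    """Recombination frequency at map distance ``d`` (Morgans), Haldane model."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d, dtype=float)))


@dataclass(frozen=True)
class GenomeSpec:
    """Layout of the simulated genome.

    Parameters
    ----------
    n_markers:
        Total number of marker loci, ``m``.
    n_chromosomes:
        Number of linkage groups (default 10).
    map_length_per_chromosome:
        Genetic length of every chromosome, in Morgans (default 1.0).
    remainder_policy:
        ``"strict"`` rejects an ``m`` that is not divisible by the chromosome
        count; ``"spread"`` gives the first ``m mod n_chromosomes``
        chromosomes one extra marker.
    """

    n_markers: int
    n_chromosomes: int = 10
    map_length_per_chromosome: float = 1.0
    remainder_policy: str = "strict"

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.n_markers < 1:
            raise ConfigurationError("n_markers and n_chromosomes must be positive")
        if self.map_length_per_chromosome <= 0:
            raise ConfigurationError("map_length_per_chromosome must be positive")
        if self.remainder_policy not in ("strict", "spread"):
            raise ConfigurationError(f"unknown remainder_policy {self.remainder_policy!r}")
        if self.remainder_policy == "strict" and self.n_markers % self.n_chromosomes:
            raise ConfigurationError(
                f"{self.n_markers} markers cannot be split evenly over "
                f"{self.n_chromosomes} chromosomes; use remainder_policy='spread'"
            )

    @property
    def markers_per_chromosome(self) -> list[int]:
        base, rem = divmod(self.n_markers, self.n_chromosomes)
        return [base + (1 if i < rem else 0) for i in range(self.n_chromosomes)]

    def marker_map(self) -> pd.DataFrame:
        """Per-marker (chromosome, position) table; positions in centimorgans."""
        rows = []
        idx = 0
        for chrom, mc in enumerate(self.markers_per_chromosome, start=1):
            spacing = self.map_length_per_chromosome / (mc - 1) if mc > 1 else 0.0
            for j in range(mc):
                rows.append((f"M{idx}", chrom, 100.0 * j * spacing))
                idx += 1
        return pd.DataFrame(rows, columns=["marker_id", "chromosome", "position_cM"])


@dataclass
class DHPopulation:
    """A simulated DH progeny set.

    ``genotypes`` is an n x m matrix with entries in {-1, +1}; ``qtl_indices``
    (if set) are marker column indices, sorted in genome order.
    """

    genotypes: np.ndarray
    marker_map: pd.DataFrame
    spec: GenomeSpec
    qtl_indices: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes, dtype=np.float64)
        if g.ndim != 2:
            raise ConfigurationError("genotypes must be a 2-D matrix")
        if not np.isin(g, (-1.0, 1.0)).all():
            raise ConfigurationError("DH genotype codes must all be -1 or +1")
        self.genotypes = g
        if self.qtl_indices is not None:
            q = np.asarray(self.qtl_indices, dtype=np.intp)
            if q.size > self.n_markers:
                raise ConstraintViolation("qtl must not exceed the number of markers")
            self.qtl_indices = np.sort(q)

    @property
    def n_lines(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_qtl(self) -> int:
        return 0 if self.qtl_indices is None else int(self.qtl_indices.size)


def simulate_dh_genotypes(
    spec: GenomeSpec,
    n: int,
    seed: int | np.random.Generator | np.random.SeedSequence = 0,
) -> DHPopulation:
    """Simulate ``n`` DH lines on the genome described by ``spec``.

    Each chromosome is an independent first-order Markov chain over the
    equally spaced markers, with switch probability given by the Haldane map
    function at the inter-marker distance.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = _as_rng(seed)
    blocks = []
    for mc in spec.markers_per_chromosome:
        start = rng.integers(0, 2, size=n) * 2.0 - 1.0
        if mc == 1:
            blocks.append(start[:, None])
            continue
        d = spec.map_length_per_chromosome / (mc - 1)
        r = haldane(d)
        flips = rng.random((n, mc - 1)) < r
        # cumulative product of -1 at every recombination event
        signs = np.cumprod(np.where(flips, -1.0, 1.0), axis=1)
        blocks.append(np.concatenate([start[:, None], start[:, None] * signs], axis=1))
    genotypes = np.concatenate(blocks, axis=1)
    stored_seed = seed if isinstance(seed, int) else None
    return DHPopulation(genotypes, spec.marker_map(), spec, seed=stored_seed)


def place_qtl(
    pop: DHPopulation,
    q: int,
    rule: str = "evenly_spaced",
    seed: int | np.random.Generator | np.random.SeedSequence = 0,
) -> DHPopulation:
    """Return a copy of ``pop`` with ``q`` QTL placed at marker loci.

    ``evenly_spaced`` places QTL deterministically at indices
    ``floor(i * m / q)``; ``random`` draws a uniform sample of marker indices
    without replacement and sorts it.  QTL are always a subset of the marker
    panel (q <= m).
    """
    m = pop.n_markers
    if not 1 <= q <= m:
        raise ConstraintViolation(f"need 1 <= q <= m, got q={q}, m={m}")
    if rule == "evenly_spaced":
        idx = np.array([(i * m) // q for i in range(q)], dtype=np.intp)
    elif rule == "random":
        rng = _as_rng(seed)
        idx = np.sort(rng.choice(m, size=q, replace=False))
    else:
        raise ConfigurationError(f"unknown placement rule {rule!r}")
    return dataclasses.replace(pop, qtl_indices=idx)


def export_genotypes(pop: DHPopulation, genotype_path, map_path=None) -> None:
    """Write genotypes (lines x markers CSV) and optionally the marker map."""
    df = pd.DataFrame(
        pop.genotypes.astype(int),
        index=[f"L{i}" for i in range(pop.n_lines)],
        columns=pop.marker_map["marker_id"],
    )
    df.to_csv(genotype_path, index_label="line_id")
    if map_path is not None:
        pop.marker_map.to_csv(map_path, index=False)


def export_plink(pop: DHPopulation, prefix: str) -> None:
    """PLINK-style .ped/.map export (alleles A/B, fully homozygous)."""
    alleles = np.where(pop.genotypes > 0, "A", "B")
    with open(f"{prefix}.ped", "w") as fh:
        for i in range(pop.n_lines):
            gts = " ".join(f"{a} {a}" for a in alleles[i])
            fh.write(f"FAM L{i} 0 0 0 -9 {gts}\n")
    with open(f"{prefix}.map", "w") as fh:
        for _, row in pop.marker_map.iterrows():
            fh.write(f"{row.chromosome} {row.marker_id} {row.position_cM / 100.0} 0\n")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
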