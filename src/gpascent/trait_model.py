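"""Quantitative-trait architecture on top of a DH population.

The phenotype model is

    Pheno = mu + Xa * a + Xe * epi + eps,

where ``Xa`` holds the -1/+1 codes at the QTL, ``Xe`` holds element-wise
products of the codes of paired neighboring QTL (additive-by-additive
epistasis; a DH population has no heterozygotes, so A x A terms are the only
two-locus interactions available), and the scalar effects ``a`` and ``epi``
are shared by all loci/pairs.  The genetic variance decomposes as

    VG = a^2 Va + epi^2 Vepi + 2 a epi Cov,

with Va/Vepi/Cov the empirical (co)variances of the additive and epistatic
row sums.  Effect scalars are solved so that the epistatic share of
a^2 Va + epi^2 Vepi equals a user-chosen proportion, and the error variance
is set from broad-sense heritability h as Ve = VG (1 - h) / h.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ArchitectureError, ConfigurationError
from .population import DHPopulation

__all__ = [
    "TraitArchitecture",
    "VarianceDecomposition",
    "PhenotypeSet",
    "build_incidence_matrices",
    "qtl_pairs",
    "empirical_variance_components",
    "solve_effect_scalars",
    "simulate_phenotypes",
    "simulate_trait",
    "export_phenotypes",
    "architecture_report",
]


@dataclass
class TraitArchitecture:
    """Effect scalars and structural choices for one simulated trait."""

    a: float
    epi: float
    epi_proportion: float
    h: float
    qtl_pairs: list[tuple[int, int]] = field(default_factory=list)
    mu: float = 0.0

    def __post_init__(self) -> None:
        if self.a < 0 or self.epi < 0:
            raise ConfigurationError("effect scalars must be non-negative")
        if not 0.0 <= self.epi_proportion <= 1.0:
            raise ConfigurationError("epi_proportion must lie in [0, 1]")
        if not 0.0 < self.h <= 1.0:
            raise ConfigurationError("heritability must lie in (0, 1]")
        if (self.epi_proportion == 0.0) != (self.epi == 0.0):
            raise ConfigurationError("epi_proportion == 0 iff epi == 0")
        if (self.epi_proportion == 1.0) != (self.a == 0.0):
            raise ConfigurationError("epi_proportion == 1 iff a == 0")


@dataclass
class VarianceDecomposition:
    """Variance components of the simulated genetic values.

    ``Va``/``Vepi`` are sample variances over lines of the additive and
    epistatic row sums, ``Cov`` their sample covariance; ``VG`` and ``Ve``
    are filled in once effect scalars and heritability are known.
    """

    Va: float
    Vepi: float
    Cov: float
    VG: float = float("nan")
    Ve: float = float("nan")

    def complete(self, a: float, epi: float, h: float) -> "VarianceDecomposition":
        VG = a * a * self.Va + epi * epi * self.Vepi + 2.0 * a * epi * self.Cov
        Ve = VG * (1.0 - h) / h
        return VarianceDecomposition(self.Va, self.Vepi, self.Cov, VG=VG, Ve=Ve)


@dataclass
class PhenotypeSet:
    """Simulated phenotypes and the underlying genetic values."""

    values: np.ndarray
    genetic_values: np.ndarray
    seed: int | None
    variance: VarianceDecomposition | None = None


def qtl_pairs(qtl_indices: np.ndarray, pairing: str = "disjoint") -> list[tuple[int, int]]:
    """Pairs of neighboring QTL in genome order.

    ``disjoint`` pairs consecutive QTL without overlap: (1,2), (3,4), ...
    giving floor(q/2) pairs (an odd trailing QTL stays purely additive).
    ``chain`` uses the sliding chain (1,2), (2,3), ... with q-1 pairs.
    """
    idx = np.sort(np.asarray(qtl_indices, dtype=np.intp))
    if pairing == "disjoint":
        return [(int(idx[i]), int(idx[i + 1])) for i in range(0, len(idx) - 1, 2)]
    if pairing == "chain":
        return [(int(idx[i]), int(idx[i + 1])) for i in range(len(idx) - 1)]
    raise ConfigurationError(f"unknown pairing {pairing!r}")


def build_incidence_matrices(
    pop: DHPopulation, pairing: str = "disjoint"
) -> tuple[np.ndarray, np.ndarray]:
    """Additive (n x q) and epistatic (n x p) incidence matrices.

    Epistatic columns are products of the +-1 codes of paired neighboring
    QTL, so each column is itself a +-1 variable.
    """
    if pop.qtl_indices is None or pop.n_qtl == 0:
        raise ArchitectureError("population has no QTL placed; call place_qtl first")
    Xa = pop.genotypes[:, pop.qtl_indices]
    pairs = qtl_pairs(pop.qtl_indices, pairing)
    if pairs:
        Xe = np.column_stack([pop.genotypes[:, i] * pop.genotypes[:, j] for i, j in pairs])
    else:
        Xe = np.empty((pop.n_lines, 0))
    return Xa, Xe


def empirical_variance_components(Xa: np.ndarray, Xe: np.ndarray) -> VarianceDecomposition:
    """Va, Vepi and Cov from the row sums of the incidence matrices."""
    if Xa.shape[0] < 2:
        raise ConfigurationError("need at least 2 lines to estimate variances")
    sa = Xa.sum(axis=1)
    Va = float(np.var(sa, ddof=1))
    if Xe.size == 0:
        return VarianceDecomposition(Va, 0.0, 0.0)
    se = Xe.sum(axis=1)
    Vepi = float(np.var(se, ddof=1))
    Cov = float(np.cov(sa, se, ddof=1)[0, 1])
    return VarianceDecomposition(Va, Vepi, Cov)


def solve_effect_scalars(
    target_epi_proportion: float, Va: float, Vepi: float
) -> tuple[float, float]:
    """Scalars (a, epi) giving a^2 Va + epi^2 Vepi = 1 with the requested
    epistatic share of that sum.

    The covariance cross-term is deliberately excluded from the share
    definition (it still enters VG when calibrating the error variance).
    """
    t = target_epi_proportion
    if not 0.0 <= t <= 1.0:
        raise ConfigurationError("target epistatic proportion must lie in [0, 1]")
    if t < 1.0 and Va <= 0.0:
        raise ConfigurationError("additive variance is zero but target < 1")
    if t > 0.0 and Vepi <= 0.0:
        raise ConfigurationError("epistatic variance is zero but target > 0")
    a = np.sqrt((1.0 - t) / Va) if t < 1.0 else 0.0
    epi = np.sqrt(t / Vepi) if t > 0.0 else 0.0
    return float(a), float(epi)


def simulate_phenotypes(
    pop: DHPopulation,
    arch: TraitArchitecture,
    seed: int | np.random.Generator | np.random.SeedSequence = 0,
    pairing: str | None = None,
) -> PhenotypeSet:
    """Draw phenotypes for ``pop`` under ``arch``.

    Genetic values are mu + a * rowsum(Xa) + epi * rowsum(Xe); errors are
    i.i.d. Normal(0, Ve) with Ve = VG (1 - h) / h (h = 1 gives noiseless
    phenotypes).  When ``arch.qtl_pairs`` is set those exact pairs are used;
    otherwise pairs are derived from the population with ``pairing``.
    """
    if pop.qtl_indices is None:
        raise ArchitectureError("population has no QTL placed")
    if arch.epi_proportion > 0 and pop.n_qtl < 2:
        raise ArchitectureError("epistasis requested but fewer than 2 QTL available")
    Xa = pop.genotypes[:, pop.qtl_indices]
    pairs = arch.qtl_pairs or qtl_pairs(pop.qtl_indices, pairing or "disjoint")
    if pairs:
        Xe = np.column_stack([pop.genotypes[:, i] * pop.genotypes[:, j] for i, j in pairs])
    else:
        Xe = np.empty((pop.n_lines, 0))
    comp = empirical_variance_components(Xa, Xe).complete(arch.a, arch.epi, arch.h)
    genetic = arch.mu + arch.a * Xa.sum(axis=1)
    if Xe.size:
        genetic = genetic + arch.epi * Xe.sum(axis=1)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if comp.Ve > 0:
        values = genetic + rng.normal(0.0, np.sqrt(comp.Ve), size=genetic.shape)
    else:
        values = genetic.copy()
    stored_seed = seed if isinstance(seed, int) else None
    return PhenotypeSet(values, genetic, stored_seed, variance=comp)


def simulate_trait(
    pop: DHPopulation,
    epi_proportion: float,
    h: float,
    seed: int | np.random.Generator | np.random.SeedSequence = 0,
    pairing: str = "disjoint",
    mu: float = 0.0,
) -> tuple[PhenotypeSet, TraitArchitecture]:
    """Solve effect scalars for the requested architecture and simulate."""
    Xa, Xe = build_incidence_matrices(pop, pairing)
    if epi_proportion > 0 and Xe.shape[1] == 0:
        raise ArchitectureError("epistasis requested but no QTL pair available")
    comp = empirical_variance_components(Xa, Xe)
    a, epi = solve_effect_scalars(epi_proportion, comp.Va, comp.Vepi)
    arch = TraitArchitecture(
        a=a,
        epi=epi,
        epi_proportion=epi_proportion,
        h=h,
        qtl_pairs=qtl_pairs(pop.qtl_indices, pairing),
        mu=mu,
    )
    return simulate_phenotypes(pop, arch, seed), arch


def export_phenotypes(phen: PhenotypeSet, path) -> None:
    """Two-column CSV (line_id, phenotype)."""
    import pandas as pd

    pd.DataFrame(
        {"line_id": [f"L{i}" for i in range(len(phen.values))], "phenotype": phen.values}
    ).to_csv(path, index=False)


def architecture_report(arch: TraitArchitecture, phen: PhenotypeSet) -> dict:
    """JSON-serializable summary of the trait architecture and its variances."""
    v = phen.variance
    vp = float(np.var(phen.values, ddof=1))
    return {
        "a": arch.a,
        "epi": arch.epi,
        "epi_proportion": arch.epi_proportion,
        "mu": arch.mu,
        "target_h": arch.h,
        "Va": v.Va,
        "Vepi": v.Vepi,
        "Cov": v.Cov,
        "VG": v.VG,
        "Ve": v.Ve,
        "realized_h": float(np.var(phen.genetic_values, ddof=1) / vp) if vp > 0 else 1.0,
        "n_qtl_pairs": len(arch.qtl_pairs),
    }
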