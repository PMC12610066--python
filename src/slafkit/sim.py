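"""Structured genotype and toy-genome simulation.

The generator produces diploid SNP panels with the statistical features the
downstream analyses assume: K ancestral gene pools diverged from a common
ancestral allele-frequency spectrum under a Balding-Nichols beta model,
labeled collection populations whose members draw individual ancestry
proportions from population-specific Dirichlet priors (so each labeled
population contains both near-pure and admixed accessions), binomial
genotype sampling from each sample's mixed allele frequency, and independent
per-call missingness.  Monomorphic loci are retained -- removing them is the
downstream MAF filter's job.

Defaults mirror a germplasm panel of 213 accessions from 8 collection sites
(sizes 29, 29, 10, 9, 11, 29, 61, 35 for codes B, E, ES, ED, EY, G, Q, X),
K = 3 ancestral pools at FST 0.1, and 5,000 biallelic SNPs spread over 12
chromosomes named Chr01..Chr12.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .variants import MISSING, GenotypeMatrix, PopulationMap, VariantSite, write_vcf

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_population",
    "simulate_genome",
    "write_dataset",
    "write_fasta",
    "DEFAULT_POP_CODES",
    "DEFAULT_POP_SIZES",
]

DEFAULT_POP_CODES = ("B", "E", "ES", "ED", "EY", "G", "Q", "X")
DEFAULT_POP_SIZES = (29, 29, 10, 9, 11, 29, 61, 35)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the structured-genotype generator.

    ``fst_per_pop`` gives the Balding-Nichols divergence of each ancestral
    pool from the common ancestor; ``admixture_alpha`` scales the Dirichlet
    concentration around each labeled population's base ancestry vector
    (larger -> purer accessions); ``primary_weight`` is the share of the base
    vector on the population's primary ancestral pool.
    """

    n_ancestral_pops: int = 3
    fst_per_pop: tuple[float, ...] | float = 0.1
    pop_sizes: tuple[int, ...] = DEFAULT_POP_SIZES
    pop_codes: tuple[str, ...] = DEFAULT_POP_CODES
    admixture_alpha: float = 10.0
    primary_weight: float = 0.8
    n_loci: int = 5000
    n_chromosomes: int = 12
    missing_rate: float = 0.02
    maf_floor: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ancestral_pops < 1:
            raise ValueError("n_ancestral_pops must be >= 1")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")
        if len(self.pop_codes) != len(self.pop_sizes):
            raise ValueError("pop_codes and pop_sizes length mismatch")
        if sum(self.pop_sizes) < 1 or any(s < 0 for s in self.pop_sizes):
            raise ValueError("pop_sizes must be non-negative with positive sum")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.maf_floor < 0.5:
            raise ValueError("maf_floor must be in [0, 0.5)")
        for f in self.fst_values:
            if not 0.0 <= f < 1.0:
                raise ValueError("fst values must be in [0, 1)")
        if self.admixture_alpha <= 0:
            raise ValueError("admixture_alpha must be positive")
        if not 0.0 < self.primary_weight <= 1.0:
            raise ValueError("primary_weight must be in (0, 1]")

    @property
    def fst_values(self) -> tuple[float, ...]:
        if isinstance(self.fst_per_pop, (int, float)):
            return (float(self.fst_per_pop),) * self.n_ancestral_pops
        if len(self.fst_per_pop) != self.n_ancestral_pops:
            raise ValueError("fst_per_pop length must equal n_ancestral_pops")
        return tuple(float(f) for f in self.fst_per_pop)

    @property
    def n_samples(self) -> int:
        return int(sum(self.pop_sizes))


@dataclass
class SimTruth:
    """Ground truth of one simulation run."""

    ancestral_freqs: np.ndarray        # (K, n_loci)
    ancestry_proportions: np.ndarray   # (n_samples, K), rows sum to 1
    population_labels: list[str]       # per-sample collection code
    sample_ids: list[str]

    @property
    def ancestral_assignment(self) -> list[int]:
        """Dominant ancestral pool per sample (argmax of ancestry)."""
        return [int(i) for i in self.ancestry_proportions.argmax(axis=1)]


def _base_ancestry_vectors(n_pops: int, k: int, primary_weight: float) -> np.ndarray:
    """Base ancestry vector per labeled population: most weight on its
    primary ancestral pool (round-robin assignment), the rest spread evenly."""
    base = np.full((n_pops, k), (1.0 - primary_weight) / max(k - 1, 1))
    if k == 1:
        return np.ones((n_pops, 1))
    for j in range(n_pops):
        base[j, j % k] = primary_weight
    return base


def simulate_population(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Draw a structured diploid genotype matrix plus its generating truth.

    Ancestral pool frequencies follow the Balding-Nichols beta
    ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` around a common ancestral frequency
    drawn uniformly above the MAF floor; each sample's genotype at a locus
    is Binomial(2, q . p_locus) with q its ancestry vector; missingness is
    independent Bernoulli per call.  Deterministic for a fixed config.
    """
    rng = np.random.default_rng(config.seed)
    k = config.n_ancestral_pops
    m = config.n_loci
    n = config.n_samples

    anc = rng.uniform(config.maf_floor, 1.0 - config.maf_floor, size=m)
    freqs = np.empty((k, m))
    for j, f in enumerate(config.fst_values):
        if f < 1e-12:
            freqs[j] = anc
        else:
            a = anc * (1.0 - f) / f
            b = (1.0 - anc) * (1.0 - f) / f
            freqs[j] = rng.beta(a, b)

    base = _base_ancestry_vectors(len(config.pop_sizes), k, config.primary_weight)
    labels: list[str] = []
    sample_ids: list[str] = []
    ancestry = np.empty((n, k))
    row = 0
    for code, size, bvec in zip(config.pop_codes, config.pop_sizes, base):
        for i in range(size):
            ancestry[row] = rng.dirichlet(config.admixture_alpha * bvec)
            labels.append(code)
            sample_ids.append(f"{code}{i + 1}")
            row += 1

    mixed = ancestry @ freqs                     # (n, m) per-sample allele-1 freq
    genotypes = rng.binomial(2, mixed).astype(np.int16)
    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        genotypes[mask] = MISSING

    chrom_names, positions = _locus_coordinates(rng, m, config.n_chromosomes)
    ref_alt = _draw_alleles(rng, m)

    sites = []
    for j in range(m):
        d = genotypes[:, j]
        gt = np.empty((n, 2), dtype=np.int16)
        gt[:, 0] = np.where(d >= 1, 1, 0)
        gt[:, 1] = np.where(d == 2, 1, 0)
        miss = d == MISSING
        gt[miss] = MISSING
        sites.append(
            VariantSite(
                chrom=chrom_names[j],
                pos=int(positions[j]),
                ref=ref_alt[j][0],
                alt=(ref_alt[j][1],),
                genotypes=gt,
            )
        )
    matrix = GenotypeMatrix(sample_ids, sites)
    truth = SimTruth(
        ancestral_freqs=freqs,
        ancestry_proportions=ancestry,
        population_labels=labels,
        sample_ids=sample_ids,
    )
    return matrix, truth


def _locus_coordinates(
    rng: np.random.Generator, m: int, n_chromosomes: int, spacing_scale: int = 1000
) -> tuple[list[str], np.ndarray]:
    """Spread loci over chromosomes in contiguous blocks with random sorted
    unique 1-based positions (~1 SNP per ``spacing_scale`` bp on average)."""
    per = np.full(n_chromosomes, m // n_chromosomes)
    per[: m % n_chromosomes] += 1
    names: list[str] = []
    pos = np.empty(m, dtype=np.int64)
    start = 0
    for c, count in enumerate(per, start=1):
        if count == 0:
            continue
        span = max(int(count) * spacing_scale, 10)
        p = np.sort(rng.choice(span, size=count, replace=False)) + 1
        pos[start : start + count] = p
        names.extend([f"Chr{c:02d}"] * int(count))
        start += int(count)
    return names, pos


def _draw_alleles(rng: np.random.Generator, m: int) -> list[tuple[str, str]]:
    ref = rng.integers(0, 4, size=m)
    alt = (ref + rng.integers(1, 4, size=m)) % 4
    return [(_BASES[r], _BASES[a]) for r, a in zip(ref, alt)]


# ---------------------------------------------------------------------------
# Toy genomes
# ---------------------------------------------------------------------------

def simulate_genome(
    length: int,
    repeat_fraction: float = 0.0,
    seed: int = 0,
    gc: float = 0.4,
    mean_block: int = 200,
) -> str:
    """Random nucleotide sequence with a soft-masked (lowercase) fraction.

    Masked bases are laid down in contiguous blocks (geometric lengths,
    mean ``mean_block``) at random starts until exactly
    ``round(length * repeat_fraction)`` bases are lowercase.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= repeat_fraction < 1.0:
        raise ValueError("repeat_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = rng.choice(_BASES, size=length, p=probs)
    target = round(length * repeat_fraction)
    masked = np.zeros(length, dtype=bool)
    while masked.sum() < target:
        start = int(rng.integers(0, length))
        block = int(rng.geometric(1.0 / mean_block))
        end = min(start + block, length)
        need = target - int(masked[:].sum())
        new = (~masked[start:end]).cumsum()
        if new.size and new[-1] > need:
            end = start + int(np.searchsorted(new, need)) + 1
        masked[start:end] = True
    out = seq.copy()
    out[masked] = np.char.lower(seq[masked])
    return "".join(out)


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Dataset export
# ---------------------------------------------------------------------------

def write_dataset(matrix: GenotypeMatrix, truth: SimTruth, out_dir: str | Path) -> dict[str, Path]:
    """Write VCF, population map and truth tables; returns the file paths.

    The VCF round-trips losslessly through :func:`slafkit.variants.read_vcf`.
    """
    if matrix.n_samples == 0:
        raise ValueError("cannot write a dataset with zero samples")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "popmap": out / "popmap.tsv",
        "ancestry": out / "truth_ancestry.tsv",
        "freqs": out / "truth_ancestral_freqs.tsv",
    }
    write_vcf(matrix, paths["vcf"])
    PopulationMap(dict(zip(truth.sample_ids, truth.population_labels))).write(paths["popmap"])
    k = truth.ancestry_proportions.shape[1]
    with open(paths["ancestry"], "w") as fh:
        fh.write("sample_id\tpopulation\t" + "\t".join(f"Q{i + 1}" for i in range(k)) + "\n")
        for sid, lab, q in zip(truth.sample_ids, truth.population_labels, truth.ancestry_proportions):
            fh.write(f"{sid}\t{lab}\t" + "\t".join(f"{v:.6f}" for v in q) + "\n")
    with open(paths["freqs"], "w") as fh:
        fh.write("locus\t" + "\t".join(f"P{i + 1}" for i in range(k)) + "\n")
        for j in range(truth.ancestral_freqs.shape[1]):
            fh.write(f"{j}\t" + "\t".join(f"{v:.6f}" for v in truth.ancestral_freqs[:, j]) + "\n")
    return paths
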