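"""Genotype containers, VCF I/O, SNP filtering and the Hardy-Weinberg exact test.

The central object is :class:`GenotypeMatrix`, a samples x loci store of
diploid allele-index calls.  Two views are maintained: the raw allele pairs
(needed for nucleotide-specific fingerprint encoding) and an integer *dosage*
matrix counting non-reference alleles per call (the substrate of distance,
PCA and kinship computations).  Missing calls -- including half-missing
``./x`` genotypes -- carry the sentinel ``-1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from cyvcf2 import VCF

MISSING = -1

__all__ = [
    "MISSING",
    "VariantSite",
    "GenotypeMatrix",
    "PopulationMap",
    "VcfParseError",
    "read_vcf",
    "write_vcf",
    "allele_frequencies",
    "minor_allele_frequency",
    "site_integrity",
    "filter_sites",
    "hwe_exact_test",
    "genotype_counts",
]


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be interpreted."""


@dataclass(frozen=True)
class VariantSite:
    """A single variant locus with its per-sample diploid calls.

    ``genotypes`` is an ``(n_samples, 2)`` integer array of allele indices
    into ``(ref,) + alt``; ``-1`` marks a missing allele.  A call with any
    missing allele is treated as entirely missing.
    """

    chrom: str
    pos: int          # 1-based
    ref: str
    alt: tuple[str, ...]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"POS must be >= 1, got {self.pos}")
        gt = np.asarray(self.genotypes)
        if gt.ndim != 2 or gt.shape[1] != 2:
            raise ValueError("genotypes must be an (n_samples, 2) array")
        if gt.size and gt.max() >= 1 + len(self.alt):
            raise ValueError("allele index outside ref+alt range")

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alt)

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref,) + self.alt

    @property
    def called(self) -> np.ndarray:
        """Boolean mask of samples with a fully non-missing call."""
        return (self.genotypes >= 0).all(axis=1)

    @property
    def integrity(self) -> float:
        """Fraction of samples with a non-missing call (locus integrity, INT)."""
        return float(self.called.mean()) if len(self.genotypes) else 0.0

    @property
    def is_biallelic(self) -> bool:
        return len(self.alt) == 1


class GenotypeMatrix:
    """Samples x loci diploid genotype matrix.

    Parameters
    ----------
    sample_ids:
        Ordered sample identifiers.
    sites:
        Ordered :class:`VariantSite` records; every site must carry one call
        per sample.
    """

    def __init__(self, sample_ids: Sequence[str], sites: Sequence[VariantSite]):
        self.sample_ids = list(sample_ids)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        self.sites = list(sites)
        for s in self.sites:
            if len(s.genotypes) != len(self.sample_ids):
                raise ValueError(
                    f"site {s.chrom}:{s.pos} has {len(s.genotypes)} calls "
                    f"for {len(self.sample_ids)} samples"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def dosage(self) -> np.ndarray:
        """``(n_samples, n_sites)`` counts of non-reference alleles; -1 = missing."""
        if not self.sites:
            return np.zeros((self.n_samples, 0), dtype=np.int16)
        out = np.empty((self.n_samples, self.n_sites), dtype=np.int16)
        for j, s in enumerate(self.sites):
            gt = s.genotypes
            d = (gt > 0).sum(axis=1).astype(np.int16)
            d[(gt < 0).any(axis=1)] = MISSING
            out[:, j] = d
        return out

    def integrity(self) -> np.ndarray:
        return np.array([s.integrity for s in self.sites])

    def take_sites(self, indices: Iterable[int]) -> "GenotypeMatrix":
        return GenotypeMatrix(self.sample_ids, [self.sites[i] for i in indices])

    def take_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        rows = [self.sample_index(s) for s in sample_ids]
        sites = [
            VariantSite(
                chrom=s.chrom, pos=s.pos, ref=s.ref, alt=s.alt, genotypes=s.genotypes[rows]
            )
            for s in self.sites
        ]
        return GenotypeMatrix(list(sample_ids), sites)

    def __iter__(self) -> Iterator[VariantSite]:
        return iter(self.sites)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        if self.sample_ids != other.sample_ids or self.n_sites != other.n_sites:
            return False
        for a, b in zip(self.sites, other.sites):
            if (a.chrom, a.pos, a.ref, a.alt) != (b.chrom, b.pos, b.ref, b.alt):
                return False
            if not np.array_equal(a.genotypes, b.genotypes):
                return False
        return True


@dataclass
class PopulationMap:
    """Assignment of every sample to a population code (e.g. B, E, ES ... X)."""

    assignments: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, sample_id: str) -> str:
        return self.assignments[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.assignments

    def __len__(self) -> int:
        return len(self.assignments)

    @property
    def codes(self) -> list[str]:
        """Population codes in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.assignments.values():
            seen.setdefault(c)
        return list(seen)

    def samples_for(self, code: str) -> list[str]:
        return [s for s, c in self.assignments.items() if c == code]

    def validate(self, matrix: GenotypeMatrix) -> None:
        missing = [s for s in matrix.sample_ids if s not in self.assignments]
        if missing:
            raise ValueError(f"samples without population code: {missing[:5]} ...")

    @classmethod
    def read(cls, path: str | Path) -> "PopulationMap":
        assignments: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                sample, code = line.split("\t")[:2]
                assignments[sample] = code
        return cls(assignments)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sample, code in self.assignments.items():
                fh.write(f"{sample}\t{code}\n")


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read diploid GT calls from a VCF into a :class:`GenotypeMatrix`.

    Phased and unphased separators are treated identically; half-missing
    calls (``./1``) are recorded as fully missing; multiallelic records are
    retained with all alternate alleles.
    """
    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # htslib raises bare OSError subclasses
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    sites: list[VariantSite] = []
    for i, rec in enumerate(vcf, start=1):
        try:
            gt = np.array([g[:2] for g in rec.genotypes], dtype=np.int16)
        except Exception as exc:
            raise VcfParseError(f"malformed genotypes at record {i} ({rec.CHROM}:{rec.POS})") from exc
        gt[(gt < 0).any(axis=1)] = MISSING
        sites.append(
            VariantSite(chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=tuple(rec.ALT), genotypes=gt)
        )
    return GenotypeMatrix(samples, sites)


def write_vcf(matrix: GenotypeMatrix, path: str | Path, contigs: Sequence[str] | None = None) -> None:
    """Write a minimal deterministic VCF 4.2 with GT-only genotype columns."""
    if matrix.n_samples == 0:
        raise ValueError("refusing to write a VCF with zero samples")
    if contigs is None:
        seen: dict[str, None] = {}
        for s in matrix.sites:
            seen.setdefault(s.chrom)
        contigs = list(seen)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=slafkit\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(matrix.sample_ids) + "\n")
        for s in matrix.sites:
            alt = ",".join(s.alt) if s.alt else "."
            calls = []
            for a, b in s.genotypes:
                if a < 0 or b < 0:
                    calls.append("./.")
                else:
                    calls.append(f"{a}/{b}")
            fh.write(
                f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


# ---------------------------------------------------------------------------
# Per-site statistics and filters
# ---------------------------------------------------------------------------

def _genotype_array(site: VariantSite | np.ndarray) -> np.ndarray:
    gt = site.genotypes if isinstance(site, VariantSite) else np.asarray(site)
    if gt.ndim != 2 or gt.shape[1] != 2:
        raise ValueError("expected an (n_samples, 2) genotype array")
    return gt


def allele_frequencies(site: VariantSite | np.ndarray, n_alleles: int | None = None) -> np.ndarray:
    """Allele frequencies over non-missing gene copies.

    The returned vector has one entry per allele index (``ref`` first).  Gene
    copies from half-missing calls are excluded because such calls are stored
    fully missing.
    """
    gt = _genotype_array(site)
    if n_alleles is None:
        n_alleles = site.n_alleles if isinstance(site, VariantSite) else int(gt.max()) + 1
    copies = gt[(gt >= 0).all(axis=1)].ravel()
    if copies.size == 0:
        raise ValueError("no non-missing calls at site")
    counts = np.bincount(copies, minlength=n_alleles).astype(float)
    return counts / counts.sum()


def minor_allele_frequency(site: VariantSite | np.ndarray) -> float:
    """MAF: frequency of the second-most-frequent allele (min(p, 1-p) when biallelic)."""
    freqs = allele_frequencies(site)
    if freqs.size < 2:
        return 0.0
    return float(np.sort(freqs)[::-1][1])


def site_integrity(site: VariantSite | np.ndarray) -> float:
    gt = _genotype_array(site)
    if len(gt) == 0:
        return 0.0
    return float((gt >= 0).all(axis=1).mean())


def filter_sites(matrix: GenotypeMatrix, maf_min: float = 0.05, int_min: float = 0.3) -> GenotypeMatrix:
    """Retain sites with MAF >= ``maf_min`` and locus integrity >= ``int_min``.

    Both thresholds are inclusive.  Sample set and site order are preserved;
    the operation is idempotent.  Sites where every call is missing are
    always dropped (their MAF is undefined).
    """
    keep = []
    for i, s in enumerate(matrix.sites):
        if s.integrity < int_min:
            continue
        if not s.called.any():
            continue
        if minor_allele_frequency(s) < maf_min:
            continue
        keep.append(i)
    return matrix.take_sites(keep)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def genotype_counts(site: VariantSite | np.ndarray) -> tuple[int, int, int]:
    """(hom-ref, het, hom-alt) counts for a biallelic site, ignoring missing calls."""
    gt = _genotype_array(site)
    called = gt[(gt >= 0).all(axis=1)]
    d = (called > 0).sum(axis=1)
    return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional test of Hardy-Weinberg genotype proportions.

    Conditions on the observed allele counts and enumerates every
    heterozygote count of the same parity; the p-value is the total
    probability of configurations no more likely than the observed one.
    Computed in exact integer arithmetic, so ties in probability are handled
    without floating-point ambiguity.  Returns a value in (0, 1].
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("at least one genotyped individual required")
    n_a = 2 * n_aa + n_ab
    rare = min(n_a, 2 * n - n_a)
    # Unnormalized weight of a heterozygote count h (same parity as rare):
    #   w(h) = C(n, h) * C(n - h, (rare - h) / 2) * 2**h
    # obtained from the multinomial count of genotype configurations.
    def weight(h: int) -> int:
        return math.comb(n, h) * math.comb(n - h, (rare - h) // 2) * (1 << h)

    hets = range(rare % 2, rare + 1, 2)
    weights = {h: weight(h) for h in hets}
    w_obs = weights[n_ab]
    total = sum(weights.values())
    p = sum(w for w in weights.values() if w <= w_obs)
    return float(Fraction(p, total))


def hwe_chi2_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """One-degree-of-freedom chi-square HWE test (no continuity correction)."""
    from scipy.stats import chi2

    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("at least one genotyped individual required")
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1 - p
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    stat = ((obs - exp) ** 2 / exp).sum()
    return float(chi2.sf(stat, df=1))
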