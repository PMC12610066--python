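"""Per-locus and per-population genetic-diversity indices.

Implements the classical marker-diversity battery for diploid SNP panels:

* MAF       minor allele frequency
* Ne        effective (expected) allele number, ``1 / sum(p_i^2)``
* He        expected heterozygosity, ``1 - sum(p_i^2)``
* H         Nei's gene diversity with the small-sample correction
            ``2n / (2n - 1) * (1 - sum(p_i^2))`` (n diploid individuals typed)
* Ho        observed heterozygosity
* Na        observed allele number
* A         count of loci polymorphic within a population
* PIC       polymorphism information content (Botstein estimator)
* I         Shannon-Wiener index, ``-sum(p_i ln p_i)``

Population summaries report (min, max, mean) of each index over loci, the
standard table layout of germplasm-diversity studies, rendered as
``min-max(mean)`` strings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .variants import (
    GenotypeMatrix,
    PopulationMap,
    VariantSite,
    allele_frequencies,
)

__all__ = [
    "compute_pic",
    "compute_he",
    "compute_nei_h",
    "compute_shannon",
    "compute_ne",
    "compute_ho",
    "LocusStats",
    "locus_stats",
    "DiversitySummary",
    "summarize_population",
    "diversity_table",
    "unweighted_mean_row",
    "render_range",
    "parse_range",
    "INDEX_ORDER",
]

_FREQ_TOL = 1e-9

# Table column order used by rendered summaries.
INDEX_ORDER = ("maf", "ne", "he", "h", "na", "ho", "pic", "i")


def _check_freqs(freqs: Sequence[float]) -> np.ndarray:
    p = np.asarray(freqs, dtype=float)
    if (p < 0).any():
        raise ValueError("allele frequencies must be non-negative")
    if abs(p.sum() - 1.0) > _FREQ_TOL:
        raise ValueError(f"allele frequencies must sum to 1, got {p.sum()!r}")
    return p


def compute_he(freqs: Sequence[float]) -> float:
    """Expected heterozygosity He = 1 - sum(p_i^2)."""
    p = _check_freqs(freqs)
    return float(1.0 - np.sum(p * p))


def compute_ne(freqs: Sequence[float]) -> float:
    """Effective allele number Ne = 1 / sum(p_i^2)."""
    p = _check_freqs(freqs)
    return float(1.0 / np.sum(p * p))


def compute_nei_h(freqs: Sequence[float], n_typed: int) -> float:
    """Nei's gene diversity with the unbiased small-sample correction.

    ``H = 2n/(2n-1) * (1 - sum p_i^2)`` where ``n_typed`` is the number of
    diploid individuals actually genotyped at the locus.  H >= He, with
    equality in the large-sample limit.
    """
    if n_typed < 1:
        raise ValueError("n_typed must be >= 1")
    two_n = 2 * n_typed
    return float(two_n / (two_n - 1)) * compute_he(freqs)


def compute_shannon(freqs: Sequence[float]) -> float:
    """Shannon-Wiener index I = -sum(p_i ln p_i); zero-frequency terms contribute 0."""
    p = _check_freqs(freqs)
    p = p[p > 0]
    val = float(-np.sum(p * np.log(p)))
    return val if val > 0.0 else 0.0


def compute_pic(freqs: Sequence[float]) -> float:
    """Polymorphism information content (Botstein estimator).

    ``PIC = 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2``; bounded by 0.375 for
    biallelic loci (attained at p = q = 0.5).
    """
    p = _check_freqs(freqs)
    sq = p * p
    s1 = float(np.sum(sq))
    # sum_{i<j} 2 p_i^2 p_j^2 = (sum p_i^2)^2 - sum p_i^4
    s2 = s1 * s1 - float(np.sum(sq * sq))
    return 1.0 - s1 - s2


def compute_ho(site: VariantSite | np.ndarray, subset: Sequence[int] | None = None) -> float:
    """Observed heterozygosity: heterozygous calls / non-missing calls."""
    gt = site.genotypes if isinstance(site, VariantSite) else np.asarray(site)
    if subset is not None:
        gt = gt[np.asarray(subset, dtype=int)]
    called = gt[(gt >= 0).all(axis=1)]
    if len(called) == 0:
        raise ValueError("no non-missing calls in subset")
    return float((called[:, 0] != called[:, 1]).mean())


@dataclass(frozen=True)
class LocusStats:
    """Bundle of per-locus indices (one population, one locus)."""

    maf: float
    ne: float
    he: float
    h: float
    ho: float
    na: int
    pic: float
    i: float
    n_typed: int

    def as_dict(self) -> dict[str, float]:
        return {
            "maf": self.maf, "ne": self.ne, "he": self.he, "h": self.h,
            "na": float(self.na), "ho": self.ho, "pic": self.pic, "i": self.i,
        }


def locus_stats(site: VariantSite, subset: Sequence[int] | None = None) -> LocusStats:
    """Compute every index at one locus over an optional sample subset.

    Frequencies are taken over observed gene copies only; ``n_typed`` is the
    number of individuals with a call, which drives the Nei correction.
    """
    gt = site.genotypes
    if subset is not None:
        gt = gt[np.asarray(subset, dtype=int)]
    called = gt[(gt >= 0).all(axis=1)]
    if len(called) == 0:
        raise ValueError(f"no data at {site.chrom}:{site.pos} in subset")
    freqs = allele_frequencies(called, n_alleles=site.n_alleles)
    observed = freqs[freqs > 0]
    n_typed = len(called)
    maf = float(np.sort(freqs)[::-1][1]) if freqs.size >= 2 else 0.0
    return LocusStats(
        maf=maf,
        ne=compute_ne(freqs),
        he=compute_he(freqs),
        h=compute_nei_h(freqs, n_typed),
        ho=float((called[:, 0] != called[:, 1]).mean()),
        na=int(observed.size),
        pic=compute_pic(freqs),
        i=compute_shannon(freqs),
        n_typed=n_typed,
    )


@dataclass
class DiversitySummary:
    """(min, max, mean) of each index over loci for one population, plus A."""

    code: str
    n_samples: int
    n_loci: int
    a: int  # loci with >= 2 observed alleles in this population
    stats: dict[str, tuple[float, float, float]]  # index -> (min, max, mean)

    def mean(self, index: str) -> float:
        return self.stats[index][2]


def summarize_population(
    matrix: GenotypeMatrix, pop_map: PopulationMap, code: str
) -> DiversitySummary:
    """Per-population diversity summary over loci.

    Only members of the population contribute; loci with zero non-missing
    calls within the population are skipped.  ``A`` counts loci where at
    least two alleles are observed within the population.
    """
    samples = [s for s in matrix.sample_ids if s in pop_map and pop_map[s] == code]
    if not samples:
        raise ValueError(f"unknown or empty population code {code!r}")
    idx = [matrix.sample_index(s) for s in samples]
    per_locus: list[LocusStats] = []
    for site in matrix.sites:
        gt = site.genotypes[idx]
        if not (gt >= 0).all(axis=1).any():
            continue
        per_locus.append(locus_stats(site, subset=idx))
    if not per_locus:
        raise ValueError(f"population {code!r} has no typed loci")
    stats: dict[str, tuple[float, float, float]] = {}
    for key in INDEX_ORDER:
        vals = np.array([ls.as_dict()[key] for ls in per_locus])
        stats[key] = (float(vals.min()), float(vals.max()), float(vals.mean()))
    a = sum(1 for ls in per_locus if ls.na >= 2)
    return DiversitySummary(
        code=code, n_samples=len(samples), n_loci=len(per_locus), a=a, stats=stats
    )


def unweighted_mean_row(values: Sequence[float]) -> float:
    """Mean-row entry: unweighted arithmetic mean over population values."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no population values")
    return float(v.mean())


def diversity_table(matrix: GenotypeMatrix, pop_map: PopulationMap) -> pd.DataFrame:
    """Assemble the per-population diversity table plus an unweighted Mean row.

    Columns follow the conventional order MAF, Ne, He, H, A, Na, Ho, PIC, I;
    range-bearing columns are rendered as ``min-max(mean)`` with 3 decimals,
    MAF as its mean alone and A as an integer count.
    """
    pop_map.validate(matrix)
    summaries = [summarize_population(matrix, pop_map, c) for c in pop_map.codes]
    rows = []
    for s in summaries:
        row = {"Germplasm": s.code, "MAF": f"{s.mean('maf'):.3f}"}
        for key, col in [("ne", "Ne"), ("he", "He"), ("h", "H")]:
            row[col] = render_range(*s.stats[key])
        row["A"] = f"{s.a:,}"
        for key, col in [("na", "Na"), ("ho", "Ho"), ("pic", "PIC"), ("i", "I")]:
            row[col] = render_range(*s.stats[key])
        rows.append(row)
    mean_row = {"Germplasm": "Mean"}
    mean_row["MAF"] = f"{unweighted_mean_row([s.mean('maf') for s in summaries]):.3f}"
    for key, col in [("ne", "Ne"), ("he", "He"), ("h", "H")]:
        mean_row[col] = f"{unweighted_mean_row([s.mean(key) for s in summaries]):.3f}"
    mean_row["A"] = f"{round(unweighted_mean_row([s.a for s in summaries])):,}"
    for key, col in [("na", "Na"), ("ho", "Ho"), ("pic", "PIC"), ("i", "I")]:
        mean_row[col] = f"{unweighted_mean_row([s.mean(key) for s in summaries]):.3f}"
    rows.append(mean_row)
    return pd.DataFrame(rows).set_index("Germplasm")


_RANGE_RE = re.compile(r"^\s*([0-9.]+)\s*[-–]\s*([0-9.]+)\s*\(\s*([0-9.]+)\s*\)\s*$")


def render_range(vmin: float, vmax: float, vmean: float) -> str:
    """Render a (min, max, mean) triple as ``min-max(mean)`` with 3 decimals."""
    return f"{vmin:.3f}–{vmax:.3f}({vmean:.3f})"


def parse_range(text: str) -> tuple[float, float, float]:
    """Inverse of :func:`render_range` (accepts hyphen or en-dash)."""
    m = _RANGE_RE.match(text)
    if not m:
        raise ValueError(f"not a min-max(mean) string: {text!r}")
    return tuple(float(g) for g in m.groups())  # type: ignore[return-value]
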