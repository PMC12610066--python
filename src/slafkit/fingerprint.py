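"""Core-marker selection and color-coded DNA fingerprint encoding.

A *core marker* is a SNP suitable for a germplasm-identification panel:
biallelic, genotyped in every accession, common (MAF >= 0.20), informative
(PIC >= 0.35), consistent with Hardy-Weinberg proportions (exact-test
p > 0.01), isolated from neighbouring variants (none within 100 bp flanking
regions of the unfiltered variant set) and evenly spread along the genome
(at most ``per_window_quota`` markers per genomic window, keeping the most
informative).

Fingerprints map each accession's genotype at the core markers to the
conventional color scheme: yellow C/C, green A/A, blue T/T, purple G/G,
white for heterozygous and gray for missing calls.  The payload string (one
state character per marker appended to the sample id) is the machine-level
fingerprint from which 2-D barcodes may be rendered.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

from .diversity import compute_pic
from .variants import (
    GenotypeMatrix,
    VariantSite,
    allele_frequencies,
    genotype_counts,
    hwe_exact_test,
    hwe_chi2_test,
    minor_allele_frequency,
)

__all__ = [
    "CoreMarkerCriteria",
    "CoreMarkerSet",
    "FingerprintCard",
    "select_core_markers",
    "encode_fingerprint",
    "decode_fingerprint",
    "STATE_COLORS",
]

# state character -> display color; H = heterozygous, N = missing
STATE_COLORS = {
    "C": "yellow",
    "A": "green",
    "T": "blue",
    "G": "purple",
    "H": "white",
    "N": "gray",
}

_PAYLOAD_SEP = "|"


@dataclass(frozen=True)
class CoreMarkerCriteria:
    """Thresholds of the core-marker filter chain."""

    integrity_min: float = 1.0
    maf_min: float = 0.20
    pic_min: float = 0.35
    hwe_p_min: float = 0.01
    exclusion_radius: int = 100     # bp; neighbours at distance <= radius disqualify
    window_size: int = 1_000_000    # bp; uniformity window
    per_window_quota: int = 1
    hwe_test: str = "exact"         # "exact" or "chi2"

    def __post_init__(self) -> None:
        if not 0.0 <= self.integrity_min <= 1.0:
            raise ValueError("integrity_min must be in [0, 1]")
        if self.exclusion_radius < 0:
            raise ValueError("exclusion_radius must be >= 0")
        if self.window_size < 1 or self.per_window_quota < 1:
            raise ValueError("window_size and per_window_quota must be >= 1")
        if self.hwe_test not in ("exact", "chi2"):
            raise ValueError("hwe_test must be 'exact' or 'chi2'")


@dataclass
class CoreMarkerSet:
    """Selected markers (sorted by chrom, pos) plus a per-site audit trail.

    ``audit`` maps ``(chrom, pos)`` of every rejected candidate to the first
    criterion that removed it.
    """

    marker_indices: list[int]
    markers: list[tuple[str, int, str, str]]  # (chrom, pos, ref, alt)
    audit: dict[tuple[str, int], str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.markers)


def select_core_markers(
    matrix: GenotypeMatrix, criteria: CoreMarkerCriteria | None = None
) -> CoreMarkerSet:
    """Apply the core-marker filter chain and record why each site failed.

    Stages, in order: biallelic -> integrity -> MAF -> PIC -> HWE ->
    adjacency exclusion against the *unfiltered* candidate set -> per-window
    thinning by PIC.  The audit trail records the first failing stage per
    rejected site.
    """
    crit = criteria or CoreMarkerCriteria()
    hwe = hwe_exact_test if crit.hwe_test == "exact" else hwe_chi2_test
    audit: dict[tuple[str, int], str] = {}

    positions_by_chrom: dict[str, list[int]] = {}
    for s in matrix.sites:
        positions_by_chrom.setdefault(s.chrom, []).append(s.pos)
    for chrom in positions_by_chrom:
        positions_by_chrom[chrom].sort()

    survivors: list[tuple[int, VariantSite, float]] = []  # (index, site, pic)
    for i, site in enumerate(matrix.sites):
        key = (site.chrom, site.pos)
        if not site.is_biallelic:
            audit[key] = "multiallelic"
            continue
        if site.integrity < crit.integrity_min:
            audit[key] = "integrity"
            continue
        if minor_allele_frequency(site) < crit.maf_min:
            audit[key] = "maf"
            continue
        pic = compute_pic(allele_frequencies(site))
        if pic < crit.pic_min:
            audit[key] = "pic"
            continue
        if hwe(*genotype_counts(site)) <= crit.hwe_p_min:
            audit[key] = "hwe"
            continue
        if _has_neighbor(positions_by_chrom[site.chrom], site.pos, crit.exclusion_radius):
            audit[key] = "adjacency"
            continue
        survivors.append((i, site, pic))

    # Per-window uniformity thinning: keep the highest-PIC markers per window
    # up to the quota (ties broken by position for determinism).
    by_window: dict[tuple[str, int], list[tuple[int, VariantSite, float]]] = {}
    for entry in survivors:
        _, site, _ = entry
        by_window.setdefault((site.chrom, site.pos // crit.window_size), []).append(entry)
    selected: list[tuple[int, VariantSite]] = []
    for window_entries in by_window.values():
        ranked = sorted(window_entries, key=lambda e: (-e[2], e[1].pos))
        for _, site, _ in ranked[crit.per_window_quota :]:
            audit[(site.chrom, site.pos)] = "window_quota"
        selected.extend((i, s) for i, s, _ in ranked[: crit.per_window_quota])

    selected.sort(key=lambda e: (e[1].chrom, e[1].pos))
    return CoreMarkerSet(
        marker_indices=[i for i, _ in selected],
        markers=[(s.chrom, s.pos, s.ref, s.alt[0]) for _, s in selected],
        audit=audit,
    )


def _has_neighbor(sorted_positions: list[int], pos: int, radius: int) -> bool:
    """True if any *other* variant lies within ``radius`` bp of ``pos``."""
    if radius == 0:
        return False
    lo = bisect.bisect_left(sorted_positions, pos - radius)
    hi = bisect.bisect_right(sorted_positions, pos + radius)
    for p in sorted_positions[lo:hi]:
        if p != pos:
            return True
    return False


@dataclass(frozen=True)
class FingerprintCard:
    """One accession's ordered genotype-state string over the core markers."""

    sample_id: str
    states: str  # one of C/A/T/G (homozygous base), H (het), N (missing) per marker

    @property
    def payload(self) -> str:
        return f"{self.sample_id}{_PAYLOAD_SEP}{self.states}"

    @property
    def colors(self) -> list[str]:
        return [STATE_COLORS[c] for c in self.states]


def encode_fingerprint(
    sample_id: str, markers: CoreMarkerSet, matrix: GenotypeMatrix
) -> FingerprintCard:
    """Encode one sample's genotypes at the core markers as a state string.

    Homozygous calls map to their base letter (hence its color), heterozygous
    to ``H`` (white) and missing to ``N`` (gray).
    """
    row = matrix.sample_index(sample_id)
    lookup = {(s.chrom, s.pos): s for s in matrix.sites}
    chars: list[str] = []
    for chrom, pos, ref, alt in markers.markers:
        site = lookup.get((chrom, pos))
        if site is None:
            raise KeyError(f"marker {chrom}:{pos} absent from matrix")
        a, b = site.genotypes[row]
        if a < 0 or b < 0:
            chars.append("N")
        elif a != b:
            chars.append("H")
        else:
            chars.append(site.alleles[a])
    return FingerprintCard(sample_id=sample_id, states="".join(chars))


def decode_fingerprint(payload: str | FingerprintCard, markers: CoreMarkerSet) -> list[str]:
    """Recover the per-marker genotype states from a payload string.

    Homozygous states decode to ``X/X`` with their base letter; ``H`` decodes
    to ``het`` (the base identities are not recoverable from the white state)
    and ``N`` to ``missing``.
    """
    text = payload.payload if isinstance(payload, FingerprintCard) else payload
    if _PAYLOAD_SEP not in text:
        raise ValueError("malformed payload: missing separator")
    _, states = text.rsplit(_PAYLOAD_SEP, 1)
    if len(states) != len(markers):
        raise ValueError(
            f"payload has {len(states)} states for {len(markers)} markers"
        )
    out = []
    for c in states:
        if c in "ACGT":
            out.append(f"{c}/{c}")
        elif c == "H":
            out.append("het")
        elif c == "N":
            out.append("missing")
        else:
            raise ValueError(f"invalid state character {c!r}")
    return out
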