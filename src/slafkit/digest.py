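"""In silico double-digest simulation and enzyme-scheme scoring.

Reduced-representation (SLAF-style) libraries sequence restriction fragments
whose length falls in a selectable window.  This module predicts cut sites
of IUPAC-ambiguous recognition sequences, tiles a genome into fragments,
selects candidate sequencing tags (both flanks enzymatic, length within the
window) and scores an enzyme scheme by tag yield, duplication (repeat
content or non-unique sequence) and genomic uniformity (coefficient of
variation of tag counts over fixed bins).

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "Enzyme",
    "HAEIII",
    "HPY166II",
    "Fragment",
    "DigestScheme",
    "find_cut_sites",
    "double_digest",
    "select_tags",
    "score_scheme",
    "IUPAC",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_SEQ_RE = re.compile(r"^[ACGTacgt]+$")


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: IUPAC recognition sequence and blunt/sticky cut
    offset measured from the 5' end of the recognition site."""

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        site = self.recognition.upper()
        bad = [c for c in site if c not in IUPAC]
        if bad:
            raise ValueError(f"invalid IUPAC letters in recognition site: {bad}")
        if not 0 <= self.cut_offset <= len(site):
            raise ValueError("cut_offset must lie within the recognition site")

    @property
    def pattern(self) -> re.Pattern:
        expanded = "".join(
            c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in self.recognition.upper()
        )
        # lookahead so overlapping matches are found
        return re.compile(f"(?=({expanded}))", re.IGNORECASE)


# The classic SLAF double-digest pair: both blunt cutters.
HAEIII = Enzyme("HaeIII", "GGCC", 2)
HPY166II = Enzyme("Hpy166II", "GTNNAC", 3)


@dataclass(frozen=True)
class Fragment:
    """A digestion fragment: [start, end) on ``chrom`` with flank provenance
    (enzyme name, or ``"end"`` for a sequence terminus)."""

    chrom: str
    start: int
    end: int
    left_flank: str
    right_flank: str
    masked_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("fragment end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_double_flanked(self) -> bool:
        return self.left_flank != "end" and self.right_flank != "end"


@dataclass
class DigestScheme:
    """Quality metrics of one enzyme scheme on one genome."""

    enzymes: tuple[str, ...]
    window: tuple[int, int]
    n_fragments: int
    n_tags: int
    duplication_rate: float
    uniformity_cv: float


def _validate_sequence(seq: str) -> None:
    if not seq:
        raise ValueError("empty sequence")
    if not _SEQ_RE.match(seq):
        bad = sorted({c for c in seq if c.upper() not in "ACGT"})
        raise ValueError(f"sequence contains non-ACGT characters: {bad}")


def find_cut_sites(seq: str, enzyme: Enzyme) -> list[int]:
    """All cut coordinates of ``enzyme`` on ``seq`` (case-insensitive,
    overlapping recognition sites allowed)."""
    _validate_sequence(seq)
    return [m.start() + enzyme.cut_offset for m in enzyme.pattern.finditer(seq)]


def double_digest(
    seq: str, enzymes: Sequence[Enzyme], chrom: str = "seq"
) -> list[Fragment]:
    """Digest ``seq`` with the union of all enzymes' cut sites.

    Fragments tile the sequence without gaps or overlap; each records the
    enzyme that produced each flank (``"end"`` at sequence termini).  Cuts at
    the very ends of the sequence are ignored (they produce no new fragment).
    """
    if not enzymes:
        raise ValueError("at least one enzyme required")
    _validate_sequence(seq)
    cut_by: dict[int, str] = {}
    for enz in enzymes:
        for pos in find_cut_sites(seq, enz):
            if 0 < pos < len(seq):
                # deterministic provenance when two enzymes cut the same spot
                cut_by[pos] = min(cut_by.get(pos, enz.name), enz.name)
    cuts = sorted(cut_by)
    bounds = [0, *cuts, len(seq)]
    flanks = ["end", *[cut_by[c] for c in cuts], "end"]
    frags = []
    for i in range(len(bounds) - 1):
        start, end = bounds[i], bounds[i + 1]
        sub = seq[start:end]
        masked = sum(1 for c in sub if c.islower()) / len(sub)
        frags.append(
            Fragment(
                chrom=chrom,
                start=start,
                end=end,
                left_flank=flanks[i],
                right_flank=flanks[i + 1],
                masked_fraction=masked,
            )
        )
    return frags


def select_tags(
    fragments: Sequence[Fragment],
    window_min: int = 364,
    window_max: int = 394,
    require_double_flank: bool = True,
) -> list[Fragment]:
    """Fragments usable as sequencing tags: length within the window
    (inclusive) and, by default, an enzymatic cut on both flanks."""
    if window_min > window_max:
        raise ValueError("window_min must not exceed window_max")
    return [
        f
        for f in fragments
        if window_min <= f.length <= window_max
        and (f.is_double_flanked or not require_double_flank)
    ]


def _load_genome(genome: Mapping[str, str] | str | Path) -> dict[str, str]:
    if isinstance(genome, (str, Path)):
        records = {r.id: str(r.seq) for r in SeqIO.parse(str(genome), "fasta")}
        if not records:
            raise ValueError(f"no sequences in FASTA {genome}")
        return records
    return dict(genome)


def score_scheme(
    genome: Mapping[str, str] | str | Path,
    enzymes: Sequence[Enzyme],
    window: tuple[int, int] = (364, 394),
    masked_cutoff: float = 0.5,
    bin_size: int = 1_000_000,
) -> DigestScheme:
    """Digest a genome and score the enzyme scheme.

    Duplication rate is the fraction of tags that are repeat-like (soft-masked
    fraction above ``masked_cutoff``) or whose uppercase sequence occurs more
    than once among tags.  Uniformity is the coefficient of variation of tag
    counts over fixed ``bin_size`` windows spanning the genome.
    """
    seqs = _load_genome(genome)
    if not seqs:
        raise ValueError("empty genome")
    all_frags: list[Fragment] = []
    tag_seqs: list[str] = []
    tags: list[Fragment] = []
    for chrom, seq in seqs.items():
        frags = double_digest(seq, enzymes, chrom=chrom)
        all_frags.extend(frags)
        for t in select_tags(frags, *window):
            tags.append(t)
            tag_seqs.append(seq[t.start : t.end].upper())
    if tags:
        mult = Counter(tag_seqs)
        dup = sum(
            1
            for t, s in zip(tags, tag_seqs)
            if t.masked_fraction > masked_cutoff or mult[s] > 1
        )
        dup_rate = dup / len(tags)
    else:
        dup_rate = 0.0
    counts = []
    for chrom, seq in seqs.items():
        n_bins = max(1, -(-len(seq) // bin_size))
        per_bin = np.zeros(n_bins)
        for t in tags:
            if t.chrom == chrom:
                per_bin[min(t.start // bin_size, n_bins - 1)] += 1
        counts.append(per_bin)
    allc = np.concatenate(counts)
    cv = float(allc.std() / allc.mean()) if allc.mean() > 0 else float("inf")
    return DigestScheme(
        enzymes=tuple(e.name for e in enzymes),
        window=window,
        n_fragments=len(all_frags),
        n_tags=len(tags),
        duplication_rate=dup_rate,
        uniformity_cv=cv,
    )
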