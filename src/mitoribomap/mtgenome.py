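"""Circular mitochondrial genome model.

Human mtDNA is a closed circle of 16,569 bp whose two strands are named by
buoyant density: the guanine-rich heavy (H) strand and the cytosine-rich
light (L) strand.  The deposited reference sequence (rCRS numbering) is the
C-rich strand, so for human mtDNA the forward/deposited sequence is the
L-strand and the H-strand is its reverse complement.  All coordinates in
this package are 1-based, inclusive, circular reference coordinates; a
position refers to the same rung of the duplex on either strand.

This module provides sequence access on either biological strand, masked
base counting, degenerate restriction-site scanning on the circle, and the
default analysis masks used throughout (analysis window 300-16,200, the
OriL exclusion 5,747-5,847, and +/-5 windows around each restriction cut).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

__all__ = [
    "MtGenome",
    "Region",
    "AnalysisMask",
    "RestrictionSite",
    "load_reference",
    "base_counts",
    "find_restriction_sites",
    "default_masks",
    "write_regions_bed",
    "read_regions_bed",
    "write_sites_bed",
    "COMPLEMENT",
    "IUPAC",
]

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# IUPAC degenerate nucleotide codes -> the set of concrete bases they admit.
IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}

_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a concrete {A,C,G,T} sequence."""
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def iupac_revcomp(pattern: str) -> str:
    return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(pattern))


@dataclass(frozen=True)
class Region:
    """1-based inclusive region on the circle.

    ``wraps=True`` marks a region crossing the origin (e.g. 16,200 -> 300):
    a position p is inside iff p >= start or p <= end.
    """

    start: int
    end: int
    wraps: bool = False

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise ValueError("region coordinates are 1-based and positive")
        if not self.wraps and self.start > self.end:
            raise ValueError(
                f"non-wrapping region has start {self.start} > end {self.end}; "
                "set wraps=True for an origin-spanning region"
            )

    def contains(self, pos: int) -> bool:
        if self.wraps:
            return pos >= self.start or pos <= self.end
        return self.start <= pos <= self.end

    def positions(self, length: int) -> list[int]:
        """All member positions on a circle of the given length, ascending."""
        if self.wraps:
            return list(range(1, self.end + 1)) + list(range(self.start, length + 1))
        return list(range(self.start, self.end + 1))


@dataclass
class MtGenome:
    """A single circular reference sequence with biological strand labels.

    ``strand_of_forward`` is the buoyant-density name of the deposited
    (forward) strand, assigned by the G-rich rule: the H-strand is the
    strand with the higher G fraction, so the forward sequence is L exactly
    when it contains fewer G than C.
    """

    name: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("empty sequence")
        for i, c in enumerate(self.sequence):
            if c not in "ACGT":
                raise ValueError(
                    f"ambiguous or invalid base {c!r} at position {i + 1} "
                    f"in {self.name}; the reference must be unambiguous A/C/G/T"
                )
        g = self.sequence.count("G")
        c = self.sequence.count("C")
        self._strand_of_forward = "L" if g < c else "H"

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def strand_of_forward(self) -> str:
        return self._strand_of_forward

    @property
    def strand_of_reverse(self) -> str:
        return "H" if self.strand_of_forward == "L" else "L"

    def is_ascending(self, strand: str) -> bool:
        """True if the strand's 5'->3' direction is ascending ref coordinates.

        The deposited strand reads 5'->3' with ascending coordinates; its
        complement reads 5'->3' with descending coordinates.
        """
        if strand not in ("H", "L"):
            raise ValueError(f"unknown strand {strand!r}; expected 'H' or 'L'")
        return strand == self.strand_of_forward

    def orientation(self, strand: str) -> int:
        """+1 for the ascending strand, -1 for the descending strand."""
        return 1 if self.is_ascending(strand) else -1

    def wrap(self, pos: int) -> int:
        """Map any integer onto 1..length circularly."""
        if not self.circular and not (1 <= pos <= self.length):
            raise ValueError(f"position {pos} outside linear genome")
        return (pos - 1) % self.length + 1

    def base_at(self, pos: int, strand: str | None = None) -> str:
        """Base at a reference position as read on the given strand.

        With strand=None (or the forward strand's label) this is simply the
        deposited sequence; on the complementary strand the base is
        complemented (the coordinate does not change — it names the rung).
        """
        base = self.sequence[self.wrap(pos) - 1]
        if strand is None or strand == self.strand_of_forward:
            return base
        return COMPLEMENT[base]

    def fetch(self, start: int, length: int, strand: str | None = None) -> str:
        """Sequence of the given strand, 5'->3', starting at reference
        position ``start`` on that strand, wrapping circularly."""
        step = 1 if strand is None or self.is_ascending(strand) else -1
        return "".join(
            self.base_at(start + step * i, strand) for i in range(length)
        )


@dataclass(frozen=True)
class RestrictionSite:
    """One recognition-site match on the circle.

    ``start`` is the reference coordinate of the first base of the
    recognition hexamer on the forward strand.  For a blunt cutter severing
    between pattern positions ``cut_after`` and ``cut_after+1`` on both
    strands, the downstream fragment's 5'-terminal base sits at
    ``cut_forward = start + cut_after`` on the forward strand and at
    ``cut_reverse = start + cut_after - 1`` on the reverse strand.
    """

    start: int
    cut_forward: int
    cut_reverse: int

    def cut_coordinate(self, genome: MtGenome, strand: str) -> int:
        """Cut coordinate carrying the 5'-end on the given biological strand."""
        return self.cut_forward if genome.is_ascending(strand) else self.cut_reverse


@dataclass
class AnalysisMask:
    """Inclusion/exclusion rules for ribonucleotide totals.

    A position counts iff it lies in ``include``, in no ``exclude`` region
    and in no restriction-site window.
    """

    include: Region
    exclude: list[Region] = field(default_factory=list)
    site_windows: list[Region] = field(default_factory=list)

    def allows(self, pos: int) -> bool:
        if not self.include.contains(pos):
            return False
        for r in self.exclude:
            if r.contains(pos):
                return False
        for r in self.site_windows:
            if r.contains(pos):
                return False
        return True

    def positions(self, genome: MtGenome) -> list[int]:
        return [p for p in range(1, genome.length + 1) if self.allows(p)]


def load_reference(fasta_path: str | Path) -> MtGenome:
    """Load a single-record FASTA as a circular genome.

    Raises on a missing file, multiple records, an empty sequence, or any
    ambiguity code (mtDNA references are unambiguous; an N would silently
    corrupt strand assignment and base counting).
    """
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise FileNotFoundError(fasta_path)
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) == 0:
        raise ValueError(f"no FASTA records in {fasta_path}")
    if len(records) > 1:
        raise ValueError(
            f"{fasta_path} contains {len(records)} records; expected a single "
            "circular mitochondrial sequence"
        )
    rec = records[0]
    return MtGenome(name=rec.id, sequence=str(rec.seq))


def base_counts(
    genome: MtGenome, strand: str, mask: AnalysisMask | None = None
) -> dict[str, int]:
    """Counts of A/C/G/T as read 5'->3' on the requested biological strand.

    Complementing position by position leaves the multiset of positions
    unchanged, so the H count of base b equals the L count of complement(b)
    when unmasked.
    """
    counts = {"A": 0, "C": 0, "G": 0, "T": 0}
    for pos in range(1, genome.length + 1):
        if mask is not None and not mask.allows(pos):
            continue
        counts[genome.base_at(pos, strand)] += 1
    return counts


def _matches_at(seq: str, pattern: str, start0: int) -> bool:
    n = len(seq)
    for j, code in enumerate(pattern):
        if seq[(start0 + j) % n] not in IUPAC[code]:
            return False
    return True


def find_restriction_sites(
    genome: MtGenome, pattern: str = "GTYRAC", cut_after: int = 3
) -> list[RestrictionSite]:
    """All matches of a degenerate recognition pattern on the circle.

    The default is HincII (GTYRAC, blunt cut between positions 3 and 4),
    which is its own IUPAC reverse complement so a single forward scan
    finds every double-strand site, including origin-spanning matches.
    Non-palindromic patterns are scanned on both strands and reported by
    their forward-strand footprint.
    """
    for c in pattern:
        if c not in IUPAC:
            raise ValueError(f"invalid IUPAC code {c!r} in pattern {pattern!r}")
    if not 0 < cut_after < len(pattern):
        raise ValueError("cut_after must fall inside the pattern")

    patterns = [pattern]
    rc = iupac_revcomp(pattern)
    if rc != pattern:
        patterns.append(rc)

    seq = genome.sequence
    scan_len = genome.length if genome.circular else genome.length - len(pattern) + 1
    starts = sorted(
        {
            i
            for pat in patterns
            for i in range(scan_len)
            if _matches_at(seq, pat, i)
        }
    )
    sites = []
    for i in starts:
        start = i + 1
        sites.append(
            RestrictionSite(
                start=start,
                cut_forward=genome.wrap(start + cut_after),
                cut_reverse=genome.wrap(start + cut_after - 1),
            )
        )
    return sites


def default_masks(
    genome: MtGenome,
    sites: list[RestrictionSite],
    include: tuple[int, int] = (300, 16200),
    exclude: tuple[tuple[int, int], ...] = ((5747, 5847),),
    window: int = 5,
) -> AnalysisMask:
    """Default analysis mask: window 300-16,200, OriL 5,747-5,847 excluded,
    and a +/-window region around each restriction cut coordinate.

    The defaults presuppose rCRS-scale coordinates; on a shorter genome the
    caller must supply explicit regions.
    """
    if genome.length < include[1]:
        raise ValueError(
            f"genome length {genome.length} is shorter than the default "
            f"analysis window end {include[1]}; supply explicit include/"
            "exclude regions instead of the defaults"
        )
    site_windows = []
    for site in sites:
        for cut in (site.cut_forward, site.cut_reverse):
            lo = genome.wrap(cut - window)
            hi = genome.wrap(cut + window)
            site_windows.append(Region(lo, hi, wraps=lo > hi))
    return AnalysisMask(
        include=Region(*include),
        exclude=[Region(a, b) for a, b in exclude],
        site_windows=site_windows,
    )


# --- BED interop (0-based half-open on disk; 1-based inclusive in memory) ---

def write_regions_bed(regions: list[Region], chrom: str, length: int, path) -> None:
    """Regions as BED intervals; a wrapping region becomes two intervals."""
    with open(path, "w") as fh:
        for r in regions:
            if r.wraps:
                fh.write(f"{chrom}\t{r.start - 1}\t{length}\n")
                fh.write(f"{chrom}\t0\t{r.end}\n")
            else:
                fh.write(f"{chrom}\t{r.start - 1}\t{r.end}\n")


def read_regions_bed(path) -> list[Region]:
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            regions.append(Region(int(fields[1]) + 1, int(fields[2])))
    return regions


def write_sites_bed(sites: list[RestrictionSite], chrom: str, pattern_len: int, path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{chrom}\t{s.start - 1}\t{s.start - 1 + pattern_len}\t"
                     f"cut_fwd={s.cut_forward};cut_rev={s.cut_reverse}\n")
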