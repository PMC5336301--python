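"""Restriction-site-normalized absolute quantification of embedded
ribonucleotides, plus origin-region diagnostics.

The central trick: HincII cuts every mtDNA molecule once per site, so the
mean read count at the eleven cut sites (±5 bases) on a strand measures
"reads per molecule" *for that strand*, capture bias included.  Dividing a
strand's total masked ribonucleotide-derived reads by that strand's mean
site signal therefore cancels the (up to ~31-fold) L-over-H capture bias
and yields ribonucleotides per mtDNA molecule in absolute units.  The same
division per base identity, further divided by the strand's masked base
content and scaled by 1,000, gives the incorporation frequency per 1,000
complementary bases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .mtgenome import AnalysisMask, MtGenome, Region, RestrictionSite, base_counts
from .synthetic import STRANDS, StrandedEndCounts

__all__ = [
    "QuantResult",
    "hincii_reference_signal",
    "ribos_per_molecule",
    "strand_bias_at_sites",
    "identity_fractions",
    "freq_per_1000",
    "regional_fraction",
    "peak_positions",
    "remnant_shift",
    "quantify_library",
]

BASES_RNA = ("A", "C", "G", "U")


@dataclass
class QuantResult:
    """Per-library quantification summary.

    ribos_per_molecule  per strand, embedded ribonucleotides per mtDNA
                        molecule (absolute, bias-cancelled)
    identity_percent    per strand, percent of ribonucleotide signal that is
                        rA/rC/rG/rU (sums to 100 when signal exists)
    freq_per_1000       per strand per base, incorporations per 1,000
                        complementary bases
    hincii_mean         per strand, mean site-window signal (the per-strand
                        reads-per-molecule unit)
    bias_L_over_H_at_sites  raw L:H fold ratio at the cut-site windows
    """

    library_id: str
    ribos_per_molecule: dict[str, float] = field(default_factory=dict)
    identity_percent: dict[str, dict[str, float]] = field(default_factory=dict)
    freq_per_1000: dict[str, dict[str, float]] = field(default_factory=dict)
    hincii_mean: dict[str, float] = field(default_factory=dict)
    bias_L_over_H_at_sites: float | None = None
    n_sites_used: int = 0

    def to_dict(self) -> dict:
        return {
            "library_id": self.library_id,
            "ribos_per_molecule": self.ribos_per_molecule,
            "identity_percent": self.identity_percent,
            "freq_per_1000": self.freq_per_1000,
            "hincii_mean": self.hincii_mean,
            "bias_L_over_H_at_sites": self.bias_L_over_H_at_sites,
            "n_sites_used": self.n_sites_used,
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "QuantResult":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            library_id=d["library_id"],
            ribos_per_molecule=d["ribos_per_molecule"],
            identity_percent=d["identity_percent"],
            freq_per_1000=d["freq_per_1000"],
            hincii_mean=d["hincii_mean"],
            bias_L_over_H_at_sites=d["bias_L_over_H_at_sites"],
            n_sites_used=d["n_sites_used"],
        )


def _site_window_sum(
    counts: StrandedEndCounts,
    genome: MtGenome,
    site: RestrictionSite,
    strand: str,
    window: int,
) -> float:
    cut = site.cut_coordinate(genome, strand)
    return sum(
        counts.counts[strand].get(genome.wrap(cut + d), 0.0)
        for d in range(-window, window + 1)
    )


def hincii_reference_signal(
    counts: StrandedEndCounts,
    sites: list[RestrictionSite],
    genome: MtGenome,
    strand: str,
    window: int = 5,
) -> tuple[float, np.ndarray]:
    """Mean (and per-site vector of) read signal at the restriction cut
    coordinates ±window on one strand.

    Every molecule contributes one 5'-end per strand at each double-strand
    cut, so this mean is the strand's reads-per-molecule unit.  Raises
    "no digestion signal" when the library evidently was not digested.
    """
    if not sites:
        raise ValueError("need at least one restriction site")
    per_site = np.array(
        [_site_window_sum(counts, genome, s, strand, window) for s in sites]
    )
    if per_site.sum() <= 0:
        raise ValueError(
            f"no digestion signal on strand {strand}: was this library "
            "HincII-digested?"
        )
    return float(per_site.mean()), per_site


def ribos_per_molecule(
    counts: StrandedEndCounts,
    sites: list[RestrictionSite],
    mask: AnalysisMask,
    genome: MtGenome,
    strand: str,
    window: int = 5,
) -> float:
    """Embedded ribonucleotides per mtDNA molecule on one strand.

    Total shifted counts at mask-allowed positions (analysis window, OriL
    excluded, cut-site windows excluded) divided by the strand's mean
    cut-site signal.  Because both numerator and denominator live on the
    same strand of the same library, capture bias and sequencing depth
    cancel exactly; the result is invariant to raw-vs-RPM scale.
    """
    if not counts.shifted:
        raise ValueError(
            "ribos_per_molecule requires shifted counts (apply "
            "endmap.shift_upstream first)"
        )
    mean_site, _ = hincii_reference_signal(counts, sites, genome, strand, window)
    total = sum(
        c for pos, c in counts.counts[strand].items() if mask.allows(pos)
    )
    return total / mean_site


def strand_bias_at_sites(
    counts: StrandedEndCounts,
    sites: list[RestrictionSite],
    genome: MtGenome,
    window: int = 5,
) -> float:
    """Raw L:H fold ratio of read counts within ±window of the cut
    coordinates — the library's strand capture bias, since cuts produce
    exactly one end per strand per molecule."""
    totals = {
        s: sum(_site_window_sum(counts, genome, site, s, window) for site in sites)
        for s in STRANDS
    }
    if totals["H"] <= 0:
        raise ValueError("zero H-strand signal at restriction sites")
    return totals["L"] / totals["H"]


def identity_fractions(
    counts: StrandedEndCounts,
    genome: MtGenome,
    mask: AnalysisMask | None,
    strand: str,
) -> dict[str, float]:
    """Percent of masked ribonucleotide signal per base identity.

    Each shifted count sits on the ribonucleotide itself, so its identity
    is the genome base at that position on that strand (T reported as U).
    An empty signal returns the all-zero map.
    """
    if not counts.shifted:
        raise ValueError("identity_fractions requires shifted counts")
    sums = {b: 0.0 for b in BASES_RNA}
    for pos, c in counts.counts[strand].items():
        if mask is not None and not mask.allows(pos):
            continue
        b = genome.base_at(pos, strand)
        sums["U" if b == "T" else b] += c
    total = sum(sums.values())
    if total <= 0:
        return sums
    return {b: 100.0 * v / total for b, v in sums.items()}


def freq_per_1000(
    counts: StrandedEndCounts,
    genome: MtGenome,
    sites: list[RestrictionSite],
    mask: AnalysisMask,
    strand: str,
    window: int = 5,
) -> dict[str, float]:
    """Incorporation frequency of each ribonucleotide per 1,000
    complementary bases on one strand.

    Per base b: (per-molecule count of ribonucleotide b, via the cut-site
    division) ÷ N_b × 1000, where N_b is the masked count of base b on the
    strand where the ribonucleotide is embedded — equal to the count of
    the complementary base on the template strand.  This normalization is
    what removes the apparent rG/rC strand bias that merely reflects the
    G-rich H-strand / C-rich L-strand composition.
    """
    if not counts.shifted:
        raise ValueError("freq_per_1000 requires shifted counts")
    mean_site, _ = hincii_reference_signal(counts, sites, genome, strand, window)
    sums = {b: 0.0 for b in BASES_RNA}
    for pos, c in counts.counts[strand].items():
        if not mask.allows(pos):
            continue
        b = genome.base_at(pos, strand)
        sums["U" if b == "T" else b] += c
    n_b = base_counts(genome, strand, mask)
    out = {}
    for b in BASES_RNA:
        dna_base = "T" if b == "U" else b
        if n_b[dna_base] == 0:
            raise ValueError(f"no masked positions of base {dna_base} on {strand}")
        out[b] = (sums[b] / mean_site) / n_b[dna_base] * 1000.0
    return out


def regional_fraction(
    counts: StrandedEndCounts, region: Region, strand: str
) -> float:
    """Fraction of a strand's total counts falling inside a (possibly
    origin-wrapping) region."""
    total = counts.total(strand)
    if total <= 0:
        raise ValueError(f"no counts on strand {strand}")
    inside = sum(
        c for pos, c in counts.counts[strand].items() if region.contains(pos)
    )
    return inside / total


def peak_positions(
    counts: StrandedEndCounts, strand: str, k: int = 3
) -> list[tuple[int, float]]:
    """Top-k positions by count, descending; ties broken by ascending
    coordinate."""
    if k < 1:
        raise ValueError("k must be >= 1")
    items = sorted(counts.counts[strand].items(), key=lambda pc: (-pc[1], pc[0]))
    return items[:k]


def _modal_position(
    counts: StrandedEndCounts, region: Region, strand: str
) -> int:
    in_region = {
        pos: c for pos, c in counts.counts[strand].items() if region.contains(pos)
    }
    if not in_region:
        raise ValueError(f"no counts in region on strand {strand}")
    return min(in_region, key=lambda p: (-in_region[p], p))


def remnant_shift(
    koh: StrandedEndCounts,
    kcl: StrandedEndCounts,
    region: Region,
    strand: str,
    genome: MtGenome,
) -> int:
    """Displacement (in nt, positive = downstream in the strand's 3'
    direction) of the modal raw 5'-end after alkali versus mock treatment.

    A free 5'-end carrying n terminal ribonucleotides (an RNase H1
    primer remnant leaves two) moves +n under alkali, because hydrolysis
    strips the end through its 3'-most ribonucleotide.
    """
    if koh.shifted or kcl.shifted:
        raise ValueError("remnant_shift compares raw (unshifted) 5'-ends")
    diff = _modal_position(koh, region, strand) - _modal_position(
        kcl, region, strand
    )
    return diff * genome.orientation(strand)


def quantify_library(
    counts: StrandedEndCounts,
    genome: MtGenome,
    sites: list[RestrictionSite],
    mask: AnalysisMask,
    window: int = 5,
) -> QuantResult:
    """Full per-library summary (both strands) from shifted counts of a
    KOH + digested library."""
    result = QuantResult(library_id=counts.library_id, n_sites_used=len(sites))
    for strand in STRANDS:
        mean_site, _ = hincii_reference_signal(counts, sites, genome, strand, window)
        result.hincii_mean[strand] = mean_site
        result.ribos_per_molecule[strand] = ribos_per_molecule(
            counts, sites, mask, genome, strand, window
        )
        result.identity_percent[strand] = identity_fractions(
            counts, genome, mask, strand
        )
        result.freq_per_1000[strand] = freq_per_1000(
            counts, genome, sites, mask, strand, window
        )
    result.bias_L_over_H_at_sites = strand_bias_at_sites(
        counts, sites, genome, window
    )
    return result
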