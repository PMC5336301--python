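"""Model of the primer-extension ribonucleotide-incorporation assay.

A primed template (a 70-nt oligo annealed to a 40-nt primer, leaving a
30-nt single-stranded 5' tail) is extended by the mitochondrial replicase
in the presence of competing dNTPs and rNTPs; full-length products are
hydrolysed with alkali (which cleaves 3' of each embedded ribonucleotide)
or nicked with RNase H2 (which cleaves 5' of it), and the cleavage ladder
read off a sequencing gel gives per-position incorporation fractions.

This module covers the surrounding arithmetic: tail extraction and
composition, rNTP:dNTP fold-excess, a simple competitive-substrate
incorporation probability p = [rNTP] / ([rNTP] + D·[dNTP]) built on
published per-base discrimination factors D (a modelling choice, clearly
so labelled — the assay itself reports rates, not an equation), ladder
prediction under the two cleavage chemistries, and back-calculation of
the per-dNMP incorporation rate from per-position cleaved fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

from .mtgenome import revcomp

__all__ = [
    "PrimedTemplate",
    "InVitroConditions",
    "CleavageLadder",
    "TEMPLATE_70NT",
    "PRIMER_40NT",
    "DISCRIMINATION_FOLDS",
    "make_primed_template",
    "composition_percent",
    "fold_excess",
    "incorporation_probability",
    "expected_count",
    "cleavage_ladder",
    "rate_from_cleavage_fractions",
]

# The assay oligos: a 70-nt template and the 40-nt primer annealing to its
# 3' end, leaving a 30-nt single-stranded tail to copy.
TEMPLATE_70NT = (
    "ATGACCATGATTACGAATTCCAGCTCGGTACCGGGTTGACCTTTGGAGTCGACCTGCAGAAATTCACTGG"
)
PRIMER_40NT = "CCAGTGAATTTCTGCAGGTCGACTCCAAAGGTCAACCCGG"

# Published single-nucleotide discrimination of the mitochondrial replicase:
# fold preference for the dNTP over the corresponding rNTP.
DISCRIMINATION_FOLDS = {"G": 1_100.0, "U": 77_000.0}


@dataclass(frozen=True)
class PrimedTemplate:
    """Template/primer pair with the single-stranded 5' tail extracted."""

    template: str
    primer: str
    tail: str

    @property
    def tail_length(self) -> int:
        return len(self.tail)


@dataclass
class InVitroConditions:
    """Nucleotide concentrations (μM) and per-base discrimination folds."""

    rntp_conc: dict[str, float] = field(default_factory=dict)
    dntp_conc: dict[str, float] = field(default_factory=dict)
    discrimination: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for d in (self.rntp_conc, self.dntp_conc):
            for b, c in d.items():
                if c < 0:
                    raise ValueError(f"negative concentration for {b}")
        for b, f in self.discrimination.items():
            if f <= 0:
                raise ValueError(f"discrimination factor for {b} must be > 0")


@dataclass(frozen=True)
class CleavageLadder:
    """Cleavage-generated 5'-end offsets along the nascent strand (1-based,
    strictly increasing)."""

    treatment: str
    fragment_5p_offsets: tuple[int, ...]


def make_primed_template(
    template_seq: str = TEMPLATE_70NT, primer_seq: str = PRIMER_40NT
) -> PrimedTemplate:
    """Anneal the primer to the template's 3' end and extract the tail.

    The primer must anneal exactly: its reverse complement must be a
    suffix of the template.  The tail is the template's remaining 5'
    portion (the sequence the polymerase will copy).
    """
    template_seq = template_seq.replace(" ", "").upper()
    primer_seq = primer_seq.replace(" ", "").upper()
    annealed = revcomp(primer_seq)
    if not template_seq.endswith(annealed):
        raise ValueError(
            "primer does not anneal exactly to the template 3' end"
        )
    tail = template_seq[: len(template_seq) - len(primer_seq)]
    return PrimedTemplate(template=template_seq, primer=primer_seq, tail=tail)


def composition_percent(seq: str) -> dict[str, float]:
    """Base composition of a sequence in percent (exact rational sums)."""
    seq = seq.replace(" ", "").upper()
    if not seq:
        raise ValueError("empty sequence")
    n = len(seq)
    return {b: float(Fraction(100 * seq.count(b), n)) for b in "ACGT"}


def fold_excess(conditions: InVitroConditions) -> dict[str, float]:
    """rNTP:dNTP concentration ratio per base, plus the ratio of totals
    under key ``"overall"``."""
    out = {}
    for b, d in conditions.dntp_conc.items():
        if d <= 0:
            raise ValueError(f"zero dNTP concentration for {b}")
        out[b] = conditions.rntp_conc.get(b, 0.0) / d
    total_d = sum(conditions.dntp_conc.values())
    if total_d <= 0:
        raise ValueError("zero total dNTP concentration")
    out["overall"] = sum(conditions.rntp_conc.values()) / total_d
    return out


def incorporation_probability(base: str, conditions: InVitroConditions) -> float:
    """Probability that one templated position receives the ribonucleotide
    rather than the deoxyribonucleotide.

    Competitive-substrate model: p = r / (r + D·d) with r, d the rNTP and
    dNTP concentrations and D the discrimination fold.  Equivalently the
    odds form p = ρ/(ρ + D) with ρ = r/d the fold excess.  This equation
    is this package's modelling choice, not a measured relationship.
    """
    r = conditions.rntp_conc.get(base, 0.0)
    d = conditions.dntp_conc.get(base, 0.0)
    D = conditions.discrimination.get(base, 1.0)
    if r == 0 and d == 0:
        raise ValueError(f"both concentrations zero for base {base}")
    return r / (r + D * d)


def expected_count(rate: float, strand_length: int, rounded: bool = False):
    """Expected embedded ribonucleotides in a strand, given a per-dNMP
    incorporation rate (e.g. 1/2,000) and the strand length in bases."""
    if rate < 0 or strand_length < 0:
        raise ValueError("rate and strand_length must be non-negative")
    expected = rate * strand_length
    return round(expected) if rounded else expected


def cleavage_ladder(
    nascent_length: int, ribo_offsets: list[int], treatment: str
) -> CleavageLadder:
    """Predicted cleavage 5'-ends for a nascent strand with ribonucleotides
    at the given 1-based offsets.

    Alkali (KOH) cleaves on the 3' side of each ribonucleotide, leaving a
    5'-end at offset+1; RNase H2 nicks on the 5' side, leaving it at the
    offset itself — so the two ladders differ by exactly 1 nt per site.
    """
    if treatment not in ("KOH", "RNaseH2"):
        raise ValueError(f"treatment must be KOH or RNaseH2, got {treatment!r}")
    for off in ribo_offsets:
        if not 1 <= off <= nascent_length:
            raise ValueError(f"ribonucleotide offset {off} outside nascent strand")
    delta = 1 if treatment == "KOH" else 0
    offsets = tuple(sorted({off + delta for off in ribo_offsets}))
    return CleavageLadder(treatment=treatment, fragment_5p_offsets=offsets)


def rate_from_cleavage_fractions(
    per_position_cleaved_fraction: list[float], synthesized_length: int
) -> float:
    """Per-dNMP incorporation rate from a gel ladder quantified as the
    cleaved fraction of total product at each position: the sum of
    per-position fractions is the expected ribonucleotides per product,
    divided by the synthesized length."""
    if synthesized_length <= 0:
        raise ValueError("synthesized_length must be positive")
    for f in per_position_cleaved_fraction:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"cleaved fraction {f} outside [0, 1]")
    return sum(per_position_cleaved_fraction) / synthesized_length
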