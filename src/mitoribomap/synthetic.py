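"""Synthetic HydEn-seq / 5'-End-seq libraries with planted ground truth.

HydEn-seq maps ribonucleotides embedded in DNA: alkali (KOH) cleaves the
backbone on the 3'-side of each embedded ribonucleotide, and the exposed
5'-ends are sequenced.  The KCl mock treatment (5'-End-seq) captures only
pre-existing free 5'-ends.  This module plants a known ground truth —
embedded ribonucleotides per strand, free 5'-end hotspots (the OriH peaks,
the OriL primer remnant), restriction cuts — and samples reads from the
implied 5'-end weight distribution, so every downstream estimator can be
validated by parameter recovery.

End-capture geometry, per strand in its own 5'->3' orientation:

* a ribonucleotide at position r yields (under KOH, if hydrolysed) a raw
  5'-end at the position immediately 3' of r: reference r+1 on the
  ascending strand, r-1 on the descending strand, wrapped;
* a free 5'-end or restriction cut yields a raw end at its own coordinate;
* an RNase H1-processed primer remnant with n retained 5'-terminal
  ribonucleotides yields a KCl end at the junction and a KOH end displaced
  n bases downstream (alkali removes the remnant up to the last ribo);
* every weight on the L-strand is multiplied by the library's capture-bias
  factor before multinomial sampling, emulating the strong (up to ~31-fold)
  L-over-H recovery bias of these libraries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .mtgenome import (
    IUPAC,
    AnalysisMask,
    MtGenome,
    RestrictionSite,
    find_restriction_sites,
)

__all__ = [
    "RiboMap",
    "FreeEndMap",
    "PrimerRemnant",
    "LibraryConfig",
    "StrandedEndCounts",
    "plant_ribos",
    "default_free_ends",
    "simulate_library",
    "library_expectation",
    "write_truth",
    "read_truth",
    "write_endcounts",
    "emit_fastq",
    "synthetic_reference",
    "ORIH_HOTSPOTS",
    "ORIL_FREE_END_REGION",
]

STRANDS = ("H", "L")

# Free 5'-end landmarks of human mtDNA in rCRS numbering: the three major
# H-strand ends downstream of OriH, and the L-strand free-end zone at OriL.
ORIH_HOTSPOTS = (111, 149, 191)
ORIL_FREE_END_REGION = (5768, 5776)


@dataclass
class RiboMap:
    """Planted embedded ribonucleotides: per strand, (position, base) with
    the base read on that strand and T reported as U."""

    entries: dict[str, list[tuple[int, str]]] = field(
        default_factory=lambda: {"H": [], "L": []}
    )

    def positions(self, strand: str) -> list[int]:
        return [p for p, _ in self.entries[strand]]

    def count(self, strand: str) -> int:
        return len(self.entries[strand])


@dataclass
class FreeEndMap:
    """Planted free 5'-end hotspots: per strand, (position, weight)."""

    entries: dict[str, list[tuple[int, float]]] = field(
        default_factory=lambda: {"H": [], "L": []}
    )


@dataclass(frozen=True)
class PrimerRemnant:
    """A 5'-terminal run of ribonucleotides left on a nascent strand after
    incomplete primer removal (RNase H1 leaves the last two).

    ``junction`` is the reference coordinate of the 5'-most retained
    ribonucleotide; the run extends ``n_ribos`` bases in the strand's 3'
    direction (n_ribos=0 degenerates to a plain free end).
    """

    strand: str
    junction: int
    n_ribos: int = 2

    def __post_init__(self) -> None:
        if self.n_ribos < 0:
            raise ValueError("n_ribos must be >= 0")
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")


@dataclass
class LibraryConfig:
    """Conditions of one simulated library.

    treatment        KOH (alkaline hydrolysis; ribonucleotides visible) or
                     KCl (mock; free ends only)
    digested         whether HincII double-strand cuts were introduced
    depth            total reads sampled (multinomial, fixed depth)
    strand_bias_L_over_H
                     multiplicative capture-efficiency ratio applied to all
                     L-strand weights (the in vivo libraries show up to
                     ~31-fold)
    cleavage_prob    probability each embedded ribonucleotide is hydrolysed
                     under KOH (1.0 = complete hydrolysis, the estimator's
                     assumption)
    background_end_rate
                     uniform free-end weight added at every position of
                     both strands (nicks/degradation background)
    """

    treatment: str = "KOH"
    digested: bool = True
    depth: int = 1_000_000
    strand_bias_L_over_H: float = 1.0
    cleavage_prob: float = 1.0
    background_end_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.treatment not in ("KOH", "KCl"):
            raise ValueError(f"treatment must be KOH or KCl, got {self.treatment!r}")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0.0 <= self.cleavage_prob <= 1.0:
            raise ValueError("cleavage_prob must be in [0, 1]")
        if self.strand_bias_L_over_H <= 0:
            raise ValueError("strand bias must be positive")
        if self.background_end_rate < 0:
            raise ValueError("background_end_rate must be >= 0")


@dataclass
class StrandedEndCounts:
    """Per-position, per-strand read 5'-end counts for one library.

    ``shifted`` is False for raw read 5'-ends and True once the one-base
    upstream shift has moved each end onto the free 5'-end / hydrolysed
    ribonucleotide itself.  ``scale`` is "raw" (counts) or "RPM" (reads per
    million over both strands).
    """

    library_id: str
    counts: dict[str, dict[int, float]] = field(
        default_factory=lambda: {"H": {}, "L": {}}
    )
    scale: str = "raw"
    shifted: bool = False
    metadata: dict = field(default_factory=dict)

    def total(self, strand: str | None = None) -> float:
        if strand is None:
            return sum(self.total(s) for s in STRANDS)
        return float(sum(self.counts[strand].values()))

    def add(self, strand: str, pos: int, count: float = 1.0) -> None:
        self.counts[strand][pos] = self.counts[strand].get(pos, 0.0) + count


def plant_ribos(
    genome: MtGenome,
    planting: dict,
    seed: int,
    mask: AnalysisMask | None = None,
) -> RiboMap:
    """Plant embedded ribonucleotides on each strand.

    ``planting`` is either per-strand totals, e.g. ``{"H": 20, "L": 16}``
    (exactly that many distinct positions, uniform over eligible positions),
    or per-strand per-base rates, e.g. ``{"H": {"G": 2e-3, ...}, ...}``
    (each eligible position of base b is a ribonucleotide independently
    with probability rate(b)).  ``mask`` restricts the eligible positions;
    by default every position is eligible.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    eligible = (
        list(range(1, genome.length + 1)) if mask is None else mask.positions(genome)
    )
    ribo = RiboMap()
    for strand in STRANDS:
        want = planting.get(strand)
        if want is None:
            continue
        if isinstance(want, dict):
            for base, rate in want.items():
                if rate < 0:
                    raise ValueError(f"negative rate for {strand}:{base}")
            for pos in eligible:
                b = genome.base_at(pos, strand)
                key = "U" if b == "T" else b
                rate = want.get(key, want.get(b, 0.0))
                if rate > 0 and rng.random() < rate:
                    ribo.entries[strand].append((pos, key))
        else:
            n = int(want)
            if n > len(eligible):
                raise ValueError(
                    f"cannot plant {n} ribonucleotides on strand {strand}: only "
                    f"{len(eligible)} eligible positions"
                )
            chosen = rng.choice(len(eligible), size=n, replace=False)
            for i in sorted(chosen):
                pos = eligible[i]
                b = genome.base_at(pos, strand)
                ribo.entries[strand].append((pos, "U" if b == "T" else b))
    return ribo


def default_free_ends(
    genome: MtGenome,
    orih_weights: tuple[float, float, float] = (3.0, 2.0, 1.0),
    per_molecule: float = 1.0,
) -> FreeEndMap:
    """Free 5'-end hotspots mimicking the in vivo landscape: the three
    H-strand OriH ends (111/149/191, deepest first by default) and a
    uniform L-strand zone at OriL (5,768-5,776)."""
    ends = FreeEndMap()
    total = sum(orih_weights)
    for pos, w in zip(ORIH_HOTSPOTS, orih_weights):
        ends.entries["H"].append((pos, per_molecule * w / total))
    lo, hi = ORIL_FREE_END_REGION
    n = hi - lo + 1
    for pos in range(lo, hi + 1):
        ends.entries["L"].append((pos, per_molecule / n))
    return ends


def _end_weights(
    genome: MtGenome,
    ribos: RiboMap | None,
    ends: FreeEndMap | None,
    remnants: list[PrimerRemnant] | None,
    sites: list[RestrictionSite] | None,
    cfg: LibraryConfig,
    rng: np.random.Generator | None,
) -> dict[str, dict[int, float]]:
    """Per-strand raw-5'-end weight vectors implied by the planted truth.

    With rng=None, hydrolysis is treated in expectation (weight scaled by
    cleavage_prob) instead of Bernoulli-thinned.
    """
    w: dict[str, dict[int, float]] = {"H": {}, "L": {}}

    def add(strand: str, pos: int, weight: float) -> None:
        pos = genome.wrap(pos)
        w[strand][pos] = w[strand].get(pos, 0.0) + weight

    if ends is not None:
        for strand in STRANDS:
            for pos, weight in ends.entries[strand]:
                if weight < 0:
                    raise ValueError("free-end weights must be non-negative")
                add(strand, pos, weight)
    if cfg.background_end_rate > 0:
        for strand in STRANDS:
            for pos in range(1, genome.length + 1):
                add(strand, pos, cfg.background_end_rate)

    if cfg.treatment == "KOH" and ribos is not None:
        for strand in STRANDS:
            step = genome.orientation(strand)
            for pos, _base in ribos.entries[strand]:
                if rng is None:
                    weight = cfg.cleavage_prob
                elif rng.random() < cfg.cleavage_prob:
                    weight = 1.0
                else:
                    continue
                # alkali cleaves 3' of the ribo: the new 5'-end is one base
                # downstream in the strand's own orientation
                add(strand, pos + step, weight)

    if cfg.digested and sites:
        for site in sites:
            add(genome.strand_of_forward, site.cut_forward, 1.0)
            add(genome.strand_of_reverse, site.cut_reverse, 1.0)

    if remnants:
        for rem in remnants:
            step = genome.orientation(rem.strand)
            if cfg.treatment == "KCl":
                add(rem.strand, rem.junction, 1.0)
            else:
                # alkali strips the remnant through its 3'-most ribo
                add(rem.strand, rem.junction + step * rem.n_ribos, 1.0)

    for pos in list(w["L"]):
        w["L"][pos] *= cfg.strand_bias_L_over_H
    return w


def simulate_library(
    genome: MtGenome,
    ribos: RiboMap | None,
    ends: FreeEndMap | None,
    remnants: list[PrimerRemnant] | None,
    sites: list[RestrictionSite] | None,
    cfg: LibraryConfig,
    library_id: str = "sim",
) -> StrandedEndCounts:
    """Sample one library: raw, unshifted read 5'-end counts.

    Builds the per-strand capturable-end weight vector from all planted
    sources and draws ``cfg.depth`` reads multinomially.  Weights are
    relative; only ratios matter.
    """
    rng = np.random.default_rng(cfg.seed)
    w = _end_weights(genome, ribos, ends, remnants, sites, cfg, rng)
    keys = [(s, p) for s in STRANDS for p in sorted(w[s])]
    weights = np.array([w[s][p] for s, p in keys], dtype=float)
    total = weights.sum()
    if total <= 0:
        raise ValueError(
            "empty total weight: no capturable 5'-ends under these conditions "
            "(note that embedded ribonucleotides are invisible to KCl)"
        )
    draws = rng.multinomial(cfg.depth, weights / total)
    out = StrandedEndCounts(
        library_id=library_id,
        scale="raw",
        shifted=False,
        metadata={
            "seed": cfg.seed,
            "treatment": cfg.treatment,
            "digested": cfg.digested,
            "depth": cfg.depth,
            "strand_bias_L_over_H": cfg.strand_bias_L_over_H,
        },
    )
    for (strand, pos), n in zip(keys, draws):
        if n > 0:
            out.counts[strand][pos] = float(n)
    return out


def library_expectation(
    genome: MtGenome,
    ribos: RiboMap | None,
    ends: FreeEndMap | None,
    remnants: list[PrimerRemnant] | None,
    sites: list[RestrictionSite] | None,
    cfg: LibraryConfig,
    library_id: str = "expected",
) -> StrandedEndCounts:
    """Noise-free analog of :func:`simulate_library`: the expected end
    weights themselves as counts (no multinomial sampling, hydrolysis in
    expectation).  Useful for exact algebraic checks of the estimators."""
    w = _end_weights(genome, ribos, ends, remnants, sites, cfg, rng=None)
    total = sum(v for s in STRANDS for v in w[s].values())
    if total <= 0:
        raise ValueError("empty total weight")
    out = StrandedEndCounts(
        library_id=library_id,
        scale="raw",
        shifted=False,
        metadata={"treatment": cfg.treatment, "digested": cfg.digested,
                  "expectation": True},
    )
    for strand in STRANDS:
        out.counts[strand] = dict(sorted(w[strand].items()))
    return out


# ----------------------------- persistence -----------------------------

def write_truth(
    ribos: RiboMap | None,
    ends: FreeEndMap | None,
    remnants: list[PrimerRemnant] | None,
    path: str | Path,
) -> None:
    """Ground truth as a BED-like TSV: pos, strand, base, kind, weight."""
    with open(path, "w") as fh:
        fh.write("pos\tstrand\tbase\tkind\tweight\n")
        if ribos is not None:
            for strand in STRANDS:
                for pos, base in ribos.entries[strand]:
                    fh.write(f"{pos}\t{strand}\t{base}\tribo\t1\n")
        if ends is not None:
            for strand in STRANDS:
                for pos, weight in ends.entries[strand]:
                    fh.write(f"{pos}\t{strand}\t.\tfree_end\t{weight:g}\n")
        if remnants:
            for rem in remnants:
                fh.write(
                    f"{rem.junction}\t{rem.strand}\t.\tremnant\t{rem.n_ribos}\n"
                )


def read_truth(path: str | Path):
    """Inverse of :func:`write_truth`."""
    ribos, ends, remnants = RiboMap(), FreeEndMap(), []
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("pos")
        for line in fh:
            pos, strand, base, kind, weight = line.rstrip("\n").split("\t")
            if kind == "ribo":
                ribos.entries[strand].append((int(pos), base))
            elif kind == "free_end":
                ends.entries[strand].append((int(pos), float(weight)))
            elif kind == "remnant":
                remnants.append(PrimerRemnant(strand, int(pos), int(float(weight))))
    return ribos, ends, remnants


def write_endcounts(counts: StrandedEndCounts, path: str | Path) -> None:
    """End counts as TSV (1-based pos, strand H/L, count) with a metadata
    header so a round trip restores scale/shifted flags."""
    with open(path, "w") as fh:
        fh.write(f"# library_id={counts.library_id}\n")
        fh.write(f"# scale={counts.scale}\n")
        fh.write(f"# shifted={int(counts.shifted)}\n")
        fh.write("pos\tstrand\tcount\n")
        for strand in STRANDS:
            for pos in sorted(counts.counts[strand]):
                fh.write(f"{pos}\t{strand}\t{counts.counts[strand][pos]:.10g}\n")


def emit_fastq(
    counts: StrandedEndCounts,
    genome: MtGenome,
    read_length: int,
    path: str | Path,
) -> int:
    """Reads as exact genome substrings starting at each sampled 5'-end
    (in the strand's own 5'->3' orientation), for external-aligner round
    trips.  Returns the number of records written."""
    n = 0
    with open(path, "w") as fh:
        for strand in STRANDS:
            for pos in sorted(counts.counts[strand]):
                copies = int(round(counts.counts[strand][pos]))
                seq = genome.fetch(pos, read_length, strand)
                for i in range(copies):
                    n += 1
                    fh.write(f"@{counts.library_id}:{strand}:{pos}:{i}\n")
                    fh.write(seq + "\n+\n" + "I" * read_length + "\n")
    return n


# ----------------------- synthetic reference genome -----------------------

def synthetic_reference(
    seed: int = 2020,
    length: int = 16569,
    n_sites: int = 11,
    name: str = "chrM_synthetic",
) -> MtGenome:
    """SYNTHETIC stand-in for the human mtDNA reference (rCRS).

    A random circular sequence of rCRS length with the forward strand drawn
    at the real L-strand base composition (C-rich, so the forward strand is
    assigned L and the reverse complement H, as for rCRS), with exactly
    ``n_sites`` HincII (GTYRAC) recognition sites planted at spread-out
    coordinates and every chance match scrubbed.  It reproduces the
    coordinate conventions and compositional strand asymmetry of the real
    molecule, not its actual sequence.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    # rCRS forward-strand (L-strand) composition: A .309, C .313, G .131, T .247
    probs = np.array([0.309, 0.313, 0.131, 0.247])
    seq = list(rng.choice(bases, size=length, p=probs / probs.sum()))

    # plant n_sites concrete GTYRAC instances at spread positions (1-based)
    site_starts = np.linspace(900, length - 1200, n_sites).astype(int)
    hexamers = ["GTCGAC", "GTTAAC", "GTCAAC", "GTTGAC"]
    for k, start in enumerate(site_starts):
        hexamer = hexamers[k % len(hexamers)]
        for j, c in enumerate(hexamer):
            seq[start - 1 + j] = c

    genome = MtGenome(name=name, sequence="".join(seq))
    planted = set(int(s) for s in site_starts)
    planted_footprint = {
        genome.wrap(s + j) for s in planted for j in range(6)
    }
    pattern = "GTYRAC"
    # scrub chance matches (expected ~a dozen in 16.6 kb at this composition);
    # a mutation can itself create a new match, so rescan until stable
    for _ in range(200):
        extra = [s for s in find_restriction_sites(genome)
                 if s.start not in planted]
        if not extra:
            break
        seq = list(genome.sequence)
        for site in extra:
            for j in range(6):
                pos = genome.wrap(site.start + j)
                if pos in planted_footprint:
                    continue
                forbidden = IUPAC[pattern[j]]
                seq[pos - 1] = next(b for b in "ACGT" if b not in forbidden)
                break
        genome = MtGenome(name=name, sequence="".join(seq))
    else:  # pragma: no cover - generator invariant
        raise RuntimeError("failed to scrub chance restriction sites")

    found = {s.start for s in find_restriction_sites(genome)}
    if found != planted:  # pragma: no cover - generator invariant
        raise RuntimeError("synthetic reference lost a planted site")
    if genome.strand_of_forward != "L":  # pragma: no cover
        warnings.warn("synthetic reference forward strand is not C-rich")
    return genome
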