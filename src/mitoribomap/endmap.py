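"""Ingestion and normalization of strand-specific read 5'-end maps.

Raw read 5'-ends sit one base 3' of the feature that created them (the
hydrolysed ribonucleotide or the free 5'-end), because the sequenced base
is the first nucleotide *after* the break.  ``shift_upstream`` moves every
count one base 5' in its strand's own orientation, placing it on the
feature itself; all quantification downstream operates on shifted counts.
RPM normalization and strand-resolved bedGraph export follow the usual
conventions for these libraries.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy import stats

from .mtgenome import MtGenome
from .synthetic import STRANDS, StrandedEndCounts

__all__ = [
    "read_ends",
    "merge",
    "shift_upstream",
    "unshift",
    "rpm_normalize",
    "write_bedgraph",
    "pairwise_spearman",
]


def _bed_strand_to_biological(symbol: str, genome: MtGenome) -> str:
    """A '+'-aligned read is a fragment of the deposited strand, so it
    carries that strand's biological label (L for rCRS-like genomes)."""
    if symbol == "+":
        return genome.strand_of_forward
    if symbol == "-":
        return genome.strand_of_reverse
    raise ValueError(f"unknown strand symbol {symbol!r}")


def read_ends(
    path: str | Path, genome: MtGenome, library_id: str | None = None
) -> StrandedEndCounts:
    """Read raw 5'-end positions from BED (6-column, 0-based half-open) or
    the package TSV (1-based pos/strand/count), aggregating duplicates.

    For a BED record the read 5'-end is the interval start for '+' reads
    and the interval end for '-' reads (both converted to 1-based).
    """
    path = Path(path)
    out = StrandedEndCounts(library_id=library_id or path.stem)
    with open(path) as fh:
        header_meta: dict[str, str] = {}
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    k, _, v = line.lstrip("# ").partition("=")
                    header_meta[k.strip()] = v.strip()
                continue
            fields = line.split("\t")
            if fields[0] in ("pos", "position"):
                continue  # TSV header
            if path.suffix.lower() == ".bed" or (
                len(fields) >= 6 and fields[5] in "+-"
            ):
                start0, end0 = int(fields[1]), int(fields[2])
                strand = _bed_strand_to_biological(fields[5], genome)
                pos = start0 + 1 if fields[5] == "+" else end0
                count = 1.0
            else:
                pos, strand, count = int(fields[0]), fields[1], float(fields[2])
                if strand not in STRANDS:
                    raise ValueError(f"unknown strand symbol {strand!r}")
            if not 1 <= pos <= genome.length:
                raise ValueError(
                    f"position {pos} outside genome of length {genome.length}"
                )
            out.add(strand, pos, count)
    if header_meta.get("library_id"):
        out.library_id = header_meta["library_id"]
    out.scale = header_meta.get("scale", "raw")
    out.shifted = bool(int(header_meta.get("shifted", "0")))
    return out


def merge(a: StrandedEndCounts, b: StrandedEndCounts) -> StrandedEndCounts:
    """Sum two count maps (same scale/shift state required)."""
    if (a.scale, a.shifted) != (b.scale, b.shifted):
        raise ValueError("cannot merge counts with different scale/shift state")
    out = StrandedEndCounts(
        library_id=a.library_id, scale=a.scale, shifted=a.shifted,
        metadata=dict(a.metadata),
    )
    for src in (a, b):
        for strand in STRANDS:
            for pos, c in src.counts[strand].items():
                out.add(strand, pos, c)
    return out


def shift_upstream(counts: StrandedEndCounts, genome: MtGenome) -> StrandedEndCounts:
    """Move every raw 5'-end one base upstream (5' in its strand's own
    orientation, wrapping circularly) onto the free end / hydrolysed
    ribonucleotide itself.  Total count is conserved; the map is a
    bijection on positions per strand."""
    if counts.shifted:
        raise ValueError("counts are already shifted; refusing to double-shift")
    out = StrandedEndCounts(
        library_id=counts.library_id, scale=counts.scale, shifted=True,
        metadata=dict(counts.metadata),
    )
    for strand in STRANDS:
        step = genome.orientation(strand)
        for pos, c in counts.counts[strand].items():
            out.add(strand, genome.wrap(pos - step), c)
    return out


def unshift(counts: StrandedEndCounts, genome: MtGenome) -> StrandedEndCounts:
    """Inverse of :func:`shift_upstream` (restores raw read 5'-ends)."""
    if not counts.shifted:
        raise ValueError("counts are not shifted")
    out = StrandedEndCounts(
        library_id=counts.library_id, scale=counts.scale, shifted=False,
        metadata=dict(counts.metadata),
    )
    for strand in STRANDS:
        step = genome.orientation(strand)
        for pos, c in counts.counts[strand].items():
            out.add(strand, genome.wrap(pos + step), c)
    return out


def rpm_normalize(counts: StrandedEndCounts) -> StrandedEndCounts:
    """Reads per million over both strands combined."""
    total = counts.total()
    if total <= 0:
        raise ValueError("empty library: cannot RPM-normalize zero reads")
    out = StrandedEndCounts(
        library_id=counts.library_id, scale="RPM", shifted=counts.shifted,
        metadata=dict(counts.metadata),
    )
    for strand in STRANDS:
        for pos, c in counts.counts[strand].items():
            out.counts[strand][pos] = c * 1e6 / total
    return out


def write_bedgraph(
    counts: StrandedEndCounts, strand: str, path: str | Path, chrom: str = "chrM"
) -> None:
    """Single-strand bedGraph (0-based half-open single-base intervals),
    values on the scale of the input counts."""
    with open(path, "w") as fh:
        fh.write(
            f'track type=bedGraph name="{counts.library_id}_{strand}"\n'
        )
        for pos in sorted(counts.counts[strand]):
            fh.write(f"{chrom}\t{pos - 1}\t{pos}\t{counts.counts[strand][pos]:.10g}\n")


def pairwise_spearman(
    libraries: list[StrandedEndCounts],
    strand: str,
    universe: str = "union",
    genome: MtGenome | None = None,
) -> np.ndarray:
    """Spearman rank correlation between libraries on one strand.

    The position universe is the union of observed positions with zeros
    filled (``universe="union"``, default) or every genome position
    (``universe="genome"``, requires ``genome``).  Returns a symmetric
    matrix with a unit diagonal.
    """
    if len(libraries) < 2:
        raise ValueError("need at least two libraries")
    if universe == "genome":
        if genome is None:
            raise ValueError('universe="genome" requires the genome')
        positions = list(range(1, genome.length + 1))
    elif universe == "union":
        pos_set: set[int] = set()
        for lib in libraries:
            pos_set |= set(lib.counts[strand])
        positions = sorted(pos_set)
    else:
        raise ValueError(f"unknown universe {universe!r}")
    mat = np.array(
        [[lib.counts[strand].get(p, 0.0) for p in positions] for lib in libraries]
    )
    n = len(libraries)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            rho = stats.spearmanr(mat[i], mat[j]).statistic
            out[i, j] = out[j, i] = rho
    return out
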