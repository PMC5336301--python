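# Methods

## Coordinate and strand conventions

All positions are 1-based, inclusive, circular reference coordinates
(rCRS numbering for human mtDNA); a coordinate names a rung of the duplex,
the same on both strands. Regions may wrap the origin (`wraps=True`:
position p is inside iff p ≥ start or p ≤ end), and every coordinate
operation wraps modulo the genome length.

Strand labels are biological, not alignment-based: the H-strand is defined
as the strand with the higher G fraction, assigned from the sequence at
load time. The deposited human reference is C-rich, so the forward
sequence is the L-strand; the L-strand reads 5′→3′ in ascending
coordinates and the H-strand in descending coordinates. A read aligned to
the forward strand is therefore a fragment of the L-strand. This is the
only assignment consistent with the compositional definition of the two
strands, and it is asserted rather than assumed (loading a G-rich
reference flips the labels coherently everywhere).

## End-capture geometry

The sequenced 5′-end of a fragment is the first base *after* the break
that created it. Per strand, in that strand's own 5′→3′ orientation:

* alkali cleaves on the 3′-side of an embedded ribonucleotide at r, so the
  raw 5′-end appears at r+1 (ascending strand) or r−1 (descending);
* a free 5′-end or restriction cut produces a raw end at its own
  coordinate;
* RNase H2 (modelled in `invitro`) nicks on the 5′-side, one nucleotide
  short of the alkaline product — the two cleavage ladders are shifted
  copies of each other.

The one-base upstream shift (`endmap.shift_upstream`) moves every raw end
one base 5′ in its strand's orientation, placing KOH-derived counts
exactly on the ribonucleotide and is applied uniformly to KOH and KCl
libraries. Uniform shifting keeps the two treatments comparable
position-by-position; it is a bijection per strand, and `unshift` inverts
it exactly.

## Estimators

**Per-molecule counts.** HincII (GTYRAC, blunt cut between pattern
positions 3 and 4) cuts every molecule at each of its 11 sites, leaving
one 5′-end per strand per cut: the forward-strand end at site start+3, the
reverse-strand end at start+2. The mean signal within ±5 bases of a
strand's cut coordinates is that strand's reads-per-molecule unit, and

ribos/molecule = (masked total of shifted counts) / (mean site signal),

with the mask = analysis window 300–16,200, minus the OriL region
5,747–5,847, minus ±5 windows around both cut coordinates of every site.
Numerator and denominator share the library's depth and the strand's
capture efficiency, so both cancel: the estimate is invariant to RPM
rescaling and to any L:H capture bias (verified exactly on noise-free
expectations at planted biases 1/14/31). The ±5 site windows absorb the
±1 ambiguity of blunt-cut geometry and the one-base shift.

**Identity and frequency.** Each shifted masked count takes the identity
of the genome base at its position on its strand (T reported as U).
Identity percentages are per-strand percentages of the four
ribonucleotides. Frequencies per 1,000 complementary bases divide each
base's per-molecule count by N_b, the masked count of that base on the
strand where the ribonucleotide is embedded (equal to the complementary
base count on the template strand), ×1,000. The algebraic identity
Σ_b freq(b)·N_b/1000 = ribos/molecule is tested exactly. Using the
embedded strand's own base content is what removes the apparent rG/rC
strand asymmetry that merely reflects the G-rich H / C-rich L composition.

**Diagnostics.** `strand_bias_at_sites` is the raw L:H ratio of
site-window counts (the capture bias itself, since cuts are strand
symmetric). `peak_positions` ranks positions by count with ties broken by
ascending coordinate (determinism). `remnant_shift` compares modal raw end
positions between KOH and KCl in a region, signed in the strand's 3′
direction; modal ties take the lowest coordinate. `regional_fraction`
supports origin-wrapping regions (the OriH zone 16,200→300).

## Profile comparison

Per library, eight features: percent rA/rC/rG/rU per strand. Features are
z-scored across libraries with the sample standard deviation (n−1);
constant features become zeros with a warning rather than an error, since
small panels can produce them. Clustering is agglomerative on Euclidean
distance; the linkage defaults to complete and is exposed (`complete`,
`average`, `single`) because the upstream heatmap convention does not pin
it down — at the planted effect sizes used here (≥2-fold on one
ribonucleotide) the cluster structure is insensitive to the choice.
scipy's deterministic tie-breaking (smallest cluster index) is relied on
and the merge sequence is verified against a brute-force agglomeration
oracle.

## Synthetic data: what it emulates, and what it does not

The generator plants a known truth and samples reads from the implied
5′-end weight distribution:

* **Embedded ribonucleotides** per strand, either exact per-strand totals
  (uniform over mask-eligible positions) or per-base Bernoulli rates.
  Defaults in the demo and acceptance runs are the in vivo study
  conditions: H:20/L:16 (HeLa-like) and H:23/L:31 (fibroblast-like)
  per molecule, sampled at 1–2×10⁶ reads.
* **Free 5′-end hotspots**: the three OriH H-strand ends (111/149/191)
  and a uniform OriL L-strand zone (5,768–5,776).
* **Primer remnants**: a free end whose first n bases are ribonucleotides
  (RNase H1 leaves n=2); KCl sees the junction, KOH sees the end displaced
  n bases downstream.
* **Digestion**: one end per strand per molecule at each cut coordinate,
  uniform across sites.
* **Capture bias**: a single multiplicative factor on all L-strand weights
  (default 31 in the recovery runs — the scalar is the minimal model of a
  library-wide compositional recovery bias corrected by a single
  per-strand reference signal).
* **Sampling**: one seeded generator per library; fixed-depth multinomial
  over (strand, position) weights, so only weight ratios matter. KOH
  hydrolysis is Bernoulli per ribonucleotide with probability
  `cleavage_prob` (default 1.0, the estimator's assumption);
  `library_expectation` gives the noise-free analog for exact algebra.

Not modelled: sequencing error, PCR duplicates, mappability/NUMT effects,
adapter chemistry, per-molecule (rather than multinomial) sampling, and
nuclear background. Passing recovery tests therefore demonstrate the
correctness of the estimators' arithmetic and their bias cancellation
under the stated capture model — not robustness to alignment artefacts in
real libraries.

**Synthetic reference.** The bundled reference (`synthetic_reference`) is
a clearly-labelled synthetic stand-in for the human mtDNA sequence: rCRS
length (16,569 bp), the real forward-strand base composition (C-rich, so
forward = L), and exactly 11 HincII sites planted at spread coordinates
with all chance matches scrubbed. It reproduces the coordinate
conventions, compositional strand asymmetry and site count of the real
molecule, not its sequence; analyses of real data should load the real
reference FASTA via `load_reference`.

## In vitro model

`invitro` reproduces the arithmetic around the primer-extension assay: the
70-nt template / 40-nt primer pair leaves a 30-nt single-stranded tail
(9 A, 7 C, 8 T, 6 G = 30/23.3/26.7/20%), the standard condition is a
250-fold rNTP:dNTP excess (1 mM vs 4 µM per base), and a measured rate of
1 rNMP per 2.0×10³ dNMPs corresponds to ~8.28 ≈ 8 ribonucleotides per
16,569-base strand. The per-position incorporation probability
p = [rNTP]/([rNTP] + D·[dNTP]) is a competitive-substrate model built on
published per-base discrimination folds (D ≈ 1,100 for rG, 77,000 for rU);
it is a modelling choice of this package — the assay reports rates, not an
equation — and nothing downstream depends on it beyond its trivial limits.
Exonuclease proofreading is not modelled (proofreading was found not to
affect ribonucleotide incorporation).

## Numerical choices and degenerate inputs

* References must be unambiguous A/C/G/T; any N is rejected with its
  position (degenerate-pattern matching is for the enzyme site only).
* The OriL exclusion applies to both strands (it is a region, not a
  stranded feature).
* Estimators require shifted counts and refuse double-shifting; an
  undigested library raises "no digestion signal" instead of returning a
  meaningless ratio.
* Empty identity signal returns an all-zero map (flagged by summing to 0)
  rather than raising, so undigested/low-depth libraries can still be
  profiled.
* Spearman correlations default to the union-of-positions universe with
  zeros filled; a full-genome universe is available via
  `universe="genome"`.
* Problem sizes in the test and acceptance runs (2-kb toy circles for
  oracles, 10⁵–2×10⁶ reads for recovery) were chosen so each planted
  quantity is estimated with sampling error well inside its assertion
  tolerance.

## Known limitations

Real-library mode (BED ingestion of aligner output) is supported but only
exercised on synthetic FASTQ round trips; upstream trimming, alignment and
unique-mapping filters are out of scope. Absolute quantification assumes
complete digestion and complete alkaline hydrolysis; partial hydrolysis
(`cleavage_prob` < 1) biases estimates downward proportionally, which the
generator can demonstrate but the estimator does not correct.
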