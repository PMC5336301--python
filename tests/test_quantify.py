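"""HincII-normalized estimators: exact algebra on noise-free expectations,
parameter recovery from sampled libraries, bias cancellation, origin
diagnostics."""

import numpy as np
import pytest

from mitoribomap import endmap as em
from mitoribomap import quantify as qt
from mitoribomap.mtgenome import Region, base_counts
from mitoribomap.synthetic import (
    FreeEndMap,
    LibraryConfig,
    PrimerRemnant,
    StrandedEndCounts,
    library_expectation,
    plant_ribos,
    simulate_library,
)


def koh_digested(genome, ribos, sites, depth, bias, seed, ends=None):
    cfg = LibraryConfig(
        treatment="KOH", digested=True, depth=depth,
        strand_bias_L_over_H=bias, seed=seed,
    )
    return simulate_library(genome, ribos, ends, None, sites, cfg)


def koh_digested_expectation(genome, ribos, sites, bias=1.0, ends=None):
    cfg = LibraryConfig(
        treatment="KOH", digested=True, depth=1, strand_bias_L_over_H=bias
    )
    return library_expectation(genome, ribos, ends, None, sites, cfg)


# ----------------------- reference signal at sites -----------------------

def test_reference_signal_equal_per_site_on_expectation(genome, sites, mask):
    ribos = plant_ribos(genome, {"H": 20, "L": 16}, seed=1, mask=mask)
    exp = em.shift_upstream(koh_digested_expectation(genome, ribos, sites), genome)
    for strand in "HL":
        mean, per_site = qt.hincii_reference_signal(exp, sites, genome, strand)
        assert per_site == pytest.approx(np.ones(len(sites)))
        assert mean == pytest.approx(1.0)


def test_reference_signal_window_monotone(genome, sites, mask):
    ribos = plant_ribos(genome, {"H": 20, "L": 16}, seed=1, mask=mask)
    counts = koh_digested(genome, ribos, sites, depth=200_000, bias=1.0, seed=2)
    m0, _ = qt.hincii_reference_signal(counts, sites, genome, "H", window=0)
    m5, _ = qt.hincii_reference_signal(counts, sites, genome, "H", window=5)
    assert m5 >= m0 > 0


def test_reference_signal_requires_digestion(genome, sites, mask):
    ribos = plant_ribos(genome, {"H": 20, "L": 16}, seed=1, mask=mask)
    cfg = LibraryConfig(treatment="KOH", digested=False, depth=1000, seed=0)
    counts = simulate_library(genome, ribos, None, None, None, cfg)
    with pytest.raises(ValueError, match="digestion signal"):
        qt.hincii_reference_signal(counts, sites, genome, "H")


# --------------------------- per-molecule count ---------------------------

def test_per_molecule_exact_on_noise_free_expectation(genome, sites, mask):
    ribos = plant_ribos(genome, {"H": 20, "L": 16}, seed=3, mask=mask)
    shifted = em.shift_upstream(
        koh_digested_expectation(genome, ribos, sites), genome
    )
    assert qt.ribos_per_molecule(shifted, sites, mask, genome, "H") == pytest.approx(20.0)
    assert qt.ribos_per_molecule(shifted, sites, mask, genome, "L") == pytest.approx(16.0)


def test_per_molecule_zero_when_nothing_planted(genome, sites, mask):
    ends = FreeEndMap()
    ends.entries["H"] = [(111, 1.0)]   # outside the analysis window
    shifted = em.shift_upstream(
        koh_digested_expectation(genome, None, sites, ends=ends), genome
    )
    assert qt.ribos_per_molecule(shifted, sites, mask, genome, "H") == 0.0


def test_per_molecule_recovery_despite_31fold_bias(genome, sites, mask):
    """Parameter recovery at the in vivo truth: planted 20/16 per strand,
    2M reads, 31-fold L:H capture bias; the per-strand site division must
    cancel the bias."""
    ribos = plant_ribos(genome, {"H": 20, "L": 16}, seed=4, mask=mask)
    counts = koh_digested(genome, ribos, sites, depth=2_000_000, bias=31.0, seed=4)
    shifted = em.shift_upstream(counts, genome)
    assert qt.ribos_per_molecule(shifted, sites, mask, genome, "H") == pytest.approx(20, rel=0.05)
    assert qt.ribos_per_molecule(shifted, sites, mask, genome, "L") == pytest.approx(16, rel=0.05)


def test_per_molecule_requires_shifted_counts(genome, sites, mask):
    counts = StrandedEndCounts(library_id="u")
    counts.add("H", 1000, 1.0)
    with pytest.raises(ValueError, match="shift"):
        qt.ribos_per_molecule(counts, sites, mask, genome, "H")


def test_per_molecule_scale_invariant_raw_vs_rpm(genome, sites, mask):
    ribos = plant_ribos(genome, {"H": 20, "L": 16}, seed=6, mask=mask)
    counts = koh_digested(genome, ribos, sites, depth=500_000, bias=14.0, seed=6)
    shifted = em.shift_upstream(counts, genome)
    rpm = em.rpm_normalize(shifted)
    for strand in "HL":
        assert qt.ribos_per_molecule(rpm, sites, mask, genome, strand) == pytest.approx(
            qt.ribos_per_molecule(shifted, sites, mask, genome, strand)
        )


def test_bias_cancellation_exact_on_expectation(genome, sites, mask):
    """The estimate is invariant to any planted capture bias."""
    ribos = plant_ribos(genome, {"H": 20, "L": 16}, seed=7, mask=mask)
    estimates = []
    for bias in (1.0, 14.0, 31.0):
        shifted = em.shift_upstream(
            koh_digested_expectation(genome, ribos, sites, bias=bias), genome
        )
        estimates.append(
            tuple(
                qt.ribos_per_molecule(shifted, sites, mask, genome, s)
                for s in "HL"
            )
        )
    assert estimates[0] == pytest.approx((20.0, 16.0))
    assert estimates[1] == pytest.approx(estimates[0])
    assert estimates[2] == pytest.approx(estimates[0])


def test_doubling_planted_count_doubles_estimate(genome, sites, mask):
    r1 = plant_ribos(genome, {"H": 10, "L": 8}, seed=8, mask=mask)
    r2 = plant_ribos(genome, {"H": 20, "L": 16}, seed=8, mask=mask)
    assert set(r1.positions("H")) <= set(
        plant_ribos(genome, {"H": 10, "L": 8}, seed=8, mask=mask).positions("H")
    )
    for ribos, expected in ((r1, (10, 8)), (r2, (20, 16))):
        shifted = em.shift_upstream(
            koh_digested_expectation(genome, ribos, sites), genome
        )
        got = tuple(
            qt.ribos_per_molecule(shifted, sites, mask, genome, s) for s in "HL"
        )
        assert got == pytest.approx(expected)


def test_per_molecule_median_relative_error_across_seeds(genome, sites, mask):
    """Across many simulation seeds at 1M reads, the median relative error
    of the per-strand estimates stays below 3%."""
    ribos = plant_ribos(genome, {"H": 20, "L": 16}, seed=50, mask=mask)
    rel_errors = []
    for seed in range(50):
        counts = koh_digested(genome, ribos, sites, depth=1_000_000,
                              bias=31.0, seed=1000 + seed)
        shifted = em.shift_upstream(counts, genome)
        for strand, truth in (("H", 20), ("L", 16)):
            est = qt.ribos_per_molecule(shifted, sites, mask, genome, strand)
            rel_errors.append(abs(est - truth) / truth)
    assert np.median(rel_errors) < 0.03


# ------------------------------ strand bias ------------------------------

def test_strand_bias_recovered_and_scale_invariant(genome, sites):
    cfg = LibraryConfig(
        treatment="KCl", digested=True, depth=1_000_000,
        strand_bias_L_over_H=31.0, seed=9,
    )
    counts = simulate_library(genome, None, None, None, sites, cfg)
    bias = qt.strand_bias_at_sites(counts, sites, genome)
    assert bias == pytest.approx(31.0, rel=0.05)
    assert qt.strand_bias_at_sites(
        em.rpm_normalize(counts), sites, genome
    ) == pytest.approx(bias)


def test_strand_bias_unity_without_planted_bias(genome, sites):
    cfg = LibraryConfig(treatment="KCl", digested=True, depth=500_000, seed=10)
    counts = simulate_library(genome, None, None, None, sites, cfg)
    assert qt.strand_bias_at_sites(counts, sites, genome) == pytest.approx(1.0, rel=0.05)


# --------------------------- identity fractions ---------------------------

def test_identity_all_g_planting(genome, mask):
    g_positions = [
        p for p in mask.positions(genome) if genome.base_at(p, "H") == "G"
    ][:10]
    from mitoribomap.synthetic import RiboMap

    ribos = RiboMap()
    ribos.entries["H"] = [(p, "G") for p in g_positions]
    cfg = LibraryConfig(treatment="KOH", digested=False, depth=1)
    shifted = em.shift_upstream(
        library_expectation(genome, ribos, None, None, None, cfg), genome
    )
    fr = qt.identity_fractions(shifted, genome, mask, "H")
    assert fr == {"A": 0.0, "C": 0.0, "G": 100.0, "U": 0.0}


def test_identity_recovery_from_rate_planting(genome, sites, mask):
    """Planted per-base rates with the in vivo qualitative pattern (rG
    high, rU low) are recovered within 2 percentage points at 1M reads."""
    rates = {"A": 1.2e-3, "C": 1.2e-3, "G": 2.4e-3, "U": 0.4e-3}
    ribos = plant_ribos(genome, {"H": rates, "L": rates}, seed=11, mask=mask)
    counts = koh_digested(genome, ribos, sites, depth=1_000_000, bias=31.0, seed=11)
    shifted = em.shift_upstream(counts, genome)
    nb = {s: base_counts(genome, s, mask) for s in "HL"}
    for strand in "HL":
        truth_counts = {
            b: sum(1 for _, base in ribos.entries[strand] if base == b)
            for b in "ACGU"
        }
        total = sum(truth_counts.values())
        got = qt.identity_fractions(shifted, genome, mask, strand)
        assert sum(got.values()) == pytest.approx(100.0, abs=1e-9)
        for b in "ACGU":
            assert got[b] == pytest.approx(100.0 * truth_counts[b] / total, abs=2.0)


def test_identity_empty_signal_flagged_as_zero(genome, mask):
    empty = StrandedEndCounts(library_id="e", shifted=True)
    assert qt.identity_fractions(empty, genome, mask, "H") == {
        "A": 0.0, "C": 0.0, "G": 0.0, "U": 0.0
    }


# ------------------------- frequency per 1,000 -------------------------

def test_freq_consistency_with_per_molecule(genome, sites, mask):
    """Sum over bases of freq(b) * N_b / 1000 equals ribos_per_molecule
    exactly (noise-free algebraic identity)."""
    rates = {"A": 1e-3, "C": 1e-3, "G": 2e-3, "U": 5e-4}
    ribos = plant_ribos(genome, {"H": rates, "L": rates}, seed=12, mask=mask)
    shifted = em.shift_upstream(
        koh_digested_expectation(genome, ribos, sites, bias=31.0), genome
    )
    for strand in "HL":
        freqs = qt.freq_per_1000(shifted, genome, sites, mask, strand)
        nb = base_counts(genome, strand, mask)
        total = sum(
            freqs[b] * nb["T" if b == "U" else b] / 1000.0 for b in "ACGU"
        )
        assert total == pytest.approx(
            qt.ribos_per_molecule(shifted, sites, mask, genome, strand), abs=1e-9
        )


def test_freq_uniform_rate_recovers_1000rho(genome, sites, mask):
    rho = 2e-3
    rates = {b: rho for b in "ACGU"}
    ribos = plant_ribos(genome, {"H": rates, "L": rates}, seed=13, mask=mask)
    shifted = em.shift_upstream(
        koh_digested_expectation(genome, ribos, sites), genome
    )
    for strand in "HL":
        freqs = qt.freq_per_1000(shifted, genome, sites, mask, strand)
        for b in "ACGU":
            # the planting itself is binomial; allow 4 sigma around 1000*rho
            nb = base_counts(genome, strand, mask)["T" if b == "U" else b]
            sigma = 1000 * np.sqrt(rho * (1 - rho) / nb)
            assert abs(freqs[b] - 1000 * rho) < 4 * sigma


def test_freq_zero_for_unplanted_base(genome, sites, mask):
    rates = {"A": 1e-3, "C": 1e-3, "G": 1e-3}  # no U
    ribos = plant_ribos(genome, {"H": rates, "L": rates}, seed=14, mask=mask)
    shifted = em.shift_upstream(
        koh_digested_expectation(genome, ribos, sites), genome
    )
    assert qt.freq_per_1000(shifted, genome, sites, mask, "H")["U"] == 0.0


# ------------------------- origin diagnostics -------------------------

def test_regional_fraction_wrap_and_recovery(genome):
    region = Region(16200, 300, wraps=True)
    counts = StrandedEndCounts(library_id="o")
    counts.add("H", 16300, 30.0)
    counts.add("H", 150, 30.0)
    assert qt.regional_fraction(counts, region, "H") == pytest.approx(1.0)
    counts.add("H", 8000, 40.0)
    assert qt.regional_fraction(counts, region, "H") == pytest.approx(0.6)


def test_peak_positions_fixture_and_ties(genome):
    counts = StrandedEndCounts(library_id="orih")
    for pos, c in ((111, 100.0), (149, 200.0), (191, 300.0)):
        counts.add("H", pos, c)
    peaks = qt.peak_positions(counts, "H", k=3)
    assert peaks[0] == (191, 300.0)
    assert [p for p, _ in peaks] == [191, 149, 111]
    tied = StrandedEndCounts(library_id="t")
    for pos in (40, 10, 30, 20):
        tied.add("L", pos, 1.0)
    assert [p for p, _ in qt.peak_positions(tied, "L", k=2)] == [10, 20]


def test_peak_positions_matches_full_sort_oracle(genome):
    rng = np.random.default_rng(15)
    counts = StrandedEndCounts(library_id="r")
    for pos in rng.choice(np.arange(1, 1000), size=80, replace=False):
        counts.add("H", int(pos), float(rng.integers(1, 20)))
    oracle = sorted(counts.counts["H"].items(), key=lambda pc: (-pc[1], pc[0]))
    assert qt.peak_positions(counts, "H", k=80) == oracle


def test_remnant_shift_plus_two(genome):
    """An RNase H1-style remnant (two retained 5'-terminal ribos) moves the
    modal end +2 nt downstream under alkali."""
    asc = genome.strand_of_forward  # the OriL nascent strand is ascending
    region = Region(5747, 5847)
    for n in range(0, 6):
        rem = PrimerRemnant(strand=asc, junction=5770, n_ribos=n)
        kcl = simulate_library(
            genome, None, None, [rem], None,
            LibraryConfig(treatment="KCl", digested=False, depth=2000, seed=16),
        )
        koh = simulate_library(
            genome, None, None, [rem], None,
            LibraryConfig(treatment="KOH", digested=False, depth=2000, seed=17),
        )
        assert qt.remnant_shift(koh, kcl, region, asc, genome) == n
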