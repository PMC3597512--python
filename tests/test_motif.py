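"""Upstream motif scan: oracle equivalence, selection rule, matrices, density."""

import re

import numpy as np
import pandas as pd
import pytest

from pirnakit import motif, simulate
from pirnakit.io import Interval
from pirnakit.mapping import PiRNALocus
from pirnakit.motif import (
    abundance_by_motif_class,
    aligned_upstream_windows,
    classify_motifs,
    count_occurrences,
    genome_background,
    kmer_density,
    motif_matrix,
    scan_loci,
    scan_upstream,
    upstream_window,
)
from pirnakit.sequence import revcomp


def oracle_scan(window: str):
    """Regex enumeration of all GTTTC hits with full 8-mer context, plus the
    closest-to-39 (ties -> shorter spacer) selection rule."""
    hits = []
    for m in re.finditer(r"(?=GTTTC)", window):
        i = m.start()
        if i >= 2 and i + 6 <= len(window):
            hits.append((i, len(window) - i - 6))
    if not hits:
        return None
    return min(hits, key=lambda h: (abs(h[1] - 39), h[1]))


def plus_locus(genome_str, t_pos, name="u"):
    return PiRNALocus(name, "chrS1", "+", t_pos, t_pos + 21, genome_str[t_pos : t_pos + 21])


def test_planted_consensus_recovered():
    up = "A" * 13 + "CTGTTTCA" + "A" * 39
    g = {"chrS1": up + "T" + "C" * 25}
    call = scan_upstream(plus_locus(g["chrS1"], 60), g)
    assert call.has_gtttc
    assert call.core_8mer == "CTGTTTCA"
    assert call.five_prime_nt == "C"
    assert call.spacer_length == 39
    assert call.in_canonical_range


def test_no_gtttc_falls_back_to_minus_44_anchor():
    g = {"chrS1": "A" * 60 + "T" + "C" * 25}
    call = scan_upstream(plus_locus(g["chrS1"], 60), g)
    assert not call.has_gtttc
    assert call.five_prime_nt == "NM"
    assert call.spacer_length is None
    # anchor: G of the core motif at -44 => 8-mer start at -46
    assert call.motif_start == 60 - 46


def test_selection_rule_closest_to_39():
    # two GTTTC at implied spacers 36 and 50: 36 wins (|36-39| < |50-39|)
    w = ["A"] * 60
    for spacer in (36, 50):
        i = 60 - 6 - spacer
        w[i : i + 5] = "GTTTC"
    g = {"chrS1": "".join(w) + "T" + "C" * 25}
    call = scan_upstream(plus_locus(g["chrS1"], 60), g)
    assert call.spacer_length == 36
    assert oracle_scan("".join(w))[1] == 36


def test_selection_tie_prefers_shorter_spacer():
    w = ["A"] * 60
    for spacer in (36, 42):  # equidistant from 39, non-overlapping
        i = 60 - 6 - spacer
        w[i : i + 5] = "GTTTC"
    g = {"chrS1": "".join(w) + "T" + "C" * 25}
    assert scan_upstream(plus_locus(g["chrS1"], 60), g).spacer_length == 36


def test_scan_equals_regex_oracle_on_random_loci():
    rng = np.random.default_rng(17)
    g = simulate.generate_genome(1, [40_000], gc_fraction=0.45, seed=18)
    seq = g["chrS1"]
    n_checked = 0
    for _ in range(1000):
        t = int(rng.integers(100, len(seq) - 30))
        locus = PiRNALocus(f"u{t}", "chrS1", "+", t, t + 21, seq[t : t + 21])
        call = scan_upstream(locus, g)
        expect = oracle_scan(seq[t - 60 : t])
        if expect is None:
            assert not call.has_gtttc
        else:
            assert call.has_gtttc and call.spacer_length == expect[1]
            n_checked += 1
    assert n_checked > 30  # the genome must actually contain motifs


def test_strand_symmetry(planted):
    """Reverse-complementing the genome (and flipping coordinates/strands)
    leaves every call invariant."""
    genome, loci = planted
    flipped = {c: revcomp(s) for c, s in genome.items()}
    for locus in loci[:8]:
        L = len(genome[locus.chrom])
        mirrored = PiRNALocus(
            locus.species_id,
            locus.chrom,
            "-" if locus.strand == "+" else "+",
            L - locus.end,
            L - locus.start,
            locus.sequence,
        )
        a = scan_upstream(locus.to_pirna_locus(), genome)
        b = scan_upstream(mirrored, flipped)
        assert (a.has_gtttc, a.spacer_length, a.core_8mer, a.five_prime_nt) == (
            b.has_gtttc,
            b.spacer_length,
            b.core_8mer,
            b.five_prime_nt,
        )


def test_multimapper_excluded_from_scan():
    s = "T" * 21
    locus = PiRNALocus("multi", "chrS1", "+", 100, 121, s, n_mapped_loci=3)
    g = {"chrS1": "A" * 200}
    assert scan_loci([locus], g) == []


class TestClassifyMotifs:
    def test_contingency_and_spacer_histograms(self, planted):
        genome, loci = planted
        calls = scan_loci([l.to_pirna_locus() for l in loci], genome)
        classes = pd.Series({l.species_id: l.truth_class for l in loci})
        summary = classify_motifs(calls, classes)
        assert summary.contingency.to_numpy().sum() == len(calls)
        assert 0 <= summary.chi2_p <= 1
        for hist in summary.spacer_histograms.values():
            assert (hist.index >= 30).all() and (hist.index <= 50).all()

    def test_degenerate_table_raises(self):
        calls = [
            motif.MotifCall("a", "c", "+", True, 0, "CTGTTTCA", "C", 39, True),
            motif.MotifCall("b", "c", "+", True, 10, "CTGTTTCA", "C", 39, True),
        ]
        classes = pd.Series({"a": "male", "b": "male"})
        with pytest.raises(ValueError, match="degenerate"):
            classify_motifs(calls, classes)

    def test_planted_five_prime_proportion_recovered(self):
        g = simulate.generate_genome(1, [400_000], seed=61)
        rng = np.random.default_rng(62)
        n = 200
        first = ["C" if rng.random() < 0.77 else "A" for _ in range(n)]
        specs = [
            simulate.CassetteSpec(five_prime_class=f, truth_class="male")
            for f in first
        ]
        g2, loci = simulate.plant_cassettes(g, specs, seed=63)
        calls = scan_loci([l.to_pirna_locus() for l in loci], g2)
        got_c = sum(c.five_prime_nt == "C" for c in calls) / len(calls)
        want_c = first.count("C") / n
        assert got_c == pytest.approx(want_c, abs=1e-9)


class TestAbundanceByMotifClass:
    def _calls(self, classes):
        return [
            motif.MotifCall(f"s{i}", "c", "+", cls != "NM", i * 100, "CTGTTTCA", cls, 39, True)
            for i, cls in enumerate(classes)
        ]

    def test_planted_4x_class_significant(self):
        rng = np.random.default_rng(3)
        classes = ["C"] * 60 + ["A"] * 60 + ["T"] * 60
        calls = self._calls(classes)
        ab = pd.Series(
            np.concatenate([rng.gamma(20, 4.0 / 20, 60) * 4, rng.gamma(20, 4.0 / 20, 120)]),
            index=[f"s{i}" for i in range(180)],
        )
        res = abundance_by_motif_class(calls, ab)
        assert res.pairwise_welch.loc["C", "A"] < 0.01
        assert res.pairwise_welch.loc["C", "T"] < 0.01
        assert res.stats.loc["C", "mean_rpm"] > res.stats.loc["A", "mean_rpm"]

    def test_null_no_significant_pairs(self):
        rng = np.random.default_rng(4)
        classes = ["C"] * 80 + ["A"] * 80
        calls = self._calls(classes)
        ab = pd.Series(rng.gamma(10, 1.0, 160), index=[f"s{i}" for i in range(160)])
        res = abundance_by_motif_class(calls, ab)
        assert res.pairwise_welch.loc["C", "A"] > 0.01

    def test_singleton_class_excluded(self):
        calls = self._calls(["C"] * 5 + ["G"])
        ab = pd.Series(np.arange(6, dtype=float) + 1, index=[f"s{i}" for i in range(6)])
        res = abundance_by_motif_class(calls, ab)
        assert res.excluded_classes == ["G"]
        assert np.isnan(res.stats.loc["G", "sem"])
        assert np.isnan(res.pairwise_welch.loc["C", "G"])


class TestMotifMatrix:
    def test_frequencies_normalize(self):
        windows = ["ACGT", "AAGT", "ACTT"]
        mm = motif_matrix(windows, {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25})
        assert np.allclose(mm.freq.sum(axis=1), 1.0, atol=1e-9)
        assert (mm.info >= 0).all()

    def test_identical_windows_give_background_log_pattern(self):
        q = {"A": 0.3, "C": 0.2, "G": 0.2, "T": 0.3}
        mm = motif_matrix(["ACGT"] * 10, q)
        expect = [-np.log2(q[b]) for b in "ACGT"]
        assert np.allclose(mm.info.to_numpy(), expect)

    def test_uniform_windows_near_zero_information(self):
        rng = np.random.default_rng(9)
        windows = ["".join(rng.choice(list("ACGT"), 8)) for _ in range(4000)]
        mm = motif_matrix(windows, {b: 0.25 for b in "ACGT"})
        assert mm.info.max() < 0.01

    def test_hand_computed_toy_example(self):
        # position 0: A,A,A,C -> f = (.75, .25, 0, 0) vs uniform background
        windows = ["AA", "AC", "AG", "CT"]
        mm = motif_matrix(windows, {b: 0.25 for b in "ACGT"})
        f = [0.75, 0.25]
        expect0 = 0.75 * np.log2(0.75 / 0.25) + 0.25 * np.log2(0.25 / 0.25)
        assert mm.info.iloc[0] == pytest.approx(expect0)
        assert mm.freq.iloc[0]["A"] == 0.75

    def test_aligned_windows_centre_on_ttt(self, planted):
        genome, loci = planted
        by_id = {l.species_id: l.to_pirna_locus() for l in loci}
        calls = scan_loci(list(by_id.values()), genome)
        windows = aligned_upstream_windows(calls, by_id, genome, span=(-2, 2))
        assert windows
        for w in windows:
            assert w[1:4] == "TTT"  # GTTTC central T at the window centre


class TestKmerDensity:
    def test_planted_forward_occurrences(self):
        seq = list("A" * 1000)
        for pos in (100, 300, 500, 700):
            seq[pos : pos + 5] = "GTTTC"
        g = {"chrS1": "".join(seq)}
        d = kmer_density(g, [Interval("chrS1", 0, 1000)])
        assert d == pytest.approx(4.0)

    def test_poly_a_region_zero(self):
        g = {"chrS1": "A" * 2000}
        assert kmer_density(g, [Interval("chrS1", 0, 2000)]) == 0.0

    def test_overlapping_occurrences_counted(self):
        assert count_occurrences("GTTTCGTTTC", "GTTTC") == 2
        assert count_occurrences("TTTTTT", "TTT") == 4

    def test_reverse_strand_counted(self):
        g = {"chrS1": "A" * 495 + revcomp("GTTTC") + "A" * 500}
        assert kmer_density(g, [Interval("chrS1", 0, 1000)]) == pytest.approx(1.0)


def test_genome_background_composition():
    q = genome_background({"c1": "AACC", "c2": "GT"})
    assert q == {"A": 2 / 6, "C": 2 / 6, "G": 1 / 6, "T": 1 / 6}
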