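"""Minicluster grouping and pair-composition statistics.

Overlapping piRNA loci expressed from different thymidines downstream of a
single shared core motif form "miniclusters"; uniquely mapping loci whose
motif is not shared are "solitary". This module groups loci by motif
identity, relates spacer length to abundance, counts thymidines in the
optimal 35-42 nt window downstream of each motif, and tests whether
two-member germline-enriched miniclusters pair by enrichment class more
often than random assortment of their members would predict.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from pirnakit.motif import MotifCall

WINDOW_T_RANGE = (35, 42)


@dataclasses.dataclass
class Minicluster:
    motif_key: tuple[str, str, int]
    members: list[MotifCall]

    @property
    def size(self) -> int:
        return len(self.members)


def group_miniclusters(
    calls: Sequence[MotifCall],
) -> tuple[list[Minicluster], list[MotifCall]]:
    """Partition motif calls into miniclusters (shared motif) and solitary loci.

    Only calls with a GTTTC motif can share a motif key; NM calls are always
    solitary. The partition is exhaustive and disjoint, and invariant to
    input order (members sorted by locus id).
    """
    by_key: dict[tuple[str, str, int], list[MotifCall]] = defaultdict(list)
    solitary: list[MotifCall] = []
    for call in calls:
        if call.has_gtttc:
            by_key[call.motif_key].append(call)
        else:
            solitary.append(call)
    clusters = []
    for key in sorted(by_key):
        members = sorted(by_key[key], key=lambda c: c.locus_id)
        if len(members) >= 2:
            clusters.append(Minicluster(key, members))
        else:
            solitary.extend(members)
    solitary.sort(key=lambda c: c.locus_id)
    return clusters, solitary


# ---------------------------------------------------------------------------
# spacer-length abundance profile
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SpacerProfile:
    profile: pd.DataFrame  # index spacer length; columns (group, stat)
    welch: pd.DataFrame  # per matched spacer length: t, p

    def argmax(self, group: str) -> int:
        return int(self.profile[(group, "mean_rpm")].idxmax())


def spacer_abundance_profile(
    clusters: Iterable[Minicluster],
    solitary: Iterable[MotifCall],
    abundance: pd.Series,
) -> SpacerProfile:
    """Mean abundance +/- SEM by spacer length, miniclustered vs solitary,
    with a two-tailed Welch test at every spacer length observed in both
    groups with >= 2 members each."""
    groups = {
        "miniclustered": [m for c in clusters for m in c.members],
        "solitary": [c for c in solitary if c.has_gtttc],
    }
    values: dict[str, dict[int, list[float]]] = {g: defaultdict(list) for g in groups}
    for g, calls in groups.items():
        for call in calls:
            if call.spacer_length is not None and call.locus_id in abundance.index:
                values[g][call.spacer_length].append(float(abundance[call.locus_id]))

    spacers = sorted(set(values["miniclustered"]) | set(values["solitary"]))
    cols = {}
    for g in groups:
        means, sems, ns = [], [], []
        for s in spacers:
            vals = np.asarray(values[g].get(s, []))
            ns.append(vals.size)
            means.append(vals.mean() if vals.size else np.nan)
            sems.append(stats.sem(vals) if vals.size >= 2 else np.nan)
        cols[(g, "mean_rpm")] = means
        cols[(g, "sem")] = sems
        cols[(g, "n")] = ns
    profile = pd.DataFrame(cols, index=spacers)
    profile.index.name = "spacer_length"

    welch_rows = {}
    for s in spacers:
        a = values["miniclustered"].get(s, [])
        b = values["solitary"].get(s, [])
        if len(a) >= 2 and len(b) >= 2:
            res = stats.ttest_ind(a, b, equal_var=False)
            welch_rows[s] = {"t": float(res.statistic), "p": float(res.pvalue)}
    welch = pd.DataFrame(welch_rows).T if welch_rows else pd.DataFrame(columns=["t", "p"])
    return SpacerProfile(profile, welch)


# ---------------------------------------------------------------------------
# downstream-window thymidine richness
# ---------------------------------------------------------------------------

def window_t_count(
    call: MotifCall, genome: Mapping[str, str], window: tuple[int, int] = WINDOW_T_RANGE
) -> int:
    """Thymidines at spacer distances `window` downstream of a motif's 8-mer.

    A spacer distance s places the candidate T at s nucleotides past the
    8-mer's 3' end on the locus strand.
    """
    if not call.has_gtttc:
        raise ValueError("window T-richness is defined only for GTTTC motifs")
    seq = genome[call.chrom]
    lo, hi = window
    count = 0
    for s in range(lo, hi + 1):
        if call.strand == "+":
            pos = call.motif_start + 8 + s
            base = seq[pos] if 0 <= pos < len(seq) else ""
        else:
            pos = call.motif_start - 8 - s
            base = seq[pos] if 0 <= pos < len(seq) else ""
            base = {"A": "T", "T": "A", "C": "G", "G": "C"}.get(base.upper(), "")
        if base.upper() == "T":
            count += 1
    return count


@dataclasses.dataclass
class WindowTComparison:
    shared_counts: np.ndarray
    non_shared_counts: np.ndarray
    welch_stat: float
    welch_p: float

    @property
    def mean_shared(self) -> float:
        return float(self.shared_counts.mean())

    @property
    def mean_non_shared(self) -> float:
        return float(self.non_shared_counts.mean())


def window_t_richness(
    clusters: Iterable[Minicluster],
    solitary: Iterable[MotifCall],
    genome: Mapping[str, str],
    window: tuple[int, int] = WINDOW_T_RANGE,
) -> WindowTComparison:
    """Compare window thymidine counts of shared vs non-shared motifs
    (one count per distinct motif, two-tailed Welch)."""
    shared_keys = {c.motif_key: c.members[0] for c in clusters}
    non_shared = {c.motif_key: c for c in solitary if c.has_gtttc}
    shared = np.array([window_t_count(c, genome, window) for c in shared_keys.values()])
    non = np.array([window_t_count(c, genome, window) for c in non_shared.values()])
    if shared.size < 2 or non.size < 2:
        raise ValueError("need >= 2 shared and >= 2 non-shared motifs for the Welch test")
    res = stats.ttest_ind(shared, non, equal_var=False)
    return WindowTComparison(shared, non, float(res.statistic), float(res.pvalue))


# ---------------------------------------------------------------------------
# pair composition: random-assortment test
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PairCompositionResult:
    n_pairs: int
    observed: dict[str, float]  # fractions of male_male / female_female / male_female
    observed_counts: dict[str, int]
    p_male: float
    q_female: float
    expected: dict[str, float]  # p^2, q^2, 2pq
    observed_matching: float
    expected_matching: float
    chi2_stat: float | None
    chi2_p: float | None
    permutation_expected: dict[str, float] | None = None


_KEYS = ("male_male", "female_female", "male_female")


def _fractions_from_counts(mm: float, ff: float, mf: float) -> dict[str, float]:
    n = mm + ff + mf
    return {"male_male": mm / n, "female_female": ff / n, "male_female": mf / n}


def _expected_from_p(p: float) -> dict[str, float]:
    q = 1.0 - p
    return {"male_male": p * p, "female_female": q * q, "male_female": 2 * p * q}


def pair_composition_from_fractions(
    n_pairs: int, frac_mm: float, frac_ff: float, frac_mf: float
) -> PairCompositionResult:
    """Random-assortment expectation from an already-tabulated pair composition.

    Member fractions come from the pairs themselves (each pair contributes
    two members): p = (2*mm + mf) / 2n. Expected fractions under random
    re-pairing are p^2, q^2 and 2pq; the chi-squared compares matching vs
    mixed observed counts against their expectations.
    """
    if n_pairs <= 0:
        raise ValueError("need at least one pair")
    total = frac_mm + frac_ff + frac_mf
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError("pair fractions must sum to 1")
    counts = {
        "male_male": frac_mm * n_pairs,
        "female_female": frac_ff * n_pairs,
        "male_female": frac_mf * n_pairs,
    }
    p = (2 * counts["male_male"] + counts["male_female"]) / (2 * n_pairs)
    expected = _expected_from_p(p)
    observed = _fractions_from_counts(**dict(zip(("mm", "ff", "mf"), counts.values())))
    obs_match = observed["male_male"] + observed["female_female"]
    exp_match = expected["male_male"] + expected["female_female"]
    if 0.0 < exp_match < 1.0:
        obs_2 = np.array([obs_match, 1 - obs_match]) * n_pairs
        exp_2 = np.array([exp_match, 1 - exp_match]) * n_pairs
        chi2 = float(((obs_2 - exp_2) ** 2 / exp_2).sum())
        chi2_p = float(stats.chi2.sf(chi2, df=1))
    else:
        chi2 = chi2_p = None
    return PairCompositionResult(
        n_pairs=n_pairs,
        observed=observed,
        observed_counts={k: int(round(v)) for k, v in counts.items()},
        p_male=p,
        q_female=1.0 - p,
        expected=expected,
        observed_matching=obs_match,
        expected_matching=exp_match,
        chi2_stat=chi2,
        chi2_p=chi2_p,
    )


def pair_composition(
    clusters: Iterable[Minicluster],
    classification: pd.Series,
    n_permutations: int = 0,
    seed: int | None = None,
) -> PairCompositionResult:
    """Random-assortment test on two-member germline-enriched miniclusters.

    Only miniclusters of exactly two members, both classified male or female,
    are analyzed. The analytic expectation randomly re-pairs the observed
    members (p^2, q^2, 2pq); with `n_permutations` > 0 a seeded permutation
    version (shuffle members across pairs) is reported alongside.
    """
    pairs = []
    for cluster in clusters:
        if cluster.size != 2:
            continue
        cls = [classification.get(m.locus_id) for m in cluster.members]
        if all(c in ("male", "female") for c in cls):
            pairs.append(tuple(sorted(cls)))
    if not pairs:
        raise ValueError("no two-member germline-enriched miniclusters")
    n = len(pairs)
    mm = sum(1 for p in pairs if p == ("male", "male"))
    ff = sum(1 for p in pairs if p == ("female", "female"))
    mf = n - mm - ff
    result = pair_composition_from_fractions(n, mm / n, ff / n, mf / n)

    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        members = np.array([c for pair in pairs for c in pair])
        acc = {k: 0.0 for k in _KEYS}
        for _ in range(n_permutations):
            rng.shuffle(members)
            halves = members.reshape(-1, 2)
            both_male = (halves == "male").all(axis=1).sum()
            both_female = (halves == "female").all(axis=1).sum()
            acc["male_male"] += both_male / n
            acc["female_female"] += both_female / n
            acc["male_female"] += (n - both_male - both_female) / n
        result.permutation_expected = {k: v / n_permutations for k, v in acc.items()}
    return result
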