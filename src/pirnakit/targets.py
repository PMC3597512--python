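"""21U RNA target search and 22G RNA attribution.

piRNAs silence transcripts through imperfect antisense complementarity,
triggering production of secondary 22G RNAs near the targeting site. A
target site is any 21-nt transcript window whose sequence matches the
reverse complement of a 21U RNA with at most 3 mismatches (pure Hamming: no
gaps, no G:U wobble, all positions weighted equally). A 22G RNA is
attributed to the male or female piRNA population when its antisense
footprint on a transcript lies within 40 nt (footprint-to-footprint gap;
overlap counts as 0) of a target site of that class; species near both
classes are ambiguous, and species detected in a piwi-mutant (prg-1) library
are excluded as piwi-independent before attribution.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from pirnakit.sequence import revcomp, sliding_mismatches


@dataclasses.dataclass(frozen=True)
class TargetSite:
    transcript_id: str
    start: int  # 21-nt antisense footprint on the transcript, 0-based half-open
    end: int
    source_21u: str
    n_mismatches: int

    def __post_init__(self):
        if self.end - self.start != 21:
            raise ValueError("target footprint must be 21 nt")
        if not 0 <= self.n_mismatches <= 3:
            raise ValueError("mismatch count must be 0-3")


@dataclasses.dataclass(frozen=True)
class TranscriptHit:
    """Footprint of a small-RNA read on a transcript (antisense)."""

    transcript_id: str
    start: int
    end: int


@dataclasses.dataclass
class Attribution22G:
    species_22g: str
    attributed_to: str  # male_only / female_only / ambiguous / none
    supporting: list[tuple[TargetSite, int]]  # (site, gap distance)


def find_targets(
    sequences_21u: Mapping[str, str],
    transcripts: Mapping[str, str],
    max_mismatches: int = 3,
) -> list[TargetSite]:
    """All ungapped antisense matches of each 21U on each transcript.

    The 21U's reverse complement is slid along the transcript; windows with
    Hamming distance <= max_mismatches become target sites. U is read as T.
    """
    sites = []
    enc_transcripts = {tid: seq.upper().replace("U", "T") for tid, seq in transcripts.items()}
    for u_id, u_seq in sequences_21u.items():
        u_seq = u_seq.upper().replace("U", "T")
        if len(u_seq) != 21:
            raise ValueError(f"{u_id}: 21U sequence must be 21 nt")
        pattern = revcomp(u_seq)
        for tid, tseq in enc_transcripts.items():
            mism = sliding_mismatches(pattern, tseq)
            for start in np.flatnonzero(mism <= max_mismatches):
                sites.append(
                    TargetSite(tid, int(start), int(start) + 21, u_id, int(mism[start]))
                )
    return sites


def footprint_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Nucleotide gap between two footprints on a transcript (overlap -> 0)."""
    if a_end <= b_start:
        return b_start - a_end
    if b_end <= a_start:
        return a_start - b_end
    return 0


def attribute_22g(
    hits_22g: Mapping[str, Sequence[TranscriptHit]],
    sites: Sequence[TargetSite],
    class_of_21u: Mapping[str, str],
    prg1_detected: Iterable[str] = (),
    distance: int = 40,
) -> dict[str, Attribution22G]:
    """Attribute 22G species to male/female piRNA populations by proximity.

    `hits_22g` maps 22G species id to its transcript footprints;
    `class_of_21u` maps 21U species id to its enrichment class. Species with
    any read in the prg-1 library are excluded ('none', no supporting sites).
    """
    prg1 = set(prg1_detected)
    sites_by_transcript: dict[str, list[TargetSite]] = defaultdict(list)
    for site in sites:
        if class_of_21u.get(site.source_21u) in ("male", "female"):
            sites_by_transcript[site.transcript_id].append(site)

    out = {}
    for g_id, footprints in hits_22g.items():
        if g_id in prg1:
            out[g_id] = Attribution22G(g_id, "none", [])
            continue
        supporting = []
        near = {"male": False, "female": False}
        for fp in footprints:
            for site in sites_by_transcript.get(fp.transcript_id, ()):
                gap = footprint_gap(fp.start, fp.end, site.start, site.end)
                if gap <= distance:
                    supporting.append((site, gap))
                    near[class_of_21u[site.source_21u]] = True
        if near["male"] and near["female"]:
            label = "ambiguous"
        elif near["male"]:
            label = "male_only"
        elif near["female"]:
            label = "female_only"
        else:
            label = "none"
        out[g_id] = Attribution22G(g_id, label, supporting)
    return out


def attribution_summary(attributions: Mapping[str, Attribution22G]) -> dict[str, int]:
    counts = {"male_only": 0, "female_only": 0, "ambiguous": 0, "none": 0}
    for att in attributions.values():
        counts[att.attributed_to] += 1
    return counts


# ---------------------------------------------------------------------------
# randomization tests
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RandomizationResult:
    observed: int
    random_counts: np.ndarray
    chi2_stat: float | None
    chi2_p: float | None

    @property
    def random_mean(self) -> float:
        return float(self.random_counts.mean())

    def percentile_of_observed(self) -> float:
        return float(100.0 * (self.random_counts < self.observed).mean())


def _chi2_2x2(obs_in: float, obs_out: float, exp_in: float, exp_out: float):
    table = np.array([[obs_in, obs_out], [exp_in, exp_out]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return None, None
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def overlap_randomization(
    hits_22g: Mapping[str, Sequence[TranscriptHit]],
    sites: Sequence[TargetSite],
    male_21u: Iterable[str],
    female_21u: Iterable[str],
    all_21u: Sequence[str],
    n_reps: int = 1000,
    distance: int = 40,
    prg1_detected: Iterable[str] = (),
    seed: int | None = None,
) -> RandomizationResult:
    """Compare observed both-attributed 22G count against random 21U sets.

    Each repetition draws disjoint random "male" and "female" 21U sets of the
    observed sizes from `all_21u` and recomputes how many 22G species lie
    within `distance` of a target site of both sets. The observed count is
    tested against the random mean with a 2x2 chi-squared (both vs not-both).
    """
    male_set, female_set = set(male_21u), set(female_21u)
    prg1 = set(prg1_detected)
    g_ids = [g for g in hits_22g if g not in prg1]
    g_index = {g: i for i, g in enumerate(g_ids)}
    u_index = {u: i for i, u in enumerate(all_21u)}

    # boolean proximity matrix: (21U species) x (22G species)
    prox = np.zeros((len(all_21u), len(g_ids)), dtype=bool)
    sites_by_transcript: dict[str, list[TargetSite]] = defaultdict(list)
    for site in sites:
        if site.source_21u in u_index:
            sites_by_transcript[site.transcript_id].append(site)
    for g_id in g_ids:
        gi = g_index[g_id]
        for fp in hits_22g[g_id]:
            for site in sites_by_transcript.get(fp.transcript_id, ()):
                gap = footprint_gap(fp.start, fp.end, site.start, site.end)
                if gap <= distance:
                    prox[u_index[site.source_21u], gi] = True

    def both_count(males: set[str], females: set[str]) -> int:
        m_rows = [u_index[u] for u in males if u in u_index]
        f_rows = [u_index[u] for u in females if u in u_index]
        near_m = prox[m_rows].any(axis=0) if m_rows else np.zeros(len(g_ids), bool)
        near_f = prox[f_rows].any(axis=0) if f_rows else np.zeros(len(g_ids), bool)
        return int((near_m & near_f).sum())

    observed = both_count(male_set, female_set)
    rng = np.random.default_rng(seed)
    n_m, n_f = len(male_set), len(female_set)
    if n_m + n_f > len(all_21u):
        raise ValueError("male + female set sizes exceed the 21U universe")
    random_counts = np.empty(n_reps, dtype=int)
    universe = np.asarray(all_21u, dtype=object)
    for rep in range(n_reps):
        draw = rng.choice(len(universe), size=n_m + n_f, replace=False)
        random_counts[rep] = both_count(
            set(universe[draw[:n_m]]), set(universe[draw[n_m:]])
        )
    total = len(g_ids)
    chi2, p = _chi2_2x2(
        observed, total - observed, random_counts.mean(), total - random_counts.mean()
    )
    return RandomizationResult(observed, random_counts, chi2, p)


def shared_target_genes(sites: Sequence[TargetSite], species: Iterable[str]) -> set[str]:
    """Transcripts targeted by any of the given 21U species."""
    members = set(species)
    return {s.transcript_id for s in sites if s.source_21u in members}


def target_gene_overlap_randomization(
    sites: Sequence[TargetSite],
    male_21u: Iterable[str],
    female_21u: Iterable[str],
    all_21u: Sequence[str],
    n_reps: int = 1000,
    seed: int | None = None,
) -> RandomizationResult:
    """Same randomization scheme on shared target-gene counts."""
    male_set, female_set = set(male_21u), set(female_21u)
    genes_by_u: dict[str, set[str]] = defaultdict(set)
    for site in sites:
        genes_by_u[site.source_21u].add(site.transcript_id)

    def overlap(males, females) -> int:
        gm = set().union(*(genes_by_u.get(u, set()) for u in males)) if males else set()
        gf = set().union(*(genes_by_u.get(u, set()) for u in females)) if females else set()
        return len(gm & gf)

    observed = overlap(male_set, female_set)
    rng = np.random.default_rng(seed)
    n_m, n_f = len(male_set), len(female_set)
    universe = np.asarray(all_21u, dtype=object)
    random_counts = np.empty(n_reps, dtype=int)
    for rep in range(n_reps):
        draw = rng.choice(len(universe), size=n_m + n_f, replace=False)
        random_counts[rep] = overlap(set(universe[draw[:n_m]]), set(universe[draw[n_m:]]))
    all_genes = len({s.transcript_id for s in sites})
    chi2, p = _chi2_2x2(
        observed, max(all_genes - observed, 0),
        random_counts.mean(), max(all_genes - random_counts.mean(), 0),
    )
    return RandomizationResult(observed, random_counts, chi2, p)


@dataclasses.dataclass
class GeneSetResult:
    observed_in_category: int
    expected_in_category: float
    n_targets: int
    chi2_stat: float | None
    chi2_p: float | None


def geneset_enrichment(
    target_genes: Iterable[str],
    category: Iterable[str],
    universe: Sequence[str],
    n_random: int = 1000,
    seed: int | None = None,
) -> GeneSetResult:
    """Test whether target genes are enriched/depleted in a gene category.

    Matched-size random gene lists are drawn from the universe without
    replacement; the observed in-category count is compared to the random
    expectation with a 2x2 chi-squared.
    """
    targets = set(target_genes)
    cat = set(category)
    if not cat:
        raise ValueError("category gene set is empty")
    n = len(targets)
    if n == 0 or n > len(universe):
        raise ValueError("target list empty or larger than the gene universe")
    observed = len(targets & cat)
    rng = np.random.default_rng(seed)
    uni = np.asarray(list(universe), dtype=object)
    in_cat = np.isin(uni, list(cat))
    random_counts = np.empty(n_random, dtype=int)
    for rep in range(n_random):
        draw = rng.choice(len(uni), size=n, replace=False)
        random_counts[rep] = int(in_cat[draw].sum())
    expected = float(random_counts.mean())
    chi2, p = _chi2_2x2(observed, n - observed, expected, n - expected)
    return GeneSetResult(observed, expected, n, chi2, p)
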