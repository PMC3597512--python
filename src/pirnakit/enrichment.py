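"""Enrichment Score classification of germline-enriched small RNAs.

Each species starts with a score of 0. For every within-protocol pair of one
male and one female germline library, the score decreases by 1 if the species
is more than `fold_threshold`-fold abundant in the male library and increases
by 1 if more than `fold_threshold`-fold abundant in the female library
(strict multiplicative comparison: zero against a positive abundance always
exceeds any fold, zero against zero contributes nothing). Species scoring at
or below -`score_threshold` are male germline-enriched, at or above
+`score_threshold` female; the rest are non-enriched. Two filters precede
scoring (species with no reads in any germline library; species with higher
abundance in a piwi-mutant than a wild-type reference library) and a
validation step reclassifies species whose average fold abundance does not
favor their class.

The false-discovery-rate null replaces each real library with counts drawn
from a Poisson distribution whose rate is the species' count in a single
reference library, randomly reassigns the design's sex/protocol labels over
the control libraries, and reclassifies; the classified fraction across
repetitions estimates the FDR of the thresholds.

The engine is generic over species class (21U or 26G RNAs) and library
design: the same machinery runs on any manifest with male and female
germline libraries.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from pirnakit.io import CountTable, LibraryDesign

CLASSES = ("male", "female", "non_enriched", "excluded_zero", "excluded_mutant")


def count_comparisons(design: LibraryDesign) -> int:
    """Number of within-protocol male x female library comparisons."""
    return len(design.comparisons())


def enrichment_score(
    abundances: pd.Series | dict,
    design: LibraryDesign,
    fold_threshold: float = 5.0,
    min_unit: float = 0.0,
) -> int:
    """Enrichment Score for a single species (negative = male-enriched).

    With the default `min_unit` of 0 the comparison is strictly
    multiplicative: any positive abundance against a zero exceeds any fold,
    and zero against zero contributes nothing. A positive `min_unit` floors
    the denominator (an excursion additionally requires the larger side to
    exceed fold_threshold * min_unit), which is the appropriate reading for
    raw counts, where a single read against zero is not fold evidence.
    """
    ab = pd.Series(abundances, dtype=float)
    if (ab < 0).any():
        raise ValueError("abundances must be non-negative")
    score = 0
    for m_id, f_id in design.comparisons():
        m, f = ab[m_id], ab[f_id]
        if m > fold_threshold * max(f, min_unit):
            score -= 1
        elif f > fold_threshold * max(m, min_unit):
            score += 1
    return score


def enrichment_scores(
    norm: pd.DataFrame,
    design: LibraryDesign,
    fold_threshold: float = 5.0,
    min_unit: float = 0.0,
) -> pd.Series:
    """Vectorised Enrichment Scores for every species (rows of `norm`)."""
    if (norm < 0).any().any():
        raise ValueError("abundances must be non-negative")
    score = pd.Series(0, index=norm.index, dtype=int)
    for m_id, f_id in design.comparisons():
        m, f = norm[m_id], norm[f_id]
        score -= (m > fold_threshold * f.clip(lower=min_unit)).astype(int)
        score += (f > fold_threshold * m.clip(lower=min_unit)).astype(int)
    return score


def average_fold(
    norm: pd.DataFrame, design: LibraryDesign, pseudocount: float = 0.25
) -> pd.DataFrame:
    """Average fold abundance per species across all comparisons.

    Per pair the fold is (male + pc) / (female + pc); the male average is the
    geometric mean over pairs and the female average its reciprocal. The
    pseudocount (default 0.25 RPM) keeps ratios defined at zero abundance.
    """
    pairs = design.comparisons()
    if not pairs:
        raise ValueError("design has no male x female comparisons")
    log_folds = np.zeros((len(norm), len(pairs)))
    for j, (m_id, f_id) in enumerate(pairs):
        log_folds[:, j] = np.log(
            (norm[m_id].to_numpy() + pseudocount) / (norm[f_id].to_numpy() + pseudocount)
        )
    avg_m = np.exp(log_folds.mean(axis=1))
    return pd.DataFrame(
        {"avg_fold_male": avg_m, "avg_fold_female": 1.0 / avg_m}, index=norm.index
    )


@dataclasses.dataclass
class GermlineEnrichment:
    """Model object: germline-enrichment classification of a count table.

    Parameters
    ----------
    counts : CountTable
        Raw and normalized per-library abundances for every species.
    design : LibraryDesign
        Library manifest; must contain at least one male and one female
        germline library.
    fold_threshold, score_threshold :
        Per-comparison fold cutoff (default 5) and classification score
        cutoff (default 3).
    mutant_lib, reference_lib :
        Library ids for the piwi-mutant dependence filter (e.g. a prg-1
        young-adult library against an N2 young-adult library); species more
        abundant in the mutant are excluded as likely piwi-independent.
    pseudocount :
        RPM pseudocount used only for average-fold validation.
    """

    counts: CountTable
    design: LibraryDesign
    fold_threshold: float = 5.0
    score_threshold: int = 3
    mutant_lib: str | None = None
    reference_lib: str | None = None
    pseudocount: float = 0.25

    def __post_init__(self):
        self.design.validate_counts(self.counts)
        if count_comparisons(self.design) == 0:
            raise ValueError(
                "enrichment analysis requires at least one male and one female "
                "germline library in the manifest"
            )

    def fit(self) -> "EnrichmentResults":
        germ = self.design.germline_ids()
        norm = self.counts.norm[germ]
        raw = self.counts.raw[germ]

        scores = enrichment_scores(norm, self.design, self.fold_threshold)
        folds = average_fold(norm, self.design, self.pseudocount)

        classification = pd.Series("non_enriched", index=norm.index, dtype=object)
        classification[scores <= -self.score_threshold] = "male"
        classification[scores >= self.score_threshold] = "female"

        # validation: a classified species whose average fold abundance does
        # not favor its class is demoted to non-enriched
        reclassified = pd.Series(False, index=norm.index)
        bad_male = (classification == "male") & (folds["avg_fold_male"] <= 1.0)
        bad_female = (classification == "female") & (folds["avg_fold_female"] <= 1.0)
        reclassified[bad_male | bad_female] = True
        classification[bad_male | bad_female] = "non_enriched"

        # exclusion filters take precedence over any score
        if self.mutant_lib is not None and self.reference_lib is not None:
            mut = self.counts.norm[self.mutant_lib]
            ref = self.counts.norm[self.reference_lib]
            classification[mut > ref] = "excluded_mutant"
        classification[(raw == 0).all(axis=1)] = "excluded_zero"

        table = pd.DataFrame(
            {
                "score": scores,
                "classification": classification,
                "avg_fold_male": folds["avg_fold_male"],
                "avg_fold_female": folds["avg_fold_female"],
                "reclassified": reclassified,
            }
        )
        table.index.name = "species_id"
        return EnrichmentResults(self, table)


@dataclasses.dataclass
class EnrichmentResults:
    """Fitted classification results; `table` has one row per species."""

    model: GermlineEnrichment
    table: pd.DataFrame

    @property
    def classification(self) -> pd.Series:
        return self.table["classification"]

    @property
    def scores(self) -> pd.Series:
        return self.table["score"]

    def class_counts(self) -> pd.Series:
        return self.classification.value_counts().reindex(CLASSES, fill_value=0)

    def analyzed(self) -> pd.DataFrame:
        """Rows surviving the exclusion filters."""
        keep = ~self.classification.isin(["excluded_zero", "excluded_mutant"])
        return self.table[keep]

    def summary(self) -> str:
        n = len(self.table)
        counts = self.class_counts()
        analyzed = counts["male"] + counts["female"] + counts["non_enriched"]
        lines = [
            "Germline enrichment classification",
            "=" * 50,
            f"species total            {n}",
            f"excluded (no reads)      {counts['excluded_zero']}",
            f"excluded (mutant filter) {counts['excluded_mutant']}",
            f"analyzed                 {analyzed}",
            f"comparisons per species  {count_comparisons(self.model.design)}",
            f"fold / score thresholds  {self.model.fold_threshold:g} / "
            f"{self.model.score_threshold}",
            "-" * 50,
        ]
        for cls in ("male", "female", "non_enriched"):
            pct = 100.0 * counts[cls] / analyzed if analyzed else 0.0
            lines.append(f"{cls:<24} {counts[cls]:>6}  ({pct:5.1f}%)")
        lines.append(f"reclassified by avg fold {int(self.table['reclassified'].sum())}")
        return "\n".join(lines)


def classify(
    counts: CountTable,
    design: LibraryDesign,
    fold_threshold: float = 5.0,
    score_threshold: int = 3,
    **kwargs,
) -> EnrichmentResults:
    """Functional shorthand for GermlineEnrichment(...).fit()."""
    return GermlineEnrichment(
        counts, design, fold_threshold=fold_threshold, score_threshold=score_threshold, **kwargs
    ).fit()


# the classification engine is generic over species class; 26G RNA analysis
# is the same fit under a reduced manifest (libraries from genotypes lacking
# 26G expression removed at the manifest level)
run_26g = classify


# ---------------------------------------------------------------------------
# Poisson-null false discovery rate
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FdrResult:
    fractions: np.ndarray  # classified fraction per repetition
    n_species: int
    n_reps: int

    @property
    def mean_fraction(self) -> float:
        return float(self.fractions.mean())

    @property
    def mean_percent(self) -> float:
        return 100.0 * self.mean_fraction


def fdr_simulation(
    lambdas: np.ndarray,
    design: LibraryDesign,
    n_reps: int = 1000,
    fold_threshold: float = 5.0,
    score_threshold: int = 3,
    min_unit: float = 1.0,
    seed: int | None = None,
) -> FdrResult:
    """Poisson-null FDR of the Enrichment Score thresholds.

    For each repetition, every species gets one raw Poisson count per control
    library (rate = the species' count in the reference library), the
    germline design's sex/protocol labels are randomly permuted over the
    control libraries, and the standard scoring/thresholding is applied. The
    classified fraction uses all simulated species as the denominator.

    Because the null operates on raw counts, the default `min_unit` of one
    read floors the fold denominator: a single read against zero is sampling
    noise, not a fold excursion (set min_unit=0 for the strict rule).
    """
    lambdas = np.asarray(lambdas, dtype=float)
    if (lambdas < 0).any():
        raise ValueError("Poisson rates must be non-negative")
    rng = np.random.default_rng(seed)

    germ = [design.get(i) for i in design.germline_ids()]
    n_ctrl = len(germ)
    labels = np.array(
        [(1 if l.sex == "male" else 0, 1 if l.protocol == "monoP_dependent" else 0) for l in germ]
    )
    n_species = lambdas.size
    fractions = np.empty(n_reps)
    for rep in range(n_reps):
        counts = rng.poisson(lambdas[:, None], size=(n_species, n_ctrl)).astype(float)
        perm = rng.permutation(n_ctrl)
        lab = labels[perm]
        score = np.zeros(n_species, dtype=np.int64)
        for proto in (0, 1):
            male_cols = np.flatnonzero((lab[:, 0] == 1) & (lab[:, 1] == proto))
            female_cols = np.flatnonzero((lab[:, 0] == 0) & (lab[:, 1] == proto))
            for mc in male_cols:
                m = counts[:, mc]
                for fc in female_cols:
                    f = counts[:, fc]
                    score -= (m > fold_threshold * np.maximum(f, min_unit)).astype(np.int64)
                    score += (f > fold_threshold * np.maximum(m, min_unit)).astype(np.int64)
        classified = np.abs(score) >= score_threshold
        fractions[rep] = classified.mean()
    return FdrResult(fractions, n_species, n_reps)


# ---------------------------------------------------------------------------
# embryo enrichment comparison
# ---------------------------------------------------------------------------

def welch_t(x, y) -> tuple[float, float]:
    """Two-tailed Welch's t-test (unequal variances)."""
    res = stats.ttest_ind(np.asarray(x, float), np.asarray(y, float), equal_var=False)
    return float(res.statistic), float(res.pvalue)


@dataclasses.dataclass
class EmbryoComparison:
    detection: pd.DataFrame  # per class: detected / not detected in embryo
    chi2_stat: float
    chi2_p: float
    fold_by_class: dict[str, np.ndarray]  # per-species average embryo fold
    mean_fold: dict[str, float]
    fold_ratio_female_over_male: float
    welch_stat: float
    welch_p: float


def embryo_comparison(
    counts: CountTable,
    design: LibraryDesign,
    classification: pd.Series,
    pseudocount: float = 0.25,
) -> EmbryoComparison:
    """Compare embryo behavior of male- vs female-classified species.

    Detection: at least one read in at least one embryo library (2x2 Pearson
    chi-squared between classes). Abundance: per species, the geometric mean
    over all (same-sex germline library, embryo library) pairs of the embryo
    to germline abundance ratio; Welch's two-tailed t between classes on the
    log ratios' exponentials.
    """
    embryo = design.embryo_ids()
    if not embryo:
        raise ValueError("design contains no embryo libraries")

    det_rows = {}
    fold_by_class: dict[str, np.ndarray] = {}
    for cls in ("male", "female"):
        members = classification.index[classification == cls]
        det = (counts.raw.loc[members, embryo] > 0).any(axis=1)
        det_rows[cls] = [int(det.sum()), int((~det).sum())]
        germ = [l.id for l in design.subset(sex=cls)]
        logs = []
        for g in germ:
            for e in embryo:
                logs.append(
                    np.log(
                        (counts.norm.loc[members, e].to_numpy() + pseudocount)
                        / (counts.norm.loc[members, g].to_numpy() + pseudocount)
                    )
                )
        fold_by_class[cls] = np.exp(np.mean(logs, axis=0)) if logs else np.zeros(0)

    detection = pd.DataFrame(det_rows, index=["detected", "not_detected"]).T
    tab = detection.to_numpy()
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        chi2, p_chi2 = float("nan"), float("nan")  # degenerate: a zero margin
    else:
        chi2, p_chi2, _, _ = stats.chi2_contingency(tab, correction=False)
    t, p_t = welch_t(fold_by_class["female"], fold_by_class["male"])
    mean_fold = {cls: float(v.mean()) if v.size else float("nan") for cls, v in fold_by_class.items()}
    ratio = mean_fold["female"] / mean_fold["male"] if mean_fold["male"] else float("nan")
    return EmbryoComparison(
        detection=detection,
        chi2_stat=float(chi2),
        chi2_p=float(p_chi2),
        fold_by_class=fold_by_class,
        mean_fold=mean_fold,
        fold_ratio_female_over_male=float(ratio),
        welch_stat=t,
        welch_p=p_t,
    )
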