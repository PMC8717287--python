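"""Color-allele frequency estimation under dominance and haplodiploidy.

The color locus has two alleles, ferruginous ``f`` (dominant) and black
``b``.  Queens and workers are diploid, so black females are ``bb`` and
the black-allele frequency among females is estimated by inverting the
Hardy–Weinberg proportion of the only unambiguous phenotype class:

    b_female = sqrt(n_black_females / n_females)

Drones are haploid males whose phenotype equals their genotype, so the
male estimate is the plain proportion of black males.  Combined
estimates treat males and females as equal individuals: each female
contributes ``b_female`` effective black individuals on average, each
black male one.

Temporal change per locality is tested with a Pearson chi-square test of
independence on the 2 x P table of effective (b, f) counts across P
collection periods; effective counts may be non-integer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from mimicline.specimen_io import (
    Caste,
    ColorGenotype,
    ColorPhenotype,
    SpecimenTable,
)


class EstimateError(ValueError):
    """Estimator undefined for the given counts."""


@dataclass
class AlleleFrequencyEstimate:
    """Black/ferruginous allele frequencies for one locality and period."""

    locality: str
    period: str
    b: float
    f: float
    n_females: int
    n_black_females: int
    n_males: int
    n_black_males: int
    effective_b_count: float
    effective_f_count: float


def female_allele_freq(n_black_females: int, n_females: int) -> tuple[float, float]:
    """(b, f) from diploid females: b = sqrt(black proportion)."""
    if n_females < 1:
        raise EstimateError("no females: female allele frequency undefined")
    if not 0 <= n_black_females <= n_females:
        raise EstimateError("black female count outside [0, n_females]")
    b = float(np.sqrt(n_black_females / n_females))
    return b, 1.0 - b


def male_allele_freq(n_black_males: int, n_males: int) -> tuple[float, float]:
    """(b, f) from haploid males: phenotype proportion is the allele frequency."""
    if n_males < 1:
        raise EstimateError("no males: male allele frequency undefined")
    if not 0 <= n_black_males <= n_males:
        raise EstimateError("black male count outside [0, n_males]")
    b = n_black_males / n_males
    return b, 1.0 - b


def combined_allele_freq(
    n_black_females: int,
    n_females: int,
    n_black_males: int,
    n_males: int,
    locality: str = "",
    period: str = "",
) -> AlleleFrequencyEstimate:
    """Combine sexes treating individuals equally.

    Effective black count = b_female * n_females + n_black_males; the
    combined frequency divides by the total number of individuals (not
    allele copies), so a female counts once despite carrying two copies.
    Either sex may be absent, in which case the estimate reduces to the
    other sex's estimator.
    """
    if n_females + n_males < 1:
        raise EstimateError("no individuals")
    b_eff = 0.0
    if n_females > 0:
        b_f, _ = female_allele_freq(n_black_females, n_females)
        b_eff += b_f * n_females
    if n_males > 0:
        b_eff += n_black_males
    total = n_females + n_males
    b = b_eff / total
    return AlleleFrequencyEstimate(
        locality=locality,
        period=period,
        b=b,
        f=1.0 - b,
        n_females=n_females,
        n_black_females=n_black_females,
        n_males=n_males,
        n_black_males=n_black_males,
        effective_b_count=b_eff,
        effective_f_count=total - b_eff,
    )


def estimate_from_table(
    table: SpecimenTable,
    group_by: tuple[str, ...] = ("locality", "period"),
    use_known_genotypes: bool = False,
) -> list[AlleleFrequencyEstimate]:
    """Per-group allele-frequency estimates from a specimen table.

    Specimens with unknown phenotype are excluded.  With
    ``use_known_genotypes`` females whose color locus was sequenced
    contribute exact allele counts (ff -> 0, fb -> 1, bb -> 2 black
    copies, scaled to one individual) instead of entering the
    Hardy–Weinberg inversion.
    """
    groups: dict[tuple, list] = {}
    for r in table:
        if r.color_phenotype is ColorPhenotype.UNKNOWN:
            continue
        key = tuple(getattr(r, g) for g in group_by)
        groups.setdefault(key, []).append(r)
    estimates = []
    for key, recs in sorted(groups.items()):
        males = [r for r in recs if r.caste is Caste.DRONE]
        females = [r for r in recs if r.caste is not Caste.DRONE]
        n_black_males = sum(r.color_phenotype is ColorPhenotype.BLACK for r in males)
        if use_known_genotypes:
            known = [r for r in females if r.color_genotype is not ColorGenotype.UNKNOWN]
            unknown = [r for r in females if r.color_genotype is ColorGenotype.UNKNOWN]
            # each genotyped female contributes her exact black-copy dose / 2
            dose = {"ff": 0.0, "fb": 0.5, "bb": 1.0}
            b_known = sum(dose[r.color_genotype.value] for r in known)
            n_black_unknown = sum(r.color_phenotype is ColorPhenotype.BLACK for r in unknown)
            b_eff = b_known
            if unknown:
                b_u, _ = female_allele_freq(n_black_unknown, len(unknown))
                b_eff += b_u * len(unknown)
            b_eff += n_black_males
            total = len(females) + len(males)
            if total < 1:
                raise EstimateError(f"group {key}: no individuals")
            est = AlleleFrequencyEstimate(
                locality=str(key[0]) if key else "",
                period=str(key[1]) if len(key) > 1 else "",
                b=b_eff / total,
                f=1.0 - b_eff / total,
                n_females=len(females),
                n_black_females=sum(
                    r.color_phenotype is ColorPhenotype.BLACK for r in females
                ),
                n_males=len(males),
                n_black_males=n_black_males,
                effective_b_count=b_eff,
                effective_f_count=total - b_eff,
            )
        else:
            est = combined_allele_freq(
                n_black_females=sum(
                    r.color_phenotype is ColorPhenotype.BLACK for r in females
                ),
                n_females=len(females),
                n_black_males=n_black_males,
                n_males=len(males),
                locality=str(key[0]) if key else "",
                period=str(key[1]) if len(key) > 1 else "",
            )
        estimates.append(est)
    return estimates


def period_independence_test(counts) -> tuple[float, int, float]:
    """Pearson chi-square test of allele-frequency homogeneity across periods.

    ``counts`` is a 2 x P array: row 0 = effective b counts, row 1 =
    effective f counts, one column per period.  Non-integer effective
    counts are accepted.  No continuity correction; df = P - 1.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 2 or counts.shape[1] < 2:
        raise EstimateError("need a 2 x P table with P >= 2")
    if np.any(counts < 0):
        raise EstimateError("negative counts")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise EstimateError("degenerate table: zero row or column margin")
    chi2, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return float(chi2), int(df), float(p)
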