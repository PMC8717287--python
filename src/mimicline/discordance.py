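"""Chi-square tests of mito-nuclear discordance inside the hybrid zone.

Two goodness-of-fit constructions quantify whether mitochondrial
haplogroups and color alleles moved through the transition zone at the
same rate:

1. **Haplogroup vs. color-allele frequencies** — if gene flow were
   identical, the northern/southern haplogroup counts in the hybrid
   zone should be proportional to the ferruginous/black color-allele
   frequencies there (the northern haplogroup is ancestrally paired
   with the ferruginous allele, the southern with black).
2. **Color frequencies within a haplogroup** — whether the color-allele
   composition of one haplogroup departs from the overall hybrid-zone
   color frequencies (most informative for the rarer southern
   haplogroup, which in the field carries almost exclusively black
   alleles).

Color alleles are read directly from haploid males (phenotype =
genotype) and from females whose color locus was sequenced; females
with unknown genotype are excluded.  By default each diploid female
contributes two allele copies and each male one; the alternative
"individuals-equal" weighting (one unit per specimen) is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from mimicline.specimen_io import (
    Caste,
    ColorGenotype,
    MtHaplogroup,
    SpecimenTable,
)


class DiscordanceError(ValueError):
    """Degenerate or unusable discordance inputs."""


@dataclass
class DiscordanceInput:
    """Haplogroup and color-allele counts within the hybrid-zone window."""

    n_north: int
    n_south: int
    f_alleles: float
    b_alleles: float
    f_by_group: dict
    b_by_group: dict
    window_km: tuple[float, float]

    @property
    def freq_f(self) -> float:
        return self.f_alleles / (self.f_alleles + self.b_alleles)

    @property
    def freq_b(self) -> float:
        return self.b_alleles / (self.f_alleles + self.b_alleles)


def hybrid_zone_window(
    table: SpecimenTable, override: tuple[float, float] | None = None
) -> tuple[float, float]:
    """Transect interval where the two haplogroups co-occur.

    Default: [southernmost northern-haplogroup specimen, northernmost
    southern-haplogroup specimen].  An explicit ``override`` interval
    wins, including when the haplogroup ranges do not overlap.
    """
    if override is not None:
        return (float(override[0]), float(override[1]))
    north = [r.transect_km for r in table if r.mt_haplogroup is MtHaplogroup.NORTHERN]
    south = [r.transect_km for r in table if r.mt_haplogroup is MtHaplogroup.SOUTHERN]
    if not north or not south:
        raise DiscordanceError("need at least one specimen of each haplogroup")
    lo, hi = min(north), max(south)
    if lo > hi:
        raise DiscordanceError(
            "haplogroup ranges do not overlap; supply an explicit window"
        )
    return (lo, hi)


_ALLELE_COPIES = {
    ColorGenotype.FF: (2.0, 0.0),
    ColorGenotype.FB: (1.0, 1.0),
    ColorGenotype.BB: (0.0, 2.0),
    ColorGenotype.F: (1.0, 0.0),
    ColorGenotype.B: (0.0, 1.0),
}


def collect_discordance_input(
    table: SpecimenTable,
    window: tuple[float, float] | None = None,
    counting: str = "alleles",
) -> DiscordanceInput:
    """Tally haplogroups and color alleles inside the hybrid-zone window.

    Uses all males plus females with a sequenced color genotype.
    ``counting="alleles"`` (default) weights diploid females as two
    copies; ``counting="individuals"`` weights every specimen as one
    unit (a heterozygous female then splits 0.5/0.5).
    """
    if counting not in ("alleles", "individuals"):
        raise DiscordanceError(f"unknown counting mode {counting!r}")
    lo, hi = hybrid_zone_window(table, window)
    n_by_group = {MtHaplogroup.NORTHERN: 0, MtHaplogroup.SOUTHERN: 0}
    f_by_group = {MtHaplogroup.NORTHERN: 0.0, MtHaplogroup.SOUTHERN: 0.0}
    b_by_group = {MtHaplogroup.NORTHERN: 0.0, MtHaplogroup.SOUTHERN: 0.0}
    for r in table:
        if not lo <= r.transect_km <= hi:
            continue
        if r.mt_haplogroup is MtHaplogroup.UNKNOWN:
            continue
        if r.color_genotype not in _ALLELE_COPIES:
            continue  # females without a sequenced color locus
        n_by_group[r.mt_haplogroup] += 1
        f_c, b_c = _ALLELE_COPIES[r.color_genotype]
        if counting == "individuals" and r.caste is not Caste.DRONE:
            f_c, b_c = f_c / 2.0, b_c / 2.0
        f_by_group[r.mt_haplogroup] += f_c
        b_by_group[r.mt_haplogroup] += b_c
    return DiscordanceInput(
        n_north=n_by_group[MtHaplogroup.NORTHERN],
        n_south=n_by_group[MtHaplogroup.SOUTHERN],
        f_alleles=sum(f_by_group.values()),
        b_alleles=sum(b_by_group.values()),
        f_by_group={k.value: v for k, v in f_by_group.items()},
        b_by_group={k.value: v for k, v in b_by_group.items()},
        window_km=(lo, hi),
    )


def _gof(observed: np.ndarray, expected: np.ndarray) -> tuple[float, int, float]:
    if np.any(expected <= 0):
        raise DiscordanceError("zero expected cell in goodness-of-fit test")
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, 1, p


def haplotype_vs_colorallele_gof(inp: DiscordanceInput) -> tuple[float, int, float]:
    """Test 1: haplogroup counts vs. color-allele frequency expectations.

    Observed (n_north, n_south); expected proportional to the overall
    (f, b) color-allele frequencies in the hybrid zone — northern
    paired with ferruginous, its ancestral color.  Pearson GOF, df = 1,
    no continuity correction.
    """
    total = inp.n_north + inp.n_south
    if total == 0:
        raise DiscordanceError("no haplogroup-typed specimens in the window")
    observed = np.array([inp.n_north, inp.n_south], dtype=float)
    expected = np.array([inp.freq_f, inp.freq_b]) * total
    return _gof(observed, expected)


def color_within_haplotype_gof(
    inp: DiscordanceInput, haplogroup: str
) -> tuple[float, int, float]:
    """Test 2: color-allele counts within one haplogroup vs. overall frequencies.

    Observed (f, b) counts among carriers of ``haplogroup``; expected =
    overall hybrid-zone color frequencies scaled to the haplogroup
    total.  Pearson GOF, df = 1.
    """
    if haplogroup not in inp.f_by_group:
        raise DiscordanceError(f"unknown haplogroup {haplogroup!r}")
    obs_f = inp.f_by_group[haplogroup]
    obs_b = inp.b_by_group[haplogroup]
    total = obs_f + obs_b
    if total == 0:
        raise DiscordanceError(f"no color alleles observed for haplogroup {haplogroup!r}")
    observed = np.array([obs_f, obs_b], dtype=float)
    expected = np.array([inp.freq_f, inp.freq_b]) * total
    return _gof(observed, expected)


def discordance_report(
    table: SpecimenTable,
    window: tuple[float, float] | None = None,
    counting: str = "alleles",
) -> dict:
    """Both tests plus the observed color x haplogroup composition."""
    inp = collect_discordance_input(table, window, counting)
    chi2_1, df1, p1 = haplotype_vs_colorallele_gof(inp)
    result = {
        "window_km": list(inp.window_km),
        "counting": counting,
        "n_north": inp.n_north,
        "n_south": inp.n_south,
        "f_alleles": inp.f_alleles,
        "b_alleles": inp.b_alleles,
        "composition": {
            g: {"f": inp.f_by_group[g], "b": inp.b_by_group[g]}
            for g in inp.f_by_group
        },
        "haplotype_vs_colorallele": {"chi2": chi2_1, "df": df1, "p": p1},
        "color_within_haplotype": {},
    }
    for g in ("northern", "southern"):
        try:
            chi2, df, p = color_within_haplotype_gof(inp, g)
            result["color_within_haplotype"][g] = {"chi2": chi2, "df": df, "p": p}
        except DiscordanceError as exc:
            result["color_within_haplotype"][g] = {"error": str(exc)}
    return result
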