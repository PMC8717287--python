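"""Synthetic hybrid-zone data with the statistical structure the analyses assume.

The generator emulates a two-lineage secondary-contact zone along a 1D
north–south transect:

* a **color cline** in the frequency of the recessive black allele
  (black fixed in the south, ferruginous in the north), with diploid
  females drawn at Hardy–Weinberg proportions and haploid drones drawn
  Bernoulli, phenotypes following ferruginous dominance;
* a **mitochondrial cline** in the probability of carrying the southern
  COI haplogroup, offset south of the color cline (the mito-nuclear
  discordance signal);
* a **COI alignment** whose two haplogroup consensus sequences differ
  at a configurable number of fixed sites plus private within-group
  variants at disjoint sites, so planted counts are additive;
* a **nuclear SNP matrix** whose samples follow an admixture gradient
  between two ancestral allele-frequency vectors, contaminated with
  planted NUMT intervals containing tightly clustered SNPs fixed
  between the mitochondrial haplogroup sample groups, plus scattered
  genuinely ancestry-fixed SNPs, low-quality calls, short contigs and
  non-biallelic sites to exercise every filter tier.

Default cline parameters are the fitted field values for the mimicry
transition zone (color center 661.6 km / width 134.3 km; mtDNA center
607.0 km / width 157.6 km; nuclear center 650.6 km / width 292 km), so
parameter-recovery tests double as plausibility checks.  All generators
are pure functions of their configuration (which includes the seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mimicline.cline_fit import ClineModel, ModelClass, cline_value
from mimicline.seqstats import Alignment
from mimicline.snp_filter import NUMTAnnotationSet, NUMTInterval, SNPMatrix
from mimicline.specimen_io import (
    Caste,
    ColorGenotype,
    ColorPhenotype,
    MtHaplogroup,
    SpecimenRecord,
    SpecimenTable,
)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic hybrid zone."""

    seed: int = 1
    # specimen table
    n_specimens: int = 2000
    male_fraction: float = 0.2
    transect_extent: tuple[float, float] = (0.0, 1300.0)
    color_cline: tuple[float, float] = (661.6, 134.3)  # center, width (km)
    mt_cline: tuple[float, float] = (607.0, 157.6)
    nuclear_cline: tuple[float, float] = (650.6, 292.0)
    nuclear_noise_sd: float = 0.1
    # COI alignment
    coi_length: int = 500
    n_fixed_coi_diffs: int = 8
    within_group_shared: int = 4  # total private variants carried by exactly 2 bees
    within_group_singletons: int = 1  # total private variants carried by 1 bee
    # SNP matrix
    n_snps: int = 2000
    n_samples_genomic: int = 20
    n_southern_genomic: int = 3
    n_contigs: int = 20
    contig_length: int = 50_000
    n_short_contigs: int = 2
    short_contig_length: int = 10_000
    n_numt_intervals: int = 2
    numt_interval_length: int = 1000
    numt_snps_per_interval: int = 15
    n_ancestry_fixed_snps: int = 30
    ancestral_freq_divergence: float = 0.2
    low_quality_call_fraction: float = 0.02
    non_biallelic_fraction: float = 0.01

    def __post_init__(self) -> None:
        lo, hi = self.transect_extent
        if hi <= lo:
            raise ConfigError("transect extent must be increasing")
        for name, (c, w) in (
            ("color_cline", self.color_cline),
            ("mt_cline", self.mt_cline),
            ("nuclear_cline", self.nuclear_cline),
        ):
            if w <= 0:
                raise ConfigError(f"{name}: width must be positive")
            if not lo <= c <= hi:
                raise ConfigError(f"{name}: center {c} outside transect extent")
        n_planted = self.n_fixed_coi_diffs + self.within_group_shared + self.within_group_singletons
        if n_planted > self.coi_length:
            raise ConfigError("planted COI variants exceed alignment length")
        if self.numt_interval_length > self.contig_length:
            raise ConfigError("NUMT interval longer than contig")
        if not 0 <= self.male_fraction <= 1:
            raise ConfigError("male_fraction outside [0, 1]")


def _cline_prob(x: np.ndarray, center: float, width: float) -> np.ndarray:
    """Increasing model-I unit-range sigmoid along the transect."""
    model = ClineModel(ModelClass.II_FREE_NONE, c=center, w=width, pmin=0.0, pmax=1.0)
    return np.asarray(cline_value(model, x))


def simulate_specimens(config: SimulationConfig) -> SpecimenTable:
    """Draw a specimen table from the configured clines.

    Positions are uniform on the transect (mapped back to latitudes on
    a fixed meridian); the black-allele frequency decreases northward
    along the color cline and the southern-haplogroup probability
    decreases northward along the mtDNA cline.
    """
    rng = np.random.default_rng([config.seed, 1])
    lo, hi = config.transect_extent
    x = np.sort(rng.uniform(lo, hi, size=config.n_specimens))
    b_freq = 1.0 - _cline_prob(x, *config.color_cline)  # black common in the south
    p_south = 1.0 - _cline_prob(x, *config.mt_cline)
    is_male = rng.random(config.n_specimens) < config.male_fraction
    # map transect km back onto latitudes north of a fixed reference
    ref_lat = 38.0
    lat = ref_lat + x / 111.19492664455873  # km per degree at R = 6371.0088
    records = []
    for i in range(config.n_specimens):
        b = b_freq[i]
        if is_male[i]:
            caste = Caste.DRONE
            geno = ColorGenotype.B if rng.random() < b else ColorGenotype.F
            pheno = ColorPhenotype.BLACK if geno is ColorGenotype.B else ColorPhenotype.FERRUGINOUS
        else:
            caste = Caste.WORKER if rng.random() < 0.8 else Caste.QUEEN
            u = rng.random()
            if u < b * b:
                geno = ColorGenotype.BB
            elif u < b * b + 2 * b * (1 - b):
                geno = ColorGenotype.FB
            else:
                geno = ColorGenotype.FF
            pheno = (
                ColorPhenotype.BLACK if geno is ColorGenotype.BB else ColorPhenotype.FERRUGINOUS
            )
        hap = MtHaplogroup.SOUTHERN if rng.random() < p_south[i] else MtHaplogroup.NORTHERN
        records.append(
            SpecimenRecord(
                id=f"bee{i:05d}",
                caste=caste,
                latitude=float(lat[i]),
                longitude=-123.0,
                color_phenotype=pheno,
                color_genotype=geno,
                mt_haplogroup=hap,
                period="2014-2019",
                locality=f"zone{int(x[i] // 100):02d}",
            )
        )
    return SpecimenTable.from_records(records)


def simulate_cline_observations(
    center: float,
    width: float,
    n: int,
    seed: int,
    extent: tuple[float, float] = (0.0, 1300.0),
    increasing: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary trait observations drawn from a model-I cline.

    Convenience generator for parameter-recovery experiments: positions
    uniform on ``extent``, y ~ Bernoulli(p(x)) with p the unit-range
    sigmoid (decreasing when ``increasing=False``).
    """
    rng = np.random.default_rng(seed)
    lo, hi = extent
    x = np.sort(rng.uniform(lo, hi, size=n))
    p = _cline_prob(x, center, width)
    if not increasing:
        p = 1.0 - p
    y = (rng.random(n) < p).astype(float)
    return x, y


def simulate_coi_alignment(table: SpecimenTable, config: SimulationConfig) -> Alignment:
    """COI alignment matching each specimen's haplogroup.

    The two haplogroup consensus sequences differ at exactly
    ``n_fixed_coi_diffs`` sites.  The groups additionally carry
    ``within_group_shared`` private variants present in exactly two
    members of one group (parsimony-informative) and
    ``within_group_singletons`` variants present in one member, both
    totals alternating between the groups, all at mutually disjoint
    sites so planted counts are additive.
    """
    rng = np.random.default_rng([config.seed, 2])
    bases = np.array(list("ACGT"))
    consensus_n = rng.choice(bases, size=config.coi_length)
    n_private = config.within_group_shared + config.within_group_singletons
    n_special = config.n_fixed_coi_diffs + n_private
    special = rng.choice(config.coi_length, size=n_special, replace=False)
    fixed_sites = special[: config.n_fixed_coi_diffs]
    private_site_list = special[config.n_fixed_coi_diffs :]
    both_groups = [MtHaplogroup.NORTHERN, MtHaplogroup.SOUTHERN]
    # (site, group, carrier count): shared variants first, then singletons
    private_plan = [
        (
            int(site),
            both_groups[v % 2],
            2 if v < config.within_group_shared else 1,
        )
        for v, site in enumerate(private_site_list)
    ]
    consensus_s = consensus_n.copy()
    for site in fixed_sites:
        alternatives = [b for b in "ACGT" if b != consensus_n[site]]
        consensus_s[site] = rng.choice(alternatives)
    consensus = {
        MtHaplogroup.NORTHERN: consensus_n,
        MtHaplogroup.SOUTHERN: consensus_s,
    }

    members = {
        MtHaplogroup.NORTHERN: [r.id for r in table if r.mt_haplogroup is MtHaplogroup.NORTHERN],
        MtHaplogroup.SOUTHERN: [r.id for r in table if r.mt_haplogroup is MtHaplogroup.SOUTHERN],
    }
    seqs = {
        rid: consensus[group].copy()
        for group, ids in members.items()
        for rid in ids
    }
    for site, group, carriers in private_plan:
        ids = members[group]
        if len(ids) < carriers + 2:
            raise ConfigError(
                f"haplogroup {group.value} too small for planted private variants"
            )
        chosen = rng.choice(len(ids), size=carriers, replace=False)
        base = consensus[group][site]
        variant = rng.choice([b for b in "ACGT" if b != base])
        for ci in chosen:
            seqs[ids[ci]][site] = variant

    ids = [r.id for r in table if r.mt_haplogroup is not MtHaplogroup.UNKNOWN]
    return Alignment(
        ids=ids,
        sequences=["".join(seqs[rid]) for rid in ids],
        groups={r.id: r.mt_haplogroup.value for r in table},
    )


def simulate_snp_matrix(
    config: SimulationConfig,
) -> tuple[SNPMatrix, NUMTAnnotationSet, dict]:
    """Nuclear SNP matrix with planted NUMT contamination.

    Background sites are drawn binomially from admixture-weighted
    allele frequencies (two ancestral vectors separated by
    ``ancestral_freq_divergence``; per-sample admixture follows the
    nuclear cline).  Planted site classes:

    * clustered NUMT sites inside ``n_numt_intervals`` intervals, fixed
      between the southern/northern mitochondrial sample groups;
    * ``n_ancestry_fixed_snps`` scattered genuinely nuclear sites fixed
      between the same groups;
    * a fraction of low-quality calls and non-biallelic sites on
      background sites only.

    Returns the matrix, the truth annotation intervals
    (tier ``annotation``), and a truth dict with per-site NUMT and
    ancestry-fixed masks plus per-sample admixture and positions.
    """
    rng = np.random.default_rng([config.seed, 3])
    lo, hi = config.transect_extent

    n_samples = config.n_samples_genomic
    n_south = config.n_southern_genomic
    if n_south >= n_samples:
        raise ConfigError("need more total samples than southern samples")
    samples = [f"gen{i:03d}" for i in range(n_samples)]
    sample_x = np.sort(rng.uniform(lo, hi, size=n_samples))
    # southern haplogroup carriers sit at the southern end of the transect
    groups = {
        s: ("southern" if i < n_south else "northern") for i, s in enumerate(samples)
    }
    q_north = np.clip(
        _cline_prob(sample_x, *config.nuclear_cline)
        + rng.normal(0.0, config.nuclear_noise_sd, size=n_samples),
        0.0,
        1.0,
    )

    contig_lengths = {}
    long_names = []
    for i in range(config.n_contigs):
        name = f"contig{i:03d}"
        contig_lengths[name] = config.contig_length
        long_names.append(name)
    short_names = []
    for i in range(config.n_short_contigs):
        name = f"short{i:03d}"
        contig_lengths[name] = config.short_contig_length
        short_names.append(name)

    # NUMT intervals on distinct long contigs
    if config.n_numt_intervals > config.n_contigs:
        raise ConfigError("more NUMT intervals than contigs")
    numt_contigs = rng.choice(config.n_contigs, size=config.n_numt_intervals, replace=False)
    intervals = []
    for ci in numt_contigs:
        start = int(rng.integers(1, config.contig_length - config.numt_interval_length))
        intervals.append(
            NUMTInterval(
                long_names[ci], start, start + config.numt_interval_length - 1,
                "annotation", "planted-numt",
            )
        )
    annot = NUMTAnnotationSet(intervals)

    # site coordinates: background uniform over all contigs, NUMT sites
    # clustered inside their intervals
    site_list: list[tuple[str, int, str]] = []  # contig, pos, kind
    n_background = config.n_snps
    all_names = long_names + short_names
    weights = np.array([contig_lengths[c] for c in all_names], dtype=float)
    weights /= weights.sum()
    chosen = rng.choice(len(all_names), size=n_background, p=weights)
    taken: set[tuple[str, int]] = set()
    for ci in chosen:
        cname = all_names[ci]
        while True:
            p = int(rng.integers(1, contig_lengths[cname] + 1))
            if (cname, p) not in taken:
                taken.add((cname, p))
                site_list.append((cname, p, "background"))
                break
    for iv in intervals:
        offsets = rng.choice(
            config.numt_interval_length, size=config.numt_snps_per_interval, replace=False
        )
        for off in np.sort(offsets):
            p = iv.start + int(off)
            if (iv.contig, p) not in taken:
                taken.add((iv.contig, p))
                site_list.append((iv.contig, p, "numt"))
    # ancestry-fixed sites on long contigs, outside NUMT intervals
    n_fixed_placed = 0
    while n_fixed_placed < config.n_ancestry_fixed_snps:
        cname = long_names[int(rng.integers(config.n_contigs))]
        p = int(rng.integers(1, contig_lengths[cname] + 1))
        if (cname, p) in taken:
            continue
        if annot.contains(np.array([cname]), np.array([p]))[0]:
            continue
        taken.add((cname, p))
        site_list.append((cname, p, "ancestry_fixed"))
        n_fixed_placed += 1

    site_list.sort(key=lambda t: (t[0], t[1]))
    n_sites = len(site_list)
    contig_arr = np.array([s[0] for s in site_list])
    pos_arr = np.array([s[1] for s in site_list], dtype=int)
    kind_arr = np.array([s[2] for s in site_list])

    # ancestral allele-frequency vectors for the two nuclear backgrounds
    base_freq = rng.uniform(0.05, 0.95, size=n_sites)
    shift = config.ancestral_freq_divergence * rng.choice([-1.0, 1.0], size=n_sites)
    freq_north = np.clip(base_freq + shift / 2.0, 0.01, 0.99)
    freq_south = np.clip(base_freq - shift / 2.0, 0.01, 0.99)

    p_sample = q_north[None, :] * freq_north[:, None] + (1 - q_north[None, :]) * freq_south[:, None]
    genotypes = rng.binomial(2, p_sample).astype(np.int8)

    south_idx = [i for i, s in enumerate(samples) if groups[s] == "southern"]
    north_idx = [i for i, s in enumerate(samples) if groups[s] == "northern"]
    planted = np.isin(kind_arr, ("numt", "ancestry_fixed"))
    genotypes[np.ix_(planted, south_idx)] = 2
    genotypes[np.ix_(planted, north_idx)] = 0

    bases = "ACGT"
    ref = rng.choice(list(bases), size=n_sites)
    alt = np.array([rng.choice([b for b in bases if b != r]) for r in ref])
    biallelic = np.ones(n_sites, dtype=bool)
    background = kind_arr == "background"
    tri = rng.random(n_sites) < config.non_biallelic_fraction
    biallelic[background & tri] = False

    depth = rng.poisson(20, size=(n_sites, n_samples)) + 3
    gq = rng.integers(30, 100, size=(n_sites, n_samples))
    low_q = rng.random((n_sites, n_samples)) < config.low_quality_call_fraction
    low_q[planted] = False  # planted truth survives the quality filter
    depth[low_q & (rng.random((n_sites, n_samples)) < 0.5)] = 1
    gq[low_q] = 10

    matrix = SNPMatrix(
        contig=contig_arr,
        pos=pos_arr,
        ref=ref,
        alt=alt,
        biallelic=biallelic,
        samples=samples,
        genotypes=genotypes,
        depth=depth,
        gq=gq,
        contig_lengths=contig_lengths,
        sample_groups=groups,
    )
    truth = {
        "numt_site_mask": kind_arr == "numt",
        "ancestry_fixed_mask": kind_arr == "ancestry_fixed",
        "sample_positions_km": sample_x,
        "admixture_north": q_north,
        "sample_groups": groups,
        "freq_north": freq_north,
        "freq_south": freq_south,
    }
    return matrix, annot, truth
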