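"""Variant-filtering cascade with tiered NUMT exclusion and fixed-SNP scan.

Nuclear copies of mitochondrial DNA (NUMTs) attract misaligned
mitochondrial reads and therefore yield SNPs that look perfectly fixed
between mitochondrial haplogroups while being artifacts of the
mitochondrial genome itself.  The cascade retains only high-confidence
nuclear SNPs:

1. quality filter — biallelic sites, per-call depth >= 3 and genotype
   quality >= 20 (failing calls set missing);
2. structural filter — drop sites on contigs < 20 kb and sites with any
   missing call;
3. tiered interval exclusion — assembly annotation intervals, homology
   hits against related-species mitochondrial genomes, and
   flank-verified members of the fixed-SNP scan;
4. fixed-SNP scan — sites completely fixed between two sample groups
   (e.g. southern vs. northern mitochondrial haplogroup carriers);
5. clustering diagnostics — inter-site distances among fixed SNPs,
   split by NUMT flag: genuine NUMT SNPs cluster tightly.

Intervals are 1-based closed internally (matching VCF positions); BED
I/O converts from 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

MISSING = -1  # genotype code; 0 hom-ref, 1 het, 2 hom-alt


class SNPError(ValueError):
    """Malformed genotype matrix or filter misuse."""


@dataclass
class SNPMatrix:
    """Biallelic-genotype matrix with per-call depth/quality metadata."""

    contig: np.ndarray  # (n_sites,) str
    pos: np.ndarray  # (n_sites,) int, 1-based
    ref: np.ndarray
    alt: np.ndarray
    biallelic: np.ndarray  # (n_sites,) bool
    samples: list[str]
    genotypes: np.ndarray  # (n_sites, n_samples) int8
    depth: np.ndarray  # (n_sites, n_samples) int
    gq: np.ndarray  # (n_sites, n_samples) int
    contig_lengths: dict = field(default_factory=dict)
    sample_groups: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_sites = len(self.pos)
        if self.genotypes.shape != (n_sites, len(self.samples)):
            raise SNPError("genotype matrix shape does not match sites x samples")
        for cname in np.unique(self.contig):
            p = self.pos[self.contig == cname]
            if np.any(np.diff(p) <= 0):
                raise SNPError(f"positions not strictly increasing on contig {cname}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def take_sites(self, mask: np.ndarray) -> "SNPMatrix":
        return replace(
            self,
            contig=self.contig[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            biallelic=self.biallelic[mask],
            genotypes=self.genotypes[mask],
            depth=self.depth[mask],
            gq=self.gq[mask],
        )


@dataclass(frozen=True)
class NUMTInterval:
    contig: str
    start: int  # 1-based closed
    end: int
    tier: str  # annotation | homology | fixed_scan
    note: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise SNPError(f"interval start {self.start} > end {self.end}")


@dataclass
class NUMTAnnotationSet:
    """Tiered exclusion intervals (1-based closed)."""

    intervals: list[NUMTInterval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.intervals)

    def contains(self, contig: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Boolean mask of (contig, pos) pairs falling in any interval."""
        mask = np.zeros(len(pos), dtype=bool)
        for iv in self.intervals:
            mask |= (contig == iv.contig) & (pos >= iv.start) & (pos <= iv.end)
        return mask

    @classmethod
    def read_bed(cls, path: str | Path, tier: str = "annotation") -> "NUMTAnnotationSet":
        intervals = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                name = parts[3] if len(parts) > 3 else ""
                # BED is 0-based half-open; internal is 1-based closed
                intervals.append(
                    NUMTInterval(parts[0], int(parts[1]) + 1, int(parts[2]), tier, name)
                )
        return cls(intervals)

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for iv in self.intervals:
                fh.write(f"{iv.contig}\t{iv.start - 1}\t{iv.end}\t{iv.tier}\n")


def quality_filter(m: SNPMatrix, min_depth: int = 3, min_gq: int = 20) -> SNPMatrix:
    """Keep biallelic sites; set calls with depth < 3 or GQ < 20 missing.

    Both thresholds are inclusive (depth >= min_depth, GQ >= min_gq
    pass).
    """
    m = m.take_sites(m.biallelic.astype(bool))
    geno = m.genotypes.copy()
    geno[(m.depth < min_depth) | (m.gq < min_gq)] = MISSING
    return replace(m, genotypes=geno)


def structural_filter(m: SNPMatrix, min_contig: int = 20_000, max_missing: int = 0) -> SNPMatrix:
    """Drop sites on short contigs and sites with missing calls.

    ``min_contig`` is inclusive (a 20 000 bp contig passes).  With the
    default ``max_missing=0`` a single missing call discards the site.
    """
    lengths = np.empty(m.n_sites)
    for i, cname in enumerate(m.contig):
        if cname not in m.contig_lengths:
            raise SNPError(f"contig length unknown for {cname}")
        lengths[i] = m.contig_lengths[cname]
    n_missing = np.sum(m.genotypes == MISSING, axis=1)
    return m.take_sites((lengths >= min_contig) & (n_missing <= max_missing))


def interval_exclude(m: SNPMatrix, annot: NUMTAnnotationSet) -> tuple[SNPMatrix, dict]:
    """Remove sites inside any annotation interval (1-based closed).

    Returns the filtered matrix and the count removed per tier.
    """
    removed_per_tier: dict[str, int] = {}
    overall = np.zeros(m.n_sites, dtype=bool)
    for tier in sorted({iv.tier for iv in annot.intervals}):
        sub = NUMTAnnotationSet([iv for iv in annot.intervals if iv.tier == tier])
        hit = sub.contains(m.contig, m.pos)
        removed_per_tier[tier] = int(np.sum(hit & ~overall))
        overall |= hit
    return m.take_sites(~overall), removed_per_tier


def region_exclude_color_locus(
    m: SNPMatrix, contig: str, start: int, end: int
) -> tuple[SNPMatrix, int]:
    """Exclude the color-locus interval so nuclear structure is color-free."""
    annot = NUMTAnnotationSet([NUMTInterval(contig, start, end, "color_locus")])
    out, removed = interval_exclude(m, annot)
    return out, removed.get("color_locus", 0)


@dataclass
class FixedSNPReport:
    """Sites fully fixed between two sample groups, with NUMT flags."""

    contig: np.ndarray
    pos: np.ndarray
    numt_flag: np.ndarray  # bool per fixed site
    group_a: list[str]
    group_b: list[str]

    @property
    def n_fixed(self) -> int:
        return len(self.pos)

    def per_contig_counts(self) -> dict:
        names, counts = np.unique(self.contig, return_counts=True)
        return dict(zip(names.tolist(), counts.tolist()))


def fixed_snp_scan(
    m: SNPMatrix,
    group_a: list[str],
    group_b: list[str],
    annot: NUMTAnnotationSet | None = None,
) -> FixedSNPReport:
    """Find sites fully fixed between two disjoint sample groups.

    A site is fixed iff every group-A sample is homozygous for one
    allele and every group-B sample homozygous for the other; a single
    heterozygous or missing call disqualifies the site.  If ``annot``
    is given, fixed sites inside its intervals are flagged as NUMTs.
    """
    if set(group_a) & set(group_b):
        raise SNPError("sample groups overlap")
    if not group_a or not group_b:
        raise SNPError("both groups must be non-empty")
    idx_a = [m.samples.index(s) for s in group_a]
    idx_b = [m.samples.index(s) for s in group_b]
    ga = m.genotypes[:, idx_a]
    gb = m.genotypes[:, idx_b]
    a_ref = np.all(ga == 0, axis=1)
    a_alt = np.all(ga == 2, axis=1)
    b_ref = np.all(gb == 0, axis=1)
    b_alt = np.all(gb == 2, axis=1)
    fixed = (a_ref & b_alt) | (a_alt & b_ref)
    contig = m.contig[fixed]
    pos = m.pos[fixed]
    if annot is not None and len(annot):
        flags = annot.contains(contig, pos)
    else:
        flags = np.zeros(len(pos), dtype=bool)
    return FixedSNPReport(contig=contig, pos=pos, numt_flag=flags,
                          group_a=list(group_a), group_b=list(group_b))


def numt_cluster_report(report: FixedSNPReport, close_bp: int = 1000) -> dict:
    """Clustering diagnostics for fixed SNPs: NUMTs sit in tight clusters.

    For consecutive fixed-site pairs within a contig, records the
    inter-site distance and whether either endpoint is NUMT-flagged,
    then summarizes the fraction of close pairs (< ``close_bp``)
    involving NUMTs and the median distances per class.
    """
    distances: list[int] = []
    involves_numt: list[bool] = []
    for cname in np.unique(report.contig):
        sel = report.contig == cname
        p = report.pos[sel]
        f = report.numt_flag[sel]
        order = np.argsort(p)
        p, f = p[order], f[order]
        for i in range(len(p) - 1):
            distances.append(int(p[i + 1] - p[i]))
            involves_numt.append(bool(f[i] or f[i + 1]))
    distances_arr = np.array(distances)
    numt_arr = np.array(involves_numt, dtype=bool)
    close = distances_arr < close_bp if len(distances_arr) else np.array([], dtype=bool)
    n_close = int(np.sum(close))
    out = {
        "per_contig_fixed_counts": report.per_contig_counts(),
        "n_fixed": report.n_fixed,
        "n_fixed_numt": int(np.sum(report.numt_flag)),
        "pair_distances": distances,
        "pair_involves_numt": involves_numt,
        "n_close_pairs": n_close,
        "close_pair_numt_fraction": (
            float(np.sum(close & numt_arr) / n_close) if n_close else 0.0
        ),
        "median_distance_numt_pairs": (
            float(np.median(distances_arr[numt_arr])) if np.any(numt_arr) else None
        ),
        "median_distance_non_numt_pairs": (
            float(np.median(distances_arr[~numt_arr])) if np.any(~numt_arr) else None
        ),
    }
    return out


# ---------------------------------------------------------------------------
# naive homology scanner (test-support stand-in for an external aligner)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def naive_homology_scan(
    reference: dict,
    queries: dict,
    k: int = 15,
    min_len: int = 60,
    min_identity: float = 0.8,
) -> NUMTAnnotationSet:
    """Exact-seed, ungapped-extension scan of mito queries against contigs.

    A deliberately simple matcher for synthetic tests: k-mer seeds
    (both strands of each query) anchor ungapped extensions that stop
    after three consecutive mismatches; hits shorter than ``min_len``
    or below ``min_identity`` are discarded, surviving hits on the same
    contig are merged when they overlap or touch.  With k = 15 the
    chance of a random seed match is 4^-15 per position, so random
    sequence yields essentially no hits.

    ``reference`` and ``queries`` map names to uppercase DNA strings.
    Returns 1-based closed intervals, tier ``homology``.
    """
    seeds: dict[str, bool] = {}
    for qseq in queries.values():
        qseq = qseq.upper()
        for strand_seq in (qseq, _revcomp(qseq)):
            for i in range(len(strand_seq) - k + 1):
                seeds[strand_seq[i : i + k]] = True

    raw_hits: dict[str, list[tuple[int, int]]] = {}
    for cname, cseq in reference.items():
        cseq = cseq.upper()
        hits: list[tuple[int, int]] = []
        i = 0
        n = len(cseq)
        while i <= n - k:
            kmer = cseq[i : i + k]
            if kmer in seeds:
                start, end = _extend(cseq, i, i + k - 1, seeds, k)
                length = end - start + 1
                if length >= min_len:
                    hits.append((start, end))
                    i = end + 1
                    continue
            i += 1
        if hits:
            raw_hits[cname] = hits

    intervals: list[NUMTInterval] = []
    for cname, hits in raw_hits.items():
        hits.sort()
        merged = [list(hits[0])]
        for s, e in hits[1:]:
            if s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            intervals.append(NUMTInterval(cname, s + 1, e + 1, "homology", "naive-scan"))
    return NUMTAnnotationSet(intervals)


def _extend(cseq: str, start: int, end: int, seeds: dict, k: int) -> tuple[int, int]:
    # grow the hit while consecutive reference k-mers keep matching the
    # query seed set; a 3-in-a-row miss terminates the extension
    misses = 0
    e = end
    while e + 1 < len(cseq) and misses < 3:
        nxt = cseq[e + 2 - k : e + 2]
        if len(nxt) == k and nxt in seeds:
            e += 1
            misses = 0
        else:
            e += 1
            misses += 1
    e -= misses
    misses = 0
    s = start
    while s > 0 and misses < 3:
        prv = cseq[s - 1 : s - 1 + k]
        if prv in seeds:
            s -= 1
            misses = 0
        else:
            s -= 1
            misses += 1
    s += misses
    return s, e


# ---------------------------------------------------------------------------
# VCF I/O

def write_vcf(m: SNPMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT:DP:GQ calls."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for cname in sorted(m.contig_lengths):
            fh.write(f"##contig=<ID={cname},length={m.contig_lengths[cname]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(m.samples) + "\n")
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for i in range(m.n_sites):
            calls = [
                f"{gt_str[int(m.genotypes[i, j])]}:{int(m.depth[i, j])}:{int(m.gq[i, j])}"
                for j in range(m.n_samples)
            ]
            fh.write(
                f"{m.contig[i]}\t{int(m.pos[i])}\t.\t{m.ref[i]}\t{m.alt[i]}\t.\tPASS\t.\t"
                "GT:DP:GQ\t" + "\t".join(calls) + "\n"
            )


def read_vcf(path: str | Path, sample_groups: dict | None = None) -> SNPMatrix:
    """Read a VCF with GT:DP:GQ calls via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    contig_lengths = dict(zip(vcf.seqnames, vcf.seqlens)) if vcf.seqlens else {}
    contigs, pos, ref, alt, biallelic = [], [], [], [], []
    genos, depths, gqs = [], [], []
    for var in vcf:
        contigs.append(var.CHROM)
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0] if var.ALT else ".")
        biallelic.append(len(var.ALT) == 1)
        row = np.full(len(samples), MISSING, dtype=np.int8)
        for j, g in enumerate(var.genotypes):
            a, b = g[0], g[1]
            if a >= 0 and b >= 0:
                row[j] = a + b
        genos.append(row)
        dp = var.format("DP")
        gq = var.format("GQ")
        depths.append(dp[:, 0] if dp is not None else np.zeros(len(samples), dtype=int))
        gqs.append(gq[:, 0] if gq is not None else np.zeros(len(samples), dtype=int))
    return SNPMatrix(
        contig=np.array(contigs),
        pos=np.array(pos, dtype=int),
        ref=np.array(ref),
        alt=np.array(alt),
        biallelic=np.array(biallelic, dtype=bool),
        samples=samples,
        genotypes=np.array(genos, dtype=np.int8),
        depth=np.array(depths, dtype=int),
        gq=np.array(gqs, dtype=int),
        contig_lengths=contig_lengths,
        sample_groups=sample_groups or {},
    )
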