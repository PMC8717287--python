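"""Alignment summaries, haplotype collapsing, and haplotype networks.

Works on aligned COI or color-locus sequences.  Provides variable and
parsimony-informative site counts, pairwise p-distance divergence,
inter-group fixed differences, a %-divergence to divergence-time
conversion, simple indel (gap) coding, and a reticulation-tolerant
minimum-spanning haplotype network in the spirit of statistical
parsimony networks: at shallow divergence (a handful of mutational
steps) the union of all minimum spanning trees yields the same
two-haplogroup topology while remaining exactly defined and cheap to
compute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
from Bio import SeqIO

GAP = "-"
MISSING = "N"
#: IUPAC codes representing heterozygous (two-state) or multi-state bases.
AMBIGUOUS = set("RYSWKMBDHV")


class AlignmentError(ValueError):
    """Malformed alignment or unusable request."""


@dataclass
class Alignment:
    """Equal-length uppercase sequences with ids and optional group labels."""

    ids: list[str]
    sequences: list[str]
    groups: dict = field(default_factory=dict)  # id -> group label

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentError("empty alignment")
        if len(self.ids) != len(self.sequences):
            raise AlignmentError("ids and sequences differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate sequence ids")
        L = len(self.sequences[0])
        if any(len(s) != L for s in self.sequences):
            raise AlignmentError("sequences are not aligned (unequal lengths)")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def __len__(self) -> int:
        return len(self.sequences)

    @classmethod
    def read_fasta(cls, path: str | Path, groups: dict | None = None) -> "Alignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        return cls(
            ids=[r.id for r in records],
            sequences=[str(r.seq) for r in records],
            groups=groups or {},
        )

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sid, seq in zip(self.ids, self.sequences):
                fh.write(f">{sid}\n{seq}\n")


def _site_states(aln: Alignment, col: int) -> list[str]:
    return [s[col] for s in aln.sequences]


def site_summary(aln: Alignment) -> dict:
    """Count variable and parsimony-informative sites.

    A site is variable if it carries >= 2 distinct states among
    unambiguous, non-gap, non-N bases; parsimony-informative if >= 2 of
    those states each occur in >= 2 sequences.
    """
    if len(aln) < 2:
        raise AlignmentError("need at least two sequences")
    n_var = n_pi = 0
    for col in range(aln.length):
        counts: dict[str, int] = {}
        for ch in _site_states(aln, col):
            if ch in (GAP, MISSING) or ch in AMBIGUOUS:
                continue
            counts[ch] = counts.get(ch, 0) + 1
        if len(counts) >= 2:
            n_var += 1
            if sum(1 for v in counts.values() if v >= 2) >= 2:
                n_pi += 1
    return {"n_variable": n_var, "n_parsimony_informative": n_pi}


def pairwise_divergence(seq_a: str, seq_b: str) -> float:
    """Percent p-distance over sites where both carry unambiguous bases."""
    if len(seq_a) != len(seq_b):
        raise AlignmentError("sequences differ in length")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    comparable = diffs = 0
    for a, b in zip(seq_a, seq_b):
        if a in (GAP, MISSING) or b in (GAP, MISSING) or a in AMBIGUOUS or b in AMBIGUOUS:
            continue
        comparable += 1
        if a != b:
            diffs += 1
    if comparable == 0:
        raise AlignmentError("no comparable sites between sequences")
    return 100.0 * diffs / comparable


def fixed_differences(aln: Alignment, group_a: str, group_b: str) -> int:
    """Sites where the two groups carry different, internally fixed states.

    Members with N or a gap at a site are ignored at that site; a single
    migrant carrying the other group's state breaks fixation.
    """
    idx_a = [i for i, sid in enumerate(aln.ids) if aln.groups.get(sid) == group_a]
    idx_b = [i for i, sid in enumerate(aln.ids) if aln.groups.get(sid) == group_b]
    if not idx_a or not idx_b:
        raise AlignmentError(f"group label {group_a!r} or {group_b!r} absent")
    n_fixed = 0
    for col in range(aln.length):
        states_a = {
            aln.sequences[i][col]
            for i in idx_a
            if aln.sequences[i][col] not in (GAP, MISSING)
        }
        states_b = {
            aln.sequences[i][col]
            for i in idx_b
            if aln.sequences[i][col] not in (GAP, MISSING)
        }
        if len(states_a) == 1 and len(states_b) == 1 and states_a != states_b:
            n_fixed += 1
    return n_fixed


def divergence_time(divergence_percent: float, rate_percent_per_myr: float = 1.5) -> float:
    """Convert % sequence divergence to millions of years: T = d / rate."""
    if rate_percent_per_myr <= 0:
        raise AlignmentError("substitution rate must be positive")
    return divergence_percent / rate_percent_per_myr


@dataclass
class Haplotype:
    sequence: str
    member_ids: list[str]
    gap_states: tuple = ()

    @property
    def count(self) -> int:
        return len(self.member_ids)


def collapse_haplotypes(
    aln: Alignment, exclude_heterozygous: bool = False
) -> tuple[list[Haplotype], list[str]]:
    """Merge identical sequences into haplotypes.

    Sequences identical over non-N sites merge (N acts as a wildcard;
    the representative keeps the resolved base).  With
    ``exclude_heterozygous`` any sequence carrying an IUPAC
    heterozygous/ambiguity code is dropped and reported — used for the
    diploid color locus where such codes mark heterozygous individuals.

    Returns (haplotypes, excluded ids).
    """
    if len(aln) == 0:
        raise AlignmentError("empty alignment")
    excluded: list[str] = []
    haplotypes: list[Haplotype] = []
    for sid, seq in zip(aln.ids, aln.sequences):
        if exclude_heterozygous and any(ch in AMBIGUOUS for ch in seq):
            excluded.append(sid)
            continue
        merged = False
        for hap in haplotypes:
            if _compatible(hap.sequence, seq):
                hap.sequence = _resolve(hap.sequence, seq)
                hap.member_ids.append(sid)
                merged = True
                break
        if not merged:
            haplotypes.append(Haplotype(sequence=seq, member_ids=[sid]))
    return haplotypes, excluded


def _compatible(a: str, b: str) -> bool:
    return all(x == y or x == MISSING or y == MISSING for x, y in zip(a, b))


def _resolve(a: str, b: str) -> str:
    return "".join(y if x == MISSING else x for x, y in zip(a, b))


def code_gaps(aln: Alignment) -> dict:
    """Simple indel coding: one binary character per distinct gap run.

    Each maximal run of ``-`` with identical start/end across sequences
    becomes one presence/absence character; a sequence scores 1 when it
    carries exactly that run.  Returns the character boundary list and
    the per-sequence state matrix.
    """
    runs_per_seq: list[set[tuple[int, int]]] = []
    all_runs: set[tuple[int, int]] = set()
    for seq in aln.sequences:
        runs: set[tuple[int, int]] = set()
        start = None
        for i, ch in enumerate(seq + "X"):  # sentinel terminates a trailing run
            if ch == GAP and start is None:
                start = i
            elif ch != GAP and start is not None:
                runs.add((start, i - 1))
                start = None
        runs_per_seq.append(runs)
        all_runs |= runs
    characters = sorted(all_runs)
    matrix = [
        [1 if run in runs else 0 for run in characters] for runs in runs_per_seq
    ]
    return {"characters": characters, "matrix": matrix, "ids": list(aln.ids)}


def hamming_distance(hap_a: Haplotype, hap_b: Haplotype) -> int:
    """Mutational steps between haplotypes.

    Substitution differences over sites where both carry concrete
    states (identical ambiguity codes match; any other code/base pair
    mismatches; N or gap at either -> site skipped) plus one step per
    differing gap-coded character.
    """
    steps = 0
    for a, b in zip(hap_a.sequence, hap_b.sequence):
        if a in (GAP, MISSING) or b in (GAP, MISSING):
            continue
        if a != b:
            steps += 1
    steps += sum(1 for ga, gb in zip(hap_a.gap_states, hap_b.gap_states) if ga != gb)
    return steps


def attach_gap_characters(haplotypes: list[Haplotype]) -> None:
    """Populate each haplotype's gap-coded character states in place."""
    aln = Alignment(
        ids=[f"h{i}" for i in range(len(haplotypes))],
        sequences=[h.sequence for h in haplotypes],
    )
    coded = code_gaps(aln)
    for hap, states in zip(haplotypes, coded["matrix"]):
        hap.gap_states = tuple(states)


def build_msn(
    haplotypes: list[Haplotype], groups: dict | None = None
) -> nx.Graph:
    """Minimum-spanning haplotype network with tie retention.

    An edge belongs to the network iff it belongs to at least one
    minimum spanning tree of the complete haplotype graph (cut
    property: edge (u, v, d) is MST-eligible iff u and v lie in
    different components of the subgraph restricted to edges with
    distance < d).  Tied alternative connections are therefore kept,
    giving the reticulations a statistical-parsimony network would
    show.  Edges are annotated with the step count ``d`` and the
    ``d - 1`` implied unsampled intermediates.
    """
    if not haplotypes:
        raise AlignmentError("no haplotypes")
    groups = groups or {}
    g = nx.Graph()
    for i, hap in enumerate(haplotypes):
        comp: dict[str, int] = {}
        for sid in hap.member_ids:
            label = groups.get(sid, "")
            comp[label] = comp.get(label, 0) + 1
        g.add_node(i, sequence=hap.sequence, count=hap.count,
                   member_ids=list(hap.member_ids), group_composition=comp)
    n = len(haplotypes)
    if n == 1:
        return g
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            edges.append((hamming_distance(haplotypes[i], haplotypes[j]), i, j))
    edges.sort()
    # process in weight tiers: an edge is kept iff its endpoints are in
    # different components of the strictly-lighter subgraph
    uf = list(range(n))

    def find(a: int) -> int:
        while uf[a] != a:
            uf[a] = uf[uf[a]]
            a = uf[a]
        return a

    k = 0
    while k < len(edges):
        d = edges[k][0]
        tier = []
        while k < len(edges) and edges[k][0] == d:
            tier.append(edges[k])
            k += 1
        keep = [(i, j) for _, i, j in tier if find(i) != find(j)]
        for i, j in keep:
            g.add_edge(i, j, distance=d, intermediate_steps=max(0, d - 1))
        for i, j in keep:
            ri, rj = find(i), find(j)
            if ri != rj:
                uf[ri] = rj
    return g


def write_network_tsv(g: nx.Graph, path: str | Path) -> None:
    """Edge list with node annotations as a plain TSV."""
    with open(path, "w") as fh:
        fh.write("# nodes\n")
        fh.write("node\tcount\tmembers\tgroups\n")
        for node, data in g.nodes(data=True):
            comp = ",".join(f"{k}:{v}" for k, v in sorted(data["group_composition"].items()))
            fh.write(f"{node}\t{data['count']}\t{','.join(data['member_ids'])}\t{comp}\n")
        fh.write("# edges\n")
        fh.write("node_a\tnode_b\tdistance\tintermediate_steps\n")
        for u, v, data in g.edges(data=True):
            fh.write(f"{u}\t{v}\t{data['distance']}\t{data['intermediate_steps']}\n")
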