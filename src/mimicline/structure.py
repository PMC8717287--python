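"""Nuclear population structure from filtered SNPs.

Distances, neighbor joining, LD pruning, PCA, and ancestry proportions
by simplex-constrained non-negative matrix factorization with
cross-entropy K selection (an sNMF-style analysis: the Q matrix rows
are per-sample ancestry proportions, and the number of ancestral
populations K is chosen by the minimum mean cross-entropy of masked
genotype entries predicted from the factorization).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mimicline.snp_filter import MISSING, SNPMatrix
from mimicline.specimen_io import SpecimenTable


class StructureError(ValueError):
    """Unusable input for a structure analysis."""


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise StructureError("distance matrix shape mismatch")
        if not np.allclose(v, v.T) or np.any(np.diag(v) != 0) or np.any(v < 0):
            raise StructureError("distance matrix must be symmetric, non-negative, zero-diagonal")


def genotype_distance(m: SNPMatrix) -> DistanceMatrix:
    """Allele-sharing distance: mean |dosage_i - dosage_j| / 2 over shared sites."""
    if m.n_samples < 2:
        raise StructureError("need at least 2 samples")
    g = m.genotypes.astype(float)
    g[m.genotypes == MISSING] = np.nan
    n = m.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = np.abs(g[:, i] - g[:, j]) / 2.0
            valid = ~np.isnan(diff)
            if not np.any(valid):
                raise StructureError(
                    f"samples {m.samples[i]} and {m.samples[j]} share no called sites"
                )
            d[i, j] = d[j, i] = float(np.mean(diff[valid]))
    return DistanceMatrix(ids=list(m.samples), values=d)


# ---------------------------------------------------------------------------
# neighbor joining


@dataclass
class TreeNode:
    """Minimal unrooted-tree node; children carry branch lengths."""

    name: str = ""
    children: list = field(default_factory=list)  # (TreeNode, branch_length)

    def newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if not self.children:
            return self.name
        inner = ",".join(f"{c._newick()}:{bl:.6f}" for c, bl in self.children)
        return f"({inner}){self.name}"

    def leaf_names(self) -> list[str]:
        if not self.children:
            return [self.name]
        out = []
        for c, _ in self.children:
            out.extend(c.leaf_names())
        return out

    def tip_distances(self) -> dict:
        """Path lengths between all leaf pairs (for additivity checks)."""
        paths: dict[str, dict[str, float]] = {}

        def walk(node: TreeNode, dist_to_here: dict):
            if not node.children:
                for other, d in dist_to_here.items():
                    paths.setdefault(other, {})[node.name] = d
                    paths.setdefault(node.name, {})[other] = d
                dist_to_here = {**dist_to_here, node.name: 0.0}
            for c, bl in node.children:
                walk(c, {k: v + bl for k, v in dist_to_here.items()})

        # accumulate leaf-to-leaf distances by rooting the walk here
        leaves = self.leaf_names()

        def collect(node: TreeNode) -> dict:
            if not node.children:
                return {node.name: 0.0}
            below: dict[str, float] = {}
            child_maps = []
            for c, bl in node.children:
                cm = {k: v + bl for k, v in collect(c).items()}
                child_maps.append(cm)
            for a_i in range(len(child_maps)):
                for b_i in range(a_i + 1, len(child_maps)):
                    for la, da in child_maps[a_i].items():
                        for lb, db in child_maps[b_i].items():
                            paths.setdefault(la, {})[lb] = da + db
                            paths.setdefault(lb, {})[la] = da + db
                below = {k: v for cm in child_maps for k, v in cm.items()}
            return below

        collect(self)
        return {a: paths.get(a, {}) for a in leaves}


def neighbor_joining(d: DistanceMatrix, outgroup: str | None = None) -> TreeNode:
    """Saitou–Nei neighbor joining with the Studier–Keppler criterion.

    Ties in the Q criterion break toward the smallest (i, j) index pair
    in the current node ordering; negative branch lengths are clamped
    to zero with the deficit transferred to the sibling branch.  With
    ``outgroup`` the returned (still logically unrooted) tree is
    arranged so the outgroup is the first child of the root
    trifurcation.
    """
    n = len(d.ids)
    if n < 3:
        raise StructureError("neighbor joining needs at least 3 samples")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in d.ids]
    dist = d.values.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        sub = dist[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        q = (r - 2) * sub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest (i, j) pair on ties: lexicographic scan of the min set
        qmin = np.min(q)
        ii, jj = min(
            (a, b)
            for a in range(r)
            for b in range(a + 1, r)
            if q[a, b] == qmin
        )
        i_g, j_g = active[ii], active[jj]
        dij = sub[ii, jj]
        li = 0.5 * dij + (row_sums[ii] - row_sums[jj]) / (2 * (r - 2))
        lj = dij - li
        if li < 0:
            lj += -li  # transfer the deficit to the sibling edge
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        parent = TreeNode(children=[(nodes[i_g], li), (nodes[j_g], lj)])
        new_row = np.zeros(dist.shape[0] + 1)
        for kk in range(r):
            k_g = active[kk]
            if k_g in (i_g, j_g):
                continue
            new_row[k_g] = 0.5 * (dist[i_g, k_g] + dist[j_g, k_g] - dij)
        dist = np.pad(dist, ((0, 1), (0, 1)))
        dist[-1, : len(new_row)] = new_row
        dist[: len(new_row), -1] = new_row
        nodes.append(parent)
        active = [a for a in active if a not in (i_g, j_g)] + [len(nodes) - 1]

    a, b, c = active
    # final trifurcation: each branch length from the three-point formula
    la = 0.5 * (dist[a, b] + dist[a, c] - dist[b, c])
    lb = 0.5 * (dist[a, b] + dist[b, c] - dist[a, c])
    lc = 0.5 * (dist[a, c] + dist[b, c] - dist[a, b])
    branches = [(nodes[a], max(la, 0.0)), (nodes[b], max(lb, 0.0)), (nodes[c], max(lc, 0.0))]
    root = TreeNode(children=branches)
    if outgroup is not None:
        if outgroup not in d.ids:
            raise StructureError(f"outgroup {outgroup!r} not among samples")
        root.children.sort(key=lambda cb: 0 if outgroup in cb[0].leaf_names() else 1)
    return root


# ---------------------------------------------------------------------------
# LD pruning, PCA


def ld_prune(m: SNPMatrix, r2_max: float = 0.5, window: int = 5000) -> SNPMatrix:
    """Greedy keep-first LD pruning within a bp window.

    Scanning left to right, a site is dropped when its squared dosage
    correlation with any already-kept site within ``window`` bp on the
    same contig exceeds ``r2_max`` (strictly; a pair at exactly the
    bound is kept, as is a perfectly correlated pair just outside the
    window).  No retained pair can violate the bound.
    """
    keep = np.zeros(m.n_sites, dtype=bool)
    g = m.genotypes.astype(float)
    g[m.genotypes == MISSING] = np.nan
    kept_by_contig: dict[str, list[int]] = {}
    for i in range(m.n_sites):
        cname = m.contig[i]
        drop = False
        for j in reversed(kept_by_contig.get(cname, [])):
            if m.pos[i] - m.pos[j] > window:
                break
            # 1e-12 guard: corrcoef rounding must not flip the strict bound
            if _r2(g[i], g[j]) > r2_max + 1e-12:
                drop = True
                break
        if not drop:
            keep[i] = True
            kept_by_contig.setdefault(cname, []).append(i)
    return m.take_sites(keep)


def _r2(a: np.ndarray, b: np.ndarray) -> float:
    valid = ~(np.isnan(a) | np.isnan(b))
    a, b = a[valid], b[valid]
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass
class PCAResult:
    scores: np.ndarray  # samples x components
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray  # sites x components


def pca(m: SNPMatrix, n_components: int = 2) -> PCAResult:
    """PCA of the column-centered dosage matrix (samples x sites).

    Requires complete data (run the structural filter first).  The sign
    of each component is fixed so its largest-magnitude loading is
    positive, making scores deterministic.
    """
    if np.any(m.genotypes == MISSING):
        raise StructureError("PCA requires no missing genotypes")
    x = m.genotypes.T.astype(float)  # samples x sites
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int(np.sum(s > 1e-10))
    if n_components > rank:
        raise StructureError(f"requested {n_components} components but rank is {rank}")
    total_var = float(np.sum(s**2)) / (x.shape[0] - 1)
    scores = u[:, :n_components] * s[:n_components]
    loadings = vt[:n_components].T
    for comp in range(n_components):
        jmax = int(np.argmax(np.abs(loadings[:, comp])))
        if loadings[jmax, comp] < 0:
            loadings[:, comp] *= -1
            scores[:, comp] *= -1
    ev = s[:n_components] ** 2 / (x.shape[0] - 1)
    return PCAResult(
        scores=scores,
        explained_variance=ev,
        explained_variance_ratio=ev / total_var if total_var > 0 else ev,
        loadings=loadings,
    )


# ---------------------------------------------------------------------------
# sNMF-style ancestry


@dataclass
class AncestryResult:
    K: int
    Q: np.ndarray  # samples x K, rows on the simplex
    G: np.ndarray  # K x sites allele frequencies
    cross_entropy: dict  # K -> mean held-out cross-entropy
    selected_K: int
    sample_ids: list[str] = field(default_factory=list)


def _nmf_fit(
    x: np.ndarray,
    w: np.ndarray,
    K: int,
    rng: np.random.Generator,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Alternating constrained least squares for X ~ Q G.

    Q rows live on the simplex (solved per sample by non-negative least
    squares with a penalty row enforcing the sum-to-one constraint); G
    entries are allele frequencies in [0, 1] (batched per-site ridge
    solve, clipped).  Masked entries (w = 0) are excluded from both
    updates.
    """
    from scipy.optimize import nnls

    n, p = x.shape
    q = rng.random((n, K)) + 0.1
    q /= q.sum(axis=1, keepdims=True)
    g = rng.random((K, p)) * 0.8 + 0.1
    penalty = 10.0
    prev = np.inf
    for _ in range(max_iter):
        # G-step: per-site normal equations sum_i w_is q_i q_i^T g_s = ...
        a = np.einsum("is,ik,il->skl", w, q, q) + 1e-9 * np.eye(K)
        b = np.einsum("is,ik,is->sk", w, q, x)
        g = np.clip(np.linalg.solve(a, b[..., None])[..., 0].T, 1e-6, 1.0)
        # Q-step: per-sample NNLS with the simplex enforced by a penalty row
        gt = g.T  # p x K
        for i in range(n):
            rows = w[i] > 0
            a_i = np.vstack([gt[rows], penalty * np.ones((1, K))])
            b_i = np.concatenate([x[i, rows], [penalty]])
            sol, _ = nnls(a_i, b_i)
            s = sol.sum()
            q[i] = sol / s if s > 0 else 1.0 / K
        obj = float(np.sum(w * (x - q @ g) ** 2))
        if prev - obj < tol * max(prev, 1.0):
            break
        prev = obj
    return q, g


def _cross_entropy(x: np.ndarray, pred: np.ndarray, mask: np.ndarray) -> float:
    p = np.clip(pred[mask], 1e-6, 1.0 - 1e-6)
    d = x[mask]
    return float(-np.mean(d * np.log(p) + (1.0 - d) * np.log1p(-p)))


def nmf_admixture(
    m: SNPMatrix,
    k_range=range(1, 11),
    seed: int = 0,
    n_restarts: int = 10,
    masked_fraction: float = 0.05,
    max_iter: int = 500,
) -> AncestryResult:
    """Ancestry proportions via simplex-constrained NMF, K by cross-entropy.

    The dosage/2 matrix is factorized as Q G (Q: samples x K ancestry
    proportions on the simplex; G: K x sites ancestral allele
    frequencies in [0, 1]) by masked multiplicative updates.  A random
    5% of entries is held out; the mean held-out cross-entropy over
    ``n_restarts`` restarts scores each K and the minimizer is
    selected.  The returned Q/G come from the best restart at the
    selected K.
    """
    if np.any(m.genotypes == MISSING):
        raise StructureError("admixture estimation requires no missing genotypes")
    k_range = list(k_range)
    if max(k_range) > m.n_samples:
        raise StructureError("K cannot exceed the number of samples")
    x = m.genotypes.T.astype(float) / 2.0  # samples x sites in [0, 1]
    rng = np.random.default_rng(seed)
    mask = rng.random(x.shape) < masked_fraction  # held out
    w = (~mask).astype(float)

    ce_by_k: dict[int, float] = {}
    best_by_k: dict[int, tuple[float, np.ndarray, np.ndarray]] = {}
    for K in k_range:
        ces = []
        best = None
        for _ in range(n_restarts):
            q, g = _nmf_fit(x, w, K, rng, max_iter=max_iter)
            ce = _cross_entropy(x, q @ g, mask)
            ces.append(ce)
            if best is None or ce < best[0]:
                best = (ce, q, g)
        ce_by_k[K] = float(np.mean(ces))
        best_by_k[K] = best
    selected = min(ce_by_k, key=lambda K: ce_by_k[K])
    _, q, g = best_by_k[selected]
    return AncestryResult(
        K=selected,
        Q=q,
        G=g,
        cross_entropy=ce_by_k,
        selected_K=selected,
        sample_ids=list(m.samples),
    )


def nuclear_cline_input(
    result: AncestryResult, table: SpecimenTable, cluster: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample (transect_km, ancestry proportion) pairs for cline fitting.

    ``cluster`` indexes the ancestral population (0-based column of Q)
    whose proportion becomes the continuous trait for a gaussian cline.
    """
    by_id = {r.id: r for r in table}
    xs, qs = [], []
    for sid, row in zip(result.sample_ids, result.Q):
        if sid not in by_id:
            raise StructureError(f"sample {sid!r} has no specimen record")
        xs.append(by_id[sid].transect_km)
        qs.append(float(row[cluster]))
    return np.array(xs), np.array(qs)
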