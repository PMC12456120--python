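"""Population structure from genotype likelihoods: LD pruning, PCA,
admixture proportions, genetic distances and neighbour-joining trees.

All operations run on posterior mean genotypes (dosages) or directly on
the likelihoods; no genotypes are ever hard-called.  The PCA covariance
is the standard frequency-standardised form

    C_ij = (1/S) sum_s (d_is - 2 f_s)(d_js - 2 f_s) / (2 f_s (1 - f_s))

over polymorphic sites, with d the Hardy-Weinberg posterior dosage.
Admixture proportions are estimated by the classical likelihood EM with
individual allele frequencies h_is = sum_k q_ik F_sk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import glcore

NEI_DISTANCE_CAP = 50.0


@dataclass
class TreeNode:
    """Recursive tree node; leaves carry a label, internal nodes children."""

    label: str | None = None
    children: list = field(default_factory=list)  # list of (TreeNode, branch_length)

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.label]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def to_newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if not self.children:
            return str(self.label)
        inner = ",".join(f"{c._newick()}:{bl:.6g}" for c, bl in self.children)
        return f"({inner})"


@dataclass
class AdmixtureFit:
    Q: np.ndarray  # individuals x K
    F: np.ndarray  # sites x K
    loglik: float
    K: int
    loglik_path: np.ndarray


def ld_prune(
    dosages: np.ndarray,
    window: int = 100,
    step: int = 5,
    vif: float = 2.0,
) -> np.ndarray:
    """Greedy LD pruning on dosage r^2 in sliding SNP windows.

    Within each window of ``window`` SNPs (advancing by ``step``), the
    site with the largest summed offending r^2 is removed until all
    remaining pairs satisfy r^2 < 1 - 1/vif (vif = 2 gives r^2 < 0.5);
    on ties the lowest-index site is kept.  Passes repeat until no site
    is removed, which makes the operation idempotent.  Sites must be
    ordered by scaffold and position.  Returns kept site indices.
    """
    d = np.asarray(dosages, dtype=np.float64)
    S = d.shape[0]
    thr = 1.0 - 1.0 / vif
    kept = np.arange(S)
    while True:
        removed_any = False
        keep_mask = np.ones(len(kept), dtype=bool)
        n = len(kept)
        start = 0
        while start < n:
            win = [i for i in range(start, min(start + window, n)) if keep_mask[i]]
            if len(win) > 1:
                sub = d[kept[win]]
                with np.errstate(invalid="ignore", divide="ignore"):
                    r = np.corrcoef(sub)
                r2 = np.nan_to_num(r, nan=0.0) ** 2
                np.fill_diagonal(r2, 0.0)
                while True:
                    offend = r2 >= thr
                    if not offend.any():
                        break
                    load = (r2 * offend).sum(axis=1)
                    # remove the most-entangled site; on exact ties drop the later one
                    worst = int(np.flatnonzero(load == load.max())[-1])
                    keep_mask[win[worst]] = False
                    removed_any = True
                    r2[worst, :] = 0.0
                    r2[:, worst] = 0.0
            if start + window >= n:
                break
            start += step
        kept = kept[keep_mask]
        if not removed_any:
            break
    return kept


def pca_covariance(gl: np.ndarray, f_hat: np.ndarray):
    """Frequency-standardised covariance, eigenvalues and PC scores.

    Only polymorphic sites (0 < f < 1) enter.  Eigenvectors are sorted
    by descending eigenvalue; each has its largest-magnitude loading
    forced positive so results are deterministic.

    Returns (C, eigenvalues, scores) with scores = eigenvectors (N x N).
    """
    f = np.asarray(f_hat, dtype=np.float64)
    poly = (f > 0) & (f < 1)
    if not poly.any():
        raise glcore.EstimationError("all sites monomorphic; PCA undefined")
    d = glcore.posterior_dosage(np.asarray(gl)[poly], f[poly])
    fp = f[poly]
    centred = d - 2 * fp[:, None]
    norm = 2 * fp * (1 - fp)
    C = (centred.T / norm) @ centred / poly.sum()
    C = (C + C.T) / 2.0
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    for k in range(vecs.shape[1]):
        j = np.argmax(np.abs(vecs[:, k]))
        if vecs[j, k] < 0:
            vecs[:, k] = -vecs[:, k]
    return C, vals, vecs


def _admixture_loglik(gln, Q, F):
    h = Q @ F.T  # individuals x sites
    h = np.clip(h, 1e-9, 1 - 1e-9)
    prior = np.stack([(1 - h) ** 2, 2 * h * (1 - h), h**2], axis=-1)  # N x S x 3
    lik = np.einsum("snG,nsG->ns", gln, prior)
    return float(np.log(np.maximum(lik, 1e-300)).sum()), h


def admixture_em(
    gl: np.ndarray,
    K: int,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 300,
    n_restarts: int = 3,
) -> AdmixtureFit:
    """Admixture proportions and cluster allele frequencies by EM.

    Maximises sum_{s,i} log sum_g GL_isg P(g | h_is) with h_is =
    sum_k q_ik F_sk under Hardy-Weinberg.  Runs ``n_restarts`` seeded
    initialisations and keeps the best log-likelihood.  Q rows sum to 1.
    """
    gl = np.asarray(gl, dtype=np.float64)
    S, N, _ = gl.shape
    if K < 1:
        raise glcore.ParameterError("K must be >= 1")
    if K > N:
        raise glcore.ParameterError("K cannot exceed the number of individuals")
    gln = glcore.normalise_gl(gl)
    best = None
    for r in range(n_restarts):
        rng = np.random.default_rng((seed, r))
        Q = rng.dirichlet(np.ones(K), size=N)
        F = rng.uniform(0.05, 0.95, size=(S, K))
        if K == 1:
            Q = np.ones((N, 1))
        path = []
        ll_prev = -np.inf
        for _ in range(max_iter):
            h = np.clip(Q @ F.T, 1e-9, 1 - 1e-9)  # N x S
            prior = np.stack([(1 - h) ** 2, 2 * h * (1 - h), h**2], axis=-1)
            post = np.swapaxes(gln, 0, 1) * prior  # N x S x 3
            post /= np.maximum(post.sum(axis=-1, keepdims=True), 1e-300)
            e = post[..., 1] + 2 * post[..., 2]  # expected minor alleles, N x S
            # attribute allele copies to clusters
            a = Q[:, None, :] * F[None, :, :] / h[..., None]  # N x S x K
            b = Q[:, None, :] * (1 - F)[None, :, :] / (1 - h)[..., None]
            A = np.einsum("ns,nsk->sk", e, a)  # minor copies per site/cluster
            B = np.einsum("ns,nsk->sk", 2 - e, b)
            F = np.clip(A / np.maximum(A + B, 1e-12), 1e-6, 1 - 1e-6)
            if K > 1:
                Qnew = (np.einsum("ns,nsk->nk", e, a) + np.einsum("ns,nsk->nk", 2 - e, b)) / (2 * S)
                Q = Qnew / Qnew.sum(axis=1, keepdims=True)
            ll, _ = _admixture_loglik(gln, Q, F)
            path.append(ll)
            if ll - ll_prev < tol and np.isfinite(ll_prev):
                break
            ll_prev = ll
        fit = AdmixtureFit(Q=Q, F=F, loglik=path[-1], K=K, loglik_path=np.array(path))
        if best is None or fit.loglik > best.loglik:
            best = fit
    return best


def distance_matrix(data: np.ndarray, method: str) -> np.ndarray:
    """Pairwise distances between groups or individuals.

    ``nei_groups``: data is a (G, S) matrix of group allele-frequency
    vectors; D = -ln( sum p1 p2 / sqrt(sum p1^2 sum p2^2) ), capped at
    50 (with a warning) when the identity is zero.
    ``covariance_individuals``: data is an (N, N) covariance; D_ij =
    C_ii + C_jj - 2 C_ij, floored at 0.
    """
    data = np.asarray(data, dtype=np.float64)
    if method == "nei_groups":
        G = data.shape[0]
        D = np.zeros((G, G))
        norms = (data**2).sum(axis=1)
        for i in range(G):
            for j in range(i + 1, G):
                cross = float(data[i] @ data[j])
                denom = np.sqrt(norms[i] * norms[j])
                if denom == 0 or cross <= 0:
                    warnings.warn("zero genetic identity; capping Nei distance")
                    D[i, j] = D[j, i] = NEI_DISTANCE_CAP
                else:
                    D[i, j] = D[j, i] = min(-np.log(cross / denom), NEI_DISTANCE_CAP)
        return D
    if method == "covariance_individuals":
        C = data
        diag = np.diag(C)
        D = diag[:, None] + diag[None, :] - 2 * C
        np.fill_diagonal(D, 0.0)
        return np.maximum(D, 0.0)
    raise glcore.ParameterError(f"unknown distance method {method!r}")


def nj_tree(D: np.ndarray, labels) -> TreeNode:
    """Saitou-Nei neighbour joining with deterministic tie-breaking.

    Negative branch lengths are floored at zero with a warning; Q-matrix
    ties resolve to the lowest index pair.  Returns the root TreeNode
    (use ``.to_newick()`` for serialisation).
    """
    D = np.asarray(D, dtype=np.float64)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise glcore.ParameterError("distance matrix must be square and symmetric")
    n = D.shape[0]
    if n < 3:
        raise glcore.ParameterError("need at least 3 taxa")
    nodes = [TreeNode(label=str(l)) for l in labels]
    D = D.copy()
    active = list(range(n))

    def _branch(bl):
        if bl < 0:
            warnings.warn("negative NJ branch length floored at 0")
            return 0.0
        return float(bl)

    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        R = sub.sum(axis=1)
        Q = (m - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = np.argmin(Q)  # argmin returns the first minimum: lowest index pair
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (R[i] - R[j]) / (2 * (m - 2))
        lj = dij - li
        new = TreeNode(
            children=[(nodes[active[i]], _branch(li)), (nodes[active[j]], _branch(lj))]
        )
        dnew = 0.5 * (sub[i, :] + sub[j, :] - dij)
        gi, gj = active[i], active[j]
        D[gi, :] = 0.0
        D[:, gi] = 0.0
        for pos, a in enumerate(active):
            D[gi, a] = D[a, gi] = dnew[pos]
        D[gi, gi] = 0.0
        nodes[gi] = new
        active.pop(j)
    a, b = active
    bl = _branch(D[a, b])
    # attach the final edge at the internal node so the unrooted tree keeps
    # its true branch lengths (trifurcating root, standard NJ output)
    if nodes[a].children:
        root = nodes[a]
        root.children.append((nodes[b], bl))
    elif nodes[b].children:
        root = nodes[b]
        root.children.append((nodes[a], bl))
    else:
        root = TreeNode(children=[(nodes[a], bl / 2), (nodes[b], bl / 2)])
    return root
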