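"""Genotype-likelihood core: GL model, site filtering, major/minor
assignment, allele-frequency EM and SNP calling.

All downstream stages of the pipeline operate on the data produced here.
Genotype likelihoods follow the standard two-term read mixture for a
diploid genotype ``g`` copies of the minor allele under a single global
per-base error rate ``eps``:

    P(read = minor | g) = (g/2)(1 - eps) + ((2 - g)/2)(eps/3)

Likelihood triples are stored scaled so the per-(site, individual)
maximum equals 1 (the Beagle convention); a missing individual is an
all-equal triple.  Allele-frequency estimation is the classical EM under
a Hardy-Weinberg prior; the SNP test is a 1-df likelihood-ratio test of
``f = f_hat`` against ``f = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

ALLELES = np.array(["A", "C", "G", "T"])
ALLELE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

#: genotype minor-allele copy numbers
GENOTYPES = np.array([0, 1, 2])

DEFAULT_ERROR_RATE = 0.01
DEFAULT_EM_TOL = 1e-6
DEFAULT_EM_MAX_ITER = 100
DEFAULT_EM_START = 0.2  # any interior point works; fixed for reproducibility
DEFAULT_SNP_PVAL = 1e-6
DEFAULT_MIN_MAF = 0.05


class ParameterError(ValueError):
    """Invalid model parameter."""


class EstimationError(RuntimeError):
    """Estimation impossible (e.g. all individuals missing)."""


@dataclass
class FreqEstimate:
    """Per-site minor-allele frequency estimate from the EM."""

    f_hat: float
    loglik: float
    n_used: int


def _check_eps(eps: float) -> None:
    if not (0.0 < eps < 0.5):
        raise ParameterError(f"error rate must be in (0, 0.5), got {eps}")


def gl_from_counts(n_major, n_minor, eps: float = DEFAULT_ERROR_RATE) -> np.ndarray:
    """Genotype-likelihood triples from major/minor read counts.

    Parameters
    ----------
    n_major, n_minor
        Read counts supporting the major and the minor allele.  Scalars
        or arrays of any (broadcastable) shape; reads of neither allele
        are assumed to have been dropped upstream.
    eps
        Per-base error rate.

    Returns
    -------
    ndarray with one trailing axis of length 3, the likelihoods of
    g = 0, 1, 2 minor-allele copies scaled so the maximum is 1.  A
    (0, 0) count pair yields the flat triple (1, 1, 1).
    """
    _check_eps(eps)
    n_major = np.asarray(n_major, dtype=np.float64)
    n_minor = np.asarray(n_minor, dtype=np.float64)
    # per-read probabilities of observing the minor allele for g=0,1,2
    p_minor = np.array([eps / 3.0, 0.5 * (1 - eps) + 0.5 * (eps / 3.0), 1 - eps])
    p_major = p_minor[::-1]
    logl = (
        n_major[..., None] * np.log(p_major)
        + n_minor[..., None] * np.log(p_minor)
    )
    logl -= logl.max(axis=-1, keepdims=True)
    return np.exp(logl)


def missing_mask(gl: np.ndarray) -> np.ndarray:
    """True where an individual carries no information (all-equal triple)."""
    return np.all(gl == gl[..., :1], axis=-1)


def normalise_gl(gl: np.ndarray) -> np.ndarray:
    """Rescale triples to sum to one (probabilities over genotypes)."""
    return gl / gl.sum(axis=-1, keepdims=True)


def hwe_priors(f) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities [(1-f)^2, 2f(1-f), f^2]."""
    f = np.asarray(f, dtype=np.float64)
    return np.stack([(1 - f) ** 2, 2 * f * (1 - f), f**2], axis=-1)


def _site_loglik(gln: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Log-likelihood of frequency f per site; gln is sum-normalised (S,N,3)."""
    prior = hwe_priors(f)  # (S, 3)
    lik = np.einsum("sng,sg->sn", gln, prior)
    return np.log(np.maximum(lik, 1e-300)).sum(axis=1)


def estimate_maf_em(
    gl: np.ndarray,
    tol: float = DEFAULT_EM_TOL,
    max_iter: int = DEFAULT_EM_MAX_ITER,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """EM estimate of the minor-allele frequency per site.

    The fixed point is ``f <- (1/2n) sum_i E[g_i | GL_i, f]`` with a
    Hardy-Weinberg prior.  Missing individuals (flat triples) are kept
    in the denominator: their posterior expectation equals the prior
    mean, so they pull the update nowhere while keeping n honest.

    Parameters
    ----------
    gl
        Scaled likelihoods, shape (S, N, 3) or (N, 3) for one site.

    Returns
    -------
    (f_hat, loglik, n_used) arrays of length S.  ``loglik`` is computed
    with triples re-normalised to probabilities, hence always <= 0.
    """
    gl = np.asarray(gl, dtype=np.float64)
    squeeze = gl.ndim == 2
    if squeeze:
        gl = gl[None]
    n_used = (~missing_mask(gl)).sum(axis=1)
    if np.any(n_used == 0):
        raise EstimationError("site with all individuals missing")
    gln = normalise_gl(gl)
    S, N, _ = gln.shape
    f = np.full(S, DEFAULT_EM_START)
    active = np.ones(S, dtype=bool)
    g_vals = GENOTYPES.astype(np.float64)
    for _ in range(max_iter):
        sub = gln[active]
        prior = hwe_priors(f[active])
        post = sub * prior[:, None, :]
        post /= np.maximum(post.sum(axis=-1, keepdims=True), 1e-300)
        f_new = (post @ g_vals).mean(axis=1) / 2.0
        delta = np.abs(f_new - f[active])
        f[active] = f_new
        still = delta >= tol
        idx = np.flatnonzero(active)
        active[idx[~still]] = False
        if not active.any():
            break
    loglik = _site_loglik(gln, f)
    if squeeze:
        return f[0], loglik[0], int(n_used[0])
    return f, loglik, n_used


def snp_lrt(
    gl: np.ndarray,
    snp_pval: float = DEFAULT_SNP_PVAL,
    min_maf: float = DEFAULT_MIN_MAF,
    tol: float = DEFAULT_EM_TOL,
    max_iter: int = DEFAULT_EM_MAX_ITER,
):
    """Likelihood-ratio SNP test per site.

    Tests ``f = f_hat`` against the monomorphic null ``f = 0`` with a
    chi-square(1) reference.  A site is called a SNP when ``p <
    snp_pval`` and its minor-allele frequency exceeds ``min_maf``.

    Returns a dict of arrays: f_hat, loglik, lrt, pval, is_snp, n_used.
    """
    gl = np.asarray(gl, dtype=np.float64)
    squeeze = gl.ndim == 2
    if squeeze:
        gl = gl[None]
    f_hat, loglik, n_used = estimate_maf_em(gl, tol=tol, max_iter=max_iter)
    gln = normalise_gl(gl)
    ll0 = _site_loglik(gln, np.zeros(len(gln)))
    lrt = np.maximum(2.0 * (loglik - ll0), 0.0)
    pval = chi2.sf(lrt, df=1)
    maf = np.minimum(f_hat, 1.0 - f_hat)
    is_snp = (pval < snp_pval) & (maf > min_maf)
    out = {
        "f_hat": f_hat,
        "loglik": loglik,
        "lrt": lrt,
        "pval": pval,
        "is_snp": is_snp,
        "n_used": n_used,
    }
    if squeeze:
        out = {k: v[0] for k, v in out.items()}
    return out


def assign_major_minor(base_counts: np.ndarray, ref_alleles) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Major/minor assignment with the major forced to the reference.

    Parameters
    ----------
    base_counts
        (S, 4) summed read counts per site in A, C, G, T order.
    ref_alleles
        Length-S array of reference bases (letters or codes 0-3).

    Returns
    -------
    (major, minor, ok): integer allele codes and a validity mask.  The
    minor allele is the non-reference base with the highest summed
    count; ties break lexicographically (lowest code).  Sites with zero
    reads overall are flagged not-ok.
    """
    base_counts = np.asarray(base_counts, dtype=np.float64)
    ref = np.asarray(
        [ALLELE_CODE[a] if isinstance(a, str) else int(a) for a in np.atleast_1d(ref_alleles)]
    )
    S = base_counts.shape[0]
    masked = base_counts.copy()
    masked[np.arange(S), ref] = -1.0  # exclude the reference column
    # argmax takes the first (lowest code) maximum: lexicographic tie-break
    minor = masked.argmax(axis=1)
    ok = base_counts.sum(axis=1) > 0
    return ref, minor, ok


def site_filters(
    counts: np.ndarray,
    mean_depths: np.ndarray,
    min_ind_frac: float = 0.5,
    min_ind_frac_small: float = 0.9,
    small_group: int = 12,
    max_depth_factor: float = 3.0,
) -> np.ndarray:
    """Per-site keep mask for one sample group.

    A site is kept when (a) the fraction of individuals with at least
    one read is >= 50% of the group (>= 90% for groups smaller than 12;
    both boundaries inclusive) and (b) the total site depth does not
    exceed ``max_depth_factor`` times the expected total depth (the sum
    of per-individual mean depths), which removes collapsed repeats.

    Parameters
    ----------
    counts
        (S, N, k) read counts; summed over the trailing axis.
    mean_depths
        Length-N per-individual mean depths (X-fold).
    """
    counts = np.asarray(counts)
    if counts.shape[1] == 0:
        raise ParameterError("empty sample group")
    depth = counts.sum(axis=2)
    n = counts.shape[1]
    frac = min_ind_frac_small if n < small_group else min_ind_frac
    n_covered = (depth > 0).sum(axis=1)
    keep = n_covered >= frac * n
    expected_total = float(np.sum(mean_depths))
    keep &= depth.sum(axis=1) <= max_depth_factor * expected_total
    return keep


def posterior_dosage(gl: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Posterior mean genotype E[g | GL, f] under Hardy-Weinberg.

    gl: (S, N, 3) scaled likelihoods; f: (S,) frequencies.  Returns
    (S, N) dosages in [0, 2].
    """
    prior = hwe_priors(np.asarray(f, dtype=np.float64))
    post = np.asarray(gl, dtype=np.float64) * prior[:, None, :]
    post /= np.maximum(post.sum(axis=-1, keepdims=True), 1e-300)
    return post @ GENOTYPES.astype(np.float64)
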