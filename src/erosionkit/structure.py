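"""Population structure from genotype likelihoods.

A covariance matrix over individuals is built from posterior expected
genotypes under a Hardy-Weinberg prior at the estimated allele frequencies
(each site standardized by its binomial variance), decomposed into
principal components; admixture proportions are estimated with the standard
genotype-likelihood admixture model (individual allele frequencies
h_is = sum_k q_ik f_ks, binomial genotype prior, EM updates of Q and F),
taking the best of many random starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gl import GenotypeLikelihoods, estimate_maf_em

_F_CLIP = (1e-5, 1.0 - 1e-5)


@dataclass
class CovarianceMatrix:
    matrix: np.ndarray  # (n, n)
    n_sites_used: int
    samples: list[str] = field(default_factory=list)


@dataclass
class AdmixtureFit:
    K: int
    Q: np.ndarray  # (n, K) admixture proportions, rows sum to 1
    F: np.ndarray  # (K, L) cluster minor-allele frequencies
    loglik: float
    seed: int
    start_logliks: list[float] = field(default_factory=list)
    loglik_path: list[float] = field(default_factory=list)


def _expected_genotypes(gls: GenotypeLikelihoods, f: np.ndarray) -> np.ndarray:
    """(n_ind, n_sites) posterior mean minor-allele dose under HWE prior."""
    lin = gls.linear()
    prior = np.stack([(1 - f) ** 2, 2 * f * (1 - f), f**2], axis=1)
    post = lin * prior[:, None, :]
    post /= np.maximum(post.sum(axis=2, keepdims=True), 1e-300)
    return (post @ np.array([0.0, 1.0, 2.0])).T


def gl_covariance(
    gls: GenotypeLikelihoods,
    freqs: np.ndarray | None = None,
    maf_bounds: tuple[float, float] = (0.05, 0.95),
) -> CovarianceMatrix:
    """Standardized genotype covariance between individuals.

    C_ij = (1/L) sum_s (E[g_is] - 2 f_s)(E[g_js] - 2 f_s) / (2 f_s (1-f_s)),
    with E[g] the posterior expected minor dose; sites whose frequency falls
    outside ``maf_bounds`` are excluded.
    """
    if gls.n_individuals < 2:
        raise ValueError("covariance needs >= 2 individuals")
    f = np.asarray(freqs) if freqs is not None else (
        gls.maf if gls.maf is not None else estimate_maf_em(gls)
    )
    keep = (f >= maf_bounds[0]) & (f <= maf_bounds[1])
    if not keep.any():
        raise ValueError("no sites within the allele-frequency bounds")
    sub = gls.subset_sites(keep)
    fk = f[keep]
    eg = _expected_genotypes(sub, fk)  # (N, L)
    centered = eg - 2 * fk[None, :]
    scale = np.sqrt(2 * fk * (1 - fk))
    z = centered / scale[None, :]
    cov = (z @ z.T) / fk.size
    return CovarianceMatrix(matrix=cov, n_sites_used=int(fk.size),
                            samples=list(gls.samples))


def pca(cov: CovarianceMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spectral decomposition of the covariance, eigenvalues descending.

    Returns (eigenvalues, eigenvectors, scores), where column k of
    ``eigenvectors`` is the k-th PC axis and ``scores`` scales each axis by
    sqrt(eigenvalue).
    """
    mat = cov.matrix if isinstance(cov, CovarianceMatrix) else np.asarray(cov)
    vals, vecs = np.linalg.eigh(mat)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    scores = vecs * np.sqrt(np.maximum(vals, 0.0))[None, :]
    return vals, vecs, scores


# ---------------------------------------------------------------------------
# admixture EM
# ---------------------------------------------------------------------------

def _admixture_loglik(lin: np.ndarray, Q: np.ndarray, F: np.ndarray) -> float:
    h = Q @ F  # (N, L)
    prior = np.stack([(1 - h) ** 2, 2 * h * (1 - h), h**2], axis=2)
    mix = (lin.transpose(1, 0, 2) * prior).sum(axis=2)  # (N, L)
    return float(np.log(np.maximum(mix, 1e-300)).sum())


def _admixture_em_once(
    lin: np.ndarray,
    K: int,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    L_snl = lin.transpose(1, 0, 2)  # (N, L, 3)
    N, Lsites, _ = L_snl.shape
    Q = rng.dirichlet(np.ones(K), size=N)
    F = np.clip(rng.uniform(0.05, 0.95, size=(K, Lsites)), *_F_CLIP)
    dose = np.array([0.0, 1.0, 2.0])
    path: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        h = np.clip(Q @ F, 1e-9, 1 - 1e-9)  # (N, L)
        prior = np.stack([(1 - h) ** 2, 2 * h * (1 - h), h**2], axis=2)
        w = L_snl * prior
        mix = w.sum(axis=2)
        ll = float(np.log(np.maximum(mix, 1e-300)).sum())
        path.append(ll)
        w /= np.maximum(mix[:, :, None], 1e-300)
        a = w @ dose  # expected minor-allele count (N, L)
        b = 2.0 - a  # expected major-allele count
        # attribute expected allele copies to clusters
        qf = Q[:, :, None] * F[None, :, :]  # (N, K, L)
        q1f = Q[:, :, None] * (1.0 - F)[None, :, :]
        minor_k = qf / np.maximum(h[:, None, :], 1e-300) * a[:, None, :]
        major_k = q1f / np.maximum((1.0 - h)[:, None, :], 1e-300) * b[:, None, :]
        Q = (minor_k + major_k).sum(axis=2) / (2.0 * Lsites)
        Q /= Q.sum(axis=1, keepdims=True)
        F = minor_k.sum(axis=0) / np.maximum((minor_k + major_k).sum(axis=0), 1e-300)
        F = np.clip(F, *_F_CLIP)
        if ll - prev < tol and np.isfinite(prev):
            break
        prev = ll
    final = _admixture_loglik(lin, Q, F)
    path.append(final)
    return Q, F, final, path


def admixture_em(
    gls: GenotypeLikelihoods,
    K: int,
    seed: int = 0,
    n_starts: int = 100,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> AdmixtureFit:
    """Admixture proportions by EM from genotype likelihoods.

    Runs ``n_starts`` independent random initializations and returns the fit
    with the highest final log-likelihood; per-start final log-likelihoods
    are kept on the result. F is clipped to [1e-5, 1-1e-5] each update to
    avoid boundary absorption.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > gls.n_individuals:
        raise ValueError("K cannot exceed the number of individuals")
    lin = gls.linear()
    rng = np.random.default_rng(seed)
    best = None
    start_lls: list[float] = []
    for _ in range(n_starts):
        Q, F, ll, path = _admixture_em_once(lin, K, rng, tol, max_iter)
        start_lls.append(ll)
        if best is None or ll > best[2]:
            best = (Q, F, ll, path)
    Q, F, ll, path = best
    return AdmixtureFit(K=K, Q=Q, F=F, loglik=ll, seed=seed,
                        start_logliks=start_lls, loglik_path=path)
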