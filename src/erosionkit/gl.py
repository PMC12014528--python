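"""Genotype likelihoods from read pileups.

Converts per-site base observations into per-individual genotype
likelihoods over {major/major, major/minor, minor/minor}, estimates the
per-base sequencing error rate from reads aligned to a haploid reference
(e.g. a mitochondrial consensus), estimates per-site minor allele
frequencies by EM, and applies the standard low-coverage site filters
(MAF, SNP likelihood-ratio test, minimum individuals with data,
transversions only).

Bases are coded 0=A, 1=C, 2=G, 3=T throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: unordered base pairs that are transitions (purine<->purine, pyrimidine<->pyrimidine)
TRANSITION_PAIRS = frozenset({frozenset({0, 2}), frozenset({1, 3})})

_MIN_E = 1e-12  # floor on the error rate inside log-likelihoods


def is_transition(a: int, b: int) -> bool:
    return frozenset({int(a), int(b)}) in TRANSITION_PAIRS


@dataclass
class Pileup:
    """Per-site, per-individual observed base counts.

    ``counts[i, s, b]`` is the number of reads of base ``b`` for individual
    ``i`` at site ``s``. All reads in one pileup share a single Phred base
    quality (the simulator emits a constant per-base error rate); read order
    is never meaningful downstream, so counts are a lossless representation.
    """

    scaffolds: np.ndarray  # (n_sites,) str
    positions: np.ndarray  # (n_sites,) int, 1-based
    counts: np.ndarray  # (n_ind, n_sites, 4) int
    quality: float  # Phred base quality shared by all reads
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.scaffolds = np.asarray(self.scaffolds, dtype=object)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3 or self.counts.shape[2] != 4:
            raise ValueError("counts must have shape (n_ind, n_sites, 4)")
        if self.quality < 0:
            raise ValueError("quality must be >= 0")
        if not self.samples:
            self.samples = [f"ind{i}" for i in range(self.counts.shape[0])]
        for scaf in np.unique(self.scaffolds):
            pos = self.positions[self.scaffolds == scaf]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {scaf}")

    @property
    def n_individuals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_sites(self) -> int:
        return self.counts.shape[1]

    @property
    def depth(self) -> np.ndarray:
        """(n_ind, n_sites) total read depth."""
        return self.counts.sum(axis=2)


@dataclass
class ErrorModel:
    """Per-base sequencing error rate, optionally with a transversion-only rate.

    ``rate`` is the probability that a read base differs from the template
    base; each of the three alternative bases is equally likely (rate/3).
    ``tv_rate`` rescales transversion mismatches alone to a per-base rate
    (x 3/2, since two of the three possible miscalls are transversions),
    for analyses that discard transitions to dodge post-mortem deamination.
    """

    rate: float
    tv_rate: float | None = None
    n_bases: int = 0
    n_mismatches: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 0.75:
            raise ValueError(f"error rate must be in [0, 0.75], got {self.rate}")


@dataclass
class GenotypeLikelihoods:
    """Per-site genotype likelihoods with major/minor polarization.

    ``loglik[s, i, g]`` is the natural-log likelihood of genotype ``g``
    (minor-allele dose 0, 1, 2) for individual ``i`` at site ``s``,
    normalized so the per-triplet maximum is 0 (1 on the linear scale).
    Individuals without reads at a site carry a flat triplet.
    """

    scaffolds: np.ndarray
    positions: np.ndarray
    major: np.ndarray  # (n_sites,) base codes
    minor: np.ndarray
    loglik: np.ndarray  # (n_sites, n_ind, 3)
    samples: list[str]
    maf: np.ndarray | None = None  # (n_sites,) minor allele frequency

    @property
    def n_sites(self) -> int:
        return self.loglik.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.loglik.shape[1]

    def linear(self) -> np.ndarray:
        """Likelihood triplets on the linear scale (max of each triplet = 1)."""
        return np.exp(self.loglik)

    @property
    def has_data(self) -> np.ndarray:
        """(n_sites, n_ind) True where the individual has >=1 read (non-flat)."""
        return ~np.all(self.loglik == self.loglik[:, :, :1], axis=2)

    @property
    def markers(self) -> list[str]:
        return [f"{s}_{p}" for s, p in zip(self.scaffolds, self.positions)]

    def subset_sites(self, mask: np.ndarray) -> "GenotypeLikelihoods":
        return GenotypeLikelihoods(
            scaffolds=self.scaffolds[mask],
            positions=self.positions[mask],
            major=self.major[mask],
            minor=self.minor[mask],
            loglik=self.loglik[mask],
            samples=list(self.samples),
            maf=None if self.maf is None else self.maf[mask],
        )


# ---------------------------------------------------------------------------
# error-rate estimation from a haploid reference
# ---------------------------------------------------------------------------

def estimate_error_rate_from_haploid(
    consensus: str, pileup: Pileup, min_quality: int = 30
) -> ErrorModel:
    """Estimate the per-base error rate from reads over a haploid sequence.

    Every read base that differs from the haploid consensus is an error, so
    the rate is simply mismatches / total among bases with quality >=
    ``min_quality``. The transversion-only rate counts transversion
    mismatches and scales by 3/2.
    """
    if pileup.n_sites != len(consensus):
        raise ValueError("consensus length does not match pileup site count")
    if pileup.quality < min_quality:
        raise ValueError(
            f"no bases pass the quality filter (pileup quality {pileup.quality} "
            f"< min_quality {min_quality})"
        )
    cons = np.array([BASE_INDEX[c] for c in consensus.upper()], dtype=np.int64)
    counts = pileup.counts.sum(axis=0)  # (n_sites, 4)
    total = int(counts.sum())
    if total == 0:
        raise ValueError("no bases available to estimate the error rate")
    match = int(counts[np.arange(len(cons)), cons].sum())
    n_mis = total - match
    tv_mis = 0
    for b in range(4):
        mask = cons != b
        obs = int(counts[mask, b].sum())
        tv = np.array([not is_transition(c, b) for c in cons[mask]])
        tv_mis += int(counts[mask][tv, b].sum()) if mask.any() else 0
    rate = n_mis / total
    tv_rate = 1.5 * tv_mis / total
    return ErrorModel(rate=rate, tv_rate=tv_rate, n_bases=total, n_mismatches=n_mis)


# ---------------------------------------------------------------------------
# genotype likelihoods
# ---------------------------------------------------------------------------

def call_genotype_likelihoods(pileup: Pileup, error_model: ErrorModel) -> GenotypeLikelihoods:
    """Compute per-individual genotype likelihoods at every pileup site.

    For genotype (a1, a2) the per-read base probability is
    ``[P(b|a1) + P(b|a2)] / 2`` with ``P(b|a) = 1-e`` if ``b == a`` else
    ``e/3``; the site likelihood is the product over reads. The major and
    minor alleles are the two highest-count bases across all individuals,
    ties broken in base order A<C<G<T.
    """
    e = max(float(error_model.rate), _MIN_E)
    if e >= 0.75:
        raise ValueError("error rate must be < 0.75")
    counts = pileup.counts
    n_ind, n_sites, _ = counts.shape

    totals = counts.sum(axis=0)  # (n_sites, 4)
    # stable argsort on -counts resolves ties in base order
    order = np.argsort(-totals, axis=1, kind="stable")
    major = order[:, 0].astype(np.int8)
    minor = order[:, 1].astype(np.int8)

    sites = np.arange(n_sites)
    n_maj = counts[:, sites, major]  # (n_ind, n_sites)
    n_min = counts[:, sites, minor]
    depth = counts.sum(axis=2)
    n_other = depth - n_maj - n_min

    log_match = np.log(1.0 - e)
    log_err = np.log(e / 3.0)
    log_het_allele = np.log((1.0 - e + e / 3.0) / 2.0)

    ll = np.empty((n_sites, n_ind, 3))
    ll[:, :, 0] = (n_maj * log_match + (depth - n_maj) * log_err).T
    ll[:, :, 1] = ((n_maj + n_min) * log_het_allele + n_other * log_err).T
    ll[:, :, 2] = (n_min * log_match + (depth - n_min) * log_err).T
    ll -= ll.max(axis=2, keepdims=True)  # flat (0,0,0) where depth == 0

    return GenotypeLikelihoods(
        scaffolds=pileup.scaffolds.copy(),
        positions=pileup.positions.copy(),
        major=major,
        minor=minor,
        loglik=ll,
        samples=list(pileup.samples),
    )


def call_genotypes(gls: GenotypeLikelihoods, post_cutoff: float = 0.95) -> np.ndarray:
    """Hard genotype calls (minor-allele dose) from posterior probabilities.

    Uses a Hardy-Weinberg prior at the estimated minor allele frequency and
    emits -1 (missing) where the best genotype's posterior falls below
    ``post_cutoff`` or the individual has no reads.
    """
    f = gls.maf if gls.maf is not None else estimate_maf_em(gls)
    lin = gls.linear()
    prior = np.stack([(1 - f) ** 2, 2 * f * (1 - f), f**2], axis=1)  # (S, 3)
    post = lin * prior[:, None, :]
    post /= np.maximum(post.sum(axis=2, keepdims=True), 1e-300)
    best = post.argmax(axis=2)
    calls = best.T.astype(np.int8)  # (n_ind, n_sites)
    ok = (post.max(axis=2) >= post_cutoff) & gls.has_data
    calls[~ok.T] = -1
    return calls


# ---------------------------------------------------------------------------
# allele-frequency EM and the SNP likelihood-ratio test
# ---------------------------------------------------------------------------

def _hwe_prior(f: np.ndarray) -> np.ndarray:
    return np.stack([(1 - f) ** 2, 2 * f * (1 - f), f**2], axis=-1)


def sites_loglik(gls: GenotypeLikelihoods, f: np.ndarray) -> np.ndarray:
    """Per-site log-likelihood sum_i log sum_g L_ig P(g | f) over individuals with data."""
    lin = gls.linear()
    prior = _hwe_prior(np.asarray(f, dtype=float))
    if prior.ndim == 1:
        prior = np.broadcast_to(prior, (gls.n_sites, 3))
    mix = (lin * prior[:, None, :]).sum(axis=2)
    mix = np.maximum(mix, 1e-300)
    contrib = np.where(gls.has_data, np.log(mix), 0.0)
    return contrib.sum(axis=1)


def estimate_maf_em(
    gls: GenotypeLikelihoods, tol: float = 1e-8, max_iter: int = 500
) -> np.ndarray:
    """EM estimate of the per-site minor allele frequency under Hardy-Weinberg.

    Iterates the standard fixed point: posterior genotype weights under the
    current f, then f <- mean expected minor dose / 2, until
    ``max |delta f| < tol``. The observed-data log-likelihood is
    non-decreasing across iterations (EM guarantee).
    """
    lin = gls.linear()
    mask = gls.has_data
    n_eff = mask.sum(axis=1)
    f = np.full(gls.n_sites, 0.2)
    dose_w = np.array([0.0, 1.0, 2.0])
    for _ in range(max_iter):
        prior = _hwe_prior(f)
        w = lin * prior[:, None, :]
        w /= np.maximum(w.sum(axis=2, keepdims=True), 1e-300)
        dose = w @ dose_w  # (S, N)
        with np.errstate(invalid="ignore"):
            f_new = (dose * mask).sum(axis=1) / np.maximum(2 * n_eff, 1)
        f_new = np.where(n_eff == 0, 0.0, f_new)
        delta = np.abs(f_new - f).max() if f.size else 0.0
        f = f_new
        if delta < tol:
            break
    return f


def snp_lrt(gls: GenotypeLikelihoods, f_hat: np.ndarray) -> np.ndarray:
    """Likelihood-ratio test of polymorphism: 2[l(f_hat) - l(0)] vs chi2(1).

    Boundary convention: p = 1 where f_hat is (numerically) 0; the
    half-chi-square mixture refinement is deliberately not applied, which is
    conservative.
    """
    f_hat = np.asarray(f_hat, dtype=float)
    ll_f = sites_loglik(gls, f_hat)
    ll_0 = sites_loglik(gls, np.zeros_like(f_hat))
    stat = np.maximum(2.0 * (ll_f - ll_0), 0.0)
    p = chi2.sf(stat, df=1)
    return np.where(f_hat < 1e-9, 1.0, p)


# ---------------------------------------------------------------------------
# site filters
# ---------------------------------------------------------------------------

def filter_sites(
    gls: GenotypeLikelihoods,
    min_maf: float = 0.05,
    snp_p: float = 1e-6,
    min_ind: int = 1,
    rm_transitions: bool = True,
    tol: float = 1e-8,
) -> GenotypeLikelihoods:
    """Apply the standard low-coverage site filters, preserving site order.

    Retains sites whose estimated minor allele frequency is >= ``min_maf``,
    whose SNP LRT p-value is <= ``snp_p``, that have data for >= ``min_ind``
    individuals and, with ``rm_transitions``, whose major/minor pair is not
    A/G or C/T. The transversion filter is applied after major/minor
    inference and before the MAF/LRT thresholds.
    """
    keep = np.ones(gls.n_sites, dtype=bool)
    if rm_transitions:
        trans = np.array(
            [is_transition(a, b) for a, b in zip(gls.major, gls.minor)], dtype=bool
        )
        keep &= ~trans
    f = gls.maf if gls.maf is not None else estimate_maf_em(gls, tol=tol)
    p = snp_lrt(gls, f)
    keep &= f >= min_maf
    keep &= p <= snp_p
    keep &= gls.has_data.sum(axis=1) >= min_ind
    out = gls.subset_sites(keep)
    out.maf = f[keep]
    if out.n_sites == 0:
        warnings.warn("no sites survived filtering", stacklevel=2)
    return out
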