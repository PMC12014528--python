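"""Genome-wide heterozygosity with coverage-bias calibration.

Per-individual heterozygosity is the heterozygous-class weight of a
two-class (homozygous vs heterozygous) folded site mixture, estimated by EM
in windows — the per-individual analogue of a folded site-frequency
spectrum. Because low coverage hides one allele of heterozygous sites, raw
estimates are biased downward; the calibration here rebuilds the classic
downsampling design (five fractions x three replicates of one
high-coverage individual, 15 datasets), fits a polynomial of relative
heterozygosity against achieved coverage, and divides raw estimates by the
predicted relative heterozygosity at their coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gl import GenotypeLikelihoods, Pileup, _MIN_E

#: downsampling fractions of the reference coverage used in the calibration design
DEFAULT_FRACTIONS = (0.25, 0.40, 0.50, 0.60, 0.80)

#: Published coverage-correction polynomials (highest order first), shipped
#: as opaque presets for reference only and never applied by default: their
#: coverage normalization cannot be reconstructed (the contemporary cubic
#: does not evaluate to 1 at its own reference coverage), so a freshly
#: fitted curve is always used instead.
PRINTED_CORRECTION_PRESETS = {
    "contemporary": np.array([0.0008, -0.0265, 0.2998, 0.2191]),
    "historic": np.array([0.0063, -0.1399, 1.781]),
}


# ---------------------------------------------------------------------------
# two-class site likelihoods and the heterozygosity EM
# ---------------------------------------------------------------------------

def site_het_likelihood(triplet: np.ndarray) -> np.ndarray:
    """Fold a linear-scale genotype triplet into (homozygous, heterozygous).

    The homozygous class takes the max of the two homozygote likelihoods
    (folding convention: after major/minor polarization the major homozygote
    dominates, and max avoids double counting); the heterozygous class is
    the major/minor likelihood. Accepts a single triplet or an (..., 3) array.
    """
    t = np.asarray(triplet, dtype=float)
    hom = np.maximum(t[..., 0], t[..., 2])
    return np.stack([hom, t[..., 1]], axis=-1)


@dataclass
class HetEMResult:
    p_het: float
    n_iter: int
    loglik: float
    uninformative: bool = False

    def __float__(self) -> float:
        return self.p_het


def estimate_heterozygosity_em(
    two_class: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 5000,
    init: tuple[float, float] = (0.999, 0.001),
) -> HetEMResult:
    """EM for the heterozygous-site proportion of a two-class mixture.

    ``two_class`` is an (n_sites, 2) array of linear-scale (hom, het)
    likelihoods. Iterates p_k <- (1/S) sum_s p_k L_sk / sum_j p_j L_sj until
    ``max |delta p| < tol``; the observed-data log-likelihood is
    non-decreasing. If every site is uninformative (flat), the
    initialization is returned with ``uninformative=True``.
    """
    L = np.asarray(two_class, dtype=float)
    if L.ndim != 2 or L.shape[1] != 2:
        raise ValueError("two_class must have shape (n_sites, 2)")
    if L.shape[0] == 0:
        raise ValueError("need at least one site")
    scale = L.max(axis=1, keepdims=True)
    informative = (scale[:, 0] > 0) & (np.abs(L[:, 0] - L[:, 1]) > 1e-12 * scale[:, 0])
    if not informative.any():
        return HetEMResult(p_het=init[1], n_iter=0, loglik=float("nan"), uninformative=True)
    Ln = L / np.maximum(scale, 1e-300)
    p = np.array(init, dtype=float)
    S = Ln.shape[0]
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        mix = Ln @ p
        r = Ln * p / np.maximum(mix[:, None], 1e-300)
        p_new = r.sum(axis=0) / S
        delta = np.abs(p_new - p).max()
        p = p_new
        if delta < tol:
            break
    loglik = float(np.log(np.maximum(Ln @ p, 1e-300)).sum())
    return HetEMResult(p_het=float(p[1]), n_iter=n_iter, loglik=loglik)


def individual_site_likelihoods(
    pileup: Pileup,
    individual: int,
    error_rate: float,
    exclude_transitions: bool = False,
) -> np.ndarray:
    """(n_sites, 2) linear (hom, het) likelihoods for one individual.

    The two candidate alleles at each site are that individual's two
    highest-count bases (ties in base order); sites without reads are flat.
    With ``exclude_transitions`` sites whose candidate pair is A/G or C/T are
    flattened (uninformative) — the standard defence against post-mortem
    C->T / G->A damage in historic samples.
    """
    e = max(float(error_rate), _MIN_E)
    counts = pileup.counts[individual]  # (S, 4)
    order = np.argsort(-counts, axis=1, kind="stable")
    a1, a2 = order[:, 0], order[:, 1]
    sites = np.arange(counts.shape[0])
    n1 = counts[sites, a1]
    n2 = counts[sites, a2]
    depth = counts.sum(axis=1)
    n_other = depth - n1 - n2

    log_match = np.log(1 - e)
    log_err = np.log(e / 3)
    log_het = np.log((1 - e + e / 3) / 2)
    ll_hom1 = n1 * log_match + (depth - n1) * log_err
    ll_hom2 = n2 * log_match + (depth - n2) * log_err
    ll_het = (n1 + n2) * log_het + n_other * log_err
    ll = np.stack([np.maximum(ll_hom1, ll_hom2), ll_het], axis=1)
    ll -= ll.max(axis=1, keepdims=True)
    out = np.exp(ll)
    if exclude_transitions:
        from .gl import is_transition

        trans = np.array([is_transition(x, y) for x, y in zip(a1, a2)])
        out[trans] = 1.0
    return out


# ---------------------------------------------------------------------------
# windowed estimates
# ---------------------------------------------------------------------------

def windowed_heterozygosity(
    gls: GenotypeLikelihoods,
    window_bp: int = 1_000_000,
    min_informative_frac: float = 0.10,
    tol: float = 1e-8,
    coverage: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-individual raw heterozygosity in non-overlapping windows.

    Windows with fewer than ``min_informative_frac`` of their sites
    informative for the individual are dropped. Columns: individual,
    scaffold, start, end (1-based inclusive), n_sites, n_informative,
    raw_het, coverage.
    """
    lin = gls.linear()
    two = site_het_likelihood(lin)  # (S, N, 2)
    has_data = gls.has_data
    rows = []
    for scaf in pd.unique(pd.Series(gls.scaffolds)):
        s_mask = gls.scaffolds == scaf
        pos = gls.positions[s_mask]
        win = (pos - 1) // window_bp
        for w in np.unique(win):
            idx = np.flatnonzero(s_mask)[win == w]
            for i, sample in enumerate(gls.samples):
                informative = has_data[idx, i]
                n_inf = int(informative.sum())
                if n_inf < min_informative_frac * idx.size or n_inf == 0:
                    continue
                res = estimate_heterozygosity_em(two[idx, i, :], tol=tol)
                rows.append(
                    {
                        "individual": sample,
                        "scaffold": scaf,
                        "start": int(w * window_bp + 1),
                        "end": int((w + 1) * window_bp),
                        "n_sites": int(idx.size),
                        "n_informative": n_inf,
                        "raw_het": res.p_het,
                        "coverage": float("nan") if coverage is None else float(coverage[i]),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "individual", "scaffold", "start", "end",
            "n_sites", "n_informative", "raw_het", "coverage",
        ],
    )


def genomewide_heterozygosity(windows: pd.DataFrame) -> pd.Series:
    """Site-weighted mean of windowed raw heterozygosity per individual."""
    def agg(g: pd.DataFrame) -> float:
        return float(np.average(g["raw_het"], weights=g["n_informative"]))

    return windows.groupby("individual").apply(agg, include_groups=False)


# ---------------------------------------------------------------------------
# downsampling and the calibration curve
# ---------------------------------------------------------------------------

def downsample_pileup(pileup: Pileup, fraction: float, seed: int = 0) -> Pileup:
    """Retain each read independently with probability ``fraction``."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if fraction == 1.0:
        return Pileup(
            scaffolds=pileup.scaffolds.copy(),
            positions=pileup.positions.copy(),
            counts=pileup.counts.copy(),
            quality=pileup.quality,
            samples=list(pileup.samples),
        )
    rng = np.random.default_rng(seed)
    kept = rng.binomial(pileup.counts, fraction).astype(pileup.counts.dtype)
    return Pileup(
        scaffolds=pileup.scaffolds.copy(),
        positions=pileup.positions.copy(),
        counts=kept,
        quality=pileup.quality,
        samples=list(pileup.samples),
    )


@dataclass
class CalibrationCurve:
    """Polynomial map from coverage to relative heterozygosity.

    The polynomial is fitted by least squares to the replicate table of
    (achieved coverage, het_downsampled / het_full) points in the anchored
    form p(x) = 1 + (x - ref) q(x), which constrains the curve through
    (reference coverage, 1): the full-coverage estimate defines "authentic"
    heterozygosity, so corrected == raw at the reference coverage by
    construction. ``coefficients`` are the expanded standard-form
    coefficients (highest order first); ``reduced`` stores q.
    """

    degree: int
    coefficients: np.ndarray
    reference_coverage: float
    replicates: pd.DataFrame  # columns: fraction, replicate, coverage, relative_het
    het_full: float
    reduced: np.ndarray | None = None  # coefficients of q, highest first

    @property
    def min_fitted_coverage(self) -> float:
        return float(self.replicates["coverage"].min())

    def predict(self, coverage: float | np.ndarray) -> np.ndarray:
        if self.reduced is not None:
            x = np.asarray(coverage, dtype=float)
            return 1.0 + (x - self.reference_coverage) * np.polyval(self.reduced, x)
        return np.polyval(self.coefficients, coverage)


def build_calibration_curve(
    pileup: Pileup,
    error_rate: float,
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
    replicates: int = 3,
    degree: int = 3,
    seed: int = 0,
    individual: int = 0,
    tol: float = 1e-8,
) -> CalibrationCurve:
    """Fit a coverage-bias curve by downsampling one high-coverage individual.

    For every (fraction, replicate) pair the pileup is independently
    thinned, heterozygosity re-estimated, and the ratio to the full-coverage
    estimate recorded against the achieved mean depth; a least-squares
    polynomial of the stated degree is fitted to the
    ``len(fractions) * replicates`` support points (15 under the defaults).
    """
    if len(set(fractions)) < 2:
        raise ValueError("calibration needs at least two distinct fractions")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    sub = Pileup(
        scaffolds=pileup.scaffolds,
        positions=pileup.positions,
        counts=pileup.counts[individual][None, :, :],
        quality=pileup.quality,
        samples=[pileup.samples[individual]],
    )
    two_full = individual_site_likelihoods(sub, 0, error_rate)
    full = estimate_heterozygosity_em(two_full, tol=tol)
    if full.uninformative or full.p_het <= 0:
        raise ValueError("full-coverage data yield no informative heterozygosity")
    ref_cov = float(sub.depth.mean())

    rows = []
    rng = np.random.default_rng(seed)
    for frac in fractions:
        for rep in range(replicates):
            ds = downsample_pileup(sub, frac, seed=int(rng.integers(2**31)))
            two = individual_site_likelihoods(ds, 0, error_rate)
            res = estimate_heterozygosity_em(two, tol=tol)
            if res.uninformative:
                raise ValueError(
                    f"fraction {frac} leaves no informative sites; coverage too low"
                )
            rows.append(
                {
                    "fraction": frac,
                    "replicate": rep + 1,
                    "coverage": float(ds.depth.mean()),
                    "relative_het": res.p_het / full.p_het,
                }
            )
    table = pd.DataFrame(rows)
    x = table["coverage"].to_numpy()
    y = table["relative_het"].to_numpy()
    # anchored fit: p(x) = 1 + (x - ref) q(x) with q of degree - 1,
    # solved by ordinary least squares on (y - 1)
    basis = np.vander(x, degree) * (x - ref_cov)[:, None]
    q, *_ = np.linalg.lstsq(basis, y - 1.0, rcond=None)
    expanded = np.polymul(q, [1.0, -ref_cov])
    coeffs = np.zeros(degree + 1)
    coeffs[-expanded.size:] = expanded
    coeffs[-1] += 1.0
    return CalibrationCurve(
        degree=degree,
        coefficients=coeffs,
        reference_coverage=ref_cov,
        replicates=table,
        het_full=full.p_het,
        reduced=q,
    )


def apply_correction(
    raw_het: float | np.ndarray, coverage: float, curve: CalibrationCurve
) -> float | np.ndarray:
    """Correct a raw heterozygosity estimate for coverage bias.

    Divides by the curve's predicted relative heterozygosity at ``coverage``
    (clipped below at 0.05 to avoid explosion). Coverage must lie within
    [0.5 x min fitted coverage, 1.5 x reference coverage]; outside that
    range the polynomial is unconstrained and correction refuses to
    extrapolate.
    """
    lo = 0.5 * curve.min_fitted_coverage
    hi = 1.5 * curve.reference_coverage
    if not lo <= coverage <= hi:
        raise ValueError(
            f"coverage {coverage:.2f}x outside the calibrated range "
            f"[{lo:.2f}, {hi:.2f}]x; refusing to extrapolate"
        )
    pred = float(np.maximum(curve.predict(coverage), 0.05))
    return raw_het / pred


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def kruskal_wallis(groups) -> tuple[float, float]:
    """Rank-based Kruskal-Wallis H with tie correction and chi-square p.

    ``groups`` is a sequence of 1-D value sequences. Degenerate input where
    every value is identical returns (0.0, 1.0).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)
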