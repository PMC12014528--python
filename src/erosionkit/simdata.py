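"""Two-epoch synthetic population-genomic data with known ground truth.

Emulates the sampling design of a temporal (museum vs. modern) resequencing
study: diploid genotypes for a historic and a contemporary cohort separated
by a diversity bottleneck, planted autozygous tracts of controlled length
classes, shotgun read pileups with sequencing error and strand-collapsed
post-mortem C->T / G->A damage, and epoch-labelled mitochondrial haplotype
alignments. Every generator records its ground truth so downstream
estimators can be tested for parameter recovery.

Site frequencies are drawn from a neutral-like folded-free SFS with density
proportional to 1/x truncated to [1/2N, 1 - 1/2N]; sites are independent
(no linkage) except for planted tracts, since every downstream statistic is
per-site or tract-based. Damage is position-independent: downstream filters
act on transitions regardless of position in the read, and a constant rate
keeps the expectation analytic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np

from .gl import BASES, Pileup

#: ROH length classes (bp), lower-inclusive; the open top class is capped
#: at 20 Mb for tract drawing.
ROH_CLASS_BOUNDS = [
    (500_000, 1_000_000),
    (1_000_000, 2_000_000),
    (2_000_000, 5_000_000),
    (5_000_000, 10_000_000),
    (10_000_000, 20_000_000),
]
ROH_CLASS_LABELS = ["0.5-1", "1-2", "2-5", "5-10", ">10"]


@dataclass
class SimConfig:
    """Parameters of the two-epoch simulation.

    ``theta`` is the expected per-site heterozygosity of the historic epoch;
    ``bottleneck_factor`` multiplies the expected heterozygosity of the
    contemporary epoch (1 = no bottleneck). Coverages are mean depths in x.
    The mutation rate and generation time defaults (1.905e-8 per site per
    generation; six years) are the values standardly adopted for koala.
    """

    n_historic: int = 20
    n_contemporary: int = 20
    n_sites: int = 50_000
    n_scaffolds: int = 5
    scaffold_length: int = 20_000_000
    theta: float = 0.0014
    bottleneck_factor: float = 0.3
    coverage_historic: float = 4.0
    coverage_contemporary: float = 12.3
    error_rate: float = 0.001
    damage_rate: float = 0.02
    mu: float = 1.905e-8
    generation_time: float = 6.0
    two_n: int = 100  # SFS truncation bound 1/2N
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_historic", "n_contemporary", "n_sites", "n_scaffolds",
                     "scaffold_length", "two_n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("theta", "error_rate", "damage_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.bottleneck_factor <= 1.0:
            raise ValueError("bottleneck_factor must be in (0, 1]")
        if self.coverage_historic < 0 or self.coverage_contemporary < 0:
            raise ValueError("coverages must be >= 0")
        if self.theta > sfs_expected_het(self.two_n):
            raise ValueError(
                f"theta={self.theta} exceeds the mean heterozygosity of the "
                f"truncated SFS ({sfs_expected_het(self.two_n):.4f})"
            )

    @property
    def scaffold_names(self) -> list[str]:
        return [f"scaf{i + 1}" for i in range(self.n_scaffolds)]

    @property
    def genome_length(self) -> int:
        return self.n_scaffolds * self.scaffold_length


def sfs_expected_het(two_n: int = 100) -> float:
    """E[2p(1-p)] under density 1/x truncated to [1/2N, 1-1/2N]."""
    a, b = 1.0 / two_n, 1.0 - 1.0 / two_n
    c = 1.0 / math.log(b / a)
    return c * (2.0 * (b - a) - (b * b - a * a))


@dataclass
class GenotypeData:
    """Diploid genotypes (alt-allele dose; -1 = missing) at simulated sites."""

    scaffolds: np.ndarray  # (n_sites,) str
    positions: np.ndarray  # (n_sites,) int, 1-based
    ref: np.ndarray  # (n_sites,) base codes
    alt: np.ndarray
    genotypes: np.ndarray  # (n_ind, n_sites) int8
    samples: list[str]
    epochs: list[str]  # per sample: "historic" | "contemporary" (or pop label)
    scaffold_lengths: dict[str, int]
    alt_freqs: dict[str, np.ndarray] = field(default_factory=dict)  # per epoch

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    @property
    def genome_length(self) -> int:
        return sum(self.scaffold_lengths.values())

    def copy(self) -> "GenotypeData":
        return GenotypeData(
            scaffolds=self.scaffolds.copy(),
            positions=self.positions.copy(),
            ref=self.ref.copy(),
            alt=self.alt.copy(),
            genotypes=self.genotypes.copy(),
            samples=list(self.samples),
            epochs=list(self.epochs),
            scaffold_lengths=dict(self.scaffold_lengths),
            alt_freqs={k: v.copy() for k, v in self.alt_freqs.items()},
        )


@dataclass
class TruthTable:
    """Ground truth recorded by the simulator.

    ``true_het`` is the realized per-individual heterozygosity (fraction of
    simulated sites that are heterozygous); ``true_froh`` is summed planted
    tract length over total scaffold length; ``hap_freqs`` holds the
    expected per-epoch mitochondrial haplotype frequency vectors.
    """

    samples: list[str]
    epochs: list[str]
    true_het: np.ndarray
    true_froh: np.ndarray
    planted_tracts: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    hap_freqs: dict[str, np.ndarray] = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "individual": self.samples,
                "epoch": self.epochs,
                "true_het": self.true_het,
                "true_froh": self.true_froh,
            }
        )


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _site_positions(cfg: SimConfig, rng: np.random.Generator):
    """Distinct sorted site coordinates across scaffolds."""
    per = rng.multinomial(cfg.n_sites, np.full(cfg.n_scaffolds, 1.0 / cfg.n_scaffolds))
    scaffolds, positions = [], []
    for name, k in zip(cfg.scaffold_names, per):
        if k == 0:
            continue
        pos = rng.choice(cfg.scaffold_length, size=k, replace=False) + 1
        pos.sort()
        scaffolds.extend([name] * k)
        positions.append(pos)
    return (
        np.array(scaffolds, dtype=object),
        np.concatenate(positions) if positions else np.array([], dtype=np.int64),
    )


def _drift_generations(cfg: SimConfig) -> int:
    """Wright-Fisher generations at size 2N whose het loss matches the bottleneck."""
    if cfg.bottleneck_factor >= 1.0:
        return 0
    return max(1, round(math.log(cfg.bottleneck_factor) / math.log(1.0 - 1.0 / cfg.two_n)))


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeData, TruthTable]:
    """Simulate diploid genotypes for both epochs with a drift bottleneck.

    Each site is polymorphic with probability theta / E_SFS[2p(1-p)], with
    its historic frequency drawn from the truncated 1/x SFS (so the expected
    per-site heterozygosity is exactly ``theta``). Contemporary frequencies
    follow from repeated binomial Wright-Fisher resampling for the number of
    generations whose cumulative het loss (1 - 1/2N)^t equals
    ``bottleneck_factor``; genotypes are Hardy-Weinberg draws per epoch.
    """
    rng = np.random.default_rng(cfg.seed)
    scaffolds, positions = _site_positions(cfg, rng)
    S = cfg.n_sites

    ref = rng.integers(0, 4, size=S).astype(np.int8)
    alt = ((ref + rng.integers(1, 4, size=S)) % 4).astype(np.int8)

    e_sfs = sfs_expected_het(cfg.two_n)
    is_poly = rng.random(S) < (cfg.theta / e_sfs if cfg.theta > 0 else 0.0)
    a, b = 1.0 / cfg.two_n, 1.0 - 1.0 / cfg.two_n
    p_hist = np.zeros(S)
    n_poly = int(is_poly.sum())
    p_hist[is_poly] = a * (b / a) ** rng.random(n_poly)

    p_cont = p_hist.copy()
    q = p_cont[is_poly]
    for _ in range(_drift_generations(cfg)):
        q = rng.binomial(cfg.two_n, q) / cfg.two_n
    p_cont[is_poly] = q

    samples = [f"hist{i + 1}" for i in range(cfg.n_historic)] + [
        f"cont{i + 1}" for i in range(cfg.n_contemporary)
    ]
    epochs = ["historic"] * cfg.n_historic + ["contemporary"] * cfg.n_contemporary
    genotypes = np.zeros((len(samples), S), dtype=np.int8)
    poly_idx = np.flatnonzero(is_poly)
    if poly_idx.size:
        genotypes[: cfg.n_historic, poly_idx] = rng.binomial(
            2, p_hist[poly_idx], size=(cfg.n_historic, poly_idx.size)
        )
        genotypes[cfg.n_historic:, poly_idx] = rng.binomial(
            2, p_cont[poly_idx], size=(cfg.n_contemporary, poly_idx.size)
        )

    geno = GenotypeData(
        scaffolds=scaffolds,
        positions=positions,
        ref=ref,
        alt=alt,
        genotypes=genotypes,
        samples=samples,
        epochs=epochs,
        scaffold_lengths={n: cfg.scaffold_length for n in cfg.scaffold_names},
        alt_freqs={"historic": p_hist, "contemporary": p_cont},
    )
    truth = TruthTable(
        samples=samples,
        epochs=epochs,
        true_het=(genotypes == 1).mean(axis=1),
        true_froh=np.zeros(len(samples)),
        planted_tracts={s: [] for s in samples},
    )
    return geno, truth


# ---------------------------------------------------------------------------
# planted runs of homozygosity
# ---------------------------------------------------------------------------

def _draw_tract_lengths(
    target_bp: float,
    mix: np.ndarray,
    scaffold_length: int,
    rng: np.random.Generator,
) -> list[int]:
    """Tract lengths from the class mix summing to within +-10% of target."""
    min_len = ROH_CLASS_BOUNDS[0][0]
    if target_bp < 0.9 * min_len:
        raise ValueError(
            f"froh target of {target_bp:.0f} bp is below the minimum tract "
            f"length ({min_len} bp); infeasible"
        )
    lengths: list[int] = []
    placed = 0.0
    attempts = 0
    while placed < 0.90 * target_bp:
        attempts += 1
        if attempts > 10_000:
            raise ValueError("could not assemble tract lengths for froh target")
        k = rng.choice(len(ROH_CLASS_BOUNDS), p=mix)
        lo, hi = ROH_CLASS_BOUNDS[k]
        hi = min(hi, scaffold_length)
        if lo >= hi:
            continue
        length = int(rng.uniform(lo, hi))
        if placed + length > 1.10 * target_bp:
            room = 1.10 * target_bp - placed
            if room < min_len:
                raise ValueError("froh target infeasible with 0.5 Mb minimum tracts")
            length = int(rng.uniform(min_len, room))
        lengths.append(length)
        placed += length
    return lengths


def plant_roh(
    geno: GenotypeData,
    truth: TruthTable,
    froh_target: float | dict[str, float],
    length_class_mix: Sequence[float] | None = None,
    seed: int = 0,
    samples: Sequence[str] | None = None,
) -> tuple[GenotypeData, TruthTable]:
    """Force non-overlapping autozygous tracts into individual genomes.

    Tract lengths are drawn from ``length_class_mix`` over the five ROH
    length classes (default uniform) and placed uniformly without overlap;
    within a tract every site is made homozygous for an allele drawn from
    the site's epoch allele frequency. The realized FROH lands within +-10%
    relative of ``froh_target`` whenever scaffold lengths permit.
    """
    mix = (
        np.full(len(ROH_CLASS_BOUNDS), 1.0 / len(ROH_CLASS_BOUNDS))
        if length_class_mix is None
        else np.asarray(length_class_mix, dtype=float)
    )
    if mix.shape != (len(ROH_CLASS_BOUNDS),) or abs(mix.sum() - 1) > 1e-9 or (mix < 0).any():
        raise ValueError("length_class_mix must be a distribution over the 5 classes")

    rng = np.random.default_rng(seed)
    geno = geno.copy()
    truth = replace(
        truth,
        true_het=truth.true_het.copy(),
        true_froh=truth.true_froh.copy(),
        planted_tracts={k: list(v) for k, v in truth.planted_tracts.items()},
    )
    total_len = geno.genome_length
    scaf_names = list(geno.scaffold_lengths)
    scaf_len = np.array([geno.scaffold_lengths[s] for s in scaf_names], dtype=float)

    targets = (
        froh_target
        if isinstance(froh_target, dict)
        else {s: float(froh_target) for s in (samples or geno.samples)}
    )
    for sample, target in targets.items():
        if not 0.0 <= target < 1.0:
            raise ValueError("froh_target must be in [0, 1)")
        if target == 0.0:
            continue
        i = geno.samples.index(sample)
        epoch = geno.epochs[i]
        lengths = _draw_tract_lengths(
            target * total_len, mix, max(geno.scaffold_lengths.values()), rng
        )
        occupied: dict[str, list[tuple[int, int]]] = {s: [] for s in scaf_names}
        tracts: list[tuple[str, int, int]] = []
        for length in sorted(lengths, reverse=True):
            placed = False
            for _ in range(500):
                s_idx = rng.choice(len(scaf_names), p=scaf_len / scaf_len.sum())
                name = scaf_names[s_idx]
                max_start = geno.scaffold_lengths[name] - length + 1
                if max_start < 1:
                    continue
                start = int(rng.integers(1, max_start + 1))
                end = start + length - 1
                if all(end < s0 or start > e0 for s0, e0 in occupied[name]):
                    occupied[name].append((start, end))
                    tracts.append((name, start, end))
                    placed = True
                    break
            if not placed:
                raise ValueError(
                    f"could not place a {length} bp tract for {sample}; "
                    "froh_target infeasible for the scaffold lengths"
                )
        freqs = geno.alt_freqs.get(epoch)
        for name, start, end in tracts:
            in_tract = (
                (geno.scaffolds == name)
                & (geno.positions >= start)
                & (geno.positions <= end)
            )
            idx = np.flatnonzero(in_tract)
            p_local = freqs[idx] if freqs is not None else np.full(idx.size, 0.5)
            geno.genotypes[i, idx] = 2 * (rng.random(idx.size) < p_local).astype(np.int8)
        truth.planted_tracts[sample] = truth.planted_tracts.get(sample, []) + tracts
        truth.true_froh[i] = (
            sum(e - s + 1 for _, s, e in truth.planted_tracts[sample]) / total_len
        )
        truth.true_het[i] = (geno.genotypes[i] == 1).mean()
    return geno, truth


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def simulate_reads(
    geno: GenotypeData,
    coverage: float | Sequence[float],
    error_rate: float,
    damage_rate: float | Sequence[float] = 0.0,
    seed: int = 0,
) -> Pileup:
    """Emit a read pileup: Poisson depth, uniform allele choice, error, damage.

    Per-site depth is Poisson(coverage); each read carries one of the two
    genotype alleles. Post-mortem damage is applied to the template first
    (a true C emitted as T and a true G as A with probability
    ``damage_rate``, strand-collapsed), then sequencing error flips the base
    to one of the three others with probability ``error_rate`` (uniformly).
    Qualities are recorded as the Phred equivalent of the error rate.
    """
    damage = np.asarray(damage_rate, dtype=float)
    if error_rate < 0 or np.any(damage < 0):
        raise ValueError("rates must be non-negative")
    cov = np.asarray(coverage, dtype=float)
    if np.any(cov < 0):
        raise ValueError("coverage must be >= 0")
    rng = np.random.default_rng(seed)
    N, S = geno.genotypes.shape
    cov = np.broadcast_to(cov, (N,)) if cov.ndim <= 1 and cov.size in (1, N) else cov
    depth = rng.poisson(np.broadcast_to(cov.reshape(-1, 1), (N, S)))
    g = np.maximum(geno.genotypes, 0)  # missing -> no reads drawn from alt
    depth = np.where(geno.genotypes < 0, 0, depth)

    n_alt = rng.binomial(depth, g / 2.0)
    true_counts = np.zeros((N, S, 4), dtype=np.int64)
    ii = np.arange(N)[:, None]
    ss = np.arange(S)[None, :]
    np.add.at(true_counts, (ii, ss, np.broadcast_to(geno.ref, (N, S))), depth - n_alt)
    np.add.at(true_counts, (ii, ss, np.broadcast_to(geno.alt, (N, S))), n_alt)

    if np.any(damage > 0):
        # per-individual damage (historic libraries only, typically)
        dmg_p = np.broadcast_to(damage.reshape(-1, 1), (N, S)) if damage.ndim else damage
        c_idx, g_idx, t_idx, a_idx = 1, 2, 3, 0
        dmg_c = rng.binomial(true_counts[:, :, c_idx], dmg_p)
        dmg_g = rng.binomial(true_counts[:, :, g_idx], dmg_p)
        true_counts[:, :, c_idx] -= dmg_c
        true_counts[:, :, t_idx] += dmg_c
        true_counts[:, :, g_idx] -= dmg_g
        true_counts[:, :, a_idx] += dmg_g

    obs = np.zeros_like(true_counts)
    if error_rate > 0:
        third = np.full(3, 1.0 / 3.0)
        for b in range(4):
            n = true_counts[:, :, b]
            keep = rng.binomial(n, 1.0 - error_rate)
            err = (n - keep).ravel()
            split = rng.multinomial(err, third).reshape(N, S, 3)
            obs[:, :, b] += keep
            others = [x for x in range(4) if x != b]
            for j, o in enumerate(others):
                obs[:, :, o] += split[:, :, j]
    else:
        obs = true_counts

    quality = 93.0 if error_rate == 0 else min(93.0, -10.0 * math.log10(error_rate))
    return Pileup(
        scaffolds=geno.scaffolds.copy(),
        positions=geno.positions.copy(),
        counts=obs.astype(np.int32),
        quality=quality,
        samples=list(geno.samples),
    )


# ---------------------------------------------------------------------------
# mitochondrial haplotypes
# ---------------------------------------------------------------------------

class MtRecord(NamedTuple):
    name: str
    epoch: str
    pop: str
    sequence: str


@dataclass
class MtSimulation:
    """Simulated epoch-labelled mitochondrial alignment with truth frequencies."""

    haplotypes: list[str]
    records: list[MtRecord]
    historic_freqs: np.ndarray
    contemporary_freqs: np.ndarray
    seed: int

    @property
    def truth_freqs(self) -> dict[str, np.ndarray]:
        return {"historic": self.historic_freqs, "contemporary": self.contemporary_freqs}


def simulate_mt_haplotypes(
    n_historic: int,
    n_contemporary: int,
    n_haplotypes: int,
    seq_length: int,
    seed: int = 0,
    historic_freqs: Sequence[float] | None = None,
    drop_rare: int = 0,
    mean_mutations: float = 2.0,
    pop: str = "POP1",
) -> MtSimulation:
    """Simulate epoch-labelled mitochondrial sequences.

    Haplotype sequences grow on a random genealogy: each new haplotype copies
    a uniformly chosen existing one and adds 1 + Poisson(mean_mutations)
    substitutions at previously unmutated positions, which guarantees all
    haplotypes are pairwise distinct. Historic haplotype frequencies default
    to a flat Dirichlet draw; the contemporary epoch loses the ``drop_rare``
    rarest haplotypes (frequencies renormalized), emulating diversity loss.
    """
    if n_haplotypes < 1:
        raise ValueError("n_haplotypes must be >= 1")
    if seq_length <= 0:
        raise ValueError("seq_length must be strictly positive")
    rng = np.random.default_rng(seed)
    root = rng.integers(0, 4, size=seq_length)
    haps = [root]
    free = list(rng.permutation(seq_length))
    for i in range(1, n_haplotypes):
        parent = haps[int(rng.integers(len(haps)))].copy()
        k = 1 + int(rng.poisson(mean_mutations))
        if k > len(free):
            raise ValueError("seq_length too short for distinct haplotypes")
        for _ in range(k):
            pos = free.pop()
            parent[pos] = (parent[pos] + int(rng.integers(1, 4))) % 4
        haps.append(parent)
    hap_seqs = ["".join(BASES[b] for b in h) for h in haps]

    if historic_freqs is None:
        fh = rng.dirichlet(np.ones(n_haplotypes))
    else:
        fh = np.asarray(historic_freqs, dtype=float)
        if fh.shape != (n_haplotypes,) or abs(fh.sum() - 1) > 1e-8:
            raise ValueError("historic_freqs must be a length-n_haplotypes distribution")
    if drop_rare < 0 or drop_rare >= n_haplotypes:
        if drop_rare != 0:
            raise ValueError("drop_rare must leave at least one haplotype")
    fc = fh.copy()
    if drop_rare:
        rare = np.argsort(fh, kind="stable")[:drop_rare]
        fc[rare] = 0.0
        fc /= fc.sum()

    records = []
    for epoch, n, freqs in (("historic", n_historic, fh), ("contemporary", n_contemporary, fc)):
        draws = rng.choice(n_haplotypes, size=n, p=freqs)
        for j, h in enumerate(draws):
            records.append(MtRecord(f"{epoch[:4]}_mt{j + 1}", epoch, pop, hap_seqs[int(h)]))
    return MtSimulation(
        haplotypes=hap_seqs,
        records=records,
        historic_freqs=fh,
        contemporary_freqs=fc,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# two-population panel (for structure analyses)
# ---------------------------------------------------------------------------

def simulate_two_populations(
    n_per_pop: tuple[int, int],
    n_sites: int,
    fst: float = 0.1,
    seed: int = 0,
    scaffold_length: int = 10_000_000,
) -> GenotypeData:
    """Balding-Nichols two-population genotype panel at a target FST.

    Ancestral frequencies are uniform on [0.1, 0.9]; each population's
    frequency is Beta(p(1-F)/F, (1-p)(1-F)/F). Population labels are stored
    in the epoch field ("pop1"/"pop2").
    """
    if not 0 < fst < 1:
        raise ValueError("fst must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.9, size=n_sites)
    coef = (1.0 - fst) / fst
    n1, n2 = n_per_pop
    genos = []
    for _ in range(2):
        pk = rng.beta(p * coef, (1 - p) * coef)
        genos.append(pk)
    g1 = rng.binomial(2, genos[0], size=(n1, n_sites)).astype(np.int8)
    g2 = rng.binomial(2, genos[1], size=(n2, n_sites)).astype(np.int8)
    positions = np.sort(rng.choice(scaffold_length, size=n_sites, replace=False)) + 1
    ref = rng.integers(0, 4, size=n_sites).astype(np.int8)
    alt = ((ref + rng.integers(1, 4, size=n_sites)) % 4).astype(np.int8)
    samples = [f"p1_{i + 1}" for i in range(n1)] + [f"p2_{i + 1}" for i in range(n2)]
    return GenotypeData(
        scaffolds=np.array(["scaf1"] * n_sites, dtype=object),
        positions=positions,
        ref=ref,
        alt=alt,
        genotypes=np.vstack([g1, g2]),
        samples=samples,
        epochs=["pop1"] * n1 + ["pop2"] * n2,
        scaffold_lengths={"scaf1": scaffold_length},
        alt_freqs={"pop1": genos[0], "pop2": genos[1]},
    )
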