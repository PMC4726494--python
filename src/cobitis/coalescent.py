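"""Coalescent TMRCA and θ estimation by sequential importance sampling.

The age of a clonal mitochondrial lineage is estimated from a sample of
haplotypes under the neutral Kingman coalescent with infinite-sites
mutation.  Time is measured in coalescent units of N_f generations (N_f =
female effective size for a haploid, maternally inherited locus), so that
while k lineages are ancestral, each pair coalesces at rate 1 and each
lineage mutates at rate θ/2, with θ = 2 N_f μ and μ the per-locus,
per-generation mutation rate.

The sample probability has no closed form for general data; it satisfies
the backward recursion over the most recent event (a coalescence of two
identical sequences, or the removal of the youngest mutation — necessarily
a site private to a singleton haplotype):

    n(n-1+θ) p(C) = Σ_{k: n_k≥2} n_k(n_k-1) p(C - e_k)
                  + θ Σ_{k: n_k=1, k has a private site} p(C with one
                    private site of k removed)

Sequential importance sampling follows Griffiths & Tavaré: propose the
backward event with probability proportional to its coefficient and
accumulate the ratio Σ coefficients / (n(n-1+θ)) as the particle weight.
Histories simulated at a single driving θ₀ are re-weighted to evaluate the
whole likelihood curve L(θ), from which the profile maximum is refined by
golden-section search.  The TMRCA posterior is the importance-weighted
distribution of simulated genealogy heights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.special import logsumexp


# ---------------------------------------------------------------------------
# data container

@dataclass
class HaplotypeSample:
    """Distinct haplotypes of a binary infinite-sites matrix, with multiplicities.

    ``site_matrix`` has one row per segregating site and one column per
    distinct haplotype (0 = ancestral, 1 = derived); ``multiplicities``
    gives the number of sampled copies of each distinct haplotype.
    """

    site_matrix: np.ndarray
    multiplicities: np.ndarray

    def __post_init__(self) -> None:
        self.site_matrix = np.asarray(self.site_matrix, dtype=np.int8)
        if self.site_matrix.ndim != 2:
            raise ValueError("site_matrix must be 2-D (sites x distinct haplotypes)")
        self.multiplicities = np.asarray(self.multiplicities, dtype=int)
        if self.multiplicities.ndim != 1 or len(self.multiplicities) != self.site_matrix.shape[1]:
            raise ValueError("multiplicities must have one entry per distinct haplotype")
        if (self.multiplicities < 1).any():
            raise ValueError("multiplicities must be >= 1")
        S, d = self.site_matrix.shape
        if S:
            counts = self.site_matrix @ self.multiplicities
            if (counts == 0).any() or (counts == self.n).any():
                raise ValueError("site_matrix contains an invariant column (non-segregating site)")
        # distinct haplotypes must really be distinct
        cols = {tuple(self.site_matrix[:, j]) for j in range(d)}
        if len(cols) != d:
            raise ValueError("duplicate haplotype columns; merge their multiplicities")

    @property
    def n(self) -> int:
        return int(self.multiplicities.sum())

    @property
    def n_sites(self) -> int:
        return int(self.site_matrix.shape[0])

    @property
    def n_distinct(self) -> int:
        return int(self.site_matrix.shape[1])

    @classmethod
    def from_sequences(cls, seqs: Sequence[Sequence[int]]) -> "HaplotypeSample":
        """Build from per-individual 0/1 site vectors (rows = individuals)."""
        arr = np.asarray(seqs, dtype=np.int8)
        if arr.ndim != 2:
            raise ValueError("expected a 2-D array of per-individual site vectors")
        # drop invariant columns, then collapse identical rows
        seg = (arr.sum(axis=0) > 0) & (arr.sum(axis=0) < arr.shape[0])
        arr = arr[:, seg]
        uniq, counts = np.unique(arr, axis=0, return_counts=True)
        return cls(uniq.T.copy(), counts)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "HaplotypeSample":
        """Read aligned sequences and reduce biallelic segregating sites to 0/1.

        The majority allele at each biallelic site is coded 0.  Sites with
        more than two observed bases are rejected (they violate the
        infinite-sites assumption outright).
        """
        from Bio import SeqIO

        seqs = [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]
        if not seqs:
            raise ValueError(f"no sequences in {path}")
        if len({len(s) for s in seqs}) != 1:
            raise ValueError("sequences are not aligned (unequal lengths)")
        n, L = len(seqs), len(seqs[0])
        cols = []
        for j in range(L):
            bases = [s[j] for s in seqs]
            alleles = sorted(set(bases) - {"-", "N"})
            if len(alleles) <= 1:
                continue
            if len(alleles) > 2:
                raise ValueError(f"site {j + 1} has {len(alleles)} alleles; infinite-sites reduction impossible")
            counts = {a: bases.count(a) for a in alleles}
            major = max(alleles, key=lambda a: (counts[a], a))
            cols.append([0 if b == major else 1 for b in bases])
        mat = np.array(cols, dtype=np.int8).reshape(len(cols), n)
        return cls.from_sequences(mat.T)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HaplotypeSample":
        """Read a plain 0/1 matrix (rows = individuals, columns = sites)."""
        arr = np.loadtxt(str(path), dtype=int, ndmin=2)
        return cls.from_sequences(arr)

    def expand(self) -> np.ndarray:
        """Full (sites x n) matrix with haplotypes repeated per multiplicity."""
        return np.repeat(self.site_matrix, self.multiplicities, axis=1)


# ---------------------------------------------------------------------------
# infinite-sites compatibility

def check_infinite_sites(sample: HaplotypeSample) -> tuple[bool, list[tuple[int, int]]]:
    """Four-gamete test over all site pairs.

    Returns (True, []) when every pair of sites shows at most three of the
    four gametes 00/01/10/11 among the sampled sequences; otherwise returns
    False together with the conflicting (i, j) site index pairs.
    """
    M = sample.site_matrix
    w = sample.multiplicities
    conflicts: list[tuple[int, int]] = []
    S = M.shape[0]
    for i in range(S):
        for j in range(i + 1, S):
            a, b = M[i], M[j]
            gametes = {(int(x), int(y)) for x, y, m in zip(a, b, w) if m > 0}
            if len(gametes) == 4:
                conflicts.append((i, j))
    return (not conflicts), conflicts


def rooted_compatible(sample: HaplotypeSample) -> bool:
    """True iff the data admit a rooted perfect phylogeny (all-ancestral root).

    Stricter than the four-gamete test: derived-carrier sets of any two
    sites must be nested or disjoint.
    """
    M = sample.expand()
    carriers = [frozenset(np.nonzero(M[i])[0].tolist()) for i in range(M.shape[0])]
    for i in range(len(carriers)):
        for j in range(i + 1, len(carriers)):
            a, b = carriers[i], carriers[j]
            inter = a & b
            if inter and not (a <= b or b <= a):
                return False
    return True


# ---------------------------------------------------------------------------
# Ewens infinite-alleles cross-check

@dataclass(frozen=True)
class EwensTheta:
    theta: float
    unbounded: bool = False


def ewens_ml_theta(n: int, k: int) -> EwensTheta:
    """ML θ under the infinite-alleles model from the number of distinct haplotypes.

    Solves E[K] = Σ_{i=0}^{n-1} θ/(θ+i) = k.  k=1 gives θ=0; k=n has no
    finite maximum (the expected allele count approaches n only as θ→∞)
    and is flagged ``unbounded``.
    """
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    if k == 1:
        return EwensTheta(0.0)
    if k == n:
        return EwensTheta(math.inf, unbounded=True)

    def expected_k(theta: float) -> float:
        return sum(theta / (theta + i) for i in range(n))

    lo, hi = 1e-12, 1.0
    while expected_k(hi) < k:
        hi *= 2.0
    theta = brentq(lambda t: expected_k(t) - k, lo, hi, xtol=1e-12, rtol=1e-12)
    return EwensTheta(float(theta))


# ---------------------------------------------------------------------------
# SIS core

@dataclass
class _ParticleStats:
    """Sufficient statistics of one simulated backward history."""

    n_mut: int
    coal_logsum: float          # Σ log n_k(n_k-1) over chosen coalescences
    level_counts: np.ndarray    # number of steps taken while n = k (index k)
    log_q: float                # proposal log-probability (at the driving θ)
    height: float               # simulated genealogy height (coalescent units)
    stuck: bool


def _state_from_sample(sample: HaplotypeSample) -> dict[frozenset, int]:
    state: dict[frozenset, int] = {}
    for j in range(sample.n_distinct):
        hap = frozenset(np.nonzero(sample.site_matrix[:, j])[0].tolist())
        state[hap] = int(sample.multiplicities[j])
    return state


def _enumerate_moves(state: dict[frozenset, int], theta: float):
    """Backward moves: (coefficient, kind, payload)."""
    moves = []
    types = list(state.items())
    for hap, mult in types:
        if mult >= 2:
            moves.append((mult * (mult - 1), "coal", hap))
    if theta > 0:
        for hap, mult in types:
            if mult == 1 and hap:
                others = set()
                for other, _ in types:
                    if other is not hap:
                        others |= other
                private = hap - others
                if private:
                    moves.append((theta, "mut", (hap, max(private))))
    return moves


def _run_particles(
    sample: HaplotypeSample,
    theta0: float,
    n_particles: int,
    rng: np.random.Generator,
) -> list[_ParticleStats]:
    """Simulate backward histories at driving value θ₀."""
    n0 = sample.n
    base_state = _state_from_sample(sample)
    out: list[_ParticleStats] = []
    for _ in range(n_particles):
        state = dict(base_state)
        n = n0
        n_mut = 0
        coal_logsum = 0.0
        level_counts = np.zeros(n0 + 1, dtype=np.int64)
        log_q = 0.0
        height = 0.0
        stuck = False
        # terminal state: a single all-ancestral lineage (MRCA reached, no
        # segregating mutations left to explain)
        while n > 1 or any(state):
            moves = _enumerate_moves(state, theta0)
            if not moves:
                stuck = True
                break
            total = sum(m[0] for m in moves)
            r = rng.random() * total
            acc = 0.0
            for coef, kind, payload in moves:
                acc += coef
                if r < acc:
                    break
            log_q += math.log(coef / total)
            level_counts[n] += 1
            height += rng.exponential(2.0 / (n * (n - 1 + theta0)))
            if kind == "coal":
                hap = payload
                mult = state[hap]
                coal_logsum += math.log(mult * (mult - 1))
                state[hap] = mult - 1
                n -= 1
            else:
                hap, site = payload
                n_mut += 1
                newhap = hap - {site}
                del state[hap]
                state[newhap] = state.get(newhap, 0) + 1
        out.append(_ParticleStats(n_mut, coal_logsum, level_counts, log_q, height, stuck))
    return out


def _log_weights(stats: list[_ParticleStats], theta: float, n0: int) -> np.ndarray:
    """Re-weight recorded histories to mutation rate θ."""
    ks = np.arange(n0 + 1, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_rates = np.log(np.maximum(ks * (ks - 1 + theta), 1e-300))
    out = np.empty(len(stats))
    log_theta = math.log(theta) if theta > 0 else -math.inf
    for i, st in enumerate(stats):
        if st.stuck or (theta == 0.0 and st.n_mut > 0):
            out[i] = -math.inf
            continue
        lp = st.coal_logsum + st.n_mut * log_theta - float(st.level_counts @ log_rates)
        out[i] = lp - st.log_q
    return out


@dataclass(frozen=True)
class SisLoglik:
    loglik: float
    mc_se: float            # std. error of log L-hat (delta method)
    n_particles: int
    theta: float
    seed: int


def _loglik_from_logw(logw: np.ndarray) -> tuple[float, float]:
    N = len(logw)
    finite = np.isfinite(logw)
    if not finite.any():
        return -math.inf, math.inf
    log_mean = logsumexp(logw[finite]) - math.log(N)
    # SE of L-hat / L-hat
    log_sq = logsumexp(2 * logw[finite]) - math.log(N)
    var = math.exp(log_sq) - math.exp(2 * log_mean)
    se_rel = math.sqrt(max(var, 0.0) / N) / math.exp(log_mean)
    return float(log_mean), float(se_rel)


def sis_loglik(
    sample: HaplotypeSample,
    theta: float,
    n_particles: int = 100_000,
    seed: int = 0,
) -> SisLoglik:
    """Importance-sampling estimate of the log sample probability at θ.

    The estimator of the likelihood itself (not its log) is unbiased.
    Rejects samples that fail the four-gamete/rooted-compatibility checks;
    θ=0 with segregating sites present gives log-likelihood -inf.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    ok, conflicts = check_infinite_sites(sample)
    if not ok or not rooted_compatible(sample):
        raise ValueError(f"sample violates the infinite-sites model (conflicting site pairs: {conflicts})")
    if theta == 0.0:
        if sample.n_sites > 0:
            return SisLoglik(-math.inf, math.inf, n_particles, theta, seed)
        return SisLoglik(0.0, 0.0, n_particles, theta, seed)
    rng = np.random.default_rng(seed)
    stats = _run_particles(sample, theta, n_particles, rng)
    logw = _log_weights(stats, theta, sample.n)
    ll, se = _loglik_from_logw(logw)
    return SisLoglik(ll, se, n_particles, theta, seed)


# ---------------------------------------------------------------------------
# θ profile

@dataclass
class ThetaEstimate:
    theta_hat: float
    grid: np.ndarray
    loglik: np.ndarray
    mc_se: np.ndarray
    driving_theta: float
    n_particles: int
    seed: int
    support2_low: float = math.nan   # θ range with log L within 2 units of max
    support2_high: float = math.nan


def watterson_theta(sample: HaplotypeSample) -> float:
    """Watterson's moment estimator, used as the SIS driving value."""
    n = sample.n
    h = sum(1.0 / i for i in range(1, n))
    return sample.n_sites / h if h > 0 else 0.0


def ml_theta_profile(
    sample: HaplotypeSample,
    theta_grid: Optional[Sequence[float]] = None,
    n_particles: int = 100_000,
    seed: int = 0,
    refine: bool = True,
) -> ThetaEstimate:
    """Profile the SIS likelihood over a θ grid and locate the maximum.

    Histories are simulated once at a driving θ₀ (Watterson's estimate,
    or the grid median for monomorphic data) and re-weighted across the
    grid, so all grid points share common random histories.  The grid
    maximum is refined by golden-section search on the continuous
    re-weighted curve.
    """
    ok, conflicts = check_infinite_sites(sample)
    if not ok or not rooted_compatible(sample):
        raise ValueError(f"sample violates the infinite-sites model (conflicting site pairs: {conflicts})")
    if theta_grid is None:
        tw = watterson_theta(sample)
        center = tw if tw > 0 else 0.1
        theta_grid = np.geomspace(center / 10.0, center * 10.0, 21)
    grid = np.asarray(sorted(float(t) for t in theta_grid))
    if grid.size == 0:
        raise ValueError("theta grid must be non-empty")
    if (grid <= 0).any():
        raise ValueError("theta grid values must be > 0")
    theta0 = watterson_theta(sample)
    if theta0 <= 0:
        theta0 = float(np.median(grid))
    rng = np.random.default_rng(seed)
    stats = _run_particles(sample, theta0, n_particles, rng)
    n0 = sample.n

    lls = np.empty(grid.size)
    ses = np.empty(grid.size)
    for i, t in enumerate(grid):
        lls[i], ses[i] = _loglik_from_logw(_log_weights(stats, t, n0))

    best = int(np.argmax(lls))
    theta_hat = float(grid[best])
    if refine and grid.size >= 2 and sample.n_sites > 0:
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, grid.size - 1)]
        if hi > lo:
            res = minimize_scalar(
                lambda t: -_loglik_from_logw(_log_weights(stats, float(t), n0))[0],
                bounds=(float(lo), float(hi)),
                method="bounded",
                options={"xatol": 1e-4 * float(hi)},
            )
            if res.success and -res.fun >= lls[best]:
                theta_hat = float(res.x)

    # 2-log-unit support interval from the grid curve
    mask = lls >= lls[best] - 2.0
    s_lo = float(grid[mask][0]) if mask.any() else math.nan
    s_hi = float(grid[mask][-1]) if mask.any() else math.nan
    return ThetaEstimate(theta_hat, grid, lls, ses, theta0, n_particles, seed, s_lo, s_hi)


# ---------------------------------------------------------------------------
# TMRCA posterior

@dataclass(frozen=True)
class TmrcaEstimate:
    mean: float
    ci_low: float
    ci_high: float
    n_particles: int
    seed: int
    ess: float      # effective sample size of the importance weights


def weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Inverse of the cumulative normalized weight function; ties -> midpoint."""
    order = np.argsort(values)
    v = np.asarray(values, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    cw = np.cumsum(w)
    cw /= cw[-1]
    idx = int(np.searchsorted(cw, q, side="left"))
    idx = min(idx, len(v) - 1)
    if idx > 0 and math.isclose(cw[idx - 1], q, rel_tol=0.0, abs_tol=1e-12):
        return 0.5 * (v[idx - 1] + v[idx])
    return float(v[idx])


@dataclass
class JointTmrcaSamples:
    """Pooled (TMRCA, θ) posterior draws with importance weights.

    θ values are drawn from the normalized profile likelihood over its grid
    (a flat prior on the grid); conditional TMRCA particles are simulated at
    each drawn θ and pooled with their importance weights.  This propagates
    θ uncertainty into downstream unit conversions.
    """

    heights: np.ndarray
    thetas: np.ndarray          # θ draw attached to each pooled height
    weights: np.ndarray         # normalized within each θ block, / n_draws
    n_theta_draws: int
    seed: int


def tmrca_theta_joint(
    sample: HaplotypeSample,
    profile: "ThetaEstimate",
    n_theta_draws: int = 8,
    n_particles: int = 3000,
    seed: int = 0,
) -> JointTmrcaSamples:
    """Joint (TMRCA, θ) posterior by pooling conditional SIS runs."""
    rng = np.random.default_rng(seed)
    w = np.exp(profile.loglik - profile.loglik.max())
    w = w / w.sum()
    draws = rng.choice(profile.grid, size=n_theta_draws, p=w)
    hs, ths, ws = [], [], []
    for k, th in enumerate(draws):
        th = float(th)
        stats = _run_particles(sample, th, n_particles,
                               np.random.default_rng(rng.integers(2**31)))
        logw = _log_weights(stats, th, sample.n)
        finite = np.isfinite(logw)
        if not finite.any():
            continue
        ww = np.exp(logw[finite] - logw[finite].max())
        ww = ww / ww.sum() / n_theta_draws
        hs.append(np.array([s.height for s in stats])[finite])
        ths.append(np.full(finite.sum(), th))
        ws.append(ww)
    if not hs:
        raise RuntimeError("no finite-weight particles in any conditional run")
    return JointTmrcaSamples(np.concatenate(hs), np.concatenate(ths),
                             np.concatenate(ws), n_theta_draws, seed)


def tmrca_posterior(
    sample: HaplotypeSample,
    theta: float,
    n_particles: int = 100_000,
    seed: int = 0,
) -> TmrcaEstimate:
    """Importance-weighted posterior mean and 95% interval of the TMRCA.

    Times are in coalescent units of N_f generations.  Genealogy heights
    are simulated jointly with the backward histories at the given θ and
    weighted by the importance weights.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    ok, conflicts = check_infinite_sites(sample)
    if not ok or not rooted_compatible(sample):
        raise ValueError(f"sample violates the infinite-sites model (conflicting site pairs: {conflicts})")
    if theta == 0.0 and sample.n_sites > 0:
        raise ValueError("theta = 0 is incompatible with segregating sites")
    rng = np.random.default_rng(seed)
    theta_run = theta if theta > 0 else 1e-12
    stats = _run_particles(sample, theta_run, n_particles, rng)
    logw = _log_weights(stats, theta_run, sample.n)
    heights = np.array([s.height for s in stats])
    finite = np.isfinite(logw)
    if not finite.any():
        raise RuntimeError("all particles received zero weight; data incompatible?")
    w = np.exp(logw[finite] - logw[finite].max())
    h = heights[finite]
    w_norm = w / w.sum()
    mean = float(np.sum(w_norm * h))
    lo = weighted_quantile(h, w, 0.025)
    hi = weighted_quantile(h, w, 0.975)
    ess = float(1.0 / np.sum(w_norm**2))
    return TmrcaEstimate(mean, lo, hi, n_particles, seed, ess)
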