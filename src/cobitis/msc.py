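"""Speciation-time estimation under the multispecies coalescent (MSC).

Divergence times of the three sexual species are estimated from multilocus
nuclear alignments on the fixed species topology ((taenia, tanaitica),
elongatoides), abbreviated ((T,N),E).  The model parameters are the two
divergence times τ_TN < τ_TNE, measured in expected substitutions per
site, and five population-size parameters θ = 4·N_e·μ (one per extant
species and one per ancestral population).  Within each species-tree
branch, gene-tree lineages coalesce pairwise at rate 2/θ (time in
substitution units); sequences evolve along gene trees under JC69, with
per-locus rate scalars carrying among-locus rate variation.

Inference is Metropolis-within-Gibbs: per-locus gene-tree updates
(node-time slides and narrow exchanges), θ multiplier updates, and τ
"rubber-band" slides that rescale the coalescent times contained in the
affected populations, as in standard MSC samplers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

SPECIES = ("T", "N", "E")
THETA_KEYS = ("theta_T", "theta_N", "theta_E", "theta_TN", "theta_TNE")
PARAM_KEYS = ("tau_TN", "tau_TNE") + THETA_KEYS

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


# ---------------------------------------------------------------------------
# containers

@dataclass
class MscModel:
    """Fixed ((T,N),E) species tree with divergence times and θ parameters."""

    tau_TN: float
    tau_TNE: float
    theta_T: float
    theta_N: float
    theta_E: float
    theta_TN: float
    theta_TNE: float

    def __post_init__(self) -> None:
        if not 0 < self.tau_TN < self.tau_TNE:
            raise ValueError("need 0 < tau_TN < tau_TNE")
        for k in THETA_KEYS:
            if getattr(self, k) <= 0:
                raise ValueError(f"{k} must be > 0")

    def theta(self, pop: str) -> float:
        return getattr(self, f"theta_{pop}")

    def as_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in PARAM_KEYS}


@dataclass
class LocusAlignment:
    """One aligned nuclear locus with a sequence->species map and rate scalar."""

    names: list[str]
    sequences: np.ndarray          # (n_seqs, L) int8 codes 0..3; -1 = missing
    species_map: dict[str, str]
    rate_scalar: float = 1.0

    def __post_init__(self) -> None:
        self.sequences = np.asarray(self.sequences, dtype=np.int8)
        if self.sequences.ndim != 2 or self.sequences.shape[0] != len(self.names):
            raise ValueError("sequences must be (n_seqs, L) aligned to names")
        for nm in self.names:
            if nm not in self.species_map:
                raise ValueError(f"sequence {nm!r} missing from species map")
        if self.rate_scalar <= 0:
            raise ValueError("rate scalar must be > 0")

    @property
    def length(self) -> int:
        return int(self.sequences.shape[1])

    def species_of(self, name: str) -> str:
        return self.species_map[name]

    def subset(self, keep: Iterable[str]) -> "LocusAlignment":
        keep = list(keep)
        idx = [self.names.index(nm) for nm in keep]
        return LocusAlignment(keep, self.sequences[idx].copy(),
                              {nm: self.species_map[nm] for nm in keep},
                              self.rate_scalar)

    def drop_species(self, species: str) -> "LocusAlignment":
        keep = [nm for nm in self.names if self.species_map[nm] != species]
        return self.subset(keep)

    @classmethod
    def from_fasta(cls, path: str | Path, species_map: dict[str, str],
                   rate_scalar: float = 1.0) -> "LocusAlignment":
        from Bio import SeqIO

        names, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            names.append(rec.id)
            rows.append([_BASE_CODE.get(b, -1) for b in str(rec.seq).upper()])
        if not names:
            raise ValueError(f"no sequences in {path}")
        if len({len(r) for r in rows}) != 1:
            raise ValueError(f"unequal sequence lengths in {path}")
        return cls(names, np.array(rows, dtype=np.int8), species_map, rate_scalar)

    def to_fasta(self, path: str | Path) -> None:
        letters = np.array(list("ACGT"))
        with open(path, "w") as fh:
            for nm, row in zip(self.names, self.sequences):
                seq = "".join("N" if b < 0 else letters[b] for b in row)
                fh.write(f">{nm}\n{seq}\n")

    def site_patterns(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique site columns and their counts, for likelihood compression."""
        if self.length == 0:
            return np.zeros((self.sequences.shape[0], 0), dtype=np.int8), np.zeros(0, dtype=int)
        patterns, counts = np.unique(self.sequences, axis=1, return_counts=True)
        return patterns, counts


# ---------------------------------------------------------------------------
# gene trees

class GeneTree:
    """Rooted binary gene tree: tips 0..n_tips-1, internal nodes above.

    ``time`` holds node ages in expected-substitution units (tips at 0);
    ``parent[root] = -1``.
    """

    def __init__(self, tip_labels: Sequence[str], parent: np.ndarray, time: np.ndarray):
        self.tip_labels = list(tip_labels)
        self.parent = np.asarray(parent, dtype=int)
        self.time = np.asarray(time, dtype=float)
        self.n_tips = len(self.tip_labels)
        if len(self.parent) != len(self.time) or len(self.parent) != 2 * self.n_tips - 1:
            raise ValueError("parent/time arrays must have 2*n_tips-1 entries")
        self._rebuild_children()

    def _rebuild_children(self) -> None:
        n = len(self.parent)
        self.children: list[list[int]] = [[] for _ in range(n)]
        root = -1
        for v in range(n):
            p = self.parent[v]
            if p < 0:
                root = v
            else:
                self.children[p].append(v)
        self.root = root
        # topology-dependent caches (node times do not affect these)
        out, stack = [], [self.root]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(self.children[v])
        self._preorder = out
        self._postorder = out[::-1]

    @classmethod
    def from_parent_map(cls, tip_labels: Sequence[str], node_time: dict[int, float],
                        parent_map: dict[int, int],
                        tip_ids: Optional[Sequence[int]] = None) -> "GeneTree":
        if tip_ids is None:
            tip_ids = list(range(len(tip_labels)))
        internal = sorted(set(node_time) - set(tip_ids), key=lambda v: node_time[v])
        order = list(tip_ids) + internal
        remap = {old: new for new, old in enumerate(order)}
        n = len(order)
        parent = np.full(n, -1, dtype=int)
        time = np.zeros(n)
        for old, new in remap.items():
            time[new] = node_time[old]
            if old in parent_map:
                parent[new] = remap[parent_map[old]]
        return cls(tip_labels, parent, time)

    def copy(self) -> "GeneTree":
        return GeneTree(self.tip_labels, self.parent.copy(), self.time.copy())

    def preorder(self) -> list[int]:
        return self._preorder

    def postorder(self) -> list[int]:
        return self._postorder

    def branch_lengths(self) -> np.ndarray:
        bl = np.zeros(len(self.parent))
        for v in range(len(self.parent)):
            p = self.parent[v]
            if p >= 0:
                bl[v] = self.time[p] - self.time[v]
        return bl

    def is_valid(self) -> bool:
        return all(self.time[self.parent[v]] > self.time[v]
                   for v in range(len(self.parent)) if self.parent[v] >= 0)

    def newick(self) -> str:
        def rec(v: int) -> str:
            if not self.children[v]:
                lab = self.tip_labels[v]
                blen = self.time[self.parent[v]] - self.time[v] if self.parent[v] >= 0 else 0.0
                return f"{lab}:{blen:.8g}"
            inner = ",".join(rec(c) for c in self.children[v])
            if self.parent[v] >= 0:
                blen = self.time[self.parent[v]] - self.time[v]
                return f"({inner}):{blen:.8g}"
            return f"({inner})"
        return rec(self.root) + ";"


# ---------------------------------------------------------------------------
# JC69 likelihood

def _jc_transform(partial: np.ndarray, d: float) -> np.ndarray:
    """Apply the JC69 transition operator over branch length d to partials.

    (P_d v)_x = e·v_x + (1-e)/4 · Σ_y v_y  with e = exp(-4d/3).
    """
    e = math.exp(-4.0 * max(d, 0.0) / 3.0)
    s = partial.sum(axis=1, keepdims=True)
    return e * partial + (1.0 - e) * 0.25 * s


def jc69_loglik(tree: GeneTree, alignment: LocusAlignment) -> float:
    """Felsenstein-pruning log-likelihood under JC69 with uniform base frequencies.

    Branch lengths are node-time differences multiplied by the locus rate
    scalar.  Missing bases (-1) are treated as fully ambiguous.  An empty
    alignment has log-likelihood 0 (prior-only runs).
    """
    patterns, counts = alignment.site_patterns()
    return _jc69_loglik_patterns(tree, alignment, patterns, counts)


def _tip_partials(tree: GeneTree, alignment: LocusAlignment,
                  patterns: np.ndarray) -> list:
    """Per-node conditional likelihood arrays for tips (constant per locus)."""
    npat = patterns.shape[1]
    name_to_row = {nm: i for i, nm in enumerate(alignment.names)}
    out = [None] * len(tree.parent)
    for v in range(len(tree.parent)):
        if not tree.children[v]:
            obs = patterns[name_to_row[tree.tip_labels[v]]]
            tip = np.zeros((npat, 4))
            miss = obs < 0
            tip[np.arange(npat)[~miss], obs[~miss]] = 1.0
            tip[miss] = 1.0
            out[v] = tip
    return out


def _jc69_loglik_cached(tree: GeneTree, scalar: float, tips: list,
                        counts: np.ndarray) -> float:
    partials = list(tips)
    time = tree.time
    for v in tree.postorder():
        kids = tree.children[v]
        if not kids:
            continue
        tv = time[v]
        c0, c1 = kids[0], kids[1]
        prod = (_jc_transform(partials[c0], (tv - time[c0]) * scalar)
                * _jc_transform(partials[c1], (tv - time[c1]) * scalar))
        partials[v] = prod
    site_lik = 0.25 * partials[tree.root].sum(axis=1)
    if (site_lik <= 0).any():
        return -math.inf
    return float(np.dot(counts, np.log(site_lik)))


def _jc69_loglik_patterns(tree: GeneTree, alignment: LocusAlignment,
                          patterns: np.ndarray, counts: np.ndarray) -> float:
    if patterns.shape[1] == 0:
        return 0.0
    tips = _tip_partials(tree, alignment, patterns)
    return _jc69_loglik_cached(tree, alignment.rate_scalar, tips, counts)


# ---------------------------------------------------------------------------
# rate scalars

def jc_distance(p: float) -> float:
    """JC69-corrected distance from a proportion of differing sites."""
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def _pairwise_p(a: np.ndarray, b: np.ndarray) -> float:
    valid = (a >= 0) & (b >= 0)
    if not valid.any():
        return math.nan
    return float((a[valid] != b[valid]).mean())


def compute_rate_scalars(loci: Sequence[LocusAlignment], outgroup_species: str = "OUT",
                         corrected: bool = True) -> np.ndarray:
    """Per-locus mutation-rate scalars from ingroup-vs-outgroup distances.

    scalar_i = (mean ingroup-outgroup distance at locus i) / (grand mean
    over loci); the scalars average to 1.  Distances are JC-corrected by
    default (``corrected=False`` uses raw p-distances).
    """
    means = []
    for idx, locus in enumerate(loci):
        og = [i for i, nm in enumerate(locus.names) if locus.species_of(nm) == outgroup_species]
        ig = [i for i, nm in enumerate(locus.names) if locus.species_of(nm) != outgroup_species]
        if not og:
            raise ValueError(f"locus {idx} has no outgroup ({outgroup_species!r}) sequence")
        ds = []
        for i in ig:
            for j in og:
                p = _pairwise_p(locus.sequences[i], locus.sequences[j])
                ds.append(jc_distance(p) if corrected else p)
        means.append(float(np.mean(ds)))
    means = np.asarray(means)
    if means.mean() <= 0:
        raise ValueError("degenerate distances; cannot normalize scalars")
    return means / means.mean()


# ---------------------------------------------------------------------------
# MSC density

_SPECIES_BIT = {"T": 1, "N": 2, "E": 4}
_POPS = ("T", "N", "E", "TN", "TNE")


def species_masks(tree: GeneTree, species_of_tip: dict[str, str]) -> np.ndarray:
    """Bitmask of descendant species per node (T=1, N=2, E=4)."""
    masks = np.zeros(len(tree.parent), dtype=np.int8)
    for v in tree.postorder():
        if not tree.children[v]:
            masks[v] = _SPECIES_BIT[species_of_tip[tree.tip_labels[v]]]
        else:
            m = 0
            for c in tree.children[v]:
                m |= masks[c]
            masks[v] = m
    return masks


def _pop_of_mask(mask: int, t: float, tau2: float, tau3: float) -> Optional[str]:
    if mask == 4:
        return "E" if t < tau3 else "TNE"
    if mask in (1, 2):
        if t < tau2:
            return "T" if mask == 1 else "N"
        return "TN" if t < tau3 else "TNE"
    if mask == 3:
        if t < tau2:
            return None
        return "TN" if t < tau3 else "TNE"
    return "TNE" if t >= tau3 else None


def node_species_sets(tree: GeneTree, species_of_tip: dict[str, str]) -> list[frozenset]:
    masks = species_masks(tree, species_of_tip)
    bit_to_sp = {1: "T", 2: "N", 4: "E"}
    return [frozenset(sp for b, sp in bit_to_sp.items() if m & b) for m in masks]


def msc_log_density(tree: GeneTree, species_of_tip: dict[str, str],
                    model: MscModel) -> float:
    """Log density of a gene tree under the ((T,N),E) multispecies coalescent.

    Returns -inf for gene trees that are impossible under the species tree
    (e.g. an inter-species coalescence below the relevant τ).
    """
    return _msc_logdens_masks(tree, species_masks(tree, species_of_tip), model)


_POP_INDEX = {p: i for i, p in enumerate(_POPS)}


def _msc_stats(tree: GeneTree, masks: np.ndarray, tau2: float, tau3: float):
    """Per-population sufficient statistics of the MSC density.

    Returns (n_coal[5], W[5]) with pops ordered T,N,E,TN,TNE, where W_p is
    ∫ k(k-1) dt over the population's presence intervals; or None when the
    gene tree is impossible under the species tree.  The log density is
    then Σ_p n_coal_p·log(2/θ_p) − W_p/θ_p.
    """
    times = tree.time
    parent = tree.parent
    n = len(parent)
    segs: list[list] = [[], [], [], [], []]
    for v in range(n):
        p = parent[v]
        if p < 0:
            continue
        t0 = times[v]
        t1 = times[p]
        if t1 <= t0:
            return None
        m = masks[v]
        if m == 4:
            if t0 < tau3:
                segs[2].append((t0, min(t1, tau3)))
            if t1 > tau3:
                segs[4].append((max(t0, tau3), t1))
        elif m == 1 or m == 2:
            if t0 < tau2:
                segs[m - 1].append((t0, min(t1, tau2)))
            if t1 > tau2 and t0 < tau3:
                segs[3].append((max(t0, tau2), min(t1, tau3)))
            if t1 > tau3:
                segs[4].append((max(t0, tau3), t1))
        elif m == 3:
            if t0 < tau2:
                return None
            if t0 < tau3:
                segs[3].append((t0, min(t1, tau3)))
            if t1 > tau3:
                segs[4].append((max(t0, tau3), t1))
        else:
            if t0 < tau3:
                return None
            segs[4].append((t0, t1))
    ncoal = np.zeros(5)
    for v in range(n):
        if tree.children[v]:
            pop = _pop_of_mask(masks[v], times[v], tau2, tau3)
            if pop is None:
                return None
            ncoal[_POP_INDEX[pop]] += 1
    W = np.zeros(5)
    for pi in range(5):
        intervals = segs[pi]
        if len(intervals) < 2:
            continue
        pts = sorted({t for iv in intervals for t in iv})
        acc = 0.0
        for a, b in zip(pts[:-1], pts[1:]):
            mid = 0.5 * (a + b)
            k = 0
            for lo, hi in intervals:
                if lo <= mid < hi:
                    k += 1
            if k >= 2:
                acc += k * (k - 1) * (b - a)
        W[pi] = acc
    return ncoal, W


def _logdens_from_stats(stats, model: MscModel) -> float:
    if stats is None:
        return -math.inf
    ncoal, W = stats
    thetas = np.array([model.theta_T, model.theta_N, model.theta_E,
                       model.theta_TN, model.theta_TNE])
    return float(np.sum(ncoal * np.log(2.0 / thetas)) - np.sum(W / thetas))


def _msc_logdens_masks(tree: GeneTree, masks: np.ndarray, model: MscModel) -> float:
    return _logdens_from_stats(
        _msc_stats(tree, masks, model.tau_TN, model.tau_TNE), model)


# ---------------------------------------------------------------------------
# prior sampling of gene trees (used for chain initialization)

def sample_gene_tree(species_of_tip: dict[str, str], tip_labels: Sequence[str],
                     model: MscModel, rng: np.random.Generator) -> GeneTree:
    """Draw a gene tree from the MSC prior given the species assignment."""
    node_time = {i: 0.0 for i in range(len(tip_labels))}
    parent: dict[int, int] = {}
    nxt = len(tip_labels)

    def coalesce(lineages: list[int], theta: float, t0: float, t1: float) -> list[int]:
        nonlocal nxt
        t = t0
        lineages = list(lineages)
        while len(lineages) > 1:
            k = len(lineages)
            t += rng.exponential(theta / (k * (k - 1)))
            if t >= t1:
                break
            i, j = rng.choice(k, size=2, replace=False)
            a, b = lineages[i], lineages[j]
            node_time[nxt] = t
            parent[a] = nxt
            parent[b] = nxt
            lineages = [x for x in lineages if x not in (a, b)] + [nxt]
            nxt += 1
        return lineages

    by_sp = {sp: [i for i, nm in enumerate(tip_labels) if species_of_tip[nm] == sp]
             for sp in SPECIES}
    t_lin = coalesce(by_sp["T"], model.theta_T, 0.0, model.tau_TN)
    n_lin = coalesce(by_sp["N"], model.theta_N, 0.0, model.tau_TN)
    e_lin = coalesce(by_sp["E"], model.theta_E, 0.0, model.tau_TNE)
    tn_lin = coalesce(t_lin + n_lin, model.theta_TN, model.tau_TN, model.tau_TNE)
    coalesce(tn_lin + e_lin, model.theta_TNE, model.tau_TNE, math.inf)
    return GeneTree.from_parent_map(tip_labels, node_time, parent)


# ---------------------------------------------------------------------------
# priors and chain configuration

@dataclass
class MscPriors:
    """Gamma(2, 2/mean) priors on τ_TNE and each θ; τ_TN/τ_TNE ~ U(0,1)."""

    tau_mean: float
    theta_mean: float

    @classmethod
    def from_data(cls, loci: Sequence[LocusAlignment]) -> "MscPriors":
        """Heuristic hyper-means: within-species diversity for θ̄ and half the
        deepest between-species distance for τ̄."""
        within, between = [], []
        for locus in loci:
            for i in range(len(locus.names)):
                for j in range(i + 1, len(locus.names)):
                    si = locus.species_of(locus.names[i])
                    sj = locus.species_of(locus.names[j])
                    if si not in SPECIES or sj not in SPECIES:
                        continue
                    p = _pairwise_p(locus.sequences[i], locus.sequences[j])
                    d = jc_distance(p)
                    (within if si == sj else between).append(d)
        theta_mean = max(float(np.mean(within)) if within else 1e-3, 1e-4)
        tau_mean = max(float(np.mean(between)) / 2.0 if between else 1e-2, 1e-3)
        return cls(tau_mean=tau_mean, theta_mean=theta_mean)

    def log_prior(self, model: MscModel) -> float:
        # Gamma(shape=2, rate=2/mean): log f = log(rate^2 x e^{-rate x})
        lp = 0.0
        r = 2.0 / self.tau_mean
        lp += 2.0 * math.log(r) + math.log(model.tau_TNE) - r * model.tau_TNE - math.lgamma(2.0)
        lp -= math.log(model.tau_TNE)  # tau_TN | tau_TNE ~ U(0, tau_TNE)
        rt = 2.0 / self.theta_mean
        for k in THETA_KEYS:
            th = getattr(model, k)
            lp += 2.0 * math.log(rt) + math.log(th) - rt * th - math.lgamma(2.0)
        return lp


@dataclass
class ChainConfig:
    n_iter: int = 6000
    burnin_frac: float = 0.25
    thin_to: int = 2000
    slides_per_locus: int = 2
    exchanges_per_locus: int = 1
    ess_floor: float = 50.0
    tune: bool = True


@dataclass
class PosteriorSummary:
    """Means, 95% equal-tail intervals and ESS per parameter."""

    table: pd.DataFrame
    settings: dict = field(default_factory=dict)

    def mean(self, key: str) -> float:
        return float(self.table.loc[key, "mean"])

    def interval(self, key: str) -> tuple[float, float]:
        return (float(self.table.loc[key, "q2.5"]), float(self.table.loc[key, "q97.5"]))


def ess_autocorr(x: np.ndarray) -> float:
    """Effective sample size via Geyer's initial-positive-sequence estimator."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.allclose(x, x[0]):
        return float(n)
    x = x - x.mean()
    acov = np.correlate(x, x, mode="full")[n - 1:] / n
    if acov[0] <= 0:
        return float(n)
    rho = acov / acov[0]
    # sum adjacent pairs until a pair sum goes non-positive
    s = 0.0
    for k in range(1, n // 2):
        pair = rho[2 * k - 1] + rho[2 * k] if 2 * k < len(rho) else 0.0
        if pair <= 0:
            break
        s += pair
    tau = 1.0 + 2.0 * s
    return float(n / max(tau, 1.0))


def summarize_posterior(samples: pd.DataFrame | dict, settings: Optional[dict] = None) -> PosteriorSummary:
    """Posterior means, 2.5/97.5 percentiles and autocorrelation-based ESS."""
    df = pd.DataFrame(samples)
    if df.empty:
        raise ValueError("no posterior samples to summarize")
    rows = {}
    for col in df.columns:
        x = df[col].to_numpy(dtype=float)
        rows[col] = {
            "mean": float(x.mean()),
            "q2.5": float(np.percentile(x, 2.5)),
            "q97.5": float(np.percentile(x, 97.5)),
            "ess": ess_autocorr(x),
        }
    return PosteriorSummary(pd.DataFrame(rows).T, settings or {})


# ---------------------------------------------------------------------------
# the sampler

@dataclass
class McmcResult:
    samples: pd.DataFrame
    acceptance: dict[str, float]
    ess: dict[str, float]
    settings: dict
    warnings: list[str]

    @property
    def mixing_ok(self) -> bool:
        return not self.warnings


class _MscState:
    def __init__(self, loci, model, priors, rng):
        self.model = model
        self.priors = priors
        self.loci = loci
        self.patterns = [loc.site_patterns() for loc in loci]
        self.trees = [sample_gene_tree(loc.species_map, loc.names, model, rng)
                      for loc in loci]
        self.tips = [_tip_partials(t, loc, pat[0])
                     for t, loc, pat in zip(self.trees, loci, self.patterns)]
        self.masks = [species_masks(t, loc.species_map)
                      for t, loc in zip(self.trees, loci)]
        self.logliks = [self._loglik(i) for i in range(len(loci))]
        self.stats = [_msc_stats(t, mk, model.tau_TN, model.tau_TNE)
                      for t, mk in zip(self.trees, self.masks)]
        self.logdens = [_logdens_from_stats(s, model) for s in self.stats]

    def _loglik(self, i: int, tree=None) -> float:
        tree = tree if tree is not None else self.trees[i]
        _, cnt = self.patterns[i]
        return _jc69_loglik_cached(tree, self.loci[i].rate_scalar, self.tips[i], cnt)


def mcmc_msc(
    loci: Sequence[LocusAlignment],
    scalars: Optional[Sequence[float]] = None,
    priors: Optional[MscPriors] = None,
    chain: Optional[ChainConfig] = None,
    seed: int = 0,
) -> McmcResult:
    """Posterior sampling of (τ, θ) on the fixed ((T,N),E) species tree.

    ``scalars`` overrides the per-locus rate scalars stored on the
    alignments.  Priors default to data-driven hyper-means.  Low effective
    sample sizes are reported in ``result.warnings`` (and as Python
    warnings), never silently accepted.
    """
    loci = [loc for loc in loci]
    if not loci:
        raise ValueError("need at least one locus")
    for loc in loci:
        for nm in loc.names:
            if loc.species_of(nm) not in SPECIES:
                raise ValueError(
                    f"sequence {nm!r} maps to species {loc.species_of(nm)!r}; "
                    f"drop non-ingroup sequences (e.g. with drop_species) first")
    if scalars is not None:
        if len(scalars) != len(loci):
            raise ValueError("need one scalar per locus")
        loci = [LocusAlignment(l.names, l.sequences, l.species_map, float(s))
                for l, s in zip(loci, scalars)]
    if priors is None:
        priors = MscPriors.from_data(loci)
    cfg = chain or ChainConfig()
    rng = np.random.default_rng(seed)

    model = MscModel(
        tau_TN=priors.tau_mean * 0.5, tau_TNE=priors.tau_mean,
        theta_T=priors.theta_mean, theta_N=priors.theta_mean,
        theta_E=priors.theta_mean, theta_TN=priors.theta_mean,
        theta_TNE=priors.theta_mean)
    st = _MscState(loci, model, priors, rng)

    steps = {"slide": 0.6, "root": 0.6, "theta": 0.8, "tau2": 0.3, "tau3": 0.3}
    acc = {k: [0, 0] for k in ("slide", "exchange", "theta", "tau2", "tau3")}

    n_burn = int(cfg.n_iter * cfg.burnin_frac)
    keep_every = max(1, (cfg.n_iter - n_burn) // cfg.thin_to)
    records: list[dict[str, float]] = []

    def tune(key: str, accepted: bool) -> None:
        if not cfg.tune:
            return
        # Robbins-Monro toward ~30% acceptance, burn-in only
        delta = 0.05 if accepted else -0.02
        steps[key] = float(np.clip(steps[key] * math.exp(delta), 1e-3, 5.0))

    for it in range(cfg.n_iter):
        in_burn = it < n_burn
        m = st.model
        # ---- gene-tree updates
        for i, tree in enumerate(st.trees):
            n_nodes = len(tree.parent)
            internals = list(range(tree.n_tips, n_nodes))
            for _ in range(cfg.slides_per_locus):
                v = internals[rng.integers(len(internals))]
                old_t = tree.time[v]
                lo = max(tree.time[c] for c in tree.children[v])
                if v == tree.root:
                    # multiplicative slide above the younger child bound
                    u = rng.normal(0.0, steps["root"])
                    new_t = lo + (old_t - lo) * math.exp(u)
                    log_hastings = u
                else:
                    hi = tree.time[tree.parent[v]]
                    new_t = rng.uniform(lo, hi)
                    log_hastings = 0.0
                tree.time[v] = new_t
                new_stats = _msc_stats(tree, st.masks[i], m.tau_TN, m.tau_TNE)
                if new_stats is None:
                    tree.time[v] = old_t
                    acc["slide"][1] += 1
                    continue
                new_ld = _logdens_from_stats(new_stats, m)
                new_ll = st._loglik(i)
                log_a = (new_ld - st.logdens[i]) + (new_ll - st.logliks[i]) + log_hastings
                if math.log(rng.random()) < log_a:
                    st.logdens[i], st.logliks[i] = new_ld, new_ll
                    st.stats[i] = new_stats
                    acc["slide"][0] += 1
                    if in_burn and v == tree.root:
                        tune("root", True)
                else:
                    tree.time[v] = old_t
                    acc["slide"][1] += 1
                    if in_burn and v == tree.root:
                        tune("root", False)
            for _ in range(cfg.exchanges_per_locus):
                # narrow exchange: swap a grandchild with its uncle
                cands = [v for v in internals
                         if v != tree.root and tree.parent[v] >= 0
                         and len(tree.children[v]) == 2]
                if not cands:
                    continue
                c = cands[rng.integers(len(cands))]
                p = tree.parent[c]
                sibs = [x for x in tree.children[p] if x != c]
                s = sibs[0]
                a = tree.children[c][rng.integers(2)]
                if tree.time[s] >= tree.time[c]:
                    acc["exchange"][1] += 1
                    continue
                # perform swap: a -> child of p, s -> child of c
                tree.parent[a] = p
                tree.parent[s] = c
                tree._rebuild_children()
                cand_masks = species_masks(tree, st.loci[i].species_map)
                cand_stats = _msc_stats(tree, cand_masks, m.tau_TN, m.tau_TNE)
                if cand_stats is not None:
                    new_ld = _logdens_from_stats(cand_stats, m)
                    new_ll = st._loglik(i)
                    log_a = (new_ld - st.logdens[i]) + (new_ll - st.logliks[i])
                else:
                    log_a = -math.inf
                if log_a > -math.inf and math.log(rng.random()) < log_a:
                    st.logdens[i], st.logliks[i] = new_ld, new_ll
                    st.masks[i] = cand_masks
                    st.stats[i] = cand_stats
                    acc["exchange"][0] += 1
                else:
                    tree.parent[a] = c
                    tree.parent[s] = p
                    tree._rebuild_children()
                    acc["exchange"][1] += 1
        # ---- theta multipliers
        for key in THETA_KEYS:
            old = getattr(st.model, key)
            u = rng.uniform(-steps["theta"], steps["theta"])
            new = old * math.exp(u)
            cand = MscModel(**{**st.model.as_dict(), key: new})
            new_dens = [_logdens_from_stats(s, cand) for s in st.stats]
            log_a = (st.priors.log_prior(cand) - st.priors.log_prior(st.model)
                     + sum(new_dens) - sum(st.logdens) + u)
            if math.log(rng.random()) < log_a:
                st.model = cand
                st.logdens = new_dens
                acc["theta"][0] += 1
                if in_burn:
                    tune("theta", True)
            else:
                acc["theta"][1] += 1
                if in_burn:
                    tune("theta", False)
        # ---- tau rubber-band moves
        for key in ("tau2", "tau3"):
            _tau_rubber_band(st, key, steps[key], rng, acc, tune if in_burn else None)
        # ---- record
        if not in_burn and (it - n_burn) % keep_every == 0:
            rec = st.model.as_dict()
            rec["log_likelihood"] = float(sum(st.logliks))
            records.append(rec)

    samples = pd.DataFrame(records)
    acceptance = {k: (v[0] / max(v[0] + v[1], 1)) for k, v in acc.items()}
    ess = {k: ess_autocorr(samples[k].to_numpy()) for k in PARAM_KEYS}
    warns = [f"low ESS for {k}: {v:.0f} < floor {cfg.ess_floor:.0f}"
             for k, v in ess.items() if v < cfg.ess_floor]
    for w in warns:
        warnings.warn(w, RuntimeWarning, stacklevel=2)
    settings = {"n_iter": cfg.n_iter, "burnin": n_burn, "thin": keep_every,
                "seed": seed, "priors": {"tau_mean": priors.tau_mean,
                                         "theta_mean": priors.theta_mean}}
    return McmcResult(samples, acceptance, ess, settings, warns)


def _tau_rubber_band(st: _MscState, which: str, step: float,
                     rng: np.random.Generator, acc: dict, tune_fn) -> None:
    m = st.model
    tau2, tau3 = m.tau_TN, m.tau_TNE
    log_hastings = 0.0
    if which == "tau2":
        w = step * tau3
        new = _reflect(tau2 + rng.uniform(-w, w), 0.0, tau3)
        if not 0.0 < new < tau3:
            acc[which][1] += 1
            return
        cand = MscModel(**{**m.as_dict(), "tau_TN": new})
    else:
        # multiplier proposal keeps the move reversible under the tau2 bound
        u = rng.uniform(-step, step)
        new = tau3 * math.exp(u)
        if not new > tau2:
            acc[which][1] += 1
            if tune_fn:
                tune_fn(which, False)
            return
        cand = MscModel(**{**m.as_dict(), "tau_TNE": new})
        log_hastings = u
    new_trees, log_jac = [], 0.0
    t2n, t3n = cand.tau_TN, cand.tau_TNE
    for tree, masks in zip(st.trees, st.masks):
        nt = tree.copy()
        for v in range(nt.n_tips, len(nt.parent)):
            t = nt.time[v]
            pop = _pop_of_mask(masks[v], t, tau2, tau3)
            if pop is None:
                return  # current state invalid; should not happen
            if which == "tau2":
                if pop in ("T", "N"):
                    nt.time[v] = t * t2n / tau2
                    log_jac += math.log(t2n / tau2)
                elif pop == "TN":
                    nt.time[v] = tau3 - (tau3 - t) * (tau3 - t2n) / (tau3 - tau2)
                    log_jac += math.log((tau3 - t2n) / (tau3 - tau2))
            else:
                if pop == "E":
                    nt.time[v] = t * t3n / tau3
                    log_jac += math.log(t3n / tau3)
                elif pop == "TN":
                    nt.time[v] = tau2 + (t - tau2) * (t3n - tau2) / (tau3 - tau2)
                    log_jac += math.log((t3n - tau2) / (tau3 - tau2))
                elif pop == "TNE":
                    nt.time[v] = t + (t3n - tau3)
        new_trees.append(nt)
    new_dens, new_lls, new_stats = [], [], []
    for i, nt in enumerate(new_trees):
        stats = _msc_stats(nt, st.masks[i], cand.tau_TN, cand.tau_TNE)
        if stats is None:
            acc[which][1] += 1
            if tune_fn:
                tune_fn(which, False)
            return
        new_stats.append(stats)
        new_dens.append(_logdens_from_stats(stats, cand))
        new_lls.append(st._loglik(i, tree=nt))
    log_a = (st.priors.log_prior(cand) - st.priors.log_prior(m)
             + sum(new_dens) - sum(st.logdens)
             + sum(new_lls) - sum(st.logliks) + log_jac + log_hastings)
    if math.log(rng.random()) < log_a:
        st.model = cand
        st.trees = new_trees
        st.logdens = new_dens
        st.logliks = new_lls
        st.stats = new_stats
        acc[which][0] += 1
        if tune_fn:
            tune_fn(which, True)
    else:
        acc[which][1] += 1
        if tune_fn:
            tune_fn(which, False)


def _reflect(x: float, lo: float, hi: float) -> float:
    width = hi - lo
    if width <= 0:
        return lo
    y = (x - lo) % (2.0 * width)
    if y < 0:
        y += 2.0 * width
    return lo + (width - abs(y - width))
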