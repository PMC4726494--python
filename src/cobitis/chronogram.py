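"""Penalized-likelihood divergence-time estimation (chronogram fitting).

A rooted phylogram with branch lengths in substitutions/site is converted
into an ultrametric chronogram (node ages in MYA, tips at 0) with
branch-specific substitution rates.  Following the penalized-likelihood
approach of Sanderson, the objective is a Poisson log-likelihood of the
per-branch expected substitution counts x_j = b_j·L with mean r_j·t_j·L,
minus λ times a rate-roughness penalty (squared rate differences between a
branch and its parent branch, plus the variance of the root's child rates).
λ = 0 saturates the model (one free rate per branch); λ → ∞ converges to a
single-rate clock (the Langley-Fitch solution).  The smoothing value is
chosen by leave-one-tip-out cross-validation with a chi-squared-style
(obs − pred)²/pred score.

One fixed calibration age (at the MRCA of a named tip set, typically the
root) sets the absolute time scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

MIN_BRANCH_LENGTH = 1e-8   # substitutions/site floor for zero-length input branches


@dataclass
class Phylogram:
    """Rooted tree with branch lengths in substitutions/site and alignment length L."""

    tree: dendropy.Tree
    L: int

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("alignment length L must be > 0")
        # explicit rootedness: bipartition encoding would otherwise collapse
        # the basal bifurcation in place
        self.tree.is_rooted = True
        n_tips = len(self.tree.leaf_nodes())
        if n_tips < 2:
            raise ValueError("phylogram needs >= 2 tips")
        for node in self.tree.preorder_node_iter():
            if node.parent_node is not None and (node.edge.length or 0.0) < 0:
                raise ValueError("negative branch length")

    @classmethod
    def from_newick(cls, source: str | Path, L: int) -> "Phylogram":
        src = str(source)
        if "(" in src:
            tree = dendropy.Tree.get(data=src, schema="newick")
        else:
            tree = dendropy.Tree.get(path=src, schema="newick")
        return cls(tree, L)

    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]


@dataclass(frozen=True)
class CalibrationPoint:
    """Fixed age (MYA) at the MRCA of the named tips."""

    tips: tuple[str, ...]
    age: float

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("calibration age must be > 0")
        if not self.tips:
            raise ValueError("calibration needs at least one tip label")


@dataclass
class Chronogram:
    """Fitted ultrametric tree: node ages (MYA) and per-branch rates."""

    tree: dendropy.Tree               # annotated: node.age, node.edge.rate
    lam: float
    objective: float
    converged: bool
    n_restarts: int
    seed: int
    diagnostics: dict = field(default_factory=dict)

    def ages(self) -> dict[str, float]:
        out = {}
        for i, node in enumerate(self.tree.preorder_node_iter()):
            key = node.taxon.label if node.taxon else f"node{i}"
            out[key] = float(node.age)
        return out

    def internal_ages(self) -> np.ndarray:
        return np.array([nd.age for nd in self.tree.preorder_internal_node_iter()])

    def rates(self) -> np.ndarray:
        return np.array([nd.edge.rate for nd in self.tree.preorder_node_iter()
                         if nd.parent_node is not None])

    def max_age_spread(self) -> float:
        """Max minus min root-to-tip age distance (0 for an ultrametric tree)."""
        depths = []
        for leaf in self.tree.leaf_node_iter():
            d = 0.0
            nd = leaf
            while nd.parent_node is not None:
                d += nd.parent_node.age - nd.age
                nd = nd.parent_node
            depths.append(d)
        return float(max(depths) - min(depths))

    def warm_start(self) -> dict:
        """Ages and rates keyed by leaf set, for seeding related fits."""
        ages, rates = {}, {}
        for nd in self.tree.preorder_node_iter():
            key = frozenset(lf.taxon.label for lf in nd.leaf_iter())
            if not nd.is_leaf():
                ages[key] = float(nd.age)
            if nd.parent_node is not None:
                rates[key] = float(nd.edge.rate)
        return {"ages": ages, "rates": rates}

    def to_newick(self) -> str:
        """Newick with branch lengths = durations (MYA) and rate comments."""
        for node in self.tree.preorder_node_iter():
            if node.parent_node is not None:
                node.edge.length = node.parent_node.age - node.age
                node.annotations.drop()
                node.annotations.add_new("rate", f"{node.edge.rate:.6g}")
        return self.tree.as_string(schema="newick", suppress_annotations=False).strip()


# ---------------------------------------------------------------------------
# internal indexed representation

class _PLProblem:
    def __init__(self, phylogram: Phylogram, calibration: CalibrationPoint):
        tree = phylogram.tree
        self.L = phylogram.L
        self.nodes = list(tree.preorder_node_iter())
        self.index = {id(nd): i for i, nd in enumerate(self.nodes)}
        self.parent = np.array(
            [self.index[id(nd.parent_node)] if nd.parent_node is not None else -1
             for nd in self.nodes])
        self.is_tip = np.array([nd.is_leaf() for nd in self.nodes])
        self.n = len(self.nodes)
        self.blen = np.array(
            [max(nd.edge.length or 0.0, MIN_BRANCH_LENGTH) if nd.parent_node is not None else 0.0
             for nd in self.nodes])
        self.x = self.blen * self.L  # continuous substitution counts
        # internal nodes other than root get a depth-fraction parameter
        self.internal = [i for i in range(self.n) if not self.is_tip[i]]
        self.free_internal = [i for i in self.internal if i != 0]
        self.branches = [i for i in range(self.n) if self.parent[i] >= 0]
        # calibration node = MRCA of named tips
        labels = {lf.taxon.label: self.index[id(lf)] for lf in tree.leaf_node_iter()}
        missing = [t for t in calibration.tips if t not in labels]
        if missing:
            raise ValueError(f"calibration tips not in tree: {missing}")
        taxa = [tree.taxon_namespace.get_taxon(t) for t in calibration.tips]
        if len(calibration.tips) == 1:
            raise ValueError("calibration tip set must contain >= 2 tips (tips have age 0)")
        mrca = tree.mrca(taxa=taxa)
        self.calib_node = self.index[id(mrca)]
        self.calib_age = calibration.age
        # path of free-internal nodes from root (exclusive) down to calib node (inclusive)
        path = []
        v = self.calib_node
        while v != 0:
            path.append(v)
            v = self.parent[v]
        self.calib_path = path  # empty when the root is calibrated
        self.root_children = [i for i in range(self.n) if self.parent[i] == 0]
        # branch -> parent-branch (child node of parent edge) for the penalty
        self.parent_branch = np.array(
            [self.parent[i] if self.parent[self.parent[i]] >= 0 else -1
             for i in self.branches])
        # log-gamma of continuous counts, precomputed
        self.lgx = gammaln(self.x[self.branches] + 1.0)

    # ---- parameter packing: z (logit fractions, len free_internal), log r (len branches)

    def n_params(self) -> tuple[int, int]:
        return len(self.free_internal), len(self.branches)

    def ages_from_fractions(self, frac: np.ndarray) -> np.ndarray:
        """Node ages from per-node depth fractions; calibration pins the scale."""
        fr = {node: frac[k] for k, node in enumerate(self.free_internal)}
        # root age: product of fractions along the path to the calibrated node
        prod = 1.0
        for v in self.calib_path:
            prod *= fr[v]
        root_age = self.calib_age / prod
        ages = np.zeros(self.n)
        ages[0] = root_age
        for i in range(1, self.n):  # preorder: parent before child
            if self.is_tip[i]:
                ages[i] = 0.0
            else:
                ages[i] = ages[self.parent[i]] * fr[i]
        return ages

    def durations(self, ages: np.ndarray) -> np.ndarray:
        return np.array([ages[self.parent[i]] - ages[i] for i in self.branches])

    def objective(self, ages: np.ndarray, rates: np.ndarray, lam: float) -> float:
        """Penalized log-likelihood (to be maximized)."""
        t = self.durations(ages)
        if (t <= 0).any():
            return -math.inf
        mu = rates * t * self.L
        x = self.x[self.branches]
        ll = float(np.sum(x * np.log(mu) - mu) - self.lgx.sum())
        pen = 0.0
        rate_of = {b: rates[k] for k, b in enumerate(self.branches)}
        for k, b in enumerate(self.branches):
            pb = self.parent_branch[k]
            if pb >= 0:
                pen += (rates[k] - rate_of[pb]) ** 2
        rc = np.array([rate_of[c] for c in self.root_children])
        pen += float(np.var(rc))
        return ll - lam * pen

    def pack(self, frac: np.ndarray, rates: np.ndarray) -> np.ndarray:
        z = np.log(frac / (1.0 - frac))
        return np.concatenate([z, np.log(rates)])

    def unpack(self, params: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        nf, nb = self.n_params()
        z = np.clip(params[:nf], -30, 30)
        frac = 1.0 / (1.0 + np.exp(-z))
        rates = np.exp(np.clip(params[nf:], -46, 23))
        return frac, rates

    def neg_objective(self, params: np.ndarray, lam: float) -> float:
        frac, rates = self.unpack(params)
        obj = self.objective(self.ages_from_fractions(frac), rates, lam)
        return -obj if math.isfinite(obj) else 1e12

    def leafsets(self) -> list[frozenset]:
        sets: list[frozenset] = [frozenset()] * self.n
        for i in range(self.n - 1, -1, -1):
            nd = self.nodes[i]
            if self.is_tip[i]:
                sets[i] = frozenset({nd.taxon.label})
            else:
                s = frozenset()
                for j in range(self.n):
                    if self.parent[j] == i:
                        s |= sets[j]
                sets[i] = s
        return sets

    def initial_params(self, warm_start: Optional[dict] = None) -> np.ndarray:
        # init ages proportional to max root-to-tip path length below each node
        height = np.zeros(self.n)
        for i in range(self.n - 1, -1, -1):
            if not self.is_tip[i]:
                kids = [j for j in range(self.n) if self.parent[j] == i]
                height[i] = max(height[j] + self.blen[j] for j in kids)
        frac = np.array([
            np.clip(height[v] / max(height[self.parent[v]], 1e-12), 0.05, 0.95)
            for v in self.free_internal])
        ages = self.ages_from_fractions(frac)
        total_t = self.durations(ages).sum()
        global_rate = max(self.x[self.branches].sum() / (total_t * self.L), 1e-12)
        rates = np.full(len(self.branches), global_rate)
        if warm_start is not None:
            # seed from a previous fit's ages/rates keyed by tip leaf sets
            # (tolerates missing nodes, e.g. after pruning a tip)
            sets = self.leafsets()
            ws_ages = warm_start.get("ages", {})
            ws_rates = warm_start.get("rates", {})

            def lookup(table, key):
                if key in table:
                    return table[key]
                for other, val in table.items():
                    if key <= other and len(other - key) <= 1:
                        return val
                return None

            age_of = {}
            for k, v in enumerate(self.free_internal):
                a = lookup(ws_ages, sets[v])
                if a is not None:
                    age_of[v] = a
            for k, v in enumerate(self.free_internal):
                if v in age_of:
                    pa = age_of.get(self.parent[v])
                    if pa is None:
                        pa = lookup(ws_ages, sets[self.parent[v]])
                    if pa and pa > 0:
                        frac[k] = float(np.clip(age_of[v] / pa, 0.01, 0.99))
            for k, b in enumerate(self.branches):
                r = lookup(ws_rates, sets[b])
                if r is not None and r > 0:
                    rates[k] = r
        return self.pack(frac, rates)


# ---------------------------------------------------------------------------
# public operations

def pl_objective(phylogram: Phylogram, ages: dict, rates: dict, lam: float,
                 calibration: Optional[CalibrationPoint] = None) -> float:
    """Evaluate the penalized log-likelihood at given ages and rates.

    ``ages`` maps taxon label (tips) or preorder node index (internals) to
    age; ``rates`` maps preorder branch index (index of the child node in
    preorder) to rate.  Mostly a transparent hook for validation; model
    fitting uses the internal representation directly.
    """
    tips = phylogram.tip_labels()
    calibration = calibration or CalibrationPoint(tuple(tips), max(ages.values()))
    prob = _PLProblem(phylogram, calibration)
    age_vec = np.zeros(prob.n)
    for i, nd in enumerate(prob.nodes):
        key = nd.taxon.label if nd.taxon else i
        if key in ages:
            age_vec[i] = ages[key]
        elif i in ages:
            age_vec[i] = ages[i]
        elif not prob.is_tip[i]:
            raise ValueError(f"no age supplied for internal node {i}")
    rate_vec = np.array([rates[b] for b in prob.branches])
    if (prob.durations(age_vec) <= 0).any():
        raise ValueError("ages must strictly decrease from parent to child")
    return prob.objective(age_vec, rate_vec, lam)


def fit_chronogram(
    phylogram: Phylogram,
    lam: float,
    calibration: CalibrationPoint,
    n_restarts: int = 10,
    seed: int = 0,
    perturb: float = 0.5,
    warm_start: Optional[dict] = None,
) -> Chronogram:
    """Maximize the penalized likelihood over node ages and branch rates.

    Ages are parameterized by per-node depth fractions (logit-transformed)
    so parent > child ordering holds by construction and the calibrated
    node keeps its fixed age; rates are log-transformed.  The best of
    ``n_restarts`` seeded quasi-Newton starts is returned; lack of
    optimizer convergence is reported in ``converged``/``diagnostics``,
    never silently.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    prob = _PLProblem(phylogram, calibration)
    rng = np.random.default_rng(seed)
    base = prob.initial_params(warm_start)
    best = None
    n_fail = 0
    for r in range(max(n_restarts, 1)):
        p0 = base if r == 0 else base + rng.normal(0.0, perturb, size=base.shape)
        res = minimize(prob.neg_objective, p0, args=(lam,), method="L-BFGS-B",
                       options={"maxiter": 500})
        if not res.success:
            n_fail += 1
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not math.isfinite(best.fun) or best.fun >= 1e12:
        raise RuntimeError("penalized-likelihood optimization failed to find a feasible point")
    frac, rates = prob.unpack(best.x)
    ages = prob.ages_from_fractions(frac)
    tree = phylogram.tree.clone(depth=1)
    out_nodes = list(tree.preorder_node_iter())
    for i, nd in enumerate(out_nodes):
        nd.age = float(ages[i])
    rate_of_branch = {b: rates[k] for k, b in enumerate(prob.branches)}
    for i, nd in enumerate(out_nodes):
        if nd.parent_node is not None:
            nd.edge.rate = float(rate_of_branch[i])
    return Chronogram(
        tree=tree, lam=lam, objective=-float(best.fun),
        converged=(n_fail < max(n_restarts, 1)), n_restarts=n_restarts, seed=seed,
        diagnostics={"n_failed_restarts": n_fail, "message": str(best.message)},
    )


@dataclass
class CvResult:
    lambdas: np.ndarray
    scores: np.ndarray
    selected: float
    per_tip: dict = field(default_factory=dict)
    noise_floor: Optional[np.ndarray] = None


def cross_validate_lambda(
    phylogram: Phylogram,
    lambda_grid: Optional[Sequence[float]] = None,
    calibration: Optional[CalibrationPoint] = None,
    n_restarts: int = 3,
    seed: int = 0,
    plateau_tol: float = 0.1,
    plateau_abs: Optional[float] = None,
    score: str = "stability",
) -> CvResult:
    """Select the smoothing value λ by leave-one-tip-out cross-validation.

    The default ``"stability"`` score removes each tip in turn, refits, and
    accumulates D² = Σ_nodes (age_full − age_pruned)² / age_full over the
    internal nodes shared by the full and pruned chronograms — node-age
    estimates that are robust to tip deletion indicate an adequately
    smoothed model.  The alternative ``"prediction"`` score keeps the
    pruned tip's parent as a degree-two node (its age stays identifiable
    through the smoothing penalty) and scores the removed terminal
    branch's expected substitutions, Σ (observed − predicted)²/predicted.

    Selection takes the largest λ whose score lies within ``plateau_tol``
    (relative) plus ``plateau_abs`` (absolute; default 1% of the
    calibration age, the scale below which summed node-age shifts are not
    interpretable) of the minimum — a parsimony tie-break for the plateaus
    the CV curve shows on clock-like data, in the spirit of the
    one-standard-error rule.  Tips attached directly to the root are
    skipped (their removal would re-root the tree).
    """
    if score not in ("stability", "prediction"):
        raise ValueError("score must be 'stability' or 'prediction'")
    if lambda_grid is None:
        lambda_grid = 10.0 ** np.arange(-3.0, 3.5, 0.5)  # 1e-3 .. 1e3, half decades
    lambdas = np.array(sorted(float(l) for l in lambda_grid))
    if lambdas.size == 0:
        raise ValueError("lambda grid must be non-empty")
    tree = phylogram.tree
    tips = phylogram.tip_labels()
    if len(tips) < 4:
        raise ValueError("cross-validation needs >= 4 tips")
    calibration = calibration or CalibrationPoint(tuple(tips), 1.0)

    scores = np.zeros(lambdas.size)
    per_tip: dict[str, list[float]] = {}
    for li, lam in enumerate(lambdas):
        full_ages = None
        ws = None
        if score == "stability":
            full_fit = fit_chronogram(phylogram, lam, calibration,
                                      n_restarts=n_restarts, seed=seed)
            full_ages = {frozenset(lf.taxon.label for lf in nd.leaf_iter()): nd.age
                         for nd in full_fit.tree.preorder_internal_node_iter()}
            # pruned refits are warm-started from the full fit: the D2 score
            # then measures data-driven age shifts, not restart jitter
            ws = full_fit.warm_start()
        total = 0.0
        for tip in tips:
            leaf = tree.find_node_with_taxon_label(tip)
            parent = leaf.parent_node
            sib = [c for c in parent.child_nodes() if c is not leaf][0]
            grand = parent.parent_node
            if grand is None:
                continue  # pruning would re-root; calibration undefined
            calib_tips = tuple(t for t in calibration.tips if t != tip)
            if len(calib_tips) < 2:
                calib_tips = tuple(t for t in tips if t != tip)
            pruned = tree.clone(depth=1)
            pruned.prune_taxa_with_labels(
                [tip], suppress_unifurcations=(score == "stability"))
            sub = Phylogram(pruned, phylogram.L)
            fit = fit_chronogram(sub, lam, CalibrationPoint(calib_tips, calibration.age),
                                 n_restarts=1 if ws is not None else n_restarts,
                                 seed=seed, warm_start=ws)
            if score == "stability":
                contrib = 0.0
                parent_leaves = frozenset(lf.taxon.label for lf in parent.leaf_iter())
                for nd in fit.tree.preorder_internal_node_iter():
                    leaves = frozenset(lf.taxon.label for lf in nd.leaf_iter())
                    key = leaves if leaves in full_ages else leaves | {tip}
                    if key == parent_leaves:
                        continue  # the pruned tip's parent has no counterpart
                    if key in full_ages and full_ages[key] > 0:
                        contrib += (full_ages[key] - nd.age) ** 2 / full_ages[key]
            else:
                # attachment node = the retained degree-two parent of the tip:
                # the rootmost node whose leaf set equals the sibling clade's
                sib_leaves = {lf.taxon.label for lf in sib.leaf_iter()}
                attach = _node_with_leafset(fit.tree, sib_leaves)
                if attach is None or attach.parent_node is None:
                    continue
                pred = attach.edge.rate * attach.age * phylogram.L
                obs = max(leaf.edge.length or 0.0, MIN_BRANCH_LENGTH) * phylogram.L
                # denominator floored at half a substitution: near-zero
                # predictions on very short attachments otherwise dominate
                contrib = (obs - pred) ** 2 / max(pred, 0.5)
            total += contrib
            per_tip.setdefault(tip, []).append(contrib)
        scores[li] = total
    if plateau_abs is None:
        plateau_abs = 0.01 * calibration.age if score == "stability" else 0.0
    best = float(scores.min())
    eligible = np.nonzero(scores <= best * (1.0 + plateau_tol) + plateau_abs)[0]
    selected = float(lambdas[eligible[-1]])
    return CvResult(lambdas, scores, selected, per_tip)


def _node_with_leafset(tree: dendropy.Tree, leafset: set[str]):
    for node in tree.preorder_node_iter():
        leaves = {lf.taxon.label for lf in node.leaf_iter()}
        if leaves == leafset:
            return node
    return None


def lineage_average_rate(chronogram: Chronogram, tip_set: Sequence[str],
                         terminal_only: bool = False) -> float:
    """Mean substitution rate over the spanning subtree of a tip set.

    The subtree runs from the MRCA of the tips down to each tip; the mean
    is the unweighted arithmetic mean over its branches.  With
    ``terminal_only`` the mean covers only the tips' terminal branches.
    """
    tips = list(tip_set)
    if not tips:
        raise ValueError("tip set must be non-empty")
    tree = chronogram.tree
    leaf_nodes = []
    for t in tips:
        nd = tree.find_node_with_taxon_label(t)
        if nd is None:
            raise ValueError(f"tip {t!r} not in chronogram")
        leaf_nodes.append(nd)
    if terminal_only:
        return float(np.mean([nd.edge.rate for nd in leaf_nodes]))
    if len(tips) == 1:
        return float(leaf_nodes[0].edge.rate)
    mrca = tree.mrca(taxa=[tree.taxon_namespace.get_taxon(t) for t in tips])
    rates = []
    for nd in leaf_nodes:
        v = nd
        while v is not mrca:
            rates.append((id(v), v.edge.rate))
            v = v.parent_node
    seen = {}
    for key, r in rates:
        seen[key] = r
    return float(np.mean(list(seen.values())))
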