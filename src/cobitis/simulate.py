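"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here with its true
parameters recorded alongside: infinite-sites coalescent haplotype samples,
multispecies-coalescent (MSC) loci with JC69 sequences, clock or
rate-perturbed phylograms with Poisson substitution noise, GISH signal
lists with true origin labels, and the reference karyotype / cohort table
fixtures.  All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np

from .coalescent import HaplotypeSample
from .karyotype import CATEGORIES, GishChromosome, load_reference_table
from .msc import GeneTree, LocusAlignment, MscModel

NUCLEOTIDES = np.array(list("ACGT"))


@dataclass
class SimTruth:
    """True parameters and latent variables of a simulated dataset."""

    generator: str
    params: dict
    seed: int
    latent: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(f"not JSON-serializable: {type(o)}")
        return json.dumps(
            {"generator": self.generator, "params": self.params,
             "seed": self.seed, "latent": self.latent},
            sort_keys=True, indent=2, default=default)


# ---------------------------------------------------------------------------
# infinite-sites coalescent samples

def simulate_infinite_sites_sample(
    n: int, theta: float, seed: int = 0
) -> tuple[HaplotypeSample, SimTruth]:
    """Kingman coalescent sample with infinite-sites mutation.

    While k lineages remain, each of the C(k,2) pairs coalesces at rate 1
    (time in units of N_f generations) and mutations fall on each branch as
    a Poisson process of rate θ/2, each creating a brand-new site.  Returns
    the reduced haplotype sample and the truth record (TMRCA, total tree
    length, per-lineage mutation counts).
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    rng = np.random.default_rng(seed)
    # genealogy: nodes 0..n-1 tips; merge randomly
    active = list(range(n))
    node_time = {i: 0.0 for i in range(n)}
    parent: dict[int, int] = {}
    nxt = n
    t = 0.0
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        node_time[nxt] = t
        parent[a] = nxt
        parent[b] = nxt
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    root = active[0]
    tmrca = node_time[root]
    # descendant tip sets, bottom-up (children always have smaller ids)
    desc: dict[int, set[int]] = {i: {i} for i in range(n)}
    for v in range(n, nxt):
        desc[v] = set()
    for v in range(nxt):
        if v in parent:
            desc[parent[v]] |= desc[v]
    # mutations: Poisson(theta/2 * branch length) per branch, new site each
    site_carriers: list[set[int]] = []
    total_len = 0.0
    for v, par in parent.items():
        blen = node_time[par] - node_time[v]
        total_len += blen
        n_mut = rng.poisson(theta / 2.0 * blen)
        for _ in range(n_mut):
            carriers = set(desc[v])
            if 0 < len(carriers) < n:
                site_carriers.append(carriers)
    if site_carriers:
        mat = np.zeros((len(site_carriers), n), dtype=np.int8)
        for s, carriers in enumerate(site_carriers):
            mat[s, sorted(carriers)] = 1
        sample = HaplotypeSample.from_sequences(mat.T)
    else:
        sample = HaplotypeSample(np.zeros((0, 1), dtype=np.int8), np.array([n]))
    truth = SimTruth(
        "infinite_sites_coalescent",
        {"n": n, "theta": theta},
        seed,
        {"tmrca": tmrca, "total_branch_length": total_len,
         "n_segregating": len(site_carriers)},
    )
    return sample, truth


# ---------------------------------------------------------------------------
# MSC loci

def _coalesce_in_population(
    lineages: list[int],
    node_time: dict[int, float],
    parent: dict[int, int],
    theta: float,
    t_start: float,
    t_end: float,
    nxt: int,
    rng: np.random.Generator,
) -> tuple[list[int], int]:
    """Censored pairwise-rate-2/θ coalescent within one species-tree branch."""
    t = t_start
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(theta / (k * (k - 1)))  # total rate k(k-1)/theta
        if t >= t_end:
            return lineages, nxt
        i, j = rng.choice(k, size=2, replace=False)
        a, b = lineages[i], lineages[j]
        node_time[nxt] = t
        parent[a] = nxt
        parent[b] = nxt
        lineages = [x for x in lineages if x not in (a, b)] + [nxt]
        nxt += 1
    return lineages, nxt


def _jc69_evolve(root_seq: np.ndarray, tree: GeneTree, scalar: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Evolve sequences down a gene tree under JC69 (branch lengths × scalar)."""
    n_nodes = len(tree.time)
    L = len(root_seq)
    seqs = np.empty((n_nodes, L), dtype=np.int8)
    root = tree.root
    seqs[root] = root_seq
    order = tree.preorder()
    for v in order:
        if v == root:
            continue
        d = (tree.time[tree.parent[v]] - tree.time[v]) * scalar
        p_change = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
        seq = seqs[tree.parent[v]].copy()
        hit = rng.random(L) < p_change
        if hit.any():
            # conditional on change: uniform over the three other bases
            shift = rng.integers(1, 4, size=int(hit.sum()))
            seq[hit] = (seq[hit] + shift) % 4
        seqs[v] = seq
    return seqs


def simulate_msc_loci(
    model: MscModel,
    n_loci: int,
    seqs_per_species: int = 2,
    locus_length: int = 500,
    scalars: Optional[Sequence[float]] = None,
    seed: int = 0,
    outgroup_tau: Optional[float] = None,
) -> tuple[list[LocusAlignment], SimTruth]:
    """Simulate per-locus alignments under the 3-species MSC with JC69.

    Gene trees coalesce within the fixed species tree ((T,N),E) in
    substitution-time units (pairwise coalescence rate 2/θ inside each
    population); sequences evolve under JC69 with per-locus branch lengths
    multiplied by the locus rate scalar.  ``outgroup_tau`` adds one
    outgroup sequence ("out") diverging at that depth (no coalescent
    variance on the outgroup stem beyond the root population's).
    """
    rng = np.random.default_rng(seed)
    if scalars is None:
        scalars = np.ones(n_loci)
    scalars = np.asarray(scalars, dtype=float)
    if len(scalars) != n_loci:
        raise ValueError("need one rate scalar per locus")
    loci: list[LocusAlignment] = []
    gene_trees: list[GeneTree] = []
    for locus in range(n_loci):
        names, species = [], []
        for sp in ("T", "N", "E"):
            for i in range(seqs_per_species):
                names.append(f"{sp.lower()}{i}")
                species.append(sp)
        n_tips = len(names)
        node_time = {i: 0.0 for i in range(n_tips)}
        parent: dict[int, int] = {}
        nxt = n_tips
        by_sp = {sp: [i for i, s in enumerate(species) if s == sp] for sp in ("T", "N", "E")}
        t_lin, nxt = _coalesce_in_population(by_sp["T"], node_time, parent,
                                             model.theta_T, 0.0, model.tau_TN, nxt, rng)
        n_lin, nxt = _coalesce_in_population(by_sp["N"], node_time, parent,
                                             model.theta_N, 0.0, model.tau_TN, nxt, rng)
        e_lin, nxt = _coalesce_in_population(by_sp["E"], node_time, parent,
                                             model.theta_E, 0.0, model.tau_TNE, nxt, rng)
        tn_lin, nxt = _coalesce_in_population(t_lin + n_lin, node_time, parent,
                                              model.theta_TN, model.tau_TN,
                                              model.tau_TNE, nxt, rng)
        # coalesce remaining in root population
        root_lin, nxt = _coalesce_in_population(tn_lin + e_lin, node_time, parent,
                                                model.theta_TNE, model.tau_TNE,
                                                math.inf, nxt, rng)
        root = root_lin[0]
        if outgroup_tau is not None:
            names.append("out")
            species.append("OUT")
            og_tip = nxt
            node_time[og_tip] = 0.0
            nxt += 1
            new_root = nxt
            node_time[new_root] = max(outgroup_tau + rng.exponential(model.theta_TNE / 2.0),
                                      node_time[root] + 1e-12)
            parent[root] = new_root
            parent[og_tip] = new_root
            nxt += 1
            root = new_root
        tree = GeneTree.from_parent_map(names, node_time, parent)
        root_seq = rng.integers(0, 4, size=locus_length).astype(np.int8)
        seqs = _jc69_evolve(root_seq, tree, scalars[locus], rng)
        tip_seqs = seqs[: len(names)]
        aln = LocusAlignment(
            names=list(names),
            sequences=tip_seqs.copy(),
            species_map={nm: sp for nm, sp in zip(names, species)},
            rate_scalar=float(scalars[locus]),
        )
        loci.append(aln)
        gene_trees.append(tree)
    truth = SimTruth(
        "msc_jc69",
        {"tau_TN": model.tau_TN, "tau_TNE": model.tau_TNE,
         "theta_T": model.theta_T, "theta_N": model.theta_N,
         "theta_E": model.theta_E, "theta_TN": model.theta_TN,
         "theta_TNE": model.theta_TNE,
         "n_loci": n_loci, "seqs_per_species": seqs_per_species,
         "locus_length": locus_length, "scalars": list(map(float, scalars)),
         "outgroup_tau": outgroup_tau},
        seed,
        {"gene_tree_heights": [float(t.time[t.root]) for t in gene_trees]},
    )
    return loci, truth


# ---------------------------------------------------------------------------
# chronograms and phylograms

def simulate_chronogram(n_tips: int, root_age: float, seed: int = 0) -> dendropy.Tree:
    """Random ultrametric tree: Yule (pure-birth) shape rescaled to root_age.

    Node ages are stored in ``node.age`` (tips at 0), branch lengths in
    time units.
    """
    if n_tips < 2:
        raise ValueError("need >= 2 tips")
    rng = np.random.default_rng(seed)
    # forward pure-birth: start with 2 lineages at time 0 (the root)
    split_times = [0.0]
    k = 2
    t = 0.0
    while k < n_tips:
        t += rng.exponential(1.0 / k)
        split_times.append(t)
        k += 1
    # depth of tree = time of last split + one more mean waiting time
    depth = t + rng.exponential(1.0 / k)
    scale = root_age / depth
    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n_tips)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    # build by sequential random attachment consistent with split times
    root = tree.seed_node
    root.age = root_age
    left = dendropy.Node()
    right = dendropy.Node()
    root.add_child(left)
    root.add_child(right)
    tips = [left, right]
    for s in range(1, n_tips - 1):
        age = (depth - split_times[s]) * scale
        idx = int(rng.integers(0, len(tips)))
        node = tips.pop(idx)
        node.age = age
        a, b = dendropy.Node(), dendropy.Node()
        node.add_child(a)
        node.add_child(b)
        tips.extend([a, b])
    order = rng.permutation(n_tips)
    for i, node in enumerate(tips):
        node.age = 0.0
        node.taxon = taxa[int(order[i])]
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = node.parent_node.age - node.age
    return tree


def simulate_phylogram(
    chronogram: dendropy.Tree,
    base_rate: float,
    L: int,
    sigma: float = 0.0,
    seed: int = 0,
) -> tuple[dendropy.Tree, SimTruth]:
    """Poisson-noise phylogram from a true chronogram.

    Branch rates follow either a strict clock (``sigma=0``) or a
    log-normal random walk along the tree (each child edge's log-rate is
    the parent edge's plus N(0, σ²)).  Substitution counts are
    Poisson(r·t·L); branch lengths are counts / L (substitutions/site).
    """
    rng = np.random.default_rng(seed)
    tree = chronogram.clone(depth=1)
    rates: dict[int, float] = {}
    true_rates = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent_rate = rates.get(id(node.parent_node), base_rate)
        if sigma > 0:
            rate = parent_rate * math.exp(rng.normal(0.0, sigma))
        else:
            rate = base_rate
        rates[id(node)] = rate
        duration = node.parent_node.age - node.age
        x = rng.poisson(rate * duration * L)
        node.edge.length = x / L
        true_rates[node.taxon.label if node.taxon else f"node{id(node) % 10_000}"] = rate
    truth = SimTruth(
        "poisson_phylogram",
        {"base_rate": base_rate, "L": L, "sigma": sigma,
         "root_age": float(chronogram.seed_node.age)},
        seed,
        {"ages": {nd.taxon.label if nd.taxon else "": float(nd.age)
                  for nd in chronogram.leaf_node_iter()}},
    )
    return tree, truth


# ---------------------------------------------------------------------------
# GISH signal lists

def simulate_gish_chromosomes(
    comp_green: str,
    comp_red: str,
    table=None,
    green_mean: float = 0.9,
    concentration: float = 50.0,
    seed: int = 0,
) -> tuple[list[GishChromosome], list[str]]:
    """Two-channel GISH signal list for a hybrid metaphase with known origins.

    Chromosomes of the green-probed parental complement draw their green
    fraction from Beta(concentration·green_mean, concentration·(1-green_mean));
    the red-probed complement from the mirror distribution.  Returns the
    chromosome list and the true origin labels ('green'/'red').
    """
    if table is None:
        table = load_reference_table()
    rng = np.random.default_rng(seed)
    chroms: list[GishChromosome] = []
    labels: list[str] = []
    for comp, side in ((comp_green, "green"), (comp_red, "red")):
        for letter in comp:
            kt = table[letter]
            for cat in CATEGORIES:
                for _ in range(getattr(kt, cat)):
                    mean = green_mean if side == "green" else 1.0 - green_mean
                    a = concentration * mean
                    b = concentration * (1.0 - mean)
                    gf = float(rng.beta(a, b))
                    chroms.append(GishChromosome(category=cat, green_fraction=gf))
                    labels.append(side)
    return chroms, labels


# ---------------------------------------------------------------------------
# fixtures on disk

def make_fixtures(outdir: str | Path) -> dict[str, str]:
    """Write the reference tables and a deterministic GISH list; return checksums.

    Output files are byte-identical across runs (the GISH list uses a fixed
    internal seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    checksums: dict[str, str] = {}
    for name in ("table1_karyotypes.tsv", "table2_cohort.tsv"):
        data = resources.files("cobitis").joinpath(f"data/{name}").read_bytes()
        path = outdir / name
        path.write_bytes(data)
        checksums[name] = hashlib.sha256(data).hexdigest()
    chroms, labels = simulate_gish_chromosomes("E", "N", seed=20160125)
    lines = ["category\tgreen_fraction\ttrue_origin"]
    for c, lab in zip(chroms, labels):
        lines.append(f"{c.category}\t{c.green_fraction:.6f}\t{lab}")
    gish = ("\n".join(lines) + "\n").encode()
    (outdir / "gish_signals_EN.tsv").write_bytes(gish)
    checksums["gish_signals_EN.tsv"] = hashlib.sha256(gish).hexdigest()
    return checksums
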