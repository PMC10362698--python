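"""Synthetic homologous families from a simulated phylogeny.

A Yule (pure-birth) tree is grown to the requested number of extant
leaves; a root sequence drawn uniformly over the 20 amino acids then
evolves along the branches under a 20-state Jukes-Cantor process: on a
branch of length t each site substitutes with probability
1 - exp(-rate * t), the replacement uniform over the other 19 residues.
The result is a gap-free alignment whose rows carry genuine tree
structure: close relatives are more similar, and cutting the tree at a
fixed evolutionary distance from the root yields clade labels that a
good sequence embedding should separate.

An optional fitness attachment draws one effect per clade plus a
depth-dependent term and Gaussian noise, emulating a smooth
latent-linked fitness landscape (a T50-like quantity) for regression
tests.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
from dendropy.simulate import treesim
from sklearn.metrics import silhouette_score

from .msa_prep import AlignedFamily

logger = logging.getLogger(__name__)

N_AMINO = 20  # residues 1..20; the simulator emits gap-free alignments


@dataclass
class SimConfig:
    """Desk-scale defaults: 300 leaves (the full-scale reference used
    10,000), length 60, one expected substitution per site per unit
    branch length scaled down to 0.3, and a root-distance clade cut."""

    n_leaves: int = 300
    seq_length: int = 60
    substitution_rate: float = 0.3
    clade_threshold: float = 1.2
    seed: int = 42
    fitness_noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.n_leaves < 2:
            raise ValueError("need at least 2 leaves")
        if self.substitution_rate <= 0 or self.clade_threshold <= 0:
            raise ValueError("rate and clade threshold must be positive")


@dataclass
class SimFamily:
    family: AlignedFamily
    tree: dendropy.Tree
    clade_labels: np.ndarray
    fitness: np.ndarray | None = None
    fitness_true: np.ndarray | None = None  # noise-free values, for recovery tests
    root_distances: np.ndarray = field(default=None)  # type: ignore[assignment]


def simulate_tree(n_leaves: int, seed: int) -> dendropy.Tree:
    """Yule tree (birth rate 1, death rate 0) with ``n_leaves`` extant tips.

    Deterministic for a given seed; leaves are renamed seq_0..seq_{n-1}
    in taxon order and the tree serializes to Newick.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_leaves,
        rng=random.Random(seed))
    # the sampler stops at the n-th speciation, leaving that cherry with
    # zero-length tips; the Yule sample conditioned on n extant tips hangs
    # an Exp(n * birth_rate) tail after the last split
    hang = np.random.default_rng(seed).exponential(1.0 / n_leaves)
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"seq_{i}"
        leaf.edge.length = (leaf.edge.length or 0.0) + hang
    return tree


def evolve_sequences(tree: dendropy.Tree, length: int, rate: float, seed: int
                     ) -> AlignedFamily:
    """Evolve a root sequence down the tree; returns the leaf alignment.

    Residue codes are 1..20 (no gaps), so the family plugs directly
    into the 21-letter one-hot encoding used by the model.
    """
    rng = np.random.default_rng(seed)
    root = tree.seed_node
    seqs: dict[int, np.ndarray] = {
        id(root): rng.integers(1, N_AMINO + 1, size=length).astype(np.int8)}
    ids, rows = [], []
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent_seq = seqs[id(node.parent_node)]
        t = node.edge.length or 0.0
        p_sub = 1.0 - np.exp(-rate * t)
        seq = parent_seq.copy()
        hit = rng.random(length) < p_sub
        if hit.any():
            # uniform over the other 19 residues
            shift = rng.integers(1, N_AMINO, size=int(hit.sum()))
            seq[hit] = ((seq[hit] - 1 + shift) % N_AMINO + 1).astype(np.int8)
        seqs[id(node)] = seq
        if node.is_leaf():
            ids.append(node.taxon.label)
            rows.append(seq)
    return AlignedFamily(ids=ids, matrix=np.stack(rows))


def clade_labels(tree: dendropy.Tree, threshold: float) -> np.ndarray:
    """Group leaves by cutting the tree at ``threshold`` from the root.

    Each maximal subtree whose root edge crosses the threshold becomes
    one group; leaves are labeled in leaf-iteration order.  A threshold
    at or beyond the tree height leaves a single group (with a
    warning).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    group_of: dict[str, int] = {}
    next_label = 0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_dist = node.parent_node.root_distance or 0.0
        if node.root_distance >= threshold > parent_dist:
            for leaf in node.leaf_iter():
                group_of[leaf.taxon.label] = next_label
            next_label += 1
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if not group_of:
        logger.warning("clade threshold %.3g is beyond the tree height; one group",
                       threshold)
        return np.zeros(len(leaves), dtype=int)
    return np.array([group_of[name] for name in leaves], dtype=int)


def simulate_family(cfg: SimConfig) -> SimFamily:
    """Tree + sequences + clade labels in one seeded call."""
    tree = simulate_tree(cfg.n_leaves, cfg.seed)
    fam = evolve_sequences(tree, cfg.seq_length, cfg.substitution_rate, cfg.seed + 1)
    labels = clade_labels(tree, cfg.clade_threshold)
    depths = np.array([lf.root_distance for lf in tree.leaf_node_iter()])
    return SimFamily(family=fam, tree=tree, clade_labels=labels,
                     root_distances=depths)


def attach_fitness(sim: SimFamily, seed: int, noise_sd: float | None = None,
                   base: float = 60.0, clade_sd: float = 4.0,
                   depth_coef: float = 1.0) -> SimFamily:
    """Attach a smooth clade-plus-depth fitness with Gaussian noise.

    fitness_i = base + effect[clade_i] + depth_coef * root_distance_i
    + noise, with one effect per clade drawn once from N(0, clade_sd^2).
    The noise-free values are recorded for recovery tests.  Defaults
    give T50-like values in the 50-70 degree range.
    """
    rng = np.random.default_rng(seed)
    sd = 0.5 if noise_sd is None else noise_sd
    labels = sim.clade_labels
    effects = rng.normal(0.0, clade_sd, size=int(labels.max()) + 1)
    true = base + effects[labels] + depth_coef * sim.root_distances
    sim.fitness_true = true
    sim.fitness = true + rng.normal(0.0, sd, size=true.size)
    return sim


def latent_separation_score(embeddings: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette coefficient (Euclidean) of embeddings vs labels."""
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("silhouette needs at least two labels")
    if counts.min() < 2:
        raise ValueError("every label needs at least two members")
    return float(silhouette_score(np.asarray(embeddings), labels, metric="euclidean"))


def write_newick(tree: dendropy.Tree, path: str) -> None:
    tree.write(path=str(path), schema="newick")


def write_labels_tsv(sim: SimFamily, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("id\tclade\n")
        for name, lab in zip(sim.family.ids, sim.clade_labels):
            fh.write(f"{name}\t{lab}\n")


def write_fitness_tsv(sim: SimFamily, path: str) -> None:
    if sim.fitness is None:
        raise ValueError("no fitness attached")
    with open(path, "w") as fh:
        fh.write("id\tfitness\n")
        for name, y in zip(sim.family.ids, sim.fitness):
            fh.write(f"{name}\t{y:.6f}\n")
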