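"""Sequence simulation under the K2P substitution model.

Sites evolve independently down a rooted tree with branch lengths in
expected substitutions per site, equal base frequencies, and a
transition/transversion *rate* ratio ``kappa = alpha/beta`` (alpha the
transition rate, beta the rate of each of the two transversions; a branch of
length ``d`` has ``d = (alpha + 2*beta) * t``).  The closed-form
substitution probabilities along a branch are

    P(transition)        = 1/4 + 1/4*exp(-4*beta*t) - 1/2*exp(-2*(alpha+beta)*t)
    P(each transversion) = 1/4 - 1/4*exp(-4*beta*t)

which is exact, so no event-level (Gillespie) simulation is needed.  No
indels and no among-site rate variation are generated — the K2P distance
assumes neither; gap handling is exercised with hand-crafted alignments.

Reproducibility: a single NumPy generator keyed by ``seed`` is consumed in a
documented order — the root sequence first, then one uniform draw per site
per branch in preorder — so a fixed seed gives byte-identical output across
runs and platforms.

The genus scenario builder emits a balanced genus-structured tree in which
every between-genus tip-to-tip path length equals ``inter_depth`` and every
within-genus path equals ``intra_depth``, together with the matching FASTA /
Newick / TSV trio, so the whole pipeline can run end-to-end with no data
download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .alignments import AlignedSequence, TaxonTable
from .errors import SimulationSpecError
from .k2p import DistanceMatrix
from .sisters import GenusTree, genus_tree_from_string

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimSpec:
    """A simulation instance: tree (with branch lengths), K2P parameters,
    sequence length, seed, and species-to-genus assignments."""

    newick: str
    kappa: float
    seq_length: int
    seed: int
    genus_map: dict

    def __post_init__(self):
        if not (self.kappa >= 0 and math.isfinite(self.kappa)):
            raise SimulationSpecError(f"kappa must be finite and >= 0, got {self.kappa}")
        if self.seq_length <= 0:
            raise SimulationSpecError("seq_length must be positive")


@dataclass
class GenusScenario:
    """A balanced multi-genus study design.

    ``intra_depth`` / ``inter_depth`` are expected tip-to-tip path lengths
    (substitutions/site) within and between genera; ``inter_depth`` must
    exceed ``intra_depth``.  ``seq_length`` defaults to 10,000 sites so
    distance estimates are tight enough for parameter-recovery checks;
    ``kappa`` defaults to 4, a typical mammalian mitochondrial
    transition/transversion rate ratio.
    """

    n_genera: int
    species_per_genus: int
    intra_depth: float
    inter_depth: float
    seed: int = 0
    seq_length: int = 10_000
    kappa: float = 4.0

    def __post_init__(self):
        if self.n_genera < 2:
            raise SimulationSpecError("a scenario needs at least 2 genera")
        if self.species_per_genus < 1:
            raise SimulationSpecError("species_per_genus must be >= 1")
        if not (self.inter_depth > self.intra_depth >= 0):
            raise SimulationSpecError(
                "need inter_depth > intra_depth >= 0, got "
                f"inter={self.inter_depth} intra={self.intra_depth}"
            )


def branch_transition_matrix(length: float, kappa: float) -> np.ndarray:
    """4x4 base-substitution probability matrix (order A, C, G, T) for one
    branch of the given expected length under K2P."""
    if not (math.isfinite(length) and length >= 0):
        raise SimulationSpecError(f"branch length must be finite and >= 0: {length}")
    beta_t = length / (kappa + 2.0)
    alpha_t = kappa * beta_t
    e1 = math.exp(-4.0 * beta_t)
    e2 = math.exp(-2.0 * (alpha_t + beta_t))
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1  # each of the two transversions
    p_same = 1.0 - p_ts - 2.0 * p_tv
    # A=0, C=1, G=2, T=3; transitions: A<->G, C<->T
    M = np.full((4, 4), p_tv)
    for i, j in ((0, 2), (2, 0), (1, 3), (3, 1)):
        M[i, j] = p_ts
    np.fill_diagonal(M, p_same)
    return M


def _evolve(parent_states: np.ndarray, M: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Vectorized per-site categorical draw: child state from parent state
    via the cumulative rows of M and one uniform per site."""
    cum = np.cumsum(M, axis=1)
    idx = (u[:, None] > cum[parent_states]).sum(axis=1)
    # guard against cum[-1] = 1 - eps under floating-point rounding
    return np.minimum(idx, 3).astype(np.int8)


def simulate_alignment(spec: SimSpec) -> tuple[list[AlignedSequence], DistanceMatrix]:
    """Simulate one alignment and return it with the matrix of true
    tip-to-tip path lengths (percent substitutions/site).

    The root sequence is uniform over {A, C, G, T}; each branch is then
    evolved in preorder with the closed-form substitution probabilities.
    """
    tree = dendropy.Tree.get(
        data=spec.newick, schema="newick", preserve_underscores=True,
        rooting="force-rooted",
    )
    rng = np.random.default_rng(spec.seed)
    L = spec.seq_length
    states: dict = {tree.seed_node: rng.integers(0, 4, size=L, dtype=np.int8)}
    depth: dict = {tree.seed_node: 0.0}
    tip_states: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        blen = node.edge.length if node.edge.length is not None else 0.0
        if not (isinstance(blen, (int, float)) and math.isfinite(blen) and blen >= 0):
            raise SimulationSpecError(f"invalid branch length: {blen!r}")
        depth[node] = depth[node.parent_node] + blen
        M = branch_transition_matrix(float(blen), spec.kappa)
        states[node] = _evolve(states[node.parent_node], M, rng.random(L))
        if node.is_leaf():
            tip_states[node.taxon.label] = states[node]
    # true distances: tip-to-tip path length = depth_i + depth_j - 2*depth_mrca
    labels = tuple(sorted(tip_states))
    leaf_by_label = {
        l.taxon.label: l for l in tree.leaf_node_iter()
    }
    n = len(labels)
    true = np.zeros((n, n))
    pdm = tree.phylogenetic_distance_matrix()
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(
                leaf_by_label[labels[i]].taxon, leaf_by_label[labels[j]].taxon
            )
            true[i, j] = true[j, i] = 100.0 * d
    seqs = [
        AlignedSequence(
            record_id=label,
            species_id=label,
            accession="",
            residues=bytes(_BASES[tip_states[label]]).decode("ascii"),
        )
        for label in labels
    ]
    return seqs, DistanceMatrix(labels=labels, values=true)


def _pectinate(leaves: list[str], tip_len: float) -> str:
    """Binary ladder joining ``leaves`` with zero-length internal edges so
    every leaf sits ``tip_len`` below the subtree root and every leaf pair
    is ``2*tip_len`` apart."""
    clause = f"{leaves[0]}:{tip_len:g}"
    for leaf in leaves[1:]:
        clause = f"({clause},{leaf}:{tip_len:g}):0"
    # strip the trailing ':0' on the subtree root edge; caller appends length
    return clause.rsplit(":", 1)[0] if len(leaves) > 1 else f"{leaves[0]}"


def make_genus_scenario(s: GenusScenario) -> tuple[SimSpec, TaxonTable, GenusTree]:
    """Build the tree, taxonomy table and simulation spec for a scenario.

    Genus MRCAs hang off a zero-length backbone at depth
    ``(inter_depth - intra_depth) / 2`` from the root and species tips a
    further ``intra_depth / 2`` below, so all between-genus paths equal
    ``inter_depth`` and all within-genus paths ``intra_depth`` exactly.
    """
    stem = (s.inter_depth - s.intra_depth) / 2.0
    tip = s.intra_depth / 2.0
    genus_names = [f"Genus{i + 1:02d}" for i in range(s.n_genera)]
    genus_map: dict[str, str] = {}
    clades = []
    for g in genus_names:
        species = [f"{g}_sp{k + 1}" for k in range(s.species_per_genus)]
        for sp in species:
            genus_map[sp] = g
        if len(species) == 1:
            clades.append(f"{species[0]}:{stem + tip:g}")
        else:
            clades.append(f"{_pectinate(species, tip)}:{stem:g}")
    backbone = clades[0]
    for clade in clades[1:]:
        backbone = f"({backbone},{clade}):0"
    newick = backbone.rsplit(":", 1)[0] + ";"
    table = TaxonTable(
        pd.DataFrame(
            {
                "species_id": list(genus_map),
                "genus": [genus_map[sp] for sp in genus_map],
                "accession": ["" for _ in genus_map],
            }
        )
    )
    gtree = genus_tree_from_string(newick, table)
    spec = SimSpec(
        newick=newick,
        kappa=s.kappa,
        seq_length=s.seq_length,
        seed=s.seed,
        genus_map=genus_map,
    )
    return spec, table, gtree
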