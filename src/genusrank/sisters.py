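"""Reference phylogeny handling: monophyly tests and sister-genus enumeration.

The genus-rank procedure is phylogeny-aware: for every genus in a rooted
reference tree the relevant divergence is to its *sister clade* — the other
child (or, below a polytomy, the union of the other children) of the parent
of the genus's most recent common ancestor.  When that sister clade contains
several genera, the focal genus is compared to all species of all of them,
which yields a conservative (downward-biased spread) estimate of sister
divergence.

Only the topology of the supplied Newick tree is used; branch lengths are
discarded.  Tip labels must resolve to species in the taxonomy table.

Node identifiers are assigned by preorder numbering of the internal nodes of
the working tree (after any exclusions), starting at 1, so reports can cite
"node N" the way annotated summary phylogenies do.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import dendropy

from .alignments import TaxonTable
from .errors import (
    GenusNotFoundError,
    InputError,
    MonophylyError,
    TreeError,
    UnmatchedTipError,
)

logger = logging.getLogger("genusrank")


@dataclass(frozen=True)
class SisterComparison:
    """One focal genus versus its sister genus or multi-genus lineage.

    ``species_pairs`` is the full cross product of the focal genus's species
    against the sister clade's species; ``pair_distances``, ``mean`` and
    ``sd`` are filled by :func:`genusrank.twosigma.comparison_stats` (``sd``
    stays None when only one pair exists).
    """

    node_id: int
    focal_genus: str
    sister_genera: frozenset
    species_pairs: tuple
    pair_distances: tuple | None = None
    mean: float | None = None
    sd: float | None = None

    @property
    def label(self) -> str:
        sisters = "+".join(sorted(self.sister_genera))
        return f"{self.focal_genus} vs {sisters}"

    @property
    def n_pairs(self) -> int:
        return len(self.species_pairs)


class GenusTree:
    """A rooted tree whose tips resolve to genera through a taxonomy table."""

    def __init__(self, tree: dendropy.Tree, table: TaxonTable):
        tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(tips) != len(set(tips)):
            dup = sorted({t for t in tips if tips.count(t) > 1})
            raise TreeError(f"duplicate tip labels: {dup}")
        unmatched = sorted(t for t in tips if t not in table)
        if unmatched:
            raise UnmatchedTipError(
                f"tree tips absent from taxonomy table: {unmatched}"
            )
        self.tree = tree
        self.table = table
        self._leafset: dict = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                self._leafset[node] = frozenset([node.taxon.label])
            else:
                s = frozenset()
                for ch in node.child_nodes():
                    s |= self._leafset[ch]
                self._leafset[node] = s
        self._node_id: dict = {}
        next_id = 1
        for node in tree.preorder_node_iter():
            if not node.is_leaf():
                self._node_id[node] = next_id
                next_id += 1

    # -- basic queries -----------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return sorted(self._leafset[self.tree.seed_node])

    @property
    def genera_present(self) -> list[str]:
        return sorted({self.table.genus_of(t) for t in self.tip_labels})

    def tips_of(self, genus: str) -> list[str]:
        tips = [t for t in self.tip_labels if self.table.genus_of(t) == genus]
        if not tips:
            raise GenusNotFoundError(f"genus {genus!r} has no tips in the tree")
        return tips

    def node_id(self, node) -> int:
        return self._node_id[node]

    def mrca(self, labels: Iterable[str]):
        """Smallest node whose descendant tips contain all ``labels``
        (a single label's MRCA is the leaf itself)."""
        want = frozenset(labels)
        # walk up from one tip until the leafset covers the target
        start = next(
            leaf
            for leaf in self.tree.leaf_node_iter()
            if leaf.taxon.label in want
        )
        node = start
        while not want <= self._leafset[node]:
            node = node.parent_node
        return node

    def is_monophyletic(self, genus: str) -> bool:
        """True iff the MRCA of the genus's tips has exactly those tips as
        descendants (singletons are monophyletic by convention)."""
        tips = frozenset(self.tips_of(genus))
        return self._leafset[self.mrca(tips)] == tips

    def without_genera(self, genera: Iterable[str]) -> "GenusTree":
        """A copy of this tree with all tips of ``genera`` removed."""
        drop = set(genera)
        keep = [t for t in self.tip_labels if self.table.genus_of(t) not in drop]
        if len(keep) < 2:
            raise InputError("fewer than two tips remain after exclusions")
        pruned = self.tree.extract_tree_with_taxa_labels(labels=keep)
        return GenusTree(pruned, self.table)


def _load_tree(src: str, table: TaxonTable, *, is_path: bool, root_on: str | None):
    kwargs = dict(schema="newick", preserve_underscores=True, rooting="force-rooted")
    if is_path:
        tree = dendropy.Tree.get(path=str(src), **kwargs)
    else:
        tree = dendropy.Tree.get(data=src, **kwargs)
    if root_on is not None:
        tip = next(
            (l for l in tree.leaf_node_iter() if l.taxon.label == root_on), None
        )
        if tip is None:
            raise UnmatchedTipError(f"--root-on tip {root_on!r} not in tree")
        tree.reroot_at_edge(tip.edge, update_bipartitions=False)
    n_root_children = len(tree.seed_node.child_nodes())
    if n_root_children > 2:
        logger.warning(
            "root has %d children (basal polytomy); treating the tree as "
            "rooted at that polytomy — supply root_on to reroot instead",
            n_root_children,
        )
    return GenusTree(tree, table)


def read_newick(path, table: TaxonTable, root_on: str | None = None) -> GenusTree:
    """Parse a rooted Newick file; tips must match the taxonomy table.

    Branch lengths are ignored.  A basal polytomy is accepted at the root
    with a warning; pass ``root_on=<tip>`` to reroot on a tip's edge instead.
    """
    return _load_tree(str(path), table, is_path=True, root_on=root_on)


def genus_tree_from_string(
    newick: str, table: TaxonTable, root_on: str | None = None
) -> GenusTree:
    """As :func:`read_newick` but from a Newick string."""
    return _load_tree(newick, table, is_path=False, root_on=root_on)


def enumerate_comparisons(
    gtree: GenusTree,
    exclusions: Iterable[str] = (),
    require_monophyly: bool = True,
) -> list[SisterComparison]:
    """Enumerate one sister comparison per genus (distances unfilled).

    Excluded genera are removed from the tree entirely before enumeration.
    Reciprocal genus-versus-single-genus comparisons are deduplicated so each
    pair appears once (keyed by the unordered pair of genus sets), while
    genus-versus-multi-genus-lineage comparisons are kept per focal genus.
    A genus whose MRCA is the root has no sister and is skipped with a
    warning.
    """
    exclusions = set(exclusions)
    work = gtree.without_genera(exclusions) if exclusions else gtree
    genera = work.genera_present
    if require_monophyly:
        offenders = [g for g in genera if not work.is_monophyletic(g)]
        if offenders:
            raise MonophylyError(
                f"non-monophyletic genera: {offenders}; resolve or exclude them"
            )
    out: list[SisterComparison] = []
    seen: set = set()
    for genus in genera:
        tips = frozenset(work.tips_of(genus))
        mrca = work.mrca(tips)
        if mrca is work.tree.seed_node:
            logger.warning("genus %s spans the root; no sister clade, skipped", genus)
            continue
        parent = mrca.parent_node
        sister_tips = work._leafset[parent] - work._leafset[mrca]
        sister_genera = frozenset(work.table.genus_of(t) for t in sister_tips)
        if len(sister_genera) == 1:
            key = frozenset([frozenset([genus]), sister_genera])
        else:
            key = (genus, sister_genera)
        if key in seen:
            continue
        seen.add(key)
        pairs = tuple(
            (f, s) for f in sorted(tips) for s in sorted(sister_tips)
        )
        out.append(
            SisterComparison(
                node_id=work.node_id(parent),
                focal_genus=genus,
                sister_genera=sister_genera,
                species_pairs=pairs,
            )
        )
    return out


def comparisons_to_tsv(cmps: Sequence[SisterComparison], path) -> None:
    """Write comparisons as TSV (node_id, focal_genus, sister_genera,
    n_pairs, mean, sd); unfilled statistics serialize as ``NA``."""
    with open(path, "w") as fh:
        fh.write("node_id\tfocal_genus\tsister_genera\tn_pairs\tmean\tsd\n")
        for c in cmps:
            mean = "NA" if c.mean is None else f"{c.mean:.2f}"
            sd = "NA" if c.sd is None else f"{c.sd:.2f}"
            fh.write(
                f"{c.node_id}\t{c.focal_genus}\t{'+'.join(sorted(c.sister_genera))}"
                f"\t{c.n_pairs}\t{mean}\t{sd}\n"
            )


def fill(cmp: SisterComparison, **fields) -> SisterComparison:
    """Return a copy of ``cmp`` with the given fields replaced."""
    return replace(cmp, **fields)
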