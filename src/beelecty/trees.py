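"""Genus-level phylogenies: Newick IO, cophenetic distances, tip insertion.

Trees are genus-level (one tip per genus) with a companion tip->family map,
mirroring how genus-level backbone phylogenies are used for both the bee
and plant sides of the analysis.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Optional

import dendropy
import numpy as np
import pandas as pd


class GenusTree:
    """A rooted genus-level tree with branch lengths and a tip->family map."""

    def __init__(self, tree: dendropy.Tree, family_map: Mapping[str, str]):
        tree.is_rooted = True
        tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(tips) != len(set(tips)):
            dupes = sorted({t for t in tips if tips.count(t) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError(f"negative branch length: {edge.length}")
        missing = [t for t in tips if t not in family_map]
        if missing:
            raise ValueError(f"tips missing from family map: {missing}")
        self._tree = tree
        self.family_map: Dict[str, str] = {t: family_map[t] for t in tips}

    # -- basic accessors ---------------------------------------------------
    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list:
        return sorted(leaf.taxon.label for leaf in self._tree.leaf_node_iter())

    def __len__(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    # -- IO ----------------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str, family_map: Mapping[str, str]) -> "GenusTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
            raise ValueError(f"duplicate tip labels in newick: {exc}") from exc
        return cls(tree, family_map)

    @classmethod
    def read(cls, path, family_table_path) -> "GenusTree":
        """Read a Newick file plus a companion CSV with genus,family columns."""
        fam = pd.read_csv(family_table_path)
        fam_map = dict(zip(fam["genus"].astype(str), fam["family"].astype(str)))
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
        return cls(tree, fam_map)

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write(self, path, family_table_path=None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_newick() + "\n")
        if family_table_path is not None:
            pd.DataFrame(
                sorted(self.family_map.items()), columns=["genus", "family"]
            ).to_csv(family_table_path, index=False)

    def clone(self) -> "GenusTree":
        return GenusTree(
            self._tree.clone(depth=1), dict(self.family_map)
        )


def cophenetic_distances(tree: GenusTree, genera: Optional[Iterable[str]] = None) -> pd.DataFrame:
    """Pairwise path-length (cophenetic) distances between genus tips.

    Parameters
    ----------
    genera
        Restrict the output to these genera. Every requested genus must be
        a tip of the tree.
    """
    pdm = tree.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.tree.taxon_namespace if t.label in tree.family_map}
    if genera is None:
        wanted = sorted(taxa)
    else:
        wanted = sorted(set(genera))
        absent = [g for g in wanted if g not in taxa]
        if absent:
            raise KeyError(f"genera absent from tree: {absent}")
    n = len(wanted)
    out = np.zeros((n, n))
    for i, a in enumerate(wanted):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[a], taxa[wanted[j]])
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=wanted, columns=wanted)


def insert_missing_genera(
    tree: GenusTree, missing: Mapping[str, str], seed: int
) -> GenusTree:
    """Graft genera absent from the tree as new tips within their family.

    Each missing genus is attached at a uniformly chosen node inside its
    family's clade: the chosen node's subtending edge is bisected and the
    new tip branches off the midpoint with length equal to half that edge
    (for a family represented by a single tip, the new genus becomes its
    sister). Randomness is fully determined by ``seed``.
    """
    rng = np.random.default_rng(seed)
    out = tree.clone()
    t = out.tree
    fam_map = out.family_map

    for genus in sorted(missing):
        family = missing[genus]
        fam_tips = [
            leaf for leaf in t.leaf_node_iter() if fam_map.get(leaf.taxon.label) == family
        ]
        if not fam_tips:
            raise ValueError(f"family {family!r} has no existing tips in the tree")
        if len(fam_tips) == 1:
            candidates = fam_tips
        else:
            mrca = t.mrca(taxa=[leaf.taxon for leaf in fam_tips])
            candidates = [
                n for n in mrca.preorder_iter() if n is not mrca and n.edge.length
            ]
            if not candidates:
                candidates = fam_tips
        target = candidates[rng.integers(len(candidates))]

        edge_len = target.edge.length or 1.0
        parent = target.parent_node
        knot = dendropy.Node()
        knot.edge.length = edge_len / 2.0
        if parent is not None:
            parent.remove_child(target)
            parent.add_child(knot)
        else:  # target is the seed node's child-less corner case
            t.seed_node = knot
        target.edge.length = edge_len / 2.0
        knot.add_child(target)
        taxon = t.taxon_namespace.new_taxon(label=genus)
        tip = dendropy.Node(taxon=taxon)
        tip.edge.length = edge_len / 2.0
        knot.add_child(tip)
        fam_map[genus] = family

    return GenusTree(t, fam_map)
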