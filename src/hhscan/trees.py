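"""Gene-tree collections: newick I/O and genomic anchors."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple

import dendropy
import pandas as pd

from .io import InputError


@dataclass
class GeneTreeSet:
    """An ordered collection of rooted gene trees.

    Tip labels carry group and individual identity (e.g. ``C1_2`` is the
    second haplotype of individual 1 in group C).  Internal-node labels,
    when numeric, are read as support values in [0, 100].  ``anchors``
    optionally places each tree at a genomic coordinate (chrom, 1-based
    position) for windowed analyses.
    """

    trees: List[dendropy.Tree]
    anchors: Optional[List[Tuple[str, int]]] = None

    def __post_init__(self) -> None:
        if self.anchors is not None and len(self.anchors) != len(self.trees):
            raise InputError(
                f"{len(self.anchors)} anchors for {len(self.trees)} trees"
            )

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)


def read_gene_trees(path: str | Path, anchors_path: str | Path | None = None) -> GeneTreeSet:
    """Read one newick tree per line; internal labels are kept as supports."""
    trees = dendropy.TreeList.get(
        path=str(path),
        schema="newick",
        suppress_internal_node_taxa=True,
        rooting="default-rooted",
        preserve_underscores=True,
    )
    anchors = None
    if anchors_path is not None:
        df = pd.read_csv(anchors_path, sep="\t")
        if not {"chrom", "pos"} <= set(df.columns):
            raise InputError(f"anchors file {anchors_path} needs columns 'chrom' and 'pos'")
        anchors = list(zip(df["chrom"].astype(str), df["pos"].astype(int)))
    return GeneTreeSet(trees=list(trees), anchors=anchors)


def write_gene_trees(
    treeset: GeneTreeSet, path: str | Path, anchors_path: str | Path | None = None
) -> None:
    with open(path, "w") as fh:
        for tree in treeset.trees:
            fh.write(
                tree.as_string(
                    schema="newick",
                    suppress_rooting=True,
                    unquoted_underscores=True,
                ).strip()
                + "\n"
            )
    if anchors_path is not None and treeset.anchors is not None:
        pd.DataFrame(treeset.anchors, columns=["chrom", "pos"]).to_csv(
            anchors_path, sep="\t", index=False
        )
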