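"""Dollo parsimony mapping of synteny loss onto the fixed species tree.

Each ancestral block (an Amborella physical-map contig) is assumed
present at the root — synteny with an ancestral block, once destroyed, is
not regained, so a single origin with losses only (Dollo) is the apt
model. For a given presence/absence pattern over the tips, the minimum
set of loss branches is the set of stems of the maximal all-absent
clades; losses are thereby placed as deep as possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .synteny_anchor import SyntenyCall
from .synthetic_data import BRANCHES, SPECIES_TREE_NEWICK, TAXA

__all__ = [
    "build_presence_matrix",
    "dollo_loss_map",
    "dollo_losses_for_pattern",
    "LossMap",
    "TreeNode",
    "parse_species_tree",
]


@dataclass
class TreeNode:
    """Rooted tree node; the branch above a node is named by its tips."""

    children: list["TreeNode"] = field(default_factory=list)
    taxon: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def tips(self) -> tuple[str, ...]:
        if self.is_leaf:
            return (self.taxon,)
        out: list[str] = []
        for c in self.children:
            out.extend(c.tips())
        return tuple(out)

    @property
    def branch_name(self) -> str:
        return "+".join(self.tips())


def parse_species_tree(newick: str = SPECIES_TREE_NEWICK) -> TreeNode:
    """Parse a newick topology (branch lengths ignored) into a TreeNode."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")

    def convert(node) -> TreeNode:
        if node.is_leaf():
            return TreeNode(taxon=node.taxon.label.replace(" ", "_"))
        return TreeNode(children=[convert(c) for c in node.child_nodes()])

    return convert(tree.seed_node)


def build_presence_matrix(
    synteny_calls: Iterable[SyntenyCall] | Iterable[tuple[str, str]],
    taxa: Sequence[str] = TAXA,
    contigs: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Block x taxon presence matrix from synteny calls.

    A cell is present iff the contig has >= 1 call against that taxon's
    genome; the Amborella column is forced present (blocks are defined
    from Amborella contigs). ``synteny_calls`` may be SyntenyCall objects
    or raw (contig_id, taxon) pairs. ``contigs`` optionally fixes the row
    set (e.g. all eligible contigs, including ones with no call anywhere).
    """
    pairs: list[tuple[str, str]] = []
    for call in synteny_calls:
        if isinstance(call, SyntenyCall):
            pairs.append((call.contig_id, call.genome))
        else:
            pairs.append((call[0], call[1]))
    for _contig, taxon in pairs:
        if taxon not in taxa:
            raise ValueError(f"synteny call references unknown taxon '{taxon}'")
    row_ids = sorted(contigs) if contigs is not None else sorted({c for c, _ in pairs})
    matrix = pd.DataFrame(False, index=row_ids, columns=list(taxa))
    for contig, taxon in pairs:
        if contig in matrix.index:
            matrix.loc[contig, taxon] = True
    if "Amborella" in matrix.columns:
        matrix["Amborella"] = True
    return matrix


@dataclass
class LossMap:
    """Per-branch Dollo loss totals plus per-block placements."""

    branch_losses: dict[str, int]
    block_placements: dict[str, tuple[str, ...]]

    @property
    def total_losses(self) -> int:
        return sum(self.branch_losses.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"losses": [self.branch_losses.get(b, 0) for b in BRANCHES]},
            index=list(BRANCHES),
        )


def dollo_losses_for_pattern(
    absent: set[str], tree: TreeNode
) -> tuple[str, ...]:
    """Minimum-cardinality loss branches for one block's absence pattern.

    The minimum set is unique: the stems of the maximal clades whose tips
    are all absent (each such stem explains its whole clade with one loss;
    any other minimal explanation needs at least as many, shallower,
    losses — the deep placement is therefore also the tie policy).
    """
    placements: list[str] = []

    def place(node: TreeNode) -> None:
        for child in node.children:
            if all(t in absent for t in child.tips()):
                placements.append(child.branch_name)
            else:
                place(child)

    place(tree)
    return tuple(sorted(placements))


def dollo_loss_map(
    matrix: pd.DataFrame,
    tree: TreeNode | None = None,
) -> LossMap:
    """Map synteny losses for every block onto the species tree.

    ``matrix`` is the block x taxon presence matrix; blocks absent in
    Amborella violate the single-origin convention and raise. Returns
    per-branch totals and per-block loss placements.
    """
    tree = tree or parse_species_tree()
    tree_taxa = set(tree.tips())
    if not tree_taxa <= set(matrix.columns):
        missing = tree_taxa - set(matrix.columns)
        raise ValueError(f"matrix lacks taxa {sorted(missing)}")
    branch_losses: dict[str, int] = {}
    block_placements: dict[str, tuple[str, ...]] = {}
    for block, row in matrix.iterrows():
        if "Amborella" in matrix.columns and not row["Amborella"]:
            raise ValueError(
                f"block '{block}' absent in Amborella: blocks are defined "
                "from Amborella contigs and must be present there"
            )
        absent = {t for t in tree_taxa if not row[t]}
        placements = dollo_losses_for_pattern(absent, tree)
        block_placements[str(block)] = placements
        for b in placements:
            branch_losses[b] = branch_losses.get(b, 0) + 1
    return LossMap(branch_losses=branch_losses, block_placements=block_placements)


def write_loss_tables(
    loss_map: LossMap, branch_path, placement_path
) -> None:
    loss_map.to_frame().to_csv(branch_path, sep="\t", index_label="branch")
    with open(placement_path, "w") as fh:
        fh.write("block\tloss_branches\n")
        for block, placements in sorted(loss_map.block_placements.items()):
            fh.write(f"{block}\t{','.join(placements) if placements else '.'}\n")
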