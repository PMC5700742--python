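"""Clade labeling of phylogenetic trees via reference anchor leaves.

To place query sequences (e.g. the NAC or WRKY members of a newly
annotated genome) into the clades defined by a reference study, reference
sequences of known clade membership ("anchors") are included in the tree.
Each query leaf is then labeled either by its nearest anchor (minimal
patristic distance) or by the smallest enclosing clade that contains an
anchor. Labeled trees support per-species group censuses, monophyly
checks, and a root-to-group ordering used to compare tree organisation
across studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import dendropy

from .errors import ConfigurationError, InputError

logger = logging.getLogger("tfrep")


@dataclass
class AnchoredTree:
    """A rooted tree plus anchor (leaf -> group) and species maps."""

    tree: dendropy.Tree
    anchors: dict[str, str] = field(default_factory=dict)
    species: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = set(self.leaf_map())
        missing = set(self.anchors) - labels
        if missing:
            raise ConfigurationError(
                f"anchor leaves not in tree: {sorted(missing)}"
            )

    def leaf_map(self) -> dict[str, dendropy.Node]:
        out = {}
        for leaf in self.tree.leaf_node_iter():
            label = leaf.taxon.label if leaf.taxon else leaf.label
            out[label] = leaf
        return out

    def is_rooted(self) -> bool:
        # A basal trifurcation is the classic unrooted representation.
        return bool(self.tree.is_rooted) or len(
            self.tree.seed_node.child_nodes()
        ) <= 2


def load_tree(path_or_string: str | Path, midpoint_root: bool = False) -> dendropy.Tree:
    """Read a newick tree (file path or literal string). With
    ``midpoint_root`` the tree is midpoint-rooted after loading."""
    src = str(path_or_string)
    if src.lstrip().startswith("("):
        tree = dendropy.Tree.get(data=src, schema="newick", preserve_underscores=True)
    else:
        tree = dendropy.Tree.get(path=src, schema="newick", preserve_underscores=True)
    if midpoint_root:
        tree.reroot_at_midpoint(update_bipartitions=True)
        tree.is_rooted = True
    return tree


def read_two_column_tsv(path: str | Path) -> dict[str, str]:
    """Read a leaf -> label map (anchor or species assignments)."""
    out = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 2:
                raise InputError(f"{path}:{ln}: expected 2 columns")
            out[f[0]] = f[1]
    return out


# ---------------------------------------------------------------------------
# tree arithmetic (paths, depths, MRCA) on dendropy nodes


def _path_to_root(node: dendropy.Node) -> list[dendropy.Node]:
    path = [node]
    while path[-1].parent_node is not None:
        path.append(path[-1].parent_node)
    return path


def _edge_len(node: dendropy.Node) -> float:
    length = node.edge.length if node.edge is not None else None
    return float(length) if length is not None else 0.0


def _depth_maps(tree: dendropy.Tree) -> tuple[dict, dict]:
    """(branch-length depth, edge-count depth) for every node."""
    blen: dict[dendropy.Node, float] = {}
    edges: dict[dendropy.Node, int] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            blen[node] = 0.0
            edges[node] = 0
        else:
            blen[node] = blen[node.parent_node] + _edge_len(node)
            edges[node] = edges[node.parent_node] + 1
    return blen, edges


def _mrca(a: dendropy.Node, b: dendropy.Node) -> dendropy.Node:
    ancestors_a = set(_path_to_root(a))
    for node in _path_to_root(b):
        if node in ancestors_a:
            return node
    raise InputError("nodes share no ancestor (disconnected tree)")


def patristic_distance(
    tree: dendropy.Tree, leaf_a: dendropy.Node, leaf_b: dendropy.Node
) -> float:
    blen, _ = _depth_maps(tree)
    m = _mrca(leaf_a, leaf_b)
    return blen[leaf_a] + blen[leaf_b] - 2.0 * blen[m]


# ---------------------------------------------------------------------------


def assign_groups(
    atree: AnchoredTree, method: str = "nearest-anchor"
) -> dict[str, Optional[str]]:
    """Label every leaf with a group.

    ``nearest-anchor`` gives each query leaf the group of the anchor at
    minimal patristic distance (ties: smaller query-to-MRCA distance, then
    lexicographically smallest group, logged). ``smallest-anchored-clade``
    gives the group of the smallest clade containing the query and at
    least one anchor, provided all anchors in that clade agree; otherwise
    the leaf stays unlabeled. Anchors keep their own labels. With no
    anchors all queries are unlabeled.
    """
    if method not in ("nearest-anchor", "smallest-anchored-clade"):
        raise ConfigurationError(f"unknown method {method!r}")
    if not atree.is_rooted():
        raise InputError(
            "tree is unrooted (basal multifurcation): re-load with "
            "midpoint_root=True or supply a rooted tree"
        )
    leaves = atree.leaf_map()
    anchor_nodes = {name: leaves[name] for name in atree.anchors}
    blen, _ = _depth_maps(atree.tree)

    labels: dict[str, Optional[str]] = {}
    for name, node in leaves.items():
        if name in atree.anchors:
            labels[name] = atree.anchors[name]
            continue
        if not anchor_nodes:
            labels[name] = None
            continue
        if method == "nearest-anchor":
            candidates = []
            for aname, anode in anchor_nodes.items():
                m = _mrca(node, anode)
                dist = blen[node] + blen[anode] - 2.0 * blen[m]
                to_mrca = blen[node] - blen[m]
                candidates.append((dist, to_mrca, atree.anchors[aname], aname))
            candidates.sort()
            if len(candidates) > 1 and candidates[0][:2] == candidates[1][:2] \
                    and candidates[0][2] != candidates[1][2]:
                logger.info(
                    "leaf %s equidistant from groups %s and %s: chose %s",
                    name, candidates[0][2], candidates[1][2], candidates[0][2],
                )
            labels[name] = candidates[0][2]
        else:
            labels[name] = _smallest_anchored_clade_label(node, atree)
    return labels


def _smallest_anchored_clade_label(
    node: dendropy.Node, atree: AnchoredTree
) -> Optional[str]:
    current = node.parent_node
    while current is not None:
        groups = set()
        for leaf in current.leaf_iter():
            label = leaf.taxon.label if leaf.taxon else leaf.label
            if label in atree.anchors:
                groups.add(atree.anchors[label])
        if groups:
            return groups.pop() if len(groups) == 1 else None
        current = current.parent_node
    return None


@dataclass
class GroupCensus:
    """Per-(group, species) leaf counts with per-group monophyly flags."""

    counts: dict[tuple[str, str], int]
    monophyletic: dict[str, bool]

    def count(self, group: str, species: str) -> int:
        return self.counts.get((group, species), 0)


def group_census(
    atree: AnchoredTree, labels: dict[str, Optional[str]]
) -> GroupCensus:
    """Count labeled leaves per (group, species) and flag each group
    monophyletic iff its leaves form a complete clade."""
    leaves = atree.leaf_map()
    counts: dict[tuple[str, str], int] = {}
    members: dict[str, list[dendropy.Node]] = {}
    for name, group in labels.items():
        if group is None:
            continue
        sp = atree.species.get(name, "unknown")
        counts[(group, sp)] = counts.get((group, sp), 0) + 1
        members.setdefault(group, []).append(leaves[name])
    mono = {}
    for group, nodes in members.items():
        m = nodes[0]
        for other in nodes[1:]:
            m = _mrca(m, other)
        clade_size = sum(1 for _ in m.leaf_iter())
        mono[group] = clade_size == len(nodes)
    return GroupCensus(counts, mono)


def root_order(
    atree: AnchoredTree, labels: dict[str, Optional[str]]
) -> list[list[str]]:
    """Order groups by the depth of each group's MRCA (edge count from the
    root, branch-length depth as tie-break). Groups tied on both are
    reported together as one rank (a list), so the result is a list of
    ranks from closest-to-root to furthest.
    """
    leaves = atree.leaf_map()
    blen, edges = _depth_maps(atree.tree)
    members: dict[str, list[dendropy.Node]] = {}
    for name, group in labels.items():
        if group is not None:
            members.setdefault(group, []).append(leaves[name])
    keyed = []
    for group, nodes in members.items():
        m = nodes[0]
        for other in nodes[1:]:
            m = _mrca(m, other)
        keyed.append(((edges[m], blen[m]), group))
    keyed.sort(key=lambda t: (t[0], t[1]))
    ranks: list[list[str]] = []
    last_key = None
    for key, group in keyed:
        if key == last_key:
            ranks[-1].append(group)
        else:
            ranks.append([group])
            last_key = key
    return ranks


# ---------------------------------------------------------------------------
# output


def write_labeled_tree(
    atree: AnchoredTree, labels: dict[str, Optional[str]], path: str | Path
) -> None:
    """Write a newick copy with each labeled leaf renamed ``name|group``."""
    # re-parse rather than clone: dendropy shallow clones share the taxon
    # namespace, and relabeling must not mutate the input tree
    tree = dendropy.Tree.get(
        data=atree.tree.as_string(schema="newick"),
        schema="newick",
        preserve_underscores=True,
    )
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else leaf.label
        group = labels.get(label)
        if group is not None and leaf.taxon:
            leaf.taxon.label = f"{label}|{group}"
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


def write_census_tsv(census: GroupCensus, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("group\tspecies\tcount\tmonophyletic\n")
        for (group, sp), n in sorted(census.counts.items()):
            fh.write(f"{group}\t{sp}\t{n}\t{census.monophyletic[group]}\n")
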