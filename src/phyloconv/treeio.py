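"""Rooted phylogenies with branch lengths: Newick I/O, pruning, distances.

Node ids are stable integers assigned in post-order during parsing; all
deterministic tie-breaking elsewhere in the package references this order.
Branch lengths are required on every non-root edge because every downstream
comparative method is undefined without them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NewickError",
    "TreeError",
    "TreeNode",
    "Phylogeny",
    "parse_newick",
    "write_newick",
    "prune_to_taxa",
    "patristic_matrix",
    "is_ultrametric",
    "read_newick_file",
    "write_newick_file",
]


class TreeError(ValueError):
    """Invalid tree structure or operation."""


class NewickError(TreeError):
    """Malformed Newick input; message carries the offending position."""


@dataclass
class TreeNode:
    id: int
    parent_id: Optional[int]
    child_ids: list[int] = field(default_factory=list)
    branch_length: Optional[float] = None  # None only at the root
    label: str = ""

    @property
    def is_tip(self) -> bool:
        return not self.child_ids


class Phylogeny:
    """A rooted tree with branch lengths, indexed by integer node ids."""

    def __init__(self, nodes: dict[int, TreeNode], root_id: int):
        self.nodes = nodes
        self.root_id = root_id
        self._validate()

    # -- construction / validation -------------------------------------

    def _validate(self) -> None:
        if self.root_id not in self.nodes:
            raise TreeError("root id not among nodes")
        root = self.nodes[self.root_id]
        if root.parent_id is not None:
            raise TreeError("root must not have a parent")
        seen: set[int] = set()
        stack = [self.root_id]
        while stack:
            nid = stack.pop()
            if nid in seen:
                raise TreeError("cycle detected in tree")
            seen.add(nid)
            node = self.nodes[nid]
            for cid in node.child_ids:
                child = self.nodes.get(cid)
                if child is None or child.parent_id != nid:
                    raise TreeError(f"broken parent link at node {cid}")
                stack.append(cid)
        if seen != set(self.nodes):
            raise TreeError("tree is not connected (orphan nodes present)")
        labels = [self.nodes[t].label for t in self.tip_ids]
        if any(not lab for lab in labels):
            raise TreeError("every tip must carry a non-empty label")
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dup}")
        for nid, node in self.nodes.items():
            if nid != self.root_id:
                bl = node.branch_length
                if bl is None or not math.isfinite(bl) or bl < 0:
                    raise TreeError(
                        f"node {nid} ({node.label or 'internal'}) lacks a "
                        f"finite non-negative branch length"
                    )

    # -- basic queries --------------------------------------------------

    @property
    def tip_ids(self) -> list[int]:
        return [nid for nid in self.postorder() if self.nodes[nid].is_tip]

    @property
    def tip_labels(self) -> list[str]:
        return [self.nodes[t].label for t in self.tip_ids]

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    @property
    def branch_ids(self) -> list[int]:
        """All non-root node ids (a branch is named by its child node)."""
        return [nid for nid in self.postorder() if nid != self.root_id]

    def postorder(self) -> Iterator[int]:
        stack: list[tuple[int, bool]] = [(self.root_id, False)]
        while stack:
            nid, expanded = stack.pop()
            if expanded:
                yield nid
            else:
                stack.append((nid, True))
                for cid in reversed(self.nodes[nid].child_ids):
                    stack.append((cid, False))

    def preorder(self) -> Iterator[int]:
        stack = [self.root_id]
        while stack:
            nid = stack.pop()
            yield nid
            for cid in reversed(self.nodes[nid].child_ids):
                stack.append(cid)

    def depths(self) -> dict[int, float]:
        """Sum of branch lengths from the root to every node."""
        out = {self.root_id: 0.0}
        for nid in self.preorder():
            if nid == self.root_id:
                continue
            node = self.nodes[nid]
            out[nid] = out[node.parent_id] + node.branch_length
        return out

    def tip_id_of_label(self) -> dict[str, int]:
        return {self.nodes[t].label: t for t in self.tip_ids}

    def path_to_root(self, nid: int) -> list[int]:
        """Node ids from ``nid`` up to and including the root."""
        path = [nid]
        while self.nodes[path[-1]].parent_id is not None:
            path.append(self.nodes[path[-1]].parent_id)
        return path

    def mrca(self, a: int, b: int) -> int:
        anc_a = set(self.path_to_root(a))
        for nid in self.path_to_root(b):
            if nid in anc_a:
                return nid
        raise TreeError("disconnected nodes")  # pragma: no cover

    def subtree_ids(self, nid: int) -> list[int]:
        out = []
        stack = [nid]
        while stack:
            cur = stack.pop()
            out.append(cur)
            stack.extend(self.nodes[cur].child_ids)
        return out

    def copy(self) -> "Phylogeny":
        nodes = {
            nid: TreeNode(n.id, n.parent_id, list(n.child_ids),
                          n.branch_length, n.label)
            for nid, n in self.nodes.items()
        }
        return Phylogeny(nodes, self.root_id)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny with {self.n_tips} tips, {len(self.nodes)} nodes>"


# ---------------------------------------------------------------------------
# Newick parsing
# ---------------------------------------------------------------------------

def _strip_comments(text: str) -> str:
    out, depth = [], 0
    for ch in text:
        if ch == "[":
            depth += 1
        elif ch == "]":
            if depth == 0:
                raise NewickError("unbalanced ']' comment bracket")
            depth -= 1
        elif depth == 0:
            out.append(ch)
    if depth:
        raise NewickError("unterminated '[' comment")
    return "".join(out)


class _Cursor:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def next(self) -> str:
        ch = self.peek()
        self.pos += 1
        return ch

    def skip_ws(self) -> None:
        while self.peek() and self.peek() in " \t\n\r":
            self.pos += 1

    def error(self, msg: str) -> NewickError:
        return NewickError(f"{msg} at position {self.pos}")


_LABEL_TERMINATORS = set("(),:;")


def _read_label(cur: _Cursor) -> str:
    cur.skip_ws()
    if cur.peek() == "'":
        cur.next()
        out = []
        while True:
            ch = cur.next()
            if ch == "":
                raise cur.error("unterminated quoted label")
            if ch == "'":
                if cur.peek() == "'":  # escaped quote
                    out.append("'")
                    cur.next()
                    continue
                break
            out.append(ch)
        return "".join(out)
    out = []
    while cur.peek() and cur.peek() not in _LABEL_TERMINATORS:
        out.append(cur.next())
    return "".join(out).strip().replace("_", " ") or ""


def _read_length(cur: _Cursor) -> Optional[float]:
    cur.skip_ws()
    if cur.peek() != ":":
        return None
    cur.next()
    cur.skip_ws()
    start = cur.pos
    while cur.peek() and cur.peek() in "0123456789+-.eE":
        cur.next()
    token = cur.text[start:cur.pos]
    try:
        return float(token)
    except ValueError:
        cur.pos = start
        raise cur.error(f"invalid branch length {token!r}")


class _Raw:
    __slots__ = ("children", "label", "length", "pos")

    def __init__(self) -> None:
        self.children: list[_Raw] = []
        self.label = ""
        self.length: Optional[float] = None
        self.pos = 0


def _parse_clade(cur: _Cursor) -> _Raw:
    node = _Raw()
    node.pos = cur.pos
    cur.skip_ws()
    if cur.peek() == "(":
        cur.next()
        while True:
            node.children.append(_parse_clade(cur))
            cur.skip_ws()
            ch = cur.peek()
            if ch == ",":
                cur.next()
                continue
            if ch == ")":
                cur.next()
                break
            raise cur.error("expected ',' or ')'")
    node.label = _read_label(cur)
    node.length = _read_length(cur)
    return node


def parse_newick(text: str) -> Phylogeny:
    """Parse a single Newick tree with branch lengths on all non-root edges.

    Quoted and unquoted labels are supported; square-bracket comments are
    stripped; a trifurcating (unrooted-style) root is rejected.
    """
    cur = _Cursor(_strip_comments(text))
    cur.skip_ws()
    if cur.peek() != "(":
        raise cur.error("tree must start with '('")
    root = _parse_clade(cur)
    cur.skip_ws()
    if cur.peek() != ";":
        raise cur.error("expected ';' after tree")
    cur.next()
    cur.skip_ws()
    if cur.peek():
        raise cur.error("trailing characters after ';'")

    if len(root.children) > 2:
        raise NewickError(
            f"root has {len(root.children)} children; an unrooted "
            f"trifurcating root is not accepted"
        )

    # assign stable integer ids in post-order
    nodes: dict[int, TreeNode] = {}
    counter = 0

    def build(raw: _Raw, parent_id: Optional[int]) -> int:
        nonlocal counter
        child_ids = []
        # post-order: children receive ids before their parent; parent ids
        # are patched afterwards
        placeholder: list[int] = []
        for ch in raw.children:
            placeholder.append(build(ch, None))
        nid = counter
        counter += 1
        for cid in placeholder:
            nodes[cid].parent_id = nid
            child_ids.append(cid)
        if parent_id is None and raw.length is None:
            bl = None
        else:
            bl = raw.length
        if not raw.children and raw.length is None:
            raise NewickError(
                f"tip {raw.label!r} lacks a branch length "
                f"(near position {raw.pos})"
            )
        nodes[nid] = TreeNode(nid, None, child_ids, bl, raw.label)
        return nid

    root_id = build(root, None)
    node = nodes[root_id]
    if node.branch_length is not None and node.branch_length != 0.0:
        # a root edge has no meaning in a rooted tree; keep depth 0
        node.branch_length = None
    else:
        node.branch_length = None
    for nid, n in nodes.items():
        if nid != root_id and n.branch_length is None:
            raise NewickError(
                f"internal node {n.label or nid} lacks a branch length"
            )
    try:
        return Phylogeny(nodes, root_id)
    except TreeError as exc:
        raise NewickError(str(exc)) from exc


def _format_label(label: str) -> str:
    if label == "":
        return ""
    if any(ch in label for ch in "(),:;'\t\n []"):
        return "'" + label.replace("'", "''") + "'"
    return label.replace(" ", "_")


def write_newick(tree: Phylogeny) -> str:
    """Serialize to Newick; branch lengths keep 12 significant digits."""

    def emit(nid: int) -> str:
        node = tree.nodes[nid]
        if node.is_tip:
            body = _format_label(node.label)
        else:
            inner = ",".join(emit(c) for c in node.child_ids)
            body = f"({inner}){_format_label(node.label)}"
        if node.branch_length is not None:
            body += f":{node.branch_length:.12g}"
        return body

    return emit(tree.root_id) + ";"


def read_newick_file(path) -> Phylogeny:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_newick(fh.read())


def write_newick_file(tree: Phylogeny, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(write_newick(tree) + "\n")


# ---------------------------------------------------------------------------
# Structural operations
# ---------------------------------------------------------------------------

def prune_to_taxa(tree: Phylogeny, keep: Sequence[str] | set[str]) -> Phylogeny:
    """Restrict the tree to the tips in ``keep``.

    Unary internal nodes left behind are removed with their branch lengths
    summed onto the child, so patristic distances among kept tips are
    preserved exactly. The returned tree has fresh post-order node ids.
    """
    keep = set(keep)
    have = set(tree.tip_labels)
    unknown = sorted(keep - have)
    if unknown:
        raise TreeError(f"labels not in tree: {unknown}")
    if len(keep) < 2:
        raise TreeError("need at least 2 tips to keep")

    # mark nodes on a root->kept-tip path
    keep_ids = {tid for tid in tree.tip_ids if tree.nodes[tid].label in keep}
    marked: set[int] = set()
    for tid in keep_ids:
        for nid in tree.path_to_root(tid):
            if nid in marked:
                break
            marked.add(nid)

    # rebuild: collapse unary chains, drop root stem
    def collapse(nid: int, extra: float) -> tuple[list, float, str]:
        """Return (children_raw, total_length, label) for the surviving node."""
        node = tree.nodes[nid]
        kept_children = [c for c in node.child_ids if c in marked]
        bl = (node.branch_length or 0.0) + extra
        if nid in keep_ids:
            return [], bl, node.label
        if len(kept_children) == 1:
            return collapse(kept_children[0], bl)
        return ([collapse(c, 0.0) for c in kept_children], bl, node.label)

    root = tree.root_id
    kept_children = [c for c in tree.nodes[root].child_ids if c in marked]
    if len(kept_children) == 1:
        # root became unary: new root is the first descendant with >=2 kept
        # children (its stem length is discarded; depths shift, patristic
        # distances do not)
        nid = kept_children[0]
        while True:
            kc = [c for c in tree.nodes[nid].child_ids if c in marked]
            if len(kc) >= 2 or nid in keep_ids:
                break
            nid = kc[0]
        raw_children = [collapse(c, 0.0)
                        for c in tree.nodes[nid].child_ids if c in marked]
        raw = (raw_children, 0.0, tree.nodes[nid].label)
    else:
        raw = ([collapse(c, 0.0) for c in kept_children], 0.0,
               tree.nodes[root].label)

    nodes: dict[int, TreeNode] = {}
    counter = 0

    def build(raw_node, is_root: bool) -> int:
        nonlocal counter
        children_raw, bl, label = raw_node
        cids = [build(c, False) for c in children_raw]
        nid = counter
        counter += 1
        for cid in cids:
            nodes[cid].parent_id = nid
        nodes[nid] = TreeNode(nid, None, cids,
                              None if is_root else bl, label)
        return nid

    return Phylogeny(nodes, build(raw, True))


def patristic_matrix(tree: Phylogeny) -> pd.DataFrame:
    """Tip-pair path-length matrix (symmetric, zero diagonal), label-indexed."""
    tips = tree.tip_ids
    labels = [tree.nodes[t].label for t in tips]
    depths = tree.depths()
    pos = {t: i for i, t in enumerate(tips)}
    n = len(tips)
    mrca_depth = np.zeros((n, n))
    np.fill_diagonal(mrca_depth, [depths[t] for t in tips])

    # for each internal node, pairs of tips in different child subtrees have
    # their MRCA exactly there
    tips_below: dict[int, list[int]] = {}
    for nid in tree.postorder():
        node = tree.nodes[nid]
        if node.is_tip:
            tips_below[nid] = [pos[nid]]
            continue
        groups = [tips_below[c] for c in node.child_ids]
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                a = np.array(groups[i])[:, None]
                b = np.array(groups[j])[None, :]
                mrca_depth[a, b] = depths[nid]
                mrca_depth[b.T, a.T] = depths[nid]
        tips_below[nid] = [x for g in groups for x in g]

    d = np.array([depths[t] for t in tips])
    mat = d[:, None] + d[None, :] - 2.0 * mrca_depth
    np.fill_diagonal(mat, 0.0)
    return pd.DataFrame(mat, index=labels, columns=labels)


def shared_depth_matrix(tree: Phylogeny) -> pd.DataFrame:
    """Depth of the MRCA for every tip pair (diagonal = tip depth)."""
    tips = tree.tip_ids
    labels = [tree.nodes[t].label for t in tips]
    depths = tree.depths()
    pm = patristic_matrix(tree).to_numpy()
    d = np.array([depths[t] for t in tips])
    shared = (d[:, None] + d[None, :] - pm) / 2.0
    return pd.DataFrame(shared, index=labels, columns=labels)


def is_ultrametric(tree: Phylogeny, rel_tol: float = 1e-6) -> tuple[bool, float]:
    """Check tip-depth equality; returns (flag, max depth spread)."""
    depths = tree.depths()
    tip_depths = [depths[t] for t in tree.tip_ids]
    lo, hi = min(tip_depths), max(tip_depths)
    spread = hi - lo
    if hi == 0:
        return True, 0.0
    return (spread / hi) <= rel_tol, spread
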