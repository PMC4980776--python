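"""Canonical atom signatures.

An atom signature is a canonical text encoding of the bonded environment
around one atom (the *root*) up to a topological radius *height* h: the
height-0 signature is just the root's label, height 1 adds its neighbours,
and so on.  The signature of a molecule is the multiset of its atoms'
signatures; pooling consecutive heights (1-3 by default) gives a sparse
substructure-count descriptor that works well with linear models.

Encoding
--------
The encoded subgraph is the ball of radius h around the root: all atoms at
bond distance <= h and every bond between them.  Atom labels are bracketed
element symbols, lower-cased when aromatic, with an optional formal-charge
suffix (``[C]``, ``[c]``, ``[O-]``, ``[N+]``).  A vertex's children are its
next-layer neighbours, rendered inside one pair of parentheses and each
prefixed by its bond symbol ("" single, ``=`` double, ``#`` triple;
aromatic bonds are implied by aromatic atom labels).  Rings make the
expansion re-visit atoms: an atom reached along several branches is
rendered in each branch, and a bond between two atoms of the same layer is
rendered as a leaf back-reference inside that layer (so the text saturates
exactly at the root's eccentricity).  Every atom that occurs more than
once carries a closure integer, shared by all its occurrences and numbered
by first appearance in the final string, which makes the text decodable.

Canonical order: the children of each vertex are sorted by their fully
rendered subtrees (closure numbers blanked); residual ties, which can only
matter when closures are present, are broken by taking the
lexicographically smallest complete string over the tied orderings.  The
result is deterministic and independent of atom input order.
"""

from __future__ import annotations

import itertools
from collections import Counter, deque
from dataclasses import dataclass

from .chemio import Atom, MolecularGraph

_BOND_SYMBOL = {1: "", 2: "=", 3: "#", "ar": ""}

#: bound on the tie-permutation product explored during canonicalization;
#: reached only for ring systems far more symmetric than drug-like molecules
_MAX_TIE_COMBINATIONS = 10_000


@dataclass(frozen=True)
class AtomSignature:
    """Canonical signature of one atom at one height."""

    root: int
    height: int
    text: str


def _atom_label(atom: Atom, closure: int | None = None) -> str:
    sym = atom.symbol
    if atom.aromatic:
        sym = sym[0].lower() + sym[1:]
    if atom.charge > 0:
        sym += "+" if atom.charge == 1 else f"+{atom.charge}"
    elif atom.charge < 0:
        sym += "-" if atom.charge == -1 else f"-{-atom.charge}"
    if closure is not None:
        sym += f",{closure}"
    return f"[{sym}]"


def bfs_distances(graph: MolecularGraph, root: int) -> dict[int, int]:
    """Bond-count distance from ``root`` to every reachable atom."""
    adj = graph.neighbors()
    dist = {root: 0}
    queue = deque([root])
    while queue:
        v = queue.popleft()
        for u, _ in adj[v]:
            if u not in dist:
                dist[u] = dist[v] + 1
                queue.append(u)
    return dist


def ball_atoms(graph: MolecularGraph, root: int, height: int) -> set[int]:
    """Atoms within ``height`` bonds of ``root`` (the signature's support)."""
    return {v for v, d in bfs_distances(graph, root).items() if d <= height}


class _Expansion:
    """Layered expansion of the radius-h ball around a root atom."""

    def __init__(self, graph: MolecularGraph, root: int, height: int):
        self.graph = graph
        self.root = root
        adj = graph.neighbors()
        dist = bfs_distances(graph, root)
        self.dist = {v: d for v, d in dist.items() if d <= height}
        # children: next-layer neighbours; partners: same-layer ring bonds
        self.children: dict[int, list[tuple[int, int | str]]] = {}
        self.partners: dict[int, list[tuple[int, int | str]]] = {}
        for v, d in self.dist.items():
            self.children[v] = [
                (u, o) for u, o in adj[v] if self.dist.get(u) == d + 1
            ]
            self.partners[v] = [
                (u, o) for u, o in adj[v] if self.dist.get(u) == d
            ]
        self._count_occurrences()
        self._key_cache: dict[int, str] = {}
        self._involved_cache: dict[int, bool] = {}

    def _count_occurrences(self) -> None:
        occ = {v: 0 for v in self.dist}
        occ[self.root] = 1
        order = sorted(self.dist, key=self.dist.get)
        for v in order:
            for u, _ in self.children[v]:
                occ[u] += occ[v]
        total = dict(occ)
        for v in order:
            for u, _ in self.partners[v]:
                total[u] += occ[v]
        self.needs_closure = {v: total[v] > 1 for v in self.dist}

    # -- order-invariant subtree keys (closure digits blanked) -------------

    def subtree_key(self, v: int) -> str:
        key = self._key_cache.get(v)
        if key is None:
            label = _atom_label(self.graph.atoms[v])
            if self.needs_closure[v]:
                label += "!"
            entries = sorted(
                [_BOND_SYMBOL[o] + self.subtree_key(u) for u, o in self.children[v]]
                + [
                    _BOND_SYMBOL[o] + _atom_label(self.graph.atoms[u]) + "!"
                    for u, o in self.partners[v]
                ]
            )
            key = label + ("(" + "".join(entries) + ")" if entries else "")
            self._key_cache[v] = key
        return key

    def _subtree_involves_closure(self, v: int) -> bool:
        cached = self._involved_cache.get(v)
        if cached is None:
            cached = (
                self.needs_closure[v]
                or bool(self.partners[v])
                or any(self._subtree_involves_closure(u) for u, _ in self.children[v])
            )
            self._involved_cache[v] = cached
        return cached

    # -- canonical rendering ----------------------------------------------

    def render(self) -> str:
        # Per atom, sort child entries by their invariant keys and locate
        # groups of tied entries whose order can still affect the string
        # (possible only when closures occur inside the tied subtrees).
        base_order: dict[int, list[tuple[str, str, int, int | str]]] = {}
        tie_groups: list[tuple[int, int, int]] = []  # (atom, start, stop)
        for v in self.dist:
            entries = [
                (_BOND_SYMBOL[o] + self.subtree_key(u), "child", u, o)
                for u, o in self.children[v]
            ] + [
                (_BOND_SYMBOL[o] + _atom_label(self.graph.atoms[u]) + "!", "partner", u, o)
                for u, o in self.partners[v]
            ]
            entries.sort(key=lambda e: e[0])
            base_order[v] = entries
            start = 0
            while start < len(entries):
                stop = start
                while stop < len(entries) and entries[stop][0] == entries[start][0]:
                    stop += 1
                if stop - start > 1 and any(
                    e[1] == "partner" or self._subtree_involves_closure(e[2])
                    for e in entries[start:stop]
                ):
                    tie_groups.append((v, start, stop))
                start = stop

        if not tie_groups:
            return self._render_once(base_order)

        n_combos = 1
        for _, start, stop in tie_groups:
            for k in range(2, stop - start + 1):
                n_combos *= k
        choices = [
            itertools.permutations(range(stop - start))
            for _, start, stop in tie_groups
        ]
        best: str | None = None
        for combo in itertools.islice(itertools.product(*choices), _MAX_TIE_COMBINATIONS):
            order = {v: list(entries) for v, entries in base_order.items()}
            for (v, start, stop), perm in zip(tie_groups, combo):
                group = base_order[v][start:stop]
                order[v][start:stop] = [group[k] for k in perm]
            text = self._render_once(order)
            if best is None or text < best:
                best = text
        return best  # type: ignore[return-value]

    def _render_once(self, order: dict[int, list]) -> str:
        closure_ids: dict[int, int] = {}

        def label_of(v: int) -> str:
            closure = None
            if self.needs_closure[v]:
                if v not in closure_ids:
                    closure_ids[v] = len(closure_ids) + 1
                closure = closure_ids[v]
            return _atom_label(self.graph.atoms[v], closure)

        def emit(v: int) -> str:
            text = label_of(v)
            parts = []
            for _, kind, u, o in order[v]:
                if kind == "child":
                    parts.append(_BOND_SYMBOL[o] + emit(u))
                else:
                    parts.append(_BOND_SYMBOL[o] + label_of(u))
            if parts:
                text += "(" + "".join(parts) + ")"
            return text

        return emit(self.root)


def atom_signature(graph: MolecularGraph, root: int, height: int) -> AtomSignature:
    """Canonical signature of ``root`` at the given height.

    Deterministic and independent of the atom input order; for heights at
    or beyond the root's eccentricity the text stops changing.
    """
    if not (0 <= root < graph.n_atoms):
        raise IndexError(f"root {root} out of range for {graph.n_atoms} atoms")
    if height < 0:
        raise ValueError("height must be non-negative")
    return AtomSignature(root, height, _Expansion(graph, root, height).render())


def molecule_signatures(graph: MolecularGraph, heights) -> Counter:
    """Multiset of atom-signature texts over all atoms and heights.

    One candidate signature is produced per (atom, height) pair; identical
    texts arising for the *same* root at different heights (a small
    molecule saturating below the largest height) are counted once, while
    identical texts rooted at different atoms accumulate.
    """
    heights = sorted(set(int(h) for h in heights))
    if not heights:
        raise ValueError("heights must be non-empty")
    counts: Counter = Counter()
    for root in range(graph.n_atoms):
        texts = {atom_signature(graph, root, h).text for h in heights}
        counts.update(texts)
    return counts
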