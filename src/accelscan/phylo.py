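"""Phylogenetic trees, reversible nucleotide models, pruning likelihoods,
branch scaling and alignment simulation.

This module is the numerical core of the package.  It provides

* a light-weight rooted tree (:class:`PhyloTree`) with a strict newick
  parser/writer,
* a time-reversible nucleotide substitution model
  (:class:`SubstitutionModel`) with spectral matrix exponentials,
* Felsenstein pruning likelihoods under a two-parameter branch scaling:
  a global scale ``s`` applied to every branch and a subtree scale
  ``rho`` applied multiplicatively to the branches of a designated
  clade, and
* forward simulation of alignment columns under the same scaled process.

The heavy per-column recursion lives in :class:`LikelihoodEngine`, which
compiles a tree into flat arrays and, when numba is importable, runs a
jitted kernel.  The functional wrappers (:func:`column_log_likelihood`,
:func:`element_log_likelihood`, :func:`simulate_element`) build an engine
on the fly and are convenient for small inputs and tests.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from scipy.linalg import expm as _dense_expm

__all__ = [
    "BASES",
    "MISSING_CHARS",
    "NewickError",
    "Node",
    "PhyloTree",
    "parse_newick",
    "SubstitutionModel",
    "NeutralModel",
    "ScaleConfig",
    "transition_matrix",
    "column_log_likelihood",
    "element_log_likelihood",
    "simulate_element",
    "prune_to_species",
    "LikelihoodEngine",
]

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
BASE_INDEX.update({b.lower(): i for i, b in enumerate(BASES)})
#: characters treated as missing data (all-ones partial likelihood)
MISSING_CHARS = frozenset("-Nn")

SCALE_MIN, SCALE_MAX = 1e-3, 100.0
RHO_MIN, RHO_MAX = 1.0, 100.0


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

class NewickError(ValueError):
    """Malformed newick input; carries the 0-based offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class Node:
    """A node of a rooted tree; ``length`` is the branch to the parent."""

    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.length = float(length)
        self.children: list[Node] = []
        self.parent: Node | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    def copy(self) -> "Node":
        new = Node(self.name, self.length)
        for c in self.children:
            new.add_child(c.copy())
        return new


class PhyloTree:
    """Rooted phylogenetic tree with branch lengths in substitutions/site."""

    def __init__(self, root: Node):
        self.root = root

    # -- traversal ---------------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        """Yield nodes children-first (root last)."""
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for c in reversed(node.children):
                stack.append(c)

    @property
    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def total_length(self) -> float:
        return sum(n.length for n in self.postorder() if n is not self.root)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        names = []
        for node in self.postorder():
            if node.length < 0:
                raise ValueError(
                    f"negative branch length {node.length} at {node.name!r}")
            if node.is_leaf:
                if not node.name:
                    raise ValueError("leaf without a name")
                names.append(node.name)
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate leaf names: {sorted(dupes)}")

    # -- serialization -----------------------------------------------------
    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                body = node.name or ""
            else:
                body = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.name:
                    body += node.name
            if node is self.root:
                return body
            return f"{body}:{node.length:.17g}"

        return fmt(self.root) + ";"

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.copy())

    # -- clade machinery ---------------------------------------------------
    def mrca(self, leaf_names: Iterable[str]) -> Node:
        wanted = set(leaf_names)
        unknown = wanted - set(self.leaf_names)
        if unknown:
            raise ValueError(f"unknown leaf names: {sorted(unknown)}")
        if not wanted:
            raise ValueError("empty leaf set")
        # path from each wanted leaf to the root; intersect
        by_name = {n.name: n for n in self.leaves}
        paths = []
        for name in wanted:
            path = []
            node: Node | None = by_name[name]
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(path)
        common = set(paths[0])
        for p in paths[1:]:
            common &= set(p)
        # deepest common ancestor = first element of any path that is common
        for node in paths[0]:
            if node in common:
                return node
        raise AssertionError("disconnected tree")  # pragma: no cover

    def clade_nodes(self, leaf_names: Iterable[str]) -> list[Node]:
        """Nodes whose parent edges form the subtree identified by a leaf set.

        The leaf set must be exactly the leaves below its MRCA (a clade) and
        must be a proper subset of all leaves.  The returned list contains
        every node of the clade including its root, whose edge to the rest of
        the tree is part of the subtree.
        """
        wanted = frozenset(leaf_names)
        if wanted == frozenset(self.leaf_names):
            raise ValueError("subtree spans every leaf; scales unidentifiable")
        anc = self.mrca(wanted)
        clade = []
        stack = [anc]
        while stack:
            node = stack.pop()
            clade.append(node)
            stack.extend(node.children)
        below = {n.name for n in clade if n.is_leaf}
        if below != set(wanted):
            raise ValueError(
                f"leaf set {sorted(wanted)} is not a clade "
                f"(its MRCA spans {sorted(below)})")
        return clade

    def prune_to(self, names: Iterable[str]) -> "PhyloTree":
        """Restrict to a leaf subset, suppressing unary nodes (lengths sum)."""
        keep = set(names)
        if not keep:
            raise ValueError("cannot prune to an empty leaf set")
        unknown = keep - set(self.leaf_names)
        if unknown:
            raise ValueError(f"unknown leaf names: {sorted(unknown)}")

        def rec(node: Node) -> Node | None:
            if node.is_leaf:
                if node.name in keep:
                    return Node(node.name, node.length)
                return None
            kids = [k for k in (rec(c) for c in node.children) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                kids[0].length += node.length
                return kids[0]
            new = Node(node.name, node.length)
            for k in kids:
                new.add_child(k)
            return new

        new_root = rec(self.root)
        assert new_root is not None
        new_root.length = 0.0
        tree = PhyloTree(new_root)
        tree.validate()
        return tree


_NEWICK_SPECIALS = "():,;"


def parse_newick(text: str) -> PhyloTree:
    """Parse a newick string into a :class:`PhyloTree`.

    Raises :class:`NewickError` with the offending position on syntax
    errors, and ``ValueError`` on duplicate leaf names.
    """
    s = text
    n = len(s)
    i = 0

    def skip_ws() -> None:
        nonlocal i
        while i < n and s[i].isspace():
            i += 1

    def read_token() -> str:
        nonlocal i
        j = i
        while i < n and s[i] not in _NEWICK_SPECIALS and not s[i].isspace():
            i += 1
        return s[j:i]

    def parse_clade() -> Node:
        nonlocal i
        skip_ws()
        node = Node()
        if i < n and s[i] == "(":
            i += 1
            while True:
                node.add_child(parse_clade())
                skip_ws()
                if i >= n:
                    raise NewickError("unexpected end of input", i)
                if s[i] == ",":
                    i += 1
                    continue
                if s[i] == ")":
                    i += 1
                    break
                raise NewickError(f"expected ',' or ')', found {s[i]!r}", i)
        skip_ws()
        node.name = read_token() or None
        skip_ws()
        if i < n and s[i] == ":":
            i += 1
            skip_ws()
            j = i
            tok = read_token()
            try:
                node.length = float(tok)
            except ValueError:
                raise NewickError(f"invalid branch length {tok!r}", j) from None
        return node

    root = parse_clade()
    skip_ws()
    if i >= n or s[i] != ";":
        raise NewickError("expected ';'", i)
    tree = PhyloTree(root)
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# Substitution models
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class SubstitutionModel:
    """Time-reversible nucleotide model over the fixed alphabet ACGT.

    Attributes
    ----------
    freqs : ndarray, shape (4,)
        Equilibrium frequencies ``pi`` (nonnegative, sum to 1).
    rate_matrix : ndarray, shape (4, 4)
        Instantaneous rates ``Q``; rows sum to 0, off-diagonals >= 0,
        normalized so the expected rate ``-sum_i pi_i Q_ii`` is 1.
    """

    freqs: np.ndarray
    rate_matrix: np.ndarray

    def __post_init__(self):
        pi = np.asarray(self.freqs, dtype=float)
        q = np.asarray(self.rate_matrix, dtype=float)
        if pi.shape != (4,) or q.shape != (4, 4):
            raise ValueError("model must be over the 4-letter alphabet ACGT")
        if np.any(pi < 0):
            raise ValueError("negative equilibrium frequency")
        if abs(pi.sum() - 1.0) > 1e-6:
            raise ValueError(f"frequencies sum to {pi.sum()!r}, not 1")
        pi = pi / pi.sum()
        object.__setattr__(self, "freqs", pi)
        object.__setattr__(self, "rate_matrix", q)

    # -- constructors ------------------------------------------------------
    @classmethod
    def general_reversible(
        cls,
        freqs: Sequence[float],
        exchangeabilities: Sequence[float],
    ) -> "SubstitutionModel":
        """Build a normalized REV/GTR model.

        ``exchangeabilities`` are the 6 symmetric rates in upper-triangle
        order (AC, AG, AT, CG, CT, GT).
        """
        pi = np.asarray(freqs, dtype=float)
        r = np.asarray(exchangeabilities, dtype=float)
        if r.shape != (6,) or np.any(r < 0):
            raise ValueError("need 6 nonnegative exchangeabilities")
        ex = np.zeros((4, 4))
        ex[np.triu_indices(4, k=1)] = r
        ex = ex + ex.T
        q = ex * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        rate = -(pi * np.diag(q)).sum()
        if rate <= 0:
            raise ValueError("degenerate rate matrix")
        return cls(pi, q / rate)

    @classmethod
    def jukes_cantor(cls) -> "SubstitutionModel":
        return cls.general_reversible(np.full(4, 0.25), np.ones(6))

    # -- properties --------------------------------------------------------
    def expected_rate(self) -> float:
        return -float((self.freqs * np.diag(self.rate_matrix)).sum())

    def is_reversible(self, tol: float = 1e-8) -> bool:
        flux = self.freqs[:, None] * self.rate_matrix
        return bool(np.allclose(flux, flux.T, atol=tol))

    def validate(self, tol: float = 1e-8) -> None:
        q = self.rate_matrix
        off = q[~np.eye(4, dtype=bool)]
        if np.any(off < -tol):
            raise ValueError("negative off-diagonal rate")
        if np.any(np.abs(q.sum(axis=1)) > 1e-8):
            raise ValueError("rate-matrix rows do not sum to 0")
        if not self.is_reversible(tol=1e-6):
            raise ValueError("detailed balance violated (model is not REV)")
        if abs(self.expected_rate() - 1.0) > 1e-6:
            raise ValueError("rate matrix not normalized to 1 subst/site")

    def spectral(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Eigendecomposition ``P(t) = A @ diag(exp(w t)) @ B``.

        Uses the symmetrization ``D^{1/2} Q D^{-1/2}`` valid for reversible
        models; guaranteed-real eigenvalues and orthogonal eigenvectors.
        """
        pi = np.where(self.freqs > 0, self.freqs, 1e-300)
        d = np.sqrt(pi)
        sym = self.rate_matrix * (d[:, None] / d[None, :])
        sym = (sym + sym.T) / 2.0
        w, u = np.linalg.eigh(sym)
        a = u / d[:, None]
        b = (u * d[:, None]).T
        return w, np.ascontiguousarray(a), np.ascontiguousarray(b)


def transition_matrix(subst: SubstitutionModel, t: float) -> np.ndarray:
    """Return ``P(t) = exp(Q t)``; rows sum to 1, entries >= 0.

    Reversible models use the spectral route; anything else falls back to
    dense scaling-and-squaring.
    """
    if t < 0:
        raise ValueError(f"branch length must be >= 0, got {t}")
    if subst.is_reversible(tol=1e-6):
        w, a, b = subst.spectral()
        p = (a * np.exp(w * t)) @ b
    else:  # pragma: no cover - REV is the only supported family
        p = _dense_expm(subst.rate_matrix * t)
    np.clip(p, 0.0, None, out=p)
    p /= p.sum(axis=1, keepdims=True)
    return p


# ---------------------------------------------------------------------------
# Neutral model and branch scaling
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class NeutralModel:
    """The null evolutionary process: a tree plus a reversible model."""

    tree: PhyloTree
    subst: SubstitutionModel

    def validate(self) -> None:
        self.tree.validate()
        self.subst.validate()

    @property
    def leaf_names(self) -> list[str]:
        return self.tree.leaf_names


@dataclasses.dataclass(frozen=True)
class ScaleConfig:
    """Branch scaling: global scale ``s`` and subtree scale ``rho``.

    ``rho`` multiplies branch lengths of the clade identified by
    ``subtree`` (a leaf-name set) on top of ``s``.
    """

    s: float = 1.0
    rho: float = 1.0
    subtree: frozenset[str] | None = None

    def __post_init__(self):
        if not (SCALE_MIN <= self.s <= SCALE_MAX):
            raise ValueError(f"global scale {self.s} outside "
                             f"[{SCALE_MIN}, {SCALE_MAX}]")
        if not (RHO_MIN <= self.rho <= RHO_MAX):
            raise ValueError(f"subtree scale {self.rho} outside "
                             f"[{RHO_MIN}, {RHO_MAX}]")
        if self.subtree is not None:
            object.__setattr__(self, "subtree", frozenset(self.subtree))
        if self.rho != 1.0 and not self.subtree:
            raise ValueError("subtree scale requires a subtree leaf set")


# ---------------------------------------------------------------------------
# Pruning kernel
# ---------------------------------------------------------------------------

def _pruning_columns_numpy(parent, leaf_row, tvec, w, a, b, pi, seqs):
    n_nodes = parent.shape[0]
    n_cols = seqs.shape[1]
    acc = np.ones((n_nodes, n_cols, 4))
    logscale = np.zeros(n_cols)
    bad = np.zeros(n_cols, dtype=bool)
    pmats = np.einsum("ik,ek,kj->eij", a, np.exp(np.outer(tvec, w)), b)
    np.clip(pmats, 0.0, None, out=pmats)
    pmats[tvec == 0.0] = np.eye(4)  # exact identity, not roundoff residue
    for i in range(n_nodes - 1):
        p = pmats[i]
        if leaf_row[i] >= 0:
            bases = seqs[leaf_row[i]]
            msg = np.ones((n_cols, 4))
            obs = bases >= 0
            msg[obs] = p[:, bases[obs]].T
        else:
            msg = acc[i] @ p.T
        m = msg.max(axis=1)
        ok = m > 0
        bad |= ~ok
        safe = np.where(ok, m, 1.0)
        with np.errstate(divide="ignore"):
            logscale += np.where(ok, np.log(safe), 0.0)
        acc[parent[i]] *= msg / safe[:, None]
    lik = acc[n_nodes - 1] @ pi
    out = np.full(n_cols, -np.inf)
    good = (lik > 0) & ~bad
    out[good] = np.log(lik[good]) + logscale[good]
    return out


try:  # pragma: no cover - exercised indirectly
    import numba as _numba

    @_numba.njit(cache=True, fastmath=False)
    def _pruning_columns_numba(parent, leaf_row, tvec, w, a, b, pi, seqs):
        n_nodes = parent.shape[0]
        n_cols = seqs.shape[1]
        acc = np.ones((n_nodes, n_cols, 4))
        logscale = np.zeros(n_cols)
        p = np.empty((4, 4))
        ew = np.empty(4)
        msg = np.empty(4)
        for i in range(n_nodes - 1):
            if tvec[i] == 0.0:  # exact identity, not roundoff residue
                for x in range(4):
                    for y in range(4):
                        p[x, y] = 1.0 if x == y else 0.0
            else:
                for k in range(4):
                    ew[k] = math.exp(w[k] * tvec[i])
                for x in range(4):
                    for y in range(4):
                        v = 0.0
                        for k in range(4):
                            v += a[x, k] * ew[k] * b[k, y]
                        p[x, y] = v if v > 0.0 else 0.0
            par = parent[i]
            lr = leaf_row[i]
            if lr >= 0:
                for c in range(n_cols):
                    base = seqs[lr, c]
                    if base >= 0:
                        for x in range(4):
                            acc[par, c, x] *= p[x, base]
            else:
                for c in range(n_cols):
                    m = 0.0
                    for x in range(4):
                        v = 0.0
                        for y in range(4):
                            v += acc[i, c, y] * p[x, y]
                        msg[x] = v
                        if v > m:
                            m = v
                    if m <= 0.0:
                        logscale[c] = -np.inf
                    elif logscale[c] != -np.inf:
                        logscale[c] += math.log(m)
                        for x in range(4):
                            acc[par, c, x] *= msg[x] / m
        out = np.empty(n_cols)
        for c in range(n_cols):
            v = 0.0
            for x in range(4):
                v += pi[x] * acc[n_nodes - 1, c, x]
            if v <= 0.0 or logscale[c] == -np.inf:
                out[c] = -np.inf
            else:
                out[c] = math.log(v) + logscale[c]
        return out

    _KERNEL = _pruning_columns_numba
except Exception:  # pragma: no cover
    _KERNEL = _pruning_columns_numpy


class LikelihoodEngine:
    """Compiled pruning machinery for one neutral model.

    Flattens the tree into postorder arrays and caches the spectral
    decomposition of the rate matrix; ``loglik`` and ``simulate`` then
    work on integer-encoded alignments (rows ordered as ``leaf_names``,
    ``-1`` marking missing data).
    """

    def __init__(self, model: NeutralModel):
        self.model = model
        nodes = list(model.tree.postorder())
        index = {id(n): i for i, n in enumerate(nodes)}
        self._nodes = nodes
        self.n_nodes = len(nodes)
        self.parent = np.array(
            [index[id(n.parent)] if n.parent is not None else -1
             for n in nodes], dtype=np.int64)
        self.blen = np.array([n.length for n in nodes])
        self.blen[-1] = 0.0  # root edge never contributes
        self.leaf_names = [n.name for n in nodes if n.is_leaf]
        row_of = {name: r for r, name in enumerate(self.leaf_names)}
        self.leaf_row = np.array(
            [row_of[n.name] if n.is_leaf else -1 for n in nodes],
            dtype=np.int64)
        self.n_leaves = len(self.leaf_names)
        self.pi = model.subst.freqs
        self.w, self.a, self.b = model.subst.spectral()
        self._mask_cache: dict[frozenset, np.ndarray | None] = {}

    # -- encoding ----------------------------------------------------------
    def encode(self, seqs: Mapping[str, str],
               length: int | None = None) -> np.ndarray:
        """Integer-encode an alignment dict; absent species become missing."""
        lengths = {len(v) for v in seqs.values()}
        if length is None:
            if len(lengths) > 1:
                raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
            length = lengths.pop() if lengths else 0
        elif lengths and lengths != {length}:
            raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
        unknown = set(seqs) - set(self.leaf_names)
        if unknown:
            raise ValueError(f"unknown leaf names: {sorted(unknown)}")
        out = np.full((self.n_leaves, length), -1, dtype=np.int8)
        for r, name in enumerate(self.leaf_names):
            seq = seqs.get(name)
            if seq is None:
                continue
            for c, ch in enumerate(seq):
                if ch in MISSING_CHARS:
                    continue
                try:
                    out[r, c] = BASE_INDEX[ch]
                except KeyError:
                    raise ValueError(
                        f"invalid symbol {ch!r} in sequence for {name!r}"
                    ) from None
        return out

    def decode(self, seqs: np.ndarray) -> dict[str, str]:
        table = np.array(list(BASES + "-"))
        return {name: "".join(table[np.where(row >= 0, row, 4)])
                for name, row in zip(self.leaf_names, seqs)}

    # -- scaling -----------------------------------------------------------
    def subtree_mask(self, leaf_names: Iterable[str]) -> np.ndarray:
        """Boolean per-node mask of the edges scaled by ``rho``."""
        key = frozenset(leaf_names)
        if key not in self._mask_cache:
            clade = self.model.tree.clade_nodes(key)
            ids = {id(n) for n in clade}
            self._mask_cache[key] = np.array(
                [id(n) in ids for n in self._nodes])
        return self._mask_cache[key]

    def _effective_lengths(self, s: float, rho: float,
                           mask: np.ndarray | None) -> np.ndarray:
        t = self.blen * s
        if mask is not None and rho != 1.0:
            t = t.copy()
            t[mask] *= rho
        return t

    # -- likelihood --------------------------------------------------------
    def loglik_columns(self, seqs: np.ndarray, s: float = 1.0,
                       rho: float = 1.0,
                       mask: np.ndarray | None = None) -> np.ndarray:
        if self.n_nodes == 1:  # single-leaf tree: no branches at all
            out = np.full(seqs.shape[1], 0.0)
            bases = seqs[0]
            obs = bases >= 0
            with np.errstate(divide="ignore"):
                out[obs] = np.log(self.pi[bases[obs]])
            return out
        tvec = self._effective_lengths(s, rho, mask)
        return _KERNEL(self.parent, self.leaf_row, tvec,
                       self.w, self.a, self.b, self.pi, seqs)

    def loglik(self, seqs: np.ndarray, s: float = 1.0, rho: float = 1.0,
               mask: np.ndarray | None = None) -> float:
        return float(self.loglik_columns(seqs, s, rho, mask).sum())

    # -- simulation --------------------------------------------------------
    def simulate(self, length: int, rng: np.random.Generator,
                 s: float = 1.0, rho: float = 1.0,
                 mask: np.ndarray | None = None) -> np.ndarray:
        """Draw an alignment of ``length`` iid columns under the scaled model."""
        if length < 1:
            raise ValueError("length must be >= 1")
        tvec = self._effective_lengths(s, rho, mask)
        states = np.empty((self.n_nodes, length), dtype=np.int64)
        cum_pi = np.cumsum(self.pi)
        states[-1] = np.searchsorted(cum_pi, rng.random(length) * cum_pi[-1],
                                     side="right")
        pmats = np.einsum("ik,ek,kj->eij", self.a,
                          np.exp(np.outer(tvec, self.w)), self.b)
        np.clip(pmats, 0.0, None, out=pmats)
        pmats[tvec == 0.0] = np.eye(4)
        pmats /= pmats.sum(axis=2, keepdims=True)
        cum = np.cumsum(pmats, axis=2)
        for i in range(self.n_nodes - 2, -1, -1):
            rows = cum[i][states[self.parent[i]]]
            u = rng.random(length)
            states[i] = (rows < u[:, None]).sum(axis=1)
        np.clip(states, 0, 3, out=states)
        out = np.empty((self.n_leaves, length), dtype=np.int8)
        for i in range(self.n_nodes):
            r = self.leaf_row[i]
            if r >= 0:
                out[r] = states[i]
        return out


# ---------------------------------------------------------------------------
# Functional wrappers (spec surface)
# ---------------------------------------------------------------------------

def _engine_and_mask(model: NeutralModel,
                     scales: ScaleConfig) -> tuple[LikelihoodEngine,
                                                   np.ndarray | None]:
    engine = LikelihoodEngine(model)
    mask = engine.subtree_mask(scales.subtree) if scales.subtree else None
    return engine, mask


def column_log_likelihood(model: NeutralModel, scales: ScaleConfig,
                          column: Mapping[str, str]) -> float:
    """Log probability of one alignment column under the scaled model."""
    engine, mask = _engine_and_mask(model, scales)
    seqs = engine.encode({k: v for k, v in column.items()}, length=1)
    return float(engine.loglik_columns(seqs, scales.s, scales.rho, mask)[0])


def element_log_likelihood(model: NeutralModel, scales: ScaleConfig,
                           aln: Mapping[str, str]) -> float:
    """Log likelihood of an aligned element (iid columns)."""
    engine, mask = _engine_and_mask(model, scales)
    seqs = engine.encode(aln)
    if seqs.shape[1] == 0:
        return 0.0
    return engine.loglik(seqs, scales.s, scales.rho, mask)


def simulate_element(model: NeutralModel, scales: ScaleConfig, length: int,
                     seed: int | np.random.Generator) -> dict[str, str]:
    """Simulate per-leaf sequences of ``length`` sites; deterministic by seed."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    engine, mask = _engine_and_mask(model, scales)
    return engine.decode(engine.simulate(length, rng, scales.s,
                                         scales.rho, mask))


def prune_to_species(model: NeutralModel,
                     present: Iterable[str]) -> NeutralModel:
    """Restrict the model to the given leaves (substitution model unchanged)."""
    present = set(present)
    kept = present & set(model.leaf_names)
    if not kept:
        raise ValueError("no overlap between requested species and tree leaves")
    return NeutralModel(model.tree.prune_to(kept), model.subst)
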