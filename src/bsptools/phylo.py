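"""Distance-based phylogenetics: pairwise-deletion distances, neighbor
joining, bootstrap supports and Newick serialization.

Distances are computed per sequence pair over the columns where neither
sequence is gapped (*pairwise deletion*).  Three models are offered for
converting the observed proportion of differing sites ``p`` into an
evolutionary distance (expected substitutions per site):

``p``        the raw proportion itself;
``poisson``  -ln(1 - p), correcting for multiple hits at a site under a
             one-parameter Poisson model;
``dayhoff``  the PAM time ``t`` at which the Dayhoff (1978) empirical
             amino-acid replacement model predicts expected identity
             ``1 - p`` — found by a monotone one-dimensional root search
             on the model's expected-identity curve.

Trees are built with the Saitou-Nei neighbor-joining agglomeration and
supports estimated by column-resampling bootstrap.  The tree container is
a scikit-bio ``TreeNode``; the NJ agglomeration itself is implemented
here.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.optimize import brentq
from skbio import TreeNode

GAP = "-"


class PhyloError(ValueError):
    pass


@dataclass
class Alignment:
    """Equal-length gapped protein rows keyed by sequence ids."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise PhyloError("ids and rows differ in count")
        if len({len(r) for r in self.rows}) > 1:
            raise PhyloError("alignment rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise PhyloError("duplicate sequence ids")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        cols = rng.integers(0, self.n_columns, size=self.n_columns)
        rows = ["".join(r[c] for c in cols) for r in self.rows]
        return Alignment(list(self.ids), rows)


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray  # substitutions/site; nan = undefined, inf = saturated
    n_sites: np.ndarray

    @property
    def well_defined(self) -> bool:
        return bool(np.all(np.isfinite(self.d)))


@dataclass
class PhyloTree:
    """An unrooted NJ tree (stored with a trifurcating root node)."""

    root: TreeNode
    supports: dict[frozenset, float] = field(default_factory=dict)
    clamped: bool = False

    @property
    def leaf_names(self) -> list[str]:
        return [t.name for t in self.root.tips()]


# --- Dayhoff model --------------------------------------------------------


class _DayhoffModel:
    """Expected-identity curve of the Dayhoff (1978) replacement model.

    Built from the standard exchangeabilities/frequencies; the rate matrix
    is scaled so that time is measured in expected substitutions per site.
    The identity curve I(t) = sum_i pi_i P_ii(t) is evaluated through a
    spectral decomposition of the reversible generator.
    """

    def __init__(self) -> None:
        raw = json.loads(
            resources.files("bsptools.data").joinpath("dayhoff.json").read_text()
        )
        pi = np.asarray(raw["frequencies"], dtype=float)
        pi /= pi.sum()
        n = len(pi)
        S = np.zeros((n, n))
        it = iter(raw["exchangeabilities_lower_triangle"])
        for i in range(n):
            for j in range(i + 1, n):
                S[i, j] = S[j, i] = next(it)
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float(np.dot(pi, np.diag(Q)))
        Q /= mu
        self.pi = pi
        self.Q = Q
        # symmetrize: B = D^1/2 Q D^-1/2 is symmetric for reversible Q
        sq = np.sqrt(pi)
        B = (Q * sq[:, None]) / sq[None, :]
        lam, V = np.linalg.eigh((B + B.T) / 2.0)
        self._lam = lam
        self._coef = (pi[:, None] * V**2).sum(axis=0)
        self.identity_floor = float(np.sum(pi**2))

    def expected_identity(self, t: float) -> float:
        return float(np.sum(self._coef * np.exp(self._lam * t)))

    def distance(self, p: float, t_max: float = 50.0) -> float:
        """Invert the identity curve: the t with I(t) = 1 - p."""
        if p <= 0:
            return 0.0
        target = 1.0 - p
        if target <= self.expected_identity(t_max):
            return math.inf  # saturated
        return brentq(lambda t: self.expected_identity(t) - target, 0.0, t_max)


_dayhoff_model: _DayhoffModel | None = None


def dayhoff_model() -> _DayhoffModel:
    global _dayhoff_model
    if _dayhoff_model is None:
        _dayhoff_model = _DayhoffModel()
    return _dayhoff_model


# --- pairwise distances ---------------------------------------------------


def pairwise_distance(a: str, b: str, model: str = "dayhoff") -> tuple[float, int]:
    """Distance between two gapped rows under pairwise deletion.

    Returns ``(distance, n_sites)``.  ``distance`` is ``nan`` when no
    comparable columns remain and ``inf`` when the observed difference is
    beyond the model's saturation bound.
    """
    if len(a) != len(b):
        raise PhyloError("rows differ in length")
    n_sites = diffs = 0
    for x, y in zip(a, b):
        if x == GAP or y == GAP:
            continue
        n_sites += 1
        diffs += x != y
    if n_sites == 0:
        return math.nan, 0
    p = diffs / n_sites
    if model == "p":
        return p, n_sites
    if model == "poisson":
        return (math.inf, n_sites) if p >= 1.0 else (-math.log(1.0 - p), n_sites)
    if model == "dayhoff":
        return dayhoff_model().distance(p), n_sites
    raise PhyloError(f"unknown distance model {model!r}")


def distance_matrix(aln: Alignment, model: str = "dayhoff") -> DistanceMatrix:
    n = len(aln.ids)
    d = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    for i in range(n):
        sites[i, i] = sum(c != GAP for c in aln.rows[i])
        for j in range(i + 1, n):
            dij, nij = pairwise_distance(aln.rows[i], aln.rows[j], model)
            d[i, j] = d[j, i] = dij
            sites[i, j] = sites[j, i] = nij
    return DistanceMatrix(list(aln.ids), d, sites)


# --- neighbor joining -----------------------------------------------------


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Repeatedly joins the pair minimizing Q(i,j) = (n-2) d(i,j) - r_i - r_j
    (ties broken by the smallest index pair), with the standard branch
    length and distance-update formulas.  Negative branch lengths are
    clamped to zero and flagged.  The final three lineages are joined at a
    trifurcating root, giving the unrooted topology.
    """
    n = len(dm.ids)
    if n < 3:
        raise PhyloError("neighbor joining needs at least 3 taxa")
    if not dm.well_defined:
        raise PhyloError("distance matrix contains undefined or saturated entries")

    d = dm.d.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=name) for name in dm.ids]
    clamped = False

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped = True
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        parent = TreeNode()
        nodes[i].length = clamp(li)
        nodes[j].length = clamp(lj)
        parent.extend([nodes[i], nodes[j]])
        keep = [k for k in range(m) if k not in (i, j)]
        new_d = np.zeros(m - 2)
        for idx, k in enumerate(keep):
            new_d[idx] = (d[i, k] + d[j, k] - d[i, j]) / 2.0
        d = np.vstack(
            [
                np.hstack([d[np.ix_(keep, keep)], new_d[:, None]]),
                np.hstack([new_d, [0.0]]),
            ]
        )
        nodes = [nodes[k] for k in keep] + [parent]

    # join the last three lineages at a trifurcation
    root = TreeNode()
    (a, b, c) = (0, 1, 2)
    la = (d[a, b] + d[a, c] - d[b, c]) / 2.0
    lb = (d[a, b] + d[b, c] - d[a, c]) / 2.0
    lc = (d[a, c] + d[b, c] - d[a, b]) / 2.0
    for node, length in zip(nodes, (la, lb, lc)):
        node.length = clamp(length)
        root.append(node)
    return PhyloTree(root=root, clamped=clamped)


def bipartitions(tree: PhyloTree | TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree.

    Each internal edge splits the leaves in two; the side not containing
    the alphabetically first leaf is the canonical representative.
    """
    root = tree.root if isinstance(tree, PhyloTree) else tree
    all_leaves = frozenset(t.name for t in root.tips())
    ref = min(all_leaves)
    out: set[frozenset] = set()
    for node in root.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            out.add(side)
    return out


def bootstrap(
    aln: Alignment,
    model: str = "dayhoff",
    replicates: int = 100,
    seed: int = 0,
) -> dict[frozenset, float]:
    """Column-resampling bootstrap supports for the full-data NJ tree.

    Resamples alignment columns with replacement ``replicates`` times,
    rebuilding distances and the NJ tree each round.  The support of each
    bipartition of the full-data tree is the percentage of successful
    replicates containing it.  Replicates whose resampled matrix has an
    undefined or saturated distance are dropped, tallied and warned about.
    Fully deterministic for a given seed.
    """
    if replicates < 1:
        raise PhyloError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    full = nj_tree(distance_matrix(aln, model))
    targets = bipartitions(full)
    counts = {bp: 0 for bp in targets}
    dropped = 0
    kept = 0
    for _ in range(replicates):
        rep = aln.resample_columns(rng)
        dmat = distance_matrix(rep, model)
        if not dmat.well_defined:
            dropped += 1
            continue
        kept += 1
        rep_bps = bipartitions(nj_tree(dmat))
        for bp in targets:
            if bp in rep_bps:
                counts[bp] += 1
    if dropped:
        warnings.warn(f"{dropped}/{replicates} bootstrap replicates dropped "
                      "(undefined or saturated distances)")
    if kept == 0:
        raise PhyloError("all bootstrap replicates dropped")
    return {bp: 100.0 * c / kept for bp, c in counts.items()}


def annotate_supports(tree: PhyloTree, supports: dict[frozenset, float]) -> PhyloTree:
    """Attach bootstrap percentages as internal node labels."""
    all_leaves = frozenset(t.name for t in tree.root.tips())
    ref = min(all_leaves)
    for node in tree.root.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        key = side if ref not in side else all_leaves - side
        if key in supports:
            node.name = _fmt_number(supports[key])
    tree.supports = dict(supports)
    return tree


# --- Newick ---------------------------------------------------------------

_NEWICK_META = set("()[]{}':;, \t\n")


def _quote(label: str) -> str:
    if label and not (_NEWICK_META & set(label)):
        return label
    return "'" + label.replace("'", "''") + "'"


def _fmt_number(x: float) -> str:
    return format(x, ".12g")


def _node_to_newick(node: TreeNode) -> str:
    if node.is_tip():
        s = _quote(node.name or "")
    else:
        s = "(" + ",".join(_node_to_newick(c) for c in node.children) + ")"
        if node.name:
            s += _quote(node.name)
    if node.length is not None:
        s += ":" + _fmt_number(node.length)
    return s


def write_newick(tree: PhyloTree, with_supports: bool = True) -> str:
    """Serialize to Newick; supports (if attached) ride as internal labels."""
    root = tree.root
    if with_supports and tree.supports:
        annotate_supports(tree, tree.supports)
    return _node_to_newick(root) + ";\n"


def read_newick(text: str) -> PhyloTree:
    """Parse Newick produced by :func:`write_newick` (or compatible)."""
    root = TreeNode.read([text.strip()], convert_underscores=False)
    tree = PhyloTree(root=root)
    # recover supports from numeric internal labels
    all_leaves = frozenset(t.name for t in root.tips())
    if not all_leaves:
        return tree
    ref = min(all_leaves)
    for node in root.non_tips(include_self=False):
        if node.name:
            try:
                value = float(node.name)
            except ValueError:
                continue
            side = frozenset(t.name for t in node.tips())
            if ref in side:
                side = all_leaves - side
            tree.supports[side] = value
    return tree
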