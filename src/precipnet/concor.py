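"""CONCOR blockmodelling: convergence of iterated correlations.

CONCOR partitions network nodes into groups of approximately structurally
equivalent nodes — nodes that relate to everyone else in the same way. Each
node's profile is its row of the co-occurrence matrix; correlating profiles,
then correlating the columns of the resulting correlation matrix, and so on,
empirically drives every off-diagonal entry to +1 or -1. The sign pattern
then defines a bipartition, applied recursively to yield a blockmodel.

The fitted partition is evaluated with intrablock and interblock densities
on the binarized network, judged against the whole-network density as the
significance cut-off.

Conventions for cases the iteration alone does not settle:

* self-entries are excluded pairwise when first correlating two profiles
  (standard one-mode practice);
* constant (zero-variance) profiles — isolates — are removed before
  iteration and collected in a trailing residual block;
* a pairwise-excluded vector that is still constant contributes r = 0;
* a correlation matrix with no sign structure (all off-diagonal entries
  equal, e.g. from a complete uniform-weight network) is degenerate: the
  group is returned unsplit with a warning, as is a perfectly homogeneous
  group (all correlations +1);
* if the iteration stalls without reaching ±1, the split uses the sign of
  the final matrix's first row, with a convergence warning.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np

from .network import CooccurrenceNetwork, binarize, network_density

__all__ = [
    "ConcorConfig",
    "SplitResult",
    "BlockModel",
    "concor_split",
    "concor_partition",
    "block_densities",
    "ConcorConvergenceWarning",
]


class ConcorConvergenceWarning(UserWarning):
    """Emitted when iterated correlations fail to reach a ±1 pattern."""


@dataclass(frozen=True)
class ConcorConfig:
    """Tunables of the recursive CONCOR fit.

    max_depth bounds the bipartition tree (depth d gives at most 2**d
    blocks, default 3 → up to 8); groups smaller than 2 * min_block_size are
    not split further. Profiles correlate the weighted co-occurrence counts
    by default (they carry the equivalence signal); densities are always
    computed on binarized edges.
    """

    max_depth: int = 3
    convergence_tol: float = 1e-8
    max_iterations: int = 200
    min_block_size: int = 2
    profile_source: str = "weighted"  # "weighted" | "binary"

    def __post_init__(self) -> None:
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.min_block_size < 1:
            raise ValueError("min_block_size must be >= 1")
        if self.profile_source not in ("weighted", "binary"):
            raise ValueError("profile_source must be 'weighted' or 'binary'")


@dataclass(frozen=True)
class SplitResult:
    group_a: tuple[int, ...]
    group_b: tuple[int, ...]  # empty when no split was possible
    converged: bool
    degenerate: bool
    n_iterations: int

    @property
    def did_split(self) -> bool:
        return len(self.group_a) > 0 and len(self.group_b) > 0


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Plain Pearson r; 0 when either vector has zero variance."""
    if len(x) < 2:
        return 0.0
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd @ xd) * (yd @ yd))
    if denom == 0:
        return 0.0
    return float(np.clip((xd @ yd) / denom, -1.0, 1.0))


def _initial_correlation(profiles: np.ndarray) -> np.ndarray:
    """Profile correlations with pairwise deletion of the two self-entries."""
    n = profiles.shape[0]
    c = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mask = np.ones(n, dtype=bool)
            mask[[i, j]] = False
            r = _pearson(profiles[i, mask], profiles[j, mask])
            c[i, j] = c[j, i] = r
    return c


def _iterate(c: np.ndarray) -> np.ndarray:
    """One CONCOR step: correlation matrix of the columns of c."""
    with np.errstate(invalid="ignore", divide="ignore"):
        nxt = np.corrcoef(c, rowvar=False)
    nxt = np.nan_to_num(nxt, nan=0.0)
    np.fill_diagonal(nxt, 1.0)
    return np.clip(nxt, -1.0, 1.0)


def concor_split(profiles: np.ndarray, config: ConcorConfig | None = None) -> SplitResult:
    """Bipartition node indices 0..n-1 by iterated profile correlations.

    ``profiles`` is the (square, symmetric) co-occurrence submatrix of the
    group. Nodes whose final correlation with node 0 is >= 0 form group A.
    """
    config = config or ConcorConfig()
    profiles = np.asarray(profiles, dtype=float)
    n = profiles.shape[0]
    if profiles.ndim != 2 or profiles.shape != (n, n) or n < 2:
        raise ValueError("profiles must be a square matrix over >= 2 nodes")

    c = _initial_correlation(profiles)
    converged = False
    n_iter = 0
    tol = config.convergence_tol
    offdiag = ~np.eye(n, dtype=bool)

    def _at_pm1(m: np.ndarray) -> bool:
        off = m[offdiag]
        return off.size == 0 or bool(np.all(np.abs(np.abs(off) - 1.0) < tol))

    for n_iter in range(1, config.max_iterations + 1):
        if _at_pm1(c):
            converged = True
            break
        off = c[offdiag]
        if off.max() - off.min() < tol:  # no sign structure to exploit
            return SplitResult(tuple(range(n)), (), False, True, n_iter)
        nxt = _iterate(c)
        stalled = np.allclose(nxt, c, atol=tol)
        c = nxt
        if stalled:  # fixed point: either at ±1 (checked below) or short of it
            converged = _at_pm1(c)
            break

    if not converged:
        _warnings.warn(
            f"CONCOR did not reach a ±1 pattern in {n_iter} iterations; "
            "splitting by the sign pattern of the final matrix",
            ConcorConvergenceWarning,
            stacklevel=2,
        )
    signs = c[0] >= 0
    group_a = tuple(int(i) for i in np.flatnonzero(signs))
    group_b = tuple(int(i) for i in np.flatnonzero(~signs))
    degenerate = len(group_b) == 0  # perfectly homogeneous: nothing to split
    return SplitResult(group_a, group_b, converged, degenerate, n_iter)


@dataclass(frozen=True)
class BlockModel:
    """A fitted recursive-CONCOR partition with its density evaluation.

    Blocks are numbered in left-to-right order of the bipartition tree;
    isolates (constant profiles) occupy a final residual block when present.
    ``density_matrix[i, j]`` holds the intrablock (i == j) or interblock
    density; singleton-block diagonals are NaN. ``significant`` flags
    densities strictly above the whole-network cut-off.
    """

    nodes: tuple[str, ...]
    partition: dict[str, int]
    blocks: tuple[tuple[str, ...], ...]
    density_matrix: np.ndarray
    cutoff: float
    significant: np.ndarray
    split_tree: dict
    converged: bool
    residual_block: int | None = None
    warnings: tuple[str, ...] = field(default=())

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


def concor_partition(
    net: CooccurrenceNetwork, config: ConcorConfig | None = None
) -> BlockModel:
    """Recursively bipartition the network into a blockmodel.

    Splits recurse on the submatrix of the original profile matrix, stopping
    at ``max_depth``, when a group has fewer than ``2 * min_block_size``
    members, or when a group is degenerate (homogeneous or structureless).
    The density matrix is computed on the binarized network and judged
    against the whole-network density.
    """
    config = config or ConcorConfig()
    if net.n_nodes < 2:
        raise ValueError("blockmodelling needs at least 2 nodes")
    profiles = (
        net.weight.astype(float)
        if config.profile_source == "weighted"
        else binarize(net).astype(float)
    )
    n = net.n_nodes
    offdiag = ~np.eye(n, dtype=bool)
    # isolates/constant profiles: Pearson undefined → residual block
    is_constant = np.array(
        [np.ptp(profiles[i][offdiag[i]]) == 0.0 if n > 1 else True for i in range(n)]
    )
    residual_idx = [int(i) for i in np.flatnonzero(is_constant)]
    active_idx = [int(i) for i in np.flatnonzero(~is_constant)]

    notes: list[str] = []
    all_converged = True
    leaf_groups: list[list[int]] = []

    def recurse(idx: list[int], depth: int) -> dict:
        nonlocal all_converged
        node_names = [net.nodes[i] for i in idx]
        if depth >= config.max_depth or len(idx) < 2 * config.min_block_size:
            leaf_groups.append(idx)
            return {"nodes": node_names}
        sub = profiles[np.ix_(idx, idx)]
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always", ConcorConvergenceWarning)
            result = concor_split(sub, config)
        for w in caught:
            all_converged = False
            notes.append(str(w.message))
        if result.degenerate or not result.did_split:
            if result.degenerate and not result.converged:
                notes.append(
                    f"group {node_names} has no correlation structure; left unsplit"
                )
            leaf_groups.append(idx)
            return {"nodes": node_names}
        left = [idx[i] for i in result.group_a]
        right = [idx[i] for i in result.group_b]
        return {
            "nodes": node_names,
            "children": [recurse(left, depth + 1), recurse(right, depth + 1)],
        }

    if len(active_idx) >= 2:
        tree = recurse(active_idx, 0)
    elif active_idx:
        leaf_groups.append(active_idx)
        tree = {"nodes": [net.nodes[active_idx[0]]]}
    else:
        tree = {"nodes": []}

    blocks: list[tuple[str, ...]] = [
        tuple(net.nodes[i] for i in grp) for grp in leaf_groups
    ]
    residual_block: int | None = None
    if residual_idx:
        residual_block = len(blocks)
        blocks.append(tuple(net.nodes[i] for i in residual_idx))
        notes.append(
            f"{len(residual_idx)} constant-profile node(s) placed in residual block "
            f"{residual_block}"
        )
    partition = {v: b for b, grp in enumerate(blocks) for v in grp}

    density = block_densities(net, partition)
    cutoff = network_density(net)
    with np.errstate(invalid="ignore"):
        significant = np.where(np.isnan(density), False, density > cutoff)
    return BlockModel(
        nodes=net.nodes,
        partition=partition,
        blocks=tuple(blocks),
        density_matrix=density,
        cutoff=cutoff,
        significant=significant,
        split_tree=tree,
        converged=all_converged,
        residual_block=residual_block,
        warnings=tuple(notes),
    )


def block_densities(
    net: CooccurrenceNetwork, partition: dict[str, int]
) -> np.ndarray:
    """Block-by-block density matrix on binarized edges.

    Intrablock density of block B = edges within B over C(|B|, 2) (NaN for
    singletons); interblock density of (B1, B2) = edges between them over
    |B1|·|B2|.
    """
    missing = set(net.nodes) - set(partition)
    if missing:
        raise ValueError(f"partition does not cover node(s) {sorted(missing)}")
    block_ids = sorted(set(partition[v] for v in net.nodes))
    pos = {b: i for i, b in enumerate(block_ids)}
    adj = binarize(net)
    members = {b: [i for i, v in enumerate(net.nodes) if partition[v] == b] for b in block_ids}
    k = len(block_ids)
    out = np.full((k, k), np.nan)
    for b1 in block_ids:
        m1 = members[b1]
        size = len(m1)
        possible = size * (size - 1) / 2
        if possible > 0:
            within = adj[np.ix_(m1, m1)].sum() / 2
            out[pos[b1], pos[b1]] = within / possible
        for b2 in block_ids:
            if b2 <= b1:
                continue
            m2 = members[b2]
            between = adj[np.ix_(m1, m2)].sum()
            out[pos[b1], pos[b2]] = out[pos[b2], pos[b1]] = between / (size * len(m2))
    return out
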