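"""Similarity / association matrices and the two drug-side-effect
heterogeneous graphs.

A heterogeneous graph mixes three edge types: drug-drug similarity links,
side-effect-side-effect similarity links and drug-side-effect association
links.  Its adjacency is the block matrix ``[[M, O], [O.T, S]]``; because
every row concatenates an entity's similarity and association profiles, the
adjacency doubles as the node attribute matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityMatrix",
    "AssociationMatrix",
    "HeteroGraph",
    "cosine_similarity",
    "set_similarity",
    "jaccard_index",
    "build_hetero_graph",
    "laplace_normalize",
]

_KINDS = ("chem", "dise", "side_effect")
_VIEWS = ("chem", "dise")


def _as_array(x) -> np.ndarray:
    return x.values if hasattr(x, "values") and isinstance(getattr(x, "values"), np.ndarray) else np.asarray(x)


@dataclass
class SimilarityMatrix:
    """Symmetric [0, 1]-valued similarity matrix over one entity type."""

    values: np.ndarray
    kind: str = "chem"
    entity_ids: list[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in _KINDS:
            raise ValueError(f"unknown similarity kind {self.kind!r}")
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != n:
            raise ValueError("similarity matrix must be square")
        if self.entity_ids is None:
            prefix = "s" if self.kind == "side_effect" else "r"
            self.entity_ids = [f"{prefix}{i}" for i in range(n)]
        if len(self.entity_ids) != n:
            raise ValueError("entity_ids length does not match matrix dimension")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def validate(self, atol: float = 1e-8) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=atol):
            raise ValueError("similarity matrix is not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=atol):
            raise ValueError("similarity diagonal must equal 1")
        if v.min() < -atol or v.max() > 1 + atol:
            raise ValueError("similarity entries must lie in [0, 1]")


@dataclass
class AssociationMatrix:
    """Binary drug x side-effect association matrix ``O``."""

    values: np.ndarray
    drug_ids: list[str] | None = None
    side_effect_ids: list[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("association matrix must be 2-D")
        nr, ns = self.values.shape
        if self.drug_ids is None:
            self.drug_ids = [f"r{i}" for i in range(nr)]
        if self.side_effect_ids is None:
            self.side_effect_ids = [f"s{j}" for j in range(ns)]
        if len(self.drug_ids) != nr or len(self.side_effect_ids) != ns:
            raise ValueError("id list lengths do not match matrix shape")

    @property
    def n_drugs(self) -> int:
        return self.values.shape[0]

    @property
    def n_side_effects(self) -> int:
        return self.values.shape[1]

    @property
    def n_positives(self) -> int:
        return int(self.values.sum())

    def validate(self) -> None:
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("association entries must be binary")


@dataclass
class HeteroGraph:
    """One view of the drug-side-effect heterogeneous graph.

    ``adjacency`` is ``[[M, O], [O.T, S]]`` of shape (N_v, N_v) with
    ``N_v = n_drugs + n_side_effects``; ``attributes`` aliases it.  The
    similarity diagonals supply the self-connections, so no extra identity
    is added before degree computation.
    """

    view: str
    adjacency: np.ndarray
    n_drugs: int
    n_side_effects: int
    _normalized: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.view not in _VIEWS:
            raise ValueError(f"unknown view {self.view!r}")
        nv = self.n_drugs + self.n_side_effects
        if self.adjacency.shape != (nv, nv):
            raise ValueError("adjacency shape inconsistent with node counts")

    @property
    def n_nodes(self) -> int:
        return self.n_drugs + self.n_side_effects

    @property
    def attributes(self) -> np.ndarray:
        return self.adjacency

    @property
    def degree(self) -> np.ndarray:
        return np.diag(self.adjacency.sum(axis=1))

    @property
    def normalized(self) -> np.ndarray:
        if self._normalized is None:
            self._normalized = laplace_normalize(self.adjacency)
        return self._normalized


def cosine_similarity(profiles, kind: str = "chem",
                      entity_ids: Sequence[str] | None = None) -> SimilarityMatrix:
    """Pairwise cosine similarity between rows of a nonnegative feature
    matrix (e.g. binary substructure fingerprints).

    The diagonal is forced to 1; pairs involving an all-zero row get 0
    off-diagonal similarity by convention.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.size == 0:
        raise ValueError("empty profile matrix")
    if profiles.ndim != 2:
        raise ValueError("profiles must be a 2-D matrix (rows = entities)")
    if profiles.min() < 0:
        raise ValueError("profiles must be nonnegative")
    norms = np.linalg.norm(profiles, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    sim = (profiles @ profiles.T) / np.outer(safe, safe)
    zero = norms == 0
    sim[zero, :] = 0.0
    sim[:, zero] = 0.0
    np.fill_diagonal(sim, 1.0)
    sim = np.clip((sim + sim.T) / 2.0, 0.0, 1.0)
    ids = list(entity_ids) if entity_ids is not None else None
    return SimilarityMatrix(sim, kind=kind, entity_ids=ids)


def jaccard_index(a: frozenset, b: frozenset) -> float:
    """|a & b| / |a | b| for two nonempty sets."""
    return len(a & b) / len(a | b)


def set_similarity(memberships: Sequence, kind: str = "dise",
                   entity_ids: Sequence[str] | None = None,
                   measure: Callable[[frozenset, frozenset], float] | None = None,
                   ) -> SimilarityMatrix:
    """Similarity between entities described by association sets (e.g. the
    diseases a drug treats, or the drugs a side effect co-occurs with).

    ``measure`` is a pluggable set-overlap function; the default is the
    Jaccard index, which grows with the number of shared members.  A pair
    where both sets are empty scores 0; the diagonal is 1.
    """
    sets = [frozenset(m) for m in memberships]
    n = len(sets)
    if n == 0:
        raise ValueError("empty membership list")
    sim = np.zeros((n, n))
    if measure is None:
        # vectorised Jaccard through a binary membership matrix
        universe = sorted(set().union(*sets)) if any(sets) else []
        index = {u: k for k, u in enumerate(universe)}
        member = np.zeros((n, max(len(universe), 1)))
        for i, s in enumerate(sets):
            for u in s:
                member[i, index[u]] = 1.0
        inter = member @ member.T
        sizes = member.sum(axis=1)
        union = sizes[:, None] + sizes[None, :] - inter
        np.divide(inter, union, out=sim, where=union > 0)
    else:
        for i in range(n):
            for j in range(i + 1, n):
                if sets[i] and sets[j]:
                    sim[i, j] = sim[j, i] = measure(sets[i], sets[j])
    np.fill_diagonal(sim, 1.0)
    ids = list(entity_ids) if entity_ids is not None else None
    return SimilarityMatrix(sim, kind=kind, entity_ids=ids)


def build_hetero_graph(m: SimilarityMatrix | np.ndarray,
                       s: SimilarityMatrix | np.ndarray,
                       o: AssociationMatrix | np.ndarray,
                       view: str) -> HeteroGraph:
    """Assemble the block adjacency ``[[M, O], [O.T, S]]`` for one view."""
    mv, sv, ov = _as_array(m), _as_array(s), _as_array(o)
    nr, ns = ov.shape
    if mv.shape != (nr, nr):
        raise ValueError(f"drug similarity is {mv.shape}, expected ({nr}, {nr})")
    if sv.shape != (ns, ns):
        raise ValueError(f"side-effect similarity is {sv.shape}, expected ({ns}, {ns})")
    adj = np.block([[mv, ov], [ov.T, sv]])
    return HeteroGraph(view=view, adjacency=adj, n_drugs=nr, n_side_effects=ns)


def laplace_normalize(graph: HeteroGraph | np.ndarray) -> np.ndarray:
    """Symmetric normalisation ``D^{-1/2} A D^{-1/2}``, ``D_ii = sum_j A_ij``.

    Requires every node to have positive degree (the unit similarity
    diagonal guarantees this for properly built graphs).
    """
    a = graph.adjacency if isinstance(graph, HeteroGraph) else np.asarray(graph, dtype=float)
    deg = a.sum(axis=1)
    bad = np.flatnonzero(deg <= 0)
    if bad.size:
        raise ValueError(f"zero-degree node(s) at index {bad.tolist()}: "
                         "cannot Laplace-normalize")
    d = 1.0 / np.sqrt(deg)
    return a * np.outer(d, d)
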