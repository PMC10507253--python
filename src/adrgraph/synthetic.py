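"""Seed-controlled synthetic drug / side-effect datasets with planted
block structure.

Drugs and side effects are partitioned into communities; associations are
dense within a community and sparse across (a planted bipartite block
model).  Each drug community owns disjoint substructure and disease
signature feature sets whose noisy per-drug memberships yield the chemical
(cosine) and disease-based (set overlap) drug similarities; side-effect
similarity is computed from each side effect's associated-drug set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graphs import (AssociationMatrix, SimilarityMatrix, cosine_similarity,
                     set_similarity)

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate_dataset"]


@dataclass
class SyntheticConfig:
    n_drugs: int = 60
    n_side_effects: int = 120
    n_blocks: int = 3
    p_in: float = 0.5
    p_out: float = 0.02
    n_substructures: int = 96
    n_diseases: int = 90
    noise_flip: float = 0.01
    seed: int = 0

    def __post_init__(self):
        for name in ("n_drugs", "n_side_effects", "n_blocks",
                     "n_substructures", "n_diseases"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        for name in ("p_in", "p_out", "noise_flip"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.p_in <= self.p_out:
            raise ValueError("p_in must exceed p_out for planted structure")
        if min(self.n_drugs, self.n_side_effects,
               self.n_substructures, self.n_diseases) < self.n_blocks:
            raise ValueError("every size must be >= n_blocks")


@dataclass
class SyntheticDataset:
    m_chem: SimilarityMatrix
    m_dise: SimilarityMatrix
    s: SimilarityMatrix
    o: AssociationMatrix
    drug_blocks: np.ndarray
    side_effect_blocks: np.ndarray
    config: SyntheticConfig

    @property
    def matrices(self):
        """(M_chem, M_dise, S, O) raw arrays, the model's input order."""
        return (self.m_chem.values, self.m_dise.values,
                self.s.values, self.o.values)


def _block_labels(rng: np.random.Generator, n: int, n_blocks: int) -> np.ndarray:
    # round-robin counts (every block nonempty), randomly assigned
    return rng.permutation(np.arange(n) % n_blocks)


def _noisy_membership(rng: np.random.Generator, labels: np.ndarray,
                      n_features: int, n_blocks: int, flip: float) -> np.ndarray:
    signatures = np.array_split(np.arange(n_features), n_blocks)
    member = np.zeros((labels.size, n_features))
    for i, lab in enumerate(labels):
        member[i, signatures[lab]] = 1.0
    if flip > 0:
        flips = rng.random(member.shape) < flip
        member = np.abs(member - flips)
    return member


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one dataset; bitwise reproducible for a fixed ``config.seed``.

    One seed stream is split per matrix, so adding a matrix later would not
    perturb earlier draws.
    """
    ss = np.random.SeedSequence(config.seed)
    r_labels, r_assoc, r_fp, r_dise = (np.random.default_rng(c)
                                       for c in ss.spawn(4))

    drug_blocks = _block_labels(r_labels, config.n_drugs, config.n_blocks)
    se_blocks = _block_labels(r_labels, config.n_side_effects, config.n_blocks)

    same = drug_blocks[:, None] == se_blocks[None, :]
    p = np.where(same, config.p_in, config.p_out)
    o_values = (r_assoc.random(p.shape) < p).astype(float)
    o = AssociationMatrix(o_values)

    fingerprints = _noisy_membership(r_fp, drug_blocks, config.n_substructures,
                                     config.n_blocks, config.noise_flip)
    m_chem = cosine_similarity(fingerprints, kind="chem",
                               entity_ids=o.drug_ids)

    disease_member = _noisy_membership(r_dise, drug_blocks, config.n_diseases,
                                       config.n_blocks, config.noise_flip)
    disease_sets = [frozenset(np.flatnonzero(row)) for row in disease_member]
    m_dise = set_similarity(disease_sets, kind="dise", entity_ids=o.drug_ids)

    se_drug_sets = [frozenset(np.flatnonzero(o_values[:, j]))
                    for j in range(config.n_side_effects)]
    s = set_similarity(se_drug_sets, kind="side_effect",
                       entity_ids=o.side_effect_ids)

    return SyntheticDataset(m_chem=m_chem, m_dise=m_dise, s=s, o=o,
                            drug_blocks=drug_blocks, side_effect_blocks=se_blocks,
                            config=config)

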