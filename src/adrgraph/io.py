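"""Delimited-text persistence for dataset matrices.

A dataset directory holds four tab-delimited matrices (header row of entity
IDs, index column) plus ``meta.json`` recording the dimensions and, for
synthetic data, the generating configuration and block labels.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .graphs import AssociationMatrix, SimilarityMatrix
from .synthetic import SyntheticConfig, SyntheticDataset

__all__ = ["write_matrix", "read_matrix", "write_dataset", "read_dataset"]

_FILES = {"m_chem": "M_chem.tsv", "m_dise": "M_dise.tsv",
          "s": "S.tsv", "o": "O.tsv"}


def write_matrix(path, values, row_ids, col_ids) -> None:
    df = pd.DataFrame(np.asarray(values), index=list(row_ids), columns=list(col_ids))
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_dataset(dataset: SyntheticDataset, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    o = dataset.o
    write_matrix(out / _FILES["m_chem"], dataset.m_chem.values, o.drug_ids, o.drug_ids)
    write_matrix(out / _FILES["m_dise"], dataset.m_dise.values, o.drug_ids, o.drug_ids)
    write_matrix(out / _FILES["s"], dataset.s.values, o.side_effect_ids, o.side_effect_ids)
    write_matrix(out / _FILES["o"], o.values, o.drug_ids, o.side_effect_ids)
    meta = {
        "n_drugs": o.n_drugs,
        "n_side_effects": o.n_side_effects,
        "config": asdict(dataset.config),
        "drug_blocks": dataset.drug_blocks.tolist(),
        "side_effect_blocks": dataset.side_effect_blocks.tolist(),
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1))
    return out


def read_dataset(data_dir) -> SyntheticDataset:
    d = Path(data_dir)
    meta = json.loads((d / "meta.json").read_text())
    o_df = read_matrix(d / _FILES["o"])
    drug_ids = [str(i) for i in o_df.index]
    se_ids = [str(c) for c in o_df.columns]
    o = AssociationMatrix(o_df.to_numpy(float), drug_ids=drug_ids, side_effect_ids=se_ids)
    m_chem = SimilarityMatrix(read_matrix(d / _FILES["m_chem"]).to_numpy(float),
                              kind="chem", entity_ids=drug_ids)
    m_dise = SimilarityMatrix(read_matrix(d / _FILES["m_dise"]).to_numpy(float),
                              kind="dise", entity_ids=drug_ids)
    s = SimilarityMatrix(read_matrix(d / _FILES["s"]).to_numpy(float),
                         kind="side_effect", entity_ids=se_ids)
    cfg = SyntheticConfig(**meta["config"]) if "config" in meta else SyntheticConfig(
        n_drugs=meta["n_drugs"], n_side_effects=meta["n_side_effects"])
    return SyntheticDataset(
        m_chem=m_chem, m_dise=m_dise, s=s, o=o,
        drug_blocks=np.asarray(meta.get("drug_blocks", [0] * o.n_drugs)),
        side_effect_blocks=np.asarray(meta.get("side_effect_blocks", [0] * o.n_side_effects)),
        config=cfg)
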