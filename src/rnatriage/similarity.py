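"""2D structural similarity ranking of scaffold derivatives.

Derivative candidates are ranked by Tanimoto similarity of circular
(Morgan) fingerprints to a parent scaffold; only 2D connectivity enters,
so no docked pose or conformer is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .docking import CompoundRecord

__all__ = ["FingerprintConfig", "SimilarityRanking", "similarity_rank", "read_smiles_csv"]


@dataclass(frozen=True)
class FingerprintConfig:
    """Circular-fingerprint settings: ECFP-like, radius 2, 2048 bits by default."""

    radius: int = 2
    n_bits: int = 2048


@dataclass
class SimilarityRanking:
    parent: CompoundRecord
    entries: list[tuple[str, float]] = field(default_factory=list)  # sorted descending


def _fingerprint(record: CompoundRecord, cfg: FingerprintConfig):
    if not record.smiles:
        raise ValueError(f"record {record.compound_id!r} has no SMILES")
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise ValueError(
            f"unparsable SMILES for record {record.compound_id!r}: {record.smiles!r}"
        )
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=cfg.radius, fpSize=cfg.n_bits
    )
    return gen.GetFingerprint(mol)


def similarity_rank(
    parent: CompoundRecord,
    candidates: list[CompoundRecord],
    fp_config: FingerprintConfig = FingerprintConfig(),
) -> SimilarityRanking:
    """Rank candidates by fingerprint Tanimoto similarity to the parent.

    Deterministic for a fixed config; ties are broken lexicographically by
    candidate id so the ordering is reproducible.
    """
    pfp = _fingerprint(parent, fp_config)
    scored = []
    for cand in candidates:
        cfp = _fingerprint(cand, fp_config)
        scored.append((cand.compound_id, float(DataStructs.TanimotoSimilarity(pfp, cfp))))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return SimilarityRanking(parent=parent, entries=scored)


def read_smiles_csv(path) -> list[CompoundRecord]:
    """Read a two-column CSV ``compound_id,smiles`` into compound records."""
    df = pd.read_csv(path)
    if not {"compound_id", "smiles"} <= set(df.columns):
        raise ValueError("SMILES CSV needs columns compound_id,smiles")
    return [
        CompoundRecord(compound_id=str(r.compound_id), smiles=str(r.smiles))
        for r in df.itertuples()
    ]
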