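"""Post-processing of docking-score tables from an RNA virtual screen.

A screen produces one best-pose docking energy (kcal/mol, lower = more
favourable) per compound per RNA target. Hit selection uses the classic
z-score rule: a compound is a hit when its score lies more than ``k``
sample standard deviations below the mean of the score distribution for
that target. Counter-screen targets (off-target hairpins) are used to
discard promiscuous compounds: a primary hit that also passes the same
rule on any counter target is removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CompoundRecord",
    "DockingScoreTable",
    "HitSelectionResult",
    "SelectivityResult",
    "select_hits",
    "filter_selectivity",
    "rank_top",
    "read_docking_csv",
    "write_docking_csv",
]

DOCKING_CSV_COLUMNS = ["compound_id", "target_id", "score_kcal_mol", "n_poses"]


@dataclass(frozen=True)
class CompoundRecord:
    """A screened compound: library identifier, optional screen alias and SMILES."""

    compound_id: str
    alias: str | None = None
    smiles: str | None = None

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValueError("compound_id must be non-empty")


@dataclass
class DockingScoreTable:
    """Best-pose docking scores for one RNA target.

    Rows hold one (compound, score, n_poses) triple per compound; any
    pose-level aggregation (minimum over poses) happens before the table
    is built.
    """

    target_id: str
    scores: pd.DataFrame  # columns: compound_id, score_kcal_mol, n_poses

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.scores, columns=DOCKING_CSV_COLUMNS[:1] + DOCKING_CSV_COLUMNS[2:])
        if df["compound_id"].duplicated().any():
            dup = df.loc[df["compound_id"].duplicated(), "compound_id"].iloc[0]
            raise ValueError(f"duplicate compound in table {self.target_id!r}: {dup!r}")
        bad = ~np.isfinite(df["score_kcal_mol"].to_numpy(dtype=float))
        if bad.any():
            raise ValueError(
                f"non-finite score for compound {df.loc[bad, 'compound_id'].iloc[0]!r}"
            )
        if (df["n_poses"].to_numpy(dtype=int) < 1).any():
            raise ValueError("n_poses must be >= 1")
        self.scores = df.reset_index(drop=True)

    @classmethod
    def from_records(
        cls, target_id: str, rows: list[tuple[str, float, int]]
    ) -> "DockingScoreTable":
        df = pd.DataFrame(rows, columns=["compound_id", "score_kcal_mol", "n_poses"])
        return cls(target_id=target_id, scores=df)

    def __len__(self) -> int:
        return len(self.scores)

    def score_of(self, compound_id: str) -> float | None:
        sel = self.scores.loc[self.scores["compound_id"] == compound_id, "score_kcal_mol"]
        return None if sel.empty else float(sel.iloc[0])


@dataclass
class HitSelectionResult:
    """Outcome of the mean − k·SD hit rule on one score table."""

    target_id: str
    mean: float
    sd: float
    k: float
    threshold: float
    hit_ids: list[str] = field(default_factory=list)
    hit_scores: dict[str, float] = field(default_factory=dict)


@dataclass
class SelectivityResult:
    """Partition of a hit set into retained and counter-screen-removed compounds."""

    retained_ids: list[str]
    removed: list[tuple[str, str]]  # (compound_id, first offending target)


def select_hits(table: DockingScoreTable, k: float = 2.0) -> HitSelectionResult:
    """Select hits scoring more than ``k`` sample SDs below the table mean.

    The threshold is ``mean − k·sd`` with the sample (n−1) standard
    deviation; membership uses a strict inequality, so with zero variance
    no compound is a hit.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if len(table) < 2:
        raise ValueError("insufficient scores: need at least 2 rows to define an SD")
    scores = table.scores["score_kcal_mol"].to_numpy(dtype=float)
    mean = float(np.mean(scores))
    sd = float(np.std(scores, ddof=1))
    threshold = mean - k * sd
    hits = table.scores[scores < threshold].sort_values(
        ["score_kcal_mol", "compound_id"]
    )
    return HitSelectionResult(
        target_id=table.target_id,
        mean=mean,
        sd=sd,
        k=k,
        threshold=threshold,
        hit_ids=hits["compound_id"].tolist(),
        hit_scores=dict(zip(hits["compound_id"], hits["score_kcal_mol"].astype(float))),
    )


def filter_selectivity(
    hits: HitSelectionResult,
    counter_tables: list[DockingScoreTable],
    k: float = 2.0,
) -> SelectivityResult:
    """Remove hits that also pass the mean − k·SD rule on any counter target.

    Each counter table is scored against its own distribution. A hit absent
    from a counter table is treated as not binding that target (with a
    logged warning). The first offending target, in the order the counter
    tables are given, is recorded for each removed compound.
    """
    counter_hits: list[tuple[str, set[str], set[str]]] = []
    for table in counter_tables:
        res = select_hits(table, k=k)
        present = set(table.scores["compound_id"])
        counter_hits.append((table.target_id, set(res.hit_ids), present))

    retained: list[str] = []
    removed: list[tuple[str, str]] = []
    for cid in hits.hit_ids:
        offender = None
        for target_id, chits, present in counter_hits:
            if cid not in present:
                logger.warning(
                    "compound %s missing from counter table %s; treated as non-binder",
                    cid,
                    target_id,
                )
                continue
            if cid in chits:
                offender = target_id
                break
        if offender is None:
            retained.append(cid)
        else:
            removed.append((cid, offender))
    return SelectivityResult(retained_ids=retained, removed=removed)


def rank_top(
    sel: SelectivityResult, table: DockingScoreTable, n: int
) -> list[str]:
    """Return the ``n`` retained compounds with the lowest primary-target score.

    Ties are broken lexicographically by compound_id. Asking for more
    compounds than were retained returns them all (logged).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    scored = sorted(
        ((table.score_of(cid), cid) for cid in sel.retained_ids),
        key=lambda t: (t[0], t[1]),
    )
    if n > len(scored):
        logger.info(
            "requested top %d but only %d retained; returning all", n, len(scored)
        )
        n = len(scored)
    return [cid for _, cid in scored[:n]]


def read_docking_csv(path) -> dict[str, DockingScoreTable]:
    """Read a docking CSV (compound_id,target_id,score_kcal_mol,n_poses) into per-target tables."""
    df = pd.read_csv(path)
    missing = set(DOCKING_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"docking CSV missing columns: {sorted(missing)}")
    out = {}
    for target_id, grp in df.groupby("target_id", sort=False):
        out[str(target_id)] = DockingScoreTable(
            target_id=str(target_id),
            scores=grp[["compound_id", "score_kcal_mol", "n_poses"]],
        )
    return out


def write_docking_csv(path, tables: list[DockingScoreTable]) -> None:
    frames = []
    for t in tables:
        df = t.scores.copy()
        df.insert(1, "target_id", t.target_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
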