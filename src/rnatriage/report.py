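"""Stage orchestration, per-compound summary table and hit-rate accounting."""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import pandas as pd

from .docking import CompoundRecord
from .fid import FIDResult, analyze_plate
from .std import STDCall, STDConfig, run_std

__all__ = [
    "CompoundSummary",
    "RateReport",
    "merge_summaries",
    "validation_rates",
    "fold_affinity",
    "run_std_screen",
    "run_fid_screen",
    "round_half_up",
    "summaries_to_frame",
]


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves going up (17.5 -> 18)."""
    return int(math.floor(x + 0.5))


@dataclass
class CompoundSummary:
    """One merged row of the final screen summary.

    Missing stage results stay None and render as "ND" — absent is not
    zero.
    """

    compound_id: str
    alias: str | None = None
    docking_score: float | None = None
    std_call: str | None = None
    fid_pct: float | None = None
    fid_call: str | None = None
    csp_regions: list[str] | None = None
    kd_display: str | None = None  # "29.10", "> 1000", or None -> ND
    flags: set[str] = field(default_factory=set)


@dataclass
class RateReport:
    """Headline counts and half-up-rounded percentage rates for the screen."""

    n_total: int
    std_testable: int
    std_hits: int
    fid_hits: int
    union_validated: int
    std_rate_pct: int
    fid_rate_pct: int
    union_rate_pct: int


def run_std_screen(
    std_spectra: dict, cfg: STDConfig = STDConfig()
) -> dict[str, STDCall]:
    """Run testability gating and binder calling over per-compound spectra.

    ``std_spectra`` maps alias -> (plain, off, on); off/on may be None
    for compounds without a usable 1D spectrum.
    """
    return {
        alias: run_std(alias, plain, off, on, cfg)
        for alias, (plain, off, on) in sorted(std_spectra.items())
    }


def run_fid_screen(wells, band: float = 15.0) -> dict[str, FIDResult]:
    """Run the plate analysis and index the results by compound."""
    return {r.compound_id: r for r in analyze_plate(wells, band=band)}


def merge_summaries(
    compounds: list[CompoundRecord],
    docking_scores: dict[str, float] | None = None,
    std_calls: dict[str, STDCall] | None = None,
    fid_results: dict[str, FIDResult] | None = None,
    csp_regions: dict[str, list[str]] | None = None,
    kd_fits: dict[str, str] | None = None,
) -> list[CompoundSummary]:
    """Merge stage outputs (keyed by alias) into one row per compound."""
    seen = set()
    rows = []
    for c in compounds:
        key = c.alias or c.compound_id
        if key in seen:
            raise ValueError(f"conflicting duplicate compound {key!r}")
        seen.add(key)
        std = (std_calls or {}).get(key)
        fid = (fid_results or {}).get(key)
        rows.append(
            CompoundSummary(
                compound_id=c.compound_id,
                alias=c.alias,
                docking_score=(docking_scores or {}).get(key),
                std_call=std.call if std else None,
                fid_pct=fid.pct_fid_mean if fid else None,
                fid_call=fid.call if fid else None,
                csp_regions=(csp_regions or {}).get(key),
                kd_display=(kd_fits or {}).get(key),
                flags=set(fid.flags) if fid else set(),
            )
        )
    return rows


def summaries_to_frame(rows: list[CompoundSummary]) -> pd.DataFrame:
    """Render the summary as a DataFrame with "ND" for absent results."""

    def nd(v, fmt="{}"):
        return "ND" if v is None else fmt.format(v)

    return pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "alias": r.alias or "",
                "docking_score_kcal_mol": nd(r.docking_score, "{:.3f}"),
                "std_call": nd(r.std_call),
                "pct_fid": nd(r.fid_pct, "{:.1f}"),
                "fid_call": nd(r.fid_call),
                "csp_regions": "; ".join(r.csp_regions) if r.csp_regions else "ND",
                "kd_uM": r.kd_display or "ND",
                "flags": "; ".join(sorted(r.flags)),
            }
            for r in rows
        ]
    )


def validation_rates(
    std_hits: set, fid_hits: set, n_total: int, std_testable: int = 0
) -> RateReport:
    """Hit counts and percentage rates; the union counts every validated binder once."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    std_hits, fid_hits = set(std_hits), set(fid_hits)
    union = std_hits | fid_hits
    return RateReport(
        n_total=n_total,
        std_testable=std_testable,
        std_hits=len(std_hits),
        fid_hits=len(fid_hits),
        union_validated=len(union),
        std_rate_pct=round_half_up(100.0 * len(std_hits) / n_total),
        fid_rate_pct=round_half_up(100.0 * len(fid_hits) / n_total),
        union_rate_pct=round_half_up(100.0 * len(union) / n_total),
    )


_BOUND_RE = re.compile(r"^\s*>\s*([\d.eE+-]+)\s*$")


def fold_affinity(kd_a: float, kd_b) -> float | str:
    """Fold difference in affinity of A over B (ratio of KDs, KD_b / KD_a).

    When ``kd_b`` is a lower bound (a string like ">1000"), the result is
    itself a lower bound, rendered ">B/kd_a".
    """
    if kd_a <= 0:
        raise ValueError("kd_a must be positive")
    if isinstance(kd_b, str):
        m = _BOUND_RE.match(kd_b)
        if not m:
            raise ValueError(f"cannot parse KD bound {kd_b!r}")
        bound = float(m.group(1))
        if bound <= 0:
            raise ValueError("KD bound must be positive")
        return f">{bound / kd_a:.1f}"
    if kd_b <= 0:
        raise ValueError("kd_b must be positive")
    return float(kd_b) / float(kd_a)


def fold_affinity_value(fold: float | str) -> float:
    """Numeric magnitude of a fold-affinity result, bound or not."""
    if isinstance(fold, str):
        return float(_BOUND_RE.match(fold).group(1))
    return float(fold)
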