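"""Fluorescence indicator displacement (FID) assay analysis.

An intercalating dye (e.g. TO-PRO-1) fluoresces when bound to the target
RNA. The dye's affinity is calibrated by titrating RNA at fixed dye and
fitting the one-site isotherm

    Y = Bmax * X / (KD + X)

where X is the RNA concentration and Y the fluorescence (RFU). The
screen is then run at the RNA concentration giving a chosen initial dye
fraction bound (typically 0.1), and each ligand's displacement is scored
as

    %FID = 100 * (F0 - F) / F0

against the RNA+dye blank F0. Ligands displacing the dye by more than a
±band (default 15%) in every replicate are hits; consistent negative
%FID marks fluorescence enhancers. Dye-only and RNA-only control wells
flag ligands that fluoresce with the dye or the RNA themselves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import Model
from sklearn.base import BaseEstimator, RegressorMixin

logger = logging.getLogger(__name__)

__all__ = [
    "PlateWell",
    "DyeBindingFit",
    "FIDResult",
    "OneSiteBindingModel",
    "fit_dye_binding",
    "conc_at_fraction_bound",
    "percent_fid",
    "classify_fid",
    "annotate_controls",
    "analyze_plate",
    "read_plate_csv",
    "write_plate_csv",
]

PLATE_CSV_COLUMNS = [
    "well_id",
    "rna_nM",
    "dye_nM",
    "compound_id",
    "ligand_uM",
    "rfu",
    "replicate",
]


@dataclass
class PlateWell:
    """One 96-well-plate reading: contents plus raw fluorescence."""

    well_id: str
    rna_nM: float
    dye_nM: float
    compound_id: str | None
    ligand_uM: float
    rfu: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if not np.isfinite(self.rfu):
            raise ValueError(f"well {self.well_id}: non-finite RFU")
        if min(self.rna_nM, self.dye_nM, self.ligand_uM) < 0:
            raise ValueError(f"well {self.well_id}: negative concentration")
        if self.replicate < 1:
            raise ValueError(f"well {self.well_id}: replicate must be >= 1")
        if self.compound_id == "":
            self.compound_id = None


def _one_site(x, bmax, kd):
    return bmax * x / (kd + x)


class OneSiteBindingModel(BaseEstimator, RegressorMixin):
    """Nonlinear least-squares fit of the one-site isotherm Y = Bmax·X/(KD+X).

    Scikit-learn style: ``fit(X, y)`` with concentrations X (any unit)
    and responses y, then fitted attributes ``kd_``, ``bmax_``,
    ``se_kd_``, ``se_bmax_``, ``converged_`` and ``predict(X)``.

    Initialisation: Bmax0 = max(y), KD0 = concentration nearest half of
    Bmax0; both parameters are bounded positive.
    """

    def __init__(self, ftol: float = 1e-10):
        self.ftol = ftol

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise ValueError("X and y must have the same length")
        if not np.any(np.abs(y) > 0):
            raise ValueError("flat response: all responses are zero")
        bmax0 = float(np.max(y))
        half_idx = int(np.argmin(np.abs(y - bmax0 / 2.0)))
        kd0 = float(x[half_idx])
        if kd0 <= 0:
            kd0 = float(np.median(x[x > 0])) if np.any(x > 0) else 1.0
        model = Model(_one_site)
        params = model.make_params()
        params["bmax"].set(value=max(bmax0, 1e-12), min=1e-12)
        params["kd"].set(value=max(kd0, 1e-12), min=1e-12)
        result = model.fit(y, params, x=x, fit_kws={"ftol": self.ftol, "xtol": self.ftol})
        if not result.success:
            raise RuntimeError(f"one-site fit did not converge: {result.message}")
        self.kd_ = float(result.params["kd"].value)
        self.bmax_ = float(result.params["bmax"].value)
        self.se_kd_ = float(result.params["kd"].stderr or 0.0)
        self.se_bmax_ = float(result.params["bmax"].stderr or 0.0)
        self.n_points_ = int(x.size)
        self.converged_ = bool(result.success)
        self.result_ = result
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float)
        return _one_site(x, self.bmax_, self.kd_)


@dataclass
class DyeBindingFit:
    """Fitted dye-RNA affinity from the calibration titration."""

    kd_nM: float
    bmax_rfu: float
    se_kd: float
    se_bmax: float
    n_points: int
    converged: bool


def fit_dye_binding(wells: list[PlateWell]) -> DyeBindingFit:
    """Fit the dye calibration titration (varying RNA, fixed dye) to the one-site isotherm."""
    if not wells:
        raise ValueError("no wells supplied")
    dye = {w.dye_nM for w in wells}
    if len(dye) != 1:
        raise ValueError(f"dye concentration must be constant across wells, got {sorted(dye)}")
    x = np.array([w.rna_nM for w in wells], dtype=float)
    y = np.array([w.rfu for w in wells], dtype=float)
    concs = np.unique(x)
    if concs.size < 5 or 0.0 not in concs:
        raise ValueError("need >= 5 distinct RNA concentrations including 0")
    est = OneSiteBindingModel().fit(x, y)
    return DyeBindingFit(
        kd_nM=est.kd_,
        bmax_rfu=est.bmax_,
        se_kd=est.se_kd_,
        se_bmax=est.se_bmax_,
        n_points=est.n_points_,
        converged=est.converged_,
    )


def conc_at_fraction_bound(fit: DyeBindingFit | float, f: float) -> float:
    """RNA concentration at which the dye's fraction bound equals ``f``.

    Exact inversion of the one-site isotherm: X = f·KD/(1−f). The screen
    is typically run at f = 0.1 to maximise displacement sensitivity.
    """
    if not 0.0 < f < 1.0:
        raise ValueError("fraction bound must be strictly between 0 and 1")
    kd = fit.kd_nM if isinstance(fit, DyeBindingFit) else float(fit)
    return f * kd / (1.0 - f)


def percent_fid(f0: float, f: float) -> float:
    """Percent indicator displacement 100·(F0 − F)/F0; negative for enhancement."""
    if f0 <= 0:
        raise ValueError("blank fluorescence F0 must be positive")
    return 100.0 * (f0 - f) / f0


def classify_fid(pct_fid_per_replicate, band: float = 15.0) -> str:
    """Call a ligand from its replicate %FID values.

    ``hit`` iff every replicate displaces by strictly more than the band;
    ``enhancer`` iff every replicate is below −band; otherwise ``none``.
    The all-replicates rule avoids single-well false positives.
    """
    vals = list(pct_fid_per_replicate)
    if not vals:
        raise ValueError("need at least one replicate %FID value")
    if all(v > band for v in vals):
        return "hit"
    if all(v < -band for v in vals):
        return "enhancer"
    return "none"


@dataclass
class FIDResult:
    compound_id: str
    pct_fid_per_replicate: list[float]
    pct_fid_mean: float
    fluorescence_change: float  # 100 − mean %FID
    call: str
    flags: set[str] = field(default_factory=set)


def _mean_rfu(wells: list[PlateWell]) -> float:
    return float(np.mean([w.rfu for w in wells]))


def annotate_controls(
    dye_ligand_wells: dict[str, list[PlateWell]],
    rna_ligand_wells: dict[str, list[PlateWell]],
    dye_only: list[PlateWell],
    rna_only: list[PlateWell],
    band: float = 15.0,
) -> dict[str, set[str]]:
    """Flag dye-interacting and intrinsically fluorescent ligands from control wells.

    A ligand is flagged ``dye_interactor`` when its dye+ligand wells exceed
    the dye-only baseline by more than ``band`` percent (relative), and
    ``intrinsic_fluorophore`` analogously for RNA+ligand vs RNA-only.
    """
    flags: dict[str, set[str]] = {}
    for name, ligand_wells, baseline_wells, flag in (
        ("dye-only", dye_ligand_wells, dye_only, "dye_interactor"),
        ("rna-only", rna_ligand_wells, rna_only, "intrinsic_fluorophore"),
    ):
        if not ligand_wells:
            continue
        if not baseline_wells:
            raise ValueError(f"missing baseline wells for control type {name!r}")
        baseline = _mean_rfu(baseline_wells)
        for cid, wells in ligand_wells.items():
            rel = 100.0 * (_mean_rfu(wells) - baseline) / baseline
            if rel > band:
                flags.setdefault(cid, set()).add(flag)
    return flags


def _role(w: PlateWell) -> str:
    has_rna, has_dye, has_cmpd = w.rna_nM > 0, w.dye_nM > 0, w.compound_id is not None
    if has_rna and has_dye:
        return "assay" if has_cmpd else "blank"
    if has_dye:
        return "dye_ligand" if has_cmpd else "dye_only"
    if has_rna:
        return "rna_ligand" if has_cmpd else "rna_only"
    return "buffer"


def analyze_plate(
    wells: list[PlateWell], band: float = 15.0, control_band: float | None = None
) -> list[FIDResult]:
    """Full screening-plate analysis: %FID per replicate, hit calls and control flags.

    Well roles are inferred from nonzero components; empty compound_id
    marks blank/control wells. Buffer-only wells, if present, are
    subtracted from every reading first. F0 is taken per replicate from
    the RNA+dye blank wells.
    """
    by_role: dict[str, list[PlateWell]] = {}
    for w in wells:
        by_role.setdefault(_role(w), []).append(w)

    buffer_wells = by_role.get("buffer", [])
    offset = _mean_rfu(buffer_wells) if buffer_wells else 0.0
    if buffer_wells:
        logger.info("subtracting buffer baseline of %.3f RFU from all wells", offset)
    else:
        logger.info("no buffer-only wells; using raw RFU")

    blanks = by_role.get("blank", [])
    if not blanks:
        raise ValueError("no RNA+dye blank wells on the plate; cannot compute F0")
    f0_by_rep: dict[int, float] = {}
    for rep in {w.replicate for w in blanks}:
        f0_by_rep[rep] = _mean_rfu([w for w in blanks if w.replicate == rep]) - offset
    f0_overall = _mean_rfu(blanks) - offset

    def _group(role: str) -> dict[str, list[PlateWell]]:
        out: dict[str, list[PlateWell]] = {}
        for w in by_role.get(role, []):
            out.setdefault(w.compound_id, []).append(w)
        return out

    flags = annotate_controls(
        _group("dye_ligand"),
        _group("rna_ligand"),
        by_role.get("dye_only", []),
        by_role.get("rna_only", []),
        band=band if control_band is None else control_band,
    )

    results = []
    for cid, cw in sorted(_group("assay").items()):
        pcts = []
        for w in sorted(cw, key=lambda w: w.replicate):
            f0 = f0_by_rep.get(w.replicate, f0_overall)
            pcts.append(percent_fid(f0, w.rfu - offset))
        mean = float(np.mean(pcts))
        results.append(
            FIDResult(
                compound_id=cid,
                pct_fid_per_replicate=pcts,
                pct_fid_mean=mean,
                fluorescence_change=100.0 - mean,
                call=classify_fid(pcts, band=band),
                flags=flags.get(cid, set()),
            )
        )
    return results


def read_plate_csv(path) -> list[PlateWell]:
    df = pd.read_csv(path, keep_default_na=False)
    missing = set(PLATE_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plate CSV missing columns: {sorted(missing)}")
    wells = []
    for r in df.itertuples():
        cid = str(r.compound_id).strip()
        wells.append(
            PlateWell(
                well_id=str(r.well_id),
                rna_nM=float(r.rna_nM),
                dye_nM=float(r.dye_nM),
                compound_id=cid or None,
                ligand_uM=float(r.ligand_uM),
                rfu=float(r.rfu),
                replicate=int(r.replicate),
            )
        )
    return wells


def write_plate_csv(path, wells: list[PlateWell]) -> None:
    pd.DataFrame(
        [
            {
                "well_id": w.well_id,
                "rna_nM": w.rna_nM,
                "dye_nM": w.dye_nM,
                "compound_id": w.compound_id or "",
                "ligand_uM": w.ligand_uM,
                "rfu": w.rfu,
                "replicate": w.replicate,
            }
            for w in wells
        ]
    ).to_csv(path, index=False)
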