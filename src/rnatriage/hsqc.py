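"""HSQC titration analysis: chemical shift perturbations and KD fitting.

Aromatic C–H correlations (C2-H2, C5-H5, C6-H6, C8-H8) of an A/C-labelled
RNA hairpin are followed across a ligand titration. Two exchange regimes
are handled:

* **fast exchange** — peaks move continuously; the chemical shift
  perturbation (CSP) of a peak between free and bound states is the
  weighted Pythagorean distance

      CSP = sqrt(δH² + α·δC²),   α = 0.14 by default,

  and the CSP-vs-concentration trajectory is fitted to the isotherm
  CSP(X) = Bmax·X/(KD + X).

* **intermediate exchange** — free-state peaks broaden and lose volume;
  the fraction bound at ligand concentration X is B = 1 − V(X)/V(0) and
  is fitted to B(X) = Bmax·X/(KD + X) + NS·X, with NS the slope of a
  linear nonspecific-binding term.

Significantly perturbed residues (CSP ≥ mean + 1·SD by default) are
mapped onto secondary-structure regions of the hairpin (apical loop,
junction, dicing-site bulge, mismatches, stem).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lmfit import Model
from sklearn.base import BaseEstimator, RegressorMixin

logger = logging.getLogger(__name__)

__all__ = [
    "Peak2D",
    "TitrationSeries",
    "CSPTable",
    "ExchangeFit",
    "compute_csp",
    "csp_table",
    "flag_significant",
    "map_to_regions",
    "fraction_bound",
    "FastExchangeFitter",
    "IntermediateExchangeFitter",
    "fit_fast",
    "fit_intermediate",
    "DEFAULT_REGION_MAP",
    "load_region_map",
    "read_peaklist",
    "write_peaklist",
    "read_titration_manifest",
]

CORRELATIONS = ("C2-H2", "C5-H5", "C6-H6", "C8-H8")
REGIONS = ("apical loop", "junction", "dicing-site bulge", "stem", "mismatch")

PEAKLIST_CSV_COLUMNS = [
    "residue",
    "base",
    "correlation",
    "ppm_h",
    "ppm_c",
    "volume",
    "intensity",
    "status",
]


@dataclass
class Peak2D:
    """One assigned 2D correlation peak."""

    position: int  # 1-based construct numbering
    base: str  # A|C|G|U
    correlation: str
    d_h: float
    d_c: float
    volume: float
    intensity: float
    status: str = "ok"  # ok | overlapped (unquantifiable)

    def __post_init__(self) -> None:
        if self.correlation not in CORRELATIONS:
            raise ValueError(f"unknown correlation {self.correlation!r}")
        if self.base not in "ACGU":
            raise ValueError(f"unknown base {self.base!r}")
        if self.volume < 0:
            raise ValueError("peak volume must be non-negative")

    @property
    def key(self) -> tuple[int, str]:
        return (self.position, self.correlation)

    @property
    def label(self) -> str:
        return f"{self.base}{self.position} {self.correlation}"


PeakList = dict  # (position, correlation) -> Peak2D


def build_peaklist(peaks: list[Peak2D]) -> PeakList:
    out: PeakList = {}
    for p in peaks:
        if p.key in out:
            raise ValueError(f"duplicate peak {p.label}")
        out[p.key] = p
    return out


@dataclass
class TitrationSeries:
    """Per-concentration peak lists at constant RNA concentration."""

    ligand_conc_uM: list[float]
    peak_lists: list[PeakList]
    rna_conc_uM: float = float("nan")

    def __post_init__(self) -> None:
        c = np.asarray(self.ligand_conc_uM, dtype=float)
        if c.size != len(self.peak_lists):
            raise ValueError("one peak list per concentration required")
        if c.size == 0 or c[0] != 0.0:
            raise ValueError("first titration point must be the 0 uM reference")
        if not np.all(np.diff(c) > 0):
            raise ValueError("ligand concentrations must be strictly increasing")

    @property
    def reference(self) -> PeakList:
        return self.peak_lists[0]


def compute_csp(
    free: Peak2D, bound: Peak2D, alpha: float = 0.14, convention: str = "literal"
) -> float:
    """Weighted Pythagorean chemical shift perturbation between two states.

    ``convention="literal"`` computes sqrt(δH² + α·δC²); ``"scaled"``
    uses the alternative sqrt(δH² + (α·δC)²) weighting.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if free.key != bound.key:
        raise ValueError(
            f"residue/correlation mismatch: {free.label} vs {bound.label}"
        )
    dh = bound.d_h - free.d_h
    dc = bound.d_c - free.d_c
    if convention == "literal":
        return float(np.sqrt(dh * dh + alpha * dc * dc))
    if convention == "scaled":
        return float(np.sqrt(dh * dh + (alpha * dc) ** 2))
    raise ValueError(f"unknown CSP convention {convention!r}")


@dataclass
class CSPTable:
    """Per-peak CSPs with a significance flag and the rule that set it."""

    table: pd.DataFrame  # position, base, correlation, csp_ppm, status, significant
    threshold_used: float = float("nan")
    rule_name: str = ""

    def flagged(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def csp_table(
    series: TitrationSeries,
    point: int = -1,
    alpha: float = 0.14,
    convention: str = "literal",
) -> CSPTable:
    """CSPs of every trackable peak between the reference and one titration point.

    Peaks marked overlapped in either state are carried with their status
    and excluded from statistics downstream.
    """
    ref = series.reference
    bound_list = series.peak_lists[point]
    rows = []
    for key, free in sorted(ref.items()):
        bound = bound_list.get(key)
        if bound is None:
            continue
        unquantifiable = free.status != "ok" or bound.status != "ok"
        rows.append(
            {
                "position": free.position,
                "base": free.base,
                "correlation": free.correlation,
                "csp_ppm": np.nan
                if unquantifiable
                else compute_csp(free, bound, alpha=alpha, convention=convention),
                "status": "ok" if not unquantifiable else "overlapped",
            }
        )
    df = pd.DataFrame(rows)
    df["significant"] = False
    return CSPTable(table=df)


def flag_significant(table: CSPTable, rule: str = "mean+1sd") -> CSPTable:
    """Flag CSPs at or above mean + n·SD of the quantifiable values.

    With zero variance nothing is flagged (logged); fewer than 3
    quantifiable CSPs is an error because the statistic is meaningless.
    """
    m = re.fullmatch(r"mean\+([\d.]+)sd", rule.replace(" ", ""))
    if not m:
        raise ValueError(f"unknown significance rule {rule!r}")
    nsd = float(m.group(1))
    df = table.table.copy()
    ok = df["status"] == "ok"
    vals = df.loc[ok, "csp_ppm"].to_numpy(dtype=float)
    if vals.size < 3:
        raise ValueError("need at least 3 quantifiable CSPs to set a threshold")
    sd = float(np.std(vals, ddof=1))
    mean = float(np.mean(vals))
    threshold = mean + nsd * sd
    if sd <= 1e-12 * max(1.0, abs(mean)):  # identical CSPs up to float noise
        logger.info("all CSPs identical; nothing flagged")
        df["significant"] = False
    else:
        df["significant"] = ok & (df["csp_ppm"] >= threshold)
    return CSPTable(table=df, threshold_used=threshold, rule_name=rule)


# Approximate secondary-structure partition of the hairpin construct
# (positions 20-52): stem arms flanking two mismatches, a three-base-pair
# junction on either side of the apical loop, and the dicing-site bulge.
DEFAULT_REGION_MAP: dict[int, str] = {
    **{p: "stem" for p in range(20, 25)},
    25: "mismatch",
    **{p: "stem" for p in range(26, 30)},
    **{p: "junction" for p in range(30, 33)},
    **{p: "apical loop" for p in range(33, 40)},
    **{p: "junction" for p in range(40, 42)},
    **{p: "dicing-site bulge" for p in range(42, 45)},
    45: "mismatch",
    **{p: "stem" for p in range(46, 53)},
}


def load_region_map(path) -> dict[int, str]:
    """Read a ``position=region`` key-value text file."""
    out: dict[int, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        pos, region = line.split("=", 1)
        region = region.strip()
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r} for position {pos}")
        out[int(pos)] = region
    return out


@dataclass
class RegionSummary:
    counts: dict[str, int]
    residues: dict[str, list[str]]
    dominant: list[str]


def map_to_regions(
    flags: CSPTable | list[tuple[int, str]], regions: dict[int, str] | None = None
) -> RegionSummary:
    """Summarise flagged residues per secondary-structure region."""
    region_map = DEFAULT_REGION_MAP if regions is None else regions
    if isinstance(flags, CSPTable):
        flagged = [
            (int(r.position), f"{r.base}{r.position}")
            for r in flags.flagged().itertuples()
        ]
    else:
        flagged = [(pos, f"{base}{pos}") for pos, base in flags]
    counts: dict[str, int] = {}
    residues: dict[str, list[str]] = {}
    for pos, label in flagged:
        if pos not in region_map:
            raise KeyError(f"residue {label} has no region mapping")
        region = region_map[pos]
        counts[region] = counts.get(region, 0) + 1
        residues.setdefault(region, []).append(label)
    top = max(counts.values()) if counts else 0
    dominant = sorted(r for r, c in counts.items() if c == top) if counts else []
    return RegionSummary(counts=counts, residues=residues, dominant=dominant)


def fraction_bound(v_x: float, v_ref: float) -> float:
    """Fraction bound from free-peak volumes: B = 1 − V(X)/V(0), clipped to [0, 1]."""
    if v_ref <= 0:
        raise ValueError("reference peak volume must be positive")
    if v_x < 0:
        raise ValueError("peak volume must be non-negative")
    b = 1.0 - v_x / v_ref
    if not 0.0 <= b <= 1.0:
        logger.info("fraction bound %.4f outside [0,1]; clipping", b)
    return float(np.clip(b, 0.0, 1.0))


def _isotherm(x, bmax, kd):
    return bmax * x / (kd + x)


def _isotherm_ns_linear(x, bmax, kd, ns):
    return bmax * x / (kd + x) + ns * x


def _isotherm_ns_const(x, bmax, kd, ns):
    return bmax * x / (kd + x) + ns


class _IsothermFitterBase(BaseEstimator, RegressorMixin):
    """Shared lmfit plumbing for the one-site isotherm fitters."""

    _func = staticmethod(_isotherm)
    _param_names = ("bmax", "kd")

    def _initial(self, x, y):
        bmax0 = float(np.max(y)) if np.max(y) > 0 else 1.0
        half = bmax0 / 2.0
        pos = x > 0
        kd0 = float(x[pos][np.argmin(np.abs(y[pos] - half))]) if pos.any() else 1.0
        return {"bmax": max(bmax0, 1e-12), "kd": max(kd0, 1e-12), "ns": 0.0}

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.size != y.size:
            raise ValueError("X and y must have the same length")
        if np.unique(x).size < 4:
            raise ValueError("need at least 4 distinct concentrations")
        model = Model(self._func)
        init = self._initial(x, y)
        params = model.make_params()
        for name in self._param_names:
            params[name].set(value=init[name])
        params["kd"].set(min=1e-9)
        params["bmax"].set(min=0.0)
        result = model.fit(y, params, x=x, fit_kws={"ftol": 1e-12, "xtol": 1e-12})
        if not result.success:
            raise RuntimeError(f"isotherm fit did not converge: {result.message}")
        for name in self._param_names:
            setattr(self, f"{name}_", float(result.params[name].value))
            setattr(self, f"se_{name}_", float(result.params[name].stderr or 0.0))
        self.converged_ = bool(result.success)
        self.n_points_ = int(x.size)
        self.residual_rms_ = float(np.sqrt(np.mean(result.residual**2)))
        self.result_ = result
        self._post_fit(x, y)
        return self

    def _post_fit(self, x, y):  # pragma: no cover - overridden
        pass

    def predict(self, X):
        x = np.asarray(X, dtype=float)
        return self._func(x, *[getattr(self, f"{n}_") for n in self._param_names])


class FastExchangeFitter(_IsothermFitterBase):
    """Fast-exchange KD fitter: CSP(X) = Bmax·X/(KD + X).

    When the trajectory has not approached its plateau (max observed CSP
    below ``saturation_fraction``·Bmax) the fitted KD is only a lower
    bound; ``saturated_`` is False and ``kd_bound_`` records
    "> max tested concentration".
    """

    def __init__(self, saturation_fraction: float = 0.8):
        self.saturation_fraction = saturation_fraction

    def _post_fit(self, x, y):
        self.saturated_ = bool(np.max(y) >= self.saturation_fraction * self.bmax_)
        self.kd_bound_ = None if self.saturated_ else f"> {np.max(x):g}"


class IntermediateExchangeFitter(_IsothermFitterBase):
    """Intermediate-exchange KD fitter: B(X) = Bmax·X/(KD + X) + NS·X.

    NS is the slope of the linear nonspecific term (``ns_term="linear"``);
    a constant-offset reading is available via ``ns_term="constant"``.
    ``saturated_`` is set when the fitted specific fraction bound exceeds
    ``saturation_threshold`` within the sampled range.
    """

    _param_names = ("bmax", "kd", "ns")

    def __init__(self, ns_term: str = "linear", saturation_threshold: float = 0.95):
        if ns_term not in ("linear", "constant"):
            raise ValueError("ns_term must be 'linear' or 'constant'")
        self.ns_term = ns_term
        self.saturation_threshold = saturation_threshold

    @property
    def _func(self):
        return _isotherm_ns_linear if self.ns_term == "linear" else _isotherm_ns_const

    def _post_fit(self, x, y):
        specific = _isotherm(np.max(x), self.bmax_, self.kd_)
        self.saturated_ = bool(specific >= self.saturation_threshold)
        self.kd_bound_ = None if self.saturated_ else f"> {np.max(x):g}"


@dataclass
class ExchangeFit:
    """Fitted titration parameters for one exchange regime."""

    model: str  # fast_csp | intermediate_volume
    kd_uM: float
    se_kd: float
    bmax: float
    se_bmax: float
    ns: float
    se_ns: float
    saturated: bool
    converged: bool
    kd_display: str
    residual_rms: float
    n_points: int


def _resolve_residues(series: TitrationSeries, residues) -> list[tuple[int, str]]:
    keys = []
    for r in residues:
        if isinstance(r, str):
            m = re.fullmatch(r"([ACGU])?(\d+)[ /:]([\w-]+)", r.strip())
            if not m:
                raise ValueError(f"cannot parse residue spec {r!r}")
            keys.append((int(m.group(2)), m.group(3)))
        else:
            keys.append(tuple(r))
    for key in keys:
        if key not in series.reference:
            raise KeyError(f"residue {key} not in the reference peak list")
    return keys


def fit_intermediate(series: TitrationSeries, residues) -> ExchangeFit:
    """Fit pooled per-residue fraction-bound values to the Eq-with-NS isotherm.

    For each chosen residue the free-peak volume at every concentration is
    converted to B = 1 − V(X)/V(0); points are pooled across residues and
    fitted jointly.
    """
    keys = _resolve_residues(series, residues)
    concs = np.asarray(series.ligand_conc_uM, dtype=float)
    if concs.size < 4:
        raise ValueError("need at least 4 titration points")
    xs, bs = [], []
    for key in keys:
        v0 = series.reference[key].volume
        if v0 <= 0:
            raise ValueError(f"reference volume must be positive for {key}")
        for conc, plist in zip(concs, series.peak_lists):
            peak = plist.get(key)
            if peak is None or peak.status != "ok":
                continue
            xs.append(conc)
            bs.append(fraction_bound(peak.volume, v0))
    est = IntermediateExchangeFitter().fit(np.array(xs), np.array(bs))
    return ExchangeFit(
        model="intermediate_volume",
        kd_uM=est.kd_,
        se_kd=est.se_kd_,
        bmax=est.bmax_,
        se_bmax=est.se_bmax_,
        ns=est.ns_,
        se_ns=est.se_ns_,
        saturated=est.saturated_,
        converged=est.converged_,
        kd_display=est.kd_bound_ or f"{est.kd_:.2f}",
        residual_rms=est.residual_rms_,
        n_points=est.n_points_,
    )


def fit_fast(
    series: TitrationSeries, residues, alpha: float = 0.14, convention: str = "literal"
) -> ExchangeFit:
    """Fit pooled CSP trajectories to CSP(X) = Bmax·X/(KD + X).

    CSPs are computed against the 0 μM reference at every concentration;
    an unsaturated trajectory yields a lower-bound KD (kd_display of the
    form "> max tested").
    """
    keys = _resolve_residues(series, residues)
    concs = np.asarray(series.ligand_conc_uM, dtype=float)
    if concs.size < 4:
        raise ValueError("need at least 4 titration points")
    xs, ys = [], []
    for key in keys:
        free = series.reference[key]
        for conc, plist in zip(concs, series.peak_lists):
            peak = plist.get(key)
            if peak is None or peak.status != "ok" or free.status != "ok":
                continue
            xs.append(conc)
            ys.append(compute_csp(free, peak, alpha=alpha, convention=convention))
    est = FastExchangeFitter().fit(np.array(xs), np.array(ys))
    return ExchangeFit(
        model="fast_csp",
        kd_uM=est.kd_,
        se_kd=est.se_kd_,
        bmax=est.bmax_,
        se_bmax=est.se_bmax_,
        ns=0.0,
        se_ns=0.0,
        saturated=est.saturated_,
        converged=est.converged_,
        kd_display=est.kd_bound_ or f"{est.kd_:.2f}",
        residual_rms=est.residual_rms_,
        n_points=est.n_points_,
    )


def read_peaklist(path) -> PeakList:
    """Read one titration point's peak list.

    Accepts the CSV contract (header
    ``residue,base,correlation,ppm_h,ppm_c,volume,intensity,status``) or a
    whitespace-separated Sparky-style variant whose first column combines
    base and position (e.g. ``A40 C2-H2 7.53 141.2 1e6 5e5 ok``).
    """
    text = Path(path).read_text()
    first = text.splitlines()[0]
    peaks = []
    if "," in first:
        df = pd.read_csv(path, keep_default_na=False)
        missing = set(PEAKLIST_CSV_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"peak list missing columns: {sorted(missing)}")
        for r in df.itertuples():
            peaks.append(
                Peak2D(
                    position=int(r.residue),
                    base=str(r.base),
                    correlation=str(r.correlation),
                    d_h=float(r.ppm_h),
                    d_c=float(r.ppm_c),
                    volume=float(r.volume),
                    intensity=float(r.intensity),
                    status=str(r.status) or "ok",
                )
            )
    else:
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            m = re.fullmatch(r"([ACGU])(\d+)", parts[0])
            if not m:
                raise ValueError(f"cannot parse Sparky residue label {parts[0]!r}")
            peaks.append(
                Peak2D(
                    position=int(m.group(2)),
                    base=m.group(1),
                    correlation=parts[1],
                    d_h=float(parts[2]),
                    d_c=float(parts[3]),
                    volume=float(parts[4]),
                    intensity=float(parts[5]),
                    status=parts[6] if len(parts) > 6 else "ok",
                )
            )
    return build_peaklist(peaks)


def write_peaklist(path, peaks: PeakList) -> None:
    pd.DataFrame(
        [
            {
                "residue": p.position,
                "base": p.base,
                "correlation": p.correlation,
                "ppm_h": p.d_h,
                "ppm_c": p.d_c,
                "volume": p.volume,
                "intensity": p.intensity,
                "status": p.status,
            }
            for _, p in sorted(peaks.items())
        ]
    ).to_csv(path, index=False)


def read_titration_manifest(path, rna_conc_uM: float = float("nan")) -> TitrationSeries:
    """Read a manifest CSV ``ligand_conc_uM,peaklist_path`` (paths relative to the manifest)."""
    base = Path(path).parent
    df = pd.read_csv(path)
    if not {"ligand_conc_uM", "peaklist_path"} <= set(df.columns):
        raise ValueError("manifest needs columns ligand_conc_uM,peaklist_path")
    df = df.sort_values("ligand_conc_uM")
    lists = [read_peaklist(base / p) for p in df["peaklist_path"]]
    return TitrationSeries(
        ligand_conc_uM=df["ligand_conc_uM"].astype(float).tolist(),
        peak_lists=lists,
        rna_conc_uM=rna_conc_uM,
    )
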