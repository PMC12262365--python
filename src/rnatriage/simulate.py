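"""Synthetic-data generators for every pipeline stage.

Each generator produces data with the statistical structure its analysis
stage assumes: normally distributed docking scores with planted
low-score hits; one-site dye-binding fluorescence with competitive
displacement modelled through an apparent dye KD; Lorentzian 1D spectra
whose on-resonance amplitudes are attenuated for binders; and HSQC
titrations in fast exchange (peak positions interpolate with fraction
bound) or intermediate exchange (free-peak volumes decay with fraction
bound plus a linear nonspecific term). Noise is multiplicative Gaussian
for intensity-like quantities and additive for spectral baselines.

``make_screen_fixture`` assembles a 40-compound bundle whose planted
truths reproduce the headline classification outcomes of the pre-miR-31
screen it emulates: 22 STD-testable compounds of which 7 are binders,
4 indicator-displacement hits, and the control-well artefacts for the
dye-interacting and intrinsically fluorescent ligands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .docking import CompoundRecord, DockingScoreTable
from .fid import PlateWell
from .std import Spectrum1D

__all__ = [
    "simulate_docking_table",
    "PlateDesign",
    "LigandSpec",
    "simulate_fid_plate",
    "simulate_spectrum",
    "simulate_std_pair",
    "ResidueParams",
    "simulate_hsqc_titration",
    "ScreenFixture",
    "make_screen_fixture",
    "FIXTURE_ALIASES",
    "STD_BINDER_ALIASES",
    "FID_HIT_ALIASES",
    "FID_ENHANCER_ALIASES",
    "DYE_INTERACTOR_ALIASES",
    "INTRINSIC_FLUOROPHORE_ALIASES",
]


def simulate_docking_table(
    n: int,
    mean: float,
    sd: float,
    planted: list[tuple[str, float]] = (),
    seed: int = 0,
    target_id: str = "target",
    id_prefix: str = "CMPD",
) -> DockingScoreTable:
    """Normal(mean, sd) background scores plus planted compounds at mean + z·sd."""
    if n < 2:
        raise ValueError("need n >= 2 background compounds")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    ids = [pid for pid, _ in planted]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate planted compound ids")
    rng = np.random.default_rng(seed)
    rows = [
        (f"{id_prefix}{i:05d}", float(s), 25)
        for i, s in enumerate(rng.normal(mean, sd, size=n))
    ]
    rows += [(pid, mean + z * sd, 25) for pid, z in planted]
    return DockingScoreTable.from_records(target_id, rows)


@dataclass(frozen=True)
class PlateDesign:
    """Concentrations and layout of a screening plate."""

    rna_nM: float = 50.9
    dye_nM: float = 500.0
    ligand_uM: float = 100.0
    replicates: int = 2
    bmax_rfu: float = 1000.0
    dye_baseline_frac: float = 0.05  # free-dye fluorescence, as a fraction of Bmax
    rna_baseline_frac: float = 0.02  # RNA autofluorescence, as a fraction of Bmax


@dataclass(frozen=True)
class LigandSpec:
    """Planted truth for one ligand on a simulated plate.

    ``kd_uM`` None means no displacement; ``assay_add_frac`` adds
    fluorescence to the assay well (as a fraction of the blank F0), and
    the control-add fractions add to the dye+ligand / RNA+ligand control
    wells relative to their baselines.
    """

    compound_id: str
    kd_uM: float | None = None
    assay_add_frac: float = 0.0
    dye_control_add_frac: float = 0.0
    rna_control_add_frac: float = 0.0

    @classmethod
    def from_shorthand(cls, compound_id: str, spec) -> "LigandSpec":
        if isinstance(spec, (int, float)):
            return cls(compound_id, kd_uM=float(spec))
        if spec == "inert":
            return cls(compound_id)
        if spec == "enhancer":
            return cls(compound_id, assay_add_frac=0.4, rna_control_add_frac=0.5)
        if spec == "dye_binder":
            return cls(compound_id, assay_add_frac=0.4, dye_control_add_frac=0.5)
        raise ValueError(f"unknown ligand behavior {spec!r}")


def _displaced_fluorescence(design: PlateDesign, dye_kd_nM: float, kd_uM: float | None) -> float:
    """Blank and competitor fluorescence from the apparent-KD approximation.

    A competitor at concentration L raises the dye's apparent KD to
    KD·(1 + L/KD_L); no ternary depletion is solved.
    """
    kd_app = dye_kd_nM
    if kd_uM is not None:
        kd_app = dye_kd_nM * (1.0 + design.ligand_uM / kd_uM)
    return design.bmax_rfu * design.rna_nM / (kd_app + design.rna_nM)


def simulate_fid_plate(
    design: PlateDesign,
    dye_kd_nM: float,
    ligands: list,
    noise_sigma: float = 0.02,
    seed: int = 0,
) -> list[PlateWell]:
    """Simulate a full screening plate with blanks, controls and assay wells.

    ``ligands`` entries are LigandSpec objects or ``(id, kd_uM | behavior)``
    shorthands with behaviors in {inert, enhancer, dye_binder}.
    """
    rng = np.random.default_rng(seed)
    specs = [
        lg if isinstance(lg, LigandSpec) else LigandSpec.from_shorthand(*lg)
        for lg in ligands
    ]
    f0 = _displaced_fluorescence(design, dye_kd_nM, None)
    dye_base = design.dye_baseline_frac * design.bmax_rfu
    rna_base = design.rna_baseline_frac * design.bmax_rfu
    wells: list[PlateWell] = []
    n = 0

    def add(rna, dye, cid, lig, expected, rep):
        nonlocal n
        n += 1
        rfu = expected * (1.0 + rng.normal(0.0, noise_sigma))
        wells.append(
            PlateWell(
                well_id=f"W{n:03d}",
                rna_nM=rna,
                dye_nM=dye,
                compound_id=cid,
                ligand_uM=lig,
                rfu=rfu,
                replicate=rep,
            )
        )

    for rep in range(1, design.replicates + 1):
        add(design.rna_nM, design.dye_nM, None, 0.0, f0, rep)  # blank
        add(0.0, design.dye_nM, None, 0.0, dye_base, rep)  # dye only
        add(design.rna_nM, 0.0, None, 0.0, rna_base, rep)  # rna only
    for spec in specs:
        f_assay = _displaced_fluorescence(design, dye_kd_nM, spec.kd_uM)
        f_assay += spec.assay_add_frac * f0
        for rep in range(1, design.replicates + 1):
            add(design.rna_nM, design.dye_nM, spec.compound_id, design.ligand_uM, f_assay, rep)
            add(
                0.0,
                design.dye_nM,
                spec.compound_id,
                design.ligand_uM,
                dye_base * (1.0 + spec.dye_control_add_frac),
                rep,
            )
            add(
                design.rna_nM,
                0.0,
                spec.compound_id,
                design.ligand_uM,
                rna_base * (1.0 + spec.rna_control_add_frac),
                rep,
            )
    return wells


def _lorentzian(ppm: np.ndarray, center: float, amplitude: float, width: float) -> np.ndarray:
    return amplitude * width**2 / (width**2 + (ppm - center) ** 2)


def simulate_spectrum(
    peaks: list[tuple[float, float, float]],
    noise_sigma: float = 1.0,
    seed: int = 0,
    ppm_range: tuple[float, float] = (12.0, 0.0),
    n_points: int = 1201,
    meta: dict | None = None,
) -> Spectrum1D:
    """A plain 1D spectrum: Lorentzian mixture (center, amplitude, width) plus additive noise."""
    hi, lo = ppm_range
    ppm = np.linspace(hi, lo, n_points)
    for center, _, _ in peaks:
        if not lo <= center <= hi:
            raise ValueError(f"peak at {center} ppm outside axis range {ppm_range}")
    signal = np.zeros_like(ppm)
    for center, amp, width in peaks:
        signal += _lorentzian(ppm, center, amp, width)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sigma, size=ppm.size) if noise_sigma > 0 else 0.0
    m = {"resonance_role": "plain"}
    m.update(meta or {})
    return Spectrum1D(ppm=ppm, intensity=signal + noise, meta=m)


def simulate_std_pair(
    peaks: list[tuple[float, float, float]],
    binder: bool,
    attenuation: float = 0.2,
    noise_sigma: float = 1.0,
    seed: int = 0,
    on_irradiation_ppm: float = 4.9,
    **axis_kwargs,
) -> tuple[Spectrum1D, Spectrum1D]:
    """Off/on resonance spectrum pair for one compound.

    A binder's on-resonance amplitudes are scaled by (1 − attenuation);
    a non-binder's on-resonance spectrum carries the same signal with
    independent noise.
    """
    if not 0.0 < attenuation <= 1.0:
        raise ValueError("attenuation must be in (0, 1]")
    rng = np.random.default_rng(seed)
    off = simulate_spectrum(
        peaks,
        noise_sigma=noise_sigma,
        seed=int(rng.integers(2**31 - 1)),
        meta={"resonance_role": "off", "irradiation_ppm": -40.0},
        **axis_kwargs,
    )
    on_peaks = (
        [(c, a * (1.0 - attenuation), w) for c, a, w in peaks] if binder else peaks
    )
    on = simulate_spectrum(
        on_peaks,
        noise_sigma=noise_sigma,
        seed=int(rng.integers(2**31 - 1)),
        meta={"resonance_role": "on", "irradiation_ppm": on_irradiation_ppm},
        **axis_kwargs,
    )
    return off, on


@dataclass(frozen=True)
class ResidueParams:
    """Free-state peak parameters and bound-state endpoint shifts for one residue."""

    position: int
    base: str
    correlation: str
    d_h0: float
    d_c0: float
    delta_h: float = 0.0  # endpoint shift, ppm
    delta_c: float = 0.0
    v0: float = 1.0e6


def simulate_hsqc_titration(
    regime: str,
    residue_params: list[ResidueParams],
    kd_uM: float,
    concs: list[float],
    ns_per_uM: float = 0.0,
    bmax: float = 1.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    rna_conc_uM: float = 100.0,
):
    """Forward-model a titration series in one exchange regime.

    Fast exchange moves each peak by fb(X)·(endpoint shifts) with
    fb(X) = X/(KD+X); intermediate exchange keeps positions and scales
    free-peak volumes by 1 − [Bmax·X/(KD+X) + NS·X]. Multiplicative noise
    applies to volumes/intensities and, scaled by the endpoint shift, to
    peak positions. Negative noisy volumes are clipped at zero.
    """
    from .hsqc import Peak2D, TitrationSeries, build_peaklist

    if regime not in ("fast", "intermediate"):
        raise ValueError("regime must be 'fast' or 'intermediate'")
    concs = [float(c) for c in concs]
    rng = np.random.default_rng(seed)
    lists = []
    for x in concs:
        fb = x / (kd_uM + x)
        occupancy = bmax * fb + ns_per_uM * x
        peaks = []
        for rp in residue_params:
            if regime == "fast":
                dh = fb * rp.delta_h + rng.normal(0.0, noise_sigma * abs(rp.delta_h))
                dc = fb * rp.delta_c + rng.normal(0.0, noise_sigma * abs(rp.delta_c))
                vol = rp.v0 * (1.0 + rng.normal(0.0, noise_sigma))
                d_h, d_c = rp.d_h0 + dh, rp.d_c0 + dc
            else:
                d_h, d_c = rp.d_h0, rp.d_c0
                vol = rp.v0 * (1.0 - occupancy) * (1.0 + rng.normal(0.0, noise_sigma))
            if vol < 0:
                vol = 0.0
            peaks.append(
                Peak2D(
                    position=rp.position,
                    base=rp.base,
                    correlation=rp.correlation,
                    d_h=d_h,
                    d_c=d_c,
                    volume=vol,
                    intensity=vol,
                )
            )
        lists.append(build_peaklist(peaks))
    return TitrationSeries(ligand_conc_uM=concs, peak_lists=lists, rna_conc_uM=rna_conc_uM)


# ---------------------------------------------------------------------------
# The 40-compound screen fixture
# ---------------------------------------------------------------------------

FIXTURE_ALIASES: tuple[str, ...] = tuple(
    [f"A{i}" for i in range(1, 12)]
    + [f"B{i}" for i in range(1, 13)]
    + [f"C{i}" for i in range(1, 12)]
    + [f"RA{i}" for i in range(1, 5)]
    + ["DA1", "DA2"]
)

STD_BINDER_ALIASES = frozenset({"A1", "A5", "A9", "B7", "C4", "C6", "RA3"})
# No detectable 1H spectrum in aqueous buffer -> STD-untestable.
STD_UNTESTABLE_ALIASES = frozenset(
    {"C11", "DA1", "DA2", "A2", "A3", "A6", "B2", "B3", "B8", "B10", "B12",
     "C2", "C5", "C8", "C9", "C10", "RA1", "RA2"}
)
FID_HIT_ALIASES = frozenset({"DA1", "A1", "C11", "DA2"})
FID_ENHANCER_ALIASES = frozenset(
    {"A10", "A11", "B1", "B5", "B11", "C1", "C3", "C6", "C7", "RA1", "RA4"}
)
DYE_INTERACTOR_ALIASES = frozenset(
    {"A9", "A10", "A11", "B6", "B9", "B12", "C1", "C3", "C6", "C11"}
)
INTRINSIC_FLUOROPHORE_ALIASES = frozenset({"A10", "B12", "C1", "C3"})

# Back-derived dye calibration used for the plate design (fb 0.1 at 50.9 nM RNA).
FIXTURE_DYE_KD_NM = 458.1

_TABLE_SCORES = {"DA1": -19.893, "C4A": -26.043, "C4": -18.690, "A1": -21.117}


@dataclass
class ScreenFixture:
    """In-memory bundle of synthetic raw data for the 40-compound screen."""

    compounds: list[CompoundRecord]
    docking: DockingScoreTable
    # alias -> (plain, off, on); off/on are None for untestable compounds
    std_spectra: dict[str, tuple[Spectrum1D, Spectrum1D | None, Spectrum1D | None]]
    fid_wells: list[PlateWell]
    dye_kd_nM: float
    truths: dict = field(default_factory=dict)


def make_screen_fixture(seed: int = 0) -> ScreenFixture:
    """Build the deterministic 40-compound fixture.

    Planted truths: 22 STD-testable compounds of which exactly the 7
    known binders are attenuated on-resonance; 4 competitive
    displacement hits; 11 fluorescence enhancers; dye-interactor and
    intrinsic-fluorophore control artefacts for the flagged compounds.
    Effect sizes sit comfortably beyond every threshold so the
    classification outcome is seed-robust.
    """
    rng = np.random.default_rng(seed)
    compounds = [
        CompoundRecord(compound_id=f"LIB-{i + 1:04d}", alias=alias)
        for i, alias in enumerate(FIXTURE_ALIASES)
    ]

    # Docking scores: background plus the printed scores for aliased compounds.
    rows = []
    for c in compounds:
        score = _TABLE_SCORES.get(c.alias, float(rng.normal(-15.0, 2.0)))
        rows.append((c.alias, score, 25))
    docking = DockingScoreTable.from_records("pre-miR-31", rows)

    # STD stage: aromatic/aliphatic Lorentzian peaks, sigma 1, amplitude 100.
    std_spectra: dict[str, tuple] = {}
    for idx, c in enumerate(compounds):
        alias = c.alias
        sub = np.random.default_rng([seed, idx])
        if alias in STD_UNTESTABLE_ALIASES:
            plain = simulate_spectrum([], noise_sigma=1.0, seed=int(sub.integers(2**31 - 1)))
            std_spectra[alias] = (plain, None, None)
            continue
        centers = sorted(sub.uniform(6.0, 9.0, size=3))
        peaks = [(float(cpm), 100.0, 0.05) for cpm in centers]
        plain = simulate_spectrum(peaks, noise_sigma=1.0, seed=int(sub.integers(2**31 - 1)))
        off, on = simulate_std_pair(
            peaks,
            binder=alias in STD_BINDER_ALIASES,
            attenuation=0.3,
            noise_sigma=1.0,
            seed=int(sub.integers(2**31 - 1)),
        )
        std_spectra[alias] = (plain, off, on)

    # FID stage: competitive hits at KD_L = 100 uM (~47% displacement at the
    # fb 0.1 design point), enhancers at +40% of F0, control artefacts +50%.
    specs = []
    for c in compounds:
        alias = c.alias
        specs.append(
            LigandSpec(
                compound_id=alias,
                kd_uM=100.0 if alias in FID_HIT_ALIASES else None,
                assay_add_frac=0.4 if alias in FID_ENHANCER_ALIASES else 0.0,
                dye_control_add_frac=0.5 if alias in DYE_INTERACTOR_ALIASES else 0.0,
                rna_control_add_frac=0.5 if alias in INTRINSIC_FLUOROPHORE_ALIASES else 0.0,
            )
        )
    fid_wells = simulate_fid_plate(
        PlateDesign(),
        dye_kd_nM=FIXTURE_DYE_KD_NM,
        ligands=specs,
        noise_sigma=0.02,
        seed=int(rng.integers(2**31 - 1)),
    )

    truths = {
        "std_testable": sorted(set(FIXTURE_ALIASES) - STD_UNTESTABLE_ALIASES),
        "std_binders": sorted(STD_BINDER_ALIASES),
        "fid_hits": sorted(FID_HIT_ALIASES),
        "fid_enhancers": sorted(FID_ENHANCER_ALIASES),
        "dye_interactors": sorted(DYE_INTERACTOR_ALIASES),
        "intrinsic_fluorophores": sorted(INTRINSIC_FLUOROPHORE_ALIASES),
    }
    return ScreenFixture(
        compounds=compounds,
        docking=docking,
        std_spectra=std_spectra,
        fid_wells=fid_wells,
        dye_kd_nM=FIXTURE_DYE_KD_NM,
        truths=truths,
    )
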