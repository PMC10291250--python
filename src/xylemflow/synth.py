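"""Synthetic-study generator.

Emulates the sampling design of the field study the pipeline targets:
14 species (5 drought-deciduous angiosperms, 8 evergreen angiosperms, one
gymnosperm) × 6 trees, with per tree 2 coarse-root and 3 branch flow/density
segments, anatomy sectors on trees 1-3, and stem cores — emitting CSV-ready
tables that every analysis module ingests with zero schema friction, plus
the full ground truth for recovery tests.

Calibration
-----------
All habit×organ defaults are solved from the published group values rather
than set free-hand:

* Within-sector conduit diameters are lognormal.  For each angiosperm
  habit×organ cell the printed triple (D_h, CD, F) pins down the lognormal
  median m and log-SD σ_w exactly:  D_h = m·e^{4.5σ_w²} and
  F = CD·(π/4)·m²·e^{2σ_w²}  give  σ_w² = ln(CD·(π/4)·D_h²/F)/7.
  The gymnosperm cell is under-determined and uses geometric SD 1.35.
* Species- and tree-level lognormal diameter multipliers u (mean 1) carry
  the between-unit heterogeneity.  Conduit density co-varies as u^{-1/2}
  ("narrower conduits partially compensated by higher densities"), with a
  normaliser exp(-0.375σ²) per level so that the group means of D_h, CD
  and F are all preserved exactly while ΣD⁴ gains a Jensen factor
  e^{4σ²} per level.  The total factor is solved so that the group means
  of KS_pot reproduce the published KS_hydr group means (root 9.5,
  branch 2.3 kg m⁻¹ MPa⁻¹ s⁻¹) at the fixed flow ratio r = 0.25.
* The cross-organ correlation ρ of the multipliers is solved so that the
  expected tree-wise mean root:branch ratio of KS_hydr equals the
  published deciduous value 5.1 (a mean of ratios, which heterogeneity
  pushes above the ratio of means).

Everything else (flow noise, wood-density coupling to lumen fraction,
Huber-value targets, tree heights) follows the published per-group values;
see the package methods note for the full derivation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .anatomy import ConduitSet, WATER_20C
from .flow import G_PER_H_TO_KG_PER_S, SegmentGeometry, xylem_area
from .density import core_volume, segment_volume

__all__ = [
    "SpeciesSpec",
    "StudyConfig",
    "SyntheticStudy",
    "default_config",
    "generate_conduits",
    "generate_flow",
    "generate_study",
    "lognormal_from_traits",
]

log = logging.getLogger(__name__)

_HP_CONST = math.pi * WATER_20C.rho / (128.0 * WATER_20C.eta)  # SI, per m² reference


# ---------------------------------------------------------------------------
# species roster (leaf habit and tree height per the study's Table-1 design)

@dataclass(frozen=True)
class SpeciesSpec:
    name: str
    habit: str  # deciduous | evergreen | gymnosperm
    height_m: float
    height_sd: float


DEFAULT_SPECIES: Tuple[SpeciesSpec, ...] = (
    SpeciesSpec("Albizia schimperiana", "deciduous", 10, 2.5),
    SpeciesSpec("Bridelia micrantha", "deciduous", 8, 0.9),
    SpeciesSpec("Combretum molle", "deciduous", 6, 1.1),
    SpeciesSpec("Croton macrostachyus", "deciduous", 11, 4.5),
    SpeciesSpec("Schefflera abyssinica", "deciduous", 16, 3.6),
    SpeciesSpec("Apodytes dimidiata", "evergreen", 16, 3.1),
    SpeciesSpec("Calpurnia aurea", "evergreen", 8, 1.7),
    SpeciesSpec("Chionanthus mildbraedii", "evergreen", 12, 6.5),
    SpeciesSpec("Dovyalis abyssinica", "evergreen", 7, 0.7),
    SpeciesSpec("Ekebergia capensis", "evergreen", 12, 2.5),
    SpeciesSpec("Maesa lanceolata", "evergreen", 6, 1.8),
    SpeciesSpec("Prunus africana", "evergreen", 10, 4.1),
    SpeciesSpec("Teclea nobilis", "evergreen", 7, 0.9),
    SpeciesSpec("Afrocarpus falcatus", "gymnosperm", 13, 2.9),
)


# ---------------------------------------------------------------------------
# habit×organ anatomical targets (published group means; the two branch CD/F
# cells follow from the published organ and habit contrasts)

_ANATOMY_TARGETS: Dict[Tuple[str, str], dict] = {
    ("deciduous", "root"): dict(dh_um=68.0, cd_mm2=80.0, f_pct=21.0),
    ("evergreen", "root"): dict(dh_um=57.0, cd_mm2=139.0, f_pct=22.0),
    ("deciduous", "branch"): dict(dh_um=45.5, cd_mm2=126.0, f_pct=13.6),
    ("evergreen", "branch"): dict(dh_um=34.5, cd_mm2=168.0, f_pct=11.5),
    # gymnosperm tracheids: high-CD / small-D_h outlier only
    ("gymnosperm", "root"): dict(cd_mm2=947.0, f_pct=25.0, gsd=1.35),
    ("gymnosperm", "branch"): dict(dh_um=11.1, f_pct=26.2, gsd=1.35),
}

#: published group-mean measured conductivities, kg m^-1 MPa^-1 s^-1
_KSHYDR_TARGET = {"root": 9.5, "branch": 2.3}
#: published tree-wise mean root:branch ratio of KS_hydr, deciduous species
_RB_KSHYDR_DECIDUOUS = 5.1

#: wood-density group means (g cm^-3) at the habit-mean lumen fraction
_WD_INTERCEPT = {
    ("deciduous", "root"): 0.48,
    ("evergreen", "root"): 0.57,
    ("gymnosperm", "root"): 0.42,
    ("deciduous", "branch"): 0.63,
    ("evergreen", "branch"): 0.66,
    ("gymnosperm", "branch"): 0.48,
}
_WD_STEM_OFFSET = {"deciduous": 0.04, "evergreen": 0.09, "gymnosperm": 0.04}

#: Huber-value group means, m² m^-2
_HV_TARGET = {"deciduous": 26.4e-4, "evergreen": 13.9e-4, "gymnosperm": 0.696e-4}

#: debarked segment outer diameter, mm (mean, SD)
_SEGMENT_DIAMETER = {
    ("deciduous", "root"): (3.82, 0.62),
    ("evergreen", "root"): (4.10, 0.44),
    ("gymnosperm", "root"): (4.00, 0.40),
    ("deciduous", "branch"): (4.90, 0.50),
    ("evergreen", "branch"): (4.90, 0.50),
    ("gymnosperm", "branch"): (4.90, 0.50),
}


def lognormal_from_traits(
    dh_um: Optional[float] = None,
    cd_mm2: Optional[float] = None,
    f_pct: Optional[float] = None,
    gsd: Optional[float] = None,
) -> Tuple[float, float, float]:
    """Solve (median µm, log-SD, CD mm^-2) of the within-sector lognormal.

    With all of D_h, CD and F given, the geometric SD is identified:
    σ_w² = ln(CD·(π/4)·D_h² / F) / 7.  With a fixed gsd, the missing one
    of D_h/CD is derived from F instead.
    """
    if dh_um and cd_mm2 and f_pct:
        cd_um2 = cd_mm2 * 1e-6
        ratio = cd_um2 * math.pi / 4.0 * dh_um**2 / (f_pct / 100.0)
        if ratio <= 1.0:
            raise ValueError("infeasible D_h/CD/F combination (would need gsd < 1)")
        s2 = math.log(ratio) / 7.0
        return dh_um * math.exp(-4.5 * s2), math.sqrt(s2), cd_mm2
    if gsd is None:
        raise ValueError("under-determined cell needs an explicit gsd")
    s = math.log(gsd)
    s2 = s * s
    if cd_mm2 and f_pct and not dh_um:
        cd_um2 = cd_mm2 * 1e-6
        m = math.sqrt((f_pct / 100.0) / (cd_um2 * math.pi / 4.0 * math.exp(2 * s2)))
        return m, s, cd_mm2
    if dh_um and f_pct and not cd_mm2:
        m = dh_um * math.exp(-4.5 * s2)
        cd_um2 = (f_pct / 100.0) / (math.pi / 4.0 * m**2 * math.exp(2 * s2))
        return m, s, cd_um2 * 1e6
    raise ValueError("need (dh, cd, f) or two of them plus gsd")


def _base_kspot(median_um: float, sigma_w: float, cd_mm2: float) -> float:
    """Expected Hagen-Poiseuille KS_pot (kg m^-1 MPa^-1 s^-1) of the cell."""
    m = median_um * 1e-6
    e_d4 = m**4 * math.exp(8.0 * sigma_w**2)
    cd_m2 = cd_mm2 * 1e6
    return _HP_CONST * cd_m2 * e_d4


@dataclass
class StudyConfig:
    """All tunable parameters of the synthetic study.

    The defaults are the calibrated study conditions; the derived fields
    (``anatomy``, ``sigma_species``, ``rho_organ``) are recomputed in
    ``__post_init__`` from the published targets.
    """

    seed: int = 0
    species: Tuple[SpeciesSpec, ...] = DEFAULT_SPECIES
    n_trees: int = 6
    n_root_samples: int = 2
    n_branch_samples: int = 3
    n_anatomy_trees: int = 3

    # flow spec
    flow_ratio: float = 0.25  # r = KS_hydr / KS_pot
    flow_noise_sd: float = 0.25  # lognormal log-SD per flow sample
    plugging_range: Tuple[float, float] = (0.3, 1.0)  # initial / plateau
    pressure_kpa: Dict[str, float] = field(
        default_factory=lambda: {"root": 1.0, "branch": 2.0}
    )
    segment_length_m: Dict[str, float] = field(
        default_factory=lambda: {"root": 0.10, "branch": 0.05}
    )

    # sector spec
    sector_angle_range: Tuple[float, float] = (20.0, 70.0)  # degrees
    conduits_per_sector_median: float = 52.0
    conduits_per_sector_log_sd: float = 0.40

    # heterogeneity: tree-level diameter-multiplier log-variance is fixed;
    # the species-level share and the cross-organ correlation are solved in
    # __post_init__ from the published KS_hydr means and deciduous R:B.
    sigma_tree_sq: float = 0.10
    cd_coupling_exponent: float = 0.5  # CD ~ u^-gamma

    # wood density spec
    wd_slope_per_f_pct: Dict[str, float] = field(
        default_factory=lambda: {"root": 0.0066, "branch": 0.0025}
    )
    wd_species_noise: Dict[str, float] = field(
        default_factory=lambda: {"root": 0.05, "branch": 0.045, "stem": 0.035}
    )
    wd_tree_noise: float = 0.03
    wd_sample_noise: float = 0.02

    # leaf area spec
    hv_log_sd: float = 0.262  # gsd ~ 1.3

    # design quirks exercised downstream
    discard_root_flow_species: str = "Albizia schimperiana"
    no_stem_core_species: str = "Teclea nobilis"

    # derived calibration (filled in __post_init__)
    anatomy: Dict[Tuple[str, str], Tuple[float, float, float]] = field(init=False)
    sigma_species_sq: float = field(init=False)
    rho_organ: float = field(init=False)

    def __post_init__(self) -> None:
        self.anatomy = {
            key: lognormal_from_traits(**targets)
            for key, targets in _ANATOMY_TARGETS.items()
        }
        # angiosperm-mean base KS_pot per organ (5 deciduous, 8 evergreen)
        base = {}
        for organ in ("root", "branch"):
            b_dec = _base_kspot(*self.anatomy[("deciduous", organ)])
            b_eve = _base_kspot(*self.anatomy[("evergreen", organ)])
            base[organ] = (5 * b_dec + 8 * b_eve) / 13.0
        # Jensen factor so that r * E[KS_pot] hits the published KS_hydr means
        j = math.sqrt(
            (_KSHYDR_TARGET["root"] / (self.flow_ratio * base["root"]))
            * (_KSHYDR_TARGET["branch"] / (self.flow_ratio * base["branch"]))
        )
        if j <= 1.0:
            raise ValueError("published means need no heterogeneity; check targets")
        total_sq = math.log(j) / 4.0
        if total_sq <= self.sigma_tree_sq:
            raise ValueError("sigma_tree_sq exceeds the total calibrated variance")
        self.sigma_species_sq = total_sq - self.sigma_tree_sq
        # cross-organ correlation from the deciduous tree-wise R:B target
        r0_dec = _base_kspot(*self.anatomy[("deciduous", "root")]) / _base_kspot(
            *self.anatomy[("deciduous", "branch")]
        )
        noise_corr = math.exp(self.flow_noise_sd**2 / self.n_branch_samples)
        needed = math.log(_RB_KSHYDR_DECIDUOUS / (r0_dec * noise_corr))
        self.rho_organ = 1.0 - needed / (12.25 * total_sq)
        if not (0.0 < self.rho_organ < 1.0):
            raise ValueError("R:B calibration produced an invalid correlation")
        for key, (m, s, cd) in self.anatomy.items():
            f = cd * 1e-6 * math.pi / 4.0 * (m**2) * math.exp(2 * s * s)
            if f >= 1.0:
                raise ValueError(f"infeasible CD×diameter combination for {key}")

    @property
    def sigma_species(self) -> float:
        return math.sqrt(self.sigma_species_sq)

    @property
    def sigma_tree(self) -> float:
        return math.sqrt(self.sigma_tree_sq)


def default_config(seed: int = 0, **overrides) -> StudyConfig:
    return StudyConfig(seed=seed, **overrides)


# ---------------------------------------------------------------------------
# random-effect helpers

def _bivariate_logeffects(rng: np.random.Generator, sigma_sq: float, rho: float):
    """Correlated per-organ multipliers (root, branch), each mean 1."""
    z = rng.standard_normal(2)
    z_b = rho * z[0] + math.sqrt(max(0.0, 1 - rho * rho)) * z[1]
    s = math.sqrt(sigma_sq)
    return (
        math.exp(s * z[0] - sigma_sq / 2.0),
        math.exp(s * z_b - sigma_sq / 2.0),
    )


def _cell_params(
    config: StudyConfig, habit: str, organ: str, u_sp: float, u_tr: float
) -> Tuple[float, float, float]:
    """Effective (median µm, sigma_w, CD mm^-2) for one tree×organ.

    Diameter median scales with u; conduit density with u^-γ times the
    per-level normaliser exp(-γ(γ+1)/2·σ²) that keeps E[CD] at the target.
    """
    m0, s_w, cd0 = config.anatomy[(habit, organ)]
    g = config.cd_coupling_exponent
    norm = math.exp(-g * (g + 1) / 2.0 * config.sigma_species_sq) * math.exp(
        -g * (g + 1) / 2.0 * config.sigma_tree_sq
    )
    u = u_sp * u_tr
    m = m0 * u
    cd = cd0 * u ** (-g) * norm
    # physical guard: a cell cannot exceed ~92% lumen; the far upper tail of
    # the diameter multiplier is accommodated by thinning its density
    f = cd * 1e-6 * math.pi / 4.0 * m**2 * math.exp(2 * s_w * s_w)
    if f > 0.92:
        cd *= 0.92 / f
    return m, s_w, cd


def _expected_kspot(median_um: float, sigma_w: float, cd_mm2: float) -> float:
    return _base_kspot(median_um, sigma_w, cd_mm2)


# ---------------------------------------------------------------------------
# generators

def _draw_sector(
    config: StudyConfig,
    rng: np.random.Generator,
    sample_id: str,
    organ: str,
    median_um: float,
    sigma_w: float,
    cd_mm2: float,
    max_tries: int = 50,
) -> ConduitSet:
    """One measured sector: area from the target count and CD, Poisson count,
    lognormal diameters.

    The drawn lumina are never rejected (rejection would truncate the ΣD⁴
    tail and bias KS_pot); in the rare cell whose drawn lumina exceed 90 %
    of the nominal sector area, the sector is enlarged to fit them, which
    only lowers that sector's apparent density.
    """
    f_analytic = (
        cd_mm2 * 1e-6 * math.pi / 4.0 * median_um**2 * math.exp(2 * sigma_w**2)
    )
    if f_analytic >= 1.0:
        raise ValueError(
            f"infeasible CD×diameter combination for {sample_id} (F ≥ 100%)"
        )
    lo, hi = config.sector_angle_range
    angle = rng.uniform(lo, hi)
    n_expect = config.conduits_per_sector_median * math.exp(
        config.conduits_per_sector_log_sd * rng.standard_normal()
    )
    n_expect = max(n_expect, 10.0)
    cd_um2 = cd_mm2 * 1e-6
    area_um2 = n_expect / cd_um2
    n = 0
    for _ in range(max_tries):
        n = rng.poisson(n_expect)
        if n >= 1:
            break
    n = max(n, 1)
    d = median_um * np.exp(sigma_w * rng.standard_normal(n))
    lumen = math.pi / 4.0 * d**2
    if lumen.sum() > 0.90 * area_um2:
        log.warning("sector %s enlarged to fit drawn lumina (F near 90%%)", sample_id)
        area_um2 = lumen.sum() / 0.90
    return ConduitSet(
        sample_id=sample_id,
        organ=organ,
        sector_angle=float(angle),
        sector_area=float(area_um2),
        lumen_areas=lumen,
        from_diameters=True,
    )


def generate_conduits(
    config: StudyConfig, species: str, organ: str, seed: int
) -> ConduitSet:
    """One standalone sector for a species of the roster (fresh species- and
    tree-level effects each call; use generate_study for a coherent study)."""
    spec = next(s for s in config.species if s.name == species)
    rng = np.random.default_rng(seed)
    u_sp = _bivariate_logeffects(rng, config.sigma_species_sq, config.rho_organ)
    u_tr = _bivariate_logeffects(rng, config.sigma_tree_sq, config.rho_organ)
    idx = 0 if organ == "root" else 1
    m, s_w, cd = _cell_params(config, spec.habit, organ, u_sp[idx], u_tr[idx])
    return _draw_sector(config, rng, f"{species}-single-{organ}", organ, m, s_w, cd)


def _flush_stage_factors(rng: np.random.Generator) -> List[float]:
    """Monotone approach to the plateau; the last increment is < 2 % so the
    plateau value itself is selected as k_max."""
    if rng.random() < 0.5:
        return [0.90, 0.97, 0.995, 1.0]
    return [0.95, 0.995, 1.0]


def generate_flow(
    config: StudyConfig,
    rng: np.random.Generator,
    sample_id: str,
    organ: str,
    geometry: SegmentGeometry,
    kspot_tree: float,
) -> Tuple[List[dict], float]:
    """Flow records for one segment; returns (records, true KS_hydr).

    The plateau flow inverts the axial-conductivity equation for
    K_h = r · KS_pot(tree) · A_xylem with multiplicative lognormal noise;
    the initial (pre-flush) stage is the plateau times a plugging factor.
    """
    nu = config.flow_noise_sd
    ks_true = (
        config.flow_ratio
        * kspot_tree
        * math.exp(nu * rng.standard_normal() - nu * nu / 2.0)
    )
    area = xylem_area(geometry)
    k_h = ks_true * area
    dp_kpa = config.pressure_kpa[organ]
    plateau_gh = k_h * (dp_kpa * 1e-3) / geometry.length / G_PER_H_TO_KG_PER_S
    plug = rng.uniform(*config.plugging_range)
    records = [
        dict(
            sample_id=sample_id,
            stage="initial",
            pressure_kPa=dp_kpa,
            flow_g_per_h=plug * plateau_gh,
        )
    ]
    for i, f in enumerate(_flush_stage_factors(rng), start=1):
        records.append(
            dict(
                sample_id=sample_id,
                stage=f"flush_{i}",
                pressure_kPa=dp_kpa,
                flow_g_per_h=f * plateau_gh,
            )
        )
    return records, ks_true


def _segment_geometry(
    config: StudyConfig,
    rng: np.random.Generator,
    sample_id: str,
    habit: str,
    organ: str,
) -> SegmentGeometry:
    mean_d, sd_d = _SEGMENT_DIAMETER[(habit, organ)]
    d = max(rng.normal(mean_d, sd_d), 2.0)
    ecc = rng.uniform(0.0, 0.05)
    taper = 1.0 + rng.normal(0.0, 0.03)
    pith = None
    if organ == "branch":
        pith = float(np.clip(rng.normal(1.0, 0.15), 0.5, 0.45 * d))
    return SegmentGeometry(
        sample_id=sample_id,
        organ=organ,
        length=config.segment_length_m[organ],
        end1_d1=d * (1 + ecc),
        end1_d2=d * (1 - ecc),
        end2_d1=d * taper * (1 + ecc),
        end2_d2=d * taper * (1 - ecc),
        pith_d1=pith,
        pith_d2=pith,
    )


@dataclass
class SyntheticStudy:
    """Complete generated study: emitted tables plus retained ground truth."""

    config: StudyConfig
    trees: pd.DataFrame  # species, tree_id, leaf_habit, height_m
    conduits: pd.DataFrame  # one row per conduit
    flow: pd.DataFrame  # one row per flow record
    segments: pd.DataFrame  # geometry + dry mass per segment / core
    leaf_areas: pd.DataFrame  # sample_id, leaf_area_m2
    ground_truth: pd.DataFrame  # per tree×organ true parameters

    def tables(self) -> Dict[str, pd.DataFrame]:
        return {
            "trees": self.trees,
            "conduits": self.conduits,
            "flow": self.flow,
            "segments": self.segments,
            "leaf_areas": self.leaf_areas,
            "ground_truth": self.ground_truth,
        }


def generate_study(config: StudyConfig) -> SyntheticStudy:
    """Generate the full study deterministically from ``config.seed``."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    fbar = {
        (h, o): cd * 1e-6 * math.pi / 4 * m**2 * math.exp(2 * s * s) * 100.0
        for (h, o), (m, s, cd) in config.anatomy.items()
    }

    tree_rows, conduit_rows, flow_rows = [], [], []
    segment_rows, leaf_rows, truth_rows = [], [], []

    for spec in config.species:
        u_sp = _bivariate_logeffects(rng, config.sigma_species_sq, config.rho_organ)
        # species-level lumen fraction (analytic, %) drives the WD trade-off
        wd_species = {}
        for idx, organ in enumerate(("root", "branch")):
            m, s_w, cd = _cell_params(config, spec.habit, organ, u_sp[idx], 1.0)
            f_sp = cd * 1e-6 * math.pi / 4 * m**2 * math.exp(2 * s_w**2) * 100.0
            wd_species[organ] = (
                _WD_INTERCEPT[(spec.habit, organ)]
                - config.wd_slope_per_f_pct[organ]
                * (f_sp - fbar[(spec.habit, organ)])
                + rng.normal(0.0, config.wd_species_noise[organ])
            )
        wd_species["stem"] = (
            wd_species["root"]
            + _WD_STEM_OFFSET[spec.habit]
            + rng.normal(0.0, config.wd_species_noise["stem"])
        )

        core_trees = set()
        if spec.name != config.no_stem_core_species:
            lo = min(3, config.n_trees)
            n_cores = int(rng.integers(lo, config.n_trees + 1))
            core_trees = set(
                rng.choice(config.n_trees, size=n_cores, replace=False) + 1
            )

        for t in range(1, config.n_trees + 1):
            height = max(float(rng.normal(spec.height_m, spec.height_sd)), 2.0)
            tree_rows.append(
                dict(
                    species=spec.name,
                    tree_id=t,
                    leaf_habit=spec.habit,
                    height_m=height,
                )
            )
            u_tr = _bivariate_logeffects(
                rng, config.sigma_tree_sq, config.rho_organ
            )
            wd_tree = {
                k: wd_species[k] + rng.normal(0.0, config.wd_tree_noise)
                for k in wd_species
            }

            for idx, organ in enumerate(("root", "branch")):
                m, s_w, cd = _cell_params(
                    config, spec.habit, organ, u_sp[idx], u_tr[idx]
                )
                kspot_tree = _expected_kspot(m, s_w, cd)
                truth_rows.append(
                    dict(
                        species=spec.name,
                        tree_id=t,
                        organ=organ,
                        leaf_habit=spec.habit,
                        median_um=m,
                        sigma_w=s_w,
                        cd_mm2=cd,
                        kspot_tree=kspot_tree,
                        kshydr_tree=config.flow_ratio * kspot_tree,
                        wd_tree=wd_tree[organ],
                        height_m=height,
                    )
                )

                # anatomy sector (trees 1..n_anatomy_trees)
                if t <= config.n_anatomy_trees:
                    sid = f"{spec.name}|T{t}|{organ}|anat"
                    sector = _draw_sector(config, rng, sid, organ, m, s_w, cd)
                    for a in sector.lumen_areas:
                        conduit_rows.append(
                            dict(
                                sample_id=sid,
                                species=spec.name,
                                tree_id=t,
                                organ=organ,
                                leaf_habit=spec.habit,
                                sector_angle_deg=sector.sector_angle,
                                sector_area_um2=sector.sector_area,
                                lumen_area_um2=float(a),
                            )
                        )

                # flow + density segments
                n_samples = (
                    config.n_root_samples if organ == "root" else config.n_branch_samples
                )
                for k in range(1, n_samples + 1):
                    sid = f"{spec.name}|T{t}|{organ}|{k}"
                    geom = _segment_geometry(config, rng, sid, spec.habit, organ)
                    discard_flow = (
                        organ == "root"
                        and spec.name == config.discard_root_flow_species
                    )
                    records, ks_true = generate_flow(
                        config, rng, sid, organ, geom, kspot_tree
                    )
                    if not discard_flow:
                        for r in records:
                            flow_rows.append(
                                dict(
                                    species=spec.name,
                                    tree_id=t,
                                    organ=organ,
                                    leaf_habit=spec.habit,
                                    **r,
                                )
                            )
                    wd_sample = wd_tree[organ] + rng.normal(
                        0.0, config.wd_sample_noise
                    )
                    geom.dry_mass = wd_sample * segment_volume(geom)
                    segment_rows.append(
                        dict(
                            sample_id=sid,
                            species=spec.name,
                            tree_id=t,
                            organ=organ,
                            leaf_habit=spec.habit,
                            length_m=geom.length,
                            end1_d1_mm=geom.end1_d1,
                            end1_d2_mm=geom.end1_d2,
                            end2_d1_mm=geom.end2_d1,
                            end2_d2_mm=geom.end2_d2,
                            pith_d1_mm=geom.pith_d1,
                            pith_d2_mm=geom.pith_d2,
                            dry_mass_g=geom.dry_mass,
                            core_length_mm=None,
                        )
                    )
                    if organ == "branch":
                        area = xylem_area(geom)
                        leaf = (
                            area
                            / _HV_TARGET[spec.habit]
                            * math.exp(
                                config.hv_log_sd * rng.standard_normal()
                                + config.hv_log_sd**2 / 2.0
                            )
                        )
                        leaf_rows.append(dict(sample_id=sid, leaf_area_m2=leaf))

            # stem core
            if t in core_trees:
                sid = f"{spec.name}|T{t}|stem_core|1"
                core_len = float(rng.uniform(30.0, 80.0))
                wd_sample = wd_tree["stem"] + rng.normal(0.0, config.wd_sample_noise)
                segment_rows.append(
                    dict(
                        sample_id=sid,
                        species=spec.name,
                        tree_id=t,
                        organ="stem_core",
                        leaf_habit=spec.habit,
                        length_m=core_len * 1e-3,
                        end1_d1_mm=None,
                        end1_d2_mm=None,
                        end2_d1_mm=None,
                        end2_d2_mm=None,
                        pith_d1_mm=None,
                        pith_d2_mm=None,
                        dry_mass_g=wd_sample * core_volume(core_len),
                        core_length_mm=core_len,
                    )
                )

    return SyntheticStudy(
        config=config,
        trees=pd.DataFrame(tree_rows),
        conduits=pd.DataFrame(conduit_rows),
        flow=pd.DataFrame(flow_rows),
        segments=pd.DataFrame(segment_rows),
        leaf_areas=pd.DataFrame(leaf_rows),
        ground_truth=pd.DataFrame(truth_rows),
    )
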