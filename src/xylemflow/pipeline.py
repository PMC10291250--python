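"""End-to-end analysis: CSV bundle → trait tables → comparison tables.

The bundle layout is the one ``synth.generate_study`` emits (and that real
measurement campaigns can be coerced into): ``trees``, ``conduits``,
``flow``, ``segments``, ``leaf_areas`` tables.  The report mirrors the
standard presentation of such studies: per-trait leaf-habit contrasts
(deciduous − evergreen on species means), organ contrasts (root − branch),
a wood-density summary with Tukey letters, root-to-branch ratios, a
species-mean Pearson correlation matrix and the tree-height models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

from . import anatomy as _anatomy
from . import density as _density
from . import flow as _flow
from . import stats as _stats

__all__ = [
    "anatomy_table",
    "flow_table",
    "density_table",
    "trait_table",
    "habit_contrast_table",
    "organ_contrast_table",
    "rb_ratio_table",
    "wood_density_summary",
    "correlation_table",
    "height_model_table",
    "analyze",
]

log = logging.getLogger(__name__)

#: traits compared between organs (root − branch) in the organ table
ORGAN_TRAITS = ["Dh_um", "CD_mm2", "F_pct", "KS_pot", "KS_hydr", "WD"]


def anatomy_table(conduits: pd.DataFrame, dh_method: str = "d5_over_d4") -> pd.DataFrame:
    """Per-sector anatomical traits from the long per-conduit table."""
    rows = []
    meta_cols = [c for c in ("species", "tree_id", "organ", "leaf_habit") if c in conduits]
    for sid, grp in conduits.groupby("sample_id", sort=True):
        cs = _anatomy.ConduitSet(
            sample_id=str(sid),
            organ=str(grp["organ"].iloc[0]),
            sector_angle=float(grp["sector_angle_deg"].iloc[0]),
            sector_area=float(grp["sector_area_um2"].iloc[0]),
            lumen_areas=grp["lumen_area_um2"].to_numpy(),
        )
        tr = _anatomy.anatomy_traits(cs, dh_method=dh_method)
        row = {c: grp[c].iloc[0] for c in meta_cols}
        rows.append(
            dict(
                sample_id=sid,
                **row,
                n_conduits=tr.n_conduits,
                CD_mm2=tr.CD,
                F_pct=tr.F,
                Dmean_um=tr.D_mean,
                Dh_um=tr.D_h,
                KS_pot=tr.KS_pot,
            )
        )
    return pd.DataFrame(rows)


def _segment_geometry_from_row(row: pd.Series) -> _flow.SegmentGeometry:
    def val(name):
        v = row.get(name)
        return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)

    return _flow.SegmentGeometry(
        sample_id=str(row["sample_id"]),
        organ=str(row["organ"]),
        length=float(row["length_m"]),
        end1_d1=val("end1_d1_mm"),
        end1_d2=val("end1_d2_mm"),
        end2_d1=val("end2_d1_mm"),
        end2_d2=val("end2_d2_mm"),
        pith_d1=val("pith_d1_mm"),
        pith_d2=val("pith_d2_mm"),
        dry_mass=val("dry_mass_g"),
        core_length_mm=val("core_length_mm"),
    )


def flow_table(
    flow_records: pd.DataFrame,
    segments: pd.DataFrame,
    leaf_areas: Optional[pd.DataFrame] = None,
    stability_tol: float = 0.02,
) -> pd.DataFrame:
    """Per-sample measured hydraulic traits (k_max selection included)."""
    leaf_map: Mapping[str, float] = {}
    if leaf_areas is not None and len(leaf_areas):
        leaf_map = dict(zip(leaf_areas["sample_id"], leaf_areas["leaf_area_m2"]))
    seg_map = {row["sample_id"]: row for _, row in segments.iterrows()}
    meta_cols = [c for c in ("species", "tree_id", "organ", "leaf_habit") if c in flow_records]
    rows = []
    for sid, grp in flow_records.groupby("sample_id", sort=True):
        if sid not in seg_map:
            log.warning("flow sample %s has no segment geometry; skipped", sid)
            continue
        geom = _segment_geometry_from_row(seg_map[sid])
        records = [
            _flow.FlowRecord(
                sample_id=str(sid),
                stage=str(stage),
                pressure_head=float(p),
                mass_flow=float(f),
            )
            for stage, p, f in zip(
                grp["stage"], grp["pressure_kPa"], grp["flow_g_per_h"]
            )
        ]
        tr = _flow.hydraulic_traits(
            records, geom, leaf_area=leaf_map.get(sid), stability_tol=stability_tol
        )
        row = {c: grp[c].iloc[0] for c in meta_cols}
        rows.append(
            dict(
                sample_id=sid,
                **row,
                Kh=tr.K_h,
                Kh_initial=tr.K_h_initial,
                A_xylem_m2=tr.A_xylem,
                KS_hydr=tr.KS_hydr,
                K_L=tr.K_L,
                HV=tr.HV,
            )
        )
    return pd.DataFrame(rows)


def density_table(segments: pd.DataFrame) -> pd.DataFrame:
    """Per-segment (and per-core) wood density."""
    meta_cols = [c for c in ("species", "tree_id", "organ", "leaf_habit") if c in segments]
    rows = []
    for _, seg in segments.iterrows():
        if pd.isna(seg.get("dry_mass_g")):
            continue
        geom = _segment_geometry_from_row(seg)
        res = _density.density_result(geom)
        rows.append(
            dict(
                sample_id=seg["sample_id"],
                **{c: seg[c] for c in meta_cols},
                fresh_volume_cm3=res.fresh_volume,
                WD=res.WD,
            )
        )
    return pd.DataFrame(rows)


def trait_table(
    anatomy_df: pd.DataFrame,
    flow_df: pd.DataFrame,
    density_df: pd.DataFrame,
) -> pd.DataFrame:
    """Long per-sample trait table (species, tree_id, organ, trait, value).

    Wood density of stem cores appears as organ ``stem`` so that it can be
    contrasted and correlated like any organ-level trait.
    """
    frames = []

    def melt(df: pd.DataFrame, cols) -> pd.DataFrame:
        id_cols = [c for c in ("sample_id", "species", "tree_id", "organ", "leaf_habit") if c in df]
        m = df.melt(
            id_vars=id_cols, value_vars=[c for c in cols if c in df],
            var_name="trait", value_name="value",
        )
        return m.dropna(subset=["value"])

    if len(anatomy_df):
        frames.append(melt(anatomy_df, ["CD_mm2", "F_pct", "Dmean_um", "Dh_um", "KS_pot"]))
    if len(flow_df):
        frames.append(melt(flow_df, ["KS_hydr", "K_L", "HV", "Kh"]))
    if len(density_df):
        dd = density_df.copy()
        dd["organ"] = dd["organ"].replace({"stem_core": "stem"})
        frames.append(melt(dd, ["WD"]))
    out = pd.concat(frames, ignore_index=True)
    return out


def _species_trait_means(samples: pd.DataFrame) -> pd.DataFrame:
    tree = _stats.aggregate_tree_means(samples)
    return _stats.species_means(tree)


def habit_contrast_table(
    species_df: pd.DataFrame, angiosperm_only: bool = True
) -> pd.DataFrame:
    """Deciduous − evergreen contrasts per organ × trait on species means."""
    df = species_df
    if angiosperm_only:
        df = df[df["leaf_habit"] != "gymnosperm"]
    rows = []
    for (trait, organ), grp in df.groupby(["trait", "organ"], sort=True):
        habits = dict(zip(grp["species"], grp["leaf_habit"]))
        values = dict(zip(grp["species"], grp["value"]))
        try:
            c = _stats.habit_contrast(values, habits)
        except ValueError:
            continue
        rows.append(
            dict(trait=trait, organ=organ, contrast=c.contrast, SE=c.SE,
                 df=c.df, t_ratio=c.t_ratio, p_value=c.p_value)
        )
    return pd.DataFrame(rows)


def organ_contrast_table(
    species_df: pd.DataFrame, traits=None, angiosperm_only: bool = True
) -> pd.DataFrame:
    """Root − branch contrasts per trait on species means."""
    df = species_df
    if angiosperm_only:
        df = df[df["leaf_habit"] != "gymnosperm"]
    trait_map = {
        "Dh_um": "Dh_um", "CD_mm2": "CD_mm2", "F_pct": "F_pct",
        "KS_pot": "KS_pot", "KS_hydr": "KS_hydr", "WD": "WD",
    }
    rows = []
    for trait in traits or ORGAN_TRAITS:
        sub = df[df["trait"] == trait_map.get(trait, trait)]
        root = sub[sub["organ"] == "root"]["value"].to_numpy()
        branch = sub[sub["organ"] == "branch"]["value"].to_numpy()
        if not len(root) or not len(branch):
            continue
        c = _stats.organ_contrast(root, branch)
        rows.append(
            dict(trait=trait, contrast=c.contrast, SE=c.SE, df=c.df,
                 t_ratio=c.t_ratio, p_value=c.p_value)
        )
    return pd.DataFrame(rows)


def rb_ratio_table(
    tree_df: pd.DataFrame, species_df: pd.DataFrame,
    tree_level_traits=("KS_hydr", "WD"),
) -> pd.DataFrame:
    """Mean root:branch ratios per leaf habit and trait.

    Traits with per-tree replication use tree-wise pairing; the rest pair
    species means.  The statistic is the mean of per-pair ratios.
    """
    rows = []
    traits = sorted(set(tree_df["trait"])) if len(tree_df) else []
    for trait in traits:
        level = "tree" if trait in tree_level_traits else "species"
        src = tree_df if level == "tree" else species_df
        sub = src[src["trait"] == trait]
        for habit, grp in sub.groupby("leaf_habit", sort=True):
            key = ["species", "tree_id"] if level == "tree" else ["species"]
            piv = grp.pivot_table(index=key, columns="organ", values="value")
            if "root" not in piv or "branch" not in piv:
                continue
            piv = piv.dropna(subset=["root", "branch"])
            if not len(piv):
                continue
            ratios, mean = _stats.rb_ratio(
                piv["root"].to_dict(), piv["branch"].to_dict()
            )
            rows.append(
                dict(trait=trait, leaf_habit=habit, level=level,
                     n_pairs=len(ratios), rb_mean=mean,
                     rb_median=float(ratios.median()))
            )
    return pd.DataFrame(rows)


def wood_density_summary(tree_df: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per species × organ WD mean ± SE with Tukey letters across species."""
    wd = tree_df[tree_df["trait"] == "WD"]
    rows = []
    for organ, grp in wd.groupby("organ", sort=True):
        groups = {
            sp: g["value"].to_numpy()
            for sp, g in grp.groupby("species")
            if len(g) >= 2
        }
        letters = {}
        if len(groups) >= 2:
            try:
                letters = _stats.tukey_letters(groups, alpha=alpha).letters
            except ValueError:
                log.warning("degenerate WD groups for organ %s; no letters", organ)
        for sp, g in grp.groupby("species"):
            v = g["value"].to_numpy()
            rows.append(
                dict(
                    organ=organ, species=sp,
                    leaf_habit=g["leaf_habit"].iloc[0],
                    n=len(v), WD_mean=float(v.mean()),
                    WD_se=float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan,
                    letters=letters.get(sp, ""),
                )
            )
    return pd.DataFrame(rows)


def correlation_table(species_df: pd.DataFrame) -> pd.DataFrame:
    """Species-mean Pearson correlations between organ-tagged traits."""
    piv = species_df.pivot_table(
        index="species", columns=["trait", "organ"], values="value"
    )
    piv.columns = [f"{t}:{o}" for t, o in piv.columns]
    return _stats.pearson_matrix(piv)


def height_model_table(tree_df: pd.DataFrame, traits=("Dh_um", "KS_hydr")) -> pd.DataFrame:
    """Random-intercept (species) models of trait vs tree height, per organ."""
    rows = []
    for trait in traits:
        sub = tree_df[(tree_df["trait"] == trait) & tree_df["height_m"].notna()]
        for organ, grp in sub.groupby("organ", sort=True):
            if grp["species"].nunique() < 2 or len(grp) < 6:
                continue
            res = _stats.height_model(
                grp["value"].to_numpy(), grp["height_m"].to_numpy(),
                grp["species"].to_numpy(),
            )
            rows.append(
                dict(trait=trait, organ=organ, slope=res.slope,
                     slope_p=res.slope_p, var_ratio=res.psi, n=len(grp))
            )
    return pd.DataFrame(rows)


@dataclass
class AnalysisResult:
    anatomy: pd.DataFrame
    flow: pd.DataFrame
    density: pd.DataFrame
    samples: pd.DataFrame  # long per-sample trait table
    tree_means: pd.DataFrame
    species_means: pd.DataFrame
    habit_contrasts: pd.DataFrame
    organ_contrasts: pd.DataFrame
    rb_ratios: pd.DataFrame
    wd_summary: pd.DataFrame
    correlations: pd.DataFrame
    height_models: pd.DataFrame

    def tables(self) -> Dict[str, pd.DataFrame]:
        return {k: getattr(self, k) for k in (
            "anatomy", "flow", "density", "samples", "tree_means",
            "species_means", "habit_contrasts", "organ_contrasts",
            "rb_ratios", "wd_summary", "correlations", "height_models",
        )}


def analyze(
    bundle: Mapping[str, pd.DataFrame],
    dh_method: str = "d5_over_d4",
    extras: bool = True,
) -> AnalysisResult:
    """Run the whole pipeline on a bundle of input tables.

    ``extras=False`` skips the post-hoc letter display, the correlation
    matrix and the height models (the expensive presentation layers) —
    useful when the core trait tables and contrasts are re-computed over
    many simulated studies.
    """
    anatomy_df = anatomy_table(bundle["conduits"], dh_method=dh_method)
    flow_df = flow_table(
        bundle["flow"], bundle["segments"], bundle.get("leaf_areas")
    )
    density_df = density_table(bundle["segments"])
    samples = trait_table(anatomy_df, flow_df, density_df)

    trees_meta = bundle.get("trees")
    tree_means = _stats.aggregate_tree_means(samples)
    if trees_meta is not None and "height_m" in trees_meta:
        tree_means = tree_means.merge(
            trees_meta[["species", "tree_id", "height_m"]],
            on=["species", "tree_id"], how="left",
        )
    else:
        tree_means["height_m"] = np.nan
    sp_means = _stats.species_means(tree_means.drop(columns=["height_m"]))

    return AnalysisResult(
        anatomy=anatomy_df,
        flow=flow_df,
        density=density_df,
        samples=samples,
        tree_means=tree_means,
        species_means=sp_means,
        habit_contrasts=habit_contrast_table(sp_means),
        organ_contrasts=organ_contrast_table(sp_means),
        rb_ratios=rb_ratio_table(tree_means, sp_means),
        wd_summary=wood_density_summary(tree_means) if extras else pd.DataFrame(),
        correlations=correlation_table(sp_means) if extras else pd.DataFrame(),
        height_models=height_model_table(tree_means) if extras else pd.DataFrame(),
    )
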