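"""End-to-end pipeline stages tying the library modules together.

``run_spatial`` takes each slide from mask to indicator grid;
``run_survival`` runs the full statistical procedure from censoring to the
combined risk score.  Both write CSV/JSON outputs (with the full config
echoed for provenance) and are deterministic given the config seed.
"""

from __future__ import annotations

import json
import logging
import math

import numpy as np
import pandas as pd

from . import bands, cells as cells_mod, gradients, interface, masks, survival
from .config import DataError, RunConfig

log = logging.getLogger("immunogradient")


# ---------------------------------------------------------------------------
# spatial stage
# ---------------------------------------------------------------------------

def analyse_slide(
    mask: masks.TissueMask,
    cellset: cells_mod.CellSet,
    config: RunConfig,
) -> dict:
    """Mask -> interface -> bands -> densities -> indicator grid for one slide.

    Returns a dict with the retained interface, band map, density profile,
    compartment densities and the indicator variant table.  Raises
    :class:`DataError` when no interface of sufficient length exists.
    """
    iface = interface.extract_interface(mask)
    retained = interface.filter_short_boundaries(iface, config.min_boundary_um)
    log.info(
        "interface: %d boundaries traced, %d retained (>= %g um), total %.0f um",
        len(iface), len(retained), config.min_boundary_um, retained.total_length_um,
    )
    if len(retained) == 0:
        raise DataError(
            f"no boundary of at least {config.min_boundary_um} um; "
            "interface zone is empty"
        )
    band_map = bands.compute_band_map(
        mask, retained, config.band_width_um, config.grid_max_width_um
    )
    counts = cells_mod.assign_cells_to_bands(cellset, band_map)
    if counts.excluded:
        log.warning("%d CD8+ cells outside the raster were excluded", counts.excluded)
    profile = cells_mod.band_density_profile(counts, band_map.areas_mm2)
    comp = cells_mod.compartment_densities(cellset, mask, band_map)
    grid = gradients.variant_grid(
        profile, config.variant_widths_um, config.band_width_um
    )
    return {
        "interface": retained,
        "band_map": band_map,
        "profile": profile,
        "compartments": comp,
        "indicators": grid,
    }


def run_spatial(config: RunConfig) -> pd.DataFrame:
    """Run the spatial stage for every configured slide.

    Per-slide failures are recorded (indicators undefined, ``error`` column)
    and the run continues.  Writes ``profiles_<slide>.csv`` and a combined
    ``indicators.csv``; returns the indicator table (one row per slide x
    variant).
    """
    out_dir = config.ensure_output_dir()
    rows = []
    for slide in config.slides:
        try:
            if str(slide.mask).endswith((".json", ".geojson")):
                mask = masks.rasterize_geojson(slide.mask, config.pixel_size_um)
            else:
                mask = masks.read_mask(slide.mask, config.pixel_size_um, config.label_codes)
            cellset = cells_mod.read_cells(slide.cells)
            result = analyse_slide(mask, cellset, config)
        except (DataError, ValueError, OSError) as err:
            log.error("slide %s failed: %s", slide.slide, err)
            rows.append(
                {
                    "slide": slide.slide,
                    "indicator": "",
                    "rank": 0,
                    "label": "",
                    "value": float("nan"),
                    "defined": False,
                    "reason": str(err),
                }
            )
            continue
        result["profile"].to_frame().to_csv(
            out_dir / f"profiles_{slide.slide}.csv", index=False
        )
        tbl = result["indicators"].table.copy()
        tbl.insert(0, "slide", slide.slide)
        comp = result["compartments"]
        for name, v in (
            ("density_epithelial", comp.epithelial_density),
            ("density_stromal", comp.stromal_density),
            ("density_overall", comp.overall_iz_density),
        ):
            tbl.loc[len(tbl)] = [
                slide.slide, name, 0, name, v, not math.isnan(v), ""
            ]
        rows.append(tbl)
    table = pd.concat(
        [r if isinstance(r, pd.DataFrame) else pd.DataFrame([r]) for r in rows],
        ignore_index=True,
    ) if rows else pd.DataFrame(
        columns=["slide", "indicator", "rank", "label", "value", "defined", "reason"]
    )
    table.to_csv(out_dir / "indicators.csv", index=False)
    with open(out_dir / "spatial_provenance.json", "w") as fh:
        json.dump({"config": config.echo()}, fh, indent=2)
    return table


# ---------------------------------------------------------------------------
# survival stage
# ---------------------------------------------------------------------------

GRADE_DUMMIES = ("g1", "g2", "g3")
#: grade dummies screened univariably; only G3 is eligible for multivariable models
ENUMERATION_EXCLUDED = {"g1", "g2"}

SCREENING_FEATURES = (
    "id_value",
    "cm_value",
    "density_epithelial",
    "density_stromal",
    "density_overall",
    "stage_t1",
    "g1",
    "g2",
    "g3",
    "positive_retur",
    "recurrent_tumor",
    "retur_or_recurrent",
    "cis",
    "multifocal",
    "size_gt_30mm",
    "age",
    "male",
)


def _add_derived_columns(cohort: pd.DataFrame) -> pd.DataFrame:
    out = cohort.copy()
    if "grade" in out.columns:
        for g in GRADE_DUMMIES:
            if g not in out.columns:
                out[g] = (out["grade"] == g.upper()).astype(int)
    if "stage" in out.columns and "stage_t1" not in out.columns:
        out["stage_t1"] = (out["stage"] == "T1").astype(int)
    if (
        "retur_or_recurrent" not in out.columns
        and {"positive_retur", "recurrent_tumor"} <= set(out.columns)
    ):
        out["retur_or_recurrent"] = (
            (out["positive_retur"] != 0) | (out["recurrent_tumor"] != 0)
        ).astype(int)
    return out


def select_best_variant(
    cohort: pd.DataFrame, variants: pd.DataFrame, indicator: str
) -> tuple[int, pd.Series]:
    """Pick the indicator variant with the lowest univariable p-value.

    ``variants`` holds one column per variant rank (values aligned with the
    cohort rows).  Ties break toward the smaller zone width (smaller rank),
    i.e. closer to the interface.  Returns (rank, values).
    """
    best_rank, best_p = None, np.inf
    for rank in sorted(int(c) for c in variants.columns):
        col = variants[rank]
        if col.dropna().nunique() < 2:
            continue
        tmp = cohort[[survival.DURATION_COL, survival.EVENT_COL]].copy()
        tmp[indicator] = col.to_numpy()
        try:
            res = survival.univariable_cox(tmp, indicator)
        except ValueError:
            continue
        if res.converged and np.isfinite(res.p[indicator]) and res.p[indicator] < best_p:
            best_rank, best_p = rank, res.p[indicator]
    if best_rank is None:
        raise DataError(f"no usable {indicator} variant")
    return best_rank, variants[best_rank]


def merge_indicators(clinical: pd.DataFrame, indicator_table: pd.DataFrame) -> pd.DataFrame:
    """Join per-slide indicator variants onto the clinical table.

    The clinical table must carry a ``slide`` column; the best ID and CM
    variants (lowest univariable p on the merged cohort) become the
    ``id_value`` and ``cm_value`` columns, and compartment densities are
    joined as-is.
    """
    if "slide" not in clinical.columns:
        raise DataError("clinical table needs a 'slide' column to join indicators")
    out = clinical.copy()
    for indicator, col in (("ID", "id_value"), ("CM", "cm_value")):
        sub = indicator_table[
            (indicator_table["indicator"] == indicator) & indicator_table["defined"]
        ]
        if sub.empty:
            continue
        wide = sub.pivot_table(index="slide", columns="rank", values="value")
        aligned = wide.reindex(out["slide"]).reset_index(drop=True)
        rank, values = select_best_variant(out, aligned, indicator.lower())
        out[col] = values.to_numpy()
        out[col + "_variant_rank"] = rank
    for dens in ("density_epithelial", "density_stromal", "density_overall"):
        sub = indicator_table[indicator_table["indicator"] == dens]
        if not sub.empty:
            m = sub.set_index("slide")["value"]
            out[dens] = m.reindex(out["slide"]).to_numpy()
    return out


def run_survival(
    config: RunConfig,
    clinical: pd.DataFrame,
    indicator_table: pd.DataFrame | None = None,
) -> dict:
    """Censor, split, screen, enumerate, filter, CV-rank, test, score.

    Returns the model report as a dict (also written as JSON, with KM curves
    and risk scores as CSVs).  Raises :class:`DataError` on degenerate input
    (no events, missing required columns).
    """
    missing = {survival.DURATION_COL, survival.EVENT_COL} - set(clinical.columns)
    if missing:
        raise DataError(f"clinical table missing columns: {sorted(missing)}")
    cohort = _add_derived_columns(clinical)
    if indicator_table is not None:
        cohort = merge_indicators(cohort, indicator_table)
    cohort = survival.censor_rfs(cohort, config.horizon_months)
    if cohort[survival.EVENT_COL].sum() == 0:
        raise DataError("cohort has no recurrence events; survival modeling aborted")

    train, test = survival.split_cohort(cohort, config.n_train, config.n_test, config.seed)

    screened: dict[str, survival.CoxModelResult] = {}
    for feat in SCREENING_FEATURES:
        if feat not in train.columns or train[feat].dropna().nunique() < 2:
            continue
        try:
            screened[feat] = survival.univariable_cox(train, feat)
        except ValueError as err:
            log.info("screening %s skipped: %s", feat, err)
    selected = survival.select_features(screened, config.alpha)
    eligible = [f for f in selected if f not in ENUMERATION_EXCLUDED]
    log.info("univariable screening selected %s (eligible: %s)", selected, eligible)

    combos = survival.enumerate_models(eligible)
    kept = survival.fit_and_filter(train, combos, config.alpha)
    ranked = survival.rank_models_by_cv(train, kept, config.cv_folds, config.seed)
    best = ranked[0] if ranked else None
    if best is not None:
        best.train_c = survival.evaluate_on(train, best, refit_on=train)
        best.test_c = survival.evaluate_on(test, best, refit_on=train)

    out_dir = config.ensure_output_dir()
    report = {
        "n": len(cohort),
        "n_events": int(cohort[survival.EVENT_COL].sum()),
        "univariable": {f: r.to_dict() for f, r in screened.items()},
        "selected_features": selected,
        "models": [m.to_dict() for m in ranked],
        "best_model": best.to_dict() if best else None,
        "seed": config.seed,
        "tie_method": "Efron",
        "config": config.echo(),
    }

    scored = None
    if "id_value" in cohort.columns and cohort["id_value"].notna().all():
        scored = survival.score_cohort(cohort)
        scored.to_csv(out_dir / "risk_scores.csv", index=False)
        curves, pvals = survival.km_logrank(scored, scored["risk_category"])
        for name, curve in curves.items():
            curve.to_csv(out_dir / f"km_risk_{name}.csv", index=False)
        pvals.to_csv(out_dir / "km_risk_logrank.csv", index=False)
        report["risk_group_logrank"] = pvals.to_dict(orient="records")
        report["risk_group_sizes"] = (
            scored["risk_category"].value_counts().to_dict()
        )

    with open(out_dir / "model_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    report["scored_cohort"] = scored
    return report
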