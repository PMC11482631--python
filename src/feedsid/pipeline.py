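"""Stage orchestration: compose the analysis stages and write report files.

A run takes ingredient, diet, digesta and endogenous tables (from CSV
files or the bundled reference dataset), and produces

* ``composition_summary.csv`` — per-component mean/min/max/CV with the
  high-variability flag,
* ``aid.csv`` / ``sid.csv`` — digestibility summary tables,
* ``correlations.csv`` — Pearson r (and p) between composition variables
  and SID responses,
* ``models.csv`` — stepwise prediction equations with RSD, R2, adjusted
  R2, F-test p and n,
* ``manifest.json`` — inputs, seed, package version and every analysis
  toggle in effect, so a run is reproducible from its output directory.

When no pig-level digesta table is available (the reference dataset
publishes only treatment summaries) the SID table is reconstructed from
the summary AID values, the diet assays and the endogenous losses — the
same arithmetic as the per-replicate chain, applied at the mean level.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import composition_stats as cs
from . import digestibility as dig
from . import prediction as pred
from .feedtables import (
    DietAssay,
    EndogenousLosses,
    IngredientSample,
    fixtures,
    read_table,
)
from .synthetic_trial import NFREE_DIET_ID

logger = logging.getLogger("feedsid")

__all__ = ["RunConfig", "run_pipeline", "composition_frame",
           "sid_from_summary", "fit_prediction_models",
           "DEFAULT_CANDIDATES", "DEFAULT_RESPONSES"]

#: Candidate predictors for the headline stepwise run: the proximate
#: components plus the processing-temperature midpoint (HT, deg C).
DEFAULT_CANDIDATES: tuple[str, ...] = (
    "DM", "GE", "CP", "EE", "Ash", "CF", "NDF", "ADF", "Ca", "TP", "TGS", "HT",
)

#: SID responses modelled by default: crude protein and the first four
#: limiting amino acids for pigs, plus valine.
DEFAULT_RESPONSES: tuple[str, ...] = ("CP", "Lys", "Met", "Thr", "Trp", "Val")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on."""

    ingredients: str | None = None
    diets: str | None = None
    digesta: str | None = None
    endogenous: str | None = None
    use_fixtures: bool = False
    out: str = "feedsid_out"
    seed: int = 0
    cv_threshold: float = 10.0
    alpha: float = 0.05
    p_enter: float = 0.05
    p_remove: float = 0.10
    zscore_threshold: float | None = 3.0
    candidates: Sequence[str] = DEFAULT_CANDIDATES
    responses: Sequence[str] = DEFAULT_RESPONSES


def composition_frame(ingredients: Sequence[IngredientSample],
                      include_aa: bool = False) -> pd.DataFrame:
    """Lot-by-variable frame of composition covariates (plus HT)."""
    rows = {}
    for ing in ingredients:
        row = dict(ing.proximate)
        row["HT"] = ing.heat_mid_c
        if include_aa:
            row.update(ing.aa_profile)
        rows[ing.sample_id] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def sid_from_summary(aid_table: pd.DataFrame,
                     diets: Mapping[str, DietAssay],
                     endogenous: EndogenousLosses,
                     sample_ids: Sequence[str]) -> pd.DataFrame:
    """Apply the SID correction to a component-by-ingredient AID table."""
    out = {}
    for diet_id in sample_ids:
        diet = diets[diet_id]
        col = {}
        for comp in aid_table.index:
            if comp not in endogenous:
                continue
            conc = dig.diet_concentration_dm(diet, comp)
            col[comp] = dig.compute_sid(
                float(aid_table.loc[comp, diet_id]), endogenous[comp], conc)
        out[diet_id] = col
    table = pd.DataFrame(out)
    table.index.name = "component"
    return table


def fit_prediction_models(covariates: pd.DataFrame,
                          sid_table: pd.DataFrame,
                          responses: Sequence[str] = DEFAULT_RESPONSES,
                          candidates: Sequence[str] = DEFAULT_CANDIDATES,
                          p_enter: float = 0.05,
                          p_remove: float = 0.10
                          ) -> dict[str, pred.RegressionModel]:
    """Stepwise equation per SID response over the candidate pool."""
    x = covariates[[c for c in candidates if c in covariates.columns]]
    models = {}
    for comp in responses:
        if comp not in sid_table.index:
            continue
        y = sid_table.loc[comp, x.index].to_numpy(dtype=float)
        models[comp] = pred.stepwise_select(
            x, y, p_enter=p_enter, p_remove=p_remove,
            response=f"SID_{comp}")
    return models


def _models_frame(models: Mapping[str, pred.RegressionModel]) -> pd.DataFrame:
    rows = []
    for comp, m in models.items():
        rows.append({
            "response": m.response,
            "equation": m.equation(),
            "predictors": ";".join(m.predictors),
            "intercept": round(m.intercept, 3),
            "rsd": round(m.rsd, 3),
            "r2": round(m.r2, 3),
            "adj_r2": round(m.adj_r2, 3),
            "p_value": m.p_value,
            "n": m.n,
        })
    return pd.DataFrame(rows)


def _load_inputs(config: RunConfig):
    if config.use_fixtures:
        bundle = fixtures()
        return bundle.ingredients, bundle.diets, None, bundle.endogenous, bundle
    if not config.ingredients:
        raise ValueError("config must name an ingredients table or use_fixtures")
    ingredients = read_table(config.ingredients, "ingredients")
    diets = ({d.diet_id: d for d in read_table(config.diets, "diets")}
             if config.diets else {})
    digesta = (read_table(config.digesta, "digesta")
               if config.digesta else None)
    endogenous = (read_table(config.endogenous, "endogenous")
                  if config.endogenous else None)
    return ingredients, diets, digesta, endogenous, None


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every applicable stage and write the report bundle.

    Returns a mapping of stage name to output path.  Stages whose inputs
    are absent are skipped with a log message; the composition stage only
    needs ingredients, the digestibility stage needs diets plus either
    pig-level digesta or a summary AID table (bundled dataset), and the
    correlation/regression stages need an SID table.
    """
    out_dir = Path(config.out)
    out_dir.mkdir(parents=True, exist_ok=True)
    ingredients, diets, digesta, endogenous, bundle = _load_inputs(config)
    outputs: dict[str, Path] = {}

    logger.info("composition: %d ingredient lots", len(ingredients))
    summary = cs.summarize_ingredients(ingredients, threshold=config.cv_threshold)
    path = out_dir / "composition_summary.csv"
    summary.to_csv(path)
    outputs["composition_summary"] = path

    sid_means: pd.DataFrame | None = None
    sample_ids = [i.sample_id for i in ingredients]
    if digesta is not None and diets and endogenous is not None:
        nfree = [o for o in digesta if o.diet_id == NFREE_DIET_ID]
        test = [o for o in digesta if o.diet_id != NFREE_DIET_ID]
        if nfree:
            endogenous = dig.endogenous_from_nfree(nfree, diets[NFREE_DIET_ID])
        logger.info("digestibility: %d test observations, %d nitrogen-free",
                    len(test), len(nfree))
        aid_long = dig.aid_observations(test, diets)
        replicates = dig.sid_observations(aid_long, diets, endogenous)
        aid_summary = dig.summarize_table(
            replicates, "aid_pct", alpha=config.alpha,
            zscore_threshold=config.zscore_threshold)
        sid_summary = dig.summarize_table(
            replicates, "sid_pct", alpha=config.alpha,
            zscore_threshold=config.zscore_threshold)
        (out_dir / "aid.csv").write_text(aid_summary.to_csv())
        (out_dir / "sid.csv").write_text(sid_summary.to_csv())
        outputs["aid"] = out_dir / "aid.csv"
        outputs["sid"] = out_dir / "sid.csv"
        sid_means = sid_summary[[c for c in sid_summary.columns
                                 if c in sample_ids]]
    elif bundle is not None:
        logger.info("digestibility: reconstructing SID from summary AID table")
        aid_values = bundle.aid[sample_ids]
        sid_means = sid_from_summary(aid_values, diets, endogenous, sample_ids)
        aid_values.to_csv(out_dir / "aid.csv")
        sid_means.to_csv(out_dir / "sid.csv")
        outputs["aid"] = out_dir / "aid.csv"
        outputs["sid"] = out_dir / "sid.csv"
    else:
        logger.info("digestibility: skipped (no digesta or summary inputs)")

    if sid_means is not None:
        covariates = composition_frame(ingredients)
        responses = [c for c in config.responses if c in sid_means.index]
        variables = covariates[
            [c for c in config.candidates if c in covariates.columns]].copy()
        for comp in responses:
            variables[f"SID_{comp}"] = sid_means.loc[comp, variables.index]
        r, p = pred.pearson_matrix(variables)
        r.to_csv(out_dir / "correlations.csv")
        p.to_csv(out_dir / "correlation_pvalues.csv")
        outputs["correlations"] = out_dir / "correlations.csv"

        models = fit_prediction_models(
            covariates, sid_means, responses=responses,
            candidates=config.candidates,
            p_enter=config.p_enter, p_remove=config.p_remove)
        _models_frame(models).to_csv(out_dir / "models.csv", index=False)
        outputs["models"] = out_dir / "models.csv"
        for comp, m in models.items():
            logger.info("model %s: %s", comp, m.equation())

    manifest = {
        "package": "feedsid",
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, (tuple, list)) else v)
                   for k, v in asdict(config).items()},
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    outputs["manifest"] = manifest_path
    return outputs
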