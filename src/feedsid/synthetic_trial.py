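"""Synthetic cannulated-pig digestibility trial.

The reference study design is two incomplete 11 x 3 Latin squares:
22 ileal-cannulated pigs, 3 consecutive periods, 11 diets (one test diet
per ingredient lot plus a nitrogen-free diet), every diet appearing
exactly once per square-period and collecting 6 pig-period replicates
overall.  Pig-level assay data of such trials are rarely published, so
this module generates them from configurable ground truth, which makes
end-to-end pipeline tests and parameter-recovery studies possible.

The generative model mirrors the marker-ratio arithmetic in reverse.
Test diets carry the ingredient at a fixed inclusion rate (40% air-dry by
default) in a protein-free carrier, with TiO2 at 0.30%.  For a diet with
true dry-matter digestibility ``d`` the digesta marker concentration is
``T_d = T_r / (1 - d)``; the undigested flow of a component per kg DM
intake is ``diet_conc_dm * (1 - SID_true/100) + IAA_end_true`` and its
digesta concentration that flow times ``T_d / T_r``, times a
multiplicative lognormal assay error with unit mean and configurable CV.
On the nitrogen-free diet the flow is the endogenous loss alone.  With
the noise CV at zero the estimation chain returns the true SID and
endogenous losses to machine precision, which is the simulator's
calibration identity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import digestibility as dig
from .feedtables import (
    COMPONENTS,
    DietAssay,
    DigestaObservation,
    EndogenousLosses,
    IngredientSample,
)
from .prediction import RegressionModel

__all__ = [
    "TrialDesign",
    "TrialGroundTruth",
    "build_design",
    "generate_trial",
    "SimulatedTrial",
    "EstimationResult",
    "run_estimation",
    "fit_sid_slope",
    "recovery_report",
    "default_ground_truth",
]

NFREE_DIET_ID = "NFREE"


@dataclass
class TrialDesign:
    """Pig-period-diet assignments of a two-square incomplete Latin square."""

    assignments: pd.DataFrame  # columns: pig_id, period, diet_id, square
    diet_ids: tuple[str, ...]

    def validate(self) -> None:
        df = self.assignments
        n_diets = len(self.diet_ids)
        n_periods = df["period"].nunique()
        expected = 2 * n_diets * n_periods
        if len(df) != expected:
            raise ValueError(f"expected {expected} assignments, got {len(df)}")
        counts = df["diet_id"].value_counts()
        if set(counts.index) != set(self.diet_ids) or counts.nunique() != 1:
            raise ValueError("diets are not equireplicated")
        per_cell = df.groupby(["square", "period"])["diet_id"].nunique()
        if (per_cell != n_diets).any():
            raise ValueError("a diet repeats within a square-period")
        per_pig = df.groupby("pig_id")["diet_id"].nunique()
        if (per_pig != n_periods).any():
            raise ValueError("a pig repeats a diet across periods")


def build_design(n_pigs: int = 22, n_diets: int = 11, n_periods: int = 3,
                 seed: int = 0,
                 diet_ids: Sequence[str] | None = None) -> TrialDesign:
    """Build a balanced two-square incomplete Latin square.

    Per square the construction is cyclic: pig slot ``i`` receives in
    period ``j`` the diet ``(i + o_j) mod n_diets`` with distinct random
    period offsets ``o_j``, which guarantees each diet appears exactly
    once per square-period and that no pig repeats a diet.  Pig labels
    are then shuffled.  Deterministic for a fixed ``seed``.
    """
    if n_pigs != 2 * n_diets:
        raise ValueError("n_pigs must equal 2 * n_diets (two squares)")
    if not 0 < n_periods < n_diets:
        raise ValueError("need 0 < n_periods < n_diets")
    if diet_ids is None:
        diet_ids = tuple(f"D{k + 1:02d}" for k in range(n_diets))
    else:
        diet_ids = tuple(diet_ids)
        if len(diet_ids) != n_diets:
            raise ValueError("diet_ids length must equal n_diets")
    rng = np.random.default_rng(seed)
    pig_labels = [f"P{k + 1:02d}" for k in range(n_pigs)]
    shuffled = list(rng.permutation(pig_labels))
    rows = []
    for square in (1, 2):
        offsets = rng.choice(n_diets, size=n_periods, replace=False)
        for slot in range(n_diets):
            pig = shuffled[(square - 1) * n_diets + slot]
            for j in range(n_periods):
                rows.append({
                    "pig_id": pig,
                    "period": j + 1,
                    "diet_id": diet_ids[(slot + int(offsets[j])) % n_diets],
                    "square": square,
                })
    design = TrialDesign(pd.DataFrame(rows), diet_ids)
    design.validate()
    return design


@dataclass
class TrialGroundTruth:
    """Configurable truth underlying a simulated trial.

    ``true_sid`` maps ``(ingredient_id, component)`` to a true SID in %,
    ``true_endogenous`` maps components to basal losses in g/kg DM intake,
    ``true_dm_digestibility`` maps diet ids to the true fraction of dietary
    DM disappearing before the ileum (defaults 0.75 for test diets, 0.90
    for the nitrogen-free diet), and ``noise_cv`` is the CV of the
    multiplicative lognormal assay error (0.05 by default).
    """

    true_sid: dict[tuple[str, str], float]
    true_endogenous: dict[str, float]
    true_dm_digestibility: dict[str, float] = field(default_factory=dict)
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        for diet, d in self.true_dm_digestibility.items():
            if not 0 < d < 1:
                raise ValueError(f"DM digestibility for {diet} must be in (0,1)")

    def dm_digestibility(self, diet_id: str) -> float:
        if diet_id in self.true_dm_digestibility:
            return self.true_dm_digestibility[diet_id]
        return 0.90 if diet_id == NFREE_DIET_ID else 0.75


@dataclass
class SimulatedTrial:
    """Output bundle of :func:`generate_trial`."""

    design: TrialDesign
    truth: TrialGroundTruth
    diets: dict[str, DietAssay]
    digesta: list[DigestaObservation]

    @property
    def nfree_observations(self) -> list[DigestaObservation]:
        return [o for o in self.digesta if o.diet_id == NFREE_DIET_ID]

    @property
    def test_observations(self) -> list[DigestaObservation]:
        return [o for o in self.digesta if o.diet_id != NFREE_DIET_ID]


def _lognormal_factors(rng: np.random.Generator, cv: float,
                       size: int) -> np.ndarray:
    """Unit-mean multiplicative errors with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _diet_from_ingredient(ing: IngredientSample, inclusion: float,
                          carrier_dm_pct: float,
                          marker_pct: float) -> DietAssay:
    aa = {a: inclusion * v for a, v in ing.aa_profile.items()}
    return DietAssay(
        diet_id=ing.sample_id,
        dm_pct=inclusion * ing.proximate["DM"] + (1 - inclusion) * carrier_dm_pct,
        cp_pct=inclusion * ing.proximate["CP"],
        aa_pct=aa,
        marker_pct=marker_pct,
    )


def generate_trial(ingredients: Iterable[IngredientSample],
                   truth: TrialGroundTruth,
                   design: TrialDesign,
                   inclusion: float = 0.40,
                   carrier_dm_pct: float = 90.3,
                   marker_pct: float = 0.30) -> SimulatedTrial:
    """Simulate diet and digesta assays for every design assignment.

    Every design diet except :data:`NFREE_DIET_ID` must match an
    ingredient's ``sample_id``.  Only components with an entry in
    ``truth.true_sid`` for the ingredient are assayed; the nitrogen-free
    digesta carries every component of ``truth.true_endogenous``.  The
    single ``truth.seed`` drives all noise draws, consumed in design row
    order and canonical component order.
    """
    by_id = {ing.sample_id: ing for ing in ingredients}
    missing = [d for d in design.diet_ids
               if d != NFREE_DIET_ID and d not in by_id]
    if missing:
        raise ValueError(f"design diets without an ingredient: {missing}")

    diets: dict[str, DietAssay] = {}
    for diet_id in design.diet_ids:
        if diet_id == NFREE_DIET_ID:
            diets[diet_id] = DietAssay(diet_id=NFREE_DIET_ID,
                                       dm_pct=carrier_dm_pct, cp_pct=0.0,
                                       aa_pct={}, marker_pct=marker_pct)
        else:
            diets[diet_id] = _diet_from_ingredient(
                by_id[diet_id], inclusion, carrier_dm_pct, marker_pct)

    rng = np.random.default_rng(truth.seed)
    observations: list[DigestaObservation] = []
    for _, row in design.assignments.iterrows():
        diet = diets[row["diet_id"]]
        t_r = dig.diet_marker_dm(diet)
        d = truth.dm_digestibility(row["diet_id"])
        t_d = t_r / (1.0 - d)
        conc: dict[str, float] = {}
        if row["diet_id"] == NFREE_DIET_ID:
            comps = [c for c in COMPONENTS if c in truth.true_endogenous]
            eps = _lognormal_factors(rng, truth.noise_cv, len(comps))
            for comp, e in zip(comps, eps):
                flow = truth.true_endogenous[comp] * e
                conc[comp] = flow * (t_d / t_r)
        else:
            comps = [c for c in COMPONENTS
                     if (row["diet_id"], c) in truth.true_sid]
            eps = _lognormal_factors(rng, truth.noise_cv, len(comps))
            for comp, e in zip(comps, eps):
                diet_conc = dig.diet_concentration_dm(diet, comp)
                sid = truth.true_sid[(row["diet_id"], comp)]
                flow = (diet_conc * (1.0 - sid / 100.0)
                        + truth.true_endogenous.get(comp, 0.0))
                if flow < 0:
                    warnings.warn(
                        f"negative implied ileal flow for {row['diet_id']}/"
                        f"{comp} (true SID {sid} with endogenous "
                        f"{truth.true_endogenous.get(comp, 0.0)}); floored at 0"
                    )
                    flow = 0.0
                conc[comp] = flow * (t_d / t_r) * e
        observations.append(DigestaObservation(
            pig_id=row["pig_id"], period=int(row["period"]),
            diet_id=row["diet_id"], conc_dm=conc, marker_dm=t_d,
        ))
    return SimulatedTrial(design=design, truth=truth, diets=diets,
                          digesta=observations)


@dataclass
class EstimationResult:
    """Digestibility estimates recovered from one simulated trial."""

    endogenous: EndogenousLosses
    replicates: pd.DataFrame        # long: pig, period, diet, component, aid, sid
    sid_means: pd.DataFrame         # wide: component rows x ingredient columns
    aid_means: pd.DataFrame


def run_estimation(sim: SimulatedTrial) -> EstimationResult:
    """Run the full marker-ratio estimation chain on a simulated trial."""
    endogenous = dig.endogenous_from_nfree(sim.nfree_observations,
                                           sim.diets[NFREE_DIET_ID])
    aid = dig.aid_observations(sim.test_observations, sim.diets)
    replicates = dig.sid_observations(aid, sim.diets, endogenous)
    sid_means = replicates.pivot_table(index="component", columns="diet_id",
                                       values="sid_pct", aggfunc="mean")
    aid_means = replicates.pivot_table(index="component", columns="diet_id",
                                       values="aid_pct", aggfunc="mean")
    return EstimationResult(endogenous=endogenous, replicates=replicates,
                            sid_means=sid_means, aid_means=aid_means)


def fit_sid_slope(estimates: EstimationResult,
                  predictor_values: Mapping[str, float],
                  component: str,
                  predictor: str = "NDF",
                  weighted: bool = True) -> RegressionModel:
    """Regress estimated SID means on a composition covariate.

    Used by the slope-recovery analysis.  Because the assay error is
    multiplicative on the undigested ileal flow, the variance of an
    estimated SID mean scales with the squared undigested fraction
    ``(1 - SID/100)**2``; with ``weighted=True`` (the default) the fit is
    weighted accordingly, which keeps the slope's confidence interval at
    its nominal level when the true SID spans a wide range.  Set
    ``weighted=False`` for an ordinary unweighted fit.
    """
    from .prediction import ols_fit, wls_fit

    cols = [c for c in estimates.sid_means.columns if c in predictor_values]
    x = pd.DataFrame({predictor: [predictor_values[c] for c in cols]},
                     index=cols)
    y = estimates.sid_means.loc[component, cols].to_numpy(dtype=float)
    response = f"SID_{component}"
    if not weighted:
        return ols_fit(x, y, response=response)
    undigested = np.maximum(1e-6, 1.0 - y / 100.0)
    return wls_fit(x, y, weights=1.0 / undigested ** 2, response=response)


def recovery_report(truth: TrialGroundTruth,
                    estimates: EstimationResult,
                    models: Mapping[str, RegressionModel] | None = None,
                    planted_slopes: Mapping[str, tuple[str, float]] | None = None
                    ) -> pd.DataFrame:
    """Per-component bias and RMSE of estimated SID against the truth.

    ``bias`` is the mean of (estimate - truth) over ingredients; ``rmse``
    the root-mean-square error.  When ``models`` and ``planted_slopes``
    (mapping a response component to ``(predictor, true_slope)``) are
    given, a ``slope_bias`` column reports fitted-minus-true slope for
    those components.
    """
    rows = []
    components = sorted({c for (_, c) in truth.true_sid})
    for comp in components:
        diffs = []
        for (diet_id, c), true_val in truth.true_sid.items():
            if c != comp:
                continue
            if comp not in estimates.sid_means.index or \
                    diet_id not in estimates.sid_means.columns:
                raise KeyError(f"no estimate for ({diet_id}, {comp})")
            diffs.append(estimates.sid_means.loc[comp, diet_id] - true_val)
        diffs = np.asarray(diffs)
        row = {"component": comp, "bias": float(diffs.mean()),
               "rmse": float(np.sqrt((diffs ** 2).mean()))}
        if models and planted_slopes and comp in planted_slopes:
            predictor, true_slope = planted_slopes[comp]
            model = models[comp]
            row["slope_bias"] = model.coefficients[predictor] - true_slope
        rows.append(row)
    return pd.DataFrame(rows).set_index("component")


def default_ground_truth(ingredients: Iterable[IngredientSample],
                         sid_table: pd.DataFrame,
                         endogenous: EndogenousLosses,
                         noise_cv: float = 0.05,
                         seed: int = 0) -> TrialGroundTruth:
    """Ground truth taking true SIDs from a published-style summary table.

    ``sid_table`` is a component-by-ingredient table of SID %; components
    or ingredients absent from the table are left out of the truth.
    """
    ingredients = list(ingredients)
    ids = [ing.sample_id for ing in ingredients]
    true_sid = {}
    for comp in sid_table.index:
        if comp not in COMPONENTS:
            continue
        for diet_id in ids:
            if diet_id in sid_table.columns:
                true_sid[(diet_id, comp)] = float(sid_table.loc[comp, diet_id])
    return TrialGroundTruth(
        true_sid=true_sid,
        true_endogenous={c: float(v) for c, v in endogenous.items()},
        noise_cv=noise_cv,
        seed=seed,
    )
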