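"""Marker-ratio ileal digestibility: AID, basal endogenous losses, SID.

The computation chain uses an indigestible marker (TiO2 included at 0.30%
of the diet).  With ``AA_d``/``T_d`` the component and marker concentrations
in ileal digesta and ``AA_r``/``T_r`` those in the diet (all g/kg DM):

* apparent ileal digestibility
  ``AID = [1 - (AA_d * T_r) / (AA_r * T_d)] * 100``;
* basal endogenous loss measured on a nitrogen-free diet
  ``IAA_end = AA_d * (T_r / T_d)`` (g per kg DM intake);
* standardized ileal digestibility
  ``SID = AID + 100 * IAA_end / AA_diet`` where ``AA_diet`` is the
  *dietary* concentration of the component in g/kg DM.

On the last equation: the conventional SID correction divides the
endogenous flow by the dietary concentration, and that is the reading
implemented here — it is the only one that reproduces the bundled SID
summary table from the AID table, diet assays and endogenous losses
(e.g. RSC1 crude protein: 70.29 + 100 * 21.24 / 194.93 = 81.19).

Diet assays arrive on an air-dry basis and digesta assays on a DM basis;
every quantity is converted to g/kg DM before entering the marker ratios.
No digestibility value is clamped: AID may be negative and SID may exceed
100 (proline routinely does, because its endogenous flow is large).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .feedtables import (
    DietAssay,
    DigestaObservation,
    EndogenousLosses,
)

__all__ = [
    "to_dm_basis",
    "compute_aid",
    "compute_endogenous",
    "compute_sid",
    "diet_concentration_dm",
    "aid_observations",
    "endogenous_from_nfree",
    "sid_observations",
    "drop_outliers_zscore",
    "TreatmentSummary",
    "summarize_treatments",
    "summarize_table",
]


def to_dm_basis(conc_airdry: float, dm_pct: float) -> float:
    """Convert an air-dry-basis concentration to a dry-matter basis.

    ``dm_pct`` is the dry-matter content in percent; the result keeps the
    units of ``conc_airdry`` scaled by ``100 / dm_pct``.
    """
    if dm_pct <= 0 or dm_pct > 100:
        raise ValueError(f"dm_pct must lie in (0, 100], got {dm_pct}")
    return conc_airdry / (dm_pct / 100.0)


def compute_aid(aa_d: float, t_d: float, aa_r: float, t_r: float) -> float:
    """Apparent ileal digestibility (%) from marker ratios.

    Parameters are the digesta component and marker concentrations and the
    diet component and marker concentrations, all in g/kg DM.  The result
    is scale-invariant: rescaling all four inputs by a common positive
    factor leaves it unchanged.  Values below 0 are possible and returned
    as-is.
    """
    if aa_r <= 0:
        raise ZeroDivisionError("diet concentration aa_r must be > 0")
    if t_d <= 0 or t_r <= 0:
        raise ZeroDivisionError("marker concentrations must be > 0")
    return 100.0 * (1.0 - (aa_d * t_r) / (aa_r * t_d))


def compute_endogenous(aa_d_nfree: float, t_r_nfree: float,
                       t_d_nfree: float) -> float:
    """Basal endogenous loss (g/kg DM intake) from a nitrogen-free diet.

    ``aa_d_nfree`` is the digesta concentration of the component,
    ``t_r_nfree`` / ``t_d_nfree`` the marker concentrations in the
    nitrogen-free diet and its digesta (all g/kg DM).
    """
    if t_d_nfree <= 0:
        raise ZeroDivisionError("digesta marker concentration must be > 0")
    return aa_d_nfree * (t_r_nfree / t_d_nfree)


def compute_sid(aid_pct: float, iaa_end: float, diet_conc_dm: float) -> float:
    """Standardized ileal digestibility (%) from AID and endogenous loss.

    ``diet_conc_dm`` is the dietary concentration of the component in
    g/kg DM; ``iaa_end`` the basal endogenous loss in g/kg DM intake.
    With nonnegative losses the result is never below ``aid_pct``.
    """
    if diet_conc_dm <= 0:
        raise ValueError("dietary concentration must be > 0")
    if iaa_end < 0:
        raise ValueError("endogenous loss must be >= 0")
    return aid_pct + 100.0 * iaa_end / diet_conc_dm


def diet_concentration_dm(diet: DietAssay, component: str) -> float:
    """Dietary concentration of ``component`` in g/kg DM.

    Air-dry percent -> g/kg air-dry (x10) -> g/kg DM (/ DM fraction).
    """
    return to_dm_basis(diet.component_pct(component) * 10.0, diet.dm_pct)


def diet_marker_dm(diet: DietAssay) -> float:
    """Marker (TiO2) concentration of the diet in g/kg DM."""
    return to_dm_basis(diet.marker_pct * 10.0, diet.dm_pct)


# ---------------------------------------------------------------------------
# Per-replicate pipeline


def aid_observations(observations: Iterable[DigestaObservation],
                     diets: Mapping[str, DietAssay]) -> pd.DataFrame:
    """Per pig-period AID for every assayed component.

    Returns a long-format frame with columns
    ``pig_id, period, diet_id, component, aid_pct``.  Components present in
    the digesta assay but absent from the diet assay are skipped (they
    cannot enter the marker ratio).
    """
    rows = []
    for obs in observations:
        diet = diets[obs.diet_id]
        t_r = diet_marker_dm(diet)
        for component, aa_d in obs.conc_dm.items():
            try:
                aa_r = diet_concentration_dm(diet, component)
            except KeyError:
                continue
            if aa_r <= 0:
                continue
            rows.append({
                "pig_id": obs.pig_id,
                "period": obs.period,
                "diet_id": obs.diet_id,
                "component": component,
                "aid_pct": compute_aid(aa_d, obs.marker_dm, aa_r, t_r),
            })
    return pd.DataFrame(rows)


def endogenous_from_nfree(nfree_observations: Iterable[DigestaObservation],
                          nfree_diet: DietAssay) -> EndogenousLosses:
    """Average basal endogenous losses over the nitrogen-free replicates."""
    t_r = diet_marker_dm(nfree_diet)
    per_component: dict[str, list[float]] = {}
    for obs in nfree_observations:
        for component, aa_d in obs.conc_dm.items():
            loss = compute_endogenous(aa_d, t_r, obs.marker_dm)
            per_component.setdefault(component, []).append(loss)
    if not per_component:
        raise ValueError("no nitrogen-free observations supplied")
    return EndogenousLosses(
        {c: float(np.mean(v)) for c, v in per_component.items()}
    )


def sid_observations(aid_table: pd.DataFrame,
                     diets: Mapping[str, DietAssay],
                     endogenous: EndogenousLosses) -> pd.DataFrame:
    """Attach the SID correction to a long-format AID table.

    Adds a ``sid_pct`` column: ``aid_pct + 100 * IAA_end / diet_conc_dm``
    per row, using each row's diet and component.
    """
    out = aid_table.copy()
    sid = np.empty(len(out))
    for i, (_, row) in enumerate(out.iterrows()):
        diet = diets[row["diet_id"]]
        conc = diet_concentration_dm(diet, row["component"])
        sid[i] = compute_sid(row["aid_pct"], endogenous[row["component"]], conc)
    out["sid_pct"] = sid
    return out


def drop_outliers_zscore(values: Sequence[float],
                         threshold: float = 3.0) -> np.ndarray:
    """Remove values whose |Z| exceeds ``threshold`` within the cell.

    Z-scores use the cell's own mean and sample SD.  A constant cell (SD 0)
    is returned unchanged.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        return arr
    sd = arr.std(ddof=1)
    if sd == 0:
        return arr
    z = (arr - arr.mean()) / sd
    return arr[np.abs(z) <= threshold]


# ---------------------------------------------------------------------------
# Treatment-level summaries (means, pooled SEM, ANOVA, letter groups)


@dataclass
class TreatmentSummary:
    """One component's treatment comparison across ingredient groups."""

    means: dict[str, float]
    sem: float
    p_value: float
    letters: dict[str, str]


def _compact_letters(group_names: Sequence[str],
                     means: Mapping[str, float],
                     significant: set[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display: groups sorted by descending mean; a maximal
    run of mutually non-different groups shares one letter."""
    ordered = sorted(group_names, key=lambda g: -means[g])
    runs: list[tuple[int, int]] = []
    i = 0
    n = len(ordered)
    while i < n:
        j = i
        while j + 1 < n and all(
            (ordered[a], ordered[b]) not in significant
            for a in range(i, j + 2) for b in range(a + 1, j + 2)
        ):
            j += 1
        runs.append((i, j))
        i += 1
    # keep only runs not nested in another run
    maximal = [r for r in runs
               if not any(o != r and o[0] <= r[0] and r[1] <= o[1] for o in runs)]
    maximal.sort()
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, list[str]] = {g: [] for g in ordered}
    for k, (lo, hi) in enumerate(maximal):
        for idx in range(lo, hi + 1):
            letters[ordered[idx]].append(alphabet[k % len(alphabet)])
    if len(maximal) == 1:
        # no contrasts significant anywhere: single shared letter
        return {g: "a" for g in ordered}
    return {g: "".join(v) for g, v in letters.items()}


def summarize_treatments(groups: Mapping[str, Sequence[float]],
                         alpha: float = 0.05) -> TreatmentSummary:
    """Compare per-replicate values across treatment groups.

    Computes per-group means, a single pooled SEM (``sqrt(MSE / n)`` with
    ``n`` the common replicate count), the one-way ANOVA F-test p-value and
    Tukey-HSD letter groups at ``alpha``.  Requires at least two groups
    with at least two replicates each.
    """
    if len(groups) < 2:
        raise ValueError("need at least two treatment groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")
    means = {g: float(arr.mean()) for g, arr in arrays.items()}
    n_total = sum(arr.size for arr in arrays.values())
    k = len(arrays)
    sse = sum(((arr - arr.mean()) ** 2).sum() for arr in arrays.values())
    mse = sse / (n_total - k)
    n_per = n_total / k
    sem = math.sqrt(mse / n_per)

    if mse == 0:
        identical = len({round(m, 12) for m in means.values()}) == 1
        p_value = 1.0 if identical else 0.0
        significant = set() if identical else {
            (a, b)
            for a, b in combinations(arrays, 2) if means[a] != means[b]
        }
        significant |= {(b, a) for a, b in list(significant)}
    else:
        _, p_value = stats.f_oneway(*arrays.values())
        values = np.concatenate(list(arrays.values()))
        labels = np.concatenate(
            [np.full(arr.size, g, dtype=object) for g, arr in arrays.items()]
        )
        tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
        significant = set()
        for (a, b), reject in zip(
            combinations(tukey.groupsunique, 2), tukey.reject
        ):
            if reject:
                significant.add((a, b))
                significant.add((b, a))
    letters = _compact_letters(list(arrays), means, significant)
    return TreatmentSummary(means=means, sem=float(sem),
                            p_value=float(p_value), letters=letters)


def summarize_table(replicates: pd.DataFrame,
                    value_column: str,
                    group_column: str = "diet_id",
                    component_column: str = "component",
                    alpha: float = 0.05,
                    zscore_threshold: float | None = 3.0) -> pd.DataFrame:
    """Build a digestibility summary table from per-replicate values.

    ``replicates`` is long-format (one row per pig-period x component).
    For each component: optional |Z|>threshold outlier exclusion within
    each treatment cell, then :func:`summarize_treatments`.  Returns a
    wide table indexed by component with one column per treatment group
    plus ``mean`` (grand mean of group means), ``sem``, ``p_value`` and
    per-group ``<group>_letters`` columns.
    """
    records = []
    group_ids = list(dict.fromkeys(replicates[group_column]))
    for component, chunk in replicates.groupby(component_column, sort=False):
        groups = {}
        for gid in group_ids:
            vals = chunk.loc[chunk[group_column] == gid, value_column].to_numpy()
            if vals.size == 0:
                continue
            if zscore_threshold is not None:
                vals = drop_outliers_zscore(vals, zscore_threshold)
            groups[gid] = vals
        summary = summarize_treatments(groups, alpha=alpha)
        row: dict[str, object] = {"component": component}
        row.update(summary.means)
        row["mean"] = float(np.mean(list(summary.means.values())))
        row["sem"] = summary.sem
        row["p_value"] = summary.p_value
        for gid, let in summary.letters.items():
            row[f"{gid}_letters"] = let
        records.append(row)
    return pd.DataFrame(records).set_index("component")
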