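"""Multi-lot composition summaries and the CV > 10% variability screen.

For each chemical component measured across ingredient lots the summary is
mean, min, max and the coefficient of variation
``CV% = 100 * SD / mean`` with the sample (n-1) standard deviation.
Components whose CV exceeds a threshold (10% by convention in feed
evaluation) are flagged as highly variable — for rapeseed cake these are
typically the fat and fiber fractions and the glucosinolates.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .feedtables import AMINO_ACIDS, PROXIMATE_COMPONENTS, IngredientSample

__all__ = [
    "summarize_samples",
    "flag_high_variation",
    "summarize_ingredients",
    "round_half_up",
]


def summarize_samples(values: Sequence[float]) -> dict[str, float]:
    """Mean, min, max and CV% of one component across lots.

    Requires at least two values (the sample SD needs a degree of freedom)
    and a nonzero mean (the CV is undefined otherwise).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values to summarize variability")
    mean = float(arr.mean())
    if mean == 0:
        raise ValueError("CV is undefined for a zero-mean component")
    sd = float(arr.std(ddof=1))
    return {
        "mean": mean,
        "min": float(arr.min()),
        "max": float(arr.max()),
        "cv_pct": 100.0 * sd / mean,
    }


def flag_high_variation(cv_by_component: Mapping[str, float],
                        threshold: float = 10.0) -> list[str]:
    """Components whose CV% strictly exceeds ``threshold``, in input order."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    for comp, cv in cv_by_component.items():
        if cv < 0:
            raise ValueError(f"CV for {comp} must be >= 0, got {cv}")
    return [c for c, cv in cv_by_component.items() if cv > threshold]


def summarize_ingredients(ingredients: Iterable[IngredientSample],
                          threshold: float = 10.0) -> pd.DataFrame:
    """Per-component summary table over a set of ingredient lots.

    Rows are the proximate components followed by the amino acids; columns
    ``mean, min, max, cv_pct, flagged``.  A component missing from some
    lots is summarized over the lots that report it.
    """
    ingredients = list(ingredients)
    rows = {}
    for comp in PROXIMATE_COMPONENTS:
        vals = [s.proximate[comp] for s in ingredients if comp in s.proximate]
        if len(vals) >= 2:
            rows[comp] = summarize_samples(vals)
    for aa in AMINO_ACIDS:
        vals = [s.aa_profile[aa] for s in ingredients if aa in s.aa_profile]
        if len(vals) >= 2:
            rows[aa] = summarize_samples(vals)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "component"
    flagged = set(flag_high_variation(table["cv_pct"].to_dict(), threshold))
    table["flagged"] = [c in flagged for c in table.index]
    return table


def round_half_up(value: float, decimals: int = 2) -> float:
    """Round half away from zero, matching the report-table convention."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
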