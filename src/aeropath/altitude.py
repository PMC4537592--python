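"""Probing the atmosphere: per-level wind models for flight duration.

For each atmospheric level, flight duration is modelled as a function of the
tailwind and crosswind components at that level; the minimal-AICc subset of
terms is selected per level, and levels are then compared by AICc to find
the altitude at which winds best explain the flight times.  Ocean-stage
models carry a nest-ID random intercept by default, coastal models do not.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixedlm import FitError, fit_lmm

__all__ = [
    "regression_aicc",
    "CandidateModel",
    "AltitudeScanResult",
    "fit_candidate",
    "candidate_term_sets",
    "best_subset_per_level",
    "altitude_scan",
    "SmallSampleError",
]

logger = logging.getLogger(__name__)

#: Candidate fixed-effect terms for the per-level wind models.
WIND_TERMS = ("tailwind", "crosswind", "tailwind:crosswind", "tailwind^2")

UNINFORMATIVE_MARGIN = 2.0


class SmallSampleError(ValueError):
    pass


def regression_aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample AIC: ``-2 loglik + 2k + 2k(k+1)/(n-k-1)``."""
    if n <= k + 1:
        raise SmallSampleError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def _term_column(df: pd.DataFrame, term: str) -> np.ndarray:
    if term == "tailwind":
        return df["tailwind_ms"].to_numpy(dtype=float)
    if term == "crosswind":
        return df["crosswind_ms"].to_numpy(dtype=float)
    if term == "tailwind^2":
        return df["tailwind_ms"].to_numpy(dtype=float) ** 2
    if term == "tailwind:crosswind":
        return (df["tailwind_ms"] * df["crosswind_ms"]).to_numpy(dtype=float)
    raise KeyError(term)


@dataclass
class CandidateModel:
    stage: str
    level_id: str
    terms: tuple[str, ...]
    random_effects: tuple[str, ...]
    llf: float
    k: int
    n: int
    aicc: float
    params: dict[str, float] = field(default_factory=dict)
    uninformative: bool = False

    @property
    def is_null(self) -> bool:
        return not self.terms


def fit_candidate(
    df: pd.DataFrame,
    terms: tuple[str, ...],
    *,
    stage: str = "",
    level_id: str = "",
    random_effects: tuple[str, ...] = (),
    response: str = "duration_min",
) -> CandidateModel:
    """ML fit of ``response ~ intercept + terms`` with optional random intercepts."""
    y = df[response].to_numpy(dtype=float)
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for t in terms:
        cols.append(_term_column(df, t))
        names.append(t)
    X = np.column_stack(cols)
    groups = {g: df[g].to_numpy() for g in random_effects}
    res = fit_lmm(y, X, names, groups)
    aicc = regression_aicc(res.llf, res.k, res.n)
    return CandidateModel(
        stage=stage,
        level_id=level_id,
        terms=tuple(terms),
        random_effects=tuple(random_effects),
        llf=res.llf,
        k=res.k,
        n=res.n,
        aicc=aicc,
        params=dict(zip(res.names, res.params)),
    )


def candidate_term_sets(terms: tuple[str, ...] = WIND_TERMS) -> list[tuple[str, ...]]:
    """All term subsets respecting marginality.

    The tailwind:crosswind interaction requires both main effects and the
    quadratic term requires linear tailwind.  The empty (null) set is included.
    """
    out = []
    for r in range(len(terms) + 1):
        for sub in itertools.combinations(terms, r):
            s = set(sub)
            if "tailwind:crosswind" in s and not {"tailwind", "crosswind"} <= s:
                continue
            if "tailwind^2" in s and "tailwind" not in s:
                continue
            out.append(sub)
    return out


def best_subset_per_level(
    df: pd.DataFrame,
    *,
    stage: str,
    level_id: str,
    random_effects: tuple[str, ...] = (),
    response: str = "duration_min",
    terms: tuple[str, ...] = WIND_TERMS,
) -> CandidateModel:
    """Minimal-AICc wind model at one level, guarded against the null.

    If no subset improves on the intercept-only model by at least two AICc
    units, the null model is returned flagged ``uninformative``.
    """
    fits: list[CandidateModel] = []
    for sub in candidate_term_sets(terms):
        try:
            fits.append(
                fit_candidate(
                    df, sub, stage=stage, level_id=level_id,
                    random_effects=random_effects, response=response,
                )
            )
        except FitError as exc:
            logger.warning(
                "candidate %s at level %s excluded: %s", sub, level_id, exc
            )
    if not fits:
        raise FitError(f"no candidate model could be fit at level {level_id}")
    null = next(f for f in fits if f.is_null)
    best = min(fits, key=lambda f: (f.aicc, len(f.terms)))
    if best.is_null or best.aicc > null.aicc - UNINFORMATIVE_MARGIN:
        null.uninformative = True
        return null
    return best


@dataclass
class AltitudeScanResult:
    stage: str
    table: pd.DataFrame  # level_id, altitude_m, terms, k, aicc, daicc, uninformative
    selected_level: str | None
    models: dict[str, CandidateModel]

    @property
    def selected_altitude_m(self) -> float | None:
        if self.selected_level is None:
            return None
        row = self.table.loc[self.table["level_id"] == self.selected_level]
        return float(row["altitude_m"].iloc[0])


def altitude_scan(
    annotations: pd.DataFrame,
    *,
    stage: str,
    random_effects: tuple[str, ...] = (),
    response: str = "duration_min",
    terms: tuple[str, ...] = WIND_TERMS,
) -> AltitudeScanResult:
    """Select the wind altitude whose best model has the lowest AICc.

    ``annotations`` is long-format with one row per segment x level and
    columns level_id, level_altitude_m, tailwind_ms, crosswind_ms plus the
    response and any random-effect grouping columns.  Ties are broken toward
    the lowest altitude; if every level is uninformative the scan returns a
    null selection with a warning.
    """
    levels = list(dict.fromkeys(annotations["level_id"]))
    if len(levels) < 2:
        raise ValueError("altitude scan needs at least two annotated levels")
    models: dict[str, CandidateModel] = {}
    rows = []
    for level in levels:
        sub = annotations.loc[annotations["level_id"] == level]
        alt = float(sub["level_altitude_m"].mean()) if "level_altitude_m" in sub else np.nan
        model = best_subset_per_level(
            sub, stage=stage, level_id=level,
            random_effects=random_effects, response=response, terms=terms,
        )
        models[level] = model
        rows.append(
            {
                "level_id": level,
                "altitude_m": alt,
                "terms": "+".join(model.terms) if model.terms else "1",
                "k": model.k,
                "loglik": model.llf,
                "aicc": model.aicc,
                "uninformative": model.uninformative,
            }
        )
    table = pd.DataFrame(rows)
    informative = table.loc[~table["uninformative"]]
    if informative.empty:
        logger.warning("all levels uninformative for %s stage; null selection", stage)
        selected = None
        table["daicc"] = table["aicc"] - table["aicc"].min()
    else:
        # sort by (aicc, altitude): ties resolved toward the lowest altitude
        order = informative.sort_values(["aicc", "altitude_m"], kind="mergesort")
        selected = str(order["level_id"].iloc[0])
        table["daicc"] = table["aicc"] - float(order["aicc"].iloc[0])
    return AltitudeScanResult(stage=stage, table=table, selected_level=selected, models=models)
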