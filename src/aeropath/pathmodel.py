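"""Multilevel piecewise path models.

A path model is a DAG of component regressions: age and flight stage act on
the wind components a bird experiences, and winds (plus possibly age/stage
directly) act on the response (flight duration or log groundspeed).  Each
endogenous variable gets its own maximum-likelihood mixed-effects regression
with nest-ID and individual-ID random intercepts.  Overall fit is summarized
by Fisher's C over the d-separation basis set, model size by the summed
component parameter count K, and model comparison by
``AICc = C + 2 K n / (n - K - 1)`` with Akaike weights.

Backward elimination removes terms whose deletion raises the path AICc by
less than two, wind-component submodel terms first, then response terms,
after pre-screening the tailwind:crosswind and tailwind:stage interactions
under the same rule.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .mixedlm import FitError, LMMResult, fit_lmm

__all__ = [
    "PathDAG",
    "ComponentModel",
    "PathFit",
    "Claim",
    "standardize_table",
    "basis_set",
    "fishers_c",
    "path_aicc",
    "akaike_weights",
    "fit_components",
    "fit_path",
    "backward_eliminate",
    "EliminationResult",
]

logger = logging.getLogger(__name__)

EXOGENOUS = ("age", "stage")
WIND_NODES = ("tailwind", "crosswind")

INTERACTION_TERMS = ("tailwind:crosswind", "tailwind:stage")

P_FLOOR = 1e-16


class PathModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# data preparation


def standardize_table(df: pd.DataFrame, *, require_groundspeed: bool = True) -> pd.DataFrame:
    """Build the standardized analysis table from reconstructed segments.

    Continuous variables (tailwind, crosswind, duration, log groundspeed)
    are z-scored; age is coded juvenile=0 / adult=1 and stage coast=0 /
    ocean=1 so coefficient signs match the reference coding.  Groundspeed is
    log-transformed before scaling.
    """
    out = pd.DataFrame(index=df.index.copy())
    for col in ("tag_id", "nest_id", "individual_id"):
        if col in df.columns:
            out[col] = df[col]
    age = df["age"]
    if age.dtype == object:
        bad = set(age.unique()) - {"adult", "juvenile"}
        if bad:
            raise PathModelError(f"unknown age classes {sorted(bad)}")
        out["age"] = (age == "adult").astype(float)
    else:
        out["age"] = age.astype(float)
    stage = df["stage"]
    if stage.dtype == object:
        bad = set(stage.unique()) - {"ocean", "coast"}
        if bad:
            raise PathModelError(f"unknown stages {sorted(bad)}")
        out["stage"] = (stage == "ocean").astype(float)
    else:
        out["stage"] = stage.astype(float)

    def zscore(x: pd.Series, name: str) -> pd.Series:
        x = x.astype(float)
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise PathModelError(f"zero-variance variable {name!r} cannot be standardized")
        return (x - x.mean()) / sd

    out["tailwind"] = zscore(df["tailwind_ms"], "tailwind")
    out["crosswind"] = zscore(df["crosswind_ms"], "crosswind")
    out["flight_duration"] = zscore(df["duration_min"], "flight_duration")
    if require_groundspeed or "groundspeed_ms" in df.columns:
        gs = df["groundspeed_ms"].astype(float)
        if (gs <= 0).any():
            raise PathModelError("groundspeed must be positive for the log transform")
        out["log_groundspeed"] = zscore(np.log(gs), "log_groundspeed")
    return out


def _term_column(df: pd.DataFrame, term: str) -> np.ndarray:
    if term == "tailwind^2":
        return df["tailwind"].to_numpy(dtype=float) ** 2
    if ":" in term:
        a, b = term.split(":")
        return (df[a] * df[b]).to_numpy(dtype=float)
    return df[term].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# DAG


@dataclass(frozen=True)
class PathDAG:
    """Directed acyclic system of component regressions.

    ``response`` names the response node ("flight_duration" or
    "log_groundspeed"); the three ``*_terms`` tuples list the fixed-effect
    terms of each endogenous node's regression.  ``tailwind^2`` and the
    interaction terms are modelling terms of the response submodel, not DAG
    nodes; the quadratic requires linear tailwind.
    """

    response: str = "flight_duration"
    tailwind_terms: tuple[str, ...] = ("stage", "age")
    crosswind_terms: tuple[str, ...] = ("stage", "age")
    response_terms: tuple[str, ...] = ("stage", "age", "tailwind", "crosswind", "tailwind^2")
    random_effects: tuple[str, ...] = ("nest_id", "individual_id")

    def __post_init__(self):
        for t in self.tailwind_terms + self.crosswind_terms:
            if t not in EXOGENOUS:
                raise PathModelError(f"wind submodels accept only exogenous terms, got {t!r}")
        s = set(self.response_terms)
        if "tailwind^2" in s and "tailwind" not in s:
            raise PathModelError("tailwind^2 requires the linear tailwind term")
        for it in INTERACTION_TERMS:
            if it in s:
                a, b = it.split(":")
                if a not in s or b not in s:
                    raise PathModelError(f"interaction {it} requires both main effects")

    @property
    def quadratic(self) -> bool:
        return "tailwind^2" in self.response_terms

    @property
    def nodes(self) -> tuple[str, ...]:
        return EXOGENOUS + WIND_NODES + (self.response,)

    @property
    def endogenous(self) -> tuple[str, ...]:
        return WIND_NODES + (self.response,)

    def parents(self, node: str) -> tuple[str, ...]:
        if node == "tailwind":
            return self.tailwind_terms
        if node == "crosswind":
            return self.crosswind_terms
        if node == self.response:
            return tuple(
                t for t in self.response_terms if t in EXOGENOUS + WIND_NODES
            )
        return ()

    def model_terms(self, node: str) -> tuple[str, ...]:
        if node == self.response:
            return self.response_terms
        return self.parents(node)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {(p, c) for c in self.endogenous for p in self.parents(c)}

    def equations(self) -> str:
        parts = []
        for node in self.endogenous:
            terms = self.model_terms(node)
            if not terms and node != self.response:
                continue  # printed tables omit intercept-only wind submodels
            rhs = " + ".join(terms) if terms else "1"
            parts.append(f"{node} ~ {rhs}")
        return "; ".join(parts)


# ---------------------------------------------------------------------------
# d-separation basis set


@dataclass(frozen=True)
class Claim:
    """Independence claim X _||_ Y | cond, tested as X's slope in Y ~ cond + X."""

    predictor: str
    target: str
    cond: tuple[str, ...]


def basis_set(nodes, edges, order=None) -> list[Claim]:
    """Shipley d-separation basis set of a DAG.

    One claim per non-adjacent pair with a defined causal order (pairs of
    parentless nodes are unconstrained and skipped).  The conditioning set is
    the union of both nodes' parents; the regression target is the causally
    later node (ties resolved by the supplied node order).
    """
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(g):
        raise PathModelError("path diagram must be acyclic")
    order = list(order if order is not None else nodes)
    rank = {n: i for i, n in enumerate(order)}
    claims: list[Claim] = []
    for x, y in itertools.combinations(sorted(g.nodes, key=rank.get), 2):
        if g.has_edge(x, y) or g.has_edge(y, x):
            continue
        px, py = set(g.predecessors(x)), set(g.predecessors(y))
        if not px and not py:
            continue  # both exogenous: no causal order defined
        # target = causally later node: a descendant, or the endogenous one,
        # or (both endogenous, unordered) the later in the supplied order
        if nx.has_path(g, x, y):
            pred, tgt = x, y
        elif nx.has_path(g, y, x):
            pred, tgt = y, x
        elif not px:
            pred, tgt = x, y
        elif not py:
            pred, tgt = y, x
        else:
            pred, tgt = x, y
        cond = tuple(sorted((px | py) - {pred, tgt}, key=rank.get))
        claims.append(Claim(predictor=pred, target=tgt, cond=cond))
    return claims


def path_claims(dag: PathDAG) -> list[Claim]:
    """Basis set of a path DAG, with the quadratic term attached.

    When the response model carries ``tailwind^2``, any claim conditioning on
    tailwind with the response as target also conditions on the quadratic.
    """
    claims = basis_set(dag.nodes, dag.edges, order=dag.nodes)
    if not dag.quadratic:
        return claims
    out = []
    for c in claims:
        if c.target == dag.response and "tailwind" in c.cond:
            out.append(replace(c, cond=c.cond + ("tailwind^2",)))
        else:
            out.append(c)
    return out


# ---------------------------------------------------------------------------
# information criteria


def fishers_c(p_values) -> float:
    """``C = -2 * sum(ln p)`` over the basis-set p-values (0 for an empty set)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return 0.0
    if np.any(p > 1.0) or np.any(~np.isfinite(p)):
        raise PathModelError("p-values must lie in (0, 1]")
    if np.any(p <= 0.0):
        warnings.warn("p-value <= 0 clipped to 1e-16 in Fisher's C", RuntimeWarning)
        p = np.clip(p, P_FLOOR, 1.0)
    return float(-2.0 * np.sum(np.log(p)))


def path_aicc(c: float, k: int, n: int) -> float:
    """Path-model AICc: ``C + 2 K n / (n - K - 1)``."""
    if n <= k + 1:
        raise PathModelError(f"path AICc undefined for n={n}, K={k}")
    return c + 2.0 * k * n / (n - k - 1.0)


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights ``exp(-d_i/2) / sum_j exp(-d_j/2)`` (overflow-safe)."""
    a = np.asarray(list(aicc_values), dtype=float)
    if a.size == 0 or np.any(~np.isfinite(a)):
        raise PathModelError("AICc values must be finite and nonempty")
    d = a - a.min()
    w = np.exp(-0.5 * d)
    return w / w.sum()


# ---------------------------------------------------------------------------
# fitting


@dataclass
class ComponentModel:
    node: str
    terms: tuple[str, ...]
    result: LMMResult

    @property
    def k(self) -> int:
        return self.result.k

    @property
    def llf(self) -> float:
        return self.result.llf


@dataclass
class PathFit:
    dag: PathDAG
    components: dict[str, ComponentModel]
    claims: list[Claim]
    claim_pvalues: list[float]
    fishers_c: float
    k: int
    n: int
    aicc: float

    def coefficient_table(self) -> pd.DataFrame:
        rows = []
        for node, comp in self.components.items():
            res = comp.result
            for name, est, se, p in zip(res.names, res.params, res.se, res.pvalues):
                rows.append(
                    {"node": node, "term": name, "estimate": est, "se": se, "p": p}
                )
        return pd.DataFrame(rows)


class _FitCache:
    """Memoizes mixed-model fits on one analysis table across candidate DAGs."""

    def __init__(self, table: pd.DataFrame, random_effects: tuple[str, ...]):
        self.table = table
        self.random_effects = tuple(g for g in random_effects if g in table.columns)
        if len(self.random_effects) < len(random_effects):
            missing = set(random_effects) - set(self.random_effects)
            logger.warning("random effects %s absent from table; dropped", sorted(missing))
        self._groups = {g: table[g].to_numpy() for g in self.random_effects}
        self._cache: dict[tuple, LMMResult] = {}

    def fit(self, node: str, terms: tuple[str, ...]) -> LMMResult:
        key = (node, tuple(terms))
        if key not in self._cache:
            y = self.table[node].to_numpy(dtype=float)
            cols = [np.ones(len(self.table))]
            names = ["intercept"]
            for t in terms:
                cols.append(_term_column(self.table, t))
                names.append(t)
            self._cache[key] = fit_lmm(y, np.column_stack(cols), names, self._groups)
        return self._cache[key]


def fit_components(
    dag: PathDAG, table: pd.DataFrame, cache: _FitCache | None = None
) -> dict[str, ComponentModel]:
    """One ML mixed-effects fit per endogenous node of the DAG."""
    cache = cache or _FitCache(table, dag.random_effects)
    out: dict[str, ComponentModel] = {}
    for node in dag.endogenous:
        terms = dag.model_terms(node)
        res = cache.fit(node, terms)
        if res.singular:
            logger.info("%s ~ %s: variance on boundary for %s", node, terms, res.singular)
        out[node] = ComponentModel(node=node, terms=terms, result=res)
    return out


def fit_path(dag: PathDAG, table: pd.DataFrame, cache: _FitCache | None = None) -> PathFit:
    """Fit all component models and score the DAG by Fisher's C and path AICc."""
    cache = cache or _FitCache(table, dag.random_effects)
    components = fit_components(dag, table, cache)
    claims = path_claims(dag)
    pvals = []
    for c in claims:
        res = cache.fit(c.target, c.cond + (c.predictor,))
        pvals.append(res.coef_pvalue(c.predictor))
    c_stat = fishers_c(pvals)
    k = sum(comp.k for comp in components.values())
    n = len(table)
    return PathFit(
        dag=dag,
        components=components,
        claims=claims,
        claim_pvalues=pvals,
        fishers_c=c_stat,
        k=k,
        n=n,
        aicc=path_aicc(c_stat, k, n),
    )


# ---------------------------------------------------------------------------
# backward elimination


@dataclass
class EliminationResult:
    final: PathFit
    selection_table: pd.DataFrame
    history: list[PathFit] = field(default_factory=list)


def _drop_response_term(dag: PathDAG, term: str) -> PathDAG:
    drop = {term}
    if term == "tailwind":
        drop.add("tailwind^2")  # the quadratic rides on the linear term
    return replace(dag, response_terms=tuple(t for t in dag.response_terms if t not in drop))


def _drop_wind_term(dag: PathDAG, node: str, term: str) -> PathDAG:
    if node == "tailwind":
        return replace(dag, tailwind_terms=tuple(t for t in dag.tailwind_terms if t != term))
    return replace(dag, crosswind_terms=tuple(t for t in dag.crosswind_terms if t != term))


def _removable_response_terms(dag: PathDAG) -> list[str]:
    present = set(dag.response_terms)
    out = []
    for t in dag.response_terms:
        if t == "tailwind^2":
            continue  # the quadratic is a fixed modelling choice, not an edge;
            # it is removed together with the tailwind edge it rides on
        if t == "tailwind" and any(it in present for it in INTERACTION_TERMS):
            continue
        if t in ("crosswind", "stage") and any(
            it in present and t in it.split(":") for it in INTERACTION_TERMS
        ):
            continue
        out.append(t)
    return out


def backward_eliminate(
    table: pd.DataFrame,
    response: str = "flight_duration",
    *,
    random_effects: tuple[str, ...] = ("nest_id", "individual_id"),
    threshold: float = 2.0,
    include_interactions: bool = True,
    quadratic: bool | None = None,
) -> EliminationResult:
    """Backward-eliminate the full path model down to its parsimonious form.

    Starting from the global model (age and stage on both wind components;
    age, stage and winds on the response, plus the two interactions), each
    interaction is pre-screened and dropped if its deletion raises the path
    AICc by less than ``threshold``; then wind-submodel terms and finally
    response terms are removed greedily under the same rule.  Every candidate
    visited is recorded in a selection table alongside the null model (the
    final model with its response paths removed), with delta-AICc, Akaike
    weights and Fisher's C.

    The quadratic tailwind term is a fixed modelling choice carried by every
    candidate (default: on for flight duration, off for groundspeed) rather
    than an elimination candidate: the d-separation C statistic only
    constrains missing edges, so curvature is decided upstream, by the
    altitude-probe stage of the analysis.
    """
    if quadratic is None:
        quadratic = response == "flight_duration"
    base_terms = ("stage", "age", "tailwind", "crosswind") + (
        ("tailwind^2",) if quadratic else ()
    )
    full_terms = base_terms + (INTERACTION_TERMS if include_interactions else ())
    dag = PathDAG(
        response=response,
        tailwind_terms=("stage", "age"),
        crosswind_terms=("stage", "age"),
        response_terms=full_terms,
        random_effects=random_effects,
    )
    cache = _FitCache(table, random_effects)
    visited: dict[PathDAG, PathFit] = {}

    def score(d: PathDAG) -> PathFit:
        if d not in visited:
            visited[d] = fit_path(d, table, cache)
        return visited[d]

    current = score(dag)

    # pre-screen interactions
    for it in INTERACTION_TERMS:
        if it not in current.dag.response_terms:
            continue
        trial = score(_drop_response_term(current.dag, it))
        if trial.aicc < current.aicc + threshold:
            logger.info("interaction %s dropped (dAICc=%.2f)", it, trial.aicc - current.aicc)
            current = trial

    # phase 1: wind-component submodel terms
    while True:
        candidates = []
        for node in WIND_NODES:
            for term in current.dag.parents(node):
                candidates.append(score(_drop_wind_term(current.dag, node, term)))
        if not candidates:
            break
        best = min(candidates, key=lambda f: f.aicc)
        if best.aicc < current.aicc + threshold:
            current = best
        else:
            break

    # phase 2: response submodel terms
    while True:
        candidates = [
            score(_drop_response_term(current.dag, t))
            for t in _removable_response_terms(current.dag)
        ]
        if not candidates:
            break
        best = min(candidates, key=lambda f: f.aicc)
        if best.aicc < current.aicc + threshold:
            current = best
        else:
            break

    # null model: final model with all paths to the response removed
    null_dag = replace(current.dag, response_terms=())
    score(null_dag)

    fits = sorted(visited.values(), key=lambda f: f.aicc)
    aiccs = [f.aicc for f in fits]
    w = akaike_weights(aiccs)
    table_rows = pd.DataFrame(
        {
            "model_equations": [f.dag.equations() for f in fits],
            "K": [f.k for f in fits],
            "AICc": aiccs,
            "dAICc": [a - aiccs[0] for a in aiccs],
            "W": w,
            "cumW": np.cumsum(w),
            "fishers_C": [f.fishers_c for f in fits],
        }
    )
    return EliminationResult(final=current, selection_table=table_rows, history=fits)
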