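"""Piecewise structural-equation modelling.

Each response variable gets its own component regression (OLS, a linear mixed
model with a random-intercept factor, or a SAR error model); the directed
graph is tested globally by Shipley's d-separation procedure: every
non-adjacent ordered pair contributes an independence claim conditioned on
the parents of both variables, the claim p-values combine into Fisher's
C = -2 sum ln p with df = 2k, and C is referred to an upper-tail chi-square.

Graphs are specified as edge lists (``A -> B`` directed, ``A ~~ B``
correlated errors) or as mappings {response: [parents]}.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import chi2

logger = logging.getLogger(__name__)


def parse_graph(text: str) -> tuple[nx.DiGraph, set[frozenset]]:
    """Parse a one-edge-per-line graph spec: 'A -> B' and 'A ~~ B' lines."""
    g = nx.DiGraph()
    corr: set[frozenset] = set()
    for line in text.splitlines():
        line = line.split("#")[0].strip()
        if not line:
            continue
        if "->" in line:
            a, b = (s.strip() for s in line.split("->"))
            g.add_edge(a, b)
        elif "~~" in line:
            a, b = (s.strip() for s in line.split("~~"))
            corr.add(frozenset((a, b)))
        else:
            raise ValueError(f"unparseable graph line: {line!r}")
    return g, corr


@dataclass
class ComponentSpec:
    """How one response is modelled: family plus optional extras."""

    family: str = "ols"                      # ols | lmm | sar
    group: str | None = None                 # random-intercept column for lmm
    weights: object | None = None            # SpatialWeights for sar


@dataclass
class PathModel:
    graph: nx.DiGraph
    coefficients: dict = field(default_factory=dict)   # (parent, child) -> beta
    pvalues: dict = field(default_factory=dict)
    r2: dict = field(default_factory=dict)
    aic: dict = field(default_factory=dict)
    correlated_errors: set = field(default_factory=set)

    def edge_frame(self) -> pd.DataFrame:
        rows = [{"source": a, "target": b, "estimate": v,
                 "p": self.pvalues.get((a, b), np.nan)}
                for (a, b), v in self.coefficients.items()]
        return pd.DataFrame(rows)


def _fit_component(data: pd.DataFrame, response: str, parents: list,
                   spec: ComponentSpec) -> dict:
    """Fit one component model; returns coefficients, p-values, AIC, R2."""
    y = data[response].to_numpy(dtype=float)
    n = len(y)
    if spec.family == "sar":
        from .regression import sar_error_fit
        X = np.column_stack([np.ones(n)] + [data[p].to_numpy(dtype=float) for p in parents])
        fit = sar_error_fit(X, y, spec.weights, names=["Intercept"] + list(parents))
        summ = fit.summary().set_index("term")
        trend = X @ fit.beta
        r2 = float(np.corrcoef(trend, y)[0, 1] ** 2) if np.std(trend) > 0 else 0.0
        return {"coef": summ["estimate"].to_dict(), "p": summ["p"].to_dict(),
                "aic": fit.aic, "r2": r2}
    if spec.family == "lmm" and spec.group is not None:
        import warnings

        import statsmodels.formula.api as smf
        from statsmodels.tools.sm_exceptions import ConvergenceWarning
        rhs = " + ".join(parents) if parents else "1"
        model = smf.mixedlm(f"{response} ~ {rhs}", data, groups=data[spec.group])
        with warnings.catch_warnings():
            # near-zero random-effect variance during subset enumeration is
            # expected and handled by AIC; silence the boundary warnings
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            fit = model.fit(reml=False)
        fe = list(model.exog_names)
        var_fixed = float(np.var(model.exog @ fit.params[fe].to_numpy()))
        var_group = float(fit.cov_re.to_numpy().sum()) if fit.cov_re.size else 0.0
        r2 = var_fixed / (var_fixed + var_group + float(fit.scale))
        return {"coef": fit.params[fe].to_dict(), "p": fit.pvalues[fe].to_dict(),
                "aic": float(fit.aic), "r2": r2}
    import statsmodels.api as sm
    X = sm.add_constant(data[list(parents)].astype(float)) if parents else \
        pd.DataFrame({"const": np.ones(n)}, index=data.index)
    fit = sm.OLS(y, X).fit()
    coef = {(k if k != "const" else "Intercept"): v for k, v in fit.params.items()}
    pv = {(k if k != "const" else "Intercept"): v for k, v in fit.pvalues.items()}
    return {"coef": coef, "p": pv, "aic": float(fit.aic), "r2": float(fit.rsquared)}


def select_component_models(candidates: dict[str, list], data: pd.DataFrame,
                            specs: dict[str, ComponentSpec] | None = None,
                            correlated_errors: set | None = None) -> PathModel:
    """Exhaustive all-subset AIC selection of each response's parent set.

    ``candidates`` maps each response to its candidate parents; for every
    response all 2^k parent subsets are fitted and the minimum-AIC subset is
    kept (ties broken by fewer parameters, then lexicographic term order).
    The resulting directed graph must be acyclic.
    """
    specs = specs or {}
    g = nx.DiGraph()
    for resp, parents in candidates.items():
        g.add_node(resp)
        for p in parents:
            g.add_edge(p, resp)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("candidate graph is cyclic")

    model = PathModel(graph=nx.DiGraph(), correlated_errors=correlated_errors or set())
    model.graph.add_nodes_from(g.nodes)
    for resp, parents in candidates.items():
        spec = specs.get(resp, ComponentSpec())
        best = None
        for k in range(len(parents) + 1):
            for subset in itertools.combinations(sorted(parents), k):
                try:
                    fit = _fit_component(data, resp, list(subset), spec)
                except Exception as exc:
                    logger.info("skipped %s ~ %s (%s)", resp, subset, exc)
                    continue
                key = (fit["aic"], len(subset), subset)
                if best is None or key < best[0]:
                    best = (key, subset, fit)
        if best is None:
            raise RuntimeError(f"every candidate submodel failed for {resp!r}")
        _, subset, fit = best
        for p in subset:
            model.graph.add_edge(p, resp)
            model.coefficients[(p, resp)] = fit["coef"][p]
            model.pvalues[(p, resp)] = fit["p"][p]
        model.r2[resp] = fit["r2"]
        model.aic[resp] = fit["aic"]
    return model


def basis_set(graph: nx.DiGraph, correlated_errors: set | None = None) -> list:
    """Shipley's d-separation basis: independence claims for the DAG.

    One claim per non-adjacent pair, ordered so the non-ancestor is the
    response, with conditioning set = parents of both variables.  Pairs
    declared as correlated errors are excluded.
    Returns a list of (x, y, conditioning set) meaning 'y independent of x'.
    """
    if not nx.is_directed_acyclic_graph(graph):
        raise ValueError("d-separation basis requires a DAG")
    corr = {frozenset(p) for p in (correlated_errors or set())}
    order = {v: i for i, v in enumerate(nx.topological_sort(graph))}
    claims = []
    nodes = sorted(graph.nodes, key=order.get)
    for a, b in itertools.combinations(nodes, 2):
        if graph.has_edge(a, b) or graph.has_edge(b, a):
            continue
        if frozenset((a, b)) in corr:
            continue
        x, y = (a, b) if order[a] < order[b] else (b, a)
        cond = sorted(set(graph.predecessors(x)) | set(graph.predecessors(y)))
        claims.append((x, y, cond))
    return claims


@dataclass
class DsepResult:
    claims: list
    pvalues: list
    C: float
    df: int
    p: float


def dsep_pvalue(data: pd.DataFrame, x: str, y: str, cond: list,
                spec: ComponentSpec | None = None) -> float:
    """p-value of the would-be edge x -> y given the conditioning set.

    Fits y ~ x + cond in the response's component family and returns the
    two-sided p of the x coefficient.
    """
    spec = spec or ComponentSpec()
    parents = [x] + [c for c in cond if c != x]
    fit = _fit_component(data, y, parents, spec)
    return float(fit["p"][x])


def fishers_c(pvalues) -> DsepResult:
    """Fisher's C = -2 sum ln p over k claims, df = 2k, chi-square upper tail.

    Zero p-values are floored at the smallest positive float (flagged); an
    empty claim list yields C = 0, df = 0, p = 1 (saturated model, vacuous fit).
    """
    ps = np.asarray(list(pvalues), dtype=float)
    if ps.size == 0:
        return DsepResult(claims=[], pvalues=[], C=0.0, df=0, p=1.0)
    if np.any((ps < 0) | (ps > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(ps == 0):
        logger.warning("flooring %d zero p-values at the machine minimum", int((ps == 0).sum()))
        ps = np.maximum(ps, np.finfo(float).tiny)
    C = float(-2.0 * np.sum(np.log(ps)))
    df = 2 * ps.size
    return DsepResult(claims=[], pvalues=list(ps), C=C, df=df,
                      p=float(chi2.sf(C, df)))


def dsep_test(model: PathModel, data: pd.DataFrame,
              specs: dict[str, ComponentSpec] | None = None) -> DsepResult:
    """Run the full d-separation test of a fitted path model on data."""
    specs = specs or {}
    claims = basis_set(model.graph, model.correlated_errors)
    ps = [dsep_pvalue(data, x, y, cond, specs.get(y)) for x, y, cond in claims]
    res = fishers_c(ps)
    return DsepResult(claims=claims, pvalues=ps, C=res.C, df=res.df, p=res.p)


def standardized_effects(model: PathModel) -> pd.DataFrame:
    """Direct, indirect, and total effects for every ordered variable pair.

    Direct = edge coefficient; indirect = sum over all directed paths of the
    product of path coefficients (excluding the direct edge); total = sum.
    Coefficients are assumed standardized (variables z-scored before fitting).
    """
    g = model.graph
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("effects require an acyclic model")
    nodes = list(nx.topological_sort(g))
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    B = np.zeros((n, n))
    for (a, b), v in model.coefficients.items():
        if a in idx and b in idx:
            B[idx[a], idx[b]] = v
    # total effects: sum over all path lengths = sum_{k>=1} B^k = B (I - B)^-1
    total = B @ np.linalg.inv(np.eye(n) - B)
    rows = []
    for a in nodes:
        for b in nodes:
            if a == b:
                continue
            t = total[idx[a], idx[b]]
            d = B[idx[a], idx[b]]
            if t == 0 and d == 0:
                continue
            rows.append({"source": a, "target": b, "direct": d,
                         "indirect": t - d, "total": t})
    return pd.DataFrame(rows)
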