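"""Graph covariates and zero-inflated binomial regression of overlaps.

Per adjacency edge, the number of genomes with an overlap (y) out of the
genomes with the adjacency (n) is modelled as a zero-inflated binomial:

    P(Y = y) = phi * I(y = 0) + (1 - phi) * C(n, y) p^y (1 - p)^(n - y)

with logit(p) = X beta and an intercept-only inflation probability phi.
Node metrics (degree, triangles, local transitivity, eigenvector
centrality, genome counts) are computed on the undirected simple
projection of adjacency edges and summed over the two endpoints of every
edge to form covariates.  A bidirectional stepwise search bounded by the
intercept-only and full models picks the covariate subset by AIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logit

from .graph import AdjacencyGraph

CANDIDATE_COVARIATES = ("n_genomes", "degree", "triangles", "transitivity", "centrality")


def _undirected_projection(graph: AdjacencyGraph) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(graph.nodes)
    for (u, v) in graph.adj_edges:
        if u != v:
            G.add_edge(u, v)
    return G


def _eigenvector_centrality(G: nx.Graph) -> Dict[int, float]:
    """Leading eigenvector of the largest component's adjacency matrix.

    Power iteration to 1e-10, L2-normalized over all nodes; nodes outside
    the largest connected component get 0.
    """
    cent = {n: 0.0 for n in G.nodes}
    if G.number_of_edges() == 0:
        return cent
    comp = max(nx.connected_components(G), key=lambda c: (len(c), sorted(c)))
    nodes = sorted(comp)
    A = nx.to_numpy_array(G.subgraph(nodes), nodelist=nodes)
    # Shift by I so the dominant eigenvalue is strictly largest in modulus
    # (plain power iteration oscillates on bipartite graphs); the leading
    # eigenvector is unchanged.
    A = A + np.eye(len(nodes))
    x = np.ones(len(nodes)) / np.sqrt(len(nodes))
    for _ in range(10000):
        x_new = A @ x
        norm = np.linalg.norm(x_new)
        if norm == 0:
            break
        x_new /= norm
        if np.max(np.abs(x_new - x)) < 1e-10:
            x = x_new
            break
        x = x_new
    x = np.abs(x)
    x /= np.linalg.norm(x)
    for n, v in zip(nodes, x):
        cent[n] = float(v)
    return cent


def node_metrics(graph: AdjacencyGraph) -> pd.DataFrame:
    """Per-node degree, triangles, local transitivity, eigenvector
    centrality and genome counts on the undirected simple projection."""
    if not graph.nodes:
        raise ValueError("empty graph")
    G = _undirected_projection(graph)
    tri = nx.triangles(G)
    clust = nx.clustering(G)
    cent = _eigenvector_centrality(G)
    rows = [
        dict(node=n, n_genomes=graph.n_genomes.get(n, 0), degree=G.degree(n),
             triangles=tri[n], transitivity=clust[n], centrality=cent[n])
        for n in sorted(G.nodes)
    ]
    return pd.DataFrame(rows).set_index("node")


def edge_covariates(
    graph: AdjacencyGraph,
    metrics: Optional[pd.DataFrame] = None,
    genomes_covariate: str = "edge_n",
) -> pd.DataFrame:
    """One row per directed adjacency edge: y, n and endpoint-summed covariates.

    ``genomes_covariate='edge_n'`` (default) takes the "total size"
    covariate to be the edge's own adjacency weight (genomes with the
    adjacent pair); ``'node_sum'`` instead sums the per-node genome counts
    of the two endpoints.
    """
    if metrics is None:
        metrics = node_metrics(graph)
    if genomes_covariate not in ("edge_n", "node_sum"):
        raise ValueError(f"unknown genomes_covariate {genomes_covariate!r}")
    rows = []
    for (u, v), n in sorted(graph.adj_edges.items()):
        y = graph.ovl_edges.get((u, v), 0)
        row = dict(u=u, v=v, y=y, n=n)
        for m in ("degree", "triangles", "transitivity", "centrality"):
            row[m] = float(metrics.loc[u, m] + metrics.loc[v, m])
        if genomes_covariate == "edge_n":
            row["n_genomes"] = float(n)
        else:
            row["n_genomes"] = float(metrics.loc[u, "n_genomes"] + metrics.loc[v, "n_genomes"])
        rows.append(row)
    return pd.DataFrame(rows)


def zib_loglik(
    y: np.ndarray, n: np.ndarray, X: np.ndarray, beta: np.ndarray, phi: float
) -> float:
    """Zero-inflated binomial log-likelihood, log-sum-exp stabilized."""
    if not 0.0 <= phi < 1.0:
        raise ValueError(f"phi must be in [0,1), got {phi}")
    y = np.asarray(y, float)
    n = np.asarray(n, float)
    X = np.asarray(X, float)
    eta = X @ np.asarray(beta, float)
    # log p and log(1-p) without overflow
    log_p = -np.logaddexp(0.0, -eta)
    log_q = -np.logaddexp(0.0, eta)
    log_binom = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1) + y * log_p + (n - y) * log_q
    with np.errstate(divide="ignore"):
        log_phi = np.log(phi)
        log_1mphi = np.log1p(-phi)
    ll = np.where(
        y == 0,
        np.logaddexp(log_phi, log_1mphi + n * log_q),
        log_1mphi + log_binom,
    )
    return float(ll.sum())


@dataclass
class ZIBResults:
    """Fit results: estimates, uncertainties, diagnostics and summary()."""

    model: "ZeroInflatedBinomial"
    params: np.ndarray  # (beta..., eta_phi) on the standardized scale
    loglik: float
    converged: bool
    cov_params: Optional[np.ndarray]
    message: str = ""

    @property
    def k_params(self) -> int:
        return len(self.params)

    @property
    def beta(self) -> np.ndarray:
        return self.params[:-1]

    @property
    def phi(self) -> float:
        return float(expit(self.params[-1]))

    @property
    def aic(self) -> float:
        return 2 * self.k_params - 2 * self.loglik

    @property
    def bse(self) -> np.ndarray:
        if self.cov_params is None:
            return np.full(self.k_params, np.nan)
        with np.errstate(invalid="ignore"):
            return np.sqrt(np.diag(self.cov_params))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        se = self.bse
        return np.column_stack([self.params - z * se, self.params + z * se])

    @property
    def boundary(self) -> List[str]:
        """Flags for estimates pinned at the parameter-space edge."""
        flags = []
        p = expit(self.model.X @ self.beta)
        if np.all(p > 1 - 1e-6):
            flags.append("p_hat_at_1")
        if np.all(p < 1e-6):
            flags.append("p_hat_at_0")
        if self.phi < 1e-6:
            flags.append("phi_at_0")
        return flags

    def unstandardized_beta(self) -> np.ndarray:
        """Coefficients on the original covariate scale (intercept adjusted)."""
        beta = self.beta.copy()
        mu, sd = self.model.covariate_means, self.model.covariate_sds
        raw = beta.copy()
        if len(beta) > 1:
            raw[1:] = beta[1:] / sd
            raw[0] = beta[0] - np.sum(beta[1:] * mu / sd)
        return raw

    def report(self) -> pd.DataFrame:
        names = list(self.model.exog_names) + ["logit_phi"]
        ci = self.conf_int()
        return pd.DataFrame(
            dict(term=names, estimate=self.params, se=self.bse,
                 ci_low=ci[:, 0], ci_high=ci[:, 1])
        )

    def summary(self) -> str:
        rep = self.report()
        lines = [
            "Zero-inflated binomial regression",
            f"  edges: {len(self.model.y)}   loglik: {self.loglik:.4f}   "
            f"AIC: {self.aic:.4f}   converged: {self.converged}",
            f"  phi (zero inflation): {self.phi:.4f}",
        ]
        if self.boundary:
            lines.append(f"  boundary flags: {', '.join(self.boundary)}")
        lines.append(rep.to_string(index=False, float_format=lambda v: f"{v: .4f}"))
        return "\n".join(lines)


class ZeroInflatedBinomial:
    """Zero-inflated binomial model of overlap counts on adjacency edges.

    Parameters
    ----------
    y, n : arrays of successes and trials per edge (0 <= y <= n, n >= 1).
    X : covariate matrix *without* intercept column, or None for
        intercept-only; columns are z-scored before fitting (means/sds
        kept for back-transformation) unless ``standardize=False``.
    """

    def __init__(
        self,
        y: Sequence[float],
        n: Sequence[float],
        X: Optional[np.ndarray] = None,
        exog_names: Optional[Sequence[str]] = None,
        standardize: bool = True,
        fix_phi: Optional[float] = None,
    ) -> None:
        self.y = np.asarray(y, float)
        self.n = np.asarray(n, float)
        if np.any(self.y < 0) or np.any(self.y > self.n) or np.any(self.n < 1):
            raise ValueError("require 0 <= y <= n and n >= 1")
        raw = np.empty((len(self.y), 0)) if X is None else np.asarray(X, float)
        if raw.ndim == 1:
            raw = raw[:, None]
        self.covariate_means = raw.mean(axis=0) if raw.size else np.array([])
        sds = raw.std(axis=0, ddof=0) if raw.size else np.array([])
        self.covariate_sds = np.where(sds == 0, 1.0, sds) if sds.size else sds
        Z = (raw - self.covariate_means) / self.covariate_sds if (standardize and raw.size) else raw
        self.X = np.column_stack([np.ones(len(self.y)), Z])
        names = list(exog_names) if exog_names is not None else [f"x{i+1}" for i in range(raw.shape[1])]
        self.exog_names = ["intercept"] + names
        self.fix_phi = fix_phi
        if len(self.y) < self.X.shape[1] + 2:
            raise ValueError("need at least p + 2 edges for p covariates")

    @classmethod
    def from_edge_data(
        cls, edges: pd.DataFrame, covariates: Sequence[str] = (), **kw
    ) -> "ZeroInflatedBinomial":
        X = edges[list(covariates)].to_numpy() if covariates else None
        return cls(edges["y"], edges["n"], X, exog_names=list(covariates), **kw)

    def loglike(self, params: np.ndarray) -> float:
        beta, eta_phi = params[:-1], params[-1]
        phi = float(expit(eta_phi)) if self.fix_phi is None else self.fix_phi
        phi = min(phi, 1 - 1e-12)
        return zib_loglik(self.y, self.n, self.X, beta, phi)

    def score(self, params: np.ndarray) -> np.ndarray:
        """Analytic gradient of the log-likelihood."""
        beta, eta_phi = params[:-1], params[-1]
        phi = float(expit(eta_phi)) if self.fix_phi is None else self.fix_phi
        phi = min(max(phi, 1e-12), 1 - 1e-12)
        eta = self.X @ beta
        p = expit(eta)
        log_q = -np.logaddexp(0.0, eta)
        zero = self.y == 0
        # mixture responsibility of the binomial branch for y = 0 edges
        log_B = np.log1p(-phi) + self.n * log_q
        log_S = np.logaddexp(np.log(phi), log_B)
        w = np.exp(log_B - log_S)
        deta = np.where(zero, -w * self.n * p, self.y - self.n * p)
        g_beta = self.X.T @ deta
        if self.fix_phi is not None:
            g_phi = 0.0
        else:
            # d/d logit(phi); phi(1-phi) is the Jacobian of the logistic map
            g_phi = float(
                np.sum(
                    np.where(
                        zero,
                        phi * (1 - phi) * (1 - np.exp(self.n * log_q)) / np.exp(log_S),
                        -phi,
                    )
                )
            )
        return np.append(g_beta, g_phi)

    def fit(self, start: Optional[np.ndarray] = None, maxiter: int = 500) -> ZIBResults:
        """Maximize the likelihood by quasi-Newton (BFGS) with the
        analytic score.

        Non-convergence is reported in the results (converged flag and
        optimizer message), never raised.
        """
        p = self.X.shape[1]
        if start is None:
            frac = (self.y.sum() + 0.5) / (self.n.sum() + 1.0)
            start = np.zeros(p + 1)
            start[0] = logit(np.clip(frac, 1e-6, 1 - 1e-6))
            zfrac = np.mean(self.y == 0)
            start[-1] = logit(np.clip(zfrac / 2 + 1e-3, 1e-6, 1 - 1e-6))

        def nll(params: np.ndarray) -> float:
            val = self.loglike(params)
            return np.inf if not np.isfinite(val) else -val

        def njac(params: np.ndarray) -> np.ndarray:
            return -self.score(params)

        res = minimize(nll, start, jac=njac, method="BFGS",
                       options=dict(maxiter=maxiter, gtol=1e-6))
        cov = None
        try:
            from statsmodels.tools.numdiff import approx_hess

            H = approx_hess(res.x, nll)
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = None
        return ZIBResults(
            model=self, params=res.x, loglik=float(-res.fun),
            converged=bool(res.success), cov_params=cov, message=res.message,
        )


def fit_zib(
    edges: pd.DataFrame, covariates: Sequence[str] = (), **kw
) -> ZIBResults:
    """Convenience wrapper: build a ZeroInflatedBinomial from an edge
    table (columns y, n plus covariates) and fit it."""
    return ZeroInflatedBinomial.from_edge_data(edges, covariates, **kw).fit()


@dataclass
class StepwiseResult:
    terms: Tuple[str, ...]
    fit: ZIBResults
    trace: List[Tuple[Tuple[str, ...], float]] = field(default_factory=list)

    def trace_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dict(terms="+".join(t) or "(intercept)", aic=a) for t, a in self.trace]
        )


def stepwise_select(
    edges: pd.DataFrame,
    candidates: Sequence[str] = CANDIDATE_COVARIATES,
) -> StepwiseResult:
    """Bidirectional stepwise AIC search over covariate subsets.

    Bounded below by the intercept-only model and above by the full
    model; at each step the single add or drop with the lowest AIC is
    taken, stopping when no move improves AIC.  Deterministic: candidate
    moves are evaluated in a fixed order and strict improvement is
    required.
    """
    cache: Dict[Tuple[str, ...], ZIBResults] = {}

    def fit_terms(terms: Tuple[str, ...]) -> ZIBResults:
        if terms not in cache:
            cache[terms] = fit_zib(edges, terms)
        return cache[terms]

    current: Tuple[str, ...] = ()
    cur_fit = fit_terms(current)
    trace = [(current, cur_fit.aic)]
    while True:
        moves: List[Tuple[str, ...]] = []
        for c in candidates:
            if c not in current:
                moves.append(tuple(list(current) + [c]))
        for c in current:
            moves.append(tuple(t for t in current if t != c))
        best: Optional[Tuple[Tuple[str, ...], ZIBResults]] = None
        for terms in moves:
            f = fit_terms(terms)
            if best is None or f.aic < best[1].aic:
                best = (terms, f)
        if best is None or best[1].aic >= cur_fit.aic - 1e-9:
            break
        current, cur_fit = best
        trace.append((current, cur_fit.aic))
    return StepwiseResult(terms=current, fit=cur_fit, trace=trace)


def fit_report(step: StepwiseResult, candidates: Sequence[str] = CANDIDATE_COVARIATES) -> pd.DataFrame:
    """Forest-plot style report: estimate and 95% CI per term, with
    dropped terms marked (NaN estimates, kept=False)."""
    rep = step.fit.report().set_index("term")
    rows = []
    for term in ["intercept", *candidates, "logit_phi"]:
        if term in rep.index:
            r = rep.loc[term]
            rows.append(dict(term=term, estimate=r["estimate"], se=r["se"],
                             ci_low=r["ci_low"], ci_high=r["ci_high"], kept=True))
        else:
            rows.append(dict(term=term, estimate=np.nan, se=np.nan,
                             ci_low=np.nan, ci_high=np.nan, kept=False))
    return pd.DataFrame(rows)
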