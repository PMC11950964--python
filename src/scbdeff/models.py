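"""Inferential models for effective SCBD.

Two layers of inference over the species-level predictor table:

* Gaussian GLMs (ordinary least squares) of effective SCBD on a focal
  environmental axis (aridity or the soil composite) with two-way
  focal x trait interactions, plus prediction grids at the moderator's
  25th percentile, mean band, and 75th percentile.

* A recursive path model (observed-variable SEM): an acyclic system of
  linear equations among observed variables.  For recursive models with
  independent errors, equation-wise least squares coincides with maximum
  likelihood, so each endogenous equation is solved from the sample
  covariance; the model-implied covariance is assembled by path tracing
  and compared to the sample covariance through the ML discrepancy
  F_ML = ln|Sigma| - ln|S| + tr(S Sigma^-1) - m, giving the chi-square
  statistic (n-1) F_ML, SRMR, GFI and CFI.  Direct effects are edge
  coefficients; indirect effects are sums of coefficient products over
  directed paths of length >= 2.  Model selection removes the least
  significant path and accepts the removal iff AICc decreases.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "InteractionGLM",
    "fit_interaction_glm",
    "default_path_structure",
    "PathModel",
    "fit_path_model",
    "effect_decomposition",
    "backward_eliminate",
    "normality_report",
    "saturated_structure",
    "simulate_path_data",
]


# ---------------------------------------------------------------------------
# Gaussian GLM with focal-environment x moderator interactions
# ---------------------------------------------------------------------------

class InteractionGLM(BaseEstimator):
    """OLS of a response on main effects plus focal x moderator interactions.

    Parameters
    ----------
    focal : str
        The focal environmental predictor (e.g. ``"aridity"`` or ``"soil"``).
    moderators : list of str
        Columns whose two-way interaction with the focal axis is modeled.
    covariates : list of str, optional
        Additional main-effect-only columns.
    response : str
        Response column name (default ``"scbd_eff"``).

    Attributes
    ----------
    terms_ : DataFrame
        name, coefficient, std error, t value, p value per term.
    r_squared_ : float
    residuals_ : Series
    """

    def __init__(self, focal: str = "aridity", moderators=None, covariates=None,
                 response: str = "scbd_eff"):
        self.focal = focal
        self.moderators = moderators
        self.covariates = covariates
        self.response = response

    def fit(self, X: pd.DataFrame, y=None):
        import statsmodels.api as sm

        table = X
        moderators = list(self.moderators or [])
        covariates = list(self.covariates or [])
        if y is None:
            y = table[self.response]
        needed = [self.focal] + moderators + covariates
        if table[needed].isna().any().any() or pd.Series(y).isna().any():
            raise ValueError("missing values in modeled columns")
        design = {"Intercept": np.ones(len(table))}
        design[self.focal] = table[self.focal].to_numpy(dtype=float)
        for m in moderators + covariates:
            design[m] = table[m].to_numpy(dtype=float)
        for m in moderators:
            design[f"{self.focal}:{m}"] = design[self.focal] * design[m]
        Xd = pd.DataFrame(design, index=table.index)
        if len(table) <= Xd.shape[1]:
            raise ValueError("more terms than observations")
        rank = np.linalg.matrix_rank(Xd.to_numpy())
        if rank < Xd.shape[1]:
            # name the aliased columns for the error message
            q, r = np.linalg.qr(Xd.to_numpy())
            aliased = [Xd.columns[i] for i in range(Xd.shape[1]) if abs(r[i, i]) < 1e-10]
            raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
        res = sm.OLS(np.asarray(y, float), Xd).fit()
        self.model_ = res
        self.terms_ = pd.DataFrame(
            {
                "term": Xd.columns,
                "coefficient": res.params.to_numpy(),
                "std_err": res.bse.to_numpy(),
                "t_value": res.tvalues.to_numpy(),
                "p_value": res.pvalues.to_numpy(),
            }
        ).set_index("term")
        self.r_squared_ = float(res.rsquared)
        self.residuals_ = pd.Series(res.resid.to_numpy(), index=table.index, name="residual")
        self._table = table
        self._moderator_list = moderators
        self._covariate_list = covariates
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        cols = self.terms_.index
        design = {"Intercept": np.ones(len(X))}
        for c in cols:
            if c == "Intercept":
                continue
            if ":" in c:
                a, b = c.split(":")
                design[c] = X[a].to_numpy(float) * X[b].to_numpy(float)
            else:
                design[c] = X[c].to_numpy(float)
        Xd = pd.DataFrame(design, index=X.index)[cols]
        return Xd.to_numpy() @ self.terms_["coefficient"].to_numpy()

    def prediction_grid(self, moderator: str, n_points: int = 50,
                        level: float = 0.95) -> pd.DataFrame:
        """High / Mean / Low curves over the focal axis.

        The moderator is held at its 75th percentile (High), mean (Mean)
        and 25th percentile (Low); every other predictor at its mean.
        Returns focal value, band label, prediction and CI bounds.
        """
        t = self._table
        focal_grid = np.linspace(t[self.focal].min(), t[self.focal].max(), n_points)
        bands = {
            "High": float(np.percentile(t[moderator], 75)),
            "Mean": float(t[moderator].mean()),
            "Low": float(np.percentile(t[moderator], 25)),
        }
        frames = []
        for label, mval in bands.items():
            base = {self.focal: focal_grid}
            for c in self._moderator_list + self._covariate_list:
                base[c] = np.full(n_points, mval if c == moderator else float(t[c].mean()))
            grid = pd.DataFrame(base)
            design = {"Intercept": np.ones(n_points)}
            for c in self.terms_.index:
                if c == "Intercept":
                    continue
                if ":" in c:
                    a, b = c.split(":")
                    design[c] = grid[a].to_numpy() * grid[b].to_numpy()
                else:
                    design[c] = grid[c].to_numpy()
            Xd = pd.DataFrame(design)[self.terms_.index]
            pred = self.model_.get_prediction(Xd)
            ci = pred.conf_int(alpha=1 - level)
            frames.append(pd.DataFrame({
                self.focal: focal_grid,
                "band": label,
                "predicted": pred.predicted_mean,
                "ci_lower": ci[:, 0],
                "ci_upper": ci[:, 1],
            }))
        return pd.concat(frames, ignore_index=True)


def fit_interaction_glm(table: pd.DataFrame, focal: str = "aridity",
                        moderators=None, covariates=None,
                        response: str = "scbd_eff") -> InteractionGLM:
    """Fit the focal-environment interaction GLM on a predictor table."""
    if moderators is None:
        moderators = ["height_cm", "sla_cm2_per_g", "leaf_production",
                      "species_mpd", "c3_relative_abundance"]
        moderators = [m for m in moderators if m in table.columns]
    return InteractionGLM(focal=focal, moderators=moderators,
                          covariates=covariates, response=response).fit(table)


# ---------------------------------------------------------------------------
# Recursive path model
# ---------------------------------------------------------------------------

DEFAULT_MEDIATORS = ("height_cm", "sla_cm2_per_g", "leaf_production",
                     "species_mpd", "c3_relative_abundance")


def default_path_structure(mediators=DEFAULT_MEDIATORS,
                           response: str = "scbd_eff") -> list[tuple[str, str]]:
    """The full recursive structure: aridity -> soil; {aridity, soil} ->
    each mediator; all seven predictors -> the response."""
    edges = [("aridity", "soil")]
    for m in mediators:
        edges += [("aridity", m), ("soil", m)]
    for v in ("aridity", "soil", *mediators):
        edges.append((v, response))
    return edges


@dataclass
class FitIndices:
    chi_square: float
    df: int
    p_value: float
    srmr: float
    gfi: float
    cfi: float

    def as_dict(self):
        return {
            "chi_square": self.chi_square, "df": self.df, "p_value": self.p_value,
            "srmr": self.srmr, "gfi": self.gfi, "cfi": self.cfi,
        }


class PathModel(BaseEstimator):
    """Recursive observed-variable path model.

    Parameters
    ----------
    structure : list of (source, target) edges
        Must be acyclic.  Variables that are never a target are exogenous;
        their covariance is left saturated.
    standardize : bool
        z-standardize all columns before fitting (default), so path
        coefficients are comparable across differently scaled traits.

    Attributes
    ----------
    edges_ : DataFrame
        source, target, coefficient, std error, z, p per directed path.
    implied_cov_ : DataFrame
        Model-implied covariance over all variables.
    fit_indices_ : FitIndices
    aicc_ : float
    log_likelihood_ : float
    n_ : int
    """

    def __init__(self, structure=None, standardize: bool = True):
        self.structure = structure
        self.standardize = standardize

    # -- helpers ------------------------------------------------------------
    def _graph(self, edges):
        g = nx.DiGraph()
        g.add_edges_from(edges)
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise ValueError(f"path structure is cyclic: {cyc}")
        return g

    def fit(self, X: pd.DataFrame, y=None):
        edges = list(self.structure) if self.structure is not None else default_path_structure()
        g = self._graph(edges)
        variables = list(nx.topological_sort(g))
        missing = sorted(set(variables) - set(map(str, X.columns)))
        if missing:
            raise ValueError(f"structure references absent columns: {missing}")
        data = X[variables].astype(float)
        if data.isna().any().any():
            raise ValueError("missing values in modeled columns")
        if self.standardize:
            sd = data.std(ddof=1)
            if (sd <= 0).any():
                raise ValueError(f"constant columns: {list(sd.index[sd <= 0])}")
            data = (data - data.mean()) / sd
        n, m = data.shape
        S = np.cov(data.to_numpy(), rowvar=False, ddof=1)
        if np.linalg.matrix_rank(S) < m:
            raise ValueError("singular sample covariance")
        idx = {v: i for i, v in enumerate(variables)}
        endogenous = [v for v in variables if g.in_degree(v) > 0]
        exogenous = [v for v in variables if g.in_degree(v) == 0]
        max_eq = max((g.in_degree(v) for v in endogenous), default=0)
        if n <= max_eq + 1:
            raise ValueError("sample size too small for the largest equation")

        B = np.zeros((m, m))
        rows = []
        resid_var = {}
        for v in endogenous:
            parents = sorted(g.predecessors(v), key=idx.get)
            pi = [idx[p] for p in parents]
            vi = idx[v]
            Spp = S[np.ix_(pi, pi)]
            spy = S[pi, vi]
            b = np.linalg.solve(Spp, spy)
            psi = float(S[vi, vi] - b @ spy)
            resid_var[v] = max(psi, 1e-12)
            B[vi, pi] = b
            # OLS standard errors: Var(b) = psi * (X'X)^{-1} ~ psi/(n-1) * Spp^{-1}
            dof = n - len(pi) - 1
            sigma2 = resid_var[v] * (n - 1) / max(dof, 1)
            cov_b = sigma2 * np.linalg.inv(Spp) / (n - 1)
            se = np.sqrt(np.diag(cov_b))
            for p, bj, sj in zip(parents, b, se):
                z = bj / sj if sj > 0 else np.inf
                rows.append({
                    "source": p, "target": v, "coefficient": float(bj),
                    "std_err": float(sj), "z_value": float(z),
                    "p_value": float(2 * stats.norm.sf(abs(z))),
                })

        # implied covariance by path tracing: Sigma = (I-B)^-1 Psi (I-B)^-T
        Psi = np.zeros((m, m))
        exo_idx = [idx[v] for v in exogenous]
        Psi[np.ix_(exo_idx, exo_idx)] = S[np.ix_(exo_idx, exo_idx)]
        for v in endogenous:
            Psi[idx[v], idx[v]] = resid_var[v]
        IB = np.linalg.inv(np.eye(m) - B)
        Sigma = IB @ Psi @ IB.T

        _, logdet_S = np.linalg.slogdet(S)
        _, logdet_Sig = np.linalg.slogdet(Sigma)
        Sig_inv = np.linalg.inv(Sigma)
        f_ml = float(logdet_Sig - logdet_S + np.trace(S @ Sig_inv) - m)
        # saturated / numerically exact fits: snap roundoff to an exact zero
        f_ml = 0.0 if f_ml < 1e-10 else f_ml
        chi2 = (n - 1) * f_ml
        k_free = len(rows) + len(endogenous) + len(exogenous) * (len(exogenous) + 1) // 2
        df = m * (m + 1) // 2 - k_free
        p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0

        d = np.sqrt(np.diag(S))
        resid_std = (S - Sigma) / np.outer(d, d)
        tri = np.tril_indices(m)
        srmr = float(np.sqrt(np.mean(resid_std[tri] ** 2)))
        num = np.trace((Sig_inv @ (S - Sigma)) @ (Sig_inv @ (S - Sigma)))
        den = np.trace((Sig_inv @ S) @ (Sig_inv @ S))
        gfi = float(1 - num / den)
        # independence null model for CFI
        Sigma0 = np.diag(np.diag(S))
        f0 = float(np.linalg.slogdet(Sigma0)[1] - logdet_S
                   + np.trace(S @ np.linalg.inv(Sigma0)) - m)
        chi2_0 = (n - 1) * max(f0, 0.0)
        df0 = m * (m - 1) // 2
        denom = max(chi2_0 - df0, chi2 - df, 1e-300)
        cfi = float(1 - max(chi2 - df, 0.0) / denom)

        loglik = -0.5 * n * (m * np.log(2 * np.pi) + logdet_Sig + np.trace(S @ Sig_inv))
        aicc_pen = (2 * k_free * (k_free + 1) / (n - k_free - 1)) if n > k_free + 1 else np.inf
        self.variables_ = variables
        self.exogenous_ = exogenous
        self.endogenous_ = endogenous
        self.edges_ = pd.DataFrame(rows)
        self.coef_matrix_ = pd.DataFrame(B, index=variables, columns=variables)
        self.resid_var_ = pd.Series(resid_var)
        self.implied_cov_ = pd.DataFrame(Sigma, index=variables, columns=variables)
        self.sample_cov_ = pd.DataFrame(S, index=variables, columns=variables)
        self.fit_indices_ = FitIndices(chi_square=float(chi2), df=int(df),
                                       p_value=p_value, srmr=srmr, gfi=gfi, cfi=cfi)
        self.log_likelihood_ = float(loglik)
        self.k_free_ = int(k_free)
        self.aicc_ = float(-2 * loglik + 2 * k_free + aicc_pen)
        self.n_ = n
        self._input = X
        return self

    # -- effects ------------------------------------------------------------
    def effect_decomposition(self) -> pd.DataFrame:
        """Direct, indirect and total effects for every (source, target).

        Total effects come from the geometric series (I-B)^-1 - I, which
        sums coefficient products over all directed paths; the indirect
        part subtracts the direct edge.
        """
        B = self.coef_matrix_.to_numpy()
        m = B.shape[0]
        total = np.linalg.inv(np.eye(m) - B) - np.eye(m)
        indirect = total - B
        rows = []
        g = nx.DiGraph(list(zip(self.edges_["source"], self.edges_["target"])))
        for s in self.variables_:
            for t in self.variables_:
                if s == t:
                    continue
                i, j = self.variables_.index(t), self.variables_.index(s)
                if not (g.has_edge(s, t) or abs(total[i, j]) > 0):
                    continue
                rows.append({
                    "source": s, "target": t,
                    "direct": float(B[i, j]),
                    "indirect": float(indirect[i, j]),
                    "total": float(total[i, j]),
                })
        return pd.DataFrame(rows)

    def mediator_coefficients(self, response: str | None = None) -> pd.DataFrame:
        """The mediator-equation coefficients (environment -> mediator paths),
        emitted separately because summaries of indirect influence sometimes
        report these rather than path products."""
        resp = response or self.endogenous_[-1]
        return self.edges_[(self.edges_["target"] != resp)].reset_index(drop=True)

    # -- model selection ----------------------------------------------------
    def backward_eliminate(self, protect_last_parent: bool = True):
        """AICc-guided backward elimination of directed paths.

        Repeatedly proposes removing the currently least significant path
        (largest Wald p-value); the removal is accepted iff AICc decreases,
        otherwise the next least significant candidate is proposed; stops
        when no removal decreases AICc.  A path that is its target's last
        parent is never removed (the equation would be orphaned).

        Returns ``(model, trace)``: the refitted reduced model and a
        DataFrame logging each accepted removal and its AICc.
        """
        current = self
        trace = [{"removed": None, "aicc": self.aicc_, "k_free": self.k_free_}]
        while True:
            edges = current.edges_.sort_values("p_value", ascending=False)
            g = nx.DiGraph(list(zip(current.edges_["source"], current.edges_["target"])))
            accepted = False
            for _, row in edges.iterrows():
                s, t = row["source"], row["target"]
                if protect_last_parent and g.in_degree(t) <= 1:
                    continue
                new_struct = [(a, b) for a, b in zip(current.edges_["source"],
                                                     current.edges_["target"])
                              if not (a == s and b == t)]
                cand = PathModel(structure=new_struct, standardize=self.standardize)
                cand.fit(self._input)
                if cand.aicc_ < current.aicc_:
                    trace.append({"removed": f"{s}->{t}", "aicc": cand.aicc_,
                                  "k_free": cand.k_free_})
                    current = cand
                    accepted = True
                    break
            if not accepted or len(current.edges_) <= 1:
                break
        return current, pd.DataFrame(trace)

    def __sklearn_is_fitted__(self):
        return hasattr(self, "edges_")


def fit_path_model(table: pd.DataFrame, structure=None, standardize: bool = True) -> PathModel:
    """Fit a recursive path model; default structure if none given."""
    return PathModel(structure=structure, standardize=standardize).fit(table)


def saturated_structure(variables: list[str]) -> list[tuple[str, str]]:
    """A fully recursive DAG: each variable regressed on all its
    predecessors in the given order (df = 0, zero discrepancy)."""
    return [(variables[i], variables[j])
            for j in range(len(variables)) for i in range(j)]


def simulate_path_data(coefficients: dict, n: int, seed: int,
                       error_sd: float | dict = 1.0) -> pd.DataFrame:
    """Draw from a linear-Gaussian recursive system.

    ``coefficients`` maps (source, target) edges to path coefficients.
    Exogenous variables are standard normal; each endogenous variable is
    its parents' weighted sum plus N(0, error_sd) noise.  The generating
    truth for recovery checks.
    """
    rng = np.random.default_rng(seed)
    g = nx.DiGraph(list(coefficients))
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("coefficient edges must form a DAG")
    data = {}
    for v in nx.topological_sort(g):
        parents = list(g.predecessors(v))
        sd = error_sd.get(v, 1.0) if isinstance(error_sd, dict) else error_sd
        noise = rng.normal(0.0, sd, n)
        if parents:
            data[v] = sum(coefficients[(p, v)] * data[p] for p in parents) + noise
        else:
            data[v] = noise
    return pd.DataFrame(data)


def effect_decomposition(model: PathModel) -> pd.DataFrame:
    return model.effect_decomposition()


def backward_eliminate(model: PathModel):
    return model.backward_eliminate()


# ---------------------------------------------------------------------------
# normality diagnostics (advisory only)
# ---------------------------------------------------------------------------

def normality_report(table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Shapiro-Wilk statistic and p-value per column, plus Q-Q plot data.

    Purely advisory: never gates any pipeline stage.  Constant columns are
    flagged with NaN statistics.  The ``qq`` column holds a (theoretical,
    sample) quantile array usable for plotting.
    """
    cols = list(columns or table.select_dtypes("number").columns)
    rows = []
    for c in cols:
        x = table[c].dropna().to_numpy(dtype=float)
        if x.size < 3 or np.ptp(x) == 0:
            rows.append({"variable": c, "n": x.size, "statistic": np.nan,
                         "p_value": np.nan, "constant": bool(x.size and np.ptp(x) == 0),
                         "qq": None})
            continue
        stat, p = stats.shapiro(x)
        osm, osr = stats.probplot(x, dist="norm", fit=False)
        rows.append({"variable": c, "n": x.size, "statistic": float(stat),
                     "p_value": float(p), "constant": False,
                     "qq": np.column_stack([osm, osr])})
    return pd.DataFrame(rows).set_index("variable")
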