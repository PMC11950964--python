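"""Interaction GLMs, the recursive path model, effects and model selection."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from scbdeff import (
    InteractionGLM,
    PathModel,
    default_path_structure,
    fit_interaction_glm,
    fit_path_model,
    normality_report,
)
from scbdeff.models import DEFAULT_MEDIATORS, saturated_structure, simulate_path_data

TRUE_COEFS = {("aridity", "soil"): 0.5}
for i, m in enumerate(DEFAULT_MEDIATORS):
    TRUE_COEFS[("aridity", m)] = 0.3 - 0.1 * i
    TRUE_COEFS[("soil", m)] = -0.25 + 0.08 * i
for i, v in enumerate(("aridity", "soil", *DEFAULT_MEDIATORS)):
    TRUE_COEFS[(v, "scbd_eff")] = [0.2, -0.3, 0.15, -0.2, 0.1, 0.25, -0.15][i]


def simulate_glm_data(n, interaction, seed):
    rng = np.random.default_rng(seed)
    aridity = rng.normal(size=n)
    trait = rng.normal(size=n)
    y = 0.4 * aridity + 0.2 * trait + interaction * aridity * trait + rng.normal(size=n)
    return pd.DataFrame({"aridity": aridity, "trait": trait, "scbd_eff": y})


# --- GLM ---------------------------------------------------------------------

def test_glm_matches_normal_equations(rng):
    df = simulate_glm_data(120, 0.5, 0)
    fit = InteractionGLM(focal="aridity", moderators=["trait"]).fit(df)
    X = np.column_stack([np.ones(120), df["aridity"], df["trait"],
                         df["aridity"] * df["trait"]])
    beta = np.linalg.solve(X.T @ X, X.T @ df["scbd_eff"])
    np.testing.assert_allclose(fit.terms_["coefficient"], beta, atol=1e-10)


def test_glm_interaction_recovery():
    df = simulate_glm_data(500, 0.5, 42)
    fit = InteractionGLM(focal="aridity", moderators=["trait"]).fit(df)
    est = fit.terms_.loc["aridity:trait", "coefficient"]
    assert 0.4 <= est <= 0.6


def test_glm_type_one_error_of_interaction():
    hits = 0
    reps = 25
    for seed in range(reps):
        df = simulate_glm_data(200, 0.0, seed)
        fit = InteractionGLM(focal="aridity", moderators=["trait"]).fit(df)
        row = fit.terms_.loc["aridity:trait"]
        hits += abs(row["coefficient"]) <= 2 * row["std_err"]
    assert hits >= int(0.88 * reps)


def test_glm_rank_deficiency_names_aliased_terms():
    df = simulate_glm_data(50, 0.0, 1)
    df["copy"] = df["trait"]
    with pytest.raises(ValueError, match="aliased"):
        InteractionGLM(focal="aridity", moderators=["trait", "copy"]).fit(df)


def test_glm_missing_values_rejected():
    df = simulate_glm_data(50, 0.0, 2)
    df.loc[3, "trait"] = np.nan
    with pytest.raises(ValueError, match="missing"):
        InteractionGLM(focal="aridity", moderators=["trait"]).fit(df)


def test_prediction_grid_bands_ordered_by_moderator():
    df = simulate_glm_data(400, 0.8, 3)
    fit = InteractionGLM(focal="aridity", moderators=["trait"]).fit(df)
    grid = fit.prediction_grid("trait")
    assert set(grid["band"]) == {"High", "Mean", "Low"}
    # positive interaction: High band has the steeper positive slope
    slopes = {
        b: np.polyfit(g["aridity"], g["predicted"], 1)[0]
        for b, g in grid.groupby("band")
    }
    assert slopes["High"] > slopes["Mean"] > slopes["Low"]


def test_predictor_table_glm_runs(default_landscape):
    from scbdeff import (
        assemble_predictor_table, decompose, effective_scbd, mpd_per_site,
        occurrence_profile, patristic_distances, species_level_mpd,
    )

    land = default_landscape
    part = decompose(land.community)
    prof = occurrence_profile(land.community)
    eff = effective_scbd(part.scbd_, prof)
    D = patristic_distances(land.tree, prune_to=land.species)
    sp_mpd = species_level_mpd(land.community, mpd_per_site(land.community, D))
    table, _ = assemble_predictor_table(
        land.community, land.site_env, land.traits, sp_mpd, eff["scbd_eff"]
    )
    fit = fit_interaction_glm(table.dropna(), focal="aridity")
    assert 0 <= fit.r_squared_ <= 1
    assert (fit.terms_["p_value"].between(0, 1)).all()


# --- path model ---------------------------------------------------------------

def fml_optimizer_oracle(data, structure):
    """Independent covariance-fitting ML oracle: minimize F_ML over all free
    path coefficients and error variances with a generic optimizer."""
    variables = list(nx.topological_sort(nx.DiGraph(structure)))
    X = data[variables].to_numpy()
    S = np.cov(X, rowvar=False, ddof=1)
    m = len(variables)
    idx = {v: i for i, v in enumerate(variables)}
    g = nx.DiGraph(structure)
    endo = [v for v in variables if g.in_degree(v) > 0]
    exo = [v for v in variables if g.in_degree(v) == 0]
    edges = list(structure)

    def implied(theta):
        B = np.zeros((m, m))
        for (s, t), val in zip(edges, theta[: len(edges)]):
            B[idx[t], idx[s]] = val
        Psi = np.zeros((m, m))
        ei = [idx[v] for v in exo]
        Psi[np.ix_(ei, ei)] = S[np.ix_(ei, ei)]
        for j, v in enumerate(endo):
            Psi[idx[v], idx[v]] = np.exp(theta[len(edges) + j])
        IB = np.linalg.inv(np.eye(m) - B)
        return IB @ Psi @ IB.T

    def fml(theta):
        Sig = implied(theta)
        sign, logdet = np.linalg.slogdet(Sig)
        if sign <= 0:
            return 1e6
        return logdet - np.linalg.slogdet(S)[1] + np.trace(S @ np.linalg.inv(Sig)) - m

    theta0 = np.concatenate([np.zeros(len(edges)), np.zeros(len(endo))])
    res = optimize.minimize(fml, theta0, method="Nelder-Mead",
                            options={"maxiter": 40000, "xatol": 1e-10, "fatol": 1e-14})
    res = optimize.minimize(fml, res.x, method="Powell",
                            options={"maxiter": 40000, "xtol": 1e-12, "ftol": 1e-14})
    return dict(zip(edges, res.x[: len(edges)]))


def test_equationwise_ls_equals_covariance_ml():
    structure = [("a", "b"), ("a", "c"), ("b", "c")]
    data = simulate_path_data(
        {("a", "b"): 0.6, ("a", "c"): -0.4, ("b", "c"): 0.5}, n=400, seed=9
    )
    model = PathModel(structure=structure, standardize=False).fit(data)
    oracle = fml_optimizer_oracle(data, structure)
    for _, row in model.edges_.iterrows():
        assert row["coefficient"] == pytest.approx(
            oracle[(row["source"], row["target"])], abs=1e-4
        )


def test_saturated_model_fits_perfectly(rng):
    data = pd.DataFrame(rng.normal(size=(80, 4)), columns=list("abcd"))
    model = PathModel(structure=saturated_structure(list("abcd")),
                      standardize=False).fit(data)
    assert model.fit_indices_.chi_square == 0.0
    assert model.fit_indices_.srmr == pytest.approx(0.0, abs=1e-8)
    assert model.fit_indices_.gfi == pytest.approx(1.0, abs=1e-8)
    assert model.fit_indices_.cfi == pytest.approx(1.0, abs=1e-8)
    assert model.fit_indices_.df == 0


def test_default_dag_recovery():
    data = simulate_path_data(TRUE_COEFS, n=5000, seed=1)
    model = fit_path_model(data, standardize=False)
    for _, row in model.edges_.iterrows():
        assert row["coefficient"] == pytest.approx(
            TRUE_COEFS[(row["source"], row["target"])], abs=0.05
        )
    assert model.fit_indices_.srmr < 0.08


def test_cyclic_structure_rejected(rng):
    data = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
    with pytest.raises(ValueError, match="cyclic"):
        PathModel(structure=[("a", "b"), ("b", "a")]).fit(data)


def test_singular_covariance_rejected(rng):
    x = rng.normal(size=50)
    data = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.normal(size=50)})
    with pytest.raises(ValueError, match="singular|constant"):
        PathModel(structure=[("a", "c"), ("b", "c")], standardize=False).fit(data)


def test_misspecification_raises_chi_square_and_srmr():
    coefs = {("a", "b"): 0.7, ("a", "c"): 0.5, ("b", "c"): 0.6}
    data = simulate_path_data(coefs, n=1500, seed=4)
    true_model = PathModel(structure=list(coefs), standardize=False).fit(data)
    dropped = PathModel(structure=[("a", "b"), ("a", "c")], standardize=False).fit(data)
    assert dropped.fit_indices_.chi_square > true_model.fit_indices_.chi_square
    assert dropped.fit_indices_.srmr > true_model.fit_indices_.srmr


# --- effects -------------------------------------------------------------------

def test_two_edge_chain_indirect_product():
    data = simulate_path_data({("a", "b"): 0.5, ("b", "c"): 0.4}, n=100000, seed=2)
    model = PathModel(structure=[("a", "b"), ("b", "c")], standardize=False).fit(data)
    eff = model.effect_decomposition()
    ab = model.edges_.set_index(["source", "target"])["coefficient"]
    row = eff[(eff.source == "a") & (eff.target == "c")].iloc[0]
    # exact product identity of the fitted coefficients
    assert row["indirect"] == pytest.approx(
        ab[("a", "b")] * ab[("b", "c")], abs=1e-12
    )
    assert row["direct"] == 0.0
    # and close to the generating 0.20 at this n
    assert row["indirect"] == pytest.approx(0.20, abs=0.02)


def path_enumeration_oracle(model):
    """Exhaustive simple-path enumeration of indirect effects."""
    coefs = model.edges_.set_index(["source", "target"])["coefficient"]
    g = nx.DiGraph(list(coefs.index))
    out = {}
    for s in model.variables_:
        for t in model.variables_:
            if s == t:
                continue
            total = 0.0
            for path in nx.all_simple_paths(g, s, t):
                if len(path) >= 3:
                    prod = 1.0
                    for u, v in zip(path, path[1:]):
                        prod *= coefs[(u, v)]
                    total += prod
            out[(s, t)] = total
    return out


def test_indirect_effects_match_enumeration_on_random_dags(rng):
    for seed in range(5):
        gen = np.random.default_rng(seed)
        nodes = list("abcdef")
        edges = [
            (nodes[i], nodes[j])
            for i, j in itertools.combinations(range(6), 2)
            if gen.random() < 0.5
        ]
        if not any(t == "f" for _, t in edges):
            edges.append(("a", "f"))
        coefs = {e: float(gen.normal(0, 0.4)) for e in edges}
        data = simulate_path_data(coefs, n=300, seed=seed + 100)
        model = PathModel(structure=edges, standardize=False).fit(data)
        oracle = path_enumeration_oracle(model)
        eff = model.effect_decomposition()
        for _, row in eff.iterrows():
            assert row["indirect"] == pytest.approx(
                oracle[(row["source"], row["target"])], abs=1e-10
            )


def test_no_directed_path_means_zero_indirect():
    data = simulate_path_data({("a", "c"): 0.5, ("b", "c"): 0.4}, n=200, seed=3)
    model = PathModel(structure=[("a", "c"), ("b", "c")], standardize=False).fit(data)
    eff = model.effect_decomposition()
    assert (eff["indirect"] == 0).all()


def test_total_effect_equals_simple_regression_slope():
    """Path-tracing identity: in a linear-Gaussian system the total effect
    of the root on the response equals the simple regression slope."""
    data = simulate_path_data(TRUE_COEFS, n=20000, seed=8)
    model = fit_path_model(data, standardize=False)
    eff = model.effect_decomposition()
    total = eff[(eff.source == "aridity") & (eff.target == "scbd_eff")]["total"].iloc[0]
    slope = np.polyfit(data["aridity"], data["scbd_eff"], 1)[0]
    assert total == pytest.approx(slope, abs=0.03)


# --- model selection ------------------------------------------------------------

def test_aicc_formula_identity():
    data = simulate_path_data(TRUE_COEFS, n=300, seed=5)
    model = fit_path_model(data, standardize=False)
    k, n = model.k_free_, model.n_
    expected = -2 * model.log_likelihood_ + 2 * k + 2 * k * (k + 1) / (n - k - 1)
    assert model.aicc_ == pytest.approx(expected, abs=1e-10)


def test_backward_elimination_removes_null_path_keeps_true_paths():
    coefs = dict(TRUE_COEFS)
    coefs[("species_mpd", "scbd_eff")] = 0.0  # one true-zero path
    removed_zero = kept_true = 0
    reps = 12
    for seed in range(reps):
        data = simulate_path_data(coefs, n=2000, seed=seed)
        model = fit_path_model(data, standardize=False)
        reduced, trace = model.backward_eliminate()
        eliminated = set(trace["removed"].dropna())
        removed_zero += "species_mpd->scbd_eff" in eliminated
        kept_true += all(
            f"{s}->{t}" not in eliminated
            for (s, t), c in coefs.items()
            if abs(c) > 0.05
        )
        # AICc strictly decreases along accepted removals
        aiccs = trace["aicc"].to_numpy()
        assert (np.diff(aiccs) < 0).all()
    assert removed_zero >= int(0.75 * reps)
    assert kept_true == reps


def test_elimination_never_orphans_an_equation():
    coefs = {("a", "b"): 0.0001, ("b", "c"): 0.5}
    data = simulate_path_data(coefs, n=500, seed=6)
    model = PathModel(structure=list(coefs), standardize=False).fit(data)
    reduced, _ = model.backward_eliminate()
    # a->b is b's only parent: protected even though its coefficient is ~0
    assert len(reduced.edges_) == 2


# --- normality diagnostics --------------------------------------------------------

def test_shapiro_calibration_and_power():
    normal_ok = expo_flagged = 0
    reps = 20
    for seed in range(reps):
        gen = np.random.default_rng(seed)
        df = pd.DataFrame({"norm": gen.normal(size=500), "expo": gen.exponential(size=500)})
        rep = normality_report(df)
        normal_ok += rep.loc["norm", "p_value"] > 0.01
        expo_flagged += rep.loc["expo", "p_value"] < 0.01
    assert normal_ok >= int(0.9 * reps)
    assert expo_flagged >= int(0.9 * reps)


def test_constant_column_flagged_without_statistic():
    rep = normality_report(pd.DataFrame({"flat": np.ones(20)}))
    assert bool(rep.loc["flat", "constant"])
    assert np.isnan(rep.loc["flat", "statistic"])
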