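"""Feature screening, random-forest modelling and interpretation.

The modelling stage mirrors a standard interpretable-ML workflow for
agronomic drivers:

* Pearson screening keeps climate features that correlate with the target
  (|r| > 0.15) and are not redundant within their variable category
  (|r| < 0.50 against already-selected features of the same category).
* A random-forest regressor (bootstrap + per-split feature subsampling) is
  the workhorse model; variable importance is %IncMSE — the percent increase
  of out-of-bag MSE when one feature's out-of-bag values are permuted.
* Partial dependence curves show the marginal expected response along one
  feature, averaging model predictions over the observed values of all
  others.
* A representative CART tree (the most accurate of a set of bootstrap
  candidates, scored on its out-of-bag rows) turns the forest's structure
  into explicit threshold rules.
* Model comparison uses k-fold (default sixfold) cross-validated RMSE, R²
  and RPIQ (IQR of the observations divided by RMSE) across four predictor
  scenarios: A biological only (incl. measured light interception), B + full
  climate, C + screened climate, D full climate but no light interception.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.ensemble._forest import (
    _generate_unsampled_indices,
    _get_n_samples_bootstrap,
)
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor

from .climate_features import (
    BIO_COLUMNS,
    TARGET_COLUMN,
    climate_feature_columns,
    feature_category,
)

logger = logging.getLogger("yieldgap")

DEFAULT_R_MIN = 0.15
DEFAULT_R_CROSS_MAX = 0.50


@dataclass(frozen=True)
class RFParams:
    """Forest hyperparameters; defaults follow the classic randomForest
    regression setup (p/3 features per split, small leaves)."""

    n_estimators: int = 500
    max_features: float = 1.0 / 3.0
    min_samples_leaf: int = 5
    max_depth: int | None = None

    def build(self, seed: int) -> RandomForestRegressor:
        return RandomForestRegressor(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            min_samples_leaf=self.min_samples_leaf,
            max_depth=self.max_depth,
            bootstrap=True,
            oob_score=True,
            random_state=seed,
            n_jobs=1,
        )


# ---------------------------------------------------------------------------
# Pearson screening
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    target: str
    table: pd.DataFrame  # feature, r, p, category, selected, reason
    selected: list[str]
    r_min: float
    r_cross_max: float


def pearson_screen(
    features: pd.DataFrame,
    target: pd.Series,
    r_min: float = DEFAULT_R_MIN,
    r_cross_max: float = DEFAULT_R_CROSS_MAX,
    categories: dict[str, str] | None = None,
) -> SelectionResult:
    """Greedy correlation screening of candidate feature columns.

    Features are ranked by |r| with the target; in that order a feature is
    admitted if |r| > r_min and its |r| with every already-admitted feature
    of the same category is < r_cross_max.  Constant columns are rejected
    (correlation undefined).  Thresholds apply to absolute correlations, so
    negatively correlated stressors pass the screen too.
    """
    if len(features) < 30:
        raise ValueError(f"need >= 30 rows for screening, got {len(features)}")
    y = np.asarray(target, dtype=float)
    cols = list(features.columns)
    if categories is None:
        categories = {c: feature_category(c) for c in cols}

    records = []
    for c in cols:
        x = features[c].to_numpy(dtype=float)
        if np.std(x) == 0.0:
            records.append((c, np.nan, np.nan, categories[c], False, "constant"))
            continue
        r, p = stats.pearsonr(x, y)
        records.append((c, float(r), float(p), categories[c], False, ""))
    table = pd.DataFrame(
        records, columns=["feature", "r", "p", "category", "selected", "reason"]
    )

    # stable sort: ties in |r| (e.g. duplicated columns) keep input order
    order = (
        table.dropna(subset=["r"])
        .assign(abs_r=lambda d: d["r"].abs())
        .sort_values("abs_r", ascending=False, kind="stable")
    )
    selected: list[str] = []
    reasons: dict[str, str] = {}
    X = features.to_numpy(dtype=float)
    col_idx = {c: i for i, c in enumerate(cols)}
    for _, row in order.iterrows():
        c = row["feature"]
        if abs(row["r"]) <= r_min:
            reasons[c] = "low target correlation"
            continue
        redundant = False
        for s in selected:
            if categories[s] != categories[c]:
                continue
            rx = np.corrcoef(X[:, col_idx[c]], X[:, col_idx[s]])[0, 1]
            if abs(rx) >= r_cross_max:
                redundant = True
                reasons[c] = f"redundant within category (|r|={abs(rx):.2f} with {s})"
                break
        if not redundant:
            selected.append(c)
    table["selected"] = table["feature"].isin(selected)
    table["reason"] = [
        reasons.get(c, "" if sel else "constant" if rsn == "constant" else rsn)
        for c, sel, rsn in zip(table["feature"], table["selected"], table["reason"])
    ]
    logger.info(
        "screen vs %s: %d of %d features selected", target.name, len(selected), len(cols)
    )
    return SelectionResult(
        target=str(target.name),
        table=table,
        selected=selected,
        r_min=r_min,
        r_cross_max=r_cross_max,
    )


# ---------------------------------------------------------------------------
# random forest fitting
# ---------------------------------------------------------------------------

@dataclass
class RFModel:
    """A fitted forest plus the training matrix needed for out-of-bag
    interpretation."""

    model: RandomForestRegressor
    feature_names: list[str]
    X: np.ndarray  # float32, C-ordered (tree predict fast path)
    y: np.ndarray
    oob_prediction: np.ndarray
    oob_r2: float

    def predict_frame(self, X: pd.DataFrame) -> np.ndarray:
        return self.model.predict(X[self.feature_names].to_numpy(dtype=np.float32))


def one_hot_cultivar(X: pd.DataFrame) -> pd.DataFrame:
    """One-hot encode the integer cultivar code (column order deterministic)."""
    if "cultivar_id" not in X.columns:
        return X
    dummies = pd.get_dummies(X["cultivar_id"].astype(int), prefix="cultivar", dtype=float)
    dummies = dummies[sorted(dummies.columns)]
    return pd.concat([X.drop(columns=["cultivar_id"]), dummies], axis=1)


def fit_rf(
    features: pd.DataFrame,
    target: pd.Series | np.ndarray,
    seed: int,
    params: RFParams = RFParams(),
) -> RFModel:
    """Fit a bootstrap random-forest regressor with out-of-bag predictions."""
    if features.isna().any().any():
        raise ValueError("feature matrix contains missing values")
    n = len(features)
    if n < 2 * params.min_samples_leaf:
        raise ValueError(
            f"{n} rows cannot satisfy min_samples_leaf={params.min_samples_leaf}"
        )
    X = np.ascontiguousarray(features.to_numpy(dtype=np.float32))
    y = np.asarray(target, dtype=float)
    model = params.build(seed)
    model.fit(X, y)
    oob_pred = model.oob_prediction_
    return RFModel(
        model=model,
        feature_names=list(features.columns),
        X=X,
        y=y,
        oob_prediction=oob_pred,
        oob_r2=float(model.oob_score_),
    )


def _oob_index_sets(rf: RFModel) -> list[np.ndarray]:
    n = len(rf.y)
    try:
        nb = _get_n_samples_bootstrap(n, rf.model.max_samples, None)
    except TypeError:  # older scikit-learn without the sample_weight argument
        nb = _get_n_samples_bootstrap(n, rf.model.max_samples)
    sets = []
    for est in rf.model.estimators_:
        try:
            idx = _generate_unsampled_indices(est.random_state, n, nb, None)
        except TypeError:
            idx = _generate_unsampled_indices(est.random_state, n, nb)
        sets.append(np.asarray(idx))
    return sets


def _oob_mse(rf: RFModel, X: np.ndarray, oob_sets: list[np.ndarray]) -> float:
    """Out-of-bag MSE of the forest when predicting from matrix ``X``."""
    n = len(rf.y)
    sums = np.zeros(n)
    counts = np.zeros(n)
    for est, oob in zip(rf.model.estimators_, oob_sets):
        pred = est.predict(X[oob], check_input=False)
        sums[oob] += pred
        counts[oob] += 1
    valid = counts > 0
    resid = rf.y[valid] - sums[valid] / counts[valid]
    return float(np.mean(resid**2))


# ---------------------------------------------------------------------------
# %IncMSE importance
# ---------------------------------------------------------------------------

@dataclass
class ImportanceTable:
    table: pd.DataFrame  # feature, inc_mse_pct, rank
    n_repeats: int
    seed: int
    oob_mse_baseline: float

    def rank_of(self, feature: str) -> int:
        return int(self.table.set_index("feature").loc[feature, "rank"])


def importance_incmse(
    rf: RFModel, n_repeats: int = 10, seed: int = 0
) -> ImportanceTable:
    """Permutation importance on the out-of-bag records.

    For each feature, its column is permuted (whole-column permutation,
    re-drawn per repeat), the forest's out-of-bag MSE is recomputed, and
    %IncMSE = 100 * (MSE_oob_permuted - MSE_oob) / MSE_oob averaged over
    repeats.  Irrelevant features score near zero.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    oob_sets = _oob_index_sets(rf)
    mse_base = _oob_mse(rf, rf.X, oob_sets)
    n, p = rf.X.shape
    # per-tree cached OOB matrices: permuting a feature then only touches one
    # column in place (swap in, predict, swap back), avoiding full copies
    trees = rf.model.estimators_
    oob_X = [np.ascontiguousarray(rf.X[oob]) for oob in oob_sets]
    perms = [rng.permutation(n) for _ in range(n_repeats)]
    rows = []
    for j, name in enumerate(rf.feature_names):
        ratios = []
        for perm in perms:
            permcol = rf.X[perm, j]
            sums = np.zeros(n)
            counts = np.zeros(n)
            for est, oob, Xo in zip(trees, oob_sets, oob_X):
                orig = Xo[:, j].copy()
                Xo[:, j] = permcol[oob]
                pred = est.predict(Xo, check_input=False)
                Xo[:, j] = orig
                sums[oob] += pred
                counts[oob] += 1
            valid = counts > 0
            resid = rf.y[valid] - sums[valid] / counts[valid]
            mse_perm = float(np.mean(resid**2))
            ratios.append((mse_perm - mse_base) / mse_base)
        rows.append(
            {
                "feature": name,
                "inc_mse_pct": 100.0 * float(np.mean(ratios)),
                "inc_mse_pct_sd": 100.0 * float(np.std(ratios, ddof=1)) if n_repeats > 1 else 0.0,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["inc_mse_pct", "feature"], ascending=[False, True], kind="stable"
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return ImportanceTable(
        table=table.reset_index(drop=True),
        n_repeats=n_repeats,
        seed=seed,
        oob_mse_baseline=mse_base,
    )


# ---------------------------------------------------------------------------
# partial dependence
# ---------------------------------------------------------------------------

@dataclass
class PDPCurve:
    feature: str
    grid: np.ndarray
    response: np.ndarray
    grid_policy: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"grid": self.grid, "response": self.response})


def partial_dependence_curve(
    rf: RFModel,
    feature_name: str,
    grid_points: int = 50,
    percentiles: tuple[float, float] = (1.0, 99.0),
) -> PDPCurve:
    """Brute-force partial dependence: for each grid value (equally spaced
    between the 1st and 99th percentile of the feature) set every row's
    feature to that value and average the forest's predictions."""
    if feature_name not in rf.feature_names:
        raise KeyError(f"feature {feature_name!r} not in model")
    j = rf.feature_names.index(feature_name)
    col = rf.X[:, j].astype(float)
    lo, hi = np.percentile(col, percentiles)
    grid = np.linspace(lo, hi, grid_points)
    response = np.empty(grid_points)
    Xc = rf.X.copy()
    for g, v in enumerate(grid):
        Xc[:, j] = v
        response[g] = float(rf.model.predict(Xc).mean())
    return PDPCurve(
        feature=feature_name,
        grid=grid,
        response=response,
        grid_policy=f"linspace p{percentiles[0]:g}-p{percentiles[1]:g}, {grid_points} points",
    )


# ---------------------------------------------------------------------------
# metrics and cross-validation
# ---------------------------------------------------------------------------

def rpiq(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Ratio of performance to interquartile distance: IQR(obs) / RMSE."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.size < 4:
        raise ValueError("need >= 4 observations for RPIQ")
    rmse = float(np.sqrt(np.mean((observed - predicted) ** 2)))
    iqr = float(np.percentile(observed, 75) - np.percentile(observed, 25))
    if rmse == 0.0:
        logger.warning("RPIQ with zero RMSE: returning inf")
        return math.inf
    return iqr / rmse


@dataclass
class CVReport:
    scenario: str
    k: int
    seed: int
    rmse: list[float]
    r2: list[float]
    rpiq: list[float]
    fold_policy: str = "seed-shuffled row-level k-fold"

    def summary(self) -> dict:
        def ms(v: list[float]) -> dict:
            return {
                "mean": float(np.mean(v)),
                "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
            }

        return {
            "scenario": self.scenario,
            "k": self.k,
            "seed": self.seed,
            "fold_policy": self.fold_policy,
            "rmse": ms(self.rmse),
            "r2": ms(self.r2),
            "rpiq": ms(self.rpiq),
        }


def cross_validate(
    features: pd.DataFrame,
    target: pd.Series | np.ndarray,
    k: int = 6,
    seed: int = 0,
    params: RFParams = RFParams(),
    scenario: str = "",
) -> CVReport:
    """Sixfold (by default) cross-validated RMSE / R² / RPIQ of the forest."""
    n = len(features)
    if n < 10 * k:
        raise ValueError(f"need >= {10 * k} rows for {k}-fold CV, got {n}")
    X = features.to_numpy(dtype=np.float32)
    y = np.asarray(target, dtype=float)
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    rmses, r2s, rpiqs = [], [], []
    for fold, (tr, te) in enumerate(kf.split(X)):
        model = params.build(seed + fold)
        model.set_params(oob_score=False)
        model.fit(X[tr], y[tr])
        pred = model.predict(X[te])
        rmses.append(float(np.sqrt(np.mean((y[te] - pred) ** 2))))
        r2s.append(float(r2_score(y[te], pred)))
        rpiqs.append(rpiq(y[te], pred))
    return CVReport(scenario=scenario, k=k, seed=seed, rmse=rmses, r2=r2s, rpiq=rpiqs)


# ---------------------------------------------------------------------------
# representative decision tree
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    node_id: int
    feature: str | None  # None for leaves
    threshold: float | None
    n: int
    mean_response: float
    left: int | None = None
    right: int | None = None


@dataclass
class DecisionRuleSet:
    nodes: list[TreeNode]
    rules: list[dict]  # leaf rules: predicates + n + mean response
    score_rmse_oob: float
    candidate_index: int

    def split_features(self, max_node_depth: int | None = None) -> list[tuple[str, float]]:
        """(feature, threshold) of internal splits, optionally only down to a
        node depth (root = depth 0)."""
        depths = {0: 0}
        for node in self.nodes:
            if node.feature is None:
                continue
            for child in (node.left, node.right):
                depths[child] = depths[node.node_id] + 1
        return [
            (n.feature, n.threshold)
            for n in self.nodes
            if n.feature is not None
            and (max_node_depth is None or depths[n.node_id] <= max_node_depth)
        ]

    def to_json_dict(self) -> dict:
        return {
            "score_rmse_oob": self.score_rmse_oob,
            "candidate_index": self.candidate_index,
            "nodes": [vars(n) for n in self.nodes],
            "rules": self.rules,
        }


def _extract_ruleset(
    tree: DecisionTreeRegressor,
    feature_names: list[str],
    score: float,
    candidate_index: int,
) -> DecisionRuleSet:
    t = tree.tree_
    nodes = []
    for i in range(t.node_count):
        is_leaf = t.children_left[i] == -1
        nodes.append(
            TreeNode(
                node_id=i,
                feature=None if is_leaf else feature_names[t.feature[i]],
                threshold=None if is_leaf else float(t.threshold[i]),
                n=int(t.n_node_samples[i]),
                mean_response=float(t.value[i][0][0]),
                left=None if is_leaf else int(t.children_left[i]),
                right=None if is_leaf else int(t.children_right[i]),
            )
        )
    rules = []

    def walk(i: int, preds: list[str]) -> None:
        if t.children_left[i] == -1:
            rules.append(
                {
                    "predicates": list(preds),
                    "n": int(t.n_node_samples[i]),
                    "mean_response": float(t.value[i][0][0]),
                }
            )
            return
        name = feature_names[t.feature[i]]
        thr = float(t.threshold[i])
        walk(t.children_left[i], preds + [f"{name} <= {thr:.4g}"])
        walk(t.children_right[i], preds + [f"{name} > {thr:.4g}"])

    walk(0, [])
    return DecisionRuleSet(
        nodes=nodes, rules=rules, score_rmse_oob=score, candidate_index=candidate_index
    )


def fit_representative_tree(
    features: pd.DataFrame,
    target: pd.Series | np.ndarray,
    n_candidates: int = 25,
    seed: int = 0,
    max_depth: int = 3,
    min_samples_leaf: int = 20,
) -> DecisionRuleSet:
    """Fit CART candidates on bootstrap resamples and keep the one with the
    lowest RMSE on its own out-of-bag rows — the 'most representative' tree."""
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    X = features.to_numpy(dtype=float)
    y = np.asarray(target, dtype=float)
    n = len(y)
    if min_samples_leaf * 2 > n:
        raise ValueError("min_samples_leaf unsatisfiable for this sample size")
    rng = np.random.default_rng(seed)
    best: tuple[float, int, DecisionTreeRegressor] | None = None
    for c in range(n_candidates):
        boot = rng.integers(0, n, n)
        oob_mask = np.ones(n, dtype=bool)
        oob_mask[boot] = False
        if not oob_mask.any():
            continue
        tree = DecisionTreeRegressor(
            max_depth=max_depth,
            min_samples_leaf=min_samples_leaf,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[boot], y[boot])
        pred = tree.predict(X[oob_mask])
        score = float(np.sqrt(np.mean((y[oob_mask] - pred) ** 2)))
        if best is None or score < best[0]:
            best = (score, c, tree)
    assert best is not None
    score, idx, tree = best
    return _extract_ruleset(tree, list(features.columns), score, idx)


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioSpec:
    id: str
    description: str
    include_li: bool
    climate: str  # "none" | "full" | "selected"

    def __post_init__(self) -> None:
        if self.climate not in ("none", "full", "selected"):
            raise ValueError(f"unknown climate mode {self.climate!r}")


SCENARIOS: dict[str, ScenarioSpec] = {
    "A": ScenarioSpec("A", "biological variables incl. light interception", True, "none"),
    "B": ScenarioSpec("B", "biological + full meteorological variables", True, "full"),
    "C": ScenarioSpec("C", "biological + selected meteorological variables", True, "selected"),
    "D": ScenarioSpec("D", "biological (no light interception) + full meteorological", False, "full"),
}


def build_design(
    features: pd.DataFrame,
    scenario: ScenarioSpec,
    selected_climate: list[str] | None = None,
) -> pd.DataFrame:
    """Predictor matrix for one scenario (cultivar one-hot encoded)."""
    bio = [c for c in BIO_COLUMNS if scenario.include_li or c != "light_interception"]
    missing = [c for c in bio if c not in features.columns]
    if missing:
        raise KeyError(f"scenario {scenario.id}: missing columns {missing}")
    cols = list(bio)
    if scenario.climate == "full":
        cols += climate_feature_columns(features)
    elif scenario.climate == "selected":
        if selected_climate is None:
            raise ValueError(f"scenario {scenario.id} needs a selected-climate list")
        missing = [c for c in selected_climate if c not in features.columns]
        if missing:
            raise KeyError(f"scenario {scenario.id}: missing columns {missing}")
        cols += list(selected_climate)
    return one_hot_cultivar(features[cols])


@dataclass
class ScenarioRunConfig:
    """Knobs for the full modelling pass (sizes kept explicit so runs can be
    scaled to the machine)."""

    seed: int = 0
    k_folds: int = 6
    rf_params: RFParams = field(default_factory=RFParams)
    r_min: float = DEFAULT_R_MIN
    r_cross_max: float = DEFAULT_R_CROSS_MAX
    importance_repeats: int = 10
    pdp_top_n: int = 6
    pdp_grid_points: int = 50
    tree_candidates: int = 25
    tree_max_depth: int = 3
    scenario_ids: tuple[str, ...] = ("A", "B", "C", "D")


def run_scenarios(
    features: pd.DataFrame,
    gaps: pd.DataFrame,
    config: ScenarioRunConfig = ScenarioRunConfig(),
    out_dir: str | Path | None = None,
) -> dict:
    """The full modelling stage for the three targets.

    * overall yield: cross-validated scenarios A-D plus interpretation
      (importance / PDPs / representative tree) of the selected-variable
      model,
    * yield gap (normalized yield): screened-climate + biological model,
    * light interception: biological (no LI) + full climate model.

    Returns a JSON-serialisable report; with ``out_dir`` set, also writes
    cv_report.json, scenario_comparison.csv, importance_*.csv, pdp_*.csv and
    rules_*.json.  Deterministic given the seed.
    """
    df = features.merge(gaps[["plot_id", "year", "y_n"]], on=["plot_id", "year"], validate="1:1")
    climate_cols = climate_feature_columns(features)
    y_yield = df[TARGET_COLUMN]
    y_gap = df["y_n"]
    y_li = df["light_interception"]

    sel_yield = pearson_screen(
        df[climate_cols], y_yield, config.r_min, config.r_cross_max
    )
    sel_gap = pearson_screen(df[climate_cols], y_gap, config.r_min, config.r_cross_max)

    report: dict = {
        "seed": config.seed,
        "selected_climate_yield": sel_yield.selected,
        "selected_climate_gap": sel_gap.selected,
        "cv": {},
    }
    artifacts: dict[str, object] = {}

    # --- scenario cross-validation on overall yield
    for sid in config.scenario_ids:
        spec = SCENARIOS[sid]
        X = build_design(df, spec, sel_yield.selected)
        cv = cross_validate(
            X, y_yield, k=config.k_folds, seed=config.seed, params=config.rf_params,
            scenario=sid,
        )
        report["cv"][sid] = cv.summary()

    # --- interpretation models
    def interpret(tag: str, X: pd.DataFrame, y: pd.Series, pdp_features_hint: list[str]) -> dict:
        rf = fit_rf(X, y, seed=config.seed, params=config.rf_params)
        imp = importance_incmse(rf, n_repeats=config.importance_repeats, seed=config.seed)
        top = list(imp.table["feature"].head(config.pdp_top_n))
        for f in pdp_features_hint:
            if f in X.columns and f not in top:
                top.append(f)
        pdps = {
            f: partial_dependence_curve(rf, f, grid_points=config.pdp_grid_points)
            for f in top
        }
        tree = fit_representative_tree(
            X, y,
            n_candidates=config.tree_candidates,
            seed=config.seed,
            max_depth=config.tree_max_depth,
        )
        artifacts[f"importance_{tag}"] = imp
        artifacts[f"pdp_{tag}"] = pdps
        artifacts[f"rules_{tag}"] = tree
        return {
            "oob_r2": rf.oob_r2,
            "top_features": list(imp.table["feature"].head(10)),
            "tree_splits": tree.split_features(),
        }

    # overall yield model on biological + selected climate (scenario C design)
    X_yield = build_design(df, SCENARIOS["C"], sel_yield.selected)
    report["yield_model"] = interpret("yield", X_yield, y_yield, [])

    # yield-gap model: biological (no LI) + climate selected against the gap,
    # always retaining the two canonical seasonal stressors (hypothesis-driven
    # variables are kept even when the redundancy rule would swap them for a
    # correlated proxy)
    bio_no_li = [c for c in BIO_COLUMNS if c != "light_interception"]
    canonical = [c for c in ("vpdmax_summer_cur", "tmean_winter_cur") if c in df.columns]
    gap_climate = sel_gap.selected + [c for c in canonical if c not in sel_gap.selected]
    X_gap = one_hot_cultivar(df[bio_no_li + gap_climate])
    report["gap_model"] = interpret("gap", X_gap, y_gap, canonical)

    # light-interception model: biological (no LI) + full climate
    X_li = one_hot_cultivar(df[bio_no_li + climate_cols])
    report["li_model"] = interpret("li", X_li, y_li, [])

    if out_dir is not None:
        _write_artifacts(Path(out_dir), report, artifacts)
    return report


def _write_artifacts(out: Path, report: dict, artifacts: dict[str, object]) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "cv_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    rows = []
    for sid, summ in report["cv"].items():
        rows.append(
            {
                "scenario": sid,
                "description": SCENARIOS[sid].description,
                "rmse_mean": summ["rmse"]["mean"],
                "rmse_sd": summ["rmse"]["sd"],
                "r2_mean": summ["r2"]["mean"],
                "r2_sd": summ["r2"]["sd"],
                "rpiq_mean": summ["rpiq"]["mean"],
                "rpiq_sd": summ["rpiq"]["sd"],
            }
        )
    pd.DataFrame(rows).to_csv(out / "scenario_comparison.csv", index=False)
    for key, obj in artifacts.items():
        if key.startswith("importance_"):
            obj.table.to_csv(out / f"{key}.csv", index=False)
        elif key.startswith("pdp_"):
            for fname, curve in obj.items():
                safe = fname.replace("/", "_")
                curve.to_frame().to_csv(out / f"{key}_{safe}.csv", index=False)
        elif key.startswith("rules_"):
            (out / f"{key}.json").write_text(
                json.dumps(obj.to_json_dict(), indent=2, sort_keys=True)
            )
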