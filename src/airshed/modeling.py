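"""Regression machinery: OLS core, bivariate screening, category-constrained
forward stepwise selection, an unconstrained automated comparator, and
session-interaction tests.

Model building follows the campaign design: session dummies are forced
into every model (the last session label is the reference level); the
best airport proxy enters first; traffic and distance-to-road candidates
are then added greedily by bivariate p-value, one variable per base
metric, each retained only while its multivariate p stays below the
entry threshold. Partial R-squared is the sequential (entry-order)
incremental R-squared, so the per-group shares telescope exactly to the
total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import RunConfig

CATEGORIES = ("airport_proxy", "dist_road_class", "traffic_proxy")

_AIRPORT_PREFIXES = ("dist_terminal", "dist_runway", "dist_centroid", "dist_fence")

NON_COVARIATE_COLUMNS = {"record_id", "session", "fence_flag", "no2_ppb"}


def categorize(term: str) -> str:
    """Covariate category: airport proxy, distance to road class, or
    (other) traffic proxy."""
    if term.startswith(_AIRPORT_PREFIXES):
        return "airport_proxy"
    if term.startswith("dist_class"):
        return "dist_road_class"
    return "traffic_proxy"


def base_metric(term: str) -> str:
    """The underlying data source of a covariate.

    Variables built from the same source at different radii (or with a
    wind-rose reweighting) share a base metric and may not coexist in one
    structured model. Kernel traffic density and ADT-weighted road length
    are both ADT-weighted syntheses of the whole network, so they share
    the base 'adt_density'.
    """
    if term.startswith("traffic_density") or term.startswith("adt_len"):
        return "adt_density"
    if term.startswith("windlen_class"):
        return "len_class" + term.removeprefix("windlen_class")
    if term.startswith("dist_"):
        return term   # distances carry no radius suffix
    parts = term.rsplit("_", 1)
    if len(parts) == 2 and parts[1].isdigit():
        return parts[0]
    return term


def term_radius(term: str) -> float | None:
    parts = term.rsplit("_", 1)
    if len(parts) == 2 and parts[1].isdigit():
        return float(parts[1])
    return None


def term_metadata(columns) -> pd.DataFrame:
    """Category / base metric / radius registry for covariate columns."""
    rows = [
        {"term": c, "category": categorize(c), "base_metric": base_metric(c),
         "radius": term_radius(c)}
        for c in columns if c not in NON_COVARIATE_COLUMNS
    ]
    df = pd.DataFrame(rows).set_index("term")
    if df.index.has_duplicates:
        raise ValueError("duplicate covariate columns")
    return df


def sessions_in_order(cov: pd.DataFrame) -> list[str]:
    """Session labels by first appearance (the last is the reference)."""
    return list(pd.unique(cov["session"]))


def design_matrix(
    cov: pd.DataFrame,
    terms: list[str],
    sessions_order: list[str] | None = None,
) -> pd.DataFrame:
    """Intercept + session dummies (reference = last session) + terms."""
    if sessions_order is None:
        sessions_order = sessions_in_order(cov)
    X = pd.DataFrame({"const": np.ones(len(cov))}, index=cov.index)
    for s in sessions_order[:-1]:
        X[f"session_{s}"] = (cov["session"] == s).astype(float)
    for t in terms:
        X[t] = cov[t].to_numpy(float)
    return X


@dataclass
class FittedLUR:
    """A fitted general linear model of NO2 on GIS covariates.

    ``terms`` is the full design column order (sessions first);
    ``entry_order`` the covariate entry sequence used for the sequential
    partial R-squared decomposition.
    """

    terms: list[str]
    params: pd.Series
    se: pd.Series
    t: pd.Series
    p: pd.Series
    r2: float
    n: int
    residuals: np.ndarray
    sessions_order: list[str]
    entry_order: list[str] = field(default_factory=list)
    partial_r2: dict[str, float] = field(default_factory=dict)

    @property
    def covariate_terms(self) -> list[str]:
        return [t for t in self.terms
                if t != "const" and not t.startswith("session_")]

    def summary_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "estimate": self.params, "se": self.se, "t": self.t, "p": self.p,
        })
        df["partial_r2"] = [self.partial_r2.get(
            "sessions" if t.startswith("session_") else t, np.nan)
            for t in df.index]
        return df

    @classmethod
    def from_coefficients(
        cls,
        intercept: float,
        session_effects: dict[str, float],
        coefficients: dict[str, float],
        sessions_order: list[str] | None = None,
    ) -> "FittedLUR":
        """Assemble a prediction-only model from printed coefficients.

        The reference session (zero effect) must be the last label of
        ``sessions_order``; inferential fields (SE, t, p) are NaN.
        """
        if sessions_order is None:
            sessions_order = list(session_effects)
        params = {"const": intercept}
        for s in sessions_order[:-1]:
            params[f"session_{s}"] = session_effects.get(s, 0.0)
        params.update(coefficients)
        params = pd.Series(params, dtype=float)
        nan = pd.Series(np.nan, index=params.index)
        return cls(terms=list(params.index), params=params, se=nan.copy(),
                   t=nan.copy(), p=nan.copy(), r2=float("nan"), n=0,
                   residuals=np.array([]), sessions_order=list(sessions_order),
                   entry_order=list(coefficients))


class RankDeficiencyError(ValueError):
    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design is rank deficient; collinear columns: {self.columns}")


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(float)
    rank = np.linalg.matrix_rank(arr)
    if rank < X.shape[1]:
        # pivoted QR points at the dependent columns
        from scipy.linalg import qr

        _, _, piv = qr(arr, mode="economic", pivoting=True)
        raise RankDeficiencyError([X.columns[i] for i in sorted(piv[rank:])])


def fit_glm(response, design: pd.DataFrame) -> FittedLUR:
    """Ordinary least squares with classical standard errors.

    ``design`` must already contain the intercept and session dummies
    (see :func:`design_matrix`); raises on rank deficiency, listing the
    collinear columns.
    """
    y = np.asarray(response, dtype=float)
    if len(y) <= design.shape[1]:
        raise ValueError("need more observations than design columns")
    _check_full_rank(design)
    res = sm.OLS(y, design).fit()
    sessions = [c.removeprefix("session_") for c in design.columns
                if c.startswith("session_")]
    return FittedLUR(
        terms=list(design.columns),
        params=res.params, se=res.bse, t=res.tvalues, p=res.pvalues,
        r2=float(res.rsquared), n=int(res.nobs),
        residuals=np.asarray(res.resid),
        sessions_order=sessions + ["<reference>"],
    )


def fit_terms(
    cov: pd.DataFrame,
    terms: list[str],
    sessions_order: list[str] | None = None,
    response: str = "no2_ppb",
) -> FittedLUR:
    """Fit NO2 on session dummies plus the given covariate terms."""
    if sessions_order is None:
        sessions_order = sessions_in_order(cov)
    X = design_matrix(cov, terms, sessions_order)
    fit = fit_glm(cov[response], X)
    fit.sessions_order = list(sessions_order)
    fit.entry_order = list(terms)
    fit.partial_r2 = sequential_partial_r2(cov, terms, sessions_order, response)
    return fit


def predict(model: FittedLUR, rows: pd.DataFrame) -> np.ndarray:
    """Linear predictor at covariate rows (must carry a 'session' column
    and every covariate term of the model)."""
    missing = [t for t in model.covariate_terms if t not in rows.columns]
    if missing:
        raise KeyError(f"rows lack model terms: {missing}")
    unknown = set(rows["session"]) - set(model.sessions_order)
    if unknown:
        raise KeyError(f"rows carry sessions unknown to the model: {sorted(unknown)}")
    X = design_matrix(rows, model.covariate_terms, model.sessions_order)[model.terms]
    return X.to_numpy(float) @ model.params.loc[model.terms].to_numpy(float)


def sequential_partial_r2(
    cov: pd.DataFrame,
    entry_order: list[str],
    sessions_order: list[str] | None = None,
    response: str = "no2_ppb",
) -> dict[str, float]:
    """Entry-order incremental R-squared per term group.

    Session dummies form the first group ("sessions"); each covariate
    term is its own group. Increments telescope to the full-model
    R-squared exactly.
    """
    if sessions_order is None:
        sessions_order = sessions_in_order(cov)
    y = cov[response].to_numpy(float)
    out: dict[str, float] = {}
    prev_r2 = 0.0
    included: list[str] = []
    for group in ["sessions"] + list(entry_order):
        if group != "sessions":
            included.append(group)
        X = design_matrix(cov, included, sessions_order)
        r2 = float(sm.OLS(y, X).fit().rsquared)
        out[group] = r2 - prev_r2
        prev_r2 = r2
    return out


# -------------------------------------------------------------- screening

def bivariate_screen(
    cov: pd.DataFrame,
    config: RunConfig,
    sessions_order: list[str] | None = None,
) -> pd.DataFrame:
    """One session-adjusted GLM per covariate.

    Each fit regresses NO2 on the session dummies plus a single
    covariate; returns a frame (term, estimate, se, t, p, category,
    base_metric) sorted by p within category. Undefined (all-NaN) and
    zero-variance covariates are skipped and listed in
    ``result.attrs["skipped"]``.
    """
    if sessions_order is None:
        sessions_order = sessions_in_order(cov)
    meta = term_metadata(cov.columns)
    rows, skipped = [], []
    for term in meta.index:
        x = cov[term].to_numpy(float)
        if np.any(np.isnan(x)) or np.std(x) == 0.0:
            skipped.append(term)
            continue
        X = design_matrix(cov, [term], sessions_order)
        try:
            fit = fit_glm(cov["no2_ppb"], X)
        except RankDeficiencyError:
            skipped.append(term)
            continue
        rows.append({
            "term": term,
            "estimate": fit.params[term], "se": fit.se[term],
            "t": fit.t[term], "p": fit.p[term],
            "category": meta.loc[term, "category"],
            "base_metric": meta.loc[term, "base_metric"],
        })
    df = pd.DataFrame(rows)
    if len(df):
        df["category"] = pd.Categorical(df["category"], categories=CATEGORIES)
        df = df.sort_values(["category", "p", "term"]).reset_index(drop=True)
    df.attrs["skipped"] = skipped
    return df


def _best(group: pd.DataFrame) -> pd.Series:
    """Strongest association: smallest p, then larger |t|, then name."""
    g = group.assign(abs_t=group["t"].abs())
    g = g.sort_values(["p", "abs_t", "term"], ascending=[True, False, True])
    return g.iloc[0]


def select_candidates(screen: pd.DataFrame, p_enter: float = 0.05) -> dict[str, str]:
    """One candidate term per category: the strongest significant
    association. Categories with no significant term are omitted."""
    out: dict[str, str] = {}
    for cat in CATEGORIES:
        sub = screen[(screen["category"] == cat) & (screen["p"] < p_enter)]
        if len(sub):
            out[cat] = str(_best(sub)["term"])
    return out


def _candidate_pool(screen: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Best significant variant per base metric among the traffic and
    distance-to-road categories, ordered by ascending bivariate p.

    Buffer variants wider than ``candidate_max_radius_m`` are screened
    but not admitted as structured candidates.
    """
    pool = screen[screen["category"].isin(["traffic_proxy", "dist_road_class"])]
    pool = pool[pool["p"] < config.p_enter]
    if not config.include_wind_weighted:
        pool = pool[~pool["term"].str.startswith("windlen")]
    radii = pool["term"].map(term_radius)
    pool = pool[radii.isna() | (radii <= config.candidate_max_radius_m)]
    rows = [_best(g) for _, g in pool.groupby("base_metric", observed=True)]
    if not rows:
        return pool.iloc[0:0]
    return pd.DataFrame(rows).sort_values(["p", "term"]).reset_index(drop=True)


def structured_stepwise(
    cov: pd.DataFrame,
    config: RunConfig,
    sessions_order: list[str] | None = None,
) -> FittedLUR:
    """Category-constrained forward stepwise model building.

    Sessions are always included. The strongest significant airport
    proxy enters first; candidates from the traffic-proxy and
    distance-to-road categories (one variable per base metric) are then
    added greedily by bivariate p-value. A candidate is retained only if
    its multivariate p stays below ``p_enter``; after each addition any
    term whose p rose above the threshold is removed again. Worst case
    the sessions-only model is returned.
    """
    if sessions_order is None:
        sessions_order = sessions_in_order(cov)
    screen = bivariate_screen(cov, config, sessions_order)
    included: list[str] = []
    blocked_bases: set[str] = set()

    def try_add(term: str) -> bool:
        trial = included + [term]
        try:
            fit = fit_terms(cov, trial, sessions_order)
        except (RankDeficiencyError, ValueError):
            return False
        if fit.p[term] >= config.p_enter:
            return False
        included.append(term)
        # backward pass: evict anything the new term displaced
        while True:
            fit = fit_terms(cov, included, sessions_order)
            worst, worst_p = None, config.p_enter
            for t in included:
                if fit.p[t] >= worst_p:
                    worst, worst_p = t, fit.p[t]
            if worst is None:
                break
            included.remove(worst)
            blocked_bases.discard(base_metric(worst))
        return term in included

    if len(screen):
        airport = screen[(screen["category"] == "airport_proxy")
                         & (screen["p"] < config.p_enter)]
        if len(airport):
            term = str(_best(airport)["term"])
            if try_add(term):
                blocked_bases.add(base_metric(term))
        for _, row in _candidate_pool(screen, config).iterrows():
            term = str(row["term"])
            if base_metric(term) in blocked_bases or term in included:
                continue
            if try_add(term):
                blocked_bases.add(base_metric(term))
    return fit_terms(cov, included, sessions_order)


def automated_stepwise(
    cov: pd.DataFrame,
    config: RunConfig,
    sessions_order: list[str] | None = None,
    structured: FittedLUR | None = None,
) -> tuple[FittedLUR, dict]:
    """Classical unconstrained forward stepwise over all screening-
    significant terms (enter/stay at ``p_enter``).

    Serves as a comparator for the structured procedure. The report
    flags coefficient signs that disagree with the bivariate screen (the
    "counterintuitive effect" check), pairs of included covariates with
    |correlation| >= 0.95, and the term-set difference versus a
    structured fit when one is supplied.
    """
    if sessions_order is None:
        sessions_order = sessions_in_order(cov)
    screen = bivariate_screen(cov, config, sessions_order)
    pool = screen[screen["p"] < config.p_enter]
    if not config.include_wind_weighted:
        pool = pool[~pool["term"].str.startswith("windlen")]
    candidates = list(pool["term"])
    bivariate_sign = dict(zip(screen["term"], np.sign(screen["estimate"])))

    included: list[str] = []
    while True:
        best_term, best_p = None, config.p_enter
        for term in candidates:
            if term in included:
                continue
            try:
                fit = fit_terms(cov, included + [term], sessions_order)
            except (RankDeficiencyError, ValueError):
                continue
            if fit.p[term] < best_p:
                best_term, best_p = term, fit.p[term]
        if best_term is None:
            break
        included.append(best_term)
        while True:  # backward elimination at the same threshold
            fit = fit_terms(cov, included, sessions_order)
            drop = [t for t in included if fit.p[t] >= config.p_enter]
            if not drop:
                break
            included.remove(max(drop, key=lambda t: fit.p[t]))

    fit = fit_terms(cov, included, sessions_order)
    report = {
        "sign_flips_vs_bivariate": [
            t for t in included
            if np.sign(fit.params[t]) != bivariate_sign.get(t, np.sign(fit.params[t]))
        ],
        "collinear_pairs": _collinear_pairs(cov, included, threshold=0.95),
    }
    if structured is not None:
        report["terms_only_in_automated"] = sorted(
            set(included) - set(structured.covariate_terms))
        report["terms_only_in_structured"] = sorted(
            set(structured.covariate_terms) - set(included))
        shared = set(included) & set(structured.covariate_terms)
        report["sign_disagreements_vs_structured"] = sorted(
            t for t in shared
            if np.sign(fit.params[t]) != np.sign(structured.params[t])
        )
    return fit, report


def _collinear_pairs(cov: pd.DataFrame, terms: list[str], threshold: float) -> list[tuple[str, str]]:
    pairs = []
    for i, a in enumerate(terms):
        for b in terms[i + 1:]:
            rho = np.corrcoef(cov[a].to_numpy(float), cov[b].to_numpy(float))[0, 1]
            if abs(rho) >= threshold:
                pairs.append((a, b))
    return pairs


# ------------------------------------------------------------ interactions

def session_interactions(
    model: FittedLUR,
    cov: pd.DataFrame,
    sessions_order: list[str] | None = None,
) -> pd.DataFrame:
    """Season-varying-slope check for every covariate in a fitted model.

    For each non-session term the final model is refit with
    session x term interaction columns added; the interaction block is
    tested jointly (F-test against the main-effects model) and the
    per-session slopes are reported.
    """
    if sessions_order is None:
        sessions_order = sessions_in_order(cov)
    terms = model.covariate_terms
    y = cov["no2_ppb"].to_numpy(float)
    base_X = design_matrix(cov, terms, sessions_order)
    base_fit = sm.OLS(y, base_X).fit()
    reference = sessions_order[-1]
    rows = []
    for term in terms:
        X = base_X.copy()
        int_cols = []
        for s in sessions_order[:-1]:
            col = f"{term}:session_{s}"
            X[col] = X[term] * X[f"session_{s}"]
            int_cols.append(col)
        full_fit = sm.OLS(y, X).fit()
        fval, pval, _ = full_fit.compare_f_test(base_fit)
        slopes = {f"slope_{reference}": full_fit.params[term]}
        for s, col in zip(sessions_order[:-1], int_cols):
            slopes[f"slope_{s}"] = full_fit.params[term] + full_fit.params[col]
        rows.append({"term": term, "interaction_F": float(fval),
                     "interaction_p": float(pval), **slopes})
    return pd.DataFrame(rows)
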