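"""Robustness checks on a final model: subsample stability, fence versus
non-fence refits, and per-session model building."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .modeling import FittedLUR, fit_terms, sessions_in_order, structured_stepwise


@dataclass
class StabilityReport:
    """Coefficient stability across random subsamples at one fraction."""

    fraction: float
    replicates: int
    seed: int
    per_term: pd.DataFrame   # index term: mean_estimate, sd_estimate, share_significant
    n_skipped: int = 0


def _stratified_subsample(cov: pd.DataFrame, fraction: float,
                          rng: np.random.Generator) -> pd.DataFrame:
    """Simple random subsample without replacement, stratified by session
    so the session dummies stay estimable."""
    parts = []
    for _, g in cov.groupby("session", sort=False):
        k = max(1, int(round(fraction * len(g))))
        idx = rng.choice(len(g), size=min(k, len(g)), replace=False)
        parts.append(g.iloc[np.sort(idx)])
    return pd.concat(parts, ignore_index=True)


def subsample_stability(
    cov: pd.DataFrame,
    terms: list[str],
    fractions: list[float],
    replicates: int,
    seed: int,
    config: RunConfig,
    p_threshold: float | None = None,
) -> list[StabilityReport]:
    """Refit a fixed term set on random subsamples of the records.

    For each fraction and replicate the final model's terms are refit on
    a without-replacement subsample (stratified by session); the report
    aggregates the estimate mean and SD and the share of replicates in
    which each term stayed significant. A fraction of 1.0 reproduces the
    full-data fit exactly in every replicate.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    if any(not 0.0 < f <= 1.0 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    if p_threshold is None:
        p_threshold = config.p_enter
    sessions_order = sessions_in_order(cov)
    rng = np.random.default_rng(seed)
    reports = []
    for frac in fractions:
        estimates: dict[str, list[float]] = {t: [] for t in terms}
        signif: dict[str, list[bool]] = {t: [] for t in terms}
        n_skipped = 0
        for _ in range(replicates):
            sub = cov if frac >= 1.0 else _stratified_subsample(cov, frac, rng)
            if len(sub) <= len(terms) + len(sessions_order):
                n_skipped += 1
                continue
            try:
                fit = fit_terms(sub, terms, sessions_order)
            except ValueError:
                n_skipped += 1
                continue
            for t in terms:
                estimates[t].append(float(fit.params[t]))
                signif[t].append(bool(fit.p[t] < p_threshold))
        per_term = pd.DataFrame({
            "mean_estimate": {t: np.mean(v) if v else np.nan for t, v in estimates.items()},
            # identical replicates (fraction 1.0) get an exact zero, not
            # the ulp-level artifact of the mean subtraction
            "sd_estimate": {t: (0.0 if len(set(v)) == 1 else np.std(v, ddof=1))
                            if len(v) > 1 else np.nan
                            for t, v in estimates.items()},
            "share_significant": {t: np.mean(v) if v else np.nan for t, v in signif.items()},
        })
        reports.append(StabilityReport(fraction=frac, replicates=replicates,
                                       seed=seed, per_term=per_term,
                                       n_skipped=n_skipped))
    return reports


def split_refit(
    cov: pd.DataFrame,
    terms: list[str],
    config: RunConfig,
    split_flag: str = "fence_flag",
) -> dict:
    """Refit the final term set separately within each stratum of a flag.

    Returns the full-data fit, the per-stratum fits, and the percent
    difference of each stratum estimate versus the full-data estimate
    (NaN for an unfittable stratum).
    """
    sessions_order = sessions_in_order(cov)
    full = fit_terms(cov, terms, sessions_order)
    fits: dict[int, FittedLUR | None] = {}
    rows = {}
    for value, g in cov.groupby(split_flag, sort=True):
        try:
            fit = fit_terms(g, terms, sessions_order)
        except ValueError:
            fits[value] = None
            rows[value] = pd.Series(np.nan, index=terms)
            continue
        fits[value] = fit
        rows[value] = pd.Series(
            {t: 100.0 * (fit.params[t] - full.params[t]) / abs(full.params[t])
             if full.params[t] != 0 else np.nan for t in terms})
    comparison = pd.DataFrame(rows)
    comparison.columns = [f"{split_flag}={v}_pct_diff" for v in comparison.columns]
    return {"full": full, "strata": fits, "percent_difference": comparison}


def per_session_models(cov: pd.DataFrame, config: RunConfig) -> dict:
    """Independent structured stepwise within each session.

    Single-session data carry no session dummies, so each model is an
    intercept plus selected covariates. The category-overlap metric is
    the Jaccard index, across sessions, of the selected explanatory
    source categories — airport proximity versus traffic (distance to
    road class and other traffic proxies combined) — 1.0 when every
    session's model represents the same sources. The per-session base
    metric sets are also reported for finer comparison.
    """
    from .modeling import base_metric, categorize

    fits: dict[str, FittedLUR] = {}
    term_sets: dict[str, set[str]] = {}
    cat_sets: dict[str, set[str]] = {}
    for session, g in cov.groupby("session", sort=False):
        fit = structured_stepwise(g.reset_index(drop=True), config,
                                  sessions_order=[str(session)])
        fits[str(session)] = fit
        term_sets[str(session)] = {base_metric(t) for t in fit.covariate_terms}
        cat_sets[str(session)] = {
            "airport" if categorize(t) == "airport_proxy" else "traffic"
            for t in fit.covariate_terms
        }
    sets = list(cat_sets.values())
    union = set().union(*sets) if sets else set()
    inter = set.intersection(*sets) if sets else set()
    overlap = len(inter) / len(union) if union else 1.0
    return {"fits": fits, "base_metric_sets": term_sets,
            "category_sets": cat_sets, "category_overlap": overlap}
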