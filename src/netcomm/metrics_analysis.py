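"""Per-run and cross-run summary statistics.

Quantitative genetics: narrow-sense heritability h² is estimated each
generation as the ordinary least-squares slope of offspring trait values on
mid-parent trait values, and additive variance as h² times the phenotypic
variance.  Slopes outside [0, 1] are reported raw — they are sampling noise,
not clipped.

Community metrics: *coexistence* means both species are still present
regionally when the run reaches its horizon; *persistence time* is the
generation of the first regional extinction (capped at the horizon).  The
ecosystem-function proxies compare the regional census with a critical
population size — 0.9 times the maximum regional census observed across a
set of runs — via the first generation above that threshold and the
fraction of generations spent above it.  The metapopulation/metacommunity
contrast subtracts, from each two-species run, the single-species mean of
the same metric matched on landscape arrangement.

*Mismatch* is the census-weighted mean absolute gap between each patch's
mean trait value and its resource quality, averaged over post-canalization
generations — a direct measure of how well populations track their local
optimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from netcomm.engine import RunRecord

__all__ = [
    "midparent_heritability",
    "coexistence",
    "persistence_time",
    "critical_population",
    "time_to_09k",
    "prop_above_09k",
    "metrics_09k_table",
    "metapop_contrast",
    "mismatch",
    "fit_summary_models",
    "ModelReport",
]


def midparent_heritability(
    offspring_phenotypes: np.ndarray, midparent_phenotypes: np.ndarray
) -> float:
    """OLS slope of offspring on mid-parent trait values (h² estimate).

    Returns NaN when fewer than 3 pairs are available or the mid-parent
    variance is (numerically) zero.
    """
    off = np.asarray(offspring_phenotypes, dtype=float)
    mid = np.asarray(midparent_phenotypes, dtype=float)
    if off.shape != mid.shape:
        raise ValueError("offspring and midparent arrays must be paired")
    if off.size < 3:
        return float("nan")
    mid_c = mid - mid.mean()
    denom = float(mid_c @ mid_c)
    if denom <= 1e-12 * off.size:
        return float("nan")
    return float(mid_c @ (off - off.mean()) / denom)


# ---------------------------------------------------------------------------
# per-run community metrics
# ---------------------------------------------------------------------------

def coexistence(run: "RunRecord") -> bool:
    """True iff both species have positive regional census at the run horizon."""
    if run.generations_run < run.config.generations:
        return False
    last = run.table.iloc[-1]
    founded = [sp.name for sp in run.params if sp.n0 > 0]
    if len(founded) < 2:
        return False
    return all(
        sum(last[f"census_{name}_p{p}"] for p in range(3)) > 0 for name in founded
    )


def persistence_time(run: "RunRecord") -> int:
    """Generation of the first regional species extinction, capped at the horizon."""
    gens = [g for g in run.extinction_gen.values() if g is not None]
    return min(gens) if gens else run.config.generations


def critical_population(runs: Sequence["RunRecord"]) -> float:
    """0.9 × the maximum regional census observed across all given runs."""
    if not runs:
        raise ValueError("critical_population needs at least one run")
    return 0.9 * max(float(r.total_regional_census().max()) for r in runs)


def time_to_09k(run: "RunRecord", threshold: float) -> float:
    """First generation with regional census above ``threshold`` (NaN if never)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    census = run.total_regional_census()
    above = run.table["generation"][census > threshold]
    return float(above.iloc[0]) if len(above) else float("nan")


def prop_above_09k(run: "RunRecord", threshold: float) -> float:
    """Fraction of recorded generations with regional census above ``threshold``."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    census = run.total_regional_census()
    return float((census > threshold).mean())


def metrics_09k_table(
    runs: Sequence["RunRecord"],
    labels: Sequence[str],
    threshold: float,
) -> pd.DataFrame:
    """One row per run: landscape label and both critical-population metrics."""
    if len(runs) != len(labels):
        raise ValueError("one landscape label per run required")
    return pd.DataFrame(
        {
            "landscape": list(labels),
            "time_to_09k": [time_to_09k(r, threshold) for r in runs],
            "prop_above_09k": [prop_above_09k(r, threshold) for r in runs],
        }
    )


def metapop_contrast(
    metacomm: pd.DataFrame, metapop: pd.DataFrame
) -> pd.DataFrame:
    """Two-species metrics minus the matched single-species means.

    Both tables need ``landscape``, ``time_to_09k`` and ``prop_above_09k``
    columns (see :func:`metrics_09k_table`).  Each metacommunity run is
    matched to the mean of the metapopulation runs with the same landscape
    label; an unmatched label is an error.
    """
    means = metapop.groupby("landscape")[["time_to_09k", "prop_above_09k"]].mean()
    missing = set(metacomm["landscape"]) - set(means.index)
    if missing:
        raise ValueError(f"no metapopulation runs for landscapes: {sorted(missing)}")
    out = metacomm.copy()
    matched = means.loc[out["landscape"]].to_numpy()
    out["delta_time_to_09k"] = out["time_to_09k"].to_numpy() - matched[:, 0]
    out["delta_prop_above_09k"] = out["prop_above_09k"].to_numpy() - matched[:, 1]
    return out


def mismatch(run: "RunRecord", skip_canalization: bool = True) -> float:
    """Census-weighted mean |patch mean trait − patch resource quality|.

    Averaged over patches, species and (by default post-canalization)
    generations, with each patch × species cell weighted by its census.
    Empty cells carry zero weight; returns NaN if nothing is alive.
    """
    tab = run.table
    if skip_canalization:
        tab = tab[tab["generation"] > run.config.canalization_gens]
    num = 0.0
    den = 0.0
    for sp in run.params:
        name = sp.name
        for p in range(3):
            w = tab[f"census_{name}_p{p}"].to_numpy(dtype=float)
            phen = tab[f"mean_phen_{name}_p{p}"].to_numpy(dtype=float)
            q = tab[f"resource_q_p{p}"].to_numpy(dtype=float)
            ok = (w > 0) & np.isfinite(phen)
            num += float((w[ok] * np.abs(phen[ok] - q[ok])).sum())
            den += float(w[ok].sum())
    return num / den if den > 0 else float("nan")


# ---------------------------------------------------------------------------
# cross-run models
# ---------------------------------------------------------------------------

@dataclass
class ModelReport:
    """Factor-level summaries of the coexistence and persistence models."""

    coexistence_table: pd.DataFrame | None
    persistence_table: pd.DataFrame | None
    warnings: list[str]


def _sequential_deviance(summary: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    """Type-I (sequential) analysis of deviance for a binomial-logit GLM."""
    import statsmodels.api as sm
    from scipy import stats

    y = summary["coexistence"].astype(float).to_numpy()
    rows = []
    X = np.ones((len(summary), 1))
    prev = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    for term in terms:
        X = np.column_stack([X, summary[term].astype(float).to_numpy()])
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        drop = prev.deviance - fit.deviance
        rows.append(
            {
                "factor": term,
                "df": 1,
                "deviance": drop,
                "p_value": float(stats.chi2.sf(max(drop, 0.0), 1)),
            }
        )
        prev = fit
    rows.append(
        {
            "factor": "residual",
            "df": int(prev.df_resid),
            "deviance": prev.deviance,
            "p_value": float("nan"),
        }
    )
    return pd.DataFrame(rows)


def _sequential_variance(summary: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    """Type-I percentage of variance in persistence time explained per term."""
    import statsmodels.api as sm
    from scipy import stats

    y = summary["persistence"].astype(float).to_numpy()
    sst = float(((y - y.mean()) ** 2).sum())
    rows = []
    X = np.ones((len(summary), 1))
    prev_sse = sst
    for term in terms:
        X = np.column_stack([X, summary[term].astype(float).to_numpy()])
        fit = sm.OLS(y, X).fit()
        sse = float(fit.ssr)
        ss_term = prev_sse - sse
        f = ss_term / max(sse / max(fit.df_resid, 1), 1e-300)
        rows.append(
            {
                "factor": term,
                "pct_var": 100.0 * ss_term / sst if sst > 0 else float("nan"),
                "p_value": float(stats.f.sf(max(f, 0.0), 1, max(fit.df_resid, 1))),
            }
        )
        prev_sse = sse
    rows.append(
        {
            "factor": "residual",
            "pct_var": 100.0 * prev_sse / sst if sst > 0 else float("nan"),
            "p_value": float("nan"),
        }
    )
    return pd.DataFrame(rows)


def fit_summary_models(
    summary: pd.DataFrame,
    coexistence_terms: list[str] | None = None,
    persistence_terms: list[str] | None = None,
) -> ModelReport:
    """Fit the standard cross-run models to an experiment summary table.

    Coexistence is modeled by a binomial GLM with logit link on competitor
    dispersal, competitor network size and landscape heterogeneity;
    persistence time by a linear model on competitor dispersal, network
    size and mutation rate.  Both report sequential (Type-I) contributions
    per factor.  Terms whose column is constant in the data are dropped
    with a warning (a single-level factor carries no information).
    """
    warnings: list[str] = []
    coexistence_terms = coexistence_terms or [
        "competitor_d",
        "competitor_n",
        "heterogeneity",
    ]
    persistence_terms = persistence_terms or [
        "competitor_d",
        "competitor_n",
        "competitor_mu",
    ]

    def usable(terms: list[str]) -> list[str]:
        kept = []
        for t in terms:
            if t not in summary.columns:
                warnings.append(f"term {t!r} missing from summary; dropped")
            elif summary[t].nunique() < 2:
                warnings.append(f"term {t!r} has a single level; dropped")
            else:
                kept.append(t)
        return kept

    co_terms = usable(coexistence_terms)
    pe_terms = usable(persistence_terms)
    co_tab = (
        _sequential_deviance(summary, co_terms)
        if co_terms and summary["coexistence"].nunique() > 1
        else None
    )
    if co_tab is None:
        warnings.append("coexistence model not fit (no usable terms or no variation)")
    pe_tab = _sequential_variance(summary, pe_terms) if pe_terms else None
    if pe_tab is None:
        warnings.append("persistence model not fit (no usable terms)")
    return ModelReport(
        coexistence_table=co_tab, persistence_table=pe_tab, warnings=warnings
    )
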