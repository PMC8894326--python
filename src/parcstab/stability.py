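"""Variation factor (VF) and the factorial analysis of measure stability.

The variation factor quantifies how much a graph measure changes when the
parcellation is perturbed.  For a local measure x with values per subject i
and parcel p under the standard (SP) and a modified (MP) parcellation,

    VF(%) = (1/N)(1/P) * sum_p sum_i (x_ip^MP - x_ip^SP)^2
                                     / ((x_ip^MP + x_ip^SP) / 2)^2 * 100,

i.e. the mean squared relative difference in percent (note: no square root is
taken — VF is not a root-mean-square).  The global-measure variant drops the
parcel average.  Subject/parcel pairs whose denominator is exactly zero are
excluded from the average and counted.  VF = 0 means perfect stability; a
measure with large VF is vulnerable to parcellation errors.

One VF is computed per (measure, instance, design cell); the per-instance VF
values are then the replicates of a MANOVA in which the per-measure VFs are
the response vector and atlas, dataset and threshold are fixed factors,
tested with Pillai's trace, with Bonferroni-corrected pairwise post hocs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .graph_metrics import REGISTRY, MetricResult

__all__ = [
    "UndefinedVFError",
    "ManovaResult",
    "vf_local",
    "vf_global",
    "variation_factor",
    "build_stability_table",
    "manova_pillai",
    "posthoc_bonferroni",
]


class UndefinedVFError(ValueError):
    """Every subject/parcel pair had a zero denominator."""


def _vf(x_sp: np.ndarray, x_mp: np.ndarray) -> tuple[float, int]:
    x_sp = np.asarray(x_sp, float)
    x_mp = np.asarray(x_mp, float)
    if x_sp.shape != x_mp.shape:
        raise ValueError(f"shape mismatch: SP {x_sp.shape} vs MP {x_mp.shape}")
    mean = (x_mp + x_sp) / 2.0
    diff = x_mp - x_sp
    # a pair with zero denominator is undefined under the formula unless the
    # values are identical, in which case it contributes zero (VF(x, x) = 0
    # must hold for any x); truly undefined pairs are excluded and counted
    included = (mean != 0) | (diff == 0)
    excluded = int((~included).sum())
    if not included.any():
        raise UndefinedVFError("all pairs have zero denominator")
    ratio = np.divide(diff[included], mean[included],
                      out=np.zeros(int(included.sum())),
                      where=mean[included] != 0)
    return float(np.mean(ratio**2) * 100.0), excluded


def vf_local(x_sp: np.ndarray, x_mp: np.ndarray) -> tuple[float, int]:
    """VF(%) for a local measure; inputs are subjects × parcels arrays.

    Returns ``(vf_percent, excluded_pair_count)``.
    """
    x_sp = np.atleast_2d(np.asarray(x_sp, float))
    x_mp = np.atleast_2d(np.asarray(x_mp, float))
    return _vf(x_sp, x_mp)


def vf_global(x_sp: np.ndarray, x_mp: np.ndarray) -> tuple[float, int]:
    """VF(%) for a global measure; inputs are length-N subject vectors."""
    x_sp = np.atleast_1d(np.asarray(x_sp, float))
    x_mp = np.atleast_1d(np.asarray(x_mp, float))
    if x_sp.ndim != 1:
        raise ValueError("global VF expects per-subject vectors")
    return _vf(x_sp, x_mp)


def variation_factor(measure: str, x_sp: np.ndarray, x_mp: np.ndarray
                     ) -> tuple[float, int]:
    """Route to the local or global VF according to the measure registry."""
    if measure not in REGISTRY:
        raise KeyError(f"unknown measure {measure!r}")
    if REGISTRY[measure].level == "global":
        return vf_global(x_sp, x_mp)
    return vf_local(x_sp, x_mp)


def _stack_subjects(results: list[dict[str, MetricResult]], measure: str
                    ) -> np.ndarray | None:
    """Subjects × parcels (local) or subjects (global) array for one measure."""
    if any(measure not in r for r in results):
        return None
    vals = [r[measure].value for r in results]
    return np.stack([np.atleast_1d(np.asarray(v, float)) for v in vals]) \
        if REGISTRY[measure].level == "local" else np.asarray(vals, float)


def build_stability_table(
        sp_results: list[dict[str, MetricResult]],
        mp_results: list[list[dict[str, MetricResult]]],
        atlas: str = "synthetic", dataset: str = "synthetic",
        threshold: float | None = None) -> pd.DataFrame:
    """Long-format VF table: one row per (measure, instance) for one design cell.

    ``sp_results`` holds one measure→result mapping per subject;
    ``mp_results`` one such list per modified-parcellation instance.
    Measures missing from any subject's results (e.g. undefined on that graph)
    are skipped for that instance.
    """
    if not mp_results:
        raise ValueError("no modified-parcellation instances supplied")
    rows = []
    for inst_idx, inst_results in enumerate(mp_results):
        if len(inst_results) != len(sp_results):
            raise ValueError(
                f"instance {inst_idx}: {len(inst_results)} subjects, "
                f"expected {len(sp_results)}")
        for measure in REGISTRY:
            x_sp = _stack_subjects(sp_results, measure)
            x_mp = _stack_subjects(inst_results, measure)
            if x_sp is None or x_mp is None:
                continue
            try:
                vf, excluded = variation_factor(measure, x_sp, x_mp)
            except UndefinedVFError:
                continue
            rows.append({"measure": measure, "instance": inst_idx,
                         "atlas": atlas, "dataset": dataset,
                         "threshold": threshold, "vf_percent": vf,
                         "excluded_pairs": excluded})
    return pd.DataFrame(rows)


@dataclass
class ManovaResult:
    """Pillai's trace tests per factor, plus the design actually fitted."""

    effects: pd.DataFrame   # index: factor; columns: pillai, F, df_num, df_den, p
    n_obs: int
    responses: list[str]
    factors: list[str]

    def __str__(self) -> str:
        lines = [f"MANOVA (Pillai's trace) on {len(self.responses)} responses, "
                 f"{self.n_obs} observations"]
        for factor, row in self.effects.iterrows():
            lines.append(
                f"  {factor}: V = {row.pillai:.4f}, "
                f"F({row.df_num:.0f}, {row.df_den:.0f}) = {row.F:.3f}, "
                f"p = {row.p:.3g}")
        return "\n".join(lines)


def _pivot_wide(table: pd.DataFrame, factors: list[str]) -> pd.DataFrame:
    idx = ["instance"] + factors
    wide = table.pivot_table(index=idx, columns="measure",
                             values="vf_percent", aggfunc="mean")
    if wide.isna().any().any():
        bad = wide.columns[wide.isna().any()].tolist()
        wide = wide.drop(columns=bad)
    return wide.reset_index()


def manova_pillai(table: pd.DataFrame,
                  factors: list[str] = ("atlas", "dataset", "threshold"),
                  interactions: bool = False) -> ManovaResult:
    """Main-effects MANOVA of the per-measure VFs on the design factors.

    Observations are (instance × design-cell) rows; the response vector holds
    one VF per measure.  Factors with fewer than two observed levels are
    dropped from the model.  Fitted with statsmodels; Pillai's trace
    V = tr[H (H + E)^-1] and its standard F approximation are reported per
    factor.
    """
    from statsmodels.multivariate.manova import MANOVA

    factors = [f for f in factors if table[f].nunique() > 1]
    if not factors:
        raise ValueError("no factor has two or more levels")
    wide = _pivot_wide(table, factors)
    responses = [c for c in wide.columns if c in REGISTRY]
    if not responses:
        raise ValueError("no complete response measures")
    y = wide[responses].to_numpy(float)
    keep = [c for c in responses if np.ptp(y[:, responses.index(c)]) > 0]
    if not keep:
        raise ValueError("all responses are constant; error matrix is singular")
    endog = wide[keep]
    endog.columns = [f"m{i}" for i in range(len(keep))]

    terms = [f"C({f})" for f in factors]
    if interactions and len(factors) > 1:
        terms += [f"C({a}):C({b})" for a, b in combinations(factors, 2)]
    data = pd.concat([endog.reset_index(drop=True),
                      wide[factors].reset_index(drop=True)], axis=1)

    rows = {}
    if len(keep) == 1:
        # one response: Pillai's trace test degenerates to the classical
        # F test of the factor in a univariate linear model
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        fit = smf.ols("m0 ~ " + " + ".join(terms), data=data).fit()
        tab = anova_lm(fit, typ=2)
        sse = float(tab.loc["Residual", "sum_sq"])
        for f, term in zip(factors, terms):
            ssh = float(tab.loc[term, "sum_sq"])
            rows[f] = {"pillai": ssh / (ssh + sse),
                       "F": float(tab.loc[term, "F"]),
                       "df_num": float(tab.loc[term, "df"]),
                       "df_den": float(tab.loc["Residual", "df"]),
                       "p": float(tab.loc[term, "PR(>F)"])}
    else:
        formula = (" + ".join(f"m{i}" for i in range(len(keep)))
                   + " ~ " + " + ".join(terms))
        try:
            fit = MANOVA.from_formula(formula, data=data).mv_test()
        except np.linalg.LinAlgError as err:
            raise ValueError(f"rank-deficient MANOVA design: {err}") from None
        for f, term in zip(factors, terms):
            pillai = fit.results[term]["stat"].loc["Pillai's trace"]
            rows[f] = {"pillai": float(pillai["Value"]),
                       "F": float(pillai["F Value"]),
                       "df_num": float(pillai["Num DF"]),
                       "df_den": float(pillai["Den DF"]),
                       "p": float(pillai["Pr > F"])}
    return ManovaResult(effects=pd.DataFrame(rows).T, n_obs=len(wide),
                        responses=keep, factors=list(factors))


def posthoc_bonferroni(table: pd.DataFrame, factor: str,
                       response: str = "vf_percent",
                       measure: str | None = None) -> pd.DataFrame:
    """Bonferroni-corrected pairwise two-sample t tests between factor levels."""
    data = table if measure is None else table[table["measure"] == measure]
    levels = sorted(data[factor].dropna().unique(), key=str)
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has fewer than two levels")
    groups = {lv: data.loc[data[factor] == lv, response].to_numpy(float)
              for lv in levels}
    for lv, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"level {lv!r} has fewer than two observations")
    pairs = list(combinations(levels, 2))
    rows = []
    for a, b in pairs:
        t, p = stats.ttest_ind(groups[a], groups[b])
        rows.append({"level_a": a, "level_b": b, "t": float(t), "p_raw": float(p),
                     "p_bonferroni": min(1.0, float(p) * len(pairs))})
    return pd.DataFrame(rows)
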