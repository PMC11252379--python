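"""Group comparisons respecting the anther > cell > track nesting.

Two routes:

* :func:`compare_groups_mixed` — a linear mixed model with a random intercept
  per anther and a nested variance component per cell, fitted by maximum
  likelihood; the group effect (stage or genotype) is tested with a
  likelihood-ratio test against the intercept-only model.  Estimation is
  delegated to statsmodels MixedLM.
* :func:`compare_groups_permutation` — a self-contained hierarchical
  permutation test: the statistic is the difference of group means of the
  per-anther mean metric, and the null is built by permuting group labels
  across anthers, honoring the anther as the independent experimental unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError


@dataclass
class ComparisonResult:
    fixed_effect: str
    levels: list[str]
    estimates: dict[str, float]  # group means of the metric
    statistic: float
    p_value: float
    method: str  # {"lrt_mixed", "hier_permutation"}
    n_tracks: int
    n_cells: int
    n_anthers: int
    singular: bool = False

    def to_dict(self) -> dict:
        return {
            "fixed_effect": self.fixed_effect,
            "levels": self.levels,
            "estimates": self.estimates,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "method": self.method,
            "n_tracks": self.n_tracks,
            "n_cells": self.n_cells,
            "n_anthers": self.n_anthers,
            "singular": self.singular,
        }


def _check(data: pd.DataFrame, metric: str, fixed: str, anther: str, cell: str) -> None:
    for col in (metric, fixed, anther, cell):
        if col not in data.columns:
            raise ParameterError(f"missing column: {col}")
    if data[fixed].nunique() < 2:
        raise ParameterError(f"fixed factor {fixed!r} needs at least 2 levels")
    if data[anther].nunique() < 2:
        raise ParameterError("need at least 2 anthers overall")


def compare_groups_mixed(
    data: pd.DataFrame,
    metric: str = "avg_speed",
    fixed: str = "stage",
    anther: str = "anther_id",
    cell: str = "cell_id",
    log_scale: bool = False,
) -> ComparisonResult:
    """Likelihood-ratio test of the fixed factor under nested random intercepts.

    Both the full model (metric ~ fixed factor) and the null (intercept only)
    carry a random intercept per anther plus a variance component per cell
    within anther, and are fitted by ML so the LRT is valid.  Zero variance
    components (singular fits) are flagged but the p-value is still reported.
    Metrics are analyzed on their natural scale unless ``log_scale``.
    """
    import statsmodels.formula.api as smf

    _check(data, metric, fixed, anther, cell)
    df = data[[metric, fixed, anther, cell]].dropna().reset_index(drop=True)
    df.columns = ["y", "g", "anther", "cell"]
    if log_scale:
        if (df["y"] <= 0).any():
            raise ParameterError("log_scale requires strictly positive metric values")
        df["y"] = np.log(df["y"])
    # make cell coding unambiguous under nesting
    df["cell"] = df["anther"].astype(str) + "/" + df["cell"].astype(str)

    vc = {"cell": "0 + C(cell)"}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = smf.mixedlm(
            "y ~ C(g)", df, groups=df["anther"], re_formula="1", vc_formula=vc
        ).fit(reml=False)
        null = smf.mixedlm(
            "y ~ 1", df, groups=df["anther"], re_formula="1", vc_formula=vc
        ).fit(reml=False)
    lr = 2.0 * (full.llf - null.llf)
    k = df["g"].nunique() - 1
    p = float(sps.chi2.sf(max(lr, 0.0), k))
    singular = bool(
        np.any(np.asarray(full.cov_re).diagonal() < 1e-8)
        or np.any(np.asarray(list(full.vcomp)) < 1e-8)
    )
    est = df.groupby("g")["y"].mean()
    if log_scale:
        est = np.exp(est)
    return ComparisonResult(
        fixed_effect=fixed,
        levels=sorted(df["g"].astype(str).unique()),
        estimates={str(k_): float(v) for k_, v in est.items()},
        statistic=float(lr),
        p_value=p,
        method="lrt_mixed",
        n_tracks=len(df),
        n_cells=df["cell"].nunique(),
        n_anthers=df["anther"].nunique(),
        singular=singular,
    )


def variance_components(
    data: pd.DataFrame,
    metric: str = "avg_speed",
    anther: str = "anther_id",
    cell: str = "cell_id",
    log_scale: bool = False,
) -> dict[str, float]:
    """Anther / cell / residual variance decomposition of a per-track metric.

    Fits the intercept-only nested mixed model by ML and returns the estimated
    variance components, e.g. to quantify the between-anther coupling of
    average speeds (the "anther effect").
    """
    import statsmodels.formula.api as smf

    df = data[[metric, anther, cell]].dropna().reset_index(drop=True)
    df.columns = ["y", "anther", "cell"]
    if log_scale:
        df["y"] = np.log(df["y"])
    df["cell"] = df["anther"].astype(str) + "/" + df["cell"].astype(str)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.mixedlm(
            "y ~ 1", df, groups=df["anther"], re_formula="1",
            vc_formula={"cell": "0 + C(cell)"},
        ).fit(reml=False)
    return {
        "anther_var": float(np.asarray(fit.cov_re).ravel()[0]),
        "cell_var": float(np.asarray(list(fit.vcomp)).ravel()[0]),
        "residual_var": float(fit.scale),
    }


def compare_groups_permutation(
    data: pd.DataFrame,
    metric: str = "avg_speed",
    fixed: str = "stage",
    anther: str = "anther_id",
    n_perm: int = 999,
    seed: int | None = 0,
) -> ComparisonResult:
    """Hierarchical permutation test with the anther as the exchangeable unit.

    Restricted to two-level factors.  The observed statistic is the absolute
    difference between the two group means of per-anther mean metrics; the
    null distribution permutes group labels across anthers, and
    p = (1 + #{null ≥ observed}) / (1 + n_perm).  Deterministic given ``seed``.
    """
    for col in (metric, fixed, anther):
        if col not in data.columns:
            raise ParameterError(f"missing column: {col}")
    per_anther = data.groupby(anther).agg(y=(metric, "mean"), g=(fixed, "first"))
    mixed = data.groupby(anther)[fixed].nunique()
    if (mixed > 1).any():
        raise ParameterError("fixed factor varies within an anther; cannot permute anthers")
    levels = sorted(per_anther["g"].astype(str).unique())
    if len(levels) != 2:
        raise ParameterError("permutation test requires exactly 2 factor levels")
    counts = per_anther["g"].value_counts()
    if (counts < 2).any():
        raise ParameterError("cannot permute: a group has fewer than 2 anthers")

    y = per_anther["y"].to_numpy()
    labels = (per_anther["g"].astype(str) == levels[1]).to_numpy()

    def statistic(lab: np.ndarray) -> float:
        return abs(y[lab].mean() - y[~lab].mean())

    obs = statistic(labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if statistic(perm) >= obs - 1e-15:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    est = data.groupby(fixed)[metric].mean()
    return ComparisonResult(
        fixed_effect=fixed,
        levels=levels,
        estimates={str(k): float(v) for k, v in est.items()},
        statistic=float(obs),
        p_value=float(p),
        method="hier_permutation",
        n_tracks=len(data),
        n_cells=data["cell_id"].nunique() if "cell_id" in data.columns else 0,
        n_anthers=len(per_anther),
    )


def pairwise_comparisons(
    data: pd.DataFrame,
    metric: str = "avg_speed",
    fixed: str = "stage",
    method: str = "lrt_mixed",
    adjust: str | None = None,
    **kwargs,
) -> pd.DataFrame:
    """All pairwise level comparisons of the fixed factor.

    P-values are reported unadjusted by default; ``adjust="bh"`` applies a
    Benjamini–Hochberg correction across the pairs.
    """
    levels = sorted(data[fixed].astype(str).unique())
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            sub = data[data[fixed].astype(str).isin([levels[i], levels[j]])]
            try:
                if method == "lrt_mixed":
                    res = compare_groups_mixed(sub, metric=metric, fixed=fixed, **kwargs)
                else:
                    res = compare_groups_permutation(sub, metric=metric, fixed=fixed, **kwargs)
            except ParameterError as exc:
                rows.append(
                    {"level_a": levels[i], "level_b": levels[j], "p_value": np.nan,
                     "statistic": np.nan, "method": method, "note": str(exc)}
                )
                continue
            rows.append(
                {
                    "level_a": levels[i],
                    "level_b": levels[j],
                    "estimate_a": res.estimates.get(levels[i], np.nan),
                    "estimate_b": res.estimates.get(levels[j], np.nan),
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "method": method,
                    "n_tracks": res.n_tracks,
                    "n_anthers": res.n_anthers,
                }
            )
    out = pd.DataFrame(rows)
    if adjust == "bh" and len(out):
        from statsmodels.stats.multitest import multipletests

        mask = out["p_value"].notna()
        adj = np.full(len(out), np.nan)
        if mask.any():
            adj[mask.to_numpy()] = multipletests(out.loc[mask, "p_value"], method="fdr_bh")[1]
        out["p_adjusted"] = adj
    return out
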