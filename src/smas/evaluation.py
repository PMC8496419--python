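"""Cohort-level comparison of slab methods.

Outcomes (proportion of abnormal superpixels, or median distance of
abnormal superpixels from the ONH) are collected into a long-format table
with one row per (eye, method).  Paired differences against a reference
method (SMAS by default) are summarised with percentile-bootstrap
confidence intervals, and a Bland–Altman-style table relates the mean
proportion to the standardized difference per eye.

Mixed-model inference (method as fixed effect, eye as random intercept)
is routine statistics and is delegated to statsmodels through a thin
optional adapter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def outcome_table(results: dict[str, dict[str, float]], metric: str
                  ) -> pd.DataFrame:
    """Long-format table (eye, method, y) from nested per-eye results.

    ``results[eye][method]`` is the outcome value.  Eyes missing a method
    keep their other rows; the missing pair is simply absent (a warning is
    left to the caller's logging).
    """
    rows = [
        {"eye": eye, "method": method, "y": y}
        for eye, per_method in results.items()
        for method, y in per_method.items()
        if y is not None and np.isfinite(y)
    ]
    df = pd.DataFrame(rows, columns=["eye", "method", "y"])
    df.attrs["metric"] = metric
    if df.duplicated(["eye", "method"]).any():
        raise ValueError("duplicate (eye, method) pair")
    return df


def paired_differences(table: pd.DataFrame, reference: str = "SMAS",
                       n_boot: int = 10_000, seed: int = 0,
                       ci: float = 95.0) -> pd.DataFrame:
    """Per-method mean of (method - reference) with bootstrap CI.

    Differences are paired within eye; eyes missing either value are
    dropped for that method.  The percentile bootstrap resamples eyes.
    """
    if reference not in set(table["method"]):
        raise ValueError(f"reference {reference!r} absent from table")
    wide = table.pivot(index="eye", columns="method", values="y")
    rng = np.random.default_rng(seed)
    alpha = (100.0 - ci) / 2
    out = []
    for method in wide.columns:
        if method == reference:
            continue
        d = (wide[method] - wide[reference]).dropna().to_numpy()
        if d.size == 0:
            continue
        mean = float(d.mean())
        if d.size < 2:
            lo = hi = np.nan
        else:
            idx = rng.integers(0, d.size, size=(n_boot, d.size))
            boot = d[idx].mean(axis=1)
            lo, hi = np.percentile(boot, [alpha, 100 - alpha])
        out.append({"method": method, "reference": reference, "n_eyes": d.size,
                    "mean_diff": mean, "ci_low": float(lo), "ci_high": float(hi)})
    return pd.DataFrame(out)


def bland_altman_table(table: pd.DataFrame, reference: str = "SMAS"
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean vs standardized difference of proportions, per eye and method.

    standardized difference = (y_ref - y_method) / y_ref; eyes with a zero
    reference proportion are excluded.  Returns the per-eye table and a
    per-method summary with the OLS slope and R² of standardized
    difference on the mean.
    """
    wide = table.pivot(index="eye", columns="method", values="y")
    if reference not in wide.columns:
        raise ValueError(f"reference {reference!r} absent from table")
    rows = []
    for method in wide.columns:
        if method == reference:
            continue
        sub = wide[[reference, method]].dropna()
        sub = sub[sub[reference] > 0]
        for eye, (y_ref, y_m) in sub.iterrows():
            rows.append({"eye": eye, "method": method,
                         "mean": (y_ref + y_m) / 2.0,
                         "std_diff": (y_ref - y_m) / y_ref})
    per_eye = pd.DataFrame(rows, columns=["eye", "method", "mean", "std_diff"])
    summaries = []
    for method, sub in per_eye.groupby("method"):
        x, y = sub["mean"].to_numpy(), sub["std_diff"].to_numpy()
        if len(sub) >= 2 and np.ptp(x) > 0:
            slope, intercept = np.polyfit(x, y, 1)
            r2 = 0.0 if np.ptp(y) == 0 else float(np.corrcoef(x, y)[0, 1] ** 2)
        else:
            slope, intercept, r2 = np.nan, np.nan, np.nan
        summaries.append({"method": method, "slope": float(slope),
                          "intercept": float(intercept), "r2": r2,
                          "n_eyes": len(sub)})
    return per_eye, pd.DataFrame(summaries)


def mixed_model_anova(table: pd.DataFrame, reference: str = "SMAS"):
    """Optional adapter: random-intercept model y ~ method + (1 | eye).

    Fits ``statsmodels`` MixedLM (REML) with the slab method as fixed
    effect and eye as random intercept, mirroring the repeated-measures
    design.  Returns the fitted results object.
    """
    import statsmodels.formula.api as smf

    data = table.copy()
    cats = [reference] + sorted(m for m in data["method"].unique() if m != reference)
    data["method"] = pd.Categorical(data["method"], categories=cats)
    model = smf.mixedlm("y ~ method", data, groups=data["eye"])
    return model.fit(reml=True)
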