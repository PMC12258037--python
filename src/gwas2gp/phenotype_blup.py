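"""Per-line BLUP breeding values from replicated multi-year trials.

Model (default): value = mu + year (fixed) + line (random) + eps, fitted by
REML; replicate is absorbed into the residual.  The reported BLUP for line i
is mu_hat (fixed part averaged over years) plus the shrunken line effect.
A random-year alternative simply drops year from the fixed design (the
shared year effect is then absorbed by the residual/intercept), exposed via
``year_fixed=False``.

For a balanced design with r observations per line the BLUP has the closed
form mu_hat + (s2_line / (s2_line + s2_eps / r)) * (ybar_i - mu_hat), which
the test-suite uses as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._reml import reml_fit, blup_random_effects

REQUIRED_COLUMNS = ("line_id", "year", "replicate", "trait", "value")


@dataclass
class BlupTable:
    values: pd.DataFrame          # index line_id, one column per trait
    variance_components: pd.DataFrame  # index trait: sigma2_line, sigma2_residual


def _check_records(records: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"phenotype records missing columns: {missing}")
    if records.duplicated(["line_id", "year", "replicate", "trait"]).any():
        raise ValueError("duplicate (line, year, replicate, trait) records")
    if not np.all(np.isfinite(records["value"].to_numpy(dtype=float))):
        raise ValueError("non-finite phenotype values")


def fit_blup(records: pd.DataFrame, trait: str,
             year_fixed: bool = True) -> BlupTable:
    """REML BLUPs for one trait.

    Sorting is canonical (by line then year then replicate), so permuting
    the input record order leaves the output bit-identical.
    """
    _check_records(records)
    sub = records.loc[records["trait"] == trait].sort_values(
        ["line_id", "year", "replicate"], kind="stable")
    if sub.empty:
        raise ValueError(f"no records for trait {trait!r}")

    lines = np.sort(sub["line_id"].unique())
    if lines.size < 2:
        raise ValueError("at least two lines are required to fit a BLUP model")
    line_index = pd.Index(lines)
    li = line_index.get_indexer(sub["line_id"])
    y = sub["value"].to_numpy(dtype=float)
    n = y.size

    # fixed design: intercept (+ year contrasts)
    X = [np.ones(n)]
    years = np.sort(sub["year"].unique())
    if year_fixed and years.size > 1:
        for yr in years[1:]:
            X.append((sub["year"].to_numpy() == yr).astype(float))
    X = np.column_stack(X)

    Z = np.zeros((n, lines.size))
    Z[np.arange(n), li] = 1.0

    fit = reml_fit(y, X, Z @ Z.T)
    u_hat = blup_random_effects(fit, Zt=Z.T)

    # fixed part averaged over the year levels present -> grand mu_hat
    if X.shape[1] > 1:
        mu_hat = fit.beta[0] + np.mean(
            np.concatenate([[0.0], fit.beta[1:]]))
    else:
        mu_hat = fit.beta[0]

    values = pd.DataFrame({trait: mu_hat + u_hat}, index=line_index)
    values.index.name = "line_id"
    vc = pd.DataFrame(
        {"sigma2_line": [fit.sigma2_g], "sigma2_residual": [fit.sigma2_e],
         "loglik": [fit.loglik]},
        index=pd.Index([trait], name="trait"))
    return BlupTable(values=values, variance_components=vc)


def fit_all_blups(records: pd.DataFrame, year_fixed: bool = True) -> BlupTable:
    """Fit every trait present and merge into one table (outer join on line)."""
    tables = [fit_blup(records, t, year_fixed=year_fixed)
              for t in sorted(records["trait"].unique())]
    values = pd.concat([t.values for t in tables], axis=1)
    vc = pd.concat([t.variance_components for t in tables], axis=0)
    return BlupTable(values=values, variance_components=vc)


def balanced_blup_closed_form(records: pd.DataFrame, trait: str,
                              sigma2_line: float, sigma2_eps: float):
    """Closed-form shrinkage BLUP for a balanced design (test oracle).

    BLUP_i = mu_hat + (s2_l / (s2_l + s2_e / r)) (ybar_i - mu_hat) after
    removing fixed year means; valid only when every line has the same
    number of observations in every year.
    """
    sub = records.loc[records["trait"] == trait]
    counts = sub.groupby("line_id").size()
    if counts.nunique() != 1:
        raise ValueError("design is not balanced")
    r = int(counts.iloc[0])
    year_mean = sub.groupby("year")["value"].transform("mean")
    adj = sub["value"] - year_mean + sub["value"].mean()
    ybar = adj.groupby(sub["line_id"]).mean().sort_index()
    mu = ybar.mean()
    shrink = sigma2_line / (sigma2_line + sigma2_eps / r)
    return mu + shrink * (ybar - mu)


def summarize_traits(blups: BlupTable) -> pd.DataFrame:
    """Max / min / mean / sample variance (n-1) / SD per trait."""
    if blups.values.empty:
        raise ValueError("empty BLUP table")
    rows = {}
    for trait in blups.values.columns:
        v = blups.values[trait].dropna().to_numpy()
        var = float(np.var(v, ddof=1)) if v.size > 1 else 0.0
        rows[trait] = {"max": v.max(), "min": v.min(), "mean": v.mean(),
                       "variance": var, "sd": np.sqrt(var)}
    out = pd.DataFrame(rows).T
    out.index.name = "trait"
    return out[["max", "min", "mean", "variance", "sd"]]


def correlate_traits(blups: BlupTable):
    """Pairwise Pearson r with two-tailed p (t-distribution).

    Zero-variance traits yield NaN entries (r undefined).
    """
    traits = list(blups.values.columns)
    k = len(traits)
    r_mat = pd.DataFrame(np.eye(k), index=traits, columns=traits)
    p_mat = pd.DataFrame(np.zeros((k, k)), index=traits, columns=traits)
    for i in range(k):
        for j in range(i + 1, k):
            pair = blups.values[[traits[i], traits[j]]].dropna()
            x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if len(pair) < 3 or np.std(x) == 0 or np.std(y) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(x, y)
            r_mat.iloc[i, j] = r_mat.iloc[j, i] = r
            p_mat.iloc[i, j] = p_mat.iloc[j, i] = p
    return r_mat, p_mat
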