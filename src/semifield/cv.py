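"""Leave-one-line-out genomic prediction and its summary statistics.

The full dataset is fitted once to get variance components and fixed
effects; corrected phenotypes are the records minus the fitted fixed
part, averaged per line. Each line's records are then dropped in turn
and its GEBV predicted through G from the remaining records. Accuracy is
the correlation between corrected line means and held-out GEBVs scaled
by sqrt(h2); inflation is the slope of corrected line means regressed on
GEBVs (1 = no inflation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from semifield.reml import MixedModelFit, ModelBundle, blup_solve, reml_fit

__all__ = [
    "CorrectedPhenotypes",
    "CVResult",
    "correct_phenotypes",
    "loo_cv",
    "prediction_accuracy",
    "prediction_inflation",
]


@dataclass
class CorrectedPhenotypes:
    yc: np.ndarray
    line_means: pd.Series


@dataclass
class CVResult:
    gebv: pd.Series
    ybar_c: pd.Series
    acc: float
    cor: float
    h2_used: float
    slope: float
    slope_t: float
    slope_p: float
    fold_status: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)


def correct_phenotypes(full_fit: MixedModelFit, bundle: ModelBundle) -> CorrectedPhenotypes:
    """y_c = y - X b_hat from the full-data fit; line means pool all areas."""
    yc = bundle.y - bundle.X @ full_fit.blues
    lines = pd.Series(list(bundle.meta["line"]), name="line")
    means = pd.Series(yc).groupby(lines).mean()
    means.index.name = "line"
    return CorrectedPhenotypes(yc=yc, line_means=means)


def _gebv_of(bundle, blups, line):
    g_block = next(b for b in bundle.blocks if b.label == "g")
    idx = g_block.level_ids.index(line)
    return float(blups["g"][idx])


def loo_cv(bundle: ModelBundle, full_fit: MixedModelFit | None = None,
           reestimate_vcs: bool = True, max_iter: int = 100,
           progress=None) -> pd.Series:
    """Held-out GEBV per line.

    Each fold drops all records of one line and either re-runs REML
    (default, ``reestimate_vcs=True``) or plugs in the full-data variance
    components and only re-solves the mixed-model equations. The held-out
    line keeps its columns (it still appears as a neighbor/level), so its
    GEBV is predicted through G.
    """
    if full_fit is None:
        full_fit = reml_fit(bundle, max_iter=max_iter)
    lines_per_record = np.asarray(bundle.meta["line"])
    fold_lines = sorted(set(lines_per_record))
    gebv, status = {}, {}
    for line in fold_lines:
        mask = lines_per_record != line
        sub = bundle.subset(mask)
        try:
            if reestimate_vcs:
                fit = reml_fit(sub, init=full_fit.vcs, max_iter=max_iter)
                blups, ok = fit.blups, fit.converged
            else:
                _, blups = blup_solve(sub, full_fit.vcs)
                ok = True
        except Exception as err:  # fold-level failure is recorded, not fatal
            status[line] = f"failed: {err}"
            continue
        gebv[line] = _gebv_of(bundle, blups, line)
        status[line] = "ok" if ok else "not converged"
    s = pd.Series(gebv, name="gebv")
    s.index.name = "line"
    s.attrs["fold_status"] = status
    return s


def prediction_accuracy(ybar_c: pd.Series, gebv: pd.Series, h2_used: float):
    """ACC = sign(cor) * sqrt(cor^2 / h2). Returns (acc, cor, warnings)."""
    warns = []
    common = ybar_c.index.intersection(gebv.index)
    if len(common) < 3:
        raise ValueError("need at least 3 lines with both corrected means and GEBVs")
    if h2_used <= 0:
        raise ValueError("h2 must be positive to scale the accuracy")
    a = ybar_c.loc[common].to_numpy(dtype=float)
    b = gebv.loc[common].to_numpy(dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        warns.append("zero variance in corrected means or GEBVs; accuracy undefined")
        return np.nan, np.nan, warns
    cor = float(np.corrcoef(a, b)[0, 1])
    acc = float(np.sign(cor) * np.sqrt(cor * cor / h2_used))
    if abs(acc) > 1:
        warns.append(f"scaled accuracy {acc:.3f} exceeds 1 (reported unclipped)")
    return acc, cor, warns


def prediction_inflation(ybar_c: pd.Series, gebv: pd.Series):
    """OLS slope of corrected line means on GEBVs; t-test of slope = 1."""
    common = ybar_c.index.intersection(gebv.index)
    if len(common) < 3:
        raise ValueError("need at least 3 lines for the inflation regression")
    y = ybar_c.loc[common].to_numpy(dtype=float)
    x = gebv.loc[common].to_numpy(dtype=float)
    if np.var(x) == 0:
        return np.nan, np.nan, np.nan
    res = stats.linregress(x, y)
    if res.stderr == 0:
        t = 0.0 if abs(res.slope - 1.0) < 1e-12 else np.inf
        p = 1.0 if t == 0.0 else 0.0
    else:
        t = (res.slope - 1.0) / res.stderr
        p = float(2 * stats.t.sf(abs(t), len(common) - 2))
    return float(res.slope), float(t), p


def run_loo_cv(bundle: ModelBundle, h2_used: float, full_fit: MixedModelFit | None = None,
               reestimate_vcs: bool = True, max_iter: int = 100) -> CVResult:
    """Full LOO-CV summary: GEBVs, scaled accuracy and inflation slope."""
    if full_fit is None:
        full_fit = reml_fit(bundle, max_iter=max_iter)
    corrected = correct_phenotypes(full_fit, bundle)
    gebv = loo_cv(bundle, full_fit=full_fit, reestimate_vcs=reestimate_vcs,
                  max_iter=max_iter)
    acc, cor, warns = prediction_accuracy(corrected.line_means, gebv, h2_used)
    slope, t, p = prediction_inflation(corrected.line_means, gebv)
    return CVResult(gebv=gebv, ybar_c=corrected.line_means, acc=acc, cor=cor,
                    h2_used=h2_used, slope=slope, slope_t=t, slope_p=p,
                    fold_status=gebv.attrs.get("fold_status", {}), warnings=warns)
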