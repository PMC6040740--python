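"""Cross-plate statistical testing of OCR log-ratio differences.

Within a plate, the log-scale difference between two interval effects of a
biosample is an OCR log-ratio (e.g. ``theta_M - theta_Ei`` is the log of the
maximal over ETC-independent fold change).  Comparing a biosample ``b`` to the
plate-matched control ``c`` on the same plate cancels plate and plate-interval
effects, giving the double difference

    ddtheta[b, p] = (theta_a,b - theta_b',b) - (theta_a,c - theta_b',c)

per plate ``p`` and per ratio metric.  Across plates these are modelled as

    ddtheta[b, p] = mu[b] + eps[b, p]

fitted jointly over all biosamples by one-way fixed-effects least squares, so
the error variance is pooled over the complete dataset — this is what makes
biosamples measured on few plates testable at all.  Each ``mu[b] = 0`` null is
assessed with a Student t test on ``N - B`` pooled degrees of freedom
(``N`` total (biosample, plate) observations, ``B`` biosamples), with 95%
confidence intervals from the same t distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .within_plate import EstimationError, WithinPlateFit

__all__ = [
    "DDTHETA_DEFS",
    "compute_ddtheta",
    "TestResults",
    "test_biosamples",
    "qq_residuals",
]

#: Interval pair (a, b') defining each ratio metric's log difference
#: ``theta_a - theta_b'`` (intervals: 1=I, 2=Ai, 3=M, 4=Ei).
DDTHETA_DEFS: dict[str, tuple[int, int]] = {
    "EI_prop": (1, 4),
    "AI_prop": (1, 2),
    "EAi_prop": (2, 4),
    "MI_fold": (3, 1),
    "MEi_fold": (3, 4),
}


def compute_ddtheta(
    fits: Iterable[WithinPlateFit] | Mapping[str, WithinPlateFit],
    control: str,
    metrics: Iterable[str] = tuple(DDTHETA_DEFS),
) -> pd.DataFrame:
    """Per-(biosample, plate) log-ratio differences vs the matched control.

    Plates on which the control is absent are skipped for all biosamples (the
    double difference is undefined without a same-plate anchor).
    """
    if isinstance(fits, Mapping):
        fits = list(fits.values())
    rows = []
    skipped: list[str] = []
    for fit in fits:
        if control not in fit.biosamples:
            skipped.append(fit.plate_id)
            continue
        theta_c = fit.theta_of(control)
        for bios in fit.biosamples:
            if bios == control:
                continue
            theta_b = fit.theta_of(bios)
            for metric in metrics:
                a, b2 = DDTHETA_DEFS[metric]
                val = (theta_b[a - 1] - theta_b[b2 - 1]) - (
                    theta_c[a - 1] - theta_c[b2 - 1]
                )
                rows.append(
                    {
                        "biosample": bios,
                        "plate_id": fit.plate_id,
                        "metric": metric,
                        "ddtheta": float(val),
                    }
                )
    out = pd.DataFrame(rows, columns=["biosample", "plate_id", "metric", "ddtheta"])
    out.attrs["skipped_plates"] = skipped
    return out


@dataclass
class TestResults:
    """Per-(biosample, metric) effect estimates and tests plus residuals."""

    table: pd.DataFrame
    residuals: pd.DataFrame
    alpha: float = 0.05
    alternative: str = "two-sided"

    def sd_residuals(self) -> pd.Series:
        """Pooled residual standard deviation per metric (sqrt of sigma2)."""
        return self.table.groupby("metric")["sigma"].first()


def _pvalue(t: np.ndarray, df: int, alternative: str) -> np.ndarray:
    if alternative == "two-sided":
        return 2 * stats.t.sf(np.abs(t), df)
    if alternative == "less":
        return stats.t.cdf(t, df)
    if alternative == "greater":
        return stats.t.sf(t, df)
    raise ValueError(f"unknown alternative {alternative!r}")


def test_biosamples(
    ddtheta: pd.DataFrame,
    alpha: float = 0.05,
    alternative: str = "two-sided",
    adjust: str | None = None,
) -> TestResults:
    """Test ``mu_b = 0`` per biosample and metric with pooled error variance.

    Fits ``ddtheta[b, p] = mu_b + eps[b, p]`` jointly across all biosamples of
    each metric; equivalently (and implemented as) ``mu_hat_b`` is the plate
    mean and ``sigma2 = RSS / (N - B)``.  The standard error of ``mu_hat_b``
    is ``sigma / sqrt(n_b)``; p-values and CIs come from the t distribution
    with ``N - B`` degrees of freedom.

    Parameters
    ----------
    ddtheta
        Long table with columns biosample, plate_id, metric, ddtheta.
    adjust
        ``"bh"`` adds a Benjamini–Hochberg adjusted p-value column per metric;
        raw p-values are always reported.
    """
    rows = []
    resid_rows = []
    for metric, sub in ddtheta.groupby("metric"):
        groups = sub.groupby("biosample")["ddtheta"]
        mu = groups.mean()
        n_b = groups.size()
        N = len(sub)
        B = len(mu)
        df = N - B
        if df < 2:
            raise EstimationError(
                f"metric {metric!r}: {df} residual degrees of freedom; "
                "need at least 2 to pool an error variance"
            )
        resid = sub["ddtheta"].to_numpy(float) - mu.reindex(sub["biosample"]).to_numpy()
        sigma2 = float(np.sum(resid**2) / df)
        sigma = np.sqrt(sigma2)
        se = sigma / np.sqrt(n_b.to_numpy(float))
        t = mu.to_numpy() / se
        p = _pvalue(t, df, alternative)
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        for i, bios in enumerate(mu.index):
            rows.append(
                {
                    "biosample": bios,
                    "metric": metric,
                    "mu_hat": float(mu.iloc[i]),
                    "ratio": float(np.exp(mu.iloc[i])),
                    "se": float(se[i]),
                    "t": float(t[i]),
                    "p_value": float(p[i]),
                    "ci_low": float(mu.iloc[i] - tcrit * se[i]),
                    "ci_high": float(mu.iloc[i] + tcrit * se[i]),
                    "n_plates": int(n_b.iloc[i]),
                    "df": int(df),
                    "sigma": float(sigma),
                }
            )
        resid_rows.append(sub.assign(resid=resid))
    table = pd.DataFrame(rows)
    if adjust == "bh" and not table.empty:
        table["p_adj"] = (
            table.groupby("metric")["p_value"].transform(_benjamini_hochberg)
        )
    residuals = (
        pd.concat(resid_rows, ignore_index=True)
        if resid_rows
        else pd.DataFrame(columns=["biosample", "plate_id", "metric", "ddtheta", "resid"])
    )
    return TestResults(table=table, residuals=residuals, alpha=alpha,
                       alternative=alternative)


def _benjamini_hochberg(p: pd.Series) -> pd.Series:
    p = p.astype(float)
    n = len(p)
    order = np.argsort(p.to_numpy())
    ranked = p.to_numpy()[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return pd.Series(out, index=p.index)


def qq_residuals(residuals: np.ndarray | pd.Series) -> pd.DataFrame:
    """Standardized residual quantiles against standard normal quantiles.

    Returns a frame with ``theoretical`` and ``observed`` columns for the
    normality diagnostic.  Constant residuals standardize to zeros.
    """
    x = np.sort(np.asarray(residuals, float))
    n = len(x)
    sd = x.std(ddof=1) if n > 1 else 0.0
    observed = (x - x.mean()) / sd if sd > 0 else np.zeros(n)
    theoretical = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return pd.DataFrame({"theoretical": theoretical, "observed": observed})
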