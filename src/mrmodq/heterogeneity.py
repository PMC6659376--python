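"""Global heterogeneity testing and per-SNP outlier scanning.

Under homogeneity (all instruments valid, model correct) the generalized
Cochran's Q follows chi-squared with L - 1 df, and each per-SNP contribution
Q_j is approximately chi-squared with 1 df. A SNP whose contribution exceeds
the upper-alpha chi2(1) quantile (3.84 at alpha = 0.05), or a Bonferroni
-corrected threshold chi2(1) at 1 - alpha/L, is a candidate pleiotropic
outlier to examine in a sensitivity analysis — not to remove automatically.

Practical guidance: use exact weights for the global heterogeneity test, and
iterative weights when assessing the outlier status of individual SNPs (exact
weighting corrects regression dilution aggressively enough that weak SNPs can
look like outliers).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import SummaryData
from .estimators import FitResult, fit

__all__ = ["OutlierReport", "HeterogeneityTest", "outlier_scan", "heterogeneity_test", "leave_one_out"]


@dataclass(frozen=True)
class OutlierReport:
    """Per-SNP Q contributions with nominal and Bonferroni flags, sorted by Q_j."""

    table: pd.DataFrame
    alpha: float
    nominal_threshold: float
    bonferroni_threshold: float
    scheme: str

    def flagged(self, correction: str = "bonferroni") -> list[str]:
        col = {"none": "flag_nominal", "bonferroni": "flag_bonferroni"}[correction]
        return list(self.table.loc[self.table[col], "snp"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "nominal_threshold": self.nominal_threshold,
            "bonferroni_threshold": self.bonferroni_threshold,
            "scheme": self.scheme,
            "rows": self.table.to_dict(orient="records"),
        }


class HeterogeneityTest(NamedTuple):
    q: float
    df: int
    p_value: float


def outlier_scan(ds: SummaryData, fit_result: FitResult, alpha: float = 0.05) -> OutlierReport:
    """Scan per-SNP Q contributions against chi2(1) thresholds.

    ``flag_nominal``: Q_j above the upper-alpha chi2(1) quantile.
    ``flag_bonferroni``: Q_j above the chi2(1) quantile at 1 - alpha/L
    (computed exactly, not a lookup constant). Bonferroni flags imply
    nominal flags; the report is sorted by Q_j descending.
    """
    qj = fit_result.q.contributions
    if qj.shape[0] != ds.L:
        raise ValueError("fit contributions not aligned with dataset")
    nominal = float(stats.chi2.ppf(1 - alpha, 1))
    bonferroni = float(stats.chi2.ppf(1 - alpha / ds.L, 1))
    table = pd.DataFrame(
        {
            "snp": ds.snp_id,
            "q_contribution": qj,
            "p_value": stats.chi2.sf(qj, 1),
            "flag_nominal": qj > nominal,
            "flag_bonferroni": qj > bonferroni,
        }
    ).sort_values("q_contribution", ascending=False, kind="stable").reset_index(drop=True)
    return OutlierReport(table, alpha, nominal, bonferroni, fit_result.scheme)


def heterogeneity_test(fit_result: FitResult) -> HeterogeneityTest:
    """The scheme's Q at its own estimate, with df = L - 1 and its chi2 p-value."""
    q = fit_result.q
    return HeterogeneityTest(q.q, q.df, q.p_value)


def leave_one_out(ds: SummaryData, scheme: str = "first",
                  effects: str = "multiplicative", **fit_kwargs) -> pd.DataFrame:
    """Refit with each SNP removed in turn.

    Returns one row per removed SNP: the refitted estimate, SE, Q and phi_hat.
    Supports the sensitivity analysis of dropping a dominant outlier.
    """
    if ds.L < 3:
        raise ValueError("leave-one-out requires L >= 3")
    rows = []
    for snp in ds.snp_id:
        sub = ds.drop(snp)
        res = fit(sub, scheme=scheme, effects=effects, **fit_kwargs)
        rows.append(
            {
                "removed_snp": snp,
                "beta": res.beta,
                "se": res.se,
                "q": res.q.q,
                "q_p_value": res.q.p_value,
                "phi_hat": res.phi_hat,
            }
        )
    return pd.DataFrame(rows)
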