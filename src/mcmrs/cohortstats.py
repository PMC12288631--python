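"""Group comparisons and association analyses on QC-passed cohort tables.

Implements the study's statistical battery: Welch's unequal-variance
t-tests on metabolite ratios, absolute tCr and cord cross-sectional areas
(HC vs SCI), percent differences of group means, and Pearson/Spearman
correlations between lumbar metabolite ratios and clinical/lesion
covariates.  No multiplicity correction is applied by default, matching
the analysis it reproduces; Benjamini-Hochberg is available as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: Planned group contrasts: column -> preferred one-sided direction
#: (direction of the hypothesised SCI change; used only when
#: ``alternative="directional"``).
DEFAULT_CONTRASTS = {
    "tNAA/tCr": "less",
    "tCho/tCr": "less",
    "mI/tCr": "greater",
    "tCr": "two-sided",
    "WMA": "less",
    "GMA": "less",
}

#: Clinical/lesion covariates correlated with the ratios within SCI.
DEFAULT_ASSOCIATIONS = (
    "LEMS",
    "LELT",
    "LEPP",
    "lesion_volume",
    "tissue_bridges",
    "time_since_injury",
)


@dataclass
class GroupComparison:
    """One Welch contrast between reference (HC) and comparison (SCI) group."""

    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t: float
    df: float
    p: float
    percent_difference: float
    alternative: str = "two-sided"

    def __post_init__(self) -> None:
        if self.df <= 0:
            raise ValueError("Welch degrees of freedom must be positive")
        if not 0 <= self.p <= 1:
            raise ValueError("p-value out of [0, 1]")


def welch_test(a, b, alternative: str = "two-sided") -> GroupComparison:
    """Welch's unequal-variance t-test of reference sample ``a`` vs ``b``.

    ``t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b)`` with
    Welch-Satterthwaite degrees of freedom.  ``alternative`` follows the
    scipy convention for the location of ``a`` relative to ``b``.
    Degenerate samples with zero variance in both groups and equal means
    return t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")

    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0 and a.mean() == b.mean():
        t, p = 0.0, 1.0
        df = float(a.size + b.size - 2)
    else:
        res = sps.ttest_ind(a, b, equal_var=False, alternative=alternative)
        t, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    return GroupComparison(
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        n_a=int(a.size),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_b=int(b.size),
        t=t,
        df=df,
        p=p,
        percent_difference=percent_difference(a.mean(), b.mean()),
        alternative=alternative,
    )


def percent_difference(mean_hc: float, mean_sci: float, ndigits: int = 1) -> float:
    """Percent change of the SCI mean relative to the HC mean.

    ``100 * (mean_sci - mean_hc) / mean_hc`` rounded to ``ndigits``
    decimals (one decimal, the reporting convention).
    """
    if mean_hc == 0:
        raise ZeroDivisionError("reference mean must be non-zero")
    delta = 100.0 * (mean_sci - mean_hc) / mean_hc
    return round(delta, ndigits) if ndigits is not None else delta


@dataclass
class CorrelationResult:
    coefficient: float
    p: float
    method: str
    n: int
    defined: bool = True


def correlate(x, y, method: str = "pearson") -> CorrelationResult:
    """Pearson or Spearman (midrank-tied) correlation of paired samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant input: correlation undefined")
        return CorrelationResult(np.nan, np.nan, method, int(x.size), defined=False)
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(float(r), float(p), method, int(x.size))


def run_analysis(
    table: pd.DataFrame,
    contrasts: dict[str, str] | None = None,
    associations: tuple[str, ...] = DEFAULT_ASSOCIATIONS,
    alternative: str = "two-sided",
    reference_group: str = "HC",
    comparison_group: str = "SCI",
    fdr: bool = False,
) -> pd.DataFrame:
    """Run every planned contrast and the association battery.

    ``table`` needs ``subject_id``-indexed rows with a ``group`` column;
    metabolite-ratio/area columns feed Welch contrasts and, within the
    comparison (SCI) group, Pearson and Spearman correlations against the
    clinical covariates.  ``alternative="directional"`` runs each contrast
    one-sided in its hypothesised direction; the report labels which was
    used.  Missing columns skip their contrast with a logged reason.
    Returns a long-format results table, deterministic for identical
    inputs.
    """
    contrasts = DEFAULT_CONTRASTS if contrasts is None else contrasts
    if "group" not in table.columns:
        raise ValueError("cohort table needs a 'group' column")
    grp_a = table[table["group"] == reference_group]
    grp_b = table[table["group"] == comparison_group]
    if grp_a.empty or grp_b.empty:
        raise ValueError(
            f"both groups must be non-empty (got {len(grp_a)} {reference_group}, "
            f"{len(grp_b)} {comparison_group})"
        )

    rows = []
    for col, direction in contrasts.items():
        if col not in table.columns:
            logger.info("contrast %s skipped: column missing", col)
            continue
        a = grp_a[col].dropna().to_numpy()
        b = grp_b[col].dropna().to_numpy()
        if a.size < 2 or b.size < 2:
            logger.info("contrast %s skipped: insufficient data", col)
            continue
        alt = direction if (alternative == "directional" and direction != "two-sided") else "two-sided"
        # a one-sided test for a decrease in SCI means HC (a) > SCI (b)
        gc = welch_test(a, b, alternative={"less": "greater", "greater": "less"}.get(alt, alt))
        rows.append(
            {
                "kind": "welch",
                "measure": col,
                "method": f"welch_{gc.alternative}",
                "mean_hc": round(gc.mean_a, 2),
                "sd_hc": round(gc.sd_a, 2),
                "n_hc": gc.n_a,
                "mean_sci": round(gc.mean_b, 2),
                "sd_sci": round(gc.sd_b, 2),
                "n_sci": gc.n_b,
                "statistic": gc.t,
                "df": gc.df,
                "p": gc.p,
                "delta_pct": gc.percent_difference,
            }
        )

    ratio_cols = [c for c in ("tNAA/tCr", "tCho/tCr", "mI/tCr") if c in table.columns]
    for cov in associations:
        if cov not in table.columns:
            logger.info("association %s skipped: column missing", cov)
            continue
        for col in ratio_cols:
            paired = grp_b[[col, cov]].dropna()
            if len(paired) < 3:
                continue
            for method in ("pearson", "spearman"):
                cr = correlate(paired[col], paired[cov], method)
                rows.append(
                    {
                        "kind": "correlation",
                        "measure": f"{col}~{cov}",
                        "method": method,
                        "n_sci": cr.n,
                        "statistic": cr.coefficient,
                        "p": cr.p,
                    }
                )

    report = pd.DataFrame(rows)
    if fdr and not report.empty:
        from statsmodels.stats.multitest import multipletests

        mask = report["p"].notna()
        report.loc[mask, "p_fdr"] = multipletests(report.loc[mask, "p"], method="fdr_bh")[1]
    return report
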