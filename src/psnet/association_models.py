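"""Association analyses: size-vs-characteristic correlations over
sub-communities and the provider-level random-intercept models

    CoC ~ I + b_T * T + b_P * P + specialty contrasts + [b_A * A_CoC] + u + e

where T is the provider's local transitivity, P their patient count, the
specialty contrasts are against the PCP reference category, A_CoC the mean
CoC of the provider's network neighbours (Model 2 only), u a Gaussian random
intercept on the provider's network community and e the residual.
Estimation is restricted maximum likelihood; per-coefficient p-values are
Wald tests with one degree of freedom (normal approximation).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

SPECIALTY_TERMS = ("bh_specialist", "psychiatrist", "psychologist")

CHARACTERISTICS = (
    "mean_degree", "mean_degree_to_pcp", "pct_pcp_within", "mean_transitivity",
    "mean_coc", "prop_psychiatrist", "prop_pcp", "prop_psychologist",
    "prop_bh_specialist",
)


def _safe_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(pearson, spearman) over pairwise-complete values; NaN when a side is
    constant or fewer than 3 pairs remain."""
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    pear = stats.pearsonr(x, y).statistic
    spear = stats.spearmanr(x, y).statistic
    return float(pear), float(spear)


def correlate_size_vs_characteristics(summary: pd.DataFrame) -> pd.DataFrame:
    """Pearson and Spearman correlations of sub-community size with each
    network characteristic, one row per characteristic."""
    present = [c for c in CHARACTERISTICS if c in summary.columns]
    if len(summary) < 3:
        raise ValueError("need at least 3 sub-communities for correlations")
    size = summary["size"].to_numpy(dtype=float)
    rows = []
    for col in present:
        pear, spear = _safe_corr(size, summary[col].to_numpy(dtype=float))
        n = int((~summary[col].isna()).sum())
        if np.isnan(pear):
            logger.warning("correlation undefined for %s (constant or too few rows)", col)
        rows.append((col, pear, spear, n))
    return pd.DataFrame(rows, columns=["characteristic", "pearson", "spearman", "n"])


def unadjusted_association(profiles: pd.DataFrame) -> tuple[float, float]:
    """(Pearson r, Spearman rho) between provider transitivity and mean CoC."""
    x = profiles["transitivity"].to_numpy(dtype=float)
    y = profiles["mean_coc"].to_numpy(dtype=float)
    pear, spear = _safe_corr(x, y)
    if np.isnan(pear):
        logger.warning("unadjusted transitivity-CoC association undefined")
    return pear, spear


@dataclass
class MixedModelFit:
    """REML fit of the provider-level continuity model."""

    model: str  # "model1" or "model2"
    params: dict = field(default_factory=dict)
    bse: dict = field(default_factory=dict)
    pvalues: dict = field(default_factory=dict)
    sigma2_u: float = float("nan")
    sigma2_e: float = float("nan")
    n_used: int = 0
    n_dropped: int = 0
    groups: str = "community"
    converged: bool = True
    singular: bool = False
    random_intercept: bool = True
    standardized_transitivity: float = float("nan")  # SD(CoC) units per SD of T

    def conf_int(self, term: str, alpha: float = 0.05) -> tuple[float, float]:
        z = stats.norm.ppf(1 - alpha / 2)
        return self.params[term] - z * self.bse[term], self.params[term] + z * self.bse[term]

    def report(self) -> pd.DataFrame:
        rows = [
            (term, self.params[term], self.bse[term], self.pvalues[term])
            for term in self.params
        ]
        return pd.DataFrame(rows, columns=["term", "estimate", "se", "p"])


_TERM_MAP = {
    "Intercept": "intercept",
    "transitivity": "transitivity",
    "n_patients": "n_patients",
    "alter_mean_coc": "alter_coc",
}
for _s in SPECIALTY_TERMS:
    _TERM_MAP[f"C(specialty_group, Treatment('pcp'))[T.{_s}]"] = _s


def fit_coc_model(
    profiles: pd.DataFrame,
    include_alter_coc: bool = False,
    grouping: str = "community",
    random_intercept: bool = True,
) -> MixedModelFit:
    """Fit Model 1 (without alter CoC) or Model 2 (with it).

    Rows with any missing response or predictor are dropped listwise.  With
    fewer than two groups the random intercept is unidentifiable and the fit
    falls back to an ordinary least-squares model with a warning;
    ``random_intercept=False`` forces that fixed-intercept fit (sigma^2_u
    pinned at zero), which reproduces ordinary least squares exactly.
    """
    needed = ["mean_coc", "transitivity", "n_patients", "specialty_group", grouping]
    if include_alter_coc:
        needed.append("alter_mean_coc")
    data = profiles[needed].replace("", np.nan).dropna().copy()
    n_dropped = len(profiles) - len(data)
    if n_dropped:
        logger.info("fit_coc_model: %d rows dropped for missingness", n_dropped)

    rhs = "transitivity + n_patients + C(specialty_group, Treatment('pcp'))"
    if include_alter_coc:
        rhs += " + alter_mean_coc"
    formula = f"mean_coc ~ {rhs}"

    fit = MixedModelFit(
        model="model2" if include_alter_coc else "model1",
        n_used=len(data), n_dropped=n_dropped, groups=grouping,
    )

    n_groups = data[grouping].nunique()
    if n_groups < 2 or not random_intercept:
        if n_groups < 2:
            logger.warning("fewer than 2 %s groups: falling back to fixed-intercept OLS",
                           grouping)
        res = smf.ols(formula, data=data).fit()
        fit.random_intercept = False
        fit.sigma2_u = 0.0
        fit.sigma2_e = float(res.mse_resid)
        params, bse, pvals = res.params, res.bse, res.pvalues
        # Wald p on normal approximation for consistency with the mixed fit
        pvals = pd.Series(
            2 * stats.norm.sf(np.abs(res.params / res.bse)), index=res.params.index
        )
    else:
        md = smf.mixedlm(formula, data=data, groups=data[grouping])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = md.fit(reml=True)
        fit.converged = bool(res.converged)
        fit.sigma2_u = float(res.cov_re.iloc[0, 0])
        fit.sigma2_e = float(res.scale)
        if fit.sigma2_u < 1e-10 * fit.sigma2_e:
            fit.singular = True
            logger.info("random-intercept variance at boundary (singular fit)")
        params = res.fe_params
        bse = res.bse_fe
        pvals = pd.Series(
            2 * stats.norm.sf(np.abs(params / bse)), index=params.index
        )

    for raw, nice in _TERM_MAP.items():
        if raw in params.index:
            fit.params[nice] = float(params[raw])
            fit.bse[nice] = float(bse[raw])
            fit.pvalues[nice] = float(pvals[raw])

    sd_t = float(data["transitivity"].std())
    sd_coc = float(data["mean_coc"].std())
    if sd_coc > 0:
        fit.standardized_transitivity = fit.params["transitivity"] * sd_t / sd_coc
    return fit


def model_report(fits: list[MixedModelFit]) -> pd.DataFrame:
    """Long-format (model, term, estimate, se, p) table plus variance
    components for each fitted model."""
    frames = []
    for f in fits:
        rep = f.report()
        rep.insert(0, "model", f.model)
        extra = pd.DataFrame(
            [
                (f.model, "var_random_intercept", f.sigma2_u, float("nan"), float("nan")),
                (f.model, "var_residual", f.sigma2_e, float("nan"), float("nan")),
                (f.model, "n_used", f.n_used, float("nan"), float("nan")),
                (f.model, "standardized_transitivity", f.standardized_transitivity,
                 float("nan"), float("nan")),
            ],
            columns=["model", "term", "estimate", "se", "p"],
        )
        frames.append(pd.concat([rep, extra], ignore_index=True))
    return pd.concat(frames, ignore_index=True)
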