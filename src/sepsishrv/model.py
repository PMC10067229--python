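"""Group testing, stepwise logistic deterioration model and ROC comparison.

Analysis layer of the pipeline:

* Kruskal–Wallis screening of every (feature, summary kind, 3-h bin) across
  the NOD/SOD/POD strata, uncorrected p < 0.05 flags.
* Univariate logistic regression of progressive organ dysfunction (POD = 1,
  SOD and NOD pooled as controls) on each bin-0 feature; Wald 95% CIs on the
  odds-ratio scale; features at p < 0.20 become candidates.
* Forward-stepwise multivariate logistic regression selected by Akaike's
  Information Criterion, starting from the intercept-only model.
* AUROC by the Mann-Whitney pairwise formulation (ties count 1/2) and the
  DeLong structural-components test for two correlated ROC curves, used to
  compare the HRV model against qSOFA and an externally supplied severity
  score.

The model surface follows the statsmodels idiom: ``DeteriorationModel``
wraps the design matrix and labels, ``.fit()`` returns a
``DeteriorationResults`` carrying estimates, uncertainties, diagnostics and a
``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "kruskal_wallis_screen",
    "roc_auc",
    "delong_compare",
    "univariate_logistic",
    "forward_stepwise_aic",
    "qsofa_score",
    "evaluate_model",
    "DeteriorationModel",
    "DeteriorationResults",
]


# -- nonparametric screening -------------------------------------------------


def kruskal_wallis_screen(
    summaries: pd.DataFrame,
    labels: pd.DataFrame,
    feature_names: list[str],
    kinds: tuple[str, ...] = ("mean",),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Kruskal–Wallis rank test per feature x summary kind x bin across groups.

    ``summaries`` is the per-patient-per-bin table; ``labels`` maps
    patient_id -> label. Groups absent from a bin are dropped (noted in the
    ``groups_present`` column); bins with fewer than two represented groups
    are skipped. Returns one row per test with H, p, per-group medians/IQRs
    and an uncorrected significance flag at ``alpha``.
    """
    lab = labels.set_index("patient_id")["label"]
    df = summaries.merge(lab.rename("label"), left_on="patient_id", right_index=True)
    rows = []
    for b, grp in df.groupby("bin_index", sort=True):
        for kind in kinds:
            for f in feature_names:
                col = f"{kind}_{f}"
                if col not in grp.columns:
                    continue
                samples, names = [], []
                for g in ("NOD", "SOD", "POD"):
                    v = grp.loc[grp["label"] == g, col].dropna().to_numpy()
                    if len(v) > 0:
                        samples.append(v)
                        names.append(g)
                if len(samples) < 2 or sum(len(s) for s in samples) < 3:
                    continue
                if np.ptp(np.concatenate(samples)) == 0:
                    h, p = 0.0, 1.0
                else:
                    h, p = stats.kruskal(*samples)
                row = {
                    "feature": f,
                    "kind": kind,
                    "bin_index": int(b),
                    "H": float(h),
                    "p": float(p),
                    "significant": bool(p < alpha),
                    "groups_present": ",".join(names),
                }
                for g, v in zip(names, samples):
                    q1, med, q3 = np.percentile(v, [25, 50, 75])
                    row[f"median_{g}"] = med
                    row[f"iqr_{g}"] = q3 - q1
                rows.append(row)
    return pd.DataFrame(rows)


# -- ROC / AUROC -------------------------------------------------------------


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC via the Mann-Whitney formulation: P(case > control) + 1/2 P(tie)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    pos, neg = s[y == 1], s[y == 0]
    ranks = stats.rankdata(s)
    u = np.sum(ranks[y == 1]) - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def _delong_components(scores: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """(AUC, V10 case components, V01 control components)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    # psi(x, y) = 1 if x > y, 0.5 if tie, 0 otherwise
    cmp = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (pos[:, None] == neg[None, :])
    auc = float(cmp.mean())
    v10 = cmp.mean(axis=1)  # per case
    v01 = cmp.mean(axis=0)  # per control
    return auc, v10, v01


@dataclass
class ROCComparison:
    auc_a: float
    auc_b: float
    difference: float
    variance: float
    z: float
    p_value: float
    covariance: np.ndarray = field(default=None)  # type: ignore[assignment]


def delong_compare(scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray) -> ROCComparison:
    """DeLong test for two correlated ROC curves on the same subjects.

    The variance of the AUC difference comes from the empirical covariance of
    the per-subject structural components; identical scores give difference 0
    with p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(int)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValueError("scores and labels must be paired (identical shapes)")
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes")
    auc_a, v10_a, v01_a = _delong_components(a, y)
    auc_b, v10_b, v01_b = _delong_components(b, y)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = float(cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1])
    diff = auc_a - auc_b
    if var_diff <= 0:
        z = 0.0 if diff == 0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(var_diff)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return ROCComparison(auc_a, auc_b, diff, var_diff, float(z), p, cov)


# -- logistic modelling ------------------------------------------------------


def _fit_logit(X: np.ndarray, y: np.ndarray) -> sm.discrete.discrete_model.BinaryResultsWrapper | None:
    """Maximum-likelihood logit fit; None when it fails or separates."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception:
            return None
    if not res.mle_retvals.get("converged", False):
        return None
    if np.any(~np.isfinite(res.bse)) or np.any(res.bse > 1e4):
        return None  # quasi-separation: Wald machinery meaningless
    return res


def univariate_logistic(
    design: pd.DataFrame, y: np.ndarray, candidate_gate: float = 0.20
) -> pd.DataFrame:
    """One logistic fit per feature; POD = 1, SOD and NOD pooled = 0.

    Returns per-feature OR, Wald 95% CI, p-value, convergence flag and a
    candidate flag at p < ``candidate_gate``. Non-convergent or separating
    fits are flagged and excluded from candidacy.
    """
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    rows = []
    for f in design.columns:
        x = design[f].to_numpy(dtype=float)
        ok = np.isfinite(x)
        res = _fit_logit(sm.add_constant(x[ok]), y[ok]) if ok.sum() >= 4 else None
        if res is None:
            rows.append(
                {"feature": f, "OR": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                 "p": np.nan, "converged": False, "candidate": False}
            )
            warnings.warn(f"univariate logistic for {f!r} failed to converge or separated",
                          stacklevel=2)
            continue
        beta, se = res.params[1], res.bse[1]
        p = float(res.pvalues[1])
        rows.append(
            {
                "feature": f,
                "OR": float(np.exp(beta)),
                "ci_low": float(np.exp(beta - 1.959963984540054 * se)),
                "ci_high": float(np.exp(beta + 1.959963984540054 * se)),
                "p": p,
                "converged": True,
                "candidate": bool(p < candidate_gate),
            }
        )
    return pd.DataFrame(rows)


def forward_stepwise_aic(
    design: pd.DataFrame, y: np.ndarray, candidates: list[str]
):
    """Forward-stepwise logistic selection by AIC.

    Starts from intercept-only; each step adds the candidate with the largest
    AIC decrease; stops when no addition lowers AIC. Exact ties break by
    candidate list order (deterministic). Returns (selected feature names,
    fitted statsmodels results, intercept-only results).
    """
    y = np.asarray(y).astype(int)
    n = len(y)
    null_res = sm.Logit(y, np.ones((n, 1))).fit(disp=0)
    selected: list[str] = []
    current_aic = null_res.aic
    current_res = null_res
    remaining = list(candidates)
    while remaining:
        best = None
        for f in remaining:
            cols = selected + [f]
            X = design[cols].to_numpy(dtype=float)
            ok = np.all(np.isfinite(X), axis=1)
            res = _fit_logit(sm.add_constant(X[ok]), y[ok])
            if res is None:
                continue
            if res.aic < current_aic - 1e-12 and (best is None or res.aic < best[1] - 1e-12):
                best = (f, res.aic, res)
        if best is None:
            break
        selected.append(best[0])
        current_aic, current_res = best[1], best[2]
        remaining.remove(best[0])
    return selected, current_res, null_res


def qsofa_score(rr: float, sbp: float, gcs: float) -> float:
    """Quick-SOFA: respiratory rate >= 22, systolic BP <= 100, GCS < 15.

    NaN when any component is missing.
    """
    vals = np.asarray([rr, sbp, gcs], dtype=float)
    if np.any(~np.isfinite(vals)):
        return np.nan
    return float((rr >= 22.0) + (sbp <= 100.0) + (gcs < 15.0))


def evaluate_model(result, null_result=None) -> dict[str, float]:
    """Diagnostics of a fitted logit: deviance, df, pseudo-R², LR p-value.

    Deviance is -2 log-likelihood of the fitted model; df counts non-intercept
    terms; pseudo-R² is McFadden's 1 - ll/ll0 by default.
    """
    deviance = float(-2.0 * result.llf)
    df_model = int(result.df_model)
    out = {"deviance": deviance, "df_model": df_model}
    ll0 = null_result.llf if null_result is not None else result.llnull
    out["pseudo_r2_mcfadden"] = float(1.0 - result.llf / ll0) if ll0 != 0 else 0.0
    lr = 2.0 * (result.llf - ll0)
    out["lr_pvalue"] = float(stats.chi2.sf(max(lr, 0.0), max(df_model, 1))) if df_model else 1.0
    # Nagelkerke, reported alongside
    n = int(result.nobs)
    cox_snell = 1.0 - np.exp(2.0 * (ll0 - result.llf) / n)
    denom = 1.0 - np.exp(2.0 * ll0 / n)
    out["pseudo_r2_nagelkerke"] = float(cox_snell / denom) if denom > 0 else np.nan
    out["aic"] = float(result.aic)
    return out


# -- statsmodels-style wrapper ----------------------------------------------


class DeteriorationModel:
    """Stepwise logistic model of progressive organ dysfunction.

    Built from the bin-0 design matrix (per-patient first-3-hour feature
    means) and the NOD/SOD/POD label table; POD is the event, SOD and NOD
    pooled are controls. ``fit()`` runs the univariate p < 0.20 screen, then
    forward-stepwise AIC selection, and returns a ``DeteriorationResults``.
    """

    def __init__(
        self,
        design: pd.DataFrame,
        labels: np.ndarray | pd.Series,
        candidate_gate: float = 0.20,
    ) -> None:
        self.design = design
        y = pd.Series(labels, index=design.index) if not isinstance(labels, pd.Series) else labels
        if y.dtype == object or str(y.dtype).startswith("str"):
            y = (y == "POD").astype(int)
        self.y = y.to_numpy(dtype=int)
        if len(np.unique(self.y)) < 2:
            raise ValueError("outcome must contain both POD cases and controls")
        self.candidate_gate = candidate_gate

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        label_col: str = "label",
        feature_cols: list[str] | None = None,
        candidate_gate: float = 0.20,
    ) -> "DeteriorationModel":
        feats = feature_cols or [c for c in data.columns if c != label_col]
        return cls(data[feats], data[label_col], candidate_gate=candidate_gate)

    def fit(self) -> "DeteriorationResults":
        # listwise exclusion of patients with any missing candidate feature
        complete = np.all(np.isfinite(self.design.to_numpy(dtype=float)), axis=1)
        design = self.design.loc[complete]
        y = self.y[complete]
        excluded = list(self.design.index[~complete])
        uni = univariate_logistic(design, y, self.candidate_gate)
        candidates = list(uni.loc[uni["candidate"], "feature"])
        selected, res, null_res = forward_stepwise_aic(design, y, candidates)
        return DeteriorationResults(
            model=self,
            univariate=uni,
            selected=selected,
            _res=res,
            _null=null_res,
            design=design,
            y=y,
            excluded_patients=excluded,
        )


@dataclass
class DeteriorationResults:
    """Fitted deterioration model: estimates, uncertainties and diagnostics."""

    model: DeteriorationModel
    univariate: pd.DataFrame
    selected: list[str]
    _res: object
    _null: object
    design: pd.DataFrame
    y: np.ndarray
    excluded_patients: list = field(default_factory=list)

    @property
    def params(self) -> pd.Series:
        return pd.Series(np.asarray(self._res.params), index=["const"] + self.selected)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.asarray(self._res.bse), index=["const"] + self.selected)

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(np.asarray(self._res.pvalues), index=["const"] + self.selected)

    @property
    def odds_ratios(self) -> pd.DataFrame:
        z = 1.959963984540054
        beta, se = self.params, self.bse
        return pd.DataFrame(
            {
                "OR": np.exp(beta),
                "ci_low": np.exp(beta - z * se),
                "ci_high": np.exp(beta + z * se),
                "p": self.pvalues,
            }
        ).drop(index="const")

    @property
    def aic(self) -> float:
        return float(self._res.aic)

    def diagnostics(self) -> dict[str, float]:
        return evaluate_model(self._res, self._null)

    def predict(self, design: pd.DataFrame | None = None) -> np.ndarray:
        """Predicted POD probabilities (in-sample by default)."""
        d = self.design if design is None else design
        X = sm.add_constant(d[self.selected].to_numpy(dtype=float), has_constant="add")
        beta = np.asarray(self._res.params)
        return 1.0 / (1.0 + np.exp(-X @ beta))

    def auroc(self) -> float:
        return roc_auc(self.predict(), self.y)

    def summary(self) -> str:
        diag = self.diagnostics()
        lines = [
            "Progressive-organ-dysfunction logistic model (forward-stepwise AIC)",
            f"n = {len(self.y)} ({int(self.y.sum())} POD events); "
            f"excluded (incomplete bin-0 features): {len(self.excluded_patients)}",
            "",
            "Univariate screen (candidates at p < %.2f):" % self.model.candidate_gate,
            self.univariate.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
            "",
            f"Selected features: {', '.join(self.selected) if self.selected else '(intercept only)'}",
        ]
        if self.selected:
            lines += ["", "Multivariate odds ratios:",
                      self.odds_ratios.to_string(float_format=lambda v: f"{v:.4g}")]
        lines += [
            "",
            f"AIC {diag['aic']:.2f} | deviance {diag['deviance']:.2f} "
            f"on {diag['df_model']} df | McFadden R2 {diag['pseudo_r2_mcfadden']:.3f} "
            f"| LR p {diag['lr_pvalue']:.4g}",
            f"In-sample AUROC {self.auroc():.3f}",
        ]
        return "\n".join(lines)
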