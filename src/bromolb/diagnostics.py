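"""Diagnostic-test statistics for the biopsy cohort.

Covers the 2x2 diagnostic metrics (sensitivity, specificity, binary-test
AUC, phi, Fisher exact p), rank tests, association/effect-size screening,
ROC threshold selection (Youden index and closest-to-top-left), and
binomial logistic regression with Wald inference, Nagelkerke R-squared and
Cohen's f-squared. Fisher, Mann-Whitney, chi-square and the logistic MLE
are delegated to scipy/statsmodels; everything else is computed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .errors import SeparationError, ValidationError


# ---------------------------------------------------------------------------
# 2x2 tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with orientation: outcome = event (e.g. pneumothorax), test = classifier.

    tp = test+/event+, fn = test-/event+, fp = test+/event-, tn = test-/event-.
    """

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        counts = (self.tp, self.fn, self.fp, self.tn)
        if any(c < 0 for c in counts) or sum(counts) < 1:
            raise ValidationError("2x2 counts must be nonnegative with total >= 1")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def as_array(self) -> np.ndarray:
        return np.array([[self.tp, self.fn], [self.fp, self.tn]])


@dataclass
class DiagnosticSummary:
    sensitivity: float
    specificity: float
    auc: float                 # binary test: (Se + Sp) / 2
    phi: float
    fisher_p: float
    false_negatives: int
    false_positives: int


def build_table(cohort: pd.DataFrame, outcome_field: str,
                test_field: str) -> ContingencyTable2x2:
    """Exact cross-tabulation of two boolean columns."""
    if len(cohort) == 0:
        raise ValidationError("empty cohort")
    for col in (outcome_field, test_field):
        if col not in cohort.columns:
            raise ValidationError(f"missing column {col!r}")
        bad = cohort[cohort[col].isna()]
        if len(bad):
            ids = bad.get("case_id", bad.index).tolist()
            raise ValidationError(f"missing values in {col!r} for cases {ids}")
    o = cohort[outcome_field].astype(bool).to_numpy()
    t = cohort[test_field].astype(bool).to_numpy()
    return ContingencyTable2x2(tp=int((t & o).sum()), fn=int((~t & o).sum()),
                               fp=int((t & ~o).sum()), tn=int((~t & ~o).sum()))


def phi_coefficient(table: ContingencyTable2x2) -> float:
    """Effect size of a 2x2 association; equals the Pearson correlation of the
    0/1-encoded vectors."""
    a, b, c, d = table.tp, table.fn, table.fp, table.tn
    denom = np.sqrt(float(a + b) * (c + d) * (a + c) * (b + d))
    if denom == 0:
        return 0.0
    return float((a * d - b * c) / denom)


def contingency_coefficient(table: ContingencyTable2x2) -> float:
    """Pearson's contingency coefficient C = sqrt(chi2 / (chi2 + n))."""
    chi2 = stats.chi2_contingency(table.as_array(), correction=False)[0]
    return float(np.sqrt(chi2 / (chi2 + table.total)))


def fisher_exact(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p (sum of fixed-margin tables with probability
    at most that of the observed table)."""
    return float(stats.fisher_exact(table.as_array(), alternative="two-sided")[1])


def diagnostic_metrics(table: ContingencyTable2x2) -> DiagnosticSummary:
    """Sensitivity, specificity, binary-test AUC, phi and Fisher p for a 2x2 table."""
    if table.tp + table.fn == 0 or table.fp + table.tn == 0:
        raise ValidationError("both outcome classes must be present")
    se = table.tp / (table.tp + table.fn)
    sp = table.tn / (table.tn + table.fp)
    return DiagnosticSummary(
        sensitivity=float(se), specificity=float(sp), auc=float((se + sp) / 2.0),
        phi=phi_coefficient(table), fisher_p=fisher_exact(table),
        false_negatives=table.fn, false_positives=table.fp,
    )


def odds_ratio(table: ContingencyTable2x2) -> float:
    """Cross-product odds ratio (tp*tn)/(fn*fp)."""
    if table.fn == 0 or table.fp == 0:
        return float("inf")
    return float(table.tp * table.tn) / float(table.fn * table.fp)


# ---------------------------------------------------------------------------
# rank test
# ---------------------------------------------------------------------------

def mann_whitney_u(group_a, group_b) -> tuple[float, float]:
    """Mann-Whitney U (of group_a) with two-sided p; exact for combined
    n <= 20 without ties, tie-corrected normal approximation otherwise."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be nonempty")
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < combined.size
    method = "exact" if (combined.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    """Binomial logistic regression summary (Wald inference)."""

    names: list[str]
    coef: np.ndarray           # log-odds, intercept first
    se: np.ndarray
    wald: np.ndarray           # (B / SE)^2, chi-square with df 1
    df: np.ndarray
    p_values: np.ndarray
    odds_ratios: np.ndarray    # exp(B)
    ci_low: np.ndarray         # exp(B - 1.96 SE)
    ci_high: np.ndarray
    nagelkerke_r2: float
    cohens_f2: float
    llf: float
    n: int

    def row(self, name: str) -> dict:
        i = self.names.index(name)
        return {"B": float(self.coef[i]), "SE": float(self.se[i]),
                "wald": float(self.wald[i]), "p": float(self.p_values[i]),
                "OR": float(self.odds_ratios[i]),
                "ci": (float(self.ci_low[i]), float(self.ci_high[i]))}


def logistic_fit(design: pd.DataFrame | np.ndarray, outcomes,
                 names: list[str] | None = None) -> LogisticFit:
    """Maximum-likelihood logistic fit with an intercept.

    Raises :class:`SeparationError` on complete or quasi-complete separation
    instead of silently diverging.
    """
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = names or [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(outcomes, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValidationError("outcomes must be binary 0/1")
    Xc = sm.add_constant(X, has_constant="add")
    import warnings
    try:
        with warnings.catch_warnings():
            warnings.filterwarnings("error", message=".*[Ss]eparation.*")
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200, method="newton")
    except Exception as err:  # separation warning/error or singular Hessian
        raise SeparationError(f"logistic fit failed: {err}") from err
    if not res.mle_retvals.get("converged", False) or np.abs(res.params).max() > 25:
        raise SeparationError("complete or quasi-complete separation detected")
    coef, se = np.asarray(res.params), np.asarray(res.bse)
    wald = (coef / se) ** 2
    pvals = stats.chi2.sf(wald, df=1)
    n = len(y)
    llnull = res.llnull
    r2_cs = 1.0 - np.exp(2.0 * (llnull - res.llf) / n)
    r2_max = 1.0 - np.exp(2.0 * llnull / n)
    nagelkerke = float(r2_cs / r2_max) if r2_max > 0 else 0.0
    f2 = nagelkerke / (1.0 - nagelkerke) if nagelkerke < 1.0 else float("inf")
    return LogisticFit(
        names=["const"] + list(names), coef=coef, se=se, wald=wald,
        df=np.ones_like(coef), p_values=pvals,
        odds_ratios=np.exp(coef), ci_low=np.exp(coef - 1.96 * se),
        ci_high=np.exp(coef + 1.96 * se),
        nagelkerke_r2=nagelkerke, cohens_f2=float(f2), llf=float(res.llf), n=n,
    )


# ---------------------------------------------------------------------------
# ROC analysis
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    thresholds: np.ndarray       # candidate decision thresholds (HU)
    sensitivity: np.ndarray      # per threshold, rule: value <= threshold -> positive
    specificity: np.ndarray
    auc: float
    youden_threshold: float
    top_left_threshold: float


def roc_analysis(values, outcomes, lower_indicates_event: bool = True) -> RocResult:
    """ROC over thresholds at midpoints between sorted unique values.

    With ``lower_indicates_event`` the decision rule is value <= threshold.
    AUC is the trapezoidal area; the Youden optimum maximizes Se + Sp - 1 and
    the top-left optimum minimizes sqrt((1-Se)^2 + (1-Sp)^2); threshold ties
    are broken toward the more specific (more conservative) threshold.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if y.all() or not y.any():
        raise ValidationError("both outcome classes must be present for ROC")
    score = -v if lower_indicates_event else v
    uniq = np.unique(v)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    pos = (v[None, :] <= thresholds[:, None]) if lower_indicates_event \
        else (v[None, :] >= thresholds[:, None])
    se = (pos & y).sum(axis=1) / y.sum()
    sp = (~pos & ~y).sum(axis=1) / (~y).sum()

    order = np.argsort(1.0 - sp, kind="stable")
    fpr = np.concatenate([[0.0], (1.0 - sp)[order], [1.0]])
    tpr = np.concatenate([[0.0], se[order], [1.0]])
    auc = float(np.trapezoid(tpr, fpr))

    def _optimum(crit: np.ndarray, maximize: bool) -> float:
        best = crit.max() if maximize else crit.min()
        tol = 1e-12
        tie = np.nonzero(np.abs(crit - best) <= tol)[0]
        return float(thresholds[tie[np.argmax(sp[tie])]])

    youden = _optimum(se + sp - 1.0, maximize=True)
    top_left = _optimum(np.sqrt((1 - se) ** 2 + (1 - sp) ** 2), maximize=False)
    return RocResult(thresholds=thresholds, sensitivity=se, specificity=sp,
                     auc=auc, youden_threshold=youden, top_left_threshold=top_left)


# ---------------------------------------------------------------------------
# association screening
# ---------------------------------------------------------------------------

@dataclass
class AssociationReport:
    spearman: pd.DataFrame            # continuous x continuous
    phi: pd.DataFrame                 # binary x binary
    contingency: pd.DataFrame         # binary x binary
    pearson_with_outcome: pd.Series   # continuous vs binary outcome
    high_correlation_groups: list[list[str]]
    selected_predictors: list[str]
    max_predictors_rule_of_ten: int


def association_screen(cohort: pd.DataFrame, outcome: str = "pneumothorax",
                       corr_threshold: float = 0.7) -> AssociationReport:
    """Pairwise correlation/effect-size screen with rule-of-ten documentation.

    Continuous columns are compared by Spearman correlation, binary columns by
    phi and the contingency coefficient, and continuous columns against the
    binary outcome by Pearson correlation. Within each highly correlated group
    the member with the largest |effect size| against the outcome is selected,
    and the number of retained predictors is capped at one per ten events in
    the rarer outcome class.
    """
    df = cohort.drop(columns=[c for c in ("case_id",) if c in cohort])
    y = df[outcome].astype(bool)
    binary = [c for c in df.columns
              if df[c].dtype == bool and c != outcome]
    cont = [c for c in df.columns
            if np.issubdtype(df[c].dtype, np.number) and c != outcome
            and df[c].nunique() > 5]

    spearman = df[cont].corr(method="spearman") if cont else pd.DataFrame()
    phi_m = pd.DataFrame(np.eye(len(binary)), index=binary, columns=binary)
    cc_m = phi_m.copy()
    for i, a in enumerate(binary):
        for b in binary[i + 1:]:
            t = build_table(df.assign(case_id=df.index), a, b)
            phi_m.loc[a, b] = phi_m.loc[b, a] = phi_coefficient(t)
            cc_m.loc[a, b] = cc_m.loc[b, a] = contingency_coefficient(t)
    pearson_out = pd.Series(
        {c: float(np.corrcoef(df[c], y.astype(float))[0, 1]) for c in cont})

    # effect size against the outcome for every candidate predictor
    effect = {}
    for c in binary:
        effect[c] = abs(phi_coefficient(build_table(df.assign(case_id=df.index),
                                                    outcome, c)))
    for c in cont:
        effect[c] = abs(pearson_out[c])

    # group predictors whose mutual |correlation| exceeds the threshold
    all_pred = binary + cont
    corr = pd.DataFrame(np.eye(len(all_pred)), index=all_pred, columns=all_pred)
    if len(binary):
        corr.loc[binary, binary] = phi_m.abs()
    if len(cont):
        corr.loc[cont, cont] = spearman.abs()
    groups, seen = [], set()
    for c in all_pred:
        if c in seen:
            continue
        grp = [c] + [d for d in all_pred
                     if d != c and abs(corr.loc[c, d]) >= corr_threshold]
        seen.update(grp)
        groups.append(grp)
    selected = [max(g, key=lambda c: effect.get(c, 0.0)) for g in groups]
    selected.sort(key=lambda c: -effect.get(c, 0.0))
    n_events = int(min(y.sum(), (~y).sum()))
    cap = max(1, n_events // 10)
    return AssociationReport(
        spearman=spearman, phi=phi_m, contingency=cc_m,
        pearson_with_outcome=pearson_out,
        high_correlation_groups=[g for g in groups if len(g) > 1],
        selected_predictors=selected[:cap],
        max_predictors_rule_of_ten=cap,
    )
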