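"""Two-stage stepwise model building, cross-validated ROC evaluation, and
the randomization (spuriousness) test for terrain covariates.

Stage 1 forward-selects among the survey covariates (gear, habitat, month,
temperature, latitude, depth, lunar phase and the latitude interactions) by
AIC, skipping additions blocked by the |r| > 0.60 correlation screen. Stage 2
then offers the terrain (buffer-statistic) covariates to the stage-1 winner:
a terrain term is retained only if it lowers AIC AND does not degrade
cross-validated utility. Because many terrain candidates are screened, a
permutation test estimates the probability that the retained terrain term is
spurious: each replicate permutes every terrain candidate column (preserving
its marginal distribution), refits the base model plus each permuted
candidate singly, and records the percent deviance explained by the best
one; the spurious probability is the fraction of replicates in which that
best random term beats the true term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .covariates import DesignBuilder, DesignMatrix
from .glmm import ModelFit, fit_glmm, predict_proba

#: non-terrain candidate terms and the latitude interactions (stage 1)
STAGE1_TERMS = ("gear", "habitat", "month", "temp_c", "lat_bin", "depth_bin", "lunar3")
STAGE1_INTERACTIONS = ("lat_bin:depth_bin", "lat_bin:month", "lat_bin:temp_c")

CORRELATION_LIMIT = 0.60
DEFAULT_RANDOMIZATION_REPS = 500


# ---------------------------------------------------------------------------
# Species filter
# ---------------------------------------------------------------------------

def filter_modelable(records: pd.DataFrame, min_spawners: int = 90) -> pd.DataFrame:
    """Per-species sample accounting and modelability.

    A species is modelable when its count of spawning-condition females is
    strictly greater than ``min_spawners``. "Valid sets" (gear deployments
    with >= 3 histologically sampled fish of the species) are reported as a
    diagnostic.
    """
    rows = []
    for sp, grp in records.groupby("species"):
        per_set = grp.groupby("set_id").size()
        rows.append(
            {
                "species": sp,
                "n_samples": len(grp),
                "n_spawning_females": int(grp["spawning"].sum()),
                "n_valid_sets": int((per_set >= 3).sum()),
                "modelable": int(grp["spawning"].sum()) > min_spawners,
            }
        )
    return pd.DataFrame(rows).set_index("species")


# ---------------------------------------------------------------------------
# Correlation screen
# ---------------------------------------------------------------------------

def _cramers_v(a: pd.Series, b: pd.Series) -> float:
    tab = pd.crosstab(a, b).to_numpy(float)
    n = tab.sum()
    if n == 0:
        return np.nan
    row = tab.sum(axis=1, keepdims=True)
    col = tab.sum(axis=0, keepdims=True)
    expected = row @ col / n
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.nansum((tab - expected) ** 2 / np.where(expected > 0, expected, np.nan))
    k = min(tab.shape) - 1
    if k <= 0:
        return 0.0
    return float(np.sqrt(chi2 / (n * k)))


def _correlation_ratio(cat: pd.Series, num: pd.Series) -> float:
    df = pd.DataFrame({"c": cat, "x": pd.to_numeric(num, errors="coerce")}).dropna()
    if df.empty or df["x"].var() == 0:
        return np.nan
    grand = df["x"].mean()
    ss_between = df.groupby("c")["x"].apply(lambda s: len(s) * (s.mean() - grand) ** 2).sum()
    ss_total = ((df["x"] - grand) ** 2).sum()
    return float(np.sqrt(ss_between / ss_total)) if ss_total > 0 else np.nan


@dataclass
class ScreenResult:
    matrix: pd.DataFrame                    # pairwise |association|
    blocked: frozenset[frozenset]           # pairs with |r| > limit
    excluded: tuple[str, ...]               # zero-variance terms

    def is_blocked(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.blocked


def correlation_screen(
    values: pd.DataFrame, kinds: dict[str, str], limit: float = CORRELATION_LIMIT
) -> ScreenResult:
    """Pairwise association matrix and the blocked term pairs.

    Numeric-numeric pairs use Pearson |r|, factor-factor pairs Cramer's V,
    and mixed pairs the correlation ratio (eta). Pairs strictly above
    ``limit`` are blocked from co-occurring in a model; |r| == limit exactly
    is allowed. Zero-variance terms are excluded with a warning record.
    """
    terms = list(values.columns)
    excluded = []
    for t in terms:
        col = values[t]
        if kinds[t] == "num" and pd.to_numeric(col, errors="coerce").var() == 0:
            excluded.append(t)
        elif kinds[t] == "cat" and col.nunique(dropna=True) < 2:
            excluded.append(t)
    use = [t for t in terms if t not in excluded]
    mat = pd.DataFrame(np.eye(len(use)), index=use, columns=use)
    blocked = set()
    for i, a in enumerate(use):
        for b in use[i + 1:]:
            ka, kb = kinds[a], kinds[b]
            if ka == "num" and kb == "num":
                sub = values[[a, b]].apply(pd.to_numeric, errors="coerce").dropna()
                r = abs(sub[a].corr(sub[b])) if len(sub) > 2 else np.nan
            elif ka == "cat" and kb == "cat":
                r = _cramers_v(values[a], values[b])
            elif ka == "cat":
                r = _correlation_ratio(values[a], values[b])
            else:
                r = _correlation_ratio(values[b], values[a])
            mat.loc[a, b] = mat.loc[b, a] = r
            if np.isfinite(r) and r > limit:
                blocked.add(frozenset((a, b)))
    return ScreenResult(mat, frozenset(blocked), tuple(excluded))


# ---------------------------------------------------------------------------
# ROC / cross-validation
# ---------------------------------------------------------------------------

def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC by the rank-sum formulation with midranks for ties, in
    percent."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        return np.nan
    ranks = rankdata(scores)
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    return float(100.0 * auc)


def optimal_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Lowest observed-score threshold maximising TPR + TNR under a
    ``score >= t`` positive rule."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    cands = np.unique(scores)
    best_t, best_j = cands[0], -np.inf
    n1 = labels.sum()
    n0 = len(labels) - n1
    for t in cands:
        pred = scores >= t
        tpr = (pred & (labels == 1)).sum() / n1 if n1 else 0.0
        tnr = (~pred & (labels == 0)).sum() / n0 if n0 else 0.0
        j = tpr + tnr
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_t)


@dataclass
class CVReport:
    auc: float                  # pooled test-set AUC, percent
    fpr: float                  # percent
    fnr: float                  # percent
    thresholds: list[float]     # per-fold, chosen on the training ROC
    pooled_threshold: float
    grade: str
    auc_fold_mean: float
    fold_assignments: np.ndarray
    seed: int
    k: int
    confusion: dict = field(default_factory=dict)


def crossvalidate(
    design: DesignMatrix,
    k: int = 10,
    seed: int = 0,
    n_quad: int | None = None,
) -> CVReport:
    """k-fold cross-validation with class-stratified folds.

    Per fold: fit on the training rows, choose the threshold maximising
    TPR + TNR on the *training* ROC, then classify the held-out rows.
    Error rates come from the pooled confusion counts; the AUC is computed
    on the concatenated held-out predictions (the per-fold mean is also
    reported).
    """
    y = design.y.astype(int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of = np.full(len(y), -1)
    pooled_scores = np.empty(len(y))
    thresholds: list[float] = []
    fold_aucs: list[float] = []
    tp = fp = tn = fn = 0
    fit_kwargs = {} if n_quad is None else {"n_quad": n_quad}
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        fold_of[te] = fold
        d_tr = design.subset(tr)
        fit = fit_glmm(d_tr, fit_null=False, **fit_kwargs)
        s_tr = predict_proba(fit, d_tr.X)
        t = optimal_threshold(s_tr, y[tr])
        thresholds.append(t)
        s_te = predict_proba(fit, design.subset(te).X)
        pooled_scores[te] = s_te
        pred = s_te >= t
        yt = y[te]
        tp += int((pred & (yt == 1)).sum())
        fp += int((pred & (yt == 0)).sum())
        tn += int((~pred & (yt == 0)).sum())
        fn += int((~pred & (yt == 1)).sum())
        a = auc_mann_whitney(s_te, yt)
        if np.isfinite(a):
            fold_aucs.append(a)
    auc = auc_mann_whitney(pooled_scores, y)
    fpr = 100.0 * fp / (fp + tn) if (fp + tn) else np.nan
    fnr = 100.0 * fn / (fn + tp) if (fn + tp) else np.nan
    return CVReport(
        auc=auc,
        fpr=fpr,
        fnr=fnr,
        thresholds=thresholds,
        pooled_threshold=optimal_threshold(pooled_scores, y),
        grade=grade_auc(auc),
        auc_fold_mean=float(np.mean(fold_aucs)) if fold_aucs else np.nan,
        fold_assignments=fold_of,
        seed=seed,
        k=k,
        confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
    )


def grade_auc(auc_percent: float) -> str:
    """Utility grade: excellent (>= 90), good (80-89), fair (70-79),
    poor (< 70)."""
    if not np.isfinite(auc_percent) or not 0 <= auc_percent <= 100:
        raise ValueError("AUC must be in [0, 100]")
    if auc_percent >= 90:
        return "excellent"
    if auc_percent >= 80:
        return "good"
    if auc_percent >= 70:
        return "fair"
    return "poor"


# ---------------------------------------------------------------------------
# Forward stepwise
# ---------------------------------------------------------------------------

@dataclass
class StepwiseResult:
    best_terms: tuple[str, ...]
    best_fit: ModelFit
    path: list[tuple[tuple[str, ...], float]]       # accepted models (terms, AIC)
    visited: list[tuple[tuple[str, ...], float]]    # all evaluated, ranked by AIC
    fits: dict[tuple[str, ...], ModelFit]
    cv: CVReport | None = None


def _margins_present(term: str, current: tuple[str, ...], override: bool) -> bool:
    if ":" not in term or override:
        return True
    a, b = term.split(":")
    return a in current and b in current


def forward_stepwise(
    builder: DesignBuilder,
    candidates: tuple[str, ...],
    base: tuple[str, ...] = (),
    screen: ScreenResult | None = None,
    hierarchy_override: bool = False,
    stage: int = 1,
    stage1_cv: CVReport | None = None,
    cv_seed: int = 0,
    cv_k: int = 10,
    auc_tolerance: float = 0.5,
    n_quad: int | None = None,
) -> StepwiseResult:
    """Forward-stepwise AIC selection.

    At each step the candidate giving the largest AIC decrease is added;
    candidates blocked by the correlation screen against any current term,
    or interactions whose margins are absent, are skipped. Selection stops
    when no candidate lowers AIC. Stage 2 (terrain variables added to the
    fixed stage-1 winner) additionally requires that the candidate's
    cross-validated AUC not fall more than ``auc_tolerance`` points below
    the stage-1 model's.
    """
    fit_kwargs = {} if n_quad is None else {"n_quad": n_quad}
    fits: dict[tuple[str, ...], ModelFit] = {}

    def get_fit(terms: tuple[str, ...]) -> ModelFit:
        if terms not in fits:
            fits[terms] = fit_glmm(builder.build(terms), **fit_kwargs)
        return fits[terms]

    current = tuple(base)
    base_fit = get_fit(current)
    if not base_fit.converged:
        raise RuntimeError("base model did not converge; aborting stepwise")
    current_aic = base_fit.aic
    path = [(current, current_aic)]
    visited = [(current, current_aic)]
    ref_auc = stage1_cv.auc if (stage == 2 and stage1_cv is not None) else None
    remaining = [c for c in candidates if c not in current]

    while remaining:
        results = []
        for cand in remaining:
            if screen is not None and any(
                screen.is_blocked(cand, t) for t in current
            ):
                continue
            if not _margins_present(cand, current, hierarchy_override):
                continue
            try:
                f = get_fit(current + (cand,))
            except (ValueError, RuntimeError, np.linalg.LinAlgError):
                continue
            visited.append((current + (cand,), f.aic))
            results.append((f.aic, cand, f))
        if not results:
            break
        results.sort(key=lambda r: (r[0], candidates.index(r[1])))
        best_aic, best_cand, best_fit = results[0]
        if best_aic >= current_aic:
            break
        if ref_auc is not None:
            cand_cv = crossvalidate(
                best_fit.design, k=cv_k, seed=cv_seed, n_quad=n_quad
            )
            if cand_cv.auc < ref_auc - auc_tolerance:
                # predictive utility degraded: do not retain, stop offering
                remaining.remove(best_cand)
                continue
        current = current + (best_cand,)
        current_aic = best_aic
        path.append((current, current_aic))
        remaining.remove(best_cand)

    visited.sort(key=lambda v: v[1])
    return StepwiseResult(
        best_terms=current,
        best_fit=fits[current],
        path=path,
        visited=visited,
        fits=fits,
    )


# ---------------------------------------------------------------------------
# Randomization (spuriousness) test
# ---------------------------------------------------------------------------

@dataclass
class RandomizationReport:
    true_term: str
    true_percent_deviance: float
    replicate_percents: np.ndarray
    spurious_probability: float
    reps: int
    seed: int


def randomization_test(
    builder: DesignBuilder,
    base_terms: tuple[str, ...],
    true_term: str,
    candidates: tuple[str, ...],
    reps: int = DEFAULT_RANDOMIZATION_REPS,
    seed: int = 0,
    n_quad: int | None = None,
) -> RandomizationReport:
    """Probability that the retained terrain term is spurious.

    Each replicate independently permutes every terrain candidate's
    underlying column (permutation preserves the marginal distribution
    exactly), refits base + each permuted candidate singly, and records the
    percent deviance explained by the best of them (largest AIC reduction).
    The spurious probability is the fraction of replicates whose best random
    candidate explains more deviance than the true term does.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    fit_kwargs = {} if n_quad is None else {"n_quad": n_quad}
    rng = np.random.default_rng(seed)

    base_fit = fit_glmm(builder.build(base_terms), **fit_kwargs)
    d_null = base_fit.null_deviance
    true_fit = fit_glmm(builder.build(base_terms + (true_term,)), **fit_kwargs)
    if true_fit.n != base_fit.n:
        raise ValueError("rows differ between base and terrain models")
    true_pct = 100.0 * (base_fit.deviance - true_fit.deviance) / d_null

    source_cols = {}
    for cand in candidates:
        source_cols[cand] = builder.resolve(cand).source

    best_pcts = np.empty(reps)
    records0 = builder.records
    for rep in range(reps):
        shuffled = records0.copy()
        for cand in candidates:
            col = source_cols[cand]
            shuffled[col] = rng.permutation(shuffled[col].to_numpy())
        b = DesignBuilder(
            shuffled,
            term_defs=builder.term_defs,
            group_col=builder.group_col,
        )
        best = -np.inf
        for cand in candidates:
            try:
                f = fit_glmm(b.build(base_terms + (cand,)), fit_null=False, **fit_kwargs)
            except (ValueError, np.linalg.LinAlgError):
                continue
            pct = 100.0 * (base_fit.deviance - f.deviance) / d_null
            # "largest reduction in AIC" and largest deviance share coincide
            # when candidates carry equal parameter counts; rank by AIC.
            if -f.aic > best:
                best = -f.aic
                best_pct = pct
        best_pcts[rep] = best_pct if np.isfinite(best) else 0.0
    spurious = float(np.mean(best_pcts > true_pct))
    return RandomizationReport(
        true_term=true_term,
        true_percent_deviance=true_pct,
        replicate_percents=best_pcts,
        spurious_probability=spurious,
        reps=reps,
        seed=seed,
    )
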