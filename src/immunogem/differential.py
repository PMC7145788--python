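"""Univariate and multivariate differential statistics on omics matrices.

Covers the cohort analysis chain: log2 normalisation, age binning, PCA
outlier screening (Hotelling T²), per-feature explained variation,
Welch/Student and paired contrasts, sparse PLS-DA with VIP scores and
cross-validated AUC, the combined selection rule, Spearman correlation
maps, and Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: selection thresholds used throughout the study reports
DEFAULT_THRESHOLDS = {
    "p": 0.05,
    "fdr": 0.05,
    "vip": 1.0,
    "rc": 0.05,
    "auc": 0.65,
    "rho": 0.70,
}


# ---------------------------------------------------------------------------
# normalisation / binning / QC
# ---------------------------------------------------------------------------

def log2_normalize(values: pd.DataFrame, offset: float = 1.0) -> pd.DataFrame:
    """log2(x + offset); the offset keeps zero intensities finite."""
    arr = values.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("negative intensities cannot be log-normalised")
    return pd.DataFrame(np.log2(arr + offset), index=values.index,
                        columns=values.columns)


def assign_age_bins(sample_meta: pd.DataFrame, target_ages=(12, 24, 36),
                    window: float = 6.0) -> pd.Series:
    """Assign each sample to its nearest target age within ±``window`` months.

    Samples outside every window are dropped.  If one subject has several
    samples in a bin, the one closest to the target age is kept (earlier
    sample on ties).  Returns a Series sample -> bin for the kept samples.
    """
    target_ages = sorted(target_ages)
    rows = []
    for sample, row in sample_meta.iterrows():
        age = row["age_months"]
        dists = [abs(age - t) for t in target_ages]
        i = int(np.argmin(dists))
        if dists[i] <= window:
            rows.append((sample, row["subject"], target_ages[i], dists[i], age))
    df = pd.DataFrame(rows, columns=["sample", "subject", "bin", "dist", "age"])
    df = df.sort_values(["subject", "bin", "dist", "age", "sample"])
    kept = df.groupby(["subject", "bin"], sort=True).head(1)
    return kept.set_index("sample")["bin"]


def pca_outlier_check(values: pd.DataFrame, n_components: int = 2,
                      confidence: float = 0.95) -> list[str]:
    """Samples outside the Hotelling T² ellipse of the first PCs.

    Data are column-centred; scores on the leading ``n_components`` are
    tested against the T² limit ``k(n-1)/(n-k) * F_{k,n-k}(confidence)``.
    """
    n = len(values)
    if n <= n_components:
        raise ValueError(f"need more than {n_components} samples, got {n}")
    X = values.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    k = n_components
    scores = U[:, :k] * s[:k]
    var = (s[:k] ** 2) / (n - 1)
    var = np.where(var <= 0, np.inf, var)
    t2 = ((scores ** 2) / var).sum(axis=1)
    if confidence >= 1.0:
        return []
    limit = k * (n - 1) / (n - k) * stats.f.ppf(confidence, k, n - k)
    return [s_ for s_, t in zip(values.index, t2) if t > limit]


# ---------------------------------------------------------------------------
# explained variation
# ---------------------------------------------------------------------------

def _design_blocks(meta: pd.DataFrame, interactions: bool):
    """Ordered covariate blocks: age, sex, group (+ pairwise interactions)."""
    age = meta["age_months"].to_numpy(dtype=float)
    age = (age - age.mean())[:, None]
    sex = (meta["sex"] == "F").to_numpy(dtype=float)
    sex = (sex - sex.mean())[:, None]
    groups = pd.get_dummies(meta["group"], drop_first=True).to_numpy(dtype=float)
    groups = groups - groups.mean(axis=0)
    blocks = [("age", age), ("sex", sex), ("group", groups)]
    if interactions:
        blocks += [
            ("age:sex", age * sex),
            ("age:group", age * groups),
            ("sex:group", sex * groups),
        ]
    return blocks


def variance_explained(values_log2: pd.DataFrame, sample_meta: pd.DataFrame,
                       interactions: bool = True) -> pd.DataFrame:
    """Per-feature explained variation (%) by age, sex, group and interactions.

    Sequential (type I) sums of squares from a linear model fitted per
    feature: each factor's EV% is the incremental drop in residual sum of
    squares when its block enters, relative to the total sum of squares.
    Per-feature EV percentages therefore sum to at most 100.  Collinear
    blocks contribute 0 with a warning.
    """
    meta = sample_meta.loc[values_log2.index]
    blocks = _design_blocks(meta, interactions)
    Y = values_log2.to_numpy(dtype=float)
    Y = Y - Y.mean(axis=0)
    tss = (Y ** 2).sum(axis=0)
    tss = np.where(tss == 0, np.inf, tss)

    n = len(meta)
    X = np.ones((n, 0))
    prev_rss = (Y ** 2).sum(axis=0)
    out = {}
    for name, block in blocks:
        X_new = np.hstack([X, block])
        beta, _, rank, _ = np.linalg.lstsq(X_new, Y, rcond=None)
        if rank < X_new.shape[1]:
            warnings.warn(f"factor {name!r} is rank-deficient in the design; "
                          "its EV may be partially absorbed", stacklevel=2)
        resid = Y - X_new @ beta
        rss = (resid ** 2).sum(axis=0)
        out[name] = 100.0 * np.clip(prev_rss - rss, 0, None) / tss
        prev_rss = rss
        X = X_new
    ev = pd.DataFrame(out, index=values_log2.columns)
    return ev


def ev_summary(ev: pd.DataFrame) -> pd.Series:
    """Population summary: median EV% per factor across features."""
    return ev.median(axis=0)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    # ranks as an empirical CDF factor; this exact operation order matches
    # the standard reference implementations bit for bit
    ecdf = np.arange(1, m + 1) / float(m)
    ranked = p[order] / ecdf
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# univariate contrasts
# ---------------------------------------------------------------------------

@dataclass
class ContrastResult:
    """Per-feature statistics for one group (or before/after) comparison."""

    name: str
    table: pd.DataFrame  # columns: log2fc, t, p, q [, vip, rc, selected_*]
    auc: float | None = None
    n_a: int = 0
    n_b: int = 0
    notes: dict = field(default_factory=dict)


def _welch_table(A: np.ndarray, B: np.ndarray, columns, equal_var: bool) -> pd.DataFrame:
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(A, B, axis=0, equal_var=equal_var)
    log2fc = A.mean(axis=0) - B.mean(axis=0)
    # degenerate variance in both groups: no evidence either way -> p = 1
    degenerate = (A.var(axis=0) == 0) & (B.var(axis=0) == 0)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    df = pd.DataFrame({"log2fc": log2fc, "t": t, "p": p}, index=columns)
    df["q"] = bh_fdr(df["p"].to_numpy())
    df["degenerate"] = degenerate
    return df


def two_sample_contrast(values_log2: pd.DataFrame, sample_meta: pd.DataFrame,
                        group_a: str, group_b: str, age_bin: int | None = None,
                        bins: pd.Series | None = None,
                        equal_var: bool = False) -> ContrastResult:
    """Welch (default) two-sample t per feature; log2FC = mean(A) − mean(B).

    If ``age_bin`` is given, samples are restricted to that bin (``bins``
    from :func:`assign_age_bins`; nominal_age metadata otherwise).
    """
    meta = sample_meta.loc[values_log2.index]
    mask = pd.Series(True, index=meta.index)
    if age_bin is not None:
        if bins is not None:
            mask = meta.index.isin(bins.index[bins == age_bin])
        else:
            mask = (meta["nominal_age"] == age_bin).to_numpy()
    sel = values_log2.loc[mask]
    meta = meta.loc[sel.index]
    A = sel[meta["group"] == group_a].to_numpy(dtype=float)
    B = sel[meta["group"] == group_b].to_numpy(dtype=float)
    if len(A) < 2 or len(B) < 2:
        raise ValueError(
            f"contrast {group_a} vs {group_b} (bin {age_bin}): "
            f"need >= 2 samples per group, got {len(A)}/{len(B)}"
        )
    table = _welch_table(A, B, values_log2.columns, equal_var)
    table["selected_uni"] = table["p"] < DEFAULT_THRESHOLDS["p"]
    name = f"{group_a}_vs_{group_b}" + (f"_{age_bin}m" if age_bin is not None else "")
    return ContrastResult(name=name, table=table, n_a=len(A), n_b=len(B))


def paired_seroconversion_contrast(values_log2: pd.DataFrame,
                                   sample_meta: pd.DataFrame,
                                   group: str) -> ContrastResult:
    """Within-subject change after seroconversion (after minus before).

    Per subject, the before- and after-seroconversion samples are averaged;
    a paired t test is applied per feature.  Subjects lacking samples on
    either side are excluded and counted in the result notes.
    """
    meta = sample_meta.loc[values_log2.index]
    meta = meta[meta["group"] == group]
    before, after = [], []
    excluded = 0
    for subject, rows in meta.groupby("subject"):
        sc = rows["seroconversion_age"].iloc[0]
        if not np.isfinite(sc):
            excluded += 1
            continue
        pre = rows.index[rows["age_months"] < sc]
        post = rows.index[rows["age_months"] >= sc]
        if len(pre) == 0 or len(post) == 0:
            excluded += 1
            continue
        before.append(values_log2.loc[pre].mean(axis=0))
        after.append(values_log2.loc[post].mean(axis=0))
    if len(before) < 2:
        raise ValueError(
            f"paired contrast for {group}: only {len(before)} usable subjects"
        )
    B = np.vstack(before)
    A = np.vstack(after)
    D = A - B
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_rel(A, B, axis=0)
    degenerate = D.var(axis=0) == 0
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    table = pd.DataFrame(
        {"log2fc": D.mean(axis=0), "t": t, "p": p}, index=values_log2.columns)
    table["q"] = bh_fdr(table["p"].to_numpy())
    table["degenerate"] = degenerate
    table["selected_uni"] = table["p"] < DEFAULT_THRESHOLDS["p"]
    return ContrastResult(name=f"{group}_after_vs_before", table=table,
                          n_a=len(after), n_b=len(before),
                          notes={"excluded_subjects": excluded})


def group_totals_anova(values_log2: pd.DataFrame, sample_meta: pd.DataFrame,
                       age_bin: int, bins: pd.Series | None = None) -> tuple[float, float]:
    """One-way ANOVA on per-sample total signal across the three groups."""
    meta = sample_meta.loc[values_log2.index]
    if bins is not None:
        mask = meta.index.isin(bins.index[bins == age_bin])
    else:
        mask = (meta["nominal_age"] == age_bin).to_numpy()
    sel = values_log2.loc[mask]
    meta = meta.loc[sel.index]
    totals = sel.sum(axis=1)
    samples = [totals[meta["group"] == g].to_numpy() for g in sorted(meta["group"].unique())]
    if len(samples) < 2:
        raise ValueError("ANOVA needs at least two groups in the bin")
    if all(np.var(s) == 0 for s in samples):
        return float("nan"), 1.0
    f, p = stats.f_oneway(*samples)
    return float(f), float(p)


# ---------------------------------------------------------------------------
# sparse PLS-DA
# ---------------------------------------------------------------------------

@dataclass
class PLSDAModel:
    """Fitted sparse PLS-DA (PLS1 on a centred 0/1 class indicator)."""

    weights: np.ndarray       # features x components (normalised, sparse)
    loadings: np.ndarray      # features x components
    scores: np.ndarray        # samples x components
    y_loadings: np.ndarray    # components
    ssy: np.ndarray           # class variance explained per component
    coef: np.ndarray          # features: final-predictor regression coefficients
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    features: list


def plsda_fit(values: pd.DataFrame, labels, n_components: int = 2,
              keep_per_component: int | None = 20,
              scale: bool = True) -> PLSDAModel:
    """NIPALS-style sparse PLS1 against a binary class indicator.

    Each component's weight vector keeps only its ``keep_per_component``
    largest-|weight| features (soft thresholding at the (k+1)-th largest
    magnitude, then renormalisation); ``None`` keeps all features, giving
    ordinary PLS-DA.  ``coef`` holds each feature's regression coefficient
    in the final linear predictor.
    """
    X = values.to_numpy(dtype=float).copy()
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"PLS-DA needs exactly 2 classes, got {classes.size}")
    yv = (y == classes[1]).astype(float)

    n, p = X.shape
    if n_components > min(n - 1, p):
        raise ValueError(f"n_components={n_components} exceeds the data rank bound")
    x_mean = X.mean(axis=0)
    X -= x_mean
    x_scale = X.std(axis=0, ddof=1) if scale else np.ones(p)
    x_scale = np.where(x_scale == 0, 1.0, x_scale)
    X /= x_scale
    y_mean = yv.mean()
    yc = yv - y_mean

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    Q = np.zeros(n_components)
    ssy = np.zeros(n_components)
    Xd, yd = X.copy(), yc.copy()
    k = keep_per_component
    fitted = 0
    for a in range(n_components):
        w = Xd.T @ yd
        if np.linalg.norm(w) <= 1e-14:
            break
        if k is not None and k < p:
            thr = np.partition(np.abs(w), p - k - 1)[p - k - 1]
            w = np.sign(w) * np.clip(np.abs(w) - thr, 0, None)
            if np.linalg.norm(w) <= 1e-14:
                break
        w = w / np.linalg.norm(w)
        t = Xd @ w
        tt = t @ t
        if tt <= 1e-14:
            break
        pl = Xd.T @ t / tt
        q = yd @ t / tt
        Xd = Xd - np.outer(t, pl)
        yd = yd - q * t
        W[:, a], P[:, a], T[:, a], Q[a] = w, pl, t, q
        ssy[a] = q * q * tt
        fitted = a + 1

    # deflation may exhaust the class signal early; use the components
    # actually fitted
    W, P, T, Q, ssy = (W[:, :fitted], P[:, :fitted], T[:, :fitted],
                       Q[:fitted], ssy[:fitted])
    if fitted:
        # B = W (P'W)^-1 q maps the (centred, scaled) X to the predictor
        coef = W @ np.linalg.solve(P.T @ W, Q)
    else:
        coef = np.zeros(p)
    return PLSDAModel(weights=W, loadings=P, scores=T, y_loadings=Q, ssy=ssy,
                      coef=coef, x_mean=x_mean, x_scale=x_scale, y_mean=y_mean,
                      features=list(values.columns))


def plsda_predict(model: PLSDAModel, values: pd.DataFrame) -> np.ndarray:
    X = (values.to_numpy(dtype=float) - model.x_mean) / model.x_scale
    return X @ model.coef + model.y_mean


def vip_scores(model: PLSDAModel) -> pd.Series:
    """VIP_j = sqrt( p · Σ_a SSY_a w_ja² / Σ_a SSY_a ); Σ_j VIP_j² = p."""
    p = model.weights.shape[0]
    ssy = model.ssy
    total = ssy.sum()
    if total == 0:
        return pd.Series(np.zeros(p), index=model.features)
    W2 = model.weights ** 2  # weight columns are unit-norm
    vip = np.sqrt(p * (W2 @ ssy) / total)
    return pd.Series(vip, index=model.features)


def cv_auc(values: pd.DataFrame, labels, n_components: int = 2,
           keep_per_component: int | None = 20, folds: int = 5,
           repeats: int = 10, seed: int = 0) -> float:
    """Mean stratified k-fold cross-validated AUC of the PLS-DA predictor."""
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("cv_auc needs exactly 2 classes")
    min_count = counts.min()
    if min_count < folds:
        logger.warning("smallest class has %d members; reducing folds from %d",
                       min_count, folds)
        folds = max(2, int(min_count))
    ybin = (y == classes[1]).astype(int)
    # stratify on first-appearance class codes so the fold assignment (and
    # hence the CV estimate) is invariant to renaming or swapping the labels
    strata = pd.factorize(y)[0]
    aucs = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=seed * 1000 + rep)
        pred = np.zeros(len(y))
        for train, test in skf.split(values, strata):
            m = plsda_fit(values.iloc[train], y[train],
                          n_components=n_components,
                          keep_per_component=keep_per_component)
            pred[test] = plsda_predict(m, values.iloc[test])
        aucs.append(roc_auc_score(ybin, pred))
    return float(np.mean(aucs))


# ---------------------------------------------------------------------------
# combined selection and correlation map
# ---------------------------------------------------------------------------

def full_contrast(values_log2: pd.DataFrame, sample_meta: pd.DataFrame,
                  group_a: str, group_b: str, age_bin: int | None = None,
                  bins: pd.Series | None = None, thresholds: dict | None = None,
                  n_components: int = 2, keep_per_component: int | None = 20,
                  cv_repeats: int = 3, seed: int = 0) -> ContrastResult:
    """Univariate + sparse PLS-DA contrast with the combined selection rule."""
    res = two_sample_contrast(values_log2, sample_meta, group_a, group_b,
                              age_bin=age_bin, bins=bins)
    meta = sample_meta.loc[values_log2.index]
    if age_bin is not None:
        if bins is not None:
            mask = meta.index.isin(bins.index[bins == age_bin])
        else:
            mask = (meta["nominal_age"] == age_bin).to_numpy()
    else:
        mask = pd.Series(True, index=meta.index).to_numpy()
    sel = values_log2.loc[mask]
    meta = meta.loc[sel.index]
    in_pair = meta["group"].isin([group_a, group_b]).to_numpy()
    X = sel.loc[in_pair]
    y = (meta.loc[in_pair, "group"] == group_a).astype(int).to_numpy()

    n_comp = min(n_components, len(X) - 1)
    model = plsda_fit(X, y, n_components=n_comp,
                      keep_per_component=keep_per_component)
    res.table["vip"] = vip_scores(model)
    res.table["rc"] = pd.Series(model.coef, index=model.features)
    res.auc = cv_auc(X, y, n_components=n_comp,
                     keep_per_component=keep_per_component,
                     repeats=cv_repeats, seed=seed)
    return select_altered_features(res, thresholds)


def select_altered_features(contrast: ContrastResult,
                            thresholds: dict | None = None) -> ContrastResult:
    """Combined selection: "multi+uni" needs AUC, |RC|, VIP and p to all pass;
    "uni-only" needs only p < threshold."""
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    t = contrast.table
    if "vip" not in t or "rc" not in t or contrast.auc is None:
        raise ValueError("contrast lacks multivariate fields (vip/rc/auc)")
    uni = t["p"] < thr["p"]
    multi = ((contrast.auc >= thr["auc"]) & (t["vip"] > thr["vip"])
             & (t["rc"].abs() > thr["rc"]) & uni)
    t["auc"] = contrast.auc
    t["selected_uni"] = uni
    t["selected_multi"] = multi
    t["basis"] = np.where(multi, "multi+uni", np.where(uni, "uni-only", ""))
    return contrast


def spearman_map(matrix_a: pd.DataFrame, matrix_b: pd.DataFrame,
                 rho_threshold: float | None = None,
                 p_threshold: float = 0.05):
    """Feature-by-feature Spearman rank correlation across paired samples.

    Rows of the two matrices must be aligned one-to-one (same subject and
    age).  Returns ``(rho, p, mask)`` DataFrames indexed features_a x
    features_b; the mask applies |rho| > threshold and p < threshold
    (default ρ > 0.70 as in the study reports).
    """
    if rho_threshold is None:
        rho_threshold = DEFAULT_THRESHOLDS["rho"]
    if len(matrix_a) != len(matrix_b):
        raise ValueError("matrices must have the same (paired) samples")
    n = len(matrix_a)
    if n < 4:
        raise ValueError(f"need >= 4 paired samples, got {n}")
    pa, pb = matrix_a.shape[1], matrix_b.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho_all, p_all = stats.spearmanr(matrix_a.to_numpy(), matrix_b.to_numpy())
    if pa + pb == 2:  # scipy collapses the 2-variable case to scalars
        rho_all = np.array([[1.0, rho_all], [rho_all, 1.0]])
        p_all = np.array([[0.0, p_all], [p_all, 0.0]])
    rho = pd.DataFrame(rho_all[:pa, pa:], index=matrix_a.columns,
                       columns=matrix_b.columns)
    p = pd.DataFrame(p_all[:pa, pa:], index=matrix_a.columns,
                     columns=matrix_b.columns)
    mask = (rho > rho_threshold) & (p < p_threshold)
    return rho, p, mask
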