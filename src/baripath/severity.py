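"""T2D-severity stratification from routine clinical variables.

Patients are described at each time point (baseline, 1 and 5 years after
Roux-en-Y gastric bypass) by seven variables routinely linked to type-2
diabetes severity: HbA1C, fasting blood glucose, T2D duration, age, sex,
the number of glucose-lowering drugs, and insulin requirement.  All
patient-by-timepoint rows are stacked, standardized, reduced by
correlation-matrix PCA (components retained by the Kaiser-Guttman rule,
eigenvalue >= 1), and partitioned into two clusters — "Mild" and
"Severe" — by Ward hierarchical clustering on the retained scores.
Time-sensitive variables (age, T2D duration) carry each patient's
baseline value in every row, so a patient cannot drift toward "Severe"
merely because time passed.

The fitted model stores the standardization constants, loadings and
cluster centroids, and can project an independent cohort onto the same
severity space.  Trajectory labels, ADA remission status, standardized
odds ratios and covariate-adjusted group comparisons round out the
clinical analytics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SEVERITY_VARIABLES",
    "SeverityModel",
    "impute_median",
    "build_feature_matrix",
    "fit_severity_model",
    "project",
    "assign_trajectories",
    "classify_dr",
    "standardized_or",
    "fold_change",
    "compare_groups",
    "dunn_test",
]

#: The seven clustering variables, in canonical column order.
SEVERITY_VARIABLES = [
    "hba1c",
    "fbg",
    "t2d_duration",
    "age",
    "sex",
    "n_glucose_drugs",
    "insulin_use",
]

TIMEPOINTS = ["baseline", "1y", "5y"]

#: Variables frozen at their baseline value for every time point.
TIME_SENSITIVE = ["t2d_duration", "age"]

_BINARY_VARIABLES = {"sex", "insulin_use"}


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def impute_median(records: pd.DataFrame) -> pd.DataFrame:
    """Impute missing cells: numeric columns by the median (midpoint of the
    two central values for even counts), categorical columns by the mode.

    Raises ``ValueError`` naming any column that is entirely missing.
    """
    out = records.copy()
    skip = {"patient_id", "timepoint"}
    for col in out.columns:
        if col in skip:
            continue
        series = out[col]
        mask = series.isna()
        if not mask.any():
            continue
        non_missing = series[~mask]
        if len(non_missing) == 0:
            raise ValueError(f"variable {col!r} has no non-missing values to impute from")
        if pd.api.types.is_numeric_dtype(non_missing) and not pd.api.types.is_bool_dtype(non_missing):
            fill = float(np.median(non_missing.to_numpy(dtype=float)))
        else:
            fill = non_missing.mode().iloc[0]
        out.loc[mask, col] = fill
    return out


# ---------------------------------------------------------------------------
# feature matrix
# ---------------------------------------------------------------------------

def _encode(records: pd.DataFrame) -> pd.DataFrame:
    df = records.copy()
    if "sex" in df.columns:
        if df["sex"].dtype == object:
            df["sex"] = df["sex"].map({"F": 0, "M": 1})
        df["sex"] = df["sex"].astype(float)
    if "insulin_use" in df.columns:
        df["insulin_use"] = df["insulin_use"].astype(float)
    return df


def build_feature_matrix(records: pd.DataFrame, standardize: bool = True) -> pd.DataFrame:
    """Stack patient-by-timepoint rows into the 7-column clustering matrix.

    Age and T2D duration are replaced, at every time point, by the
    patient's baseline value.  Sex is encoded F=0/M=1 and insulin use
    0/1.  Columns are standardized to mean 0, sd 1 over the stacked rows
    (sample sd, ``ddof=1``); standardization can be disabled for callers
    that standardize with stored model constants instead.

    The index of the result is a (patient_id, timepoint) MultiIndex.
    """
    df = _encode(records)
    missing_cols = [c for c in SEVERITY_VARIABLES if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing clustering variables: {missing_cols}")

    baseline = df[df["timepoint"] == "baseline"].set_index("patient_id")
    patients = df["patient_id"].unique()
    absent = [p for p in patients if p not in baseline.index]
    if absent:
        raise ValueError(f"patients without a baseline row: {absent[:5]}")

    df = df.set_index(["patient_id", "timepoint"])
    for col in TIME_SENSITIVE:
        df[col] = baseline[col].reindex(df.index.get_level_values("patient_id")).to_numpy()

    X = df[SEVERITY_VARIABLES].astype(float)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"missing values remain in {bad}; impute first")
    if standardize:
        sds = X.std(ddof=1)
        zero = sds[sds == 0].index.tolist()
        if zero:
            raise ValueError(f"zero-variance columns: {zero}")
        X = (X - X.mean()) / sds
    return X


# ---------------------------------------------------------------------------
# PCA + clustering
# ---------------------------------------------------------------------------

def pca_correlation(X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decomposition of the correlation matrix of ``X``.

    Returns (eigenvalues, loadings) sorted by decreasing eigenvalue.
    Loadings columns carry a deterministic sign (largest-magnitude
    element positive).
    """
    Z = np.asarray(X, dtype=float)
    R = np.corrcoef(Z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(R)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    for j in range(eigvecs.shape[1]):
        k = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[k, j] < 0:
            eigvecs[:, j] *= -1
    return eigvals, eigvecs


@dataclass
class SeverityModel:
    """Fitted severity model: standardization constants, PCA loadings,
    retained components, Ward tree, cluster labels and centroids."""

    variables: list[str]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray           # p x p eigenvector matrix
    eigenvalues: np.ndarray
    n_retained: int
    linkage_tree: np.ndarray
    labels: pd.Series              # "Mild"/"Severe" per training row
    centroids: dict[str, np.ndarray] = field(default_factory=dict)
    scores: pd.DataFrame | None = None

    def to_json(self, path=None) -> str:
        payload = {
            "variables": self.variables,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "n_retained": self.n_retained,
            "centroids": {k: v.tolist() for k, v in self.centroids.items()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "SeverityModel":
        d = json.loads(text)
        return cls(
            variables=d["variables"],
            means=np.array(d["means"]),
            sds=np.array(d["sds"]),
            loadings=np.array(d["loadings"]),
            eigenvalues=np.array(d["eigenvalues"]),
            n_retained=d["n_retained"],
            linkage_tree=np.empty((0, 4)),
            labels=pd.Series(dtype=object),
            centroids={k: np.array(v) for k, v in d["centroids"].items()},
        )


def _consolidate(scores: np.ndarray, labels: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """Deterministic centroid consolidation (k-means with the Ward cut as
    initialization).  Guarantees every training row lies nearest its own
    cluster centroid, so projecting a training row reproduces its label."""
    labels = labels.copy()
    for _ in range(max_iter):
        centroids = np.stack([scores[labels == k].mean(axis=0) for k in (0, 1)])
        dist = np.linalg.norm(scores[:, None, :] - centroids[None, :, :], axis=2)
        new = np.argmin(dist, axis=1)
        if (new == labels).all():
            break
        if len(np.unique(new)) < 2:   # refuse to collapse a cluster
            break
        labels = new
    return labels


def fit_severity_model(features: pd.DataFrame) -> SeverityModel:
    """Fit the severity model on a standardized feature matrix.

    Correlation-matrix PCA, Kaiser-Guttman retention (eigenvalue >= 1),
    Ward linkage on the retained scores, tree cut at k=2, then a
    deterministic centroid-consolidation pass.  The cluster with the
    higher mean standardized HbA1C is labelled "Severe".
    """
    if len(features) < 8:
        raise ValueError("need at least 8 rows to fit the severity model")
    X = features.astype(float)
    sds_s = X.std(ddof=1)
    dead = sds_s.index[sds_s == 0].tolist()
    if dead:
        # a constant column carries no clustering information
        warnings.warn(f"zero-variance columns dropped from the PCA: {dead}")
        X = X.drop(columns=dead)
        if "hba1c" in dead or X.shape[1] < 2:
            raise ValueError("unlabelable: too little variance to cluster")
    means = X.mean().to_numpy()
    sds = X.std(ddof=1).to_numpy()
    Z = (X - X.mean()) / X.std(ddof=1)

    eigvals, loadings = pca_correlation(Z)
    n_retained = int(np.sum(eigvals >= 1.0))
    if n_retained < 2:
        warnings.warn("fewer than 2 components with eigenvalue >= 1; proceeding with 1")
        n_retained = max(n_retained, 1)

    scores_all = Z.to_numpy() @ loadings
    scores = scores_all[:, :n_retained]
    tree = linkage(scores, method="ward")
    cut = fcluster(tree, t=2, criterion="maxclust") - 1
    if len(np.unique(cut)) < 2:
        raise ValueError("tree cut produced an empty cluster")
    cut = _consolidate(scores, cut)

    hba1c_std = Z["hba1c"].to_numpy()
    mean0, mean1 = hba1c_std[cut == 0].mean(), hba1c_std[cut == 1].mean()
    if abs(mean0 - mean1) < 1e-8:
        raise ValueError("unlabelable: both clusters have the same mean HbA1C")
    severe = 0 if mean0 > mean1 else 1
    names = np.where(cut == severe, "Severe", "Mild")

    centroids = {
        "Mild": scores[names == "Mild"].mean(axis=0),
        "Severe": scores[names == "Severe"].mean(axis=0),
    }
    return SeverityModel(
        variables=list(X.columns),
        means=means,
        sds=sds,
        loadings=loadings,
        eigenvalues=eigvals,
        n_retained=n_retained,
        linkage_tree=tree,
        labels=pd.Series(names, index=features.index, name="cluster"),
        centroids=centroids,
        scores=pd.DataFrame(scores, index=features.index,
                            columns=[f"PC{i+1}" for i in range(n_retained)]),
    )


def project(model: SeverityModel, features: pd.DataFrame) -> pd.Series:
    """Assign new rows to severity clusters using the fitted model.

    Rows are standardized with the model's stored means/sds, multiplied
    by the stored loadings, and assigned to the nearer cluster centroid
    (Euclidean distance in retained-component space).  ``features`` must
    be an **unstandardized** matrix with the model's variables (use
    ``build_feature_matrix(records, standardize=False)``).
    """
    missing = [v for v in model.variables if v not in features.columns]
    if missing:
        raise ValueError(f"missing variables for projection: {missing}")
    X = features[model.variables].astype(float)
    if X.isna().any().any():
        raise ValueError("missing values in projection input; impute first")
    Z = (X.to_numpy() - model.means) / model.sds
    scores = Z @ model.loadings[:, : model.n_retained]
    names = sorted(model.centroids)
    cents = np.stack([model.centroids[k] for k in names])
    dist = np.linalg.norm(scores[:, None, :] - cents[None, :, :], axis=2)
    idx = np.argmin(dist, axis=1)
    return pd.Series([names[i] for i in idx], index=features.index, name="cluster")


# ---------------------------------------------------------------------------
# trajectories & remission
# ---------------------------------------------------------------------------

def assign_trajectories(baseline: pd.Series, five_year: pd.Series) -> pd.Series:
    """Trajectory label per patient from (baseline cluster, 5-year cluster).

    (Mild, Mild) -> Stable-Mild; (Severe, Mild) -> 5y-Rep+ (good
    responders); (Severe, Severe) -> 5y-Rep- (poor responders);
    (Mild, Severe) -> Other.
    """
    patients = baseline.index
    if five_year.isna().any() or baseline.isna().any():
        raise ValueError("missing cluster assignment")
    missing = [p for p in patients if p not in five_year.index]
    if missing:
        raise ValueError(f"patients without a 5y assignment: {missing[:5]}")
    mapping = {
        ("Mild", "Mild"): "Stable-Mild",
        ("Severe", "Mild"): "5y-Rep+",
        ("Severe", "Severe"): "5y-Rep-",
        ("Mild", "Severe"): "Other",
    }
    out = {p: mapping[(baseline[p], five_year[p])] for p in patients}
    return pd.Series(out, name="trajectory")


def classify_dr(record: pd.Series | pd.DataFrame):
    """ADA diabetes-remission status at 5 years.

    DR iff HbA1C < 6.5 %, fasting glucose < 7 mmol/L, and no
    glucose-lowering medication (zero drugs, no insulin); strict
    inequalities.
    """
    if isinstance(record, pd.DataFrame):
        return record.apply(classify_dr, axis=1).rename("dr_status")
    needed = ["hba1c", "fbg", "n_glucose_drugs", "insulin_use"]
    if any(pd.isna(record.get(k)) for k in needed):
        raise ValueError("missing fields for remission classification")
    ok = (
        record["hba1c"] < 6.5
        and record["fbg"] < 7.0
        and record["n_glucose_drugs"] == 0
        and not bool(record["insulin_use"])
    )
    return "DR" if ok else "non-DR"


# ---------------------------------------------------------------------------
# standardized odds ratios
# ---------------------------------------------------------------------------

@dataclass
class OrResult:
    variable: str
    odds_ratio: float | None        # None when inestimable
    ci_low: float | None
    ci_high: float | None
    separation_flag: bool


def standardized_or(records: pd.DataFrame, labels: pd.Series,
                    variables: list[str] | None = None) -> list[OrResult]:
    """Univariate standardized odds ratios for Severe-cluster membership.

    Per variable, a logistic model of cluster (Severe=1) on the variable:
    continuous variables are standardized (OR per 1 sd), binary 0/1
    variables enter as-is.  Wald 95 % CIs.  Perfect separation (divergent
    coefficient, |beta| > 10, or non-convergence) yields a sentinel OR
    with ``separation_flag`` set.
    """
    import statsmodels.api as sm

    if variables is None:
        variables = [v for v in SEVERITY_VARIABLES if v != "sex"]
    df = _encode(records.copy()) if "sex" in records.columns else records.copy()
    y = labels.map({"Mild": 0, "Severe": 1}).to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both clusters must be present")

    out: list[OrResult] = []
    for var in variables:
        x = df[var].astype(float).to_numpy()
        uniq = np.unique(x)
        if not (len(uniq) <= 2 and set(uniq) <= {0.0, 1.0}):
            sd = x.std(ddof=1)
            if sd == 0:
                out.append(OrResult(var, None, None, None, False))
                continue
            x = (x - x.mean()) / sd
        X = sm.add_constant(x)
        sep = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, X).fit(disp=0, maxiter=100, method="bfgs")
            beta = res.params[1]
            if not res.mle_retvals.get("converged", True) or abs(beta) > 10:
                sep = True
        except Exception:
            sep = True
        if sep:
            out.append(OrResult(var, None, None, None, True))
        else:
            lo, hi = res.conf_int()[1]
            out.append(OrResult(var, float(np.exp(beta)),
                                float(np.exp(lo)), float(np.exp(hi)), False))
    return out


# ---------------------------------------------------------------------------
# misc clinical statistics
# ---------------------------------------------------------------------------

def fold_change(v_x: float, v_x1: float) -> float:
    """Relative change between consecutive time points: (Tx+1 - Tx)/Tx."""
    if v_x == 0:
        raise ValueError("fold change undefined for a zero reference value")
    return (v_x1 - v_x) / v_x


def dunn_test(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Dunn's rank-based pairwise comparisons after a Kruskal-Wallis layout.

    Returns one row per group pair with the z statistic and two-sided
    normal p-value (tie-corrected pooled variance); BH-adjusted q across
    the pairs.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ranks = stats.rankdata(values)
    n = len(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12 * (n - 1))
    var_base = n * (n + 1) / 12 - tie_term
    labels = np.unique(groups)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            na, nb = (groups == a).sum(), (groups == b).sum()
            z = (ranks[groups == a].mean() - ranks[groups == b].mean()) / np.sqrt(
                var_base * (1 / na + 1 / nb))
            p = 2 * stats.norm.sf(abs(z))
            rows.append({"group_a": a, "group_b": b, "z": z, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def compare_groups(records: pd.DataFrame, group_col: str,
                   variables: list[str],
                   covariates: tuple[str, ...] = ("age", "sex")) -> pd.DataFrame:
    """Per-variable group comparisons adjusted for age and sex.

    Continuous variables: OLS of the variable on group + covariates,
    F-test of the group term.  Binary/categorical variables: logistic
    model with the covariates, likelihood-ratio test of the group term.
    p-values are BH-adjusted within the variable family.  Constant
    covariates are dropped with a warning.
    """
    import statsmodels.api as sm

    df = _encode(records.copy()) if "sex" in records.columns else records.copy()
    groups = pd.get_dummies(df[group_col], drop_first=True).astype(float)
    covs = []
    for c in covariates:
        if c in df.columns:
            col = df[c].astype(float)
            if col.nunique() <= 1:
                warnings.warn(f"covariate {c!r} is constant; dropped")
            else:
                covs.append(col)
    C = pd.concat(covs, axis=1) if covs else pd.DataFrame(index=df.index)

    rows = []
    for var in variables:
        y = df[var].astype(float)
        mask = y.notna()
        yv = y[mask]
        G = groups[mask]
        Cv = C.loc[mask] if len(C.columns) else None
        binary = set(np.unique(yv)) <= {0.0, 1.0}
        X_full = pd.concat([G] + ([Cv] if Cv is not None else []), axis=1)
        X_full = sm.add_constant(X_full.to_numpy(dtype=float))
        X_red = (sm.add_constant(Cv.to_numpy(dtype=float))
                 if Cv is not None and len(Cv.columns)
                 else np.ones((mask.sum(), 1)))
        try:
            if binary:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    full = sm.Logit(yv.to_numpy(), X_full).fit(disp=0, maxiter=200, method="bfgs")
                    red = sm.Logit(yv.to_numpy(), X_red).fit(disp=0, maxiter=200, method="bfgs")
                lr = 2 * (full.llf - red.llf)
                p = float(stats.chi2.sf(max(lr, 0.0), df=G.shape[1]))
            else:
                full = sm.OLS(yv.to_numpy(), X_full).fit()
                red = sm.OLS(yv.to_numpy(), X_red).fit()
                p = float(full.compare_f_test(red)[1])
        except Exception:
            p = float("nan")
        rows.append({"variable": var, "p": p if np.isfinite(p) else 1.0})
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
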