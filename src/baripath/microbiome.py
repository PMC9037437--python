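"""Count-matrix statistics: rarefaction, filtering, diversity, ordination
and differential abundance.

Conventions follow the study design the package targets: samples are
rarefied without replacement to a fixed depth with a fixed seed
(default 711), taxa detected in fewer than 20 % of samples are dropped,
relative abundances are taken over the retained taxa, and a second
filter keeps taxa whose mean relative abundance is at least 0.1 %.
Group effects are quantified with Cliff's delta (positive = enriched in
the first group, conventionally "Severe") alongside Welch t-test
p-values, BH-adjusted across taxa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "EffectSizeResult",
    "OrdinationResult",
    "rarefy",
    "filter_prevalence",
    "relative_abundance",
    "filter_mean_abundance",
    "aggregate_rank",
    "alpha_diversity",
    "bray_curtis",
    "pcoa",
    "dbrda_univariate",
    "fit_vectors",
    "cliffs_delta",
    "differential_abundance",
    "rosner_outliers",
    "correlate_clinical",
]

RANKS = ("class", "genus", "species")


@dataclass
class CountMatrix:
    """Taxa-by-samples integer counts with lineage and sample metadata.

    ``counts``: DataFrame, rows = taxa, columns = samples.
    ``lineage``: DataFrame indexed by taxon with class/genus/species.
    ``samples``: DataFrame indexed by sample id (group labels, covariates).
    """

    counts: pd.DataFrame
    lineage: pd.DataFrame
    samples: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        missing = self.counts.index.difference(self.lineage.index)
        if len(missing):
            raise ValueError(f"lineage missing for taxa: {list(missing[:5])}")

    @property
    def taxa(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_taxa(self, taxa) -> "CountMatrix":
        return CountMatrix(self.counts.loc[taxa], self.lineage.loc[taxa], self.samples)

    def subset_samples(self, sample_ids) -> "CountMatrix":
        samples = self.samples.loc[sample_ids] if len(self.samples) else self.samples
        return CountMatrix(self.counts[list(sample_ids)], self.lineage, samples)

    def to_tsv(self, counts_path, lineage_path=None, samples_path=None) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="taxon_id")
        if lineage_path is not None:
            self.lineage.to_csv(lineage_path, sep="\t", index_label="taxon_id")
        if samples_path is not None and len(self.samples):
            self.samples.to_csv(samples_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, counts_path, lineage_path, samples_path=None) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="taxon_id")
        lineage = pd.read_csv(lineage_path, sep="\t", index_col="taxon_id")
        samples = (pd.read_csv(samples_path, sep="\t", index_col="sample_id")
                   if samples_path is not None else pd.DataFrame())
        return cls(counts, lineage, samples)


# ---------------------------------------------------------------------------
# rarefaction and filters
# ---------------------------------------------------------------------------

def rarefy(cm: CountMatrix, depth: int, seed: int = 711) -> CountMatrix:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    One multivariate-hypergeometric draw per sample from a single
    generator seeded with ``seed``; the same seed always reproduces the
    same matrix.  Samples below ``depth`` raise an error naming them.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    totals = cm.counts.sum(axis=0)
    low = totals[totals < depth]
    if len(low):
        raise ValueError(f"samples below rarefaction depth {depth}: {list(low.index)}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(cm.counts.to_numpy(dtype=np.int64))
    arr = cm.counts.to_numpy(dtype=np.int64)
    for j in range(arr.shape[1]):
        out[:, j] = rng.multivariate_hypergeometric(arr[:, j], depth)
    counts = pd.DataFrame(out, index=cm.counts.index, columns=cm.counts.columns)
    return CountMatrix(counts, cm.lineage, cm.samples)


def filter_prevalence(cm: CountMatrix, min_prev: float = 0.20) -> CountMatrix:
    """Drop taxa detected (count > 0) in fewer than ``min_prev`` of samples.

    Boundary is inclusive: a taxon present in exactly ``min_prev * n``
    samples is kept.
    """
    n = cm.counts.shape[1]
    prevalence = (cm.counts > 0).sum(axis=1)
    keep = prevalence >= min_prev * n
    if not keep.any():
        raise ValueError("prevalence filter removed every taxon")
    return cm.subset_taxa(cm.taxa[keep])


def relative_abundance(cm: CountMatrix) -> pd.DataFrame:
    """Per-sample proportions over the retained taxa (columns sum to 1)."""
    totals = cm.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero samples: {list(zero.index)}")
    return cm.counts / totals


def filter_mean_abundance(rel_abund: pd.DataFrame, min_mean: float = 0.001) -> pd.Index:
    """Taxa whose mean relative abundance across samples is >= ``min_mean``."""
    return rel_abund.index[rel_abund.mean(axis=1) >= min_mean]


def aggregate_rank(cm: CountMatrix, rank: str) -> CountMatrix:
    """Sum counts over taxa sharing the same lineage label at ``rank``."""
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    labels = cm.lineage.loc[cm.taxa, rank]
    agg = cm.counts.groupby(labels).sum()
    agg.index.name = "taxon_id"
    lineage = pd.DataFrame(index=agg.index, columns=list(RANKS))
    lineage[rank] = agg.index
    # ranks above the aggregation level are kept when unambiguous
    for higher in RANKS[: RANKS.index(rank)]:
        mapping = cm.lineage.groupby(labels)[higher].agg(
            lambda s: s.iloc[0] if s.nunique() == 1 else "")
        lineage[higher] = mapping
    return CountMatrix(agg, lineage.fillna(""), cm.samples)


# ---------------------------------------------------------------------------
# diversity & dissimilarity
# ---------------------------------------------------------------------------

def alpha_diversity(cm: CountMatrix) -> pd.DataFrame:
    """Observed taxa, Shannon (natural log) and Simpson (1 - sum p^2)."""
    totals = cm.counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("zero-total sample")
    p = cm.counts / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(p > 0, np.log(p.where(p > 0, 1.0)), 0.0)
    shannon = -(p.to_numpy() * logp).sum(axis=0)
    simpson = 1.0 - (p.to_numpy() ** 2).sum(axis=0)
    observed = (cm.counts > 0).sum(axis=0)
    return pd.DataFrame(
        {"observed": observed, "shannon": shannon, "simpson": simpson},
        index=cm.sample_ids,
    )


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between samples (columns of ``table``)."""
    X = table.to_numpy(dtype=float).T
    if (X < 0).any():
        raise ValueError("negative entries")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    D = squareform(pdist(X, metric="braycurtis"))
    return pd.DataFrame(D, index=table.columns, columns=table.columns)


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame       # samples x positive axes, scaled sqrt(eig)
    eigenvalues: np.ndarray         # all eigenvalues, non-increasing
    proportion_explained: np.ndarray  # per positive axis, denominator = sum of positives


def pcoa(D: pd.DataFrame) -> OrdinationResult:
    """Principal-coordinates analysis of a dissimilarity matrix.

    Gower double-centering of -0.5 * D^2 followed by eigen-decomposition.
    Coordinates are returned for positive eigenvalues only; negative
    eigenvalues are reported but excluded from the proportion-explained
    denominator.
    """
    A = D.to_numpy(dtype=float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(A), 0, atol=1e-10):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    n = A.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (A**2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-10
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    for j in range(coords.shape[1]):       # deterministic axis orientation
        k = np.argmax(np.abs(coords[:, j]))
        if coords[k, j] < 0:
            coords[:, j] *= -1
    prop = eigvals[pos] / eigvals[pos].sum()
    cols = [f"PCo{i+1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=D.index, columns=cols),
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


def _dbrda_r2(Y: np.ndarray, x: np.ndarray, total: float) -> float:
    xc = x - x.mean()
    fitted = (Y.T @ xc) ** 2 / (xc @ xc)
    return float(fitted.sum() / total)


def dbrda_univariate(D: pd.DataFrame, variable: pd.Series | np.ndarray,
                     n_perm: int = 999, seed: int = 711) -> dict:
    """Distance-based redundancy analysis with a single predictor.

    The positive-eigenvalue PCoA axes are regressed on the (centered)
    predictor; R^2 = constrained inertia / total positive inertia,
    adjusted by Ezekiel's formula, and reported in percent.  The p-value
    comes from free permutations of the predictor.
    """
    x = np.asarray(variable, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 samples")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    ord_res = pcoa(D)
    Y = ord_res.coordinates.to_numpy()
    total = ord_res.eigenvalues[ord_res.eigenvalues > 0].sum()

    r2 = _dbrda_r2(Y, x, total)
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(x) for _ in range(n_perm)], axis=1)
    Pc = perms - perms.mean(axis=0)
    ss = (Pc**2).sum(axis=0)
    r2_perm = ((Y.T @ Pc) ** 2).sum(axis=0) / ss / total
    p = (1 + np.sum(r2_perm >= r2)) / (1 + n_perm)
    r2_adj = 1 - (1 - r2) * (n - 1) / (n - 2)
    return {"r2": r2, "r2_adj_pct": 100 * r2_adj, "p": float(p)}


def fit_vectors(ordination: OrdinationResult, rel_abund: pd.DataFrame,
                n_perm: int = 999, seed: int = 711,
                r2_threshold: float = 0.5) -> pd.DataFrame:
    """Fit taxon abundances onto the first two ordination axes.

    Per taxon: least-squares direction, squared multiple correlation R^2,
    permutation p-value, and a flag for R^2 above the threshold.
    Zero-variance taxa are skipped with a warning.
    """
    Y = ordination.coordinates.to_numpy()[:, :2]
    Yc = Y - Y.mean(axis=0)
    G = np.linalg.pinv(Yc.T @ Yc)
    rng = np.random.default_rng(seed)
    rows = []
    for taxon in rel_abund.index:
        v = rel_abund.loc[taxon].to_numpy(dtype=float)
        vc = v - v.mean()
        ss = vc @ vc
        if ss == 0:
            warnings.warn(f"zero-variance taxon {taxon!r} skipped")
            continue
        beta = G @ (Yc.T @ vc)
        r2 = float((beta @ (Yc.T @ vc)) / ss)
        perm_r2 = np.empty(n_perm)
        for i in range(n_perm):
            vp = rng.permutation(vc)
            bp = G @ (Yc.T @ vp)
            perm_r2[i] = (bp @ (Yc.T @ vp)) / ss
        p = (1 + np.sum(perm_r2 >= r2)) / (1 + n_perm)
        norm = np.linalg.norm(beta)
        direction = beta / norm if norm > 0 else beta
        rows.append({"taxon": taxon, "dx": direction[0], "dy": direction[1],
                     "r2": r2, "p": float(p), "flagged": r2 > r2_threshold})
    if not rows:
        return pd.DataFrame(columns=["dx", "dy", "r2", "p", "flagged"]
                            ).rename_axis("taxon")
    return pd.DataFrame(rows).set_index("taxon")


# ---------------------------------------------------------------------------
# effect sizes and differential abundance
# ---------------------------------------------------------------------------

@dataclass
class EffectSizeResult:
    taxon: str
    delta: float
    ci_low: float
    ci_high: float
    p_welch: float
    q: float | None = None


def cliffs_delta(group_a, group_b, alpha: float = 0.05) -> EffectSizeResult:
    """Cliff's delta of ``group_a`` versus ``group_b`` with an asymptotic CI.

    delta = [#(a > b) - #(a < b)] / (n_a * n_b) over all pairs; positive
    values mean ``group_a`` (conventionally the Severe group) is
    enriched.  The confidence interval uses Cliff's consistent variance
    estimate with the asymmetric (Fisher-z-like) transform, so bounds
    stay inside [-1, 1].  A Welch two-sample t-test p-value is computed
    alongside.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    dij = np.sign(a[:, None] - b[None, :])
    d = dij.mean()
    n1, n2 = len(a), len(b)
    if n1 > 1 and n2 > 1:
        di = dij.mean(axis=1)
        dj = dij.mean(axis=0)
        s2 = (n2**2 * np.sum((di - d) ** 2) + n1**2 * np.sum((dj - d) ** 2)
              - np.sum((dij - d) ** 2)) / (n1 * n2 * (n1 - 1) * (n2 - 1))
        s2 = max(s2, 0.0)
        z = stats.norm.ppf(1 - alpha / 2)
        if s2 == 0:
            lo = hi = d
        else:
            # asymmetric interval: (d - d^3 -/+ z*s*sqrt(1 - 2d^2 + d^4 + z^2 s^2))
            #                      / (1 - d^2 + z^2 s^2)
            zs = z**2 * s2
            denom = 1 - d**2 + zs
            half = z * np.sqrt(s2) * np.sqrt(1 - 2 * d**2 + d**4 + zs)
            lo = (d - d**3 - half) / denom
            hi = (d - d**3 + half) / denom
        lo, hi = max(lo, -1.0), min(hi, 1.0)
    else:
        lo, hi = -1.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = stats.ttest_ind(a, b, equal_var=False).pvalue
    if not np.isfinite(p):
        p = 1.0
    return EffectSizeResult("", float(d), float(lo), float(hi), float(p))


def _cliffs_delta_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Vectorized Cliff's delta per row (taxa) of two group matrices."""
    sign = np.sign(A[:, :, None] - B[:, None, :])
    return sign.mean(axis=(1, 2))


def _van_elteren(a_by_stratum, b_by_stratum) -> float:
    """Stratified rank test (van Elteren): combine per-stratum
    Wilcoxon statistics weighted by 1/(n_s + 1); normal p-value."""
    num, var = 0.0, 0.0
    for a, b in zip(a_by_stratum, b_by_stratum):
        n1, n2 = len(a), len(b)
        if n1 == 0 or n2 == 0:
            continue
        ranks = stats.rankdata(np.concatenate([a, b]))
        W = ranks[:n1].sum()
        ew = n1 * (n1 + n2 + 1) / 2
        vw = n1 * n2 * (n1 + n2 + 1) / 12
        w = 1.0 / (n1 + n2 + 1)
        num += w * (W - ew)
        var += w**2 * vw
    if var == 0:
        return 1.0
    return float(2 * stats.norm.sf(abs(num) / np.sqrt(var)))


def differential_abundance(rel_abund: pd.DataFrame, groups: pd.Series,
                           group_a: str = "Severe", group_b: str = "Mild",
                           strata: pd.Series | None = None) -> pd.DataFrame:
    """Per-taxon Cliff's delta + Welch p with BH adjustment across taxa.

    Positive delta = enriched in ``group_a``.  When ``strata`` is given
    (e.g. metformin intake or cluster transition), a robustness pass
    recomputes the effect within each stratum: a taxon keeps its
    ``robust`` flag when the per-stratum delta signs agree with the
    overall sign and the stratum-combined rank test has p < 0.05.
    """
    ga = groups[groups == group_a].index
    gb = groups[groups == group_b].index
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("each group needs at least 2 samples")
    A = rel_abund[ga].to_numpy(dtype=float)
    B = rel_abund[gb].to_numpy(dtype=float)

    rows = []
    for i, taxon in enumerate(rel_abund.index):
        res = cliffs_delta(A[i], B[i])
        res.taxon = taxon
        rows.append(res)
    out = pd.DataFrame(
        {"taxon": [r.taxon for r in rows],
         "delta": [r.delta for r in rows],
         "ci_low": [r.ci_low for r in rows],
         "ci_high": [r.ci_high for r in rows],
         "p_welch": [r.p_welch for r in rows]}
    ).set_index("taxon")
    out["q"] = multipletests(out["p_welch"], method="fdr_bh")[1]

    if strata is not None:
        robust = []
        for taxon in out.index:
            sign0 = np.sign(out.loc[taxon, "delta"])
            ok = True
            a_s, b_s = [], []
            for level in strata.unique():
                sa = [s for s in ga if strata[s] == level]
                sb = [s for s in gb if strata[s] == level]
                if len(sa) < 2 or len(sb) < 2:
                    continue
                av = rel_abund.loc[taxon, sa].to_numpy(dtype=float)
                bv = rel_abund.loc[taxon, sb].to_numpy(dtype=float)
                a_s.append(av)
                b_s.append(bv)
                d = cliffs_delta(av, bv).delta
                if sign0 != 0 and d * sign0 < 0:
                    ok = False
            p_strat = _van_elteren(a_s, b_s) if a_s else 1.0
            robust.append(ok and p_strat < 0.05)
        out["robust"] = robust
    return out


# ---------------------------------------------------------------------------
# outliers & correlations
# ---------------------------------------------------------------------------

def rosner_outliers(values, k: int = 5, alpha: float = 0.001) -> list[int]:
    """Generalized ESD (Rosner) test for up to ``k`` outliers.

    Iteratively removes the most extreme point and compares the
    studentized extreme against the lambda_i critical value; returns the
    indices (into ``values``) of the flagged outliers — the largest i
    with a significant statistic, plus all more-extreme points.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if k >= n - 2:
        raise ValueError("k must be smaller than n - 2")
    if np.std(x, ddof=1) == 0:
        raise ValueError("zero standard deviation")
    remaining = list(range(n))
    removed: list[int] = []
    stats_r = []
    for i in range(1, k + 1):
        sub = x[remaining]
        mean, sd = sub.mean(), sub.std(ddof=1)
        if sd == 0:
            break
        devs = np.abs(sub - mean)
        j = int(np.argmax(devs))
        R = devs[j] / sd
        ni = len(sub)
        pcrit = 1 - alpha / (2 * ni)
        t = stats.t.ppf(pcrit, ni - 2)
        lam = (ni - 1) * t / np.sqrt((ni - 2 + t**2) * ni)
        stats_r.append((R, lam))
        removed.append(remaining.pop(j))
    n_out = 0
    for i, (R, lam) in enumerate(stats_r, start=1):
        if R > lam:
            n_out = i
    return removed[:n_out]


def correlate_clinical(rel_abund: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlations between taxa (rows) and clinical variables.

    Returns a long table (taxon, variable, rho, p, q) with BH adjustment
    across the whole grid and two significance tiers (p < .05, q < 0.1).
    Constant variables yield missing rho.
    """
    samples = [s for s in rel_abund.columns if s in clinical.index]
    rows = []
    for taxon in rel_abund.index:
        x = rel_abund.loc[taxon, samples].to_numpy(dtype=float)
        for var in clinical.columns:
            y = clinical.loc[samples, var].to_numpy(dtype=float)
            mask = np.isfinite(x) & np.isfinite(y)
            if mask.sum() < 3 or np.ptp(y[mask]) == 0 or np.ptp(x[mask]) == 0:
                rows.append({"taxon": taxon, "variable": var,
                             "rho": np.nan, "p": np.nan})
                continue
            rho, p = stats.spearmanr(x[mask], y[mask])
            rows.append({"taxon": taxon, "variable": var, "rho": rho, "p": p})
    out = pd.DataFrame(rows)
    valid = out["p"].notna()
    out["q"] = np.nan
    if valid.any():
        out.loc[valid, "q"] = multipletests(out.loc[valid, "p"], method="fdr_bh")[1]
    out["sig_p05"] = out["p"] < 0.05
    out["sig_q10"] = out["q"] < 0.10
    return out
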