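"""Fecal-matter-transplant analytics.

Quantifies donor-to-recipient engraftment (shared detected species over
donor detected species, both rarefied at the same depth and seed),
collapses the four animals per donor into one donor-level value by
geometric mean to avoid pseudoreplication, and computes the murine
metabolic phenotype statistics: OGTT area under the curve (trapezoidal,
baseline area below the minimum subtracted), HOMA-IR and QUICKI insulin
resistance/sensitivity indexes, and intestinal energy absorption.
Inference runs on the 13 donor-level values by default; animal-level
results are descriptive only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .microbiome import CountMatrix, differential_abundance, rarefy

__all__ = [
    "EngraftmentResult",
    "engraftment_fraction",
    "engraftment_table",
    "collapse_pseudoreplicates",
    "ogtt_auc",
    "homa_ir",
    "quicki",
    "energy_balance",
    "group_phenotype_tests",
    "recipient_differential",
]

#: Default rarefaction depths: donor-vs-recipient comparisons and
#: within-animal comparisons.
DONOR_RECIPIENT_DEPTH = 65_000
WITHIN_ANIMAL_DEPTH = 113_000


@dataclass
class EngraftmentResult:
    donor_id: str
    recipient_id: str
    shared_species: int
    donor_species: int
    fraction: float


def _detected(counts: pd.Series, min_reads: int = 1) -> set:
    return set(counts.index[counts >= min_reads])


def engraftment_fraction(donor: pd.Series, recipient: pd.Series,
                         depth: int = DONOR_RECIPIENT_DEPTH, seed: int = 711,
                         min_reads: int = 1,
                         donor_id: str = "donor", recipient_id: str = "recipient",
                         lineage: pd.DataFrame | None = None) -> EngraftmentResult:
    """Share of the donor's detected species also detected in the recipient.

    Donor and recipient are rarefied independently at the same depth and
    seed; a species is "detected" at >= ``min_reads`` rarefied reads.
    """
    if lineage is None:
        lineage = pd.DataFrame(index=donor.index.union(recipient.index),
                               columns=["class", "genus", "species"]).fillna("")
    d_cm = rarefy(CountMatrix(donor.to_frame(donor_id), lineage), depth, seed)
    r_cm = rarefy(CountMatrix(recipient.to_frame(recipient_id), lineage), depth, seed)
    donor_set = _detected(d_cm.counts[donor_id], min_reads)
    if not donor_set:
        raise ValueError("donor species set is empty")
    recip_set = _detected(r_cm.counts[recipient_id], min_reads)
    shared = donor_set & recip_set
    return EngraftmentResult(donor_id, recipient_id, len(shared), len(donor_set),
                             len(shared) / len(donor_set))


def engraftment_table(donors: CountMatrix, recipients: CountMatrix,
                      manifest: pd.DataFrame,
                      depth: int = DONOR_RECIPIENT_DEPTH, seed: int = 711,
                      min_reads: int = 1) -> pd.DataFrame:
    """Engraftment fraction for every animal in the manifest.

    Donor and recipient matrices are rarefied once each (same depth and
    seed) before the per-pair presence/absence comparison.
    """
    shared_taxa = donors.taxa.union(recipients.taxa)

    def expand(cm: CountMatrix) -> pd.DataFrame:
        return cm.counts.reindex(shared_taxa, fill_value=0)

    lineage = pd.DataFrame(index=shared_taxa, columns=["class", "genus", "species"]).fillna("")
    d_r = rarefy(CountMatrix(expand(donors), lineage), depth, seed)
    r_r = rarefy(CountMatrix(expand(recipients), lineage), depth, seed)
    rows = []
    for _, rec in manifest.iterrows():
        donor, animal = rec["donor_id"], rec["animal_id"]
        donor_set = _detected(d_r.counts[donor], min_reads)
        if not donor_set:
            raise ValueError(f"donor {donor!r} has an empty species set")
        recip_set = _detected(r_r.counts[animal], min_reads)
        shared = donor_set & recip_set
        rows.append({"donor_id": donor, "animal_id": animal,
                     "donor_cluster": rec.get("donor_cluster", ""),
                     "shared_species": len(shared),
                     "donor_species": len(donor_set),
                     "fraction": len(shared) / len(donor_set)})
    return pd.DataFrame(rows)


def collapse_pseudoreplicates(values: pd.Series, animal_to_donor: pd.Series,
                              gm_offset: float | None = None) -> pd.Series:
    """Geometric mean per donor of the per-animal values.

    Multiple animals share one donor and are not independent; collapsing
    them yields the donor-level inferential unit.  Non-positive values
    raise unless ``gm_offset`` is given, in which case the offset is
    added before and subtracted after the geometric mean (documented,
    reversible zero handling).
    """
    v = values.astype(float)
    if gm_offset is None:
        if (v <= 0).any():
            raise ValueError("non-positive values; pass gm_offset to handle them")
        offset = 0.0
    else:
        offset = float(gm_offset)
    donors = animal_to_donor.reindex(v.index)
    if donors.isna().any():
        orphans = list(v.index[donors.isna()])
        raise ValueError(f"animals without a donor mapping: {orphans[:5]}")
    logs = np.log(v + offset)
    out = np.exp(logs.groupby(donors).mean()) - offset
    return out.rename(values.name)


# ---------------------------------------------------------------------------
# phenotype formulas
# ---------------------------------------------------------------------------

def ogtt_auc(times, glucose) -> float:
    """Incremental OGTT area under the curve (mmol/L x min).

    Trapezoidal integration of glucose over [0, 90] minutes (the -30 min
    fasting sample is excluded), minus the rectangle below the smallest
    glucose value in the window — so a flat curve scores 0.
    """
    t = np.asarray(times, dtype=float)
    g = np.asarray(glucose, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    mask = t >= 0
    t, g = t[mask], g[mask]
    if len(t) < 3:
        raise ValueError("need at least 3 time points from t=0 onward")
    auc = np.trapezoid(g, t)
    return float(auc - g.min() * (t[-1] - t[0]))


def homa_ir(fbg_mg_dl: float, insulin_mU_L: float) -> float:
    """HOMA-IR = (fasting glucose (mg/dl) * 0.0555 * fasting insulin (mU/L)) / 22.5."""
    if fbg_mg_dl <= 0 or insulin_mU_L <= 0:
        raise ValueError("glucose and insulin must be positive")
    return fbg_mg_dl * 0.0555 * insulin_mU_L / 22.5


def quicki(fbg_mg_dl: float, insulin_mU_L: float, base: float = 10.0) -> float:
    """QUICKI = 1 / (log(fasting glucose (mg/dl)) + log(fasting insulin (mU/L))).

    Base-10 logarithms by default (the index's original definition);
    switchable via ``base``.
    """
    if fbg_mg_dl <= 1 or insulin_mU_L <= 1:
        raise ValueError("glucose and insulin must exceed 1 for a positive log-sum")
    denom = np.log(fbg_mg_dl) / np.log(base) + np.log(insulin_mU_L) / np.log(base)
    if denom <= 0:
        raise ValueError("non-positive log-sum")
    return float(1.0 / denom)


def energy_balance(intake_g_day: float, diet_kcal_g: float,
                   fecal_g_day: float, fecal_kcal_g: float) -> dict:
    """Daily energy excreted/absorbed and intestinal absorption percentage.

    absorption % = (ingested - excreted) / ingested x 100, i.e. the share
    of ingested energy not recovered in feces.  Excretion exceeding
    intake is a measurement artefact: warned about, value still returned.
    """
    if intake_g_day <= 0:
        raise ValueError("intake must be positive")
    ingested = intake_g_day * diet_kcal_g
    excreted = fecal_g_day * fecal_kcal_g
    if excreted > ingested:
        warnings.warn("excreted energy exceeds ingested energy (measurement artefact)")
    absorbed = ingested - excreted
    return {"kcal_excreted_day": excreted, "kcal_absorbed_day": absorbed,
            "absorption_pct": 100.0 * absorbed / ingested}


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def _two_sample_test(a: np.ndarray, b: np.ndarray, alpha_screen: float = 0.05
                     ) -> tuple[str, float]:
    """Welch t-test when both groups pass Shapiro normality and Levene
    variance homogeneity screens; Wilcoxon rank-sum otherwise."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        normal = (len(a) < 3 or stats.shapiro(a).pvalue > alpha_screen) and \
                 (len(b) < 3 or stats.shapiro(b).pvalue > alpha_screen)
        homosc = stats.levene(a, b).pvalue > alpha_screen
        if normal and homosc:
            return "welch", float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        return "wilcoxon", float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def group_phenotype_tests(donor_values: pd.DataFrame, donor_clusters: pd.Series,
                          group_a: str = "Severe", group_b: str = "Mild"
                          ) -> pd.DataFrame:
    """Per-variable two-group tests on donor-level values.

    ``donor_values``: donors x variables (already pseudoreplication-
    collapsed).  Normality/variance screens choose Welch vs Wilcoxon per
    variable; BH adjustment across the variable family.  The donor-level
    n — not the animal-level n — is the inferential unit.
    """
    ga = donor_clusters[donor_clusters == group_a].index
    gb = donor_clusters[donor_clusters == group_b].index
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("need at least 2 donors per cluster")
    rows = []
    for var in donor_values.columns:
        a = donor_values.loc[donor_values.index.intersection(ga), var].dropna().to_numpy(dtype=float)
        b = donor_values.loc[donor_values.index.intersection(gb), var].dropna().to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            continue
        if np.ptp(np.concatenate([a, b])) == 0:
            rows.append({"variable": var, "test": "none", "p": 1.0,
                         "mean_a": a.mean(), "mean_b": b.mean()})
            continue
        test, p = _two_sample_test(a, b)
        rows.append({"variable": var, "test": test, "p": p,
                     "mean_a": a.mean(), "mean_b": b.mean()})
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.set_index("variable")


def recipient_differential(rel_abund: pd.DataFrame, manifest: pd.DataFrame,
                           group_a: str = "Severe", group_b: str = "Mild",
                           gm_offset: float = 1e-6) -> pd.DataFrame:
    """Two-pass differential abundance for recipient animals.

    Animal-level Cliff's delta (descriptive) and donor-collapsed
    (geometric mean per donor, inferential) passes are both reported;
    ``agree`` marks taxa whose effect direction and q < 0.1 significance
    hold in both.
    """
    animal_groups = manifest.set_index("animal_id")["donor_cluster"]
    animal_to_donor = manifest.set_index("animal_id")["donor_id"]
    animal_pass = differential_abundance(rel_abund[animal_groups.index],
                                         animal_groups, group_a, group_b)

    donor_abund = pd.DataFrame({
        taxon: collapse_pseudoreplicates(rel_abund.loc[taxon, animal_groups.index],
                                         animal_to_donor, gm_offset=gm_offset)
        for taxon in rel_abund.index
    }).T
    donor_groups = manifest.drop_duplicates("donor_id").set_index("donor_id")["donor_cluster"]
    donor_pass = differential_abundance(donor_abund, donor_groups, group_a, group_b)

    out = animal_pass.join(donor_pass, lsuffix="_animal", rsuffix="_donor")
    out["agree"] = (
        (np.sign(out["delta_animal"]) == np.sign(out["delta_donor"]))
        & (out["q_animal"] < 0.1) & (out["q_donor"] < 0.1)
    )
    return out
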