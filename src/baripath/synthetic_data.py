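"""Synthetic study generator.

Emulates the statistical structure the downstream analytics assume, so
every stage is testable without access to the original cohort or
sequencing archives:

* a two-group (Mild/Severe) clinical cohort over 7 severity variables at
  three time points, with a fraction of baseline-Severe patients
  transitioning to Mild after surgery;
* overdispersed species count matrices (log-normal abundance
  perturbation, then one multinomial draw per sample) with a set of
  planted Severe-enriched taxa at a chosen log2 fold change;
* recipient-mouse communities derived from donor communities by partial
  Bernoulli engraftment plus a single dominant diet-contaminant taxon
  (60 % of recipient reads by default), together with severity-linked
  OGTT, insulin and energy-balance phenotype series.

All generation is bit-reproducible given the spec seed; distributional
forms and baseline levels are artifact choices meant to be realistic,
not estimates of any real population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .microbiome import CountMatrix

__all__ = [
    "CohortSpec",
    "CommunitySpec",
    "FmtSpec",
    "MouseExperiment",
    "generate_cohort",
    "generate_counts",
    "generate_fmt",
    "generate_ko_membership",
    "write_fixture_study",
]

#: Standardized Severe-minus-Mild mean gaps, in Mild-group sd units,
#: mirroring the cohort contrasts the generator emulates (HbA1C and T2D
#: duration strongest, age moderate).
DEFAULT_EFFECT_SIZES = {
    "hba1c": 2.8,
    "fbg": 1.8,
    "t2d_duration": 2.8,
    "n_glucose_drugs": 2.0,
    "insulin_use": 2.0,
    "age": 0.9,
}


@dataclass
class CohortSpec:
    """Parameters of the synthetic clinical cohort."""

    n_patients: int = 100
    prop_severe_baseline: float = 0.55
    prop_responders: float = 0.455     # 55 % -> 30 % Severe over 5 years
    effect_sizes: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_SIZES))
    missing_rate: float = 0.0
    prop_female: float = 0.80
    seed: int = 711

    def __post_init__(self):
        for name in ("prop_severe_baseline", "prop_responders", "missing_rate", "prop_female"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not all(np.isfinite(list(self.effect_sizes.values()))):
            raise ValueError("effect sizes must be finite")


@dataclass
class CommunitySpec:
    """Parameters of the synthetic species count matrix."""

    n_taxa: int = 300
    planted_taxa: list = field(default_factory=list)   # (taxon_id, log2 FC Severe/Mild)
    depth_mean: float = 50_000
    overdispersion: float = 0.8        # sd of the per-sample log-normal perturbation
    base_sigma: float = 1.5            # spread of baseline log abundances
    n_classes: int = 8
    seed: int = 711

    def __post_init__(self):
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.overdispersion <= 0:
            raise ValueError("overdispersion must be positive")


@dataclass
class FmtSpec:
    """Parameters of the synthetic FMT (donor -> mouse) experiment."""

    animals_per_donor: int = 4
    p_engraft: float = 0.6
    contaminant_fraction: float = 0.6
    contaminant_taxon: str = "contaminant_Lactococcus"
    depth_mean: float = 80_000
    # Severe-recipient phenotype shifts: OGTT peak glucose (mmol/L),
    # fasting insulin (mU/L), daily food intake (g/day).
    ogtt_peak_shift: float = 4.0
    insulin_shift: float = 6.0
    food_intake_shift: float = -0.4
    seed: int = 711

    def __post_init__(self):
        if self.animals_per_donor < 1:
            raise ValueError("animals_per_donor must be >= 1")
        if not 0 <= self.p_engraft <= 1:
            raise ValueError("p_engraft must lie in [0, 1]")
        if not 0 <= self.contaminant_fraction < 1:
            raise ValueError("contaminant_fraction must lie in [0, 1)")


@dataclass
class MouseExperiment:
    """Donor/cage/animal manifest plus longitudinal phenotype series."""

    manifest: pd.DataFrame      # animal_id, cage, donor_id, donor_cluster, treatment_group
    phenotypes: pd.DataFrame    # long: animal_id, variable, time, value

    def ogtt(self, animal_id: str) -> pd.DataFrame:
        ph = self.phenotypes
        sel = ph[(ph["animal_id"] == animal_id)
                 & ph["variable"].isin(["ogtt_glucose", "ogtt_insulin"])]
        return sel.pivot(index="time", columns="variable", values="value").sort_index()


# ---------------------------------------------------------------------------
# clinical cohort
# ---------------------------------------------------------------------------

_TIME_OFFSET = {"baseline": 0.0, "1y": 1.0, "5y": 5.0}
# Post-surgery mean improvements applied to everyone (Mild reference level).
_POST_SHIFT = {
    "baseline": {"hba1c": 0.0, "fbg": 0.0, "weight": 0.0},
    "1y": {"hba1c": -0.6, "fbg": -0.8, "weight": -0.25},
    "5y": {"hba1c": -0.55, "fbg": -0.7, "weight": -0.22},
}
# Medication structure mirroring the emulated cohort composition: most
# patients shed glucose-lowering drugs after surgery while Severe patients
# keep theirs, and insulin use is essentially confined to the Severe group.
_DRUG_BASE = {"baseline": 0.9, "1y": -0.7, "5y": -0.7}
_DRUG_GAIN = {"baseline": 0.92, "1y": 1.25, "5y": 1.25}
_INSULIN_LOGIT_BASE = {"baseline": -4.6, "1y": -5.3, "5y": -5.3}
_INSULIN_GAIN = 2.6


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the clinical table and the planted severity labels.

    Returns ``(records, truth)``: records has three rows per patient
    (baseline/1y/5y); truth carries the planted Mild/Severe label per
    patient and time point for recovery tests.  Age and T2D duration
    advance deterministically by exactly 1 and 5 years.
    """
    n = spec.n_patients
    n_severe = int(round(spec.prop_severe_baseline * n))
    n_mild = n - n_severe
    if min(n_severe, n_mild) < 4:
        raise ValueError("need at least 4 patients per planted group")
    rng = substream(spec.seed, "cohort")
    es = {**DEFAULT_EFFECT_SIZES, **spec.effect_sizes}

    ids = [f"P{i+1:03d}" for i in range(n)]
    base_group = np.array(["Severe"] * n_severe + ["Mild"] * n_mild)
    rng.shuffle(base_group)
    # exactly round(prop_responders * n_severe) baseline-Severe patients
    # transition to Mild, so the prevalence drop is deterministic
    severe_idx = np.flatnonzero(base_group == "Severe")
    n_resp = int(round(spec.prop_responders * n_severe))
    responder = np.zeros(n, dtype=bool)
    responder[rng.choice(severe_idx, size=n_resp, replace=False)] = True

    sex = np.where(rng.random(n) < spec.prop_female, "F", "M")
    age0 = np.clip(rng.normal(48, 10, n) + 10 * es["age"] * (base_group == "Severe"), 25, 78)
    dur0 = np.clip(rng.normal(5, 4, n) + 4 * es["t2d_duration"] * (base_group == "Severe"), 0.2, 35)
    height = np.clip(rng.normal(1.65, 0.08, n), 1.45, 1.95)
    weight0 = np.clip(rng.normal(125, 20, n), 80, 200)

    # Longitudinal clinical variables are strongly autocorrelated within a
    # patient; split the unit noise into a persistent patient effect and a
    # per-visit residual (cross-sectional sd stays 1).
    _A, _B = 0.75, np.sqrt(1 - 0.75**2)
    u_hba1c, u_fbg, u_drug = (rng.normal(0, 1, n) for _ in range(3))

    rec_rows, truth_rows = [], []
    for t in ("baseline", "1y", "5y"):
        if t == "baseline":
            grp = base_group
        else:
            # responders transition to Mild within the first year and stay
            grp = np.where(responder, "Mild", base_group)
        sev = (grp == "Severe").astype(float)
        shift = _POST_SHIFT[t]
        z_hba1c = _A * u_hba1c + _B * rng.normal(0, 1, n)
        z_fbg = _A * u_fbg + _B * rng.normal(0, 1, n)
        z_drug = _A * u_drug + _B * rng.normal(0, 1, n)
        hba1c = np.clip(6.3 + shift["hba1c"] + 0.6 * (es["hba1c"] * sev + z_hba1c), 4.5, 14)
        fbg = np.clip(6.2 + shift["fbg"] + 1.2 * (es["fbg"] * sev + z_fbg), 3.2, 20)
        drug_latent = _DRUG_BASE[t] + _DRUG_GAIN[t] * es["n_glucose_drugs"] * sev + z_drug
        drugs = np.digitize(drug_latent, [0.5, 1.5]).astype(int)     # ordinal {0,1,2}
        p_ins = _sigmoid(_INSULIN_LOGIT_BASE[t] + _INSULIN_GAIN * es["insulin_use"] * sev)
        insulin = rng.random(n) < p_ins
        weight = weight0 * (1 + shift["weight"]) * np.exp(rng.normal(0, 0.03, n))
        rec_rows.append(pd.DataFrame({
            "patient_id": ids,
            "timepoint": t,
            "hba1c": np.round(hba1c, 2),
            "fbg": np.round(fbg, 2),
            "t2d_duration": np.round(dur0 + _TIME_OFFSET[t], 2),
            "age": np.round(age0 + _TIME_OFFSET[t], 1),
            "sex": sex,
            "n_glucose_drugs": drugs,
            "insulin_use": insulin,
            "weight": np.round(weight, 1),
            "bmi": np.round(weight / height**2, 1),
        }))
        truth_rows.append(pd.DataFrame({
            "patient_id": ids, "timepoint": t, "group": grp}))

    records = pd.concat(rec_rows, ignore_index=True)
    truth = pd.concat(truth_rows, ignore_index=True)

    if spec.missing_rate > 0:
        protect = {"patient_id", "timepoint"}
        cols = [c for c in records.columns if c not in protect]
        mask = rng.random((len(records), len(cols))) < spec.missing_rate
        for j, c in enumerate(cols):
            col = records[c]
            if col.dtype == bool or col.dtype == int:
                records[c] = col.astype(object)
            records.loc[mask[:, j], c] = np.nan
    return records, truth


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

_CLASS_POOL = [
    "Bacteroidia", "Clostridia", "Bacilli", "Actinobacteria",
    "Gammaproteobacteria", "Epsilonproteobacteria", "Verrucomicrobiae",
    "Negativicutes", "Coriobacteriia", "Erysipelotrichia",
]


def _make_lineage(n_taxa: int, n_classes: int, rng: np.random.Generator,
                  planted_ids: list[str]) -> pd.DataFrame:
    classes = _CLASS_POOL[:n_classes]
    taxa = [f"T{i+1:04d}" for i in range(n_taxa)]
    cls = rng.choice(classes, size=n_taxa)
    # planted taxa mimic the Severe-enriched Bacteroidia signature
    for t in planted_ids:
        cls[taxa.index(t)] = "Bacteroidia"
    genus = [f"{c[:4]}_g{(i % 23) + 1:02d}" for i, c in enumerate(cls)]
    species = [f"{g} sp{i+1:04d}" for i, g in enumerate(genus)]
    return pd.DataFrame({"class": cls, "genus": genus, "species": species},
                        index=pd.Index(taxa, name="taxon_id"))


def default_planted_taxa(n: int = 12, lfc: float = 2.0) -> list[tuple[str, float]]:
    """A dozen Severe-enriched taxa at the given log2 fold change."""
    return [(f"T{i+1:04d}", lfc) for i in range(n)]


def generate_counts(spec: CommunitySpec, group_labels: pd.Series) -> CountMatrix:
    """Overdispersed species counts with planted group effects.

    Baseline log abundances are normal with sd ``base_sigma``; planted
    taxa get a moderately high baseline (so they survive the 0.1 % mean
    abundance filter) plus ``log(2) * lfc`` in Severe samples.  Each
    sample draws a log-normal perturbation (sd = ``overdispersion``),
    a Poisson depth around ``depth_mean``, and one multinomial read
    vector, so column sums equal the drawn depths exactly.
    """
    samples = list(group_labels.index)
    rng = substream(spec.seed, "counts")
    planted_ids = [t for t, _ in spec.planted_taxa]
    valid = {f"T{i+1:04d}" for i in range(spec.n_taxa)}
    unknown = [t for t in planted_ids if t not in valid]
    if unknown:
        raise ValueError(f"planted taxa absent from lineage: {unknown}")
    lineage = _make_lineage(spec.n_taxa, spec.n_classes, rng, planted_ids)
    taxa = list(lineage.index)

    base = rng.normal(0.0, spec.base_sigma, spec.n_taxa)
    lfc_vec = np.zeros(spec.n_taxa)
    for t, lfc in spec.planted_taxa:
        i = taxa.index(t)
        base[i] = 0.6          # ~0.2 % relative abundance in Mild samples
        lfc_vec[i] = lfc

    severe = group_labels.reindex(samples).eq("Severe").to_numpy()
    counts = np.empty((spec.n_taxa, len(samples)), dtype=np.int64)
    for j, _ in enumerate(samples):
        logw = base + rng.normal(0.0, spec.overdispersion, spec.n_taxa)
        if severe[j]:
            logw = logw + np.log(2.0) * lfc_vec
        w = np.exp(logw - logw.max())
        p = w / w.sum()
        depth = rng.poisson(spec.depth_mean)
        counts[:, j] = rng.multinomial(depth, p)
    cm = CountMatrix(
        pd.DataFrame(counts, index=lineage.index, columns=samples),
        lineage,
        pd.DataFrame({"group": group_labels.reindex(samples)}),
    )
    return cm


# ---------------------------------------------------------------------------
# FMT experiment
# ---------------------------------------------------------------------------

_OGTT_TIMES = np.array([-30, 0, 15, 30, 60, 90], dtype=float)
_GLUCOSE_BASE = np.array([8.4, 8.0, 16.0, 13.0, 10.5, 9.0])       # mmol/L
_PEAK_PROFILE = np.array([0.0, 0.05, 1.0, 0.70, 0.45, 0.25])
_INSULIN_TIMES = np.array([0, 15, 30, 60], dtype=float)
_INSULIN_BASE = np.array([8.0, 25.0, 20.0, 12.0])                 # mU/L
_DIET_KCAL_G = 4.676


def generate_fmt(spec: FmtSpec, donor_counts: CountMatrix
                 ) -> tuple[CountMatrix, MouseExperiment]:
    """Recipient-mouse communities and phenotype series from donor samples.

    Each recipient community is a Bernoulli(``p_engraft``) subsample of
    its donor's species, re-normalized to ``1 - contaminant_fraction``,
    with the remaining mass on a single diet-contaminant taxon.  OGTT
    glucose/insulin, food-intake and fecal series are generated with a
    donor-level random effect plus animal-level noise; Severe recipients
    get the configured phenotype shifts.
    """
    if spec.contaminant_taxon in donor_counts.taxa:
        raise ValueError("contaminant taxon id collides with a donor taxon")
    rng = substream(spec.seed, "fmt")
    donors = list(donor_counts.sample_ids)
    clusters = donor_counts.samples["cluster"] if "cluster" in donor_counts.samples else \
        donor_counts.samples["group"]

    taxa = list(donor_counts.taxa) + [spec.contaminant_taxon]
    lineage = donor_counts.lineage.copy()
    lineage.loc[spec.contaminant_taxon] = ["Bacilli", "Lactococcus", "Lactococcus lactis"]

    rel = donor_counts.counts / donor_counts.counts.sum(axis=0)
    counts = {}
    manifest_rows, pheno_rows = [], []
    for c_idx, donor in enumerate(donors):
        cluster = clusters[donor]
        severe = cluster == "Severe"
        donor_rel = rel[donor].to_numpy()
        present = donor_rel > 0
        d_glu = rng.normal(0, 0.5)           # donor random effects
        d_ins = rng.normal(0, 0.15)
        d_food = rng.normal(0, 0.1)
        for a in range(spec.animals_per_donor):
            animal = f"{donor}_m{a+1}"
            engraft = present & (rng.random(len(donor_rel)) < spec.p_engraft)
            w = donor_rel * engraft
            total = w.sum()
            if total == 0:                   # degenerate draw: nothing engrafted
                w = np.zeros_like(donor_rel)
            else:
                w = w / total * (1 - spec.contaminant_fraction)
            p = np.append(w, spec.contaminant_fraction)
            if p.sum() == 0:
                p[-1] = 1.0
            p = p / p.sum()
            depth = rng.poisson(spec.depth_mean)
            counts[animal] = rng.multinomial(depth, p)
            manifest_rows.append({
                "animal_id": animal, "cage": f"cage_{c_idx+1:02d}",
                "donor_id": donor, "donor_cluster": cluster,
                "treatment_group": donor_counts.samples.get("treatment_group",
                                                            pd.Series(dtype=object)).get(donor, "none"),
            })
            # --- phenotypes -------------------------------------------------
            glu = (_GLUCOSE_BASE
                   + (spec.ogtt_peak_shift * _PEAK_PROFILE if severe else 0.0)
                   + d_glu + rng.normal(0, 0.8, len(_OGTT_TIMES)))
            glu = np.clip(glu, 3.0, None)
            ins = (_INSULIN_BASE * (1 + (spec.insulin_shift / _INSULIN_BASE[0] if severe else 0.0))
                   * np.exp(d_ins + rng.normal(0, 0.25, len(_INSULIN_TIMES))))
            food = max(0.5, 2.9 + (spec.food_intake_shift if severe else 0.0)
                       + d_food + rng.normal(0, 0.15))
            fecal_g = max(0.05, (0.95 if not severe else 0.80) + rng.normal(0, 0.08))
            fecal_kcal = max(1.0, (3.2 if not severe else 2.9) + rng.normal(0, 0.15))
            for t, v in zip(_OGTT_TIMES, glu):
                pheno_rows.append((animal, "ogtt_glucose", t, round(float(v), 3)))
            for t, v in zip(_INSULIN_TIMES, ins):
                pheno_rows.append((animal, "ogtt_insulin", t, round(float(v), 3)))
            pheno_rows.append((animal, "food_intake_g_day", 0.0, round(float(food), 3)))
            pheno_rows.append((animal, "fecal_output_g_day", 0.0, round(float(fecal_g), 3)))
            pheno_rows.append((animal, "fecal_kcal_g", 0.0, round(float(fecal_kcal), 3)))
            pheno_rows.append((animal, "diet_kcal_g", 0.0, _DIET_KCAL_G))
            for week in range(0, 15, 2):     # body composition, no group effect
                mass = 22 + 1.1 * week + rng.normal(0, 1.2)
                pheno_rows.append((animal, "body_mass_g", float(week), round(float(mass), 2)))
                pheno_rows.append((animal, "fat_mass_g", float(week), round(float(0.25 * mass + rng.normal(0, 0.8)), 2)))
                pheno_rows.append((animal, "lean_mass_g", float(week), round(float(0.65 * mass + rng.normal(0, 0.8)), 2)))

    recipients = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(taxa, name="taxon_id")),
        lineage,
        pd.DataFrame({"donor_id": {r["animal_id"]: r["donor_id"] for r in manifest_rows},
                      "group": {r["animal_id"]: r["donor_cluster"] for r in manifest_rows}}),
    )
    experiment = MouseExperiment(
        manifest=pd.DataFrame(manifest_rows),
        phenotypes=pd.DataFrame(pheno_rows,
                                columns=["animal_id", "variable", "time", "value"]),
    )
    return recipients, experiment


# ---------------------------------------------------------------------------
# KO membership / pathway hierarchy fixtures
# ---------------------------------------------------------------------------

def generate_ko_membership(taxa, n_kos: int = 120, n_pathways: int = 15,
                           density: float = 0.25, seed: int = 711
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Toy binary KO-by-species membership and a KO -> pathway hierarchy.

    Each KO is carried by a random ``density`` fraction of species; each
    KO belongs to one or two level-2 pathways (so the
    multiple-membership convention is exercised).
    """
    rng = substream(seed, "ko")
    taxa = list(taxa)
    kos = [f"K{i+1:05d}" for i in range(n_kos)]
    M = (rng.random((n_kos, len(taxa))) < density).astype(int)
    membership = pd.DataFrame(M, index=pd.Index(kos, name="ko_id"), columns=taxa)
    rows = []
    for i, ko in enumerate(kos):
        n_assign = 1 + int(rng.random() < 0.2)
        for pw in rng.choice(n_pathways, size=n_assign, replace=False):
            rows.append({"ko_id": ko, "level": 2,
                         "pathway_id": f"map{pw+1:03d}",
                         "pathway_name": f"pathway_{pw+1:03d}"})
    hierarchy = pd.DataFrame(rows)
    return membership, hierarchy


# ---------------------------------------------------------------------------
# fixture materialization
# ---------------------------------------------------------------------------

def write_fixture_study(out_dir, n_patients: int = 60, n_taxa: int = 300,
                        seed: int = 711) -> dict:
    """Materialize a complete small synthetic study on disk.

    Writes clinical CSV, human count/lineage/metadata TSVs, KO membership
    and hierarchy TSVs, donor + recipient count TSVs, the mouse manifest
    CSV and the phenotype long CSV.  Returns the path map.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_spec = CohortSpec(n_patients=n_patients, seed=seed)
    records, truth = generate_cohort(cohort_spec)
    records.to_csv(out / "clinical.csv", index=False)
    truth.to_csv(out / "clinical_truth.csv", index=False)

    labels_5y = truth[truth["timepoint"] == "5y"].set_index("patient_id")["group"]
    comm_spec = CommunitySpec(n_taxa=n_taxa, planted_taxa=default_planted_taxa(),
                              depth_mean=50_000, seed=seed)
    human = generate_counts(comm_spec, labels_5y)
    human.to_tsv(out / "human_counts.tsv", out / "lineage.tsv", out / "human_samples.tsv")

    # 13 donors: 4 Mild, 9 Severe, matching the transplant design
    mild = labels_5y[labels_5y == "Mild"].index[:4]
    severe = labels_5y[labels_5y == "Severe"].index[:9]
    if len(mild) < 4 or len(severe) < 9:
        raise ValueError("cohort too small for the 4 Mild + 9 Severe donor "
                         "design; increase n_patients")
    donors = human.subset_samples(list(mild) + list(severe))
    donors.samples["cluster"] = donors.samples["group"]
    donors.to_tsv(out / "donor_counts.tsv", samples_path=out / "donor_samples.tsv")

    fmt_spec = FmtSpec(seed=seed)
    recipients, experiment = generate_fmt(fmt_spec, donors)
    recipients.to_tsv(out / "recipient_counts.tsv", out / "recipient_lineage.tsv",
                      out / "recipient_samples.tsv")
    experiment.manifest.to_csv(out / "mouse_manifest.csv", index=False)
    experiment.phenotypes.to_csv(out / "mouse_phenotypes.csv", index=False)

    membership, hierarchy = generate_ko_membership(human.taxa, seed=seed)
    membership.to_csv(out / "ko_membership.tsv", sep="\t")
    hierarchy.to_csv(out / "ko_hierarchy.tsv", sep="\t", index=False)
    return {p.name: p for p in out.iterdir()}
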