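"""End-to-end orchestration: configuration, seeds, logging and file formats.

Both pipelines are deterministic: all randomness derives from the single
global seed via named substreams (one per stage), every output table is
written with a fixed float format, and the run manifest records the
config hash and per-stage seeds, so two runs with equal hashes produce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from ._rng import substream_seed
from . import fmt as fmt_mod
from . import functions as fn_mod
from . import microbiome as mb
from . import severity as sev

__all__ = ["RunConfig", "run_human_pipeline", "run_fmt_pipeline"]

logger = logging.getLogger("baripath")

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Paths, depths, thresholds and the global seed for a pipeline run."""

    clinical: str | None = None
    counts: str | None = None
    lineage: str | None = None
    sample_metadata: str | None = None
    ko_membership: str | None = None
    ko_hierarchy: str | None = None
    mouse_manifest: str | None = None
    donor_counts: str | None = None
    recipient_counts: str | None = None
    phenotypes: str | None = None
    out_dir: str = "results"
    seed: int = 711
    human_depth: int = 48_000
    mouse_depth: int = 65_000
    within_animal_depth: int = 113_000
    min_prevalence: float = 0.20
    min_mean_abundance: float = 0.001
    n_permutations: int = 999
    pathway_level: int | str = 2

    def __post_init__(self):
        for name in ("human_depth", "mouse_depth", "within_animal_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("min_prevalence", "min_mean_abundance"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")      # where results land does not change them
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, cfg_hash: str, **kwargs) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", float_format=_FLOAT_FMT, **kwargs)


def _stage(manifest: dict, name: str, seed: int) -> int:
    s = substream_seed(seed, name)
    manifest["stages"].append({"stage": name, "seed": s})
    logger.info("stage %s (seed %d)", name, s)
    return s


def run_human_pipeline(config: RunConfig) -> dict:
    """Clinical clustering plus human microbiome analytics.

    Stages: impute -> cluster -> trajectories -> rarefy -> filter ->
    diversity -> ordination -> dbRDA -> differential abundance -> KO
    inference -> clinical correlations.  Microbiome stages are skipped
    with a log notice when no count input is configured; a stage failure
    aborts with a stage-named error, partial outputs retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    manifest: dict = {"config_hash": cfg_hash, "seed": config.seed, "stages": []}
    results: dict = {"manifest": manifest}

    def run_stage(name, fn):
        _stage(manifest, name, config.seed)
        try:
            return fn()
        except Exception as exc:
            _dump_manifest(out, manifest)
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    if config.clinical is None:
        raise ValueError("clinical input is required")
    records = pd.read_csv(config.clinical)

    records = run_stage("impute", lambda: sev.impute_median(records))

    def _cluster():
        # unstandardized input: the model stores raw-scale means/sds so an
        # independent cohort can be projected later
        features = sev.build_feature_matrix(records, standardize=False)
        model = sev.fit_severity_model(features)
        assignments = model.labels.rename("cluster").reset_index()
        return model, assignments

    model, assignments = run_stage("cluster", _cluster)
    results["model"] = model
    model.to_json(out / "severity_model.json")

    def _traj():
        wide = assignments.set_index(["patient_id", "timepoint"])["cluster"].unstack()
        traj = sev.assign_trajectories(wide["baseline"], wide["5y"])
        rec5 = records[records["timepoint"] == "5y"].set_index("patient_id")
        dr = sev.classify_dr(rec5)
        table = assignments.merge(traj.rename("trajectory"), left_on="patient_id",
                                  right_index=True)
        table = table.merge(dr.rename("dr_status"), left_on="patient_id", right_index=True)
        return table.sort_values(["patient_id", "timepoint"]).reset_index(drop=True)

    table = run_stage("trajectories", _traj)
    results["assignments"] = table
    _write(table, out / "assignments.tsv", cfg_hash, index=False)

    if config.counts is None:
        logger.info("no count input configured; microbiome stages skipped")
        _dump_manifest(out, manifest)
        return results

    cm = mb.CountMatrix.from_tsv(config.counts, config.lineage, config.sample_metadata)

    rare_seed = substream_seed(config.seed, "rarefy")
    cm_r = run_stage("rarefy", lambda: mb.rarefy(cm, config.human_depth, rare_seed))
    cm_f = run_stage("filter", lambda: mb.filter_prevalence(cm_r, config.min_prevalence))
    rel = mb.relative_abundance(cm_f)
    keep = mb.filter_mean_abundance(rel, config.min_mean_abundance)
    rel = rel.loc[keep]
    _write(rel, out / "relative_abundance.tsv", cfg_hash)

    alpha = run_stage("diversity", lambda: mb.alpha_diversity(cm_r))
    _write(alpha, out / "alpha_diversity.tsv", cfg_hash)

    genus = mb.aggregate_rank(cm_f, "genus")
    D = mb.bray_curtis(mb.relative_abundance(genus))

    def _ordination():
        res = mb.pcoa(D)
        return res

    ord_res = run_stage("ordination", _ordination)
    _write(ord_res.coordinates, out / "pcoa_coordinates.tsv", cfg_hash)

    groups = cm.samples["group"].reindex(rel.columns)

    def _dbrda():
        x = groups.eq("Severe").astype(float)
        return mb.dbrda_univariate(D, x.reindex(D.index),
                                   n_perm=config.n_permutations,
                                   seed=substream_seed(config.seed, "dbrda"))

    results["dbrda"] = run_stage("dbrda", _dbrda)

    diffab = run_stage("differential_abundance",
                       lambda: mb.differential_abundance(rel, groups))
    results["differential_abundance"] = diffab
    _write(diffab, out / "differential_abundance.tsv", cfg_hash)

    if config.ko_membership is not None:
        def _ko():
            membership = fn_mod.KOMembership.from_tsv(config.ko_membership)
            hierarchy = fn_mod.PathwayHierarchy.from_tsv(config.ko_hierarchy)
            ko = fn_mod.infer_ko(rel, membership)
            pathways = fn_mod.collapse_pathways(ko, hierarchy, config.pathway_level)
            pdiff = fn_mod.pathway_differential(pathways, groups)
            return ko, pathways, pdiff

        ko, pathways, pdiff = run_stage("ko_inference", _ko)
        results["pathway_differential"] = pdiff
        _write(pdiff, out / "pathway_differential.tsv", cfg_hash)

    def _correlations():
        clin5 = records[records["timepoint"] == "5y"].set_index("patient_id")
        cols = [c for c in ("hba1c", "fbg", "t2d_duration", "bmi", "weight") if c in clin5]
        hits = diffab[diffab["q"] < 0.1].index
        if len(hits) == 0:
            return pd.DataFrame()
        shared = [s for s in rel.columns if s in clin5.index]
        return mb.correlate_clinical(rel.loc[hits, shared], clin5.loc[shared, cols])

    corr = run_stage("clinical_correlations", _correlations)
    if len(corr):
        _write(corr, out / "clinical_correlations.tsv", cfg_hash, index=False)
    results["clinical_correlations"] = corr

    _dump_manifest(out, manifest)
    return results


def run_fmt_pipeline(config: RunConfig) -> dict:
    """Engraftment -> recipient differential abundance -> phenotype tests."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    manifest: dict = {"config_hash": cfg_hash, "seed": config.seed, "stages": []}
    results: dict = {"manifest": manifest}

    mouse_manifest = pd.read_csv(config.mouse_manifest)
    donors = mb.CountMatrix.from_tsv(config.donor_counts, config.lineage)
    recipients = mb.CountMatrix.from_tsv(config.recipient_counts, config.lineage)
    orphans = set(mouse_manifest["donor_id"]) - set(donors.sample_ids)
    if orphans:
        raise ValueError(f"manifest donors without count columns: {sorted(orphans)}")
    orphan_animals = set(mouse_manifest["animal_id"]) - set(recipients.sample_ids)
    if orphan_animals:
        raise ValueError(f"manifest animals without count columns: {sorted(orphan_animals)}")

    _stage(manifest, "engraftment", config.seed)
    engraft = fmt_mod.engraftment_table(
        donors, recipients, mouse_manifest, depth=config.mouse_depth,
        seed=substream_seed(config.seed, "engraftment"))
    results["engraftment"] = engraft
    _write(engraft, out / "engraftment.tsv", cfg_hash, index=False)

    _stage(manifest, "recipient_differential", config.seed)
    rec_r = mb.rarefy(recipients, config.mouse_depth,
                      substream_seed(config.seed, "recipient_rarefy"))
    rec_f = mb.filter_prevalence(rec_r, config.min_prevalence)
    rel = mb.relative_abundance(rec_f)
    rel = rel.loc[mb.filter_mean_abundance(rel, config.min_mean_abundance)]
    rec_diff = fmt_mod.recipient_differential(rel, mouse_manifest)
    results["recipient_differential"] = rec_diff
    _write(rec_diff, out / "recipient_differential.tsv", cfg_hash)

    _stage(manifest, "phenotypes", config.seed)
    pheno = pd.read_csv(config.phenotypes)
    donor_map = mouse_manifest.set_index("animal_id")["donor_id"]
    donor_clusters = mouse_manifest.drop_duplicates("donor_id") \
                                   .set_index("donor_id")["donor_cluster"]

    per_animal = _animal_phenotypes(pheno)
    donor_values = pd.DataFrame({
        col: fmt_mod.collapse_pseudoreplicates(per_animal[col], donor_map,
                                               gm_offset=1e-9)
        for col in per_animal.columns
    })
    stats_table = fmt_mod.group_phenotype_tests(donor_values, donor_clusters)
    results["phenotype_tests"] = stats_table
    results["donor_values"] = donor_values
    _write(donor_values, out / "donor_phenotypes.tsv", cfg_hash)
    _write(stats_table, out / "phenotype_tests.tsv", cfg_hash)

    _dump_manifest(out, manifest)
    return results


def _animal_phenotypes(pheno: pd.DataFrame) -> pd.DataFrame:
    """Per-animal derived phenotypes from the long series table."""
    out = {}
    for animal, sub in pheno.groupby("animal_id"):
        row = {}
        glu = sub[sub["variable"] == "ogtt_glucose"].sort_values("time")
        ins = sub[sub["variable"] == "ogtt_insulin"].sort_values("time")
        if len(glu):
            row["ogtt_auc"] = fmt_mod.ogtt_auc(glu["time"], glu["value"])
            fasting_glu_mg_dl = float(glu.loc[glu["time"] == 0, "value"].iloc[0]) / 0.0555
            if len(ins):
                fasting_ins = float(ins.loc[ins["time"] == 0, "value"].iloc[0])
                row["homa_ir"] = fmt_mod.homa_ir(fasting_glu_mg_dl, fasting_ins)
                row["quicki"] = fmt_mod.quicki(fasting_glu_mg_dl, fasting_ins)
        scal = sub.set_index("variable")["value"]
        if "food_intake_g_day" in scal.index:
            eb = fmt_mod.energy_balance(
                float(scal.get("food_intake_g_day")),
                float(scal.get("diet_kcal_g", 4.676)),
                float(scal.get("fecal_output_g_day", 0.0)),
                float(scal.get("fecal_kcal_g", 0.0)))
            row["food_intake_g_day"] = float(scal.get("food_intake_g_day"))
            row["kcal_excreted_day"] = eb["kcal_excreted_day"]
            row["kcal_absorbed_day"] = eb["kcal_absorbed_day"]
            row["absorption_pct"] = eb["absorption_pct"]
        out[animal] = row
    return pd.DataFrame(out).T.sort_index()


def _dump_manifest(out: Path, manifest: dict) -> None:
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
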