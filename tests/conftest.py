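import numpy as np
import pandas as pd
import pytest

import baripath as bp


@pytest.fixture(scope="session")
def cohort():
    """Small planted cohort: records, truth labels, features, fitted model."""
    records, truth = bp.generate_cohort(bp.CohortSpec(n_patients=60, seed=11))
    features = bp.build_feature_matrix(records, standardize=False)
    model = bp.fit_severity_model(features)
    planted = truth.set_index(["patient_id", "timepoint"]).reindex(features.index)["group"]
    return {"records": records, "truth": truth, "features": features,
            "model": model, "planted": planted}


@pytest.fixture(scope="session")
def community():
    """Planted 60-sample community with 12 Severe-enriched taxa (LFC 2)."""
    labels = pd.Series(["Severe"] * 30 + ["Mild"] * 30,
                       index=[f"S{i:02d}" for i in range(60)], name="group")
    spec = bp.CommunitySpec(n_taxa=300,
                            planted_taxa=bp.synthetic_data.default_planted_taxa(12, 2.0),
                            depth_mean=50_000, seed=5)
    cm = bp.generate_counts(spec, labels)
    return {"labels": labels, "cm": cm,
            "planted": [t for t, _ in spec.planted_taxa]}


@pytest.fixture(scope="session")
def fmt_study():
    """13-donor transplant study: donor counts, recipients, experiment."""
    labels = pd.Series(["Severe"] * 9 + ["Mild"] * 4,
                       index=[f"D{i:02d}" for i in range(13)], name="group")
    dcm = bp.generate_counts(
        bp.CommunitySpec(n_taxa=150, depth_mean=90_000, base_sigma=1.2, seed=3), labels)
    dcm.samples["cluster"] = dcm.samples["group"]
    recipients, experiment = bp.generate_fmt(bp.FmtSpec(seed=3), dcm)
    return {"donors": dcm, "recipients": recipients, "experiment": experiment,
            "clusters": labels}


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("study")
    bp.write_fixture_study(out, n_patients=40, n_taxa=120, seed=7)
    return out


def toy_count_matrix(counts: np.ndarray, samples=None) -> bp.CountMatrix:
    """Helper: wrap a plain array in a CountMatrix with dummy lineage."""
    n_taxa = counts.shape[0]
    taxa = [f"t{i}" for i in range(n_taxa)]
    samples = samples or [f"s{j}" for j in range(counts.shape[1])]
    lineage = pd.DataFrame(
        {"class": ["c" + str(i % 3) for i in range(n_taxa)],
         "genus": ["g" + str(i % 5) for i in range(n_taxa)],
         "species": taxa},
        index=pd.Index(taxa, name="taxon_id"))
    return bp.CountMatrix(pd.DataFrame(counts, index=lineage.index, columns=samples),
                          lineage)
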