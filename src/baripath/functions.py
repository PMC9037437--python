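"""Pangenome-based functional inference.

KEGG-orthology (KO) group abundances are inferred from species
abundances: the abundance of a KO in a sample is the sum of the
abundances of all species whose pangenome carries that KO (binary
incidence weighting).  KO abundances are then collapsed into pathways at
a chosen annotation level; a KO belonging to several pathways
contributes its full abundance to each.  Both the raw sums and
per-sample-normalized versions are available, and pathway-level group
differences reuse the Cliff's-delta/Welch/BH machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .microbiome import correlate_clinical, differential_abundance

__all__ = [
    "KOMembership",
    "PathwayHierarchy",
    "infer_ko",
    "collapse_pathways",
    "pathway_differential",
    "species_ko_correlation",
]

logger = logging.getLogger(__name__)


@dataclass
class KOMembership:
    """Binary KO-by-species incidence matrix."""

    matrix: pd.DataFrame        # rows = KO ids, columns = species/taxon ids

    def __post_init__(self):
        vals = set(np.unique(self.matrix.to_numpy()))
        if not vals <= {0, 1}:
            raise ValueError("membership entries must be 0/1")

    @classmethod
    def from_tsv(cls, path) -> "KOMembership":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


@dataclass
class PathwayHierarchy:
    """KO -> pathway mapping with annotation levels.

    ``table`` columns: ko_id, level, pathway_id, pathway_name.  A KO may
    belong to multiple pathways at the same level.
    """

    table: pd.DataFrame

    def levels(self) -> list:
        return sorted(self.table["level"].unique())

    @classmethod
    def from_tsv(cls, path) -> "PathwayHierarchy":
        return cls(pd.read_csv(path, sep="\t"))


def infer_ko(abundances: pd.DataFrame, membership: KOMembership,
             normalize: bool = False) -> pd.DataFrame:
    """KO abundance per sample: membership matrix x species abundances.

    ``abundances``: species x samples (post-rarefaction relative
    abundances by default; raw counts work identically).  Species absent
    from the membership table are ignored (their number is logged).
    With ``normalize`` the KO columns are rescaled to sum to 1 per
    sample.
    """
    M = membership.matrix
    shared = abundances.index.intersection(M.columns)
    if len(shared) == 0:
        raise ValueError("no species shared between abundance table and membership")
    ignored = len(abundances.index) - len(shared)
    if ignored:
        logger.info("infer_ko: %d species absent from the membership table ignored", ignored)
    out = M[shared].to_numpy(dtype=float) @ abundances.loc[shared].to_numpy(dtype=float)
    ko = pd.DataFrame(out, index=M.index, columns=abundances.columns)
    if normalize:
        totals = ko.sum(axis=0).replace(0, np.nan)
        ko = (ko / totals).fillna(0.0)
    return ko


def collapse_pathways(ko_abund: pd.DataFrame, hierarchy: PathwayHierarchy,
                      level) -> pd.DataFrame:
    """Pathway abundance = sum of member-KO abundances (no splitting)."""
    table = hierarchy.table
    if level not in set(table["level"]):
        raise ValueError(f"unknown hierarchy level {level!r}")
    sub = table[table["level"] == level]
    rows = {}
    for pathway, kos in sub.groupby("pathway_id")["ko_id"]:
        members = ko_abund.index.intersection(kos)
        if len(members):
            rows[pathway] = ko_abund.loc[members].sum(axis=0)
    return pd.DataFrame(rows).T.rename_axis("pathway_id")


def pathway_differential(pathway_abund: pd.DataFrame, groups: pd.Series,
                         group_a: str = "Severe", group_b: str = "Mild"
                         ) -> pd.DataFrame:
    """Per-pathway Cliff's delta + Welch p + BH q across pathways.

    All-zero pathways are excluded rather than reported as NaN; the dual
    significance tiers (p < .05, q < 0.1) are flagged.
    """
    nonzero = pathway_abund.index[(pathway_abund != 0).any(axis=1)]
    out = differential_abundance(pathway_abund.loc[nonzero], groups,
                                 group_a=group_a, group_b=group_b)
    out["sig_p05"] = out["p_welch"] < 0.05
    out["sig_q10"] = out["q"] < 0.10
    return out


def species_ko_correlation(species_abund: pd.DataFrame,
                           ko_abund: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho grid between selected species and inferred KOs.

    Returns a long table (taxon = species, variable = KO id, rho, p, q);
    constant rows are reported with missing rho.
    """
    return correlate_clinical(species_abund, ko_abund.T)
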