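"""Molecular-family (subnetwork) aggregation, enrichment, and congruency.

Spectral networking groups MS1 features whose fragmentation spectra are
similar into subnetworks ("molecular families"); this module consumes
those ids from the annotation table, sums member relative abundances per
sample, tests each subnetwork for producer enrichment with the same
Dunnett-vs-Control machinery the feature cascade uses, selects the
abundant/diverse/enriched focus networks, and quantifies how well each
labeling (subnetwork id, structural class, library match) predicts the
treatment-association categories of exometabolite features.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .classify import CascadeResult, test_exometabolites
from .io import DIELS, PRODUCERS, FeatureTable, relative_abundance
from .stats import CongruencyResult, congruency_r2

log = logging.getLogger(__name__)

__all__ = [
    "aggregate_subnetworks", "test_subnetwork_enrichment",
    "select_focus_subnetworks", "subnetwork_class_congruency",
    "heatmap_matrix",
]


def aggregate_subnetworks(table: FeatureTable, annotations: pd.DataFrame,
                          result: CascadeResult | None = None,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subnetwork summed relative abundance and membership summary.

    Singletons (features without a subnetwork id) are excluded.  Returns
    ``(shares, members)``: a subnetwork x sample frame of summed member
    shares, and a per-subnetwork frame with member/exudate-node counts
    and the majority structural class among annotated members.
    """
    ann = annotations[annotations["subnetwork_id"].notna()]
    if ann.empty:
        raise ValueError("no subnetwork ids in annotations")
    rel = relative_abundance(table)
    member_of = ann.set_index("feature_id")["subnetwork_id"]
    present = member_of.index.intersection(rel.data.index)
    member_of = member_of.loc[present]
    shares = rel.data.loc[present].groupby(member_of).sum()
    shares.index.name = "subnetwork_id"

    exudate_cls = {"exometabolite", "benthic_exudate", "planktonic_exudate",
                   "incubation_artifact"}
    rows = []
    for sn, grp in ann.groupby("subnetwork_id"):
        feats = grp["feature_id"].tolist()
        n_exudate = n_exo = 0
        if result is not None:
            lab = result.labels.reindex(feats)
            n_exudate = int(lab.isin(exudate_cls).sum())
            n_exo = int((lab == "exometabolite").sum())
        classes = grp["structural_class"].dropna()
        if len(classes):
            counts = classes.value_counts()
            top = counts[counts == counts.max()]
            consensus = top.index[0] if len(top) == 1 else "unclassified"
        else:
            consensus = np.nan
        rows.append({"subnetwork_id": sn, "n_members": len(feats),
                     "n_exudate_nodes": n_exudate, "n_exometabolite_nodes": n_exo,
                     "consensus_class": consensus})
    members = pd.DataFrame(rows).set_index("subnetwork_id")
    return shares, members


def test_subnetwork_enrichment(shares: pd.DataFrame, meta: pd.DataFrame,
                               alpha: float = 0.05, *, min_fold: float = 2.0,
                               ) -> pd.DataFrame:
    """Dunnett-vs-Control enrichment of summed subnetwork shares.

    A subnetwork is enriched in a (producer, diel) cell iff its BH-FDR
    adjusted Dunnett p (pooled family over subnetworks x producers x
    diel) is below ``alpha`` AND its mean share is at least ``min_fold``
    times the Control mean.
    """
    pseudo = FeatureTable(shares.copy())
    _, tests, _ = test_exometabolites(pseudo, meta, list(shares.index),
                                      alpha, test_on="raw")
    end = meta[(meta["role"] == "experimental") & (meta["timepoint"] == "end")]
    folds = []
    for row in tests.itertuples(index=False):
        ctrl = end.loc[(end["treatment"] == "Control") & (end["diel"] == row.diel),
                       "sample_id"]
        cell = end.loc[(end["treatment"] == row.treatment) & (end["diel"] == row.diel),
                       "sample_id"]
        c = shares.loc[row.feature_id, ctrl].mean()
        m = shares.loc[row.feature_id, cell].mean()
        folds.append(m / c if c > 0 else np.inf if m > 0 else 1.0)
    tests = tests.rename(columns={"feature_id": "subnetwork_id"})
    tests["fold_vs_control"] = folds
    tests["enriched"] = (tests["p_fdr"] < alpha) & (tests["fold_vs_control"] >= min_fold)
    return tests


def select_focus_subnetworks(enrichment: pd.DataFrame, shares: pd.DataFrame,
                             members: pd.DataFrame, meta: pd.DataFrame, *,
                             min_share: float = 0.0005, min_exudate_nodes: int = 5,
                             alpha: float = 0.01, min_fold: float = 2.0) -> list:
    """Focus networks: abundant AND diverse AND significantly enriched.

    * abundant: mean summed share > 0.05% of at least one exometabolome
      (per-producer mean over endpoint replicates);
    * diverse: more than five exudate nodes;
    * enriched: >= 2x Control mean share with Dunnett FDR p < 0.01.
    """
    end = meta[(meta["role"] == "experimental") & (meta["timepoint"] == "end")]
    prod_means = {}
    for trt in PRODUCERS:
        cols = end.loc[end["treatment"] == trt, "sample_id"]
        prod_means[trt] = shares[cols].mean(axis=1)
    abundant = pd.DataFrame(prod_means).max(axis=1) > min_share
    diverse = members["n_exudate_nodes"] > min_exudate_nodes
    strong = enrichment[(enrichment["p_fdr"] < alpha)
                        & (enrichment["fold_vs_control"] >= min_fold)]
    enriched_ids = set(strong["subnetwork_id"])
    selected = [sn for sn in shares.index
                if bool(abundant.get(sn, False)) and bool(diverse.get(sn, False))
                and sn in enriched_ids]
    log.info("focus selection: %d abundant, %d diverse, %d enriched -> %d",
             int(abundant.sum()), int(diverse.sum()), len(enriched_ids), len(selected))
    return selected


def subnetwork_class_congruency(categories: pd.DataFrame, annotations: pd.DataFrame,
                                label_sets=("subnetwork_id", "structural_class",
                                            "library_match")) -> pd.DataFrame:
    """Congruency of each annotation labeling with treatment categories.

    For every label set, Theil's U (``congruency_r2``) of the treatment-
    association category given the label, over the labeled exometabolite
    features; label sets with a single level are skipped with a warning.
    """
    merged = categories.merge(annotations, on="feature_id", how="left")
    rows = []
    for label in label_sets:
        sub = merged[merged[label].notna()]
        if sub.empty or sub[label].nunique() < 2 or sub["category"].nunique() < 2:
            warnings.warn(f"label set {label!r} has fewer than two levels; skipped")
            continue
        res: CongruencyResult = congruency_r2(sub["category"].to_numpy(),
                                              sub[label].astype(str).to_numpy())
        rows.append({"label_set": label, "r2": res.r2, "g2": res.g2, "p": res.p,
                     "dof": res.dof, "n_labeled": res.n, "cramers_v": res.cramers_v})
    return pd.DataFrame(rows)


def heatmap_matrix(table: FeatureTable, annotations: pd.DataFrame,
                   selected, meta: pd.DataFrame, diel: str = "Day") -> pd.DataFrame:
    """Per-feature z-scored relative abundance over daytime endpoint samples.

    Rows are the member features of the selected subnetworks (grouped by
    subnetwork id); constant features give zero rows with a warning.
    """
    end = meta[(meta["role"] == "experimental") & (meta["timepoint"] == "end")
               & (meta["diel"] == diel)]
    cols = end["sample_id"].tolist()
    ann = annotations[annotations["subnetwork_id"].isin(list(selected))]
    feats = [f for f in ann.sort_values("subnetwork_id")["feature_id"]
             if f in table.data.index]
    rel = relative_abundance(table, cols).data.loc[feats]
    sd = rel.std(axis=1, ddof=1)
    const = sd == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant feature(s) map to zero rows")
    z = rel.sub(rel.mean(axis=1), axis=0).div(sd.where(~const, 1.0), axis=0)
    z[const] = 0.0
    z.insert(0, "subnetwork_id",
             ann.set_index("feature_id")["subnetwork_id"].reindex(feats).to_numpy())
    return z
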