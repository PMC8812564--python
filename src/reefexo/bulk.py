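"""Producer effects on bulk biogeochemistry and DOC-metabolome coupling.

Endpoint water chemistry (DO, pH, DOC, nutrients) is compared across the
six incubation groups per diel period with one-way ANOVA, BH-FDR
corrected across analytes within a diel period; analytes passing the
omnibus screen get Dunnett many-to-one comparisons against the Control.
Separately, per-sample summed exudate- and ambient-feature peak areas
are regressed against DOC to test whether the resolved ion features
track the independently measured carbon release.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DIELS, PRODUCERS, FeatureTable
from .stats import LinearFit, bh_fdr, dunnett_many_to_one, linear_fit, one_way_anova

__all__ = ["producer_effect_tests", "doc_metabolome_coupling"]


def _endpoint_groups(meta: pd.DataFrame, diel: str) -> dict[str, list[str]]:
    end = meta[(meta["role"] == "experimental") & (meta["timepoint"] == "end")
               & (meta["diel"] == diel)]
    groups = {}
    for trt in ("Control",) + PRODUCERS:
        ids = end.loc[end["treatment"] == trt, "sample_id"].tolist()
        if len(ids) < 2:
            raise ValueError(f"group {trt}/{diel} has fewer than 2 replicates")
        groups[trt] = ids
    return groups


def producer_effect_tests(bulk: pd.DataFrame, meta: pd.DataFrame,
                          analytes=None, alpha: float = 0.05,
                          mode: str = "endpoint") -> pd.DataFrame:
    """Per analyte x diel ANOVA (FDR across analytes) plus Dunnett vs Control.

    ``mode='delta'`` subtracts the diel-matched ambient-start mean from
    every endpoint value first (production/consumption over the 8-h
    incubation); ``'endpoint'`` tests raw endpoint concentrations.
    """
    if analytes is None:
        analytes = [c for c in bulk.columns]
    rows = []
    for diel in DIELS:
        groups = _endpoint_groups(meta, diel)
        exp = meta[meta["role"] == "experimental"]
        amb = exp.loc[(exp["treatment"] == "Ambient") & (exp["diel"] == diel),
                      "sample_id"].tolist()
        anova_ps = []
        per_analyte = []
        for analyte in analytes:
            offset = bulk.loc[amb, analyte].mean() if mode == "delta" else 0.0
            arrs = {t: bulk.loc[ids, analyte].to_numpy() - offset
                    for t, ids in groups.items()}
            a = one_way_anova(list(arrs.values()))
            anova_ps.append(a.p)
            per_analyte.append((analyte, arrs, a))
        fdr = bh_fdr(anova_ps)
        for (analyte, arrs, a), p_adj in zip(per_analyte, fdr):
            dn = dunnett_many_to_one(arrs["Control"],
                                     [arrs[t] for t in PRODUCERS], sided="two-sided")
            for j, producer in enumerate(PRODUCERS):
                rows.append({
                    "analyte": analyte, "diel": diel, "treatment": producer,
                    "anova_F": a.F, "anova_p": a.p, "anova_p_fdr": float(p_adj),
                    "mean_diff": float(dn.mean_diffs[j]),
                    "direction": "increase" if dn.mean_diffs[j] > 0 else "decrease",
                    "dunnett_p": float(dn.pvalues[j]),
                    "significant": bool(p_adj < alpha and dn.pvalues[j] < alpha),
                })
    return pd.DataFrame(rows)


@dataclass
class DocCoupling:
    exudate: dict[str, LinearFit]    # per diel
    ambient: dict[str, LinearFit]


def doc_metabolome_coupling(table: FeatureTable, labels: pd.Series,
                            bulk: pd.DataFrame, meta: pd.DataFrame) -> DocCoupling:
    """Regress DOC on summed exudate- and ambient-feature peak areas, per diel.

    Exudate classes couple to carbon release; ambient features, already
    present in the starting reef water, should not.
    """
    exudate_cls = {"exometabolite", "benthic_exudate", "planktonic_exudate",
                   "incubation_artifact"}
    exu = labels.index[labels.isin(exudate_cls)]
    amb = labels.index[labels == "ambient"]
    end = meta[(meta["role"] == "experimental") & (meta["timepoint"] == "end")]
    out_e, out_a = {}, {}
    for diel in DIELS:
        ids = [s for s in end.loc[end["diel"] == diel, "sample_id"]
               if s in bulk.index]
        doc = bulk.loc[ids, "DOC"].to_numpy()
        out_e[diel] = linear_fit(table.data.loc[exu, ids].sum(axis=0).to_numpy(), doc)
        out_a[diel] = linear_fit(table.data.loc[amb, ids].sum(axis=0).to_numpy(), doc)
    return DocCoupling(exudate=out_e, ambient=out_a)
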