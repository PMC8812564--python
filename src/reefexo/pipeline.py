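"""End-to-end orchestration: cascade -> ordination -> energetics -> networks -> bulk.

`run_pipeline` consumes either the four native input TSVs or a simulation
config, executes every stage in cascade order, writes tidy TSV outputs
plus a JSON run manifest (config hash, seeds, thresholds, per-stage row
counts), and returns the in-memory results for programmatic use.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bulk import doc_metabolome_coupling, producer_effect_tests
from .chem import (feature_standardized_weighting, formula_quality_filter,
                   regress_stoichiometry_vs_bulk, sample_weighted_nosc)
from .classify import CascadeConfig, classify_features, treatment_association_categories, \
    class_peak_area_summary
from .io import (DIELS, PRODUCERS, FeatureTable, formula_map, read_annotations,
                 read_bulk_chemistry, read_feature_table, read_sample_metadata,
                 relative_abundance, write_annotations, write_bulk_chemistry,
                 write_feature_table, write_sample_metadata)
from .networks import (aggregate_subnetworks, heatmap_matrix,
                       select_focus_subnetworks, subnetwork_class_congruency,
                       test_subnetwork_enrichment)
from .stats import angular_zscore_transform, pairwise_permanova, pcoa, permanova, \
    tukey_hsd
from .synthetic import SimulationConfig, generate_experiment

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "ordinate_exometabolomes",
           "producer_stoichiometry"]


@dataclass
class PipelineConfig:
    """All thresholds as named keys, defaulting to the study conventions."""

    cascade: CascadeConfig = field(default_factory=CascadeConfig)
    permanova_permutations: int = 999
    focus_min_share: float = 0.0005
    focus_min_exudate_nodes: int = 5
    focus_alpha: float = 0.01
    focus_min_fold: float = 2.0
    subnetwork_alpha: float = 0.05
    stoichiometry_diel: str = "Day"
    seed: int = 0


@dataclass
class PipelineResult:
    cascade: object
    categories: pd.DataFrame
    class_summary: pd.DataFrame
    ordination: dict
    stoichiometry: pd.DataFrame | None
    stoichiometry_z: pd.DataFrame | None
    tukey_letters: dict | None
    subnetworks: dict | None
    bulk_effects: pd.DataFrame | None
    doc_coupling: object | None
    stoich_vs_bulk: dict | None
    manifest: dict


# --------------------------------------------------------------------------
# ordination stage
# --------------------------------------------------------------------------

def ordinate_exometabolomes(table: FeatureTable, meta: pd.DataFrame,
                            exometabolites, *, n_perm: int = 999, seed: int = 0) -> dict:
    """PCoA + PERMANOVA of samples on exometabolite relative abundances.

    Per-sample shares of the exometabolite features are angular
    transformed, z-scored per feature, and ordinated on Euclidean
    distances (equivalently, a PCA of the transformed matrix).  PERMANOVA
    partitions the same distances by treatment, diel, and their
    interaction in that sequential order; pairwise treatment contrasts
    are reported with raw and BH-adjusted permutation p-values.
    """
    exp = meta[meta["role"] == "experimental"]
    samples = exp["sample_id"].tolist()
    rel = relative_abundance(table, samples).data.loc[list(exometabolites)]
    z = angular_zscore_transform(rel.to_numpy())
    x = z.T                                       # samples x features
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    ord_ = pcoa(d)
    treatment = exp["treatment"].to_numpy()
    diel = exp["diel"].to_numpy()
    perm = permanova(d, treatment, diel, n_perm=n_perm, seed=seed)
    pairwise = pairwise_permanova(d, treatment, n_perm=n_perm, seed=seed)
    return {"samples": samples, "distance": d, "pcoa": ord_,
            "permanova": perm, "pairwise": pairwise}


# --------------------------------------------------------------------------
# stoichiometry stage
# --------------------------------------------------------------------------

def producer_stoichiometry(table: FeatureTable, meta: pd.DataFrame,
                           annotations: pd.DataFrame, significant_cells: dict,
                           diel: str = "Day") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Weighted NOSC/stoichiometry per producer endpoint sample.

    For each producer, the feature set is its exometabolite features
    significantly enriched in the given diel period that survived the
    formula quality filter; per endpoint replicate of that producer the
    carbon-weighted NOSC, dG_cox, elemental ratios, and ternary class
    shares are computed on relative abundances within that feature set.
    Also returns the z-score-weighted robustness variant.
    """
    good = formula_quality_filter(annotations)
    formulas = formula_map(good)
    rel = relative_abundance(table)
    end = meta[(meta["role"] == "experimental") & (meta["timepoint"] == "end")
               & (meta["diel"] == diel)]
    rows, zrows = [], []
    for producer in PRODUCERS:
        feats = [f for f, cells in significant_cells.items()
                 if (producer, diel) in cells and f in formulas]
        if not feats:
            log.warning("no formula-bearing exometabolites for %s/%s", producer, diel)
            continue
        sids = end.loc[end["treatment"] == producer, "sample_id"].tolist()
        for s in sids:
            st = sample_weighted_nosc(rel, formulas, feats, s)
            rows.append({"treatment": producer, "sample_id": s,
                         "n_features": st.n_features,
                         "weighted_nosc": st.weighted_nosc, "gibbs": st.gibbs,
                         "nc": st.nc, "pc": st.pc, "hc": st.hc, "oc": st.oc,
                         "share_P": st.ternary[0], "share_N_noP": st.ternary[1],
                         "share_CHOS": st.ternary[2],
                         "frac_N": st.frac_n, "frac_P": st.frac_p})
        zv = feature_standardized_weighting(rel, formulas, feats, sids)
        for s, zrow in zv.iterrows():
            zrows.append({"treatment": producer, "sample_id": s,
                          "weighted_nosc": zrow["weighted_nosc"],
                          "gibbs": zrow["gibbs"]})
    return pd.DataFrame(rows), pd.DataFrame(zrows)


# --------------------------------------------------------------------------
# top level
# --------------------------------------------------------------------------

def _hash_config(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig | None = None, *, outdir=None,
                 feature_table: FeatureTable | None = None,
                 metadata: pd.DataFrame | None = None,
                 annotations: pd.DataFrame | None = None,
                 bulk: pd.DataFrame | None = None,
                 simulate: SimulationConfig | None = None,
                 inputs: dict | None = None) -> PipelineResult:
    """Run every stage on supplied tables, file paths, or a simulation.

    Exactly one input route must be given: in-memory tables,
    ``inputs={"features": path, "metadata": path, ...}``, or
    ``simulate=SimulationConfig(...)``.  With ``outdir`` set, all stage
    outputs are written as TSV plus ``manifest.json``.
    """
    cfg = config or PipelineConfig()
    truth = None
    if simulate is not None:
        sim = generate_experiment(simulate)
        feature_table, metadata = sim.feature_table, sim.metadata
        annotations, bulk, truth = sim.annotations, sim.bulk, sim.truth
    elif inputs is not None:
        metadata = read_sample_metadata(inputs["metadata"])
        feature_table = read_feature_table(inputs["features"],
                                           inputs.get("dialect", "native"), metadata)
        annotations = (read_annotations(inputs["annotations"], feature_table.feature_ids)
                       if "annotations" in inputs else None)
        bulk = read_bulk_chemistry(inputs["bulk"]) if "bulk" in inputs else None
    if feature_table is None or metadata is None:
        raise ValueError("missing input: provide tables, paths, or a simulation config")

    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # stage 1-5: cascade
    cascade = classify_features(feature_table, metadata, cfg.cascade)
    exo = cascade.labels.index[cascade.labels == "exometabolite"].tolist()
    categories = treatment_association_categories(cascade.significant_cells, exo)
    summary = class_peak_area_summary(feature_table, cascade.labels, metadata)

    # ordination + PERMANOVA
    ordination = {}
    if exo:
        ordination = ordinate_exometabolomes(
            feature_table, metadata, exo,
            n_perm=cfg.permanova_permutations, seed=cfg.seed)

    # energetics & stoichiometry
    stoich = stoich_z = letters = None
    if annotations is not None and exo:
        stoich, stoich_z = producer_stoichiometry(
            feature_table, metadata, annotations, cascade.significant_cells,
            cfg.stoichiometry_diel)
        if len(stoich) and stoich["treatment"].nunique() >= 2:
            groups = [stoich.loc[stoich["treatment"] == t, "gibbs"].to_numpy()
                      for t in stoich["treatment"].unique()]
            if all(len(g) >= 2 for g in groups):
                tk = tukey_hsd(groups)
                letters = dict(zip(stoich["treatment"].unique(), tk.letters))

    # subnetworks
    subnets = None
    if annotations is not None and annotations["subnetwork_id"].notna().any():
        shares, members = aggregate_subnetworks(feature_table, annotations, cascade)
        enrich = test_subnetwork_enrichment(shares, metadata, cfg.subnetwork_alpha)
        focus = select_focus_subnetworks(
            enrich, shares, members, metadata, min_share=cfg.focus_min_share,
            min_exudate_nodes=cfg.focus_min_exudate_nodes,
            alpha=cfg.focus_alpha, min_fold=cfg.focus_min_fold)
        congr = (subnetwork_class_congruency(categories, annotations)
                 if len(categories) else pd.DataFrame())
        heat = (heatmap_matrix(feature_table, annotations, focus, metadata)
                if focus else pd.DataFrame())
        subnets = {"shares": shares, "members": members, "enrichment": enrich,
                   "focus": focus, "congruency": congr, "heatmap": heat}

    # bulk chemistry
    effects = coupling = stoich_fits = None
    if bulk is not None:
        effects = producer_effect_tests(bulk, metadata)
        coupling = doc_metabolome_coupling(feature_table, cascade.labels, bulk, metadata)
        if stoich is not None and len(stoich):
            idx = stoich.set_index("sample_id")
            try:
                stoich_fits = regress_stoichiometry_vs_bulk(idx, bulk)
            except (ValueError, KeyError) as e:
                log.warning("stoichiometry-vs-bulk regression skipped: %s", e)

    counts = cascade.counts()
    manifest = {
        "package_version": __version__,
        "config_hash": _hash_config(asdict(cfg)),
        "seed": cfg.seed,
        "thresholds": asdict(cfg.cascade),
        "n_features": len(feature_table.data),
        "n_samples": len(feature_table.data.columns),
        "cascade_counts": counts,
        "n_exometabolite": counts["exometabolite"],
        "counts_conserved": sum(counts.values()) == len(feature_table.data),
    }
    if ordination:
        perm = ordination["permanova"]
        manifest["permanova_r2"] = dict(zip(perm.terms, np.round(perm.r2, 4).tolist()))
    if subnets is not None:
        manifest["n_subnetworks"] = int(len(subnets["shares"]))
        manifest["n_focus_subnetworks"] = len(subnets["focus"])

    result = PipelineResult(cascade, categories, summary, ordination, stoich,
                            stoich_z, letters, subnets, effects, coupling,
                            stoich_fits, manifest)
    if out is not None:
        _write_outputs(out, feature_table, metadata, annotations, bulk, truth, result)
    return result


def _write_outputs(out: Path, table, metadata, annotations, bulk, truth,
                   res: PipelineResult) -> None:
    cascade = res.cascade
    cls = cascade.labels.rename("class").to_frame()
    cls = cls.join(cascade.fold_changes)
    cls.index.name = "feature_id"
    cls.to_csv(out / "feature_classification.tsv", sep="\t")
    if len(cascade.tests):
        cascade.tests.to_csv(out / "exometabolite_tests.tsv", sep="\t", index=False)
    res.class_summary.to_csv(out / "class_summary.tsv", sep="\t")
    if len(res.categories):
        res.categories.to_csv(out / "treatment_categories.tsv", sep="\t", index=False)
    if res.stoichiometry is not None:
        res.stoichiometry.to_csv(out / "sample_stoichiometry.tsv", sep="\t", index=False)
    if res.stoichiometry_z is not None and len(res.stoichiometry_z):
        res.stoichiometry_z.to_csv(out / "sample_stoichiometry_zweighted.tsv",
                                   sep="\t", index=False)
    if res.subnetworks is not None:
        res.subnetworks["enrichment"].to_csv(out / "subnetwork_enrichment.tsv",
                                             sep="\t", index=False)
        pd.Series(res.subnetworks["focus"], name="subnetwork_id").to_csv(
            out / "focus_subnetworks.tsv", sep="\t", index=False)
        if len(res.subnetworks["congruency"]):
            res.subnetworks["congruency"].to_csv(out / "congruency.tsv",
                                                 sep="\t", index=False)
        if len(res.subnetworks["heatmap"]):
            res.subnetworks["heatmap"].to_csv(out / "heatmap_matrix.tsv", sep="\t")
    if res.bulk_effects is not None:
        res.bulk_effects.to_csv(out / "bulk_effects.tsv", sep="\t", index=False)
    if res.doc_coupling is not None:
        rows = []
        for kind, fits in (("exudate", res.doc_coupling.exudate),
                           ("ambient", res.doc_coupling.ambient)):
            for diel, fit in fits.items():
                rows.append({"features": kind, "diel": diel, "slope": fit.slope,
                             "intercept": fit.intercept, "r2": fit.r2, "p": fit.p,
                             "n": fit.n})
        pd.DataFrame(rows).to_csv(out / "doc_coupling.tsv", sep="\t", index=False)
    if truth is not None:
        truth.to_csv(out / "truth_labels.tsv", sep="\t", index=False)
        write_feature_table(table, out / "features.tsv")
        write_sample_metadata(metadata, out / "metadata.tsv")
        if annotations is not None:
            write_annotations(annotations, out / "annotations.tsv")
        if bulk is not None:
            write_bulk_chemistry(bulk, out / "bulk_chemistry.tsv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(res.manifest, fh, indent=2, default=str)
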