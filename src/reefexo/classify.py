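"""The five-stage feature-classification cascade.

Order of operations on an aligned feature table with blanks, ambient
(starting reef water) samples, and endpoint incubation samples:

1. **background** — mean peak area over all non-blank samples less than
   twice the maximum peak area over all blanks; removed.
2. **transient** — at or above the detection threshold (2e5, double the
   instrument noise threshold) in fewer than three experimental samples;
   removed.
3. **ambient vs exudate** — exudate iff the log2 ratio of the mean
   endpoint peak area of any (treatment, diel) cell — Controls included —
   to the mean ambient-start peak area exceeds 1 (i.e. at least doubled).
   Means are floored at the noise threshold first so empty ambient
   baselines give finite, conservative ratios.
4. **exometabolite** — exudate features whose relative abundance is
   significantly enriched in at least one producer endpoint vs the
   Control endpoint (one-way ANOVA context, Dunnett many-to-one, BH FDR
   over the pooled feature x producer x diel family, adjusted p < alpha).
5. **subtypes** — remaining exudate features become incubation artifacts
   (doubled vs ambient in both Day and Night Controls), benthic exudates
   (doubled in >= 1 producer incubation), or planktonic exudates (doubled
   in either Control), with precedence artifact > benthic > planktonic.

The cascade conserves counts: background + transient + ambient + exudate
equals the total, and exometabolite + benthic + planktonic + artifact
equals the exudate count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DIELS, PRODUCERS, FeatureTable, relative_abundance
from .stats import bh_fdr, dunnett_sf

log = logging.getLogger(__name__)

__all__ = [
    "CascadeConfig", "CascadeResult",
    "flag_background", "flag_transient", "split_ambient_exudate",
    "test_exometabolites", "classify_exudate_subtypes",
    "class_peak_area_summary", "treatment_association_categories",
    "classify_features",
]

CLASS_LABELS = ("background", "transient", "ambient", "exometabolite",
                "benthic_exudate", "planktonic_exudate", "incubation_artifact")


@dataclass
class CascadeConfig:
    """Every threshold of the cascade, defaulting to the study conventions."""

    noise_floor: float = 1e5
    transient_threshold: float = 2e5
    transient_min_samples: int = 3
    log2_threshold: float = 1.0
    alpha: float = 0.05
    sided: str = "greater"            # enrichment relative to Control
    fdr_family: str = "pooled"        # or "per-diel"
    test_on: str = "relative"         # or "raw"
    anova_gate: bool = False          # gate Dunnett on the omnibus F test


@dataclass
class CascadeResult:
    labels: pd.Series                   # feature_id -> class label
    fold_changes: pd.DataFrame          # feature x (treatment, diel) log2 ratios
    tests: pd.DataFrame                 # tidy Dunnett/FDR table (exudate features)
    significant_cells: dict             # feature_id -> set of (producer, diel)
    config: CascadeConfig

    def counts(self) -> dict:
        return {c: int((self.labels == c).sum()) for c in CLASS_LABELS}


def _experimental(meta: pd.DataFrame) -> pd.DataFrame:
    return meta[meta["role"] == "experimental"]


# --------------------------------------------------------------------------
# stage 1: background
# --------------------------------------------------------------------------

def flag_background(table: FeatureTable, meta: pd.DataFrame) -> list[str]:
    """Features whose non-blank mean is below twice the blank maximum."""
    blanks = meta.loc[meta["role"] == "blank", "sample_id"].tolist()
    if not blanks:
        raise ValueError("background filter undefined without blank samples")
    samples = _experimental(meta)["sample_id"].tolist()
    sample_mean = table.data[samples].mean(axis=1)
    blank_max = table.data[blanks].max(axis=1)
    flagged = table.data.index[sample_mean < 2.0 * blank_max].tolist()
    log.info("background filter removed %d of %d features", len(flagged), len(table.data))
    return flagged


# --------------------------------------------------------------------------
# stage 2: transient
# --------------------------------------------------------------------------

def flag_transient(table: FeatureTable, meta: pd.DataFrame,
                   threshold: float = 2e5, min_samples: int = 3) -> list[str]:
    """Features replicated (>= threshold) in fewer than ``min_samples``
    experimental samples."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    samples = _experimental(meta)["sample_id"].tolist()
    counts = (table.data[samples] >= threshold).sum(axis=1)
    flagged = table.data.index[counts < min_samples].tolist()
    log.info("transient filter removed %d features", len(flagged))
    return flagged


# --------------------------------------------------------------------------
# stage 3: ambient vs exudate
# --------------------------------------------------------------------------

def _cell_log2_ratios(table: FeatureTable, meta: pd.DataFrame,
                      floor: float) -> pd.DataFrame:
    """log2(mean endpoint cell / mean ambient start), means floored first.

    Columns are 'treatment|diel' for every endpoint (treatment, diel)
    cell, Controls included.
    """
    exp = _experimental(meta)
    amb = exp.loc[(exp["treatment"] == "Ambient"), "sample_id"].tolist()
    if not amb:
        raise ValueError("no ambient (starting reef water) samples")
    amb_mean = np.maximum(table.data[amb].mean(axis=1), floor)
    cols = {}
    end = exp[exp["timepoint"] == "end"]
    for trt in ("Control",) + PRODUCERS:
        for diel in DIELS:
            cell = end.loc[(end["treatment"] == trt) & (end["diel"] == diel),
                           "sample_id"].tolist()
            if not cell:
                continue
            cell_mean = np.maximum(table.data[cell].mean(axis=1), floor)
            cols[f"{trt}|{diel}"] = np.log2(cell_mean / amb_mean)
    return pd.DataFrame(cols, index=table.data.index)


def split_ambient_exudate(table: FeatureTable, meta: pd.DataFrame,
                          log2_threshold: float = 1.0, floor: float = 1e5,
                          ) -> tuple[list[str], list[str], pd.DataFrame]:
    """Partition features into (ambient, exudate) by endpoint fold change."""
    ratios = _cell_log2_ratios(table, meta, floor)
    is_exudate = (ratios > log2_threshold).any(axis=1)
    exudate = ratios.index[is_exudate].tolist()
    ambient = ratios.index[~is_exudate].tolist()
    return ambient, exudate, ratios


# --------------------------------------------------------------------------
# stage 4: exometabolites
# --------------------------------------------------------------------------

def test_exometabolites(table: FeatureTable, meta: pd.DataFrame,
                        features, alpha: float = 0.05, *,
                        sided: str = "greater", test_on: str = "relative",
                        fdr_family: str = "pooled", anova_gate: bool = False,
                        ) -> tuple[list[str], pd.DataFrame, dict]:
    """Dunnett-vs-Control enrichment test of exudate features.

    Per diel period the six endpoint groups (Control + five producers)
    enter a pooled-variance many-to-one comparison on per-sample relative
    abundances (``test_on='raw'`` switches to peak areas); adjusted
    p-values are then BH-corrected across the pooled family of all
    features x producers x diel periods.  A feature is an exometabolite
    iff any corrected p falls below ``alpha``.

    Returns the exometabolite ids, the tidy test table, and the
    significant (producer, diel) cells per feature.
    """
    features = list(features)
    exp = _experimental(meta)
    end = exp[exp["timepoint"] == "end"]
    if test_on == "relative":
        values = relative_abundance(table, exp["sample_id"].tolist()).data
    else:
        values = table.data
    rows = []
    for diel in DIELS:
        groups = {}
        for trt in ("Control",) + PRODUCERS:
            cell = end.loc[(end["treatment"] == trt) & (end["diel"] == diel),
                           "sample_id"].tolist()
            if len(cell) < 2:
                raise ValueError(f"group {trt}/{diel} has fewer than 2 replicates")
            groups[trt] = values.loc[features, cell].to_numpy(dtype=float)
        mats = list(groups.values())
        ns = np.array([m.shape[1] for m in mats], dtype=float)
        N, g = ns.sum(), len(mats)
        df = int(N - g)
        means = np.stack([m.mean(axis=1) for m in mats], axis=1)      # nfeat x 6
        ss_w = sum(((m - m.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) for m in mats)
        mse = ss_w / df
        ss_b = ((means - (np.stack([m.sum(axis=1) for m in mats], axis=1).sum(axis=1)
                          / N)[:, None]) ** 2 * ns[None, :]).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            fstat = (ss_b / (g - 1)) / mse
        diffs = means[:, 1:] - means[:, :1]
        se = np.sqrt(mse[:, None] * (1.0 / ns[None, 1:] + 1.0 / ns[0]))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, diffs / se,
                         np.where(diffs > 0, np.inf, np.where(diffs < 0, -np.inf, 0.0)))
        p_dunnett = dunnett_sf(t, ns[1:], ns[0], df, sided=sided)
        degenerate = mse == 0
        if degenerate.any():
            # no residual variance anywhere: p=1 unless means differ exactly
            for i in np.where(degenerate)[0]:
                p_dunnett[i] = np.where(np.isfinite(t[i]), 1.0,
                                        np.where(t[i] > 0, 0.0, 1.0))
        for j, producer in enumerate(PRODUCERS):
            for i, fid in enumerate(features):
                rows.append({"feature_id": fid, "treatment": producer, "diel": diel,
                             "mean_diff": diffs[i, j], "t": t[i, j],
                             "p_dunnett": p_dunnett[i, j],
                             "anova_F": fstat[i], "df": df})
    tests = pd.DataFrame(rows)
    if fdr_family == "pooled":
        tests["p_fdr"] = bh_fdr(tests["p_dunnett"].to_numpy())
    elif fdr_family == "per-diel":
        tests["p_fdr"] = np.nan
        for diel in DIELS:
            m = tests["diel"] == diel
            tests.loc[m, "p_fdr"] = bh_fdr(tests.loc[m, "p_dunnett"].to_numpy())
    else:
        raise ValueError(f"unknown fdr_family {fdr_family!r}")
    sig = tests["p_fdr"] < alpha
    if anova_gate:
        from scipy import stats as sps
        g = 6
        p_anova = pd.Series(sps.f.sf(tests["anova_F"], g - 1, tests["df"]),
                            index=tests.index)
        sig &= p_anova < alpha
    tests["significant"] = sig
    cells: dict[str, set] = {f: set() for f in features}
    for row in tests[tests["significant"]].itertuples(index=False):
        cells[row.feature_id].add((row.treatment, row.diel))
    exo = [f for f in features if cells[f]]
    return exo, tests, cells


# --------------------------------------------------------------------------
# stage 5: subtypes
# --------------------------------------------------------------------------

def classify_exudate_subtypes(fold_changes: pd.DataFrame, exudate_features,
                              exometabolite_set, log2_threshold: float = 1.0,
                              ) -> pd.Series:
    """Label non-exometabolite exudate features by where they doubled.

    ``fold_changes`` is the stage-3 cell table (log2 vs ambient start).
    Precedence: incubation_artifact (doubled in both Controls) > benthic
    (doubled in >= 1 producer incubation) > planktonic (doubled in either
    Control).
    """
    exo = set(exometabolite_set)
    doubled = fold_changes > log2_threshold
    ctrl_day = doubled.get("Control|Day", pd.Series(False, index=doubled.index))
    ctrl_night = doubled.get("Control|Night", pd.Series(False, index=doubled.index))
    prod_cols = [c for c in doubled.columns if not c.startswith("Control|")]
    any_producer = doubled[prod_cols].any(axis=1)
    out = {}
    for fid in exudate_features:
        if fid in exo:
            out[fid] = "exometabolite"
        elif bool(ctrl_day[fid]) and bool(ctrl_night[fid]):
            out[fid] = "incubation_artifact"
        elif bool(any_producer[fid]):
            out[fid] = "benthic_exudate"
        elif bool(ctrl_day[fid]) or bool(ctrl_night[fid]):
            out[fid] = "planktonic_exudate"
        else:
            # cannot happen when the same threshold produced the exudate set
            out[fid] = "benthic_exudate"
    return pd.Series(out, name="subtype")


# --------------------------------------------------------------------------
# summaries
# --------------------------------------------------------------------------

def class_peak_area_summary(table: FeatureTable, labels: pd.Series,
                            meta: pd.DataFrame, *, include_artifacts: bool = False,
                            ) -> pd.DataFrame:
    """Per-sample fraction of total peak area held by each feature class."""
    samples = _experimental(meta)["sample_id"].tolist()
    totals = table.data[samples].sum(axis=0)
    classes = [c for c in CLASS_LABELS
               if include_artifacts or c != "incubation_artifact"]
    rows = {}
    for cls in classes:
        feats = labels.index[labels == cls]
        rows[cls] = table.data.loc[feats, samples].sum(axis=0) / totals
    return pd.DataFrame(rows)


def treatment_association_categories(significant_cells: dict,
                                     exometabolite_set) -> pd.DataFrame:
    """Per-exometabolite source producers and diel activity.

    'unique' means exactly one producer; diel activity is day-only,
    night-only, or both.  The category string is used downstream for the
    congruency analysis.
    """
    rows = []
    for fid in exometabolite_set:
        cells = significant_cells.get(fid, set())
        producers = sorted({t for t, _ in cells})
        diels = {d for _, d in cells}
        activity = ("both" if diels == {"Day", "Night"}
                    else "day-only" if diels == {"Day"} else "night-only")
        rows.append({"feature_id": fid,
                     "producers": "|".join(producers),
                     "n_producers": len(producers),
                     "diel_activity": activity,
                     "category": "|".join(producers) + "//" + activity,
                     "unique": len(producers) == 1,
                     "all_producers": len(producers) == len(PRODUCERS)})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# full cascade
# --------------------------------------------------------------------------

def classify_features(table: FeatureTable, meta: pd.DataFrame,
                      config: CascadeConfig | None = None) -> CascadeResult:
    """Run the complete cascade and return per-feature labels."""
    cfg = config or CascadeConfig()
    labels = pd.Series("", index=table.data.index, name="class", dtype=object)

    bg = flag_background(table, meta)
    labels[bg] = "background"
    remaining = labels.index[labels == ""]

    trans = flag_transient(table.subset_features(remaining), meta,
                           cfg.transient_threshold, cfg.transient_min_samples)
    labels[trans] = "transient"
    remaining = labels.index[labels == ""]

    ambient, exudate, ratios = split_ambient_exudate(
        table.subset_features(remaining), meta, cfg.log2_threshold, cfg.noise_floor)
    labels[ambient] = "ambient"

    if exudate:
        exo, tests, cells = test_exometabolites(
            table, meta, exudate, cfg.alpha, sided=cfg.sided,
            test_on=cfg.test_on, fdr_family=cfg.fdr_family,
            anova_gate=cfg.anova_gate)
        subtype = classify_exudate_subtypes(ratios, exudate, exo, cfg.log2_threshold)
        labels[subtype.index] = subtype
    else:
        tests = pd.DataFrame()
        cells = {}
    log.info("cascade counts: %s",
             {c: int((labels == c).sum()) for c in CLASS_LABELS})
    return CascadeResult(labels=labels, fold_changes=ratios, tests=tests,
                         significant_cells=cells, config=cfg)
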