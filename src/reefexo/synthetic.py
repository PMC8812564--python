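"""Synthetic benthic-exudation experiments with planted ground truth.

Emulates the study design the analysis pipeline expects: triplicate 8-h
daytime and nighttime incubations of five benthic primary producers
(Porites, Pocillopora, CCA, Dictyota, Turf) plus filtered-seawater
Controls, triplicate ambient starting reef water per diel period, and
eight process blanks — 42 experimental samples and 8 blanks.

Feature classes are planted explicitly so the full classification cascade
is testable against known labels:

``background``
    present in the blanks at a configurable fraction (>= 1/2) of their
    sample intensity, so the 2x-max-blank rule recovers them;
``transient``
    above the detection threshold in fewer than three experimental
    samples;
``ambient``
    constant (up to noise) from start to end of every incubation;
``exometabolite``
    enriched in the endpoint samples of 1-5 source producers with
    lognormal fold changes centred on 40 (geometric SD 5, truncated to a
    realistic dynamic range);
``benthic_exudate``
    enriched in one producer but with highly variable (CV ~ 2) replicate
    responses attached to the incubation itself — the irreproducible
    enrichments the strict Dunnett criterion is designed to reject;
``planktonic_exudate``
    enriched in the Day or Night Control incubations only;
``incubation_artifact``
    enriched in both Day and Night Controls (and all incubations).

Noise model: multiplicative mean-preserving lognormal on the expected
intensity plus a small additive detector floor, truncated at zero.
Formulas follow per-compound-class templates whose O:C / H:C / N:C / P:C
marginals give each producer a distinct stoichiometric and energetic
signature; bulk DOC covaries linearly with the summed exudate peak area
at a configurable R².

A single seed drives everything through named SeedSequence substreams, so
outputs are bit-reproducible and adding one component does not perturb
the draws of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chem import FormulaRecord
from .io import DIELS, PRODUCERS, FeatureTable

__all__ = [
    "SimulationConfig",
    "SyntheticExperiment",
    "generate_experiment",
    "generate_formula",
    "generate_bulk_chemistry",
    "FORMULA_TEMPLATES",
]

FORMULA_TEMPLATES = ("lipid_like", "sugar_like", "peptide_like", "P_rich", "N_heterocycle")

#: structural-class vocabulary attached to annotated features per template
TEMPLATE_CLASS = {
    "lipid_like": "Fatty acyls",
    "sugar_like": "Carbohydrates",
    "peptide_like": "Peptides",
    "P_rich": "Organophosphates",
    "N_heterocycle": "Alkaloids",
}

_MONO = {"C": 12.0, "H": 1.007825, "N": 14.003074, "O": 15.994915,
         "P": 30.973762, "S": 31.972071}


@dataclass
class SimulationConfig:
    """All knobs of the generator, defaulting to the study conditions."""

    # features per planted class
    n_background: int = 150
    n_transient: int = 100
    n_ambient: int = 300
    n_exometabolite: int = 250
    n_benthic: int = 150
    n_planktonic: int = 80
    n_artifact: int = 40

    replicates: int = 3
    n_blanks: int = 8

    # noise
    sigma: float = 0.3               # lognormal ln-SD of replicate intensities
    sigma_benthic: float = 1.5       # response noise of marginal benthic exudates
    additive_noise: float = 2e3      # SD of the additive detector floor term
    noise_floor: float = 1e5         # instrument noise threshold (XIC units)
    transient_threshold: float = 2e5 # double the noise threshold

    # intensities (XIC area units; medians of per-feature lognormals)
    ambient_median: float = 3e6
    ambient_gsd: float = np.e        # geometric SD of per-feature baselines
    background_median: float = 8e5
    transient_median: float = 1e6
    exo_baseline_median: float = 2e5
    benthic_baseline_median: float = 4e5
    planktonic_baseline_median: float = 4e5
    artifact_baseline_median: float = 3e5
    baseline_gsd: float = 1.8
    blank_fraction: float = 0.7      # background level in blanks vs samples

    # planted effects
    exo_fold_median: float = 40.0    # lognormal median of exometabolite folds
    exo_fold_gsd: float = 5.0        # geometric SD ("SD fivefold")
    exo_fold_range: tuple = (5.0, 150.0)
    benthic_fold_range: tuple = (4.5, 8.0)
    control_fold_range: tuple = (2.5, 5.0)  # planktonic + artifact enrichment
    # fraction of exometabolites with 1/2/3/5 source producers
    source_count_probs: tuple = (0.86, 0.10, 0.03, 0.01)
    diel_probs: tuple = (0.6, 0.1, 0.3)     # day-only, night-only, both
    # per-producer exudation scale (Turf strongest, Porites weakest)
    producer_scale: dict = field(default_factory=lambda: {
        "Porites": 0.5, "Pocillopora": 1.1, "CCA": 0.8,
        "Dictyota": 1.2, "Turf": 1.6})
    # dominant formula template per producer and its mixture weight;
    # the remainder draws from shared primary-metabolite pools
    producer_template: dict = field(default_factory=lambda: {
        "Porites": "peptide_like", "Pocillopora": "P_rich", "CCA": "sugar_like",
        "Dictyota": "lipid_like", "Turf": "N_heterocycle"})
    shared_templates: tuple = ("sugar_like", "peptide_like")
    template_dominance: float = 0.7
    formula_coverage: float = 0.85   # fraction of features with any formula
    quality_good_fraction: float = 0.75
    networked_fraction: float = 0.66 # exometabolite features in subnetworks
    subnetwork_size: int = 8

    # bulk chemistry
    doc_baseline: float = 75.0       # uM C in ambient reef water
    doc_r2_day: float = 0.84
    doc_r2_night: float = 0.63
    doc_turf_release: float = 46.0   # uM above Control in Turf endpoints

    seed: int = 0

    def class_counts(self) -> dict:
        return {
            "background": self.n_background, "transient": self.n_transient,
            "ambient": self.n_ambient, "exometabolite": self.n_exometabolite,
            "benthic_exudate": self.n_benthic, "planktonic_exudate": self.n_planktonic,
            "incubation_artifact": self.n_artifact,
        }


@dataclass
class SyntheticExperiment:
    feature_table: FeatureTable
    metadata: pd.DataFrame
    annotations: pd.DataFrame
    bulk: pd.DataFrame
    truth: pd.DataFrame


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named substream of the global seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(stream.encode())]))


# --------------------------------------------------------------------------
# design
# --------------------------------------------------------------------------

def _build_metadata(cfg: SimulationConfig) -> pd.DataFrame:
    rows = []
    for diel in DIELS:
        for r in range(1, cfg.replicates + 1):
            rows.append({"sample_id": f"Ambient_{diel}_r{r}", "role": "experimental",
                         "treatment": "Ambient", "diel": diel, "timepoint": "start",
                         "replicate": r})
    for trt in ("Control",) + PRODUCERS:
        for diel in DIELS:
            for r in range(1, cfg.replicates + 1):
                rows.append({"sample_id": f"{trt}_{diel}_end_r{r}", "role": "experimental",
                             "treatment": trt, "diel": diel, "timepoint": "end",
                             "replicate": r})
    for b in range(1, cfg.n_blanks + 1):
        rows.append({"sample_id": f"Blank_{b}", "role": "blank", "treatment": np.nan,
                     "diel": np.nan, "timepoint": np.nan, "replicate": b})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# formulas
# --------------------------------------------------------------------------

def generate_formula(template_name: str, rng: np.random.Generator) -> FormulaRecord:
    """Draw one molecular formula from a compound-class template.

    Templates fix the marginal means of the elemental ratios: lipid-like
    formulas have O:C near 0.15 and H:C near 1.8 (NOSC around -1.5),
    sugar-like formulas land near NOSC 0, P-rich formulas always carry at
    least one phosphorus.
    """
    if template_name not in FORMULA_TEMPLATES:
        raise ValueError(f"unknown formula template {template_name!r}")
    if template_name == "lipid_like":
        a = int(np.clip(round(rng.normal(18, 4)), 10, 30))
        oc = np.clip(rng.normal(0.15, 0.05), 0.02, 0.35)
        hc = np.clip(rng.normal(1.80, 0.12), 1.3, 2.1)
        n = 1 if rng.random() < 0.10 else 0
        p, s = 0, int(rng.random() < 0.05)
    elif template_name == "sugar_like":
        a = int(rng.integers(6, 13))
        oc = np.clip(rng.normal(0.95, 0.08), 0.6, 1.1)
        hc = np.clip(rng.normal(1.90, 0.08), 1.6, 2.1)
        n, p, s = 0, 0, 0
    elif template_name == "peptide_like":
        a = int(rng.integers(10, 26))
        oc = np.clip(rng.normal(0.30, 0.05), 0.15, 0.5)
        hc = np.clip(rng.normal(1.60, 0.10), 1.2, 2.0)
        n = max(1, int(round(np.clip(rng.normal(0.27, 0.05), 0.05, 0.45) * a)))
        p, s = 0, int(rng.random() < 0.10)
    elif template_name == "P_rich":
        a = int(rng.integers(10, 25))
        oc = np.clip(rng.normal(0.55, 0.08), 0.35, 0.8)
        hc = np.clip(rng.normal(1.40, 0.12), 1.0, 1.8)
        n = int(round(np.clip(rng.normal(0.10, 0.05), 0.0, 0.3) * a))
        p = 1 + int(rng.random() < 0.15)
        s = 0
    else:  # N_heterocycle
        a = int(rng.integers(8, 17))
        oc = np.clip(rng.normal(0.25, 0.05), 0.1, 0.45)
        hc = np.clip(rng.normal(1.20, 0.10), 0.8, 1.6)
        n = max(1, int(round(np.clip(rng.normal(0.35, 0.08), 0.1, 0.6) * a)))
        p, s = 0, 0
    o = max(0, int(round(oc * a)))
    h = int(round(hc * a))
    h = int(np.clip(h, 1, 2 * a + 2 + n))   # valence bound
    return FormulaRecord(c=a, h=h, n=n, o=o, p=p, s=s)


def _mono_mass(f: FormulaRecord) -> float:
    return (f.c * _MONO["C"] + f.h * _MONO["H"] + f.n * _MONO["N"]
            + f.o * _MONO["O"] + f.p * _MONO["P"] + f.s * _MONO["S"])


# --------------------------------------------------------------------------
# truth construction
# --------------------------------------------------------------------------

def _plant_truth(cfg: SimulationConfig) -> pd.DataFrame:
    rng_cls = _rng(cfg.seed, "classes")
    rows = []
    fid = 0
    for cls, count in cfg.class_counts().items():
        for _ in range(count):
            fid += 1
            row = {"feature_id": f"F{fid:05d}", "planted_class": cls,
                   "source_treatments": "", "diel_activity": "",
                   "planted_fold_change": 1.0, "formula_template": ""}
            if cls == "exometabolite":
                k = rng_cls.choice([1, 2, 3, 5], p=cfg.source_count_probs)
                src = sorted(rng_cls.choice(PRODUCERS, size=k, replace=False))
                diel = rng_cls.choice(["day", "night", "both"], p=cfg.diel_probs)
                lo, hi = cfg.exo_fold_range
                fold = float(np.clip(
                    cfg.exo_fold_median * np.exp(rng_cls.normal(0.0, np.log(cfg.exo_fold_gsd))),
                    lo, hi))
                row.update(source_treatments="|".join(src), diel_activity=diel,
                           planted_fold_change=fold)
            elif cls == "benthic_exudate":
                src = [rng_cls.choice(PRODUCERS)]
                fold = float(rng_cls.uniform(*cfg.benthic_fold_range))
                row.update(source_treatments=src[0], diel_activity="both",
                           planted_fold_change=fold)
            elif cls == "planktonic_exudate":
                diel = rng_cls.choice(["day", "night"])
                fold = float(rng_cls.uniform(*cfg.control_fold_range))
                row.update(diel_activity=diel, planted_fold_change=fold)
            elif cls == "incubation_artifact":
                fold = float(rng_cls.uniform(*cfg.control_fold_range))
                row.update(diel_activity="both", planted_fold_change=fold)
            rows.append(row)
    truth = pd.DataFrame(rows)

    # formula templates: exometabolites lean toward their producer's class
    rng_tpl = _rng(cfg.seed, "templates")
    templates = []
    for _, row in truth.iterrows():
        if row["planted_class"] == "exometabolite":
            dominant = cfg.producer_template[row["source_treatments"].split("|")[0]]
            if rng_tpl.random() < cfg.template_dominance:
                templates.append(dominant)
            else:
                shared = [t for t in cfg.shared_templates if t != dominant]
                templates.append(rng_tpl.choice(shared or list(cfg.shared_templates)))
        else:
            templates.append(rng_tpl.choice(FORMULA_TEMPLATES))
    truth["formula_template"] = templates
    return truth


# --------------------------------------------------------------------------
# intensities
# --------------------------------------------------------------------------

def _expected_matrix(cfg: SimulationConfig, truth: pd.DataFrame,
                     meta: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expected (noise-free) intensity per feature x sample, plus sigma and
    transient sample assignments."""
    rng = _rng(cfg.seed, "baselines")
    samples = meta["sample_id"].to_numpy()
    is_blank = (meta["role"] == "blank").to_numpy()
    trt = meta["treatment"].to_numpy(dtype=object)
    diel = meta["diel"].to_numpy(dtype=object)
    tp = meta["timepoint"].to_numpy(dtype=object)
    nF, nS = len(truth), len(samples)
    mu = np.zeros((nF, nS))
    sigma = np.full((nF, nS), cfg.sigma)

    med = {
        "background": cfg.background_median, "transient": cfg.transient_median,
        "ambient": cfg.ambient_median, "exometabolite": cfg.exo_baseline_median,
        "benthic_exudate": cfg.benthic_baseline_median,
        "planktonic_exudate": cfg.planktonic_baseline_median,
        "incubation_artifact": cfg.artifact_baseline_median,
    }
    gsd = {"ambient": cfg.ambient_gsd}
    exp_idx = ~is_blank
    end_mask = (tp == "end")

    diel_map = {"day": ("Day",), "night": ("Night",), "both": ("Day", "Night")}
    for i, row in enumerate(truth.itertuples(index=False)):
        cls = row.planted_class
        g = gsd.get(cls, cfg.baseline_gsd)
        base = med[cls] * np.exp(rng.normal(0.0, np.log(g)))
        if cls == "background":
            mu[i, exp_idx] = base
            mu[i, is_blank] = cfg.blank_fraction * base
        elif cls == "transient":
            present = rng.choice(np.where(exp_idx)[0], size=2, replace=False)
            mu[i, present] = base
        elif cls == "ambient":
            mu[i, exp_idx] = base
        elif cls == "exometabolite":
            mu[i, exp_idx] = base
            srcs = row.source_treatments.split("|")
            for s in srcs:
                for d in diel_map[row.diel_activity]:
                    cell = end_mask & (trt == s) & (diel == d)
                    mu[i, cell] = base * row.planted_fold_change * cfg.producer_scale[s]
        elif cls == "benthic_exudate":
            mu[i, exp_idx] = base
            s = row.source_treatments
            cell = end_mask & (trt == s)
            mu[i, cell] = base * row.planted_fold_change
            # noise rides on the incubation response, not the baseline
            sigma[i, cell] = cfg.sigma_benthic
        elif cls == "planktonic_exudate":
            mu[i, exp_idx] = base
            d = row.diel_activity.capitalize()
            cell = end_mask & (trt == "Control") & (diel == d)
            mu[i, cell] = base * row.planted_fold_change
        elif cls == "incubation_artifact":
            mu[i, exp_idx] = base
            mu[i, end_mask] = base * row.planted_fold_change
    return mu, sigma, samples


def _apply_noise(cfg: SimulationConfig, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    rng = _rng(cfg.seed, "noise")
    z = rng.normal(0.0, 1.0, size=mu.shape)
    vals = mu * np.exp(sigma * z - sigma**2 / 2.0)  # mean-preserving
    vals = vals + rng.normal(0.0, cfg.additive_noise, size=mu.shape)
    return np.clip(vals, 0.0, None)


# --------------------------------------------------------------------------
# annotations
# --------------------------------------------------------------------------

def _build_annotations(cfg: SimulationConfig, truth: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    rng = _rng(cfg.seed, "annotations")
    n = len(truth)
    formulas: dict[str, FormulaRecord] = {}
    rows = []

    # subnetworks: chunk each producer's exometabolite features; a share of
    # ambient/planktonic features also network (non-exudate families)
    subnet_of: dict[str, int] = {}
    next_id = 1
    exo = truth[truth["planted_class"] == "exometabolite"]
    for producer in PRODUCERS:
        fids = [r.feature_id for r in exo.itertuples(index=False)
                if r.source_treatments.split("|")[0] == producer]
        keep = [f for f in fids if rng.random() < cfg.networked_fraction]
        for start in range(0, len(keep), cfg.subnetwork_size):
            chunk = keep[start:start + cfg.subnetwork_size]
            if len(chunk) < 2:
                continue
            for f in chunk:
                subnet_of[f] = next_id
            next_id += 1
    other = truth[truth["planted_class"].isin(["ambient", "planktonic_exudate"])]
    pool = [f for f in other["feature_id"] if rng.random() < 0.4]
    for start in range(0, len(pool), 10):
        chunk = pool[start:start + 10]
        if len(chunk) < 2:
            continue
        for f in chunk:
            subnet_of[f] = next_id
        next_id += 1

    for row in truth.itertuples(index=False):
        fid = row.feature_id
        rec = {"feature_id": fid, "formula": np.nan, "zodiac_score": np.nan,
               "chimeric": np.nan, "tree_fragments_explained": np.nan,
               "tree_intensity_explained": np.nan,
               "subnetwork_id": subnet_of.get(fid, np.nan),
               "structural_class": np.nan, "library_match": np.nan}
        if rng.random() < cfg.formula_coverage:
            f = generate_formula(row.formula_template, rng)
            formulas[fid] = f
            rec["formula"] = str(f)
            if rng.random() < cfg.quality_good_fraction:
                rec.update(zodiac_score=float(rng.uniform(0.981, 1.0)),
                           chimeric=bool(rng.random() < 0.05),
                           tree_fragments_explained=int(5 + rng.poisson(8)),
                           tree_intensity_explained=float(rng.uniform(0.81, 0.99)))
            else:
                rec.update(zodiac_score=float(rng.uniform(0.5, 0.98)),
                           chimeric=bool(rng.random() < 0.4),
                           tree_fragments_explained=int(rng.poisson(4)),
                           tree_intensity_explained=float(rng.uniform(0.3, 0.85)))
            if rng.random() < 0.6:
                rec["structural_class"] = TEMPLATE_CLASS[row.formula_template]
            if rng.random() < 0.25:
                rec["library_match"] = f"lib:{TEMPLATE_CLASS[row.formula_template]}"
        rows.append(rec)
    ann = pd.DataFrame(rows)
    ann["formula_record"] = [formulas.get(f) for f in ann["feature_id"]]
    ann["subnetwork_id"] = ann["subnetwork_id"].astype("Int64")
    return ann, formulas


# --------------------------------------------------------------------------
# bulk chemistry
# --------------------------------------------------------------------------

def generate_bulk_chemistry(feature_table: FeatureTable, truth: pd.DataFrame,
                            meta: pd.DataFrame, cfg: SimulationConfig,
                            formulas: dict | None = None) -> pd.DataFrame:
    """Bulk biogeochemistry coupled to the planted metabolite signal.

    DOC is an affine function of the summed exudate-class peak area, with
    Gaussian noise scaled so the realized day/night coefficient of
    determination lands near the configured targets.  TDN and TDP derive
    from the per-sample exometabolite-weighted N:C and P:C, so organic
    nutrient stoichiometry genuinely predicts the bulk pools.
    """
    rng = _rng(cfg.seed, "bulk")
    exp = meta[meta["role"] == "experimental"]
    sids = exp["sample_id"].tolist()
    exudate_cls = {"exometabolite", "benthic_exudate", "planktonic_exudate",
                   "incubation_artifact"}
    exu_feats = truth.loc[truth["planted_class"].isin(exudate_cls), "feature_id"]
    sums = feature_table.data.loc[exu_feats, sids].sum(axis=0)

    # per-sample exometabolite-weighted N:C and P:C from planted formulas
    if formulas is None:
        formulas = {}
    exo_feats = [f for f in truth.loc[truth["planted_class"] == "exometabolite",
                                      "feature_id"] if f in formulas]
    nc = pd.Series(0.05, index=sids)
    pc = pd.Series(0.01, index=sids)
    if exo_feats:
        mat = feature_table.data.loc[exo_feats, sids].to_numpy()
        ncs = np.array([formulas[f].n / formulas[f].c for f in exo_feats])
        pcs = np.array([formulas[f].p / formulas[f].c for f in exo_feats])
        tot = mat.sum(axis=0)
        tot[tot == 0] = 1.0
        nc = pd.Series((mat * ncs[:, None]).sum(axis=0) / tot, index=sids)
        pc = pd.Series((mat * pcs[:, None]).sum(axis=0) / tot, index=sids)

    # DOC slope anchored so mean Turf-endpoint release matches config
    end = exp[exp["timepoint"] == "end"]
    turf = end.loc[end["treatment"] == "Turf", "sample_id"]
    ctrl = end.loc[end["treatment"] == "Control", "sample_id"]
    denom = sums[turf].mean() - sums[ctrl].mean()
    slope = cfg.doc_turf_release / denom if denom > 0 else 0.0
    doc = cfg.doc_baseline + slope * sums
    for d, r2 in (("Day", cfg.doc_r2_day), ("Night", cfg.doc_r2_night)):
        cell = end.loc[end["diel"] == d, "sample_id"]
        signal_sd = doc[cell].std(ddof=1)
        noise_sd = signal_sd * np.sqrt(max(1.0 / r2 - 1.0, 0.0)) if r2 > 0 else 0.0
        doc[cell] = doc[cell] + rng.normal(0.0, noise_sd, size=len(cell))
    amb = exp.loc[exp["timepoint"] == "start", "sample_id"]
    doc[amb] = doc[amb] + rng.normal(0.0, 1.0, size=len(amb))

    # inorganic nutrients with coral-leaning planted effects
    def per_sample(base, effects, sd):
        out = pd.Series(base, index=sids, dtype=float)
        for trt_name, delta in effects.items():
            cell = end.loc[end["treatment"] == trt_name, "sample_id"]
            out[cell] += delta
        return (out + rng.normal(0.0, sd, size=len(sids))).clip(lower=0.0)

    po4 = per_sample(0.20, {"Porites": 0.25, "Pocillopora": 0.35}, 0.03)
    no3 = per_sample(0.60, {"Porites": 0.30, "Pocillopora": 0.40,
                            "CCA": -0.10, "Dictyota": -0.15, "Turf": -0.15}, 0.06)
    nh4 = per_sample(0.30, {"Pocillopora": 0.30}, 0.04)
    sil = per_sample(2.0, {}, 0.15)
    don = (0.5 + 80.0 * nc + rng.normal(0.0, 0.4, size=len(sids))).clip(lower=0.2)
    dop = (0.05 + 20.0 * pc + rng.normal(0.0, 0.05, size=len(sids))).clip(lower=0.02)
    tdn = no3 + nh4 + don
    tdp = po4 + dop

    # oxygen / pH: photosynthesis by day, respiration by night
    do = pd.Series(210.0, index=sids, dtype=float)
    ph = pd.Series(8.05, index=sids, dtype=float)
    day_do = {"Turf": 60.0, "Dictyota": 45.0, "CCA": 35.0, "Porites": 10.0,
              "Pocillopora": 12.0}
    night_do = {"Turf": -50.0, "Porites": -18.0, "Pocillopora": -20.0,
                "Dictyota": -10.0, "CCA": -8.0}
    for d, table in (("Day", day_do), ("Night", night_do)):
        for trt_name, delta in table.items():
            cell = end[(end["treatment"] == trt_name) & (end["diel"] == d)]["sample_id"]
            do[cell] += delta
            ph[cell] += delta / 500.0
    do += rng.normal(0.0, 6.0, size=len(sids))
    ph += rng.normal(0.0, 0.015, size=len(sids))

    bulk = pd.DataFrame({
        "DO": do, "pH": ph, "DOC": doc, "PO4": po4, "NO3NO2": no3, "NH4": nh4,
        "silicate": sil, "TDN": tdn, "TDP": tdp, "DON": don, "DOP": dop,
    })
    bulk.index.name = "sample_id"
    return bulk


# --------------------------------------------------------------------------
# top level
# --------------------------------------------------------------------------

def generate_experiment(cfg: SimulationConfig | None = None, **overrides) -> SyntheticExperiment:
    """Generate one complete synthetic experiment.

    Deterministic given ``cfg.seed``; pass keyword overrides to tweak a
    default config in place (``generate_experiment(seed=7)``).
    """
    if cfg is None:
        cfg = SimulationConfig()
    if overrides:
        cfg = replace(cfg, **overrides)
    if cfg.replicates < 2:
        raise ValueError("replicates must be >= 2 for grouped tests")
    meta = _build_metadata(cfg)
    truth = _plant_truth(cfg)
    mu, sigma, samples = _expected_matrix(cfg, truth, meta)
    vals = _apply_noise(cfg, mu, sigma)
    data = pd.DataFrame(vals, index=truth["feature_id"].tolist(), columns=samples)
    data.index.name = "feature_id"
    ann, formulas = _build_annotations(cfg, truth)
    mz = pd.Series({fid: (_mono_mass(f) + 1.00728) for fid, f in formulas.items()})
    rt_rng = _rng(cfg.seed, "rt")
    rt = pd.Series(rt_rng.uniform(0.5, 12.0, size=len(truth)),
                   index=truth["feature_id"].tolist())
    mz = mz.reindex(data.index)
    table = FeatureTable(data, mz=mz, rt=rt)
    bulk = generate_bulk_chemistry(table, truth, meta, cfg, formulas)
    return SyntheticExperiment(table, meta, ann, bulk, truth)
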