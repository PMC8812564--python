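"""Molecular formulas, carbon oxidation state, and exometabolome stoichiometry.

The nominal oxidation state of carbon (NOSC, also written Z_C) of a neutral
CHNOPS molecule with counts (a=C, b=H, c=N, d=O, e=P, f=S) and net charge Z
is

    NOSC = 4 - (-Z + 4a + b - 3c - 2d + 5e - 2f) / a

ranging from -4 (methane) to +4 (CO2).  More reduced carbon (lower NOSC)
yields more free energy on complete oxidation; the standard Gibbs energy
of the carbon-oxidation half reaction at 298 K is approximated by the
linear relation of LaRowe & Van Cappellen (2011),

    dG_cox = 60.3 - 28.5 * NOSC   [kJ (mol C)^-1].

Per-sample summaries weight each formula-bearing exometabolite feature by
its XIC abundance: NOSC by carbon content (abundance x C count), elemental
ratios (N:C, P:C, H:C, O:C) by plain abundance of the per-molecule ratio.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import linear_fit

__all__ = [
    "FormulaRecord",
    "SampleStoichiometry",
    "parse_formula",
    "formula_quality_filter",
    "nosc",
    "gibbs_cox",
    "sample_weighted_nosc",
    "sample_stoichiometry",
    "feature_standardized_weighting",
    "regress_stoichiometry_vs_bulk",
    "GIBBS_INTERCEPT",
    "GIBBS_SLOPE",
]

#: affine constants of the NOSC -> dG_cox relation, kJ (mol C)^-1
GIBBS_INTERCEPT = 60.3
GIBBS_SLOPE = -28.5

_CHNOPS = ("C", "H", "N", "O", "P", "S")
_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
_CHARGE = re.compile(r"([+-])(\d*)$")   # trailing "+", "-", "+2", "-2", ...


@dataclass(frozen=True)
class FormulaRecord:
    """Element counts of a molecular formula (Hill notation source)."""

    c: int = 0
    h: int = 0
    n: int = 0
    o: int = 0
    p: int = 0
    s: int = 0
    charge: int = 0
    non_chnops: bool = False     # contains elements outside C,H,N,O,P,S

    def __str__(self) -> str:
        parts = []
        for sym, cnt in zip(_CHNOPS, (self.c, self.h, self.n, self.o, self.p, self.s)):
            if cnt == 1:
                parts.append(sym)
            elif cnt > 1:
                parts.append(f"{sym}{cnt}")
        return "".join(parts)


def parse_formula(text: str) -> FormulaRecord:
    """Parse a Hill-notation molecular formula with optional trailing charge.

    Elements outside CHNOPS do not raise but flag the record
    ``non_chnops``; such records are excluded from NOSC downstream.
    A string that is not a formula at all raises ``ValueError``.
    """
    if not isinstance(text, str) or not text.strip():
        raise ValueError(f"malformed formula: {text!r}")
    body = text.strip()
    charge = 0
    m = _CHARGE.search(body)
    if m:
        charge = int(m.group(2) or "1") * (1 if m.group(1) == "+" else -1)
        body = body[: m.start()]
    counts: dict[str, int] = {}
    pos = 0
    other = False
    for m in _TOKEN.finditer(body):
        if m.start() != pos:
            raise ValueError(f"malformed formula: {text!r}")
        pos = m.end()
        sym, num = m.group(1), m.group(2)
        cnt = int(num) if num else 1
        if sym in _CHNOPS:
            counts[sym] = counts.get(sym, 0) + cnt
        else:
            other = True
    if pos != len(body) or (not counts and not other):
        raise ValueError(f"malformed formula: {text!r}")
    return FormulaRecord(
        c=counts.get("C", 0), h=counts.get("H", 0), n=counts.get("N", 0),
        o=counts.get("O", 0), p=counts.get("P", 0), s=counts.get("S", 0),
        charge=charge, non_chnops=other,
    )


def nosc(formula: FormulaRecord) -> float:
    """Nominal oxidation state of carbon of a CHNOPS formula."""
    if formula.c < 1:
        raise ValueError("NOSC undefined without carbon")
    a, b, c, d, e, f = formula.c, formula.h, formula.n, formula.o, formula.p, formula.s
    return 4.0 - (-formula.charge + 4 * a + b - 3 * c - 2 * d + 5 * e - 2 * f) / a


def gibbs_cox(nosc_value: float, *, intercept: float = GIBBS_INTERCEPT,
              slope: float = GIBBS_SLOPE) -> float:
    """Standard Gibbs energy of carbon oxidation, kJ (mol C)^-1.

    Strictly decreasing in NOSC: reduced molecules carry more potential
    catabolic energy.
    """
    return intercept + slope * nosc_value


# --------------------------------------------------------------------------
# annotation quality filter
# --------------------------------------------------------------------------

_QUALITY_FIELDS = ("zodiac_score", "chimeric",
                   "tree_fragments_explained", "tree_intensity_explained")


def formula_quality_filter(annotations: pd.DataFrame) -> pd.DataFrame:
    """Retain only annotations whose formula assignment is high quality.

    Keep a row iff ZODIAC score > 0.98, the consensus spectrum is not
    chimeric, and the best fragmentation tree explains > 4 fragments and
    > 80% of spectral intensity.  Rows missing any quality field are
    excluded with a warning.  Pure predicate: order-independent and
    idempotent.
    """
    ann = annotations
    missing = ann[list(_QUALITY_FIELDS)].isna().any(axis=1) | ann["formula"].isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} annotation(s) missing quality fields; excluded")
    ok = (
        ~missing
        & (ann["zodiac_score"] > 0.98)
        & (~ann["chimeric"].astype("boolean").fillna(True).astype(bool))
        & (ann["tree_fragments_explained"] > 4)
        & (ann["tree_intensity_explained"] > 0.80)
    )
    return ann.loc[ok.fillna(False)]


# --------------------------------------------------------------------------
# per-sample weighted summaries
# --------------------------------------------------------------------------

@dataclass
class SampleStoichiometry:
    sample_id: str
    n_features: int
    weighted_nosc: float
    gibbs: float                 # kJ (mol C)^-1
    nc: float                    # weighted mean N:C per molecule
    pc: float
    hc: float
    oc: float
    ternary: tuple[float, float, float]   # (P-containing, N-not-P, CHO(S)-only)
    frac_n: float                # abundance fraction of N-containing molecules
    frac_p: float


def _gather(feature_table, formulas: dict, features, sample: str):
    """Abundances and formula arrays for the usable features of one sample."""
    feats = [f for f in features
             if f in formulas and not formulas[f].non_chnops and formulas[f].c >= 1]
    if not feats:
        raise ValueError(f"no formula-bearing exometabolite features for sample {sample!r}")
    ab = feature_table.data.loc[feats, sample].to_numpy(dtype=float)
    recs = [formulas[f] for f in feats]
    return feats, ab, recs


def _stoich_from_weights(sample, feats, ab, recs, nosc_weights) -> SampleStoichiometry:
    a = np.array([r.c for r in recs], dtype=float)
    zc = np.array([nosc(r) for r in recs])
    wn = nosc_weights
    if wn.sum() <= 0:
        raise ValueError(f"all-zero weights for sample {sample!r}")
    wnosc = float((wn * zc).sum() / wn.sum())
    w = ab
    if w.sum() <= 0:
        raise ValueError(f"zero total abundance for sample {sample!r}")
    ratios = {
        "nc": np.array([r.n for r in recs]) / a,
        "pc": np.array([r.p for r in recs]) / a,
        "hc": np.array([r.h for r in recs]) / a,
        "oc": np.array([r.o for r in recs]) / a,
    }
    wm = {k: float((w * v).sum() / w.sum()) for k, v in ratios.items()}
    has_p = np.array([r.p >= 1 for r in recs])
    has_n = np.array([r.n >= 1 for r in recs])
    cls_p = float(w[has_p].sum() / w.sum())
    cls_n = float(w[has_n & ~has_p].sum() / w.sum())
    cls_cho = float(w[~has_n & ~has_p].sum() / w.sum())
    return SampleStoichiometry(
        sample_id=sample, n_features=len(feats),
        weighted_nosc=wnosc, gibbs=gibbs_cox(wnosc),
        nc=wm["nc"], pc=wm["pc"], hc=wm["hc"], oc=wm["oc"],
        ternary=(cls_p, cls_n, cls_cho), frac_n=float(w[has_n].sum() / w.sum()),
        frac_p=float(w[has_p].sum() / w.sum()),
    )


def sample_weighted_nosc(feature_table, formulas: dict, features, sample: str) -> SampleStoichiometry:
    """Carbon-weighted NOSC (and derived stoichiometry) for one sample.

    NOSC weights are the carbon content of each feature: abundance times
    formula carbon count.  Scale-invariant in the abundances.
    """
    feats, ab, recs = _gather(feature_table, formulas, features, sample)
    a = np.array([r.c for r in recs], dtype=float)
    return _stoich_from_weights(sample, feats, ab, recs, ab * a)


def sample_stoichiometry(feature_table, formulas: dict, features, sample: str) -> SampleStoichiometry:
    """Alias of :func:`sample_weighted_nosc` returning the full summary."""
    return sample_weighted_nosc(feature_table, formulas, features, sample)


def feature_standardized_weighting(feature_table, formulas: dict, features,
                                   samples=None) -> pd.DataFrame:
    """Robustness variant: weight by per-feature z-scored peak area.

    Each feature is internally z-scored across samples (subtract its mean
    peak area, divide by its SD), removing among-feature differences in
    absolute and relative ionization.  Within each sample the z-scores are
    shifted by the sample minimum to make them valid non-negative weights.
    Constant features are excluded with a warning.
    """
    if samples is None:
        samples = list(feature_table.data.columns)
    feats = [f for f in features
             if f in formulas and not formulas[f].non_chnops and formulas[f].c >= 1]
    if not feats:
        raise ValueError("no formula-bearing features")
    mat = feature_table.data.loc[feats, samples].to_numpy(dtype=float)
    sd = mat.std(axis=1, ddof=1)
    const = sd == 0
    if const.all():
        raise ValueError("all features constant across samples")
    if const.any():
        warnings.warn(f"{int(const.sum())} constant feature(s) excluded from z-weighting")
    keep = ~const
    feats = [f for f, k in zip(feats, keep) if k]
    mat = mat[keep]
    z = (mat - mat.mean(axis=1, keepdims=True)) / mat.std(axis=1, ddof=1, keepdims=True)
    recs = [formulas[f] for f in feats]
    a = np.array([r.c for r in recs], dtype=float)
    zc = np.array([nosc(r) for r in recs])
    rows = []
    for j, s in enumerate(samples):
        w = (z[:, j] - z[:, j].min()) * a
        if w.sum() <= 1e-8 * a.sum():
            # all z-profiles coincide in this sample: fall back to equal weights
            w = np.ones_like(w)
        wnosc = float((w * zc).sum() / w.sum())
        rows.append({"sample_id": s, "weighted_nosc": wnosc, "gibbs": gibbs_cox(wnosc)})
    return pd.DataFrame(rows).set_index("sample_id")


def regress_stoichiometry_vs_bulk(stoich: pd.DataFrame, bulk: pd.DataFrame):
    """OLS fits of bulk TDN on weighted N:C and bulk TDP on weighted P:C.

    ``stoich`` must be indexed by sample with columns nc/pc; ``bulk`` by
    sample with columns TDN/TDP.  Returns ``{"nc_tdn": LinearFit,
    "pc_tdp": LinearFit}`` over the matched samples.
    """
    common = stoich.index.intersection(bulk.index)
    if len(common) < 3:
        raise ValueError("need at least three matched samples")
    return {
        "nc_tdn": linear_fit(stoich.loc[common, "nc"], bulk.loc[common, "TDN"]),
        "pc_tdp": linear_fit(stoich.loc[common, "pc"], bulk.loc[common, "TDP"]),
    }
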