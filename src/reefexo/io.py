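"""Data model and text I/O for feature tables, metadata, annotations, bulk chemistry.

The package's native interchange is long-format UTF-8 TSV ("." decimal):
one (feature, sample) pair per row for peak areas.  An adapter for the
MZmine wide "quant table" CSV export is provided so aligned feature lists
can be consumed directly.  Gap-filled zeros are meaningful data (filters
compare means including them), so missing cells are filled with 0 and
counted, never treated as NaN.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import parse_formula

log = logging.getLogger(__name__)

__all__ = [
    "TREATMENTS", "PRODUCERS", "DIELS", "TIMEPOINTS",
    "FeatureTable", "read_feature_table", "write_feature_table",
    "read_sample_metadata", "write_sample_metadata",
    "read_annotations", "write_annotations",
    "read_bulk_chemistry", "write_bulk_chemistry",
    "relative_abundance",
]

TREATMENTS = ("Ambient", "Control", "Porites", "Pocillopora", "CCA", "Dictyota", "Turf")
PRODUCERS = ("Porites", "Pocillopora", "CCA", "Dictyota", "Turf")
DIELS = ("Day", "Night")
TIMEPOINTS = ("start", "end")

_FLOAT_FMT = "%.17g"     # round-trips float64 exactly


@dataclass
class FeatureTable:
    """Aligned MS1 feature quantification table.

    ``data`` is a features x samples frame of non-negative XIC peak areas
    (float64); ``mz`` (Da) and ``rt`` (minutes) are optional per-feature
    series sharing the feature index.
    """

    data: pd.DataFrame
    mz: pd.Series | None = None
    rt: pd.Series | None = None

    def __post_init__(self):
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dupes}")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("peak areas must be non-negative")
        self.data = self.data.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def subset_samples(self, samples) -> "FeatureTable":
        return FeatureTable(self.data[list(samples)].copy(), self.mz, self.rt)

    def subset_features(self, features) -> "FeatureTable":
        return FeatureTable(self.data.loc[list(features)].copy(), self.mz, self.rt)


def relative_abundance(table: FeatureTable, sample_subset=None) -> FeatureTable:
    """Convert peak areas to per-sample shares of the summed peak area.

    Every column of the result sums to 1; feature order is preserved.
    Idempotent up to floating error.  A sample whose total peak area is 0
    has no defined composition and raises, naming the sample.
    """
    data = table.data if sample_subset is None else table.data[list(sample_subset)]
    totals = data.sum(axis=0)
    bad = totals[totals <= 0]
    if len(bad):
        raise ValueError(f"all-zero sample(s): {list(bad.index)}")
    return FeatureTable(data / totals, table.mz, table.rt)


# --------------------------------------------------------------------------
# feature table I/O
# --------------------------------------------------------------------------

def read_feature_table(path, dialect: str = "native", metadata: pd.DataFrame | None = None) -> FeatureTable:
    """Read an aligned feature table.

    Dialects
    --------
    ``native``
        Long TSV with columns feature_id, sample_id, peak_area and
        optional mz, rt.
    ``mzmine``
        Wide CSV in the MZmine quant-table convention: ``row ID``,
        ``row m/z``, ``row retention time`` plus one ``<sample> Peak
        area`` column per sample.
    ``wide``
        Plain wide table: feature_id column plus one column per sample.

    Missing cells become 0 (gap-fill convention) with a logged count.  If
    ``metadata`` is supplied, every sample column must have a metadata
    record; an unknown column raises naming it.
    """
    path = Path(path)
    if dialect == "native":
        long = pd.read_csv(path, sep="\t", dtype={"feature_id": str, "sample_id": str},
                           float_precision="round_trip")
        if long.duplicated(["feature_id", "sample_id"]).any():
            raise ValueError("duplicate (feature, sample) rows")
        data = long.pivot(index="feature_id", columns="sample_id", values="peak_area")
        mz = rt = None
        if "mz" in long.columns:
            mz = long.groupby("feature_id")["mz"].first().reindex(data.index)
        if "rt" in long.columns:
            rt = long.groupby("feature_id")["rt"].first().reindex(data.index)
    elif dialect == "mzmine":
        wide = pd.read_csv(path, float_precision="round_trip")
        wide["row ID"] = wide["row ID"].astype(str)
        if wide["row ID"].duplicated().any():
            raise ValueError("duplicate feature ids in 'row ID'")
        area_cols = [c for c in wide.columns if c.endswith(" Peak area")]
        data = wide.set_index("row ID")[area_cols]
        data.columns = [c[: -len(" Peak area")].strip() for c in area_cols]
        data.index.name = "feature_id"
        mz = wide.set_index("row ID")["row m/z"] if "row m/z" in wide.columns else None
        rt = (wide.set_index("row ID")["row retention time"]
              if "row retention time" in wide.columns else None)
    elif dialect == "wide":
        wide = pd.read_csv(path, sep="\t", dtype={"feature_id": str},
                           float_precision="round_trip")
        if wide["feature_id"].duplicated().any():
            raise ValueError("duplicate feature ids")
        data = wide.set_index("feature_id")
        mz = rt = None
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    n_missing = int(data.isna().sum().sum())
    if n_missing:
        log.warning("filled %d missing cell(s) with 0", n_missing)
        warnings.warn(f"filled {n_missing} missing cell(s) with 0")
        data = data.fillna(0.0)
    if metadata is not None:
        unknown = [c for c in data.columns if c not in set(metadata["sample_id"])]
        if unknown:
            raise ValueError(f"sample column(s) without metadata record: {unknown}")
    return FeatureTable(data, mz, rt)


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a feature table as native long TSV (bit round-trip for reals)."""
    long = table.data.stack().rename("peak_area").reset_index()
    long.columns = ["feature_id", "sample_id", "peak_area"]
    if table.mz is not None:
        long = long.merge(table.mz.rename("mz"), left_on="feature_id", right_index=True)
    if table.rt is not None:
        long = long.merge(table.rt.rename("rt"), left_on="feature_id", right_index=True)
    long.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# --------------------------------------------------------------------------
# sample metadata
# --------------------------------------------------------------------------

_META_COLS = ("sample_id", "role", "treatment", "diel", "timepoint", "replicate")


def _validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    if meta.empty:
        raise ValueError("no samples in metadata")
    for col in _META_COLS:
        if col not in meta.columns:
            raise ValueError(f"metadata missing column {col!r}")
    if meta["sample_id"].duplicated().any():
        dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dupes}")
    if not meta["role"].isin(["blank", "experimental"]).all():
        bad = sorted(set(meta["role"]) - {"blank", "experimental"})
        raise ValueError(f"unknown role label(s): {bad}")
    blanks = meta["role"] == "blank"
    for col in ("treatment", "diel", "timepoint"):
        if meta.loc[blanks, col].notna().any():
            raise ValueError(f"blank samples must not carry {col!r}")
    exp = meta.loc[~blanks]
    if not exp["treatment"].isin(TREATMENTS).all():
        bad = sorted(set(exp["treatment"].dropna()) - set(TREATMENTS))
        raise ValueError(f"unknown treatment label(s): {bad}")
    if not exp["diel"].isin(DIELS).all():
        raise ValueError("diel must be Day or Night")
    if not exp["timepoint"].isin(TIMEPOINTS).all():
        raise ValueError("timepoint must be start or end")
    amb = exp["treatment"] == "Ambient"
    if (exp.loc[amb, "timepoint"] != "start").any():
        raise ValueError("Ambient samples must be timepoint=start")
    design = exp.groupby(["treatment", "diel", "timepoint"]).size()
    log.info("design cells:\n%s", design.to_string())
    return meta


def read_sample_metadata(path) -> pd.DataFrame:
    """Read and validate the sample metadata TSV."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("treatment", "diel", "timepoint"):
        if col in meta.columns:
            meta[col] = meta[col].replace("", np.nan)
    return _validate_metadata(meta)


def write_sample_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# annotations
# --------------------------------------------------------------------------

def read_annotations(path, feature_ids=None) -> pd.DataFrame:
    """Read the per-feature annotation TSV (formulas, quality, subnetworks).

    Formulas are parsed into :class:`~reefexo.chem.FormulaRecord` objects
    in a ``formula_record`` column; an unparsable formula drops the
    feature's annotation with a warning.  A ``zodiac_score`` without a
    formula violates the table invariant and raises.  Annotation tables
    may be supersets of the feature table: unknown ids warn but stay.
    """
    ann = pd.read_csv(path, sep="\t", dtype={"feature_id": str, "formula": str})
    if ann["feature_id"].duplicated().any():
        raise ValueError("duplicate feature ids in annotations")
    has_formula = ann["formula"].notna() & (ann["formula"].astype(str).str.strip() != "")
    if "zodiac_score" in ann.columns:
        orphan = ann["zodiac_score"].notna() & ~has_formula
        if orphan.any():
            raise ValueError("zodiac_score present without formula for "
                             f"{ann.loc[orphan, 'feature_id'].tolist()}")
    records, drop = [], []
    for i, row in ann.iterrows():
        if not has_formula[i]:
            records.append(None)
            continue
        try:
            records.append(parse_formula(row["formula"]))
        except ValueError:
            records.append(None)
            drop.append(row["feature_id"])
    if drop:
        warnings.warn(f"dropped unparsable formula(s) for feature(s): {drop}")
        ann.loc[ann["feature_id"].isin(drop), "formula"] = np.nan
    ann["formula_record"] = records
    if feature_ids is not None:
        extra = set(ann["feature_id"]) - set(feature_ids)
        if extra:
            warnings.warn(f"{len(extra)} annotation row(s) not in the feature table (kept)")
    if "subnetwork_id" in ann.columns:
        ann["subnetwork_id"] = pd.to_numeric(ann["subnetwork_id"], errors="coerce").astype("Int64")
    return ann


def write_annotations(ann: pd.DataFrame, path) -> None:
    out = ann.drop(columns=["formula_record"], errors="ignore")
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def formula_map(ann: pd.DataFrame) -> dict:
    """feature_id -> FormulaRecord for rows carrying a parsed formula."""
    return {fid: rec for fid, rec in zip(ann["feature_id"], ann["formula_record"])
            if rec is not None}


# --------------------------------------------------------------------------
# bulk chemistry
# --------------------------------------------------------------------------

_BULK_TOL = 0.5   # uM slack on derived DON/DOP consistency

BULK_ANALYTES = ("DO", "pH", "DOC", "PO4", "NO3NO2", "NH4", "silicate",
                 "TDN", "TDP", "DON", "DOP")


def read_bulk_chemistry(path) -> pd.DataFrame:
    """Read the per-sample bulk chemistry TSV and check derived pools.

    DON = TDN - (NO3NO2 + NH4) and DOP = TDP - PO4 are recomputed when the
    required columns are present; a stored value further than 0.5 uM from
    the recomputation raises.
    """
    bulk = pd.read_csv(path, sep="\t", dtype={"sample_id": str},
                       float_precision="round_trip").set_index("sample_id")
    conc = [c for c in bulk.columns if c not in ("pH",)]
    neg = (bulk[conc] < -_BULK_TOL).any()
    if neg.any():
        raise ValueError(f"negative concentration(s) in {list(neg[neg].index)}")
    if {"TDN", "NO3NO2", "NH4"} <= set(bulk.columns):
        don = bulk["TDN"] - bulk["NO3NO2"] - bulk["NH4"]
        if "DON" in bulk.columns:
            if (bulk["DON"] - don).abs().max() > _BULK_TOL:
                raise ValueError("stored DON inconsistent with TDN - (NO3NO2 + NH4)")
        else:
            bulk["DON"] = don
    if {"TDP", "PO4"} <= set(bulk.columns):
        dop = bulk["TDP"] - bulk["PO4"]
        if "DOP" in bulk.columns:
            if (bulk["DOP"] - dop).abs().max() > _BULK_TOL:
                raise ValueError("stored DOP inconsistent with TDP - PO4")
        else:
            bulk["DOP"] = dop
    return bulk


def write_bulk_chemistry(bulk: pd.DataFrame, path) -> None:
    bulk.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
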