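"""Literature-style trait-record tables.

A trait record is one published observation of a trait (e.g. total ovariole
number) for one species: a single value, a min-max range, or a mean with a
deviation, plus taxonomy at species/genus/family/order rank, a
reproductive-caste flag (eusocial workers are excluded from analysis), a
source id, and an outlier flag.  Tables are pandas DataFrames in a fixed
TSV dialect (``"."`` for missing fields).

The module provides the intraspecific percent-difference statistics,
exclusion filtering with an audit log, aggregation to a taxonomic rank on
the log10 scale, and the two resampling protocols used by replicated
regressions (one-record-per-taxon reshuffling, and per-family downsampling
by half).
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "RANKS",
    "make_records",
    "read_records",
    "write_records",
    "validate_records",
    "point_values",
    "percent_difference",
    "percent_difference_table",
    "filter_records",
    "aggregate_by_rank",
    "resample_records",
]

COLUMNS = [
    "species",
    "genus",
    "family",
    "order",
    "trait",
    "kind",
    "value",
    "min",
    "max",
    "mean",
    "deviation",
    "caste",
    "source_id",
    "outlier",
]

RANKS = ("species", "genus", "family")

_NUMERIC = ["value", "min", "max", "mean", "deviation"]


class RecordError(ValueError):
    """Raised for malformed trait records."""


def make_records(rows: Iterable[dict]) -> pd.DataFrame:
    """Build a validated record table from row dicts (missing fields filled)."""
    df = pd.DataFrame(list(rows))
    for col in COLUMNS:
        if col not in df.columns:
            df[col] = np.nan if col in _NUMERIC else None
    df = df[COLUMNS].copy()
    df["caste"] = df["caste"].fillna("unknown")
    df["outlier"] = df["outlier"].astype("boolean").fillna(False).astype(bool)
    for col in _NUMERIC:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    validate_records(df)
    return df.reset_index(drop=True)


def validate_records(df: pd.DataFrame) -> None:
    if not set(COLUMNS) <= set(df.columns):
        missing = sorted(set(COLUMNS) - set(df.columns))
        raise RecordError(f"missing columns: {missing}")
    bad_kind = set(df["kind"].dropna()) - {"single", "range", "mean_dev"}
    if bad_kind:
        raise RecordError(f"unknown record kinds: {sorted(bad_kind)}")
    rng = df[df["kind"] == "range"]
    if (rng["min"] > rng["max"]).any():
        raise RecordError("range record with min > max")
    md = df[df["kind"] == "mean_dev"]
    if (md["deviation"] < 0).any():
        raise RecordError("negative deviation")
    for col in _NUMERIC:
        vals = df[col].dropna()
        if not np.isfinite(vals).all():
            raise RecordError(f"non-finite values in column {col!r}")


def read_records(path_or_buf) -> pd.DataFrame:
    df = pd.read_csv(path_or_buf, sep="\t", na_values=["."], keep_default_na=True)
    df["outlier"] = (
        df.get("outlier", pd.Series(False, index=df.index))
        .map({True: True, False: False, "true": True, "false": False, 1: True, 0: False})
        .fillna(False)
        .astype(bool)
    )
    return make_records(df.to_dict("records"))


def write_records(df: pd.DataFrame, path_or_buf) -> None:
    out = df.copy()
    out["outlier"] = out["outlier"].map({True: "true", False: "false"})
    out.to_csv(path_or_buf, sep="\t", index=False, na_rep=".")


def point_values(df: pd.DataFrame) -> np.ndarray:
    """One summary value per record: single value, range midpoint, or mean."""
    vals = np.empty(len(df))
    kinds = df["kind"].to_numpy()
    vals[:] = df["value"].to_numpy()
    is_rng = kinds == "range"
    vals[is_rng] = (df.loc[is_rng, "min"].to_numpy() + df.loc[is_rng, "max"].to_numpy()) / 2.0
    is_md = kinds == "mean_dev"
    vals[is_md] = df.loc[is_md, "mean"].to_numpy()
    if not np.isfinite(vals).all():
        raise RecordError("record(s) without a usable value")
    return vals


def percent_difference(records: pd.DataFrame) -> float:
    """Intraspecific percent difference for one species' records of one trait.

    A single range record gives ``100*(max-min)/median`` with the median of
    the two endpoints (their midpoint); a single mean-with-deviation record
    gives ``100*(2*deviation)/mean``; multiple independent records give
    ``100*(max-min)/median`` over the per-record point values.
    """
    if len(records) == 0:
        raise RecordError("no records")
    if records["species"].nunique() > 1 or records["trait"].nunique() > 1:
        raise RecordError("records must share one species and one trait")
    if len(records) == 1:
        row = records.iloc[0]
        if row["kind"] == "range":
            med = (row["min"] + row["max"]) / 2.0
            if med == 0:
                raise RecordError(f"degenerate range record for {row['species']}: zero median")
            return float(100.0 * (row["max"] - row["min"]) / med)
        if row["kind"] == "mean_dev":
            if row["mean"] == 0:
                raise RecordError(f"degenerate mean_dev record for {row['species']}: zero mean")
            return float(100.0 * (2.0 * row["deviation"]) / row["mean"])
        return 0.0  # a lone single-value record reports no variation
    pts = point_values(records)
    med = float(np.median(pts))
    if med == 0:
        raise RecordError(f"degenerate records for {records.iloc[0]['species']}: zero median")
    return float(100.0 * (pts.max() - pts.min()) / med)


def percent_difference_table(df: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Per-species percent difference for every species with usable records."""
    sub = df[df["trait"] == trait]
    rows = []
    for species, grp in sub.groupby("species", sort=True):
        informative = len(grp) > 1 or grp.iloc[0]["kind"] in ("range", "mean_dev")
        try:
            pd_val = percent_difference(grp)
        except RecordError:
            continue
        rows.append(
            {
                "species": species,
                "trait": trait,
                "percent_difference": pd_val,
                "n_records": len(grp),
                "informative": informative,
            }
        )
    return pd.DataFrame(rows, columns=["species", "trait", "percent_difference", "n_records", "informative"])


def filter_records(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the exclusion rules; return (kept records, audit log).

    Removes records from non-reproductive individuals of eusocial species
    (e.g. workers) and records flagged as unvalidated outliers.  The audit
    log has one row per removal with the reason.
    """
    reasons = pd.Series("", index=df.index, dtype=object)
    reasons[df["caste"] == "non_reproductive"] = "non-reproductive caste"
    reasons[df["outlier"]] = np.where(
        reasons[df["outlier"]] == "", "flagged outlier", reasons[df["outlier"]] + "; flagged outlier"
    )
    dropped = reasons != ""
    audit = df.loc[dropped, ["species", "trait", "source_id"]].copy()
    audit["reason"] = reasons[dropped]
    return df.loc[~dropped].reset_index(drop=True), audit.reset_index(drop=True)


def aggregate_by_rank(
    df: pd.DataFrame, rank: str, trait: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean of log10 point values per taxon at ``rank`` for one trait.

    All continuous traits are analysed on the log10 scale, so aggregation
    happens after the transform.  Records with non-positive point values
    cannot be log-transformed; they are skipped and reported in the second
    returned frame.
    """
    if rank not in RANKS:
        raise RecordError(f"rank must be one of {RANKS}, got {rank!r}")
    sub = df[df["trait"] == trait].copy()
    if sub[rank].isna().any():
        raise RecordError(f"records missing the {rank!r} field")
    pts = point_values(sub)
    bad = pts <= 0
    errors = sub.loc[bad, [rank, "trait", "source_id"]].copy()
    errors["reason"] = "non-positive value cannot be log10-transformed"
    sub = sub.loc[~bad]
    logs = np.log10(pts[~bad])
    agg = (
        pd.DataFrame({rank: sub[rank].to_numpy(), "log10_value": logs})
        .groupby(rank, sort=True)
        .agg(log10_value=("log10_value", "mean"), n_records=("log10_value", "size"))
        .reset_index()
        .rename(columns={rank: "taxon"})
    )
    agg.insert(1, "trait", trait)
    return agg, errors.reset_index(drop=True)


def resample_records(
    df: pd.DataFrame, mode: str, rank: str = "species", seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """The two replicated-regression resampling protocols.

    ``reshuffle``: for each taxon at ``rank``, keep exactly one record chosen
    uniformly at random (accounts for variation across records of a taxon).
    ``downsample_half``: for each family with k records, keep ceil(k/2)
    chosen uniformly without replacement.  Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if mode == "reshuffle":
        if rank not in RANKS:
            raise RecordError(f"rank must be one of {RANKS}, got {rank!r}")
        keep = []
        for _, grp in df.groupby(rank, sort=True):
            keep.append(grp.index[rng.integers(len(grp))])
        return df.loc[keep].reset_index(drop=True)
    if mode == "downsample_half":
        keep = []
        for _, grp in df.groupby("family", sort=True):
            k = len(grp)
            chosen = rng.choice(grp.index.to_numpy(), size=math.ceil(k / 2), replace=False)
            keep.extend(sorted(chosen))
        return df.loc[sorted(keep)].reset_index(drop=True)
    raise RecordError(f"unknown resampling mode {mode!r}")
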