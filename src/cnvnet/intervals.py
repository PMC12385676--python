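"""Interval algebra over CNV loss/gain calls.

Copy-number calls are split by type, merged per type across samples, and the
merged loss/gain tracks are combined per base into three disjoint tracks:

* ``shared``      — bases called both as loss and as gain somewhere in the cohort,
* ``unique_loss`` — bases called only as loss,
* ``unique_gain`` — bases called only as gain.

All coordinates are 0-based half-open (BED convention).  Regions are plain
pandas DataFrames with columns ``chrom``, ``start``, ``end``; CNV calls add
``cnv_type`` (``loss``/``gain``) and ``sample_id``.  The heavy lifting
(merge / set-intersect / subtract / overlap join) is delegated to pyranges,
which reproduces bedtools' default semantics: book-ended intervals coalesce
on merge, and a single base of overlap suffices for annotation.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd
import pyranges as pr

REGION_COLUMNS = ["chrom", "start", "end"]
CNV_TYPES = ("loss", "gain")

#: labels a RegionSet may carry
REGION_LABELS = ("merged_loss", "merged_gain", "shared", "unique_loss", "unique_gain")


class IntervalError(ValueError):
    """Raised for malformed intervals, calls or gene-model rows."""


def _empty_regions() -> pd.DataFrame:
    return pd.DataFrame({"chrom": pd.Series(dtype=str),
                         "start": pd.Series(dtype="int64"),
                         "end": pd.Series(dtype="int64")})


def validate_regions(df: pd.DataFrame, *, name: str = "regions") -> pd.DataFrame:
    """Check region invariants (columns present, start < end) and normalize dtypes."""
    missing = [c for c in REGION_COLUMNS if c not in df.columns]
    if missing:
        raise IntervalError(f"{name}: missing columns {missing}")
    if len(df) == 0:
        return _empty_regions()
    out = df.copy()
    out["chrom"] = out["chrom"].astype(str)
    out["start"] = out["start"].astype("int64")
    out["end"] = out["end"].astype("int64")
    bad = out["start"] >= out["end"]
    if bad.any():
        rows = out.index[bad].tolist()[:5]
        raise IntervalError(f"{name}: start >= end at rows {rows}")
    if (out["chrom"] == "").any():
        raise IntervalError(f"{name}: empty chromosome name")
    return out


def _to_pyranges(df: pd.DataFrame, extra: Iterable[str] = ()) -> pr.PyRanges:
    cols = {"Chromosome": df["chrom"], "Start": df["start"], "End": df["end"]}
    for c in extra:
        cols[c] = df[c]
    return pr.PyRanges(pd.DataFrame(cols))


def _from_pyranges(g: pr.PyRanges) -> pd.DataFrame:
    df = g.df
    if len(df) == 0:
        return _empty_regions()
    out = df.rename(columns={"Chromosome": "chrom", "Start": "start", "End": "end"})
    out["chrom"] = out["chrom"].astype(str)
    return (out[REGION_COLUMNS]
            .sort_values(["chrom", "start", "end"], kind="mergesort")
            .reset_index(drop=True))


def merge_regions(regions: pd.DataFrame) -> pd.DataFrame:
    """Coalesce overlapping or book-ended intervals into a sorted, disjoint set."""
    regions = validate_regions(regions)
    if len(regions) == 0:
        return _empty_regions()
    return _from_pyranges(_to_pyranges(regions).merge(slack=0))


def merge_same_type(calls: pd.DataFrame, cnv_type: str) -> pd.DataFrame:
    """Merge all calls of one CNV type across samples into a disjoint RegionSet.

    Sample identity is dropped here: the cohort-level loss (or gain) track is
    the union over every sample's calls of that type.
    """
    if cnv_type not in CNV_TYPES:
        raise IntervalError(f"unknown cnv_type {cnv_type!r}; expected one of {CNV_TYPES}")
    for col in ("cnv_type",):
        if col not in calls.columns:
            raise IntervalError("calls table must carry a 'cnv_type' column")
    unknown = set(calls["cnv_type"].unique()) - set(CNV_TYPES)
    if unknown:
        raise IntervalError(f"calls carry unknown cnv_type values {sorted(unknown)}")
    subset = calls.loc[calls["cnv_type"] == cnv_type, REGION_COLUMNS]
    return merge_regions(subset)


def shared_regions(loss: pd.DataFrame, gain: pd.DataFrame) -> pd.DataFrame:
    """Per-base intersection of merged loss and gain tracks."""
    loss = validate_regions(loss, name="loss")
    gain = validate_regions(gain, name="gain")
    if len(loss) == 0 or len(gain) == 0:
        return _empty_regions()
    return _from_pyranges(_to_pyranges(loss).set_intersect(_to_pyranges(gain)))


def unique_regions(loss: pd.DataFrame, gain: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-base set differences: (loss − gain, gain − loss).

    Together with :func:`shared_regions` this partitions loss ∪ gain.
    """
    loss = validate_regions(loss, name="loss")
    gain = validate_regions(gain, name="gain")
    if len(gain) == 0:
        unique_loss = merge_regions(loss) if len(loss) else _empty_regions()
    else:
        unique_loss = (_from_pyranges(_to_pyranges(loss).subtract(_to_pyranges(gain)))
                       if len(loss) else _empty_regions())
    if len(loss) == 0:
        unique_gain = merge_regions(gain) if len(gain) else _empty_regions()
    else:
        unique_gain = (_from_pyranges(_to_pyranges(gain).subtract(_to_pyranges(loss)))
                       if len(gain) else _empty_regions())
    return unique_loss, unique_gain


def cnv_region_tracks(calls: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Run the full interval algorithm on a call table.

    Returns the five labelled tracks: merged_loss, merged_gain, shared,
    unique_loss, unique_gain.
    """
    merged_loss = merge_same_type(calls, "loss")
    merged_gain = merge_same_type(calls, "gain")
    shared = shared_regions(merged_loss, merged_gain)
    unique_loss, unique_gain = unique_regions(merged_loss, merged_gain)
    return {"merged_loss": merged_loss,
            "merged_gain": merged_gain,
            "shared": shared,
            "unique_loss": unique_loss,
            "unique_gain": unique_gain}


def annotate_genes(regions: pd.DataFrame,
                   gene_models: pd.DataFrame,
                   gene_type_filter: str | None = None) -> tuple[pd.DataFrame, list[str]]:
    """Report genes overlapping each region by at least one base.

    Parameters
    ----------
    regions : DataFrame with chrom/start/end.
    gene_models : DataFrame with chrom/start/end/symbol/gene_type.
    gene_type_filter : restrict to one gene type (``protein_coding`` or
        ``lncRNA``); ``None`` keeps all.

    Returns
    -------
    (per_region, union) : per_region has one row per (region, gene) overlap
        with the region coordinates and the gene symbol; union is the
        deduplicated, sorted list of all reported symbols.
    """
    regions = validate_regions(regions, name="regions")
    for col in ("symbol", "gene_type"):
        if col not in gene_models.columns:
            raise IntervalError(f"gene model table missing column {col!r}")
    genes = validate_regions(gene_models, name="gene_models")
    genes["symbol"] = gene_models["symbol"].astype(str).values
    genes["gene_type"] = gene_models["gene_type"].astype(str).values
    if gene_type_filter is not None:
        genes = genes[genes["gene_type"] == gene_type_filter]
    empty = pd.DataFrame({"chrom": [], "start": [], "end": [], "symbol": [], "gene_type": []})
    if len(regions) == 0 or len(genes) == 0:
        return empty, []
    joined = _to_pyranges(regions).join(_to_pyranges(genes.reset_index(drop=True),
                                                     extra=["symbol", "gene_type"])).df
    if len(joined) == 0:
        return empty, []
    per_region = (joined.rename(columns={"Chromosome": "chrom", "Start": "start", "End": "end"})
                  [["chrom", "start", "end", "symbol", "gene_type"]])
    per_region["chrom"] = per_region["chrom"].astype(str)
    per_region = (per_region.drop_duplicates()
                  .sort_values(["chrom", "start", "end", "symbol"], kind="mergesort")
                  .reset_index(drop=True))
    union = sorted(per_region["symbol"].unique())
    return per_region, union
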