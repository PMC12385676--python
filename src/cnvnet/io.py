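"""Readers and writers for the pipeline's file formats.

Coordinates on disk follow BED (0-based half-open).  One-based inclusive
input (coordinates as printed in clinical tables) is converted by the readers
when ``one_based=True``.  GFF3 parsing is delegated to pyranges, which also
handles the 1-based to 0-based shift.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pyranges as pr

from .intervals import IntervalError, validate_regions
from .network import normalize_symbol
from .report import DOSAGE_COLUMNS

CALL_COLUMNS = ["chrom", "start", "end", "cnv_type", "sample_id"]

#: accepted GFF3 attribute keys for the gene symbol and the gene type
_GFF_SYMBOL_KEYS = ("gene_name", "Name", "gene_id")
_GFF_TYPE_KEYS = ("gene_type", "gene_biotype", "biotype")


def read_cnv_calls(path: str | Path, *, one_based: bool = False) -> pd.DataFrame:
    """Read CNV calls from BED3+2 (chrom, start, end, cnv_type, sample_id)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=CALL_COLUMNS, dtype={0: str, 3: str, 4: str})
    if df[["start", "end"]].isna().any().any():
        raise IntervalError(f"{path}: malformed coordinates")
    if one_based:
        df["start"] = df["start"].astype(int) - 1
    df["cnv_type"] = df["cnv_type"].str.lower()
    bad = ~df["cnv_type"].isin(["loss", "gain"])
    if bad.any():
        raise IntervalError(
            f"{path}: unknown cnv_type at line(s) {(df.index[bad] + 1).tolist()[:5]}")
    checked = validate_regions(df, name=str(path))
    return checked[["chrom", "start", "end"]].join(df[["cnv_type", "sample_id"]])


def write_cnv_calls(calls: pd.DataFrame, path: str | Path) -> None:
    calls[CALL_COLUMNS].to_csv(path, sep="\t", header=False, index=False,
                               lineterminator="\n")


def write_bed(regions: pd.DataFrame, path: str | Path) -> None:
    regions[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False,
                                              index=False, lineterminator="\n")


def read_gene_models(path: str | Path, *, one_based: bool = False) -> pd.DataFrame:
    """Read gene models from BED or GFF3 into chrom/start/end/symbol/gene_type.

    BED input carries the symbol in column 4; the gene type rides in column 5
    (3+2 layout) or column 7 (BED6+1 layout).  GFF3 input keeps ``gene``
    features only, reading the symbol from gene_name/Name/gene_id and the
    type from gene_type/gene_biotype/biotype attributes.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        df = pr.read_gff3(str(path), full=True).df
        df = df[df["Feature"] == "gene"].reset_index(drop=True)
        sym_key = next((k for k in _GFF_SYMBOL_KEYS if k in df.columns), None)
        type_key = next((k for k in _GFF_TYPE_KEYS if k in df.columns), None)
        if sym_key is None:
            raise IntervalError(f"{path}: no gene symbol attribute "
                                f"(looked for {_GFF_SYMBOL_KEYS})")
        out = pd.DataFrame({"chrom": df["Chromosome"].astype(str),
                            "start": df["Start"], "end": df["End"],
                            "symbol": df[sym_key].astype(str),
                            "gene_type": (df[type_key].astype(str) if type_key
                                          else "protein_coding")})
    else:
        raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if raw.shape[1] < 4:
            raise IntervalError(f"{path}: gene-model BED needs >= 4 columns")
        type_col = 4 if raw.shape[1] in (5,) else (6 if raw.shape[1] >= 7 else None)
        out = pd.DataFrame({"chrom": raw[0], "start": raw[1].astype(int),
                            "end": raw[2].astype(int), "symbol": raw[3],
                            "gene_type": (raw[type_col] if type_col is not None
                                          else "protein_coding")})
        if one_based:
            out["start"] -= 1
    bad = out["start"] >= out["end"]
    if bad.any():
        raise IntervalError(f"{path}: start >= end at line(s) "
                            f"{(out.index[bad] + 1).tolist()[:5]}")
    return out.reset_index(drop=True)


def write_gene_models(genes: pd.DataFrame, path: str | Path) -> None:
    """Write gene models as a 5-column BED (chrom, start, end, symbol, gene_type)."""
    genes[["chrom", "start", "end", "symbol", "gene_type"]].to_csv(
        path, sep="\t", header=False, index=False, lineterminator="\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One symbol per line; uppercased, deduplicated, input order preserved."""
    seen: dict[str, None] = {}
    with open(path) as fh:
        for line in fh:
            s = normalize_symbol(line)
            if s and not s.startswith("#"):
                seen.setdefault(s, None)
    return list(seen)


def write_gene_list(symbols: list[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in symbols:
            fh.write(f"{s}\n")


def read_dosage_table(path: str | Path) -> pd.DataFrame:
    """TSV with a ``symbol`` column plus pLI / LOEUF / sHet / pHaplo / pTriplo."""
    df = pd.read_csv(path, sep="\t")
    if "symbol" not in df.columns:
        raise ValueError(f"{path}: dosage table needs a 'symbol' column")
    df["symbol"] = df["symbol"].map(normalize_symbol)
    df = df.set_index("symbol")
    for col in ("pLI", "pHaplo", "pTriplo"):
        if col in df.columns:
            vals = df[col].dropna()
            if ((vals < 0) | (vals > 1)).any():
                raise ValueError(f"{path}: {col} outside [0, 1]")
    return df


def write_dosage_table(dosage: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in DOSAGE_COLUMNS if c in dosage.columns]
    dosage[cols].to_csv(path, sep="\t", index_label="symbol",
                        float_format="%.6g", lineterminator="\n")
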