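"""Candidate-gene reporting: dosage flags, overlap bookkeeping, diagnostic yield.

The report row is one CNV-derived gene with its CNV origin (loss/gain),
membership in the smallest propagated interactome and in the NDD gene panel,
topological role labels, dosage-sensitivity scores and flags.  Dosage flags
use the probability-of-haploinsufficiency (pHaplo) and probability-of-
triplosensitivity (pTriplo) scores: a deletion candidate is flagged when
pHaplo >= 0.55 and a duplication candidate when pTriplo >= 0.68 (the study's
operating points; the stricter literature cutoffs 0.86/0.94 are available as
the ``strict`` preset).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

REPORT_SCHEMA_VERSION = "1.0"

DOSAGE_COLUMNS = ["pLI", "LOEUF", "sHet", "pHaplo", "pTriplo"]

#: named threshold presets (haplo, triplo)
THRESHOLD_PRESETS = {"study": (0.55, 0.68), "strict": (0.86, 0.94)}


@dataclass(frozen=True)
class YieldSummary:
    """Cohort diagnostic yield: pathogenic calls over samples passing QC."""
    n_tested: int
    n_passed_qc: int
    n_pathogenic: int
    yield_percent: int


def compute_yield(n_pathogenic: int, n_passed_qc: int,
                  n_tested: int | None = None) -> YieldSummary:
    """Diagnostic yield as a whole percent, rounded half away from zero.

    9 pathogenic findings in 29 samples passing QC give 31.03... -> 31%.
    """
    if n_passed_qc < 1:
        raise ValueError("n_passed_qc must be >= 1")
    if not 0 <= n_pathogenic <= n_passed_qc:
        raise ValueError("need 0 <= n_pathogenic <= n_passed_qc")
    if n_tested is None:
        n_tested = n_passed_qc
    if n_passed_qc > n_tested:
        raise ValueError("n_passed_qc cannot exceed n_tested")
    pct = 100.0 * n_pathogenic / n_passed_qc
    return YieldSummary(n_tested=n_tested, n_passed_qc=n_passed_qc,
                        n_pathogenic=n_pathogenic,
                        yield_percent=int(math.floor(pct + 0.5)))


def flag_dosage(dosage: pd.DataFrame, *,
                haplo_threshold: float = 0.55,
                triplo_threshold: float = 0.68) -> pd.DataFrame:
    """Per-gene haplo/triplo flags from a dosage-score table indexed by symbol.

    Flags are boundary-inclusive (>=).  A missing score never sets its flag;
    such genes are listed in the ``score_missing`` audit column.
    """
    for thr in (haplo_threshold, triplo_threshold):
        if not 0.0 <= thr <= 1.0:
            raise ValueError(f"threshold {thr} out of [0, 1]")
    out = pd.DataFrame(index=dosage.index)
    ph = dosage.get("pHaplo", pd.Series(np.nan, index=dosage.index))
    pt = dosage.get("pTriplo", pd.Series(np.nan, index=dosage.index))
    out["haplo_flag"] = (ph >= haplo_threshold).fillna(False)
    out["triplo_flag"] = (pt >= triplo_threshold).fillna(False)
    out["score_missing"] = ph.isna() | pt.isna()
    return out


def top_k_per_group(table: pd.DataFrame, group_col: str, score_col: str,
                    k: int, *, ascending: bool = False) -> pd.DataFrame:
    """Generic top-k-per-group extractor (e.g. top-5 GO terms per module).

    Returns at most k rows per group, ordered by score within group; ties are
    broken by original row order for determinism.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0 or len(table) == 0:
        return table.iloc[0:0]
    return (table.sort_values(score_col, ascending=ascending, kind="mergesort")
            .groupby(group_col, sort=False, group_keys=False)
            .head(k)
            .sort_index())


@dataclass
class CandidateReport:
    candidates: pd.DataFrame
    summary: dict


def _require_unique(symbols: pd.Index | pd.Series, what: str) -> None:
    dup = pd.Index(symbols)[pd.Index(symbols).duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate symbols in {what}: {dup}")


def assemble_candidates(cnv_genes: pd.DataFrame,
                        smallest_members: set[str] | list[str],
                        ndd_panel: set[str] | list[str],
                        roles: pd.DataFrame | None = None,
                        dosage: pd.DataFrame | None = None,
                        *,
                        haplo_threshold: float = 0.55,
                        triplo_threshold: float = 0.68) -> CandidateReport:
    """Build the candidate-gene report.

    Parameters
    ----------
    cnv_genes : DataFrame with columns ``symbol`` and ``cnv_origin``
        (loss/gain), one row per CNV-derived gene.
    smallest_members : node set of the smallest propagated interactome.
    ndd_panel : NDD panel gene symbols.
    roles : optional role-label table indexed by symbol
        (hub_axis/integration_axis).
    dosage : optional dosage-score table indexed by symbol.

    The summary block records the overlap bookkeeping, including the
    inclusion–exclusion count of distinct smallest-interactome members drawn
    from the CNV gene list and the panel:
    ``n_smallest_distinct = |CNV∩S| + |panel∩S| - |CNV∩panel∩S|``.
    """
    _require_unique(cnv_genes["symbol"], "cnv_genes")
    if roles is not None:
        _require_unique(roles.index, "roles")
    if dosage is not None:
        _require_unique(dosage.index, "dosage")
    smallest = {s.upper() for s in smallest_members}
    panel = {s.upper() for s in ndd_panel}

    df = cnv_genes.copy()
    df["symbol"] = df["symbol"].str.upper()
    df = df.set_index("symbol")
    df["in_smallest_interactome"] = [s in smallest for s in df.index]
    df["in_ndd_panel"] = [s in panel for s in df.index]
    if roles is not None:
        df = df.join(roles[["hub_axis", "integration_axis"]])
    else:
        df["hub_axis"] = pd.NA
        df["integration_axis"] = pd.NA
    if dosage is not None:
        present = [c for c in DOSAGE_COLUMNS if c in dosage.columns]
        df = df.join(dosage[present])
        flags = flag_dosage(dosage, haplo_threshold=haplo_threshold,
                            triplo_threshold=triplo_threshold)
        df = df.join(flags[["haplo_flag", "triplo_flag"]])
        df[["haplo_flag", "triplo_flag"]] = df[["haplo_flag", "triplo_flag"]].fillna(False)
    else:
        df["haplo_flag"] = False
        df["triplo_flag"] = False
    # headline flag pairs deletion candidates with haploinsufficiency and
    # duplication candidates with triplosensitivity
    df["headline_flag"] = np.where(df["cnv_origin"] == "loss",
                                   df["haplo_flag"], df["triplo_flag"])
    df = df.sort_values(["in_smallest_interactome", "headline_flag", "hub_axis"],
                        ascending=[False, False, True], kind="mergesort")

    cnv_set = set(df.index)
    cnv_in_smallest = cnv_set & smallest
    panel_in_smallest = panel & smallest
    both_in_smallest = cnv_in_smallest & panel_in_smallest
    summary = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "n_cnv_genes": len(cnv_set),
        "n_panel_genes": len(panel),
        "n_cnv_in_smallest": len(cnv_in_smallest),
        "n_panel_in_smallest": len(panel_in_smallest),
        "n_cnv_in_smallest_and_panel": len(both_in_smallest),
        "n_cnv_in_panel": len(cnv_set & panel),
        # inclusion–exclusion over the two membership lists
        "n_smallest_distinct": (len(cnv_in_smallest) + len(panel_in_smallest)
                                - len(both_in_smallest)),
        "n_haplo_flagged": int(df["haplo_flag"].sum()),
        "n_triplo_flagged": int(df["triplo_flag"].sum()),
    }
    return CandidateReport(candidates=df, summary=summary)


def write_report(report: CandidateReport, out_dir: str | Path) -> dict[str, Path]:
    """Write candidates.tsv and report.json; byte-stable for fixed input."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv_path = out_dir / "candidates.tsv"
    json_path = out_dir / "report.json"
    df = report.candidates.reset_index().rename(columns={"index": "symbol"})
    df.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g",
              lineterminator="\n", na_rep="NA")
    payload = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "summary": report.summary,
        "candidates": json.loads(df.to_json(orient="records")),
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"tsv": tsv_path, "json": json_path}


def read_report(json_path: str | Path) -> CandidateReport:
    """Round-trip a JSON report back into memory."""
    with open(json_path) as fh:
        payload = json.load(fh)
    df = pd.DataFrame(payload["candidates"])
    if len(df):
        df = df.set_index("symbol")
    return CandidateReport(candidates=df, summary=payload["summary"])
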