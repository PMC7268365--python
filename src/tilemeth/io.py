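"""Reading and writing the pipeline's on-disk formats.

Formats handled here:

* **Cytosine report** — the Bismark-style tab-separated methylation-call
  dialect: ``chromosome  position(1-based)  strand  count_methylated
  count_unmethylated  context  [trinucleotide]``, one row per cytosine.
  On read, CpG-context calls on the two strands of a dyad are merged onto the
  forward-strand C (the reverse-strand G at ``p`` folds into ``p - 1``),
  which maximises per-site depth in sparse single-cell libraries.
* **BED3/BED6** region files (0-based half-open), with an optional seventh
  column carrying the region class.
* **Sample sheet** — a headered TSV wiring sample ids to call files, lambda
  spike-in files, treatment group/dose labels and mapping efficiency.
* **CpG map** — a two-column TSV of reference CpG positions.

In memory, calls live in a pandas DataFrame with columns
``chrom, pos, context, meth, unmeth`` sorted by (chrom, pos); region sets are
DataFrames with columns ``chrom, start, end, strand, name, region_class``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .genome import GenomeCpGMap

__all__ = [
    "CALL_COLUMNS",
    "REGION_COLUMNS",
    "REGION_CLASSES",
    "SampleMethylome",
    "read_cytosine_report",
    "write_cytosine_report",
    "read_sample_sheet",
    "load_samples",
    "read_regions_bed",
    "write_regions_bed",
    "read_cpg_map",
    "write_cpg_map",
    "validate_regions",
    "empty_calls",
]

CALL_COLUMNS = ["chrom", "pos", "context", "meth", "unmeth"]
REGION_COLUMNS = ["chrom", "start", "end", "strand", "name", "region_class"]
REGION_CLASSES = frozenset(
    {
        "gene",
        "promoter",
        "CGI_met",
        "CGI_unmet",
        "ICR",
        "exon",
        "intron",
        "intergenic",
        "LINE",
        "SINE",
        "LTR",
        "rRNA",
        "tRNA",
    }
)
_CONTEXTS = ("CG", "CHG", "CHH")
_TRI = {"CG": "CGN", "CHG": "CHG", "CHH": "CHH"}

SHEET_COLUMNS = [
    "sample_id",
    "group",
    "dose",
    "call_file",
    "lambda_file",
    "mapping_efficiency",
]


def empty_calls() -> pd.DataFrame:
    """An empty, correctly-typed calls table."""
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype=np.int64),
            "context": pd.Series(dtype=str),
            "meth": pd.Series(dtype=np.int64),
            "unmeth": pd.Series(dtype=np.int64),
        }
    )


@dataclass
class SampleMethylome:
    """One cell's methylation calls plus its sample-sheet metadata.

    ``calls`` holds at most one row per (chrom, pos, context) with
    ``meth + unmeth >= 1``; mapping efficiency is carried from the sample
    sheet rather than recomputed (alignment is upstream of this package).
    """

    sample_id: str
    calls: pd.DataFrame
    group: str = ""
    dose: str = ""
    mapping_efficiency: float = float("nan")

    def __post_init__(self):
        self.calls = _normalise_calls(self.calls)

    def fractions(self, context: str = "CG") -> pd.DataFrame:
        """Per-site methylation fractions for one context."""
        sub = self.calls[self.calls["context"] == context]
        total = sub["meth"] + sub["unmeth"]
        out = sub[["chrom", "pos"]].copy()
        out["fraction"] = sub["meth"] / total
        out["total"] = total
        return out

    @property
    def n_covered_cpgs(self) -> int:
        """Distinct CG-context dyads with at least one read."""
        return int((self.calls["context"] == "CG").sum())


def _normalise_calls(calls: pd.DataFrame) -> pd.DataFrame:
    calls = calls.loc[:, CALL_COLUMNS].copy()
    calls["pos"] = calls["pos"].astype(np.int64)
    calls["meth"] = calls["meth"].astype(np.int64)
    calls["unmeth"] = calls["unmeth"].astype(np.int64)
    calls = calls[(calls["meth"] + calls["unmeth"]) >= 1]
    calls = calls.sort_values(["chrom", "pos", "context"], kind="mergesort")
    return calls.reset_index(drop=True)


def read_cytosine_report(
    path: str | os.PathLike,
    sample_id: str | None = None,
    group: str = "",
    dose: str = "",
    mapping_efficiency: float = float("nan"),
    strand_merge: bool = True,
) -> SampleMethylome:
    """Parse a cytosine report into a :class:`SampleMethylome`.

    Rows with zero total reads are dropped. With ``strand_merge`` (default),
    reverse-strand CG calls at position ``p`` are folded onto the dyad's
    forward C at ``p - 1`` and counts summed; merging is idempotent, so
    re-reading an already merged report is a no-op.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(
            path,
            sep="\t",
            header=None,
            dtype=str,
            comment="#",
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        raw = pd.DataFrame()
    if raw.empty:
        return SampleMethylome(
            sample_id or path.stem, empty_calls(), group, dose, mapping_efficiency
        )
    if raw.shape[1] not in (6, 7):
        raise ParseError(
            f"{path}: expected 6 or 7 tab-separated columns, found {raw.shape[1]}"
        )
    raw.columns = ["chrom", "pos", "strand", "meth", "unmeth", "context"] + (
        ["tri"] if raw.shape[1] == 7 else []
    )

    for col in ("pos", "meth", "unmeth"):
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round())
        if bad.any():
            raise ParseError(f"non-integer {col!r} field", line=int(bad.idxmax()) + 1)
        raw[col] = vals.astype(np.int64)
    if (raw["pos"] < 1).any():
        raise ParseError("position < 1", line=int((raw["pos"] < 1).idxmax()) + 1)
    if (raw[["meth", "unmeth"]] < 0).any().any():
        bad = ((raw["meth"] < 0) | (raw["unmeth"] < 0)).idxmax()
        raise ParseError("negative count", line=int(bad) + 1)
    badctx = ~raw["context"].isin(_CONTEXTS)
    if badctx.any():
        i = int(badctx.idxmax())
        raise ParseError(f"unknown context token {raw['context'][i]!r}", line=i + 1)
    badstr = ~raw["strand"].isin(["+", "-"])
    if badstr.any():
        i = int(badstr.idxmax())
        raise ParseError(f"unknown strand {raw['strand'][i]!r}", line=i + 1)

    raw = raw[(raw["meth"] + raw["unmeth"]) >= 1]
    if strand_merge:
        minus_cg = (raw["strand"] == "-") & (raw["context"] == "CG")
        raw.loc[minus_cg, "pos"] -= 1
    merged = (
        raw.groupby(["chrom", "pos", "context"], as_index=False)[["meth", "unmeth"]]
        .sum()
        .sort_values(["chrom", "pos", "context"], kind="mergesort")
        .reset_index(drop=True)
    )
    return SampleMethylome(
        sample_id or path.stem, merged[CALL_COLUMNS], group, dose, mapping_efficiency
    )


def write_cytosine_report(methylome: SampleMethylome, path: str | os.PathLike) -> None:
    """Write the merged-call dialect read by :func:`read_cytosine_report`.

    All rows are emitted on the forward strand (dyads are already merged),
    sorted by chromosome then position, with the trinucleotide column filled
    with ``CGN`` for CG calls and the context token otherwise.
    """
    calls = methylome.calls
    out = pd.DataFrame(
        {
            "chrom": calls["chrom"],
            "pos": calls["pos"],
            "strand": "+",
            "meth": calls["meth"],
            "unmeth": calls["unmeth"],
            "context": calls["context"],
            "tri": calls["context"].map(_TRI),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_sample_sheet(path: str | os.PathLike, check_paths: bool = True) -> pd.DataFrame:
    """Load and validate the experiment's sample sheet.

    Expects a headered TSV with columns ``sample_id, group, dose, call_file,
    lambda_file, mapping_efficiency``. Paths are resolved relative to the
    sheet's directory and checked for existence unless ``check_paths=False``.
    """
    path = Path(path)
    try:
        sheet = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty sample sheet")
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if sheet.empty:
        raise ValidationError(f"{path}: sample sheet has no rows")
    if sheet["sample_id"].duplicated().any():
        dup = sheet["sample_id"][sheet["sample_id"].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate sample id {dup!r}")
    sheet = sheet[SHEET_COLUMNS].copy()
    sheet["mapping_efficiency"] = sheet["mapping_efficiency"].astype(float)
    if ((sheet["mapping_efficiency"] < 0) | (sheet["mapping_efficiency"] > 1)).any():
        raise ValidationError(f"{path}: mapping efficiency outside [0, 1]")
    base = path.parent
    for col in ("call_file", "lambda_file"):
        sheet[col] = [
            str(p) if os.path.isabs(p) else str(base / p) for p in sheet[col]
        ]
        if check_paths:
            for p in sheet[col]:
                if not os.path.exists(p):
                    raise ValidationError(f"{path}: missing file {p}")
    return sheet.reset_index(drop=True)


def load_samples(sheet: pd.DataFrame, strand_merge: bool = True) -> list[SampleMethylome]:
    """Read every call file referenced by a validated sample sheet."""
    return [
        read_cytosine_report(
            row.call_file,
            sample_id=row.sample_id,
            group=row.group,
            dose=row.dose,
            mapping_efficiency=float(row.mapping_efficiency),
            strand_merge=strand_merge,
        )
        for row in sheet.itertuples()
    ]


def validate_regions(regions: pd.DataFrame) -> pd.DataFrame:
    """Check the region-set contract (start < end, known strand) and retype."""
    regions = regions.loc[:, REGION_COLUMNS].copy()
    regions["start"] = regions["start"].astype(np.int64)
    regions["end"] = regions["end"].astype(np.int64)
    if (regions["start"] >= regions["end"]).any():
        bad = regions[regions["start"] >= regions["end"]].iloc[0]
        raise ValidationError(
            f"region {bad['name']!r}: start {bad['start']} >= end {bad['end']}"
        )
    if (regions["start"] < 0).any():
        raise ValidationError("negative region start")
    if not regions["strand"].isin(["+", "-", "."]).all():
        raise ValidationError("strand must be one of '+', '-', '.'")
    return regions.reset_index(drop=True)


def read_regions_bed(path: str | os.PathLike, region_class: str | None = None) -> pd.DataFrame:
    """Read a BED3/BED6(+class) file into a region DataFrame.

    ``region_class`` assigns one class to every interval; when omitted the
    class is taken from a seventh BED column. BED's 0-based half-open
    convention is kept as-is. Overlapping intervals are allowed.
    """
    path = Path(path)
    try:
        bed = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        bed = pd.DataFrame(columns=range(6))
    ncol = bed.shape[1]
    if ncol not in (0, 3, 6, 7):
        raise ParseError(f"{path}: expected 3, 6 or 7 BED columns, found {ncol}")
    out = pd.DataFrame(columns=REGION_COLUMNS)
    if ncol == 0 or bed.empty:
        return validate_regions(out) if not out.empty else out
    out["chrom"] = bed[0]
    out["start"] = pd.to_numeric(bed[1])
    out["end"] = pd.to_numeric(bed[2])
    out["name"] = bed[3] if ncol >= 6 else [f"region_{i}" for i in range(len(bed))]
    out["strand"] = bed[5] if ncol >= 6 else "."
    if region_class is not None:
        out["region_class"] = region_class
    elif ncol == 7:
        out["region_class"] = bed[6]
    else:
        raise ValidationError(f"{path}: no class column and no region_class given")
    return validate_regions(out)


def write_regions_bed(regions: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write BED6 plus a seventh class column."""
    regions = validate_regions(regions)
    out = regions[["chrom", "start", "end", "name"]].copy()
    out["score"] = 0
    out["strand"] = regions["strand"]
    out["region_class"] = regions["region_class"]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_cpg_map(path: str | os.PathLike) -> GenomeCpGMap:
    """Read a two-column (chrom, 1-based position) TSV into a CpG map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos"], dtype={0: str})
    return GenomeCpGMap(
        {chrom: sub["pos"].to_numpy(np.int64) for chrom, sub in df.groupby("chrom", sort=False)}
    )


def write_cpg_map(cpg_map: GenomeCpGMap, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, pos in cpg_map.positions.items():
            for p in pos:
                fh.write(f"{chrom}\t{p}\n")
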