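"""Per-cell quality control.

A cell enters the downstream analysis only if its mapping efficiency is at
least 10% and it covers strictly more than one million CpG sites (both
thresholds configurable for reduced-scale data). The bisulfite conversion
rate is estimated from unmethylated lambda spike-in DNA as the fraction of
lambda cytosine calls that read unmethylated.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .io import SampleMethylome

__all__ = ["QCReport", "conversion_rate", "global_methylation", "sample_qc", "cohort_qc"]


@dataclass(frozen=True)
class QCReport:
    sample_id: str
    conversion_rate: float
    n_covered_cpgs: int
    mapping_efficiency: float
    global_cg: float
    global_chg: float
    global_chh: float
    passed: bool

    def to_dict(self) -> dict:
        return asdict(self)


def conversion_rate(lambda_calls: pd.DataFrame) -> float:
    """Unmethylated lambda calls over total lambda calls.

    Lambda DNA carries no methylation, so any methylated call is a conversion
    failure; the statistic is pooled over reads and therefore invariant to
    batching and call order.
    """
    if lambda_calls is None or len(lambda_calls) == 0:
        raise InsufficientDataError("no lambda spike-in calls")
    meth = int(lambda_calls["meth"].sum())
    unmeth = int(lambda_calls["unmeth"].sum())
    if meth + unmeth == 0:
        raise InsufficientDataError("lambda calls carry zero reads")
    return unmeth / (meth + unmeth)


def global_methylation(methylome: SampleMethylome, context: str = "CG") -> float:
    """Unweighted mean of per-site methylation fractions in one context."""
    sub = methylome.calls[methylome.calls["context"] == context]
    if sub.empty:
        raise InsufficientDataError(f"no calls in context {context!r}")
    total = sub["meth"] + sub["unmeth"]
    return float((sub["meth"] / total).mean())


def sample_qc(
    methylome: SampleMethylome,
    lambda_calls: pd.DataFrame | None = None,
    min_mapping: float = 0.10,
    min_cpg: int = 1_000_000,
) -> QCReport:
    """Quality report and inclusion decision for one cell.

    Passing requires mapping efficiency >= ``min_mapping`` (inclusive) and a
    covered-CpG count strictly greater than ``min_cpg`` — a cell sitting
    exactly on the CpG threshold fails.
    """
    def _safe_global(ctx: str) -> float:
        try:
            return global_methylation(methylome, ctx)
        except InsufficientDataError:
            return float("nan")

    try:
        conv = conversion_rate(lambda_calls) if lambda_calls is not None else float("nan")
    except InsufficientDataError:
        conv = float("nan")
    n_cpg = methylome.n_covered_cpgs
    passed = bool(methylome.mapping_efficiency >= min_mapping) and n_cpg > min_cpg
    return QCReport(
        sample_id=methylome.sample_id,
        conversion_rate=conv,
        n_covered_cpgs=n_cpg,
        mapping_efficiency=float(methylome.mapping_efficiency),
        global_cg=_safe_global("CG"),
        global_chg=_safe_global("CHG"),
        global_chh=_safe_global("CHH"),
        passed=passed,
    )


def cohort_qc(
    samples: list[SampleMethylome],
    lambda_calls: dict[str, pd.DataFrame] | None = None,
    min_mapping: float = 0.10,
    min_cpg: int = 1_000_000,
) -> pd.DataFrame:
    """One QC row per cell; ``lambda_calls`` maps sample id to spike-in calls."""
    lambda_calls = lambda_calls or {}
    reports = [
        sample_qc(s, lambda_calls.get(s.sample_id), min_mapping, min_cpg) for s in samples
    ]
    return pd.DataFrame([r.to_dict() for r in reports]).set_index("sample_id")
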