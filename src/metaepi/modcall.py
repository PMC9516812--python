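"""Kinetics-based modification calling.

SMRT sequencing reports an interpulse duration (IPD) for every incorporated
base; methylated templates slow the polymerase, so the per-site IPD ratio
against an unmodified in-silico control rises above 1. A site is tested with a
one-sample, upper-tailed t test of its per-molecule IPD ratios against the
control mean, and the phred-like modification quality value is
QV = -10*log10(p), capped at 1000.

Because pooled molecules come from many cells, the aggregate signal reflects
the fraction of cells methylated at that position ("methylation fraction").
That fraction is estimated by the method of moments:
f = clip((mean - mu0) / (mu_m - mu0), 0, 1), with mu_m the expected IPD ratio
of a fully modified site.

Site status is three-valued: a position with fewer than ``min_coverage``
molecules on a strand is *unevaluable* — which is distinct from unmethylated —
and a position passes filters only with coverage >= 10 per strand and QV >= 30.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ModificationRecord, ValidationError

__all__ = [
    "ControlKineticModel",
    "ModCall",
    "QV_CAP",
    "detect_modified_position",
    "estimate_fraction",
    "call_genome",
    "calls_from_records",
]

QV_CAP = 1000.0

#: default filter thresholds: 10x per strand, QV >= 30
MIN_COVERAGE = 10
MIN_QV = 30.0


@dataclass(frozen=True)
class ControlKineticModel:
    """Expected kinetic behaviour of unmodified template."""

    mu0: float = 1.0
    sigma0: float = 0.35

    def __post_init__(self) -> None:
        if self.sigma0 <= 0:
            raise ValidationError("sigma0 must be > 0")


@dataclass(frozen=True)
class ModCall:
    """A modification record plus the test behind it and its filter verdict."""

    record: ModificationRecord
    t: float
    p: float
    pass_filters: bool
    status: str  # methylated | unmethylated | unevaluable

    @property
    def qv(self) -> float:
        return self.record.qv


def _qv_from_p(p: float) -> float:
    if p <= 0.0:
        return QV_CAP
    return min(-10.0 * math.log10(p), QV_CAP)


def detect_modified_position(
    ipd_ratios: Sequence[float], control: ControlKineticModel
) -> tuple[float, float, float]:
    """One-sample upper-tailed t test of IPD ratios against the control mean.

    Returns ``(t, p, qv)``. With fewer than two observations there is no test:
    the result is ``(nan, 1.0, 0.0)``, i.e. an insufficient-coverage non-call.
    Zero-variance samples are degenerate: p is 1 unless the mean exceeds the
    control with n >= 10, in which case p underflows and QV hits the cap.
    """
    x = np.asarray(ipd_ratios, dtype=float)
    n = x.size
    if n < 2:
        return (float("nan"), 1.0, 0.0)
    sd = float(x.std(ddof=1))
    mean = float(x.mean())
    if sd == 0.0:
        if mean > control.mu0 and n >= 10:
            return (float("inf"), 0.0, QV_CAP)
        return (0.0, 1.0, _qv_from_p(1.0))
    res = stats.ttest_1samp(x, popmean=control.mu0, alternative="greater")
    t = float(res.statistic)
    p = float(res.pvalue)
    return (t, p, _qv_from_p(p))


def estimate_fraction(
    ipd_ratios: Sequence[float], control: ControlKineticModel, mu_m: float
) -> float:
    """Moment estimate of the methylated cell fraction at one position-strand."""
    if mu_m <= control.mu0:
        raise ValidationError("mu_m must exceed mu0 (signal must be positive)")
    mean = float(np.mean(ipd_ratios))
    f = (mean - control.mu0) / (mu_m - control.mu0)
    return float(min(max(f, 0.0), 1.0))


def call_genome(
    ipd_table: pd.DataFrame,
    control: ControlKineticModel,
    mu_m: float | Mapping[str, float] = 4.0,
    min_coverage: int = MIN_COVERAGE,
    min_qv: float = MIN_QV,
    mod_types: Mapping[tuple[str, int, str], str] | None = None,
) -> list[ModCall]:
    """Call every observed (contig, position, strand) from per-molecule IPDs.

    ``ipd_table`` has columns contig_id, position, strand, ipd_ratio, one row
    per molecule observation. ``mu_m`` may be a single value or a map from
    modification type (via ``mod_types``) to expected modified-site IPD ratio.
    Positions below ``min_coverage`` are marked unevaluable — never silently
    dropped, and never conflated with unmethylated.
    """
    required = {"contig_id", "position", "strand", "ipd_ratio"}
    if not required <= set(ipd_table.columns):
        raise ValidationError(f"IPD table missing columns {sorted(required - set(ipd_table.columns))}")
    calls: list[ModCall] = []
    grouped = ipd_table.groupby(["contig_id", "position", "strand"], sort=True)
    for (contig, pos, strand), grp in grouped:
        x = grp["ipd_ratio"].to_numpy(dtype=float)
        mod_type = "unknown"
        if mod_types is not None:
            mod_type = mod_types.get((contig, int(pos), strand), "unknown")
        mu = mu_m[mod_type] if isinstance(mu_m, Mapping) else float(mu_m)
        t, p, qv = detect_modified_position(x, control)
        frac = estimate_fraction(x, control, mu) if x.size else None
        cov = int(x.size)
        rec = ModificationRecord(
            contig_id=contig,
            position=int(pos),
            strand=strand,
            mod_type=mod_type,
            coverage=cov,
            qv=qv,
            frac=frac,
        )
        passed = cov >= min_coverage and qv >= min_qv
        if cov < min_coverage:
            status = "unevaluable"
        elif passed:
            status = "methylated"
        else:
            status = "unmethylated"
        calls.append(ModCall(record=rec, t=t, p=p, pass_filters=passed, status=status))
    return calls


def calls_from_records(
    records: Iterable[ModificationRecord],
    min_coverage: int = MIN_COVERAGE,
    min_qv: float = MIN_QV,
) -> list[ModCall]:
    """Annotate pre-computed modification records with the filter verdict."""
    out: list[ModCall] = []
    for r in records:
        passed = r.coverage >= min_coverage and r.qv >= min_qv
        if r.coverage < min_coverage:
            status = "unevaluable"
        elif passed:
            status = "methylated"
        else:
            status = "unmethylated"
        out.append(ModCall(record=r, t=float("nan"), p=float("nan"),
                           pass_filters=passed, status=status))
    return out
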