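"""Relative quantification: dCt, detection calls, ddCt contrasts, fold changes.

The Livak 2^-ddCt scheme is used throughout.  Per sample, ``delta_ct`` is the
gene Ct minus the median reference-gene Ct of the sample's PCR run.  Between
two conditions,

    log2_fc = mean dCt(reference condition) - mean dCt(compared condition)
    fold_change = 2 ** log2_fc

so a gene expressed more strongly in the compared condition (lower dCt) gets
a fold change above one.  Down-regulation is reported with the reciprocal
signed convention (0.4-fold becomes -2.5).

A Ct at the detection ceiling (40 cycles by default) encodes an undetected
transcript; such values enter dCt at the ceiling, a conservative floor on
expression, and a contrast whose sides are detected/undetected exclusively is
flagged instead of given a numeric fold change.  The ``expression_index``
(ceiling - dCt) is a monotone expression proxy used for clustering and PCA.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .errors import MissingReferenceError
from .io import CtTable

EXPECTED_REFERENCE_WELLS = 4


@dataclass(frozen=True)
class NormalizedExpression:
    """dCt of one gene in one sample, with censoring and expression index."""

    gene_id: str
    genotype: str
    time_point: int
    replicate: int
    run_id: str
    delta_ct: float
    censored: bool
    expression_index: float


@dataclass
class ContrastResult:
    """ddCt contrast of one gene between two (genotype, time point) conditions.

    ``exclusive`` is None for a numeric contrast; otherwise it flags which
    side carried all the expression ("compared_only", "reference_only") or
    that neither side was detected ("undetected"), and the numeric fields
    are NaN.
    """

    gene_id: str
    reference_condition: tuple[str, int]
    compared_condition: tuple[str, int]
    ddct: float
    log2_fc: float
    fold_change: float
    signed_fc: float
    n_ref: int
    n_cmp: int
    exclusive: str | None = None

    @property
    def is_numeric(self) -> bool:
        return self.exclusive is None


def compute_reference_ct(wells: Sequence[float], ceiling: float = 40.0) -> float:
    """Median Ct of a run's reference-gene wells.

    Warns when fewer than the expected four technical replicate wells are
    present; raises :class:`MissingReferenceError` on an empty list.
    """
    wells = list(wells)
    if not wells:
        raise MissingReferenceError("no reference-gene wells supplied")
    if any(not (0 < w <= ceiling) for w in wells):
        raise ValueError(f"reference well Ct outside (0, {ceiling}]: {wells}")
    if len(wells) < EXPECTED_REFERENCE_WELLS:
        warnings.warn(
            f"only {len(wells)} reference wells present "
            f"(expected {EXPECTED_REFERENCE_WELLS})",
            stacklevel=2,
        )
    return float(np.median(wells))


def compute_delta_ct(table: CtTable) -> pd.DataFrame:
    """Normalize every Ct record against its run's median reference Ct.

    Returns a DataFrame with the record columns plus ``reference_ct``,
    ``delta_ct``, ``censored`` (Ct at the ceiling) and ``expression_index``
    (ceiling - delta_ct).
    """
    ref_by_run: dict[str, float] = {}
    for run in table.records["run_id"].unique():
        wells = table.reference_wells.get(run)
        if not wells:
            raise MissingReferenceError(f"run {run!r} has no reference wells")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref_by_run[run] = compute_reference_ct(wells, table.ceiling)
    df = table.records.copy()
    df["reference_ct"] = df["run_id"].map(ref_by_run)
    df["delta_ct"] = df["ct"] - df["reference_ct"]
    df["censored"] = df["ct"] >= table.ceiling
    df["expression_index"] = table.ceiling - df["delta_ct"]
    return df


def call_detection(
    ct_values: Sequence[float],
    ceiling: float = 40.0,
    min_detected: int = 2,
) -> bool:
    """Is a gene expressed in a condition?

    Expressed iff at least ``min_detected`` replicates have Ct below the
    ceiling; with fewer replicates than ``min_detected`` every replicate
    must be detected (so a single uncensored replicate counts as expressed).
    """
    values = list(ct_values)
    if not values:
        raise ValueError("no replicate values supplied")
    detected = sum(v < ceiling for v in values)
    return detected >= min(min_detected, len(values))


def signed_fold_change(fold_change: float) -> float:
    """Reciprocal reporting convention: 0.4-fold becomes -2.5; |sfc| >= 1."""
    if fold_change <= 0 or math.isnan(fold_change):
        raise ValueError(f"fold change must be positive, got {fold_change}")
    return fold_change if fold_change >= 1 else -1.0 / fold_change


def compute_contrast(
    gene_id: str,
    ref_values: Sequence[float],
    cmp_values: Sequence[float],
    ref_censored: Sequence[bool] | None = None,
    cmp_censored: Sequence[bool] | None = None,
    reference_condition: tuple[str, int] = ("", 0),
    compared_condition: tuple[str, int] = ("", 0),
) -> ContrastResult:
    """ddCt contrast between two conditions from replicate dCt values.

    Replicates are averaged per condition before differencing:
    ``ddct = mean(cmp) - mean(ref)`` and ``log2_fc = -ddct``, so lower dCt in
    the compared condition (more transcript) gives a positive log2 fold
    change.  When the censoring flags show one side entirely undetected the
    result is flagged exclusive instead of numeric.
    """
    ref = [float(v) for v in ref_values]
    cmp_ = [float(v) for v in cmp_values]
    if not ref or not cmp_:
        raise ValueError(f"{gene_id}: empty replicate list in contrast")
    common = dict(
        gene_id=gene_id,
        reference_condition=reference_condition,
        compared_condition=compared_condition,
        n_ref=len(ref),
        n_cmp=len(cmp_),
    )
    if ref_censored is not None and cmp_censored is not None:
        ref_out = all(ref_censored)
        cmp_out = all(cmp_censored)
        if ref_out or cmp_out:
            if ref_out and cmp_out:
                exclusive = "undetected"
            elif ref_out:
                exclusive = "compared_only"
            else:
                exclusive = "reference_only"
            nan = float("nan")
            return ContrastResult(
                ddct=nan, log2_fc=nan, fold_change=nan, signed_fc=nan,
                exclusive=exclusive, **common,
            )
    ddct = float(np.mean(cmp_) - np.mean(ref))
    log2_fc = -ddct
    fold_change = 2.0 ** log2_fc
    return ContrastResult(
        ddct=ddct,
        log2_fc=log2_fc,
        fold_change=fold_change,
        signed_fc=signed_fold_change(fold_change),
        **common,
    )
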