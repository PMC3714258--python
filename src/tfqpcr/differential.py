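"""Statistical gating of fold-change calls.

A gene is "modulated" in a contrast when three gates all pass: the per-gene
one-way ANOVA across every genotype x time group survives Benjamini-Hochberg
FDR correction (default alpha 0.05), the pairwise Student t-test on dCt
replicate values is significant (default alpha 0.05), and the absolute signed
fold change reaches the 2-fold threshold.  A further 10-fold threshold marks
drastic modulation; the x>=10 call set is by construction a subset of the
x>=2 set.  Everything else is "steady expression".

Two comparison modes are run over a two-genotype time-course design:

* mode 1 (``time_course``): within each genotype, 5d-0d, 10d-0d, 10d-5d;
* mode 2 (``genotype``): embryogenic vs non-embryogenic genotype at each
  time point (fold change > 1 means more transcript in the embryogenic one).

A single ANOVA per gene (all genotype x time groups) gates both modes; the
FDR correction is applied over the genes tested within each mode.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError
from .io import CtTable
from .quantify import ContrastResult, call_detection, compute_contrast, compute_delta_ct

MODE_TIME_COURSE = "time_course"
MODE_GENOTYPE = "genotype"

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_STEADY = "steady"
STATUS_EXCLUSIVE = "exclusive"
STATUS_UNTESTABLE = "untestable"

MAG_NONE = "none"
MAG_X2 = "x2"
MAG_X10 = "x10"

#: GeneCallTable columns, in output order
CALL_COLUMNS = (
    "gene_id", "mode", "genotype", "contrast", "reference_condition",
    "compared_condition", "n_ref", "n_cmp", "ddct", "log2_fc", "fold_change",
    "signed_fc", "anova_p", "anova_fdr", "t_p", "status", "magnitude",
    "expressed_ref", "expressed_cmp", "exclusive",
)


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA F and p.

    Degenerate inputs follow the gating semantics: zero within-group variance
    with unequal means gives (inf, 0.0); all values identical gives
    (nan, nan), i.e. the gene is untestable.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 values each")
    pooled = np.concatenate(arrays)
    grand = pooled.mean()
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return (float("nan"), float("nan"))
        return (float("inf"), 0.0)
    with warnings.catch_warnings():
        # near-identical replicates trip scipy's precision-loss warning;
        # such genes still get an (extreme, correct) F
        warnings.simplefilter("ignore", RuntimeWarning)
        f, p = stats.f_oneway(*arrays)
    return (float(f), float(p))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def two_sample_t_test(
    a: Sequence[float],
    b: Sequence[float],
    variant: str = "student",
) -> tuple[float, float]:
    """Two-sided two-sample t-test on dCt replicate values.

    Student (pooled-variance) by default, Welch with ``variant="welch"``.
    Zero variance on both sides yields p = 1 at equal means and p = 0
    (infinite t) at unequal means.
    """
    if variant not in ("student", "welch"):
        raise ConfigError(f"unknown t-test variant {variant!r}")
    x = np.asarray(list(a), dtype=float)
    y = np.asarray(list(b), dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs >= 2 values")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if x.mean() == y.mean():
            return (0.0, 1.0)
        return (math.copysign(float("inf"), x.mean() - y.mean()), 0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(x, y, equal_var=(variant == "student"))
    return (float(t), float(p))


def call_gene_status(
    contrast: ContrastResult,
    anova_fdr: float,
    t_p: float,
    alpha_fdr: float = 0.05,
    alpha_t: float = 0.05,
    fold_thresholds: tuple[float, float] = (2.0, 10.0),
) -> tuple[str, str]:
    """Gate one contrast into (status, magnitude).

    Modulated iff ``anova_fdr < alpha_fdr`` and ``t_p < alpha_t`` and
    ``|signed_fc| >= fold_thresholds[0]``; direction from the sign; magnitude
    ``x10`` when additionally ``|signed_fc| >= fold_thresholds[1]`` (both
    thresholds inclusive).  Anything else is steady.  NaN gate values never
    pass, so an untestable ANOVA leaves the gene steady unless flagged
    upstream.
    """
    if not contrast.is_numeric:
        return (STATUS_EXCLUSIVE, MAG_NONE)
    lo, hi = fold_thresholds
    afc = abs(contrast.signed_fc)
    modulated = (anova_fdr < alpha_fdr) and (t_p < alpha_t) and (afc >= lo)
    if not modulated:
        return (STATUS_STEADY, MAG_NONE)
    status = STATUS_UP if contrast.log2_fc > 0 else STATUS_DOWN
    return (status, MAG_X10 if afc >= hi else MAG_X2)


@dataclass
class ComparisonConfig:
    """Tunable gates for :func:`run_comparison_modes`."""

    alpha_fdr: float = 0.05
    alpha_t: float = 0.05
    fold_thresholds: tuple[float, float] = (2.0, 10.0)
    t_variant: str = "student"
    min_detected: int = 2
    fdr_scope: str = "per_mode"  # or "global"


def run_comparison_modes(
    table: CtTable,
    embryogenic: str | None = None,
    config: ComparisonConfig | None = None,
) -> pd.DataFrame:
    """Run both comparison modes over a genotype x time-course Ct table.

    Returns the GeneCallTable: one row per gene per contrast with the ddCt
    quantities, the three gate statistics and the (status, magnitude) call.
    ``embryogenic`` names the genotype treated as the embryogenic culture for
    mode 2 (defaults to "Col-0" when present, else the lexicographically
    first genotype); mode 2 is skipped for single-genotype tables.
    """
    cfg = config or ComparisonConfig()
    norm = compute_delta_ct(table)
    genotypes = table.genotypes
    times = table.time_points
    if embryogenic is None:
        embryogenic = "Col-0" if "Col-0" in genotypes else genotypes[0]
    if embryogenic not in genotypes:
        raise ConfigError(f"genotype {embryogenic!r} not in table")

    # per (gene, condition) replicate dCt vectors, censor flags, detection
    grouped: dict[tuple[str, str, int], dict] = {}
    for (gene, gt, tp), grp in norm.groupby(
        ["gene_id", "genotype", "time_point"], sort=False
    ):
        grouped[(gene, gt, int(tp))] = {
            "delta_ct": grp["delta_ct"].tolist(),
            "censored": grp["censored"].tolist(),
            "expressed": call_detection(
                grp["ct"].tolist(), table.ceiling, cfg.min_detected
            ),
        }
    genes = sorted({k[0] for k in grouped})

    # one ANOVA per gene across every genotype x time group with >= 2 reps
    anova_p: dict[str, float] = {}
    for gene in genes:
        groups = [
            grouped[(gene, gt, tp)]["delta_ct"]
            for gt in genotypes
            for tp in times
            if (gene, gt, tp) in grouped
            and len(grouped[(gene, gt, tp)]["delta_ct"]) >= 2
        ]
        if len(groups) < 2:
            anova_p[gene] = float("nan")
        else:
            anova_p[gene] = one_way_anova(groups)[1]

    def fdr_map(gene_subset: list[str]) -> dict[str, float]:
        tested = [g for g in gene_subset if not math.isnan(anova_p[g])]
        if not tested:
            return {}
        adj = bh_adjust([anova_p[g] for g in tested])
        return dict(zip(tested, adj))

    fdr_global = fdr_map(genes) if cfg.fdr_scope == "global" else None

    rows: list[dict] = []

    def emit(gene, mode, genotype, label, ref_key, cmp_key, fdr):
        ref = grouped.get((gene, *ref_key))
        cmp_ = grouped.get((gene, *cmp_key))
        if ref is None or cmp_ is None:
            return
        base = dict(
            gene_id=gene, mode=mode, genotype=genotype, contrast=label,
            reference_condition=f"{ref_key[0]}:{ref_key[1]}d",
            compared_condition=f"{cmp_key[0]}:{cmp_key[1]}d",
            anova_p=anova_p[gene],
            anova_fdr=fdr.get(gene, float("nan")),
            expressed_ref=ref["expressed"], expressed_cmp=cmp_["expressed"],
        )
        if len(ref["delta_ct"]) < 2 or len(cmp_["delta_ct"]) < 2:
            rows.append(dict(
                base, n_ref=len(ref["delta_ct"]), n_cmp=len(cmp_["delta_ct"]),
                ddct=float("nan"), log2_fc=float("nan"),
                fold_change=float("nan"), signed_fc=float("nan"),
                t_p=float("nan"), status=STATUS_UNTESTABLE,
                magnitude=MAG_NONE, exclusive=None,
            ))
            return
        contrast = compute_contrast(
            gene, ref["delta_ct"], cmp_["delta_ct"],
            ref["censored"], cmp_["censored"],
            reference_condition=ref_key, compared_condition=cmp_key,
        )
        if contrast.is_numeric:
            t_p = two_sample_t_test(
                ref["delta_ct"], cmp_["delta_ct"], cfg.t_variant
            )[1]
        else:
            t_p = float("nan")
        status, magnitude = call_gene_status(
            contrast, base["anova_fdr"], t_p,
            cfg.alpha_fdr, cfg.alpha_t, cfg.fold_thresholds,
        )
        rows.append(dict(
            base, n_ref=contrast.n_ref, n_cmp=contrast.n_cmp,
            ddct=contrast.ddct, log2_fc=contrast.log2_fc,
            fold_change=contrast.fold_change, signed_fc=contrast.signed_fc,
            t_p=t_p, status=status, magnitude=magnitude,
            exclusive=contrast.exclusive,
        ))

    # mode 1: successive time points within each genotype
    fdr1 = fdr_global if fdr_global is not None else fdr_map(genes)
    pairs = [(ref_t, cmp_t) for i, ref_t in enumerate(times)
             for cmp_t in times[i + 1:]]
    for gene in genes:
        for gt in genotypes:
            for ref_t, cmp_t in pairs:
                emit(gene, MODE_TIME_COURSE, gt, f"{cmp_t}d-{ref_t}d",
                     (gt, ref_t), (gt, cmp_t), fdr1)

    # mode 2: embryogenic vs the other genotype at each time point
    others = [g for g in genotypes if g != embryogenic]
    if others:
        fdr2 = fdr_global if fdr_global is not None else fdr_map(genes)
        for gene in genes:
            for other in others:
                for tp in times:
                    emit(gene, MODE_GENOTYPE, embryogenic,
                         f"{embryogenic}-vs-{other}:{tp}d",
                         (other, tp), (embryogenic, tp), fdr2)

    return pd.DataFrame(rows, columns=list(CALL_COLUMNS))
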