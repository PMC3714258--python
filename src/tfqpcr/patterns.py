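"""Higher-order expression-pattern classification.

Covers set accounting of expressed genes (Venn regions), two-axis trajectory
labels over the induction (5d vs 0d) and formation (10d vs 5d) stages, the
genotype-contrast classifier that picks out genes behaving differently in
embryogenic versus non-embryogenic cultures, k-means clustering of
expression-index profiles, and a sample-level PCA for replicate quality
control.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import ConfigError
from .differential import (
    MAG_NONE,
    MAG_X2,
    MAG_X10,
    MODE_TIME_COURSE,
    STATUS_DOWN,
    STATUS_STEADY,
    STATUS_UP,
)

TRAJECTORY_CLASSES = ("up_x2", "up_x10", "down_x2", "down_x10", "steady")
SE_GROUPS = ("i", "ii", "iii_a", "iii_b", "iv", "none")


# ---------------------------------------------------------------------------
# Venn accounting


def venn_regions(sets: Mapping[str, Iterable]) -> dict[str, int]:
    """Counts of the disjoint regions of 2 or 3 named sets.

    Region labels join the member-set names with ``&`` (e.g. ``"0d&5d"`` is
    the genes in exactly those two sets).  Counts sum to the union size.
    """
    named = {name: set(vals) for name, vals in sets.items()}
    if len(named) not in (2, 3):
        raise ConfigError("venn_regions supports 2 or 3 sets")
    names = list(named)
    regions: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for inside in itertools.combinations(names, r):
            outside = [n for n in names if n not in inside]
            members = set.intersection(*(named[n] for n in inside))
            for n in outside:
                members -= named[n]
            regions["&".join(inside)] = len(members)
    return regions


# ---------------------------------------------------------------------------
# trajectory classification


def call_label(signed_fc: float, modulated: bool) -> str:
    """Finest trajectory label for one contrast call."""
    if not modulated or np.isnan(signed_fc):
        return "steady"
    direction = "up" if signed_fc > 0 else "down"
    return f"{direction}_{'x10' if abs(signed_fc) >= 10 else 'x2'}"


def classify_trajectory(
    induction: tuple[float, bool],
    formation: tuple[float, bool],
) -> tuple[str, str]:
    """Label the induction- and formation-stage contrasts of one gene.

    Each argument is ``(signed_fc, modulated)``; a contrast that is not
    modulated (failed gates or below 2-fold) is "steady".
    """
    return (call_label(*induction), call_label(*formation))


#: Table-2-style row/column orders (x>=2 rows contain their x>=10 subsets)
_CROSSTAB_ROWS = ("up_x2", "up_x10", "down_x2", "down_x10", "steady")
_CROSSTAB_COLS = ("down_x2", "down_x10", "up_x2", "up_x10", "steady")


def crosstab_trajectories(labels: pd.DataFrame) -> pd.DataFrame:
    """Cross-tabulate induction-stage against formation-stage classes.

    ``labels`` needs columns ``induction_class`` and ``formation_class``
    holding finest labels.  In the output the ``*_x2`` rows/columns roll up
    their ``*_x10`` subsets (a gene at 16-fold counts in both ``up_x2`` and
    ``up_x10``), mirroring nested fold-change thresholds; a ``row_total``
    column gives the induction-stage totals.
    """

    def roll(label: str) -> set[str]:
        if label.endswith("_x10"):
            return {label, label.replace("_x10", "_x2")}
        return {label}

    counts = pd.DataFrame(
        0, index=list(_CROSSTAB_ROWS), columns=list(_CROSSTAB_COLS), dtype=int
    )
    totals = pd.Series(0, index=list(_CROSSTAB_ROWS), dtype=int)
    for _, row in labels.iterrows():
        rows = roll(str(row["induction_class"]))
        cols = roll(str(row["formation_class"]))
        for r in rows:
            totals[r] += 1
            for c in cols:
                counts.loc[r, c] += 1
    counts.insert(0, "row_total", totals)
    counts.index.name = "induction_class"
    return counts


# ---------------------------------------------------------------------------
# SE-specific (genotype-contrast) classification


@dataclass(frozen=True)
class ContrastCall:
    """One contrast of one gene in one genotype: signed fold change + gate."""

    signed_fc: float
    modulated: bool

    @property
    def label(self) -> str:
        return call_label(self.signed_fc, self.modulated)

    @property
    def direction(self) -> str:
        if not self.modulated:
            return STATUS_STEADY
        return STATUS_UP if self.signed_fc > 0 else STATUS_DOWN


@dataclass(frozen=True)
class GenotypeCalls:
    """Per-genotype evidence inspected by the SE-specific classifier.

    ``induction`` is the 5d-0d contrast and ``formation`` the 5d-10d
    contrast (expression at 5 d relative to 10 d); ``expressed`` is true
    when the gene is detected at any culture time point of the genotype.
    """

    expressed: bool
    induction: ContrastCall
    formation: ContrastCall


def classify_se_specific(
    embryogenic: GenotypeCalls,
    non_embryogenic: GenotypeCalls,
) -> str:
    """Assign a gene to one genotype-contrast group.

    Precedence (groups are disjoint):

    i.      expressed in the embryogenic culture, never detected in the
            non-embryogenic one (exclusive expression);
    iii_a.  up-regulated in the embryogenic and down-regulated in the
            non-embryogenic culture at 5d-0d (both modulated); iii_b the
            reverse;
    ii.     modulated in the embryogenic culture but steady in the
            non-embryogenic one across both inspected contrasts;
    iv.     down-regulated in the non-embryogenic culture while the two
            genotypes' per-contrast labels differ (a gene with identical
            labels in both cultures is a shared response, not SE-specific);
    none.   everything else.
    """
    emb, mut = embryogenic, non_embryogenic
    if emb.expressed and not mut.expressed:
        return "i"
    if emb.induction.modulated and mut.induction.modulated:
        if emb.induction.direction == STATUS_UP and mut.induction.direction == STATUS_DOWN:
            return "iii_a"
        if emb.induction.direction == STATUS_DOWN and mut.induction.direction == STATUS_UP:
            return "iii_b"
    emb_modulated = emb.induction.modulated or emb.formation.modulated
    mut_modulated = mut.induction.modulated or mut.formation.modulated
    if emb_modulated and not mut_modulated:
        return "ii"
    same_profile = (
        emb.induction.label == mut.induction.label
        and emb.formation.label == mut.formation.label
    )
    if not same_profile and (
        (mut.induction.modulated and mut.induction.direction == STATUS_DOWN)
        or (mut.formation.modulated and mut.formation.direction == STATUS_DOWN)
    ):
        return "iv"
    return "none"


def _flip_signed(signed_fc: float) -> float:
    """signed_fc of the reversed contrast (reciprocal convention)."""
    if np.isnan(signed_fc) or abs(signed_fc) <= 1:
        return signed_fc if np.isnan(signed_fc) else 1.0
    return -signed_fc


def genotype_calls_from_table(
    calls: pd.DataFrame,
    genotype: str,
    induction_contrast: str = "5d-0d",
    formation_contrast: str = "10d-5d",
) -> dict[str, GenotypeCalls]:
    """Build per-gene :class:`GenotypeCalls` from a GeneCallTable.

    The formation evidence is taken from the pipeline's 10d-5d contrast and
    re-expressed as 5d-10d by flipping the signed fold change.  Exclusive
    or untestable contrasts contribute an unmodulated (steady) call; the
    expressed flag is the union over the genotype's conditions.
    """
    sub = calls[
        (calls["mode"] == MODE_TIME_COURSE) & (calls["genotype"] == genotype)
    ]
    out: dict[str, GenotypeCalls] = {}
    for gene, grp in sub.groupby("gene_id"):
        by_contrast = {r["contrast"]: r for _, r in grp.iterrows()}

        def _call(name: str, flip: bool) -> ContrastCall:
            row = by_contrast.get(name)
            if row is None:
                return ContrastCall(float("nan"), False)
            sfc = float(row["signed_fc"])
            modulated = row["status"] in (STATUS_UP, STATUS_DOWN)
            return ContrastCall(_flip_signed(sfc) if flip else sfc, modulated)

        expressed = bool(
            grp[["expressed_ref", "expressed_cmp"]].to_numpy().any()
        )
        out[gene] = GenotypeCalls(
            expressed=expressed,
            induction=_call(induction_contrast, flip=False),
            formation=_call(formation_contrast, flip=True),
        )
    return out


def se_groups_from_calls(
    calls: pd.DataFrame,
    embryogenic: str,
    non_embryogenic: str,
) -> pd.Series:
    """SE-specific group per gene from a two-genotype GeneCallTable."""
    emb = genotype_calls_from_table(calls, embryogenic)
    mut = genotype_calls_from_table(calls, non_embryogenic)
    genes = sorted(set(emb) | set(mut))
    missing = ContrastCall(float("nan"), False)
    empty = GenotypeCalls(False, missing, missing)
    return pd.Series(
        {
            g: classify_se_specific(emb.get(g, empty), mut.get(g, empty))
            for g in genes
        },
        name="se_group",
    )


# ---------------------------------------------------------------------------
# k-means pattern clustering


def kmeans_patterns(
    profiles: pd.DataFrame,
    k: int = 4,
    restarts: int = 10,
    seed: int = 0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Cluster per-gene expression-index profiles with Lloyd's k-means.

    ``profiles`` is genes x time points (condition means of the
    40 - dCt expression index).  Runs ``restarts`` seeded restarts keeping
    the lowest within-cluster sum of squares, then renumbers clusters 1..k
    by descending centroid mean so labels are deterministic.  Returns
    (per-gene cluster labels, centroid matrix indexed by cluster).
    """
    X = profiles.to_numpy(dtype=float)
    if k < 1:
        raise ConfigError("k must be >= 1")
    n_distinct = np.unique(X, axis=0).shape[0]
    if k > n_distinct:
        raise ConfigError(
            f"k={k} exceeds the {n_distinct} distinct profiles available"
        )
    km = KMeans(
        n_clusters=k, n_init=restarts, random_state=seed, algorithm="lloyd"
    ).fit(X)
    order = np.argsort(-km.cluster_centers_.mean(axis=1), kind="stable")
    relabel = {int(old): rank + 1 for rank, old in enumerate(order)}
    labels = pd.Series(
        [relabel[int(l)] for l in km.labels_], index=profiles.index,
        name="cluster",
    )
    centroids = pd.DataFrame(
        km.cluster_centers_[order], columns=profiles.columns,
        index=pd.RangeIndex(1, k + 1, name="cluster"),
    )
    return labels, centroids


def mean_profiles(norm: pd.DataFrame, genotype: str | None = None) -> pd.DataFrame:
    """Per-gene mean expression_index at each time point (k-means input)."""
    df = norm if genotype is None else norm[norm["genotype"] == genotype]
    wide = df.pivot_table(
        index="gene_id", columns="time_point", values="expression_index",
        aggfunc="mean",
    )
    wide.columns = [f"{int(c)}d" for c in wide.columns]
    return wide


# ---------------------------------------------------------------------------
# PCA quality control


def pca_samples(
    matrix: pd.DataFrame,
    center: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Sample-level PCA of a samples x genes expression-index matrix.

    Column-centered (unscaled) singular-value decomposition; zero-variance
    genes are dropped.  Sign convention: the largest-magnitude element of
    each loading vector is positive.  Returns (scores, loadings,
    variance_fractions); the fractions sum to one.
    """
    if matrix.shape[0] < 2:
        raise ConfigError("PCA needs at least 2 samples")
    X = matrix.to_numpy(dtype=float)
    keep = X.var(axis=0) > 0
    X = X[:, keep]
    genes = matrix.columns[keep]
    if center:
        X = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    # deterministic signs: biggest loading component positive per PC
    for j in range(vt.shape[0]):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    n_keep = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    u, s, vt = u[:, :n_keep], s[:n_keep], vt[:n_keep]
    pcs = [f"PC{i + 1}" for i in range(n_keep)]
    scores = pd.DataFrame(u * s, index=matrix.index, columns=pcs)
    loadings = pd.DataFrame(vt.T, index=genes, columns=pcs)
    var = s ** 2
    fractions = var / var.sum() if var.size else var
    return scores, loadings, fractions
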