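"""Summary tables: directional counts with percentages and annotation tallies.

Percentages are rounded half-away-from-zero to whole percent, the convention
that reproduces every verifiable printed value in the study this pipeline is
modelled on (e.g. 546/673 -> 81, 312/358 -> 87).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections.abc import Iterable, Mapping

import pandas as pd

from .differential import MODE_TIME_COURSE, STATUS_DOWN, STATUS_UP
from .errors import ConfigError
from .io import AnnotationTable


def rounded_percent(numerator: float, denominator: float) -> int:
    """100 * numerator / denominator, rounded half-away-from-zero."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    x = 100.0 * numerator / denominator
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class DirectionalSummary:
    """One row of a directional-count table (up/down split of one contrast)."""

    comparison: str
    threshold: str
    n_total: int
    n_up: int
    n_down: int

    @property
    def pct_up(self) -> int:
        return rounded_percent(self.n_up, self.n_total)

    @property
    def pct_down(self) -> int:
        return rounded_percent(self.n_down, self.n_total)


def percentage_table(
    n_up: int,
    n_down: int,
    comparison: str = "",
    threshold: str = "x2",
) -> DirectionalSummary:
    """Directional summary from up/down counts."""
    if n_up < 0 or n_down < 0:
        raise ConfigError("counts must be non-negative")
    if n_up + n_down == 0:
        raise ConfigError("empty summary: no up- or down-regulated genes")
    return DirectionalSummary(
        comparison=comparison, threshold=threshold,
        n_total=n_up + n_down, n_up=n_up, n_down=n_down,
    )


def directional_counts(calls: pd.DataFrame, genotype: str) -> pd.DataFrame:
    """Directional-count table over a genotype's time-course contrasts.

    One row per (contrast, threshold): at x2 every modulated gene counts,
    at x10 only the drastic subset, so the x10 totals are nested within the
    x2 totals.
    """
    sub = calls[
        (calls["mode"] == MODE_TIME_COURSE) & (calls["genotype"] == genotype)
    ]
    rows = []
    for contrast, grp in sub.groupby("contrast", sort=False):
        for threshold in ("x2", "x10"):
            if threshold == "x2":
                mask = grp["status"].isin([STATUS_UP, STATUS_DOWN])
            else:
                mask = grp["magnitude"] == "x10"
            n_up = int((grp.loc[mask, "status"] == STATUS_UP).sum())
            n_down = int((grp.loc[mask, "status"] == STATUS_DOWN).sum())
            if n_up + n_down == 0:
                continue
            s = percentage_table(n_up, n_down, str(contrast), threshold)
            rows.append(dict(
                comparison=s.comparison, threshold=s.threshold,
                n_total=s.n_total, n_up=s.n_up, n_down=s.n_down,
                pct_up=s.pct_up, pct_down=s.pct_down,
            ))
    return pd.DataFrame(rows)


def annotation_tally(
    genes: Iterable[str],
    annotation: AnnotationTable,
) -> dict:
    """Family and functional-category tallies over a gene set.

    A gene carrying several categories counts once in each category row but
    only once in the annotated total.  Returns family counts, category
    counts, the number and rounded percentage of annotated genes, and the
    gene-set size (the denominator is carried so report rows are
    unambiguous).
    """
    genes = set(genes)
    families: dict[str, int] = {}
    categories: dict[str, int] = {}
    annotated = 0
    for g in sorted(genes):
        fam = annotation.family.get(g)
        if fam:
            families[fam] = families.get(fam, 0) + 1
        cats = annotation.categories.get(g, set())
        if cats:
            annotated += 1
        for c in sorted(cats):
            categories[c] = categories.get(c, 0) + 1
    return {
        "family_counts": pd.Series(families, dtype=int).sort_values(
            ascending=False
        ),
        "category_counts": pd.Series(categories, dtype=int).sort_values(
            ascending=False
        ),
        "n_genes": len(genes),
        "n_annotated": annotated,
        "pct_annotated": rounded_percent(annotated, len(genes)) if genes else 0,
    }


def hormone_direction_tally(
    status_by_gene: Mapping[str, str],
    annotation: AnnotationTable,
) -> pd.DataFrame:
    """Percent up-/down-regulated per hormone class.

    ``status_by_gene`` maps each modulated gene to "up" or "down"; genes
    without a hormone class, and hormone classes with no modulated genes,
    are omitted.
    """
    per_class: dict[str, list[str]] = {}
    for gene, status in status_by_gene.items():
        hclass = annotation.hormone_class.get(gene)
        if hclass and status in (STATUS_UP, STATUS_DOWN):
            per_class.setdefault(hclass, []).append(status)
    rows = []
    for hclass in sorted(per_class):
        statuses = per_class[hclass]
        n_up = statuses.count(STATUS_UP)
        n_down = statuses.count(STATUS_DOWN)
        rows.append(dict(
            hormone_class=hclass, n_up=n_up, n_down=n_down,
            pct_up=rounded_percent(n_up, n_up + n_down),
            pct_down=rounded_percent(n_down, n_up + n_down),
        ))
    return pd.DataFrame(
        rows, columns=["hormone_class", "n_up", "n_down", "pct_up", "pct_down"]
    )
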