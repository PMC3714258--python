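"""Synthetic Ct-data generator with full ground truth.

Emulates the measurement process of a two-genotype (embryogenic vs
non-embryogenic), three-time-point (0/5/10 d), three-replicate qRT-PCR
screen: each (genotype, time point) is one PCR run carrying four reference
wells; every gene's true dCt trajectory is a baseline plus planted log2
effects, and the observed Ct is the run's realized reference level plus the
true dCt plus Gaussian cycle noise, censored at the 40-cycle detection
ceiling.  Because the planted dCt is defined relative to the run's reference
median, setting ``noise_sd = 0`` makes the pipeline recover the planted log2
fold changes exactly, independent of reference-well scatter.

Planted gene classes:

* ``steady`` / ``up_x2`` / ``up_x10`` / ``down_x2`` / ``down_x10`` -- the
  same induction-stage (5d vs 0d) effect in both genotypes (auxin response
  shared by the cultures), hence no genotype contrast;
* ``unexpressed`` -- at the ceiling in every sample;
* ``se_i`` .. ``se_iv`` -- the four genotype-contrast groups: exclusive
  expression in the embryogenic culture (i), modulated only there (ii),
  opposite directions (iii_a/iii_b), and mutant-biased down-regulation (iv).

Class counts follow the configured fractions by largest-remainder
apportionment, then a seeded shuffle assigns classes to gene ids; everything
downstream is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from collections.abc import Mapping

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .errors import ConfigError
from .io import CtTable, DEFAULT_REFERENCE_GENE

CLASSES = (
    "steady", "up_x2", "up_x10", "down_x2", "down_x10", "unexpressed",
    "se_i", "se_ii", "se_iii_a", "se_iii_b", "se_iv",
)

#: study-scale default class mix: mostly steady, modulation dominated by
#: up-regulation, a small SE-specific complement
DEFAULT_FRACTIONS: dict[str, float] = {
    "steady": 0.50,
    "up_x2": 0.12,
    "up_x10": 0.10,
    "down_x2": 0.06,
    "down_x10": 0.04,
    "unexpressed": 0.06,
    "se_i": 0.02,
    "se_ii": 0.04,
    "se_iii_a": 0.02,
    "se_iii_b": 0.02,
    "se_iv": 0.02,
}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic screen.

    Effects are log2 fold changes applied between 0 d and 5 d; the x10-class
    effect must stay at or above log2(10) so planted truth is consistent
    with the 10-fold calling threshold.  Noise is Gaussian on the Ct (cycle)
    scale.  ``run_per_replicate`` splits every biological replicate onto its
    own PCR run instead of one run per condition.
    """

    n_genes: int = 200
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FRACTIONS)
    )
    effect_x2: float = 1.5
    effect_x10: float = 3.5
    noise_sd: float = 0.25
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    reference_ct_mean: float = 22.0
    reference_ct_sd: float = 0.2
    wells_per_run: int = 4
    ceiling: float = 40.0
    n_replicates: int = 3
    time_points: tuple[int, ...] = (0, 5, 10)
    genotypes: tuple[str, str] = ("Col-0", "tan1-2")
    run_per_replicate: bool = False
    seed: int = 0

    def validate(self) -> None:
        unknown = set(self.class_fractions) - set(CLASSES)
        if unknown:
            raise ConfigError(f"unknown gene classes: {sorted(unknown)}")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class fractions sum to {total}, expected 1")
        if self.class_fractions.get("up_x10", 0) or self.class_fractions.get(
            "down_x10", 0
        ) or any(
            self.class_fractions.get(c, 0) for c in ("se_i", "se_ii",
                                                     "se_iii_a", "se_iii_b")
        ):
            if self.effect_x10 < math.log2(10):
                raise ConfigError(
                    "effect_x10 below log2(10): planted x10 classes would "
                    "contradict the 10-fold threshold"
                )


def allocate_classes(fractions: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of ``n`` genes over the classes."""
    shares = {c: fractions.get(c, 0.0) * n for c in CLASSES}
    counts = {c: int(math.floor(s)) for c, s in shares.items()}
    remainder = n - sum(counts.values())
    by_frac = sorted(
        CLASSES, key=lambda c: (-(shares[c] - counts[c]), CLASSES.index(c))
    )
    for c in by_frac[:remainder]:
        counts[c] += 1
    return counts


# per class: (emb induction, emb formation, mut induction, mut formation,
#             emb expressed, mut expressed); effects are in units of
# (effect_x2, effect_x10) picked below
def _class_effects(cls: str, e2: float, e10: float):
    table = {
        "steady":      (0.0, 0.0, 0.0, 0.0, True, True),
        "up_x2":       (+e2, 0.0, +e2, 0.0, True, True),
        "up_x10":      (+e10, 0.0, +e10, 0.0, True, True),
        "down_x2":     (-e2, 0.0, -e2, 0.0, True, True),
        "down_x10":    (-e10, 0.0, -e10, 0.0, True, True),
        "unexpressed": (0.0, 0.0, 0.0, 0.0, False, False),
        "se_i":        (+e10, 0.0, 0.0, 0.0, True, False),
        "se_ii":       (+e10, 0.0, 0.0, 0.0, True, True),
        "se_iii_a":    (+e10, 0.0, -e10, 0.0, True, True),
        "se_iii_b":    (-e10, 0.0, +e10, 0.0, True, True),
        "se_iv":       (-e2, 0.0, -e10, 0.0, True, True),
    }
    return table[cls]


def _effect_label(effect: float) -> str:
    if abs(effect) < 1.0:
        return "steady"
    direction = "up" if effect > 0 else "down"
    return f"{direction}_{'x10' if abs(effect) >= math.log2(10) else 'x2'}"


def _planted_se_group(cls: str) -> str:
    return cls[3:] if cls.startswith("se_") else "none"


def generate_dataset(config: GeneratorConfig) -> tuple[CtTable, pd.DataFrame]:
    """Generate a Ct table and its ground truth.

    The ground truth has one row per gene: planted class, SE-specific group,
    per-genotype expressed flags, trajectory labels and planted log2 effects
    for the induction (5d-0d) and formation (10d-5d) contrasts of the
    embryogenic genotype.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    counts = allocate_classes(config.class_fractions, config.n_genes)
    labels = [c for c in CLASSES for _ in range(counts[c])]
    rng.shuffle(labels)
    width = max(4, len(str(config.n_genes)))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(config.n_genes)]

    emb, mut = config.genotypes
    baselines = np.clip(
        rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes),
        2.0, 14.0,
    )

    # PCR runs and their reference wells
    runs: list[tuple[str, str, int, int]] = []  # (run_id, genotype, time, rep)
    for gt in config.genotypes:
        for tp in config.time_points:
            if config.run_per_replicate:
                for rep in range(1, config.n_replicates + 1):
                    runs.append((f"{gt}_{tp}d_r{rep}", gt, tp, rep))
            else:
                runs.append((f"{gt}_{tp}d", gt, tp, 0))
    wells: dict[str, list[float]] = {}
    ref_median: dict[str, float] = {}
    for run_id, *_ in runs:
        w = rng.normal(
            config.reference_ct_mean, config.reference_ct_sd,
            config.wells_per_run,
        )
        w = np.clip(w, 1.0, config.ceiling)
        wells[run_id] = [float(v) for v in w]
        ref_median[run_id] = float(np.median(w))

    def run_for(gt: str, tp: int, rep: int) -> str:
        return f"{gt}_{tp}d_r{rep}" if config.run_per_replicate else f"{gt}_{tp}d"

    records = []
    truth_rows = []
    for gene, cls, b in zip(gene_ids, labels, baselines):
        e_ind_emb, e_form_emb, e_ind_mut, e_form_mut, exp_emb, exp_mut = (
            _class_effects(cls, config.effect_x2, config.effect_x10)
        )
        per_genotype = {
            emb: (e_ind_emb, e_form_emb, exp_emb),
            mut: (e_ind_mut, e_form_mut, exp_mut),
        }
        for gt in config.genotypes:
            e_ind, e_form, expressed = per_genotype[gt]
            cum = {0: 0.0}
            if len(config.time_points) > 1:
                cum[config.time_points[1]] = e_ind
            if len(config.time_points) > 2:
                cum[config.time_points[2]] = e_ind + e_form
            for tp in config.time_points:
                for rep in range(1, config.n_replicates + 1):
                    run_id = run_for(gt, tp, rep)
                    if not expressed:
                        ct = config.ceiling
                    else:
                        # up-regulation lowers dCt by the planted log2 effect
                        true_dct = b - cum.get(tp, 0.0)
                        ct = (
                            ref_median[run_id]
                            + true_dct
                            + (rng.normal(0.0, config.noise_sd)
                               if config.noise_sd > 0 else 0.0)
                        )
                        ct = float(min(max(ct, 1.0), config.ceiling))
                    records.append(dict(
                        gene_id=gene, genotype=gt, time_point=tp,
                        replicate=rep, run_id=run_id, ct=ct,
                    ))
        truth_rows.append(dict(
            gene_id=gene, planted_class=cls,
            se_group=_planted_se_group(cls),
            emb_expressed=exp_emb, mut_expressed=exp_mut,
            induction_class=_effect_label(e_ind_emb) if exp_emb else "steady",
            formation_class=_effect_label(e_form_emb) if exp_emb else "steady",
            emb_log2_induction=e_ind_emb, emb_log2_formation=e_form_emb,
            mut_log2_induction=e_ind_mut, mut_log2_formation=e_form_mut,
        ))

    table = CtTable(
        records=pd.DataFrame.from_records(records),
        reference_wells=wells,
        reference_gene_id=DEFAULT_REFERENCE_GENE,
        ceiling=config.ceiling,
    )
    truth = pd.DataFrame(truth_rows).set_index("gene_id")
    return table, truth


def ct_table_to_frame(table: CtTable) -> pd.DataFrame:
    """Flatten a CtTable (records + reference wells) back into file rows."""
    ref_rows = [
        dict(gene_id=table.reference_gene_id, genotype="", time_point=0,
             replicate=i + 1, run_id=run, ct=ct)
        for run, well_cts in sorted(table.reference_wells.items())
        for i, ct in enumerate(well_cts)
    ]
    return pd.concat(
        [table.records, pd.DataFrame(ref_rows)], ignore_index=True
    )


# ---------------------------------------------------------------------------
# recovery instrumentation


def confusion_metrics(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    """Sensitivity, specificity and empirical FDR from a 2x2 confusion."""
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    fdr = fp / (tp + fp) if tp + fp else 0.0
    return {"sensitivity": sens, "specificity": spec, "fdr": fdr,
            "tp": tp, "fp": fp, "fn": fn, "tn": tn}


def recovery_metrics(
    truth: pd.DataFrame,
    calls: pd.DataFrame,
    embryogenic: str = "Col-0",
    se_groups: pd.Series | None = None,
    clusters: pd.Series | None = None,
    cluster_truth: pd.Series | None = None,
) -> dict:
    """Compare pipeline calls against planted truth.

    Detection metrics are computed on the embryogenic genotype's induction
    (5d-0d) contrast: a planted positive is any gene with a modulated
    induction class, a called positive any gene with status up/down there.
    Optionally adds the SE-group confusion matrix and the adjusted Rand
    index of a clustering against planted archetypes.
    """
    from .differential import MODE_TIME_COURSE, STATUS_DOWN, STATUS_UP

    sub = calls[
        (calls["mode"] == MODE_TIME_COURSE)
        & (calls["genotype"] == embryogenic)
        & (calls["contrast"] == "5d-0d")
    ].set_index("gene_id")
    truth_genes = set(truth.index)
    call_genes = set(sub.index)
    if truth_genes != call_genes:
        diff = sorted(truth_genes.symmetric_difference(call_genes))
        raise ValueError(f"gene sets differ between truth and calls: {diff}")

    planted_pos = truth["induction_class"] != "steady"
    called_pos = sub.loc[truth.index, "status"].isin(
        [STATUS_UP, STATUS_DOWN]
    )
    tp = int((planted_pos & called_pos).sum())
    fp = int((~planted_pos & called_pos).sum())
    fn = int((planted_pos & ~called_pos).sum())
    tn = int((~planted_pos & ~called_pos).sum())
    out: dict = {"induction_detection": confusion_metrics(tp, fp, fn, tn)}

    recovered = sub.loc[truth.index].apply(
        lambda r: _row_label(r), axis=1
    )
    out["induction_class_exact"] = float(
        (recovered == truth["induction_class"]).mean()
    )
    if se_groups is not None:
        aligned = se_groups.reindex(truth.index).fillna("none")
        out["se_confusion"] = pd.crosstab(
            truth["se_group"], aligned, rownames=["planted"],
            colnames=["recovered"],
        )
        out["se_exact"] = float((aligned == truth["se_group"]).mean())
    if clusters is not None and cluster_truth is not None:
        idx = clusters.index.intersection(cluster_truth.index)
        out["cluster_ari"] = float(
            adjusted_rand_score(cluster_truth.loc[idx], clusters.loc[idx])
        )
    return out


def _row_label(row) -> str:
    from .patterns import call_label

    if row["status"] in ("up", "down"):
        return call_label(float(row["signed_fc"]), True)
    return "steady"
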