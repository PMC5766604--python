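"""Scenario orchestration and method-comparison statistics.

Scenario 1 classifies all nine grasp classes at five noise levels
(sigma = 0, 0.2, 0.4, 0.6, 0.8).  Scenario 2 enumerates every c-class
subproblem of the nine classes for c in {2, 4, 6, 8} — 36 + 126 + 84 + 9
= 255 problems — at a single noise level.  Human subjects are replaced by
seeded synthetic replicates of the generator; per-method mean t-scores
are compared by one-way ANOVA with pairwise post-hoc t-tests.
"""

from __future__ import annotations

import itertools
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .classification import HyperGrids, select_and_test, tscore_normalize
from .metrics import metric_report
from .preprocessing import split_dataset
from .synthetic import SynthSpec, generate_dataset

logger = logging.getLogger(__name__)

DEFAULT_SIGMAS = (0.0, 0.2, 0.4, 0.6, 0.8)
DEFAULT_METHODS = ("pca", "l1", "sspca", "srssd")


@dataclass
class ExperimentConfig:
    """Everything needed to regenerate a scenario run."""

    scenario: int = 1
    methods: tuple = DEFAULT_METHODS
    sigmas: tuple = DEFAULT_SIGMAS
    c_values: tuple = (2, 4, 6, 8)
    n_subjects: int = 6
    seed: int = 0
    grids: HyperGrids = field(default_factory=HyperGrids)
    synth: SynthSpec = field(default_factory=SynthSpec)
    subsample_fraction: float = 1.0  # scenario-2 problem subsampling
    learner_opts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("methods must be nonempty")
        if self.scenario not in (1, 2):
            raise ValueError(f"scenario must be 1 or 2, got {self.scenario}")
        if not (0.0 < self.subsample_fraction <= 1.0):
            raise ValueError("subsample_fraction must lie in (0, 1]")


def enumerate_problems(c: int, class_labels=None) -> list[tuple]:
    """All unordered c-class subsets of the nine classes, lexicographic."""
    if class_labels is None:
        class_labels = [f"A{i}" for i in range(1, 10)]
    if not (2 <= c <= len(class_labels)):
        raise ValueError(f"c must lie in [2, {len(class_labels)}], got {c}")
    return list(itertools.combinations(class_labels, c))


def _subject_spec(base: SynthSpec, subject: int, seed: int) -> SynthSpec:
    """Per-replicate generator spec with a derived seed."""
    spec = SynthSpec(**{**base.__dict__})
    spec.seed = (seed * 10007 + subject * 101 + 13) % (2**31)
    return spec


def _records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def run_scenario1(config: ExperimentConfig) -> pd.DataFrame:
    """Nine-class benchmark: subjects x methods x noise levels.

    Returns a tidy frame with one row per (subject, method, sigma) holding
    the selected hyperparameters, test accuracy, t-score and the sparsity/
    commonality/selectivity metrics of the winning solution.
    """
    records, metric_rows = [], []
    for subject in range(config.n_subjects):
        spec = _subject_spec(config.synth, subject, config.seed)
        dataset, _ = generate_dataset(spec)
        split = split_dataset(dataset.labels, seed=spec.seed + 1)
        for method in config.methods:
            for sigma in config.sigmas:
                t0 = time.perf_counter()
                rec, art = select_and_test(
                    dataset, split, method, config.grids, sigma,
                    seed=spec.seed, subject_id=subject,
                    learner_opts=config.learner_opts,
                )
                report = metric_report(
                    art["U_test"], art["learner"].dictionary_, art["y_test"])
                metric_rows.append(dict(
                    coeff_sparsity=report.coeff_sparsity,
                    dict_sparsity=report.dict_sparsity,
                    mean_commonality=report.mean_commonality,
                    mean_selectivity=report.mean_selectivity,
                ))
                records.append(rec)
                logger.info("subject %d %s sigma=%.1f acc=%.3f (%.1fs)",
                            subject, method, sigma, rec.accuracy,
                            time.perf_counter() - t0)
    tscore_normalize(records)
    df = _records_to_frame(records)
    return pd.concat([df, pd.DataFrame(metric_rows)], axis=1)


def run_scenario2(config: ExperimentConfig, sigma: float = 0.8) -> pd.DataFrame:
    """c-class subproblem benchmark at a single noise level.

    Enumerates every c-class problem for c in config.c_values; with
    ``subsample_fraction < 1`` a seeded subset of problems is run and the
    fraction is recorded in every output row.
    """
    rng = np.random.default_rng(config.seed)
    problems = []
    for c in config.c_values:
        probs = enumerate_problems(c, config.synth.class_labels)
        if config.subsample_fraction < 1.0:
            keep = max(1, int(round(config.subsample_fraction * len(probs))))
            idx = np.sort(rng.choice(len(probs), size=keep, replace=False))
            probs = [probs[i] for i in idx]
        problems.extend([(c, p) for p in probs])

    records, extra = [], []
    for subject in range(config.n_subjects):
        spec = _subject_spec(config.synth, subject, config.seed)
        dataset, _ = generate_dataset(spec)
        for c, problem in problems:
            sub = dataset.subset(problem)
            split = split_dataset(sub.labels, seed=spec.seed + 1)
            for method in config.methods:
                rec, _ = select_and_test(
                    sub, split, method, config.grids, sigma,
                    seed=spec.seed, subject_id=subject,
                    learner_opts=config.learner_opts,
                )
                rec.problem = "+".join(problem)
                records.append(rec)
                extra.append(dict(c=c,
                                  subsample_fraction=config.subsample_fraction))
    tscore_normalize(records)
    df = _records_to_frame(records)
    return pd.concat([df, pd.DataFrame(extra)], axis=1)


@dataclass
class ComparisonResult:
    """One-way ANOVA over methods plus pairwise post-hoc t-tests."""

    group_means: dict
    group_sizes: dict
    anova_f: float
    anova_p: float
    pairwise: pd.DataFrame  # method_a, method_b, t, p_raw, p_bonferroni


def compare_methods(df: pd.DataFrame, value: str = "tscore",
                    group: str = "method") -> ComparisonResult:
    """Compare per-method score distributions.

    One-way ANOVA across the method groups followed by all pairwise
    two-sample t-tests; Bonferroni-adjusted p-values are reported
    alongside the raw ones.
    """
    groups = {m: sub[value].to_numpy(dtype=float)
              for m, sub in df.groupby(group)}
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >= 2 groups with >= 2 records each")
    names = sorted(groups)
    f, p = scipy.stats.f_oneway(*[groups[m] for m in names])
    rows = []
    pairs = list(itertools.combinations(names, 2))
    for a, b in pairs:
        t, pr = scipy.stats.ttest_ind(groups[a], groups[b])
        rows.append(dict(method_a=a, method_b=b, t=float(t), p_raw=float(pr),
                         p_bonferroni=float(min(1.0, pr * len(pairs)))))
    return ComparisonResult(
        group_means={m: float(np.mean(groups[m])) for m in names},
        group_sizes={m: int(len(groups[m])) for m in names},
        anova_f=float(f), anova_p=float(p),
        pairwise=pd.DataFrame(rows),
    )
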