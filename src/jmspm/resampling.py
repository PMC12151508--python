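"""Familial bootstrap: whole-family resampling for cluster-robust uncertainty.

Family cohorts violate the independence assumption of the fitted models.  The
familial bootstrap draws families (not individuals) with replacement until
the original family count is reached, refits the statistic of interest on
each replicate, and summarizes the replicate distribution by its median and
min-max range.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Callable, List

import numpy as np

from .cohort import Cohort, Individual

__all__ = ["BootstrapSummary", "familial_bootstrap", "resample_families"]


@dataclass
class BootstrapSummary:
    statistic: str
    n_reps: int
    values: List[float]
    median: float
    range: tuple
    seed: int
    failures: List[int] = field(default_factory=list)
    valid: bool = True

    def __post_init__(self):
        if self.values:
            assert self.range[0] <= self.median <= self.range[1]


def resample_families(cohort: Cohort, rng: np.random.Generator, tag: str = "b") -> Cohort:
    """Draw families with replacement (same family count); duplicated
    families receive fresh family and subject ids."""
    fams = cohort.family_ids()
    by_fam = {}
    for ind in cohort.individuals:
        by_fam.setdefault(ind.family_id, []).append(ind)
    picks = rng.choice(len(fams), size=len(fams), replace=True)
    new_inds = []
    for k, j in enumerate(picks):
        for ind in by_fam[fams[j]]:
            clone = copy.copy(ind)
            clone.covariates = dict(ind.covariates)
            clone.family_id = f"{tag}F{k:04d}"
            clone.subject_id = f"{tag}F{k:04d}:{ind.subject_id}"
            new_inds.append(clone)
    return Cohort(individuals=new_inds,
                  provenance={"bootstrap_of": cohort.provenance, "tag": tag})


def familial_bootstrap(
    cohort: Cohort,
    fit_fn: Callable[[Cohort], float],
    n_reps: int = 100,
    seed: int = 0,
    statistic: str = "statistic",
) -> BootstrapSummary:
    """Median and range of ``fit_fn`` over family-resampled replicates.

    Replicates on which ``fit_fn`` raises are dropped and recorded; more than
    10% failures invalidates the summary (``valid=False``).  Deterministic
    under ``seed``.
    """
    if len(cohort.family_ids()) < 1:
        raise ValueError("cohort has no families")
    rng = np.random.default_rng(seed)
    values, failures = [], []
    for rep in range(n_reps):
        boot = resample_families(cohort, rng, tag=f"r{rep}")
        try:
            values.append(float(fit_fn(boot)))
        except Exception:
            failures.append(rep)
    if not values:
        raise RuntimeError("all bootstrap replicates failed")
    arr = np.asarray(values)
    return BootstrapSummary(
        statistic=statistic, n_reps=n_reps, values=values,
        median=float(np.median(arr)), range=(float(arr.min()), float(arr.max())),
        seed=seed, failures=failures,
        valid=(len(failures) <= 0.10 * n_reps),
    )
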