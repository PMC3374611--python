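"""Simulation studies on synthetic cohorts: type-I calibration and recovery.

These routines drive the generator + analysis stack end to end on many
replicate cohorts and summarize the operating characteristics that the
package's tests assert:

* with every planted composition effect zeroed, the stepwise entry test
  should fire at its nominal level, and per-term MANCOVA P values should
  be uniform;
* with one strong planted factor -> category effect, stepwise selection
  should enter the planted cluster centroid first, and Ward clustering at
  the true k should recover the planted probe blocks.

Replicate counts and cohort sizes default to values that keep each study
in the tens of seconds on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gene_clustering import cluster_centroids, cluster_genes
from .perm_mancova import DesignVariable, sequential_mancova, stepwise_select
from .synthetic_cohort import generate_cohort, null_config, planted_config
from .taxa_composition import bin_to_categories, clr_transform


def _cohort_clr(cohort):
    comp = bin_to_categories(cohort.taxa_counts, cohort.taxonomy.to_dict())
    return clr_transform(comp)


def _truth_centroids(cohort):
    return cluster_centroids(
        cohort.expression.values, cohort.truth.probe_factor, method="median"
    )


def null_selection_rate(
    n_replicates: int = 200,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
    n_probes: int = 60,
) -> float:
    """Fraction of all-effects-zero cohorts where stepwise enters a variable.

    One candidate (the first latent cluster's centroid, which has no
    planted composition effect) is offered per cohort, so the selection
    rate estimates the entry test's size at ``alpha``.
    """
    hits = 0
    for i in range(n_replicates):
        cohort = generate_cohort(null_config(seed=seed * 100003 + i, n_probes=n_probes))
        clr = _cohort_clr(cohort)
        centroid = _truth_centroids(cohort).loc[0, clr.index]
        trace, _ = stepwise_select(
            clr,
            [DesignVariable("cluster_0", "continuous", centroid)],
            alpha_enter=alpha,
            n_perm=n_perm,
            seed=(seed * 11 + i) % (2 ** 31),
        )
        hits += int(len(trace.entries) > 0)
    return hits / n_replicates


def mancova_rejection_rate(
    n_replicates: int = 200,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
    n_probes: int = 40,
) -> float:
    """Pooled per-term rejection rate of a 3-term MANCOVA on null cohorts.

    Terms: phenotype (2 df), age, gender — none has any planted effect on
    composition, so each term's P should be uniform and the pooled
    rejection rate at ``alpha`` should sit inside its binomial band.
    """
    rejections, total = 0, 0
    for i in range(n_replicates):
        cohort = generate_cohort(null_config(seed=seed * 99991 + i, n_probes=n_probes))
        clr = _cohort_clr(cohort)
        meta = cohort.metadata.loc[clr.index]
        terms = [
            DesignVariable("phenotype", "categorical", meta["phenotype"]),
            DesignVariable("age", "continuous", meta["age"].astype(float)),
            DesignVariable("gender", "categorical", meta["gender"]),
        ]
        res = sequential_mancova(
            clr, terms, n_perm=n_perm, seed=(seed * 13 + i) % (2 ** 31)
        )
        rejections += int((res.table["p"] <= alpha).sum())
        total += len(terms)
    return rejections / total


def recovery_first_entry_rate(
    n_replicates: int = 100,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
    n_probes: int = 200,
) -> float:
    """Fraction of planted cohorts whose stepwise run enters the planted
    centroid first.

    Candidate pool: the ten truth-assignment cluster centroids plus four
    clinical covariates (age, BMI, gender, smoker).  The planted factor's
    centroid explains ~20-30% of the CLR variance under the planted
    configuration.
    """
    first_hits = 0
    for i in range(n_replicates):
        cohort = generate_cohort(
            planted_config(seed=seed * 90007 + i, n_probes=n_probes)
        )
        clr = _cohort_clr(cohort)
        centroids = _truth_centroids(cohort)
        meta = cohort.metadata.loc[clr.index]
        candidates = [
            DesignVariable(f"cluster_{lab}", "continuous", centroids.loc[lab, clr.index])
            for lab in centroids.index
        ]
        candidates += [
            DesignVariable("age", "continuous", meta["age"].astype(float)),
            DesignVariable("bmi", "continuous", meta["bmi"].astype(float)),
            DesignVariable("gender", "categorical", meta["gender"]),
            DesignVariable("smoker", "categorical", meta["smoker"]),
        ]
        trace, _ = stepwise_select(
            clr,
            candidates,
            alpha_enter=alpha,
            n_perm=n_perm,
            seed=(seed * 17 + i) % (2 ** 31),
            max_steps=1,
        )
        if len(trace.entries) and trace.entries["term"].iloc[0] == "cluster_0":
            first_hits += 1
    return first_hits / n_replicates


def ward_recovery_ari(seed: int = 0, noise_sd: float = 0.05, n_probes: int = 200) -> float:
    """Adjusted Rand index of Ward clustering at the true k on a planted cohort."""
    cohort = generate_cohort(planted_config(seed=seed, noise_sd=noise_sd, n_probes=n_probes))
    k = cohort.config.n_latent_clusters
    sol = cluster_genes(cohort.expression.values, k=k)
    return adjusted_rand_index(
        cohort.truth.probe_factor.to_numpy(), sol.assignment.to_numpy()
    )


def adjusted_rand_index(a: np.ndarray, b: np.ndarray) -> float:
    """Adjusted Rand index between two label vectors (contingency form)."""
    a = np.asarray(a)
    b = np.asarray(b)
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    ct = np.zeros((ua.size, ub.size), dtype=np.int64)
    np.add.at(ct, (ia, ib), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(ct).sum()
    sum_a = comb2(ct.sum(axis=1)).sum()
    sum_b = comb2(ct.sum(axis=0)).sum()
    n = comb2(a.size)
    expected = sum_a * sum_b / n
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))
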