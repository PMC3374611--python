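"""Synthetic paired expression / microbiome / metadata cohorts.

Generates cohorts that mimic the study design every downstream stage is
exercised on: three phenotype groups (ileal Crohn's disease, ulcerative
colitis, non-IBD control; 34/27/23 subjects by default), a probe x sample
log2-ratio expression matrix with block (latent-factor) structure, a
genus x sample 16S count table whose seven-category composition is driven
by phenotype effects and by the same latent factors that drive gene
clusters (the planted host-microbe association), and a clinical/genotype
metadata table drawn from the published cohort's marginal frequencies.

The generator records its ground truth (factor scores, probe-to-factor
assignment, effect matrix) so parameter-recovery and type-I-error
calibration tests need no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .expression_qc import ExpressionMatrix
from .taxa_composition import CATEGORIES

PHENOTYPES = ("CD", "UC", "Control")

#: Default genus panel: five per category, recognizable ileal taxa.
DEFAULT_GENERA = {
    "Actinobacteria": ["Bifidobacterium", "Collinsella", "Actinomyces", "Rothia", "Corynebacterium"],
    "Bacteroidetes": ["Bacteroides", "Parabacteroides", "Prevotella", "Alistipes", "Odoribacter"],
    "Firmicutes.ClostridiumIV": ["Faecalibacterium", "Ruminococcus", "Oscillibacter", "Subdoligranulum", "Anaerofilum"],
    "Firmicutes.ClostridiumXIVa": ["Roseburia", "Blautia", "Coprococcus", "Dorea", "Lachnospira"],
    "Firmicutes.Bacilli": ["Lactobacillus", "Streptococcus", "Enterococcus", "Granulicatella", "Gemella"],
    "Proteobacteria": ["Escherichia/Shigella", "Klebsiella", "Sutterella", "Haemophilus", "Bilophila"],
    "Other": ["Fusobacterium", "Akkermansia", "Veillonella", "Victivallis", "TM7_genus"],
}

#: Marginal covariate frequencies by phenotype (CD, UC, Control),
#: matching the published cohort characteristics.
COVARIATE_FREQUENCIES = {
    "nod2_risk": (0.35, 0.19, 0.13),
    "atg16l1": {  # levels R/R, R/NR, NR/NR
        "CD": (0.41, 0.56, 0.03),
        "UC": (0.41, 0.41, 0.18),
        "Control": (0.43, 0.35, 0.22),
    },
    "male": (0.38, 0.59, 0.30),
    "caucasian": (0.94, 0.96, 0.96),
    "smoker": (0.38, 0.11, 0.22),
    "cdiff_pos": (0.0, 0.30, 0.0),
    "asa5": (0.52, 0.70, 0.0),
    "steroids": (0.55, 0.74, 0.0),
    "immunomod": (0.50, 0.52, 0.0),
    "anti_tnf": {  # levels current, past, never
        "CD": (0.35, 0.09, 0.56),
        "UC": (0.41, 0.07, 0.52),
        "Control": (0.0, 0.0, 1.0),
    },
    # median (range) per phenotype for the two numeric covariates
    "age": {"CD": (36, 21, 59), "UC": (43, 17, 64), "Control": (55, 32, 84)},
    "bmi": {"CD": (25, 16, 38), "UC": (24, 18, 43), "Control": (28, 20, 38)},
}


class ConfigurationError(ValueError):
    """Impossible cohort configuration."""


def _default_effect_matrix(n_factors: int) -> np.ndarray:
    """One planted association: factor 0 raises Proteobacteria log-abundance."""
    m = np.zeros((n_factors, len(CATEGORIES)))
    m[0, CATEGORIES.index("Proteobacteria")] = 1.0
    return m


def _default_phenotype_effects() -> np.ndarray:
    """Ileal-CD-like dysbiosis: Clostridia down, Proteobacteria up in CD."""
    eff = np.zeros((3, len(CATEGORIES)))
    eff[0, CATEGORIES.index("Firmicutes.ClostridiumIV")] = -0.8
    eff[0, CATEGORIES.index("Proteobacteria")] = 0.7
    eff[1, CATEGORIES.index("Firmicutes.ClostridiumXIVa")] = -0.3
    eff[1, CATEGORIES.index("Proteobacteria")] = 0.3
    return eff


@dataclass
class CohortConfig:
    """Knobs of the synthetic cohort; defaults emulate the study design."""

    n_per_phenotype: tuple[int, int, int] = (34, 27, 23)
    n_probes: int = 400
    n_latent_clusters: int = 10
    probes_per_cluster: Optional[Sequence[int]] = None  # default: near-uniform
    noise_sd: float = 0.1
    n_genera: int = 35
    sequencing_depth: int = 5000
    effect_matrix: Optional[np.ndarray] = None  # factors x 7 categories
    phenotype_effects: Optional[np.ndarray] = None  # 3 x 7 categories
    concentration: float = 50.0
    baseline_composition: tuple = (0.05, 0.25, 0.20, 0.25, 0.05, 0.15, 0.05)
    age_shift: bool = True  # phenotype-dependent age (as in the cohort table)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_per_phenotype):
            raise ConfigurationError("phenotype group sizes must be positive")
        if self.n_probes <= 0 or self.n_latent_clusters <= 0:
            raise ConfigurationError("counts must be positive")
        if self.n_latent_clusters > self.n_probes:
            raise ConfigurationError("more latent clusters than probes")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if self.concentration <= 0:
            raise ConfigurationError("concentration must be positive")
        if self.n_genera < len(CATEGORIES):
            raise ConfigurationError("need at least one genus per category")
        if self.effect_matrix is None:
            self.effect_matrix = _default_effect_matrix(self.n_latent_clusters)
        self.effect_matrix = np.asarray(self.effect_matrix, dtype=float)
        if self.effect_matrix.shape != (self.n_latent_clusters, len(CATEGORIES)):
            raise ConfigurationError(
                "effect_matrix must be n_latent_clusters x 7 "
                f"(got {self.effect_matrix.shape})"
            )
        if self.phenotype_effects is None:
            self.phenotype_effects = _default_phenotype_effects()
        self.phenotype_effects = np.asarray(self.phenotype_effects, dtype=float)
        if self.phenotype_effects.shape != (3, len(CATEGORIES)):
            raise ConfigurationError("phenotype_effects must be 3 x 7")
        if abs(sum(self.baseline_composition) - 1.0) > 1e-9:
            raise ConfigurationError("baseline composition must sum to 1")


@dataclass
class CohortTruth:
    """Ground truth recorded by the generator."""

    factor_scores: pd.DataFrame  # samples x factors
    probe_factor: pd.Series  # probe -> factor index
    effect_matrix: pd.DataFrame  # factors x categories
    category_probs: pd.DataFrame  # samples x 7 expected composition


@dataclass
class SyntheticCohort:
    """A paired synthetic dataset plus its ground truth."""

    expression: ExpressionMatrix
    taxa_counts: pd.DataFrame  # genera x samples
    taxonomy: pd.Series  # genus -> category
    metadata: pd.DataFrame  # samples x covariates
    truth: CohortTruth
    config: CohortConfig

    @property
    def sample_ids(self) -> list:
        return list(self.metadata.index)


def _sample_metadata(rng: np.random.Generator, config: CohortConfig) -> pd.DataFrame:
    rows = []
    sid = 0
    for p_idx, (phen, n) in enumerate(zip(PHENOTYPES, config.n_per_phenotype)):
        for _ in range(n):
            sid += 1
            f = COVARIATE_FREQUENCIES
            atg = rng.choice(["R/R", "R/NR", "NR/NR"], p=_close(f["atg16l1"][phen]))
            tnf = rng.choice(["current", "past", "never"], p=_close(f["anti_tnf"][phen]))
            med, lo, hi = f["age"][phen] if config.age_shift else f["age"]["UC"]
            age = float(np.clip(rng.normal(med, (hi - lo) / 5.0), lo, hi))
            bmed, blo, bhi = f["bmi"][phen]
            bmi = float(np.clip(rng.normal(bmed, (bhi - blo) / 5.0), blo, bhi))
            rows.append(
                {
                    "sample_id": f"S{sid:03d}",
                    "phenotype": phen,
                    "nod2": "R" if rng.random() < f["nod2_risk"][p_idx] else "NR",
                    "atg16l1": atg,
                    "age": round(age, 1),
                    "gender": "male" if rng.random() < f["male"][p_idx] else "female",
                    "race": "Caucasian" if rng.random() < f["caucasian"][p_idx] else "Other",
                    "smoker": "yes" if rng.random() < f["smoker"][p_idx] else "no",
                    "bmi": round(bmi, 1),
                    "cdiff": "pos" if rng.random() < f["cdiff_pos"][p_idx] else "neg",
                    "asa5": "yes" if rng.random() < f["asa5"][p_idx] else "no",
                    "steroids": "yes" if rng.random() < f["steroids"][p_idx] else "no",
                    "immunomod": "yes" if rng.random() < f["immunomod"][p_idx] else "no",
                    "anti_tnf": tnf,
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def _close(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    return p / p.sum()


def _genus_panel(config: CohortConfig) -> tuple[list[str], pd.Series]:
    """Genus names and genus->category map, n_genera split over 7 categories."""
    per_cat = np.full(len(CATEGORIES), config.n_genera // len(CATEGORIES))
    per_cat[: config.n_genera % len(CATEGORIES)] += 1
    genera, mapping = [], {}
    for cat, n in zip(CATEGORIES, per_cat):
        pool = DEFAULT_GENERA[cat]
        for i in range(n):
            name = pool[i] if i < len(pool) else f"{cat.split('.')[-1]}_genus{i + 1}"
            genera.append(name)
            mapping[name] = cat
    return genera, pd.Series(mapping, name="category")


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw one reproducible cohort from the configured generative model.

    Expression: probe value = intercept + loading * factor_score + noise,
    each probe loading on exactly one latent factor.  Composition: per
    sample, category log-abundance = log(baseline) + phenotype effect +
    effect_matrix' . factor_scores, softmaxed to probabilities, split
    uniformly across the category's genera, and realized as
    Dirichlet-multinomial counts at the configured depth/concentration.
    """
    rng = np.random.default_rng(config.seed)
    metadata = _sample_metadata(rng, config)
    n = len(metadata)
    k = config.n_latent_clusters

    # latent factor scores
    z = rng.standard_normal((n, k))
    factor_scores = pd.DataFrame(
        z, index=metadata.index, columns=[f"factor_{i}" for i in range(k)]
    )

    # probe block structure
    if config.probes_per_cluster is None:
        sizes = np.full(k, config.n_probes // k)
        sizes[: config.n_probes % k] += 1
    else:
        sizes = np.asarray(config.probes_per_cluster, dtype=int)
        if sizes.sum() != config.n_probes or len(sizes) != k:
            raise ConfigurationError(
                "probes_per_cluster must have n_latent_clusters entries summing "
                "to n_probes"
            )
    probe_factor = np.repeat(np.arange(k), sizes)
    probe_ids = [f"probe_{i:04d}" for i in range(config.n_probes)]
    loadings = rng.uniform(0.6, 1.4, size=config.n_probes)
    intercepts = rng.normal(0.0, 0.3, size=config.n_probes)
    noise = rng.normal(0.0, config.noise_sd, size=(config.n_probes, n))
    values = intercepts[:, None] + loadings[:, None] * z[:, probe_factor].T + noise
    expression = ExpressionMatrix(
        values=pd.DataFrame(values, index=probe_ids, columns=metadata.index),
        flags=pd.DataFrame(
            np.zeros((config.n_probes, n), dtype=int),
            index=probe_ids,
            columns=metadata.index,
        ),
    )

    # composition
    phen_idx = metadata["phenotype"].map({p: i for i, p in enumerate(PHENOTYPES)})
    logits = (
        np.log(np.asarray(config.baseline_composition))
        + config.phenotype_effects[phen_idx.to_numpy()]
        + z @ config.effect_matrix
    )
    probs = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    category_probs = pd.DataFrame(probs, index=metadata.index, columns=list(CATEGORIES))

    genera, taxonomy = _genus_panel(config)
    cat_of = taxonomy.to_numpy()
    genus_share = np.array(
        [1.0 / (cat_of == c).sum() for c in cat_of]
    )
    cat_col = np.array([list(CATEGORIES).index(c) for c in cat_of])
    genus_probs = probs[:, cat_col] * genus_share  # samples x genera

    counts = np.zeros((len(genera), n), dtype=int)
    for j in range(n):
        alpha = config.concentration * genus_probs[j]
        theta = rng.dirichlet(np.clip(alpha, 1e-8, None))
        counts[:, j] = rng.multinomial(config.sequencing_depth, theta)
    taxa_counts = pd.DataFrame(counts, index=genera, columns=metadata.index)

    truth = CohortTruth(
        factor_scores=factor_scores,
        probe_factor=pd.Series(probe_factor, index=probe_ids, name="factor"),
        effect_matrix=pd.DataFrame(
            config.effect_matrix,
            index=[f"factor_{i}" for i in range(k)],
            columns=list(CATEGORIES),
        ),
        category_probs=category_probs,
    )
    return SyntheticCohort(
        expression=expression,
        taxa_counts=taxa_counts,
        taxonomy=taxonomy,
        metadata=metadata,
        truth=truth,
        config=config,
    )


def planted_config(seed: int, effect: float = 0.7, **overrides) -> CohortConfig:
    """Config with a single strong factor->Proteobacteria association.

    The default effect size makes the planted factor's centroid explain
    roughly 20-30% of the CLR response variance at the default noise and
    depth (comfortably past the 15% recovery-regime floor); phenotype
    effects are off so the planted factor is the only composition signal.
    """
    k = overrides.pop("n_latent_clusters", 10)
    m = np.zeros((k, len(CATEGORIES)))
    m[0, CATEGORIES.index("Proteobacteria")] = effect
    defaults = dict(
        n_latent_clusters=k,
        effect_matrix=m,
        phenotype_effects=np.zeros((3, len(CATEGORIES))),
        seed=seed,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


def null_config(seed: int, **overrides) -> CohortConfig:
    """Config with every composition effect zeroed (type-I calibration)."""
    k = overrides.pop("n_latent_clusters", 10)
    defaults = dict(
        n_latent_clusters=k,
        effect_matrix=np.zeros((k, len(CATEGORIES))),
        phenotype_effects=np.zeros((3, len(CATEGORIES))),
        seed=seed,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


def write_cohort(cohort: SyntheticCohort, directory) -> dict[str, Path]:
    """Write the three analysis inputs plus truth files as tab-separated text.

    Round-trips losslessly through the package's readers.  Refuses to
    write an empty (0-sample) cohort.
    """
    if len(cohort.sample_ids) == 0:
        raise ValueError("cannot write an empty cohort")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _w(name: str, df: pd.DataFrame, index_label: str):
        p = directory / name
        df.to_csv(p, sep="\t", index_label=index_label)
        paths[name] = p

    _w("expression.tsv", cohort.expression.values, "probe_id")
    if cohort.expression.flags is not None:
        _w("expression_flags.tsv", cohort.expression.flags, "probe_id")
    _w("taxa_counts.tsv", cohort.taxa_counts, "genus")
    _w("taxonomy.tsv", cohort.taxonomy.to_frame(), "genus")
    _w("metadata.tsv", cohort.metadata, "sample_id")
    _w("truth_factor_scores.tsv", cohort.truth.factor_scores, "sample_id")
    _w("truth_probe_factor.tsv", cohort.truth.probe_factor.to_frame(), "probe_id")
    _w("truth_effect_matrix.tsv", cohort.truth.effect_matrix, "factor")
    return paths
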