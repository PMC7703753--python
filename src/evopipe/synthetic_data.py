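"""Synthetic cohort generator with known ground truth.

Emulates the shape of a clinical NMR-metabolomics case/control table: ~925
samples, 73 block-correlated continuous "metabolic" measures (half of them
exponentiated to a positive, right-skewed scale), 27 mixed binary/continuous
"clinical" features, a 3-level latent disease severity (none /
non-obstructive / obstructive) binarised two ways (P1: any disease vs none;
P2: obstructive vs rest), class imbalance and MCAR missingness on the
metabolic block.  Informative features carry a severity-proportional mean
shift (metabolic) or a severity-dependent Bernoulli rate (clinical); an
optional XOR pair adds a purely non-linear signal that linear models cannot
express.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .data_model import FeatureTable, LabeledDataset


@dataclass
class SyntheticConfig:
    """Generator settings; defaults emulate the study cohort's shape."""

    n_samples: int = 925
    n_metabolic: int = 73
    n_clinical: int = 27
    class_proportions: tuple = (0.20, 0.20, 0.60)  # (none, non-obstructive, obstructive)
    n_informative_metabolic: int = 10
    n_informative_clinical: int = 5
    effect_size: float = 1.0
    correlation_block_size: int = 5
    xor_pair: bool = False
    xor_logit_weight: float = 8.0
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        props = tuple(float(p) for p in self.class_proportions)
        if len(props) != 3 or any(p <= 0 for p in props):
            raise ValueError("class_proportions must be 3 positive values")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        if self.n_informative_metabolic > self.n_metabolic:
            raise ValueError("n_informative_metabolic exceeds n_metabolic")
        if self.n_informative_clinical > self.n_clinical:
            raise ValueError("n_informative_clinical exceeds n_clinical")
        self.class_proportions = props


@dataclass
class SyntheticGroundTruth:
    """Planted structure of a generated dataset."""

    latent_class: np.ndarray  # per-sample severity in {0, 1, 2}
    informative_indices: list  # global column indices (metabolic block first)
    effect_sizes: dict  # index -> effect size
    xor_pair_indices: tuple | None = None
    feature_names: list = field(default_factory=list)


def _exact_class_counts(proportions, n):
    """Largest-remainder apportionment: counts match round(p*n) within 1."""
    raw = np.asarray(proportions) * n
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    for _ in range(n - counts.sum()):
        i = int(np.argmax(remainder))
        counts[i] += 1
        remainder[i] = -1
    return counts


def generate(config: SyntheticConfig):
    """Generate ``(dataset_P1, dataset_P2, truth)``.

    P1 labels = (severity >= 1); P2 labels = (severity == 2).  Both datasets
    share the same feature matrix.  Fully deterministic in ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples

    # --- latent severity ---------------------------------------------------
    if config.xor_pair:
        x1 = (rng.random(n) < 0.5).astype(float)
        x2 = (rng.random(n) < 0.5).astype(float)
        xor = np.logical_xor(x1, x2).astype(float)
        delta = config.xor_logit_weight * (xor - 0.5)
        p0, p1, p2 = config.class_proportions
        q_ge1 = expit(logit(p1 + p2) + delta)
        q_eq2 = expit(logit(p2) + delta)
        u = rng.random(n)
        severity = np.where(u < q_eq2, 2, np.where(u < q_ge1, 1, 0))
    else:
        x1 = x2 = None
        counts = _exact_class_counts(config.class_proportions, n)
        severity = np.repeat([0, 1, 2], counts)
        severity = severity[rng.permutation(n)]

    # --- metabolic block: correlated Gaussians, severity mean shifts -------
    b = max(1, config.correlation_block_size)
    rho = 0.6
    Z = np.empty((n, config.n_metabolic))
    for start in range(0, config.n_metabolic, b):
        width = min(b, config.n_metabolic - start)
        factor = rng.standard_normal(n)[:, None]
        noise = rng.standard_normal((n, width))
        Z[:, start : start + width] = np.sqrt(rho) * factor + np.sqrt(1 - rho) * noise

    informative_met = sorted(
        rng.choice(config.n_metabolic, size=config.n_informative_metabolic, replace=False)
    )
    effects = {}
    for j in informative_met:
        Z[:, j] += config.effect_size * severity
        effects[int(j)] = config.effect_size
    # Half the metabolic columns on a positive, right-skewed scale.
    skewed = np.arange(config.n_metabolic) % 2 == 1
    Z[:, skewed] = np.exp(0.5 * Z[:, skewed])

    # --- clinical block ----------------------------------------------------
    C = np.empty((n, config.n_clinical))
    clin_kinds = []
    informative_clin = []
    j = 0
    if config.xor_pair:
        C[:, 0], C[:, 1] = x1, x2
        clin_kinds += ["binary", "binary"]
        j = 2
    n_inf_clin = min(config.n_informative_clinical, config.n_clinical - j)
    for _ in range(n_inf_clin):
        base = rng.uniform(0.25, 0.6)
        rate = expit(logit(base) + config.effect_size * (severity - 1))
        C[:, j] = (rng.random(n) < rate).astype(float)
        clin_kinds.append("binary")
        informative_clin.append(j)
        effects[config.n_metabolic + j] = config.effect_size
        j += 1
    while j < config.n_clinical:
        if (j - n_inf_clin) % 3 == 2:
            C[:, j] = rng.standard_normal(n)
            clin_kinds.append("continuous")
        else:
            C[:, j] = (rng.random(n) < rng.uniform(0.1, 0.9)).astype(float)
            clin_kinds.append("binary")
        j += 1

    # --- assemble ----------------------------------------------------------
    values = np.hstack([Z, C])
    names = [f"met_{i:03d}" for i in range(config.n_metabolic)] + [
        f"clin_{i:03d}" for i in range(config.n_clinical)
    ]
    kinds = ["continuous"] * config.n_metabolic + clin_kinds

    if config.missing_rate > 0:
        mask = rng.random((n, config.n_metabolic)) < config.missing_rate
        values[:, : config.n_metabolic][mask] = np.nan

    table = FeatureTable(
        values=values,
        feature_names=names,
        feature_kinds=kinds,
        sample_ids=[f"s{i:05d}" for i in range(n)],
    )
    labels_p1 = (severity >= 1).astype(int)
    labels_p2 = (severity == 2).astype(int)
    truth = SyntheticGroundTruth(
        latent_class=severity,
        informative_indices=sorted(
            [int(i) for i in informative_met]
            + [config.n_metabolic + i for i in informative_clin]
        ),
        effect_sizes=effects,
        xor_pair_indices=(config.n_metabolic, config.n_metabolic + 1)
        if config.xor_pair
        else None,
        feature_names=names,
    )
    ds_p1 = LabeledDataset(table.copy(), labels_p1, "P1")
    ds_p2 = LabeledDataset(table.copy(), labels_p2, "P2")
    return ds_p1, ds_p2, truth


def make_xor_dataset(
    n_samples: int = 400, n_noise: int = 8, seed: int = 0
) -> LabeledDataset:
    """Two fair binary features, label = XOR, plus Gaussian noise features.

    Logistic regression cannot express this target; tree classifiers and
    feature constructors can, which is the mechanism motivating pipeline
    search over bare linear baselines.
    """
    rng = np.random.default_rng(seed)
    x1 = (rng.random(n_samples) < 0.5).astype(float)
    x2 = (rng.random(n_samples) < 0.5).astype(float)
    label = np.logical_xor(x1, x2).astype(int)
    noise = rng.standard_normal((n_samples, n_noise))
    values = np.column_stack([x1, x2, noise])
    table = FeatureTable(
        values=values,
        feature_names=["xor_a", "xor_b"] + [f"noise_{i}" for i in range(n_noise)],
        feature_kinds=["binary", "binary"] + ["continuous"] * n_noise,
        sample_ids=[f"s{i:05d}" for i in range(n_samples)],
    )
    return LabeledDataset(table, label, "xor")


def planted_recovery_check(
    truth: SyntheticGroundTruth, pfi, top_k: int
) -> float:
    """Fraction of planted informative features recovered in the PFI top-k.

    Returns ``|top_k PFI features ∩ informative| / min(top_k, n_informative)``.
    """
    ranking = pfi.ranking()[:top_k]
    top_names = {name for name, _ in ranking}
    informative_names = {truth.feature_names[i] for i in truth.informative_indices}
    denom = min(top_k, len(informative_names))
    if denom == 0:
        return 0.0
    return len(top_names & informative_names) / denom
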