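"""Synthetic paired-omics generator with known ground truth.

The simulator emulates the statistical structure the imputation model
assumes: two non-negative modalities measured on the same samples, driven by
a shared latent cluster structure, with a subset of samples missing the
target modality entirely.  Samples are assigned to ``c_true`` latent
clusters; both modalities are (noisy, optionally non-linearly warped) images
of the same soft membership matrix times modality-specific centroid
matrices, so the cluster representation of any reasonable subset of samples
is consistent — the premise behind the centroid-consistency loss.  Binary
phenotype labels are a deterministic function of the latent cluster, and
survival times are exponential with a log-hazard proportional to a latent
cluster risk, so downstream classification and survival analyses have known
signal to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .evaluation import PhenotypeLabels, SurvivalData
from .io import OmicsMatrix, PairedOmicsDataset, align_samples
from .training import CompletedMatrix

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "simulate_paired_omics",
    "ground_truth_mse",
    "default_spec",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one simulated paired-omics world."""

    n: int = 400
    p: int = 60
    q: int = 40
    c_true: int = 4
    missing_fraction: float = 0.25
    map_kind: str = "linear"  # or "mlp_nonlinear"
    noise_sd: float = 0.05
    label_rule: Callable[[np.ndarray], np.ndarray] | None = None  # clusters -> {0,1}
    hazard_coef: float = 1.0
    censor_rate: float = 0.2
    seed: int = 0
    membership_jitter: float = 0.15
    centroid_scale: float = 2.0

    def __post_init__(self) -> None:
        if not self.n >= self.c_true >= 1:
            raise ValueError("need n >= c_true >= 1")
        if not 0.0 < self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must lie in (0, 1)")
        if self.noise_sd < 0 or not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("noise_sd >= 0 and censor_rate in [0, 1) required")
        if self.map_kind not in ("linear", "mlp_nonlinear"):
            raise ValueError("map_kind must be 'linear' or 'mlp_nonlinear'")


def default_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """The default benchmark world used throughout the test suite."""
    return SyntheticSpec(seed=seed, **overrides)


@dataclass
class GroundTruth:
    """Everything the simulator knows that the trainer must not see."""

    target_withheld: OmicsMatrix  # true target rows of the missing samples
    labels: PhenotypeLabels
    survival: SurvivalData
    clusters: np.ndarray  # latent cluster per sample (source order)
    memberships: np.ndarray  # V_true (n x c_true)
    target_centroids: np.ndarray  # U_y (c_true x q)
    risk: np.ndarray  # latent risk per sample

    def truth_rows(self, ids: list[str]) -> np.ndarray:
        return self.target_withheld.subset_samples(ids).values


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _draw_centroids(
    rng: np.random.Generator, c: int, dim: int, scale: float, min_sep: float
) -> np.ndarray:
    """Non-negative centroid rows with pairwise distance >= min_sep."""
    for _ in range(50):
        U = rng.uniform(0.0, scale, size=(c, dim))
        if c == 1:
            return U
        d = np.linalg.norm(U[:, None, :] - U[None, :, :], axis=2)
        if d[np.triu_indices(c, 1)].min() >= min_sep:
            return U
    raise ValueError(
        "could not draw centroids with the required separation; lower noise_sd"
    )


def simulate_paired_omics(spec: SyntheticSpec) -> tuple[PairedOmicsDataset, GroundTruth]:
    """Draw one paired dataset plus its ground truth; reproducible per seed."""
    rng = np.random.default_rng(spec.seed)
    n, p, q, c = spec.n, spec.p, spec.q, spec.c_true

    z = rng.integers(0, c, size=n)
    one_hot = np.eye(c)[z]
    jitter = rng.dirichlet(np.ones(c), size=n)
    V = (1.0 - spec.membership_jitter) * one_hot + spec.membership_jitter * jitter

    min_sep = 4.0 * spec.noise_sd
    U_x = _draw_centroids(rng, c, p, spec.centroid_scale, min_sep)
    U_y = _draw_centroids(rng, c, q, spec.centroid_scale, min_sep)

    X = np.maximum(V @ U_x + rng.normal(0.0, spec.noise_sd, size=(n, p)), 0.0)

    Z = V @ U_y
    if spec.map_kind == "linear":
        Y_clean = Z
    else:
        # fixed seeded 1-hidden-layer positive map: smooth and non-negative
        h_dim = max(q, 16)
        W1 = rng.normal(0.0, 1.0, size=(q, h_dim)) / np.sqrt(q)
        W2 = rng.normal(0.0, 1.0, size=(h_dim, q)) / np.sqrt(h_dim)
        Y_clean = _softplus(_softplus(Z @ W1) @ W2)
    Y_full = np.maximum(Y_clean + rng.normal(0.0, spec.noise_sd, size=(n, q)), 0.0)

    sample_ids = [f"S{i:04d}" for i in range(n)]
    feat_x = [f"src_{j}" for j in range(p)]
    feat_y = [f"tgt_{j}" for j in range(q)]
    source = OmicsMatrix(sample_ids, feat_x, X)

    k = int(np.floor(spec.missing_fraction * n + 0.5))
    missing_rows = np.sort(rng.choice(n, size=k, replace=False))
    missing_set = set(missing_rows.tolist())
    observed_rows = [i for i in range(n) if i not in missing_set]
    target = OmicsMatrix(
        [sample_ids[i] for i in observed_rows], feat_y, Y_full[observed_rows]
    )
    withheld = OmicsMatrix(
        [sample_ids[i] for i in missing_rows], feat_y, Y_full[missing_rows]
    )
    ds = align_samples(source, target)

    label_rule = spec.label_rule or (lambda zz: (zz % 2 == 1).astype(int))
    labels = PhenotypeLabels(sample_ids, label_rule(z))

    risk = z / max(c - 1, 1) - 0.5  # latent risk increases with cluster index
    rate = np.exp(spec.hazard_coef * risk)
    times = rng.exponential(1.0 / rate)
    censored = rng.uniform(size=n) < spec.censor_rate
    obs_times = np.where(censored, times * rng.uniform(size=n), times)
    survival = SurvivalData(sample_ids, obs_times, (~censored).astype(int))

    gt = GroundTruth(
        target_withheld=withheld,
        labels=labels,
        survival=survival,
        clusters=z,
        memberships=V,
        target_centroids=U_y,
        risk=risk,
    )
    return ds, gt


def ground_truth_mse(completed: CompletedMatrix, gt: GroundTruth) -> float:
    """MSE of the imputed rows against the withheld ground truth."""
    imputed = completed.imputed_ids
    covered = set(gt.target_withheld.sample_ids)
    gap = [s for s in imputed if s not in covered]
    if gap:
        raise ValueError(f"ground truth does not cover imputed samples: {gap[:5]}")
    if not imputed:
        return 0.0
    pred = completed.rows(imputed)
    truth = gt.truth_rows(imputed)
    return float(np.mean((pred - truth) ** 2))
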