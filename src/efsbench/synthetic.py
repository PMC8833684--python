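"""Seeded synthetic radiomic feature tables with controlled correlation.

Real radiomic panels are dominated by blocks of near-duplicate features
(|r| > 0.95, e.g. volume vs. surface area vs. diameters) plus a few
strongly anti-correlated pairs (r < -0.95), and only a small subset of
features carries label signal. The generator reproduces exactly these
pathologies: features are drawn from a zero-mean multivariate normal
whose correlation matrix contains configurable equicorrelated blocks and
anti-correlated pairs; labels come from a logistic model on a planted
informative subset, rank-thresholded so class counts hit the configured
prevalences exactly.

The default study shape mirrors the cohort the benchmark emulates:
252 lesions x 120 features with class counts 182 pathologic / 52
pathologic-with-ECS (a nested subset) / 70 non-pathologic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .catalog_io import FeatureTable, LabelSet, feature_catalog

__all__ = [
    "SyntheticConfig",
    "ConfigurationError",
    "simulate_dataset",
    "paper_shape_config",
    "planted_config",
]

#: maximum admissible shift of any configured correlation entry after
#: positive semi-definite repair
PSD_REPAIR_TOLERANCE = 0.02


class ConfigurationError(ValueError):
    """The requested correlation structure or prevalence is infeasible."""


@dataclass
class SyntheticConfig:
    n_samples: int = 252
    n_features: int = 120
    #: (block size, within-block correlation) pairs
    blocks: list[tuple[int, float]] = field(default_factory=list)
    #: one negative correlation per injected anti-correlated pair
    anti_pairs: list[float] = field(default_factory=list)
    n_informative: int = 0
    #: standardized mean shift per informative feature
    effect_size: float = 0.0
    prevalence: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        assigned = sum(s for s, _ in self.blocks) + 2 * len(self.anti_pairs)
        if assigned > self.n_features:
            raise ConfigurationError(
                "blocks and anti-pairs exceed the feature count"
            )
        for size, rho in self.blocks:
            if size < 2 or not abs(rho) < 1:
                raise ConfigurationError(f"invalid block ({size}, {rho})")
        for rho in self.anti_pairs:
            if not (-1 < rho < 0):
                raise ConfigurationError(f"anti-pair correlation {rho} not in (-1, 0)")
        if self.n_informative > self.n_features:
            raise ConfigurationError("n_informative exceeds n_features")
        for task, frac in self.prevalence.items():
            if not 0 < frac < 1:
                raise ConfigurationError(f"prevalence for {task!r} not in (0,1)")


def paper_shape_config(seed: int = 0) -> SyntheticConfig:
    """Study-shaped configuration: 252 x 120 with nested class structure.

    Two tight correlation blocks (emulating the shape/size cluster and a
    texture-redundancy cluster), two anti-correlated pairs at -0.97, ten
    informative features with a moderate per-feature effect.
    """
    return SyntheticConfig(
        n_samples=252,
        n_features=120,
        blocks=[(6, 0.97), (4, 0.96)],
        anti_pairs=[-0.97, -0.97],
        n_informative=10,
        effect_size=2.0,
        prevalence={
            "pathologic": 182 / 252,
            "pathologic_with_ECS": 52 / 252,
            "non_pathologic": 70 / 252,
        },
        seed=seed,
    )


def planted_config(
    n_features: int,
    n_informative: int,
    effect_size: float = 3.0,
    n_samples: int = 252,
    seed: int = 0,
) -> SyntheticConfig:
    """Independent features with a planted informative subset (one task)."""
    return SyntheticConfig(
        n_samples=n_samples,
        n_features=n_features,
        n_informative=n_informative,
        effect_size=effect_size,
        prevalence={"pathologic": 0.5},
        seed=seed,
    )


def _target_correlation(config: SyntheticConfig) -> tuple[np.ndarray, list[tuple[int, int, float]]]:
    d = config.n_features
    C = np.eye(d)
    targets: list[tuple[int, int, float]] = []
    pos = 0
    for size, rho in config.blocks:
        for i in range(pos, pos + size):
            for j in range(i + 1, pos + size):
                C[i, j] = C[j, i] = rho
                targets.append((i, j, rho))
        pos += size
    for rho in config.anti_pairs:
        i, j = pos, pos + 1
        C[i, j] = C[j, i] = rho
        targets.append((i, j, rho))
        pos += 2
    return C, targets


def _psd_repair(C: np.ndarray, targets) -> np.ndarray:
    """Clip negative eigenvalues and re-normalize the diagonal to 1."""
    w, V = np.linalg.eigh(C)
    if w.min() >= 1e-10:
        return C
    w = np.clip(w, 1e-8, None)
    R = (V * w) @ V.T
    dinv = 1.0 / np.sqrt(np.diag(R))
    R = R * dinv[:, None] * dinv[None, :]
    shift = max(abs(R[i, j] - rho) for i, j, rho in targets) if targets else 0.0
    if shift > PSD_REPAIR_TOLERANCE:
        raise ConfigurationError(
            f"correlation structure infeasible: PSD repair moved a target "
            f"entry by {shift:.3f} (> {PSD_REPAIR_TOLERANCE})"
        )
    return R


def _informative_indices(config: SyntheticConfig) -> np.ndarray:
    # plant signal in the trailing (independent) features so block
    # membership and informativeness stay orthogonal concerns
    d, k = config.n_features, config.n_informative
    return np.arange(d - k, d)


def _threshold_labels(score: np.ndarray, n_pos: int) -> np.ndarray:
    y = np.zeros(len(score), dtype=int)
    y[np.argsort(score)[::-1][:n_pos]] = 1
    return y


def simulate_dataset(config: SyntheticConfig) -> tuple[FeatureTable, LabelSet]:
    """Draw one seeded dataset; identical config+seed gives identical output.

    Labels per task use a logistic model on the informative features:
    latent score = effect_size / sqrt(k) * sum of informative columns plus
    standard logistic noise, rank-thresholded at the configured prevalence
    so class counts are exact. ECS scores are ranked within the pathologic
    subset only, which makes ECS a strict subset of pathologic by
    construction; non_pathologic is the complement of pathologic and its
    configured prevalence must agree with 1 - prevalence(pathologic).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, d = config.n_samples, config.n_features

    C, targets = _target_correlation(config)
    C = _psd_repair(C, targets)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(d))
    X = rng.standard_normal((n, d)) @ L.T

    if d == 120:
        names = [e.name for e in feature_catalog()]
    else:
        names = [f"F{j}" for j in range(d)]
    ids = [f"LN_{i:03d}" for i in range(n)]
    table = FeatureTable(ids, names, X)

    info = _informative_indices(config)
    k = max(len(info), 1)
    labels: dict[str, np.ndarray] = {}

    def n_pos(task: str) -> int:
        npos = round(config.prevalence[task] * n)
        if npos <= 0 or npos >= n:
            raise ConfigurationError(f"prevalence for {task!r} is degenerate")
        return npos

    if "pathologic" in config.prevalence:
        score = (
            config.effect_size / np.sqrt(k) * X[:, info].sum(axis=1)
            + rng.logistic(size=n)
        )
        labels["pathologic"] = _threshold_labels(score, n_pos("pathologic"))

    if "pathologic_with_ECS" in config.prevalence:
        if "pathologic" not in labels:
            raise ConfigurationError("ECS task requires the pathologic task")
        # ECS signal uses a subset of the pathologic informative features
        info_ecs = info[: max(len(info) // 2, 1)] if len(info) else info
        score_ecs = (
            config.effect_size / np.sqrt(max(len(info_ecs), 1))
            * X[:, info_ecs].sum(axis=1)
            + rng.logistic(size=n)
        )
        ecs = np.zeros(n, dtype=int)
        inside = np.flatnonzero(labels["pathologic"] == 1)
        npos = n_pos("pathologic_with_ECS")
        if npos > len(inside):
            raise ConfigurationError("ECS prevalence exceeds pathologic prevalence")
        ecs[inside[np.argsort(score_ecs[inside])[::-1][:npos]]] = 1
        labels["pathologic_with_ECS"] = ecs

    if "non_pathologic" in config.prevalence:
        if "pathologic" not in labels:
            raise ConfigurationError("non_pathologic task requires pathologic")
        npos = n_pos("non_pathologic")
        if npos != n - int(labels["pathologic"].sum()):
            raise ConfigurationError(
                "non_pathologic prevalence inconsistent with pathologic"
            )
        labels["non_pathologic"] = 1 - labels["pathologic"]

    if not labels:
        raise ConfigurationError("no tasks configured")
    return table, LabelSet(ids, labels)
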