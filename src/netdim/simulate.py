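"""Ordinal Likert data from a correlated common-factor model.

Items load on k correlated latent factors; an optional extra orthogonal
"wording" factor models the method effect of positively framed items.  The
latent item responses are standard normal and are cut at per-item thresholds
into the five observed categories 0-4, so the generator has a closed-form
population correlation matrix against which every downstream estimator can
be checked.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .scale import DS_ES_32, ItemResponseMatrix, ScaleDefinition

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "population_correlation",
    "simulate_dataset",
    "scenario_config",
    "two_factor_config",
    "QUINTILE_THRESHOLDS",
    "SKEWED_THRESHOLDS",
    "SCENARIOS",
]

#: Equal-probability cut points on the standard-normal scale (20% per category).
QUINTILE_THRESHOLDS: tuple[float, ...] = tuple(stats.norm.ppf([0.2, 0.4, 0.6, 0.8]))

#: Right-shifted cut points mimicking a mostly-low severity distribution.
SKEWED_THRESHOLDS: tuple[float, ...] = tuple(stats.norm.ppf([0.45, 0.7, 0.85, 0.95]))


class ConfigError(ValueError):
    """The generative configuration is internally inconsistent."""


@dataclass(frozen=True)
class SimulationConfig:
    """Generative model for one synthetic sample.

    loading_matrix is p x k standardized loadings; factor_correlations is
    the k x k factor correlation matrix Phi (unit diagonal, positive
    definite).  thresholds holds 4 strictly increasing cut points per item.
    method_effect_items load additionally on one orthogonal wording factor
    with loading method_effect_loading.
    """

    n: int
    loading_matrix: np.ndarray
    factor_correlations: np.ndarray
    thresholds: np.ndarray
    seed: int
    method_effect_items: frozenset[int] = frozenset()
    method_effect_loading: float = 0.0
    scale: ScaleDefinition | None = None

    def __post_init__(self) -> None:
        lam = np.atleast_2d(np.asarray(self.loading_matrix, dtype=float))
        phi = np.atleast_2d(np.asarray(self.factor_correlations, dtype=float))
        thr = np.asarray(self.thresholds, dtype=float)
        if thr.ndim == 1:
            thr = np.tile(thr, (lam.shape[0], 1))
        object.__setattr__(self, "loading_matrix", lam)
        object.__setattr__(self, "factor_correlations", phi)
        object.__setattr__(self, "thresholds", thr)
        p, k = lam.shape
        if phi.shape != (k, k):
            raise ConfigError(f"factor_correlations must be {k}x{k}")
        if not np.allclose(phi, phi.T) or not np.allclose(np.diag(phi), 1.0):
            raise ConfigError("factor_correlations must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(phi).min() <= 0:
            raise ConfigError("factor_correlations must be positive definite")
        if thr.shape != (p, 4):
            raise ConfigError("thresholds must give 4 cut points per item")
        if np.any(np.diff(thr, axis=1) <= 0):
            raise ConfigError("thresholds must be strictly increasing")
        if not (0.0 <= self.method_effect_loading < 1.0):
            raise ConfigError("method_effect_loading must be in [0, 1)")
        if any(i < 0 or i >= p for i in self.method_effect_items):
            raise ConfigError("method_effect_items indices out of range")
        comm = self._communalities()
        if np.any(comm >= 1.0):
            bad = int(np.argmax(comm))
            raise ConfigError(
                f"item {bad} has communality {comm[bad]:.3f} >= 1; lower its loadings"
            )
        if self.n < 1:
            raise ConfigError("n must be positive")

    @property
    def p(self) -> int:
        return self.loading_matrix.shape[0]

    @property
    def k(self) -> int:
        return self.loading_matrix.shape[1]

    def _method_vector(self) -> np.ndarray:
        m = np.zeros(self.p)
        for i in self.method_effect_items:
            m[i] = self.method_effect_loading
        return m

    def _communalities(self) -> np.ndarray:
        lam, phi = self.loading_matrix, self.factor_correlations
        comm = np.einsum("ij,jk,ik->i", lam, phi, lam)
        return comm + self._method_vector() ** 2

    @property
    def true_membership(self) -> np.ndarray:
        """Item -> factor index by largest absolute loading."""
        return np.argmax(np.abs(self.loading_matrix), axis=1)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n": self.n,
                "loading_matrix": self.loading_matrix.tolist(),
                "factor_correlations": self.factor_correlations.tolist(),
                "thresholds": self.thresholds.tolist(),
                "method_effect_items": sorted(self.method_effect_items),
                "method_effect_loading": self.method_effect_loading,
                "seed": self.seed,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        return cls(
            n=d["n"],
            loading_matrix=np.array(d["loading_matrix"]),
            factor_correlations=np.array(d["factor_correlations"]),
            thresholds=np.array(d["thresholds"]),
            method_effect_items=frozenset(d["method_effect_items"]),
            method_effect_loading=d["method_effect_loading"],
            seed=d["seed"],
        )


@dataclass(frozen=True)
class SimulatedDataset:
    responses: ItemResponseMatrix
    latent_scores: np.ndarray
    latent_responses: np.ndarray
    true_membership: np.ndarray
    config: SimulationConfig


def population_correlation(config: SimulationConfig) -> np.ndarray:
    """Model-implied correlation of the latent item responses.

    Sigma = Lambda Phi Lambda' + m m' + Theta with Theta diagonal chosen to
    give a unit diagonal (m is the wording-factor loading vector).
    """
    lam, phi = config.loading_matrix, config.factor_correlations
    m = config._method_vector()
    sigma = lam @ phi @ lam.T + np.outer(m, m)
    np.fill_diagonal(sigma, 1.0)
    return sigma


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Draw one sample: multivariate-normal latent responses cut at the
    item thresholds into integer categories 0-4.  Fixed seed gives a
    bit-identical dataset."""
    rng = np.random.default_rng(config.seed)
    p, k, n = config.p, config.k, config.n
    chol_phi = np.linalg.cholesky(config.factor_correlations)
    eta = rng.standard_normal((n, k)) @ chol_phi.T
    m = config._method_vector()
    wording = rng.standard_normal((n, 1))
    comm = config._communalities()
    eps = rng.standard_normal((n, p)) * np.sqrt(1.0 - comm)
    ystar = eta @ config.loading_matrix.T + wording * m + eps
    values = np.empty((n, p), dtype=np.int64)
    for j in range(p):
        values[:, j] = np.searchsorted(config.thresholds[j], ystar[:, j])
    scale = config.scale
    if scale is None or scale.p != p:
        scale = _generic_scale(p) if p != 32 else DS_ES_32
    responses = ItemResponseMatrix(values=values, scale=scale)
    return SimulatedDataset(
        responses=responses,
        latent_scores=eta,
        latent_responses=ystar,
        true_membership=config.true_membership,
        config=config,
    )


def _generic_scale(p: int) -> ScaleDefinition:
    from .scale import ItemMeta, Scale, Subscale

    items = tuple(
        ItemMeta(i + 1, f"synthetic item {i + 1}", Scale.defeat, Subscale.defeat)
        for i in range(p)
    )
    return ScaleDefinition(items=items)


# --- named scenarios --------------------------------------------------------

#: Loading magnitudes are cycled over this pattern so every cluster mixes
#: stronger and weaker indicators (range matching well-constructed clinical
#: questionnaires).
_LOADING_CYCLE = (0.70, 0.80, 0.65, 0.75, 0.60, 0.85)


def _block_loadings(sizes: Sequence[int]) -> np.ndarray:
    p, k = sum(sizes), len(sizes)
    lam = np.zeros((p, k))
    row = 0
    for f, size in enumerate(sizes):
        for i in range(size):
            lam[row, f] = _LOADING_CYCLE[row % len(_LOADING_CYCLE)]
            row += 1
    return lam


SCENARIOS = ("online_4dim", "clinical_3dim", "unidimensional", "high_overlap")


def scenario_config(
    scenario: str,
    n: int | None = None,
    seed: int = 0,
    thresholds: Sequence[float] = QUINTILE_THRESHOLDS,
) -> SimulationConfig:
    """Named generative presets for the 32-item battery.

    online_4dim
        Four correlated factors splitting the items 13/3/10/6 — the large
        defeat cluster, the three positively framed "winner" items, and the
        external/internal entrapment clusters; factor correlations 0.6-0.8.
        Default n = 480 (the online sample size).
    clinical_3dim
        Three factors splitting the items 16/9/7 (all defeat items
        together); default n = 150.
    unidimensional
        One common factor for all 32 items.
    high_overlap
        Two 16-item factors correlated at 0.91 — the regime in which
        traditional factor-count heuristics collapse the two constructs.
    """
    thr = np.asarray(thresholds, dtype=float)
    if scenario == "online_4dim":
        lam = _block_loadings([13, 3, 10, 6])
        phi = np.array(
            [
                [1.00, 0.60, 0.70, 0.65],
                [0.60, 1.00, 0.60, 0.60],
                [0.70, 0.60, 1.00, 0.80],
                [0.65, 0.60, 0.80, 1.00],
            ]
        )
        n = 480 if n is None else n
    elif scenario == "clinical_3dim":
        lam = _block_loadings([16, 9, 7])
        phi = np.array(
            [
                [1.00, 0.70, 0.75],
                [0.70, 1.00, 0.80],
                [0.75, 0.80, 1.00],
            ]
        )
        n = 150 if n is None else n
    elif scenario == "unidimensional":
        lam = _block_loadings([32])
        phi = np.eye(1)
        n = 480 if n is None else n
    elif scenario == "high_overlap":
        lam = np.zeros((32, 2))
        lam[:16, 0] = 0.8
        lam[16:, 1] = 0.8
        phi = np.array([[1.0, 0.91], [0.91, 1.0]])
        n = 480 if n is None else n
    else:
        raise ValueError(
            f"unknown scenario {scenario!r}; available: {', '.join(SCENARIOS)}"
        )
    return SimulationConfig(
        n=n,
        loading_matrix=lam,
        factor_correlations=phi,
        thresholds=thr,
        seed=seed,
        scale=DS_ES_32,
    )


def two_factor_config(
    phi12: float,
    n: int = 2000,
    seed: int = 0,
    loading: float = 0.7,
    items_per_factor: int = 16,
) -> SimulationConfig:
    """Two equally sized factors with a single inter-factor correlation —
    the sweep used to contrast network-based and scree-based dimension
    counts as the factors become nearly indistinguishable."""
    p = 2 * items_per_factor
    lam = np.zeros((p, 2))
    lam[:items_per_factor, 0] = loading
    lam[items_per_factor:, 1] = loading
    phi = np.array([[1.0, phi12], [phi12, 1.0]])
    return SimulationConfig(
        n=n,
        loading_matrix=lam,
        factor_correlations=phi,
        thresholds=np.asarray(QUINTILE_THRESHOLDS),
        seed=seed,
        scale=DS_ES_32 if p == 32 else None,
    )
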