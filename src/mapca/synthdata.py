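"""Synthetic multi-domain data with controllable shift, label scarcity and outliers.

Each domain draws Gaussian class blobs (one isotropic blob per class) whose
means can be translated, rotated (in the first two feature dimensions) or
replaced wholesale, emulating the covariate and conditional shift seen
between subjects, sessions and recording devices in EEG-style feature data.
Features imitate differential-entropy EEG features only in scale: moderate
dimension, continuous, roughly Gaussian per class; no raw-signal structure
is simulated.

Outliers are drawn uniformly in an inflated bounding box of the domain and
carry *random* ground-truth labels; the outlier mask is recorded so that
downstream checks can compare memberships and restrict accuracy to genuine
instances.  Label scarcity: exactly ``ceil(labeled_fraction * n)`` instances
are labeled, stratified by class over the inliers.

Everything is deterministic given the config (which includes the seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from typing import Sequence

import numpy as np

from .exceptions import InputError, ParameterError
from .kernels import KernelSpec
from .solver import Hyperparams
from .sources import SourceModel, project_model, train_source

__all__ = [
    "DomainConfig",
    "Domain",
    "TaskBundle",
    "make_domain",
    "make_multisource_task",
    "make_recovery_task",
    "recovery_hyperparams",
    "default_class_means",
]


@dataclass(frozen=True)
class DomainConfig:
    """Generative law of one domain.

    ``class_means`` (M x d) overrides the default placement, which puts class
    m at ``separation`` along coordinate m.  ``shift`` is a d-vector
    translation applied to the whole domain after an optional rotation by
    ``rotation`` radians in the first two feature dimensions.  ``class_std``
    is the isotropic within-class standard deviation.  ``outlier_scale``
    inflates the domain bounding box from which outliers are drawn.
    """

    M: int = 3
    d: int = 4
    n_per_class: int = 40
    separation: float = 3.0
    class_means: tuple | None = None
    class_std: float = 1.0
    shift: tuple | None = None
    rotation: float = 0.0
    outlier_fraction: float = 0.0
    outlier_scale: float = 2.0
    labeled_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M < 2:
            raise ParameterError("need at least two classes")
        if self.n_per_class < 2:
            raise ParameterError("n_per_class must be >= 2")
        if not (0.0 <= self.outlier_fraction < 0.5):
            raise ParameterError("outlier_fraction must lie in [0, 0.5)")
        if not (0.0 < self.labeled_fraction <= 1.0):
            raise ParameterError("labeled_fraction must lie in (0, 1]")
        if self.class_std <= 0 or self.outlier_scale <= 0 or self.separation <= 0:
            raise ParameterError("scales must be positive")

    def means(self) -> np.ndarray:
        if self.class_means is not None:
            means = np.asarray(self.class_means, dtype=float)
            if means.shape != (self.M, self.d):
                raise ParameterError(
                    f"class_means must have shape ({self.M}, {self.d})"
                )
            return means
        return default_class_means(self.M, self.d, self.separation)


def default_class_means(M: int, d: int, separation: float) -> np.ndarray:
    """Class m at ``separation`` along coordinate ``m % d``."""
    means = np.zeros((M, d))
    for m in range(M):
        means[m, m % d] = separation
    return means


@dataclass(frozen=True)
class Domain:
    """One generated domain with ground-truth masks."""

    X: np.ndarray
    y: np.ndarray
    labeled_mask: np.ndarray
    outlier_mask: np.ndarray
    config: DomainConfig

    @property
    def y_partial(self) -> np.ndarray:
        """Labels with unlabeled instances set to -1 (the solver convention)."""
        out = self.y.copy()
        out[~self.labeled_mask] = -1
        return out


def make_domain(config: DomainConfig) -> Domain:
    """Draw one domain from its config; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    means = config.means()
    n = config.M * config.n_per_class
    X = np.vstack([
        rng.normal(means[m], config.class_std, size=(config.n_per_class, config.d))
        for m in range(config.M)
    ])
    y = np.repeat(np.arange(config.M), config.n_per_class)

    if config.rotation:
        c, s = math.cos(config.rotation), math.sin(config.rotation)
        R = np.array([[c, -s], [s, c]])
        X[:, :2] = X[:, :2] @ R.T
    if config.shift is not None:
        shift = np.asarray(config.shift, dtype=float)
        if shift.shape == ():
            shift = np.full(config.d, float(shift))
        if shift.shape != (config.d,):
            raise ParameterError(f"shift must be a {config.d}-vector or scalar")
        X = X + shift

    outlier_mask = np.zeros(n, dtype=bool)
    n_out = int(round(config.outlier_fraction * n))
    if n_out:
        lo, hi = X.min(axis=0), X.max(axis=0)
        center, half = (lo + hi) / 2.0, (hi - lo) / 2.0
        lo = center - config.outlier_scale * half
        hi = center + config.outlier_scale * half
        idx = rng.choice(n, size=n_out, replace=False)
        X[idx] = rng.uniform(lo, hi, size=(n_out, config.d))
        y[idx] = rng.integers(0, config.M, size=n_out)
        outlier_mask[idx] = True

    labeled_mask = _stratified_labels(rng, y, outlier_mask, config)
    return Domain(X=X, y=y, labeled_mask=labeled_mask, outlier_mask=outlier_mask,
                  config=config)


def _stratified_labels(
    rng: np.random.Generator,
    y: np.ndarray,
    outlier_mask: np.ndarray,
    config: DomainConfig,
) -> np.ndarray:
    """Choose exactly ceil(labeled_fraction * n) labeled instances.

    Stratified over the inlier class pools (largest-remainder apportionment,
    remainders tied toward the lower class index); outliers are used only if
    the inlier pool is exhausted.
    """
    n = len(y)
    L = math.ceil(config.labeled_fraction * n)
    pools = [np.flatnonzero((y == m) & ~outlier_mask) for m in range(config.M)]
    sizes = np.array([len(p) for p in pools])
    total = sizes.sum()
    take = np.minimum(sizes, (L * sizes) // max(total, 1))
    # distribute the remainder one by one, largest fractional share first
    while take.sum() < min(L, total):
        frac = np.where(take < sizes, L * sizes / max(total, 1) - take, -np.inf)
        take[int(np.argmax(frac))] += 1
    mask = np.zeros(n, dtype=bool)
    for pool, t in zip(pools, take):
        if t:
            mask[rng.choice(pool, size=int(t), replace=False)] = True
    short = L - int(mask.sum())
    if short > 0:  # only when outliers crowd out the inliers
        rest = np.flatnonzero(~mask)
        mask[rng.choice(rest, size=short, replace=False)] = True
    return mask


@dataclass(frozen=True)
class TaskBundle:
    """A target domain plus projected source models and relevance ground truth."""

    target: Domain
    sources: tuple[SourceModel, ...]
    source_domains: tuple[Domain, ...]
    relevance: tuple[bool, ...]

    def to_dict(self) -> dict:
        def dom(d: Domain) -> dict:
            return {
                "X": d.X.tolist(),
                "y": d.y.tolist(),
                "labeled_mask": d.labeled_mask.tolist(),
                "outlier_mask": d.outlier_mask.tolist(),
                "config": _config_dict(d.config),
            }

        return {
            "schema": "mapca-task/1",
            "target": dom(self.target),
            "sources": [
                {
                    "alpha": s.alpha.tolist(),
                    "X": s.X.tolist(),
                    "kernels": [{"family": k.family, "sigma": k.sigma} for k in s.kernels],
                    "classes": np.asarray(s.classes).tolist(),
                    "origin": s.origin,
                    "name": s.name,
                }
                for s in self.sources
            ],
            "source_domains": [dom(d) for d in self.source_domains],
            "relevance": list(self.relevance),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "TaskBundle":
        if payload.get("schema") != "mapca-task/1":
            raise InputError("not a mapca task bundle")

        def dom(p: dict) -> Domain:
            return Domain(
                X=np.asarray(p["X"], dtype=float),
                y=np.asarray(p["y"], dtype=int),
                labeled_mask=np.asarray(p["labeled_mask"], dtype=bool),
                outlier_mask=np.asarray(p["outlier_mask"], dtype=bool),
                config=_config_from_dict(p["config"]),
            )

        sources = tuple(
            SourceModel(
                alpha=np.asarray(s["alpha"], dtype=float),
                X=np.asarray(s["X"], dtype=float),
                kernels=tuple(KernelSpec(**k) for k in s["kernels"]),
                classes=np.asarray(s["classes"]),
                origin=s["origin"],
                name=s["name"],
            )
            for s in payload["sources"]
        )
        return cls(
            target=dom(payload["target"]),
            sources=sources,
            source_domains=tuple(dom(p) for p in payload["source_domains"]),
            relevance=tuple(bool(r) for r in payload["relevance"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "TaskBundle":
        return cls.from_dict(json.loads(text))


def _config_dict(config: DomainConfig) -> dict:
    out = asdict(config)
    if out["class_means"] is not None:
        out["class_means"] = np.asarray(out["class_means"]).tolist()
    if out["shift"] is not None:
        out["shift"] = np.asarray(out["shift"]).tolist()
    return out


def _config_from_dict(payload: dict) -> DomainConfig:
    payload = dict(payload)
    if payload.get("class_means") is not None:
        payload["class_means"] = tuple(map(tuple, payload["class_means"]))
    if payload.get("shift") is not None:
        shift = payload["shift"]
        payload["shift"] = tuple(shift) if isinstance(shift, list) else shift
    return DomainConfig(**payload)


def make_multisource_task(
    target_config: DomainConfig,
    source_configs: Sequence[DomainConfig],
    relevance: Sequence[bool] | None = None,
    hp: Hyperparams | None = None,
    kernels: KernelSpec | Sequence[KernelSpec] | None = None,
    k: int = 5,
    tau: float | None = None,
) -> TaskBundle:
    """Generate a target domain plus source models projected onto it.

    Source domains are fully labeled for training regardless of their
    configured labeled fraction.  ``relevance`` records which sources share
    the target's law (ground truth for weight-recovery checks).
    """
    for cfg in source_configs:
        if cfg.M != target_config.M or cfg.d != target_config.d:
            raise ParameterError("all domains must share M and d")
    target = make_domain(target_config)
    source_domains = []
    sources = []
    for i, cfg in enumerate(source_configs):
        dom = make_domain(cfg)
        source_domains.append(dom)
        model = train_source(dom.X, dom.y, hp=hp, kernels=kernels, k=k, tau=tau,
                             name=f"source-{i}")
        sources.append(project_model(model, target.X))
    if relevance is None:
        relevance = [False] * len(source_configs)
    if len(relevance) != len(source_configs):
        raise ParameterError("relevance flags must match the source count")
    return TaskBundle(
        target=target,
        sources=tuple(sources),
        source_domains=tuple(source_domains),
        relevance=tuple(bool(r) for r in relevance),
    )


def recovery_hyperparams() -> Hyperparams:
    """Hyperparameters of the source-relevance recovery benchmark.

    Two departures from the solver defaults, both dictated by the structure
    of the objective rather than tuned:

    * ``beta = 100`` (~ the sample size): the model-discrepancy term is a
      per-sample *average* while the data-fit and clustering terms are sums
      over the n ~ 120 instances, so beta must be of order n for source
      knowledge to carry comparable weight;
    * ``eta = 0.01``: recovering a dominant weight for the relevant source
      requires the ridge on gamma to be small relative to the discrepancy
      scale (a large eta forces uniform weights by construction).
    """
    return Hyperparams(beta=100.0, eta=0.01)


def make_recovery_task(
    seed: int,
    outlier_fraction: float = 0.0,
    n_per_class: int = 40,
    kernels: KernelSpec | Sequence[KernelSpec] | None = None,
) -> TaskBundle:
    """The canonical two-source benchmark with known source relevance.

    The target draws three Gaussian classes (d = 4, separation 3, 10%%
    labeled).  Source 0 is *relevant*: same law, different draw, fully
    labeled.  Source 1 is *misleading*: the class means are rolled by one
    position (classes swap places — maximal conditional shift) and the
    domain is additionally translated and mildly rotated.  Its support
    overlaps the target, so its confident wrong decisions create genuine
    negative transfer when fused in with a nonzero weight.
    """
    base = DomainConfig(
        M=3, d=4, n_per_class=n_per_class, separation=3.0,
        labeled_fraction=0.1, outlier_fraction=outlier_fraction, seed=seed,
    )
    relevant = replace(
        base, labeled_fraction=1.0, outlier_fraction=0.0, seed=seed + 10_000,
    )
    means = base.means()
    irrelevant = replace(
        base,
        labeled_fraction=1.0,
        outlier_fraction=0.0,
        class_means=tuple(map(tuple, np.roll(means, 1, axis=0))),
        shift=0.5,
        rotation=0.3,
        seed=seed + 20_000,
    )
    return make_multisource_task(
        base, [relevant, irrelevant], relevance=[True, False],
        hp=recovery_hyperparams(), kernels=kernels,
    )
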