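"""Delimited-matrix I/O, YAML config parsing and model archives.

Matrices are plain delimited text (whitespace or comma separated, optional
header row).  Fitted models and source models are stored as versioned JSON
archives so they survive round trips without binary formats.

Config keys (YAML)::

    graph:
      k: 5
      tau: null          # null -> median heuristic
    kernel:
      family: gaussian
      sigma: null          # null -> 1/d
      multi:               # optional list; overrides family/sigma
        - {family: gaussian, sigma: null}
        - {family: laplacian, sigma: null}
    solver:
      lam: 1.0
      lambda_s: 1.0
      C: 1.0
      beta: 1.0
      eta: 1.0
      max_iter: 50
      window: 5
      eps: 1.0e-4
      membership_lwm_weighted: true
    adaptation:
      divergence: target_scatter   # or identity
    weighting:
      mode: optimal                # uniform | distance | fixed
      delta: 100.0
      weights: null
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import InputError
from .kernels import KernelSpec
from .solver import FitResult, Hyperparams, LabelEncoding
from .sources import SourceModel, WeightingScheme

__all__ = [
    "read_matrix",
    "write_matrix",
    "load_config",
    "config_to_hyperparams",
    "config_to_kernels",
    "config_to_graph_params",
    "config_to_weighting",
    "save_fit",
    "load_fit",
    "save_source",
    "load_source",
]


def read_matrix(path: str | Path) -> np.ndarray:
    """Read a delimited text matrix; a non-numeric first row is a header.

    The delimiter is detected from the first data line (comma, tab or
    semicolon; otherwise any whitespace).
    """
    path = Path(path)
    sep = r"\s+"
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        for cand in (",", "\t", ";"):
            if cand in line:
                sep = cand
                break
        break
    frame = pd.read_csv(path, sep=sep, engine="python", header=None,
                        comment="#", skip_blank_lines=True)
    first = frame.iloc[0]
    if not all(_is_number(v) for v in first):
        frame = frame.iloc[1:]
    try:
        values = frame.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise InputError(f"{path} contains non-numeric entries") from exc
    return values


def _is_number(value) -> bool:
    try:
        float(value)
        return True
    except (TypeError, ValueError):
        return False


def write_matrix(path: str | Path, matrix: np.ndarray, fmt: str = "%.17g") -> None:
    np.savetxt(path, np.atleast_2d(np.asarray(matrix)), fmt=fmt, delimiter="\t")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise InputError(f"{path} must contain a YAML mapping")
    return cfg


def config_to_hyperparams(cfg: dict) -> Hyperparams:
    solver = dict(cfg.get("solver", {}))
    adaptation = cfg.get("adaptation", {})
    if "divergence" in adaptation:
        solver["divergence"] = adaptation["divergence"]
    return Hyperparams(**solver)


def config_to_kernels(cfg: dict) -> tuple[KernelSpec, ...]:
    kernel = cfg.get("kernel", {})
    multi = kernel.get("multi")
    if multi:
        return tuple(
            KernelSpec(family=item.get("family", "gaussian"), sigma=item.get("sigma"))
            for item in multi
        )
    return (KernelSpec(family=kernel.get("family", "gaussian"),
                       sigma=kernel.get("sigma")),)


def config_to_graph_params(cfg: dict) -> tuple[int, float | None]:
    graph = cfg.get("graph", {})
    return int(graph.get("k", 5)), graph.get("tau")


def config_to_weighting(cfg: dict) -> WeightingScheme:
    w = cfg.get("weighting", {})
    weights = w.get("weights")
    return WeightingScheme(
        mode=w.get("mode", "optimal"),
        delta=float(w.get("delta", 100.0)),
        weights=None if weights is None else np.asarray(weights, dtype=float),
    )


def _kernels_payload(specs) -> list:
    return [{"family": s.family, "sigma": s.sigma} for s in specs]


def save_fit(result: FitResult, path: str | Path) -> None:
    """Serialize a fitted model to a versioned JSON archive."""
    payload = {
        "schema": "mapca-fit/1",
        "alpha": result.alpha.tolist(),
        "gamma": result.gamma.tolist(),
        "V": result.V.tolist(),
        "kernels": _kernels_payload(result.kernels),
        "X": result.X.tolist(),
        "Xhat": result.Xhat.tolist(),
        "k": result.k,
        "tau": result.tau,
        "classes": np.asarray(result.classes).tolist(),
        "hp": _hp_payload(result.hp),
        "labeled_mask": result.labeled_mask.tolist(),
        "converged": result.converged,
        "stop_reason": result.stop_reason,
        "n_iter": result.n_iter,
        "obj_history": list(result.obj_history),
        "partial_history": [[stage, val] for stage, val in result.partial_history],
    }
    Path(path).write_text(json.dumps(payload))


def _hp_payload(hp: Hyperparams) -> dict:
    return {
        "lam": hp.lam, "lambda_s": hp.lambda_s, "C": hp.C, "beta": hp.beta,
        "eta": hp.eta, "max_iter": hp.max_iter, "window": hp.window,
        "eps": hp.eps, "membership_lwm_weighted": hp.membership_lwm_weighted,
        "divergence": hp.divergence,
    }


def load_fit(path: str | Path) -> FitResult:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema") != "mapca-fit/1":
        raise InputError(f"{path} is not a mapca fit archive")
    return FitResult(
        alpha=np.asarray(payload["alpha"], dtype=float),
        gamma=np.asarray(payload["gamma"], dtype=float),
        V=np.asarray(payload["V"], dtype=float),
        kernels=tuple(KernelSpec(**k) for k in payload["kernels"]),
        X=np.asarray(payload["X"], dtype=float),
        Xhat=np.asarray(payload["Xhat"], dtype=float),
        k=int(payload["k"]),
        tau=float(payload["tau"]),
        encoding=LabelEncoding(classes=np.asarray(payload["classes"])),
        hp=Hyperparams(**payload["hp"]),
        labeled_mask=np.asarray(payload["labeled_mask"], dtype=bool),
        converged=bool(payload["converged"]),
        stop_reason=payload["stop_reason"],
        n_iter=int(payload["n_iter"]),
        obj_history=tuple(payload["obj_history"]),
        partial_history=tuple((s, v) for s, v in payload["partial_history"]),
    )


def save_source(model: SourceModel, path: str | Path) -> None:
    payload = {
        "schema": "mapca-source/1",
        "alpha": model.alpha.tolist(),
        "X": model.X.tolist(),
        "kernels": _kernels_payload(model.kernels),
        "classes": np.asarray(model.classes).tolist(),
        "origin": model.origin,
        "name": model.name,
    }
    Path(path).write_text(json.dumps(payload))


def load_source(path: str | Path) -> SourceModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema") != "mapca-source/1":
        raise InputError(f"{path} is not a mapca source archive")
    return SourceModel(
        alpha=np.asarray(payload["alpha"], dtype=float),
        X=np.asarray(payload["X"], dtype=float),
        kernels=tuple(KernelSpec(**k) for k in payload["kernels"]),
        classes=np.asarray(payload["classes"]),
        origin=payload["origin"],
        name=payload["name"],
    )
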