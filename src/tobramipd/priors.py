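"""Discrete (nonparametric) population priors: container, JSON I/O, defaults.

A discrete prior is a finite set of support points — population-scale
parameter vectors ``(vs, ki, ks, k12, k21)`` — with probability weights.
Priors are exchanged as structured JSON::

    {
      "label": "...",
      "dimensions": [{"name": "vs", "unit": "L/kg", "low": ..., "high": ...}, ...],
      "points": [[vs, ki, ks, k12, k21, weight], ...]
    }

The default prior shipped here is a synthetic quasi-random construction
(log-uniform Sobol points over wide adult-plausible ranges) — it is NOT the
published pediatric population model, whose support points are not public.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy.stats import qmc

from .pk import PARAM_NAMES, SupportPoint

__all__ = ["DiscretePrior", "default_prior", "load_prior", "DEFAULT_BOUNDS", "PARAM_UNITS"]

PARAM_UNITS = {
    "vs": "L/kg",
    "ki": "1/h",
    "ks": "1/h per mL/min",
    "k12": "1/h",
    "k21": "1/h",
}

#: log-uniform ranges of the synthetic default prior, per dimension
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "vs": (0.15, 0.55),
    "ki": (0.003, 0.03),
    "ks": (0.0015, 0.005),
    "k12": (0.05, 4.0),
    "k21": (0.05, 4.0),
}

_WEIGHT_TOL = 1e-6


@dataclass
class DiscretePrior:
    """A weighted finite support for the population parameter distribution.

    ``theta`` is an (n, 5) array with columns in :data:`~tobramipd.pk.PARAM_NAMES`
    order; ``weights`` an (n,) probability vector; ``bounds`` a (5, 2) array
    of per-dimension [low, high].
    """

    theta: np.ndarray
    weights: np.ndarray
    bounds: np.ndarray
    label: str = "unnamed prior"

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.bounds = np.asarray(self.bounds, dtype=float)
        if self.theta.ndim != 2 or self.theta.shape[1] != len(PARAM_NAMES):
            raise ValueError(f"theta must be (n, {len(PARAM_NAMES)})")
        if self.weights.shape != (self.theta.shape[0],):
            raise ValueError("weights must be (n,)")
        if self.bounds.shape != (len(PARAM_NAMES), 2):
            raise ValueError("bounds must be (5, 2)")
        if np.any(self.weights < 0):
            raise ValueError("weights must be >= 0")
        total = self.weights.sum()
        if total <= 0:
            raise ValueError("weights must have positive total mass")
        if abs(total - 1.0) > _WEIGHT_TOL:
            warnings.warn(
                f"prior weights sum to {total:.8g}; renormalizing", stacklevel=2
            )
        self.weights = self.weights / total

    def __len__(self) -> int:
        return self.theta.shape[0]

    def __iter__(self) -> Iterator[SupportPoint]:
        for row, w in zip(self.theta, self.weights):
            yield SupportPoint(*row, weight=float(w))

    @property
    def points(self) -> list[SupportPoint]:
        return list(self)

    def column(self, name: str) -> np.ndarray:
        return self.theta[:, PARAM_NAMES.index(name)]

    def replace_weights(self, weights: np.ndarray) -> "DiscretePrior":
        return DiscretePrior(self.theta, weights, self.bounds, self.label)

    @classmethod
    def from_points(
        cls, points: Sequence[SupportPoint], bounds: np.ndarray | None = None,
        label: str = "unnamed prior",
    ) -> "DiscretePrior":
        theta = np.array([p.as_array() for p in points], dtype=float)
        weights = np.array([p.weight for p in points], dtype=float)
        if bounds is None:
            lo = theta.min(axis=0)
            hi = theta.max(axis=0)
            bounds = np.column_stack([lo, hi])
        return cls(theta, weights, bounds, label)

    # ---- JSON interchange -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "dimensions": [
                {
                    "name": name,
                    "unit": PARAM_UNITS[name],
                    "low": float(self.bounds[i, 0]),
                    "high": float(self.bounds[i, 1]),
                }
                for i, name in enumerate(PARAM_NAMES)
            ],
            "points": [
                [*map(float, row), float(w)] for row, w in zip(self.theta, self.weights)
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, payload: dict) -> "DiscretePrior":
        try:
            label = payload["label"]
            dims = payload["dimensions"]
            points = payload["points"]
        except KeyError as exc:  # strict schema
            raise ValueError(f"prior file missing required key: {exc}") from exc
        names = [d["name"] for d in dims]
        if names != list(PARAM_NAMES):
            raise ValueError(
                f"prior dimensions must be {list(PARAM_NAMES)} in order, got {names}"
            )
        bounds = np.array([[d["low"], d["high"]] for d in dims], dtype=float)
        if np.any(bounds[:, 0] > bounds[:, 1]):
            raise ValueError("prior bounds must satisfy low <= high")
        arr = np.asarray(points, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != len(PARAM_NAMES) + 1:
            raise ValueError("each prior point must have 5 parameters + weight")
        theta, weights = arr[:, :-1], arr[:, -1]
        eps = 1e-9
        if np.any(theta < bounds[:, 0] - eps) or np.any(theta > bounds[:, 1] + eps):
            raise ValueError("prior points must lie within the declared bounds")
        return cls(theta, weights, bounds, label)

    @classmethod
    def from_json(cls, path: str | Path) -> "DiscretePrior":
        return cls.from_dict(json.loads(Path(path).read_text()))


def load_prior(path: str | Path | None, *, seed: int = 0) -> DiscretePrior:
    """Load a prior JSON file, or build the synthetic default when no file is given."""
    if path is None:
        return default_prior(seed=seed)
    return DiscretePrior.from_json(path)


def default_prior(
    n_points: int = 2000,
    *,
    seed: int = 0,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> DiscretePrior:
    """Synthetic default prior — not the published pediatric model.

    ``n_points`` scrambled-Sobol points, log-uniform over wide
    adult-plausible ranges (see :data:`DEFAULT_BOUNDS`), with equal weights.
    The scramble uses an explicit seed so the prior is reproducible
    bit-for-bit.
    """
    bdict = dict(DEFAULT_BOUNDS)
    if bounds:
        bdict.update(bounds)
    barr = np.array([bdict[name] for name in PARAM_NAMES], dtype=float)
    sampler = qmc.Sobol(d=len(PARAM_NAMES), scramble=True, rng=np.random.default_rng(seed))
    # draw a power-of-two batch (Sobol balance) and keep the first n_points
    m = max(int(np.ceil(np.log2(max(n_points, 2)))), 1)
    unit = sampler.random_base2(m)[:n_points]
    log_lo = np.log(barr[:, 0])
    log_hi = np.log(barr[:, 1])
    theta = np.exp(log_lo + unit * (log_hi - log_lo))
    weights = np.full(n_points, 1.0 / n_points)
    return DiscretePrior(
        theta, weights, barr,
        label=f"synthetic default (log-uniform Sobol, n={n_points}, seed={seed})",
    )
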