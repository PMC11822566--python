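"""Minimal tree-structured Parzen estimator (TPE) for hyperparameter search.

Sequential model-based optimization: past trials are split at the gamma
quantile of the loss into a "good" and a "bad" set; each parameter gets a
one-dimensional Parzen density l(x) over good values and g(x) over bad
values, candidates are drawn from l and the one maximizing l(x)/g(x) is
proposed.  The first trial always evaluates the space's default
configuration, and a handful of startup trials are sampled uniformly before
the density model kicks in.

The search space is a dict ``name -> {"low", "high", "type", "default"}``
with type one of ``float``, ``int``, ``logfloat``.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.stats import gaussian_kde

__all__ = ["TPESampler", "validate_space", "default_params"]


def validate_space(space: dict) -> None:
    for name, s in space.items():
        if "low" not in s or "high" not in s:
            raise ValueError(f"space parameter {name!r} needs 'low' and 'high'")
        if not (s["low"] < s["high"]):
            raise ValueError(f"invalid bounds for {name!r}: low must be < high")
        t = s.get("type", "float")
        if t not in ("float", "int", "logfloat"):
            raise ValueError(f"unknown type {t!r} for {name!r}")
        if t == "logfloat" and s["low"] <= 0:
            raise ValueError(f"logfloat parameter {name!r} requires low > 0")


def _to_internal(v, s):
    return math.log(v) if s.get("type") == "logfloat" else float(v)


def _from_internal(u, s):
    t = s.get("type", "float")
    v = math.exp(u) if t == "logfloat" else u
    v = min(max(v, s["low"]), s["high"])
    return int(round(v)) if t == "int" else float(v)


def default_params(space: dict) -> dict:
    """The default configuration: stated default, else the midpoint."""
    out = {}
    for name, s in space.items():
        if "default" in s:
            out[name] = s["default"]
        else:
            t = s.get("type", "float")
            if t == "logfloat":
                mid = math.exp((math.log(s["low"]) + math.log(s["high"])) / 2)
            else:
                mid = (s["low"] + s["high"]) / 2
            out[name] = int(round(mid)) if t == "int" else mid
    return out


class TPESampler:
    def __init__(self, space: dict, seed: int = 0, *, n_startup: int = 5,
                 gamma: float = 0.25, n_candidates: int = 24):
        validate_space(space)
        self.space = space
        self.rng = np.random.default_rng(seed)
        self.n_startup = n_startup
        self.gamma = gamma
        self.n_candidates = n_candidates

    def _uniform(self) -> dict:
        out = {}
        for name, s in self.space.items():
            lo, hi = _to_internal(s["low"], s), _to_internal(s["high"], s)
            out[name] = _from_internal(self.rng.uniform(lo, hi), s)
        return out

    def _density(self, values: np.ndarray, lo: float, hi: float):
        """Parzen density over observed values; uniform fallback for degenerate
        (too few or zero-variance) samples."""
        if values.size < 2 or np.ptp(values) < 1e-12:
            span = hi - lo
            center = values[0] if values.size else (lo + hi) / 2
            width = max(span / 10, 1e-6)

            def pdf(x):
                return np.exp(-((np.asarray(x) - center) / width) ** 2 / 2)

            def sample(n, rng):
                return rng.normal(center, width, n)

            return pdf, sample
        kde = gaussian_kde(values)

        def sample(n, rng):
            return values[rng.integers(values.size, size=n)] + \
                rng.normal(0, kde.factor * values.std(ddof=1), n)

        return kde.pdf, sample

    def suggest(self, history: Sequence[tuple[dict, float]]) -> dict:
        """Propose the next configuration given (params, loss) history."""
        if len(history) == 0:
            return default_params(self.space)
        if len(history) < self.n_startup:
            return self._uniform()
        losses = np.array([h[1] for h in history])
        n_good = max(1, int(np.ceil(self.gamma * len(history))))
        order = np.argsort(losses, kind="stable")
        good_idx, bad_idx = order[:n_good], order[n_good:]
        out = {}
        for name, s in self.space.items():
            lo, hi = _to_internal(s["low"], s), _to_internal(s["high"], s)
            vals = np.array([_to_internal(h[0][name], s) for h in history])
            l_pdf, l_sample = self._density(vals[good_idx], lo, hi)
            g_pdf, _ = self._density(vals[bad_idx], lo, hi) if bad_idx.size else (lambda x: np.ones_like(np.asarray(x, dtype=float)), None)
            cand = np.clip(l_sample(self.n_candidates, self.rng), lo, hi)
            score = l_pdf(cand) / np.maximum(g_pdf(cand), 1e-12)
            out[name] = _from_internal(float(cand[int(np.argmax(score))]), s)
        return out
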