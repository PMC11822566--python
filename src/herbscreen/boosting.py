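"""Gradient-boosted regression trees for binary classification, from scratch.

Two closely related learners live here:

* :func:`fit_gbdt` — classic stagewise GBDT.  The model after k rounds is
  ``M_k(x) = M_{k-1}(x) + lr * h_k(x)`` where each weak learner h_k is a
  regression tree fit by least squares to the negative gradient of the binary
  logistic loss at the current prediction, with a single Newton step per leaf
  (the per-tree line search).  The final score is
  ``sigmoid(base_score + lr * sum_k h_k(x))``.

* :func:`fit_goss_gbm` — the histogram variant: split thresholds are limited
  to per-feature histogram bin edges (equal-frequency quantiles), each tree is
  fit on a Gradient-based One-Side Sampling (GOSS) subsample — all
  large-|gradient| rows kept, a random fraction of the small-gradient rest
  with compensating weight (1-a)/b — and sparse features can optionally be
  merged by Exclusive Feature Bundling (EFB) before training.

With ``a = 1`` (no GOSS) and enough bins the histogram learner reduces exactly
to the plain GBDT: both search the same midpoint thresholds with the same
variance-reduction gain, ties broken by lowest feature index then lowest
threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "RegressionTree",
    "GBDTModel",
    "GossGBMModel",
    "GossConfig",
    "FeatureBundle",
    "fit_gbdt",
    "fit_goss_gbm",
    "predict_score",
    "goss_sample",
    "efb_bundle",
    "apply_bundles",
    "reconstruct_from_bundles",
]

_EPS = 1e-12


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def _log_loss(y, p):
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


# ---------------------------------------------------------------------------
# Trees


@dataclass
class RegressionTree:
    """Binary regression tree: internal nodes are (feature, threshold) tests
    with rule ``x[feature] <= threshold -> left``; leaves carry real values."""

    root: dict

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(X.shape[0])
        self._fill(self.root, X, np.arange(X.shape[0]), out)
        return out

    def _fill(self, node, X, idx, out):
        if "value" in node:
            out[idx] = node["value"]
            return
        go_left = X[idx, node["feature"]] <= node["threshold"]
        self._fill(node["left"], X, idx[go_left], out)
        self._fill(node["right"], X, idx[~go_left], out)

    def depth(self) -> int:
        def d(n):
            return 0 if "value" in n else 1 + max(d(n["left"]), d(n["right"]))
        return d(self.root)


def _feature_boundaries(X: np.ndarray, max_bins: int | None) -> list[np.ndarray]:
    """Candidate split thresholds per feature.

    Without a bin limit: midpoints between consecutive unique values (exact
    search).  With a limit: at most ``max_bins - 1`` equal-frequency quantile
    edges, falling back to the exact midpoints when the feature has few
    distinct values — so the histogram search coincides with the exact one
    whenever bins >= cardinality.
    """
    bounds = []
    for f in range(X.shape[1]):
        u = np.unique(X[:, f])
        if u.size < 2:
            bounds.append(np.empty(0))
            continue
        mids = (u[:-1] + u[1:]) / 2.0
        if max_bins is not None and mids.size > max_bins - 1:
            qs = np.quantile(X[:, f], np.linspace(0, 1, max_bins + 1)[1:-1])
            mids = np.unique(qs)
        bounds.append(mids)
    return bounds


def _bin_codes(X: np.ndarray, bounds: list[np.ndarray]) -> tuple[np.ndarray, int]:
    d = X.shape[1]
    nbins = max((b.size for b in bounds), default=0) + 1
    codes = np.empty(X.shape, dtype=np.int64)
    for f in range(d):
        codes[:, f] = np.searchsorted(bounds[f], X[:, f], side="left")
    return codes, nbins


def _build_tree(codes, bounds, nbins, g, h, w, idx, depth, max_depth,
                min_gain=_EPS) -> dict:
    """Grow one regression tree on weighted gradients.

    Split gain is the weighted variance reduction of the least-squares fit to
    g; leaf values are a single Newton step  sum(w*g) / sum(w*h).  Ties are
    broken toward the lowest feature index, then the lowest threshold (argmax
    over a feature-major gain table returns exactly that).
    """
    wg, wh, wt = w[idx] * g[idx], w[idx] * h[idx], w[idx]
    G, W = wg.sum(), wt.sum()
    leaf = {"value": float(G / (wh.sum() + _EPS))}
    if depth >= max_depth or idx.size < 2:
        return leaf

    d = codes.shape[1]
    C = codes[idx]                                    # (n, d)
    offs = np.arange(d) * nbins
    flat = (C + offs).ravel()
    rep = np.repeat(wg, d), np.repeat(wh, d), np.repeat(wt, d)
    SG = np.bincount(flat, weights=rep[0], minlength=d * nbins).reshape(d, nbins)
    SH = np.bincount(flat, weights=rep[1], minlength=d * nbins).reshape(d, nbins)
    SW = np.bincount(flat, weights=rep[2], minlength=d * nbins).reshape(d, nbins)
    CG, CH, CW = SG.cumsum(1), SH.cumsum(1), SW.cumsum(1)

    # candidate k means "split at bounds[f][k]": left = codes <= k
    GL, WL = CG[:, :-1], CW[:, :-1]
    GR, WR = G - GL, W - WL
    nb = np.array([b.size for b in bounds])
    valid = (np.arange(nbins - 1)[None, :] < nb[:, None]) & (WL > 0) & (WR > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = GL**2 / np.maximum(WL, _EPS) + GR**2 / np.maximum(WR, _EPS) - G**2 / max(W, _EPS)
    gain = np.where(valid, gain, -np.inf)
    best = int(np.argmax(gain))
    f, k = divmod(best, nbins - 1)
    if not np.isfinite(gain[f, k]) or gain[f, k] <= min_gain:
        return leaf
    thr = float(bounds[f][k])
    go_left = codes[idx, f] <= k
    left = _build_tree(codes, bounds, nbins, g, h, w, idx[go_left],
                       depth + 1, max_depth, min_gain)
    right = _build_tree(codes, bounds, nbins, g, h, w, idx[~go_left],
                        depth + 1, max_depth, min_gain)
    return {"feature": int(f), "threshold": thr, "left": left, "right": right}


# ---------------------------------------------------------------------------
# GOSS & EFB


@dataclass(frozen=True)
class GossConfig:
    """GOSS parameters: keep the top ``a`` fraction by |gradient|, sample a
    ``b`` fraction of the remainder with compensating weight (1-a)/b."""

    a: float = 0.2
    b: float = 0.2

    def __post_init__(self):
        if not (0 <= self.a <= 1 and 0 <= self.b <= 1):
            raise ValueError("GOSS fractions a, b must lie in [0, 1]")
        if self.a + self.b > 1 + 1e-12:
            raise ValueError(f"GOSS fractions must satisfy a + b <= 1, got a={self.a}, b={self.b}")
        if self.b == 0 and self.a < 1:
            raise ValueError("GOSS requires b > 0 unless a == 1")


def goss_sample(gradients: Sequence[float], config: GossConfig,
                seed: int | np.random.Generator = 0) -> tuple[np.ndarray, np.ndarray]:
    """One-side sample by gradient magnitude.

    Returns (indices, weights): the ceil(a*n) largest-|gradient| rows with
    weight 1, plus ceil(b*n) uniformly sampled remaining rows with weight
    (1-a)/b.  Reproducible under a fixed seed.
    """
    g = np.asarray(gradients, dtype=float)
    if g.size == 0:
        raise ValueError("empty gradient vector")
    n = g.size
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if config.a >= 1.0:
        return np.arange(n), np.ones(n)
    n_top = int(np.ceil(config.a * n))
    order = np.argsort(-np.abs(g), kind="stable")
    top, rest = order[:n_top], order[n_top:]
    n_sample = min(int(np.ceil(config.b * n)), rest.size)
    sampled = rng.choice(rest, size=n_sample, replace=False) if n_sample else rest[:0]
    idx = np.concatenate([top, np.sort(sampled)])
    amp = (1.0 - config.a) / config.b if config.b > 0 else 1.0
    weights = np.concatenate([np.ones(n_top), np.full(n_sample, amp)])
    return idx, weights


@dataclass
class FeatureBundle:
    """A set of (nearly) mutually exclusive features merged into one column.

    ``offsets[i]`` shifts member i's nonzero values so members do not collide:
    the bundled value is ``offsets[i] + x_i`` for the first nonzero member
    (0 when all members are zero).
    """

    features: list[int] = field(default_factory=list)
    offsets: list[float] = field(default_factory=list)


def efb_bundle(X: np.ndarray, conflict_budget: int = 0) -> list[FeatureBundle]:
    """Greedy conflict-bounded exclusive feature bundling.

    Features are visited in descending nonzero count; each joins the first
    existing bundle whose accumulated conflict count (rows where both the
    feature and the bundle are nonzero) stays within ``conflict_budget``,
    otherwise it starts a new bundle.  Dense matrices degrade gracefully to
    singleton bundles.
    """
    X = np.asarray(X)
    if (X < 0).any():
        raise ValueError("EFB expects nonnegative (binary or sparse count) features")
    d = X.shape[1]
    nnz = (X != 0).sum(axis=0)
    order = np.argsort(-nnz, kind="stable")
    bundles: list[FeatureBundle] = []
    bundle_nz: list[np.ndarray] = []
    bundle_conflicts: list[int] = []
    for f in order:
        col_nz = X[:, f] != 0
        placed = False
        for bi, bz in enumerate(bundle_nz):
            conflicts = int(np.sum(col_nz & bz))
            if bundle_conflicts[bi] + conflicts <= conflict_budget:
                bundles[bi].features.append(int(f))
                bundle_nz[bi] = bz | col_nz
                bundle_conflicts[bi] += conflicts
                placed = True
                break
        if not placed:
            bundles.append(FeatureBundle(features=[int(f)]))
            bundle_nz.append(col_nz.copy())
            bundle_conflicts.append(0)
    for b in bundles:
        off = 0.0
        b.offsets = []
        for f in b.features:
            b.offsets.append(off)
            off += float(X[:, f].max())
    return bundles


def apply_bundles(X: np.ndarray, bundles: list[FeatureBundle]) -> np.ndarray:
    """Project X onto its bundled representation (one column per bundle)."""
    X = np.asarray(X, dtype=float)
    out = np.zeros((X.shape[0], len(bundles)))
    for j, b in enumerate(bundles):
        taken = np.zeros(X.shape[0], dtype=bool)
        for f, off in zip(b.features, b.offsets):
            nz = (X[:, f] != 0) & ~taken
            out[nz, j] = off + X[nz, f]
            taken |= nz
    return out


def reconstruct_from_bundles(Xb: np.ndarray, bundles: list[FeatureBundle],
                             n_features: int) -> np.ndarray:
    """Invert :func:`apply_bundles` (exact wherever no conflict occurred)."""
    X = np.zeros((Xb.shape[0], n_features))
    for j, b in enumerate(bundles):
        v = Xb[:, j]
        edges = np.array(b.offsets + [np.inf])
        for i, f in enumerate(b.features):
            mine = (v > edges[i]) & (v <= edges[i + 1] if np.isfinite(edges[i + 1]) else v > edges[i])
            X[mine, f] = v[mine] - edges[i]
    return X


# ---------------------------------------------------------------------------
# Models


@dataclass
class GBDTModel:
    """Stagewise additive model: sigmoid(base_score + lr * sum of tree outputs)."""

    trees: list[RegressionTree]
    learning_rate: float
    base_score: float
    n_features: int
    train_loss_curve: list[float] = field(default_factory=list)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(f"feature width mismatch: model expects {self.n_features}, got {X.shape[1]}")
        raw = np.full(X.shape[0], self.base_score)
        for t in self.trees:
            raw += self.learning_rate * t.predict(X)
        return raw

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        return _sigmoid(self.decision_function(X))

    # --- serialization -----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({
            "kind": type(self).__name__,
            "learning_rate": self.learning_rate,
            "base_score": self.base_score,
            "n_features": self.n_features,
            "trees": [t.root for t in self.trees],
            "train_loss_curve": self.train_loss_curve,
            **self._extra_json(),
        })

    def _extra_json(self) -> dict:
        return {}

    @classmethod
    def from_json(cls, s: str) -> "GBDTModel":
        d = json.loads(s)
        model_cls = GossGBMModel if d.get("kind") == "GossGBMModel" else GBDTModel
        m = model_cls(
            trees=[RegressionTree(r) for r in d["trees"]],
            learning_rate=d["learning_rate"],
            base_score=d["base_score"],
            n_features=d["n_features"],
            train_loss_curve=d.get("train_loss_curve", []),
        )
        if isinstance(m, GossGBMModel) and d.get("bundles") is not None:
            m.bundles = [FeatureBundle(features=b["features"], offsets=b["offsets"])
                         for b in d["bundles"]]
            m.n_raw_features = d["n_raw_features"]
        return m


@dataclass
class GossGBMModel(GBDTModel):
    """Histogram/GOSS booster; optionally predicts through EFB bundles."""

    bundles: list[FeatureBundle] | None = None
    n_raw_features: int | None = None

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.bundles is not None:
            if X.shape[1] != self.n_raw_features:
                raise ValueError(
                    f"feature width mismatch: model expects {self.n_raw_features}, got {X.shape[1]}")
            X = apply_bundles(X, self.bundles)
        return super().decision_function(X)

    def _extra_json(self) -> dict:
        if self.bundles is None:
            return {"bundles": None}
        return {
            "bundles": [{"features": b.features, "offsets": b.offsets} for b in self.bundles],
            "n_raw_features": self.n_raw_features,
        }


def _validate_xy(X, y, M):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y length mismatch")
    classes = np.unique(y)
    if not np.isin(classes, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    if classes.size < 2:
        raise ValueError("both classes must be present in y")
    if M < 0:
        raise ValueError("tree count M must be >= 0")
    return X, y


def _boost(X, y, M, depth, learning_rate, bounds, goss: GossConfig | None,
           rng: np.random.Generator | None):
    codes, nbins = _bin_codes(X, bounds)
    p_base = y.mean()
    base = float(np.log(p_base / (1 - p_base)))
    raw = np.full(y.size, base)
    trees, losses = [], [_log_loss(y, _sigmoid(raw))]
    for _ in range(M):
        p = _sigmoid(raw)
        g = y - p                       # negative gradient of logistic loss
        h = p * (1 - p)
        if goss is not None and goss.a < 1.0:
            idx_s, w_s = goss_sample(g, goss, rng)
            idx0 = idx_s
            w = np.zeros(y.size)
            w[idx_s] = w_s
            node_idx = np.sort(idx0)
        else:
            w = np.ones(y.size)
            node_idx = np.arange(y.size)
        root = _build_tree(codes, bounds, nbins, g, h, w, node_idx, 0, depth)
        tree = RegressionTree(root)
        raw += learning_rate * tree.predict(X)
        trees.append(tree)
        losses.append(_log_loss(y, _sigmoid(raw)))
    return trees, base, losses


def fit_gbdt(X, y, M: int = 100, depth: int = 3, learning_rate: float = 0.1) -> GBDTModel:
    """Fit a plain GBDT binary classifier with exact split search.

    ``M = 0`` yields the prior-only model (every score equals the sigmoid of
    the base log-odds of y).  Single-class y raises; an all-but-one-identical
    y is accepted and yields a prior-dominated model.
    """
    X, y = _validate_xy(X, y, M)
    if not (0 < learning_rate <= 1):
        raise ValueError("learning_rate must be in (0, 1]")
    bounds = _feature_boundaries(X, None)
    trees, base, losses = _boost(X, y, M, depth, learning_rate, bounds, None, None)
    return GBDTModel(trees=trees, learning_rate=learning_rate, base_score=base,
                     n_features=X.shape[1], train_loss_curve=losses)


def fit_goss_gbm(X, y, M: int = 100, depth: int = 3, learning_rate: float = 0.1,
                 goss: GossConfig | None = None, bins: int = 32,
                 seed: int = 0, use_efb: bool = False,
                 conflict_budget: int = 0) -> GossGBMModel:
    """Fit the histogram booster with GOSS subsampling (and optional EFB)."""
    X, y = _validate_xy(X, y, M)
    if bins < 2:
        raise ValueError("bins must be >= 2")
    goss = goss or GossConfig()
    rng = np.random.default_rng(seed)
    bundles = None
    n_raw = X.shape[1]
    Xt = X
    if use_efb:
        bundles = efb_bundle(X, conflict_budget)
        Xt = apply_bundles(X, bundles)
    bounds = _feature_boundaries(Xt, bins)
    trees, base, losses = _boost(Xt, y, M, depth, learning_rate, bounds, goss, rng)
    return GossGBMModel(trees=trees, learning_rate=learning_rate, base_score=base,
                        n_features=Xt.shape[1], train_loss_curve=losses,
                        bundles=bundles, n_raw_features=n_raw if use_efb else None)


def predict_score(model: GBDTModel, x) -> np.ndarray | float:
    """Score in (0, 1) for one sample or a matrix of samples."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    s = model.predict_score(x)
    return float(s[0]) if single else s
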