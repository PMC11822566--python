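"""Flexible neural tree (FNT) classifier.

An FNT is a typed tree built from two instruction sets: function instructions
``+_n`` (a *flexible neuron* with n children, n >= 2) and terminal
instructions ``x_i`` (input features).  A neuron with child outputs
x_1..x_n, weights w_1..w_n and activation parameters (a, b) computes

    o = sum_j w_j * x_j,        y = exp(-((o - a) / b)^2),

a Gaussian bump peaking at o = a with width |b|.  Because children may be
terminals at any depth, the topology realizes sparse cross-layer
connections; with inputs scaled to [0, 1] every neuron output lies in
(0, 1], so a 0.5 decision threshold is meaningful at the root.

The topology is searched by genetic programming (tournament selection,
subtree crossover, grow/prune/point mutation) and the continuous parameters
of the champion structure are tuned by global-best particle swarm
optimization (PSO); :func:`fit_fnt` alternates the two, never letting the
champion fitness worsen.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "FntNode",
    "FntModel",
    "eval_neuron",
    "eval_tree",
    "random_tree",
    "evolve_structure",
    "pso_minimize",
    "pso_optimize",
    "fit_fnt",
]

_MIN_B = 1e-6


@dataclass
class FntNode:
    """One instruction: a ``+_n`` flexible neuron or a terminal ``x_i``."""

    kind: str                       # "function" | "terminal"
    index: int = 0                  # terminal feature index
    weights: np.ndarray | None = None
    a: float = 0.0
    b: float = 1.0
    children: list["FntNode"] = field(default_factory=list)

    def __post_init__(self):
        if self.kind == "function":
            if len(self.children) < 2:
                raise ValueError("function node (+_n) requires arity n >= 2")
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.size != len(self.children):
                raise ValueError("function node needs one weight per child")
            if abs(self.b) < _MIN_B:
                raise ValueError("activation width b must be nonzero")
        elif self.kind != "terminal":
            raise ValueError(f"unknown node kind {self.kind!r}")

    def copy(self) -> "FntNode":
        if self.kind == "terminal":
            return FntNode("terminal", index=self.index)
        return FntNode("function", weights=self.weights.copy(), a=self.a, b=self.b,
                       children=[c.copy() for c in self.children])

    def depth(self) -> int:
        if self.kind == "terminal":
            return 0
        return 1 + max(c.depth() for c in self.children)

    def terminals(self) -> set[int]:
        if self.kind == "terminal":
            return {self.index}
        return set().union(*(c.terminals() for c in self.children))

    def function_nodes(self) -> list["FntNode"]:
        """Preorder list of function nodes (parameter-carrying nodes)."""
        if self.kind == "terminal":
            return []
        out = [self]
        for c in self.children:
            out.extend(c.function_nodes())
        return out

    def all_nodes(self) -> list["FntNode"]:
        out = [self]
        for c in self.children:
            out.extend(c.all_nodes())
        return out


def eval_neuron(weights: Sequence[float], inputs: Sequence[float],
                a: float, b: float) -> float | np.ndarray:
    """Gaussian flexible-neuron activation exp(-((sum w*x - a)/b)^2).

    Peaks at 1 when the weighted sum equals ``a``; always strictly positive.
    ``inputs`` may be a vector (one value per child) or a matrix of child
    output columns for vectorized evaluation.
    """
    if abs(b) < _MIN_B:
        raise ValueError("activation width b must be nonzero")
    w = np.asarray(weights, dtype=float)
    x = np.asarray(inputs, dtype=float)
    if x.ndim == 1:
        if w.size != x.size:
            raise ValueError("weights and inputs length mismatch")
        o = float(w @ x)
        return float(np.exp(-(((o - a) / b) ** 2)))
    o = x @ w
    return np.exp(-(((o - a) / b) ** 2))


def _eval_node(node: FntNode, X: np.ndarray) -> np.ndarray:
    if node.kind == "terminal":
        return X[:, node.index]
    cols = np.column_stack([_eval_node(c, X) for c in node.children])
    return eval_neuron(node.weights, cols, node.a, node.b)


@dataclass
class FntModel:
    """A complete flexible neural tree with its training fitness (MSE)."""

    root: FntNode
    input_width: int
    fitness: float = np.inf

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.input_width:
            raise ValueError(
                f"feature width mismatch: model expects {self.input_width}, got {X.shape[1]}")
        return _eval_node(self.root, X)

    def copy(self) -> "FntModel":
        return FntModel(self.root.copy(), self.input_width, self.fitness)

    # --- genome serialization ---------------------------------------------

    def to_json(self) -> str:
        def enc(n: FntNode):
            if n.kind == "terminal":
                return {"instruction": f"x{n.index}"}
            return {"instruction": f"+{len(n.children)}", "weights": n.weights.tolist(),
                    "a": n.a, "b": n.b, "children": [enc(c) for c in n.children]}
        return json.dumps({"input_width": self.input_width, "fitness": self.fitness,
                           "root": enc(self.root)})

    @classmethod
    def from_json(cls, s: str) -> "FntModel":
        d = json.loads(s)

        def dec(nd) -> FntNode:
            ins = nd["instruction"]
            if ins.startswith("x"):
                return FntNode("terminal", index=int(ins[1:]))
            return FntNode("function", weights=np.array(nd["weights"]),
                           a=nd["a"], b=nd["b"], children=[dec(c) for c in nd["children"]])
        return cls(dec(d["root"]), d["input_width"], d.get("fitness", np.inf))


def eval_tree(model: FntModel, x: Sequence[float]) -> float:
    """Score a single feature vector through the tree; in (0, 1] for a neuron
    root (and in [0, 1] for a bare-terminal root with [0, 1]-scaled inputs)."""
    x = np.asarray(x, dtype=float)
    return float(model.predict_score(x[None, :])[0])


# ---------------------------------------------------------------------------
# Random generation and genetic-programming structure search


def _rand_params(rng: np.random.Generator, n: int):
    w = rng.uniform(-1, 1, n)
    a = rng.uniform(0, 1)
    b = rng.uniform(0.1, 2.0)
    return w, a, b


def _distinct_terminals(rng, width, n):
    # direct siblings carry distinct feature indices when the width allows
    if n <= width:
        return rng.choice(width, size=n, replace=False)
    return rng.integers(0, width, size=n)


def random_tree(rng: np.random.Generator, width: int, max_depth: int = 4,
                max_arity: int = 5, p_terminal: float = 0.4) -> FntNode:
    """Grow a random FNT: neurons become more likely to close off with depth."""
    def grow(depth):
        if depth >= max_depth or (depth > 0 and rng.random() < p_terminal):
            return FntNode("terminal", index=int(rng.integers(width)))
        n = int(rng.integers(2, max_arity + 1))
        kids = []
        term_idx = iter(_distinct_terminals(rng, width, n))
        for _ in range(n):
            child = grow(depth + 1)
            if child.kind == "terminal":
                child.index = int(next(term_idx))
            kids.append(child)
        w, a, b = _rand_params(rng, n)
        return FntNode("function", weights=w, a=a, b=b, children=kids)
    root = grow(0)
    if root.kind == "terminal":     # ensure at least one neuron at the root
        n = int(rng.integers(2, max_arity + 1))
        idx = _distinct_terminals(rng, width, n)
        w, a, b = _rand_params(rng, n)
        root = FntNode("function", weights=w, a=a, b=b,
                       children=[FntNode("terminal", index=int(i)) for i in idx])
    return root


def _mse(root: FntNode, X, y) -> float:
    out = _eval_node(root, X)
    return float(np.mean((out - y) ** 2))


def _calibrate_params(root: FntNode, X, y, rng) -> None:
    """Draw random weights, then aim each neuron's Gaussian at the positive
    class: a is centered on the positives' weighted-sum distribution and b
    scaled to its spread (bottom-up, so child activations are current).

    A supervised initialization heuristic in the spirit of data-aware neural
    weight initialization: uniform-random (a, b) almost never produce an
    activation that varies with the label, leaving structure fitness blind.
    """
    def rec(node: FntNode) -> np.ndarray:
        if node.kind == "terminal":
            return X[:, node.index]
        cols = np.column_stack([rec(c) for c in node.children])
        node.weights = rng.uniform(-1, 1, len(node.children))
        o = cols @ node.weights
        pos = o[y == 1]
        ref = pos if pos.size else o
        node.a = float(ref.mean())
        node.b = float(max(ref.std() * rng.uniform(0.8, 1.6), 0.05))
        return np.exp(-(((o - node.a) / node.b) ** 2))
    rec(root)


def _memetic_mse(root: FntNode, X, y, rng, restarts: int) -> float:
    """Structure fitness: best MSE over the current parameters plus a few
    parameter re-draws — uniform-random and class-calibrated — keeping the
    winning draw on the tree.

    Without this, every topology scores near var(y) under arbitrary random
    parameters and the structure search cannot tell informative terminals
    from noise.
    """
    best = _mse(root, X, y)
    for r in range(restarts):
        saved = [(n.weights.copy(), n.a, n.b) for n in root.function_nodes()]
        if r % 2 == 0:
            _calibrate_params(root, X, y, rng)
        else:
            for n in root.function_nodes():
                n.weights, n.a, n.b = _rand_params(rng, len(n.children))
        f = _mse(root, X, y)
        if f < best:
            best = f
        else:
            for n, (w, a, b) in zip(root.function_nodes(), saved):
                n.weights, n.a, n.b = w, a, b
    return best


def _crossover(a: FntNode, b: FntNode, rng, max_depth) -> FntNode:
    child = a.copy()
    nodes = child.all_nodes()
    donor_nodes = b.all_nodes()
    for _ in range(8):          # retry until the depth budget holds
        target = nodes[int(rng.integers(len(nodes)))]
        donor = donor_nodes[int(rng.integers(len(donor_nodes)))].copy()
        saved = (target.kind, target.index, target.weights, target.a, target.b,
                 target.children)
        target.kind = donor.kind
        target.index = donor.index
        target.weights = donor.weights
        target.a, target.b = donor.a, donor.b
        target.children = donor.children
        if child.depth() <= max_depth and child.kind == "function":
            return child
        (target.kind, target.index, target.weights, target.a, target.b,
         target.children) = saved
    return child


def _mutate(root: FntNode, rng, width, max_depth, max_arity) -> FntNode:
    tree = root.copy()
    nodes = tree.all_nodes()
    node = nodes[int(rng.integers(len(nodes)))]
    op = rng.random()
    if node.kind == "terminal":
        if op < 0.5 and tree.depth() < max_depth:
            # grow: replace the terminal with a small neuron
            n = int(rng.integers(2, max_arity + 1))
            idx = _distinct_terminals(rng, width, n)
            w, a, b = _rand_params(rng, n)
            node.kind = "function"
            node.weights, node.a, node.b = w, a, b
            node.children = [FntNode("terminal", index=int(i)) for i in idx]
        else:
            node.index = int(rng.integers(width))
    else:
        if op < 0.4:
            # point mutation: re-randomize this neuron's parameters
            node.weights, node.a, node.b = _rand_params(rng, len(node.children))
        elif op < 0.7 and node is not tree:
            # prune: collapse the neuron to a terminal
            node.kind = "terminal"
            node.index = int(rng.integers(width))
            node.children = []
            node.weights = None
        else:
            # re-draw one child terminal index
            terms = [c for c in node.children if c.kind == "terminal"]
            if terms:
                t = terms[int(rng.integers(len(terms)))]
                t.index = int(rng.integers(width))
    return tree


def evolve_structure(dataset: tuple[np.ndarray, np.ndarray], population_size: int = 20,
                     generations: int = 10, seed: int = 0, *, max_depth: int = 4,
                     max_arity: int = 5, tournament: int = 3,
                     p_crossover: float = 0.6, param_restarts: int = 2) -> FntModel:
    """Genetic-programming search over FNT topologies.

    Fitness is the MSE between tree output and 0/1 labels; the champion is
    the best structure (with its parameters) ever seen, so best fitness is
    non-increasing across generations.  ``generations = 0`` returns the best
    tree of the random initial population.
    """
    if population_size < 2:
        raise ValueError("population_size must be >= 2")
    X = np.asarray(dataset[0], dtype=float)
    y = np.asarray(dataset[1], dtype=float).ravel()
    if np.unique(y).size < 2:
        raise ValueError("labeled dataset must contain both classes")
    width = X.shape[1]
    rng = np.random.default_rng(seed)
    pop = [random_tree(rng, width, max_depth, max_arity) for _ in range(population_size)]
    fits = np.array([_memetic_mse(t, X, y, rng, param_restarts) for t in pop])
    best_i = int(np.argmin(fits))
    champion, champ_fit = pop[best_i].copy(), float(fits[best_i])
    for _ in range(generations):
        new_pop = [champion.copy()]                   # elitism
        while len(new_pop) < population_size:
            def pick():
                c = rng.integers(population_size, size=tournament)
                return pop[c[int(np.argmin(fits[c]))]]
            if rng.random() < p_crossover:
                child = _crossover(pick(), pick(), rng, max_depth)
            else:
                child = _mutate(pick(), rng, width, max_depth, max_arity)
            new_pop.append(child)
        pop = new_pop
        fits = np.array([_memetic_mse(t, X, y, rng, param_restarts) for t in pop])
        i = int(np.argmin(fits))
        if fits[i] < champ_fit:
            champion, champ_fit = pop[i].copy(), float(fits[i])
    return FntModel(champion, width, champ_fit)


# ---------------------------------------------------------------------------
# PSO parameter optimization


def pso_minimize(fn: Callable[[np.ndarray], float], x0: np.ndarray,
                 swarm_size: int = 20, iterations: int = 100, seed: int = 0, *,
                 inertia: float = 0.7, cognitive: float = 1.5, social: float = 1.5,
                 init_spread: float = 1.0) -> tuple[np.ndarray, float, list[float]]:
    """Global-best PSO over a real vector; particle 0 starts at ``x0``.

    Returns (best position, best value, global-best trajectory).  The
    trajectory is non-increasing by construction.
    """
    x0 = np.asarray(x0, dtype=float)
    dim = x0.size
    rng = np.random.default_rng(seed)
    pos = x0 + rng.normal(0, init_spread, (swarm_size, dim))
    pos[0] = x0
    vel = rng.normal(0, 0.1 * init_spread, (swarm_size, dim))
    pbest = pos.copy()
    pbest_f = np.array([fn(p) for p in pos])
    gi = int(np.argmin(pbest_f))
    gbest, gbest_f = pbest[gi].copy(), float(pbest_f[gi])
    traj = [gbest_f]
    vmax = 4.0 * init_spread
    for _ in range(iterations):
        r1 = rng.random((swarm_size, dim))
        r2 = rng.random((swarm_size, dim))
        vel = inertia * vel + cognitive * r1 * (pbest - pos) + social * r2 * (gbest - pos)
        np.clip(vel, -vmax, vmax, out=vel)
        pos = pos + vel
        f = np.array([fn(p) for p in pos])
        better = f < pbest_f
        pbest[better] = pos[better]
        pbest_f[better] = f[better]
        gi = int(np.argmin(pbest_f))
        if pbest_f[gi] < gbest_f:
            gbest, gbest_f = pbest[gi].copy(), float(pbest_f[gi])
        traj.append(gbest_f)
    return gbest, gbest_f, traj


def _flatten_params(root: FntNode) -> np.ndarray:
    parts = []
    for n in root.function_nodes():         # preorder
        parts.append(n.weights)
        parts.append([n.a, n.b])
    return np.concatenate(parts) if parts else np.empty(0)


def _set_params(root: FntNode, vec: np.ndarray) -> None:
    i = 0
    for n in root.function_nodes():
        k = len(n.children)
        n.weights = vec[i:i + k].copy()
        i += k
        n.a = float(vec[i])
        b = float(vec[i + 1])
        n.b = b if abs(b) >= _MIN_B else (_MIN_B if b >= 0 else -_MIN_B)
        i += 2


def pso_optimize(model: FntModel, dataset: tuple[np.ndarray, np.ndarray],
                 swarm_size: int = 20, iterations: int = 100, seed: int = 0) -> FntModel:
    """Tune all weights and (a, b) of a fixed structure by global-best PSO.

    The incumbent parameters seed particle 0, so the returned fitness is
    never worse than the input's.  A bare-terminal tree (no parameters)
    is returned unchanged.
    """
    X = np.asarray(dataset[0], dtype=float)
    y = np.asarray(dataset[1], dtype=float).ravel()
    x0 = _flatten_params(model.root)
    if x0.size == 0 or iterations == 0:
        out = model.copy()
        out.fitness = _mse(out.root, X, y)
        return out
    work = model.root.copy()

    def objective(v):
        _set_params(work, v)
        return _mse(work, X, y)

    best, best_f, _ = pso_minimize(objective, x0, swarm_size, iterations, seed)
    out = model.copy()
    _set_params(out.root, best)
    out.fitness = best_f
    return out


def fit_fnt(X, y, *, population_size: int = 20, generations: int = 8,
            swarm_size: int = 16, pso_iterations: int = 30, rounds: int = 2,
            seed: int = 0, max_depth: int = 4, max_arity: int = 5) -> FntModel:
    """Alternate GP structure search and PSO parameter tuning.

    Each alternation round keeps the champion only if it improves, so the
    champion fitness is non-increasing across rounds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    champion = None
    for r in range(rounds):
        s1, s2 = int(rng.integers(2**31)), int(rng.integers(2**31))
        cand = evolve_structure((X, y), population_size, generations, s1,
                                max_depth=max_depth, max_arity=max_arity)
        cand = pso_optimize(cand, (X, y), swarm_size, pso_iterations, s2)
        if champion is None or cand.fitness < champion.fitness:
            champion = cand
    return champion
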