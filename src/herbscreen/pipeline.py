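"""End-to-end multi-source ensemble screening and herb ranking.

The pipeline trains each classifier family (plain GBDT, flexible neural
tree, GOSS histogram booster) once per data source (a component-derived
positive set and a target-derived positive set, each balanced with decoys
selected by minimal summed Tanimoto), screens an OB/DL-pre-filtered compound
library with every model, takes the union of actives per algorithm across
sources, counts how often each medicinal herb is annotated to an active
compound, keeps the top-k herbs per algorithm, and finally integrates the
per-algorithm lists: herbs present in at least ``min_count`` lists become
the candidate set.  Accuracy is the precision of that candidate set against
a reference herb list.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .boosting import GossConfig, fit_gbdt, fit_goss_gbm
from .chem import Compound, fingerprint_matrix
from .fnt import fit_fnt
from .negatives import select_negatives
from .tpe import TPESampler

logger = logging.getLogger("herbscreen")

__all__ = [
    "PipelineSettings",
    "EnsembleResult",
    "normalize_herb",
    "ob_dl_filter",
    "tpe_search",
    "screen",
    "herb_frequencies",
    "top_k",
    "integrate",
    "evaluate_accuracy",
    "run_pipeline",
]


def normalize_herb(name: str) -> str:
    """Case-fold and collapse whitespace so name variants merge."""
    return " ".join(name.strip().lower().split())


# ---------------------------------------------------------------------------
# Individual stages


def ob_dl_filter(library: Sequence[Compound], ob_min: float = 25.0,
                 dl_min: float = 0.15) -> list[Compound]:
    """Keep compounds with OB >= ob_min (percent) and DL >= dl_min, inclusive.

    Order is preserved.  Compounds missing either annotation make the filter
    ill-defined, so they raise with the offending ids listed.
    """
    missing = [c.id for c in library if c.ob is None or c.dl is None]
    if missing:
        raise ValueError(f"compounds missing OB/DL annotations: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    return [c for c in library if c.ob >= ob_min and c.dl >= dl_min]


def _cv_loss(backend: str, params: dict, X, y, seed: int, folds: int = 3) -> float:
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    losses = []
    for tr, te in skf.split(X, y):
        model = _fit_backend(backend, X[tr], y[tr], params, seed)
        p = np.clip(model.predict_score(X[te]), 1e-12, 1 - 1e-12)
        losses.append(float(-np.mean(y[te] * np.log(p) + (1 - y[te]) * np.log(1 - p))))
    return float(np.mean(losses))


def _fit_backend(backend: str, X, y, params: dict, seed: int):
    params = dict(params)
    if backend == "gbdt":
        return fit_gbdt(X, y, **params)
    if backend == "goss_gbm":
        goss = GossConfig(params.pop("goss_a", 0.2), params.pop("goss_b", 0.2))
        return fit_goss_gbm(X, y, goss=goss, seed=seed, **params)
    if backend == "fnt":
        return fit_fnt(X, y, seed=seed, **params)
    raise ValueError(f"unknown backend {backend!r}")


def tpe_search(backend: str, dataset: tuple[np.ndarray, np.ndarray], space: dict,
               n_trials: int, seed: int = 0) -> dict:
    """TPE hyperparameter search minimizing 3-fold cross-validated log loss.

    Trial 1 always evaluates the space's default configuration, so the
    returned configuration is never worse (in cv loss) than the default.
    Returns ``{"params", "cv_loss", "trials"}``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if backend not in ("gbdt", "goss_gbm"):
        raise ValueError("TPE search supports the boosted backends only")
    X = np.asarray(dataset[0], dtype=float)
    y = np.asarray(dataset[1], dtype=float).ravel()
    sampler = TPESampler(space, seed=seed)
    history: list[tuple[dict, float]] = []
    for _ in range(n_trials):
        params = sampler.suggest(history)
        loss = _cv_loss(backend, params, X, y, seed)
        history.append((params, loss))
    best = min(history, key=lambda h: h[1])
    return {"params": best[0], "cv_loss": best[1], "trials": history}


def screen(model, library: Sequence[Compound], threshold: float = 0.5) -> list[Compound]:
    """Score the library and keep compounds scoring strictly above threshold.

    Scores are attached to the returned compounds.  An empty library returns
    an empty list; a feature-width mismatch propagates from the model.
    """
    if not library:
        return []
    X = fingerprint_matrix([c.featurize() for c in library]).astype(float)
    scores = np.asarray(model.predict_score(X)).ravel()
    out = []
    for c, s in zip(library, scores):
        c.score = float(s)
        if s > threshold:
            out.append(c)
    return out


def herb_frequencies(actives: Sequence[Compound],
                     annotation: Mapping[str, set[str]]) -> dict[str, int]:
    """Count, per herb, how many active compounds are annotated to it.

    Every herb of a multi-herb compound gains one count, so the counts sum to
    the total annotation degree of the actives.  Unannotated actives are
    logged and skipped.
    """
    counts: Counter[str] = Counter()
    skipped = 0
    for c in actives:
        herbs = annotation.get(c.id)
        if not herbs:
            skipped += 1
            continue
        for h in herbs:
            counts[normalize_herb(h)] += 1
    if skipped:
        logger.info("herb_frequencies: %d active compounds without herb annotation", skipped)
    return dict(counts)


def top_k(table: Mapping[str, int], k: int = 20) -> list[tuple[str, int]]:
    """Herbs sorted by count descending, ties by name ascending; at most k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(table.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


def integrate(lists: Sequence[Sequence], min_count: int = 2) -> list[str]:
    """Herbs appearing in at least ``min_count`` of the given ranked lists.

    Accepts lists of herb names or of (name, count) pairs.  Ordered by the
    number of lists containing the herb (descending), ties by name.
    """
    if len(lists) < 2:
        raise ValueError("integration needs at least 2 lists")
    member: Counter[str] = Counter()
    for lst in lists:
        names = {normalize_herb(it[0] if isinstance(it, (tuple, list)) else it)
                 for it in lst}
        member.update(names)
    kept = [(h, n) for h, n in member.items() if n >= min_count]
    kept.sort(key=lambda kv: (-kv[1], kv[0]))
    return [h for h, _ in kept]


def evaluate_accuracy(candidates: Sequence[str], reference: set[str]) -> float:
    """Precision of the candidate herb list against the reference set."""
    if not candidates:
        raise ValueError("cannot evaluate an empty candidate list")
    ref = {normalize_herb(r) for r in reference}
    hits = sum(1 for c in candidates if normalize_herb(c) in ref)
    return hits / len(candidates)


# ---------------------------------------------------------------------------
# Full pipeline


@dataclass
class PipelineSettings:
    """Knobs of the full run; defaults follow the documented protocol
    (negative:positive ratio 2, OB >= 25 / DL >= 0.15, screen at 0.5,
    top-20 per algorithm, integration at membership >= 2)."""

    ratio: int = 2
    ob_min: float = 25.0
    dl_min: float = 0.15
    threshold: float = 0.5
    k: int = 20
    min_count: int = 2
    merge_sources: bool = True
    algorithms: tuple[str, ...] = ("gbdt", "fnt", "goss_gbm")
    seed: int = 0
    tpe_trials: int = 0
    gbdt_params: dict = field(default_factory=lambda: {
        "M": 60, "depth": 3, "learning_rate": 0.1})
    goss_params: dict = field(default_factory=lambda: {
        "M": 60, "depth": 3, "learning_rate": 0.1, "bins": 32,
        "goss_a": 0.2, "goss_b": 0.2})
    fnt_params: dict = field(default_factory=lambda: {
        "population_size": 20, "generations": 8, "swarm_size": 16,
        "pso_iterations": 30, "rounds": 2, "max_depth": 3, "max_arity": 5})
    tpe_space: dict = field(default_factory=lambda: {
        "M": {"low": 20, "high": 120, "type": "int", "default": 60},
        "depth": {"low": 2, "high": 4, "type": "int", "default": 3},
        "learning_rate": {"low": 0.02, "high": 0.5, "type": "logfloat", "default": 0.1},
    })


@dataclass
class EnsembleResult:
    """Per-algorithm frequency tables and top-k lists, the integrated
    candidate herbs, and precision against the reference set."""

    frequency_tables: dict[str, dict[str, int]]
    top_lists: dict[str, list[tuple[str, int]]]
    integrated: list[str]
    accuracy: float | None
    log: dict

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=1, default=str)


def _stage(name):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    return _Ctx()


def run_pipeline(inputs: dict, settings: PipelineSettings | None = None) -> EnsembleResult:
    """Run the full multi-source ensemble protocol.

    ``inputs`` follows :func:`herbscreen.synth.simulate_pipeline_inputs`:
    ``sources`` maps a source name to ``{"positives": [...], "decoys" or
    "negatives": [...]}``; plus ``library``, ``annotation`` and an optional
    ``reference`` herb set.  All randomness derives from ``settings.seed``.
    """
    settings = settings or PipelineSettings()
    log: dict = {"seed": settings.seed, "settings": {
        k: v for k, v in asdict(settings).items() if not isinstance(v, dict)}}

    with _stage("ob_dl_filter"):
        library = inputs["library"]
        if library and library[0].ob is not None:
            filtered = ob_dl_filter(library, settings.ob_min, settings.dl_min)
        else:
            filtered = list(library)
            log["ob_dl_filter"] = "skipped (library carries no OB/DL annotations)"
        log["library_size"] = len(library)
        log["library_after_ob_dl"] = len(filtered)

    with _stage("training_sets"):
        datasets = {}
        for sname, src in inputs["sources"].items():
            pos = src["positives"]
            if "negatives" in src:
                neg = src["negatives"]
            else:
                neg = select_negatives(pos, src["decoys"], settings.ratio)
            X = np.vstack([
                fingerprint_matrix([c.featurize() for c in pos]),
                fingerprint_matrix([c.featurize() for c in neg]),
            ]).astype(float)
            y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
            datasets[sname] = (X, y)
            log[f"dataset_{sname}"] = {"positives": len(pos), "negatives": len(neg)}

    annotation = inputs["annotation"]
    freq_tables: dict[str, dict[str, int]] = {}
    top_lists: dict[str, list[tuple[str, int]]] = {}
    active_sets: dict[str, dict[str, list[Compound]]] = {}

    for ai, algo in enumerate(settings.algorithms):
        active_sets[algo] = {}
        for si, (sname, (X, y)) in enumerate(datasets.items()):
            seed = int(np.random.SeedSequence(
                [settings.seed, ai, si]).generate_state(1)[0] % 2**31)
            with _stage(f"train[{algo}/{sname}]"):
                params = {"gbdt": settings.gbdt_params,
                          "goss_gbm": settings.goss_params,
                          "fnt": settings.fnt_params}[algo]
                if settings.tpe_trials > 0 and algo in ("gbdt", "goss_gbm"):
                    base = {k: v for k, v in params.items()
                            if k not in settings.tpe_space}
                    found = tpe_search(algo, (X, y), settings.tpe_space,
                                       settings.tpe_trials, seed)
                    params = {**base, **found["params"]}
                    log[f"tpe_{algo}_{sname}"] = {"params": found["params"],
                                                  "cv_loss": found["cv_loss"]}
                model = _fit_backend(algo, X, y, params, seed)
            with _stage(f"screen[{algo}/{sname}]"):
                actives = screen(model, filtered, settings.threshold)
                active_sets[algo][sname] = actives
                log[f"actives_{algo}_{sname}"] = len(actives)

        if settings.merge_sources:
            seen: dict[str, Compound] = {}
            for acts in active_sets[algo].values():
                for c in acts:
                    seen.setdefault(c.id, c)
            merged = list(seen.values())
            log[f"actives_{algo}_union"] = len(merged)
            log[f"active_ids_{algo}"] = sorted(seen)
            freq_tables[algo] = herb_frequencies(merged, annotation)
            top_lists[algo] = top_k(freq_tables[algo], settings.k)
        else:
            for sname, acts in active_sets[algo].items():
                key = f"{algo}:{sname}"
                freq_tables[key] = herb_frequencies(acts, annotation)
                top_lists[key] = top_k(freq_tables[key], settings.k)

    with _stage("integrate"):
        integrated = integrate(list(top_lists.values()), settings.min_count)
        log["integrated_size"] = len(integrated)

    accuracy = None
    reference = inputs.get("reference")
    if reference and integrated:
        with _stage("evaluate"):
            accuracy = evaluate_accuracy(integrated, set(reference))
            log["accuracy"] = accuracy

    return EnsembleResult(frequency_tables=freq_tables, top_lists=top_lists,
                          integrated=integrated, accuracy=accuracy, log=log)
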