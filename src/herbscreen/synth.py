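"""Synthetic benchmark generator with known ground truth.

Emulates every input of the screening pipeline at the feature-table level:

* **Actives** are bit-flip perturbations of a few random scaffold
  fingerprints, so compounds from one scaffold share high Tanimoto
  similarity (a crude but controllable stand-in for congeneric chemical
  series).
* **Decoys** are uniform-random fingerprints at popcounts matched to the
  actives, so they cannot be told apart by bit density alone and sit at low
  Tanimoto distance to every scaffold.
* The **screening library** mixes unseen actives (fresh perturbations of the
  same scaffolds) with fresh decoys and carries oral-bioavailability /
  drug-likeness annotations drawn so that a configurable fraction passes the
  OB >= 25 %, DL >= 0.15 pre-filter.
* The **herb annotation** maps library compounds to herb names; a planted
  subset of herbs is annotated mostly with active-derived compounds (at rate
  ``enrichment``), the rest mostly with decoys.  The planted herb names are
  the ground-truth reference set for recovery experiments.

Everything is driven by one integer seed and is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .chem import Compound, Fingerprint

__all__ = [
    "SimulationConfig",
    "simulate_compound_sets",
    "simulate_herb_annotation",
    "simulate_pipeline_inputs",
    "write_simulation",
]


@dataclass
class SimulationConfig:
    """Benchmark conditions.

    Defaults give a positive set of 124 compounds (4 scaffolds x 31) against
    a 1,000-decoy pool — the balanced-dataset worked-example sizes — plus a
    500-compound screening library and a 120-herb vocabulary of which 8 are
    planted.  ``bit_flip_rate = 0.25`` puts intra-scaffold Tanimoto around
    0.4–0.5 against a ~0.15 active–decoy background, the similarity regime
    where classifier families genuinely disagree on borderline compounds;
    ``background_rate`` is the database's annotation non-specificity (how
    often a non-planted herb contains an active-derived compound),
    deliberately decoupled from ``enrichment``.
    """

    n_scaffolds: int = 4
    actives_per_scaffold: int = 31
    n_decoys: int = 1000
    fingerprint_width: int = 256
    bit_flip_rate: float = 0.25
    n_herbs: int = 120
    n_planted_herbs: int = 8
    enrichment: float = 0.9
    background_rate: float = 0.03
    seed: int = 0
    # screening library composition
    n_library_actives: int = 160
    n_library_decoys: int = 340
    compounds_per_herb: int = 12
    ob_dl_pass_rate: float = 0.8
    scaffold_density: float = 0.25

    def __post_init__(self):
        if self.n_planted_herbs > self.n_herbs:
            raise ValueError("n_planted_herbs must be <= n_herbs")
        for p in (self.bit_flip_rate, self.enrichment, self.ob_dl_pass_rate,
                  self.scaffold_density, self.background_rate):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")
        popcount = int(round(self.scaffold_density * self.fingerprint_width))
        if not (0 < popcount < self.fingerprint_width):
            raise ValueError(
                f"infeasible popcount {popcount} for width {self.fingerprint_width}")


def _random_fp(rng, width, popcount) -> Fingerprint:
    popcount = int(np.clip(popcount, 0, width))
    return Fingerprint.from_on_bits(rng.choice(width, size=popcount, replace=False), width)


def _perturb(rng, scaffold_bits: np.ndarray, rate: float) -> Fingerprint:
    flips = rng.random(scaffold_bits.size) < rate
    return Fingerprint(np.where(flips, 1 - scaffold_bits, scaffold_bits).astype(np.uint8))


def simulate_compound_sets(config: SimulationConfig) -> tuple[list[Compound], list[Compound], list[Compound]]:
    """Generate (positives, decoy_pool, screening_library).

    Library compounds carry OB/DL annotations and a hidden ``label`` field
    (``active``/``inactive``) recording their ground-truth provenance; the
    pipeline itself never reads the label.
    """
    rng = np.random.default_rng(config.seed)
    w = config.fingerprint_width
    pop = int(round(config.scaffold_density * w))
    scaffolds = [_random_fp(rng, w, pop) for _ in range(config.n_scaffolds)]

    positives = []
    for s, sc in enumerate(scaffolds):
        for i in range(config.actives_per_scaffold):
            positives.append(Compound(
                id=f"act-s{s}-{i:03d}",
                fingerprint=_perturb(rng, sc.bits, config.bit_flip_rate),
                label="active"))

    # decoys at popcounts matched to the generated actives
    act_pops = np.array([c.fingerprint.popcount for c in positives])
    decoy_pool = [
        Compound(id=f"dec-{i:04d}",
                 fingerprint=_random_fp(rng, w, rng.choice(act_pops)),
                 label="inactive")
        for i in range(config.n_decoys)
    ]

    def annotate(c: Compound):
        if rng.random() < config.ob_dl_pass_rate:
            c.ob = float(rng.uniform(25, 100))
            c.dl = float(rng.uniform(0.15, 1.0))
        else:
            c.ob = float(rng.uniform(0, 25))
            c.dl = float(rng.uniform(0, 1.0))
        return c

    library = []
    for i in range(config.n_library_actives):
        s = int(rng.integers(config.n_scaffolds))
        library.append(annotate(Compound(
            id=f"lib-act-{i:04d}",
            fingerprint=_perturb(rng, scaffolds[s].bits, config.bit_flip_rate),
            label="active")))
    for i in range(config.n_library_decoys):
        library.append(annotate(Compound(
            id=f"lib-dec-{i:04d}",
            fingerprint=_random_fp(rng, w, rng.choice(act_pops)),
            label="inactive")))
    order = rng.permutation(len(library))
    library = [library[i] for i in order]
    return positives, decoy_pool, library


def simulate_herb_annotation(config: SimulationConfig,
                             screening_library: list[Compound]
                             ) -> tuple[dict[str, set[str]], set[str]]:
    """Generate (compound_id -> herb names mapping, planted reference set).

    Planted herbs draw their compounds from the active-derived part of the
    library with probability ``enrichment`` (decoy-derived otherwise).
    Non-planted herbs draw actives at the low ``background_rate`` —
    annotation specificity is a property of the database, distinct from how
    strongly the planted herbs are enriched — so they are annotated mostly
    with decoys.
    """
    rng = np.random.default_rng(config.seed + 1)
    herb_names = [f"herb-{i:03d}" for i in range(config.n_herbs)]
    planted = set(rng.choice(config.n_herbs, size=config.n_planted_herbs, replace=False).tolist())
    actives = [c.id for c in screening_library if c.label == "active"]
    decoys = [c.id for c in screening_library if c.label != "active"]
    annotation: dict[str, set[str]] = {}
    for hi, herb in enumerate(herb_names):
        rate = config.enrichment if hi in planted else config.background_rate
        chosen: set[str] = set()
        guard = 0
        while len(chosen) < min(config.compounds_per_herb,
                                len(actives) + len(decoys)) and guard < 10000:
            guard += 1
            pool = actives if (rng.random() < rate and actives) else decoys
            if not pool:
                pool = actives or decoys
            chosen.add(pool[int(rng.integers(len(pool)))])
        for cid in chosen:
            annotation.setdefault(cid, set()).add(herb)
    reference = {herb_names[i] for i in planted}
    return annotation, reference


def simulate_pipeline_inputs(config: SimulationConfig) -> dict:
    """Bundle a full two-source pipeline input set.

    The positives are split by scaffold parity into a "component"-style
    source and a "target"-style source, mirroring a pipeline trained on a
    literature-derived component set plus target-derived compound sets.
    """
    positives, decoy_pool, library = simulate_compound_sets(config)
    annotation, reference = simulate_herb_annotation(config, library)
    comp = [c for c in positives if int(c.id.split("-s")[1][0]) % 2 == 0]
    targ = [c for c in positives if int(c.id.split("-s")[1][0]) % 2 == 1]
    half = len(decoy_pool) // 2
    return {
        "sources": {
            "component": {"positives": comp, "decoys": decoy_pool[:half]},
            "target": {"positives": targ, "decoys": decoy_pool[half:]},
        },
        "library": library,
        "annotation": annotation,
        "reference": reference,
        "config": config,
    }


def write_simulation(config: SimulationConfig, outdir) -> None:
    """Write the simulated inputs as plain-text CSVs plus reference.txt."""
    import pandas as pd
    from .chem import write_fingerprint_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    positives, decoys, library = simulate_compound_sets(config)
    annotation, reference = simulate_herb_annotation(config, library)
    w = config.fingerprint_width
    write_fingerprint_csv(positives, outdir / "positives.csv", width=w)
    write_fingerprint_csv(decoys, outdir / "decoys.csv", width=w)
    write_fingerprint_csv(library, outdir / "library.csv", width=w)
    rows = [{"compound_id": cid, "herb": h}
            for cid, herbs in sorted(annotation.items()) for h in sorted(herbs)]
    pd.DataFrame(rows).to_csv(outdir / "annotation.csv", index=False)
    (outdir / "reference.txt").write_text("\n".join(sorted(reference)) + "\n")
    import json
    (outdir / "sim_config.json").write_text(json.dumps(asdict(config), indent=1))
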