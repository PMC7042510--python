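"""Synthetic two-group expression data with planted ceRNA triples.

The generator emulates the study design the pipeline assumes: a 3-vs-3
control/stretch contrast measured on log2 scale, with a subset of
lncRNA-miRNA-mRNA triples carrying the ceRNA signature.  For a planted
triple the lncRNA is shifted by ``effect_delta`` (log2 units, negative
for stretch-induced loss) in the stretch group, the miRNA tracks the
lncRNA negatively with strength ``coupling_beta`` (so it shifts up and
anticorrelates within groups), and the mRNA tracks the miRNA negatively
in turn (net shift ``beta^2 * delta``, same sign as the lncRNA).
Non-planted genes are pure noise around gene-specific baselines drawn
uniformly in [4, 14] log2 units.  The interaction table contains the
planted edges plus Bernoulli decoy edges over every non-planted
(miRNA, target) pair.

Everything is reproducible from one integer seed; per-stage substreams
are derived from it deterministically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, Interaction, InteractionSet
from . import reference_tables


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic dataset.

    Defaults are the planted-recovery conditions exercised throughout
    the test-suite: 50 lncRNAs, 100 miRNAs, 200 mRNAs, 20 planted
    triples, a -2 log2-unit stretch effect on planted lncRNAs, coupling
    0.8, residual sd 0.3 log2 units, decoy edge rate 0.02, 3 samples
    per group.
    """

    n_lnc: int = 50
    n_mir: int = 100
    n_mrna: int = 200
    samples_per_group: int = 3
    n_triples: int = 20
    effect_delta: float = -2.0
    coupling_beta: float = 0.8
    noise_sd: float = 0.3
    decoy_edge_rate: float = 0.02
    k_planted: int = 1  # shared miRNAs per planted triple
    count_scale: bool = False  # emit Poisson counts around 2^log2 value
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_lnc", "n_mir", "n_mrna", "samples_per_group",
                     "n_triples", "k_planted"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be positive")
        if self.n_triples > min(self.n_lnc, self.n_mrna):
            raise ValueError("config field n_triples exceeds available "
                             "lncRNAs or mRNAs")
        if self.n_triples * self.k_planted > self.n_mir:
            raise ValueError("config field k_planted: not enough miRNAs "
                             "for disjoint planted sets")
        if self.noise_sd <= 0:
            raise ValueError("config field noise_sd must be positive")
        if not (0 <= self.coupling_beta <= 1):
            raise ValueError("config field coupling_beta must lie in [0, 1]")
        if not (0 <= self.decoy_edge_rate <= 1):
            raise ValueError("config field decoy_edge_rate must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Planted triples with their expected directions, plus a config echo."""

    triples: list[tuple[str, tuple[str, ...], str]]  # (lnc, mirs, mrna)
    directions: dict[str, str] = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return {(lnc, mrna) for lnc, _, mrna in self.triples}

    def to_json(self, path: str | Path) -> None:
        payload = {"seed": self.seed, "config": self.config,
                   "directions": self.directions,
                   "triples": [[l, list(u), m] for l, u, m in self.triples]}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(triples=[(l, tuple(u), m)
                            for l, u, m in payload["triples"]],
                   directions=payload["directions"],
                   config=payload["config"], seed=payload["seed"])


def generate_dataset(config: GeneratorConfig
                     ) -> tuple[ExpressionMatrix, InteractionSet, GroundTruth]:
    """Draw one synthetic dataset: expression, interactions, ground truth."""
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(4)
    rng_mean, rng_plant, rng_noise, rng_decoy = \
        (np.random.default_rng(s) for s in streams)

    lncs = [f"lnc{i:04d}" for i in range(config.n_lnc)]
    mirs = [f"mir{i:04d}" for i in range(config.n_mir)]
    mrnas = [f"mrna{i:04d}" for i in range(config.n_mrna)]
    genes = lncs + mirs + mrnas
    n = config.samples_per_group
    samples = [f"control_{i+1}" for i in range(n)] + \
        [f"stretch_{i+1}" for i in range(n)]
    stretch_ind = np.r_[np.zeros(n), np.ones(n)]

    mu = pd.Series(rng_mean.uniform(4.0, 14.0, len(genes)), index=genes)

    # choose planted genes; miRNA blocks are disjoint across triples
    p_lnc = list(rng_plant.choice(lncs, config.n_triples, replace=False))
    p_mrna = list(rng_plant.choice(mrnas, config.n_triples, replace=False))
    mir_pool = list(rng_plant.choice(
        mirs, config.n_triples * config.k_planted, replace=False))
    triples = []
    for i in range(config.n_triples):
        block = tuple(mir_pool[i * config.k_planted:(i + 1) * config.k_planted])
        triples.append((p_lnc[i], block, p_mrna[i]))

    values = pd.DataFrame(
        mu.to_numpy()[:, None] +
        rng_noise.normal(0.0, config.noise_sd, (len(genes), 2 * n)),
        index=genes, columns=samples)
    for lnc, block, mrna in triples:
        lnc_vals = mu[lnc] + config.effect_delta * stretch_ind + \
            rng_noise.normal(0.0, config.noise_sd, 2 * n)
        values.loc[lnc] = lnc_vals
        lnc_dev = lnc_vals - mu[lnc]
        mir_dev_sum = np.zeros(2 * n)
        for mir in block:
            mir_vals = mu[mir] - config.coupling_beta * lnc_dev + \
                rng_noise.normal(0.0, config.noise_sd, 2 * n)
            values.loc[mir] = mir_vals
            mir_dev_sum += mir_vals - mu[mir]
        mrna_vals = mu[mrna] - config.coupling_beta * \
            (mir_dev_sum / len(block)) + \
            rng_noise.normal(0.0, config.noise_sd, 2 * n)
        values.loc[mrna] = mrna_vals

    # interaction table: planted edges plus decoys over non-planted pairs
    planted_edges: set[tuple[str, str, str]] = set()
    for lnc, block, mrna in triples:
        for mir in block:
            planted_edges.add((mir, lnc, "lncRNA"))
            planted_edges.add((mir, mrna, "mRNA"))
    edges = {Interaction(m, t, b, "planted") for m, t, b in planted_edges}
    targets = [(t, "lncRNA") for t in lncs] + [(t, "mRNA") for t in mrnas]
    draw = rng_decoy.random((len(mirs), len(targets)))
    for i, mir in enumerate(mirs):
        for j, (t, b) in enumerate(targets):
            if (mir, t, b) in planted_edges:
                continue
            if draw[i, j] < config.decoy_edge_rate:
                edges.add(Interaction(mir, t, b, "decoy"))
    interactions = InteractionSet(frozenset(edges))

    biotype = pd.Series({g: ("lncRNA" if g in set(lncs) else
                             "miRNA" if g in set(mirs) else "mRNA")
                         for g in genes}, name="biotype")
    group = pd.Series({s: ("stretch" if s.startswith("stretch") else
                           "control") for s in samples}, name="group")
    if config.count_scale:
        counts = rng_noise.poisson(np.power(2.0, values.to_numpy()))
        values = pd.DataFrame(counts.astype(float), index=genes,
                              columns=samples)
    matrix = ExpressionMatrix(values, biotype, group)

    sign = "Down" if config.effect_delta < 0 else "Up"
    anti = "Up" if sign == "Down" else "Down"
    directions = {}
    for lnc, block, mrna in triples:
        directions[lnc] = sign
        directions[mrna] = sign
        for mir in block:
            directions[mir] = anti
    truth = GroundTruth(triples=triples, directions=directions,
                        config=asdict(config), seed=config.seed)
    return matrix, interactions, truth


def recovery_metrics(inferred: pd.DataFrame,
                     truth: GroundTruth) -> dict[str, float]:
    """True-positive rate and false-discovery proportion of inferred pairs.

    ``tpr`` = recovered planted (lncRNA, mRNA) pairs / planted pairs;
    ``fdp`` = non-planted among inferred / max(1, inferred).  An empty
    inference yields tpr 0 and fdp 0 by convention.
    """
    planted = truth.pairs
    if inferred.empty:
        inferred_pairs: set[tuple[str, str]] = set()
    else:
        inferred_pairs = set(zip(inferred["lncrna"], inferred["mrna"]))
    tp = len(inferred_pairs & planted)
    return {"tpr": tp / len(planted) if planted else 0.0,
            "false_discovery_proportion":
                len(inferred_pairs - planted) / max(1, len(inferred_pairs)),
            "n_inferred": float(len(inferred_pairs))}


def write_fixture_tables(out_dir: str | Path) -> dict[str, Path]:
    """Write the bundled reference tables as byte-stable TSV files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {
        "de_lncrna": ("reference_de_lncrna.tsv",
                      reference_tables.DE_LNCRNA_TSV),
        "de_mirna": ("reference_de_mirna.tsv",
                     reference_tables.DE_MIRNA_TSV),
        "de_mrna": ("reference_de_mrna.tsv",
                    reference_tables.DE_MRNA_TSV),
        "degrees": ("reference_degrees.tsv",
                    reference_tables.DEGREES_TSV),
    }
    out = {}
    for key, (name, payload) in files.items():
        path = out_dir / name
        path.write_text(payload)
        out[key] = path
    return out
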