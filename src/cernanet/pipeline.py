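"""Config-driven orchestration of the full ceRNA analysis chain.

simulate/ingest -> differential expression -> ceRNA pair inference ->
tripartite network, hubs and subnetworks -> optional enrichment.  Every
run writes a JSON manifest recording the package version, seed, the
thresholds in force and per-stage row counts, so a run is reproducible
and self-describing: identical config + seed gives identical manifests.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .core_io import (read_expression_table, read_interaction_table,
                      read_gmt, write_network, write_interaction_table,
                      write_expression_table)
from .diffexpr import (normalize_log2, differential_expression,
                       apply_de_filter, write_de_table)
from .cerna import directional_candidates, infer_cerna_pairs
from .network import (build_network, node_degrees, top_hubs,
                      extract_subnetwork, network_summary)
from .enrichment import ora, top_terms
from .synthetic import GeneratorConfig, generate_dataset

logger = logging.getLogger("cernanet")


@dataclass
class PipelineConfig:
    """Fully defaulted run configuration; every field lands in the manifest."""

    # either a simulation block or explicit input paths
    simulate: dict | None = None
    expression: str | None = None
    design: str | None = None
    biotypes: str | None = None
    interactions: str | None = None
    normalize: bool = False  # raw counts in, CPM + log2(x+1) applied
    pseudocount: float = 1.0
    # DE gate
    fc_threshold: float = 1.5
    p_threshold: float = 0.05
    use_fdr: bool = False
    welch: bool = False
    # ceRNA gate
    orientation: str = "both"
    hypergeom_p: float = 0.01
    min_shared: int = 1
    require_positive_corr: bool = False
    corr_p: float = 0.05
    min_senscor: float | None = None
    # network reporting
    hub_top: int = 20
    min_degree: int = 5
    subnetwork_centers: list[str] = field(default_factory=list)
    # enrichment
    gmt: str | None = None
    enrich_background: str | None = None
    enrich_top: int = 10
    enrich_max_fdr: float = 1.0
    # bookkeeping
    out_dir: str = "cerna_run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.simulate is None:
            needed = {"expression": self.expression, "design": self.design,
                      "biotypes": self.biotypes,
                      "interactions": self.interactions}
            for name, p in needed.items():
                if p is None:
                    raise ValueError(f"config needs either a simulate block "
                                     f"or an input path for {name!r}")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name} file not found: {p}")
        for name in ("gmt", "enrich_background"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")


def _read_two_column_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep=None, engine="python", header=None,
                     comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns")
    first = df.iloc[0]
    if first[1] not in ("control", "stretch", "lncRNA", "miRNA", "mRNA"):
        df = df.iloc[1:]  # header row
    return {str(k).strip(): str(v).strip()
            for k, v in zip(df.iloc[:, 0], df.iloc[:, 1])}


def _setup_logging(out_dir: Path) -> None:
    root = logging.getLogger("cernanet")
    root.setLevel(logging.INFO)
    have = {getattr(h, "_cerna_tag", None) for h in root.handlers}
    if "stderr" not in have:
        h = logging.StreamHandler(sys.stderr)
        h._cerna_tag = "stderr"
        h.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        root.addHandler(h)
    fh = logging.FileHandler(out_dir / "run.log", mode="w")
    fh._cerna_tag = "logfile"
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root.handlers = [h for h in root.handlers
                     if getattr(h, "_cerna_tag", None) != "logfile"]
    root.addHandler(fh)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full chain and return the manifest (also written to disk)."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(out_dir)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config": {k: v for k, v in asdict(config).items()}}

    # --- ingest or simulate -------------------------------------------------
    if config.simulate is not None:
        sim = GeneratorConfig(**{**config.simulate, "seed": config.seed})
        matrix, interactions, truth = generate_dataset(sim)
        truth.to_json(out_dir / "truth.json")
        write_expression_table(matrix, out_dir / "expr.tsv")
        write_interaction_table(interactions, out_dir / "interactions.tsv")
        logger.info("simulated dataset: %d genes x %d samples, %d edges",
                    len(matrix.gene_ids), len(matrix.samples),
                    len(interactions))
    else:
        design = _read_two_column_map(config.design)
        biotypes = _read_two_column_map(config.biotypes)
        matrix = read_expression_table(config.expression, design, biotypes)
        interactions = read_interaction_table(config.interactions)
    if config.normalize:
        matrix = normalize_log2(matrix, pseudocount=config.pseudocount)

    manifest["detected"] = {bt: len(matrix.genes_of(bt))
                            for bt in ("lncRNA", "miRNA", "mRNA")}

    # --- differential expression -------------------------------------------
    de = differential_expression(matrix, welch=config.welch)
    filtered = apply_de_filter(de, config.fc_threshold, config.p_threshold,
                               config.use_fdr)
    de_counts = {}
    per_biotype = {}
    for bt, tag in (("lncRNA", "lnc"), ("miRNA", "mir"), ("mRNA", "mrna")):
        sub = filtered[filtered["biotype"] == bt]
        write_de_table(sub, out_dir / f"de_{tag}.tsv")
        per_biotype[bt] = sub
        up = int((sub["direction"] == "Up").sum())
        down = int((sub["direction"] == "Down").sum())
        de_counts[bt] = {"up": up, "down": down, "total": len(sub)}
    manifest["differential_expression"] = de_counts
    logger.info("DE filter (FC>=%.2f, P<=%.3g): %s", config.fc_threshold,
                config.p_threshold,
                {bt: c["total"] for bt, c in de_counts.items()})

    # --- ceRNA inference ----------------------------------------------------
    candidates = directional_candidates(per_biotype["lncRNA"],
                                        per_biotype["miRNA"],
                                        per_biotype["mRNA"], interactions,
                                        orientation=config.orientation)
    pairs = infer_cerna_pairs(
        candidates, interactions, matrix=matrix,
        hypergeom_p=config.hypergeom_p, min_shared=config.min_shared,
        require_positive_corr=config.require_positive_corr,
        corr_p=config.corr_p, min_senscor=config.min_senscor)
    pairs.to_csv(out_dir / "pairs.tsv", sep="\t", index=False)
    manifest["cerna"] = {"candidate_triples": len(candidates),
                         "pairs": len(pairs)}

    # --- network ------------------------------------------------------------
    if pairs.empty:
        manifest["network"] = {"n_lncrna": 0, "n_mirna": 0, "n_mrna": 0,
                               "n_edges": 0}
        manifest["hubs"] = []
        manifest["subnetworks"] = {}
    else:
        net = build_network(pairs)
        write_network(net, out_dir / "net.graphml", "GraphML")
        write_network(net, out_dir / "net.sif", "SIF")
        degrees = node_degrees(net)
        degrees.to_csv(out_dir / "degrees.tsv", sep="\t", index=False)
        hubs = top_hubs(degrees, k=config.hub_top,
                        min_degree=config.min_degree)
        hubs.to_csv(out_dir / "hubs.tsv", sep="\t", index=False)
        manifest["network"] = network_summary(net)
        manifest["hubs"] = hubs.to_dict("records")
        manifest["subnetworks"] = {}
        for center in config.subnetwork_centers:
            sub = extract_subnetwork(net, center)
            write_network(sub, out_dir / f"subnetwork_{center}.graphml",
                          "GraphML")
            manifest["subnetworks"][center] = network_summary(sub)

    # --- enrichment ---------------------------------------------------------
    if config.gmt is not None:
        collection = read_gmt(config.gmt)
        if pairs.empty:
            manifest["enrichment"] = {"terms_tested": 0, "terms_reported": 0}
        else:
            query = set(pairs["mrna"])
            if config.enrich_background is not None:
                background = {line.strip() for line in
                              Path(config.enrich_background
                                   ).read_text().splitlines() if line.strip()}
            else:
                background = collection.all_members | query
            rows = ora(query, collection, background)
            rows.to_csv(out_dir / "enrich.tsv", sep="\t", index=False)
            best = top_terms(rows, top_k=config.enrich_top,
                             max_fdr=config.enrich_max_fdr)
            manifest["enrichment"] = {"terms_tested": len(rows),
                                      "terms_reported": len(best)}

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline complete; outputs in %s", out_dir)
    return manifest
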