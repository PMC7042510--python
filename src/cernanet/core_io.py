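"""Domain containers and file IO for the ceRNA analysis pipeline.

The pipeline works on three RNA classes — lncRNA, miRNA and mRNA — measured
in a two-group design (unstretched control endothelial cells vs. cells under
cyclic stretch).  This module defines the in-memory containers
(:class:`ExpressionMatrix`, :class:`InteractionSet`,
:class:`GeneSetCollection`) and the readers/writers for the plain-text
formats the pipeline touches: TSV/CSV expression tables, typed
miRNA-target interaction tables, GMT gene-set files, and SIF/GraphML
network exports.

All identifier matching is exact after whitespace trimming; case is
preserved, because expression tables in this domain mix Ensembl accessions
with gene symbols and silent case-folding could merge distinct genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("cernanet")

BIOTYPES = ("lncRNA", "miRNA", "mRNA")
GROUPS = ("control", "stretch")

#: biotype sort order used by every deterministic tie-break in the package
BIOTYPE_ORDER = {"lncRNA": 0, "miRNA": 1, "mRNA": 2}


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with group design and biotypes.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, one column per sample.  Units are
        log2-normalized expression unless the producer says otherwise.
    biotype
        Series mapping every gene id in ``values.index`` to one of
        ``lncRNA``, ``miRNA``, ``mRNA``.
    group
        Series mapping every sample in ``values.columns`` to ``control``
        or ``stretch``.
    """

    values: pd.DataFrame
    biotype: pd.Series
    group: pd.Series

    def __post_init__(self) -> None:
        self.values.index = self.values.index.astype(str).str.strip()
        dup = self.values.index[self.values.index.duplicated()].unique()
        if len(dup):
            raise ValueError(f"duplicate gene ids: {sorted(dup)}")
        self.biotype = self.biotype.reindex(self.values.index)
        if self.biotype.isna().any():
            missing = self.biotype.index[self.biotype.isna()].tolist()
            raise ValueError(f"genes without biotype: {missing[:5]}")
        bad = set(self.biotype) - set(BIOTYPES)
        if bad:
            raise ValueError(f"unknown biotypes: {sorted(bad)}")
        self.group = self.group.reindex(self.values.columns)
        if self.group.isna().any():
            missing = self.group.index[self.group.isna()].tolist()
            raise ValueError(f"samples without group: {missing}")
        badg = set(self.group) - set(GROUPS)
        if badg:
            raise ValueError(f"unknown groups: {sorted(badg)}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.group[s] == group]

    def genes_of(self, biotype: str) -> list[str]:
        return [g for g in self.values.index if self.biotype[g] == biotype]

    def subset_biotype(self, biotype: str) -> "ExpressionMatrix":
        genes = self.genes_of(biotype)
        return ExpressionMatrix(self.values.loc[genes].copy(),
                                self.biotype.loc[genes].copy(),
                                self.group.copy())


@dataclass(frozen=True)
class Interaction:
    """One typed miRNA-target edge (miRNA represses the target)."""

    mirna: str
    target: str
    target_biotype: str  # "lncRNA" or "mRNA"
    source: str = ""


@dataclass
class InteractionSet:
    """Deduplicated miRNA-target pairs with target biotype.

    Targets are either lncRNAs (sponge candidates) or mRNAs (repressed
    messengers).  Biotype must be consistent per target id.
    """

    pairs: frozenset[Interaction]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for p in self.pairs:
            if p.target_biotype not in ("lncRNA", "mRNA"):
                raise ValueError(
                    f"target biotype must be lncRNA or mRNA, got "
                    f"{p.target_biotype!r} for {p.target}")
            prev = seen.setdefault(p.target, p.target_biotype)
            if prev != p.target_biotype:
                raise ValueError(
                    f"conflicting biotype for target {p.target!r}: "
                    f"{prev} vs {p.target_biotype}")
        self._mirnas_of: dict[str, set[str]] = {}
        self._targets_of: dict[str, set[tuple[str, str]]] = {}
        for p in self.pairs:
            self._mirnas_of.setdefault(p.target, set()).add(p.mirna)
            self._targets_of.setdefault(p.mirna, set()).add(
                (p.target, p.target_biotype))

    def __len__(self) -> int:
        return len(self.pairs)

    def mirnas_of(self, target: str) -> set[str]:
        """miRNAs interacting with a given lncRNA or mRNA."""
        return set(self._mirnas_of.get(target, set()))

    def targets_of(self, mirna: str, biotype: str | None = None) -> set[str]:
        out = self._targets_of.get(mirna, set())
        if biotype is None:
            return {t for t, _ in out}
        return {t for t, b in out if b == biotype}

    @property
    def mirna_universe(self) -> set[str]:
        """All miRNAs appearing in at least one pair (default background)."""
        return set(self._targets_of)

    @classmethod
    def from_tuples(cls, rows: Iterable[tuple]) -> "InteractionSet":
        return cls(frozenset(Interaction(*r) for r in rows))


@dataclass
class GeneSetCollection:
    """Term id -> (term name, unique member gene ids)."""

    sets: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {term!r} is empty")
            if len(set(members)) != len(members):
                raise ValueError(f"gene set {term!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, term: str) -> set[str]:
        return set(self.sets[term][1])

    @property
    def all_members(self) -> set[str]:
        out: set[str] = set()
        for _, members in self.sets.values():
            out.update(members)
        return out


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

def _sniff_sep(header: str) -> str:
    # tab preferred; fall back to comma
    return "\t" if "\t" in header else ","


def read_expression_table(path: str | Path,
                          design: Mapping[str, str],
                          biotypes: Mapping[str, str]) -> ExpressionMatrix:
    """Read a genes x samples table and attach design and biotype metadata.

    The file must have a header row of sample ids and a first column of
    gene ids; separator (tab or comma) is sniffed from the header.  Genes
    absent from ``biotypes`` are dropped with a logged count; a sample
    absent from ``design`` is an error.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = _sniff_sep(header)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str).str.strip()
    df.columns = [str(c).strip() for c in df.columns]

    dup = df.index[df.index.duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicate gene ids in {path.name}: {sorted(dup)}")
    for s in df.columns:
        if s not in design:
            raise ValueError(f"sample {s!r} missing from the design map")

    values = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                values.iloc[i, j] = float(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric cell at gene {df.index[i]!r}, "
                    f"sample {col!r}: {raw!r}") from None

    biotypes = {str(k).strip(): v for k, v in biotypes.items()}
    known = [g for g in values.index if g in biotypes]
    dropped = len(values) - len(known)
    if dropped:
        logger.info("read_expression_table: dropped %d genes with no "
                    "biotype assignment", dropped)
    values = values.loc[known]
    biotype = pd.Series({g: biotypes[g] for g in known}, name="biotype")
    group = pd.Series({s: design[s] for s in values.columns}, name="group")
    return ExpressionMatrix(values, biotype, group)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# interaction tables
# ---------------------------------------------------------------------------

def read_interaction_table(path: str | Path) -> InteractionSet:
    """Read a typed miRNA-target TSV/CSV: mirna, target, target_biotype[, source].

    Rows are deduplicated; an unknown biotype string or a target labelled
    with two different biotypes is an error.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise ValueError(f"interaction table {path.name} is empty")
    sep = _sniff_sep(header)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty:
        raise ValueError(f"interaction table {path.name} has no rows")
    required = ["mirna", "target", "target_biotype"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"interaction table missing columns: {missing}")
    rows = []
    for _, r in df.iterrows():
        bt = str(r["target_biotype"]).strip()
        if bt not in ("lncRNA", "mRNA"):
            raise ValueError(f"unknown target biotype {bt!r} for "
                             f"target {r['target']!r}")
        src = str(r["source"]).strip() if "source" in df.columns and \
            pd.notna(r.get("source")) else ""
        rows.append(Interaction(str(r["mirna"]).strip(),
                                str(r["target"]).strip(), bt, src))
    iset = InteractionSet(frozenset(rows))
    counts = {bt: sum(1 for p in iset.pairs if p.target_biotype == bt)
              for bt in ("lncRNA", "mRNA")}
    logger.info("read_interaction_table: %d unique pairs "
                "(lncRNA targets: %d, mRNA targets: %d)",
                len(iset), counts["lncRNA"], counts["mRNA"])
    return iset


def write_interaction_table(interactions: InteractionSet,
                            path: str | Path) -> None:
    rows = sorted((p.mirna, p.target, p.target_biotype, p.source)
                  for p in interactions.pairs)
    pd.DataFrame(rows, columns=["mirna", "target", "target_biotype",
                                "source"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: term, description, then member ids, tab-separated.

    Blank lines are skipped; duplicate members within a set are collapsed.
    """
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"GMT line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}")
            term, desc, *members = fields
            uniq = tuple(dict.fromkeys(m.strip() for m in members
                                       if m.strip()))
            if not uniq:
                raise ValueError(f"GMT line {lineno}: set {term!r} is empty")
            sets[term.strip()] = (desc.strip(), uniq)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, (desc, members) in collection.sets.items():
            fh.write("\t".join([term, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------

#: SIF interaction labels by (sorted) endpoint biotypes
_SIF_LABELS = {
    frozenset(("lncRNA", "miRNA")): "lnc-mir",
    frozenset(("miRNA", "mRNA")): "mir-mrna",
}


def write_network(network: nx.Graph, path: str | Path,
                  dialect: str = "GraphML") -> None:
    """Export a tripartite ceRNA network as SIF or GraphML.

    SIF uses the interaction labels ``lnc-mir`` and ``mir-mrna``; isolated
    nodes are written as single-column lines.  GraphML carries the node
    attribute ``biotype`` and round-trips losslessly through
    :func:`read_network`.
    """
    if dialect not in ("SIF", "GraphML"):
        raise ValueError(f"unknown network dialect {dialect!r}")
    if dialect == "GraphML":
        nx.write_graphml(network, str(path))
        return
    with open(path, "w") as fh:
        written: set[str] = set()
        for u, v in sorted(network.edges()):
            bts = frozenset((network.nodes[u]["biotype"],
                             network.nodes[v]["biotype"]))
            label = _SIF_LABELS[bts]
            # orient lncRNA/miRNA first so the label reads left-to-right
            if BIOTYPE_ORDER[network.nodes[u]["biotype"]] > \
                    BIOTYPE_ORDER[network.nodes[v]["biotype"]]:
                u, v = v, u
            fh.write(f"{u}\t{label}\t{v}\n")
            written.update((u, v))
        for n in sorted(set(network.nodes) - written):
            fh.write(f"{n}\n")


def read_network(path: str | Path) -> nx.Graph:
    """Read a GraphML network written by :func:`write_network`."""
    g = nx.read_graphml(str(path))
    out = nx.Graph()
    for n, data in g.nodes(data=True):
        out.add_node(str(n), biotype=data["biotype"])
    for u, v in g.edges():
        out.add_edge(str(u), str(v))
    return out
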