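"""Presence/absence repertoires of prophage protein clusters.

Builds binary isolate x protein-cluster matrices at each of the six
clustering levels (identity 0/50/80 % crossed with coverage 50/80 %),
applies the rare-cluster frequency filter, determines which capsule loci
(K-loci) are diverse enough for association testing, and clusters prophages
into variants by weighted gene-repertoire relatedness (wGRR).

Coordinates and conventions
---------------------------
* A matrix entry is 1 iff at least one member protein of the cluster occurs
  in the isolate (presence is an OR over members).
* Cluster and isolate identifiers are opaque strings; all orderings are
  lexicographic so that outputs are reproducible byte for byte.
* Only isolates whose K-locus call carries a confident class (by default
  ``Good``, ``Very Good`` or ``Perfect``) should enter association matrices;
  use :func:`confident_isolates` to subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "IsolateRecord",
    "ClusteringLevel",
    "LEVELS",
    "PresenceMatrix",
    "GeneRepertoire",
    "confident_isolates",
    "build_matrix",
    "filter_rare",
    "eligible_loci",
    "wgrr",
    "variant_clusters",
]

#: K-locus confidence classes treated as reliable calls.
CONFIDENT_CLASSES = frozenset({"Good", "Very Good", "Perfect"})


@dataclass(frozen=True)
class IsolateRecord:
    """One bacterial isolate with its lineage and capsule assignment.

    Parameters
    ----------
    isolate_id : str
        Unique identifier of the genome.
    sc : str
        Sequence-cluster (lineage) label from genome-distance clustering.
    k_locus : str
        Capsule synthesis locus call (e.g. ``KL2``).
    k_confidence : str
        Call confidence class; ``Good``/``Very Good``/``Perfect`` are
        treated as confident.
    species : str
        Species tag (free text, informational).
    """

    isolate_id: str
    sc: str
    k_locus: str
    k_confidence: str = "Good"
    species: str = "K. pneumoniae"

    def __post_init__(self) -> None:
        if not self.sc or not self.k_locus:
            raise ValueError(
                f"isolate {self.isolate_id!r}: SC and K-locus labels must be non-empty"
            )


@dataclass(frozen=True, order=True)
class ClusteringLevel:
    """One protein-clustering resolution: identity and coverage thresholds (%)."""

    identity: int
    coverage: int

    def __post_init__(self) -> None:
        if self.identity not in (0, 50, 80) or self.coverage not in (50, 80):
            raise ValueError(
                f"invalid clustering level i{self.identity}c{self.coverage}: "
                "identity must be 0/50/80 and coverage 50/80"
            )

    @property
    def label(self) -> str:
        return f"i{self.identity}c{self.coverage}"

    @classmethod
    def from_label(cls, label: str) -> "ClusteringLevel":
        ident, cov = label.lstrip("i").split("c")
        return cls(int(ident), int(cov))


#: The six clustering resolutions used throughout the pipeline.
LEVELS: tuple[ClusteringLevel, ...] = tuple(
    ClusteringLevel(i, c) for i in (0, 50, 80) for c in (50, 80)
)


@dataclass
class PresenceMatrix:
    """Binary isolates x protein-cluster matrix at one clustering level.

    ``df`` has isolate ids as the index and cluster ids as (sorted) columns,
    with values in {0, 1} (dtype int8).
    """

    level: ClusteringLevel
    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates or self.df.columns.has_duplicates:
            raise ValueError("duplicate isolate or cluster ids in presence matrix")
        vals = self.df.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("presence matrix entries must be 0/1")
        self.df = self.df.astype(np.int8)

    @property
    def isolates(self) -> list[str]:
        return list(self.df.index)

    @property
    def clusters(self) -> list[str]:
        return list(self.df.columns)


@dataclass(frozen=True)
class GeneRepertoire:
    """The gene content of one prophage, for wGRR computation."""

    prophage_id: str
    genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"prophage {self.prophage_id!r}: empty gene repertoire")


def confident_isolates(
    isolates: Sequence[IsolateRecord],
    allowed: Iterable[str] = CONFIDENT_CLASSES,
) -> list[IsolateRecord]:
    """Subset isolates whose K-locus confidence class is in ``allowed``."""
    allowed = set(allowed)
    return [r for r in isolates if r.k_confidence in allowed]


def build_matrix(
    membership: pd.DataFrame,
    isolates: Sequence[IsolateRecord],
    level: ClusteringLevel,
    min_protein_length: int | None = None,
) -> PresenceMatrix:
    """Build a presence/absence matrix from a protein-cluster membership table.

    Parameters
    ----------
    membership : DataFrame
        Columns ``protein_id``, ``isolate_id``, ``cluster_id`` and optionally
        ``length`` (amino acids).
    isolates : sequence of IsolateRecord
        Defines the row axis; every isolate id in the table must appear here.
    level : ClusteringLevel
        The resolution the table was clustered at (metadata only).
    min_protein_length : int, optional
        If given and the table carries a ``length`` column, member proteins
        shorter than this are ignored (the association pipeline uses 300 aa).

    Returns
    -------
    PresenceMatrix
        Entry 1 iff >=1 member protein of the cluster occurs in the isolate.
    """
    ids = [r.isolate_id for r in isolates]
    known = set(ids)
    tab = membership
    if min_protein_length is not None and "length" in tab.columns:
        tab = tab[tab["length"] >= min_protein_length]
    unknown = sorted(set(tab["isolate_id"]) - known)
    if unknown:
        raise ValueError(f"membership table references unknown isolate ids: {unknown}")
    df = pd.DataFrame(0, index=pd.Index(ids, name="isolate_id"), columns=[], dtype=np.int8)
    if len(tab):
        pivot = (
            tab.assign(_one=1)
            .pivot_table(
                index="isolate_id", columns="cluster_id", values="_one", aggfunc="max", fill_value=0
            )
            .reindex(index=ids, fill_value=0)
        )
        pivot = pivot[sorted(pivot.columns)]
        df = pivot.astype(np.int8)
        df.index.name = "isolate_id"
    return PresenceMatrix(level=level, df=df)


def filter_rare(
    matrix: PresenceMatrix,
    sc_map: Mapping[str, str],
    min_isolates: int = 3,
    min_scs: int = 2,
) -> PresenceMatrix:
    """Drop rare protein clusters.

    A cluster is kept iff it is carried by at least ``min_isolates`` isolates
    drawn from at least ``min_scs`` distinct sequence clusters.  The isolate
    axis is unchanged.
    """
    missing = [i for i in matrix.isolates if i not in sc_map]
    if missing:
        raise ValueError(f"isolates without an SC assignment: {missing}")
    scs = np.asarray([sc_map[i] for i in matrix.isolates])
    keep = []
    vals = matrix.df.to_numpy(dtype=bool)
    for j, cluster in enumerate(matrix.clusters):
        carriers = vals[:, j]
        if carriers.sum() >= min_isolates and len(set(scs[carriers])) >= min_scs:
            keep.append(cluster)
    return PresenceMatrix(level=matrix.level, df=matrix.df[keep])


def eligible_loci(isolates: Sequence[IsolateRecord], min_scs: int = 10) -> list[str]:
    """K-loci observed in at least ``min_scs`` distinct sequence clusters, sorted."""
    seen: dict[str, set[str]] = {}
    for r in isolates:
        seen.setdefault(r.k_locus, set()).add(r.sc)
    return sorted(k for k, scs in seen.items() if len(scs) >= min_scs)


def wgrr(rep_a: GeneRepertoire, rep_b: GeneRepertoire, bbh: pd.DataFrame) -> float:
    """Weighted gene-repertoire relatedness between two prophages.

    wGRR(A, B) = sum of bidirectional-best-hit identities / min(|A|, |B|).

    ``bbh`` has columns ``gene_a``, ``gene_b``, ``identity`` (fractions in
    [0, 1]) and must be a one-to-one matching between subsets of the two
    repertoires.
    """
    if len(bbh) == 0:
        return 0.0
    if bbh["gene_a"].duplicated().any() or bbh["gene_b"].duplicated().any():
        raise ValueError("bbh table is not a one-to-one matching (duplicated gene)")
    if not set(bbh["gene_a"]).issubset(rep_a.genes) or not set(bbh["gene_b"]).issubset(rep_b.genes):
        raise ValueError("bbh table references genes outside the repertoires")
    ident = np.asarray(bbh["identity"], dtype=float)
    if (ident < 0).any() or (ident > 1).any():
        raise ValueError("identities must be fractions in [0, 1]")
    return float(ident.sum() / min(len(rep_a.genes), len(rep_b.genes)))


def variant_clusters(
    prophage_ids: Sequence[str],
    pairwise: Mapping[tuple[str, str], float],
    threshold: float = 0.95,
) -> dict[str, str]:
    """Single-linkage phage-variant labels at a wGRR threshold.

    Prophages joined by any chain of pairwise wGRR >= ``threshold`` share a
    variant; the variant label is the lexicographically smallest member id.
    """
    g: nx.Graph = nx.Graph()
    g.add_nodes_from(prophage_ids)
    for (a, b), w in pairwise.items():
        ba = pairwise.get((b, a))
        if ba is not None and abs(ba - w) > 1e-12:
            raise ValueError(f"asymmetric wGRR values for pair ({a!r}, {b!r})")
        if w >= threshold:
            g.add_edge(a, b)
    labels: dict[str, str] = {}
    for comp in nx.connected_components(g):
        rep = min(comp)
        for node in comp:
            labels[node] = rep
    return labels
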