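"""Functional annotation aggregation and K-locus diversity of RBP clusters.

Profile-profile hit tables (PHROG categories for function, ECOD X/T-levels
for domain topology) are consumed as data; this module aggregates them to
cluster-level labels:

* per PC80 cluster, ECOD hits above a probability floor are reduced to the
  best hit per X-level and the top five distinct T-levels;
* per PC50 cluster, the modal T-level combination among its member PC80
  clusters becomes the label, with an independent flag if any member
  carries the pectin-lyase-like fold (T-level 207.2.1) characteristic of
  classical depolymerases;
* receptor-binding proteins (RBPs) are called from PHROG tail-fiber /
  tail-spike hits, and their domains assigned from ECOD hits at stricter
  thresholds;
* the spread of K-loci among a cluster's member isolates is summarized by
  the Gini-Simpson index 1 - sum(p_i^2): 0 when all members share one
  K-locus, approaching 1 when spread over many.

Note the two distinct probability floors: 0.70 for PC80 ECOD reporting,
0.90 for RBP calling and RBP domain assignment.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PhrogHit",
    "EcodHit",
    "Pc80Annotation",
    "Pc50Label",
    "annotate_pc80",
    "label_pc50",
    "is_rbp",
    "rbp_domains",
    "simpson",
    "diversity_table",
    "prophage_domain_summary",
    "PECTIN_LYASE_TLEVEL",
]

PECTIN_LYASE_TLEVEL = "207.2.1"
_RBP_CATEGORIES = ("tail fiber", "tail spike")


@dataclass(frozen=True)
class PhrogHit:
    cluster_id: str
    category: str
    probability: float
    qcov: float
    scov: float

    def __post_init__(self) -> None:
        for name in ("probability", "qcov", "scov"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"PhrogHit.{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class EcodHit:
    cluster_id: str
    x_level: str
    t_level: str
    probability: float
    tcov: float = 1.0

    def __post_init__(self) -> None:
        if not self.t_level.startswith(f"{self.x_level}."):
            raise ValueError(
                f"T-level {self.t_level!r} is not nested under X-level {self.x_level!r}"
            )
        for name in ("probability", "tcov"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"EcodHit.{name} must be in [0, 1], got {v}")


@dataclass
class Pc80Annotation:
    pc80_id: str
    #: (t_level, probability) sorted by probability descending, <= 5 entries
    t_levels: list[tuple[str, float]] = field(default_factory=list)

    @property
    def combination(self) -> frozenset[str]:
        return frozenset(t for t, _ in self.t_levels)


@dataclass
class Pc50Label:
    pc50_id: str
    modal_combination: frozenset[str]
    pectin_lyase: bool


def annotate_pc80(
    hits: Sequence[EcodHit],
    min_prob: float = 0.70,
    max_tlevels: int = 5,
) -> Pc80Annotation:
    """Aggregate one PC80 cluster's ECOD hits.

    Hits below ``min_prob`` are dropped; within each X-level only the
    maximum-probability hit survives; the top ``max_tlevels`` distinct
    T-levels by probability are reported.
    """
    ids = {h.cluster_id for h in hits}
    if len(ids) > 1:
        raise ValueError(f"hits reference several PC80 clusters: {sorted(ids)}")
    pc80 = ids.pop() if ids else ""
    passing = [h for h in hits if h.probability >= min_prob]
    best_per_x: dict[str, EcodHit] = {}
    for h in passing:
        cur = best_per_x.get(h.x_level)
        if cur is None or (h.probability, h.t_level) > (cur.probability, cur.t_level):
            best_per_x[h.x_level] = h
    best: dict[str, float] = {}
    for h in best_per_x.values():
        best[h.t_level] = max(best.get(h.t_level, 0.0), h.probability)
    ordered = sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))[:max_tlevels]
    return Pc80Annotation(pc80_id=pc80, t_levels=ordered)


def label_pc50(pc50_id: str, members: Sequence[Pc80Annotation]) -> Pc50Label:
    """Label a PC50 cluster by the modal T-level combination of its members.

    Ties break to the larger combination, then lexicographic.  Members
    without any passing annotation contribute the empty combination.  The
    pectin-lyase flag is set independently if T-level 207.2.1 occurs in
    any member annotation.
    """
    if not members:
        raise ValueError(f"PC50 {pc50_id!r} has no member annotations")
    combos = Counter(m.combination for m in members)
    modal = sorted(
        combos.items(),
        key=lambda kv: (-kv[1], -len(kv[0]), tuple(sorted(kv[0]))),
    )[0][0]
    flag = any(PECTIN_LYASE_TLEVEL in m.combination for m in members)
    return Pc50Label(pc50_id=pc50_id, modal_combination=modal, pectin_lyase=flag)


def _normalize_category(cat: str) -> str:
    return cat.lower().replace("fibre", "fiber")


def is_rbp(
    hits: Sequence[PhrogHit],
    min_prob: float = 0.90,
    min_qcov: float = 0.50,
    min_scov: float = 0.50,
) -> bool:
    """Call a cluster an RBP from its PHROG hits.

    True iff at least one hit whose category contains "tail fiber" (any
    spelling) or "tail spike" passes all three thresholds.
    """
    for h in hits:
        cat = _normalize_category(h.category)
        if not any(key in cat for key in _RBP_CATEGORIES):
            continue
        if h.probability >= min_prob and h.qcov >= min_qcov and h.scov >= min_scov:
            return True
    return False


def rbp_domains(
    hits: Sequence[EcodHit],
    min_prob: float = 0.90,
    min_tcov: float = 0.10,
) -> frozenset[str]:
    """ECOD T-levels assigned to an RBP cluster (multi-domain allowed)."""
    return frozenset(
        h.t_level for h in hits if h.probability >= min_prob and h.tcov >= min_tcov
    )


def simpson(counts: Mapping[str, int]) -> float:
    """Gini-Simpson diversity 1 - sum(p_i^2) of K-locus membership counts."""
    vals = np.asarray(list(counts.values()), dtype=float)
    if (vals < 0).any():
        raise ValueError("counts must be non-negative")
    total = vals.sum()
    if total < 1:
        raise ValueError("total count must be >= 1")
    p = vals / total
    return float(1.0 - np.sum(p * p))


def diversity_table(
    rbp_clusters: Mapping[str, frozenset[str]],
    membership: pd.DataFrame,
    isolate_kloci: Mapping[str, str],
    isolate_scs: Mapping[str, str],
    min_members: int = 10,
    min_scs: int = 3,
) -> pd.DataFrame:
    """Per-RBP-cluster Simpson diversity of member K-loci.

    ``rbp_clusters`` maps cluster id -> assigned domain set; ``membership``
    has columns ``cluster_id`` and ``isolate_id`` (one row per member
    protein occurrence).  Clusters with fewer than ``min_members`` member
    proteins or spanning fewer than ``min_scs`` SCs are excluded.
    """
    rows = []
    for cid in sorted(rbp_clusters):
        mem = membership[membership["cluster_id"] == cid]
        if len(mem) < min_members:
            continue
        scs = {isolate_scs[i] for i in mem["isolate_id"]}
        if len(scs) < min_scs:
            continue
        k_counts = Counter(isolate_kloci[i] for i in mem["isolate_id"])
        rows.append(
            dict(
                cluster_id=cid,
                n_members=len(mem),
                n_scs=len(scs),
                domains=",".join(sorted(rbp_clusters[cid])) or "none",
                simpson=simpson(k_counts),
            )
        )
    return pd.DataFrame(rows, columns=["cluster_id", "n_members", "n_scs",
                                       "domains", "simpson"])


def prophage_domain_summary(
    gene_order: pd.DataFrame,
    prophage_meta: pd.DataFrame,
    rbp_calls: Mapping[str, bool],
    domain_sets: Mapping[str, frozenset[str]],
    min_completeness: float = 90.0,
    neighborhood: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratify near-complete prophages by the domain content of their RBPs.

    ``gene_order`` has columns ``prophage_id``, ``position`` (integer gene
    rank), ``cluster_id``; ``prophage_meta`` has ``prophage_id``,
    ``k_locus``, ``completeness`` (percent).  A prophage with completeness
    >= ``min_completeness`` is classified per K-locus as:

    * ``single:<domain>`` — its RBPs carry exactly one domain overall;
    * ``multi_domain`` — more than one distinct domain;
    * ``rbp_no_domain`` — has an RBP but no assigned domain;
    * ``no_rbp`` — no gene called as RBP.

    For ``rbp_no_domain`` prophages, genes within ``neighborhood``
    positions of an RBP are scanned and their domains reported in the
    second returned table.
    """
    meta = prophage_meta[prophage_meta["completeness"] >= min_completeness]
    rows, neigh_rows = [], []
    for _, pm in meta.iterrows():
        pid, kl = pm["prophage_id"], pm["k_locus"]
        genes = gene_order[gene_order["prophage_id"] == pid].sort_values("position")
        rbp_positions = [
            int(g["position"]) for _, g in genes.iterrows()
            if rbp_calls.get(g["cluster_id"], False)
        ]
        if not rbp_positions:
            stratum = "no_rbp"
        else:
            domains: set[str] = set()
            for _, g in genes.iterrows():
                if rbp_calls.get(g["cluster_id"], False):
                    domains |= domain_sets.get(g["cluster_id"], frozenset())
            if len(domains) == 1:
                stratum = f"single:{next(iter(domains))}"
            elif len(domains) > 1:
                stratum = "multi_domain"
            else:
                stratum = "rbp_no_domain"
                for _, g in genes.iterrows():
                    pos = int(g["position"])
                    if any(0 < abs(pos - rp) <= neighborhood for rp in rbp_positions):
                        for d in sorted(domain_sets.get(g["cluster_id"], frozenset())):
                            neigh_rows.append(
                                dict(prophage_id=pid, k_locus=kl,
                                     neighbor_cluster=g["cluster_id"], domain=d,
                                     offset=min(pos - rp for rp in rbp_positions
                                                if 0 < abs(pos - rp) <= neighborhood))
                            )
        rows.append(dict(prophage_id=pid, k_locus=kl, stratum=stratum))
    per_prophage = pd.DataFrame(rows, columns=["prophage_id", "k_locus", "stratum"])
    counts = (
        per_prophage.groupby(["k_locus", "stratum"]).size().reset_index(name="count")
        if len(per_prophage)
        else pd.DataFrame(columns=["k_locus", "stratum", "count"])
    )
    neighbors = pd.DataFrame(
        neigh_rows, columns=["prophage_id", "k_locus", "neighbor_cluster", "domain", "offset"]
    )
    counts.attrs["per_prophage"] = per_prophage
    return counts, neighbors
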