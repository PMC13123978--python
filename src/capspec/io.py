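"""On-disk formats: Rtab presence/absence matrices and plain TSV tables.

The Rtab dialect is the tab-separated binary matrix common to bacterial
pan-genome association tools: the first column holds cluster ids, the
header row holds isolate ids, entries are 0/1.  All writers emit UTF-8
with deterministic (sorted) row ordering; readers report malformed rows
with line numbers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .assoc import AssociationResult
from .repertoire import ClusteringLevel, IsolateRecord, PresenceMatrix

__all__ = [
    "write_rtab",
    "read_rtab",
    "write_metadata",
    "read_metadata",
    "write_associations",
    "read_associations",
]

_META_COLUMNS = ["isolate_id", "sc", "k_locus", "k_confidence", "species"]


def write_rtab(matrix: PresenceMatrix, path: str | Path) -> None:
    """Write a presence matrix as Rtab (rows = clusters, columns = isolates)."""
    df = matrix.df.T  # clusters x isolates
    df = df.sort_index()
    df.index.name = "Gene"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_rtab(path: str | Path, level: ClusteringLevel) -> PresenceMatrix:
    """Read an Rtab file back into a :class:`PresenceMatrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    bad = df.apply(lambda col: ~col.isin((0, 1))).to_numpy()
    if bad.any():
        rows = sorted({int(i) + 2 for i in bad.any(axis=1).nonzero()[0]})
        raise ValueError(f"non-binary entries in Rtab file {path} at lines {rows}")
    out = df.T
    out.index.name = "isolate_id"
    out.columns.name = None
    return PresenceMatrix(level=level, df=out[sorted(out.columns)])


def write_metadata(isolates: Sequence[IsolateRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            dict(isolate_id=r.isolate_id, sc=r.sc, k_locus=r.k_locus,
                 k_confidence=r.k_confidence, species=r.species)
            for r in isolates
        ],
        columns=_META_COLUMNS,
    ).sort_values("isolate_id")
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_metadata(path: str | Path) -> list[IsolateRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _META_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ValueError(f"metadata file {path} missing required columns: {missing}")
    records = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        if any(pd.isna(d[c]) for c in _META_COLUMNS[:3]):
            raise ValueError(f"metadata file {path}: empty required field at line {lineno}")
        records.append(
            IsolateRecord(
                isolate_id=d["isolate_id"],
                sc=d["sc"],
                k_locus=d["k_locus"],
                k_confidence=d.get("k_confidence") or "Good",
                species=d.get("species") or "K. pneumoniae",
            )
        )
    return records


def write_associations(results: Sequence[AssociationResult], path: str | Path) -> None:
    rows = []
    for r in sorted(results, key=lambda r: (r.k_locus, r.level, r.cluster_id)):
        row = dict(
            k_locus=r.k_locus,
            level=r.level,
            cluster_id=r.cluster_id,
            p_value=f"{r.p_value:.6g}",
            n_tests=r.n_tests,
            threshold=f"{r.threshold:.6g}",
            significant=int(r.significant),
            modes_retaining=",".join(f"{a:g}" for a in r.modes_retaining),
        )
        for a, b in sorted(r.beta_by_mode.items()):
            row[f"beta_a{a:g}"] = f"{b:.6g}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_associations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"k_locus", "level", "cluster_id", "p_value", "significant"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise ValueError(f"association file {path} missing columns: {missing}")
    return df
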