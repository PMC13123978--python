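"""Synthetic lineage-structured populations with planted capsule-specific clusters.

The generator emulates the data structure of a bacterial pan-genome
association study of phage-host capsule specificity:

* a population partitioned into sequence clusters (SCs, lineage labels)
  with Dirichlet-multinomial size variation;
* K-locus (capsule) assignments that track lineage strongly but
  imperfectly — each SC has a dominant K-locus and isolates switch away
  from it at a configurable rate, mimicking capsule swaps;
* binary prophage protein-cluster repertoires containing
  - background clusters carried independently at random frequencies,
  - planted *true RBP* clusters carried with high probability by isolates
    of a target K-locus and rarely otherwise,
  - *lineage confounder* clusters that track one SC irrespective of
    K-locus (the decoys that population-structure covariates must reject),
  - *correlated copies* that duplicate another planted column up to
    independent bit flips;
* merge/split behaviour of planted families across the six clustering
  resolutions, so cross-level predictor selection can be exercised;
* companion detection/QC/annotation tables so the interval and annotation
  stages are testable without external tools.

No sequences are simulated; SC labels are the only population-structure
object, matching their use as covariates downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from ._rng import child_rng
from .repertoire import LEVELS, ClusteringLevel, IsolateRecord, PresenceMatrix

__all__ = [
    "ConfigError",
    "PlantedSpec",
    "SimConfig",
    "PlantedClusterInfo",
    "PlantedTruth",
    "SyntheticStudy",
    "simulate_population",
    "simulate_repertoires",
    "simulate_companion_tables",
    "simulate_study",
    "default_benchmark_config",
]

#: the default ("base") clustering resolution at which columns are planted
BASE_LEVEL = ClusteringLevel(50, 50)


class ConfigError(ValueError):
    """A simulation configuration field is invalid."""


@dataclass(frozen=True)
class PlantedSpec:
    """Generative parameters for one planted protein cluster.

    ``kind`` is one of:

    ``true_rbp``
        carried with probability ``sensitivity`` by isolates of
        ``target_klocus`` and ``fpr`` by all others;
    ``lineage_confounder``
        carried with probability ``sensitivity`` inside ``confounder_sc``
        (irrespective of K-locus) and ``fpr`` outside it; if
        ``confounder_sc`` is None the largest SC whose dominant K-locus is
        ``target_klocus`` is chosen, making the decoy maximally collinear
        with the signal;
    ``correlated_copy``
        equal to the ``true_rbp`` column for the same target K-locus with
        independent flips at rate ``copy_noise``.
    """

    target_klocus: str
    sensitivity: float = 0.9
    fpr: float = 0.01
    kind: Literal["true_rbp", "lineage_confounder", "correlated_copy"] = "true_rbp"
    confounder_sc: str | None = None
    copy_noise: float = 0.02
    domain_tlevel: str = "207.2.1"

    def validate(self) -> None:
        for name in ("sensitivity", "fpr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"PlantedSpec.{name} must be in [0, 1], got {v}")
        if self.kind == "true_rbp" and self.sensitivity <= self.fpr:
            raise ConfigError(
                "PlantedSpec.sensitivity must exceed fpr for a true_rbp "
                f"(got {self.sensitivity} <= {self.fpr})"
            )
        if not 0.0 <= self.copy_noise < 0.5:
            raise ConfigError(f"PlantedSpec.copy_noise must be in [0, 0.5), got {self.copy_noise}")
        if self.kind not in ("true_rbp", "lineage_confounder", "correlated_copy"):
            raise ConfigError(f"PlantedSpec.kind unknown: {self.kind!r}")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study."""

    n_isolates: int = 500
    n_sc: int = 25
    sc_concentration: float = 5.0
    n_kloci: int = 5
    k_switch_rate: float = 0.1
    n_background_clusters: int = 200
    background_freq_range: tuple[float, float] = (0.05, 0.30)
    planted_specs: tuple[PlantedSpec, ...] = ()
    merge_prob: float = 0.5
    split_prob: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_isolates < 1:
            raise ConfigError(f"SimConfig.n_isolates must be >= 1, got {self.n_isolates}")
        if not 1 <= self.n_sc <= self.n_isolates:
            raise ConfigError(
                f"SimConfig.n_sc must be in [1, n_isolates], got {self.n_sc}"
            )
        if self.n_kloci < 2:
            raise ConfigError(f"SimConfig.n_kloci must be >= 2, got {self.n_kloci}")
        if self.sc_concentration <= 0:
            raise ConfigError(
                f"SimConfig.sc_concentration must be positive, got {self.sc_concentration}"
            )
        for name in ("k_switch_rate", "merge_prob", "split_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"SimConfig.{name} must be in [0, 1], got {v}")
        lo, hi = self.background_freq_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigError(
                f"SimConfig.background_freq_range must satisfy 0 <= lo <= hi <= 1, "
                f"got {self.background_freq_range}"
            )
        if self.n_background_clusters < 0:
            raise ConfigError(
                f"SimConfig.n_background_clusters must be >= 0, got {self.n_background_clusters}"
            )
        for spec in self.planted_specs:
            spec.validate()


@dataclass
class PlantedClusterInfo:
    """Ground truth for one planted cluster."""

    cluster_id: str  # base-level id
    kind: str
    target_klocus: str | None
    spec: PlantedSpec
    #: level label -> cluster ids carrying this family at that level
    level_map: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class PlantedTruth:
    """Ground truth for all planted clusters, plus the background id list."""

    planted: dict[str, PlantedClusterInfo]
    background_ids: list[str]
    background_freqs: dict[str, float]

    def ids_of_kind(self, kind: str) -> list[str]:
        return sorted(c for c, info in self.planted.items() if info.kind == kind)

    def level_ids(self, cluster_id: str, level: ClusteringLevel) -> list[str]:
        """All cluster ids at ``level`` that carry the planted family."""
        return self.planted[cluster_id].level_map[level.label]


@dataclass
class SyntheticStudy:
    isolates: list[IsolateRecord]
    matrices: dict[str, PresenceMatrix]  # keyed by level label
    truth: PlantedTruth
    detection_table: pd.DataFrame | None = None
    qc_table: pd.DataFrame | None = None
    phrog_hits: pd.DataFrame | None = None
    ecod_hits: pd.DataFrame | None = None

    @property
    def sc_map(self) -> dict[str, str]:
        return {r.isolate_id: r.sc for r in self.isolates}

    @property
    def k_map(self) -> dict[str, str]:
        return {r.isolate_id: r.k_locus for r in self.isolates}


def simulate_population(config: SimConfig, seed: int) -> list[IsolateRecord]:
    """Draw the lineage-structured population with K-locus assignments.

    SC sizes follow a symmetric Dirichlet-multinomial (every SC is seeded
    with one isolate first, so no SC is empty).  Each SC draws a dominant
    K-locus uniformly with replacement; each isolate keeps its SC's
    dominant K-locus with probability ``1 - k_switch_rate`` and otherwise
    switches uniformly to one of the other loci.
    """
    config.validate()
    rng = child_rng(seed, "simulate_population")
    n, m = config.n_isolates, config.n_sc
    weights = rng.dirichlet(np.full(m, config.sc_concentration))
    sc_idx = np.empty(n, dtype=int)
    sc_idx[:m] = np.arange(m)  # guarantee non-empty SCs
    sc_idx[m:] = rng.choice(m, size=n - m, p=weights)
    kloci = [f"KL{i + 1}" for i in range(config.n_kloci)]
    dominant = rng.integers(config.n_kloci, size=m)
    records: list[IsolateRecord] = []
    switch = rng.random(n) < config.k_switch_rate
    for i in range(n):
        s = sc_idx[i]
        k = dominant[s]
        if switch[i]:
            others = [j for j in range(config.n_kloci) if j != k]
            k = others[rng.integers(len(others))]
        records.append(
            IsolateRecord(
                isolate_id=f"ISO{i + 1:05d}",
                sc=f"SC{s + 1:03d}",
                k_locus=kloci[k],
                k_confidence="Good",
            )
        )
    return records


def _dominant_k_by_sc(isolates: Sequence[IsolateRecord]) -> dict[str, str]:
    df = pd.DataFrame({"sc": [r.sc for r in isolates], "k": [r.k_locus for r in isolates]})
    out: dict[str, str] = {}
    for sc, grp in df.groupby("sc"):
        counts = grp["k"].value_counts()
        out[sc] = sorted(counts[counts == counts.max()].index)[0]
    return out


def _resolve_confounder_sc(
    spec: PlantedSpec, isolates: Sequence[IsolateRecord]
) -> str:
    if spec.confounder_sc is not None:
        scs = {r.sc for r in isolates}
        if spec.confounder_sc not in scs:
            raise ConfigError(f"confounder_sc {spec.confounder_sc!r} not in population")
        return spec.confounder_sc
    dom = _dominant_k_by_sc(isolates)
    candidates = [sc for sc, k in dom.items() if k == spec.target_klocus]
    if not candidates:
        raise ConfigError(
            f"no SC has dominant K-locus {spec.target_klocus!r}; "
            "cannot auto-place lineage confounder"
        )
    sizes = pd.Series([r.sc for r in isolates]).value_counts()
    return sorted(candidates, key=lambda sc: (-sizes[sc], sc))[0]


def simulate_repertoires(
    isolates: Sequence[IsolateRecord],
    config: SimConfig,
    seed: int,
) -> tuple[dict[str, PresenceMatrix], PlantedTruth]:
    """Generate presence matrices at all six levels plus the planted truth.

    Columns are planted at the base resolution (identity 50 / coverage 50).
    At each looser level a planted family may merge with one randomly
    chosen background family (the carrier sets are unioned); at each
    stricter level it may split into two sub-clusters partitioning its
    carriers.  Background columns are identical across levels.
    """
    if not isolates:
        raise ConfigError("isolates must be non-empty")
    config.validate()
    rng = child_rng(seed, "simulate_repertoires")
    n = len(isolates)
    ids = [r.isolate_id for r in isolates]
    k_arr = np.asarray([r.k_locus for r in isolates])
    sc_arr = np.asarray([r.sc for r in isolates])
    k_present = set(k_arr)

    cols: dict[str, np.ndarray] = {}
    freqs: dict[str, float] = {}
    lo, hi = config.background_freq_range
    for j in range(config.n_background_clusters):
        f = float(rng.uniform(lo, hi))
        cid = f"bg{j + 1:04d}"
        cols[cid] = (rng.random(n) < f).astype(np.int8)
        freqs[cid] = f

    planted: dict[str, PlantedClusterInfo] = {}
    rbp_by_target: dict[str, str] = {}
    for spec in config.planted_specs:
        if spec.kind in ("true_rbp", "lineage_confounder", "correlated_copy"):
            if spec.target_klocus not in k_present:
                raise ConfigError(
                    f"planted target K-locus {spec.target_klocus!r} absent from population"
                )
        if spec.kind == "true_rbp":
            cid = f"rbp_{spec.target_klocus}"
            is_target = k_arr == spec.target_klocus
            p = np.where(is_target, spec.sensitivity, spec.fpr)
            cols[cid] = (rng.random(n) < p).astype(np.int8)
            rbp_by_target[spec.target_klocus] = cid
            planted[cid] = PlantedClusterInfo(cid, spec.kind, spec.target_klocus, spec)
        elif spec.kind == "lineage_confounder":
            sc = _resolve_confounder_sc(spec, isolates)
            cid = f"conf_{sc}"
            inside = sc_arr == sc
            p = np.where(inside, spec.sensitivity, spec.fpr)
            cols[cid] = (rng.random(n) < p).astype(np.int8)
            info = PlantedClusterInfo(cid, spec.kind, spec.target_klocus,
                                      replace(spec, confounder_sc=sc))
            planted[cid] = info
        elif spec.kind == "correlated_copy":
            parent = rbp_by_target.get(spec.target_klocus)
            if parent is None:
                raise ConfigError(
                    f"correlated_copy for {spec.target_klocus!r} requires a true_rbp "
                    "spec for the same target earlier in planted_specs"
                )
            cid = f"copy_{spec.target_klocus}"
            flips = rng.random(n) < spec.copy_noise
            cols[cid] = (cols[parent] ^ flips.astype(np.int8)).astype(np.int8)
            planted[cid] = PlantedClusterInfo(cid, spec.kind, spec.target_klocus, spec)

    background_ids = sorted(freqs)
    base_df = pd.DataFrame(
        {c: cols[c] for c in sorted(cols)}, index=pd.Index(ids, name="isolate_id")
    )

    # strictness order: lower identity/coverage = looser clustering
    ordered = sorted(LEVELS)
    base_rank = ordered.index(BASE_LEVEL)
    matrices: dict[str, PresenceMatrix] = {}
    for rank, level in enumerate(ordered):
        df = base_df.copy()
        for cid, info in planted.items():
            level_ids = [cid]
            if rank < base_rank and background_ids and rng.random() < config.merge_prob:
                partner = background_ids[rng.integers(len(background_ids))]
                merged = f"{cid}+{partner}"
                df[merged] = (df[cid].to_numpy() | df[partner].to_numpy()).astype(np.int8)
                df = df.drop(columns=[cid, partner])
                level_ids = [merged]
            elif rank > base_rank and rng.random() < config.split_prob:
                carriers = np.flatnonzero(df[cid].to_numpy())
                if len(carriers) >= 2:
                    perm = rng.permutation(carriers)
                    half = len(perm) // 2
                    a = np.zeros(n, dtype=np.int8)
                    b = np.zeros(n, dtype=np.int8)
                    a[perm[:half]] = 1
                    b[perm[half:]] = 1
                    df[f"{cid}_s1"] = a
                    df[f"{cid}_s2"] = b
                    df = df.drop(columns=[cid])
                    level_ids = [f"{cid}_s1", f"{cid}_s2"]
            info.level_map[level.label] = level_ids
        df = df[sorted(df.columns)]
        matrices[level.label] = PresenceMatrix(level=level, df=df)

    truth = PlantedTruth(planted=planted, background_ids=background_ids,
                         background_freqs=freqs)
    return matrices, truth


def simulate_companion_tables(
    study: SyntheticStudy,
    seed: int,
    contig_length: int = 100_000,
    span_length: int = 30_000,
    jitter: int = 500,
    pad: int = 2_000,
    hit_prob: float = 0.95,
) -> SyntheticStudy:
    """Attach detection/QC interval tables and PHROG/ECOD hit tables.

    Each isolate receives one synthetic contig with one true prophage span;
    the two detection tools report the span jittered by up to ``jitter``
    bases on each side.  QC records trim the extended region back to the
    true span with a known completeness.  Hit tables give every planted
    true-RBP cluster a tail-fiber PHROG call and its configured ECOD
    T-level with probability ``hit_prob``; background clusters draw
    non-tail categories.
    """
    rng = child_rng(seed, "simulate_companion_tables")
    det_rows, qc_rows = [], []
    for r in study.isolates:
        start = int(rng.integers(pad + jitter, contig_length - span_length - pad - jitter))
        end = start + span_length
        for tool in ("virsorter", "phispy"):
            js, je = int(rng.integers(0, jitter + 1)), int(rng.integers(0, jitter + 1))
            det_rows.append(
                dict(isolate_id=r.isolate_id, contig_id=f"{r.isolate_id}_c1",
                     contig_length=contig_length, start=max(0, start - js),
                     end=min(contig_length, end + je), tool=tool)
            )
        completeness = float(np.round(rng.uniform(50, 100), 1))
        confidence = str(rng.choice(["low", "medium", "high"], p=[0.2, 0.3, 0.5]))
        qc_rows.append(
            dict(isolate_id=r.isolate_id, contig_id=f"{r.isolate_id}_c1",
                 region_index=0, start=start, end=end,
                 completeness=completeness, confidence=confidence)
        )
    detection = pd.DataFrame(det_rows)
    qc = pd.DataFrame(qc_rows)

    other_cats = ["major capsid", "terminase", "integrase", "lysin", "portal"]
    other_tlevels = ["2004.1.1", "3240.1.1", "877.1.1", "101.1.1"]
    phrog_rows, ecod_rows = [], []
    base = study.matrices[BASE_LEVEL.label]
    for cid in base.clusters:
        info = study.truth.planted.get(cid)
        if info is not None and info.kind in ("true_rbp", "correlated_copy"):
            if rng.random() < hit_prob:
                phrog_rows.append(dict(cluster_id=cid, category="tail fiber",
                                       probability=float(rng.uniform(0.92, 1.0)),
                                       qcov=float(rng.uniform(0.6, 1.0)),
                                       scov=float(rng.uniform(0.6, 1.0))))
            if rng.random() < hit_prob:
                ecod_rows.append(dict(cluster_id=cid,
                                      x_level=info.spec.domain_tlevel.split(".")[0],
                                      t_level=info.spec.domain_tlevel,
                                      probability=float(rng.uniform(0.92, 1.0)),
                                      tcov=float(rng.uniform(0.2, 0.9))))
        else:
            phrog_rows.append(dict(cluster_id=cid,
                                   category=str(rng.choice(other_cats)),
                                   probability=float(rng.uniform(0.7, 1.0)),
                                   qcov=float(rng.uniform(0.3, 1.0)),
                                   scov=float(rng.uniform(0.3, 1.0))))
            if rng.random() < 0.5:
                t = str(rng.choice(other_tlevels))
                ecod_rows.append(dict(cluster_id=cid, x_level=t.split(".")[0],
                                      t_level=t,
                                      probability=float(rng.uniform(0.5, 1.0)),
                                      tcov=float(rng.uniform(0.05, 0.9))))
    study.detection_table = detection
    study.qc_table = qc
    study.phrog_hits = pd.DataFrame(phrog_rows)
    study.ecod_hits = pd.DataFrame(ecod_rows)
    return study


def simulate_study(config: SimConfig, seed: int | None = None,
                   companions: bool = False) -> SyntheticStudy:
    """Run the full generator: population, repertoires and (optionally) tables."""
    seed = config.seed if seed is None else seed
    isolates = simulate_population(config, seed)
    matrices, truth = simulate_repertoires(isolates, config, seed)
    study = SyntheticStudy(isolates=isolates, matrices=matrices, truth=truth)
    if companions:
        study = simulate_companion_tables(study, seed)
    return study


def default_benchmark_config(target_klocus: str = "KL1",
                             with_confounder: bool = True) -> SimConfig:
    """The default synthetic benchmark.

    500 isolates in 25 SCs, capsule-switch rate 0.1, 200 background
    clusters, one planted true-RBP cluster for the target K-locus with
    sensitivity 0.9 and false-positive rate 0.01, and (by default) one
    lineage-confounder decoy placed on the largest SC dominated by the
    target K-locus.
    """
    specs: list[PlantedSpec] = [
        PlantedSpec(target_klocus=target_klocus, sensitivity=0.9, fpr=0.01, kind="true_rbp")
    ]
    if with_confounder:
        specs.append(
            PlantedSpec(target_klocus=target_klocus, sensitivity=0.9, fpr=0.02,
                        kind="lineage_confounder")
        )
    return SimConfig(
        n_isolates=500,
        n_sc=25,
        k_switch_rate=0.1,
        n_background_clusters=200,
        planted_specs=tuple(specs),
    )
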