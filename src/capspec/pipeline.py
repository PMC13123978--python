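"""End-to-end orchestration helpers tying the pipeline stages together.

These functions run GWAS across the six clustering resolutions for one
K-locus, assemble :class:`~capspec.curation.PredictorEvidence` for every
retained predictor (isolate- and SC-level metrics, bootstrap CIs,
SC concordance), and apply selection and curation.  The CLI and the
acceptance harness are thin wrappers over them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assoc import AssociationResult, GwasConfig, run_gwas
from .curation import (
    CurationCall,
    CurationRules,
    PredictorEvidence,
    Selection,
    curate,
    sc_concordance,
    strongest_per_locus,
)
from .metrics import bootstrap_cis, confusion, metric_set, sc_confusion
from .repertoire import IsolateRecord, PresenceMatrix

__all__ = ["LocusReport", "evaluate_predictors", "analyse_locus"]


@dataclass
class LocusReport:
    """Everything the pipeline produced for one K-locus."""

    k_locus: str
    associations: list[AssociationResult] = field(default_factory=list)
    evidence: list[PredictorEvidence] = field(default_factory=list)
    selection: Selection | None = None
    curation: dict[str, CurationCall] = field(default_factory=dict)


def evaluate_predictors(
    matrices: dict[str, PresenceMatrix],
    isolates: list[IsolateRecord],
    associations: list[AssociationResult],
    n_boot: int = 100,
    seed: int = 0,
) -> list[PredictorEvidence]:
    """Build full evidence for every significant association."""
    by_id = {r.isolate_id: r for r in isolates}
    evidence: list[PredictorEvidence] = []
    for res in associations:
        if not res.significant:
            continue
        matrix = matrices[res.level]
        recs = [by_id[i] for i in matrix.isolates]
        scs = [r.sc for r in recs]
        y = np.asarray([1 if r.k_locus == res.k_locus else 0 for r in recs])
        x = matrix.df[res.cluster_id].to_numpy()
        conc, _ = sc_concordance(x, y, scs)
        evidence.append(
            PredictorEvidence(
                k_locus=res.k_locus,
                cluster_id=res.cluster_id,
                level=res.level,
                association=res,
                isolate_metrics=metric_set(confusion(x, y)),
                sc_metrics=metric_set(sc_confusion(x, y, scs)),
                isolate_ci=bootstrap_cis(x, y, n_reps=n_boot, seed=seed),
                sc_ci=bootstrap_cis(x, y, n_reps=n_boot, seed=seed, sc_labels=scs),
                sc_concordance=conc,
            )
        )
    return evidence


def analyse_locus(
    matrices: dict[str, PresenceMatrix],
    isolates: list[IsolateRecord],
    k_locus: str,
    gwas_config: GwasConfig | None = None,
    rules: CurationRules | None = None,
    n_boot: int = 100,
    seed: int = 0,
) -> LocusReport:
    """GWAS across all resolutions, then evaluation, selection and curation."""
    gwas_config = gwas_config or GwasConfig()
    associations: list[AssociationResult] = []
    for label in sorted(matrices):
        associations.extend(run_gwas(matrices[label], k_locus, isolates, gwas_config))
    evidence = evaluate_predictors(matrices, isolates, associations,
                                   n_boot=n_boot, seed=seed)
    selection = strongest_per_locus(evidence) if evidence else Selection(
        k_locus=k_locus, chosen=None, rule_trail=["no retained predictors"]
    )
    if selection.k_locus == "":
        selection.k_locus = k_locus
    curation_calls = {
        f"{e.level}/{e.cluster_id}": curate(e, rules) for e in evidence
    }
    return LocusReport(
        k_locus=k_locus,
        associations=associations,
        evidence=evidence,
        selection=selection,
        curation=curation_calls,
    )
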