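"""Cross-resolution predictor selection and strong/likely curation.

For each K-locus the retained association candidates from all six
clustering resolutions are pooled; those with isolate-level precision of
at least 0.8 compete, and the candidate with the highest F1 x MCC product
wins — provided both F1 and MCC reach 0.5.  Ties break by higher
precision, then higher recall, then lexicographic (level label, cluster
id), so selection never depends on input order.

Curation then grades the winner (or any candidate) against a configurable
rule set combining isolate- and SC-level metrics plus an SC-concordance
score (Jaccard overlap between predictor-positive and K-positive SC
sets, a numerical stand-in for inspecting predictor/K-locus co-mapping
along the phylogeny).  The default strong/likely thresholds are a
documented reconstruction, fully exposed in :class:`CurationRules`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .assoc import AssociationResult
from .metrics import BootstrapCI, MetricSet

__all__ = [
    "PredictorEvidence",
    "Selection",
    "CurationRules",
    "CurationCall",
    "strongest_per_locus",
    "sc_concordance",
    "curate",
]


@dataclass
class PredictorEvidence:
    """All evidence gathered for one retained predictor."""

    k_locus: str
    cluster_id: str
    level: str
    association: AssociationResult
    isolate_metrics: MetricSet
    sc_metrics: MetricSet | None = None
    isolate_ci: BootstrapCI | None = None
    sc_ci: BootstrapCI | None = None
    annotation: str | None = None
    sc_concordance: float | None = None


@dataclass
class Selection:
    """Outcome of strongest-predictor selection for one K-locus."""

    k_locus: str
    chosen: PredictorEvidence | None
    rule_trail: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class CurationRules:
    """Thresholds of the strong/likely curation layer (reconstruction defaults)."""

    min_precision: float = 0.8
    min_f1: float = 0.5
    min_mcc: float = 0.5
    min_sc_precision: float = 0.8
    min_concordance: float = 0.5
    likely_min_recall: float = 0.2


@dataclass
class CurationCall:
    category: str  # strong | likely | none
    reasons: list[str] = field(default_factory=list)


def strongest_per_locus(
    evidence: Sequence[PredictorEvidence],
    min_precision: float = 0.8,
    min_f1: float = 0.5,
    min_mcc: float = 0.5,
) -> Selection:
    """Pick the strongest predictor for one K-locus across all resolutions.

    Filter to isolate precision >= ``min_precision``; among survivors take
    the argmax of F1 x MCC; report it only if its F1 and MCC both clear
    their gates, else the selection is empty.
    """
    if not evidence:
        return Selection(k_locus="", chosen=None, rule_trail=["no candidates"])
    loci = {e.k_locus for e in evidence}
    if len(loci) != 1:
        raise ValueError(f"evidence mixes K-loci: {sorted(loci)}")
    k_locus = loci.pop()
    trail: list[str] = []

    survivors = []
    for e in evidence:
        if e.isolate_metrics.precision >= min_precision:
            survivors.append(e)
        else:
            trail.append(
                f"{e.level}/{e.cluster_id}: precision "
                f"{e.isolate_metrics.precision:.3f} < {min_precision}"
            )
    if not survivors:
        trail.append("no candidate passed the precision gate")
        return Selection(k_locus=k_locus, chosen=None, rule_trail=trail)

    def sort_key(e: PredictorEvidence):
        m = e.isolate_metrics
        return (-(m.f1 * m.mcc), -m.precision, -m.recall, e.level, e.cluster_id)

    best = sorted(survivors, key=sort_key)[0]
    m = best.isolate_metrics
    trail.append(
        f"argmax F1*MCC: {best.level}/{best.cluster_id} "
        f"(F1={m.f1:.3f}, MCC={m.mcc:.3f}, product={m.f1 * m.mcc:.3f})"
    )
    if m.f1 < min_f1 or m.mcc < min_mcc:
        trail.append(
            f"final gate failed: F1 {m.f1:.3f} >= {min_f1} and MCC {m.mcc:.3f} >= "
            f"{min_mcc} required"
        )
        return Selection(k_locus=k_locus, chosen=None, rule_trail=trail)
    trail.append("final gate passed")
    return Selection(k_locus=k_locus, chosen=best, rule_trail=trail)


def sc_concordance(
    predictor: Sequence[int],
    klocus: Sequence[int],
    sc_labels: Sequence[str],
) -> tuple[float, bool]:
    """Jaccard overlap of predictor-positive and K-positive SC sets.

    Returns (score, defined).  Both sets empty is scored 0 and flagged
    undefined.
    """
    p = np.asarray(predictor, dtype=bool)
    k = np.asarray(klocus, dtype=bool)
    scs = np.asarray(sc_labels)
    if not (len(p) == len(k) == len(scs)):
        raise ValueError("inputs must be equal length")
    p_set = set(scs[p])
    k_set = set(scs[k])
    union = p_set | k_set
    if not union:
        return 0.0, False
    return len(p_set & k_set) / len(union), True


def curate(evidence: PredictorEvidence,
           rules: CurationRules | None = None) -> CurationCall:
    """Grade one predictor as strong, likely or none.

    strong: retained by GWAS, isolate and SC precision both >= 0.8, F1 and
    MCC >= 0.5, SC-concordance >= 0.5.  likely: retained by GWAS and
    isolate precision >= 0.8 with recall >= 0.2 at either level, or all
    strong metric gates pass at isolate level only.  Every rule outcome is
    logged in ``reasons``.
    """
    rules = rules or CurationRules()
    for name in ("association", "isolate_metrics", "sc_metrics", "sc_concordance"):
        if getattr(evidence, name) is None:
            raise ValueError(f"curation requires evidence field {name!r}")
    reasons: list[str] = []
    im, sm = evidence.isolate_metrics, evidence.sc_metrics

    def check(label: str, ok: bool) -> bool:
        reasons.append(f"{label}: {'pass' if ok else 'fail'}")
        return ok

    retained = check("retained by GWAS", evidence.association.significant)
    iso_prec = check(
        f"isolate precision >= {rules.min_precision}",
        im.precision >= rules.min_precision,
    )
    sc_prec = check(
        f"SC precision >= {rules.min_sc_precision}",
        sm.precision >= rules.min_sc_precision,
    )
    f1_ok = check(f"F1 >= {rules.min_f1}", im.f1 >= rules.min_f1)
    mcc_ok = check(f"MCC >= {rules.min_mcc}", im.mcc >= rules.min_mcc)
    conc_ok = check(
        f"SC concordance >= {rules.min_concordance}",
        evidence.sc_concordance >= rules.min_concordance,
    )
    if retained and iso_prec and sc_prec and f1_ok and mcc_ok and conc_ok:
        reasons.append("category: strong")
        return CurationCall(category="strong", reasons=reasons)

    recall_ok = check(
        f"recall >= {rules.likely_min_recall} at either level",
        im.recall >= rules.likely_min_recall or sm.recall >= rules.likely_min_recall,
    )
    if retained and iso_prec and (recall_ok or (f1_ok and mcc_ok)):
        reasons.append("category: likely")
        return CurationCall(category="likely", reasons=reasons)
    reasons.append("category: none")
    return CurationCall(category="none", reasons=reasons)
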