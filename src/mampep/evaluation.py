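"""Evaluation metrics and reports.

Classification quality uses the area under the ROC curve in its
Mann-Whitney formulation (ties count one half) and Spearman's rank
correlation; generated peptides are judged by the high-affinity rate, the
fraction whose (oracle-)scored IC50 falls below the 500 nM binder cutoff;
motif extraction is quantified by the fraction of true anchor sites
recovered among the top-scoring sites.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .mam import site_scores_ensemble, site_summary
from .network import Ensemble, predict_ensemble
from .peptide_io import BINDER_THRESHOLD_NM, Dataset
from .synthetic import SyntheticAllele, oracle_ic50

__all__ = ["EvalReport", "auc", "srcc", "high_affinity_rate",
           "motif_recovery", "run_report"]


def auc(labels, scores) -> float:
    """Probability that a random positive outscores a random negative.

    Mann-Whitney formulation; tied scores count 1/2. Requires both classes.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: only one class present")
    return float(roc_auc_score(labels, scores))


def srcc(x, y) -> float:
    """Spearman's rank correlation (Pearson correlation of mid-ranks)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("inputs must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("SRCC undefined for a constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def high_affinity_rate(ic50s, threshold: float = BINDER_THRESHOLD_NM) -> float:
    """Fraction of IC50 values strictly below ``threshold`` (nM)."""
    ic50s = np.asarray(ic50s, dtype=np.float64)
    if ic50s.size == 0:
        raise ValueError("empty input")
    return float(np.mean(ic50s < threshold))


def motif_recovery(site_means, true_anchors) -> float:
    """Fraction of true anchors among the top-|anchors| sites by mean score.

    Ties resolve toward the lower site index. Sites are 1-based.
    """
    means = np.asarray(site_means, dtype=np.float64)
    anchors = set(int(a) for a in true_anchors)
    if not anchors:
        raise ValueError("empty anchor set")
    if len(anchors) > means.size:
        raise ValueError("more anchors than sites")
    order = np.lexsort((np.arange(means.size), -means))   # descending, leftmost ties
    top = set((order[:len(anchors)] + 1).tolist())
    return len(top & anchors) / len(anchors)


@dataclass
class EvalReport:
    """Bundle of evaluation metrics plus a configuration echo."""

    auc: float
    srcc: float
    n: int
    srcc_target: str = "labels"
    high_affinity_rate: Optional[float] = None
    motif_recovery: Optional[float] = None
    config: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        doc = {k: v for k, v in self.__dict__.items() if v is not None}
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "EvalReport":
        p = Path(str(source))
        doc = json.loads(p.read_text() if p.exists() else str(source))
        return cls(**doc)


def run_report(ensemble: Ensemble, test: Dataset,
               allele: Optional[SyntheticAllele] = None,
               generated=None, config: Optional[dict] = None) -> EvalReport:
    """Evaluate an ensemble on a labeled test set.

    SRCC pairs the predicted probability with -log(IC50) when affinities are
    present (continuous ranking) and with the binary labels otherwise; the
    choice is echoed in the report. When a ground-truth allele and a
    generated set are supplied, the high-affinity rate of the mutants is
    scored with the oracle. Motif recovery is reported when the allele is
    given and the test set has uniform length: the top mean-score sites over
    true binders are compared with the allele's anchors.
    """
    probs = predict_ensemble(ensemble, test)
    labels = test.labels()
    report_auc = auc(labels, probs)
    if test.has_ic50():
        target, target_name = -np.log(test.ic50s()), "-log(ic50)"
    else:
        target, target_name = labels.astype(float), "labels"
    report_srcc = srcc(probs, target)

    rate = None
    if generated is not None and allele is not None:
        seqs = [g.generated for g in generated]
        if seqs:
            rate = high_affinity_rate([oracle_ic50(allele, s).ic50 for s in seqs])

    recovery = None
    if allele is not None and len(test.lengths()) == 1:
        binders = test.subset([i for i, r in enumerate(test) if r.label == 1])
        if len(binders) > 0:
            mat = site_scores_ensemble(ensemble, binders)
            means = site_summary(mat)["mean"].to_numpy()
            recovery = motif_recovery(means, allele.anchors)

    return EvalReport(
        auc=report_auc, srcc=report_srcc, n=len(test),
        srcc_target=target_name, high_affinity_rate=rate,
        motif_recovery=recovery, config=config or {},
    )
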