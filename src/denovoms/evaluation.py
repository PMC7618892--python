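"""Peptide-spectrum-match evaluation: residue/peptide precision-recall,
confidence-sweep PR curves, the surrogate FDR confidence threshold, and a
coarse error taxonomy.

Residue matching is mass-based, not string-based: a predicted residue
matches the aligned true residue when their masses differ by less than a
residue tolerance AND the aligned cumulative (prefix) masses differ by at
most a prefix tolerance, evaluated from both termini with the union taken.
Isobaric substitutions (I/L; deamidated-N vs D) therefore do not count as
errors, which is standard practice in de novo sequencing benchmarks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np

from .chemistry import ResidueVocabulary
from .knapsack import Prediction
from .ms_io import AnnotatedPSM

logger = logging.getLogger(__name__)

__all__ = [
    "AA_MASS_TOL",
    "PREFIX_MASS_TOL",
    "aa_matches",
    "peptide_match",
    "MetricReport",
    "compute_metrics",
    "PRCurve",
    "pr_curve",
    "fdr_threshold",
    "classify_errors",
    "ERROR_CLASSES",
]

AA_MASS_TOL = 0.1  # Da, residue-level match tolerance
PREFIX_MASS_TOL = 0.5  # Da, cumulative-mass alignment tolerance


def _match_pass(
    pred_m: np.ndarray, true_m: np.ndarray, aa_tol: float, prefix_tol: float
) -> np.ndarray:
    """One directional pass: flags over predicted positions."""
    n = min(pred_m.size, true_m.size)
    flags = np.zeros(pred_m.size, dtype=bool)
    cum_p = np.cumsum(pred_m)
    cum_t = np.cumsum(true_m)
    for i in range(n):
        if (
            abs(pred_m[i] - true_m[i]) < aa_tol
            and abs(cum_p[i] - cum_t[i]) <= prefix_tol
        ):
            flags[i] = True
    return flags


def aa_matches(
    pred: Sequence[str],
    truth: Sequence[str],
    vocab: ResidueVocabulary,
    aa_tol: float = AA_MASS_TOL,
    prefix_tol: float = PREFIX_MASS_TOL,
) -> Tuple[np.ndarray, int]:
    """Per-position match flags for the predicted residues, plus the count.

    Positions are aligned from the N terminus and again from the C
    terminus; a predicted residue counts as matched if either pass accepts
    it (the union), which credits correct subsequences on both sides of a
    local error.
    """
    if len(pred) == 0 or len(truth) == 0:
        raise ValueError("aa_matches requires non-empty sequences")
    pm = np.array([vocab.mass(t) for t in pred])
    tm = np.array([vocab.mass(t) for t in truth])
    fwd = _match_pass(pm, tm, aa_tol, prefix_tol)
    bwd = _match_pass(pm[::-1], tm[::-1], aa_tol, prefix_tol)[::-1]
    flags = fwd | bwd
    return flags, int(flags.sum())


def peptide_match(
    pred: Sequence[str], truth: Sequence[str], vocab: ResidueVocabulary
) -> bool:
    """Full-length match under the mass rule (lengths equal, all matched)."""
    if len(pred) != len(truth) or len(pred) == 0:
        return False
    _, n = aa_matches(pred, truth, vocab)
    return n == len(pred)


@dataclass
class MetricReport:
    """Aggregate residue- and peptide-level metrics over a prediction set."""

    aa_precision: float
    aa_recall: float
    aa_error_rate: float
    peptide_precision: float
    peptide_recall: float
    peptide_accuracy: float
    n_psms: int
    n_predictions: int
    precision_defined: bool = True

    def to_dict(self) -> Dict:
        return asdict(self)


def compute_metrics(
    predictions: Iterable[Prediction],
    truths: Iterable[AnnotatedPSM],
    vocab: ResidueVocabulary,
) -> MetricReport:
    """Join predictions to ground truth by spectrum id and aggregate.

    Peptide recall divides full matches by the number of ground-truth
    PSMs; peptide precision divides by the number of predictions made.
    Residue-level metrics aggregate matched residues over predicted
    (precision) and true (recall) residue totals.
    """
    truth_map: Dict[str, Tuple[str, ...]] = {}
    for psm in truths:
        truth_map[psm.spectrum.id] = tuple(psm.peptide)
    preds: Dict[str, Prediction] = {}
    for p in predictions:
        if p.spectrum_id in preds:
            raise ValueError(f"duplicate prediction for spectrum {p.spectrum_id!r}")
        preds[p.spectrum_id] = p

    n_truths = len(truth_map)
    n_predictions = 0
    n_pep_correct = 0
    aa_matched = 0
    aa_pred_total = 0
    aa_true_total = 0
    for sid, pred in preds.items():
        if sid not in truth_map:
            continue
        n_predictions += 1
        truth = truth_map[sid]
        aa_pred_total += len(pred.peptide)
        aa_true_total += len(truth)
        if len(pred.peptide) == 0:
            continue
        _, n = aa_matches(pred.peptide, truth, vocab)
        aa_matched += n
        if n == len(pred.peptide) == len(truth):
            n_pep_correct += 1
    # truths with no prediction still count in recall denominators
    for sid, truth in truth_map.items():
        if sid not in preds:
            aa_true_total += len(truth)

    precision_defined = n_predictions > 0
    pep_prec = n_pep_correct / n_predictions if precision_defined else 0.0
    aa_prec = aa_matched / aa_pred_total if aa_pred_total else 0.0
    return MetricReport(
        aa_precision=aa_prec,
        aa_recall=aa_matched / aa_true_total if aa_true_total else 0.0,
        aa_error_rate=1.0 - aa_prec,
        peptide_precision=pep_prec,
        peptide_recall=n_pep_correct / n_truths if n_truths else 0.0,
        peptide_accuracy=pep_prec,
        n_psms=n_truths,
        n_predictions=n_predictions,
        precision_defined=precision_defined,
    )


@dataclass
class PRCurve:
    """Precision/recall pairs swept over descending confidence thresholds."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    auc: float

    def to_table(self) -> "np.ndarray":
        return np.column_stack([self.thresholds, self.precision, self.recall])


def _correctness(
    predictions: Sequence[Prediction],
    truths: Iterable[AnnotatedPSM],
    vocab: ResidueVocabulary,
) -> Tuple[np.ndarray, np.ndarray, int]:
    truth_map = {psm.spectrum.id: tuple(psm.peptide) for psm in truths}
    conf, correct = [], []
    for p in predictions:
        if p.spectrum_id not in truth_map:
            continue
        conf.append(p.confidence)
        correct.append(peptide_match(p.peptide, truth_map[p.spectrum_id], vocab))
    return np.asarray(conf, dtype=float), np.asarray(correct, dtype=bool), len(truth_map)


def pr_curve(
    predictions: Sequence[Prediction],
    truths: Sequence[AnnotatedPSM],
    vocab: ResidueVocabulary,
) -> PRCurve:
    """Peptide-level precision-recall curve over the confidence sweep.

    Thresholds run from the highest observed confidence (retaining at
    least one prediction) to the lowest (retaining all); the area under
    the curve is the recall-axis trapezoid, anchored at recall 0.
    """
    conf, correct, n_truths = _correctness(predictions, truths, vocab)
    if conf.size == 0:
        raise ValueError("no predictions join to the ground truth")
    order = np.argsort(-conf, kind="stable")
    conf, correct = conf[order], correct[order]
    thresholds = np.unique(conf)[::-1]
    precision, recall = [], []
    for thr in thresholds:
        keep = conf >= thr
        k = int(keep.sum())
        c = int(correct[keep].sum())
        precision.append(c / k)
        recall.append(c / n_truths)
    precision = np.asarray(precision)
    recall = np.asarray(recall)
    auc = float(np.trapezoid(np.concatenate([[precision[0]], precision]),
                             np.concatenate([[0.0], recall])))
    return PRCurve(thresholds=thresholds, precision=precision, recall=recall, auc=auc)


def fdr_threshold(
    predictions: Sequence[Prediction],
    truths: Sequence[AnnotatedPSM],
    vocab: ResidueVocabulary,
    target_fdr: float = 0.05,
) -> Optional[float]:
    """Surrogate-FDR confidence cutoff.

    Returns the lowest confidence c such that among predictions with
    confidence >= c the fraction disagreeing with the reference peptide is
    <= target_fdr, or None when no cutoff achieves the target. This is a
    surrogate computed against database-search-style ground truth, NOT a
    target-decoy FDR.
    """
    conf, correct, _ = _correctness(predictions, truths, vocab)
    if conf.size == 0 or not correct.any():
        logger.warning("fdr_threshold: no correct predictions; no cutoff exists")
        return None
    order = np.argsort(-conf, kind="stable")
    conf, correct = conf[order], correct[order]
    cum_err = np.cumsum(~correct)
    cum_n = np.arange(1, conf.size + 1)
    best: Optional[float] = None
    # candidate cutoffs are the observed confidences; at ties take the
    # last index of the tied block (the full "fraction >= c")
    for i in range(conf.size):
        if i + 1 < conf.size and conf[i + 1] == conf[i]:
            continue
        if cum_err[i] / cum_n[i] <= target_fdr:
            best = float(conf[i])
    if best is None:
        logger.warning(
            "fdr_threshold: no confidence cutoff reaches FDR <= %.3g", target_fdr
        )
        return None
    empirical = cum_err[conf >= best][-1] / cum_n[conf >= best][-1]
    assert empirical <= target_fdr
    return best


ERROR_CLASSES = (
    "1 AA substitution",
    "2 AA errors",
    ">2 AA errors",
    "length mismatch",
    "precursor-mass mismatch",
)


def classify_errors(
    pred: Sequence[str], truth: Sequence[str], vocab: ResidueVocabulary
) -> str:
    """Assign a wrong prediction to one error class.

    Classes are mutually exclusive and evaluated in order: equal-length
    predictions are binned by their number of unmatched residues (1, 2,
    >2 under the mass rule); unequal lengths are a length mismatch; the
    residual bucket (e.g. an empty prediction) is a precursor-mass
    mismatch.
    """
    if len(pred) == len(truth) and len(pred) > 0:
        _, n = aa_matches(pred, truth, vocab)
        n_err = len(pred) - n
        if n_err == 0:
            raise ValueError("classify_errors called on a full match")
        if n_err == 1:
            return ERROR_CLASSES[0]
        if n_err == 2:
            return ERROR_CLASSES[1]
        return ERROR_CLASSES[2]
    if len(pred) != len(truth) and len(pred) > 0:
        return ERROR_CLASSES[3]
    return ERROR_CLASSES[4]
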