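"""Instance-level evaluation: subcomponent matching and micro-averaged P/R/F1.

Predictions are matched to gold annotations per note by canonical
medication name (the gold protocol is name-anchored, not span-anchored).
Within a matched pair each subcomponent present in gold scores a true
positive if equal and a false negative otherwise (plus a false positive
if the prediction offered a different value); a predicted subcomponent
absent from gold is a false positive.  A whole instance is correct only
if every gold-presented subcomponent is correctly extracted and the
prediction presents nothing spurious.  Symptoms are scored as per-note
multisets of canonicals.  Scores are micro-averages of counts aggregated
over the corpus, with the 0/0 -> 0 convention for degenerate ratios.

One deliberate exemption: a predicted date whose provenance is
``note-date-default`` (the authorship-date fallback attached when a
sentence states no date) is treated as *no extracted date*, since it is
an imputation rather than an extraction.
"""

from __future__ import annotations

import json
import logging
import math
from collections import Counter
import datetime as dt
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

from pydantic import BaseModel, Field

from pghdkit.corpus import ExtractionResult
from pghdkit.extract import MedicationInstance
from pghdkit.lexicon import normalize_term

logger = logging.getLogger(__name__)

COMPONENTS = ("medication_instance", "medication", "unit", "quantity", "date", "symptom")


class GoldWhen(BaseModel):
    date: Optional[dt.date] = None
    time_of_day: Optional[dt.time] = None


class GoldInstance(BaseModel):
    medication: str  # canonical name
    quantity: Optional[float] = None
    unit: Optional[str] = None  # canonical unit
    when: Optional[GoldWhen] = None


class GoldAnnotation(BaseModel):
    note_id: str
    instances: List[GoldInstance] = []
    symptoms: List[str] = []  # canonicals, with multiplicity


class ConfusionCounts(BaseModel):
    tp: int = Field(0, ge=0)
    fp: int = Field(0, ge=0)
    fn: int = Field(0, ge=0)

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            tp=self.tp + other.tp, fp=self.fp + other.fp, fn=self.fn + other.fn
        )


class ComponentMetrics(BaseModel):
    precision: float
    recall: float
    f1: float
    notes_n: int
    instances_n: int
    counts: ConfusionCounts


class MetricsReport(BaseModel):
    components: Dict[str, ComponentMetrics]

    def to_tsv(self) -> str:
        lines = ["component\tprecision\trecall\tf1\tnotes_n\tinstances_n"]
        for name in COMPONENTS:
            m = self.components[name]
            lines.append(
                f"{name}\t{m.precision:.2f}\t{m.recall:.2f}\t{m.f1:.2f}"
                f"\t{m.notes_n}\t{m.instances_n}"
            )
        return "\n".join(lines) + "\n"


def prf(counts: ConfusionCounts) -> Tuple[float, float, float]:
    """Precision, recall, F1 from confusion counts; 0/0 ratios yield 0."""
    if counts.tp + counts.fp == 0:
        logger.debug("prf: empty prediction denominator, precision = 0 by convention")
        p = 0.0
    else:
        p = counts.tp / (counts.tp + counts.fp)
    if counts.tp + counts.fn == 0:
        logger.debug("prf: empty gold denominator, recall = 0 by convention")
        r = 0.0
    else:
        r = counts.tp / (counts.tp + counts.fn)
    f1 = 0.0 if p + r == 0 else 2 * p * r / (p + r)
    return p, r, f1


def _effective_when(inst: MedicationInstance) -> Tuple[Optional[dt.date], Optional[dt.time]]:
    """Predicted (date, time) with the note-date-default imputation removed."""
    w = inst.when
    if w is None:
        return None, None
    d = w.date if w.provenance != "note-date-default" else None
    return d, w.time_of_day


def _gold_when(g: GoldInstance) -> Tuple[Optional[dt.date], Optional[dt.time]]:
    if g.when is None:
        return None, None
    return g.when.date, g.when.time_of_day


def _qty_equal(a: Optional[float], b: Optional[float]) -> bool:
    if a is None or b is None:
        return a is None and b is None
    return math.isclose(a, b, rel_tol=1e-9, abs_tol=1e-9)


def instance_correct(pred: MedicationInstance, gold: GoldInstance) -> bool:
    """All-subcomponents rule: correct iff every gold-presented
    subcomponent is present and equal in the prediction and the
    prediction presents no subcomponent absent from gold."""
    if normalize_term(pred.medication.canonical) != normalize_term(gold.medication):
        return False
    if not _qty_equal(pred.quantity, gold.quantity):
        return False
    pred_unit = normalize_term(pred.unit.canonical) if pred.unit else None
    gold_unit = normalize_term(gold.unit) if gold.unit else None
    if pred_unit != gold_unit:
        return False
    return _effective_when(pred) == _gold_when(gold)


def _score_subcomponent(counts, present_gold, present_pred, equal) -> None:
    if present_gold and present_pred:
        if equal:
            counts.tp += 1
        else:
            counts.fp += 1
            counts.fn += 1
    elif present_gold:
        counts.fn += 1
    elif present_pred:
        counts.fp += 1


def match_note(pred: ExtractionResult, gold: GoldAnnotation) -> Dict[str, ConfusionCounts]:
    """Score one note: per-component confusion counts.

    Predicted instances are paired with gold instances sharing the same
    canonical medication name, in text/list order within each name.
    """
    if pred.note_id != gold.note_id:
        raise ValueError(f"note_id mismatch: {pred.note_id!r} vs {gold.note_id!r}")
    counts = {name: ConfusionCounts() for name in COMPONENTS}

    by_name_pred: Dict[str, List[MedicationInstance]] = {}
    for inst in pred.medication_instances:
        by_name_pred.setdefault(normalize_term(inst.medication.canonical), []).append(inst)
    by_name_gold: Dict[str, List[GoldInstance]] = {}
    for g in gold.instances:
        by_name_gold.setdefault(normalize_term(g.medication), []).append(g)

    matched: List[Tuple[MedicationInstance, GoldInstance]] = []
    unmatched_pred: List[MedicationInstance] = []
    unmatched_gold: List[GoldInstance] = []
    for name in set(by_name_pred) | set(by_name_gold):
        ps = by_name_pred.get(name, [])
        gs = by_name_gold.get(name, [])
        k = min(len(ps), len(gs))
        matched.extend(zip(ps[:k], gs[:k]))
        unmatched_pred.extend(ps[k:])
        unmatched_gold.extend(gs[k:])

    for p, g in matched:
        counts["medication"].tp += 1
        _score_subcomponent(
            counts["quantity"], g.quantity is not None, p.quantity is not None,
            _qty_equal(p.quantity, g.quantity),
        )
        p_unit = normalize_term(p.unit.canonical) if p.unit else None
        g_unit = normalize_term(g.unit) if g.unit else None
        _score_subcomponent(
            counts["unit"], g_unit is not None, p_unit is not None, p_unit == g_unit
        )
        g_when = _gold_when(g)
        p_when = _effective_when(p)
        _score_subcomponent(
            counts["date"],
            g_when != (None, None),
            p_when != (None, None),
            p_when == g_when,
        )
        if instance_correct(p, g):
            counts["medication_instance"].tp += 1
        else:
            counts["medication_instance"].fp += 1
            counts["medication_instance"].fn += 1

    for p in unmatched_pred:
        counts["medication"].fp += 1
        counts["medication_instance"].fp += 1
        if p.quantity is not None:
            counts["quantity"].fp += 1
        if p.unit is not None:
            counts["unit"].fp += 1
        if _effective_when(p) != (None, None):
            counts["date"].fp += 1
    for g in unmatched_gold:
        counts["medication"].fn += 1
        counts["medication_instance"].fn += 1
        if g.quantity is not None:
            counts["quantity"].fn += 1
        if g.unit is not None:
            counts["unit"].fn += 1
        if _gold_when(g) != (None, None):
            counts["date"].fn += 1

    pred_syms = Counter(
        normalize_term(s.symptom.canonical) for s in pred.symptom_mentions
    )
    gold_syms = Counter(normalize_term(s) for s in gold.symptoms)
    inter = sum((pred_syms & gold_syms).values())
    counts["symptom"].tp += inter
    counts["symptom"].fp += sum(pred_syms.values()) - inter
    counts["symptom"].fn += sum(gold_syms.values()) - inter
    return counts


def _gold_component_sizes(golds: Sequence[GoldAnnotation]) -> Dict[str, Tuple[int, int]]:
    sizes = {}
    predicates = {
        "medication_instance": lambda g: True,
        "medication": lambda g: True,
        "unit": lambda g: g.unit is not None,
        "quantity": lambda g: g.quantity is not None,
        "date": lambda g: _gold_when(g) != (None, None),
    }
    for name, pred_fn in predicates.items():
        notes_n = sum(1 for g in golds if any(pred_fn(i) for i in g.instances))
        inst_n = sum(sum(1 for i in g.instances if pred_fn(i)) for g in golds)
        sizes[name] = (notes_n, inst_n)
    sizes["symptom"] = (
        sum(1 for g in golds if g.symptoms),
        sum(len(g.symptoms) for g in golds),
    )
    return sizes


def evaluate_corpus(
    preds: Sequence[ExtractionResult], golds: Sequence[GoldAnnotation]
) -> MetricsReport:
    """Aggregate per-note counts over the corpus and compute micro P/R/F1.

    A gold note without a prediction is scored against an empty
    prediction (with a warning); predictions for unknown note_ids are
    ignored with a warning.
    """
    pred_by_id = {}
    for p in preds:
        pred_by_id[p.note_id] = p
    gold_ids = {g.note_id for g in golds}
    for nid in pred_by_id:
        if nid not in gold_ids:
            logger.warning("prediction for note %s has no gold annotation; ignored", nid)

    totals = {name: ConfusionCounts() for name in COMPONENTS}
    for g in golds:
        p = pred_by_id.get(g.note_id)
        if p is None:
            logger.warning("gold note %s has no prediction; scoring as empty", g.note_id)
            p = ExtractionResult(note_id=g.note_id)
        note_counts = match_note(p, g)
        for name in COMPONENTS:
            totals[name] = totals[name] + note_counts[name]

    sizes = _gold_component_sizes(golds)
    components = {}
    for name in COMPONENTS:
        p_, r_, f1_ = prf(totals[name])
        notes_n, inst_n = sizes[name]
        components[name] = ComponentMetrics(
            precision=p_, recall=r_, f1=f1_, notes_n=notes_n, instances_n=inst_n,
            counts=totals[name],
        )
    return MetricsReport(components=components)


def write_gold(golds: Sequence[GoldAnnotation], path: Union[str, Path]) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for g in golds:
            fh.write(g.model_dump_json() + "\n")


def read_gold(path: Union[str, Path]) -> List[GoldAnnotation]:
    golds = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                golds.append(GoldAnnotation.model_validate_json(line))
    return golds


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def report_to_json(report: MetricsReport) -> str:
    return json.dumps(
        {
            name: {
                "precision": m.precision,
                "recall": m.recall,
                "f1": m.f1,
                "notes_n": m.notes_n,
                "instances_n": m.instances_n,
                "tp": m.counts.tp,
                "fp": m.counts.fp,
                "fn": m.counts.fn,
            }
            for name, m in report.components.items()
        },
        indent=2,
    )
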