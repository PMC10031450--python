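import random
from datetime import date, time

import pytest

from pghdkit.corpus import ExtractionResult
from pghdkit.extract import MedicationInstance, extract_corpus
from pghdkit.lexicon import EntityMention, Vocabulary
from pghdkit.metrics import (
    COMPONENTS,
    ConfusionCounts,
    GoldAnnotation,
    GoldInstance,
    GoldWhen,
    evaluate_corpus,
    instance_correct,
    match_note,
    prf,
    read_gold,
    write_gold,
)
from pghdkit.simulate import GeneratorConfig, generate_corpus
from pghdkit.temporal import ResolvedWhen


def _med_mention(canonical="Diphenhydramine", start=0, end=8):
    return EntityMention(
        start=start, end=end, surface=canonical[: end - start], vocabulary=Vocabulary.medication,
        concept_id="RX:1", canonical=canonical, sentence_index=0, head_token_index=0,
    )


def _unit_mention(canonical="ml"):
    return EntityMention(
        start=10, end=12, surface=canonical, vocabulary=Vocabulary.unit,
        concept_id="U:1", canonical=canonical, sentence_index=0, head_token_index=2,
    )


def _pred(instances, note_id="n1"):
    return ExtractionResult(note_id=note_id, medication_instances=instances)


def _inst(canonical="Diphenhydramine", quantity=None, unit=None, when=None):
    return MedicationInstance(
        medication=_med_mention(canonical),
        quantity=quantity,
        unit=_unit_mention(unit) if unit else None,
        when=when,
    )


WHEN_6AM = ResolvedWhen(raw="6:00 am", time_of_day=time(6, 0))


class TestPrf:
    def test_printed_precision_recall_reproduce_f1(self):
        p, r, f1 = prf(ConfusionCounts(tp=97, fp=3, fn=19))
        assert round(f1, 2) == 0.90

    @pytest.mark.parametrize(
        "tp,fp,fn,expected",
        [
            (0, 0, 0, (0.0, 0.0, 0.0)),
            (5, 5, 5, (0.5, 0.5, 0.5)),
            (1, 0, 0, (1.0, 1.0, 1.0)),
        ],
    )
    def test_examples(self, tp, fp, fn, expected):
        assert prf(ConfusionCounts(tp=tp, fp=fp, fn=fn)) == expected

    def test_matches_brute_force_on_random_grid(self):
        # independent arithmetic oracle on a random subset of the count grid
        rng = random.Random(0)
        for _ in range(300):
            tp, fp, fn = (rng.randrange(21) for _ in range(3))
            p, r, f1 = prf(ConfusionCounts(tp=tp, fp=fp, fn=fn))
            exp_p = tp / (tp + fp) if tp + fp else 0.0
            exp_r = tp / (tp + fn) if tp + fn else 0.0
            exp_f = 2 * exp_p * exp_r / (exp_p + exp_r) if exp_p + exp_r else 0.0
            assert (p, r, f1) == (exp_p, exp_r, exp_f)

    def test_f1_between_min_and_max_of_p_r(self):
        for tp, fp, fn in [(3, 1, 5), (10, 2, 0), (1, 9, 9)]:
            p, r, f1 = prf(ConfusionCounts(tp=tp, fp=fp, fn=fn))
            assert min(p, r) - 1e-12 <= f1 <= max(p, r) + 1e-12


class TestInstanceCorrect:
    def test_identity_is_correct(self):
        pred = _inst(quantity=2.0, when=WHEN_6AM)
        gold = GoldInstance(
            medication="Diphenhydramine", quantity=2.0,
            when=GoldWhen(time_of_day=time(6, 0)),
        )
        assert instance_correct(pred, gold)

    def test_missed_unit_is_wrong(self):
        pred = _inst(canonical="Gabapentin", quantity=2.6)
        gold = GoldInstance(medication="Gabapentin", quantity=2.6, unit="ml")
        assert not instance_correct(pred, gold)

    def test_spurious_subcomponent_is_wrong(self):
        pred = _inst(quantity=5.0)
        gold = GoldInstance(medication="Diphenhydramine")
        assert not instance_correct(pred, gold)

    def test_default_date_imputation_is_not_spurious(self):
        pred = _inst(
            quantity=2.0,
            when=ResolvedWhen(raw="", date=date(2020, 11, 5), provenance="note-date-default"),
        )
        gold = GoldInstance(medication="Diphenhydramine", quantity=2.0)
        assert instance_correct(pred, gold)

    def test_reflexive_on_pipeline_output(self, lexicons, backend):
        notes, _ = generate_corpus(GeneratorConfig(n_notes=15, seed=5))
        for result in extract_corpus(notes, lexicons, backend):
            for inst in result.medication_instances:
                mirror = GoldInstance(
                    medication=inst.medication.canonical,
                    quantity=inst.quantity,
                    unit=inst.unit.canonical if inst.unit else None,
                    when=GoldWhen(
                        date=inst.when.date if inst.when.provenance != "note-date-default" else None,
                        time_of_day=inst.when.time_of_day,
                    )
                    if inst.when and (inst.when.time_of_day or inst.when.provenance != "note-date-default")
                    and inst.when.status.value == "resolved"
                    else None,
                )
                assert instance_correct(inst, mirror)


class TestMatchNote:
    def test_identity_all_true_positives(self):
        pred = _pred([_inst(quantity=2.0, unit="ml", when=WHEN_6AM)])
        gold = GoldAnnotation(
            note_id="n1",
            instances=[
                GoldInstance(
                    medication="Diphenhydramine", quantity=2.0, unit="ml",
                    when=GoldWhen(time_of_day=time(6, 0)),
                )
            ],
        )
        counts = match_note(pred, gold)
        for name in ("medication_instance", "medication", "unit", "quantity", "date"):
            assert (counts[name].tp, counts[name].fp, counts[name].fn) == (1, 0, 0)

    def test_wrong_quantity_scores_fp_and_fn(self):
        pred = _pred([_inst(quantity=3.0)])
        gold = GoldAnnotation(
            note_id="n1", instances=[GoldInstance(medication="Diphenhydramine", quantity=2.0)]
        )
        counts = match_note(pred, gold)
        assert (counts["quantity"].fp, counts["quantity"].fn) == (1, 1)
        assert counts["medication"].tp == 1
        assert counts["medication_instance"].tp == 0

    def test_spurious_medication_is_false_positive(self):
        pred = _pred([_inst(canonical="Water")])
        gold = GoldAnnotation(note_id="n1", instances=[])
        counts = match_note(pred, gold)
        assert counts["medication"].fp == 1
        assert counts["medication"].tp == 0

    def test_missed_medication_is_false_negative(self):
        pred = _pred([])
        gold = GoldAnnotation(note_id="n1", instances=[GoldInstance(medication="Gabapentin")])
        counts = match_note(pred, gold)
        assert counts["medication"].fn == 1

    def test_symptoms_scored_as_multisets(self):
        pred = ExtractionResult(note_id="n1")
        gold = GoldAnnotation(note_id="n1", symptoms=["Fever", "Fever", "Cough"])
        counts = match_note(pred, gold)
        assert counts["symptom"].fn == 3

    def test_note_id_mismatch_is_hard_error(self):
        with pytest.raises(ValueError, match="note_id"):
            match_note(ExtractionResult(note_id="a"), GoldAnnotation(note_id="b"))


class TestEvaluateCorpus:
    def _identity_setup(self, n=20, seed=9):
        notes, golds = generate_corpus(GeneratorConfig(n_notes=n, seed=seed))
        return notes, golds

    def test_identity_pred_equals_gold_is_perfect(self, lexicons, backend):
        # pseudo-predictions constructed directly from gold
        _, golds = self._identity_setup()
        preds = []
        for g in golds:
            insts = [
                _inst(
                    canonical=i.medication,
                    quantity=i.quantity,
                    unit=i.unit,
                    when=ResolvedWhen(
                        raw="x", date=i.when.date if i.when else None,
                        time_of_day=i.when.time_of_day if i.when else None,
                    )
                    if i.when
                    else None,
                )
                for i in g.instances
            ]
            preds.append(
                ExtractionResult(
                    note_id=g.note_id,
                    medication_instances=insts,
                    symptom_mentions=[],
                )
            )
        golds_no_sym = [
            GoldAnnotation(note_id=g.note_id, instances=g.instances) for g in golds
        ]
        report = evaluate_corpus(preds, golds_no_sym)
        for name in ("medication_instance", "medication", "unit", "quantity", "date"):
            m = report.components[name]
            if m.instances_n:
                assert (m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0)

    def test_empty_predictions_give_zero_scores(self):
        _, golds = self._identity_setup()
        report = evaluate_corpus([], golds)
        med = report.components["medication"]
        assert med.precision == 0.0 and med.recall == 0.0

    def test_order_invariance_and_count_aggregation(self, lexicons, backend):
        notes, golds = self._identity_setup(n=30, seed=10)
        preds = extract_corpus(notes, lexicons, backend)
        r1 = evaluate_corpus(preds, golds)
        r2 = evaluate_corpus(list(reversed(preds)), list(reversed(golds)))
        assert r1 == r2
        # splitting the corpus and summing counts gives the same totals
        half = len(golds) // 2
        ra = evaluate_corpus(preds[:half], golds[:half])
        rb = evaluate_corpus(preds[half:], golds[half:])
        for name in COMPONENTS:
            combined = ra.components[name].counts + rb.components[name].counts
            assert combined == r1.components[name].counts

    def test_gold_sizes_count_notes_and_instances(self):
        golds = [
            GoldAnnotation(
                note_id="a",
                instances=[
                    GoldInstance(medication="Gabapentin", quantity=2.6, unit="ml"),
                    GoldInstance(medication="Gabapentin", quantity=2.0, unit="ml"),
                ],
            ),
            GoldAnnotation(note_id="b", symptoms=["Fever"]),
        ]
        report = evaluate_corpus([], golds)
        assert report.components["medication"].notes_n == 1
        assert report.components["medication"].instances_n == 2
        assert report.components["unit"].instances_n == 2
        assert report.components["symptom"].notes_n == 1
        assert report.components["symptom"].instances_n == 1

    def test_tsv_rendering_shape(self):
        _, golds = self._identity_setup(n=5, seed=2)
        tsv = evaluate_corpus([], golds).to_tsv()
        lines = tsv.strip().split("\n")
        assert lines[0].split("\t") == [
            "component", "precision", "recall", "f1", "notes_n", "instances_n",
        ]
        assert len(lines) == 1 + len(COMPONENTS)


def test_gold_round_trip(tmp_path):
    _, golds = generate_corpus(GeneratorConfig(n_notes=12, seed=4))
    p = tmp_path / "gold.jsonl"
    write_gold(golds, p)
    assert read_gold(p) == golds
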