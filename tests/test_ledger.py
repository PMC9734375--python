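"""Event-log behaviour: transfection registration, template reuse,
activity validation, reagent arithmetic, filtering, and replay
determinism."""

import datetime as dt

import pytest

from clonetrack import errors
from clonetrack.ledger import (
    Ledger,
    ReagentInput,
    TransfectionMetadata,
    reagent_volumes,
)
from clonetrack.naming import SampleName, parse_well
from clonetrack.vocab import default_vocabulary

D = dt.date


class TestNewTransfection:
    def test_registers_designator_and_transfect_record(self, fresh_ledger, meta_factory):
        designator = fresh_ledger.new_transfection(meta_factory(), D(2020, 1, 13))
        assert designator == "20200113mChOCT4sg2"
        assert designator in fresh_ledger.registry
        assert fresh_ledger.records[-1].activity == "Transfect"

    def test_duplicate_designator_rejected(self, fresh_ledger, meta_factory):
        fresh_ledger.new_transfection(meta_factory())
        with pytest.raises(errors.UniquenessError):
            fresh_ledger.new_transfection(meta_factory())

    def test_three_distinct_calls_three_transfect_records(self, fresh_ledger, meta_factory):
        for day in (13, 14, 15):
            fresh_ledger.new_transfection(meta_factory(date=D(2020, 1, day)))
        table = fresh_ledger.filter_records(lambda r: r.activity == "Transfect")
        assert len(table) == 3

    def test_unknown_fp_token_rejected(self, fresh_ledger, meta_factory):
        with pytest.raises(errors.ValidationError):
            fresh_ledger.new_transfection(meta_factory(fp="tdTom"))

    def test_guide_mismatch_rejected(self, fresh_ledger):
        meta = TransfectionMetadata(
            name=SampleName(D(2020, 1, 13), "mCh", "OCT4", "sg2"),
            guide_rna="sg9",
        )
        with pytest.raises(errors.ValidationError):
            fresh_ledger.new_transfection(meta)


class TestTemplateReuse:
    def test_clone_carries_constructs_with_new_date(self, fresh_ledger, meta_factory):
        src = meta_factory()
        src.notes = "original notes"
        src.attachments = ["counter.png"]
        fresh_ledger.new_transfection(src)
        copy = fresh_ledger.clone_transfection_template(
            "20200113mChOCT4sg2", D(2020, 1, 20)
        )
        assert copy.designator == "20200120mChOCT4sg2"
        assert copy.notes == "" and copy.attachments == []
        assert copy.guide_rna == src.guide_rna

    def test_copy_is_independent_of_source(self, fresh_ledger, meta_factory):
        fresh_ledger.new_transfection(meta_factory())
        copy = fresh_ledger.clone_transfection_template(
            "20200113mChOCT4sg2", D(2020, 1, 20)
        )
        copy.plasmid_components.append("extra")
        assert "extra" not in fresh_ledger.metadata["20200113mChOCT4sg2"].plasmid_components

    def test_registering_the_copy_adds_a_second_root(self, fresh_ledger, meta_factory):
        fresh_ledger.new_transfection(meta_factory())
        copy = fresh_ledger.clone_transfection_template(
            "20200113mChOCT4sg2", D(2020, 1, 20)
        )
        fresh_ledger.new_transfection(copy)
        assert len(fresh_ledger.registry.roots()) == 2

    def test_unknown_source(self, fresh_ledger):
        with pytest.raises(errors.LookupError_):
            fresh_ledger.clone_transfection_template("nope", D(2020, 1, 20))


class TestRecordActivity:
    def test_appends_with_increasing_seq(self, fresh_ledger, meta_factory):
        d = fresh_ledger.new_transfection(meta_factory())
        r1 = fresh_ledger.record_activity(D(2020, 1, 16), d, "Image")
        r2 = fresh_ledger.record_activity(D(2020, 1, 14), d, "Feed w Ri")
        assert r2.seq == r1.seq + 1  # retroactive date, still later seq

    def test_invalid_activity(self, fresh_ledger, meta_factory):
        d = fresh_ledger.new_transfection(meta_factory())
        with pytest.raises(errors.ValidationError):
            fresh_ledger.record_activity(D(2020, 1, 16), d, "Vortex")

    def test_unknown_sample(self, fresh_ledger):
        with pytest.raises(errors.LookupError_):
            fresh_ledger.record_activity(D(2020, 1, 16), "ghost", "Image")

    def test_discontinued_sample_warns_but_records(self, fresh_ledger, meta_factory):
        d = fresh_ledger.new_transfection(meta_factory())
        clone = fresh_ledger.designate_clone(D(2020, 1, 16), d, parse_well("C6"))
        fresh_ledger.record_activity(D(2020, 1, 18), clone, "Discontinue")
        record = fresh_ledger.record_activity(D(2020, 1, 20), clone, "Freeze")
        assert record.warnings
        assert fresh_ledger.records[-1] is record

    def test_future_dated_entries_allowed(self, fresh_ledger, meta_factory):
        d = fresh_ledger.new_transfection(meta_factory())
        record = fresh_ledger.record_activity(
            D(2030, 1, 1), d, "Passage", planned=True
        )
        assert record.planned


class TestReagentPlan:
    def test_volume_is_amount_over_concentration(self):
        meta = TransfectionMetadata(
            name=SampleName(D(2020, 1, 13), "mCh", "OCT4", "sg2"),
            reagent_inputs=[ReagentInput("donor", 100.0, 500.0)],
        )
        plan = reagent_volumes(meta)
        assert plan.volumes == (("donor", 5.0),)
        assert plan.total_volume == 5.0
        assert plan.warnings == ()

    def test_capacity_warning(self):
        meta = TransfectionMetadata(
            name=SampleName(D(2020, 1, 13), "mCh", "OCT4", "sg2"),
            reagent_inputs=[
                ReagentInput("a", 10.0, 700.0),
                ReagentInput("b", 10.0, 500.0),
            ],
            vessel_capacity=100.0,
        )
        plan = reagent_volumes(meta)
        assert plan.total_volume == pytest.approx(120.0)
        assert plan.warnings

    def test_empty_reagent_list(self):
        meta = TransfectionMetadata(
            name=SampleName(D(2020, 1, 13), "mCh", "OCT4", "sg2")
        )
        plan = reagent_volumes(meta)
        assert plan.total_volume == 0 and plan.warnings == ()

    def test_nonpositive_concentration(self):
        meta = TransfectionMetadata(
            name=SampleName(D(2020, 1, 13), "mCh", "OCT4", "sg2"),
            reagent_inputs=[ReagentInput("bad", 0.0, 500.0)],
        )
        with pytest.raises(errors.ArithmeticDomainError):
            reagent_volumes(meta)


class TestFilterAndReplay:
    def test_filter_equals_brute_force_scan(self, replica):
        ledger, _, _ = replica
        table = ledger.filter_records(lambda r: r.activity == "Freeze")
        brute = sorted(
            (r for r in ledger.records if r.activity == "Freeze"),
            key=lambda r: (r.date, r.seq),
        )
        assert [row[0] for row in table.rows] == [str(r.seq) for r in brute]

    def test_always_false_predicate_is_empty(self, replica):
        ledger, _, _ = replica
        assert len(ledger.filter_records(lambda r: False)) == 0

    def test_replay_reproduces_byte_identical_csv(self):
        from clonetrack.fixtures import study_replica

        a, _, _ = study_replica()
        b, _, _ = study_replica()
        assert a.to_csv() == b.to_csv()
        assert a.registry.to_csv() == b.registry.to_csv()

    def test_csv_round_trip_of_records(self, replica):
        ledger, _, _ = replica
        clone = Ledger(default_vocabulary())
        clone.load_records_csv(ledger.to_csv())
        assert clone.to_csv() == ledger.to_csv()
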