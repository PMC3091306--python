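"""MFQL parsing and evaluation against synthetic MasterScans."""

import numpy as np
import pytest

from lipidquery import masterscan as msc
from lipidquery import mfql
from lipidquery.averaging import AveragedSpectrum, ResolutionModel
from lipidquery.chem import SumComposition, Tolerance, parse_sum_composition
from lipidquery.mfql import MfqlSyntaxError, evaluate, parse_mfql, run_queries

MODEL = ResolutionModel(100000.0, anchor=400.0)


def _masterscan(precursors, fragments_by_precursor, polarity="+", n_acq=2):
    """Hand-built MasterScan: exact peaks, no jitter."""
    entries = []
    for p in precursors:
        entry = msc.PrecursorEntry(p, np.full(n_acq, 1000.0))
        for f in fragments_by_precursor.get(p, []):
            entry.msms.append(msc.FragmentEntry(f, np.full(n_acq, 100.0)))
        entries.append(entry)
    return msc.MasterScan(
        acquisition_ids=[f"a{i}" for i in range(n_acq)],
        polarity=polarity,
        entries=entries,
        resolution_ms1=MODEL,
        resolution_ms2=MODEL,
    )


class TestParser:
    def test_pc_query_structure(self, pc_query_text):
        q = parse_mfql(pc_query_text)
        assert q.name == "Phosphatidylcholine"
        assert set(q.defines) == {"headPC", "prPC"}
        assert len(q.identify.clauses()) == 2
        assert q.identify.op == "AND"
        assert q.suchthat is not None
        assert [c for c, _ in q.report] == [
            "MASS", "NAME", "CHEMSC", "ERROR", "INTENS", "FRAGINTENS"
        ]

    def test_define_bodies(self, pc_query_text):
        q = parse_mfql(pc_query_text)
        head = q.defines["headPC"].body
        assert isinstance(head, SumComposition)
        assert head.charge == 1
        pr = q.defines["prPC"].body
        assert pr.charge == 1 and pr.dbr_range == (1.5, 7.5)

    def test_missing_identify_is_syntax_error(self):
        with pytest.raises(MfqlSyntaxError):
            parse_mfql("QUERYNAME = x; DEFINE a = 'C1'; REPORT M = a.mass;")

    def test_undefined_variable_is_error(self):
        text = (
            "QUERYNAME = x; DEFINE a = 'C1' WITH CHG = +1;"
            " IDENTIFY a IN MS1+ REPORT M = b.mass;"
        )
        with pytest.raises(MfqlSyntaxError):
            parse_mfql(text)

    def test_syntax_error_carries_location(self):
        try:
            parse_mfql("QUERYNAME = x;\nDEFINE a = ;")
        except MfqlSyntaxError as exc:
            assert exc.line == 2
        else:
            pytest.fail("expected a syntax error")

    def test_mass_and_mass_list_defines(self):
        q = parse_mfql(
            "QUERYNAME = m; DEFINE a = 184.0733 WITH CHG = +1;"
            " DEFINE b = (184.07, 104.1); IDENTIFY a IN MS1+ OR b IN MS1+"
            " REPORT M = a.mass;"
        )
        assert q.defines["a"].body == 184.0733
        assert q.defines["b"].body == (184.07, 104.1)


class TestReportExpressions:
    def _bindings(self):
        pr = parse_sum_composition("C44 H87 N1 O8 P1")
        head = parse_sum_composition("C5 H15 O4 N1 P1")
        e = msc.PrecursorEntry(788.6180, np.array([1.0, 2.0]))
        f = msc.FragmentEntry(184.0733, np.array([10.0, 20.0]))
        return {
            "prPC": mfql.VariableBinding("prPC", e, SumComposition(pr.counts, 1),
                                         788.6164),
            "headPC": mfql.VariableBinding("headPC", f, SumComposition(head.counts, 1),
                                           184.0733),
        }

    def _eval(self, text):
        q = parse_mfql(
            "QUERYNAME = t; DEFINE prPC = 'C1'; DEFINE headPC = 'C1';"
            " IDENTIFY prPC IN MS1+ REPORT X = " + text + ";"
        )
        return mfql.evaluate_report_expression(q.report[0][1], self._bindings())

    def test_composition_subtraction_and_indexing(self):
        assert self._eval("(prPC.chemsc - headPC.chemsc)[C] - 3") == 36

    def test_db_index_uses_dbr(self):
        assert self._eval("prPC.chemsc[db] - 1.5") == pytest.approx(1.0)

    def test_format_truncates_toward_zero(self):
        # errppm of the binding is (788.6180-788.6164)/788.6164*1e6 ~ 2.03
        assert self._eval('"%dppm" % "(prPC.errppm)"') == "2ppm"

    def test_name_formatting(self):
        out = self._eval(
            '"PC [%d:%d]" % "((prPC.chemsc - headPC.chemsc)[C] - 3,'
            ' prPC.chemsc[db] - 1.5)"'
        )
        assert out == "PC [36:1]"

    def test_intensity_vector_passthrough(self):
        out = self._eval("prPC.intensity")
        np.testing.assert_array_equal(out, [1.0, 2.0])

    def test_format_arity_mismatch_is_error(self):
        with pytest.raises(mfql.MfqlEvalError):
            self._eval('"%d:%d" % "(prPC.errppm)"')


class TestEvaluate:
    PC361 = 788.6164
    HEAD = 184.0733

    def test_pc_identified(self, pc_query_text):
        q = parse_mfql(pc_query_text)
        ms = _masterscan([self.PC361], {self.PC361: [self.HEAD]})
        rows = evaluate(q, ms)
        assert len(rows) == 1
        assert rows[0].columns["NAME"] == "PC [36:1]"
        assert rows[0].columns["CHEMSC"] == "C44 H87 N1 O8 P1"

    def test_odd_carbon_precursor_rejected_by_suchthat(self, pc_query_text):
        # at 789.6164 the only in-tolerance compositions have odd C
        q = parse_mfql(pc_query_text)
        ms = _masterscan([789.6164], {789.6164: [self.HEAD]})
        assert evaluate(q, ms) == []

    def test_missing_fragment_fails_and(self, pc_query_text):
        q = parse_mfql(pc_query_text)
        ms = _masterscan([self.PC361], {self.PC361: [500.5]})
        assert evaluate(q, ms) == []

    def test_unrelated_fragments_do_not_block(self, pc_query_text):
        q = parse_mfql(pc_query_text)
        ms = _masterscan(
            [self.PC361],
            {self.PC361: [104.5, self.HEAD, 313.2, 605.5, 701.0]},
        )
        assert len(evaluate(q, ms)) == 1

    def test_polarity_mismatch_yields_nothing(self, pc_query_text):
        q = parse_mfql(pc_query_text)
        ms = _masterscan([self.PC361], {self.PC361: [self.HEAD]}, polarity="-")
        assert evaluate(q, ms) == []

    def test_soundness_all_reported_within_tolerance(self, pc_query_text):
        rng = np.random.default_rng(6)
        q = parse_mfql(pc_query_text)
        precs = sorted(rng.uniform(700, 900, 40))
        ms = _masterscan(precs, {p: [self.HEAD] for p in precs})
        tol = Tolerance(5, "ppm")
        rows = evaluate(q, ms, tol_ms1=tol)
        # every reported precursor must match some PC composition within tol
        from lipidquery.chem import enumerate_compositions, parse_sc_constraint
        con = parse_sc_constraint("C[30..48]H[30..200]N[1]O[8]P[1]", charge=1,
                                  dbr_range=(1.5, 7.5))
        for r in rows:
            assert enumerate_compositions(con, r.precursor_mz, tol)

    def test_and_subset_of_or(self, pc_query_text):
        rng = np.random.default_rng(8)
        precs = sorted(rng.uniform(700, 900, 30))
        frag_map = {p: ([self.HEAD] if rng.random() < 0.5 else [150.0]) for p in precs}
        ms = _masterscan(precs, frag_map)
        q_and = parse_mfql(pc_query_text)
        q_or = parse_mfql(pc_query_text.replace("AND\n", "OR\n"))
        got_and = {r.precursor_mz for r in evaluate(q_and, ms)}
        got_or = {r.precursor_mz for r in evaluate(q_or, ms)}
        assert got_and <= got_or

    def test_tolerance_monotonicity(self, pc_query_text):
        rng = np.random.default_rng(9)
        q = parse_mfql(pc_query_text)
        precs = sorted(self.PC361 + rng.normal(0, 0.004, 20))
        ms = _masterscan(precs, {p: [self.HEAD] for p in precs})
        seen = set()
        for ppm in (1.0, 3.0, 5.0, 10.0):
            rows = evaluate(q, ms, tol_ms1=Tolerance(ppm, "ppm"))
            got = {(r.precursor_mz, r.columns["CHEMSC"]) for r in rows}
            assert seen <= got
            seen = got


class TestRunQueries:
    def test_rows_partitioned_by_query(self, pc_query_text, tmp_path):
        q_pc = parse_mfql(pc_query_text)
        q_any = parse_mfql(
            "QUERYNAME = AnyHead;\n"
            "DEFINE h = 'C5 H15 O4 N1 P1' WITH CHG = +1;\n"
            "IDENTIFY h IN MS2+\n"
            "REPORT M = h.mass;\n"
        )
        ms = _masterscan([788.6164], {788.6164: [184.0733]})
        out = tmp_path / "report.csv"
        frame = run_queries([q_pc, q_any], ms, out)
        assert sorted(frame["QUERY"].unique()) == ["AnyHead", "Phosphatidylcholine"]
        assert out.exists()

    def test_no_match_gives_header_only(self, pc_query_text, tmp_path):
        q = parse_mfql(pc_query_text)
        ms = _masterscan([900.0], {})
        out = tmp_path / "empty.csv"
        frame = run_queries([q], ms, out)
        assert len(frame) == 0
        assert out.read_text().startswith("QUERY,PRECURSOR_MZ")

    def test_rerun_is_byte_identical(self, pc_query_text, tmp_path):
        q = parse_mfql(pc_query_text)
        ms = _masterscan([788.6164], {788.6164: [184.0733]})
        p1, p2 = tmp_path / "r1.csv", tmp_path / "r2.csv"
        run_queries([q], ms, p1)
        run_queries([q], ms, p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestEndToEnd:
    def test_simulated_pc_dataset(self, pc_masterscan, pc_query_text):
        """Identification on the full simulated pipeline, decoys excluded."""
        q = parse_mfql(pc_query_text)
        rows = evaluate(q, pc_masterscan)
        assert [r.columns["NAME"] for r in rows] == ["PC [36:1]"]
        assert rows[0].columns["CHEMSC"] == "C44 H87 N1 O8 P1"
        # reporter-fragment intensities emulate a precursor-ion scan: the
        # per-acquisition profile follows the simulated abundance multipliers
        frag = rows[0].columns["FRAGINTENS"]
        assert frag.shape == (3,)
        assert np.all(frag > 0)
        from lipidquery.synth import pc_truth
        mult = np.array(pc_truth().acquisition_multipliers)
        np.testing.assert_allclose(
            frag / frag[0], mult / mult[0], rtol=0.15
        )
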