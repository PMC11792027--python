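"""AS event enumeration geometry and differential testing."""

import numpy as np
import pandas as pd
import pytest

from isoformatlas.formats_io import Annotation
from isoformatlas.quant_diff import CountsMatrix
from isoformatlas.splice_events import enumerate_events
from isoformatlas.splice_events import test_events as run_test_events
from conftest import make_transcript


def ann(*txs):
    return Annotation.from_transcripts(list(txs))


def by_type(events):
    out = {}
    for e in events:
        out.setdefault(e.type, []).append(e)
    return out


class TestEnumeration:
    def test_exon_skip(self):
        t1 = make_transcript("t1", "g", [(0, 100), (200, 300), (400, 500)])
        t2 = make_transcript("t2", "g", [(0, 100), (400, 500)])
        events = enumerate_events(ann(t1, t2))
        assert len(events) == 1
        (ev,) = events
        assert ev.type == "ES"
        assert ev.coordinates == (100, 200, 300, 400)
        assert ev.inclusion == {"t1"} and ev.exclusion == {"t2"}

    def test_identical_chains_no_events(self):
        t1 = make_transcript("t1", "g", [(0, 100), (200, 300)])
        t2 = make_transcript("t2", "g", [(10, 100), (200, 320)])  # same chain
        assert enumerate_events(ann(t1, t2)) == []

    def test_intron_retention(self):
        t1 = make_transcript("t1", "g", [(0, 300)])
        t2 = make_transcript("t2", "g", [(0, 100), (200, 300)])
        (ev,) = enumerate_events(ann(t1, t2))
        assert ev.type == "IR"
        assert ev.coordinates == (100, 200)
        assert ev.inclusion == {"t1"}  # the retaining isoform

    def test_alt3_and_alt5_strand_aware(self):
        # differing acceptor (right end), shared donor
        t1 = make_transcript("t1", "g", [(0, 100), (200, 400)])
        t2 = make_transcript("t2", "g", [(0, 100), (250, 400)])
        (ev,) = enumerate_events(ann(t1, t2))
        assert ev.type == "ALT3"
        assert ev.inclusion == {"t1"}  # shorter intron = more exon retained
        t1m = make_transcript("m1", "g", [(0, 100), (200, 400)], strand="-")
        t2m = make_transcript("m2", "g", [(0, 100), (250, 400)], strand="-")
        (evm,) = enumerate_events(ann(t1m, t2m))
        assert evm.type == "ALT5"

    def test_alt_site_not_emitted_for_skip_pattern(self):
        """A skip junction shares a donor with the inclusion path but is an
        ES event, not an alternative splice site."""
        t1 = make_transcript("t1", "g", [(0, 100), (200, 300), (400, 500)])
        t2 = make_transcript("t2", "g", [(0, 100), (400, 500)])
        types = {e.type for e in enumerate_events(ann(t1, t2))}
        assert types == {"ES"}

    def test_alternative_first_and_last_exons(self):
        t1 = make_transcript("t1", "g", [(0, 100), (400, 500), (600, 700)])
        t2 = make_transcript("t2", "g", [(150, 250), (400, 500), (600, 700)])
        events = by_type(enumerate_events(ann(t1, t2)))
        assert set(events) == {"AF"}
        t3 = make_transcript("t3", "g", [(0, 100), (400, 500), (600, 700)])
        t4 = make_transcript("t4", "g", [(0, 100), (400, 500), (800, 900)])
        events = by_type(enumerate_events(ann(t3, t4)))
        assert set(events) == {"AL"}
        # strand-aware: the same geometry on minus strand swaps AF and AL
        t5 = make_transcript("t5", "g", [(0, 100), (400, 500), (600, 700)], strand="-")
        t6 = make_transcript("t6", "g", [(150, 250), (400, 500), (600, 700)], strand="-")
        assert set(by_type(enumerate_events(ann(t5, t6)))) == {"AL"}

    def test_mutually_exclusive_exons(self):
        t1 = make_transcript("t1", "g", [(0, 100), (200, 300), (600, 700)])
        t2 = make_transcript("t2", "g", [(0, 100), (400, 500), (600, 700)])
        events = by_type(enumerate_events(ann(t1, t2)))
        assert set(events) == {"MX"}
        (ev,) = events["MX"]
        assert ev.inclusion == {"t1"} and ev.exclusion == {"t2"}

    def test_deduplicated_across_pairs(self):
        # three isoforms, two sharing the inclusion path
        t1 = make_transcript("t1", "g", [(0, 100), (200, 300), (400, 500)])
        t2 = make_transcript("t2", "g", [(10, 100), (200, 300), (400, 520)])
        t3 = make_transcript("t3", "g", [(0, 100), (400, 500)])
        events = [e for e in enumerate_events(ann(t1, t2, t3)) if e.type == "ES"]
        assert len(events) == 1
        assert events[0].inclusion == {"t1", "t2"}

    def test_invariant_under_id_relabeling_and_order(self):
        t1 = make_transcript("t1", "g", [(0, 100), (200, 300), (400, 500)])
        t2 = make_transcript("t2", "g", [(0, 100), (400, 500)])
        a = enumerate_events(ann(t1, t2))
        z1 = make_transcript("z9", "g", [(0, 100), (200, 300), (400, 500)])
        z2 = make_transcript("a0", "g", [(0, 100), (400, 500)])
        b = enumerate_events(ann(z2, z1))
        assert [(e.event_id, e.type) for e in a] == [
            (e.event_id, e.type) for e in b
        ]

    def test_inclusion_exclusion_always_disjoint(self, small_sim):
        _, _, truth = small_sim
        for ev in enumerate_events(truth.annotation):
            assert not (ev.inclusion & ev.exclusion)
            assert ev.inclusion and ev.exclusion


class TestDifferential:
    def matrix(self, incl_a, excl_a, incl_b, excl_b):
        df = pd.DataFrame({"a1": [incl_a, excl_a], "b1": [incl_b, excl_b]},
                          index=["tin", "tout"])
        return CountsMatrix(df, {"a1": "A", "b1": "B"})

    @pytest.fixture
    def event(self):
        t1 = make_transcript("tin", "g", [(0, 100), (200, 300), (400, 500)])
        t2 = make_transcript("tout", "g", [(0, 100), (400, 500)])
        (ev,) = enumerate_events(ann(t1, t2))
        return ev

    def test_balanced_table_null(self, event):
        res = run_test_events([event], self.matrix(50, 50, 50, 50), "A", "B")
        row = res.iloc[0]
        assert row["p_value"] == pytest.approx(1.0)
        assert row["psi_a"] == row["psi_b"] == pytest.approx(0.5)
        assert not row["significant"]

    def test_strong_switch_significant(self, event):
        row = run_test_events([event], self.matrix(90, 10, 10, 90), "A", "B").iloc[0]
        assert row["p_value"] < 1e-10
        assert row["significant"]
        assert row["delta_psi"] == pytest.approx(-0.8)

    def test_alpha_gate_strict(self, event):
        # find a table with p just above 0.01: [13,7;6,14] gives p ~ 0.056
        row = run_test_events([event], self.matrix(13, 7, 6, 14), "A", "B").iloc[0]
        assert 0.01 < row["p_value"]
        assert not row["significant"]

    def test_zero_condition_total_untestable(self, event):
        row = run_test_events([event], self.matrix(0, 0, 40, 60), "A", "B").iloc[0]
        assert not row["testable"]
        assert row["p_value"] == 1.0
        assert np.isnan(row["psi_a"])

    def test_swapping_conditions_mirrors_psi_keeps_p(self, event):
        fwd = run_test_events([event], self.matrix(70, 30, 20, 80), "A", "B").iloc[0]
        rev = run_test_events([event], self.matrix(70, 30, 20, 80), "B", "A").iloc[0]
        assert rev["psi_a"] == fwd["psi_b"] and rev["psi_b"] == fwd["psi_a"]
        assert rev["p_value"] == pytest.approx(fwd["p_value"])

    def test_psi_in_unit_interval(self, small_sim):
        cfg, _, truth = small_sim
        events = enumerate_events(truth.annotation)
        rng = np.random.default_rng(0)
        tids = sorted(truth.annotation.transcripts)
        df = pd.DataFrame(
            {
                "a1": rng.integers(0, 200, len(tids)),
                "b1": rng.integers(0, 200, len(tids)),
            },
            index=tids,
        )
        cm = CountsMatrix(df, {"a1": "A", "b1": "B"})
        res = run_test_events(events, cm, "A", "B")
        ok = res["testable"]
        assert ((res.loc[ok, "psi_a"] >= 0) & (res.loc[ok, "psi_a"] <= 1)).all()
        assert ((res.loc[ok, "psi_b"] >= 0) & (res.loc[ok, "psi_b"] <= 1)).all()


class TestPlantedRecovery:
    def test_planted_delta_psi_events_recovered(self, clean_sim):
        """Planted PSI switches (0.7 -> 0.3) are significant with ample
        reads; most null events are not (fixed seed)."""
        from isoformatlas.formats_io import read_reads
        from isoformatlas.quant_diff import quantify

        cfg, paths, truth = clean_sim
        reads = {s: read_reads(paths[f"reads_{s}"]) for s in cfg.samples}
        cm = quantify(reads, truth.annotation, conditions=truth.samples)
        events = enumerate_events(truth.annotation)
        res = run_test_events(events, cm, *cfg.conditions)
        sig = set(res.loc[res["significant"], "event_id"])
        assert set(truth.as_true) <= sig
        de_genes = set(truth.de_genes)
        null_ids = {
            e.event_id
            for e in events
            if e.gene_id not in de_genes and e.event_id not in truth.as_true
        }
        fp_rate = len(sig & null_ids) / max(1, len(null_ids))
        assert fp_rate <= 0.05
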