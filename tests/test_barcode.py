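"""Pairwise identity, species assignment and replicate reconciliation."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fishauth import barcode as bc
from fishauth import taxa
from fishauth.synthetic import simulate_reference_panel

SEQ = st.text(alphabet="ACGT", min_size=5, max_size=40)


def brute_force_align(a: str, b: str, match=1, mismatch=-1, gap=-2):
    """Exhaustive semi-global alignment score (oracle; exponential).

    Free end gaps mean a prefix of exactly one sequence may be skipped
    for free at the start, and the remaining suffix of one sequence is
    free once the other is exhausted.  All interior gaps are paid.
    """
    best = float("-inf")

    def rec(i, j, score):
        nonlocal best
        if i == len(a) or j == len(b):
            best = max(best, score)  # free suffix of the other sequence
            return
        rec(i + 1, j + 1, score + (match if a[i] == b[j] else mismatch))
        rec(i + 1, j, score + gap)
        rec(i, j + 1, score + gap)

    for p in range(len(a) + 1):
        rec(p, 0, 0)
    for q in range(1, len(b) + 1):
        rec(0, q, 0)
    return best


class TestAlignment:
    @pytest.mark.parametrize(
        "a, b, score",
        [
            ("ACGT", "ACGT", 4),
            ("ACGT", "ACGA", 2),
            ("ACGTACGT", "ACGACGT", 5),  # one internal gap
        ],
    )
    def test_known_scores(self, a, b, score):
        assert bc.align_pair(a, b).score == score

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(30):
            n, m = rng.integers(3, 8, size=2)
            a = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
            b = "".join("ACGT"[i] for i in rng.integers(0, 4, m))
            assert bc.align_pair(a, b).score == brute_force_align(a, b)

    def test_non_iupac_characters_rejected(self):
        with pytest.raises(ValueError, match="non-IUPAC"):
            bc.align_pair("ACXT", "ACGT")
        with pytest.raises(ValueError, match="empty"):
            bc.align_pair("", "ACGT")

    def test_deterministic(self):
        alns = {bc.align_pair("ACGTACGT", "ACGACGT") for _ in range(5)}
        assert len(alns) == 1


class TestIdentity:
    def test_identical_full_length(self):
        s = "ACGT" * 164  # 656 bases
        assert bc.percent_identity(s, s) == 1.0

    def test_one_substitution_in_655(self):
        a = ("ACGT" * 164)[:655]
        b = a[:-1] + ("C" if a[-1] != "C" else "G")
        assert bc.percent_identity(a, b) == pytest.approx(654 / 655, abs=1e-15)

    def test_terminal_gap_columns_excluded(self):
        # overhang alignment: identity computed over the overlap only
        aln = bc.PairwiseAlignment("AACGT", "-ACGT", 4.0)
        assert bc.pairwise_identity(aln) == 1.0

    def test_internal_gap_counts_as_mismatch(self):
        aln = bc.PairwiseAlignment("ACGTACGT", "ACG-ACGT", 5.0)
        assert bc.pairwise_identity(aln) == pytest.approx(7 / 8)

    def test_n_matches_nothing(self):
        assert bc.percent_identity("ACGN", "ACGN") == pytest.approx(3 / 4)

    def test_all_gap_overlap_rejected(self):
        with pytest.raises(ValueError, match="non-terminal"):
            bc.pairwise_identity(bc.PairwiseAlignment("--", "--", 0.0))

    @given(a=SEQ, n_subs=st.integers(0, 10))
    def test_symmetric_and_bounded(self, a, n_subs):
        rng = np.random.default_rng(len(a) + n_subs)
        b = list(a)
        for i in rng.choice(len(a), size=min(n_subs, len(a)), replace=False):
            b[i] = "ACGT"[rng.integers(4)]
        b = "".join(b)
        ab = bc.percent_identity(a, b)
        assert 0.0 <= ab <= 1.0
        assert ab == pytest.approx(bc.percent_identity(b, a), abs=1e-12)
        assert (ab == 1.0) == (a == b)

    def test_symmetric_for_overhanging_pair(self):
        long = "ACGTACGTACGTACGTACGT"
        short = long[4:16]
        assert bc.percent_identity(long, short) == bc.percent_identity(short, long) == 1.0

    @given(a=SEQ)
    def test_self_identity_is_one(self, a):
        assert bc.percent_identity(a, a) == 1.0


def _random_panel(rng, n_refs, length=120, n_groups=None):
    n_groups = n_groups or max(2, n_refs // 2)
    group_seqs = {
        f"g{k}": "".join("ACGT"[i] for i in rng.integers(0, 4, length))
        for k in range(n_groups)
    }
    records = []
    for i in range(n_refs):
        g = f"g{i % n_groups}"
        records.append(
            bc.PanelRecord(f"R{i}", f"Species {i}", g, group_seqs[g])
        )
    return bc.ReferencePanel(records, sister_map={})


class TestAssignment:
    def test_congener_group_reported_unambiguously(self, panel):
        query = panel.record_for_species("Gadus chalcogrammus").sequence
        a = bc.assign_species(query, panel)
        assert a.status == "UNAMBIGUOUS"
        assert a.best_group == frozenset({"chalcogramma-group"})
        assert a.best_identity == 1.0

    def test_cross_group_tie_is_ambiguous(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
        other = seq[:50] + "".join("ACGT"[i] for i in rng.integers(0, 4, 50))
        p = bc.ReferencePanel(
            [
                bc.PanelRecord("R1", "Sp one", "g1", seq),
                bc.PanelRecord("R2", "Sp two", "g2", seq),
                bc.PanelRecord("R3", "Sp three", "g3", other),
            ],
            sister_map={},
        )
        a = bc.assign_species(seq, p)
        assert a.status == "AMBIGUOUS_GROUP"
        assert a.best_group == frozenset({"g1", "g2"})
        # runner-up is the best hit outside the tied groups
        assert a.runner_up_species == "Sp three"

    def test_reverse_complement_query_recovers_assignment(self, panel):
        query = panel.record_for_species("Gadus morhua").sequence
        a = bc.assign_species(bc.reverse_complement(query), panel)
        assert a.best_group == frozenset({"morhua"})
        assert a.orientation == "reverse"
        assert a.best_identity == 1.0

    def test_below_threshold_status(self, panel):
        ref = panel.record_for_species("Melanogrammus aeglefinus").sequence
        arr = list(ref)
        rng = np.random.default_rng(1)
        for i in rng.choice(len(arr), size=10, replace=False):  # ~1.5% divergence
            arr[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[arr[i]]
        a = bc.assign_species("".join(arr), panel)
        assert a.status == "BELOW_THRESHOLD"
        assert a.best_identity == pytest.approx(1 - 10 / 655)

    def test_agrees_with_brute_force_scan(self, rng):
        """assign_species must equal an independent all-pairs scan."""
        for trial in range(6):
            panel = _random_panel(rng, n_refs=int(rng.integers(4, 21)))
            for _ in range(20):
                base = panel.records[rng.integers(len(panel.records))].sequence
                arr = list(base)
                for i in rng.choice(len(arr), size=rng.integers(0, 6), replace=False):
                    arr[i] = "ACGT"[rng.integers(4)]
                if rng.random() < 0.3:  # exercise the alignment path too
                    cut = int(rng.integers(1, 4))
                    arr = arr[cut:]
                query = "".join(arr)
                got = bc.assign_species(query, panel, check_orientation=False)
                idents = [bc.percent_identity(query, r.sequence) for r in panel.records]
                best = max(idents)
                tied_groups = {
                    r.group for r, s in zip(panel.records, idents) if s == best
                }
                assert got.best_identity == best
                assert got.best_group == frozenset(tied_groups)
                outside = [
                    (s, r) for r, s in zip(panel.records, idents) if r.group not in tied_groups
                ]
                if outside:
                    assert got.runner_up_identity == max(s for s, _ in outside)


class TestAccuracy:
    def test_group_level_accuracy_on_clean_queries(self, panel):
        """500 non-chimeric queries at error rate 0.003 against the
        default panel (all divergences > 2%) assign to the right group
        every time."""
        from fishauth.synthetic import SimulationConfig, simulate_metadata, simulate_queries

        config = SimulationConfig(
            seed=17, n_samples=250, chimera_fraction=0.0, seq_error_rate=0.003
        )
        _, truth = simulate_metadata(config)
        queries = simulate_queries(panel, truth, config.seq_error_rate, seed=18)
        assert len(queries) == 500
        correct = 0
        for qid, seq in queries.items():
            expected = taxa.group_of(truth.loc[qid.split("/")[0], "true_species"])
            a = bc.assign_species(seq, panel)
            correct += a.best_group == frozenset({expected})
        assert correct == 500


class TestMixedDetection:
    def test_paper_style_mosaic_flags_mixed(self, panel):
        """A haddock/cod blend: best hit haddock below threshold with
        runner-up cod (not haddock's nearest relative, whiting)."""
        from fishauth.tree import encode

        a = encode(panel.record_for_species("Melanogrammus aeglefinus").sequence)
        b = encode(panel.record_for_species("Gadus morhua").sequence)
        rng = np.random.default_rng(3)
        diff = np.flatnonzero(a != b)
        mosaic = a.copy()
        picked = diff[rng.random(len(diff)) < 0.45]
        mosaic[picked] = b[picked]
        query = "".join("ACGT"[i] for i in mosaic)
        assignment = bc.assign_species(query, panel)
        assert assignment.status == "BELOW_THRESHOLD"
        assert assignment.best_species in ("Melanogrammus aeglefinus", "Gadus morhua")
        assert bc.detect_mixed(assignment, panel)

    def test_above_threshold_never_mixed(self, panel):
        query = panel.record_for_species("Melanogrammus aeglefinus").sequence
        assignment = bc.assign_species(query, panel)
        assert not bc.detect_mixed(assignment, panel)

    def test_sister_consistent_divergence_not_mixed(self, panel):
        # a degraded pure haddock: runner-up stays whiting (its sister)
        ref = panel.record_for_species("Melanogrammus aeglefinus").sequence
        arr = list(ref)
        rng = np.random.default_rng(7)
        for i in rng.choice(len(arr), size=6, replace=False):
            arr[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[arr[i]]
        assignment = bc.assign_species("".join(arr), panel)
        assert assignment.status == "BELOW_THRESHOLD"
        assert assignment.runner_up_species == "Merlangius merlangus"
        assert not bc.detect_mixed(assignment, panel)

    def test_missing_sister_entry_raises(self, panel):
        stripped = bc.ReferencePanel(panel.records, panel.species_groups, sister_map={})
        ref = panel.record_for_species("Melanogrammus aeglefinus").sequence
        arr = list(ref)
        rng = np.random.default_rng(7)
        for i in rng.choice(len(arr), size=6, replace=False):
            arr[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[arr[i]]
        assignment = bc.assign_species("".join(arr), stripped)
        with pytest.raises(KeyError, match="sister"):
            bc.detect_mixed(assignment, stripped)


def _assignment(group, species="Gadus morhua", runner_group=None):
    return bc.SpeciesAssignment(
        query_id="q",
        best_group=frozenset({group}),
        best_species=species,
        best_identity=1.0,
        runner_up_species="Merlangius merlangus" if runner_group else None,
        runner_up_identity=0.9 if runner_group else None,
        runner_up_group=runner_group,
        status="UNAMBIGUOUS",
    )


class TestReconciliation:
    def test_agreeing_replicates_keep_group(self):
        r = bc.reconcile_replicates("s", _assignment("morhua"), _assignment("morhua"))
        assert r.kind == "GROUP" and r.group == "morhua"

    def test_disagreeing_replicates_are_mixed(self):
        r = bc.reconcile_replicates(
            "s", _assignment("morhua"), _assignment("aeglefinus", "Melanogrammus aeglefinus")
        )
        assert r.kind == "MIXED"
        assert r.groups == frozenset({"morhua", "aeglefinus"})

    def test_mixed_flag_takes_best_and_runner_up_groups(self):
        flagged = _assignment("aeglefinus", "Melanogrammus aeglefinus", runner_group="morhua")
        r = bc.reconcile_replicates("s", flagged, _assignment("aeglefinus"), (True, False))
        assert r.kind == "MIXED"
        assert r.groups == frozenset({"aeglefinus", "morhua"})

    def test_single_replicate_is_tagged(self):
        r = bc.reconcile_replicates("s", _assignment("morhua"), None)
        assert r.kind == "GROUP" and r.group == "morhua"
        assert "single-replicate" in r.notes

    def test_no_replicates_unresolved(self):
        r = bc.reconcile_replicates("s", None, None)
        assert r.kind == "UNRESOLVED"


class TestPanelIO:
    def test_fasta_round_trip(self, panel, tmp_path):
        path = tmp_path / "panel.fasta"
        panel.to_fasta(path)
        loaded = bc.ReferencePanel.from_fasta(path)
        assert [r.species for r in loaded.records] == [r.species for r in panel.records]
        assert [r.sequence for r in loaded.records] == [r.sequence for r in panel.records]
        assert loaded.species_groups == panel.species_groups
        # sister map re-derived from sequences is identical
        assert loaded.sister_map == panel.sister_map

    def test_bad_header_rejected(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">just_an_id\nACGT\n")
        with pytest.raises(ValueError, match="refID"):
            bc.ReferencePanel.from_fasta(path)
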