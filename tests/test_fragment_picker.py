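"""Fragment scoring, picking, quota, fit, and file formats."""

import math

import numpy as np
import pytest

from classfrag import fragment_picker as fp, synthetic, template_select as ts
from classfrag.fragment_picker import (
    AA_ORDER,
    SSPrediction,
    SequenceProfile,
    library_fit,
    pick_fragments,
    profile_score,
    read_fragment_file,
    read_pssm,
    read_ss2,
    ss_match_score,
    write_fragment_file,
    write_pssm,
    write_ss2,
)
from classfrag.synthetic import SSSpec
from classfrag.template_select import HomologHit, filter_templates


class TestProfileScore:
    def test_argmax_template_scores_zero(self):
        rng = np.random.default_rng(0)
        rows = rng.normal(size=(5, 20))
        letters = "".join(AA_ORDER[i] for i in rows.argmax(axis=1))
        assert profile_score(rows, letters) == pytest.approx(0.0)

    def test_single_column_example(self):
        row = np.full((1, 20), -5.0)
        row[0, AA_ORDER.index("A")] = 2.0
        row[0, AA_ORDER.index("G")] = -1.0
        assert profile_score(row, "G") == pytest.approx(3.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        rows = rng.normal(size=(3, 20))
        for letters in ("ACD", "WYV", "GGG"):
            expected = sum(
                max(rows[i]) - rows[i][AA_ORDER.index(c)]
                for i, c in enumerate(letters))
            assert profile_score(rows, letters) == pytest.approx(expected)

    def test_unknown_letter_error(self):
        with pytest.raises(ValueError):
            profile_score(np.zeros((1, 20)), "Z")


class TestSSMatchScore:
    def test_certain_prediction_zero(self):
        rows = np.tile([1.0, 0.0, 0.0], (3, 1))
        assert ss_match_score(rows, "HHH") == pytest.approx(0.0)

    def test_partial_certainty(self):
        rows = np.tile([0.8, 0.1, 0.1], (3, 1))
        assert ss_match_score(rows, "HHH") == pytest.approx(0.6)

    def test_matches_direct_sum(self):
        rng = np.random.default_rng(5)
        raw = rng.uniform(0.1, 1.0, size=(4, 3))
        rows = raw / raw.sum(axis=1, keepdims=True)
        ss = "HECH"
        expected = sum(1 - rows[i]["HEC".index(c)] for i, c in enumerate(ss))
        assert ss_match_score(rows, ss) == pytest.approx(expected)

    def test_bad_letter_error(self):
        with pytest.raises(ValueError):
            ss_match_score(np.full((1, 3), 1 / 3), "X")


def brute_force_ranking(sequence, profile, pred, db, length, pos):
    """Independent enumeration: score every sentinel-free window directly."""
    scored = []
    for rec in db:
        phi = rec.residues["phi"].to_numpy()
        psi = rec.residues["psi"].to_numpy()
        omg = rec.residues["omega"].to_numpy()
        for s in range(len(rec) - length + 1):
            window = slice(s, s + length)
            # phi of the first and psi/omega of the last window residue are
            # never consumed when rebuilding, so sentinels there are fine
            if not (np.all(np.isfinite(phi[s + 1: s + length])) and
                    np.all(np.isfinite(psi[s: s + length - 1])) and
                    np.all(np.isfinite(omg[s: s + length - 1]))):
                continue
            ps = profile_score(profile.scores[pos - 1: pos - 1 + length],
                               rec.sequence[window])
            ss = ss_match_score(pred.probs[pos - 1: pos - 1 + length],
                                rec.ss[window])
            scored.append((ps + ss, rec.id, s + 1))
    scored.sort()
    return scored


class TestPickFragments:
    def test_pool_smaller_than_n_frags(self, toy):
        db, native, spec, profile, pred = toy
        lib = pick_fragments(native.sequence, profile, pred, db,
                             length=9, n_frags=200)
        pool = sum(max(0, len(rec) - 9 + 1) for rec in db)
        got = len(lib.get(1, 9))
        assert got == min(200, pool)
        assert got < 200  # the toy pool really is smaller

    def test_ranking_matches_brute_force(self, toy):
        db, native, spec, profile, pred = toy
        length = 3
        lib = pick_fragments(native.sequence, profile, pred, db,
                             length=length, n_frags=10)
        for pos in (1, 5, 10):
            expected = brute_force_ranking(native.sequence, profile, pred,
                                           db, length, pos)[:10]
            got = [(f.score, f.template_id, f.template_start)
                   for f in lib.get(pos, length)]
            for (es, ei, ep), (gs, gi, gp) in zip(expected, got):
                assert (ei, ep) == (gi, gp)
                assert gs == pytest.approx(es, abs=1e-9)

    def test_unique_zero_scorer_ranks_first(self):
        # one template window is the per-column argmax with certain SS
        db, _ = synthetic.make_template_db({"mainly_alpha": 2},
                                           lengths=(20, 25), seed=4)
        rec = next(iter(db))
        start = 5
        seq_win = rec.sequence[start: start + 3]
        ss_win = rec.ss[start: start + 3]
        L = 3
        scores = np.full((L, 20), -10.0)
        probs = np.zeros((L, 3))
        for i in range(L):
            scores[i, AA_ORDER.index(seq_win[i])] = 5.0
            probs[i, "HEC".index(ss_win[i])] = 1.0
        # make every other window imperfect by construction: unknown-best rows
        lib = pick_fragments("AAA", SequenceProfile(scores),
                             SSPrediction(probs), db, length=3, n_frags=5)
        top = lib.get(1, 3)[0]
        assert top.score == pytest.approx(0.0)
        assert (top.template_id, top.template_start) == (rec.id, start + 1)

    def test_sorted_ascending(self, toy):
        db, native, spec, profile, pred = toy
        lib = pick_fragments(native.sequence, profile, pred, db,
                             length=3, n_frags=30)
        for frags in lib.entries.values():
            scores = [f.score for f in frags]
            assert scores == sorted(scores)

    def test_quota_split_and_conservation(self, toy):
        db, native, spec, profile, pred = toy
        flat = SSPrediction(np.full((len(native), 3), 1 / 3), name="uniform")
        n_frags = 7
        lib = pick_fragments(native.sequence, profile, [pred, flat], db,
                             length=9, n_frags=n_frags)
        assert fp._quota_split(n_frags, 2) == [4, 3]
        for frags in lib.entries.values():
            assert len(frags) == n_frags
            keys = [(f.template_id, f.template_start) for f in frags]
            assert len(set(keys)) == len(keys)  # duplicates resolved
            assert {f.source for f in frags} == {"synthetic", "uniform"}

    def test_ss_weight_monotonicity(self, toy):
        # with a certain predictor, raising w_ss never demotes a perfectly
        # SS-matching fragment below a mismatching one
        db, native, spec, profile, pred = toy
        certain = SSPrediction(
            np.eye(3)["HEC".index("H") if False else 0].reshape(1, 3).repeat(
                len(native), axis=0))
        for w_ss in (1.0, 5.0, 20.0):
            lib = pick_fragments(native.sequence, profile, certain, db,
                                 length=3, n_frags=50, w_ss=w_ss)
            for frags in lib.entries.values():
                match_ranks = [i for i, f in enumerate(frags) if f.ss == "HHH"]
                mismatch_ranks = [i for i, f in enumerate(frags)
                                  if "H" not in f.ss]
                if match_ranks and mismatch_ranks and w_ss >= 5.0:
                    assert max(match_ranks) < min(mismatch_ranks)

    def test_class_filter_respected_end_to_end(self, toy):
        db, native, spec, profile, pred = toy
        hits = [HomologHit(db.ids[0], 0.001)]
        kept = filter_templates(db, "mainly_alpha", max_resolution=None,
                                homologs=hits)
        lib = pick_fragments(native.sequence, profile, pred, kept,
                             length=9, n_frags=100)
        allowed = set(kept.ids)
        for frags in lib.entries.values():
            for f in frags:
                assert f.template_id in allowed
                assert f.template_id != db.ids[0]

    def test_empty_db_error(self, toy):
        _, native, spec, profile, pred = toy
        with pytest.raises(ValueError):
            pick_fragments(native.sequence, profile, pred,
                           ts.TemplateDB(), length=3, n_frags=5)


class TestLibraryFit:
    def test_native_windows_fit_zero(self, alpha_native):
        native, spec, profile, pred = alpha_native
        rec = ts.record_from_structure(native, resolution=1.0)
        db = ts.TemplateDB({"native": rec})
        lib = pick_fragments(native.sequence, profile, pred, db,
                             length=9, n_frags=500)
        fit = library_fit(lib, native)
        assert (fit["best_rmsd"] < 1e-3).all()

    def test_helix_fragments_do_not_fit_strand(self):
        helix_db, _ = synthetic.make_template_db({"mainly_alpha": 2},
                                                 lengths=(30, 40), seed=6)
        strand = synthetic.make_ideal_structure(SSSpec([("E", 12)]), seed=6)
        profile, pred = synthetic.make_profile_and_ss(
            strand.sequence, "E" * 12, sharpness=0.5, seed=6)
        lib = pick_fragments(strand.sequence, profile, pred, helix_db,
                             length=9, n_frags=20)
        fit = library_fit(lib, strand)
        assert (fit["best_rmsd"] > 1.5).all()

    def test_empty_candidates_sentinel_row(self, alpha_native):
        native, *_ = alpha_native
        lib = fp.FragmentLibrary(target_length=len(native), n_frags=5)
        lib.entries[(1, 9)] = []
        fit = library_fit(lib, native)
        assert math.isnan(fit.loc[0, "best_rmsd"])
        assert fit.loc[0, "n_candidates"] == 0


class TestFragmentFile:
    def test_round_trip(self, tmp_path, alpha_native):
        native, spec, profile, pred = alpha_native
        db, _ = synthetic.make_template_db({"mainly_alpha": 2},
                                           lengths=(20, 30), seed=2)
        lib = pick_fragments(native.sequence, profile, pred, db,
                             length=3, n_frags=5)
        p = tmp_path / "frags.txt"
        write_fragment_file(lib, p)
        back = read_fragment_file(p)
        assert set(back.entries) == set(lib.entries)
        for key in lib.entries:
            for a, b in zip(lib.entries[key], back.entries[key]):
                assert (a.template_id, a.template_start) == \
                       (b.template_id, b.template_start)
                assert a.aa == b.aa and a.ss == b.ss
                for ta, tb in zip(a.torsions, b.torsions):
                    if ta.phi is None:
                        assert tb.phi is None
                    else:
                        assert ta.phi == pytest.approx(tb.phi, abs=1e-3)

    def test_neighbor_header_counts(self, tmp_path, alpha_native):
        native, spec, profile, pred = alpha_native
        db, _ = synthetic.make_template_db({"mainly_alpha": 2},
                                           lengths=(20, 30), seed=2)
        lib = pick_fragments(native.sequence, profile, pred, db,
                             length=3, n_frags=4)
        p = tmp_path / "frags.txt"
        write_fragment_file(lib, p)
        for line in p.read_text().splitlines():
            if line.strip().startswith("position:"):
                parts = line.split()
                pos, n = int(parts[1]), int(parts[3])
                assert n == len(lib.get(pos, 3))


class TestReaders:
    def test_pssm_round_trip(self, tmp_path, alpha_native):
        native, spec, profile, pred = alpha_native
        p = tmp_path / "t.pssm"
        write_pssm(native.sequence, profile, p)
        back = read_pssm(p)
        assert back.scores.shape == profile.scores.shape
        assert np.allclose(back.scores, profile.scores, atol=0.05)

    def test_ss2_round_trip(self, tmp_path, alpha_native):
        native, spec, profile, pred = alpha_native
        p = tmp_path / "t.ss2"
        write_ss2(native.sequence, pred, p)
        back = read_ss2(p)
        assert np.allclose(back.probs, pred.probs, atol=2e-3)

    def test_blosum_fallback_profile(self):
        prof = SequenceProfile.from_sequence("ACDEF")
        assert prof.scores.shape == (5, 20)
        # diagonal dominance: the native residue scores highest in its row
        for i, a in enumerate("ACDEF"):
            assert prof.scores[i].argmax() == AA_ORDER.index(a)
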