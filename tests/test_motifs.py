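"""PWM parsing, scanning (vs brute force), projection and Fisher enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coregrn.motifs import (
    PWM,
    default_threshold,
    enrich,
    project_hits,
    read_motif_library,
    scan,
    write_motif_library,
)

from conftest import make_pwm

BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
COMP = str.maketrans("ACGT", "TGCA")


def brute_force_hits(seq, pwm, threshold):
    """Independent rescoring of every position and strand by direct lookup."""
    L = len(pwm)
    lo = np.log2(pwm.matrix / pwm.background)
    out = []
    for o in range(len(seq) - L + 1):
        win = seq[o:o + L]
        fwd = sum(lo[i, BASE_IDX[b]] if b in BASE_IDX else 0.0 for i, b in enumerate(win))
        rc = win.translate(COMP)[::-1]
        rev = sum(lo[i, BASE_IDX[b]] if b in BASE_IDX else 0.0 for i, b in enumerate(rc))
        if fwd >= threshold - 1e-12:
            out.append((o, "+", fwd))
        if rev >= threshold - 1e-12:
            out.append((o, "-", rev))
    return out


class TestLibraryIO:
    def write(self, tmp_path, body):
        p = tmp_path / "m.jaspar"
        p.write_text(body)
        return p

    def test_uniform_counts_give_uniform_columns(self, tmp_path):
        body = ">M1 X\nA [ 1 1 1 1 ]\nC [ 1 1 1 1 ]\nG [ 1 1 1 1 ]\nT [ 1 1 1 1 ]\n"
        (pwm,) = read_motif_library(self.write(tmp_path, body))
        np.testing.assert_allclose(pwm.matrix, 0.25)

    def test_pseudocount_arithmetic(self, tmp_path):
        body = ">M1 X\nA [ 10 0 0 0 ]\nC [ 0 10 0 0 ]\nG [ 0 0 10 0 ]\nT [ 0 0 0 10 ]\n"
        (pwm,) = read_motif_library(self.write(tmp_path, body))
        assert pwm.matrix[0, 0] == pytest.approx(10.5 / 12)

    def test_round_trip(self, tmp_path):
        pwms = [make_pwm("ACGTACGTAA", "M1"), make_pwm("TTTTCCCCGG", "M2")]
        path = tmp_path / "lib.jaspar"
        write_motif_library(pwms, path)
        back = read_motif_library(path, family_map={"M1": "F1", "M2": "F1"}, pseudocount=0.0)
        for orig, rt in zip(pwms, back):
            np.testing.assert_allclose(orig.matrix, rt.matrix, atol=1e-3)

    def test_ragged_matrix_raises(self, tmp_path):
        body = ">M1 X\nA [ 1 1 ]\nC [ 1 1 1 ]\nG [ 1 1 ]\nT [ 1 1 ]\n"
        with pytest.raises(ValueError, match="ragged"):
            read_motif_library(self.write(tmp_path, body))

    def test_missing_family_mapping_raises(self, tmp_path):
        body = ">M9 X\nA [ 1 1 1 1 ]\nC [ 1 1 1 1 ]\nG [ 1 1 1 1 ]\nT [ 1 1 1 1 ]\n"
        with pytest.raises(ValueError, match="family"):
            read_motif_library(self.write(tmp_path, body), family_map={})


class TestScan:
    def test_consensus_limit_finds_exact_occurrences(self, rng):
        pwm = make_pwm("ACGTACGTAC")
        seq = "T" * 50 + "ACGTACGTAC" + "G" * 50 + "ACGTACGTAC" + "T" * 20
        hits = scan({"p": seq}, pwm, pwm.max_score)
        fwd = hits[hits["strand"] == "+"]
        assert fwd["offset"].tolist() == [50, 110]

    def test_palindrome_symmetric_hits(self):
        pwm = make_pwm("ACGCGCGT")  # reverse complement of ACGCGCGT is ACGCGCGT
        seq = "T" * 30 + "ACGCGCGT" + "A" * 30
        hits = scan({"p": seq}, pwm, pwm.max_score)
        by_strand = hits.groupby("strand")["center"].apply(list).to_dict()
        assert by_strand["+"] == by_strand["-"]

    def test_hits_equal_brute_force(self, rng):
        pwms = [make_pwm("".join(rng.choice(list("ACGT"), 10)), f"M{i}") for i in range(3)]
        seqs = {f"s{j}": "".join(rng.choice(list("ACGT"), 300)) for j in range(10)}
        for pwm in pwms:
            thr = default_threshold(pwm)
            got = scan(seqs, pwm, thr)
            for sid, seq in seqs.items():
                expect = brute_force_hits(seq, pwm, thr)
                sub = got[got["peak_id"] == sid]
                assert sorted(zip(sub["offset"], sub["strand"])) == sorted(
                    (o, s) for o, s, _ in expect)

    def test_strand_duality(self, rng):
        pwm = make_pwm("ACGTAAGGTC")
        seq = "".join(rng.choice(list("ACGT"), 400))
        rc = seq.translate(COMP)[::-1]
        fwd = scan({"s": seq}, pwm, 0.6 * pwm.max_score)
        rev = scan({"s": rc}, pwm, 0.6 * pwm.max_score)
        # a + hit at offset o on seq is a - hit at len-L-o on the revcomp
        L = len(pwm)
        plus = sorted(fwd.loc[fwd["strand"] == "+", "offset"])
        minus_rc = sorted(len(seq) - L - rev.loc[rev["strand"] == "-", "offset"])
        assert plus == minus_rc

    def test_n_bases_score_as_background(self):
        pwm = make_pwm("AAAAAA")
        hits = scan({"p": "NNNNNN" + "AAAAAA"}, pwm, pwm.max_score)
        assert hits["offset"].tolist() == [6]

    def test_short_sequence_skipped(self):
        pwm = make_pwm("AAAAAAAAAA")
        hits = scan({"short": "AAA", "ok": "A" * 20}, pwm, pwm.max_score)
        assert hits.attrs["n_skipped"] == 1
        assert set(hits["peak_id"]) == {"ok"}


class TestProjection:
    def test_no_hits_all_false(self):
        out = project_hits(["a", "b"], pd.DataFrame(columns=["peak_id", "pwm_id"]))
        assert out.empty or not out.any().any()

    def test_every_peak_hit_density_one(self):
        hits = pd.DataFrame({"peak_id": ["a", "b"], "pwm_id": "M1"})
        out = project_hits(["a", "b"], hits, window=2)
        assert out["M1"].all()
        assert (out["M1_density"] == 1.0).all()

    def test_rolling_mean_equals_convolution_oracle(self, rng):
        ids = [f"p{i}" for i in range(60)]
        present = rng.random(60) < 0.3
        hits = pd.DataFrame({"peak_id": [i for i, m in zip(ids, present) if m],
                             "pwm_id": "M1"})
        w = 5
        out = project_hits(ids, hits, window=w)
        oracle = pd.Series(present.astype(float)).rolling(w, center=True, min_periods=1).mean()
        np.testing.assert_allclose(out["M1_density"].to_numpy(), oracle.to_numpy())

    def test_unknown_peak_raises(self):
        hits = pd.DataFrame({"peak_id": ["zz"], "pwm_id": ["M1"]})
        with pytest.raises(ValueError, match="unknown"):
            project_hits(["a"], hits)


def seqs_with_presence(pwm, n_with, n_without, prefix):
    with_ = {f"{prefix}w{i}": "T" * 20 + pwm.consensus + "T" * 20 for i in range(n_with)}
    without = {f"{prefix}o{i}": "T" * (40 + len(pwm)) for i in range(n_without)}
    return {**with_, **without}


class TestEnrichment:
    def test_forced_table_odds_ratio_and_exact_p(self):
        pwm = make_pwm("ACGTACGTGG", "M1")
        target = seqs_with_presence(pwm, 40, 60, "t")
        bg = seqs_with_presence(pwm, 10, 90, "b")
        res = enrich(target, bg, [pwm], min_score_bits=pwm.max_score - 1e-9)
        row = res.iloc[0]
        assert (row.n_target_with, row.n_bg_with) == (40, 10)
        assert row.odds_ratio == pytest.approx(6.0)
        # exact hypergeometric tail oracle
        p_oracle = stats.hypergeom.sf(40 - 1, 200, 50, 100)
        assert row.p == pytest.approx(p_oracle, abs=1e-10)
        assert row.p < 1e-5

    def test_identical_rates_null(self):
        pwm = make_pwm("ACGTACGTGG", "M1")
        target = seqs_with_presence(pwm, 20, 20, "t")
        bg = seqs_with_presence(pwm, 20, 20, "b")
        res = enrich(target, bg, [pwm], min_score_bits=pwm.max_score - 1e-9)
        assert res.iloc[0].odds_ratio == pytest.approx(1.0)
        assert res.iloc[0].p >= 0.5

    def test_fisher_matches_hypergeometric_on_random_tables(self, rng):
        for _ in range(50):
            n1, n2 = rng.integers(5, 250, 2)
            k1 = rng.integers(0, n1 + 1)
            k2 = rng.integers(0, n2 + 1)
            _, p = stats.fisher_exact([[k1, n1 - k1], [k2, n2 - k2]], alternative="greater")
            oracle = stats.hypergeom.sf(k1 - 1, n1 + n2, k1 + k2, n1)
            assert p == pytest.approx(oracle, abs=1e-10)

    def test_bh_monotone_and_bounded(self, rng):
        pwms = [make_pwm("".join(rng.choice(list("ACGT"), 10)), f"M{i}") for i in range(8)]
        target = {f"t{i}": "".join(rng.choice(list("ACGT"), 120)) for i in range(30)}
        bg = {f"b{i}": "".join(rng.choice(list("ACGT"), 120)) for i in range(30)}
        res = enrich(target, bg, pwms)
        assert (res["p_adj"] <= 1).all()
        assert (res["p_adj"] >= res["p"] - 1e-12).all()
        assert res["p_adj"].is_monotonic_increasing

    def test_planted_family_ranks_first(self, rng):
        planted = make_pwm("ACGTTGCAGG", "PLANT")
        decoys = [make_pwm("".join(rng.choice(list("ACGT"), 10)), f"D{i}") for i in range(4)]
        target = {}
        for i in range(60):
            s = list("".join(rng.choice(list("ACGT"), 200)))
            if rng.random() < 0.5:
                s[30:40] = planted.consensus
            target[f"t{i}"] = "".join(s)
        bg = {f"b{i}": "".join(rng.choice(list("ACGT"), 200)) for i in range(60)}
        res = enrich(target, bg, [planted] + decoys)
        assert res.iloc[0].pwm_id == "PLANT"

    def test_empty_sets_raise(self):
        pwm = make_pwm("ACGTACGTAC")
        with pytest.raises(ValueError, match="non-empty"):
            enrich({}, {"b": "ACGT" * 20}, [pwm])
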