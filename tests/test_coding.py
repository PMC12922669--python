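"""Trial coding: pair contingency, episodic retrieval, awareness, contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rrcl import code_trials, build_contrasts
from rrcl.coding import code_er, contrast_weights


def make_log(stimuli, responses=None, participant="p", block=1):
    """Build a one-block trial log from position label sequences."""
    n = len(stimuli)
    responses = responses or stimuli
    return pd.DataFrame(
        {
            "participant": participant,
            "block": block,
            "trial": range(1, n + 1),
            "practice": 0,
            "stimulus": stimuli,
            "response": responses,
            "accuracy": [int(s == r) for s, r in zip(stimuli, responses)],
            "rt_ms": 400.0,
        }
    )


L, M, R = "left", "middle", "right"


def brute_force_er(responses):
    """Independent quadratic-time retrieval scan (the test oracle)."""
    out = []
    for i in range(len(responses)):
        if i == 0:
            out.append((None, None))
            continue
        r = responses[i - 1]
        found = None
        for m in range(i - 2, -1, -1):  # largest m <= i-2 with responses[m] == r
            if responses[m] == r:
                found = m
                break
        if found is None:
            out.append((None, None))
        else:
            label = "match" if responses[found + 1] == responses[i] else "mismatch"
            out.append((label, found + 1))  # 1-based trial number of the source
    return out


class TestContingencyCoding:
    def test_cl_example_and_block_initial(self, scheme1):
        coded = code_trials(make_log([M, R, L, R]), scheme1)
        assert coded["cl"].tolist()[0] is None  # no predecessor
        # middle->right hf, right->left hf, left->right lf under set 1
        assert coded["cl"].tolist()[1:] == ["hf", "hf", "lf"]

    def test_pcl_is_lagged_cl(self, scheme1):
        coded = code_trials(make_log([M, L, R, M, L]), scheme1)
        assert coded["pcl"].tolist()[0] is None
        assert coded["pcl"].tolist()[1] is None  # second trial of a block
        assert coded["pcl"].tolist()[2:] == coded["cl"].tolist()[1:-1]

    def test_pcl_two_pair_example(self, scheme1):
        # middle->left (lf), left->right (lf): at "right", pcl=lf and cl=lf
        coded = code_trials(make_log([M, L, R]), scheme1)
        assert coded.loc[2, "pcl"] == "lf"
        assert coded.loc[2, "cl"] == "lf"

    def test_cl_agrees_with_map_lookup(self, scheme1, rng):
        """Brute-force oracle: direct lookup in the scheme's hi map."""
        labels = ["left", "middle", "right"]
        stim = [rng.integers(0, 3)]
        for _ in range(999):
            stim.append(rng.choice([x for x in range(3) if x != stim[-1]]))
        seq = [labels[s] for s in stim]
        coded = code_trials(make_log(seq), scheme1)
        hi = {p.label: scheme1.hi(p).label for p in __import__("rrcl").Position}
        for t in range(1, len(seq)):
            expected = "hf" if hi[seq[t - 1]] == seq[t] else "lf"
            assert coded.loc[t, "cl"] == expected

    def test_unordered_input_rejected(self, scheme1):
        log = make_log([M, R, L])
        log["trial"] = [1, 3, 2]
        with pytest.raises(ValueError, match="ordered"):
            code_trials(log, scheme1)


class TestEpisodicRetrieval:
    def test_worked_nine_trial_sequence(self, scheme1):
        """Reference worked example: L,M,R,L,R,L,M,R,M over trials 1-9.

        Trial 8 (pair M->R) retrieves the last pair starting with a middle
        response (trials 2-3, M->R): match.  Trial 9 (pair R->M) retrieves
        trials 5-6 (R->L): mismatch.
        """
        coded = code_trials(make_log([L, M, R, L, R, L, M, R, M]), scheme1)
        assert coded.loc[7, "er"] == "match"
        assert coded.loc[7, "er_source_trial"] == 2
        assert coded.loc[8, "er"] == "mismatch"
        assert coded.loc[8, "er_source_trial"] == 5

    def test_first_occurrence_undefined(self, scheme1):
        coded = code_trials(make_log([L, M, R]), scheme1)
        assert coded["er"].isna().all()  # no starting response seen twice

    def test_search_runs_over_responses_not_stimuli(self, scheme1):
        # an error at trial 2 (pressed R for stimulus M) redirects retrieval
        stimuli = [L, M, R, L, R]
        responses = [L, R, R, L, R]
        coded = code_trials(make_log(stimuli, responses), scheme1)
        # trial 5's pair starts with response(4)=L; last earlier L response
        # is trial 1, so the retrieved pair is trials 1-2 (L->R): match
        assert coded.loc[4, "er"] == "match"
        assert coded.loc[4, "er_source_trial"] == 1

    def test_quadratic_scan_oracle_agreement(self, rng):
        """Exact agreement with the independent quadratic-time oracle."""
        labels = ["left", "middle", "right"]
        for _ in range(60):
            resp = [rng.integers(0, 3)]
            for _ in range(99):
                nxt = rng.integers(0, 3)
                # responses may repeat (errors); keep some repeats in
                resp.append(nxt)
            seq = [labels[s] for s in resp]
            got = code_er(make_log(seq, seq))
            expected = brute_force_er(seq)
            for i, (lab, src) in enumerate(expected):
                assert got["er"].iloc[i] == lab or (
                    lab is None and pd.isna(got["er"].iloc[i])
                )
                if src is None:
                    assert np.isnan(got["er_source_trial"].iloc[i])
                else:
                    assert got["er_source_trial"].iloc[i] == src

    def test_lookback_stays_within_block(self, scheme1):
        log1 = make_log([L, M, R], block=1)
        log2 = make_log([M, R, L], block=2)
        log = pd.concat([log1, log2], ignore_index=True)
        coded = code_trials(log, scheme1)
        assert coded["er"].isna().all()  # block 2 cannot retrieve block 1


class TestReversalCoding:
    @pytest.mark.parametrize("a", [0, 1, 2])
    @pytest.mark.parametrize("b", [0, 1, 2])
    @pytest.mark.parametrize("c", [0, 1, 2])
    def test_reversal_equals_mixed_contingency_cell(self, scheme1, a, b, c):
        """rev=reversal exactly when {cl, pcl} = {hf, lf} in either order.

        Exhaustive over all 12 two-step paths (plus impossible repeats,
        which are skipped).
        """
        if a == b or b == c:
            pytest.skip("repetition cannot occur")
        labels = ["left", "middle", "right"]
        coded = code_trials(make_log([labels[a], labels[b], labels[c]]), scheme1)
        rev, cl, pcl = coded.loc[2, ["rev", "cl", "pcl"]]
        assert (rev == "reversal") == (a == c)
        assert (rev == "reversal") == ({cl, pcl} == {"hf", "lf"})


class TestAwarenessCoding:
    def _aware(self, participant, correct_pairs):
        rows = []
        for first in (L, M, R):
            for second in (L, M, R):
                if first == second:
                    continue
                rows.append(
                    {
                        "participant": participant,
                        "seq_first": first,
                        "seq_second": second,
                        "true_label": "frequent",
                        "judged_label": "frequent",
                        "correct": int((first, second) in correct_pairs),
                    }
                )
        return pd.DataFrame(rows)

    def test_all_correct_table(self, scheme1):
        aware = self._aware("p", {(a, b) for a in (L, M, R) for b in (L, M, R) if a != b})
        coded = code_trials(make_log([M, R, L]), scheme1, aware)
        assert coded["ca"].tolist() == [None, "correct", "correct"]

    def test_label_depends_only_on_pair_type(self, scheme1):
        aware = self._aware("p", {(M, R)})
        coded = code_trials(make_log([M, R, L, M, R]), scheme1, aware)
        mr = coded[(coded["cl"].notna()) & (coded["stimulus"] == R)]
        assert set(mr["ca"]) == {"correct"}
        other = coded[(coded["ca"].notna()) & (coded["stimulus"] != R)]
        assert set(other["ca"]) == {"incorrect"}

    def test_missing_judgment_rejected(self, scheme1):
        aware = self._aware("p", set()).iloc[:-1]
        with pytest.raises(ValueError, match="no judgment"):
            code_trials(make_log([M, R, M, R, L, M]), scheme1, aware)

    def test_trialwise_labels_match_tables(self, small_coded, small_study):
        """Each trial's awareness label equals the table entry of its pair."""
        for pid, g in small_coded.groupby("participant"):
            aware = small_study.awareness
            aware = aware[aware["participant"] == pid]
            lut = {
                (r.seq_first, r.seq_second): bool(r.correct)
                for r in aware.itertuples()
            }
            for _, blk in g.groupby("block"):
                prev = blk["stimulus"].shift(1)
                mask = blk["trial"] > 1
                expected = [
                    "correct" if lut[(p, s)] else "incorrect"
                    for p, s in zip(prev[mask], blk["stimulus"][mask])
                ]
                assert blk.loc[mask, "ca"].tolist() == expected


class TestContrasts:
    def test_balanced_half_weights(self):
        labels = pd.Series(["hf"] * 50 + ["lf"] * 50)
        assert contrast_weights(labels, "cl") == (0.5, -0.5)

    def test_80_20_split(self):
        labels = pd.Series(["hf"] * 80 + ["lf"] * 20)
        w_hi, w_lo = contrast_weights(labels, "cl")
        assert w_hi == pytest.approx(0.2)
        assert w_lo == pytest.approx(-0.8)
        assert w_hi - w_lo == pytest.approx(1.0)

    @given(n_hi=st.integers(1, 400), n_lo=st.integers(1, 400))
    @settings(derandomize=True, max_examples=50)
    def test_mean_zero_difference_one(self, n_hi, n_lo):
        labels = pd.Series(["hf"] * n_hi + ["lf"] * n_lo)
        df = pd.DataFrame({"cl": labels})
        X, weights = build_contrasts(df, ("cl",))
        assert abs(X["cl"].mean()) < 1e-10
        w_hi, w_lo = weights["cl"]
        assert w_hi - w_lo == 1.0  # exact by construction

    def test_single_level_rejected(self):
        df = pd.DataFrame({"cl": ["hf"] * 10})
        with pytest.raises(ValueError, match="single level"):
            build_contrasts(df, ("cl",))

    def test_undefined_labels_rejected(self):
        df = pd.DataFrame({"cl": ["hf", "lf", None]})
        with pytest.raises(ValueError, match="undefined"):
            build_contrasts(df, ("cl",))

    def test_products_nearly_orthogonal_to_parents(self, rng):
        """Product columns decorrelate from their centered parents.

        The orthogonality of centered predictors and their products holds
        when the predictors are independent (as the transition process makes
        consecutive pair contingencies); residual correlation on iid labels
        is sampling noise of order 1/sqrt(n).
        """
        n = 20000
        df = pd.DataFrame(
            {
                "cl": np.where(rng.random(n) < 0.8, "hf", "lf"),
                "pcl": np.where(rng.random(n) < 0.8, "hf", "lf"),
                "ca": np.where(rng.random(n) < 0.63, "correct", "incorrect"),
            }
        )
        X, _ = build_contrasts(df, ("cl", "pcl", "ca"), (("cl", "pcl"), ("cl", "ca")))
        for prod, parents in [("cl:pcl", ("cl", "pcl")), ("cl:ca", ("cl", "ca"))]:
            for p in parents:
                assert abs(np.corrcoef(X[prod], X[p])[0, 1]) < 0.05

    def test_coding_is_pure(self, small_study, scheme1):
        from rrcl import code_study

        a = code_study(small_study)
        b = code_study(small_study)
        pd.testing.assert_frame_equal(a, b)


class TestRetrievalProbabilityLaw:
    def test_match_probability_tracks_contingency(self, scheme1):
        """P(match | hf) -> p_hi and P(match | lf) -> p_lo on clean data."""
        from rrcl import SimConfig, GroundTruth, generate_study, code_study

        gt = GroundTruth(err_rate=0.0)
        cfg = SimConfig(
            n_participants=2, n_blocks=1, n_practice=10, n_test=6000,
            seed=11, ground_truth=gt,
        )
        coded = code_study(generate_study(cfg)).dropna(subset=["cl", "er"])
        for level, target in (("hf", 0.8), ("lf", 0.2)):
            sub = coded[coded["cl"] == level]
            p = (sub["er"] == "match").mean()
            se = np.sqrt(target * (1 - target) / len(sub))
            assert abs(p - target) < 3 * se
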