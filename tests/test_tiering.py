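"""Evidence-tier scoring, direction consistency and the worked-example table."""
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ptmr.tiering import (
    direction_consistency,
    load_table2,
    score_feature,
    score_table,
    tier_table,
)

PL, BL, BR = "plasma_pwas", "blood_twas", "breast_twas"


class TestScoreFeature:
    @pytest.mark.parametrize(
        "assoc,colocs,score,tier",
        [
            # three layers fully concordant and colocalizing
            ({PL: (0.0049, -4.147), BL: (0.0002, -3.979), BR: (1.46e-5, -4.613)},
             {PL: 0.779, BL: 0.843, BR: 0.863}, 6, "Strong"),
            # one layer misses the colocalization point
            ({PL: (0.0004, 4.839), BL: (1.09e-10, 6.843), BR: (8.14e-7, 5.341)},
             {PL: 0.989, BL: 0.195, BR: 0.79}, 5, "Strong"),
            # significant plasma only, no colocalization anywhere
            ({PL: (7.60e-5, 5.226), BL: (0.6460, 0.460)}, {PL: 0.0, BL: 0.0}, 1, "Weak"),
            # association everywhere, colocalization nowhere
            ({PL: (0.0036, -4.273), BL: (0.0011, -3.451), BR: (0.0004, -3.736)},
             {PL: 0.618, BL: 0.001, BR: 0.175}, 3, "Moderate"),
            # no evidence at all
            ({PL: (0.9, 0.1)}, {}, 0, "None"),
        ],
    )
    def test_scoring_rule(self, assoc, colocs, score, tier):
        rec = score_feature("X", assoc, colocs)
        assert rec.score == score
        assert rec.tier == tier

    def test_pph4_point_is_strict(self):
        rec = score_feature("X", {PL: (0.01, 2.5)}, {PL: 0.75})
        assert rec.score == 1
        rec = score_feature("X", {PL: (0.01, 2.5)}, {PL: 0.7500001})
        assert rec.score == 2

    def test_plasma_layer_required(self):
        with pytest.raises(ValueError, match="plasma"):
            score_feature("X", {BL: (0.01, 2.0)}, {})

    @pytest.mark.parametrize("bad_p", [0.0, -0.1, 1.5])
    def test_out_of_range_pfdr_rejected(self, bad_p):
        with pytest.raises(ValueError):
            score_feature("X", {PL: (bad_p, 1.0)}, {})

    def test_score_bounded_by_layers_with_data(self):
        rec = score_feature("X", {PL: (1e-9, 5.0)}, {PL: 0.99})
        assert rec.score == 2  # one layer can contribute at most 2

    @settings(max_examples=100, deadline=None)
    @given(
        p=st.floats(min_value=1e-12, max_value=1.0),
        delta=st.floats(min_value=0.0, max_value=0.5),
        pph4=st.floats(min_value=0.0, max_value=1.0),
        dup=st.floats(min_value=0.0, max_value=0.3),
    )
    def test_score_monotone_in_evidence(self, p, delta, pph4, dup):
        """Decreasing a p-value or increasing a PPH4 never decreases the score."""
        weaker = score_feature("X", {PL: (p, 2.0)}, {PL: pph4}).score
        stronger = score_feature(
            "X", {PL: (max(p - delta, 1e-15), 2.0)}, {PL: min(pph4 + dup, 1.0)}
        ).score
        assert stronger >= weaker

    def test_tier_boundaries(self):
        # boundaries exactly {0},{1,2},{3,4},{5,6}
        by_score = {0: "None", 1: "Weak", 2: "Weak", 3: "Moderate",
                    4: "Moderate", 5: "Strong", 6: "Strong"}
        assoc_full = {PL: (1e-5, 1.0), BL: (1e-5, 1.0), BR: (1e-5, 1.0)}
        for score, tier in by_score.items():
            n_coloc = max(score - 3, 0)
            n_assoc = min(score, 3)
            assoc = {lay: ((1e-5, 1.0) if i < n_assoc else (0.9, 0.1))
                     for i, lay in enumerate([PL, BL, BR])}
            colocs = {lay: 0.99 for lay in [PL, BL, BR][:n_coloc]}
            rec = score_feature("X", assoc, colocs)
            assert rec.score == score and rec.tier == tier


class TestDirectionConsistency:
    def test_discordant_transcriptome_layers_flagged(self):
        assert direction_consistency({PL: 4.194, BL: -2.547, BR: -3.266}) is False

    def test_concordant_layers_pass(self):
        assert direction_consistency({PL: -4.147, BL: -3.979, BR: -4.613}) is True

    def test_single_layer_not_assessable(self):
        assert direction_consistency({PL: 2.0}) is None

    def test_insignificant_layers_carry_no_direction(self):
        flags = {PL: True, BL: False}
        assert direction_consistency({PL: 5.2, BL: -0.5}, flags) is True

    def test_plasma_required(self):
        with pytest.raises(ValueError):
            direction_consistency({BL: 1.0, BR: 2.0})


class TestWorkedExampleTable:
    def test_scores_and_tiers_reproduce_all_rows(self):
        df = load_table2()
        records = score_table(df)
        assert len(records) == 25
        for rec, (_, row) in zip(records, df.iterrows()):
            assert rec.score == row["score"], rec.feature_id
            assert rec.tier == row["power"].split(" ")[0], rec.feature_id

    def test_inconsistent_protein_flagged(self):
        records = {r.feature_id: r for r in score_table(load_table2())}
        assert records["MST1"].direction_consistent is False
        assert records["MST1"].score == 4  # flag does not change the score
        assert records["CSK"].direction_consistent is True

    def test_tier_counts(self):
        counts = tier_table(score_table(load_table2()))
        assert counts == {"None": 0, "Weak": 14, "Moderate": 6, "Strong": 5}


class TestTierTable:
    def test_empty_input_all_zeros(self):
        assert tier_table([]) == {"None": 0, "Weak": 0, "Moderate": 0, "Strong": 0}

    def test_counts_sum_to_input_length(self):
        recs = score_table(load_table2())
        assert sum(tier_table(recs).values()) == len(recs)

    def test_single_top_score_record(self):
        rec = score_feature(
            "X",
            {PL: (1e-6, 2.0), BL: (1e-6, 2.0), BR: (1e-6, 2.0)},
            {PL: 0.9, BL: 0.9, BR: 0.9},
        )
        assert tier_table([rec]) == {"None": 0, "Weak": 0, "Moderate": 0, "Strong": 1}
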