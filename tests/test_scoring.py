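import numpy as np
import pandas as pd
import pytest

from miriscore.errors import ConfigError
from miriscore.scoring import (
    extract_signature,
    fc_component,
    interaction_score_raw,
    inverse_bonus,
    onco_score,
    scale_is_per_mirna,
    select_prime_targets,
)


class TestFcComponent:
    def test_context_maximum_is_one(self):
        ctx = [0.5, 2.0, -1.0]
        assert fc_component(2.0, ctx)[0] == pytest.approx(1.0)

    def test_zero_stays_zero(self):
        assert fc_component(0.0, [1.0, -1.0])[0] == 0.0

    def test_half_the_positive_maximum(self):
        assert fc_component(1.0, [2.0, 1.0, -3.0])[0] == pytest.approx(0.5)

    def test_negative_scaled_by_min(self):
        assert fc_component(-1.5, [2.0, -3.0])[0] == pytest.approx(-0.5)

    def test_empty_context_raises(self):
        with pytest.raises(ConfigError):
            fc_component(1.0, [])


class TestInverseBonus:
    def test_dn_mirna_upregulated_significant_target(self):
        assert inverse_bonus("DN", 1.2, 0.01)[0] == 1

    def test_insignificant_target_no_bonus(self):
        assert inverse_bonus("DN", 1.2, 0.2)[0] == 0

    def test_same_direction_no_bonus(self):
        assert inverse_bonus("UP", 1.0, 0.001)[0] == 0

    def test_bad_direction_raises(self):
        with pytest.raises(ValueError):
            inverse_bonus("SIDEWAYS", 1.0, 0.01)


class TestInteractionScoreRaw:
    def test_maximal_dn_oncogene_pattern(self):
        assert interaction_score_raw(1, 1, 1, -1, 1, "DN")[0] == pytest.approx(5.0)

    def test_maximal_up_suppressor_pattern(self):
        assert interaction_score_raw(1, -1, 1, 1, -1, "UP")[0] == pytest.approx(5.0)

    def test_hand_arithmetic_dn(self):
        got = interaction_score_raw(0.65, 0.4, 0, -0.2, 0.3, "DN")[0]
        assert got == pytest.approx(1.55)

    def test_direction_flip_changes_signed_terms_only(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            c1 = rng.uniform(0.65, 1)
            c2, c4, c5 = rng.uniform(-1, 1, size=3)
            c3 = rng.integers(0, 2)
            up = interaction_score_raw(c1, c2, c3, c4, c5, "UP")[0]
            dn = interaction_score_raw(c1, c2, c3, c4, c5, "DN")[0]
            assert up + dn == pytest.approx(2 * (c1 + c3))

    def test_unknown_direction_raises(self):
        with pytest.raises(ValueError):
            interaction_score_raw(1, 0, 0, 0, 0, "XX")


class TestScaleIsPerMirna:
    def test_minmax_arithmetic(self):
        scaled, degen = scale_is_per_mirna([5.0, 0.0, -5.0])
        assert np.allclose(scaled, [1.0, 0.0, -1.0])
        assert not degen

    def test_maximum_is_exactly_one(self):
        rng = np.random.default_rng(1)
        raw = rng.normal(size=17)
        scaled, _ = scale_is_per_mirna(raw)
        assert scaled.max() == 1.0
        assert scaled.min() == -1.0

    def test_degenerate_all_equal(self):
        scaled, degen = scale_is_per_mirna([2.0, 2.0, 2.0])
        assert degen
        assert np.allclose(scaled, 0.0)

    def test_empty_raises(self):
        with pytest.raises(ConfigError):
            scale_is_per_mirna([])


def _fake_scored(rows):
    return pd.DataFrame(
        rows,
        columns=["mirna", "direction", "gene", "c1", "c2", "c3", "c4", "c5",
                 "is_raw", "is_scaled", "degenerate"],
    )


class TestSelectPrimeTargets:
    def test_ties_kept_and_flagged(self):
        scored = _fake_scored([
            ("m1", "DN", "g1", 1, 0, 0, 0, 0, 3.0, 1.0, False),
            ("m1", "DN", "g2", 1, 0, 0, 0, 0, 3.0, 1.0, False),
            ("m1", "DN", "g3", 1, 0, 0, 0, 0, 0.0, -1.0, False),
            ("m2", "UP", "g1", 1, 0, 0, 0, 0, 2.0, 1.0, False),
        ])
        prime = select_prime_targets(scored)
        assert len(prime) == 3
        m1 = prime[prime["mirna"] == "m1"]
        assert m1["tied"].all()
        assert set(prime.loc[prime["gene"] == "g1", "gene_prime_count"]) == {2}

    def test_degenerate_mirna_excluded(self):
        scored = _fake_scored([
            ("m1", "DN", "g1", 1, 0, 0, 0, 0, 1.0, 0.0, True),
        ])
        assert len(select_prime_targets(scored)) == 0

    def test_synthetic_prime_edges(self, default_dataset, pipeline_results):
        prime = pipeline_results["prime"]
        edges = set(zip(default_dataset.truth_edges["mirna"],
                        default_dataset.truth_edges["gene"]))
        truth = default_dataset.truth_mirnas["mirna"]
        recovered = sum(
            any((m, g) in edges for g in prime[prime["mirna"] == m]["gene"])
            for m in truth
        )
        assert recovered / len(truth) >= 0.95


class TestOncoScore:
    def test_extremes(self):
        prime = _fake_scored([
            ("m1", "DN", "onco", 1, 1.0, 1, -1.0, 1.0, 5.0, 1.0, False),
            ("m2", "UP", "supp", 1, -1.0, 1, 1.0, -1.0, 5.0, 1.0, False),
            ("m3", "DN", "mid", 1, 0.1, 0, 0.0, 0.0, 1.0, 1.0, False),
        ])
        os_table = onco_score(prime)
        assert os_table.loc["onco", "os_raw"] == pytest.approx(3.0)
        assert os_table.loc["onco", "os_scaled"] == pytest.approx(1.0)
        assert os_table.loc["supp", "os_raw"] == pytest.approx(-3.0)
        assert os_table.loc["supp", "os_scaled"] == pytest.approx(-1.0)

    def test_minmax_matches_brute_force(self):
        rng = np.random.default_rng(4)
        rows = []
        for i in range(15):
            c2, c4, c5 = rng.uniform(-1, 1, size=3)
            rows.append((f"m{i}", "DN", f"g{i}", 1, c2, 0, c4, c5, 1.0, 1.0, False))
        os_table = onco_score(_fake_scored(rows))
        raw = os_table["os_raw"].to_numpy()
        lo, hi = raw.min(), raw.max()
        expected = 2 * (raw - lo) / (hi - lo) - 1
        assert np.allclose(os_table["os_scaled"], expected)

    def test_multi_prime_gene_uses_max_abs_interaction(self):
        prime = _fake_scored([
            ("m1", "DN", "g", 1, 0.2, 0, -0.1, 0.0, 1.0, 1.0, False),
            ("m2", "DN", "g", 1, 0.9, 0, -0.8, 0.5, 3.0, 1.0, False),
            ("m3", "DN", "h", 1, 0.0, 0, 0.0, 0.0, 0.5, 1.0, False),
        ])
        os_table = onco_score(prime)
        assert os_table.loc["g", "os_raw"] == pytest.approx(0.9 + 0.8 + 0.5)

    def test_empty_prime_raises(self):
        with pytest.raises(ConfigError):
            onco_score(_fake_scored([]))


class TestExtractSignature:
    def test_dedup_arithmetic_65_of_85(self):
        # 85 prime interactions; 12 genes carry 32 of them (8x3 + 4x2)
        rows = []
        g = 0
        for i in range(8):
            for _ in range(3):
                rows.append((f"m{len(rows)}", "DN", f"dup{i}", 1, 0.5, 0, 0, 0, 1, 1.0, False))
        for i in range(8, 12):
            for _ in range(2):
                rows.append((f"m{len(rows)}", "DN", f"dup{i}", 1, 0.5, 0, 0, 0, 1, 1.0, False))
        while len(rows) < 85:
            rows.append((f"m{len(rows)}", "DN", f"uniq{g}", 1, 0.1, 0, 0, 0, 1, 1.0, False))
            g += 1
        prime = _fake_scored(rows)
        assert len(prime) == 85
        sig = extract_signature(prime, onco_score(prime))
        assert len(sig) == 65
        assert (sig.loc[[f"dup{i}" for i in range(8)], "multiplicity"] == 3).all()

    def test_no_duplicates_signature_equals_prime_size(self):
        rows = [(f"m{i}", "DN", f"g{i}", 1, 0.1 * i, 0, 0, 0, 1, 1.0, False)
                for i in range(10)]
        prime = _fake_scored(rows)
        sig = extract_signature(prime, onco_score(prime))
        assert len(sig) == 10

    def test_planted_multi_target_multiplicity(self, default_dataset, pipeline_results):
        sig = pipeline_results["signature"]
        tg = default_dataset.truth_genes
        prime_onco = tg[(tg["label"] == "oncogene") & tg["prime"]]["gene"].iloc[0]
        assert sig.loc[prime_onco, "multiplicity"] == 4
        assert sig.index.get_loc(prime_onco) == 0  # top of the ranking


class TestEndToEndScoring:
    def test_is_scaled_bounds(self, pipeline_results):
        scored = pipeline_results["scored"]
        ok = scored[~scored["degenerate"]]
        for _m, grp in ok.groupby("mirna"):
            assert grp["is_scaled"].max() == 1.0
            assert grp["is_scaled"].min() == -1.0
        assert scored["is_raw"].between(-4, 5).all()

    def test_direction_consistency(self, pipeline_results):
        scored = pipeline_results["scored"]
        assert set(scored["direction"]) <= {"UP", "DN"}
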