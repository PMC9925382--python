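import numpy as np
import pandas as pd
import pytest

import missplice as mp
from missplice.deltarules import RuleConfig

from ._oracles import oracle_delta_predictions
from .conftest import make_transcript


def _rec(tx, pos, channel, score, vid="V1"):
    return mp.DeltaScoreRecord(
        variant_id=vid, chrom=tx.chrom, pos=pos, channel=channel, score=score
    )


@pytest.fixture()
def tx6():
    return make_transcript(6)


@pytest.fixture()
def donor_site(tx6):
    return tx6.site(3, "donor")


def _with_gate(tx, site, extra):
    """Scores always including the affected-site loss that gates the rules."""
    return [_rec(tx, site.pos, f"{site.kind}_loss", 0.9)] + extra


class TestRules:
    def test_single_exon_skipping_needs_both_flanking_losses(self, tx6, donor_site):
        scores = _with_gate(tx6, donor_site,
                            [_rec(tx6, tx6.acceptor_pos(3), "acceptor_loss", 0.8)])
        result = mp.interpret_delta_scores(scores, donor_site, tx6)
        cats = [(p.category, p.exons) for p in result.predictions]
        assert ("single_exon_skipping", [3]) in cats

    def test_double_extension_requires_next_intron_loss(self, tx6, donor_site):
        scores = _with_gate(tx6, donor_site, [
            _rec(tx6, tx6.acceptor_pos(3), "acceptor_loss", 0.8),
            _rec(tx6, tx6.donor_pos(4), "donor_loss", 0.3),
        ])
        result = mp.interpret_delta_scores(scores, donor_site, tx6)
        cats = {(p.category, tuple(p.exons or ())) for p in result.predictions}
        assert ("double_exon_skipping", (3, 4)) in cats
        # the double is only ever emitted alongside its constituent single
        assert ("single_exon_skipping", (3,)) in cats

    def test_intron_retention_needs_both_intron_flanks(self, tx6, donor_site):
        scores = _with_gate(tx6, donor_site,
                            [_rec(tx6, tx6.acceptor_pos(4), "acceptor_loss", 0.5)])
        result = mp.interpret_delta_scores(scores, donor_site, tx6)
        assert [("intron_retention", p.intron) for p in result.predictions
                if p.category == "intron_retention"] == [("intron_retention", 3)]

    def test_cryptic_gain_within_flanking_bounds(self, tx6, donor_site):
        scores = _with_gate(tx6, donor_site,
                            [_rec(tx6, donor_site.pos + 37, "donor_gain", 0.4)])
        result = mp.interpret_delta_scores(scores, donor_site, tx6)
        cryptics = [p for p in result.predictions if p.category == "cryptic_donor"]
        assert [p.cryptic_pos for p in cryptics] == [donor_site.pos + 37]

    def test_gain_beyond_flanking_bounds_is_other(self, tx6, donor_site):
        far = tx6.acceptor_pos(6) + 5  # well outside exon3/intron3
        scores = _with_gate(tx6, donor_site, [_rec(tx6, far, "donor_gain", 0.6)])
        result = mp.interpret_delta_scores(scores, donor_site, tx6)
        assert not [p for p in result.predictions if p.category == "cryptic_donor"]
        assert any("outside flanking bounds" in reason for _, reason in result.other_records)

    def test_mismatched_gain_channel_is_other(self, tx6, donor_site):
        scores = _with_gate(tx6, donor_site,
                            [_rec(tx6, donor_site.pos + 37, "acceptor_gain", 0.6)])
        result = mp.interpret_delta_scores(scores, donor_site, tx6)
        assert not [p for p in result.predictions if p.category.startswith("cryptic")]

    def test_gain_at_annotated_site_is_other(self, tx6, donor_site):
        scores = _with_gate(tx6, donor_site,
                            [_rec(tx6, tx6.donor_pos(4), "donor_gain", 0.7)])
        result = mp.interpret_delta_scores(scores, donor_site, tx6)
        assert any("gain at annotated site" in reason for _, reason in result.other_records)

    def test_no_affected_site_loss_means_no_predicted_impact(self, tx6, donor_site):
        scores = [_rec(tx6, donor_site.pos + 37, "donor_gain", 0.9)]
        result = mp.interpret_delta_scores(scores, donor_site, tx6)
        assert result.status == "no predicted impact"
        assert result.predictions == []
        assert result.missplicing_predicted is False


def test_every_score_lands_in_exactly_one_bucket(tx6, donor_site):
    rng = np.random.default_rng(77)
    positions = ([tx6.donor_pos(i) for i in range(1, 6)]
                 + [tx6.acceptor_pos(i) for i in range(2, 7)]
                 + [donor_site.pos + 9, donor_site.pos + 800, donor_site.pos - 15])
    channels = ["donor_loss", "acceptor_loss", "donor_gain", "acceptor_gain"]
    for trial in range(30):
        scores = [_rec(tx6, donor_site.pos, "donor_loss", 0.9)]
        for _ in range(rng.integers(0, 12)):
            scores.append(
                _rec(tx6, int(rng.choice(positions)), str(rng.choice(channels)),
                     float(rng.uniform(0.002, 1.0)))
            )
        result = mp.interpret_delta_scores(scores, donor_site, tx6)
        assert sum(result.bucket_counts.values()) == len(scores)


@pytest.mark.parametrize("strand", ["+", "-"])
@pytest.mark.parametrize("site_spec", [(3, "donor"), (4, "acceptor")])
def test_rule_engine_matches_brute_force_oracle(strand, site_spec):
    """Randomized score sets on a 6-exon transcript: the engine's emitted
    prediction identities equal an independent exhaustive rule oracle."""
    tx = make_transcript(6, strand=strand)
    site = tx.site(*site_spec)
    seed = (101 if strand == "+" else 202) + 10 * site_spec[0]
    rng = np.random.default_rng(seed)
    annotated = ([tx.donor_pos(i) for i in range(1, 6)]
                 + [tx.acceptor_pos(i) for i in range(2, 7)])
    sign = 1 if strand == "+" else -1
    unannotated = [site.pos + d * sign for d in (-20, 9, 33, 150, 1200)]
    channels = ["donor_loss", "acceptor_loss", "donor_gain", "acceptor_gain"]
    config = RuleConfig()
    checked = 0
    for trial in range(60):
        scores = []
        for _ in range(int(rng.integers(1, 14))):
            pos = int(rng.choice(annotated + unannotated))
            scores.append(_rec(tx, pos, str(rng.choice(channels)),
                               float(rng.uniform(0.0, 1.0))))
        expected = oracle_delta_predictions(
            scores, site, tx, config.decision_threshold
        )
        result = mp.interpret_delta_scores(scores, site, tx, config)
        got = {p.identity for p in result.predictions}
        # oracle folds single/double skipping into one identity vocabulary
        assert got == expected, (trial, sorted(got), sorted(expected))
        checked += 1
    assert checked == 60


def test_raising_threshold_never_adds_predictions(tx6, donor_site):
    rng = np.random.default_rng(9)
    annotated = ([tx6.donor_pos(i) for i in range(1, 6)]
                 + [tx6.acceptor_pos(i) for i in range(2, 7)])
    scores = [_rec(tx6, donor_site.pos, "donor_loss", 0.9)]
    for _ in range(10):
        scores.append(_rec(tx6, int(rng.choice(annotated)),
                           str(rng.choice(["donor_loss", "acceptor_loss"])),
                           float(rng.uniform(0.002, 1.0))))
    previous = None
    for thr in (0.011, 0.05, 0.2, 0.5, 0.8):
        got = {p.identity for p in mp.interpret_delta_scores(
            scores, donor_site, tx6, RuleConfig(decision_threshold=thr)).predictions}
        if previous is not None:
            assert got <= previous
        previous = got


class TestLoading:
    def test_neutral_scores_dropped_and_counted(self, tmp_path, tx6):
        path = tmp_path / "d.tsv"
        pd.DataFrame(
            {"variant_id": ["V1"] * 3, "chrom": ["chr1"] * 3,
             "pos": [1000, 1001, 1002],
             "channel": ["donor_loss", "donor_gain", "acceptor_gain"],
             "score": [0.0005, 0.001, 0.2]}
        ).to_csv(path, sep="\t", index=False)
        records, stats = mp.load_delta_scores(path, transcripts=[tx6])
        assert len(records) == 1 and stats["n_neutral"] == 2

    def test_out_of_window_records_dropped(self, tmp_path, tx6):
        path = tmp_path / "d.tsv"
        pd.DataFrame(
            {"variant_id": ["V1"] * 2, "chrom": ["chr1"] * 2,
             "pos": [1000, 6001],
             "channel": ["donor_loss", "donor_gain"], "score": [0.5, 0.5]}
        ).to_csv(path, sep="\t", index=False)
        records, stats = mp.load_delta_scores(
            path, variant_positions={"V1": 1000}
        )
        assert len(records) == 1 and stats["n_out_of_window"] == 1

    def test_fixture_delta_file_loads_expected_count(self, fixture100, transcripts100):
        vdf = pd.read_csv(fixture100.paths["variants"], sep="\t")
        records, _ = mp.load_delta_scores(
            fixture100.paths["delta_scores"], transcripts=transcripts100,
            variant_positions=dict(zip(vdf.variant_id, vdf.pos)),
        )
        for vid, truth in fixture100.truth["delta"].items():
            assert sum(r.variant_id == vid for r in records) == truth["n_above_neutral"]

    def test_spliceai_vcf_dialect(self, tmp_path):
        path = tmp_path / "s.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=SpliceAI,Number=.,Type=String,Description="x">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t1000\t.\tG\tA\t.\t.\t"
            "SpliceAI=A|GENE|0.05|0.00|0.60|0.02|-10|3|-2|7\n"
        )
        records, stats = mp.load_delta_scores(path, format="spliceai_vcf")
        by_channel = {r.channel: r for r in records}
        assert by_channel["donor_gain"].score == 0.60
        assert by_channel["donor_gain"].pos == 998
        assert "acceptor_loss" not in by_channel  # 0.00 is neutral
        assert stats["n_neutral"] == 1
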