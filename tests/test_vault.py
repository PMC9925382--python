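import numpy as np
import pytest

import missplice as mp
from missplice.simfix import FixtureConfig, PlantedEvent, default_config, generate_fixture
from missplice.vault import VaultConfig, group_concordance


def _build(fx):
    txs = mp.load_transcripts(fx.paths["annotation"])
    tables = [mp.read_junction_table(fx.paths["junctions"], "snaptron_tsv")]
    return mp.build_vault(tables, txs, sample_groups=fx.truth["groups"])


@pytest.fixture(scope="module")
def grouped_vault(tmp_path_factory):
    """1,000-sample fixture with two tissue groups and one group-specific
    rank swap planted at gene 1."""
    events = [
        PlantedEvent(0, 4, "donor", "cryptic_donor", 0.40, cryptic_offset=13),
        PlantedEvent(0, 4, "donor", "exon_skipping", 0.12, skipped_exons=(4,)),
        # gene 1: global order cryptic > skip, but reversed inside "muscle"
        PlantedEvent(1, 4, "donor", "cryptic_donor", 0.30, cryptic_offset=21,
                     group_frequencies={"muscle": 0.05, "blood": 0.55}),
        PlantedEvent(1, 4, "donor", "exon_skipping", 0.20, skipped_exons=(4,),
                     group_frequencies={"muscle": 0.45, "blood": 0.05}),
    ]
    cfg = FixtureConfig(
        n_genes=2, n_samples=1000, planted_events=events,
        groups={"blood": 0.5, "muscle": 0.5}, variants=[],
    )
    fx = generate_fixture(cfg, tmp_path_factory.mktemp("grouped"), seed=23)
    return fx, _build(fx)


def test_planted_frequency_order_is_recovered(vault100, fixture100):
    table = mp.query_top_events(vault100, "TX1:E4:donor", config=VaultConfig(top_n=10))
    truth = sorted(
        (e for e in fixture100.truth["events"] if e["site_id"] == "TX1:E4:donor"),
        key=lambda e: -e["n_samples"],
    )
    got = [r.n_samples for r in table.rows]
    assert got == [e["n_samples"] for e in truth if e["n_samples"] > 0]
    assert [r.rank for r in table.rows] == list(range(1, len(got) + 1))


def test_annotated_sample_count_matches_fixture(vault100, fixture100):
    # annotated splicing support is tallied per site from its own intron
    n = vault100.annotated_n_samples("TX1:E4:donor")
    assert 0 < n <= fixture100.truth["n_samples"]
    assert n == vault100.annotated_n_samples("TX1:E4:donor")  # deterministic


def test_tie_break_prefers_more_reads_then_tighter_event():
    tx = mp.TranscriptModel("T", "G", "chr1", "+",
                            exons=[(100, 199), (400, 499), (700, 799), (1000, 1099)])
    site = tx.site(2, "donor")

    def jc(start, end, reads):
        return mp.JunctionCounts(
            mp.Junction("chr1", "+", start, end),
            per_sample={f"S{i}": r for i, r in enumerate(reads)},
        )

    tables = [[
        jc(500, 699, [1, 1, 1]),          # annotated intron 2
        jc(513, 699, [5, 5]),             # cryptic +13, 2 samples, 10 reads
        jc(530, 699, [1, 1]),             # cryptic +30, 2 samples, 2 reads
        jc(521, 699, [1, 1]),             # cryptic +21, 2 samples, 2 reads
    ]]
    db = mp.build_vault(tables, [tx])
    rows = mp.query_top_events(db, site.site_id).rows
    assert [r.event.cryptic_offset for r in rows] == [13, 21, 30]


def test_rebuild_is_deterministic(fixture100):
    a, b = _build(fixture100), _build(fixture100)
    for site_id in a.sites:
        ea = [(e.identity, e.n_samples, e.total_reads) for e in a.events[site_id]]
        eb = [(e.identity, e.n_samples, e.total_reads) for e in b.events[site_id]]
        assert ea == eb


def test_save_load_round_trip(vault100, tmp_path):
    path = tmp_path / "v.db"
    vault100.save(path)
    back = mp.VaultDB.load(path)
    for site_id in vault100.sites:
        a = sorted((e.identity, e.n_samples) for e in vault100.events[site_id])
        b = sorted((e.identity, e.n_samples) for e in back.events[site_id])
        assert a == b
    t1 = mp.query_top_events(vault100, "TX1:E4:donor").to_dataframe()
    t2 = mp.query_top_events(back, "TX1:E4:donor").to_dataframe()
    assert t1.equals(t2)


def test_top_n_one_returns_highest_supported_event(vault100):
    table = mp.query_top_events(vault100, "TX1:E4:donor", config=VaultConfig(top_n=1))
    starred = table.top_star_rows()
    assert len(starred) == 1
    assert starred[0].n_samples == max(r.n_samples for r in table.rows)


def test_filter_excludes_but_keeps_in_unfiltered_list():
    tx = mp.TranscriptModel("T", "G", "chr1", "+",
                            exons=[(i * 300 + 1, i * 300 + 100) for i in range(6)])
    site = tx.site(3, "donor")

    def jc(start, end, n):
        return mp.JunctionCounts(
            mp.Junction("chr1", "+", start, end),
            per_sample={f"S{i}": 1 for i in range(n)},
        )

    # 3-exon skipping with the HIGHEST sample count, plus one cryptic
    skip3 = jc(tx.donor_pos(1) + 1, tx.acceptor_pos(5) - 1, 30)
    cryp = jc(tx.donor_pos(3) + 14, tx.acceptor_pos(4) - 1, 5)
    db = mp.build_vault([[skip3, cryp]], [tx])
    table = mp.query_top_events(db, site.site_id)
    assert table.rows[0].event.category == "exon_skipping"
    assert table.rows[0].in_top_n_star is False  # filtered: 3 exons skipped
    assert table.rows[0].filtered_rank is None
    starred = table.top_star_rows()
    assert [r.event.category for r in starred] == ["cryptic_donor"]
    assert starred[0].filtered_rank == 1


def test_top_n_and_filter_monotonicity(vault100):
    site = "TX1:E4:donor"
    previous: set = set()
    for n in range(1, 8):
        cfg = VaultConfig(top_n=n)
        ids = {r.event.identity for r in mp.query_top_events(vault100, site, cfg).top_star_rows()}
        assert previous <= ids
        previous = ids
    base = VaultConfig()
    n_base = len(mp.query_top_events(vault100, site, base).top_star_rows())
    for relaxed in (VaultConfig(max_cryptic_nt=2000), VaultConfig(max_skipped_exons=5),
                    VaultConfig(top_n=10, max_cryptic_nt=5000, max_skipped_exons=6)):
        rows = mp.query_top_events(vault100, site, relaxed).rows
        eligible = [r for r in rows if r.filtered_rank is not None]
        assert len(eligible) >= n_base


def test_group_partition_sums_to_global(grouped_vault):
    fx, db = grouped_vault
    groups = db.groups()
    for site_id, events in db.events.items():
        for ev in events:
            table = {g: 0 for g in groups}
            for g in groups:
                rows = mp.query_top_events(db, site_id, group=g).rows
                for r in rows:
                    if r.event.identity == ev.identity:
                        table[g] = r.n_samples
            assert sum(table.values()) == ev.n_samples


def test_group_query_ranks_follow_group_truth(grouped_vault):
    fx, db = grouped_vault
    site = "TX2:E4:donor"
    muscle = mp.query_top_events(db, site, group="muscle").rows
    glob = mp.query_top_events(db, site).rows
    assert glob[0].event.category == "cryptic_donor"
    assert muscle[0].event.category == "exon_skipping"


def test_concordance_self_is_one(grouped_vault):
    fx, db = grouped_vault
    out = group_concordance(db, groups=["blood"], reference="blood",
                            config=VaultConfig(top_n=2))
    conc = out["rank_concordance"]
    assert (conc.dropna(subset=["concordance"]).concordance == 1.0).all()
    assert out["spearman"]["blood"] == pytest.approx(1.0)


def test_concordance_detects_planted_rank_swap(grouped_vault):
    fx, db = grouped_vault
    out = group_concordance(db, groups=["muscle", "blood"], reference=None,
                            sites=["TX1:E4:donor", "TX2:E4:donor"],
                            config=VaultConfig(top_n=1))
    conc = out["rank_concordance"].set_index(["group", "rank"]).concordance
    # muscle swaps ranks 1<->2 at one of the two sites
    assert conc[("muscle", 1)] == pytest.approx(0.5)
    assert conc[("blood", 1)] == pytest.approx(1.0)


def test_cooccurrence_extremes():
    tx = mp.TranscriptModel("T", "G", "chr1", "+",
                            exons=[(100, 199), (400, 499), (700, 799), (1000, 1099)])

    def jc(start, end, samples):
        return mp.JunctionCounts(
            mp.Junction("chr1", "+", start, end), per_sample={s: 1 for s in samples}
        )

    shared = ["S1", "S2", "S3"]
    tables = [[
        jc(513, 699, shared),                # cryptic +13
        jc(526, 699, shared),                # cryptic +26: identical samples
        jc(547, 699, ["S7", "S8"]),          # cryptic +47: disjoint
    ]]
    db = mp.build_vault(tables, [tx])
    site = "T:E2:donor"
    same = mp.event_cooccurrence(db, site, ("cryptic_donor", 512), ("cryptic_donor", 525))
    assert same["jaccard"] == 1.0
    disjoint = mp.event_cooccurrence(db, site, ("cryptic_donor", 512), ("cryptic_donor", 546))
    assert disjoint["jaccard"] == 0.0


def test_cooccurrence_recovers_planted_overlap(tmp_path):
    cfg = default_config(n_samples=1000, n_genes=1)
    fx = generate_fixture(cfg, tmp_path / "co", seed=5)
    db = _build(fx)
    out = mp.event_cooccurrence(db, "TX1:E4:donor", 1, 2)
    # planted 5% overlap between the top-2 events; binomial error at n=1000
    assert out["jaccard"] == pytest.approx(0.05, abs=0.03)


def test_variant_spec_resolution(vault100, fixture100):
    import pandas as pd

    vdf = pd.read_csv(fixture100.paths["variants"], sep="\t")
    row = vdf.iloc[0]
    sites = mp.resolve_sites(vault100, {"chrom": row.chrom, "pos": int(row.pos)})
    assert sites[0].site_id == row.site_id


def test_unresolvable_variant_lists_nearest_sites(vault100):
    with pytest.raises(KeyError, match="nearest annotated sites"):
        mp.resolve_sites(vault100, {"chrom": "chr1", "pos": 2})


def test_zero_samples_is_an_error(transcripts100):
    with pytest.raises(ValueError, match="zero samples"):
        mp.build_vault([[]], transcripts100)
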