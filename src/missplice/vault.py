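"""Ranked per-splice-site catalogs of natural mis-splicing events.

For every annotated donor and acceptor, events classified from aggregated
junction tables are ranked by the number of samples supporting them; the
"starred" filter (at most ``max_skipped_exons`` skipped, cryptic boundary
within ``max_cryptic_nt``) defines the Top-N* shortlist used as a
prediction of variant-associated mis-splicing. Defaults (Top-4, <=2 exons,
<=600 nt) are the optimized configuration.

Persistence is a single-file embedded SQLite store plus a canonical TSV
export; rebuilding from identical inputs is deterministic.
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

import pandas as pd
from scipy import stats

from .annotation import SpliceSite, TranscriptModel, build_splice_site_index
from .events import MisSplicingEvent, events_for_site
from .junctions import Junction, JunctionCounts, filter_and_aggregate

__all__ = [
    "VaultConfig",
    "EventRow",
    "RankedEventTable",
    "VaultDB",
    "build_vault",
    "resolve_sites",
    "query_top_events",
    "group_concordance",
    "event_cooccurrence",
]

# variant-to-site resolution windows around the annotated boundary
# (exonic bases, intronic bases) in transcript direction
DONOR_REGION = (3, 6)
ACCEPTOR_REGION = (2, 20)


@dataclass
class VaultConfig:
    """Filter/ranking configuration; defaults reproduce Top-4*."""

    top_n: int = 4
    max_skipped_exons: int = 2
    max_cryptic_nt: int = 600
    group_by: Optional[str] = None

    def __post_init__(self):
        if min(self.top_n, self.max_skipped_exons, self.max_cryptic_nt) < 1:
            raise ValueError("VaultConfig values must be positive")

    def passes_filter(self, ev: MisSplicingEvent) -> bool:
        if ev.category == "exon_skipping":
            return len(ev.skipped_exons) <= self.max_skipped_exons
        return abs(ev.cryptic_offset) <= self.max_cryptic_nt


@dataclass
class EventRow:
    rank: int  # unfiltered rank, 1-based contiguous
    event: MisSplicingEvent
    n_samples: int
    total_reads: int
    filtered_rank: Optional[int]
    in_top_n_star: bool


@dataclass
class RankedEventTable:
    site: SpliceSite
    annotated_n_samples: int
    rows: list[EventRow] = field(default_factory=list)

    def top_star_rows(self) -> list[EventRow]:
        return [r for r in self.rows if r.in_top_n_star]

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            ev = r.event
            recs.append(
                {
                    "site_id": self.site.site_id,
                    "rank": r.rank,
                    "filtered_rank": r.filtered_rank,
                    "in_top_n_star": r.in_top_n_star,
                    "category": ev.category,
                    "skipped_exons": ",".join(map(str, ev.skipped_exons or [])),
                    "cryptic_pos": ev.cryptic_pos,
                    "cryptic_offset": ev.cryptic_offset,
                    "n_samples": r.n_samples,
                    "total_reads": r.total_reads,
                    "max_event_ratio": ev.max_event_ratio,
                    "annotated_n_samples": self.annotated_n_samples,
                }
            )
        return pd.DataFrame(recs)


@dataclass
class VaultDB:
    """In-memory catalog: sites, full unfiltered event lists, group data."""

    transcripts: dict[str, TranscriptModel]
    sites: dict[str, SpliceSite]
    events: dict[str, list[MisSplicingEvent]]
    annotated_samples: dict[str, frozenset]
    sample_groups: Optional[dict[str, str]]
    n_total_samples: int
    config: VaultConfig
    provenance: dict = field(default_factory=dict)

    def annotated_n_samples(self, site_id: str, group: Optional[str] = None) -> int:
        samples = self.annotated_samples.get(site_id, frozenset())
        if group is None:
            return len(samples)
        if self.sample_groups is None:
            raise ValueError("vault built without sample groups")
        return sum(1 for s in samples if self.sample_groups.get(s) == group)

    def groups(self) -> list[str]:
        if self.sample_groups is None:
            return []
        return sorted(set(self.sample_groups.values()))

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        con = sqlite3.connect(str(path))
        try:
            cur = con.cursor()
            cur.executescript(
                """
                DROP TABLE IF EXISTS meta; DROP TABLE IF EXISTS transcripts;
                DROP TABLE IF EXISTS sites; DROP TABLE IF EXISTS events;
                CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT);
                CREATE TABLE transcripts (transcript_id TEXT PRIMARY KEY, payload TEXT);
                CREATE TABLE sites (site_id TEXT PRIMARY KEY, payload TEXT,
                                    annotated_samples TEXT);
                CREATE TABLE events (site_id TEXT, payload TEXT);
                """
            )
            cur.execute(
                "INSERT INTO meta VALUES ('config', ?)",
                (json.dumps(vars(self.config)),),
            )
            cur.execute(
                "INSERT INTO meta VALUES ('provenance', ?)",
                (json.dumps(self.provenance, sort_keys=True),),
            )
            cur.execute(
                "INSERT INTO meta VALUES ('n_total_samples', ?)",
                (str(self.n_total_samples),),
            )
            cur.execute(
                "INSERT INTO meta VALUES ('sample_groups', ?)",
                (json.dumps(self.sample_groups, sort_keys=True),),
            )
            for tx in self.transcripts.values():
                cur.execute(
                    "INSERT INTO transcripts VALUES (?, ?)",
                    (tx.transcript_id, json.dumps({
                        "gene_id": tx.gene_id, "chrom": tx.chrom, "strand": tx.strand,
                        "exons": tx.exons, "cds_start": tx.cds_start,
                        "cds_end": tx.cds_end,
                    })),
                )
            for site_id, site in sorted(self.sites.items()):
                cur.execute(
                    "INSERT INTO sites VALUES (?, ?, ?)",
                    (site_id, json.dumps(vars(site)),
                     json.dumps(sorted(self.annotated_samples.get(site_id, frozenset())))),
                )
                for ev in self.events.get(site_id, []):
                    j = ev.junction
                    cur.execute(
                        "INSERT INTO events VALUES (?, ?)",
                        (site_id, json.dumps({
                            "category": ev.category,
                            "skipped_exons": ev.skipped_exons,
                            "cryptic_pos": ev.cryptic_pos,
                            "cryptic_offset": ev.cryptic_offset,
                            "junction": [j.chrom, j.strand, j.intron_start,
                                         j.intron_end, j.donor_annotated,
                                         j.acceptor_annotated],
                            "n_samples": ev.n_samples,
                            "total_reads": ev.total_reads,
                            "max_event_ratio": ev.max_event_ratio,
                            "sample_set": sorted(ev.sample_set) if ev.sample_set is not None else None,
                        })),
                    )
            con.commit()
        finally:
            con.close()

    @classmethod
    def load(cls, path) -> "VaultDB":
        con = sqlite3.connect(str(path))
        try:
            meta = dict(con.execute("SELECT key, value FROM meta"))
            transcripts = {}
            for tx_id, payload in con.execute("SELECT * FROM transcripts"):
                d = json.loads(payload)
                transcripts[tx_id] = TranscriptModel(
                    transcript_id=tx_id, gene_id=d["gene_id"], chrom=d["chrom"],
                    strand=d["strand"], exons=[tuple(e) for e in d["exons"]],
                    cds_start=d["cds_start"], cds_end=d["cds_end"],
                )
            sites, annotated, events = {}, {}, {}
            for site_id, payload, ann in con.execute("SELECT * FROM sites"):
                sites[site_id] = SpliceSite(**json.loads(payload))
                annotated[site_id] = frozenset(json.loads(ann))
                events[site_id] = []
            for site_id, payload in con.execute("SELECT * FROM events"):
                d = json.loads(payload)
                jc, js, j1, j2, da, aa = d["junction"]
                events[site_id].append(
                    MisSplicingEvent(
                        site=sites[site_id], category=d["category"],
                        junction=Junction(jc, js, j1, j2, da, aa),
                        skipped_exons=d["skipped_exons"],
                        cryptic_pos=d["cryptic_pos"],
                        cryptic_offset=d["cryptic_offset"],
                        n_samples=d["n_samples"], total_reads=d["total_reads"],
                        max_event_ratio=d["max_event_ratio"],
                        sample_set=frozenset(d["sample_set"]) if d["sample_set"] is not None else None,
                    )
                )
            groups = json.loads(meta["sample_groups"])
            return cls(
                transcripts=transcripts, sites=sites, events=events,
                annotated_samples=annotated, sample_groups=groups,
                n_total_samples=int(meta["n_total_samples"]),
                config=VaultConfig(**json.loads(meta["config"])),
                provenance=json.loads(meta["provenance"]),
            )
        finally:
            con.close()

    def export_tsv(self, path, config: Optional[VaultConfig] = None) -> None:
        frames = [
            query_top_events(self, site_id, config=config or self.config).to_dataframe()
            for site_id in sorted(self.sites)
        ]
        frames = [f for f in frames if not f.empty]
        df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        df.to_csv(path, sep="\t", index=False)


def _sort_key(ev: MisSplicingEvent, n: int, reads: int) -> tuple:
    # ties: more reads first, then tighter event, then 5'-most coordinate
    tightness = (
        len(ev.skipped_exons) if ev.category == "exon_skipping" else abs(ev.cryptic_offset)
    )
    return (-n, -reads, tightness, ev.junction.intron_start, ev.junction.intron_end,
            ev.category)


def build_vault(
    junction_tables: Iterable[list[JunctionCounts]],
    transcripts: Iterable[TranscriptModel],
    config: Optional[VaultConfig] = None,
    sample_groups: Optional[dict[str, str]] = None,
    provenance: Optional[dict] = None,
) -> VaultDB:
    """Aggregate junction tables and build the full per-site event catalog.

    Every annotated site is stored, with its complete (unfiltered) event
    list and the per-sample support needed for group views and
    co-occurrence; Top-N* filtering is applied at query time.
    """
    config = config or VaultConfig()
    tx_map = {tx.transcript_id: tx for tx in transcripts}
    if not tx_map:
        raise ValueError("no transcripts supplied")
    index = build_splice_site_index(tx_map.values())
    agg = filter_and_aggregate(junction_tables, index, sample_groups=sample_groups)
    all_samples = set()
    for jc in agg:
        all_samples |= set(jc.per_sample or {})
    if not all_samples:
        raise ValueError("zero samples in junction inputs")
    by_key = {jc.junction.key: jc for jc in agg}
    annotated_keys = index.annotated_junctions
    unannotated = [jc for jc in agg if jc.junction.key not in annotated_keys]

    sites: dict[str, SpliceSite] = {}
    events: dict[str, list[MisSplicingEvent]] = {}
    annotated_samples: dict[str, frozenset] = {}
    for tx in tx_map.values():
        introns = tx.introns()
        for site in tx.splice_sites():
            sites[site.site_id] = site
            s, e = introns[site.intron_index - 1]
            ann = by_key.get((tx.chrom, tx.strand, s, e))
            annotated_samples[site.site_id] = (
                frozenset(ann.samples()) if ann is not None else frozenset()
            )
            events[site.site_id] = events_for_site(
                site, unannotated, tx, index=index, annotated_counts=ann
            )
    return VaultDB(
        transcripts=tx_map, sites=sites, events=events,
        annotated_samples=annotated_samples, sample_groups=sample_groups,
        n_total_samples=len(all_samples), config=config,
        provenance=provenance or {},
    )


def resolve_sites(db: VaultDB, locus) -> list[SpliceSite]:
    """Resolve a site_id, (chrom, pos, kind) tuple, or variant spec dict.

    Variant specs resolve to the nearest annotated site whose donor or
    acceptor motif region covers the variant position (donor: last 3
    exonic .. first 6 intronic bases; acceptor: last 20 intronic .. first
    2 exonic bases).
    """
    if isinstance(locus, SpliceSite):
        return [locus]
    if isinstance(locus, str):
        if locus not in db.sites:
            raise KeyError(f"unknown site_id {locus!r}")
        return [db.sites[locus]]
    if isinstance(locus, tuple) and len(locus) == 3:
        chrom, pos, kind = locus
        hits = [
            s for s in db.sites.values()
            if s.chrom == chrom and s.pos == pos and s.kind == kind
        ]
        if not hits:
            raise KeyError(f"no annotated {kind} at {chrom}:{pos}")
        return sorted(hits, key=lambda s: s.site_id)
    if isinstance(locus, dict):
        chrom, pos = locus["chrom"], int(locus["pos"])
        hits = []
        for s in db.sites.values():
            if s.chrom != chrom:
                continue
            exonic, intronic = DONOR_REGION if s.kind == "donor" else ACCEPTOR_REGION
            sign = 1 if s.strand == "+" else -1
            if s.kind == "donor":
                lo_t, hi_t = -(exonic - 1), intronic
            else:
                lo_t, hi_t = -intronic, exonic - 1
            delta = (pos - s.pos) * sign
            if lo_t <= delta <= hi_t:
                hits.append(s)
        if not hits:
            nearest = sorted(
                (s for s in db.sites.values() if s.chrom == chrom),
                key=lambda s: abs(s.pos - pos),
            )[:3]
            names = ", ".join(f"{s.site_id}@{s.pos}" for s in nearest)
            raise KeyError(
                f"variant {chrom}:{pos} is outside every splice-site motif region; "
                f"nearest annotated sites: {names}"
            )
        return sorted(hits, key=lambda s: (abs(s.pos - pos), s.site_id))
    raise TypeError(f"cannot resolve locus {locus!r}")


def _ranked_rows(
    db: VaultDB, site_id: str, config: VaultConfig, group: Optional[str]
) -> list[EventRow]:
    evs = db.events.get(site_id, [])
    counted = []
    for ev in evs:
        if group is None:
            n = ev.n_samples
        else:
            if db.sample_groups is None:
                raise ValueError("vault built without sample groups")
            if ev.sample_set is None:
                raise ValueError("per-sample data not retained; rebuild with per_sample counts")
            n = sum(1 for s in ev.sample_set if db.sample_groups.get(s) == group)
            if n == 0:
                continue
        counted.append((ev, n))
    counted.sort(key=lambda t: _sort_key(t[0], t[1], t[0].total_reads))
    filtered = [t for t in counted if config.passes_filter(t[0])]
    filtered_rank = {id(ev): i + 1 for i, (ev, _) in enumerate(filtered)}
    rows = []
    for i, (ev, n) in enumerate(counted, 1):
        fr = filtered_rank.get(id(ev))
        rows.append(
            EventRow(
                rank=i, event=ev, n_samples=n, total_reads=ev.total_reads,
                filtered_rank=fr, in_top_n_star=fr is not None and fr <= config.top_n,
            )
        )
    return rows


def query_top_events(
    db: VaultDB,
    locus,
    config: Optional[VaultConfig] = None,
    group: Optional[str] = None,
) -> RankedEventTable:
    """Ranked events for one site (both unfiltered and starred ranks).

    A locus resolving to several transcripts' sites returns the first in
    deterministic (distance, site_id) order; use :func:`resolve_sites`
    to enumerate all of them.
    """
    config = config or db.config
    site = resolve_sites(db, locus)[0]
    return RankedEventTable(
        site=site,
        annotated_n_samples=db.annotated_n_samples(site.site_id, group),
        rows=_ranked_rows(db, site.site_id, config, group),
    )


def group_concordance(
    db: VaultDB,
    groups: list[str],
    reference: Optional[str] = None,
    sites: Optional[Iterable[str]] = None,
    config: Optional[VaultConfig] = None,
) -> dict:
    """Per-rank agreement of each group's starred ranking with a reference.

    For each group and rank r (1..top_n), the fraction of sites whose
    rank-r starred event is identical to the reference's rank-r event,
    over sites where the reference has a rank-r event; plus the Spearman
    correlation of per-event sample counts (group vs reference).
    """
    config = config or db.config
    site_ids = sorted(sites) if sites is not None else sorted(db.sites)
    known = db.groups()
    for g in groups:
        if g not in known:
            raise KeyError(f"unknown sample group {g!r}; have {known}")

    def starred(site_id, group):
        rows = _ranked_rows(db, site_id, config, group)
        return {r.filtered_rank: r for r in rows if r.filtered_rank is not None}

    ref_tables = {sid: starred(sid, reference) for sid in site_ids}
    rank_rows = []
    spearman = {}
    for g in groups:
        ref_counts, grp_counts = [], []
        for r in range(1, config.top_n + 1):
            num = den = 0
            for sid in site_ids:
                ref_row = ref_tables[sid].get(r)
                if ref_row is None:
                    continue
                den += 1
                grp_row = starred(sid, g).get(r)
                if grp_row is not None and grp_row.event.identity == ref_row.event.identity:
                    num += 1
            rank_rows.append(
                {"group": g, "rank": r,
                 "concordance": num / den if den else float("nan"),
                 "n_sites": den}
            )
        for sid in site_ids:
            grp_rows = {row.event.identity: row.n_samples
                        for row in _ranked_rows(db, sid, config, g)
                        if row.filtered_rank is not None}
            for fr, ref_row in ref_tables[sid].items():
                ref_counts.append(ref_row.n_samples)
                grp_counts.append(grp_rows.get(ref_row.event.identity, 0))
        if len(ref_counts) >= 2:
            rho = stats.spearmanr(ref_counts, grp_counts).statistic
        else:
            rho = float("nan")
        spearman[g] = rho
    return {"rank_concordance": pd.DataFrame(rank_rows), "spearman": spearman}


def event_cooccurrence(
    db: VaultDB, site, event_a, event_b
) -> dict:
    """Sample-overlap (Jaccard) of two events at one site.

    ``event_a``/``event_b`` are event identity tuples (see
    ``MisSplicingEvent.identity``) or starred ranks (ints).
    """
    site = resolve_sites(db, site)[0]
    rows = _ranked_rows(db, site.site_id, db.config, None)

    def find(spec):
        if isinstance(spec, int):
            for r in rows:
                if r.filtered_rank == spec:
                    return r.event
            raise KeyError(f"no starred rank {spec} at {site.site_id}")
        for r in rows:
            if r.event.identity == tuple(spec):
                return r.event
        raise KeyError(f"no event {spec!r} at {site.site_id}")

    ev_a, ev_b = find(event_a), find(event_b)
    if ev_a.sample_set is None or ev_b.sample_set is None:
        raise ValueError(
            "per-sample data not retained at build time; rebuild with per_sample=True"
        )
    inter = ev_a.sample_set & ev_b.sample_set
    union = ev_a.sample_set | ev_b.sample_set
    return {
        "jaccard": len(inter) / len(union) if union else 0.0,
        "n_a": len(ev_a.sample_set),
        "n_b": len(ev_b.sample_set),
        "n_both": len(inter),
        "n_union": len(union),
    }
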