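"""Transcript annotation ingest and splice-site indexing.

Transcript models are the frame of reference for every mis-splicing event:
each internal exon boundary is a donor (3' end of the exon in transcript
direction) or an acceptor (5' end), and the introns between consecutive
exons define the annotated splice junctions that split reads are compared
against.

Coordinate conventions (used package-wide):

* all genomic coordinates are 1-based inclusive;
* a splice site's ``pos`` is the last EXONIC base adjacent to the intron
  (donor = transcript-direction 3' end of the exon, acceptor = 5' start);
* intron intervals are stored as (first intronic base, last intronic base);
* "upstream"/"downstream" are always in transcript direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import gffutils
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptModel",
    "SpliceSite",
    "SpliceSiteIndex",
    "AnnotationParseError",
    "load_transcripts",
    "write_gtf",
    "build_splice_site_index",
]


class AnnotationParseError(ValueError):
    """Raised for malformed annotation records; names the offending line."""


@dataclass(frozen=True)
class SpliceSite:
    """One annotated donor or acceptor of one transcript.

    ``pos`` is the last exonic base adjacent to the intron. ``exon_index``
    is the 1-based ordinal (in transcript direction) of the exon the site
    belongs to; ``intron_index`` the ordinal of the adjacent intron.
    """

    site_id: str
    transcript_id: str
    chrom: str
    strand: str
    kind: str  # "donor" | "acceptor"
    pos: int
    exon_index: int
    intron_index: int


@dataclass
class TranscriptModel:
    """Ordered exon structure of one transcript.

    ``exons`` are (start, end) 1-based inclusive genomic intervals ordered
    5'->3' in transcript direction: genomic starts strictly increase on the
    + strand and strictly decrease on the - strand.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.transcript_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: needs >=1 exon")
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.transcript_id}: exon start > end ({s}>{e})")
        by_start = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(by_start, by_start[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"{self.transcript_id}: overlapping exons {(s1, e1)} and {(s2, e2)}"
                )
        self.exons = sorted(self.exons, reverse=self.strand == "-")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_length(self, exon_index: int) -> int:
        s, e = self.exons[exon_index - 1]
        return e - s + 1

    def introns(self) -> list[tuple[int, int]]:
        """Intron intervals (first..last intronic base) in transcript order."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append((e1 + 1, s2 - 1))
            else:
                out.append((e2 + 1, s1 - 1))
        return out

    def donor_pos(self, exon_index: int) -> int:
        """Genomic position of the donor of exon ``exon_index`` (1-based ordinal)."""
        s, e = self.exons[exon_index - 1]
        return e if self.strand == "+" else s

    def acceptor_pos(self, exon_index: int) -> int:
        s, e = self.exons[exon_index - 1]
        return s if self.strand == "+" else e

    def splice_sites(self) -> list[SpliceSite]:
        """All donors (exons 1..n-1) and acceptors (exons 2..n)."""
        sites: list[SpliceSite] = []
        n = self.n_exons
        for i in range(1, n):
            sites.append(
                SpliceSite(
                    site_id=f"{self.transcript_id}:E{i}:donor",
                    transcript_id=self.transcript_id,
                    chrom=self.chrom,
                    strand=self.strand,
                    kind="donor",
                    pos=self.donor_pos(i),
                    exon_index=i,
                    intron_index=i,
                )
            )
        for i in range(2, n + 1):
            sites.append(
                SpliceSite(
                    site_id=f"{self.transcript_id}:E{i}:acceptor",
                    transcript_id=self.transcript_id,
                    chrom=self.chrom,
                    strand=self.strand,
                    kind="acceptor",
                    pos=self.acceptor_pos(i),
                    exon_index=i,
                    intron_index=i - 1,
                )
            )
        return sites

    def site(self, exon_index: int, kind: str) -> SpliceSite:
        for s in self.splice_sites():
            if s.exon_index == exon_index and s.kind == kind:
                return s
        raise KeyError(f"{self.transcript_id}: no {kind} at exon {exon_index}")


@dataclass
class SpliceSiteIndex:
    """Registry of annotated splice sites and junctions across transcripts."""

    by_position: dict[tuple[str, str, int, str], set[SpliceSite]] = field(
        default_factory=dict
    )
    annotated_junctions: set[tuple[str, str, int, int]] = field(default_factory=set)

    def add_transcript(self, tx: TranscriptModel) -> None:
        for site in tx.splice_sites():
            key = (site.chrom, site.strand, site.pos, site.kind)
            self.by_position.setdefault(key, set()).add(site)
        for start, end in tx.introns():
            self.annotated_junctions.add((tx.chrom, tx.strand, start, end))

    def is_annotated(self, chrom: str, strand: str, pos: int, kind: str) -> bool:
        return (chrom, strand, pos, kind) in self.by_position

    def sites_at(self, chrom: str, strand: str, pos: int, kind: str) -> set[SpliceSite]:
        return self.by_position.get((chrom, strand, pos, kind), set())

    def junction_is_annotated(
        self, chrom: str, strand: str, start: int, end: int
    ) -> bool:
        return (chrom, strand, start, end) in self.annotated_junctions

    def all_sites(self) -> Iterable[SpliceSite]:
        for sites in self.by_position.values():
            yield from sites


def _prevalidate_gtf(path: Path) -> None:
    """Cheap structural check so parse errors can name the offending line."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise AnnotationParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise AnnotationParseError(
                    f"{path}:{lineno}: non-integer coordinates {fields[3]!r}/{fields[4]!r}"
                ) from None
            if start > end or start < 1:
                raise AnnotationParseError(
                    f"{path}:{lineno}: invalid interval {start}-{end}"
                )
            if fields[6] not in {"+", "-", "."}:
                raise AnnotationParseError(
                    f"{path}:{lineno}: bad strand {fields[6]!r}"
                )


def _load_gtf(path: Path) -> list[TranscriptModel]:
    _prevalidate_gtf(path)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, dict] = {}
    cds_span: dict[str, tuple[int, int]] = {}
    for feat in db.all_features():
        if feat.featuretype not in {"exon", "CDS"}:
            continue
        tx_id = feat.attributes.get("transcript_id", [None])[0]
        if tx_id is None:
            raise AnnotationParseError(
                f"{path}: {feat.featuretype} record without transcript_id"
            )
        gene_id = feat.attributes.get("gene_id", [tx_id])[0]
        if feat.featuretype == "exon":
            rec = exons.setdefault(
                tx_id,
                {"gene_id": gene_id, "chrom": feat.seqid, "strand": feat.strand, "exons": []},
            )
            rec["exons"].append((feat.start, feat.end))
        else:
            lo, hi = cds_span.get(tx_id, (feat.start, feat.end))
            cds_span[tx_id] = (min(lo, feat.start), max(hi, feat.end))
    models = []
    for tx_id, rec in exons.items():
        cds = cds_span.get(tx_id)
        try:
            models.append(
                TranscriptModel(
                    transcript_id=tx_id,
                    gene_id=rec["gene_id"],
                    chrom=rec["chrom"],
                    strand=rec["strand"],
                    exons=rec["exons"],
                    cds_start=cds[0] if cds else None,
                    cds_end=cds[1] if cds else None,
                )
            )
        except ValueError as exc:
            logger.warning("rejected transcript %s: %s", tx_id, exc)
    return models


def _load_refseq_tsv(path: Path) -> list[TranscriptModel]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"transcript_id", "gene", "chrom", "strand", "exon_starts", "exon_ends"}
    missing = required - set(df.columns)
    if missing:
        raise AnnotationParseError(f"{path}: missing columns {sorted(missing)}")
    models = []
    for row_i, row in df.iterrows():
        starts = [int(x) for x in str(row.exon_starts).rstrip(",").split(",")]
        ends = [int(x) for x in str(row.exon_ends).rstrip(",").split(",")]
        if len(starts) != len(ends):
            raise AnnotationParseError(
                f"{path}: row {row_i + 2}: exon_starts/exon_ends length mismatch"
            )
        cds_start = int(row.cds_start) if "cds_start" in df.columns and pd.notna(row.get("cds_start")) else None
        cds_end = int(row.cds_end) if "cds_end" in df.columns and pd.notna(row.get("cds_end")) else None
        try:
            models.append(
                TranscriptModel(
                    transcript_id=row.transcript_id,
                    gene_id=row.gene,
                    chrom=row.chrom,
                    strand=row.strand,
                    exons=list(zip(starts, ends)),
                    cds_start=cds_start,
                    cds_end=cds_end,
                )
            )
        except ValueError as exc:
            logger.warning("rejected transcript %s: %s", row.transcript_id, exc)
    return models


def load_transcripts(annotation_path, dialect: str = "gtf") -> list[TranscriptModel]:
    """Load transcript models from GTF (Ensembl dialect) or RefSeq-style TSV.

    Exons are normalized to 1-based inclusive coordinates and sorted in
    transcript direction. Transcripts with overlapping exons are rejected
    with a logged diagnostic; the rest still load.
    """
    path = Path(annotation_path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "gtf":
        return _load_gtf(path)
    if dialect == "refseq_tsv":
        return _load_refseq_tsv(path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def write_gtf(transcripts: Iterable[TranscriptModel], path) -> None:
    """Write transcript models back out as Ensembl-dialect GTF."""
    with open(path, "w") as fh:
        for tx in sorted(transcripts, key=lambda t: t.transcript_id):
            attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
            for start, end in sorted(tx.exons):
                fh.write(
                    f"{tx.chrom}\tmissplice\texon\t{start}\t{end}\t.\t{tx.strand}\t.\t{attrs}\n"
                )
            if tx.cds_start is not None and tx.cds_end is not None:
                for start, end in sorted(tx.exons):
                    lo = max(start, tx.cds_start)
                    hi = min(end, tx.cds_end)
                    if lo <= hi:
                        fh.write(
                            f"{tx.chrom}\tmissplice\tCDS\t{lo}\t{hi}\t.\t{tx.strand}\t0\t{attrs}\n"
                        )


def build_splice_site_index(transcripts: Iterable[TranscriptModel]) -> SpliceSiteIndex:
    """Index every donor/acceptor and every annotated intron interval.

    For an n-exon transcript this contributes n-1 donors, n-1 acceptors and
    n-1 annotated junctions (deduplicated across transcripts sharing introns).
    """
    transcripts = list(transcripts)
    if not transcripts:
        raise ValueError("empty transcript set")
    index = SpliceSiteIndex()
    for tx in transcripts:
        index.add_transcript(tx)
    return index
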