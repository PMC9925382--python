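"""Classify unannotated junctions into mis-splicing events and annotate
reading-frame consequences.

An event is always anchored to one annotated splice site of one transcript:

* exon skipping — a split read joining the annotated donor of exon ``a`` to
  the annotated acceptor of exon ``b`` with ``b >= a+2`` evidences skipping
  of exons ``a+1..b-1``; the event is anchored to every donor and acceptor
  of every skipped exon (a variant at any of them can elicit it);
* cryptic donor — an unannotated donor spliced to the annotated partner
  acceptor across the site's intron (cryptic acceptor symmetric).
  Junctions with both ends unannotated are never events.

``cryptic_offset`` is the signed boundary-to-boundary distance from the
annotated site to the cryptic boundary in transcript direction: positive
into the intron, negative into the exon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Union

from Bio.Seq import Seq

from .annotation import SpliceSite, SpliceSiteIndex, TranscriptModel
from .junctions import Junction, JunctionCounts

logger = logging.getLogger(__name__)

__all__ = [
    "MisSplicingEvent",
    "IntronRetention",
    "FrameEffect",
    "classify_junction",
    "events_for_site",
    "frame_effect",
]

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class MisSplicingEvent:
    """One classified unannotated splicing event at one annotated site."""

    site: SpliceSite
    category: str  # exon_skipping | cryptic_donor | cryptic_acceptor
    junction: Junction
    skipped_exons: Optional[list[int]] = None
    cryptic_pos: Optional[int] = None
    cryptic_offset: Optional[int] = None
    n_samples: int = 0
    total_reads: int = 0
    max_event_ratio: Optional[float] = None
    sample_set: Optional[frozenset] = None

    @property
    def identity(self) -> tuple:
        """Dedup/matching key within a site catalog."""
        if self.category == "exon_skipping":
            return ("exon_skipping", tuple(self.skipped_exons))
        return (self.category, self.cryptic_pos)


@dataclass(frozen=True)
class IntronRetention:
    """Retention of one intron; enters frame analysis only (split reads
    cannot quantify it)."""

    intron_index: int


@dataclass
class FrameEffect:
    net_nt_change: int
    in_frame: bool
    ptc_status: str = "unknown"  # none | ptc | unknown
    ir_all_frames_ptc: Optional[bool] = None


def _strand_sign(strand: str) -> int:
    return 1 if strand == "+" else -1


def classify_junction(
    junction: Junction,
    site: SpliceSite,
    transcript: TranscriptModel,
    index: Optional[SpliceSiteIndex] = None,
) -> Optional[MisSplicingEvent]:
    """Attribute one junction to ``site`` as an event, or return None.

    Annotation status of junction ends prefers the junction's own flags
    (set against the global site index during aggregation), falling back
    to ``index`` or the transcript's own sites.
    """
    if junction.chrom != transcript.chrom or junction.strand != transcript.strand:
        return None
    n = transcript.n_exons
    introns = set(transcript.introns())
    if (junction.intron_start, junction.intron_end) in introns:
        return None

    donor_exon = {transcript.donor_pos(i): i for i in range(1, n)}
    acceptor_exon = {transcript.acceptor_pos(i): i for i in range(2, n + 1)}
    d_pos = junction.donor_exonic_pos
    a_pos = junction.acceptor_exonic_pos

    def _end_annotated(pos: int, kind: str, flag: Optional[bool], local: dict) -> bool:
        if flag is not None:
            return flag
        if index is not None:
            return index.is_annotated(transcript.chrom, transcript.strand, pos, kind)
        return pos in local

    donor_annot = _end_annotated(d_pos, "donor", junction.donor_annotated, donor_exon)
    acceptor_annot = _end_annotated(
        a_pos, "acceptor", junction.acceptor_annotated, acceptor_exon
    )

    a = donor_exon.get(d_pos)
    b = acceptor_exon.get(a_pos)

    # exon skipping: both ends annotated in THIS transcript, nonconsecutive
    if a is not None and b is not None and b >= a + 2:
        skipped = list(range(a + 1, b))
        if site.exon_index in skipped:
            return MisSplicingEvent(
                site=site, category="exon_skipping", junction=junction,
                skipped_exons=skipped,
            )
        return None

    sign = _strand_sign(transcript.strand)
    if site.kind == "donor":
        if site.exon_index + 1 > n:
            return None
        partner = transcript.acceptor_pos(site.exon_index + 1)
        if a_pos == partner and not donor_annot:
            offset = (d_pos - site.pos) * sign
            if offset == 0:
                return None
            return MisSplicingEvent(
                site=site, category="cryptic_donor", junction=junction,
                cryptic_pos=d_pos, cryptic_offset=offset,
            )
        return None
    else:  # acceptor site
        if site.exon_index - 1 < 1:
            return None
        partner = transcript.donor_pos(site.exon_index - 1)
        if d_pos == partner and not acceptor_annot:
            offset = (site.pos - a_pos) * sign
            if offset == 0:
                return None
            return MisSplicingEvent(
                site=site, category="cryptic_acceptor", junction=junction,
                cryptic_pos=a_pos, cryptic_offset=offset,
            )
        return None


def events_for_site(
    site: SpliceSite,
    junctions: Iterable[JunctionCounts],
    transcript: TranscriptModel,
    index: Optional[SpliceSiteIndex] = None,
    annotated_counts: Optional[JunctionCounts] = None,
) -> list[MisSplicingEvent]:
    """Classify every junction against ``site``, deduplicate, carry counts.

    ``annotated_counts`` (per-sample support for the site's own annotated
    junction) enables the per-sample max event ratio
    ``event / (event + annotated)``.
    """
    by_identity: dict[tuple, MisSplicingEvent] = {}
    for jc in junctions:
        ev = classify_junction(jc.junction, site, transcript, index=index)
        if ev is None:
            continue
        prior = by_identity.get(ev.identity)
        if prior is None:
            ev.n_samples = jc.n_samples
            ev.total_reads = jc.total_reads
            if jc.per_sample is not None:
                ev.sample_set = frozenset(jc.samples())
                if annotated_counts is not None and annotated_counts.per_sample:
                    ratios = [
                        c / (c + annotated_counts.per_sample.get(s, 0))
                        for s, c in jc.per_sample.items()
                        if c >= 1
                    ]
                    ev.max_event_ratio = max(ratios) if ratios else None
            by_identity[ev.identity] = ev
        else:
            prior.n_samples += jc.n_samples
            prior.total_reads += jc.total_reads
            if jc.per_sample is not None and prior.sample_set is not None:
                prior.sample_set = prior.sample_set | frozenset(jc.samples())
    return list(by_identity.values())


def _modified_blocks(
    event: Union[MisSplicingEvent, IntronRetention], tx: TranscriptModel
) -> list[tuple[int, int]]:
    """Exonic blocks of the mature transcript with the event applied,
    ordered in transcript direction."""
    blocks = list(tx.exons)
    if isinstance(event, IntronRetention):
        i = event.intron_index - 1
        s1, e1 = blocks[i]
        s2, e2 = blocks[i + 1]
        merged = (min(s1, s2), max(e1, e2))
        return blocks[:i] + [merged] + blocks[i + 2:]
    if event.category == "exon_skipping":
        drop = set(event.skipped_exons)
        return [b for i, b in enumerate(blocks, 1) if i not in drop]
    i = event.site.exon_index - 1
    s, e = blocks[i]
    if event.category == "cryptic_donor":
        # move the 3' (transcript) end of the exon to the cryptic boundary
        blocks[i] = (s, event.cryptic_pos) if tx.strand == "+" else (event.cryptic_pos, e)
    else:  # cryptic_acceptor: move the 5' start
        blocks[i] = (event.cryptic_pos, e) if tx.strand == "+" else (s, event.cryptic_pos)
    return blocks


def _spliced_seq(blocks, tx: TranscriptModel, genome) -> str:
    parts = []
    for s, e in blocks:
        seq = genome[tx.chrom][s - 1:e].seq.upper()
        if tx.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        parts.append(seq)
    return "".join(parts)


def _map_to_spliced(pos: int, blocks, strand: str) -> Optional[int]:
    offset = 0
    for s, e in blocks:
        if s <= pos <= e:
            return offset + (pos - s if strand == "+" else e - pos)
        offset += e - s + 1
    return None


def _net_change(event: Union[MisSplicingEvent, IntronRetention], tx: TranscriptModel) -> int:
    if isinstance(event, IntronRetention):
        s, e = tx.introns()[event.intron_index - 1]
        return e - s + 1
    if event.category == "exon_skipping":
        return -sum(tx.exon_length(i) for i in event.skipped_exons)
    return event.cryptic_offset


def frame_effect(
    event: Union[MisSplicingEvent, IntronRetention],
    transcript: TranscriptModel,
    genome=None,
) -> FrameEffect:
    """Net transcript length change, frame preservation and PTC status.

    Exon skipping removes the skipped exon lengths; a cryptic boundary
    shifts the transcript by its signed offset; intron retention adds the
    intron length. PTC scanning reconstructs the mature spliced sequence
    with the event applied and translates from the annotated start codon;
    it requires a genome FASTA and CDS annotation, otherwise ``unknown``.
    For intron retention with sequence, the retained intron is additionally
    scanned for stop codons in all three frames.
    """
    net = _net_change(event, transcript)
    fx = FrameEffect(net_nt_change=net, in_frame=net % 3 == 0)

    if isinstance(event, IntronRetention) and genome is not None:
        s, e = transcript.introns()[event.intron_index - 1]
        seq = genome[transcript.chrom][s - 1:e].seq.upper()
        if transcript.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        fx.ir_all_frames_ptc = all(
            any(seq[i:i + 3] in _STOPS for i in range(f, len(seq) - 2, 3))
            for f in range(3)
        )

    if genome is None or transcript.cds_start is None or transcript.cds_end is None:
        return fx

    blocks = _modified_blocks(event, transcript)
    if transcript.strand == "+":
        cds_first, cds_last = transcript.cds_start, transcript.cds_end
    else:
        cds_first, cds_last = transcript.cds_end, transcript.cds_start
    seq = _spliced_seq(blocks, transcript, genome)
    start_idx = _map_to_spliced(cds_first, blocks, transcript.strand)
    if start_idx is None:
        logger.warning("start codon not present in modified transcript; PTC unknown")
        return fx
    stop_idx = _map_to_spliced(cds_last, blocks, transcript.strand)
    annotated_stop_end = stop_idx if stop_idx is not None else len(seq) - 1
    first_stop_end = None
    for i in range(start_idx, len(seq) - 2, 3):
        if seq[i:i + 3] in _STOPS:
            first_stop_end = i + 2
            break
    if first_stop_end is None:
        fx.ptc_status = "none"
    elif first_stop_end < annotated_stop_end:
        fx.ptc_status = "ptc"
    else:
        fx.ptc_status = "none"
    return fx
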