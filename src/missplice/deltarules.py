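"""Interpretive rules turning SpliceAI delta-scores into structured
mis-splicing predictions.

SpliceAI emits, per genomic position, the change in predicted donor and
acceptor probability between reference and variant sequence (gain/loss
channels). Scores are collected across the maximum +/-5,000 nt window of
the variant; scores at or below a neutrality floor (0.001) are discarded
up front. Predictions are then called at a decision threshold (0.011 by
default, a budget-matched operating point — deliberately far below the
model's recommended general-purpose thresholds):

* single-exon skipping — donor AND acceptor loss at both sites flanking
  an exon;
* double-exon skipping — additionally, loss of the annotated site of the
  next intron out (upstream or downstream);
* intron retention — donor and acceptor loss at both sites flanking an
  intron;
* cryptic activation — a gain, in the channel matching the affected
  site's kind, at an unannotated position within the exon and intron
  flanking the variant's splice site.

Loss of the affected annotated site itself constitutes a prediction that
mis-splicing occurs. Everything else above the neutrality floor (losses at
unannotated sites, gains at annotated sites, gains outside the flanking
bounds or in the mismatched channel) is bucketed ``other``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .annotation import SpliceSite, TranscriptModel

__all__ = [
    "DeltaScoreRecord",
    "RuleConfig",
    "SpliceAIPrediction",
    "InterpretationResult",
    "load_delta_scores",
    "interpret_delta_scores",
]

CHANNELS = ("acceptor_gain", "acceptor_loss", "donor_gain", "donor_loss")


@dataclass(frozen=True)
class DeltaScoreRecord:
    variant_id: str
    chrom: str
    pos: int
    channel: str
    score: float
    ref_allele: Optional[str] = None
    alt_allele: Optional[str] = None
    anchored: bool = True

    def __post_init__(self):
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"delta score {self.score} outside [0, 1]")


@dataclass
class RuleConfig:
    neutral_threshold: float = 0.001
    decision_threshold: float = 0.011
    window_nt: int = 5000

    def __post_init__(self):
        if not 0 <= self.neutral_threshold <= self.decision_threshold <= 1:
            raise ValueError("need 0 <= neutral <= decision <= 1")


@dataclass
class SpliceAIPrediction:
    variant_id: str
    category: str  # single_exon_skipping | double_exon_skipping | intron_retention
    #             | cryptic_donor | cryptic_acceptor
    supporting_scores: list[DeltaScoreRecord]
    exons: Optional[list[int]] = None
    intron: Optional[int] = None
    cryptic_pos: Optional[int] = None

    @property
    def score_summary(self) -> float:
        return min(r.score for r in self.supporting_scores)

    @property
    def identity(self) -> tuple:
        if self.category in ("single_exon_skipping", "double_exon_skipping"):
            return ("exon_skipping", tuple(self.exons))
        if self.category == "intron_retention":
            return ("intron_retention", self.intron)
        return (self.category, self.cryptic_pos)


@dataclass
class InterpretationResult:
    variant_id: str
    predictions: list[SpliceAIPrediction]
    missplicing_predicted: bool
    status: str  # "predicted" | "no predicted impact"
    bucket_counts: dict = field(default_factory=dict)
    other_records: list[tuple[DeltaScoreRecord, str]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.predictions)


def _read_raw_tsv(path: Path) -> list[dict]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"variant_id", "chrom", "pos", "channel", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df.to_dict("records")


def _read_spliceai_vcf(path: Path) -> list[dict]:
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info.get("SpliceAI")
            if info is None:
                continue
            entries = info if isinstance(info, (tuple, list)) else [info]
            for entry in entries:
                f = str(entry).split("|")
                alt = f[0]
                ds = [float(x) for x in f[2:6]]   # AG, AL, DG, DL
                dp = [int(x) for x in f[6:10]]
                vid = f"{rec.chrom}:{rec.pos}:{rec.ref}:{alt}"
                for (channel, score, delta) in zip(
                    ("acceptor_gain", "acceptor_loss", "donor_gain", "donor_loss"),
                    ds, dp,
                ):
                    out.append({
                        "variant_id": vid, "chrom": rec.chrom,
                        "pos": rec.pos + delta, "channel": channel,
                        "score": score, "ref": rec.ref, "alt": alt,
                    })
    return out


def load_delta_scores(
    path,
    format: str = "raw_tsv",
    transcripts: Optional[Iterable[TranscriptModel]] = None,
    variant_positions: Optional[dict[str, int]] = None,
    config: Optional[RuleConfig] = None,
) -> tuple[list[DeltaScoreRecord], dict]:
    """Load delta-score records, dropping neutral and out-of-window scores.

    Returns ``(records, stats)`` where stats counts the neutral
    (score <= floor) and out-of-window drops. Records on a chromosome no
    loaded transcript touches are kept but flagged unanchored.
    """
    config = config or RuleConfig()
    path = Path(path)
    if format == "raw_tsv":
        raw = _read_raw_tsv(path)
    elif format == "spliceai_vcf":
        raw = _read_spliceai_vcf(path)
    else:
        raise ValueError(f"unknown delta-score format {format!r}")
    tx_chroms = {tx.chrom for tx in transcripts} if transcripts else None
    records, n_neutral, n_window = [], 0, 0
    for row in raw:
        score = float(row["score"])
        if score <= config.neutral_threshold:
            n_neutral += 1
            continue
        vid = str(row["variant_id"])
        pos = int(row["pos"])
        if variant_positions is not None and vid in variant_positions:
            if abs(pos - variant_positions[vid]) > config.window_nt:
                n_window += 1
                continue
        anchored = tx_chroms is None or str(row["chrom"]) in tx_chroms
        records.append(
            DeltaScoreRecord(
                variant_id=vid, chrom=str(row["chrom"]), pos=pos,
                channel=str(row["channel"]), score=score,
                ref_allele=row.get("ref"), alt_allele=row.get("alt"),
                anchored=anchored,
            )
        )
    return records, {"n_neutral": n_neutral, "n_out_of_window": n_window}


def _flanking_bounds(site: SpliceSite, tx: TranscriptModel) -> list[tuple[int, int]]:
    """Genomic intervals of the exon and intron flanking the variant site."""
    exon = tx.exons[site.exon_index - 1]
    intron = tx.introns()[site.intron_index - 1]
    return [tuple(sorted(exon)), tuple(sorted(intron))]


def interpret_delta_scores(
    scores: Iterable[DeltaScoreRecord],
    site: SpliceSite,
    transcript: TranscriptModel,
    config: Optional[RuleConfig] = None,
) -> InterpretationResult:
    """Apply the interpretive rules for one variant anchored to ``site``.

    Every above-neutral score lands in exactly one bucket —
    ``affected_site_loss``, ``supporting`` (cited by >=1 emitted
    prediction) or ``other`` — so bucket counts sum to the input count.
    """
    config = config or RuleConfig()
    scores = [r for r in scores if r.score > config.neutral_threshold]
    variant_id = scores[0].variant_id if scores else "?"
    n = transcript.n_exons
    donor_pos = {transcript.donor_pos(i): i for i in range(1, n)}
    acceptor_pos = {transcript.acceptor_pos(i): i for i in range(2, n + 1)}

    def site_kind_at(rec: DeltaScoreRecord) -> Optional[int]:
        table = donor_pos if rec.channel.startswith("donor") else acceptor_pos
        return table.get(rec.pos)

    # the affected site's own loss gates everything
    loss_channel = f"{site.kind}_loss"
    affected_losses = [
        r for r in scores if r.channel == loss_channel and r.pos == site.pos
    ]
    if not affected_losses:
        return InterpretationResult(
            variant_id=variant_id, predictions=[], missplicing_predicted=False,
            status="no predicted impact",
            bucket_counts={"affected_site_loss": 0, "supporting": 0,
                           "other": len(scores)},
            other_records=[(r, "not interpreted: no affected-site loss") for r in scores],
        )

    called = [r for r in scores if r.score >= config.decision_threshold]
    # annotated-site losses above decision threshold, by kind and exon index
    donor_loss: dict[int, DeltaScoreRecord] = {}
    acceptor_loss: dict[int, DeltaScoreRecord] = {}
    for r in called:
        idx = site_kind_at(r)
        if idx is None:
            continue
        if r.channel == "donor_loss":
            donor_loss[idx] = max(r, donor_loss.get(idx), key=lambda x: -1 if x is None else x.score)
        elif r.channel == "acceptor_loss":
            acceptor_loss[idx] = max(r, acceptor_loss.get(idx), key=lambda x: -1 if x is None else x.score)

    predictions: list[SpliceAIPrediction] = []
    # single-exon skipping: both flanking sites of an internal exon lost
    singles = []
    for k in range(2, n):
        if k in donor_loss and k in acceptor_loss:
            pred = SpliceAIPrediction(
                variant_id=variant_id, category="single_exon_skipping",
                supporting_scores=[acceptor_loss[k], donor_loss[k]], exons=[k],
            )
            predictions.append(pred)
            singles.append(k)
    # double-exon skipping: the next intron out is also lost; the same
    # pair can be reached from either constituent single skip, so dedup
    doubles: dict[tuple, SpliceAIPrediction] = {}
    for k in singles:
        if k - 1 >= 2 and (k - 1) in acceptor_loss:
            doubles.setdefault(
                (k - 1, k),
                SpliceAIPrediction(
                    variant_id=variant_id, category="double_exon_skipping",
                    supporting_scores=[acceptor_loss[k - 1], acceptor_loss[k], donor_loss[k]],
                    exons=[k - 1, k],
                ),
            )
        if k + 1 <= n - 1 and (k + 1) in donor_loss:
            doubles.setdefault(
                (k, k + 1),
                SpliceAIPrediction(
                    variant_id=variant_id, category="double_exon_skipping",
                    supporting_scores=[acceptor_loss[k], donor_loss[k], donor_loss[k + 1]],
                    exons=[k, k + 1],
                ),
            )
    predictions.extend(doubles[key] for key in sorted(doubles))
    # intron retention: both sites flanking an intron lost
    for j in range(1, n):
        if j in donor_loss and (j + 1) in acceptor_loss:
            predictions.append(
                SpliceAIPrediction(
                    variant_id=variant_id, category="intron_retention",
                    supporting_scores=[donor_loss[j], acceptor_loss[j + 1]], intron=j,
                )
            )
    # cryptic activation: matching-channel gains at unannotated positions
    # within the exon/intron flanking the variant site
    bounds = _flanking_bounds(site, transcript)
    gain_channel = f"{site.kind}_gain"
    seen_cryptic = set()
    for r in called:
        if r.channel != gain_channel:
            continue
        if site_kind_at(r) is not None:
            continue  # gain at an annotated site: uninterpretable
        if not any(lo <= r.pos <= hi for lo, hi in bounds):
            continue
        key = (r.pos, r.channel)
        if key in seen_cryptic:
            continue
        seen_cryptic.add(key)
        predictions.append(
            SpliceAIPrediction(
                variant_id=variant_id,
                category="cryptic_donor" if site.kind == "donor" else "cryptic_acceptor",
                supporting_scores=[r], cryptic_pos=r.pos,
            )
        )

    supporting_ids = {id(r) for p in predictions for r in p.supporting_scores}
    affected_ids = {id(r) for r in affected_losses}
    other = []
    for r in scores:
        if id(r) in affected_ids or id(r) in supporting_ids:
            continue
        if r.channel.endswith("_loss"):
            reason = ("annotated-site loss below decision threshold or not in a rule"
                      if site_kind_at(r) is not None else "loss at unannotated site")
        else:
            reason = ("gain at annotated site" if site_kind_at(r) is not None
                      else "gain outside flanking bounds or mismatched channel")
        other.append((r, reason))
    n_supporting = len(supporting_ids - affected_ids)
    return InterpretationResult(
        variant_id=variant_id, predictions=predictions,
        missplicing_predicted=any(
            r.score >= config.decision_threshold for r in affected_losses
        ),
        status="predicted",
        bucket_counts={
            "affected_site_loss": len(affected_ids),
            "supporting": n_supporting,
            "other": len(other),
        },
        other_records=other,
    )
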