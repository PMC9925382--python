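"""Splice-junction count ingestion and annotation-anchored aggregation.

Dialects supported:

* ``star_sj`` — STAR ``SJ.out.tab`` (9 columns, one sample per file);
  only uniquely-mapped read counts are used unless asked otherwise.
* ``snaptron_tsv`` — recount3/snaptron-style TSV with an embedded
  multi-sample count list (``sample:count,...``).
* ``bed6`` — half-open BED intervals with the score column as read count.

Junction intervals are the intron: first..last intronic base, 1-based.
Gzip input is transparently supported.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .annotation import SpliceSiteIndex

logger = logging.getLogger(__name__)

__all__ = ["Junction", "JunctionCounts", "read_junction_table", "filter_and_aggregate"]

_STAR_STRAND = {"0": ".", "1": "+", "2": "-"}


@dataclass(frozen=True)
class Junction:
    """One strand-aware intron interval (1-based, first..last intronic base)."""

    chrom: str
    strand: str
    intron_start: int
    intron_end: int
    donor_annotated: Optional[bool] = None
    acceptor_annotated: Optional[bool] = None

    def __post_init__(self):
        if self.intron_start > self.intron_end:
            raise ValueError(f"intron_start > intron_end ({self.intron_start}>{self.intron_end})")

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.chrom, self.strand, self.intron_start, self.intron_end)

    @property
    def donor_exonic_pos(self) -> int:
        """Last exonic base on the donor side of this intron."""
        return self.intron_start - 1 if self.strand == "+" else self.intron_end + 1

    @property
    def acceptor_exonic_pos(self) -> int:
        """First exonic base on the acceptor side of this intron."""
        return self.intron_end + 1 if self.strand == "+" else self.intron_start - 1


@dataclass
class JunctionCounts:
    """Per-sample split-read support for one junction."""

    junction: Junction
    per_sample: Optional[dict[str, int]] = None
    sample_groups: Optional[dict[str, str]] = None
    _n_samples: Optional[int] = None
    _total_reads: Optional[int] = None

    @property
    def n_samples(self) -> int:
        if self.per_sample is not None:
            return sum(1 for c in self.per_sample.values() if c >= 1)
        return self._n_samples or 0

    @property
    def total_reads(self) -> int:
        if self.per_sample is not None:
            return sum(self.per_sample.values())
        return self._total_reads or 0

    def n_samples_in_group(self, group: str) -> int:
        if self.per_sample is None or self.sample_groups is None:
            raise ValueError("per-sample data and groups required for group tallies")
        return sum(
            1
            for s, c in self.per_sample.items()
            if c >= 1 and self.sample_groups.get(s) == group
        )

    def samples(self) -> set[str]:
        if self.per_sample is None:
            raise ValueError("per-sample data not retained")
        return {s for s, c in self.per_sample.items() if c >= 1}


def _open_text(path: Path):
    return gzip.open(path, "rt") if str(path).endswith(".gz") else open(path)


def _parse_star_sj(path: Path, sample_id: str, include_multimapped: bool) -> list[JunctionCounts]:
    if sample_id is None:
        raise ValueError("star_sj dialect requires a sample_id")
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = line.split()
            if len(f) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            strand = _STAR_STRAND.get(f[3])
            if strand is None:
                raise ValueError(f"{path}:{lineno}: bad strand code {f[3]!r}")
            reads = int(f[6]) + (int(f[7]) if include_multimapped else 0)
            if reads < 0:
                raise ValueError(f"{path}:{lineno}: negative read count")
            if reads == 0:
                continue
            out.append(
                JunctionCounts(
                    Junction(chrom, strand, start, end), per_sample={sample_id: reads}
                )
            )
    return out


def _parse_snaptron(path: Path) -> list[JunctionCounts]:
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: expected >=6 columns")
            _jid, chrom, start, end, strand, samples = f[:6]
            per_sample = {}
            for item in samples.split(","):
                if not item:
                    continue
                sid, count = item.rsplit(":", 1)
                count = int(count)
                if count < 0:
                    raise ValueError(f"{path}:{lineno}: negative count for {sid}")
                per_sample[sid] = count
            out.append(
                JunctionCounts(
                    Junction(chrom, strand, int(start), int(end)), per_sample=per_sample
                )
            )
    return out


def _parse_bed6(path: Path, sample_id: str) -> list[JunctionCounts]:
    if sample_id is None:
        raise ValueError("bed6 dialect requires a sample_id")
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split()
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns")
            chrom, start, end, _name, score, strand = f[:6]
            reads = int(score)
            if reads < 0:
                raise ValueError(f"{path}:{lineno}: negative read count")
            # BED is 0-based half-open: first intronic base = start+1, last = end
            out.append(
                JunctionCounts(
                    Junction(chrom, strand, int(start) + 1, int(end)),
                    per_sample={sample_id: reads},
                )
            )
    return out


def read_junction_table(
    path,
    dialect: str,
    sample_id: Optional[str] = None,
    include_multimapped: bool = False,
) -> list[JunctionCounts]:
    """Read one junction count table, normalizing coordinates to 1-based intron bases."""
    path = Path(path)
    if dialect == "star_sj":
        return _parse_star_sj(path, sample_id, include_multimapped)
    if dialect == "snaptron_tsv":
        return _parse_snaptron(path)
    if dialect == "bed6":
        return _parse_bed6(path, sample_id)
    raise ValueError(f"unknown junction dialect {dialect!r}")


def _annotation_flags(
    chrom: str, strand: str, start: int, end: int, index: SpliceSiteIndex
) -> tuple[bool, bool]:
    j = Junction(chrom, strand, start, end)
    donor_ok = index.is_annotated(chrom, strand, j.donor_exonic_pos, "donor")
    acceptor_ok = index.is_annotated(chrom, strand, j.acceptor_exonic_pos, "acceptor")
    return donor_ok, acceptor_ok


def _resolve_unknown_strand(
    chrom: str, start: int, end: int, index: SpliceSiteIndex
) -> Optional[str]:
    """Assign a strand to an undirected junction by annotated-end matching."""
    hits = []
    for strand in ("+", "-"):
        d, a = _annotation_flags(chrom, strand, start, end, index)
        if d or a:
            hits.append(strand)
    if len(hits) == 1:
        return hits[0]
    return None


def filter_and_aggregate(
    tables: Iterable[list[JunctionCounts]],
    index: SpliceSiteIndex,
    sample_groups: Optional[dict[str, str]] = None,
) -> list[JunctionCounts]:
    """Merge per-sample tables and keep junctions anchored to annotation.

    Junctions with neither end matching an annotated splice site are
    removed; survivors carry donor/acceptor annotation flags. Single-read,
    single-sample junctions are deliberately retained: most genuine
    stochastic mis-splicing support is a lone split read. Merging is
    associative and order-independent.
    """
    merged: dict[tuple, dict[str, int]] = {}
    for table in tables:
        for jc in table:
            j = jc.junction
            strand = j.strand
            if strand == ".":
                strand = _resolve_unknown_strand(j.chrom, j.intron_start, j.intron_end, index)
                if strand is None:
                    logger.info(
                        "dropping strand-unresolvable junction %s:%d-%d",
                        j.chrom, j.intron_start, j.intron_end,
                    )
                    continue
            key = (j.chrom, strand, j.intron_start, j.intron_end)
            bucket = merged.setdefault(key, {})
            if jc.per_sample is None:
                raise ValueError("aggregation requires per-sample counts")
            for sid, count in jc.per_sample.items():
                bucket[sid] = bucket.get(sid, 0) + count
    out = []
    for (chrom, strand, start, end), per_sample in sorted(merged.items()):
        donor_ok, acceptor_ok = _annotation_flags(chrom, strand, start, end, index)
        if not donor_ok and not acceptor_ok:
            continue
        out.append(
            JunctionCounts(
                Junction(chrom, strand, start, end, donor_ok, acceptor_ok),
                per_sample=dict(sorted(per_sample.items())),
                sample_groups=sample_groups,
            )
        )
    return out
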