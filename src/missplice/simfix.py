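"""Synthetic, truth-annotated fixtures for every other module.

The generator emits a small genome with multi-exon genes (canonical GT-AG
intron boundaries, a clean ORF), per-sample splice-junction tables with
planted mis-splicing events, raw delta-score files realizing configured
rule patterns, and variant plus observed-event tables — together with a
serialized truth record sufficient to recompute every expected output.

The statistical regime mirrors real compendium data: event presence is
drawn independently per sample at a configured frequency, and read counts
per present sample follow a geometric law with most of its mass at a
single read (by default P(count = 1) = 0.78, the single-read fraction
typical of true stochastic mis-splicing support). Planted event pairs can
be given an explicit sample-overlap (Jaccard) target to emulate the
mutual exclusivity of competing events at one site.

Identical seed + config reproduce byte-identical fixtures.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .annotation import TranscriptModel, write_gtf

__all__ = [
    "PlantedEvent",
    "PlantedVariant",
    "FixtureConfig",
    "Fixture",
    "default_config",
    "generate_fixture",
]

_BASES = np.array(list("ACGT"))


@dataclass
class PlantedEvent:
    """One natural mis-splicing event to seed into the sample tables."""

    gene: int
    exon_index: int
    kind: str  # anchor site kind: donor | acceptor
    category: str  # exon_skipping | cryptic_donor | cryptic_acceptor
    frequency: float
    skipped_exons: Optional[tuple[int, ...]] = None
    cryptic_offset: Optional[int] = None
    group_frequencies: Optional[dict[str, float]] = None
    observed: bool = False

    def validate(self, n_exons: int) -> None:
        if not 0 <= self.frequency <= 1:
            raise ValueError(f"event frequency {self.frequency} outside [0, 1]")
        if self.category == "exon_skipping":
            if not self.skipped_exons:
                raise ValueError("exon_skipping event needs skipped_exons")
            lo, hi = min(self.skipped_exons), max(self.skipped_exons)
            if lo < 2 or hi > n_exons - 1:
                raise ValueError(f"skipped exons {self.skipped_exons} not internal")
            if sorted(self.skipped_exons) != list(range(lo, hi + 1)):
                raise ValueError("skipped exons must be consecutive")
            if self.exon_index not in self.skipped_exons:
                raise ValueError("anchor exon must be among the skipped exons")
        else:
            if not self.cryptic_offset:
                raise ValueError("cryptic event needs a nonzero cryptic_offset")
            if self.exon_index < 1 or self.exon_index > n_exons:
                raise ValueError(f"exon {self.exon_index} outside transcript")


@dataclass
class PlantedVariant:
    """A splice-site variant with a delta-score pattern and observed truth."""

    gene: int
    exon_index: int
    kind: str = "donor"
    # intronic offset of the planted cryptic gain; defaults to the same
    # boundary as the default planted natural cryptic, emulating a variant
    # that activates the naturally occurring event
    cryptic_gain_offset: int = 13
    include_intron_retention: bool = False
    include_double_skip: bool = False
    observed_ir_intron: Optional[int] = None


@dataclass
class FixtureConfig:
    n_genes: int = 3
    exons_per_gene: int = 8
    exon_length: tuple[int, int] = (75, 150)
    intron_length: tuple[int, int] = (120, 400)
    n_samples: int = 100
    groups: Optional[dict[str, float]] = None
    annotated_frequency: float = 0.9
    annotated_read_p: float = 0.1
    single_read_prob: float = 0.78
    planted_events: list[PlantedEvent] = field(default_factory=list)
    cooccurrence: list[tuple[int, int, float]] = field(default_factory=list)
    variants: list[PlantedVariant] = field(default_factory=list)
    n_noise_junctions: int = 3
    noise_frequency: float = 0.05
    junction_dialect: str = "snaptron_tsv"
    ir_stop_introns: list[tuple[int, int]] = field(default_factory=list)


def default_config(n_samples: int = 100, n_genes: int = 3) -> FixtureConfig:
    """The standard study-like fixture: per gene, a donor site of exon 4
    carrying five planted events at well-separated sample frequencies
    (0.40, 0.12, 0.05, 0.02, 0.01), a splice-site variant with the first
    two events experimentally 'observed', and a delta-score pattern
    realizing one exon-skipping and one cryptic prediction."""
    events, variants, pairs = [], [], []
    for g in range(n_genes):
        base = len(events)
        events += [
            PlantedEvent(g, 4, "donor", "cryptic_donor", 0.40,
                         cryptic_offset=13, observed=True),
            PlantedEvent(g, 4, "donor", "exon_skipping", 0.12,
                         skipped_exons=(4,), observed=True),
            PlantedEvent(g, 4, "donor", "cryptic_donor", 0.05, cryptic_offset=-52),
            PlantedEvent(g, 4, "donor", "exon_skipping", 0.02, skipped_exons=(4, 5)),
            PlantedEvent(g, 4, "donor", "cryptic_donor", 0.01, cryptic_offset=87),
        ]
        pairs.append((base, base + 1, 0.05))
        variants.append(PlantedVariant(gene=g, exon_index=4, kind="donor"))
    cfg = FixtureConfig(n_genes=n_genes, n_samples=n_samples,
                        planted_events=events, cooccurrence=pairs,
                        variants=variants,
                        ir_stop_introns=[(0, 4)])
    return cfg


@dataclass
class Fixture:
    """Paths plus the truth record of one generated fixture."""

    outdir: Path
    config: FixtureConfig
    truth: dict
    transcripts: list[TranscriptModel]
    paths: dict


def _event_junction(ev: PlantedEvent, tx: TranscriptModel) -> tuple[int, int]:
    """Intron interval (first..last intronic base) evidencing the event."""
    sign = 1 if tx.strand == "+" else -1
    if ev.category == "exon_skipping":
        a, b = min(ev.skipped_exons) - 1, max(ev.skipped_exons) + 1
        d, acc = tx.donor_pos(a), tx.acceptor_pos(b)
    elif ev.category == "cryptic_donor":
        site_pos = tx.donor_pos(ev.exon_index)
        d = site_pos + ev.cryptic_offset * sign
        acc = tx.acceptor_pos(ev.exon_index + 1)
    else:  # cryptic_acceptor
        site_pos = tx.acceptor_pos(ev.exon_index)
        acc = site_pos - ev.cryptic_offset * sign
        d = tx.donor_pos(ev.exon_index - 1)
    if tx.strand == "+":
        return d + 1, acc - 1
    return acc + 1, d - 1


def _build_geometry(cfg: FixtureConfig, rng: np.random.Generator) -> list[TranscriptModel]:
    # minimum intron/exon lengths imposed by planted cryptic offsets
    min_intron: dict[tuple[int, int], int] = {}
    min_exon: dict[tuple[int, int], int] = {}
    for ev in cfg.planted_events:
        if ev.category == "exon_skipping":
            continue
        intron_idx = ev.exon_index if ev.category == "cryptic_donor" else ev.exon_index - 1
        if ev.cryptic_offset > 0:
            key = (ev.gene, intron_idx)
            min_intron[key] = max(min_intron.get(key, 0), ev.cryptic_offset + 30)
        else:
            key = (ev.gene, ev.exon_index)
            min_exon[key] = max(min_exon.get(key, 0), -ev.cryptic_offset + 10)
    for v in cfg.variants:
        key = (v.gene, v.exon_index)
        min_intron[key] = max(min_intron.get(key, 0), v.cryptic_gain_offset + 30)

    transcripts = []
    cursor = 1001
    for g in range(cfg.n_genes):
        strand = "+" if g % 2 == 0 else "-"
        n = cfg.exons_per_gene
        exon_lens = rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1, size=n)
        intron_lens = rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1, size=n - 1)
        for i in range(n):
            exon_lens[i] = max(exon_lens[i], min_exon.get((g, i + 1), 0))
        for i in range(n - 1):
            intron_lens[i] = max(intron_lens[i], min_intron.get((g, i + 1), 0))
        # genomic left-to-right layout; exon/intron ordinals follow transcript
        # direction, so reverse the length arrays for minus-strand genes
        e_lens = exon_lens if strand == "+" else exon_lens[::-1]
        i_lens = intron_lens if strand == "+" else intron_lens[::-1]
        exons_genomic = []
        pos = cursor
        for i in range(n):
            exons_genomic.append((pos, pos + int(e_lens[i]) - 1))
            pos += int(e_lens[i])
            if i < n - 1:
                pos += int(i_lens[i])
        cursor = pos + 2000
        tx = TranscriptModel(
            transcript_id=f"TX{g + 1}", gene_id=f"GENE{g + 1}", chrom="chr1",
            strand=strand, exons=exons_genomic,
        )
        transcripts.append(tx)
    return transcripts


def _compose_sequence(
    cfg: FixtureConfig, transcripts: list[TranscriptModel], rng: np.random.Generator
) -> str:
    length = max(e for tx in transcripts for _, e in tx.exons) + 2000
    seq = rng.choice(_BASES, size=length)  # 1-based positions -> index pos-1

    def put(pos: int, bases: str):
        seq[pos - 1:pos - 1 + len(bases)] = list(bases)

    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for tx in transcripts:
        for s, e in tx.introns():
            if tx.strand == "+":
                put(s, "GT")
                put(e - 1, "AG")
            else:
                put(e - 1, "AC")  # revcomp GT
                put(s, "CT")      # revcomp AG
    # CDS: starts at the 5' end of exon 2, stops inside the second-last exon
    for tx in transcripts:
        _install_orf(tx, seq, comp)
    for g, intron_idx in cfg.ir_stop_introns:
        tx = transcripts[g]
        s, e = tx.introns()[intron_idx - 1]
        mid = (s + e) // 2
        stops = "TAAATAAATAA"  # stop codons land in all three frames
        if tx.strand == "+":
            put(mid, stops)
        else:
            put(mid, "".join(comp[b] for b in reversed(stops)))
    return "".join(seq)


def _install_orf(tx: TranscriptModel, seq: np.ndarray, comp: dict) -> None:
    """Plant ATG...TAA with a stop-free annotated reading frame."""
    blocks = tx.exons
    # transcript-direction coordinate walk over exonic bases
    coords = []
    for s, e in blocks:
        rng_iter = range(s, e + 1) if tx.strand == "+" else range(e, s - 1, -1)
        coords.extend(rng_iter)
    exon_starts_t = np.cumsum([0] + [e - s + 1 for s, e in blocks])
    start_t = int(exon_starts_t[1])            # first base of exon 2
    last_allowed = int(exon_starts_t[-2]) - 1  # last base of second-last exon
    n_codons = (last_allowed - start_t + 1) // 3
    stop_t = start_t + n_codons * 3 - 3        # first base of the stop codon

    def base_at(t: int) -> str:
        g = coords[t]
        b = seq[g - 1]
        return b if tx.strand == "+" else comp[b]

    def set_base(t: int, b: str) -> None:
        g = coords[t]
        seq[g - 1] = b if tx.strand == "+" else comp[b]

    for t, b in zip(range(start_t, start_t + 3), "ATG"):
        set_base(t, b)
    for c in range(start_t + 3, stop_t, 3):
        codon = base_at(c) + base_at(c + 1) + base_at(c + 2)
        if codon in {"TAA", "TAG", "TGA"}:
            set_base(c + 2, "C")
    for t, b in zip(range(stop_t, stop_t + 3), "TAA"):
        set_base(t, b)
    g_start, g_stop = coords[start_t], coords[stop_t + 2]
    tx.cds_start = min(g_start, g_stop)
    tx.cds_end = max(g_start, g_stop)


def _assign_groups(cfg: FixtureConfig, samples: list[str]) -> Optional[dict[str, str]]:
    if cfg.groups is None:
        return None
    names = sorted(cfg.groups)
    fractions = np.array([cfg.groups[g] for g in names], dtype=float)
    fractions = fractions / fractions.sum()
    bounds = np.floor(np.cumsum(fractions) * len(samples)).astype(int)
    out, lo = {}, 0
    for name, hi in zip(names, bounds):
        for s in samples[lo:hi]:
            out[s] = name
        lo = hi
    for s in samples[lo:]:
        out[s] = names[-1]
    return out


def _draw_memberships(
    cfg: FixtureConfig,
    samples: list[str],
    groups: Optional[dict[str, str]],
    rng: np.random.Generator,
) -> list[set[str]]:
    """Per-event sample sets; co-occurrence pairs are built jointly so the
    realized Jaccard overlap matches the configured target."""
    n = len(samples)
    paired = {i for pair in cfg.cooccurrence for i in pair[:2]}
    memberships: list[Optional[set]] = [None] * len(cfg.planted_events)
    for idx, ev in enumerate(cfg.planted_events):
        if idx in paired:
            continue
        if ev.group_frequencies is not None and groups is not None:
            chosen = set()
            for s in samples:
                f = ev.group_frequencies.get(groups[s], ev.frequency)
                if rng.random() < f:
                    chosen.add(s)
            memberships[idx] = chosen
        else:
            mask = rng.random(n) < ev.frequency
            memberships[idx] = {s for s, m in zip(samples, mask) if m}
    for i, j, jac in cfg.cooccurrence:
        fa = cfg.planted_events[i].frequency
        fb = cfg.planted_events[j].frequency
        union = min(n, int(round(n * (fa + fb) / (1 + jac))))
        both = int(round(jac * union))
        na, nb = int(round(n * fa)), int(round(n * fb))
        both = min(both, na, nb)
        pool = list(samples)
        picked = rng.choice(pool, size=min(union, n), replace=False)
        shared = set(picked[:both])
        a_only = set(picked[both:both + (na - both)])
        b_only = set(picked[both + (na - both):both + (na - both) + (nb - both)])
        memberships[i] = shared | a_only
        memberships[j] = shared | b_only
    return memberships


def generate_fixture(config: FixtureConfig, outdir, seed: int) -> Fixture:
    """Emit a complete fixture directory and its truth record."""
    cfg = config
    for ev in cfg.planted_events:
        ev.validate(cfg.exons_per_gene)
        if ev.gene >= cfg.n_genes:
            raise ValueError(f"event references missing gene {ev.gene}")
    for v in cfg.variants:
        if v.gene >= cfg.n_genes:
            raise ValueError(f"variant references missing gene {v.gene}")
        if v.include_double_skip and v.include_intron_retention:
            raise ValueError(
                "a planted variant realizes either the double-skip or the "
                "intron-retention pattern, not both (their loss scores interact)"
            )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    transcripts = _build_geometry(cfg, rng)
    sequence = _compose_sequence(cfg, transcripts, rng)

    gtf_path = outdir / "annotation.gtf"
    write_gtf(transcripts, gtf_path)
    fasta_path = outdir / "genome.fa"
    with open(fasta_path, "w") as fh:
        fh.write(">chr1\n")
        for i in range(0, len(sequence), 80):
            fh.write(sequence[i:i + 80] + "\n")

    samples = [f"S{i + 1:05d}" for i in range(cfg.n_samples)]
    groups = _assign_groups(cfg, samples)
    memberships = _draw_memberships(cfg, samples, groups, rng)

    # per-sample read counts, keyed by junction interval
    counts: dict[tuple[int, int], dict[str, int]] = {}
    annotated_members: dict[tuple[int, int], set] = {}
    for tx in transcripts:
        for s, e in tx.introns():
            mask = rng.random(cfg.n_samples) < cfg.annotated_frequency
            present = [smp for smp, m in zip(samples, mask) if m]
            reads = rng.geometric(cfg.annotated_read_p, size=len(present))
            counts[(s, e)] = dict(zip(present, map(int, reads)))
            annotated_members[(s, e)] = set(present)
    event_junctions = []
    for ev, members in zip(cfg.planted_events, memberships):
        j = _event_junction(ev, transcripts[ev.gene])
        event_junctions.append(j)
        ordered = sorted(members)
        reads = rng.geometric(cfg.single_read_prob, size=len(ordered))
        bucket = counts.setdefault(j, {})
        for smp, r in zip(ordered, map(int, reads)):
            bucket[smp] = bucket.get(smp, 0) + r
    noise_junctions = []
    noise_base = max(e for tx in transcripts for _, e in tx.exons) + 500
    for k in range(cfg.n_noise_junctions):
        j = (noise_base + 100 * k, noise_base + 100 * k + 60)
        noise_junctions.append(j)
        mask = rng.random(cfg.n_samples) < cfg.noise_frequency
        present = [smp for smp, m in zip(samples, mask) if m]
        counts[j] = {smp: 1 for smp in present}

    strand_of = {}
    for tx in transcripts:
        for s, e in tx.introns():
            strand_of[(s, e)] = tx.strand
    for ev, j in zip(cfg.planted_events, event_junctions):
        strand_of[j] = transcripts[ev.gene].strand
    for j in noise_junctions:
        strand_of[j] = "+"

    paths = {"annotation": gtf_path, "genome": fasta_path}
    if cfg.junction_dialect == "snaptron_tsv":
        jpath = outdir / "junctions.tsv"
        with open(jpath, "w") as fh:
            for idx, (j, per_sample) in enumerate(sorted(counts.items()), 1):
                if not per_sample:
                    continue
                entry = ",".join(f"{s}:{c}" for s, c in sorted(per_sample.items()))
                fh.write(f"J{idx}\tchr1\t{j[0]}\t{j[1]}\t{strand_of[j]}\t{entry}\n")
        paths["junctions"] = jpath
    elif cfg.junction_dialect == "star_sj":
        jdir = outdir / "junctions"
        jdir.mkdir(exist_ok=True)
        strand_code = {"+": 1, "-": 2}
        for smp in samples:
            with open(jdir / f"{smp}.SJ.out.tab", "w") as fh:
                for j, per_sample in sorted(counts.items()):
                    c = per_sample.get(smp)
                    if c:
                        fh.write(
                            f"chr1\t{j[0]}\t{j[1]}\t{strand_code[strand_of[j]]}"
                            f"\t0\t0\t{c}\t0\t30\n"
                        )
        paths["junctions"] = jdir
    else:
        raise ValueError(f"unsupported fixture dialect {cfg.junction_dialect!r}")

    # variants, delta scores, observed events
    variant_rows, delta_rows, observed_rows = [], [], []
    delta_truth = {}
    for v in cfg.variants:
        tx = transcripts[v.gene]
        site_pos = tx.donor_pos(v.exon_index) if v.kind == "donor" else tx.acceptor_pos(v.exon_index)
        sign = 1 if tx.strand == "+" else -1
        var_pos = site_pos + sign  # first intronic base (essential GT/AG)
        ref = sequence[var_pos - 1]
        alt = "A" if ref != "A" else "C"
        vid = f"VAR_{tx.transcript_id}_E{v.exon_index}{v.kind[0].upper()}"
        site_id = f"{tx.transcript_id}:E{v.exon_index}:{v.kind}"
        variant_rows.append(
            (vid, "chr1", var_pos, ref, alt, tx.transcript_id, site_id)
        )
        k = v.exon_index
        cryptic_pos = site_pos + v.cryptic_gain_offset * sign
        plan = [
            (site_pos, f"{v.kind}_loss", 0.9),
            (tx.acceptor_pos(k) if v.kind == "donor" else tx.donor_pos(k),
             "acceptor_loss" if v.kind == "donor" else "donor_loss", 0.8),
            (cryptic_pos, f"{v.kind}_gain", 0.4),
            # uninterpretable extras: a far gain and an unannotated loss
            (tx.acceptor_pos(2) - 5 * sign, "acceptor_gain", 0.3),
            (site_pos - 30 * sign, "donor_loss", 0.05),
            # neutral scores, dropped at load time
            (site_pos + 3 * sign, "donor_gain", 0.0005),
            (site_pos + 9 * sign, "acceptor_gain", 0.001),
        ]
        expected = [
            ("exon_skipping", (k,)),
            ("cryptic_donor" if v.kind == "donor" else "cryptic_acceptor", cryptic_pos),
        ]
        if v.include_double_skip:
            nxt = k + 1 if v.kind == "donor" else k - 1
            plan.append((tx.donor_pos(nxt) if v.kind == "donor" else tx.acceptor_pos(nxt),
                         "donor_loss" if v.kind == "donor" else "acceptor_loss", 0.3))
            expected.append(("exon_skipping", tuple(sorted((k, nxt)))))
        if v.include_intron_retention:
            # lose both ends of the intron adjacent to the site
            if v.kind == "donor":
                plan.append((tx.acceptor_pos(k + 1), "acceptor_loss", 0.2))
                expected.append(("intron_retention", k))
            else:
                plan.append((tx.donor_pos(k - 1), "donor_loss", 0.2))
                expected.append(("intron_retention", k - 1))
        for pos, channel, score in plan:
            delta_rows.append((vid, "chr1", pos, channel, score))
        delta_truth[vid] = {
            "expected": [[c, list(p) if isinstance(p, tuple) else p] for c, p in expected],
            "n_above_neutral": sum(1 for _, _, s in plan if s > 0.001),
            "variant_pos": var_pos,
            "site_id": site_id,
        }
        for ev in cfg.planted_events:
            if not ev.observed or ev.gene != v.gene:
                continue
            if ev.exon_index != v.exon_index or ev.kind != v.kind:
                continue
            if ev.category == "exon_skipping":
                label = ("single_exon_skipping" if len(ev.skipped_exons) == 1
                         else "double_exon_skipping" if len(ev.skipped_exons) == 2
                         else "multi_exon_skipping")
                observed_rows.append(
                    (vid, tx.transcript_id, site_id, label,
                     ",".join(map(str, ev.skipped_exons)), "", "", "")
                )
            else:
                j = _event_junction(ev, tx)
                cp = (j[0] - 1 if (tx.strand == "+") == (ev.category == "cryptic_donor")
                      else j[1] + 1)
                observed_rows.append(
                    (vid, tx.transcript_id, site_id, ev.category, "", cp, "", "")
                )
        if v.observed_ir_intron is not None:
            observed_rows.append(
                (vid, tx.transcript_id, site_id, "intron_retention", "", "",
                 v.observed_ir_intron, "")
            )

    vpath = outdir / "variants.tsv"
    with open(vpath, "w") as fh:
        fh.write("variant_id\tchrom\tpos\tref\talt\ttranscript_id\tsite_id\n")
        for row in variant_rows:
            fh.write("\t".join(map(str, row)) + "\n")
    dpath = outdir / "delta_scores.tsv"
    with open(dpath, "w") as fh:
        fh.write("variant_id\tchrom\tpos\tchannel\tscore\n")
        for row in delta_rows:
            fh.write("\t".join(map(str, row)) + "\n")
    opath = outdir / "observed_events.tsv"
    with open(opath, "w") as fh:
        fh.write("variant_id\ttranscript_id\tsite_id\tcategory\tskipped_exons"
                 "\tcryptic_pos\tintron_index\tin_frame\n")
        for row in observed_rows:
            fh.write("\t".join(map(str, row)) + "\n")
    paths.update(variants=vpath, delta_scores=dpath, observed_events=opath)

    truth_events = []
    for ev, members, j in zip(cfg.planted_events, memberships, event_junctions):
        tx = transcripts[ev.gene]
        rec = {
            "gene": ev.gene, "transcript_id": tx.transcript_id,
            "site_id": f"{tx.transcript_id}:E{ev.exon_index}:{ev.kind}",
            "category": ev.category,
            "skipped_exons": list(ev.skipped_exons) if ev.skipped_exons else None,
            "cryptic_offset": ev.cryptic_offset,
            "junction": list(j), "frequency": ev.frequency,
            "n_samples": len(members), "observed": ev.observed,
        }
        if groups is not None:
            rec["group_n_samples"] = {
                g: sum(1 for s in members if groups[s] == g)
                for g in sorted(set(groups.values()))
            }
        truth_events.append(rec)
    pair_truth = []
    for i, jdx, jac in cfg.cooccurrence:
        a, b = memberships[i], memberships[jdx]
        union = a | b
        pair_truth.append(
            {"events": [i, jdx], "target_jaccard": jac,
             "realized_jaccard": len(a & b) / len(union) if union else 0.0}
        )
    truth = {
        "seed": seed,
        "n_samples": cfg.n_samples,
        "samples": samples,
        "groups": groups,
        "transcripts": {
            tx.transcript_id: {
                "strand": tx.strand, "n_exons": tx.n_exons,
                "exons": [list(e) for e in tx.exons],
                "introns": [list(i) for i in tx.introns()],
                "cds": [tx.cds_start, tx.cds_end],
            }
            for tx in transcripts
        },
        "events": truth_events,
        "cooccurrence": pair_truth,
        "noise_junctions": [list(j) for j in noise_junctions],
        "delta": delta_truth,
        "annotated_frequency": cfg.annotated_frequency,
    }
    tpath = outdir / "truth.json"
    with open(tpath, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    paths["truth"] = tpath
    return Fixture(outdir=outdir, config=cfg, truth=truth,
                   transcripts=transcripts, paths=paths)
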