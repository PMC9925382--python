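"""Independent brute-force oracles for junction classification and the
delta-score rules.

Both oracles re-derive splice-site geometry directly from raw exon
coordinates (genomically sorted) rather than going through the package's
site accessors, and enumerate every candidate attribution exhaustively.
They exist only to cross-check the implementations on small transcripts.
"""

from __future__ import annotations


def boundary_maps(tx):
    """(donor position -> exon ordinal, acceptor position -> exon ordinal),
    derived from genomically sorted exons and the strand."""
    exons = sorted(tx.exons)
    n = len(exons)
    donors, acceptors = {}, {}
    for g, (s, e) in enumerate(exons):
        # transcript ordinal of this genomic exon
        k = g + 1 if tx.strand == "+" else n - g
        if tx.strand == "+":
            if k < n:
                donors[e] = k       # 3' end in transcript direction
            if k > 1:
                acceptors[s] = k    # 5' start
        else:
            if k < n:
                donors[s] = k
            if k > 1:
                acceptors[e] = k
    return donors, acceptors


def oracle_classify(junction, site, tx):
    """Exhaustive attribution of one junction to one site, or None.

    Returns a tuple mirroring MisSplicingEvent identity plus the offset:
    ("exon_skipping", exons) | ("cryptic_donor"/"cryptic_acceptor",
    cryptic_pos, offset).
    """
    if junction.chrom != tx.chrom or junction.strand != tx.strand:
        return None
    donors, acceptors = boundary_maps(tx)
    # genomic ends of the intron interval and their adjacent exonic bases
    left, right = junction.intron_start - 1, junction.intron_end + 1
    if tx.strand == "+":
        d_end, a_end = left, right
    else:
        d_end, a_end = right, left

    # annotated junction? then it is normal splicing, never an event
    for a, exon_a in donors.items():
        for b, exon_b in acceptors.items():
            if exon_b == exon_a + 1 and d_end == a and a_end == b:
                return None

    # exon skipping: every (donor exon a, acceptor exon b >= a+2) pair
    for a, exon_a in donors.items():
        for b, exon_b in acceptors.items():
            if exon_b >= exon_a + 2 and d_end == a and a_end == b:
                skipped = tuple(range(exon_a + 1, exon_b))
                if site.exon_index in skipped:
                    return ("exon_skipping", skipped)
                return None

    sign = 1 if tx.strand == "+" else -1
    if site.kind == "donor":
        partner = [p for p, k in acceptors.items() if k == site.exon_index + 1]
        if partner and a_end == partner[0] and d_end not in donors:
            offset = (d_end - site.pos) * sign
            if offset:
                return ("cryptic_donor", d_end, offset)
    else:
        partner = [p for p, k in donors.items() if k == site.exon_index - 1]
        if partner and d_end == partner[0] and a_end not in acceptors:
            offset = (site.pos - a_end) * sign
            if offset:
                return ("cryptic_acceptor", a_end, offset)
    return None


def oracle_delta_predictions(scores, site, tx, decision_threshold, neutral=0.001):
    """Exhaustive rule evaluation: identity tuples of every prediction."""
    scores = [r for r in scores if r.score > neutral]
    loss_channel = f"{site.kind}_loss"
    if not any(r.channel == loss_channel and r.pos == site.pos for r in scores):
        return set()
    called = [r for r in scores if r.score >= decision_threshold]
    donors, acceptors = boundary_maps(tx)
    n = len(tx.exons)

    def lost(kind, exon):
        table = donors if kind == "donor" else acceptors
        positions = [p for p, k in table.items() if k == exon]
        return any(
            r.channel == f"{kind}_loss" and r.pos in positions for r in called
        )

    out = set()
    singles = [k for k in range(2, n) if lost("donor", k) and lost("acceptor", k)]
    for k in singles:
        out.add(("exon_skipping", (k,)))
        if k - 1 >= 2 and lost("acceptor", k - 1):
            out.add(("exon_skipping", (k - 1, k)))
        if k + 1 <= n - 1 and lost("donor", k + 1):
            out.add(("exon_skipping", (k, k + 1)))
    for j in range(1, n):
        if lost("donor", j) and lost("acceptor", j + 1):
            out.add(("intron_retention", j))
    # flanking bounds: the site's exon plus its adjacent intron
    exons = sorted(tx.exons)
    g = site.exon_index - 1 if tx.strand == "+" else n - site.exon_index
    exon_iv = exons[g]
    introns = [(e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(exons, exons[1:])]
    gi = site.intron_index - 1 if tx.strand == "+" else n - 1 - site.intron_index
    intron_iv = introns[gi]
    gain_channel = f"{site.kind}_gain"
    table = donors if site.kind == "donor" else acceptors
    for r in called:
        if r.channel != gain_channel:
            continue
        if r.pos in table:
            continue
        if exon_iv[0] <= r.pos <= exon_iv[1] or intron_iv[0] <= r.pos <= intron_iv[1]:
            cat = "cryptic_donor" if site.kind == "donor" else "cryptic_acceptor"
            out.add((cat, r.pos))
    return out
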