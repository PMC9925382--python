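"""Match predicted against observed mis-splicing events and compute
sensitivity/PPV, precision-recall sweeps, filter grids and subsampling
detection curves.

Matching is exact: an exon-skipping prediction matches only an observed
event with the identical skipped-exon set; a cryptic prediction matches
only the identical genomic cryptic position (no distance window — windows
would inflate PPV). Intron retention is evaluated for delta-score
predictions only, since a catalog built from split reads cannot rank IR.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .deltarules import SpliceAIPrediction
from .junctions import JunctionCounts
from .vault import RankedEventTable, VaultConfig, VaultDB, query_top_events

__all__ = [
    "ObservedEvent",
    "ObservedEventSet",
    "ConfusionCounts",
    "load_observed_events",
    "write_observed_events",
    "match_events",
    "precision_recall_comparison",
    "subsample_detection_curve",
]

OBSERVED_CATEGORIES = {
    "single_exon_skipping",
    "double_exon_skipping",
    "multi_exon_skipping",
    "cryptic_donor",
    "cryptic_acceptor",
    "intron_retention",
}


@dataclass(frozen=True)
class ObservedEvent:
    category: str
    exons: Optional[tuple[int, ...]] = None
    cryptic_pos: Optional[int] = None
    intron: Optional[int] = None
    in_frame: Optional[bool] = None

    @property
    def identity(self) -> tuple:
        if self.category.endswith("exon_skipping"):
            return ("exon_skipping", self.exons)
        if self.category == "intron_retention":
            return ("intron_retention", self.intron)
        return (self.category, self.cryptic_pos)


@dataclass
class ObservedEventSet:
    variant_id: str
    transcript_id: str
    site_id: str
    events: list[ObservedEvent] = field(default_factory=list)


def _skipping_label(exons: tuple[int, ...]) -> str:
    if len(exons) == 1:
        return "single_exon_skipping"
    if len(exons) == 2:
        return "double_exon_skipping"
    return "multi_exon_skipping"


def load_observed_events(path, transcripts=None) -> list[ObservedEventSet]:
    """Read an observed-event TSV (one row per validated event).

    Columns: variant_id, transcript_id, site_id, category, skipped_exons
    (comma-separated ordinals), cryptic_pos, intron_index, in_frame.
    Unknown category strings are an error naming the row.
    """
    df = pd.read_csv(path, sep="\t", dtype={"skipped_exons": str})
    by_variant: dict[str, ObservedEventSet] = {}
    for i, row in df.iterrows():
        category = str(row["category"])
        if category not in OBSERVED_CATEGORIES:
            raise ValueError(f"{path}: row {i + 2}: unknown category {category!r}")
        exons = None
        if isinstance(row.get("skipped_exons"), str) and row["skipped_exons"]:
            exons = tuple(int(x) for x in row["skipped_exons"].split(","))
        ev = ObservedEvent(
            category=category,
            exons=exons,
            cryptic_pos=int(row["cryptic_pos"]) if pd.notna(row.get("cryptic_pos")) else None,
            intron=int(row["intron_index"]) if pd.notna(row.get("intron_index")) else None,
            in_frame=bool(row["in_frame"]) if pd.notna(row.get("in_frame")) else None,
        )
        obs = by_variant.setdefault(
            str(row["variant_id"]),
            ObservedEventSet(
                variant_id=str(row["variant_id"]),
                transcript_id=str(row["transcript_id"]),
                site_id=str(row["site_id"]),
            ),
        )
        obs.events.append(ev)
    return list(by_variant.values())


def write_observed_events(observed: Iterable[ObservedEventSet], path) -> None:
    rows = []
    for obs in observed:
        for ev in obs.events:
            rows.append(
                {
                    "variant_id": obs.variant_id,
                    "transcript_id": obs.transcript_id,
                    "site_id": obs.site_id,
                    "category": ev.category,
                    "skipped_exons": ",".join(map(str, ev.exons)) if ev.exons else "",
                    "cryptic_pos": ev.cryptic_pos,
                    "intron_index": ev.intron,
                    "in_frame": ev.in_frame,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    per_category: dict = field(default_factory=dict)

    @property
    def sensitivity(self) -> Optional[float]:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else None

    @property
    def ppv(self) -> Optional[float]:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else None


def _prediction_identities(predicted) -> set[tuple]:
    """Normalize a prediction container to a set of identity tuples."""
    if predicted is None:
        return set()
    if isinstance(predicted, RankedEventTable):
        return {r.event.identity for r in predicted.top_star_rows()}
    out = set()
    for item in predicted:
        if isinstance(item, SpliceAIPrediction):
            out.add(item.identity)
        elif hasattr(item, "event"):  # EventRow
            out.add(item.event.identity)
        elif hasattr(item, "identity"):
            out.add(item.identity)
        else:
            out.add(tuple(item))
    return out


def _category_of_identity(ident: tuple) -> str:
    kind, payload = ident
    if kind == "exon_skipping":
        return _skipping_label(tuple(payload))
    if kind == "intron_retention":
        return "intron_retention"
    return kind


def match_events(
    predicted,
    observed,
    include_intron_retention: bool = False,
    pessimistic_ir: bool = False,
) -> ConfusionCounts:
    """Exact-identity confusion counts of predictions vs observed events.

    ``predicted`` is either a per-variant mapping (variant_id -> prediction
    container) matched against a list of ObservedEventSet, or a single
    container matched against one ObservedEventSet. Observed intron
    retention is excluded unless the predictor can call it
    (``include_intron_retention``) or ``pessimistic_ir`` counts it as a
    miss regardless.
    """
    if isinstance(observed, ObservedEventSet):
        observed = [observed]
        predicted = {observed[0].variant_id: predicted}
    counts = ConfusionCounts()

    def bump(cat: str, key: str):
        slot = counts.per_category.setdefault(cat, {"tp": 0, "fp": 0, "fn": 0})
        slot[key] += 1
        setattr(counts, key, getattr(counts, key) + 1)

    for obs in observed:
        pred_ids = _prediction_identities(predicted.get(obs.variant_id))
        obs_ids = set()
        for ev in obs.events:
            if ev.category == "intron_retention" and not include_intron_retention:
                if pessimistic_ir:
                    bump("intron_retention", "fn")
                continue
            obs_ids.add(ev.identity)
        if not include_intron_retention:
            pred_ids = {p for p in pred_ids if p[0] != "intron_retention"}
        for ident in pred_ids & obs_ids:
            bump(_category_of_identity(ident), "tp")
        for ident in pred_ids - obs_ids:
            bump(_category_of_identity(ident), "fp")
        for ident in obs_ids - pred_ids:
            bump(_category_of_identity(ident), "fn")
    return counts


def _vault_predictions(
    db: VaultDB, variants: list[dict], config: VaultConfig
) -> dict[str, set[tuple]]:
    out = {}
    for v in variants:
        table = query_top_events(db, v["site_id"], config=config)
        out[v["variant_id"]] = _prediction_identities(table)
    return out


def precision_recall_comparison(
    observed: list[ObservedEventSet],
    mode: str,
    db: Optional[VaultDB] = None,
    variants: Optional[list[dict]] = None,
    config: Optional[VaultConfig] = None,
    top_n_range: Iterable[int] = range(1, 11),
    delta_predictions: Optional[dict[float, dict[str, list]]] = None,
    skip_grid: Iterable[int] = (1, 2, 3, 4),
    cryptic_grid: Iterable[int] = (100, 300, 600, 1000, 2000),
) -> pd.DataFrame:
    """Performance sweeps in one of three modes.

    * ``rank_sweep`` — sensitivity/PPV of the starred catalog at each Top-N;
    * ``budget_matched`` — for each Top-N, the delta threshold whose total
      prediction count equals the Top-N* count (ties toward the lower
      threshold; no exact match -> nearest count, flagged), with metrics
      at that threshold;
    * ``filter_grid`` — metrics across max_skipped_exons x max_cryptic_nt
      combinations at fixed Top-N.
    """
    config = config or (db.config if db is not None else VaultConfig())
    rows = []
    if mode == "rank_sweep":
        for n in top_n_range:
            cfg = VaultConfig(
                top_n=n, max_skipped_exons=config.max_skipped_exons,
                max_cryptic_nt=config.max_cryptic_nt,
            )
            preds = _vault_predictions(db, variants, cfg)
            cc = match_events(preds, observed)
            rows.append(
                {"top_n": n,
                 "n_predictions": sum(len(p) for p in preds.values()),
                 "tp": cc.tp, "fp": cc.fp, "fn": cc.fn,
                 "sensitivity": cc.sensitivity, "ppv": cc.ppv}
            )
    elif mode == "budget_matched":
        if delta_predictions is None:
            raise ValueError("budget_matched mode needs delta_predictions")
        grid = sorted(delta_predictions)
        grid_counts = {
            t: sum(len(_prediction_identities(p))
                   for p in delta_predictions[t].values())
            for t in grid
        }
        for n in top_n_range:
            cfg = VaultConfig(
                top_n=n, max_skipped_exons=config.max_skipped_exons,
                max_cryptic_nt=config.max_cryptic_nt,
            )
            vault_preds = _vault_predictions(db, variants, cfg)
            target = sum(len(p) for p in vault_preds.values())
            exact = [t for t in grid if grid_counts[t] == target]
            if exact:
                chosen, is_exact = exact[0], True
            else:
                chosen = min(grid, key=lambda t: (abs(grid_counts[t] - target), t))
                is_exact = False
            cc = match_events(
                delta_predictions[chosen], observed, include_intron_retention=True
            )
            rows.append(
                {"top_n": n, "vault_count": target, "delta_threshold": chosen,
                 "delta_count": grid_counts[chosen], "exact_budget": is_exact,
                 "tp": cc.tp, "fp": cc.fp, "fn": cc.fn,
                 "sensitivity": cc.sensitivity, "ppv": cc.ppv}
            )
    elif mode == "filter_grid":
        for ms, mc in itertools.product(skip_grid, cryptic_grid):
            cfg = VaultConfig(top_n=config.top_n, max_skipped_exons=ms, max_cryptic_nt=mc)
            preds = _vault_predictions(db, variants, cfg)
            cc = match_events(preds, observed)
            rows.append(
                {"max_skipped_exons": ms, "max_cryptic_nt": mc,
                 "n_predictions": sum(len(p) for p in preds.values()),
                 "tp": cc.tp, "fp": cc.fp, "fn": cc.fn,
                 "sensitivity": cc.sensitivity, "ppv": cc.ppv}
            )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(rows)


def target_sample_sets(
    aggregated: Iterable[JunctionCounts], keys: Iterable[tuple]
) -> dict[tuple, set[str]]:
    """Per-target sample-presence sets pulled from aggregated junctions."""
    wanted = set(keys)
    by_key = {jc.junction.key: jc for jc in aggregated}
    out = {}
    for key in wanted:
        jc = by_key.get(key)
        out[key] = jc.samples() if jc is not None else set()
    return out


def subsample_detection_curve(
    sample_sets: dict,
    all_samples: Iterable[str],
    subset_sizes: Iterable[int],
    replicates: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Fraction of target events with >=1 supporting sample in random
    sample subsets, averaged over replicates.

    For an event present independently in a fraction f of samples, the
    expected detection fraction at subset size n is 1 - (1 - f)^n.
    """
    samples = sorted(set(all_samples))
    rng = np.random.default_rng(seed)
    targets = list(sample_sets.values())
    if not targets:
        raise ValueError("no target events supplied")
    rows = []
    for size in subset_sizes:
        if size > len(samples):
            raise ValueError(f"subset size {size} exceeds cohort size {len(samples)}")
        fracs = []
        for _ in range(replicates):
            subset = set(rng.choice(samples, size=size, replace=False)) if size else set()
            detected = sum(1 for s in targets if s & subset)
            fracs.append(detected / len(targets))
        rows.append(
            {"subset_size": size, "mean_detected": float(np.mean(fracs)),
             "sd_detected": float(np.std(fracs, ddof=1)) if replicates > 1 else 0.0,
             "replicates": replicates}
        )
    return pd.DataFrame(rows)
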