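"""Benchmark scoring for virus-host prediction tools.

Predictions are scored per gold-standard (virus, host) pair at a chosen
taxonomic rank (genus by default). Each pair is classified independently:

* NA — the tool made no call for the virus (or none at the rank);
* TP — the predicted taxon equals the pair's host taxon at the rank;
* FP — the predicted taxon differs.

False negatives comprise both FPs and NAs (failures to recover a true
pair), so FN = FP + NA and sensitivity reduces to TP / actual_pairs. A
virus with k gold hosts contributes k outcomes, so a single call can be a
TP for one pair and an FP for another.

Metrics:

    precision (PPV) = TP / (TP + FP)
    sensitivity (TPR) = TP / (TP + FN)
    F1 = 2 * PPV * TPR / (PPV + TPR)

Undefined ratios (0/0) are reported as 0 and flagged, keeping report tables
numeric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical rank order, shallow to deep.
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
RANK_DEPTH = {rank: i for i, rank in enumerate(RANKS)}

REPORT_COLUMNS = [
    "tool",
    "actual_pairs",
    "predicted_pairs",
    "na",
    "tp",
    "fp",
    "fn",
    "precision",
    "sensitivity",
    "f1",
]


# --------------------------------------------------------------------------
# lineages

Lineage = dict  # rank -> taxon name, partial, canonical rank order


def parse_lineage(text: str) -> Lineage | None:
    """Parse ``rank:name;rank:name`` into an ordered rank->name map.

    The literal ``NA`` (any case) or an empty string yields ``None`` (no
    call). Unknown ranks are fatal; ranks are reordered canonically.
    """
    text = text.strip()
    if not text or text.upper() == "NA":
        return None
    entries: dict[str, str] = {}
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        rank, sep, name = chunk.partition(":")
        rank, name = rank.strip().lower(), name.strip()
        if not sep or not name:
            raise ValueError(f"malformed lineage entry {chunk!r}")
        if rank not in RANK_DEPTH:
            raise ValueError(f"unknown rank {rank!r} in lineage {text!r}")
        entries[rank] = name
    return {rank: entries[rank] for rank in RANKS if rank in entries}


def format_lineage(lineage: Lineage | None) -> str:
    if not lineage:
        return "NA"
    return ";".join(f"{rank}:{lineage[rank]}" for rank in RANKS if rank in lineage)


def taxon_at_rank(lineage: Lineage | None, rank: str) -> str | None:
    """Case-folded, whitespace-trimmed taxon name at ``rank`` (or None)."""
    if not lineage:
        return None
    name = lineage.get(rank)
    return name.strip().casefold() if name else None


# --------------------------------------------------------------------------
# records


@dataclass(frozen=True)
class VirusHostPair:
    """A gold-standard virus-host association."""

    virus_id: str
    host_id: str
    host_lineage: Lineage = field(default_factory=dict)


@dataclass(frozen=True)
class PredictionRecord:
    """One tool's host call for one virus; ``predicted_lineage`` None = NA."""

    tool: str
    virus_id: str
    predicted_lineage: Lineage | None = None


@dataclass(frozen=True)
class OutcomeCounts:
    """Per-tool confusion counts over gold pairs."""

    actual_pairs: int
    predicted_pairs: int
    na: int
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        counts = (self.actual_pairs, self.predicted_pairs, self.na, self.tp, self.fp, self.fn)
        if min(counts) < 0:
            raise ValueError("counts must be non-negative")
        if self.predicted_pairs != self.tp + self.fp:
            raise ValueError("predicted_pairs must equal tp + fp")
        if self.actual_pairs != self.tp + self.fp + self.na:
            raise ValueError("actual_pairs must equal tp + fp + na")
        if self.fn != self.fp + self.na:
            raise ValueError("fn must equal fp + na")

    @classmethod
    def from_confusion(cls, tp: int, fp: int, na: int) -> "OutcomeCounts":
        return cls(
            actual_pairs=tp + fp + na,
            predicted_pairs=tp + fp,
            na=na,
            tp=tp,
            fp=fp,
            fn=fp + na,
        )


@dataclass(frozen=True)
class Metrics:
    """Precision / sensitivity / F1 with flags for 0/0 ratios."""

    precision: float
    sensitivity: float
    f1: float
    undefined: frozenset = frozenset()


# --------------------------------------------------------------------------
# scoring


def score_tool(
    gold: Iterable[VirusHostPair],
    predictions: Iterable[PredictionRecord],
    rank: str = "genus",
) -> OutcomeCounts:
    """Classify every gold pair against a tool's predictions at ``rank``."""
    if rank not in RANK_DEPTH:
        raise ValueError(f"unknown rank {rank!r}")
    by_virus: dict[str, PredictionRecord] = {}
    for rec in predictions:
        key = rec.virus_id
        if key in by_virus:
            raise ValueError(
                f"duplicate prediction for virus {rec.virus_id!r} "
                f"(tool {rec.tool!r})"
            )
        by_virus[key] = rec

    tp = fp = na = 0
    gold = list(gold)
    for pair in gold:
        truth = taxon_at_rank(pair.host_lineage, rank)
        if truth is None:
            raise ValueError(
                f"gold pair ({pair.virus_id!r}, {pair.host_id!r}) has no "
                f"taxon at rank {rank!r}"
            )
        rec = by_virus.get(pair.virus_id)
        called = taxon_at_rank(rec.predicted_lineage, rank) if rec else None
        if called is None:
            na += 1
        elif called == truth:
            tp += 1
        else:
            fp += 1
    return OutcomeCounts.from_confusion(tp=tp, fp=fp, na=na)


def compute_metrics(counts: OutcomeCounts) -> Metrics:
    """Precision, sensitivity and F1 from confusion counts."""
    undefined = set()
    if counts.tp + counts.fp == 0:
        precision = 0.0
        undefined.add("precision")
    else:
        precision = counts.tp / (counts.tp + counts.fp)
    if counts.tp + counts.fn == 0:
        sensitivity = 0.0
        undefined.add("sensitivity")
    else:
        sensitivity = counts.tp / (counts.tp + counts.fn)
    if precision + sensitivity == 0:
        f1 = 0.0
        undefined.add("f1")
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return Metrics(
        precision=precision,
        sensitivity=sensitivity,
        f1=f1,
        undefined=frozenset(undefined),
    )


def benchmark_report(
    gold: Iterable[VirusHostPair],
    predictions: Iterable[PredictionRecord],
    rank: str = "genus",
) -> pd.DataFrame:
    """One row per tool with counts and metrics, sorted by F1 ascending."""
    gold = list(gold)
    by_tool: dict[str, list[PredictionRecord]] = {}
    for rec in predictions:
        by_tool.setdefault(rec.tool, []).append(rec)
    rows = []
    for tool in sorted(by_tool):
        counts = score_tool(gold, by_tool[tool], rank=rank)
        metrics = compute_metrics(counts)
        rows.append(
            (
                tool,
                counts.actual_pairs,
                counts.predicted_pairs,
                counts.na,
                counts.tp,
                counts.fp,
                counts.fn,
                metrics.precision,
                metrics.sensitivity,
                metrics.f1,
            )
        )
    frame = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return frame.sort_values(["f1", "tool"], kind="stable").reset_index(drop=True)


# --------------------------------------------------------------------------
# TSV interfaces


def read_gold_tsv(source) -> list[VirusHostPair]:
    """Gold table: columns virus_id, host_id, lineage (rank:name;...)."""
    frame = pd.read_csv(source, sep="\t", dtype=str)
    required = {"virus_id", "host_id", "lineage"}
    if not required <= set(frame.columns):
        raise ValueError(f"gold table needs columns {sorted(required)}")
    pairs = []
    seen = set()
    for row in frame.itertuples(index=False):
        key = (row.virus_id, row.host_id)
        if key in seen:
            raise ValueError(f"duplicate gold pair {key!r}")
        seen.add(key)
        pairs.append(
            VirusHostPair(
                virus_id=row.virus_id,
                host_id=row.host_id,
                host_lineage=parse_lineage(row.lineage) or {},
            )
        )
    return pairs


def write_gold_tsv(pairs: Iterable[VirusHostPair], out) -> None:
    frame = pd.DataFrame(
        [
            (p.virus_id, p.host_id, format_lineage(p.host_lineage))
            for p in pairs
        ],
        columns=["virus_id", "host_id", "lineage"],
    )
    frame.to_csv(out, sep="\t", index=False)


def read_predictions_tsv(source) -> list[PredictionRecord]:
    """Prediction table: columns tool, virus_id, lineage (or literal NA)."""
    frame = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    required = {"tool", "virus_id", "lineage"}
    if not required <= set(frame.columns):
        raise ValueError(f"prediction table needs columns {sorted(required)}")
    return [
        PredictionRecord(
            tool=row.tool,
            virus_id=row.virus_id,
            predicted_lineage=parse_lineage(row.lineage),
        )
        for row in frame.itertuples(index=False)
    ]


def write_predictions_tsv(records: Iterable[PredictionRecord], out) -> None:
    frame = pd.DataFrame(
        [
            (r.tool, r.virus_id, format_lineage(r.predicted_lineage))
            for r in records
        ],
        columns=["tool", "virus_id", "lineage"],
    )
    frame.to_csv(out, sep="\t", index=False)


def write_report_tsv(report: pd.DataFrame, out) -> None:
    report.to_csv(out, sep="\t", index=False, float_format="%.4f")


def predictions_from_host_calls(
    tool: str,
    calls: Mapping[str, str],
    taxonomy: Mapping[str, Lineage],
) -> list[PredictionRecord]:
    """Lift per-contig host-id calls into rank-labeled prediction records
    using a host taxonomy table; hosts missing from the taxonomy are fatal."""
    records = []
    for virus_id in sorted(calls):
        host_id = calls[virus_id]
        if host_id not in taxonomy:
            raise ValueError(f"host {host_id!r} absent from the taxonomy table")
        records.append(
            PredictionRecord(
                tool=tool,
                virus_id=virus_id,
                predicted_lineage=dict(taxonomy[host_id]),
            )
        )
    return records
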