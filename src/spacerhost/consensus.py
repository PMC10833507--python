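"""Inter-method agreement and environment-consistency annotation.

When several prediction tools are run on the same viral contigs, their calls
can be compared at a minimum taxonomic rank: two lineages agree when the
deepest rank they share carries the same name and is at least as deep as the
minimum rank (order by default). Each contig is then assigned to the
combination of tools whose calls mutually agree — the counts are suitable
for upset-style plotting — and each prediction can be flagged for
consistency with a trait profile of the source environment (e.g. halophilic,
sulfate-reducing taxa for a hypersaline pond).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import pandas as pd

from .benchmark import RANK_DEPTH, RANKS, Lineage, parse_lineage

logger = logging.getLogger(__name__)

DEFAULT_MIN_RANK = "order"


# --------------------------------------------------------------------------
# lineage agreement


def lowest_common_rank(a: Lineage, b: Lineage) -> str | None:
    """Deepest rank present in both lineages with equal (case-folded) names."""
    common = None
    for rank in RANKS:
        na, nb = a.get(rank), b.get(rank)
        if na and nb and na.strip().casefold() == nb.strip().casefold():
            common = rank
    return common


def lineages_agree(a: Lineage, b: Lineage, min_rank: str = DEFAULT_MIN_RANK) -> bool:
    """True iff the two lineages share a taxon at ``min_rank`` or deeper.

    Symmetric, and reflexive on non-empty lineages deep enough to reach
    ``min_rank``.
    """
    if min_rank not in RANK_DEPTH:
        raise ValueError(f"unknown rank {min_rank!r}")
    rank = lowest_common_rank(a, b)
    return rank is not None and RANK_DEPTH[rank] >= RANK_DEPTH[min_rank]


# --------------------------------------------------------------------------
# agreement sets (upset-plot counts)

ToolPredictions = Mapping[str, Mapping[str, Lineage]]  # tool -> contig -> lineage


def _clique_depth(tools: tuple[str, ...], calls: Mapping[str, Lineage]) -> int:
    """Deepest pairwise agreement rank within a candidate clique."""
    depth = -1
    for x, y in itertools.combinations(tools, 2):
        rank = lowest_common_rank(calls[x], calls[y])
        if rank is not None:
            depth = max(depth, RANK_DEPTH[rank])
    return depth


def agreement_sets(
    predictions: ToolPredictions, min_rank: str = DEFAULT_MIN_RANK
) -> dict[tuple[str, ...], int]:
    """Count contigs per combination of mutually agreeing tools.

    For each contig, the tools that predicted it are searched for the best
    clique under pairwise :func:`lineages_agree`: largest first, then the
    clique with the deepest internal agreement, then alphabetical tool-set
    name. Tools outside the chosen clique count that contig in their
    singleton (tool-exclusive) set, so per-tool counts across combinations
    partition each tool's prediction set.
    """
    if len(predictions) < 2:
        raise ValueError("agreement analysis needs at least two tools")
    counts: dict[tuple[str, ...], int] = {}
    contigs = sorted({c for preds in predictions.values() for c in preds})
    for contig in contigs:
        calls = {
            tool: preds[contig]
            for tool, preds in predictions.items()
            if contig in preds and preds[contig]
        }
        tools = sorted(calls)
        cliques = []
        for size in range(len(tools), 1, -1):
            for combo in itertools.combinations(tools, size):
                if all(
                    lineages_agree(calls[x], calls[y], min_rank)
                    for x, y in itertools.combinations(combo, 2)
                ):
                    cliques.append(combo)
            if cliques:
                break  # only the largest cliques matter
        if cliques:
            if len(cliques) > 1:
                logger.info(
                    "contig %s: non-transitive agreement, candidate cliques %s",
                    contig,
                    cliques,
                )
            best_depth = max(_clique_depth(c, calls) for c in cliques)
            chosen = min(c for c in cliques if _clique_depth(c, calls) == best_depth)
        else:
            chosen = ()
        if chosen:
            counts[chosen] = counts.get(chosen, 0) + 1
        for tool in tools:
            if tool not in chosen:
                counts[(tool,)] = counts.get((tool,), 0) + 1
    return counts


def write_agreement_tsv(counts: Mapping[tuple[str, ...], int], out) -> None:
    """Agreement table: combination (tools joined by '&') and contig count."""
    frame = pd.DataFrame(
        sorted((("&".join(combo), n) for combo, n in counts.items())),
        columns=["combination", "count"],
    )
    frame.to_csv(out, sep="\t", index=False)


# --------------------------------------------------------------------------
# environment consistency


class TraitTable:
    """Host traits by (taxon name, rank); (taxon, rank) pairs are unique."""

    def __init__(self, rows: Iterable[tuple[str, str, Iterable[str]]] = ()):
        self._traits: dict[tuple[str, str], frozenset[str]] = {}
        for taxon, rank, traits in rows:
            self.add(taxon, rank, traits)

    def add(self, taxon: str, rank: str, traits: Iterable[str]) -> None:
        rank = rank.strip().lower()
        if rank not in RANK_DEPTH:
            raise ValueError(f"unknown rank {rank!r} for taxon {taxon!r}")
        key = (taxon.strip().casefold(), rank)
        if key in self._traits:
            raise ValueError(f"duplicate trait entry for {key!r}")
        self._traits[key] = frozenset(t.strip().casefold() for t in traits if t.strip())

    def traits_for(self, taxon: str, rank: str) -> frozenset[str]:
        return self._traits.get((taxon.strip().casefold(), rank.strip().lower()), frozenset())

    def __len__(self) -> int:
        return len(self._traits)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return (key[0].strip().casefold(), key[1].strip().lower()) in self._traits


def read_trait_table(source) -> TraitTable:
    """Trait TSV: columns taxon, rank, traits (comma-separated)."""
    frame = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    required = {"taxon", "rank", "traits"}
    if not required <= set(frame.columns):
        raise ValueError(f"trait table needs columns {sorted(required)}")
    table = TraitTable()
    for row in frame.itertuples(index=False):
        table.add(row.taxon, row.rank, row.traits.split(","))
    return table


def read_environment_profile(source) -> frozenset[str]:
    """Environment profile: one accepted trait per line ('#' comments allowed)."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    elif isinstance(source, str) and "\n" in source:
        lines = source.splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()
    traits = frozenset(
        line.strip().casefold()
        for line in lines
        if line.strip() and not line.lstrip().startswith("#")
    )
    return traits


def _round_pct(numerator: int, denominator: int) -> float:
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class EnvironmentSummary:
    tool: str
    total: int
    consistent: int
    percentage: float  # half-up rounded to 2 d.p.


def environment_consistency(
    predictions: ToolPredictions,
    traits: TraitTable,
    accepted: Iterable[str],
) -> tuple[dict[str, EnvironmentSummary], dict[tuple[str, str], bool]]:
    """Flag every prediction for consistency with the source environment.

    A prediction is consistent iff its predicted taxon, or any ancestor
    named in its lineage, carries at least one accepted trait. Taxa absent
    from the trait table contribute nothing (and are logged), so a fully
    unknown lineage is inconsistent by default. Returns per-tool summaries
    and per-(tool, contig) flags.
    """
    accepted = frozenset(t.strip().casefold() for t in accepted if t.strip())
    if not accepted:
        raise ValueError("the accepted trait set must be non-empty")
    summaries: dict[str, EnvironmentSummary] = {}
    flags: dict[tuple[str, str], bool] = {}
    for tool in sorted(predictions):
        calls = predictions[tool]
        consistent = 0
        for contig in sorted(calls):
            lineage = calls[contig]
            ok = False
            known = False
            for rank in RANKS:
                name = lineage.get(rank)
                if not name:
                    continue
                tr = traits.traits_for(name, rank)
                if (name, rank) in traits:
                    known = True
                if tr & accepted:
                    ok = True
                    break
            if not known and not ok:
                logger.info(
                    "tool %s, contig %s: no lineage taxon found in the trait "
                    "table; marked inconsistent",
                    tool,
                    contig,
                )
            flags[(tool, contig)] = ok
            consistent += ok
        total = len(calls)
        summaries[tool] = EnvironmentSummary(
            tool=tool,
            total=total,
            consistent=consistent,
            percentage=_round_pct(consistent, total) if total else 0.0,
        )
    return summaries, flags


def write_environment_tsv(summaries: Mapping[str, EnvironmentSummary], out) -> None:
    frame = pd.DataFrame(
        [
            (s.tool, s.total, s.consistent, s.percentage)
            for s in summaries.values()
        ],
        columns=["tool", "predictions", "consistent", "percentage"],
    )
    frame.to_csv(out, sep="\t", index=False)
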