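"""Host assignment from filtered spacer matches.

One host is called per viral contig by three ordered criteria:

1. all matches point to a single candidate host — assign it;
2. otherwise assign the host with the most spacers matching pairwise
   non-overlapping regions of the contig (maximum non-overlapping interval
   count, greedy earliest-end, which is optimal for this objective);
3. on exact criterion-2 ties, assign the host whose matching spacer sits
   closest to the 5' (leader) end of its CRISPR array — the most recently
   acquired spacer, hence the most likely recent infection.

Residual exact ties are broken by lexicographically smallest host id and
logged as unresolved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .crispr_arrays import SpacerDatabase
from .spacer_matching import SpacerMatch

logger = logging.getLogger(__name__)

PREDICTION_COLUMNS = [
    "contig_id",
    "host_id",
    "criterion",
    "n_matches",
    "n_nonoverlapping",
    "best_relative_position",
]


@dataclass(frozen=True)
class HostPrediction:
    """A per-contig host call and the criterion that decided it."""

    contig_id: str
    host_id: str
    criterion: int  # 1, 2 or 3
    n_matches: int
    n_nonoverlapping: int | None = None  # present when criterion >= 2
    best_relative_position: float | None = None  # present when criterion == 3

    def __post_init__(self) -> None:
        if self.criterion not in (1, 2, 3):
            raise ValueError(f"bad criterion {self.criterion}")
        if self.n_matches < 1:
            raise ValueError("a prediction needs at least one supporting match")
        if self.criterion == 3 and not (0.0 <= self.best_relative_position <= 1.0):
            raise ValueError("best_relative_position must lie in [0, 1]")


def count_nonoverlapping(intervals: Iterable[tuple[int, int]]) -> int:
    """Maximum number of pairwise non-overlapping closed intervals.

    Overlap on closed intervals: [a, b] and [c, d] overlap iff a <= d and
    c <= b. Greedy selection by earliest end is optimal for this objective.
    """
    chosen = 0
    last_end = None
    for start, end in sorted(intervals, key=lambda iv: (iv[1], iv[0])):
        if start > end:
            raise ValueError(f"bad interval ({start}, {end})")
        if last_end is None or start > last_end:
            chosen += 1
            last_end = end
    return chosen


def assign_host(
    matches: Sequence[SpacerMatch], spacer_db: SpacerDatabase
) -> HostPrediction | None:
    """Call one host for one contig's filtered matches (or None if empty)."""
    matches = list(matches)
    if not matches:
        return None
    contig_ids = {m.contig_id for m in matches}
    if len(contig_ids) != 1:
        raise ValueError(f"matches span multiple contigs: {sorted(contig_ids)}")
    contig_id = matches[0].contig_id
    for m in matches:
        spacer_db.spacer(m.spacer_id)  # unresolvable spacer ids are fatal

    by_host: dict[str, list[SpacerMatch]] = {}
    for m in matches:
        by_host.setdefault(m.host_id, []).append(m)

    if len(by_host) == 1:
        host_id = next(iter(by_host))
        return HostPrediction(
            contig_id=contig_id,
            host_id=host_id,
            criterion=1,
            n_matches=len(matches),
        )

    # criterion 2: most spacers matching non-overlapping contig regions
    nonoverlap = {
        host: count_nonoverlapping(m.interval for m in ms)
        for host, ms in by_host.items()
    }
    best = max(nonoverlap.values())
    tied = sorted(h for h, n in nonoverlap.items() if n == best)
    if len(tied) == 1:
        host_id = tied[0]
        return HostPrediction(
            contig_id=contig_id,
            host_id=host_id,
            criterion=2,
            n_matches=len(by_host[host_id]),
            n_nonoverlapping=best,
        )

    # criterion 3: among tied hosts, the spacer closest to the array's 5' end
    best_pos = {
        host: min(
            spacer_db.relative_position_of(m.spacer_id) for m in by_host[host]
        )
        for host in tied
    }
    winner = min(tied, key=lambda h: (best_pos[h], h))
    runners = [h for h in tied if h != winner and best_pos[h] == best_pos[winner]]
    if runners:
        logger.warning(
            "contig %s: unresolved tie between %s at relative position %.4f; "
            "choosing lexicographically smallest host",
            contig_id,
            [winner, *runners],
            best_pos[winner],
        )
    return HostPrediction(
        contig_id=contig_id,
        host_id=winner,
        criterion=3,
        n_matches=len(by_host[winner]),
        n_nonoverlapping=best,
        best_relative_position=best_pos[winner],
    )


def predict_all(
    matches: Iterable[SpacerMatch], spacer_db: SpacerDatabase
) -> list[HostPrediction]:
    """Group matches per contig and call a host for each; contigs without
    matches are simply absent (they become NA downstream)."""
    by_contig: dict[str, list[SpacerMatch]] = {}
    for m in matches:
        by_contig.setdefault(m.contig_id, []).append(m)
    return [
        assign_host(by_contig[cid], spacer_db) for cid in sorted(by_contig)
    ]


def candidate_hosts(matches: Iterable[SpacerMatch]) -> dict[str, list[str]]:
    """Simple-mode output: every candidate host per contig, no criteria."""
    by_contig: dict[str, set[str]] = {}
    for m in matches:
        by_contig.setdefault(m.contig_id, set()).add(m.host_id)
    return {cid: sorted(hosts) for cid, hosts in sorted(by_contig.items())}


def predictions_to_frame(predictions: Iterable[HostPrediction]) -> pd.DataFrame:
    rows = [
        (
            p.contig_id,
            p.host_id,
            p.criterion,
            p.n_matches,
            p.n_nonoverlapping,
            p.best_relative_position,
        )
        for p in predictions
    ]
    return pd.DataFrame(rows, columns=PREDICTION_COLUMNS)


def write_predictions_tsv(predictions: Iterable[HostPrediction], out) -> None:
    """Tab-separated prediction table with a header row; inapplicable
    criterion statistics are left empty."""
    predictions_to_frame(predictions).to_csv(out, sep="\t", index=False)


def read_predictions_tsv(source) -> pd.DataFrame:
    frame = pd.read_csv(source, sep="\t")
    missing = set(PREDICTION_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"prediction table lacks columns {sorted(missing)}")
    return frame
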