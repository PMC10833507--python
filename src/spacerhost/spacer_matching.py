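"""Spacer-to-viral-contig matching.

A spacer hit links a viral contig (carrying the protospacer) to a candidate
host (carrying the spacer). Hits are produced either natively — an exhaustive
ungapped sliding-window scan of both contig strands — or by ingesting
precomputed BLASTN hits in 12-column tabular format.

Local aligners can truncate a hit, silently dropping mismatching spacer ends;
the *true mismatch* count charges every unaligned spacer base as a mismatch:

    true_mismatches = spacer_length - alignment_length + reported_mismatches

The standard filter keeps only ungapped hits with at most 2 true mismatches.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .crispr_arrays import (
    Spacer,
    SpacerDatabase,
    host_of_spacer_id,
    load_sequences,
)

logger = logging.getLogger(__name__)

BLAST6_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]

DEFAULT_MAX_TRUE_MISMATCHES = 2


def true_mismatch_count(
    spacer_length: int, alignment_length: int, raw_mismatches: int
) -> int:
    """Mismatches charged to a hit after penalizing truncation.

    Every spacer base left out of the alignment counts as a mismatch on top
    of the mismatches reported within the aligned region.
    """
    if min(spacer_length, alignment_length, raw_mismatches) < 0:
        raise ValueError("lengths and mismatch counts must be non-negative")
    if alignment_length > spacer_length:
        raise ValueError(
            f"alignment length {alignment_length} exceeds spacer length "
            f"{spacer_length}: inconsistent hit"
        )
    return spacer_length - alignment_length + raw_mismatches


@dataclass(frozen=True)
class SpacerMatch:
    """One ungapped-or-BLAST hit of a spacer on a viral contig.

    Contig coordinates are 1-based inclusive on the forward strand
    (``contig_start <= contig_end``); ``strand`` records which contig strand
    carries the protospacer. ``true_mismatches`` is derived, never supplied.
    """

    spacer_id: str
    host_id: str
    contig_id: str
    contig_start: int
    contig_end: int
    strand: str  # "+" or "-"
    alignment_length: int
    raw_mismatches: int
    gap_opens: int
    spacer_length: int
    true_mismatches: int = field(init=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.contig_start > self.contig_end:
            raise ValueError("contig_start must be <= contig_end")
        object.__setattr__(
            self,
            "true_mismatches",
            true_mismatch_count(
                self.spacer_length, self.alignment_length, self.raw_mismatches
            ),
        )
        span = self.contig_end - self.contig_start + 1
        # for gapped hits the alignment length counts gap columns, so the
        # contig span may legitimately differ; enforce only when ungapped
        if self.gap_opens == 0 and span != self.alignment_length:
            raise ValueError(
                f"ungapped hit spans {span} bp on the contig but alignment "
                f"length is {self.alignment_length}"
            )

    @property
    def interval(self) -> tuple[int, int]:
        return (self.contig_start, self.contig_end)


def _match_sort_key(m: SpacerMatch):
    return (m.contig_id, m.contig_start, m.strand, m.spacer_id)


# --------------------------------------------------------------------------
# BLAST tabular ingestion / export


def read_blast_tabular(
    source,
    spacer_db: SpacerDatabase | dict[str, Spacer],
    *,
    query_is_contig: bool = True,
) -> list[SpacerMatch]:
    """Read 12-column BLAST tabular hits into :class:`SpacerMatch` records.

    By default the query side is the viral contig and the subject side the
    spacer database (contigs searched against spacers); set
    ``query_is_contig=False`` for the opposite layout. The strand is inferred
    from coordinate order: a descending coordinate pair on either side marks
    a minus-strand hit; contig coordinates are normalized to ascending order.

    Unknown spacer ids and malformed rows are fatal (with the line number).
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    try:
        table = pd.read_csv(
            source,
            sep="\t",
            header=None,
            names=BLAST6_COLUMNS,
            comment="#",
            dtype={
                "qseqid": str,
                "sseqid": str,
                "length": "int64",
                "mismatch": "int64",
                "gapopen": "int64",
                "qstart": "int64",
                "qend": "int64",
                "sstart": "int64",
                "send": "int64",
            },
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed BLAST tabular input: {exc}") from exc

    lookup = spacer_db.spacer if isinstance(spacer_db, SpacerDatabase) else None
    matches: list[SpacerMatch] = []
    for line_no, row in enumerate(table.itertuples(index=False), start=1):
        if query_is_contig:
            contig_id, spacer_id = row.qseqid, row.sseqid
            c1, c2 = row.qstart, row.qend
            s1, s2 = row.sstart, row.send
        else:
            contig_id, spacer_id = row.sseqid, row.qseqid
            c1, c2 = row.sstart, row.send
            s1, s2 = row.qstart, row.qend
        try:
            if lookup is not None:
                spacer_length = lookup(spacer_id).length
            else:
                spacer_length = spacer_db[spacer_id].length
        except KeyError:
            raise ValueError(
                f"line {line_no}: unknown spacer id {spacer_id!r}"
            ) from None
        strand = "-" if (c1 > c2) != (s1 > s2) else "+"
        contig_start, contig_end = min(c1, c2), max(c1, c2)
        try:
            matches.append(
                SpacerMatch(
                    spacer_id=spacer_id,
                    host_id=host_of_spacer_id(spacer_id),
                    contig_id=contig_id,
                    contig_start=int(contig_start),
                    contig_end=int(contig_end),
                    strand=strand,
                    alignment_length=int(row.length),
                    raw_mismatches=int(row.mismatch),
                    gap_opens=int(row.gapopen),
                    spacer_length=spacer_length,
                )
            )
        except ValueError as exc:
            raise ValueError(f"line {line_no}: {exc}") from exc
    return matches


def write_blast_tabular(matches: Iterable[SpacerMatch], out) -> int:
    """Serialize matches to the 12-column tabular layout (query = contig).

    Minus-strand hits are written with descending spacer-side coordinates,
    mirroring BLASTN's convention. E-value and bit score are placeholders
    (the native matcher does not compute them). Returns rows written.
    """
    rows = []
    for m in matches:
        ident = 100.0 * (m.alignment_length - m.raw_mismatches) / m.alignment_length
        sstart, send = (1, m.spacer_length) if m.strand == "+" else (m.spacer_length, 1)
        rows.append(
            (
                m.contig_id,
                m.spacer_id,
                f"{ident:.3f}",
                m.alignment_length,
                m.raw_mismatches,
                m.gap_opens,
                m.contig_start,
                m.contig_end,
                sstart,
                send,
                "0.0",
                f"{2.0 * (m.alignment_length - m.raw_mismatches):.1f}",
            )
        )
    frame = pd.DataFrame(rows, columns=BLAST6_COLUMNS)
    frame.to_csv(out, sep="\t", header=False, index=False)
    return len(rows)


# --------------------------------------------------------------------------
# native matcher

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode_contig(seq: str) -> np.ndarray:
    """Contig bytes with every non-ACGT character mapped to a sentinel that
    matches nothing (including N-vs-N)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()
    acgt = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    arr[~acgt] = 0xFF
    return arr


def _encode_spacer(seq: str) -> np.ndarray:
    """Spacer bytes; N gets a sentinel distinct from the contig's so every N
    counts as a mismatch."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()
    arr[arr == ord("N")] = 0xFE
    return arr


def native_match(
    spacers: SpacerDatabase | Sequence[Spacer],
    contigs,
    max_true_mismatches: int = DEFAULT_MAX_TRUE_MISMATCHES,
) -> list[SpacerMatch]:
    """Exhaustive ungapped scan of every spacer against both contig strands.

    Emits every full-length placement with Hamming distance at most
    ``max_true_mismatches`` (N matches nothing and always counts as a
    mismatch). Placements overhanging contig ends are not considered. Output
    is sorted by (contig_id, contig_start, strand, spacer_id) so downstream
    results are reproducible.
    """
    spacer_list = (
        list(spacers.spacers.values())
        if isinstance(spacers, SpacerDatabase)
        else list(spacers)
    )
    if not spacer_list:
        raise ValueError("empty spacer database")
    seqs = load_sequences(contigs)

    # pre-encode each spacer once, both orientations
    encoded = [
        (s, _encode_spacer(s.sequence), _encode_spacer(_revcomp(s.sequence)))
        for s in spacer_list
    ]

    matches: list[SpacerMatch] = []
    for contig_id, contig_seq in seqs.items():
        contig_arr = _encode_contig(contig_seq)
        n = contig_arr.size
        for spacer, fwd, rev in encoded:
            L = fwd.size
            if L > n:
                continue
            windows = sliding_window_view(contig_arr, L)
            for strand, pattern in (("+", fwd), ("-", rev)):
                dists = (windows != pattern).sum(axis=1)
                for offset in np.nonzero(dists <= max_true_mismatches)[0]:
                    matches.append(
                        SpacerMatch(
                            spacer_id=spacer.spacer_id,
                            host_id=spacer.host_id,
                            contig_id=contig_id,
                            contig_start=int(offset) + 1,
                            contig_end=int(offset) + L,
                            strand=strand,
                            alignment_length=L,
                            raw_mismatches=int(dists[offset]),
                            gap_opens=0,
                            spacer_length=L,
                        )
                    )
    matches.sort(key=_match_sort_key)
    return matches


# --------------------------------------------------------------------------
# filtering


def filter_matches(
    matches: Iterable[SpacerMatch],
    max_true_mismatches: int = DEFAULT_MAX_TRUE_MISMATCHES,
) -> list[SpacerMatch]:
    """Keep only gapless hits with at most ``max_true_mismatches`` true
    mismatches (stable order). Idempotent."""
    return [
        m
        for m in matches
        if m.gap_opens == 0 and m.true_mismatches <= max_true_mismatches
    ]


def filter_matches_simple(
    matches: Iterable[SpacerMatch], max_raw_mismatches: int = 2
) -> list[SpacerMatch]:
    """Simple-mode filter: at most ``max_raw_mismatches`` aligner-reported
    mismatches, with no gap or truncation logic."""
    return [m for m in matches if m.raw_mismatches <= max_raw_mismatches]
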