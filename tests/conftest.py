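from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from spacerhost import (
    CrisprArray,
    Spacer,
    SpacerDatabase,
    SpacerMatch,
)
from spacerhost.crispr_arrays import make_spacer_id

#: The ten published benchmark rows: tool, (tp, fp, na), and the printed
#: (precision, sensitivity, f1) triple, over 1,046 gold virus-host pairs.
PUBLISHED_BENCHMARK_ROWS = [
    ("hostphinder", (367, 677, 2), (0.3515, 0.3509, 0.3512)),
    ("crispropendb", (259, 133, 654), (0.6607, 0.2476, 0.3602)),
    ("virhostmatcher_top30", (459, 284, 303), (0.6178, 0.4388, 0.5131)),
    ("php_refdb", (550, 451, 45), (0.5495, 0.5258, 0.5374)),
    ("virhostmatcher_top5", (604, 34, 408), (0.9467, 0.5774, 0.7173)),
    ("wish", (794, 252, 0), (0.7591, 0.7591, 0.7591)),
    ("virhostmatcher_net_strict", (829, 74, 143), (0.9181, 0.7925, 0.8507)),
    ("virhostmatcher_net", (921, 125, 0), (0.8805, 0.8805, 0.8805)),
    ("php_custom", (952, 94, 0), (0.9101, 0.9101, 0.9101)),
    ("rafah", (1001, 45, 0), (0.957, 0.957, 0.957)),
]

TOTAL_GOLD_PAIRS = 1046


def simple_spacer_db(
    hosts_positions: dict[str, list[float]], array_span: tuple[int, int] = (1000, 2000)
) -> tuple[SpacerDatabase, dict[str, list[str]]]:
    """Build a database with one forward array per host and one spacer per
    requested relative position (spacer ids returned per host)."""
    a0, a1 = array_span
    arrays, spacers, ids = [], [], {}
    for host, positions in hosts_positions.items():
        array_id = f"{host}.arr1"
        arrays.append(
            CrisprArray(
                array_id=array_id,
                host_id=host,
                replicon_id=host,
                array_start=a0,
                array_end=a1,
                orientation="forward",
            )
        )
        ids[host] = []
        for i, rel in enumerate(positions):
            start = a0 + round(rel * (a1 - a0))
            end = start + 29
            sid = make_spacer_id(host, array_id, i, host, start, end)
            spacers.append(
                Spacer(
                    spacer_id=sid,
                    array_id=array_id,
                    host_id=host,
                    replicon_id=host,
                    spacer_start=start,
                    spacer_end=end,
                    sequence="A" * 30,
                    index_in_array=i,
                )
            )
            ids[host].append(sid)
    return SpacerDatabase(arrays, spacers), ids


def make_match(
    spacer_id: str,
    host_id: str,
    contig_id: str,
    start: int,
    end: int,
    *,
    strand: str = "+",
    raw_mismatches: int = 0,
    gap_opens: int = 0,
    spacer_length: int | None = None,
    alignment_length: int | None = None,
) -> SpacerMatch:
    length = alignment_length if alignment_length is not None else end - start + 1
    return SpacerMatch(
        spacer_id=spacer_id,
        host_id=host_id,
        contig_id=contig_id,
        contig_start=start,
        contig_end=end,
        strand=strand,
        alignment_length=length,
        raw_mismatches=raw_mismatches,
        gap_opens=gap_opens,
        spacer_length=spacer_length if spacer_length is not None else length,
    )


def genus_lineage(genus: str, order: str | None = None) -> dict:
    lineage = {"domain": "Bacteria"}
    if order:
        lineage["order"] = order
    lineage["genus"] = genus
    return lineage


def inter_method_fixture() -> dict[str, dict[str, dict]]:
    """Five tools over shared contigs, reproducing the published agreement
    structure: set sizes CCDB=5, OpenDB=5, CRISPR=8, PHP=54, RaFAH=87 with
    PHP exclusive on 45 contigs and RaFAH agreeing nowhere except two
    PHP/RaFAH pairs and one CRISPR/PHP/RaFAH triple."""
    tools = ("ccdb", "crispr", "opendb", "php", "rafah")
    preds: dict[str, dict[str, dict]] = {t: {} for t in tools}
    n = 0

    def contig() -> str:
        nonlocal n
        n += 1
        return f"c{n:03d}"

    def add(members: list[str], count: int, disagree: list[str] = ()):  # noqa: B006
        for _ in range(count):
            cid = contig()
            lin = genus_lineage(f"Shared{n:03d}")
            for t in members:
                preds[t][cid] = lin
            for j, t in enumerate(disagree):
                preds[t][cid] = genus_lineage(f"Odd{n:03d}x{j}")

    add(["ccdb", "crispr"], 2)
    add(["ccdb", "crispr", "php"], 3, disagree=["rafah"])  # rafah calls, disagrees
    add(["opendb", "php"], 1)
    add(["crispr", "php"], 2)
    add(["crispr", "php", "rafah"], 1)
    add(["php", "rafah"], 2)
    add(["php"], 45)
    add(["opendb"], 4)
    add(["rafah"], 81)
    return preds
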