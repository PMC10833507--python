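"""Synthetic data generation for the full prediction and benchmarking
pipeline.

Three generators produce, with no external downloads, every input the other
modules consume:

* :func:`simulate_hosts` — host genomes carrying implanted CRISPR arrays
  (alternating repeat-spacer runs), the matching GFF3 annotation, and a
  truth table of every spacer;
* :func:`simulate_contigs` — viral contigs carrying protospacers copied
  from those spacers at controlled substitution counts and strands, plus
  gold virus-host pairs and an implant manifest;
* :func:`realize_confusion` — gold/prediction tables realizing an exact
  (TP, FP, NA) confusion triple for the benchmark scorer.

Background sequence is i.i.d. uniform over ACGT, so chance full-length
spacer hits at the default lengths (28-43 bp, at most 2 mismatches) are
astronomically unlikely. All generators are deterministic given the
configured seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .benchmark import PredictionRecord, VirusHostPair
from .crispr_arrays import make_spacer_id
from .spacer_matching import _revcomp

BASES = "ACGT"

TRUTH_COLUMNS = [
    "host_id",
    "array_id",
    "spacer_id",
    "replicon",
    "spacer_start",
    "spacer_end",
    "orientation",
    "index_in_array",
    "sequence",
]

MANIFEST_COLUMNS = [
    "contig_id",
    "spacer_id",
    "host_id",
    "position",
    "strand",
    "n_substitutions",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped defaults for a desk-scale synthetic community.

    Spacer lengths default to the 28-43 bp range observed in real CRISPR
    arrays; the repeat length (30 bp) is a typical direct-repeat size.
    """

    n_hosts: int = 10
    arrays_per_host: int = 1
    spacers_per_array: int = 6
    repeat_length: int = 30
    spacer_length_range: tuple[int, int] = (28, 43)
    n_contigs: int = 20
    implants_per_contig: int = 1
    mismatch_schedule: tuple[int, ...] = (0,)
    reverse_strand_prob: float = 0.5
    genome_length: int = 20_000
    contig_length: int = 5_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_hosts", "arrays_per_host", "spacers_per_array",
                     "repeat_length", "n_contigs", "genome_length",
                     "contig_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.implants_per_contig < 0:
            raise ValueError("implants_per_contig must be >= 0")
        if not 0.0 <= self.reverse_strand_prob <= 1.0:
            raise ValueError("reverse_strand_prob must lie in [0, 1]")
        lo, hi = self.spacer_length_range
        if not 1 <= lo <= hi <= self.contig_length:
            raise ValueError("spacer_length_range must fit within a contig")


def _random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(BASES) for _ in range(length))


@dataclass
class HostSimulation:
    genomes: dict[str, str]  # replicon id (== host id) -> sequence
    gff: str
    truth: pd.DataFrame  # one row per spacer


@dataclass
class ContigSimulation:
    contigs: dict[str, str]
    gold: pd.DataFrame  # virus_id, host_id
    manifest: pd.DataFrame


def simulate_hosts(cfg: SimulationConfig) -> HostSimulation:
    """Generate host genomes with implanted repeat-spacer arrays.

    Each host carries one replicon named after the host. Arrays are placed
    in disjoint genome blocks (fatal if an array cannot fit its block), with
    random 5'->3' orientation; reverse-oriented arrays are written to the
    genome as the reverse complement of the biological locus, exactly as an
    annotation tool reporting a minus-strand array would describe them.
    """
    rng = random.Random(cfg.seed)
    genomes: dict[str, str] = {}
    gff_lines = ["##gff-version 3"]
    truth_rows: list[tuple] = []

    width = max(3, len(str(cfg.n_hosts)))
    for h in range(cfg.n_hosts):
        host_id = f"H{h + 1:0{width}d}"
        genome = list(_random_seq(rng, cfg.genome_length))
        block = cfg.genome_length // cfg.arrays_per_host
        for a in range(cfg.arrays_per_host):
            array_id = f"{host_id}.arr{a + 1}"
            repeat = _random_seq(rng, cfg.repeat_length)
            spacer_seqs = [
                _random_seq(rng, rng.randint(*cfg.spacer_length_range))
                for _ in range(cfg.spacers_per_array)
            ]
            bio = repeat + "".join(s + repeat for s in spacer_seqs)
            alen = len(bio)
            if alen > block:
                raise ValueError(
                    f"array {array_id} ({alen} bp) exceeds its genome block "
                    f"({block} bp); increase genome_length or shrink the array"
                )
            orientation = "reverse" if rng.random() < 0.5 else "forward"
            start = a * block + rng.randint(0, block - alen) + 1  # 1-based
            end = start + alen - 1
            inserted = _revcomp(bio) if orientation == "reverse" else bio
            genome[start - 1 : start - 1 + alen] = list(inserted)

            strand = "-" if orientation == "reverse" else "+"
            gff_lines.append(
                f"{host_id}\tsim\trepeat_region\t{start}\t{end}\t.\t{strand}\t.\t"
                f"ID={array_id}"
            )
            # biological offsets of each spacer within the locus
            off = cfg.repeat_length
            for i, seq in enumerate(spacer_seqs):
                L = len(seq)
                if orientation == "forward":
                    s_start = start + off
                    s_end = s_start + L - 1
                else:
                    s_end = end - off
                    s_start = s_end - L + 1
                spacer_id = make_spacer_id(host_id, array_id, i, host_id, s_start, s_end)
                gff_lines.append(
                    f"{host_id}\tsim\tbinding_site\t{s_start}\t{s_end}\t.\t{strand}\t.\t"
                    f"ID={array_id}.sp{i};Parent={array_id}"
                )
                truth_rows.append(
                    (host_id, array_id, spacer_id, host_id, s_start, s_end,
                     orientation, i, seq)
                )
                off += L + cfg.repeat_length
        genomes[host_id] = "".join(genome)

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return HostSimulation(genomes=genomes, gff="\n".join(gff_lines) + "\n", truth=truth)


def _mutate(rng: random.Random, seq: str, n_sub: int) -> str:
    """Apply n_sub substitutions at distinct positions, never reusing a
    position and never leaving ACGT."""
    if n_sub > len(seq):
        raise ValueError(f"cannot place {n_sub} substitutions in {len(seq)} bp")
    chars = list(seq)
    for pos in rng.sample(range(len(seq)), n_sub):
        chars[pos] = rng.choice([b for b in BASES if b != chars[pos]])
    return "".join(chars)


def simulate_contigs(truth: pd.DataFrame, cfg: SimulationConfig) -> ContigSimulation:
    """Generate viral contigs with protospacers implanted from the truth
    table.

    Each contig draws all of its implants from a single randomly chosen
    host (so gold pairs are unambiguous); implant k overall takes its
    substitution count from ``mismatch_schedule`` cyclically, is reverse
    complemented with probability ``reverse_strand_prob``, and is placed at
    a position not overlapping any earlier implant (fatal after repeated
    failures).
    """
    if truth.empty:
        raise ValueError("the truth spacer table is empty")
    rng = random.Random(cfg.seed + 1_000_003)
    by_host: dict[str, list[tuple[str, str]]] = {}
    for row in truth.itertuples(index=False):
        by_host.setdefault(row.host_id, []).append((row.spacer_id, row.sequence))
    hosts = sorted(by_host)

    contigs: dict[str, str] = {}
    gold_rows: list[tuple[str, str]] = []
    manifest_rows: list[tuple] = []
    implant_counter = 0
    width = max(3, len(str(cfg.n_contigs)))
    for c in range(cfg.n_contigs):
        contig_id = f"contig{c + 1:0{width}d}"
        contig = list(_random_seq(rng, cfg.contig_length))
        host_id = rng.choice(hosts)
        pool = by_host[host_id]
        if cfg.implants_per_contig <= len(pool):
            picks = rng.sample(pool, cfg.implants_per_contig)
        else:
            picks = [rng.choice(pool) for _ in range(cfg.implants_per_contig)]
        occupied: list[tuple[int, int]] = []
        for spacer_id, seq in picks:
            n_sub = cfg.mismatch_schedule[implant_counter % len(cfg.mismatch_schedule)]
            implant_counter += 1
            mutated = _mutate(rng, seq, n_sub)
            strand = "-" if rng.random() < cfg.reverse_strand_prob else "+"
            insert = _revcomp(mutated) if strand == "-" else mutated
            L = len(insert)
            placed = None
            for _ in range(500):
                pos = rng.randint(0, cfg.contig_length - L)  # 0-based
                if all(pos + L <= s or pos >= e for s, e in occupied):
                    placed = pos
                    break
            if placed is None:
                raise ValueError(
                    f"could not place {cfg.implants_per_contig} implants "
                    f"without overlap on a {cfg.contig_length} bp contig"
                )
            occupied.append((placed, placed + L))
            contig[placed : placed + L] = list(insert)
            manifest_rows.append(
                (contig_id, spacer_id, host_id, placed + 1, strand, n_sub)
            )
        contigs[contig_id] = "".join(contig)
        gold_rows.append((contig_id, host_id))

    gold = pd.DataFrame(gold_rows, columns=["virus_id", "host_id"])
    manifest = pd.DataFrame(manifest_rows, columns=MANIFEST_COLUMNS)
    return ContigSimulation(contigs=contigs, gold=gold, manifest=manifest)


def realize_confusion(
    counts: tuple[int, int, int],
    total_pairs: int,
    seed: int = 0,
    tool: str = "tool",
) -> tuple[list[VirusHostPair], list[PredictionRecord]]:
    """Emit gold pairs and predictions scoring exactly (tp, fp, na).

    Each virus gets its own genus; TP viruses are predicted at the gold
    genus, FP viruses at a genus absent from the gold set, NA viruses get no
    prediction. Outcome labels are shuffled across viruses with ``seed``.
    """
    tp, fp, na = counts
    if min(tp, fp, na) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp + fp + na != total_pairs:
        raise ValueError(
            f"tp + fp + na = {tp + fp + na} does not equal total_pairs = {total_pairs}"
        )
    outcomes = ["tp"] * tp + ["fp"] * fp + ["na"] * na
    random.Random(seed).shuffle(outcomes)

    gold: list[VirusHostPair] = []
    predictions: list[PredictionRecord] = []
    for i, outcome in enumerate(outcomes, start=1):
        virus = f"v{i:05d}"
        genus = f"Genus{i:05d}"
        gold.append(
            VirusHostPair(
                virus_id=virus,
                host_id=f"Host{i:05d}",
                host_lineage={"domain": "Bacteria", "genus": genus},
            )
        )
        if outcome == "tp":
            predictions.append(
                PredictionRecord(
                    tool=tool,
                    virus_id=virus,
                    predicted_lineage={"domain": "Bacteria", "genus": genus},
                )
            )
        elif outcome == "fp":
            predictions.append(
                PredictionRecord(
                    tool=tool,
                    virus_id=virus,
                    predicted_lineage={"domain": "Bacteria", "genus": f"Wrong{i:05d}"},
                )
            )
    return gold, predictions


def write_fasta(sequences: Mapping[str, str], out, width: int = 60) -> None:
    """Write a {id: sequence} mapping as 60-column wrapped FASTA."""
    def _dump(fh):
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")

    if isinstance(out, (str, Path)):
        with open(out, "w") as fh:
            _dump(fh)
    else:
        _dump(out)
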