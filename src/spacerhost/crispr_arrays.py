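"""CRISPR array and spacer handling.

Parses CRISPR array annotations (GFF3, as produced by array-detection tools
such as CRISPRDetect), extracts spacer sequences with full provenance, and
computes each spacer's position relative to the array's 5' (leader) end.

Coordinates are GFF3-style 1-based inclusive throughout this module; any
conversion to Python's 0-based half-open slices happens locally and is noted
where it occurs.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Feature-type defaults for the GFF dialect written by CRISPRDetect-style
#: tools. Both are overridable because feature naming varies across versions.
DEFAULT_ARRAY_TYPE = "repeat_region"
DEFAULT_SPACER_TYPE = "binding_site"

#: Attribute keys searched (in order) for an embedded spacer sequence before
#: falling back to slicing the genome.
SEQUENCE_ATTRIBUTES = ("Note", "sequence")

VALID_BASES = frozenset("ACGTN")

#: Field separator inside spacer identifiers. Host and array identifiers may
#: not contain it, so the host is always recoverable from a hit's subject id.
ID_SEP = "|"


class DegenerateArrayError(ValueError):
    """Raised when an array has zero extent (array_end == array_start)."""


@dataclass(frozen=True)
class CrisprArray:
    """One CRISPR array (repeat-spacer locus) on a host replicon.

    ``orientation`` is the predicted 5'->3' direction of the locus: spacers
    near the leader (5') end were acquired most recently.
    """

    array_id: str
    host_id: str
    replicon_id: str
    array_start: int  # 1-based inclusive
    array_end: int  # 1-based inclusive
    orientation: str = "forward"  # forward | reverse | unknown

    def __post_init__(self) -> None:
        if ID_SEP in self.array_id or ID_SEP in self.host_id:
            raise ValueError(
                f"{ID_SEP!r} is reserved and may not appear in array/host ids: "
                f"{self.array_id!r}, {self.host_id!r}"
            )
        if self.orientation not in ("forward", "reverse", "unknown"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if self.array_start > self.array_end:
            raise ValueError(
                f"array {self.array_id}: start {self.array_start} > end {self.array_end}"
            )
        if self.array_end == self.array_start:
            raise DegenerateArrayError(
                f"array {self.array_id}: zero-length array at {self.array_start}"
            )

    @property
    def length(self) -> int:
        return self.array_end - self.array_start + 1


@dataclass(frozen=True)
class Spacer:
    """One spacer with its genomic provenance.

    ``sequence`` is the biological (locus-oriented, 5'->3') spacer sequence:
    for reverse-oriented arrays it is the reverse complement of the forward
    genome slice. ``index_in_array`` counts from the array's leader end, so
    index 0 is the most recently acquired spacer.
    """

    spacer_id: str
    array_id: str
    host_id: str
    replicon_id: str
    spacer_start: int  # 1-based inclusive, on the forward strand of the replicon
    spacer_end: int  # 1-based inclusive
    sequence: str
    index_in_array: int

    def __post_init__(self) -> None:
        if self.spacer_start > self.spacer_end:
            raise ValueError(
                f"spacer {self.spacer_id}: start {self.spacer_start} > end {self.spacer_end}"
            )
        if len(self.sequence) != self.spacer_end - self.spacer_start + 1:
            raise ValueError(
                f"spacer {self.spacer_id}: sequence length {len(self.sequence)} "
                f"!= span {self.spacer_end - self.spacer_start + 1}"
            )
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"spacer {self.spacer_id}: non-ACGTN characters {sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return self.spacer_end - self.spacer_start + 1


def make_spacer_id(
    host_id: str, array_id: str, index: int, replicon_id: str, start: int, end: int
) -> str:
    """Delimited spacer identifier: ``host|array|index|replicon:start-end``."""
    return (
        f"{host_id}{ID_SEP}{array_id}{ID_SEP}{index}"
        f"{ID_SEP}{replicon_id}:{start}-{end}"
    )


def parse_spacer_id(spacer_id: str) -> tuple[str, str, int, str, int, int]:
    """Invert :func:`make_spacer_id`; raises ``ValueError`` on malformed ids."""
    parts = spacer_id.split(ID_SEP)
    if len(parts) != 4:
        raise ValueError(f"malformed spacer id {spacer_id!r}")
    host_id, array_id, index, locus = parts
    replicon_id, _, span = locus.rpartition(":")
    lo, _, hi = span.partition("-")
    if not replicon_id or not lo or not hi:
        raise ValueError(f"malformed spacer id {spacer_id!r}")
    return host_id, array_id, int(index), replicon_id, int(lo), int(hi)


def host_of_spacer_id(spacer_id: str) -> str:
    """Recover the host identifier from a spacer id (e.g. a BLAST subject id)."""
    return parse_spacer_id(spacer_id)[0]


class SpacerDatabase:
    """Indexed collection of arrays and spacers for lookup during matching
    and host assignment."""

    def __init__(self, arrays: Iterable[CrisprArray], spacers: Iterable[Spacer]):
        self.arrays: dict[str, CrisprArray] = {}
        for a in arrays:
            if a.array_id in self.arrays:
                raise ValueError(f"duplicate array id {a.array_id!r}")
            self.arrays[a.array_id] = a
        self.spacers: dict[str, Spacer] = {}
        for s in spacers:
            if s.spacer_id in self.spacers:
                raise ValueError(f"duplicate spacer id {s.spacer_id!r}")
            if s.array_id not in self.arrays:
                raise ValueError(
                    f"spacer {s.spacer_id!r} references unknown array {s.array_id!r}"
                )
            arr = self.arrays[s.array_id]
            if not (arr.array_start <= s.spacer_start <= s.spacer_end <= arr.array_end):
                raise ValueError(
                    f"spacer {s.spacer_id!r} lies outside its array "
                    f"{arr.array_id!r} ({arr.array_start}-{arr.array_end})"
                )
            self.spacers[s.spacer_id] = s

    def __len__(self) -> int:
        return len(self.spacers)

    def spacer(self, spacer_id: str) -> Spacer:
        try:
            return self.spacers[spacer_id]
        except KeyError:
            raise KeyError(f"unknown spacer id {spacer_id!r}") from None

    def array_of(self, spacer_id: str) -> CrisprArray:
        return self.arrays[self.spacer(spacer_id).array_id]

    def spacer_length(self, spacer_id: str) -> int:
        return self.spacer(spacer_id).length

    def relative_position_of(self, spacer_id: str) -> float:
        s = self.spacer(spacer_id)
        return relative_position(s, self.arrays[s.array_id])


def relative_position(spacer: Spacer, array: CrisprArray) -> float:
    """Position of a spacer within its array, scaled to [0, 1].

    0 means closest to the 5' (leader) end, 1 closest to the 3' end. For a
    forward array this is (spacer_start - array_start) / (array_end -
    array_start); for a reverse array the coordinates are mirrored so 0 still
    denotes the biological leader end.
    """
    if spacer.array_id != array.array_id:
        raise ValueError(
            f"spacer {spacer.spacer_id} does not belong to array {array.array_id}"
        )
    extent = array.array_end - array.array_start
    if extent == 0:
        raise DegenerateArrayError(f"array {array.array_id} has zero extent")
    if array.orientation == "reverse":
        return (array.array_end - spacer.spacer_end) / extent
    return (spacer.spacer_start - array.array_start) / extent


# --------------------------------------------------------------------------
# sequence / GFF input


def load_sequences(source) -> dict[str, str]:
    """Load FASTA sequences into a plain {id: uppercase sequence} dict.

    Accepts a path, an open handle, a mapping of id -> sequence string, or an
    iterable of Bio.SeqRecord.
    """
    if isinstance(source, Mapping):
        return {k: str(v).upper() for k, v in source.items()}
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    if hasattr(source, "read"):
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(source, "fasta")}
    return {rec.id: str(rec.seq).upper() for rec in source}


def _gff_db(gff) -> gffutils.FeatureDB:
    """Build an in-memory gffutils DB from a path, handle, or GFF text."""
    if hasattr(gff, "read"):
        gff = gff.read()
    from_string = True
    if isinstance(gff, Path):
        gff, from_string = str(gff), False
    elif isinstance(gff, str) and "\n" not in gff and os.path.exists(gff):
        from_string = False
    return gffutils.create_db(
        gff,
        dbfn=":memory:",
        from_string=from_string,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )


def _feature_id(feat, fallback: str) -> str:
    for key in ("ID", "Name"):
        if key in feat.attributes and feat.attributes[key]:
            return feat.attributes[key][0]
    return fallback


def _attribute_sequence(feat) -> str | None:
    for key in SEQUENCE_ATTRIBUTES:
        vals = feat.attributes.get(key, [])
        for v in vals:
            cand = v.strip().upper()
            if cand and set(cand) <= VALID_BASES:
                return cand
    return None


def parse_crisprdetect_gff(
    gff,
    genome,
    *,
    array_type: str = DEFAULT_ARRAY_TYPE,
    spacer_type: str = DEFAULT_SPACER_TYPE,
    host_map: Mapping[str, str] | None = None,
) -> tuple[list[CrisprArray], list[Spacer]]:
    """Parse CRISPR arrays and spacers from a GFF3 annotation.

    Array features (``array_type``, default ``repeat_region``) define loci;
    spacer features (``spacer_type``, default ``binding_site``) are attached
    to their parent array via a ``Parent`` attribute when present, otherwise
    by coordinate containment on the same replicon. Spacer sequences come
    from a ``Note``/``sequence`` attribute when one holds plain nucleotides
    (assumed locus-oriented), otherwise from the genome slice, reverse
    complemented for reverse-oriented arrays.

    ``host_map`` maps replicon ids to host (genome/MAG) ids; by default each
    replicon is its own host.

    Returns ``(arrays, spacers)``; spacers are rejected with a warning when
    their coordinates fall outside the parent array or the sequence contains
    characters outside ACGTN. A replicon named in the GFF but absent from the
    genome is fatal.
    """
    seqs = load_sequences(genome)
    host_map = dict(host_map or {})
    db = _gff_db(gff)

    arrays: list[CrisprArray] = []
    arrays_by_id: dict[str, CrisprArray] = {}
    orientation_map = {"+": "forward", "-": "reverse"}
    n_auto = 0
    for feat in db.features_of_type(array_type):
        n_auto += 1
        array_id = _feature_id(feat, f"array{n_auto}")
        if feat.seqid not in seqs:
            raise ValueError(
                f"replicon {feat.seqid!r} (array {array_id}) not present in the genome FASTA"
            )
        orientation = orientation_map.get(feat.strand, "unknown")
        if orientation == "unknown":
            logger.warning(
                "array %s has no strand; assuming forward orientation", array_id
            )
        try:
            arr = CrisprArray(
                array_id=array_id,
                host_id=host_map.get(feat.seqid, feat.seqid),
                replicon_id=feat.seqid,
                array_start=feat.start,
                array_end=feat.end,
                orientation=orientation,
            )
        except DegenerateArrayError:
            logger.warning("rejecting zero-length array %s", array_id)
            continue
        arrays.append(arr)
        arrays_by_id[array_id] = arr

    # collect spacer features per array: Parent attribute wins, containment
    # is the fallback
    per_array: dict[str, list] = {a.array_id: [] for a in arrays}
    for feat in db.features_of_type(spacer_type):
        if feat.seqid not in seqs:
            raise ValueError(
                f"replicon {feat.seqid!r} (spacer feature at {feat.start}) "
                "not present in the genome FASTA"
            )
        parent_ids = feat.attributes.get("Parent", [])
        target = None
        for pid in parent_ids:
            if pid in per_array:
                target = pid
                break
        if target is None:
            for arr in arrays:
                if (
                    arr.replicon_id == feat.seqid
                    and arr.array_start <= feat.start
                    and feat.end <= arr.array_end
                ):
                    target = arr.array_id
                    break
        if target is None:
            logger.warning(
                "rejecting spacer at %s:%d-%d: no parent array contains it",
                feat.seqid,
                feat.start,
                feat.end,
            )
            continue
        arr = arrays_by_id[target]
        if not (arr.array_start <= feat.start <= feat.end <= arr.array_end):
            logger.warning(
                "rejecting spacer at %s:%d-%d: outside parent array %s (%d-%d)",
                feat.seqid,
                feat.start,
                feat.end,
                arr.array_id,
                arr.array_start,
                arr.array_end,
            )
            continue
        per_array[target].append(feat)

    spacers: list[Spacer] = []
    for arr in arrays:
        feats = sorted(per_array[arr.array_id], key=lambda f: (f.start, f.end))
        if arr.orientation == "reverse":
            feats = feats[::-1]  # leader is at array_end
        for index, feat in enumerate(feats):
            seq = _attribute_sequence(feat)
            if seq is None:
                # 1-based inclusive -> 0-based half-open slice
                seq = seqs[arr.replicon_id][feat.start - 1 : feat.end]
                if arr.orientation == "reverse":
                    seq = str(Seq(seq).reverse_complement())
            if len(seq) != feat.end - feat.start + 1:
                logger.warning(
                    "rejecting spacer at %s:%d-%d: sequence length mismatch",
                    arr.replicon_id,
                    feat.start,
                    feat.end,
                )
                continue
            sid = make_spacer_id(
                arr.host_id, arr.array_id, index, arr.replicon_id, feat.start, feat.end
            )
            try:
                spacers.append(
                    Spacer(
                        spacer_id=sid,
                        array_id=arr.array_id,
                        host_id=arr.host_id,
                        replicon_id=arr.replicon_id,
                        spacer_start=feat.start,
                        spacer_end=feat.end,
                        sequence=seq,
                        index_in_array=index,
                    )
                )
            except ValueError as exc:
                logger.warning("rejecting spacer %s: %s", sid, exc)
    logger.info("parsed %d arrays, %d spacers", len(arrays), len(spacers))
    return arrays, spacers


def write_spacer_fasta(spacers: Iterable[Spacer], out) -> int:
    """Write spacers as FASTA (60-column wrapped), one record per spacer.

    The record id is the full spacer id, so host, array, index and
    coordinates are recoverable from a BLAST subject id alone. Duplicate
    spacer ids are fatal. Returns the number of records written.
    """
    spacers = list(spacers)
    seen: set[str] = set()
    for s in spacers:
        if s.spacer_id in seen:
            raise ValueError(f"duplicate spacer id {s.spacer_id!r}")
        seen.add(s.spacer_id)
    records = [
        SeqRecord(Seq(s.sequence), id=s.spacer_id, description="") for s in spacers
    ]
    if isinstance(out, (str, Path)):
        with open(out, "w") as fh:
            return SeqIO.write(records, fh, "fasta")
    return SeqIO.write(records, out, "fasta")


def read_spacer_fasta(source) -> list[Spacer]:
    """Re-read a spacer FASTA written by :func:`write_spacer_fasta`."""
    close = False
    if isinstance(source, str) and "\n" in source:
        handle = io.StringIO(source)
    elif isinstance(source, (str, Path)):
        handle = open(source)
        close = True
    else:
        handle = source
    spacers = []
    try:
        for rec in SeqIO.parse(handle, "fasta"):
            host, array, index, replicon, start, end = parse_spacer_id(rec.id)
            spacers.append(
                Spacer(
                    spacer_id=rec.id,
                    array_id=array,
                    host_id=host,
                    replicon_id=replicon,
                    spacer_start=start,
                    spacer_end=end,
                    sequence=str(rec.seq).upper(),
                    index_in_array=index,
                )
            )
    finally:
        if close:
            handle.close()
    return spacers
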