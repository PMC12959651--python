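"""Domain types and file readers/writers.

Conventions
-----------
All coordinates are 1-based and intervals are closed on both ends, the
standard convention for protein sequence positions.  Only protein-level
deletions are handled: genomic or transcript coordinates must be mapped to
protein coordinates upstream (e.g. with TransVar or VEP) before they reach
these readers.

Variants are short (1-10 residue) sequence-retaining deletions.  Deletions
starting at position 1 are rejected because removing the initiator methionine
prevents protein synthesis, so pathogenicity prediction is meaningless there.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: maximum deletion length in residues; longer events are rejected because a
#: 30-nt in-frame genomic deletion removes at most 10 codons.
MAX_DELETION_LENGTH = 10

LABELS = ("pathogenic", "benign", "unlabeled")

_THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Xaa": "X",
}

# p.Ala5del / p.A5del and p.Ala5_Gly7del / p.A5_G7del; nothing else.
_HGVS_SINGLE = re.compile(
    r"^p\.\(?([A-Z][a-z]{2}|[A-Z])(\d+)del\)?$"
)
_HGVS_RANGE = re.compile(
    r"^p\.\(?([A-Z][a-z]{2}|[A-Z])(\d+)_([A-Z][a-z]{2}|[A-Z])(\d+)del\)?$"
)


class VariantError(ValueError):
    """A deletion variant violates its contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence under a stable identifier.

    The identifier is treated as opaque; in practice it is a UniProt
    accession or a MANE-select transcript/protein id.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DeletionVariant:
    """One sequence-retaining deletion at the protein level.

    ``start`` and ``end`` are 1-based inclusive residue positions of the
    deleted stretch.  ``deleted_seq``, when given, is validated against the
    protein sequence by :meth:`validate_against`.
    """

    protein_id: str
    start: int
    end: int
    deleted_seq: str | None = None
    label: str = "unlabeled"
    source: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise VariantError(
                f"{self.protein_id}: bad coordinates {self.start}-{self.end}"
            )
        if self.start == 1:
            raise VariantError(
                f"{self.protein_id}: deletion at position 1 removes the "
                "start codon; not predictable"
            )
        if self.length > MAX_DELETION_LENGTH:
            raise VariantError(
                f"{self.protein_id}:{self.start}-{self.end}: deletion length "
                f"{self.length} exceeds {MAX_DELETION_LENGTH}"
            )
        if self.label not in LABELS:
            raise VariantError(f"unknown label {self.label!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def variant_id(self) -> str:
        return f"{self.protein_id}:{self.start}-{self.end}"

    def validate_against(self, protein: ProteinRecord) -> None:
        """Check coordinates (and deleted_seq if present) against *protein*."""
        if self.end > protein.length:
            raise VariantError(
                f"{self.variant_id}: end beyond protein length {protein.length}"
            )
        if self.deleted_seq is not None:
            observed = protein.sequence[self.start - 1 : self.end]
            if observed != self.deleted_seq.upper():
                raise VariantError(
                    f"{self.variant_id}: deleted_seq {self.deleted_seq!r} "
                    f"does not match sequence {observed!r}"
                )


@dataclass
class AnnotationTrack:
    """Intervals of one annotation category on one protein.

    Categories are an open vocabulary (``domain``, ``repeat``, ``TM``,
    ``IDR``, ``last_exon``, ``palindrome``, secondary-structure classes,
    SwissProt region names, ...).  Intervals are 1-based closed and may
    overlap; overlap queries use their union.
    """

    protein_id: str
    category: str
    intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s, e in self.intervals:
            if s < 1 or e < s:
                raise ValueError(
                    f"{self.protein_id}/{self.category}: bad interval {s}-{e}"
                )

    def overlaps(self, start: int, end: int) -> bool:
        """True iff the closed interval [start, end] intersects any interval."""
        return any(s <= end and start <= e for s, e in self.intervals)


@dataclass
class NumericAnnotation:
    """A per-residue vector or a per-protein scalar under a name.

    Examples: per-residue conservation information content, per-residue
    solvent accessibility, a per-protein gene-age scalar.
    """

    protein_id: str
    name: str
    values: np.ndarray | float

    @property
    def is_scalar(self) -> bool:
        return np.isscalar(self.values) or np.ndim(self.values) == 0

    def check_length(self, protein: ProteinRecord) -> None:
        if not self.is_scalar and len(self.values) != protein.length:
            raise ValueError(
                f"{self.protein_id}/{self.name}: vector length "
                f"{len(self.values)} != protein length {protein.length}"
            )


@dataclass(frozen=True)
class PropertyScale:
    """An amino-acid → value map (AAindex/ProtDCal-style propensity scale)."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.values)
        if missing:
            raise ValueError(
                f"scale {self.name!r} missing amino acids {sorted(missing)}"
            )


@dataclass
class RejectedRecord:
    """A variant-table row that failed validation, with its reason."""

    row: int
    reason: str
    message: str


def _parse_hgvs_del(text: str) -> tuple[int, int, str | None]:
    """Parse an HGVS-p deletion of the forms ``p.X#del`` / ``p.X#_Y#del``.

    Returns (start, end, deleted_seq or None when only termini are implied).
    Any other HGVS form raises :class:`VariantError`.
    """
    m = _HGVS_SINGLE.match(text)
    if m:
        aa, pos = m.groups()
        one = _THREE_TO_ONE.get(aa, aa if len(aa) == 1 else None)
        if one is None:
            raise VariantError(f"unknown residue code {aa!r} in {text!r}")
        return int(pos), int(pos), one
    m = _HGVS_RANGE.match(text)
    if m:
        aa1, p1, aa2, p2 = m.groups()
        start, end = int(p1), int(p2)
        if end < start:
            raise VariantError(f"reversed range in {text!r}")
        return start, end, None
    raise VariantError(f"unsupported HGVS form {text!r} (only p.X#del / p.X#_Y#del)")


_DEFAULT_COLUMNS = {
    "protein_id": "protein_id",
    "start": "start",
    "end": "end",
    "hgvs": "hgvs_p",
    "label": "label",
    "source": "source",
}


def read_variants(
    path: str | Path,
    *,
    sep: str | None = None,
    columns: Mapping[str, str] | None = None,
    proteins: Mapping[str, ProteinRecord] | None = None,
    return_report: bool = False,
) -> list[DeletionVariant] | tuple[list[DeletionVariant], list[RejectedRecord]]:
    """Read a deletion-variant table (CSV/TSV).

    Rows carry either explicit ``start``/``end`` columns or an HGVS-p
    deletion string.  Coordinates are 1-based closed.  Invalid rows
    (malformed coordinates, length > 10, start-codon deletions) are rejected
    record-by-record with a reason; duplicate (protein_id, start, end) rows
    are collapsed to one, and duplicates with conflicting labels are dropped
    with a warning.

    Parameters
    ----------
    sep:
        Field separator; inferred from the extension when omitted
        (``.tsv`` → tab, otherwise comma).
    columns:
        Optional logical-name → file-column mapping overriding the defaults
        ``protein_id, start, end, hgvs_p, label, source``.
    proteins:
        When given, coordinates and deleted sequences are validated against
        the protein records.
    return_report:
        Also return the list of rejected rows.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    colmap = dict(_DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)

    accepted: dict[tuple[str, int, int], DeletionVariant] = {}
    conflicted: set[tuple[str, int, int]] = set()
    rejected: list[RejectedRecord] = []

    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=sep)
        if reader.fieldnames is None:
            result: list[DeletionVariant] = []
            return (result, rejected) if return_report else result
        for i, row in enumerate(reader, start=2):  # header is line 1
            try:
                variant = _row_to_variant(row, colmap)
                if proteins is not None:
                    protein = proteins.get(variant.protein_id)
                    if protein is not None:
                        variant.validate_against(protein)
            except VariantError as exc:
                reason = "length" if "exceeds" in str(exc) else (
                    "start_codon" if "start codon" in str(exc) else "malformed"
                )
                rejected.append(RejectedRecord(i, reason, str(exc)))
                continue
            key = (variant.protein_id, variant.start, variant.end)
            if key in conflicted:
                continue
            prior = accepted.get(key)
            if prior is None:
                accepted[key] = variant
            elif prior.label != variant.label:
                # conflicting labels across sources: drop the variant entirely
                logger.warning(
                    "conflicting labels for %s (%s vs %s); variant dropped",
                    variant.variant_id, prior.label, variant.label,
                )
                del accepted[key]
                conflicted.add(key)

    variants = list(accepted.values())
    return (variants, rejected) if return_report else variants


def _row_to_variant(
    row: Mapping[str, str], colmap: Mapping[str, str]
) -> DeletionVariant:
    pid = (row.get(colmap["protein_id"]) or "").strip()
    if not pid:
        raise VariantError("missing protein id")
    label = (row.get(colmap["label"]) or "unlabeled").strip().lower() or "unlabeled"
    source = (row.get(colmap["source"]) or "").strip()

    start_raw = (row.get(colmap["start"]) or "").strip()
    end_raw = (row.get(colmap["end"]) or "").strip()
    deleted_seq = None
    if start_raw and end_raw:
        try:
            start, end = int(start_raw), int(end_raw)
        except ValueError as exc:
            raise VariantError(f"non-integer coordinates {start_raw!r}/{end_raw!r}") from exc
    else:
        hgvs = (row.get(colmap["hgvs"]) or "").strip()
        if not hgvs:
            raise VariantError("row has neither start/end nor an HGVS string")
        start, end, deleted_seq = _parse_hgvs_del(hgvs)
    return DeletionVariant(pid, start, end, deleted_seq, label, source)


def write_variants(variants: Iterable[DeletionVariant], path: str | Path) -> None:
    """Write variants in the canonical CSV dialect read by :func:`read_variants`.

    Rows are sorted by (protein_id, start, end) so that
    write(read(f)) is byte-stable.
    """
    path = Path(path)
    rows = sorted(variants, key=lambda v: (v.protein_id, v.start, v.end))
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["protein_id", "start", "end", "deleted_seq", "label", "source"])
        for v in rows:
            writer.writerow(
                [v.protein_id, v.start, v.end, v.deleted_seq or "", v.label, v.source]
            )


def read_fasta(path: str | Path) -> dict[str, ProteinRecord]:
    """Read a protein FASTA into an id → :class:`ProteinRecord` map.

    Sequences are uppercased; a duplicated id raises ``ValueError``.
    """
    records: dict[str, ProteinRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        records[rec.id] = ProteinRecord(rec.id, str(rec.seq).upper())
    return records


def write_fasta(proteins: Mapping[str, ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write proteins as FASTA (fixed line width, ids sorted)."""
    with Path(path).open("w") as fh:
        for pid in sorted(proteins):
            seq = proteins[pid].sequence
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_annotation_tracks(
    path: str | Path,
    proteins: Mapping[str, ProteinRecord] | None = None,
    *,
    columns: Mapping[str, str] | None = None,
) -> list[AnnotationTrack]:
    """Read a TSV of (protein_id, category, start, end) interval rows.

    Intervals are grouped per (protein, category); overlapping intervals in
    one category are kept as-is (overlap queries use the union).  An interval
    beyond a known protein's length is an error; for unknown proteins it is
    kept with a warning.
    """
    colmap = {"protein_id": "protein_id", "category": "category",
              "start": "start", "end": "end"}
    if columns:
        colmap.update(columns)
    grouped: dict[tuple[str, str], list[tuple[int, int]]] = {}
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            pid = row[colmap["protein_id"]].strip()
            cat = row[colmap["category"]].strip()
            s, e = int(row[colmap["start"]]), int(row[colmap["end"]])
            if proteins is not None:
                protein = proteins.get(pid)
                if protein is not None and e > protein.length:
                    raise ValueError(
                        f"{pid}/{cat}: interval {s}-{e} exceeds length {protein.length}"
                    )
                if protein is None:
                    logger.warning("annotation for unknown protein %s", pid)
            grouped.setdefault((pid, cat), []).append((s, e))
    return [
        AnnotationTrack(pid, cat, sorted(iv))
        for (pid, cat), iv in sorted(grouped.items())
    ]


def write_annotation_tracks(tracks: Iterable[AnnotationTrack], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["protein_id", "category", "start", "end"])
        for track in sorted(tracks, key=lambda t: (t.protein_id, t.category)):
            for s, e in track.intervals:
                writer.writerow([track.protein_id, track.category, s, e])


def read_numeric_annotations(path: str | Path) -> list[NumericAnnotation]:
    """Read a TSV of numeric annotations.

    Columns: ``protein_id, name, values`` where ``values`` is either a single
    number (per-protein scalar) or a comma-joined per-residue vector.
    """
    out: list[NumericAnnotation] = []
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            raw = row["values"].strip()
            if "," in raw:
                values: np.ndarray | float = np.array(
                    [float(x) for x in raw.split(",")]
                )
            else:
                values = float(raw)
            out.append(NumericAnnotation(row["protein_id"].strip(), row["name"].strip(), values))
    return out


def write_numeric_annotations(
    annotations: Iterable[NumericAnnotation], path: str | Path
) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["protein_id", "name", "values"])
        for a in sorted(annotations, key=lambda a: (a.protein_id, a.name)):
            if a.is_scalar:
                raw = repr(float(a.values))
            else:
                raw = ",".join(repr(float(x)) for x in a.values)
            writer.writerow([a.protein_id, a.name, raw])


def read_property_scales(path: str | Path) -> list[PropertyScale]:
    """Read physicochemical property scales.

    Two formats are accepted:

    * the AAindex1 flat format (records delimited by ``//``, with the ``H``
      accession line and the two ``I``-introduced value rows in the standard
      ``A/L R/K ...`` column order);
    * a simple TSV with columns ``scale, amino_acid, value``.

    The format is sniffed from the first non-blank line.
    """
    path = Path(path)
    text = path.read_text()
    first = next((ln for ln in text.splitlines() if ln.strip()), "")
    if first.startswith("H ") or first.startswith("H\t"):
        return _parse_aaindex(text)
    return _parse_scale_tsv(text)


# AAindex1 value rows list the 20 amino acids in this fixed order:
# row 1 = A R N D C Q E G H I, row 2 = L K M F P S T W Y V.
_AAINDEX_ORDER = ["A", "R", "N", "D", "C", "Q", "E", "G", "H", "I",
                  "L", "K", "M", "F", "P", "S", "T", "W", "Y", "V"]


def _parse_aaindex(text: str) -> list[PropertyScale]:
    scales: list[PropertyScale] = []
    accession: str | None = None
    numbers: list[float] = []
    in_values = False
    for line in text.splitlines():
        if line.startswith("H "):
            accession = line[2:].strip()
        elif line.startswith("I "):
            in_values = True
        elif line.startswith("//"):
            if accession and len(numbers) == 20:
                scales.append(
                    PropertyScale(accession, dict(zip(_AAINDEX_ORDER, numbers)))
                )
            elif accession:
                raise ValueError(
                    f"AAindex record {accession}: expected 20 values, got {len(numbers)}"
                )
            accession, numbers, in_values = None, [], False
        elif in_values and line[:1] in (" ", "\t"):
            numbers.extend(float(tok) for tok in line.split())
        elif in_values:
            in_values = False
    return scales


def _parse_scale_tsv(text: str) -> list[PropertyScale]:
    grouped: dict[str, dict[str, float]] = {}
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    for row in reader:
        grouped.setdefault(row["scale"].strip(), {})[row["amino_acid"].strip()] = float(
            row["value"]
        )
    return [PropertyScale(name, vals) for name, vals in sorted(grouped.items())]


def read_edge_list(path: str | Path) -> list[tuple[str, str, float]]:
    """Read a protein-interaction edge list (TSV: node, node, weight).

    The weight column is optional; absent weights default to 1.0.
    """
    edges: list[tuple[str, str, float]] = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] in ("node1", "protein1"):  # header
                continue
            weight = float(parts[2]) if len(parts) > 2 else 1.0
            edges.append((parts[0], parts[1], weight))
    return edges
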