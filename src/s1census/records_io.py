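"""Reading, validating, merging and writing annotated protein records.

A record couples an amino-acid sequence with UniProt-style annotation:
protein/gene names, taxonomic lineage, phylum, and the 1-based inclusive
boundaries of its S1 domains. Sequence data travels as FASTA, annotation as
a flat TSV, so the whole pipeline is self-contained and diffable.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ValidationError

logger = logging.getLogger("s1census")

#: The 20 canonical residues plus X for ambiguous/unknown positions.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")

METADATA_COLUMNS = (
    "accession",
    "protein_name",
    "gene_name",
    "lineage",
    "phylum",
    "s1_boundaries",
    "has_extra_domains",
)


def _validate_boundaries(accession: str, boundaries, seq_len: int | None) -> None:
    prev_end = 0
    for start, end in boundaries:
        if not (1 <= start <= end):
            raise ValidationError(
                f"{accession}: boundary {start}-{end} violates 1 <= start <= end"
            )
        if start <= prev_end:
            raise ValidationError(
                f"{accession}: boundary {start}-{end} overlaps or is out of order"
            )
        if seq_len is not None and end > seq_len:
            raise ValidationError(
                f"{accession}: boundary {start}-{end} exceeds sequence length {seq_len}"
            )
        prev_end = end


def _validate_sequence(accession: str, sequence: str) -> None:
    bad = set(sequence) - VALID_RESIDUES
    if bad:
        raise ValidationError(
            f"{accession}: non-amino-acid character(s) {sorted(bad)} in sequence"
        )


@dataclass(frozen=True)
class RecordMetadata:
    """Annotation of one record, everything except the sequence itself."""

    accession: str
    protein_name: str
    gene_name: str
    lineage: tuple[str, ...]
    phylum: str
    s1_boundaries: tuple[tuple[int, int], ...]
    has_extra_domains: bool

    def __post_init__(self) -> None:
        _validate_boundaries(self.accession, self.s1_boundaries, None)


@dataclass(frozen=True)
class ProteinRecord:
    """One annotated sequence with taxonomy and S1-domain boundaries.

    Boundaries are 1-based inclusive (UniProt convention); conversion to
    Python slices happens in exactly one place, :meth:`domain_slice`.
    """

    accession: str
    protein_name: str
    gene_name: str
    lineage: tuple[str, ...]
    phylum: str
    sequence: str
    s1_boundaries: tuple[tuple[int, int], ...]
    has_extra_domains: bool

    def __post_init__(self) -> None:
        _validate_sequence(self.accession, self.sequence)
        _validate_boundaries(self.accession, self.s1_boundaries, len(self.sequence))

    @property
    def domain_count(self) -> int:
        return len(self.s1_boundaries)

    @property
    def has_ambiguous_residues(self) -> bool:
        """True when the sequence contains X; X never counts as an identity match."""
        return "X" in self.sequence

    def domain_slice(self, start: int, end: int) -> str:
        """Slice by a 1-based inclusive boundary pair."""
        return self.sequence[start - 1 : end]


@dataclass
class Dataset:
    """A list of records plus a free-text provenance tag."""

    records: list[ProteinRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.accession in seen:
                raise ValidationError(f"duplicate accession {rec.accession} in dataset")
            seen.add(rec.accession)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def accessions(self) -> list[str]:
        return [rec.accession for rec in self.records]

    def subset(self, keep: set[str], provenance: str | None = None) -> "Dataset":
        return Dataset(
            [rec for rec in self.records if rec.accession in keep],
            provenance if provenance is not None else self.provenance,
        )


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an accession -> uppercased sequence mapping.

    The accession is the first whitespace-delimited token of each header.
    Raises :class:`FormatError` for a header with no text after ``>``
    (naming the line number) and :class:`ValidationError` for residues
    outside the 20-letter alphabet plus X (naming the accession).
    """
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(">") and not line[1:].strip():
            raise FormatError(f"{path}: malformed FASTA header on line {lineno}")
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = str(rec.seq).upper()
        _validate_sequence(rec.id, seq)
        seqs[rec.id] = seq
    return seqs


def _parse_boundary_field(accession: str, text: str) -> tuple[tuple[int, int], ...]:
    if not text.strip():
        return ()
    pairs = []
    for token in text.split(","):
        token = token.strip()
        parts = token.split("-")
        if len(parts) != 2:
            raise ValidationError(
                f"{accession}: unparsable boundary token {token!r}"
            )
        try:
            start, end = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise ValidationError(
                f"{accession}: unparsable boundary token {token!r}"
            ) from exc
        pairs.append((start, end))
    return tuple(pairs)


def _parse_bool(accession: str, text: str) -> bool:
    lowered = text.strip().lower()
    if lowered == "true":
        return True
    if lowered == "false":
        return False
    raise ValidationError(
        f"{accession}: has_extra_domains must be 'true' or 'false', got {text!r}"
    )


def read_metadata(path) -> list[RecordMetadata]:
    """Read the annotation TSV into partial records (all fields but sequence)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [col for col in METADATA_COLUMNS if col not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata column(s) {missing}")
    metas = []
    for row in df.itertuples(index=False):
        acc = row.accession
        lineage = tuple(t.strip() for t in row.lineage.split(";") if t.strip())
        metas.append(
            RecordMetadata(
                accession=acc,
                protein_name=row.protein_name,
                gene_name=row.gene_name,
                lineage=lineage,
                phylum=row.phylum,
                s1_boundaries=_parse_boundary_field(acc, row.s1_boundaries),
                has_extra_domains=_parse_bool(acc, row.has_extra_domains),
            )
        )
    return metas


def merge(seqs: dict[str, str], meta: list[RecordMetadata], provenance: str = "") -> Dataset:
    """Join sequences with annotation on accession.

    Only accessions present in both inputs survive; the number dropped from
    each side is logged. Boundaries are re-validated against the actual
    sequence length (a :class:`ValidationError` names the offending record).
    """
    meta_by_acc = {m.accession: m for m in meta}
    records = []
    for m in meta:  # metadata order makes the merge deterministic
        seq = seqs.get(m.accession)
        if seq is None:
            continue
        records.append(
            ProteinRecord(
                accession=m.accession,
                protein_name=m.protein_name,
                gene_name=m.gene_name,
                lineage=m.lineage,
                phylum=m.phylum,
                sequence=seq,
                s1_boundaries=m.s1_boundaries,
                has_extra_domains=m.has_extra_domains,
            )
        )
    n_seq_only = len(set(seqs) - set(meta_by_acc))
    n_meta_only = len(set(meta_by_acc) - set(seqs))
    if n_seq_only or n_meta_only:
        logger.info(
            "merge dropped %d sequence-only and %d metadata-only accessions",
            n_seq_only,
            n_meta_only,
        )
    return Dataset(records, provenance)


def write_dataset(ds: Dataset, fasta_path, meta_path) -> None:
    """Write a dataset as FASTA + metadata TSV; round-trips through read/merge."""
    seq_records = [
        SeqRecord(Seq(rec.sequence), id=rec.accession, description="")
        for rec in ds.records
    ]
    with open(fasta_path, "w", encoding="utf-8") as fh:
        SeqIO.write(seq_records, fh, "fasta")
    rows = [
        {
            "accession": rec.accession,
            "protein_name": rec.protein_name,
            "gene_name": rec.gene_name,
            "lineage": ";".join(rec.lineage),
            "phylum": rec.phylum,
            "s1_boundaries": ",".join(f"{s}-{e}" for s, e in rec.s1_boundaries),
            "has_extra_domains": "true" if rec.has_extra_domains else "false",
        }
        for rec in ds.records
    ]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(
        meta_path, sep="\t", index=False
    )


def read_dataset(fasta_path, meta_path, provenance: str = "") -> Dataset:
    """Convenience composition: read FASTA + TSV and merge."""
    return merge(read_fasta(fasta_path), read_metadata(meta_path), provenance)


def with_metadata(rec: ProteinRecord, **changes) -> ProteinRecord:
    """Return a copy of *rec* with the given fields replaced (revalidated)."""
    return replace(rec, **changes)
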