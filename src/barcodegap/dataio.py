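"""Reading, validation and assembly of barcode datasets.

A barcode dataset couples COI sequences (FASTA) with a specimen metadata
table (TSV) keyed by specimen id.  Sequences may be of mixed length (e.g. a
650-bp 5' fragment alongside the full 1800-bp gene); downstream distance
computation handles this by pairwise deletion, so no global trimming happens
at read time.  IUPAC ambiguity codes are kept verbatim and only excluded
site-by-site when distances are computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger("barcodegap")

IUPAC_CODES = set("ACGTRYSWKMBDHVN-")

#: Region set used in the original survey; passed to :func:`read_metadata`
#: when region validation is wanted.
DEFAULT_REGIONS = (
    "Raja Ampat",
    "Vogelkop",
    "Bomberai",
    "Lengguru",
    "South New Guinea",
    "North New Guinea",
    "Australia",
)

UNASSIGNED = "unassigned"


class BarcodeError(ValueError):
    """Malformed input (FASTA/metadata) or an impossible dataset."""


@dataclass(frozen=True)
class SequenceRecord:
    """One barcode sequence: a specimen id plus an uppercase nucleotide string."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise BarcodeError("sequence record with empty id")
        if not self.seq:
            raise BarcodeError(f"sequence record {self.id!r} has empty sequence")
        bad = set(self.seq) - IUPAC_CODES
        if bad:
            raise BarcodeError(
                f"sequence {self.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class SpecimenMetadata:
    """Taxonomic and geographic annotation for one specimen."""

    id: str
    species: str
    genus: str
    family: str = UNASSIGNED
    order: str = UNASSIGNED
    clade: str = UNASSIGNED
    locality: str = UNASSIGNED
    region: str = UNASSIGNED


@dataclass
class BarcodeDataset:
    """Joined sequences + metadata; the unit every analysis stage consumes."""

    records: list[SequenceRecord]
    meta: list[SpecimenMetadata]
    alignment_mode: str = "prealigned"  # or "length-trimmed"

    def __post_init__(self) -> None:
        rec_ids = [r.id for r in self.records]
        meta_ids = [m.id for m in self.meta]
        if sorted(rec_ids) != sorted(meta_ids):
            raise BarcodeError("records and metadata ids do not match one-to-one")
        if len(self.records) < 2:
            raise BarcodeError("a dataset needs at least 2 records")
        # keep metadata in record order
        by_id = {m.id: m for m in self.meta}
        self.meta = [by_id[r.id] for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def meta_frame(self) -> pd.DataFrame:
        """Metadata as a DataFrame indexed by specimen id, in record order."""
        return pd.DataFrame([vars(m) for m in self.meta]).set_index("id")


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA into normalized records (uppercased, U→T).

    Raises :class:`BarcodeError` on duplicate ids or empty sequences, naming
    the offending entry.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if not entry.id:
            raise BarcodeError(f"{path}: entry with empty header")
        if entry.id in seen:
            raise BarcodeError(f"{path}: duplicate sequence id {entry.id!r}")
        seen.add(entry.id)
        seq = _normalize(str(entry.seq))
        if not seq:
            raise BarcodeError(f"{path}: entry {entry.id!r} has an empty sequence")
        records.append(SequenceRecord(id=entry.id, seq=seq))
    if not records:
        raise BarcodeError(f"{path}: no FASTA entries found")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA (plain headers, one record per entry)."""
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


_META_REQUIRED = ("id", "species", "genus")
_META_OPTIONAL = ("family", "order", "clade", "locality", "region")


def read_metadata(
    path: str | Path, regions: tuple[str, ...] | None = None
) -> list[SpecimenMetadata]:
    """Read the specimen metadata TSV.

    The header must contain at least ``id``, ``species``, ``genus`` (and
    ``region`` if region validation is requested via *regions*).  Missing
    optional columns (family, order, clade, locality, region) are marked
    ``unassigned``.  Taxonomy must be nested: a species under two genera, a
    genus under two families, or a family under two orders is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna(UNASSIGNED)
    for col in _META_REQUIRED:
        if col not in df.columns:
            raise BarcodeError(f"{path}: metadata header lacks required column {col!r}")
    for col in _META_OPTIONAL:
        if col not in df.columns:
            df[col] = UNASSIGNED
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise BarcodeError(f"{path}: duplicate specimen ids {dups}")

    conflicts = []
    for child, parent in (("species", "genus"), ("genus", "family"), ("family", "order")):
        sub = df[df[parent] != UNASSIGNED]
        counts = sub.groupby(child)[parent].nunique()
        for name in counts[counts > 1].index:
            parents = sorted(sub.loc[sub[child] == name, parent].unique())
            conflicts.append(f"{child} {name!r} under {parent}s {parents}")
    if conflicts:
        raise BarcodeError(f"{path}: non-nested taxonomy: " + "; ".join(conflicts))

    if regions is not None:
        bad = sorted(set(df["region"]) - set(regions) - {UNASSIGNED})
        if bad:
            raise BarcodeError(f"{path}: regions outside the configured set: {bad}")

    return [
        SpecimenMetadata(
            id=row["id"],
            species=row["species"],
            genus=row["genus"],
            family=row["family"],
            order=row["order"],
            clade=row["clade"],
            locality=row["locality"],
            region=row["region"],
        )
        for row in df.to_dict("records")
    ]


def write_metadata(meta: list[SpecimenMetadata], path: str | Path) -> None:
    """Write metadata rows as the TSV :func:`read_metadata` reads."""
    df = pd.DataFrame([vars(m) for m in meta])
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


@dataclass
class CodingValidation:
    """Report from :func:`validate_coding`: per-record stop codons and gaps."""

    internal_stops: dict[str, list[int]] = field(default_factory=dict)
    gap_bearing: list[str] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not self.internal_stops and not self.gap_bearing


def validate_coding(
    records: list[SequenceRecord],
    frame: int = 0,
    code: int = 2,
) -> CodingValidation:
    """Check records for internal stop codons and indel (gap) characters.

    Protein-coding barcodes from functional mitochondrial genes should show
    neither.  *code* is an NCBI genetic-code table id (default 2, vertebrate
    mitochondrial).  A stop codon in the final (possibly partial) codon
    position is a legitimate terminus and is not flagged.  Report-only: never
    raises.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    stops = set(CodonTable.unambiguous_dna_by_id[code].stop_codons)
    report = CodingValidation()
    for rec in records:
        if "-" in rec.seq:
            report.gap_bearing.append(rec.id)
        coding = rec.seq[frame:]
        n_codons = len(coding) // 3
        hit = [
            frame + 3 * k
            for k in range(n_codons - 1)  # last full codon may be a terminus
            if coding[3 * k : 3 * k + 3] in stops
        ]
        if hit:
            report.internal_stops[rec.id] = hit
    return report


def assemble_dataset(
    records: list[SequenceRecord],
    meta: list[SpecimenMetadata],
    alignment_mode: str = "prealigned",
) -> BarcodeDataset:
    """Inner-join sequences and metadata on specimen id.

    Records lacking metadata (and vice versa) are dropped with a warning;
    fewer than 2 joined records is an error.
    """
    meta_by_id = {m.id: m for m in meta}
    joined_records = [r for r in records if r.id in meta_by_id]
    dropped_records = [r.id for r in records if r.id not in meta_by_id]
    rec_ids = {r.id for r in joined_records}
    dropped_meta = [m.id for m in meta if m.id not in rec_ids]
    if dropped_records:
        logger.warning("%d sequence(s) lack metadata: %s", len(dropped_records), dropped_records)
    if dropped_meta:
        logger.warning("%d metadata row(s) lack sequences: %s", len(dropped_meta), dropped_meta)
    if len(joined_records) < 2:
        raise BarcodeError(
            f"joined dataset has {len(joined_records)} record(s); need at least 2"
        )
    joined_meta = [meta_by_id[r.id] for r in joined_records]
    return BarcodeDataset(records=joined_records, meta=joined_meta, alignment_mode=alignment_mode)
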