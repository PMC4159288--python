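"""Reading, validating, filtering and summarising barcode libraries.

A *barcode library* is an aligned FASTA of COI-5P sequences plus a
tab-separated metadata table assigning each specimen to a species, genus
and family.  All downstream analyses (distances, trees, networks, gap
partitioning) consume the validated :class:`BarcodeLibrary`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import AMBIGUITY, IUPAC_DNA, encode_matrix, informative_length

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ("specimen_id", "species", "genus", "family")


class LibraryError(ValueError):
    """Raised when a library violates a structural invariant."""


@dataclass(frozen=True)
class BarcodeRecord:
    """One specimen: an identifier, taxonomy labels and an aligned sequence."""

    specimen_id: str
    species: str
    genus: str
    family: str
    sequence: str

    def informative_length(self) -> int:
        return informative_length(self.sequence)


@dataclass
class BarcodeLibrary:
    """An ordered collection of aligned, validated barcode records."""

    records: list[BarcodeRecord]
    alignment_length: int = field(default=0)

    def __post_init__(self) -> None:
        if self.records and self.alignment_length == 0:
            self.alignment_length = len(self.records[0].sequence)
        validate_records(self.records, self.alignment_length)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.specimen_id for r in self.records]

    @property
    def species_labels(self) -> dict[str, str]:
        return {r.specimen_id: r.species for r in self.records}

    @property
    def genus_labels(self) -> dict[str, str]:
        return {r.specimen_id: r.genus for r in self.records}

    @property
    def family_labels(self) -> dict[str, str]:
        return {r.specimen_id: r.family for r in self.records}

    def encoded(self) -> np.ndarray:
        """``(n, L)`` uint8 matrix (A=0..T=3, everything else 4)."""
        return encode_matrix([r.sequence for r in self.records])

    def subset(self, specimen_ids) -> "BarcodeLibrary":
        """Sub-library containing the given specimens, original order kept."""
        wanted = set(specimen_ids)
        missing = wanted - set(self.ids)
        if missing:
            raise LibraryError(f"unknown specimen ids: {sorted(missing)}")
        recs = [r for r in self.records if r.specimen_id in wanted]
        return BarcodeLibrary(recs, self.alignment_length)

    def subset_species(self, species_names) -> "BarcodeLibrary":
        wanted = set(species_names)
        recs = [r for r in self.records if r.species in wanted]
        if not recs:
            raise LibraryError(f"no specimens for species {sorted(wanted)}")
        return BarcodeLibrary(recs, self.alignment_length)

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.specimen_id, r.species, r.genus, r.family) for r in self.records],
            columns=list(METADATA_COLUMNS),
        )


@dataclass(frozen=True)
class CompositionSummary:
    """Mean base composition over the unambiguous positions of a library."""

    freq_A: float
    freq_C: float
    freq_G: float
    freq_T: float
    at_content: float
    n_sequences: int
    length_min: int
    length_max: int


def validate_records(records: list[BarcodeRecord], alignment_length: int) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.specimen_id in seen:
            raise LibraryError(f"duplicate specimen_id: {rec.specimen_id!r}")
        seen.add(rec.specimen_id)
        if len(rec.sequence) != alignment_length:
            raise LibraryError(
                f"{rec.specimen_id}: sequence length {len(rec.sequence)} != "
                f"alignment length {alignment_length}; align the input to a "
                "common coordinate frame first"
            )
        for pos, ch in enumerate(rec.sequence):
            if ch not in IUPAC_DNA:
                raise LibraryError(
                    f"{rec.specimen_id}: illegal character {ch!r} at "
                    f"alignment column {pos + 1}"
                )


def read_library(
    fasta_path,
    metadata_path,
    column_map: dict[str, str] | None = None,
) -> BarcodeLibrary:
    """Read and validate a FASTA + TSV metadata pair.

    Parameters
    ----------
    fasta_path, metadata_path
        Aligned FASTA and a tab-separated table with a header row providing
        ``specimen_id``, ``species``, ``genus`` and ``family``.
    column_map
        Optional mapping from our canonical column names to the names used
        in the metadata file (e.g. a BOLD-style export:
        ``{"specimen_id": "Sample ID", "species": "Species"}``).

    FASTA identifiers must resolve 1:1 against the metadata; orphans on
    either side are a hard error.
    """
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str).fillna("")
    if column_map:
        meta = meta.rename(columns={v: k for k, v in column_map.items()})
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise LibraryError(f"metadata missing columns: {missing_cols}")
    if meta["specimen_id"].duplicated().any():
        dup = meta.loc[meta["specimen_id"].duplicated(), "specimen_id"].iloc[0]
        raise LibraryError(f"duplicate specimen_id: {dup!r}")
    rows = meta.set_index("specimen_id")

    seqs: dict[str, str] = {}
    order: list[str] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise LibraryError(f"duplicate specimen_id: {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
        order.append(rec.id)

    fasta_orphans = [i for i in order if i not in rows.index]
    meta_orphans = [i for i in rows.index if i not in seqs]
    if fasta_orphans or meta_orphans:
        raise LibraryError(
            "FASTA/metadata mismatch; FASTA records without metadata: "
            f"{fasta_orphans}; metadata rows without FASTA: {meta_orphans}"
        )

    records = []
    for sid in order:
        row = rows.loc[sid]
        for col in ("species", "genus", "family"):
            if not str(row[col]).strip():
                raise LibraryError(f"{sid}: empty {col!r} in metadata")
        records.append(
            BarcodeRecord(
                specimen_id=sid,
                species=str(row["species"]),
                genus=str(row["genus"]),
                family=str(row["family"]),
                sequence=seqs[sid],
            )
        )
    return BarcodeLibrary(records)


def write_library(lib: BarcodeLibrary, fasta_path, metadata_path) -> None:
    """Write a library back to the FASTA + TSV dialect :func:`read_library` accepts."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.specimen_id, description="")
        for r in lib.records
    ]
    Path(fasta_path).parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write(seq_records, str(fasta_path), "fasta")
    lib.metadata_frame().to_csv(metadata_path, sep="\t", index=False)


def filter_min_length(lib: BarcodeLibrary, min_bases: int = 401) -> BarcodeLibrary:
    """Keep records whose informative (non-gap, non-N) length is >= ``min_bases``.

    The default of 401 implements the ">400 base pairs" inclusion rule:
    a 402-base fragment is kept, a 400-base fragment is dropped.
    """
    if min_bases < 1:
        raise ValueError("min_bases must be >= 1")
    kept = [r for r in lib.records if r.informative_length() >= min_bases]
    if not kept:
        logger.warning(
            "filter_min_length(min_bases=%d) removed every record", min_bases
        )
        return BarcodeLibrary([], lib.alignment_length)
    dropped = len(lib.records) - len(kept)
    if dropped:
        logger.info("filter_min_length: dropped %d short records", dropped)
    return BarcodeLibrary(kept, lib.alignment_length)


def composition_summary(lib: BarcodeLibrary, pooled: bool = False) -> CompositionSummary:
    """Base composition over unambiguous A/C/G/T positions.

    By default each sequence contributes its own frequency vector and the
    vectors are averaged with equal weight per sequence (the convention used
    by barcode-database summary tools); ``pooled=True`` instead pools raw
    base counts over all sequences.  Sequences with zero unambiguous
    positions are excluded with a warning.
    """
    if not len(lib):
        raise LibraryError("composition of an empty library is undefined")
    per_seq = []
    counts_total = np.zeros(4)
    lengths = []
    for rec in lib.records:
        seq = rec.sequence
        counts = np.array([seq.count(b) for b in "ACGT"], dtype=float)
        total = counts.sum()
        lengths.append(rec.informative_length())
        if total == 0:
            logger.warning(
                "%s has no unambiguous bases; excluded from composition",
                rec.specimen_id,
            )
            continue
        per_seq.append(counts / total)
        counts_total += counts
    if not per_seq:
        raise LibraryError("no sequence with unambiguous bases")
    freqs = counts_total / counts_total.sum() if pooled else np.mean(per_seq, axis=0)
    return CompositionSummary(
        freq_A=float(freqs[0]),
        freq_C=float(freqs[1]),
        freq_G=float(freqs[2]),
        freq_T=float(freqs[3]),
        at_content=float(freqs[0] + freqs[3]),
        n_sequences=len(lib),
        length_min=int(min(lengths)),
        length_max=int(max(lengths)),
    )
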