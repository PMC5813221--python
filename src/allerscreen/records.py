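"""Protein records and the allergen/toxin database.

Sequences are plain strings over the 20 standard amino acids plus the
ambiguity codes X, B, Z and U.  Ambiguity codes are retained but are never
counted as identities downstream — a conservative choice for a safety screen.
Database curation metadata (allergen name, status, keyword tags, exposure
route) lives in a tab-delimited sidecar file joined to the FASTA on id.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: Residue codes accepted but never counted as identities: unknown (X),
#: Asx (B), Glx (Z) and selenocysteine (U).
AMBIGUITY_CODES = frozenset("XBZU")
VALID_RESIDUES = STANDARD_AA | AMBIGUITY_CODES

VALID_STATUS = frozenset({"iuis", "putative", "unassigned"})
VALID_TAGS = frozenset({"allergen", "toxin", "toxic"})
VALID_ROUTES = frozenset({"food", "airway", "contact", "unknown"})

# IUIS-style label: 3-letter genus, >=1-letter species, space, number with an
# optional isoform suffix, e.g. "Sal k 3" or "Der f 25.0101".
_ALLERGEN_NAME_RE = re.compile(r"^[A-Z][a-z]{2} [a-z]+ \d+(\.\d+)?$")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with identifier and organism metadata."""

    id: str
    sequence: str
    description: str = ""
    organism: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("ProteinRecord id must be non-empty")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 1:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        bad = set(seq) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal residue character(s) "
                f"{sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AllergenEntry:
    """A database record: sequence plus curation metadata.

    ``status`` distinguishes IUIS-listed allergens from putative and
    unassigned ones; ``tags`` are the keyword limits used in database triage
    ("allergen", "toxin", "toxic"); ``route`` is the exposure route when known.
    """

    record: ProteinRecord
    allergen_name: str = ""
    source_taxon: str = ""
    status: str = "unassigned"
    tags: frozenset[str] = field(default_factory=frozenset)
    route: str | None = None

    def __post_init__(self) -> None:
        if self.status not in VALID_STATUS:
            raise ValueError(
                f"entry {self.record.id!r}: unknown status {self.status!r} "
                f"(expected one of {sorted(VALID_STATUS)})"
            )
        tags = frozenset(self.tags)
        object.__setattr__(self, "tags", tags)
        bad = tags - VALID_TAGS
        if bad:
            raise ValueError(
                f"entry {self.record.id!r}: unknown tag(s) {sorted(bad)!r}"
            )
        if not tags:
            raise ValueError(
                f"entry {self.record.id!r}: database entries must carry at "
                "least one keyword tag"
            )
        if self.route is not None and self.route not in VALID_ROUTES:
            raise ValueError(
                f"entry {self.record.id!r}: unknown route {self.route!r}"
            )
        if self.allergen_name and not _ALLERGEN_NAME_RE.match(self.allergen_name):
            raise ValueError(
                f"entry {self.record.id!r}: allergen_name "
                f"{self.allergen_name!r} is not an IUIS-style label"
            )

    @property
    def id(self) -> str:
        return self.record.id

    @property
    def sequence(self) -> str:
        return self.record.sequence

    @property
    def display_name(self) -> str:
        """Allergen label for reporting; falls back to the accession."""
        return self.allergen_name or self.record.id


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    The header's first whitespace-delimited token becomes the id, the
    remainder the description.  Sequences are uppercased.  An empty file
    yields an empty list with a logged warning; illegal residues raise with
    the offending entry named.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ValueError(f"{path}: FASTA entry with empty header")
        desc = rec.description
        # SeqIO's description echoes the id as the first token.
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        records.append(
            ProteinRecord(id=rec.id, sequence=str(rec.seq), description=desc)
        )
    if not records:
        logger.warning("FASTA file %s contained no sequences", path)
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    """Write records as standard FASTA, 60 residues per line."""
    if not records:
        raise ValueError("write_fasta: record list must be non-empty")
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(seqs, handle, "fasta")


def write_metadata(entries: Sequence[AllergenEntry], path: str | Path) -> None:
    """Write the tab-delimited metadata sidecar for a list of entries."""
    rows = [
        {
            "id": e.record.id,
            "allergen_name": e.allergen_name,
            "source_taxon": e.source_taxon,
            "status": e.status,
            "tags": ",".join(sorted(e.tags)),
            "route": e.route or "",
        }
        for e in entries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def save_database(entries: Sequence[AllergenEntry], fasta_path: str | Path,
                  metadata_path: str | Path) -> None:
    write_fasta([e.record for e in entries], fasta_path)
    write_metadata(entries, metadata_path)


def load_database(fasta_path: str | Path,
                  metadata_path: str | Path) -> list[AllergenEntry]:
    """Join FASTA sequences with the metadata sidecar into AllergenEntry list.

    Every metadata row must reference a FASTA id and vice versa; duplicate
    ids on either side, unknown statuses and unknown tags all raise.
    Entries are returned in FASTA order.
    """
    records = read_fasta(fasta_path)
    by_id = {r.id: r for r in records}

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str).fillna("")
    required = {"id", "status", "tags"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise ValueError(
            f"{metadata_path}: missing metadata column(s) {sorted(missing_cols)}"
        )
    if meta["id"].duplicated().any():
        dups = sorted(meta.loc[meta["id"].duplicated(), "id"])
        raise ValueError(f"{metadata_path}: duplicate metadata id(s) {dups}")

    meta_ids = set(meta["id"])
    unknown = sorted(meta_ids - set(by_id))
    if unknown:
        raise ValueError(
            f"{metadata_path}: metadata references missing FASTA id(s) {unknown}"
        )
    unreferenced = sorted(set(by_id) - meta_ids)
    if unreferenced:
        raise ValueError(
            f"{fasta_path}: FASTA record(s) without metadata row: {unreferenced}"
        )

    meta_by_id = {row["id"]: row for _, row in meta.iterrows()}
    entries = []
    for rec in records:
        row = meta_by_id[rec.id]
        tags = frozenset(t for t in row["tags"].split(",") if t)
        entries.append(
            AllergenEntry(
                record=rec,
                allergen_name=row.get("allergen_name", ""),
                source_taxon=row.get("source_taxon", ""),
                status=row["status"],
                tags=tags,
                route=row.get("route", "") or None,
            )
        )
    return entries


def filter_by_tags(entries: Iterable[AllergenEntry],
                   wanted: Iterable[str]) -> list[AllergenEntry]:
    """Keyword triage: keep entries whose tags intersect ``wanted``.

    Order is preserved; the result is always a subsequence of the input.
    """
    wanted = set(wanted)
    return [e for e in entries if e.tags & wanted]
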