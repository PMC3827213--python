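"""Sequence and catalog I/O.

Reads and writes plain FASTA (via Biopython) into :class:`SequenceRecord`
objects, and loads the packaged TSV catalogs of cyanophage and cyanobacterial
sHSP accessions.  The catalogs are offline fixtures; resolving an accession to
its sequence is an explicit, network-touching step (:func:`fetch_accessions`)
that nothing in the library calls implicitly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residues accepted in strict mode: the 20 canonical amino acids plus X
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")

PHAGE_CATALOG = "cyanophage_catalog.tsv"
HOST_CATALOG = "host_catalog.tsv"

GROUP_SYN_PHAGE = "synechococcus_phage"
GROUP_PRO_PHAGE = "prochlorococcus_phage"
GROUP_HOST = "synechococcus_host"


class SeqIOError(ValueError):
    """Malformed sequence input (bad residues, duplicate ids, empty file)."""


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence with its identity and free-text provenance."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("sequence id must be non-empty")
        if not self.residues:
            raise SeqIOError(f"sequence {self.id!r} is empty")
        if "-" in self.residues or "." in self.residues:
            raise SeqIOError(f"sequence {self.id!r} contains gap characters")

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class CatalogEntry:
    """One catalog row: an accession, its nomenclature label and group."""

    organism: str
    accession: str
    label: str
    group: str
    gene_count: int | None = None  # hosts only


def _clean_residues(raw: str, rec_id: str, strict: bool) -> str:
    residues = raw.upper()
    bad = set(residues) - VALID_RESIDUES
    if bad:
        if strict:
            raise SeqIOError(
                f"sequence {rec_id!r} contains illegal residues {sorted(bad)!r}; "
                "use strict=False to map them to X"
            )
        residues = "".join(c if c in VALID_RESIDUES else "X" for c in residues)
    return residues


def read_fasta(path: str | Path, strict: bool = True) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Residues are uppercased.  Characters outside the 20-letter alphabet plus X
    raise in strict mode (the default) and are mapped to X otherwise; motif
    semantics are undefined on ambiguity codes, so mapping is opt-in.
    Record order is preserved; duplicate ids are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SeqIOError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=_clean_residues(str(rec.seq), rec.id, strict),
                description=desc,
            )
        )
    if not records:
        raise SeqIOError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, wrap: int = 60) -> None:
    """Write records as plain FASTA, wrapped at ``wrap`` columns.

    Output is deterministic: identical records produce byte-identical files.
    """
    records = list(records)
    if not records:
        raise SeqIOError("refusing to write an empty FASTA file")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise SeqIOError("duplicate sequence ids in output records")
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, rec.length, wrap):
                fh.write(rec.residues[i : i + wrap] + "\n")


def records_to_biopython(records: Iterable[SequenceRecord]) -> list[_BioSeqRecord]:
    """Convert to Biopython records (for interop with Bio.* consumers)."""
    return [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]


# ---------------------------------------------------------------------------
# packaged catalogs
# ---------------------------------------------------------------------------

_PREFIX_TO_GROUP = (
    ("HspSP-", GROUP_SYN_PHAGE),
    ("HspPP-", GROUP_PRO_PHAGE),
    ("HspS-", GROUP_HOST),
)


def group_from_label(label: str) -> str:
    """Infer the catalog group from a nomenclature prefix (HspSP-/HspPP-/HspS-)."""
    for prefix, group in _PREFIX_TO_GROUP:
        if label.startswith(prefix):
            return group
    raise SeqIOError(f"unknown nomenclature prefix in label {label!r}")


def packaged_path(name: str) -> Path:
    """Filesystem path of a packaged data fixture."""
    return Path(str(resources.files("shspkit.data") / name))


def load_catalog(path: str | Path | None = None) -> list[CatalogEntry]:
    """Load a catalog TSV into :class:`CatalogEntry` rows.

    With ``path=None`` both packaged catalogs (phage and host) are loaded and
    concatenated.  Groups are recomputed from the nomenclature prefix and must
    agree with the file's ``group`` column; for hosts, the number of rows per
    organism must equal the recorded gene count.
    """
    if path is None:
        return load_catalog(packaged_path(PHAGE_CATALOG)) + load_catalog(
            packaged_path(HOST_CATALOG)
        )
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"organism", "accession", "label", "group"}
    if not required.issubset(df.columns):
        raise SeqIOError(f"catalog {path} lacks columns {sorted(required - set(df.columns))}")
    entries: list[CatalogEntry] = []
    for row in df.itertuples(index=False):
        if any(pd.isna(v) for v in (row.organism, row.accession, row.label, row.group)):
            raise SeqIOError(f"malformed catalog row {row!r}")
        group = group_from_label(row.label)
        if group != row.group:
            raise SeqIOError(
                f"catalog row {row.accession}: group {row.group!r} does not match label prefix"
            )
        gene_count = None
        if "gene_count" in df.columns and not pd.isna(getattr(row, "gene_count", None)):
            gene_count = int(row.gene_count)
        entries.append(
            CatalogEntry(
                organism=row.organism,
                accession=row.accession,
                label=row.label,
                group=group,
                gene_count=gene_count,
            )
        )
    accs = [e.accession for e in entries]
    if len(set(accs)) != len(accs):
        raise SeqIOError("duplicate accessions in catalog")
    # host invariant: rows per organism == recorded gene_count
    hosts = [e for e in entries if e.group == GROUP_HOST]
    per_org: dict[str, int] = {}
    for e in hosts:
        per_org[e.organism] = per_org.get(e.organism, 0) + 1
    for e in hosts:
        if e.gene_count is None or per_org[e.organism] != e.gene_count:
            raise SeqIOError(
                f"host {e.organism}: {per_org[e.organism]} accessions listed "
                f"but gene_count={e.gene_count}"
            )
    return entries


def fetch_accessions(
    accessions: Iterable[str], email: str, strict: bool = True
) -> list[SequenceRecord]:
    """Fetch protein sequences from NCBI by accession (network-touching).

    This is the only function in the package that opens a network connection;
    it is never called by the offline pipeline, tests or batch scripts.
    """
    from Bio import Entrez

    Entrez.email = email
    accessions = list(accessions)
    handle = Entrez.efetch(
        db="protein", id=",".join(accessions), rettype="fasta", retmode="text"
    )
    data = handle.read()
    handle.close()
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(io.StringIO(data), "fasta"):
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=_clean_residues(str(rec.seq), rec.id, strict),
                description=desc,
            )
        )
    return records
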