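"""Readers and writers for every external format the pipeline touches.

Covered formats: protein FASTA, plain-text unwanted-domain lists, BLAST+
12-column tabular hit files (``-outfmt 6`` dialect), InterProScan TSV, and
the tab-delimited prediction table the pipeline emits.

Conventions
-----------
* A record's id is the first whitespace-delimited token of its FASTA header,
  matching the BLAST+ seqid convention so precomputed hit files join cleanly.
* A single trailing ``*`` (stop codon) is stripped on read; an internal ``*``
  is an error, since internal stops indicate pseudogene or frame artifacts
  the user must resolve upstream.
* ``X`` (ambiguous residue) is a legal sequence character.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino acids plus X (ambiguity).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AMINO_ACIDS + "X"
_ALPHABET_SET = frozenset(ALPHABET)


class FormatError(ValueError):
    """Raised for malformed input files or records."""


@dataclass(frozen=True)
class ProteinRecord:
    """One identified amino-acid sequence.

    Parameters
    ----------
    id : str
        First whitespace-delimited token of the FASTA header; unique within
        a :class:`Proteome`.
    sequence : str
        Uppercase residues over the 20 amino acids plus ``X``.
    description : str
        Remainder of the header after the id (may be empty).
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("protein record with empty id")
        if any(c.isspace() for c in self.id):
            raise FormatError(f"protein id {self.id!r} contains whitespace")
        bad = set(self.sequence) - _ALPHABET_SET
        if bad:
            raise FormatError(
                f"record {self.id!r}: illegal sequence character(s) "
                f"{sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)


class Proteome:
    """An ordered, id-indexed collection of :class:`ProteinRecord`.

    Iteration order equals insertion (file) order; duplicate ids are an
    error, so lookups are unambiguous.
    """

    def __init__(self, records: Iterable[ProteinRecord] = ()) -> None:
        self._records: list[ProteinRecord] = []
        self._index: dict[str, ProteinRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: ProteinRecord) -> None:
        if record.id in self._index:
            raise FormatError(f"duplicate protein id {record.id!r}")
        self._records.append(record)
        self._index[record.id] = record

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._index

    def __getitem__(self, protein_id: str) -> ProteinRecord:
        return self._index[protein_id]

    def ids(self) -> list[str]:
        return [r.id for r in self._records]

    @property
    def total_residues(self) -> int:
        return sum(len(r) for r in self._records)

    def subset(self, ids: Iterable[str]) -> "Proteome":
        """Records whose id is in ``ids``, original order preserved."""
        wanted = set(ids)
        return Proteome(r for r in self._records if r.id in wanted)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Proteome):
            return NotImplemented
        return self._records == other._records

    def __repr__(self) -> str:
        return f"Proteome(n={len(self)}, residues={self.total_residues})"


@dataclass(frozen=True)
class UnwantedDomainSet:
    """Domain accessions that disqualify a candidate microProtein.

    Typically DNA-binding domain accessions: a protein still carrying one of
    these cannot be a miP by definition.
    """

    accessions: frozenset[str]

    def __contains__(self, accession: str) -> bool:
        return accession in self.accessions

    def __len__(self) -> int:
        return len(self.accessions)

    def intersects(self, domains: Iterable[str]) -> bool:
        return not self.accessions.isdisjoint(domains)


@dataclass(frozen=True)
class PredictionRecord:
    """One output row: a predicted miP with its target TFs and evidence.

    ``target_tf_ids`` and ``target_tf_lengths`` are parallel, non-empty
    lists.  ``provenance`` records which search branch produced the
    candidate: ``"tier1"`` (stringent, proteins < 550 aa) or ``"tier2"``
    (permissive + reverse rescue, proteins < 200 aa).
    """

    mip_id: str
    mip_length: int
    target_tf_ids: tuple[str, ...]
    target_tf_lengths: tuple[int, ...]
    mip_domains: tuple[str, ...]
    provenance: str

    def __post_init__(self) -> None:
        if not self.target_tf_ids:
            raise FormatError(f"prediction {self.mip_id!r} has no targets")
        if len(self.target_tf_ids) != len(self.target_tf_lengths):
            raise FormatError(
                f"prediction {self.mip_id!r}: target id/length lists "
                "are not parallel"
            )
        if self.provenance not in ("tier1", "tier2"):
            raise FormatError(
                f"prediction {self.mip_id!r}: provenance must be "
                f"'tier1' or 'tier2', got {self.provenance!r}"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> Proteome:
    """Read a protein FASTA file into a :class:`Proteome`.

    Multi-line sequences are concatenated, letters uppercased, and a single
    trailing ``*`` stripped.  Duplicate ids and residues outside the
    amino-acid alphabet are hard errors.  An empty file yields an empty
    proteome with a logged warning.
    """
    path = Path(path)
    proteome = Proteome()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        proteome.add(ProteinRecord(id=rec.id, sequence=seq, description=desc))
    if len(proteome) == 0:
        logger.warning("FASTA file %s contains no records", path)
    return proteome


def write_fasta(proteome: Proteome, path: str | Path, width: int = 60) -> None:
    """Write a proteome as FASTA, wrapping sequences at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in proteome:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Unwanted-domain list


def read_unwanted_domains(path: str | Path) -> UnwantedDomainSet:
    """Read a one-accession-per-line list; ``#`` comments and blanks allowed."""
    accessions: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.split("#", 1)[0].strip()
            if not stripped:
                continue
            if any(c.isspace() for c in stripped):
                raise FormatError(
                    f"{path}:{lineno}: accession contains whitespace: "
                    f"{stripped!r}"
                )
            accessions.add(stripped)
    return UnwantedDomainSet(frozenset(accessions))


def write_unwanted_domains(unwanted: UnwantedDomainSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for acc in sorted(unwanted.accessions):
            fh.write(acc + "\n")


# ---------------------------------------------------------------------------
# BLAST+ tabular (outfmt 6)

_BLAST_COLUMNS = 12


def read_blast_tabular(path: str | Path):
    """Parse a BLAST+ 12-column tabular hit file into ``SearchHit`` objects.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore.  When the same (query, subject) pair has
    multiple HSP lines, only the minimum-E-value one is kept.
    """
    from .homology import SearchHit  # deferred: avoids a module cycle

    best: dict[tuple[str, str], SearchHit] = {}
    order: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != _BLAST_COLUMNS:
                raise FormatError(
                    f"{path}:{lineno}: expected {_BLAST_COLUMNS} columns, "
                    f"got {len(fields)}"
                )
            qseqid, sseqid = fields[0], fields[1]
            try:
                pident = float(fields[2])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparseable field: {exc}")
            if evalue < 0:
                raise FormatError(f"{path}:{lineno}: negative E-value")
            hit = SearchHit(
                query_id=qseqid,
                subject_id=sseqid,
                raw_score=int(round(bitscore)),
                evalue=evalue,
                query_span=(qstart, qend),
                subject_span=(sstart, send),
                identity_fraction=pident / 100.0,
            )
            key = (qseqid, sseqid)
            if key not in best:
                best[key] = hit
                order.append(key)
            elif hit.evalue < best[key].evalue:
                best[key] = hit
    return [best[k] for k in order]


def write_blast_tabular(hits, path: str | Path) -> None:
    """Write ``SearchHit`` objects in the BLAST+ 12-column tabular dialect.

    The E-value is written at full precision so that replaying the file
    through :func:`read_blast_tabular` reproduces pipeline decisions
    exactly.  Mismatch and gap-open counts are not tracked by the built-in
    engine and are written as 0.
    """
    with open(path, "w") as fh:
        for h in hits:
            qs, qe = h.query_span if h.query_span else (0, 0)
            ss, se = h.subject_span if h.subject_span else (0, 0)
            alen = max(qe - qs + 1, se - ss + 1) if h.query_span else 0
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{100.0 * h.identity_fraction:.2f}",
                        str(alen),
                        "0",
                        "0",
                        str(qs),
                        str(qe),
                        str(ss),
                        str(se),
                        f"{h.evalue:.17g}",
                        str(h.raw_score),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# InterProScan TSV

_IPS_MIN_COLUMNS = 11
_IPS_ACCESSION_COLUMN = 11  # 0-based index of column 12 (InterPro accession)


def read_interproscan_tsv(path: str | Path):
    """Parse InterProScan TSV output into ``DomainHit`` objects.

    Only rows carrying an integrated InterPro accession (column 12, not
    ``-``) yield hits; member-database signatures without an integrated
    accession are skipped, since the domain filters operate on InterPro
    accessions.
    """
    from .domains import DomainHit  # deferred: avoids a module cycle

    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < _IPS_MIN_COLUMNS:
                raise FormatError(
                    f"{path}:{lineno}: expected >= {_IPS_MIN_COLUMNS} "
                    f"columns, got {len(fields)}"
                )
            if len(fields) <= _IPS_ACCESSION_COLUMN:
                logger.debug("%s:%d: no InterPro accession column", path, lineno)
                continue
            accession = fields[_IPS_ACCESSION_COLUMN]
            if accession == "-" or not accession:
                logger.debug("%s:%d: unintegrated signature skipped", path, lineno)
                continue
            span = None
            try:
                start, stop = int(fields[6]), int(fields[7])
                span = (start, stop)
            except (ValueError, IndexError):
                pass
            hits.append(DomainHit(protein_id=fields[0], domain_id=accession, span=span))
    return hits


# ---------------------------------------------------------------------------
# Prediction table

_PREDICTION_HEADER = [
    "mip_id",
    "mip_length",
    "target_tf_ids",
    "target_tf_lengths",
    "mip_domains",
    "provenance",
]
_LIST_SEP = ";"


def write_predictions(records: Sequence[PredictionRecord], path: str | Path) -> None:
    """Write predictions as a tab-delimited table, rows sorted by mip_id.

    List-valued fields are semicolon-joined; an empty domain set is written
    as ``-``.  One row per miP keeps the file greppable.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(_PREDICTION_HEADER) + "\n")
        for rec in sorted(records, key=lambda r: r.mip_id):
            domains = _LIST_SEP.join(rec.mip_domains) if rec.mip_domains else "-"
            fh.write(
                "\t".join(
                    [
                        rec.mip_id,
                        str(rec.mip_length),
                        _LIST_SEP.join(rec.target_tf_ids),
                        _LIST_SEP.join(str(x) for x in rec.target_tf_lengths),
                        domains,
                        rec.provenance,
                    ]
                )
                + "\n"
            )


def read_predictions(path: str | Path) -> list[PredictionRecord]:
    """Read a prediction table written by :func:`write_predictions`."""
    records: list[PredictionRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _PREDICTION_HEADER:
            raise FormatError(f"{path}: unexpected prediction-table header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(_PREDICTION_HEADER):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(_PREDICTION_HEADER)} "
                    f"columns, got {len(fields)}"
                )
            domains: tuple[str, ...]
            domains = () if fields[4] == "-" else tuple(fields[4].split(_LIST_SEP))
            records.append(
                PredictionRecord(
                    mip_id=fields[0],
                    mip_length=int(fields[1]),
                    target_tf_ids=tuple(fields[2].split(_LIST_SEP)),
                    target_tf_lengths=tuple(
                        int(x) for x in fields[3].split(_LIST_SEP)
                    ),
                    mip_domains=domains,
                    provenance=fields[5],
                )
            )
    return records
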