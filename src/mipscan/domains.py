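"""Domain annotation and architecture queries.

A protein's *domain architecture* is here the unordered set of domain
accessions annotated on it; the pipeline's filters are pure set operations
on architectures (intersection with the unwanted set, subset of the target
union).  Multiplicity and domain order are deliberately ignored.

Annotations come from one of two sources:

* :func:`scan` — a built-in motif scanner matching exact consensus patterns
  (with ``.`` as a single-residue wildcard) from a :class:`DomainLibrary`.
  This is the self-contained path used by the synthetic fixtures.
* :func:`mipscan.io_formats.read_interproscan_tsv` — imported InterProScan
  annotations, the path real proteomes take.

Proteins with no annotated domains have the empty architecture: they pass
the unwanted-domain filter trivially and the foreign-domain filter by the
empty-subset rule.  Degenerate domains that a motif or profile scan cannot
see (for example an HLH domain that has lost its basic residues) are
invisible here by construction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

from .io_formats import FormatError, Proteome, UnwantedDomainSet

MIN_PATTERN_LENGTH = 6


@dataclass(frozen=True)
class DomainHit:
    """One domain occurrence on one protein.

    ``span`` is a 1-based inclusive residue interval; imported annotations
    may lack it.
    """

    protein_id: str
    domain_id: str
    span: Optional[tuple[int, int]] = None


@dataclass(frozen=True)
class DomainLibrary:
    """Deterministic motif library: (accession, consensus pattern) entries.

    Patterns are exact consensus strings over the amino-acid alphabet with
    ``.`` matching any single residue; minimum length 6 keeps spurious
    matches in random flanking sequence negligible (20^-6 per position).
    """

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for domain_id, pattern in self.entries:
            if domain_id in seen:
                raise FormatError(f"duplicate domain id {domain_id!r}")
            seen.add(domain_id)
            if len(pattern) < MIN_PATTERN_LENGTH:
                raise FormatError(
                    f"pattern for {domain_id!r} shorter than "
                    f"{MIN_PATTERN_LENGTH} residues"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


@dataclass(frozen=True)
class DomainArchitecture:
    """The deduplicated, unordered domain-accession set of one protein."""

    protein_id: str
    domain_set: frozenset[str]


def _pattern_to_regex(pattern: str) -> re.Pattern[str]:
    # '.' is the wildcard; every other character matches literally.
    body = "".join("." if c == "." else re.escape(c) for c in pattern)
    return re.compile(f"(?=({body}))")  # lookahead: overlapping occurrences


def scan(proteome: Proteome, library: DomainLibrary) -> list[DomainHit]:
    """Find every occurrence of every library pattern in every sequence.

    Order is deterministic: proteome order, then library order, then
    position.  Overlapping occurrences are all reported.
    """
    if len(library) == 0:
        raise ValueError("empty domain library")
    compiled = [(d, _pattern_to_regex(p), len(p)) for d, p in library]
    hits: list[DomainHit] = []
    for rec in proteome:
        for domain_id, regex, plen in compiled:
            for m in regex.finditer(rec.sequence):
                start = m.start() + 1
                hits.append(
                    DomainHit(
                        protein_id=rec.id,
                        domain_id=domain_id,
                        span=(start, start + plen - 1),
                    )
                )
    return hits


def architecture_of(
    protein_id: str, hits: Iterable[DomainHit]
) -> DomainArchitecture:
    """Architecture of one protein from a hit collection (may be empty)."""
    return DomainArchitecture(
        protein_id=protein_id,
        domain_set=frozenset(
            h.domain_id for h in hits if h.protein_id == protein_id
        ),
    )


def architectures_from_hits(
    hits: Iterable[DomainHit],
) -> dict[str, frozenset[str]]:
    """Group hits into a protein_id → domain-set mapping."""
    out: dict[str, set[str]] = {}
    for h in hits:
        out.setdefault(h.protein_id, set()).add(h.domain_id)
    return {pid: frozenset(s) for pid, s in out.items()}


def contains_unwanted(
    arch: DomainArchitecture | frozenset[str], unwanted: UnwantedDomainSet
) -> bool:
    """True iff the architecture intersects the unwanted-domain set."""
    domain_set = arch.domain_set if isinstance(arch, DomainArchitecture) else arch
    return unwanted.intersects(domain_set)


# ---------------------------------------------------------------------------
# Library file I/O: two-column TSV (accession, pattern), '#' comments.


def read_domain_library(path: str | Path) -> DomainLibrary:
    entries: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.split("#", 1)[0].rstrip("\n").strip()
            if not stripped:
                continue
            fields = stripped.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 tab-separated columns"
                )
            entries.append((fields[0], fields[1]))
    return DomainLibrary(entries=tuple(entries))


def write_domain_library(library: DomainLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        for domain_id, pattern in library:
            fh.write(f"{domain_id}\t{pattern}\n")
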