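"""The microProtein prediction pipeline.

microProteins (miPs) are small truncated TF-like proteins that retain a
protein-protein interaction domain but have lost the DNA-binding domain
(DBD); they modulate their target transcription factors by joining or
titrating TF complexes.  Candidates are detected by homology with the TF
set, then pruned by domain and length filters:

1. *Tier 1* — search the TFs against every proteome protein shorter than
   550 aa at a stringent E-value cutoff (default 1e-7).  The 550-aa limit
   covers every characterized miP and typical interaction-domain sizes.
2. *Tier 2* — because miPs are typically under 200 aa, additionally search
   the TFs against proteins shorter than 200 aa at a permissive cutoff
   (default 0.5), then rescue only those forward hits that also hit the TF
   set in a reverse search (default cutoff 0.1); asymmetric spurious
   matches are discarded.
3. Merge both tiers, annotate domains, then filter: candidates carrying an
   unwanted (DBD) accession are removed; candidate-target pairs where the
   candidate exceeds 1.1x the target length are removed (the 10% tolerance
   admits longer linker regions); candidates carrying a domain found in
   none of their surviving targets are removed.

Boundary conventions: "shorter than 550/200" is strict (a 550-aa protein is
excluded), and "larger than 1.1 times" is strict (a candidate at exactly
1.1x its target survives).  A proteome record whose id equals a query TF id
is never a candidate.  Tier-2 targets are taken from the reverse search:
the forward hit establishes candidacy, the reverse search defines which TFs
the candidate credibly matches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from .domains import DomainHit, DomainLibrary, architectures_from_hits, scan
from .homology import (
    STAGE_REVERSE,
    STAGE_TIER1,
    STAGE_TIER2,
    BuiltinSearchBackend,
    SearchBackend,
    SearchHit,
)
from .io_formats import (
    PredictionRecord,
    ProteinRecord,
    Proteome,
    UnwantedDomainSet,
)

logger = logging.getLogger(__name__)

TIER1 = "tier1"
TIER2 = "tier2"


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable thresholds of the pipeline.

    max_mip_length : int
        Upper length bound (exclusive) for tier-1 subjects, default 550 aa.
    small_protein_length : int
        Upper length bound (exclusive) for tier-2 subjects, default 200 aa.
    tier1_cutoff, tier2_cutoff, reverse_cutoff : float
        E-value cutoffs for the stringent forward, permissive forward, and
        reverse searches (defaults 1e-7, 0.5, 0.1).
    length_ratio : float
        Candidate/target length tolerance, default 1.1 (10%).
    """

    max_mip_length: int = 550
    small_protein_length: int = 200
    tier1_cutoff: float = 1e-7
    tier2_cutoff: float = 0.5
    reverse_cutoff: float = 0.1
    length_ratio: float = 1.1

    def __post_init__(self) -> None:
        if not (0 < self.small_protein_length <= self.max_mip_length):
            raise ValueError(
                "require 0 < small_protein_length <= max_mip_length"
            )
        if not (self.tier1_cutoff <= self.tier2_cutoff):
            raise ValueError("require tier1_cutoff <= tier2_cutoff")
        if self.length_ratio < 1:
            raise ValueError("length_ratio must be >= 1")


@dataclass
class CandidateMiP:
    """A putative miP with per-target evidence.

    ``targets`` maps each credited TF id to the best (minimum) E-value of
    the evidence linking them.  ``tier`` records provenance: tier1 wins
    when a protein is found by both branches.
    """

    protein_id: str
    tier: str
    targets: dict[str, float] = field(default_factory=dict)

    def add_target(self, tf_id: str, evalue: float) -> None:
        if tf_id == self.protein_id:
            return  # self-pairing excluded
        prev = self.targets.get(tf_id)
        if prev is None or evalue < prev:
            self.targets[tf_id] = evalue


def partition_by_length(proteome: Proteome, limit: int) -> Proteome:
    """Records strictly shorter than ``limit``, original order preserved."""
    if limit <= 0:
        raise ValueError("length limit must be positive")
    return Proteome(r for r in proteome if len(r) < limit)


def _candidates_from_hits(
    hits: Iterable[SearchHit], tf_ids: frozenset[str], tier: str
) -> dict[str, CandidateMiP]:
    """Subjects become candidates; the querying TF becomes a target."""
    out: dict[str, CandidateMiP] = {}
    for h in hits:
        if h.subject_id in tf_ids:
            continue  # a record sharing an id with a query TF is never a candidate
        cand = out.setdefault(
            h.subject_id, CandidateMiP(protein_id=h.subject_id, tier=tier)
        )
        cand.add_target(h.query_id, h.evalue)
    return out


def tier1_candidates(
    tfs: Proteome,
    proteome: Proteome,
    cfg: PipelineConfig,
    backend: SearchBackend,
) -> dict[str, CandidateMiP]:
    """Stringent search of the TFs against proteins < max_mip_length."""
    if len(tfs) == 0:
        raise ValueError("empty query set")
    db = partition_by_length(proteome, cfg.max_mip_length)
    if len(db) == 0:
        return {}
    hits = backend.search_stage(tfs, db, cfg.tier1_cutoff, STAGE_TIER1)
    return _candidates_from_hits(hits, frozenset(tfs.ids()), TIER1)


def tier2_candidates(
    tfs: Proteome,
    proteome: Proteome,
    cfg: PipelineConfig,
    backend: SearchBackend,
) -> dict[str, CandidateMiP]:
    """Permissive small-protein search with reverse rescue.

    Forward: TFs vs proteins < small_protein_length at tier2_cutoff.
    Each forward-hit subject is then used as a query against the full TF
    set; subjects without a reverse hit at reverse_cutoff are discarded,
    and the surviving candidates' targets are the reverse-search TFs.
    """
    if len(tfs) == 0:
        raise ValueError("empty query set")
    tf_ids = frozenset(tfs.ids())
    db = partition_by_length(proteome, cfg.small_protein_length)
    if len(db) == 0:
        return {}
    forward = backend.search_stage(tfs, db, cfg.tier2_cutoff, STAGE_TIER2)
    subject_ids = [
        sid
        for sid in dict.fromkeys(h.subject_id for h in forward)
        if sid not in tf_ids
    ]
    if not subject_ids:
        return {}
    reverse_queries = proteome.subset(subject_ids)
    reverse = backend.search_stage(
        reverse_queries, tfs, cfg.reverse_cutoff, STAGE_REVERSE
    )
    out: dict[str, CandidateMiP] = {}
    for h in reverse:
        if h.subject_id == h.query_id:
            continue
        cand = out.setdefault(
            h.query_id, CandidateMiP(protein_id=h.query_id, tier=TIER2)
        )
        cand.add_target(h.subject_id, h.evalue)
    return {pid: c for pid, c in out.items() if c.targets}


def merge_candidates(
    t1: Mapping[str, CandidateMiP], t2: Mapping[str, CandidateMiP]
) -> dict[str, CandidateMiP]:
    """Union keyed by protein id; tier1 wins, minimum E-value per pair."""
    merged: dict[str, CandidateMiP] = {}
    for source in (t1, t2):
        for pid, cand in source.items():
            if pid not in merged:
                merged[pid] = CandidateMiP(
                    protein_id=pid, tier=cand.tier, targets=dict(cand.targets)
                )
            else:
                existing = merged[pid]
                if cand.tier == TIER1:
                    existing.tier = TIER1
                for tf_id, ev in cand.targets.items():
                    existing.add_target(tf_id, ev)
    return merged


def filter_unwanted_domains(
    cands: Mapping[str, CandidateMiP],
    architectures: Mapping[str, frozenset[str]],
    unwanted: UnwantedDomainSet,
) -> dict[str, CandidateMiP]:
    """Drop candidates whose architecture intersects the unwanted set.

    Candidates with no annotated domains pass: the filter can only act on
    mapped domains.
    """
    return {
        pid: cand
        for pid, cand in cands.items()
        if not unwanted.intersects(architectures.get(pid, frozenset()))
    }


def filter_length_ratio(
    cands: Mapping[str, CandidateMiP],
    lengths: Mapping[str, int],
    ratio: float,
) -> dict[str, CandidateMiP]:
    """Per-pair length filter: drop (miP, TF) pairs with len > ratio * tf_len.

    The boundary is inclusive (a candidate at exactly ratio x the target
    length survives).  A candidate is removed entirely only when none of
    its targets survive.
    """
    out: dict[str, CandidateMiP] = {}
    for pid, cand in cands.items():
        mip_len = lengths[pid]
        surviving = {
            tf_id: ev
            for tf_id, ev in cand.targets.items()
            if not (mip_len > ratio * lengths[tf_id])
        }
        if surviving:
            out[pid] = CandidateMiP(
                protein_id=pid, tier=cand.tier, targets=surviving
            )
    return out


def filter_foreign_domains(
    cands: Mapping[str, CandidateMiP],
    architectures: Mapping[str, frozenset[str]],
) -> dict[str, CandidateMiP]:
    """Keep candidates whose domains all occur in >= 1 surviving target.

    The test is domain_set(miP) ⊆ union of the surviving targets' domain
    sets; an empty candidate domain set always passes.  Run after the
    length-ratio filter so the union ranges over surviving targets only.
    """
    out: dict[str, CandidateMiP] = {}
    for pid, cand in cands.items():
        union: set[str] = set()
        for tf_id in cand.targets:
            union |= architectures.get(tf_id, frozenset())
        if architectures.get(pid, frozenset()) <= union:
            out[pid] = cand
    return out


def run_pipeline(
    proteome: Proteome,
    tfs: Proteome,
    unwanted: UnwantedDomainSet,
    cfg: PipelineConfig | None = None,
    search_backend: SearchBackend | None = None,
    domain_hits: Optional[Sequence[DomainHit]] = None,
    domain_library: Optional[DomainLibrary] = None,
) -> list[PredictionRecord]:
    """Run the full prediction pipeline and return sorted predictions.

    Domain annotation comes from exactly one source: precomputed
    ``domain_hits`` (e.g. parsed InterProScan TSV) or a ``domain_library``
    scanned with the built-in motif scanner.  Stage survivor counts are
    logged at INFO level so runs can be audited.
    """
    cfg = cfg or PipelineConfig()
    backend = search_backend or BuiltinSearchBackend()
    if len(tfs) == 0:
        raise ValueError("pipeline: empty query set")
    if len(proteome) == 0:
        raise ValueError("pipeline: empty proteome")
    if domain_hits is None and domain_library is None:
        raise ValueError(
            "pipeline: provide domain_hits or domain_library for annotation"
        )
    if domain_hits is not None and domain_library is not None:
        raise ValueError("pipeline: provide only one domain-annotation source")

    def _stage(name: str, cands: Mapping[str, CandidateMiP]):
        logger.info("stage %-18s: %d candidates", name, len(cands))

    try:
        t1 = tier1_candidates(tfs, proteome, cfg, backend)
        _stage("tier1", t1)
        t2 = tier2_candidates(tfs, proteome, cfg, backend)
        _stage("tier2", t2)
        merged = merge_candidates(t1, t2)
        _stage("merged", merged)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed during candidate search: {exc}") from exc

    # Annotate the proteome and the TF set together; TFs absent from the
    # proteome still need architectures for the foreign-domain union.
    universe = Proteome(list(proteome))
    for rec in tfs:
        if rec.id not in universe:
            universe.add(rec)
    if domain_hits is not None:
        hits = list(domain_hits)
    else:
        assert domain_library is not None
        hits = scan(universe, domain_library)
    architectures = architectures_from_hits(hits)

    lengths = {rec.id: len(rec) for rec in universe}
    for cand in merged.values():
        unknown = [t for t in cand.targets if t not in lengths]
        if unknown:
            raise RuntimeError(
                f"pipeline failed during length lookup: unknown target ids "
                f"{unknown} for candidate {cand.protein_id!r}"
            )

    try:
        after_dbd = filter_unwanted_domains(merged, architectures, unwanted)
        _stage("unwanted-domain", after_dbd)
        after_ratio = filter_length_ratio(after_dbd, lengths, cfg.length_ratio)
        _stage("length-ratio", after_ratio)
        after_foreign = filter_foreign_domains(after_ratio, architectures)
        _stage("foreign-domain", after_foreign)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed during filtering: {exc}") from exc

    records: list[PredictionRecord] = []
    for pid in sorted(after_foreign):
        cand = after_foreign[pid]
        tf_ids = tuple(sorted(cand.targets))
        records.append(
            PredictionRecord(
                mip_id=pid,
                mip_length=lengths[pid],
                target_tf_ids=tf_ids,
                target_tf_lengths=tuple(lengths[t] for t in tf_ids),
                mip_domains=tuple(sorted(architectures.get(pid, frozenset()))),
                provenance=cand.tier,
            )
        )
    logger.info("pipeline: %d predictions", len(records))
    return records
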