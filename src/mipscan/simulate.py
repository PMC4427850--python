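"""Seed-deterministic synthetic proteomes with planted miPs and decoys.

The generator emulates the sequence features the pipeline exploits: each
synthetic TF family carries a unique DNA-binding-domain (DBD) motif near
its N terminus and a unique protein-protein-interaction (PPI) motif near
its C terminus, embedded in random flanking sequence.  Planted proteins:

* ``true_mip_tier1`` — C-terminal truncations of a family TF retaining the
  intact PPI motif and lacking the DBD, diverged at a low substitution
  rate: strong homology, caught by the stringent tier-1 search.
* ``true_mip_tier2`` — small proteins sharing only a short, heavily
  diverged PPI neighborhood with their family: weak homology calibrated to
  miss the tier-1 cutoff but survive the permissive tier-2 search plus
  reverse rescue.  Detectability is enforced by construction-time search
  with bounded redraws rather than analytic divergence calculus.
* ``decoy_dbd`` — N-terminal truncations retaining the DBD motif (removed
  by the unwanted-domain filter).
* ``decoy_oversized`` — DBD-free paralogs longer than 1.1x their family
  TFs (removed by the length-ratio filter); when the required length would
  reach the 550-aa partition limit they are generated above it instead and
  are partition-killed.
* ``decoy_foreign`` — miP-like truncations carrying an extra motif found
  in no TF (removed by the foreign-domain filter).
* ``decoy_random`` — unrelated random sequences (never hit the TFs; the
  generator redraws any that do by chance).

Residue composition is uniform over the 20 standard amino acids, which is
adequate for exercising the filters but not for E-value realism on biased
real proteomes.  All sampling flows from the single spec seed, so equal
specs yield byte-identical fixtures.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .domains import DomainLibrary, read_domain_library, write_domain_library
from .homology import BuiltinSearchBackend, SearchBackend, search
from .io_formats import (
    AMINO_ACIDS,
    FormatError,
    ProteinRecord,
    Proteome,
    UnwantedDomainSet,
    read_fasta,
    read_unwanted_domains,
    write_fasta,
    write_unwanted_domains,
)
from .pipeline import PipelineConfig, partition_by_length

DBD_MOTIF_LEN = 14
PPI_MOTIF_LEN = 16
N_FLANK_LEN = 20  # residues before the DBD motif in a full TF
C_FLANK_LEN = 15  # residues after the PPI motif
TIER2_CONTEXT = 10  # diverged flank kept around the PPI motif in tier-2 miPs
MAX_REDRAW_ROUNDS = 30

TRUE_CLASSES = frozenset({"true_mip_tier1", "true_mip_tier2"})
DECOY_CLASSES = frozenset(
    {"decoy_dbd", "decoy_oversized", "decoy_foreign", "decoy_random"}
)
ALL_CLASSES = TRUE_CLASSES | DECOY_CLASSES | {"tf"}


def _default_decoy_counts() -> dict[str, int]:
    return {
        "dbd_retaining": 4,
        "oversized_paralog": 4,
        "foreign_domain": 4,
        "unrelated_random": 4,
        "tier2_distant": 3,
    }


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic benchmark proteome.

    ``decoy_counts`` holds total counts per class; ``tier2_distant``
    entries are the planted tier-2 true miPs (decoys from the stringent
    search's point of view, true positives for the full pipeline).
    ``mutation_rate`` is the per-residue substitution probability applied
    outside planted motifs; ``tier2_mutation_rate`` is the higher rate
    (default 0.45) used for the distant tier-2 miPs.
    """

    n_tf_families: int = 2
    tfs_per_family: int = 2
    tf_length_range: tuple[int, int] = (350, 500)
    mips_per_family: int = 3
    mip_length_range: tuple[int, int] = (80, 180)
    decoy_counts: dict[str, int] = field(default_factory=_default_decoy_counts)
    mutation_rate: float = 0.05
    tier2_mutation_rate: float = 0.45
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_tf_families < 1 or self.tfs_per_family < 1:
            raise ValueError("need at least one TF family with one TF")
        if min(self.decoy_counts.values(), default=0) < 0 or self.mips_per_family < 0:
            raise ValueError("counts must be non-negative")
        for rate in (self.mutation_rate, self.tier2_mutation_rate):
            if not (0 <= rate < 1):
                raise ValueError("mutation rates must lie in [0, 1)")
        lo, hi = self.mip_length_range
        if not (0 < lo <= hi < 550):
            raise ValueError("mip_length_range must lie within (0, 550)")
        if lo < PPI_MOTIF_LEN + C_FLANK_LEN + TIER2_CONTEXT:
            raise ValueError(
                "mip_length_range too short to contain the PPI motif and "
                "its flank"
            )
        tlo, thi = self.tf_length_range
        min_tf = N_FLANK_LEN + DBD_MOTIF_LEN + PPI_MOTIF_LEN + C_FLANK_LEN + 20
        if tlo < min_tf:
            raise ValueError(f"tf_length_range minimum must be >= {min_tf}")
        if thi < tlo:
            raise ValueError("tf_length_range must be non-decreasing")


@dataclass
class GroundTruth:
    """Per-protein class labels and expected miP→TF target sets."""

    labels: dict[str, str]
    expected_targets: dict[str, frozenset[str]]

    def planted_mips(self) -> list[str]:
        return [pid for pid, c in self.labels.items() if c in TRUE_CLASSES]

    def of_class(self, cls: str) -> list[str]:
        return [pid for pid, c in self.labels.items() if c == cls]


@dataclass
class Fixture:
    """A generated benchmark: sequences, annotations, and ground truth."""

    proteome: Proteome
    tfs: Proteome
    unwanted: UnwantedDomainSet
    library: DomainLibrary
    truth: GroundTruth
    spec: FixtureSpec


# ---------------------------------------------------------------------------
# sequence helpers


def _random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(n))


def _mutate(
    rng: random.Random,
    seq: str,
    rate: float,
    protected: list[tuple[int, int]] = (),
) -> str:
    """Substitute residues at ``rate``, leaving protected [start, end) spans."""
    out = list(seq)
    for i in range(len(out)):
        if any(s <= i < e for s, e in protected):
            continue
        if rng.random() < rate:
            choices = AMINO_ACIDS.replace(out[i], "")
            out[i] = rng.choice(choices)
    return "".join(out)


@dataclass
class _Family:
    index: int
    dbd_acc: str
    dbd_motif: str
    ppi_acc: str
    ppi_motif: str
    base_seq: str
    tf_length: int
    dbd_span: tuple[int, int]  # [start, end) 0-based on base_seq
    ppi_span: tuple[int, int]
    tf_ids: list[str]


def _make_family(rng: random.Random, f: int, spec: FixtureSpec) -> _Family:
    tf_len = rng.randint(*spec.tf_length_range)
    dbd_motif = _random_seq(rng, DBD_MOTIF_LEN)
    ppi_motif = _random_seq(rng, PPI_MOTIF_LEN)
    mid_len = tf_len - N_FLANK_LEN - DBD_MOTIF_LEN - PPI_MOTIF_LEN - C_FLANK_LEN
    base = (
        _random_seq(rng, N_FLANK_LEN)
        + dbd_motif
        + _random_seq(rng, mid_len)
        + ppi_motif
        + _random_seq(rng, C_FLANK_LEN)
    )
    dbd_span = (N_FLANK_LEN, N_FLANK_LEN + DBD_MOTIF_LEN)
    ppi_start = tf_len - C_FLANK_LEN - PPI_MOTIF_LEN
    return _Family(
        index=f,
        dbd_acc=f"SYNDBD{f:03d}",
        dbd_motif=dbd_motif,
        ppi_acc=f"SYNPPI{f:03d}",
        ppi_motif=ppi_motif,
        base_seq=base,
        tf_length=tf_len,
        dbd_span=dbd_span,
        ppi_span=(ppi_start, ppi_start + PPI_MOTIF_LEN),
        tf_ids=[],
    )


def _tier1_mip_seq(rng: random.Random, fam: _Family, spec: FixtureSpec) -> str:
    length = rng.randint(*spec.mip_length_range)
    seq = fam.base_seq[-length:]
    offset = fam.tf_length - length
    ppi = (fam.ppi_span[0] - offset, fam.ppi_span[1] - offset)
    return _mutate(rng, seq, spec.mutation_rate, [ppi])


def _make_tier2_seq(
    rng: random.Random, fam: _Family, length: int, rate: float
) -> str:
    """Random sequence with a short, heavily diverged PPI neighborhood.

    Only ~36 residues of family context are planted, so the alignment
    signal is weak enough to miss the stringent cutoff while the reverse
    rescue still finds it (verified afterwards; the generator redraws on
    failure).
    """
    ctx_start = fam.ppi_span[0] - TIER2_CONTEXT
    ctx_end = fam.ppi_span[1] + TIER2_CONTEXT
    context = _mutate(rng, fam.base_seq[ctx_start:ctx_end], rate)
    pos = rng.randint(0, length - len(context))
    return (
        _random_seq(rng, pos)
        + context
        + _random_seq(rng, length - pos - len(context))
    )


def _dbd_decoy_seq(rng: random.Random, fam: _Family, spec: FixtureSpec) -> str:
    length = rng.randint(*spec.mip_length_range)
    seq = fam.base_seq[:length]
    return _mutate(rng, seq, spec.mutation_rate, [fam.dbd_span])


def _oversized_seq(rng: random.Random, fam: _Family, spec: FixtureSpec) -> str:
    """DBD-free paralog longer than 1.1x the family TF length.

    Splices the DBD motif out of the family sequence and pads with random
    residues; if the needed length would reach the 550-aa tier-1 limit the
    decoy is made longer still, so it is partition-killed instead of
    ratio-killed — absent from output either way.
    """
    needed = int(fam.tf_length * 1.1) + 2
    if needed >= 550:
        needed = 560
    core = fam.base_seq[: fam.dbd_span[0]] + fam.base_seq[fam.dbd_span[1]:]
    ppi = (fam.ppi_span[0] - DBD_MOTIF_LEN, fam.ppi_span[1] - DBD_MOTIF_LEN)
    core = _mutate(rng, core, spec.mutation_rate, [ppi])
    return core + _random_seq(rng, needed - len(core))


def _foreign_decoy_seq(
    rng: random.Random, fam: _Family, foreign_motif: str, spec: FixtureSpec
) -> str:
    length = rng.randint(*spec.mip_length_range)
    seq = fam.base_seq[-length:]
    offset = fam.tf_length - length
    ppi = (fam.ppi_span[0] - offset, fam.ppi_span[1] - offset)
    seq = _mutate(rng, seq, spec.mutation_rate, [ppi])
    # overwrite part of the N-terminal flank (never the PPI span) with the
    # foreign motif
    seq = foreign_motif + seq[len(foreign_motif):]
    return seq


# ---------------------------------------------------------------------------
# generation


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Generate a labeled benchmark proteome from ``spec``.

    Deterministic: two calls with equal specs return identical fixtures.
    Tier-2 and random-decoy sequences are redrawn (bounded rounds) until
    the construction-time search confirms the detectability promises;
    exhausting the retry budget is an error.
    """
    rng = random.Random(spec.seed)
    families = [
        _make_family(rng, f + 1, spec) for f in range(spec.n_tf_families)
    ]
    foreign_motif = _random_seq(rng, PPI_MOTIF_LEN)

    records: list[ProteinRecord] = []
    labels: dict[str, str] = {}
    expected: dict[str, frozenset[str]] = {}

    for fam in families:
        for i in range(spec.tfs_per_family):
            tf_id = f"tf{fam.index}_{i + 1}"
            seq = _mutate(
                rng,
                fam.base_seq,
                spec.mutation_rate,
                [fam.dbd_span, fam.ppi_span],
            )
            fam.tf_ids.append(tf_id)
            records.append(ProteinRecord(id=tf_id, sequence=seq))
            labels[tf_id] = "tf"
            expected[tf_id] = frozenset()

    def plant(pid: str, seq: str, cls: str, fam: Optional[_Family]) -> None:
        records.append(ProteinRecord(id=pid, sequence=seq))
        labels[pid] = cls
        expected[pid] = frozenset(fam.tf_ids) if cls in TRUE_CLASSES else frozenset()

    for fam in families:
        for j in range(spec.mips_per_family):
            plant(
                f"mip{fam.index}_{j + 1}",
                _tier1_mip_seq(rng, fam, spec),
                "true_mip_tier1",
                fam,
            )

    counts = dict(_default_decoy_counts())
    counts.update(spec.decoy_counts)
    fam_cycle = lambda k: families[k % len(families)]

    tier2_lengths: dict[str, int] = {}
    for k in range(counts.get("tier2_distant", 0)):
        fam = fam_cycle(k)
        length = rng.randint(
            spec.mip_length_range[0],
            min(spec.mip_length_range[1], 199),
        )
        pid = f"t2mip{k + 1}"
        tier2_lengths[pid] = length
        plant(
            pid,
            _make_tier2_seq(rng, fam, length, spec.tier2_mutation_rate),
            "true_mip_tier2",
            fam,
        )

    for k in range(counts.get("dbd_retaining", 0)):
        plant(f"dbddecoy{k + 1}", _dbd_decoy_seq(rng, fam_cycle(k), spec),
              "decoy_dbd", None)
    for k in range(counts.get("oversized_paralog", 0)):
        plant(f"bigdecoy{k + 1}", _oversized_seq(rng, fam_cycle(k), spec),
              "decoy_oversized", None)
    for k in range(counts.get("foreign_domain", 0)):
        plant(
            f"foreigndecoy{k + 1}",
            _foreign_decoy_seq(rng, fam_cycle(k), foreign_motif, spec),
            "decoy_foreign",
            None,
        )
    rand_lengths: dict[str, int] = {}
    for k in range(counts.get("unrelated_random", 0)):
        length = rng.randint(*spec.mip_length_range)
        pid = f"randdecoy{k + 1}"
        rand_lengths[pid] = length
        plant(pid, _random_seq(rng, length), "decoy_random", None)

    proteome = Proteome(records)
    tfs = proteome.subset(
        [tid for fam in families for tid in fam.tf_ids]
    )
    unwanted = UnwantedDomainSet(
        frozenset(fam.dbd_acc for fam in families)
    )
    entries = [(fam.dbd_acc, fam.dbd_motif) for fam in families]
    entries += [(fam.ppi_acc, fam.ppi_motif) for fam in families]
    entries.append(("SYNFOR001", foreign_motif))
    library = DomainLibrary(entries=tuple(entries))
    truth = GroundTruth(labels=labels, expected_targets=expected)
    fixture = Fixture(
        proteome=proteome,
        tfs=tfs,
        unwanted=unwanted,
        library=library,
        truth=truth,
        spec=spec,
    )

    # Construction-time enforcement of the detectability promises: redraw
    # offending tier-2 miPs / random decoys with fresh sequences of the same
    # length, so the search space size stays fixed across rounds.
    fam_of = {
        pid: families[k % len(families)]
        for k, pid in enumerate(sorted(tier2_lengths, key=_t2_order))
    }
    cfg = PipelineConfig()
    backend = BuiltinSearchBackend()
    for _ in range(MAX_REDRAW_ROUNDS):
        violations = verify_fixture(fixture, cfg, backend)
        if not violations:
            return fixture
        offending = sorted({v.split(":", 1)[0] for v in violations})
        replaced: list[ProteinRecord] = []
        for rec in fixture.proteome:
            if rec.id in offending and rec.id in tier2_lengths:
                fam = fam_of[rec.id]
                seq = _make_tier2_seq(
                    rng, fam, tier2_lengths[rec.id], spec.tier2_mutation_rate
                )
                replaced.append(ProteinRecord(id=rec.id, sequence=seq))
            elif rec.id in offending and rec.id in rand_lengths:
                replaced.append(
                    ProteinRecord(
                        id=rec.id,
                        sequence=_random_seq(rng, rand_lengths[rec.id]),
                    )
                )
            else:
                if rec.id in offending:
                    raise RuntimeError(
                        f"fixture promise violated for non-redrawable "
                        f"protein {rec.id!r}: {violations}"
                    )
                replaced.append(rec)
        fixture.proteome = Proteome(replaced)
        fixture.tfs = fixture.proteome.subset(fixture.tfs.ids())
    raise RuntimeError(
        f"could not satisfy fixture promises within {MAX_REDRAW_ROUNDS} "
        f"redraw rounds; last violations: {violations}"
    )


def _t2_order(pid: str) -> int:
    return int(pid.removeprefix("t2mip"))


def verify_fixture(
    fixture: Fixture,
    cfg: PipelineConfig | None = None,
    backend: SearchBackend | None = None,
) -> list[str]:
    """Check the constructed detectability/undetectability promises.

    Returns a list of ``"<protein_id>: <problem>"`` strings (empty on
    success): tier-1 miPs must hit an expected TF at the stringent cutoff;
    tier-2 miPs must miss the stringent cutoff yet pass the permissive
    forward search and the reverse rescue; random decoys must hit nothing.
    Violations are data, not exceptions.
    """
    cfg = cfg or PipelineConfig()
    if backend is None:
        backend = BuiltinSearchBackend()
    truth = fixture.truth
    violations: list[str] = []

    big = partition_by_length(fixture.proteome, cfg.max_mip_length)
    small = partition_by_length(fixture.proteome, cfg.small_protein_length)
    big_hits = (
        backend.search_stage(fixture.tfs, big, cfg.tier2_cutoff, "tier1")
        if len(big)
        else []
    )
    small_hits = (
        backend.search_stage(fixture.tfs, small, cfg.tier2_cutoff, "tier2")
        if len(small)
        else []
    )
    stringent = {
        h.subject_id for h in big_hits if h.evalue <= cfg.tier1_cutoff
    }
    forward_small = {h.subject_id for h in small_hits}
    any_forward = {h.subject_id for h in big_hits} | forward_small

    tier2_ids = [
        pid for pid in truth.of_class("true_mip_tier2")
        if pid in fixture.proteome
    ]
    reverse_ok: set[str] = set()
    if tier2_ids:
        rev_hits = backend.search_stage(
            fixture.proteome.subset(tier2_ids),
            fixture.tfs,
            cfg.reverse_cutoff,
            "reverse",
        )
        reverse_ok = {h.query_id for h in rev_hits}

    for pid in truth.of_class("true_mip_tier1"):
        if pid not in stringent:
            violations.append(f"{pid}: tier-1 miP not detected at tier1_cutoff")
    for pid in tier2_ids:
        if pid in stringent:
            violations.append(f"{pid}: tier-2 miP detected by tier-1 search")
        elif pid not in forward_small:
            violations.append(f"{pid}: tier-2 miP missed by forward tier-2 search")
        elif pid not in reverse_ok:
            violations.append(f"{pid}: tier-2 miP failed the reverse rescue")
    for pid in truth.of_class("decoy_random"):
        if pid in any_forward:
            violations.append(f"{pid}: random decoy hit a TF")
    return violations


# ---------------------------------------------------------------------------
# fixture file I/O

TRUTH_HEADER = ["protein_id", "label", "expected_targets"]


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_HEADER) + "\n")
        for pid in sorted(truth.labels):
            targets = ",".join(sorted(truth.expected_targets.get(pid, ())))
            fh.write(f"{pid}\t{truth.labels[pid]}\t{targets or '-'}\n")


def read_truth(path: str | Path) -> GroundTruth:
    labels: dict[str, str] = {}
    expected: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TRUTH_HEADER:
            raise FormatError(f"{path}: unexpected truth-table header")
        for line in fh:
            if not line.strip():
                continue
            pid, label, targets = line.rstrip("\n").split("\t")
            if label not in ALL_CLASSES:
                raise FormatError(f"{path}: unknown label {label!r}")
            labels[pid] = label
            expected[pid] = (
                frozenset() if targets == "-" else frozenset(targets.split(","))
            )
    return GroundTruth(labels=labels, expected_targets=expected)


def write_fixture(fixture: Fixture, outdir: str | Path) -> None:
    """Write proteome.fasta, tfs.fasta, unwanted.txt, domain_lib.tsv, truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(fixture.proteome, outdir / "proteome.fasta")
    write_fasta(fixture.tfs, outdir / "tfs.fasta")
    write_unwanted_domains(fixture.unwanted, outdir / "unwanted.txt")
    write_domain_library(fixture.library, outdir / "domain_lib.tsv")
    write_truth(fixture.truth, outdir / "truth.tsv")


def read_fixture(outdir: str | Path, spec: FixtureSpec | None = None) -> Fixture:
    """Read a fixture directory written by :func:`write_fixture`."""
    outdir = Path(outdir)
    return Fixture(
        proteome=read_fasta(outdir / "proteome.fasta"),
        tfs=read_fasta(outdir / "tfs.fasta"),
        unwanted=read_unwanted_domains(outdir / "unwanted.txt"),
        library=read_domain_library(outdir / "domain_lib.tsv"),
        truth=read_truth(outdir / "truth.tsv"),
        spec=spec or FixtureSpec(),
    )
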