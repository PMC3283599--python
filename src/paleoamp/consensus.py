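"""Consensus calling for cloned amplicons under replication rules.

The authentication logic is conservative: per-column strict-majority calls
within an amplicon, IUPAC ambiguity codes whenever clones tie or
independent replicates disagree, and explicit replication status per
fragment.  A fragment counts as validated when it was amplified in at
least two independent PCR sessions, when two largely overlapping amplicons
replicate each other, or when a single amplicon is identical (IUPAC-
compatibly) to a validated consensus from another sample.

Coordinates are 1-based inclusive throughout, so ambiguity positions are
reported on the gene frame (e.g. an A/G conflict at gene position 938 is
recorded as ``(938, "R")``).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

from . import iupac

REPLICATION_LEVELS = (
    "replicated_independent",
    "replicated_same_session",
    "overlapping_replicates",
    "single_cross_validated",
    "unvalidated",
)


@dataclass(frozen=True)
class Amplicon:
    """Aligned, primer-trimmed clones of one PCR product."""

    sample_id: str
    fragment_id: str
    pcr_session: str
    clones: tuple[str, ...]
    coords: tuple[int, int]  # 1-based inclusive on the gene frame

    def __post_init__(self):
        if not self.clones:
            raise ValueError("amplicon needs at least one clone")
        span = self.coords[1] - self.coords[0] + 1
        for c in self.clones:
            if "-" in c or "." in c:
                raise ValueError("gapped clones are not supported (indel-free model)")
            if len(c) != span:
                raise ValueError(
                    f"clone length {len(c)} != span {span} for "
                    f"{self.sample_id}/{self.fragment_id}"
                )

    @property
    def n_clones(self) -> int:
        return len(self.clones)


@dataclass
class ConsensusRecord:
    """A consensus sequence over the IUPAC alphabet with provenance."""

    sequence: str
    level: str  # amplicon | fragment | sample | combined
    coords: tuple[int, int]
    support: tuple[int, ...] = ()  # clones consistent with the call, per column
    replication_status: str = "unvalidated"
    ambiguous_positions: list[tuple[int, str]] = field(default_factory=list)
    sample_id: str = ""
    fragment_id: str = ""
    pcr_session: str = ""
    n_clones: int = 0

    def __post_init__(self):
        span = self.coords[1] - self.coords[0] + 1
        if len(self.sequence) != span:
            raise ValueError(
                f"sequence length {len(self.sequence)} != span {span}"
            )

    @property
    def start(self) -> int:
        return self.coords[0]

    @property
    def end(self) -> int:
        return self.coords[1]


def _ambiguous_positions(sequence: str, start: int) -> list[tuple[int, str]]:
    return [
        (start + i, b)
        for i, b in enumerate(sequence)
        if len(iupac.base_set(b)) > 1
    ]


def call_amplicon_consensus(a: Amplicon) -> ConsensusRecord:
    """Per-column strict-majority consensus of one amplicon's clones.

    A column where two (or more) bases tie for the top count is emitted as
    the IUPAC code of the tied set, never an arbitrary pick.  Support is
    the number of clones whose base belongs to the emitted set.
    """
    seq = []
    support = []
    for col in zip(*a.clones):
        counts = Counter(b.upper() for b in col if b.upper() in "ACGT")
        if not counts:
            seq.append("N")
            support.append(0)
            continue
        top = max(counts.values())
        tied = sorted(b for b, n in counts.items() if n == top)
        seq.append(iupac.code_for(tied))
        support.append(sum(counts[b] for b in tied))
    sequence = "".join(seq)
    return ConsensusRecord(
        sequence=sequence,
        level="amplicon",
        coords=a.coords,
        support=tuple(support),
        ambiguous_positions=_ambiguous_positions(sequence, a.coords[0]),
        sample_id=a.sample_id,
        fragment_id=a.fragment_id,
        pcr_session=a.pcr_session,
        n_clones=a.n_clones,
    )


def _shared_span(a: tuple[int, int], b: tuple[int, int]) -> tuple[int, int] | None:
    lo, hi = max(a[0], b[0]), min(a[1], b[1])
    return (lo, hi) if lo <= hi else None


def _compatible_over_shared_span(rec: ConsensusRecord, other: ConsensusRecord) -> bool:
    span = _shared_span(rec.coords, other.coords)
    if span is None:
        return False
    for p in range(span[0], span[1] + 1):
        x = rec.sequence[p - rec.start]
        y = other.sequence[p - other.start]
        if not iupac.compatible(x, y):
            return False
    return True


def validate_replication(
    fragment_id: str,
    amplicons: list[Amplicon],
    cross_sample_consensuses: list[ConsensusRecord] = (),
) -> str:
    """Classify how well a fragment's amplicons replicate each other.

    Two amplicons with *different* coordinate spans that overlap over at
    least half of the shorter span count as valid replicates even when each
    was amplified only once, mirroring the treatment of largely-overlapping
    amplicon pairs.  A single amplicon can still be rescued when its
    consensus is IUPAC-compatible with a validated consensus from another
    sample over the shared span.
    """
    if not amplicons:
        raise ValueError(f"no amplicons for fragment {fragment_id}")
    if len(amplicons) == 2 and amplicons[0].coords != amplicons[1].coords:
        span = _shared_span(amplicons[0].coords, amplicons[1].coords)
        if span is not None:
            shorter = min(
                a.coords[1] - a.coords[0] + 1 for a in amplicons
            )
            if (span[1] - span[0] + 1) / shorter >= 0.5:
                return "overlapping_replicates"
    sessions = {a.pcr_session for a in amplicons}
    if len(amplicons) >= 2:
        if len(sessions) >= 2:
            return "replicated_independent"
        return "replicated_same_session"
    solo = call_amplicon_consensus(amplicons[0])
    for other in cross_sample_consensuses:
        if other.sample_id and other.sample_id == solo.sample_id:
            continue
        if _compatible_over_shared_span(solo, other):
            return "single_cross_validated"
    return "unvalidated"


def merge_replicates(consensuses: list[ConsensusRecord]) -> ConsensusRecord:
    """Merge replicate consensuses of one fragment, IUPAC-coding conflicts.

    Positions where all replicates agree keep the base; positions where two
    replicates disagree with different unambiguous bases become the 2-fold
    IUPAC code of the pair and are listed in ``ambiguous_positions``.  A
    three-way conflict yields the 3-fold code with a warning.
    """
    if not consensuses:
        raise ValueError("nothing to merge")
    coords = consensuses[0].coords
    for c in consensuses[1:]:
        if c.coords != coords:
            raise ValueError("replicates must be coordinate-registered")
    seq = []
    conflicts: list[tuple[int, str]] = []
    for i in range(coords[1] - coords[0] + 1):
        codes = {c.sequence[i].upper() for c in consensuses}
        if len(codes) == 1:
            seq.append(codes.pop())
            continue
        sets = [iupac.base_set(c) for c in codes]
        merged = frozenset().union(*sets)
        code = iupac.code_for(merged)
        unambiguous = {c for c in codes if len(iupac.base_set(c)) == 1}
        if len(unambiguous) >= 3:
            warnings.warn(
                f"three-way conflict at position {coords[0] + i}: {sorted(codes)}"
            )
        seq.append(code)
        conflicts.append((coords[0] + i, code))
    sequence = "".join(seq)
    support = ()
    if all(len(c.support) == len(sequence) for c in consensuses):
        support = tuple(
            sum(c.support[i] for c in consensuses) for i in range(len(sequence))
        )
    rec = consensuses[0]
    return ConsensusRecord(
        sequence=sequence,
        level="fragment",
        coords=coords,
        support=support,
        ambiguous_positions=conflicts,
        sample_id=rec.sample_id,
        fragment_id=rec.fragment_id,
    )


@dataclass
class Assembly:
    """Result of stitching coordinate-registered consensuses: contigs plus
    the uncovered spans between them."""

    contigs: list[ConsensusRecord]
    uncovered: list[tuple[int, int]]
    warnings: list[str] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        if len(self.contigs) != 1:
            raise ValueError(f"assembly has {len(self.contigs)} contigs, not 1")
        return self.contigs[0].sequence

    def coverage_span(self) -> tuple[int, int]:
        return (self.contigs[0].start, self.contigs[-1].end)


def _stitch(
    records: list[ConsensusRecord],
    level: str,
    on_conflict: str,
) -> Assembly:
    """Shared machinery for fragment assembly and sample combination.

    ``on_conflict`` is "error" (incompatible overlap is a hard error, used
    when stitching fragments of one sample) or "union" (emit the union code
    with a warning, the conservative cross-sample rule).
    """
    if not records:
        raise ValueError("nothing to assemble")
    records = sorted(records, key=lambda r: (r.start, r.end))
    lo = min(r.start for r in records)
    hi = max(r.end for r in records)
    sets: list[frozenset[str] | None] = [None] * (hi - lo + 1)
    owner: list[str] = [""] * (hi - lo + 1)
    supp: list[int] = [0] * (hi - lo + 1)
    notes: list[str] = []
    for rec in records:
        label = rec.fragment_id or rec.sample_id or rec.level
        has_support = len(rec.support) == len(rec.sequence)
        for i, code in enumerate(rec.sequence):
            p = rec.start + i - lo
            s = iupac.base_set(code)
            if sets[p] is None:
                sets[p] = s
                owner[p] = label
            else:
                inter = sets[p] & s
                if inter:
                    sets[p] = inter
                elif on_conflict == "error":
                    raise ValueError(
                        f"incompatible overlap between {owner[p]} and {label} "
                        f"at position {lo + p}"
                    )
                else:
                    sets[p] = sets[p] | s
                    msg = (
                        f"incompatible bases at position {lo + p} "
                        f"({owner[p]} vs {label}); emitting union code"
                    )
                    warnings.warn(msg)
                    notes.append(msg)
            if has_support:
                supp[p] += rec.support[i]
    contigs: list[ConsensusRecord] = []
    uncovered: list[tuple[int, int]] = []
    i = 0
    n = len(sets)
    sample_id = records[0].sample_id if level == "sample" else ""
    while i < n:
        if sets[i] is None:
            j = i
            while j < n and sets[j] is None:
                j += 1
            uncovered.append((lo + i, lo + j - 1))
            i = j
            continue
        j = i
        while j < n and sets[j] is not None:
            j += 1
        seq = "".join(iupac.code_for(sets[k]) for k in range(i, j))
        contigs.append(
            ConsensusRecord(
                sequence=seq,
                level=level,
                coords=(lo + i, lo + j - 1),
                support=tuple(supp[i:j]),
                ambiguous_positions=_ambiguous_positions(seq, lo + i),
                sample_id=sample_id,
            )
        )
        i = j
    return Assembly(contigs=contigs, uncovered=uncovered, warnings=notes)


def assemble_fragments(fragment_consensuses: list[ConsensusRecord]) -> Assembly:
    """Stitch one sample's fragment consensuses into contig(s).

    Overlapping columns must be IUPAC-compatible; the emitted code is the
    set intersection (so R over A narrows to A).  An incompatible overlap
    is a hard error naming the fragment pair and position.  Coverage gaps
    split the output into contigs with the uncovered spans reported.
    """
    return _stitch(fragment_consensuses, level="sample", on_conflict="error")


def combine_samples(sample_consensuses: list[ConsensusRecord]) -> Assembly:
    """Combine per-sample consensuses into the final sequence.

    Compatible columns narrow to the intersection code; incompatible
    columns fall back to the union code with a warning (conservative: the
    disagreement is kept visible as ambiguity rather than resolved by
    majority).  Coverage is the union of the samples' spans.
    """
    return _stitch(sample_consensuses, level="combined", on_conflict="union")
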