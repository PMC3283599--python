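"""Post-mortem damage quantification from clone-vs-consensus differences.

Ancient templates carry hydrolytic deamination of cytosine, which the
polymerase reads as C→T (or G→A when the lesion sat on the complementary
strand).  Authentic ancient amplifications therefore show clone-level
substitution spectra dominated by these two "C*" transitions.  This module
classifies every clone-vs-consensus difference into the 12 directed
substitution types and summarizes them as integer percentages of
transitions (%TS), deaminated cytosines (%C*) and transversions (%TV).

Counting rule: a change is a distinct (position, consensus→clone base)
event — the same mutation seen in several clones at the same place counts
once, while two different changes at one position each count once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import iupac
from .consensus import Amplicon, call_amplicon_consensus
from .simdata import CloneLibrary

#: the 12 directed substitution types, in reporting order
SUBSTITUTION_TYPES: tuple[tuple[str, str], ...] = (
    ("T", "C"),
    ("C", "T"),
    ("A", "G"),
    ("G", "A"),
    ("C", "G"),
    ("A", "C"),
    ("T", "A"),
    ("G", "T"),
    ("A", "T"),
    ("C", "A"),
    ("G", "C"),
    ("T", "G"),
)

TRANSITIONS = (("T", "C"), ("C", "T"), ("A", "G"), ("G", "A"))
DEAMINATION = (("C", "T"), ("G", "A"))  # C* on the reported strand


@dataclass
class SubstitutionSpectrum:
    """Deduplicated counts of the 12 directed substitution types."""

    counts: dict[tuple[str, str], int] = field(
        default_factory=lambda: {t: 0 for t in SUBSTITUTION_TYPES}
    )
    n_clones: int = 0
    n_pcr: int = 0
    skipped_ambiguous: tuple[int, ...] = ()  # consensus columns not counted

    def __post_init__(self):
        full = {t: 0 for t in SUBSTITUTION_TYPES}
        for k, v in self.counts.items():
            key = (k[0].upper(), k[1].upper())
            if key not in full:
                raise ValueError(f"not a substitution type: {k}")
            if v < 0:
                raise ValueError(f"negative count for {k}")
            full[key] = int(v)
        self.counts = full

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "SubstitutionSpectrum") -> "SubstitutionSpectrum":
        merged = {t: self.counts[t] + other.counts[t] for t in SUBSTITUTION_TYPES}
        return SubstitutionSpectrum(
            counts=merged,
            n_clones=self.n_clones + other.n_clones,
            n_pcr=self.n_pcr + other.n_pcr,
            skipped_ambiguous=tuple(
                sorted(set(self.skipped_ambiguous) | set(other.skipped_ambiguous))
            ),
        )


@dataclass(frozen=True)
class DamageStats:
    """Integer-percent summary of a substitution spectrum."""

    pct_ts: int
    pct_cstar: int
    pct_tv: int
    total_changes: int


def _round_half_away(x: float) -> int:
    """Round half away from zero (93.75→94, 87.5→88, 12.5→13)."""
    return int(x + 0.5) if x >= 0 else -int(-x + 0.5)


def _change_events(
    clones: Sequence[str], consensus: str
) -> tuple[set[tuple[int, str, str]], tuple[int, ...]]:
    """Distinct (position, consensus_base, clone_base) events, plus the
    ambiguous consensus columns that were skipped."""
    for c in clones:
        if len(c) != len(consensus):
            raise ValueError(
                f"clone length {len(c)} != consensus length {len(consensus)}"
            )
    skipped = tuple(
        i for i, b in enumerate(consensus) if len(iupac.base_set(b)) != 1
    )
    skip_set = set(skipped)
    events: set[tuple[int, str, str]] = set()
    for clone in clones:
        for i, (ref, obs) in enumerate(zip(consensus.upper(), clone.upper())):
            if i in skip_set or obs not in "ACGT":
                continue
            if obs != ref:
                events.add((i, ref, obs))
    return events, skipped


def classify_changes(
    clones: Sequence[str], consensus: str
) -> SubstitutionSpectrum:
    """Spectrum of distinct (position, change) events across clones.

    Columns where the consensus is ambiguous (or missing) are skipped and
    reported in ``skipped_ambiguous`` (0-based indices); clone bases
    outside A/C/G/T are ignored.
    """
    events, skipped = _change_events(clones, consensus)
    spec = SubstitutionSpectrum(n_clones=len(clones))
    for _, ref, obs in events:
        spec.counts[(ref, obs)] += 1
    spec.skipped_ambiguous = skipped
    return spec


def spectrum_stats(s: SubstitutionSpectrum) -> DamageStats:
    """%TS / %C* / %TV as integer percents, half rounded away from zero."""
    total = s.total
    if total == 0:
        return DamageStats(0, 0, 0, 0)
    ts = sum(s.counts[t] for t in TRANSITIONS)
    cstar = sum(s.counts[t] for t in DEAMINATION)
    tv = total - ts
    return DamageStats(
        pct_ts=_round_half_away(100.0 * ts / total),
        pct_cstar=_round_half_away(100.0 * cstar / total),
        pct_tv=_round_half_away(100.0 * tv / total),
        total_changes=total,
    )


_REPORT_COLUMNS = (
    ["sample_id", "fragment_id", "length_bp", "n_pcr", "n_pcr_independent", "n_clones"]
    + [f"{a}>{b}" for a, b in SUBSTITUTION_TYPES]
    + ["pct_ts", "pct_cstar", "pct_tv"]
)


def damage_report(
    library: CloneLibrary,
    consensuses: dict[tuple[str, str, str], str] | None = None,
) -> pd.DataFrame:
    """Per sample × fragment damage table.

    Changes are scored against each amplicon's *own* consensus (so a PCR
    that amplified a divergent paralog contributes only its clones' damage,
    not the paralog's divergence), deduplicated across all clones of the
    sample × fragment, then summarized.  ``consensuses`` may override the
    per-amplicon consensus, keyed by (sample, fragment, session).
    """
    frag_map = library.fragment_map()
    groups = library.amplicon_groups()
    by_pair: dict[tuple[str, str], dict[str, list]] = {}
    for (sample, frag, session), clones in groups.items():
        by_pair.setdefault((sample, frag), {})[session] = clones
    rows = []
    for (sample, frag), sessions in sorted(by_pair.items()):
        fragment = frag_map.get(frag)
        events: set[tuple[int, str, str]] = set()
        n_clones = 0
        for session, clones in sorted(sessions.items()):
            seqs = [c.sequence for c in clones]
            if consensuses and (sample, frag, session) in consensuses:
                cons = consensuses[(sample, frag, session)]
            else:
                amp = Amplicon(
                    sample_id=sample,
                    fragment_id=frag,
                    pcr_session=session,
                    clones=tuple(seqs),
                    coords=(fragment.start, fragment.end)
                    if fragment
                    else (1, len(seqs[0])),
                )
                cons = call_amplicon_consensus(amp).sequence
            sess_events, _ = _change_events(seqs, cons)
            events.update(sess_events)
            n_clones += len(seqs)
        spec = SubstitutionSpectrum(n_clones=n_clones, n_pcr=len(sessions))
        for _, a, b in events:
            spec.counts[(a, b)] += 1
        stats = spectrum_stats(spec)
        row = {
            "sample_id": sample,
            "fragment_id": frag,
            "length_bp": fragment.length if fragment else len(next(iter(sessions.values()))[0].sequence),
            "n_pcr": len(sessions),
            "n_pcr_independent": len(sessions),
            "n_clones": n_clones,
            "pct_ts": stats.pct_ts,
            "pct_cstar": stats.pct_cstar,
            "pct_tv": stats.pct_tv,
        }
        for a, b in SUBSTITUTION_TYPES:
            row[f"{a}>{b}"] = spec.counts[(a, b)]
        rows.append(row)
    return pd.DataFrame(rows, columns=_REPORT_COLUMNS)
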