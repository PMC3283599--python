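"""Synthetic ancient-DNA clone libraries with ground-truth labels.

The generator emulates the statistical structure that degraded-template
amplicon work has to cope with:

* short overlapping amplicons tiling a mitochondrial protein-coding gene,
  plus a handful of nuclear amplicons;
* length-dependent amplification success, with nuclear templates decaying
  faster than mitochondrial ones (exponential survival above the shortest
  designed amplicon length);
* occasional co-amplification of a divergent nuclear-mitochondrial
  paralog (numt) whose relative template abundance is low;
* clone-level miscoding lesions dominated by cytosine deamination, read
  as C→T on the reported strand and G→A when the lesion sat on the
  complementary strand, on top of a much rarer uniform polymerase error.

Every clone carries its template class and the exact damaged sites, so the
downstream consensus/damage/numt modules can be scored against truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .fragments import Fragment, design_fragments

MITO_STOPS = frozenset(
    CodonTable.unambiguous_dna_by_name["Vertebrate Mitochondrial"].stop_codons
)
STANDARD_STOPS = frozenset(CodonTable.unambiguous_dna_by_name["Standard"].stop_codons)

#: third-codon-position base composition typical of mammalian cytb
CYTB_THIRDPOS_FREQS = {"A": 0.39, "C": 0.36, "G": 0.03, "T": 0.21}

#: shortest designed amplicon (bp incl. primers); survival is 1 below this
MIN_AMPLICON_BP = 97

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated clone library."""

    mt_gene_length: int = 1140
    numt_divergence: float = 0.12
    deamination_rate: float = 0.02
    polymerase_error_rate: float = 0.001
    clones_per_pcr: int = 8
    pcr_sessions_per_fragment: int = 2
    mt_survival_halflife: float = 180.0
    nuc_survival_halflife: float = 90.0
    numt_weight: float = 0.1
    fragments: tuple[Fragment, ...] = field(
        default_factory=lambda: tuple(design_fragments())
    )
    samples: tuple[str, ...] = ("S1", "S2", "S3")
    nuc_gene_length: int = 1206
    seed: int = 0

    def __post_init__(self):
        if self.mt_gene_length % 3:
            raise ValueError("mt_gene_length must be divisible by 3")
        if self.nuc_gene_length % 3:
            raise ValueError("nuc_gene_length must be divisible by 3")
        for name in ("numt_divergence", "deamination_rate", "polymerase_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.numt_weight < 1.0:
            raise ValueError("numt_weight must be in [0, 1)")
        if self.mt_survival_halflife <= 0 or self.nuc_survival_halflife <= 0:
            raise ValueError("survival half-lives must be positive")
        if self.clones_per_pcr < 1 or self.pcr_sessions_per_fragment < 1:
            raise ValueError("clone and session counts must be >= 1")
        for f in self.fragments:
            limit = self.mt_gene_length if f.gene == "mt" else self.nuc_gene_length
            if not 1 <= f.start <= f.end <= limit:
                raise ValueError(
                    f"fragment {f.fragment_id} [{f.start},{f.end}] outside gene "
                    f"of length {limit}"
                )


@dataclass(frozen=True)
class ReferenceSet:
    """The three template sequences a library is amplified from."""

    mt_seq: str
    numt_seq: str
    nuc_gene_seq: str

    def __post_init__(self):
        if len(self.mt_seq) != len(self.numt_seq):
            raise ValueError("mt and numt references must have equal length")


@dataclass(frozen=True)
class CloneRecord:
    """One sequenced clone with its provenance and simulation truth."""

    sample_id: str
    fragment_id: str
    pcr_session: str
    clone_id: str
    sequence: str
    template_truth: str  # "mt" | "numt" | "nuclear" | "" for real data
    damage_sites: tuple[int, ...] = ()  # 0-based within the amplicon
    error_sites: tuple[int, ...] = ()

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def full_id(self) -> str:
        return f"{self.sample_id}|{self.fragment_id}|{self.pcr_session}|{self.clone_id}"


@dataclass
class CloneLibrary:
    """All clones of one experiment, grouped on demand."""

    clones: list[CloneRecord]
    fragments: tuple[Fragment, ...]
    config: SimConfig | None = None
    references: ReferenceSet | None = None

    def fragment_map(self) -> dict[str, Fragment]:
        return {f.fragment_id: f for f in self.fragments}

    def amplicon_groups(self) -> dict[tuple[str, str, str], list[CloneRecord]]:
        """Clones keyed by (sample_id, fragment_id, pcr_session)."""
        out: dict[tuple[str, str, str], list[CloneRecord]] = {}
        for c in self.clones:
            out.setdefault((c.sample_id, c.fragment_id, c.pcr_session), []).append(c)
        return out

    def __eq__(self, other):
        if not isinstance(other, CloneLibrary):
            return NotImplemented
        return self.clones == other.clones and self.fragments == other.fragments


def survival(length_bp: float, halflife_bp: float) -> float:
    """Exponential template survival above the shortest designed amplicon."""
    return math.exp(-max(0.0, length_bp - MIN_AMPLICON_BP) / halflife_bp)


def _random_coding_sequence(
    rng: np.random.Generator,
    n_codons: int,
    stops: frozenset[str],
    thirdpos_freqs: dict[str, float] | None = None,
) -> str:
    """Random stop-free coding sequence, optionally with a biased wobble
    position so third-codon composition matches the mitochondrial norm."""
    p3 = None
    if thirdpos_freqs is not None:
        p3 = np.array([thirdpos_freqs[b] for b in "ACGT"])
        p3 = p3 / p3.sum()
    codons = []
    for _ in range(n_codons):
        for _attempt in range(200):
            b12 = rng.choice(_BASES, size=2)
            b3 = rng.choice(_BASES, p=p3) if p3 is not None else rng.choice(_BASES)
            codon = "".join(b12) + str(b3)
            if codon not in stops:
                codons.append(codon)
                break
        else:  # pragma: no cover - unreachable with 4-letter alphabet
            raise RuntimeError("could not draw a stop-free codon")
    return "".join(codons)


def _diverge(
    rng: np.random.Generator,
    seq: str,
    divergence: float,
    avoid_stops: bool,
    stops: frozenset[str],
    max_passes: int = 200,
) -> str:
    """Substitute an exact count of sites (Jukes-Cantor style: uniform over
    the three alternative bases), optionally resampling any substitution
    that creates an in-frame stop codon."""
    n = len(seq)
    k = int(round(divergence * n))
    if k == 0:
        return seq
    arr = np.array(list(seq))
    sites = rng.choice(n, size=k, replace=False)
    for pos in sites:
        alts = [b for b in "ACGT" if b != seq[pos]]
        arr[pos] = alts[rng.integers(3)]
    if not avoid_stops:
        return "".join(arr)
    mutated = set(int(p) for p in sites)
    for _ in range(max_passes):
        bad = [
            i
            for i in range(0, n - n % 3, 3)
            if "".join(arr[i : i + 3]) in stops
        ]
        if not bad:
            return "".join(arr)
        for i in bad:
            movable = [p for p in (i, i + 1, i + 2) if p in mutated]
            # original sequence was stop-free, so a stop implies a mutation
            pos = movable[int(rng.integers(len(movable)))]
            alts = [b for b in "ACGT" if b != seq[pos]]
            arr[pos] = alts[rng.integers(3)]
    raise RuntimeError(
        "failed to place substitutions without creating stop codons "
        f"after {max_passes} repair passes"
    )


def generate_references(config: SimConfig, avoid_stops: bool = True) -> ReferenceSet:
    """Draw the mt gene, its numt paralog and the nuclear gene.

    The mt gene is stop-free under the vertebrate mitochondrial code (which
    reads AGA/AGG as stops in addition to TAA/TAG) and has the typical
    mammalian cytb wobble-position composition.  The numt derives from the
    mt gene by substituting an exact ``round(divergence * length)`` count of
    random sites; by default substitutions creating in-frame stops are
    resampled, reflecting that intact-ORF numts do occur and are the hard
    case for screening.  The nuclear gene is stop-free under the standard
    code.
    """
    rng = np.random.default_rng([config.seed, 0])
    mt = _random_coding_sequence(
        rng, config.mt_gene_length // 3, MITO_STOPS, CYTB_THIRDPOS_FREQS
    )
    numt = _diverge(rng, mt, config.numt_divergence, avoid_stops, MITO_STOPS)
    nuc = _random_coding_sequence(rng, config.nuc_gene_length // 3, STANDARD_STOPS)
    return ReferenceSet(mt_seq=mt, numt_seq=numt, nuc_gene_seq=nuc)


def _damage_clone(
    rng: np.random.Generator, template: str, deam: float, polerr: float
) -> tuple[str, tuple[int, ...], tuple[int, ...]]:
    """Apply deamination (C→T / G→A at equal per-site rates) then a uniform
    polymerase error to one clone; return sequence and true lesion sites."""
    arr = np.array(list(template))
    n = len(arr)
    u = rng.random(n)
    deam_mask = ((arr == "C") | (arr == "G")) & (u < deam)
    arr[deam_mask & (arr == "C")] = "T"
    arr[deam_mask & (arr == "G")] = "A"
    err_mask = rng.random(n) < polerr
    err_sites = np.flatnonzero(err_mask)
    for pos in err_sites:
        alts = [b for b in "ACGT" if b != arr[pos]]
        arr[pos] = alts[rng.integers(3)]
    return (
        "".join(arr),
        tuple(int(i) for i in np.flatnonzero(deam_mask)),
        tuple(int(i) for i in err_sites),
    )


def simulate_clone_library(config: SimConfig, refs: ReferenceSet) -> CloneLibrary:
    """Simulate every sample × fragment × PCR session of the design.

    For a mitochondrial fragment of length L the PCR sees a template pool
    with relative abundances 1 (mt) and ``numt_weight`` (numt), thinned by
    each template's length-dependent survival s(L); the amplification
    succeeds with the pool-averaged survival and, on success, the whole
    amplicon derives from the numt with probability
    ``w·s_nuc(L) / (w·s_nuc(L) + s_mt(L))``.  Nuclear fragments amplify
    with probability s_nuc(L) from the nuclear gene.  An empty library is a
    legal outcome.
    """
    clones: list[CloneRecord] = []
    w = config.numt_weight
    for si, sample in enumerate(config.samples):
        for fi, frag in enumerate(config.fragments):
            L = frag.length
            s_mt = survival(L, config.mt_survival_halflife)
            s_nuc = survival(L, config.nuc_survival_halflife)
            for sess in range(1, config.pcr_sessions_per_fragment + 1):
                rng = np.random.default_rng([config.seed, 1, si, fi, sess])
                if frag.gene == "mt":
                    p_success = (s_mt + w * s_nuc) / (1.0 + w)
                    if rng.random() >= p_success:
                        continue
                    p_numt = (w * s_nuc) / (w * s_nuc + s_mt)
                    truth = "numt" if rng.random() < p_numt else "mt"
                    source = refs.numt_seq if truth == "numt" else refs.mt_seq
                else:
                    if rng.random() >= s_nuc:
                        continue
                    truth = "nuclear"
                    source = refs.nuc_gene_seq
                template = source[frag.start - 1 : frag.end]
                for ci in range(1, config.clones_per_pcr + 1):
                    seq, dsites, esites = _damage_clone(
                        rng,
                        template,
                        config.deamination_rate,
                        config.polymerase_error_rate,
                    )
                    clones.append(
                        CloneRecord(
                            sample_id=sample,
                            fragment_id=frag.fragment_id,
                            pcr_session=f"s{sess}",
                            clone_id=f"c{ci}",
                            sequence=seq,
                            template_truth=truth,
                            damage_sites=dsites,
                            error_sites=esites,
                        )
                    )
    return CloneLibrary(
        clones=clones, fragments=config.fragments, config=config, references=refs
    )


# ---------------------------------------------------------------------------
# serialization


def write_library(lib: CloneLibrary, out_dir: str | Path) -> dict[str, Path]:
    """Write clones.fasta + metadata.tsv + truth.tsv (+ references.fasta).

    Output is byte-identical across runs for the same library (records are
    written in library order, which is deterministic at fixed seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "clones": out / "clones.fasta",
        "metadata": out / "metadata.tsv",
        "truth": out / "truth.tsv",
        "fragments": out / "fragments.tsv",
    }
    records = [
        SeqRecord(Seq(c.sequence), id=c.full_id, description="") for c in lib.clones
    ]
    with open(paths["clones"], "w") as fh:
        SeqIO.write(records, fh, "fasta")
    meta = pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "fragment_id": c.fragment_id,
                "pcr_session": c.pcr_session,
                "clone_id": c.clone_id,
                "template_truth": c.template_truth,
                "length_bp": c.length,
            }
            for c in lib.clones
        ],
        columns=[
            "sample_id",
            "fragment_id",
            "pcr_session",
            "clone_id",
            "template_truth",
            "length_bp",
        ],
    )
    meta.to_csv(paths["metadata"], sep="\t", index=False)
    truth = pd.DataFrame(
        [
            {
                "clone": c.full_id,
                "template_truth": c.template_truth,
                "damage_sites": ",".join(map(str, c.damage_sites)),
                "error_sites": ",".join(map(str, c.error_sites)),
            }
            for c in lib.clones
        ],
        columns=["clone", "template_truth", "damage_sites", "error_sites"],
    )
    truth.to_csv(paths["truth"], sep="\t", index=False)
    frag_df = pd.DataFrame(
        [
            {"fragment_id": f.fragment_id, "start": f.start, "end": f.end, "gene": f.gene}
            for f in lib.fragments
        ],
        columns=["fragment_id", "start", "end", "gene"],
    )
    frag_df.to_csv(paths["fragments"], sep="\t", index=False)
    if lib.references is not None:
        paths["references"] = out / "references.fasta"
        refrecs = [
            SeqRecord(Seq(lib.references.mt_seq), id="mt", description=""),
            SeqRecord(Seq(lib.references.numt_seq), id="numt", description=""),
            SeqRecord(Seq(lib.references.nuc_gene_seq), id="nuclear", description=""),
        ]
        with open(paths["references"], "w") as fh:
            SeqIO.write(refrecs, fh, "fasta")
    return paths


def _parse_sites(cell) -> tuple[int, ...]:
    if pd.isna(cell) or cell == "":
        return ()
    return tuple(int(x) for x in str(cell).split(","))


def read_library(in_dir: str | Path) -> CloneLibrary:
    """Inverse of :func:`write_library` (config is not reconstructed)."""
    src = Path(in_dir)
    seqs = {r.id: str(r.seq) for r in SeqIO.parse(str(src / "clones.fasta"), "fasta")}
    truth_path = src / "truth.tsv"
    truth: dict[str, tuple[str, tuple[int, ...], tuple[int, ...]]] = {}
    if truth_path.exists():
        tdf = pd.read_csv(truth_path, sep="\t", keep_default_na=False)
        for r in tdf.itertuples():
            truth[r.clone] = (
                str(r.template_truth),
                _parse_sites(r.damage_sites),
                _parse_sites(r.error_sites),
            )
    meta = pd.read_csv(src / "metadata.tsv", sep="\t", keep_default_na=False)
    clones = []
    for r in meta.itertuples():
        fid = f"{r.sample_id}|{r.fragment_id}|{r.pcr_session}|{r.clone_id}"
        tt, dsites, esites = truth.get(fid, (str(r.template_truth), (), ()))
        clones.append(
            CloneRecord(
                sample_id=str(r.sample_id),
                fragment_id=str(r.fragment_id),
                pcr_session=str(r.pcr_session),
                clone_id=str(r.clone_id),
                sequence=seqs[fid],
                template_truth=tt,
                damage_sites=dsites,
                error_sites=esites,
            )
        )
    frag_df = pd.read_csv(src / "fragments.tsv", sep="\t")
    frags = tuple(
        Fragment(str(r.fragment_id), int(r.start), int(r.end), str(r.gene))
        for r in frag_df.itertuples()
    )
    refs = None
    ref_path = src / "references.fasta"
    if ref_path.exists():
        rd = {r.id: str(r.seq) for r in SeqIO.parse(str(ref_path), "fasta")}
        refs = ReferenceSet(rd["mt"], rd["numt"], rd["nuclear"])
    return CloneLibrary(clones=clones, fragments=frags, references=refs)
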