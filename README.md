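# paleoamp

Authentication toolkit for ancient-DNA amplicon sequencing projects, built
around the classic clone-and-replicate design: a degraded template (e.g. a
subfossil bone extract) is amplified as many short overlapping PCR
fragments, each amplicon is cloned and several clones are sequenced, and
the biological sequence must then be separated from three confounders —
post-mortem miscoding lesions, co-amplified nuclear copies of
mitochondrial DNA (numts), and simple lack of replication.

The package is aimed at people analysing such clone libraries (and at
anyone who wants to stress-test an authentication protocol on synthetic
data with known truth): it provides

- **`simdata`** — a generator of synthetic clone libraries with
  ground-truth labels: overlapping mitochondrial and nuclear amplicons,
  exponential length-dependent template survival
  s(L) = exp(−max(0, L−97)/λ) with separate half-lives for the
  mitochondrial and nuclear fractions, per-PCR co-amplification of a
  divergent numt paralog, and clone-level damage dominated by cytosine
  deamination (C→T, and G→A for lesions on the complementary strand);
- **`consensus`** — per-amplicon strict-majority consensus calling,
  replication validation (independent PCR sessions, largely-overlapping
  amplicon pairs, cross-sample identity), replicate merging with IUPAC
  ambiguity codes for conflicts (an A/G conflict becomes R, never an
  arbitrary pick), fragment assembly and cross-sample combination by
  IUPAC set intersection;
- **`damage`** — the substitution spectrum of clone-vs-consensus
  differences over the 12 directed types, deduplicated per (position,
  change), summarised as integer %TS, %C\* = (C→T + G→A)/total and %TV;
- **`numtscreen`** — multi-criterion numt discrimination: sequence-class
  partitioning by single-linkage p-distance clustering, clone-frequency
  evidence, the nuclear length-preservation threshold L\* with
  length-anchoring of long mitochondrial amplicons, a study-wide
  compatibility-graph backbone, and corroborating (never decisive) checks
  of reading frame, third-codon-position composition and the 3>1>2
  codon-position rate ordering;
- **`topotest`** — partitioned GTR+I+Γ site log-likelihoods on fixed
  trees by Felsenstein pruning, RELL bootstrap, SH and AU topology tests,
  and harmonic-mean marginal likelihoods on the 2lnBF scale (values above
  10 read as very strong evidence);
- **`pipeline` / `paleoamp` CLI** — simulate → consensus → damage →
  numt-screen orchestration with a JSON run manifest (config snapshot,
  seeds, SHA-256 digests; reruns at a fixed seed are bit-identical).

Branch lengths and substitution-model parameters for `topotest` are
inputs; the package performs no tree search and no parameter optimization.

## Worked example

The numbered scripts under `analysis/` run the whole workflow on the demo
library (three samples over the 19-amplicon tiling design):

```bash
python analysis/01_simulate_library.py
python analysis/02_call_consensus.py
python analysis/03_damage_spectrum.py
python analysis/04_numt_screen.py
python analysis/05_topology_tests.py
```

At seed 0 the first four stages print:

```
simulated 624 clones in 78 amplicons across 3 samples (seed=0)
  template origin of clones: {'mt': 488, 'numt': 24, 'nuclear': 112}
...
replication status of sample x fragment pairs:
replicated_independent    22
single_cross_validated    19
unvalidated                1
...
aggregate changes: 1019; %TS 93, %C* 91, %TV 7
...
verdicts: {'GENUINE': 41, 'NUMT': 3}
verdict x truth: {('GENUINE', 'mt'): 41, ('NUMT', 'numt'): 3}
nuclear preservation threshold from the published outcome table: {'CH475': 123} bp
```

Reading this: 624 clones were simulated, of which 24 derive from the numt
paralog; most fragments replicated across independent PCR sessions, and
single amplifications were rescued by identity to another sample's
validated consensus; the damage spectrum is dominated by deaminated
cytosines (%C\* = 91), as expected for authentic ancient amplifications;
and the screen recovers exactly the three numt-derived sequence classes
with no false positives. The topology-test demo then simulates an
alignment down a known tree and shows the generating topology retained
(SH/AU p = 1.0) while rearrangements are rejected (p < 0.01, 2lnBF far
above the very-strong threshold of 10).

The same stages are available as a CLI
(`paleoamp simulate|damage|numt-screen|pipeline|sitelik|sh|au|bf`).

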