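# Methods

## The marker and its character model

The *psbZ–trnfM* (CAU) chloroplast intergenic spacer in *Phoenix* is treated
as a composite, character-based barcode. A ~700 bp amplicon (primers
`GGTACMTCATTATGGATTGG` / `GCGGAGTAGAGCAGTTTGGT`) carries four mutation
classes, modelled as independent character slots:

1. **Five SNPs**, labelled by their positions in the *P. dactylifera*
   'Khalas' chloroplast genome (36607, 36754, 37099, 37183, 37190), with
   reference states C, T, G, A, T.
2. **A 9 bp indel** (`GTACTTTAC`, labelled 36795–36803), present in the
   reference, deleted in the *P. roebelenii* / *P. paludosa* lineage.
3. **A 12 bp minisatellite (VNTR)** built from motif 1 `CTAACTACTATA` and
   motif 2 `GTAGTTAGTATA`. RC(M1) equals M2 cyclically rotated by four
   positions — the repeat is a run of inverted repeats shifted against the
   mutational unit boundaries. Seven haplotypes are recorded
   (1 = 2M1+M2 … 5 = 6M1+M2, 6 = 2M1+P5+M2, 7 = M1+2M2), where
   P5 = `CTATA` is an M1 unit lacking its first seven bases (`CTAACTA`).
4. **A homopolymer** (C-run then A-run, reference 7C+5A).

A *composite profile* is the joint state of all four classes; profile
equality is exact equality of every slot, homopolymer run lengths included,
because the observed matrix uses them as separating characters (e.g. the
private *P. sylvestris* 8C+5A).

### The packaged character matrix

The 18-row observed matrix (13 species, counts summing to 136 individuals)
is shipped as structured data. It collapses to 15 distinct profiles: rows
r14/r15 (*rupicola*/*theophrasti*) share one, rows r16–r18 (the date-palm
complex) share another. Derived quantities — the 109/7/20 sharing partition,
the eight diagnosable species — are always computed from the matrix at run
time, never stored.

The three-species fraction computes to 20/136 = 14.7%. The published table
prints 14.8%, which is only consistent with forcing the three percentages to
sum to 100.0; this package reports the computed 14.7 and notes the
discrepancy here rather than reproducing it.

## Coordinate frame and reference scaffold

Local coordinates are 0-based half-open on a 700 bp scaffold and are
authoritative. Genome positions are retained as site labels: the published
minisatellite span (37050–37098, 49 bp) cannot contain the 60 bp reference
allele, and a 60 bp repeat at that offset would overlap position 37099, so
genome coordinates downstream of the repeat are unreliable for arithmetic.
`to_local`/`to_global` are a constant-offset bijection (offset 36560) that
is exact for the loci upstream of the minisatellite.

The scaffold layout (SNPs at 47, 194, 525, 625, 645; indel [235,244);
minisatellite [440,500); homopolymer [585,597)) is chosen so that a 560 bp
forward truncation — 80% of the amplicon — retains the minisatellite and
SNP 37099 with their anchors but loses the homopolymer and the two distal
SNPs. Truncated reads are thereby *genuinely* incomplete, which is what
motivates the "nearly complete sequences" filter downstream.

Filler between the fixed segments is drawn uniformly from ACGT with a
seeded generator (packaged seed 101) and regenerated until: neither motif
occurs outside the minisatellite span; every 15-mer anchor occurs exactly
once; and no C/A run of length ≥4 abuts the homopolymer (its immediate
flanks are non-C / non-A, so run calls are maximal). The accepted scaffold
is frozen by its seed; two builds are byte-identical.

## Numerical and algorithmic choices

- **Decomposition** is greedy left-to-right, trying M1, M2, P5 at each unit
  boundary. The motifs are pairwise prefix-distinguishable within four
  bases, so at most one motif matches at any boundary: a tiling, if it
  exists, is unique and greedy equals exhaustive search (verified against a
  brute-force enumerator over all unit-strings ≤ 60 bp). Decomposable but
  unrecorded unit patterns are first-class `"novel"` alleles; only
  undecomposable regions raise.
- **Locus localization** uses 15-mer anchors flanking each locus: exact
  match, then a ≤1-mismatch scan, then a global-alignment fallback. An
  anchor found more than once aborts localization (ambiguity is not
  guessed). In the alignment fallback, span boundaries are mapped by the
  *modal* query-minus-reference offset over each anchor window, not by the
  extreme aligned column: co-optimal gap placements inside a periodic
  repeat can shift a gap a few columns into an anchor, and the majority
  offset is invariant to that.
- **Global alignment** scores match +1, mismatch −1, gap open −5 (the
  opening base included), extension −2, via Biopython's `PairwiseAligner`;
  among co-optimal alignments the aligner's canonical first alignment is
  used, which is deterministic for fixed inputs.
- **Missing-data semantics**: every character slot degrades to missing
  independently (anchor absent, ambiguous base, malformed locus); a record
  never fails as a whole. IUPAC codes other than ACGT are missing at SNP
  sites and break homopolymer runs.
- **Distances** are uncorrected p-distances kept as exact `Fraction`s, so
  nearest-neighbour ties are decided exactly. `substitutions_only` compares
  the 619 scaffold columns outside the indel/minisatellite/homopolymer loci
  (both bases unambiguous). `with_indels` additionally counts each
  *differing* indel/repeat/homopolymer locus as one event added to both
  numerator and denominator; identical loci contribute nothing.
- **Best Match** classifies each query by its full nearest-neighbour tie
  set: correct (all conspecific), incorrect (none), ambiguous (mixed).
  **Best Close Match** leaves queries unidentified when the nearest
  neighbour exceeds the threshold (default 3%, compared exactly).
- **Rounding**: percentages are rounded half-up (decimal, not banker's) to
  one decimal for sharing summaries and two for identification summaries,
  matching the conventions of the reported tables.

## The synthetic cohort generator

The generator realizes character-matrix rows against the scaffold by
splicing allele sequences into the reference — substituting reference
states reproduces the scaffold exactly. Its defaults are the study
conditions:

| parameter | default | meaning |
|---|---|---|
| rows | the 18-row matrix | 136 individuals, 13 species |
| n_incomplete | 13 | "single read" records |
| incomplete_source | r12 (dactylifera, hap 3) | row the truncated reads come from |
| truncation_fraction | 0.80 | 5′ prefix retained ("~20% shorter") |
| reverse_reads | off | 3′-suffix truncation instead |
| noise_rate | 0.0 | per-base substitution noise |
| noise_in_loci | off | adversarial mode: noise may hit loci |

The species membership of the 13 incomplete individuals is not printed in
the source data; drawing them from the dactylifera haplotype-3 row keeps
the filtered identification dataset at 121 individuals over 11 species
(dropping *P. acaulis* and *P. atlantica*, the two singletons), matching
the reported counts. "Approximately 20% shorter" is taken as exactly 80%
retained. Noise, when enabled, spares the diagnostic loci by default so
that character calls stay exact; the adversarial switch removes that
guarantee for robustness testing.

What the generator does **not** emulate: chromatogram/base-quality error
profiles, heteroplasmy, alignment artefacts of real Sanger consensus
building, and any within-row sequence variation in the unobserved filler
(all records of a row are identical outside noise). Passing tests therefore
demonstrate correctness of the haplotyping logic under the observed
character matrix, not robustness to raw-trace noise.

## Identification results on synthetic data

On the default cohort the SNP-only Best Match test yields 6.61% correct /
91.74% ambiguous / 1.65% incorrect (121 queries): only *P. caespitosa* has
a species-specific substitution, so nearly all queries tie at distance zero
across species — consistent with the observation that a SNP-only analysis
diagnoses a single species at this locus. Counting indel, repeat and
homopolymer events (`with_indels`) raises correct identifications to
76.03%. The originally reported per-individual percentages
(82.64/14.87/2.47) are not reproducible from the printed data alone — the
species composition of the 13 excluded single-read individuals is not
given, and those percentages do not follow from the published matrix under
any choice of the 13 — so the identification machinery is validated by
exhaustive agreement with a brute-force all-pairs oracle and by synthetic
scenarios with known answers instead.

## Known limitations

- Global genome coordinates are labels; only local scaffold coordinates are
  trustworthy downstream of the minisatellite.
- The homopolymer is called on the forward strand from the 5′ anchor
  boundary only.
- Profile-based identification requires the query to have been amplified
  with the same primer pair; the anchors assume the packaged scaffold.
- Novel minisatellite alleles are reported but cannot be placed in the
  diagnostic key beyond "no match".
- `best_match`/`best_close_match` are O(n²) in cohort size; fine for
  hundreds of records, not for thousands.
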