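# Methods

This note documents the models, conventions and design choices behind
`edcscan`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Gene model and coordinate conventions

The target architecture is the canonical two-exon EDC gene: TATA box, short
noncoding exon 1 ending in the splice donor `G|GTAAG`, intron, polypyrimidine
tract + `AG` splice acceptor, 20–25 nt 5′UTR, and a single coding exon
containing the entire ORF.

All internal coordinates are 0-based half-open on the forward strand;
minus-strand features are stored as forward intervals with a strand flag.
Scanning happens in strand-local coordinates (on the scanned strand's own
sequence) and is converted at gene-model assembly, which makes the distance
rules strand-symmetric by construction. GFF3 output uses the format's
1-based inclusive columns, while the custom attributes (`ag_start`,
`donor_g`, `tata_start`) carry the 0-based internal values so a round-trip
read reproduces them exactly. `N` residues are legal input, but any signal
window containing an `N` fails its test (conservative treatment of assembly
gaps).

## Scanner parameters

| parameter | default | rationale |
|---|---|---|
| acceptor distance (UTR) | 20–25 nt, inclusive | the typical acceptor→ATG spacing of two-exon EDC genes; enforced as a hard window, widen via config if exceptions are expected |
| polypyrimidine window / threshold | 12 nt, ≥ 0.70 C+T | an operationalization of "pyrimidine tract"; no consensus numeric definition exists, so both are config-exposed |
| donor motif | `GGTAAG`, exact | exon-terminal G + intron-initial GTAAG; mismatch budget 0 by default |
| TATA pattern | `TATAWAW` (IUPAC) | standard TATA-box consensus core |
| TATA→donor distance | 60–90 nt | measured as the number of nucleotides between the end of the TATA match and the donor G; generator and scanner share this definition |
| ORF length | 60–2000 codons | the shortest known EDC proteins are ~70 residues, so 60 codons is a safe floor; the ceiling only bounds runaway scans |
| minimum intron length | 30 nt | must at least hold GTAAG + tract + AG (19 nt) with margin |
| exon-1 search depth | 10 kb upstream | generous bound; the nearest accepted donor wins (whether the original screen considered only the nearest donor is unknowable; "nearest accepted" is this package's choice) |

Ambiguities resolved deterministically: per ORF, the acceptor with the
highest pyrimidine fraction (tie → shortest UTR) is kept; among same-strand
models with overlapping CDS spans the longest ORF survives (tie → leftmost);
`ATG` is the only start codon; translation uses genetic code table 1.
The exon-1 5′ end is a *nominal* TSS placed 25 nt downstream of the TATA
match (the true TSS is not identifiable from sequence alone); recovery
scoring therefore compares TATA/donor/acceptor/CDS coordinates, never the
nominal TSS.

## Protein features

Composition profiles are exact counts over the 20 standard residues. Class
labels (not mutually exclusive): `GS_rich` if G+S ≥ 0.5, `C_rich`/`P_rich`/
`Q_rich` if the single-residue fraction ≥ 0.15. The cut-offs are inferred
from the reported extremes of real EDC proteins (loricrin-type proteins at
~70 % G+S, cysteine-rich proteins at 35–40 % C, proline-rich ones around
20 % P) and are config-exposed. Size classes: short < 70, typical 70–170
(inclusive), intermediate 171–300, long > 300 residues; the intermediate
class exists to make the classification total.

The isoelectric point solves `Z(pH) = 0` for the Henderson–Hasselbalch net
charge over the termini and the D, E, C, Y, H, K, R side chains, by bisection
on [0, 14] down to a 1e-6 pH bracket. That bracket keeps `|Z(pI)|` below
1e-3 even for long proteins with hundreds of titratable groups, where the
charge-vs-pH slope is steep. The pKa table is an EMBOSS-style set (N-term
8.6, C-term 3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1); the
choice of table moves pI values by a few tenths of a pH unit, so comparisons
against values computed with other tables should allow ±0.3.

## Motifs and repeats

Motif consensus strings use lowercase `x` as a wildcard; wildcards never
count as mismatches, and matching is case-insensitive on the subject.
Anchoring is strict: N-terminal motifs only at offset 0, C-terminal motifs
only flush with the protein end. The shipped catalogue holds the three
conserved EDC motifs with a default discovery budget of 2 mismatches (the
natural instances are near-identical but not exact); exact checks pass 0
explicitly. The beta-keratin "core box" has no published consensus string
and ships as an empty placeholder entry that users can fill in.

`repeat_score` is a self-match period profile, not a full tandem-repeat
alignment: for each period p it finds the longest contiguous run of positions
matching their p-shifted counterpart; a run shorter than p (fewer than two
full copies) does not count as a repeat block. The best period maximizes
block coverage (tie → smallest period). This is sufficient for flagging the
internally repetitive central regions of long EDC proteins; boundary-accurate
repeat decomposition is out of scope.

## Similarity expansion and orthology

Pairwise similarity is exact Smith–Waterman (BLOSUM62, gap open 11, gap
extend 1, i.e. a length-k gap costs 11 + k) rather than a heuristic seeded
search: EDC proteins are low-complexity, which degrades heuristic seeding,
and candidate pools are small enough for exact dynamic programming. The
expansion threshold is a raw alignment score (default 40), not an E-value;
E-value calibration is out of scope and the threshold is reported in output
headers. Iterative expansion is equivalent to the reachability closure of
the seeds in the ≥-threshold similarity graph and is independent of
within-round processing order. Reciprocal best hits require *unique* mutual
best scores; ties produce no pair.

## Locus statistics

The locus map orders genes by CDS midpoint (robust to nested models) between
two user-supplied anchor spans; a gene is "inside" if its midpoint lies
strictly between the anchors. The neighbor-composition statistic is the mean
Euclidean distance between the 20-dimensional composition vectors of adjacent
inside genes, tested against random orderings with an add-one permutation
p-value, `p = (1 + #{perm ≤ obs}) / (n + 1)`; with all-identical
compositions, every permutation ties and p = 1 by design. The
Euclidean-distance + permutation formulation is this package's
operationalization of "neighboring genes encode similar proteins"; it is
stated in output metadata. Synteny comparison counts, for each ortholog
pair, the other pairs with which it appears in the same relative order in
both loci.

## Synthetic data: what it emulates and what it does not

The generator plants genes that follow the architecture above exactly:
per-gene UTR length uniform on [20, 25], TATA→donor distance uniform on
[60, 90], intron length uniform on [100, 400], exon-1 length 30–55 nt,
protein lengths drawn 75 % from 70–170, 15 % from 171–300 and 10 % from
301–450 residues, mirroring the observed size distribution of EDC proteins.
Class residue distributions are G 0.35/S 0.35 (GS_rich), C 0.35, P 0.25 and
Q 0.25, with the remainder uniform — biased residues sit clearly above the
classifier thresholds so that sampling noise rarely declassifies a planted
gene. Terminal motifs are planted with probability 0.5 each. Genes of the
same class are placed in contiguous blocks (emulating duplication-derived
locus structure), interleaved with decoys, separated by 500 nt spacers of
uniform-random DNA, and flanked by two anchor regions standing in for the
S100A boundary genes. A single seeded generator drives all sampling; equal
seeds give byte-identical FASTA/GFF3.

Each planted gene segment is verified at generation time: the segment is
redrawn until the pipeline, run on the segment in its local context, recovers
exactly the planted gene with exact signal coordinates. Decoys (ORFs without
acceptor context; perfect acceptor contexts followed by a sub-minimal ORF)
are redrawn until silent, so each decoy fails exactly the rule it was
designed to violate. The random spacers are *not* scrubbed: chance
gene-like configurations can occur there, which is why recovery precision is
expected to approach but not always equal 1.

What the generator does **not** emulate: isochore/GC structure, repeat
families, sequencing error, multi-intron gene families in the locus, and
pseudogenes. Passing the recovery benchmark therefore demonstrates
correctness of the rule implementations and coordinate arithmetic, not
performance on real genomes, where promoter and splice-signal degeneracy,
assembly gaps and paralogous noise dominate the error budget.

## Problem sizes and numerical choices

The acceptance run uses one scaffold with 50 genes and 200 decoys
(~0.2–0.3 Mb) and 999 permutations for the neighbor statistic — large enough
for stable rates, small enough that the whole script completes in seconds.
Oracle-equivalence tests use 100 random 10 kb contigs for the scanners and
50 random pairs for the aligner. Permutation p-values, pI values and all
scan outputs are bit-reproducible under a fixed seed: iteration orders are
fixed, coordinates are integers, and no global random state is used.

## Known limitations

- The distance windows are hard cut-offs; real genes with atypical spacing
  (the "typical" in 20–25 nt implies exceptions) need relaxed configuration.
- Only single-coding-exon genes are modeled; the multi-exon families found
  in real EDC loci (S100-fused type proteins, PGLYRPs) are out of scope.
- The expansion score threshold is a raw-score stand-in for a calibrated
  significance cut-off.
- `repeat_score` reports periodicity, not repeat-unit boundaries.
- The pI model ignores post-translational modification and local
  electrostatic context, as all sequence-based pI estimators do.
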