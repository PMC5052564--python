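# Methods

## The prediction problem

N-linked glycosylation attaches a glycan to the side-chain amide of an Asn
residue, canonically inside the sequon Asn-X-Ser/Thr with X ≠ Pro; O-linked
glycosylation modifies the hydroxyl of Ser or Thr and has no known consensus
motif. The sequon is necessary but far from sufficient for N-glycosylation,
and O-glycosylation offers no motif at all, so predicting which candidate
residues are modified requires context beyond the local sequence — in
particular whether the residue is conformationally accessible to the
glycosylation machinery. This package predicts per-site modification
probability from a protein 3-D structure by combining sequence-derived and
structure-derived features in a random-forest classifier, with a two-step
feature-selection procedure in between.

## Feature extraction

**Sequence features** are computed over a sliding window of 2N+1 = 15
residues centered on the candidate site (half-window N = 7; the site is
window position P8; windows extending past a terminus are padded with 'X',
which evaluates to neutral values). Per site:

* Flattened PSSM log-odds: 20 values per window position, indexed
  `PSSM_P1 … PSSM_P300` by (position−1)·20 + column, with columns in the
  standard profile order `ARNDCQEGHILKMFPSTWYV`. Padding contributes zero
  columns.
* Four AAindex scales per window position (60 values): normalized average
  hydrophobicity (CIDH920105), average flexibility indices (BHAR880101),
  mean polarity (RADA880108) and the conformational parameter of beta-turn
  (BEGF750103). 'X' gives the scale mean.
* A residue conservation score per window position (15 values), defined as
  the normalized information content of the PSSM frequency column,
  1 − H_i/log2(20), where H_i = −Σ_j p_ij log2 p_ij. It is 0 for a uniform
  column and 1 for a one-hot column. All-zero frequency rows (which profile
  tools emit occasionally) are renormalized to uniform first. Defining
  conservation from frequencies rather than log-odds is a documented design
  choice; it is bounded, scale-free, and invariant to column permutation.
* The 14 physicochemical properties of the central residue only (pK1, pK2,
  pKR, pI, hydropathy, % occurrence, % buried, average volume, accessible
  surface area, van der Waals volume, polarity, side-chain polarity,
  alpha-helix and beta-strand preference). Encoding them per window
  position would multiply the block by 15 with no positional signal to
  justify it; downstream selection in practice only ever picks central
  physicochemical features.

The sequence block is 300 + 60 + 15 + 14 = 389 features.

**Structural features** are 14 per-residue channels:

* Five absolute solvent-accessibility classes (all atoms, total side chain,
  main chain, non-polar side chain, polar side chain). Accessibility is
  computed by Shrake–Rupley point sampling: each atom's van der Waals
  sphere is expanded by the probe radius (default **3.0 Å** — deliberately
  larger than the conventional 1.4 Å water probe, to emphasize grooves
  inaccessible to the bulky glycosylation machinery) and sampled with a
  deterministic golden-spiral set of 960 points; a point inside any other
  expanded sphere is buried. Radii are the NACCESS-style set (C 1.87,
  N 1.65, O 1.40, S 1.85 Å); hydrogens are stripped at parse time; unknown
  elements fall back to 1.8 Å with a warning. The sampling sphere is
  expressed in a structure-intrinsic principal-axis frame (axes oriented by
  the third coordinate moment), which makes the computed areas invariant
  under rigid motion of the input coordinates to floating-point precision
  rather than merely approximately. Side-chain atoms of carbon/sulfur count
  as non-polar, nitrogen/oxygen as polar (sulfur-as-non-polar is a
  documented convention choice).
* Three secondary-structure values: ACC, phi, psi. Phi/psi are standard
  backbone torsions computed from C(i−1)–N–CA–C and N–CA–C–N(i+1); chain
  termini, missing backbone atoms and degenerate (collinear) geometry give
  missing values. ACC — a water-contact count in the external
  secondary-structure tool that defines it — is proxied internally by the
  residue all-atom accessibility; when a real DSSP output file is supplied
  its ACC/phi/psi override the internal values verbatim (angles printed as
  360.0 are treated as missing, per that format's convention).
* An epitope log-odds score. The reference statistic comes from an external
  B-cell-epitope predictor; internally it is approximated by smoothing an
  embedded residue propensity scale over CA neighbourhoods (mean propensity
  of residues with CA within 10 Å, minus 0.1 × the neighbour count as a
  burial penalty). This is an explicit approximation: supplying a
  precomputed per-residue score table replaces it exactly.
* Four depth-index statistics: an atom's depth (dpx) is 0 if it is solvent
  accessible (SASA > 0), otherwise its distance to the nearest accessible
  atom; per residue we take mean and population SD over all atoms and over
  side-chain atoms (0 for glycine-like residues with no side chain).
* Mean atomic B-factor of the residue.

Per site, every channel is averaged over the **structure window**: all
residues having any atom strictly within R = 10 Å of any atom of the
target (the target included). Missing values are excluded channel-wise
from the average; an all-missing channel contributes 0. The strict "<" at
the radius boundary is a deterministic tie-break for a measure-zero case.

The full site vector is 389 + 14 = 403 named features. The printed feature
totals in the source literature for this encoding family are internally
inconsistent (385 sequence features vs. component counts summing to 389);
this implementation keeps the reproducible component-wise layout and does
not force the printed total.

## Dataset construction

Candidate sites are all Asn (N-linked) or all Ser/Thr (O-linked) residues
of a chain. Experimentally annotated sites are positives; unannotated
candidates in proteins that contain at least one positive are negatives
(such proteins demonstrably meet the cellular prerequisites for
glycosylation, making their unmodified candidates the most trustworthy
negatives); candidates in proteins without any annotation remain unknown
and are excluded. Negatives are under-sampled uniformly at random to a 1:1
ratio against positives. The benchmark/independent split (default 20%
independent) is performed at the structure level — all sites of a chain
land in the same partition — to prevent leakage between partitions;
site-level splitting would place near-identical windows on both sides.
Sequon conformity is metadata, not a hard filter: annotated positives
without the motif are kept with a warning. Redundancy reduction against
homologous chains is exposed as a hook taking an external cluster table;
sequence clustering itself is out of scope.

## Two-step feature selection

1. **Linear-SVM ranking.** A linear-kernel soft-margin SVM (C = 1, the
   LibSVM-style dual formulation) is fitted on z-scored features and each
   feature j is weighted by |w_j| of the primal weight vector
   w = Σ_i α_i y_i x_i. Z-scoring first is essential: without it,
   large-unit features (areas in Å²) dominate |w| regardless of
   usefulness. Zero-variance features get weight 0 by convention; ties
   break by original column order. The top 300 ranked names are the
   optimal feature candidates (OFCs).
2. **Incremental feature selection (IFS).** For prefix sizes 1..|OFC|, a
   random forest restricted to the prefix is evaluated by stratified
   5-fold cross-validation, out-of-fold scores pooled per round and AUC
   computed per round; this repeats for 20 rounds with freshly seeded fold
   shuffles and forest seeds, and the prefix AUCs are means over rounds.
   The AUC-maximal prefix is the optimal feature set (OFS); ties resolve
   to the smallest prefix (parsimony). Stratification keeps both classes
   in every fold so AUC is always defined.

IFS trains folds × rounds × |OFC| forests, so the forests inside it are
deliberately small: the package default is 100 trees, and the end-to-end
pipeline runs IFS with 10 trees, depth ≤ 8, and 33% bootstrap subsamples
per tree. Prefix selection only needs the *ranking* of mean AUCs, which
averaging over 100 fold-round evaluations per prefix stabilizes; the final
model never uses these reduced settings.

## Classifier, metrics and screening

The final classifier is a random forest (500 trees by default, √p features
per split, no class weighting — the training data is pre-balanced 1:1).
Scores are positive-class vote fractions. Reported measures: sensitivity,
specificity, precision, accuracy, MCC (0 when any denominator factor is 0)
and AUC. AUC is computed by the rank (Mann–Whitney) statistic with ties
averaged; tests verify it equals trapezoidal ROC integration to 1e−9. The
decision rule is score ≥ threshold. For proteome screening the threshold
is calibrated on negative calibration scores as the smallest candidate
score value t with fraction(negatives < t) ≥ target specificity (default
0.99), trading sensitivity for a low false-positive rate appropriate when
scanning many structures.

## Synthetic data: what it emulates and what it does not

The generator produces desk-scale inputs with known ground truth:

* **Structures**: idealized single chains with N/CA/C/O plus one pseudo
  side-chain atom (CB) per non-Gly residue. Helix and extended modes place
  the backbone at ideal torsions via internal-coordinate chain building
  (helix interior residues reproduce phi ≈ −57°, psi ≈ −47° within 2°);
  globule mode packs residues along a serpentine path on a jittered
  lattice ball (spacing 3.4 Å), which reliably buries ≥ 20% of residues at
  the 3 Å probe — the geometric property the structural channels need.
  B-factors are drawn from a seeded gamma distribution (shape 4, scale 5).
* **Profiles**: per-position frequency rows are a mixture
  λ·onehot(true residue) + (1−λ)·near-uniform noise with λ = c/(1+c);
  the default concentration c = 10 mimics a well-converged profile while
  leaving visible column noise. Log-odds are round(2·log2(p/0.05)) clipped
  to [−10, 10] against a uniform background (a deliberate simplification:
  no external composition table).
* **Sequences**: sampled with elevated Asn/Ser/Thr frequency (9/8/8%) plus
  two explicitly planted sequon motifs per protein, so candidate sites are
  plentiful at realistic chain lengths (default 200 proteins of 40–80
  residues).
* **Labels**: a site is positive iff (sequon, when required) AND its
  structure-window-averaged all-atom accessibility exceeds τ = 30 Å²
  (about the median for this geometry, so both classes are populated),
  then flipped with probability 0.05. With zero noise the label is an
  exact function of the generated inputs, so imperfect downstream recovery
  is attributable to the learner, not the data.

What passing these tests shows: the full chain — parsing, feature
extraction, encoding, selection, classification — can recover a known
sequence+structure rule from data of this shape. What it does not show:
performance on real glycoproteins, whose structures have full side chains,
whose profiles carry phylogenetic correlation, and whose positive labels
are incomplete and biased; the idealized geometry also makes
accessibility bimodal and easier to threshold than in real structures.

## Numerical and design choices

* Alternate locations: highest occupancy wins, ties to the
  lexicographically first altloc id — deterministic and conventional.
* Multi-model files contribute only the first model; common modified
  residues (MSE, SEP, TPO, PTR, …) map to their parent amino acid, other
  heteroatoms and waters are dropped; chains with gaps are indexed by
  observed residues only (0-based contiguous `seq_index`), with PDB author
  numbering retained separately for joining external per-residue tables.
* The 2×2-table and threshold conventions (MCC → 0 on zero denominators,
  decision rule closed on the positive side, threshold chosen among
  observed score values) are fixed so results are bit-reproducible.
* All stochastic steps (under-sampling, splits, fold shuffles, forest
  seeds, the generator) take explicit seeds; identical seeds give
  identical outputs.
* Problem sizes in the shipped tests and acceptance script (200 proteins
  of 40–80 residues, 960 sphere points, reduced IFS forests) are the
  package's chosen desk-scale study conditions; they keep a full pipeline
  run in the ten-minute range on a single CPU.

## Known limitations

* The internal ACC and epitope log-odds channels are proxies; fidelity to
  the external tools that define them requires injecting those tools'
  output files (supported verbatim).
* Pseudo side chains cannot distinguish polar from non-polar side-chain
  surface in synthetic data (single carbon atom), so the non-polar/polar
  class split is only exercised against hand-built fixtures and injected
  tables.
* Rigid-motion invariance relies on a principal-axis frame; for exactly
  symmetric atom arrangements (degenerate principal axes) the frame, and
  hence the point-sampled areas, can change discontinuously under
  rotation. Real and generated structures are generic in this sense.
* No mmCIF input, no assemblies, no glycan chemistry, no relative
  accessibility.
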