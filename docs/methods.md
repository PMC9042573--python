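# Methods

## Data model

A screen is described by a `RegionSpec`: a contiguous mutagenized window in
1-based protein numbering with its wild-type sequence (Psm3-HCJ 95–168,
74 aa; Rad21-NTD 18–87, 70 aa in the packaged fixtures). A
`SubstitutionRecord` is one identified suppressor allele (position, wild
type, mutant, hit count). Hit count 0 is reserved for "unknown": saturation
statistics refuse unknown counts rather than silently treating them as 1,
and matrices built from count-free tables use presence-only mode. Duplicate
table rows for the same allele merge by summing hit counts, on the grounds
that repeated isolates are independent revertants; unknown counts contribute
0, so an all-unknown group stays unknown. Premature-stop rows are rejected at
parse time — a stop in an essential subunit cannot be recovered as a
suppressor — while the simulator, by contrast, generates stops and lets
selection remove them.

## Physicochemical profiles

Relative molecular weight and relative hydropathy of a substitution are
`property(mut) − property(wt)`. Molecular weights are free-amino-acid
average masses (Da); because only differences are used, the +18 Da water
offset of the residue-mass convention cancels, and the two conventions give
identical relative values. Hydropathy uses the Kyte–Doolittle scale
(range −4.5…+4.5, so relative values lie in ±9.0). Per-position means are
unweighted over the distinct substitutions at that position; hit counts do
not weight the mean, matching the definition of the per-position average as
"sum of relative values / number of substitutions". Positions with no
substitutions are undefined and serialize as empty CSV cells, never 0, to
avoid fake signal at unmutated positions. Profiles are reported in raw Da
and Kyte–Doolittle units; no further normalization is applied.

## Conservation scoring

Column entropy is Shannon entropy in bits over the 20 standard residues,
computed from the non-gap symbols of the column (`scipy.stats.entropy`,
base 2). Ambiguity codes (B, Z, X, …) are treated as gaps. The raw
conservation score is 1 − H/log₂ 20; the *relative* ECS is a min–max
rescaling of the raw scores over the scored region, chosen because the
relative score's normalization is otherwise unspecified — raw entropies and
raw scores are always emitted alongside, and the scoring choices (entropy
base, gap policy, normalization, uniform sequence weighting) are recorded in
the profile metadata. Columns with gap fraction > 0.5 (configurable) are
flagged low-confidence. In the degenerate case of a region whose raw scores
are all equal, the relative ECS is defined as 1.0 throughout. Region
positions map to alignment columns through the reference row's gap
structure; if the region's sequence is absent from the degapped reference
the error reports the best local match (offset and identity count). No
sequence weighting is applied; the hook exists but defaults to uniform.

## Structural annotation

Structures are read with gemmi (mmCIF or PDB), first model only, hydrogens
dropped, altlocs resolved to the highest-occupancy conformer.

Contacts: residue pairs across two chains whose minimum heavy-atom distance
is ≤ 4.0 Å (van der Waals cutoff). A pair is a salt bridge if an Asp/Glu
side-chain oxygen is within 4.0 Å of a Lys/Arg/His side-chain nitrogen, else
a hydrogen bond if any N/O···N/O pair is within 3.5 Å, else van der Waals.
These cutoffs follow common structural-biology practice and are
config-overridable; searches use a k-d tree and are validated against an
O(n²) brute-force oracle in the tests.

Hydrophobic core: a residue is buried-hydrophobic if its one-letter code is
in {A, V, L, I, M, F, W, Y} and at least `burial_min` = 30 heavy atoms from
*other* residues lie within 7.5 Å of its side-chain centroid (CA for
glycine). The neighbor-count proxy was chosen over SASA to keep the geometry
self-contained and exactly testable; an SASA backend could replace it behind
the same contract. Both parameters are config values; the default suits
full-size folded domains, and the synthetic test clusters use smaller
thresholds scaled to their atom counts.

Site annotation maps each record position onto the structure via a chain id
plus numbering offset, labels it interface (≥ 1 supporting inter-chain
contact), hydrophobic core (burial), or other, and reports category
fractions over substitutions. Positions missing from the model (disordered)
are labeled unresolved and excluded from the denominators.

## Superposition and segment rotation

Superposition is the closed-form Kabsch solution (SVD of the covariance of
centered paired CA coordinates, determinant branch forced to +1 so
reflections are never returned). CA atoms are paired by author residue
number over `chain:start-end[,start-end…]` selections, since published
alignment selections are stated in author numbering. The segment rotation
angle between two states superposes state B onto state A over the alignment
selection (e.g. the invariant head), takes each state's segment axis as the
dominant principal direction of the segment's CA coordinates oriented N→C,
and reports the angle between the axes in [0°, 180°]. A segment of fewer
than 4 residues is rejected (the axis is unstable), and only the magnitude
is reported — assigning an inward/outward sign would require a reference
frame the measurement does not define. Which residues constitute "the
coiled-coil segment" of a real two-state comparison is a user-supplied
selection; the packaged synthetic hinge pair (straight base + arm rotated by
a known angle about a hinge axis) validates the measurement to ±0.5°.

## Screen simulator

The simulator emulates the screen design: for each region position,
`n_transformants_per_position` codons drawn uniformly from all 64 NNN codons
(expected stop fraction 3/64 ≈ 0.047); a library member survives iff it
translates to a non-stop residue different from the wild type, its allele is
in the hidden `TruthSet`, and an independent Bernoulli(detection probability
× allele strength) draw succeeds. Selection is all-or-none per allele — the
plate-selection readout gives no quantitative fitness, so no
growth-competition model is attempted. One substitution per revertant
matches the one-mutagenized-codon-per-construct design. All draws come from
one seeded NumPy generator in position-major order, so identical seeds give
bit-identical samples across platforms.

Defaults in the tests and the acceptance script: libraries of 60–300 codons
per position and truth sets of tens of alleles — large enough that coverage
and occupancy statistics are well resolved, small enough that 200-replicate
runs complete in seconds. The published revertant totals (387 and 812 for
the two regions) constrain only the order of magnitude of sampling depth,
not per-allele frequencies, so the ≈70 %/≈50 % ≥2-hit fractions of the real
screens are not calibration targets; the simulator instead demonstrates
*qualitatively* that the ≥2-hit statistic shifts under detection-probability
skew.

What the simulator does not model: transformation efficiency, plasmid
integration, codon usage bias (primers are NNN; no bias data exists),
epistasis, and the host cell biology. Passing the recovery tests therefore
shows the *analysis* is correct and sensitive under the stated sampling
model, not that real screens are unbiased.

### Occupancy oracle

For m surviving draws uniform over N truth alleles, the expected numbers of
alleles seen ≥1 and ≥2 times are N(1 − qᵐ) and N(1 − qᵐ) − m·qᵐ⁻¹ with
q = 1 − 1/N. Uniform allele sampling is realized *through* the codon
machinery by setting each allele's detection probability to the reciprocal
of its codon multiplicity, which exactly cancels the genetic code's
degeneracy; with a single saturated position the surviving hit vector is
then exactly uniform-multinomial conditional on m, and the pooled simulated
≥2-hit fraction is compared to the pooled closed form with a delta-method
Monte-Carlo standard error.

## Hotspot calling

Hotspots are maximal runs of ≥ `min_run` consecutive positions with
substitution number ≥ `min_count` (defaults 5 and 3). Published hotspot
intervals were identified visually, so any numeric criterion is an
interpretation; the thresholds are exposed in config and recorded in the run
metadata, and interval recovery on real data is threshold-dependent.

## Packaged fixtures

The region fixtures use synthetic scaffold sequences: the residues named in
the published text are pinned at their true positions and the rest is a
deterministic filler (the full native sequences are not among the package's
inputs). The substitution fixtures are partial — only alleles whose wild
type and mutant are both named in the text — and carry unknown hit counts.
Analyses on these fixtures exercise the machinery; they do not reproduce the
complete published matrices, which exist only as figure images. The
abstract-level count of ~300 substitutions (113 + 188 = 301 by region) is
treated as a rounded figure and never reconciled programmatically.

## Known limitations

- Conservation scoring ignores phylogenetic redundancy (no sequence
  weighting), so over-represented clades compress entropy.
- The burial proxy is resolution-dependent: CA-only models need rescaled
  thresholds, and the default `burial_min` assumes all-atom packing density.
- Contact classification is purely geometric; no angular hydrogen-bond
  criteria or protonation states.
- Rotation measurement assumes the segment is quasi-linear; strongly curved
  segments make the principal axis a poor summary.
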