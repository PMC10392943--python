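# Methods

This note documents the models, conventions and numerical choices behind
the package, and what the synthetic tests do and do not establish about
real data.

## Units of analysis

An `AntibodyComplex` is one antibody — a heavy chain, optionally a light
chain — bound to one or more antigen chains. Antibody residues carry IMGT
numbering (from a sidecar table or pre-renumbered files; the package does
not implement alignment-based numbering, which is commodity infrastructure)
and regions from the IMGT CDR definitions: CDR1 = positions 27–38,
CDR2 = 56–65, CDR3 = 105–117, frameworks the complement. A complex with no
light chain is an sdAb.

Curation keeps complexes solved by X-ray crystallography at ≤ 3.0 Å with at
least one CDR atom within 4.5 Å of the antigen. The antigen size rule
defaults to *protein* mode (≥ 50 residues, the structural-database
convention separating proteins from peptides); a *peptide* mode inverts it.
Parsing drops waters and heterogens, resolves alternate locations to the
highest occupancy (ties: first in file order), rejects non-standard
residues in antibody chains and drops them with a warning in antigen
chains.

## Contact typing

All antibody/antigen atom pairs within the contact cutoff (4.5 Å; k-d tree
search, identical to all-pairs) are fingerprinted. The structural type is
exactly one of, in ladder order:

- covalent: d ≤ r_cov(i) + r_cov(j) + 0.4 Å,
- clash: d < r_vdw(i) + r_vdw(j) − 0.4 Å,
- vdw: d ≤ r_vdw(i) + r_vdw(j) + 0.1 Å,
- proximal otherwise.

Radii are Bondi van der Waals (C 1.70, N 1.55, O 1.52, S 1.80 Å) and
standard single-bond covalent radii. Specific types are added
independently: hydrogen bond (heavy-atom donor–acceptor ≤ 3.5 Å, with
donor/acceptor capability from residue+atom-name templates; no angle term
since crystallographic files rarely carry hydrogens), ionic (formal-charge
carriers Arg NE/NH*, Lys NZ, His ND1/NE2 versus Asp OD*, Glu OE*, OXT
within 4.0 Å), hydrophobic (two carbons, each bonded to no N/O per residue
topology, within 4.5 Å). Aromatic ring–ring, cation–π, halogen and carbonyl
types are not modelled separately; their geometries fall into vdw or
hydrophobic. All thresholds live in `InteractionConfig` and can be
recalibrated.

A residue pair is classified an **interaction** when at least one
non-covalent atom pair carries a vdw/hbond/ionic/hydrophobic type;
clash-only and proximal-only pairs are **contacts** and never interactions.
Inter-chain covalency indicates a parsing anomaly and is reported but never
counted. Interaction counting is per (atom pair, type): an atom pair that
is simultaneously vdw and hydrogen-bonded contributes two. Subsampled
type-composition statistics draw ⌊10%·N⌋ of the N interaction instances
without replacement, 1000 times, seeded.

## Binding-site definitions

- *distance*: residues with ≥ 1 atom contact;
- *interactions*: residues in ≥ 1 pair classified interaction (always a
  subset of the distance site — asserted as a test invariant);
- *sasa*: residues losing > 0.1 Å² of solvent-accessible surface on complex
  formation. The 0.1 Å² floor exists to keep numerical noise out of the
  site; a noise-free fixture yields identical sites at thresholds 0.1 and
  1.0.

## SASA and epitope accessibility

SASA is Shrake–Rupley with probe 1.4 Å on a deterministic golden-section
spiral lattice (default 960 points/atom), so values are exactly
reproducible run to run. The lattice is fixed in space, not body-fixed:
translation invariance is exact, rotation invariance holds to the
discretisation error (~1 Å² per residue at 960 points, shrinking roughly
as 1/points); this is the price of determinism and is tested at exactly
that tolerance. A single isolated carbon reproduces the analytic
4π(r+probe)² sphere to machine precision.

Relative per-residue SASA divides by the residue type's theoretical
maximum exposure (Tien et al. 2013 values, bundled as swappable data); it
can slightly exceed 1 for residues more exposed than the reference
tripeptide state. **Epitope accessibility** is the mean relative SASA of
the epitope residues computed on the antigen *with the antibody removed* —
the metric describes the epitope surface as a property of the antigen, and
equals the epitope's surface area relative to what the same residues would
expose in isolation (that denominator is one per residue by construction).
Whether the source analysis used the bound antigen conformation minus the
antibody or a separately solved unbound antigen is not recoverable; the
bound-conformation-minus-antibody reading is implemented.

## Profiles

Seven-class composition partitions the 20 amino acids: aliphatic
{A,G,I,L,P,V}, aromatic {F,W,Y}, sulfur {C,M}, hydroxyl {S,T}, basic
{R,H,K}, acidic {D,E}, amine {N,Q} (His with the basics, Gly and Pro with
the aliphatics). Epitope linearity calls a residue linear iff an epitope
residue sits at sequence index ±1 on the same chain (author numbering;
insertion codes ordered lexicographically; residues missing from the
crystal break contiguity). Loop contributions attribute paratope residues
and interaction counts to CDR-H1/H2/H3 (and L1/L2/L3), with per-loop counts
also normalised by loop length. Framework positions appearing in ≥ 10% of
a dataset's interactions-defined paratopes are ranked by frequency.

Redundancy filtering greedily clusters concatenated CDR sequences at ≥ 95%
identity (edlib global alignment; identity = 1 − distance/max length),
keeps the longest-CDR-H3 representative per cluster, then rescues
discarded members whose *epitope identity* to every kept complex is below
75%. Epitope identity globally aligns the two antigen sequences (match +1,
mismatch 0, gap −1), counts epitope positions aligned to epitope positions
with the same amino acid, and divides by the smaller epitope (symmetric
and conservative toward calling epitopes similar; a union denominator is
available). The greedy reimplementation may split clusters differently at
the margin than a word-based tool would; it is exact at package scale.

## CDR-H3 orientation

The VH-anchored frame: origin = centroid of the Cα of the six CDR-H3
anchors (IMGT 102–104, 118–120); z = unit vector from the framework Cα
centroid to the origin ("up"); y = component orthogonal to z of the
direction from the origin to the Cα centroid of the FR2 VL-interface
positions (42, 49, 50, 52); x = y × z (right-handed). For the loop centre
(backbone atoms N/Cα/C/O only, so side-chain disorder cannot move the
descriptor): ρ = its distance from the origin, θ = polar angle from z,
φ = azimuth from x toward y, wrapped to (−180°, 180°]; compactness = loop
residue count / ρ. This convention realises the intended semantics — high
φ points at the VL/FR2 face, high θ means the loop folds down — and is the
single convention used throughout; alternatives can be slotted in.
Structures missing anchor or loop backbone atoms are rejected with a
logged reason, and ρ < 0.5 Å is treated as degenerate. Loop length is the
residue count, not contour length.

## Loop clustering and the overlap null

Loops are comparable only at equal residue count; similarity is minimal
backbone RMSD over rigid superpositions (Kabsch via SVD, proper rotation
enforced), on the loop atoms directly with no anchor pre-alignment.
Greedy clustering processes loops in a pinned order (length descending,
then source id) and joins the first cluster whose representative is within
1.5 Å. The partition depends on input order only up to the guarantee that
every member lies within the cutoff of its representative; both facts are
tested. The expected number of Ab+sdAb overlap clusters under random
assignment permutes the labels into the observed cluster sizes (20
replicates by default, seeded) and reports mean ± sd; on small instances
the mean matches the exactly enumerated expectation.

## Sequence statistics

Per-position compositions drop positions occupied in < 5% of sequences and
renormalise. The expected cross-repertoire identity probability treats
positions as independent conditional on loop length:
Σ_L P_A(L)·P_B(L)·Π_pos Σ_aa f_A(aa|pos,L)·f_B(aa|pos,L). The observed
counterpart is the empirical probability that random draws from the two
sets coincide, Σ_s f_A(s)·f_B(s); because the statistic actually used for
the published "actual overlap" is not fully specified, the fraction of one
set's distinct sequences present in the other is emitted alongside.
Conservation is scored as the modal residue frequency and Shannon entropy
(bits over the observed letters, bounded by log₂20).

## Resampling statistics

Group differences (sdAb minus Ab) use the unpaired mean difference, a
percentile CI from 5000 bootstrap resamples of size 300 drawn with
replacement from each group (the fixed resample size is the study's stated
design, kept even though it is unusual; a group-size-respecting mode
exists), and a two-sided permutation test on the raw pooled data
(5000 shuffles, statistic = |difference of means|, +1 smoothing so p > 0).
Significance language is p < 0.05. With a fixed seed all outputs are
bit-reproducible; under a true null the empirical type-I error at 5% sits
in [0.03, 0.07] over 1000 simulations.

## Synthetic data: what it does and does not show

The generator optimises controllability, not realism. Residues are an
idealised rigid backbone plate plus at most one side-chain tip atom on a
5.5 Å stalk facing the interface; planned residue pairs are realised by
exactly one atom pair at an exact distance drawn from a motif vocabulary
(pure vdW at 3.25 Å, vdW+H-bond at 2.90 Å, hydrophobic C–C at 3.45 Å,
ionic at 3.80 Å, proximal-only at 4.00 Å, clash at 2.50 Å, ...), with slots
spaced 20 Å so nothing unplanned falls within the cutoff — validated by
brute force at generation time. Ground truth (membership under each site
definition, exact interaction counts) is therefore known by construction.
Loop scaffolds place the CDR-H3 backbone centre exactly at requested
(ρ, θ, φ) in a frame that evaluates to the identity, making generator and
descriptor mutual inverses. Repertoires draw lengths as
base + Poisson(mean) — defaults chosen to emulate CDR-H3-like lengths
(mean ≈ 14) and the two-population mode applies a specified mean shift
(default 1.4 residues, the magnitude of the sequence-repertoire CDR-H3
difference between sdAbs and Abs).

Passing tests on these fixtures establishes that the measurement chain is
correct — detection, typing, counting, geometry and statistics recover
designed truth exactly — not that thresholds are calibrated for real
crystal structures. Synthetic residues are sparse, so their relative SASA
can exceed 1 and benchmark accessibility values sit above the [0, 1] range
typical of real epitopes; accessibility fixtures therefore use
full-backbone glycine strands (exposed ≈ 0.89) and solid burial cages
(buried = 0). A hollow shell cannot bury anything under Shrake–Rupley —
interior cavity surface still counts as accessible — so burial cages are
solid slabs of blocker atoms hugging the target.

The synthetic worked-example pair (`SYNAB`/`SYNSDAB`) is a stand-in, not
the real SARS-CoV-2 RBD structures: its designed site sizes, loop lengths
and interaction counts mirror the published single-pair comparison so the
full reporting path can be exercised end to end. Running the real
comparison requires the user to supply the coordinate files with IMGT
numbering.

## Problem sizes

Default test and reproduction runs use deliberately small instances chosen
to exercise every code path: benchmarks of 12 complexes per group,
repertoires of 2000 sequences, 10⁴ replicates for the clustering null,
1000 simulations for statistical calibration, and 960-point SASA lattices.
All scale linearly (SASA quadratically in atom count per neighbourhood)
and the same code runs full structural-database corpora.

## Known limitations

- No hydrogen-bond angle criterion without explicit hydrogens; donors and
  acceptors come from fixed templates (no His protonation modelling).
- The Arpeggio-style type vocabulary is reduced (no ring–ring, cation–π,
  halogen, carbonyl or water-mediated types).
- IMGT numbering is consumed, never computed.
- mmCIF is not read; missing atoms are not modelled.
- The frame convention for loop orientation is a documented re-derivation
  of the intended semantics, not a byte-level reimplementation of any
  external tool.
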