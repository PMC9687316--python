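# Methods

This note documents the models, conventions and numerical choices behind
each stage of the package, what the synthetic generators do and do not
emulate, and the known limitations.

## Structures, confidence and fragment selection

Structures are read from PDB text into a light chain→residue→atom model.
Waters and HETATM records are dropped at parse time (the docking
preprocessing the pipeline mirrors removes them as well); for altloc
conflicts the highest-occupancy conformer is kept, first encountered on a
tie. Residue identity is (chain id, author number, insertion code), with
author numbering 1-based and all intervals inclusive — matching how residue
ranges are printed in the field.

Per-residue confidence is the mean of a residue's atomic B-factor values.
Predicted models write one pLDDT value per residue on every atom, so the
mean is exact there and a robust summary for mixed inputs. Fragment
extraction finds maximal runs of consecutive residues with confidence
strictly above the threshold (default 90; an inclusive comparison is a
flag), then merges runs separated by at most `merge_gap` low-confidence
residues (default 15) into one multi-run fragment. The default reproduces
the canonical two-fragment split of the BBM model, whose intra-fragment
gaps are at most 13 residues while the inter-fragment gap is 19. Both the
threshold and the gap are configuration, not constants.

## Pose clustering

Pairwise RMSD between poses is computed in nm over all atoms by default,
after optimal least-squares superposition (Kabsch, proper rotations only);
`fit=false` measures raw coordinates. Clustering is the Daura/GROMOS
scheme: repeatedly take the pose with the most neighbours within the cutoff
(neighbour means RMSD ≤ cutoff, the GROMOS convention of counting the
boundary), emit it with its neighbours as a cluster, remove them, repeat.
Two determinism choices the original scheme leaves open: equal neighbour
counts break toward the lower pose index, and equal-size clusters are
ordered by center index with the tie recorded explicitly — a size tie
between top clusters is meaningful (it changes which pose is
"representative") and is therefore surfaced rather than hidden. The
representative conformation is the center of the most populated cluster.
Docked scores are engine outputs consumed as a sidecar table; the only
arithmetic applied to them is the per-fragment arithmetic mean, reported to
one decimal.

## Interface analysis

SASA uses Shrake–Rupley quadrature with a deterministic golden-spiral point
set (default 960 points per atom), Bondi van der Waals radii and a 1.4 Å
probe, all shipped as configuration. The deterministic point set makes
repeated runs bit-identical and makes ΔSASA exactly non-negative when bound
and unbound states share coordinates: removing neighbours can only uncover
quadrature points. Against closed forms, one- and two-sphere areas agree to
well under 1% at 960 points.

A residue is interfacial when ΔSASA = SASA(own chain set alone) −
SASA(complex) > 0, i.e. burial is positive. Interfacial contacts are
cross-chain residue pairs whose minimal heavy-atom distance is ≤ 5.5 Å
(inclusive; hydrogens are absent from the consumed models), counted once
per pair and classified by the polarity classes of the two residues.

Binding affinity is a linear model over the six class-pair contact counts
plus the apolar and charged percentages of the non-interacting surface
(NIS): ΔG = Σ wᵢ·ICᵢ + w_a·%NIS_apolar + w_c·%NIS_charged + b, in
kcal/mol. The weights, intercept, residue classification (charged D/E/K/R;
polar C/H/N/Q/S/T/W/Y; apolar A/F/G/I/L/M/P/V), per-residue maximum
accessible areas and the 5% relative-SASA surface threshold ship in
`data/affinity_model.json` as versioned data, not code constants: the
convention is a published model choice, and treating it as data keeps it
replaceable and auditable. NIS percentages are computed over residues whose
relative SASA in the complex is at least the threshold. The dissociation
constant is Kd = exp(ΔG/RT) with R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹ and
T = 298.15 K by default. Because published ΔG values are rounded to one
decimal, a printed (ΔG, Kd) pair can only be checked for consistency within
±0.06 kcal/mol, which is the property the test suite asserts for all twenty
bundled pairs. Reports emit the full class-pair table plus both "polar:
polar" conventions (strict, and folding charged into polar), since the
reporting convention of the source tables is ambiguous on that point.

## Peptide design

Input residue lists use the printed stretch notation: comma-separated
tokens `K82`, `R-185` (equivalent forms) and `X` for a single missing
residue, with strictly increasing numbering; `X` inherits the previous
number plus one. In lenient mode a token breaking monotonicity — a table
typo — is reassigned the only consistent number (previous + 1) and the
repair is logged; strict mode raises. One such repair fires on the bundled
tables (M223 → M233).

A stretch is a maximal run in which consecutive present residues are at
most two apart, so every gap is an isolated single missing residue; two or
more consecutive missing residues end the stretch. A stretch may contain
any number of such single gaps — the reading required by the bundled
tables, where selected stretches carry up to three bridged gaps. Peptides
substitute glycine at every gap, and candidates keep stretches of at least
8 positions (bridged gaps included). Candidate ids P1… follow the published
ordering: stretch length descending, then BBM fragment (fragment-1
complexes first), then source table order, then position. Overlap scoring
counts the BBM-side interface residues of a peptide complex that fall
inside the fragment's DNA-binding range (210–276 and 312–370, shipped as
configuration and overridable per run).

Stretch extraction works from residue numbers alone, so two printed
single-residue stretches separated by exactly one missing residue (one such
adjacency exists in the bundled fragment-2 table, I118/A120) merge into one
three-position stretch; this affects no stretch near the selection
threshold.

## Trajectory metrics

RMSD fits each frame to the reference over the fit selection only and
measures over the measure selection — fitting on the protein while
measuring the peptide deliberately retains the peptide's translational
motion, the convention used when assessing peptide stability in a binding
cavity. RMSF superposes frames on their time-average (two fitting passes,
the common convention) and reports, per residue, the root mean square
displacement over all its atoms and frames, in nm. An isotropic
per-coordinate jitter of σ therefore has expected RMSF σ√3.

Hydrogen bonds are distance-only (default 3.5 Å) between template donor and
acceptor heavy atoms (N/O/S; backbone N is a donor except in proline,
backbone O always accepts), since the models carry no hydrogens for an
angle criterion. Hydrophobic contacts are cross-chain carbon–carbon pairs
within 4.0 Å, each atom annotated main-chain (N, CA, C, O, OXT) or
side-chain; a permissive LigPlot-style mode (any heavy-atom pair between
apolar residues) is available behind a flag because reported contact lists
sometimes include polar atoms of apolar residues.

## Synthetic data

Generators produce every input class with stored truth from one seeded
generator per call (fixed seed ⇒ identical bytes):

- *Confidence tracks*: ideal extended poly-alanine with scores drawn above
  90 exactly on planted segments and at or below 90 elsewhere.
- *Toy complexes*: rows of ideal alanine residues at controlled
  separations; requested contact pairs are slid together by bisection until
  the minimal heavy-atom distance equals the target (default 4.5 Å), all
  other cross-pairs stay beyond a 6.5 Å clearance (outside both the 5.5 Å
  contact rule and the ~6.2 Å burial horizon of carbon pairs), and a
  brute-force scan verifies the realised contact set before the structure
  is returned. This is an idealized arrangement, not a docked
  conformation: the ligand "chain" is not covalently continuous.
- *Pose ensembles*: cluster centers are random internal deformations of a
  reference chain — rigid transforms would vanish under superposition —
  kept at least `separation` (default 1.0 nm, required ≥ 4× spread) apart
  in fitted RMSD; members add Gaussian noise scaled to an RMSD at most the
  spread. The defaults separate cleanly at the 0.3 nm clustering cutoff.
- *Trajectories*: reference plus independent per-residue Gaussian jitter,
  with an optional constant rigid displacement of one chain after the first
  frame (for the fit/measure RMSD conventions).
- *Peptide chains*: NeRF-built heavy-atom backbones (N, CA, C, O, CB)
  with standard bond lengths/angles and extended (−120/+120) or helical
  (−57/−47) dihedrals.

What passing on synthetic data shows — and does not. The generators plant
geometric and statistical structure (contacts, clusters, mobility) but not
the physics of real complexes: no side-chain packing, no electrostatics,
no correlated motions, no realistic conformational sampling. Recovery of
planted truth validates the *metrics and algorithms*; it says nothing about
whether a particular docked pose or affinity estimate is physically right.

## Problem sizes and numerics

Test and analysis runs use small systems chosen to keep every check
closed-form-verifiable: toy complexes of ≤ 9 residues per chain, ensembles
of ≤ 100 poses of a 10–20-residue chain, trajectories of 2 000 frames for
RMSF recovery (where the 5% tolerance reflects the Monte-Carlo error and
the small fraction of fluctuation absorbed by fitting). SASA tolerances:
1% against closed forms at 960 points, < 0.5% change under point doubling.
Clustering is validated against an independently coded brute-force Daura
implementation on random matrices up to n = 20.

## Limitations

Docking, molecular dynamics and neural peptide folding are out of scope;
poses, trajectories and scores are inputs. mmCIF and nucleic-acid chains
are unsupported. The affinity model is the published linear contact model —
not a physics-based estimate — and NIS percentages depend on the bundled
maximum-ASA table and threshold, so absolute ΔG values on arbitrary
complexes should be read as that model's output, not ground truth.
Specific published pose-level numbers (per-complex contact counts, MD
cluster memberships, named hydrogen-bond partners) require the original
pose and trajectory files, which were not deposited; the package reproduces
the procedure and every desk-derivable quantity instead.
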