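# Methods

This note documents the models, conventions and numerical choices behind
metalloscan, and what the synthetic fixtures do and do not establish about
real data.

## Structures, symmetry and frames

Structures are read from PDB format (gemmi does the parsing); coordinates
stay in the file's orthogonal Å frame throughout — no superposition is ever
performed, because the intended use is comparison of isomorphous crystals
in a common frame. A cell deviation above 2 % between series members
triggers a warning. The orthogonalization matrix follows the PDB
convention; fractional/orthogonal transforms are exact inverses to 1e-9.

Space-group operators are stored as integer rotation matrices plus rational
translations in the fractional basis. Operator tables for P1 and P4₃2₁2
(the tetragonal group of the motivating crystals) are bundled as xyz-style
triplets; any other group can be supplied as a list of such strings, parsed
by the same case- and whitespace-tolerant parser. All altlocs are kept on
parsing; distance-based operations use the highest-occupancy altloc of a
donor atom.

## Symmetry mates and crystal contacts

A symmetry mate is one operator plus one integer lattice shift. The shift
enumeration is derived per axis from the fractional bounding boxes of the
reference and the transformed copy, so screw components that push an image
past one cell are included exactly (this covers at least the conventional
3×3×3 block and widens automatically for small cells or large radii); a
one-cell margin is added for non-orthogonal cells where the per-axis bound
is not tight. Contacts are reference-to-mate atom pairs within a cutoff
(default 4.0 Å, heavy atoms — the conventional crystal-contact threshold;
the source study does not state its own). Each (operator, shift, atom,
atom) combination is reported once, in canonical order; the same physical
contact seen from the other copy appears as its mirror entry, which keeps
the output identical to the brute-force oracle used in tests.

## Metal sites and anomalous peaks

Metals are detected by element (default Re) — never by ligand residue name,
since deposited codes vary. Donors are N/O/S atoms within the coordination
cutoff (default 3.0 Å, with a 0.8 Å sanity floor), searched over the
reference and its symmetry mates. Carboxylates with both oxygens in range
list both, the shorter first. Anomalous peak lists (CSV `x,y,z,height`,
orthogonal or fractional frame) are assigned greedily by distance, each
peak to at most one site, considering all symmetry images of the peak
within a 1.0 Å match radius.

Peak-height wavelength scaling uses the bundled f″ values (Re: 12.1 e at
0.976 Å, 5.9 e at Cu Kα 1.5418 Å); the expected ratio is simply
f″_a/f″_b since anomalous peak height is linear in f″. No Cromer–Liberman
computation is attempted — other wavelengths require user-supplied values.

## Precision model

The Cruickshank DPI is computed in two variants; the default uses R_free,

    DPI = sqrt(N_atoms / N_reflections) · completeness^(−1/3) · R_free · d_min,

the R-factor variant replaces the first factor by
sqrt(N_atoms/(N_reflections − N_params)) and requires the parameter count.
Refinement statistics are taken from the series manifest, never parsed from
REMARK records (header dialects are too unstable). Per-atom B-factor
scaling (su = DPI·sqrt(B/⟨B⟩)) is available but off by default; published
per-structure su brackets are reproduced by the unscaled model. Bond su is
the quadrature sum of two positional su values; display follows the
crystallographic convention of one significant digit on the su and the
matching decimal place on the value. "Equal within error" means
|Δ| ≤ k·combined-su with k = 2 by default; the z-score is always reported
so borderline verdicts stay auditable. For one low-resolution case the
published bracket is tighter than √2×DPI predicts, suggesting extra
scaling in the original error pipeline; that behaviour is flagged in tests'
expectations but deliberately not emulated.

## Covalency classification

Two reference families ship as versioned CSVs: Cordero-2008 single-bond
covalent radii (sums combine spreads in quadrature; Re–O = 2.17 (7) Å,
Re–N = 2.22 (7) Å) and small-molecule survey averages for Re tricarbonyl
donors (imidazole N 2.185 (7), carboxylate O 2.14 (6), amide N
2.18 (1) Å). Donor context is inferred from residue + atom names
(His → imidazole N, Asp/Glu → carboxylate O, Asn/Gln → amide N), falling
back to a generic-element reference with a warning. A distance is
*covalent* if consistent with either family at multiplier k, *weak*
otherwise up to the 3.0 Å cap, *none* beyond. The either-reference rule is
deliberate: the radius sum carries the wider spread and therefore dominates
marginal calls, while the survey value pins chemically specific cases. A
consequence worth noting: at low resolution (large su) a ~2.4–2.6 Å
contact can become formally consistent with the radius sum — the z-scores
make such verdicts transparent.

## Ring stacking and cages

Ring planes are least-squares fits (smallest principal axis of the centred
coordinates; planarity rmsd is the perpendicular rms). Interplanar angles
are folded into [0°, 90°], which maps the literature's 60–120° edge-to-face
band onto ≥ 60°. Two criteria sets are provided: *small-molecule*
(face-to-face d < 4.0 Å & angle < 30°; edge-to-face d < 5.5 Å &
angle ≥ 60°; intermediate otherwise below 5.5 Å) and *macromolecular*
(face-to-face restricted to d ∈ [3.3, 3.8] Å). His side-chain rings are
selected by atom names; ligand rings are perceived name-agnostically from
covalent connectivity (< 1.8 Å bonds, five-membered N-containing cycles).

The interaction network includes symmetry-mate rings and is closed under
the 5.5 Å cutoff, so mate–mate edges that complete a bridging cage are
kept. Symmetry produces duplicate copies of every cluster; components
whose underlying ring identity set is contained in an already-kept
component are suppressed, preferring the copy anchored on the most
reference rings. Centroid su defaults to the full atom-level su (no
1/√n reduction — the conservative choice, which also matches published
brackets better); the reduced variant is available.

## Time series

Sites sharing a binding-residue key merge into one trajectory; residue-free
metals fall back to positional matching within 1.5 Å (isomorphous
assumption; no superposition). Trends use Kendall's τ (tie-corrected,
scipy) rather than a fitted slope: the claim of interest is ordinal
("tends to increase"), and τ is robust to ties and makes no distributional
assumption. Trends are computed strictly within one wavelength group,
because anomalous peak heights at different wavelengths are not comparable.
Fewer than three points yields a no-trend result. Reports are
deterministic: fixed file names, sorted keys, byte-identical on rerun.

## Synthetic data: what it emulates and what it does not

The generator plants ideal-geometry fac-[Re(CO)₃(Imi)(H₂O)X] /
fac-[Re(CO)₃(Imi)₂X] complexes (Re–C 1.92 Å, C–O 1.15 Å collinear,
mutually cis carbonyls, imidazole N at 2.185 Å) on minimal His/Asp/Asn
side-chain stubs inside the study's tetragonal cell (a = b = 81.1,
c = 37.2 Å, P4₃2₁2), over the seven-week design with per-week occupancy
schedules and wavelengths; the default schedules mirror the published
study conditions. Ligand residues carry deposited-style codes (REI/VHL) to
keep detection name-agnostic. Manifest statistics are solved so the DPI
reproduces a requested target. Anomalous peaks sit on the metal with
height = base × occupancy × (f″(λ)/f″(Cu Kα)) + Gaussian noise — an
invented stand-in (real peak heights are far noisier than refined
occupancies) used to exercise the plumbing. Positional jitter is Gaussian
and off by default, so ground truth is exact unless requested.

The optional cage plants four ring centroids as a planar quadrilateral
whose cycle edges are the requested distances (diagonals pushed beyond the
network cutoff; triangle-inequality violations are rejected before any
file is written), with two rings placed as operator preimages so the cage
genuinely spans a crystal contact. Ring orientations come from per-ring
normal tilts; the planted pairwise angles are recorded in the ground
truth.

What passing on synthetic data does **not** show: robustness to real
crystallographic noise (disorder, anisotropy, radiation damage, occupancy
refinement bias), full protein context, or map-derived peak heights.
Conversely, exact recovery at zero jitter and 3σ-bounded recovery at
0.02 Å jitter do establish that the geometry, symmetry expansion, error
propagation and bookkeeping are internally correct.

## Problem sizes and defaults

Test fixtures use a handful of residues per structure; the full synthetic
series (7 structures, 4 sites, cage) analyses in a few seconds. Key
defaults, all configurable and echoed into every report: coordination
cutoff 3.0 Å, contact cutoff 4.0 Å, ring network 5.5 Å, peak match radius
1.0 Å, k = 2, DPI variant R_free, small-molecule stacking criteria.

## Known limitations

- PDB input only (no mmCIF); reflection data and maps are out of scope —
  peak lists are consumed, not computed.
- Occupancies are read from the input, never refined.
- Bundled symmetry covers P1 and P4₃2₁2; other groups need explicit
  operator strings.
- The covalency references cover Re with protein N/O donors; other metals
  use radius sums only unless survey values are supplied.
- Cage suppression by ring-identity containment assumes symmetry-duplicate
  clusters share their ring set; two genuinely distinct cages built from
  exactly the same rings would be merged into one report entry.
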