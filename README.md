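# metalloscan

Symmetry-aware analysis of covalent metal binding sites in protein crystal
structures, built for time-series studies of metalation — the motivating
case being fac-[Re(CO)₃]⁺ complexes binding hen egg-white lysozyme over
weeks of soaking, followed across isomorphous tetragonal (P4₃2₁2) crystals.

It answers, quantitatively, the questions a structural chemist asks of such
a series:

- **Where is the metal and what does it bind?** Metal sites are found by
  element, and their coordination spheres (N/O/S donors within 3 Å) are
  assembled over the reference molecule *and* its symmetry mates.
- **Is the bond covalent?** Every distance carries a standard uncertainty
  propagated from the Cruickshank diffraction precision index,
  DPI = √(N_atoms/N_refl) · C^(−1/3) · R_free · d_min,
  with bond su = √(su_a² + su_b²). A distance d is called covalent when
  |d − d_ref| ≤ k·√(su² + su_ref²) (k = 2) against either the Cordero
  covalent-radius sum (Re–O 2.17 (7) Å, Re–N 2.22 (7) Å) or a bundled
  small-molecule survey value for the donor chemistry (e.g. 2.185 (7) Å
  for imidazole N); otherwise it is a *weak* interaction up to a 3 Å cap.
- **How strong is the anomalous signal?** Peak heights from anomalous
  difference maps are matched to sites (symmetry-aware, greedy by
  distance), and the expected wavelength scaling is f″_a/f″_b — e.g.
  12.1 e at the Re L₁-edge-optimised 0.976 Å versus 5.9 e at Cu Kα gives
  the familiar 2.1× peak gain.
- **Do the complexes stack?** Aromatic rings get least-squares planes;
  ring pairs across crystal contacts are classified face-to-face
  (d < 4.0 Å, interplanar angle < 30°), edge-to-face (d < 5.5 Å,
  angle ≥ 60° after folding into [0°, 90°]) or intermediate, and connected
  components are reported as cages — such as the four-imidazole cage
  bridging two Asp-bound complexes of symmetry-related molecules.
- **What changes over time?** Sites are matched across the series by
  binding residue, and occupancy/peak-height trends are summarised with
  Kendall's τ, strictly within one wavelength group.

A first-class synthetic-data generator plants all of this geometry with
known ground truth, so the entire pipeline is testable offline.

## Worked example

```sh
python examples/detect_metal_sites.py
```

prints (a synthetic one-week crystal with a planted 2.185 Å Re–His bond and
a deliberately long 2.60 Å Re–Asn contact, DPI 0.026 Å):

```
2 metal sites found

  HIS15    Re-NE2  2.18 (4)   -> covalent (z(covalent_radii_sum)=0.4, z(csd_survey)=0.0)
  ASN46    Re-ND2  2.60 (4)   -> weak     (z(covalent_radii_sum)=4.8, z(csd_survey)=11.0)
```

`2.18 (4)` is crystallographic bracket notation: 2.18 ± 0.04 Å, the su
being √2 × DPI. The His bond sits within error of both references
(z ≤ 2), the Asn contact matches neither, hence *weak*.

The other examples cover error propagation (`error_propagation.py`),
crystal contacts with their generating operators (`crystal_contacts.py`),
the π-stacking cage across a symmetry contact (`ring_cage.py`) and the
seven-week occupancy-trend analysis (`time_series.py`). A thin CLI wraps
the same pipeline:

```sh
metalloscan fixtures --out fx --seed 1 --cage   # synthetic 7-week series
metalloscan series fx/manifest.json --out report
metalloscan analyze fx/week_09_0.976.pdb --stats-json stats.json
```

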