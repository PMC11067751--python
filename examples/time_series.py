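"""Track metal-site occupancies over a 38-week structure series.

Generates the default seven-week synthetic study (three covalent sites plus
a weak Asn interaction, occupancies drifting upward), matches the sites
across structures and summarises the per-wavelength trends with Kendall's
tau.
"""

import tempfile
from pathlib import Path

from metalloscan import CageSpec, FixtureConfig, generate_series
from metalloscan.pipeline import analyze_series

with tempfile.TemporaryDirectory() as tmp:
    manifest, _ = generate_series(FixtureConfig(seed=1, cage=CageSpec()), Path(tmp))
    result = analyze_series(manifest, out_dir=Path(tmp) / "report")

print("site trajectories:")
for traj in result["trajectories"]:
    points = traj.sorted_points()
    occ = ", ".join(f"w{p.week:g}:{p.occupancy:.2f}" for p in points)
    print(f"  {traj.site_key[2]}{traj.site_key[1]:<4d} ({len(points)} points)  {occ}")

print("\noccupancy trends (within one wavelength group):")
for t in result["trends"]:
    if t["attribute"] == "occupancy" and t["n"] >= 3:
        print(
            f"  {t['site']:8s} at {t['wavelength']:.3f} A: "
            f"tau = {t['kendall_tau']:+.2f} ({t['direction']}, n = {t['n']})"
        )
print(
    "\nPositive tau means the refined occupancy tends to rise with time;\n"
    "trends are never mixed across wavelengths because anomalous signals\n"
    "at different wavelengths are not comparable."
)
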