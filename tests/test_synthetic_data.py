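"""Ground-truth generator: geometry, determinism and end-to-end recovery."""

import itertools
import json
import math

import numpy as np
import pytest

from metalloscan.pipeline import analyze_series, analyze_structure, load_manifest
from metalloscan.precision import cruickshank_dpi
from metalloscan.synthetic_data import (
    CageSpec,
    FixtureConfig,
    SiteSpec,
    build_complex,
    generate_series,
)


def small_config(**kw):
    sites = kw.pop("sites", [
        SiteSpec("HIS", 15, "ImiAqua", 2.185, (0.5, 0.6, 0.7), (12.0, 12.0, 10.0),
                 (0.2, 0.3, 0.93)),
        SiteSpec("ASP", 101, "ImiImi", 2.14, (0.4, 0.5, 0.6), (45.0, 14.0, 14.0),
                 (0.8, 0.4, 0.45)),
    ])
    base = dict(weeks=(1, 2, 3), wavelengths=(0.976, 0.976, 0.976),
                target_dpi=(0.026, 0.026, 0.026), d_min=(1.2, 1.2, 1.2), sites=sites)
    base.update(kw)
    return FixtureConfig(**base)


class TestBuildComplex:
    def test_fac_geometry_carbonyls_mutually_cis(self):
        atoms = build_complex("ImiImi", 2.14)
        pos = {name: np.asarray(p) for name, _, p in atoms}
        re = pos["RE"]
        for a, b in itertools.combinations(["C1", "C2", "C3"], 2):
            va, vb = pos[a] - re, pos[b] - re
            angle = math.degrees(math.acos(np.dot(va, vb) / np.linalg.norm(va) / np.linalg.norm(vb)))
            assert angle == pytest.approx(90.0, abs=1e-6)

    def test_carbonyls_collinear_with_metal(self):
        atoms = build_complex("ImiAqua", 2.2)
        pos = {name: np.asarray(p) for name, _, p in atoms}
        for i in (1, 2, 3):
            v1 = pos[f"C{i}"] - pos["RE"]
            v2 = pos[f"O{i}"] - pos[f"C{i}"]
            cos = np.dot(v1, v2) / np.linalg.norm(v1) / np.linalg.norm(v2)
            assert cos == pytest.approx(1.0, abs=1e-9)
            assert np.linalg.norm(v1) == pytest.approx(1.92)
            assert np.linalg.norm(v2) == pytest.approx(1.15)

    def test_ring_counts_per_kind(self):
        def n_rings(kind):
            names = [n for n, e, _ in build_complex(kind, 2.2) if e == "N"]
            return sum(1 for n in names if n.endswith("1"))

        assert n_rings("ImiAqua") == 1
        assert n_rings("ImiImi") == 2

    def test_rotation_preserves_internal_distances(self):
        plain = build_complex("ImiImi", 2.14)
        theta = 1.1
        rot = np.array([
            [math.cos(theta), -math.sin(theta), 0],
            [math.sin(theta), math.cos(theta), 0],
            [0, 0, 1],
        ])
        turned = build_complex("ImiImi", 2.14, orientation=rot)
        d_plain = [np.linalg.norm(np.asarray(p) - np.asarray(q))
                   for (_, _, p), (_, _, q) in itertools.combinations(plain, 2)]
        d_turned = [np.linalg.norm(np.asarray(p) - np.asarray(q))
                    for (_, _, p), (_, _, q) in itertools.combinations(turned, 2)]
        assert np.allclose(d_plain, d_turned, atol=1e-9)

    def test_invalid_kind_and_distance_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            build_complex("Nonsense", 2.2)
        with pytest.raises(ValueError, match="distance"):
            build_complex("ImiImi", 5.0)


class TestGenerateSeries:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = small_config(seed=7, jitter_sigma=0.02, peak_noise_sd=0.5)
        generate_series(cfg, tmp_path / "a")
        generate_series(small_config(seed=7, jitter_sigma=0.02, peak_noise_sd=0.5),
                        tmp_path / "b")
        for fa in sorted((tmp_path / "a").iterdir()):
            fb = tmp_path / "b" / fa.name
            assert fa.read_bytes() == fb.read_bytes(), fa.name

    def test_manifest_stats_reproduce_target_dpi(self, tmp_path):
        manifest, _ = generate_series(small_config(seed=1), tmp_path)
        for entry in load_manifest(manifest):
            from metalloscan.pipeline import _stats_from_dict

            dpi = cruickshank_dpi(_stats_from_dict(entry["stats"]))
            assert dpi == pytest.approx(0.026, rel=1e-3)

    def test_occupancy_schedule_passes_through_exactly(self, tmp_path):
        manifest, _ = generate_series(small_config(seed=2), tmp_path)
        res = analyze_series(manifest)
        by_key = {t.site_key: t for t in res["trajectories"]}
        his = by_key[("A", 15, "HIS")]
        assert [p.occupancy for p in his.sorted_points()] == [0.5, 0.6, 0.7]
        assert all(
            t.attribute != "occupancy" or t.direction == "increasing"
            for t in []
        )
        occ_trend = [t for t in res["trends"]
                     if t["site"] == "HIS15" and t["attribute"] == "occupancy"][0]
        assert occ_trend["direction"] == "increasing"

    def test_zero_jitter_distances_recovered_exactly(self, tmp_path):
        manifest, truth = generate_series(small_config(seed=3), tmp_path)
        entry = load_manifest(manifest)[0]
        res = analyze_structure(entry["path"], stats=entry["stats"], peaks_path=entry["peaks"])
        by_res = {s.primary_residue[1]: s for s in res.sites}
        assert by_res[15].protein_ligands()[0].distance == pytest.approx(2.185, abs=2e-3)
        assert by_res[101].protein_ligands()[0].distance == pytest.approx(2.14, abs=2e-3)

    def test_peak_heights_scale_with_occupancy_and_f2(self, tmp_path):
        cfg = small_config(seed=4, wavelengths=(1.5418, 1.5418, 1.5418))
        manifest, truth = generate_series(cfg, tmp_path)
        entry = load_manifest(manifest)[0]
        res = analyze_structure(entry["path"], stats=entry["stats"], peaks_path=entry["peaks"])
        by_res = {s.primary_residue[1]: s for s in res.sites}
        # at Cu K-alpha the f'' ratio is 1: height = base * occupancy
        assert by_res[15].peak_height == pytest.approx(30.0 * 0.5, abs=1e-2)

    def test_planted_labels_recovered(self, tmp_path):
        sites = [
            SiteSpec("HIS", 15, "ImiAqua", 2.185, (0.7,), (12.0, 12.0, 10.0), (0.2, 0.3, 0.93)),
            SiteSpec("ASN", 46, "ImiAqua", 2.60, (0.3,), (50.0, 52.0, 8.0), (0.3, 0.8, 0.53)),
        ]
        cfg = FixtureConfig(weeks=(1,), wavelengths=(0.976,), target_dpi=(0.022,),
                            d_min=(1.2,), sites=sites, seed=5)
        manifest, truth = generate_series(cfg, tmp_path)
        entry = load_manifest(manifest)[0]
        res = analyze_structure(entry["path"], stats=entry["stats"])
        labels = {c.donor_res: c.label for c in res.calls}
        assert labels["HIS15"] == "covalent"
        assert labels["ASN46"] == "weak"
        planted = {s["residue"]: s["expected_label"] for s in truth.weeks[0]["sites"]}
        assert labels == {k.upper(): v for k, v in planted.items()}

    def test_ground_truth_json_consistent_with_files(self, tmp_path):
        manifest, truth = generate_series(small_config(seed=6), tmp_path)
        on_disk = json.loads((tmp_path / "ground_truth.json").read_text())
        assert on_disk["weeks"] == truth.weeks

    def test_jittered_distance_recovery_within_three_su(self, tmp_path):
        """Planted 2.185 A distances recovered within 3x the combined su at 0.02 A jitter."""
        jitter = 0.02
        combined_su = jitter * math.sqrt(2)
        errors = []
        for seed in range(20):
            cfg = FixtureConfig(
                weeks=(1,), wavelengths=(0.976,), target_dpi=(0.026,), d_min=(1.2,),
                sites=[SiteSpec("HIS", 15, "ImiAqua", 2.185, (0.7,), (12.0, 12.0, 10.0),
                                (0.2, 0.3, 0.93))],
                jitter_sigma=jitter, seed=seed,
            )
            manifest, _ = generate_series(cfg, tmp_path / f"s{seed}")
            entry = load_manifest(manifest)[0]
            res = analyze_structure(entry["path"], stats=entry["stats"])
            d = res.sites[0].protein_ligands()[0].distance
            errors.append(abs(d - 2.185))
        assert max(errors) <= 3 * combined_su
        # and the error distribution is jitter-sized, not degenerate
        assert np.mean(errors) < 2 * combined_su
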