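#!/usr/bin/env python
"""Validate the imaging pipeline on voxel phantoms with known geometry.

Builds carotid-like bifurcation phantoms at isotropic (0.5 mm) and
CTA-like anisotropic (2 x 0.5 x 0.5 mm) resolution — including a
carotid-sinus bulge variant — runs centerline extraction and both radius
methods, and tabulates measured vs true radii.  Shows that the
measurement windows recover ground truth to roughly half a voxel and
that the 6-12 radii ICA window is insensitive to the sinus bulge.

Writes results/phantom_recovery.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from bifex import (
    PhantomSpec,
    distance_map,
    extract_bifurcation,
    make_bifurcation_phantom,
    measure_bifurcation,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"

CASES = {
    "iso_0.5mm": PhantomSpec(spacing=(0.5, 0.5, 0.5)),
    "cta_2x0.5x0.5mm": PhantomSpec(spacing=(2.0, 0.5, 0.5)),
    "cta_sinus_bulge_1.4": PhantomSpec(spacing=(2.0, 0.5, 0.5), sinus_bulge_factor=1.4),
    "iso_asymmetric": PhantomSpec(r_cca=4.4, r_ica=3.0, r_eca=2.5,
                                  branch_angles=(30.0, 22.0), spacing=(0.5, 0.5, 0.5)),
}


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for name, spec in CASES.items():
        mask, gt = make_bifurcation_phantom(spec)
        bc = extract_bifurcation(mask, gt.markers)
        dmap = distance_map(mask)
        for method in ("A", "B"):
            t = measure_bifurcation(mask, bc, method=method, dmap=dmap)
            for branch, got, want in (
                ("cca", t.r_cca, spec.r_cca),
                ("ica", t.r_ica, spec.r_ica),
                ("eca", t.r_eca, spec.r_eca),
            ):
                rows.append(
                    {
                        "case": name, "method": method, "branch": branch,
                        "true_mm": want, "measured_mm": round(got, 4),
                        "error_mm": round(got - want, 4),
                        "half_voxel_mm": 0.5 * max(spec.spacing),
                    }
                )
        jerr = float(np.linalg.norm(bc.bifurcation_point - gt.bifurcation_point))
        print(f"{name}: junction localisation error {jerr:.2f} mm, "
              f"ICA tortuosity {bc.ica.tortuosity:.4f}")
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "phantom_recovery.csv", index=False)
    worst = df["error_mm"].abs().max()
    within = (df["error_mm"].abs() <= df["half_voxel_mm"]).mean()
    print(f"\n{len(CASES)} phantoms x 2 methods: worst radius error {worst:.3f} mm; "
          f"{within:.0%} of measurements within half the largest voxel dimension.")
    print(f"table -> {RESULTS / 'phantom_recovery.csv'}")


if __name__ == "__main__":
    main()
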