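#!/usr/bin/env python
"""Validate the perisomatic-shell construction against closed forms.

For spherical somata of several radii at the confocal voxel geometry
(0.111 x 0.111 x 0.33 um), compares the voxel-counted volume of the 5-um
in-plane shell with the analytic annulus-stack volume, and reports the
dilation radius in pixels.  Writes results/shell_geometry.csv.

Run from the repository root:  python analysis/04_shell_geometry_check.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

from fearframe.image_quant import CellStack, extract_perisomatic_shell

OUT = Path("results/shell_geometry.csv")
VOXEL = (0.33, 0.111, 0.111)
WIDTH = 5.0


def sphere_stack(r_um: float) -> CellStack:
    vz, vy, vx = VOXEL
    nz = int(2 * (r_um + 1.0) / vz) + 3
    nxy = int(2 * (r_um + WIDTH + 1.0) / vx) + 3
    cz, cxy = (nz - 1) / 2, (nxy - 1) / 2
    zz, yy, xx = np.meshgrid(
        np.arange(nz), np.arange(nxy), np.arange(nxy), indexing="ij", sparse=True
    )
    soma = (
        ((zz - cz) * vz) ** 2 + ((yy - cxy) * vy) ** 2 + ((xx - cxy) * vx) ** 2
    ) <= r_um**2
    return CellStack(
        signal=np.zeros((nz, nxy, nxy)), soma_mask=soma, voxel_size=VOXEL
    )


def analytic_volume(r_um: float, width_um: float, nz: int, cz: float) -> float:
    vz = VOXEL[0]
    total = 0.0
    for z in range(nz):
        dz = abs((z - cz) * vz)
        if dz <= r_um:
            rxy = np.sqrt(r_um**2 - dz**2)
            total += np.pi * ((rxy + width_um) ** 2 - rxy**2) * vz
    return total


def main() -> None:
    rows = []
    for r in (3.0, 4.0, 5.0, 6.0):
        stack = sphere_stack(r)
        shell = extract_perisomatic_shell(stack, WIDTH)
        vz, vy, vx = VOXEL
        vol = shell.n_voxels * vz * vy * vx
        nz = stack.soma_mask.shape[0]
        ana = analytic_volume(r, shell.radius_px * vx, nz, (nz - 1) / 2)
        err = abs(vol - ana) / ana
        rows.append(
            {
                "soma_radius_um": r,
                "dilation_radius_px": shell.radius_px,
                "voxel_counted_um3": vol,
                "analytic_um3": ana,
                "relative_error": err,
            }
        )
        print(
            f"r = {r:.1f} um: shell {vol:8.1f} um^3 vs analytic {ana:8.1f} "
            f"um^3 (radius {shell.radius_px} px, error {100 * err:.2f}%)"
        )
    OUT.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT, index=False)
    print(f"written {OUT}")


if __name__ == "__main__":
    main()
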