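"""DDM of a rendered movie of straight bulk swimmers.

Simulates 200 non-interacting swimmers with isotropic 3D directions
(mean speed 25 um/s, relative width S = 0.2), renders a 2000-frame movie at
100 fps and 0.5 um/px (256 x 256), computes the image structure function,
fits the Schulz-swimming intermediate scattering function per q, and reports
the band-averaged speed statistics and the path-straightness ratio
R = v(3 um)/v(13 um), which is 1 for straight paths.
Writes results/ddm/{structure_function.csv,ddm_summary.json}.
"""

from pathlib import Path

import pandas as pd

import hookmotility as hm
from hookmotility import io

OUT = Path(__file__).resolve().parent.parent / "results" / "ddm"
OUT.mkdir(parents=True, exist_ok=True)

tracks = hm.simulate_swimmers_3d(200, 20.0, 0.01, speed_mean=25.0,
                                 speed_rel_width=0.2, box_size=128.0,
                                 tumble_rate=0.0, seed=1)
stack = hm.render_movie(tracks, hm.OpticsConfig(image_size=256, pixel_size=0.5),
                        seed=2)
sf = hm.image_structure_function(stack)
fit = hm.fit_isf(sf)
summary = hm.ddm_summary(fit)

pd.DataFrame([{"q": q, "tau": t, "g": sf.g[i, j]} for i, q in enumerate(sf.q)
              for j, t in enumerate(sf.tau)]).to_csv(
    OUT / "structure_function.csv", index=False)
io.write_json(summary, OUT / "ddm_summary.json")

print(f"band-averaged speed v = {summary.v:.2f} um/s (simulated 25.0)")
print(f"relative width     S = {summary.S:.3f} (simulated 0.2)")
print(f"path straightness  R = {summary.R:.3f} (straight swimmers: 1)")
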