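"""Presence-only point-process model with a noisy climate covariate.

Sightings of a species are modelled on a temperature raster measured with
error; after the MCEM correction, the intensity surface is re-predicted
under a +1 degree warming scenario and the shift in the species' preferred
zone is summarised by the intensity-weighted mean northing.
"""

import numpy as np
import pandas as pd

from eivfit import (
    MeasurementErrorSpec,
    PointPattern,
    build_berman_turner,
    fit_ppm,
    predict_intensity,
)

rng = np.random.default_rng(4)
side = 50.0
window = (0, side, 0, side)
res = 2.0
xs = np.arange(res / 2, side, res)
gx, gy = np.meshgrid(xs, xs)
raster = pd.DataFrame({"x": gx.ravel(), "y": gy.ravel()})
# north-south temperature gradient, measured with error (sigma_u^2 = 0.25)
temp_true = 12.0 + 0.12 * raster["y"].to_numpy()
raster["temp"] = temp_true + rng.normal(0, 0.5, len(raster))

# species prefers ~15 degrees: quadratic log-intensity peak mid-window
lam = 0.5 * np.exp(-0.5 * (temp_true - 15.0) ** 2)
counts = rng.poisson(lam * res**2)
idx = np.repeat(np.arange(len(raster)), counts)
pts = raster[["x", "y"]].to_numpy()[idx] + rng.uniform(-1, 1, (len(idx), 2))
pattern = PointPattern(np.clip(pts, 0, side - 1e-9), window)
print(f"{pattern.m} sightings in a {side:g} x {side:g} window")

scheme = build_berman_turner(pattern, raster)
spec = MeasurementErrorSpec(["temp"], 0.25)
fitter, result = fit_ppm(scheme, ["poly(temp, 2)"], me_spec=spec, B=40,
                         seed=1, compute_se=False)

for shift in (0.0, 1.0):
    pred = predict_intensity(fitter, result.beta, raster,
                             shift={"temp": shift})
    lam_hat = pred["intensity"].to_numpy()
    northing = float(np.sum(lam_hat * pred["y"]) / lam_hat.sum())
    print(f"+{shift:.1f} deg scenario: intensity-weighted mean northing "
          f"= {northing:.1f}")
print("Warming moves the predicted distribution toward cooler (lower-y)")
print("cells: the species' suitable zone shifts along the gradient.")
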