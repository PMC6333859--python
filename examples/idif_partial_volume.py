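"""Image-derived input function with partial-volume correction.

Estimates the recovery coefficient (RC) and spill-in factor (SP) for a
6 mm carotid imaged at 5.4 mm FWHM, then shows that mixing a known input
with a background curve and correcting recovers the input exactly.
"""

import numpy as np

from epikinet import correct_idif, estimate_rc_sp, mix_carotid
from epikinet.idif import CylinderROISpec
from epikinet.kinetics import PlasmaInput

coeff = estimate_rc_sp(fwhm_mm=5.4, vessel_diameter_mm=6.0,
                       roi_spec=CylinderROISpec(roi_radius_mm=1.0, n_slices=2))
print(f"RC = {coeff.RC:.3f}  (fraction of true carotid signal recovered)")
print(f"SP = {coeff.SP:.3f}  (fraction of background spilling into the ROI)")

times = np.linspace(0.0, 10.0, 41)
true_input = PlasmaInput(times_min=times, values=80.0 * np.exp(-0.5 * times))
background = 10.0 + 2.0 * times

measured = mix_carotid(true_input, background, coeff)
recovered = correct_idif(measured, coeff)
err = np.abs(recovered.values - true_input.values).max()
print(f"max |recovered - true| after correction: {err:.2e} kBq/mL")
print("the correction inverts Cmeas = RC*Cinput + SP*Cbkgd pointwise;")
print("no blood-sample scaling is used anywhere (ASYM is scale-invariant).")
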