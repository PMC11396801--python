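"""Calibrate primer amplification efficiency from 5-fold dilution series.

Builds noiseless and noisy dilution series with known efficiencies, fits the
standard curve (Ct vs log10 concentration) and applies the acceptance rules
(90% <= E <= 120%, R^2 >= 0.99).
"""

from refstab import fit_standard_curve, primer_qc
from refstab.calibration import curves_to_frame
from refstab.synthetic import dilution_series

designed = {"SsRPL13": 1.026, "SsCDC6": 1.005, "SsNCBP2": 1.022, "SsGAPDH": 0.85}
curves, qcs = [], []
for primer, eff in designed.items():
    series = dilution_series(primer, eff, noise_sd=0.03, replicates=3, seed=11)
    curve = fit_standard_curve(series)
    curves.append(curve)
    qcs.append(primer_qc(curve))

print(curves_to_frame(curves, qcs).round(4).to_string())
# slope ~ -3.32 corresponds to perfect doubling (E = 100%); SsGAPDH was
# designed at 85% and must fail the efficiency band.
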