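"""The two closed-form quantification formulas used downstream of the
network analysis: caliper tumor volume and qPCR relative expression."""

import mirnetkit as mk

# ellipsoid approximation from two caliper diameters (mm)
v = mk.tumor_volume(d_large=8.0, d_small=5.0)
print(f"tumor volume for 8 x 5 mm: {v:.1f} mm^3  (V = pi/6 * d1 * d2^2)")

# comparative 2^-ddCt: target Ct 1.8 cycles earlier under treatment while
# the reference gene is unchanged -> ~3.5-fold up-regulation
ct = mk.CtQuadruple(
    ct_target_treated=22.2, ct_reference_treated=15.0,
    ct_target_control=24.0, ct_reference_control=15.0,
)
fc = mk.ddct_fold_change(ct)
print(f"relative expression 2^-ddCt: {fc:.2f}-fold vs control")

# a fold change > 1 means the target amplifies earlier (more template)
# in the treated sample after normalizing to the reference gene.
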