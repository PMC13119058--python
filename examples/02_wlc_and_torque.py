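"""Worm-like-chain force-extension and the force-to-torque conversion.

Evaluates the extensible WLC for lambda-DNA (48,502 bp, contour 16.4 µm) at
a few forces, inverts it back, and converts clamp forces to post-buckling
torques with the empirical power law torque = 12.7825 * F^0.63447 pN·nm.
"""

from pscloop import (TorqueModel, WLCParams, contour_length, force_to_torque,
                     wlc_extension_to_force, wlc_force_to_extension)

wlc = WLCParams()
print(f"lambda-DNA contour length: {contour_length(48_502):.2f} um")
for f in (0.5, 2.0, 5.0, 20.0):
    x = wlc_force_to_extension(wlc, f)
    back = wlc_extension_to_force(wlc, x)
    print(f"  F = {f:5.1f} pN -> x = {x:6.3f} um "
          f"({100 * x / wlc.contour_um:5.1f}% of contour; "
          f"round trip {back:.6f} pN)")

tm = TorqueModel()
print("\npost-buckling torque on a twisted tether:")
for f in (0.3, 0.5, 1.0, 2.0):
    print(f"  F = {f:4.1f} pN -> torque = {force_to_torque(tm, f):7.3f} pN*nm")
print("\nExtension saturates toward the contour length at high force; the\n"
      "torque at 1 pN equals the power law's coefficient by construction.")
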