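"""Single-cell action potential and APD90 calibration.

Paces one human atrial cell to steady state at a 600-ms cycle length,
measures the action-potential duration at 90% repolarization, and then
finds the delayed-rectifier scaling that shortens it to the two study
settings (223 and 180 ms).
"""

from biegm import (IonicParams, PacingProtocol, calibrate_apd,
                   measure_apd90, simulate_cell)

protocol = PacingProtocol(pcl=600.0, n_beats=20)

t, vm = simulate_cell(protocol=protocol)
print(f"unscaled model: rest {vm[0]:.1f} mV, peak {vm.max():.1f} mV, "
      f"APD90 {measure_apd90(vm, 0.02):.1f} ms")

for target in (223.0, 180.0):
    skr, sks = calibrate_apd(target, protocol)
    _, vm_s = simulate_cell(IonicParams(scale_kr=skr, scale_ks=sks), protocol)
    print(f"target APD90 {target:.0f} ms -> IKr/IKs scale {skr:.3f}, "
          f"achieved {measure_apd90(vm_s, 0.02):.1f} ms")

# The scale factor > 1 means both delayed-rectifier K+ conductances are
# increased jointly, which speeds repolarization and shortens the APD.
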