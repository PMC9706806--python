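"""Build the calibration designs and simulate the sensor-array measurements.

Creates the 27-mixture tilted 3^3 factorial training design and the 10-mixture
random testing design over 2–300 μM, then measures every mixture with the
default 4-sensor MIP/NIP array at default noise.
"""
import numpy as np

import etongue as et

train = et.make_factorial_design(et.DesignSpec())
test = et.make_random_test_set(10, seed=7)
print(f"training design: {len(train)} mixtures, testing design: {len(test)}")
levels = sorted({float(s.concentrations[0]) for s in train})
print(f"CFX levels in the training design (μM): {levels}")

bank = et.default_sensor_bank()
measurement = et.simulate_array(bank, train[13], noise=et.NoiseSpec(seed=1))
print(f"\nsample {train[13].sample_id}: concentrations "
      f"{np.round(train[13].concentrations, 1)} μM")
for t in measurement.traces:
    corrected = et.correct_baseline(t)
    print(f"  {t.sensor_id:8s}: {len(t)} points, corrected peak current "
          f"{corrected.currents.max():6.3f} μA")
# Each MIP draws the largest current near its own template's peak potential;
# the NIP trace is weakest — that contrast is what the array exploits.
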