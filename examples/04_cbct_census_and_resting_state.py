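"""Multi-region rodent brain: composition census and cerebellar rest.

Prints the full-scale regional census (exactly the published totals) and
then simulates one reduced-scale cerebellar module under the packaged
calibrated Poisson drive, reporting resting rates per population.  The
mossy-fiber (Pons) rate is the model's calibration point at 8 Hz.
"""

from embsnn import KernelConfig
from embsnn.netbuilders import cbct

census = cbct.census_cbct(1.0)
print("full-scale census (scale 1):")
for region, n in census["regions"].items():
    print(f"  {region:6s} {n:>9,}")
print(f"  total  {census['total_neurons']:>9,} neurons over "
      f"{census['n_layers']} layers")

h = cbct.build_cerebellum(0.02, config=KernelConfig(seed=1))
print(f"\ncerebellar module at scale 0.02: {h.n_neurons_built:,} neurons; "
      f"simulating 2 s of rest ...")
h.net.simulate(2000.0)
for key in h.by_key:
    print(f"  {key:26s} {h.rate(key, 500.0, 2000.0):6.2f} Hz")
# granule cells fire sparsely, Purkinje cells regularly, and the Pons
# (mossy fibers) sits at its 8 Hz calibration point
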