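"""Constructors for the benchmark networks.

`brunel` builds the scale-parameterized balanced random network (fixed
indegree 11,250, power-law STDP on the excitatory-excitatory synapses);
`cbct` builds the multi-region cortico-basal ganglia-cerebellar-thalamic
rodent brain from the packaged composition table.  Both offer exact
dry-run censuses that count nodes and connections without instantiating
anything.
"""

import numpy as np

from .. import rng

__all__ = ["place_neurons_2d"]


def place_neurons_2d(n: int, extent_mm: float, seed: int,
                     stream_key: int = 0) -> np.ndarray:
    """n i.i.d. uniform positions on [0, extent]^2 from a keyed stream.

    ``stream_key`` identifies the population (conventionally its first
    global id), so placement is independent of worker count and call
    order.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if extent_mm <= 0:
        raise ValueError("extent must be > 0")
    if n == 0:
        return np.empty((0, 2))
    idx = np.arange(n, dtype=np.int64)
    x = rng.uniform(seed, rng.PURPOSE["positions"], stream_key, idx, 0)
    y = rng.uniform(seed, rng.PURPOSE["positions"], stream_key, idx, 1)
    return np.column_stack([x, y]) * extent_mm


from . import brunel, cbct                             # noqa: E402,F401
from .calibrate import calibrate_resting_input         # noqa: E402,F401

__all__ += ["brunel", "cbct", "calibrate_resting_input"]
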