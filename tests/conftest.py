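"""Shared test environment.

BLAS thread pools are pinned to one thread before numpy loads so that
MCMC trajectories (which branch on floating-point comparisons) are
bit-identical across machines with different core counts.
"""

import os

for _var in (
    "OMP_NUM_THREADS",
    "OPENBLAS_NUM_THREADS",
    "MKL_NUM_THREADS",
    "NUMEXPR_NUM_THREADS",
):
    os.environ.setdefault(_var, "1")
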