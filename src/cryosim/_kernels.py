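"""Optional numba-accelerated kernels.

The only hot loop in the simulator is the cohort-to-cohort coancestry
propagation (10,100^2 entries per generation at full scale).  A pure-numpy
implementation exists in :mod:`cryosim.pedigree`; when numba is importable the
fused upper-triangle kernel below is used instead.  Both paths are exercised
against the recursive pair oracle in the test suite.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    import numba

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    numba = None
    HAVE_NUMBA = False


if HAVE_NUMBA:

    @numba.njit(cache=True)
    def _propagate_offspring_block(P, s, d, out):  # pragma: no cover - jitted
        """out[i,j] = mean of the four parental coancestries, diag = (1+F)/2.

        P is the (symmetric) coancestry matrix over the parent generation,
        s/d the parent row indices of each offspring.  Only the upper
        triangle is computed and mirrored.
        """
        n = s.shape[0]
        for i in range(n):
            si = s[i]
            di = d[i]
            for j in range(i + 1, n):
                v = 0.25 * (P[si, s[j]] + P[si, d[j]] + P[di, s[j]] + P[di, d[j]])
                out[i, j] = v
                out[j, i] = v
            out[i, i] = 0.5 * (1.0 + P[si, di])
        return out

    def propagate_offspring_block(
        parent_phi: np.ndarray, sire_idx: np.ndarray, dam_idx: np.ndarray
    ) -> np.ndarray:
        out = np.empty((len(sire_idx), len(sire_idx)), dtype=parent_phi.dtype)
        _propagate_offspring_block(
            parent_phi,
            np.ascontiguousarray(sire_idx, dtype=np.int64),
            np.ascontiguousarray(dam_idx, dtype=np.int64),
            out,
        )
        return out

else:
    propagate_offspring_block = None
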