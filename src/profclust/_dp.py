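"""Dynamic-programming kernel for the internal profile scorer.

A profile *pass* is a glocal alignment: every match column of the profile is
consumed in order (by a match or a deletion), while sequence residues outside
the pass are free. Insertions inside the profile and deletions of profile
columns carry affine penalties. In multihit mode a sequence may be aligned by
several non-overlapping passes whose scores add up — this is what lets a
tandem-repeat sequence accumulate an elevated full-sequence score, mirroring
the behaviour of full-sequence profile-HMM bit scores on repeat proteins.

The kernel is numba-compiled; the recurrence is deliberately simple so that
an exhaustive path-enumeration oracle can reproduce it exactly on tiny
instances.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: sentinel used inside the DP for "unreachable"; far below any real score
NEG = -1e30


@njit(cache=True)
def score_batch(em, codes, lengths, gap_open, gap_ext, multihit, max_passes):
    """Score a batch of encoded sequences against one emission matrix.

    Parameters
    ----------
    em : (L, A) float64
        Per-match-column emission log-odds; the last alphabet slot is the
        catch-all for unknown residues (log-odds 0).
    codes : (S, nmax) int8
        Residue codes per sequence, padded arbitrarily beyond each length.
    lengths : (S,) int64
    gap_open, gap_ext : float
        Affine penalties in bits (negative).
    multihit : bool
        When True, allow several passes (scores add); when False a single
        pass (best-domain score).
    max_passes : int
        Sweep cap for multihit chaining.

    Returns
    -------
    (S,) float64 raw scores (may be negative; caller applies the floor).
    """
    S, _ = codes.shape
    L = em.shape[0]
    out = np.empty(S, dtype=np.float64)
    M = np.empty(L + 1, dtype=np.float64)
    I = np.empty(L + 1, dtype=np.float64)
    D = np.empty(L + 1, dtype=np.float64)
    Mp = np.empty(L + 1, dtype=np.float64)
    Ip = np.empty(L + 1, dtype=np.float64)
    Dp = np.empty(L + 1, dtype=np.float64)
    for s in range(S):
        n = lengths[s]
        entry = np.zeros(n + 1, dtype=np.float64)
        F = np.full(n + 1, NEG, dtype=np.float64)
        F_old = np.full(n + 1, NEG, dtype=np.float64)
        npass = max_passes if multihit else 1
        for _p in range(npass):
            for i in range(n + 1):
                F_old[i] = F[i]
            # sequence position 0: the only way through columns is deletion
            Mp[0] = NEG
            Ip[0] = NEG
            Dp[0] = NEG
            for j in range(1, L + 1):
                Mp[j] = NEG
                Ip[j] = NEG
                if j == 1:
                    Dp[j] = entry[0] + gap_open
                else:
                    Dp[j] = Dp[j - 1] + gap_ext
            f0 = F[0]
            if Dp[L] > f0:
                f0 = Dp[L]
            F[0] = f0
            for i in range(1, n + 1):
                c = codes[s, i - 1]
                M[0] = NEG
                I[0] = NEG
                D[0] = NEG
                for j in range(1, L + 1):
                    # match: consume column j and residue i
                    if j == 1:
                        b = entry[i - 1]
                    else:
                        b = Mp[j - 1]
                        if Ip[j - 1] > b:
                            b = Ip[j - 1]
                        if Dp[j - 1] > b:
                            b = Dp[j - 1]
                    M[j] = em[j - 1, c] + b
                    # insertion after column j (interior only; flanking
                    # residues are handled by the free state)
                    if 1 <= j <= L - 1:
                        b = Mp[j]
                        if Dp[j] > b:
                            b = Dp[j]
                        v = b + gap_open
                        if Ip[j] + gap_ext > v:
                            v = Ip[j] + gap_ext
                        I[j] = v
                    else:
                        I[j] = NEG
                    # deletion of column j at the same sequence position
                    if j == 1:
                        b = entry[i]
                        v = b + gap_open
                    else:
                        b = M[j - 1]
                        if I[j - 1] > b:
                            b = I[j - 1]
                        v = b + gap_open
                        if D[j - 1] + gap_ext > v:
                            v = D[j - 1] + gap_ext
                    D[j] = v
                ce = M[L] if M[L] > D[L] else D[L]
                f = F[i - 1] if F[i - 1] > F[i] else F[i]
                if ce > f:
                    f = ce
                F[i] = f
                for j in range(L + 1):
                    Mp[j] = M[j]
                    Ip[j] = I[j]
                    Dp[j] = D[j]
            improved = False
            for i in range(n + 1):
                if F[i] > F_old[i] + 1e-12:
                    improved = True
                    break
            if not improved:
                break
            # chain further passes after any completed prefix (or start fresh)
            for i in range(n + 1):
                e = F[i]
                if e < 0.0:
                    e = 0.0
                entry[i] = e
        out[s] = F[n]
    return out
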