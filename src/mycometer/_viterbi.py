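"""Numba kernel for local profile-HMM Viterbi scanning.

The model is a Plan7-style local architecture: free entry into any match
state (uniform begin, log2(1/M)), free exit from any match state, match /
insert / delete chain in between.  Scores are log2-odds against the
background, so insert emissions (background) contribute 0 and unaligned
flanking sequence needs no explicit state.

For every sequence position ``i`` the kernel reports the best score of any
local alignment ending with a match at ``i`` and the sequence position where
that alignment started, which is all the hit finder needs.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e30


@njit(nogil=True)
def scan_kernel(seq, mllr, tmm, tmi, tmd, tim, tii, tdm, tdd, entry):
    n = seq.shape[0]
    M = mllr.shape[0]
    vm_p = np.full(M, NEG)
    vi_p = np.full(M, NEG)
    vd_p = np.full(M, NEG)
    sm_p = np.zeros(M, np.int64)
    si_p = np.zeros(M, np.int64)
    sd_p = np.zeros(M, np.int64)
    vm_c = np.full(M, NEG)
    vi_c = np.full(M, NEG)
    vd_c = np.full(M, NEG)
    sm_c = np.zeros(M, np.int64)
    si_c = np.zeros(M, np.int64)
    sd_c = np.zeros(M, np.int64)
    end_score = np.empty(n)
    end_start = np.zeros(n, np.int64)
    for i in range(n):
        c = seq[i]
        best_end = NEG
        best_end_s = i
        for j in range(M):
            # match state M_j, consumes seq[i]
            b = entry
            s = i
            if j > 0:
                v = vm_p[j - 1] + tmm[j - 1]
                if v > b:
                    b = v
                    s = sm_p[j - 1]
                v = vi_p[j - 1] + tim[j - 1]
                if v > b:
                    b = v
                    s = si_p[j - 1]
                v = vd_p[j - 1] + tdm[j - 1]
                if v > b:
                    b = v
                    s = sd_p[j - 1]
            vm_c[j] = mllr[j, c] + b
            sm_c[j] = s
            # insert state I_j (exists between j and j+1), emits background
            if j < M - 1:
                vi_val = vm_p[j] + tmi[j]
                vi_s = sm_p[j]
                v = vi_p[j] + tii[j]
                if v > vi_val:
                    vi_val = v
                    vi_s = si_p[j]
                vi_c[j] = vi_val
                si_c[j] = vi_s
            else:
                vi_c[j] = NEG
                si_c[j] = i
            # delete state D_j, consumes nothing (same column i)
            if j >= 1:
                vd_val = vm_c[j - 1] + tmd[j - 1]
                vd_s = sm_c[j - 1]
                v = vd_c[j - 1] + tdd[j - 1]
                if v > vd_val:
                    vd_val = v
                    vd_s = sd_c[j - 1]
                vd_c[j] = vd_val
                sd_c[j] = vd_s
            else:
                vd_c[j] = NEG
                sd_c[j] = i
            if vm_c[j] > best_end:
                best_end = vm_c[j]
                best_end_s = sm_c[j]
        end_score[i] = best_end
        end_start[i] = best_end_s
        vm_p, vm_c = vm_c, vm_p
        vi_p, vi_c = vi_c, vi_p
        vd_p, vd_c = vd_c, vd_p
        sm_p, sm_c = sm_c, sm_p
        si_p, si_c = si_c, si_p
        sd_p, sd_c = sd_c, sd_p
    return end_score, end_start
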