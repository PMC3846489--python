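"""Numba kernels for the haplotype-copying HMM.

Hidden states are reference haplotypes; between adjacent markers the chain
stays on its template with probability ``1 - rho`` and otherwise jumps to a
template drawn uniformly (self included). Emissions are ``1 - copy_error``
on allele match and ``copy_error`` on mismatch; missing observations emit
nothing. ``skip1``/``skip2`` exclude an animal's own rows when it is phased
conditionally on the rest of the panel (pass -1 to use every row).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _emission_split(H, f, j, skip1, skip2):
    """Return (mass on templates carrying allele 1, total mass) at marker j."""
    K = H.shape[0]
    s1 = 0.0
    s = 0.0
    for k in range(K):
        if k == skip1 or k == skip2:
            continue
        fk = f[k]
        s += fk
        if H[k, j] == 1:
            s1 += fk
    return s1, s


@njit(cache=True)
def _transition(f, rho_j, skip1, skip2, k_eff):
    K = f.shape[0]
    if rho_j <= 0.0:
        return
    s = 0.0
    for k in range(K):
        if k == skip1 or k == skip2:
            continue
        s += f[k]
    share = rho_j * s / k_eff
    for k in range(K):
        if k == skip1 or k == skip2:
            continue
        f[k] = (1.0 - rho_j) * f[k] + share


@njit(cache=True)
def _apply_emission(H, f, j, allele, ce, skip1, skip2):
    K = H.shape[0]
    s = 0.0
    for k in range(K):
        if k == skip1 or k == skip2:
            continue
        e = (1.0 - ce) if H[k, j] == allele else ce
        f[k] *= e
        s += f[k]
    if s > 0.0:
        for k in range(K):
            if k == skip1 or k == skip2:
                continue
            f[k] /= s


@njit(cache=True)
def diploid_viterbi_orientation(Hobs, g_obs, rho_obs, ce, out1, out2):
    """Diploid copying Viterbi over the observed markers of one animal.

    States are ordered pairs of reference haplotypes; the transition
    factorizes per chain, so the maximization uses row/column/global
    maxima of the previous value matrix (O(K^2) per site). The MAP pair
    path is traced back and each observed site's phased alleles are read
    off it (the path breaks the chain-exchange symmetry that makes
    per-site orientation marginals uninformative).
    """
    K, M = Hobs.shape
    v = np.full((K, K), 1.0 / (K * K))
    case = np.zeros((M, K, K), dtype=np.uint8)
    row_arg = np.zeros((M, K), dtype=np.int32)
    col_arg = np.zeros((M, K), dtype=np.int32)
    glob_arg = np.zeros((M, 2), dtype=np.int32)
    w1 = np.zeros(K)
    w0 = np.zeros(K)
    new_v = np.zeros((K, K))
    for j in range(M):
        if j > 0:
            r = rho_obs[j]
            c_stay = 1.0 - r + r / K
            c_jump = r / K
            # row maxima over second index, column maxima over first
            rm = np.zeros(K)
            cm = np.zeros(K)
            gm = -1.0
            g1 = 0
            g2 = 0
            for k1 in range(K):
                best = -1.0
                bi = 0
                for k2 in range(K):
                    if v[k1, k2] > best:
                        best = v[k1, k2]
                        bi = k2
                rm[k1] = best
                row_arg[j, k1] = bi
                if best > gm:
                    gm = best
                    g1 = k1
                    g2 = bi
            for k2 in range(K):
                best = -1.0
                bi = 0
                for k1 in range(K):
                    if v[k1, k2] > best:
                        best = v[k1, k2]
                        bi = k1
                cm[k2] = best
                col_arg[j, k2] = bi
            glob_arg[j, 0] = g1
            glob_arg[j, 1] = g2
            for l1 in range(K):
                for l2 in range(K):
                    o0 = c_stay * c_stay * v[l1, l2]
                    o1 = c_stay * c_jump * rm[l1]
                    o2 = c_jump * c_stay * cm[l2]
                    o3 = c_jump * c_jump * gm
                    best = o0
                    bc = 0
                    if o1 > best:
                        best = o1
                        bc = 1
                    if o2 > best:
                        best = o2
                        bc = 2
                    if o3 > best:
                        best = o3
                        bc = 3
                    new_v[l1, l2] = best
                    case[j, l1, l2] = bc
            for l1 in range(K):
                for l2 in range(K):
                    v[l1, l2] = new_v[l1, l2]
        g = g_obs[j]
        vmax = 0.0
        for k in range(K):
            if Hobs[k, j] == 1:
                w1[k] = 1.0 - ce
                w0[k] = ce
            else:
                w1[k] = ce
                w0[k] = 1.0 - ce
        for k1 in range(K):
            for k2 in range(K):
                if g == 0:
                    e = w0[k1] * w0[k2]
                elif g == 2:
                    e = w1[k1] * w1[k2]
                elif g == 1:
                    e = w1[k1] * w0[k2] + w0[k1] * w1[k2]
                else:
                    e = 1.0
                v[k1, k2] *= e
                if v[k1, k2] > vmax:
                    vmax = v[k1, k2]
        if vmax > 0.0:
            for k1 in range(K):
                for k2 in range(K):
                    v[k1, k2] /= vmax
    # final argmax and traceback
    b1 = 0
    b2 = 0
    best = -1.0
    for k1 in range(K):
        for k2 in range(K):
            if v[k1, k2] > best:
                best = v[k1, k2]
                b1 = k1
                b2 = k2
    path1 = np.zeros(M, dtype=np.int32)
    path2 = np.zeros(M, dtype=np.int32)
    path1[M - 1] = b1
    path2[M - 1] = b2
    for j in range(M - 1, 0, -1):
        c = case[j, b1, b2]
        if c == 1:
            b2 = row_arg[j, b1]
        elif c == 2:
            b1 = col_arg[j, b2]
        elif c == 3:
            b1 = glob_arg[j, 0]
            b2 = glob_arg[j, 1]
        path1[j - 1] = b1
        path2[j - 1] = b2
    for j in range(M):
        g = g_obs[j]
        k1 = path1[j]
        k2 = path2[j]
        if g == 0:
            out1[j] = 0
            out2[j] = 0
        elif g == 2:
            out1[j] = 1
            out2[j] = 1
        elif g == 1:
            h1j = Hobs[k1, j]
            h2j = Hobs[k2, j]
            if h1j == 1 and h2j == 0:
                out1[j] = 1
                out2[j] = 0
            elif h1j == 0 and h2j == 1:
                out1[j] = 0
                out2[j] = 1
            else:
                # templates agree: orientation arbitrary but deterministic
                out1[j] = 1
                out2[j] = 0
        else:
            # missing call: copy the path's template alleles
            out1[j] = Hobs[k1, j]
            out2[j] = Hobs[k2, j]


@njit(cache=True)
def forward_backward_alleles(H, skip1, skip2, obs, rho, ce):
    """Posterior alternate-allele probability per marker for one chain.

    ``obs`` holds haploid alleles (0/1, -1 missing). Returns a float64
    vector of P(allele = 1) at every marker.
    """
    K, M = H.shape
    k_eff = K
    if skip1 >= 0:
        k_eff -= 1
    if skip2 >= 0:
        k_eff -= 1
    F = np.zeros((M, K))
    f = np.zeros(K)
    for k in range(K):
        if k == skip1 or k == skip2:
            continue
        f[k] = 1.0 / k_eff
    for j in range(M):
        if j > 0:
            _transition(f, rho[j], skip1, skip2, k_eff)
        if obs[j] >= 0:
            _apply_emission(H, f, j, obs[j], ce, skip1, skip2)
        for k in range(K):
            F[j, k] = f[k]
    p1 = np.zeros(M)
    b = np.zeros(K)
    for k in range(K):
        if k == skip1 or k == skip2:
            continue
        b[k] = 1.0
    for j in range(M - 1, -1, -1):
        # posterior at j
        s = 0.0
        g1 = 0.0
        for k in range(K):
            if k == skip1 or k == skip2:
                continue
            g = F[j, k] * b[k]
            s += g
            if H[k, j] == 1:
                g1 += g
        if s > 0.0:
            g1 /= s
        p1[j] = (1.0 - ce) * g1 + ce * (1.0 - g1)
        if j == 0:
            break
        # fold emission at j into b, then transition back across (j-1, j)
        v = np.zeros(K)
        sv = 0.0
        for k in range(K):
            if k == skip1 or k == skip2:
                continue
            e = 1.0
            if obs[j] >= 0:
                e = (1.0 - ce) if H[k, j] == obs[j] else ce
            v[k] = e * b[k]
            sv += v[k]
        rj = rho[j]
        share = rj * sv / k_eff
        for k in range(K):
            if k == skip1 or k == skip2:
                continue
            b[k] = (1.0 - rj) * v[k] + share
        # rescale to avoid underflow
        sb = 0.0
        for k in range(K):
            sb += b[k]
        if sb > 0.0:
            for k in range(K):
                b[k] /= sb
    return p1
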