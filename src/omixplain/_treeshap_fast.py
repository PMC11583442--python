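"""Compiled (numba) kernel for exact tree attributions.

Same algorithm as the pure-Python reference in :mod:`omixplain.explain`
(path-dependent polynomial-time Shapley attribution over root→leaf paths),
rewritten with an explicit traversal stack and undo operations so a single
set of path arrays is reused: extending the feature-weight polynomial is
order-independent, so a parent's state is restored by unwinding the child's
element and re-extending any merged-out duplicate.  The two implementations
are cross-checked in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _extend(pf, pz, po, pw, m, zero, one, feature):
    pf[m] = feature
    pz[m] = zero
    po[m] = one
    pw[m] = 1.0 if m == 0 else 0.0
    for i in range(m - 1, -1, -1):
        pw[i + 1] += one * pw[i] * (i + 1.0) / (m + 1.0)
        pw[i] = zero * pw[i] * (m - i) / (m + 1.0)
    return m + 1


@njit(cache=False)
def _unwind(pf, pz, po, pw, m, idx):
    # removes element idx from a path of m elements; returns m - 1
    depth = m - 1
    one = po[idx]
    zero = pz[idx]
    nxt = pw[depth]
    for i in range(depth - 1, -1, -1):
        if one != 0.0:
            tmp = pw[i]
            pw[i] = nxt * (depth + 1.0) / ((i + 1.0) * one)
            nxt = tmp - pw[i] * zero * (depth - i) / (depth + 1.0)
        else:
            pw[i] = pw[i] * (depth + 1.0) / (zero * (depth - i))
    for i in range(idx, depth):
        pf[i] = pf[i + 1]
        pz[i] = pz[i + 1]
        po[i] = po[i + 1]
    return depth


@njit(cache=False)
def _unwound_sum(pz, po, pw, m, idx):
    depth = m - 1
    one = po[idx]
    zero = pz[idx]
    nxt = pw[depth]
    total = 0.0
    for i in range(depth - 1, -1, -1):
        if one != 0.0:
            tmp = nxt * (depth + 1.0) / ((i + 1.0) * one)
            total += tmp
            nxt = pw[i] - tmp * zero * (depth - i) / (depth + 1.0)
        elif zero != 0.0:
            total += pw[i] / zero * (depth + 1.0) / (depth - i)
    return total


@njit(cache=False)
def tree_shap_kernel(
    children_left,
    children_right,
    feature,
    threshold,
    cover,
    values,
    x,
    phi,
):
    """Accumulate one tree's attributions for one sample into phi (p, n_out)."""
    n_nodes = children_left.shape[0]
    max_path = n_nodes + 2
    pf = np.empty(max_path, dtype=np.int64)
    pz = np.empty(max_path, dtype=np.float64)
    po = np.empty(max_path, dtype=np.float64)
    pw = np.empty(max_path, dtype=np.float64)
    m = 0

    # frame: node, parent_zero, parent_one, parent_feature, phase,
    #        hot, cold, hz, cz, iz, io, split, merged(0/1)
    stack_node = np.empty(max_path, dtype=np.int64)
    stack_pzero = np.empty(max_path, dtype=np.float64)
    stack_pone = np.empty(max_path, dtype=np.float64)
    stack_pfeat = np.empty(max_path, dtype=np.int64)
    stack_phase = np.empty(max_path, dtype=np.int64)
    stack_hot = np.empty(max_path, dtype=np.int64)
    stack_cold = np.empty(max_path, dtype=np.int64)
    stack_hz = np.empty(max_path, dtype=np.float64)
    stack_cz = np.empty(max_path, dtype=np.float64)
    stack_iz = np.empty(max_path, dtype=np.float64)
    stack_io = np.empty(max_path, dtype=np.float64)
    stack_split = np.empty(max_path, dtype=np.int64)
    stack_merged = np.empty(max_path, dtype=np.int64)

    sp = 0
    stack_node[0] = 0
    stack_pzero[0] = 1.0
    stack_pone[0] = 1.0
    stack_pfeat[0] = -1
    stack_phase[0] = 0
    sp = 1

    while sp > 0:
        top = sp - 1
        phase = stack_phase[top]
        node = stack_node[top]
        if phase == 0:
            m = _extend(
                pf, pz, po, pw, m,
                stack_pzero[top], stack_pone[top], stack_pfeat[top],
            )
            left = children_left[node]
            if left == -1:
                depth = m - 1
                for i in range(1, depth + 1):
                    w = _unwound_sum(pz, po, pw, m, i)
                    scale = w * (po[i] - pz[i])
                    for o in range(values.shape[1]):
                        phi[pf[i], o] += scale * values[node, o]
                # undo own extend and pop
                idx = 0
                for i in range(m):
                    if pf[i] == stack_pfeat[top]:
                        idx = i
                        break
                m = _unwind(pf, pz, po, pw, m, idx)
                sp -= 1
            else:
                right = children_right[node]
                split = feature[node]
                if x[split] <= threshold[node]:
                    hot, cold = left, right
                else:
                    hot, cold = right, left
                hz = cover[hot] / cover[node]
                cz = cover[cold] / cover[node]
                iz = 1.0
                io = 1.0
                merged = 0
                for i in range(1, m):
                    if pf[i] == split:
                        iz = pz[i]
                        io = po[i]
                        m = _unwind(pf, pz, po, pw, m, i)
                        merged = 1
                        break
                stack_phase[top] = 1
                stack_hot[top] = hot
                stack_cold[top] = cold
                stack_hz[top] = hz
                stack_cz[top] = cz
                stack_iz[top] = iz
                stack_io[top] = io
                stack_split[top] = split
                stack_merged[top] = merged
                # push hot child
                stack_node[sp] = hot
                stack_pzero[sp] = hz * iz
                stack_pone[sp] = io
                stack_pfeat[sp] = split
                stack_phase[sp] = 0
                sp += 1
        elif phase == 1:
            stack_phase[top] = 2
            stack_node[sp] = stack_cold[top]
            stack_pzero[sp] = stack_cz[top] * stack_iz[top]
            stack_pone[sp] = 0.0
            stack_pfeat[sp] = stack_split[top]
            stack_phase[sp] = 0
            sp += 1
        else:  # phase == 2: both children done
            if stack_merged[top] == 1:
                m = _extend(
                    pf, pz, po, pw, m,
                    stack_iz[top], stack_io[top], stack_split[top],
                )
            # undo own extend
            idx = 0
            for i in range(m):
                if pf[i] == stack_pfeat[top]:
                    idx = i
                    break
            m = _unwind(pf, pz, po, pw, m, idx)
            sp -= 1
    return phi
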