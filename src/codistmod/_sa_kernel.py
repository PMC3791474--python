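"""Numba kernels for modularity evaluation, simulated annealing and the
exhaustive small-graph oracle.

Graphs enter as CSR adjacency (``indptr``, ``indices``) over nodes
``0..n-1``.  Modularity follows the within-module edge fraction minus the
degree-expectation term:

    M = sum_s [ l_s / L  -  (d_s / 2L)^2 ]

with ``l_s`` the number of edges inside module ``s``, ``d_s`` the summed
degree of its members and ``L`` the total edge count.

The annealer follows the functional-cartography recipe: at temperature T it
proposes f*n^2 single-node reassignments and f*n collective merge/split
moves, accepting deteriorations with probability exp(dM/T), cooling
multiplicatively and halting after a fixed number of temperature stages
without improvement of the best partition found.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def modularity_value(indptr, indices, labels, L):
    """M for an explicit labelling; O(n + 2L)."""
    n = labels.shape[0]
    n_mod = 0
    for i in range(n):
        if labels[i] + 1 > n_mod:
            n_mod = labels[i] + 1
    within2 = np.zeros(n_mod, dtype=np.int64)   # 2 * l_s
    deg = np.zeros(n_mod, dtype=np.int64)       # d_s
    for i in range(n):
        li = labels[i]
        deg[li] += indptr[i + 1] - indptr[i]
        for jj in range(indptr[i], indptr[i + 1]):
            if labels[indices[jj]] == li:
                within2[li] += 1
    m = 0.0
    twoL = 2.0 * L
    for s in range(n_mod):
        m += within2[s] / twoL - (deg[s] / twoL) ** 2
    return m


@njit(cache=True, inline="always")
def _links_to(indptr, indices, labels, i, target):
    k = 0
    for jj in range(indptr[i], indptr[i + 1]):
        if labels[indices[jj]] == target:
            k += 1
    return k


@njit(cache=True, inline="always")
def _delta_move(indptr, indices, labels, mod_deg, L, i, a, b):
    """dM for moving node i from module a to module b (pre-move degrees)."""
    ki = indptr[i + 1] - indptr[i]
    kia = _links_to(indptr, indices, labels, i, a)
    kib = _links_to(indptr, indices, labels, i, b)
    return (kib - kia) / L + ki * (mod_deg[a] - mod_deg[b] - ki) / (2.0 * L * L)


@njit(cache=True)
def _edges_between(indptr, indices, labels, members, n_members, b):
    e = 0
    for t in range(n_members):
        i = members[t]
        for jj in range(indptr[i], indptr[i + 1]):
            if labels[indices[jj]] == b:
                e += 1
    return e


@njit(cache=True)
def anneal_kernel(indptr, indices, L, T0, cooling, f, stall_max, max_stages,
                  seed, labels0):
    """Simulated-annealing modularity maximization.

    Returns (best_labels, best_M, n_stages).  ``labels0`` is the starting
    partition (commonly each node in its own module).
    """
    np.random.seed(seed)
    n = labels0.shape[0]
    labels = labels0.copy()
    mod_deg = np.zeros(n, dtype=np.int64)
    for i in range(n):
        mod_deg[labels[i]] += indptr[i + 1] - indptr[i]

    cur = modularity_value(indptr, indices, labels, L)
    best = cur
    best_labels = labels.copy()

    n_single = max(1, int(f * n * n))
    n_coll = max(1, int(f * n))
    T = T0
    stall = 0
    stage = 0
    scratch = np.empty(n, dtype=np.int64)
    sub_labels = np.empty(n, dtype=np.int64)

    while stall < stall_max and stage < max_stages:
        improved = False
        accepted = 0
        proposed = 0
        # --- single-node moves (target = module of a random node, so
        # consolidation is favoured; new modules arise from split moves)
        for _ in range(n_single):
            i = np.random.randint(0, n)
            a = labels[i]
            b = labels[np.random.randint(0, n)]
            if b == a:
                continue
            proposed += 1
            dm = _delta_move(indptr, indices, labels, mod_deg, L, i, a, b)
            if dm > 0.0 or np.random.random() < np.exp(dm / T):
                ki = indptr[i + 1] - indptr[i]
                labels[i] = b
                mod_deg[a] -= ki
                mod_deg[b] += ki
                cur += dm
                accepted += 1
                if cur > best + 1e-12:
                    best = cur
                    best_labels[:] = labels
                    improved = True
        # --- collective moves
        for _ in range(n_coll):
            if np.random.random() < 0.5:
                # merge two occupied modules
                a = labels[np.random.randint(0, n)]
                b = labels[np.random.randint(0, n)]
                if a == b:
                    continue
                nm = 0
                for i in range(n):
                    if labels[i] == a:
                        scratch[nm] = i
                        nm += 1
                e_ab = _edges_between(indptr, indices, labels, scratch, nm, b)
                dm = e_ab / L - mod_deg[a] * mod_deg[b] / (2.0 * L * L)
                if dm > 0.0 or np.random.random() < np.exp(dm / T):
                    for t in range(nm):
                        labels[scratch[t]] = b
                    mod_deg[b] += mod_deg[a]
                    mod_deg[a] = 0
                    cur += dm
                    if cur > best + 1e-12:
                        best = cur
                        best_labels[:] = labels
                        improved = True
            else:
                # split: random bisection of one module refined by a short
                # local anneal, then Metropolis on the net change
                a = labels[np.random.randint(0, n)]
                nm = 0
                for i in range(n):
                    if labels[i] == a:
                        scratch[nm] = i
                        nm += 1
                if nm < 2:
                    continue
                # find a free label for the second half
                b = -1
                for cand in range(n):
                    if mod_deg[cand] == 0:
                        b = cand
                        break
                if b < 0:
                    continue
                sub_labels[:] = labels
                deg_a = mod_deg[a]
                deg_b = 0
                dtot = 0.0
                for t in range(nm):
                    if np.random.random() < 0.5:
                        i = scratch[t]
                        dm = _delta_move(indptr, indices, sub_labels, mod_deg,
                                         L, i, a, b)
                        ki = indptr[i + 1] - indptr[i]
                        sub_labels[i] = b
                        mod_deg[a] -= ki
                        mod_deg[b] += ki
                        dtot += dm
                # local refinement sweeps at the current temperature
                for _ in range(2 * nm):
                    i = scratch[np.random.randint(0, nm)]
                    src = sub_labels[i]
                    dst = b if src == a else a
                    dm = _delta_move(indptr, indices, sub_labels, mod_deg, L,
                                     i, src, dst)
                    if dm > 0.0 or np.random.random() < np.exp(dm / T):
                        ki = indptr[i + 1] - indptr[i]
                        sub_labels[i] = dst
                        mod_deg[src] -= ki
                        mod_deg[dst] += ki
                        dtot += dm
                if dtot > 0.0 or np.random.random() < np.exp(dtot / T):
                    labels[:] = sub_labels
                    cur += dtot
                    if cur > best + 1e-12:
                        best = cur
                        best_labels[:] = labels
                        improved = True
                else:  # revert bookkeeping
                    mod_deg[a] = deg_a
                    mod_deg[b] = deg_b
        T *= cooling
        stage += 1
        # a stage counts towards the stall limit only once the chain is
        # effectively frozen (low acceptance); hot stages rarely improve the
        # best yet must not trigger early termination
        frozen = proposed == 0 or accepted < 0.02 * proposed + 1
        if improved:
            stall = 0
        elif frozen:
            stall += 1

    # guard against float drift: recompute the reported modularity
    best = modularity_value(indptr, indices, best_labels, L)
    return best_labels, best, stage


@njit(cache=True)
def exhaustive_kernel(indptr, indices, L):
    """Global maximum-M partition by enumerating all restricted-growth
    strings; ties keep the lexicographically first assignment."""
    n = indptr.shape[0] - 1
    a = np.zeros(n, dtype=np.int64)        # current RGS
    bmax = np.zeros(n, dtype=np.int64)     # bmax[i] = 1 + max(a[:i])
    best = modularity_value(indptr, indices, a, L)
    best_labels = a.copy()
    for i in range(1, n):
        bmax[i] = 1
    while True:
        # advance to next RGS (lexicographic)
        i = n - 1
        while i > 0 and a[i] >= bmax[i]:
            a[i] = 0
            i -= 1
        if i == 0:
            break
        a[i] += 1
        for j in range(i + 1, n):
            bmax[j] = max(bmax[j - 1], a[j - 1] + 1)
        m = modularity_value(indptr, indices, a, L)
        if m > best + 1e-12:
            best = m
            best_labels[:] = a
    return best_labels, best
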