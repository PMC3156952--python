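"""Numba hot loops for the coalescent engine.

Time is measured backward in units of 2*N_ref generations; population sizes
are relative to N_ref.  A compiled timeline is a set of intervals; within
interval j population p has size ``size0[j, p] * exp(grow[j, p] * (t - times[j]))``
and at the start of interval j the listed merges move every lineage of a
source population into its destination.

Coalescence times inside an interval are drawn by closed-form inversion of
the integrated pair-coalescence intensity, so exponential epochs are exact.
"""

from __future__ import annotations

import numpy as np
from numba import njit

BIG = 1.0e18


@njit(cache=True, inline="always")
def _coal_candidate(k2: float, a: float, b: float, dt0: float, E: float) -> float:
    """Waiting time to coalescence from offset dt0 into an interval where the
    population size is a*exp(b*dt); E is a unit-exponential deviate."""
    if b == 0.0:
        return E * a / k2
    y = E * b * a * np.exp(b * dt0) / k2
    if y >= 1.0:
        return BIG
    return -np.log(1.0 - y) / b


@njit(cache=True)
def branch_sfs_kernel(times, size0, grow, merge_at, merge_src, merge_dst,
                      lin_pop0, lin_flat0, out, n_reps, seed):
    """Accumulate expected branch lengths per joint descendant configuration.

    lin_pop0: starting population index per lineage.
    lin_flat0: starting flat tensor index per lineage (its own stride digit).
    out: flat float64 tensor, modified in place (sum over replicates).
    """
    np.random.seed(seed)
    nb = times.shape[0]
    npop = size0.shape[1]
    nlin = lin_pop0.shape[0]
    lin_pop = np.empty(nlin, np.int64)
    lin_flat = np.empty(nlin, np.int64)
    alive = np.empty(nlin, np.bool_)
    for _rep in range(n_reps):
        for l in range(nlin):
            lin_pop[l] = lin_pop0[l]
            lin_flat[l] = lin_flat0[l]
            alive[l] = True
        n_alive = nlin
        t = 0.0
        j = 0
        while n_alive > 1:
            t_end = times[j + 1] if j + 1 < nb else BIG
            best_s = BIG
            best_p = -1
            for p in range(npop):
                k = 0
                for l in range(nlin):
                    if alive[l] and lin_pop[l] == p:
                        k += 1
                if k < 2:
                    continue
                k2 = 0.5 * k * (k - 1)
                s = _coal_candidate(k2, size0[j, p], grow[j, p], t - times[j],
                                    np.random.exponential(1.0))
                if s < best_s:
                    best_s = s
                    best_p = p
            if best_p >= 0 and t + best_s < t_end:
                dt = best_s
                for l in range(nlin):
                    if alive[l]:
                        out[lin_flat[l]] += dt
                t += dt
                k = 0
                for l in range(nlin):
                    if alive[l] and lin_pop[l] == best_p:
                        k += 1
                i1 = np.random.randint(k)
                i2 = np.random.randint(k - 1)
                if i2 >= i1:
                    i2 += 1
                c1 = -1
                c2 = -1
                cnt = 0
                for l in range(nlin):
                    if alive[l] and lin_pop[l] == best_p:
                        if cnt == i1:
                            c1 = l
                        if cnt == i2:
                            c2 = l
                        cnt += 1
                lin_flat[c1] += lin_flat[c2]
                alive[c2] = False
                n_alive -= 1
            else:
                if t_end >= BIG:
                    # malformed timeline: cannot coalesce further
                    return -1
                dt = t_end - t
                for l in range(nlin):
                    if alive[l]:
                        out[lin_flat[l]] += dt
                t = t_end
                j += 1
                for m in range(merge_at.shape[0]):
                    if merge_at[m] == j:
                        for l in range(nlin):
                            if alive[l] and lin_pop[l] == merge_src[m]:
                                lin_pop[l] = merge_dst[m]
    return 0


@njit(cache=True)
def genealogy_kernel(times, size0, grow, merge_at, merge_src, merge_dst,
                     mig, lin_pop0, seed,
                     parent, child1, child2, node_time):
    """Simulate one genealogy, recording topology and node times.

    ``mig[j, p, q]`` is the backward per-lineage migration rate p->q in
    interval j.  Sampled lineages are nodes 0..n-1; internal nodes are
    appended in coalescence order.  Returns 0 on success, -1 when the
    timeline cannot bring all lineages to a common ancestor.
    """
    np.random.seed(seed)
    nb = times.shape[0]
    npop = size0.shape[1]
    n = lin_pop0.shape[0]
    n_nodes = 2 * n - 1
    lin_node = np.empty(n, np.int64)   # node id per active slot
    lin_pop = np.empty(n, np.int64)
    alive = np.empty(n, np.bool_)
    for l in range(n):
        lin_node[l] = l
        lin_pop[l] = lin_pop0[l]
        alive[l] = True
        node_time[l] = 0.0
    for v in range(n_nodes):
        parent[v] = -1
        child1[v] = -1
        child2[v] = -1
    nxt = n
    n_alive = n
    t = 0.0
    j = 0
    while n_alive > 1:
        t_end = times[j + 1] if j + 1 < nb else BIG
        best_s = BIG
        best_p = -1
        is_mig = False
        mig_from = -1
        mig_to = -1
        for p in range(npop):
            k = 0
            for l in range(n):
                if alive[l] and lin_pop[l] == p:
                    k += 1
            if k >= 2:
                k2 = 0.5 * k * (k - 1)
                s = _coal_candidate(k2, size0[j, p], grow[j, p], t - times[j],
                                    np.random.exponential(1.0))
                if s < best_s:
                    best_s = s
                    best_p = p
                    is_mig = False
            if k >= 1:
                for q in range(npop):
                    r = mig[j, p, q]
                    if r > 0.0:
                        s = np.random.exponential(1.0) / (k * r)
                        if s < best_s:
                            best_s = s
                            best_p = p
                            is_mig = True
                            mig_from = p
                            mig_to = q
        if best_p >= 0 and t + best_s < t_end:
            t += best_s
            k = 0
            for l in range(n):
                if alive[l] and lin_pop[l] == best_p:
                    k += 1
            if is_mig:
                pick = np.random.randint(k)
                cnt = 0
                for l in range(n):
                    if alive[l] and lin_pop[l] == mig_from:
                        if cnt == pick:
                            lin_pop[l] = mig_to
                            break
                        cnt += 1
            else:
                i1 = np.random.randint(k)
                i2 = np.random.randint(k - 1)
                if i2 >= i1:
                    i2 += 1
                c1 = -1
                c2 = -1
                cnt = 0
                for l in range(n):
                    if alive[l] and lin_pop[l] == best_p:
                        if cnt == i1:
                            c1 = l
                        if cnt == i2:
                            c2 = l
                        cnt += 1
                node = nxt
                nxt += 1
                node_time[node] = t
                parent[lin_node[c1]] = node
                parent[lin_node[c2]] = node
                child1[node] = lin_node[c1]
                child2[node] = lin_node[c2]
                lin_node[c1] = node
                alive[c2] = False
                n_alive -= 1
        else:
            if t_end >= BIG:
                return -1
            t = t_end
            j += 1
            for m in range(merge_at.shape[0]):
                if merge_at[m] == j:
                    for l in range(n):
                        if alive[l] and lin_pop[l] == merge_src[m]:
                            lin_pop[l] = merge_dst[m]
    return 0


@njit(cache=True)
def tajima_null_kernel(n, S, n_reps, seed, out_d, a1, e1, e2):
    """Null distribution of Tajima's D: Kingman genealogies with exactly S
    mutations multinomially placed on branches by length."""
    np.random.seed(seed)
    freq_len = np.empty(n, np.float64)       # branch length subtending i leaves
    count = np.empty(n, np.int64)            # descendant count per active lineage
    pair_norm = n * (n - 1) / 2.0
    for rep in range(n_reps):
        for i in range(n):
            freq_len[i] = 0.0
            count[i] = 1
        k = n
        while k > 1:
            rate = k * (k - 1) / 2.0
            dt = np.random.exponential(1.0 / rate)
            for l in range(k):
                freq_len[count[l]] += dt if count[l] < n else 0.0
            i1 = np.random.randint(k)
            i2 = np.random.randint(k - 1)
            if i2 >= i1:
                i2 += 1
            count[i1] = count[i1] + count[i2]
            count[i2] = count[k - 1]
            k -= 1
        total = 0.0
        for i in range(1, n):
            total += freq_len[i]
        # multinomial placement of S mutations over frequency classes
        pi = 0.0
        s_left = S
        rem = total
        for i in range(1, n):
            if s_left <= 0:
                break
            p = freq_len[i] / rem if rem > 0 else 0.0
            if p > 1.0:
                p = 1.0
            s_i = np.random.binomial(s_left, p)
            pi += s_i * i * (n - i)
            s_left -= s_i
            rem -= freq_len[i]
        pi /= pair_norm
        denom = np.sqrt(e1 * S + e2 * S * (S - 1.0))
        out_d[rep] = (pi - S / a1) / denom if denom > 0 else 0.0
    return 0
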