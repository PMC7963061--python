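"""Numba kernel for the Wright-Fisher inversion model.

Implements, on preallocated flat arrays, exactly the model defined in
:mod:`invfate.reproduction`: soft-selection parent sampling, Poisson
recombination initiations resolved into crossovers or rightward
gene-conversion tracts, crossover suppression inside the inversion span of
heterokaryotype parents, independent assortment of chromosomes, Poisson
mutation over coding positions with gamma-distributed effects, and pruning of
whole-population fixations into a substitution log.

State layout
------------
Haplotypes live in two (2N, cap) int32 buffers holding mutation-table slots
sorted by (genome position, uid); a parity flag in ``state`` says which buffer
is current. The mutation table is a set of parallel arrays indexed by slot,
with a free-list for slot reuse; ``uid`` is a monotonically increasing global
identifier that survives slot recycling.

All randomness flows through numba's global NumPy-legacy RNG, seeded once per
run via :func:`seed_rng`.

Status codes returned by :func:`advance`: the generation being built is only
committed on OK/LOST/FIXED; GROW_* and SUBLOG_FULL ask the caller to enlarge
buffers (or drain the log) and call again.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_INV_LOST = 1
STATUS_INV_FIXED = 2
STATUS_EXTINCT = 3
STATUS_GROW_HAP = 4
STATUS_GROW_MUT = 5
STATUS_SUBLOG_FULL = 6

# indices into the int64 ``state`` vector
ST_PARITY = 0
ST_MNEXT = 1   # high-water mark of the mutation table
ST_FREETOP = 2  # free-list depth
ST_UID = 3     # next uid
ST_GEN = 4     # current generation
ST_INV = 5     # 1 once the inversion is being tracked


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def shared_fitness(ids_a, na, ids_b, nb, m_gpos, m_uid, m_s):
    """Product of max(0, 1+s) over mutations present on both haplotypes."""
    w = 1.0
    i = 0
    j = 0
    while i < na and j < nb:
        sa = ids_a[i]
        sb = ids_b[j]
        if sa == sb:
            f = 1.0 + m_s[sa]
            if f < 0.0:
                f = 0.0
            w *= f
            i += 1
            j += 1
        else:
            pa = m_gpos[sa]
            pb = m_gpos[sb]
            if pa < pb or (pa == pb and m_uid[sa] < m_uid[sb]):
                i += 1
            else:
                j += 1
    return w


@njit(cache=True)
def fitness_into(hap, hn, arr, m_gpos, m_uid, m_s, s_het, W):
    """Fitness of every individual of the current buffer into W (length N)."""
    n_hap = hap.shape[0]
    N = n_hap // 2
    for i in range(N):
        a = 2 * i
        b = a + 1
        w = shared_fitness(hap[a], hn[a], hap[b], hn[b], m_gpos, m_uid, m_s)
        if arr[a] != arr[b]:
            w *= 1.0 + s_het
        W[i] = w
    return W


@njit(cache=True)
def homozygote_fitness(ids, n, m_s):
    """Fitness of a hypothetical homozygote for one haplotype (no s_het)."""
    w = 1.0
    for j in range(n):
        f = 1.0 + m_s[ids[j]]
        if f < 0.0:
            f = 0.0
        w *= f
    return w


@njit(cache=True)
def advance(
    hap0, n0, arr0, hap1, n1, arr1,
    m_gpos, m_s, m_origin, m_uid, m_count, m_inuse, m_remove,
    free_stack, state,
    chrom_bounds, coding_lo, coding_cum,
    mu_per_gamete, r_total_init, p_co, lam,
    dfe_shape, dfe_scale, span_lo, span_hi, s_het,
    n_gens, sub_log, sub_n,
    W, Wc, co_buf, gc_lo_buf, gc_hi_buf,
):
    n_hap = hap0.shape[0]
    N = n_hap // 2
    cap = hap0.shape[1]
    mcap = m_gpos.shape[0]
    n_chrom = chrom_bounds.shape[0] - 1
    L_tot = chrom_bounds[n_chrom]
    coding_total = coding_cum[coding_cum.shape[0] - 1]
    gens_done = 0

    for _g in range(n_gens):
        # -- capacity pre-checks (conservative; mid-generation aborts retry) --
        free_avail = (mcap - state[ST_MNEXT]) + state[ST_FREETOP]
        if free_avail < 2 * n_hap + 64:
            return STATUS_GROW_MUT, gens_done
        if sub_log.shape[0] - sub_n[0] < 256:
            return STATUS_SUBLOG_FULL, gens_done
        if state[ST_PARITY] == 0:
            hs, ns, ars = hap0, n0, arr0
            hd, nd, ard = hap1, n1, arr1
        else:
            hs, ns, ars = hap1, n1, arr1
            hd, nd, ard = hap0, n0, arr0
        maxn = 0
        for h in range(n_hap):
            if ns[h] > maxn:
                maxn = ns[h]
        if maxn > cap - 64:
            return STATUS_GROW_HAP, gens_done

        # -- fitness of the current generation -------------------------------
        wsum = 0.0
        for i in range(N):
            a = 2 * i
            b = a + 1
            w = shared_fitness(hs[a], ns[a], hs[b], ns[b], m_gpos, m_uid, m_s)
            if ars[a] != ars[b]:
                w *= 1.0 + s_het
            W[i] = w
            wsum += w
            Wc[i] = wsum
        if wsum <= 0.0:
            return STATUS_EXTINCT, gens_done
        gen = state[ST_GEN] + 1

        # -- build 2N gametes -------------------------------------------------
        for g in range(n_hap):
            u = np.random.random() * wsum
            lo = 0
            hi_i = N - 1
            while lo < hi_i:
                mid = (lo + hi_i) >> 1
                if Wc[mid] > u:
                    hi_i = mid
                else:
                    lo = mid + 1
            p = lo
            if np.random.random() < 0.5:
                a = 2 * p
                b = 2 * p + 1
            else:
                a = 2 * p + 1
                b = 2 * p

            # recombination initiations + independent assortment toggles
            nco = 0
            for c in range(1, n_chrom):
                if np.random.random() < 0.5:
                    co_buf[nco] = chrom_bounds[c]
                    nco += 1
            ngc = 0
            n_ev = np.random.poisson(r_total_init) if r_total_init > 0.0 else 0
            for _e in range(n_ev):
                pos = np.random.randint(0, L_tot)
                if np.random.random() < p_co:
                    if nco < co_buf.shape[0]:
                        co_buf[nco] = pos
                        nco += 1
                else:
                    tl = np.random.poisson(lam)
                    c = 0
                    for cc in range(n_chrom):
                        if pos < chrom_bounds[cc + 1]:
                            c = cc
                            break
                    hi_t = pos + tl
                    if hi_t > chrom_bounds[c + 1]:
                        hi_t = chrom_bounds[c + 1]
                    if hi_t > pos and ngc < gc_lo_buf.shape[0]:
                        gc_lo_buf[ngc] = pos
                        gc_hi_buf[ngc] = hi_t
                        ngc += 1

            # crossover suppression in heterokaryotype parents
            if span_lo >= 0 and ars[a] != ars[b]:
                k = 0
                for j in range(nco):
                    x = co_buf[j]
                    if not (span_lo <= x < span_hi):
                        co_buf[k] = x
                        k += 1
                nco = k
            for j in range(1, nco):  # insertion sort (tiny)
                x = co_buf[j]
                k = j - 1
                while k >= 0 and co_buf[k] > x:
                    co_buf[k + 1] = co_buf[k]
                    k -= 1
                co_buf[k + 1] = x

            # arrangement flag from the crossover phase at the span
            if span_lo >= 0:
                ph = 0
                for j in range(nco):
                    if co_buf[j] <= span_lo:
                        ph += 1
                    else:
                        break
                ard[g] = ars[a] if (ph & 1) == 0 else ars[b]
            else:
                ard[g] = ars[a]

            # merge parental mutations by source
            ia = 0
            ib = 0
            nout = 0
            ico = 0
            na_ = ns[a]
            nb_ = ns[b]
            row_a = hs[a]
            row_b = hs[b]
            out = hd[g]
            while ia < na_ or ib < nb_:
                take_a = False
                both = False
                if ia >= na_:
                    slot = row_b[ib]
                elif ib >= nb_:
                    slot = row_a[ia]
                    take_a = True
                else:
                    sa = row_a[ia]
                    sb = row_b[ib]
                    if sa == sb:
                        slot = sa
                        both = True
                    else:
                        pa = m_gpos[sa]
                        pb = m_gpos[sb]
                        if pa < pb or (pa == pb and m_uid[sa] < m_uid[sb]):
                            slot = sa
                            take_a = True
                        else:
                            slot = sb
                x = m_gpos[slot]
                while ico < nco and co_buf[ico] <= x:
                    ico += 1
                ph = ico & 1
                ingc = 0
                for j in range(ngc):
                    if gc_lo_buf[j] <= x < gc_hi_buf[j]:
                        ingc = 1
                        break
                src = ph ^ ingc  # 0 -> haplotype a contributes, 1 -> b
                if both:
                    if nout >= cap:
                        return STATUS_GROW_HAP, gens_done
                    out[nout] = slot
                    nout += 1
                    ia += 1
                    ib += 1
                elif take_a:
                    if src == 0:
                        if nout >= cap:
                            return STATUS_GROW_HAP, gens_done
                        out[nout] = slot
                        nout += 1
                    ia += 1
                else:
                    if src == 1:
                        if nout >= cap:
                            return STATUS_GROW_HAP, gens_done
                        out[nout] = slot
                        nout += 1
                    ib += 1

            # de novo mutation
            k_new = np.random.poisson(mu_per_gamete) if mu_per_gamete > 0.0 else 0
            for _m in range(k_new):
                if nout >= cap:
                    return STATUS_GROW_HAP, gens_done
                u2 = np.random.randint(0, coding_total)
                lo_s = 0
                hi_s = coding_cum.shape[0] - 1
                while lo_s < hi_s - 1:
                    mid = (lo_s + hi_s) >> 1
                    if coding_cum[mid] <= u2:
                        lo_s = mid
                    else:
                        hi_s = mid
                gpos = coding_lo[lo_s] + (u2 - coding_cum[lo_s])
                sval = -np.random.gamma(dfe_shape, dfe_scale)
                if state[ST_FREETOP] > 0:
                    state[ST_FREETOP] -= 1
                    slot = free_stack[state[ST_FREETOP]]
                else:
                    slot = state[ST_MNEXT]
                    state[ST_MNEXT] += 1
                m_gpos[slot] = gpos
                m_s[slot] = sval
                m_origin[slot] = gen
                m_uid[slot] = state[ST_UID]
                state[ST_UID] += 1
                m_inuse[slot] = 1
                m_remove[slot] = 0
                lo_i = 0
                hi_i2 = nout
                while lo_i < hi_i2:
                    mid = (lo_i + hi_i2) >> 1
                    sm = out[mid]
                    pm = m_gpos[sm]
                    if pm < gpos or (pm == gpos and m_uid[sm] < m_uid[slot]):
                        lo_i = mid + 1
                    else:
                        hi_i2 = mid
                for j in range(nout, lo_i, -1):
                    out[j] = out[j - 1]
                out[lo_i] = slot
                nout += 1
            nd[g] = nout

        # -- recount, free lost slots, prune whole-population fixations -------
        mnext = state[ST_MNEXT]
        for slot in range(mnext):
            m_count[slot] = 0
        for h in range(n_hap):
            row = hd[h]
            for j in range(nd[h]):
                m_count[row[j]] += 1
        nrem = 0
        for slot in range(mnext):
            if m_inuse[slot] == 1:
                c = m_count[slot]
                if c == 0:
                    m_inuse[slot] = 0
                    free_stack[state[ST_FREETOP]] = slot
                    state[ST_FREETOP] += 1
                elif c == n_hap:
                    r = sub_n[0]
                    sub_log[r, 0] = m_uid[slot]
                    sub_log[r, 1] = m_gpos[slot]
                    sub_log[r, 2] = m_s[slot]
                    sub_log[r, 3] = m_origin[slot]
                    sub_log[r, 4] = gen
                    sub_n[0] = r + 1
                    m_remove[slot] = 1
                    nrem += 1
        if nrem > 0:
            for h in range(n_hap):
                row = hd[h]
                k = 0
                nh = nd[h]
                for j in range(nh):
                    if m_remove[row[j]] == 0:
                        row[k] = row[j]
                        k += 1
                nd[h] = k
            for slot in range(mnext):
                if m_remove[slot] == 1:
                    m_remove[slot] = 0
                    m_inuse[slot] = 0
                    free_stack[state[ST_FREETOP]] = slot
                    state[ST_FREETOP] += 1

        # -- commit -----------------------------------------------------------
        state[ST_GEN] = gen
        state[ST_PARITY] = 1 - state[ST_PARITY]
        gens_done += 1
        if state[ST_INV] == 1:
            ic = 0
            for h in range(n_hap):
                ic += ard[h]
            if ic == 0:
                return STATUS_INV_LOST, gens_done
            if ic == n_hap:
                return STATUS_INV_FIXED, gens_done
    return STATUS_OK, gens_done
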