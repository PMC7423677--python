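"""Numba-compiled hot loop of the MCMC sampler.

State layout (per locus ``l``; ``nnod = 2*ntips - 1`` nodes, tips first):

* ``par/ch1/ch2[l, i]`` — tree links (-1 where absent), ``tms[l, i]`` node
  times, ``npo[l, i]`` population at the node (tips: sampled population).
* ``nev/evt/evb[l, i, k]`` — migration events on the edge above node ``i``
  in increasing time order; ``evb`` holds the band index.  Backward in
  time an event moves the lineage from the band's target population into
  its source population.  Between events the population changes only by
  implicit merges at divergence times.
* ``pat[l, q, tip]`` — IUPAC-bitmask site patterns, ``patw`` their counts.

All functions mutate arrays in place and restore them on rejection.  The
pure-Python implementations in :mod:`mscmig.inference` are the reference
these kernels are tested against.
"""

import numpy as np
from numba import njit

INF = 1.0e30


@njit(cache=True)
def _pop_at(ppar, pend, p, t):
    while pend[p] <= t:
        p = ppar[p]
    return p


@njit(cache=True)
def _recompute_bounds(ppar, tau, pend, bsrc, btgt, blo, bhi):
    npop = ppar.shape[0]
    for p in range(npop):
        pend[p] = INF if ppar[p] < 0 else tau[ppar[p]]
    for b in range(bsrc.shape[0]):
        blo[b] = max(tau[bsrc[b]], tau[btgt[b]])
        bhi[b] = min(pend[bsrc[b]], pend[btgt[b]])


@njit(cache=True)
def _locus_loglik(par, ch1, ch2, tms, pat, patw, npat, partial):
    nnod = par.shape[0]
    order = np.argsort(tms)
    root = -1
    for idx in range(nnod):
        i = order[idx]
        if par[i] < 0:
            root = i
        if ch1[i] < 0:
            for q in range(npat):
                code = pat[q, i]
                for s in range(4):
                    partial[i, q, s] = (code >> s) & 1
        else:
            for q in range(npat):
                for s in range(4):
                    partial[i, q, s] = 1.0
            for ci in range(2):
                c = ch1[i] if ci == 0 else ch2[i]
                d = tms[i] - tms[c]
                if d < 0.0:
                    return -INF
                e = np.exp(-4.0 * d / 3.0)
                ps = 0.25 + 0.75 * e
                pdf = 0.25 - 0.25 * e
                for q in range(npat):
                    tot = (partial[c, q, 0] + partial[c, q, 1]
                           + partial[c, q, 2] + partial[c, q, 3])
                    for s in range(4):
                        partial[i, q, s] *= (pdf * tot
                                             + (ps - pdf) * partial[c, q, s])
    ll = 0.0
    for q in range(npat):
        site = 0.25 * (partial[root, q, 0] + partial[root, q, 1]
                       + partial[root, q, 2] + partial[root, q, 3])
        if site <= 0.0:
            return -INF
        ll += patw[q] * np.log(site)
    return ll


@njit(cache=True)
def _locus_segments(par, ch1, ch2, tms, npo, nev, evt, evb,
                    ppar, tau, pend, bsrc, btgt, blo, bhi,
                    seg_s, seg_e, seg_p, seg_lin, final_pop):
    """Residence segments of every edge; returns count or -1 if invalid."""
    nnod = par.shape[0]
    ns = 0
    for i in range(nnod):
        final_pop[i] = -1
    for i in range(nnod):
        pr = par[i]
        if pr < 0:
            continue
        t0 = tms[i]
        p = npo[i]
        top = tms[pr]
        if top < t0:
            return -1
        prev = t0
        for k in range(nev[i]):
            x = evt[i, k]
            b = evb[i, k]
            if x < prev or x > top:
                return -1
            prev = x
            while pend[p] <= x:
                seg_s[ns] = t0
                seg_e[ns] = pend[p]
                seg_p[ns] = p
                seg_lin[ns] = i
                ns += 1
                t0 = pend[p]
                p = ppar[p]
            seg_s[ns] = t0
            seg_e[ns] = x
            seg_p[ns] = p
            seg_lin[ns] = i
            ns += 1
            if p != btgt[b]:
                return -1
            if not (blo[b] <= x < bhi[b]):
                return -1
            p = bsrc[b]
            t0 = x
        while pend[p] <= top:
            seg_s[ns] = t0
            seg_e[ns] = pend[p]
            seg_p[ns] = p
            seg_lin[ns] = i
            ns += 1
            t0 = pend[p]
            p = ppar[p]
        seg_s[ns] = t0
        seg_e[ns] = top
        seg_p[ns] = p
        seg_lin[ns] = i
        ns += 1
        final_pop[i] = p
    for j in range(nnod):
        if ch1[j] >= 0:
            c1 = ch1[j]
            c2 = ch2[j]
            if final_pop[c1] >= 0 and final_pop[c1] != npo[j]:
                return -1
            if final_pop[c2] >= 0 and final_pop[c2] != npo[j]:
                return -1
    return ns


@njit(cache=True)
def _locus_stats(par, ch1, ch2, tms, npo, nev, evt, evb,
                 ppar, tau, pend, bsrc, btgt, blo, bhi,
                 seg_s, seg_e, seg_p, seg_lin, final_pop,
                 bps, kbuf, st_nc, st_pi, st_nm, st_me):
    """Sufficient statistics of one locus genealogy.

    Fills per-population coalescence counts ``st_nc`` and pair-time
    integrals ``st_pi`` (coefficient of ``2/theta``), and per-band event
    counts ``st_nm`` and exposure integrals ``st_me`` (coefficient of
    ``M``).  Returns 0, or -1 if the genealogy is inconsistent.
    """
    nnod = par.shape[0]
    npop = ppar.shape[0]
    nband = bsrc.shape[0]
    for p in range(npop):
        st_nc[p] = 0.0
        st_pi[p] = 0.0
    for b in range(nband):
        st_nm[b] = 0.0
        st_me[b] = 0.0
    ns = _locus_segments(par, ch1, ch2, tms, npo, nev, evt, evb,
                         ppar, tau, pend, bsrc, btgt, blo, bhi,
                         seg_s, seg_e, seg_p, seg_lin, final_pop)
    if ns < 0:
        return -1
    for j in range(nnod):
        if ch1[j] >= 0:
            st_nc[npo[j]] += 1.0
    for i in range(nnod):
        for k in range(nev[i]):
            st_nm[evb[i, k]] += 1.0
    nb = 0
    for s in range(ns):
        bps[nb] = seg_s[s]
        nb += 1
        bps[nb] = seg_e[s]
        nb += 1
    sub = bps[:nb]
    sub.sort()
    for z in range(nb - 1):
        a = sub[z]
        c = sub[z + 1]
        if c <= a:
            continue
        mid = 0.5 * (a + c)
        dt = c - a
        for p in range(npop):
            kbuf[p] = 0
        for s in range(ns):
            if seg_s[s] <= mid and mid < seg_e[s]:
                kbuf[seg_p[s]] += 1
        for p in range(npop):
            kp = kbuf[p]
            if kp >= 2:
                st_pi[p] += dt * kp * (kp - 1) * 0.5
        for b in range(nband):
            if blo[b] <= mid and mid < bhi[b]:
                st_me[b] += dt * kbuf[btgt[b]]
    return 0


@njit(cache=True)
def _dens_from_stats(st_nc, st_pi, st_nm, st_me, theta, bM):
    logd = 0.0
    for p in range(theta.shape[0]):
        if st_nc[p] > 0.0:
            logd += st_nc[p] * np.log(2.0 / theta[p])
        logd -= (2.0 / theta[p]) * st_pi[p]
    for b in range(bM.shape[0]):
        if st_nm[b] > 0.0:
            if bM[b] <= 0.0:
                return -INF
            logd += st_nm[b] * np.log(bM[b])
        logd -= bM[b] * st_me[b]
    return logd


@njit(cache=True)
def _locus_dens(par, ch1, ch2, tms, npo, nev, evt, evb,
                ppar, tau, pend, bsrc, btgt, blo, bhi, theta, bM,
                seg_s, seg_e, seg_p, seg_lin, final_pop,
                bps, kbuf, st_nc, st_pi, st_nm, st_me):
    ok = _locus_stats(par, ch1, ch2, tms, npo, nev, evt, evb,
                      ppar, tau, pend, bsrc, btgt, blo, bhi,
                      seg_s, seg_e, seg_p, seg_lin, final_pop,
                      bps, kbuf, st_nc, st_pi, st_nm, st_me)
    if ok < 0:
        return -INF
    return _dens_from_stats(st_nc, st_pi, st_nm, st_me, theta, bM)


@njit(cache=True)
def _last_pop_of_edge(npo_i, nev_i, evb_i, bsrc):
    """Population of the lineage just after its last explicit event."""
    if nev_i == 0:
        return npo_i
    return bsrc[evb_i[nev_i - 1]]


# ---------------------------------------------------------------------------
# Moves
# ---------------------------------------------------------------------------

@njit(cache=True)
def _move_node_slide(l, ntips, par, ch1, ch2, tms, npo, nev, evt, evb,
                     ppar, tau, pend, bsrc, btgt, blo, bhi, theta, bM,
                     pat, patw, npat, partial,
                     seg_s, seg_e, seg_p, seg_lin, final_pop, bps, kbuf,
                     st_nc, st_pi, st_nm, st_me, ll, cdens, w_node, acc):
    nnod = 2 * ntips - 1
    parl = par[l]
    ch1l = ch1[l]
    ch2l = ch2[l]
    tmsl = tms[l]
    npol = npo[l]
    nevl = nev[l]
    evtl = evt[l]
    evbl = evb[l]
    for i in range(ntips, nnod):
        acc[0, 1] += 1.0
        a = ch1l[i]
        b = ch2l[i]
        lo = tmsl[a] if nevl[a] == 0 else evtl[a, nevl[a] - 1]
        lob = tmsl[b] if nevl[b] == 0 else evtl[b, nevl[b] - 1]
        if lob > lo:
            lo = lob
        if parl[i] >= 0:
            hi = evtl[i, 0] if nevl[i] > 0 else tmsl[parl[i]]
        else:
            hi = INF
        told = tmsl[i]
        tnew = told + (2.0 * np.random.random() - 1.0) * w_node
        ok = False
        for _ in range(64):
            if tnew < lo:
                tnew = 2.0 * lo - tnew
            elif tnew > hi:
                tnew = 2.0 * hi - tnew
            else:
                ok = True
                break
        if not ok or tnew < lo or tnew > hi:
            continue
        base_a = _last_pop_of_edge(npol[a], nevl[a], evbl[a], bsrc)
        base_b = _last_pop_of_edge(npol[b], nevl[b], evbl[b], bsrc)
        pa = _pop_at(ppar, pend, base_a, tnew)
        pb = _pop_at(ppar, pend, base_b, tnew)
        if pa != pb:
            continue
        q = pa
        if parl[i] >= 0:
            if nevl[i] > 0:
                if _pop_at(ppar, pend, q, evtl[i, 0]) != btgt[evbl[i, 0]]:
                    continue
            else:
                if _pop_at(ppar, pend, q, tmsl[parl[i]]) != npol[parl[i]]:
                    continue
        qold = npol[i]
        tmsl[i] = tnew
        npol[i] = q
        nd = _locus_dens(parl, ch1l, ch2l, tmsl, npol, nevl, evtl, evbl,
                         ppar, tau, pend, bsrc, btgt, blo, bhi, theta, bM,
                         seg_s, seg_e, seg_p, seg_lin, final_pop,
                         bps, kbuf, st_nc, st_pi, st_nm, st_me)
        if nd <= -INF:
            tmsl[i] = told
            npol[i] = qold
            continue
        nl = _locus_loglik(parl, ch1l, ch2l, tmsl, pat[l], patw[l],
                           npat[l], partial)
        logr = (nd - cdens[l]) + (nl - ll[l])
        if logr >= 0.0 or np.log(np.random.random()) < logr:
            cdens[l] = nd
            ll[l] = nl
            acc[0, 0] += 1.0
        else:
            tmsl[i] = told
            npol[i] = qold


@njit(cache=True)
def _move_event_slides(l, ntips, par, ch1, ch2, tms, npo, nev, evt, evb,
                       ppar, tau, pend, bsrc, btgt, blo, bhi, theta, bM,
                       seg_s, seg_e, seg_p, seg_lin, final_pop, bps, kbuf,
                       st_nc, st_pi, st_nm, st_me, ll, cdens, acc):
    nnod = 2 * ntips - 1
    parl = par[l]
    ch1l = ch1[l]
    ch2l = ch2[l]
    tmsl = tms[l]
    npol = npo[l]
    nevl = nev[l]
    evtl = evt[l]
    evbl = evb[l]
    for i in range(nnod):
        if parl[i] < 0:
            continue
        for k in range(nevl[i]):
            acc[1, 1] += 1.0
            b = evbl[i, k]
            tgt = btgt[b]
            a = tmsl[i] if k == 0 else evtl[i, k - 1]
            c = tmsl[parl[i]] if k == nevl[i] - 1 else evtl[i, k + 1]
            prev_base = npol[i] if k == 0 else bsrc[evbl[i, k - 1]]
            # residence of the lineage in the band target
            if prev_base != tgt:
                pchain = prev_base
                while ppar[pchain] >= 0 and pchain != tgt:
                    pchain = ppar[pchain]
                if pchain != tgt:
                    continue
                if tau[tgt] > a:
                    a = tau[tgt]
            lo = a if a > blo[b] else blo[b]
            hi = c if c < bhi[b] else bhi[b]
            if hi <= lo:
                continue
            xold = evtl[i, k]
            xnew = lo + np.random.random() * (hi - lo)
            evtl[i, k] = xnew
            nd = _locus_dens(parl, ch1l, ch2l, tmsl, npol, nevl, evtl, evbl,
                             ppar, tau, pend, bsrc, btgt, blo, bhi, theta, bM,
                             seg_s, seg_e, seg_p, seg_lin, final_pop,
                             bps, kbuf, st_nc, st_pi, st_nm, st_me)
            logr = nd - cdens[l]
            if nd > -INF and (logr >= 0.0
                              or np.log(np.random.random()) < logr):
                cdens[l] = nd
                acc[1, 0] += 1.0
            else:
                evtl[i, k] = xold


@njit(cache=True)
def _resident_rate(x, p, ns, seg_s, seg_e, seg_p, seg_lin, cand):
    """Residents in population ``p`` covering time ``x``; returns count."""
    n = 0
    for s in range(ns):
        if seg_p[s] == p and seg_s[s] <= x and x < seg_e[s]:
            cand[n] = seg_lin[s]
            n += 1
    return n


@njit(cache=True)
def _next_breakpoint(x, nb, bps):
    lo = 0
    hi = nb
    while lo < hi:
        mid = (lo + hi) // 2
        if bps[mid] <= x:
            lo = mid + 1
        else:
            hi = mid
    return bps[lo] if lo < nb else INF


@njit(cache=True)
def _path_logq(x0, p0, x_end, ev_t, ev_b, n_ev, partner,
               ns, seg_s, seg_e, seg_p, seg_lin, cand,
               nb, bps, ppar, pend, bsrc, btgt, blo, bhi, theta, bM):
    """Log-density of a given migration path under the conditional process.

    The path starts at time ``x0`` in population ``p0``, undergoes the
    listed events (times/bands, increasing), and finally coalesces with
    resident lineage ``partner`` at ``x_end``.  Rates: each resident in the
    current population contributes ``2/theta``; each band whose target is
    the current population and whose window covers the current time
    contributes ``M``.  Returns -INF if the path is impossible under the
    residents.
    """
    x = x0
    p = _pop_at(ppar, pend, p0, x)
    logq = 0.0
    ke = 0
    nband = bsrc.shape[0]
    for _ in range(1000000):
        target = ev_t[ke] if ke < n_ev else x_end
        k = _resident_rate(x, p, ns, seg_s, seg_e, seg_p, seg_lin, cand)
        rate = k * 2.0 / theta[p]
        for b in range(nband):
            if btgt[b] == p and blo[b] <= x and x < bhi[b]:
                rate += bM[b]
        nxt = _next_breakpoint(x, nb, bps)
        if nxt < target:
            logq -= rate * (nxt - x)
            x = nxt
            p = _pop_at(ppar, pend, p, x)
            continue
        logq -= rate * (target - x)
        x = target
        if ke < n_ev:
            b = ev_b[ke]
            if btgt[b] != p or not (blo[b] <= x and x < bhi[b]):
                return -INF
            if bM[b] <= 0.0:
                return -INF
            logq += np.log(bM[b])
            p = _pop_at(ppar, pend, bsrc[b], x)
            ke += 1
        else:
            k = _resident_rate(x, p, ns, seg_s, seg_e, seg_p, seg_lin, cand)
            found = False
            for s in range(k):
                if cand[s] == partner:
                    found = True
            if not found:
                return -INF
            logq += np.log(2.0 / theta[p])
            return logq
    return -INF


@njit(cache=True)
def _simulate_path(x0, p0, K, tmp_t, tmp_b,
                   ns, seg_s, seg_e, seg_p, seg_lin, cand,
                   nb, bps, ppar, pend, bsrc, btgt, blo, bhi, theta, bM):
    """Simulate a migration/coalescence path for one detached lineage.

    Returns ``(n_events, partner, y, logq)``; ``partner = -1`` signals
    failure (event capacity exceeded or no coalescence within bounds).
    """
    x = x0
    p = _pop_at(ppar, pend, p0, x)
    logq = 0.0
    m = 0
    nband = bsrc.shape[0]
    for _ in range(1000000):
        k = _resident_rate(x, p, ns, seg_s, seg_e, seg_p, seg_lin, cand)
        crate = 2.0 / theta[p]
        rate = k * crate
        for b in range(nband):
            if btgt[b] == p and blo[b] <= x and x < bhi[b]:
                rate += bM[b]
        nxt = _next_breakpoint(x, nb, bps)
        if rate <= 0.0:
            if nxt >= INF:
                return 0, -1, 0.0, -INF
            x = nxt
            p = _pop_at(ppar, pend, p, x)
            continue
        e = np.random.exponential(1.0 / rate)
        if x + e >= nxt:
            logq -= rate * (nxt - x)
            x = nxt
            p = _pop_at(ppar, pend, p, x)
            continue
        x = x + e
        logq -= rate * e
        u = np.random.random() * rate
        if u < k * crate:
            idx = int(u / crate)
            if idx >= k:
                idx = k - 1
            logq += np.log(crate)
            return m, cand[idx], x, logq
        u -= k * crate
        chosen = -1
        for b in range(nband):
            if btgt[b] == p and blo[b] <= x and x < bhi[b]:
                if u < bM[b]:
                    chosen = b
                    break
                u -= bM[b]
        if chosen < 0:  # numerical slack: retry from the same time
            continue
        if m >= K:
            return 0, -1, 0.0, -INF
        tmp_t[m] = x
        tmp_b[m] = chosen
        m += 1
        logq += np.log(bM[chosen])
        p = _pop_at(ppar, pend, bsrc[chosen], x)
    return 0, -1, 0.0, -INF


@njit(cache=True)
def _save_locus(l, par, ch1, ch2, tms, npo, nev, evt, evb,
                spar, sch1, sch2, stms, snpo, snev, sevt, sevb):
    nnod = par.shape[1]
    for i in range(nnod):
        spar[i] = par[l, i]
        sch1[i] = ch1[l, i]
        sch2[i] = ch2[l, i]
        stms[i] = tms[l, i]
        snpo[i] = npo[l, i]
        snev[i] = nev[l, i]
        for k in range(nev[l, i]):
            sevt[i, k] = evt[l, i, k]
            sevb[i, k] = evb[l, i, k]


@njit(cache=True)
def _restore_locus(l, par, ch1, ch2, tms, npo, nev, evt, evb,
                   spar, sch1, sch2, stms, snpo, snev, sevt, sevb):
    nnod = par.shape[1]
    for i in range(nnod):
        par[l, i] = spar[i]
        ch1[l, i] = sch1[i]
        ch2[l, i] = sch2[i]
        tms[l, i] = stms[i]
        npo[l, i] = snpo[i]
        nev[l, i] = snev[i]
        for k in range(snev[i]):
            evt[l, i, k] = sevt[i, k]
            evb[l, i, k] = sevb[i, k]


@njit(cache=True)
def _move_regraft(l, ntips, par, ch1, ch2, tms, npo, nev, evt, evb,
                  ppar, tau, pend, bsrc, btgt, blo, bhi, theta, bM,
                  pat, patw, npat, partial,
                  seg_s, seg_e, seg_p, seg_lin, final_pop, bps, kbuf,
                  st_nc, st_pi, st_nm, st_me, ll, cdens,
                  spar, sch1, sch2, stms, snpo, snev, sevt, sevb,
                  tmp_t, tmp_b, cand, acc):
    nnod = 2 * ntips - 1
    K = evt.shape[2]
    acc[2, 1] += 1.0
    # choose a non-root lineage to move
    i = np.random.randint(nnod)
    for _ in range(64):
        if par[l, i] >= 0:
            break
        i = np.random.randint(nnod)
    if par[l, i] < 0:
        return
    _save_locus(l, par, ch1, ch2, tms, npo, nev, evt, evb,
                spar, sch1, sch2, stms, snpo, snev, sevt, sevb)
    pr = par[l, i]
    sib = ch2[l, pr] if ch1[l, pr] == i else ch1[l, pr]
    gp = par[l, pr]
    t_old = tms[l, pr]
    old_partner = sib
    old_nev = nev[l, i]
    # --- splice out pr: sib's edge absorbs pr's edge
    if gp >= 0:
        if nev[l, sib] + nev[l, pr] > K:
            return
        for k in range(nev[l, pr]):
            evt[l, sib, nev[l, sib] + k] = evt[l, pr, k]
            evb[l, sib, nev[l, sib] + k] = evb[l, pr, k]
        nev[l, sib] += nev[l, pr]
        par[l, sib] = gp
        if ch1[l, gp] == pr:
            ch1[l, gp] = sib
        else:
            ch2[l, gp] = sib
    else:
        par[l, sib] = -1
    nev[l, pr] = 0
    par[l, pr] = -1
    ch1[l, pr] = -1
    ch2[l, pr] = -1
    par[l, i] = -1
    # resident root (trunk owner): the remaining parentless node
    rr = -1
    for j in range(nnod):
        if par[l, j] < 0 and j != pr and j != i:
            rr = j
    # --- resident segments (edges of the spliced forest minus lineage i)
    ns = _locus_segments(par[l], ch1[l], ch2[l], tms[l], npo[l], nev[l],
                         evt[l], evb[l], ppar, tau, pend, bsrc, btgt,
                         blo, bhi, seg_s, seg_e, seg_p, seg_lin, final_pop)
    if ns < 0:
        _restore_locus(l, par, ch1, ch2, tms, npo, nev, evt, evb,
                       spar, sch1, sch2, stms, snpo, snev, sevt, sevb)
        return
    # trunk segments above the resident root (kept migration events, then
    # implicit merges up to the root population, extending to infinity)
    t0 = tms[l, rr]
    p = npo[l, rr]
    for k in range(nev[l, rr]):
        x = evt[l, rr, k]
        b = evb[l, rr, k]
        while pend[p] <= x:
            seg_s[ns] = t0
            seg_e[ns] = pend[p]
            seg_p[ns] = p
            seg_lin[ns] = rr
            ns += 1
            t0 = pend[p]
            p = ppar[p]
        seg_s[ns] = t0
        seg_e[ns] = x
        seg_p[ns] = p
        seg_lin[ns] = rr
        ns += 1
        p = bsrc[b]
        t0 = x
    while pend[p] < INF:
        seg_s[ns] = t0
        seg_e[ns] = pend[p]
        seg_p[ns] = p
        seg_lin[ns] = rr
        ns += 1
        t0 = pend[p]
        p = ppar[p]
    seg_s[ns] = t0
    seg_e[ns] = INF
    seg_p[ns] = p
    seg_lin[ns] = rr
    ns += 1
    # breakpoints: all segment boundaries (includes taus via merges)
    nb = 0
    for s in range(ns):
        if seg_s[s] < INF:
            bps[nb] = seg_s[s]
            nb += 1
        if seg_e[s] < INF:
            bps[nb] = seg_e[s]
            nb += 1
    for p2 in range(tau.shape[0]):
        bps[nb] = tau[p2]
        nb += 1
    sub = bps[:nb]
    sub.sort()
    # --- density of the OLD path under the residents
    logq_old = _path_logq(tms[l, i], npo[l, i], t_old,
                          sevt[i], sevb[i], old_nev, old_partner,
                          ns, seg_s, seg_e, seg_p, seg_lin, cand,
                          nb, bps, ppar, pend, bsrc, btgt, blo, bhi,
                          theta, bM)
    # --- simulate the NEW path
    m, partner, y, logq_new = _simulate_path(
        tms[l, i], npo[l, i], K, tmp_t, tmp_b,
        ns, seg_s, seg_e, seg_p, seg_lin, cand,
        nb, bps, ppar, pend, bsrc, btgt, blo, bhi, theta, bM)
    if partner < 0 or logq_old <= -INF:
        _restore_locus(l, par, ch1, ch2, tms, npo, nev, evt, evb,
                       spar, sch1, sch2, stms, snpo, snev, sevt, sevb)
        return
    # trunk-event rule: never absorb events that would sit above a new root
    if partner == rr:
        for k in range(nev[l, rr]):
            if evt[l, rr, k] > y:
                _restore_locus(l, par, ch1, ch2, tms, npo, nev, evt, evb,
                               spar, sch1, sch2, stms, snpo, snev,
                               sevt, sevb)
                return
    # --- attach
    pcoal = _pop_at(ppar, pend,
                    bsrc[tmp_b[m - 1]] if m > 0 else npo[l, i], y)
    nev[l, i] = m
    for k in range(m):
        evt[l, i, k] = tmp_t[k]
        evb[l, i, k] = tmp_b[k]
    tms[l, pr] = y
    npo[l, pr] = pcoal
    ch1[l, pr] = i if i < partner else partner
    ch2[l, pr] = partner if i < partner else i
    par[l, i] = pr
    if par[l, partner] < 0:  # coalesced with the trunk: pr is the new root
        par[l, partner] = pr
        par[l, pr] = -1
    else:
        p2 = par[l, partner]
        par[l, pr] = p2
        if ch1[l, p2] == partner:
            ch1[l, p2] = pr
        else:
            ch2[l, p2] = pr
        par[l, partner] = pr
        # split partner's events at y
        keep = 0
        for k in range(nev[l, partner]):
            if evt[l, partner, k] <= y:
                keep += 1
        up = nev[l, partner] - keep
        for k in range(up):
            evt[l, pr, k] = evt[l, partner, keep + k]
            evb[l, pr, k] = evb[l, partner, keep + k]
        nev[l, pr] = up
        nev[l, partner] = keep
    nd = _locus_dens(par[l], ch1[l], ch2[l], tms[l], npo[l], nev[l],
                     evt[l], evb[l], ppar, tau, pend, bsrc, btgt, blo, bhi,
                     theta, bM, seg_s, seg_e, seg_p, seg_lin, final_pop,
                     bps, kbuf, st_nc, st_pi, st_nm, st_me)
    if nd <= -INF:
        _restore_locus(l, par, ch1, ch2, tms, npo, nev, evt, evb,
                       spar, sch1, sch2, stms, snpo, snev, sevt, sevb)
        return
    nl = _locus_loglik(par[l], ch1[l], ch2[l], tms[l], pat[l], patw[l],
                       npat[l], partial)
    logr = (nl - ll[l]) + (nd - cdens[l]) + (logq_old - logq_new)
    if logr >= 0.0 or np.log(np.random.random()) < logr:
        ll[l] = nl
        cdens[l] = nd
        acc[2, 0] += 1.0
    else:
        _restore_locus(l, par, ch1, ch2, tms, npo, nev, evt, evb,
                       spar, sch1, sch2, stms, snpo, snev, sevt, sevb)


@njit(cache=True)
def _gamma_logpdf(x, shape, rate):
    return (shape - 1.0) * np.log(x) - rate * x


@njit(cache=True)
def _update_theta_m(nloci, par, ch1, ch2, tms, npo, nev, evt, evb,
                    ppar, tau, pend, bsrc, btgt, blo, bhi, theta, bM,
                    seg_s, seg_e, seg_p, seg_lin, final_pop, bps, kbuf,
                    lst_nc, lst_pi, lst_nm, lst_me,
                    ag_nc, ag_pi, ag_nm, ag_me, cdens,
                    th_a, th_b, m_a, m_b, w_theta, w_m, acc):
    npop = ppar.shape[0]
    nband = bsrc.shape[0]
    for p in range(npop):
        ag_nc[p] = 0.0
        ag_pi[p] = 0.0
    for b in range(nband):
        ag_nm[b] = 0.0
        ag_me[b] = 0.0
    for l in range(nloci):
        _locus_stats(par[l], ch1[l], ch2[l], tms[l], npo[l], nev[l],
                     evt[l], evb[l], ppar, tau, pend, bsrc, btgt, blo, bhi,
                     seg_s, seg_e, seg_p, seg_lin, final_pop, bps, kbuf,
                     lst_nc[l], lst_pi[l], lst_nm[l], lst_me[l])
        for p in range(npop):
            ag_nc[p] += lst_nc[l, p]
            ag_pi[p] += lst_pi[l, p]
        for b in range(nband):
            ag_nm[b] += lst_nm[l, b]
            ag_me[b] += lst_me[l, b]
    for p in range(npop):
        acc[3, 1] += 1.0
        u = (2.0 * np.random.random() - 1.0) * w_theta
        thn = theta[p] * np.exp(u)
        if thn <= 0.0 or not np.isfinite(thn):
            continue
        dlog = np.log(thn) - np.log(theta[p])
        logr = (-ag_nc[p] * dlog
                - 2.0 * ag_pi[p] * (1.0 / thn - 1.0 / theta[p])
                + _gamma_logpdf(thn, th_a, th_b)
                - _gamma_logpdf(theta[p], th_a, th_b)
                + dlog)
        if logr >= 0.0 or np.log(np.random.random()) < logr:
            theta[p] = thn
            acc[3, 0] += 1.0
    for b in range(nband):
        acc[4, 1] += 1.0
        u = (2.0 * np.random.random() - 1.0) * w_m
        mn = bM[b] * np.exp(u)
        if mn <= 0.0 or not np.isfinite(mn):
            continue
        dlog = np.log(mn) - np.log(bM[b])
        logr = (ag_nm[b] * dlog
                - ag_me[b] * (mn - bM[b])
                + _gamma_logpdf(mn, m_a, m_b)
                - _gamma_logpdf(bM[b], m_a, m_b)
                + dlog)
        if logr >= 0.0 or np.log(np.random.random()) < logr:
            bM[b] = mn
            acc[4, 0] += 1.0
    # refresh cached densities under the new parameters
    for l in range(nloci):
        cdens[l] = _dens_from_stats(lst_nc[l], lst_pi[l], lst_nm[l],
                                    lst_me[l], theta, bM)


@njit(cache=True)
def _move_tau(pd_, nloci, ntips, par, ch1, ch2, tms, npo, nev, evt, evb,
              ppar, pc1, pc2, tau, pend, bsrc, btgt, blo, bhi, theta, bM,
              pat, patw, npat, partial,
              seg_s, seg_e, seg_p, seg_lin, final_pop, bps, kbuf,
              st_nc, st_pi, st_nm, st_me, ll, cdens,
              sav_tms, sav_evt, sav_ll, sav_cd, w_tau, tau_a, tau_b, acc):
    acc[5, 1] += 1.0
    c1 = pc1[pd_]
    c2 = pc2[pd_]
    lo = max(tau[c1], tau[c2])
    hi = pend[pd_]
    told = tau[pd_]
    tnew = told + (2.0 * np.random.random() - 1.0) * w_tau
    ok = False
    for _ in range(64):
        if tnew < lo:
            tnew = 2.0 * lo - tnew
        elif tnew > hi:
            tnew = 2.0 * hi - tnew
        else:
            ok = True
            break
    if not ok or tnew <= lo or tnew >= hi:
        return
    # save movable state
    nnod = 2 * ntips - 1
    K = evt.shape[2]
    for l in range(nloci):
        sav_ll[l] = ll[l]
        sav_cd[l] = cdens[l]
        for j in range(nnod):
            sav_tms[l, j] = tms[l, j]
            for k in range(nev[l, j]):
                sav_evt[l, j, k] = evt[l, j, k]
    sc1 = (tnew - tau[c1]) / (told - tau[c1])
    sc2 = (tnew - tau[c2]) / (told - tau[c2])
    is_root = hi >= INF
    shift = tnew - told
    scp = 1.0 if is_root else (hi - tnew) / (hi - told)
    logj = 0.0
    for l in range(nloci):
        for j in range(ntips, nnod):
            q = npo[l, j]
            t = tms[l, j]
            if q == c1:
                tms[l, j] = tau[c1] + (t - tau[c1]) * sc1
                logj += np.log(sc1)
            elif q == c2:
                tms[l, j] = tau[c2] + (t - tau[c2]) * sc2
                logj += np.log(sc2)
            elif q == pd_:
                if is_root:
                    tms[l, j] = t + shift
                else:
                    tms[l, j] = hi - (hi - t) * scp
                    logj += np.log(scp)
        for j in range(nnod):
            for k in range(nev[l, j]):
                tgt = btgt[evb[l, j, k]]
                x = evt[l, j, k]
                if tgt == c1:
                    evt[l, j, k] = tau[c1] + (x - tau[c1]) * sc1
                    logj += np.log(sc1)
                elif tgt == c2:
                    evt[l, j, k] = tau[c2] + (x - tau[c2]) * sc2
                    logj += np.log(sc2)
                elif tgt == pd_:
                    if is_root:
                        evt[l, j, k] = x + shift
                    else:
                        evt[l, j, k] = hi - (hi - x) * scp
                        logj += np.log(scp)
    tau[pd_] = tnew
    _recompute_bounds(ppar, tau, pend, bsrc, btgt, blo, bhi)
    logr = logj + (_gamma_logpdf(tnew, tau_a, tau_b)
                   - _gamma_logpdf(told, tau_a, tau_b))
    valid = True
    for l in range(nloci):
        nd = _locus_dens(par[l], ch1[l], ch2[l], tms[l], npo[l], nev[l],
                         evt[l], evb[l], ppar, tau, pend, bsrc, btgt,
                         blo, bhi, theta, bM,
                         seg_s, seg_e, seg_p, seg_lin, final_pop,
                         bps, kbuf, st_nc, st_pi, st_nm, st_me)
        if nd <= -INF:
            valid = False
            break
        nl = _locus_loglik(par[l], ch1[l], ch2[l], tms[l], pat[l], patw[l],
                           npat[l], partial)
        if nl <= -INF:
            valid = False
            break
        logr += (nd - sav_cd[l]) + (nl - sav_ll[l])
        cdens[l] = nd
        ll[l] = nl
    if valid and (logr >= 0.0 or np.log(np.random.random()) < logr):
        acc[5, 0] += 1.0
        return
    # restore
    tau[pd_] = told
    _recompute_bounds(ppar, tau, pend, bsrc, btgt, blo, bhi)
    for l in range(nloci):
        ll[l] = sav_ll[l]
        cdens[l] = sav_cd[l]
        for j in range(nnod):
            tms[l, j] = sav_tms[l, j]
            for k in range(nev[l, j]):
                evt[l, j, k] = sav_evt[l, j, k]


@njit(cache=True)
def run_chain(iterations, burn_in, sample_every, do_tune, seed,
              ppar, pc1, pc2, tau, theta, bsrc, btgt, bM,
              par, ch1, ch2, tms, npo, nev, evt, evb,
              pat, patw, npat,
              th_a, th_b, tau_a, tau_b, m_a, m_b,
              w_node, w_theta, w_m, w_tau, internal_pops,
              rec_theta, rec_tau, rec_M, rec_ll, rec_it, acc,
              out_ll, out_cd):
    np.random.seed(seed)
    nloci = par.shape[0]
    nnod = par.shape[1]
    ntips = (nnod + 1) // 2
    npop = ppar.shape[0]
    nband = bsrc.shape[0]
    K = evt.shape[2]
    maxpat = pat.shape[1]
    pend = np.empty(npop)
    blo = np.empty(max(nband, 1))
    bhi = np.empty(max(nband, 1))
    _recompute_bounds(ppar, tau, pend, bsrc, btgt, blo, bhi)
    # scratch
    segcap = nnod * (K + npop + 2) + npop + 4
    seg_s = np.empty(segcap)
    seg_e = np.empty(segcap)
    seg_p = np.empty(segcap, dtype=np.int64)
    seg_lin = np.empty(segcap, dtype=np.int64)
    final_pop = np.empty(nnod, dtype=np.int64)
    bps = np.empty(2 * segcap + npop + 4)
    kbuf = np.empty(npop, dtype=np.int64)
    partial = np.empty((nnod, maxpat, 4))
    st_nc = np.empty(npop)
    st_pi = np.empty(npop)
    st_nm = np.empty(max(nband, 1))
    st_me = np.empty(max(nband, 1))
    lst_nc = np.empty((nloci, npop))
    lst_pi = np.empty((nloci, npop))
    lst_nm = np.empty((nloci, max(nband, 1)))
    lst_me = np.empty((nloci, max(nband, 1)))
    ag_nc = np.empty(npop)
    ag_pi = np.empty(npop)
    ag_nm = np.empty(max(nband, 1))
    ag_me = np.empty(max(nband, 1))
    spar = np.empty(nnod, dtype=np.int64)
    sch1 = np.empty(nnod, dtype=np.int64)
    sch2 = np.empty(nnod, dtype=np.int64)
    stms = np.empty(nnod)
    snpo = np.empty(nnod, dtype=np.int64)
    snev = np.empty(nnod, dtype=np.int64)
    sevt = np.empty((nnod, K))
    sevb = np.empty((nnod, K), dtype=np.int64)
    tmp_t = np.empty(K)
    tmp_b = np.empty(K, dtype=np.int64)
    cand = np.empty(nnod + 2, dtype=np.int64)
    sav_tms = np.empty((nloci, nnod))
    sav_evt = np.empty((nloci, nnod, K))
    sav_ll = np.empty(nloci)
    sav_cd = np.empty(nloci)
    ll = np.empty(nloci)
    cdens = np.empty(nloci)
    for l in range(nloci):
        ll[l] = _locus_loglik(par[l], ch1[l], ch2[l], tms[l], pat[l],
                              patw[l], npat[l], partial)
        cdens[l] = _locus_dens(par[l], ch1[l], ch2[l], tms[l], npo[l],
                               nev[l], evt[l], evb[l], ppar, tau, pend,
                               bsrc, btgt, blo, bhi, theta, bM,
                               seg_s, seg_e, seg_p, seg_lin, final_pop,
                               bps, kbuf, st_nc, st_pi, st_nm, st_me)
    # burn-in-only window auto-tune (frozen afterwards): aim for 20-50%
    # acceptance per move class
    tune_every = 250
    prev = np.zeros((6, 2))
    tau_prev = np.zeros((npop, 2))
    tau_cnt = np.zeros((npop, 2))
    rec = 0
    for it in range(iterations):
        for l in range(nloci):
            if ntips > 1:
                _move_node_slide(l, ntips, par, ch1, ch2, tms, npo, nev,
                                 evt, evb, ppar, tau, pend, bsrc, btgt,
                                 blo, bhi, theta, bM, pat, patw, npat,
                                 partial, seg_s, seg_e, seg_p, seg_lin,
                                 final_pop, bps, kbuf, st_nc, st_pi,
                                 st_nm, st_me, ll, cdens, w_node, acc)
                _move_regraft(l, ntips, par, ch1, ch2, tms, npo, nev, evt,
                              evb, ppar, tau, pend, bsrc, btgt, blo, bhi,
                              theta, bM, pat, patw, npat, partial,
                              seg_s, seg_e, seg_p, seg_lin, final_pop,
                              bps, kbuf, st_nc, st_pi, st_nm, st_me,
                              ll, cdens, spar, sch1, sch2, stms, snpo,
                              snev, sevt, sevb, tmp_t, tmp_b, cand, acc)
            if nband > 0:
                _move_event_slides(l, ntips, par, ch1, ch2, tms, npo, nev,
                                   evt, evb, ppar, tau, pend, bsrc, btgt,
                                   blo, bhi, theta, bM,
                                   seg_s, seg_e, seg_p, seg_lin, final_pop,
                                   bps, kbuf, st_nc, st_pi, st_nm, st_me,
                                   ll, cdens, acc)
        _update_theta_m(nloci, par, ch1, ch2, tms, npo, nev, evt, evb,
                        ppar, tau, pend, bsrc, btgt, blo, bhi, theta, bM,
                        seg_s, seg_e, seg_p, seg_lin, final_pop, bps, kbuf,
                        lst_nc, lst_pi, lst_nm, lst_me,
                        ag_nc, ag_pi, ag_nm, ag_me, cdens,
                        th_a, th_b, m_a, m_b, w_theta, w_m, acc)
        for z in range(internal_pops.shape[0]):
            pd_ = internal_pops[z]
            a0 = acc[5, 0]
            a1 = acc[5, 1]
            _move_tau(pd_, nloci, ntips, par, ch1, ch2, tms, npo, nev,
                      evt, evb, ppar, pc1, pc2, tau, pend, bsrc, btgt,
                      blo, bhi, theta, bM, pat, patw, npat, partial,
                      seg_s, seg_e, seg_p, seg_lin, final_pop, bps, kbuf,
                      st_nc, st_pi, st_nm, st_me, ll, cdens,
                      sav_tms, sav_evt, sav_ll, sav_cd, w_tau[pd_],
                      tau_a, tau_b, acc)
            tau_cnt[pd_, 0] += acc[5, 0] - a0
            tau_cnt[pd_, 1] += acc[5, 1] - a1
        if do_tune != 0 and it < burn_in and (it + 1) % tune_every == 0:
            # node / theta / M windows (global)
            for cls in range(5):
                att = acc[cls, 1] - prev[cls, 1]
                if att > 0:
                    rate = (acc[cls, 0] - prev[cls, 0]) / att
                    fac = 1.0
                    if rate > 0.45:
                        fac = 1.4
                    elif rate < 0.20:
                        fac = 1.0 / 1.4
                    if cls == 0:
                        w_node *= fac
                    elif cls == 3:
                        w_theta *= fac
                    elif cls == 4:
                        w_m *= fac
                prev[cls, 0] = acc[cls, 0]
                prev[cls, 1] = acc[cls, 1]
            for z in range(internal_pops.shape[0]):
                pd_ = internal_pops[z]
                att = tau_cnt[pd_, 1] - tau_prev[pd_, 1]
                if att > 0:
                    rate = (tau_cnt[pd_, 0] - tau_prev[pd_, 0]) / att
                    if rate > 0.45:
                        w_tau[pd_] *= 1.4
                    elif rate < 0.20:
                        w_tau[pd_] /= 1.4
                tau_prev[pd_, 0] = tau_cnt[pd_, 0]
                tau_prev[pd_, 1] = tau_cnt[pd_, 1]
        if it >= burn_in and (it - burn_in) % sample_every == 0:
            if rec < rec_ll.shape[0]:
                for p in range(npop):
                    rec_theta[rec, p] = theta[p]
                for z in range(internal_pops.shape[0]):
                    rec_tau[rec, z] = tau[internal_pops[z]]
                for b in range(nband):
                    rec_M[rec, b] = bM[b]
                tot = 0.0
                for l in range(nloci):
                    tot += ll[l]
                rec_ll[rec] = tot
                rec_it[rec] = it
                rec += 1
    for l in range(nloci):
        out_ll[l] = ll[l]
        out_cd[l] = cdens[l]
    return rec

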