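"""Numerical kernel for the layered forward model.

One function evaluates all layers (occupancy f, coactivation/quenching F,
activation efficiency FEaA, window competition R×T, promoter activity M)
for every nucleus on the %EL grid.  The code is written as plain loops so
that it can be JIT-compiled with numba when available; the pure-Python
path is identical and is the one exercised by the exhaustive-enumeration
oracle tests.

Occupancy uses a forward/backward dynamic program over sites sorted by end
coordinate.  Configurations are subsets of mutually non-overlapping sites;
the statistical weight of a configuration is the product of per-site weights
``w_i = K_tf * norm_score_i * [TF]_nu`` times a cooperativity factor ``omega``
for every *consecutively bound* pair of sites of the cooperative TF whose
edge-to-edge gap is within the cooperativity range.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(fn):
            return fn

        return deco


@njit(cache=True)
def _occupancy_one(w, start, end, tfidx, coop_tfid, coop_w, coop_r):
    """Marginal bound probability of each site at one nucleus.

    Sites must be sorted by ``end``.  Returns f (n,) and the total
    partition function Z (for diagnostics).
    """
    n = w.shape[0]
    Z = np.zeros(n)
    # forward: Z[i] = w[i] * (1 + sum_{j compatible} omega(j, i) * Z[j])
    for i in range(n):
        acc = 1.0
        for j in range(i):
            if end[j] <= start[i]:
                om = 1.0
                if (
                    coop_tfid >= 0
                    and tfidx[i] == coop_tfid
                    and tfidx[j] == coop_tfid
                    and (start[i] - end[j]) <= coop_r
                ):
                    om = coop_w
                acc += om * Z[j]
        Z[i] = w[i] * acc
    ztot = 1.0
    for i in range(n):
        ztot += Z[i]
    # backward: B[i] = 1 + sum_{k after i, compatible} w[k] * omega(i, k) * B[k]
    B = np.ones(n)
    for i in range(n - 1, -1, -1):
        acc = 1.0
        for k in range(i + 1, n):
            if start[k] >= end[i]:
                om = 1.0
                if (
                    coop_tfid >= 0
                    and tfidx[i] == coop_tfid
                    and tfidx[k] == coop_tfid
                    and (start[k] - end[i]) <= coop_r
                ):
                    om = coop_w
                acc += w[k] * om * B[k]
        B[i] = acc
    f = np.empty(n)
    for i in range(n):
        f[i] = Z[i] * B[i] / ztot
    return f, ztot


@njit(cache=True)
def forward_layers(
    conc,          # (n_tf, m) concentrations per nucleus
    tfidx,         # (n,) site TF index
    start, end,    # (n,) locus coords, sites sorted by end
    score,         # (n,) normalized PWM scores
    gap,           # (n, n) edge-to-edge distances (0 when touching/overlap)
    overlap,       # (n, n) uint8, 1 when intervals intersect
    act_channel,   # (n,) uint8: 1 = true activator site
    coact_channel, # (n,) uint8: 1 = coactivation-target site (e.g. Hb)
    K,             # (n_tf,)
    Ea_site,       # (n,) activator efficacy per site (0 for pure quenchers)
    Eq_tf,         # (n_tf,) quenching efficiency (0 for activators)
    qr_tf,         # (n_tf,) quenching range in bp
    edge_src,      # (n_edges,) source TF index per coactivation edge
    edge_tgt,      # (n_edges,) target TF index per coactivation edge
    Eco,           # (n_edges,) coactivation efficiency
    corange,       # (n_edges,) coactivation range in bp
    coop_tfid, coop_w, coop_r,
):
    """Occupancy, coactivation/quenching and activation-efficiency layers.

    Returns f, F, FE (each (n, m)) and rep (n, m), the per-site repression
    efficiency E_q*f_q.  Window competition and the promoter law are cheap
    and live in :mod:`thermoexpr.thermo_model`.
    """
    n = tfidx.shape[0]
    m = conc.shape[1]
    f = np.zeros((n, m))
    F = np.zeros((n, m))
    FE = np.zeros((n, m))
    rep = np.zeros((n, m))
    n_edges = edge_src.shape[0]
    w = np.empty(n)
    A = np.empty(n)
    q = np.empty(n)
    for v in range(m):
        for i in range(n):
            w[i] = K[tfidx[i]] * score[i] * conc[tfidx[i], v]
        fv, _ = _occupancy_one(w, start, end, tfidx, coop_tfid, coop_w, coop_r)
        for i in range(n):
            f[i, v] = fv[i]
        # channel split: coactivation converts part of a bound target site
        # into the activator channel
        for i in range(n):
            if act_channel[i] == 1:
                A[i] = fv[i]
                q[i] = 0.0
            elif coact_channel[i] == 1:
                p_nocoact = 1.0
                for e in range(n_edges):
                    if edge_tgt[e] != tfidx[i]:
                        continue
                    for j in range(n):
                        if j == i or tfidx[j] != edge_src[e]:
                            continue
                        if overlap[i, j] == 1:
                            continue
                        if gap[i, j] <= corange[e]:
                            p_nocoact *= 1.0 - Eco[e] * fv[j]
                A[i] = fv[i] * (1.0 - p_nocoact)
                q[i] = fv[i] * p_nocoact
            else:
                A[i] = 0.0
                q[i] = fv[i]
        for i in range(n):
            rep[i, v] = Eq_tf[tfidx[i]] * q[i]
        # quenching: bound quenchers within range multiplicatively reduce
        # the activator channel of nearby sites
        for i in range(n):
            if A[i] <= 0.0:
                F[i, v] = 0.0
                continue
            red = 1.0
            for j in range(n):
                if j == i or q[j] <= 0.0 or overlap[i, j] == 1:
                    continue
                if gap[i, j] <= qr_tf[tfidx[j]]:
                    red *= 1.0 - Eq_tf[tfidx[j]] * q[j]
            F[i, v] = A[i] * red
        for i in range(n):
            FE[i, v] = F[i, v] * Ea_site[i]
    return f, F, FE, rep


HAVE_NUMBA = _HAVE_NUMBA
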