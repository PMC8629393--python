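"""Fused clock-driven simulation kernel (numba) for one stimulus presentation.

This reproduces, step for step and in the same arithmetic order, the
composition of the reference operations ``lgn_step`` → ``adex_step`` →
``clopath_update``/``istdp_update`` under the global update order:

1. draw LGN spikes for this step,
2. update synaptic currents from the *previous* step's spikes (one-step
   transmission delay everywhere),
3. AdEx integration and spike detection (excitatory, then inhibitory
   population),
4. plasticity using this step's presynaptic spikes and postsynaptic
   voltages (traces updated with this step's events before the weight
   update reads them; the depression term reads the pre-update ū̄),
5. weight clipping (inline, on touched entries).

A test cross-checks this kernel against the plain-numpy reference path.
Weight matrices are laid out (pre, post) so that the per-presynaptic-spike
inner loops touch contiguous rows.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# indices into the packed neuron/global parameter vector
NP_C = 0
NP_GL = 1
NP_EL = 2
NP_DELTAT = 3
NP_VTREST = 4
NP_VTMAX = 5
NP_TAUVT = 6
NP_TAUZ = 7
NP_TAUWAD = 8
NP_ISP = 9
NP_A = 10
NP_B = 11
NP_TAUIEXC = 12
NP_TAUIINH = 13
NP_THETAP = 14
NP_THETAM = 15
NP_TAUP = 16
NP_TAUM = 17
NP_TAUUBB = 18
NP_TAUX = 19
NP_TAUISTDP = 20
NP_CLAMPMV = 21
NP_CLAMPSTEPS = 22
NP_SIZE = 23

# columns of the Clopath projection-parameter rows [lgn_e, lgn_i, e_i]
CP_ALTP = 0
CP_ALTD = 1
CP_UREF = 2
CP_WMIN = 3
CP_WMAX = 4

# columns of the iSTDP projection-parameter rows [i_e, i_i]
IP_ETA = 0
IP_RHO = 1
IP_WMIN = 2
IP_WMAX = 3

# flag vector layout
FL_PLASTIC_LE = 0
FL_PLASTIC_LI = 1
FL_PLASTIC_EI = 2
FL_PLASTIC_IE = 3
FL_PLASTIC_II = 4
FL_INH_ON = 5
FL_SIZE = 6

_EXP_ARG_MAX = 30.0


@njit(cache=True)
def _adex_population(
    n, dt, NP, u, VT, wad, z, Iexc, Iinh, clamp, exc_in, inh_in, spikes
):
    """One AdEx step for a population; fills ``spikes`` with 0/1."""
    C = NP[NP_C]
    gL = NP[NP_GL]
    EL = NP[NP_EL]
    DT_ = NP[NP_DELTAT]
    clamp_mv = NP[NP_CLAMPMV]
    for j in range(n):
        Iexc[j] = Iexc[j] * (1.0 - dt / NP[NP_TAUIEXC]) + exc_in[j]
        Iinh[j] = Iinh[j] * (1.0 - dt / NP[NP_TAUIINH]) + inh_in[j]
        spiked = False
        if clamp[j] > 0:
            clamp[j] -= 1
            u[j] = clamp_mv if clamp[j] > 0 else EL
        else:
            arg = (u[j] - VT[j]) / DT_
            if arg > _EXP_ARG_MAX:
                arg = _EXP_ARG_MAX
            # synaptic drive enters at voltage scale (the voltage-pulse
            # approximation: a presynaptic spike of weight w depolarizes by
            # ~w mV through the 1 ms current kernel); intrinsic currents
            # (leak, exponential, adaptation, afterpotential) are in pA/C
            dudt = (
                -gL * (u[j] - EL)
                + gL * DT_ * np.exp(arg)
                - wad[j]
                + z[j]
            ) / C + Iexc[j] - Iinh[j]
            u[j] = u[j] + dt * dudt
            if u[j] > VT[j]:
                spiked = True
                u[j] = clamp_mv
                clamp[j] = int(NP[NP_CLAMPSTEPS])
        VT[j] += dt / NP[NP_TAUVT] * (NP[NP_VTREST] - VT[j])
        z[j] *= 1.0 - dt / NP[NP_TAUZ]
        wad[j] += dt / NP[NP_TAUWAD] * (NP[NP_A] * (u[j] - EL) - wad[j])
        if spiked:
            VT[j] = NP[NP_VTMAX]
            z[j] = NP[NP_ISP]
            wad[j] += NP[NP_B]
            spikes[j] = 1
        else:
            spikes[j] = 0


@njit(cache=True)
def _clopath_proj(
    dt, NP, cp, W, x_pre, pre_spk, u_post, ubp, ubm, ubb_old
):
    """Voltage-STDP weight update for one projection.

    Both terms are accumulated before a single clip, matching the
    reference operation's semantics at the weight bounds.
    """
    n_pre, n_post = W.shape
    a_ltp = cp[CP_ALTP]
    a_ltd = cp[CP_ALTD]
    u_ref = cp[CP_UREF]
    wmin = cp[CP_WMIN]
    wmax = cp[CP_WMAX]
    thp = NP[NP_THETAP]
    thm = NP[NP_THETAM]
    ltp_gate = np.zeros(n_post)
    ltd_gate = np.zeros(n_post)
    ltp_js = np.empty(n_post, dtype=np.int64)
    n_ltp = 0
    for j in range(n_post):
        du = u_post[j] - thp
        dup = ubp[j] - thm
        if du > 0.0 and dup > 0.0:
            ltp_gate[j] = dt * a_ltp * du * dup
            ltp_js[n_ltp] = j
            n_ltp += 1
        dum = ubm[j] - thm
        if dum > 0.0:
            ltd_gate[j] = dt * a_ltd * (ubb_old[j] / u_ref) * dum
    for i in range(n_pre):
        if pre_spk[i]:
            # spiking presynaptic row: both terms, all columns
            for j in range(n_post):
                dw = ltp_gate[j] * x_pre[i] - ltd_gate[j]
                if dw != 0.0:
                    w = W[i, j] + dw
                    if w > wmax:
                        w = wmax
                    elif w < wmin:
                        w = wmin
                    W[i, j] = w
        elif n_ltp > 0 and x_pre[i] != 0.0:
            # potentiation only, on the gated columns
            for k in range(n_ltp):
                j = ltp_js[k]
                w = W[i, j] + ltp_gate[j] * x_pre[i]
                if w > wmax:
                    w = wmax
                elif w < wmin:
                    w = wmin
                W[i, j] = w


@njit(cache=True)
def _istdp_proj(ip, W, x_pre, x_post, pre_spk, post_spk, no_self):
    """Symmetric iSTDP update for one projection (accumulate, then clip)."""
    n_pre, n_post = W.shape
    eta = ip[IP_ETA]
    rho = ip[IP_RHO]
    wmin = ip[IP_WMIN]
    wmax = ip[IP_WMAX]
    any_spk = False
    for i in range(n_pre):
        if pre_spk[i]:
            any_spk = True
    for j in range(n_post):
        if post_spk[j]:
            any_spk = True
    if not any_spk:
        return
    for i in range(n_pre):
        for j in range(n_post):
            if no_self and i == j:
                continue
            dw = 0.0
            if pre_spk[i]:
                dw += eta * (x_post[j] - rho)
            if post_spk[j]:
                dw += eta * x_pre[i]
            if dw != 0.0:
                w = W[i, j] + dw
                if w < wmin:
                    w = wmin
                elif w > wmax:
                    w = wmax
                W[i, j] = w


@njit(cache=True)
def simulate_presentation(
    T,
    dt,
    rates,
    uniforms,
    NP,
    CP,
    IP,
    flags,
    Wle,
    Wli,
    Wei,
    Wie,
    Wii,
    xL,
    sL_prev,
    uE,
    VTE,
    wadE,
    zE,
    IexcE,
    IinhE,
    clampE,
    ubpE,
    ubmE,
    ubbE,
    xcE,
    xiE,
    sE_prev,
    uI,
    VTI,
    wadI,
    zI,
    IexcI,
    IinhI,
    clampI,
    ubpI,
    ubmI,
    ubbI,
    xiI,
    sI_prev,
    recL,
    recE,
    recI,
    recIexcE,
    recIinhE,
    recUE,
):
    """Simulate T steps of one stimulus presentation; all state in place."""
    nL = xL.shape[0]
    nE = uE.shape[0]
    nI = uI.shape[0]
    decay_x = np.exp(-dt / NP[NP_TAUX])
    decay_xi = np.exp(-dt / NP[NP_TAUISTDP])
    inh_on = flags[FL_INH_ON] != 0

    sL_now = np.zeros(nL, dtype=np.uint8)
    sE_now = np.zeros(nE, dtype=np.uint8)
    sI_now = np.zeros(nI, dtype=np.uint8)
    excE_in = np.zeros(nE)
    inhE_in = np.zeros(nE)
    excI_in = np.zeros(nI)
    inhI_in = np.zeros(nI)
    ubb_oldE = np.zeros(nE)
    ubb_oldI = np.zeros(nI)

    for t in range(T):
        # 1. LGN spikes this step (Poisson thinning at 1 ms resolution)
        for i in range(nL):
            p = rates[i] * dt * 1e-3
            if p > 1.0:
                p = 1.0
            sL_now[i] = 1 if uniforms[t, i] < p else 0

        # 2. synaptic drive from previous-step spikes
        for j in range(nE):
            excE_in[j] = 0.0
            inhE_in[j] = 0.0
        for j in range(nI):
            excI_in[j] = 0.0
            inhI_in[j] = 0.0
        for i in range(nL):
            if sL_prev[i]:
                for j in range(nE):
                    excE_in[j] += Wle[i, j]
                for j in range(nI):
                    excI_in[j] += Wli[i, j]
        for i in range(nE):
            if sE_prev[i]:
                for j in range(nI):
                    excI_in[j] += Wei[i, j]
        if inh_on:
            for k in range(nI):
                if sI_prev[k]:
                    for j in range(nE):
                        inhE_in[j] += Wie[k, j]
                    for j in range(nI):
                        if j != k:
                            inhI_in[j] += Wii[k, j]

        # 3. AdEx integration and spike detection
        _adex_population(
            nE, dt, NP, uE, VTE, wadE, zE, IexcE, IinhE, clampE,
            excE_in, inhE_in, sE_now,
        )
        _adex_population(
            nI, dt, NP, uI, VTI, wadI, zI, IexcI, IinhI, clampI,
            excI_in, inhI_in, sI_now,
        )

        # 4. plasticity: traces first (with this step's events), then weights
        # excitatory-rule presynaptic traces: exact impulse response of the
        # driven trace ODE (jump 1/τ_x per spike); iSTDP traces jump by 1
        xjump = 1.0 / NP[NP_TAUX]
        for i in range(nL):
            xL[i] = xL[i] * decay_x + sL_now[i] * xjump
        for j in range(nE):
            xcE[j] = xcE[j] * decay_x + sE_now[j] * xjump
            xiE[j] = xiE[j] * decay_xi + sE_now[j]
            ubpE[j] += dt / NP[NP_TAUP] * (uE[j] - ubpE[j])
            ubmE[j] += dt / NP[NP_TAUM] * (uE[j] - ubmE[j])
            ubb_oldE[j] = ubbE[j]
            d = uE[j] - NP[NP_EL]
            drive = d * d if d > 0.0 else 0.0
            ubbE[j] += dt / NP[NP_TAUUBB] * (drive - ubbE[j])
        for j in range(nI):
            xiI[j] = xiI[j] * decay_xi + sI_now[j]
            ubpI[j] += dt / NP[NP_TAUP] * (uI[j] - ubpI[j])
            ubmI[j] += dt / NP[NP_TAUM] * (uI[j] - ubmI[j])
            ubb_oldI[j] = ubbI[j]
            d = uI[j] - NP[NP_EL]
            drive = d * d if d > 0.0 else 0.0
            ubbI[j] += dt / NP[NP_TAUUBB] * (drive - ubbI[j])

        if flags[FL_PLASTIC_LE]:
            _clopath_proj(dt, NP, CP[0], Wle, xL, sL_now, uE, ubpE, ubmE, ubb_oldE)
        if flags[FL_PLASTIC_LI]:
            _clopath_proj(dt, NP, CP[1], Wli, xL, sL_now, uI, ubpI, ubmI, ubb_oldI)
        if flags[FL_PLASTIC_EI]:
            _clopath_proj(dt, NP, CP[2], Wei, xcE, sE_now, uI, ubpI, ubmI, ubb_oldI)
        if flags[FL_PLASTIC_IE]:
            _istdp_proj(IP[0], Wie, xiI, xiE, sI_now, sE_now, False)
        if flags[FL_PLASTIC_II]:
            _istdp_proj(IP[1], Wii, xiI, xiI, sI_now, sI_now, True)

        # 5. records and spike rotation
        for i in range(nL):
            recL[t, i] = sL_now[i]
            sL_prev[i] = sL_now[i]
        for j in range(nE):
            recE[t, j] = sE_now[j]
            sE_prev[j] = sE_now[j]
            recIexcE[t, j] = IexcE[j]
            recIinhE[t, j] = IinhE[j]
            recUE[t, j] = uE[j]
        for j in range(nI):
            recI[t, j] = sI_now[j]
            sI_prev[j] = sI_now[j]
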