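"""Explicit central-difference time integration kernel for 1-d mass chains.

Compiled with numba for speed: the default time step (1e-7 s) over tens of
milliseconds means a few hundred thousand steps per run, and calibration and
protection sweeps run the chain hundreds of times.

Sign convention: node displacements ``u`` are positive upward (direction of
plate motion).  For an element joining a lower node ``lo`` to an upper node
``hi``, the deflection ``d = u[lo] - u[hi]`` is positive in compression; a
positive element force pushes the nodes apart (``-f`` on ``lo``, ``+f`` on
``hi``).

Element laws (``e_law``):

* 0 linear spring, ``par[0] = k`` (N/m);
* 1 quasi-linear viscoelastic block, ``par = [A (Pa), B, L (m), area (m^2),
  Q, tau (s)]``, compression-only by construction, exact one-term recursive
  relaxation update;
* 2 piecewise-linear curve over deflection magnitude (breakpoints in
  ``c_x`` (m) / ``c_f`` (N), final slope extrapolated);
* 3 arch-coupled fascia: segment compression ``d`` stretches the fascia by
  ``c*d`` (arch-flattening leverage ``c = par[0]``); the resisting force on
  the segment is ``c * curve(c*d)`` for ``d > 0``.

Flags (``e_flag``, laws 0 and 2): 0 both signs, 1 compression-only,
2 tension-only.
"""

import numpy as np
from numba import njit

LAW_LINEAR = 0
LAW_QLV = 1
LAW_CURVE = 2
LAW_FASCIA = 3

FLAG_BOTH = 0
FLAG_COMPRESSION = 1
FLAG_TENSION = 2

STATUS_OK = 0
STATUS_UNSTABLE = 1


@njit(cache=True)
def _curve_eval(x, xs, fs, npts):
    """Piecewise-linear interpolation with final-slope extrapolation.

    Returns (force, local slope).  Domain is x >= 0 with xs[0] = 0.
    """
    if npts < 2:
        return 0.0, 0.0
    for i in range(1, npts):
        if x <= xs[i]:
            slope = (fs[i] - fs[i - 1]) / (xs[i] - xs[i - 1])
            return fs[i - 1] + slope * (x - xs[i - 1]), slope
    slope = (fs[npts - 1] - fs[npts - 2]) / (xs[npts - 1] - xs[npts - 2])
    return fs[npts - 1] + slope * (x - xs[npts - 1]), slope


@njit(cache=True)
def run_chain(masses, prescribed, plate_u, v0,
              e_lo, e_hi, e_law, e_flag, par, c_x, c_f, c_n,
              dt, n_steps, stride, gravity):
    """Advance the chain ``n_steps`` steps of size ``dt``.

    ``plate_u`` (length ``n_steps + 1``) prescribes the plate-node
    displacement when ``prescribed`` is true; otherwise node 0 is a free
    impactor mass with initial velocity ``v0[0]``.

    Returns displacement/velocity/element-force histories sampled every
    ``stride`` steps, energy histories (kinetic, internal work absorbed by
    elements, external work done by the prescribed plate), the accumulated
    plate-contact impulse, and a status flag.
    """
    n_nodes = masses.size
    n_elem = e_lo.size
    u = np.zeros(n_nodes)
    vh = v0.copy()
    if prescribed:
        u[0] = plate_u[0]

    inv_m = np.empty(n_nodes)
    for i in range(n_nodes):
        inv_m[i] = 1.0 / masses[i]
    if prescribed:
        inv_m[0] = 0.0

    h_state = np.zeros(n_elem)
    sige_prev = np.zeros(n_elem)
    d_prev = np.zeros(n_elem)
    f_prev = np.zeros(n_elem)

    n_out = n_steps // stride + 1
    u_hist = np.zeros((n_out, n_nodes))
    v_hist = np.zeros((n_out, n_nodes))
    f_hist = np.zeros((n_out, n_elem))
    ke_hist = np.zeros(n_out)
    int_hist = np.zeros(n_out)
    ext_hist = np.zeros(n_out)
    v_hist[0] = vh
    for i in range(n_nodes):
        if prescribed and i == 0:
            continue
        ke_hist[0] += 0.5 * masses[i] * vh[i] * vh[i]

    internal = 0.0
    ext_work = 0.0
    impulse = 0.0
    status = STATUS_OK
    fnod = np.zeros(n_nodes)
    ke = 0.0
    fplate_prev = 0.0
    du_prev = 0.0

    for step in range(n_steps):
        for i in range(n_nodes):
            fnod[i] = 0.0
        wmax2 = 0.0
        fplate = 0.0
        for e in range(n_elem):
            lo = e_lo[e]
            hi = e_hi[e]
            d = u[lo] - u[hi]
            law = e_law[e]
            f = 0.0
            ktan = 0.0
            if law == LAW_LINEAR:
                k = par[e, 0]
                if e_flag[e] == FLAG_COMPRESSION:
                    if d > 0.0:
                        f = k * d
                        ktan = k
                elif e_flag[e] == FLAG_TENSION:
                    if d < 0.0:
                        f = k * d
                        ktan = k
                else:
                    f = k * d
                    ktan = k
            elif law == LAW_QLV:
                A = par[e, 0]
                B = par[e, 1]
                L = par[e, 2]
                area = par[e, 3]
                Q = par[e, 4]
                tau = par[e, 5]
                eps = d / L if d > 0.0 else 0.0
                ebe = np.exp(B * eps)
                sige = A * (ebe - 1.0)
                decay = np.exp(-dt / tau)
                half = np.exp(-dt / (2.0 * tau))
                h_state[e] = decay * h_state[e] + half * (sige - sige_prev[e])
                sige_prev[e] = sige
                g_inf = 1.0 / (1.0 + Q)
                g1 = Q / (1.0 + Q)
                f = area * (g_inf * sige + g1 * h_state[e])
                if f < 0.0:
                    f = 0.0
                ktan = area / L * A * B * ebe
            elif law == LAW_CURVE:
                if e_flag[e] == FLAG_TENSION:
                    if d < 0.0:
                        fv, sl = _curve_eval(-d, c_x[e], c_f[e], c_n[e])
                        f = -fv
                        ktan = sl
                elif e_flag[e] == FLAG_COMPRESSION:
                    if d > 0.0:
                        f, ktan = _curve_eval(d, c_x[e], c_f[e], c_n[e])
                else:
                    fv, sl = _curve_eval(abs(d), c_x[e], c_f[e], c_n[e])
                    f = fv if d >= 0.0 else -fv
                    ktan = sl
            else:  # LAW_FASCIA
                c = par[e, 0]
                if d > 0.0:
                    fv, sl = _curve_eval(c * d, c_x[e], c_f[e], c_n[e])
                    f = c * fv
                    ktan = c * c * sl
            w2 = ktan * (inv_m[lo] + inv_m[hi])
            if w2 > wmax2:
                wmax2 = w2
            fnod[lo] -= f
            fnod[hi] += f
            if lo == 0:
                fplate += f
            internal += 0.5 * (f_prev[e] + f) * (d - d_prev[e])
            f_prev[e] = f
            d_prev[e] = d

        if dt * dt * wmax2 > 4.0 or not np.isfinite(u[n_nodes - 1]):
            status = STATUS_UNSTABLE
            break

        ke = 0.0
        for i in range(n_nodes):
            if prescribed and i == 0:
                continue
            a = fnod[i] * inv_m[i] - gravity
            vnew = vh[i] + a * dt
            vsync = 0.5 * (vh[i] + vnew)
            ke += 0.5 * masses[i] * vsync * vsync
            vh[i] = vnew
            u[i] += vnew * dt
        if prescribed:
            # trapezoidal work accumulation, lagged one step: the force at
            # the end of the previous increment is this step's fplate
            ext_work += 0.5 * (fplate_prev + fplate) * du_prev
            du_prev = plate_u[step + 1] - plate_u[step]
            fplate_prev = fplate
            u[0] = plate_u[step + 1]
            vh[0] = du_prev / dt
        impulse += fplate * dt

        if (step + 1) % stride == 0:
            j = (step + 1) // stride
            for i in range(n_nodes):
                u_hist[j, i] = u[i]
                v_hist[j, i] = vh[i]
            for e in range(n_elem):
                f_hist[j, e] = f_prev[e]
            ke_hist[j] = ke
            int_hist[j] = internal
            ext_hist[j] = ext_work

    return (u_hist, v_hist, f_hist, ke_hist, int_hist, ext_hist,
            impulse, status)
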